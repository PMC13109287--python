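"""End-to-end orchestration: generate → features → train → analyze → report.

A run is driven by a :class:`RunConfig` (YAML-serialisable).  Every
stochastic stage receives a seed derived from the master seed, and the run
directory records a manifest (config, seeds, stage timings) so deterministic
outputs are reproducible from it.

Layout of a run directory::

    run/
      clouds/      generated point clouds + pair tables (generate stage)
      features/    feature matrices (HDF5) + normaliser stats (features stage)
      model/       trained network weights + training history (train stage)
      reports/     MI ranking, PCA, thresholds, ablation, summary JSON
      manifest.json
"""

from __future__ import annotations

import json
import time
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .analysis import (
    FEATURE_SUBSETS,
    ablation_experiment,
    class_thresholds,
    mi_ranking,
    pca_evr,
    pearson_correlations,
    stratified_auc,
)
from .features import (
    DescriptorCache,
    FeatureNormalizer,
    HydrophobicityScale,
    PairFeatureMatrix,
    build_feature_matrix,
    save_feature_matrices,
)
from .network import (
    CIRNet,
    ClassifierConfig,
    PredictionSet,
    predict,
    roc_curve_auc,
    train,
)
from .synthetic import GeneratorConfig, SyntheticDataset, generate_dataset

__all__ = ["RunConfig", "run", "build_features", "split_indices", "RunResult"]


@dataclass
class RunConfig:
    """Configuration of a full pipeline run."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    classifier: ClassifierConfig = field(default_factory=ClassifierConfig)
    scale_path: str | None = None  # None: packaged surrogate scale
    max_patch_pairs: int = 4  # patch-pair cap per residue pair
    ablation_repetitions: int = 10
    feature_subsets: tuple = FEATURE_SUBSETS
    split_fractions: tuple = (0.70, 0.15, 0.15)
    mi_bins: int | None = None
    seed: int = 0

    def __post_init__(self):
        # the master seed drives every stochastic stage
        self.generator.seed = self.seed
        self.classifier.seed = self.seed + 101

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        gen = GeneratorConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                 for k, v in raw.pop("generator", {}).items()})
        clf = ClassifierConfig(**{k: (tuple(v) if isinstance(v, list) else v)
                                  for k, v in raw.pop("classifier", {}).items()})
        known = {k: v for k, v in raw.items()
                 if k in cls.__dataclass_fields__ and k not in ("generator", "classifier")}
        return cls(generator=gen, classifier=clf, **known)

    def to_yaml(self, path) -> None:
        d = {
            "generator": asdict(self.generator),
            "classifier": asdict(self.classifier),
            **{k: getattr(self, k) for k in
               ("scale_path", "max_patch_pairs", "ablation_repetitions",
                "mi_bins", "seed")},
        }

        def clean(obj):
            if isinstance(obj, tuple):
                return [clean(v) for v in obj]
            if isinstance(obj, dict):
                return {k: clean(v) for k, v in obj.items()}
            return obj

        Path(path).write_text(yaml.safe_dump(clean(d), sort_keys=False))


def build_features(
    dataset: SyntheticDataset,
    scale: HydrophobicityScale | None = None,
    max_patch_pairs: int = 4,
) -> list[PairFeatureMatrix]:
    """Raw feature matrices for every labeled pair of a dataset.

    One descriptor cache per complex: a residue's patch descriptors are
    shared across all pairs and neighbor slots it participates in.
    """
    scale = scale or HydrophobicityScale.surrogate()
    out = []
    for cx in dataset.complexes:
        cache = DescriptorCache()
        for pair in cx.pairs:
            out.append(
                build_feature_matrix(
                    cx.cloud_a, cx.cloud_b, pair, scale,
                    cache=cache, max_pairs=max_patch_pairs,
                )
            )
    return out


def matrices_to_arrays(matrices: list[PairFeatureMatrix]):
    """Stack matrices into (X, y, classes) arrays for training/analysis."""
    x = np.stack([m.matrix for m in matrices])
    y = np.array([1 if m.pair.is_core else 0 for m in matrices])
    classes = np.array([m.pair.pair_class for m in matrices], dtype=object)
    return x, y, classes


def split_indices(n: int, fractions=(0.70, 0.15, 0.15), seed: int = 0):
    """Random train/validation/test index split."""
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    n_tr = int(fractions[0] * n)
    n_va = int(fractions[1] * n)
    return order[:n_tr], order[n_tr : n_tr + n_va], order[n_tr + n_va :]


@dataclass
class RunResult:
    """In-memory results of a pipeline run."""

    dataset: SyntheticDataset
    matrices: list
    normalizer: FeatureNormalizer
    model: CIRNet
    history: dict
    predictions: PredictionSet  # test split
    test_auc: float
    mi_report: pd.DataFrame
    pca_report: object
    threshold_report: object
    ablation: pd.DataFrame | None
    correlations: pd.DataFrame
    summary: dict


def run(config: RunConfig, out_dir=None, stages=("generate", "features", "train", "analyze"),
        log=print) -> RunResult:
    """Execute the pipeline and (optionally) persist artifacts per stage."""
    out = Path(out_dir) if out_dir is not None else None
    t_all = time.time()
    timings = {}
    log(f"[run] master seed {config.seed}")

    t0 = time.time()
    dataset = generate_dataset(config.generator, out / "clouds" if out else None)
    timings["generate"] = time.time() - t0
    log(f"[generate] {config.generator.n_complexes} complexes, "
        f"{dataset.n_core} core + {dataset.n_decoy} decoy pairs "
        f"({timings['generate']:.1f}s)")

    scale = (HydrophobicityScale.from_csv(config.scale_path)
             if config.scale_path else HydrophobicityScale.surrogate())

    t0 = time.time()
    matrices_raw = build_features(dataset, scale, config.max_patch_pairs)
    timings["features"] = time.time() - t0
    log(f"[features] {len(matrices_raw)} pair matrices ({timings['features']:.1f}s)")

    x_raw, y, classes = matrices_to_arrays(matrices_raw)
    tr, va, te = split_indices(len(matrices_raw), config.split_fractions, config.seed + 7)
    normalizer = FeatureNormalizer().fit([matrices_raw[i] for i in tr])
    matrices = normalizer.transform(matrices_raw)
    x, _, _ = matrices_to_arrays(matrices)

    if out:
        (out / "features").mkdir(parents=True, exist_ok=True)
        save_feature_matrices(matrices_raw, out / "features" / "raw.h5")
        save_feature_matrices(matrices, out / "features" / "normalized.h5")
        normalizer.to_json(out / "features" / "normalizer.json")

    t0 = time.time()
    model = CIRNet(config.classifier, input_shape=x.shape[1:])
    history = train(model, x[tr], y[tr], x[va], y[va])
    timings["train"] = time.time() - t0
    preds = predict(model, x[te], labels=y[te], classes=classes[te])
    _, _, _, test_auc = roc_curve_auc(preds)
    log(f"[train] {len(history['loss'])} epochs, test AUC {test_auc:.3f} "
        f"({timings['train']:.1f}s)")

    if out:
        (out / "model").mkdir(parents=True, exist_ok=True)
        model.save(out / "model" / "weights.npz")
        pd.DataFrame(history).to_csv(out / "model" / "history.csv", index=False)

    t0 = time.time()
    flat = x.reshape(len(x), -1)
    scores_all, _ = model.forward(x)
    # MI and PCA need a minimally sized sample; smoke-scale runs skip them
    if len(y) >= 50 and len(y) > flat.shape[1]:
        mi_report = mi_ranking(flat, y, scores_all, bins=config.mi_bins)
        pca_report = pca_evr(flat)
    else:
        log(f"[analyze] only {len(y)} pairs: skipping MI ranking and PCA")
        mi_report, pca_report = None, None
    threshold_report = class_thresholds(
        PredictionSet(scores_all, y, classes)
    )
    direct_raw = x_raw[:, :, 0]  # neighbor-0 raw complementarities
    correlations = pearson_correlations(direct_raw)
    strat = {
        kind: stratified_auc(direct_raw[:, i], y == 1, y == 0)
        for i, kind in enumerate(("shape", "electrostatic", "hydropathy"))
    }
    ablation = None
    if config.ablation_repetitions > 0:
        ablation = ablation_experiment(
            x, y,
            repetitions=config.ablation_repetitions,
            subsets=config.feature_subsets,
            config=config.classifier,
            seed=config.seed + 31,
        )
    timings["analyze"] = time.time() - t0
    log(f"[analyze] done ({timings['analyze']:.1f}s)")

    summary = {
        "n_pairs": int(len(y)),
        "n_core": int(y.sum()),
        "test_auc": float(test_auc),
        "direct_auc": strat,
        "class_thresholds": {k: float(v) for k, v in threshold_report.thresholds.items()},
        "confusion_universal": threshold_report.confusion_universal,
        "confusion_class_specific": threshold_report.confusion_class_specific,
        "timings_s": {k: round(v, 2) for k, v in timings.items()},
        "seed": config.seed,
    }
    if mi_report is not None:
        summary["mi_top_feature"] = mi_report.iloc[0]["feature"]
        summary["mi_true_neighbor0"] = {
            k: float(mi_report.set_index("feature").loc[f"{k}_n0", "mi_true"])
            for k in ("shape", "electrostatic", "hydropathy")
        }
    if pca_report is not None:
        summary["pca_evr"] = [float(v) for v in pca_report.evr[:5]]
        summary["pca_n_selected"] = int(pca_report.n_selected)
    if ablation is not None:
        summary["ablation_median_accuracy"] = {
            k: float(v) for k, v in
            ablation.groupby("subset")["accuracy"].median().items()
        }
    if out:
        (out / "reports").mkdir(parents=True, exist_ok=True)
        if mi_report is not None:
            mi_report.to_csv(out / "reports" / "mi_ranking.csv", index=False)
        if pca_report is not None:
            pd.DataFrame({
                "eigenvalue": pca_report.eigenvalues,
                "evr": pca_report.evr,
                "cumulative_evr": pca_report.cumulative_evr,
            }).to_csv(out / "reports" / "pca.csv", index=False)
        threshold_report.per_class.to_csv(out / "reports" / "class_thresholds.csv", index=False)
        correlations.to_csv(out / "reports" / "correlations.csv", index=False)
        if ablation is not None:
            ablation.to_csv(out / "reports" / "ablation.csv", index=False)
        (out / "reports" / "summary.json").write_text(json.dumps(summary, indent=2))
        manifest = {
            "seed": config.seed,
            "timings_s": summary["timings_s"],
            "generator": {k: (list(v) if isinstance(v, tuple) else v)
                          for k, v in asdict(config.generator).items()},
            "classifier": {k: (list(v) if isinstance(v, tuple) else v)
                           for k, v in asdict(config.classifier).items()},
        }
        (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    log(f"[run] total {time.time() - t_all:.1f}s")
    return RunResult(
        dataset=dataset,
        matrices=matrices,
        normalizer=normalizer,
        model=model,
        history=history,
        predictions=preds,
        test_auc=float(test_auc),
        mi_report=mi_report,
        pca_report=pca_report,
        threshold_report=threshold_report,
        ablation=ablation,
        correlations=correlations,
        summary=summary,
    )
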