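"""Per-residue-pair complementarity features.

Each putative core-interacting pair (A, B) is summarised by a 3×10 matrix:
for the partner residue B itself (neighbor 0) and the nine nearest residues
around it, the columns hold the shape complementarity Z_s and electrostatic
complementarity Z_el (mean Zernike-descriptor distances between patches on
the two residues' surface points, projected with opposite z-orientations)
and the hydropathy complementarity

    H_r = -a (H_A H_B)^2 + b (H_A H_B),

a parabola in the product of the two residues' hydrophobicity indices with
roots at the minimum and maximum index products and vertex near one
(a = 0.033, b = 0.363).  Low values of all three features mean high
complementarity.  Matrices are min–max normalised to [0, 1] with statistics
from the training split only.
"""

from __future__ import annotations

import json
import warnings
from dataclasses import dataclass, field
from importlib import resources
from pathlib import Path

import h5py
import numpy as np
import pandas as pd

from .surface import SurfacePointCloud, ResiduePairLabel
from .zernike import (
    DEFAULT_ORDER,
    DEFAULT_RADIUS,
    PatchError,
    complementarity_distance,
    patch_descriptor,
)

__all__ = [
    "HydrophobicityScale",
    "PairFeatureMatrix",
    "FeatureNormalizer",
    "DescriptorCache",
    "hydropathy_complementarity",
    "residue_complementarity",
    "select_neighbors",
    "build_feature_matrix",
    "save_feature_matrices",
    "load_feature_matrices",
]

FEATURE_ROWS = ("shape", "electrostatic", "hydropathy")
N_NEIGHBORS = 9
NEIGHBOR_RADIUS = 10.0
#: Worst-complementarity fill for padded neighbor columns (post-normalisation).
PAD_VALUE = 1.0
#: Default cap on patch-pair combinations per residue pair.
MAX_PATCH_PAIRS = 16


@dataclass(frozen=True)
class HydrophobicityScale:
    """Residue hydrophobicity indices H plus the parabola coefficients.

    Indices near zero mark hydrophobic residues; higher values mark
    increasingly hydrophilic (polar, then charged) ones.
    """

    values: dict
    a: float = 0.033
    b: float = 0.363

    def index(self, resname: str) -> float:
        try:
            return self.values[resname.upper()]
        except KeyError:
            raise KeyError(f"residue {resname!r} missing from hydrophobicity scale")

    @property
    def vertex_product(self) -> float:
        """Index product at the parabola's maximum, b / 2a."""
        return self.b / (2 * self.a)

    @property
    def vertex_value(self) -> float:
        """Maximum of the parabola, b² / 4a."""
        return self.b**2 / (4 * self.a)

    @property
    def upper_root(self) -> float:
        """Nonzero root of the parabola, b / a."""
        return self.b / self.a

    @classmethod
    def from_csv(cls, path, a: float = 0.033, b: float = 0.363) -> "HydrophobicityScale":
        """Load a two-column (resname, H) CSV scale file ('#' comments)."""
        df = pd.read_csv(path, comment="#")
        df.columns = [c.strip().lower() for c in df.columns]
        if "resname" not in df.columns or "h" not in df.columns:
            raise ValueError(f"{path}: scale file needs 'resname' and 'H' columns")
        vals = {str(r).upper(): float(h) for r, h in zip(df["resname"], df["h"])}
        if any(v < 0 for v in vals.values()):
            raise ValueError("hydrophobicity indices must be non-negative")
        return cls(values=vals, a=a, b=b)

    @classmethod
    def surrogate(cls) -> "HydrophobicityScale":
        """The class-based synthetic surrogate scale shipped with the package.

        The published per-residue index values are not reproduced; the
        surrogate preserves only the class structure (hydrophobic near 0,
        polar intermediate, charged high, maximum product = b/a = 11).
        """
        ref = resources.files("cirfeat").joinpath("data/hydrophobicity_surrogate.csv")
        with resources.as_file(ref) as path:
            return cls.from_csv(path)


def hydropathy_complementarity(
    h_a: float, h_b: float, scale: HydrophobicityScale | None = None
) -> float:
    """Hydropathy complementarity H_r = −a(H_A·H_B)² + b(H_A·H_B).

    Values close to zero (products near either root) mean the two residues
    have matching hydropathy character; values near the vertex (≈ 1) mean a
    hydrophobic/hydrophilic mismatch.
    """
    if h_a < 0 or h_b < 0:
        raise ValueError("hydrophobicity indices must be non-negative")
    a = scale.a if scale is not None else 0.033
    b = scale.b if scale is not None else 0.363
    x = h_a * h_b
    return -a * x**2 + b * x


class DescriptorCache:
    """Memoises patch Zernike descriptors per (chain, point, kind, sign).

    A residue's surface points are reused across every pair and neighbor in
    which it appears, so caching descriptors dominates the pipeline's
    performance profile.
    """

    def __init__(self, radius: float = DEFAULT_RADIUS, order: int = DEFAULT_ORDER):
        self.radius = radius
        self.order = order
        self._store: dict = {}

    def get(self, cloud: SurfacePointCloud, index: int, kind: str, sign: int):
        """Descriptor for the patch centred at ``index``; None if too sparse."""
        key = (cloud.chain, int(index), kind, sign)
        if key not in self._store:
            try:
                self._store[key] = patch_descriptor(
                    cloud, int(index), kind=kind, sign=sign,
                    radius=self.radius, order=self.order,
                )
            except PatchError:
                self._store[key] = None
        return self._store[key]


def _subsample_indices(idx: np.ndarray, k: int) -> np.ndarray:
    """Deterministic evenly spaced subsample of a residue's point indices."""
    if len(idx) <= k:
        return idx
    pick = np.linspace(0, len(idx) - 1, k).round().astype(int)
    return idx[np.unique(pick)]


def residue_complementarity(
    cloud_a: SurfacePointCloud,
    points_a: np.ndarray,
    cloud_b: SurfacePointCloud,
    points_b: np.ndarray,
    kind: str,
    cache: DescriptorCache | None = None,
    max_pairs: int | None = MAX_PATCH_PAIRS,
) -> float:
    """Mean descriptor distance between patches on two residues' points.

    Patches on chain A are projected with their solvent side toward +z and
    those on chain B toward −z (the opposite-verse convention), so low values
    mean complementary surfaces.  With ``max_pairs`` set, at most
    ``⌊√max_pairs⌋`` evenly spaced points per residue are used; ``None``
    computes the exact all-pairs mean.  Points whose patches are too sparse
    are skipped; if all are skipped a :class:`~cirfeat.zernike.PatchError`
    is raised.
    """
    cache = cache or DescriptorCache()
    if max_pairs is not None:
        per = max(1, int(np.sqrt(max_pairs)))
        points_a = _subsample_indices(np.asarray(points_a), per)
        points_b = _subsample_indices(np.asarray(points_b), per)
    desc_a = [d for i in points_a if (d := cache.get(cloud_a, i, kind, +1)) is not None]
    desc_b = [d for i in points_b if (d := cache.get(cloud_b, i, kind, -1)) is not None]
    if not desc_a or not desc_b:
        raise PatchError("all patches too sparse for residue complementarity")
    dists = [complementarity_distance(da, db) for da in desc_a for db in desc_b]
    return float(np.mean(dists))


def select_neighbors(
    cloud_b: SurfacePointCloud,
    key_b: tuple,
    k: int = N_NEIGHBORS,
    radius: float = NEIGHBOR_RADIUS,
) -> list:
    """The partner residue followed by its ``k`` nearest neighbors.

    Neighbors are residues of the same chain whose surface-point centroids
    lie within ``radius`` of the partner's centroid, sorted by ascending
    centroid distance with ties broken by (chain, residue number).  Missing
    neighbors are padded with ``None``.
    """
    cents = cloud_b.residue_centroids()
    if key_b not in cents:
        raise KeyError(f"residue {key_b} not present in cloud {cloud_b.chain}")
    origin = cents[key_b]
    cands = []
    for key, cent in cents.items():
        if key == key_b:
            continue
        d = float(np.linalg.norm(cent - origin))
        if d < radius:
            cands.append((d, key[0], key[1], key))
    cands.sort(key=lambda t: (t[0], t[1], t[2]))
    neigh = [t[3] for t in cands[:k]]
    neigh += [None] * (k - len(neigh))
    return [key_b] + neigh


@dataclass
class PairFeatureMatrix:
    """Raw or normalised 3×10 complementarity matrix for one residue pair.

    Rows follow :data:`FEATURE_ROWS`; column j refers to the j-th entry of
    the partner's neighbor list (column 0 = the putative partner itself).
    ``padded`` marks columns without a real neighbor; after normalisation
    they carry the worst-complementarity fill value 1.0.
    """

    matrix: np.ndarray
    pair: ResiduePairLabel
    padded: np.ndarray = field(default_factory=lambda: np.zeros(10, dtype=bool))
    normalized: bool = False


def build_feature_matrix(
    cloud_a: SurfacePointCloud,
    cloud_b: SurfacePointCloud,
    pair: ResiduePairLabel,
    scale: HydrophobicityScale,
    cache: DescriptorCache | None = None,
    max_pairs: int | None = MAX_PATCH_PAIRS,
) -> PairFeatureMatrix:
    """Assemble the raw 3×10 feature matrix for one labeled residue pair."""
    cache = cache or DescriptorCache()
    pts_a = cloud_a.residue_point_indices()
    pts_b = cloud_b.residue_point_indices()
    if pair.key_a not in pts_a:
        raise KeyError(f"residue {pair.key_a} has no surface points")
    neighbors = select_neighbors(cloud_b, pair.key_b)
    mat = np.full((3, len(neighbors)), np.nan)
    padded = np.zeros(len(neighbors), dtype=bool)
    h_a = scale.index(pair.key_a[2])
    for j, key in enumerate(neighbors):
        if key is None:
            padded[j] = True
            continue
        mat[0, j] = residue_complementarity(
            cloud_a, pts_a[pair.key_a], cloud_b, pts_b[key], "shape", cache, max_pairs
        )
        mat[1, j] = residue_complementarity(
            cloud_a, pts_a[pair.key_a], cloud_b, pts_b[key], "electrostatic", cache, max_pairs
        )
        mat[2, j] = hydropathy_complementarity(h_a, scale.index(key[2]), scale)
    return PairFeatureMatrix(matrix=mat, pair=pair, padded=padded)


class FeatureNormalizer:
    """Per-feature-row min–max scaling to [0, 1], fitted on the training split.

    Values outside the training range are clipped (and counted); padded
    columns are filled with the worst-complementarity value 1.0; a zero-range
    row maps to 0 with a warning.  Idempotent on already-normalised data only
    if refit — apply exactly once per matrix.
    """

    def __init__(self):
        self.row_min: np.ndarray | None = None
        self.row_max: np.ndarray | None = None
        self.n_clipped: int = 0

    def fit(self, matrices: list[PairFeatureMatrix]) -> "FeatureNormalizer":
        stack = np.stack([m.matrix for m in matrices])  # (n, 3, 10)
        valid = ~np.stack([np.broadcast_to(m.padded, m.matrix.shape) for m in matrices])
        flat = np.where(valid, stack, np.nan)
        self.row_min = np.nanmin(flat, axis=(0, 2))
        self.row_max = np.nanmax(flat, axis=(0, 2))
        return self

    def transform(self, matrices: list[PairFeatureMatrix]) -> list[PairFeatureMatrix]:
        if self.row_min is None:
            raise RuntimeError("normalizer not fitted")
        rng = self.row_max - self.row_min
        out = []
        for m in matrices:
            mat = m.matrix.copy()
            for r in range(mat.shape[0]):
                if rng[r] <= 0:
                    warnings.warn(f"feature row {FEATURE_ROWS[r]} has zero range; mapped to 0")
                    mat[r] = 0.0
                else:
                    scaled = (mat[r] - self.row_min[r]) / rng[r]
                    self.n_clipped += int(np.sum((scaled < 0) | (scaled > 1)))
                    mat[r] = np.clip(scaled, 0.0, 1.0)
            mat[:, m.padded] = PAD_VALUE
            out.append(
                PairFeatureMatrix(matrix=mat, pair=m.pair, padded=m.padded, normalized=True)
            )
        return out

    def fit_transform(self, matrices):
        return self.fit(matrices).transform(matrices)

    def to_json(self, path) -> None:
        Path(path).write_text(
            json.dumps({"row_min": list(self.row_min), "row_max": list(self.row_max)})
        )

    @classmethod
    def from_json(cls, path) -> "FeatureNormalizer":
        d = json.loads(Path(path).read_text())
        norm = cls()
        norm.row_min = np.asarray(d["row_min"], dtype=float)
        norm.row_max = np.asarray(d["row_max"], dtype=float)
        return norm


def save_feature_matrices(matrices: list[PairFeatureMatrix], path) -> None:
    """Persist feature matrices with pair metadata to HDF5."""
    with h5py.File(path, "w") as f:
        f.create_dataset("matrix", data=np.stack([m.matrix for m in matrices]))
        f.create_dataset("padded", data=np.stack([m.padded for m in matrices]))
        f.attrs["normalized"] = bool(matrices and matrices[0].normalized)
        meta = [
            (
                m.pair.key_a[0], m.pair.key_a[1], m.pair.key_a[2],
                m.pair.key_b[0], m.pair.key_b[1], m.pair.key_b[2],
                m.pair.label, m.pair.pair_class,
            )
            for m in matrices
        ]
        f.create_dataset("pairs", data=np.array(meta, dtype="S16"))


def feature_matrices_to_csv(matrices: list[PairFeatureMatrix], path) -> None:
    """Long-format CSV export: one row per (pair, feature row, neighbor)."""
    rows = []
    for i, m in enumerate(matrices):
        for r, row_name in enumerate(FEATURE_ROWS):
            for j in range(m.matrix.shape[1]):
                rows.append({
                    "pair_index": i,
                    "chainA": m.pair.key_a[0], "resnumA": m.pair.key_a[1],
                    "chainB": m.pair.key_b[0], "resnumB": m.pair.key_b[1],
                    "label": m.pair.label, "pair_class": m.pair.pair_class,
                    "feature": row_name, "neighbor": j,
                    "value": m.matrix[r, j], "padded": bool(m.padded[j]),
                })
    pd.DataFrame(rows).to_csv(path, index=False)


def load_feature_matrices(path) -> list[PairFeatureMatrix]:
    with h5py.File(path, "r") as f:
        mats = f["matrix"][...]
        padded = f["padded"][...]
        normalized = bool(f.attrs.get("normalized", False))
        meta = [[x.decode() for x in row] for row in f["pairs"][...]]
    out = []
    for mat, pad, row in zip(mats, padded, meta):
        pair = ResiduePairLabel(
            (row[0], int(row[1]), row[2]),
            (row[3], int(row[4]), row[5]),
            row[6],
            row[7],
        )
        out.append(PairFeatureMatrix(matrix=mat, pair=pair, padded=pad, normalized=normalized))
    return out
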