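"""Synthetic protein-complex generator with planted ground truth.

Each synthetic "complex" is a pair of surface point clouds built from smooth
random height fields (sums of seeded Gaussian bumps):

* an *interface disk* per chain, each sampled on its own jittered lattice:
  chain A carries the field h_A, chain B its mirror displaced to a ~2.5 Å
  gap, mixed with an independent field at weight (1 − η_s) plus vertical
  jitter — η_s = 1 with zero noise gives exactly mirrored (perfectly
  complementary) surfaces, η_s = 0 removes the planted shape signal
  entirely;
* a *far disk* per chain, laterally displaced beyond the 6 Å interface rule,
  providing the non-interacting surface from which decoy residues are drawn;
* per-point electrostatic potentials drawn so that interfacial A/B values
  have correlation −ρ_el (sign-complementary) while non-interfacial values
  are independent;
* residues tiled as contiguous Voronoi groups of surface points, with
  chemical classes sampled from a distance-dependent profile (hydrophobic
  core, charged rim), which in turn plants the hydropathy-complementarity
  signal between core pairs.

The generator targets the statistical structure the downstream analyses
assume, not physical realism.  Labels are produced by re-detection with the
interface/core-pair operations themselves, so every emitted complex passes
the 6 Å / 3 Å / 5 Å consistency checks by construction.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .residues import CHARGED, HYDROPHOBIC, POLAR
from .surface import (
    DECOY_LABEL,
    InterfaceRegion,
    ResiduePairLabel,
    SurfacePointCloud,
    _eligible_decoy_residues,
    detect_interface,
    find_core_pairs,
    interface_center,
    write_pair_table,
    write_point_cloud,
)
from .residues import pair_class

__all__ = ["GeneratorConfig", "GroundTruth", "SyntheticComplex", "SyntheticDataset",
           "generate_complex", "generate_dataset"]

_H_LIST = sorted(HYDROPHOBIC)
_P_LIST = sorted(POLAR)
_C_LIST = sorted(CHARGED)


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic benchmark.

    Defaults plant the qualitative structure the analyses probe — strong
    shape and hydropathy signals, a weaker electrostatic one — calibrated so
    the direct (neighbor-0) complementarities separate core pairs from
    decoys with ROC AUCs near the values reported for real complexes
    (shape ≈ 0.8, hydropathy ≈ 0.7, electrostatics ≈ 0.65).
    """

    n_complexes: int = 60
    disk_radius: float = 20.0  # Å, interface and far disks
    spacing: float = 0.5  # Å, lattice spacing (4 surface points per Å²)
    gap: float = 2.5  # Å, vertical separation of the mirrored interfaces
    eta_shape: float = 0.6  # mirror-vs-independent mixing weight in [0, 1]
    rho_el: float = 0.6  # interfacial potential anti-correlation in [-1, 1]
    n_bumps: int = 18
    shape_amplitude: float = 0.8  # Å, bump amplitude bound of height fields
    bump_sigma: tuple = (2.5, 4.5)  # Å, bump width range (shape)
    el_amplitude: float = 1.0  # potential units
    el_sigma: tuple = (3.0, 5.0)
    noise: float = 0.2  # Å, independent vertical jitter per chain
    el_noise: float = 0.05  # potential units, jitter on the potentials
    points_per_residue: int = 64
    core_h_freq: float = 0.70  # hydrophobic frequency at the interface center
    h_slope: float = 0.012  # per Å decay of the H frequency
    core_c_freq: float = 0.07  # charged frequency at the center
    c_slope: float = 0.013  # per Å growth of the C frequency
    far_offset: float = 48.0  # Å, lateral displacement of the far disks
    # decoy residues stay this far from the far-disk edge.  The default keeps
    # them within 8 Å of the far-disk centre, deep enough that their patches
    # never graze the sampled-disk boundary — the same interior geometry as
    # core residues (< 5 Å from the interface centre) — so decoy and core
    # patches share support statistics and differ only in the planted fields.
    edge_margin: float = 12.0
    decoys_per_complex: int | None = None  # None: match the core-pair count
    # optional rejection of geometries whose interface surfaces come closer
    # than this (Å).  Off by default: conditioning the accepted height fields
    # on mutual avoidance induces |correlation| between them, which the
    # sign-blind descriptor distance reads as planted complementarity even
    # at eta_shape = 0.  Occasional surface crossings are statistically
    # harmless for the benchmark.
    min_separation: float | None = None
    max_retries: int = 10
    seed: int = 0

    def validate(self) -> None:
        if not 0 <= self.eta_shape <= 1:
            raise ValueError("eta_shape must be in [0, 1]")
        if not -1 <= self.rho_el <= 1:
            raise ValueError("rho_el must be in [-1, 1]")
        for name in ("core_h_freq", "core_c_freq"):
            if not 0 <= getattr(self, name) <= 1:
                raise ValueError(f"{name} must be in [0, 1]")


class BumpField:
    """Smooth random field: a sum of Gaussian bumps with analytic gradient."""

    def __init__(self, rng: np.random.Generator, radius: float, n_bumps: int,
                 amplitude: float, sigma_range: tuple):
        r = radius * np.sqrt(rng.random(n_bumps))
        t = rng.uniform(0, 2 * np.pi, n_bumps)
        self.centers = np.column_stack([r * np.cos(t), r * np.sin(t)])
        self.amps = rng.uniform(-amplitude, amplitude, n_bumps)
        self.sigmas = rng.uniform(*sigma_range, n_bumps)

    def value(self, xy: np.ndarray) -> np.ndarray:
        d2 = ((xy[:, None, :] - self.centers[None]) ** 2).sum(-1)
        return (self.amps * np.exp(-d2 / (2 * self.sigmas**2))).sum(-1)

    def grad(self, xy: np.ndarray) -> np.ndarray:
        diff = xy[:, None, :] - self.centers[None]  # (n, k, 2)
        g = np.exp(-(diff**2).sum(-1) / (2 * self.sigmas**2))
        w = -self.amps * g / self.sigmas**2
        return (w[:, :, None] * diff).sum(1)


@dataclass
class GroundTruth:
    """Planted parameters and re-detected labels for one complex."""

    index: int
    eta_shape: float
    rho_el: float
    interface_center: np.ndarray
    core_pairs: list = field(default_factory=list)
    decoy_pairs: list = field(default_factory=list)
    retries: int = 0


@dataclass
class SyntheticComplex:
    cloud_a: SurfacePointCloud
    cloud_b: SurfacePointCloud
    iface_a: InterfaceRegion
    iface_b: InterfaceRegion
    truth: GroundTruth

    @property
    def pairs(self) -> list[ResiduePairLabel]:
        return list(self.truth.core_pairs) + list(self.truth.decoy_pairs)


def _disk_lattice(rng: np.random.Generator, radius: float, spacing: float) -> np.ndarray:
    n = int(np.ceil(2 * radius / spacing)) + 1
    ax = np.linspace(-radius, radius, n)
    x, y = np.meshgrid(ax, ax, indexing="ij")
    xy = np.column_stack([x.ravel(), y.ravel()])
    xy = xy + rng.normal(0, 0.15 * spacing, xy.shape)  # break lattice symmetry
    return xy[np.hypot(xy[:, 0], xy[:, 1]) <= radius]


def _tile_residues(rng, points: np.ndarray, per_residue: int,
                   seeds: np.ndarray | None = None) -> np.ndarray:
    """Voronoi tiling of points into contiguous residue-sized groups.

    With explicit planar ``seeds``, points are assigned to those (used to
    tile both interface disks against the same seed set, so residues face
    each other across the interface).  Returns a 0-based group index per
    point.
    """
    if seeds is None:
        n_res = max(1, len(points) // per_residue)
        seeds = points[rng.choice(len(points), size=n_res, replace=False), :2]
    _, grp = cKDTree(seeds).query(points[:, :2], k=1)
    return grp


def _class_profile(cfg: GeneratorConfig, d: float) -> np.ndarray:
    """(H, P, C) class probabilities at distance ``d`` from the interface
    center: hydrophobic-enriched core decaying to a charged-enriched rim
    within 20 Å, then blending to the uniform composition of the remote
    solvent-exposed surface (decoy pairings are near-uniform there)."""
    dd = min(d, 20.0)
    p_h = np.clip(cfg.core_h_freq - cfg.h_slope * dd, 0.05, 0.95)
    p_c = np.clip(cfg.core_c_freq + cfg.c_slope * dd, 0.02, 0.9)
    p_p = max(1.0 - p_h - p_c, 0.02)
    probs = np.array([p_h, p_p, p_c])
    probs = probs / probs.sum()
    if d > 20.0:
        w = min((d - 20.0) / 5.0, 1.0)  # full uniformity beyond 25 Å
        probs = (1 - w) * probs + w * np.full(3, 1 / 3)
    return probs


def _assign_residues(rng, cfg, positions, group, start_num, center) -> tuple[np.ndarray, np.ndarray]:
    """Residue numbers and names for a tiled disk; classes follow the
    distance-dependent hydrophobic-core/charged-rim profile."""
    resnum = np.empty(len(positions), dtype=int)
    resname = np.empty(len(positions), dtype=object)
    lists = (_H_LIST, _P_LIST, _C_LIST)
    for g in np.unique(group):
        sel = group == g
        cent = positions[sel].mean(axis=0)
        d = float(np.linalg.norm(cent - center))
        cls = rng.choice(3, p=_class_profile(cfg, d))
        name = lists[cls][rng.integers(len(lists[cls]))]
        resnum[sel] = start_num + int(g)
        resname[sel] = name
    return resnum, resname


def generate_complex(cfg: GeneratorConfig, index: int) -> SyntheticComplex:
    """Generate one synthetic complex; deterministic under (cfg.seed, index).

    Geometries whose interface surfaces come closer than
    ``cfg.min_separation`` are regenerated with the next sub-seed (bounded
    retries).
    """
    cfg.validate()
    for retry in range(cfg.max_retries):
        rng = np.random.default_rng(np.random.SeedSequence((cfg.seed, index, retry)))
        out = _try_generate(cfg, index, rng, retry)
        if out is not None:
            return out
    raise RuntimeError(
        f"complex {index}: no feasible geometry in {cfg.max_retries} attempts"
    )


def _try_generate(cfg, index, rng, retry):
    R = cfg.disk_radius
    # each chain is sampled on its own jittered lattice, as two independently
    # computed surfaces would be
    xy_a = _disk_lattice(rng, R, cfg.spacing)
    xy_b = _disk_lattice(rng, R, cfg.spacing)

    h_a = BumpField(rng, R, cfg.n_bumps, cfg.shape_amplitude, cfg.bump_sigma)
    h_bp = BumpField(rng, R, cfg.n_bumps, cfg.shape_amplitude, cfg.bump_sigma)
    za = h_a.value(xy_a) + rng.normal(0, cfg.noise, len(xy_a))
    h_mix_b = cfg.eta_shape * h_a.value(xy_b) + (1 - cfg.eta_shape) * h_bp.value(xy_b)
    zb = cfg.gap - h_mix_b + rng.normal(0, cfg.noise, len(xy_b))
    if cfg.min_separation is not None:
        sep = (cfg.gap - cfg.eta_shape * h_a.value(xy_a)
               - (1 - cfg.eta_shape) * h_bp.value(xy_a) - h_a.value(xy_a))
        if np.min(sep) < cfg.min_separation:
            return None

    grad_a = h_a.grad(xy_a)  # ∇z of the A interface surface
    grad_b = -(cfg.eta_shape * h_a.grad(xy_b) + (1 - cfg.eta_shape) * h_bp.grad(xy_b))  # ∇z_B

    phi_a_field = BumpField(rng, R, cfg.n_bumps, cfg.el_amplitude, cfg.el_sigma)
    phi_bp_field = BumpField(rng, R, cfg.n_bumps, cfg.el_amplitude, cfg.el_sigma)
    phi_a = phi_a_field.value(xy_a) + rng.normal(0, cfg.el_noise, len(xy_a))
    phi_b = (
        -cfg.rho_el * phi_a_field.value(xy_b)
        + np.sqrt(1 - cfg.rho_el**2) * phi_bp_field.value(xy_b)
        + rng.normal(0, cfg.el_noise, len(xy_b))
    )

    # far (non-interacting) disks, laterally displaced beyond the 6 Å rule
    far_a_xy = _disk_lattice(rng, R, cfg.spacing) + np.array([cfg.far_offset, 0.0])
    far_b_xy = _disk_lattice(rng, R, cfg.spacing) + np.array([-cfg.far_offset, 0.0])
    hf_a = BumpField(rng, R, cfg.n_bumps, cfg.shape_amplitude, cfg.bump_sigma)
    hf_b = BumpField(rng, R, cfg.n_bumps, cfg.shape_amplitude, cfg.bump_sigma)
    pf_a = BumpField(rng, R, cfg.n_bumps, cfg.el_amplitude, cfg.el_sigma)
    pf_b = BumpField(rng, R, cfg.n_bumps, cfg.el_amplitude, cfg.el_sigma)

    def _local(xy_abs, offset):
        return xy_abs - np.array([offset, 0.0])

    zfa = hf_a.value(_local(far_a_xy, cfg.far_offset)) + rng.normal(0, cfg.noise, len(far_a_xy))
    zfb = cfg.gap - hf_b.value(_local(far_b_xy, -cfg.far_offset)) + rng.normal(0, cfg.noise, len(far_b_xy))

    def _up_normals(grad):
        n = np.column_stack([-grad[:, 0], -grad[:, 1], np.ones(len(grad))])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    def _down_normals(grad):
        # outward (solvent) side of chain B faces -z: normal = (∇z, -1)/‖·‖
        n = np.column_stack([grad[:, 0], grad[:, 1], -np.ones(len(grad))])
        return n / np.linalg.norm(n, axis=1, keepdims=True)

    pos_a = np.vstack([np.column_stack([xy_a, za]),
                       np.column_stack([far_a_xy, zfa])])
    nrm_a = np.vstack([_up_normals(grad_a),
                       _up_normals(hf_a.grad(_local(far_a_xy, cfg.far_offset)))])
    pot_a = np.concatenate([phi_a,
                            pf_a.value(_local(far_a_xy, cfg.far_offset))
                            + rng.normal(0, cfg.el_noise, len(far_a_xy))])

    pos_b = np.vstack([np.column_stack([xy_b, zb]),
                       np.column_stack([far_b_xy, zfb])])
    nrm_b = np.vstack([_down_normals(grad_b),
                       _down_normals(-hf_b.grad(_local(far_b_xy, -cfg.far_offset)))])
    pot_b = np.concatenate([phi_b,
                            pf_b.value(_local(far_b_xy, -cfg.far_offset))
                            + rng.normal(0, cfg.el_noise, len(far_b_xy))])

    center0 = np.array([0.0, 0.0, cfg.gap / 2])

    # interface disks share one Voronoi seed set so residues face each other;
    # far disks are tiled independently; groups never straddle the lateral gap
    n_res_iface = max(1, len(xy_a) // cfg.points_per_residue)
    iface_seeds = xy_a[rng.choice(len(xy_a), size=n_res_iface, replace=False)]
    n_ia, n_ib = len(xy_a), len(xy_b)
    grp_a1 = _tile_residues(rng, pos_a[:n_ia], cfg.points_per_residue, iface_seeds)
    grp_b1 = _tile_residues(rng, pos_b[:n_ib], cfg.points_per_residue, iface_seeds)
    num_a1, name_a1 = _assign_residues(rng, cfg, pos_a[:n_ia], grp_a1, 1, center0)
    num_a2, name_a2 = _assign_residues(
        rng, cfg, pos_a[n_ia:],
        _tile_residues(rng, pos_a[n_ia:], cfg.points_per_residue),
        int(num_a1.max()) + 1, center0,
    )
    num_b1, name_b1 = _assign_residues(rng, cfg, pos_b[:n_ib], grp_b1, 1, center0)
    num_b2, name_b2 = _assign_residues(
        rng, cfg, pos_b[n_ib:],
        _tile_residues(rng, pos_b[n_ib:], cfg.points_per_residue),
        int(num_b1.max()) + 1, center0,
    )

    cloud_a = SurfacePointCloud(
        "A", pos_a, nrm_a, pot_a,
        np.concatenate([num_a1, num_a2]), np.concatenate([name_a1, name_a2]),
    )
    cloud_b = SurfacePointCloud(
        "B", pos_b, nrm_b, pot_b,
        np.concatenate([num_b1, num_b2]), np.concatenate([name_b1, name_b2]),
    )

    iface_a, iface_b = detect_interface(cloud_a, cloud_b)
    if iface_a.is_empty or iface_b.is_empty:
        return None
    core = find_core_pairs(cloud_a, cloud_b, iface_a, iface_b)
    if not core:
        return None
    n_decoys = cfg.decoys_per_complex if cfg.decoys_per_complex is not None else len(core)
    decoys = _sample_edge_safe_decoys(cfg, rng, cloud_a, cloud_b, iface_a, iface_b, n_decoys)
    truth = GroundTruth(
        index=index,
        eta_shape=cfg.eta_shape,
        rho_el=cfg.rho_el,
        interface_center=interface_center(cloud_a, cloud_b, iface_a, iface_b),
        core_pairs=core,
        decoy_pairs=decoys,
        retries=retry,
    )
    return SyntheticComplex(cloud_a, cloud_b, iface_a, iface_b, truth)


def _sample_edge_safe_decoys(cfg, rng, cloud_a, cloud_b, iface_a, iface_b, n):
    """Decoys drawn from non-interfacial residues away from disk boundaries.

    Patches centred near the rim of a finite sampled disk are generator
    artifacts (real surfaces are closed); residues whose centroid lies
    within ``edge_margin`` of a far-disk edge are therefore excluded from
    decoy sampling so decoy patches share the statistics of interface
    patches.
    """

    def eligible(cloud, iface, offset):
        keys = _eligible_decoy_residues(cloud, iface)
        cents = cloud.residue_centroids()
        keep = []
        for k in keys:
            local = cents[k][:2] - np.array([offset, 0.0])
            if np.hypot(*local) <= cfg.disk_radius - cfg.edge_margin:
                keep.append(k)
        return keep

    elig_a = eligible(cloud_a, iface_a, cfg.far_offset)
    elig_b = eligible(cloud_b, iface_b, -cfg.far_offset)
    m = min(n, len(elig_a), len(elig_b))
    pick_a = rng.choice(len(elig_a), size=m, replace=False)
    pick_b = rng.choice(len(elig_b), size=m, replace=False)
    out = []
    for ia, ib in zip(pick_a, pick_b):
        ka, kb = elig_a[int(ia)], elig_b[int(ib)]
        out.append(ResiduePairLabel(ka, kb, DECOY_LABEL, pair_class(ka[2], kb[2])))
    return out


@dataclass
class SyntheticDataset:
    complexes: list
    config: GeneratorConfig

    @property
    def pair_table(self) -> pd.DataFrame:
        rows = []
        for cx in self.complexes:
            for p in cx.pairs:
                rows.append({
                    "complex": cx.truth.index,
                    "chainA": p.key_a[0], "resnumA": p.key_a[1], "resnameA": p.key_a[2],
                    "chainB": p.key_b[0], "resnumB": p.key_b[1], "resnameB": p.key_b[2],
                    "label": p.label, "pair_class": p.pair_class,
                })
        return pd.DataFrame(rows)

    @property
    def n_core(self) -> int:
        return sum(len(c.truth.core_pairs) for c in self.complexes)

    @property
    def n_decoy(self) -> int:
        return sum(len(c.truth.decoy_pairs) for c in self.complexes)

    def manifest(self) -> dict:
        return {
            "config": {k: (list(v) if isinstance(v, tuple) else v)
                       for k, v in asdict(self.config).items()},
            "complexes": [
                {"index": c.truth.index, "retries": c.truth.retries,
                 "n_core": len(c.truth.core_pairs), "n_decoy": len(c.truth.decoy_pairs)}
                for c in self.complexes
            ],
        }


def generate_dataset(cfg: GeneratorConfig, out_dir=None) -> SyntheticDataset:
    """Generate the full labeled dataset (and optionally write it to disk).

    Labels come from re-detection with the interface operations, so the pair
    tables are consistent with the emitted clouds by construction.  With
    ``out_dir`` set, writes per-complex point clouds (columnar text), the
    TSV pair tables, and a JSON manifest of seeds and configuration.
    """
    complexes = [generate_complex(cfg, i) for i in range(cfg.n_complexes)]
    ds = SyntheticDataset(complexes=complexes, config=cfg)
    if out_dir is not None:
        out = Path(out_dir)
        (out / "clouds").mkdir(parents=True, exist_ok=True)
        for c in complexes:
            write_point_cloud(c.cloud_a, out / "clouds" / f"complex{c.truth.index:04d}_A.txt")
            write_point_cloud(c.cloud_b, out / "clouds" / f"complex{c.truth.index:04d}_B.txt")
            write_pair_table(c.pairs, out / "clouds" / f"complex{c.truth.index:04d}_pairs.tsv")
        ds.pair_table.to_csv(out / "pairs.tsv", sep="\t", index=False)
        (out / "manifest.json").write_text(json.dumps(ds.manifest(), indent=2))
    return ds
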