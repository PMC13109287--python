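"""Surface point clouds and interface geometry.

A protein chain is represented by a solvent-accessible surface sampled as a
point cloud: positions, outward unit normals, a per-point electrostatic
potential, and the residue each point belongs to.  Interfaces are the surface
regions of one chain within 6 Å of the partner surface; their center is the
centroid of the member points.  Core-interacting residue pairs are cross-chain
pairs whose residue centroids are closer than 3 Å and both within 5 Å of the
interface center; decoys are randomly cross-paired residues that generate no
interfacial surface points.

Computing the surface itself (DMS-style sampling) and the potential
(Poisson–Boltzmann) is upstream of this package; the reader only defines the
expected columnar format: ``x y z nx ny nz potential chain resnum resname``.
"""

from __future__ import annotations

import gzip
import io
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .residues import STANDARD_RESIDUES, pair_class

__all__ = [
    "SurfacePointCloud",
    "InterfaceRegion",
    "ResiduePairLabel",
    "PointCloudFormatError",
    "read_point_cloud",
    "write_point_cloud",
    "detect_interface",
    "interface_center",
    "find_core_pairs",
    "sample_decoy_pairs",
    "annular_composition",
    "read_pair_table",
    "write_pair_table",
]

_COLUMNS = ["x", "y", "z", "nx", "ny", "nz", "potential", "chain", "resnum", "resname"]

CORE_LABEL = "core-interacting"
DECOY_LABEL = "non-interacting"


class PointCloudFormatError(ValueError):
    """Raised for malformed point-cloud files (missing columns, bad rows)."""


@dataclass
class SurfacePointCloud:
    """Per-chain surface point cloud.

    Attributes
    ----------
    chain : str
        Chain identifier shared by all points.
    positions : (n, 3) float array, Å.
    normals : (n, 3) float array, outward unit normals.
    potential : (n,) float array, electrostatic potential (consistent units).
    resnum : (n,) int array, 1-based residue numbers.
    resname : (n,) str array, three-letter residue names.
    """

    chain: str
    positions: np.ndarray
    normals: np.ndarray
    potential: np.ndarray
    resnum: np.ndarray
    resname: np.ndarray
    nonstandard: frozenset = field(default_factory=frozenset)

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        self.normals = np.asarray(self.normals, dtype=float)
        self.potential = np.asarray(self.potential, dtype=float)
        self.resnum = np.asarray(self.resnum, dtype=int)
        self.resname = np.asarray(self.resname, dtype=object)
        n = len(self.positions)
        if n == 0:
            raise ValueError("empty point cloud")
        for name in ("normals",):
            if getattr(self, name).shape != (n, 3):
                raise ValueError(f"{name} shape mismatch")
        norms = np.linalg.norm(self.normals, axis=1)
        if np.any(norms < 1e-12):
            bad = int(np.argmin(norms))
            raise ValueError(f"zero-length normal at point {bad}")
        self.normals = self.normals / norms[:, None]
        nonstd = {str(r) for r in self.resname if str(r).upper() not in STANDARD_RESIDUES}
        self.nonstandard = frozenset(nonstd)

    def __len__(self) -> int:
        return len(self.positions)

    @property
    def n_points(self) -> int:
        return len(self.positions)

    def residue_keys(self) -> list[tuple[str, int, str]]:
        """Unique residues, ordered by residue number."""
        seen: dict[tuple[str, int, str], None] = {}
        for num, name in zip(self.resnum, self.resname):
            seen[(self.chain, int(num), str(name))] = None
        return sorted(seen, key=lambda k: k[1])

    def residue_point_indices(self) -> dict[tuple[str, int, str], np.ndarray]:
        """Map residue key -> indices of the surface points it generates."""
        order = np.argsort(self.resnum, kind="stable")
        out: dict[tuple[str, int, str], list[int]] = {}
        for i in order:
            key = (self.chain, int(self.resnum[i]), str(self.resname[i]))
            out.setdefault(key, []).append(int(i))
        return {k: np.asarray(v, dtype=int) for k, v in out.items()}

    def residue_centroids(self) -> dict[tuple[str, int, str], np.ndarray]:
        """Centroid of the surface points generated by each residue."""
        return {
            key: self.positions[idx].mean(axis=0)
            for key, idx in self.residue_point_indices().items()
        }


@dataclass(frozen=True)
class InterfaceRegion:
    """Surface points of one chain within the cutoff of the partner surface."""

    indices: np.ndarray
    center: np.ndarray | None

    @property
    def is_empty(self) -> bool:
        return len(self.indices) == 0


@dataclass(frozen=True)
class ResiduePairLabel:
    """A labeled cross-chain residue pair with its chemical pair class."""

    key_a: tuple[str, int, str]
    key_b: tuple[str, int, str]
    label: str  # CORE_LABEL or DECOY_LABEL
    pair_class: str

    @property
    def is_core(self) -> bool:
        return self.label == CORE_LABEL


def _open_text(path: Path):
    if str(path).endswith(".gz"):
        return io.TextIOWrapper(gzip.open(path, "rb"))
    return open(path, "r")


def read_point_cloud(path, fmt: str = "auto") -> SurfacePointCloud:
    """Read a surface point cloud from columnar text or CSV.

    The columnar format is whitespace-separated ``x y z nx ny nz potential
    chain resnum resname`` with ``#`` comments; the CSV dialect carries the
    same columns with a header row.  Normals are re-normalised on load; a
    zero-length normal is a validation error naming the offending row.
    Nonstandard residue names are flagged (``cloud.nonstandard``) but their
    points are retained.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if fmt == "auto":
        with _open_text(path) as fh:
            for line in fh:
                line = line.strip()
                if line and not line.startswith("#"):
                    fmt = "table" if "," in line else "columnar-text"
                    break
            else:
                raise PointCloudFormatError(f"{path}: no data rows")
    with _open_text(path) as fh:
        if fmt in ("columnar-text", "columnar"):
            df = pd.read_csv(fh, sep=r"\s+", comment="#", header=None, names=_COLUMNS)
        elif fmt in ("table", "csv"):
            df = pd.read_csv(fh, comment="#")
            df.columns = [c.strip().lower() for c in df.columns]
        else:
            raise ValueError(f"unknown format {fmt!r}")
    missing = [c for c in _COLUMNS if c not in df.columns]
    if missing:
        raise PointCloudFormatError(f"{path}: missing column(s) {', '.join(missing)}")
    numeric = ["x", "y", "z", "nx", "ny", "nz", "potential"]
    coerced = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = coerced.isna().any(axis=1)
    if bad.any():
        raise PointCloudFormatError(
            f"{path}: malformed numeric value(s) in row(s) {list(df.index[bad])[:5]}"
        )
    normals = coerced[["nx", "ny", "nz"]].to_numpy()
    norms = np.linalg.norm(normals, axis=1)
    if np.any(norms < 1e-12):
        row = int(np.argmin(norms))
        raise PointCloudFormatError(f"{path}: zero-length normal at row {row}")
    chains = df["chain"].astype(str).unique()
    if len(chains) != 1:
        raise PointCloudFormatError(f"{path}: multiple chain ids {list(chains)}")
    return SurfacePointCloud(
        chain=str(chains[0]),
        positions=coerced[["x", "y", "z"]].to_numpy(),
        normals=normals,
        potential=coerced["potential"].to_numpy(),
        resnum=df["resnum"].astype(int).to_numpy(),
        resname=df["resname"].astype(str).to_numpy(dtype=object),
    )


def write_point_cloud(cloud: SurfacePointCloud, path) -> None:
    """Write a cloud in the columnar text format (round-trips with the reader)."""
    path = Path(path)
    with open(path, "w") as fh:
        fh.write("# x y z nx ny nz potential chain resnum resname\n")
        for i in range(len(cloud)):
            x, y, z = cloud.positions[i]
            nx, ny, nz = cloud.normals[i]
            fh.write(
                f"{x:.4f} {y:.4f} {z:.4f} {nx:.6f} {ny:.6f} {nz:.6f} "
                f"{cloud.potential[i]:.5f} {cloud.chain} "
                f"{int(cloud.resnum[i])} {cloud.resname[i]}\n"
            )


def detect_interface(
    cloud_a: SurfacePointCloud,
    cloud_b: SurfacePointCloud,
    cutoff: float = 6.0,
) -> tuple[InterfaceRegion, InterfaceRegion]:
    """Binding-site detection: points of each chain strictly within ``cutoff``
    of the partner surface.  Symmetric in its arguments.

    Returns a pair of (possibly empty) :class:`InterfaceRegion`; an empty
    interface is a flagged result, not an exception.
    """
    tree_a = cKDTree(cloud_a.positions)
    tree_b = cKDTree(cloud_b.positions)
    d_a, _ = tree_b.query(cloud_a.positions, k=1)
    d_b, _ = tree_a.query(cloud_b.positions, k=1)
    idx_a = np.nonzero(d_a < cutoff)[0]
    idx_b = np.nonzero(d_b < cutoff)[0]

    def region(cloud, idx):
        center = cloud.positions[idx].mean(axis=0) if len(idx) else None
        return InterfaceRegion(indices=idx, center=center)

    return region(cloud_a, idx_a), region(cloud_b, idx_b)


def interface_center(
    cloud_a: SurfacePointCloud,
    cloud_b: SurfacePointCloud,
    iface_a: InterfaceRegion,
    iface_b: InterfaceRegion,
) -> np.ndarray:
    """Centroid of the union of the two chains' interfacial surface points."""
    if iface_a.is_empty or iface_b.is_empty:
        raise ValueError("cannot define a center for an empty interface")
    pts = np.vstack([cloud_a.positions[iface_a.indices], cloud_b.positions[iface_b.indices]])
    return pts.mean(axis=0)


def find_core_pairs(
    cloud_a: SurfacePointCloud,
    cloud_b: SurfacePointCloud,
    iface_a: InterfaceRegion,
    iface_b: InterfaceRegion,
    pair_cutoff: float = 3.0,
    center_cutoff: float = 5.0,
) -> list[ResiduePairLabel]:
    """Core-interacting residue pairs.

    Each residue is represented by the centroid of the surface points it
    generates.  A cross-chain pair is core when the two centroids are strictly
    closer than ``pair_cutoff`` and both lie strictly within ``center_cutoff``
    of the interface center.  Water-mediated contacts are not modelled.
    """
    if iface_a.is_empty or iface_b.is_empty:
        raise ValueError("interfaces are empty; no core pairs can exist")
    center = interface_center(cloud_a, cloud_b, iface_a, iface_b)
    cents_a = cloud_a.residue_centroids()
    cents_b = cloud_b.residue_centroids()
    near_a = {k: c for k, c in cents_a.items() if np.linalg.norm(c - center) < center_cutoff}
    near_b = {k: c for k, c in cents_b.items() if np.linalg.norm(c - center) < center_cutoff}
    pairs: list[ResiduePairLabel] = []
    for ka, ca in near_a.items():
        for kb, cb in near_b.items():
            if np.linalg.norm(ca - cb) < pair_cutoff:
                pairs.append(
                    ResiduePairLabel(ka, kb, CORE_LABEL, pair_class(ka[2], kb[2]))
                )
    pairs.sort(key=lambda p: (p.key_a[1], p.key_b[1]))
    return pairs


def _eligible_decoy_residues(cloud: SurfacePointCloud, iface: InterfaceRegion):
    """Residues generating zero surface points inside the interface region."""
    iface_set = set(int(i) for i in iface.indices)
    out = []
    for key, idx in cloud.residue_point_indices().items():
        if not iface_set.intersection(int(i) for i in idx):
            out.append(key)
    return out


def sample_decoy_pairs(
    cloud_a: SurfacePointCloud,
    cloud_b: SurfacePointCloud,
    iface_a: InterfaceRegion,
    iface_b: InterfaceRegion,
    n: int,
    rng: np.random.Generator | int | None = None,
) -> list[ResiduePairLabel]:
    """Non-interacting decoy pairs.

    Residues eligible as decoys generate no surface points within the
    interfacial regions; ``n`` of them are drawn uniformly on each chain and
    randomly cross-paired.  Reproducible under a fixed ``rng`` seed.  If fewer
    eligible residues exist than requested, all are used (with a warning).
    """
    rng = np.random.default_rng(rng)
    elig_a = _eligible_decoy_residues(cloud_a, iface_a)
    elig_b = _eligible_decoy_residues(cloud_b, iface_b)
    if n == 0:
        return []
    if not elig_a or not elig_b:
        warnings.warn("no eligible non-interfacial residues; returning no decoys")
        return []
    m = min(n, len(elig_a), len(elig_b))
    if m < n:
        warnings.warn(f"only {m} eligible decoy pairs available ({n} requested)")
    pick_a = rng.choice(len(elig_a), size=m, replace=False)
    pick_b = rng.choice(len(elig_b), size=m, replace=False)
    pairs = []
    for ia, ib in zip(pick_a, pick_b):
        ka, kb = elig_a[int(ia)], elig_b[int(ib)]
        pairs.append(ResiduePairLabel(ka, kb, DECOY_LABEL, pair_class(ka[2], kb[2])))
    return pairs


def annular_composition(
    cloud: SurfacePointCloud,
    center: np.ndarray,
    max_radius: float = 20.0,
    ring_width: float = 1.0,
) -> pd.DataFrame:
    """Chemical-class composition in concentric annuli around a center.

    Residues (represented by their surface-point centroids) are binned into
    rings ``[k*w, (k+1)*w)`` of distance from ``center``; each non-empty ring
    reports the fractions of hydrophobic, polar and charged residues (summing
    to 1).  Empty rings carry NaN fractions.  Nonstandard residues are
    excluded from the composition.
    """
    from .residues import residue_class

    center = np.asarray(center, dtype=float)
    n_rings = int(np.ceil(max_radius / ring_width))
    counts = np.zeros((n_rings, 3))
    classes = {"H": 0, "P": 1, "C": 2}
    for key, cent in cloud.residue_centroids().items():
        name = key[2].upper()
        if name not in STANDARD_RESIDUES:
            continue
        d = float(np.linalg.norm(cent - center))
        k = int(d // ring_width)
        if k < n_rings:
            counts[k, classes[residue_class(name)]] += 1
    totals = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = counts / totals[:, None]
    frac[totals == 0] = np.nan
    return pd.DataFrame(
        frac,
        columns=["H", "P", "C"],
        index=pd.Index(
            [ring_width * k for k in range(n_rings)], name="ring_inner_radius"
        ),
    ).assign(n_residues=totals.astype(int))


def write_pair_table(pairs: Sequence[ResiduePairLabel], path) -> None:
    """Tab-separated pair table: chainA resnumA resnameA chainB resnumB resnameB label."""
    rows = [
        {
            "chainA": p.key_a[0], "resnumA": p.key_a[1], "resnameA": p.key_a[2],
            "chainB": p.key_b[0], "resnumB": p.key_b[1], "resnameB": p.key_b[2],
            "label": p.label,
        }
        for p in pairs
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)


def read_pair_table(path) -> list[ResiduePairLabel]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for _, r in df.iterrows():
        ka = (str(r["chainA"]), int(r["resnumA"]), str(r["resnameA"]))
        kb = (str(r["chainB"]), int(r["resnumB"]), str(r["resnameB"]))
        out.append(ResiduePairLabel(ka, kb, str(r["label"]), pair_class(ka[2], kb[2])))
    return out
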