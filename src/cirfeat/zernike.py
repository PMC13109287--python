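"""2D Zernike descriptors of protein surface patches.

A patch is the set of surface points inside a sphere of radius ``R`` (default
9 Å) centred on a surface point.  The patch is re-oriented so that its
least-squares plane normal lies along the z-axis with the solvent-exposed
side facing +z (or -z, for the partner patch of a complementarity
comparison).  An apex ``C`` is placed on the z-axis at the minimal height
such that every secant from ``C`` to a patch point makes an angle of at most
45° with the axis; each point is labelled with its distance ``r`` to ``C``
and projected onto the x-y plane, rescaled to the unit disk, and binned onto
a 25×25 pixel grid (pixel value = mean ``r`` for the shape image, mean
electrostatic potential for the electrostatic image).

The disk image f(r, ψ) is expanded in the 2D Zernike basis

    Z_nm(r, ψ) = R_nm(r) e^{imψ},
    c_nm = (n+1)/π ∫∫ Z*_nm f  r dr dψ,

with R_nm the standard radial polynomial.  The vector of coefficient norms
|c_nm| (the Zernike descriptor) is invariant under rotations about the disk
centre; the Euclidean distance between the descriptors of two oppositely
oriented patches measures their complementarity (smaller = more
complementary).
"""

from __future__ import annotations

from dataclasses import dataclass
from functools import lru_cache
from math import factorial

import numpy as np

from .surface import SurfacePointCloud

__all__ = [
    "Patch",
    "OrientedPatch",
    "Projection",
    "ZernikeDescriptor",
    "extract_patch",
    "orient_patch",
    "build_projection",
    "zernike_radial",
    "zernike_index_pairs",
    "zernike_moments",
    "zernike_moments_fn",
    "reconstruct",
    "complementarity_distance",
    "patch_descriptor",
]

DEFAULT_RADIUS = 9.0
DEFAULT_ORDER = 20
GRID_SIZE = 25
THETA_MAX_DEG = 45.0
MIN_PATCH_POINTS = 10


class PatchError(ValueError):
    """Raised for unusable patches (too sparse, degenerate geometry)."""


@dataclass(frozen=True)
class Patch:
    """Surface points within ``radius`` of a centre point of a cloud."""

    indices: np.ndarray
    center_index: int
    center: np.ndarray
    radius: float
    positions: np.ndarray
    normals: np.ndarray
    potential: np.ndarray


@dataclass(frozen=True)
class OrientedPatch:
    """Patch in its canonical frame: plane normal along z, solvent side +z,
    centroid at the origin."""

    points: np.ndarray  # (n, 3)
    potential: np.ndarray


@dataclass(frozen=True)
class Projection:
    """25×25 disk image of a patch (shape or electrostatic)."""

    grid: np.ndarray  # (G, G) float, fill 0 where masked
    mask: np.ndarray  # (G, G) bool, True where occupied
    kind: str  # 'shape' | 'electrostatic'
    apex_height: float
    sign: int  # +1: solvent side +z; -1: partner orientation


@dataclass(frozen=True)
class ZernikeDescriptor:
    """Rotation-invariant vector of |c_nm|, 0 ≤ m ≤ n ≤ N, n−m even."""

    order: int
    values: np.ndarray

    def __len__(self) -> int:
        return len(self.values)


def extract_patch(cloud: SurfacePointCloud, center_index: int, radius: float = DEFAULT_RADIUS) -> Patch:
    """All cloud points within ``radius`` of the point at ``center_index``.

    Raises :class:`PatchError` when fewer than 10 points fall in the sphere
    (a plane cannot be fitted reliably).
    """
    if not 0 <= center_index < len(cloud):
        raise IndexError(f"center index {center_index} out of range")
    center = cloud.positions[center_index]
    d = np.linalg.norm(cloud.positions - center, axis=1)
    idx = np.nonzero(d <= radius)[0]
    if len(idx) < MIN_PATCH_POINTS:
        raise PatchError(
            f"patch at point {center_index} has only {len(idx)} points (< {MIN_PATCH_POINTS})"
        )
    return Patch(
        indices=idx,
        center_index=center_index,
        center=center,
        radius=radius,
        positions=cloud.positions[idx],
        normals=cloud.normals[idx],
        potential=cloud.potential[idx],
    )


def _rotation_to_z(normal: np.ndarray) -> np.ndarray:
    """Minimal rotation matrix taking the unit vector ``normal`` to +z."""
    n = normal / np.linalg.norm(normal)
    z = np.array([0.0, 0.0, 1.0])
    c = float(np.dot(n, z))
    if c > 1 - 1e-12:
        return np.eye(3)
    if c < -1 + 1e-12:  # antiparallel: rotate π about x
        return np.diag([1.0, -1.0, -1.0])
    axis = np.cross(n, z)
    s = np.linalg.norm(axis)
    axis = axis / s
    k = np.array(
        [[0, -axis[2], axis[1]], [axis[2], 0, -axis[0]], [-axis[1], axis[0], 0]]
    )
    return np.eye(3) + s * k + (1 - c) * (k @ k)


def orient_patch(patch: Patch) -> OrientedPatch:
    """Canonical orientation: least-squares plane normal along z, the
    solvent-exposed side (mean outward normal) facing +z, centroid at origin.

    The in-plane frame is canonicalised as well (planar principal axis along
    x, sign fixed by the third moment): descriptors are rotation-invariant in
    the continuum, but pixel binning is not, and a deterministic frame makes
    mirror-image patches produce exactly mirrored disk images.  Raises
    :class:`PatchError` on rank-deficient point sets.
    """
    pts = patch.positions - patch.positions.mean(axis=0)
    # least-squares plane normal = singular vector of the smallest singular value
    u, s, vt = np.linalg.svd(pts, full_matrices=False)
    if s[1] < 1e-9:  # points collinear: no unique plane
        raise PatchError("degenerate patch: points are (nearly) collinear")
    normal = vt[2]
    mean_out = patch.normals.mean(axis=0)
    if np.linalg.norm(mean_out) < 1e-9:
        raise PatchError("degenerate patch: mean outward normal vanishes")
    if np.dot(normal, mean_out) < 0:
        normal = -normal
    rot = _rotation_to_z(normal)
    pts = pts @ rot.T
    pts = _canonical_in_plane(pts)
    return OrientedPatch(points=pts, potential=patch.potential.copy())


def _canonical_in_plane(pts: np.ndarray) -> np.ndarray:
    """Rotate about z so the planar principal axis lies along +x.

    The axis sign is fixed by the third moment of the projections (falling
    back to the extremal coordinate when the distribution is symmetric); the
    second axis completes a right-handed frame.  Under this convention a
    mirror-image patch lands in the exactly y-mirrored frame.
    """
    uv = pts[:, :2]
    cov = uv.T @ uv
    _, evecs = np.linalg.eigh(cov)
    e1 = evecs[:, 1]  # largest-variance axis
    proj = uv @ e1
    skew = float(np.sum(proj**3))
    scale = float(np.sum(proj**2)) ** 1.5 / max(len(proj), 1) ** 0.5
    if abs(skew) < 1e-9 * max(scale, 1e-30):
        skew = float(proj.max() + proj.min())
    if skew < 0:
        e1 = -e1
    e2 = np.array([-e1[1], e1[0]])  # z × e1
    out = pts.copy()
    out[:, 0] = uv @ e1
    out[:, 1] = uv @ e2
    return out


def build_projection(
    oriented: OrientedPatch,
    kind: str = "shape",
    theta_max: float = THETA_MAX_DEG,
    grid_size: int = GRID_SIZE,
    sign: int = 1,
) -> Projection:
    """Project an oriented patch to a ``grid_size``×``grid_size`` disk image.

    With ``sign=-1`` the patch is reflected through its fitted plane first so
    that its solvent-exposed side faces −z — the convention under which two
    perfectly complementary (mirrored) patches produce identical images.
    The apex C sits on the solvent side of the z-axis at the minimal height
    at which every secant to a patch point stays within ``theta_max`` of the
    axis.  Pixel values are the mean secant length r (shape) or the mean
    potential (electrostatic) of the points projected into the pixel; empty
    pixels and pixels centred outside the unit circle are masked.
    """
    if kind not in ("shape", "electrostatic"):
        raise ValueError(f"unknown projection kind {kind!r}")
    if sign not in (1, -1):
        raise ValueError("sign must be +1 or -1")
    pts = oriented.points.copy()
    if sign == -1:
        pts[:, 2] = -pts[:, 2]
    w = sign * pts[:, 2]  # height measured toward the solvent side
    rho = np.hypot(pts[:, 0], pts[:, 1])
    rho_max = float(rho.max())
    if rho_max < 1e-9:
        raise PatchError("degenerate projection: all points on the z-axis")
    tan_t = np.tan(np.deg2rad(theta_max))
    apex = float(np.max(w + rho / tan_t))  # minimal admissible apex height
    r_secant = np.hypot(rho, apex - w)

    half = 2.0 / grid_size
    ix = np.clip(((pts[:, 0] / rho_max + 1.0) / half).astype(int), 0, grid_size - 1)
    iy = np.clip(((pts[:, 1] / rho_max + 1.0) / half).astype(int), 0, grid_size - 1)
    flat = ix * grid_size + iy
    values = r_secant if kind == "shape" else oriented.potential
    sums = np.bincount(flat, weights=values, minlength=grid_size**2)
    counts = np.bincount(flat, minlength=grid_size**2)
    occupied = counts > 0
    if occupied.sum() < 2:
        raise PatchError("degenerate projection: all points fall in one pixel")
    grid = np.zeros(grid_size**2)
    grid[occupied] = sums[occupied] / counts[occupied]
    grid = grid.reshape(grid_size, grid_size)
    mask = occupied.reshape(grid_size, grid_size)
    # disk support: drop pixels whose centre lies outside the unit circle
    centers = (np.arange(grid_size) + 0.5) * half - 1.0
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    inside = np.hypot(cx, cy) <= 1.0
    mask = mask & inside
    grid[~mask] = 0.0
    return Projection(grid=grid, mask=mask, kind=kind, apex_height=sign * apex, sign=sign)


def zernike_index_pairs(order: int) -> list[tuple[int, int]]:
    """Valid (n, m) index pairs: 0 ≤ m ≤ n ≤ order with n − m even."""
    return [(n, m) for n in range(order + 1) for m in range(n % 2, n + 1, 2)]


def zernike_radial(n: int, m: int, r) -> np.ndarray:
    """Radial Zernike polynomial R_nm(r).

    R_nm(r) = Σ_k (−1)^k (n−k)! / [k! ((n+m)/2 − k)! ((n−m)/2 − k)!] r^{n−2k}
    for 0 ≤ m ≤ n with n − m even.
    """
    if m < 0 or m > n:
        raise ValueError(f"require 0 <= m <= n, got (n, m) = ({n}, {m})")
    if (n - m) % 2:
        raise ValueError(f"n - m must be even, got (n, m) = ({n}, {m})")
    r = np.asarray(r, dtype=float)
    out = np.zeros_like(r)
    for k in range((n - m) // 2 + 1):
        coef = ((-1) ** k * factorial(n - k)) / (
            factorial(k) * factorial((n + m) // 2 - k) * factorial((n - m) // 2 - k)
        )
        out = out + coef * r ** (n - 2 * k)
    return out


#: Polar quadrature resolution: Gauss–Legendre radial nodes (exact for the
#: polynomial radial parts up to well beyond order 20) × uniform angles
#: (spectrally accurate for the trigonometric azimuthal parts).
N_RADIAL = 64
N_ANGULAR = 128


@lru_cache(maxsize=8)
def _polar_quadrature(order: int):
    """Zernike basis and weights on the Gauss–Legendre × uniform polar grid.

    Returns (pairs, kernel, r_nodes, psi_nodes) where ``kernel`` has shape
    (n_pairs, N_RADIAL * N_ANGULAR) and already folds in the prefactor
    (n+1)/π, the conjugation, and the quadrature weights r w_r Δψ, so that
    ``coeffs = kernel @ f_nodes``.
    """
    x, w = np.polynomial.legendre.leggauss(N_RADIAL)
    r = 0.5 * (x + 1.0)
    wr = 0.5 * w
    psi = (np.arange(N_ANGULAR) + 0.5) * (2.0 * np.pi / N_ANGULAR)
    dpsi = 2.0 * np.pi / N_ANGULAR
    R, PSI = np.meshgrid(r, psi, indexing="ij")
    WEIGHT = (R * np.repeat(wr[:, None], N_ANGULAR, axis=1)) * dpsi
    pairs = zernike_index_pairs(order)
    kernel = np.empty((len(pairs), N_RADIAL * N_ANGULAR), dtype=complex)
    for i, (n, m) in enumerate(pairs):
        z = zernike_radial(n, m, R) * np.exp(1j * m * PSI)
        kernel[i] = (((n + 1) / np.pi) * np.conj(z) * WEIGHT).ravel()
    return pairs, kernel, R.ravel(), PSI.ravel()


@lru_cache(maxsize=8)
def _node_pixel_lookup(grid_size: int):
    """Flat pixel index of each polar quadrature node on a pixel grid."""
    _, _, r, psi = _polar_quadrature(0)
    x = r * np.cos(psi)
    y = r * np.sin(psi)
    half = 2.0 / grid_size
    ix = np.clip(((x + 1.0) / half).astype(int), 0, grid_size - 1)
    iy = np.clip(((y + 1.0) / half).astype(int), 0, grid_size - 1)
    return ix * grid_size + iy


def zernike_moments(
    projection: Projection,
    order: int = DEFAULT_ORDER,
    center: bool = True,
) -> tuple[ZernikeDescriptor, np.ndarray]:
    """Expansion coefficients c_nm of a disk image.

    The piecewise-constant pixel image is sampled at the nodes of a polar
    Gauss–Legendre × uniform-angle quadrature (exact for the basis
    polynomials themselves), with masked pixels contributing zero.  With
    ``center=True`` (default) the image is mean-centred over its occupied
    pixels first, so the arbitrary apex offset (shape) or potential baseline
    does not dominate c_00.  Returns the descriptor of norms |c_nm| and the
    complex coefficient vector.
    """
    mask = projection.mask
    if not mask.any():
        raise PatchError("empty projection")
    f = projection.grid.astype(float).copy()
    if center:
        f[mask] = f[mask] - f[mask].mean()
    f[~mask] = 0.0
    pairs, kernel, _, _ = _polar_quadrature(order)
    lookup = _node_pixel_lookup(mask.shape[0])
    coeffs = kernel @ f.ravel()[lookup]
    return ZernikeDescriptor(order=order, values=np.abs(coeffs)), coeffs


def zernike_moments_fn(
    fn,
    order: int = DEFAULT_ORDER,
) -> tuple[ZernikeDescriptor, np.ndarray]:
    """Expansion coefficients of an analytic function f(r, ψ) on the disk.

    Bypasses pixelisation entirely; used for convergence and invariance
    studies where the underlying function is known in closed form.
    """
    pairs, kernel, r, psi = _polar_quadrature(order)
    coeffs = kernel @ np.asarray(fn(r, psi), dtype=float)
    return ZernikeDescriptor(order=order, values=np.abs(coeffs)), coeffs


def reconstruct(
    coeffs: np.ndarray,
    order: int,
    grid_size: int = GRID_SIZE,
) -> tuple[np.ndarray, np.ndarray]:
    """Partial Zernike sum on a pixel grid (real-function convention).

    For a real image only m ≥ 0 coefficients are stored; negative-m terms are
    restored via c_{n,−m} = c*_{n,m}, i.e. f = Σ_n [c_n0 R_n0 +
    2 Re(Σ_{m>0} c_nm Z_nm)].  Returns (values, inside_mask).
    """
    half = 2.0 / grid_size
    centers = (np.arange(grid_size) + 0.5) * half - 1.0
    cx, cy = np.meshgrid(centers, centers, indexing="ij")
    r = np.hypot(cx, cy)
    psi = np.arctan2(cy, cx)
    inside = r <= 1.0
    rc = np.clip(r, 0.0, 1.0)
    pairs = zernike_index_pairs(order)
    out = np.zeros((grid_size, grid_size))
    for i, (n, m) in enumerate(pairs):
        if i >= len(coeffs):
            break
        term = coeffs[i] * zernike_radial(n, m, rc) * np.exp(1j * m * psi)
        out += np.real(term) if m == 0 else 2.0 * np.real(term)
    out[~inside] = 0.0
    return out, inside


def complementarity_distance(a: ZernikeDescriptor, b: ZernikeDescriptor) -> float:
    """Euclidean distance between two Zernike descriptors.

    Lower values indicate higher complementarity when the two patches were
    projected with opposite z-orientations (signs +1 and −1).
    """
    if a.order != b.order:
        raise ValueError(f"descriptor order mismatch: {a.order} != {b.order}")
    return float(np.linalg.norm(a.values - b.values))


def descriptor_to_csv(descriptor: ZernikeDescriptor, path) -> None:
    """Write a descriptor as CSV with columns n, m, value."""
    pairs = zernike_index_pairs(descriptor.order)
    with open(path, "w") as fh:
        fh.write("n,m,value\n")
        for (n, m), v in zip(pairs, descriptor.values):
            fh.write(f"{n},{m},{float(v)!r}\n")


def descriptor_from_csv(path) -> ZernikeDescriptor:
    import csv

    with open(path) as fh:
        rows = list(csv.DictReader(fh))
    order = max(int(r["n"]) for r in rows)
    expected = zernike_index_pairs(order)
    got = [(int(r["n"]), int(r["m"])) for r in rows]
    if got != expected:
        raise ValueError(f"{path}: incomplete or misordered descriptor table")
    return ZernikeDescriptor(order=order, values=np.array([float(r["value"]) for r in rows]))


def projection_to_csv(projection: Projection, path) -> None:
    """Export the pixel grid as a plain CSV matrix (masked pixels as nan)."""
    grid = projection.grid.copy()
    grid[~projection.mask] = np.nan
    np.savetxt(path, grid, delimiter=",")


def patch_descriptor(
    cloud: SurfacePointCloud,
    center_index: int,
    kind: str = "shape",
    sign: int = 1,
    radius: float = DEFAULT_RADIUS,
    order: int = DEFAULT_ORDER,
) -> ZernikeDescriptor:
    """Convenience: extract, orient, project and expand in one call."""
    patch = extract_patch(cloud, center_index, radius)
    oriented = orient_patch(patch)
    proj = build_projection(oriented, kind=kind, sign=sign)
    desc, _ = zernike_moments(proj, order)
    return desc
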