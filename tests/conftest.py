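"""Shared fixtures: handmade clouds and a mirrored synthetic complex."""

from __future__ import annotations

import numpy as np
import pytest

from cirfeat.surface import SurfacePointCloud


def make_cloud(chain, positions, resnums=None, resnames=None, potential=None,
               normals=None):
    positions = np.asarray(positions, dtype=float)
    n = len(positions)
    if normals is None:
        normals = np.tile([0.0, 0.0, 1.0], (n, 1))
    if potential is None:
        potential = np.zeros(n)
    if resnums is None:
        resnums = np.arange(1, n + 1)
    if resnames is None:
        resnames = np.array(["ALA"] * n, dtype=object)
    return SurfacePointCloud(chain, positions, np.asarray(normals, float),
                             np.asarray(potential, float), np.asarray(resnums),
                             np.asarray(resnames, dtype=object))


@pytest.fixture
def plane_cloud_pair():
    """Two parallel 5×5 planar clouds, 5 Å apart vertically."""
    ax = np.arange(5.0)
    x, y = np.meshgrid(ax, ax, indexing="ij")
    pts = np.column_stack([x.ravel(), y.ravel(), np.zeros(25)])
    a = make_cloud("A", pts)
    down = np.tile([0.0, 0.0, -1.0], (25, 1))
    b = make_cloud("B", pts + [0, 0, 5.0], normals=down)
    return a, b


def mirrored_heightfield_complex(seed=0, n=45, extent=12.0, gap=3.0,
                                 anti_potential=True):
    """A pair of clouds whose surfaces are exact mirrors (z_B = gap − z_A)
    sampled on a shared lattice, with sign-flipped potentials — the
    perfect-complementarity construction."""
    rng = np.random.default_rng(seed)
    xs = np.linspace(-extent, extent, n)
    x, y = np.meshgrid(xs, xs, indexing="ij")
    z = np.zeros_like(x)
    pot = np.zeros_like(x)
    for _ in range(6):
        x0, y0 = rng.uniform(-8, 8, 2)
        s = rng.uniform(2, 4)
        z += rng.uniform(-1.5, 1.5) * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s * s))
        x0, y0 = rng.uniform(-8, 8, 2)
        pot += rng.uniform(-1, 1) * np.exp(-((x - x0) ** 2 + (y - y0) ** 2) / (2 * s * s))
    gx, gy = np.gradient(z, xs, xs)
    na = np.stack([-gx, -gy, np.ones_like(z)], axis=-1)
    na /= np.linalg.norm(na, axis=-1, keepdims=True)
    gxb, gyb = np.gradient(gap - z, xs, xs)
    nb = np.stack([gxb, gyb, -np.ones_like(z)], axis=-1)
    nb /= np.linalg.norm(nb, axis=-1, keepdims=True)
    resnum = np.arange(x.size) // 20 + 1
    pot_b = -pot if anti_potential else pot
    a = make_cloud("A", np.stack([x, y, z], -1).reshape(-1, 3),
                   resnums=resnum, potential=pot.ravel(),
                   normals=na.reshape(-1, 3))
    b = make_cloud("B", np.stack([x, y, gap - z], -1).reshape(-1, 3),
                   resnums=resnum, potential=pot_b.ravel(),
                   normals=nb.reshape(-1, 3))
    return a, b


@pytest.fixture(scope="session")
def mirror_pair():
    return mirrored_heightfield_complex(seed=0)
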