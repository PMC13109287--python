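"""Hydropathy scale, residue complementarities, neighbors, normalisation."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import cirfeat.features as feat
from cirfeat.features import (
    DescriptorCache,
    FeatureNormalizer,
    HydrophobicityScale,
    PairFeatureMatrix,
    build_feature_matrix,
    hydropathy_complementarity,
    load_feature_matrices,
    residue_complementarity,
    save_feature_matrices,
    select_neighbors,
)
from cirfeat.surface import ResiduePairLabel, CORE_LABEL
from conftest import make_cloud, mirrored_heightfield_complex


class TestHydrophobicityScale:
    def test_surrogate_covers_all_twenty_residues(self):
        scale = HydrophobicityScale.surrogate()
        assert len(scale.values) == 20
        assert all(v >= 0 for v in scale.values.values())
        # hydrophobic residues sit near zero, charged ones high
        assert scale.index("GLY") < scale.index("SER") < scale.index("ARG")

    def test_max_product_matches_upper_root(self):
        scale = HydrophobicityScale.surrogate()
        hmax = max(scale.values.values())
        assert hmax * hmax == pytest.approx(scale.upper_root, rel=1e-6)

    def test_missing_residue_raises(self):
        scale = HydrophobicityScale.surrogate()
        with pytest.raises(KeyError):
            scale.index("XYZ")

    def test_csv_roundtrip(self, tmp_path):
        p = tmp_path / "scale.csv"
        p.write_text("resname,H\nALA,0.5\n" + "\n".join(
            f"{r},{1.0}" for r in sorted(HydrophobicityScale.surrogate().values)
            if r != "ALA"))
        assert HydrophobicityScale.from_csv(p).index("ala") == 0.5


class TestHydropathyComplementarity:
    def test_zero_product_is_root(self):
        assert hydropathy_complementarity(0.0, 0.0) == 0.0

    def test_vertex_value(self):
        scale = HydrophobicityScale.surrogate()
        x = scale.vertex_product  # b / 2a = 5.5
        h = hydropathy_complementarity(np.sqrt(x), np.sqrt(x), scale)
        assert h == pytest.approx(scale.b**2 / (4 * scale.a))
        assert h == pytest.approx(0.99825)

    def test_upper_root(self):
        scale = HydrophobicityScale.surrogate()
        x = scale.upper_root  # b / a = 11
        assert hydropathy_complementarity(np.sqrt(x), np.sqrt(x), scale) == pytest.approx(0.0, abs=1e-12)

    @settings(deadline=None)
    @given(st.floats(0, 3.4), st.floats(0, 3.4))
    def test_symmetric_and_product_only(self, ha, hb):
        scale = HydrophobicityScale.surrogate()
        ab = hydropathy_complementarity(ha, hb, scale)
        ba = hydropathy_complementarity(hb, ha, scale)
        assert ab == ba
        # depends only on the product
        assert ab == pytest.approx(
            hydropathy_complementarity(ha * hb if hb else 0.0, 1.0 if hb else 0.0, scale),
            rel=1e-9, abs=1e-12,
        )

    def test_negative_index_rejected(self):
        with pytest.raises(ValueError):
            hydropathy_complementarity(-1.0, 2.0)


class TestResidueComplementarity:
    def test_mirrored_single_point_residues_near_zero(self, mirror_pair):
        a, b = mirror_pair
        center = int(np.argmin(np.linalg.norm(a.positions, axis=1)))
        d = residue_complementarity(a, [center], b, [center], "shape")
        assert d < 1e-6

    def test_mean_over_patch_pair_combinations(self, monkeypatch):
        queued = iter([0.1, 0.3, 0.2, 0.6])
        monkeypatch.setattr(feat, "complementarity_distance", lambda a, b: next(queued))

        class FakeCache:
            def get(self, cloud, index, kind, sign):
                return object()

        a, b = mirrored_heightfield_complex(seed=1)
        d = residue_complementarity(a, [0, 1], b, [0, 1], "shape", cache=FakeCache(),
                                    max_pairs=None)
        assert d == pytest.approx(np.mean([0.1, 0.3, 0.2, 0.6]))

    def test_subsampling_cap_limits_combinations(self, monkeypatch):
        calls = []
        monkeypatch.setattr(feat, "complementarity_distance",
                            lambda a, b: calls.append(1) or 0.5)

        class FakeCache:
            def get(self, cloud, index, kind, sign):
                return object()

        a, b = mirrored_heightfield_complex(seed=1)
        residue_complementarity(a, list(range(20)), b, list(range(20)), "shape",
                                cache=FakeCache(), max_pairs=16)
        assert len(calls) <= 16


class TestSelectNeighbors:
    def test_isolated_residue_padded(self):
        cloud = make_cloud("B", [[0, 0, 0], [50, 0, 0]], resnums=[1, 2])
        lst = select_neighbors(cloud, ("B", 1, "ALA"))
        assert len(lst) == 10
        assert lst[0] == ("B", 1, "ALA")
        assert lst[1:] == [None] * 9

    def test_nine_nearest_of_twelve_by_brute_force(self):
        rng = np.random.default_rng(1)
        pts = rng.uniform(-4, 4, (13, 3))
        cloud = make_cloud("B", pts, resnums=np.arange(1, 14))
        lst = select_neighbors(cloud, ("B", 1, "ALA"), radius=50.0)
        d = np.linalg.norm(pts[1:] - pts[0], axis=1)
        expected = [("B", int(i + 2), "ALA") for i in np.argsort(d)[:9]]
        assert lst[1:] == expected

    def test_equidistant_tie_broken_by_residue_number(self):
        cloud = make_cloud("B", [[0, 0, 0], [2, 0, 0], [-2, 0, 0]], resnums=[5, 9, 7])
        lst = select_neighbors(cloud, ("B", 5, "ALA"))
        assert [k[1] for k in lst[1:3]] == [7, 9]


def _label(na, nb):
    from cirfeat.residues import pair_class
    return ResiduePairLabel(("A", na[0], na[1]), ("B", nb[0], nb[1]), CORE_LABEL,
                            pair_class(na[1], nb[1]))


class TestBuildFeatureMatrix:
    def test_matrix_shape_and_column0_consistency(self, mirror_pair):
        a, b = mirror_pair
        scale = HydrophobicityScale.surrogate()
        key_a = a.residue_keys()[len(a.residue_keys()) // 2]
        key_b = b.residue_keys()[len(b.residue_keys()) // 2]
        pair = _label((key_a[1], key_a[2]), (key_b[1], key_b[2]))
        cache = DescriptorCache()
        m = build_feature_matrix(a, b, pair, scale, cache=cache, max_pairs=4)
        assert m.matrix.shape == (3, 10)
        # column 0 equals the direct pair complementarities
        pa, pb = a.residue_point_indices(), b.residue_point_indices()
        direct = residue_complementarity(a, pa[pair.key_a], b, pb[pair.key_b],
                                         "shape", cache, 4)
        assert m.matrix[0, 0] == pytest.approx(direct)
        h = hydropathy_complementarity(scale.index(key_a[2]), scale.index(key_b[2]), scale)
        assert m.matrix[2, 0] == pytest.approx(h)
        assert np.isfinite(m.matrix[:, ~m.padded]).all()


class TestNormalizer:
    def _mats(self, values):
        out = []
        for v in values:
            m = np.full((3, 10), float(v))
            out.append(PairFeatureMatrix(matrix=m, pair=_label((1, "ALA"), (1, "GLY"))))
        return out

    def test_minmax_scaling(self):
        mats = self._mats([0, 5, 10])
        norm = FeatureNormalizer().fit(mats)
        scaled = norm.transform(mats)
        assert [m.matrix[0, 0] for m in scaled] == [0.0, 0.5, 1.0]

    def test_values_beyond_training_range_clipped(self):
        norm = FeatureNormalizer().fit(self._mats([0, 10]))
        out = norm.transform(self._mats([20]))[0]
        assert out.matrix.max() == 1.0
        assert norm.n_clipped > 0

    def test_idempotent_with_same_stats(self):
        mats = self._mats([0, 2, 10])
        norm = FeatureNormalizer().fit(mats)
        once = norm.transform(mats)
        # applying the scaling function to already-scaled values with the same
        # affine map is the identity only for the fixed points 0; instead check
        # that transform is deterministic
        twice = norm.transform(mats)
        assert all(np.array_equal(x.matrix, y.matrix) for x, y in zip(once, twice))

    def test_zero_range_row_maps_to_zero_with_warning(self):
        mats = self._mats([3, 3, 3])
        norm = FeatureNormalizer().fit(mats)
        with pytest.warns(UserWarning, match="zero range"):
            out = norm.transform(mats)
        assert np.all(out[0].matrix == 0.0)

    def test_padded_columns_get_worst_value(self):
        m = PairFeatureMatrix(
            matrix=np.zeros((3, 10)),
            pair=_label((1, "ALA"), (1, "GLY")),
            padded=np.array([False] * 8 + [True] * 2),
        )
        ref = self._mats([0, 10])
        norm = FeatureNormalizer().fit(ref + [m])
        out = norm.transform([m])[0]
        assert np.all(out.matrix[:, 8:] == 1.0)


def test_hdf5_roundtrip(tmp_path):
    rng = np.random.default_rng(0)
    mats = [
        PairFeatureMatrix(matrix=rng.random((3, 10)),
                          pair=_label((i, "ALA"), (i, "SER")),
                          padded=np.arange(10) >= 8)
        for i in range(1, 4)
    ]
    path = tmp_path / "feat.h5"
    save_feature_matrices(mats, path)
    back = load_feature_matrices(path)
    assert len(back) == 3
    for m, b in zip(mats, back):
        assert np.allclose(m.matrix, b.matrix)
        assert m.pair == b.pair
        assert np.array_equal(m.padded, b.padded)


def test_long_format_csv_export(tmp_path):
    import pandas as pd
    from cirfeat.features import feature_matrices_to_csv
    rng = np.random.default_rng(1)
    mats = [PairFeatureMatrix(matrix=rng.random((3, 10)),
                              pair=_label((i, "ALA"), (i, "SER")))
            for i in range(2)]
    feature_matrices_to_csv(mats, tmp_path / "long.csv")
    df = pd.read_csv(tmp_path / "long.csv")
    assert len(df) == 2 * 3 * 10
    v = df[(df.pair_index == 1) & (df.feature == "electrostatic") & (df.neighbor == 4)]
    assert v["value"].iloc[0] == mats[1].matrix[1, 4]
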