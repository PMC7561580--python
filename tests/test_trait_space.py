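"""Preprocessing, weighted Gower dissimilarity and corrected PCoA."""

import numpy as np
import pandas as pd
import pytest

from traitshore import (
    DistanceMatrix,
    TraitTable,
    ValidationError,
    generate_traits,
    gower_distance,
    pcoa,
    preprocess_traits,
    select_axes,
    trait_axis_correlations,
)
from traitshore.trait_space import build_functional_space, fix_axis_signs

from conftest import euclidean_distance_matrix


class TestPreprocess:
    def test_continuous_columns_are_zscores_of_logs(self, traits50):
        pre = preprocess_traits(traits50)
        for t in pre.continuous_traits():
            col = pre.data[t].to_numpy()
            assert abs(col.mean()) < 1e-10
            assert abs(col.std(ddof=1) - 1.0) < 1e-10

    def test_binary_trait_untouched(self, traits50):
        pre = preprocess_traits(traits50)
        assert (pre.data["pneumatocysts"]
                == traits50.data["pneumatocysts"]).all()

    def test_constant_column_rejected(self, tiny_traits):
        df = tiny_traits.data.copy()
        df["length"] = 10.0
        with pytest.raises(ValidationError, match="length"):
            preprocess_traits(TraitTable(df))

    def test_nonpositive_value_names_species_and_trait(self, tiny_traits):
        df = tiny_traits.data.copy()
        df.loc["sp2", "sta"] = 0.0
        tt = TraitTable.__new__(TraitTable)  # bypass constructor check
        tt.data, tt.kinds = df, dict(tiny_traits.kinds)
        tt.weights, tt.blocks = dict(tiny_traits.weights), \
            dict(tiny_traits.blocks)
        tt.preprocessed = False
        with pytest.raises(ValidationError, match="sta.*sp2"):
            preprocess_traits(tt)

    def test_branching_order_zero_allowed(self, tiny_traits):
        df = tiny_traits.data.copy()
        df.loc["sp1", "branching_order"] = 0.0
        pre = preprocess_traits(TraitTable(df))
        assert np.isfinite(pre.data["branching_order"]).all()


class TestGower:
    def test_identical_rows_have_zero_distance(self, tiny_traits):
        df = tiny_traits.data.copy()
        df.loc["sp2", "pneumatocysts"] = 0.0  # now sp1 == sp2 everywhere
        D = gower_distance(preprocess_traits(TraitTable(df)))
        assert D.values[0, 1] == pytest.approx(0.0, abs=1e-12)

    def test_pneumatocyst_only_difference_hand_value(self, tiny_traits):
        """Two species equal on all continuous traits: the weighted
        Gower formula gives w_pneu / sum(w) = 0.25 / 2.99."""
        D = gower_distance(preprocess_traits(tiny_traits))
        assert D.values[0, 1] == pytest.approx(0.25 / 2.99, abs=1e-12)

    def test_opposite_extremes_distance_one(self):
        df = pd.DataFrame({
            "sta": [10.0, 100.0, 10.0], "sa_v": [5.0, 50.0, 5.0],
            "thickness": [0.1, 1.0, 0.1], "tdmc": [0.1, 0.5, 0.1],
            "c_n": [5.0, 30.0, 5.0], "length": [1.0, 100.0, 1.0],
            "pneumatocysts": [0.0, 1.0, 0.0],
            "branching_order": [0.0, 8.0, 0.0], "sa_p": [1.0, 9.0, 1.0],
        }, index=["a", "b", "a2"])
        D = gower_distance(preprocess_traits(TraitTable(df)))
        assert D.values[0, 1] == pytest.approx(1.0, abs=1e-12)
        assert D.values.max() <= 1.0 + 1e-12

    def test_invariant_to_row_and_column_order(self, traits50):
        pre = preprocess_traits(traits50)
        D = gower_distance(pre)
        rng = np.random.default_rng(0)
        rows = rng.permutation(pre.species_ids)
        cols = rng.permutation(pre.trait_names)
        shuffled = TraitTable(pre.data.loc[rows, cols], pre.kinds,
                              pre.weights, pre.blocks, preprocessed=True)
        D2 = gower_distance(shuffled).to_dataframe()
        np.testing.assert_allclose(
            D2.loc[D.labels, D.labels].to_numpy(), D.values, atol=1e-12)

    def test_weight_rescaling_is_a_noop(self, traits50):
        pre = preprocess_traits(traits50)
        doubled = TraitTable(pre.data, pre.kinds,
                             {t: 2 * w for t, w in pre.weights.items()},
                             pre.blocks, preprocessed=True)
        np.testing.assert_allclose(gower_distance(doubled).values,
                                   gower_distance(pre).values, atol=1e-12)

    def test_zero_range_trait_contributes_nothing(self, tiny_traits):
        pre = preprocess_traits(tiny_traits)
        df = pre.data.copy()
        df["pneumatocysts"] = 0.0  # zero range within binary is fine;
        # make a continuous trait constant post-hoc instead
        df["sa_p"] = 0.0
        tt = TraitTable(df, pre.kinds, pre.weights, pre.blocks,
                        preprocessed=True)
        with pytest.warns(UserWarning, match="zero range"):
            D = gower_distance(tt)
        assert np.isfinite(D.values).all()


class TestPcoa:
    def test_recovers_collinear_configuration(self):
        pts = np.array([[0.0], [1.0], [3.0]])
        D = DistanceMatrix(["a", "b", "c"], euclidean_distance_matrix(pts))
        fs = pcoa(D)
        rec = euclidean_distance_matrix(fs.coordinates)
        np.testing.assert_allclose(rec, D.values, atol=1e-10)
        assert fs.correction_method == "none applied"

    def test_point_cloud_distances_reproduced(self):
        rng = np.random.default_rng(3)
        pts = rng.normal(size=(12, 4))
        D = DistanceMatrix(list("abcdefghijkl"),
                           euclidean_distance_matrix(pts))
        fs = pcoa(D)
        rec = euclidean_distance_matrix(fs.coordinates)
        np.testing.assert_allclose(rec, D.values, atol=1e-8)

    def test_non_euclidean_matrix_cailliez_corrected(self):
        """A dissimilarity violating the triangle inequality has negative
        PCoA eigenvalues; the Cailliez constant removes them all."""
        D = np.array([[0, 1, 1, 1],
                      [1, 0, 1, 1],
                      [1, 1, 0, 5.0],
                      [1, 1, 5.0, 0]])
        dm = DistanceMatrix(list("abcd"), D)
        fs = pcoa(dm, correction="cailliez")
        assert fs.correction_method == "cailliez"
        assert (fs.eigenvalues > 0).all()
        from traitshore.trait_space import _cailliez_constant, _double_center
        c = _cailliez_constant(D)
        Dc = D + c
        np.fill_diagonal(Dc, 0.0)
        w = np.linalg.eigvalsh(_double_center(Dc ** 2))
        assert w.min() >= -1e-8 * max(1.0, abs(w).max())

    def test_sqrt_correction_available(self):
        D = np.array([[0, 1, 1, 1],
                      [1, 0, 1, 1],
                      [1, 1, 0, 5.0],
                      [1, 1, 5.0, 0]])
        fs = pcoa(DistanceMatrix(list("abcd"), D), correction="sqrt")
        assert fs.correction_method == "sqrt"
        assert (fs.eigenvalues > 0).all()

    def test_too_few_objects(self):
        D = DistanceMatrix(["a", "b"], np.array([[0.0, 1.0], [1.0, 0.0]]))
        with pytest.raises(ValidationError):
            pcoa(D)


class TestSelectAxes:
    def test_quality_rule_finds_intrinsic_dimensionality(self):
        rng = np.random.default_rng(5)
        pts = rng.normal(size=(10, 3))
        D = DistanceMatrix([f"s{i}" for i in range(10)],
                           euclidean_distance_matrix(pts))
        fs = select_axes(pcoa(D), quality_rule=True)
        assert fs.m == 3
        assert fs.quality == pytest.approx(0.0, abs=1e-12)

    def test_fixed_m_capped_with_warning(self):
        pts = np.array([[0.0], [1.0], [3.0], [7.0]])
        D = DistanceMatrix(list("abcd"), euclidean_distance_matrix(pts))
        with pytest.warns(UserWarning, match="capping"):
            fs = select_axes(pcoa(D), m=4)
        assert fs.m == 1

    def test_requested_m_kept_when_available(self, traits50):
        fs = build_functional_space(traits50, m=2)
        assert fs.m == 2


class TestTraitAxisCorrelations:
    def test_perfect_and_orthogonal_correlations(self, space50):
        """A trait equal to the axis-1 scores correlates at r = 1; a
        trait orthogonal to axis 1 by construction at |r| < 1e-10."""
        ax1 = space50.coordinates[:, 0]
        ax2 = space50.coordinates[:, 1]
        orth = ax2 - ax2.mean() - ((ax2 - ax2.mean()) @ (ax1 - ax1.mean())
                                   / np.sum((ax1 - ax1.mean()) ** 2)
                                   ) * (ax1 - ax1.mean())
        fake = TraitTable(
            pd.DataFrame({"axis_like": ax1, "orth_like": orth},
                         index=space50.labels),
            kinds={"axis_like": "continuous", "orth_like": "continuous"},
            weights={"axis_like": 1.0, "orth_like": 1.0},
            blocks={"axis_like": "x", "orth_like": "x"},
            preprocessed=True)
        tab = trait_axis_correlations(fake, space50).set_index(
            ["trait", "axis"])["r"]
        assert tab[("axis_like", 1)] == pytest.approx(1.0, abs=1e-10)
        assert abs(tab[("orth_like", 1)]) < 1e-10

    def test_axis_sign_convention_deterministic(self, traits50):
        a = build_functional_space(traits50, m=4)
        b = build_functional_space(traits50, m=4)
        np.testing.assert_array_equal(a.coordinates, b.coordinates)
        tab = trait_axis_correlations(preprocess_traits(traits50), a)
        ax1 = tab[tab["axis"] == 1]
        top = ax1.loc[ax1["r"].abs().idxmax()]
        assert top["r"] > 0

    def test_economics_axis_sign_pattern(self):
        """STA and SA:V oppose thickness on axis 1 in >= 18/20 seeds —
        the surface-vs-structure trade-off."""
        hits = 0
        for seed in range(20):
            tt = generate_traits(50, rng_seed=seed)
            fs = build_functional_space(tt, m=2)
            tab = trait_axis_correlations(preprocess_traits(tt), fs)
            ax1 = tab[tab["axis"] == 1].set_index("trait")["r"]
            if (np.sign(ax1["sta"]) == np.sign(ax1["sa_v"])
                    and np.sign(ax1["sta"]) != np.sign(ax1["thickness"])):
                hits += 1
        assert hits >= 18


def test_fix_axis_signs_idempotent(traits50, space50):
    pre = preprocess_traits(traits50)
    again = fix_axis_signs(space50, pre)
    np.testing.assert_array_equal(again.coordinates, space50.coordinates)
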