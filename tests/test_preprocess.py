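"""Depth normalization, prevalence, CLR and PCA behavior."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fibermwas import (
    CompositionMatrix,
    clr_transform,
    normalize_to_min_depth,
    prevalence,
    principal_components,
)


def _cm(rows, kind="raw_counts", columns=None):
    arr = np.asarray(rows, dtype=float)
    df = pd.DataFrame(arr, columns=columns or [f"g{i}" for i in range(arr.shape[1])])
    return CompositionMatrix(df, kind=kind)


class TestNormalizeToMinDepth:
    def test_two_sample_case(self):
        out = normalize_to_min_depth(_cm([[60, 40], [150, 50]]))
        assert out.kind == "depth_normalized"
        np.testing.assert_allclose(out.values.sum(axis=1), [100, 100])
        np.testing.assert_allclose(out.values.iloc[1], [75, 25])

    def test_equal_totals_is_identity(self):
        cm = _cm([[10, 20], [15, 15]])
        out = normalize_to_min_depth(cm)
        np.testing.assert_allclose(out.values, cm.values)

    def test_scale_factors(self):
        cm = _cm([[50, 0], [45, 30], [90, 60]])  # totals 50, 75, 150
        out = normalize_to_min_depth(cm)
        factors = out.values.sum(axis=1) / cm.values.sum(axis=1)
        np.testing.assert_allclose(factors, [1.0, 2 / 3, 1 / 3])

    def test_preserves_proportions(self, rng):
        counts = rng.integers(0, 50, size=(8, 12)).astype(float) + rng.random((8, 12))
        cm = _cm(counts)
        out = normalize_to_min_depth(cm)
        p_in = cm.values.div(cm.values.sum(axis=1), axis=0)
        p_out = out.values.div(out.values.sum(axis=1), axis=0)
        np.testing.assert_allclose(p_in, p_out, atol=1e-12)

    def test_empty_sample_rejected(self):
        with pytest.raises(ValueError, match="zero total"):
            normalize_to_min_depth(_cm([[0, 0], [1, 2]]))

    def test_wrong_kind_rejected(self):
        cm = _cm([[0.5, 0.5]], kind="relative")
        with pytest.raises(ValueError):
            normalize_to_min_depth(cm)


class TestPrevalence:
    def test_fractions(self):
        cm = _cm([[1, 0, 0], [2, 0, 1], [3, 0, 2], [0, 0, 3], [1, 0, 4]])
        prev = prevalence(cm)
        np.testing.assert_allclose(prev, [0.8, 0.0, 0.8])

    def test_never_absent_genus_is_one(self):
        assert prevalence(_cm([[1], [2], [3]]))["g0"] == 1.0

    def test_undefined_on_clr(self):
        clr = clr_transform(_cm([[1, 2], [3, 4]]))
        with pytest.raises(ValueError):
            prevalence(clr)


class TestClr:
    def test_hand_example_half_quarter_quarter(self):
        # proportions (0.5, 0.25, 0.25): clr = (2/3 ln2, -1/3 ln2, -1/3 ln2)
        cm = _cm([[500000, 250000, 250000]])
        out = clr_transform(cm, pseudocount=1e-9)
        expected = [2 / 3 * np.log(2), -np.log(2) / 3, -np.log(2) / 3]
        np.testing.assert_allclose(out.values.iloc[0], expected, atol=1e-6)
        np.testing.assert_allclose(out.values.iloc[0], [0.4621, -0.2310, -0.2310], atol=1e-4)

    def test_uniform_row_maps_to_zero(self):
        out = clr_transform(_cm([[7, 7, 7, 7]]))
        np.testing.assert_allclose(out.values.iloc[0], 0.0, atol=1e-12)

    def test_matches_scikit_bio_on_closed_composition(self, rng):
        skbio_comp = pytest.importorskip("skbio.stats.composition")
        counts = rng.integers(1, 100, size=(6, 9)).astype(float)
        ours = clr_transform(_cm(counts), pseudocount=0.5)
        theirs = skbio_comp.clr((counts + 0.5) / (counts + 0.5).sum(axis=1, keepdims=True))
        np.testing.assert_allclose(ours.values, theirs, atol=1e-10)

    def test_nonpositive_pseudocount_rejected(self):
        with pytest.raises(ValueError):
            clr_transform(_cm([[1, 2]]), pseudocount=0.0)

    @settings(max_examples=60, deadline=None, derandomize=True)
    @given(st.lists(st.integers(min_value=0, max_value=10_000), min_size=3, max_size=40))
    def test_rows_sum_to_zero(self, row):
        out = clr_transform(_cm([row]))
        assert abs(out.values.iloc[0].sum()) < 1e-10


class TestPrincipalComponents:
    def test_two_point_example(self):
        # two samples on one log-ratio axis: scores are +/- sqrt(2), with the
        # sign fixed by the largest-magnitude-loading-positive convention
        clr = CompositionMatrix(
            pd.DataFrame([[-1.0, 1.0], [1.0, -1.0]], columns=["a", "b"]), kind="clr"
        )
        scores = principal_components(clr, k=1)
        np.testing.assert_allclose(scores["PC1"], [-np.sqrt(2), np.sqrt(2)], atol=1e-12)

    def test_constant_column_does_not_perturb_scores(self, rng):
        base = rng.normal(size=(12, 5))
        base -= base.mean(axis=1, keepdims=True)
        df = pd.DataFrame(base)
        with_const = df.copy()
        with_const[5] = 3.0
        with_const = with_const.sub(with_const.mean(axis=1), axis=0)  # re-center rows
        s1 = principal_components(CompositionMatrix(df, kind="clr"), k=2)
        # adding a constant column then re-centering shifts every row equally;
        # column-centering inside PCA removes it, so scores agree
        s2 = principal_components(CompositionMatrix(with_const, kind="clr"), k=2)
        np.testing.assert_allclose(np.abs(s1.values), np.abs(s2.values), atol=1e-10)

    def test_scores_orthogonal_and_variance_bounded(self, rng):
        base = rng.normal(size=(30, 8))
        base -= base.mean(axis=1, keepdims=True)
        clr = CompositionMatrix(pd.DataFrame(base), kind="clr")
        scores = principal_components(clr, k=3)
        assert abs(scores["PC1"] @ scores["PC2"]) < 1e-10
        assert abs(scores["PC2"] @ scores["PC3"]) < 1e-10
        centered = base - base.mean(axis=0, keepdims=True)
        total_var = (centered ** 2).sum()
        comp_var = (scores.values ** 2).sum()
        assert comp_var <= total_var + 1e-9
        # rank of a row-centered matrix is at most min(n-1, g); full rank recovers all
        full = principal_components(clr, k=7)
        np.testing.assert_allclose((full.values ** 2).sum(), total_var, rtol=1e-10)

    def test_bad_k_rejected(self):
        clr = CompositionMatrix(pd.DataFrame(np.zeros((4, 4))), kind="clr")
        with pytest.raises(ValueError):
            principal_components(clr, k=0)
        with pytest.raises(ValueError):
            principal_components(clr, k=4)
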