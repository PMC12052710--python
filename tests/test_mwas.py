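"""Two-part association model: routing, permutation p-values, Bonferroni."""

import math

import numpy as np
import pandas as pd
import pytest

from fibermwas import (
    MwasModelSpec,
    SimConfig,
    bonferroni_select,
    generate_cohort,
    mwas_screen,
    permutation_association,
    route_genera,
)


class TestRouting:
    def test_sixty_percent_boundary(self):
        prev = pd.Series({"a": 0.59, "b": 0.60, "c": 1.0, "d": 0.0})
        binary, quant = route_genera(prev, 0.60)
        assert set(binary) == {"a", "d"}
        assert set(quant) == {"b", "c"}

    def test_partition_property(self, rng):
        prev = pd.Series(rng.random(50), index=[f"g{i}" for i in range(50)])
        binary, quant = route_genera(prev, 0.6)
        assert set(binary) | set(quant) == set(prev.index)
        assert set(binary) & set(quant) == set()

    def test_invalid_prevalence_rejected(self):
        with pytest.raises(ValueError):
            route_genera(pd.Series([1.2]), 0.6)


class TestPermutationAssociation:
    def test_hand_enumerated_binary_case(self):
        """n=4, balanced presence, no covariates: 2 of 6 splits reach |t_obs|."""
        y = np.array([10.0, 9.0, 1.0, 2.0])
        b = np.array([1.0, 1.0, 0.0, 0.0])
        res = permutation_association(y, b, pcs=None, n_permutations=10)
        assert res.exhaustive
        assert res.n_permutations == 6
        assert res.p == pytest.approx(1 / 3, abs=1e-12)

    def test_constant_phenotype_ties_at_one(self):
        y = np.full(8, 5.0)
        g = np.arange(8.0)
        res = permutation_association(y, g, n_permutations=200)
        assert res.p == 1.0

    def test_constant_predictor_unestimable(self):
        res = permutation_association(np.arange(6.0), np.ones(6), n_permutations=200)
        assert not res.estimable
        assert math.isnan(res.p)

    def test_collinear_predictor_unestimable(self, rng):
        pcs = rng.normal(size=(20, 1))
        g = 2.0 * pcs[:, 0] + 1.0  # exactly in the covariate span
        res = permutation_association(rng.normal(size=20), g, pcs, n_permutations=200)
        assert not res.estimable

    def test_sampled_p_never_zero(self, rng):
        y = np.concatenate([np.full(10, 10.0), np.zeros(10)])
        g = np.concatenate([np.ones(10), np.zeros(10)])
        res = permutation_association(y, g, n_permutations=499, method="sampled", seed=3)
        assert res.p >= 1 / 500

    def test_monte_carlo_agrees_with_enumeration(self, rng):
        """Sampled p within 3 binomial SE of the exhaustive p for tiny n."""
        for trial in range(8):
            n = int(rng.integers(5, 8))
            y = rng.normal(size=n)
            g = rng.normal(size=n)
            exact = permutation_association(y, g, n_permutations=10_000, method="exhaustive")
            mc = permutation_association(y, g, n_permutations=2000, method="sampled",
                                         seed=trial)
            se = math.sqrt(max(exact.p * (1 - exact.p), 1e-12) / 2000)
            assert abs(mc.p - exact.p) <= 3 * se + 1 / 2000

    def test_exhaustive_refused_when_space_too_large(self, rng):
        y, g = rng.normal(size=30), rng.normal(size=30)
        with pytest.raises(ValueError, match="arrangements"):
            permutation_association(y, g, n_permutations=1000, method="exhaustive")

    def test_freedman_lane_scheme_agrees_on_strong_signal(self, rng):
        pcs = rng.normal(size=(40, 2))
        g = rng.normal(size=40)
        y = 2.0 * g + pcs @ np.array([1.0, -1.0]) + rng.normal(size=40)
        a = permutation_association(y, g, pcs, n_permutations=999, seed=1)
        b = permutation_association(y, g, pcs, n_permutations=999, seed=1,
                                    scheme="freedman_lane")
        assert a.p == pytest.approx(1 / 1000)
        assert b.p == pytest.approx(1 / 1000)
        assert a.t == pytest.approx(b.t)


class TestBonferroni:
    def test_adjustment_arithmetic(self):
        p = pd.Series([0.0001, 0.02])
        out = bonferroni_select(p, m=2, alpha=0.01)
        np.testing.assert_allclose(out["p_adjusted"], [0.0002, 0.04])
        assert list(out["significant"]) == [True, False]

    def test_single_test(self):
        out = bonferroni_select(pd.Series([0.005]), m=1, alpha=0.01)
        assert bool(out["significant"].iloc[0])

    def test_empty_input(self):
        out = bonferroni_select(pd.Series([], dtype=float), m=1)
        assert out.empty

    def test_monotone_in_alpha(self, rng):
        p = pd.Series(rng.random(50) * 0.02)
        strict = bonferroni_select(p, alpha=0.001)["significant"]
        loose = bonferroni_select(p, alpha=0.01)["significant"]
        assert set(p.index[strict]) <= set(p.index[loose])

    def test_family_size_validation(self):
        with pytest.raises(ValueError):
            bonferroni_select(pd.Series([0.1]), m=0)
        with pytest.raises(ValueError):
            bonferroni_select(pd.Series([0.1, 0.2]), m=1)


@pytest.fixture(scope="module")
def screen_result():
    cfg = SimConfig(n_samples=120, n_genera=60, n_causal_quant=1,
                    n_causal_binary=1, quant_r2=0.25, binary_shift=2.5,
                    depth_range=(3000, 6000), seed=5)
    ab, ph, truth = generate_cohort(cfg)
    spec = MwasModelSpec(seed=5, n_permutations=30_000)
    res = mwas_screen(ab, truth.true_rate_per_sample["NDFD"], spec)
    return res, truth


class TestMwasScreen:
    def test_every_genus_in_exactly_one_part(self, screen_result):
        res, _ = screen_result
        assert set(res["part"]) <= {"binary", "quantitative"}
        assert len(res) == res["feature"].nunique()
        binary = res.loc[res["part"] == "binary", "prevalence"]
        quant = res.loc[res["part"] == "quantitative", "prevalence"]
        assert (binary < 0.60).all()
        assert (quant >= 0.60).all()

    def test_planted_genera_have_smallest_p(self, screen_result):
        res, truth = screen_result
        planted = set(truth.causal.feature)
        top = set(res.nsmallest(2, "p")["feature"])
        assert top == planted

    def test_all_p_positive(self, screen_result):
        res, _ = screen_result
        assert (res["p"].dropna() > 0).all()

    def test_binary_part_detects_presence_effect(self, screen_result):
        res, truth = screen_result
        binary_genus = truth.causal.loc[truth.causal.part == "binary", "feature"].iloc[0]
        row = res.set_index("feature").loc[binary_genus]
        assert row["part"] == "binary"
        assert row["significant"]
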