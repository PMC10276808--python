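"""Propensity scores, matching, CEM, weighting schemes, balance metrics."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from svycausal.causal import (
    DEFAULT_CEM_PLAN,
    NoOverlapError,
    ReplicateEngine,
    absolute_smd,
    assign_isw,
    balance_table,
    cem_match,
    coarsen,
    estimate_causal_effect,
    estimate_propensity,
    propensity_weights,
    psm_greedy_match,
)
from svycausal.experiment import MethodConfig


def brute_force_greedy(e, z):
    """Independent oracle: explicit priority loop over sorted scores.

    Exposed processed by descending score (ties: lowest index); each takes
    the available control minimizing (|distance|, index) lexicographically.
    """
    e = np.asarray(e, dtype=float)
    exposed = sorted(np.flatnonzero(z == 1), key=lambda i: (-e[i], i))
    available = set(np.flatnonzero(z == 0).tolist())
    pairs = []
    for i in exposed:
        if not available:
            break
        j = min(available, key=lambda j: (abs(e[i] - e[j]), j))
        pairs.append((i, j))
        available.discard(j)
    return pairs


class TestPropensity:
    def test_constant_osw_modes_coincide(self, rng):
        n = 300
        df = pd.DataFrame(
            {
                "bmi": rng.normal(29, 5, n),
                "insomnia": rng.integers(0, 2, n),
                "osw": np.ones(n),
            }
        )
        a = estimate_propensity(df, ["bmi"], "osw_weighted")
        b = estimate_propensity(df, ["bmi"], "osw_covariate")
        np.testing.assert_allclose(a.e_hat, b.e_hat, atol=1e-8)

    def test_null_model_returns_exposure_rate(self, rng):
        n = 500
        z = rng.integers(0, 2, n)
        df = pd.DataFrame(
            {"x": rng.normal(size=n), "insomnia": z, "osw": rng.uniform(0.5, 2, n)}
        )
        # covariate unrelated to exposure: e_hat ~ weighted exposure rate
        fit = estimate_propensity(df, [], "osw_weighted")
        wrate = np.average(z, weights=df["osw"])
        np.testing.assert_allclose(fit.e_hat, wrate, atol=1e-8)

    def test_recovers_generating_slopes(self, midi_sample):
        fit = estimate_propensity(midi_sample, ["bmi", "age"], "osw_covariate")
        import math

        for name, true_val in (("bmi", math.log(1.025)), ("age", math.log(1.019))):
            lo, hi = fit.fit.wald_interval(name)
            assert lo <= true_val <= hi


class TestPropensityWeights:
    def test_printed_formulas(self):
        e = np.array([0.25, 0.25])
        z = np.array([1, 0])
        np.testing.assert_allclose(propensity_weights(e, z, "iptw"), [4.0, 4.0 / 3.0])
        np.testing.assert_allclose(propensity_weights(e, z, "odds"), [1.0, 1.0 / 3.0])

    def test_symmetric_case_balances_exactly(self):
        z = np.array([1, 1, 1, 0, 0, 0])
        w = propensity_weights(np.full(6, 0.5), z, "iptw")
        assert np.sum(w * z) / np.sum(w) == pytest.approx(0.5)

    def test_degenerate_scores_rejected(self):
        with pytest.raises(ValueError):
            propensity_weights(np.array([0.0, 0.5]), np.array([0, 1]), "iptw")


class TestGreedyMatch:
    def test_hand_traced_descending_order(self):
        # exposed 0.9, 0.5; controls 0.85, 0.55, 0.10
        e = np.array([0.9, 0.5, 0.85, 0.55, 0.10])
        z = np.array([1, 1, 0, 0, 0])
        m = psm_greedy_match(e, z)
        pairs = set(zip(m.exposed.tolist(), m.controls.tolist()))
        assert pairs == {(0, 2), (1, 3)}  # 0.10 discarded

    def test_tie_breaks_to_lowest_row_index(self):
        e = np.array([0.8, 0.79, 0.81])
        z = np.array([1, 0, 0])
        m = psm_greedy_match(e, z)
        assert m.controls.tolist() == [1]  # 0.79 at the lower row index

    def test_identical_scores_degenerate(self):
        z = np.array([1, 1, 1, 0, 0, 0, 0, 0])
        e = np.full(8, 0.4)
        m = psm_greedy_match(e, z)
        assert m.n_pairs == 3
        assert np.sum(np.abs(e[m.exposed] - e[m.controls])) == 0.0

    def test_more_exposed_than_controls(self):
        e = np.array([0.9, 0.8, 0.7, 0.5])
        z = np.array([1, 1, 1, 0])
        m = psm_greedy_match(e, z)
        assert m.n_pairs == 1
        assert m.exposed.tolist() == [0]  # highest score claims the control

    def test_empty_group_rejected(self):
        with pytest.raises(NoOverlapError):
            psm_greedy_match(np.array([0.5]), np.array([1]))

    @settings(max_examples=40, deadline=None, derandomize=True)
    @given(
        n=st.integers(4, 200),
        seed=st.integers(0, 10_000),
        dups=st.booleans(),
    )
    def test_matches_bruteforce_oracle(self, n, seed, dups):
        rng = np.random.default_rng(seed)
        e = rng.random(n)
        if dups:  # force heavy score ties
            e = np.round(e, 1)
        z = rng.integers(0, 2, n)
        if z.sum() in (0, n):
            z[0], z[-1] = 1, 0
        m = psm_greedy_match(e, z)
        expected = brute_force_greedy(e, z)
        assert list(zip(m.exposed.tolist(), m.controls.tolist())) == expected


class TestISW:
    def test_partner_weight_inherited(self):
        e = np.array([0.9, 0.85])
        z = np.array([1, 0])
        m = psm_greedy_match(e, z)
        osw = np.array([2.0, 0.4])
        np.testing.assert_allclose(assign_isw(m, osw), [2.0, 2.0])

    def test_uniform_weights_unchanged(self):
        e = np.array([0.6, 0.4, 0.55, 0.45])
        z = np.array([1, 1, 0, 0])
        m = psm_greedy_match(e, z)
        np.testing.assert_allclose(assign_isw(m, np.ones(4)), 1.0)

    def test_total_isw_twice_exposed_osw(self, rng):
        n = 60
        e = rng.random(n)
        z = rng.integers(0, 2, n)
        z[:5], z[5:10] = 1, 0
        m = psm_greedy_match(e, z)
        osw = rng.uniform(0.5, 3, n)
        isw = assign_isw(m, osw)
        assert isw.sum() == pytest.approx(2 * osw[m.exposed].sum())


class TestCoarsen:
    def test_bmi_style_interval_membership(self):
        bins = coarsen(np.array([29.9, 15.0, 31.0]), [18.5, 25, 30])
        assert bins.tolist() == [2, 0, 3]

    def test_cutpoint_joins_right_bin(self):
        assert coarsen(np.array([25.0]), [18.5, 25, 30]).tolist() == [2]

    def test_quartile_cutpoints_balance_counts(self, rng):
        x = rng.normal(size=1000)
        cuts = np.quantile(x, [0.25, 0.5, 0.75])
        counts = np.bincount(coarsen(x, cuts))
        assert counts.max() - counts.min() <= 1

    def test_invalid_cutpoints_rejected(self):
        with pytest.raises(ValueError):
            coarsen(np.array([1.0]), [])
        with pytest.raises(ValueError):
            coarsen(np.array([1.0]), [2.0, 2.0])


class TestCEM:
    def _toy(self):
        # two bins by x<0.5; bin A: 2 exposed 4 unexposed; bin B: 8 exposed 16 unexposed
        x = np.r_[np.zeros(6), np.ones(24)]
        z = np.r_[np.ones(2), np.zeros(4), np.ones(8), np.zeros(16)]
        return pd.DataFrame({"x": x, "insomnia": z.astype(int), "osw": np.ones(30)})

    def test_printed_formula_arithmetic(self):
        df = self._toy()
        bins = cem_match(df, {"x": [0.5]})
        # retained: 10 exposed, 20 unexposed; bin A unexposed weight = (20/10)*(2/4)
        z = df["insomnia"].to_numpy()[bins.rows]
        wA = bins.cemw[(df["x"].to_numpy()[bins.rows] < 0.5) & (z == 0)]
        np.testing.assert_allclose(wA, 1.0)
        assert np.all(bins.cemw[z == 1] == 1.0)

    def test_mass_conservation_exact(self, midi_sample):
        bins = cem_match(midi_sample, DEFAULT_CEM_PLAN, include_osw=True)
        z = midi_sample.frame["insomnia"].to_numpy()[bins.rows]
        assert bins.cemw[z == 1].sum() == pytest.approx(z.sum(), rel=1e-12)
        assert bins.cemw[z == 0].sum() == pytest.approx((1 - z).sum(), rel=1e-12)

    def test_within_bin_equalization(self, midi_sample):
        """CEMW-weighted unexposed share of each bin equals the exposed share."""
        bins = cem_match(midi_sample, DEFAULT_CEM_PLAN)
        z = midi_sample.frame["insomnia"].to_numpy()[bins.rows]
        n_exp, n_ctl = z.sum(), (1 - z).sum()
        for b in range(bins.n_bins_retained):
            sel = bins.bin_id == b
            exp_share = z[sel].sum() / n_exp
            ctl_share = bins.cemw[sel & (z == 0)].sum() / n_ctl
            assert ctl_share == pytest.approx(exp_share, rel=1e-9)

    def test_pruning_removes_single_group_bins(self):
        df = pd.DataFrame(
            {
                "x": [0.0, 0.0, 1.0, 1.0, 2.0],
                "insomnia": [1, 0, 1, 0, 1],  # last bin exposed-only
                "osw": np.ones(5),
            }
        )
        bins = cem_match(df, {"x": [0.5, 1.5]})
        assert bins.n_bins_pruned == 1
        assert 4 in bins.pruned

    def test_no_overlap_raises(self):
        df = pd.DataFrame(
            {"x": [0.0, 1.0], "insomnia": [1, 0], "osw": np.ones(2)}
        )
        with pytest.raises(NoOverlapError):
            cem_match(df, {"x": [0.5]})


class TestBalance:
    def test_direct_formula(self):
        df = pd.DataFrame(
            {
                "x": [1.0, 1.4, 0.8, 1.2],
                "insomnia": [1, 1, 0, 0],
                "osw": np.ones(4),
            }
        )
        # means 1.2 vs 1.0; exposed sd = 0.2 -> smd 1.0; scale the example
        got = absolute_smd(df, "x")
        assert got == pytest.approx(0.2 / 0.2)
        # textbook example: means 1.2 vs 1.0 with s_exposed 0.5 -> 0.4
        assert abs(1.2 - 1.0) / 0.5 == pytest.approx(0.4)

    def test_identical_groups_zero(self, rng):
        x = rng.normal(size=50)
        df = pd.DataFrame(
            {
                "x": np.r_[x, x],
                "insomnia": np.r_[np.ones(50), np.zeros(50)].astype(int),
                "osw": np.ones(100),
            }
        )
        assert absolute_smd(df, "x") == pytest.approx(0.0, abs=1e-12)

    def test_cem_zeroes_coarsened_indicator_smd(self, midi_sample):
        """After CEM on one variable, the bin-indicator SMD under CEMW is 0."""
        df = midi_sample.frame.copy()
        bins = cem_match(df, {"bmi": [18.5, 25, 30]})
        codes = coarsen(df["bmi"].to_numpy(), [18.5, 25, 30])
        df["bmi_bin"] = np.array([f"bin{c}" for c in codes])
        out = absolute_smd(df, "bmi_bin", rows=bins.rows, analysis_weights=bins.cemw)
        present = {f"bin{c}" for c in codes[bins.rows]}
        for level, smd in out.items():
            if level in present:
                assert smd == pytest.approx(0.0, abs=1e-9)

    def test_balance_table_shape(self, midi_sample):
        tab = balance_table(midi_sample, ["bmi", "age"])
        assert list(tab.columns) == ["covariate", "smd_before", "smd_after"]
        assert (tab["smd_before"] >= 0).all()


class TestEstimation:
    def test_cemw_osw_reduces_to_cemw_when_osw_unit(self, midi_sample):
        df = midi_sample.frame.copy()
        df["osw"] = 1.0
        c1 = MethodConfig("cem", "coarsened", False, "cemw")
        c2 = MethodConfig("cem", "coarsened", False, "cemw_osw")
        e1 = estimate_causal_effect(df, "mci", c1)
        e2 = estimate_causal_effect(df, "mci", c2)
        assert e1.estimate == pytest.approx(e2.estimate, rel=1e-10)
        assert e1.ci == pytest.approx(e2.ci, rel=1e-10)

    def test_htn_restriction_applied_before_matching(self, midi_sample):
        eng = ReplicateEngine(midi_sample, "htn", ["bmi", "age"])
        assert (eng.df["y_htn1"] == 0).all()
        assert eng.df.shape[0] < midi_sample.n

    def test_underspec_drops_confounder(self, midi_sample):
        cfg = MethodConfig("psm", "osw_covariate", False, "osw", "under")
        est = estimate_causal_effect(midi_sample, "mci", cfg)
        assert est.n_used > 0 and est.ci[0] <= est.estimate <= est.ci[1]

    def test_iptw_balances_weighted_means(self, midi_population):
        """With the true-model propensity, IPTW drives covariate SMDs near 0
        (large-n check on the full population with unit weights)."""
        df = midi_population.frame.copy()
        df["osw"] = 1.0
        eng = ReplicateEngine(df, "mci", ["bmi", "age"])
        e_hat = eng.propensity("osw_weighted").e_hat
        w = propensity_weights(e_hat, eng.z, "iptw")
        smd = absolute_smd(df, "age", rows=np.arange(len(df)), analysis_weights=w)
        smd_before = absolute_smd(df, "age")
        assert smd < 0.05 and smd < 0.5 * smd_before

    def test_unweighted_psm_uses_model_covariance(self, midi_sample):
        eng = ReplicateEngine(midi_sample, "mci", ["bmi", "age"])
        m = eng.matched("osw_covariate")
        fit = eng._fit(m.rows, None, adjusted=False)
        assert fit.cov_type == "model"
        fit_w = eng._fit(m.rows, m.analysis_weights("osw", eng.osw), adjusted=False)
        assert fit_w.cov_type == "linearized"
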