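"""Pooling, heterogeneity, model selection, sensitivity and meta-regression."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import metacred as mc


def brute_force_pool(thetas, ses):
    """Independent re-derivation of fixed/random pooling and heterogeneity
    from the weight formulas, in plain Python arithmetic."""
    k = len(thetas)
    w = [1.0 / s**2 for s in ses]
    sw = sum(w)
    theta_fe = sum(wi * t for wi, t in zip(w, thetas)) / sw
    se_fe = (1.0 / sw) ** 0.5
    q = sum(wi * (t - theta_fe) ** 2 for wi, t in zip(w, thetas))
    i2 = max(0.0, (q - (k - 1)) / q) * 100.0 if q > 0 else 0.0
    denom = sw - sum(wi**2 for wi in w) / sw
    tau2 = max(0.0, (q - (k - 1)) / denom) if denom > 0 else 0.0
    w_re = [1.0 / (s**2 + tau2) for s in ses]
    sw_re = sum(w_re)
    theta_re = sum(wi * t for wi, t in zip(w_re, thetas)) / sw_re
    se_re = (1.0 / sw_re) ** 0.5
    return dict(theta_fe=theta_fe, se_fe=se_fe, q=q, i2=i2, tau2=tau2,
                theta_re=theta_re, se_re=se_re)


def _effects(thetas, ses):
    return [
        mc.EffectEstimate(t, s, "allele", f"s{i}", 2000 + i)
        for i, (t, s) in enumerate(zip(thetas, ses))
    ]


class TestPoolFixed:
    def test_single_study_identity(self):
        m = mc.pool_fixed(_effects([0.2], [0.1]))
        assert m.or_pooled == pytest.approx(math.exp(0.2))
        assert m.ci_low == pytest.approx(math.exp(0.2 - 1.959964 * 0.1), rel=1e-6)
        assert m.ci_high == pytest.approx(math.exp(0.2 + 1.959964 * 0.1), rel=1e-6)
        assert m.model == "fixed"
        assert m.q_stat == 0.0

    def test_worked_pair(self, worked_pair):
        m = mc.pool_fixed(worked_pair)
        assert m.pooled_log_or == pytest.approx(0.34655, abs=1e-4)
        assert m.pooled_se == pytest.approx(0.070711, abs=1e-5)

    def test_order_invariance(self, worked_pair):
        fwd = mc.pool_fixed(worked_pair)
        rev = mc.pool_fixed(worked_pair[::-1])
        assert fwd == rev

    def test_empty_list_errors(self):
        with pytest.raises(ValueError):
            mc.pool_fixed([])


class TestHeterogeneity:
    def test_identical_effects(self):
        het = mc.heterogeneity(_effects([0.3, 0.3], [0.1, 0.2]))
        assert het.q_stat == pytest.approx(0.0, abs=1e-12)
        assert het.i_squared_pct == 0.0
        assert het.tau2 == 0.0

    def test_worked_pair(self, worked_pair):
        het = mc.heterogeneity(worked_pair)
        assert het.q_stat == pytest.approx(24.02, abs=0.01)
        assert het.i_squared_pct == pytest.approx(95.8, abs=0.1)
        assert het.tau2 == pytest.approx(0.2302, abs=1e-4)

    def test_single_study_errors(self):
        with pytest.raises(ValueError):
            mc.heterogeneity(_effects([0.2], [0.1]))


class TestPoolRandom:
    def test_tau2_zero_collapses_to_fixed(self):
        effects = _effects([0.25, 0.25, 0.25], [0.1, 0.15, 0.2])
        fixed = mc.pool_fixed(effects)
        random = mc.pool_random_dl(effects)
        assert random.pooled_log_or == pytest.approx(fixed.pooled_log_or)
        assert random.pooled_se == pytest.approx(fixed.pooled_se)

    def test_worked_pair(self, worked_pair):
        m = mc.pool_random_dl(worked_pair)
        assert m.pooled_log_or == pytest.approx(0.34655, abs=1e-4)
        assert m.pooled_se == pytest.approx(0.34655, abs=1e-3)

    @given(
        thetas=st.lists(st.floats(-2, 2), min_size=2, max_size=8),
        raw_ses=st.lists(st.floats(0.05, 1.0), min_size=8, max_size=8),
    )
    @settings(max_examples=80, deadline=None)
    def test_random_ci_never_narrower_than_fixed(self, thetas, raw_ses):
        ses = raw_ses[: len(thetas)]
        effects = _effects(thetas, ses)
        assert mc.pool_random_dl(effects).pooled_se >= mc.pool_fixed(effects).pooled_se - 1e-12


class TestBruteForceEquivalence:
    @pytest.mark.parametrize("k", [2, 3, 4])
    def test_matches_independent_derivation(self, k):
        rng = np.random.default_rng(k)
        for _ in range(50):
            thetas = list(rng.normal(0, 0.5, k))
            ses = list(rng.uniform(0.05, 0.5, k))
            oracle = brute_force_pool(thetas, ses)
            effects = _effects(thetas, ses)
            fixed = mc.pool_fixed(effects)
            random = mc.pool_random_dl(effects)
            het = mc.heterogeneity(effects)
            assert fixed.pooled_log_or == pytest.approx(oracle["theta_fe"], rel=1e-12, abs=1e-12)
            assert fixed.pooled_se == pytest.approx(oracle["se_fe"], rel=1e-12)
            assert het.q_stat == pytest.approx(oracle["q"], rel=1e-12, abs=1e-12)
            assert het.i_squared_pct == pytest.approx(oracle["i2"], rel=1e-12, abs=1e-12)
            assert het.tau2 == pytest.approx(oracle["tau2"], rel=1e-12, abs=1e-12)
            assert random.pooled_log_or == pytest.approx(oracle["theta_re"], rel=1e-12, abs=1e-12)
            assert random.pooled_se == pytest.approx(oracle["se_re"], rel=1e-12)


class TestInvariants:
    @given(
        thetas=st.lists(st.floats(-2, 2), min_size=2, max_size=6),
        raw_ses=st.lists(st.floats(0.05, 1.0), min_size=6, max_size=6),
        scale=st.floats(0.5, 3.0),
    )
    @settings(max_examples=80, deadline=None)
    def test_pooled_within_range_and_scale_invariance(self, thetas, raw_ses, scale):
        ses = raw_ses[: len(thetas)]
        effects = _effects(thetas, ses)
        for m in (mc.pool_fixed(effects), mc.pool_random_dl(effects)):
            assert min(thetas) - 1e-9 <= m.pooled_log_or <= max(thetas) + 1e-9
        scaled = _effects(thetas, [s * scale for s in ses])
        assert mc.pool_fixed(scaled).pooled_log_or == pytest.approx(
            mc.pool_fixed(effects).pooled_log_or, rel=1e-9, abs=1e-12
        )


class TestSelectModel:
    @pytest.mark.parametrize(
        "i2, q_p, expected",
        [(0.0, 0.9, "fixed"), (84.3, 0.5, "random"), (40.0, 0.05, "random"),
         (50.0, 0.5, "fixed"), (60.0, 0.5, "random")],
    )
    def test_default_policy(self, i2, q_p, expected):
        het = mc.HetStats(q_stat=10.0, q_p=q_p, i_squared_pct=i2, tau2=0.1)
        assert mc.select_model(het) == expected


class TestMantelHaenszel:
    def test_single_table_equals_crude_or(self):
        assert mc.mantel_haenszel_or([(20, 80, 10, 90)]) == pytest.approx(2.25)

    def test_identical_tables_preserve_or(self):
        tables = [(20, 80, 10, 90)] * 3
        assert mc.mantel_haenszel_or(tables) == pytest.approx(2.25)


class TestSensitivitySuite:
    def test_identical_studies_stable(self, record_factory):
        records = [record_factory(f"S{i}", 2000 + i, (20, 50, 30), (40, 45, 15))
                   for i in range(4)]
        report = mc.sensitivity_suite(records)
        lo, hi = report.loo_or_range
        assert lo == pytest.approx(hi)
        assert report.stable
        assert report.drop_first_or is not None

    def test_outlier_driven_significance_is_unstable(self, record_factory):
        # four small uninformative studies plus one large study that alone
        # drives significance: leave-one-out must flag instability
        records = [record_factory(f"S{i}", 2000 + i, (10, 15, 5), (9, 16, 5))
                   for i in range(4)]
        records.append(record_factory("S9", 2010, (1272, 1363, 365), (1470, 1260, 270)))
        full = mc.pool([mc.effect_from_record(r) for r in records])
        assert full.p_value < 0.05  # significance present in the full analysis
        report = mc.sensitivity_suite(records)
        assert not report.stable

    def test_no_hwe_violations_drop_equals_full(self, record_factory):
        records = [record_factory(f"S{i}", 2000 + i, (30, 40, 30), (25, 50, 25))
                   for i in range(3)]
        full = mc.pool([mc.effect_from_record(r) for r in records])
        report = mc.sensitivity_suite(records)
        assert report.drop_hwe_or == pytest.approx(full.or_pooled)


class TestCumulative:
    def test_single_study(self, record_factory):
        out = mc.cumulative_by_year([record_factory("S1", 2001)])
        assert len(out) == 1
        assert out[0].k == 1

    def test_last_element_is_full_pool(self, record_factory):
        records = [record_factory(f"S{i}", 2000 + i, (20 + i, 50, 30), (40, 45, 15))
                   for i in range(5)]
        out = mc.cumulative_by_year(records)
        full = mc.pool(
            [mc.effect_from_record(r) for r in sorted(records, key=lambda r: r.year)],
            evidence=mc.evidence_amount(records),
        )
        assert out[-1].pooled_log_or == pytest.approx(full.pooled_log_or)
        amounts = [m.evidence_amount for m in out]
        assert amounts == sorted(amounts)
        assert len(out) == 5


class TestSubgroup:
    def test_single_stratum_equals_overall(self, record_factory):
        records = [record_factory(f"S{i}", 2000 + i, (20, 50, 30), (40, 45, 15),
                                  ethnicity="Asian") for i in range(3)]
        strata = mc.subgroup(records, "ethnicity")
        assert set(strata) == {"Asian"}
        overall = mc.pool([mc.effect_from_record(r) for r in records],
                          evidence=mc.evidence_amount(records))
        assert strata["Asian"].pooled_log_or == pytest.approx(overall.pooled_log_or)

    def test_stratum_estimates_recover_targets(self):
        # Asian OR 1.5 vs Caucasian OR 1.0 by construction
        rng_sets = []
        for eth, or_allele, seed in (("Asian", 1.5, 11), ("Caucasian", 1.0, 22)):
            cfg = mc.SimulationConfig(n_studies=6, maf=0.3, or2=or_allele**2,
                                      lambda_true=0.5, n_cases=4000, n_controls=4000,
                                      seed=seed)
            records, _ = mc.simulate_catalogue(cfg)
            for r in records:
                r.ethnicity = eth
                r.study_id = f"{eth}-{r.study_id}"
            rng_sets.extend(records)
        strata = mc.subgroup(rng_sets, "ethnicity")
        assert strata["Asian"].or_pooled == pytest.approx(1.5, abs=0.08)
        assert strata["Caucasian"].or_pooled == pytest.approx(1.0, abs=0.08)


class TestMetaRegression:
    def test_exact_linear_recovery(self):
        x = [0.0, 1.0, 2.0, 3.0]
        thetas = [0.1 + 0.2 * xi for xi in x]
        effects = _effects(thetas, [0.1] * 4)
        slope, se, p = mc.meta_regression(effects, x)
        assert slope == pytest.approx(0.2, rel=1e-9)

    def test_order_invariance(self):
        x = [0.0, 1.0, 2.0, 3.0]
        thetas = [0.05, 0.3, 0.35, 0.7]
        effects = _effects(thetas, [0.1, 0.2, 0.15, 0.1])
        fwd = mc.meta_regression(effects, x)
        rev = mc.meta_regression(effects[::-1], x[::-1])
        assert fwd[0] == pytest.approx(rev[0])

    def test_constant_covariate_errors(self):
        effects = _effects([0.1, 0.2, 0.3], [0.1] * 3)
        with pytest.raises(ValueError, match="constant"):
            mc.meta_regression(effects, [1.0, 1.0, 1.0])

    def test_null_type_one_error(self):
        # uncorrelated covariate: rejection near 0.05 over replicates
        rng = np.random.default_rng(5)
        rejections = 0
        n_rep = 400
        for _ in range(n_rep):
            thetas = rng.normal(0.2, 0.1, 8)
            effects = _effects(list(thetas), [0.1] * 8)
            x = list(rng.normal(0, 1, 8))
            _, _, p = mc.meta_regression(effects, x)
            rejections += p < 0.05
        assert 0.02 <= rejections / n_rep <= 0.10


class TestCoverage:
    def test_fixed_effect_ci_nominal_coverage_small(self):
        # quick version of the calibration check (full size in acceptance)
        covered = 0
        n_rep = 300
        for rep in range(n_rep):
            cfg = mc.SimulationConfig(n_studies=10, maf=0.3, or2=1.3**2,
                                      lambda_true=0.5, tau2=0.0,
                                      n_cases=2000, n_controls=2000, seed=50000 + rep)
            records, _ = mc.simulate_catalogue(cfg)
            m = mc.pool_fixed([mc.effect_from_record(r) for r in records])
            covered += m.ci_low <= 1.3 <= m.ci_high
        assert 0.91 <= covered / n_rep <= 0.99
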