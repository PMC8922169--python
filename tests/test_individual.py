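"""Between-/within-worker variance decomposition and the BOHS-NVvA test."""

import math

import numpy as np
import pytest
from scipy import stats

from ohcompliance import (
    InsufficientDataError,
    NoRepeatsError,
    OELSpec,
    Outcome,
    Route,
    SEGSpec,
    VarianceComponents,
    Z95,
    bohs_nvva_test,
    fit_lognormal,
    generate_seg,
    individual_theta,
    sensitivity_filter,
    statistical_test_1995,
    variance_components,
)

from conftest import make_seg


def _manual_anova(groups):
    """Independent mean-square oracle: direct textbook computation."""
    sizes = np.array([len(g) for g in groups], float)
    n, k = sizes.sum(), len(groups)
    allv = np.concatenate(groups)
    grand = allv.mean()
    ssw = sum(((np.asarray(g) - np.mean(g)) ** 2).sum() for g in groups)
    ssb = sum(m * (np.mean(g) - grand) ** 2 for m, g in zip(sizes, groups))
    msw = ssw / (n - k)
    msb = ssb / (k - 1)
    n0 = (n - (sizes**2).sum() / n) / (k - 1)
    return grand, msw, max(0.0, (msb - msw) / n0), n0


class TestVarianceComponents:
    def test_within_constant_workers(self):
        # each worker perfectly repeatable, workers differ
        seg = make_seg("A", {"w1": [0.2, 0.2], "w2": [0.4, 0.4], "w3": [0.8, 0.8]})
        vc = variance_components(seg)
        assert vc.sigma2_w == pytest.approx(0.0, abs=1e-15)
        means = np.log([0.2, 0.4, 0.8])
        assert vc.sigma2_b == pytest.approx(np.var(means, ddof=1))
        assert vc.rho_b == pytest.approx(1.0)

    def test_all_values_equal(self):
        seg = make_seg("A", {"w1": [0.5] * 3, "w2": [0.5] * 3})
        vc = variance_components(seg)
        assert vc.sigma2_b == 0.0
        assert vc.sigma2_w == 0.0
        assert vc.rho_b == 0.0

    def test_balanced_matches_mean_square_oracle(self):
        rng = np.random.default_rng(42)
        groups = [list(rng.normal(0.0, 1.0, 4)) for _ in range(5)]
        seg = make_seg(
            "A", {f"w{i}": [math.exp(v) for v in g] for i, g in enumerate(groups)}
        )
        vc = variance_components(seg)
        grand, msw, s2b, n0 = _manual_anova(groups)
        assert vc.mu_log == pytest.approx(grand, abs=1e-10)
        assert vc.sigma2_w == pytest.approx(msw, abs=1e-10)
        assert vc.sigma2_b == pytest.approx(s2b, abs=1e-10)
        assert vc.n0 == pytest.approx(4.0)

    def test_unbalanced_matches_oracle_and_f_statistic(self):
        rng = np.random.default_rng(7)
        sizes = [2, 3, 5, 1, 4]
        # distinct worker means so the between-worker signal is not clamped
        groups = [list(rng.normal(0.8 * i, 0.5, s)) for i, s in enumerate(sizes)]
        seg = make_seg(
            "A", {f"w{i}": [math.exp(v) for v in g] for i, g in enumerate(groups)}
        )
        vc = variance_components(seg)
        grand, msw, s2b, n0 = _manual_anova(groups)
        assert vc.sigma2_w == pytest.approx(msw, abs=1e-12)
        assert vc.sigma2_b == pytest.approx(s2b, abs=1e-12)
        assert vc.n0 == pytest.approx(n0, abs=1e-12)
        # cross-check mean squares against scipy's one-way ANOVA F statistic
        f = stats.f_oneway(*groups)
        msb = s2b * n0 + msw
        assert msb / msw == pytest.approx(f.statistic, rel=1e-10)

    def test_negative_between_estimate_clamped(self):
        # between-worker spread far smaller than within-worker noise
        seg = make_seg("A", {"w1": [0.2, 0.9, 0.3], "w2": [0.25, 0.85, 0.35]})
        vc = variance_components(seg)
        assert vc.sigma2_b >= 0.0

    def test_single_worker_with_all_repeats(self):
        seg = make_seg("A", {"w1": [0.2, 0.3, 0.25, 0.4, 0.35, 0.3]})
        vc = variance_components(seg)
        assert vc.sigma2_b == 0.0
        assert math.isnan(vc.n0)

    def test_preconditions(self):
        with pytest.raises(InsufficientDataError):
            variance_components(make_seg("A", {"w1": [0.2, 0.3]}))
        no_rep = make_seg("A", {f"w{i}": [0.2] for i in range(6)})
        with pytest.raises(NoRepeatsError):
            variance_components(no_rep)


class TestIndividualTheta:
    def test_half_when_group_p95_at_oel(self, oel):
        s2w = 0.4
        mu = -Z95 * math.sqrt(s2w)
        vc = VarianceComponents(mu, 0.3, s2w, 5, 20, 4.0)
        assert individual_theta(vc, oel) == pytest.approx(0.5)

    def test_degenerate_between_variance(self, oel):
        low = VarianceComponents(math.log(0.2), 0.0, 0.1, 5, 20, 4.0)
        assert individual_theta(low, oel) == 0.0
        high = VarianceComponents(math.log(2.0), 0.0, 0.1, 5, 20, 4.0)
        assert individual_theta(high, oel) == 1.0

    def test_closed_form_value(self, oel):
        # frozen from Monte-Carlo over simulated worker means (±0.002)
        vc = VarianceComponents(math.log(0.2), 0.2, 0.5, 5, 20, 4.0)
        assert individual_theta(vc, oel) == pytest.approx(0.15912, abs=2e-4)

    def test_monotone_in_parameters(self, oel):
        base = VarianceComponents(math.log(0.2), 0.2, 0.5, 5, 20, 4.0)
        t0 = individual_theta(base, oel)
        up_mu = VarianceComponents(math.log(0.3), 0.2, 0.5, 5, 20, 4.0)
        up_w = VarianceComponents(math.log(0.2), 0.2, 0.8, 5, 20, 4.0)
        up_b = VarianceComponents(math.log(0.2), 0.5, 0.5, 5, 20, 4.0)
        assert individual_theta(up_mu, oel) > t0
        assert individual_theta(up_w, oel) > t0
        # group 95th percentile below OEL here, so more spread ⇒ more exceeders
        assert individual_theta(up_b, oel) > t0


class TestBohsNvvaTest:
    def test_homogeneous_seg_routes_to_group_test(self, oel):
        seg = make_seg(
            "A", {"w1": [0.09, 0.11, 0.10], "w2": [0.10, 0.095, 0.105]}
        )
        res = bohs_nvva_test(seg, oel)
        assert res.route is Route.GROUP_TEST
        assert res.decision.outcome is Outcome.COMPLIANCE
        assert res.decision.statistic < 0.05

    def test_heterogeneous_seg_routes_to_individual_test(self, oel):
        # workers internally constant at 0.5 and 2.0: rho_B = 1, theta = 0.5
        seg = make_seg("A", {"w1": [0.5] * 3, "w2": [2.0] * 3})
        res = bohs_nvva_test(seg, oel)
        assert res.route is Route.INDIVIDUAL_TEST
        assert res.rho_b == pytest.approx(1.0)
        assert res.theta == pytest.approx(0.5)
        assert res.decision.outcome is Outcome.NON_COMPLIANCE

    def test_individual_route_compliant_when_theta_small(self, oel):
        seg = make_seg("A", {"w1": [0.010] * 3, "w2": [0.012] * 3})
        res = bohs_nvva_test(seg, oel)
        assert res.route is Route.INDIVIDUAL_TEST
        assert res.theta < 0.20
        assert res.decision.outcome is Outcome.COMPLIANCE

    def test_decision_flips_across_theta_threshold(self, oel):
        """theta just below 0.20 is compliant; just above is not.

        Two internally constant workers give sigma_B = |Δlog|/√2 and
        mu = mean log, so theta = 1 − Φ(−mu/sigma_B) is exactly steerable.
        """
        z80 = stats.norm.ppf(0.80)
        sb = 0.5 / math.sqrt(2)  # from Δlog = 0.5
        for eps, expected in ((0.02, Outcome.COMPLIANCE), (-0.02, Outcome.NON_COMPLIANCE)):
            mu = -(z80 + eps) * sb
            lo, hi = mu - 0.25, mu + 0.25
            seg = make_seg(
                "A", {"w1": [math.exp(lo)] * 3, "w2": [math.exp(hi)] * 3}
            )
            res = bohs_nvva_test(seg, oel)
            assert res.route is Route.INDIVIDUAL_TEST
            assert res.decision.outcome is expected

    def test_zero_between_variance_limit_matches_group_rule(self, oel):
        """With sigma2_B = 0 the BOHS decision equals the 5%-exceedance test."""
        for seed in range(20):
            spec = SEGSpec(
                seg_id=f"S{seed}",
                n_workers=10,
                repeats_per_worker=(4,) * 10,
                mu_log=math.log(0.3),
                sigma2_b=0.0,
                sigma2_w=0.5,
                seed=seed,
            )
            seg = generate_seg(spec)
            res = bohs_nvva_test(seg, oel)
            group = statistical_test_1995(fit_lognormal(seg.concentrations()), oel)
            assert res.decision.outcome is group.outcome


class TestSensitivityFilter:
    def test_single_repeat_worker_excluded(self):
        one = make_seg("A", {"w1": [0.1, 0.2], "w2": [0.3], "w3": [0.4]})
        two = make_seg("B", {"w1": [0.1, 0.2, 0.3], "w2": [0.3, 0.4, 0.2]})
        assert sensitivity_filter([one, two]) == [two]

    def test_empty_input(self):
        assert sensitivity_filter([]) == []
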