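"""Closed testing machinery: Simes, combination, stage p-values, outcomes."""

import math

import numpy as np
import pytest
from hypothesis import given, strategies as st
from scipy.stats import norm

from enrichtrial import (
    DesignConfig,
    Stage1Data,
    Stage2Data,
    TrialRecord,
    adaptive_outcome,
    combine,
    ff_outcome,
    fs_outcome,
    simes,
    stage_pvalues,
)
from enrichtrial.testing import _reject_enrich, _reject_no_enrich, _stage1_z


@pytest.mark.parametrize(
    "p1,p3,expected",
    [(0.5, 0.5, 0.5), (0.01, 0.04, 0.02), (0.03, 0.60, 0.06)],
)
def test_simes_values(p1, p3, expected):
    assert simes(p1, p3) == pytest.approx(expected)
    assert simes(p3, p1) == pytest.approx(expected)  # symmetry


@given(p1=st.floats(0, 1), p3=st.floats(0, 1))
def test_simes_bounds(p1, p3):
    s = simes(p1, p3)
    lo = min(p1, p3)
    assert lo - 1e-15 <= s <= min(1.0, 2.0 * lo) + 1e-15
    assert s <= max(p1, p3) + 1e-15


def test_simes_rejects_out_of_range():
    with pytest.raises(ValueError):
        simes(-0.1, 0.5)
    with pytest.raises(ValueError):
        simes(0.5, 1.2)


class TestCombine:
    w = 1 / math.sqrt(2)

    def test_half_is_fixed_point(self):
        assert combine(0.5, 0.5, 0.6, 0.8) == pytest.approx(0.5)

    def test_equal_alpha_inputs(self):
        expected = 1 - norm.cdf(math.sqrt(2) * norm.ppf(0.975))
        assert combine(0.025, 0.025, self.w, self.w) == pytest.approx(
            expected, rel=1e-6
        )
        assert expected == pytest.approx(0.00278, abs=2e-5)

    @given(
        p1=st.floats(0.001, 0.999),
        p2=st.floats(0.001, 0.999),
        d=st.floats(0.001, 0.2),
    )
    def test_strictly_decreasing_in_each_argument(self, p1, p2, d):
        w = self.w
        if p1 + d < 1:
            assert combine(p1 + d, p2, w, w) > combine(p1, p2, w, w)
        if p2 + d < 1:
            assert combine(p1, p2 + d, w, w) > combine(p1, p2, w, w)

    def test_degenerate_pvalues_clamped(self):
        assert 0.0 <= combine(0.0, 0.5, self.w, self.w) < 0.5
        assert 0.5 < combine(1.0, 0.5, self.w, self.w) <= 1.0

    def test_invalid_weights(self):
        with pytest.raises(ValueError):
            combine(0.5, 0.5, 0.5, 0.5)


class TestStagePValues:
    def test_null_interim_gives_uniform_center(self, config):
        ps = stage_pvalues(Stage1Data(0.0, 0.0), config)
        assert ps.p1 == pytest.approx(0.5)
        assert ps.p3 == pytest.approx(0.5)
        assert ps.p13 == pytest.approx(0.5)

    def test_enriched_stage2_p13_equals_p1(self, config):
        est = 1.959964 / math.sqrt(0.5 * 0.105)
        ps = stage_pvalues(Stage2Data(enriched=True, est1=est), config)
        assert ps.p1 == pytest.approx(0.025, rel=1e-5)
        assert ps.p13 == ps.p1
        assert ps.p3 is None

    def test_stage1_simes_from_zscores(self, config):
        # choose est so that z1 = 2.5 and z3 = 2.0
        z1, z3 = 2.5, 2.0
        est1 = z1 / math.sqrt(0.25 * 0.105)
        est3 = z3 / math.sqrt(0.5 * 0.105)
        est2 = (est3 - 0.5 * est1) / 0.5
        ps = stage_pvalues(Stage1Data(est1, est2), config)
        p1, p3 = 1 - norm.cdf(2.5), 1 - norm.cdf(2.0)
        assert ps.p13 == pytest.approx(min(2 * p1, p3), rel=1e-9)
        assert ps.p13 == pytest.approx(0.0124, abs=2e-4)

    def test_information_scaling_by_stage(self, config):
        """The same estimate is stronger evidence in the stage with the
        larger information share."""
        p_s1 = stage_pvalues(Stage1Data(5.0, 5.0), config).p1
        p_s2 = stage_pvalues(
            Stage2Data(enriched=False, est1=5.0, est2=5.0), config
        ).p1
        assert p_s1 == pytest.approx(p_s2)  # tau = 0.5 is symmetric
        p_enr = stage_pvalues(Stage2Data(enriched=True, est1=5.0), config).p1
        assert p_enr < p_s2  # enrichment doubles the stage-2 information


class TestAdaptiveOutcome:
    def test_overwhelming_evidence_no_enrichment(self, config):
        rec = TrialRecord(
            stage1=Stage1Data(50.0, 50.0),
            decision=2,
            stage2=Stage2Data(enriched=False, est1=50.0, est2=50.0),
        )
        out = adaptive_outcome(rec, config)
        assert out.reject_h01 and out.reject_h03
        assert not out.r1 and out.r3

    def test_enriched_trial_never_rejects_h03(self, config):
        rec = TrialRecord(
            stage1=Stage1Data(50.0, 50.0),
            decision=1,
            stage2=Stage2Data(enriched=True, est1=50.0),
        )
        out = adaptive_outcome(rec, config)
        assert out.reject_h01
        assert not out.reject_h03
        assert out.r1

    def test_null_data_rejects_nothing(self, config):
        rec = TrialRecord(
            stage1=Stage1Data(-1.0, 0.0),
            decision=2,
            stage2=Stage2Data(enriched=False, est1=0.0, est2=-2.0),
        )
        out = adaptive_outcome(rec, config)
        assert not out.reject_h01 and not out.reject_h03
        assert not out.r1 and not out.r3

    def test_coherence_rejection_implies_small_pvalues(self, config, rng):
        """Closed-test coherence: rejection of H01 requires the combined
        P1 and P13 both at or below alpha."""
        for _ in range(200):
            e = rng.normal(2.0, 6.0, size=4)
            rec = TrialRecord(
                stage1=Stage1Data(e[0], e[1]),
                decision=2,
                stage2=Stage2Data(enriched=False, est1=e[2], est2=e[3]),
            )
            out = adaptive_outcome(rec, config)
            if out.reject_h01:
                assert out.combined.p1 <= config.alpha
                assert out.combined.p13 <= config.alpha
            if not out.reject_h01 and not out.reject_h03:
                assert min(out.combined.p1, out.combined.p3) > config.alpha or (
                    out.combined.p13 > config.alpha
                )


class TestFixedDesigns:
    def test_ff_intersection_blocks_rejection(self, config):
        # z1 = 1.5, z3 = 2.2: both elementary p-values small-ish but the
        # Simes p-value 0.0278 exceeds alpha, so nothing is rejected.
        est1 = 1.5 / math.sqrt(0.5 * 0.105)
        est3 = 2.2 / math.sqrt(0.105)
        out = ff_outcome(est1, est3, config)
        assert out.combined.p13 == pytest.approx(0.0278, abs=2e-4)
        assert not out.reject_h01 and not out.reject_h03

    def test_ff_rejects_both_with_strong_evidence(self, config):
        est1 = 3.5 / math.sqrt(0.5 * 0.105)
        est3 = 3.5 / math.sqrt(0.105)
        out = ff_outcome(est1, est3, config)
        assert out.reject_h01 and out.reject_h03

    def test_ff_can_reject_h03_alone(self, config):
        est1 = -1.0 / math.sqrt(0.5 * 0.105)
        est3 = 2.5 / math.sqrt(0.105)
        out = ff_outcome(est1, est3, config)
        assert out.reject_h03 and not out.reject_h01

    def test_fs_boundary_and_null(self, config):
        est = 1.959964 / math.sqrt(0.105)
        assert fs_outcome(est, config).reject_h01  # p = alpha rejects
        assert not fs_outcome(0.0, config).reject_h01
        assert not fs_outcome(est, config).reject_h03

    def test_fs_power_at_effect_ten(self, config):
        # P(reject | theta1 = 10) = Phi(10 sqrt(I) - z_alpha) = 0.90
        p = norm.cdf(10 * math.sqrt(0.105) - norm.ppf(0.975))
        assert p == pytest.approx(0.90, abs=5e-3)


class TestPoolingIdentity:
    def test_combined_z_equals_pooled_estimate_z(self, config, rng):
        """With sqrt(tau) weights and no enrichment the combined H01
        z-statistic equals the z-statistic of the pooled estimate
        tau*est1_s1 + (1-tau)*est1_s2 at the full information lambda*I."""
        for lam, tau in [(0.5, 0.5), (0.3, 0.4), (0.7, 0.2)]:
            cfg = DesignConfig(lambda_frac=lam, tau=tau, info_total=0.105)
            e = rng.normal(3.0, 5.0, size=4)
            z1_1, z3_1, _ = _stage1_z(e[0], e[1], cfg)
            z1_2 = e[2] * math.sqrt(lam * (1 - tau) * 0.105)
            zc = cfg.w1 * z1_1 + cfg.w2 * z1_2
            pooled = tau * e[0] + (1 - tau) * e[2]
            z_pooled = pooled * math.sqrt(lam * 0.105)
            assert zc == pytest.approx(z_pooled, abs=1e-10)


class TestFWERStrongControl:
    """The headline guarantee: whatever the enrichment rule, the adaptive
    closed test rejects a true null with probability at most alpha."""

    N = 100_000

    @pytest.mark.parametrize(
        "theta1,theta2",
        [
            (0.0, 0.0),  # both null
            (0.0, -8.0),  # theta1 = 0, theta3 < 0
            (-6.0, 6.0),  # theta1 < 0, theta3 = 0
        ],
    )
    @pytest.mark.parametrize("rule", ["always", "never", "random"])
    def test_fwer_at_null_configurations(self, config, theta1, theta2, rule):
        rng = np.random.default_rng(hash((rule, theta1, theta2)) % 2**31)
        lam = config.lambda_frac
        t3 = lam * theta1 + (1 - lam) * theta2
        e1 = theta1 + rng.standard_normal(self.N) * math.sqrt(
            config.var_stage1_s1
        )
        e2 = theta2 + rng.standard_normal(self.N) * math.sqrt(
            config.var_stage1_s2
        )
        z1_1, z3_1, z13_1 = _stage1_z(e1, e2, config)
        if rule == "always":
            enrich = np.ones(self.N, dtype=bool)
        elif rule == "never":
            enrich = np.zeros(self.N, dtype=bool)
        else:
            enrich = rng.random(self.N) < 0.5
        false_rej = np.zeros(self.N, dtype=bool)
        idx_e = np.flatnonzero(enrich)
        idx_c = np.flatnonzero(~enrich)
        if idx_e.size:
            s2 = theta1 + rng.standard_normal(idx_e.size) * math.sqrt(
                config.var_stage2_s1_enriched
            )
            r01 = _reject_enrich(z1_1[idx_e], z13_1[idx_e], s2, config)
            false_rej[idx_e] = r01 if theta1 <= 0 else False
        if idx_c.size:
            s1 = theta1 + rng.standard_normal(idx_c.size) * math.sqrt(
                config.var_stage2_s1
            )
            s2 = theta2 + rng.standard_normal(idx_c.size) * math.sqrt(
                config.var_stage2_s2
            )
            r01, r03 = _reject_no_enrich(
                z1_1[idx_c], z3_1[idx_c], z13_1[idx_c], s1, s2, config
            )
            bad = np.zeros(idx_c.size, dtype=bool)
            if theta1 <= 0:
                bad |= r01
            if t3 <= 1e-12:
                bad |= r03
            false_rej[idx_c] = bad
        rate = false_rej.mean()
        mc_se = math.sqrt(config.alpha * (1 - config.alpha) / self.N)
        assert rate <= config.alpha + 3 * mc_se
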