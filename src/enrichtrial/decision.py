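"""Bayes-optimal interim enrichment decision.

At the interim analysis the sufficient statistic x1 = (est1, est2) is
observed and the trial must either enrich (d = 1, recruit only from S1 in
stage 2, test only H01) or continue in the full population (d = 2).  The
Bayes rule chooses the option with the larger conditional expected gain
E{G(theta, X) | X1 = x1, d}, where by default

    G(theta, X) = lambda * theta1 * R1 + theta3 * R3

rewards a subpopulation-only claim in proportion to the subpopulation size
and effect, and a full-population claim in proportion to the overall
effect.  The expectation is over the posterior of theta given x1 and over
the stage-2 data.

For the enrichment option the stage-2 sampling distribution can be
integrated out analytically: the closed test rejects H01 after enrichment
exactly when the stage-2 estimate clears a critical value kappa(x1) that is
linear in the stage-1 z-statistics, so the conditional rejection
probability is a normal tail probability.  For the continuation option one
stage-2 dataset is simulated per posterior draw (replicating stage 2 per
draw is less efficient than spending the effort on more posterior draws).
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Callable, Optional, Tuple

import numpy as np
from scipy.special import ndtr, ndtri

from .design import DesignConfig, Stage1Data, Theta
from .prior import Posterior, Prior, posterior_update, sample_posterior
from .testing import TestOutcome, _reject_no_enrich, _stage1_z

__all__ = [
    "GainSpec",
    "DecisionEvaluation",
    "critical_value",
    "expected_gain_enrich",
    "expected_gain_continue",
    "decide",
    "evaluate_gain",
]


@dataclass(frozen=True)
class GainSpec:
    """Gain assigned to a completed trial.

    The default is lambda*theta1 if only H01 is rejected, theta3 if H03 is
    rejected, 0 otherwise.  A custom ``(theta, outcome, config) -> float``
    strategy may be supplied to reward the two claims differently; the
    decision and boundary machinery only exercise the default.
    """

    strategy: Optional[Callable[[Theta, TestOutcome, DesignConfig], float]] = None

    def __call__(
        self, theta: Theta, outcome: TestOutcome, config: DesignConfig
    ) -> float:
        if self.strategy is not None:
            return float(self.strategy(theta, outcome, config))
        lam = config.lambda_frac
        if outcome.r3:
            return theta.theta3(lam)
        if outcome.r1:
            return lam * theta.theta1
        return 0.0


def evaluate_gain(theta: Theta, outcome: TestOutcome, config: DesignConfig) -> float:
    """G(theta, X) = lambda*theta1*R1 + theta3*R3 for one completed trial."""
    return GainSpec()(theta, outcome, config)


@dataclass(frozen=True)
class DecisionEvaluation:
    """Monte Carlo comparison of the two interim options at a given x1."""

    gain_enrich: float
    gain_continue: float
    se_enrich: float
    se_continue: float
    decision: int
    m_used: int


def critical_value(x1: Stage1Data, config: DesignConfig) -> float:
    """Threshold kappa(x1) on the enriched stage-2 estimate.

    After enrichment the combined z-statistics for H01 and H0,13 are both
    increasing linear functions of the stage-2 estimate, so H01 is rejected
    by the closed test iff est1_stage2 >= kappa with

        kappa = max(c1, c13) / sqrt((1-tau) I),
        c_j = (Phi^-1(1-alpha) - w1 z_j^(1)) / w2,  j in {1, 13}.
    """
    if config.w2 == 0:
        raise ValueError("w2 = 0 leaves stage 2 without influence; kappa undefined")
    z1, _, z13 = _stage1_z(x1.est1, x1.est2, config)
    zalpha = -ndtri(config.alpha)
    c1 = (zalpha - config.w1 * z1) / config.w2
    c13 = (zalpha - config.w1 * z13) / config.w2
    return float(
        max(c1, c13) / math.sqrt((1.0 - config.tau) * config.info_total)
    )


def expected_gain_enrich(
    x1: Stage1Data, theta_sample: np.ndarray, config: DesignConfig
) -> Tuple[float, float]:
    """Conditional expected gain of enriching, analytic in stage 2.

    Averages lambda*theta_i1 * P(est1_stage2 >= kappa(x1) | theta_i1) over
    the posterior sample; the stage-2 tail probability is exact, so the
    only Monte Carlo noise is over theta.  Returns (mean, standard error).
    """
    theta_sample = np.asarray(theta_sample, dtype=float)
    if theta_sample.size == 0:
        raise ValueError("theta_sample must be nonempty")
    kappa = critical_value(x1, config)
    s2_sd = math.sqrt(config.var_stage2_s1_enriched)
    t1 = theta_sample[:, 0]
    p_rej = ndtr((t1 - kappa) / s2_sd)
    vals = config.lambda_frac * t1 * p_rej
    m = vals.size
    se = float(vals.std(ddof=1) / math.sqrt(m)) if m > 1 else 0.0
    return float(vals.mean()), se


def expected_gain_continue(
    x1: Stage1Data,
    theta_sample: np.ndarray,
    config: DesignConfig,
    rng: np.random.Generator,
) -> Tuple[float, float]:
    """Conditional expected gain of continuing in the full population.

    One stage-2 dataset is simulated per posterior draw; the closed test is
    applied with the fixed stage-1 data and the gain evaluated at that
    draw's theta.  Returns (mean, standard error).
    """
    theta_sample = np.asarray(theta_sample, dtype=float)
    if theta_sample.size == 0:
        raise ValueError("theta_sample must be nonempty")
    lam = config.lambda_frac
    z1_1, z3_1, z13_1 = _stage1_z(x1.est1, x1.est2, config)
    t1, t2 = theta_sample[:, 0], theta_sample[:, 1]
    e1 = t1 + rng.standard_normal(t1.size) * math.sqrt(config.var_stage2_s1)
    e2 = t2 + rng.standard_normal(t2.size) * math.sqrt(config.var_stage2_s2)
    rej01, rej03 = _reject_no_enrich(z1_1, z3_1, z13_1, e1, e2, config)
    t3 = lam * t1 + (1.0 - lam) * t2
    vals = np.where(rej03, t3, np.where(rej01, lam * t1, 0.0))
    m = vals.size
    se = float(vals.std(ddof=1) / math.sqrt(m)) if m > 1 else 0.0
    return float(vals.mean()), se


def decide(
    x1: Stage1Data,
    prior: Prior,
    config: DesignConfig,
    m: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    z_tie: float = 0.0,
    posterior: Optional[Posterior] = None,
) -> DecisionEvaluation:
    """Bayes decision at x1: 1 (enrich) or 2 (continue).

    One posterior sample of size ``m`` serves both options (common random
    numbers for the comparison).  Enrichment is chosen only when its
    estimated gain exceeds the continuation gain by more than
    ``z_tie * max(se_enrich, se_continue)``; ties go to continuation, which
    preserves the ability to test H03.  A precomputed ``posterior`` may be
    passed to skip the conjugate update.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    if posterior is None:
        posterior = posterior_update(prior, x1, config)
    sample = sample_posterior(posterior, m, rng)
    g_e, se_e = expected_gain_enrich(x1, sample, config)
    g_c, se_c = expected_gain_continue(x1, sample, config, rng)
    margin = z_tie * max(se_e, se_c)
    decision = 1 if g_e > g_c + margin else 2
    return DecisionEvaluation(
        gain_enrich=g_e,
        gain_continue=g_c,
        se_enrich=se_e,
        se_continue=se_c,
        decision=decision,
        m_used=m,
    )
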