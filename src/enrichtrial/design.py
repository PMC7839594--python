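"""Trial design constants and the normal sampling model.

A two-population phase III trial compares a new treatment with control in a
pre-specified biomarker subpopulation S1 (a fraction ``lambda_frac`` of the
full population) and its complement S2.  After a fraction ``tau`` of the
total sample has been observed, an interim analysis decides whether to
*enrich* -- restrict the rest of recruitment to S1 -- or continue in the
full population.

With a total sample of ``n`` patients randomised 1:1 to treatment and
control and responses of common standard deviation ``sigma``, the full-trial
estimate of the overall effect theta3 carries Fisher information

    I = n / (4 sigma^2).

All stage-wise effect estimates are normal with precisions that are simple
multiples of I, so the trial is simulated at the summary-statistic level;
no patient-level data are generated.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Optional

import numpy as np
from scipy import stats

__all__ = [
    "DesignConfig",
    "Theta",
    "Stage1Data",
    "Stage2Data",
    "TrialRecord",
    "information_from_n",
    "calibrate_information",
    "simulate_stage1",
    "simulate_stage2",
]

_W_TOL = 1e-12
_INFO_AGREE_TOL = 1e-9


def information_from_n(n_total: float, sigma: float) -> float:
    """Fisher information I = n / (4 sigma^2) of the full-trial estimate of
    theta3 under equal randomisation.

    Parameters
    ----------
    n_total : total number of patients (> 0).
    sigma : response standard deviation (> 0), in effect units.
    """
    if n_total <= 0 or sigma <= 0:
        raise ValueError("n_total and sigma must be positive")
    return n_total / (4.0 * sigma**2)


def calibrate_information(delta: float, power: float, alpha: float) -> float:
    """Information giving the stated one-sided power at effect ``delta``.

    For a single level-``alpha`` one-sided test of H03: theta3 <= 0, the
    information required for power ``power`` at theta3 = delta is

        I = ((Phi^-1(power) + Phi^-1(1 - alpha)) / delta)^2.
    """
    if not (0.0 < power < 1.0):
        raise ValueError("power must be in (0, 1)")
    if not (0.0 < alpha < 0.5):
        raise ValueError("alpha must be in (0, 0.5)")
    if delta <= 0:
        raise ValueError("delta must be positive")
    return float(((stats.norm.ppf(power) + stats.norm.ppf(1.0 - alpha)) / delta) ** 2)


@dataclass(frozen=True)
class DesignConfig:
    """All fixed constants of an adaptive enrichment design.

    Parameters
    ----------
    lambda_frac : fraction of the population in subpopulation S1, in (0, 1).
    tau : fraction of the total sample observed at the interim analysis.
    alpha : one-sided familywise error level.
    info_total : total Fisher information I (1/effect^2).  May be omitted
        when ``n_total`` and ``sigma`` are given, in which case
        I = n/(4 sigma^2); if both forms are supplied they must agree.
    n_total, sigma : optional sample-size parameterisation.
    w1, w2 : inverse-normal combination weights with w1^2 + w2^2 = 1.
        Default sqrt(tau), sqrt(1 - tau), which makes the combined
        z-statistic equal to the pooled-estimate z-statistic when no
        enrichment occurs.
    """

    lambda_frac: float
    tau: float
    alpha: float = 0.025
    info_total: Optional[float] = None
    n_total: Optional[float] = None
    sigma: Optional[float] = None
    w1: Optional[float] = None
    w2: Optional[float] = None

    def __post_init__(self) -> None:
        for name in ("lambda_frac", "tau", "alpha"):
            v = getattr(self, name)
            if not (0.0 < v < 1.0):
                raise ValueError(f"{name} must be strictly inside (0, 1), got {v}")
        info = self.info_total
        if self.n_total is not None or self.sigma is not None:
            if self.n_total is None or self.sigma is None:
                raise ValueError("n_total and sigma must be supplied together")
            derived = information_from_n(self.n_total, self.sigma)
            if info is not None and abs(info - derived) > _INFO_AGREE_TOL:
                raise ValueError(
                    f"info_total={info} disagrees with n/(4 sigma^2)={derived}"
                )
            info = derived
        if info is None:
            raise ValueError("supply info_total or (n_total, sigma)")
        if info <= 0:
            raise ValueError("information must be positive")
        object.__setattr__(self, "info_total", float(info))
        if (self.w1 is None) != (self.w2 is None):
            raise ValueError("w1 and w2 must be supplied together")
        if self.w1 is None:
            object.__setattr__(self, "w1", math.sqrt(self.tau))
            object.__setattr__(self, "w2", math.sqrt(1.0 - self.tau))
        if abs(self.w1**2 + self.w2**2 - 1.0) > _W_TOL:
            raise ValueError("combination weights must satisfy w1^2 + w2^2 = 1")

    # -- per-arm sample sizes (require the (n, sigma) parameterisation) -----

    def _require_n(self) -> float:
        if self.n_total is None:
            raise ValueError("per-arm counts need the (n_total, sigma) form")
        return self.n_total

    @property
    def m11(self) -> float:
        """Per-arm stage-1 count in S1: lambda*tau*n/2."""
        return self.lambda_frac * self.tau * self._require_n() / 2.0

    @property
    def m21(self) -> float:
        """Per-arm stage-1 count in S2: (1-lambda)*tau*n/2."""
        return (1.0 - self.lambda_frac) * self.tau * self._require_n() / 2.0

    @property
    def m12(self) -> float:
        """Per-arm stage-2 count in S1 without enrichment."""
        return self.lambda_frac * (1.0 - self.tau) * self._require_n() / 2.0

    @property
    def m22(self) -> float:
        """Per-arm stage-2 count in S2 without enrichment."""
        return (1.0 - self.lambda_frac) * (1.0 - self.tau) * self._require_n() / 2.0

    @property
    def m12_enriched(self) -> float:
        """Per-arm stage-2 count in S1 under enrichment: (1-tau)*n/2."""
        return (1.0 - self.tau) * self._require_n() / 2.0

    # -- stage-wise estimator variances --------------------------------------

    @property
    def var_stage1_s1(self) -> float:
        return 1.0 / (self.lambda_frac * self.tau * self.info_total)

    @property
    def var_stage1_s2(self) -> float:
        return 1.0 / ((1.0 - self.lambda_frac) * self.tau * self.info_total)

    @property
    def var_stage2_s1(self) -> float:
        return 1.0 / (self.lambda_frac * (1.0 - self.tau) * self.info_total)

    @property
    def var_stage2_s2(self) -> float:
        return 1.0 / ((1.0 - self.lambda_frac) * (1.0 - self.tau) * self.info_total)

    @property
    def var_stage2_s1_enriched(self) -> float:
        return 1.0 / ((1.0 - self.tau) * self.info_total)


@dataclass(frozen=True)
class Theta:
    """True treatment effects (theta1 in S1, theta2 in S2).

    The full-population effect theta3 = lambda*theta1 + (1-lambda)*theta2 is
    derived through :meth:`theta3`.
    """

    theta1: float
    theta2: float

    def theta3(self, lambda_frac: float) -> float:
        return lambda_frac * self.theta1 + (1.0 - lambda_frac) * self.theta2


@dataclass(frozen=True)
class Stage1Data:
    """Stage-1 effect estimates: the interim sufficient statistic X1."""

    est1: float
    est2: float

    def est3(self, lambda_frac: float) -> float:
        return lambda_frac * self.est1 + (1.0 - lambda_frac) * self.est2


@dataclass(frozen=True)
class Stage2Data:
    """Stage-2 effect estimates (X2).

    When the trial was enriched only S1 is sampled in stage 2, so ``est2``
    is absent and no stage-2 estimate of theta3 exists.
    """

    enriched: bool
    est1: float
    est2: Optional[float] = None

    def __post_init__(self) -> None:
        if self.enriched and self.est2 is not None:
            raise ValueError("est2 must be absent for an enriched stage 2")
        if not self.enriched and self.est2 is None:
            raise ValueError("est2 required when stage 2 is not enriched")

    def est3(self, lambda_frac: float) -> float:
        if self.enriched:
            raise ValueError("theta3 is not estimable after enrichment")
        return lambda_frac * self.est1 + (1.0 - lambda_frac) * self.est2


@dataclass(frozen=True)
class TrialRecord:
    """Full trial data X = (X1, d(X1), X2); decision 1 = enrich, 2 = continue."""

    stage1: Stage1Data
    decision: int
    stage2: Stage2Data

    def __post_init__(self) -> None:
        if self.decision not in (1, 2):
            raise ValueError("decision must be 1 (enrich) or 2 (continue)")
        if self.stage2.enriched != (self.decision == 1):
            raise ValueError("stage2.enriched inconsistent with decision")


def simulate_stage1(
    theta: Theta, config: DesignConfig, rng: np.random.Generator
) -> Stage1Data:
    """Draw the interim estimates.

    est1 ~ N(theta1, (lambda*tau*I)^-1) and est2 ~ N(theta2,
    ((1-lambda)*tau*I)^-1), independent given theta.
    """
    e1 = rng.normal(theta.theta1, math.sqrt(config.var_stage1_s1))
    e2 = rng.normal(theta.theta2, math.sqrt(config.var_stage1_s2))
    return Stage1Data(est1=float(e1), est2=float(e2))


def simulate_stage2(
    theta: Theta, config: DesignConfig, enrich: bool, rng: np.random.Generator
) -> Stage2Data:
    """Draw the stage-2 estimates, independent of stage 1 given theta.

    Enriched: est1 ~ N(theta1, ((1-tau)*I)^-1) only.  Not enriched:
    est1 ~ N(theta1, (lambda*(1-tau)*I)^-1) and est2 ~ N(theta2,
    ((1-lambda)*(1-tau)*I)^-1).
    """
    if enrich:
        e1 = rng.normal(theta.theta1, math.sqrt(config.var_stage2_s1_enriched))
        return Stage2Data(enriched=True, est1=float(e1))
    e1 = rng.normal(theta.theta1, math.sqrt(config.var_stage2_s1))
    e2 = rng.normal(theta.theta2, math.sqrt(config.var_stage2_s2))
    return Stage2Data(enriched=False, est1=float(e1), est2=float(e2))
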