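"""Closed testing with Simes intersection tests and inverse-normal combination.

Three one-sided null hypotheses are in play: H01: theta1 <= 0, H03:
theta3 <= 0 and their intersection H0,13.  The closed testing principle
rejects H01 overall only if level-alpha tests reject both H01 and H0,13
(similarly for H03), which gives strong familywise error control whatever
interim enrichment rule is used.

Per stage, the elementary p-values come from the normal z-statistics of the
stage's estimates and the intersection p-value from Simes' rule

    S(p, q) = min{2 min(p, q), max(p, q)}.

Stages are merged by the weighted inverse-normal combination

    W(P1, P2) = 1 - Phi(w1 Phi^-1(1 - P1) + w2 Phi^-1(1 - P2)),

with prespecified w1^2 + w2^2 = 1, so the combined statistic is standard
normal under the null regardless of the data-dependent enrichment decision.
After enrichment stage 2 contains no information on theta3: H03 is no
longer testable and the stage-2 intersection p-value is the stage-2
p-value for H01.

The module also provides the two nonadaptive comparator designs: the fixed
full-population design (FF; single-stage closed test of H01 and H03) and
the fixed subpopulation design (FS; all patients from S1, only H01 tested).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass
from typing import Optional, Union

import numpy as np
from scipy.special import ndtr, ndtri

from .design import DesignConfig, Stage1Data, Stage2Data, TrialRecord

__all__ = [
    "PValueSet",
    "TestOutcome",
    "simes",
    "combine",
    "stage_pvalues",
    "adaptive_outcome",
    "ff_outcome",
    "fs_outcome",
]

logger = logging.getLogger(__name__)

# Phi^-1 diverges at 0 and 1; degenerate p-values are clamped to the widest
# machine-representable open interval before inversion.
_P_LO = 1e-300
_P_HI = 1.0 - 1e-16


@dataclass(frozen=True)
class PValueSet:
    """One stage's p-values for H01, H03 and H0,13 (p3 absent if enriched)."""

    p1: float
    p13: float
    p3: Optional[float] = None

    @property
    def z1(self) -> float:
        return float(-ndtri(self.p1))

    @property
    def z3(self) -> float:
        if self.p3 is None:
            raise ValueError("no H03 p-value for an enriched stage")
        return float(-ndtri(self.p3))

    @property
    def z13(self) -> float:
        return float(-ndtri(self.p13))


@dataclass(frozen=True)
class TestOutcome:
    """Overall closed-test result.

    ``r1`` indicates H01 rejected while H03 is not (the subpopulation-only
    claim); ``r3`` indicates H03 rejected.  These are the indicators the
    gain function consumes and are mutually exclusive by construction.
    """

    reject_h01: bool
    reject_h03: bool
    combined: PValueSet

    @property
    def r1(self) -> bool:
        return self.reject_h01 and not self.reject_h03

    @property
    def r3(self) -> bool:
        return self.reject_h03


def simes(p1: float, p3: float) -> float:
    """Simes p-value for the intersection of two one-sided hypotheses."""
    if not (0.0 <= p1 <= 1.0 and 0.0 <= p3 <= 1.0):
        raise ValueError("p-values must lie in [0, 1]")
    return min(2.0 * min(p1, p3), max(p1, p3))


def _clamp(p: float) -> float:
    if p <= 0.0 or p >= 1.0:
        logger.warning("degenerate p-value %s clamped before Phi^-1", p)
        return min(max(p, _P_LO), _P_HI)
    return p


def combine(p_stage1: float, p_stage2: float, w1: float, w2: float) -> float:
    """Weighted inverse-normal combination of two stage-wise p-values."""
    if abs(w1 * w1 + w2 * w2 - 1.0) > 1e-12:
        raise ValueError("weights must satisfy w1^2 + w2^2 = 1")
    z1 = -ndtri(_clamp(p_stage1))
    z2 = -ndtri(_clamp(p_stage2))
    return float(1.0 - ndtr(w1 * z1 + w2 * z2))


def stage_pvalues(
    stage: Union[Stage1Data, Stage2Data], config: DesignConfig
) -> PValueSet:
    """p-values for one stage, using the stage-appropriate information.

    Stage 1: z1 = est1*sqrt(lambda*tau*I), z3 = est3*sqrt(tau*I).
    Stage 2 without enrichment: the same with tau replaced by 1-tau.
    Stage 2 with enrichment: z1 = est1*sqrt((1-tau)*I) and p13 = p1.
    """
    lam, tau, info = config.lambda_frac, config.tau, config.info_total
    if isinstance(stage, Stage1Data):
        z1 = stage.est1 * math.sqrt(lam * tau * info)
        z3 = stage.est3(lam) * math.sqrt(tau * info)
    elif stage.enriched:
        z1 = stage.est1 * math.sqrt((1.0 - tau) * info)
        p1 = float(ndtr(-z1))
        return PValueSet(p1=p1, p13=p1, p3=None)
    else:
        z1 = stage.est1 * math.sqrt(lam * (1.0 - tau) * info)
        z3 = stage.est3(lam) * math.sqrt((1.0 - tau) * info)
    p1 = float(ndtr(-z1))
    p3 = float(ndtr(-z3))
    return PValueSet(p1=p1, p3=p3, p13=simes(p1, p3))


def adaptive_outcome(record: TrialRecord, config: DesignConfig) -> TestOutcome:
    """Overall closed-test decision for a completed adaptive trial.

    H01 is rejected overall iff the combined P1 <= alpha and combined
    P13 <= alpha; H03 analogously, and never after enrichment (stage 2
    carries no theta3 information).
    """
    s1 = stage_pvalues(record.stage1, config)
    s2 = stage_pvalues(record.stage2, config)
    w1, w2, alpha = config.w1, config.w2, config.alpha
    p1c = combine(s1.p1, s2.p1, w1, w2)
    p13c = combine(s1.p13, s2.p13, w1, w2)
    if record.stage2.enriched:
        combined = PValueSet(p1=p1c, p13=p13c, p3=None)
        return TestOutcome(
            reject_h01=p1c <= alpha and p13c <= alpha,
            reject_h03=False,
            combined=combined,
        )
    p3c = combine(s1.p3, s2.p3, w1, w2)
    combined = PValueSet(p1=p1c, p3=p3c, p13=p13c)
    return TestOutcome(
        reject_h01=p1c <= alpha and p13c <= alpha,
        reject_h03=p3c <= alpha and p13c <= alpha,
        combined=combined,
    )


def ff_outcome(est1: float, est3: float, config: DesignConfig) -> TestOutcome:
    """Closed test of the fixed full-population design.

    ``est1`` and ``est3`` are the full-data estimates with variances
    (lambda*I)^-1 and I^-1; the intersection uses the single-stage Simes
    p-value (no combination step).
    """
    lam, info, alpha = config.lambda_frac, config.info_total, config.alpha
    p1 = float(ndtr(-est1 * math.sqrt(lam * info)))
    p3 = float(ndtr(-est3 * math.sqrt(info)))
    p13 = simes(p1, p3)
    combined = PValueSet(p1=p1, p3=p3, p13=p13)
    return TestOutcome(
        reject_h01=p1 <= alpha and p13 <= alpha,
        reject_h03=p3 <= alpha and p13 <= alpha,
        combined=combined,
    )


def fs_outcome(est1: float, config: DesignConfig) -> TestOutcome:
    """Single one-sided test of the fixed subpopulation design.

    All n patients come from S1, so est1 has variance I^-1; H03 is never
    tested.
    """
    p1 = float(ndtr(-est1 * math.sqrt(config.info_total)))
    combined = PValueSet(p1=p1, p13=p1, p3=None)
    return TestOutcome(
        reject_h01=p1 <= config.alpha, reject_h03=False, combined=combined
    )


# ---------------------------------------------------------------------------
# Vectorised kernels.  The scalar functions above define the contract; these
# evaluate the same closed tests on arrays and are what the decision and
# operating-characteristic machinery call in bulk.
# ---------------------------------------------------------------------------


def _simes_z(z1: np.ndarray, z3: np.ndarray) -> np.ndarray:
    """z-scale Simes statistic: Phi^-1(1 - S(p1, p3)) for p = 1 - Phi(z)."""
    p1 = ndtr(-np.asarray(z1))
    p3 = ndtr(-np.asarray(z3))
    p13 = np.minimum(2.0 * np.minimum(p1, p3), np.maximum(p1, p3))
    return -ndtri(np.clip(p13, _P_LO, _P_HI))


def _stage1_z(est1, est2, config: DesignConfig):
    """Stage-1 z-statistics (z1, z3, z13) for arrays of interim estimates."""
    lam, tau, info = config.lambda_frac, config.tau, config.info_total
    est1 = np.asarray(est1, dtype=float)
    est2 = np.asarray(est2, dtype=float)
    est3 = lam * est1 + (1.0 - lam) * est2
    z1 = est1 * math.sqrt(lam * tau * info)
    z3 = est3 * math.sqrt(tau * info)
    return z1, z3, _simes_z(z1, z3)


def _reject_no_enrich(z1_1, z3_1, z13_1, e1_2, e2_2, config: DesignConfig):
    """Rejection indicators (H01, H03) without enrichment.

    Stage-1 z-statistics may be scalars (a fixed interim dataset) or arrays
    broadcastable against the stage-2 estimate arrays.
    """
    lam, tau, info = config.lambda_frac, config.tau, config.info_total
    w1, w2 = config.w1, config.w2
    zalpha = -ndtri(config.alpha)
    e1_2 = np.asarray(e1_2, dtype=float)
    e2_2 = np.asarray(e2_2, dtype=float)
    e3_2 = lam * e1_2 + (1.0 - lam) * e2_2
    z1_2 = e1_2 * math.sqrt(lam * (1.0 - tau) * info)
    z3_2 = e3_2 * math.sqrt((1.0 - tau) * info)
    z13_2 = _simes_z(z1_2, z3_2)
    z1c = w1 * z1_1 + w2 * z1_2
    z3c = w1 * z3_1 + w2 * z3_2
    z13c = w1 * z13_1 + w2 * z13_2
    rej01 = (z1c >= zalpha) & (z13c >= zalpha)
    rej03 = (z3c >= zalpha) & (z13c >= zalpha)
    return rej01, rej03


def _reject_enrich(z1_1, z13_1, e1_2, config: DesignConfig):
    """H01 rejection indicator after enrichment (H03 is never rejected)."""
    tau, info = config.tau, config.info_total
    w1, w2 = config.w1, config.w2
    zalpha = -ndtri(config.alpha)
    z1_2 = np.asarray(e1_2, dtype=float) * math.sqrt((1.0 - tau) * info)
    z1c = w1 * z1_1 + w2 * z1_2
    z13c = w1 * z13_1 + w2 * z1_2
    return (z1c >= zalpha) & (z13c >= zalpha)


def _reject_ff(est1, est3, config: DesignConfig):
    """Vectorised FF closed test; returns (reject H01, reject H03)."""
    lam, info = config.lambda_frac, config.info_total
    zalpha = -ndtri(config.alpha)
    z1 = np.asarray(est1, dtype=float) * math.sqrt(lam * info)
    z3 = np.asarray(est3, dtype=float) * math.sqrt(info)
    z13 = _simes_z(z1, z3)
    return (z1 >= zalpha) & (z13 >= zalpha), (z3 >= zalpha) & (z13 >= zalpha)
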