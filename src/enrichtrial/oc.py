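"""Operating characteristics of adaptive and fixed designs.

Design-level performance is summarised by the expected gain E{G(theta, X)},
the probability P(R1) that only the subpopulation hypothesis H01 is
rejected, the probability P(R3) that the full-population hypothesis H03 is
rejected, and (for the adaptive design) the probability of enrichment.
Expectations are over the prior on theta and the sampling distribution of
the trial.

The adaptive (AE) and fixed full-population (FF) designs are evaluated by
Monte Carlo -- one full trial per replicate, with the AE interim decision
taken from a precomputed boundary rule.  The fixed subpopulation (FS)
design is a single one-sided z-test and is evaluated exactly: its rejection
probability given theta1 is Phi(theta1 sqrt(I) - z_alpha), which is plugged
in for point priors and integrated by adaptive quadrature over the theta1
marginal for normal priors.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import integrate
from scipy.special import ndtr, ndtri
from scipy.stats import norm

from .design import DesignConfig
from .prior import Prior
from .testing import _reject_enrich, _reject_ff, _reject_no_enrich, _stage1_z
from .boundary import DecisionRule, build_boundary, lookup_bulk

__all__ = [
    "OCResult",
    "evaluate_adaptive",
    "evaluate_ff",
    "evaluate_fs",
    "best_design_map",
    "sweep",
]


@dataclass(frozen=True)
class OCResult:
    """Operating characteristics of one design under one prior."""

    design: str
    e_gain: float
    p_r1: float
    p_r3: float
    se_gain: float
    se_r1: float
    se_r3: float
    n_reps: int
    p_enrich: Optional[float] = None
    se_enrich: Optional[float] = None

    def as_dict(self) -> Dict[str, object]:
        return {
            "design": self.design,
            "p_r1": self.p_r1,
            "p_r3": self.p_r3,
            "p_enrich": self.p_enrich,
            "e_gain": self.e_gain,
            "se_gain": self.se_gain,
            "n_reps": self.n_reps,
        }


def _draw_thetas(prior: Prior, n: int, rng: np.random.Generator) -> np.ndarray:
    if prior.kind == "point":
        return np.tile(np.array(prior.theta0, dtype=float), (n, 1))
    mean, cov = prior.mean, prior.cov
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    return mean + rng.standard_normal((n, 2)) @ L.T


def _binom_se(p: float, n: int) -> float:
    return math.sqrt(max(p * (1.0 - p), 0.0) / n)


def evaluate_adaptive(
    rule: DecisionRule,
    prior: Prior,
    config: DesignConfig,
    n: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> OCResult:
    """Simulate the adaptive design end to end.

    Per replicate: draw theta from the prior, simulate the interim
    estimates, read the enrichment decision off the boundary rule, simulate
    stage 2 accordingly, apply the closed test and evaluate the gain.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    lam = config.lambda_frac
    thetas = _draw_thetas(prior, n, rng)
    t1, t2 = thetas[:, 0], thetas[:, 1]
    e1 = t1 + rng.standard_normal(n) * math.sqrt(config.var_stage1_s1)
    e2 = t2 + rng.standard_normal(n) * math.sqrt(config.var_stage1_s2)
    enrich = lookup_bulk(rule, e1, e2) == 1
    z1_1, z3_1, z13_1 = _stage1_z(e1, e2, config)

    rej01 = np.zeros(n, dtype=bool)
    rej03 = np.zeros(n, dtype=bool)
    idx_e = np.flatnonzero(enrich)
    idx_c = np.flatnonzero(~enrich)
    # Stage-2 noise is drawn for every replicate in a fixed order so the
    # stream does not depend on the decision pattern.
    z2a = rng.standard_normal(n)
    z2b = rng.standard_normal(n)
    if idx_e.size:
        e1_2 = t1[idx_e] + z2a[idx_e] * math.sqrt(config.var_stage2_s1_enriched)
        rej01[idx_e] = _reject_enrich(z1_1[idx_e], z13_1[idx_e], e1_2, config)
    if idx_c.size:
        e1_2 = t1[idx_c] + z2a[idx_c] * math.sqrt(config.var_stage2_s1)
        e2_2 = t2[idx_c] + z2b[idx_c] * math.sqrt(config.var_stage2_s2)
        r01, r03 = _reject_no_enrich(
            z1_1[idx_c], z3_1[idx_c], z13_1[idx_c], e1_2, e2_2, config
        )
        rej01[idx_c] = r01
        rej03[idx_c] = r03

    t3 = lam * t1 + (1.0 - lam) * t2
    gains = np.where(rej03, t3, np.where(rej01, lam * t1, 0.0))
    p_r1 = float(np.mean(rej01 & ~rej03))
    p_r3 = float(np.mean(rej03))
    p_enrich = float(np.mean(enrich))
    return OCResult(
        design="AE",
        e_gain=float(gains.mean()),
        p_r1=p_r1,
        p_r3=p_r3,
        se_gain=float(gains.std(ddof=1) / math.sqrt(n)),
        se_r1=_binom_se(p_r1, n),
        se_r3=_binom_se(p_r3, n),
        n_reps=n,
        p_enrich=p_enrich,
        se_enrich=_binom_se(p_enrich, n),
    )


def evaluate_ff(
    prior: Prior,
    config: DesignConfig,
    n: int = 100_000,
    rng: Optional[np.random.Generator] = None,
) -> OCResult:
    """Monte Carlo evaluation of the fixed full-population design.

    The full-data estimates are built as the lambda-weighted sum of
    independent subpopulation estimates, which reproduces the joint normal
    law of (est1, est3) by construction.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if rng is None:
        rng = np.random.default_rng()
    lam, info = config.lambda_frac, config.info_total
    thetas = _draw_thetas(prior, n, rng)
    t1, t2 = thetas[:, 0], thetas[:, 1]
    e1 = t1 + rng.standard_normal(n) / math.sqrt(lam * info)
    e2 = t2 + rng.standard_normal(n) / math.sqrt((1.0 - lam) * info)
    e3 = lam * e1 + (1.0 - lam) * e2
    rej01, rej03 = _reject_ff(e1, e3, config)
    t3 = lam * t1 + (1.0 - lam) * t2
    gains = np.where(rej03, t3, np.where(rej01 & ~rej03, lam * t1, 0.0))
    p_r1 = float(np.mean(rej01 & ~rej03))
    p_r3 = float(np.mean(rej03))
    return OCResult(
        design="FF",
        e_gain=float(gains.mean()),
        p_r1=p_r1,
        p_r3=p_r3,
        se_gain=float(gains.std(ddof=1) / math.sqrt(n)),
        se_r1=_binom_se(p_r1, n),
        se_r3=_binom_se(p_r3, n),
        n_reps=n,
    )


def evaluate_fs(prior: Prior, config: DesignConfig) -> OCResult:
    """Exact operating characteristics of the fixed subpopulation design.

    P(R1 | theta1) = Phi(theta1 sqrt(I) - Phi^-1(1-alpha)); the gain is
    lambda * theta1 on rejection.  For a normal prior both quantities are
    integrated over the theta1 marginal.
    """
    info, lam, alpha = config.info_total, config.lambda_frac, config.alpha
    zalpha = -ndtri(alpha)
    sqrt_i = math.sqrt(info)

    def p_rej(t1):
        return ndtr(t1 * sqrt_i - zalpha)

    if prior.kind == "point" or (prior.kind == "bvn" and prior.var1 <= 1e-12):
        t1 = prior.theta0[0] if prior.kind == "point" else prior.mu1
        p = float(p_rej(t1))
        e_gain = lam * t1 * p
    else:
        mu, sd = prior.mu1, math.sqrt(prior.var1)
        lo, hi = mu - 12.0 * sd, mu + 12.0 * sd
        p, err_p = integrate.quad(
            lambda t: p_rej(t) * norm.pdf(t, mu, sd), lo, hi
        )
        e_gain, err_g = integrate.quad(
            lambda t: lam * t * p_rej(t) * norm.pdf(t, mu, sd), lo, hi
        )
        tol = 1e-6 * max(1.0, abs(e_gain))
        if err_p > 1e-6 or err_g > tol:
            raise RuntimeError(
                f"FS quadrature did not converge: abserr p={err_p}, gain={err_g}"
            )
    return OCResult(
        design="FS",
        e_gain=float(e_gain),
        p_r1=float(p),
        p_r3=0.0,
        se_gain=0.0,
        se_r1=0.0,
        se_r3=0.0,
        n_reps=0,
    )


def best_design_map(
    theta_grid: Iterable[Tuple[float, float]],
    config: DesignConfig,
    n: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    m: int = 100_000,
    min_cell: Optional[float] = None,
    tie_ses: float = 2.0,
) -> pd.DataFrame:
    """Label each one-point prior with the design of highest expected gain.

    For every grid point an optimal adaptive rule is built for the point
    prior at that theta, then AE, FF and FS expected gains are compared.
    Winners within ``tie_ses`` combined standard errors of the runner-up
    are flagged as statistical ties.
    """
    if rng is None:
        rng = np.random.default_rng()
    rows = []
    for t1, t2 in theta_grid:
        prior = Prior.point(t1, t2)
        rule = build_boundary(prior, config, m=m, min_cell=min_cell, rng=rng)
        res = {
            "AE": evaluate_adaptive(rule, prior, config, n=n, rng=rng),
            "FF": evaluate_ff(prior, config, n=n, rng=rng),
            "FS": evaluate_fs(prior, config),
        }
        ranked = sorted(res.values(), key=lambda r: r.e_gain, reverse=True)
        winner, second = ranked[0], ranked[1]
        tie_se = math.hypot(winner.se_gain, second.se_gain)
        rows.append(
            {
                "theta1": t1,
                "theta2": t2,
                "winner": winner.design,
                "tie": (winner.e_gain - second.e_gain) <= tie_ses * tie_se,
                **{f"e_gain_{k}": v.e_gain for k, v in res.items()},
            }
        )
    return pd.DataFrame(rows)


def sweep(
    parameter: str,
    values: Sequence[float],
    prior: Prior,
    config: DesignConfig,
    n: int = 100_000,
    rng: Optional[np.random.Generator] = None,
    m: int = 100_000,
    min_cell: Optional[float] = None,
    designs: Sequence[str] = ("FS", "FF", "AE"),
) -> pd.DataFrame:
    """Re-optimise and evaluate designs along a design-parameter sweep.

    ``parameter`` is one of ``tau``, ``lambda`` or ``prior-var`` (the
    latter sets both prior variances).  The adaptive rule is rebuilt for
    every value.  Invalid values are skipped with a logged warning.
    """
    import logging

    log = logging.getLogger(__name__)
    if rng is None:
        rng = np.random.default_rng()
    rows: List[dict] = []
    for value in values:
        try:
            cfg, pri = _apply_sweep_value(parameter, value, prior, config)
        except ValueError as exc:
            log.warning("skipping sweep value %s: %s", value, exc)
            continue
        for design in designs:
            if design == "FS":
                res = evaluate_fs(pri, cfg)
            elif design == "FF":
                res = evaluate_ff(pri, cfg, n=n, rng=rng)
            elif design == "AE":
                rule = build_boundary(pri, cfg, m=m, min_cell=min_cell, rng=rng)
                res = evaluate_adaptive(rule, pri, cfg, n=n, rng=rng)
            else:
                raise ValueError(f"unknown design {design!r}")
            rows.append({parameter: value, **res.as_dict()})
    return pd.DataFrame(rows)


def _apply_sweep_value(
    parameter: str, value: float, prior: Prior, config: DesignConfig
) -> Tuple[DesignConfig, Prior]:
    if parameter == "tau":
        cfg = DesignConfig(
            lambda_frac=config.lambda_frac, tau=value, alpha=config.alpha,
            info_total=config.info_total,
        )
        return cfg, prior
    if parameter == "lambda":
        cfg = DesignConfig(
            lambda_frac=value, tau=config.tau, alpha=config.alpha,
            info_total=config.info_total, w1=config.w1, w2=config.w2,
        )
        return cfg, prior
    if parameter == "prior-var":
        if prior.kind != "bvn":
            raise ValueError("prior-var sweep needs a bvn prior")
        pri = Prior.bvn(prior.mu1, prior.mu2, value, value, prior.rho)
        return config, pri
    raise ValueError(f"unknown sweep parameter {parameter!r}")
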