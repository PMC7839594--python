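"""Priors on the treatment-effect pair and the conjugate interim update.

Two prior families are supported for theta = (theta1, theta2): a one-point
prior (all mass at a single theta0, which makes the interim decision adapt
to sampling variability only) and a bivariate normal prior

    theta ~ N2(mu, Sigma),  Sigma = [[s1^2, rho s1 s2], [rho s1 s2, s2^2]].

The interim likelihood is exactly bivariate normal -- the stage-1 estimates
are independent normals centred at theta with precisions lambda*tau*I and
(1-lambda)*tau*I -- so the posterior given X1 is the standard normal-normal
conjugate update:

    Lambda_post = Sigma^-1 + D,   D = diag(lambda*tau*I, (1-lambda)*tau*I)
    mu_post     = Lambda_post^-1 (Sigma^-1 mu + D x1).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence, Tuple

import numpy as np

from .design import DesignConfig, Stage1Data

__all__ = ["Prior", "Posterior", "posterior_update", "sample_posterior"]

# Prior variances below this are treated as exactly known components.
_VAR_POINT = 1e-12


@dataclass(frozen=True)
class Prior:
    """Prior on (theta1, theta2): ``point`` mass at theta0 or bivariate normal."""

    kind: str
    theta0: Optional[Tuple[float, float]] = None
    mu1: Optional[float] = None
    mu2: Optional[float] = None
    var1: Optional[float] = None
    var2: Optional[float] = None
    rho: float = 0.0

    def __post_init__(self) -> None:
        if self.kind == "point":
            if self.theta0 is None:
                raise ValueError("point prior requires theta0")
            object.__setattr__(self, "theta0", tuple(float(t) for t in self.theta0))
        elif self.kind == "bvn":
            if None in (self.mu1, self.mu2, self.var1, self.var2):
                raise ValueError("bvn prior requires mu1, mu2, var1, var2")
            if self.var1 < 0 or self.var2 < 0:
                raise ValueError("prior variances must be nonnegative")
            if abs(self.rho) >= 1.0:
                raise ValueError(
                    "|rho| must be < 1; for a perfectly correlated prior use a "
                    "1-D parameterization"
                )
        else:
            raise ValueError(f"unknown prior kind {self.kind!r}")

    @classmethod
    def point(cls, theta1: float, theta2: float) -> "Prior":
        return cls(kind="point", theta0=(theta1, theta2))

    @classmethod
    def bvn(
        cls, mu1: float, mu2: float, var1: float, var2: float, rho: float = 0.0
    ) -> "Prior":
        return cls(kind="bvn", mu1=mu1, mu2=mu2, var1=var1, var2=var2, rho=rho)

    @property
    def mean(self) -> np.ndarray:
        if self.kind == "point":
            return np.array(self.theta0, dtype=float)
        return np.array([self.mu1, self.mu2], dtype=float)

    @property
    def cov(self) -> np.ndarray:
        if self.kind == "point":
            return np.zeros((2, 2))
        off = self.rho * np.sqrt(self.var1 * self.var2)
        return np.array([[self.var1, off], [off, self.var2]], dtype=float)


@dataclass(frozen=True)
class Posterior:
    """Posterior on (theta1, theta2); a point mass or a bivariate normal."""

    kind: str
    mean: Tuple[float, float]
    cov: Optional[Tuple[Tuple[float, float], Tuple[float, float]]] = None

    @property
    def mean_vec(self) -> np.ndarray:
        return np.array(self.mean, dtype=float)

    @property
    def cov_mat(self) -> np.ndarray:
        if self.kind == "point":
            return np.zeros((2, 2))
        return np.array(self.cov, dtype=float)

    def marginal_sd(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_mat))


def _data_precision(config: DesignConfig) -> np.ndarray:
    lam, tau, info = config.lambda_frac, config.tau, config.info_total
    return np.diag([lam * tau * info, (1.0 - lam) * tau * info])


def posterior_update(
    prior: Prior, x1: Stage1Data, config: DesignConfig
) -> Posterior:
    """Conjugate posterior of theta given the interim estimates.

    A point prior passes through unchanged.  A bivariate normal prior with a
    zero variance on one component is handled as a conditional update with
    that component held fixed.
    """
    if prior.kind == "point":
        return Posterior(kind="point", mean=prior.theta0)
    x = np.array([x1.est1, x1.est2], dtype=float)
    D = _data_precision(config)
    var = np.array([prior.var1, prior.var2], dtype=float)
    degenerate = var <= _VAR_POINT
    if degenerate.all():
        return Posterior(kind="point", mean=(prior.mu1, prior.mu2))
    if degenerate.any():
        # One component known exactly: rho is irrelevant for the update of
        # the free component (the degenerate margin carries no randomness).
        free = int(np.argmin(degenerate))  # index of the free component
        prec = 1.0 / var[free] + D[free, free]
        mean_free = (prior.mean[free] / var[free] + D[free, free] * x[free]) / prec
        mean = prior.mean.copy()
        mean[free] = mean_free
        cov = np.zeros((2, 2))
        cov[free, free] = 1.0 / prec
        return Posterior(kind="bvn", mean=tuple(mean), cov=tuple(map(tuple, cov)))
    prior_prec = np.linalg.inv(prior.cov)
    post_prec = prior_prec + D
    post_cov = np.linalg.inv(post_prec)
    post_mean = post_cov @ (prior_prec @ prior.mean + D @ x)
    return Posterior(
        kind="bvn", mean=tuple(post_mean), cov=tuple(map(tuple, post_cov))
    )


def sample_posterior(
    post: Posterior, m: int, rng: np.random.Generator
) -> np.ndarray:
    """Draw ``m`` i.i.d. theta pairs from the posterior, shape (m, 2).

    Bivariate normal draws use the lower Cholesky factor of the covariance
    (with an eigenvalue fallback for semi-definite matrices) so a given seed
    reproduces the sample exactly.
    """
    if m < 1:
        raise ValueError("m must be >= 1")
    mean = post.mean_vec
    if post.kind == "point":
        return np.tile(mean, (m, 1))
    cov = post.cov_mat
    try:
        L = np.linalg.cholesky(cov)
    except np.linalg.LinAlgError:
        w, V = np.linalg.eigh(cov)
        L = V @ np.diag(np.sqrt(np.clip(w, 0.0, None)))
    z = rng.standard_normal((m, 2))
    return mean + z @ L.T
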