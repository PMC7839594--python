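"""Independent semi-analytic oracles for expected-gain quantities.

These integrate the exact rejection regions of the closed tests instead of
re-running the package's Monte Carlo path.  The key reduction: the Simes
condition S(p, q) <= a, with S(p, q) = min{2 min(p,q), max(p,q)}, holds

    for every q            if p <= a/2,
    iff q <= a             if a/2 < p <= a,
    iff q <= a/2           if p > a,

so conditioning on the first coordinate turns every rejection event into a
half-line in the second, whose probability is a normal tail.  The outer
integral over the first coordinate is then a 1-D quadrature of a piecewise
smooth function with known breakpoints.
"""

import math

from scipy import integrate
from scipy.stats import norm


def _simes_threshold(p, a):
    """Largest q with S(p, q) <= a (math.inf when every q qualifies)."""
    if p <= a / 2:
        return math.inf
    if p <= a:
        return a
    return a / 2


def ff_expected_gain(theta1, theta2, config):
    """E{G} of the fixed full-population design at a known theta.

    Conditions on the subpopulation estimate e1 and integrates the
    full-population estimate analytically.
    """
    lam, info, alpha = config.lambda_frac, config.info_total, config.alpha
    t3 = lam * theta1 + (1 - lam) * theta2
    sd1 = 1 / math.sqrt(lam * info)
    # e3 | e1 ~ N(lam*e1 + (1-lam)*theta2, (1-lam)/info)
    s3 = math.sqrt((1 - lam) / info)

    def p_le(a, m):
        # P(p3 <= a | e1) = P(e3 >= -Phi^-1(a)/sqrt(info))
        if a == math.inf:
            return 1.0
        return 1 - norm.cdf((-norm.ppf(a) / math.sqrt(info) - m) / s3)

    def inner(e1):
        p1 = norm.sf(e1 * math.sqrt(lam * info))
        m = lam * e1 + (1 - lam) * theta2
        q = _simes_threshold(p1, alpha)
        a3 = min(alpha, q)  # rej H03 <=> p3 <= alpha and Simes cond
        gain = t3 * p_le(a3, m)
        if p1 <= alpha / 2:
            # H01 rejected whatever p3; only the non-rej03 part counts
            gain += lam * theta1 * (1.0 - p_le(a3, m))
        # for alpha/2 < p1 <= alpha, rej01 requires p3 <= alpha = a3,
        # which also rejects H03: the R1 region is empty there
        return gain * norm.pdf(e1, theta1, sd1)

    # breakpoints where p1 crosses alpha/2 and alpha
    b = [-norm.ppf(alpha / 2) / math.sqrt(lam * info),
         -norm.ppf(alpha) / math.sqrt(lam * info)]
    lo, hi = theta1 - 10 * sd1, theta1 + 10 * sd1
    pts = sorted(x for x in b if lo < x < hi)
    val, err = integrate.quad(inner, lo, hi, points=pts, limit=200)
    assert err < 1e-6
    return val


def continue_expected_gain(x1, theta1, theta2, config):
    """E{G(theta, X) | X1 = x1, continue} at a known theta.

    Conditions on the stage-2 subpopulation estimate and integrates the
    stage-2 complement estimate analytically through the combined closed
    test with the fixed stage-1 data.
    """
    from enrichtrial.testing import _stage1_z

    lam, tau, info, alpha = (
        config.lambda_frac, config.tau, config.info_total, config.alpha,
    )
    w1, w2 = config.w1, config.w2
    zalpha = norm.ppf(1 - alpha)
    z1_1, z3_1, z13_1 = (float(z) for z in _stage1_z(x1.est1, x1.est2, config))
    t3 = lam * theta1 + (1 - lam) * theta2
    # stage-2 thresholds implied by the combination statistics
    a13 = norm.cdf(-(zalpha - w1 * z13_1) / w2)   # on p13_2
    a3 = norm.cdf(-(zalpha - w1 * z3_1) / w2)     # on p3_2
    e1_cut = (zalpha - w1 * z1_1) / w2 / math.sqrt(lam * (1 - tau) * info)
    sd1 = math.sqrt(config.var_stage2_s1)
    s3 = math.sqrt((1 - lam) / ((1 - tau) * info))  # SD of e3 given e1

    def p_le(a, m):
        if a == math.inf:
            return 1.0
        if a <= 0.0:
            return 0.0
        return 1 - norm.cdf(
            (-norm.ppf(a) / math.sqrt((1 - tau) * info) - m) / s3
        )

    def inner(e1):
        p1_2 = norm.sf(e1 * math.sqrt(lam * (1 - tau) * info))
        m = lam * e1 + (1 - lam) * theta2
        q = _simes_threshold(p1_2, a13)
        m3 = min(a3, q)
        gain = t3 * p_le(m3, m)
        if e1 >= e1_cut:
            gain += lam * theta1 * (p_le(q, m) - p_le(m3, m))
        return gain * norm.pdf(e1, theta1, sd1)

    c = math.sqrt(lam * (1 - tau) * info)
    b = [e1_cut]
    if 0 < a13 / 2 < 1:
        b.append(-norm.ppf(a13 / 2) / c)
    if 0 < a13 < 1:
        b.append(-norm.ppf(a13) / c)
    lo, hi = theta1 - 10 * sd1, theta1 + 10 * sd1
    pts = sorted(x for x in b if lo < x < hi)
    val, err = integrate.quad(inner, lo, hi, points=pts, limit=200)
    assert err < 1e-6
    return val
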