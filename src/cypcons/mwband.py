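"""Molecular-weight-band enrichment statistics and threshold geometry.

Large CYP3A4 inhibitors are disproportionately often potent: the active-site
pocket of the isozyme is big and adaptable, and the fraction of active (and
of potent) compounds rises with molecular weight up to a plateau near
450 Da.  This module provides the statistics used to locate and defend that
band threshold: normalized activity histograms, sigmoid/linear/bell-shaped
curve fits and their intersection, Wilson score intervals, the one-tailed
pooled two-proportion z-test with its power, and expected-count intervals
for auditing classifier output against a binomial prior.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.proportion import proportion_confint

#: exact normal quantile is the default; set False to use the textbook 1.96
USE_EXACT_QUANTILE = True


def _z_crit(confidence: float, one_tailed: bool = False) -> float:
    alpha = 1.0 - confidence
    q = 1.0 - (alpha if one_tailed else alpha / 2.0)
    if not USE_EXACT_QUANTILE and abs(confidence - 0.95) < 1e-12 and not one_tailed:
        return 1.96
    return float(stats.norm.ppf(q))


def wilson_interval(k: int, n: int, confidence: float = 0.95) -> tuple[float, float]:
    """Wilson score interval for a binomial proportion, no continuity correction."""
    if n <= 0 or k < 0 or k > n:
        raise ValueError(f"invalid counts k={k}, n={n}")
    lo, hi = proportion_confint(k, n, alpha=1.0 - confidence, method="wilson")
    return float(lo), float(hi)


@dataclass(frozen=True)
class ProportionTest:
    k1: int
    n1: int
    k2: int
    n2: int
    nu1: float
    nu2: float
    z: float
    p_one_tailed: float
    ci1: tuple[float, float]
    ci2: tuple[float, float]
    power: float
    beta: float
    degenerate: bool = False


def two_proportion_z_one_tailed(k1: int, n1: int, k2: int, n2: int, alpha: float = 0.05) -> ProportionTest:
    """Pooled-variance z-test of H0: nu1 = nu2 against H1: nu1 < nu2.

    No continuity correction.  A degenerate pooled variance (all successes or
    all failures) is flagged and the p-value is set by the sign convention:
    0.5 because the observed difference is then necessarily zero.
    """
    if n1 <= 0 or n2 <= 0 or not (0 <= k1 <= n1) or not (0 <= k2 <= n2):
        raise ValueError("invalid counts")
    nu1, nu2 = k1 / n1, k2 / n2
    pooled = (k1 + k2) / (n1 + n2)
    var = pooled * (1.0 - pooled) * (1.0 / n1 + 1.0 / n2)
    degenerate = var == 0.0
    if degenerate:
        z, p = 0.0, 0.5
        warnings.warn("degenerate pooled variance (all successes or all failures)", stacklevel=2)
    else:
        z = (nu1 - nu2) / np.sqrt(var)
        p = float(stats.norm.cdf(z))
    power, beta = two_proportion_power(nu1 if 0 < nu1 < 1 else None, nu2 if 0 < nu2 < 1 else None, n1, n2, alpha=alpha)
    return ProportionTest(
        k1=k1, n1=n1, k2=k2, n2=n2, nu1=nu1, nu2=nu2, z=float(z), p_one_tailed=float(p),
        ci1=wilson_interval(k1, n1), ci2=wilson_interval(k2, n2),
        power=power, beta=beta, degenerate=degenerate,
    )


def two_proportion_power(
    p1: float | None,
    p2: float | None,
    n1: int,
    n2: int,
    alpha: float = 0.05,
    one_tailed: bool = True,
) -> tuple[float, float]:
    """Normal-approximation power of the two-proportion test at the observed effect.

    z_power = (|p1 - p2| - z_alpha * SE0) / SE1 with SE0 pooled under H0 and
    SE1 unpooled under H1; power = Phi(z_power), beta = 1 - power.  Returns
    (nan, nan) when either proportion is degenerate.
    """
    if p1 is None or p2 is None:
        return float("nan"), float("nan")
    if not (0 < p1 < 1 and 0 < p2 < 1):
        raise ValueError("proportions must lie strictly inside (0, 1)")
    z_a = _z_crit(1.0 - alpha * (1 if one_tailed else 0.5), one_tailed=True) if one_tailed else _z_crit(1.0 - alpha)
    pbar = (n1 * p1 + n2 * p2) / (n1 + n2)
    se0 = np.sqrt(pbar * (1 - pbar) * (1 / n1 + 1 / n2))
    se1 = np.sqrt(p1 * (1 - p1) / n1 + p2 * (1 - p2) / n2)
    z_power = (abs(p1 - p2) - z_a * se0) / se1
    power = float(stats.norm.cdf(z_power))
    return power, 1.0 - power


@dataclass
class BandHistogram:
    bin_edges: np.ndarray  # Da, anchored at 0
    n_active: np.ndarray
    n_inactive: np.ndarray

    @property
    def centers(self) -> np.ndarray:
        return 0.5 * (self.bin_edges[:-1] + self.bin_edges[1:])

    @property
    def totals(self) -> np.ndarray:
        return self.n_active + self.n_inactive

    @property
    def fraction_active(self) -> np.ndarray:
        """Per-bin active/(active+inactive); NaN where the bin is empty."""
        with np.errstate(invalid="ignore", divide="ignore"):
            return np.where(self.totals > 0, self.n_active / np.maximum(self.totals, 1), np.nan)


def normalized_histogram(mws_active, mws_inactive, bin_width: float = 50.0) -> BandHistogram:
    """Bin active/inactive MWs (bins anchored at 0) and normalize per bin."""
    if bin_width <= 0:
        raise ValueError("bin width must be positive")
    mws_active = np.asarray(mws_active, dtype=float)
    mws_inactive = np.asarray(mws_inactive, dtype=float)
    if mws_active.size + mws_inactive.size == 0:
        raise ValueError("no compounds given")
    top = max(mws_active.max(initial=0.0), mws_inactive.max(initial=0.0))
    edges = np.arange(0.0, (np.floor(top / bin_width) + 2) * bin_width, bin_width)
    n_act, _ = np.histogram(mws_active, bins=edges)
    n_inact, _ = np.histogram(mws_inactive, bins=edges)
    return BandHistogram(bin_edges=edges, n_active=n_act, n_inactive=n_inact)


def logistic_curve(x, a, x0, b):
    """Sigmoid fraction-active model y = a / (1 + (x0/x)^b)."""
    x = np.asarray(x, dtype=float)
    return a / (1.0 + (x0 / x) ** b)


def line_curve(x, slope, intercept):
    return slope * np.asarray(x, dtype=float) + intercept


def weibull4_curve(x, a, b, c, x0):
    """Four-parameter Weibull peak (SigmaPlot parameterization)."""
    x = np.asarray(x, dtype=float)
    k = ((c - 1.0) / c) ** (1.0 / c)
    u = (x - x0) / b + k
    u = np.maximum(u, 0.0)
    with np.errstate(invalid="ignore"):
        y = a * ((c - 1.0) / c) ** ((1.0 - c) / c) * u ** (c - 1.0) * np.exp(-(u**c) + (c - 1.0) / c)
    return np.nan_to_num(y)


@dataclass
class FittedCurves:
    logistic: tuple[float, float, float]  # a, x0, b
    line: tuple[float, float]  # slope, intercept
    weibull4: tuple[float, float, float, float] | None
    r2: dict = field(default_factory=dict)
    logistic_range: tuple[float, float] = (0.0, 950.0)
    linear_range: tuple[float, float] = (150.0, 550.0)
    intersection_mw: float = float("nan")
    intersection_flagged: bool = False


def _fit(model, x, y, p0, weights=None, name="fit"):
    sigma = None if weights is None else 1.0 / np.sqrt(np.maximum(weights, 1e-12))
    try:
        popt, _ = optimize.curve_fit(model, x, y, p0=p0, sigma=sigma, maxfev=20000)
    except RuntimeError as exc:
        raise RuntimeError(f"{name} fit did not converge: {exc}") from exc
    resid = y - model(x, *popt)
    ss_tot = float(np.sum((y - y.mean()) ** 2))
    r2 = 1.0 - float(np.sum(resid**2)) / ss_tot if ss_tot > 0 else 0.0
    return tuple(float(p) for p in popt), r2


def intersect_curves(
    logistic_params: tuple[float, float, float],
    line_params: tuple[float, float],
    search: tuple[float, float],
) -> float:
    """Root of logistic(x) - line(x) in ``search`` nearest the upper end (bisection)."""
    f = lambda x: logistic_curve(x, *logistic_params) - line_curve(x, *line_params)
    lo, hi = search
    xs = np.linspace(lo, hi, 2001)
    vals = f(xs)
    sign_change = np.nonzero(np.diff(np.sign(vals)) != 0)[0]
    if sign_change.size == 0:
        return float("nan")
    i = sign_change[-1]  # nearest the upper end of the linear range
    return float(optimize.brentq(f, xs[i], xs[i + 1]))


def fit_band_threshold(
    hist: BandHistogram,
    logistic_range: tuple[float, float] = (0.0, 950.0),
    linear_range: tuple[float, float] = (150.0, 550.0),
    weighted: bool = False,
    fit_weibull: bool = True,
) -> FittedCurves:
    """Fit sigmoid/linear(/Weibull) shapes to a normalized histogram and intersect them.

    Only populated bins participate.  Each family is fitted on its own MW
    range; the band threshold is the intersection of the sigmoid and the line
    nearest the upper end of the linear range.
    """
    frac = hist.fraction_active
    centers = hist.centers
    ok = ~np.isnan(frac)

    def select(rng):
        m = ok & (centers >= rng[0]) & (centers <= rng[1])
        return centers[m], frac[m], (hist.totals[m].astype(float) if weighted else None)

    x_l, y_l, w_l = select(logistic_range)
    if x_l.size < 4:
        raise ValueError("too few populated bins in the logistic range")
    plateau = max(float(np.nanmax(y_l)), 1e-3)
    logistic_p, r2_logistic = _fit(
        logistic_curve, x_l, y_l, p0=(plateau, float(np.median(x_l)), 4.0), weights=w_l, name="logistic"
    )

    x_ln, y_ln, w_ln = select(linear_range)
    if x_ln.size < 3:
        raise ValueError("too few populated bins in the linear range")
    line_p, r2_line = _fit(line_curve, x_ln, y_ln, p0=(1e-3, 0.0), weights=w_ln, name="line")

    weibull_p, r2_weibull = None, None
    if fit_weibull:
        x_w, y_w, w_w = select((0.0, float(centers[ok].max())))
        try:
            weibull_p, r2_weibull = _fit(
                weibull4_curve, x_w, y_w,
                p0=(plateau, 600.0, 2.0, float(x_w[np.argmax(y_w)])), weights=w_w, name="weibull4",
            )
        except RuntimeError:
            warnings.warn("four-parameter Weibull fit did not converge; omitted", stacklevel=2)

    inter = intersect_curves(logistic_p, line_p, (linear_range[0], logistic_range[1]))
    flagged = not (linear_range[0] <= inter <= max(linear_range[1], logistic_range[1])) or np.isnan(inter)
    # a near-flat line cannot define a threshold
    if abs(line_p[0]) < 1e-6:
        flagged = True
    r2 = {"logistic": r2_logistic, "line": r2_line}
    if r2_weibull is not None:
        r2["weibull4"] = r2_weibull
    return FittedCurves(
        logistic=logistic_p, line=line_p, weibull4=weibull_p, r2=r2,
        logistic_range=logistic_range, linear_range=linear_range,
        intersection_mw=inter, intersection_flagged=flagged,
    )


def expected_count_interval(k: int, n: int, m: int, confidence: float = 0.95) -> tuple[int, int]:
    """Wilson interval of k/n scaled to m compounds, rounded to nearest integers."""
    if m <= 0:
        raise ValueError("m must be positive")
    lo, hi = wilson_interval(k, n, confidence)
    return int(round(lo * m)), int(round(hi * m))
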