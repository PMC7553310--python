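"""Quantitative procedures on measured response curves.

Covers the standalone analyses around the ODE model: mRNA half-life from
actinomycin-D chase series (3-parameter exponential decay), EC50 from
IFNα dose-response series (4-parameter Hill), area under activation
curves, cubic smoothing splines for immunoblot time courses, and the
qPCR arithmetic (RQ = 2^-ddCt, reference-gene normalization).
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import make_smoothing_spline
from scipy.optimize import least_squares

log = logging.getLogger(__name__)

__all__ = [
    "DecayFit",
    "HillFit",
    "fit_exponential_decay",
    "fit_hill",
    "auc_timecourse",
    "smooth_timecourse",
    "relative_quantity",
    "normalize_to_reference",
]


@dataclass
class DecayFit:
    """f(t) = d + a * 2^(-t / t_half)."""

    d: float
    a: float
    t_half: float  # hours; inf when classified stable
    residual_sum: float
    stable: bool  # half-life exceeds (or decay absent within) the observation window

    def __call__(self, t):
        t = np.asarray(t, float)
        if math.isinf(self.t_half):
            return np.full_like(t, self.d + self.a)
        return self.d + self.a * np.exp(-math.log(2.0) * t / self.t_half)


@dataclass
class HillFit:
    """f(x) = d + a * x^b / (c^b + x^b); c is the EC50 (inflection dose)."""

    d: float
    a: float
    b: float
    c: float  # EC50, U/ml
    residual_sum: float
    ec50_in_range: bool
    poor_fit: bool = False

    @property
    def ec50(self) -> float:
        return self.c

    def __call__(self, x):
        x = np.asarray(x, float)
        with np.errstate(divide="ignore", invalid="ignore"):
            xb = np.where(x > 0, x, 0.0) ** self.b
        return self.d + self.a * xb / (self.c**self.b + xb)


def fit_exponential_decay(times, values) -> DecayFit:
    """Least-squares fit of the 3-parameter exponential decay to a chase series.

    A series whose fitted half-life exceeds the observation window (or that
    does not decrease at all) is classified ``stable`` with t_half = inf.
    """
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if len(t) < 4:
        raise ValueError("need at least 4 points to fit a 3-parameter decay")
    if np.any(t < 0):
        raise ValueError("times must be non-negative")
    window = float(t.max() - t.min())
    # non-decreasing series: no measurable decay
    slope = np.polyfit(t, y, 1)[0]
    if np.all(np.diff(y[np.argsort(t)]) >= 0) or (y.max() - y.min()) == 0:
        return DecayFit(d=float(y.mean()), a=0.0, t_half=math.inf,
                        residual_sum=float(np.sum((y - y.mean()) ** 2)), stable=True)

    # parameters: d, a, log(t_half); robust defaults (half the window)
    def resid(p):
        d, a, lth = p
        return d + a * np.exp(-math.log(2.0) * t / math.exp(lth)) - y

    p0 = [float(y.min()), float(y.max() - y.min()), math.log(max(window / 2, 1e-3))]
    lo = [-np.inf, 0.0, math.log(1e-3)]
    hi = [np.inf, np.inf, math.log(window * 100)]
    sol = least_squares(resid, p0, bounds=(lo, hi))
    d, a, t_half = sol.x[0], sol.x[1], math.exp(sol.x[2])
    rss = float(np.sum(sol.fun**2))
    # no measurable decay: fitted decline over the window buried in noise
    resid_sd = math.sqrt(rss / max(len(t) - 3, 1))
    decline = a * (1.0 - 2.0 ** (-window / t_half))
    stable = t_half > window or slope >= 0 or decline < 2.0 * resid_sd
    return DecayFit(d=float(d), a=float(a),
                    t_half=math.inf if stable else float(t_half),
                    residual_sum=rss, stable=bool(stable))


def fit_hill(doses, values) -> HillFit:
    """Least-squares fit of the sigmoidal 4-parameter Hill function.

    Doses are in U/ml; at least 5 dose levels including a zero/low anchor
    are required.  The slope b is constrained positive and the EC50 is
    fitted on the log scale for conditioning.  A response without a clear
    monotone trend beyond noise is flagged ``poor_fit``.
    """
    x = np.asarray(doses, float)
    y = np.asarray(values, float)
    levels = np.unique(x)
    if len(levels) < 5:
        raise ValueError("need at least 5 dose levels")
    if levels.min() > 0.1 * levels.max():
        raise ValueError("need a zero or low-dose anchor")
    pos = levels[levels > 0]

    def resid(p):
        d, a, b, lc = p
        c = math.exp(lc)
        with np.errstate(over="ignore"):
            xb = np.where(x > 0, x, 0.0) ** b
            return d + a * xb / (c**b + xb) - y

    span = float(y.max() - y.min())
    p0 = [float(y.min()), max(span, 1e-12), 1.0, math.log(np.median(pos))]
    lo = [-np.inf, 0.0, 0.05, math.log(pos.min() / 100)]
    hi = [np.inf, np.inf, 20.0, math.log(pos.max() * 100)]
    sol = least_squares(resid, p0, bounds=(lo, hi))
    d, a, b, c = sol.x[0], sol.x[1], sol.x[2], math.exp(sol.x[3])
    rss = float(np.sum(sol.fun**2))
    in_range = pos.min() <= c <= pos.max()
    # poor fit: the sigmoid explains little variance beyond a flat response
    rss_flat = float(np.sum((y - y.mean()) ** 2))
    poor = a <= 0 or rss_flat == 0 or (1.0 - rss / rss_flat) < 0.5
    if poor:
        log.warning("Hill fit flagged poor (rss=%.3g, amplitude=%.3g)", rss, a)
    return HillFit(d=float(d), a=float(a), b=float(b), c=float(c),
                   residual_sum=rss, ec50_in_range=bool(in_range), poor_fit=bool(poor))


def auc_timecourse(times, values) -> float:
    """Trapezoidal area under an activation curve over the observed window."""
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if len(t) < 2:
        raise ValueError("need at least 2 points")
    if np.any(np.diff(t) < 0):
        raise ValueError("times must be sorted ascending")
    return float(np.trapezoid(y, t))


def smooth_timecourse(times, values, p: float = 0.8) -> np.ndarray:
    """Cubic smoothing spline minimizing p*sum (y-s)^2 + (1-p)*int s''^2.

    p = 1 interpolates, p = 0 gives the least-squares straight line;
    the default 0.8 matches routine smoothing of immunoblot time courses.
    Fewer than 4 points fall back to linear interpolation (with a warning).
    """
    if not 0 <= p <= 1:
        raise ValueError("smoothing weight p must be in [0, 1]")
    t = np.asarray(times, float)
    y = np.asarray(values, float)
    if len(t) < 4:
        log.warning("fewer than 4 points: returning linear interpolation")
        return y.copy()
    if p == 0:
        coef = np.polyfit(t, y, 1)
        return np.polyval(coef, t)
    # convert to scipy's lam * int s''^2 penalty convention
    lam = (1.0 - p) / p
    spl = make_smoothing_spline(t, y, lam=lam)
    return spl(t)


def relative_quantity(delta_delta_ct) -> float | np.ndarray:
    """Fold change from a ddCt value: RQ = 2^(-ddCt)."""
    arr = np.asarray(delta_delta_ct, float)
    if not np.all(np.isfinite(arr)):
        raise ValueError("ddCt values must be finite")
    out = 2.0 ** (-arr)
    return float(out) if out.ndim == 0 else out


def normalize_to_reference(target: pd.Series | pd.DataFrame,
                           reference: pd.Series) -> pd.Series | pd.DataFrame:
    """Element-wise ratio target/reference over matching sample keys.

    Samples with a zero or missing reference value are dropped with a warning.
    """
    ref = reference.replace(0, np.nan)
    bad = ref.index[ref.isna()]
    if len(bad):
        log.warning("dropping samples with zero/missing reference: %s", list(bad))
    ref = ref.dropna()
    if isinstance(target, pd.DataFrame):
        out = target.loc[target.index.intersection(ref.index)]
        return out.div(ref.loc[out.index], axis=0)
    common = target.index.intersection(ref.index)
    return target.loc[common] / ref.loc[common]
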