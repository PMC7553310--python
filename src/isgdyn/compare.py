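"""Model ranking (AIC, likelihood-ratio statistic) and prediction profiles.

A prediction-profile confidence band for a model prediction z(t) is the set
of values the prediction can take while the re-optimized -2 log L stays
within the chi-square quantile of the chosen confidence level (3.8415 for
95%, one degree of freedom).  The constraint is imposed as a strong
quadratic penalty lambda*(z(theta) - z_target)^2 appended to the residual
vector, with all free parameters re-optimized at each target value.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import chi2

from .likelihood import FitResult, TimecourseDataset, _Objective
from .model import ModelStructure, ParameterSet

__all__ = [
    "aic",
    "lrt_statistic",
    "rank_models",
    "PredictionProfile",
    "prediction_profile",
    "profile_bounds",
]


def aic(k: int, log_likelihood: float) -> float:
    """Akaike information criterion, 2k - 2 log L (smaller is preferred)."""
    if k < 0:
        raise ValueError("k must be non-negative")
    return 2.0 * k - 2.0 * log_likelihood


def lrt_statistic(delta_df: int, log_likelihood: float, alpha: float = 0.95) -> float:
    """Likelihood-ratio ranking statistic: chi2 quantile(alpha, delta_df) - 2 log L.

    ``delta_df`` is the degree-of-freedom difference to the reference (full)
    model; delta_df = 0 contributes no quantile term.
    """
    if delta_df < 0:
        raise ValueError("delta_df must be non-negative")
    if not 0 < alpha < 1:
        raise ValueError("alpha must be in (0, 1)")
    icdf = 0.0 if delta_df == 0 else float(chi2.ppf(alpha, df=delta_df))
    return icdf - 2.0 * log_likelihood


def rank_models(fits: dict[str, FitResult], alpha: float = 0.95) -> pd.DataFrame:
    """Rank fitted model variants by AIC and by the LRT statistic.

    ``fits`` maps model name -> FitResult.  The model with the most fitted
    parameters is the reference for the pairwise LRT; every other model must
    be nested in it (its free-parameter names a subset of the reference's).
    """
    if len(fits) < 2:
        raise ValueError("need at least two fitted models to rank")
    names = list(fits)
    ks = {n: fits[n].k for n in names}
    ref = max(names, key=lambda n: ks[n])
    ref_free = set(fits[ref].best_params.free_names)
    rows = []
    for n in names:
        free = set(fits[n].best_params.free_names)
        if n != ref and not free <= ref_free:
            raise ValueError(
                f"model {n!r} is not nested in reference {ref!r}: "
                f"extra parameters {sorted(free - ref_free)}"
            )
        ddf = ks[ref] - ks[n]
        ll = fits[n].log_likelihood
        rows.append(
            {
                "model": n,
                "k": ks[n],
                "neg2_log_likelihood": fits[n].best_objective,
                "aic": aic(ks[n], ll),
                "lrt_statistic": lrt_statistic(ddf, ll, alpha),
                "delta_df": ddf,
            }
        )
    table = pd.DataFrame(rows).sort_values("aic").reset_index(drop=True)
    return table


@dataclass
class PredictionProfile:
    species: str
    times: np.ndarray
    best: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    confidence: float
    threshold: float
    widened: np.ndarray  # per-time flag: inner optimization did not converge


def profile_bounds(residual_fn, predict_fn, theta0, bounds, threshold: float,
                   penalty_weight: float, rel_tol: float = 1e-3,
                   max_doublings: int = 60):
    """Lower/upper bound of one scalar prediction at the given threshold.

    ``residual_fn(theta)`` returns the data residual vector (sum of squares =
    -2 log L up to a constant), ``predict_fn(theta)`` the scalar prediction.
    Scans the target value z outward from the unconstrained optimum, doubling
    the step until the re-optimized objective exceeds ``threshold`` above the
    optimum, then bisects the crossing to ``rel_tol`` relative precision.

    Returns (lower, upper, converged_flag).
    """
    theta0 = np.asarray(theta0, float)
    r0 = residual_fn(theta0)
    obj0 = float(r0 @ r0)
    z0 = float(predict_fn(theta0))
    sqrt_w = np.sqrt(penalty_weight)

    def solve_at(z, theta_start):
        def resid(theta):
            r = residual_fn(theta)
            return np.concatenate([r, [sqrt_w * (predict_fn(theta) - z)]])

        sol = least_squares(resid, theta_start, bounds=bounds, method="trf",
                            xtol=1e-10, ftol=1e-10)
        r = residual_fn(sol.x)
        return float(r @ r) - obj0, sol.x, sol.status > 0

    converged = True
    out = []
    for direction in (-1.0, +1.0):
        step = max(abs(z0) * 0.02, 1e-8)
        theta = theta0.copy()
        z_in, z_out = z0, None
        for _ in range(max_doublings):
            z = z_in + direction * step
            delta, theta_new, ok = solve_at(z, theta)
            converged &= ok
            if delta > threshold:
                z_out = z
                break
            z_in, theta = z, theta_new
            step *= 2.0
        if z_out is None:  # threshold never crossed within scan range
            converged = False
            out.append(z_in)
            continue
        # bisect the crossing
        while abs(z_out - z_in) > rel_tol * max(abs(z_in), abs(z_out), 1e-12):
            zm = 0.5 * (z_in + z_out)
            delta, theta_new, ok = solve_at(zm, theta)
            converged &= ok
            if delta > threshold:
                z_out = zm
            else:
                z_in, theta = zm, theta_new
        out.append(z_in)
    lower, upper = min(out[0], z0), max(out[1], z0)
    return lower, upper, converged


def prediction_profile(model: ModelStructure, data: TimecourseDataset,
                       fit: FitResult, species: str, times,
                       confidence: float = 0.95,
                       penalty_scale: float = 1e6) -> PredictionProfile:
    """Prediction-profile confidence band for one species along a time course.

    At each requested time the predicted concentration is pushed away from
    its best-fit value while all free parameters are re-optimized; the band
    edge is where -2 log L rises by the chi-square quantile (one degree of
    freedom) of the confidence level.  The penalty weight is
    ``penalty_scale / sigma_ref^2`` with sigma_ref the smallest fitted noise
    sd, strong enough to pin the prediction without distorting the band.
    """
    if confidence < 0 or confidence >= 1:
        raise ValueError("confidence must be in [0, 1)")
    threshold = float(chi2.ppf(confidence, df=1)) if confidence > 0 else 0.0
    times = np.asarray(times, float)
    obj = _Objective(model, fit.best_params, data)
    params = fit.best_params
    theta0 = params.to_vector()
    bounds = params.vector_bounds()
    sidx = model.species_index(species)
    noise_names = [o.noise_parameter for o in model.observables
                   if o.noise_parameter in params.values]
    sigma_ref = min(params.values[nm] for nm in noise_names)
    weight = penalty_scale / sigma_ref**2
    dose = data.doses[-1]

    def data_residuals(theta):
        r = obj.residuals(theta)
        return r

    lower = np.empty_like(times)
    upper = np.empty_like(times)
    best = np.empty_like(times)
    widened = np.zeros(len(times), dtype=bool)
    for i, t in enumerate(times):
        def predict(theta, _t=float(t)):
            p = params.with_vector(theta)
            from .simulate import simulate  # local import to avoid cycle

            traj = simulate(model, p, dose, [_t], rtol=obj.rtol, atol=obj.atol)
            return float(traj.states[0, sidx])

        best[i] = predict(theta0)
        if threshold == 0.0:
            lower[i] = upper[i] = best[i]
            continue
        lo, hi, ok = profile_bounds(
            data_residuals, predict, theta0, bounds, threshold, weight
        )
        lower[i], upper[i] = lo, hi
        widened[i] = not ok
    return PredictionProfile(
        species=species, times=times, best=best, lower=lower, upper=upper,
        confidence=confidence, threshold=threshold, widened=widened,
    )
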