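"""Maximum-likelihood calibration: objective, Latin-hypercube multi-start fits.

The error model is additive Gaussian per observable with one standard
deviation parameter each, so

    -2 log L = sum over points [ (y - yhat)^2 / sigma^2 + log(2 pi sigma^2) ]

Scale and noise parameters are fitted jointly with the kinetic constants.
Local optimization is bounded trust-region least squares in log10 parameter
space on the residual vector extended with per-point sqrt(2 log(sigma/sigma_lo))
pseudo-residuals (sigma_lo = the noise parameter's lower bound), which
reproduces the exact likelihood up to an additive constant; reported
objectives are always the exact -2 log L.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import least_squares
from scipy.stats import qmc

from .model import ConfigurationError, ModelStructure, ParameterSet
from .simulate import IntegrationError, compile_model, equilibrate, _integrate

log = logging.getLogger(__name__)

__all__ = [
    "TimecourseDataset",
    "FitResult",
    "neg2_log_likelihood",
    "latin_hypercube_starts",
    "multistart_fit",
]

DATA_COLUMNS = ["time_h", "observable", "replicate", "dose_Uml", "condition", "value"]

#: fits whose final objective is within this of the best count as the same optimum
CONVERGENCE_TOL = 1e-2


@dataclass
class TimecourseDataset:
    """Long-format time-course measurements.

    Columns: time_h, observable, replicate, dose_Uml, condition, value.
    """

    frame: pd.DataFrame

    def __post_init__(self):
        missing = [c for c in DATA_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset missing columns {missing}; expected {DATA_COLUMNS}")
        self.frame = self.frame.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def observables(self) -> list[str]:
        return sorted(self.frame["observable"].unique())

    @property
    def doses(self) -> list[float]:
        return sorted(self.frame["dose_Uml"].unique())

    def check_against(self, model: ModelStructure) -> None:
        known = {o.name for o in model.observables}
        unknown = set(self.observables) - known
        if unknown:
            raise ValueError(f"dataset observables not in model: {sorted(unknown)}")

    def subset(self, observables) -> "TimecourseDataset":
        return TimecourseDataset(
            self.frame[self.frame["observable"].isin(list(observables))].copy()
        )


@dataclass
class FitResult:
    best_params: ParameterSet
    best_objective: float  # exact -2 log L
    waterfall: np.ndarray  # sorted final objectives over all starts
    n_converged_to_best: int
    seed: int
    n_data: int = 0
    at_bound: list[str] = field(default_factory=list)
    start_objectives: np.ndarray | None = None  # unsorted, per start

    @property
    def k(self) -> int:
        """Degrees of freedom: number of fitted parameters."""
        return len(self.best_params.free_names)

    @property
    def log_likelihood(self) -> float:
        return -0.5 * self.best_objective


class _Objective:
    """Residual/objective evaluator with one simulation per dose per call."""

    def __init__(self, model: ModelStructure, params: ParameterSet,
                 data: TimecourseDataset, rtol: float = 1e-6, atol: float = 1e-9):
        data.check_against(model)
        self.model = model
        self.template = params
        self.cm = compile_model(model)
        self.rtol, self.atol = rtol, atol
        df = data.frame
        self.y = df["value"].to_numpy(float)
        self.n = len(df)
        # per-dose time grids and per-point lookup indices
        self.doses: list[float] = []
        self.time_grids: list[np.ndarray] = []
        dose_idx = np.empty(self.n, dtype=int)
        time_idx = np.empty(self.n, dtype=int)
        for d, sub in df.groupby("dose_Uml", sort=True):
            tg = np.unique(sub["time_h"].to_numpy(float))
            self.doses.append(float(d))
            self.time_grids.append(tg)
        for i, row in df.iterrows():
            di = self.doses.index(float(row["dose_Uml"]))
            dose_idx[i] = di
            time_idx[i] = np.searchsorted(self.time_grids[di], float(row["time_h"]))
        self.dose_idx, self.time_idx = dose_idx, time_idx
        # observable -> species column indices, scale/noise parameter names
        obs_names = sorted(df["observable"].unique())
        self.obs_of = np.array([obs_names.index(o) for o in df["observable"]])
        self.obs_species_idx = []
        self.scale_names, self.noise_names, self.noise_lo = [], [], []
        for o in obs_names:
            od = model.observable(o)
            self.obs_species_idx.append([model.species_index(s) for s in od.species])
            self.scale_names.append(od.scale_parameter)
            self.noise_names.append(od.noise_parameter)
            self.noise_lo.append(params.bounds[od.noise_parameter][0])
        self.obs_names = obs_names
        self.ifn_idx = model.species_index("IFN")
        self.nm_per_u = model.config.ifn_nM_per_U

    def predictions(self, params: ParameterSet) -> np.ndarray:
        k = self.cm.k_vector(params)
        y0_eq = equilibrate(self.model, params, rtol=self.rtol, atol=self.atol)
        yhat = np.empty(self.n)
        for di, (dose, tg) in enumerate(zip(self.doses, self.time_grids)):
            y0 = y0_eq.copy()
            y0[self.ifn_idx] += dose * self.nm_per_u
            states = _integrate(self.cm, y0, tg, k, self.rtol, self.atol)
            for oi, cols in enumerate(self.obs_species_idx):
                scale = params.values[self.scale_names[oi]]
                vals = scale * states[:, cols].sum(axis=1)
                mask = (self.dose_idx == di) & (self.obs_of == oi)
                yhat[mask] = vals[self.time_idx[mask]]
        return yhat

    def _sigmas(self, params: ParameterSet) -> np.ndarray:
        sig = np.array([params.values[nm] for nm in self.noise_names])
        return sig[self.obs_of]

    def residuals(self, vec: np.ndarray) -> np.ndarray:
        """Extended residual vector for least-squares (log10 free-param vector)."""
        params = self.template.with_vector(vec)
        sig = self._sigmas(params)
        lo = np.array(self.noise_lo)[self.obs_of]
        try:
            yhat = self.predictions(params)
        except IntegrationError as err:
            log.warning("integration failed during fit: %s", err)
            return np.full(2 * self.n, 1e4)
        r = (self.y - yhat) / sig
        pseudo = np.sqrt(np.maximum(2.0 * np.log(sig / lo), 0.0))
        return np.concatenate([r, pseudo])

    def neg2_log_likelihood(self, params: ParameterSet) -> float:
        sig = self._sigmas(params)
        try:
            yhat = self.predictions(params)
        except IntegrationError:
            return float("inf")
        return float(np.sum((self.y - yhat) ** 2 / sig**2 + np.log(2 * np.pi * sig**2)))


def neg2_log_likelihood(model: ModelStructure, params: ParameterSet,
                        data: TimecourseDataset) -> float:
    """Exact -2 log L of the dataset under the model and parameter set."""
    return _Objective(model, params, data).neg2_log_likelihood(params)


def latin_hypercube_starts(n: int, bounds, seed: int) -> np.ndarray:
    """``n`` parameter vectors Latin-hypercube-stratified uniformly in log10 space.

    ``bounds`` is a sequence of positive (lo, hi) pairs on the linear scale;
    the returned array (n × d) is on the linear scale.
    """
    if n < 1:
        raise ConfigurationError("need at least one start")
    bounds = [(float(lo), float(hi)) for lo, hi in bounds]
    for lo, hi in bounds:
        if not (0 < lo < hi):
            raise ConfigurationError(f"bad bounds ({lo}, {hi}): need 0 < lo < hi")
    d = len(bounds)
    unit = qmc.LatinHypercube(d=d, seed=seed).random(n)
    lo = np.log10([b[0] for b in bounds])
    hi = np.log10([b[1] for b in bounds])
    return 10.0 ** (lo + unit * (hi - lo))


def multistart_fit(model: ModelStructure, data: TimecourseDataset,
                   params: ParameterSet, n_starts: int = 25, seed: int = 0,
                   max_nfev: int | None = 500, xtol: float = 1e-10,
                   ftol: float = 1e-10) -> FitResult:
    """Multi-start bounded least-squares calibration in log10 parameter space.

    ``params`` supplies values, bounds and free/fixed flags; fixed parameters
    are never touched.  Each start is drawn by Latin hypercube sampling over
    the free-parameter box and refined with a trust-region reflective local
    optimizer.  Returns the best fit plus the full waterfall of sorted final
    objectives.
    """
    if n_starts < 2:
        raise ConfigurationError("n_starts must be >= 2")
    obj = _Objective(model, params, data)
    free = params.free_names
    starts = latin_hypercube_starts(
        n_starts, [params.bounds[nm] for nm in free], seed=seed
    )
    lo, hi = params.vector_bounds()
    finals = np.full(n_starts, np.inf)
    solutions: list[np.ndarray | None] = [None] * n_starts
    failures = []
    for i in range(n_starts):
        x0 = np.log10(starts[i])
        try:
            sol = least_squares(
                obj.residuals, x0, bounds=(lo, hi), method="trf",
                x_scale="jac", tr_solver="exact",
                xtol=xtol, ftol=ftol, max_nfev=max_nfev,
            )
            finals[i] = obj.neg2_log_likelihood(params.with_vector(sol.x))
            solutions[i] = sol.x
        except Exception as err:  # noqa: BLE001 - keep scanning other starts
            failures.append(f"start {i}: {err}")
            log.warning("start %d failed: %s", i, err)
    if not np.isfinite(finals).any():
        raise RuntimeError("all optimization starts failed:\n" + "\n".join(failures))
    order = np.argsort(finals)
    best_i = int(order[0])
    best_params = params.with_vector(solutions[best_i])
    best_obj = float(finals[best_i])
    waterfall = np.sort(finals[np.isfinite(finals)])
    n_best = int(np.sum(waterfall <= waterfall[0] + CONVERGENCE_TOL))
    return FitResult(
        best_params=best_params,
        best_objective=best_obj,
        waterfall=waterfall,
        n_converged_to_best=n_best,
        seed=seed,
        n_data=len(data),
        at_bound=best_params.at_bound(),
        start_objectives=finals,
    )
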