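"""Synthetic data generation for every analysis in the package.

The generators emulate the study design the package targets: IFNα
stimulation at 500 U/ml, the time grid 0, 1, 2, 3, 4, 8, 12, 24 h,
biological triplicates with additive Gaussian noise per observable,
actinomycin-D decay series with three mRNA stability classes
(0.5-2 h, 5-7 h, stable), log-spaced dose-response series, and a
class-structured log2 expression matrix (default split 21 early /
27 intermediate / 5 late).  Every generator is deterministic for a
fixed seed and returns the ground truth alongside the noisy data.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.integrate import odeint

from .classify import DEFAULT_TIME_GRID, ExpressionMatrix
from .likelihood import TimecourseDataset
from .model import ModelStructure, ParameterSet
from .reference import reference_parameters
from .simulate import observe, simulate

__all__ = [
    "GeneratorConfig",
    "CLASS_HALF_LIFE_RANGES",
    "generate_timecourse",
    "generate_decay_series",
    "generate_dose_response",
    "generate_expression_matrix",
    "decay_class_of",
]

#: mRNA half-life ranges per temporal class, hours; the stable class decays
#: too slowly to measure within the chase window
CLASS_HALF_LIFE_RANGES = {
    "early": (0.5, 2.0),
    "intermediate": (5.0, 7.0),
    "stable": (math.inf, math.inf),
}

DEFAULT_CLASS_COUNTS = {"early": 21, "intermediate": 27, "late": 5}


@dataclass
class GeneratorConfig:
    seed: int = 0
    n_replicates: int = 3
    times: tuple[float, ...] = DEFAULT_TIME_GRID
    dose_Uml: float = 500.0
    #: noise sd as a fraction of each observable's dynamic range
    noise_fraction: float = 0.10
    true_params: ParameterSet | None = None
    condition: str = "IFNa"

    def rng(self) -> np.random.Generator:
        return np.random.default_rng(self.seed)


def generate_timecourse(model: ModelStructure, cfg: GeneratorConfig,
                        observables: list[str] | None = None
                        ) -> tuple[TimecourseDataset, dict]:
    """Noisy replicate time courses of the model's observables.

    The noiseless observable trajectory is computed with ``simulate`` +
    ``observe`` at the true parameters (the committed reference set by
    default); each replicate adds Gaussian noise with sd equal to
    ``noise_fraction`` times the observable's dynamic range.  Returns the
    dataset and a ground-truth record (true parameters and noise sds).
    """
    params = cfg.true_params or reference_parameters(model)
    traj = simulate(model, params, cfg.dose_Uml, np.asarray(cfg.times))
    clean = observe(traj, model, params)
    if observables is not None:
        clean = clean[clean["observable"].isin(observables)]
    rng = cfg.rng()
    recs = []
    sigmas: dict[str, float] = {}
    for obs, sub in clean.groupby("observable", sort=True):
        v = sub["value"].to_numpy()
        sigma = cfg.noise_fraction * float(v.max() - v.min())
        sigma = max(sigma, 1e-12)
        sigmas[obs] = sigma
        for rep in range(1, cfg.n_replicates + 1):
            noise = rng.normal(0.0, sigma, size=len(v)) if cfg.noise_fraction > 0 else 0.0
            for t, y in zip(sub["time_h"], v + noise):
                recs.append((float(t), obs, rep, cfg.dose_Uml, cfg.condition, float(y)))
    frame = pd.DataFrame(
        recs, columns=["time_h", "observable", "replicate", "dose_Uml", "condition", "value"]
    )
    truth = {"params": params, "sigmas": sigmas, "clean": clean}
    return TimecourseDataset(frame), truth


def generate_decay_series(t_half: float, cfg: GeneratorConfig,
                          times: tuple[float, ...] = (0, 1, 2, 4, 6, 8, 10, 12),
                          d: float = 0.1, a: float = 1.0,
                          noise_sd: float = 0.05, n_replicates: int = 2,
                          gene: str = "gene") -> pd.DataFrame:
    """Actinomycin-D chase series from f(t) = d + a·2^(−t/t_half) plus noise.

    ``t_half = inf`` produces the stable class (flat series).  Biological
    duplicates by default, matching routine chase designs.
    """
    if not (t_half > 0):
        raise ValueError("t_half must be positive (inf for stable)")
    t = np.asarray(times, float)
    clean = d + a * (np.exp(-math.log(2.0) * t / t_half) if math.isfinite(t_half)
                     else np.ones_like(t))
    rng = cfg.rng()
    recs = []
    for rep in range(1, n_replicates + 1):
        noisy = clean + (rng.normal(0, noise_sd, len(t)) if noise_sd > 0 else 0.0)
        recs += [(float(ti), gene, rep, float(y)) for ti, y in zip(t, noisy)]
    return pd.DataFrame(recs, columns=["time_h", "gene", "replicate", "value"])


def generate_dose_response(ec50: float, cfg: GeneratorConfig,
                           doses: tuple[float, ...] | None = None,
                           d: float = 0.05, a: float = 1.0, b: float = 1.2,
                           noise_sd_fraction: float = 0.05,
                           n_replicates: int = 3,
                           gene: str = "gene") -> pd.DataFrame:
    """4-parameter Hill dose-response series plus noise.

    Default doses: 0 plus eight log-spaced levels between 10 and 5000 U/ml;
    noise sd is a fraction of the amplitude ``a``.
    """
    if not ec50 > 0:
        raise ValueError("ec50 must be positive")
    if doses is None:
        doses = (0.0, *np.geomspace(10, 5000, 8))
    x = np.asarray(doses, float)
    with np.errstate(divide="ignore"):
        xb = np.where(x > 0, x, 0.0) ** b
    clean = d + a * xb / (ec50**b + xb)
    rng = cfg.rng()
    sd = noise_sd_fraction * a
    recs = []
    for rep in range(1, n_replicates + 1):
        noisy = clean + (rng.normal(0, sd, len(x)) if sd > 0 else 0.0)
        recs += [(float(xi), gene, rep, float(y)) for xi, y in zip(x, noisy)]
    return pd.DataFrame(recs, columns=["dose_Uml", "gene", "replicate", "value"])


def decay_class_of(t_half: float, stable: bool) -> str:
    """Temporal class implied by a fitted mRNA half-life.

    The boundary between the short-lived (early) and intermediate classes
    is the midpoint of the gap between their generating ranges (3.5 h);
    half-lives beyond the chase window are the stable class.
    """
    if stable or math.isinf(t_half):
        return "stable"
    return "early" if t_half < 3.5 else "intermediate"


# -- expression matrix ----------------------------------------------------

#: signal motif timescales for the induction kinetics (hours): activation
#: delay of ISGF3-driven transcription and the decay of the active signal
_TAU_ON, _TAU_OFF = 0.7, 6.0

_CLASS_FOR_MATRIX = {"early": "early", "intermediate": "intermediate", "late": "stable"}


def _induction_profile(t_half: float, times: np.ndarray) -> np.ndarray:
    """Normalized transcript induction: dm/dt = s(t) - kdeg·m on a fine grid,
    with s(t) = (1 - exp(-t/tau_on))·exp(-t/tau_off)."""
    kdeg = 0.0 if math.isinf(t_half) else math.log(2.0) / t_half

    def rhs(m, t):
        s = (1.0 - math.exp(-t / _TAU_ON)) * math.exp(-t / _TAU_OFF)
        return s - kdeg * m

    fine = np.linspace(0.0, float(times.max()), 481)
    m = odeint(rhs, 0.0, fine).ravel()
    m = np.interp(times, fine, m)
    return m / m.max()


def generate_expression_matrix(
    class_counts: dict[str, int] | None = None,
    cfg: GeneratorConfig | None = None,
    noise_sd: float = 0.1,
    fold_range: tuple[float, float] = (4.0, 64.0),
) -> tuple[ExpressionMatrix, pd.DataFrame]:
    """Class-structured log2 expression matrix with paired untreated baselines.

    Per gene: a temporal class, an mRNA half-life drawn from the class range
    (the late class maps to stable transcripts), an induction profile from
    the kinetic motif, and a peak fold change drawn log-uniformly from
    ``fold_range``.  Treated values are baseline + log2 induction + noise;
    untreated values are baseline + noise, replicate-paired.  Genes whose
    noiseless profile would peak outside their class window are redrawn, so
    the returned truth labels are exact by construction.

    Returns the matrix and a truth table (gene, class, t_half, peak fold).
    """
    counts = dict(class_counts or DEFAULT_CLASS_COUNTS)
    cfg = cfg or GeneratorConfig()
    rng = cfg.rng()
    times = np.asarray(cfg.times, float)
    data = {}
    truth_rows = []
    gi = 0
    for cls, n in counts.items():
        if n < 0:
            raise ValueError("class counts must be non-negative")
        lo, hi = CLASS_HALF_LIFE_RANGES[_CLASS_FOR_MATRIX[cls]]
        for _ in range(n):
            gi += 1
            gene = f"G{gi:03d}"
            for _attempt in range(50):
                t_half = math.inf if math.isinf(lo) else float(rng.uniform(lo, hi))
                profile = _induction_profile(t_half, times)
                tmax = float(times[profile.argmax()])
                ok = (
                    (cls == "early" and tmax <= 4.0)
                    or (cls == "intermediate" and tmax == 8.0)
                    or (cls == "late" and tmax >= 12.0)
                )
                if ok:
                    break
            else:
                raise RuntimeError(f"could not place gene in class {cls}")
            fold = float(np.exp(rng.uniform(*np.log(fold_range))))
            baseline = float(rng.uniform(5.0, 10.0))
            log2_induction = np.log2(1.0 + (fold - 1.0) * profile)
            for t, li in zip(times, log2_induction):
                for rep in range(1, cfg.n_replicates + 1):
                    eps_t = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
                    eps_u = rng.normal(0, noise_sd) if noise_sd > 0 else 0.0
                    data[(gene, float(t), rep, "treated")] = baseline + li + eps_t
                    data[(gene, float(t), rep, "untreated")] = baseline + eps_u
            truth_rows.append(
                {"gene": gene, "class": cls, "t_half": t_half, "peak_fold": fold,
                 "t_max": tmax}
            )
    idx = pd.MultiIndex.from_tuples(
        [(t, r, c) for t in times for r in range(1, cfg.n_replicates + 1)
         for c in ("treated", "untreated")],
        names=["time_h", "replicate", "condition"],
    )
    genes = [row["gene"] for row in truth_rows]
    frame = pd.DataFrame(
        [[data[(g, t, r, c)] for (t, r, c) in idx] for g in genes],
        index=genes, columns=idx,
    )
    truth = pd.DataFrame(truth_rows).set_index("gene")
    return ExpressionMatrix(frame), truth
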