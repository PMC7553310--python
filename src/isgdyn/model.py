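"""Declarative reaction-network models of IFNα-induced JAK/STAT signaling.

Two model variants are provided:

``core``
    Ligand-activated receptor, STAT1/STAT2 phosphorylation, one-step
    synergistic ISGF3 assembly, nucleocytoplasmic shuttling, and
    ISGF3-driven transcription of ten interferon-stimulated mRNAs
    (six antiviral genes plus the pathway components IRF9, SOCS1 and
    USP18, and the repressor transcript IRF2 is absent).

``core_feedback``
    The core model extended by an inducible transcriptional repressor:
    IRF2 is transcribed, translated, imported into the nucleus and
    reversibly occupies a conserved pool of transcription-factor binding
    sites (TFBS).  Occupied sites reduce ISGF3-driven transcription of
    the repressed gene set via the promoter occupancy factor
    ``TFBS_free / (TFBS_free + TFBS_IRF2)``.

All rate laws are mass action; the two deliberate deviations are the
saturating SOCS1 inhibition of receptor activation,
``1 / (1 + SOCS1/ki_socs1)``, and the promoter-occupancy factor above.
Concentrations are in nM (promoter states in arbitrary units), time in
hours, so second-order rate constants are in 1/(nM·h).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np

__all__ = [
    "Species",
    "Inhibition",
    "Reaction",
    "ObservableDef",
    "ModelStructure",
    "ParameterSet",
    "ModelConfig",
    "build_model",
    "default_parameters",
    "conservation_matrix",
    "ANTIVIRAL_GENES",
    "INDUCED_GENES",
    "BASAL_GENES",
    "REPRESSED_GENES",
    "VARIANTS",
]

ANTIVIRAL_GENES = ("IRF1", "TRIM21", "MX1", "EIF2AK2", "IFI6", "IFITM3")
#: genes transcribed from a basal promoter in addition to ISGF3 induction
BASAL_GENES = ("IRF9", "SOCS1", "USP18", "IRF2")
INDUCED_GENES = ANTIVIRAL_GENES + BASAL_GENES
#: gene set whose promoters carry the IRF2-repressible binding site
REPRESSED_GENES = ANTIVIRAL_GENES + ("SOCS1",)

VARIANTS = ("core", "core_feedback")

_FEEDBACK_SPECIES = ("IRF2c", "IRF2n", "TFBS_free", "TFBS_IRF2", "mIRF2")
_FEEDBACK_PARAMS = (
    "vmax_mIRF2",
    "basal_mIRF2",
    "kdeg_mIRF2",
    "ktl_irf2",
    "kdeg_irf2",
    "kimp_irf2",
    "kon_irf2",
    "koff_irf2",
)

#: translocation rate constants whose upper bound is raised to 1e2
TRANSLOCATION_PARAMS = ("kimp_isgf3", "kexp_s1", "kexp_s2", "kexp_irf9", "kimp_irf2")


class ConfigurationError(ValueError):
    """Raised for invalid model configuration (missing half-life, bad bounds)."""


@dataclass(frozen=True)
class Species:
    name: str
    compartment: str  # extracellular | cytoplasm | nucleus
    role: str  # ligand | receptor | signaling protein | complex | mRNA | promoter state
    initial_concentration: float = 0.0

    def __post_init__(self):
        if self.initial_concentration < 0:
            raise ValueError(f"negative initial concentration for {self.name}")
        if self.compartment not in ("extracellular", "cytoplasm", "nucleus"):
            raise ValueError(f"unknown compartment {self.compartment!r}")


@dataclass(frozen=True)
class Inhibition:
    """Multiplicative factor on a mass-action rate.

    kind ``saturating``: 1 / (1 + [species]/K) with K named by ``parameter``
    (SOCS1 inhibition of receptor activation).

    kind ``promoter_occupancy``: [free]/([free]+[bound]) for the promoter
    state pair named by ``species`` = (free, bound); carries no parameter.
    """

    kind: str
    species: tuple[str, ...]
    parameter: str | None = None

    def __post_init__(self):
        if self.kind not in ("saturating", "promoter_occupancy"):
            raise ValueError(f"unknown inhibition kind {self.kind!r}")


@dataclass(frozen=True)
class Reaction:
    name: str
    reactants: tuple[str, ...]
    products: tuple[str, ...]
    rate_parameter: str
    inhibition: Inhibition | None = None

    @property
    def parameters(self) -> tuple[str, ...]:
        if self.inhibition is not None and self.inhibition.parameter:
            return (self.rate_parameter, self.inhibition.parameter)
        return (self.rate_parameter,)


@dataclass(frozen=True)
class ObservableDef:
    """Observable = scale × (sum of species), Gaussian noise of sd ``noise_parameter``."""

    name: str
    species: tuple[str, ...]
    scale_parameter: str
    noise_parameter: str


@dataclass
class ParameterSet:
    """Named positive parameter values with bounds and free/fixed flags.

    Sampling and optimization operate on log10-transformed free values.
    """

    values: dict[str, float]
    bounds: dict[str, tuple[float, float]]
    free: dict[str, bool]

    def __post_init__(self):
        self.validate()

    def validate(self) -> None:
        for name, v in self.values.items():
            lo, hi = self.bounds[name]
            if not (lo > 0 and hi > lo):
                raise ConfigurationError(f"bad bounds for {name}: ({lo}, {hi})")
            if not (lo <= v <= hi):
                raise ConfigurationError(
                    f"value {v:g} of {name} outside bounds ({lo:g}, {hi:g})"
                )

    # -- free-parameter vector interface (log10 scale) -------------------
    @property
    def free_names(self) -> list[str]:
        return [n for n in self.values if self.free[n]]

    def to_vector(self) -> np.ndarray:
        return np.log10([self.values[n] for n in self.free_names])

    def vector_bounds(self) -> tuple[np.ndarray, np.ndarray]:
        lo = np.log10([self.bounds[n][0] for n in self.free_names])
        hi = np.log10([self.bounds[n][1] for n in self.free_names])
        return lo, hi

    def with_vector(self, vec: np.ndarray) -> "ParameterSet":
        new = dict(self.values)
        for name, x in zip(self.free_names, vec):
            new[name] = 10.0 ** float(x)
        return ParameterSet(new, dict(self.bounds), dict(self.free))

    def updated(self, **kwargs: float) -> "ParameterSet":
        new = dict(self.values)
        new.update(kwargs)
        return ParameterSet(new, dict(self.bounds), dict(self.free))

    def fixing(self, *names: str, all_except: list[str] | None = None) -> "ParameterSet":
        """Return a copy with the given parameters fixed (or all but `all_except`)."""
        free = dict(self.free)
        if all_except is not None:
            for n in free:
                free[n] = n in all_except
        for n in names:
            free[n] = False
        return ParameterSet(dict(self.values), dict(self.bounds), free)

    def at_bound(self, rel_tol: float = 1e-3) -> list[str]:
        """Free parameters within ``rel_tol`` (log10) of a bound: a practical
        non-identifiability flag."""
        out = []
        for n in self.free_names:
            lo, hi = self.bounds[n]
            x = math.log10(self.values[n])
            if x - math.log10(lo) < rel_tol or math.log10(hi) - x < rel_tol:
                out.append(n)
        return out


@dataclass
class ModelConfig:
    """Tunable structural constants (all placeholders overridable by the user)."""

    ifn_nM_per_U: float = 0.002  # conversion of IFNα dose from U/ml to nM
    stat1_total_nM: float = 100.0  # cytoplasmic STAT1 pool (reference species)
    stat2_total_nM: float = 50.0
    irf9_initial_nM: float = 10.0
    receptor_nM: float = 1000.0  # non-limiting receptor pool
    tfbs_total_au: float = 1.0  # conserved promoter-site pool


@dataclass(frozen=True)
class ModelStructure:
    variant: str
    species: tuple[Species, ...]
    reactions: tuple[Reaction, ...]
    observables: tuple[ObservableDef, ...]
    fixed_parameters: dict[str, float]
    config: ModelConfig = field(default_factory=ModelConfig)

    @property
    def species_names(self) -> list[str]:
        return [s.name for s in self.species]

    @property
    def kinetic_parameters(self) -> list[str]:
        seen: dict[str, None] = {}
        for r in self.reactions:
            for p in r.parameters:
                seen.setdefault(p, None)
        return list(seen)

    @property
    def kinetic_parameter_count(self) -> int:
        return len(self.kinetic_parameters)

    @property
    def observable_parameters(self) -> list[str]:
        out = []
        for o in self.observables:
            out.extend([o.scale_parameter, o.noise_parameter])
        return out

    def species_index(self, name: str) -> int:
        return self.species_names.index(name)

    def observable(self, name: str) -> ObservableDef:
        for o in self.observables:
            if o.name == name:
                return o
        raise KeyError(f"no observable {name!r} in model {self.variant}")

    def stoichiometric_matrix(self) -> np.ndarray:
        """Net stoichiometry, species × reactions."""
        idx = {n: i for i, n in enumerate(self.species_names)}
        N = np.zeros((len(self.species), len(self.reactions)))
        for j, r in enumerate(self.reactions):
            for s in r.reactants:
                N[idx[s], j] -= 1
            for s in r.products:
                N[idx[s], j] += 1
        return N

    def validate(self) -> None:
        names = self.species_names
        if len(set(names)) != len(names):
            raise ValueError("duplicate species names")
        known = set(names)
        for r in self.reactions:
            for s in r.reactants + r.products:
                if s not in known:
                    raise ValueError(f"reaction {r.name}: unknown species {s}")
            if r.inhibition is not None:
                for s in r.inhibition.species:
                    if s not in known:
                        raise ValueError(f"inhibition in {r.name}: unknown species {s}")
        used = set()
        for r in self.reactions:
            used.update(r.reactants)
            used.update(r.products)
            if r.inhibition is not None:
                used.update(r.inhibition.species)
        unused = known - used
        if unused:
            raise ValueError(f"species never used in a reaction: {sorted(unused)}")
        for o in self.observables:
            for s in o.species:
                if s not in known:
                    raise ValueError(f"observable {o.name}: unknown species {s}")


def _species_table(variant: str, cfg: ModelConfig) -> list[Species]:
    sp: list[Species] = [
        Species("IFN", "extracellular", "ligand", 0.0),
        Species("Rec", "cytoplasm", "receptor", cfg.receptor_nM),
        Species("ActRec", "cytoplasm", "receptor", 0.0),
        Species("RecUSP18", "cytoplasm", "complex", 0.0),
        Species("STAT1c", "cytoplasm", "signaling protein", cfg.stat1_total_nM),
        Species("pSTAT1c", "cytoplasm", "signaling protein", 0.0),
        Species("STAT2c", "cytoplasm", "signaling protein", cfg.stat2_total_nM),
        Species("pSTAT2c", "cytoplasm", "signaling protein", 0.0),
        Species("IRF9c", "cytoplasm", "signaling protein", cfg.irf9_initial_nM),
        Species("ISGF3c", "cytoplasm", "complex", 0.0),
        Species("SOCS1", "cytoplasm", "signaling protein", 0.0),
        Species("USP18", "cytoplasm", "signaling protein", 0.0),
        Species("ISGF3n", "nucleus", "complex", 0.0),
        Species("STAT1n", "nucleus", "signaling protein", 0.0),
        Species("STAT2n", "nucleus", "signaling protein", 0.0),
        Species("IRF9n", "nucleus", "signaling protein", 0.0),
    ]
    genes = INDUCED_GENES if variant == "core_feedback" else tuple(
        g for g in INDUCED_GENES if g != "IRF2"
    )
    if variant == "core_feedback":
        sp += [
            Species("IRF2c", "cytoplasm", "signaling protein", 0.0),
            Species("IRF2n", "nucleus", "signaling protein", 0.0),
            Species("TFBS_free", "nucleus", "promoter state", cfg.tfbs_total_au),
            Species("TFBS_IRF2", "nucleus", "promoter state", 0.0),
        ]
    sp += [Species(f"m{g}", "nucleus", "mRNA", 0.0) for g in genes]
    return sp


def _reaction_table(variant: str) -> list[Reaction]:
    socs1_inh = Inhibition("saturating", ("SOCS1",), "ki_socs1")
    rx: list[Reaction] = [
        Reaction("receptor_activation", ("IFN", "Rec"), ("ActRec",), "kact", socs1_inh),
        Reaction("receptor_inactivation", ("ActRec",), ("Rec",), "kinact"),
        Reaction("usp18_binding", ("ActRec", "USP18"), ("RecUSP18",), "kon_usp18"),
        Reaction("usp18_release", ("RecUSP18",), ("Rec", "USP18"), "koff_usp18"),
        Reaction("receptor_synthesis", (), ("Rec",), "ksyn_rec"),
        Reaction("receptor_turnover", ("Rec",), (), "kdeg_rec"),
        Reaction("ifn_depletion", ("IFN",), (), "kdeg_ifn"),
        Reaction("stat1_phosphorylation", ("STAT1c", "ActRec"), ("pSTAT1c", "ActRec"), "kphos_s1"),
        Reaction("stat2_phosphorylation", ("STAT2c", "ActRec"), ("pSTAT2c", "ActRec"), "kphos_s2"),
        Reaction("stat1_dephosphorylation", ("pSTAT1c",), ("STAT1c",), "kdephos_s1"),
        Reaction("stat2_dephosphorylation", ("pSTAT2c",), ("STAT2c",), "kdephos_s2"),
        # one-step synergistic assembly of the ISGF3 trimer
        Reaction("isgf3_formation", ("pSTAT1c", "pSTAT2c", "IRF9c"), ("ISGF3c",), "kform_isgf3"),
        Reaction("isgf3_import", ("ISGF3c",), ("ISGF3n",), "kimp_isgf3"),
        Reaction("isgf3_dissociation", ("ISGF3n",), ("STAT1n", "STAT2n", "IRF9n"), "kdiss_isgf3"),
        Reaction("stat1_export", ("STAT1n",), ("STAT1c",), "kexp_s1"),
        Reaction("stat2_export", ("STAT2n",), ("STAT2c",), "kexp_s2"),
        Reaction("irf9_export", ("IRF9n",), ("IRF9c",), "kexp_irf9"),
    ]
    genes = INDUCED_GENES if variant == "core_feedback" else tuple(
        g for g in INDUCED_GENES if g != "IRF2"
    )
    occupancy = Inhibition("promoter_occupancy", ("TFBS_free", "TFBS_IRF2"))
    for g in genes:
        inh = occupancy if (variant == "core_feedback" and g in REPRESSED_GENES) else None
        rx.append(
            Reaction(f"transcription_{g}", ("ISGF3n",), ("ISGF3n", f"m{g}"), f"vmax_m{g}", inh)
        )
    for g in BASAL_GENES:
        if g in ("IRF2",) and variant != "core_feedback":
            continue
        rx.append(Reaction(f"basal_transcription_{g}", (), (f"m{g}",), f"basal_m{g}"))
    for g in genes:
        rx.append(Reaction(f"decay_m{g}", (f"m{g}",), (), f"kdeg_m{g}"))
    for g in ("IRF9", "SOCS1", "USP18") + (("IRF2",) if variant == "core_feedback" else ()):
        prot = {"IRF9": "IRF9c", "SOCS1": "SOCS1", "USP18": "USP18", "IRF2": "IRF2c"}[g]
        rx.append(Reaction(f"translation_{g}", (f"m{g}",), (f"m{g}", prot), f"ktl_{g.lower()}"))
        rx.append(Reaction(f"turnover_{g}", (prot,), (), f"kdeg_{g.lower()}"))
    if variant == "core_feedback":
        rx += [
            # IRF2n turnover shares kdeg_irf2 with the cytoplasmic pool
            Reaction("turnover_IRF2n", ("IRF2n",), (), "kdeg_irf2"),
            Reaction("irf2_import", ("IRF2c",), ("IRF2n",), "kimp_irf2"),
            Reaction("tfbs_binding", ("IRF2n", "TFBS_free"), ("TFBS_IRF2",), "kon_irf2"),
            Reaction("tfbs_release", ("TFBS_IRF2",), ("IRF2n", "TFBS_free"), "koff_irf2"),
        ]
    return rx


def _observable_table(variant: str) -> list[ObservableDef]:
    def obs(name: str, *species: str) -> ObservableDef:
        return ObservableDef(name, species, f"s_{name}", f"sd_{name}")

    table = [
        obs("pJAK1", "ActRec"),
        obs("pSTAT1", "pSTAT1c", "ISGF3c"),
        obs("SOCS1", "SOCS1"),
        obs("USP18", "USP18"),
        obs("IRF9n", "IRF9n", "ISGF3n"),
    ]
    genes = INDUCED_GENES if variant == "core_feedback" else tuple(
        g for g in INDUCED_GENES if g != "IRF2"
    )
    table += [obs(f"m{g}", f"m{g}") for g in genes]
    return table


def build_model(
    variant: str,
    half_lives: dict[str, float] | None = None,
    config: ModelConfig | None = None,
) -> ModelStructure:
    """Assemble a model variant with the antiviral mRNA decay constants fixed.

    ``half_lives`` maps each antiviral gene to its measured mRNA half-life in
    hours; the corresponding first-order degradation constants are fixed at
    ln(2)/t_half and excluded from optimization.
    """
    if variant not in VARIANTS:
        raise ValueError(f"unknown model variant {variant!r}; choose from {VARIANTS}")
    if half_lives is None:
        half_lives = DEFAULT_HALF_LIVES
    missing = [g for g in ANTIVIRAL_GENES if g not in half_lives]
    if missing:
        raise ConfigurationError(f"missing mRNA half-life for: {missing}")
    for g in ANTIVIRAL_GENES:
        if not half_lives[g] > 0:
            raise ConfigurationError(f"half-life for {g} must be positive")
    cfg = config or ModelConfig()
    fixed = {f"kdeg_m{g}": math.log(2.0) / half_lives[g] for g in ANTIVIRAL_GENES}
    m = ModelStructure(
        variant=variant,
        species=tuple(_species_table(variant, cfg)),
        reactions=tuple(_reaction_table(variant)),
        observables=tuple(_observable_table(variant)),
        fixed_parameters=fixed,
        config=cfg,
    )
    m.validate()
    return m


#: measured half-life classes of the six antiviral transcripts (hours); the
#: late genes are stable on the 24 h observation window
DEFAULT_HALF_LIVES = {
    "IRF1": 0.75,
    "TRIM21": 1.5,
    "MX1": 6.0,
    "EIF2AK2": 5.5,
    "IFI6": 48.0,
    "IFITM3": 60.0,
}


def default_parameters(model: ModelStructure) -> ParameterSet:
    """Kinetic + observable parameters at mid-log-range defaults.

    Kinetic constants are bounded [1e-6, 1] except translocation constants
    ([1e-6, 1e2]); fixed mRNA decay constants keep their half-life-derived
    value (bounds widened to contain it when the class half-life is short).
    Observable scales are bounded [1e-3, 1e3] and noise sd [1e-3, 1e2].
    """
    values: dict[str, float] = {}
    bounds: dict[str, tuple[float, float]] = {}
    free: dict[str, bool] = {}
    for p in model.kinetic_parameters:
        if p in TRANSLOCATION_PARAMS:
            bounds[p] = (1e-6, 1e2)
            values[p] = 1e-2
        else:
            bounds[p] = (1e-6, 1.0)
            values[p] = 1e-3
        free[p] = True
    for p, v in model.fixed_parameters.items():
        lo, hi = bounds[p]
        bounds[p] = (lo, max(hi, v))
        values[p] = v
        free[p] = False
    for o in model.observables:
        values[o.scale_parameter] = 1.0
        bounds[o.scale_parameter] = (1e-3, 1e3)
        free[o.scale_parameter] = True
        values[o.noise_parameter] = 0.1
        bounds[o.noise_parameter] = (1e-3, 1e2)
        free[o.noise_parameter] = True
    return ParameterSet(values, bounds, free)


def conservation_matrix(model: ModelStructure) -> list[dict[str, float]]:
    """Conserved linear combinations of species (left null space of N).

    Returned as dictionaries mapping species name to an integer coefficient;
    each combination has identically zero time derivative under the model's
    rate laws, whatever the rates are.
    """
    import sympy

    N = sympy.Matrix(model.stoichiometric_matrix().astype(int))
    null = N.T.nullspace()
    names = model.species_names
    out = []
    for vec in null:
        denom = sympy.lcm([sympy.fraction(x)[1] for x in vec])
        vec = vec * denom
        if sum(1 for x in vec if x < 0) > sum(1 for x in vec if x > 0):
            vec = -vec
        out.append({names[i]: float(vec[i]) for i in range(len(names)) if vec[i] != 0})
    return out
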