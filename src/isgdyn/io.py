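"""Readers/writers for the package's CSV schemas, parameter files and SBML.

Native formats: long-format time-course CSV (columns time_h, observable,
replicate, dose_Uml, condition, value), parameter JSON (values, bounds,
free flags), and an SBML Level 3 export of a model structure written with
lxml (species, compartments, parameters, reactions with stoichiometry).
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd
from lxml import etree

from .likelihood import DATA_COLUMNS, FitResult, TimecourseDataset
from .model import ModelStructure, ParameterSet

__all__ = [
    "read_timecourse_csv",
    "write_timecourse_csv",
    "read_params_json",
    "write_params_json",
    "write_fit_json",
    "export_sbml",
    "read_sbml_counts",
]

SBML_NS = "http://www.sbml.org/sbml/level3/version2/core"


class SchemaError(ValueError):
    """A file does not match the expected column schema."""


def read_timecourse_csv(path) -> TimecourseDataset:
    frame = pd.read_csv(path)
    missing = [c for c in DATA_COLUMNS if c not in frame.columns]
    if missing:
        raise SchemaError(
            f"{path}: missing columns {missing}; expected header {DATA_COLUMNS}"
        )
    return TimecourseDataset(frame[DATA_COLUMNS])


def write_timecourse_csv(data: TimecourseDataset, path) -> None:
    data.frame[DATA_COLUMNS].to_csv(path, index=False)


def write_params_json(params: ParameterSet, path) -> None:
    doc = {
        "values": params.values,
        "bounds": {k: list(v) for k, v in params.bounds.items()},
        "free": params.free,
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_params_json(path) -> ParameterSet:
    doc = json.loads(Path(path).read_text())
    return ParameterSet(
        values=doc["values"],
        bounds={k: tuple(v) for k, v in doc["bounds"].items()},
        free=doc["free"],
    )


def write_fit_json(fit: FitResult, path) -> None:
    doc = {
        "best_objective": fit.best_objective,
        "k": fit.k,
        "n_data": fit.n_data,
        "seed": fit.seed,
        "n_converged_to_best": fit.n_converged_to_best,
        "waterfall": list(map(float, fit.waterfall)),
        "at_bound": fit.at_bound,
        "best_values": fit.best_params.values,
        "free": fit.best_params.free,
        "bounds": {k: list(v) for k, v in fit.best_params.bounds.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=1, sort_keys=True))


def read_fit_json(path) -> FitResult:
    import numpy as np

    doc = json.loads(Path(path).read_text())
    params = ParameterSet(
        values=doc["best_values"],
        bounds={k: tuple(v) for k, v in doc["bounds"].items()},
        free=doc["free"],
    )
    return FitResult(
        best_params=params,
        best_objective=doc["best_objective"],
        waterfall=np.asarray(doc["waterfall"]),
        n_converged_to_best=doc["n_converged_to_best"],
        seed=doc["seed"],
        n_data=doc["n_data"],
        at_bound=doc["at_bound"],
    )


def export_sbml(model: ModelStructure, path,
                params: ParameterSet | None = None) -> None:
    """Write the model as an SBML Level 3 Version 2 document.

    Kinetic rate laws are emitted as the product of the rate constant and
    the reactant concentrations (inhibition factors as MathML divides).
    Parameter values default to 1 when no ParameterSet is supplied.
    """
    if not model.species or not model.reactions:
        raise ValueError("refusing to export an empty model")
    nsmap = {None: SBML_NS}
    sbml = etree.Element("sbml", nsmap=nsmap, level="3", version="2")
    mdl = etree.SubElement(sbml, "model", id=f"isgdyn_{model.variant}")
    comps = etree.SubElement(mdl, "listOfCompartments")
    for c in ("extracellular", "cytoplasm", "nucleus"):
        etree.SubElement(comps, "compartment", id=c, constant="true", size="1")
    sps = etree.SubElement(mdl, "listOfSpecies")
    for s in model.species:
        etree.SubElement(
            sps, "species", id=s.name, compartment=s.compartment,
            initialConcentration=repr(float(s.initial_concentration)),
            hasOnlySubstanceUnits="false", boundaryCondition="false",
            constant="false",
        )
    pars = etree.SubElement(mdl, "listOfParameters")
    for p in model.kinetic_parameters:
        v = params.values[p] if params is not None else 1.0
        etree.SubElement(pars, "parameter", id=p, value=repr(float(v)),
                         constant="true")
    rxs = etree.SubElement(mdl, "listOfReactions")
    for r in model.reactions:
        rx = etree.SubElement(rxs, "reaction", id=r.name, reversible="false")
        if r.reactants:
            lor = etree.SubElement(rx, "listOfReactants")
            for sp in sorted(set(r.reactants)):
                etree.SubElement(lor, "speciesReference", species=sp,
                                 stoichiometry=str(r.reactants.count(sp)),
                                 constant="true")
        if r.products:
            lop = etree.SubElement(rx, "listOfProducts")
            for sp in sorted(set(r.products)):
                etree.SubElement(lop, "speciesReference", species=sp,
                                 stoichiometry=str(r.products.count(sp)),
                                 constant="true")
        kl = etree.SubElement(rx, "kineticLaw")
        math_el = etree.SubElement(
            kl, "math", nsmap={None: "http://www.w3.org/1998/Math/MathML"}
        )
        math_el.append(_rate_mathml(r))
    tree = etree.ElementTree(sbml)
    tree.write(str(path), xml_declaration=True, encoding="UTF-8",
               pretty_print=True)


def _ci(name: str):
    el = etree.Element("ci")
    el.text = f" {name} "
    return el


def _apply(op: str, *args):
    ap = etree.Element("apply")
    ap.append(etree.Element(op))
    for a in args:
        ap.append(a)
    return ap


def _cn(value: float):
    el = etree.Element("cn")
    el.text = f" {value} "
    return el


def _rate_mathml(r):
    terms = [_ci(r.rate_parameter)] + [_ci(sp) for sp in r.reactants]
    if r.inhibition is not None:
        if r.inhibition.kind == "saturating":
            s, = r.inhibition.species
            denom = _apply("plus", _cn(1.0),
                           _apply("divide", _ci(s), _ci(r.inhibition.parameter)))
            terms.append(_apply("divide", _cn(1.0), denom))
        else:
            free_sp, bound_sp = r.inhibition.species
            terms.append(
                _apply("divide", _ci(free_sp),
                       _apply("plus", _ci(free_sp), _ci(bound_sp)))
            )
    if len(terms) == 1:
        return terms[0]
    return _apply("times", *terms)


def read_sbml_counts(path) -> dict[str, int]:
    """Species/reaction/parameter counts of an SBML file plus stoichiometry
    checksum, for round-trip verification."""
    tree = etree.parse(str(path))
    ns = {"s": SBML_NS}
    species = tree.findall(".//s:species", ns)
    reactions = tree.findall(".//s:reaction", ns)
    parameters = tree.findall(".//s:parameter", ns)
    stoich = 0.0
    for ref in tree.findall(".//s:listOfReactants/s:speciesReference", ns):
        stoich -= float(ref.get("stoichiometry", 1))
    for ref in tree.findall(".//s:listOfProducts/s:speciesReference", ns):
        stoich += float(ref.get("stoichiometry", 1))
    return {
        "n_species": len(species),
        "n_reactions": len(reactions),
        "n_parameters": len(parameters),
        "net_stoichiometry": stoich,
    }
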