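"""Reference parameterization used as ground truth for synthetic data.

The kinetic constants below were chosen once, by constraining the extended
(feedback) model to the qualitative behavior of IFNα-stimulated hepatoma
cells: rapid but transient receptor/JAK activation shut down by SOCS1 and
USP18, ISGF3 peaking within the first hours, antiviral transcript peak
times ordered early < intermediate < late according to their mRNA
half-life class, a transient SOCS1 response, and a broad repressor (IRF2)
expression peak around 5-10 h that trims the late tail of the repressed
genes.  They are committed as a fixture: synthetic studies, tests and the
acceptance analyses all simulate from this set.

Units: concentrations nM (promoter states a.u.), time h; second-order
constants 1/(nM h).
"""

from __future__ import annotations

from .model import (
    ANTIVIRAL_GENES,
    ModelStructure,
    ParameterSet,
    default_parameters,
)

__all__ = ["REFERENCE_KINETICS", "reference_parameters"]

REFERENCE_KINETICS: dict[str, float] = {
    # receptor module
    "kact": 2e-3,
    "kinact": 0.1,
    "ki_socs1": 0.05,
    "kon_usp18": 0.01,
    "koff_usp18": 0.05,
    "ksyn_rec": 0.1,
    "kdeg_rec": 1e-4,
    "kdeg_ifn": 0.05,
    # STAT phosphorylation cycle
    "kphos_s1": 0.2,
    "kphos_s2": 0.2,
    "kdephos_s1": 1.0,
    "kdephos_s2": 1.0,
    # ISGF3 assembly and shuttling
    "kform_isgf3": 1e-3,
    "kimp_isgf3": 10.0,
    "kdiss_isgf3": 0.4,
    "kexp_s1": 2.0,
    "kexp_s2": 2.0,
    "kexp_irf9": 1.0,
    # ISGF3-driven transcription
    "vmax_mIRF1": 0.2,
    "vmax_mTRIM21": 0.15,
    "vmax_mMX1": 0.2,
    "vmax_mEIF2AK2": 0.15,
    "vmax_mIFI6": 0.1,
    "vmax_mIFITM3": 0.1,
    "vmax_mIRF9": 0.1,
    "vmax_mSOCS1": 0.5,
    "vmax_mUSP18": 0.1,
    "vmax_mIRF2": 0.3,
    # basal transcription
    "basal_mIRF9": 0.4,
    "basal_mSOCS1": 1e-4,
    "basal_mUSP18": 1e-4,
    "basal_mIRF2": 1e-4,
    # mRNA decay of the non-fixed transcripts
    "kdeg_mIRF9": 0.1,
    "kdeg_mSOCS1": 0.7,
    "kdeg_mUSP18": 0.08,
    "kdeg_mIRF2": 0.3,
    # translation and protein turnover
    "ktl_irf9": 0.5,
    "kdeg_irf9": 0.2,
    "ktl_socs1": 1.0,
    "kdeg_socs1": 1.0,
    "ktl_usp18": 0.5,
    "kdeg_usp18": 0.1,
    "ktl_irf2": 1.0,
    "kdeg_irf2": 0.7,
    # IRF2 feedback: nuclear import and promoter binding
    "kimp_irf2": 10.0,
    "kon_irf2": 1.0,
    "koff_irf2": 0.05,
}


def reference_parameters(model: ModelStructure) -> ParameterSet:
    """Reference ParameterSet for a model variant (kinetics above, scales 1).

    Parameters absent from the variant (feedback constants in the core
    model) are dropped; fixed antiviral decay constants keep the values
    implied by the model's half-life configuration.
    """
    ps = default_parameters(model)
    updates = {
        k: v for k, v in REFERENCE_KINETICS.items() if k in ps.values
    }
    for g in ANTIVIRAL_GENES:  # fixed from half-lives, not from this table
        updates.pop(f"kdeg_m{g}", None)
    return ps.updated(**updates)
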