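"""Selection and temporal classification of IFNα-upregulated genes.

Works on a log2 expression time-course matrix with paired treated /
untreated replicates (default time grid 0, 1, 2, 3, 4, 8, 12, 24 h).
Genes are called upregulated when some time point shows a paired t-test
p below alpha together with an average linear fold change above the
threshold; upregulated genes are then classified by the time of maximal
mean induction: early (t_max <= 4 h), intermediate (t_max = 8 h), late
(t_max >= 12 h).
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

log = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TIME_GRID",
    "ExpressionMatrix",
    "select_upregulated",
    "classify_by_tmax",
    "order_for_heatmap",
]

DEFAULT_TIME_GRID = (0.0, 1.0, 2.0, 3.0, 4.0, 8.0, 12.0, 24.0)

CLASS_BOUNDARIES = {"early": 4.0, "intermediate": 8.0, "late": 12.0}


class ExpressionMatrix:
    """Genes × (time, replicate, condition) log2 expression values.

    ``frame`` has gene rows and a 3-level column MultiIndex
    (time_h, replicate, condition) with condition in {treated, untreated};
    replicates are paired across conditions at every time point.
    """

    def __init__(self, frame: pd.DataFrame):
        if not isinstance(frame.columns, pd.MultiIndex) or frame.columns.nlevels != 3:
            raise ValueError(
                "expected columns as a (time_h, replicate, condition) MultiIndex"
            )
        self.frame = frame
        for t in self.times:
            tr = set(self._cols(t, "treated"))
            un = set(self._cols(t, "untreated"))
            if tr != un or not tr:
                raise ValueError(f"unpaired replicates at time {t}")

    @property
    def genes(self) -> list[str]:
        return list(self.frame.index)

    @property
    def times(self) -> list[float]:
        return sorted({float(t) for t in self.frame.columns.get_level_values(0)})

    def _cols(self, time: float, condition: str) -> list:
        cols = self.frame.columns
        return [
            c[1] for c in cols if float(c[0]) == time and c[2] == condition
        ]

    def values_at(self, time: float, condition: str) -> pd.DataFrame:
        reps = sorted(self._cols(time, condition))
        return pd.DataFrame(
            {r: self.frame[(time, r, condition)] for r in reps}
        )

    def induction(self) -> pd.DataFrame:
        """Mean log2(treated) - mean log2(untreated) per gene and time point."""
        out = {}
        for t in self.times:
            out[t] = (
                self.values_at(t, "treated").mean(axis=1)
                - self.values_at(t, "untreated").mean(axis=1)
            )
        return pd.DataFrame(out)

    @classmethod
    def from_long(cls, frame: pd.DataFrame) -> "ExpressionMatrix":
        """Build from long format (gene, time_h, replicate, condition, log2_value)."""
        wide = frame.pivot_table(
            index="gene", columns=["time_h", "replicate", "condition"],
            values="log2_value",
        )
        return cls(wide)


def select_upregulated(matrix: ExpressionMatrix, alpha: float = 0.05,
                       min_fold: float = 2.0, bh_correct: bool = False) -> pd.DataFrame:
    """Significantly upregulated genes: paired t-test p < alpha and average
    fold change > min_fold at some time point.

    The paired two-sided t-test compares treated vs untreated replicates per
    time point; the fold change is 2^(mean log2 difference).  No multiple
    testing correction is applied by default; ``bh_correct`` switches on a
    per-time-point Benjamini-Hochberg adjustment.
    """
    times = [t for t in matrix.times if t > 0 or True]
    pvals = {}
    folds = {}
    for t in times:
        tr = matrix.values_at(t, "treated")
        un = matrix.values_at(t, "untreated")
        if tr.shape[1] < 2:
            raise ValueError("need at least 2 paired replicates")
        res = stats.ttest_rel(tr.to_numpy(), un.to_numpy(), axis=1)
        p = pd.Series(res.pvalue, index=matrix.genes)
        if bh_correct:
            from statsmodels.stats.multitest import multipletests

            p = pd.Series(
                multipletests(p.fillna(1.0), method="fdr_bh")[1], index=p.index
            )
        pvals[t] = p
        folds[t] = 2.0 ** (tr.mean(axis=1) - un.mean(axis=1))
    pmat = pd.DataFrame(pvals)
    fmat = pd.DataFrame(folds)
    hit = (pmat < alpha) & (fmat > min_fold)
    selected = hit.any(axis=1)
    out = pd.DataFrame(
        {
            "gene": matrix.genes,
            "min_p": pmat.min(axis=1),
            "max_fold": fmat.max(axis=1),
            "selected": selected,
        }
    ).set_index("gene")
    return out[out["selected"]].drop(columns="selected")


def _class_of(tmax: float) -> tuple[str, bool]:
    """Class for a peak time; off-grid times snap to the nearest rule boundary."""
    if tmax <= CLASS_BOUNDARIES["early"]:
        return "early", False
    if tmax == CLASS_BOUNDARIES["intermediate"]:
        return "intermediate", False
    if tmax >= CLASS_BOUNDARIES["late"]:
        return "late", False
    # strictly between rule boundaries (finer grid): nearest boundary wins
    nearest = min(CLASS_BOUNDARIES.items(), key=lambda kv: abs(kv[1] - tmax))
    log.warning("t_max=%.3g h between class boundaries; assigning %s", tmax, nearest[0])
    cls = {"early": "early", "intermediate": "intermediate", "late": "late"}[nearest[0]]
    return cls, True


def classify_by_tmax(profiles: pd.DataFrame, pvalues: pd.Series | None = None
                     ) -> pd.DataFrame:
    """Classify per-gene induction profiles by their time of maximal induction.

    ``profiles``: genes × time points (mean induction, e.g. log2 fold change).
    Ties in the maximum resolve to the earliest time.  Returns a table with
    t_max, class, and the maximal induction value per gene.
    """
    times = np.array([float(t) for t in profiles.columns])
    needed = {4.0, 8.0, 12.0}
    if not needed <= set(times):
        raise ValueError("time grid must contain 4, 8 and 12 h")
    vals = profiles.to_numpy(float)
    # earliest argmax on ties
    imax = vals.argmax(axis=1)
    rows = []
    for gi, gene in enumerate(profiles.index):
        tmax = float(times[imax[gi]])
        cls, snapped = _class_of(tmax)
        rows.append(
            {
                "gene": gene,
                "t_max": tmax,
                "class": cls,
                "max_log2_fc": float(vals[gi, imax[gi]]),
                "boundary_snapped": snapped,
            }
        )
    table = pd.DataFrame(rows).set_index("gene")
    if pvalues is not None:
        table["p_value"] = pvalues.reindex(table.index)
    return table


def order_for_heatmap(table: pd.DataFrame, matrix: ExpressionMatrix) -> list[str]:
    """Display order: t_max ascending, ties by 1 h fold change descending."""
    ind = matrix.induction()
    if 1.0 not in ind.columns:
        raise ValueError("matrix lacks the 1 h time point")
    fc1 = 2.0 ** ind[1.0]
    key = pd.DataFrame(
        {"t_max": table["t_max"], "fc1": fc1.reindex(table.index)}
    )
    ordered = key.sort_values(["t_max", "fc1"], ascending=[True, False])
    return list(ordered.index)
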