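"""Gene selection and early/intermediate/late classification."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from isgdyn.classify import (
    DEFAULT_TIME_GRID,
    ExpressionMatrix,
    classify_by_tmax,
    order_for_heatmap,
    select_upregulated,
)
from isgdyn.synth import GeneratorConfig, generate_expression_matrix


def toy_matrix(values: dict, n_reps=3, times=(0.0, 1.0, 4.0, 8.0, 12.0)):
    """Build an ExpressionMatrix from per-gene log2 fold profiles.

    ``values``: gene -> list of log2 inductions per time point; replicates
    get deterministic offsets so the paired t-test is well defined.
    """
    cols = pd.MultiIndex.from_tuples(
        [(t, r, c) for t in times for r in range(1, n_reps + 1)
         for c in ("treated", "untreated")],
        names=["time_h", "replicate", "condition"],
    )
    offsets = [0.0, 0.05, -0.05][:n_reps]
    rows = {}
    for gene, prof in values.items():
        row = []
        for t, fc in zip(times, prof):
            for r in range(n_reps):
                row += [5.0 + fc + offsets[r], 5.0 + offsets[r]]
        rows[gene] = row
    frame = pd.DataFrame.from_dict(rows, orient="index")
    frame.columns = cols
    return ExpressionMatrix(frame)


class TestSelectUpregulated:
    def test_flat_matrix_selects_nothing(self):
        mat = toy_matrix({"g1": [0] * 5, "g2": [0] * 5})
        assert len(select_upregulated(mat)) == 0

    def test_pvalues_match_manual_paired_ttest(self):
        mat, _ = generate_expression_matrix(
            {"early": 3, "intermediate": 2, "late": 0}, GeneratorConfig(seed=9),
            noise_sd=0.2,
        )
        t0 = 8.0
        tr = mat.values_at(t0, "treated").to_numpy()
        un = mat.values_at(t0, "untreated").to_numpy()
        diffs = tr - un
        tstat = diffs.mean(axis=1) / (diffs.std(axis=1, ddof=1) / np.sqrt(diffs.shape[1]))
        manual_p = 2 * stats.t.sf(np.abs(tstat), df=diffs.shape[1] - 1)
        res = stats.ttest_rel(tr, un, axis=1)
        assert np.allclose(res.pvalue, manual_p)

    def test_selection_thresholds(self):
        mat = toy_matrix({"strong": [0, 2, 2, 1, 0], "weak": [0, 0.5, 0.5, 0, 0]})
        sel = select_upregulated(mat, alpha=0.05, min_fold=2.0)
        assert list(sel.index) == ["strong"]
        # alpha=1, fold 0 admits everything; alpha=0 admits nothing
        assert len(select_upregulated(mat, alpha=1.0, min_fold=0.0)) == 2
        assert len(select_upregulated(mat, alpha=0.0, min_fold=0.0)) == 0


class TestClassifyByTmax:
    def test_rule_boundaries(self):
        grid = list(DEFAULT_TIME_GRID)
        profiles = pd.DataFrame(
            {
                "peak2": _peaked(grid, 2.0),
                "peak4": _peaked(grid, 4.0),
                "peak8": _peaked(grid, 8.0),
                "peak12": _peaked(grid, 12.0),
                "rising": np.linspace(0, 3, len(grid)),
            },
            index=grid,
        ).T
        table = classify_by_tmax(profiles)
        assert table.loc["peak2", "class"] == "early"
        assert table.loc["peak4", "class"] == "early"
        assert table.loc["peak8", "class"] == "intermediate"
        assert table.loc["peak12", "class"] == "late"
        assert table.loc["rising", "t_max"] == 24.0
        assert table.loc["rising", "class"] == "late"

    def test_tie_resolves_to_earliest_time(self):
        grid = list(DEFAULT_TIME_GRID)
        prof = pd.DataFrame({"tied": [0, 3, 3, 1, 1, 1, 0, 0]}, index=grid).T
        table = classify_by_tmax(prof)
        assert table.loc["tied", "t_max"] == 1.0

    def test_off_grid_peak_snaps_to_nearest_boundary_with_flag(self):
        grid = [0.0, 2.0, 4.0, 6.0, 8.0, 12.0, 24.0]
        prof = pd.DataFrame({"g": _peaked(grid, 6.0)}, index=grid).T
        table = classify_by_tmax(prof)
        assert table.loc["g", "boundary_snapped"]

    def test_invariant_to_monotone_rescaling(self):
        mat, _ = generate_expression_matrix(
            {"early": 4, "intermediate": 4, "late": 2}, GeneratorConfig(seed=3),
            noise_sd=0.05,
        )
        prof = mat.induction()
        t1 = classify_by_tmax(prof)
        t2 = classify_by_tmax(3.0 * prof + 1.0)
        assert (t1["class"] == t2["class"]).all()

    def test_synthetic_fixture_class_counts_recovered(self):
        counts = {"early": 6, "intermediate": 5, "late": 3}
        mat, truth = generate_expression_matrix(counts, GeneratorConfig(seed=11),
                                                noise_sd=0.0)
        table = classify_by_tmax(mat.induction())
        assert table["class"].value_counts().to_dict() == counts
        assert (table["class"] == truth["class"]).all()


class TestHeatmapOrder:
    def test_two_key_sort(self):
        grid = list(DEFAULT_TIME_GRID)
        mat = toy_matrix(
            {"a": [0, np.log2(3), 2, 1, 0, 0, 0, 0],
             "b": [0, 1.0, 2, 1, 0, 0, 0, 0],
             "c": [0, 0.5, 1, 2, 3, 2, 1, 0]},
            times=tuple(grid),
        )
        table = classify_by_tmax(mat.induction())
        order = order_for_heatmap(table, mat)
        # a and b peak at 2 h; a has the larger 1 h fold change; c peaks later
        assert order == ["a", "b", "c"]

    def test_order_matches_independent_sort(self):
        mat, _ = generate_expression_matrix(
            {"early": 5, "intermediate": 5, "late": 3}, GeneratorConfig(seed=21),
            noise_sd=0.05,
        )
        table = classify_by_tmax(mat.induction())
        order = order_for_heatmap(table, mat)
        ind = mat.induction()
        expected = sorted(
            table.index,
            key=lambda g: (table.loc[g, "t_max"], -(2.0 ** ind.loc[g, 1.0])),
        )
        assert order == expected


def _peaked(grid, peak_time):
    return [2.0 if t == peak_time else (0.5 if t > 0 else 0.0) for t in grid]
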