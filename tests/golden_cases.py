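"""Deterministic figure fixtures shared by the golden-file test and the
regeneration script (scripts/make_goldens.py)."""

from __future__ import annotations

import io

from goenrichview import (
    AnalysisSet,
    AxisConfig,
    Selection,
    assemble_rows,
    attach,
    parse_obo,
)
from goenrichview.enrichment import EnrichmentRecord

from conftest import B, C, D, DIAMOND_OBO, E, R


def _rec(gid, p, orat, exp, obs, direction):
    return EnrichmentRecord(
        go_id=gid,
        p_value=p,
        odds_ratio=orat,
        expected_count=exp,
        observed_count=obs,
        gene_set_size=obs + 30,
        term_name=gid,
        direction=direction,
    )


def case_single_path_four_analyses():
    """4 rows x 4 analyses: significance/direction varies across columns."""
    ont = parse_obo(io.StringIO(DIAMOND_OBO))
    analyses = []
    for k in range(1, 5):
        recs = {
            D: _rec(D, 0.001 * k, 2.0 + k, 2.5, 5 * k, "over"),
            E: _rec(E, 0.02 * k, 0.5, 4.0, 1, "under"),
        }
        analyses.append((f"analysis_{k}", recs))
    aset = AnalysisSet(analyses=analyses)
    index = attach(ont, aset)
    rows = assemble_rows(Selection(paths=[(R, B, D, E)]), ont, index)
    return rows, aset.labels, AxisConfig(mode="fold_change"), None


def case_two_paths_odds_ratio_axis():
    """Merged-prefix selection on the odds-ratio scale, with a caption."""
    ont = parse_obo(io.StringIO(DIAMOND_OBO))
    analyses = [
        ("control", {D: _rec(D, 0.4, 1.1, 3.0, 3, "over")}),
        ("treated", {D: _rec(D, 1e-4, 30.0, 2.0, 12, "over")}),  # OR clamps
    ]
    aset = AnalysisSet(analyses=analyses)
    index = attach(ont, aset)
    rows = assemble_rows(
        Selection(paths=[(R, B, D), (R, C, D)]), ont, index
    )
    return rows, aset.labels, AxisConfig(mode="odds_ratio"), "dose response"


def case_single_row_empty_panel():
    """One label with no record anywhere: an empty panel, no polygons."""
    ont = parse_obo(io.StringIO(DIAMOND_OBO))
    aset = AnalysisSet(analyses=[("only", {})])
    index = attach(ont, aset)
    rows = assemble_rows(Selection(paths=[(R,)]), ont, index)
    return rows, aset.labels, AxisConfig(), None


GOLDEN_CASES = {
    "single_path_four_analyses": case_single_path_four_analyses,
    "two_paths_odds_ratio_axis": case_two_paths_odds_ratio_axis,
    "single_row_empty_panel": case_single_row_empty_panel,
}
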