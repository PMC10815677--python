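"""Published reference results from the male urothelial-carcinoma urine study.

The workflow implemented here was developed on a cohort of 251 male UCa
cases and 111 controls measured at 10 amplicons / 65 retained CpG units.
That cohort is not publicly deposited, so the constants below record the
*printed* outputs of the study — the selected-target lists of the five
selection approaches, the or-panel report with history-stratified metrics,
and the final published decision-matrix thresholds — exactly as the study
report presents them.  They serve two purposes:

* worked-example checks of the set arithmetic (consensus intersection,
  pairwise selector overlaps, panel ranking) on real published inputs, and
* a report-comparison mode that re-applies the ranking and best-panel rules
  to the printed panel metrics.

They are reference inputs, never a substitute for running the pipeline.
"""

from __future__ import annotations

from .consensus_decision import PanelEvaluation
from .data_model import CpGUnitID, parse_target_notation

__all__ = [
    "SELECTED_TARGETS",
    "SELECTED_TARGET_COUNTS",
    "PANEL_REPORT_ROWS",
    "published_panel_report",
    "DECISION_THRESHOLDS",
    "GENE_ANNOTATIONS",
    "selected_sets",
]

#: Selected-target lists of the five selection approaches plus the row of
#: singular CpGs with >50% sensitivity at >=95% specificity, in the compact
#: group notation understood by :func:`parse_target_notation`.
SELECTED_TARGETS: dict[str, str] = {
    "bt_acc": "35_5 and 7 2_6 and 11 78_2.3 and 12.13.14 71_5 14_7.8.9 and 1 64_3",
    "bt_spec": (
        "35_5 and 7 78_2.3 and 12.13.14 2_6 and 7 14_1 and 6 74_9 "
        "71_8.9.10 and 3.4 and 11 and 5"
    ),
    "rf_acc": (
        "35_2.3 and 7 and 5 78_2.3 and 12.13.14 and 7.8 and 6 "
        "2_6 and 3 and 8 and 2 and 9.10 and 4 and 1 and 11 and 7 "
        "71_11 and 8.9.10 and 6.7 and 3.4 and 12 and 5 and 2 "
        "14_7.8.9 and 2.3 and 6 and 1 and 10 and 13 and 4.5 and 11.12 and 14 "
        "70_3.4 and 6 and 5 and 9.10 and 7 "
        "42_10 and 9 and 6.7.8 and 4.5 and 1 and 12 "
        "74_8 and 10.11.12 and 6 and 3.4 and 9 64_3"
    ),
    "rf_spec": (
        "78_2.3 and 12.13.14 and 6 and 7.8 35_5 and 2.3 and 7 "
        "2_8 and 6 and 3 and 2 and 1 and 7 and 11 and 4 and 9.10 "
        "71_11 and 3.4 and 8.9.10 and 6.7 and 5 and 12 "
        "14_1 and 6 and 2.3 and 11.12 and 10 and 14 and 13 and 4.5 and 7.8.9 "
        "74_8 and 6 and 3.4 70_3.4 and 7 and 6 "
        "42_2.3 and 9 and 10 and 4.5 and 1 and 12"
    ),
    "lasso": "02_6 35_7 42_9 78_2.3",
    "singular": (
        "02_6 and 8 and 3 and 4 and 2 and 9.10 and 11 and 7 78_6 "
        "14_11.12 and 10 and 7.8.9 and 2.3 and 13 70_6 74_6 22_2 and 3 "
        "35_7 42_1 and 10"
    ),
}

#: Published "Number of Selected Targets" per row.
SELECTED_TARGET_COUNTS: dict[str, int] = {
    "bt_acc": 10,
    "bt_spec": 13,
    "rf_acc": 49,
    "rf_spec": 43,
    "lasso": 4,
    "singular": 21,
}


def selected_sets(keys=("rf_acc", "rf_spec", "bt_acc", "bt_spec", "lasso")) -> list[set[CpGUnitID]]:
    """Parse the published selected-target lists for the given selectors."""
    return [parse_target_notation(SELECTED_TARGETS[k]) for k in keys]


#: Published or-panel report: (members, overall, no-history stratum,
#: history stratum) with (sensitivity %, specificity %) pairs, in the
#: published row order.
PANEL_REPORT_ROWS: list[tuple[tuple[str, ...], tuple[int, int], tuple[int, int], tuple[int, int]]] = [
    (("02_CpG_6",), (58, 96), (70, 98), (40, 94)),
    (("02_CpG_6", "35_CpG_7"), (61, 95), (72, 98), (43, 90)),
    (("35_CpG_7",), (50, 95), (59, 100), (37, 90)),
    (("78_CpG_2.3",), (43, 95), (54, 98), (28, 92)),
    (("02_CpG_6", "35_CpG_7", "78_CpG_2.3"), (61, 93), (73, 98), (43, 86)),
    (("35_CpG_7", "78_CpG_2.3"), (54, 93), (65, 98), (37, 86)),
]


def published_panel_report() -> list[PanelEvaluation]:
    """The printed panel metrics as :class:`PanelEvaluation` rows (fractions)."""
    rows = []
    for members, overall, no_hist, hist in PANEL_REPORT_ROWS:
        rows.append(
            PanelEvaluation(
                members=members,
                sensitivity=overall[0] / 100,
                specificity=overall[1] / 100,
                sensitivity_no_history=no_hist[0] / 100,
                specificity_no_history=no_hist[1] / 100,
                sensitivity_history=hist[0] / 100,
                specificity_history=hist[1] / 100,
            )
        )
    return rows


#: Final published decision-matrix thresholds (methylation fraction at 95%
#: specificity); exceeding either threshold stratifies the patient for
#: cystoscopy.
DECISION_THRESHOLDS: dict[str, float] = {
    "02_CpG_6": 0.435,
    "35_CpG_7": 0.465,
}

#: Cohort-specific gene annotations of the decision-matrix targets
#: (optional labels, never identifiers).
GENE_ANNOTATIONS: dict[str, str] = {
    "02_CpG_6": "ALOX5",
    "35_CpG_7": "TRPS1",
    "78_CpG_2.3": "chr16 intergenic",
}
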