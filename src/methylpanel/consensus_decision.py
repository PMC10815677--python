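"""Cross-method consensus and or-rule decision-matrix panels.

CpG units selected by *every* selection approach form the candidate set.
Candidates are combined into "or-matrices": a panel of (CpG, threshold)
pairs that calls a specimen positive as soon as any member's methylation
value strictly exceeds its calibrated threshold.  All non-empty candidate
subsets are evaluated, ranked by overall specificity (descending) and then
overall sensitivity, panels below the specificity floor are flagged as
excluded, and the best admissible panel is the one maximizing sensitivity.
Metrics are reported overall and stratified by prior-tumor history for
cases and controls alike.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, replace
from typing import Iterable, Mapping, Sequence

import pandas as pd

from .data_model import CpGUnitID, MethylationDataset
from .selection_engines import SelectionResult

__all__ = [
    "DecisionMatrix",
    "PanelEvaluation",
    "consensus",
    "classify",
    "evaluate_panel",
    "enumerate_panels",
    "rank_panels",
    "select_best_panel",
]

#: exhaustive subset enumeration is capped; consensus sets are small by design
MAX_CANDIDATES = 20


@dataclass(frozen=True)
class DecisionMatrix:
    """An or-rule panel: positive iff any member value strictly exceeds its threshold."""

    members: tuple[tuple[str, float], ...]

    def __post_init__(self) -> None:
        if not self.members:
            raise ValueError("a decision matrix needs at least one member")
        for name, thr in self.members:
            if not 0.0 <= thr <= 1.0:
                raise ValueError(f"threshold for {name} must lie in [0, 1], got {thr}")

    @property
    def member_names(self) -> tuple[str, ...]:
        return tuple(name for name, _ in self.members)


@dataclass(frozen=True)
class PanelEvaluation:
    """Sensitivity/specificity of a panel, overall and by prior-tumor history.

    An undefined metric (empty stratum) is ``nan``, never zero.
    """

    members: tuple[str, ...]
    sensitivity: float
    specificity: float
    sensitivity_no_history: float
    specificity_no_history: float
    sensitivity_history: float
    specificity_history: float
    thresholds: tuple[float, ...] | None = None
    meets_floor: bool | None = None


def consensus(results: Sequence[SelectionResult | Iterable]) -> set:
    """CpGs concordantly selected by all approaches (set intersection)."""
    if not results:
        raise ValueError("need at least one selection result")
    sets = [
        set(r.selected) if isinstance(r, SelectionResult) else set(r) for r in results
    ]
    out = sets[0]
    for s in sets[1:]:
        out = out & s
    return out


def classify(matrix: DecisionMatrix, ds: MethylationDataset) -> pd.Series:
    """Per-sample boolean call: True = positive (any member above threshold)."""
    pos = pd.Series(False, index=ds.sample_ids)
    for name, thr in matrix.members:
        if name not in ds.values.columns:
            raise KeyError(f"panel member {name!r} not in dataset")
        col = ds.values[name]
        if col.isna().any():
            sid = col.index[col.isna()][0]
            raise ValueError(
                f"missing value for panel member {name!r} (sample {sid!r}); impute first"
            )
        pos |= col > thr
    return pos


def _rate(calls: pd.Series, mask: pd.Series, positive: bool) -> float:
    sub = calls[mask]
    if len(sub) == 0:
        return float("nan")
    return float((sub == positive).mean())


def evaluate_panel(matrix: DecisionMatrix, ds: MethylationDataset) -> PanelEvaluation:
    """Sensitivity over cases, specificity over controls; overall and by history."""
    calls = classify(matrix, ds)
    case = ds.case_mask
    hist = ds.metadata["uca_history"].astype(bool)
    return PanelEvaluation(
        members=matrix.member_names,
        sensitivity=_rate(calls, case, True),
        specificity=_rate(calls, ~case, False),
        sensitivity_no_history=_rate(calls, case & ~hist, True),
        specificity_no_history=_rate(calls, ~case & ~hist, False),
        sensitivity_history=_rate(calls, case & hist, True),
        specificity_history=_rate(calls, ~case & hist, False),
        thresholds=tuple(t for _, t in matrix.members),
    )


def rank_panels(evaluations: Sequence[PanelEvaluation]) -> list[PanelEvaluation]:
    """Rank by overall specificity (descending), then overall sensitivity."""
    return sorted(
        evaluations,
        key=lambda e: (-e.specificity, -e.sensitivity, len(e.members)),
    )


def enumerate_panels(
    candidates: Iterable,
    thresholds: Mapping[str, float] | pd.DataFrame,
    ds: MethylationDataset,
    floor: float = 0.95,
) -> list[PanelEvaluation]:
    """Evaluate and rank all 2^k - 1 non-empty candidate subsets.

    ``thresholds`` maps canonical CpG names to calibrated cut points (or is
    a calibration table with ``cpg``/``threshold`` columns).  Panels whose
    overall specificity falls below ``floor`` are kept in the ranking but
    flagged ``meets_floor=False``.
    """
    names = sorted(
        c.canonical_name if isinstance(c, CpGUnitID) else str(c) for c in candidates
    )
    if not names:
        raise ValueError("candidate set is empty")
    if len(names) > MAX_CANDIDATES:
        raise ValueError(f"refusing to enumerate >{MAX_CANDIDATES} candidates ({len(names)})")
    if isinstance(thresholds, pd.DataFrame):
        thresholds = dict(zip(thresholds["cpg"], thresholds["threshold"]))
    missing = [n for n in names if n not in thresholds]
    if missing:
        raise KeyError(f"no calibrated threshold for {missing}")
    evals = []
    for r in range(1, len(names) + 1):
        for combo in itertools.combinations(names, r):
            matrix = DecisionMatrix(tuple((n, float(thresholds[n])) for n in combo))
            ev = evaluate_panel(matrix, ds)
            evals.append(replace(ev, meets_floor=bool(ev.specificity >= floor)))
    return rank_panels(evals)


def select_best_panel(
    ranked: Sequence[PanelEvaluation], floor: float = 0.95
) -> PanelEvaluation | None:
    """Best admissible panel: max sensitivity among panels at/above the floor.

    Ties resolve to higher specificity, then fewer members.  Returns
    ``None`` when no panel meets the floor.
    """
    admissible = [e for e in ranked if e.specificity >= floor]
    if not admissible:
        return None
    return min(
        admissible, key=lambda e: (-e.sensitivity, -e.specificity, len(e.members))
    )
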