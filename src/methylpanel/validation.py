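"""Repeated train/test-split validation with pooled-ROC summarization.

A previously selected feature set (with fixed hyperparameters — no nested
re-tuning) is validated by repeatedly splitting the cohort: two-thirds of
the controls train, one-third tests, and the cases are randomly
down-sampled to the *same absolute* train/test counts so that every split
is class-balanced.  Per iteration, accuracy / sensitivity / specificity /
AUC are recorded on the test set; the predicted case-probabilities and true
labels of all iterations are pooled into a single ROC curve giving the
pooled AUC and the sensitivity at the specificity floor.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MethylationDataset
from .roc_calibration import auc as roc_auc
from .roc_calibration import threshold_at_specificity
from .selection_engines import make_learner

__all__ = ["ValidationSummary", "repeated_split_validate", "split_counts"]


@dataclass
class ValidationSummary:
    """Per-iteration metrics plus the pooled ROC summary."""

    iterations: pd.DataFrame  # columns: accuracy, sensitivity, specificity, auc
    pooled_scores: np.ndarray
    pooled_labels: np.ndarray
    pooled_auc: float
    pooled_sensitivity_at_floor: float
    floor: float

    @property
    def n_iterations(self) -> int:
        return len(self.iterations)

    def summary_row(self) -> dict:
        """One row mirroring the published per-approach report columns."""
        means = self.iterations.mean()
        return {
            "auc": float(means["auc"]),
            "accuracy": float(means["accuracy"]),
            "sensitivity": float(means["sensitivity"]),
            "specificity": float(means["specificity"]),
            "pooled_auc": self.pooled_auc,
            "sensitivity_at_floor": self.pooled_sensitivity_at_floor,
            "floor": self.floor,
            "n_iterations": self.n_iterations,
        }


def split_counts(n_controls: int) -> tuple[int, int]:
    """(train, test) control counts: floor(2n/3) train, remainder test."""
    n_train = (2 * n_controls) // 3
    return n_train, n_controls - n_train


def repeated_split_validate(
    ds: MethylationDataset,
    features,
    method: str,
    hyperparams,
    n_iter: int = 1000,
    floor: float = 0.95,
    seed: int = 0,
) -> ValidationSummary:
    """Validate a fixed feature set over ``n_iter`` random splits.

    Requires a complete dataset (impute first) and enough cases for the
    down-sampling: ``n_cases >= n_controls`` (each control count is matched
    one-to-one by a case).  Deterministic given ``seed``.
    """
    cols = list(features)
    X = ds.values[cols].to_numpy()
    if np.isnan(X).any():
        raise ValueError("validation requires a complete dataset; impute first")
    y = ds.y
    case_idx = np.flatnonzero(y == 1)
    ctrl_idx = np.flatnonzero(y == 0)
    n_tr_c, n_te_c = split_counts(len(ctrl_idx))
    needed = n_tr_c + n_te_c
    if len(case_idx) < needed:
        raise ValueError(
            f"down-sampling infeasible: need {needed} cases "
            f"({n_tr_c} train + {n_te_c} test) but have {len(case_idx)}"
        )

    root = np.random.SeedSequence(seed)
    rng = np.random.default_rng(root)
    rows = []
    pooled_scores: list[np.ndarray] = []
    pooled_labels: list[np.ndarray] = []
    for it in range(n_iter):
        ctrl_perm = rng.permutation(ctrl_idx)
        case_pick = rng.choice(case_idx, size=needed, replace=False)
        train = np.concatenate([ctrl_perm[:n_tr_c], case_pick[:n_tr_c]])
        test = np.concatenate([ctrl_perm[n_tr_c:], case_pick[n_tr_c:]])
        model = make_learner(
            method, hyperparams, seed=int(rng.integers(2**31 - 1)), n_features=len(cols)
        )
        model.fit(X[train], y[train])
        prob = model.predict_proba(X[test])[:, 1]
        pred = (prob > 0.5).astype(int)
        yt = y[test]
        rows.append(
            {
                "accuracy": float((pred == yt).mean()),
                "sensitivity": float((pred[yt == 1] == 1).mean()),
                "specificity": float((pred[yt == 0] == 0).mean()),
                "auc": roc_auc(prob, yt),
            }
        )
        pooled_scores.append(prob)
        pooled_labels.append(yt)

    scores = np.concatenate(pooled_scores)
    labels = np.concatenate(pooled_labels)
    pooled = threshold_at_specificity(scores, labels, floor=floor)
    return ValidationSummary(
        iterations=pd.DataFrame(rows),
        pooled_scores=scores,
        pooled_labels=labels,
        pooled_auc=roc_auc(scores, labels),
        pooled_sensitivity_at_floor=pooled.sensitivity,
        floor=floor,
    )
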