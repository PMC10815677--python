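"""Per-CpG ROC analysis and threshold calibration at a specificity floor.

A single CpG unit classifies a specimen as positive when its methylation
value *strictly exceeds* a threshold (the markers are hypermethylated in
tumours, so high methylation is always the positive direction).  For
clinical use the threshold of each CpG is calibrated at a pre-set
specificity floor (default >= 95%): among all ROC points meeting the floor,
the one with the highest sensitivity is chosen, so that false positives —
i.e. unnecessary cystoscopies — are bounded by design.

Thresholds are placed at observed score values (no midpoint interpolation),
which makes the calibrated cut points directly usable as published values.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.metrics import roc_auc_score

from .data_model import MethylationDataset

__all__ = [
    "CalibratedThreshold",
    "roc_points",
    "threshold_at_specificity",
    "auc",
    "calibrate_dataset",
    "SingleClassError",
]


class SingleClassError(ValueError):
    """ROC analysis needs both cases and controls."""


@dataclass(frozen=True)
class CalibratedThreshold:
    """A per-CpG cut point with the metrics achieved at it (on calibration data)."""

    cpg: str
    threshold: float
    sensitivity: float
    specificity: float
    accuracy: float
    auc: float


def _to_binary(labels) -> np.ndarray:
    arr = np.asarray(labels)
    if arr.dtype.kind in "UOS":
        y = arr == "case"
    else:
        y = arr.astype(bool)
    if y.all() or not y.any():
        raise SingleClassError("both cases and controls are required")
    return y


def roc_points(scores, labels) -> pd.DataFrame:
    """All distinct operating points of the rule ``score > threshold``.

    Candidate thresholds are the distinct observed scores plus the -inf/+inf
    sentinels; consecutive thresholds yielding the identical
    (sensitivity, specificity) point are merged, keeping the largest finite
    threshold of the run.  Points are ordered by increasing threshold
    (sensitivity non-increasing, specificity non-decreasing).
    """
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    if np.isnan(s).any():
        raise ValueError("scores must not be missing")
    cases = np.sort(s[y])
    ctrls = np.sort(s[~y])
    thr = np.concatenate(([-np.inf], np.unique(s), [np.inf]))
    # positives strictly above the threshold
    sens = (len(cases) - np.searchsorted(cases, thr, side="right")) / len(cases)
    spec = np.searchsorted(ctrls, thr, side="right") / len(ctrls)

    keep_thr, keep_sens, keep_spec = [], [], []
    i = 0
    while i < len(thr):
        j = i
        while j + 1 < len(thr) and sens[j + 1] == sens[i] and spec[j + 1] == spec[i]:
            j += 1
        # representative threshold: largest finite one in the run, if any
        rep = j
        while rep > i and np.isinf(thr[rep]):
            rep -= 1
        keep_thr.append(thr[rep])
        keep_sens.append(sens[i])
        keep_spec.append(spec[i])
        i = j + 1
    return pd.DataFrame({"threshold": keep_thr, "sensitivity": keep_sens, "specificity": keep_spec})


def threshold_at_specificity(scores, labels, floor: float = 0.95, cpg: str = "") -> CalibratedThreshold:
    """Calibrate the cut point at a specificity floor.

    Among ROC points with specificity >= ``floor`` (the all-negative point
    always qualifies) the point maximizing sensitivity is returned; ties
    break towards higher specificity, then towards the larger threshold.
    Accuracy is computed at the chosen threshold on the calibration data.
    """
    y = _to_binary(labels)
    s = np.asarray(scores, dtype=float)
    pts = roc_points(s, y)
    ok = pts[pts["specificity"] >= floor]
    best = ok.sort_values(
        ["sensitivity", "specificity", "threshold"], ascending=False, kind="mergesort"
    ).iloc[0]
    t = float(best["threshold"])
    pos = s > t
    acc = float(((pos & y) | (~pos & ~y)).mean())
    return CalibratedThreshold(
        cpg=cpg,
        threshold=t,
        sensitivity=float(best["sensitivity"]),
        specificity=float(best["specificity"]),
        accuracy=acc,
        auc=auc(s, y),
    )


def auc(scores, labels) -> float:
    """Area under the ROC curve = Mann-Whitney probability, ties counted half."""
    y = _to_binary(labels)
    return float(roc_auc_score(y, np.asarray(scores, dtype=float)))


def calibrate_dataset(ds: MethylationDataset, floor: float = 0.95) -> pd.DataFrame:
    """Calibrate every CpG of a complete (imputed) dataset.

    Returns one row per CpG: ``cpg, threshold, sensitivity, specificity,
    accuracy, auc``.
    """
    if ds.missing_mask.any().any():
        raise ValueError("calibration requires a complete dataset; impute first")
    y = ds.y
    rows = [
        threshold_at_specificity(ds.values[c].to_numpy(), y, floor=floor, cpg=c)
        for c in ds.cpg_names
    ]
    return pd.DataFrame([r.__dict__ for r in rows])
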