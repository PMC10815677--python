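"""Missingness-based CpG exclusion and within-amplicon imputation.

CpG units with more than 5% missing values are excluded outright.  The few
remaining missing cells are filled by exploiting the strong correlation of
CpG units on the same amplicon: for each target unit the amplicon mates are
ranked by absolute Pearson correlation (computed on pairwise-complete
observations), an ordinary least-squares line of the target on the donor is
fitted over their jointly observed samples, and the fitted prediction —
clipped to [0, 1] — replaces the missing value.  If no mate is observed for
a given sample the target's observed mean is used as a last resort (logged
as a fallback).  Observed cells are never altered.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data_model import MethylationDataset

__all__ = ["filter_missingness", "impute", "ImputationResult", "ImputationError"]

#: columns of the imputation log
LOG_COLUMNS = ("sample_id", "cpg", "donor", "r", "slope", "intercept", "fallback")

#: minimum jointly observed samples for a mate to qualify as donor (OLS
#: degeneracy guard)
MIN_JOINT_OBS = 3


class ImputationError(ValueError):
    """Imputation cannot proceed (e.g. an entirely missing CpG)."""


def filter_missingness(
    ds: MethylationDataset, max_missing_frac: float = 0.05
) -> tuple[MethylationDataset, pd.DataFrame]:
    """Drop CpG units whose missing fraction strictly exceeds the bound.

    Returns the filtered dataset and a table of exclusions with the
    per-CpG missing fraction (columns ``cpg``, ``missing_frac``).
    """
    frac = ds.missing_mask.mean(axis=0)
    excluded = frac[frac > max_missing_frac]
    report = pd.DataFrame(
        {"cpg": excluded.index, "missing_frac": excluded.to_numpy()}
    ).reset_index(drop=True)
    kept = [c for c in ds.cpg_names if c not in set(excluded.index)]
    return ds.select_cpgs(kept), report


@dataclass
class ImputationResult:
    dataset: MethylationDataset
    log: pd.DataFrame


def _ranked_donors(values: pd.DataFrame, target: str, mates: list[str]) -> list[tuple[str, float]]:
    """Amplicon mates usable as donors, best (largest |r|) first.

    Ties in |r| break by column order.  Mates with fewer than
    ``MIN_JOINT_OBS`` jointly observed samples or an undefined correlation
    (constant input) are skipped.
    """
    t = values[target]
    ranked: list[tuple[float, int, str, float]] = []
    for pos, m in enumerate(mates):
        joint = t.notna() & values[m].notna()
        if int(joint.sum()) < MIN_JOINT_OBS:
            continue
        a = t[joint].to_numpy()
        b = values[m][joint].to_numpy()
        if np.std(a) == 0.0 or np.std(b) == 0.0:
            continue
        r = float(np.corrcoef(a, b)[0, 1])
        if not np.isfinite(r):
            continue
        ranked.append((-abs(r), pos, m, r))
    ranked.sort()
    return [(m, r) for _, _, m, r in ranked]


def impute(ds: MethylationDataset) -> ImputationResult:
    """Fill every missing cell by within-amplicon linear-model prediction.

    Meant to run after :func:`filter_missingness`.  One OLS line is fitted
    per (target, donor) pair on their jointly observed samples and reused
    for every missing cell served by that donor.  The returned log has one
    row per imputed cell (see :data:`LOG_COLUMNS`).
    """
    observed = ds.values  # donor values are always the original observations
    out = ds.values.copy()
    amap = ds.amplicon_map
    by_amp: dict[str, list[str]] = {}
    for name in ds.cpg_names:
        by_amp.setdefault(amap[name], []).append(name)

    log_rows: list[dict] = []
    fits: dict[tuple[str, str], tuple[float, float]] = {}

    for target in ds.cpg_names:
        miss = observed[target].isna()
        if not miss.any():
            continue
        if miss.all():
            raise ImputationError(f"CpG {target!r} has no observed values")
        mates = [m for m in by_amp[amap[target]] if m != target]
        donors = _ranked_donors(observed, target, mates)
        fallback_mean = float(observed[target].mean())

        for sid in observed.index[miss]:
            filled = False
            for donor, r in donors:
                x = observed.at[sid, donor]
                if pd.isna(x):
                    continue
                key = (target, donor)
                if key not in fits:
                    joint = observed[target].notna() & observed[donor].notna()
                    slope, intercept = np.polyfit(
                        observed[donor][joint].to_numpy(),
                        observed[target][joint].to_numpy(),
                        deg=1,
                    )
                    fits[key] = (float(slope), float(intercept))
                slope, intercept = fits[key]
                pred = float(np.clip(slope * x + intercept, 0.0, 1.0))
                out.at[sid, target] = pred
                log_rows.append(
                    dict(
                        sample_id=sid, cpg=target, donor=donor, r=r,
                        slope=slope, intercept=intercept, fallback=False,
                    )
                )
                filled = True
                break
            if not filled:
                out.at[sid, target] = float(np.clip(fallback_mean, 0.0, 1.0))
                log_rows.append(
                    dict(
                        sample_id=sid, cpg=target, donor="", r=np.nan,
                        slope=np.nan, intercept=np.nan, fallback=True,
                    )
                )

    log = pd.DataFrame(log_rows, columns=list(LOG_COLUMNS))
    new_ds = MethylationDataset(values=out, metadata=ds.metadata.copy())
    return ImputationResult(dataset=new_ds, log=log)
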