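"""Synthetic methylation cohorts with amplicon-correlated CpG units.

The generator emulates the statistical structure the selection workflow
relies on, without attempting to model mass-spectrometric measurement
error mechanistically:

* values in [0, 1] produced by a latent Gaussian factor model pushed
  through the inverse logit — one shared factor per amplicon with loading
  ``sqrt(rho)`` induces the strong within-amplicon correlation of CpG
  units measured on the same PCR product;
* a planted subset of units is mean-shifted on the latent (logit) scale in
  cases only — hypermethylation in tumours;
* cases with a prior-tumor history get an attenuated shift
  (``effect_size * history_attenuation``), mimicking the weaker signal of
  small surveillance-detected recurrences;
* missingness is completely at random at per-CpG rates, optionally with
  per-CpG overrides so that some units exceed the 5% exclusion bound.

Everything is deterministic given ``seed``.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy.special import expit, logit

from .data_model import CpGUnitID, MethylationDataset

__all__ = ["SimulationConfig", "generate", "cpg_universe", "make_imputation_fixture"]


@dataclass(frozen=True)
class SimulationConfig:
    """Parameters of the cohort simulator.

    Defaults mirror the study scale: 251 cases / 111 controls, 10 amplicons
    of 7 units each (70 units, of which 5 default to 10% missingness and are
    therefore expected to fall to the >5%-missing exclusion, leaving ~65),
    roughly 40/111 population controls, and ~40% of cases with prior-tumor
    history.
    """

    n_cases: int = 251
    n_controls: int = 111
    n_amplicons: int = 10
    units_per_amplicon: int | Sequence[int] = 7
    planted_cpgs: frozenset[CpGUnitID] | None = None
    effect_size: float = 1.5
    history_fraction: float = 0.4
    history_attenuation: float = 0.5
    within_amplicon_rho: float = 0.7
    missing_rate: float = 0.01
    missing_overrides: Mapping[str, float] = field(default_factory=dict)
    n_high_missing_units: int = 5
    high_missing_rate: float = 0.10
    control_history_fraction: float = 0.3
    population_control_fraction: float = 40 / 111
    latent_scale: float = 1.0
    baseline_range: tuple[float, float] = (0.15, 0.45)
    leukocyte_max: float = 450.0
    seed: int = 0

    def units_list(self) -> list[int]:
        if isinstance(self.units_per_amplicon, int):
            return [self.units_per_amplicon] * self.n_amplicons
        lst = list(self.units_per_amplicon)
        if len(lst) != self.n_amplicons:
            raise ValueError("units_per_amplicon list must have n_amplicons entries")
        return lst

    def validate(self) -> None:
        if self.n_cases <= 0 or self.n_controls <= 0 or self.n_amplicons <= 0:
            raise ValueError("counts must be positive")
        if any(m <= 0 for m in self.units_list()):
            raise ValueError("units per amplicon must be positive")
        for name, v in [
            ("history_fraction", self.history_fraction),
            ("history_attenuation", self.history_attenuation),
            ("within_amplicon_rho", self.within_amplicon_rho),
            ("missing_rate", self.missing_rate),
            ("control_history_fraction", self.control_history_fraction),
            ("population_control_fraction", self.population_control_fraction),
            ("high_missing_rate", self.high_missing_rate),
        ]:
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {v}")
        for k, v in self.missing_overrides.items():
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"missing override for {k} must lie in [0, 1]")
        universe = {c.canonical_name for c in cpg_universe(self)}
        for c in self.resolved_planted():
            if c.canonical_name not in universe:
                raise ValueError(f"planted CpG {c.canonical_name} not in the generated universe")

    def resolved_planted(self) -> frozenset[CpGUnitID]:
        if self.planted_cpgs is not None:
            return frozenset(self.planted_cpgs)
        return frozenset(default_planted(self))


def cpg_universe(config: SimulationConfig) -> list[CpGUnitID]:
    """Deterministic CpG-unit labels for the configured amplicons.

    Each amplicon's second unit merges two neighbouring CpGs (a dotted
    label, as EpiTYPER produces when CpGs share a mass fragment); the rest
    are single CpGs.
    """
    cpgs: list[CpGUnitID] = []
    for a, m in enumerate(config.units_list(), start=1):
        label = f"{a:02d}"
        idx = 1
        for u in range(m):
            if u == 1 and m >= 2:
                cpgs.append(CpGUnitID(label, (idx, idx + 1)))
                idx += 2
            else:
                cpgs.append(CpGUnitID(label, (idx,)))
                idx += 1
    return cpgs


def default_planted(config: SimulationConfig) -> list[CpGUnitID]:
    """Three planted markers spread over distinct amplicons (middle units)."""
    universe = cpg_universe(config)
    by_amp: dict[str, list[CpGUnitID]] = {}
    for c in universe:
        by_amp.setdefault(c.amplicon, []).append(c)
    amps = sorted(by_amp)
    picks = sorted({amps[1 % len(amps)], amps[len(amps) // 2], amps[-2 % len(amps)]})
    return [by_amp[a][len(by_amp[a]) // 2] for a in picks]


def _default_missing_rates(config: SimulationConfig, names: list[str]) -> dict[str, float]:
    rates = {n: config.missing_rate for n in names}
    if config.missing_overrides:
        for k, v in config.missing_overrides.items():
            if k not in rates:
                raise ValueError(f"missing override for unknown CpG {k}")
            rates[k] = v
    elif config.n_high_missing_units:
        # spread the high-missingness units over the panel ends
        step = max(1, len(names) // max(1, config.n_high_missing_units))
        for i in range(config.n_high_missing_units):
            rates[names[(i * step + step // 2) % len(names)]] = config.high_missing_rate
    return rates


def generate(config: SimulationConfig) -> MethylationDataset:
    """Draw one cohort from the latent factor model. Deterministic in ``seed``."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    cpgs = cpg_universe(config)
    names = [c.canonical_name for c in cpgs]
    planted = {c.canonical_name for c in config.resolved_planted()}
    n = config.n_cases + config.n_controls
    p = len(names)
    amp_labels = sorted({c.amplicon for c in cpgs})
    amp_index = {a: i for i, a in enumerate(amp_labels)}
    col_amp = np.array([amp_index[c.amplicon] for c in cpgs])

    # per-CpG baseline methylation on the logit scale
    lo, hi = config.baseline_range
    base = rng.uniform(logit(lo), logit(hi), size=p)

    rho = config.within_amplicon_rho
    factors = rng.standard_normal((n, len(amp_labels)))
    eps = rng.standard_normal((n, p))
    z = np.sqrt(rho) * factors[:, col_amp] + np.sqrt(1.0 - rho) * eps

    is_case = np.zeros(n, dtype=bool)
    is_case[: config.n_cases] = True
    history = np.zeros(n, dtype=bool)
    history[: config.n_cases] = rng.random(config.n_cases) < config.history_fraction

    shift = np.zeros((n, p))
    planted_cols = np.array([j for j, nm in enumerate(names) if nm in planted], dtype=int)
    if planted_cols.size:
        eff = np.where(history, config.effect_size * config.history_attenuation, config.effect_size)
        shift[np.ix_(is_case, planted_cols)] = eff[is_case][:, None]

    values = expit(base[None, :] + config.latent_scale * z + shift)

    rates = _default_missing_rates(config, names)
    rate_vec = np.array([rates[nm] for nm in names])
    mask = rng.random((n, p)) < rate_vec[None, :]
    values = values.astype(float)
    values[mask] = np.nan

    sample_ids = [f"case_{i + 1:03d}" for i in range(config.n_cases)] + [
        f"ctrl_{i + 1:03d}" for i in range(config.n_controls)
    ]
    vdf = pd.DataFrame(values, index=pd.Index(sample_ids, name="sample_id"), columns=names)

    n_pop = int(round(config.population_control_fraction * config.n_controls))
    subtype = np.array(["not_applicable"] * n, dtype=object)
    ctrl_subtypes = np.array(["urological"] * config.n_controls, dtype=object)
    pop_idx = rng.choice(config.n_controls, size=n_pop, replace=False)
    ctrl_subtypes[pop_idx] = "population"
    subtype[config.n_cases:] = ctrl_subtypes
    uro = subtype == "urological"
    history[uro] = rng.random(uro.sum()) < config.control_history_fraction

    grade = np.full(n, np.nan, dtype=object)
    stage = np.full(n, np.nan, dtype=object)
    grade[: config.n_cases] = np.where(rng.random(config.n_cases) < 0.2, "high", "low")
    stage[: config.n_cases] = rng.choice(["Ta", "T1", "T2"], size=config.n_cases, p=[0.6, 0.25, 0.15])

    meta = pd.DataFrame(
        {
            "group": np.where(is_case, "case", "control"),
            "control_subtype": subtype,
            "uca_history": history,
            "grade": grade,
            "stage": stage,
            "leukocytes_per_ul": np.round(rng.uniform(0.0, config.leukocyte_max, size=n), 1),
        },
        index=vdf.index,
    )
    return MethylationDataset(values=vdf, metadata=meta)


def make_imputation_fixture() -> MethylationDataset:
    """Tiny cohort where one CpG is an exact affine function of an amplicon mate.

    Within amplicon 01, ``01_CpG_2.3 = 0.5 * 01_CpG_1 + 0.1`` wherever both
    are observed, and it is missing exactly where ``01_CpG_1 = 0.6`` — so a
    within-amplicon linear-model imputation must recover 0.4 there exactly.
    A weakly related third unit and a second amplicon are included so donor
    ranking is non-trivial.
    """
    x = np.array([0.10, 0.20, 0.30, 0.40, 0.50, 0.60, 0.70, 0.15, 0.25, 0.35, 0.45, 0.55])
    y = 0.5 * x + 0.1
    y[x == 0.6] = np.nan
    # third unit: loosely related to x (correlation well below |1|)
    z = np.array([0.30, 0.10, 0.50, 0.20, 0.60, 0.40, 0.70, 0.25, 0.15, 0.55, 0.35, 0.65])
    w = np.array([0.82, 0.78, 0.80, 0.79, 0.81, 0.83, 0.77, 0.80, 0.79, 0.81, 0.78, 0.82])
    names = ["01_CpG_1", "01_CpG_2.3", "01_CpG_4", "02_CpG_1"]
    sample_ids = [f"s{i + 1:02d}" for i in range(len(x))]
    vdf = pd.DataFrame(
        np.column_stack([x, y, z, w]),
        index=pd.Index(sample_ids, name="sample_id"),
        columns=names,
    )
    groups = ["case"] * 6 + ["control"] * 6
    return MethylationDataset.from_values(vdf, groups)
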