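"""Core data structures for CpG-unit methylation cohorts.

A cohort is a samples x CpG-unit table of methylation fractions in [0, 1]
(missing values allowed) together with per-sample clinical metadata and a
mapping of each CpG unit to the PCR amplicon it was measured in.  A "CpG
unit" is one or more neighbouring CpG dinucleotides that fall on the same
mass fragment in EpiTYPER mass spectrometry and therefore yield a single
methylation value; its label joins the member CpG indices with dots
(e.g. ``78_CpG_2.3`` = CpGs 2 and 3 of amplicon 78).

All tabular I/O is tab-delimited UTF-8 with a header row, the first column
holding the sample identifier and missing values encoded as the literal
token ``NA``.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CpGUnitID",
    "SampleRecord",
    "MethylationDataset",
    "DatasetValidationError",
    "TargetNotationError",
    "parse_target_notation",
    "format_targets",
    "read_dataset",
    "write_dataset",
    "filter_leukocytes",
]

GROUPS = ("case", "control")
CONTROL_SUBTYPES = ("population", "urological", "not_applicable")
GRADES = ("low", "high")

#: Metadata columns with a defined meaning; extra columns are carried through
#: as opaque annotations.
METADATA_COLUMNS = (
    "group",
    "control_subtype",
    "uca_history",
    "grade",
    "stage",
    "leukocytes_per_ul",
)

_NAME_RE = re.compile(r"^([A-Za-z0-9]+)_(?:CpG_)?(\d+(?:\.\d+)*)$")


class DatasetValidationError(ValueError):
    """A cohort table violates a structural or value constraint."""


class TargetNotationError(ValueError):
    """Malformed compact target notation."""


def _normalize_amplicon(label: str) -> str:
    # the literature mixes "2_6" and "02_CpG_6" for the same unit; numeric
    # amplicon labels are zero-padded to two characters
    label = str(label)
    if label.isdigit():
        return label.zfill(2)
    return label


@dataclass(frozen=True, order=True)
class CpGUnitID:
    """Identifier of one measured CpG unit.

    Parameters
    ----------
    amplicon
        Amplicon label; numeric labels are normalized to two characters
        (``"2"`` and ``"02"`` are the same amplicon).
    units
        Strictly increasing, positive CpG indices within the amplicon that
        make up this unit.
    """

    amplicon: str
    units: tuple[int, ...]

    def __post_init__(self) -> None:
        object.__setattr__(self, "amplicon", _normalize_amplicon(self.amplicon))
        object.__setattr__(self, "units", tuple(int(u) for u in self.units))
        if not self.units:
            raise ValueError("CpG unit needs at least one CpG index")
        if any(u <= 0 for u in self.units):
            raise ValueError(f"CpG indices must be positive: {self.units}")
        if any(b <= a for a, b in zip(self.units, self.units[1:])):
            raise ValueError(f"CpG indices must be strictly increasing: {self.units}")

    @property
    def unit_label(self) -> str:
        return ".".join(str(u) for u in self.units)

    @property
    def canonical_name(self) -> str:
        return f"{self.amplicon}_CpG_{self.unit_label}"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.canonical_name

    @classmethod
    def parse(cls, text: str) -> "CpGUnitID":
        """Parse ``"02_CpG_6"`` (canonical) or ``"2_6"`` (compact)."""
        m = _NAME_RE.match(text.strip())
        if m is None:
            raise TargetNotationError(f"not a CpG unit name: {text!r}")
        return cls(m.group(1), tuple(int(u) for u in m.group(2).split(".")))


@dataclass(frozen=True)
class SampleRecord:
    """Clinical metadata for one urine specimen."""

    sample_id: str
    group: str
    control_subtype: str = "not_applicable"
    uca_history: bool = False
    grade: str | None = None
    stage: str | None = None
    leukocytes_per_ul: float | None = None

    def __post_init__(self) -> None:
        if self.group not in GROUPS:
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: group must be one of {GROUPS}, got {self.group!r}"
            )
        if self.control_subtype not in CONTROL_SUBTYPES:
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: unknown control subtype {self.control_subtype!r}"
            )
        if (self.group == "case") != (self.control_subtype == "not_applicable"):
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: control_subtype must be 'not_applicable' "
                f"iff the sample is a case"
            )
        if self.control_subtype == "population" and self.uca_history:
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: population controls have no tumor history"
            )
        if self.grade is not None and self.grade not in GRADES:
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: grade must be one of {GRADES}"
            )
        if self.leukocytes_per_ul is not None and self.leukocytes_per_ul < 0:
            raise DatasetValidationError(
                f"sample {self.sample_id!r}: negative leukocyte count"
            )


@dataclass
class MethylationDataset:
    """A methylation cohort: value table plus sample metadata.

    Attributes
    ----------
    values
        DataFrame indexed by sample id with one column per CpG unit
        (canonical names).  Entries are methylation fractions in [0, 1];
        ``NaN`` marks a missing measurement.
    metadata
        DataFrame indexed by the same sample ids (same order) with at least
        the columns in :data:`METADATA_COLUMNS`; additional columns are kept
        untouched.
    """

    values: pd.DataFrame
    metadata: pd.DataFrame

    def __post_init__(self) -> None:
        self.values = self.values.astype(float)
        if not self.values.index.is_unique:
            dup = self.values.index[self.values.index.duplicated()][0]
            raise DatasetValidationError(f"duplicate sample id {dup!r}")
        if not self.values.columns.is_unique:
            dup = self.values.columns[self.values.columns.duplicated()][0]
            raise DatasetValidationError(f"duplicate CpG column {dup!r}")
        if not self.values.index.equals(self.metadata.index):
            raise DatasetValidationError(
                "values and metadata must share the same sample ids in the same order"
            )
        missing_cols = [c for c in METADATA_COLUMNS if c not in self.metadata.columns]
        if missing_cols:
            raise DatasetValidationError(f"metadata lacks columns {missing_cols}")
        bad = (self.values < 0) | (self.values > 1)
        if bad.any().any():
            col = bad.any(axis=0).idxmax()
            row = bad[col].idxmax()
            raise DatasetValidationError(
                f"methylation value out of [0, 1] for sample {row!r}, CpG {col!r}: "
                f"{self.values.at[row, col]}"
            )
        # parse once to validate column names and cache the identifiers
        self._cpg_ids = tuple(CpGUnitID.parse(c) for c in self.values.columns)
        for rec in self.sample_records():
            pass  # SampleRecord.__post_init__ validates each row

    # -- accessors ---------------------------------------------------------

    @property
    def sample_ids(self) -> pd.Index:
        return self.values.index

    @property
    def cpg_names(self) -> list[str]:
        return list(self.values.columns)

    @property
    def cpg_ids(self) -> tuple[CpGUnitID, ...]:
        return self._cpg_ids

    @property
    def amplicon_map(self) -> dict[str, str]:
        """Canonical CpG name -> amplicon label."""
        return {c.canonical_name: c.amplicon for c in self._cpg_ids}

    @property
    def missing_mask(self) -> pd.DataFrame:
        return self.values.isna()

    @property
    def n_samples(self) -> int:
        return len(self.values)

    @property
    def n_cpgs(self) -> int:
        return self.values.shape[1]

    @property
    def case_mask(self) -> pd.Series:
        return self.metadata["group"] == "case"

    @property
    def y(self) -> np.ndarray:
        """Binary labels, 1 = case."""
        return self.case_mask.to_numpy().astype(int)

    def sample_records(self) -> Iterable[SampleRecord]:
        for sid, row in self.metadata.iterrows():
            yield SampleRecord(
                sample_id=str(sid),
                group=row["group"],
                control_subtype=row["control_subtype"],
                uca_history=bool(row["uca_history"]),
                grade=None if pd.isna(row["grade"]) else row["grade"],
                stage=None if pd.isna(row["stage"]) else row["stage"],
                leukocytes_per_ul=(
                    None if pd.isna(row["leukocytes_per_ul"]) else float(row["leukocytes_per_ul"])
                ),
            )

    # -- constructors / subsetting ----------------------------------------

    @classmethod
    def from_values(
        cls,
        values: pd.DataFrame,
        groups: Sequence[str],
        **metadata_overrides: Sequence,
    ) -> "MethylationDataset":
        """Build a dataset from a value table and case/control labels.

        Convenience constructor for simulations and tests: fills the
        remaining metadata columns with neutral defaults (urological
        controls, no history, no leukocyte counts).
        """
        groups = list(groups)
        if len(groups) != len(values):
            raise DatasetValidationError("one group label per sample required")
        meta = pd.DataFrame(index=values.index)
        meta["group"] = groups
        meta["control_subtype"] = [
            "not_applicable" if g == "case" else "urological" for g in groups
        ]
        meta["uca_history"] = False
        meta["grade"] = pd.Series(np.nan, index=values.index, dtype=object)
        meta["stage"] = pd.Series(np.nan, index=values.index, dtype=object)
        meta["leukocytes_per_ul"] = np.nan
        for key, col in metadata_overrides.items():
            meta[key] = list(col)
        return cls(values=values, metadata=meta)

    def select_samples(self, sample_ids: Sequence) -> "MethylationDataset":
        return MethylationDataset(
            values=self.values.loc[sample_ids].copy(),
            metadata=self.metadata.loc[sample_ids].copy(),
        )

    def select_cpgs(self, names: Sequence[str]) -> "MethylationDataset":
        return MethylationDataset(
            values=self.values.loc[:, list(names)].copy(),
            metadata=self.metadata.copy(),
        )

    def write(self, values_path, metadata_path) -> None:
        write_dataset(self, values_path, metadata_path)


# -- compact target notation ----------------------------------------------

_UNIT_RE = re.compile(r"^\d+(?:\.\d+)*$")


def parse_target_notation(text: str) -> set[CpGUnitID]:
    """Expand the compact published notation into CpG unit identifiers.

    Groups of units sharing an amplicon are written
    ``"<amplicon>_<unit> and <unit> and ..."`` and separated by whitespace,
    e.g. ``"2_6 and 7 35_5"`` -> {02_CpG_6, 02_CpG_7, 35_CpG_5}.  A bare
    unit after ``and`` inherits the preceding amplicon label.
    """
    tokens = text.split()
    out: set[CpGUnitID] = set()
    amplicon: str | None = None
    i = 0
    while i < len(tokens):
        tok = tokens[i]
        if tok == "and":
            i += 1
            if i >= len(tokens):
                raise TargetNotationError(f"dangling 'and' at token {i} in {text!r}")
            unit = tokens[i]
            if "_" in unit:
                # a full token after "and" starts a new group
                out.add(CpGUnitID.parse(unit))
                amplicon = CpGUnitID.parse(unit).amplicon
            else:
                if amplicon is None or not _UNIT_RE.match(unit):
                    raise TargetNotationError(
                        f"malformed continuation {unit!r} at token {i} in {text!r}"
                    )
                out.add(CpGUnitID(amplicon, tuple(int(u) for u in unit.split("."))))
        elif "_" in tok:
            cpg = CpGUnitID.parse(tok)
            amplicon = cpg.amplicon
            out.add(cpg)
        else:
            raise TargetNotationError(f"unexpected token {tok!r} at position {i} in {text!r}")
        i += 1
    return out


def format_targets(cpgs: Iterable[CpGUnitID]) -> str:
    """Inverse of :func:`parse_target_notation` (canonical ordering)."""
    by_amp: dict[str, list[CpGUnitID]] = {}
    for c in sorted(set(cpgs)):
        by_amp.setdefault(c.amplicon, []).append(c)
    groups = []
    for amp in sorted(by_amp):
        units = [c.unit_label for c in by_amp[amp]]
        groups.append(f"{amp}_{units[0]}" + "".join(f" and {u}" for u in units[1:]))
    return " ".join(groups)


# -- tabular I/O -----------------------------------------------------------

_READ_KWARGS = dict(sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)


def read_dataset(values_path, metadata_path) -> MethylationDataset:
    """Read the TSV pair (values table, metadata table) into a dataset.

    Both files are tab-delimited with a header row, the first column the
    sample id and ``NA`` the only missing token.  Value columns are named
    by canonical CpG unit names.
    """
    values = pd.read_csv(values_path, **_READ_KWARGS)
    try:
        values = values.astype(float)
    except ValueError as exc:
        raise DatasetValidationError(f"non-numeric methylation value: {exc}") from exc
    meta = pd.read_csv(metadata_path, **_READ_KWARGS)
    if "uca_history" in meta.columns:
        meta["uca_history"] = meta["uca_history"].map(
            {"True": True, "False": False, True: True, False: False}
        )
    if "leukocytes_per_ul" in meta.columns:
        meta["leukocytes_per_ul"] = meta["leukocytes_per_ul"].astype(float)
    missing = values.index.difference(meta.index)
    if len(missing):
        raise DatasetValidationError(
            f"sample {missing[0]!r} present in values but absent from metadata"
        )
    extra = meta.index.difference(values.index)
    if len(extra):
        raise DatasetValidationError(
            f"sample {extra[0]!r} present in metadata but absent from values"
        )
    meta = meta.loc[values.index]
    return MethylationDataset(values=values, metadata=meta)


def write_dataset(ds: MethylationDataset, values_path, metadata_path) -> None:
    ds.values.to_csv(values_path, sep="\t", na_rep="NA")
    ds.metadata.to_csv(metadata_path, sep="\t", na_rep="NA")


# -- sample-level exclusion -------------------------------------------------

def filter_leukocytes(ds: MethylationDataset, max_count: float = 500.0) -> MethylationDataset:
    """Drop specimens whose urinary leukocyte count exceeds ``max_count``/µL.

    High leukocyte counts dilute tumour-derived DNA with unmethylated
    leukocyte DNA and suppress the methylation signal.  The rule is a strict
    exclusion: samples with a count strictly greater than the bound are
    removed; samples without a recorded count are kept (absence of evidence
    is not exclusion).  Survivor order is preserved.
    """
    counts = ds.metadata["leukocytes_per_ul"]
    keep = ~(counts > max_count)  # NaN compares False, hence kept
    return ds.select_samples(ds.sample_ids[keep.to_numpy()])
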