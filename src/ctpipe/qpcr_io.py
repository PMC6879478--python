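"""Reading and writing Ct report files.

Per-sample Ct reports are tab-separated text files with a dot as decimal
separator.  Several vendor export dialects are supported (see
:data:`DIALECTS`); each dialect is a declarative :class:`FormatDialect`
describing how to locate the data block and which columns hold the feature
name, the Ct value and the quality flag.  A two-column treatment file maps
each sample file to one of exactly two treatment groups; the group of the
first listed sample is the calibrator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

__all__ = [
    "OK",
    "UNRELIABLE",
    "UNDETERMINED",
    "MISSING",
    "FeatureRecord",
    "CtDataset",
    "TreatmentMap",
    "FormatDialect",
    "DIALECTS",
    "CtParseError",
    "TreatmentFileError",
    "AssemblyError",
    "parse_ct_file",
    "parse_treatment_file",
    "assemble_dataset",
    "write_ct_table",
    "read_ct_table",
]

# Reliability categories.
OK = "OK"
UNRELIABLE = "Unreliable"
UNDETERMINED = "Undetermined"

#: Missing Ct values are carried as NaN.
MISSING = math.nan

#: Sentinels (case-insensitive) treated as a missing Ct on input.
DEFAULT_SENTINELS = ("undetermined", "no ct", "na", "")


class CtParseError(ValueError):
    """A Ct report file could not be parsed."""


class TreatmentFileError(ValueError):
    """The treatment file violates its two-column / two-group contract."""


class AssemblyError(ValueError):
    """Per-sample record lists cannot be assembled into one dataset."""


@dataclass(frozen=True)
class FeatureRecord:
    """One data row of a Ct report: feature name, Ct (NaN if missing), flag."""

    feature_name: str
    ct: float
    flag: str = ""
    position: str | None = None

    def __post_init__(self):
        if not self.feature_name:
            raise CtParseError("feature name must be non-empty")

    @property
    def is_missing(self) -> bool:
        return math.isnan(self.ct)


@dataclass(frozen=True)
class FormatDialect:
    """Declarative description of one tab-separated Ct report layout.

    ``header=True`` dialects locate the data block by scanning for the first
    row whose tab-split fields include one alias for every required column;
    everything above it is skipped.  ``header=False`` dialects (Plain) are
    positional: column 0 = feature, 1 = Ct, 2 = optional flag.
    """

    name: str
    header: bool
    feature_aliases: tuple[str, ...] = ()
    ct_aliases: tuple[str, ...] = ()
    flag_aliases: tuple[str, ...] = ()
    position_aliases: tuple[str, ...] = ()
    undetermined_sentinels: tuple[str, ...] = DEFAULT_SENTINELS

    def with_sentinels(self, sentinels) -> "FormatDialect":
        return replace(self, undetermined_sentinels=tuple(s.lower() for s in sentinels))


#: Built-in dialects.  SDS (v2.3/2.4 exports), EDS and Plain are exercised by
#: the test suite; OpenArray/LightCycler/CFX/BioMark are shipped as editable
#: templates with the conventional column names of those instruments.
DIALECTS: dict[str, FormatDialect] = {
    "Plain": FormatDialect(name="Plain", header=False),
    "SDS": FormatDialect(
        name="SDS",
        header=True,
        feature_aliases=("Detector", "Detector Name"),
        ct_aliases=("Ct", "Avg Ct"),
        flag_aliases=("Flag", "Flags"),
        position_aliases=("Well",),
    ),
    "EDS": FormatDialect(
        name="EDS",
        header=True,
        feature_aliases=("Target Name", "Target"),
        ct_aliases=("CT", "Ct", "Cq"),
        flag_aliases=("Flag", "Flags"),
        position_aliases=("Well",),
    ),
    "OpenArray": FormatDialect(
        name="OpenArray",
        header=True,
        feature_aliases=("Assay ID", "Assay Name", "Gene"),
        ct_aliases=("Ct", "Crt"),
        flag_aliases=("ThroughHole.Outlier", "Flag"),
        position_aliases=("ThroughHole.Address", "Well"),
    ),
    "LightCycler": FormatDialect(
        name="LightCycler",
        header=True,
        feature_aliases=("Name", "Gene Name"),
        ct_aliases=("Cp", "Ct"),
        flag_aliases=("Status", "Flag"),
        position_aliases=("Pos", "Position"),
    ),
    "CFX": FormatDialect(
        name="CFX",
        header=True,
        feature_aliases=("Target", "Content"),
        ct_aliases=("Cq", "Ct"),
        flag_aliases=("Call", "Flag"),
        position_aliases=("Well",),
    ),
    "BioMark": FormatDialect(
        name="BioMark",
        header=True,
        feature_aliases=("Name", "Assay"),
        ct_aliases=("Value", "Ct"),
        flag_aliases=("Call", "Quality"),
        position_aliases=("ID", "Chamber"),
    ),
}


def _parse_ct_token(token: str, dialect: FormatDialect, row_no: int, path) -> float:
    token = token.strip()
    if token.lower() in dialect.undetermined_sentinels:
        return MISSING
    try:
        return float(token)
    except ValueError:
        raise CtParseError(
            f"{path}: row {row_no}: Ct value {token!r} is neither numeric "
            f"(dot decimal separator) nor a recognised missing-value sentinel"
        ) from None


def parse_ct_file(path, dialect: FormatDialect | str = "Plain") -> list[FeatureRecord]:
    """Parse one per-sample Ct report into an ordered list of records.

    Records are returned in file row order.  Sentinel Ct values (e.g.
    "Undetermined") become NaN; anything else non-numeric is an error naming
    the offending row.
    """
    if isinstance(dialect, str):
        try:
            dialect = DIALECTS[dialect]
        except KeyError:
            raise CtParseError(f"unknown dialect {dialect!r}; known: {sorted(DIALECTS)}")
    try:
        with open(path, encoding="utf-8") as fh:
            lines = fh.read().splitlines()
    except OSError as exc:
        raise CtParseError(f"cannot read {path}: {exc}") from exc

    if dialect.header:
        cols = _locate_header(lines, dialect, path)
        start, fcol, ccol, gcol, pcol = cols
    else:
        start, fcol, ccol, gcol, pcol = 0, 0, 1, 2, None

    records: list[FeatureRecord] = []
    for row_no, line in enumerate(lines[start:], start=start + 1):
        if not line.strip():
            continue
        fields = line.split("\t")
        if len(fields) <= max(fcol, ccol):
            raise CtParseError(
                f"{path}: row {row_no}: expected at least {max(fcol, ccol) + 1} "
                f"tab-separated fields, found {len(fields)}"
            )
        name = fields[fcol].strip()
        if not name:
            raise CtParseError(f"{path}: row {row_no}: empty feature name")
        ct = _parse_ct_token(fields[ccol], dialect, row_no, path)
        flag = fields[gcol].strip() if gcol is not None and gcol < len(fields) else ""
        pos = fields[pcol].strip() if pcol is not None and pcol < len(fields) else None
        records.append(FeatureRecord(name, ct, flag, pos))
    if not records:
        raise CtParseError(f"{path}: no data rows found (dialect {dialect.name})")
    return records


def _locate_header(lines, dialect: FormatDialect, path):
    """Find the header row containing feature + Ct columns; return indices."""
    for i, line in enumerate(lines):
        fields = [f.strip() for f in line.split("\t")]
        lowered = [f.lower() for f in fields]

        def find(aliases):
            for a in aliases:
                if a.lower() in lowered:
                    return lowered.index(a.lower())
            return None

        fcol = find(dialect.feature_aliases)
        ccol = find(dialect.ct_aliases)
        if fcol is not None and ccol is not None:
            gcol = find(dialect.flag_aliases)
            pcol = find(dialect.position_aliases)
            return i + 1, fcol, ccol, gcol, pcol
    raise CtParseError(
        f"{path}: data block not found: no header row with columns "
        f"{dialect.feature_aliases} and {dialect.ct_aliases} (dialect {dialect.name})"
    )


@dataclass(frozen=True)
class TreatmentMap:
    """Ordered sample -> group assignment; exactly two groups.

    The calibrator group is the group of the first listed sample; the other
    group is the target.
    """

    entries: tuple[tuple[str, str], ...]

    def __post_init__(self):
        names = [s for s, _ in self.entries]
        if len(set(names)) != len(names):
            dupes = sorted({n for n in names if names.count(n) > 1})
            raise TreatmentFileError(f"duplicate sample names: {dupes}")
        groups = {g for _, g in self.entries}
        if len(groups) != 2:
            raise TreatmentFileError(
                f"exactly two treatment groups required, found {sorted(groups)}"
            )

    @property
    def sample_names(self) -> list[str]:
        return [s for s, _ in self.entries]

    @property
    def calibrator_group(self) -> str:
        return self.entries[0][1]

    @property
    def target_group(self) -> str:
        (other,) = {g for _, g in self.entries} - {self.calibrator_group}
        return other

    def group_of(self, sample: str) -> str:
        for s, g in self.entries:
            if s == sample:
                return g
        raise KeyError(sample)

    def samples_in(self, group: str) -> list[str]:
        return [s for s, g in self.entries if g == group]

    @property
    def calibrator_samples(self) -> list[str]:
        return self.samples_in(self.calibrator_group)

    @property
    def target_samples(self) -> list[str]:
        return self.samples_in(self.target_group)


def parse_treatment_file(path) -> TreatmentMap:
    """Parse the two-column treatment file (header SampleName/Treatment)."""
    with open(path, encoding="utf-8") as fh:
        lines = [ln for ln in fh.read().splitlines() if ln.strip()]
    if not lines:
        raise TreatmentFileError(f"{path}: empty treatment file")
    header = [f.strip() for f in lines[0].split("\t")]
    if [h.lower() for h in header] != ["samplename", "treatment"]:
        raise TreatmentFileError(
            f"{path}: header must be 'SampleName<TAB>Treatment', found {header}"
        )
    entries = []
    for row_no, line in enumerate(lines[1:], start=2):
        fields = [f.strip() for f in line.split("\t")]
        if len(fields) != 2 or not all(fields):
            raise TreatmentFileError(
                f"{path}: row {row_no}: expected exactly two non-empty "
                f"tab-separated fields, found {fields}"
            )
        entries.append((fields[0], fields[1]))
    return TreatmentMap(tuple(entries))


@dataclass
class CtDataset:
    """Features x samples container of Ct values, flags and categories.

    ``ct`` is a float matrix with NaN for missing values; ``flags`` and
    ``categories`` are string matrices of the same shape.  Feature names may
    repeat (replicated assays); sample names are unique and ordered as in the
    treatment file.
    """

    feature_names: list[str]
    sample_names: list[str]
    ct: np.ndarray
    flags: np.ndarray
    categories: np.ndarray

    def __post_init__(self):
        self.ct = np.asarray(self.ct, dtype=float)
        self.flags = np.asarray(self.flags, dtype=object)
        self.categories = np.asarray(self.categories, dtype=object)
        shape = (len(self.feature_names), len(self.sample_names))
        for m, what in ((self.ct, "ct"), (self.flags, "flags"), (self.categories, "categories")):
            if m.shape != shape:
                raise AssemblyError(f"{what} matrix shape {m.shape} != {shape}")
        if len(set(self.sample_names)) != len(self.sample_names):
            raise AssemblyError("sample names must be unique")

    @property
    def n_features(self) -> int:
        return len(self.feature_names)

    @property
    def n_samples(self) -> int:
        return len(self.sample_names)

    def copy(self) -> "CtDataset":
        return CtDataset(
            list(self.feature_names),
            list(self.sample_names),
            self.ct.copy(),
            self.flags.copy(),
            self.categories.copy(),
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.ct, index=self.feature_names, columns=self.sample_names)

    def sample_index(self, sample: str) -> int:
        return self.sample_names.index(sample)


def assemble_dataset(per_sample_records: dict[str, list[FeatureRecord]],
                     treatment: TreatmentMap) -> CtDataset:
    """Assemble per-sample record lists into one dataset.

    Sample columns follow treatment-file order.  All samples must share the
    same feature name sequence; mismatches are reported with the symmetric
    difference of the offending feature sets.
    """
    missing = [s for s in treatment.sample_names if s not in per_sample_records]
    if missing:
        raise AssemblyError(f"treatment file samples missing from inputs: {missing}")

    ordered = treatment.sample_names
    ref_names = [r.feature_name for r in per_sample_records[ordered[0]]]
    for s in ordered[1:]:
        names = [r.feature_name for r in per_sample_records[s]]
        if names != ref_names:
            diff = sorted(set(names) ^ set(ref_names))
            raise AssemblyError(
                f"feature lists disagree between {ordered[0]!r} and {s!r}; "
                f"symmetric difference: {diff or 'same set, different order'}"
            )

    n_feat, n_samp = len(ref_names), len(ordered)
    ct = np.full((n_feat, n_samp), MISSING)
    flags = np.full((n_feat, n_samp), "", dtype=object)
    for j, s in enumerate(ordered):
        for i, rec in enumerate(per_sample_records[s]):
            ct[i, j] = rec.ct
            flags[i, j] = rec.flag
    categories = np.where(np.isnan(ct), UNDETERMINED, OK).astype(object)
    return CtDataset(ref_names, list(ordered), ct, flags, categories)


def write_ct_table(ds: CtDataset, path) -> None:
    """Write the Ct matrix as TSV: features as rows, samples as columns, NA
    for missing, dot decimal separator."""
    ds.to_frame().to_csv(path, sep="\t", na_rep="NA")


def read_ct_table(path) -> pd.DataFrame:
    """Read back a table written by :func:`write_ct_table`."""
    return pd.read_csv(path, sep="\t", index_col=0, na_values=["NA"], keep_default_na=False)
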