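"""Reading quantification reports and assembling the protein master table.

The unit of input is a per-sample protein quantification report: a
tab-separated file with one row per identified protein carrying its accession
and a raw precursor-area intensity, as exported by an MS search /
quantification engine.  Reports are concatenated into a proteins x samples
``MasterTable`` in which a protein absent from a sample's report is *missing*
(NaN), never zero: label-free quantification reports no area for an
undetected protein, and the distinction matters downstream (presence
filtering, "only in control" fold-change sentinels).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

__all__ = [
    "SampleQuantReport",
    "MasterTable",
    "GroupDesign",
    "GeneSetCollection",
    "read_quant_report",
    "build_master_table",
    "read_group_design",
    "read_gene_sets",
    "read_master_table",
    "write_master_table",
]


@dataclass(frozen=True)
class SampleQuantReport:
    """Proteins detected in one sample, with raw intensities.

    ``records`` maps accession -> (description, raw_intensity).  Intensities
    are strictly positive; absence is encoded by omission.
    """

    sample_id: str
    records: dict[str, tuple[str, float]]

    def __post_init__(self) -> None:
        for acc, (_, x) in self.records.items():
            if not x > 0:
                raise ValueError(
                    f"report {self.sample_id!r}: non-positive intensity for {acc!r}"
                )


@dataclass
class MasterTable:
    """Proteins x samples intensity matrix with explicit missingness.

    ``data`` is a DataFrame indexed by accession with one column per sample;
    NaN marks a protein not detected in that sample.  ``normalized`` records
    whether intensities have been rescaled to parts-per-million of the
    per-sample total (each column then sums to 1e6 over detected entries).
    """

    data: pd.DataFrame
    normalized: bool = False
    descriptions: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].tolist()
            raise ValueError(f"duplicate accessions: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].tolist()
            raise ValueError(f"duplicate sample ids: {dups}")
        if (self.data.to_numpy(dtype=float) < 0).any():
            raise ValueError("negative intensities in master table")

    @property
    def accessions(self) -> list[str]:
        return self.data.index.tolist()

    @property
    def sample_ids(self) -> list[str]:
        return self.data.columns.tolist()

    def subset_rows(self, accessions) -> "MasterTable":
        return replace(self, data=self.data.loc[list(accessions)])

    def detected(self) -> pd.DataFrame:
        """Boolean detection mask (True where a value was measured)."""
        return self.data.notna()


@dataclass(frozen=True)
class GroupDesign:
    """Named, disjoint sample groups (e.g. WT2, INS2, WT4, INS4)."""

    groups: dict[str, tuple[str, ...]]

    def __post_init__(self) -> None:
        if not self.groups:
            raise ValueError("design has no groups")
        seen: dict[str, str] = {}
        for name, samples in self.groups.items():
            if not samples:
                raise ValueError(f"group {name!r} is empty")
            for s in samples:
                if s in seen:
                    raise ValueError(
                        f"sample {s!r} assigned to both {seen[s]!r} and {name!r}"
                    )
                seen[s] = name

    def samples(self, group: str) -> tuple[str, ...]:
        try:
            return self.groups[group]
        except KeyError:
            raise KeyError(f"unknown group {group!r}") from None

    def all_samples(self) -> list[str]:
        return [s for g in self.groups.values() for s in g]

    def validate_against(self, table: MasterTable) -> None:
        missing = set(self.all_samples()) - set(table.sample_ids)
        if missing:
            raise ValueError(f"design samples absent from table: {sorted(missing)}")


@dataclass(frozen=True)
class GeneSetCollection:
    """Named gene sets: set name -> (description, frozenset of identifiers)."""

    sets: dict[str, tuple[str, frozenset[str]]]

    def __post_init__(self) -> None:
        for name, (_, members) in self.sets.items():
            if not members:
                raise ValueError(f"gene set {name!r} has no members")

    def names(self) -> list[str]:
        return list(self.sets)

    def members(self, name: str) -> frozenset[str]:
        return self.sets[name][1]


def read_quant_report(
    path,
    sample_id: str,
    accession_col: str = "accession",
    intensity_col: str = "intensity",
    description_col: str | None = "description",
) -> SampleQuantReport:
    """Parse one tab-separated per-sample quantification report.

    Zero or empty intensities are treated as "not detected" and dropped (with
    a log message); a duplicated accession or an unparsable intensity is a
    hard error.
    """
    df = pd.read_csv(path, sep="\t", dtype=str)
    for col in (accession_col, intensity_col):
        if col not in df.columns:
            raise ValueError(f"{path}: missing column {col!r}")
    dup = df[accession_col][df[accession_col].duplicated()]
    if not dup.empty:
        raise ValueError(f"{path}: duplicate accession {dup.iloc[0]!r}")
    records: dict[str, tuple[str, float]] = {}
    for i, row in df.iterrows():
        line_no = i + 2  # header is line 1
        acc = row[accession_col]
        raw = row[intensity_col]
        if raw is None or (isinstance(raw, float) and np.isnan(raw)) or str(raw).strip() == "":
            logger.info("%s line %d: %s absent (empty intensity)", sample_id, line_no, acc)
            continue
        try:
            x = float(raw)
        except ValueError:
            raise ValueError(
                f"{path} line {line_no}: unparsable intensity {raw!r}"
            ) from None
        if x == 0:
            logger.info("%s line %d: %s absent (zero intensity)", sample_id, line_no, acc)
            continue
        desc = ""
        if description_col and description_col in df.columns:
            d = row[description_col]
            desc = "" if (isinstance(d, float) and np.isnan(d)) else str(d)
        records[acc] = (desc, x)
    return SampleQuantReport(sample_id=sample_id, records=records)


def build_master_table(reports: list[SampleQuantReport]) -> MasterTable:
    """Concatenate per-sample reports into a raw master table.

    Rows are the union of accessions over all reports; a protein absent from
    a report is missing (NaN) in that sample's column.
    """
    if len(reports) < 2:
        raise ValueError("need at least 2 reports to build a master table")
    ids = [r.sample_id for r in reports]
    if len(set(ids)) != len(ids):
        raise ValueError(f"duplicate sample ids among reports: {ids}")
    accessions: list[str] = []
    seen: set[str] = set()
    descriptions: dict[str, str] = {}
    for r in reports:
        for acc, (desc, _) in r.records.items():
            if acc not in seen:
                seen.add(acc)
                accessions.append(acc)
            if desc and acc not in descriptions:
                descriptions[acc] = desc
    accessions = sorted(accessions)
    data = pd.DataFrame(np.nan, index=accessions, columns=ids, dtype=float)
    for r in reports:
        for acc, (_, x) in r.records.items():
            data.at[acc, r.sample_id] = x
    return MasterTable(data=data, normalized=False, descriptions=descriptions)


def read_group_design(path) -> GroupDesign:
    """Read a two-column TSV (sample_id, group) into a GroupDesign."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    if list(df.columns[:2]) != ["sample_id", "group"]:
        raise ValueError(f"{path}: expected columns sample_id, group")
    groups: dict[str, list[str]] = {}
    for _, row in df.iterrows():
        groups.setdefault(row["group"], []).append(row["sample_id"])
    return GroupDesign(groups={g: tuple(s) for g, s in groups.items()})


def read_gene_sets(path, upper_case: bool = True) -> GeneSetCollection:
    """Read a GMT file: one set per line, tab-separated name, description,
    then member identifiers."""
    sets: dict[str, tuple[str, frozenset[str]]] = {}
    with open(path) as fh:
        for line_no, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 3:
                raise ValueError(f"{path} line {line_no}: expected >=3 fields")
            name, desc, *members = fields
            if name in sets:
                raise ValueError(f"{path} line {line_no}: duplicate set name {name!r}")
            if upper_case:
                members = [m.upper() for m in members]
            sets[name] = (desc, frozenset(m for m in members if m))
    return GeneSetCollection(sets=sets)


def write_master_table(table: MasterTable, path) -> None:
    """Write the TSV dialect: first column 'accession', one column per sample,
    empty cell for missing.  Round-trips bit-exactly via repr-precision floats."""
    df = table.data.copy()
    df.index.name = "accession"
    with open(path, "w") as fh:
        fh.write("accession\t" + "\t".join(map(str, df.columns)) + "\n")
        for acc, row in df.iterrows():
            cells = ["" if np.isnan(v) else repr(float(v)) for v in row.to_numpy()]
            fh.write(str(acc) + "\t" + "\t".join(cells) + "\n")


def read_master_table(path, normalized: bool = False) -> MasterTable:
    """Read the TSV dialect written by :func:`write_master_table`."""
    df = pd.read_csv(path, sep="\t", index_col="accession")
    df.index = df.index.astype(str)
    df.index.name = None
    df = df.astype(float)
    return MasterTable(data=df, normalized=normalized)
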