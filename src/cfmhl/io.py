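"""Data formats for MHB panels, haplotype tables, clinical tables and metadata.

All formats are plain tab-separated text:

* **MHB panel** — extended BED: ``chrom  start  end  block_id  cpg_positions``
  with 0-based half-open intervals and a comma-separated list of CpG
  cytosine coordinates (forward strand) inside the interval.
* **Haplotype table** — one file per sample, columns
  ``block_id  pattern  count[  offset]``; a pattern is a string over
  ``{M, U}`` giving the per-CpG methylation calls of one sequenced molecule,
  ``offset`` anchors a partial pattern at its first CpG index (default 0).
* **Clinical table** — samples x tests with a header row of test names and
  an optional ``#units`` comment line; empty cells are missing values and
  are never imputed at read time.
* **Sample metadata** — columns ``sample_id  case_id  group  day`` with
  group one of ``HEALTHY``/``MAP``/``SAP``.
"""

from __future__ import annotations

import io as _stdio
from dataclasses import dataclass, field
from enum import Enum
from pathlib import Path
from typing import Iterable, Mapping, Sequence, Union

import numpy as np
import pandas as pd

PathLike = Union[str, Path]

PATTERN_ALPHABET = frozenset("MU")


class Group(str, Enum):
    """Cohort stratum: healthy control, mild AP, or severe AP (per RAC)."""

    HEALTHY = "HEALTHY"
    MAP = "MAP"
    SAP = "SAP"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


class FormatError(ValueError):
    """A file violated the format contract (parse-level problem)."""


class ValidationError(ValueError):
    """Parsed values violated a domain invariant."""


@dataclass(frozen=True)
class MhbRegion:
    """A methylation haplotype block: interval plus ordered CpG coordinates.

    Coordinates are 0-based half-open (BED convention); ``cpg_positions``
    are the genomic coordinates of the CpG cytosines on the forward strand,
    strictly increasing and contained in ``[start, end)``.  The number of
    CpGs is the maximal haplotype length observable in the block.
    """

    block_id: str
    chrom: str
    start: int
    end: int
    cpg_positions: tuple[int, ...]

    def __post_init__(self) -> None:
        if not self.block_id:
            raise ValidationError("block_id must be non-empty")
        if self.start >= self.end:
            raise ValidationError(
                f"block {self.block_id}: start {self.start} must be < end {self.end}"
            )
        pos = self.cpg_positions
        if len(pos) < 2:
            raise ValidationError(f"block {self.block_id}: needs >= 2 CpG positions")
        if any(b <= a for a, b in zip(pos, pos[1:])):
            raise ValidationError(f"block {self.block_id}: CpG positions must strictly increase")
        if pos[0] < self.start or pos[-1] >= self.end:
            raise ValidationError(
                f"block {self.block_id}: CpG positions must lie in [{self.start}, {self.end})"
            )

    @property
    def n_cpgs(self) -> int:
        return len(self.cpg_positions)


@dataclass(frozen=True, slots=True)
class HaplotypeRecord:
    """One observed methylation haplotype: pattern over {M, U} with a read count.

    ``offset`` is the 0-based index of the pattern's first CpG within its
    block, kept for traceability; the metrics enumerate substrings and do
    not use it.
    """

    block_id: str
    pattern: str
    count: int
    offset: int = 0

    def __post_init__(self) -> None:
        if not self.pattern or set(self.pattern) - PATTERN_ALPHABET:
            raise ValidationError(
                f"block {self.block_id}: pattern {self.pattern!r} must be a non-empty "
                "string over {M, U}"
            )
        if self.count < 1:
            raise ValidationError(f"block {self.block_id}: count must be >= 1, got {self.count}")
        if self.offset < 0:
            raise ValidationError(f"block {self.block_id}: offset must be >= 0")


@dataclass(frozen=True)
class SampleMeta:
    """Sample-level metadata: which patient, which stratum, which draw day."""

    sample_id: str
    case_id: str
    group: Group
    day: int = 0


@dataclass
class ClinicalTable:
    """Samples x clinical tests with explicit missingness.

    ``values`` is a float matrix with NaN as the (only) missing marker;
    sentinel numbers are never used.  ``units`` maps every test name to a
    unit string (possibly empty).
    """

    sample_ids: list[str]
    test_names: list[str]
    values: np.ndarray
    units: dict[str, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != (len(self.sample_ids), len(self.test_names)):
            raise ValidationError(
                f"values shape {self.values.shape} does not match "
                f"{len(self.sample_ids)} samples x {len(self.test_names)} tests"
            )
        for name in self.test_names:
            self.units.setdefault(name, "")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.values, index=self.sample_ids, columns=self.test_names)

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, units: Mapping[str, str] | None = None) -> "ClinicalTable":
        return cls(
            sample_ids=[str(i) for i in frame.index],
            test_names=[str(c) for c in frame.columns],
            values=frame.to_numpy(dtype=float),
            units=dict(units or {}),
        )

    @property
    def n_missing(self) -> int:
        return int(np.isnan(self.values).sum())


# ---------------------------------------------------------------------------
# MHB panel
# ---------------------------------------------------------------------------

def read_mhb_panel(path: PathLike) -> list[MhbRegion]:
    """Read an extended-BED MHB panel, sorted by (chrom, start).

    Raises :class:`FormatError` naming the offending line on malformed rows
    and :class:`ValidationError` on duplicate block ids or invariant
    violations.
    """
    regions: list[MhbRegion] = []
    seen: set[str] = set()
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) != 5:
                raise FormatError(f"{path}: line {lineno}: expected 5 tab-separated fields")
            chrom, start_s, end_s, block_id, cpg_s = fields
            try:
                start, end = int(start_s), int(end_s)
                cpgs = tuple(int(p) for p in cpg_s.split(","))
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if block_id in seen:
                raise ValidationError(f"{path}: line {lineno}: duplicate block_id {block_id!r}")
            seen.add(block_id)
            regions.append(MhbRegion(block_id, chrom, start, end, cpgs))
    regions.sort(key=lambda r: (r.chrom, r.start))
    return regions


def write_mhb_panel(regions: Iterable[MhbRegion], path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for r in sorted(regions, key=lambda r: (r.chrom, r.start)):
            cpgs = ",".join(str(p) for p in r.cpg_positions)
            fh.write(f"{r.chrom}\t{r.start}\t{r.end}\t{r.block_id}\t{cpgs}\n")


# ---------------------------------------------------------------------------
# Haplotype tables
# ---------------------------------------------------------------------------

def read_haplotype_table(path: PathLike) -> dict[str, list[HaplotypeRecord]]:
    """Read one sample's haplotype table, grouped by block id.

    Repeated (block, pattern, offset) rows have their counts aggregated.
    """
    # (block, pattern, offset) -> count
    counts: dict[tuple[str, str, int], int] = {}
    order: list[tuple[str, str, int]] = []
    with open(path, "rt", encoding="utf-8") as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith("#"):
                continue
            fields = line.split("\t")
            if len(fields) not in (3, 4):
                raise FormatError(f"{path}: line {lineno}: expected 3 or 4 fields")
            block_id, pattern = fields[0], fields[1]
            if set(pattern) - PATTERN_ALPHABET or not pattern:
                raise FormatError(
                    f"{path}: line {lineno}: pattern {pattern!r} has symbols outside {{M,U}}"
                )
            try:
                count = int(fields[2])
                offset = int(fields[3]) if len(fields) == 4 else 0
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if count <= 0:
                raise ValidationError(f"{path}: line {lineno}: count must be positive")
            key = (block_id, pattern, offset)
            if key not in counts:
                counts[key] = 0
                order.append(key)
            counts[key] += count
    table: dict[str, list[HaplotypeRecord]] = {}
    for block_id, pattern, offset in order:
        table.setdefault(block_id, []).append(
            HaplotypeRecord(block_id, pattern, counts[(block_id, pattern, offset)], offset)
        )
    return table


def write_haplotype_table(table: Mapping[str, Sequence[HaplotypeRecord]], path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        for block_id in table:
            for rec in table[block_id]:
                fh.write(f"{rec.block_id}\t{rec.pattern}\t{rec.count}\t{rec.offset}\n")


# ---------------------------------------------------------------------------
# Clinical table
# ---------------------------------------------------------------------------

def read_clinical_table(path: PathLike) -> ClinicalTable:
    """Read a samples x tests TSV; empty cells are missing, never imputed."""
    with open(path, "rt", encoding="utf-8") as fh:
        text = fh.read()
    lines = text.splitlines()
    units: dict[str, str] = {}
    data_lines = []
    header: list[str] | None = None
    for line in lines:
        if line.startswith("#units\t"):
            unit_fields = line.split("\t")[1:]
            if header is None:
                raise FormatError(f"{path}: #units line before header")
            units = dict(zip(header[1:], unit_fields))
            continue
        if line.startswith("#"):
            continue
        if header is None:
            header = line.split("\t")
            continue
        data_lines.append(line)
    if header is None:
        raise FormatError(f"{path}: no header row")
    test_names = header[1:]
    sample_ids: list[str] = []
    rows: list[list[float]] = []
    for lineno, line in enumerate(data_lines, start=1):
        fields = line.split("\t")
        if len(fields) != len(header):
            raise FormatError(f"{path}: data row {lineno}: expected {len(header)} fields")
        sample_ids.append(fields[0])
        row = []
        for name, cell in zip(test_names, fields[1:]):
            if cell == "":
                row.append(np.nan)
            else:
                try:
                    row.append(float(cell))
                except ValueError as exc:
                    raise FormatError(
                        f"{path}: data row {lineno}, test {name!r}: non-numeric cell {cell!r}"
                    ) from exc
        rows.append(row)
    values = np.array(rows, dtype=float).reshape(len(sample_ids), len(test_names))
    return ClinicalTable(sample_ids, list(test_names), values, units)


def _format_value(x: float) -> str:
    if np.isnan(x):
        return ""
    return repr(float(x))


def write_clinical_table(table: ClinicalTable, path: PathLike) -> None:
    buf = _stdio.StringIO()
    buf.write("sample_id\t" + "\t".join(table.test_names) + "\n")
    buf.write("#units\t" + "\t".join(table.units.get(t, "") for t in table.test_names) + "\n")
    for sid, row in zip(table.sample_ids, table.values):
        buf.write(sid + "\t" + "\t".join(_format_value(v) for v in row) + "\n")
    Path(path).write_text(buf.getvalue(), encoding="utf-8")


# ---------------------------------------------------------------------------
# Sample metadata
# ---------------------------------------------------------------------------

def read_sample_meta(path: PathLike) -> list[SampleMeta]:
    """Read sample metadata; enforces unique sample ids and one group per case."""
    metas: list[SampleMeta] = []
    seen_samples: set[str] = set()
    case_group: dict[str, Group] = {}
    with open(path, "rt", encoding="utf-8") as fh:
        header = fh.readline().rstrip("\n").split("\t")
        expected = ["sample_id", "case_id", "group", "day"]
        if header != expected:
            raise FormatError(f"{path}: header must be {expected}, got {header}")
        for lineno, line in enumerate(fh, start=2):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) != 4:
                raise FormatError(f"{path}: line {lineno}: expected 4 fields")
            sample_id, case_id, group_s, day_s = fields
            try:
                group = Group(group_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: unknown group {group_s!r}") from exc
            try:
                day = int(day_s)
            except ValueError as exc:
                raise FormatError(f"{path}: line {lineno}: {exc}") from exc
            if sample_id in seen_samples:
                raise ValidationError(f"{path}: line {lineno}: duplicate sample_id {sample_id!r}")
            seen_samples.add(sample_id)
            if case_id in case_group and case_group[case_id] is not group:
                raise ValidationError(
                    f"{path}: line {lineno}: case {case_id!r} assigned to multiple groups"
                )
            case_group[case_id] = group
            metas.append(SampleMeta(sample_id, case_id, group, day))
    return metas


def write_sample_meta(metas: Iterable[SampleMeta], path: PathLike) -> None:
    with open(path, "wt", encoding="utf-8") as fh:
        fh.write("sample_id\tcase_id\tgroup\tday\n")
        for m in metas:
            fh.write(f"{m.sample_id}\t{m.case_id}\t{m.group.value}\t{m.day}\n")
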