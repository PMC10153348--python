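"""Synergy-screen table model: records, label binarization, tissue partition.

A screen row ties a drug pair to a cell line with two single-drug sensitivity
scores (relative inhibition) and a Loewe synergy score. Loewe scores live on a
[-100, 75] scale (antagonism negative); the classification target is
``loewe_score > 5``. Tissues contributing fewer than 4,000 rows are "rare" and
form the few-shot evaluation targets; the rest are "common".
"""

from __future__ import annotations

import csv
import logging
import math
from collections import Counter
from dataclasses import dataclass, field

log = logging.getLogger("synergyshot")

LOEWE_MIN = -100.0
LOEWE_MAX = 75.0
LOEWE_THRESHOLD = 5.0
RARE_TISSUE_THRESHOLD = 4000

REQUIRED_COLUMNS = (
    "drug1",
    "drug2",
    "cell_line",
    "tissue",
    "sensitivity1",
    "sensitivity2",
    "loewe_score",
)


class SchemaError(ValueError):
    """Raised when a synergy table is missing required columns."""


class RowError(ValueError):
    """Raised when a data row cannot be parsed; carries the row index."""

    def __init__(self, row_index: int, message: str):
        super().__init__(f"row {row_index}: {message}")
        self.row_index = row_index


@dataclass
class SynergyRecord:
    """One screened drug pair in one cell line."""

    drug1_name: str
    drug2_name: str
    cell_line_name: str
    tissue_name: str
    sensitivity1: float
    sensitivity2: float
    loewe_score: float
    raw_text: dict[str, str] | None = None

    def validate(self, strict_range: bool = False) -> None:
        for f in ("drug1_name", "drug2_name", "cell_line_name", "tissue_name"):
            if not getattr(self, f):
                raise ValueError(f"{f} must be non-empty")
        if not (LOEWE_MIN <= self.loewe_score <= LOEWE_MAX):
            msg = (
                f"loewe_score {self.loewe_score} outside [{LOEWE_MIN}, {LOEWE_MAX}] "
                f"for pair ({self.drug1_name}, {self.drug2_name})"
            )
            if strict_range:
                raise ValueError(msg)
            log.warning(msg)


@dataclass
class LabeledExample:
    """A record plus its binary synergy label (1 iff loewe_score > threshold)."""

    record: SynergyRecord
    label: int
    prompt: str | None = None


@dataclass
class TissuePartition:
    common: set[str]
    rare: set[str]
    threshold: int = RARE_TISSUE_THRESHOLD


def binarize(loewe_score: float, threshold: float = LOEWE_THRESHOLD) -> int:
    """Binary synergy label: 1 iff the Loewe score strictly exceeds the threshold."""
    if not math.isfinite(loewe_score):
        raise ValueError(f"loewe_score must be finite, got {loewe_score}")
    return int(loewe_score > threshold)


def label_records(
    records: list[SynergyRecord], threshold: float = LOEWE_THRESHOLD
) -> list[LabeledExample]:
    return [LabeledExample(r, binarize(r.loewe_score, threshold)) for r in records]


def partition_tissues(
    records: list[SynergyRecord], threshold: int = RARE_TISSUE_THRESHOLD
) -> TissuePartition:
    """Split tissues into common (count >= threshold) and rare (count < threshold)."""
    if threshold <= 0:
        raise ValueError(f"threshold must be positive, got {threshold}")
    if not records:
        raise ValueError("partition_tissues requires a non-empty record list")
    counts = Counter(r.tissue_name for r in records)
    rare = {t for t, n in counts.items() if n < threshold}
    common = set(counts) - rare
    return TissuePartition(common=common, rare=rare, threshold=threshold)


DEFAULT_COLUMN_MAP = {c: c for c in REQUIRED_COLUMNS}

_FIELD_BY_COLUMN = {
    "drug1": "drug1_name",
    "drug2": "drug2_name",
    "cell_line": "cell_line_name",
    "tissue": "tissue_name",
}


def read_synergy_table(
    path,
    delimiter: str = ",",
    column_map: dict[str, str] | None = None,
    strict_range: bool = False,
) -> list[SynergyRecord]:
    """Read a delimited synergy table into records, preserving row order.

    ``column_map`` maps logical column names (``drug1`` ... ``loewe_score``)
    to the file's actual header names, so differently-labelled exports load
    without code changes. Original cell strings are kept in ``raw_text`` so a
    write/read round trip is byte-faithful.
    """
    cmap = dict(DEFAULT_COLUMN_MAP)
    if column_map:
        cmap.update(column_map)
    records: list[SynergyRecord] = []
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        if reader.fieldnames is None:
            return []
        header = set(reader.fieldnames)
        for logical in REQUIRED_COLUMNS:
            if cmap[logical] not in header:
                raise SchemaError(
                    f"missing required column {cmap[logical]!r} (logical {logical!r}); "
                    f"found {sorted(header)}"
                )
        for i, row in enumerate(reader):
            raw = {logical: row[cmap[logical]] for logical in REQUIRED_COLUMNS}
            try:
                numbers = {
                    c: float(raw[c]) for c in ("sensitivity1", "sensitivity2", "loewe_score")
                }
            except (TypeError, ValueError) as e:
                raise RowError(i, f"unparseable numeric cell ({e})") from e
            rec = SynergyRecord(
                drug1_name=raw["drug1"],
                drug2_name=raw["drug2"],
                cell_line_name=raw["cell_line"],
                tissue_name=raw["tissue"],
                sensitivity1=numbers["sensitivity1"],
                sensitivity2=numbers["sensitivity2"],
                loewe_score=numbers["loewe_score"],
                raw_text=raw,
            )
            rec.validate(strict_range=strict_range)
            records.append(rec)
    return records


def write_synergy_table(records: list[SynergyRecord], path, delimiter: str = ",") -> None:
    """Write records in the canonical column order, preferring raw_text strings."""
    with open(path, "w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh, delimiter=delimiter)
        writer.writerow(REQUIRED_COLUMNS)
        for r in records:
            raw = r.raw_text or {}
            writer.writerow(
                [
                    raw.get("drug1", r.drug1_name),
                    raw.get("drug2", r.drug2_name),
                    raw.get("cell_line", r.cell_line_name),
                    raw.get("tissue", r.tissue_name),
                    raw.get("sensitivity1", repr(r.sensitivity1)),
                    raw.get("sensitivity2", repr(r.sensitivity2)),
                    raw.get("loewe_score", repr(r.loewe_score)),
                ]
            )


def deduplicate(records: list[SynergyRecord]) -> list[SynergyRecord]:
    """Optional filter dropping replicate (drug1, drug2, cell_line) rows.

    Replicate screens exist in real synergy databases and are kept by default;
    this keeps the first occurrence and logs how many rows were dropped.
    """
    seen: set[tuple[str, str, str]] = set()
    out = []
    for r in records:
        key = (r.drug1_name, r.drug2_name, r.cell_line_name)
        if key not in seen:
            seen.add(key)
            out.append(r)
    if len(out) != len(records):
        log.info("deduplicate: dropped %d replicate rows", len(records) - len(out))
    return out


def canonicalize_pair_order(record: SynergyRecord) -> SynergyRecord:
    """Optional symmetrization: sort the pair lexicographically, swapping sensitivities."""
    if record.drug1_name <= record.drug2_name:
        return record
    raw = None
    if record.raw_text:
        raw = dict(record.raw_text)
        raw["drug1"], raw["drug2"] = raw["drug2"], raw["drug1"]
        raw["sensitivity1"], raw["sensitivity2"] = raw["sensitivity2"], raw["sensitivity1"]
    return SynergyRecord(
        drug1_name=record.drug2_name,
        drug2_name=record.drug1_name,
        cell_line_name=record.cell_line_name,
        tissue_name=record.tissue_name,
        sensitivity1=record.sensitivity2,
        sensitivity2=record.sensitivity1,
        loewe_score=record.loewe_score,
        raw_text=raw,
    )
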