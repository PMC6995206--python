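"""Diagnosis record parsing, ICD-10 code handling and incidence matrices.

Long-format diagnosis records (one row per patient/code event) are read from
CSV, normalized to the three-character ICD-10 level (``G43.1`` -> ``G43``)
and pivoted into a binary patient x code incidence matrix per cohort — the
substrate for all co-occurrence statistics.  Codes are additionally mapped
to WHO-style ICD-10 blocks (contiguous code ranges such as ``H53-H54``,
visual disturbances and blindness) for block-level prevalence comparisons.
"""

from __future__ import annotations

import csv
import logging
import re
from dataclasses import dataclass, field
from datetime import date as _date
from importlib import resources
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "CASE",
    "CONTROL",
    "DiagnosisRecord",
    "CohortMatrix",
    "BlockMap",
    "RecordParseError",
    "read_records",
    "truncate_code",
    "build_matrix",
    "map_block",
]

logger = logging.getLogger(__name__)

CASE = "case"
CONTROL = "control"

#: letter + two digits, optionally "." (or nothing) + 1-2 alphanumerics.
#: Accepts both dotted ("G43.1") and undotted ("G431") sub-codes.
ICD10_PATTERN = re.compile(r"^[A-Z][0-9]{2}(?:\.?[A-Z0-9]{1,2})?$", re.IGNORECASE)

UNMAPPED_BLOCK = "UNMAPPED"


class RecordParseError(ValueError):
    """Raised for unusable record files (missing columns, excess bad rows)."""


@dataclass(frozen=True)
class DiagnosisRecord:
    """One diagnosis event: a patient received an ICD-10 code."""

    patient_id: str
    cohort: str
    code: str
    date: _date | None = None

    def __post_init__(self) -> None:
        if not ICD10_PATTERN.match(self.code):
            raise ValueError(f"malformed ICD-10 code: {self.code!r}")
        if self.cohort not in (CASE, CONTROL):
            raise ValueError(f"cohort must be {CASE!r} or {CONTROL!r}, got {self.cohort!r}")


@dataclass
class CohortMatrix:
    """Binary patient x three-character-code incidence matrix for one cohort.

    Rows follow the enrolment roster (patients with no surviving records
    remain as all-zero rows so that prevalence denominators equal cohort
    size); columns are lexicographically sorted three-character codes.
    """

    cohort: str
    patient_ids: list[str]
    codes: list[str]
    incidence: np.ndarray  # (n, D) uint8

    @property
    def n(self) -> int:
        return len(self.patient_ids)

    def __post_init__(self) -> None:
        if self.incidence.shape != (len(self.patient_ids), len(self.codes)):
            raise ValueError("incidence shape does not match roster/codes")
        if len(set(self.patient_ids)) != len(self.patient_ids):
            raise ValueError("duplicate patient ids")
        if len(set(self.codes)) != len(self.codes):
            raise ValueError("duplicate codes")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.incidence, index=self.patient_ids, columns=self.codes)

    def column_counts(self) -> pd.Series:
        """Distinct patients carrying each code."""
        return pd.Series(self.incidence.sum(axis=0), index=self.codes, name="count")


@dataclass
class BlockMap:
    """Lookup from a three-character code to its ICD-10 block.

    Blocks are contiguous code ranges within one chapter letter
    (e.g. ``F30-F39`` Mood [affective] disorders).  Lookup is total:
    codes outside every declared range map to the sentinel ``UNMAPPED``.
    """

    table: pd.DataFrame = field(repr=False)  # code_start, code_end, block_id, block_name

    def __post_init__(self) -> None:
        required = {"code_start", "code_end", "block_id", "block_name"}
        if not required.issubset(self.table.columns):
            raise ValueError(f"block table needs columns {sorted(required)}")
        bad = self.table["code_start"].str[0] != self.table["code_end"].str[0]
        if bad.any():
            raise ValueError("block ranges must stay within one chapter letter")

    @classmethod
    def from_tsv(cls, path) -> "BlockMap":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    @classmethod
    def default(cls) -> "BlockMap":
        """The packaged WHO-style block table."""
        with resources.files("pdnet").joinpath("data/icd10_blocks.tsv").open() as fh:
            return cls(pd.read_csv(fh, sep="\t", dtype=str))

    def lookup(self, code: str) -> str:
        return map_block(code, self)

    def block_name(self, block_id: str) -> str:
        hit = self.table.loc[self.table["block_id"] == block_id, "block_name"]
        return hit.iloc[0] if len(hit) else UNMAPPED_BLOCK


def truncate_code(code: str) -> str:
    """Normalize an ICD-10 code to the three-character level, uppercased.

    >>> truncate_code("G43.1")
    'G43'
    """
    code = code.strip()
    if not ICD10_PATTERN.match(code):
        raise ValueError(f"malformed ICD-10 code: {code!r}")
    return code[:3].upper()


def _parse_date(text: str) -> _date | None:
    text = (text or "").strip()
    if not text:
        return None
    try:
        return _date.fromisoformat(text)
    except ValueError:
        return None  # dates are parsed opportunistically; unused by the analysis


def read_records(
    path,
    *,
    delimiter: str = ",",
    max_reject_fraction: float = 0.10,
) -> tuple[list[DiagnosisRecord], int]:
    """Read long-format diagnosis records from CSV.

    The header must declare ``patient_id``, ``cohort`` and ``icd10`` columns
    (``date`` optional).  Rows with malformed codes or unknown cohort labels
    are rejected individually; the file is rejected wholesale only if more
    than ``max_reject_fraction`` of rows fail.  Duplicate (patient, code)
    rows are retained — deduplication happens at matrix build.

    Returns
    -------
    (records, n_rejected)
    """
    records: list[DiagnosisRecord] = []
    n_rejected = 0
    n_rows = 0
    with open(path, newline="", encoding="utf-8") as fh:
        reader = csv.DictReader(fh, delimiter=delimiter)
        header = set(reader.fieldnames or [])
        missing = {"patient_id", "cohort", "icd10"} - header
        if missing:
            raise RecordParseError(f"{path}: missing required column(s) {sorted(missing)}")
        for row in reader:
            n_rows += 1
            code = (row.get("icd10") or "").strip()
            cohort = (row.get("cohort") or "").strip().lower()
            pid = (row.get("patient_id") or "").strip()
            if not pid:
                n_rejected += 1
                logger.debug("row %d rejected: empty patient id", n_rows)
                continue
            if cohort not in (CASE, CONTROL):
                n_rejected += 1
                logger.debug("row %d rejected: unknown cohort %r", n_rows, cohort)
                continue
            if not ICD10_PATTERN.match(code):
                n_rejected += 1
                logger.debug("row %d rejected: malformed ICD-10 code %r", n_rows, code)
                continue
            records.append(
                DiagnosisRecord(pid, cohort, code, _parse_date(row.get("date", "")))
            )
    if n_rows and n_rejected / n_rows > max_reject_fraction:
        raise RecordParseError(
            f"{path}: {n_rejected}/{n_rows} rows rejected "
            f"(> {max_reject_fraction:.0%} threshold)"
        )
    logger.info("%s: %d rows read, %d rejected", path, n_rows, n_rejected)
    return records, n_rejected


def build_matrix(
    records: Iterable[DiagnosisRecord],
    cohort: str,
    roster: Sequence[str],
) -> CohortMatrix:
    """Pivot records into a binary incidence matrix at the 3-character level.

    Entry (p, c) is 1 iff patient ``p`` has at least one record whose
    truncated code is ``c``.  Every roster patient gets a row (all-zero if
    they carry no records); codes are sorted lexicographically.
    """
    roster = list(roster)
    if len(set(roster)) != len(roster):
        raise ValueError("roster contains duplicate patient ids")
    row_of = {pid: i for i, pid in enumerate(roster)}
    pairs: set[tuple[int, str]] = set()
    codes: set[str] = set()
    for rec in records:
        if rec.cohort != cohort:
            continue
        if rec.patient_id not in row_of:
            raise ValueError(f"patient {rec.patient_id!r} not in roster")
        code3 = truncate_code(rec.code)
        pairs.add((row_of[rec.patient_id], code3))
        codes.add(code3)
    code_list = sorted(codes)
    col_of = {c: j for j, c in enumerate(code_list)}
    incidence = np.zeros((len(roster), len(code_list)), dtype=np.uint8)
    for i, code3 in pairs:
        incidence[i, col_of[code3]] = 1
    return CohortMatrix(cohort, roster, code_list, incidence)


def map_block(code: str, blocks: BlockMap) -> str:
    """Map a three-character code to its containing block id (total function)."""
    code = truncate_code(code)
    t = blocks.table
    hit = t[(t["code_start"] <= code) & (code <= t["code_end"])]
    if len(hit) == 0:
        return UNMAPPED_BLOCK
    # narrowest range wins if a user-supplied table overlaps
    if len(hit) > 1:
        spans = hit["code_end"].str[1:].astype(int) - hit["code_start"].str[1:].astype(int)
        return hit.loc[spans.idxmin(), "block_id"]
    return hit["block_id"].iloc[0]


def block_membership(matrix: CohortMatrix, blocks: BlockMap) -> pd.DataFrame:
    """Patient x block binary matrix: 1 iff the patient has >=1 code in the block."""
    block_ids = [map_block(c, blocks) for c in matrix.codes]
    frame = matrix.to_frame()
    grouped = frame.T.groupby(pd.Index(block_ids, name="block")).max().T
    return grouped.astype(np.uint8)
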