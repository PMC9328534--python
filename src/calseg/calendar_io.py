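"""Parsing and recoding of DHS-style contraceptive calendar strings.

A DHS contraceptive calendar stores one single-character event code per
month, with the *leftmost* non-padding column holding the most recent
month (the interview month) and later columns reaching back in time.
Dates are century-month codes (CMC): months elapsed since January 1900.

This module turns raw calendar strings into fixed 59-month
:class:`StateSequence` objects over the five-state alphabet, applies the
age-eligibility filter (15-44 at the start of the sequence), and reads
and writes the delimited-text formats used throughout the pipeline.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .states import (
    LAPM,
    MISSING,
    NONE,
    PREG,
    SEQ_LENGTH,
    STATE_LETTERS,
    STM,
    TRAD,
    letters_to_states,
    states_to_letters,
)

logger = logging.getLogger(__name__)

#: Mandatory input columns, named after the DHS individual-recode variables.
RECORD_COLUMNS = {
    "case_id": "case_id",
    "vcal": "vcal",
    "v008": "interview CMC",
    "v011": "birth CMC",
    "v005": "sampling weight (x 1e6)",
    "v021": "PSU",
    "v022": "stratum",
}


class CalendarParseError(ValueError):
    """Raised when a calendar string contains an unmapped character."""


class WindowError(ValueError):
    """Raised when a record cannot supply the full 59-month window."""


class SchemaError(ValueError):
    """Raised when an input file is missing a mandatory column."""


@dataclass
class CalendarRecord:
    """One woman's raw calendar plus survey-design and covariate fields."""

    case_id: str
    calendar: str
    interview_cmc: int
    birth_cmc: int
    weight: float
    psu: int
    stratum: int
    covariates: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.interview_cmc <= self.birth_cmc:
            raise ValueError(
                f"{self.case_id}: interview CMC {self.interview_cmc} must "
                f"postdate birth CMC {self.birth_cmc}"
            )
        if self.weight < 0:
            raise ValueError(f"{self.case_id}: negative weight {self.weight}")


@dataclass(frozen=True)
class StateSequence:
    """A 59-month state vector, month 1 earliest, month 59 most recent."""

    case_id: str
    states: np.ndarray  # int8, length 59, values 0..4
    start_cmc: int      # CMC of month 1

    def __post_init__(self) -> None:
        states = np.asarray(self.states, dtype=np.int8)
        object.__setattr__(self, "states", states)
        if states.shape != (SEQ_LENGTH,):
            raise ValueError(
                f"{self.case_id}: sequence must have exactly {SEQ_LENGTH} "
                f"months, got {states.shape}"
            )
        if states.min() < 0 or states.max() > 4:
            raise ValueError(f"{self.case_id}: states outside the 5-state alphabet")

    @property
    def letters(self) -> str:
        return states_to_letters(self.states)


@dataclass(frozen=True)
class CodeMap:
    """Mapping from single calendar characters to states (or MISSING).

    The mapping is data, not code: the shipped default mirrors the DHS-7
    recode-manual calendar codes, and surveys with dialect codes can
    supply their own.
    """

    mapping: Mapping[str, int]
    provenance: str = ""

    def __getitem__(self, char: str) -> int:
        return self.mapping[char]

    def __contains__(self, char: str) -> bool:
        return char in self.mapping


def default_code_map() -> CodeMap:
    """The DHS-7 calendar code mapping onto the five analysis states.

    Pregnancy, birth and termination (P/B/T) collapse to the single
    pregnancy state. Short-term modern methods are pill, injectable,
    male and female condom, LAM, emergency contraception, the Standard
    Days Method, diaphragm, foam/jelly and other modern methods. LAPM
    covers IUD, implant and male/female sterilization. Traditional
    covers periodic abstinence/rhythm, withdrawal, abstinence and other
    traditional methods. '?' and blank are missing.
    """
    m: dict[str, int] = {}
    for c in "BPT":
        m[c] = PREG
    m["0"] = NONE
    # short-term modern
    for c in ("1", "3", "4", "5", "C", "L", "E", "S", "F", "M"):
        m[c] = STM
    # long-acting and permanent
    for c in ("2", "6", "7", "N"):
        m[c] = LAPM
    # traditional
    for c in ("8", "9", "W", "A"):
        m[c] = TRAD
    m["?"] = MISSING
    m[" "] = MISSING
    return CodeMap(mapping=m, provenance="DHS-7 recode manual calendar codes")


def parse_calendar(record: CalendarRecord, code_map: CodeMap | None = None) -> list[tuple[int, int]]:
    """Recode a calendar string into (cmc, state) pairs, earliest first.

    The leftmost non-padding column is the interview month; each column
    to the right is one month earlier. Padding (leading/trailing blanks)
    is trimmed before alignment; internal blanks are kept as MISSING.
    """
    if code_map is None:
        code_map = default_code_map()
    raw = record.calendar
    if not raw.strip():
        raise CalendarParseError(f"{record.case_id}: empty calendar string")
    left = len(raw) - len(raw.lstrip())
    trimmed = raw.strip()
    out: list[tuple[int, int]] = []
    for offset, char in enumerate(trimmed):
        if char not in code_map:
            col = left + offset + 1
            raise CalendarParseError(
                f"{record.case_id}: unknown calendar character {char!r} "
                f"at column {col}"
            )
        cmc = record.interview_cmc - offset
        out.append((cmc, code_map[char]))
    out.reverse()
    return out


def extract_window(
    parsed: Sequence[tuple[int, int]],
    interview_cmc: int,
    case_id: str = "",
    missing_policy: str = "carry_backward",
) -> StateSequence:
    """Cut the 59 months ending at the interview month, month 1 earliest.

    ``missing_policy`` resolves MISSING months: ``"error"`` raises,
    ``"carry_backward"`` (default) copies the next observed later month,
    ``"none"`` recodes to the no-use state. Records that cannot cover
    the full window raise :class:`WindowError`.
    """
    start_cmc = interview_cmc - (SEQ_LENGTH - 1)
    if not parsed or parsed[0][0] > start_cmc or parsed[-1][0] < interview_cmc:
        raise WindowError(
            f"{case_id}: calendar covers {len(parsed)} months, "
            f"cannot span the {SEQ_LENGTH}-month window"
        )
    by_cmc = dict(parsed)
    window = np.full(SEQ_LENGTH, MISSING, dtype=np.int8)
    for i in range(SEQ_LENGTH):
        window[i] = by_cmc.get(start_cmc + i, MISSING)

    n_missing = int(np.sum(window == MISSING))
    if n_missing:
        if missing_policy == "error":
            raise WindowError(f"{case_id}: {n_missing} missing months in window")
        if missing_policy == "carry_backward":
            # fill each gap from the next observed (later) month
            nxt = MISSING
            for i in range(SEQ_LENGTH - 1, -1, -1):
                if window[i] == MISSING:
                    window[i] = nxt
                else:
                    nxt = window[i]
            if np.any(window == MISSING):
                raise WindowError(
                    f"{case_id}: window has no observed month at or after a gap"
                )
            logger.info("%s: carried %d missing months backward", case_id, n_missing)
        elif missing_policy == "none":
            covered = np.sum(window != MISSING)
            if covered < SEQ_LENGTH - n_missing:  # pragma: no cover
                raise WindowError(case_id)
            window[window == MISSING] = NONE
            logger.info("%s: recoded %d missing months to NONE", case_id, n_missing)
        else:
            raise ValueError(f"unknown missing policy {missing_policy!r}")
    return StateSequence(case_id=case_id, states=window, start_cmc=start_cmc)


def filter_eligible(
    records: Iterable[CalendarRecord],
    min_age: int = 15,
    max_age: int = 44,
) -> tuple[list[CalendarRecord], dict]:
    """Keep women aged ``min_age``..``max_age`` (completed years) at the
    start of their 59-month window. Returns (kept, report)."""
    kept, dropped = [], 0
    for rec in records:
        start_cmc = rec.interview_cmc - (SEQ_LENGTH - 1)
        age = (start_cmc - rec.birth_cmc) // 12
        if min_age <= age <= max_age:
            kept.append(rec)
        else:
            dropped += 1
    report = {"kept": len(kept), "dropped": dropped}
    logger.info("eligibility filter: kept %(kept)d, dropped %(dropped)d", report)
    return kept, report


def build_sequences(
    records: Iterable[CalendarRecord],
    code_map: CodeMap | None = None,
    missing_policy: str = "carry_backward",
) -> tuple[list[StateSequence], list[tuple[str, str]]]:
    """Parse and window a batch of records; return (sequences, exclusions).

    Exclusions are (case_id, reason) pairs for records that could not
    supply a complete window; parse errors (unknown characters) are
    genuine data errors and still raise.
    """
    seqs: list[StateSequence] = []
    excluded: list[tuple[str, str]] = []
    for rec in records:
        parsed = parse_calendar(rec, code_map)
        try:
            seqs.append(
                extract_window(parsed, rec.interview_cmc, rec.case_id, missing_policy)
            )
        except WindowError as exc:
            logger.warning("excluding %s: %s", rec.case_id, exc)
            excluded.append((rec.case_id, str(exc)))
    return seqs, excluded


# ---------------------------------------------------------------------------
# delimited-text I/O


def read_records(path, rescale_weights: bool = True) -> list[CalendarRecord]:
    """Read woman-level records from CSV (DHS variable names, see
    :data:`RECORD_COLUMNS`). Extra columns become covariates. With
    ``rescale_weights`` the v005 convention (weight x 1e6) is undone."""
    df = pd.read_csv(path, dtype={"case_id": str, "vcal": str})
    if df.empty and df.columns.size == 0:
        logger.warning("%s: empty input file", path)
        return []
    for col in RECORD_COLUMNS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r} "
                              f"({RECORD_COLUMNS[col]})")
    covar_cols = [c for c in df.columns if c not in RECORD_COLUMNS]
    scale = 1e-6 if rescale_weights else 1.0
    records = []
    for row in df.itertuples(index=False):
        records.append(
            CalendarRecord(
                case_id=str(row.case_id),
                calendar=str(row.vcal),
                interview_cmc=int(row.v008),
                birth_cmc=int(row.v011),
                weight=float(row.v005) * scale,
                psu=int(row.v021),
                stratum=int(row.v022),
                covariates={c: getattr(row, c) for c in covar_cols},
            )
        )
    if not records:
        logger.warning("%s: no rows", path)
    return records


def write_records(records: Sequence[CalendarRecord], path, rescale_weights: bool = True) -> None:
    """Inverse of :func:`read_records` (weights re-scaled to v005 units)."""
    scale = 1e6 if rescale_weights else 1.0
    rows = []
    for r in records:
        row = {
            "case_id": r.case_id,
            "vcal": r.calendar,
            "v008": r.interview_cmc,
            "v011": r.birth_cmc,
            "v005": int(round(r.weight * scale)),
            "v021": r.psu,
            "v022": r.stratum,
        }
        row.update(r.covariates)
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False)


_MONTH_COLS = [f"m{i:02d}" for i in range(1, SEQ_LENGTH + 1)]


def write_sequences(seqs: Sequence[StateSequence], path) -> None:
    """Write sequences as CSV: case_id, start_cmc, one letter per month
    (columns m01..m59, letters {N,S,L,T,P}, month 1 earliest)."""
    rows = []
    for s in seqs:
        row = {"case_id": s.case_id, "start_cmc": s.start_cmc}
        row.update(dict(zip(_MONTH_COLS, s.letters)))
        rows.append(row)
    pd.DataFrame(rows, columns=["case_id", "start_cmc"] + _MONTH_COLS).to_csv(
        path, index=False
    )


def read_sequences(path) -> list[StateSequence]:
    df = pd.read_csv(path, dtype={"case_id": str})
    for col in ["case_id", "start_cmc"] + _MONTH_COLS:
        if col not in df.columns:
            raise SchemaError(f"{path}: missing mandatory column {col!r}")
    out = []
    for row in df.itertuples(index=False):
        letters = "".join(getattr(row, c) for c in _MONTH_COLS)
        out.append(
            StateSequence(
                case_id=str(row.case_id),
                states=letters_to_states(letters),
                start_cmc=int(row.start_cmc),
            )
        )
    return out
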