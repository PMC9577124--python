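"""Cohort records, the composite bad-outcome endpoint and binary risk labels.

A *case* is one prostatectomy patient with right-censored follow-up. The
composite endpoint ("bad outcome") is biochemical recurrence (BCR, a
post-operative PSA rise >= 0.2 ng/ml), distant metastasis, or cancer-specific
death, whichever comes first. Binary risk labels are derived from the outcome
alone, without any grading input:

* training rule — high risk if the bad outcome occurred within 3 years of
  surgery OR local spread (lymph-node metastasis pN, or vessel infiltration
  pV/pL) was found at surgery; low risk if no bad outcome, more than 5 years
  of follow-up, and no local spread;
* test rule — identical but without the local-spread clauses.

Cases satisfying neither clause (event-free but with < 5 years of follow-up,
or a late bad outcome) carry an *undefined* label and are excluded from
classification metrics, while remaining usable for survival analysis.
"""

from __future__ import annotations

import enum
import io
import logging
import math
from dataclasses import dataclass, fields
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd

logger = logging.getLogger(__name__)

#: years of slack allowed between an event time and the recorded follow-up
EVENT_TIME_TOLERANCE = 1e-6

#: horizon (years) within which a bad outcome makes a case high risk
HIGH_RISK_HORIZON_YEARS = 3.0

#: minimum event-free follow-up (years, strict) for a confirmed low-risk case
LOW_RISK_FOLLOWUP_YEARS = 5.0


class LabelMode(str, enum.Enum):
    """Which risk-label rule to apply."""

    TRAIN = "train"
    TEST = "test"


class RiskValue(str, enum.Enum):
    HIGH = "high"
    LOW = "low"
    UNDEFINED = "undefined"


@dataclass(frozen=True)
class CaseRecord:
    """One patient's clinical and follow-up data.

    Missing values are ``None``, never silently zero. Event times are present
    iff the corresponding event flag is true.
    """

    case_id: str
    tma_id: str
    age: Optional[float] = None
    preop_psa: Optional[float] = None
    isup: Optional[float] = None
    pt_stage: Optional[float] = None
    pn_flag: Optional[bool] = None
    pv_flag: Optional[bool] = None
    pl_flag: Optional[bool] = None
    follow_up_years: Optional[float] = None
    bcr_flag: Optional[bool] = None
    t_bcr: Optional[float] = None
    met_flag: Optional[bool] = None
    t_met: Optional[float] = None
    cdeath_flag: Optional[bool] = None
    t_cdeath: Optional[float] = None

    def __post_init__(self) -> None:
        for flag, time, name in (
            (self.bcr_flag, self.t_bcr, "t_bcr"),
            (self.met_flag, self.t_met, "t_met"),
            (self.cdeath_flag, self.t_cdeath, "t_cdeath"),
        ):
            if time is not None:
                if time < 0:
                    raise ValueError(f"{name} must be >= 0, got {time}")
                if (
                    self.follow_up_years is not None
                    and time > self.follow_up_years + EVENT_TIME_TOLERANCE
                ):
                    raise ValueError(
                        f"{name}={time} exceeds follow_up_years="
                        f"{self.follow_up_years} for case {self.case_id}"
                    )
        if self.follow_up_years is not None and self.follow_up_years < 0:
            raise ValueError("follow_up_years must be >= 0")

    @property
    def local_spread_flags(self) -> tuple[Optional[bool], ...]:
        return (self.pn_flag, self.pv_flag, self.pl_flag)


@dataclass(frozen=True)
class BadOutcome:
    """Composite endpoint: first of BCR, metastasis or cancer-specific death."""

    occurred: bool
    time_years: float


@dataclass(frozen=True)
class RiskLabel:
    value: RiskValue
    mode: LabelMode


def derive_bad_outcome(case: CaseRecord) -> BadOutcome:
    """Derive the composite endpoint for one case.

    The endpoint occurred iff any of the three event flags is true (a missing
    flag counts as false, with a warning); its time is the earliest available
    event time, otherwise the censoring (follow-up) time.

    Raises
    ------
    ValueError
        If follow-up is missing, or an event flag is true without its time.
    """
    if case.follow_up_years is None:
        raise ValueError(f"case {case.case_id}: follow_up_years is required")

    event_times = []
    for flag, time, flag_name, time_name in (
        (case.bcr_flag, case.t_bcr, "bcr_flag", "t_bcr"),
        (case.met_flag, case.t_met, "met_flag", "t_met"),
        (case.cdeath_flag, case.t_cdeath, "cdeath_flag", "t_cdeath"),
    ):
        if flag is None:
            logger.warning(
                "case %s: %s missing, treated as no event", case.case_id, flag_name
            )
        elif flag:
            if time is None:
                raise ValueError(
                    f"case {case.case_id}: {flag_name} is true but {time_name} is missing"
                )
            event_times.append(time)

    if event_times:
        return BadOutcome(occurred=True, time_years=min(event_times))
    return BadOutcome(occurred=False, time_years=case.follow_up_years)


def _no_local_spread(case: CaseRecord) -> bool:
    """True when local spread is positively excluded.

    A missing flag does not assert spread, but confirmed absence requires at
    least one flag observed and every observed flag false.
    """
    flags = case.local_spread_flags
    observed = [f for f in flags if f is not None]
    return bool(observed) and not any(observed)


def _any_local_spread(case: CaseRecord) -> bool:
    return any(f for f in case.local_spread_flags if f is not None)


def assign_risk_label(case: CaseRecord, mode: LabelMode | str) -> RiskLabel:
    """Apply the outcome-based binary risk rule.

    Train mode: high if bad outcome within 3 years OR local spread; low if no
    bad outcome AND follow-up > 5 years AND no local spread. Test mode drops
    both local-spread clauses. Anything else is undefined.
    """
    mode = LabelMode(mode)
    outcome = derive_bad_outcome(case)

    early_bad = outcome.occurred and outcome.time_years <= HIGH_RISK_HORIZON_YEARS
    long_clean = (
        not outcome.occurred
        and case.follow_up_years is not None
        and case.follow_up_years > LOW_RISK_FOLLOWUP_YEARS
    )

    if mode is LabelMode.TRAIN:
        if early_bad or _any_local_spread(case):
            value = RiskValue.HIGH
        elif long_clean and _no_local_spread(case):
            value = RiskValue.LOW
        else:
            value = RiskValue.UNDEFINED
    else:
        if early_bad:
            value = RiskValue.HIGH
        elif long_clean:
            value = RiskValue.LOW
        else:
            value = RiskValue.UNDEFINED
        # the test rule omits the local-spread clauses; flag cases whose label
        # would differ under the train rule so the discrepancy is auditable
        if value is RiskValue.LOW and not _no_local_spread(case):
            logger.debug(
                "case %s: low risk under test rule but local spread not excluded",
                case.case_id,
            )
    return RiskLabel(value=value, mode=mode)


def is_possible_low_risk(case: CaseRecord) -> bool:
    """Event-free case whose follow-up is too short to confirm low risk.

    These are the pseudo-labeling candidates: no bad outcome and follow-up
    <= 5 years.
    """
    outcome = derive_bad_outcome(case)
    return (
        not outcome.occurred
        and case.follow_up_years is not None
        and case.follow_up_years <= LOW_RISK_FOLLOWUP_YEARS
    )


# ---------------------------------------------------------------------------
# Cohort table I/O
# ---------------------------------------------------------------------------

#: canonical column order of the cohort table
COHORT_COLUMNS = [
    "case_id",
    "tma_id",
    "age",
    "psa",
    "isup",
    "pt",
    "pn",
    "pv",
    "pl",
    "fu_years",
    "bcr",
    "t_bcr",
    "met",
    "t_met",
    "cdeath",
    "t_cdeath",
]

_FIELD_TO_COLUMN = {
    "case_id": "case_id",
    "tma_id": "tma_id",
    "age": "age",
    "preop_psa": "psa",
    "isup": "isup",
    "pt_stage": "pt",
    "pn_flag": "pn",
    "pv_flag": "pv",
    "pl_flag": "pl",
    "follow_up_years": "fu_years",
    "bcr_flag": "bcr",
    "t_bcr": "t_bcr",
    "met_flag": "met",
    "t_met": "t_met",
    "cdeath_flag": "cdeath",
    "t_cdeath": "t_cdeath",
}
_BOOL_COLUMNS = {"pn", "pv", "pl", "bcr", "met", "cdeath"}
_MANDATORY_COLUMNS = {"case_id", "tma_id", "fu_years"}


def _parse_bool(value) -> Optional[bool]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    if isinstance(value, bool):
        return value
    text = str(value).strip().lower()
    if text in ("", "na", "nan", "none"):
        return None
    if text in ("1", "true", "t", "yes"):
        return True
    if text in ("0", "false", "f", "no"):
        return False
    raise ValueError(f"cannot parse boolean value {value!r}")


def _parse_float(value) -> Optional[float]:
    if value is None or (isinstance(value, float) and math.isnan(value)):
        return None
    text = str(value).strip()
    if text in ("", "na", "nan", "none"):
        return None
    return float(text)


def read_cohort(path: str | Path | io.IOBase) -> list[CaseRecord]:
    """Read a cohort table (TSV, or CSV for a ``.csv`` suffix).

    Raises ``ValueError`` listing any missing mandatory columns.
    """
    sep = ","
    if not (isinstance(path, (str, Path)) and str(path).endswith(".csv")):
        sep = "\t"
    df = pd.read_csv(path, sep=sep, dtype=str, keep_default_na=False)
    missing = sorted(_MANDATORY_COLUMNS - set(df.columns))
    if missing:
        raise ValueError(f"cohort table missing mandatory columns: {missing}")

    records = []
    for row in df.itertuples(index=False):
        row = dict(zip(df.columns, row))
        kwargs = {}
        for field, column in _FIELD_TO_COLUMN.items():
            raw = row.get(column)
            if column in ("case_id", "tma_id"):
                kwargs[field] = str(raw)
            elif column in _BOOL_COLUMNS:
                kwargs[field] = _parse_bool(raw)
            else:
                kwargs[field] = _parse_float(raw)
        records.append(CaseRecord(**kwargs))
    return records


def _format_value(value) -> str:
    if value is None:
        return ""
    if isinstance(value, bool):
        return "1" if value else "0"
    if isinstance(value, float):
        return repr(value)  # shortest exact round-trip representation
    return str(value)


def write_cohort(records: Iterable[CaseRecord], path: str | Path) -> None:
    """Write the cohort table in canonical column order.

    Writing is byte-stable: ``write(read(p))`` reproduces a file previously
    produced by this writer.
    """
    rows = []
    for rec in records:
        row = {}
        for field, column in _FIELD_TO_COLUMN.items():
            row[column] = _format_value(getattr(rec, field))
        rows.append(row)
    df = pd.DataFrame(rows, columns=COHORT_COLUMNS)
    sep = "," if str(path).endswith(".csv") else "\t"
    df.to_csv(path, sep=sep, index=False, lineterminator="\n")


def label_counts(
    records: Sequence[CaseRecord], mode: LabelMode | str
) -> dict[str, int]:
    """Count high/low/undefined labels for a set of cases."""
    counts = {v.value: 0 for v in RiskValue}
    for rec in records:
        counts[assign_risk_label(rec, mode).value.value] += 1
    return counts
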