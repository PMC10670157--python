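"""Domain types, CSV reading/writing, and schema validation.

The analysis unit is the line of therapy (LOT): a single-arm trial patient
contributes exactly one LOT, while a real-world physician's-choice (RWPC)
control patient may contribute several, each indexed from its own start
date.  All durations are integer days from that index date; month-scale
summaries use the fixed divisor ``DAYS_PER_MONTH``.

The CSV dialect is deliberately rigid: comma-separated, UTF-8, header
required and in canonical column order, missing values are empty cells,
booleans are encoded 0/1.  Validation raises, never coerces.
"""

from __future__ import annotations

import csv
import io
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Optional

import pandas as pd

DAYS_PER_MONTH = 30.4375

TRIAL = "TRIAL"
RWPC = "RWPC"
COHORTS = (TRIAL, RWPC)

ECOG_LEVELS = (0, 1)
PRIOR_LINES_LEVELS = ("1", "2", "3plus")
AGE_LEVELS = ("lt65", "65to75", "ge75")
RESPONSE_LEVELS = ("responder", "non_responder")

MET_SITES = (
    "brain_met",
    "liver_met",
    "bone_met",
    "lymph_met",
    "adrenal_met",
    "pleural_met",
    "other_met",
)

#: Adjustment covariates, in the order they enter the propensity and
#: multivariable outcome models.
COVARIATES = ("ecog", "prior_lines") + MET_SITES + ("age_cat",)

#: Canonical CSV column order.
CSV_COLUMNS = (
    "patient_id",
    "cohort",
    "lot_seq",
    "ecog",
    "prior_lines",
    *MET_SITES,
    "age_cat",
    "egfr_tested_before",
    "prior_platinum",
    "contains_amivantamab",
    "response",
    "pfs_days",
    "pfs_event",
    "ttnt_days",
    "ttnt_event",
    "os_days",
    "os_event",
)


class SchemaError(ValueError):
    """The file header does not match the expected schema."""


class ValidationError(ValueError):
    """A record violates a type invariant or enumeration."""


@dataclass(frozen=True)
class CovariateProfile:
    """Baseline adjustment covariates measured at the start of a LOT.

    The seven metastatic-site indicators are tri-state (``True`` /
    ``False`` / ``None`` for missing) and must be missing jointly or not
    at all: chart abstraction either recorded the metastatic work-up for
    a line or recorded none of it (block missingness).
    """

    ecog: int
    prior_lines: str
    brain_met: Optional[bool]
    liver_met: Optional[bool]
    bone_met: Optional[bool]
    lymph_met: Optional[bool]
    adrenal_met: Optional[bool]
    pleural_met: Optional[bool]
    other_met: Optional[bool]
    age_cat: str

    def __post_init__(self) -> None:
        if self.ecog not in ECOG_LEVELS:
            raise ValidationError(f"ecog must be one of {ECOG_LEVELS}, got {self.ecog!r}")
        if self.prior_lines not in PRIOR_LINES_LEVELS:
            raise ValidationError(
                f"prior_lines must be one of {PRIOR_LINES_LEVELS}, got {self.prior_lines!r}"
            )
        if self.age_cat not in AGE_LEVELS:
            raise ValidationError(f"age_cat must be one of {AGE_LEVELS}, got {self.age_cat!r}")
        sites = self.site_values()
        n_missing = sum(v is None for v in sites.values())
        if n_missing not in (0, len(MET_SITES)):
            partial = sorted(k for k, v in sites.items() if v is None)
            raise ValidationError(
                "metastatic-site fields must be missing jointly or not at all; "
                f"only {partial} are missing"
            )

    def site_values(self) -> dict[str, Optional[bool]]:
        return {s: getattr(self, s) for s in MET_SITES}

    @property
    def sites_missing(self) -> bool:
        return self.brain_met is None


@dataclass(frozen=True)
class LOTRecord:
    """One treatment line for one patient."""

    patient_id: str
    cohort: str
    lot_seq: int
    covariates: CovariateProfile
    egfr_tested_before: bool
    prior_platinum: bool
    contains_amivantamab: bool
    response: Optional[str]  # "responder" | "non_responder" | None
    pfs_days: int
    pfs_event: bool
    ttnt_days: int
    ttnt_event: bool
    os_days: int
    os_event: bool

    def __post_init__(self) -> None:
        if self.cohort not in COHORTS:
            raise ValidationError(f"cohort must be one of {COHORTS}, got {self.cohort!r}")
        if not isinstance(self.lot_seq, int) or self.lot_seq < 1:
            raise ValidationError(f"lot_seq must be a positive integer, got {self.lot_seq!r}")
        if self.response is not None and self.response not in RESPONSE_LEVELS:
            raise ValidationError(
                f"response must be one of {RESPONSE_LEVELS} or missing, got {self.response!r}"
            )
        for name in ("pfs_days", "ttnt_days", "os_days"):
            v = getattr(self, name)
            if not isinstance(v, int) or v < 0:
                raise ValidationError(f"{name} must be a non-negative integer, got {v!r}")
        if self.os_event:
            if self.pfs_days > self.os_days:
                raise ValidationError(
                    f"pfs_days ({self.pfs_days}) exceeds os_days ({self.os_days}) "
                    "with an observed death"
                )
            if self.ttnt_days > self.os_days:
                raise ValidationError(
                    f"ttnt_days ({self.ttnt_days}) exceeds os_days ({self.os_days}) "
                    "with an observed death"
                )
        if self.cohort == TRIAL:
            if self.lot_seq != 1:
                raise ValidationError("trial records must have lot_seq = 1")
            if not self.contains_amivantamab:
                raise ValidationError("trial records must contain the trial agent")


@dataclass
class AnalysisSet:
    """The assembled two-cohort LOT table.

    Control patients can appear on several rows (one per eligible LOT);
    trial patients appear exactly once.  ``patient_id`` is the cluster
    identifier used by every robust-variance computation downstream.
    """

    records: list[LOTRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        seen_trial: set[str] = set()
        counts: dict[str, int] = {}
        for r in self.records:
            if r.cohort == TRIAL:
                seen_trial.add(r.patient_id)
            counts[r.patient_id] = counts.get(r.patient_id, 0) + 1
            if r.cohort == RWPC and r.contains_amivantamab:
                raise ValidationError(
                    f"control record {r.patient_id}/{r.lot_seq} contains the trial agent"
                )
        for pid, n in counts.items():
            if n > 1 and pid in seen_trial:
                raise ValidationError(f"patient {pid} appears more than once in the trial stratum")

    @property
    def n_trial(self) -> int:
        return sum(r.cohort == TRIAL for r in self.records)

    @property
    def n_control_lots(self) -> int:
        return sum(r.cohort == RWPC for r in self.records)

    @property
    def n_control_patients(self) -> int:
        return len({r.patient_id for r in self.records if r.cohort == RWPC})

    def trial_records(self) -> list[LOTRecord]:
        return [r for r in self.records if r.cohort == TRIAL]

    def control_records(self) -> list[LOTRecord]:
        return [r for r in self.records if r.cohort == RWPC]

    def to_frame(self) -> pd.DataFrame:
        """Analysis-ready DataFrame: one row per LOT.

        Tri-state fields become float columns with NaN for missing;
        ``treat`` is the 0/1 trial-membership indicator.
        """
        rows = []
        for r in self.records:
            cov = r.covariates
            row = {
                "patient_id": r.patient_id,
                "cohort": r.cohort,
                "treat": 1 if r.cohort == TRIAL else 0,
                "lot_seq": r.lot_seq,
                "ecog": cov.ecog,
                "prior_lines": cov.prior_lines,
                "age_cat": cov.age_cat,
                "egfr_tested_before": r.egfr_tested_before,
                "prior_platinum": r.prior_platinum,
                "contains_amivantamab": r.contains_amivantamab,
                "response": (
                    float("nan") if r.response is None else float(r.response == "responder")
                ),
                "pfs_days": r.pfs_days,
                "pfs_event": int(r.pfs_event),
                "ttnt_days": r.ttnt_days,
                "ttnt_event": int(r.ttnt_event),
                "os_days": r.os_days,
                "os_event": int(r.os_event),
            }
            for s in MET_SITES:
                v = getattr(cov, s)
                row[s] = float("nan") if v is None else float(v)
            rows.append(row)
        return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# CSV serialization


def _encode_bool(v: bool) -> str:
    return "1" if v else "0"


def _encode_tristate(v: Optional[bool]) -> str:
    return "" if v is None else _encode_bool(v)


def _record_to_row(r: LOTRecord) -> list[str]:
    cov = r.covariates
    return [
        r.patient_id,
        r.cohort,
        str(r.lot_seq),
        str(cov.ecog),
        cov.prior_lines,
        *[_encode_tristate(getattr(cov, s)) for s in MET_SITES],
        cov.age_cat,
        _encode_bool(r.egfr_tested_before),
        _encode_bool(r.prior_platinum),
        _encode_bool(r.contains_amivantamab),
        "" if r.response is None else r.response,
        str(r.pfs_days),
        _encode_bool(r.pfs_event),
        str(r.ttnt_days),
        _encode_bool(r.ttnt_event),
        str(r.os_days),
        _encode_bool(r.os_event),
    ]


def _parse_bool(value: str, column: str, row_no: int) -> bool:
    if value == "0":
        return False
    if value == "1":
        return True
    raise ValidationError(f"row {row_no}: {column} must be 0 or 1, got {value!r}")


def _parse_int(value: str, column: str, row_no: int) -> int:
    try:
        return int(value)
    except ValueError:
        raise ValidationError(f"row {row_no}: {column} must be an integer, got {value!r}") from None


def _row_to_record(row: dict[str, str], row_no: int) -> LOTRecord:
    sites: dict[str, Optional[bool]] = {}
    for s in MET_SITES:
        v = row[s]
        sites[s] = None if v == "" else _parse_bool(v, s, row_no)
    try:
        cov = CovariateProfile(
            ecog=_parse_int(row["ecog"], "ecog", row_no),
            prior_lines=row["prior_lines"],
            age_cat=row["age_cat"],
            **sites,
        )
        return LOTRecord(
            patient_id=row["patient_id"],
            cohort=row["cohort"],
            lot_seq=_parse_int(row["lot_seq"], "lot_seq", row_no),
            covariates=cov,
            egfr_tested_before=_parse_bool(row["egfr_tested_before"], "egfr_tested_before", row_no),
            prior_platinum=_parse_bool(row["prior_platinum"], "prior_platinum", row_no),
            contains_amivantamab=_parse_bool(
                row["contains_amivantamab"], "contains_amivantamab", row_no
            ),
            response=None if row["response"] == "" else row["response"],
            pfs_days=_parse_int(row["pfs_days"], "pfs_days", row_no),
            pfs_event=_parse_bool(row["pfs_event"], "pfs_event", row_no),
            ttnt_days=_parse_int(row["ttnt_days"], "ttnt_days", row_no),
            ttnt_event=_parse_bool(row["ttnt_event"], "ttnt_event", row_no),
            os_days=_parse_int(row["os_days"], "os_days", row_no),
            os_event=_parse_bool(row["os_event"], "os_event", row_no),
        )
    except ValidationError as e:
        if str(e).startswith("row "):
            raise
        raise ValidationError(f"row {row_no}: {e}") from None


def read_lot_table(path: str | Path) -> list[LOTRecord]:
    """Read a LOT-level CSV into validated records.

    Raises
    ------
    SchemaError
        If the header deviates from :data:`CSV_COLUMNS` (unknown, missing
        or reordered columns).
    ValidationError
        If any cell is out of enumeration or a record invariant fails;
        the message carries the 1-based data row number.
    """
    path = Path(path)
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise SchemaError("empty file: header row required") from None
        if tuple(header) != CSV_COLUMNS:
            unknown = [c for c in header if c not in CSV_COLUMNS]
            missing = [c for c in CSV_COLUMNS if c not in header]
            detail = []
            if unknown:
                detail.append(f"unknown column(s) {unknown}")
            if missing:
                detail.append(f"missing column(s) {missing}")
            if not detail:
                detail.append("columns out of canonical order")
            raise SchemaError("; ".join(detail))
        records = []
        for i, raw in enumerate(reader, start=1):
            if len(raw) != len(CSV_COLUMNS):
                raise ValidationError(
                    f"row {i}: expected {len(CSV_COLUMNS)} fields, got {len(raw)}"
                )
            records.append(_row_to_record(dict(zip(CSV_COLUMNS, raw)), i))
    return records


def write_lot_table(records: Iterable[LOTRecord], path: str | Path) -> None:
    """Write records to CSV; ``read_lot_table`` inverts it field-for-field."""
    path = Path(path)
    path.write_text(records_to_csv(records), encoding="utf-8")


def records_to_csv(records: Iterable[LOTRecord]) -> str:
    buf = io.StringIO()
    writer = csv.writer(buf, lineterminator="\n")
    writer.writerow(CSV_COLUMNS)
    for r in records:
        writer.writerow(_record_to_row(r))
    return buf.getvalue()


def with_covariates(record: LOTRecord, **changes) -> LOTRecord:
    """Copy of ``record`` with the named covariate fields replaced."""
    return replace(record, covariates=replace(record.covariates, **changes))
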