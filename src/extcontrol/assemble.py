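"""Analysis-set assembly: per-LOT eligibility filtering and endpoint checks.

Control LOTs enter the analysis only if, at initiation, the patient had
an ECOG performance status of 0 or 1, prior platinum-based therapy, and
a confirmed activating-mutation test; LOTs containing the trial agent
and every later LOT of that patient are excluded.  Trial records are
retained as-is.  Filters report exclusions, they never raise.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Optional

from .model import RWPC, TRIAL, AnalysisSet, LOTRecord

#: Fixed rule-application order; a LOT is counted once, under the first
#: rule it fails.
RULE_ORDER = ("ecog", "platinum", "testing", "amivantamab_or_subsequent")


@dataclass
class EligibilityReport:
    input_lots: int = 0
    excluded_by_rule: dict[str, int] = field(default_factory=dict)
    retained: int = 0

    def check(self) -> None:
        assert self.input_lots == self.retained + sum(self.excluded_by_rule.values())


def _failing_rule(record: LOTRecord, amivantamab_seen: bool) -> Optional[str]:
    if record.covariates.ecog not in (0, 1):  # schema already enforces; kept for clarity
        return "ecog"
    if not record.prior_platinum:
        return "platinum"
    if not record.egfr_tested_before:
        return "testing"
    if record.contains_amivantamab or amivantamab_seen:
        return "amivantamab_or_subsequent"
    return None


def assemble(records: Iterable[LOTRecord]) -> tuple[AnalysisSet, EligibilityReport]:
    """Apply per-LOT eligibility rules and build the analysis set.

    Each control LOT is judged independently against the ECOG, platinum
    and testing rules; the trial-agent rule is history-aware (a LOT
    containing the agent and all subsequent LOTs of that patient are
    dropped).  Per-rule exclusion counts follow :data:`RULE_ORDER`.
    """
    records = list(records)
    report = EligibilityReport(input_lots=len(records))
    report.excluded_by_rule = {}

    # The trial-agent rule needs each patient's history in line order.
    ami_before: dict[tuple[str, int], bool] = {}
    by_patient: dict[str, list[LOTRecord]] = {}
    for r in records:
        if r.cohort == RWPC:
            by_patient.setdefault(r.patient_id, []).append(r)
    for pid, lots in by_patient.items():
        seen = False
        for r in sorted(lots, key=lambda x: x.lot_seq):
            ami_before[(pid, r.lot_seq)] = seen
            seen = seen or r.contains_amivantamab

    kept: list[LOTRecord] = []
    for r in records:
        if r.cohort == TRIAL:
            kept.append(r)
            continue
        rule = _failing_rule(r, ami_before[(r.patient_id, r.lot_seq)])
        if rule is None:
            kept.append(r)
        else:
            report.excluded_by_rule[rule] = report.excluded_by_rule.get(rule, 0) + 1

    report.retained = len(kept)
    report.check()
    return AnalysisSet(records=kept), report


def derive_orr_flag(record: LOTRecord) -> str:
    """Response-evaluability status: ``responder`` / ``non_responder`` /
    ``excluded`` (missing response; dropped from response analyses only,
    kept for the time-to-event endpoints)."""
    if record.response is None:
        return "excluded"
    return record.response


@dataclass
class ConsistencyReport:
    """Endpoint-ordering audit.

    ``violations`` break the hard invariant (an observed death earlier
    than a progression or next-therapy time); ``suspicious`` records are
    internally possible but clinically odd (censored survival shorter
    than an observed progression/next-therapy event, e.g. survival
    follow-up lost before the progression assessment) and are flagged,
    not fatal.
    """

    violations: list[tuple[str, int, str]] = field(default_factory=list)
    suspicious: list[tuple[str, int, str]] = field(default_factory=list)

    @property
    def ok(self) -> bool:
        return not self.violations and not self.suspicious


def check_endpoint_consistency(data) -> ConsistencyReport:
    """Audit endpoint orderings.

    Accepts an :class:`AnalysisSet` or any iterable of row objects with
    ``patient_id``, ``lot_seq``, ``{pfs,ttnt,os}_days`` and ``os_event``
    attributes/keys (validated records can never carry a hard violation,
    so raw pre-validation rows are accepted too).
    """
    import pandas as pd

    if isinstance(data, AnalysisSet):
        rows = data.records
    elif isinstance(data, pd.DataFrame):
        rows = list(data.itertuples(index=False))
    else:
        rows = list(data)

    def get(row, name):
        return row[name] if isinstance(row, dict) else getattr(row, name)

    report = ConsistencyReport()
    for r in rows:
        os_days, os_event = get(r, "os_days"), bool(get(r, "os_event"))
        for name in ("pfs", "ttnt"):
            if get(r, f"{name}_days") > os_days:
                key = (get(r, "patient_id"), get(r, "lot_seq"), f"{name}_days > os_days")
                if os_event:
                    report.violations.append(key)
                else:
                    report.suspicious.append(key)
    return report
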