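"""Neighbour-rule imputation of block-missing metastatic-site fields.

A control LOT whose metastatic work-up was not recorded borrows it from
the nearest observed LOTs of the same patient:

* both neighbours observed and concordant for a site → that value;
* both observed but discordant (in either direction) → presence is
  imputed, conservative toward disease progression;
* only a prior LOT observed → last observation carried forward;
* only a subsequent LOT observed → its value carried backward;
* no observed LOT at all → left missing and counted unimputable.

"Prior"/"subsequent" mean the nearest *observed* LOT by line number, so
a run of consecutive missing lines is still imputable from the lines
flanking the run.
"""

from __future__ import annotations

from dataclasses import dataclass, replace
from typing import Optional

from .model import MET_SITES, RWPC, AnalysisSet, LOTRecord


@dataclass
class ImputationAudit:
    n_missing_before: int = 0
    n_rule_both: int = 0
    n_rule_prior_only: int = 0
    n_rule_subsequent_only: int = 0
    n_unimputable: int = 0

    @property
    def n_missing_after(self) -> int:
        return self.n_unimputable

    def check(self) -> None:
        assert self.n_missing_before == (
            self.n_rule_both
            + self.n_rule_prior_only
            + self.n_rule_subsequent_only
            + self.n_unimputable
        )


def _impute_site(prior: Optional[bool], subsequent: Optional[bool]) -> Optional[bool]:
    if prior is not None and subsequent is not None:
        return prior if prior == subsequent else True  # discordance → presence
    if prior is not None:
        return prior  # carried forward
    if subsequent is not None:
        return subsequent  # carried backward
    return None


def impute_metastases(analysis_set: AnalysisSet) -> tuple[AnalysisSet, ImputationAudit]:
    """Fill block-missing metastasis fields; observed values are never altered."""
    audit = ImputationAudit()
    by_patient: dict[str, list[int]] = {}
    records = list(analysis_set.records)
    for i, r in enumerate(records):
        if r.cohort == RWPC:
            by_patient.setdefault(r.patient_id, []).append(i)

    new_records = records.copy()
    for pid, idxs in by_patient.items():
        idxs = sorted(idxs, key=lambda i: records[i].lot_seq)
        for pos, i in enumerate(idxs):
            rec = records[i]
            if not rec.covariates.sites_missing:
                continue
            audit.n_missing_before += 1
            prior_rec = next(
                (records[j] for j in reversed(idxs[:pos]) if not records[j].covariates.sites_missing),
                None,
            )
            subsequent_rec = next(
                (records[j] for j in idxs[pos + 1 :] if not records[j].covariates.sites_missing),
                None,
            )
            if prior_rec is not None and subsequent_rec is not None:
                audit.n_rule_both += 1
            elif prior_rec is not None:
                audit.n_rule_prior_only += 1
            elif subsequent_rec is not None:
                audit.n_rule_subsequent_only += 1
            else:
                audit.n_unimputable += 1
                continue
            filled = {
                s: _impute_site(
                    None if prior_rec is None else getattr(prior_rec.covariates, s),
                    None if subsequent_rec is None else getattr(subsequent_rec.covariates, s),
                )
                for s in MET_SITES
            }
            new_records[i] = replace(rec, covariates=replace(rec.covariates, **filled))

    audit.check()
    return AnalysisSet(records=new_records), audit
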