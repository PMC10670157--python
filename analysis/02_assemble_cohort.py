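#!/usr/bin/env python
"""Assemble the analysis set: per-LOT eligibility rules + endpoint audit.

Reads results/cohort_raw.csv, applies the ECOG / prior-platinum /
mutation-testing / trial-agent rules, checks endpoint orderings, and
writes results/analysis_set.csv plus results/eligibility.json.
"""

import json
from pathlib import Path

import extcontrol as ec

OUT = Path(__file__).resolve().parents[1] / "results"

records = ec.read_lot_table(OUT / "cohort_raw.csv")
aset, report = ec.assemble(records)
ec.write_lot_table(aset.records, OUT / "analysis_set.csv")
(OUT / "eligibility.json").write_text(
    json.dumps(
        {
            "input_lots": report.input_lots,
            "excluded_by_rule": report.excluded_by_rule,
            "retained": report.retained,
        },
        indent=2,
    )
)
print(f"eligibility: retained {report.retained}/{report.input_lots} LOTs; "
      f"exclusions by rule: {report.excluded_by_rule or 'none'}")

consistency = ec.check_endpoint_consistency(aset)
print(f"endpoint audit: {len(consistency.violations)} violations, "
      f"{len(consistency.suspicious)} suspicious records")
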