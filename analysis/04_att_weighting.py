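#!/usr/bin/env python
"""Propensity-score ATT weighting and covariate balance.

Reads results/imputed.csv; fits the main-effects logistic propensity
model for trial membership; writes per-LOT weights (results/weights.csv)
and the balance table (results/balance.csv).
"""

from pathlib import Path

import extcontrol as ec

OUT = Path(__file__).resolve().parents[1] / "results"

frame = ec.AnalysisSet(records=ec.read_lot_table(OUT / "imputed.csv")).to_frame()
fit = ec.att_weights(ec.fit_propensity(frame))

wdf = frame[["patient_id", "cohort", "lot_seq"]].copy()
wdf["ps"] = fit.ps
wdf["raw_weight"] = fit.raw_weight
wdf["weight"] = fit.weight
wdf.to_csv(OUT / "weights.csv", index=False)

balance = ec.balance_table(frame, fit)
balance.to_frame().to_csv(OUT / "balance.csv", index=False)

n_control = int((fit.treat == 0).sum())
print(f"control weight sum: {fit.weight[fit.treat == 0].sum():.9f} "
      f"(n_control = {n_control}, renorm factor {fit.renorm_factor:.4f})")
print(f"max |SMD|: {balance.max_abs_smd(weighted=False):.3f} unweighted -> "
      f"{balance.max_abs_smd(weighted=True):.3f} after ATT weighting")
ov = fit.overlap_summary()
print(f"propensity overlap: trial [{ov['trial'][0]:.3f}, {ov['trial'][1]:.3f}], "
      f"control [{ov['control'][0]:.3f}, {ov['control'][1]:.3f}]")
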