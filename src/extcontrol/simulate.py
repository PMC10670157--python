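"""Synthetic two-cohort LOT-level data generator.

Emulates the statistical structure the downstream analysis assumes:

* a single-arm trial cohort (one LOT per patient) and a real-world
  control cohort in which patients contribute repeated eligible lines of
  therapy (LOTs);
* confounding through cohort-specific baseline covariate margins;
* within-patient outcome correlation through a mean-one gamma frailty
  multiplying every hazard of a patient;
* proportional-hazards exponential event times (progression, death) and
  a logistic tumour-response model, each with configurable treatment and
  covariate effects;
* block missingness of the seven metastatic-site fields on control
  LOTs, masked so that every masked LOT keeps an observed neighbouring
  LOT and therefore stays imputable (unless explicitly allowed).

``fixture_missingness_pattern`` builds the deterministic 114 + 55 record
fixture whose missingness layout (9 block-missing LOTs from 8 patients:
3 with both neighbours observed, 4 with only a prior LOT, 2 with only a
subsequent LOT) mirrors the chart-review cohort, and whose response
counts (42/114 trial responders; 9 responders, 1 missing among 55
control LOTs) reproduce the published unadjusted response contrast.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Optional

import numpy as np

from .model import (
    AGE_LEVELS,
    DAYS_PER_MONTH,
    MET_SITES,
    PRIOR_LINES_LEVELS,
    RWPC,
    TRIAL,
    AnalysisSet,
    CovariateProfile,
    LOTRecord,
)


class ConfigError(ValueError):
    """The simulation configuration is invalid; raised before any sampling."""


# Baseline category probabilities per cohort.  TRIAL matches the trial
# arm's published marginals; RWPC matches the post-imputation control
# marginals (55 LOTs).
DEFAULT_MARGINS: dict[str, dict[str, dict[str, float]]] = {
    TRIAL: {
        "ecog": {"0": 33 / 114, "1": 81 / 114},
        "prior_lines": {"1": 48 / 114, "2": 34 / 114, "3plus": 32 / 114},
        "brain_met": {"yes": 29 / 114, "no": 85 / 114},
        "liver_met": {"yes": 13 / 114, "no": 101 / 114},
        "bone_met": {"yes": 51 / 114, "no": 63 / 114},
        "lymph_met": {"yes": 62 / 114, "no": 52 / 114},
        "adrenal_met": {"yes": 6 / 114, "no": 108 / 114},
        "pleural_met": {"yes": 31 / 114, "no": 83 / 114},
        "other_met": {"yes": 42 / 114, "no": 72 / 114},
        "age_cat": {"lt65": 67 / 114, "65to75": 38 / 114, "ge75": 9 / 114},
    },
    RWPC: {
        "ecog": {"0": 23 / 55, "1": 32 / 55},
        "prior_lines": {"1": 24 / 55, "2": 17 / 55, "3plus": 14 / 55},
        "brain_met": {"yes": 8 / 55, "no": 47 / 55},
        "liver_met": {"yes": 11 / 55, "no": 44 / 55},
        "bone_met": {"yes": 27 / 55, "no": 28 / 55},
        "lymph_met": {"yes": 23 / 55, "no": 32 / 55},
        "adrenal_met": {"yes": 3 / 55, "no": 52 / 55},
        "pleural_met": {"yes": 18 / 55, "no": 37 / 55},
        "other_met": {"yes": 39 / 55, "no": 16 / 55},
        "age_cat": {"lt65": 30 / 55, "65to75": 17 / 55, "ge75": 8 / 55},
    },
}


@dataclass(frozen=True)
class LogisticModel:
    """Response model: logit P(responder) = intercept + treat*treat_delta + x'beta."""

    intercept: float = math.log(0.167 / 0.833)  # control response rate 16.7%
    treat_delta: float = math.log(2.92)  # unadjusted odds ratio scale
    cov_effects: dict[str, float] = field(default_factory=dict)


@dataclass(frozen=True)
class HazardModel:
    """Exponential PH model: hazard = rate * exp(treat*treat_loghr + x'beta)."""

    rate: float
    treat_loghr: float = 0.0
    cov_effects: dict[str, float] = field(default_factory=dict)


def _default_hazards() -> dict[str, HazardModel]:
    # Baseline rates matched to the published unadjusted control medians
    # (PFS 4.86 months, OS 11.47 months); treatment log-hazards set to the
    # published ATT-adjusted ratios.  The "ttnt" model parameterizes the
    # exponential delay between progression and the next systemic therapy.
    return {
        "pfs": HazardModel(
            rate=math.log(2) / (4.86 * DAYS_PER_MONTH),
            treat_loghr=math.log(0.42),
            cov_effects={"ecog=1": 0.35, "other_met=yes": 0.25},
        ),
        "os": HazardModel(
            rate=math.log(2) / (11.47 * DAYS_PER_MONTH),
            treat_loghr=math.log(0.48),
            cov_effects={"ecog=1": 0.45, "adrenal_met=yes": 0.35},
        ),
        "ttnt": HazardModel(rate=1 / 33.0, treat_loghr=0.0),
    }


@dataclass
class SimConfig:
    """Study-condition defaults for the synthetic generator."""

    seed: int = 0
    n_trial: int = 114
    n_control_patients: int = 38
    #: mean extra LOTs per control patient, Poisson truncated at 3
    #: (max 4 LOTs); 0.45 makes the expected control LOT count ~ 55.
    lot_rate: float = 0.45
    covariate_margins: dict[str, dict[str, dict[str, float]]] = field(
        default_factory=lambda: {c: {f: dict(m) for f, m in d.items()} for c, d in DEFAULT_MARGINS.items()}
    )
    response_model: LogisticModel = field(default_factory=LogisticModel)
    hazard_models: dict[str, HazardModel] = field(default_factory=_default_hazards)
    frailty_variance: float = 0.5
    censor_rate: float = 0.0008  # per day
    admin_cap_days: int = 760
    missing_block_prob: float = 9 / 55
    response_missing_prob: float = 1 / 55  # control LOTs only
    #: per-line probability a previously absent metastatic site appears
    site_progression_prob: float = 0.10
    allow_unimputable: bool = False

    def validate(self) -> None:
        if self.n_trial < 0 or self.n_control_patients < 0:
            raise ConfigError("cohort sizes must be non-negative")
        if self.lot_rate < 0:
            raise ConfigError("lot_rate must be >= 0")
        if self.frailty_variance < 0:
            raise ConfigError("frailty_variance must be >= 0")
        if self.censor_rate < 0:
            raise ConfigError("censor_rate must be >= 0")
        if self.admin_cap_days <= 0:
            raise ConfigError("admin_cap_days must be positive")
        for p_name in ("missing_block_prob", "response_missing_prob", "site_progression_prob"):
            p = getattr(self, p_name)
            if not 0 <= p <= 1:
                raise ConfigError(f"{p_name} must be in [0, 1]")
        for name, model in self.hazard_models.items():
            if model.rate <= 0:
                raise ConfigError(f"hazard model {name!r}: rate must be > 0")
        for cohort, fields_ in self.covariate_margins.items():
            if cohort not in (TRIAL, RWPC):
                raise ConfigError(f"unknown cohort {cohort!r} in covariate_margins")
            for fname, margin in fields_.items():
                probs = list(margin.values())
                if any(p < 0 or p > 1 for p in probs):
                    raise ConfigError(f"{cohort}/{fname}: probabilities must be in [0, 1]")
                if abs(sum(probs) - 1.0) > 1e-9:
                    raise ConfigError(f"{cohort}/{fname}: probabilities must sum to 1")


def profile_dummies(cov: CovariateProfile) -> dict[str, float]:
    """Dummy-coded covariate values against the reference levels
    (ecog 0, prior_lines 1, each site absent, age < 65)."""
    d = {
        "ecog=1": float(cov.ecog == 1),
        "prior_lines=2": float(cov.prior_lines == "2"),
        "prior_lines=3plus": float(cov.prior_lines == "3plus"),
    }
    for s in MET_SITES:
        v = getattr(cov, s)
        d[f"{s}=yes"] = 0.0 if v is None else float(v)
    d["age_cat=65to75"] = float(cov.age_cat == "65to75")
    d["age_cat=ge75"] = float(cov.age_cat == "ge75")
    return d


def _lp(dummies: dict[str, float], effects: dict[str, float]) -> float:
    unknown = set(effects) - set(dummies)
    if unknown:
        raise ConfigError(f"unknown covariate effect term(s): {sorted(unknown)}")
    return sum(effects[k] * dummies[k] for k in effects)


def _draw_profile(rng: np.random.Generator, margins: dict[str, dict[str, float]]) -> CovariateProfile:
    def pick(fname: str) -> str:
        m = margins[fname]
        levels = list(m.keys())
        return levels[rng.choice(len(levels), p=np.asarray(list(m.values())))]

    sites = {s: pick(s) == "yes" for s in MET_SITES}
    return CovariateProfile(
        ecog=int(pick("ecog")),
        prior_lines=pick("prior_lines"),
        age_cat=pick("age_cat"),
        **sites,
    )


def _bump_prior_lines(level: str) -> str:
    i = PRIOR_LINES_LEVELS.index(level)
    return PRIOR_LINES_LEVELS[min(i + 1, len(PRIOR_LINES_LEVELS) - 1)]


def _evolve_profile(rng: np.random.Generator, cov: CovariateProfile, p_new_site: float) -> CovariateProfile:
    """Next-line covariates: sites only ever appear, prior lines increment."""
    changes: dict[str, object] = {"prior_lines": _bump_prior_lines(cov.prior_lines)}
    for s in MET_SITES:
        if getattr(cov, s) is False and rng.random() < p_new_site:
            changes[s] = True
    return replace(cov, **changes)


def _draw_outcomes(
    rng: np.random.Generator,
    config: SimConfig,
    cov: CovariateProfile,
    treat: bool,
    frailty: float,
) -> dict[str, object]:
    x = profile_dummies(cov)
    hm = config.hazard_models
    t = float(treat)
    prog_rate = hm["pfs"].rate * frailty * math.exp(t * hm["pfs"].treat_loghr + _lp(x, hm["pfs"].cov_effects))
    death_rate = hm["os"].rate * frailty * math.exp(t * hm["os"].treat_loghr + _lp(x, hm["os"].cov_effects))
    delay_rate = hm["ttnt"].rate * math.exp(t * hm["ttnt"].treat_loghr)

    progression = rng.exponential(1 / prog_rate)
    death = rng.exponential(1 / death_rate)
    delay = rng.exponential(1 / delay_rate)
    followup = min(
        rng.exponential(1 / config.censor_rate) if config.censor_rate > 0 else math.inf,
        float(config.admin_cap_days),
    )

    pfs_t = min(progression, death)
    ttnt_t = min(progression + delay, death)

    rm = config.response_model
    p_resp = 1 / (1 + math.exp(-(rm.intercept + t * rm.treat_delta + _lp(x, rm.cov_effects))))
    response: Optional[str] = "responder" if rng.random() < p_resp else "non_responder"
    if not treat and rng.random() < config.response_missing_prob:
        response = None

    def obs(event_time: float) -> tuple[int, bool]:
        return int(round(min(event_time, followup))), event_time <= followup

    pfs_days, pfs_event = obs(pfs_t)
    ttnt_days, ttnt_event = obs(ttnt_t)
    os_days, os_event = obs(death)
    return {
        "response": response,
        "pfs_days": pfs_days,
        "pfs_event": pfs_event,
        "ttnt_days": ttnt_days,
        "ttnt_event": ttnt_event,
        "os_days": os_days,
        "os_event": os_event,
    }


def _draw_frailty(rng: np.random.Generator, theta: float) -> float:
    if theta == 0:
        return 1.0
    return float(rng.gamma(shape=1 / theta, scale=theta))


def simulate_cohort(config: SimConfig) -> AnalysisSet:
    """Simulate a two-cohort analysis set; identical seeds give identical output."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    records: list[LOTRecord] = []

    for i in range(config.n_trial):
        cov = _draw_profile(rng, config.covariate_margins[TRIAL])
        frailty = _draw_frailty(rng, config.frailty_variance)
        out = _draw_outcomes(rng, config, cov, treat=True, frailty=frailty)
        if out["response"] is None:  # response missingness modelled on controls only
            out["response"] = "non_responder"
        records.append(
            LOTRecord(
                patient_id=f"T{i:04d}",
                cohort=TRIAL,
                lot_seq=1,
                covariates=cov,
                egfr_tested_before=True,
                prior_platinum=True,
                contains_amivantamab=True,
                **out,
            )
        )

    control_idx: list[int] = []  # indices into records, for masking
    patient_lots: dict[str, list[int]] = {}
    for j in range(config.n_control_patients):
        pid = f"C{j:04d}"
        n_lots = 1 + min(int(rng.poisson(config.lot_rate)), 3)
        cov = _draw_profile(rng, config.covariate_margins[RWPC])
        frailty = _draw_frailty(rng, config.frailty_variance)
        for k in range(1, n_lots + 1):
            if k > 1:
                cov = _evolve_profile(rng, cov, config.site_progression_prob)
            out = _draw_outcomes(rng, config, cov, treat=False, frailty=frailty)
            records.append(
                LOTRecord(
                    patient_id=pid,
                    cohort=RWPC,
                    lot_seq=k,
                    covariates=cov,
                    egfr_tested_before=True,
                    prior_platinum=True,
                    contains_amivantamab=False,
                    **out,
                )
            )
            control_idx.append(len(records) - 1)
            patient_lots.setdefault(pid, []).append(len(records) - 1)

    # Block-mask metastatic sites on control LOTs.  Unless unimputable
    # records are explicitly allowed, a mask is only applied when the
    # patient keeps at least one observed LOT, so the neighbour rules can
    # always fill the block back in.
    masked: dict[str, int] = {}
    for idx in control_idx:
        if rng.random() >= config.missing_block_prob:
            continue
        pid = records[idx].patient_id
        if not config.allow_unimputable:
            n_unmasked = len(patient_lots[pid]) - masked.get(pid, 0)
            if n_unmasked <= 1:
                continue
        masked[pid] = masked.get(pid, 0) + 1
        records[idx] = _mask_sites(records[idx])

    return AnalysisSet(records=records)


def _mask_sites(record: LOTRecord) -> LOTRecord:
    return replace(record, covariates=replace(record.covariates, **{s: None for s in MET_SITES}))


# ---------------------------------------------------------------------------
# Deterministic fixture reproducing the chart-review missingness layout


def _assign_levels(rng: np.random.Generator, counts: dict[str, int]) -> list[str]:
    levels = [lvl for lvl, n in counts.items() for _ in range(n)]
    rng.shuffle(levels)
    return levels


_TRIAL_COUNTS = {
    "ecog": {"0": 33, "1": 81},
    "prior_lines": {"1": 48, "2": 34, "3plus": 32},
    "brain_met": {"yes": 29, "no": 85},
    "liver_met": {"yes": 13, "no": 101},
    "bone_met": {"yes": 51, "no": 63},
    "lymph_met": {"yes": 62, "no": 52},
    "adrenal_met": {"yes": 6, "no": 108},
    "pleural_met": {"yes": 31, "no": 83},
    "other_met": {"yes": 42, "no": 72},
    "age_cat": {"lt65": 67, "65to75": 38, "ge75": 9},
}

# Control patients: 27 with one LOT, 6 with two, 4 with three, 1 with four
# (38 patients, 55 LOTs).
_CONTROL_STRUCTURE = [1] * 27 + [2] * 6 + [3] * 4 + [4]


def fixture_missingness_pattern(seed: int = 20231108) -> AnalysisSet:
    """Deterministic 114-trial + 55-control-LOT analysis set.

    Exactly 9 control LOTs from 8 unique patients carry a block-missing
    metastasis profile: 3 with both neighbouring LOTs observed (one of
    them discordant — the site absent before and present after), 4 with
    only a prior LOT observed, and 2 with only a subsequent LOT
    observed.  Response counts are fixed at 42/114 trial responders and
    9 responders / 45 non-responders / 1 missing among the 55 control
    LOTs, so the unadjusted response contrast of the published study is
    reproduced from this fixture alone.
    """
    rng = np.random.default_rng(seed)
    sim = SimConfig(seed=seed)
    records: list[LOTRecord] = []

    trial_levels = {f: _assign_levels(rng, c) for f, c in _TRIAL_COUNTS.items()}
    trial_resp = _assign_levels(rng, {"responder": 42, "non_responder": 72})
    for i in range(114):
        cov = CovariateProfile(
            ecog=int(trial_levels["ecog"][i]),
            prior_lines=trial_levels["prior_lines"][i],
            age_cat=trial_levels["age_cat"][i],
            **{s: trial_levels[s][i] == "yes" for s in MET_SITES},
        )
        out = _draw_outcomes(rng, sim, cov, treat=True, frailty=1.0)
        out["response"] = trial_resp[i]
        records.append(
            LOTRecord(
                patient_id=f"T{i:04d}",
                cohort=TRIAL,
                lot_seq=1,
                covariates=cov,
                egfr_tested_before=True,
                prior_platinum=True,
                contains_amivantamab=True,
                **out,
            )
        )

    # Patient-level base covariates; sites stay constant over a patient's
    # lines (monotone trivially), prior_lines increments per line.
    base_ecog = _assign_levels(rng, {"0": 16, "1": 22})
    base_age = _assign_levels(rng, {"lt65": 21, "65to75": 12, "ge75": 5})
    base_prior = _assign_levels(rng, {"1": 20, "2": 12, "3plus": 6})
    base_sites = {
        "brain_met": _assign_levels(rng, {"yes": 6, "no": 32}),
        "liver_met": _assign_levels(rng, {"yes": 8, "no": 30}),
        "bone_met": _assign_levels(rng, {"yes": 18, "no": 20}),
        "lymph_met": _assign_levels(rng, {"yes": 16, "no": 22}),
        "adrenal_met": _assign_levels(rng, {"yes": 2, "no": 36}),
        "pleural_met": _assign_levels(rng, {"yes": 13, "no": 25}),
        "other_met": _assign_levels(rng, {"yes": 27, "no": 11}),
    }
    control_resp = _assign_levels(
        rng, {"responder": 9, "non_responder": 45, "missing": 1}
    )

    lot_counter = 0
    control_records: dict[tuple[str, int], int] = {}
    for j, n_lots in enumerate(_CONTROL_STRUCTURE):
        pid = f"C{j:02d}"
        sites = {s: base_sites[s][j] == "yes" for s in MET_SITES}
        prior = base_prior[j]
        for k in range(1, n_lots + 1):
            if k > 1:
                prior = _bump_prior_lines(prior)
            cov = CovariateProfile(
                ecog=int(base_ecog[j]),
                prior_lines=prior,
                age_cat=base_age[j],
                **sites,
            )
            out = _draw_outcomes(rng, sim, cov, treat=False, frailty=1.0)
            resp = control_resp[lot_counter]
            out["response"] = None if resp == "missing" else resp
            records.append(
                LOTRecord(
                    patient_id=pid,
                    cohort=RWPC,
                    lot_seq=k,
                    covariates=cov,
                    egfr_tested_before=True,
                    prior_platinum=True,
                    contains_amivantamab=False,
                    **out,
                )
            )
            control_records[(pid, k)] = len(records) - 1
            lot_counter += 1

    # Discordant both-neighbour case on patient C33 (three LOTs): bone
    # metastasis absent at line 1, present at line 3 (monotone appearance),
    # line 2 masked.  Patients C27..C32 have two LOTs, C33..C36 three,
    # C37 four.
    for k, bone in ((1, False), (2, True), (3, True)):
        idx = control_records[("C33", k)]
        records[idx] = replace(
            records[idx], covariates=replace(records[idx].covariates, bone_met=bone)
        )

    both = [("C33", 2), ("C34", 2), ("C37", 2)]
    prior_only = [("C27", 2), ("C28", 2), ("C29", 2), ("C37", 4)]
    subsequent_only = [("C30", 1), ("C31", 1)]
    for key in both + prior_only + subsequent_only:
        idx = control_records[key]
        records[idx] = _mask_sites(records[idx])

    return AnalysisSet(records=records)
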