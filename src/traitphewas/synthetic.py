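"""Seeded synthetic EHR cohorts with injectable effects.

The generator emulates the structure the scan assumes — a trimodal
quantitative trait split 52:413:89 across low/normal/very-high groups,
per-patient encounter streams, ICD-10 occurrence streams drawn from the
toy terminology universe, lab time series with threshold excursions and
a post-treatment event hazard, and treatment-start mentions — without
resembling any real patient. Effect sizes (diagnosis odds ratios per
phenotype group, event hazard ratios, efficacy-failure odds) are
injected through the config and exported as a machine-readable truth
table so parameter-recovery tests can close the loop.

All randomness flows from the mandatory seed; the same config writes
byte-identical bundles.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .cohort import Cohort, TraitCuts
from .terminology import Terminology, build_block_groups, load_hierarchy

__all__ = ["SimConfig", "generate_cohort", "truth_table", "toy_terminology"]

#: group share of the emulated population: deficient / normal / very high
DEFAULT_PROPORTIONS = (52 / 554, 413 / 554, 89 / 554)

#: trait mixture components (mean, sd) in nmol/h/mL RBC; fixture values
#: straddling the 8.5 and 15.0 cut-points, not study measurements.
DEFAULT_MIXTURE = {"low": (5.0, 1.5), "normal": (12.0, 1.5), "very_high": (17.0, 1.5)}

GROUP_ORDER = ("low", "normal", "very_high")


def toy_terminology() -> Terminology:
    """Block-scheme terminology over the packaged toy hierarchy."""
    return build_block_groups(load_hierarchy())


@dataclass(frozen=True)
class SimConfig:
    seed: int
    n_patients: int = 554
    group_proportions: tuple[float, float, float] = DEFAULT_PROPORTIONS
    trait_mixture: dict = field(default_factory=lambda: dict(DEFAULT_MIXTURE))
    cuts: TraitCuts = TraitCuts()
    encounters_per_patient: float = 7.0  # Poisson mean, +1 floor
    treated_fraction: float = 0.95
    #: probability a comparator-group patient is a case for each phenotype group
    icd_baseline_p: float = 0.06
    #: injected diagnosis odds ratios: {group_id: {trait_group: OR}}
    injected_icd_or: dict = field(default_factory=dict)
    #: per-result excursion probabilities beyond the low/high thresholds
    lab_excursion_low: float = 0.04
    lab_excursion_high: float = 0.04
    lab_tests: tuple[str, ...] = ("hemoglobin", "neutrophils", "glycemia")
    results_per_encounter: float = 1.5  # Poisson mean per test
    #: daily hazard of the survival event (anemia) in the comparator groups
    event_hazard_per_day: float = 1.0 / 400.0
    event_test: str = "hemoglobin"
    #: injected hazard ratios per trait group for the survival event
    injected_event_hr: dict = field(default_factory=dict)
    #: efficacy failure: comparator probability and injected OR per group
    efficacy_failure_p: float = 0.13
    injected_efficacy_or: dict = field(default_factory=dict)
    treatment_window_days: int = 365
    followup_days: int = 400

    def __post_init__(self) -> None:
        if self.seed is None:
            raise ValueError("seed is mandatory")
        if abs(sum(self.group_proportions) - 1) > 1e-9:
            raise ValueError("group proportions must sum to 1")
        for p in (self.treated_fraction, self.icd_baseline_p,
                  self.lab_excursion_low, self.lab_excursion_high,
                  self.efficacy_failure_p):
            if not 0 <= p <= 1:
                raise ValueError(f"probability {p} outside [0, 1]")
        if self.n_patients < 1:
            raise ValueError("n_patients must be positive")


def _odds_shift(p0: float, or_: float) -> float:
    """Case probability after applying an odds ratio to baseline p0."""
    odds = or_ * p0 / (1 - p0)
    return odds / (1 + odds)


def truth_table(config: SimConfig) -> pd.DataFrame:
    """Ground-truth injected effects, derivable from the config alone."""
    rows = []
    for gid, per_group in sorted(config.injected_icd_or.items()):
        for tg, or_ in sorted(per_group.items()):
            rows.append(("icd", gid, tg, "odds_ratio", float(or_)))
    for tg, hr in sorted(config.injected_event_hr.items()):
        rows.append(("survival", config.event_test, tg, "hazard_ratio", float(hr)))
    for tg, or_ in sorted(config.injected_efficacy_or.items()):
        rows.append(("efficacy", "failure", tg, "odds_ratio", float(or_)))
    return pd.DataFrame(
        rows, columns=["kind", "target", "trait_group", "parameter", "value"]
    )


# lab value generators: (mean, sd) mid-range plus threshold-crossing draws
_LAB_FIELDS = {
    "leukocytes": (7.0, 1.2, 2.5, 14.0),
    "neutrophils": (4.0, 1.0, 0.6, 9.5),
    "rbc": (4.8, 0.3, 3.2, 6.2),
    "hemoglobin": (13.0, 1.0, 7.8, 18.0),
    "mcv": (90.0, 4.0, 72.0, 108.0),
    "platelets": (280.0, 50.0, 90.0, 520.0),
    "glycemia": (0.95, 0.1, 0.55, 1.8),
    "alp": (85.0, 18.0, 25.0, 170.0),
    "alt": (25.0, 7.0, 10.0, 80.0),
    "ast": (25.0, 7.0, 10.0, 80.0),
    "ggt": (35.0, 10.0, 12.0, 110.0),
}


def generate_cohort(
    config: SimConfig, terminology: Terminology | None = None
) -> Cohort:
    """Draw one cohort bundle from the configured world.

    Trait activities come from the per-group mixture and are then
    group-labelled downstream by the same cut-points the pipeline uses,
    so a draw crossing a cut-point lands in the cut-implied group.
    Diagnosis codes are sampled from the toy terminology universe with
    per-group case probabilities shifted by the injected odds ratios.
    """
    term = terminology or toy_terminology()
    rng = np.random.default_rng(config.seed)
    n = config.n_patients
    pids = np.array([f"P{i:05d}" for i in range(n)])

    group_idx = rng.choice(3, size=n, p=np.asarray(config.group_proportions))
    groups = np.array(GROUP_ORDER, dtype=object)[group_idx]
    mu = np.array([config.trait_mixture[g][0] for g in groups])
    sd = np.array([config.trait_mixture[g][1] for g in groups])
    activity = np.clip(rng.normal(mu, sd), 0.05, None).round(2)

    sex = np.where(rng.random(n) < 0.5, "female", "male")
    birth_year = rng.integers(1930, 1996, size=n)
    patients = pd.DataFrame(
        {"patient_id": pids, "sex": sex, "birth_year": birth_year}
    )

    base = pd.Timestamp("2006-01-01")
    start_offsets = rng.integers(0, config.treatment_window_days, size=n)
    starts = base + pd.to_timedelta(start_offsets, unit="D")
    assays = pd.DataFrame(
        {
            "patient_id": pids,
            "date": starts - pd.to_timedelta(rng.integers(5, 60, size=n), unit="D"),
            "activity": activity,
        }
    )

    treated = rng.random(n) < config.treated_fraction
    mentions = pd.DataFrame(
        {
            "patient_id": pids[treated],
            "date": starts[treated],
            "source": "report",
            "payload": "Introduction d'un traitement par AZATHIOPRINE (Imurel)",
        }
    )

    # encounters: one stream per patient from treatment start onward
    n_enc = rng.poisson(config.encounters_per_patient, size=n) + 1
    enc_pid = np.repeat(np.arange(n), n_enc)
    enc_day = rng.integers(0, config.followup_days, size=n_enc.sum())
    enc_dates = starts.to_numpy()[enc_pid] + enc_day * np.timedelta64(1, "D")
    enc_types = rng.choice(
        ["hospitalization", "consultation", "session", "emergency"],
        size=n_enc.sum(), p=[0.4, 0.16, 0.28, 0.16],
    )
    encounters = pd.DataFrame(
        {
            "encounter_id": [f"E{i:06d}" for i in range(n_enc.sum())],
            "patient_id": pids[enc_pid],
            "type": enc_types,
            "start_date": enc_dates,
            "end_date": enc_dates,
        }
    )

    # diagnoses: per phenotype group, Bernoulli case status with injected OR
    dx_pid_parts: list[np.ndarray] = []
    dx_code_parts: list[np.ndarray] = []
    p0 = config.icd_baseline_p
    for group in term.group_list():
        probs = np.full(n, p0)
        for tg, or_ in config.injected_icd_or.get(group.id, {}).items():
            probs[groups == tg] = _odds_shift(p0, or_)
        is_case = rng.random(n) < probs
        idx = np.nonzero(is_case)[0]
        if len(idx) == 0:
            continue
        n_occ = rng.integers(1, 3, size=len(idx))
        rep = np.repeat(idx, n_occ)
        r = group.case_ranges[0]
        keys = rng.integers(r.start.root_key, r.end.root_key + 1, size=len(rep))
        letters = np.array([chr(ord("A") + k // 100) for k in keys])
        codes = np.array(
            [f"{c}{k % 100:02d}{rng.integers(0, 10)}" for c, k in zip(letters, keys)]
        )
        dx_pid_parts.append(rep)
        dx_code_parts.append(codes)
    if dx_pid_parts:
        dx_idx = np.concatenate(dx_pid_parts)
        dx_codes = np.concatenate(dx_code_parts)
    else:
        dx_idx = np.zeros(0, dtype=int)
        dx_codes = np.zeros(0, dtype=object)
    dx_day = rng.integers(0, config.followup_days, size=len(dx_idx))
    diagnoses = pd.DataFrame(
        {
            "patient_id": pids[dx_idx],
            "encounter_id": "",
            "date": starts.to_numpy()[dx_idx] + dx_day * np.timedelta64(1, "D"),
            "code": dx_codes,
        }
    )
    diagnoses = diagnoses.sort_values(
        ["patient_id", "date", "code"], kind="stable"
    ).reset_index(drop=True)

    # labs: per encounter per test, mid-range values with threshold excursions
    lab_frames = []
    enc_ids = encounters["encounter_id"].to_numpy()
    for test in config.lab_tests:
        mid, spread, lo_val, hi_val = _LAB_FIELDS[test]
        n_res = rng.poisson(config.results_per_encounter, size=len(encounters))
        rep = np.repeat(np.arange(len(encounters)), n_res)
        total = int(n_res.sum())
        if total == 0:
            continue
        values = rng.normal(mid, spread, size=total)
        u = rng.random(total)
        values = np.where(u < config.lab_excursion_low,
                          rng.normal(lo_val, spread / 4, size=total), values)
        values = np.where(
            (u >= config.lab_excursion_low)
            & (u < config.lab_excursion_low + config.lab_excursion_high),
            rng.normal(hi_val, spread / 4, size=total), values)
        lab_frames.append(
            pd.DataFrame(
                {
                    "patient_id": encounters["patient_id"].to_numpy()[rep],
                    "encounter_id": enc_ids[rep],
                    "date": encounters["start_date"].to_numpy()[rep],
                    "test_id": test,
                    "value": np.round(np.abs(values), 2),
                }
            )
        )

    # survival event stream: exponential first-event time per patient with
    # the injected hazard ratio, materialized as a deep low excursion
    if config.event_test in config.lab_tests and config.event_hazard_per_day > 0:
        hazard = np.full(n, config.event_hazard_per_day)
        for tg, hr in config.injected_event_hr.items():
            hazard[groups == tg] *= hr
        event_day = np.ceil(rng.exponential(1 / hazard)).astype(int)
        hit = event_day <= config.followup_days
        if hit.any():
            mid, spread, lo_val, _ = _LAB_FIELDS[config.event_test]
            lab_frames.append(
                pd.DataFrame(
                    {
                        "patient_id": pids[hit],
                        "encounter_id": "",
                        "date": starts.to_numpy()[hit]
                        + event_day[hit] * np.timedelta64(1, "D"),
                        "test_id": config.event_test,
                        "value": np.round(
                            np.abs(rng.normal(lo_val, spread / 4, size=hit.sum())), 2
                        ),
                    }
                )
            )
    labs = (
        pd.concat(lab_frames, ignore_index=True)
        if lab_frames
        else pd.DataFrame(
            columns=["patient_id", "encounter_id", "date", "test_id", "value"]
        )
    )
    labs = labs.sort_values(
        ["patient_id", "test_id", "date", "value"], kind="stable"
    ).reset_index(drop=True)

    # efficacy failure flags with injected odds ratio
    pf = np.full(n, config.efficacy_failure_p)
    for tg, or_ in config.injected_efficacy_or.items():
        pf[groups == tg] = _odds_shift(config.efficacy_failure_p, or_)
    flags = pd.DataFrame(
        {"patient_id": pids, "failure": (rng.random(n) < pf).astype(int)}
    )

    return Cohort(
        patients=patients,
        assays=assays,
        encounters=encounters,
        diagnoses=diagnoses,
        labs=labs,
        mentions=mentions,
        flags=flags,
    )
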