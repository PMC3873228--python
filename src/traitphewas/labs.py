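"""Discretization of quantitative lab results into low/high-value cases.

Two phenotyping algorithms operate per test and direction:

* global — a patient is a case given at least one result strictly beyond
  the threshold (two distinct-time results for hyperglycemia), compared
  across trait groups with a 2x2 exactly like the ICD scan;
* frequency-based — per patient, the fraction of encounters containing
  at least one beyond-threshold result, compared across trait groups
  with a pooled-variance Student t-test.

Patients with no result for a test enter neither arm for that test, so
denominators vary test by test.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .assoc import _exposed_mask
from .stats import Contingency2x2, fisher_exact, fisher_p, sample_or_woolf, student_t
from .terminology import data_path

__all__ = [
    "LabThreshold",
    "LabConfigError",
    "load_thresholds",
    "global_case",
    "encounter_frequency",
    "compare_labs",
]


class LabConfigError(ValueError):
    pass


@dataclass(frozen=True)
class LabThreshold:
    test_id: str
    label: str
    units: str
    low: float | None
    high: float | None
    min_high_occurrences: int = 1

    def __post_init__(self) -> None:
        if self.low is not None and self.high is not None and not self.low < self.high:
            raise LabConfigError(f"{self.test_id}: low threshold must be below high")
        if self.min_high_occurrences < 1:
            raise LabConfigError(f"{self.test_id}: min_high_occurrences must be >= 1")

    @property
    def low_case_defined(self) -> bool:
        return self.low is not None


def load_thresholds(path: str | Path | None = None) -> dict[str, LabThreshold]:
    """Load the thresholds config (packaged default when no path given)."""
    path = Path(path) if path else data_path("lab_thresholds.yaml")
    raw = yaml.safe_load(path.read_text())
    out = {}
    for test_id, spec in raw["tests"].items():
        out[test_id] = LabThreshold(
            test_id=test_id,
            label=spec.get("label", test_id),
            units=spec.get("units", ""),
            low=spec.get("low"),
            high=spec.get("high"),
            min_high_occurrences=int(spec.get("min_high_occurrences", 1)),
        )
    return out


def global_case(results: pd.DataFrame, threshold: LabThreshold, direction: str) -> bool:
    """Whole-history case flag for one patient and one test.

    ``results`` has columns (date, value). Comparisons are strict.
    High-value cases need ``min_high_occurrences`` results above the
    high threshold at distinct timestamps; low-value cases need one
    result below the low threshold.
    """
    if direction == "low":
        if not threshold.low_case_defined:
            raise LabConfigError(
                f"low direction undefined for test {threshold.test_id}"
            )
        return bool((results["value"] < threshold.low).any())
    if direction == "high":
        if threshold.high is None:
            raise LabConfigError(
                f"high direction undefined for test {threshold.test_id}"
            )
        over = results[results["value"] > threshold.high]
        return over["date"].nunique() >= threshold.min_high_occurrences
    raise LabConfigError(f"unknown direction {direction!r}")


def _encounter_key(results: pd.DataFrame) -> pd.Series:
    """Encounter identifier per result; calendar day stands in when absent."""
    if "encounter_id" in results.columns:
        key = results["encounter_id"].astype("object").copy()
        missing = key.isna()
    else:
        key = pd.Series([None] * len(results), index=results.index, dtype="object")
        missing = key.isna()
    if missing.any():
        day = pd.to_datetime(results.loc[missing, "date"]).dt.strftime("day:%Y-%m-%d")
        key.loc[missing] = day
    return key


def encounter_frequency(
    results: pd.DataFrame, threshold: LabThreshold, direction: str
) -> tuple[int, int, float] | None:
    """(qualifying, total, fraction) of encounters for one patient+test.

    An encounter qualifies when any of its results crosses the
    threshold; the denominator counts encounters with at least one
    result of this test. Returns None for a patient with no results
    (omitted from the frequency comparison).
    """
    if len(results) == 0:
        return None
    if direction == "low":
        if not threshold.low_case_defined:
            raise LabConfigError(
                f"low direction undefined for test {threshold.test_id}"
            )
        beyond = results["value"] < threshold.low
    elif direction == "high":
        beyond = results["value"] > threshold.high
    else:
        raise LabConfigError(f"unknown direction {direction!r}")
    key = _encounter_key(results)
    total = key.nunique()
    qualifying = key[beyond].nunique()
    return qualifying, total, qualifying / total


def compare_labs(
    patients: pd.DataFrame,
    labs: pd.DataFrame,
    thresholds: dict[str, LabThreshold],
    tests: list[str] | None = None,
    split: str = "very_high_vs_rest",
    estimator: str = "woolf_logistic",
) -> pd.DataFrame:
    """Both discretization arms for every test x direction.

    Returns one row per (test, direction), ordered by test then
    direction, carrying the global 2x2 with OR/CI/p and the per-group
    mean encounter frequencies with the Student t p-value. The
    ``neg_log10_p`` columns feed the pseudo-Manhattan plot.
    """
    tests = tests or list(thresholds)
    missing = [t for t in tests if t not in thresholds]
    if missing:
        raise LabConfigError(f"tests without thresholds: {missing}")
    exposed = dict(zip(patients["patient_id"], _exposed_mask(patients, split)))
    labs = labs[labs["patient_id"].isin(exposed)]
    rows = []
    for test_id in tests:
        thr = thresholds[test_id]
        sub = labs[labs["test_id"] == test_id]
        by_patient = dict(tuple(sub.groupby("patient_id", sort=False)))
        directions = [d for d in ("low", "high")
                      if (d == "high" and thr.high is not None)
                      or (d == "low" and thr.low_case_defined)]
        for direction in directions:
            cases = {True: 0, False: 0}
            totals = {True: 0, False: 0}
            freqs: dict[bool, list[float]] = {True: [], False: []}
            for pid, res in by_patient.items():
                arm = bool(exposed[pid])
                totals[arm] += 1
                if global_case(res, thr, direction):
                    cases[arm] += 1
                ef = encounter_frequency(res, thr, direction)
                if ef is not None:
                    freqs[arm].append(ef[2])
            table = Contingency2x2(
                cases[True], totals[True] - cases[True],
                cases[False], totals[False] - cases[False],
            )
            if table.degenerate:
                or_point = ci_low = ci_high = p_global = math.nan
            else:
                if estimator == "fisher_exact":
                    fr = fisher_exact(table)
                    est, p_global = fr.estimate, fr.p
                else:
                    est, p_global = sample_or_woolf(table), fisher_p(table)
                or_point, ci_low, ci_high = est.point, est.ci_low, est.ci_high
            if len(freqs[True]) >= 2 and len(freqs[False]) >= 2 and (
                np.var(freqs[True], ddof=1) + np.var(freqs[False], ddof=1) > 0
            ):
                _, p_freq = student_t(freqs[True], freqs[False])
            else:
                p_freq = math.nan
            rows.append(
                {
                    "test_id": test_id,
                    "label": thr.label,
                    "direction": direction,
                    "exposed_cases": table.a,
                    "exposed_total": table.a + table.b,
                    "comparator_cases": table.c,
                    "comparator_total": table.c + table.d,
                    "odds_ratio": or_point,
                    "ci_low": ci_low,
                    "ci_high": ci_high,
                    "p_global": p_global,
                    "neg_log10_p_global": (
                        -math.log10(p_global) if p_global and p_global > 0 else math.nan
                    ),
                    "exposed_mean_frequency": (
                        float(np.mean(freqs[True])) if freqs[True] else math.nan
                    ),
                    "comparator_mean_frequency": (
                        float(np.mean(freqs[False])) if freqs[False] else math.nan
                    ),
                    "p_frequency": p_freq,
                    "neg_log10_p_frequency": (
                        -math.log10(p_freq) if p_freq and p_freq > 0 else math.nan
                    ),
                }
            )
    out = pd.DataFrame(rows)
    if len(out):
        out = out.sort_values(["test_id", "direction"], kind="stable").reset_index(
            drop=True
        )
    return out
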