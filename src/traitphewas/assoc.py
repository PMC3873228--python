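"""Phenotype-wide scan over ICD-derived groups.

For every phenotype group, the study population splits into cases
(any qualifying code in the group's case ranges), excluded patients
(codes only elsewhere in the sibling exclusion range) and controls
(neither). Excluded patients leave both margins of the 2x2. Groups with
fewer cases than ``min_cases`` are not tested; the survivors get an OR,
CI and p-value from the configured estimator and Benjamini–Hochberg
flags at the configured q.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .stats import (
    Contingency2x2,
    OrEstimate,
    bh_fdr,
    fisher_exact,
    fisher_p,
    sample_or_woolf,
)
from .terminology import IcdCode, PhewasGroup, Terminology, normalize_icd10

__all__ = [
    "AssociationResult",
    "case_status",
    "run_phewas",
    "apply_fdr",
    "plot_tables",
    "results_frame",
]

SPLITS = ("very_high_vs_rest", "low_vs_rest", "cohort_vs_matched_controls")


@dataclass(frozen=True)
class AssociationResult:
    group_id: str
    label: str
    table: Contingency2x2
    n_excluded: int
    estimate: OrEstimate
    p: float
    estimator: str  # woolf_logistic | fisher_exact
    fdr_significant: bool = False

    @property
    def neg_log10_p(self) -> float:
        return -math.log10(self.p) if self.p > 0 else math.inf


def case_status(patient_codes: set[IcdCode], group: PhewasGroup) -> str:
    """case / excluded / control for one patient against one group."""
    if any(any(c in r for r in group.case_ranges) for c in patient_codes):
        return "case"
    if any(c in group.exclusion_range for c in patient_codes):
        return "excluded"
    return "control"


def _exposed_mask(patients: pd.DataFrame, split: str) -> np.ndarray:
    if split == "very_high_vs_rest":
        return (patients["trait_group"] == "very_high").to_numpy()
    if split == "low_vs_rest":
        return (patients["trait_group"] == "low").to_numpy()
    if split == "cohort_vs_matched_controls":
        if "arm" not in patients.columns:
            raise ValueError("split needs an 'arm' column (cohort/control)")
        return (patients["arm"] == "cohort").to_numpy()
    raise ValueError(f"unknown split {split!r}; one of {SPLITS}")


def run_phewas(
    patients: pd.DataFrame,
    diagnoses: pd.DataFrame,
    terminology: Terminology,
    split: str = "very_high_vs_rest",
    min_cases: int = 5,
    estimator: str = "woolf_logistic",
    min_occurrences_per_patient: int = 1,
    min_cases_unit: str = "patients",
    q: float = 0.2,
) -> tuple[list[AssociationResult], float]:
    """Scan every phenotype group; returns (results, FDR threshold line).

    ``patients`` carries patient_id and trait_group (or arm);
    ``diagnoses`` carries patient_id and code, already restricted to
    post-treatment time. A patient is a case for a group once it has
    ``min_occurrences_per_patient`` qualifying code occurrences (the
    published choice is one). ``min_cases_unit`` selects whether the
    at-least-``min_cases`` filter counts case patients (default) or raw
    code occurrences.
    """
    if len(patients) == 0:
        return [], 0.0
    pid_order = patients["patient_id"].to_numpy()
    pid_index = {p: i for i, p in enumerate(pid_order)}
    exposed = _exposed_mask(patients, split)
    n = len(pid_order)

    if len(diagnoses):
        dx = diagnoses[diagnoses["patient_id"].isin(pid_index)]
        codes = [normalize_icd10(c) for c in dx["code"]]
        dx_pid = np.fromiter((pid_index[p] for p in dx["patient_id"]), dtype=int,
                             count=len(dx))
        dx_key = np.fromiter((c.root_key for c in codes), dtype=int, count=len(codes))
    else:
        dx_pid = np.zeros(0, dtype=int)
        dx_key = np.zeros(0, dtype=int)

    results: list[AssociationResult] = []
    for group in terminology.group_list():
        if not group.case_ranges:
            continue  # nothing can qualify; skipped with a degenerate margin
        in_case = np.zeros(len(dx_key), dtype=bool)
        for r in group.case_ranges:
            in_case |= (dx_key >= r.start.root_key) & (dx_key <= r.end.root_key)
        er = group.exclusion_range
        in_excl = (dx_key >= er.start.root_key) & (dx_key <= er.end.root_key)

        occ = np.bincount(dx_pid[in_case], minlength=n)
        is_case = occ >= min_occurrences_per_patient
        near = np.zeros(n, dtype=bool)
        near[dx_pid[in_excl]] = True
        is_excluded = near & ~is_case

        n_case_unit = int(is_case.sum()) if min_cases_unit == "patients" else int(
            in_case.sum()
        )
        if n_case_unit < min_cases:
            continue
        kept = ~is_excluded
        a = int((is_case & exposed & kept).sum())
        b = int((~is_case & exposed & kept).sum())
        c = int((is_case & ~exposed & kept).sum())
        d = int((~is_case & ~exposed & kept).sum())
        table = Contingency2x2(a, b, c, d)
        if table.degenerate:
            continue
        if estimator == "fisher_exact":
            fr = fisher_exact(table)
            est, p = fr.estimate, fr.p
        elif estimator == "woolf_logistic":
            est, p = sample_or_woolf(table), fisher_p(table)
        else:
            raise ValueError(f"unknown estimator {estimator!r}")
        results.append(
            AssociationResult(
                group_id=group.id,
                label=group.label,
                table=table,
                n_excluded=int(is_excluded.sum()),
                estimate=est,
                p=p,
                estimator=estimator,
            )
        )
    return apply_fdr(results, q=q)


def apply_fdr(
    results: list[AssociationResult], q: float = 0.2
) -> tuple[list[AssociationResult], float]:
    """Benjamini–Hochberg over one scan's emitted results."""
    if not results:
        return [], 0.0
    flags, threshold = bh_fdr([r.p for r in results], q=q)
    return (
        [replace(r, fdr_significant=bool(f)) for r, f in zip(results, flags)],
        threshold,
    )


def results_frame(results: list[AssociationResult]) -> pd.DataFrame:
    """Flatten scan results into the tab-separated output layout."""
    rows = [
        {
            "group_id": r.group_id,
            "label": r.label,
            "a": r.table.a, "b": r.table.b, "c": r.table.c, "d": r.table.d,
            "n_excluded": r.n_excluded,
            "odds_ratio": r.estimate.point,
            "ci_low": r.estimate.ci_low,
            "ci_high": r.estimate.ci_high,
            "p": r.p,
            "neg_log10_p": r.neg_log10_p,
            "estimator": r.estimator,
            "fdr_significant": r.fdr_significant,
        }
        for r in results
    ]
    return pd.DataFrame(rows)


def _or_magnitude_class(or_point: float) -> int:
    """Dot-size class for the Manhattan plot (log2 magnitude of the OR)."""
    if not np.isfinite(or_point) or or_point <= 0:
        return 0
    return int(min(4, math.floor(abs(math.log2(or_point))) + 1))


def plot_tables(
    results: list[AssociationResult], fdr_threshold: float
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Plot-ready Manhattan and q-q tables for one scan.

    Manhattan rows are ordered by group code; reference lines are the
    p=0.05 dotted line and the FDR threshold dashed line (absent when no
    group passed). The q-q table pairs the sorted observed −log10 p with
    uniform order-statistic quantiles at (i−0.5)/m.
    """
    ordered = sorted(results, key=lambda r: r.group_id)
    dotted = -math.log10(0.05)
    dashed = -math.log10(fdr_threshold) if fdr_threshold > 0 else math.nan
    manhattan = pd.DataFrame(
        {
            "group_id": [r.group_id for r in ordered],
            "position": np.arange(1, len(ordered) + 1),
            "neg_log10_p": [r.neg_log10_p for r in ordered],
            "or_magnitude_class": [_or_magnitude_class(r.estimate.point)
                                   for r in ordered],
            "fdr_significant": [r.fdr_significant for r in ordered],
            "dotted_line": dotted,
            "dashed_line": dashed,
        }
    )
    m = len(results)
    obs = np.sort([r.p for r in results])
    qq = pd.DataFrame(
        {
            "expected": -np.log10((np.arange(1, m + 1) - 0.5) / m) if m else [],
            "observed": -np.log10(np.clip(obs, 1e-300, None)) if m else [],
        }
    )
    return manhattan, qq
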