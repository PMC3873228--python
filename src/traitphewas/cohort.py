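"""EHR-shaped cohort model: trait grouping, treatment dating, time filters.

A cohort is a bundle of flat tables (patients, encounters, diagnoses,
lab results, treatment mentions) in delimited-text form. The quantitative
trait (here TPMT enzyme activity, nmol/h/mL RBC) splits patients into
three exposure groups at two cut-points; analyses use only records dated
from the start of thiopurine treatment onward, with the start date taken
from CPOE prescriptions or from drug-name mentions in reports.
"""

from __future__ import annotations

import re
import unicodedata
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = [
    "TraitCuts",
    "Cohort",
    "CohortError",
    "TREATMENT_KEYWORDS",
    "assign_trait_group",
    "select_index_assay",
    "detect_treatment_start",
    "restrict_post_treatment",
    "match_controls",
    "prepare_study_population",
]

#: Brand and generic thiopurine names searched in free-text mentions.
TREATMENT_KEYWORDS = (
    "IMUREL", "AZATHIOPRINE", "IMURAN", "MERCAPTOPURINE", "PURINETHOL",
)

GROUPS = ("low", "normal", "very_high")


class CohortError(ValueError):
    pass


@dataclass(frozen=True)
class TraitCuts:
    """Group cut-points on the trait scale: below ``low`` is the deficient
    group, at or above ``high`` the very-high group, in between normal."""

    low: float = 8.5
    high: float = 15.0

    def __post_init__(self) -> None:
        if not self.low < self.high:
            raise CohortError("trait cut_low must be below cut_high")


def assign_trait_group(activity: float, cuts: TraitCuts = TraitCuts()) -> str:
    if activity < 0 or not np.isfinite(activity):
        raise CohortError(f"invalid trait activity {activity!r}")
    if activity < cuts.low:
        return "low"
    if activity >= cuts.high:
        return "very_high"
    return "normal"


def select_index_assay(
    assays: pd.DataFrame, cuts: TraitCuts = TraitCuts()
) -> tuple[pd.Timestamp, float, bool]:
    """Earliest-dated assay for one patient, with a stability flag.

    ``assays`` has columns (date, activity). ``stable`` is False when a
    later assay falls in a different trait group than the first; the
    patient is kept in the first group either way.
    """
    if len(assays) == 0:
        raise CohortError("patient has no trait assay")
    a = assays.sort_values("date", kind="stable")
    first = a.iloc[0]
    g0 = assign_trait_group(float(first["activity"]), cuts)
    stable = all(
        assign_trait_group(float(v), cuts) == g0 for v in a["activity"].iloc[1:]
    )
    return pd.Timestamp(first["date"]), float(first["activity"]), stable


def _fold(text: str) -> str:
    """Lowercase, strip accents, keep only alphabetic runs for matching."""
    norm = unicodedata.normalize("NFKD", str(text))
    return "".join(c for c in norm if not unicodedata.combining(c)).lower()


def detect_treatment_start(
    mentions: pd.DataFrame,
    keywords: tuple[str, ...] = TREATMENT_KEYWORDS,
) -> pd.Timestamp | None:
    """Earliest qualifying treatment date for one patient.

    CPOE rows qualify by having a start date; report/questionnaire rows
    qualify when their payload contains any drug keyword
    (case/diacritic-insensitive substring on alphabetic runs). Returns
    None when nothing qualifies.
    """
    if not keywords:
        raise CohortError("keyword list must be non-empty")
    if len(mentions) == 0:
        return None
    folded = [_fold(k) for k in keywords]
    dates = []
    for rec in mentions.itertuples(index=False):
        if pd.isna(rec.date):
            continue
        if rec.source == "cpoe":
            dates.append(pd.Timestamp(rec.date))
        elif rec.source in ("report", "questionnaire"):
            hay = re.sub(r"[^a-z]+", " ", _fold(rec.payload))
            if any(k in hay for k in folded):
                dates.append(pd.Timestamp(rec.date))
    return min(dates) if dates else None


def restrict_post_treatment(
    diagnoses: pd.DataFrame, labs: pd.DataFrame, start: pd.Timestamp
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Keep diagnosis events and lab results dated at or after ``start``.

    Same-day records are kept: report-derived start dates have day
    resolution only.
    """
    dx = diagnoses[pd.to_datetime(diagnoses["date"]) >= start].copy()
    lb = labs[pd.to_datetime(labs["date"]) >= start].copy()
    return dx, lb


def match_controls(
    index: pd.DataFrame,
    pool: pd.DataFrame,
    ratio: int = 3,
    seed: int = 0,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Sample sex/birth-year matched controls without replacement.

    ``index`` and ``pool`` have columns (patient_id, sex, birth_year).
    Returns (controls, shortfall) where shortfall lists strata that
    could not supply ``ratio`` controls per index patient. Patients with
    missing sex or birth year are skipped with a shortfall line.
    """
    rng = np.random.default_rng(seed)
    if set(index["patient_id"]) & set(pool["patient_id"]):
        raise CohortError("control pool overlaps the index cohort")
    taken: list[pd.DataFrame] = []
    shortfalls = []
    available = pool.copy()
    for rec in index.sort_values("patient_id").itertuples(index=False):
        if pd.isna(rec.sex) or pd.isna(rec.birth_year):
            shortfalls.append((rec.patient_id, rec.sex, rec.birth_year, ratio))
            continue
        stratum = available[
            (available["sex"] == rec.sex)
            & (available["birth_year"] == rec.birth_year)
        ]
        k = min(ratio, len(stratum))
        if k < ratio:
            shortfalls.append((rec.patient_id, rec.sex, rec.birth_year, ratio - k))
        if k:
            pick = stratum.sample(n=k, random_state=rng)
            taken.append(pick)
            available = available.drop(pick.index)
    controls = (
        pd.concat(taken, ignore_index=True)
        if taken
        else pool.iloc[0:0].copy()
    )
    shortfall = pd.DataFrame(
        shortfalls, columns=["patient_id", "sex", "birth_year", "missing"]
    )
    return controls, shortfall


# ---------------------------------------------------------------------------
# cohort bundle


@dataclass
class Cohort:
    """The five cohort tables plus derived per-patient annotations.

    Expected columns (dates ISO-8601, missing values empty):
      patients: patient_id, sex, birth_year
      assays: patient_id, date, activity
      encounters: encounter_id, patient_id, type, start_date, end_date
      diagnoses: patient_id, encounter_id, date, code
      labs: patient_id, encounter_id, date, test_id, value
      mentions: patient_id, date, source, payload
    """

    patients: pd.DataFrame
    assays: pd.DataFrame
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    mentions: pd.DataFrame
    flags: pd.DataFrame | None = None  # optional efficacy failure flags

    TABLES = ("patients", "assays", "encounters", "diagnoses", "labs", "mentions")

    @classmethod
    def read_dir(cls, path: str | Path) -> "Cohort":
        path = Path(path)
        kw = dict(sep="\t", parse_dates=False)
        tables = {}
        for name in cls.TABLES:
            f = path / f"{name}.tsv"
            if not f.exists():
                raise CohortError(f"missing cohort file: {f}")
            tables[name] = pd.read_csv(f, **kw)
        flags_file = path / "efficacy_flags.tsv"
        flags = pd.read_csv(flags_file, sep="\t") if flags_file.exists() else None
        for tab, col in [("assays", "date"), ("diagnoses", "date"),
                         ("labs", "date"), ("mentions", "date"),
                         ("encounters", "start_date")]:
            tables[tab][col] = pd.to_datetime(tables[tab][col])
        return cls(flags=flags, **tables)

    def write_dir(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        for name in self.TABLES:
            getattr(self, name).to_csv(path / f"{name}.tsv", sep="\t", index=False)
        if self.flags is not None:
            self.flags.to_csv(path / "efficacy_flags.tsv", sep="\t", index=False)


@dataclass
class StudyPopulation:
    """Cohort restricted to treated patients with post-treatment records."""

    patients: pd.DataFrame  # + trait_group, index_date, activity, treatment_start
    encounters: pd.DataFrame
    diagnoses: pd.DataFrame
    labs: pd.DataFrame
    flow: pd.DataFrame  # flow-chart accounting of exclusions
    unstable: list = field(default_factory=list)
    flags: pd.DataFrame | None = None


def prepare_study_population(
    cohort: Cohort,
    cuts: TraitCuts = TraitCuts(),
    keywords: tuple[str, ...] = TREATMENT_KEYWORDS,
) -> StudyPopulation:
    """Trait-group every assayed patient, date treatment, filter records.

    Patients without an assay, or without a detected treatment start,
    leave the study population; each exclusion step is counted in the
    flow table.
    """
    n0 = len(cohort.patients)

    # index assay per patient: earliest date wins; later assays crossing a
    # group boundary only flag the patient as unstable
    assays = cohort.assays.copy()
    assays["date"] = pd.to_datetime(assays["date"])
    act = assays["activity"].astype(float)
    grp = pd.Series(
        np.select(
            [act < cuts.low, act >= cuts.high], ["low", "very_high"], "normal"
        ),
        index=assays.index,
    )
    if (act < 0).any() or not np.isfinite(act).all():
        raise CohortError("negative or non-finite trait activity in assays")
    assays = assays.assign(_group=grp).sort_values(
        ["patient_id", "date"], kind="stable"
    )
    first = assays.drop_duplicates("patient_id", keep="first")
    n_groups = assays.groupby("patient_id")["_group"].nunique()
    unstable = sorted(n_groups.index[n_groups > 1])

    # treatment start: earliest qualifying CPOE or keyword-bearing report
    mentions = cohort.mentions
    if len(mentions):
        dated = mentions[~pd.isna(mentions["date"])]
        folded = (
            dated["payload"].astype(str)
            .str.normalize("NFKD")
            .str.encode("ascii", "ignore").str.decode("ascii")
            .str.lower()
            .str.replace(r"[^a-z]+", " ", regex=True)
        )
        pattern = "|".join(_fold(k) for k in keywords)
        qualifies = (dated["source"] == "cpoe") | (
            dated["source"].isin(["report", "questionnaire"])
            & folded.str.contains(pattern)
        )
        starts_series = (
            dated[qualifies].assign(date=lambda d: pd.to_datetime(d["date"]))
            .groupby("patient_id")["date"].min()
        )
    else:
        starts_series = pd.Series(dtype="datetime64[ns]")

    patients = cohort.patients.merge(
        first[["patient_id", "date", "activity", "_group"]], on="patient_id",
        how="inner",
    ).rename(columns={"date": "index_date", "_group": "trait_group"})
    no_assay = n0 - len(patients)
    patients["treatment_start"] = patients["patient_id"].map(starts_series)
    no_start = int(patients["treatment_start"].isna().sum())
    patients = patients.dropna(subset=["treatment_start"]).reset_index(drop=True)
    patients = patients[
        ["patient_id", "sex", "birth_year", "trait_group", "activity",
         "index_date", "treatment_start"]
    ]
    keep = set(patients["patient_id"])
    starts = dict(zip(patients["patient_id"], patients["treatment_start"]))

    def _post_treatment(table: pd.DataFrame) -> pd.DataFrame:
        sub = table[table["patient_id"].isin(keep)]
        if len(sub) == 0:
            return sub.copy()
        start = sub["patient_id"].map(starts)
        return sub[pd.to_datetime(sub["date"]) >= start].reset_index(drop=True)

    diagnoses = _post_treatment(cohort.diagnoses)
    labs = _post_treatment(cohort.labs)
    encounters = cohort.encounters[cohort.encounters["patient_id"].isin(keep)]
    flow = pd.DataFrame(
        [
            ("cohort_patients", n0),
            ("without_trait_assay", no_assay),
            ("without_treatment_start", no_start),
            ("study_population", len(patients)),
        ],
        columns=["step", "n"],
    )
    flags = None
    if cohort.flags is not None:
        flags = cohort.flags[cohort.flags["patient_id"].isin(keep)].copy()
    return StudyPopulation(
        patients=patients,
        encounters=encounters.copy(),
        diagnoses=diagnoses,
        labs=labs,
        flow=flow,
        unstable=unstable,
        flags=flags,
    )
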