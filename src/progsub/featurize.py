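"""Cohort filters and enhanced encounter representations.

Each eligible patient's record is tiled into contiguous, non-overlapping
90-day half-open windows ``[start, start+90)`` anchored at the first
encounter. Every window becomes a binary feature vector over

    [age bins | sex | race-ethnicity | Phecodes | ATC-3 | vital categories]

where a code bit is 1 iff a mapped code occurs at least once in the window,
demographic bits are re-evaluated per window (age moves through bins), and
each present vital measurement sets exactly one category bit. The window's
supervision label is the patient's state in the *following* window, with the
state machine PreMCI → MCI → AD absorbing from the first qualifying
diagnosis code onward; the final window has no label and is kept only for
sequence building.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import Cohort

#: ICD-9-CM / ICD-10-CM code lists defining the MCI and AD states.
MCI_CODES = ("331.83", "294.9", "G31.84", "F06.7", "F09",
             "R41.840", "R41.841", "R41.89", "R41.9")
AD_CODES = ("331.0", "G30", "G30.0", "G30.1", "G30.8", "G30.9")

STATE_NAMES = ("PreMCI", "MCI", "AD")
PREMCI, MCI, AD = 0, 1, 2

AGE_BIN_EDGES = (50, 55, 60, 65, 70, 75, 80, 85, 90)
SMOKING_CATEGORIES = ("non-smoker", "former", "current", "others")


@dataclass
class VitalThresholds:
    """Discretization cutoffs for BMI and blood pressure.

    BMI follows the WHO categories; blood pressure follows the 2017 ACC/AHA
    five-class scheme (normal, elevated, stage 1, stage 2, crisis).
    """

    bmi_under: float = 18.5
    bmi_normal_upper: float = 25.0
    bmi_over_upper: float = 30.0
    bp_elevated_sys: float = 120.0
    bp_stage1_sys: float = 130.0
    bp_stage1_dia: float = 80.0
    bp_stage2_sys: float = 140.0
    bp_stage2_dia: float = 90.0
    bp_crisis_sys: float = 180.0
    bp_crisis_dia: float = 120.0


def discretize_vitals(bmi=None, systolic=None, diastolic=None, smoking=None,
                      thresholds: VitalThresholds | None = None) -> set:
    """Map raw vital measurements to categorical feature names.

    Absent measurements contribute nothing; each present measurement yields
    exactly one category.
    """
    th = thresholds or VitalThresholds()
    cats = set()
    if bmi is not None:
        if bmi <= 0:
            raise ValueError(f"BMI must be positive, got {bmi}")
        if bmi <= th.bmi_under:
            cats.add("bmi:underweight")
        elif bmi < th.bmi_normal_upper:
            cats.add("bmi:normal")
        elif bmi < th.bmi_over_upper:
            cats.add("bmi:overweight")
        else:
            cats.add("bmi:obese")
    if systolic is not None or diastolic is not None:
        s = systolic if systolic is not None else 0.0
        d = diastolic if diastolic is not None else 0.0
        if s > th.bp_crisis_sys or d > th.bp_crisis_dia:
            cats.add("bp:crisis")
        elif s >= th.bp_stage2_sys or d >= th.bp_stage2_dia:
            cats.add("bp:stage2")
        elif s >= th.bp_stage1_sys or d >= th.bp_stage1_dia:
            cats.add("bp:stage1")
        elif s >= th.bp_elevated_sys:
            cats.add("bp:elevated")
        else:
            cats.add("bp:normal")
    if smoking is not None:
        smoking = str(smoking)
        cats.add(f"smoking:{smoking if smoking in SMOKING_CATEGORIES else 'others'}")
    return cats


def age_bin(age_years: float) -> str:
    if age_years < AGE_BIN_EDGES[0]:
        return "age:<50"
    for lo, hi in zip(AGE_BIN_EDGES[:-1], AGE_BIN_EDGES[1:]):
        if age_years < hi:
            return f"age:{lo}-{hi - 1}"
    return "age:90+"


def age_bin_names() -> list:
    return (["age:<50"]
            + [f"age:{lo}-{hi - 1}" for lo, hi in zip(AGE_BIN_EDGES[:-1],
                                                      AGE_BIN_EDGES[1:])]
            + ["age:90+"])


# ---------------------------------------------------------------------------
# cohort filter


def _event_dates(cohort: Cohort) -> pd.DataFrame:
    """First/last recorded activity per patient across all event tables."""
    frames = [t[["patient_id", "date"]] for t in
              (cohort.diagnoses, cohort.drugs, cohort.vitals) if len(t)]
    if not frames:
        return pd.DataFrame(columns=["min", "max"])
    ev = pd.concat(frames, ignore_index=True)
    return ev.groupby("patient_id")["date"].agg(["min", "max"])


def state_dates(cohort: Cohort, mci_codes=MCI_CODES,
                ad_codes=AD_CODES) -> pd.DataFrame:
    """First MCI and first AD diagnosis dates per patient (NaT if absent)."""
    dx = cohort.diagnoses
    code = dx["code"].astype(str)
    mci = dx[code.isin(set(mci_codes))].groupby("patient_id")["date"].min()
    ad = dx[code.isin(set(ad_codes))].groupby("patient_id")["date"].min()
    out = pd.DataFrame(index=pd.Index(cohort.patient_ids(), name="patient_id"))
    out["first_mci_date"] = mci
    out["first_ad_date"] = ad
    return out


@dataclass
class ExclusionLedger:
    """Per-rule exclusion counts, in the order the rules were applied."""

    counts: dict = field(default_factory=dict)
    excluded: dict = field(default_factory=dict)

    def exclude(self, rule: str, pids) -> None:
        pids = list(pids)
        self.counts[rule] = self.counts.get(rule, 0) + len(pids)
        self.excluded.setdefault(rule, []).extend(pids)


def cohort_filter(cohort: Cohort, mci_codes=MCI_CODES, ad_codes=AD_CODES,
                  min_age: float = 50.0, conversion_min_days: int = 180,
                  history_days: int = 365) -> tuple:
    """Apply the study inclusion rules; return (eligible ids, ledger).

    Rules, in order: (1) at least one MCI diagnosis code; (2) age >= 50 at
    the first MCI diagnosis; (3) no AD diagnosis code on or before the first
    MCI diagnosis; (4) at least one year of recorded data before and after
    the index date (the first MCI diagnosis); (5) for converters, an MCI→AD
    conversion time strictly greater than six months (> 180 days).
    """
    ledger = ExclusionLedger()
    sd = state_dates(cohort, mci_codes, ad_codes)
    ev = _event_dates(cohort)
    demo = cohort.demographics.set_index("patient_id")

    current = sd.index.tolist()

    no_mci = [p for p in current if pd.isna(sd.loc[p, "first_mci_date"])]
    ledger.exclude("no_mci_diagnosis", no_mci)
    current = [p for p in current if p not in set(no_mci)]

    too_young = []
    for p in current:
        age = (sd.loc[p, "first_mci_date"] - demo.loc[p, "birth_date"]).days \
            / 365.25
        if age < min_age:
            too_young.append(p)
    ledger.exclude("age_below_50_at_first_mci", too_young)
    current = [p for p in current if p not in set(too_young)]

    ad_first = [p for p in current
                if pd.notna(sd.loc[p, "first_ad_date"])
                and sd.loc[p, "first_ad_date"] <= sd.loc[p, "first_mci_date"]]
    ledger.exclude("ad_before_mci", ad_first)
    current = [p for p in current if p not in set(ad_first)]

    short = []
    for p in current:
        idx = sd.loc[p, "first_mci_date"]
        if p not in ev.index \
                or (idx - ev.loc[p, "min"]).days < history_days \
                or (ev.loc[p, "max"] - idx).days < history_days:
            short.append(p)
    ledger.exclude("insufficient_history", short)
    current = [p for p in current if p not in set(short)]

    fast = [p for p in current
            if pd.notna(sd.loc[p, "first_ad_date"])
            and (sd.loc[p, "first_ad_date"]
                 - sd.loc[p, "first_mci_date"]).days <= conversion_min_days]
    ledger.exclude("conversion_within_six_months", fast)
    current = [p for p in current if p not in set(fast)]

    return current, ledger


# ---------------------------------------------------------------------------
# feature space and windows


@dataclass
class FeatureSpace:
    """Ordered feature names with named block index ranges."""

    names: list
    blocks: dict  # block name -> slice

    @property
    def n_features(self) -> int:
        return len(self.names)

    def index(self, name: str) -> int:
        return self.names.index(name)

    def block_sizes(self) -> dict:
        return {k: s.stop - s.start for k, s in self.blocks.items()}

    def to_dict(self) -> dict:
        return {"names": list(self.names),
                "blocks": {k: [s.start, s.stop] for k, s in self.blocks.items()}}

    @classmethod
    def from_dict(cls, d: dict) -> "FeatureSpace":
        return cls(names=list(d["names"]),
                   blocks={k: slice(a, b) for k, (a, b) in d["blocks"].items()})


def build_feature_space(cohort: Cohort, code_maps: dict) -> FeatureSpace:
    """One shared feature space for a cohort; ordering is deterministic."""
    names, blocks = [], {}

    def block(name, cats):
        start = len(names)
        names.extend(cats)
        blocks[name] = slice(start, len(names))

    block("age", age_bin_names())
    sexes = sorted(cohort.demographics["sex"].astype(str).unique())
    block("sex", [f"sex:{s}" for s in sexes])
    races = sorted(cohort.demographics["race_ethnicity"].astype(str).unique())
    block("race", [f"race:{r}" for r in races])
    block("phecode", [f"dx:{t}" for t in code_maps["diagnosis"].targets()])
    block("atc3", [f"rx:{t}" for t in code_maps["drug"].targets()])
    block("vitals", [f"bmi:{c}" for c in ("underweight", "normal",
                                          "overweight", "obese")]
          + [f"bp:{c}" for c in ("normal", "elevated", "stage1", "stage2",
                                 "crisis")]
          + [f"smoking:{c}" for c in SMOKING_CATEGORIES])
    return FeatureSpace(names=names, blocks=blocks)


@dataclass
class EnhancedEncounter:
    """One 90-day window: binary features plus the next-window state label."""

    patient_id: str
    window_index: int
    window_start: pd.Timestamp
    window_end: pd.Timestamp
    features: np.ndarray
    label: int  # next-window state, -1 for the final (unlabeled) window


@dataclass
class PatientWindows:
    patient_id: str
    X: np.ndarray          # (T, F) uint8
    labels: np.ndarray     # (T,) int; -1 = no next window
    states: np.ndarray     # (T,) own-window state
    window_starts: pd.DatetimeIndex

    @property
    def n_windows(self) -> int:
        return self.X.shape[0]


@dataclass
class FeaturizedCohort:
    feature_space: FeatureSpace
    patients: list                    # patient ids, deterministic order
    windows: dict                     # pid -> PatientWindows
    index_dates: dict                 # pid -> first MCI date
    ledger: ExclusionLedger

    @property
    def n_nodes(self) -> int:
        return sum(w.n_windows for w in self.windows.values())


def _state_at(date, first_mci, first_ad) -> int:
    if pd.notna(first_ad) and date >= first_ad:
        return AD
    if pd.notna(first_mci) and date >= first_mci:
        return MCI
    return PREMCI


def build_windows(records, demographics: dict, feature_space: FeatureSpace,
                  code_maps: dict, first_mci, first_ad,
                  window_days: int = 90,
                  thresholds: VitalThresholds | None = None) -> PatientWindows:
    """Tile one patient's record into labeled 90-day feature windows."""
    if not records:
        raise ValueError("patient has no records")
    pid = records[0].patient_id
    t0 = records[0].date
    t_last = records[-1].date
    n_win = (t_last - t0).days // window_days + 1
    F = feature_space.n_features
    X = np.zeros((n_win, F), dtype=np.uint8)
    starts = pd.DatetimeIndex([t0 + pd.Timedelta(days=window_days * i)
                               for i in range(n_win)])

    name_to_idx = {n: i for i, n in enumerate(feature_space.names)}
    dx_map, rx_map = code_maps["diagnosis"], code_maps["drug"]

    # demographics, re-evaluated per window
    sex_bit = name_to_idx.get(f"sex:{demographics['sex']}")
    race_bit = name_to_idx.get(f"race:{demographics['race_ethnicity']}")
    for w in range(n_win):
        age = (starts[w] - demographics["birth_date"]).days / 365.25
        X[w, name_to_idx[age_bin(age)]] = 1
        if sex_bit is not None:
            X[w, sex_bit] = 1
        if race_bit is not None:
            X[w, race_bit] = 1

    for rec in records:
        w = (rec.date - t0).days // window_days
        for code in rec.diagnosis_codes:
            X[w, name_to_idx[f"dx:{dx_map.apply(code)}"]] = 1
        for code in rec.drug_codes:
            X[w, name_to_idx[f"rx:{rx_map.apply(code)}"]] = 1
        if rec.vitals:
            cats = discretize_vitals(
                bmi=rec.vitals.get("bmi"), systolic=rec.vitals.get("systolic"),
                diastolic=rec.vitals.get("diastolic"),
                smoking=rec.vitals.get("smoking"), thresholds=thresholds)
            for cat in cats:
                X[w, name_to_idx[cat]] = 1

    states = np.array([_state_at(starts[w], first_mci, first_ad)
                       for w in range(n_win)], dtype=np.int64)
    labels = np.concatenate([states[1:], [-1]])
    return PatientWindows(patient_id=pid, X=X, labels=labels, states=states,
                          window_starts=starts)


def vectorize(cohort: Cohort, code_maps: dict, eligible=None,
              mci_codes=MCI_CODES, ad_codes=AD_CODES, window_days: int = 90,
              thresholds: VitalThresholds | None = None) -> FeaturizedCohort:
    """Featurize every eligible patient under one shared feature space.

    Runs the cohort filter first when ``eligible`` is not supplied. Patients
    with fewer than two windows are excluded and counted in the ledger.
    """
    if eligible is None:
        eligible, ledger = cohort_filter(cohort, mci_codes, ad_codes)
    else:
        eligible, ledger = list(eligible), ExclusionLedger()
    fs = build_feature_space(cohort, code_maps)
    sd = state_dates(cohort, mci_codes, ad_codes)
    windows, index_dates, kept = {}, {}, []
    for pid in sorted(eligible):
        records = cohort.records_for(pid)
        pw = build_windows(records, cohort.demographics_for(pid), fs,
                           code_maps, sd.loc[pid, "first_mci_date"],
                           sd.loc[pid, "first_ad_date"],
                           window_days=window_days, thresholds=thresholds)
        if pw.n_windows < 2:
            ledger.exclude("fewer_than_two_windows", [pid])
            continue
        windows[pid] = pw
        index_dates[pid] = sd.loc[pid, "first_mci_date"]
        kept.append(pid)
    return FeaturizedCohort(feature_space=fs, patients=kept, windows=windows,
                            index_dates=index_dates, ledger=ledger)
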