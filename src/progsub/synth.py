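"""Synthetic longitudinal EHR cohorts with planted progression subphenotypes.

The generator emulates an MCI→AD progression cohort: each patient follows a
three-state semi-Markov process (Pre-MCI → MCI → AD → death/censoring) with
log-normal sojourn times, irregular encounter dates from a homogeneous
Poisson arrival process, and per-encounter Bernoulli emissions of diagnosis
and drug codes whose probabilities depend on the patient's planted subtype
and current state.

Subtype profiles are a shared base prevalence plus subtype-specific
signature-code offsets scaled by ``separation``; the same dial interpolates
the per-subtype duration parameters toward their pooled mean, so at
``separation=0`` the subtypes are exchangeable by construction and no
downstream method can recover them, while at ``separation=1`` the planted
structure is fully expressed.

All cohorts satisfy the downstream inclusion rules by construction: age at
first MCI >= 50, MCI→AD conversion time > 180 days, and at least 365 days of
records before and after the first MCI diagnosis (the index date).

The emitted code maps are synthetic stand-ins for the real ICD→Phecode and
drug→ATC-3 crosswalks, matched to the synthetic vocabulary.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .featurize import AD_CODES, MCI_CODES
from .io import Cohort, CodeMap, write_cohort

STATES = ("PreMCI", "MCI", "AD")

_STUDY_ORIGIN = pd.Timestamp("2012-01-01")


@dataclass
class GeneratorConfig:
    """Study conditions for the synthetic cohort.

    Duration defaults follow the published per-subphenotype statistics of an
    MCI→AD EHR cohort: MCI→AD sojourn means (854, 1236, 952, 805) days with
    sds (577, 725, 628, 563); first-record→AD spans of (2395, 2939, 2543,
    2365) days, which fix the pre-MCI record spans; age at first MCI
    N(76, 8.88) truncated at 50; 61.66% women; the largest subtype holding
    51.4% of patients. Post-AD survival means are chosen so the two slow
    progressors carry the worse post-AD survival, matching the reported
    ordering.
    """

    n_patients: int = 300
    n_subtypes: int = 4
    subtype_proportions: tuple = (0.514, 0.162, 0.162, 0.162)
    mci_to_ad_sojourn_mean_days: tuple = (854.0, 1236.0, 952.0, 805.0)
    mci_to_ad_sojourn_sd_days: tuple = (577.0, 725.0, 628.0, 563.0)
    pre_mci_duration_mean_days: tuple = (1541.0, 1703.0, 1591.0, 1560.0)
    pre_mci_duration_sd_days: tuple = (450.0, 450.0, 450.0, 450.0)
    post_ad_survival_mean_days: tuple = (1200.0, 800.0, 900.0, 1100.0)
    post_ad_survival_sd_days: tuple = (720.0, 480.0, 540.0, 660.0)
    encounter_rate_per_90days: float = 3.0
    code_vocabulary_sizes: dict = field(
        default_factory=lambda: {"diagnosis": 40, "drug": 24})
    subtype_prevalence_profiles: dict | None = None
    separation: float = 1.0
    censoring_prob: float = 0.3
    seed: int = 0
    # emission-profile construction knobs; at separation=1 each subtype's
    # signature block is strongly expressed (0.9 per window in MCI/AD),
    # at separation=0 every code sits at the shared base prevalence
    base_prevalence: float = 0.05
    signature_boost: float = 0.85
    premci_signature_boost: float = 0.45
    n_signature_dx: int | None = None   # default: vocabulary / n_subtypes
    n_signature_rx: int | None = None
    # vitals are always recorded at the first (intake) encounter, then at
    # this per-encounter probability
    vitals_prob: float = 0.7
    # demographics
    age_mean: float = 76.0
    age_sd: float = 8.88
    female_fraction: float = 0.6166
    race_categories: tuple = ("NHW", "NHB", "Hispanic", "Other")
    race_probs: tuple = (0.6483, 0.1648, 0.1085, 0.0784)

    def validate(self) -> None:
        if self.n_patients < 1 or self.n_subtypes < 1:
            raise ValueError("n_patients and n_subtypes must be positive")
        props = np.asarray(self.subtype_proportions, dtype=float)
        if len(props) != self.n_subtypes or abs(props.sum() - 1.0) > 1e-8 \
                or (props < 0).any():
            raise ValueError("subtype_proportions must be a probability "
                             f"vector of length {self.n_subtypes}")
        for name in ("mci_to_ad_sojourn_mean_days", "pre_mci_duration_mean_days",
                     "post_ad_survival_mean_days"):
            vals = np.asarray(getattr(self, name), dtype=float)
            if len(vals) != self.n_subtypes or (vals <= 0).any():
                raise ValueError(f"{name} must be {self.n_subtypes} positive "
                                 "durations")
        if not 0.0 <= self.separation <= 1.0:
            raise ValueError("separation must lie in [0, 1]")
        if not 0.0 <= self.censoring_prob <= 1.0:
            raise ValueError("censoring_prob must lie in [0, 1]")
        n_dx, n_rx = self.signature_sizes()
        if n_dx < 1 or self.code_vocabulary_sizes["diagnosis"] < \
                self.n_subtypes * n_dx:
            raise ValueError("diagnosis vocabulary too small for signatures")
        if n_rx < 1 or self.code_vocabulary_sizes["drug"] < \
                self.n_subtypes * n_rx:
            raise ValueError("drug vocabulary too small for signatures")

    def signature_sizes(self) -> tuple:
        """Signature-block sizes; by default the vocabulary is partitioned
        evenly across subtypes (distinct subphenotypes differ across many
        comorbidity systems, not a handful of codes)."""
        n_dx = (self.n_signature_dx if self.n_signature_dx is not None
                else self.code_vocabulary_sizes["diagnosis"]
                // self.n_subtypes)
        n_rx = (self.n_signature_rx if self.n_signature_rx is not None
                else self.code_vocabulary_sizes["drug"] // self.n_subtypes)
        return n_dx, n_rx


def dx_vocabulary(config: GeneratorConfig) -> list:
    return [f"DX{i:03d}" for i in range(config.code_vocabulary_sizes["diagnosis"])]


def rx_vocabulary(config: GeneratorConfig) -> list:
    return [f"RX{i:03d}" for i in range(config.code_vocabulary_sizes["drug"])]


def default_profiles(config: GeneratorConfig) -> dict:
    """Per-state (n_subtypes, n_codes) Bernoulli emission probabilities.

    Each subtype owns a disjoint block of signature diagnosis and drug codes
    whose per-encounter emission probability is raised above the shared base
    prevalence by ``separation * signature_boost`` once the patient is in the
    MCI or AD state, and by the smaller pre-MCI boost beforehand (so some
    subtype signal is visible before the index date, as comorbidity profiles
    are in practice).
    """
    n_dx = config.code_vocabulary_sizes["diagnosis"]
    n_rx = config.code_vocabulary_sizes["drug"]
    sig_dx, sig_rx = config.signature_sizes()
    sep = config.separation
    profiles = {}
    for kind, n_codes, n_sig in (("diagnosis", n_dx, sig_dx),
                                 ("drug", n_rx, sig_rx)):
        for state in STATES:
            boost = (config.premci_signature_boost if state == "PreMCI"
                     else config.signature_boost)
            mat = np.full((config.n_subtypes, n_codes), config.base_prevalence)
            for s in range(config.n_subtypes):
                sig = slice(s * n_sig, (s + 1) * n_sig)
                mat[s, sig] += sep * boost
            profiles[(kind, state)] = np.clip(mat, 0.0, 1.0)
    return profiles


@dataclass
class SyntheticCohort:
    """Generated tables plus the planted ground truth."""

    cohort: Cohort
    ground_truth: pd.DataFrame
    code_maps: dict
    config: GeneratorConfig

    def write(self, directory) -> None:
        d = Path(directory)
        d.mkdir(parents=True, exist_ok=True)
        write_cohort(self.cohort, d)
        gt = self.ground_truth.copy()
        for col in ("first_mci_date", "first_ad_date", "death_date",
                    "last_followup_date"):
            gt[col] = pd.to_datetime(gt[col]).dt.strftime("%Y-%m-%d")
        gt.to_csv(d / "ground_truth.csv", index=False)
        for kind, fname in (("diagnosis", "diagnosis_map_synthetic.csv"),
                            ("drug", "drug_map_synthetic.csv")):
            cm = self.code_maps[kind]
            pd.DataFrame(
                {"source_code": list(cm.mapping),
                 "target": [cm.mapping[c] for c in cm.mapping]}
            ).to_csv(d / fname, index=False)


def synthetic_code_maps(config: GeneratorConfig) -> dict:
    """Synthetic crosswalks matched to the synthetic vocabulary.

    Pairs of raw codes share one target, so the maps are genuinely
    many-to-one like the real ICD→Phecode / drug→ATC-3 crosswalks they
    stand in for. The MCI and AD ICD codes map to their real Phecodes.
    """
    dx_map = {code: f"P{i // 2:03d}" for i, code in
              enumerate(dx_vocabulary(config))}
    for code in MCI_CODES:
        dx_map[code] = "292.2"
    for code in AD_CODES:
        dx_map[code] = "290.11"
    rx_map = {code: f"{chr(65 + (i // 2) % 26)}{i // 2:02d}A"
              for i, code in enumerate(rx_vocabulary(config))}
    return {"diagnosis": CodeMap("ICD", dx_map),
            "drug": CodeMap("RX", rx_map)}


def _lognormal(rng, mean, sd, low, size=None):
    """Log-normal with the requested mean/sd, resampled above `low`."""
    sigma2 = np.log1p((sd / mean) ** 2)
    mu = np.log(mean) - sigma2 / 2.0
    for _ in range(200):
        x = rng.lognormal(mu, np.sqrt(sigma2), size=size)
        if np.all(x > low):
            return x
    return np.maximum(x, low + 1.0)


def _interp(values, separation):
    """Shrink per-subtype parameters toward their pooled mean."""
    vals = np.asarray(values, dtype=float)
    pooled = vals.mean()
    return pooled + separation * (vals - pooled)


def generate_cohort(config: GeneratorConfig) -> SyntheticCohort:
    """Generate a seeded synthetic cohort with planted subphenotypes."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    profiles = (config.subtype_prevalence_profiles
                if config.subtype_prevalence_profiles is not None
                else default_profiles(config))
    dx_vocab = np.asarray(dx_vocabulary(config))
    rx_vocab = np.asarray(rx_vocabulary(config))

    soj_mean = _interp(config.mci_to_ad_sojourn_mean_days, config.separation)
    soj_sd = _interp(config.mci_to_ad_sojourn_sd_days, config.separation)
    pre_mean = _interp(config.pre_mci_duration_mean_days, config.separation)
    pre_sd = _interp(config.pre_mci_duration_sd_days, config.separation)
    surv_mean = _interp(config.post_ad_survival_mean_days, config.separation)
    surv_sd = _interp(config.post_ad_survival_sd_days, config.separation)
    bp_shift = _interp((0.0, 4.0, 8.0, 18.0)[:config.n_subtypes]
                       if config.n_subtypes <= 4
                       else tuple(4.0 * s for s in range(config.n_subtypes)),
                       config.separation)

    demo_rows, dx_rows, rx_rows, vt_rows, gt_rows = [], [], [], [], []

    for i in range(config.n_patients):
        pid = f"P{i:05d}"
        z = int(rng.choice(config.n_subtypes, p=config.subtype_proportions))

        age = 0.0
        while age < 50.0:
            age = rng.normal(config.age_mean, config.age_sd)
        sex = "F" if rng.random() < config.female_fraction else "M"
        race = str(rng.choice(config.race_categories, p=config.race_probs))

        pre_dur = float(_lognormal(rng, pre_mean[z], pre_sd[z], 380.0))
        sojourn = float(_lognormal(rng, soj_mean[z], soj_sd[z], 200.0))
        survival = float(_lognormal(rng, surv_mean[z], surv_sd[z], 30.0))

        mci_day = int(round(pre_dur))
        ad_day = mci_day + int(round(sojourn))
        # keep >= 365 days of records after the index date by construction
        follow_min = max(60.0, 365.0 - (ad_day - mci_day) + 5.0)
        survival = max(survival, follow_min)
        censored = rng.random() < config.censoring_prob
        if censored:  # follow-up ends before (or at) the unrecorded death
            follow = float(rng.uniform(follow_min, survival))
        else:
            follow = survival
        end_day = ad_day + int(round(follow))

        # homogeneous encounter arrivals plus forced visits at the state
        # changes (a diagnosis implies a visit) and the record boundaries
        n_enc = rng.poisson(config.encounter_rate_per_90days * end_day / 90.0)
        days = np.unique(np.concatenate([
            np.round(rng.uniform(0, end_day, size=n_enc)).astype(int),
            [0, mci_day, ad_day, end_day],
        ]))
        days = days[(days >= 0) & (days <= end_day)]
        states = np.where(days < mci_day, 0, np.where(days < ad_day, 1, 2))

        first_enc_date = _STUDY_ORIGIN + pd.Timedelta(
            days=int(rng.integers(0, 2000)))
        dates = first_enc_date + pd.to_timedelta(days, unit="D")
        mci_date = first_enc_date + pd.Timedelta(days=mci_day)
        ad_date = first_enc_date + pd.Timedelta(days=ad_day)
        end_date = first_enc_date + pd.Timedelta(days=end_day)
        birth_date = mci_date - pd.Timedelta(days=round(age * 365.25))

        demo_rows.append((pid, birth_date, sex, race))
        gt_rows.append((pid, z, mci_date, ad_date,
                        pd.NaT if censored else end_date, end_date, censored))

        # per-window Bernoulli code emissions from the subtype profile for
        # the current state; each emitted code is recorded at a visit inside
        # its 90-day window (windows without a visit record nothing)
        n_win = end_day // 90 + 1
        win_starts = np.arange(n_win) * 90
        win_states = np.where(win_starts < mci_day, 0,
                              np.where(win_starts < ad_day, 1, 2))
        enc_window = days // 90
        win_encs = [np.flatnonzero(enc_window == w) for w in range(n_win)]
        for kind, vocab, rows, system in (
                ("diagnosis", dx_vocab, dx_rows, "SYN-ICD"),
                ("drug", rx_vocab, rx_rows, "SYN-RX")):
            prob = np.stack([profiles[(kind, STATES[s])][z]
                             for s in win_states])
            hits = rng.random(prob.shape) < prob
            win_idx, code_idx = np.nonzero(hits)
            for w, c in zip(win_idx, code_idx):
                encs = win_encs[w]
                if len(encs) == 0:
                    continue
                e = encs[rng.integers(len(encs))]
                rows.append((pid, dates[e], vocab[c], system))

        # staging codes: guaranteed at the first MCI/AD visit, recurrent after
        mci_encs = np.flatnonzero(states == 1)
        ad_encs = np.flatnonzero(states == 2)
        for j, e in enumerate(mci_encs):
            if j == 0 or rng.random() < 0.3:
                dx_rows.append((pid, dates[e], str(rng.choice(MCI_CODES)),
                                "SYN-ICD"))
        for j, e in enumerate(ad_encs):
            if j == 0 or rng.random() < 0.4:
                dx_rows.append((pid, dates[e], str(rng.choice(AD_CODES)),
                                "SYN-ICD"))

        # vitals at the intake encounter and then on ~70% of encounters
        for e in range(len(days)):
            if rng.random() < config.vitals_prob or e == 0:
                bmi = float(np.clip(rng.normal(27.5, 4.5), 15.0, 55.0))
                sys_bp = float(rng.normal(124.0 + bp_shift[z], 14.0))
                dia_bp = float(rng.normal(77.0, 9.0))
                smoking = str(rng.choice(
                    ["non-smoker", "former", "current", "others"],
                    p=(0.55, 0.25, 0.12, 0.08)))
                vt_rows.append((pid, dates[e], round(bmi, 1),
                                round(sys_bp, 1), round(dia_bp, 1), smoking))

    cohort = Cohort(
        demographics=pd.DataFrame(
            demo_rows, columns=["patient_id", "birth_date", "sex",
                                "race_ethnicity"]),
        diagnoses=pd.DataFrame(
            dx_rows, columns=["patient_id", "date", "code", "code_system"]),
        drugs=pd.DataFrame(
            rx_rows, columns=["patient_id", "date", "code", "code_system"]),
        vitals=pd.DataFrame(
            vt_rows, columns=["patient_id", "date", "bmi", "systolic",
                              "diastolic", "smoking"]),
    )
    ground_truth = pd.DataFrame(
        gt_rows, columns=["patient_id", "subtype", "first_mci_date",
                          "first_ad_date", "death_date",
                          "last_followup_date", "censored"])
    return SyntheticCohort(cohort=cohort, ground_truth=ground_truth,
                           code_maps=synthetic_code_maps(config),
                           config=config)


def ground_truth_summary(synthetic: SyntheticCohort) -> pd.DataFrame:
    """Per-subtype sojourn/survival statistics from true state-change dates.

    Computed from the planted timelines, never from emitted codes. Standard
    deviations are NaN (flagged) for single-patient subtypes; post-AD
    survival statistics use uncensored patients only.
    """
    gt = synthetic.ground_truth
    rows = []
    for z, grp in gt.groupby("subtype"):
        sojourn = (grp["first_ad_date"] - grp["first_mci_date"]).dt.days
        dead = grp[~grp["censored"]]
        survival = (dead["death_date"] - dead["first_ad_date"]).dt.days
        rows.append({
            "subtype": z,
            "n": len(grp),
            "sojourn_mean_days": sojourn.mean(),
            "sojourn_sd_days": sojourn.std(ddof=1) if len(grp) > 1 else np.nan,
            "post_ad_survival_mean_days":
                survival.mean() if len(dead) else np.nan,
            "post_ad_survival_sd_days":
                survival.std(ddof=1) if len(dead) > 1 else np.nan,
            "n_censored": int(grp["censored"].sum()),
        })
    return pd.DataFrame(rows).set_index("subtype")
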