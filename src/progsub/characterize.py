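"""Clinical characterization of fitted subphenotypes.

Kaplan–Meier curves with 95% confidence intervals (log(−log) / exponential
Greenwood scale, via lifelines) describe post-AD mortality (first AD
diagnosis → death, right-censored at last follow-up) and MCI→AD conversion
(first MCI → first AD, non-converters censored at the last recorded visit).
Group differences are tested with the K-sample log-rank test. Transition
statistics and per-cluster feature prevalences with pairwise χ² tests (and
Pearson correlations between cluster prevalence profiles) complete the
profile of each subphenotype.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from lifelines import KaplanMeierFitter
from lifelines.statistics import multivariate_logrank_test
from scipy import stats

#: significance tiers for the prevalence heatmap annotations
P_TIERS = ((1e-5, "****"), (1e-4, "***"), (1e-3, "**"), (1e-2, "*"))


def significance_tier(p: float) -> str:
    for cut, stars in P_TIERS:
        if p < cut:
            return stars
    return "ns"


def km_estimator(durations, events, alpha: float = 0.05) -> pd.DataFrame:
    """Product-limit survival estimate with 95% Greenwood-type CIs.

    Returns a step-function table (time, survival, ci_low, ci_high). With no
    censoring the curve equals the empirical survival function. An
    all-censored input gives a constant curve at 1 with degenerate CIs
    (flagged via the ``degenerate_ci`` attribute).
    """
    durations = np.asarray(durations, dtype=float)
    events = np.asarray(events, dtype=bool)
    if len(durations) == 0:
        raise ValueError("at least one subject required")
    kmf = KaplanMeierFitter(alpha=alpha)
    kmf.fit(durations, event_observed=events)
    ci = kmf.confidence_interval_survival_function_
    out = pd.DataFrame({
        "time": kmf.survival_function_.index.to_numpy(dtype=float),
        "survival": kmf.survival_function_["KM_estimate"].to_numpy(),
        "ci_low": ci.iloc[:, 0].to_numpy(),
        "ci_high": ci.iloc[:, 1].to_numpy(),
    })
    out.attrs["degenerate_ci"] = not events.any()
    return out


def logrank(groups: dict) -> tuple:
    """K-sample log-rank test; returns (chi2 statistic, p-value).

    ``groups`` maps group label -> (durations, events). Requires at least
    one observed event overall; otherwise the test is undefined.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    durs, evts, labs = [], [], []
    for name, (d, e) in groups.items():
        durs.extend(np.asarray(d, dtype=float))
        evts.extend(np.asarray(e, dtype=bool))
        labs.extend([name] * len(d))
    if not any(evts):
        raise ValueError("log-rank undefined with no events")
    res = multivariate_logrank_test(durs, labs, evts)
    return float(res.test_statistic), float(res.p_value)


def survival_inputs_mortality(ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Durations from first AD to death, censored at last follow-up."""
    gt = ground_truth[ground_truth["first_ad_date"].notna()].copy()
    event = gt["death_date"].notna()
    end = gt["death_date"].where(event, gt["last_followup_date"])
    return pd.DataFrame({
        "patient_id": gt["patient_id"],
        "duration": (pd.to_datetime(end)
                     - pd.to_datetime(gt["first_ad_date"])).dt.days,
        "event": event.astype(bool),
    })


def survival_inputs_conversion(ground_truth: pd.DataFrame) -> pd.DataFrame:
    """Durations from first MCI to first AD; non-converters censored."""
    gt = ground_truth.copy()
    converted = gt["first_ad_date"].notna()
    end = gt["first_ad_date"].where(converted, gt["last_followup_date"])
    return pd.DataFrame({
        "patient_id": gt["patient_id"],
        "duration": (pd.to_datetime(end)
                     - pd.to_datetime(gt["first_mci_date"])).dt.days,
        "event": converted.astype(bool),
    })


def km_by_cluster(surv: pd.DataFrame, assignments: pd.DataFrame) -> dict:
    """Per-cluster KM tables plus the log-rank comparison across clusters."""
    merged = surv.merge(assignments, on="patient_id")
    curves, groups = {}, {}
    for c, grp in merged.groupby("cluster"):
        curves[c] = km_estimator(grp["duration"], grp["event"])
        groups[c] = (grp["duration"].to_numpy(), grp["event"].to_numpy())
    stat, p = logrank(groups)
    return {"curves": curves, "logrank_stat": stat, "logrank_p": p}


def transition_stats(assignments: pd.DataFrame,
                     timelines: pd.DataFrame) -> pd.DataFrame:
    """Per-cluster mean/sd days for MCI→AD and first-record→AD transitions.

    ``timelines`` needs patient_id, first_mci_date, first_ad_date and
    first_record_date columns. Non-converters are excluded from the means
    and counted separately; single-patient clusters get NaN (flagged) sds.
    """
    tl = timelines.merge(assignments, on="patient_id")
    rows = []
    for c, grp in tl.groupby("cluster"):
        conv = grp[grp["first_ad_date"].notna()]
        soj = (pd.to_datetime(conv["first_ad_date"])
               - pd.to_datetime(conv["first_mci_date"])).dt.days
        total = (pd.to_datetime(conv["first_ad_date"])
                 - pd.to_datetime(conv["first_record_date"])).dt.days
        rows.append({
            "cluster": c, "n": len(grp), "n_converted": len(conv),
            "n_nonconverters": len(grp) - len(conv),
            "mci_to_ad_mean_days": soj.mean() if len(conv) else np.nan,
            "mci_to_ad_sd_days": soj.std(ddof=1) if len(conv) > 1 else np.nan,
            "record_to_ad_mean_days": total.mean() if len(conv) else np.nan,
            "record_to_ad_sd_days":
                total.std(ddof=1) if len(conv) > 1 else np.nan,
        })
    return pd.DataFrame(rows).set_index("cluster")


def prevalence_tests(assignments: pd.DataFrame, features: pd.DataFrame
                     ) -> dict:
    """Per-cluster prevalence matrix with pairwise tests and correlations.

    ``features`` is a patient-level binary indicator table (patient_id plus
    one 0/1 column per feature; "ever present in the record"). For every
    feature and cluster pair a 2×2 χ² test is run (Fisher's exact test when
    any expected cell count is below 5, noted per cell), annotated with the
    conventional significance tiers; Pearson correlations compare whole
    cluster prevalence profiles.
    """
    merged = features.merge(assignments, on="patient_id")
    feat_cols = [c for c in features.columns if c != "patient_id"]
    clusters = sorted(merged["cluster"].unique())
    prevalence = merged.groupby("cluster")[feat_cols].mean().loc[clusters]

    pvals, tests_used = {}, {}
    for i, a in enumerate(clusters):
        for b in clusters[i + 1:]:
            pa = merged[merged["cluster"] == a]
            pb = merged[merged["cluster"] == b]
            p_list, used_list = [], []
            for f in feat_cols:
                table = np.array([
                    [pa[f].sum(), len(pa) - pa[f].sum()],
                    [pb[f].sum(), len(pb) - pb[f].sum()],
                ], dtype=float)
                if table.sum() == 0:
                    p_list.append(1.0)
                    used_list.append("none")
                    continue
                expected = (table.sum(axis=1, keepdims=True)
                            * table.sum(axis=0, keepdims=True) / table.sum())
                if (expected < 5).any():
                    _, p = stats.fisher_exact(table)
                    used_list.append("fisher")
                else:
                    _, p, _, _ = stats.chi2_contingency(table,
                                                        correction=False)
                    used_list.append("chi2")
                p_list.append(float(p))
            pvals[(a, b)] = pd.Series(p_list, index=feat_cols)
            tests_used[(a, b)] = pd.Series(used_list, index=feat_cols)

    tiers = {pair: s.map(significance_tier) for pair, s in pvals.items()}
    corr = np.ones((len(clusters), len(clusters)))
    for i in range(len(clusters)):
        for j in range(i + 1, len(clusters)):
            r = np.corrcoef(prevalence.iloc[i], prevalence.iloc[j])[0, 1]
            corr[i, j] = corr[j, i] = r
    return {"prevalence": prevalence,
            "p_values": pvals,
            "tiers": tiers,
            "tests_used": tests_used,
            "profile_correlation": pd.DataFrame(corr, index=clusters,
                                                columns=clusters)}


def patient_level_features(feat) -> pd.DataFrame:
    """Ever-present binary indicators per patient from featurized windows."""
    rows = []
    for pid in feat.patients:
        rows.append(feat.windows[pid].X.max(axis=0))
    out = pd.DataFrame(np.asarray(rows, dtype=int),
                       columns=feat.feature_space.names)
    out.insert(0, "patient_id", feat.patients)
    return out
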