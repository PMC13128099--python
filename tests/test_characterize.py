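"""Survival machinery and subphenotype profiling."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from progsub import characterize as chr_


class TestKaplanMeier:
    def test_no_censoring_equals_empirical_survival(self, rng):
        durations = rng.integers(1, 50, size=40).astype(float)
        km = chr_.km_estimator(durations, np.ones(40, dtype=bool))
        for t, s in zip(km["time"], km["survival"]):
            assert s == pytest.approx((durations > t).mean(), abs=1e-12)

    def test_single_subject_event_at_ten(self):
        km = chr_.km_estimator([10.0], [True])
        before = km[km["time"] < 10]["survival"]
        assert (before == 1.0).all()
        assert km[km["time"] >= 10]["survival"].iloc[-1] == 0.0

    def test_textbook_six_subject_censored_fixture(self):
        """Hand-computed product-limit values for the classic 6-subject
        example: events at 6, 6, 10; censored at 6, 9, 12.

        S(6) = 1 - 2/6 = 2/3; at t=10 risk set {10, 12}:
        S(10) = 2/3 * (1 - 1/2) = 1/3.
        """
        durations = [6, 6, 6, 9, 10, 12]
        events = [True, True, False, False, True, False]
        km = chr_.km_estimator(durations, events).set_index("time")
        assert km.loc[6.0, "survival"] == pytest.approx(2 / 3, abs=1e-12)
        assert km.loc[10.0, "survival"] == pytest.approx(1 / 3, abs=1e-12)

    def test_curve_monotone_starts_at_one(self, rng):
        durations = rng.exponential(20, size=60)
        events = rng.random(60) < 0.7
        km = chr_.km_estimator(durations, events)
        assert km["survival"].iloc[0] <= 1.0 + 1e-12
        assert (np.diff(km["survival"]) <= 1e-12).all()

    def test_all_censored_constant_curve_flagged(self):
        km = chr_.km_estimator([5.0, 8.0], [False, False])
        assert (km["survival"] == 1.0).all()
        assert km.attrs["degenerate_ci"]


class TestLogrank:
    def test_identical_groups_high_p(self, rng):
        d = rng.exponential(10, size=50)
        e = np.ones(50, dtype=bool)
        stat, p = chr_.logrank({"a": (d, e), "b": (d.copy(), e.copy())})
        assert stat == pytest.approx(0.0, abs=1e-9)
        assert p > 0.99

    def test_hazard_ratio_three_detected(self, rng):
        hits = 0
        for i in range(20):
            a = rng.exponential(30, size=200)
            b = rng.exponential(10, size=200)
            e = np.ones(200, dtype=bool)
            _, p = chr_.logrank({"a": (a, e), "b": (b, e)})
            hits += p < 0.001
        assert hits >= 19

    def test_time_scale_invariance(self, rng):
        a = rng.exponential(5, size=30)
        b = rng.exponential(9, size=30)
        e = np.ones(30, dtype=bool)
        s1, p1 = chr_.logrank({"a": (a, e), "b": (b, e)})
        s2, p2 = chr_.logrank({"a": (a * 100, e), "b": (b * 100, e)})
        assert s1 == pytest.approx(s2, rel=1e-9)
        assert p1 == pytest.approx(p2, rel=1e-9)

    def test_permutation_null_p_uniform(self, rng):
        """Under random group labels the log-rank p-value is uniform."""
        d = rng.exponential(15, size=80)
        e = np.ones(80, dtype=bool)
        pvals = []
        for _ in range(300):
            lab = rng.permutation(np.repeat([0, 1], 40))
            _, p = chr_.logrank({g: (d[lab == g], e[lab == g])
                                 for g in (0, 1)})
            pvals.append(p)
        ks = stats.kstest(pvals, "uniform")
        assert ks.pvalue > 0.01

    def test_no_events_undefined(self):
        with pytest.raises(ValueError):
            chr_.logrank({"a": ([1.0], [False]), "b": ([2.0], [False])})


class TestTransitionStats:
    def _timelines(self):
        return pd.DataFrame({
            "patient_id": ["p1", "p2", "p3"],
            "first_record_date": pd.to_datetime(
                ["2012-01-01", "2012-01-01", "2012-01-01"]),
            "first_mci_date": pd.to_datetime(
                ["2014-01-01", "2014-01-01", "2014-01-01"]),
            "first_ad_date": pd.to_datetime(
                ["2014-04-11", "2016-01-01", pd.NaT]),
        })

    def test_single_patient_cluster_flagged_sd(self):
        assignments = pd.DataFrame({"patient_id": ["p1", "p2", "p3"],
                                    "cluster": [0, 1, 1]})
        out = chr_.transition_stats(assignments, self._timelines())
        assert out.loc[0, "mci_to_ad_mean_days"] == 100
        assert np.isnan(out.loc[0, "mci_to_ad_sd_days"])
        assert out.loc[1, "n_nonconverters"] == 1

    def test_single_cluster_equals_whole_cohort(self):
        assignments = pd.DataFrame({"patient_id": ["p1", "p2", "p3"],
                                    "cluster": [0, 0, 0]})
        out = chr_.transition_stats(assignments, self._timelines())
        assert out.loc[0, "n"] == 3
        assert out.loc[0, "n_converted"] == 2
        assert out.loc[0, "mci_to_ad_mean_days"] == pytest.approx(
            (100 + 730) / 2)

    def test_generator_sojourns_recovered_per_true_subtype(self, small_synth):
        gt = small_synth.ground_truth
        assignments = gt[["patient_id", "subtype"]].rename(
            columns={"subtype": "cluster"})
        timelines = gt.rename(columns={"last_followup_date":
                                       "first_record_date"})[
            ["patient_id", "first_mci_date", "first_ad_date"]].copy()
        timelines["first_record_date"] = timelines["first_mci_date"]
        out = chr_.transition_stats(assignments, timelines)
        soj = (gt["first_ad_date"] - gt["first_mci_date"]).dt.days
        pooled = soj.groupby(gt["subtype"]).mean()
        for c in out.index:
            assert out.loc[c, "mci_to_ad_mean_days"] == \
                pytest.approx(pooled[c])


class TestPrevalence:
    def _data(self, rng, delta=0.0, n=120):
        feats = pd.DataFrame({
            "patient_id": [f"p{i}" for i in range(n)],
        })
        cluster = np.repeat([0, 1], n // 2)
        p = np.where(cluster == 0, 0.3, 0.3 + delta)
        feats["f1"] = (rng.random(n) < p).astype(int)
        feats["f2"] = (rng.random(n) < 0.5).astype(int)
        assignments = pd.DataFrame({"patient_id": feats["patient_id"],
                                    "cluster": cluster})
        return assignments, feats

    def test_identical_clusters_ns_and_r_one(self, rng):
        assignments, feats = self._data(rng, delta=0.0)
        # make the two clusters literally identical
        half = len(feats) // 2
        feats.iloc[half:, 1:] = feats.iloc[:half, 1:].to_numpy()
        out = chr_.prevalence_tests(assignments, feats)
        assert (out["tiers"][(0, 1)] == "ns").all()
        assert out["profile_correlation"].loc[0, 1] == pytest.approx(1.0)

    def test_exclusive_feature_hits_smallest_tier(self, rng):
        assignments, feats = self._data(rng)
        feats["f1"] = assignments["cluster"]  # present only in cluster 1
        out = chr_.prevalence_tests(assignments, feats)
        assert out["tiers"][(0, 1)]["f1"] == "****"
        # oracle: chi2 on the constructed 2x2 table
        n = len(feats)
        table = np.array([[0, n // 2], [n // 2, 0]])
        _, p_expected, _, _ = stats.chi2_contingency(table, correction=False)
        assert out["p_values"][(0, 1)]["f1"] == pytest.approx(p_expected,
                                                              abs=1e-10)

    def test_small_expected_counts_use_fisher(self, rng):
        assignments, feats = self._data(rng, n=20)
        feats["f1"] = 0
        feats.loc[0, "f1"] = 1
        out = chr_.prevalence_tests(assignments, feats)
        assert out["tests_used"][(0, 1)]["f1"] == "fisher"

    def test_prevalence_bounded_and_reproducible(self, rng):
        assignments, feats = self._data(rng, delta=0.2)
        a = chr_.prevalence_tests(assignments, feats)
        b = chr_.prevalence_tests(assignments, feats)
        prev = a["prevalence"].to_numpy()
        assert ((prev >= 0) & (prev <= 1)).all()
        pd.testing.assert_frame_equal(a["prevalence"], b["prevalence"])

    def test_chi2_matches_scipy_on_random_tables(self, rng):
        """p-values agree with an independent contingency oracle."""
        for _ in range(50):
            n0, n1 = rng.integers(30, 80, size=2)
            k0 = int(rng.integers(6, n0 - 6))
            k1 = int(rng.integers(6, n1 - 6))
            assignments = pd.DataFrame({
                "patient_id": [f"p{i}" for i in range(n0 + n1)],
                "cluster": [0] * n0 + [1] * n1})
            f = np.zeros(n0 + n1, dtype=int)
            f[:k0] = 1
            f[n0:n0 + k1] = 1
            feats = pd.DataFrame({"patient_id": assignments["patient_id"],
                                  "f": f})
            out = chr_.prevalence_tests(assignments, feats)
            table = np.array([[k0, n0 - k0], [k1, n1 - k1]])
            expected = (table.sum(1, keepdims=True)
                        * table.sum(0, keepdims=True) / table.sum())
            if (expected < 5).any():
                _, p = stats.fisher_exact(table)
            else:
                _, p, _, _ = stats.chi2_contingency(table, correction=False)
            assert out["p_values"][(0, 1)]["f"] == pytest.approx(p,
                                                                 abs=1e-10)


def test_survival_inputs_from_ground_truth(small_synth):
    gt = small_synth.ground_truth
    mort = chr_.survival_inputs_mortality(gt)
    assert (mort["duration"] >= 0).all()
    censored = gt.set_index("patient_id")["censored"]
    assert (mort.set_index("patient_id")["event"] == ~censored).all()
    conv = chr_.survival_inputs_conversion(gt)
    assert conv["event"].all()  # every synthetic patient converts
    assert (conv["duration"] > 180).all()
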