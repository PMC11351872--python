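"""Survival estimators, association tests, and cluster profiling.

The Kaplan-Meier and log-rank implementations are checked three ways:
hand-computed product-limit tables, a label-permutation oracle, and an
independent survival library.
"""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from cpsn import (
    chisq_association,
    cluster_profiles,
    conventional_groupings,
    default_gc_config,
    km_estimate,
    logrank_test,
    simulate_cohort,
    validate_clustering,
)
from cpsn.simulate import _cluster_slices


class TestKaplanMeier:
    def test_all_censored_survival_stays_one(self):
        curves = km_estimate([1, 2, 3, 4], [0, 0, 0, 0])
        c = curves[0]
        assert len(c.times) == 0
        assert c.survival_at(10) == 1.0

    def test_single_death_among_four(self):
        # one death at t=2 with all four at risk: S(2) = (n-1)/n = 0.75
        c = km_estimate([2, 3, 4, 5], [1, 0, 0, 0])[0]
        assert c.survival_at(2) == pytest.approx(0.75)

    def test_ten_patient_hand_computed_table(self):
        """Product-limit table worked by hand, with a death/censoring tie at t=2."""
        times = [1, 2, 2, 3, 4, 5, 6, 7, 8, 9]
        events = [1, 0, 1, 1, 0, 1, 0, 1, 0, 0]
        c = km_estimate(times, events)[0]
        np.testing.assert_array_equal(c.times, [1, 2, 3, 5, 7])
        np.testing.assert_array_equal(c.at_risk, [10, 9, 7, 5, 3])
        np.testing.assert_allclose(
            c.survival,
            [0.9, 0.9 * 8 / 9, 0.9 * 8 / 9 * 6 / 7, 0.9 * 8 / 9 * 6 / 7 * 4 / 5,
             0.9 * 8 / 9 * 6 / 7 * 4 / 5 * 2 / 3],
        )

    def test_equals_one_minus_ecdf_when_uncensored(self):
        rng = np.random.default_rng(4)
        times = rng.exponential(10, size=60)
        c = km_estimate(times, np.ones(60, dtype=int))[0]
        for t in np.quantile(times, [0.1, 0.4, 0.7, 0.95]):
            assert c.survival_at(t) == pytest.approx((times > t).mean())

    def test_matches_lifelines(self):
        from lifelines import KaplanMeierFitter

        rng = np.random.default_rng(8)
        times = np.round(rng.exponential(20, size=80), 1)
        events = (rng.random(80) < 0.7).astype(int)
        c = km_estimate(times, events)[0]
        kmf = KaplanMeierFitter().fit(times, events)
        for t, s in zip(c.times, c.survival):
            assert s == pytest.approx(float(kmf.predict(t)), abs=1e-10)

    def test_one_curve_per_group(self):
        curves = km_estimate([1, 2, 3, 4], [1, 1, 1, 1], ["a", "a", "b", "b"])
        assert {c.group for c in curves} == {"a", "b"}
        assert all(c.n == 2 for c in curves)


class TestLogrank:
    def test_identical_groups_statistic_zero(self):
        times = [3, 5, 7, 9, 11]
        events = [1, 0, 1, 1, 0]
        t2, e2 = times + times, events + events
        g = ["a"] * 5 + ["b"] * 5
        result = logrank_test(t2, e2, g)
        assert result.statistic == pytest.approx(0, abs=1e-10)
        assert result.p_value == pytest.approx(1)

    def test_no_events_errors(self):
        with pytest.raises(ValueError, match="no events"):
            logrank_test([1, 2, 3], [0, 0, 0], ["a", "a", "b"])

    def test_matches_lifelines_k_sample(self):
        from lifelines.statistics import multivariate_logrank_test

        rng = np.random.default_rng(12)
        n = 120
        g = rng.choice(["a", "b", "c"], size=n)
        scale = {"a": 10, "b": 14, "c": 22}
        times = np.array([rng.exponential(scale[x]) for x in g])
        events = (rng.random(n) < 0.75).astype(int)
        ours = logrank_test(times, events, g)
        theirs = multivariate_logrank_test(times, g, events)
        assert ours.statistic == pytest.approx(theirs.test_statistic, rel=1e-8)
        assert ours.p_value == pytest.approx(theirs.p_value, rel=1e-8)
        assert ours.df == 2

    def test_agrees_with_permutation_oracle(self):
        """Asymptotic p matches a 10^4-shuffle permutation distribution."""
        rng = np.random.default_rng(5)
        n = 40
        g = np.array(["a"] * 20 + ["b"] * 20)
        times = np.concatenate([rng.exponential(10, 20), rng.exponential(16, 20)])
        events = (rng.random(n) < 0.8).astype(int)
        obs = logrank_test(times, events, g).statistic
        n_shuffles = 10_000
        perm = np.empty(n_shuffles)
        for i in range(n_shuffles):
            perm[i] = logrank_test(times, events, rng.permutation(g)).statistic
        p_perm = (perm >= obs - 1e-12).mean()
        p_asym = float(stats.chi2.sf(obs, 1))
        mc_err = 3 * np.sqrt(max(p_perm * (1 - p_perm), 1e-4) / n_shuffles)
        assert abs(p_perm - p_asym) < mc_err + 0.02

    def test_invariant_to_time_rescaling(self):
        rng = np.random.default_rng(7)
        times = rng.exponential(5, 50)
        events = (rng.random(50) < 0.6).astype(int)
        g = rng.choice(["x", "y"], 50)
        a = logrank_test(times, events, g)
        b = logrank_test(times * 12.0, events, g)
        assert a.statistic == pytest.approx(b.statistic)

    def test_power_under_hazard_ratio_three(self):
        """Exponential groups with HR 3, n=200/group: p < 0.001 almost surely."""
        rng = np.random.default_rng(42)
        hits = 0
        reps = 100
        for _ in range(reps):
            t1 = rng.exponential(1.0, 200)
            t2 = rng.exponential(3.0, 200)
            cens = rng.exponential(4.0, 400)
            times = np.concatenate([t1, t2])
            events = (times <= cens).astype(int)
            times = np.minimum(times, cens)
            p = logrank_test(times, events, ["a"] * 200 + ["b"] * 200).p_value
            hits += p < 0.001
        assert hits >= 95


class TestChiSquare:
    def test_balanced_table_no_association(self):
        a = ["x"] * 20 + ["y"] * 20
        b = (["u"] * 10 + ["v"] * 10) * 2
        r = chisq_association(a, b)
        assert r.statistic == pytest.approx(0)
        assert r.p_value == pytest.approx(1)

    def test_perfect_association_closed_form(self):
        """Balanced diagonal 2x2: chi-square equals n (= 40), p ~ 2.5e-10."""
        a = ["x"] * 20 + ["y"] * 20
        r = chisq_association(a, list(a))
        assert r.statistic == pytest.approx(40)
        assert r.p_value == pytest.approx(2.54e-10, rel=0.01)
        assert r.df == 1

    def test_degenerate_table_errors(self):
        with pytest.raises(ValueError, match="degenerate"):
            chisq_association(["x"] * 5, ["u", "u", "v", "v", "u"])

    def test_na_kept_as_category_by_default(self):
        a = ["x", "x", "y", "y", "x", "y"]
        b = ["u", None, "v", "u", None, "v"]
        r = chisq_association(a, b)
        assert "NA" in r.table.columns
        r2 = chisq_association(a, b, drop_na=True)
        assert "NA" not in r2.table.columns

    def test_low_expected_count_flag(self):
        a = ["x"] * 4 + ["y"] * 4
        b = ["u", "v"] * 4
        assert chisq_association(a, b).low_expected_warning

    def test_p_values_uniform_under_independence(self):
        """200 independent-label replicates: p-values pass a KS uniformity check."""
        rng = np.random.default_rng(123)
        pvals = []
        for _ in range(200):
            a = rng.choice(["p", "q", "r"], size=250)
            b = rng.choice(["u", "v", "w", "x"], size=250)
            pvals.append(chisq_association(a, b).p_value)
        ks_p = stats.kstest(pvals, "uniform").pvalue
        assert ks_p > 0.01


class TestClusterProfiles:
    def test_single_cluster_equals_cohort_frequencies(self, small_sim):
        prof = cluster_profiles(small_sim.cohort)
        nerve = prof[(prof.variable == "Nerve_invasion")].set_index("state")["frequency"]
        col = small_sim.cohort.data["Nerve_invasion"]
        assert nerve["Yes"] == pytest.approx((col == "Yes").mean())

    def test_frequencies_sum_to_one_per_variable(self, default_pipeline):
        sim = default_pipeline["sim"]
        prof = cluster_profiles(
            sim.cohort, assignments=default_pipeline["scan"].cluster_names(5),
            encoder=default_pipeline["model"],
        )
        sums = prof.groupby(["cluster", "variable"])["frequency"].sum()
        np.testing.assert_allclose(sums.to_numpy(), 1.0, atol=1e-9)

    def test_identical_patients_give_degenerate_profile(self, toy_schema):
        from cpsn.cohort import CohortTable

        data = pd.DataFrame(
            {
                "node_positive": ["Yes"] * 6,
                "histology": ["mixed"] * 6,
                "marker": [1.0, 2.0, 3.0, 4.0, 5.0, 6.0],
            },
            index=pd.Index([f"P{i}" for i in range(6)], name="patient_id"),
        )
        prof = cluster_profiles(CohortTable(toy_schema, data))
        cat = prof[prof.variable != "marker"]
        assert set(cat.frequency.round(9)) <= {0.0, 1.0}

    def test_profiles_match_generator_conditionals(self, default_sim):
        """Per-cluster state frequencies track the generator's analytic
        conditional distributions (quantile-slice mixture) within 0.1."""
        cfg = default_sim.config
        prof = cluster_profiles(
            default_sim.cohort, assignments=default_sim.true_labels.to_numpy()
        )
        prof = prof.set_index(["cluster", "variable", "state"])["frequency"]
        s = cfg.separation
        for vi, var in enumerate(cfg.schema):
            if var.kind == "continuous":
                continue
            spec = cfg.categorical[var.name]
            cum = np.concatenate([[0.0], np.cumsum(spec.probs)])
            slices = _cluster_slices(cfg.mixing, vi)
            for c in range(cfg.k_true):
                lo, hi = slices[c]
                width = hi - lo
                for j, state in enumerate(spec.states):
                    overlap = max(0.0, min(hi, cum[j + 1]) - max(lo, cum[j]))
                    cond = (1 - s) * spec.probs[j] + s * overlap / width
                    expect = (1 - spec.missingness) * cond
                    got = prof[(str(c), var.name, state)]
                    assert abs(got - expect) < 0.1, (var.name, state, c)


class TestValidateClustering:
    def test_cluster_linked_survival_flags_clinical(self, small_sim):
        report = validate_clustering(
            small_sim.cohort, None, small_sim.true_labels.to_numpy(),
            small_sim.survival, markers=["dMMR"],
        )
        assert report.is_clinical
        assert report.logrank.p_value < 0.05
        assert len(report.km_curves) == 5
        assert "dMMR" in report.marker_tests

    def test_shuffled_survival_not_clinical(self, small_sim):
        rng = np.random.default_rng(0)
        flags = []
        for _ in range(10):
            surv = small_sim.survival.copy()
            surv["patient_id"] = rng.permutation(surv["patient_id"].to_numpy())
            report = validate_clustering(
                small_sim.cohort, None, small_sim.true_labels.to_numpy(), surv
            )
            flags.append(report.is_clinical)
        assert sum(flags) <= 1

    def test_markers_independent_of_random_labels(self):
        """Random groupings show no marker association at the 0.01 threshold."""
        sim = simulate_cohort(default_gc_config(n=400, seed=9).with_(separation=0.0))
        rng = np.random.default_rng(1)
        markers = ["dMMR", "EGFR-IHC", "ERBB2-IHC", "p53-IHC"]
        n_sig = 0
        total = 0
        for _ in range(10):
            labels = rng.integers(0, 5, size=400)
            report = validate_clustering(sim.cohort, None, labels, sim.survival, markers=markers)
            for t in report.marker_tests.values():
                n_sig += t.p_value < 0.01
                total += 1
        assert n_sig <= 0.1 * total

    def test_km_curve_invariants(self, small_sim):
        report = validate_clustering(
            small_sim.cohort, None, small_sim.true_labels.to_numpy(), small_sim.survival
        )
        for c in report.km_curves:
            assert (np.diff(c.survival) <= 1e-12).all()
            assert (np.diff(c.at_risk) <= 0).all()
            assert c.survival_at(0) == 1 or len(c.times) == 0 or c.times[0] == 0


class TestConventionalGroupings:
    def test_age_quartiles_and_stage(self, small_sim):
        groups = conventional_groupings(small_sim.cohort)
        assert set(groups) == {"age_quartile", "Differentiation", "AJCC_Stage"}
        aq = groups["age_quartile"]
        counts = aq.value_counts()
        # cohort quartiles split observed ages into four near-equal groups
        observed = counts[[s for s in counts.index if s != "NA"]]
        assert observed.max() - observed.min() <= 0.1 * small_sim.cohort.n
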