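"""Kaplan-Meier, log-rank and supervised optimal binning."""

import numpy as np
import pytest

from sarcimmune.survival import (NoAdmissibleSplitError, SurvivalRecord,
                                 bivariate_stratify, km_estimate, logrank_test,
                                 optimal_binning)

from conftest import random_survival_records


def recs(times, events):
    return [SurvivalRecord(f"p{i}", float(t), int(e))
            for i, (t, e) in enumerate(zip(times, events))]


class TestKM:
    def test_hand_product_limit(self):
        c = km_estimate(recs([1, 2, 3], [1, 1, 1]))
        np.testing.assert_allclose(c.survival, [2 / 3, 1 / 3, 0.0])
        assert c.median == 2

    def test_all_censored(self):
        c = km_estimate(recs([5, 8, 9], [0, 0, 0]))
        assert c.event_times.size == 0
        assert c.survival_at(100) == 1.0
        assert c.median is None

    def test_single_event(self):
        c = km_estimate(recs([5], [1]))
        assert c.survival_at(5) == 0.0
        assert c.median == 5

    def test_empty_input_errors(self):
        with pytest.raises(ValueError):
            km_estimate([])

    def test_no_censoring_equals_one_minus_ecdf(self, rng):
        for _ in range(50):
            t = rng.exponential(50, size=int(rng.integers(3, 40)))
            c = km_estimate(recs(t, np.ones_like(t)))
            for et, s in zip(c.event_times, c.survival):
                assert s == pytest.approx(np.mean(t > et))

    def test_matches_lifelines(self, rng):
        from lifelines import KaplanMeierFitter

        for _ in range(30):
            records = random_survival_records(rng, int(rng.integers(3, 60)))
            c = km_estimate(records)
            kmf = KaplanMeierFitter().fit([r.time for r in records],
                                          [r.event for r in records])
            for t, s in zip(c.event_times, c.survival):
                ref = float(kmf.survival_function_at_times(t).iloc[0])
                assert s == pytest.approx(ref, abs=1e-8)

    def test_display_capping_never_alters_statistics(self, rng, tmp_path):
        """Capping PFS for plotting is cosmetic: the estimates keep raw times."""
        from sarcimmune.survival import plot_km

        records = recs([100, 600, 800], [1, 1, 1])
        c = km_estimate(records)
        assert c.median == 600  # beyond the display cap
        before = (c.event_times.copy(), c.survival.copy())
        plot_km({"all": c}, str(tmp_path / "km.png"), cap_days=500)
        np.testing.assert_array_equal(c.event_times, before[0])
        np.testing.assert_array_equal(c.survival, before[1])


class TestLogrank:
    def test_identical_groups(self):
        g = recs([1, 2, 3, 4], [1, 1, 0, 1])
        res = logrank_test([g, list(g)])
        assert res.statistic == pytest.approx(0.0, abs=1e-12)
        assert res.p == pytest.approx(1.0)

    def test_three_groups_df(self, rng):
        groups = [random_survival_records(rng, 20, prefix=f"g{i}") for i in range(3)]
        assert logrank_test(groups).df == 2

    def test_requires_two_nonempty_groups(self):
        with pytest.raises(ValueError):
            logrank_test([recs([1], [1]), []])

    def test_matches_lifelines_two_groups(self, rng):
        from lifelines.statistics import logrank_test as ll_logrank

        a = recs([1, 2, 3], [1, 1, 1])
        b = [SurvivalRecord(f"q{i}", t, 1) for i, t in enumerate([4, 5, 6])]
        res = logrank_test([a, b])
        ref = ll_logrank([1, 2, 3], [4, 5, 6], [1, 1, 1], [1, 1, 1])
        assert res.statistic == pytest.approx(ref.test_statistic, abs=1e-8)
        assert res.p == pytest.approx(ref.p_value, abs=1e-8)

    def test_group_order_invariance(self, rng):
        groups = [random_survival_records(rng, 15, prefix=f"g{i}") for i in range(3)]
        s1 = logrank_test(groups).statistic
        s2 = logrank_test(groups[::-1]).statistic
        assert s1 == pytest.approx(s2, rel=1e-10)


def brute_force_binning(cov, records, min_group):
    """Exhaustive independent search over observed covariate values."""
    best = None
    for t in sorted({cov[r.patient_id] for r in records}):
        low = [r for r in records if cov[r.patient_id] <= t]
        high = [r for r in records if cov[r.patient_id] > t]
        if len(low) < min_group or len(high) < min_group:
            continue
        p = logrank_test([low, high]).p
        if best is None or p < best[1]:
            best = (t, p)
    return best


class TestOptimalBinning:
    def test_too_few_patients(self, rng):
        records = random_survival_records(rng, 19)
        cov = {r.patient_id: float(i) for i, r in enumerate(records)}
        with pytest.raises(NoAdmissibleSplitError):
            optimal_binning(cov, records, min_group=10)

    def test_constant_covariate(self, rng):
        records = random_survival_records(rng, 40)
        cov = {r.patient_id: 1.0 for r in records}
        with pytest.raises(NoAdmissibleSplitError):
            optimal_binning(cov, records, min_group=10)

    def test_covariate_equal_to_time(self, rng):
        records = random_survival_records(rng, 24, censor_frac=0.0)
        cov = {r.patient_id: r.time for r in records}
        res = optimal_binning(cov, records, min_group=10)
        t, p = brute_force_binning(cov, records, 10)
        assert res.threshold == t
        assert res.chosen_p == pytest.approx(p, abs=1e-12)

    def test_matches_bruteforce_on_random_data(self, rng):
        for _ in range(25):
            n = int(rng.integers(20, 61))
            records = random_survival_records(rng, n)
            cov = {r.patient_id: float(v) for r, v in zip(records, rng.random(n))}
            res = optimal_binning(cov, records, min_group=5)
            t, p = brute_force_binning(cov, records, 5)
            assert res.threshold == t and res.chosen_p == pytest.approx(p, abs=1e-12)
            # group assignment consistent with the threshold
            for r in records:
                expected = "low" if cov[r.patient_id] <= res.threshold else "high"
                assert res.groups[r.patient_id] == expected

    def test_landscape_sizes(self, rng):
        records = random_survival_records(rng, 30)
        cov = {r.patient_id: float(v) for r, v in zip(records, rng.random(30))}
        res = optimal_binning(cov, records, min_group=10)
        for t, p, n_low, n_high in res.p_landscape:
            assert n_low + n_high == 30
            assert 0.0 <= p <= 1.0


class TestBivariate:
    def test_one_patient_per_quadrant(self):
        records = recs([10, 20, 30, 40], [1, 1, 1, 1])
        cov1 = {"p0": 0.0, "p1": 0.0, "p2": 1.0, "p3": 1.0}
        cov2 = {"p0": 0.0, "p1": 1.0, "p2": 0.0, "p3": 1.0}
        groups, res, medians = bivariate_stratify(cov1, cov2, 0.5, 0.5, records)
        assert {q: len(g) for q, g in groups.items()} == \
            {"LL": 1, "LH": 1, "HL": 1, "HH": 1}
        assert res.df == 3

    def test_all_below_first_threshold(self):
        records = recs([10, 20, 30, 40], [1, 1, 1, 1])
        cov1 = {r.patient_id: 0.0 for r in records}
        cov2 = {"p0": 0.0, "p1": 1.0, "p2": 0.0, "p3": 1.0}
        groups, res, medians = bivariate_stratify(cov1, cov2, 0.5, 0.5, records)
        assert len(groups["HL"]) == 0 and len(groups["HH"]) == 0
        assert res.df == 1

    def test_planted_interaction_single_cohort(self):
        """Strongly protective interaction with no main effects: the doubly
        high quadrant has the largest KM median."""
        from sarcimmune.synthetic import CohortConfig, generate_cohort
        from conftest import records_from_clinical

        cohort = generate_cohort(CohortConfig(
            n_patients=400, censoring_rate=0.0, seed=2024,
            hazard_coefficients={"t_cell_fraction": 0.0,
                                 "neoantigen_quality": 0.0,
                                 "interaction": -2.0}))
        tc = cohort.truth["t_cell_fraction"]
        q = cohort.truth["neoantigen_quality"]
        records = records_from_clinical(cohort.clinical)
        _, _, medians = bivariate_stratify(
            tc, q, float(np.median(list(tc.values()))),
            float(np.median(list(q.values()))), records)
        others = [medians[k] for k in ("LL", "LH", "HL")]
        assert all(medians["HH"] > m for m in others)
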