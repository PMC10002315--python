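"""Symptom clustering: correlation distance, three-tier allocation,
exhaustive-search equivalence, and item-wise rank-sum testing."""

import numpy as np
import pytest
from scipy import stats
from sklearn.metrics import adjusted_rand_score

from voicesym.clustering import (
    ClusteringResult,
    brute_force_best_partition,
    cluster_cohort,
    correlation_distance,
    item_wise_tests,
)
from voicesym.hamd import HamdRecord, default_profiles, generate_hamd_cohort


def _record(sid, items):
    return HamdRecord(subject_id=sid, items=np.asarray(items, dtype=int))


class TestCorrelationDistance:
    def test_identical_profiles(self):
        a = np.arange(17.0)
        assert correlation_distance(a, a) == pytest.approx(0.0)

    def test_perfectly_anticorrelated(self):
        a = np.arange(17.0)
        assert correlation_distance(a, 10.0 - 2.0 * a) == pytest.approx(2.0)

    def test_pattern_example(self):
        assert correlation_distance(
            np.array([1.0, 2.0, 3.0]), np.array([1.0, 3.0, 2.0])
        ) == pytest.approx(0.5)

    def test_matches_scipy_pearson(self):
        rng = np.random.default_rng(0)
        for _ in range(20):
            a, b = rng.uniform(0, 4, 17), rng.uniform(0, 4, 17)
            r, _ = stats.pearsonr(a, b)
            assert correlation_distance(a, b) == pytest.approx(1.0 - r, abs=1e-12)

    def test_zero_variance_gets_unit_distance(self):
        assert correlation_distance(np.zeros(17), np.arange(17.0)) == 1.0

    def test_length_mismatch_rejected(self):
        with pytest.raises(ValueError):
            correlation_distance(np.zeros(17), np.zeros(16))


class TestThreeTierClustering:
    def test_stage_assignment_follows_totals(self):
        recs, _ = generate_hamd_cohort(15, profiles=default_profiles(2.5), seed=0)
        zero = _record("Z0", [0] * 17)
        low = _record("L1", [1, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0])
        res = cluster_cohort(recs + [zero, low], seed=0)
        assert res.assignment["Z0"] == "excluded"
        assert res.stage["Z0"] == "excluded"
        assert res.stage["L1"] == "allocated"
        assert res.assignment["L1"] in (1, 2)
        for r in recs:
            if r.total >= 4:
                assert res.stage[r.subject_id] == "seed_clustered"

    def test_all_zero_cohort_rejected(self):
        recs = [_record(f"S{i}", [0] * 17) for i in range(5)]
        with pytest.raises(ValueError, match="clusterable"):
            cluster_cohort(recs, seed=0)

    @pytest.mark.parametrize("seed", range(6))
    def test_matches_exhaustive_best_partition(self, seed):
        """Well-separated profile blocks, n <= 10 clusterable subjects:
        result equals the brute-force best 2-partition of the
        within-cluster correlation-distance objective."""
        recs, _ = generate_hamd_cohort(
            4, profiles=default_profiles(4.0, g2_items=(4, 5, 6)), seed=seed
        )
        core = [r for r in recs if r.total >= 4]
        assert len(core) >= 6
        X = np.vstack([r.items for r in core]).astype(float)
        oracle_labels, oracle_obj = brute_force_best_partition(X)
        res = cluster_cohort(recs, seed=seed)
        labels = np.array([res.assignment[r.subject_id] for r in core])
        assert adjusted_rand_score(oracle_labels, labels) == pytest.approx(1.0)
        assert res.objective == pytest.approx(oracle_obj, abs=1e-9)

    def test_equidistant_low_scorer_goes_to_group_one(self):
        """A totals-2 subject exactly equidistant from both centroids is
        assigned to group 1 by the canonical tie rule."""
        u = [0, 4, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        v = [0, 0, 0, 0, 0, 0, 0, 4, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        p = [0, 1, 0, 0, 0, 0, 0, 1, 0, 0, 0, 0, 0, 0, 0, 0, 0]
        recs = [
            _record("A1", u), _record("A2", u),
            _record("B1", v), _record("B2", v),
            _record("P", p),
        ]
        res = cluster_cohort(recs, seed=0)
        d1 = correlation_distance(np.array(p, float), res.centroids[0])
        d2 = correlation_distance(np.array(p, float), res.centroids[1])
        assert d1 == pytest.approx(d2, abs=1e-12)
        assert res.assignment["P"] == 1

    def test_canonical_labels_stable_across_seeds(self):
        recs, true = generate_hamd_cohort(20, profiles=default_profiles(3.0), seed=1)
        res_a = cluster_cohort(recs, seed=10)
        res_b = cluster_cohort(recs, seed=99)
        agree = np.mean(
            [res_a.assignment[r.subject_id] == res_b.assignment[r.subject_id] for r in recs]
        )
        assert agree > 0.95
        # group 1 is the higher-item-7 ("work and activities") group
        assert res_a.centroids[0][6] >= res_a.centroids[1][6]


class TestItemWiseTests:
    def test_bonferroni_levels(self):
        recs, _ = generate_hamd_cohort(10, seed=0)
        res = cluster_cohort(recs, seed=0)
        report = item_wise_tests(recs, res.assignment)
        assert report.n_tests == 18
        assert report.corrected_levels[0] == pytest.approx(0.05 / 18)
        assert round(report.corrected_levels[0], 4) == 0.0028
        assert len(report.tests) == 18

    def test_type_one_error_controlled_under_null(self):
        """Two groups from one distribution: family-wise flags stay rare."""
        rng = np.random.default_rng(42)
        n_sig = 0
        n_sims = 200
        prof = default_profiles(effect=0.0)
        for sim in range(n_sims):
            recs, groups = generate_hamd_cohort(30, profiles=prof, seed=int(rng.integers(2**31)))
            assignment = {r.subject_id: groups[r.subject_id] for r in recs}
            report = item_wise_tests(recs, assignment)
            n_sig += sum(1 for t in report.tests.values() if t["tier"] >= 1)
        assert n_sig / (18 * n_sims) <= 0.05

    def test_shifted_item_flagged_and_matches_exact_test(self):
        rng = np.random.default_rng(7)
        recs = []
        assignment = {}
        for i in range(25):
            items = np.clip(rng.integers(0, 3, 17), 0, 2)
            items[7] = min(items[7] + 2, 4)  # planted +2 shift on item 8 (0-4 scale)
            recs.append(_record(f"G1_{i}", items))
            assignment[f"G1_{i}"] = 1
        for i in range(25):
            recs.append(_record(f"G2_{i}", np.clip(rng.integers(0, 3, 17), 0, 2)))
            assignment[f"G2_{i}"] = 2
        report = item_wise_tests(recs, assignment)
        assert report.tests["item_8"]["tier"] >= 1

        # asymptotic p agrees with exact enumeration at small n on tie-free data
        x = np.array([0.3, 1.7, 2.4, 3.1, 3.9, 2.9, 1.1, 0.6])
        y = x - 2.0 + 0.01  # shift, no ties
        p_asym = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic").pvalue
        p_exact = stats.mannwhitneyu(x, y, alternative="two-sided", method="exact").pvalue
        assert abs(p_asym - p_exact) < 0.02

    def test_empty_group_rejected(self):
        recs, _ = generate_hamd_cohort(5, seed=0)
        assignment = {r.subject_id: 1 for r in recs}
        with pytest.raises(ValueError):
            item_wise_tests(recs, assignment)
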