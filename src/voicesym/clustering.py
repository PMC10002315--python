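"""Three-tier symptom clustering of HAM-D profiles and item-wise testing.

Subjects with a HAM-D total of 0 carry no symptom information and are
excluded; subjects with total >= 4 are clustered into two groups by K-means
under correlation distance (1 - Pearson r between 17-item profiles, mean
centroids); subjects with totals 1-3 are then allocated to the nearest
centroid.  Group labels are canonicalized so group 1 is the group with the
higher centroid score on item 7 ("work and activities" — the inactivity
group), making labels stable across seeds.

Item-wise group differences use the two-sided Wilcoxon rank-sum test
(normal approximation with tie and continuity corrections) for each of the
17 items plus the total — 18 tests — with Bonferroni-corrected significance
tiers (0.05/18, 0.01/18, 0.005/18).
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from itertools import combinations
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .hamd import N_ITEMS, HamdRecord

N_TESTS = 18
TIER_ALPHAS = (0.05, 0.01, 0.005)  # '*', '**', '***' family levels


def correlation_distance(a: np.ndarray, b: np.ndarray) -> float:
    """1 - Pearson correlation between two 17-item profiles.

    A zero-variance profile has no defined correlation; such pairs get
    distance 1 (treated as uncorrelated) so the procedure stays total.
    """
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape or a.ndim != 1:
        raise ValueError("profiles must be 1-D and the same length")
    sa, sb = a.std(), b.std()
    if sa == 0 or sb == 0:
        return 1.0
    r = float(np.dot(a - a.mean(), b - b.mean()) / (len(a) * sa * sb))
    return 1.0 - r


def _distances_to_centroids(X: np.ndarray, centroids: np.ndarray) -> np.ndarray:
    """(n, k) correlation distances, vectorized over rows."""
    Xc = X - X.mean(axis=1, keepdims=True)
    Xs = X.std(axis=1, keepdims=True)
    Cc = centroids - centroids.mean(axis=1, keepdims=True)
    Cs = centroids.std(axis=1, keepdims=True)
    num = Xc @ Cc.T
    den = X.shape[1] * Xs * Cs.T
    with np.errstate(divide="ignore", invalid="ignore"):
        r = np.where(den > 0, num / np.where(den > 0, den, 1.0), 0.0)
    return 1.0 - r


@dataclass
class ClusteringResult:
    """Per-subject group assignment with stage provenance."""

    assignment: dict[str, int | str]   # subject -> 1 | 2 | "excluded"
    stage: dict[str, str]              # subject -> seed_clustered | allocated | excluded
    centroids: np.ndarray              # (2, 17) mean profiles of the seed clusters
    objective: float                   # total within-cluster correlation distance
    n_restarts_used: int
    seed: int


def _kmeans_corr(
    X: np.ndarray, seed: int, n_restarts: int, max_iter: int = 100
) -> tuple[np.ndarray, np.ndarray, float]:
    """Best-of-restarts k=2 K-means with correlation distance."""
    rng = np.random.default_rng(seed)
    n = len(X)
    best: tuple[np.ndarray, np.ndarray, float] | None = None
    for _ in range(n_restarts):
        idx = rng.choice(n, size=2, replace=False)
        # re-draw if the two seed profiles coincide
        tries = 0
        while np.allclose(X[idx[0]], X[idx[1]]) and tries < 10:
            idx = rng.choice(n, size=2, replace=False)
            tries += 1
        centroids = X[idx].astype(float).copy()
        labels = np.zeros(n, dtype=int)
        for _ in range(max_iter):
            d = _distances_to_centroids(X, centroids)
            new_labels = np.argmin(d, axis=1)
            for k in range(2):  # keep both clusters alive
                if not np.any(new_labels == k):
                    new_labels[np.argmax(d[:, 1 - k])] = k
            if np.array_equal(new_labels, labels) and _ > 0:
                break
            labels = new_labels
            for k in range(2):
                centroids[k] = X[labels == k].mean(axis=0)
        d = _distances_to_centroids(X, centroids)
        obj = float(d[np.arange(n), labels].sum())
        if best is None or obj < best[2] - 1e-12:
            best = (labels.copy(), centroids.copy(), obj)
    assert best is not None
    return best


def cluster_cohort(
    cohort: list[HamdRecord], seed: int = 0, n_restarts: int = 20
) -> ClusteringResult:
    """Three-tier clustering of a HAM-D cohort into two symptom groups."""
    totals = np.array([r.total for r in cohort])
    X_all = np.vstack([r.items for r in cohort]).astype(float)
    core = totals >= 4
    low = (totals >= 1) & (totals <= 3)
    if np.count_nonzero(core) < 2:
        raise ValueError("no clusterable subjects: need >= 2 with total >= 4")

    labels, centroids, objective = _kmeans_corr(X_all[core], seed, n_restarts)

    # canonical labels: group 1 has the higher centroid on item 7 (index 6);
    # ties fall to the current order so the rule is total
    if centroids[1][6] > centroids[0][6]:
        labels = 1 - labels
        centroids = centroids[::-1].copy()

    assignment: dict[str, int | str] = {}
    stage: dict[str, str] = {}
    core_ids = [r.subject_id for r, c in zip(cohort, core) if c]
    for sid, lab in zip(core_ids, labels):
        assignment[sid] = int(lab) + 1
        stage[sid] = "seed_clustered"
    for r, is_low, is_core in zip(cohort, low, core):
        if is_core:
            continue
        if is_low:
            d = _distances_to_centroids(r.items[None, :].astype(float), centroids)[0]
            assignment[r.subject_id] = 1 if d[0] <= d[1] else 2  # tie -> group 1
            stage[r.subject_id] = "allocated"
        else:
            assignment[r.subject_id] = "excluded"
            stage[r.subject_id] = "excluded"
    return ClusteringResult(
        assignment=assignment,
        stage=stage,
        centroids=centroids,
        objective=objective,
        n_restarts_used=n_restarts,
        seed=seed,
    )


def brute_force_best_partition(X: np.ndarray) -> tuple[np.ndarray, float]:
    """Exhaustive best 2-partition under the K-means correlation-distance
    objective (independent oracle for small n)."""
    n = len(X)
    best_labels, best_obj = None, np.inf
    idx = np.arange(n)
    for size in range(1, n // 2 + 1):
        for subset in combinations(idx, size):
            labels = np.ones(n, dtype=int)
            labels[list(subset)] = 0
            obj = 0.0
            for k in range(2):
                members = X[labels == k]
                c = members.mean(axis=0)
                obj += sum(correlation_distance(m, c) for m in members)
            if obj < best_obj - 1e-12:
                best_obj, best_labels = obj, labels.copy()
    assert best_labels is not None
    return best_labels, float(best_obj)


@dataclass
class ItemTestReport:
    """Wilcoxon rank-sum results for the 17 items and the total."""

    tests: dict[str, dict[str, float | int]]  # name -> {statistic, p_value, tier}
    alpha_family: float = 0.05
    n_tests: int = N_TESTS

    @property
    def corrected_levels(self) -> tuple[float, ...]:
        return tuple(a / self.n_tests for a in TIER_ALPHAS)

    def to_json(self, path: str | Path) -> None:
        payload = {
            "alpha_family": self.alpha_family,
            "n_tests": self.n_tests,
            "corrected_levels": list(self.corrected_levels),
            "tests": self.tests,
        }
        Path(path).write_text(json.dumps(payload, indent=2))


def item_wise_tests(
    cohort: list[HamdRecord], assignment: dict[str, int | str]
) -> ItemTestReport:
    """Two-sided rank-sum tests per item plus the total, Bonferroni tiers.

    ``tier`` counts how many corrected levels (0.05/18, 0.01/18, 0.005/18)
    the p-value clears: 0 = not significant, 3 = beyond the strictest.
    """
    g1 = [r for r in cohort if assignment.get(r.subject_id) == 1]
    g2 = [r for r in cohort if assignment.get(r.subject_id) == 2]
    if not g1 or not g2:
        raise ValueError("both groups must be non-empty")
    levels = tuple(a / N_TESTS for a in TIER_ALPHAS)

    def one_test(x: np.ndarray, y: np.ndarray) -> dict[str, float | int]:
        if np.ptp(np.concatenate([x, y])) == 0:  # all tied: no evidence
            return {"statistic": float(len(x) * len(y) / 2.0), "p_value": 1.0, "tier": 0}
        res = stats.mannwhitneyu(x, y, alternative="two-sided", method="asymptotic")
        p = float(res.pvalue)
        return {
            "statistic": float(res.statistic),
            "p_value": p,
            "tier": int(sum(p < lv for lv in levels)),
        }

    tests: dict[str, dict[str, float | int]] = {}
    A1 = np.vstack([r.items for r in g1])
    A2 = np.vstack([r.items for r in g2])
    for k in range(N_ITEMS):
        tests[f"item_{k + 1}"] = one_test(A1[:, k], A2[:, k])
    tests["total"] = one_test(
        np.array([r.total for r in g1]), np.array([r.total for r in g2])
    )
    return ItemTestReport(tests=tests)


def write_assignment_csv(path: str | Path, result: ClusteringResult) -> None:
    rows = [
        {"subject_id": sid, "group": result.assignment[sid], "stage": result.stage[sid]}
        for sid in result.assignment
    ]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_assignment_csv(path: str | Path) -> dict[str, int | str]:
    df = pd.read_csv(path)
    out: dict[str, int | str] = {}
    for _, row in df.iterrows():
        g = row["group"]
        out[str(row["subject_id"])] = g if g == "excluded" else int(g)
    return out
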