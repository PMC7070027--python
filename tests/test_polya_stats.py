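"""Exact rank-test implementations against enumeration and scipy oracles;
class summaries and trend reporting."""

import math
import random
from itertools import combinations, product

import numpy as np
import pytest
from scipy import stats as sps

from orfclass import class_series, paired_test, trend_report, unpaired_test
from orfclass.polya_stats import _signed_ranks, _u_statistic


def brute_wilcoxon_p(diffs):
    """Exhaustive 2^n enumeration of sign assignments over the observed
    ranks (two-sided)."""
    ranks, _ = _signed_ranks(diffs)
    w_obs = sum(r for r, d in zip(ranks, diffs) if d > 0)
    n = len(diffs)
    n_le = n_ge = 0
    for signs in product([0, 1], repeat=n):
        w = sum(r for r, s in zip(ranks, signs) if s)
        if w <= w_obs + 1e-9:
            n_le += 1
        if w >= w_obs - 1e-9:
            n_ge += 1
    tot = 2 ** n
    return min(1.0, 2.0 * min(n_le / tot, n_ge / tot))


def brute_mannwhitney_p(x, y):
    """Exhaustive enumeration of all C(n+m, n) group assignments."""
    pool = list(x) + list(y)
    n = len(x)
    u_obs = _u_statistic(x, y)
    idx = range(len(pool))
    n_le = n_ge = n_tot = 0
    for chosen in combinations(idx, n):
        cset = set(chosen)
        u = _u_statistic([pool[i] for i in chosen],
                         [pool[i] for i in idx if i not in cset])
        n_tot += 1
        if u <= u_obs + 1e-9:
            n_le += 1
        if u >= u_obs - 1e-9:
            n_ge += 1
    return min(1.0, 2.0 * min(n_le / n_tot, n_ge / n_tot))


class TestPairedWilcoxon:
    def test_all_negative_distinct_six_pairs(self):
        t1 = [10.0, 20.0, 30.0, 40.0, 50.0, 60.0]
        t2 = [v - d for v, d in zip(t1, [1, 2, 3, 4, 5, 6])]
        w, p, dropped = paired_test(t1, t2)
        assert w == 0
        assert p == pytest.approx(0.03125)
        assert dropped == 0

    def test_exact_equals_bruteforce_enumeration(self):
        rng = random.Random(42)
        for _ in range(80):
            n = rng.randint(5, 12)
            t1 = [rng.uniform(0, 100) for _ in range(n)]
            # mix of shifts, occasional exact ties in |d|
            t2 = [v + rng.choice([-5, -2, -1, 1, 2, 5]) * rng.uniform(0.5, 2)
                  for v in t1]
            diffs = [b - a for a, b in zip(t1, t2)]
            _, p, _ = paired_test(t1, t2)
            assert p == pytest.approx(brute_wilcoxon_p(diffs), abs=1e-12)

    def test_exact_matches_scipy_without_ties(self):
        rng = np.random.default_rng(3)
        for _ in range(50):
            n = int(rng.integers(5, 20))
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0.4, 1, n)
            _, p, _ = paired_test(list(a), list(b))
            ref = sps.wilcoxon(b - a, alternative="two-sided", method="exact")
            assert p == pytest.approx(ref.pvalue, abs=1e-9)

    def test_large_n_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(4)
        for _ in range(20):
            n = int(rng.integers(26, 80))
            a = rng.normal(0, 1, n)
            b = a + rng.normal(0.2, 1, n)
            _, p, _ = paired_test(list(a), list(b))
            ref = sps.wilcoxon(b - a, alternative="two-sided",
                               method="approx", correction=False)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_zero_differences_dropped_and_reported(self):
        t1 = [1.0, 2, 3, 4, 5, 6, 7]
        t2 = [1.0, 2, 4, 5, 6, 7, 8]
        _, _, dropped = paired_test(t1, t2)
        assert dropped == 2

    def test_all_zero_differences_degenerate(self):
        v = [1.0, 2, 3, 4, 5]
        with pytest.raises(ValueError, match="degenerate"):
            paired_test(v, v)

    def test_short_vectors_refused(self):
        with pytest.raises(ValueError):
            paired_test([1, 2, 3], [4, 5, 6])


class TestUnpairedMannWhitney:
    def test_complete_separation_three_vs_three(self):
        u, p = unpaired_test([1, 2, 3], [4, 5, 6])
        assert u == 0
        assert p == pytest.approx(0.1)

    def test_identical_vectors_p_one(self):
        v = [3.0, 1.0, 2.0]
        u, p = unpaired_test(v, v)
        assert p == pytest.approx(1.0)
        assert u == pytest.approx(4.5)  # nm/2 with all-tie half counts

    def test_exact_equals_bruteforce_enumeration(self):
        rng = random.Random(9)
        for _ in range(60):
            n = rng.randint(3, 5)
            m = rng.randint(3, 10 - n)
            x = [rng.randint(0, 8) * 0.5 for _ in range(n)]
            y = [rng.randint(0, 8) * 0.5 for _ in range(m)]
            _, p = unpaired_test(x, y)
            assert p == pytest.approx(brute_mannwhitney_p(x, y), abs=1e-12)

    def test_large_n_matches_scipy_asymptotic(self):
        rng = np.random.default_rng(5)
        for _ in range(20):
            n, m = int(rng.integers(10, 40)), int(rng.integers(10, 40))
            x = list(rng.normal(0, 1, n))
            y = list(rng.normal(0.3, 1, m))
            _, p = unpaired_test(x, y)
            ref = sps.mannwhitneyu(x, y, alternative="two-sided",
                                   method="asymptotic", use_continuity=False)
            assert p == pytest.approx(ref.pvalue, abs=1e-6)

    def test_u_conservation(self):
        rng = random.Random(11)
        for _ in range(100):
            n, m = rng.randint(3, 12), rng.randint(3, 12)
            x = [rng.uniform(0, 10) for _ in range(n)]
            y = [rng.choice(x) if rng.random() < 0.3 else rng.uniform(0, 10)
                 for _ in range(m)]
            assert _u_statistic(x, y) + _u_statistic(y, x) == \
                pytest.approx(n * m)


class TestClassSeriesAndTrend:
    def test_class_means_recovered_within_3_se(self, noise_free_sim,
                                               noise_free_run):
        truth = noise_free_sim["truth"]
        cfg = noise_free_sim["config"]
        by_key = {iso.group_key(): iso for iso in truth.isoforms}
        anns = noise_free_run.annotations
        series = class_series(anns, class_by="group")
        keyed = {}
        for ann in anns:
            k = ann.group.key
            jtxt = ";".join(f"{j.donor}-{j.acceptor}"
                            for j in k.junctions) or "."
            cid = f"{k.strand}:{k.tss_cluster}:{jtxt}:{k.tts_cluster}"
            keyed[cid] = by_key[k]
        checked = 0
        for s in series:
            iso = keyed[s.class_id]
            base = truth.polya_base_mean[iso.iso_id]
            for i, sample in enumerate(cfg.samples):
                if s.n.get(sample, 0) < 5 or s.sd.get(sample) is None:
                    continue
                expected = base * (1 - cfg.polya_decline) ** i
                se = s.sd[sample] / math.sqrt(s.n[sample])
                assert abs(s.mean[sample] - expected) < 3.5 * se + 1e-9
                checked += 1
        assert checked > 10

    def test_single_read_class_has_no_sd(self):
        from orfclass import GroupKey, TranscriptGroup
        from orfclass.orf_annotation import GroupAnnotation
        g = TranscriptGroup(key=GroupKey("+", 100, (), 500),
                            counts={"s1": 1},
                            polya_lengths={"s1": [25.0]})
        ann = GroupAnnotation(group=g, orf_calls=[])
        (s,) = class_series([ann], class_by="group")
        assert s.mean["s1"] == 25.0 and s.sd["s1"] is None and s.n["s1"] == 1

    def test_declining_simulation_detected(self, noise_free_run):
        report = trend_report(noise_free_run.series, noise_free_run.samples)
        for res in report["tests"].values():
            assert res["p_wilcoxon"] < 0.05
        negatives = [d for row in report["deltas"].values()
                     for d in row.values() if d is not None]
        assert sum(1 for d in negatives if d < 0) > 0.8 * len(negatives)

    def test_two_classes_refused_but_deltas_reported(self):
        from orfclass import ClassPolyASeries
        series = [
            ClassPolyASeries("a", mean={"t1": 100.0, "t2": 90.0},
                             sd={}, n={"t1": 5, "t2": 5}),
            ClassPolyASeries("b", mean={"t1": 80.0, "t2": 70.0},
                             sd={}, n={"t1": 5, "t2": 5}),
        ]
        report = trend_report(series, ["t1", "t2"])
        assert "refused" in report["tests"]["t1->t2"]
        assert report["deltas"]["a"]["t1->t2"] == pytest.approx(-10.0)
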