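"""PolyA tail-length summaries per transcript class and shift tests.

The per-read tail estimates come from an external polyA caller's TSV and
are pre-filtered to QC-PASS reads with tails of at least 20 nt.  Classes
(transcript groups, or groups rolled up by encoded feature) each contribute
a per-sample mean; shifts between time points are tested with the Wilcoxon
signed-rank test (each class providing one paired data point) and, as
unpaired values, the Mann-Whitney U test.  Both tests use the exact null
distribution at small n (signed-rank: enumeration of all 2^n sign
assignments via rank-sum convolution; Mann-Whitney: enumeration of all
C(n+m, n) group assignments) and the tie-corrected normal approximation
otherwise.  All p values are two-sided; no multiplicity correction is
applied.
"""

from __future__ import annotations

import logging
import math
import statistics
from dataclasses import dataclass, field
from itertools import combinations
from typing import Optional, Sequence

from .orf_annotation import GroupAnnotation

log = logging.getLogger("orfclass")


@dataclass
class ClassPolyASeries:
    class_id: str
    mean: dict[str, float] = field(default_factory=dict)
    sd: dict[str, Optional[float]] = field(default_factory=dict)
    n: dict[str, int] = field(default_factory=dict)


def class_series(annotations: Sequence[GroupAnnotation],
                 class_by: str = "group") -> list[ClassPolyASeries]:
    """Per-class, per-sample polyA summaries over usable reads.

    ``class_by="group"`` keeps every transcript group as its own class;
    ``"feature"`` pools groups by matched canonical feature (unmatched
    groups pool under "no known ORF").  Classes with no usable reads at all
    are omitted (logged).
    """
    if class_by not in ("group", "feature"):
        raise ValueError(f"class_by must be 'group' or 'feature', got {class_by!r}")
    pools: dict[str, dict[str, list[float]]] = {}
    for ann in annotations:
        g = ann.group
        if class_by == "group":
            k = g.key
            jtxt = ";".join(f"{j.donor}-{j.acceptor}" for j in k.junctions) or "."
            cid = f"{k.strand}:{k.tss_cluster}:{jtxt}:{k.tts_cluster}"
        else:
            cid = ann.matched_feature or "no known ORF"
        dest = pools.setdefault(cid, {})
        for sample, vals in g.polya_lengths.items():
            dest.setdefault(sample, []).extend(vals)
    out = []
    for cid in sorted(pools):
        per_sample = pools[cid]
        if not any(per_sample.values()):
            log.info("class %s has no polyA-usable reads; omitted", cid)
            continue
        series = ClassPolyASeries(class_id=cid)
        for sample, vals in per_sample.items():
            if not vals:
                continue
            series.mean[sample] = sum(vals) / len(vals)
            series.sd[sample] = statistics.stdev(vals) if len(vals) >= 2 else None
            series.n[sample] = len(vals)
        out.append(series)
    return out


def _signed_ranks(diffs: Sequence[float]) -> tuple[list[float], list[int]]:
    """Average ranks of |d| (ties share their midrank) and signs of d."""
    order = sorted(range(len(diffs)), key=lambda i: abs(diffs[i]))
    ranks = [0.0] * len(diffs)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and \
                abs(diffs[order[j + 1]]) == abs(diffs[order[i]]):
            j += 1
        mid = (i + j) / 2 + 1
        for k in range(i, j + 1):
            ranks[order[k]] = mid
        i = j + 1
    signs = [1 if d > 0 else -1 for d in diffs]
    return ranks, signs


def _wilcoxon_exact_p(ranks: Sequence[float], w_plus: float) -> float:
    """Exact two-sided p by convolving the 2^n sign-assignment distribution.

    Ranks are doubled to integers so tied (half-integer) midranks are exact.
    """
    r2 = [round(2 * r) for r in ranks]
    total = sum(r2)
    # counts[s] = number of sign assignments with doubled W+ == s
    counts = [0] * (total + 1)
    counts[0] = 1
    for r in r2:
        nxt = counts[:]
        for s in range(total - r + 1):
            if counts[s]:
                nxt[s + r] += counts[s]
        counts = nxt
    denom = float(2 ** len(r2))
    w2 = round(2 * w_plus)
    p_le = sum(counts[: w2 + 1]) / denom
    p_ge = sum(counts[w2:]) / denom
    return min(1.0, 2.0 * min(p_le, p_ge))


def paired_test(means_t1: Sequence[float], means_t2: Sequence[float],
                exact_max_n: int = 25) -> tuple[float, float, int]:
    """Wilcoxon signed-rank test on paired per-class means.

    Differences are taken as t2 - t1; zero differences are dropped (their
    count is returned as the third element).  Exact null for n <= 25,
    tie-corrected normal approximation (no continuity correction) beyond.
    Returns (W+ statistic, two-sided p, n_zero_dropped).
    """
    if len(means_t1) != len(means_t2):
        raise ValueError("paired vectors must have equal length")
    if len(means_t1) < 5:
        raise ValueError("paired test requires at least 5 pairs")
    diffs = [b - a for a, b in zip(means_t1, means_t2)]
    nonzero = [d for d in diffs if d != 0]
    n_zero = len(diffs) - len(nonzero)
    if not nonzero:
        raise ValueError("degenerate pairing: all differences zero")
    ranks, signs = _signed_ranks(nonzero)
    w_plus = sum(r for r, s in zip(ranks, signs) if s > 0)
    n = len(nonzero)
    if n <= exact_max_n:
        p = _wilcoxon_exact_p(ranks, w_plus)
    else:
        mu = n * (n + 1) / 4.0
        tie_term = 0.0
        seen: dict[float, int] = {}
        for d in nonzero:
            seen[abs(d)] = seen.get(abs(d), 0) + 1
        for t in seen.values():
            tie_term += t ** 3 - t
        var = n * (n + 1) * (2 * n + 1) / 24.0 - tie_term / 48.0
        z = (w_plus - mu) / math.sqrt(var)
        p = 2.0 * (1.0 - _norm_cdf(abs(z)))
    return w_plus, p, n_zero


def _norm_cdf(x: float) -> float:
    return 0.5 * (1.0 + math.erf(x / math.sqrt(2.0)))


def _u_statistic(x: Sequence[float], y: Sequence[float]) -> float:
    u = 0.0
    for xi in x:
        for yi in y:
            if xi > yi:
                u += 1.0
            elif xi == yi:
                u += 0.5
    return u


def unpaired_test(x: Sequence[float], y: Sequence[float],
                  exact_max_total: int = 12) -> tuple[float, float]:
    """Mann-Whitney U test, two-sided.

    Exact by enumeration of all C(n+m, n) assignments of the pooled values
    when n + m <= 12 (ties handled naturally by re-splitting the observed
    pool); tie-corrected normal approximation otherwise.  Returns (U of x
    over y, two-sided p).
    """
    n, m = len(x), len(y)
    if n < 3 or m < 3:
        raise ValueError("unpaired test requires at least 3 values per group")
    u_obs = _u_statistic(x, y)
    if n + m <= exact_max_total:
        pool = list(x) + list(y)
        idx = range(n + m)
        n_le = n_ge = n_tot = 0
        for chosen in combinations(idx, n):
            cset = set(chosen)
            xs = [pool[i] for i in chosen]
            ys = [pool[i] for i in idx if i not in cset]
            u = _u_statistic(xs, ys)
            n_tot += 1
            if u <= u_obs + 1e-9:
                n_le += 1
            if u >= u_obs - 1e-9:
                n_ge += 1
        p = min(1.0, 2.0 * min(n_le / n_tot, n_ge / n_tot))
    else:
        big_n = n + m
        mu = n * m / 2.0
        seen: dict[float, int] = {}
        for v in list(x) + list(y):
            seen[v] = seen.get(v, 0) + 1
        tie_term = sum(t ** 3 - t for t in seen.values())
        var = n * m / 12.0 * ((big_n + 1) - tie_term / (big_n * (big_n - 1)))
        z = (u_obs - mu) / math.sqrt(var)
        p = 2.0 * (1.0 - _norm_cdf(abs(z)))
    return u_obs, p


def trend_report(series: Sequence[ClassPolyASeries],
                 sample_order: Sequence[str]) -> dict:
    """Per-class mean polyA deltas between consecutive samples plus the
    paired (signed-rank) and unpaired (Mann-Whitney) tests over class means.

    Tests are refused (reported as None with a reason) when fewer than 5
    classes are measured in both samples of a transition.
    """
    if len(sample_order) < 2:
        raise ValueError("trend report needs at least 2 samples")
    deltas: dict[str, dict[str, Optional[float]]] = {}
    for s in series:
        row: dict[str, Optional[float]] = {}
        for a, b in zip(sample_order, sample_order[1:]):
            if a in s.mean and b in s.mean:
                row[f"{a}->{b}"] = s.mean[b] - s.mean[a]
            else:
                row[f"{a}->{b}"] = None
        deltas[s.class_id] = row
    tests: dict[str, dict] = {}
    for a, b in zip(sample_order, sample_order[1:]):
        pair = [(s.mean[a], s.mean[b]) for s in series
                if a in s.mean and b in s.mean]
        key = f"{a}->{b}"
        if len(pair) < 5:
            tests[key] = {"refused": f"only {len(pair)} classes with data "
                                     "in both samples (need >= 5)"}
            continue
        va = [p[0] for p in pair]
        vb = [p[1] for p in pair]
        w, p_w, n_zero = paired_test(va, vb)
        u, p_u = unpaired_test(va, vb)
        tests[key] = {"n_classes": len(pair), "W": w, "p_wilcoxon": p_w,
                      "zeros_dropped": n_zero, "U": u, "p_mannwhitney": p_u}
    return {"deltas": deltas, "tests": tests}


def write_trend_table(report: dict, series: Sequence[ClassPolyASeries],
                      sample_order: Sequence[str], path: str) -> None:
    with open(path, "w") as fh:
        trans = [f"{a}->{b}" for a, b in zip(sample_order, sample_order[1:])]
        cols = ["class"]
        for s in sample_order:
            cols += [f"mean_{s}", f"sd_{s}", f"n_{s}"]
        cols += [f"delta_{t}" for t in trans]
        fh.write("\t".join(cols) + "\n")
        by_id = {s.class_id: s for s in series}
        for cid in sorted(by_id):
            s = by_id[cid]
            row = [cid]
            for smp in sample_order:
                row += [f"{s.mean[smp]:.2f}" if smp in s.mean else "NA",
                        f"{s.sd[smp]:.2f}" if s.sd.get(smp) is not None else "NA",
                        str(s.n.get(smp, 0))]
            for t in trans:
                d = report["deltas"][cid][t]
                row.append(f"{d:.2f}" if d is not None else "NA")
            fh.write("\t".join(row) + "\n")
        for t, res in report["tests"].items():
            fh.write(f"# test {t}: {res}\n")
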