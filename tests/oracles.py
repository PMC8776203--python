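"""Independent brute-force oracles used to cross-check the implementation.

Everything here is written from first principles (enumeration, closed
forms, quadratic scans) and deliberately shares no code with the package.
"""

from __future__ import annotations

import itertools
from math import comb

import numpy as np


def bh_stepup(p: list[float]) -> list[float]:
    """Benjamini–Hochberg by the textbook formula: q_i = min_{j>=i} m*p_(j)/j."""
    m = len(p)
    order = sorted(range(m), key=lambda i: p[i])
    q = [0.0] * m
    running = 1.0
    for rank in range(m, 0, -1):
        i = order[rank - 1]
        running = min(running, m * p[i] / rank)
        q[i] = running
    return q


def hypergeom_pmf(a: int, n: int, r: int, k: int) -> float:
    """P(X = a) for the 2x2 family with margins (r, n-r) x (k, n-k)."""
    return comb(r, a) * comb(n - r, k - a) / comb(n, k)


def fisher_two_sided(table) -> float:
    """Two-sided Fisher p by exhaustive enumeration of the margin family.

    Sums the probabilities of all tables no more probable than the observed
    one (with the customary (1 + 1e-7) tolerance on ties).
    """
    (a, b), (c, d) = table
    n = a + b + c + d
    r, k = a + b, a + c
    if n == 0:
        return 1.0
    p_obs = hypergeom_pmf(a, n, r, k)
    total = 0.0
    for x in range(max(0, r + k - n), min(r, k) + 1):
        px = hypergeom_pmf(x, n, r, k)
        if px <= p_obs * (1 + 1e-7):
            total += px
    return min(1.0, total)


def hypergeom_upper_tail(x: int, n_total: int, n_marked: int, n_drawn: int) -> float:
    """P(X >= x) by direct summation of the hypergeometric pmf."""
    hi = min(n_marked, n_drawn)
    return sum(hypergeom_pmf(a, n_total, n_marked, n_drawn) for a in range(x, hi + 1))


def wcss(points: np.ndarray, assign: np.ndarray) -> float:
    """Within-cluster sum of squares for a given assignment."""
    total = 0.0
    for cl in np.unique(assign):
        sub = points[assign == cl]
        total += float(((sub - sub.mean(axis=0)) ** 2).sum())
    return total


def best_bipartition_wcss(points: np.ndarray) -> float:
    """Minimum WCSS over every 2-cluster partition (exhaustive)."""
    n = len(points)
    best = np.inf
    for mask in range(1, 2 ** (n - 1)):  # fix point 0 in cluster 0; skip empty
        assign = np.array([(mask >> i) & 1 for i in range(n)])
        best = min(best, wcss(points, assign))
    return best


def nearest_peak_bruteforce(genes, peaks):
    """All-pairs nearest peak per gene: (peak name, signed distance) or None."""
    out = {}
    for g in genes:
        anchor = g.start if g.strand in ("+", ".") else g.end - 1
        best = None
        for p in peaks:
            if p.chrom != g.chrom:
                continue
            if p.start <= anchor <= p.end - 1:
                d = 0
            elif anchor < p.start:
                d = p.start - anchor
            else:
                d = (p.end - 1) - anchor
            if best is None or abs(d) < abs(best[1]):
                best = (p.name, d)
        out[g.name] = best
    return out


def venn_regions_bruteforce(sets: dict) -> dict[str, int]:
    """Exclusive region counts by per-element membership bitmasks."""
    keys = sorted(sets)
    counts: dict[str, int] = {}
    for r in range(len(keys), 0, -1):
        for combo in itertools.combinations(keys, r):
            region = "&".join(str(k) for k in combo)
            inc = set(combo)
            exc = set(keys) - inc
            members = set.intersection(*(sets[k] for k in inc))
            for k in exc:
                members -= sets[k]
            counts[region] = len(members)
    return counts


def rms_top_differences(x: np.ndarray, y: np.ndarray, top_n: int) -> float:
    """Sort-square-average oracle for the leading-difference sample distance."""
    d2 = sorted(((xi - yi) ** 2 for xi, yi in zip(x, y)), reverse=True)
    d2 = d2[: min(top_n, len(d2))]
    return float(np.sqrt(sum(d2) / len(d2)))


def tmm_reference_factor(obs, ref, lib_obs, lib_ref, trim_m=0.30, trim_a=0.05) -> float:
    """Hand trim-and-weighted-average TMM factor (single pair), small n only.

    Re-derives the trimmed sets by explicit rank enumeration so the package
    implementation can be checked gene by gene.
    """
    rows = []
    for o, r in zip(obs, ref):
        if o > 0 and r > 0:
            m = np.log2((o / lib_obs) / (r / lib_ref))
            a = 0.5 * np.log2((o / lib_obs) * (r / lib_ref))
            v = (lib_obs - o) / (lib_obs * o) + (lib_ref - r) / (lib_ref * r)
            rows.append((m, a, v))
    n = len(rows)
    ms = [r[0] for r in rows]
    as_ = [r[1] for r in rows]
    lo_m = int(np.floor(n * trim_m)) + 1
    hi_m = n + 1 - lo_m
    lo_a = int(np.floor(n * trim_a)) + 1
    hi_a = n + 1 - lo_a
    rank_m = {i: 1 + sum(1 for j in range(n) if ms[j] < ms[i]) for i in range(n)}
    rank_a = {i: 1 + sum(1 for j in range(n) if as_[j] < as_[i]) for i in range(n)}
    kept = [
        i for i in range(n)
        if lo_m <= rank_m[i] <= hi_m and lo_a <= rank_a[i] <= hi_a
    ]
    num = sum(rows[i][0] / rows[i][2] for i in kept)
    den = sum(1.0 / rows[i][2] for i in kept)
    return 2.0 ** (num / den)
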