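"""Independent first-principles oracles used by the test suite.

Everything here is deliberately naive (loops, closed forms, exhaustive
enumeration) and shares no code with the package paths it checks.
"""

from __future__ import annotations

import math


def haldane_r(d_cM: float) -> float:
    """Haldane map function: recombination fraction for a distance in cM."""
    return 0.5 * (1.0 - math.exp(-2.0 * d_cM / 100.0))


def haldane_d(r: float) -> float:
    """Inverse Haldane: cM distance giving recombination fraction r."""
    return -50.0 * math.log(1.0 - 2.0 * r)


def selfing_ril_recombinant_fraction(r: float) -> float:
    """Haldane-Waddington: recombinant fraction among fully selfed RILs."""
    return 2.0 * r / (1.0 + 2.0 * r)


def brute_force_windows(pos, vals, window_bp, step_bp):
    """Sliding-window means by direct looping over the anchor grid.

    Windows [a, a + window_bp) with anchors a = 1, 1+step, ...; empty
    windows emit nothing. Returns (midpoint, mean, n_snps) tuples.
    """
    out = []
    a = 1
    while a <= max(pos):
        sel = [v for p, v in zip(pos, vals) if a <= p < a + window_bp]
        if sel:
            out.append((a + (window_bp - 1) // 2, sum(sel) / len(sel), len(sel)))
        a += step_bp
    return out


def midranks(values):
    """Mid-ranks (average rank of tied values), 1-based."""
    order = sorted(range(len(values)), key=lambda i: values[i])
    ranks = [0.0] * len(values)
    i = 0
    while i < len(order):
        j = i
        while j + 1 < len(order) and values[order[j + 1]] == values[order[i]]:
            j += 1
        avg = (i + j) / 2.0 + 1.0
        for k in range(i, j + 1):
            ranks[order[k]] = avg
        i = j + 1
    return ranks


def wilcoxon_w(x, y) -> float:
    """Rank-sum W of the first group (mid-ranks) minus n_x(n_x+1)/2."""
    ranks = midranks(list(x) + list(y))
    return sum(ranks[: len(x)]) - len(x) * (len(x) + 1) / 2.0


def dunn_z(groups: dict) -> dict:
    """Dunn (1964) pairwise Z with tie-corrected SE, from first principles."""
    names = sorted(groups)
    values = [v for g in names for v in groups[g]]
    ranks = midranks(values)
    n = len(values)
    # tie sizes
    seen = {}
    for v in values:
        seen[v] = seen.get(v, 0) + 1
    tie_term = sum(t**3 - t for t in seen.values()) / (12.0 * (n - 1))
    var_unit = n * (n + 1) / 12.0 - tie_term
    mean_rank, start = {}, 0
    for g in names:
        k = len(groups[g])
        mean_rank[g] = sum(ranks[start : start + k]) / k
        start += k
    out = {}
    for i, a in enumerate(names):
        for b in names[i + 1 :]:
            se = math.sqrt(var_unit * (1.0 / len(groups[a]) + 1.0 / len(groups[b])))
            out[(a, b)] = (mean_rank[a] - mean_rank[b]) / se
    return out


def exact_lor_null(n_rils: int, pseudocount: float):
    """Exhaustive product-binomial null of the pool log-odds ratio.

    Enumerates all (m1, m2) outcomes of two independent Binomial(n, 1/2)
    pools; returns the sorted (value, probability) pairs.
    """
    pmf = [math.comb(n_rils, m) * 0.5**n_rils for m in range(n_rils + 1)]
    items = {}
    for m1 in range(n_rils + 1):
        for m2 in range(n_rils + 1):
            v = math.log((m1 + pseudocount) / (n_rils - m1 + pseudocount)) - math.log(
                (m2 + pseudocount) / (n_rils - m2 + pseudocount)
            )
            v = round(v, 12)
            items[v] = items.get(v, 0.0) + pmf[m1] * pmf[m2]
    return sorted(items.items())


def exact_lor_quantile(n_rils: int, pseudocount: float, q: float) -> float:
    """inf{x : F(x) >= q} of the exact null, plus nothing else."""
    cum = 0.0
    for v, p in exact_lor_null(n_rils, pseudocount):
        cum += p
        if cum >= q:
            return v
    raise AssertionError("quantile not reached")


def lor_spacing_at(n_rils: int, pseudocount: float, x: float) -> float:
    """Largest gap between attainable null LOR values adjacent to x."""
    values = [v for v, _ in exact_lor_null(n_rils, pseudocount)]
    import bisect

    i = bisect.bisect_left(values, x)
    gaps = []
    if 0 < i < len(values):
        gaps.append(values[i] - values[i - 1])
    if i + 1 < len(values):
        gaps.append(values[i + 1] - values[i])
    return max(gaps)
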