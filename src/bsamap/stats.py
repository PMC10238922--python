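"""Nonparametric phenotype comparisons: Wilcoxon rank-sum, Dunn's test,
and compact letter display.

These are the tests used on animal- and line-level position tables:
two-group comparisons by Wilcoxon's rank-sum W, multi-group post-hoc
comparisons by Dunn's rank test with Bonferroni adjustment, and letters
summarising which groups are mutually indistinguishable.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class WilcoxonResult:
    W: float
    p_value: float


def wilcoxon_rank_sum(x, y, method: str = "asymptotic") -> WilcoxonResult:
    """Two-sided Wilcoxon rank-sum test.

    W is the rank sum of ``x`` (mid-ranks under ties) minus
    n_x(n_x+1)/2, i.e. the Mann-Whitney U of the first-named group; it
    can be half-integer when ties straddle the groups. The default
    p-value uses the normal approximation with tie correction and
    continuity correction — the convention of R's ``wilcox.test`` for
    tied or large samples; ``method="exact"`` switches to the exact
    distribution (untied samples only).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    res = stats.mannwhitneyu(x, y, alternative="two-sided", method=method,
                             use_continuity=True)
    return WilcoxonResult(float(res.statistic), float(res.pvalue))


@dataclass
class ComparisonResult:
    """All pairwise comparisons of a multi-group test plus group letters.

    ``pairs`` columns: group_a, group_b (lexicographic within pair and
    across rows), statistic (Dunn Z, sign = mean-rank(a) - mean-rank(b)),
    p_raw, p_adjusted (Bonferroni, capped at 1). ``letters`` maps each
    group to its compact-letter string, filled in by
    :func:`compact_letters`.
    """

    pairs: pd.DataFrame
    letters: dict[str, str] | None = None


def _groups_from_table(table: pd.DataFrame) -> dict[str, np.ndarray]:
    if not {"group", "value"}.issubset(table.columns):
        raise ValueError("phenotype table needs 'group' and 'value' columns")
    groups = {str(g): sub["value"].to_numpy(dtype=float)
              for g, sub in table.groupby("group", sort=True)}
    if len(groups) < 2:
        raise ValueError("need >= 2 groups")
    for g, v in groups.items():
        if v.size == 0:
            raise ValueError(f"group {g!r} is empty")
    return groups


def dunn_test(table: pd.DataFrame, adjust: str = "bonferroni") -> ComparisonResult:
    """Dunn's (1964) post-hoc rank test for all group pairs.

    Values of all groups are ranked together with mid-ranks; for a pair
    (a, b) the statistic is

        Z = (Rbar_a - Rbar_b) / sqrt[(N(N+1)/12 - T) (1/n_a + 1/n_b)],

    where T = sum(t^3 - t) / (12 (N - 1)) corrects for tie groups of
    size t. Two-sided normal p-values are Bonferroni-multiplied by the
    number of pairs.
    """
    if adjust != "bonferroni":
        raise ValueError("only Bonferroni adjustment is supported")
    groups = _groups_from_table(table)
    names = sorted(groups)
    values = np.concatenate([groups[g] for g in names])
    labels = np.concatenate([np.repeat(g, groups[g].size) for g in names])
    ranks = stats.rankdata(values)  # mid-ranks
    n_total = values.size
    _, tie_counts = np.unique(values, return_counts=True)
    tie_term = float(np.sum(tie_counts**3 - tie_counts)) / (12.0 * (n_total - 1))
    var_unit = n_total * (n_total + 1) / 12.0 - tie_term
    mean_rank = {g: float(ranks[labels == g].mean()) for g in names}
    n_pairs = len(names) * (len(names) - 1) // 2
    rows = []
    for a, b in combinations(names, 2):
        se = np.sqrt(var_unit * (1.0 / groups[a].size + 1.0 / groups[b].size))
        z = (mean_rank[a] - mean_rank[b]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        rows.append((a, b, float(z), float(p), float(min(1.0, p * n_pairs))))
    pairs = pd.DataFrame(rows, columns=["group_a", "group_b", "statistic",
                                        "p_raw", "p_adjusted"])
    return ComparisonResult(pairs)


def compact_letters(result: ComparisonResult, level: float = 0.05) -> dict[str, str]:
    """Insert-and-absorb compact letter display.

    Groups sharing a letter are pairwise non-significant at ``level``
    (adjusted p); each significant pair shares no letter. Letters are a
    clique cover of the non-significance graph, built by the classic
    insert-and-absorb sweep: start from one column holding every group,
    split columns on each significant pair, then absorb columns that are
    subsets of another.
    """
    pairs = result.pairs
    names = sorted(set(pairs["group_a"]) | set(pairs["group_b"]))
    columns: list[set[str]] = [set(names)]
    sig = pairs.loc[pairs["p_adjusted"] < level, ["group_a", "group_b"]]
    for a, b in sig.itertuples(index=False):
        new_cols: list[set[str]] = []
        for col in columns:
            if a in col and b in col:
                new_cols.extend([col - {a}, col - {b}])
            else:
                new_cols.append(col)
        # absorb: deduplicate, then drop any column contained in another
        uniq = [set(c) for c in {frozenset(c) for c in new_cols if c}]
        columns = [c for c in uniq if not any(c < d for d in uniq)]
    columns.sort(key=lambda c: min(names.index(g) for g in c))
    letters = {g: "" for g in names}
    for i, col in enumerate(columns):
        letter = chr(ord("a") + i)
        for g in sorted(col):
            letters[g] += letter
    result.letters = letters
    return letters
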