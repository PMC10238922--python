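"""Bulk segregant analysis core: pool allele frequencies to QTL intervals.

Pipeline, in order: per-site JU1242 allele frequency in each pool, a
strict coverage filter, 200 bp / 1 bp sliding-window smoothing of the
frequencies, a pseudocounted log-odds-ratio statistic comparing the pools
on the RIL-count scale, a genome-wide significance threshold simulated
from a product-binomial null, and run-length interval calling with
fixation flagging.

The statistic at a position with smoothed pool frequencies f1, f2 and
n RILs per pool is

    LOR = ln[ (m1 + eps) / (n - m1 + eps) ] - ln[ (m2 + eps) / (n - m2 + eps) ],
    m_i = f_i * n,

with eps a small pseudocount keeping the value finite at fixation. The
null takes m_i ~ Binomial(n, 1/2) independently in each pool — the
distribution of the JU1242 allele count among n homozygous RILs at a
neutral locus.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .pools import ORIGIN_JU, validate_pool_counts


@dataclass
class BsaParams:
    """Tuning constants of the scan.

    Defaults mirror the study design: 40 RILs per pool, pseudocount 1e-6,
    200 bp windows stepped 1 bp, sites kept only when coverage is
    strictly above 10 in both pools, and a p=0.001 genome-wide threshold
    from one million null draws.
    """

    n_rils_per_pool: int = 40
    pseudocount: float = 1e-6
    window_bp: int = 200
    step_bp: int = 1
    min_coverage: int = 10
    alpha: float = 0.001
    n_null_draws: int = 1_000_000

    def __post_init__(self) -> None:
        if min(self.n_rils_per_pool, self.window_bp, self.step_bp) < 1:
            raise ValueError("n_rils_per_pool, window_bp, step_bp must be positive")
        if self.pseudocount <= 0:
            raise ValueError("pseudocount must be > 0")
        if not 0.0 < self.alpha < 1.0:
            raise ValueError("alpha must lie in (0, 1)")
        if self.min_coverage < 0 or self.n_null_draws < 1:
            raise ValueError("min_coverage >= 0 and n_null_draws >= 1 required")


# ---------------------------------------------------------------------------
# frequencies and filtering
# ---------------------------------------------------------------------------

def ju1242_frequency(read_var, read_tot, variant_origin):
    """JU1242 allele frequency from variant/total read counts.

    At sites whose ascertained variant comes from JU1242 this is
    var/tot; at CB4932-origin sites it is 1 - var/tot. Vectorised.
    """
    read_var = np.asarray(read_var, dtype=float)
    read_tot = np.asarray(read_tot, dtype=float)
    if np.any(read_tot <= 0):
        raise ValueError("read_tot must be > 0 (filter zero-coverage sites first)")
    if np.any((read_var < 0) | (read_var > read_tot)):
        raise ValueError("need 0 <= read_var <= read_tot")
    frac = read_var / read_tot
    is_ju = np.asarray(variant_origin) == ORIGIN_JU
    return np.where(is_ju, frac, 1.0 - frac)[()]


def filter_by_coverage(counts: pd.DataFrame, min_coverage: int = 10) -> pd.DataFrame:
    """Keep sites with coverage strictly above ``min_coverage`` in both pools."""
    validate_pool_counts(counts)
    keep = (counts["tot1"] > min_coverage) & (counts["tot2"] > min_coverage)
    return counts.loc[keep].reset_index(drop=True)


def pool_frequencies(counts: pd.DataFrame) -> pd.DataFrame:
    """Per-site JU1242 frequency in each pool (columns freq1, freq2)."""
    return pd.DataFrame(
        {
            "chrom": counts["chrom"],
            "pos": counts["pos"],
            "freq1": ju1242_frequency(counts["var1"], counts["tot1"], counts["origin"]),
            "freq2": ju1242_frequency(counts["var2"], counts["tot2"], counts["origin"]),
        }
    )


# ---------------------------------------------------------------------------
# sliding-window smoothing
# ---------------------------------------------------------------------------

def _window_anchors(pos: np.ndarray, window_bp: int, step_bp: int) -> np.ndarray:
    """Anchors (window starts on the step grid, 1-based) of non-empty windows.

    Windows are [a, a + window_bp), so a site at p is covered by anchors
    in [p - window_bp + 1, p]. Empty windows are never materialised, so
    step 1 over a megabase-scale chromosome stays cheap.
    """
    lo = np.maximum(pos - window_bp + 1, 1)
    # smallest grid anchor >= lo : grid points are 1, 1+step, 1+2*step, ...
    k_lo = np.ceil((lo - 1) / step_bp).astype(np.int64)
    k_hi = (pos - 1) // step_bp  # largest grid anchor <= pos
    counts = np.maximum(k_hi - k_lo + 1, 0)
    reps = np.repeat(k_lo, counts)
    offsets = np.arange(counts.sum()) - np.repeat(np.cumsum(counts) - counts, counts)
    return np.unique(1 + (reps + offsets) * step_bp)


def _smooth_chromosome(
    pos: np.ndarray, values: np.ndarray, window_bp: int, step_bp: int
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    anchors = _window_anchors(pos, window_bp, step_bp)
    lo = np.searchsorted(pos, anchors, side="left")
    hi = np.searchsorted(pos, anchors + window_bp, side="left")
    n = hi - lo
    csum = np.concatenate([np.zeros((1, values.shape[1])), np.cumsum(values, axis=0)])
    means = (csum[hi] - csum[lo]) / n[:, None]
    mid = anchors + (window_bp - 1) // 2
    return mid, means, n


def sliding_window_smooth(
    per_site: pd.DataFrame,
    window_bp: int = 200,
    step_bp: int = 1,
    value_columns: tuple[str, ...] = ("freq1", "freq2"),
) -> pd.DataFrame:
    """Smooth per-site frequencies with a sliding window.

    Windows are 1-based, half-open [anchor, anchor + window_bp), anchored
    on the step grid; each non-empty window emits the unweighted mean of
    the SNP values inside at the window midpoint (floor). Windows with no
    SNPs emit nothing. Input must be position-sorted within chromosome.
    """
    if len(per_site) == 0:
        raise ValueError("no data: empty per-site frequency table")
    out = []
    for chrom, sub in per_site.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy(dtype=np.int64)
        vals = sub[list(value_columns)].to_numpy(dtype=float)
        mid, means, n = _smooth_chromosome(pos, vals, window_bp, step_bp)
        frame = pd.DataFrame({"chrom": chrom, "pos": mid, "n_snps_in_window": n})
        for j, c in enumerate(value_columns):
            frame[c] = means[:, j]
        out.append(frame)
    cols = ["chrom", "pos", *value_columns, "n_snps_in_window"]
    return pd.concat(out, ignore_index=True)[cols]


# ---------------------------------------------------------------------------
# log-odds ratio and its null
# ---------------------------------------------------------------------------

def lor_from_counts(m1, m2, n_rils: int, pseudocount: float):
    """LOR on the RIL-count scale (m_i = JU1242 frequency x pool size)."""
    m1 = np.asarray(m1, dtype=float)
    m2 = np.asarray(m2, dtype=float)
    eps = pseudocount
    return (
        np.log((m1 + eps) / (n_rils - m1 + eps))
        - np.log((m2 + eps) / (n_rils - m2 + eps))
    )[()]


def log_odds_ratio(f1, f2, params: BsaParams = None):
    """Pseudocounted log-odds ratio between pool JU1242 frequencies.

    Natural log. Positive values mean pool 1 carries the JU1242 allele at
    higher frequency than pool 2; finite for all inputs including
    fixation (f = 0 or 1) thanks to the pseudocount.
    """
    params = params or BsaParams()
    n = params.n_rils_per_pool
    return lor_from_counts(np.asarray(f1, float) * n, np.asarray(f2, float) * n,
                           n, params.pseudocount)


def simulate_threshold(
    params: BsaParams = None, rng_seed=None, null_model: str = "binomial"
) -> tuple[float, float]:
    """Monte-Carlo genome-wide significance thresholds (low, high).

    Draws m1, m2 independently from the null and computes the LOR of
    each pair. The null is exactly symmetric under pool swap, so the
    (alpha/2, 1-alpha/2) pair of tail quantiles equals (-t, t) with t
    the empirical (1-alpha) quantile of |LOR|; the latter is returned
    (it pools both tails, halving the Monte-Carlo error and making
    threshold_low == -threshold_high exact).

    null_model "binomial" (default) is m ~ Binomial(n_rils, 1/2):
    RIL-sampling noise only. "read_depth" additionally resamples each m
    through Poisson(20x)-depth binomial read counts, a wider null that
    accounts for finite sequencing coverage.
    """
    params = params or BsaParams()
    if params.n_null_draws < 1000:
        raise ValueError("n_null_draws must be >= 1000")
    rng = np.random.default_rng(rng_seed)
    n = params.n_rils_per_pool
    m1 = rng.binomial(n, 0.5, size=params.n_null_draws).astype(float)
    m2 = rng.binomial(n, 0.5, size=params.n_null_draws).astype(float)
    if null_model == "read_depth":
        m1 = _resample_through_reads(m1, n, rng)
        m2 = _resample_through_reads(m2, n, rng)
    elif null_model != "binomial":
        raise ValueError("null_model must be 'binomial' or 'read_depth'")
    draws = lor_from_counts(m1, m2, n, params.pseudocount)
    t = float(np.quantile(np.abs(draws), 1.0 - params.alpha))
    return -t, t


def _resample_through_reads(
    m: np.ndarray, n_rils: int, rng: np.random.Generator, mean_depth: float = 20.0,
    min_coverage: int = 10,
) -> np.ndarray:
    """Push null RIL counts through Poisson-depth binomial read sampling."""
    depth = rng.poisson(mean_depth, size=m.shape)
    depth = np.maximum(depth, min_coverage + 1)  # coverage filter keeps > min
    reads = rng.binomial(depth, m / n_rils)
    return n_rils * reads / depth


def exact_null_distribution(params: BsaParams = None):
    """Exact null LOR distribution by enumerating all (m1, m2) pairs.

    Returns (values, cdf): the sorted distinct attainable LOR values and
    the cumulative product-binomial probability at each. 41 x 41 states
    for 40-RIL pools, so this is closed-form cheap and serves as the
    reference the Monte-Carlo threshold is checked against.
    """
    params = params or BsaParams()
    n = params.n_rils_per_pool
    m = np.arange(n + 1, dtype=float)
    pm = stats.binom.pmf(np.arange(n + 1), n, 0.5)
    lor = lor_from_counts(m[:, None], m[None, :], n, params.pseudocount).ravel()
    prob = np.outer(pm, pm).ravel()
    order = np.argsort(lor)
    lor, prob = lor[order], prob[order]
    values, start = np.unique(np.round(lor, 12), return_index=True)
    cdf = np.add.reduceat(prob, start).cumsum()
    return values, cdf


def exact_threshold(params: BsaParams = None) -> tuple[float, float]:
    """Exact (low, high) null quantiles: inf{x : F(x) >= q} per tail."""
    params = params or BsaParams()
    values, cdf = exact_null_distribution(params)
    hi = values[np.searchsorted(cdf, 1.0 - params.alpha / 2.0, side="left")]
    lo = values[np.searchsorted(cdf, params.alpha / 2.0, side="left")]
    return float(lo), float(hi)


# ---------------------------------------------------------------------------
# interval calling and the full scan
# ---------------------------------------------------------------------------

@dataclass
class LorResult:
    """Scan output: per-position LOR track, thresholds, called intervals.

    ``track`` columns: chrom, pos, freq1, freq2, n_snps_in_window, lor.
    ``intervals`` columns: chrom, start, end, direction ('pool1' when the
    anterior/pool-1 JU1242 frequency is the high one, 'pool2' otherwise),
    n_positions, fixed (bool). ``fixed_regions`` restricts each interval
    to the sub-runs where the favoured pool's smoothed frequency is
    within fixation_eps of 1. Coordinates 1-based inclusive.
    """

    track: pd.DataFrame
    threshold_low: float
    threshold_high: float
    intervals: pd.DataFrame = field(default_factory=pd.DataFrame)
    fixed_regions: pd.DataFrame = field(default_factory=pd.DataFrame)


_INTERVAL_COLS = ["chrom", "start", "end", "direction", "n_positions", "fixed"]
_FIXED_COLS = ["chrom", "start", "end", "direction"]


def _runs(mask: np.ndarray):
    """(start_idx, end_idx) inclusive index pairs of True runs."""
    if not mask.any():
        return []
    d = np.diff(mask.astype(np.int8))
    starts = np.flatnonzero(d == 1) + 1
    ends = np.flatnonzero(d == -1)
    if mask[0]:
        starts = np.r_[0, starts]
    if mask[-1]:
        ends = np.r_[ends, len(mask) - 1]
    return list(zip(starts, ends))


def call_qtl_intervals(
    track: pd.DataFrame,
    thresholds: tuple[float, float],
    fixation_eps: float = 0.02,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Maximal runs of threshold-exceeding positions, with fixation flags.

    ``track`` must carry chrom, pos, lor and the smoothed freq1/freq2
    columns. Returns (intervals, fixed_regions); both may be empty.
    """
    t_lo, t_hi = thresholds
    intervals, fixed = [], []
    for chrom, sub in track.groupby("chrom", sort=False):
        pos = sub["pos"].to_numpy()
        lor = sub["lor"].to_numpy()
        for direction, mask in (("pool1", lor > t_hi), ("pool2", lor < t_lo)):
            fav = sub["freq1" if direction == "pool1" else "freq2"].to_numpy()
            for i, j in _runs(mask):
                sub_fixed = []
                inner = fav[i : j + 1] >= 1.0 - fixation_eps
                for a, b in _runs(inner):
                    sub_fixed.append((chrom, int(pos[i + a]), int(pos[i + b]), direction))
                intervals.append(
                    (chrom, int(pos[i]), int(pos[j]), direction, j - i + 1, bool(sub_fixed))
                )
                fixed.extend(sub_fixed)
    intervals_df = pd.DataFrame(intervals, columns=_INTERVAL_COLS)
    fixed_df = pd.DataFrame(fixed, columns=_FIXED_COLS)
    return intervals_df, fixed_df


def bsa_scan(
    counts: pd.DataFrame,
    params: BsaParams = None,
    rng_seed=None,
    fixation_eps: float = 0.02,
    null_model: str = "binomial",
) -> LorResult:
    """Full scan from a PoolCounts table to called QTL intervals."""
    params = params or BsaParams()
    filtered = filter_by_coverage(counts, params.min_coverage)
    if len(filtered) == 0:
        raise ValueError("no data: every site failed the coverage filter")
    freqs = pool_frequencies(filtered)
    track = sliding_window_smooth(freqs, params.window_bp, params.step_bp)
    track["lor"] = log_odds_ratio(track["freq1"], track["freq2"], params)
    t_lo, t_hi = simulate_threshold(params, rng_seed, null_model)
    intervals, fixed = call_qtl_intervals(track, (t_lo, t_hi), fixation_eps)
    return LorResult(track, t_lo, t_hi, intervals, fixed)
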