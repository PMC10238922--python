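import math

import numpy as np
import pandas as pd
import pytest

from bsamap import (
    BsaParams,
    ORIGIN_CB,
    ORIGIN_JU,
    call_qtl_intervals,
    exact_threshold,
    filter_by_coverage,
    ju1242_frequency,
    log_odds_ratio,
    simulate_threshold,
    sliding_window_smooth,
)
from oracles import brute_force_windows, exact_lor_quantile, lor_spacing_at


def _counts(rows):
    return pd.DataFrame(rows, columns=["chrom", "pos", "origin", "var1", "tot1",
                                       "var2", "tot2"])


# ---------------------------------------------------------------------------
# frequency rule and coverage filter
# ---------------------------------------------------------------------------

@pytest.mark.parametrize(
    "var,tot,origin,expected",
    [
        (12, 24, ORIGIN_JU, 0.5),
        (18, 24, ORIGIN_CB, 0.25),  # 1 - 18/24
        (0, 15, ORIGIN_JU, 0.0),
        (0, 15, ORIGIN_CB, 1.0),
    ],
)
def test_ju1242_frequency_rule(var, tot, origin, expected):
    assert ju1242_frequency(var, tot, origin) == pytest.approx(expected)


def test_zero_coverage_site_is_an_error():
    with pytest.raises(ValueError, match="read_tot"):
        ju1242_frequency(0, 0, ORIGIN_JU)


def test_coverage_filter_is_strictly_greater_than():
    counts = _counts([
        ("I", 100, ORIGIN_JU, 5, 10, 20, 30),   # tot1 == 10 -> removed
        ("I", 200, ORIGIN_JU, 6, 11, 7, 11),    # both 11 -> retained
        ("I", 300, ORIGIN_CB, 2, 30, 3, 9),     # tot2 < 10 -> removed
    ])
    kept = filter_by_coverage(counts, 10)
    assert list(kept["pos"]) == [200]


def test_all_sites_filtered_gives_no_data_error():
    counts = _counts([("I", 100, ORIGIN_JU, 1, 5, 1, 5)])
    kept = filter_by_coverage(counts, 10)
    assert len(kept) == 0
    with pytest.raises(ValueError, match="no data"):
        sliding_window_smooth(kept.assign(freq1=[], freq2=[]))


# ---------------------------------------------------------------------------
# sliding windows
# ---------------------------------------------------------------------------

def _site_freqs(pos, f1):
    return pd.DataFrame({"chrom": "I", "pos": pos, "freq1": f1, "freq2": f1})


def test_single_snp_windows_carry_its_value():
    track = sliding_window_smooth(_site_freqs([100], [0.7]), 200, 1)
    assert len(track) == 100  # anchors 1..100 each cover pos 100
    assert (track["freq1"] == 0.7).all()
    assert (track["n_snps_in_window"] == 1).all()


def test_two_snps_in_one_window_average():
    track = sliding_window_smooth(_site_freqs([100, 150], [0.4, 0.6]), 200, 1)
    both = track[track["n_snps_in_window"] == 2]
    assert len(both) > 0
    assert np.allclose(both["freq1"], 0.5)


@pytest.mark.parametrize("step", [1, 7, 250])
def test_window_means_match_brute_force(step):
    rng = np.random.default_rng(5)
    pos = np.sort(rng.choice(np.arange(1, 50_001), size=800, replace=False))
    f = rng.random(800)
    track = sliding_window_smooth(_site_freqs(pos, f), 200, step)
    expected = brute_force_windows(list(pos), list(f), 200, step)
    assert len(track) == len(expected)
    for (mid, mean, n), row in zip(expected, track.itertuples(index=False)):
        assert row.pos == mid
        assert row.freq1 == pytest.approx(mean)
        assert row.n_snps_in_window == n


# ---------------------------------------------------------------------------
# log-odds ratio
# ---------------------------------------------------------------------------

def test_equal_frequencies_give_zero_lor():
    for f in (0.0, 0.31, 1.0):
        assert log_odds_ratio(f, f) == pytest.approx(0.0, abs=1e-9)


def test_fixation_lor_equals_direct_arithmetic():
    # ln[(40+1e-6)/1e-6] + ln[(40+1e-6)/1e-6] = 2 ln(4.0000001e7)
    expected = 2.0 * math.log(4.0000001e7)
    assert log_odds_ratio(1.0, 0.0) == pytest.approx(expected, rel=1e-9)


def test_lor_antisymmetry():
    rng = np.random.default_rng(1)
    for f1, f2 in rng.random((100, 2)):
        assert log_odds_ratio(f1, f2) == pytest.approx(-log_odds_ratio(f2, f1),
                                                       abs=1e-12)


def test_lor_monotone_in_each_pool_frequency():
    f = np.linspace(0.0, 1.0, 41)
    up = log_odds_ratio(f, np.full_like(f, 0.5))
    down = log_odds_ratio(np.full_like(f, 0.5), f)
    assert np.all(np.diff(up) > 0)
    assert np.all(np.diff(down) < 0)


# ---------------------------------------------------------------------------
# null threshold
# ---------------------------------------------------------------------------

def test_thresholds_are_symmetric_and_seeded():
    params = BsaParams(n_null_draws=50_000)
    lo, hi = simulate_threshold(params, rng_seed=0)
    assert lo == -hi and hi > 0
    assert simulate_threshold(params, rng_seed=0) == (lo, hi)


def test_wide_alpha_pulls_thresholds_to_the_null_median():
    params = BsaParams(alpha=0.99, n_null_draws=50_000)
    _, hi = simulate_threshold(params, rng_seed=0)
    assert 0 <= hi < 0.35  # near the median of the symmetric null


def test_monte_carlo_threshold_matches_exact_enumeration():
    params = BsaParams(n_null_draws=200_000)
    _, hi = simulate_threshold(params, rng_seed=123)
    exact = exact_lor_quantile(40, 1e-6, 1 - params.alpha / 2)
    spacing = lor_spacing_at(40, 1e-6, exact)
    assert abs(hi - exact) <= spacing
    # package's own enumeration agrees with the independent oracle exactly
    lo_pkg, hi_pkg = exact_threshold(params)
    assert hi_pkg == pytest.approx(exact, abs=1e-9)
    assert lo_pkg == pytest.approx(exact_lor_quantile(40, 1e-6, params.alpha / 2),
                                   abs=1e-9)


def test_too_few_null_draws_rejected():
    with pytest.raises(ValueError):
        simulate_threshold(BsaParams(n_null_draws=500), rng_seed=0)
    with pytest.raises(ValueError):
        simulate_threshold(BsaParams(), rng_seed=0, null_model="bogus")


# ---------------------------------------------------------------------------
# interval calling
# ---------------------------------------------------------------------------

def _track(lor, freq1=None, freq2=None, pos=None):
    n = len(lor)
    return pd.DataFrame({
        "chrom": "IV",
        "pos": pos if pos is not None else np.arange(100, 100 + n),
        "freq1": freq1 if freq1 is not None else np.full(n, 0.5),
        "freq2": freq2 if freq2 is not None else np.full(n, 0.5),
        "lor": lor,
    })


def test_no_exceedance_calls_nothing():
    intervals, fixed = call_qtl_intervals(_track([0.1, -0.2, 0.3]), (-1.5, 1.5))
    assert intervals.empty and fixed.empty


def test_single_run_above_threshold_is_one_interval():
    lor = [0.0, 2.0, 2.5, 2.2, 0.0]
    intervals, _ = call_qtl_intervals(_track(lor), (-1.5, 1.5))
    assert len(intervals) == 1
    row = intervals.iloc[0]
    assert (row.chrom, row.start, row.end, row.direction) == ("IV", 101, 103, "pool1")
    assert row.n_positions == 3


def test_fixation_subintervals_follow_the_favoured_pool():
    lor = [-2.0, -2.5, -2.2]
    freq2 = [0.97, 0.995, 0.99]  # pool2 favoured; middle+last within eps of 1
    intervals, fixed = call_qtl_intervals(
        _track(lor, freq2=freq2), (-1.5, 1.5), fixation_eps=0.02
    )
    assert intervals.iloc[0].direction == "pool2"
    assert bool(intervals.iloc[0].fixed)
    assert len(fixed) == 1
    assert (fixed.iloc[0].start, fixed.iloc[0].end) == (101, 102)


def test_pool_swap_negates_lor_and_flips_directions():
    rng = np.random.default_rng(2)
    lor = rng.normal(0, 1.5, 50)
    f1, f2 = rng.random(50), rng.random(50)
    t = _track(lor, freq1=f1, freq2=f2)
    swapped = _track(-lor, freq1=f2, freq2=f1)
    a, fa = call_qtl_intervals(t, (-1.2, 1.2))
    b, fb = call_qtl_intervals(swapped, (-1.2, 1.2))
    flip = {"pool1": "pool2", "pool2": "pool1"}
    b_flipped = b.assign(direction=b["direction"].map(flip))
    key = ["chrom", "start", "end", "direction"]
    pd.testing.assert_frame_equal(
        a[key].sort_values(key).reset_index(drop=True),
        b_flipped[key].sort_values(key).reset_index(drop=True),
    )
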