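import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as hst

from hicsuite.insulation import (
    _minima_leftmost,
    _prominence,
    find_boundaries,
    insulation_profile,
    threshold_boundaries,
)

from conftest import make_store


def diamond_oracle(counts, weights, w, min_valid_frac=0.66):
    """Dense sliding-window insulation for one region, written from the
    window definition: pairs (a, b) with i-w <= a <= i < b <= i+w."""
    n = len(weights)
    sym = (np.triu(counts) + np.triu(counts, 1).T).astype(float)
    bal = sym * np.outer(weights, weights)
    valid = np.isfinite(weights)
    raw = np.full(n, np.nan)
    for i in range(w, n - w):
        tot, nv = 0.0, 0
        for a in range(i - w, i + 1):
            for b in range(i + 1, i + w + 1):
                if valid[a] and valid[b]:
                    tot += bal[a, b]
                    nv += 1
        if nv > 0 and nv / w**2 >= min_valid_frac:
            raw[i] = tot / nv
    mu = np.nanmean(raw)
    with np.errstate(invalid="ignore", divide="ignore"):
        return np.log2(raw / mu)


def test_uniform_map_scores_zero(uniform_store):
    table = insulation_profile(uniform_store, window_bp=(50_000,))
    w = 5
    interior = table["score"].to_numpy()[w:-w]
    np.testing.assert_allclose(interior, 0.0, atol=1e-12)
    assert np.isnan(table["score"].to_numpy()[:w]).all()


def test_two_block_map_has_unique_minimum_at_junction(tmp_path):
    n = 40
    counts = np.zeros((n, n), dtype=int)
    counts[:20, :20] = 10
    counts[20:, 20:] = 10
    store = make_store(tmp_path / "b.cool", n_bins=n, counts=np.triu(counts),
                       weights=np.ones(n))
    table = insulation_profile(store, window_bp=(50_000,), min_valid_frac=0)
    table = find_boundaries(table)
    mins = table[table["is_min"]]
    assert len(mins) == 1
    # junction between bins 19 and 20: deepest diamond is centered at 19
    assert mins.index[0] in (19, 20)


def test_sparse_profile_matches_dense_oracle(tmp_path):
    rng = np.random.default_rng(41)
    n = 80
    counts = np.triu(rng.integers(0, 6, size=(n, n)))
    weights = rng.random(n) + 0.2
    weights[[10, 11, 44]] = np.nan
    store = make_store(tmp_path / "o.cool", n_bins=n, counts=counts, weights=weights)
    for w_bins in (3, 7):
        table = insulation_profile(store, window_bp=(w_bins * 10_000,))
        oracle = diamond_oracle(counts, weights, w_bins)
        np.testing.assert_allclose(table["score"].to_numpy(), oracle,
                                   atol=1e-10, equal_nan=True)


def test_chunk_size_independence(domain_map):
    store, _ = domain_map
    a = insulation_profile(store, window_bp=(100_000,))
    b = insulation_profile(store, window_bp=(100_000,), chunksize=499)
    pd.testing.assert_frame_equal(a, b)


def test_multiple_windows_long_format(uniform_store):
    table = insulation_profile(uniform_store, window_bp=(30_000, 50_000))
    assert sorted(table["window"].unique()) == [30_000, 50_000]
    assert len(table) == 2 * uniform_store.n_bins


def test_window_too_small_rejected(uniform_store):
    with pytest.raises(ValueError, match="2 bins"):
        insulation_profile(uniform_store, window_bp=(10_000,))
    with pytest.raises(ValueError, match="multiple"):
        insulation_profile(uniform_store, window_bp=(25_000,))


class TestMinimaAndProminence:
    def _table(self, scores):
        n = len(scores)
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n) * 10, "end": np.arange(n) * 10 + 10,
            "region": "chr1", "window": 100, "score": scores,
            "n_valid_pixels": 10,
        })

    def test_v_profile(self):
        t = find_boundaries(self._table([3.0, 1.0, 3.0]))
        assert t["is_min"].tolist() == [False, True, False]
        assert t["prominence"].iloc[1] == pytest.approx(2.0)

    def test_monotone_profile_has_no_minima(self):
        t = find_boundaries(self._table([1.0, 2.0, 3.0, 4.0]))
        assert not t["is_min"].any()

    def test_shallow_minimum_limited_by_saddle(self):
        # deep minimum at 1 (score 0), shallow at 5 (score 2); the saddle
        # between them peaks at 3
        scores = [5.0, 0.0, 2.5, 3.0, 2.6, 2.0, 4.0, 6.0]
        t = find_boundaries(self._table(scores))
        mins = t[t["is_min"]]
        assert list(mins.index) == [1, 5]
        # deep minimum walks to both ends
        assert t["prominence"].iloc[1] == pytest.approx(min(5.0, 6.0) - 0.0)
        # shallow minimum: leftward walk stops at the deeper minimum
        assert t["prominence"].iloc[5] == pytest.approx(min(3.0, 6.0) - 2.0)

    def test_plateau_reports_leftmost_bin(self):
        t = find_boundaries(self._table([3.0, 1.0, 1.0, 1.0, 3.0]))
        mins = t[t["is_min"]]
        assert list(mins.index) == [1]
        assert mins["plateau_size"].iloc[0] == 3

    def test_nan_splits_runs(self):
        scores = [3.0, 1.0, 3.0, np.nan, 4.0, 2.0, 4.0]
        t = find_boundaries(self._table(scores))
        assert list(t[t["is_min"]].index) == [1, 5]

    @given(hst.lists(hst.integers(min_value=0, max_value=8), min_size=3, max_size=30))
    @settings(max_examples=60, deadline=None, derandomize=True)
    def test_prominence_matches_exhaustive_walk(self, vals):
        y = np.array(vals, dtype=float)
        mins, _ = _minima_leftmost(y)
        for m in mins:
            # exhaustive oracle: scan every index outward until a lower value
            best = []
            for step in (-1, 1):
                path = []
                i = m + step
                while 0 <= i < len(y) and y[i] >= y[m]:
                    path.append(y[i])
                    i += step
                best.append(max(path) if path else -np.inf)
            assert _prominence(y, m) == pytest.approx(min(best) - y[m])

    @given(hst.lists(hst.floats(min_value=-5, max_value=5, allow_nan=False)
                     .map(lambda x: round(x, 3)), min_size=3, max_size=25),
           hst.floats(min_value=-10, max_value=10, allow_nan=False)
           .map(lambda x: round(x, 3)))
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_prominence_invariant_to_constant_shift(self, vals, c):
        y = np.array(vals)
        t1 = find_boundaries(self._table(y))
        t2 = find_boundaries(self._table(y + c))
        np.testing.assert_array_equal(t1["is_min"], t2["is_min"])
        np.testing.assert_allclose(t1["prominence"].dropna(),
                                   t2["prominence"].dropna(), atol=1e-9)


class TestThresholding:
    def _minima_table(self, proms):
        n = len(proms)
        return pd.DataFrame({
            "chrom": "chr1", "start": np.arange(n), "end": np.arange(n) + 1,
            "region": "chr1", "window": 100,
            "score": -np.asarray(proms), "n_valid_pixels": 10,
            "is_min": True, "prominence": proms, "plateau_size": 1,
        })

    def test_otsu_separates_bimodal_exactly(self):
        proms = np.array([0.01] * 100 + [1.0] * 20)
        t = threshold_boundaries(self._minima_table(proms), "otsu")
        # exhaustive between-class-variance oracle over candidate thresholds
        best_thr, best_var = None, -1
        for thr in np.unique(proms):
            lo, hi = proms[proms < thr], proms[proms >= thr]
            if len(lo) == 0 or len(hi) == 0:
                continue
            var = len(lo) * len(hi) * (lo.mean() - hi.mean()) ** 2
            if var > best_var:
                best_var, best_thr = var, thr
        expect = proms >= best_thr
        np.testing.assert_array_equal(t["is_strong_otsu"], expect)

    def test_single_minimum_flagged_with_warning(self):
        with pytest.warns(UserWarning, match="too few"):
            t = threshold_boundaries(self._minima_table(np.array([0.4])), "otsu")
        assert t["is_strong_otsu"].all()

    def test_fixed_value(self):
        proms = np.array([0.1, 0.6, 0.4, 0.9])
        t = threshold_boundaries(self._minima_table(proms), "fixed", value=0.5)
        np.testing.assert_array_equal(t["is_strong_fixed"], proms >= 0.5)

    def test_li_runs_on_spread_prominences(self):
        rng = np.random.default_rng(42)
        proms = np.concatenate([rng.uniform(0, 0.1, 50), rng.uniform(0.8, 1.2, 10)])
        t = threshold_boundaries(self._minima_table(proms), "li")
        assert t["is_strong_li"].sum() == 10


def test_planted_boundaries_recovered(domain_map):
    """>= 90% of 4x-depleted boundaries found within +/-1 bin, strong by Otsu."""
    store, truth = domain_map
    table = insulation_profile(store, window_bp=(100_000,))
    table = find_boundaries(table)
    table = threshold_boundaries(table, "otsu")
    strong = table[table["is_strong_otsu"]]
    binsize = store.binsize
    found = set(zip(strong["chrom"], strong["start"] // binsize))
    hits = 0
    for t in truth["boundaries"].itertuples():
        # the deepest diamond for a boundary between bins b-1 and b is
        # centered at b-1; accept a +/-1-bin error around that position
        if any((t.chrom, t.bin - 1 + off) in found for off in (-1, 0, 1)):
            hits += 1
    assert hits / len(truth["boundaries"]) >= 0.9
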