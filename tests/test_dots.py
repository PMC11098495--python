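import numpy as np
import pandas as pd
import pytest
import scipy.stats as st

from hicsuite.dots import (
    call_dots,
    cluster_filter,
    lambda_bh,
    make_kernels,
    score_pixels,
)
from hicsuite.expected import expected_cis
from hicsuite.synthetic import MapRecipe, generate_map

from conftest import make_store


class TestKernels:
    def test_masks_pinned_at_w3_p1(self):
        """The four stock footprints, written out pixel by pixel (w=3, p=1)."""
        k = make_kernels(w=3, p=1)
        donut = np.array([
            [1, 1, 1, 0, 1, 1, 1],
            [1, 1, 1, 0, 1, 1, 1],
            [1, 1, 0, 0, 0, 1, 1],
            [0, 0, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 1, 1],
            [1, 1, 1, 0, 1, 1, 1],
            [1, 1, 1, 0, 1, 1, 1],
        ], dtype=bool)
        vertical = np.array([
            [0, 0, 1, 1, 1, 0, 0],
            [0, 0, 1, 1, 1, 0, 0],
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 1, 1, 1, 0, 0],
            [0, 0, 1, 1, 1, 0, 0],
        ], dtype=bool)
        lowerleft = np.array([
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0],
            [0, 0, 0, 0, 0, 0, 0],
            [1, 1, 0, 0, 0, 0, 0],
            [1, 1, 1, 0, 0, 0, 0],
            [1, 1, 1, 0, 0, 0, 0],
        ], dtype=bool)
        np.testing.assert_array_equal(k["donut"], donut)
        np.testing.assert_array_equal(k["vertical"], vertical)
        np.testing.assert_array_equal(k["horizontal"], vertical.T)
        np.testing.assert_array_equal(k["lowerleft"], lowerleft)

    def test_aliases_and_invariants(self):
        k = make_kernels(names=("top", "bottom", "donut", "lowerleft"))
        np.testing.assert_array_equal(k["top"], make_kernels()["vertical"])
        np.testing.assert_array_equal(k["bottom"], make_kernels()["horizontal"])
        for mask in k.values():
            w = mask.shape[0] // 2
            assert not mask[w, w]  # center excluded
            assert mask.sum() >= 1

    def test_bad_geometry_rejected(self):
        with pytest.raises(ValueError):
            make_kernels(w=2, p=2)
        with pytest.raises(ValueError):
            make_kernels(names=("ring",))


def convolution_oracle(counts, weights, exp_curve, kernels, min_dist, maxd):
    """Direct per-pixel, per-offset loop over a single dense region."""
    n = len(weights)
    sym = (np.triu(counts) + np.triu(counts, 1).T).astype(float)
    bal = sym * np.outer(weights, weights)
    valid = np.isfinite(weights)
    rows = {}
    for i in range(n):
        for j in range(i + min_dist, min(i + maxd, n - 1) + 1):
            if not (valid[i] and valid[j]):
                continue
            lams = {}
            ok = True
            for name, K in kernels.items():
                w = K.shape[0] // 2
                num = den = cov = 0.0
                for di in range(-w, w + 1):
                    for dj in range(-w, w + 1):
                        if not K[di + w, dj + w]:
                            continue
                        a, b = i + di, j + dj
                        if not (0 <= a < n and 0 <= b < n):
                            continue
                        if not (valid[a] and valid[b]):
                            continue
                        e = exp_curve[abs(b - a)]
                        if not (np.isfinite(e) and e > 0):
                            continue
                        cov += 1
                        num += bal[a, b]
                        den += e
                if den <= 0 or cov < 0.5 * K.sum():
                    ok = False
                    break
                f = num / den
                lams[name] = f * exp_curve[j - i] / (weights[i] * weights[j])
            if ok:
                rows[(i, j)] = lams
    return rows


def test_lambdas_match_dense_convolution_oracle(tmp_path):
    rng = np.random.default_rng(51)
    n = 40
    counts = np.triu(rng.integers(0, 12, size=(n, n)))
    weights = rng.random(n) + 0.5
    weights[[8, 25]] = np.nan
    store = make_store(tmp_path / "c.cool", n_bins=n, counts=counts, weights=weights)
    exp = expected_cis(store, smooth=False)
    kernels = make_kernels(w=3, p=1)
    scored = score_pixels(store, exp, kernels=kernels, max_dist_bp=200_000)
    curve = np.full(n, np.nan)
    sub = exp[exp["dist"].notna()]
    curve[sub["dist"].to_numpy(dtype=int)] = sub["balanced_avg"].to_numpy()
    oracle = convolution_oracle(counts, weights, curve, kernels, 2, 20)
    got = {(r.bin1_id, r.bin2_id): r for r in scored.itertuples()}
    assert set(got) == set(oracle)
    for key, lams in oracle.items():
        for name in kernels:
            assert getattr(got[key], f"la_{name}") == pytest.approx(lams[name], abs=1e-10)


def test_uniform_poisson_map_has_unit_local_factors(tmp_path):
    rng = np.random.default_rng(52)
    n = 60
    counts = np.triu(rng.poisson(20.0, size=(n, n)))
    store = make_store(tmp_path / "u.cool", n_bins=n, counts=counts, weights=np.ones(n))
    exp = expected_cis(store, smooth=False)
    scored = score_pixels(store, exp, max_dist_bp=300_000)
    curve = np.zeros(n)
    sub = exp[exp["dist"].notna()]
    curve[sub["dist"].to_numpy(dtype=int)] = sub["balanced_avg"].to_numpy()
    d = scored["bin2_id"] - scored["bin1_id"]
    ratio = scored["la_donut"] / curve[d]
    assert np.abs(np.median(ratio) - 1.0) < 0.1


def test_single_injected_dot_enrichment(tmp_path):
    """10x enrichment over one pixel on a flat background scores ~10
    against the donut background."""
    recipe = MapRecipe(chromlens=(1_000_000,), alpha=0.0, depth=3e6,
                       bad_bin_frac=0.0, dots=[("chr1", 30, 60, 10.0)],
                       dot_halfwidth=0, seed=53)
    store, truth = generate_map(recipe, str(tmp_path / "one.cool"))
    exp = expected_cis(store)
    scored = score_pixels(store, exp)
    row = scored[(scored["bin1_id"] == 30) & (scored["bin2_id"] == 60)].iloc[0]
    assert row["enr_donut"] == pytest.approx(10.0, rel=0.25)


class TestLambdaBH:
    def test_single_chunk_equals_textbook_bh(self):
        rng = np.random.default_rng(54)
        n = 500
        lam = np.full(n, 5.0)  # one lambda chunk
        obs = rng.poisson(lam)
        obs[:5] += 15
        scored = pd.DataFrame({
            "region": "chr1", "bin1_id": np.arange(n), "bin2_id": np.arange(n) + 10,
            "count": obs, "la_donut": lam,
        })
        sig, full = lambda_bh(scored, fdr_q=0.1, chunk_base=2.0 ** (1 / 3))
        edge = (2.0 ** (1 / 3)) ** (np.floor(np.log(5.0) / np.log(2.0 ** (1 / 3))) + 1)
        p = st.poisson.sf(obs - 1, edge)
        order = np.argsort(p, kind="stable")
        thresh = 0
        for k in range(n, 0, -1):
            if np.sort(p)[k - 1] <= k / n * 0.1:
                thresh = k
                break
        expect_sig = np.zeros(n, dtype=bool)
        expect_sig[order[:thresh]] = True
        np.testing.assert_array_equal(full["significant"], expect_sig)

    def test_obs_below_lambda_never_significant(self):
        scored = pd.DataFrame({
            "region": "chr1", "bin1_id": [0], "bin2_id": [5],
            "count": [3], "la_donut": [10.0],
        })
        sig, _ = lambda_bh(scored, fdr_q=0.5)
        assert len(sig) == 0

    def test_requires_all_kernels_by_default(self):
        scored = pd.DataFrame({
            "region": "chr1", "bin1_id": [0], "bin2_id": [5], "count": [100],
            "la_donut": [5.0], "la_vertical": [200.0],
        })
        sig_all, _ = lambda_bh(scored, fdr_q=0.1)
        assert len(sig_all) == 0
        sig_any, _ = lambda_bh(scored, fdr_q=0.1, require_all=False)
        assert len(sig_any) == 1


class TestClustering:
    def _sig(self, coords, qs=None):
        coords = np.asarray(coords)
        n = len(coords)
        return pd.DataFrame({
            "region": "chr1",
            "bin1_id": coords[:, 0], "bin2_id": coords[:, 1],
            "chrom1": "chr1", "start1": coords[:, 0] * 10_000,
            "end1": coords[:, 0] * 10_000 + 10_000,
            "chrom2": "chr1", "start2": coords[:, 1] * 10_000,
            "end2": coords[:, 1] * 10_000 + 10_000,
            "count": 10, "q_donut": qs if qs is not None else np.full(n, 0.01),
            "enr_donut": 5.0, "enr_lowerleft": 5.0,
        })

    def test_adjacent_pixels_form_one_cluster(self):
        calls = cluster_filter(self._sig([(10, 20), (10, 21)], qs=[0.01, 0.05]),
                               binsize=10_000)
        assert len(calls) == 1
        assert calls["cluster_size"].iloc[0] == 2
        assert calls["bin2_id"].iloc[0] == 20  # lowest q wins the centroid

    def test_distant_pixels_stay_separate(self):
        calls = cluster_filter(self._sig([(10, 20), (10, 30)]), binsize=10_000)
        assert len(calls) == 2

    def test_matches_connected_components_oracle(self):
        rng = np.random.default_rng(55)
        coords = rng.integers(0, 40, size=(30, 2))
        coords = np.sort(coords, axis=1)
        coords[:, 1] += 3
        sig = self._sig(coords)
        calls = cluster_filter(sig, binsize=10_000, radius_bp=39_000,
                               enrichment_min=None)
        # brute-force union-find on pairwise bp distances
        parent = list(range(len(coords)))

        def find(x):
            while parent[x] != x:
                x = parent[x]
            return x

        xy = coords * 10_000 + 5_000
        for i in range(len(coords)):
            for j in range(i + 1, len(coords)):
                if np.hypot(*(xy[i] - xy[j])) <= 39_000:
                    parent[find(i)] = find(j)
        n_clusters = len({find(i) for i in range(len(coords))})
        assert len(calls) == n_clusters
        assert calls["cluster_size"].sum() == len(coords)

    def test_enrichment_filter_drops_weak_centroids(self):
        sig = self._sig([(10, 20)])
        sig["enr_donut"] = 1.2
        calls = cluster_filter(sig, binsize=10_000)
        assert len(calls) == 0


def test_tile_size_independence(dots_map):
    store, _ = dots_map
    exp = expected_cis(store)
    a = call_dots(store, exp, tile_size_bp=5_000_000)
    b = call_dots(store, exp, tile_size_bp=700_000)
    pd.testing.assert_frame_equal(a.reset_index(drop=True), b.reset_index(drop=True))


def test_planted_dot_recovery(dots_map):
    store, truth = dots_map
    exp = expected_cis(store)
    calls = call_dots(store, exp, fdr_q=0.1)
    td = truth["dots"]
    hits = sum(
        len(calls[(calls["chrom1"] == t.chrom)
                  & (abs(calls["bin1_id"] - t.bin1_id) <= 1)
                  & (abs(calls["bin2_id"] - t.bin2_id) <= 1)]) > 0
        for t in td.itertuples()
    )
    true_pos = sum(
        len(td[(td["chrom"] == c.chrom1)
               & (abs(td["bin1_id"] - c.bin1_id) <= 1)
               & (abs(td["bin2_id"] - c.bin2_id) <= 1)]) > 0
        for c in calls.itertuples()
    )
    assert hits / len(td) >= 0.8
    assert true_pos / len(calls) >= 0.8
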