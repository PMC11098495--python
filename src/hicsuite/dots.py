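"""Focal contact peak ("dot"/"loop") detection.

A HiCCUPS-style pipeline: (i) the cis band of each region is queried tile
by tile, (ii) convolutional kernels score every pixel for enrichment over
its local neighborhood, (iii) pixels are tested against a Poisson null
whose rate is the locally adjusted expected count, with a lambda-chunked
Benjamini-Hochberg FDR, and (iv) significant pixels are clustered and the
cluster centroids filtered by enrichment.

Kernels are boolean masks of shape (2w+1, 2w+1) centered on the scored
pixel (axis 0 = first/upstream bin, axis 1 = second/downstream bin). The
four stock kernels are ``donut`` (ring between inner half-width p and outer
half-width w, minus the center row/column cross), ``vertical``/``top``
(column band |dj| <= p, |di| > p), ``horizontal``/``bottom`` (row band),
and ``lowerleft`` (the quadrant between the pixel and the diagonal,
di in [1, w], dj in [-w, -1], minus the inner square). User-supplied masks
of any odd size are accepted.

For each kernel k, the local factor f_k = sum(balanced observed under k) /
sum(balanced expected under k) rescales the distance expected, giving an
expected raw count lambda_k = f_k * E(d) / (w_i * w_j) for the Poisson
test. A pixel must be significant under every kernel (relaxable).
"""

from __future__ import annotations

import numpy as np
import pandas as pd
import scipy.ndimage as ndi
import scipy.sparse as sps
import scipy.stats as st
from scipy.spatial import cKDTree

from .expected import expected_curves
from .io import assign_bins, make_view

__all__ = [
    "make_kernels",
    "score_pixels",
    "lambda_bh",
    "cluster_filter",
    "call_dots",
]

KERNEL_ALIASES = {"top": "vertical", "bottom": "horizontal"}


def make_kernels(w=5, p=2, names=("donut", "vertical", "horizontal", "lowerleft")):
    """Stock convolution kernels as {name: boolean mask of shape (2w+1, 2w+1)}."""
    if not (0 <= p < w):
        raise ValueError("need 0 <= p < w")
    di, dj = np.meshgrid(np.arange(-w, w + 1), np.arange(-w, w + 1), indexing="ij")
    inner = (np.abs(di) <= p) & (np.abs(dj) <= p)
    masks = {
        "donut": ~inner & (di != 0) & (dj != 0),
        "vertical": (np.abs(dj) <= p) & (np.abs(di) > p),
        "horizontal": (np.abs(di) <= p) & (np.abs(dj) > p),
        "lowerleft": (di >= 1) & (dj <= -1) & ~inner,
    }
    out = {}
    for name in names:
        key = KERNEL_ALIASES.get(name, name)
        if key not in masks:
            raise ValueError(f"unknown kernel {name!r}")
        out[name] = masks[key]
    return out


def _odd_halfwidth(kernel):
    s = kernel.shape[0]
    if kernel.shape[0] != kernel.shape[1] or s % 2 == 0:
        raise ValueError("kernels must be square with odd size")
    return s // 2


def score_pixels(
    store,
    expected,
    view=None,
    kernels=None,
    max_dist_bp=2_000_000,
    min_dist=2,
    tile_size_bp=5_000_000,
    min_kernel_frac=0.5,
):
    """Score every in-range cis pixel position for local enrichment.

    Returns one row per scored position (including zero-count positions —
    they belong in the FDR denominator) with the raw count, per-kernel
    lambda (expected raw count) and per-kernel balanced enrichment.
    Positions whose kernels cover fewer than ``min_kernel_frac`` of their
    pixels with valid data are dropped. Tiles overlap by the kernel
    half-width so every position is scored exactly once with full context,
    making the output independent of ``tile_size_bp``.
    """
    if kernels is None:
        kernels = make_kernels()
    halfwidths = {k: _odd_halfwidth(m) for k, m in kernels.items()}
    wmax = max(halfwidths.values())
    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    wts = store.weights
    curves = expected_curves(expected)
    binsize = store.binsize
    maxd = max_dist_bp // binsize
    tile = max(int(tile_size_bp // binsize), 1)
    if tile <= 2 * wmax:
        raise ValueError("tile size must exceed the kernel diameter")

    frames = []
    for ri, row in view.iterrows():
        sel = np.flatnonzero(rid == ri)
        if len(sel) == 0:
            continue
        g0 = sel[0]
        n = len(sel)
        curve = curves[row["name"]]
        reg_w = wts[sel]
        valid = np.isfinite(reg_w)
        for t0 in range(0, n, tile):
            t1 = min(t0 + tile, n)
            # block with halo
            i0 = max(t0 - wmax, 0)
            i1 = min(t1 + wmax, n)
            j0 = i0
            j1 = min(t1 + maxd + wmax, n)
            O = store.dense(g0 + i0, g0 + i1, g0 + j0, g0 + j1, balanced=True)
            Craw = store.dense(g0 + i0, g0 + i1, g0 + j0, g0 + j1, balanced=False)
            V = np.outer(valid[i0:i1], valid[j0:j1])
            dmat = np.abs(
                np.arange(j0, j1)[None, :] - np.arange(i0, i1)[:, None]
            )
            E = curve[np.minimum(dmat, len(curve) - 1)]
            E = np.where(np.isfinite(E), E, 0.0)
            V = V & (E > 0)  # positions without an expected model are unusable
            Ofill = np.where(V & np.isfinite(O), O, 0.0)
            Ev = np.where(V, E, 0.0)

            # candidate positions: rows in [t0, t1), in-range distance, valid
            ii, jj = np.meshgrid(
                np.arange(i0, i1), np.arange(j0, j1), indexing="ij"
            )
            cand = (
                (ii >= t0)
                & (ii < t1)
                & (jj - ii >= min_dist)
                & (jj - ii <= maxd)
                & V
            )
            lam_cols, enr_cols, keep = {}, {}, cand.copy()
            for name, K in kernels.items():
                Kf = K.astype(float)
                num = ndi.correlate(Ofill, Kf, mode="constant")
                den = ndi.correlate(Ev, Kf, mode="constant")
                cov = ndi.correlate(V.astype(float), Kf, mode="constant")
                with np.errstate(invalid="ignore", divide="ignore"):
                    f = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
                lam = (
                    f
                    * E
                    / np.outer(reg_w[i0:i1], reg_w[j0:j1])
                )
                with np.errstate(invalid="ignore", divide="ignore"):
                    enr = np.where(f * E > 0, O / (f * E), np.nan)
                lam_cols[name] = lam
                enr_cols[name] = enr
                keep &= cov >= min_kernel_frac * K.sum()
                keep &= np.isfinite(lam) & (lam > 0)
            if not keep.any():
                continue
            ki, kj = np.nonzero(keep)
            rec = {
                "region": row["name"],
                "bin1_id": g0 + i0 + ki,
                "bin2_id": g0 + j0 + kj,
                "count": Craw[ki, kj].astype(np.int64),
            }
            for name in kernels:
                rec[f"la_{name}"] = lam_cols[name][ki, kj]
                rec[f"enr_{name}"] = enr_cols[name][ki, kj]
            frames.append(pd.DataFrame(rec))

    if not frames:
        cols = ["region", "bin1_id", "bin2_id", "count"]
        for name in kernels:
            cols += [f"la_{name}", f"enr_{name}"]
        return pd.DataFrame(columns=cols)
    scored = pd.concat(frames, ignore_index=True)
    bins = store.bins
    for side, col in ((1, "bin1_id"), (2, "bin2_id")):
        scored[f"chrom{side}"] = bins["chrom"].to_numpy()[scored[col]]
        scored[f"start{side}"] = bins["start"].to_numpy()[scored[col]]
        scored[f"end{side}"] = bins["end"].to_numpy()[scored[col]]
    return scored


def lambda_bh(scored, fdr_q=0.1, chunk_base=2 ** (1 / 3), require_all=True):
    """Lambda-chunked Benjamini-Hochberg selection of significant pixels.

    Per kernel, pixels are partitioned into geometric lambda chunks with
    edges ``chunk_base ** m``; within each chunk the Poisson upper-tail
    p-value is computed at the chunk's upper edge (conservative) and BH is
    applied across the chunk at level ``fdr_q``. A pixel is retained iff it
    is significant for every kernel (or any, with ``require_all=False``).
    Returns (significant subset, full table with q-value columns).
    """
    scored = scored.copy()
    kernel_names = [c[3:] for c in scored.columns if c.startswith("la_")]
    obs = scored["count"].to_numpy()
    sig_all = None
    for name in kernel_names:
        lam = scored[f"la_{name}"].to_numpy(dtype=float)
        m = np.floor(np.log(lam) / np.log(chunk_base)).astype(np.int64)
        edges = chunk_base ** (m + 1.0)
        pvals = st.poisson.sf(obs - 1, edges)
        qvals = np.ones(len(scored))
        for chunk_id in np.unique(m):
            idx = np.flatnonzero(m == chunk_id)
            p = pvals[idx]
            order = np.argsort(p, kind="stable")
            nn = len(idx)
            ranked = p[order] * nn / np.arange(1, nn + 1)
            q = np.minimum.accumulate(ranked[::-1])[::-1]
            q = np.clip(q, 0, 1)
            qvals[idx[order]] = q
        scored[f"q_{name}"] = qvals
        sig_k = qvals <= fdr_q
        sig_all = sig_k if sig_all is None else (
            (sig_all & sig_k) if require_all else (sig_all | sig_k)
        )
    scored["significant"] = sig_all if sig_all is not None else False
    return scored[scored["significant"]].copy(), scored


def cluster_filter(
    sig,
    binsize,
    radius_bp=39_000,
    enrichment_min={"donut": 1.75, "lowerleft": 1.75},
    cluster=True,
):
    """Cluster adjacent significant pixels and filter centroids by enrichment.

    Single-linkage clustering joins pixels whose bin-center distance is at
    most ``radius_bp``; the most significant pixel of each cluster (lowest
    worst-kernel q, ties broken by count then coordinates) is kept as the
    centroid. Centroids failing any ``enrichment_min`` threshold are
    dropped. Both steps can be skipped (``cluster=False`` /
    ``enrichment_min=None``).
    """
    sig = sig.copy().reset_index(drop=True)
    if len(sig) == 0:
        sig["cluster_id"] = pd.Series(dtype=np.int64)
        sig["cluster_size"] = pd.Series(dtype=np.int64)
        sig["is_centroid"] = pd.Series(dtype=bool)
        return sig
    qcols = [c for c in sig.columns if c.startswith("q_")]
    sig["q_max"] = sig[qcols].max(axis=1) if qcols else 0.0

    if cluster:
        out_frames = []
        next_id = 0
        for _, sub in sig.groupby("region", sort=False):
            sub = sub.copy()
            xy = np.column_stack(
                [
                    (sub["start1"] + sub["end1"]) / 2.0,
                    (sub["start2"] + sub["end2"]) / 2.0,
                ]
            )
            tree = cKDTree(xy)
            pairs = tree.query_pairs(r=radius_bp, output_type="ndarray")
            nloc = len(sub)
            adj = sps.coo_matrix(
                (np.ones(len(pairs)), (pairs[:, 0], pairs[:, 1]))
                if len(pairs)
                else ((), ((), ())),
                shape=(nloc, nloc),
            )
            ncomp, labels = sps.csgraph.connected_components(adj, directed=False)
            sub["cluster_id"] = labels + next_id
            next_id += ncomp
            out_frames.append(sub)
        sig = pd.concat(out_frames, ignore_index=True)
    else:
        sig["cluster_id"] = np.arange(len(sig))

    sizes = sig.groupby("cluster_id")["cluster_id"].transform("size")
    sig["cluster_size"] = sizes
    sig = sig.sort_values(
        ["cluster_id", "q_max", "count", "bin1_id", "bin2_id"],
        ascending=[True, True, False, True, True],
        kind="stable",
    )
    sig["is_centroid"] = ~sig["cluster_id"].duplicated()
    calls = sig[sig["is_centroid"]].copy()
    if enrichment_min:
        for name, thr in enrichment_min.items():
            col = f"enr_{name}"
            if col in calls.columns:
                calls = calls[calls[col] >= thr]
    return calls.sort_values(["bin1_id", "bin2_id"]).reset_index(drop=True)


def call_dots(
    store,
    expected,
    view=None,
    fdr_q=0.1,
    kernels=None,
    max_dist_bp=2_000_000,
    min_dist=2,
    tile_size_bp=5_000_000,
    radius_bp=39_000,
    enrichment_min={"donut": 1.75, "lowerleft": 1.75},
    cluster=True,
    require_all=True,
):
    """Full pipeline: score, lambda-chunked BH, cluster and filter."""
    scored = score_pixels(
        store,
        expected,
        view=view,
        kernels=kernels,
        max_dist_bp=max_dist_bp,
        min_dist=min_dist,
        tile_size_bp=tile_size_bp,
    )
    sig, _ = lambda_bh(scored, fdr_q=fdr_q, require_all=require_all)
    return cluster_filter(
        sig,
        store.binsize,
        radius_bp=radius_bp,
        enrichment_min=enrichment_min,
        cluster=cluster,
    )
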