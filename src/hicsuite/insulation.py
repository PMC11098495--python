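"""Diamond-window insulation profiles, boundary minima, and prominence.

The insulation score of a bin summarizes how frequently loci upstream of it
contact loci downstream, averaged over a sliding diamond-shaped window next
to the matrix diagonal. Local minima of the profile mark insulating
boundaries (domain/TAD edges). Each minimum's strength is its topographic
prominence — the drop from the lowest of the two maxima reached before a
deeper minimum (or the region end) in either direction — and strong
boundaries are selected with automated Li/Otsu thresholding of the
prominence distribution.

The profile is accumulated from the sparse pixel table in one pass: a pixel
(a, b) at separation d contributes to all window centers i with
max(a, b - w) <= i <= min(a + w, b - 1), implemented with a difference
array so any chunking of the pixels yields identical results.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from skimage.filters import threshold_li, threshold_otsu

from .io import assign_bins, make_view

__all__ = ["insulation_profile", "find_boundaries", "threshold_boundaries"]


def insulation_profile(
    store,
    view=None,
    window_bp=(100_000,),
    min_valid_frac=0.66,
    use_weights=True,
    chunksize=None,
):
    """Log2 insulation score per bin for one or more window sizes.

    The raw score at bin i is the mean balanced value over valid pixel
    positions (a, b) with i - w <= a <= i < b <= i + w (w in bins; the
    a = b self-pixel row is excluded, distance-1 pixels included). The final
    score is log2(raw / region mean of raw). Scores are missing within w of
    region edges and where the valid-position fraction of the window drops
    below ``min_valid_frac`` (relative to w^2).
    """
    if np.isscalar(window_bp):
        window_bp = (window_bp,)
    windows = []
    for wb in window_bp:
        if wb % store.binsize:
            raise ValueError(f"window {wb} not a multiple of binsize {store.binsize}")
        w = wb // store.binsize
        if w < 2:
            raise ValueError("window must span at least 2 bins")
        windows.append(int(w))

    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    wts = store.weights if use_weights else np.ones(store.n_bins)
    valid = np.isfinite(wts)
    n_bins = store.n_bins

    # difference-array accumulators, one per window size
    diffs = {w: np.zeros(n_bins + 1) for w in windows}
    for chunk in store.iter_pixels(chunksize):
        b1 = chunk["bin1_id"].to_numpy()
        b2 = chunk["bin2_id"].to_numpy()
        c = chunk["count"].to_numpy(dtype=float)
        r1, r2 = rid[b1], rid[b2]
        ok = (r1 >= 0) & (r1 == r2) & (b2 > b1) & valid[b1] & valid[b2]
        val = c[ok] * wts[b1[ok]] * wts[b2[ok]]
        a, b = b1[ok], b2[ok]
        for w in windows:
            sel = (b - a) <= 2 * w
            lo = np.maximum(a[sel], b[sel] - w)
            hi = np.minimum(a[sel] + w, b[sel] - 1)
            keep = hi >= lo
            np.add.at(diffs[w], lo[keep], val[sel][keep])
            np.add.at(diffs[w], hi[keep] + 1, -val[sel][keep])

    frames = []
    for w, wb in zip(windows, window_bp):
        bal_sum = np.cumsum(diffs[w])[:-1]
        score = np.full(n_bins, np.nan)
        n_valid = np.zeros(n_bins, dtype=np.int64)
        for i, row in view.iterrows():
            sel = np.flatnonzero(rid == i)
            m = len(sel)
            v = valid[sel]
            cv = np.concatenate([[0], np.cumsum(v)])
            raw = np.full(m, np.nan)
            for k in range(w, m - w):
                na = cv[k + 1] - cv[k - w]       # valid a in [k-w, k]
                nb = cv[k + w + 1] - cv[k + 1]   # valid b in [k+1, k+w]
                nv = na * nb
                n_valid[sel[k]] = nv
                if nv > 0 and nv / w**2 >= min_valid_frac:
                    raw[k] = bal_sum[sel[k]] / nv
            mu = np.nanmean(raw) if np.isfinite(raw).any() else np.nan
            if np.isfinite(mu) and mu > 0:
                with np.errstate(invalid="ignore", divide="ignore"):
                    sc = np.log2(raw / mu)
            else:
                sc = np.full(m, np.nan)
            score[sel] = sc
        df = store.bins[["chrom", "start", "end"]].copy()
        df["region"] = np.where(rid >= 0, view["name"].to_numpy()[rid.clip(0)], "")
        df["window"] = wb
        df["score"] = score
        df["n_valid_pixels"] = n_valid
        frames.append(df[rid >= 0])
    return pd.concat(frames, ignore_index=True)


def _minima_leftmost(y):
    """Indices of strict local minima; plateaus report their leftmost bin.

    Returns (indices, plateau_sizes) over a NaN-free 1D array.
    """
    n = len(y)
    idx, sizes = [], []
    i = 1
    while i < n - 1:
        j = i
        while j + 1 < n and y[j + 1] == y[i]:
            j += 1
        if j < n - 1 and y[i - 1] > y[i] and y[j + 1] > y[i]:
            idx.append(i)
            sizes.append(j - i + 1)
        i = j + 1
    return idx, sizes


def _prominence(y, m):
    """Topographic prominence of minimum m in profile y (NaN-free array)."""
    best = []
    for step in (-1, 1):
        i = m + step
        dirmax = -np.inf
        while 0 <= i < len(y):
            if y[i] < y[m]:
                break
            dirmax = max(dirmax, y[i])
            i += step
        best.append(dirmax)
    return float(min(best) - y[m])


def find_boundaries(table):
    """Mark local minima of the insulation score and compute prominence.

    Operates per (region, window); NaN stretches split the profile into
    independent runs. Adds ``is_min``, ``prominence``, ``plateau_size``.
    """
    table = table.copy()
    table["is_min"] = False
    table["prominence"] = np.nan
    table["plateau_size"] = 0
    for _, idx in table.groupby(["region", "window"], sort=False).groups.items():
        sub = table.loc[idx]
        y = sub["score"].to_numpy(dtype=float)
        # -inf (a zero diamond) is a legitimate, maximally deep score;
        # only NaN (no data) splits the profile
        finite = ~np.isnan(y)
        s = 0
        while s < len(y):  # contiguous finite runs
            if not finite[s]:
                s += 1
                continue
            e = s
            while e < len(y) and finite[e]:
                e += 1
            run = y[s:e]
            if len(run) >= 3:
                mins, sizes = _minima_leftmost(run)
                for m, sz in zip(mins, sizes):
                    gi = sub.index[s + m]
                    table.loc[gi, "is_min"] = True
                    table.loc[gi, "prominence"] = _prominence(run, m)
                    table.loc[gi, "plateau_size"] = sz
            s = e
    return table


def threshold_boundaries(table, method="otsu", value=None):
    """Flag strong boundaries by thresholding minima prominences.

    ``method`` is "li", "otsu", or "fixed" (with ``value``); the threshold
    is computed per window size on the prominences of all minima. Adds an
    ``is_strong_<method>`` column.
    """
    method = str(method).lower()
    table = table.copy()
    col = f"is_strong_{method}"
    table[col] = False
    for wb, idx in table.groupby("window", sort=False).groups.items():
        sub = table.loc[idx]
        mins = sub["is_min"].to_numpy(dtype=bool)
        prom = sub["prominence"].to_numpy(dtype=float)
        # infinitely prominent minima (zero diamonds) are always strong and
        # excluded from the threshold statistics
        pv = prom[mins & np.isfinite(prom)]
        if method == "fixed":
            if value is None:
                raise ValueError("fixed thresholding requires a value")
            thr = float(value)
        elif len(pv) < 2 or np.allclose(pv, pv[0]):
            warnings.warn(
                f"window {wb}: too few distinct prominences for {method}; "
                "flagging all minima as strong"
            )
            thr = -np.inf
        elif method == "otsu":
            thr = threshold_otsu(pv)
        elif method == "li":
            thr = threshold_li(pv)
        else:
            raise ValueError(f"unknown thresholding method {method!r}")
        strong = mins & ~np.isnan(prom) & (prom >= thr)
        table.loc[sub.index[strong], col] = True
    return table
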