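"""Snippet extraction and pileups (aggregate maps).

A snippet is a fixed-size window of the contact map centered on an anchor
bin (on-diagonal) or on a pair of anchor bins (off-diagonal). Averaging
many snippets element-wise — a pileup, or aggregate peak analysis —
reveals the typical contact pattern at a class of genomic elements (e.g.
boundaries or dot anchors) that is invisible in any single noisy window.

Anchors given as intervals are mapped to the bin containing the interval
midpoint. Cells falling outside the anchor's view region are missing (NaN),
never truncated, so every snippet in a stack has the same shape.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from multiprocessing import get_context

import numpy as np
import pandas as pd

from .expected import expected_curves
from .io import assign_bins, make_view, open_store

__all__ = ["SnippetStack", "snip", "pileup"]


@dataclass
class SnippetStack:
    """3D array (snippet, row, col) plus per-snippet provenance."""

    stack: np.ndarray
    features: pd.DataFrame
    flank_bins: int
    n_dropped: int = 0


def _anchor_bins(features, store):
    """Bin id of each anchor midpoint; pairs use (chrom1.. / chrom2..) columns."""
    feats = pd.DataFrame(features).copy()
    paired = "chrom2" in feats.columns
    if not paired:
        feats = feats.rename(columns={"chrom": "chrom1", "start": "start1", "end": "end1"})
        feats["chrom2"] = feats["chrom1"]
        feats["start2"] = feats["start1"]
        feats["end2"] = feats["end1"]
    bins = store.bins
    chrom_arr = bins["chrom"].to_numpy()
    out = []
    for side in (1, 2):
        mids = ((feats[f"start{side}"] + feats[f"end{side}"]) // 2).to_numpy()
        ids = np.full(len(feats), -1, dtype=np.int64)
        for cname in np.unique(feats[f"chrom{side}"]):
            sel = np.flatnonzero(chrom_arr == cname)
            rows = np.flatnonzero(feats[f"chrom{side}"].to_numpy() == cname)
            if len(sel) == 0:
                continue
            starts = bins["start"].to_numpy()[sel]
            pos = np.searchsorted(starts, mids[rows], side="right") - 1
            ok = (pos >= 0) & (mids[rows] < bins["end"].to_numpy()[sel][pos.clip(0)])
            ids[rows[ok]] = sel[0] + pos[ok]
        out.append(ids)
    feats["abin1"], feats["abin2"] = out
    # orient pairs to the upper triangle
    flip = feats["abin1"] > feats["abin2"]
    feats.loc[flip, ["abin1", "abin2"]] = feats.loc[flip, ["abin2", "abin1"]].to_numpy()
    return feats


def _extract(store, feats, view, rid, flank, mode, curves, use_weights):
    f = flank
    size = 2 * f + 1
    stack = np.full((len(feats), size, size), np.nan)
    region_starts = {}
    for i, row in view.iterrows():
        sel = np.flatnonzero(rid == i)
        if len(sel):
            region_starts[i] = (sel[0], sel[-1] + 1)
    cache = {}
    for k, (_, feat) in enumerate(feats.iterrows()):
        ri = feat["rid"]
        lo, hi = region_starts[ri]
        if ri not in cache:
            cache[ri] = store.dense(lo, hi, lo, hi, balanced=use_weights)
        A = cache[ri]
        a1 = int(feat["abin1"]) - lo
        a2 = int(feat["abin2"]) - lo
        m = hi - lo
        r0, r1 = a1 - f, a1 + f + 1
        c0, c1 = a2 - f, a2 + f + 1
        rr0, rr1 = max(r0, 0), min(r1, m)
        cc0, cc1 = max(c0, 0), min(c1, m)
        if rr0 >= rr1 or cc0 >= cc1:
            continue
        win = A[rr0:rr1, cc0:cc1]
        if mode == "oe":
            curve = curves[view["name"].iloc[ri]]
            d = np.abs(
                np.arange(cc0, cc1)[None, :] - np.arange(rr0, rr1)[:, None]
            )
            e = curve[np.minimum(d, len(curve) - 1)]
            with np.errstate(invalid="ignore", divide="ignore"):
                win = np.where(e > 0, win / e, np.nan)
        stack[k, rr0 - r0 : rr1 - r0, cc0 - c0 : cc1 - c0] = win
    return stack


def _worker(args):
    (uri, weight_name, feats, view, rid, flank, mode, curves, use_weights) = args
    store = open_store(uri, weight_name=weight_name)
    return _extract(store, feats, view, rid, flank, mode, curves, use_weights)


def snip(
    store,
    features,
    view=None,
    flank_bp=100_000,
    mode="oe",
    expected=None,
    use_weights=True,
    nproc=1,
):
    """Extract (2f+1)^2 windows around anchors or anchor pairs.

    ``mode="oe"`` divides each cell by the expected value at its separation
    within the anchor's region (requires ``expected``); ``mode="observed"``
    returns balanced (or raw, ``use_weights=False``) values. Anchors outside
    the view, or pairs spanning two regions, are dropped and counted in
    ``n_dropped``. Results are bit-identical for any ``nproc``.
    """
    if flank_bp % store.binsize:
        raise ValueError("flank must be a multiple of the bin size")
    if mode == "oe" and expected is None:
        raise ValueError("oe mode requires an expected table")
    flank = int(flank_bp // store.binsize)
    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    feats = _anchor_bins(features, store)
    feats["rid"] = -1
    ok = (feats["abin1"] >= 0) & (feats["abin2"] >= 0)
    r1 = np.where(ok, rid[feats["abin1"].to_numpy().clip(0)], -1)
    r2 = np.where(ok, rid[feats["abin2"].to_numpy().clip(0)], -1)
    keep = ok.to_numpy() & (r1 >= 0) & (r1 == r2)
    n_dropped = int((~keep).sum())
    if n_dropped:
        warnings.warn(f"dropped {n_dropped} anchors outside the view or spanning regions")
    feats = feats[keep].reset_index(drop=True)
    feats["rid"] = r1[keep]
    curves = expected_curves(expected) if mode == "oe" else None

    if nproc <= 1 or len(feats) < 2:
        stack = _extract(store, feats, view, rid, flank, mode, curves, use_weights)
    else:
        parts = np.array_split(np.arange(len(feats)), nproc)
        args = [
            (
                store.path if store.group == "/" else f"{store.path}::{store.group}",
                store.weight_name,
                feats.iloc[p],
                view,
                rid,
                flank,
                mode,
                curves,
                use_weights,
            )
            for p in parts
            if len(p)
        ]
        with get_context("spawn").Pool(nproc) as pool:
            chunks = pool.map(_worker, args)
        stack = np.concatenate(chunks, axis=0)
    return SnippetStack(stack=stack, features=feats, flank_bins=flank, n_dropped=n_dropped)


def pileup(stack, stat="mean"):
    """Element-wise average of a snippet stack, ignoring missing cells.

    Returns (matrix, n) where n[i, j] counts the snippets contributing to
    each cell.
    """
    arr = stack.stack if isinstance(stack, SnippetStack) else np.asarray(stack)
    n = np.isfinite(arr).sum(axis=0)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        if stat == "mean":
            out = np.nanmean(arr, axis=0)
        elif stat == "median":
            out = np.nanmedian(arr, axis=0)
        else:
            raise ValueError(f"unknown statistic {stat!r}")
    return out, n
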