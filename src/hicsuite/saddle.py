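"""Pairwise class averaging of observed/expected contacts ("saddle plots").

Bins are grouped into classes by digitizing a quantitative track (most
commonly a compartment eigenvector) into quantile bins; the mean
observed/expected contact frequency is then computed over every pair of
classes. For a compartmentalized genome the resulting class-by-class matrix
has enriched corners (like-with-like contacts) and a depleted
anti-diagonal — the saddle shape that names the method.

Means are taken over all valid matrix positions of each class pair, not
just stored nonzero pixels, so sampling zeros do not bias the averages.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .expected import expected_curves, trans_levels
from .io import assign_bins, make_view

__all__ = ["digitize_track", "saddle_aggregate", "saddle_strength", "SaddleResult"]


class SaddleResult:
    """Mean O/E per class pair (S), contributing position counts (C)."""

    def __init__(self, S, C, scale, edges=None):
        self.S = S
        self.C = C
        self.scale = scale
        self.edges = edges


def digitize_track(track, n_classes=5, lo_q=0.025, hi_q=0.975, mode="quantile",
                   value_col="value"):
    """Assign each bin a class label 1..n_classes from a quantitative track.

    Edges are quantiles linearly spaced between ``lo_q`` and ``hi_q`` of the
    valid values (``mode="quantile"``), or equal-width in value between those
    two quantiles (``mode="value"``). Values below/above the edge range get
    outlier labels 0 / n_classes+1; missing values get -1.
    """
    vals = track[value_col].to_numpy(dtype=float)
    finite = vals[np.isfinite(vals)]
    if len(finite) == 0:
        raise ValueError("track has no finite values")
    if mode == "quantile":
        edges = np.quantile(finite, np.linspace(lo_q, hi_q, n_classes + 1))
    elif mode == "value":
        lo, hi = np.quantile(finite, [lo_q, hi_q])
        edges = np.linspace(lo, hi, n_classes + 1)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    if np.any(np.diff(edges) <= 0):
        raise ValueError("degenerate digitization edges (constant track?)")
    labels = np.searchsorted(edges, vals, side="right")
    labels[vals == edges[-1]] = n_classes  # top edge is inclusive
    labels = np.where(np.isfinite(vals), labels, -1).astype(np.int64)
    out = track.copy()
    out["label"] = labels
    out.attrs["n_classes"] = n_classes
    out.attrs["edges"] = edges
    return out, edges


def saddle_aggregate(
    store,
    expected,
    digitized,
    view=None,
    scale="cis",
    min_dist=2,
    chunksize=None,
    n_classes=None,
):
    """Mean O/E over all pixels of each class pair.

    ``scale="cis"`` uses the distance-indexed expected of each region with
    itself (intra-region pixels at separation >= ``min_dist``);
    ``scale="trans"`` uses region-pair trans averages. Outlier classes
    (0 and n+1) are excluded.
    """
    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    labels = digitized["label"].to_numpy(dtype=np.int64)
    if n_classes is None:
        n_classes = digitized.attrs.get("n_classes") or int(labels.max())
    w = store.weights
    valid = np.isfinite(w) & (labels >= 1) & (labels <= n_classes)
    cid = store.chrom_ids

    n = n_classes
    S_sum = np.zeros((n + 1, n + 1))
    C = np.zeros((n + 1, n + 1), dtype=np.int64)

    if scale == "cis":
        curves = expected_curves(expected)
        exp_by_reg = {}
        for i, row in view.iterrows():
            if row["name"] not in curves:
                raise ValueError(f"expected table lacks region {row['name']!r}")
            exp_by_reg[i] = curves[row["name"]]
        for chunk in store.iter_pixels(chunksize):
            b1 = chunk["bin1_id"].to_numpy()
            b2 = chunk["bin2_id"].to_numpy()
            c = chunk["count"].to_numpy(dtype=float)
            r1, r2 = rid[b1], rid[b2]
            d = b2 - b1
            ok = (r1 >= 0) & (r1 == r2) & (d >= min_dist) & valid[b1] & valid[b2]
            for r in np.unique(r1[ok]):
                sub = ok & (r1 == r)
                e = exp_by_reg[r][d[sub]]
                oe = c[sub] * w[b1[sub]] * w[b2[sub]] / e
                keep = np.isfinite(oe)
                np.add.at(S_sum, (labels[b1[sub]][keep], labels[b2[sub]][keep]), oe[keep])
                np.add.at(S_sum, (labels[b2[sub]][keep], labels[b1[sub]][keep]), oe[keep])
        # position counts from class composition (zero pixels count too);
        # separations without an expected model contribute no O/E and are
        # excluded from the counts as well
        for i, row in view.iterrows():
            sel = np.flatnonzero(rid == i)
            lab = np.where(valid[sel], labels[sel], -1)
            m = len(sel)
            curve = exp_by_reg[i]
            for d in range(min_dist, m):
                if not (d < len(curve) and np.isfinite(curve[d]) and curve[d] > 0):
                    continue
                a, b = lab[: m - d], lab[d:]
                keep = (a >= 1) & (b >= 1)
                np.add.at(C, (a[keep], b[keep]), 1)
                np.add.at(C, (b[keep], a[keep]), 1)
    elif scale == "trans":
        levels = trans_levels(expected)
        names = view["name"].to_numpy()
        for chunk in store.iter_pixels(chunksize):
            b1 = chunk["bin1_id"].to_numpy()
            b2 = chunk["bin2_id"].to_numpy()
            c = chunk["count"].to_numpy(dtype=float)
            r1, r2 = rid[b1], rid[b2]
            ok = (r1 >= 0) & (r2 >= 0) & (cid[b1] != cid[b2]) & valid[b1] & valid[b2]
            for ra in np.unique(r1[ok]):
                for rb in np.unique(r2[ok & (r1 == ra)]):
                    sub = ok & (r1 == ra) & (r2 == rb)
                    e = levels.get((names[ra], names[rb]), np.nan)
                    oe = c[sub] * w[b1[sub]] * w[b2[sub]] / e
                    keep = np.isfinite(oe)
                    np.add.at(
                        S_sum, (labels[b1[sub]][keep], labels[b2[sub]][keep]), oe[keep]
                    )
                    np.add.at(
                        S_sum, (labels[b2[sub]][keep], labels[b1[sub]][keep]), oe[keep]
                    )
        chrom_of = view["chrom"].to_numpy()
        class_counts = np.zeros((len(view), n + 1), dtype=np.int64)
        for i in range(len(view)):
            lab = labels[(rid == i) & valid]
            class_counts[i] = np.bincount(lab, minlength=n + 1)
        for i in range(len(view)):
            for j in range(i + 1, len(view)):
                if chrom_of[i] == chrom_of[j]:
                    continue
                if (names[i], names[j]) not in levels:
                    continue
                outer = np.outer(class_counts[i], class_counts[j])
                C += outer + outer.T
    else:
        raise ValueError(f"unknown scale {scale!r}")

    S_sum = S_sum[1:, 1:]
    Cm = C[1:, 1:]
    with np.errstate(invalid="ignore"):
        S = np.where(Cm > 0, S_sum / np.where(Cm > 0, Cm, 1), np.nan)
    return SaddleResult(S=S, C=Cm, scale=scale)


def saddle_strength(result, extent=1):
    """Corner-ratio compartmentalization strength.

    (mean of the top-left extent x extent corner + mean of the bottom-right
    corner) / (sum of the two anti-diagonal corner means). 1.0 means no
    preference; NaN-safe.
    """
    S = result.S if isinstance(result, SaddleResult) else np.asarray(result)
    n = len(S)
    if not (1 <= extent <= n):
        raise ValueError(f"extent must be in [1, {n}]")
    e = extent
    tl = np.nanmean(S[:e, :e])
    br = np.nanmean(S[-e:, -e:])
    tr = np.nanmean(S[:e, -e:])
    bl = np.nanmean(S[-e:, :e])
    return float((tl + br) / (tr + bl))
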