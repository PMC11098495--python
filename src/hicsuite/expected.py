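"""Average contact frequency by genomic separation — the "expected" model.

Contact frequency in cis decays roughly as a power law of genomic
separation s; this curve, P(s), is the dominant trend in any contact map
and is the denominator of every observed/expected analysis downstream
(compartment eigenvectors, saddles, dot calling, pileups).

The computation streams over chunks of the sparse pixel table, assigns
pixels to view regions, and aggregates counts and balanced values at each
separation, while exactly accounting for masked (bad) bins: the number of
valid bin pairs at separation d inside a region is tallied from the bin
weight mask, so zero pixels and filtered bins are handled without ever
building a dense matrix.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import assign_bins, make_view

__all__ = [
    "expected_cis",
    "expected_trans",
    "smooth_expected",
    "logderiv_expected",
    "expected_curves",
    "trans_levels",
]

CIS_COLS = [
    "region1",
    "region2",
    "dist",
    "n_valid",
    "count_sum",
    "balanced_sum",
    "count_avg",
    "balanced_avg",
]


def _valid_mask(store, use_weights):
    if use_weights:
        if not store.has_weights:
            raise ValueError("store has no balancing weights")
        return np.isfinite(store.weights)
    return np.ones(store.n_bins, dtype=bool)


def expected_cis(
    store,
    view=None,
    use_weights=True,
    chunksize=None,
    smooth=True,
    sigma_log10=0.1,
    min_dist_smooth=2,
    aggregate_smoothed=True,
    include_inter=True,
):
    """Distance-indexed cis expected per view region.

    Returns one record per (region, region, d) for d = 0..len(region)-1
    with the number of valid bin pairs, raw and balanced sums and averages.
    Pixels whose bins fall into two different regions on the same
    chromosome (e.g. the two arms) are aggregated into inter-region records
    without a distance index (``include_inter``). Balanced averages are
    smoothed in log-distance space (see :func:`smooth_expected`).
    """
    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    valid = _valid_mask(store, use_weights)
    w = store.weights if use_weights else np.ones(store.n_bins)
    chrom_ids = store.chrom_ids

    # per-region offsets into flat distance-indexed accumulators
    reg_nbins = np.array([(rid == i).sum() for i in range(len(view))])
    offsets = np.concatenate([[0], np.cumsum(reg_nbins)])
    total = offsets[-1]
    count_sum = np.zeros(total)
    bal_sum = np.zeros(total)

    nreg = len(view)
    inter_count = np.zeros(nreg * nreg)
    inter_bal = np.zeros(nreg * nreg)

    for chunk in store.iter_pixels(chunksize):
        b1 = chunk["bin1_id"].to_numpy()
        b2 = chunk["bin2_id"].to_numpy()
        c = chunk["count"].to_numpy(dtype=float)
        r1, r2 = rid[b1], rid[b2]
        ok = (r1 >= 0) & (r2 >= 0) & (chrom_ids[b1] == chrom_ids[b2])
        ok &= valid[b1] & valid[b2]
        bal = c * w[b1] * w[b2]

        intra = ok & (r1 == r2)
        idx = offsets[r1[intra]] + (b2[intra] - b1[intra])
        np.add.at(count_sum, idx, c[intra])
        np.add.at(bal_sum, idx, bal[intra])

        if include_inter:
            inter = ok & (r1 != r2)
            key = np.minimum(r1[inter], r2[inter]) * nreg + np.maximum(
                r1[inter], r2[inter]
            )
            np.add.at(inter_count, key, c[inter])
            np.add.at(inter_bal, key, bal[inter])

    records = []
    for i, row in view.iterrows():
        n = reg_nbins[i]
        v = valid[rid == i]
        n_valid = np.array(
            [int(np.sum(v[: n - d] & v[d:])) for d in range(n)], dtype=np.int64
        )
        sl = slice(offsets[i], offsets[i + 1])
        df = pd.DataFrame(
            {
                "region1": row["name"],
                "region2": row["name"],
                "dist": np.arange(n),
                "n_valid": n_valid,
                "count_sum": count_sum[sl],
                "balanced_sum": bal_sum[sl],
            }
        )
        records.append(df)

    if include_inter:
        chrom_of = view["chrom"].to_numpy()
        for i in range(nreg):
            for j in range(i + 1, nreg):
                if chrom_of[i] != chrom_of[j]:
                    continue
                nv = int(valid[rid == i].sum()) * int(valid[rid == j].sum())
                records.append(
                    pd.DataFrame(
                        {
                            "region1": [view["name"].iloc[i]],
                            "region2": [view["name"].iloc[j]],
                            "dist": [np.nan],
                            "n_valid": [nv],
                            "count_sum": [inter_count[i * nreg + j]],
                            "balanced_sum": [inter_bal[i * nreg + j]],
                        }
                    )
                )

    table = pd.concat(records, ignore_index=True)
    with np.errstate(invalid="ignore", divide="ignore"):
        nv = table["n_valid"].to_numpy(dtype=float)
        table["count_avg"] = np.where(nv > 0, table["count_sum"] / nv, np.nan)
        table["balanced_avg"] = np.where(nv > 0, table["balanced_sum"] / nv, np.nan)
    table = table[CIS_COLS]
    if smooth:
        table = smooth_expected(
            table,
            sigma_log10=sigma_log10,
            min_dist=min_dist_smooth,
            agg_across_regions=aggregate_smoothed,
        )
    return table


def expected_trans(store, view=None, use_weights=True, chunksize=None):
    """Mean contact frequency per unordered pair of regions on different
    chromosomes. Inter-chromosomal maps have no distance structure, so a
    single rectangle average per region pair suffices."""
    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    valid = _valid_mask(store, use_weights)
    w = store.weights if use_weights else np.ones(store.n_bins)
    chrom_ids = store.chrom_ids
    nreg = len(view)
    count_sum = np.zeros(nreg * nreg)
    bal_sum = np.zeros(nreg * nreg)
    for chunk in store.iter_pixels(chunksize):
        b1 = chunk["bin1_id"].to_numpy()
        b2 = chunk["bin2_id"].to_numpy()
        c = chunk["count"].to_numpy(dtype=float)
        r1, r2 = rid[b1], rid[b2]
        ok = (r1 >= 0) & (r2 >= 0) & (chrom_ids[b1] != chrom_ids[b2])
        ok &= valid[b1] & valid[b2]
        key = np.minimum(r1[ok], r2[ok]) * nreg + np.maximum(r1[ok], r2[ok])
        np.add.at(count_sum, key, c[ok])
        np.add.at(bal_sum, key, c[ok] * w[b1[ok]] * w[b2[ok]])

    n_valid_reg = np.array([int(valid[rid == i].sum()) for i in range(nreg)])
    chrom_of = view["chrom"].to_numpy()
    rows = []
    for i in range(nreg):
        for j in range(i + 1, nreg):
            if chrom_of[i] == chrom_of[j]:
                continue
            nv = n_valid_reg[i] * n_valid_reg[j]
            cs = count_sum[i * nreg + j]
            bs = bal_sum[i * nreg + j]
            rows.append(
                (
                    view["name"].iloc[i],
                    view["name"].iloc[j],
                    nv,
                    cs,
                    bs,
                    cs / nv if nv else np.nan,
                    bs / nv if nv else np.nan,
                )
            )
    return pd.DataFrame(
        rows,
        columns=[
            "region1",
            "region2",
            "n_valid",
            "count_sum",
            "balanced_sum",
            "count_avg",
            "balanced_avg",
        ],
    )


def _smooth_curve(dist, bal_sum, n_valid, sigma_log10, min_dist):
    """n_valid-weighted Gaussian smoothing in log10 distance, 3-sigma cutoff."""
    out = np.full(len(dist), np.nan)
    src = (dist >= min_dist) & (n_valid > 0)
    if src.any():
        logd_src = np.log10(dist[src])
        bs, nv = bal_sum[src], n_valid[src].astype(float)
        for k in np.flatnonzero(dist >= min_dist):
            ld = np.log10(dist[k])
            sel = np.abs(logd_src - ld) <= 3 * sigma_log10
            if not sel.any():
                continue
            kern = np.exp(-0.5 * ((logd_src[sel] - ld) / sigma_log10) ** 2)
            den = np.sum(kern * nv[sel])
            if den > 0:
                out[k] = np.sum(kern * bs[sel]) / den
    # short separations pass through unsmoothed
    near = dist < min_dist
    with np.errstate(invalid="ignore", divide="ignore"):
        out[near] = np.where(
            n_valid[near] > 0, bal_sum[near] / n_valid[near], np.nan
        )
    return out


def smooth_expected(table, sigma_log10=0.1, min_dist=2, agg_across_regions=False):
    """Add ``balanced_avg_smoothed`` (and, optionally, a genome-wide
    ``balanced_avg_smoothed_agg`` pooled over regions) to a cis expected table."""
    table = table.copy()
    intra = table["dist"].notna() & (table["region1"] == table["region2"])
    table["balanced_avg_smoothed"] = np.nan
    for _, idx in table[intra].groupby("region1", sort=False).groups.items():
        sub = table.loc[idx]
        table.loc[idx, "balanced_avg_smoothed"] = _smooth_curve(
            sub["dist"].to_numpy(),
            sub["balanced_sum"].to_numpy(),
            sub["n_valid"].to_numpy(),
            sigma_log10,
            min_dist,
        )
    if agg_across_regions:
        pooled = (
            table[intra]
            .groupby("dist", sort=True)[["balanced_sum", "n_valid"]]
            .sum()
            .reset_index()
        )
        sm = _smooth_curve(
            pooled["dist"].to_numpy(),
            pooled["balanced_sum"].to_numpy(),
            pooled["n_valid"].to_numpy(),
            sigma_log10,
            min_dist,
        )
        lookup = dict(zip(pooled["dist"], sm))
        table["balanced_avg_smoothed_agg"] = np.nan
        table.loc[intra, "balanced_avg_smoothed_agg"] = [
            lookup.get(d, np.nan) for d in table.loc[intra, "dist"]
        ]
    return table


def logderiv_expected(table, value_col="balanced_avg_smoothed"):
    """Slope d log10 P / d log10 s of the (smoothed) P(s) curve.

    Central finite differences on the log-log curve; one-sided at the ends;
    NaN where P is missing or s = 0. Returns the intra-region records with a
    ``slope`` column.
    """
    intra = table["dist"].notna() & (table["region1"] == table["region2"])
    out = table[intra].copy()
    out["slope"] = np.nan
    for _, idx in out.groupby("region1", sort=False).groups.items():
        sub = out.loc[idx]
        d = sub["dist"].to_numpy(dtype=float)
        p = sub[value_col].to_numpy(dtype=float)
        keep = (d > 0) & np.isfinite(p) & (p > 0)
        if keep.sum() < 2:
            continue
        x = np.log10(d[keep])
        y = np.log10(p[keep])
        slope = np.gradient(y, x)
        vals = np.full(len(sub), np.nan)
        vals[keep] = slope
        out.loc[idx, "slope"] = vals
    return out


def expected_curves(table, value_col=None):
    """Per-region distance-indexed lookup arrays from a cis expected table.

    Returns {region name: array over d} using ``balanced_avg_smoothed`` when
    present (falling back to ``balanced_avg``), or an explicit column.
    """
    if value_col is None:
        value_col = (
            "balanced_avg_smoothed"
            if "balanced_avg_smoothed" in table.columns
            else "balanced_avg"
        )
    curves = {}
    intra = table["dist"].notna() & (table["region1"] == table["region2"])
    for name, sub in table[intra].groupby("region1", sort=False):
        sub = sub.sort_values("dist")
        arr = np.full(int(sub["dist"].max()) + 1, np.nan)
        arr[sub["dist"].to_numpy(dtype=int)] = sub[value_col].to_numpy()
        curves[name] = arr
    return curves


def trans_levels(table):
    """{(region1, region2): balanced_avg} lookup from a trans expected table."""
    out = {}
    for _, row in table.iterrows():
        out[(row["region1"], row["region2"])] = row["balanced_avg"]
        out[(row["region2"], row["region1"])] = row["balanced_avg"]
    return out
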