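"""Map utilities: cis/total coverage, random downsampling, adaptive smoothing.

Coverage profiles expose chromosome territoriality (contacts are more
frequent within than between chromosomes). Downsampling supports
controlled depth-matched comparisons. Adaptive smoothing mitigates
sampling noise at high resolution by borrowing signal from progressively
coarser scales only where the local raw count is too low.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .io import ContactStore, write_store

__all__ = ["coverage", "downsample", "adaptive_smooth"]


def coverage(store, use_weights=False, chunksize=None):
    """Per-bin cis and total contact sums.

    Every off-diagonal pixel adds its count to both incident bins; a
    diagonal pixel adds once to its bin (a self-contact). ``use_weights``
    additionally reports balanced sums (NaN at bad bins).
    """
    n = store.n_bins
    cid = store.chrom_ids
    cis_raw = np.zeros(n)
    tot_raw = np.zeros(n)
    w = store.weights
    cis_bal = np.zeros(n)
    tot_bal = np.zeros(n)
    for chunk in store.iter_pixels(chunksize):
        b1 = chunk["bin1_id"].to_numpy()
        b2 = chunk["bin2_id"].to_numpy()
        c = chunk["count"].to_numpy(dtype=float)
        off = b1 != b2
        np.add.at(tot_raw, b1, c)
        np.add.at(tot_raw, b2[off], c[off])
        cis = cid[b1] == cid[b2]
        np.add.at(cis_raw, b1[cis], c[cis])
        np.add.at(cis_raw, b2[cis & off], c[cis & off])
        if use_weights:
            bal = c * w[b1] * w[b2]
            ok = np.isfinite(bal)
            np.add.at(tot_bal, b1[ok], bal[ok])
            np.add.at(tot_bal, b2[ok & off], bal[ok & off])
            np.add.at(cis_bal, b1[cis & ok], bal[cis & ok])
            np.add.at(cis_bal, b2[cis & ok & off], bal[cis & ok & off])
    out = store.bins[["chrom", "start", "end"]].copy()
    out["cis_raw"] = cis_raw.astype(np.int64)
    out["total_raw"] = tot_raw.astype(np.int64)
    with np.errstate(invalid="ignore", divide="ignore"):
        out["cis_ratio"] = np.where(tot_raw > 0, cis_raw / np.where(tot_raw > 0, tot_raw, 1), np.nan)
    if use_weights:
        bad = ~np.isfinite(w)
        cis_bal[bad] = np.nan
        tot_bal[bad] = np.nan
        out["cis_balanced"] = cis_bal
        out["total_balanced"] = tot_bal
    return out


def downsample(store, out_path, fraction=None, target_count=None, seed=0, chunksize=None):
    """Binomially downsample pixel counts into a new cooler-schema file.

    Each pixel's count is replaced by an independent Binomial(count, p)
    draw with p = ``fraction`` or ``target_count / total``; zero draws are
    dropped. Per-pixel binomial sampling approximates without-replacement
    subsampling extremely well at contact-map scales. Seeded, reproducible.
    """
    if fraction is None:
        if target_count is None:
            raise ValueError("give fraction or target_count")
        total = 0
        for chunk in store.iter_pixels(chunksize):
            total += int(chunk["count"].sum())
        fraction = min(float(target_count) / max(total, 1), 1.0)
    if not (0 < fraction <= 1):
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    out_chunks = []
    for chunk in store.iter_pixels(chunksize):
        counts = chunk["count"].to_numpy(dtype=np.int64)
        new = rng.binomial(counts, fraction) if fraction < 1 else counts
        keep = new > 0
        sub = chunk[keep].copy()
        sub["count"] = new[keep]
        out_chunks.append(sub)
    pixels = (
        pd.concat(out_chunks, ignore_index=True)
        if out_chunks
        else pd.DataFrame(columns=["bin1_id", "bin2_id", "count"])
    )
    write_store(out_path, store.chroms, store.bins, pixels)
    return ContactStore(out_path, weight_name=store.weight_name)


def _coarsen_sum(M):
    n = M.shape[0]
    m = (n + 1) // 2
    P = np.zeros((2 * m, 2 * m))
    P[:n, :n] = M
    return P.reshape(m, 2, m, 2).sum(axis=(1, 3))


def adaptive_smooth(store, region, cutoff_counts=10, max_levels=8):
    """Multi-scale adaptive smoothing of one region's balanced matrix.

    A pyramid of 2x-coarsened raw-count matrices is built; each output
    cell resolves at the finest level whose co-located aggregate raw count
    reaches ``cutoff_counts`` (or the coarsest level). Cells resolving at a
    coarse level share that block's balanced mass *net of the cells already
    resolved at finer levels* — i.e. observed counts are split across the
    starved bins rather than double-counted — so total balanced mass is
    conserved exactly when no cells are missing. Deterministic.
    """
    i0, i1 = store.extent(region)
    raw = store.dense(i0, i1, i0, i1, balanced=False)
    bal = store.dense(i0, i1, i0, i1, balanced=True)
    n = raw.shape[0]
    raws = [raw]
    for _ in range(max_levels):
        if raws[-1].shape[0] <= 1:
            break
        raws.append(_coarsen_sum(raws[-1]))
    n_levels = len(raws)

    ii, jj = np.meshgrid(np.arange(n), np.arange(n), indexing="ij")
    assigned = np.full((n, n), n_levels - 1, dtype=np.int64)
    for lev in range(n_levels - 1, -1, -1):
        ci, cj = ii >> lev, jj >> lev
        assigned[raws[lev][ci, cj] >= cutoff_counts] = lev

    finite = np.isfinite(bal)
    out = np.full((n, n), np.nan)
    for lev in range(n_levels):
        sel = assigned == lev
        if not sel.any():
            continue
        if lev == 0:
            out[sel & finite] = bal[sel & finite]
            continue
        # residual mass of each block: cells not resolved at finer levels
        open_mask = (assigned >= lev) & finite
        num = np.where(open_mask, bal, 0.0)
        cnt = open_mask.astype(float)
        for _ in range(lev):
            num = _coarsen_sum(num)
            cnt = _coarsen_sum(cnt)
        ci, cj = ii >> lev, jj >> lev
        with np.errstate(invalid="ignore", divide="ignore"):
            vals = np.where(cnt > 0, num / np.where(cnt > 0, cnt, 1), np.nan)
        cells = sel & finite
        out[cells] = vals[ci[cells], cj[cells]]
    return out
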