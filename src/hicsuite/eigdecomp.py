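"""Compartment profiles as eigenvectors of the observed/expected map.

The plaid (checkerboard) pattern of preferential contacts between bins of
the same chromatin type is captured by the leading eigenvectors of the
contact matrix after removal of the distance trend. In cis, each region's
balanced matrix is divided by its per-diagonal mean, clipped, centered at
zero by subtracting 1, and eigendecomposed. In trans, the cis blocks of the
genome-wide matrix are masked by substituting randomly sampled trans
values, and the whole matrix is scaled by the global trans mean before
decomposition.

Because eigenvectors are defined only up to sign — and the compartment
signal is not always the first eigenvector — vectors can be oriented and
sorted by their correlation with a "phasing track" such as GC content.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import assign_bins, make_view

__all__ = ["EigResult", "eigs_cis", "eigs_trans", "phase_eigs"]


@dataclass
class EigResult:
    """Eigenvalues, eigenvector tracks, and phasing correlations.

    ``eigvals``: DataFrame (region, eig, eigval); ``eigvecs``: bin table with
    one column per vector (E1..Ek), NaN at bad bins; ``phasing_corr``:
    DataFrame (region, eig, corr) or empty when no track was given.
    """

    eigvals: pd.DataFrame
    eigvecs: pd.DataFrame
    phasing_corr: pd.DataFrame = field(default_factory=pd.DataFrame)


def _oe_cis(A, clip_percentile=(0.1, 99.9)):
    """Observed/expected minus 1 for one region's balanced dense matrix."""
    n = len(A)
    OE = np.full_like(A, np.nan)
    for d in range(n):
        diag = np.diagonal(A, offset=d)
        mu = np.nanmean(diag) if np.isfinite(diag).any() else np.nan
        if np.isfinite(mu) and mu > 0:
            idx = np.arange(n - d)
            OE[idx, idx + d] = diag / mu
            OE[idx + d, idx] = OE[idx, idx + d]
    finite = OE[np.isfinite(OE)]
    if len(finite):
        lo, hi = np.percentile(finite, clip_percentile)
        OE = np.clip(OE, lo, hi)
    return OE - 1.0


def _decompose(M, good, n_eigs):
    """Top eigenpairs (by descending eigenvalue) of a symmetric matrix with
    bad rows/columns dropped; vectors unit-norm over valid bins, NaN elsewhere."""
    n = len(M)
    sub = M[np.ix_(good, good)]
    sub = np.nan_to_num((sub + sub.T) / 2.0)
    evals, evecs = np.linalg.eigh(sub)
    order = np.argsort(evals)[::-1][:n_eigs]
    lam = evals[order]
    vecs = np.full((n, len(order)), np.nan)
    vecs[good, :] = evecs[:, order]
    return lam, vecs


def _pearson(x, y):
    ok = np.isfinite(x) & np.isfinite(y)
    if ok.sum() < 3 or np.nanstd(x[ok]) == 0 or np.nanstd(y[ok]) == 0:
        return np.nan
    return float(np.corrcoef(x[ok], y[ok])[0, 1])


def eigs_cis(
    store,
    view=None,
    n_eigs=3,
    phasing_track=None,
    clip_percentile=(0.1, 99.9),
    sort="eigenvalue",
):
    """Per-region compartment eigenvectors of the cis observed/expected map.

    Regions with fewer than ``n_eigs + 1`` valid bins yield all-missing
    vectors (with a warning). When a phasing track is supplied, vectors are
    sign-oriented (and optionally reordered, ``sort="correlation"``) by
    Pearson correlation with the track.
    """
    view = make_view(store) if view is None else view
    rid = assign_bins(store, view)
    w = store.weights
    track_vals = (
        phasing_track["value"].to_numpy(dtype=float)
        if phasing_track is not None
        else None
    )

    vec_cols = [f"E{k + 1}" for k in range(n_eigs)]
    eigvecs = store.bins[["chrom", "start", "end"]].copy()
    for col in vec_cols:
        eigvecs[col] = np.nan
    val_rows, corr_rows = [], []

    for i, row in view.iterrows():
        sel = np.flatnonzero(rid == i)
        A = store.dense(sel[0], sel[-1] + 1, sel[0], sel[-1] + 1, balanced=True)
        good = np.isfinite(w[sel])
        if good.sum() < n_eigs + 1:
            warnings.warn(
                f"region {row['name']}: fewer than {n_eigs + 1} valid bins; "
                "returning missing eigenvectors"
            )
            for k in range(n_eigs):
                val_rows.append((row["name"], vec_cols[k], np.nan))
            continue
        M = _oe_cis(A, clip_percentile)
        lam, vecs = _decompose(M, good, n_eigs)
        for k in range(n_eigs):
            val_rows.append((row["name"], vec_cols[k], lam[k]))
            eigvecs.loc[eigvecs.index[sel], vec_cols[k]] = vecs[:, k]

    result = EigResult(
        eigvals=pd.DataFrame(val_rows, columns=["region", "eig", "eigval"]),
        eigvecs=eigvecs,
    )
    if phasing_track is not None:
        result = phase_eigs(result, phasing_track, sort=sort, view=view, rid=rid)
    return result


def eigs_trans(
    store,
    n_eigs=3,
    phasing_track=None,
    seed=0,
    clip_percentile=(0.1, 99.9),
    sort="eigenvalue",
):
    """Genome-wide compartment eigenvectors from trans contacts only.

    Cis blocks are replaced by values sampled uniformly (seeded) from the
    valid trans pixels involving the same chromosome, the matrix is divided
    by the global trans mean and centered at zero, then decomposed.
    """
    if len(store.chroms) < 2:
        raise ValueError("trans eigendecomposition needs at least two chromosomes")
    rng = np.random.default_rng(seed)
    M = store.matrix(balanced=True)
    cid = store.chrom_ids
    good = np.isfinite(store.weights)
    trans_mask = cid[:, None] != cid[None, :]
    finite_trans = trans_mask & np.isfinite(M)

    # fill each cis block with draws from that chromosome's trans pool
    for c in range(len(store.chroms)):
        rows = np.flatnonzero((cid == c) & good)
        if len(rows) == 0:
            continue
        pool = M[np.ix_(rows, np.flatnonzero(cid != c))]
        pool = pool[np.isfinite(pool)]
        if len(pool) == 0:
            continue
        k = len(rows)
        draws = rng.choice(pool, size=(k, k))
        draws = np.triu(draws) + np.triu(draws, 1).T  # keep symmetry
        M[np.ix_(rows, rows)] = draws

    mu = np.nanmean(M[finite_trans])
    M = M / mu
    finite = M[np.isfinite(M)]
    if len(finite):
        lo, hi = np.percentile(finite, clip_percentile)
        M = np.clip(M, lo, hi)
    M = M - 1.0

    lam, vecs = _decompose(M, good, n_eigs)
    vec_cols = [f"E{k + 1}" for k in range(n_eigs)]
    eigvecs = store.bins[["chrom", "start", "end"]].copy()
    for k, col in enumerate(vec_cols):
        eigvecs[col] = vecs[:, k]
    result = EigResult(
        eigvals=pd.DataFrame(
            {"region": "trans", "eig": vec_cols, "eigval": lam}
        ),
        eigvecs=eigvecs,
    )
    if phasing_track is not None:
        result = phase_eigs(result, phasing_track, sort=sort)
    return result


def phase_eigs(result, phasing_track, sort="eigenvalue", view=None, rid=None):
    """Orient (and optionally reorder) eigenvectors by a phasing track.

    Each vector is multiplied by the sign of its Pearson correlation with
    the track over jointly valid bins, so reported vectors correlate
    non-negatively with the track. ``sort="correlation"`` reorders vectors
    within each region by descending absolute correlation.
    """
    track = phasing_track["value"].to_numpy(dtype=float)
    vec_cols = [c for c in result.eigvecs.columns if c.startswith("E")]
    eigvecs = result.eigvecs.copy()
    eigvals = result.eigvals.copy()
    corr_rows = []

    for region, sub in eigvals.groupby("region", sort=False):
        if rid is not None and view is not None and region != "trans":
            i = view.index[view["name"] == region][0]
            sel = rid == i
        else:
            sel = np.ones(len(eigvecs), dtype=bool)
        corrs = {}
        for col in vec_cols:
            v = eigvecs[col].to_numpy(dtype=float).copy()
            r = _pearson(v[sel], track[sel])
            if np.isfinite(r) and r < 0:
                v[sel] = -v[sel]
                eigvecs[col] = v
                r = -r
            corrs[col] = r
        order = list(vec_cols)
        if sort == "correlation":
            order = sorted(
                vec_cols, key=lambda c: -(corrs[c] if np.isfinite(corrs[c]) else -1)
            )
            block = eigvecs.loc[sel, order].to_numpy()
            eigvecs.loc[eigvecs.index[np.flatnonzero(sel)], vec_cols] = block
            lam_map = dict(zip(sub["eig"], sub["eigval"]))
            eigvals.loc[sub.index, "eigval"] = [lam_map[c] for c in order]
        for k, col in enumerate(vec_cols):
            corr_rows.append((region, col, corrs[order[k]]))

    return EigResult(
        eigvals=eigvals,
        eigvecs=eigvecs,
        phasing_corr=pd.DataFrame(corr_rows, columns=["region", "eig", "corr"]),
    )
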