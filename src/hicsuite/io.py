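"""Cooler-schema I/O, genomic views, track alignment, and matrix balancing.

This module is the data layer for the whole package. It reads and writes
single-resolution ``.cool`` and multi-resolution ``.mcool`` files (cooler
HDF5 schema v3) and exposes the three tables every analysis consumes:

* ``chroms`` — chromosome names and lengths,
* ``bins``  — a fixed-step tiling of each chromosome, optionally carrying a
  per-bin balancing ``weight`` (NaN marks a filtered-out, "bad" bin),
* ``pixels`` — the strictly upper-triangular sparse contact matrix as
  (bin1_id, bin2_id, count) records sorted by (bin1_id, bin2_id).

All coordinates are 0-based, half-open. The balanced value of a pixel is
``count * weight[bin1] * weight[bin2]`` and is missing whenever either bin
is bad, following the cooler convention.

A :class:`GenomicView`-style DataFrame (chrom, start, end, name) defines the
ordered, non-overlapping regions — e.g. chromosomes or chromosomal arms —
that serve as the 1D coordinate axis for per-region analyses.
"""

from __future__ import annotations

import os
import warnings

import h5py
import numpy as np
import pandas as pd
import scipy.sparse as sps

__all__ = [
    "ContactStore",
    "open_store",
    "write_store",
    "parse_uri",
    "make_view",
    "assign_bins",
    "align_track",
    "iterative_correction",
]

#: default number of pixels per chunk for sparse iteration
CHUNKSIZE = 10_000_000

_VIEW_COLS = ["chrom", "start", "end", "name"]


def parse_uri(uri):
    """Split ``path::/resolutions/N`` into (path, group-path)."""
    uri = str(uri)
    if "::" in uri:
        path, grp = uri.split("::", 1)
        if not grp.startswith("/"):
            grp = "/" + grp
    else:
        path, grp = uri, "/"
    return path, grp


class ContactStore:
    """Handle to one resolution of a cooler-schema file.

    The bin and chromosome tables are loaded eagerly (they are small);
    pixels are read lazily and can be streamed in chunks via
    :meth:`iter_pixels`. Dense rectangular blocks of the symmetrized
    (optionally balanced) matrix are materialized on demand with
    :meth:`matrix` / :meth:`dense`; a sparse CSR copy of the full map is
    cached on first dense access, which is appropriate for the map sizes
    this package targets (up to a few tens of thousands of bins).
    """

    def __init__(self, path, group="/", weight_name="weight"):
        self.path = str(path)
        self.group = group
        self.weight_name = weight_name
        with h5py.File(self.path, "r") as f:
            if group not in f or "pixels" not in f[group]:
                if "resolutions" in f:
                    avail = sorted(f["resolutions"].keys(), key=int)
                    raise ValueError(
                        f"no contact matrix at {group!r} in {self.path}; "
                        f"available resolutions: {', '.join(avail)}"
                    )
                raise ValueError(f"{self.path}::{group} is not a cooler-schema group")
            grp = f[group]
            names = np.array(grp["chroms/name"]).astype("U")
            lengths = np.array(grp["chroms/length"]).astype(np.int64)
            self._chroms = pd.DataFrame({"name": names, "length": lengths})
            chrom_raw = np.array(grp["bins/chrom"])
            if chrom_raw.dtype.kind in "iu":
                bin_chroms = names[chrom_raw]
            else:
                bin_chroms = np.array(chrom_raw).astype("U")
            self._bins = pd.DataFrame(
                {
                    "chrom": bin_chroms,
                    "start": np.array(grp["bins/start"], dtype=np.int64),
                    "end": np.array(grp["bins/end"], dtype=np.int64),
                }
            )
            for col in grp["bins"]:
                if col not in ("chrom", "start", "end"):
                    self._bins[col] = np.array(grp["bins"][col], dtype=float)
            self.binsize = int(grp.attrs.get("bin-size", 0)) or int(
                np.median(self._bins["end"] - self._bins["start"])
            )
            self._nnz = len(grp["pixels/bin1_id"])
        self._chrom_ids = pd.Categorical(
            self._bins["chrom"], categories=self._chroms["name"]
        ).codes.astype(np.int64)
        self._sym = None

    # ------------------------------------------------------------------ #
    # tables

    @property
    def chroms(self):
        return self._chroms

    @property
    def bins(self):
        return self._bins

    @property
    def n_bins(self):
        return len(self._bins)

    @property
    def chrom_ids(self):
        """Integer chromosome index per bin."""
        return self._chrom_ids

    @property
    def has_weights(self):
        return self.weight_name in self._bins.columns

    @property
    def weights(self):
        """Per-bin balancing weights (NaN = bad bin); ones if absent."""
        if self.has_weights:
            return self._bins[self.weight_name].to_numpy(dtype=float)
        return np.ones(self.n_bins)

    @property
    def nnz(self):
        return self._nnz

    def resolutions(self):
        """Resolutions stored in the file (single-cool files report their own)."""
        with h5py.File(self.path, "r") as f:
            if "resolutions" in f:
                return sorted(int(k) for k in f["resolutions"])
        return [self.binsize]

    # ------------------------------------------------------------------ #
    # pixels

    def iter_pixels(self, chunksize=None):
        """Yield the pixel table as DataFrames of at most ``chunksize`` rows."""
        chunksize = int(chunksize or CHUNKSIZE)
        with h5py.File(self.path, "r") as f:
            px = f[self.group]["pixels"]
            for lo in range(0, self._nnz, chunksize):
                hi = min(lo + chunksize, self._nnz)
                yield pd.DataFrame(
                    {
                        "bin1_id": np.array(px["bin1_id"][lo:hi], dtype=np.int64),
                        "bin2_id": np.array(px["bin2_id"][lo:hi], dtype=np.int64),
                        "count": np.array(px["count"][lo:hi]),
                    }
                )

    def pixels(self):
        """The full pixel table as one DataFrame."""
        chunks = list(self.iter_pixels())
        if not chunks:
            return pd.DataFrame(columns=["bin1_id", "bin2_id", "count"])
        return pd.concat(chunks, ignore_index=True)

    def _symmetric(self):
        if self._sym is None:
            px = self.pixels()
            n = self.n_bins
            upper = sps.coo_matrix(
                (px["count"].to_numpy(dtype=float), (px["bin1_id"], px["bin2_id"])),
                shape=(n, n),
            ).tocsr()
            self._sym = (upper + sps.triu(upper, k=1).T).tocsr()
        return self._sym

    def dense(self, i0, i1, j0, j1, balanced=True):
        """Dense block of the symmetrized matrix over bin-id ranges.

        With ``balanced=True``, values are multiplied by the outer product
        of weights and rows/columns of bad bins become NaN.
        """
        block = np.asarray(self._symmetric()[i0:i1, j0:j1].todense(), dtype=float)
        if balanced:
            w = self.weights
            block = block * np.outer(w[i0:i1], w[j0:j1])
        return block

    def extent(self, region):
        """(first_bin_id, last_bin_id+1) of the bins overlapping a region."""
        chrom, start, end = parse_region(region, self._chroms)
        sel = np.flatnonzero(self._bins["chrom"].to_numpy() == chrom)
        if len(sel) == 0:
            raise ValueError(f"chromosome {chrom!r} not in store")
        offset = sel[0]
        starts = self._bins["start"].to_numpy()[sel]
        i0 = offset + int(np.searchsorted(starts, start, side="right") - 1)
        i0 = max(i0, offset)
        i1 = offset + int(np.searchsorted(starts, end, side="left"))
        return i0, i1

    def matrix(self, region=None, region2=None, balanced=True):
        """Dense symmetrized matrix for a region (pair); whole genome if None."""
        if region is None:
            i0, i1 = 0, self.n_bins
        else:
            i0, i1 = self.extent(region)
        if region2 is None:
            j0, j1 = i0, i1
        else:
            j0, j1 = self.extent(region2)
        return self.dense(i0, i1, j0, j1, balanced=balanced)


def open_store(uri, weight_name="weight"):
    """Open one resolution of a ``.cool``/``.mcool`` file.

    ``uri`` may carry a resolution selector, e.g. ``data.mcool::/resolutions/10000``.
    """
    path, grp = parse_uri(uri)
    if not os.path.exists(path):
        raise FileNotFoundError(path)
    return ContactStore(path, grp, weight_name=weight_name)


def _validate_pixels(pixels, n_bins):
    b1 = pixels["bin1_id"].to_numpy(dtype=np.int64)
    b2 = pixels["bin2_id"].to_numpy(dtype=np.int64)
    if len(b1) == 0:
        return
    if b1.min() < 0 or b2.max() >= n_bins:
        raise ValueError("pixel bin ids out of range")
    if np.any(b1 > b2):
        raise ValueError("pixels must be upper-triangular (bin1_id <= bin2_id)")
    key = b1 * n_bins + b2
    if np.any(np.diff(key) <= 0):
        raise ValueError("pixels must be sorted by (bin1_id, bin2_id) without duplicates")
    if np.any(np.asarray(pixels["count"]) < 0):
        raise ValueError("negative pixel counts")


def write_store(path, chroms, bins, pixels, group=None, assembly=None):
    """Write a cooler-schema v3 file (or one resolution group of an mcool).

    Parameters
    ----------
    chroms : DataFrame with columns (name, length).
    bins : DataFrame with (chrom, start, end) and optional extra float
        columns (e.g. ``weight``).
    pixels : DataFrame with (bin1_id, bin2_id, count), upper-triangular,
        sorted, duplicate-free.
    group : HDF5 group path for multi-resolution layouts, e.g.
        ``/resolutions/10000``; root group if None.
    """
    chroms = pd.DataFrame(chroms).reset_index(drop=True)
    bins = pd.DataFrame(bins).reset_index(drop=True)
    pixels = pd.DataFrame(pixels).reset_index(drop=True)
    n_bins = len(bins)
    _validate_pixels(pixels, n_bins)

    # bins must tile each chromosome in fixed steps
    binsize = int(np.median(bins["end"] - bins["start"])) if n_bins else 0
    name_to_len = dict(zip(chroms["name"], chroms["length"]))
    codes = pd.Categorical(bins["chrom"], categories=chroms["name"]).codes
    if np.any(codes < 0):
        raise ValueError("bins reference chromosomes absent from the chrom table")
    if np.any(np.diff(codes) < 0):
        raise ValueError("bins must be ordered by the chrom table")
    for cname, sub in bins.groupby("chrom", sort=False, observed=True):
        starts = sub["start"].to_numpy()
        ends = sub["end"].to_numpy()
        if not np.array_equal(starts, np.arange(len(sub)) * binsize):
            raise ValueError(f"bins do not tile {cname} in steps of {binsize}")
        clen = name_to_len[cname]
        exp_ends = np.minimum(starts + binsize, clen)
        if not np.array_equal(ends, exp_ends):
            raise ValueError(f"bin ends malformed on {cname}")

    grp_path = group or "/"
    mode = "a" if (group and os.path.exists(path)) else "w"
    with h5py.File(path, mode) as f:
        if grp_path in f and grp_path != "/":
            del f[grp_path]
        grp = f.require_group(grp_path)
        if group:
            f.attrs["format"] = "HDF5::MCOOL"
            f.attrs["format-version"] = 2
        grp.attrs["format"] = "HDF5::Cooler"
        grp.attrs["format-version"] = 3
        grp.attrs["bin-type"] = "fixed"
        grp.attrs["bin-size"] = binsize
        grp.attrs["nchroms"] = len(chroms)
        grp.attrs["nbins"] = n_bins
        grp.attrs["nnz"] = len(pixels)
        grp.attrs["sum"] = int(pixels["count"].sum()) if len(pixels) else 0
        grp.attrs["storage-mode"] = "symmetric-upper"
        grp.attrs["generated-by"] = "hicsuite"
        if assembly:
            grp.attrs["genome-assembly"] = assembly

        cg = grp.create_group("chroms")
        maxlen = max((len(s) for s in chroms["name"]), default=1)
        cg.create_dataset(
            "name", data=np.array(chroms["name"], dtype=f"S{maxlen}")
        )
        cg.create_dataset("length", data=np.asarray(chroms["length"], dtype=np.int32))

        bg = grp.create_group("bins")
        enum_dt = h5py.enum_dtype(
            {name: i for i, name in enumerate(chroms["name"])}, basetype="i4"
        )
        bg.create_dataset("chrom", data=codes.astype("i4"), dtype=enum_dt)
        bg.create_dataset("start", data=bins["start"].to_numpy(dtype=np.int64))
        bg.create_dataset("end", data=bins["end"].to_numpy(dtype=np.int64))
        for col in bins.columns:
            if col not in ("chrom", "start", "end"):
                bg.create_dataset(col, data=bins[col].to_numpy(dtype=float))

        pg = grp.create_group("pixels")
        pg.create_dataset("bin1_id", data=pixels["bin1_id"].to_numpy(dtype=np.int64))
        pg.create_dataset("bin2_id", data=pixels["bin2_id"].to_numpy(dtype=np.int64))
        pg.create_dataset("count", data=pixels["count"].to_numpy(dtype=np.int32))

        ig = grp.create_group("indexes")
        chrom_offset = np.searchsorted(codes, np.arange(len(chroms) + 1), side="left")
        ig.create_dataset("chrom_offset", data=chrom_offset.astype(np.int64))
        bin1_offset = np.searchsorted(
            pixels["bin1_id"].to_numpy(dtype=np.int64),
            np.arange(n_bins + 1),
            side="left",
        )
        ig.create_dataset("bin1_offset", data=bin1_offset.astype(np.int64))
    return path


# ---------------------------------------------------------------------- #
# genomic views

def parse_region(region, chroms):
    """Normalize a region spec to (chrom, start, end)."""
    name_to_len = dict(zip(chroms["name"], chroms["length"]))
    if isinstance(region, str):
        if ":" in region:
            chrom, span = region.split(":")
            start, end = span.replace(",", "").split("-")
            return chrom, int(start), int(end)
        if region not in name_to_len:
            raise ValueError(f"unknown chromosome {region!r}")
        return region, 0, int(name_to_len[region])
    chrom, start, end = region[0], int(region[1]), int(region[2])
    return chrom, start, end


def make_view(store, regions=None, centromeres=None):
    """Build a validated genomic view (ordered, named, non-overlapping regions).

    * ``regions=None, centromeres=None`` — one region per chromosome, named
      by chromosome, in store order.
    * ``centromeres`` — DataFrame (chrom, mid): each listed chromosome is
      split into arms named ``<chrom>_p`` / ``<chrom>_q`` at ``mid``.
    * ``regions`` — DataFrame (chrom, start, end[, name]) taken as-is.
    """
    chroms = store.chroms if isinstance(store, ContactStore) else store
    name_to_len = dict(zip(chroms["name"], chroms["length"]))
    if regions is not None:
        view = pd.DataFrame(regions).reset_index(drop=True).copy()
        if "name" not in view.columns:
            view["name"] = [
                f"{c}:{s}-{e}" for c, s, e in zip(view["chrom"], view["start"], view["end"])
            ]
    elif centromeres is not None:
        cen = dict(zip(pd.DataFrame(centromeres)["chrom"], pd.DataFrame(centromeres)["mid"]))
        rows = []
        for _, (cname, clen) in chroms.iterrows():
            if cname in cen:
                mid = int(cen[cname])
                rows.append((cname, 0, mid, f"{cname}_p"))
                rows.append((cname, mid, clen, f"{cname}_q"))
            else:
                rows.append((cname, 0, clen, cname))
        view = pd.DataFrame(rows, columns=_VIEW_COLS)
    else:
        view = pd.DataFrame(
            {
                "chrom": chroms["name"],
                "start": 0,
                "end": chroms["length"],
                "name": chroms["name"],
            }
        )
    view = view[_VIEW_COLS].copy()
    view["start"] = view["start"].astype(np.int64)
    view["end"] = view["end"].astype(np.int64)

    if view["name"].duplicated().any() or (view["name"].astype(str) == "").any():
        raise ValueError("view region names must be unique and non-empty")
    for _, row in view.iterrows():
        if row["chrom"] not in name_to_len:
            raise ValueError(f"view chromosome {row['chrom']!r} not in store")
        if not (0 <= row["start"] < row["end"] <= name_to_len[row["chrom"]]):
            raise ValueError(f"region {row['name']} out of chromosome bounds")
    for cname, sub in view.groupby("chrom", sort=False):
        sub = sub.sort_values("start")
        if np.any(sub["end"].to_numpy()[:-1] > sub["start"].to_numpy()[1:]):
            raise ValueError(f"overlapping view regions on {cname}")
    return view


def assign_bins(store, view):
    """Region index per bin (-1 = not covered); bins assigned by midpoint."""
    mids = (store.bins["start"].to_numpy() + store.bins["end"].to_numpy()) // 2
    chrom = store.bins["chrom"].to_numpy()
    rid = np.full(store.n_bins, -1, dtype=np.int64)
    for i, row in view.iterrows():
        sel = (chrom == row["chrom"]) & (mids >= row["start"]) & (mids < row["end"])
        rid[sel] = i
    return rid


# ---------------------------------------------------------------------- #
# tracks

def align_track(intervals, store, value_col="value"):
    """Project interval-valued signal (bedGraph dialect) onto store bins.

    Each bin's value is the coverage-weighted mean of overlapping interval
    values; bins with no overlap get NaN.
    """
    iv = pd.DataFrame(intervals)
    unknown = set(iv["chrom"]) - set(store.chroms["name"])
    if unknown:
        raise ValueError(f"track chromosomes not in store: {sorted(unknown)}")
    num = np.zeros(store.n_bins)
    den = np.zeros(store.n_bins)
    bins = store.bins
    chrom_arr = bins["chrom"].to_numpy()
    for cname, sub in iv.groupby("chrom", sort=False):
        sel = np.flatnonzero(chrom_arr == cname)
        if len(sel) == 0:
            continue
        offset = sel[0]
        bin_starts = bins["start"].to_numpy()[sel]
        bin_ends = bins["end"].to_numpy()[sel]
        for s, e, v in zip(sub["start"], sub["end"], sub[value_col]):
            if not np.isfinite(v):
                continue
            lo = np.searchsorted(bin_ends, s, side="right")
            hi = np.searchsorted(bin_starts, e, side="left")
            for b in range(lo, hi):
                ov = min(e, bin_ends[b]) - max(s, bin_starts[b])
                if ov > 0:
                    num[offset + b] += ov * v
                    den[offset + b] += ov
    out = bins[["chrom", "start", "end"]].copy()
    with np.errstate(invalid="ignore"):
        out[value_col] = np.where(den > 0, num / np.where(den > 0, den, 1), np.nan)
    return out


# ---------------------------------------------------------------------- #
# balancing (fixture plumbing)

def iterative_correction(
    store, max_iter=500, tol=1e-6, min_marginal_quantile=0.02
):
    """Per-bin balancing weights by symmetric Sinkhorn iteration.

    Bins with zero marginal, or marginal below ``min_marginal_quantile`` of
    the nonzero marginals, are dropped (NaN weight) before iterating. Weights
    are scaled so that the mean nonzero balanced pixel value is 1.0 — a
    fixture-grade convention; published files use various scalings.
    """
    A = store._symmetric()
    n = store.n_bins
    marg = np.asarray(A.sum(axis=1)).ravel()
    mask = marg > 0
    if mask.any():
        cutoff = np.quantile(marg[mask], min_marginal_quantile)
        mask &= marg >= cutoff
    b = np.where(mask, 1.0, 0.0)
    for _ in range(max_iter):
        m = b * np.asarray(A.dot(b)).ravel()
        mm = m[mask]
        if len(mm) == 0:
            break
        scale = mm.mean()
        r = np.where(mask, m / scale, 1.0)
        if np.max(np.abs(r[mask] - 1.0)) < tol:
            break
        b = np.where(mask, b / np.sqrt(np.where(mask, r, 1.0)), 0.0)
    px = store.pixels()
    if len(px):
        b1 = px["bin1_id"].to_numpy()
        b2 = px["bin2_id"].to_numpy()
        vals = px["count"].to_numpy(dtype=float) * b[b1] * b[b2]
        vals = vals[vals > 0]
        if len(vals):
            b = b / np.sqrt(vals.mean())
    weights = np.where(mask, b, np.nan)
    return weights
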