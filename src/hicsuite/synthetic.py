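"""Synthetic contact-map generator with known ground truth.

Emulates the canonical features of a balanced interphase contact map —
power-law distance decay within chromosomes, flat inter-chromosomal
background, a checkerboard compartment pattern, insulating domain
boundaries, focal dot enrichments, unmappable (bad) bins, and Poisson
sampling at a chosen sequencing depth — and writes the result as a
cooler-schema file together with the truth tables needed for
parameter-recovery tests.

The expected intensity of a bin pair (i, j) is

    M_ij = base * s^alpha                     (cis; s = max(|i-j|, 1) bins)
         = trans_level                        (trans)
    M_ij *= 1 + A * v_i * v_j                 (compartments, v in {-1,+1})
    M_ij *= depletion^-(boundaries crossed)   (domains, cis only)
    M_ij *= 1 + (enr - 1) * G(di, dj)         (dots; Gaussian spot)

and counts are Poisson with rate depth * M / sum(M) over the upper
triangle. Balancing weights are fitted to the sampled map with the io
module's iterative correction, so fixtures carry realistic weights.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import ContactStore, iterative_correction, write_store

__all__ = ["MapRecipe", "generate_map", "block_vector"]


def block_vector(n_bins, block=30, rng=None):
    """Alternating +/-1 block pattern of the given block size."""
    v = np.ones(n_bins)
    idx = (np.arange(n_bins) // block) % 2
    v[idx == 1] = -1
    return v


@dataclass
class MapRecipe:
    """Ground-truth description of one synthetic map.

    Defaults give a 2-chromosome, 300-bins-per-chromosome map at 10 kb —
    small enough for dense oracles, deep enough for detection statistics.
    Structural features (compartments, domains, dots) are off unless set.
    """

    chromlens: tuple = (3_000_000, 3_000_000)
    binsize: int = 10_000
    alpha: float = -1.0
    cis_base: float = 1.0
    trans_level: float = 0.005
    compartment_strength: float = 0.0
    compartment_block_bins: int = 30
    compartment_vector: np.ndarray | None = None
    boundaries: dict = field(default_factory=dict)  # {chrom name: [bin, ...]}
    domain_depletion: float = 1.0
    dots: list = field(default_factory=list)  # [(chrom, bin1, bin2, enrichment), ...]
    dot_halfwidth: int = 1
    dot_sigma: float = 0.6
    bad_bin_frac: float = 0.02
    depth: float = 1e6
    seed: int = 0

    def chrom_names(self):
        return [f"chr{i + 1}" for i in range(len(self.chromlens))]


def _intensity(recipe, bins, cid):
    n = len(bins)
    pos = np.zeros(n, dtype=np.int64)
    for c in np.unique(cid):
        sel = cid == c
        pos[sel] = np.arange(sel.sum())

    same = cid[:, None] == cid[None, :]
    d = np.abs(pos[:, None] - pos[None, :])
    s = np.maximum(d, 1).astype(float)
    M = np.where(same, recipe.cis_base * s**recipe.alpha, recipe.trans_level)

    if recipe.compartment_vector is not None:
        v = np.asarray(recipe.compartment_vector, dtype=float)
    else:
        v = block_vector(n, recipe.compartment_block_bins)
    if recipe.compartment_strength:
        A = recipe.compartment_strength
        M = M * (1.0 + A * np.outer(v, v))

    names = recipe.chrom_names()
    if recipe.boundaries and recipe.domain_depletion > 1:
        nb = np.zeros(n)  # boundaries upstream of each bin, per chromosome
        for c, cname in enumerate(names):
            blist = sorted(recipe.boundaries.get(cname, []))
            sel = cid == c
            nb[sel] = np.searchsorted(blist, pos[sel], side="right")
        crossed = np.abs(nb[:, None] - nb[None, :])
        M = M * np.where(same, recipe.domain_depletion**-crossed, 1.0)

    if recipe.dots:
        h = recipe.dot_halfwidth
        sig = recipe.dot_sigma
        off = np.arange(-h, h + 1)
        gi, gj = np.meshgrid(off, off, indexing="ij")
        G = np.exp(-(gi**2 + gj**2) / (2 * sig**2))
        chrom_offset = np.concatenate([[0], np.cumsum(np.bincount(cid))])
        for cname, b1, b2, enr in recipe.dots:
            c = names.index(cname)
            i = chrom_offset[c] + b1
            j = chrom_offset[c] + b2
            r0, r1 = max(i - h, 0), min(i + h + 1, n)
            c0, c1 = max(j - h, 0), min(j + h + 1, n)
            spot = 1.0 + (enr - 1.0) * G[r0 - (i - h) : r1 - (i - h), c0 - (j - h) : c1 - (j - h)]
            M[r0:r1, c0:c1] *= spot
            M[c0:c1, r0:r1] *= spot.T
    if not np.all(M > 0):
        raise ValueError("recipe produces non-positive expected intensities")
    return M, v


def generate_map(recipe, path):
    """Sample a map from a recipe, write it as a .cool, return (store, truth).

    ``truth`` holds the planted compartment vector, bad-bin mask, boundary
    and dot tables (in bin and bp coordinates), and the decay exponent.
    """
    rng = np.random.default_rng(recipe.seed)
    names = recipe.chrom_names()
    chroms = pd.DataFrame({"name": names, "length": list(recipe.chromlens)})
    rows = []
    for cname, clen in zip(names, recipe.chromlens):
        starts = np.arange(0, clen, recipe.binsize)
        rows.append(
            pd.DataFrame(
                {"chrom": cname, "start": starts, "end": np.minimum(starts + recipe.binsize, clen)}
            )
        )
    bins = pd.concat(rows, ignore_index=True)
    n = len(bins)
    cid = pd.Categorical(bins["chrom"], categories=names).codes.astype(np.int64)

    M, v = _intensity(recipe, bins, cid)
    iu, ju = np.triu_indices(n)
    rates = M[iu, ju]
    rates = rates / rates.sum()
    if recipe.depth > 0:
        counts = rng.poisson(recipe.depth * rates)
    else:
        counts = np.zeros(len(rates), dtype=np.int64)

    bad = np.zeros(n, dtype=bool)
    if recipe.bad_bin_frac > 0:
        # dot anchor bins are never masked: a dot zeroed by a bad bin would
        # no longer exist in the map, making the truth table wrong
        chrom_offset = np.concatenate([[0], np.cumsum(np.bincount(cid))])
        names = recipe.chrom_names()
        anchors = {
            int(chrom_offset[names.index(c)] + b)
            for c, b1, b2, _ in recipe.dots
            for b in (b1, b2)
        }
        eligible = np.array([i for i in range(n) if i not in anchors])
        k = min(int(round(recipe.bad_bin_frac * n)), len(eligible))
        bad[rng.choice(eligible, size=k, replace=False)] = True
        counts[bad[iu] | bad[ju]] = 0

    keep = counts > 0
    pixels = pd.DataFrame(
        {"bin1_id": iu[keep], "bin2_id": ju[keep], "count": counts[keep]}
    )
    write_store(path, chroms, bins, pixels)
    store = ContactStore(path)
    # the generator knows its bad bins exactly (their pixels are zeroed), so
    # fixture weights are fitted on every bin with signal; the marginal
    # quantile filter exists for real data where bad bins must be guessed
    weights = iterative_correction(store, min_marginal_quantile=0.0)
    bins_w = bins.copy()
    bins_w["weight"] = weights
    write_store(path, chroms, bins_w, pixels)
    store = ContactStore(path)

    chrom_offset = np.concatenate([[0], np.cumsum(np.bincount(cid, minlength=len(names)))])
    boundary_rows = []
    for c, cname in enumerate(names):
        for b in recipe.boundaries.get(cname, []):
            boundary_rows.append(
                (cname, b, int(chrom_offset[c] + b), b * recipe.binsize)
            )
    dot_rows = []
    for cname, b1, b2, enr in recipe.dots:
        c = names.index(cname)
        dot_rows.append(
            (
                cname,
                b1,
                b2,
                int(chrom_offset[c] + b1),
                int(chrom_offset[c] + b2),
                b1 * recipe.binsize,
                b2 * recipe.binsize,
                enr,
            )
        )
    truth = {
        "compartment_vector": v,
        "bad_bins": bad,
        "alpha": recipe.alpha,
        "boundaries": pd.DataFrame(
            boundary_rows, columns=["chrom", "bin", "bin_id", "start"]
        ),
        "dots": pd.DataFrame(
            dot_rows,
            columns=["chrom", "bin1", "bin2", "bin1_id", "bin2_id", "start1", "start2", "enrichment"],
        ),
    }
    return store, truth
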