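# hicsuite

An analysis toolkit for binned chromosome-conformation (Hi-C / Micro-C)
contact maps stored in the cooler HDF5 schema, for computational biologists
who quantify genome folding: distance decay, A/B compartments, TAD
insulation, chromatin loops, and aggregate maps — plus a ground-truth
synthetic map generator so every method ships with parameter-recovery
tests.

## What it computes

A balanced contact map assigns each bin pair (i, j) a normalized contact
frequency `B_ij = c_ij · w_i · w_j`, where `c_ij` is the raw ligation count
and `w_i` are per-bin balancing weights (missing weight = filtered bin).
On top of this sparse upper-triangular pixel table, hicsuite provides:

- **expected** — the contact-probability curve *P(s)*: the mean balanced
  value at each genomic separation *s* within a region, with exact
  accounting of masked bins, Gaussian smoothing in log₁₀ *s*, the
  log-derivative d log *P* / d log *s*, and region-pair trans averages.
- **eigdecomp** — compartment profiles as the leading eigenvectors of the
  distance-normalized map: in cis, each diagonal of the balanced matrix is
  divided by its mean (O/E), centered, and eigendecomposed per region; in
  trans, cis blocks are masked with sampled trans values first. Vectors are
  oriented and optionally ranked by correlation with a phasing track (e.g.
  GC content).
- **saddle** — contact preferences between bin classes: a track is
  digitized into quantile classes and mean O/E is averaged over every class
  pair, giving the saddle matrix S and a corner-ratio strength summary.
- **insulation** — the diamond-window insulation score
  `log2(raw_i / mean)` where `raw_i` averages balanced values over pairs
  (a, b) with `i−w ≤ a ≤ i < b ≤ i+w`; boundaries are local minima scored
  by topographic prominence and thresholded with Li/Otsu.
- **dots** — HiCCUPS-style loop calling: convolution kernels (donut,
  vertical, horizontal, lowerleft) estimate a local expected count
  `λ_k = f_k · E(s) / (w_i w_j)` per pixel, significance is a Poisson
  upper-tail test under a lambda-chunked Benjamini–Hochberg FDR, and
  significant pixels are clustered and enrichment-filtered.
- **snipping** — fixed-size windows around anchors or anchor pairs,
  observed or O/E, averaged into pileups (APA).
- **mapops** — cis/total coverage, seeded binomial downsampling, and
  mass-conserving adaptive multiscale smoothing.
- **synthetic** — seeded generator of cooler-schema fixtures with planted
  power-law decay, checkerboard compartments, insulating domains, focal
  dots, bad bins, and Poisson sampling depth, returned with truth tables.

Every operation has a paired CLI subcommand (`hicsuite expected-cis`,
`eigs-cis`, `eigs-trans`, `saddle`, `insulation`, `dots`, `pileup`,
`coverage`, `random-sample`, `adaptive-smooth`, `make-fixture`) whose
output is byte-identical to the API call serialized the same way.

## Worked example

```python
import numpy as np
from hicsuite.synthetic import MapRecipe, generate_map
from hicsuite import expected, insulation, eigdecomp, saddle

# a 2 x 3 Mb genome at 10 kb with P(s) ~ s^-1 and a +/-1 checkerboard
store, truth = generate_map(
    MapRecipe(compartment_strength=0.3, depth=1e6, seed=0), "comp.cool")

exp = expected.expected_cis(store)
sub = exp[(exp.region1 == "chr1") & exp.dist.between(10, 100)]
slope = np.polyfit(np.log10(sub.dist), np.log10(sub.balanced_avg_smoothed), 1)[0]
print(f"P(s) log-log slope over 100 kb - 1 Mb: {slope:.3f}")

track = store.bins[["chrom", "start", "end"]].copy()
track["value"] = truth["compartment_vector"]
eig = eigdecomp.eigs_cis(store, phasing_track=track)
e1 = eig.eigvecs["E1"].to_numpy()
ok = np.isfinite(e1)
print(f"E1 sign agreement with planted compartments: "
      f"{100 * np.mean(np.sign(e1[ok]) == truth['compartment_vector'][ok]):.1f}%")

dig, _ = saddle.digitize_track(track, mode="value")
S = saddle.saddle_aggregate(store, exp, dig)
print(f"saddle strength (extent 1): {saddle.saddle_strength(S):.2f}")

# a second map with insulating boundaries at 4x depletion
store2, _ = generate_map(
    MapRecipe(boundaries={"chr1": [100, 200], "chr2": [150]},
              domain_depletion=4.0, depth=2e6, seed=0), "dom.cool")
ins = insulation.insulation_profile(store2, window_bp=(100_000,))
ins = insulation.threshold_boundaries(insulation.find_boundaries(ins), "otsu")
print(ins[ins.is_strong_otsu][["chrom", "start", "end", "prominence"]]
      .to_string(index=False))
```

prints

```
P(s) log-log slope over 100 kb - 1 Mb: -0.951
E1 sign agreement with planted compartments: 100.0%
saddle strength (extent 1): 1.76
chrom   start     end  prominence
 chr1  990000 1000000    1.953489
 chr1 1990000 2000000    1.771666
 chr2 1490000 1500000    1.784294
```

The recovered slope matches the planted exponent −1 within the sampling
noise of 10⁶ contacts; the leading eigenvector reproduces the planted
compartment assignment exactly; the saddle corners are enriched ~1.8-fold
over the anti-diagonal; and the three strong insulation minima sit one bin
upstream of the planted boundary coordinates (the deepest diamond for a
boundary between bins b−1 and b is centered at b−1).

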