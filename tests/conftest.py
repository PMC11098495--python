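import numpy as np
import pandas as pd
import pytest

from hicsuite.io import ContactStore, write_store
from hicsuite.synthetic import MapRecipe, generate_map


def make_store(path, n_bins=20, binsize=10_000, chroms=("chr1",), counts=None,
               weights=None, diag_value=1):
    """Hand-built store: dense integer counts (default all-ones upper triangle)."""
    n_chroms = len(chroms)
    per = n_bins // n_chroms
    chrom_df = pd.DataFrame({"name": list(chroms), "length": [per * binsize] * n_chroms})
    rows = []
    for c in chroms:
        starts = np.arange(per) * binsize
        rows.append(pd.DataFrame({"chrom": c, "start": starts, "end": starts + binsize}))
    bins = pd.concat(rows, ignore_index=True)
    if weights is not None:
        bins["weight"] = weights
    if counts is None:
        counts = np.full((n_bins, n_bins), 1, dtype=int)
        np.fill_diagonal(counts, diag_value)
    iu, ju = np.triu_indices(n_bins)
    c = np.asarray(counts)[iu, ju]
    keep = c > 0
    pixels = pd.DataFrame({"bin1_id": iu[keep], "bin2_id": ju[keep], "count": c[keep]})
    write_store(str(path), chrom_df, bins, pixels)
    return ContactStore(str(path))


def dense_from_store(store, balanced=True):
    return store.dense(0, store.n_bins, 0, store.n_bins, balanced=balanced)


def random_dot_list(rng, chrom, n, lo=10, hi=280, dmin=5, dmax=40, limit=290):
    out, placed = [], set()
    while len(out) < n:
        b1 = int(rng.integers(lo, hi))
        b2 = b1 + int(rng.integers(dmin, dmax + 1))
        if b2 >= limit or any(abs(b1 - p1) <= 3 and abs(b2 - p2) <= 3 for p1, p2 in placed):
            continue
        placed.add((b1, b2))
        out.append((chrom, b1, b2, float(rng.uniform(3, 5))))
    return out


@pytest.fixture(scope="session")
def fixture_dir(tmp_path_factory):
    return tmp_path_factory.mktemp("maps")


@pytest.fixture(scope="session")
def compartment_map(fixture_dir):
    """Checkerboard map: A=0.3, depth 1e6, 2 x 300 bins at 10 kb."""
    recipe = MapRecipe(compartment_strength=0.3, depth=1e6, seed=11)
    store, truth = generate_map(recipe, str(fixture_dir / "compartment.cool"))
    return store, truth


@pytest.fixture(scope="session")
def domain_map(fixture_dir):
    """Map with 7 insulating boundaries at 4x depletion."""
    recipe = MapRecipe(
        boundaries={"chr1": [60, 120, 180, 240], "chr2": [50, 150, 250]},
        domain_depletion=4,
        depth=2e6,
        seed=12,
    )
    store, truth = generate_map(recipe, str(fixture_dir / "domains.cool"))
    return store, truth


@pytest.fixture(scope="session")
def dots_map(fixture_dir):
    """Map with 50 planted dots (3-5x) at depth 1e6."""
    rng = np.random.default_rng(13)
    dots = random_dot_list(rng, "chr1", 25) + random_dot_list(rng, "chr2", 25)
    recipe = MapRecipe(dots=dots, depth=1e6, seed=13)
    store, truth = generate_map(recipe, str(fixture_dir / "dots.cool"))
    return store, truth


@pytest.fixture(scope="session")
def plain_map(fixture_dir):
    """Featureless power-law map (alpha=-1), used by many structural tests."""
    recipe = MapRecipe(depth=1e6, seed=14)
    store, truth = generate_map(recipe, str(fixture_dir / "plain.cool"))
    return store, truth


@pytest.fixture()
def uniform_store(tmp_path):
    """30-bin single-chromosome map whose balanced matrix is all ones."""
    return make_store(tmp_path / "uniform.cool", n_bins=30, weights=np.ones(30))
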