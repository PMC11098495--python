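"""Shared table serialization for the CLI and tests."""

from __future__ import annotations

import numpy as np
import pandas as pd


def format_params(params):
    return " ".join(f"{k}={v}" for k, v in sorted(params.items()))


def write_table(df, path, command=None, params=None, version=None):
    """Headered TSV with a leading comment line recording provenance.

    The comment records the tool version, the subcommand, and its full
    parameterization, so every output file documents how to regenerate it.
    """
    from . import __version__

    with open(path, "w") as fh:
        meta = f"# hicsuite v{version or __version__}"
        if command:
            meta += f" {command}"
        if params:
            meta += " " + format_params(params)
        fh.write(meta + "\n")
        df.to_csv(fh, sep="\t", index=False, na_rep="nan", float_format="%.9g")
    return path


def read_table(path):
    return pd.read_csv(path, sep="\t", comment="#", na_values=["nan"])


def read_bed(path, paired=False):
    """Headerless BED (chrom,start,end[,name]) or BEDPE (6-col) TSV.

    Files whose first line starts with 'chrom' are read as headered TSV.
    """
    with open(path) as fh:
        first = fh.readline()
    if first.lower().lstrip("#").startswith("chrom"):
        return pd.read_csv(path, sep="\t")
    ncols = len(first.rstrip("\n").split("\t"))
    if paired:
        names = ["chrom1", "start1", "end1", "chrom2", "start2", "end2"][:ncols]
    else:
        names = ["chrom", "start", "end", "name", "value"][:ncols]
    return pd.read_csv(path, sep="\t", header=None, names=names)


def read_bedgraph(path, value_col="value"):
    df = pd.read_csv(
        path,
        sep="\t",
        comment="#",
        header=None,
        names=["chrom", "start", "end", value_col],
    )
    return df
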