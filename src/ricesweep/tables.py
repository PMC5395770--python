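"""Bundled reference inventories of domesticated regions.

The package ships the published genome-wide inventory of 28 DR-I and 28
DR-II blocks detected in 355 resequenced rice accessions (296 cultivars,
39 wild, 20 outgroup), transcribed from the printed per-block tables.
Diversity and divergence columns are stored as printed, in units of
1e-5 per bp; loaders convert to per-bp rates. These inventories are used
as worked-example inputs: summary statistics recomputed from them can be
compared against the published summary figures.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .scan import DRBlock, summarize_blocks

_SCALE = 1e-5


def _load(name: str) -> pd.DataFrame:
    ref = resources.files("ricesweep.data").joinpath(name)
    with ref.open() as fh:
        df = pd.read_csv(fh, sep="\t", comment="#")
    for c in df.columns:
        if c.startswith(("pi_", "dxy_")):
            df[c] = df[c] * _SCALE
    df["length"] = df["end"] - df["start"] + 1
    return df


def load_dr1_inventory() -> pd.DataFrame:
    """28 DR-I blocks: coordinates, relaxed flag, per-group pi and Dxy."""
    return _load("dr1_inventory.tsv")


def load_dr2_inventory() -> pd.DataFrame:
    """28 DR-II blocks, including pooled-cultivar and wild pi."""
    return _load("dr2_inventory.tsv")


def inventory_blocks(df: pd.DataFrame, type_: str) -> list[DRBlock]:
    """Convert an inventory frame to DRBlock objects (stats = row values)."""
    out = []
    for _, r in df.iterrows():
        stats = {c: float(r[c]) for c in df.columns
                 if c.startswith(("pi_", "dxy_"))}
        out.append(DRBlock(type=type_, chrom=r["chrom"], start=int(r["start"]),
                           end=int(r["end"]), relaxed=bool(r["relaxed"]),
                           stats=stats))
    return out


def inventory_summary() -> pd.DataFrame:
    """Summary of both bundled inventories via :func:`summarize_blocks`."""
    blocks = (inventory_blocks(load_dr1_inventory(), "DR-I")
              + inventory_blocks(load_dr2_inventory(), "DR-II"))
    return summarize_blocks(blocks)


def wild_cultivar_ratio(df: pd.DataFrame | None = None) -> float:
    """Mean over DR-II blocks of the wild/pooled-cultivar diversity ratio."""
    if df is None:
        df = load_dr2_inventory()
    return float(np.mean(df["pi_wild"] / df["pi_cul"]))
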