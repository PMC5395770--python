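import warnings

import numpy as np
import pandas as pd
import pytest

from ricesweep.io import (MISSING, GenotypeMatrix, SampleTable, filter_snps,
                          read_vcf)
from ricesweep.simulate import SimParams, simulate


def make_sample_table(n_jap=0, n_ind=0, n_wild=0, n_out=0):
    rows = []
    for i in range(n_jap):
        rows.append((f"J{i + 1:02d}", "japonica",
                     "temperate" if i % 2 == 0 else "tropical"))
    for i in range(n_ind):
        rows.append((f"I{i + 1:02d}", "indica", "none"))
    for i in range(n_wild):
        rows.append((f"W{i + 1:02d}", "wild", "none"))
    for i in range(n_out):
        rows.append((f"O{i + 1:02d}", "outgroup", "none"))
    return SampleTable(pd.DataFrame(
        rows, columns=["sample_id", "group", "subgroup"]))


def make_gm(codes, pos=None, chrom="chr01", samples=None, qual=None,
            depth=None, ref=None, alt=None):
    """Small GenotypeMatrix from a (sites x samples) array of codes."""
    codes = np.asarray(codes, dtype=np.int8)
    S, N = codes.shape
    if pos is None:
        pos = np.arange(1, S + 1)
    if samples is None:
        samples = make_sample_table(n_jap=N)
    if isinstance(chrom, str):
        chrom = np.full(S, chrom, dtype="U32")
    return GenotypeMatrix(
        chrom=np.asarray(chrom, dtype="U32"),
        pos=np.asarray(pos, dtype=np.int64),
        ref=np.asarray(ref if ref is not None else ["A"] * S, dtype="U8"),
        alt=list(alt) if alt is not None else [("G",)] * S,
        qual=np.asarray(qual if qual is not None else [100.0] * S,
                        dtype=float),
        codes=codes,
        depth=(np.asarray(depth, dtype=np.int32) if depth is not None
               else np.full((S, N), 10, dtype=np.int32)),
        samples=samples)


SMALL_PARAMS = dict(
    chrom_lengths={"chr01": 400_000, "chr02": 400_000},
    n_jap=20, n_ind=20, n_wild=10, n_outgroup=2,
    dr1_regions=[("chr01", 100_001, 130_000)],
    dr2_regions=[("chr02", 200_001, 230_000)],
    n_genes_per_dr1=2, n_genes_background=4)


@pytest.fixture(scope="session")
def sim_small(tmp_path_factory):
    """A small simulated dataset shared across tests (seed 11)."""
    out = tmp_path_factory.mktemp("sim_small")
    params = SimParams(seed=11, **SMALL_PARAMS)
    res = simulate(params, out)
    return params, res


@pytest.fixture(scope="session")
def gm_small(sim_small):
    """The small dataset read and filtered, with its sample table."""
    params, res = sim_small
    st = SampleTable.from_tsv(res.sample_path)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = read_vcf(res.vcf_path, st)
    gmf, report = filter_snps(gm)
    return params, res, st, gm, gmf
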