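"""Input/output: VCF, sample tables, masks, block BED files.

The in-memory substrate of the whole pipeline is :class:`GenotypeMatrix`, a
sites x samples integer allele-code matrix. Cultivated rice is highly inbred,
so diploid genotypes are collapsed to a single allele code per call;
heterozygous calls are treated as missing by default (see
:func:`read_vcf`). All genomic coordinates are held 1-based inclusive
internally; BED files on disk follow the 0-based half-open convention.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

MISSING = -1

GROUPS = ("japonica", "indica", "wild", "outgroup")
SUBGROUPS = ("temperate", "tropical", "none")


class SampleTable:
    """Assignment of samples to analysis groups.

    Wraps a DataFrame with columns ``sample_id``, ``group``
    (japonica/indica/wild/outgroup), ``subgroup`` (temperate/tropical/none)
    and free-text ``origin``. The pseudo-group ``cultivar`` denotes the union
    of *japonica* and *indica*.
    """

    def __init__(self, df: pd.DataFrame):
        df = df.copy()
        if "subgroup" not in df.columns:
            df["subgroup"] = "none"
        if "origin" not in df.columns:
            df["origin"] = ""
        df["subgroup"] = df["subgroup"].fillna("none")
        if df["sample_id"].duplicated().any():
            dup = df.loc[df["sample_id"].duplicated(), "sample_id"].iloc[0]
            raise ValueError(f"duplicate sample_id: {dup!r}")
        bad = set(df["group"]) - set(GROUPS)
        if bad:
            raise ValueError(f"unknown group(s): {sorted(bad)}")
        bad = set(df["subgroup"]) - set(SUBGROUPS)
        if bad:
            raise ValueError(f"unknown subgroup(s): {sorted(bad)}")
        self.df = df.reset_index(drop=True)

    @classmethod
    def from_tsv(cls, path) -> "SampleTable":
        return cls(pd.read_csv(path, sep="\t", dtype=str))

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.df["sample_id"])

    def __len__(self) -> int:
        return len(self.df)

    def indices(self, group: str) -> np.ndarray:
        """Column indices of `group`; 'cultivar' means japonica+indica,
        'temperate'/'tropical' select japonica subgroups."""
        df = self.df
        if group == "cultivar":
            m = df["group"].isin(["japonica", "indica"])
        elif group in ("temperate", "tropical"):
            m = (df["group"] == "japonica") & (df["subgroup"] == group)
        else:
            m = df["group"] == group
        return np.flatnonzero(m.to_numpy())

    def ids(self, group: str) -> list[str]:
        return [self.df["sample_id"].iloc[i] for i in self.indices(group)]


@dataclass
class GenotypeMatrix:
    """Biallelic-or-multiallelic SNP matrix with collapsed allele codes.

    ``codes[i, j]`` is the allele index (0=REF, 1..=ALT order) of sample j at
    site i, or MISSING (-1). Positions are 1-based and strictly increasing
    within each chromosome.
    """

    chrom: np.ndarray          # (S,) unicode
    pos: np.ndarray            # (S,) int64, 1-based
    ref: np.ndarray            # (S,) unicode
    alt: list[tuple[str, ...]]  # per-site ALT allele tuple
    qual: np.ndarray           # (S,) float
    codes: np.ndarray          # (S, N) int8
    depth: np.ndarray          # (S, N) int32
    samples: SampleTable

    def __post_init__(self):
        for c in np.unique(self.chrom):
            p = self.pos[self.chrom == c]
            if len(p) > 1 and not np.all(np.diff(p) > 0):
                k = int(np.flatnonzero(np.diff(p) <= 0)[0])
                raise ValueError(
                    f"positions not strictly increasing on {c} near {p[k + 1]}")

    @property
    def n_sites(self) -> int:
        return len(self.pos)

    @property
    def n_samples(self) -> int:
        return self.codes.shape[1]

    def take_sites(self, idx) -> "GenotypeMatrix":
        idx = np.asarray(idx)
        return GenotypeMatrix(
            chrom=self.chrom[idx], pos=self.pos[idx], ref=self.ref[idx],
            alt=[self.alt[i] for i in idx.tolist()] if idx.dtype != bool
            else [a for a, k in zip(self.alt, idx) if k],
            qual=self.qual[idx], codes=self.codes[idx],
            depth=self.depth[idx], samples=self.samples)

    def sites_in(self, chrom: str, start: int, end: int) -> np.ndarray:
        """Boolean mask of sites within [start, end] (1-based inclusive)."""
        return (self.chrom == chrom) & (self.pos >= start) & (self.pos <= end)


@dataclass
class FilterReport:
    n_input: int = 0
    n_low_qual: int = 0
    n_calls_low_depth: int = 0
    n_low_maf: int = 0
    n_retained: int = 0

    def to_dict(self):
        return dict(self.__dict__)


class MaskSet:
    """Excluded intervals, 1-based inclusive, unioned per chromosome."""

    def __init__(self, intervals: Iterable[tuple[str, int, int]] = ()):
        per: dict[str, list[tuple[int, int]]] = {}
        for c, s, e in intervals:
            if e < s:
                raise ValueError(f"mask interval end < start: {c}:{s}-{e}")
            per.setdefault(c, []).append((int(s), int(e)))
        self.intervals: dict[str, list[tuple[int, int]]] = {}
        for c, ivs in per.items():
            ivs.sort()
            merged = [list(ivs[0])]
            for s, e in ivs[1:]:
                if s <= merged[-1][1] + 1:
                    merged[-1][1] = max(merged[-1][1], e)
                else:
                    merged.append([s, e])
            self.intervals[c] = [(s, e) for s, e in merged]

    @classmethod
    def from_bed(cls, path) -> "MaskSet":
        ivs = []
        with open(path) as fh:
            for line in fh:
                line = line.strip()
                if not line or line.startswith(("#", "track")):
                    continue
                f = line.split("\t")
                ivs.append((f[0], int(f[1]) + 1, int(f[2])))
        return cls(ivs)

    def contains(self, chrom: np.ndarray, pos: np.ndarray) -> np.ndarray:
        out = np.zeros(len(pos), dtype=bool)
        for c, ivs in self.intervals.items():
            on = chrom == c
            if not on.any():
                continue
            p = pos[on]
            hit = np.zeros(len(p), dtype=bool)
            for s, e in ivs:
                hit |= (p >= s) & (p <= e)
            out[on] = hit
        return out

    def masked_bp(self, chrom: str, start: int, end: int) -> int:
        """Masked base pairs overlapping [start, end] (1-based inclusive)."""
        total = 0
        for s, e in self.intervals.get(chrom, ()):
            lo, hi = max(s, start), min(e, end)
            if hi >= lo:
                total += hi - lo + 1
        return total

    def __len__(self) -> int:
        return sum(len(v) for v in self.intervals.values())


def read_vcf(path, samples: SampleTable, het_policy: str = "missing",
             seed: int | None = None) -> GenotypeMatrix:
    """Read a coordinate-sorted VCF into a GenotypeMatrix.

    Diploid GT fields are collapsed to one allele code per call: homozygous
    calls keep their allele, heterozygous calls become MISSING under the
    default policy ('missing') or a random one of the two alleles under
    'random'. Depth comes from the per-sample DP field; absent DP is
    treated as depth 0.
    """
    from cyvcf2 import VCF

    if het_policy not in ("missing", "random"):
        raise ValueError(f"unknown het_policy {het_policy!r}")
    rng = np.random.default_rng(seed)
    vcf = VCF(str(path), gts012=False)
    header_samples = list(vcf.samples)
    missing = [s for s in samples.sample_ids if s not in header_samples]
    if missing:
        raise ValueError(f"sample(s) not in VCF header: {missing}")
    vcf.set_samples(samples.sample_ids)
    order = [vcf.samples.index(s) for s in samples.sample_ids]

    chroms, poss, refs, alts, quals = [], [], [], [], []
    code_rows, depth_rows = [], []
    n_het_collapsed = 0
    last: dict[str, int] = {}
    for v in vcf:
        if v.CHROM in last and v.POS <= last[v.CHROM]:
            raise ValueError(
                f"VCF not coordinate-sorted at {v.CHROM}:{v.POS}")
        last[v.CHROM] = v.POS
        gt = np.array(v.genotype.array(), dtype=np.int32)[:, :2]
        gt = gt[order]
        a, b = gt[:, 0], gt[:, 1]
        code = np.where((a == b) & (a >= 0), a, MISSING).astype(np.int8)
        het = (a >= 0) & (b >= 0) & (a != b)
        if het.any():
            if het_policy == "missing":
                n_het_collapsed += int(het.sum())
            else:
                pick = rng.integers(0, 2, size=int(het.sum()))
                code[het] = np.where(pick == 0, a[het], b[het]).astype(np.int8)
        try:
            dp = v.format("DP")
            dp = np.asarray(dp, dtype=np.int32).reshape(-1)[order]
            dp = np.where(dp < 0, 0, dp)
        except (KeyError, TypeError):
            dp = np.zeros(len(order), dtype=np.int32)
        chroms.append(v.CHROM)
        poss.append(v.POS)
        refs.append(v.REF)
        alts.append(tuple(v.ALT))
        quals.append(v.QUAL if v.QUAL is not None else np.nan)
        code_rows.append(code)
        depth_rows.append(dp)
    n = len(samples)
    gm = GenotypeMatrix(
        chrom=np.array(chroms, dtype="U32"),
        pos=np.array(poss, dtype=np.int64),
        ref=np.array(refs, dtype="U8") if refs else np.empty(0, dtype="U8"),
        alt=alts,
        qual=np.array(quals, dtype=float),
        codes=(np.vstack(code_rows) if code_rows
               else np.empty((0, n), dtype=np.int8)),
        depth=(np.vstack(depth_rows) if depth_rows
               else np.empty((0, n), dtype=np.int32)),
        samples=samples)
    if n_het_collapsed:
        tot = max(gm.n_sites * n, 1)
        warnings.warn(
            f"collapsed {n_het_collapsed} heterozygous calls to missing "
            f"({100 * n_het_collapsed / tot:.3f}% of calls)")
    return gm


def filter_snps(gm: GenotypeMatrix, min_qual: float = 50,
                min_depth: int = 3, min_maf: float = 0.05,
                ) -> tuple[GenotypeMatrix, FilterReport]:
    """Site-quality, per-call depth and minor-allele-frequency filters.

    Boundary semantics are strict exclusions: qual < min_qual removed,
    depth < min_depth set missing, MAF < min_maf removed; equality is
    retained. MAF is computed over non-missing allele copies after the
    depth filter.
    """
    if min_qual < 0 or min_depth < 0 or min_maf < 0:
        raise ValueError("thresholds must be non-negative")
    rep = FilterReport(n_input=gm.n_sites)
    keep_q = ~(gm.qual < min_qual)   # NaN qual retained
    rep.n_low_qual = int((~keep_q).sum())
    gm = gm.take_sites(np.flatnonzero(keep_q))

    low_dp = (gm.depth < min_depth) & (gm.codes != MISSING)
    rep.n_calls_low_depth = int(low_dp.sum())
    codes = gm.codes.copy()
    codes[low_dp] = MISSING
    gm = GenotypeMatrix(gm.chrom, gm.pos, gm.ref, gm.alt, gm.qual,
                        codes, gm.depth, gm.samples)

    maf = _site_maf(gm.codes)
    keep_m = ~(maf < min_maf)
    rep.n_low_maf = int((~keep_m).sum())
    gm = gm.take_sites(np.flatnonzero(keep_m))
    rep.n_retained = gm.n_sites
    return gm, rep


def _site_maf(codes: np.ndarray) -> np.ndarray:
    """Minor-allele frequency per site over non-missing allele copies.

    For multiallelic sites: 1 - max allele frequency would understate the
    'minor' notion; we use the standard 1 - freq(major allele).
    """
    S = codes.shape[0]
    if S == 0:
        return np.empty(0)
    amax = int(codes.max(initial=0))
    counts = np.zeros((S, amax + 1), dtype=np.int64)
    for a in range(amax + 1):
        counts[:, a] = (codes == a).sum(axis=1)
    total = counts.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        maf = 1.0 - counts.max(axis=1) / total
    maf[total == 0] = 0.0
    return maf


def apply_mask(gm: GenotypeMatrix, mask: MaskSet) -> GenotypeMatrix:
    """Drop sites inside masked intervals."""
    hit = mask.contains(gm.chrom, gm.pos) if len(mask) else np.zeros(
        gm.n_sites, dtype=bool)
    return gm.take_sites(np.flatnonzero(~hit))


# --- DR block BED round-trip -------------------------------------------------

def write_blocks(blocks, path) -> None:
    """Write DR blocks as BED: 0-based half-open, name=type, score=relaxed."""
    blocks = list(blocks)
    order = sorted(range(len(blocks)),
                   key=lambda i: (blocks[i].chrom, blocks[i].start))
    if order != list(range(len(blocks))):
        warnings.warn("blocks were not sorted; sorting on write")
        blocks = [blocks[i] for i in order]
    with open(path, "w") as fh:
        for b in blocks:
            fh.write(f"{b.chrom}\t{b.start - 1}\t{b.end}\t{b.type}\t"
                     f"{int(b.relaxed)}\t.\n")


def read_blocks(path):
    """Read blocks written by :func:`write_blocks` (1-based inclusive out)."""
    from .scan import DRBlock

    out = []
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line:
                continue
            f = line.split("\t")
            out.append(DRBlock(
                type=f[3], chrom=f[0], start=int(f[1]) + 1, end=int(f[2]),
                relaxed=bool(int(f[4])) if len(f) > 4 and f[4] != "." else False))
    return out


def read_chrom_lengths(path) -> dict[str, int]:
    """Chromosome lengths from a FASTA .fai index or 2-column TSV."""
    out: dict[str, int] = {}
    with open(path) as fh:
        for line in fh:
            f = line.strip().split("\t")
            if len(f) >= 2:
                out[f[0]] = int(f[1])
    return out
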