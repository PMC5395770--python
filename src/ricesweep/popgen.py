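"""Population-genetic statistics over the genotype matrix.

Implements the near-fixed differentiation markers between the two cultivated
subspecies, Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction on
consensus coding sequences, Tajima's D with empirical genome-wide
significance, the Weir-Cockerham (1984) fixation index with a
label-permutation test, and the small hypothesis tests used when summarizing
domesticated regions.

Genotypes are collapsed allele codes of inbred lines, so each individual is
treated as a single haploid sequence throughout.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
from scipy import stats as sps

from .io import MISSING, GenotypeMatrix, SampleTable
from .scan import _group_site_counts, _within_diffs

# --- near-fixed markers ------------------------------------------------------


@dataclass
class NearFixedMarker:
    chrom: str
    pos: int
    allele_a: int       # major allele code in group A
    freq_a: float
    allele_b: int
    freq_b: float
    passes: bool


def near_fixed_markers(gm: GenotypeMatrix, samples: SampleTable,
                       group_a: str = "japonica", group_b: str = "indica",
                       threshold: float = 0.8,
                       passing_only: bool = True) -> list[NearFixedMarker]:
    """Sites where >= `threshold` of each group carries a different allele.

    Frequencies are over non-missing calls; a site with an all-missing
    group cannot be a marker.
    """
    ia, ib = samples.indices(group_a), samples.indices(group_b)
    if len(ia) == 0 or len(ib) == 0:
        raise ValueError("both groups must be non-empty")
    ca, ka = _group_site_counts(gm.codes[:, ia], np.arange(len(ia)))
    cb, kb = _group_site_counts(gm.codes[:, ib], np.arange(len(ib)))
    A = max(ca.shape[1], cb.shape[1])
    ca = np.pad(ca, ((0, 0), (0, A - ca.shape[1])))
    cb = np.pad(cb, ((0, 0), (0, A - cb.shape[1])))
    maj_a = ca.argmax(axis=1)
    maj_b = cb.argmax(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        fa = ca.max(axis=1) / ka
        fb = cb.max(axis=1) / kb
    ok = (ka > 0) & (kb > 0)
    passes = ok & (fa >= threshold) & (fb >= threshold) & (maj_a != maj_b)
    out = []
    for i in np.flatnonzero(passes if passing_only else ok):
        out.append(NearFixedMarker(
            chrom=str(gm.chrom[i]), pos=int(gm.pos[i]),
            allele_a=int(maj_a[i]), freq_a=float(fa[i]),
            allele_b=int(maj_b[i]), freq_b=float(fb[i]),
            passes=bool(passes[i])))
    return out


# --- NG86 Ka/Ks --------------------------------------------------------------

_BASES = "TCAG"
_CODON_TABLE = {}
_AA = ("FFLLSSSSYY**CC*WLLLLPPPPHHQQRRRRIIIMTTTTNNKKSSRRVVVVAAAADDEEGGGG")
for _i, (_b1, _b2, _b3) in enumerate(itertools.product(_BASES, repeat=3)):
    _CODON_TABLE[_b1 + _b2 + _b3] = _AA[_i]


def translate_codon(codon: str) -> str:
    return _CODON_TABLE[codon.upper()]


def _codon_syn_fraction(codon: str) -> np.ndarray:
    """Fraction of synonymous single-base changes at each codon position.

    Changes to stop codons count as nonsynonymous (they alter the protein),
    per the standard NG86 site counting.
    """
    aa = translate_codon(codon)
    out = np.zeros(3)
    for p in range(3):
        syn = tot = 0
        for b in _BASES:
            if b == codon[p].upper():
                continue
            alt = codon[:p] + b + codon[p + 1:]
            tot += 1
            if translate_codon(alt) == aa:
                syn += 1
        out[p] = syn / tot
    return out


def _pathway_counts(c1: str, c2: str) -> tuple[float, float]:
    """Average (nonsyn, syn) difference counts over all minimum-length
    mutational pathways between two codons; pathways through stop codons
    are skipped (unless all pass through stops, then all are used)."""
    diff_pos = [p for p in range(3) if c1[p] != c2[p]]
    if not diff_pos:
        return 0.0, 0.0
    paths = []
    for order in itertools.permutations(diff_pos):
        cur = c1
        nd = sd = 0
        through_stop = False
        for p in order:
            nxt = cur[:p] + c2[p] + cur[p + 1:]
            a1, a2 = translate_codon(cur), translate_codon(nxt)
            if a2 == "*" and len(diff_pos) > 1 and nxt != c2:
                through_stop = True
            if a1 == a2:
                sd += 1
            else:
                nd += 1
            cur = nxt
        paths.append((through_stop, nd, sd))
    usable = [(n, s) for t, n, s in paths if not t]
    if not usable:
        usable = [(n, s) for _, n, s in paths]
    nd = sum(n for n, _ in usable) / len(usable)
    sd = sum(s for _, s in usable) / len(usable)
    return nd, sd


@dataclass
class KaKsResult:
    gene_id: str
    n_sites: float      # NG86 nonsynonymous sites (averaged over sequences)
    s_sites: float
    nd: float           # nonsynonymous differences (pathway-averaged)
    sd: float
    pn: float
    ps: float
    ka: float           # JC-corrected; nan if saturated
    ks: float
    positive: bool
    saturated: bool = False
    premature_stop: bool = False


def jukes_cantor(p: float) -> float:
    """JC69 distance d = -(3/4) ln(1 - 4p/3); nan at/beyond saturation."""
    if p < 0:
        raise ValueError("proportion must be >= 0")
    if p >= 0.75:
        return float("nan")
    return -0.75 * math.log1p(-4.0 * p / 3.0)


def kaks_ng86(seq_a: str, seq_b: str, gene_id: str = "") -> KaKsResult:
    """Nei-Gojobori (1986) Ka/Ks with Jukes-Cantor correction.

    Sequences must be aligned CDS of equal length, a multiple of 3.
    The positive-selection flag is Ka/Ks > 1 or (Ks == 0 and Ka > 0).
    """
    seq_a, seq_b = seq_a.upper(), seq_b.upper()
    if len(seq_a) != len(seq_b):
        raise ValueError("sequences must have equal length")
    if len(seq_a) % 3:
        raise ValueError("length must be a multiple of 3")
    n_codons = len(seq_a) // 3
    S_a = S_b = 0.0
    nd = sd = 0.0
    premature = False
    for k in range(n_codons):
        ca = seq_a[3 * k:3 * k + 3]
        cb = seq_b[3 * k:3 * k + 3]
        if translate_codon(ca) == "*" or translate_codon(cb) == "*":
            if k < n_codons - 1:
                premature = True
        S_a += _codon_syn_fraction(ca).sum()
        S_b += _codon_syn_fraction(cb).sum()
        d_n, d_s = _pathway_counts(ca, cb)
        nd += d_n
        sd += d_s
    s_sites = (S_a + S_b) / 2.0
    n_sites = 3.0 * n_codons - s_sites
    pn = nd / n_sites if n_sites > 0 else 0.0
    ps = sd / s_sites if s_sites > 0 else 0.0
    ka = jukes_cantor(pn)
    ks = jukes_cantor(ps)
    saturated = math.isnan(ka) or math.isnan(ks)
    positive = False
    if not saturated:
        positive = (ks > 0 and ka / ks > 1) or (ks == 0 and ka > 0)
    return KaKsResult(gene_id=gene_id, n_sites=n_sites, s_sites=s_sites,
                      nd=nd, sd=sd, pn=pn, ps=ps, ka=ka, ks=ks,
                      positive=positive, saturated=saturated,
                      premature_stop=premature)


def positive_selection_enrichment(n_pos_region: int, n_region: int,
                                  n_pos_genome: int, n_genome: int
                                  ) -> tuple[float, float]:
    """Yates-corrected chi-square (df=1) comparing the fraction of
    positively selected genes in a region against the rest of the genome.

    The 2x2 table is (region pos/neg) vs (rest-of-genome pos/neg); the
    correction is floored so a perfectly proportional table gives 0.
    """
    if not (0 <= n_pos_region <= n_region and 0 <= n_pos_genome <= n_genome):
        raise ValueError("inconsistent counts")
    a = n_pos_region
    b = n_region - n_pos_region
    c = n_pos_genome - n_pos_region
    d = (n_genome - n_pos_genome) - b
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("zero margin in 2x2 table")
    N = a + b + c + d
    num = max(abs(a * d - b * c) - N / 2.0, 0.0)
    chi2 = N * num ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    p = float(sps.chi2.sf(chi2, df=1))
    return float(chi2), p


def yates_chi2(a: int, b: int, c: int, d: int) -> tuple[float, float]:
    """Yates chi-square on a raw 2x2 table (a,b / c,d)."""
    if min(a + b, c + d, a + c, b + d) <= 0:
        raise ValueError("zero margin in 2x2 table")
    N = a + b + c + d
    num = max(abs(a * d - b * c) - N / 2.0, 0.0)
    chi2 = N * num ** 2 / ((a + b) * (c + d) * (a + c) * (b + d))
    return float(chi2), float(sps.chi2.sf(chi2, df=1))


# --- Tajima's D --------------------------------------------------------------


@dataclass
class TajimaConstants:
    a1: float
    a2: float
    b1: float
    b2: float
    c1: float
    c2: float
    e1: float
    e2: float


def tajima_constants(n: int) -> TajimaConstants:
    """The 1989 constants for sample size n (number of sequences)."""
    if n < 2:
        raise ValueError("need n >= 2 sequences")
    a1 = sum(1.0 / i for i in range(1, n))
    a2 = sum(1.0 / i ** 2 for i in range(1, n))
    b1 = (n + 1) / (3.0 * (n - 1))
    b2 = 2.0 * (n ** 2 + n + 3) / (9.0 * n * (n - 1))
    c1 = b1 - 1.0 / a1
    c2 = b2 - (n + 2) / (a1 * n) + a2 / a1 ** 2
    e1 = c1 / a1
    e2 = c2 / (a1 ** 2 + a2)
    return TajimaConstants(a1, a2, b1, b2, c1, c2, e1, e2)


@dataclass
class TajimaDResult:
    region: tuple[str, int, int] | None
    n: int
    s: int
    pi_total: float     # mean pairwise differences (count, not per bp)
    constants: TajimaConstants | None
    d: float            # nan when S == 0
    significant: bool | None = None


def tajimas_d(gm: GenotypeMatrix, samples: SampleTable, group: str,
              region: tuple[str, int, int] | None = None) -> TajimaDResult:
    """Tajima's D for a group over a region (whole matrix when None).

    S counts segregating sites among non-missing calls; pi_total is the
    mean pairwise difference count with pairwise-complete comparison
    (missing pairs contribute zero, denominator C(n,2)).
    """
    idx = samples.indices(group)
    n = len(idx)
    if n < 2:
        raise ValueError("need >= 2 samples")
    m = (gm.sites_in(*region) if region is not None
         else np.ones(gm.n_sites, dtype=bool))
    counts, k = _group_site_counts(gm.codes[m][:, idx], np.arange(n))
    seg = ((counts > 0).sum(axis=1) > 1)
    S = int(seg.sum())
    npairs = n * (n - 1) // 2
    pi_total = float(_within_diffs(counts, k).sum()) / npairs
    if S == 0:
        return TajimaDResult(region, n, 0, pi_total, None, float("nan"))
    c = tajima_constants(n)
    var = c.e1 * S + c.e2 * S * (S - 1)
    d = (pi_total - S / c.a1) / math.sqrt(var)
    return TajimaDResult(region, n, S, pi_total, c, d)


def tajimas_d_windows(gm: GenotypeMatrix, samples: SampleTable, group: str,
                      windows) -> np.ndarray:
    """Per-window D values (nan where undefined), for empirical tails."""
    out = np.full(len(windows), np.nan)
    for i, w in enumerate(windows):
        try:
            r = tajimas_d(gm, samples, group, (w.chrom, w.start, w.end))
            out[i] = r.d
        except ValueError:
            pass
    return out


def empirical_tails(values: np.ndarray, alpha: float = 0.05
                    ) -> tuple[float, float]:
    """Two-tailed empirical cutoffs (alpha/2 in each tail), nan-aware."""
    v = values[~np.isnan(values)]
    if len(v) == 0:
        return float("nan"), float("nan")
    return (float(np.quantile(v, alpha / 2)),
            float(np.quantile(v, 1 - alpha / 2)))


# --- Weir-Cockerham Fst ------------------------------------------------------


@dataclass
class FstResult:
    region: tuple[str, int, int] | None
    estimate: float
    n_permutations: int
    p_value: float | None


def _wc_components(gm: GenotypeMatrix, site_mask: np.ndarray,
                   membership: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Per-site numerator/denominator of the Weir-Cockerham (1984)
    estimator for haploid-coded samples, summed over alleles.

    membership: (N,) int array, 0/1 group labels (-1 = excluded).
    Returns (numerators, denominators) per site; theta = sum(num)/sum(den).
    """
    codes = gm.codes[site_mask]
    S = codes.shape[0]
    num = np.zeros(S)
    den = np.zeros(S)
    groups = [np.flatnonzero(membership == g) for g in (0, 1)]
    r = 2
    amax = int(codes.max(initial=0))
    ni = np.zeros((S, r))
    p = np.zeros((S, r, amax + 1))
    for g, idx in enumerate(groups):
        sub = codes[:, idx]
        nonmiss = (sub != MISSING).sum(axis=1)
        ni[:, g] = nonmiss
        for a in range(amax + 1):
            with np.errstate(invalid="ignore", divide="ignore"):
                p[:, g, a] = (sub == a).sum(axis=1) / nonmiss
    nbar = ni.mean(axis=1)
    ntot = ni.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        nc = (ntot - (ni ** 2).sum(axis=1) / ntot) / (r - 1)
        for a in range(amax + 1):
            pbar = (ni * p[:, :, a]).sum(axis=1) / ntot
            s2 = (ni * (p[:, :, a] - pbar[:, None]) ** 2).sum(axis=1) \
                / ((r - 1) * nbar)
            hbar = p[:, :, a] * (1 - p[:, :, a])          # within-group het
            msg = (ni * hbar).sum(axis=1) / (ntot - r)
            msp = nbar * s2 / 1.0
            # haploid WC84: theta = (MSP - MSG)/(MSP + (nc - 1) MSG)
            num_a = msp - msg
            den_a = msp + (nc - 1) * msg
            ok = np.isfinite(num_a) & np.isfinite(den_a)
            num[ok] += num_a[ok]
            den[ok] += den_a[ok]
    return num, den


def fst_wc(gm: GenotypeMatrix, samples: SampleTable,
           group_a: str, group_b: str,
           region: tuple[str, int, int] | None = None,
           n_perm: int = 1000, seed: int | None = None) -> FstResult:
    """Multi-site Weir-Cockerham theta with a group-label permutation test.

    theta is the ratio of summed per-site variance components; the p-value
    is (1 + #{permuted theta >= observed}) / (n_perm + 1).
    """
    ia, ib = samples.indices(group_a), samples.indices(group_b)
    if len(ia) < 2 or len(ib) < 2:
        raise ValueError("need >= 2 samples per group")
    m = (gm.sites_in(*region) if region is not None
         else np.ones(gm.n_sites, dtype=bool))
    membership = np.full(gm.n_samples, -1)
    membership[ia] = 0
    membership[ib] = 1
    num, den = _wc_components(gm, m, membership)
    tot_den = den.sum()
    if tot_den == 0:
        return FstResult(region, float("nan"), 0, None)
    theta = float(num.sum() / tot_den)
    if n_perm <= 0:
        return FstResult(region, theta, 0, None)
    rng = np.random.default_rng(seed)
    pool = np.concatenate([ia, ib])
    hits = 0
    for _ in range(n_perm):
        perm = rng.permutation(pool)
        mem = np.full(gm.n_samples, -1)
        mem[perm[:len(ia)]] = 0
        mem[perm[len(ia):]] = 1
        pn, pd_ = _wc_components(gm, m, mem)
        td = pd_.sum()
        t = pn.sum() / td if td != 0 else -np.inf
        if t >= theta:
            hits += 1
    p = (1 + hits) / (n_perm + 1)
    return FstResult(region, theta, n_perm, p)


# --- t-test ------------------------------------------------------------------


def two_sample_t(values_a, values_b, welch: bool = False
                 ) -> tuple[float, float, float]:
    """Two-sample t-test (pooled by default), two-sided.

    Returns (t, df, p). Identical zero-variance samples give t=0, p=1.
    """
    a = np.asarray(values_a, dtype=float)
    b = np.asarray(values_b, dtype=float)
    if len(a) < 2 or len(b) < 2:
        raise ValueError("each sample needs >= 2 values")
    if a.var(ddof=1) == 0 and b.var(ddof=1) == 0 and a.mean() == b.mean():
        df = len(a) + len(b) - 2
        return 0.0, float(df), 1.0
    res = sps.ttest_ind(a, b, equal_var=not welch)
    return float(res.statistic), float(res.df), float(res.pvalue)
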