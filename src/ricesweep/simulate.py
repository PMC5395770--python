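"""Seeded multi-population genotype simulator.

Generates VCF + sample table + truth BED with the statistical structure the
scan assumes: a diverse wild progenitor pool, two cultivated groups
(*japonica*-like and *indica*-like) derived from it through independent
bottlenecks plus a shared-sweep component, an outgroup, and implanted
domesticated regions of both types.

The generator samples per-site population frequencies rather than running a
coalescent: each candidate site draws a wild allele frequency q from a
neutral (1/i) site-frequency spectrum; cultivar groups then experience, per
site, either a shared fixation (probability a, common to both groups), an
independent fixation (probability b_g per group), or retention of the wild
frequency. The mixture weights are solved in closed form so that expected
per-bp diversities hit the configured targets:

    E[pi_wild]    = D * E[2q(1-q)]
    E[dxy]        = E[pi_wild] * (1 - a)
    E[pi_group]   = E[dxy] * (1 - b_g)

where D is the candidate-site density. Implanted DR-I regions fix each
cultivar group for a different wild haplotype (divergent sweeps); DR-II
regions fix both groups for one haplotype carried by a designated wild
donor accession (shared sweep + introgression). Residual within-sweep
noise is small per-call flipping. There is no linkage disequilibrium and
no recombination map; see the methods note for what this does and does
not validate.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .io import SampleTable


@dataclass
class SimRegion:
    chrom: str
    start: int
    end: int
    type: str                  # "DR-I" | "DR-II"
    donor: str | None = None   # wild donor sample id (DR-II)
    direction: str | None = None


@dataclass
class SimParams:
    """Generator configuration; defaults emulate the study conditions."""
    chrom_lengths: dict[str, int] = field(
        default_factory=lambda: {"chr01": 2_000_000, "chr02": 2_000_000})
    n_jap: int = 30
    n_ind: int = 30
    n_wild: int = 12
    n_outgroup: int = 4
    n_admixed: int = 0          # extra non-typical 'japonica' mosaics
    admix_fraction: float = 0.65  # fraction of sites from an indica parent
    pi_jap: float = 0.00196
    pi_ind: float = 0.00265
    pi_wild: float = 0.0067
    dxy_jap_ind: float = 0.00617
    dr1_regions: list[tuple[str, int, int]] = field(default_factory=lambda: [
        ("chr01", 400_001, 430_000),
        ("chr01", 1_200_001, 1_240_000),
        ("chr02", 700_001, 730_000)])
    dr2_regions: list[tuple[str, int, int]] = field(default_factory=lambda: [
        ("chr01", 1_600_001, 1_630_000),
        ("chr02", 200_001, 230_000),
        ("chr02", 1_500_001, 1_540_000)])
    sweep_noise: float = 0.001      # per-call flip rate inside sweeps
    missing_rate: float = 0.02
    het_rate: float = 0.005         # artifact heterozygote rate (cultivars)
    depth_mean_cultivar: float = 20.0
    depth_mean_wild: float = 8.0
    depth_mean_outgroup: float = 20.0
    qual_low_fraction: float = 0.005  # sites drawn below the qual cutoff
    n_genes_per_dr1: int = 2
    n_genes_background: int = 8
    gene_cds_codons: int = 100
    seed: int = 0

    def __post_init__(self):
        for t in (self.pi_jap, self.pi_ind, self.pi_wild, self.dxy_jap_ind):
            if not (0 < t < 1):
                raise ValueError("diversity targets must be in (0, 1)")
        if self.dxy_jap_ind >= self.pi_wild:
            raise ValueError("dxy_jap_ind must be < pi_wild "
                             "(shared-sweep weight would be negative)")
        if self.dxy_jap_ind <= max(self.pi_jap, self.pi_ind) * 0.999:
            if self.dxy_jap_ind < max(self.pi_jap, self.pi_ind):
                raise ValueError("dxy must be >= each within-group pi")
        regions = [(c, s, e) for c, s, e in
                   list(self.dr1_regions) + list(self.dr2_regions)]
        for c, s, e in regions:
            if c not in self.chrom_lengths or not (1 <= s <= e
                                                   <= self.chrom_lengths[c]):
                raise ValueError(f"region outside chromosome: {c}:{s}-{e}")
        by_chrom: dict[str, list] = {}
        for c, s, e in regions:
            by_chrom.setdefault(c, []).append((s, e))
        for c, ivs in by_chrom.items():
            ivs.sort()
            for (s1, e1), (s2, e2) in zip(ivs, ivs[1:]):
                if s2 <= e1:
                    raise ValueError(f"overlapping implant regions on {c}")


def _sfs_expectation(m: int) -> float:
    """E[2q(1-q)] for q drawn from the neutral 1/i spectrum on m copies."""
    H = sum(1.0 / i for i in range(1, m))
    return (m - 1) / (m * H)


def expected_stats(params: SimParams) -> dict:
    """Closed-form per-bp expectations per region class.

    Expectations are on the OBSERVED scale: the mixture weights and site
    density compensate for the observation model (missing calls and
    artifact heterozygotes collapse to missing, diluting measured pairwise
    rates by ~(1 - loss)^2), so realized whole-genome statistics center on
    the configured targets.
    """
    dil_w = (1.0 - params.missing_rate) ** 2
    dil_c = (1.0 - params.missing_rate - params.het_rate) ** 2
    a = 1.0 - (params.dxy_jap_ind / params.pi_wild) * (dil_w / dil_c)
    if not 0 <= a < 1:
        raise ValueError("dxy_jap_ind too close to pi_wild for the "
                         "observation model (shared-fix weight infeasible)")
    b_jap = 1.0 - params.pi_jap / params.dxy_jap_ind
    b_ind = 1.0 - params.pi_ind / params.dxy_jap_ind
    m = 2 * params.n_wild
    density = params.pi_wild / (_sfs_expectation(m) * dil_w)
    noise_pi = 2 * params.sweep_noise * density * dil_c
    return {
        "shared_fix_prob": a,
        "fix_prob_jap": b_jap,
        "fix_prob_ind": b_ind,
        "site_density": density,
        "background": {"pi_jap": params.pi_jap, "pi_ind": params.pi_ind,
                       "pi_wild": params.pi_wild,
                       "dxy_jap_ind": params.dxy_jap_ind},
        "dr1": {"pi_jap": noise_pi, "pi_ind": noise_pi,
                "pi_wild": params.pi_wild, "dxy_jap_ind": params.pi_wild},
        "dr2": {"pi_jap": noise_pi, "pi_ind": noise_pi,
                "pi_wild": params.pi_wild, "dxy_jap_ind": noise_pi},
    }


@dataclass
class SimResult:
    vcf_path: Path
    sample_path: Path
    truth_path: Path
    truth: list[SimRegion]
    gff_path: Path | None = None
    cds_path: Path | None = None


def _sample_table(params: SimParams) -> pd.DataFrame:
    rows = []
    for i in range(params.n_jap):
        rows.append(("JAP%03d" % (i + 1), "japonica",
                     "temperate" if i < params.n_jap // 2 else "tropical"))
    for i in range(params.n_admixed):
        rows.append(("ADM%03d" % (i + 1), "japonica", "none"))
    for i in range(params.n_ind):
        rows.append(("IND%03d" % (i + 1), "indica", "none"))
    for i in range(params.n_wild):
        rows.append(("WILD%02d" % (i + 1), "wild", "none"))
    for i in range(params.n_outgroup):
        rows.append(("OUT%02d" % (i + 1), "outgroup", "none"))
    df = pd.DataFrame(rows, columns=["sample_id", "group", "subgroup"])
    df["origin"] = "simulated"
    return df


def simulate(params: SimParams, out_dir) -> SimResult:
    """Generate VCF 4.2 (GT:DP), sample TSV, truth BED and synthetic gene
    models; fully deterministic for a given params.seed."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    rng = np.random.default_rng(params.seed)
    exp = expected_stats(params)
    a = exp["shared_fix_prob"]
    b = {"jap": exp["fix_prob_jap"], "ind": exp["fix_prob_ind"]}
    density = exp["site_density"]
    m = 2 * params.n_wild
    sfs_q = np.arange(1, m) / m
    sfs_w = (1.0 / np.arange(1, m))
    sfs_w = sfs_w / sfs_w.sum()

    df = _sample_table(params)
    samples = SampleTable(df)
    n_total = len(df)
    jap_idx = samples.indices("japonica")
    adm_idx = np.array([i for i, sid in enumerate(samples.sample_ids)
                        if sid.startswith("ADM")], dtype=int)
    jap_idx = np.array([i for i in jap_idx if i not in set(adm_idx)])
    ind_idx = samples.indices("indica")
    wild_idx = samples.indices("wild")
    out_idx = samples.indices("outgroup")
    donor_id = samples.sample_ids[wild_idx[0]] if len(wild_idx) else None

    truth: list[SimRegion] = []
    for c, s, e in params.dr1_regions:
        truth.append(SimRegion(c, s, e, "DR-I"))
    for c, s, e in params.dr2_regions:
        truth.append(SimRegion(c, s, e, "DR-II", donor=donor_id,
                               direction="indica_to_japonica"))

    def region_type(chrom, pos_arr):
        t = np.zeros(len(pos_arr), dtype=np.int8)   # 0 bg, 1 DR-I, 2 DR-II
        for r in truth:
            if r.chrom != chrom:
                continue
            inside = (pos_arr >= r.start) & (pos_arr <= r.end)
            t[inside] = 1 if r.type == "DR-I" else 2
        return t

    bases = np.array(list("ACGT"))
    vcf_path = out / "sim.vcf"
    depth_mean = np.empty(n_total)
    depth_mean[samples.indices("cultivar")] = params.depth_mean_cultivar
    depth_mean[wild_idx] = params.depth_mean_wild
    depth_mean[out_idx] = params.depth_mean_outgroup
    if len(adm_idx):
        depth_mean[adm_idx] = params.depth_mean_cultivar

    with open(vcf_path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write('##FORMAT=<ID=GT,Number=1,Type=String,Description='
                 '"Genotype">\n')
        fh.write('##FORMAT=<ID=DP,Number=1,Type=Integer,Description='
                 '"Read depth">\n')
        for c, L in params.chrom_lengths.items():
            fh.write(f"##contig=<ID={c},length={L}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\tFORMAT\t"
                 + "\t".join(df["sample_id"]) + "\n")
        for chrom, L in params.chrom_lengths.items():
            n_sites = int(round(L * density))
            pos = np.sort(rng.choice(L, size=n_sites, replace=False)) + 1
            q = rng.choice(sfs_q, size=n_sites, p=sfs_w)
            rtype = region_type(chrom, pos)

            geno = np.zeros((n_sites, n_total), dtype=np.int8)
            # wild: independent Bernoulli(q) per sample
            geno[:, wild_idx] = (
                rng.random((n_sites, len(wild_idx))) < q[:, None]
            ).astype(np.int8)
            # outgroup: one shared haplotype + private divergence
            og = (rng.random(n_sites) < q).astype(np.int8)
            geno[:, out_idx] = og[:, None]

            # cultivars, background sites
            cls = rng.random(n_sites)
            shared = cls < a
            hap_shared = (rng.random(n_sites) < q).astype(np.int8)
            for gname, idx in (("jap", jap_idx), ("ind", ind_idx)):
                fixed = (~shared) & (rng.random(n_sites) < b[gname])
                hap_own = (rng.random(n_sites) < q).astype(np.int8)
                seg = (rng.random((n_sites, len(idx))) < q[:, None]
                       ).astype(np.int8)
                col = np.where(shared[:, None], hap_shared[:, None],
                               np.where(fixed[:, None], hap_own[:, None],
                                        seg))
                geno[:, idx] = col

            # implanted sweeps override cultivar genotypes
            dr1 = rtype == 1
            if dr1.any():
                hj = (rng.random(n_sites) < q).astype(np.int8)
                hi = (rng.random(n_sites) < q).astype(np.int8)
                geno[np.ix_(dr1, jap_idx)] = hj[dr1, None]
                geno[np.ix_(dr1, ind_idx)] = hi[dr1, None]
            dr2 = rtype == 2
            if dr2.any():
                hc = (rng.random(n_sites) < q).astype(np.int8)
                cult = np.concatenate([jap_idx, ind_idx])
                geno[np.ix_(dr2, cult)] = hc[dr2, None]
                # donor wild accession carries the swept haplotype
                geno[dr2, wild_idx[0]] = hc[dr2]
            sweep = dr1 | dr2
            if sweep.any() and params.sweep_noise > 0:
                cult = np.concatenate([jap_idx, ind_idx])
                flip = (rng.random((int(sweep.sum()), len(cult)))
                        < params.sweep_noise)
                sub = geno[np.ix_(sweep, cult)]
                geno[np.ix_(sweep, cult)] = np.where(flip, 1 - sub, sub)

            # admixed 'japonica': per-site mosaic of one japonica and one
            # indica parent line, admix_fraction of sites from the indica
            # parent (a mislabeled/introgressed accession)
            if len(adm_idx):
                for k, ai in enumerate(adm_idx):
                    jp = jap_idx[k % len(jap_idx)]
                    ip = ind_idx[k % len(ind_idx)]
                    pick = rng.random(n_sites) < params.admix_fraction
                    geno[:, ai] = np.where(pick, geno[:, ip], geno[:, jp])

            # observation model
            depth = rng.poisson(depth_mean[None, :],
                                size=(n_sites, n_total)).astype(np.int32)
            miss = rng.random((n_sites, n_total)) < params.missing_rate
            het = rng.random((n_sites, n_total)) < params.het_rate
            het[:, wild_idx] = False
            het[:, out_idx] = False
            qual = np.where(rng.random(n_sites) < params.qual_low_fraction,
                            rng.uniform(20, 50, n_sites),
                            rng.uniform(50, 2000, n_sites))

            ref_i = rng.integers(0, 4, n_sites)
            alt_off = rng.integers(1, 4, n_sites)
            alt_i = (ref_i + alt_off) % 4

            gt_str = np.empty((n_sites, n_total), dtype=object)
            gt_str[geno == 0] = "0/0"
            gt_str[geno == 1] = "1/1"
            gt_str[het] = "0/1"
            gt_str[miss] = "./."
            for i in range(n_sites):
                fields = "\t".join(f"{gt_str[i, j]}:{depth[i, j]}"
                                   for j in range(n_total))
                fh.write(f"{chrom}\t{pos[i]}\t.\t{bases[ref_i[i]]}\t"
                         f"{bases[alt_i[i]]}\t{qual[i]:.1f}\tPASS\t.\t"
                         f"GT:DP\t{fields}\n")

    sample_path = out / "samples.tsv"
    df.to_csv(sample_path, sep="\t", index=False)

    truth_path = out / "truth.bed"
    with open(truth_path, "w") as fh:
        for r in sorted(truth, key=lambda r: (r.chrom, r.start)):
            fh.write(f"{r.chrom}\t{r.start - 1}\t{r.end}\t{r.type}\t0\t"
                     f"{r.donor or '.'}\n")

    gff_path, cds_path = _write_genes(params, rng, out)
    return SimResult(vcf_path=vcf_path, sample_path=sample_path,
                     truth_path=truth_path, truth=truth,
                     gff_path=gff_path, cds_path=cds_path)


def _write_genes(params: SimParams, rng, out: Path):
    """Synthetic phase-0 CDS gene models inside the DR-I regions.

    The CDS sequence is random codons (no internal stops); bases at SNP
    coordinates are NOT reconciled with the VCF REF column — consensus
    substitution uses marker alleles resolved to bases via the VCF site
    records, which is exercised end-to-end in the pipeline.
    """
    genes = []
    for k, (chrom, s, e) in enumerate(params.dr1_regions):
        for g in range(params.n_genes_per_dr1):
            L = params.gene_cds_codons * 3
            span = e - s + 1
            if span < L + 200:
                continue
            gs = s + 100 + g * (span - L - 200) // max(
                params.n_genes_per_dr1, 1)
            strand = "+" if (k + g) % 2 == 0 else "-"
            genes.append((f"gene{k + 1:02d}_{g + 1}", chrom, gs,
                          gs + L - 1, strand))
    # background genes spread over windows free of implanted regions
    implants = list(params.dr1_regions) + list(params.dr2_regions)
    chroms = list(params.chrom_lengths)
    L = params.gene_cds_codons * 3
    placed = 0
    step = 0
    while placed < params.n_genes_background and step < 1000:
        chrom = chroms[step % len(chroms)]
        span = params.chrom_lengths[chrom]
        gs = 50_001 + (step // len(chroms)) * max(
            (span - 100_000) // max(params.n_genes_background, 1), L + 1000)
        step += 1
        ge = gs + L - 1
        if ge > span:
            continue
        if any(c == chrom and s <= ge + 10_000 and e >= gs - 10_000
               for c, s, e in implants):
            continue
        strand = "+" if placed % 2 == 0 else "-"
        genes.append((f"bg{placed + 1:02d}", chrom, gs, ge, strand))
        placed += 1
    if not genes:
        return None, None
    gff_path = out / "genes.gff3"
    cds_path = out / "cds.fasta"
    bases = "ACGT"
    aa_stop = {"TAA", "TAG", "TGA"}
    with open(gff_path, "w") as gf, open(cds_path, "w") as cf:
        gf.write("##gff-version 3\n")
        for gid, chrom, gs, ge, strand in genes:
            gf.write(f"{chrom}\tricesweep-sim\tgene\t{gs}\t{ge}\t.\t"
                     f"{strand}\t.\tID={gid}\n")
            gf.write(f"{chrom}\tricesweep-sim\tCDS\t{gs}\t{ge}\t.\t"
                     f"{strand}\t0\tID={gid}.cds;Parent={gid}\n")
            codons = ["ATG"]
            while len(codons) < (ge - gs + 1) // 3:
                c = "".join(bases[i] for i in rng.integers(0, 4, 3))
                if c not in aa_stop:
                    codons.append(c)
            seq = "".join(codons)
            cf.write(f">{gid}\n{seq}\n")
    return gff_path, cds_path
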