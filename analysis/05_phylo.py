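#!/usr/bin/env python
"""NJ phylogenies and wild-accession identity ranking on the DR blocks.

Builds JC-distance NJ trees (with bootstrap support) from the SNPs of the
recovered DR-I and DR-II blocks and ranks wild accessions by identity to
the cultivar consensus. On DR-I data the two cultivated groups form
separate clades (independent sweeps on divergent haplotypes); on DR-II
data they form a single clade and the designated wild donor of the swept
haplotype ranks first.
"""
import sys
import warnings
from pathlib import Path

from ricesweep import io as rio
from ricesweep import phylo
from ricesweep import scan as rscan
from ricesweep.simulate import SimParams

SIM_DIR = Path("scratch/analysis/sim")
RESULTS = Path("results")


def main():
    params = SimParams(seed=1)
    st = rio.SampleTable.from_tsv(SIM_DIR / "samples.tsv")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        gm = rio.read_vcf(SIM_DIR / "sim.vcf", st)
    gmf, _ = rio.filter_snps(gm)
    th = rscan.Thresholds()
    labeled = rscan.classify_windows(
        rscan.window_stats(gmf, st, rscan.make_windows(params.chrom_lengths)),
        th)
    blocks = rscan.merge_blocks(labeled, th)

    for t in ("DR-I", "DR-II"):
        regions = [(b.chrom, b.start, b.end) for b in blocks if b.type == t]
        tree = phylo.bootstrap_support(gmf, regions=regions, n_reps=200,
                                       seed=1)
        slug = t.replace("-", "").lower()
        (RESULTS / f"05_tree_{slug}.nwk").write_text(tree.newick())
        jap = set(st.ids("japonica"))
        ind = set(st.ids("indica"))

        def norm(s):
            s = frozenset(s)
            return s if tree.taxa[0] not in s else frozenset(
                set(tree.taxa) - s)

        parts = tree.bipartitions()
        donor = [l.split("\t")[5] for l in
                 (SIM_DIR / "truth.bed").read_text().strip().split("\n")
                 if l.split("\t")[3] == "DR-II"][0]
        joint = (norm(jap | ind) in parts
                 or norm(jap | ind | {donor}) in parts)
        print(f"{t}: japonica clade: {norm(jap) in parts}, "
              f"indica clade: {norm(ind) in parts}, "
              f"joint cultivar clade (donor may join): {joint}")
        group = "cultivar" if t == "DR-II" else "japonica"
        rank = phylo.identity_rank(gmf, st, group, regions)
        rank.to_csv(RESULTS / f"05_identity_{slug}.tsv", sep="\t",
                    index=False)
        print(f"  top wild accession by identity to {group} consensus: "
              f"{rank.iloc[0]['sample_id']} "
              f"({rank.iloc[0]['identity']:.3f} over "
              f"{int(rank.iloc[0]['n_sites'])} sites)")
    donor = [l.split("\t")[5] for l in
             (SIM_DIR / "truth.bed").read_text().strip().split("\n")
             if l.split("\t")[3] == "DR-II"][0]
    print(f"simulator truth donor for DR-II: {donor}")


if __name__ == "__main__":
    sys.exit(main())
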