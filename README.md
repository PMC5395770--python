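# ricesweep

Detection and characterization of domesticated regions in rice from
multi-population genotype data.

Asian cultivated rice comprises two subspecies, *japonica* and *indica*,
domesticated from the wild progenitor *Oryza rufipogon*. Domestication left
two distinct footprints in their genomes. In some regions each subspecies
underwent its own selective sweep on a different wild haplotype: diversity
within each cultigen collapses while divergence between them stays high. In
others a single sweep spread through both subspecies (plausibly by
introgression): diversity and divergence among all cultivars collapse
together while wild rice remains diverse. `ricesweep` implements the
windowed scan that separates these two classes, plus the statistics used to
characterize them, for anyone analyzing multi-sample rice (or other inbred
crop) VCFs against wild and outgroup panels.

## The scan

Nucleotide diversity for a sample set is the mean over sample pairs of the
per-bp difference rate, π = (number of differing SNPs) / (region length);
divergence between two sets, D<sub>xy</sub>, is the same mean over
cross-set pairs. The genome is tiled into 10-kb windows and each window is
labeled:

* **DR-I** (divergent sweeps): π<sub>jap</sub> ≤ 0.0002 and
  π<sub>ind</sub> ≤ 0.0002 and D<sub>jap-ind</sub> ≥ 0.002;
* **DR-II** (shared sweep): π<sub>jap</sub>, π<sub>ind</sub> and
  D<sub>jap-ind</sub> all ≤ 0.0002 while wild π ≥ 0.001.

Adjacent same-type windows are merged into blocks; a single intervening
window failing only the cultivar-π ceiling may be absorbed if its π stays
≤ 0.0003. Blocks are then characterized with near-fixed markers (sites
where ≥ 80% of each subspecies carries a different allele), Nei–Gojobori
(1986) Ka/Ks with Jukes–Cantor correction and a Yates-corrected χ²
enrichment test for positive selection, Tajima's D with empirical
genome-wide 5% significance, Weir–Cockerham (1984) F<sub>ST</sub> with a
label-permutation test, and neighbor-joining trees (JC distances, pairwise
deletion, bootstrap support) with an identity ranking of wild accessions
against the cultivar consensus.

A seeded simulator (`ricesweep.simulate`) generates VCF + sample table +
truth BED with the population structure the scan assumes (wild π ≈ 0.0067,
*japonica* π ≈ 0.00196, *indica* π ≈ 0.00265, D<sub>xy</sub> ≈ 0.00617,
implanted DR-I/DR-II regions), so the whole pipeline is testable without
any data download. The package also bundles the published inventory of
28 DR-I and 28 DR-II blocks from 355 resequenced accessions
(`ricesweep.tables`) as a worked example.

## Worked example

The numbered drivers under `analysis/` run the full study on simulated
data (seed 1) and write their tables under `results/`:

```bash
python analysis/01_simulate.py          # generate the dataset
python analysis/02_filter_select.py     # SNP filters + purity screen
python analysis/03_scan.py              # windowed scan -> DR blocks
python analysis/04_popgen.py            # Tajima's D, Fst, Ka/Ks
python analysis/05_phylo.py             # NJ trees + identity ranking
python analysis/06_published_inventory.py
```

`03_scan.py` prints:

```
400 windows scanned; 3 DR-I and 3 DR-II blocks
recovered == implanted: True
```

— every implanted region is recovered exactly, with no false positives.
`04_popgen.py` shows the two classes behave as the model predicts (DR-I
mean F<sub>ST</sub> 0.996 with permutation p < 0.05 in every block; DR-II
mean F<sub>ST</sub> 0.001; Tajima's D negative in every swept block), and
`05_phylo.py` shows the tree topology classes (DR-I: *japonica* and
*indica* clades separate; DR-II: one cultivar clade containing the wild
donor accession, which ranks first by consensus identity, 1.000).

`06_published_inventory.py` recomputes the published summary figures from
the bundled block inventory:

```
DR-I : 28 blocks, mean 31.8 kb, max 198 kb, total 0.89 Mb, mean pi_jap 0.00013, mean Dxy 0.0034
DR-II: 28 blocks, mean 23.0 kb, total 0.64 Mb, wild/cultivar diversity ratio 19.9-fold
within-japonica diversity, DR-II vs DR-I blocks: t=2.28 (df=54), two-sided P=0.0267
```

A command-line interface mirrors the stages (`ricesweep simulate|filter|
select-samples|scan|run|report`); `ricesweep run --config run.yaml` drives
the whole pipeline from one YAML file.

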