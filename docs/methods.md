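# Methods

## Statistics and definitions

**Diversity and divergence.** All statistics operate on a sites × samples
matrix of collapsed allele codes. Rice cultivars are highly inbred, so each
diploid genotype is collapsed to one allele: homozygous calls keep their
allele index, heterozygous calls become missing under the default policy
(residual hets in inbred lines are mostly artifacts; a `random`-allele
policy is available, and the collapsed fraction is logged). The pairwise
distance between two samples over a region is the count of SNPs where both
are non-missing and differ, divided by the physical region length; π of a
group is the mean over within-group pairs and D<sub>xy</sub> the mean over
cross-group pairs. Pairs missing at a site contribute no difference there
but keep the full length denominator — the same convention as dividing
"SNP numbers by the corresponding region length". The denominator is the
window length minus any masked bp. Multiallelic sites are retained; all
computations compare allele codes, not binary alt indicators.

**Filters.** Sites with QUAL < 50 are removed, calls with DP < 3 set
missing, and sites with minor-allele frequency < 5% (over non-missing
allele copies, after the depth step) removed. Boundaries are strict
exclusions; equality is retained. Filtering is idempotent and commutes
with masking (property-tested).

**Window classification.** The genome is tiled gap-free into 10-kb windows
(terminal partial windows keep their true length). A window is DR-I when
π<sub>jap</sub> ≤ 2×10⁻⁴, π<sub>ind</sub> ≤ 2×10⁻⁴ and
D<sub>jap-ind</sub> ≥ 2×10⁻³; DR-II when the two π and D<sub>jap-ind</sub>
are all ≤ 2×10⁻⁴ and wild π ≥ 10⁻³. The threshold gap guarantees the
classes are disjoint, and the constructor enforces it. Inclusive
boundaries are used (the source text mixes ≤/< across sections; the
Methods-text inclusive form was adopted and all cutoffs are configurable).
Windows with masked fraction > 20% or fewer than two mean callable
samples in a required group are *unclassifiable* rather than negative, so
they can neither extend nor silently split blocks.

**Block merging.** Maximal runs of adjacent same-type windows merge into
blocks. One intervening window per gap may be absorbed iff it fails only
the cultivar-π ceilings, its π values are ≤ 3×10⁻⁴ (the relaxed ceiling
that the published inventory flags with an asterisk), and both flanking
windows qualify; absorbed windows set the block's `relaxed` flag. How many
windows the original procedure could bridge is unstated; one-per-gap with
qualifying flanks is the most conservative reading that still reproduces
the flagged blocks' ≤ 3×10⁻⁴ ceiling. Block statistics are
effective-length-weighted means of member windows; block length is
end − start + 1 (1-based inclusive internally, BED 0-based half-open on
disk).

**Sample screening.** For each cultivar, π₁ is its mean distance to the
other members of its labeled group and D<sub>xy1</sub> its mean distance
to the other subspecies, both over the whole genome length (the original
denominator is unstated; the package mirrors its own π definition).
π₁ ≥ D<sub>xy1</sub> flags the sample non-typical (exclusion), equality
included. The PCA screen (mean-imputed, centered allele codes, SVD) flags
samples outside a configurable Mahalanobis radius of their group centroid
on PC1/PC2; it reports rather than auto-excludes, because the original
"not clustered" criterion was visual. Distances never impute missing data;
only PCA does.

**Near-fixed markers and Ka/Ks.** A site is a near-fixed marker when ≥ 80%
of non-missing *japonica* calls share one allele, ≥ 80% of *indica* calls
share another, and the two differ. Group-consensus coding sequences are
built by substituting each in-gene marker's group-major base into the
reference CDS (minus-strand genes complemented via the exon coordinate
map); substitutions creating premature stops are kept but flagged. Ka and
Ks follow Nei–Gojobori (1986): per-codon synonymous site fractions
averaged over the two sequences; difference counts averaged over all
minimum-length mutational pathways, skipping pathways through stop codons
unless all pass through one; Jukes–Cantor correction
d = −(3/4)·ln(1 − 4p/3) applied to pn and ps, reported saturated when
p ≥ 3/4. A gene is called positively selected when Ka/Ks > 1 or Ks = 0
with Ka > 0. Enrichment of positive selection in a region uses the
Yates-corrected χ² (df = 1) on the 2×2 table region × positive, with the
correction floored at zero. Genes overlapping a block by ≥ 1 bp count as
in it.

**Tajima's D and F<sub>ST</sub>.** D is the 1989 statistic computed from
segregating-site counts and mean pairwise differences (pairwise-complete;
undefined when S = 0), with significance from the empirical two-tailed
2.5%/97.5% quantiles of per-window D across the genome ("5% confidence
interval" is ambiguous; two-tailed was chosen since both tails are
interpreted). F<sub>ST</sub> is Weir–Cockerham 1984 for haploid-coded
samples — θ = Σ(MSP − MSG) / Σ(MSP + (n_c − 1)·MSG) over sites and
alleles — with significance from label permutations,
p = (1 + #{θ\* ≥ θ}) / (n_perm + 1). This substitutes a permutation test
for the original AMOVA-based significance; the estimator itself is the
VCFtools default.

**Phylogenies and identity ranking.** Distances are computed on SNP
columns only (mismatch proportion over pairwise-complete sites, JC
transform), so branch lengths are inflated relative to per-bp rates and
only topology, support and ranking are interpreted. Neighbor joining uses
the Studier–Keppler Q criterion with deterministic lexicographic
tie-breaking; negative branch estimates are clamped to zero and counted.
Bootstrap support resamples SNP columns with replacement; support is the
fraction of successful replicates containing each internal bipartition of
the point tree (replicates with saturated distances are dropped from the
denominator). Identity ranking scores each wild accession by the fraction
of its non-missing sites matching the per-site majority allele of the
cultivar group over the DR regions; consensus ties skip the site;
accessions with zero scored sites are reported unranked. This
majority-consensus score is a reconstruction — the original identity
measure was not formally defined.

## The synthetic-data generator

The generator samples per-site population frequencies rather than running
a coalescent: this is orders of magnitude faster, fully analytic for
calibration, and sufficient to realize the π/D<sub>xy</sub>/SFS structure
the thresholds test. Each candidate site (density ~1 per 36 bp at default
targets) draws a wild allele frequency q from a neutral 1/i spectrum on
2·n_wild copies. Wild samples draw alleles Bernoulli(q) independently. Per
site, the cultivar groups experience either a shared fixation (probability
a, same allele in both groups), an independent per-group fixation
(probability b_g), or retention of the wild frequency. Solving the
expectations

    E[π_wild] = D·E[2q(1−q)],  E[Dxy] = E[π_wild]·(1−a),
    E[π_g]    = E[Dxy]·(1−b_g)

for (a, b_jap, b_ind, D) makes the realized whole-genome statistics hit
the configured targets — by default the study-scale estimates π_jap
0.00196, π_ind 0.00265, π_wild 0.0067, D<sub>xy</sub> 0.00617. The
observation model (2% missing calls, 0.5% artifact heterozygotes that
collapse to missing, Poisson depths with a depth-3 floor, a small
low-QUAL fraction) dilutes measured pairwise rates by ≈ (1 − loss)²; the
mixture weights and site density are pre-compensated so observed rates
center on the targets (background-window means verify this within
sampling error in the test suite).

Implanted DR-I regions fix each cultivar group for a different
Bernoulli(q) haplotype (expected D<sub>xy</sub> equals wild π, far above
the 0.002 floor); DR-II regions fix both groups for one haplotype that a
designated wild "donor" accession also carries, recording the
introgression direction in the truth table. Residual within-sweep noise
is per-call flipping at 10⁻³, keeping residual π ≈ 5×10⁻⁵, below the
2×10⁻⁴ ceiling. The admixture switch appends cultivars labeled *japonica*
built as site mosaics of one *japonica* and one *indica* parent line with
a configurable *indica* fraction (default 0.65). A 50:50 mosaic provably
sits on the *retain* side of the π₁ ≥ D<sub>xy1</sub> rule whenever
π_jap < π_ind — which is presumably why the original screen pairs the
rule with PCA — so the default is biased to let the rule itself catch the
implants; set 0.5 to study the boundary case.

Default scale is a desk genome of 2 chromosomes × 2 Mb with 30 + 30
cultivars, 12 wild and 4 outgroup samples (~10⁵ sites, seconds to
generate); tests use a 2 × 0.4 Mb variant. What the generator does *not*
emulate: linkage disequilibrium and recombination maps (sites are
exchangeable), gene conversion, demographic history beyond the one-step
bottleneck mixture, depth-correlated genotyping error, or codon-level
selection inside genes. Passing tests therefore demonstrate that the scan
recovers regions with the stated diversity geometry under realistic
missingness — not that the thresholds are optimal against LD-structured
noise or real demography.

## Numerical and design notes

* MAF for multiallelic sites is 1 − max allele frequency.
* π/D<sub>xy</sub> per window use exact pair counting via allele-count
  identities ((k² − Σc²)/2 within, k_a·k_b − Σc_a c_b across), so results
  equal the all-pairs brute force to machine precision.
* The NJ tie-break (lexicographically smallest cluster-label pair at equal
  Q) makes tree output invariant to taxon input order; additive matrices
  are inverted exactly (path-length matrix equals input to 1e-9).
* Empty regions: π of a window with no SNPs is 0 (a legitimate monomorphic
  observation), but DR classification additionally requires wild π or
  D<sub>xy</sub> floors, so all-zero windows are never called.
* The bundled block inventory stores the published per-block columns as
  printed (integers × 10⁻⁵); summaries recomputed from it reproduce the
  published mean/max/total lengths exactly and the mean diversities to
  printed precision. The between-class t-test on the printed columns
  (pooled, two-sided, per the package contract; sidedness of the original
  is unstated) gives P = 0.027 — the original P = 0.011 was evidently
  computed from unrounded values. The published enrichment χ² of 32.4 is
  not recoverable from the published counts; the standard Yates formula
  gives 48.3, which the package reports (the qualitative conclusion,
  P < 10⁻⁴, is unchanged).
* Pipeline stages are pure functions of inputs plus named seeds; the run
  manifest records output checksums, and repeated runs are bit-identical.
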