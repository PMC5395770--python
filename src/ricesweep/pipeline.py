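"""End-to-end orchestration: filter -> select-samples -> scan -> popstats
-> kaks -> tree -> report, from a single validated configuration.

Every stage is a pure function of its inputs plus named seeds; re-running
with the same config reproduces deterministic outputs bit for bit.
"""
from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as rio
from . import phylo, popgen, samples as rsamples, scan


@dataclass
class RunConfig:
    vcf: str
    sample_table: str
    chrom_lengths: str              # FASTA .fai or 2-column TSV
    out_dir: str
    gff: str | None = None
    cds_fasta: str | None = None
    mask: str | None = None
    window_size: int = 10_000
    min_qual: float = 50.0
    min_depth: int = 3
    min_maf: float = 0.05
    thresholds: scan.Thresholds = field(default_factory=scan.Thresholds)
    n_permutations: int = 200
    n_bootstrap: int = 200
    kaks_enabled: bool = True
    tree_enabled: bool = True
    apply_purity: bool = False      # drop excluded cultivars before the scan
    seed: int = 0

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh)
        th = raw.pop("thresholds", None)
        cfg = cls(**raw)
        if th:
            cfg.thresholds = scan.Thresholds(**th)
        return cfg

    def validate(self) -> None:
        for name in ("vcf", "sample_table", "chrom_lengths"):
            p = getattr(self, name)
            if not Path(p).exists():
                raise FileNotFoundError(f"{name}: {p}")
        if self.kaks_enabled:
            if not self.gff or not Path(self.gff).exists():
                raise FileNotFoundError("kaks enabled but gff missing")
            if not self.cds_fasta or not Path(self.cds_fasta).exists():
                raise FileNotFoundError("kaks enabled but cds_fasta missing")
        if self.mask and not Path(self.mask).exists():
            raise FileNotFoundError(f"mask: {self.mask}")


@dataclass
class RunReport:
    filter_report: dict
    purity: pd.DataFrame
    dr_summary: pd.DataFrame
    blocks: list
    block_stats: pd.DataFrame
    kaks: pd.DataFrame | None
    enrichment: dict | None
    trees: dict
    manifest: dict


def _checksum(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()[:16]


def run_pipeline(config: RunConfig) -> RunReport:
    config.validate()
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    st = rio.SampleTable.from_tsv(config.sample_table)
    chrom_lengths = rio.read_chrom_lengths(config.chrom_lengths)
    genome_length = sum(chrom_lengths.values())

    gm = rio.read_vcf(config.vcf, st)
    gm, freport = rio.filter_snps(gm, config.min_qual, config.min_depth,
                                  config.min_maf)
    mask = rio.MaskSet.from_bed(config.mask) if config.mask else None
    if mask:
        gm = rio.apply_mask(gm, mask)

    # sample screen
    purity_rows = []
    for focal, other in (("japonica", "indica"), ("indica", "japonica")):
        for r in rsamples.purity_classify(gm, st, focal, other,
                                          genome_length):
            purity_rows.append({**r.to_dict(), "group": focal})
    purity = pd.DataFrame(purity_rows)
    purity.to_csv(out / "purity.tsv", sep="\t", index=False)
    pca_res = rsamples.pca(gm, 2)
    rsamples.flag_outliers(pca_res, st)
    pca_res.coords.to_csv(out / "pca.tsv", sep="\t")

    if config.apply_purity:
        excluded = set(purity.loc[purity["decision"] == "exclude",
                                  "sample_id"])
        keep = [s for s in st.sample_ids if s not in excluded]
        kept_idx = [st.sample_ids.index(s) for s in keep]
        st = rio.SampleTable(st.df.iloc[kept_idx])
        gm = rio.GenotypeMatrix(gm.chrom, gm.pos, gm.ref, gm.alt, gm.qual,
                                gm.codes[:, kept_idx],
                                gm.depth[:, kept_idx], st)

    # scan
    windows = scan.make_windows(chrom_lengths, config.window_size)
    stats = scan.window_stats(gm, st, windows, mask)
    labeled = scan.classify_windows(stats, config.thresholds)
    labeled.to_csv(out / "window_stats.tsv", sep="\t", index=False)
    blocks = scan.merge_blocks(labeled, config.thresholds)
    rio.write_blocks(blocks, out / "dr_blocks.bed")
    dr_summary = scan.summarize_blocks(blocks)
    dr_summary.to_csv(out / "dr_summary.tsv", sep="\t", index=False)

    # per-block popgen stats (Tajima's D per group, Fst jap-ind)
    dwin = {g: popgen.tajimas_d_windows(gm, st, g, windows)
            for g in ("japonica", "indica", "cultivar")}
    tails = {g: popgen.empirical_tails(dwin[g]) for g in dwin}
    rows = []
    rng = np.random.default_rng(config.seed)
    for b in blocks:
        region = (b.chrom, b.start, b.end)
        row = {"type": b.type, "chrom": b.chrom, "start": b.start,
               "end": b.end, "relaxed": b.relaxed}
        for g in ("japonica", "indica", "cultivar"):
            try:
                r = popgen.tajimas_d(gm, st, g, region)
                row[f"tajima_d_{g}"] = r.d
                lo, hi = tails[g]
                row[f"tajima_sig_{g}"] = bool(np.isfinite(r.d)
                                              and (r.d < lo or r.d > hi))
            except ValueError:
                row[f"tajima_d_{g}"] = float("nan")
                row[f"tajima_sig_{g}"] = False
        fst = popgen.fst_wc(gm, st, "japonica", "indica", region,
                            n_perm=config.n_permutations,
                            seed=int(rng.integers(2 ** 31)))
        row["fst"] = fst.estimate
        row["fst_p"] = fst.p_value
        rows.append(row)
    block_stats = pd.DataFrame(rows)
    block_stats.to_csv(out / "block_stats.tsv", sep="\t", index=False)

    # Ka/Ks on near-fixed markers within DR-I genes
    kaks_df = None
    enrichment = None
    if config.kaks_enabled:
        from . import genes as rgenes
        models = rgenes.read_gff3(config.gff)
        cds = rgenes.read_cds_fasta(config.cds_fasta)
        markers = popgen.near_fixed_markers(gm, st)
        site_of = {(c, p): i for i, (c, p) in
                   enumerate(zip(gm.chrom, gm.pos))}
        krows = []
        dr1_blocks = [b for b in blocks if b.type == "DR-I"]
        for g in models:
            if g.gene_id not in cds:
                continue
            in_dr1 = any(g.overlaps(b.chrom, b.start, b.end)
                         for b in dr1_blocks)
            gm_markers = [m for m in markers if m.chrom == g.chrom
                          and g.genome_to_cds(m.pos) is not None]

            def base_of(mk, which):
                i = site_of[(mk.chrom, mk.pos)]
                return rgenes.marker_base(str(gm.ref[i]), gm.alt[i], mk,
                                          which)

            seq_a, stop_a = rgenes.consensus_cds(
                g, cds[g.gene_id], gm_markers, lambda m: base_of(m, "a"))
            seq_b, stop_b = rgenes.consensus_cds(
                g, cds[g.gene_id], gm_markers, lambda m: base_of(m, "b"))
            res = popgen.kaks_ng86(seq_a, seq_b, g.gene_id)
            krows.append({"gene_id": g.gene_id, "in_dr1": in_dr1,
                          "n_markers": len(gm_markers),
                          "ka": res.ka, "ks": res.ks,
                          "positive": res.positive,
                          "premature_stop": stop_a or stop_b
                          or res.premature_stop})
        kaks_df = pd.DataFrame(krows)
        if len(kaks_df):
            kaks_df.to_csv(out / "kaks.tsv", sep="\t", index=False)
            n_pos_r = int(kaks_df.loc[kaks_df["in_dr1"], "positive"].sum())
            n_r = int(kaks_df["in_dr1"].sum())
            n_pos_g = int(kaks_df["positive"].sum())
            n_g = len(kaks_df)
            try:
                chi2, p = popgen.positive_selection_enrichment(
                    n_pos_r, n_r, n_pos_g, n_g)
                enrichment = {"chi2": chi2, "p": p, "n_pos_region": n_pos_r,
                              "n_region": n_r, "n_pos_genome": n_pos_g,
                              "n_genome": n_g}
            except ValueError:
                enrichment = None

    # NJ trees on DR-I / DR-II SNPs
    trees = {}
    if config.tree_enabled:
        for t in ("DR-I", "DR-II"):
            regions = [(b.chrom, b.start, b.end) for b in blocks
                       if b.type == t]
            if not regions:
                continue
            tr = phylo.bootstrap_support(
                gm, regions=regions, n_reps=config.n_bootstrap,
                seed=int(rng.integers(2 ** 31)))
            (out / f"tree_{t.replace('-', '').lower()}.nwk").write_text(
                tr.newick())
            trees[t] = tr
            ranking = phylo.identity_rank(
                gm, st, "cultivar" if t == "DR-II" else "japonica", regions)
            ranking.to_csv(out / f"identity_{t.replace('-', '').lower()}.tsv",
                           sep="\t", index=False)

    manifest = {
        "seed": config.seed,
        "window_size": config.window_size,
        "n_sites_filtered": gm.n_sites,
        "outputs": {p.name: _checksum(p) for p in sorted(out.iterdir())
                    if p.is_file()},
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))
    return RunReport(filter_report=freport.to_dict(), purity=purity,
                     dr_summary=dr_summary, blocks=blocks,
                     block_stats=block_stats, kaks=kaks_df,
                     enrichment=enrichment, trees=trees, manifest=manifest)
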