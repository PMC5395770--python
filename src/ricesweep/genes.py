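"""Gene models (GFF3) and group-consensus coding sequences.

A :class:`GeneModel` holds the ordered CDS exons of one gene; genomic
positions map into CDS coordinates with strand handling, so near-fixed
markers can be substituted into the reference CDS to build per-group
consensus sequences for Ka/Ks.

Only phase-0 CDS models are supported (the synthetic gene models used for
validation are phase-0 single- or multi-exon genes).
"""
from __future__ import annotations

from dataclasses import dataclass

import pandas as pd
from Bio import SeqIO
from Bio.Seq import Seq

_COMPLEMENT = str.maketrans("ACGTacgt", "TGCAtgca")


@dataclass
class GeneModel:
    gene_id: str
    chrom: str
    strand: str                      # '+' | '-'
    exons: list[tuple[int, int]]     # CDS exons, 1-based inclusive, sorted

    @property
    def span(self) -> tuple[int, int]:
        return self.exons[0][0], self.exons[-1][1]

    @property
    def cds_length(self) -> int:
        return sum(e - s + 1 for s, e in self.exons)

    def genome_to_cds(self, pos: int) -> int | None:
        """0-based CDS coordinate of a genomic position, or None if the
        position falls outside the CDS exons."""
        off = 0
        for s, e in self.exons:
            if s <= pos <= e:
                fwd = off + (pos - s)
                if self.strand == "+":
                    return fwd
                return self.cds_length - 1 - fwd
            off += e - s + 1
        return None

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        s, e = self.span
        return self.chrom == chrom and s <= end and e >= start


def read_gff3(path) -> list[GeneModel]:
    """Load CDS gene models from GFF3 (CDS features grouped by Parent/ID)."""
    rows = []
    with open(path) as fh:
        for line in fh:
            if not line.strip() or line.startswith("#"):
                continue
            f = line.rstrip("\n").split("\t")
            if len(f) < 9 or f[2] != "CDS":
                continue
            attrs = dict(kv.split("=", 1) for kv in f[8].split(";") if "=" in kv)
            gene = attrs.get("Parent", attrs.get("ID", ""))
            rows.append((gene, f[0], f[6], int(f[3]), int(f[4])))
    df = pd.DataFrame(rows, columns=["gene", "chrom", "strand", "start", "end"])
    out = []
    for gene, sub in df.groupby("gene", sort=True):
        sub = sub.sort_values("start")
        out.append(GeneModel(
            gene_id=gene, chrom=sub["chrom"].iloc[0],
            strand=sub["strand"].iloc[0],
            exons=list(zip(sub["start"], sub["end"]))))
    return out


def read_cds_fasta(path) -> dict[str, str]:
    return {rec.id: str(rec.seq).upper()
            for rec in SeqIO.parse(str(path), "fasta")}


def consensus_cds(gene: GeneModel, ref_cds: str, markers, allele_of,
                  ) -> tuple[str, bool]:
    """Substitute group-major marker alleles into the reference CDS.

    `markers` is an iterable of NearFixedMarker; `allele_of(marker)` returns
    the base (ACGT string) the group carries at that site, or None to skip.
    Returns (sequence, premature_stop_flag); minus-strand substitutions are
    complemented (the reference CDS is already in transcript orientation).
    """
    if len(ref_cds) != gene.cds_length:
        raise ValueError(
            f"{gene.gene_id}: CDS length {len(ref_cds)} != model "
            f"{gene.cds_length}")
    seq = list(ref_cds)
    for m in markers:
        if m.chrom != gene.chrom:
            continue
        ci = gene.genome_to_cds(m.pos)
        if ci is None:
            continue
        base = allele_of(m)
        if base is None:
            continue
        if gene.strand == "-":
            base = base.translate(_COMPLEMENT)
        seq[ci] = base
    new = "".join(seq)
    stop = False
    prot = str(Seq(new).translate())
    if "*" in prot[:-1]:
        stop = True
    return new, stop


def marker_base(gm_ref, gm_alt, marker, which: str) -> str | None:
    """Base string of the marker's group-major allele ('a' or 'b') given the
    site's REF string and ALT tuple."""
    code = marker.allele_a if which == "a" else marker.allele_b
    if code == 0:
        return gm_ref
    try:
        return gm_alt[code - 1]
    except IndexError:
        return None
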