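"""Jukes-Cantor distances, neighbor-joining trees with bootstrap support,
and identity ranking of wild accessions against cultivar consensus.

Distances are computed on SNP columns only (mismatch proportion over
pairwise-complete sites, JC-transformed), as in a MEGA-on-SNP-matrix
workflow; absolute branch lengths are therefore inflated relative to per-bp
rates and only topology, support and ranking are interpreted.
"""
from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SampleTable
from .samples import pairwise_diff_counts


# --- distances ---------------------------------------------------------------


@dataclass
class DistanceMatrix:
    taxa: list[str]
    d: np.ndarray                 # JC distances; nan where undefined
    p: np.ndarray                 # raw mismatch proportions
    comparable: np.ndarray        # per-pair count of pairwise-complete sites

    def undefined_pairs(self) -> list[tuple[str, str]]:
        out = []
        n = len(self.taxa)
        for i in range(n):
            for j in range(i + 1, n):
                if not np.isfinite(self.d[i, j]):
                    out.append((self.taxa[i], self.taxa[j]))
        return out


def jc_transform(p: np.ndarray) -> np.ndarray:
    """Elementwise JC69 correction; nan at/beyond saturation (p >= 3/4)."""
    with np.errstate(invalid="ignore", divide="ignore"):
        safe = np.clip(p, 0.0, 0.7499999)
        return np.where(p < 0.75, -0.75 * np.log1p(-4.0 * safe / 3.0), np.nan)


def jc_distances(gm: GenotypeMatrix, taxa: list[str] | None = None,
                 regions=None) -> DistanceMatrix:
    """Pairwise JC distances over SNP columns in `regions` (all when None),
    with pairwise deletion of missing data."""
    ids = gm.samples.sample_ids
    if taxa is None:
        taxa = ids
    idx = [ids.index(t) for t in taxa]
    if len(idx) < 2:
        raise ValueError("need >= 2 taxa")
    if regions is not None:
        m = np.zeros(gm.n_sites, dtype=bool)
        for chrom, start, end in regions:
            m |= gm.sites_in(chrom, start, end)
        codes = gm.codes[m][:, idx]
    else:
        codes = gm.codes[:, idx]
    diffs, comp = pairwise_diff_counts(codes)
    with np.errstate(invalid="ignore", divide="ignore"):
        p = np.where(comp > 0, diffs / comp, np.nan)
    np.fill_diagonal(p, 0.0)
    d = jc_transform(p)
    np.fill_diagonal(d, 0.0)
    return DistanceMatrix(taxa=list(taxa), d=d, p=p, comparable=comp)


# --- trees -------------------------------------------------------------------


@dataclass
class TreeNode:
    name: str | None = None
    children: list[tuple["TreeNode", float]] = field(default_factory=list)
    support: float | None = None

    def leaves(self) -> list[str]:
        if not self.children:
            return [self.name]
        out = []
        for c, _ in self.children:
            out.extend(c.leaves())
        return out

    def newick(self, with_support: bool = True) -> str:
        return self._nwk(with_support) + ";"

    def _nwk(self, ws: bool) -> str:
        if not self.children:
            return self.name
        inner = ",".join(f"{c._nwk(ws)}:{bl:.6g}" for c, bl in self.children)
        lab = ""
        if ws and self.support is not None:
            lab = f"{self.support:.3g}"
        return f"({inner}){lab}"


@dataclass
class Tree:
    root: TreeNode
    taxa: list[str]
    negative_branches_clamped: int = 0
    supports: dict[frozenset, float] = field(default_factory=dict)

    def newick(self, with_support: bool = True) -> str:
        return self.root.newick(with_support)

    def bipartitions(self) -> set[frozenset]:
        """Non-trivial bipartitions, each encoded as the frozenset of the
        side not containing the first taxon."""
        all_taxa = set(self.taxa)
        ref = self.taxa[0]
        out = set()

        def rec(node):
            if not node.children:
                return {node.name}
            below = set()
            for c, _ in node.children:
                sub = rec(c)
                side = sub if ref not in sub else all_taxa - sub
                if 1 < len(side) < len(all_taxa) - 1:
                    out.add(frozenset(side))
                below |= sub
            return below

        rec(self.root)
        return out


def nj_tree(dm: DistanceMatrix) -> Tree:
    """Neighbor joining (Saitou-Nei via Studier-Keppler Q criterion).

    Ties in Q are broken by the lexicographically smallest (min-name,
    max-name) pair of cluster labels, so output is independent of taxon
    input order. Negative branch lengths are clamped to zero and counted.
    """
    if dm.undefined_pairs():
        raise ValueError(f"undefined distances: {dm.undefined_pairs()[:3]}")
    n0 = len(dm.taxa)
    if n0 < 2:
        raise ValueError("need >= 2 taxa")
    if n0 == 2:
        a, b = (TreeNode(name=t) for t in dm.taxa)
        half = dm.d[0, 1] / 2
        root = TreeNode(children=[(a, half), (b, half)])
        warnings.warn("degenerate 2-taxon tree")
        return Tree(root=root, taxa=list(dm.taxa))

    nodes = [TreeNode(name=t) for t in dm.taxa]
    labels = [(t,) for t in dm.taxa]       # sorted leaf tuples as tie-break key
    D = dm.d.copy().astype(float)
    active = list(range(n0))
    clamped = 0
    while len(active) > 2:
        m = len(active)
        idx = np.array(active)
        sub = D[np.ix_(idx, idx)]
        r = sub.sum(axis=1)
        Q = (m - 2) * sub - r[:, None] - r[None, :]
        np.fill_diagonal(Q, np.inf)
        qmin = Q.min()
        ties = np.argwhere(np.isclose(Q, qmin, rtol=0, atol=1e-12))
        best = None
        for i, j in ties:
            if i >= j:
                continue
            key = tuple(sorted((min(labels[idx[i]]), min(labels[idx[j]]))))
            if best is None or key < best[0]:
                best = (key, int(i), int(j))
        _, bi, bj = best
        a, b = idx[bi], idx[bj]
        dab = D[a, b]
        la = 0.5 * dab + (r[bi] - r[bj]) / (2 * (m - 2))
        lb = dab - la
        if la < 0:
            clamped += 1
            lb = max(dab, 0.0)
            la = 0.0
        if lb < 0:
            clamped += 1
            la = max(dab, 0.0)
            lb = 0.0
        new = TreeNode(children=[(nodes[a], la), (nodes[b], lb)])
        nodes.append(new)
        labels.append(tuple(sorted(labels[a] + labels[b])))
        k = len(nodes) - 1
        D = np.pad(D, ((0, 1), (0, 1)))
        for c in active:
            if c in (a, b):
                continue
            D[k, c] = D[c, k] = 0.5 * (D[a, c] + D[b, c] - dab)
        active = [c for c in active if c not in (a, b)] + [k]
    a, b = active
    root = TreeNode(children=[(nodes[a], max(D[a, b], 0.0) / 2),
                              (nodes[b], max(D[a, b], 0.0) / 2)])
    if D[a, b] < 0:
        clamped += 1
    return Tree(root=root, taxa=sorted(dm.taxa),
                negative_branches_clamped=clamped)


def path_length_matrix(tree: Tree) -> tuple[list[str], np.ndarray]:
    """Leaf-to-leaf path lengths (for additivity checks)."""
    dists: dict[str, dict[str, float]] = {}

    def rec(node) -> dict[str, float]:
        if not node.children:
            return {node.name: 0.0}
        subs = []
        for c, bl in node.children:
            sub = rec(c)
            subs.append({k: v + bl for k, v in sub.items()})
        for i in range(len(subs)):
            for j in range(i + 1, len(subs)):
                for x, dx in subs[i].items():
                    for y, dy in subs[j].items():
                        dists.setdefault(x, {})[y] = dx + dy
                        dists.setdefault(y, {})[x] = dx + dy
        out = {}
        for s in subs:
            out.update(s)
        return out

    rec(tree.root)
    taxa = sorted(dists)
    M = np.zeros((len(taxa), len(taxa)))
    for i, x in enumerate(taxa):
        for j, y in enumerate(taxa):
            if i != j:
                M[i, j] = dists[x][y]
    return taxa, M


def bootstrap_support(gm: GenotypeMatrix, taxa: list[str] | None = None,
                      regions=None, n_reps: int = 1000,
                      seed: int | None = None) -> Tree:
    """Point NJ tree with bootstrap supports on internal bipartitions.

    SNP columns are resampled with replacement per replicate; support is
    the fraction of replicate trees containing each internal bipartition
    of the point tree.
    """
    ids = gm.samples.sample_ids
    if taxa is None:
        taxa = ids
    idx = [ids.index(t) for t in taxa]
    if regions is not None:
        m = np.zeros(gm.n_sites, dtype=bool)
        for chrom, start, end in regions:
            m |= gm.sites_in(chrom, start, end)
        codes = gm.codes[m][:, idx]
    else:
        codes = gm.codes[:, idx]

    def dm_from(cols: np.ndarray) -> DistanceMatrix:
        diffs, comp = pairwise_diff_counts(cols)
        with np.errstate(invalid="ignore", divide="ignore"):
            p = np.where(comp > 0, diffs / comp, np.nan)
        np.fill_diagonal(p, 0.0)
        d = jc_transform(p)
        np.fill_diagonal(d, 0.0)
        return DistanceMatrix(list(taxa), d, p, comp)

    point = nj_tree(dm_from(codes))
    parts = point.bipartitions()
    hits = {bp: 0 for bp in parts}
    if n_reps > 0:
        rng = np.random.default_rng(seed)
        S = codes.shape[0]
        n_ok = 0
        for _ in range(n_reps):
            cols = codes[rng.integers(0, S, size=S)]
            try:
                t = nj_tree(dm_from(cols))
            except ValueError:       # saturated/undefined replicate
                continue
            n_ok += 1
            got = t.bipartitions()
            for bp in parts:
                if bp in got:
                    hits[bp] += 1
        point.supports = {bp: hits[bp] / max(n_ok, 1) for bp in parts}
        _annotate_supports(point)
    else:
        point.supports = {}
    return point


def _annotate_supports(tree: Tree) -> None:
    all_taxa = set(tree.taxa)
    ref = tree.taxa[0]

    def rec(node) -> set:
        if not node.children:
            return {node.name}
        below = set()
        for c, _ in node.children:
            below |= rec(c)
        side = below if ref not in below else all_taxa - below
        key = frozenset(side)
        if key in tree.supports:
            node.support = tree.supports[key]
        return below

    rec(tree.root)


# --- identity ranking --------------------------------------------------------


def identity_rank(gm: GenotypeMatrix, samples: SampleTable,
                  cultivar_group: str, regions,
                  wild_group: str = "wild") -> pd.DataFrame:
    """Rank wild accessions by identity to the cultivar-group consensus.

    Consensus is the per-site majority allele over the cultivar group
    inside `regions` (ties skip the site). Identity is the fraction of the
    accession's non-missing consensus sites matching the consensus; ranks
    are dense, descending, nan for accessions with zero scored sites.
    """
    ci = samples.indices(cultivar_group)
    if len(ci) == 0:
        raise ValueError(f"empty cultivar group {cultivar_group!r}")
    wi = samples.indices(wild_group)
    m = np.zeros(gm.n_sites, dtype=bool)
    for chrom, start, end in regions:
        m |= gm.sites_in(chrom, start, end)
    codes = gm.codes[m]
    sub = codes[:, ci]
    amax = int(gm.codes.max(initial=0))
    counts = np.zeros((sub.shape[0], amax + 1), dtype=np.int64)
    for a in range(amax + 1):
        counts[:, a] = (sub == a).sum(axis=1)
    top = counts.max(axis=1)
    consensus = counts.argmax(axis=1)
    tied = (counts == top[:, None]).sum(axis=1) > 1
    usable = (top > 0) & ~tied
    rows = []
    ids = samples.sample_ids
    for i in wi:
        w = codes[:, i]
        sc = usable & (w != MISSING)
        n_sites = int(sc.sum())
        ident = (float((w[sc] == consensus[sc]).sum()) / n_sites
                 if n_sites else float("nan"))
        rows.append({"sample_id": ids[i], "identity": ident,
                     "n_sites": n_sites})
    df = pd.DataFrame(rows)
    ranked = df["identity"].rank(ascending=False, method="min")
    df["rank"] = ranked.where(df["n_sites"] > 0)
    return df.sort_values(["rank", "sample_id"]).reset_index(drop=True)
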