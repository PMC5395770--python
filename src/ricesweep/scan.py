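"""Windowed pi/Dxy scan and classification of domesticated regions.

The genome is tiled into fixed-size windows (10 kb by default). Per window
and group we compute nucleotide diversity pi — the mean over within-group
sample pairs of (differing sites)/(window length) — and, per group pair,
the divergence Dxy defined the same way over cross-group pairs. Windows are
then labeled:

* DR-I  : pi(jap) <= 0.0002 and pi(ind) <= 0.0002 and Dxy(jap,ind) >= 0.002
          — both cultigens swept, but fixed for divergent haplotypes;
* DR-II : pi(jap), pi(ind) and Dxy(jap,ind) all <= 0.0002 while wild
          pi >= 0.001 — a single shared sweep against a diverse wild
          background.

Adjacent same-type windows are merged into blocks; one intervening window
that fails only the cultivar-pi ceilings may be absorbed if its pi values
stay below a relaxed ceiling (0.0003) and both flanks qualify.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, MaskSet, SampleTable

PI_GROUPS = ("japonica", "indica", "wild", "cultivar")
DXY_PAIRS = (("japonica", "indica"), ("japonica", "wild"),
             ("indica", "wild"), ("cultivar", "wild"))
SUBGROUP_PI = ("temperate", "tropical")
SUBGROUP_DXY = (("temperate", "indica"), ("tropical", "indica"))


@dataclass(frozen=True)
class Window:
    chrom: str
    start: int   # 1-based inclusive
    end: int

    @property
    def length(self) -> int:
        return self.end - self.start + 1


@dataclass
class Thresholds:
    """Classification cutoffs, per-bp rates."""
    pi_max_cultivar: float = 0.0002
    dxy_min_dr1: float = 0.002
    dxy_max_dr2: float = 0.0002
    pi_min_wild: float = 0.001
    merged_pi_relax: float = 0.0003
    max_masked_fraction: float = 0.2
    min_callable: float = 2.0     # mean callable samples per required group

    def __post_init__(self):
        if not self.dxy_max_dr2 < self.dxy_min_dr1:
            raise ValueError("dxy_max_dr2 must be < dxy_min_dr1 "
                             "(DR-I/DR-II disjointness)")


@dataclass
class DRBlock:
    type: str                 # "DR-I" | "DR-II"
    chrom: str
    start: int
    end: int
    relaxed: bool = False
    stats: dict = field(default_factory=dict)   # length-weighted means
    n_windows: int = 0

    @property
    def length(self) -> int:
        return self.end - self.start + 1


def make_windows(chrom_lengths: dict[str, int], size: int = 10_000
                 ) -> list[Window]:
    """Gap-free, non-overlapping tiling; terminal partial window included."""
    if size <= 0:
        raise ValueError("window size must be positive")
    out = []
    for chrom, L in chrom_lengths.items():
        if L <= 0:
            raise ValueError(f"non-positive length for {chrom}")
        for s in range(1, L + 1, size):
            out.append(Window(chrom, s, min(s + size - 1, L)))
    return out


def _group_site_counts(codes: np.ndarray, idx: np.ndarray
                       ) -> tuple[np.ndarray, np.ndarray]:
    """Per-site allele counts (S x A) and non-missing totals for a group."""
    sub = codes[:, idx]
    amax = int(codes.max(initial=0))
    counts = np.zeros((codes.shape[0], amax + 1), dtype=np.int64)
    for a in range(amax + 1):
        counts[:, a] = (sub == a).sum(axis=1)
    return counts, counts.sum(axis=1)


def _within_diffs(counts: np.ndarray, k: np.ndarray) -> np.ndarray:
    """Number of differing non-missing pairs per site."""
    return (k.astype(np.int64) ** 2 - (counts ** 2).sum(axis=1)) // 2


def _cross_diffs(ca: np.ndarray, ka: np.ndarray,
                 cb: np.ndarray, kb: np.ndarray) -> np.ndarray:
    return ka.astype(np.int64) * kb - (ca * cb).sum(axis=1)


def pi_in_region(gm: GenotypeMatrix, samples: SampleTable, group: str,
                 region: tuple[str, int, int],
                 denom_length: int | None = None) -> float:
    """Within-group pi over a region; denominator is the physical region
    length (optionally overridden, e.g. length minus masked bp)."""
    idx = samples.indices(group)
    if len(idx) < 2:
        raise ValueError(f"group {group!r} needs >= 2 samples for pi")
    chrom, start, end = region
    L = denom_length if denom_length is not None else end - start + 1
    m = gm.sites_in(chrom, start, end)
    counts, k = _group_site_counts(gm.codes[m][:, idx], np.arange(len(idx)))
    d = _within_diffs(counts, k).sum()
    npairs = len(idx) * (len(idx) - 1) // 2
    return float(d) / (npairs * L)


def dxy_in_region(gm: GenotypeMatrix, samples: SampleTable,
                  group_a: str, group_b: str,
                  region: tuple[str, int, int],
                  denom_length: int | None = None) -> float:
    """Cross-group Dxy over a region (mean cross-pair per-bp distance)."""
    ia, ib = samples.indices(group_a), samples.indices(group_b)
    if len(ia) < 1 or len(ib) < 1:
        raise ValueError("both groups must be non-empty for Dxy")
    chrom, start, end = region
    L = denom_length if denom_length is not None else end - start + 1
    m = gm.sites_in(chrom, start, end)
    ca, ka = _group_site_counts(gm.codes[m][:, ia], np.arange(len(ia)))
    cb, kb = _group_site_counts(gm.codes[m][:, ib], np.arange(len(ib)))
    A = max(ca.shape[1], cb.shape[1])
    ca = np.pad(ca, ((0, 0), (0, A - ca.shape[1])))
    cb = np.pad(cb, ((0, 0), (0, A - cb.shape[1])))
    d = _cross_diffs(ca, ka, cb, kb).sum()
    return float(d) / (len(ia) * len(ib) * L)


def window_stats(gm: GenotypeMatrix, samples: SampleTable,
                 windows: list[Window], mask: MaskSet | None = None,
                 include_subgroups: bool = True) -> pd.DataFrame:
    """Per-window pi for each group and Dxy for each group pair.

    Returns one row per window with columns ``pi_<group>``, ``dxy_<a>_<b>``,
    ``masked_fraction``, ``n_snps`` and per-group mean callable sample
    counts ``callable_<group>``. The pi/Dxy denominator is the window length
    minus masked bp.
    """
    groups = [g for g in PI_GROUPS if len(samples.indices(g)) >= 2]
    pairs = [(a, b) for a, b in DXY_PAIRS
             if len(samples.indices(a)) >= 1 and len(samples.indices(b)) >= 1]
    if include_subgroups:
        groups += [g for g in SUBGROUP_PI if len(samples.indices(g)) >= 2]
        pairs += [(a, b) for a, b in SUBGROUP_DXY
                  if len(samples.indices(a)) >= 2
                  and len(samples.indices(b)) >= 1]

    # window index per site
    win_by_chrom: dict[str, list[int]] = {}
    for wi, w in enumerate(windows):
        win_by_chrom.setdefault(w.chrom, []).append(wi)
    site_win = np.full(gm.n_sites, -1, dtype=np.int64)
    for chrom, wis in win_by_chrom.items():
        on = np.flatnonzero(gm.chrom == chrom)
        if len(on) == 0:
            continue
        starts = np.array([windows[w].start for w in wis])
        ends = np.array([windows[w].end for w in wis])
        order = np.argsort(starts)
        starts, ends = starts[order], ends[order]
        wis_sorted = np.array(wis)[order]
        j = np.searchsorted(starts, gm.pos[on], side="right") - 1
        ok = (j >= 0) & (gm.pos[on] <= ends[np.clip(j, 0, None)])
        site_win[on[ok]] = wis_sorted[j[ok]]

    W = len(windows)
    inwin = site_win >= 0
    sw = site_win[inwin]
    nw = np.bincount(sw, minlength=W)

    eff_len = np.empty(W, dtype=np.float64)
    masked_frac = np.zeros(W)
    for wi, w in enumerate(windows):
        mb = mask.masked_bp(w.chrom, w.start, w.end) if mask else 0
        masked_frac[wi] = mb / w.length
        eff_len[wi] = max(w.length - mb, 0)

    data: dict[str, np.ndarray] = {}
    counts_cache: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    for g in set(groups) | {a for a, _ in pairs} | {b for _, b in pairs}:
        idx = samples.indices(g)
        if len(idx) == 0:
            continue
        counts_cache[g] = _group_site_counts(gm.codes[inwin][:, idx],
                                             np.arange(len(idx)))
    for g in groups:
        idx = samples.indices(g)
        counts, k = counts_cache[g]
        d = _within_diffs(counts, k)
        tot = np.bincount(sw, weights=d.astype(float), minlength=W)
        npairs = len(idx) * (len(idx) - 1) / 2
        with np.errstate(divide="ignore", invalid="ignore"):
            data[f"pi_{g}"] = np.where(eff_len > 0,
                                       tot / (npairs * eff_len), np.nan)
        data[f"callable_{g}"] = np.where(
            nw > 0,
            np.bincount(sw, weights=k.astype(float), minlength=W)
            / np.maximum(nw, 1),
            float(len(idx)))
    for a, b in pairs:
        ca, ka = counts_cache[a]
        cb, kb = counts_cache[b]
        A = max(ca.shape[1], cb.shape[1])
        d = _cross_diffs(np.pad(ca, ((0, 0), (0, A - ca.shape[1]))), ka,
                         np.pad(cb, ((0, 0), (0, A - cb.shape[1]))), kb)
        tot = np.bincount(sw, weights=d.astype(float), minlength=W)
        na, nb = len(samples.indices(a)), len(samples.indices(b))
        with np.errstate(divide="ignore", invalid="ignore"):
            data[f"dxy_{a}_{b}"] = np.where(eff_len > 0,
                                            tot / (na * nb * eff_len), np.nan)

    df = pd.DataFrame(data)
    df.insert(0, "chrom", [w.chrom for w in windows])
    df.insert(1, "start", [w.start for w in windows])
    df.insert(2, "end", [w.end for w in windows])
    df["length"] = [w.length for w in windows]
    df["eff_length"] = eff_len
    df["masked_fraction"] = masked_frac
    df["n_snps"] = nw
    return df


def classify_window(row, th: Thresholds) -> tuple[str, str]:
    """Label one window's stats row. Returns (label, reason); label is
    'DR-I', 'DR-II', 'none' or 'unclassifiable'."""
    req = ["pi_japonica", "pi_indica", "dxy_japonica_indica", "pi_wild"]
    vals = {k: row.get(k, np.nan) for k in req}
    if row["masked_fraction"] > th.max_masked_fraction:
        return "unclassifiable", "masked_fraction"
    for g in ("japonica", "indica", "wild"):
        c = row.get(f"callable_{g}", np.nan)
        if not np.isnan(c) and c < th.min_callable and row["n_snps"] > 0:
            return "unclassifiable", f"callable_{g}"
    if any(np.isnan(v) for v in vals.values()):
        return "unclassifiable", "undefined_stat"
    pj, pi_, dxy, pw = (vals[k] for k in req)
    if pj <= th.pi_max_cultivar and pi_ <= th.pi_max_cultivar:
        if dxy >= th.dxy_min_dr1:
            return "DR-I", ""
        if dxy <= th.dxy_max_dr2 and pw >= th.pi_min_wild:
            return "DR-II", ""
    return "none", ""


def classify_windows(stats: pd.DataFrame, th: Thresholds) -> pd.DataFrame:
    out = stats.copy()
    labels, reasons = [], []
    for _, row in stats.iterrows():
        lab, why = classify_window(row, th)
        labels.append(lab)
        reasons.append(why)
    out["label"] = labels
    out["reason"] = reasons
    return out


def _bridge_ok(row, target: str, th: Thresholds) -> bool:
    """May `row` (labeled none) be absorbed into a `target`-type block?

    Only the cultivar-pi ceilings are relaxed (to merged_pi_relax); every
    other condition of the target type must hold as stated.
    """
    if row["label"] != "none":
        return False
    pj, pi_ = row["pi_japonica"], row["pi_indica"]
    dxy, pw = row["dxy_japonica_indica"], row["pi_wild"]
    if np.isnan(pj) or np.isnan(pi_) or np.isnan(dxy):
        return False
    if not (pj <= th.merged_pi_relax and pi_ <= th.merged_pi_relax):
        return False
    if target == "DR-I":
        return dxy >= th.dxy_min_dr1
    return dxy <= th.dxy_max_dr2 and not np.isnan(pw) and pw >= th.pi_min_wild


_AGG_PREFIXES = ("pi_", "dxy_")


def merge_blocks(labeled: pd.DataFrame, th: Thresholds) -> list[DRBlock]:
    """Merge runs of same-type windows into blocks, absorbing single
    bridge windows whose only failure is a mildly elevated cultivar pi."""
    blocks: list[DRBlock] = []
    stat_cols = [c for c in labeled.columns
                 if c.startswith(_AGG_PREFIXES) and not c.startswith("pi_min")]
    for chrom, sub in labeled.groupby("chrom", sort=False):
        sub = sub.sort_values("start").reset_index(drop=True)
        n = len(sub)
        member = np.zeros(n, dtype=bool)
        relax = np.zeros(n, dtype=bool)
        lab = list(sub["label"])
        # mark bridges: none-window between two qualifying windows of the
        # same type, itself admissible under the relaxed cultivar ceilings
        eff = list(lab)
        for i in range(1, n - 1):
            if (lab[i - 1] == lab[i + 1] and lab[i - 1] in ("DR-I", "DR-II")
                    and sub["end"].iloc[i - 1] + 1 == sub["start"].iloc[i]
                    and sub["end"].iloc[i] + 1 == sub["start"].iloc[i + 1]
                    and _bridge_ok(sub.iloc[i], lab[i - 1], th)):
                eff[i] = lab[i - 1]
                relax[i] = True
        i = 0
        while i < n:
            if eff[i] not in ("DR-I", "DR-II"):
                i += 1
                continue
            j = i
            while (j + 1 < n and eff[j + 1] == eff[i]
                   and sub["end"].iloc[j] + 1 == sub["start"].iloc[j + 1]):
                j += 1
            rows = sub.iloc[i:j + 1]
            w = rows["eff_length"].to_numpy().astype(float)
            w = np.where(w > 0, w, 0.0)
            stats = {}
            for c in stat_cols:
                v = rows[c].to_numpy(dtype=float)
                ok = ~np.isnan(v) & (w > 0)
                stats[c] = float((v[ok] * w[ok]).sum() / w[ok].sum()) \
                    if ok.any() else float("nan")
            stats["n_snps"] = int(rows["n_snps"].sum())
            blocks.append(DRBlock(
                type=eff[i], chrom=chrom,
                start=int(rows["start"].iloc[0]),
                end=int(rows["end"].iloc[-1]),
                relaxed=bool(relax[i:j + 1].any()),
                stats=stats, n_windows=j - i + 1))
            i = j + 1
    blocks.sort(key=lambda b: (b.chrom, b.start))
    return blocks


def summarize_blocks(blocks: list[DRBlock]) -> pd.DataFrame:
    """Per-type summary: count, length stats and mean aggregated pi/Dxy."""
    rows = []
    for t in ("DR-I", "DR-II"):
        sel = [b for b in blocks if b.type == t]
        if not sel:
            continue
        L = np.array([b.length for b in sel], dtype=float)
        row = {"type": t, "n_blocks": len(sel),
               "mean_length": float(L.mean()),
               "min_length": float(L.min()),
               "max_length": float(L.max()),
               "total_length": float(L.sum())}
        keys = set()
        for b in sel:
            keys |= {k for k in b.stats if k != "n_snps"}
        for k in sorted(keys):
            v = [b.stats[k] for b in sel
                 if k in b.stats and not np.isnan(b.stats[k])]
            row[f"mean_{k}"] = float(np.mean(v)) if v else float("nan")
        rows.append(row)
    return pd.DataFrame(rows)
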