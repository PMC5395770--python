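"""Sample screening: per-individual pi1/Dxy1 purity rule and a PCA check.

An individual labeled *japonica* whose mean distance to other *japonica*
samples (pi1) is at least its mean distance to *indica* samples (Dxy1) is a
"non-typical" cultivar — most often an admixed line — and is flagged for
exclusion. The PCA screen reports samples lying far from their labeled group
centroid in PC1/PC2; it is reported, never auto-applied.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import MISSING, GenotypeMatrix, SampleTable


def pairwise_diff_counts(codes: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """All-pairs (#differing sites, #pairwise-complete sites) matrices.

    Both counts consider only sites where the two samples are both
    non-missing. O(S*N^2) via one matmul per allele code.
    """
    S, N = codes.shape
    nonmiss = (codes != MISSING)
    M = nonmiss.astype(np.float64)
    comparable = M.T @ M
    match = np.zeros((N, N))
    amax = int(codes.max(initial=0))
    for a in range(amax + 1):
        X = (codes == a).astype(np.float64)
        match += X.T @ X
    diffs = comparable - match
    np.fill_diagonal(diffs, 0.0)
    return diffs, comparable


def pairwise_distance(gm: GenotypeMatrix, a: str, b: str,
                      region_length: int) -> float:
    """Per-bp distance between two samples: differing-site count over the
    physical region length (sites where either call is missing do not
    count as differences)."""
    if region_length <= 0:
        raise ValueError("region_length must be positive")
    ids = gm.samples.sample_ids
    ia, ib = ids.index(a), ids.index(b)
    ca, cb = gm.codes[:, ia], gm.codes[:, ib]
    both = (ca != MISSING) & (cb != MISSING)
    if gm.n_sites and not both.any():
        warnings.warn(f"no overlapping non-missing sites for {a} vs {b}")
        return 0.0
    return float(np.count_nonzero(both & (ca != cb))) / region_length


@dataclass
class PurityRecord:
    sample_id: str
    pi1: float
    dxy1: float
    decision: str   # retain | exclude

    def to_dict(self):
        return dict(self.__dict__)


def purity_classify(gm: GenotypeMatrix, samples: SampleTable,
                    focal_group: str, other_group: str,
                    genome_length: int) -> list[PurityRecord]:
    """Classify each focal-group sample by the pi1 >= Dxy1 exclusion rule.

    pi1 is the mean per-bp distance to every other focal-group sample,
    Dxy1 the mean to every other-group sample; equality excludes.
    """
    fi = samples.indices(focal_group)
    oi = samples.indices(other_group)
    if len(fi) < 2:
        raise ValueError(f"group {focal_group!r} needs >= 2 samples "
                         "(pi1 undefined)")
    if len(oi) < 1:
        raise ValueError(f"group {other_group!r} is empty")
    diffs, _ = pairwise_diff_counts(gm.codes)
    dist = diffs / genome_length
    ids = samples.sample_ids
    out = []
    for i in fi:
        others = fi[fi != i]
        pi1 = float(dist[i, others].mean())
        oth = oi[oi != i]
        dxy1 = float(dist[i, oth].mean())
        decision = "exclude" if pi1 >= dxy1 else "retain"
        out.append(PurityRecord(ids[i], pi1, dxy1, decision))
    return out


@dataclass
class PCAResult:
    coords: pd.DataFrame           # samples x components ("PC1", ...)
    explained_variance_ratio: np.ndarray
    flagged: list[str] | None = None


def pca(gm: GenotypeMatrix, n_components: int = 2) -> PCAResult:
    """PCA of the mean-imputed, centered allele-code matrix (samples as
    observations). Deterministic up to component sign."""
    if gm.n_samples < 2:
        raise ValueError("PCA needs >= 2 samples")
    X = gm.codes.astype(np.float64).T           # N x S
    miss = gm.codes.T == MISSING
    Xm = np.ma.masked_array(X, mask=miss)
    colmean = Xm.mean(axis=0).filled(0.0)
    X = np.where(miss, colmean[None, :], X)
    X -= X.mean(axis=0, keepdims=True)
    poly = np.flatnonzero(X.std(axis=0) > 0)
    if len(poly) == 0:
        raise ValueError("no polymorphic sites")
    X = X[:, poly]
    k = min(n_components, min(X.shape) - 1, len(poly))
    if k < n_components:
        warnings.warn(f"only {k} informative components available")
    U, s, Vt = np.linalg.svd(X, full_matrices=False)
    total_var = (s ** 2).sum()
    coords = U[:, :k] * s[:k]
    # fix sign: largest-magnitude loading positive
    for j in range(k):
        i = np.argmax(np.abs(coords[:, j]))
        if coords[i, j] < 0:
            coords[:, j] *= -1
    df = pd.DataFrame(coords, index=gm.samples.sample_ids,
                      columns=[f"PC{j + 1}" for j in range(k)])
    evr = (s[:k] ** 2) / total_var
    return PCAResult(coords=df, explained_variance_ratio=evr)


def flag_outliers(pca_result: PCAResult, samples: SampleTable,
                  radius: float = 3.0) -> list[str]:
    """Samples whose PC1/PC2 position lies outside `radius` (Mahalanobis)
    of their labeled group centroid. Advisory only."""
    coords = pca_result.coords.iloc[:, :2].to_numpy()
    flagged = []
    ids = samples.sample_ids
    for group in ("japonica", "indica", "wild", "outgroup"):
        gi = samples.indices(group)
        if len(gi) < 3:
            continue
        pts = coords[gi]
        mu = pts.mean(axis=0)
        cov = np.cov(pts.T) + 1e-9 * np.eye(2)
        inv = np.linalg.inv(cov)
        d = np.einsum("ij,jk,ik->i", pts - mu, inv, pts - mu) ** 0.5
        for i, di in zip(gi, d):
            if di > radius:
                flagged.append(ids[i])
    pca_result.flagged = flagged
    return flagged
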