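"""Genotype principal components used as covariates in association models.

PCA is computed within the analysis cohort: common variants (cohort
MAF > 1%) are mean-imputed, centered at twice the allele frequency and
scaled by sqrt(2p(1-p)) — the standard variance-standardized genotype
matrix — and the top-K left singular vectors give the sample PCs.
Downstream models use the z-scored PCs 1..K.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from sklearn.utils.extmath import randomized_svd

from .formats_io import GenotypeMatrix


class PCAError(ValueError):
    pass


@dataclass
class PCSet:
    sample_ids: list[str]
    pcs: np.ndarray                 # n_samples x K
    explained_variance: np.ndarray  # per PC, non-increasing
    zscored: bool = False

    @property
    def k(self) -> int:
        return self.pcs.shape[1]

    def to_frame(self):
        import pandas as pd
        df = pd.DataFrame(self.pcs, columns=[f"PC{i+1}" for i in range(self.k)])
        df.insert(0, "sample_id", self.sample_ids)
        return df


def compute_pcs(
    genotypes: GenotypeMatrix,
    maf_min: float = 0.01,
    k: int = 10,
    seed: int = 0,
) -> PCSet:
    """Top-``k`` genotype principal components of the cohort.

    Monomorphic and rare (MAF <= ``maf_min``) variants and duplicated
    variant keys are excluded before the truncated SVD; missing dosages are
    mean-imputed.  Each PC's sign is fixed so that its largest-magnitude
    variant loading is positive, making results seed-stable.
    """
    n, m = genotypes.dosages.shape
    if n <= k:
        raise PCAError(f"need more than k={k} samples, have {n}")

    X = genotypes.dosages.astype(np.float64)
    # drop duplicated variant keys outright
    seen: set = set()
    keep_cols = []
    for j, s in enumerate(genotypes.sites):
        key = (s.chrom, s.pos, frozenset((s.ref, s.alt)))
        if key in seen:
            continue
        seen.add(key)
        keep_cols.append(j)
    X = X[:, keep_cols]

    col_mean = np.nanmean(X, axis=0)
    inds = np.where(np.isnan(X))
    X[inds] = np.take(col_mean, inds[1])
    p = col_mean / 2.0
    maf = np.minimum(p, 1.0 - p)
    informative = maf > maf_min
    X = X[:, informative]
    p = p[informative]
    if X.shape[1] < k:
        raise PCAError(
            f"only {X.shape[1]} non-degenerate variants after MAF filter; need >= {k}"
        )
    X -= 2.0 * p
    X /= np.sqrt(2.0 * p * (1.0 - p))

    U, S, Vt = randomized_svd(X, n_components=k, random_state=seed)
    # deterministic sign: largest-|loading| entry of each right vector positive
    for i in range(k):
        j = np.argmax(np.abs(Vt[i]))
        if Vt[i, j] < 0:
            Vt[i] *= -1.0
            U[:, i] *= -1.0
    pcs = U * S
    explained = S**2 / (n - 1)
    return PCSet(sample_ids=list(genotypes.samples), pcs=pcs,
                 explained_variance=explained, zscored=False)


def zscore_pcs(pcset: PCSet) -> PCSet:
    """Standardize each PC column to mean 0, SD 1 (idempotent)."""
    sd = pcset.pcs.std(axis=0, ddof=0)
    if np.any(sd == 0):
        raise PCAError("constant PC column; cannot z-score")
    z = (pcset.pcs - pcset.pcs.mean(axis=0)) / sd
    return PCSet(sample_ids=list(pcset.sample_ids), pcs=z,
                 explained_variance=pcset.explained_variance.copy(), zscored=True)
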