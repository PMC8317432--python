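"""Individual-level structure: relatedness and PCA on dosages.

The relatedness estimator is a method-of-moments correlation: each
individual's dosage vector is centred by 4 q_hat per site (q_hat the
overall sample frequency) and pairs are scored by the normalized
cross-product over loci, giving values in [-1, 1] with unit
self-relatedness.  PCA operates on column-centred dosages (covariance
of allele frequencies between individuals), with an optional mean
imputation for missing calls and a fixed sign convention so results are
reproducible bit-for-bit.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .genotyping import GenotypeMatrix

__all__ = ["relatedness_matrix", "pca_dosage", "PcaResult"]


def relatedness_matrix(genotypes: GenotypeMatrix) -> pd.DataFrame:
    """Pairwise moment-estimator relatedness over complete-case SNPs.

    r_ij = sum_l c_il c_jl / sqrt(sum_l c_il^2 * sum_l c_jl^2) with
    c_il the dosage centred by 4 q_hat at locus l.  Only SNPs with no
    missing calls enter.  The diagonal is exactly 1.
    """
    complete = genotypes.complete_case_sites()
    if not complete.any():
        raise ValueError("no complete-case SNPs for relatedness")
    dos = genotypes.dosage[:, complete].astype(float)
    q = dos.mean(axis=0) / 4
    c = dos - 4 * q[None, :]
    norms = np.sqrt((c**2).sum(axis=1))
    zero = norms == 0
    if zero.any():
        bad = [genotypes.individual_ids[i] for i in np.flatnonzero(zero)]
        raise ValueError(f"individuals with zero dosage variance: {bad}")
    r = (c @ c.T) / np.outer(norms, norms)
    np.fill_diagonal(r, 1.0)
    r = np.clip((r + r.T) / 2, -1.0, 1.0)
    ids = genotypes.individual_ids
    return pd.DataFrame(r, index=ids, columns=ids)


@dataclass
class PcaResult:
    """Principal component scores with explained-variance percentages."""

    scores: pd.DataFrame  # individuals x components
    explained_pct: np.ndarray  # per retained component, non-increasing

    @property
    def n_components(self) -> int:
        return self.scores.shape[1]


def pca_dosage(
    genotypes: GenotypeMatrix,
    n_components: int = 10,
    impute_missing: bool = True,
    scale: bool = False,
) -> PcaResult:
    """PCA of the individual covariance of centred dosages.

    Missing calls are mean-imputed per site when ``impute_missing``,
    otherwise only complete-case sites are used.  ``scale`` divides each
    site by its standard deviation (default off: pure covariance).
    Signs are fixed so each component's largest-magnitude site loading
    is positive.  ``explained_pct`` entries are percentages of the total
    variance; over a full decomposition they sum to 100.
    """
    if len(genotypes.individual_ids) < 2 or len(genotypes.site_ids) < 2:
        raise ValueError("need at least 2 individuals and 2 sites")
    dos = genotypes.dosage.astype(float)
    called = genotypes.called
    if impute_missing:
        with np.errstate(invalid="ignore"):
            site_mean = np.where(
                called.any(axis=0),
                np.where(called, dos, 0).sum(axis=0) / np.maximum(called.sum(axis=0), 1),
                0.0,
            )
        X = np.where(called, dos, site_mean[None, :])
    else:
        complete = called.all(axis=0)
        if complete.sum() < 2:
            raise ValueError("fewer than 2 complete-case sites")
        X = dos[:, complete]
    X = X - X.mean(axis=0, keepdims=True)
    if scale:
        sd = X.std(axis=0)
        keep = sd > 0
        X = X[:, keep] / sd[keep]

    U, S, Vt = np.linalg.svd(X, full_matrices=False)
    var = S**2
    total = var.sum()
    rank = int((S > S[0] * 1e-12).sum()) if S.size else 0
    k = min(n_components, rank)
    # sign convention: largest-|loading| entry of each component positive
    for c in range(k):
        j = np.argmax(np.abs(Vt[c]))
        if Vt[c, j] < 0:
            Vt[c] *= -1
            U[:, c] *= -1
    scores = U[:, :k] * S[:k]
    explained = 100 * var[:k] / total if total > 0 else np.zeros(k)
    frame = pd.DataFrame(
        scores,
        index=genotypes.individual_ids,
        columns=[f"PC{c + 1}" for c in range(k)],
    )
    return PcaResult(scores=frame, explained_pct=explained)
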