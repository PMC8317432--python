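"""Empirical-Bayes tetraploid dosage calling from read counts.

Each biallelic site is modelled independently.  The likelihood of an
individual's alternative-read count ``a`` out of depth ``d`` given
dosage ``g`` (0..4 copies of the alternative allele) is binomial with
success probability ``h_g = (g/4)(1 - eps) + (1 - g/4) eps`` where
``eps`` is a per-site error rate estimated from reads matching neither
allele.  A population allele frequency ``q`` is fitted per site by EM
under a tetrasomic Hardy-Weinberg prior Binomial(4, q); the posterior
dosage is the argmax of likelihood times prior.  Cells below a minimum
depth are missing; sites failing missingness, minor-allele-frequency or
carrier-count filters are dropped.

The caller is self-contained: it defines its own error estimator and
EM schedule and does not claim numerical identity with any external
genotyping tool.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import gammaln, logsumexp

from .simulate import MISSING, ReadCountMatrix

__all__ = [
    "MISSING",
    "GenotypeMatrix",
    "estimate_site_error",
    "genotype_loglik",
    "em_site_frequency",
    "call_genotypes",
]

EPSILON_MIN = 1e-4
EPSILON_MAX = 0.1

_G = np.arange(5)
_LOG_BINOM4 = gammaln(5) - gammaln(_G + 1) - gammaln(5 - _G)  # log C(4, g)


@dataclass
class GenotypeMatrix:
    """Called dosages (0..4, ``MISSING`` = -1) with posterior support."""

    dosage: np.ndarray  # (n_ind, n_sites) int
    posterior_max: np.ndarray  # (n_ind, n_sites) float, nan where missing
    individual_ids: list[str]
    site_ids: list[str]

    @property
    def shape(self) -> tuple[int, int]:
        return self.dosage.shape

    @property
    def called(self) -> np.ndarray:
        return self.dosage != MISSING

    def complete_case_sites(self) -> np.ndarray:
        """Boolean mask of sites with no missing calls."""
        return self.called.all(axis=0)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.dosage, index=self.individual_ids, columns=self.site_ids
        )


def estimate_site_error(ref: np.ndarray, alt: np.ndarray, other: np.ndarray) -> float:
    """Per-site error rate from reads matching neither allele.

    ``eps = (1 + sum(other)) / (2 + sum(total))``, a pseudocount-
    stabilized fraction clamped to [1e-4, 0.1].  Raises on zero depth.
    """
    total = int(np.sum(ref) + np.sum(alt) + np.sum(other))
    if total == 0:
        raise ValueError("site has zero total depth; unusable")
    eps = (1 + float(np.sum(other))) / (2 + total)
    return float(np.clip(eps, EPSILON_MIN, EPSILON_MAX))


def genotype_loglik(alt_reads, depth, epsilon) -> np.ndarray:
    """Log-likelihood of each dosage 0..4 given alt reads out of depth.

    Broadcasts over arrays: returns shape ``broadcast(a, d).shape + (5,)``.
    The binomial coefficient is included so values match the exact pmf.
    """
    a = np.asarray(alt_reads, dtype=float)
    d = np.asarray(depth, dtype=float)
    if np.any(a > d) or np.any(a < 0):
        raise ValueError("alt reads must satisfy 0 <= a <= depth")
    eps = np.asarray(epsilon, dtype=float)
    h = (_G / 4) * (1 - eps[..., None]) + (1 - _G / 4) * eps[..., None]  # (..., 5)
    a = a[..., None]
    d = d[..., None]
    log_coeff = gammaln(d + 1) - gammaln(a + 1) - gammaln(d - a + 1)
    return log_coeff + a * np.log(h) + (d - a) * np.log1p(-h)


def _log_prior(q: np.ndarray) -> np.ndarray:
    """Tetrasomic HWE log prior Binomial(g; 4, q); q shape (S,) -> (S, 5)."""
    q = np.clip(q, 1e-9, 1 - 1e-9)[:, None]
    return _LOG_BINOM4 + _G * np.log(q) + (4 - _G) * np.log1p(-q)


def _em_frequencies(
    loglik: np.ndarray,
    called: np.ndarray,
    q0: np.ndarray,
    tol: float = 1e-6,
    max_iter: int = 100,
) -> np.ndarray:
    """Vectorized per-site EM for the allele frequency under the HWE prior.

    ``loglik`` is (n_ind, S, 5); ``called`` (n_ind, S) masks usable cells.
    """
    q = np.clip(q0.astype(float), 1e-6, 1 - 1e-6)
    n_called = called.sum(axis=0)  # (S,)
    active = n_called > 0
    ll = np.where(called[..., None], loglik, 0.0)
    for _ in range(max_iter):
        post = _posteriors(ll, called, q)
        dose_mean = (post * _G).sum(axis=2)  # (n_ind, S)
        q_new = np.where(
            active,
            (dose_mean * called).sum(axis=0) / np.maximum(4 * n_called, 1),
            q,
        )
        if np.max(np.abs(q_new - q)) < tol:
            q = q_new
            break
        q = q_new
    return q


def _posteriors(loglik: np.ndarray, called: np.ndarray, q: np.ndarray) -> np.ndarray:
    """Posterior dosage probabilities; uniform (unused) rows where uncalled."""
    log_post = loglik + _log_prior(q)[None, :, :]
    log_post -= logsumexp(log_post, axis=2, keepdims=True)
    post = np.exp(log_post)
    return np.where(called[..., None], post, 0.2)


def em_site_frequency(
    logliks: np.ndarray, q0: float | None = None, return_trajectory: bool = False
):
    """EM allele-frequency estimate for a single site.

    ``logliks`` is (n_individuals, 5); rows of all -inf are treated as
    missing.  Returns ``q_hat``, or ``(q_hat, loglik_trajectory)`` with
    the observed-data log-likelihood per iteration when requested.
    """
    logliks = np.asarray(logliks, dtype=float)
    called = np.isfinite(logliks).all(axis=1)
    if not called.any():
        raise ValueError("all individuals missing at site; unusable")
    ll = logliks[called][:, None, :]  # (n, 1, 5)
    mask = np.ones((ll.shape[0], 1), dtype=bool)
    if q0 is None:
        # crude initialisation from the per-individual ML dosage
        q0 = float((np.argmax(ll[:, 0, :], axis=1)).mean() / 4)
    q = np.clip(np.array([q0]), 1e-6, 1 - 1e-6)
    traj = []
    for _ in range(100):
        traj.append(
            float(logsumexp(ll + _log_prior(q)[None, :, :], axis=2).sum())
        )
        post = _posteriors(ll, mask, q)
        q_new = np.clip((post * _G).sum(axis=2).mean() / 4, 1e-6, 1 - 1e-6)
        if abs(q_new - q[0]) < 1e-6:
            q = np.array([q_new])
            break
        q = np.array([q_new])
    traj.append(float(logsumexp(ll + _log_prior(q)[None, :, :], axis=2).sum()))
    if return_trajectory:
        return float(q[0]), np.array(traj)
    return float(q[0])


def call_genotypes(
    reads: ReadCountMatrix,
    min_depth: int = 5,
    max_missing: float = 0.10,
    maf_min: float = 0.05,
    min_carriers: int = 2,
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Call tetraploid dosages and filter sites.

    Per cell: missing when depth < ``min_depth``, otherwise the maximum-
    posterior dosage under the site's EM-fitted Binomial(4, q) prior,
    with posterior ties broken toward the dosage nearest ``4 q``.
    Per site: dropped when the missing fraction exceeds ``max_missing``,
    the minor allele frequency falls below ``maf_min``, or fewer than
    ``min_carriers`` called individuals carry either allele (a site-
    confidence proxy removing singleton-noise sites).

    Returns the genotype matrix over retained sites and a site table
    (all non-zero-depth sites) with ``epsilon, q_hat, maf, n_called``
    and a ``retained`` flag.  Raises if every site is filtered.
    """
    depth = reads.depth
    n_ind, n_sites = depth.shape
    site_depth = depth.sum(axis=0)
    usable = site_depth > 0
    if not usable.any():
        raise ValueError("no site has any reads")

    total_other = reads.other.sum(axis=0)
    eps = (1 + total_other) / (2 + site_depth)
    eps = np.clip(eps, EPSILON_MIN, EPSILON_MAX)

    called = depth >= min_depth
    # likelihood conditions on reads matching either allele, so that
    # swapping ref/alt labels maps the model exactly onto itself
    allelic = reads.ref + reads.alt
    loglik = genotype_loglik(reads.alt, allelic, eps[None, :].repeat(n_ind, axis=0))

    denom = (allelic * called).sum(axis=0)
    q0 = np.where(denom > 0, (reads.alt * called).sum(axis=0) / np.maximum(denom, 1), 0.5)
    q_hat = _em_frequencies(loglik, called, q0)

    post = _posteriors(np.where(called[..., None], loglik, 0.0), called, q_hat)
    # deterministic tie-break: nudge toward the dosage nearest 4*q_hat
    penalty = 1e-12 * np.abs(_G[None, None, :] - 4 * q_hat[None, :, None])
    dosage = np.argmax(post - penalty, axis=2)
    posterior_max = np.take_along_axis(post, dosage[..., None], axis=2)[..., 0]
    dosage = np.where(called, dosage, MISSING)
    posterior_max = np.where(called, posterior_max, np.nan)

    n_called = called.sum(axis=0)
    missing_frac = 1 - n_called / n_ind
    maf = np.minimum(q_hat, 1 - q_hat)
    alt_carriers = ((dosage >= 1) & called).sum(axis=0)
    ref_carriers = ((dosage <= 3) & called).sum(axis=0)
    retained = (
        usable
        & (missing_frac <= max_missing + 1e-12)
        & (maf >= maf_min)
        & (alt_carriers >= min_carriers)
        & (ref_carriers >= min_carriers)
    )

    site_info = pd.DataFrame(
        {
            "site_id": reads.site_ids,
            "epsilon": eps,
            "q_hat": q_hat,
            "maf": maf,
            "n_called": n_called,
            "missing_frac": missing_frac,
            "retained": retained,
        }
    ).loc[usable].reset_index(drop=True)

    if not retained.any():
        raise ValueError(
            "all sites filtered: "
            f"{int((~usable).sum())} zero-depth, "
            f"{int((missing_frac > max_missing).sum())} over missing threshold, "
            f"{int((maf < maf_min).sum())} under MAF threshold"
        )

    keep = np.flatnonzero(retained)
    genotypes = GenotypeMatrix(
        dosage=dosage[:, keep],
        posterior_max=posterior_max[:, keep],
        individual_ids=list(reads.individual_ids),
        site_ids=[reads.site_ids[j] for j in keep],
    )
    return genotypes, site_info
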