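"""Structure-corrected outlier scan and environmental association.

A deterministic differentiation scan in the FLK/XtX family: population
allele frequencies are standardized per locus, their J x J covariance
(Omega) captures shared drift and demography, and each locus is scored
by the quadratic form XtX = z' Omega^-1 z, approximately chi-square
with J degrees of freedom under neutrality.  Environmental association
is the Pearson correlation between the Omega-whitened frequency vector
and the Omega-whitened z-scored covariate — a deterministic surrogate
for a Bayes factor, monotone in association strength.  Significance
thresholds come from pseudo-observed datasets (PODs): neutral loci
simulated under the fitted Omega, pushed through the identical
standardization code path, whose 99% / 99.9% quantiles calibrate the
scan.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .diversity import pop_allele_freq
from .genotyping import GenotypeMatrix

__all__ = [
    "standardized_freqs",
    "estimate_omega",
    "xtx",
    "env_association",
    "pod_calibrate",
    "scan",
    "ScanResult",
]

OMEGA_SHRINKAGE = 0.05


def standardized_freqs(
    pop_freqs: np.ndarray, pop_sizes: np.ndarray | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Standardize population frequencies per locus.

    z_lj = (p_lj - p_bar_l) / sqrt(p_bar_l (1 - p_bar_l)) with p_bar_l
    the sample-size-weighted mean.  Loci monomorphic across all
    populations are excluded.  Returns ``(Z, p_bar, kept_mask)``.
    """
    P = np.asarray(pop_freqs, dtype=float)
    if P.ndim != 2:
        raise ValueError("pop_freqs must be loci x populations")
    if pop_sizes is None:
        w = np.full(P.shape[1], 1.0 / P.shape[1])
    else:
        w = np.asarray(pop_sizes, dtype=float)
        w = w / w.sum()
    p_bar = P @ w
    kept = (p_bar > 0) & (p_bar < 1)
    P = P[kept]
    p_bar = p_bar[kept]
    Z = (P - p_bar[:, None]) / np.sqrt(p_bar * (1 - p_bar))[:, None]
    return Z, p_bar, kept


def estimate_omega(Z: np.ndarray, shrinkage: float = OMEGA_SHRINKAGE) -> np.ndarray:
    """Population covariance of standardized frequencies, shrunk to its
    diagonal by ``shrinkage`` to guarantee invertibility."""
    Z = np.asarray(Z, dtype=float)
    L, J = Z.shape
    if L < J:
        raise ValueError(f"need at least as many loci ({L}) as populations ({J})")
    omega = Z.T @ Z / L
    omega = (1 - shrinkage) * omega + shrinkage * np.diag(np.diag(omega))
    return (omega + omega.T) / 2


def xtx(Z: np.ndarray, omega: np.ndarray) -> np.ndarray:
    """Per-locus quadratic form z' Omega^-1 z (chi-square_J under null)."""
    Z = np.asarray(Z, dtype=float)
    sol = np.linalg.solve(omega, Z.T)  # (J, L)
    return np.einsum("lj,jl->l", Z, sol)


def _inv_sqrt(omega: np.ndarray) -> np.ndarray:
    vals, vecs = np.linalg.eigh(omega)
    if vals.min() <= 0:
        raise np.linalg.LinAlgError("omega not positive definite")
    return vecs @ np.diag(1.0 / np.sqrt(vals)) @ vecs.T

def env_association(
    Z: np.ndarray, omega: np.ndarray, covariate: np.ndarray, scaled: bool = True
) -> np.ndarray:
    """Whitened per-locus correlation with a population covariate.

    Both the standardized frequency vector of each locus and the
    (optionally z-scored) covariate are whitened by Omega^(-1/2); the
    statistic is their Pearson correlation, in [-1, 1].
    """
    c = np.asarray(covariate, dtype=float)
    if c.std() == 0:
        raise ValueError("covariate is constant across populations")
    if scaled:
        c = (c - c.mean()) / c.std()
    W = _inv_sqrt(omega)
    Zw = Z @ W.T
    cw = W @ c
    Zc = Zw - Zw.mean(axis=1, keepdims=True)
    cc = cw - cw.mean()
    denom = np.sqrt((Zc**2).sum(axis=1) * (cc**2).sum())
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, Zc @ cc / denom, 0.0)
    return np.clip(r, -1.0, 1.0)


def pod_calibrate(
    omega: np.ndarray,
    freq_spectrum: np.ndarray,
    covariates: pd.DataFrame | np.ndarray | None = None,
    n_pods: int = 100_000,
    seed: int = 0,
    pop_sizes: np.ndarray | None = None,
) -> dict:
    """Neutral POD thresholds for XtX and the association statistic.

    Simulates ``n_pods`` neutral loci: a mean frequency drawn from the
    empirical locus-mean spectrum, standardized deviates from
    MVN(0, Omega), frequencies back-transformed, clamped to (0, 1), and
    re-standardized through the same code path as real loci.  Returns
    the 99% and 99.9% XtX quantiles and the 99.9% quantile of |assoc|
    per covariate.
    """
    if n_pods < 1000:
        import warnings

        warnings.warn("fewer than 1,000 PODs: quantile thresholds unstable")
    rng = np.random.default_rng(seed)
    spectrum = np.asarray(freq_spectrum, dtype=float)
    p_bar = rng.choice(spectrum, size=n_pods, replace=True)
    chol = np.linalg.cholesky(omega)
    z = rng.standard_normal((n_pods, omega.shape[0])) @ chol.T
    P = p_bar[:, None] + z * np.sqrt(p_bar * (1 - p_bar))[:, None]
    P = np.clip(P, 1e-4, 1 - 1e-4)
    Zpod, _, kept = standardized_freqs(P, pop_sizes)
    x = xtx(Zpod, omega)
    out = {
        "xtx_99": float(np.quantile(x, 0.99)),
        "xtx_999": float(np.quantile(x, 0.999)),
        "n_pods": int(kept.sum()),
        "pod_xtx": x,
    }
    if covariates is not None:
        cov = pd.DataFrame(covariates)
        assoc_999 = {}
        for name in cov.columns:
            a = env_association(Zpod, omega, cov[name].to_numpy())
            assoc_999[str(name)] = float(np.quantile(np.abs(a), 0.999))
        out["assoc_999"] = assoc_999
    return out


@dataclass
class ScanResult:
    """End-to-end scan output."""

    table: pd.DataFrame  # per-locus xtx, assoc per covariate, flags
    omega: pd.DataFrame
    thresholds: dict
    covariate_names: list[str] = field(default_factory=list)

    def outliers(self, level: str = "conservative") -> pd.DataFrame:
        col = {"conservative": "outlier_conservative",
               "very_conservative": "outlier_very_conservative"}[level]
        return self.table[self.table[col]]


def scan(
    genotypes: GenotypeMatrix,
    membership: pd.Series,
    covariates: pd.DataFrame,
    n_pods: int = 100_000,
    seed: int = 0,
    shrinkage: float = OMEGA_SHRINKAGE,
) -> ScanResult:
    """Full outlier/association scan from called dosages.

    Dosages are aggregated to population allele frequencies, Omega is
    estimated on the standardized matrix, XtX and per-covariate
    associations are computed, and POD-calibrated thresholds flag
    outliers: "conservative" = XtX above its 99% POD quantile with some
    |assoc| above its 99.9% quantile; "very conservative" = XtX above
    the 99.9% quantile with the same association condition.  Loci above
    the XtX thresholds alone are flagged separately.
    """
    q, m, labels = pop_allele_freq(genotypes, membership)
    cov = covariates.loc[labels]
    P = q.to_numpy().T  # loci x populations
    if np.isnan(P).any():
        # a locality with no calls at a site: fall back to the locus mean
        row_mean = np.nanmean(P, axis=1)
        P = np.where(np.isnan(P), row_mean[:, None], P)
    sizes = m.to_numpy().mean(axis=1)
    Z, p_bar, kept = standardized_freqs(P, sizes)
    omega = estimate_omega(Z, shrinkage)
    x = xtx(Z, omega)
    thr = pod_calibrate(omega, p_bar, cov, n_pods=n_pods, seed=seed, pop_sizes=sizes)
    pod_xtx = thr.pop("pod_xtx")

    site_ids = [s for s, k in zip(genotypes.site_ids, kept) if k]
    table = pd.DataFrame({"site_id": site_ids, "xtx": x}).set_index("site_id")
    assoc_cols = []
    for name in cov.columns:
        a = env_association(Z, omega, cov[name].to_numpy())
        col = f"assoc_{name}"
        table[col] = a
        assoc_cols.append((str(name), col))
    any_assoc = np.zeros(len(table), dtype=bool)
    for name, col in assoc_cols:
        any_assoc |= np.abs(table[col].to_numpy()) > thr["assoc_999"][name]
    table["xtx_over_99"] = table["xtx"] > thr["xtx_99"]
    table["xtx_over_999"] = table["xtx"] > thr["xtx_999"]
    table["outlier_conservative"] = table["xtx_over_99"] & any_assoc
    table["outlier_very_conservative"] = table["xtx_over_999"] & any_assoc

    thr["pod_xtx_mean"] = float(pod_xtx.mean())
    return ScanResult(
        table=table,
        omega=pd.DataFrame(omega, index=labels, columns=labels),
        thresholds=thr,
        covariate_names=[str(c) for c in cov.columns],
    )
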