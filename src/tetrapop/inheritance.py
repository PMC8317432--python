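"""Tetrasomic vs disomic inheritance diagnosis from dosage spectra.

In an autotetraploid with tetrasomic inheritance and random mating,
dosage-class frequencies at a site with allele frequency q follow
Binomial(4, q): at q = 0.5 all five classes appear with proportions
(1, 4, 6, 4, 1)/16, and the three heterozygote classes peak with
similar heights.  In an allotetraploid with two diverged subgenomes and
disomic inheritance, fixed inter-subgenome differences inflate the
duplex (g = 2) class at intermediate q.  This module bins sites by
allele frequency, averages their dosage-class proportions, and
classifies the spectrum by total-variation distance to the two
reference models.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import binom

from .genotyping import GenotypeMatrix

__all__ = [
    "GenotypeProfile",
    "genotype_frequency_profile",
    "heterozygote_balance",
    "classify_inheritance",
]


@dataclass
class GenotypeProfile:
    """Mean dosage-class proportions per allele-frequency bin."""

    bin_centers: np.ndarray  # (B,)
    class_freq: np.ndarray  # (B, 5); rows sum to 1 where populated
    n_sites_per_bin: np.ndarray  # (B,) int
    site_q: np.ndarray  # per-site allele frequency (complete-case sites)
    site_class_freq: np.ndarray  # (n_sites, 5) per-site class proportions

    def to_frame(self) -> pd.DataFrame:
        out = pd.DataFrame(
            self.class_freq, columns=[f"g{g}" for g in range(5)]
        )
        out.insert(0, "bin_center", self.bin_centers)
        out["n_sites"] = self.n_sites_per_bin
        return out


def genotype_frequency_profile(
    genotypes: GenotypeMatrix, bin_width: float = 0.02
) -> GenotypeProfile:
    """Dosage-class proportions as a function of allele frequency.

    Uses complete-case sites only (no missing calls), mirroring how the
    spectrum is normally drawn.  Per site, q = sum(g) / (4n) and the
    empirical class proportions; both are then averaged within
    allele-frequency bins of the given width.
    """
    complete = genotypes.complete_case_sites()
    if not complete.any():
        raise ValueError("no complete-case sites; cannot build profile")
    dos = genotypes.dosage[:, complete]
    n_ind = dos.shape[0]
    q = dos.sum(axis=0) / (4 * n_ind)
    class_counts = np.stack([(dos == g).sum(axis=0) for g in range(5)], axis=1)
    site_freq = class_counts / n_ind

    n_bins = int(round(1.0 / bin_width))
    edges = np.linspace(0.0, 1.0, n_bins + 1)
    idx = np.clip(np.digitize(q, edges) - 1, 0, n_bins - 1)
    centers = (edges[:-1] + edges[1:]) / 2
    class_freq = np.zeros((n_bins, 5))
    n_sites = np.zeros(n_bins, dtype=int)
    for b in range(n_bins):
        mask = idx == b
        n_sites[b] = mask.sum()
        if n_sites[b]:
            class_freq[b] = site_freq[mask].mean(axis=0)
    return GenotypeProfile(centers, class_freq, n_sites, q, site_freq)


def heterozygote_balance(
    genotypes: GenotypeMatrix,
    band: tuple[float, float] = (0.4, 0.6),
    min_sites: int = 50,
) -> float:
    """Triplex-plus-simplex to duplex ratio D at intermediate frequency.

    Over complete-case sites with allele frequency inside ``band``,
    D = (mean freq of g=1 + mean freq of g=3) / (mean freq of g=2).
    Under tetrasomic HWE at q = 0.5 the exact value is
    (4/16 + 4/16) / (6/16) = 4/3; fully disomic fixed heterozygosity
    gives 0 (all duplex).  D is invariant to allele-label swap.
    """
    profile = genotype_frequency_profile(genotypes)
    mask = (profile.site_q >= band[0]) & (profile.site_q <= band[1])
    if mask.sum() < min_sites:
        raise ValueError(
            f"only {int(mask.sum())} sites with q in {band}; need {min_sites}"
        )
    mean_freq = profile.site_class_freq[mask].mean(axis=0)
    if mean_freq[2] == 0:
        raise ValueError("no duplex genotypes in band; D undefined")
    return float((mean_freq[1] + mean_freq[3]) / mean_freq[2])


def _tetrasomic_expectation(q: float) -> np.ndarray:
    return binom.pmf(np.arange(5), 4, q)


def _disomic_expectation(q: float) -> np.ndarray:
    """Fixed-difference disomic reference: one subgenome fixed.

    For q <= 0.5 the reference allele is fixed in one subgenome and the
    other segregates at 2q, so dosage ~ Binomial(2, 2q); for q > 0.5
    symmetrically dosage = 2 + Binomial(2, 2q - 1).  At q = 0.5 this is
    a point mass on the duplex class.
    """
    out = np.zeros(5)
    if q <= 0.5:
        out[:3] = binom.pmf(np.arange(3), 2, min(2 * q, 1.0))
    else:
        out[2:] = binom.pmf(np.arange(3), 2, 2 * q - 1)
    return out


def classify_inheritance(
    profile: GenotypeProfile,
    band: tuple[float, float] = (0.4, 0.6),
    ambiguity_margin: float = 0.05,
) -> tuple[str, float]:
    """Label a dosage spectrum tetrasomic, disomic, or ambiguous.

    The observed class distribution, averaged over bins in ``band``
    weighted by their site counts, is compared by total-variation
    distance to the matching bin-wise tetrasomic (Binomial(4, q)) and
    fixed-difference disomic expectations.  The nearer model wins; when
    the two distances differ by less than ``ambiguity_margin`` the call
    is "ambiguous".  Returns (label, distance_disomic - distance_tetrasomic),
    positive scores favouring the tetrasomic model.
    """
    in_band = (
        (profile.bin_centers >= band[0])
        & (profile.bin_centers <= band[1])
        & (profile.n_sites_per_bin > 0)
    )
    if not in_band.any():
        raise ValueError(f"no populated allele-frequency bins in {band}")
    w = profile.n_sites_per_bin[in_band].astype(float)
    w /= w.sum()
    obs = (profile.class_freq[in_band] * w[:, None]).sum(axis=0)
    tet = (
        np.stack([_tetrasomic_expectation(q) for q in profile.bin_centers[in_band]])
        * w[:, None]
    ).sum(axis=0)
    dis = (
        np.stack([_disomic_expectation(q) for q in profile.bin_centers[in_band]])
        * w[:, None]
    ).sum(axis=0)
    d_tet = 0.5 * np.abs(obs - tet).sum()
    d_dis = 0.5 * np.abs(obs - dis).sum()
    score = float(d_dis - d_tet)
    if abs(d_tet - d_dis) < ambiguity_margin:
        return "ambiguous", score
    return ("tetrasomic" if d_tet < d_dis else "disomic"), score
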