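"""Synthetic tetraploid RAD-seq landscapes with known truth.

Generates the full chain needed to exercise a ploidy-aware pipeline:
a sampling landscape (localities, regions, spatially autocorrelated
climatic covariates), population allele frequencies with isolation by
distance and an optional environmental cline at a subset of loci,
individual tetraploid dosages under tetrasomic or disomic inheritance,
and per-individual read counts with overdispersed depth and sequencing
error.  Every stage records its ground truth in :class:`SimulationTruth`
so recovery can be measured exactly.

The frequency model is a logit-scale multivariate normal per locus:
``logit p_j = logit p0 + e_j`` with ``Cov(e_j, e_k) =
base_sd^2 * exp(-d_jk / ibd_range)`` over great-circle distance in km.
Adaptive loci additionally receive ``effect_size * z_j`` on the logit
scale, where ``z_j`` is the z-scored value of one climatic covariate in
population ``j``.  Loci are independent, as RAD tags effectively are.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .landscape import haversine_km

__all__ = [
    "PopulationTable",
    "SimulationTruth",
    "ReadCountMatrix",
    "simulate_landscape",
    "simulate_allele_frequencies",
    "draw_genotypes",
    "simulate_read_counts",
    "simulate_dataset",
]

#: Fixed tangent-plane origin for synthetic coordinates (central Aegean).
ORIGIN_LAT = 38.0
ORIGIN_LON = 23.0

_KM_PER_DEG_LAT = 111.32

MISSING = -1  # missing-dosage marker shared across the package


def validate_population_table(pops: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a population table violates its contract."""
    required = {"locality", "region", "lat", "lon"}
    missing = required - set(pops.columns)
    if missing:
        raise ValueError(f"population table missing columns: {sorted(missing)}")
    if pops["locality"].duplicated().any():
        raise ValueError("locality ids must be unique")
    if not pops["lat"].between(-90, 90).all():
        raise ValueError("latitudes outside [-90, 90]")
    if not pops["lon"].between(-180, 180).all():
        raise ValueError("longitudes outside [-180, 180]")
    coords = pops[["lat", "lon"]].round(10)
    if coords.duplicated().any():
        raise ValueError("two localities share identical coordinates")


@dataclass
class PopulationTable:
    """Sampling localities with coordinates and climatic covariates.

    ``frame`` holds one row per locality with columns
    ``locality, region, lat, lon, <covariate...>``.
    """

    frame: pd.DataFrame
    covariate_names: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        validate_population_table(self.frame)

    @property
    def n_localities(self) -> int:
        return len(self.frame)

    @property
    def locality_ids(self) -> list[str]:
        return list(self.frame["locality"])

    def covariates(self) -> pd.DataFrame:
        return self.frame.set_index("locality")[self.covariate_names]

    def distances_km(self) -> np.ndarray:
        """Pairwise great-circle distances (km) between localities."""
        lat = self.frame["lat"].to_numpy()
        lon = self.frame["lon"].to_numpy()
        return haversine_km(lat[:, None], lon[:, None], lat[None, :], lon[None, :])


@dataclass
class SimulationTruth:
    """Ground truth for one simulated dataset."""

    pops: PopulationTable
    freq: np.ndarray  # (n_loci, n_pops) alternative-allele frequencies
    adaptive_flags: np.ndarray  # (n_loci,) bool
    effect_size: float
    ibd_range: float
    covariate_name: str | None = None
    dosage: np.ndarray | None = None  # (n_ind, n_loci) int in 0..4
    individual_pop: np.ndarray | None = None  # (n_ind,) locality index
    mode: str | None = None
    subgenome_divergence: float = 0.0

    @property
    def individual_ids(self) -> list[str]:
        if self.individual_pop is None:
            raise ValueError("genotypes not drawn yet")
        ids = []
        counts: dict[int, int] = {}
        locs = self.pops.locality_ids
        for j in self.individual_pop:
            counts[j] = counts.get(j, 0) + 1
            ids.append(f"{locs[j]}_i{counts[j]}")
        return ids

    @property
    def membership(self) -> pd.Series:
        """Locality id per individual, indexed by individual id."""
        locs = self.pops.locality_ids
        return pd.Series(
            [locs[j] for j in self.individual_pop], index=self.individual_ids
        )


@dataclass
class ReadCountMatrix:
    """Per individual x site (ref, alt, other) read counts."""

    ref: np.ndarray
    alt: np.ndarray
    other: np.ndarray
    individual_ids: list[str]
    site_ids: list[str]

    def __post_init__(self) -> None:
        if not (self.ref.shape == self.alt.shape == self.other.shape):
            raise ValueError("count matrices must share one shape")
        if (self.ref < 0).any() or (self.alt < 0).any() or (self.other < 0).any():
            raise ValueError("negative read counts")
        n, s = self.ref.shape
        if len(self.individual_ids) != n or len(self.site_ids) != s:
            raise ValueError("id lists inconsistent with matrix shape")

    @property
    def depth(self) -> np.ndarray:
        return self.ref + self.alt + self.other

    @property
    def shape(self) -> tuple[int, int]:
        return self.ref.shape


def simulate_landscape(
    n_localities: int = 16,
    extent_km: float = 500.0,
    n_covariates: int = 3,
    seed: int = 0,
    noise_sd: float = 0.3,
    n_regions: int = 2,
) -> PopulationTable:
    """Place localities uniformly in a square and attach climatic covariates.

    Coordinates are drawn on a local tangent plane of side ``extent_km``
    centred on a fixed Mediterranean origin and converted to lat/lon.
    Each covariate is a linear north--south gradient (unit slope per
    z-scored latitude) plus independent Gaussian noise of standard
    deviation ``noise_sd``, so covariates are spatially autocorrelated
    the way real climate surfaces are.  Regions split the latitude range
    into ``n_regions`` equal-count bands (south to north).
    """
    if n_localities < 2:
        raise ValueError("need at least 2 localities")
    rng = np.random.default_rng(seed)
    for _ in range(100):
        xy = rng.uniform(-extent_km / 2, extent_km / 2, size=(n_localities, 2))
        if len(np.unique(xy.round(6), axis=0)) == n_localities:
            break
    else:  # pragma: no cover - vanishing probability
        raise RuntimeError("could not place distinct localities")
    lat = ORIGIN_LAT + xy[:, 1] / _KM_PER_DEG_LAT
    lon = ORIGIN_LON + xy[:, 0] / (_KM_PER_DEG_LAT * np.cos(np.radians(ORIGIN_LAT)))

    lat_z = (lat - lat.mean()) / lat.std()
    names = _covariate_names(n_covariates)
    cols = {}
    for k, name in enumerate(names):
        # Alternate the gradient sign so covariates correlate with
        # latitude but not perfectly with one another.
        slope = 1.0 if k % 2 == 0 else -1.0
        cols[name] = slope * lat_z + rng.normal(0.0, noise_sd, n_localities)

    order = np.argsort(lat)  # south -> north
    region_of = np.empty(n_localities, dtype=int)
    for rank, idx in enumerate(order):
        region_of[idx] = min(rank * n_regions // n_localities, n_regions - 1)
    region_names = [f"region{r + 1}" for r in range(n_regions)]

    frame = pd.DataFrame(
        {
            "locality": [f"L{i + 1:02d}" for i in range(n_localities)],
            "region": [region_names[r] for r in region_of],
            "lat": lat,
            "lon": lon,
            **cols,
        }
    )
    return PopulationTable(frame, covariate_names=names)


def _covariate_names(n: int) -> list[str]:
    # First three follow the precipitation-variable naming convention of
    # bioclimatic layers; extras are numbered onward.
    base = ["BIO12", "BIO18", "BIO19"]
    if n <= 3:
        return base[:n]
    return base + [f"BIO{i}" for i in range(1, n - 2)]


def simulate_allele_frequencies(
    pops: PopulationTable,
    n_loci: int = 5000,
    base_sd: float = 0.5,
    ibd_range: float = 200.0,
    n_adaptive: int = 0,
    effect_size: float = 0.0,
    covariate_name: str | None = None,
    seed: int = 0,
) -> SimulationTruth:
    """Draw population allele frequencies with IBD and optional IBE.

    Per locus the ancestral frequency is Uniform(0.05, 0.95); population
    frequencies are the inverse logit of a multivariate normal deviate
    with exponential distance-decay covariance.  The first ``n_adaptive``
    loci (flagged in the returned truth) get an additional logit shift of
    ``effect_size`` per standard deviation of the chosen covariate.
    """
    if base_sd <= 0 or ibd_range <= 0:
        raise ValueError("base_sd and ibd_range must be positive")
    if n_adaptive > n_loci:
        raise ValueError("n_adaptive exceeds n_loci")
    if covariate_name is None:
        covariate_name = pops.covariate_names[0] if pops.covariate_names else None
    if n_adaptive > 0 and covariate_name is None:
        raise ValueError("adaptive loci require a covariate")

    rng = np.random.default_rng(seed)
    J = pops.n_localities
    d = pops.distances_km()
    cov = base_sd**2 * np.exp(-d / ibd_range)
    chol = np.linalg.cholesky(cov + 1e-10 * np.eye(J))

    p0 = rng.uniform(0.05, 0.95, n_loci)
    deviates = rng.standard_normal((n_loci, J)) @ chol.T
    logits = np.log(p0 / (1 - p0))[:, None] + deviates

    flags = np.zeros(n_loci, dtype=bool)
    flags[:n_adaptive] = True
    if n_adaptive > 0 and effect_size != 0.0:
        z = pops.frame[covariate_name].to_numpy()
        z = (z - z.mean()) / z.std()
        logits[flags] += effect_size * z[None, :]

    freq = 1.0 / (1.0 + np.exp(-logits))
    freq = np.clip(freq, 0.001, 0.999)
    return SimulationTruth(
        pops=pops,
        freq=freq,
        adaptive_flags=flags,
        effect_size=effect_size,
        ibd_range=ibd_range,
        covariate_name=covariate_name,
    )


def draw_genotypes(
    truth: SimulationTruth,
    n_per_pop: int = 9,
    mode: str = "tetrasomic",
    subgenome_divergence: float = 0.0,
    seed: int = 0,
) -> SimulationTruth:
    """Draw individual dosages from the true population frequencies.

    Tetrasomic inheritance draws dosage ~ Binomial(4, p): all four
    homologues pair freely.  Disomic inheritance draws the sum of two
    Binomial(2, .) subgenome dosages at frequencies ``p +- delta/2``
    (clamped to [0, 1]), so ``delta = 0`` reduces exactly to the
    tetrasomic distribution and ``delta = 1`` at p = 0.5 yields fixed
    duplex heterozygotes, the allopolyploid hallmark.
    """
    if mode not in ("tetrasomic", "disomic"):
        raise ValueError(f"unknown inheritance mode: {mode!r}")
    if truth.freq is None:
        raise ValueError("truth has no frequencies")
    rng = np.random.default_rng(seed)
    L, J = truth.freq.shape
    n_ind = n_per_pop * J
    pop_idx = np.repeat(np.arange(J), n_per_pop)
    p = truth.freq[:, pop_idx].T  # (n_ind, L)
    if mode == "tetrasomic":
        dosage = rng.binomial(4, p)
    else:
        delta = float(subgenome_divergence)
        if not 0.0 <= delta <= 1.0:
            raise ValueError("subgenome_divergence must be in [0, 1]")
        p1 = np.clip(p + delta / 2, 0.0, 1.0)
        p2 = np.clip(p - delta / 2, 0.0, 1.0)
        dosage = rng.binomial(2, p1) + rng.binomial(2, p2)
    truth.dosage = dosage
    truth.individual_pop = pop_idx
    truth.mode = mode
    truth.subgenome_divergence = float(subgenome_divergence)
    return truth


def simulate_read_counts(
    dosage: np.ndarray,
    mean_depth: float = 16.0,
    depth_dispersion: float = 12.8,
    error_rate: float = 0.005,
    seed: int = 0,
    individual_ids: list[str] | None = None,
    site_ids: list[str] | None = None,
) -> ReadCountMatrix:
    """Simulate (ref, alt, other) read counts from true dosages.

    Depth is Negative-Binomial with the given mean and dispersion
    (variance = mean + mean^2 / dispersion); the defaults reproduce a
    16x (SD ~6x) coverage regime.  Each read is independently recorded
    as a third ("other") allele with probability ``error_rate/2``;
    otherwise it reports the alternative allele with probability g/4,
    flipped to the opposite allele with probability ``error_rate/2``.
    """
    if not 0.0 <= error_rate <= 0.1:
        raise ValueError("error_rate must be in [0, 0.1]")
    if mean_depth <= 0 or depth_dispersion <= 0:
        raise ValueError("mean_depth and depth_dispersion must be positive")
    dosage = np.asarray(dosage)
    if dosage.min() < 0 or dosage.max() > 4:
        raise ValueError("dosages must lie in {0..4}")
    rng = np.random.default_rng(seed)
    n, s = dosage.shape
    # NB as Gamma-Poisson: shape k, scale mean/k.
    lam = rng.gamma(depth_dispersion, mean_depth / depth_dispersion, size=(n, s))
    depth = rng.poisson(lam)

    e = error_rate
    p_alt_given_kept = (dosage / 4) * (1 - e / 2) + (1 - dosage / 4) * (e / 2)
    other = rng.binomial(depth, e / 2)
    kept = depth - other
    alt = rng.binomial(kept, p_alt_given_kept)
    ref = kept - alt
    if individual_ids is None:
        individual_ids = [f"ind{i + 1}" for i in range(n)]
    if site_ids is None:
        site_ids = [f"site{j + 1}" for j in range(s)]
    return ReadCountMatrix(ref, alt, other, individual_ids, site_ids)


def simulate_dataset(
    n_localities: int = 16,
    n_per_pop: int = 9,
    n_loci: int = 5000,
    extent_km: float = 500.0,
    base_sd: float = 0.5,
    ibd_range: float = 200.0,
    n_adaptive: int = 0,
    effect_size: float = 0.0,
    mode: str = "tetrasomic",
    subgenome_divergence: float = 0.0,
    mean_depth: float = 16.0,
    depth_dispersion: float = 12.8,
    error_rate: float = 0.005,
    n_covariates: int = 3,
    seed: int = 0,
) -> tuple[SimulationTruth, ReadCountMatrix]:
    """One-call convenience wrapper running the full generator chain.

    Sub-stage seeds are derived from ``seed`` by a fixed counter so that
    changing one stage's parameters never perturbs another's draws.
    """
    pops = simulate_landscape(
        n_localities, extent_km, n_covariates, seed=_stage_seed(seed, 0)
    )
    truth = simulate_allele_frequencies(
        pops,
        n_loci,
        base_sd,
        ibd_range,
        n_adaptive,
        effect_size,
        seed=_stage_seed(seed, 1),
    )
    draw_genotypes(truth, n_per_pop, mode, subgenome_divergence, seed=_stage_seed(seed, 2))
    reads = simulate_read_counts(
        truth.dosage,
        mean_depth,
        depth_dispersion,
        error_rate,
        seed=_stage_seed(seed, 3),
        individual_ids=truth.individual_ids,
        site_ids=[f"site{j + 1}" for j in range(n_loci)],
    )
    return truth, reads


def _stage_seed(seed: int, counter: int) -> int:
    """Fan a global seed out to per-stage seeds (fixed counter scheme)."""
    return int((int(seed) * 1009 + 101 * counter + 17) % (2**31 - 1))
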