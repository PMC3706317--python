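"""Synthetic climate fields and toy species distribution models.

Everything downstream — validation, the CMP engine, the study pipeline —
is exercised on data produced here, so no external climate dataset or
species atlas is required.  The generators emulate the *statistical
structure* of a 10-arcmin European climate grid: a smooth south-north
temperature gradient with spatially correlated local heterogeneity, a
heat-sum field (GDD5) decreasing poleward, a west-east moisture gradient,
and a land/sea mask of contiguous "sea" blobs.

Three toy models with the structural character of the classic SDM
families produce score maps from these fields:

* :func:`envelope_model` — a correlative bioclimatic envelope: hard
  climatic limits act as on-off switches, linear ramps inside the limits
  weight establishment success (sharply bounded probability surface).
* :func:`hybrid_model` — a limit-gated growth index: a smooth saturating
  growth response (toy NPP/LAI) gated by four bioclimatic limits on
  coldest-month temperature and GDD5, with the survival / establishment
  zones exposed for the nesting decomposition.
* :func:`fitness_model` — a process-based fitness index: the product of
  the probability of surviving frost and drought stress and the
  probability of ripening seed given the heat sum (smooth fitness
  product).

All generators are pure functions of their parameters and an explicit
seed; there is no hidden global random state.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .grids import BinaryMap, GridMeta, ScoreMap

__all__ = [
    "ClimateFields",
    "ClimateParams",
    "ToySpeciesLimits",
    "FitnessComponents",
    "GrowthParams",
    "FitnessParams",
    "make_climate",
    "envelope_model",
    "hybrid_model",
    "fitness_model",
    "observed_distribution",
    "random_binary_map",
    "default_species_presets",
]


@dataclass(frozen=True)
class ClimateParams:
    """Gradient and noise settings for :func:`make_climate`.

    Defaults draw a mid-latitude continental gradient: coldest-month
    temperature spanning about +8 °C (southern edge) to -22 °C (northern
    edge), GDD5 from about 3500 down to 200 degree-days, moisture rising
    west to east, all perturbed by Gaussian-correlated noise with a 5-cell
    correlation length, and a quarter of the grid masked out as sea.
    """

    t_cold_south: float = 8.0
    t_cold_north: float = -22.0
    gdd5_south: float = 3500.0
    gdd5_north: float = 200.0
    t_cold_noise_sd: float = 2.0
    gdd5_noise_sd: float = 250.0
    moisture_noise_sd: float = 0.15
    correlation_length: float = 5.0
    sea_fraction: float = 0.25


@dataclass
class ClimateFields:
    """Derived bioclimatic variables on one grid."""

    meta: GridMeta
    t_cold: np.ndarray  # minimum temperature of the coldest month, deg C
    gdd5: np.ndarray  # growing degree-days above 5 deg C, >= 0
    moisture: np.ndarray  # dimensionless moisture index in [0, 1]
    mask: np.ndarray  # True = land

    def score_map(self, values: np.ndarray) -> ScoreMap:
        return ScoreMap(self.meta, values, self.mask.copy())


@dataclass(frozen=True)
class ToySpeciesLimits:
    """Bioclimatic gates and response parameters for one toy species.

    The four hard limits follow the classic dynamic-vegetation convention:
    minimum GDD5 for establishment, minimum coldest-month temperature for
    survival and (more restrictive) establishment, maximum coldest-month
    temperature for establishment (a chilling requirement), plus a minimum
    moisture index.  Establishment is at least as restrictive as survival.
    """

    gdd5min_e: float
    t_cold_min_s: float
    t_cold_min_e: float
    t_cold_max_e: float
    moisture_min: float = 0.0

    def __post_init__(self) -> None:
        if self.t_cold_min_e < self.t_cold_min_s:
            raise ValueError(
                "establishment cold limit must be at least the survival limit"
            )
        if not self.t_cold_max_e > self.t_cold_min_e:
            raise ValueError("t_cold_max_e must exceed t_cold_min_e")


@dataclass
class FitnessComponents:
    """Per-cell survival and reproduction probabilities and their product."""

    survival_p: np.ndarray
    reproduction_p: np.ndarray
    fitness: np.ndarray


def _correlated_noise(
    rng: np.random.Generator, shape: tuple[int, int], sd: float, corr_length: float
) -> np.ndarray:
    """Gaussian-filtered white noise rescaled to the requested pointwise sd."""
    if sd == 0:
        return np.zeros(shape)
    white = rng.standard_normal(shape)
    if corr_length > 0:
        smooth = ndimage.gaussian_filter(white, sigma=corr_length, mode="reflect")
        # smoothing shrinks the variance; restore the pointwise sd
        s = smooth.std()
        if s > 0:
            smooth = smooth / s
    else:
        smooth = white
    return sd * smooth


def make_climate(
    meta: GridMeta,
    seed: int,
    params: ClimateParams = ClimateParams(),
) -> ClimateFields:
    """Generate correlated synthetic climate fields on ``meta``.

    Deterministic given (meta, seed, params).  Row 0 is the northernmost
    row, so ``t_cold`` and ``gdd5`` *increase* with row index while
    moisture increases with column index.  The sea mask is built from a
    smoothed noise field thresholded at the requested quantile, giving
    spatially contiguous invalid blobs rather than salt-and-pepper holes.
    """
    rng = np.random.default_rng(seed)
    nr, nc = meta.shape
    lat = np.linspace(0.0, 1.0, nr)[:, None]  # 0 = north edge, 1 = south edge
    lon = np.linspace(0.0, 1.0, nc)[None, :]
    p = params

    ones = np.ones((nr, nc))
    t_cold = (p.t_cold_north + (p.t_cold_south - p.t_cold_north) * lat) * ones
    t_cold += _correlated_noise(rng, (nr, nc), p.t_cold_noise_sd, p.correlation_length)

    gdd5 = (p.gdd5_north + (p.gdd5_south - p.gdd5_north) * lat) * ones
    gdd5 += _correlated_noise(rng, (nr, nc), p.gdd5_noise_sd, p.correlation_length)
    gdd5 = np.maximum(gdd5, 0.0)

    moisture = (0.15 + 0.7 * lon) * ones
    moisture += _correlated_noise(
        rng, (nr, nc), p.moisture_noise_sd, p.correlation_length
    )
    moisture = np.clip(moisture, 0.0, 1.0)

    if p.sea_fraction > 0:
        blob = ndimage.gaussian_filter(
            rng.standard_normal((nr, nc)),
            sigma=max(p.correlation_length, 1.0),
            mode="reflect",
        )
        thresh = np.quantile(blob, p.sea_fraction)
        mask = blob > thresh
    else:
        mask = np.ones((nr, nc), dtype=bool)

    return ClimateFields(
        meta=meta,
        t_cold=np.asarray(t_cold, float),
        gdd5=np.asarray(gdd5, float),
        moisture=np.asarray(moisture, float),
        mask=mask,
    )


# ---------------------------------------------------------------------------
# toy models
# ---------------------------------------------------------------------------

def _trapezoid_low(x: np.ndarray, limit: float, ramp: float) -> np.ndarray:
    """0 below ``limit``, linear ramp of width ``ramp`` above it, then 1."""
    if ramp <= 0:
        return (x >= limit).astype(float)
    return np.clip((x - limit) / ramp, 0.0, 1.0) * (x >= limit)


def _trapezoid_high(x: np.ndarray, limit: float, ramp: float) -> np.ndarray:
    """1 well below ``limit``, ramping down to 0 at it, 0 above."""
    if ramp <= 0:
        return (x <= limit).astype(float)
    return np.clip((limit - x) / ramp, 0.0, 1.0) * (x <= limit)


def envelope_model(
    climate: ClimateFields,
    limits: ToySpeciesLimits,
    ramp_width: dict[str, float] | None = None,
) -> ScoreMap:
    """Correlative bioclimatic envelope: product of trapezoidal responses.

    Each variable contributes a response that is exactly 0 outside its
    hard limit (the on-off switch), climbs linearly over ``ramp_width``
    inside the limit, and is 1 in the core (the establishment-success
    weighting).  The score is the product over variables, so any failed
    hard limit forces 0.

    ``ramp_width`` keys: ``t_cold_low``, ``t_cold_high``, ``gdd5``,
    ``moisture`` (units of the respective variable).
    """
    rw = {"t_cold_low": 4.0, "t_cold_high": 4.0, "gdd5": 400.0, "moisture": 0.15}
    if ramp_width:
        rw.update(ramp_width)
    score = (
        _trapezoid_low(climate.t_cold, limits.t_cold_min_s, rw["t_cold_low"])
        * _trapezoid_high(climate.t_cold, limits.t_cold_max_e, rw["t_cold_high"])
        * _trapezoid_low(climate.gdd5, limits.gdd5min_e, rw["gdd5"])
        * _trapezoid_low(climate.moisture, limits.moisture_min, rw["moisture"])
    )
    return climate.score_map(score)


@dataclass(frozen=True)
class GrowthParams:
    """Logistic growth response: midpoints and steepness per variable."""

    gdd5_mid: float = 900.0
    gdd5_steepness: float = 350.0
    moisture_mid: float = 0.3
    moisture_steepness: float = 0.1
    #: growth below this is treated as "no growth" for the zone decomposition
    growth_floor: float = 1e-3


def _logistic(x: np.ndarray, mid: float, steep: float) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-(x - mid) / steep))


def hybrid_model(
    climate: ClimateFields,
    limits: ToySpeciesLimits,
    growth_params: GrowthParams = GrowthParams(),
    apply_bioclim_limits: bool = True,
) -> tuple[ScoreMap, ScoreMap, BinaryMap, BinaryMap]:
    """Limit-gated growth index (toy NPP/LAI) with nested climatic zones.

    Growth is a smooth saturating (logistic) function of heat sum and
    moisture, product-combined.  The survival zone requires growth plus
    the survival cold limit; the establishment zone additionally requires
    the establishment cold window and the GDD5 minimum — so establishment
    is nested inside survival, which is nested inside the growth area, by
    construction.

    Returns ``(lai, growth, survival_zone, establishment_zone)`` where
    ``lai`` is growth masked to the establishment zone when
    ``apply_bioclim_limits`` is set and raw growth otherwise (the
    "no bioclimatic constraints" run).
    """
    gp = growth_params
    growth = _logistic(climate.gdd5, gp.gdd5_mid, gp.gdd5_steepness) * _logistic(
        climate.moisture, gp.moisture_mid, gp.moisture_steepness
    )
    growth = np.where(growth >= gp.growth_floor, growth, 0.0)
    has_growth = growth > 0
    survival = has_growth & (climate.t_cold >= limits.t_cold_min_s)
    establishment = (
        survival
        & (climate.t_cold >= limits.t_cold_min_e)
        & (climate.t_cold <= limits.t_cold_max_e)
        & (climate.gdd5 >= limits.gdd5min_e)
    )
    lai = np.where(establishment, growth, 0.0) if apply_bioclim_limits else growth
    mk = climate.mask
    return (
        climate.score_map(lai),
        climate.score_map(growth),
        BinaryMap(climate.meta, survival.astype(np.int8), mk.copy()),
        BinaryMap(climate.meta, establishment.astype(np.int8), mk.copy()),
    )


@dataclass(frozen=True)
class FitnessParams:
    """Frost / drought sensitivities and phenology for the fitness model."""

    frost_mid: float = -12.0  # deg C at which frost survival is 50%
    frost_steepness: float = 3.0
    drought_mid: float = 0.25  # moisture index at 50% drought survival
    drought_steepness: float = 0.08
    gdd_requirement: float = 800.0  # heat sum needed to ripen seed
    phenology_steepness: float = 250.0


def fitness_model(
    climate: ClimateFields,
    params: FitnessParams = FitnessParams(),
) -> tuple[ScoreMap, FitnessComponents]:
    """Process-based fitness: survival probability times reproduction probability.

    Survival combines frost survival (logistic in coldest-month
    temperature) and drought survival (logistic in the moisture index);
    reproduction is the probability that seed ripens, logistic in the heat
    sum beyond the species' requirement.  Fitness is their product, so a
    zero in either component zeroes the map regardless of the other.
    """
    p = params
    survival = _logistic(climate.t_cold, p.frost_mid, p.frost_steepness) * _logistic(
        climate.moisture, p.drought_mid, p.drought_steepness
    )
    reproduction = _logistic(
        climate.gdd5 - p.gdd_requirement, 0.0, p.phenology_steepness
    )
    fitness = survival * reproduction
    comps = FitnessComponents(
        survival_p=survival, reproduction_p=reproduction, fitness=fitness
    )
    return climate.score_map(fitness), comps


# ---------------------------------------------------------------------------
# observations and nulls
# ---------------------------------------------------------------------------

def observed_distribution(
    truth_score: ScoreMap,
    occupancy_threshold: float,
    flip_noise: float,
    seed: int,
) -> BinaryMap:
    """Noisy observed presence/absence derived from a reference envelope.

    Presence wherever ``truth_score >= occupancy_threshold``, then each
    valid cell's label is flipped independently with probability
    ``flip_noise`` (imperfect detection and atlas error).  Deterministic
    given the seed.
    """
    if not 0.0 <= flip_noise <= 1.0:
        raise ValueError("flip_noise must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vals = (truth_score.values >= occupancy_threshold).astype(np.int8)
    flips = rng.random(vals.shape) < flip_noise
    vals = np.where(flips & truth_score.mask, 1 - vals, vals)
    return BinaryMap(truth_score.meta, vals, truth_score.mask.copy())


def random_binary_map(meta: GridMeta, p: float, seed: int,
                      mask: np.ndarray | None = None) -> BinaryMap:
    """Independent Bernoulli(p) presence at every valid cell (pure random pattern)."""
    if not 0.0 <= p <= 1.0:
        raise ValueError("p must be in [0, 1]")
    rng = np.random.default_rng(seed)
    vals = (rng.random(meta.shape) < p).astype(np.int8)
    if mask is None:
        mask = np.ones(meta.shape, dtype=bool)
    return BinaryMap(meta, np.where(mask, vals, 0), np.asarray(mask, bool))


def default_species_presets() -> dict[str, ToySpeciesLimits]:
    """Three species archetypes mirroring a boreal / temperate / drought-limited design."""
    return {
        "boreal-like": ToySpeciesLimits(
            gdd5min_e=300.0,
            t_cold_min_s=-30.0,
            t_cold_min_e=-28.0,
            t_cold_max_e=-2.0,
            moisture_min=0.1,
        ),
        "temperate-like": ToySpeciesLimits(
            gdd5min_e=900.0,
            t_cold_min_s=-16.0,
            t_cold_min_e=-13.0,
            t_cold_max_e=6.0,
            moisture_min=0.2,
        ),
        "drought-limited-like": ToySpeciesLimits(
            gdd5min_e=1400.0,
            t_cold_min_s=-9.0,
            t_cold_min_e=-6.0,
            t_cold_max_e=10.0,
            moisture_min=0.35,
        ),
    }
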