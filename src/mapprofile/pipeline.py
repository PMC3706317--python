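"""End-to-end study orchestration.

Runs the full comparison workflow on synthetic data: validate each toy
model against a noisy observed distribution (AUC, SPT, pixel kappa,
multiscale kappa profile), compare the models pairwise (absolute distance
and cross-correlation profiles), derive per-model kappa anomaly profiles,
decompose the hybrid model's range into growth / survival / establishment
areas, and measure the random-pattern kappa null.  Every stage is a plain
function usable on real rasters too; :func:`run_study` wires them together
from a config mapping and writes Table-style CSV/JSON reports.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from . import cmp as cmp_mod
from .cmp import CmpResult, run_cmp
from .evaluation import (
    ValidationRecord,
    auc,
    cohen_kappa,
    confusion,
    dichotomize,
    roc_curve,
    spt_threshold,
)
from .grids import BinaryMap, GridMeta, ScoreMap, standardize, write_grid
from .synthetic import (
    ClimateParams,
    FitnessParams,
    GrowthParams,
    ToySpeciesLimits,
    default_species_presets,
    envelope_model,
    fitness_model,
    hybrid_model,
    make_climate,
    observed_distribution,
    random_binary_map,
)

__all__ = [
    "ComparisonRecord",
    "DecompositionRecord",
    "NullBaselineResult",
    "validate_model",
    "compare_models",
    "kappa_anomaly_profiles",
    "decomposition",
    "null_baseline",
    "default_config",
    "run_study",
]

log = logging.getLogger("mapprofile")


@dataclass(frozen=True)
class ComparisonRecord:
    """One Table-2-style row for a model pair."""

    pair_name: str
    d_0: float
    d_mean: float
    cc_0: float
    cc_mean: float


@dataclass(frozen=True)
class DecompositionRecord:
    """Areas (valid-cell counts) of the nested climatic zones.

    ``survival_reduction_pct`` and ``establishment_reduction_pct`` are the
    percentage of the growth area removed by the survival and
    establishment limits respectively.
    """

    growth_area: int
    survival_area: int
    establishment_area: int
    survival_reduction_pct: float
    establishment_reduction_pct: float


@dataclass
class NullBaselineResult:
    """Random-pattern kappa null over several replicate map pairs."""

    scales: list[int]
    per_scale_mean: np.ndarray
    replicates: pd.DataFrame  # one row per (replicate, scale)
    broad_scale_mean: float  # grand mean over scales >= min_scale
    min_scale: int


def validate_model(
    scores: ScoreMap,
    observed: BinaryMap,
    max_scale: int = 20,
    min_valid_fraction: float = cmp_mod.DEFAULT_MIN_VALID_FRACTION,
) -> tuple[ValidationRecord, CmpResult]:
    """Validate one standardized score map against observed presence/absence.

    AUC and the SPT come from the ROC over all valid cells; the map is
    dichotomised at the SPT and compared with the observation by Cohen's
    kappa, both pixel-by-pixel (kappa_0) and through the multiscale CMP
    profile (kappa_mean = profile mean over scales 1..max_scale).
    """
    curve = roc_curve(scores, observed)
    a = auc(curve)
    spt = spt_threshold(curve)
    predicted = dichotomize(scores, spt)
    kappa_0 = cohen_kappa(confusion(predicted, observed))
    result = run_cmp(
        predicted, observed, "kappa", max_scale=max_scale,
        min_valid_fraction=min_valid_fraction,
    )
    record = ValidationRecord(
        auc=a, spt=spt, kappa_0=kappa_0, kappa_mean=result.profile_mean
    )
    return record, result


def compare_models(
    a: ScoreMap,
    b: ScoreMap,
    max_scale: int = 20,
    pair_name: str = "a-b",
    min_valid_fraction: float = cmp_mod.DEFAULT_MIN_VALID_FRACTION,
) -> tuple[ComparisonRecord, CmpResult, CmpResult]:
    """Pairwise comparison of two standardized model outputs (D and CC)."""
    d = run_cmp(a, b, "D", max_scale=max_scale, min_valid_fraction=min_valid_fraction)
    cc = run_cmp(a, b, "CC", max_scale=max_scale, min_valid_fraction=min_valid_fraction)
    record = ComparisonRecord(
        pair_name=pair_name,
        d_0=d.global_0,
        d_mean=d.profile_mean,
        cc_0=cc.global_0,
        cc_mean=cc.profile_mean,
    )
    return record, d, cc


def kappa_anomaly_profiles(results: dict[str, CmpResult]) -> pd.DataFrame:
    """Per-model kappa anomalies relative to the cross-model mean profile.

    At each scale s the anomaly of model m is
    ``(kappa_m(s) - mean(s)) / mean(s)`` where mean(s) averages the
    models' profile values; it is NaN where the mean is 0.  Anomalies sum
    to zero across models at every defined scale.
    """
    if len(results) < 2:
        raise ValueError("need at least two models to compute anomalies")
    scale_lists = [tuple(r.scales) for r in results.values()]
    if len(set(scale_lists)) != 1:
        raise ValueError("models were profiled over different scale lists")
    scales = list(scale_lists[0])
    profiles = {name: r.profile for name, r in results.items()}
    mean = np.mean(list(profiles.values()), axis=0)
    rows = []
    for name, prof in profiles.items():
        with np.errstate(invalid="ignore", divide="ignore"):
            anomaly = np.where(mean != 0, (prof - mean) / mean, np.nan)
        for s, k, mn, an in zip(scales, prof, mean, anomaly):
            rows.append(
                {"model": name, "scale": s, "kappa": k, "mean_kappa": mn,
                 "anomaly": an}
            )
    return pd.DataFrame(rows)


def decomposition(
    growth: ScoreMap,
    survival_zone: BinaryMap,
    establishment_zone: BinaryMap,
) -> DecompositionRecord:
    """How much of the growth area the bioclimatic limits remove.

    Areas are valid-cell counts of {growth > 0}, the survival zone and the
    establishment zone; each reduction is (1 - zone / growth_area) * 100.
    """
    growth_area = int((growth.valid_values() > 0).sum())
    if growth_area == 0:
        raise ValueError("growth area is empty; decomposition undefined")
    survival_area = int(survival_zone.valid_values().sum())
    establishment_area = int(establishment_zone.valid_values().sum())
    return DecompositionRecord(
        growth_area=growth_area,
        survival_area=survival_area,
        establishment_area=establishment_area,
        survival_reduction_pct=(1 - survival_area / growth_area) * 100.0,
        establishment_reduction_pct=(1 - establishment_area / growth_area) * 100.0,
    )


def null_baseline(
    meta: GridMeta,
    p: float = 0.5,
    n_replicates: int = 10,
    max_scale: int = 20,
    seed: int = 0,
    min_scale: int = 3,
) -> NullBaselineResult:
    """Kappa CMP between pairs of independent pure-random binary maps.

    For each replicate two independent Bernoulli(p) maps are drawn on a
    fully valid grid and compared with the kappa CMP; the per-scale
    profile values are averaged over replicates, and the broad-scale grand
    mean pools scales >= ``min_scale``.  Spatially unstructured patterns
    agree only by chance, so the broad-scale mean sits near zero — the
    floor against which real model/observation profiles are read.
    """
    if n_replicates < 1:
        raise ValueError("need at least one replicate")
    rng = np.random.default_rng(seed)
    pair_seeds = rng.integers(0, 2**31 - 1, size=(n_replicates, 2))
    scales = list(range(1, max_scale + 1))
    rows = []
    profiles = np.empty((n_replicates, len(scales)))
    for i in range(n_replicates):
        a = random_binary_map(meta, p, int(pair_seeds[i, 0]))
        b = random_binary_map(meta, p, int(pair_seeds[i, 1]))
        res = run_cmp(a, b, "kappa", max_scale=max_scale)
        profiles[i] = res.profile
        for s, v in zip(scales, res.profile):
            rows.append({"replicate": i, "scale": s, "kappa": v})
    per_scale = profiles.mean(axis=0)
    broad = float(
        np.nanmean(profiles[:, [i for i, s in enumerate(scales) if s >= min_scale]])
    )
    return NullBaselineResult(
        scales=scales,
        per_scale_mean=per_scale,
        replicates=pd.DataFrame(rows),
        broad_scale_mean=broad,
        min_scale=min_scale,
    )


# ---------------------------------------------------------------------------
# the full study
# ---------------------------------------------------------------------------

def default_config() -> dict:
    """Baseline study configuration (all values overridable).

    A 100x120 grid at 10-arcmin cells with a quarter of cells masked as
    sea; three species archetypes; observations derived from each
    species' envelope truth at occupancy threshold 0.5 with 10% flip
    noise; CMP over scales 1..20; a modest random null.
    """
    species = {
        name: asdict(lim) for name, lim in default_species_presets().items()
    }
    return {
        "grid": {
            "n_rows": 100,
            "n_cols": 120,
            "cell_size": 1.0 / 6.0,
            "origin": [-10.0, 71.0],
        },
        "climate": {"seed": 42, "params": asdict(ClimateParams())},
        "species": species,
        "observation": {
            "occupancy_threshold": 0.5,
            "flip_noise": 0.1,
            "seed": 7,
        },
        "cmp": {"max_scale": 20, "min_valid_fraction": 0.5},
        "null": {"p": 0.5, "n_replicates": 5, "seed": 11, "min_scale": 3},
        "output": {"write_grids": False},
    }


def _merged_config(config: dict | None) -> dict:
    base = default_config()
    if config:
        for key, val in config.items():
            if isinstance(val, dict) and isinstance(base.get(key), dict):
                base[key].update(val)
            else:
                base[key] = val
    return base


MODEL_NAMES = ("envelope", "hybrid", "fitness")


def run_study(config: dict | None = None, out_dir: str | Path = "study_out") -> dict:
    """Run the whole synthetic study and write its reports.

    Writes ``validation.csv`` (species x model: AUC, SPT, kappa_0,
    kappa_mean), ``comparison.csv`` (species x model pair: D_0, D_mean,
    CC_0, CC_mean), ``anomaly_profiles.csv``, ``decomposition.json``,
    ``null_baseline.json`` and, when ``output.write_grids`` is set, the
    model score and multiscale index grids as ESRI ASCII rasters.  Fully
    deterministic given the config.  Returns the report bundle in memory.
    """
    cfg = _merged_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)

    g = cfg["grid"]
    meta = GridMeta(
        n_rows=int(g["n_rows"]),
        n_cols=int(g["n_cols"]),
        cell_size=float(g["cell_size"]),
        origin=tuple(g["origin"]),
    )
    log.info("stage=climate seed=%s grid=%sx%s", cfg["climate"]["seed"],
             meta.n_rows, meta.n_cols)
    climate = make_climate(
        meta, int(cfg["climate"]["seed"]), ClimateParams(**cfg["climate"]["params"])
    )

    max_scale = int(cfg["cmp"]["max_scale"])
    mvf = float(cfg["cmp"]["min_valid_fraction"])
    obs_cfg = cfg["observation"]

    validation_rows = []
    comparison_rows = []
    decomposition_out = {}
    anomaly_frames = []
    grids_to_write: list[tuple[str, ScoreMap]] = []

    for si, (species, lim_kwargs) in enumerate(sorted(cfg["species"].items())):
        limits = ToySpeciesLimits(**lim_kwargs)
        log.info("stage=models species=%s", species)
        env = standardize(envelope_model(climate, limits))
        lai, growth, surv, estab = hybrid_model(climate, limits, GrowthParams())
        hyb = standardize(lai)
        fit_params = FitnessParams(
            frost_mid=limits.t_cold_min_e,
            drought_mid=max(limits.moisture_min, 0.05),
            gdd_requirement=limits.gdd5min_e,
        )
        fit = standardize(fitness_model(climate, fit_params)[0])
        models = {"envelope": env, "hybrid": hyb, "fitness": fit}

        observed = observed_distribution(
            env,
            float(obs_cfg["occupancy_threshold"]),
            float(obs_cfg["flip_noise"]),
            int(obs_cfg["seed"]) + si,
        )

        kappa_results: dict[str, CmpResult] = {}
        for model_name, scores in models.items():
            record, kres = validate_model(
                scores, observed, max_scale=max_scale, min_valid_fraction=mvf
            )
            kappa_results[model_name] = kres
            validation_rows.append(
                {
                    "species": species,
                    "model": model_name,
                    "AUC": record.auc,
                    "SPT": record.spt,
                    "kappa_0": record.kappa_0,
                    "Kappa_mean": record.kappa_mean,
                }
            )
            log.info("stage=validate species=%s model=%s auc=%.3f", species,
                     model_name, record.auc)

        for name_a, name_b in (("hybrid", "envelope"), ("hybrid", "fitness"),
                               ("envelope", "fitness")):
            pair = f"{name_a}-{name_b}"
            record, dres, ccres = compare_models(
                models[name_a], models[name_b], max_scale=max_scale,
                pair_name=pair, min_valid_fraction=mvf,
            )
            comparison_rows.append(
                {
                    "species": species,
                    "pair": pair,
                    "D_0": record.d_0,
                    "D_mean": record.d_mean,
                    "CC_0": record.cc_0,
                    "CC_mean": record.cc_mean,
                }
            )
            if cfg["output"].get("write_grids"):
                grids_to_write.append(
                    (f"{species}_{pair}_D_multiscale.asc",
                     ScoreMap(meta, np.nan_to_num(dres.multiscale_map, nan=-9999.0),
                              dres.mask))
                )

        anomalies = kappa_anomaly_profiles(kappa_results)
        anomalies.insert(0, "species", species)
        anomaly_frames.append(anomalies)

        dec = decomposition(growth, surv, estab)
        decomposition_out[species] = asdict(dec)
        log.info(
            "stage=decomposition species=%s growth=%d survival=%d establishment=%d",
            species, dec.growth_area, dec.survival_area, dec.establishment_area,
        )

        if cfg["output"].get("write_grids"):
            for model_name, scores in models.items():
                grids_to_write.append((f"{species}_{model_name}.asc", scores))

    n_cfg = cfg["null"]
    null = null_baseline(
        meta,
        p=float(n_cfg["p"]),
        n_replicates=int(n_cfg["n_replicates"]),
        max_scale=max_scale,
        seed=int(n_cfg["seed"]),
        min_scale=int(n_cfg["min_scale"]),
    )
    log.info("stage=null broad_scale_mean=%.5f", null.broad_scale_mean)

    validation = pd.DataFrame(validation_rows)
    comparison = pd.DataFrame(comparison_rows)
    anomaly = pd.concat(anomaly_frames, ignore_index=True)

    validation.to_csv(out / "validation.csv", index=False)
    comparison.to_csv(out / "comparison.csv", index=False)
    anomaly.to_csv(out / "anomaly_profiles.csv", index=False)
    with open(out / "decomposition.json", "w") as fh:
        json.dump(decomposition_out, fh, indent=2, sort_keys=True)
    null_out = {
        "p": float(n_cfg["p"]),
        "n_replicates": int(n_cfg["n_replicates"]),
        "min_scale": null.min_scale,
        "per_scale_mean": {
            str(s): float(v) for s, v in zip(null.scales, null.per_scale_mean)
        },
        "broad_scale_mean": null.broad_scale_mean,
    }
    with open(out / "null_baseline.json", "w") as fh:
        json.dump(null_out, fh, indent=2, sort_keys=True)
    with open(out / "config.json", "w") as fh:
        json.dump(cfg, fh, indent=2, sort_keys=True)
    for fname, grid in grids_to_write:
        write_grid(grid, out / fname, format="ascii_grid")

    return {
        "validation": validation,
        "comparison": comparison,
        "anomaly_profiles": anomaly,
        "decomposition": decomposition_out,
        "null_baseline": null,
        "config": cfg,
    }
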