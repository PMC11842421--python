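"""Seeded synthetic dual-column feature tables, covariates and pathway
database with the statistical structure the analysis assumes.

The generator emulates an archived newborn blood-spot metabolomics study:
triplicate injections, batches of 40 samples, intensity-dependent
(left-censoring) missingness, per-feature replicate noise spanning both
sides of the 30% CV QC threshold, overlapping smoking indicators whose
union yields the target prevalence, planted log2-scale exposure effects
on a subset of features, and one planted enriched pathway whose
metabolite masses tie back (exactly, i.e. within any ppm tolerance) to
planted feature m/z values via the [M+H]+ adduct.

All randomness derives from a single ``numpy.random.default_rng(seed)``
stream: the same seed reproduces every artifact bit for bit.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

import numpy as np
from scipy.special import expit

from .core_io import (
    AGE_LEVELS,
    BIRTH_YEAR_LEVELS,
    PROTON_MASS,
    RACE_LEVELS,
    SES_LEVELS,
    SEX_LEVELS,
    FeatureTable,
    Injection,
    Mode,
    MzFeature,
    PathwayDB,
    SampleRecord,
)
from .exposure import COTININE_MZ, HYDROXYCOTININE_MZ, top_fraction_cutoff

__all__ = ["SimConfig", "SimResult", "simulate", "planted_pathway_signal"]

# Pathway names and sizes for the synthetic pathway database.
DEFAULT_PATHWAY_SIZES: dict[str, int] = {
    "Vitamin A (retinol) metabolism": 24,
    "Tryptophan metabolism": 73,
    "Arachidonic acid metabolism": 33,
    "C21-steroid hormone biosynthesis and metabolism": 49,
    "N-Glycan biosynthesis": 23,
    "Androgen and estrogen biosynthesis and metabolism": 40,
    "Glycerophospholipid metabolism": 36,
}

# Marginal covariate frequencies for the emulated cohort.
_RACE_P = (0.34, 0.47, 0.19)
_AGE_P = (0.11, 0.25, 0.27, 0.24, 0.13)
_BIRTH_YEAR_P = (0.21, 0.39, 0.40)
_SEX_P = (0.49, 0.51)
_SES_P = (0.22, 0.28, 0.22, 0.15, 0.13)


@dataclass
class SimConfig:
    seed: int = 0
    n_samples: int = 900
    n_features: int = 2000  # per mode, biomarker features included
    smoker_fraction: float = 0.17
    n_planted_features: int = 60  # split across the two modes
    effect_low: float = 0.5  # |log2 mean shift| range for planted features
    effect_high: float = 1.5
    cv_low: float = 0.10  # per-feature replicate CV range
    cv_high: float = 0.40
    missing_mid: float = 10.0  # log2 intensity with 50% per-replicate dropout
    missing_scale: float = 0.8
    batch_size: int = 40
    batch_sd: float = 0.25
    n_latent_factors: int = 6  # shared sample factors -> inter-feature correlation
    factor_loading_sd: float = 0.15
    baseline_mean: float = 13.5
    baseline_sd: float = 1.8
    biological_sd_low: float = 0.4
    biological_sd_high: float = 1.0
    report_prob: float = 0.11  # P(reported smoker | smoker)
    cotinine_detect_prob: float = 0.78  # P(cotinine detected | smoker)
    hydroxy_nonsmoker_detect_prob: float = 0.10
    hydroxycotinine_top_frac: float = 0.14
    plant_pathway: bool = True
    planted_pathway: str = "Vitamin A (retinol) metabolism"
    n_pathway_features: int = 6  # planted features tied to the planted pathway
    pathway_sizes: Mapping[str, int] | None = None  # defaults to DEFAULT_PATHWAY_SIZES
    pathway_mappable_prob: float = 0.75

    def __post_init__(self) -> None:
        if self.n_planted_features >= self.n_features:
            raise ValueError("n_planted_features must be < n_features")
        if not (0 < self.smoker_fraction < 1):
            raise ValueError("smoker_fraction must be in (0, 1)")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")
        if self.effect_low > self.effect_high or self.effect_low < 0:
            raise ValueError("invalid planted-effect range")
        sizes = self.pathway_sizes or DEFAULT_PATHWAY_SIZES
        if self.plant_pathway:
            if self.planted_pathway not in sizes:
                raise ValueError(f"planted pathway {self.planted_pathway!r} not in pathway set")
            if sizes[self.planted_pathway] < max(4, self.n_pathway_features):
                raise ValueError(
                    f"pathway {self.planted_pathway!r} too small "
                    f"({sizes[self.planted_pathway]} metabolites) to plant >= 4"
                )
            if self.n_pathway_features < 4:
                raise ValueError("need at least 4 pathway-tied planted features")


@dataclass
class SimResult:
    hilic: FeatureTable
    c18: FeatureTable
    samples: list[SampleRecord]
    truth: dict
    pathway_db: PathwayDB


def _draw_covariates(rng: np.random.Generator, n: int) -> dict[str, np.ndarray]:
    return {
        "race_ethnicity": rng.choice(RACE_LEVELS, size=n, p=_RACE_P),
        "maternal_age": rng.choice(AGE_LEVELS, size=n, p=_AGE_P),
        "birth_year_band": rng.choice(BIRTH_YEAR_LEVELS, size=n, p=_BIRTH_YEAR_P),
        "sex": rng.choice(SEX_LEVELS, size=n, p=_SEX_P),
        "ses": rng.choice(np.array(SES_LEVELS), size=n, p=_SES_P),
    }


def _simulate_mode(
    rng: np.random.Generator,
    cfg: SimConfig,
    mode: Mode,
    exposure: np.ndarray,
    batch_idx: np.ndarray,
    n_planted: int,
    biomarkers: dict[str, np.ndarray] | None,
) -> tuple[FeatureTable, dict]:
    """Generate one mode's injection-level table plus per-mode truth."""
    F, n = cfg.n_features, cfg.n_samples
    n_batches = int(batch_idx.max()) + 1

    mz = rng.uniform(85.0, 1275.0, size=F)
    rt = rng.uniform(10.0, 700.0, size=F)
    mu = rng.normal(cfg.baseline_mean, cfg.baseline_sd, size=F)
    sigma = rng.uniform(cfg.biological_sd_low, cfg.biological_sd_high, size=F)
    cv = rng.uniform(cfg.cv_low, cfg.cv_high, size=F)
    batch_fx = rng.normal(0.0, cfg.batch_sd, size=(F, n_batches))

    reserved = 2 if biomarkers is not None else 0  # biomarker rows in HILIC
    if biomarkers is not None:
        mz[0], rt[0] = COTININE_MZ, 60.0
        mz[1], rt[1] = HYDROXYCOTININE_MZ, 75.0

    # planted features: restricted to rows likely to survive QC
    candidates = np.where(
        (np.arange(F) >= reserved)
        & (mu >= np.median(mu))
        & (cv <= 0.22)
        & (sigma >= 0.7)
    )[0]
    if candidates.size < n_planted:
        raise ValueError("too few QC-robust candidate features to plant effects")
    planted = np.sort(rng.choice(candidates, size=n_planted, replace=False))
    effects = np.zeros(F)
    magnitude = rng.uniform(cfg.effect_low, cfg.effect_high, size=n_planted)
    sign = rng.choice([-1.0, 1.0], size=n_planted)
    effects[planted] = magnitude * sign

    z = (
        mu[:, None]
        + sigma[:, None] * rng.normal(size=(F, n))
        + effects[:, None] * exposure[None, :].astype(float)
        + batch_fx[:, batch_idx]
    )
    if cfg.n_latent_factors > 0:
        # shared latent sample factors: features co-vary as real metabolite
        # panels do (and kNN imputation has signal to exploit)
        loadings = rng.normal(0.0, cfg.factor_loading_sd, size=(F, cfg.n_latent_factors))
        factors = rng.normal(size=(cfg.n_latent_factors, n))
        z = z + loadings @ factors

    if biomarkers is not None:
        with np.errstate(divide="ignore"):
            z[0] = np.where(biomarkers["cotinine"] > 0, np.log2(biomarkers["cotinine"]), np.nan)
            z[1] = np.where(
                biomarkers["hydroxycotinine"] > 0,
                np.log2(biomarkers["hydroxycotinine"]),
                np.nan,
            )

    raw = np.exp2(z)
    noise = np.exp(
        cv[:, None, None] * rng.normal(size=(F, n, 3)) - 0.5 * cv[:, None, None] ** 2
    )
    reps = raw[:, :, None] * noise

    p_miss = expit((cfg.missing_mid - z) / cfg.missing_scale)
    dropout = rng.random(size=(F, n, 3)) < p_miss[:, :, None]
    if biomarkers is not None:
        # biomarker absence is detection-driven, not intensity-censoring
        dropout[0] = np.isnan(z[0])[:, None]
        dropout[1] = np.isnan(z[1])[:, None]
    reps[dropout] = np.nan
    reps = np.nan_to_num(reps, nan=np.nan, posinf=np.nan)  # guard overflow

    sample_ids = [f"S{i:04d}" for i in range(n)]
    injections = [
        Injection(sample_ids[i], r, f"B{batch_idx[i]:02d}")
        for i in range(n)
        for r in (1, 2, 3)
    ]
    features = [
        MzFeature(f"{mode.value}_{i:05d}", float(mz[i]), float(rt[i]), mode) for i in range(F)
    ]
    table = FeatureTable(
        features=features, injections=injections, intensities=reps.reshape(F, n * 3)
    )
    truth = {
        "planted": {
            features[i].feature_id: float(effects[i]) for i in planted
        },
        "true_log2_intensity_mean": mu.tolist(),
        "planted_indices": planted.tolist(),
    }
    return table, truth


def _build_pathway_db(
    rng: np.random.Generator,
    cfg: SimConfig,
    hilic: FeatureTable,
    c18: FeatureTable,
    planted_feature_ids: list[str],
) -> tuple[PathwayDB, dict[str, str]]:
    """Synthetic pathway database; most metabolite masses are derived from
    detected feature m/z values minus an adduct shift so they are mappable,
    and the planted pathway's first metabolites tie exactly to planted
    features via [M+H]+."""
    from .annotate import ADDUCT_SHIFTS

    sizes = dict(cfg.pathway_sizes or DEFAULT_PATHWAY_SIZES)
    tables = {Mode.HILIC_POS: hilic, Mode.C18_NEG: c18}
    id_to_mz = {
        f.feature_id: f.mz for t in tables.values() for f in t.features
    }

    # source features for mappable masses: bias toward QC-robust rows
    sources: dict[Mode, np.ndarray] = {}
    for mode, t in tables.items():
        mzs = t.mz
        start = 2 if mode is Mode.HILIC_POS else 0
        sources[mode] = mzs[start:]

    pathways: dict[str, set[str]] = {}
    masses: dict[str, float] = {}
    planted_map: dict[str, str] = {}
    counter = 0
    for name, size in sizes.items():
        members: set[str] = set()
        n_tied = 0
        if cfg.plant_pathway and name == cfg.planted_pathway:
            for fid in planted_feature_ids:
                mid = f"MET{counter:05d}"
                counter += 1
                masses[mid] = id_to_mz[fid] - PROTON_MASS
                members.add(mid)
                planted_map[fid] = mid
                n_tied += 1
        for _ in range(size - n_tied):
            mid = f"MET{counter:05d}"
            counter += 1
            if rng.random() < cfg.pathway_mappable_prob:
                mode = Mode.HILIC_POS if rng.random() < 0.5 else Mode.C18_NEG
                shift_vals = list(ADDUCT_SHIFTS[mode].values())
                for _attempt in range(20):
                    src_mz = float(rng.choice(sources[mode]))
                    shift = shift_vals[int(rng.integers(len(shift_vals)))]
                    mass = src_mz - shift
                    if mass > 50.0:
                        break
                masses[mid] = mass
            else:
                masses[mid] = float(rng.uniform(100.0, 900.0))
            members.add(mid)
        pathways[name] = members
    return PathwayDB(pathways=pathways, metabolite_masses=masses), planted_map


def simulate(cfg: SimConfig) -> SimResult:
    """Generate both modes' tables, the covariate records, the pathway
    database and a ground-truth record.  Deterministic given ``cfg.seed``."""
    rng = np.random.default_rng(cfg.seed)
    n = cfg.n_samples
    sample_ids = [f"S{i:04d}" for i in range(n)]
    batch_idx = np.arange(n) // cfg.batch_size

    cov = _draw_covariates(rng, n)

    latent = rng.random(n) < cfg.smoker_fraction
    reported = latent & (rng.random(n) < cfg.report_prob)
    cot_detected = latent & (rng.random(n) < cfg.cotinine_detect_prob)
    cotinine = np.where(cot_detected, np.exp2(rng.normal(13.0, 1.0, size=n)), 0.0)
    hyd_nonsmoker_det = (~latent) & (rng.random(n) < cfg.hydroxy_nonsmoker_detect_prob)
    hydroxy = np.zeros(n)
    hydroxy[latent] = np.exp2(rng.normal(14.5, 1.0, size=int(latent.sum())))
    hydroxy[hyd_nonsmoker_det] = np.exp2(
        rng.normal(12.5, 1.0, size=int(hyd_nonsmoker_det.sum()))
    )

    # union rule on the underlying biomarker values = ground-truth exposure
    cutoff = top_fraction_cutoff(hydroxy, cfg.hydroxycotinine_top_frac)
    hyd_flag = (hydroxy >= cutoff) & (hydroxy > 0)
    exposure = reported | (cotinine > 0) | hyd_flag

    samples = [
        SampleRecord(
            sample_id=sample_ids[i],
            reported_smoker=bool(reported[i]),
            race_ethnicity=str(cov["race_ethnicity"][i]),
            maternal_age=str(cov["maternal_age"][i]),
            birth_year_band=str(cov["birth_year_band"][i]),
            sex=str(cov["sex"][i]),
            ses=int(cov["ses"][i]),
        )
        for i in range(n)
    ]

    n_hilic_planted = cfg.n_planted_features - cfg.n_planted_features // 2
    n_c18_planted = cfg.n_planted_features // 2
    hilic, hilic_truth = _simulate_mode(
        rng,
        cfg,
        Mode.HILIC_POS,
        exposure,
        batch_idx,
        n_hilic_planted,
        biomarkers={"cotinine": cotinine, "hydroxycotinine": hydroxy},
    )
    c18, c18_truth = _simulate_mode(
        rng, cfg, Mode.C18_NEG, exposure, batch_idx, n_c18_planted, biomarkers=None
    )

    planted_hilic_ids = list(hilic_truth["planted"])
    pathway_feature_ids = (
        planted_hilic_ids[: cfg.n_pathway_features] if cfg.plant_pathway else []
    )
    pathway_db, planted_map = _build_pathway_db(rng, cfg, hilic, c18, pathway_feature_ids)

    truth = {
        "exposure": {sample_ids[i]: bool(exposure[i]) for i in range(n)},
        "latent_smoker": {sample_ids[i]: bool(latent[i]) for i in range(n)},
        "indicators": {
            "report": [sample_ids[i] for i in range(n) if reported[i]],
            "cotinine": [sample_ids[i] for i in range(n) if cotinine[i] > 0],
            "hydroxycotinine": [sample_ids[i] for i in range(n) if hyd_flag[i]],
        },
        "biomarker_features": {
            "cotinine": hilic.features[0].feature_id,
            "hydroxycotinine": hilic.features[1].feature_id,
        },
        "planted": {
            Mode.HILIC_POS.value: hilic_truth["planted"],
            Mode.C18_NEG.value: c18_truth["planted"],
        },
        "planted_pathway": cfg.planted_pathway if cfg.plant_pathway else None,
        "planted_pathway_map": planted_map,
        "true_mu": {
            Mode.HILIC_POS.value: hilic_truth["true_log2_intensity_mean"],
            Mode.C18_NEG.value: c18_truth["true_log2_intensity_mean"],
        },
    }
    return SimResult(hilic=hilic, c18=c18, samples=samples, truth=truth, pathway_db=pathway_db)


def planted_pathway_signal(sim: SimResult) -> dict[str, str]:
    """Feature -> metabolite map of the planted pathway signal.

    At least 4 planted features carry m/z values equal (exactly, hence
    within 1 ppm) to [M+H]+ adduct masses of planted-pathway metabolites.
    Raises when the simulation was run without pathway planting.
    """
    if not sim.truth["planted_pathway"]:
        raise ValueError("simulation was run with pathway planting disabled")
    return dict(sim.truth["planted_pathway_map"])
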