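"""Synthetic cohorts with the statistical structure the analysis assumes.

The generator emulates a balanced 2 genotype x 2 diet x 5 mice design with
repeated plasma/liver measurements: log-normal metabolite intensities with a
decreasing mean-variance trend, planted additive genotype/diet/interaction
effects on log2 scale, informative left-censored missingness plus a small
MCAR component, structurally-zero wild-type polyp counts with
negative-binomial mutant counts driven by one plasma metabolite, and a
targeted acyl-CoA concentration table.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .io import (
    CompoundSet,
    IntensityMatrix,
    PolypCounts,
    StudyDesign,
    ValidationError,
)

# Default group means for the total long-chain acyl-CoA pool
# (nmol per mg wet liver tissue).
ACYLCOA_TOTAL_MEANS = {"WT-LF": 1.16, "MU-LF": 0.41, "WT-HF": 1.27, "MU-HF": 1.52}
# Constant split of the long-chain total over species.
ACYLCOA_FRACTIONS = {"C12-CoA": 0.15, "C14-CoA": 0.15, "C16-CoA": 0.45,
                     "C18-CoA": 0.25}
# Free coenzyme A pool; drives the [Acyl-CoA]/[CoASH] ratio downward in the
# mutant high-fat group.
COASH_MEANS = {"WT-LF": 0.80, "MU-LF": 0.40, "WT-HF": 0.85, "MU-HF": 1.60}


@dataclass
class SimConfig:
    """Study conditions for the synthetic cohort.

    Defaults encode the study design the pipeline targets: 2x2 factorial,
    five mice per cell, ~220 metabolites of which 97/82/65 carry genotype /
    diet / interaction effects, 5% left-censoring plus 2% MCAR missingness,
    and polyp counts that are structurally zero in wild-type mice while
    mutant group totals centre on 51 (low fat) and 273 (high fat).
    """

    n_per_group: int = 5
    p_metabolites: int = 220
    n_genotype: int = 97
    n_diet: int = 82
    n_interaction: int = 65
    #: fraction of interaction-effect metabolites shared with the main-effect sets
    interaction_overlap: float = 0.5
    #: up-regulated fractions per contrast (genotype, diet, interaction)
    frac_up: tuple[float, float, float] = (61 / 97, 44 / 82, 46 / 65)
    effect_low: float = 0.5
    effect_high: float = 2.0
    baseline_log_mean: float = 10.0
    baseline_log_sd: float = 2.0
    # sd(mu) = a * exp(-b * mu) + c on log2 scale: low-abundance metabolites
    # are noisier, as in MS intensity data.
    mv_a: float = 2.0
    mv_b: float = 0.25
    mv_c: float = 0.35
    censor_quantile: float = 0.05
    mcar_rate: float = 0.02
    #: fraction of metabolites carrying database annotations
    annotated_fraction: float = 0.38
    # Polyp-count model.  Wild-type mice are structural zeros (pi0 = 1);
    # mutant counts are negative binomial with
    # log-mean beta0 + beta_D * D + beta_gdy * G * D * Y(driver), Y standardised.
    pi0: float = 1.0
    beta0: float = math.log(51 / 5)
    beta_gdy: float = 1.2
    # beta_D is calibrated so E[total MU-HF] = 273 after the lognormal
    # correction E[exp(beta_gdy * Z)] = exp(beta_gdy^2 / 2).
    beta_d: float = math.log(273 / 51) - (1.2 ** 2) / 2
    theta: float = 4.0
    #: driver metabolite index; None picks the first effect-free metabolite
    driver_index: int | None = None
    #: lognormal coefficient of variation for acyl-CoA concentrations
    acylcoa_cv: float = 0.44
    acylcoa_species: tuple[str, ...] = tuple(ACYLCOA_FRACTIONS) + ("CoASH",)
    seed: int = 0

    def validate(self) -> None:
        for name in ("censor_quantile", "mcar_rate", "interaction_overlap",
                     "pi0", "annotated_fraction"):
            value = getattr(self, name)
            if not 0.0 <= value <= 1.0:
                raise ValidationError(f"{name}={value} outside [0, 1]")
        for name in ("n_genotype", "n_diet", "n_interaction"):
            if getattr(self, name) > self.p_metabolites:
                raise ValidationError(f"{name} exceeds p_metabolites")
        if self.theta <= 0:
            raise ValidationError("theta must be > 0")
        if self.n_per_group < 1 or self.p_metabolites < 1:
            raise ValidationError("n_per_group and p_metabolites must be >= 1")
        if not 0 < self.effect_low <= self.effect_high:
            raise ValidationError("effect size range must satisfy 0 < low <= high")


@dataclass
class CohortTruth:
    """Ground truth of a simulated cohort, for recovery tests."""

    genotype_effects: dict[int, float]
    diet_effects: dict[int, float]
    interaction_effects: dict[int, float]
    driver_index: int
    driver_z: np.ndarray  # standardised driver values per mouse (plasma order)
    polyp_coefficients: dict[str, float]
    latent: dict[str, np.ndarray]  # tissue -> uncensored log2 matrix
    detection_limits: dict[str, np.ndarray]  # tissue -> per-metabolite limit
    seed: int


@dataclass
class SyntheticCohort:
    intensity: dict[str, IntensityMatrix]  # keyed by tissue (PLA, LIV)
    design: StudyDesign
    polyps: PolypCounts
    truth: CohortTruth


def _build_design(n_per_group: int) -> StudyDesign:
    """Table-1 layout: mice 1..n WT-LF, then WT-HF, MU-LF, MU-HF; both tissues."""
    sample_ids, mouse_ids, genotypes, diets, tissues = [], [], [], [], []
    mouse = 0
    for genotype in ("WT", "MU"):
        for diet in ("LF", "HF"):
            for _ in range(n_per_group):
                mouse += 1
                for tissue in ("PLA", "LIV"):
                    sample_ids.append(f"M{mouse:03d}_{tissue}")
                    mouse_ids.append(f"M{mouse:03d}")
                    genotypes.append(genotype)
                    diets.append(diet)
                    tissues.append(tissue)
    return StudyDesign(sample_ids, mouse_ids, genotypes, diets, tissues)


def _plant_effects(rng: np.random.Generator, config: SimConfig):
    """Choose effect metabolites, signs and log2 sizes for the three contrasts."""
    p = config.p_metabolites

    def draw_signed_sizes(indices: np.ndarray, frac_up: float) -> dict[int, float]:
        sizes = rng.uniform(config.effect_low, config.effect_high, len(indices))
        n_up = int(round(frac_up * len(indices)))
        signs = np.array([1.0] * n_up + [-1.0] * (len(indices) - n_up))
        rng.shuffle(signs)
        return {int(j): float(s * z) for j, s, z in zip(indices, signs, sizes)}

    geno_idx = rng.choice(p, size=config.n_genotype, replace=False)
    diet_idx = rng.choice(p, size=config.n_diet, replace=False)
    # Interaction metabolites partially overlap the union of the main sets.
    main_union = np.union1d(geno_idx, diet_idx)
    n_shared = min(int(round(config.interaction_overlap * config.n_interaction)),
                   len(main_union))
    shared = rng.choice(main_union, size=n_shared, replace=False)
    rest_pool = np.setdiff1d(np.arange(p), main_union)
    n_fresh = config.n_interaction - n_shared
    fresh = rng.choice(rest_pool, size=min(n_fresh, len(rest_pool)), replace=False)
    inter_idx = np.concatenate([shared, fresh]).astype(int)

    return (
        draw_signed_sizes(geno_idx, config.frac_up[0]),
        draw_signed_sizes(diet_idx, config.frac_up[1]),
        draw_signed_sizes(inter_idx, config.frac_up[2]),
    )


def simulate_cohort(config: SimConfig | None = None,
                    seed: int | None = None) -> SyntheticCohort:
    """Draw one synthetic cohort.

    Identical ``config`` + ``seed`` give bit-identical output.  ``seed``
    overrides ``config.seed`` when given.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(seed)

    design = _build_design(config.n_per_group)
    n_mice = 4 * config.n_per_group
    p = config.p_metabolites

    geno_eff, diet_eff, inter_eff = _plant_effects(rng, config)

    # Per-metabolite baselines and mean-variance trend on log2 scale.
    mu = rng.normal(config.baseline_log_mean, config.baseline_log_sd, p)
    sd = config.mv_a * np.exp(-config.mv_b * mu) + config.mv_c

    metabolite_ids = [f"MET{j + 1:04d}" for j in range(p)]
    annotations = _synthetic_annotations(rng, metabolite_ids,
                                         config.annotated_fraction)

    # Mouse-level factor codes (+-1), identical for both tissues.
    pla = design.subset_tissue("PLA")
    g_code = np.where(np.array(pla.genotype) == "MU", 1.0, -1.0)
    d_code = np.where(np.array(pla.diet) == "HF", 1.0, -1.0)

    effects = np.zeros((p, n_mice))
    for j, e in geno_eff.items():
        effects[j] += (e / 2.0) * g_code
    for j, e in diet_eff.items():
        effects[j] += (e / 2.0) * d_code
    for j, e in inter_eff.items():
        effects[j] += (e / 4.0) * g_code * d_code

    # The polyp model conditions on the driver metabolite's measured values,
    # so the driver is planted on a reliably detected metabolite: the
    # highest-abundance effect-free one (never near the detection limit) and
    # exempt from MCAR dropout.
    driver = config.driver_index
    if driver is None:
        planted = set(geno_eff) | set(diet_eff) | set(inter_eff)
        free = [j for j in range(p) if j not in planted]
        driver = int(max(free, key=lambda j: mu[j]))

    latent: dict[str, np.ndarray] = {}
    limits: dict[str, np.ndarray] = {}
    intensity: dict[str, IntensityMatrix] = {}
    for tissue in ("PLA", "LIV"):
        tdesign = design.subset_tissue(tissue)
        noise = rng.normal(0.0, 1.0, (p, n_mice)) * sd[:, None]
        log2_latent = mu[:, None] + effects + noise
        # Instrument detection limit: censor_quantile of all intensities
        # pooled, so missingness concentrates in low-abundance metabolites
        # (informative left-censoring).
        limit = float(np.quantile(log2_latent, config.censor_quantile))
        censored = log2_latent < limit
        mcar = rng.random((p, n_mice)) < config.mcar_rate
        mcar[driver, :] = False
        mask = censored | mcar
        raw = np.power(2.0, log2_latent)
        raw = np.where(mask, 1.0, raw)  # placeholder under the mask
        latent[tissue] = log2_latent
        limits[tissue] = np.full(p, limit)
        intensity[tissue] = IntensityMatrix(
            raw, mask, list(metabolite_ids), list(tdesign.sample_ids),
            annotations, scale_tag="raw",
        )

    driver_y = latent["PLA"][driver]
    z = (driver_y - driver_y.mean()) / driver_y.std(ddof=0)

    counts = np.zeros(n_mice, dtype=int)
    is_mu = g_code > 0
    is_hf = d_code > 0
    structural_zero = (~is_mu) & (rng.random(n_mice) < config.pi0)
    log_mean = (config.beta0 + config.beta_d * is_hf.astype(float)
                + config.beta_gdy * is_mu * is_hf * z)
    mean = np.exp(log_mean)
    nb_p = config.theta / (config.theta + mean)
    draws = rng.negative_binomial(config.theta, nb_p)
    counts = np.where(is_mu, draws, np.where(structural_zero, 0, draws))
    counts = np.where(~is_mu & structural_zero, 0, counts)

    polyps = PolypCounts(list(pla.mouse_id), counts.astype(int))
    truth = CohortTruth(
        genotype_effects=geno_eff,
        diet_effects=diet_eff,
        interaction_effects=inter_eff,
        driver_index=int(driver),
        driver_z=z,
        polyp_coefficients={
            "beta0": config.beta0, "beta_d": config.beta_d,
            "beta_gdy": config.beta_gdy, "theta": config.theta,
            "pi0": config.pi0,
        },
        latent=latent,
        detection_limits=limits,
        seed=int(seed),
    )
    return SyntheticCohort(intensity, design, polyps, truth)


def _synthetic_annotations(rng: np.random.Generator, metabolite_ids: list[str],
                           fraction: float) -> pd.DataFrame:
    """Synthetic HMDB/CAS/KEGG-style identifiers for a fraction of metabolites."""
    p = len(metabolite_ids)
    n_annotated = int(round(fraction * p))
    annotated = set(rng.choice(p, size=n_annotated, replace=False).tolist())
    rows = []
    for j, mid in enumerate(metabolite_ids):
        if j in annotated:
            rows.append({
                "name": f"compound-{j + 1}",
                "HMDB": f"HMDB{90000 + j:05d}",
                "CAS": f"{1000 + j}-00-{j % 10}",
                "KEGG": f"C{90000 + j:05d}",
            })
        else:
            rows.append({"name": "", "HMDB": "", "CAS": "", "KEGG": ""})
    return pd.DataFrame(rows, index=pd.Index(metabolite_ids))


def simulate_acylcoa(config: SimConfig | None = None,
                     seed: int | None = None) -> pd.DataFrame:
    """Per-mouse acyl-CoA concentrations (nmol per mg wet liver tissue).

    Concentrations are lognormal around group means whose defaults put the
    total long-chain pool at 1.16 / 0.41 / 1.27 / 1.52 for WT-LF / MU-LF /
    WT-HF / MU-HF in expectation.  Returns a tidy frame with columns
    ``mouse_id, group, species, concentration``.
    """
    config = config or SimConfig()
    config.validate()
    if seed is None:
        seed = config.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 2]))

    species_means: dict[str, dict[str, float]] = {}
    for species in config.acylcoa_species:
        if species == "CoASH":
            species_means[species] = dict(COASH_MEANS)
        elif species in ACYLCOA_FRACTIONS:
            frac = ACYLCOA_FRACTIONS[species]
            species_means[species] = {
                g: frac * m for g, m in ACYLCOA_TOTAL_MEANS.items()
            }
        else:
            raise ValidationError(f"no configured mean for species {species!r}")
    for species, means in species_means.items():
        if any(m < 0 for m in means.values()):
            raise ValidationError(f"negative configured mean for {species!r}")

    cv = config.acylcoa_cv
    sigma2 = math.log(1.0 + cv * cv)
    sigma = math.sqrt(sigma2)

    rows = []
    mouse = 0
    for genotype in ("WT", "MU"):
        for diet in ("LF", "HF"):
            group = f"{genotype}-{diet}"
            for _ in range(config.n_per_group):
                mouse += 1
                for species in config.acylcoa_species:
                    mean = species_means[species][group]
                    draw = mean * math.exp(
                        rng.normal(-sigma2 / 2.0, sigma)
                    ) if mean > 0 else 0.0
                    rows.append({
                        "mouse_id": f"M{mouse:03d}",
                        "group": group,
                        "species": species,
                        "concentration": draw,
                    })
    return pd.DataFrame(rows, columns=["mouse_id", "group", "species",
                                       "concentration"])


def simulate_compound_sets(cohort: SyntheticCohort, n_sets: int = 5,
                           seed: int | None = None) -> list[CompoundSet]:
    """Random compound sets over the cohort's annotated universe (for the
    enrichment stage of simulated end-to-end runs)."""
    if seed is None:
        seed = cohort.truth.seed
    rng = np.random.default_rng(np.random.SeedSequence([int(seed), 3]))
    ann = cohort.intensity["PLA"].annotation_frame()
    universe = [h for h in ann["HMDB"] if h]
    sets = []
    for k in range(n_sets):
        size = int(rng.integers(5, max(6, len(universe) // 3)))
        members = rng.choice(universe, size=min(size, len(universe)),
                             replace=False)
        sets.append(CompoundSet(f"SET{k + 1}", f"synthetic set {k + 1}",
                                frozenset(members.tolist())))
    return sets
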