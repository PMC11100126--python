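"""Synthetic multi-ancestry genotype/phenotype cohorts.

Emulates the structure the cross-population evaluation needs: one large
training population plus several smaller, genetically diverged target
populations; a heritable continuous trait with tunable polygenicity; sex and
age covariates; optional genotype missingness.

Divergence follows the Balding-Nichols model: given an ancestral allele
frequency ``p`` and a fixation index ``F`` (F_ST), a population-specific
frequency is drawn from ``Beta(p (1-F)/F, (1-p)(1-F)/F)``, which has mean
``p`` and variance ``F p (1-p)``.  Variants are in linkage equilibrium within
populations — LD is irrelevant to the metric comparison this package exists
for, and is an explicit non-goal.

Cross-population portability is degraded by two mechanisms:

* per-variant causal effects in a target population are drawn jointly normal
  with the training-population effects at correlation ``effect_correlation``
  (this attenuates discrimination, i.e. r^2, not just calibration);
* an additive environmental mean offset ``env_shift`` (this produces pure
  miscalibration, the driver of negative MSPE-based R^2 values).

Causal effects follow an equal-variance-share architecture: each of the
``causal_fraction * m`` causal variants explains ``heritability / n_causal``
of the trait variance in the training population (random sign, magnitude
scaled by its allele frequency), so the genetic variance fraction of
(genetics + noise) equals ``heritability`` exactly and every causal variant
carries real signal.  The trait SD in the training population is therefore
~1 before covariate effects, and ``env_shift`` is expressed in approximate
trait SD units.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "PopulationSpec",
    "ArchitectureSpec",
    "GenotypeMatrix",
    "draw_population_frequencies",
    "simulate_cohort",
    "inject_missingness",
]

_AGE_CENTER = 54.5  # midpoint of the 40-69 recruitment window


@dataclass(frozen=True)
class PopulationSpec:
    """Simulation parameters for one population.

    ``fst`` is the Balding-Nichols divergence from the ancestral pool,
    ``effect_correlation`` the correlation of causal effects with the training
    population (1 for the training population itself), ``env_shift`` an
    additive environmental mean offset in trait units (~trait SD).
    ``sex_effect``/``age_effect`` are covariate coefficients in trait units
    per unit covariate (sex in {0,1}; age centered at 54.5 years).
    """

    name: str
    n: int
    fst: float = 0.0
    effect_correlation: float = 1.0
    env_shift: float = 0.0
    sex_effect: float = 0.3
    age_effect: float = 0.01

    def __post_init__(self):
        if self.n < 1:
            raise ValueError(f"population {self.name!r}: n must be >= 1")
        if not 0.0 <= self.fst < 0.5:
            raise ValueError(
                f"population {self.name!r}: fst must lie in [0, 0.5), got {self.fst}"
            )
        if not 0.0 <= self.effect_correlation <= 1.0:
            raise ValueError(
                f"population {self.name!r}: effect_correlation must lie in [0, 1]"
            )


@dataclass(frozen=True)
class ArchitectureSpec:
    """Genetic architecture and cohort-level simulation parameters.

    ``causal_fraction`` close to 0 gives an oligogenic trait, larger values a
    polygenic one.  ``heritability`` is the genetic fraction of
    genetic-plus-noise variance in the training population.  Ancestral allele
    frequencies are uniform on ``maf_range``.
    """

    m: int = 5000
    causal_fraction: float = 0.01
    heritability: float = 0.5
    maf_range: tuple[float, float] = (0.05, 0.5)
    missing_rate: float = 0.0
    seed: int = 0

    def __post_init__(self):
        if not 0.0 <= self.heritability < 1.0:
            raise ValueError("heritability must lie in [0, 1)")
        if not 0.0 < self.causal_fraction <= 1.0:
            raise ValueError("causal_fraction must lie in (0, 1]")
        if self.causal_fraction * self.m < 1:
            raise ValueError("causal_fraction * m must be at least 1")
        lo, hi = self.maf_range
        if not 0.0 < lo <= hi <= 0.5:
            raise ValueError("maf_range must satisfy 0 < low <= high <= 0.5")
        if not 0.0 <= self.missing_rate < 1.0:
            raise ValueError("missing_rate must lie in [0, 1)")


@dataclass(frozen=True)
class GenotypeMatrix:
    """Individuals x variants additive dosage matrix with variant metadata.

    ``dosages`` holds effect-allele counts in {0, 1, 2} as floats with NaN
    marking missing genotypes.  ``true_betas`` (variants x populations) and
    ``population_frequencies`` retain the simulation truth for
    parameter-recovery tests; both are ``None`` for data read from disk.
    """

    dosages: np.ndarray
    variant_ids: np.ndarray
    effect_alleles: np.ndarray
    other_alleles: np.ndarray
    sample_ids: np.ndarray
    population_labels: np.ndarray
    true_betas: pd.DataFrame | None = None
    population_frequencies: pd.DataFrame | None = None

    def __post_init__(self):
        n, m = self.dosages.shape
        for name, arr, expect in [
            ("variant_ids", self.variant_ids, m),
            ("effect_alleles", self.effect_alleles, m),
            ("other_alleles", self.other_alleles, m),
            ("sample_ids", self.sample_ids, n),
            ("population_labels", self.population_labels, n),
        ]:
            if len(arr) != expect:
                raise ValueError(f"{name} has length {len(arr)}, expected {expect}")
        valid = np.isnan(self.dosages) | np.isin(self.dosages, (0.0, 1.0, 2.0))
        if not valid.all():
            raise ValueError("dosages must be 0, 1, 2 or NaN (missing)")
        if len(set(map(str, self.variant_ids))) != m:
            raise ValueError("variant ids must be unique")

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_variants(self) -> int:
        return self.dosages.shape[1]

    def call_rate(self, individuals: np.ndarray | None = None) -> np.ndarray:
        """Per-variant fraction of non-missing genotypes."""
        d = self.dosages if individuals is None else self.dosages[individuals]
        return 1.0 - np.isnan(d).mean(axis=0)

    def effect_allele_frequency(
        self, individuals: np.ndarray | None = None
    ) -> np.ndarray:
        """Per-variant effect-allele frequency among non-missing genotypes."""
        d = self.dosages if individuals is None else self.dosages[individuals]
        with np.errstate(invalid="ignore"):
            return np.nanmean(d, axis=0) / 2.0

    def maf(self, individuals: np.ndarray | None = None) -> np.ndarray:
        f = self.effect_allele_frequency(individuals)
        return np.minimum(f, 1.0 - f)

    def subset(
        self,
        individuals: np.ndarray | None = None,
        variants: np.ndarray | None = None,
    ) -> "GenotypeMatrix":
        """Row/column subset; indices or boolean masks."""
        d = self.dosages
        sample_ids, pops = self.sample_ids, self.population_labels
        if individuals is not None:
            d = d[individuals]
            sample_ids = sample_ids[individuals]
            pops = pops[individuals]
        vids, ea, oa = self.variant_ids, self.effect_alleles, self.other_alleles
        tb, pf = self.true_betas, self.population_frequencies
        if variants is not None:
            d = d[:, variants]
            vids, ea, oa = vids[variants], ea[variants], oa[variants]
            if tb is not None:
                tb = tb.iloc[np.arange(self.n_variants)[variants]]
            if pf is not None:
                pf = pf.iloc[np.arange(self.n_variants)[variants]]
        return GenotypeMatrix(
            dosages=d.copy(),
            variant_ids=vids.copy(),
            effect_alleles=ea.copy(),
            other_alleles=oa.copy(),
            sample_ids=sample_ids.copy(),
            population_labels=pops.copy(),
            true_betas=tb,
            population_frequencies=pf,
        )


def draw_population_frequencies(
    ancestral_freqs: np.ndarray, fst: float, rng: np.random.Generator
) -> np.ndarray:
    """Balding-Nichols population-specific allele frequencies.

    For ``fst == 0`` returns the ancestral frequencies unchanged; otherwise
    draws ``Beta(p (1-F)/F, (1-p)(1-F)/F)`` per variant (mean ``p``,
    variance ``F p (1-p)``).
    """
    p = np.asarray(ancestral_freqs, dtype=float)
    if np.any((p <= 0) | (p >= 1)):
        raise ValueError("ancestral frequencies must lie strictly in (0, 1)")
    if not 0.0 <= fst < 0.5:
        raise ValueError(f"fst must lie in [0, 0.5), got {fst}")
    if fst == 0.0:
        return p.copy()
    scale = (1.0 - fst) / fst
    return rng.beta(p * scale, (1.0 - p) * scale)


def _draw_effects(
    rng: np.random.Generator,
    arch: ArchitectureSpec,
    populations: Sequence[PopulationSpec],
    train_freqs: np.ndarray,
) -> tuple[np.ndarray, pd.DataFrame, float]:
    """Causal effects per population, scaled to the target heritability.

    Returns (causal indices, variants x populations beta table, noise SD).
    """
    m = arch.m
    n_causal = max(1, int(round(arch.causal_fraction * m)))
    causal = np.sort(rng.choice(m, size=n_causal, replace=False))

    # Equal-share architecture: every causal variant carries h^2 / n_causal of
    # the trait variance, with a random sign.  "Causal" is then synonymous
    # with "carrying detectable signal", which is what the oligogenic/
    # polygenic contrast is meant to emulate.
    signs = rng.choice([-1.0, 1.0], size=n_causal)
    if arch.heritability == 0.0:
        beta_train = np.zeros(n_causal)
    else:
        p = np.clip(train_freqs[causal], 0.01, 0.99)
        per_variant = arch.heritability / n_causal
        beta_train = signs * np.sqrt(per_variant / (2.0 * p * (1.0 - p)))
    sd_beta = float(beta_train.std()) if n_causal > 1 else abs(float(beta_train[0]))

    betas = pd.DataFrame(
        0.0, index=range(m), columns=[p.name for p in populations]
    )
    for pop in populations:
        rho = pop.effect_correlation
        if rho == 1.0:
            b = beta_train
        else:
            noise = rng.standard_normal(n_causal) * sd_beta
            b = rho * beta_train + np.sqrt(1.0 - rho**2) * noise
        betas.loc[causal, pop.name] = b
    noise_sd = float(np.sqrt(1.0 - arch.heritability))
    return causal, betas, noise_sd


def simulate_cohort(
    populations: Sequence[PopulationSpec], arch: ArchitectureSpec
) -> tuple[GenotypeMatrix, pd.DataFrame]:
    """Simulate genotypes, covariates and phenotype for all populations.

    The first population is the training population and must have
    ``effect_correlation == 1``.  Deterministic given ``arch.seed``.  Returns
    the genotype matrix and a phenotype table with columns ``sample_id``,
    ``population``, ``sex``, ``age``, ``genetic_value``, ``phenotype``.
    """
    if not populations:
        raise ValueError("at least one population is required")
    if populations[0].effect_correlation != 1.0:
        raise ValueError(
            "the first (training) population must have effect_correlation == 1"
        )
    names = [p.name for p in populations]
    if len(set(names)) != len(names):
        raise ValueError("population names must be unique")

    rng = np.random.default_rng(arch.seed)
    m = arch.m
    lo, hi = arch.maf_range
    ancestral = rng.uniform(lo, hi, size=m)

    pop_freqs = pd.DataFrame(index=range(m), columns=names, dtype=float)
    for pop in populations:
        pop_freqs[pop.name] = draw_population_frequencies(ancestral, pop.fst, rng)

    causal, betas, noise_sd = _draw_effects(
        rng, arch, populations, pop_freqs[populations[0].name].to_numpy()
    )

    alleles = np.array(list("ACGT"))
    eff_idx = rng.integers(0, 4, size=m)
    oth_idx = (eff_idx + rng.integers(1, 4, size=m)) % 4

    dosage_blocks, rows = [], []
    for pop in populations:
        freqs = pop_freqs[pop.name].to_numpy()
        dos = rng.binomial(2, freqs, size=(pop.n, m)).astype(float)
        beta = betas[pop.name].to_numpy()
        g_value = dos @ beta
        sex = rng.integers(0, 2, size=pop.n)
        age = rng.integers(40, 70, size=pop.n)
        noise = rng.normal(0.0, noise_sd, size=pop.n) if noise_sd > 0 else 0.0
        pheno = (
            g_value
            + pop.sex_effect * sex
            + pop.age_effect * (age - _AGE_CENTER)
            + pop.env_shift
            + noise
        )
        dosage_blocks.append(dos)
        rows.append(
            pd.DataFrame(
                {
                    "population": pop.name,
                    "sex": sex,
                    "age": age,
                    "genetic_value": g_value,
                    "phenotype": pheno,
                }
            )
        )

    dosages = np.vstack(dosage_blocks)
    pheno = pd.concat(rows, ignore_index=True)
    pheno.insert(
        0,
        "sample_id",
        np.array([f"{p}_{i:05d}" for p, i in zip(pheno["population"], pheno.index)]),
    )

    geno = GenotypeMatrix(
        dosages=dosages,
        variant_ids=np.array([f"v{j:06d}" for j in range(m)]),
        effect_alleles=alleles[eff_idx],
        other_alleles=alleles[oth_idx],
        sample_ids=pheno["sample_id"].to_numpy(),
        population_labels=pheno["population"].to_numpy(),
        true_betas=betas.set_axis([f"v{j:06d}" for j in range(m)], axis=0),
        population_frequencies=pop_freqs.set_axis(
            [f"v{j:06d}" for j in range(m)], axis=0
        ),
    )
    if arch.missing_rate > 0:
        geno = inject_missingness(
            geno, arch.missing_rate, seed=int(rng.integers(0, 2**31 - 1))
        )
    return geno, pheno


def inject_missingness(
    g: GenotypeMatrix, rate: float, seed: int
) -> GenotypeMatrix:
    """Set each dosage to missing independently with probability ``rate``."""
    if not 0.0 <= rate < 1.0:
        raise ValueError("rate must lie in [0, 1)")
    if rate == 0.0:
        return g
    rng = np.random.default_rng(seed)
    mask = rng.random(g.dosages.shape) < rate
    d = g.dosages.copy()
    d[mask] = np.nan
    return replace(g, dosages=d)
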