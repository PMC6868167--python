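"""Synthetic data generators for every stage of the cross-trait cFDR pipeline.

Three generators, all seed-deterministic:

* paired GWAS summary statistics from a four-class mixture over SNP effects
  (null / trait-1-only / trait-2-only / pleiotropic) with tunable correlation
  of the shared effects — a stand-in for two GWAS of genetically correlated
  traits run on disjoint cohorts (so the observation noise of the two
  z-scores is independent);
* genotype dosage panels with block-wise LD, built by thresholding a latent
  Gaussian AR(1) process to Hardy–Weinberg genotype frequencies at the
  target minor-allele frequency;
* genotype–phenotype cohorts with age, sex, a dichotomous + 5-level ordinal
  chronic-pain phenotype and a dichotomous + 3-level ordinal depression
  phenotype, where a ``mediation`` switch decides whether depression depends
  on the genotype only through the pain phenotype (mediated pleiotropy) or
  also directly (biological pleiotropy).

Effects in the summary-statistic generator live on the z-score scale: each
non-null SNP draws a latent mean shift delta ~ N(0, tau²) (a correlated
bivariate pair for pleiotropic SNPs) and the observed z is
delta * sqrt(n_scale) + N(0, 1), with p = 2 * Phi(-|z|).  Positions sit on
synthetic chromosomes at 1 kb spacing and rsids count up from rs900000001,
clear of real identifiers.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .ld import GenotypeMatrix

__all__ = [
    "SimulationConfig",
    "simulate_sumstats_pair",
    "pleiotropic_z_correlation",
    "write_sumstats_pair",
    "simulate_genotypes",
    "simulate_cohort",
    "TRUTH_CLASSES",
]

TRUTH_CLASSES = ("null", "trait1_only", "trait2_only", "pleiotropic")

_ALLELES = np.array(["A", "C", "G", "T"])


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one paired summary-statistic simulation.

    ``pi`` are the mixture proportions over (null, trait1-only, trait2-only,
    pleiotropic); ``tau1``/``tau2`` the SDs of the latent effect shifts on
    the z scale; ``rho`` the correlation of the pleiotropic effect pair
    (default 0.53, the genetic correlation between chronic pain grade and
    MDD that motivates conditioning); ``n1``/``n2`` notional relative sample
    sizes that multiply the non-centrality as sqrt(n).
    """

    n_snps: int = 10_000
    pi: tuple[float, float, float, float] = (0.95, 0.02, 0.02, 0.01)
    tau1: float = 3.0
    tau2: float = 3.0
    rho: float = 0.53
    n1: float = 1.0
    n2: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        pi = np.asarray(self.pi, dtype=float)
        if pi.shape != (4,) or (pi < 0).any() or abs(pi.sum() - 1.0) > 1e-9:
            raise ValueError(f"pi must be 4 non-negative proportions summing to 1, got {self.pi}")
        if self.tau1 <= 0 or self.tau2 <= 0:
            raise ValueError("tau1 and tau2 must be > 0")
        if not -1.0 <= self.rho <= 1.0:
            raise ValueError(f"rho must lie in [-1, 1], got {self.rho}")
        if self.n1 <= 0 or self.n2 <= 0:
            raise ValueError("n1 and n2 must be > 0")
        if self.n_snps < 1:
            raise ValueError("n_snps must be >= 1")


def pleiotropic_z_correlation(config: SimulationConfig) -> float:
    """Theoretical corr(z1, z2) among pleiotropic-class SNPs under the model.

    cov = rho * tau1 * tau2 * sqrt(n1 * n2); var_t = tau_t² * n_t + 1.
    """
    cov = config.rho * config.tau1 * config.tau2 * np.sqrt(config.n1 * config.n2)
    v1 = config.tau1**2 * config.n1 + 1.0
    v2 = config.tau2**2 * config.n2 + 1.0
    return float(cov / np.sqrt(v1 * v2))


def simulate_sumstats_pair(
    config: SimulationConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Generate paired summary statistics plus per-SNP truth labels.

    Returns (sumstats1, sumstats2, truth); the sumstats frames carry the
    standard dialect columns (rsid, chrom, pos, effect_allele, other_allele,
    effect, pvalue), truth carries rsid, class, delta1, delta2, z1, z2.
    Both tables share rsids, positions and allele pairs (no flips needed
    downstream; flips are exercised separately in tests).
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_snps
    classes = rng.choice(4, size=n, p=np.asarray(config.pi, dtype=float))

    d1 = np.zeros(n)
    d2 = np.zeros(n)
    m1 = classes == 1
    m2 = classes == 2
    m12 = classes == 3
    d1[m1] = rng.normal(0.0, config.tau1, m1.sum())
    d2[m2] = rng.normal(0.0, config.tau2, m2.sum())
    if m12.any():
        cov = np.array(
            [
                [config.tau1**2, config.rho * config.tau1 * config.tau2],
                [config.rho * config.tau1 * config.tau2, config.tau2**2],
            ]
        )
        pair = rng.multivariate_normal(np.zeros(2), cov, size=int(m12.sum()))
        d1[m12] = pair[:, 0]
        d2[m12] = pair[:, 1]

    # disjoint cohorts: the two observation noises are independent
    z1 = d1 * np.sqrt(config.n1) + rng.standard_normal(n)
    z2 = d2 * np.sqrt(config.n2) + rng.standard_normal(n)
    p1 = np.maximum(2.0 * stats.norm.sf(np.abs(z1)), np.nextafter(0.0, 1.0))
    p2 = np.maximum(2.0 * stats.norm.sf(np.abs(z2)), np.nextafter(0.0, 1.0))

    rsid = np.array([f"rs{900_000_001 + k}" for k in range(n)])
    chrom = np.repeat("1", n)
    pos = 1_000 * (np.arange(n) + 1)
    ea_idx = rng.integers(0, 4, size=n)
    oa_idx = (ea_idx + rng.integers(1, 4, size=n)) % 4

    def table(z, p):
        return pd.DataFrame(
            {
                "rsid": rsid,
                "chrom": chrom,
                "pos": pos,
                "effect_allele": _ALLELES[ea_idx],
                "other_allele": _ALLELES[oa_idx],
                "effect": np.round(z, 6),
                "pvalue": p,
            }
        )

    truth = pd.DataFrame(
        {
            "rsid": rsid,
            "class": np.array(TRUTH_CLASSES)[classes],
            "delta1": d1,
            "delta2": d2,
            "z1": z1,
            "z2": z2,
        }
    )
    return table(z1, p1), table(z2, p2), truth


def write_sumstats_pair(config: SimulationConfig, out_prefix: str) -> tuple[str, str, str]:
    """Write the generated pair and truth labels as TSVs; returns the paths."""
    s1, s2, truth = simulate_sumstats_pair(config)
    paths = (
        f"{out_prefix}.trait1.tsv",
        f"{out_prefix}.trait2.tsv",
        f"{out_prefix}.truth.tsv",
    )
    for df, path in zip((s1, s2, truth), paths):
        df.to_csv(path, sep="\t", index=False, float_format="%.10g")
    return paths


def simulate_genotypes(
    n_samples: int,
    block_sizes: list[int],
    within_block_rho: float,
    mafs,
    seed: int = 0,
    chrom: str = "1",
) -> GenotypeMatrix:
    """Block-LD genotype panel via a thresholded latent Gaussian AR(1).

    Within each block the latent variables follow an AR(1) with coefficient
    ``within_block_rho``; blocks are independent.  Each latent column is
    dichotomised at the Hardy–Weinberg thresholds for its target MAF, so
    dosage k has probability C(2,k) f^k (1-f)^(2-k).  ``mafs`` is either one
    frequency for all SNPs or one per SNP.
    """
    if not 0.0 <= within_block_rho < 1.0:
        raise ValueError(f"within_block_rho must be in [0, 1), got {within_block_rho}")
    n_snps = int(sum(block_sizes))
    mafs = np.broadcast_to(np.asarray(mafs, dtype=float), (n_snps,)).copy()
    if ((mafs <= 0) | (mafs > 0.5)).any():
        raise ValueError("mafs must lie in (0, 0.5]")
    rng = np.random.default_rng(seed)

    latent = np.empty((n_samples, n_snps))
    col = 0
    for size in block_sizes:
        z = rng.standard_normal((n_samples, size))
        for j in range(1, size):
            z[:, j] = within_block_rho * z[:, j - 1] + np.sqrt(
                1 - within_block_rho**2
            ) * z[:, j]
        latent[:, col : col + size] = z
        col += size

    f = mafs
    # P(dosage 0) = (1-f)^2, P(0 or 1) = 1 - f^2 under Hardy–Weinberg
    t0 = stats.norm.ppf((1 - f) ** 2)
    t1 = stats.norm.ppf(1 - f**2)
    dosages = (latent > t0).astype(float) + (latent > t1).astype(float)

    snps = pd.DataFrame(
        {
            "rsid": [f"rs{900_000_001 + k}" for k in range(n_snps)],
            "chrom": chrom,
            "pos": 1_000 * (np.arange(n_snps) + 1),
        }
    )
    return GenotypeMatrix(dosages=dosages, snps=snps)


def _proportional_odds_draw(
    rng: np.random.Generator, eta: np.ndarray, cutpoints: np.ndarray
) -> np.ndarray:
    """Draw ordinal categories from a cumulative-logit model.

    ``cutpoints`` c_1 < ... < c_K partition the latent logistic variable
    c = eta + logistic noise into K+1 categories; category 0 is "no
    phenotype", so P(category >= 1 | eta) = expit(eta - c_1).
    """
    latent = eta + rng.logistic(size=eta.shape)
    return (latent[:, None] > cutpoints[None, :]).sum(axis=1)


@dataclass(frozen=True)
class CohortParams:
    """Effect and nuisance parameters of the cohort generator.

    Age and sex act on both phenotypes (age in decades internally); baseline
    cutpoints put chronic-pain prevalence near 0.43 and depression
    prevalence near 0.28, population-cohort-like values.
    """

    beta_age_pain: float = 0.15  # per decade of age
    beta_sex_pain: float = 0.20
    beta_age_mdd: float = -0.10
    beta_sex_mdd: float = 0.45
    pain_cutpoints: tuple[float, ...] = (0.4, 1.4, 2.6, 4.0)
    mdd_cutpoints: tuple[float, ...] = (1.5, 2.3)
    age_mean: float = 57.0
    age_sd: float = 8.0
    p_female: float = 0.54


def simulate_cohort(
    n: int,
    allele_freq: float = 0.4,
    or_pain_per_allele: float = 1.02,
    or_mdd_given_pain: float = 2.0,
    or_mdd_per_allele: float = 1.0,
    mediation: bool = True,
    seed: int = 0,
    params: CohortParams = CohortParams(),
) -> pd.DataFrame:
    """Genotype–phenotype cohort for the follow-up regression stage.

    Columns: dosage (0/1/2), age (years), sex (1 = female), cp_dichot,
    cp_category (0..4, 0 iff cp_dichot 0), mdd_dichot, mdd_severity (0..2,
    0 iff mdd_dichot 0).  Chronic pain follows a proportional-odds model in
    dosage + age + sex; under ``mediation=True`` depression depends on the
    pain phenotype (plus age and sex) but not directly on dosage, while
    ``mediation=False`` adds the direct dosage effect ``or_mdd_per_allele``.
    """
    if not 0.0 < allele_freq < 1.0:
        raise ValueError(f"allele_freq must lie in (0, 1), got {allele_freq}")
    for name, v in (
        ("or_pain_per_allele", or_pain_per_allele),
        ("or_mdd_given_pain", or_mdd_given_pain),
        ("or_mdd_per_allele", or_mdd_per_allele),
    ):
        if v <= 0:
            raise ValueError(f"{name} must be > 0, got {v}")
    rng = np.random.default_rng(seed)
    dosage = rng.binomial(2, allele_freq, size=n).astype(float)
    age = rng.normal(params.age_mean, params.age_sd, size=n)
    sex = rng.binomial(1, params.p_female, size=n).astype(float)
    age_c = (age - params.age_mean) / 10.0

    eta_pain = (
        np.log(or_pain_per_allele) * dosage
        + params.beta_age_pain * age_c
        + params.beta_sex_pain * sex
    )
    cp_category = _proportional_odds_draw(rng, eta_pain, np.asarray(params.pain_cutpoints))
    cp_dichot = (cp_category > 0).astype(int)

    eta_mdd = (
        np.log(or_mdd_given_pain) * cp_dichot
        + params.beta_age_mdd * age_c
        + params.beta_sex_mdd * sex
    )
    if not mediation:
        eta_mdd = eta_mdd + np.log(or_mdd_per_allele) * dosage
    mdd_severity = _proportional_odds_draw(rng, eta_mdd, np.asarray(params.mdd_cutpoints))
    mdd_dichot = (mdd_severity > 0).astype(int)

    return pd.DataFrame(
        {
            "dosage": dosage.astype(int),
            "age": np.round(age, 2),
            "sex": sex.astype(int),
            "cp_dichot": cp_dichot,
            "cp_category": cp_category,
            "mdd_dichot": mdd_dichot,
            "mdd_severity": mdd_severity,
        }
    )
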