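"""Synthetic biparental-cross genotypes, phenotypes and growth curves.

The generator emulates a yeast screen: haploid panels drawn from a
12th-generation two-parent intercross are crossed in all MATa x MATalpha
pairs to give diploids with 0/1/2 genotype codes; a shared set of causal
SNPs additively shifts each genotype's maximum growth rate r around an
environment-specific mean; carrying capacity K follows from the energetic
cost model (K = R_total / C(r), up to lognormal noise), which couples the
two traits and makes the r-K correlation flip sign across environments; and
each genotype's logistic growth curve is sampled on a 217-point, 0-72 h grid
with additive Gaussian noise calibrated so that refitted curves hit a target
median goodness of fit R_g^2.

Two validation presets mirror the estimation checks: a null simulation with
r and K drawn independently (any refitted r-K correlation is then an
estimation artifact), and a no-saturation regime (low r, high K) in which
the per-capita growth rate at 72 h is still ~23% of the initial rate.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .cost import CostParams, cost
from .exceptions import ConfigurationError, InputDataError
from .growth import STANDARD_TIMES, GrowthCurve
from .qtl import GenotypeMatrix

__all__ = [
    "EnvironmentSpec",
    "SimConfig",
    "DEFAULT_ENVIRONMENTS",
    "simulate_cross",
    "simulate_phenotypes",
    "calibrate_noise",
    "curve_matrix",
    "simulate_growth_curves",
    "simulate_null_rk",
    "simulate_truncated_growth",
]


@dataclass(frozen=True)
class EnvironmentSpec:
    """Conditions of one environment.

    mean_r      -- environment quality Q the latent r values centre on (per h)
    R_total     -- resource pool in cost units; sets the K scale via R/C(r)
    target_rg2  -- target median R_g^2 of refitted curves (noise calibration)
    cv_r        -- coefficient of variation of latent r among genotypes
    sigma_log_K -- SD of lognormal noise multiplying the cost-model K
    """

    label: str
    mean_r: float
    R_total: float = 1.2e6
    target_rg2: float = 0.99
    cv_r: float = 0.12
    sigma_log_K: float = 0.05


# Nine environments spanning the quality range of the yeast screen
# (mean r from 0.04 to 0.35 per hour, straddling the cost minimum at ~0.13);
# resource pools vary between media and are unrelated to quality.
DEFAULT_ENVIRONMENTS: tuple[EnvironmentSpec, ...] = tuple(
    EnvironmentSpec(label=f"env{i+1:02d}_Q{q:.3f}", mean_r=q, R_total=rt)
    for i, (q, rt) in enumerate(
        zip(
            np.round(np.linspace(0.04, 0.35, 9), 4),
            1e6 * np.array([1.5, 0.9, 1.2, 0.8, 1.4, 1.0, 1.3, 1.1, 1.0]),
        )
    )
)


@dataclass(frozen=True)
class SimConfig:
    """Cross design, genetic architecture and measurement setup."""

    n_mata: int = 85
    n_matalpha: int = 86
    n_chrom: int = 16
    snps_per_chrom: int = 835
    generations: int = 12
    chrom_cM: float = 100.0
    snp_spacing_bp: int = 1000
    environments: tuple[EnvironmentSpec, ...] = DEFAULT_ENVIRONMENTS
    n_causal: int = 20
    h2_r: float = 0.75
    cost_params: CostParams = field(default_factory=CostParams)
    replicates: int = 4
    # colonies are initiated from pinned precultures, so the starting
    # population is macroscopic (~1e5 cells) and growth spans roughly one
    # order of magnitude to a visible plateau within 72 h, as in the screen;
    # a microscopic N0 would leave poor-quality environments far from
    # saturation and make K unidentifiable there.
    N0: float = 1e5
    times: np.ndarray = field(default_factory=lambda: STANDARD_TIMES.copy(), compare=False)
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("n_mata", "n_matalpha", "n_chrom", "snps_per_chrom", "generations",
                     "n_causal", "replicates"):
            if getattr(self, name) < 1:
                raise ConfigurationError(f"{name} must be positive")
        if not 0 < self.h2_r <= 1:
            raise ConfigurationError(f"h2_r must be in (0, 1], got {self.h2_r}")
        for e in self.environments:
            if not 0 < e.target_rg2 <= 1:
                raise ConfigurationError(f"target_rg2 must be in (0, 1] ({e.label})")
            if e.mean_r >= self.cost_params.r_max:
                raise ConfigurationError(
                    f"mean_r={e.mean_r} must be below r_max={self.cost_params.r_max} ({e.label})"
                )


def _haploid_panel(config: SimConfig, n_hap: int, rng: np.random.Generator) -> np.ndarray:
    """Parental-allele mosaics (0/1) for n_hap haploids, all chromosomes.

    Recombination between adjacent SNPs follows the Haldane map with the
    advanced-intercross map expansion factor generations/2.
    """
    per = config.snps_per_chrom
    expansion = config.generations / 2.0
    d = (config.chrom_cM / 100.0) / max(per - 1, 1)  # Morgans between SNPs
    rf = 0.5 * (1.0 - np.exp(-2.0 * d * expansion))
    blocks = []
    for _ in range(config.n_chrom):
        start = rng.integers(0, 2, size=(n_hap, 1))
        switches = rng.random((n_hap, per - 1)) < rf
        parity = np.cumsum(switches, axis=1) % 2
        chrom = np.concatenate([start, (start + parity) % 2], axis=1)
        blocks.append(chrom.astype(np.int8))
    return np.concatenate(blocks, axis=1)


def simulate_cross(config: SimConfig, rng: np.random.Generator | None = None) -> GenotypeMatrix:
    """All-pairs diploids from simulated MATa and MATalpha haploid panels.

    Codes are copies of one parental allele (0/1/2); positions are evenly
    spaced at ``snp_spacing_bp`` within each chromosome.
    """
    rng = np.random.default_rng(config.seed) if rng is None else rng
    Ha = _haploid_panel(config, config.n_mata, rng)
    Hb = _haploid_panel(config, config.n_matalpha, rng)
    n_snps = config.n_chrom * config.snps_per_chrom
    # codes[s, i * n_matalpha + j] = Ha[i, s] + Hb[j, s]
    codes = (Ha[:, None, :] + Hb[None, :, :]).reshape(-1, n_snps).T.astype(float)
    chroms = np.repeat([f"chr{c+1:02d}" for c in range(config.n_chrom)], config.snps_per_chrom)
    pos_one = 1 + np.arange(config.snps_per_chrom, dtype=np.int64) * config.snp_spacing_bp
    positions = np.tile(pos_one, config.n_chrom)
    snp_ids = np.array(
        [f"{c}_{p}" for c, p in zip(chroms, positions)], dtype=object
    )
    genotype_ids = np.array(
        [f"a{i:03d}xb{j:03d}" for i in range(config.n_mata) for j in range(config.n_matalpha)],
        dtype=object,
    )
    return GenotypeMatrix(
        snp_ids=snp_ids,
        chromosomes=chroms,
        positions=positions,
        codes=codes,
        genotype_ids=genotype_ids,
    )


def simulate_phenotypes(
    gm: GenotypeMatrix,
    config: SimConfig,
    rng: np.random.Generator | None = None,
    independent: bool = False,
) -> tuple[pd.DataFrame, dict]:
    """Latent (r, K) per genotype per environment.

    Default mode: r = mean_r + additive causal-SNP effects + Gaussian noise
    (effects scaled so the causal SNPs explain exactly h2_r of the realized
    r variance), truncated into (0, r_max); K = R_total / C(r) x lognormal
    noise -- the cost-model coupling.  ``independent=True`` draws r and K
    from independent normals instead (the estimation-null preset).

    Returns (truth table, architecture) where the architecture maps each
    environment to its (causal SNP indices, per-code effects on r).
    """
    rng = np.random.default_rng(config.seed + 1) if rng is None else rng
    n_gen = gm.n_genotypes
    causal = np.sort(rng.choice(gm.n_snps, size=config.n_causal, replace=False))
    z = rng.normal(size=config.n_causal)
    Xc = gm.imputed()[causal] - 1.0  # centered at the heterozygote
    g_raw = z @ Xc
    sd_g_raw = g_raw.std()

    frames = []
    arch: dict[str, tuple[np.ndarray, np.ndarray]] = {}
    eps = 1e-3
    r_hi = config.cost_params.r_max * (1.0 - 1e-3)
    for env in config.environments:
        sd_total = env.cv_r * env.mean_r
        if independent:
            r_true = rng.normal(env.mean_r, sd_total, n_gen)
            mean_K = env.R_total / cost(env.mean_r, config.cost_params)
            K_true = rng.normal(mean_K, 0.15 * mean_K, n_gen)
            K_true = np.clip(K_true, config.N0 * 1.5, None)
            arch[env.label] = (causal, np.zeros(config.n_causal))
        else:
            scale = np.sqrt(config.h2_r) * sd_total / max(sd_g_raw, 1e-12)
            g = g_raw * scale
            e = rng.normal(0.0, np.sqrt(1.0 - config.h2_r) * sd_total, n_gen)
            r_true = env.mean_r + g + e
            arch[env.label] = (causal, z * scale)
        r_true = np.clip(r_true, eps, r_hi)
        if not independent:
            C = np.asarray(cost(r_true, config.cost_params))
            K_true = (env.R_total / C) * np.exp(
                rng.normal(0.0, env.sigma_log_K, n_gen)
            )
        frames.append(
            pd.DataFrame(
                {
                    "environment": env.label,
                    "genotype": gm.genotype_ids,
                    "r_true": r_true,
                    "K_true": K_true,
                }
            )
        )
    return pd.concat(frames, ignore_index=True), arch


def calibrate_noise(target_rg2: float, clean_counts: np.ndarray) -> np.ndarray:
    """Per-curve noise SD so refitted curves reach a target median R_g^2.

    The total noise sum of squares is (1 - target) x SST of the noise-free
    curve, spread evenly over the n time points: sd = sqrt((1-target) SST/n).
    """
    Y = np.atleast_2d(np.asarray(clean_counts, dtype=float))
    sst = ((Y - Y.mean(axis=1, keepdims=True)) ** 2).sum(axis=1)
    n = Y.shape[1]
    return np.sqrt(np.maximum(1.0 - target_rg2, 0.0) * sst / n)


def curve_matrix(
    r_true: np.ndarray,
    K_true: np.ndarray,
    config: SimConfig,
    rng: np.random.Generator,
    target_rg2: float,
) -> np.ndarray:
    """Noisy replicate curves, shape (n_genotypes * replicates, n_times).

    Replicates of a genotype are contiguous rows.  Negative noisy counts are
    clipped at zero.
    """
    t = config.times
    r = np.repeat(np.asarray(r_true, float), config.replicates)[:, None]
    K = np.repeat(np.asarray(K_true, float), config.replicates)[:, None]
    clean = K / (1.0 + (K / config.N0 - 1.0) * np.exp(-r * t[None, :]))
    sd = calibrate_noise(target_rg2, clean)[:, None]
    noisy = clean + rng.normal(size=clean.shape) * sd
    return np.clip(noisy, 0.0, None)


def simulate_growth_curves(
    truth: pd.DataFrame,
    config: SimConfig,
    rng: np.random.Generator | None = None,
) -> list[GrowthCurve]:
    """Replicate growth curves for every (environment, genotype) in ``truth``."""
    rng = np.random.default_rng(config.seed + 2) if rng is None else rng
    by_label = {e.label: e for e in config.environments}
    out: list[GrowthCurve] = []
    for env, grp in truth.groupby("environment", sort=True):
        spec = by_label.get(str(env))
        target = spec.target_rg2 if spec is not None else 0.99
        Y = curve_matrix(
            grp["r_true"].to_numpy(), grp["K_true"].to_numpy(), config, rng, target
        )
        genos = grp["genotype"].to_numpy()
        for i, geno in enumerate(genos):
            for rep in range(config.replicates):
                out.append(
                    GrowthCurve(
                        environment=str(env),
                        genotype=str(geno),
                        replicate=rep,
                        times=config.times,
                        counts=Y[i * config.replicates + rep],
                    )
                )
    return out


def simulate_null_rk(
    config: SimConfig, rng: np.random.Generator | None = None
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """Null preset: r and K specified independently, then curves as usual.

    The generating r-K correlation is zero by construction, so any
    significant refitted correlation would expose estimation bias.
    Genotype labels are synthetic indices (no genotype matrix is involved).
    """
    rng = np.random.default_rng(config.seed + 3) if rng is None else rng
    n_gen = config.n_mata * config.n_matalpha
    frames = []
    for env in config.environments:
        sd_total = env.cv_r * env.mean_r
        r_true = np.clip(
            rng.normal(env.mean_r, sd_total, n_gen), 1e-3, config.cost_params.r_max * 0.999
        )
        mean_K = env.R_total / cost(env.mean_r, config.cost_params)
        K_true = np.clip(rng.normal(mean_K, 0.15 * mean_K, n_gen), config.N0 * 1.5, None)
        frames.append(
            pd.DataFrame(
                {
                    "environment": env.label,
                    "genotype": [f"g{i:05d}" for i in range(n_gen)],
                    "r_true": r_true,
                    "K_true": K_true,
                }
            )
        )
    truth = pd.concat(frames, ignore_index=True)
    return simulate_growth_curves(truth, config, rng), truth


def saturation_K(r: np.ndarray, config: SimConfig, final_rate_fraction: float) -> np.ndarray:
    """K such that the per-capita growth rate at the last time point is
    ``final_rate_fraction`` of the initial rate.

    The logistic per-capita rate is r (1 - N/K); with N0 << K the fraction
    at time T is ~ 1 - N(T)/K, so N(T) = (1 - fraction) K, giving
    K = N0 (1 + fraction^{-1} (1 - fraction) e^{rT}).
    """
    if not 0 < final_rate_fraction < 1:
        raise ConfigurationError("final_rate_fraction must be in (0, 1)")
    T = float(config.times[-1])
    r = np.asarray(r, dtype=float)
    return config.N0 * (
        1.0 + final_rate_fraction / (1.0 - final_rate_fraction) * np.exp(r * T)
    )


def simulate_truncated_growth(
    truth: pd.DataFrame,
    config: SimConfig,
    truncation: float = 0.233,
) -> tuple[list[GrowthCurve], pd.DataFrame]:
    """No-saturation preset: carrying capacities are raised so growth is cut
    off by the 72-h window instead of by the resource.

    Every genotype's K is recomputed from its r so the final per-capita rate
    is ``truncation`` of the initial rate (~23% mirrors a screen whose
    slowest media never reach the plateau).  Passing the fraction that the
    original truth K already implies reproduces the standard generator.
    Returns (curves, adjusted truth).
    """
    if len(config.times) < 50:
        raise InputDataError("truncated-growth check requires >= 50 time points")
    adjusted = truth.copy()
    adjusted["K_true"] = saturation_K(truth["r_true"].to_numpy(), config, truncation)
    return simulate_growth_curves(adjusted, config, None), adjusted


def scaled_config(
    n_genotypes: int,
    n_chrom: int = 16,
    snps_per_chrom: int = 60,
    seed: int = 0,
    environments: tuple[EnvironmentSpec, ...] = DEFAULT_ENVIRONMENTS,
    **kwargs,
) -> SimConfig:
    """A SimConfig whose haploid panel sizes give ~n_genotypes diploids.

    Convenience for scaled-down studies; all other knobs keep their
    defaults unless overridden.
    """
    n_a = max(int(np.floor(np.sqrt(n_genotypes))), 2)
    n_b = max(int(np.ceil(n_genotypes / n_a)), 2)
    return SimConfig(
        n_mata=n_a,
        n_matalpha=n_b,
        n_chrom=n_chrom,
        snps_per_chrom=snps_per_chrom,
        environments=environments,
        seed=seed,
        **kwargs,
    )
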