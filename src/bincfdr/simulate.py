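"""Synthetic GWAS summary statistics with block LD structure.

Emulates a case-control GWAS over approximately independent LD blocks:
within-block correlation follows an AR(1) profile (adjacent-SNP correlation
``ld_decay``, decaying geometrically with index distance), each block carries
2–4 causal variants with log-odds-ratio effects drawn from the fine-mapping
prior N(0, 0.2²), and Z-scores are one multivariate-normal draw per block,

    Z ~ MVN(Sigma @ lambda, Sigma),
    lambda_j = beta_j * sqrt(2 * maf_j * (1 - maf_j)) * sqrt(n_eff),
    n_eff = n_cases * n_controls / (n_cases + n_controls),

the standard expected non-centrality of the score test for a log-OR beta at
minor-allele frequency maf.  p = 2·Φ(−|Z|).

Three binary-covariate scenarios accompany the study:

* ``A`` — q ~ Bernoulli(0.05), independent of everything (irrelevant data);
* ``B`` — q ~ Bernoulli(0.4) on "functional" SNPs (causal variants plus any
  SNP within 10 kb) and Bernoulli(0.05) elsewhere (relevant data);
* ``C`` — as B with functional rate 0.8; successive columns reuse the same
  functional mask and are therefore strongly correlated (the misuse case of
  repeatedly leveraging one functional mark).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.signal import lfilter
from scipy.stats import norm

from .core import P_FLOOR

__all__ = [
    "SimulationConfig",
    "LdBlocks",
    "SimulatedStudy",
    "ar1_correlation",
    "simulate_ld_blocks",
    "sample_causal_effects",
    "simulate_z_scores",
    "p_from_z",
    "functional_mask",
    "max_r2_with_causal",
    "simulate_covariates",
    "simulate_study",
]

#: Covariate rates (non-functional, functional) per scenario.
SCENARIO_RATES = {"A": (0.05, 0.05), "B": (0.05, 0.4), "C": (0.05, 0.8)}

_BLOCK_OFFSET_BP = 10_000_000  # genomic gap between successive blocks


@dataclass(frozen=True)
class SimulationConfig:
    """Study conditions for one simulated GWAS.

    Defaults are the desk-scale profile: 24 AR(1) LD blocks of 400 SNPs,
    5000 cases / 5000 controls, 2–4 causal variants per block with log-OR
    effects ~ N(0, effect_sd²), common variants only (MAF ≥ 0.05), and a mean
    inter-SNP spacing of 450 bp.
    """

    n_blocks: int = 24
    snps_per_block: int = 400
    n_cases: int = 5000
    n_controls: int = 5000
    causal_min: int = 2
    causal_max: int = 4
    effect_sd: float = 0.2
    ld_decay: float = 0.9
    maf_range: tuple[float, float] = (0.05, 0.5)
    snp_spacing_bp: float = 450.0
    functional_window_bp: float = 10_000.0
    seed: int = 0

    def __post_init__(self):
        if min(self.n_blocks, self.snps_per_block, self.n_cases, self.n_controls) <= 0:
            raise ValueError("counts must be positive")
        if self.snps_per_block > 1000:
            raise ValueError("no more than 1000 SNPs per block")
        if not (0.0 <= self.ld_decay < 1.0):
            raise ValueError("ld_decay must lie in [0, 1)")
        if not (1 <= self.causal_min <= self.causal_max):
            raise ValueError("invalid causal variant range")

    @property
    def n_snps(self) -> int:
        return self.n_blocks * self.snps_per_block

    @property
    def n_eff(self) -> float:
        return self.n_cases * self.n_controls / (self.n_cases + self.n_controls)


def ar1_correlation(n: int, decay: float) -> np.ndarray:
    """AR(1) correlation matrix Sigma_ij = decay^|i-j| (symmetric PD for decay in [0,1))."""
    idx = np.arange(n)
    return decay ** np.abs(idx[:, None] - idx[None, :])


@dataclass
class LdBlocks:
    """Positions, MAFs and LD structure of the simulated blocks."""

    block: np.ndarray  # (m,) block id per SNP
    positions: np.ndarray  # (m,) 1-based bp positions, sorted within block
    maf: np.ndarray  # (m,)
    ld_decay: float
    n_blocks: int

    def block_indices(self, b: int) -> np.ndarray:
        return np.flatnonzero(self.block == b)

    def correlation_matrix(self, b: int) -> np.ndarray:
        return ar1_correlation(self.block_indices(b).size, self.ld_decay)


def simulate_ld_blocks(config: SimulationConfig, rng: np.random.Generator) -> LdBlocks:
    """Draw block structure: exponential inter-SNP spacing, uniform MAFs."""
    n, k = config.snps_per_block, config.n_blocks
    gaps = np.maximum(1, np.round(rng.exponential(config.snp_spacing_bp, (k, n)))).astype(
        np.int64
    )
    positions = (np.cumsum(gaps, axis=1) + _BLOCK_OFFSET_BP * np.arange(k)[:, None]).ravel()
    block = np.repeat(np.arange(k), n)
    maf = rng.uniform(*config.maf_range, k * n)
    return LdBlocks(
        block=block,
        positions=positions,
        maf=maf,
        ld_decay=config.ld_decay,
        n_blocks=k,
    )


def sample_causal_effects(
    blocks: LdBlocks, config: SimulationConfig, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Pick 2–4 causal SNPs per block and draw their log-OR effects.

    Returns (causal mask, beta); beta is 0 at non-causal SNPs.  With
    ``effect_sd = 0`` all effects vanish (complete null).
    """
    m = blocks.block.size
    causal = np.zeros(m, dtype=bool)
    beta = np.zeros(m, dtype=np.float64)
    for b in range(blocks.n_blocks):
        idx = blocks.block_indices(b)
        if idx.size < config.causal_max:
            raise ValueError(
                f"block {b} has {idx.size} SNPs, fewer than causal_max="
                f"{config.causal_max}"
            )
        k = int(rng.integers(config.causal_min, config.causal_max + 1))
        chosen = rng.choice(idx, size=k, replace=False)
        causal[chosen] = True
        beta[chosen] = rng.normal(0.0, config.effect_sd, k)
    return causal, beta


def simulate_z_scores(
    blocks: LdBlocks,
    beta: np.ndarray,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> np.ndarray:
    """One MVN(Sigma @ lambda, Sigma) Z-score draw per block, independent across blocks.

    The AR(1) noise is sampled exactly by the recursion
    z_i = rho·z_{i-1} + sqrt(1-rho²)·e_i, and the mean uses the closed-form
    Sigma columns at the (sparse) causal SNPs.
    """
    rho = blocks.ld_decay
    sqrt_neff = np.sqrt(config.n_eff)
    z = np.empty(blocks.block.size, dtype=np.float64)
    for b in range(blocks.n_blocks):
        idx = blocks.block_indices(b)
        n = idx.size
        eps = rng.standard_normal(n)
        if rho > 0.0:
            innov = eps * np.concatenate(([1.0], np.full(n - 1, np.sqrt(1.0 - rho**2))))
            noise = lfilter([1.0], [1.0, -rho], innov)
        else:
            noise = eps
        mu = np.zeros(n)
        causal_local = np.flatnonzero(beta[idx] != 0.0)
        for j in causal_local:
            gj = idx[j]
            lam = beta[gj] * np.sqrt(2.0 * blocks.maf[gj] * (1.0 - blocks.maf[gj])) * sqrt_neff
            mu += lam * rho ** np.abs(np.arange(n) - j)
        z[idx] = mu + noise
    return z


def p_from_z(z: np.ndarray) -> np.ndarray:
    """Two-sided p-values 2·Φ(−|Z|), floored at the smallest positive normal."""
    return np.maximum(2.0 * norm.sf(np.abs(z)), P_FLOOR)


def functional_mask(
    positions: np.ndarray,
    block: np.ndarray,
    causal: np.ndarray,
    window_bp: float = 10_000.0,
) -> np.ndarray:
    """True for causal SNPs and any same-block SNP within window_bp of one (inclusive)."""
    positions = np.asarray(positions)
    causal = np.asarray(causal, dtype=bool)
    mask = causal.copy()
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        cpos = positions[idx][causal[idx]]
        if cpos.size == 0:
            continue
        dist = np.abs(positions[idx][:, None] - cpos[None, :]).min(axis=1)
        mask[idx] |= dist <= window_bp
    return mask


def max_r2_with_causal(
    block: np.ndarray, causal: np.ndarray, ld_decay: float
) -> np.ndarray:
    """Per-SNP maximum r² with any causal variant.

    r² between SNPs i, j of one block is the squared AR(1) correlation
    ``ld_decay^(2|i-j|)``; across blocks r² = 0.  Causal SNPs get 1.
    """
    m = block.size
    r2 = np.zeros(m, dtype=np.float64)
    for b in np.unique(block):
        idx = np.flatnonzero(block == b)
        local_causal = np.flatnonzero(causal[idx])
        if local_causal.size == 0:
            continue
        dist = np.abs(np.arange(idx.size)[:, None] - local_causal[None, :]).min(axis=1)
        r2[idx] = ld_decay ** (2.0 * dist) if ld_decay > 0.0 else (dist == 0).astype(float)
    return r2


def simulate_covariates(
    scenario: str,
    mask: np.ndarray,
    rng: np.random.Generator,
    n_cols: int = 1,
) -> np.ndarray:
    """Draw an (m, n_cols) binary covariate matrix for one scenario.

    Columns are independent Bernoulli draws given the functional mask; in
    scenarios B and C the mask is the study's fixed causal-derived mask, which
    makes columns positively correlated (strongly so for C's 0.8 rate).
    """
    if scenario not in SCENARIO_RATES:
        raise ValueError(f"unknown scenario {scenario!r}; expected one of A, B, C")
    base, functional = SCENARIO_RATES[scenario]
    rate = np.where(np.asarray(mask, dtype=bool), functional, base)
    return (rng.random((n_cols, mask.size)) < rate).astype(np.int8).T


@dataclass
class SimulatedStudy:
    """One simulation replicate: GWAS statistics, covariates and LD truth."""

    config: SimulationConfig
    scenario: str
    blocks: LdBlocks
    causal: np.ndarray
    beta: np.ndarray
    z: np.ndarray
    p: np.ndarray
    functional: np.ndarray
    q: np.ndarray  # (m, n_iterations)
    max_r2: np.ndarray

    def to_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {
                "snp": [f"snp_{i}" for i in range(self.p.size)],
                "p": self.p,
                "q": self.q[:, 0],
                "group": self.blocks.block,
                "chrom": np.ones(self.p.size, dtype=np.int64),
                "pos": self.blocks.positions,
                "maf": self.blocks.maf,
                "z": self.z,
                "beta": self.beta,
                "causal": self.causal.astype(np.int8),
                "functional": self.functional.astype(np.int8),
                "max_r2": self.max_r2,
            }
        )
        for k in range(self.q.shape[1]):
            df[f"q_iter{k + 1}"] = self.q[:, k]
        return df


def simulate_study(
    config: SimulationConfig,
    scenario: str = "A",
    n_iterations: int = 5,
    rng: np.random.Generator | int | None = None,
) -> SimulatedStudy:
    """Generate one full replicate: LD blocks, effects, Z, p, mask, covariates."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    elif not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(rng)
    blocks = simulate_ld_blocks(config, rng)
    causal, beta = sample_causal_effects(blocks, config, rng)
    z = simulate_z_scores(blocks, beta, config, rng)
    p = p_from_z(z)
    mask = functional_mask(
        blocks.positions, blocks.block, causal, config.functional_window_bp
    )
    q = simulate_covariates(scenario, mask, rng, n_cols=n_iterations)
    return SimulatedStudy(
        config=config,
        scenario=scenario,
        blocks=blocks,
        causal=causal,
        beta=beta,
        z=z,
        p=p,
        functional=mask,
        q=q,
        max_r2=max_r2_with_causal(blocks.block, causal, config.ld_decay),
    )
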