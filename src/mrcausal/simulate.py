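"""Synthetic two-sample GWAS summary statistics with known ground truth.

The generator emulates the structure of a two-sample MR design: an exposure
GWAS and an outcome GWAS measured in independent samples, sharing a panel of
variants.  Effects live on the standardized scale, so the sampling SE of a
per-allele estimate at allele frequency p and sample size N is approximately
(2p(1−p)N)^(−1/2).  Per variant j:

* allele frequency  p_j ~ U(maf_range)
* exposure effect   |γ_j| ~ U(gamma_range) on the exposure-increasing allele
* direct effect     α_j = 0 with prob 1−prop_invalid, else N(μ_α, σ_α²),
  defined on the exposure-increasing allele (the frame in which directional
  pleiotropy is meaningful)
* outcome effect    |Γ_j| frame: β·|γ_j| + α_j  (β the causal effect)
* a random sign s_j then flips both marginal effects together — pure allele
  labeling, exactly what harmonization and estimator orientation undo
* observed betas drawn independently in the two samples around the true
  marginal effects.

Defaults mirror a stroke-exposure (N ≈ 40,585) / frailty-index-outcome
(N = 175,226) design with exposure effects strong enough that most variants
reach genome-wide significance.  The 18-variant ischemic-stroke instrument
table ships as a packaged fixture via :func:`table1_fixture`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from importlib import resources

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import InvalidConfigError
from .gwas_io import AssociationTable, LDMatrix, read_summary_stats

__all__ = [
    "SimulationConfig",
    "simulate_two_sample",
    "ld_block_fixture",
    "table1_fixture",
]

_NONPALINDROMIC_PAIRS = (
    ("A", "C"), ("A", "G"), ("C", "A"), ("C", "T"),
    ("G", "A"), ("G", "T"), ("T", "C"), ("T", "G"),
)
_PALINDROMIC_PAIRS = (("A", "T"), ("T", "A"), ("C", "G"), ("G", "C"))

#: spacing between simulated variants on a chromosome; comfortably beyond
#: the default 10,000 kb clumping window
_POSITION_STEP_BP = 25_000_000


@dataclass
class SimulationConfig:
    """Ground-truth parameters for one simulated two-sample dataset.

    ``seed`` is mandatory; every draw flows from it.  ``prop_invalid`` is the
    fraction of instruments carrying a direct (pleiotropic) effect on the
    outcome, drawn N(mu_alpha, sd_alpha²); mu_alpha ≠ 0 gives directional
    pleiotropy, mu_alpha = 0 with sd_alpha > 0 balanced pleiotropy.
    """

    seed: int
    k: int = 50
    beta_true: float = 0.1
    n_exp: int = 40_585
    n_out: int = 175_226
    maf_range: tuple[float, float] = (0.05, 0.5)
    gamma_range: tuple[float, float] = (0.05, 0.15)
    prop_invalid: float = 0.0
    mu_alpha: float = 0.0
    sd_alpha: float = 0.0
    ld_blocks: list[tuple[int, float]] | None = None
    palindromic_fraction: float = 0.0

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidConfigError("seed is mandatory")
        if self.k < 1:
            raise InvalidConfigError("k must be >= 1")
        if not (0 <= self.prop_invalid <= 1):
            raise InvalidConfigError("prop_invalid must lie in [0, 1]")
        if not (0 <= self.palindromic_fraction <= 1):
            raise InvalidConfigError("palindromic_fraction must lie in [0, 1]")
        for name in ("maf_range", "gamma_range"):
            lo, hi = getattr(self, name)
            if not (0 <= lo <= hi):
                raise InvalidConfigError(f"{name} must be ordered and non-negative")
        if not (0 < self.maf_range[1] <= 0.5):
            raise InvalidConfigError("maf_range must lie within (0, 0.5]")
        if self.n_exp < 3 or self.n_out < 3:
            raise InvalidConfigError("sample sizes must be >= 3")
        if self.sd_alpha < 0:
            raise InvalidConfigError("sd_alpha must be >= 0")
        if self.ld_blocks is not None:
            for size, r in self.ld_blocks:
                if size < 2:
                    raise InvalidConfigError("LD block size must be >= 2")
                if not (abs(r) < 1):
                    raise InvalidConfigError("LD block |r| must be < 1")


def _alleles(rng: np.random.Generator, k: int, palindromic_fraction: float):
    pal = rng.random(k) < palindromic_fraction
    ea = np.empty(k, dtype=object)
    oa = np.empty(k, dtype=object)
    idx_np = rng.integers(0, len(_NONPALINDROMIC_PAIRS), size=k)
    idx_p = rng.integers(0, len(_PALINDROMIC_PAIRS), size=k)
    for j in range(k):
        ea[j], oa[j] = (
            _PALINDROMIC_PAIRS[idx_p[j]] if pal[j] else _NONPALINDROMIC_PAIRS[idx_np[j]]
        )
    return ea, oa


def _pvalues(beta: np.ndarray, se: np.ndarray) -> np.ndarray:
    p = 2 * stats.norm.sf(np.abs(beta / se))
    return np.clip(p, np.finfo(float).tiny, 1.0)


def _assemble_table(
    ids, chrom, pos, ea, oa, eaf, beta, se, n, label, trait_type
) -> AssociationTable:
    df = pd.DataFrame(
        {
            "variant_id": ids,
            "chromosome": chrom,
            "position": pos,
            "effect_allele": ea,
            "other_allele": oa,
            "eaf": eaf,
            "beta": beta,
            "se": se,
            "pval": _pvalues(beta, se),
            "n": n,
        }
    )
    return AssociationTable(df, trait_label=label, trait_type=trait_type)


def simulate_two_sample(
    config: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, dict]:
    """Simulate exposure and outcome summary statistics plus a truth record.

    The two samples are independent: observed exposure and outcome betas are
    drawn from separate normals around the true marginal effects.  Variants
    are placed far apart (one per 25,000 kb slot across 22 chromosome
    labels), so default-window clumping never removes an unlinked variant.
    Identical seeds give bit-identical tables.
    """
    rng = np.random.default_rng(config.seed)
    k = config.k
    maf = rng.uniform(*config.maf_range, size=k)
    sign = rng.choice([-1.0, 1.0], size=k)
    gamma_mag = rng.uniform(*config.gamma_range, size=k)
    invalid = rng.random(k) < config.prop_invalid
    alpha = np.where(invalid, rng.normal(config.mu_alpha, config.sd_alpha, size=k), 0.0)
    # alpha acts on the exposure-increasing allele; the random sign is a
    # labeling flip applied to both marginal effects together
    gamma = sign * gamma_mag
    big_gamma = sign * (config.beta_true * gamma_mag + alpha)

    var_factor = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_factor * config.n_exp)
    se_y = 1.0 / np.sqrt(var_factor * config.n_out)
    beta_x = rng.normal(gamma, se_x)
    beta_y = rng.normal(big_gamma, se_y)
    ea, oa = _alleles(rng, k, config.palindromic_fraction)

    ids = [f"snp{j:05d}" for j in range(k)]
    chrom = [str((j % 22) + 1) for j in range(k)]
    pos = [1_000_000 + (j // 22) * _POSITION_STEP_BP for j in range(k)]

    exposure = _assemble_table(
        ids, chrom, pos, ea, oa, maf, beta_x, se_x,
        config.n_exp, "simulated exposure", "binary",
    )
    outcome = _assemble_table(
        ids, chrom, pos, ea, oa, maf, beta_y, se_y,
        config.n_out, "simulated outcome", "continuous",
    )
    truth = {
        "seed": config.seed,
        "beta_true": config.beta_true,
        "variant_id": ids,
        "maf": maf.tolist(),
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "big_gamma": big_gamma.tolist(),
        "invalid": invalid.tolist(),
    }
    return exposure, outcome, truth


def ld_block_fixture(
    config: SimulationConfig,
) -> tuple[AssociationTable, AssociationTable, dict, LDMatrix]:
    """Simulate correlated LD blocks plus independent filler variants.

    Each ``(size m, correlation r)`` block sits on its own chromosome with
    members 50 kb apart (inside any realistic clumping window).  The first
    member is the causal tag; member i's true marginal effect is r^i times
    the tag's, and the estimation errors of the members are drawn jointly
    (independently in the two samples) with AR(1) correlation r^|i−j| — the
    standard behaviour of marginal GWAS statistics under LD.  The returned
    :class:`LDMatrix` holds the squared correlations.  Remaining variants up
    to ``config.k`` are independent, placed as in
    :func:`simulate_two_sample`.
    """
    if not config.ld_blocks:
        raise InvalidConfigError("ld_block_fixture requires ld_blocks")
    rng = np.random.default_rng(config.seed)
    block_total = sum(size for size, _ in config.ld_blocks)
    n_free = max(0, config.k - block_total)
    k = block_total + n_free

    ids, chrom, pos = [], [], []
    gamma = np.empty(k)
    corr = np.eye(k)
    j = 0
    for b, (size, r) in enumerate(config.ld_blocks):
        tag_gamma = rng.choice([-1.0, 1.0]) * rng.uniform(*config.gamma_range)
        for i in range(size):
            ids.append(f"blk{b}_snp{i}")
            chrom.append(str(b + 1))
            pos.append(1_000_000 + i * 50_000)
            gamma[j + i] = (r**i) * tag_gamma
        for a in range(size):
            for c in range(size):
                corr[j + a, j + c] = r ** abs(a - c)
        j += size
    for i in range(n_free):
        ids.append(f"free_snp{i}")
        chrom.append(str(((len(config.ld_blocks) + i) % 22) + 1))
        pos.append(200_000_000 + (i // 22) * _POSITION_STEP_BP)
        sign = rng.choice([-1.0, 1.0])
        gamma[j + i] = sign * rng.uniform(*config.gamma_range)

    invalid = rng.random(k) < config.prop_invalid
    alpha = np.where(invalid, rng.normal(config.mu_alpha, config.sd_alpha, size=k), 0.0)
    # direct effects act on the exposure-increasing allele of each member
    big_gamma = config.beta_true * gamma + np.sign(gamma) * alpha
    maf = rng.uniform(*config.maf_range, size=k)
    var_factor = 2.0 * maf * (1.0 - maf)
    se_x = 1.0 / np.sqrt(var_factor * config.n_exp)
    se_y = 1.0 / np.sqrt(var_factor * config.n_out)

    chol = np.linalg.cholesky(corr + 1e-12 * np.eye(k))
    zx = chol @ rng.standard_normal(k)
    zy = chol @ rng.standard_normal(k)
    beta_x = gamma + se_x * zx
    beta_y = big_gamma + se_y * zy
    ea, oa = _alleles(rng, k, config.palindromic_fraction)

    exposure = _assemble_table(
        ids, chrom, pos, ea, oa, maf, beta_x, se_x,
        config.n_exp, "simulated exposure", "binary",
    )
    outcome = _assemble_table(
        ids, chrom, pos, ea, oa, maf, beta_y, se_y,
        config.n_out, "simulated outcome", "continuous",
    )
    truth = {
        "seed": config.seed,
        "beta_true": config.beta_true,
        "variant_id": ids,
        "gamma": gamma.tolist(),
        "alpha": alpha.tolist(),
        "big_gamma": big_gamma.tolist(),
        "invalid": invalid.tolist(),
        "ld_blocks": list(config.ld_blocks),
    }
    ld = LDMatrix(ids=list(ids), r2=corr**2)
    return exposure, outcome, truth, ld


def table1_fixture() -> AssociationTable:
    """The packaged 18-variant ischemic-stroke instrument table.

    EAF, beta, SE and p are as published; N = 34,217 (ischemic-stroke cases)
    is attached to every row.  The source typesets the variant-ID and
    chromosome columns run together, so IDs are stored as the full
    run-together token — an opaque, unique label — and no chromosome or
    position is recorded.
    """
    path = resources.files("mrcausal").joinpath("data/ischemic_stroke_instruments.tsv")
    with resources.as_file(path) as p:
        return read_summary_stats(p, trait_type="binary", trait_label="ischemic stroke")
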