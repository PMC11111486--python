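"""Instrument screening: significance, MAF, LD clumping, F-statistic, Steiger.

Screening follows the conventional five-criterion scheme for genetic
instrumental variables: (1) genome-wide significance of the variant-exposure
association, (2) approximate pairwise independence via greedy LD clumping,
(3) a minor-allele-frequency floor, (4) a per-variant strength floor via the
F-statistic, and (5) a Steiger directionality check that the variant explains
more variance in the exposure than in the outcome.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field as dc_field

import numpy as np
import pandas as pd

from .exceptions import (
    EmptySelectionError,
    InvalidConfigError,
    MissingFieldError,
    UnknownVariantInLDError,
)
from .gwas_io import AssociationTable, LDMatrix, harmonize

__all__ = [
    "SelectionConfig",
    "ld_clump",
    "variance_explained",
    "compute_f_statistics",
    "steiger_filter",
    "select_instruments",
]

logger = logging.getLogger(__name__)


@dataclass
class SelectionConfig:
    """Thresholds for the five screening criteria.

    Defaults follow standard two-sample MR practice: genome-wide significance
    p < 5e-8, clumping at r² < 0.001 within 10,000 kb, MAF >= 0.01, per-SNP
    F >= 10, Steiger filtering on.
    """

    pval_threshold: float = 5e-8
    clump_r2: float = 0.001
    clump_kb: float = 10_000.0
    maf_min: float = 0.01
    f_min: float = 10.0
    steiger: bool = True
    ambiguity_window: tuple[float, float] = (0.42, 0.58)
    palindromic_mode: str = "infer"

    def __post_init__(self) -> None:
        for name in ("pval_threshold", "clump_kb", "maf_min", "f_min"):
            if getattr(self, name) <= 0:
                raise InvalidConfigError(f"{name} must be strictly positive")
        if not (0 < self.clump_r2 < 1):
            raise InvalidConfigError("clump_r2 must lie in (0, 1)")


@dataclass
class SelectionStage:
    """Audit record for one screening stage."""

    stage: str
    n_in: int
    n_out: int
    removed: list[str] = dc_field(default_factory=list)
    reasons: dict[str, str] = dc_field(default_factory=dict)

    def as_row(self) -> dict:
        return {
            "stage": self.stage,
            "n_in": self.n_in,
            "n_out": self.n_out,
            "n_removed": len(self.removed),
            "removed": ",".join(self.removed),
        }


def audit_frame(audit: list[SelectionStage]) -> pd.DataFrame:
    return pd.DataFrame([s.as_row() for s in audit])


def ld_clump(
    table: AssociationTable,
    ld: LDMatrix | None = None,
    clump_r2: float = 0.001,
    clump_kb: float = 10_000.0,
    strict: bool = False,
) -> AssociationTable:
    """Greedy LD clumping by p-value priority.

    Variants are sorted by ascending p (ties broken by chromosome label then
    position); the best remaining variant is kept and every remaining variant
    that is *both* within ``clump_kb`` kilobases of it on the same chromosome
    *and* correlated at r² >= ``clump_r2`` is removed.  Variants on other
    chromosomes, or farther than the window, are never removed by that index
    variant regardless of the matrix entry.  With no LD matrix all r² are
    treated as 0 (a warning is logged): only the distance rule can then never
    remove anything, so the table passes through reordered by p.

    Raises
    ------
    MissingFieldError
        if chromosome or position is absent for any row.
    UnknownVariantInLDError
        in ``strict`` mode, if a variant is missing from the supplied matrix.
    """
    df = table.data
    if df.empty:
        raise EmptySelectionError("clump")
    if df["chromosome"].isna().any() or df["position"].isna().any():
        raise MissingFieldError("ld_clump requires chromosome and position for every variant")
    if ld is None:
        logger.warning("no LD matrix supplied; treating all pairwise r2 as 0")
    elif strict:
        for vid in df["variant_id"]:
            if vid not in ld:
                raise UnknownVariantInLDError(vid)

    order = df.sort_values(
        ["pval", "chromosome", "position"],
        ascending=True,
        kind="mergesort",
    ).reset_index(drop=True)
    ids = order["variant_id"].to_numpy()
    chrom = order["chromosome"].astype(str).to_numpy()
    pos = order["position"].to_numpy(dtype=float)
    window_bp = clump_kb * 1000.0

    alive = np.ones(len(order), dtype=bool)
    kept_idx: list[int] = []
    for i in range(len(order)):
        if not alive[i]:
            continue
        kept_idx.append(i)
        for j in range(i + 1, len(order)):
            if not alive[j]:
                continue
            if chrom[j] != chrom[i]:
                continue
            if abs(pos[j] - pos[i]) > window_bp:
                continue
            r2 = 0.0 if ld is None else ld.pairwise(ids[i], ids[j], default=0.0)
            if r2 >= clump_r2:
                alive[j] = False

    kept = order.iloc[kept_idx].reset_index(drop=True)
    return AssociationTable(kept, trait_label=table.trait_label, trait_type=table.trait_type)


def variance_explained(eaf: np.ndarray, beta: np.ndarray) -> np.ndarray:
    """Per-variant trait variance explained, 2·EAF·(1−EAF)·beta²."""
    eaf = np.asarray(eaf, dtype=float)
    beta = np.asarray(beta, dtype=float)
    return 2.0 * eaf * (1.0 - eaf) * beta**2


def compute_f_statistics(table: AssociationTable) -> pd.DataFrame:
    """Per-SNP instrument strength: R² = 2·EAF·(1−EAF)·β², F = R²(N−2)/(1−R²).

    Each row uses its own sample size N.  Returns a frame with columns
    ``variant_id``, ``r2_exposure``, ``f_stat``.
    """
    df = table.data
    if df["eaf"].isna().any():
        raise MissingFieldError("compute_f_statistics requires eaf for every variant")
    if df["n"].isna().any():
        raise MissingFieldError("compute_f_statistics requires n for every variant")
    r2 = variance_explained(df["eaf"].to_numpy(), df["beta"].to_numpy())
    n = df["n"].to_numpy(dtype=float)
    f = r2 * (n - 2.0) / (1.0 - r2)
    return pd.DataFrame(
        {"variant_id": df["variant_id"], "r2_exposure": r2, "f_stat": f}
    ).reset_index(drop=True)


def steiger_filter(
    instruments: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.DataFrame, pd.DataFrame]:
    """Directionality screen: keep variants explaining more variance in the
    exposure than in the outcome.

    Variance explained uses the same 2p(1−p)β² approximation on both sides.
    Ties (exactly equal r²) are dropped as ``ambiguous``.

    Returns
    -------
    (kept, diagnostics, exclusions)
        ``diagnostics`` has ``variant_id``, ``r2_exposure``, ``r2_outcome``
        and ``steiger_direction`` in {exposure_to_outcome, outcome_to_exposure,
        ambiguous}; ``exclusions`` lists dropped variants and reasons.
    """
    for col in ("eaf_exp", "eaf_out"):
        if instruments[col].isna().any():
            raise MissingFieldError(f"steiger_filter requires {col} for every instrument")
    r2_exp = variance_explained(
        instruments["eaf_exp"].to_numpy(), instruments["beta_exp"].to_numpy()
    )
    r2_out = variance_explained(
        instruments["eaf_out"].to_numpy(), instruments["beta_out"].to_numpy()
    )
    direction = np.where(
        r2_exp > r2_out,
        "exposure_to_outcome",
        np.where(r2_exp < r2_out, "outcome_to_exposure", "ambiguous"),
    )
    diagnostics = pd.DataFrame(
        {
            "variant_id": instruments["variant_id"],
            "r2_exposure": r2_exp,
            "r2_outcome": r2_out,
            "steiger_direction": direction,
        }
    ).reset_index(drop=True)
    keep = r2_exp > r2_out
    reasons = np.where(direction == "ambiguous", "ambiguous", "reverse-causality")
    exclusions = pd.DataFrame(
        {
            "variant_id": instruments.loc[~keep, "variant_id"],
            "reason": reasons[~keep],
        }
    ).reset_index(drop=True)
    kept = instruments.loc[keep].reset_index(drop=True)
    return kept, diagnostics, exclusions


def select_instruments(
    exposure: AssociationTable,
    outcome: AssociationTable,
    ld: LDMatrix | None = None,
    config: SelectionConfig | None = None,
) -> tuple[pd.DataFrame, list[SelectionStage]]:
    """Run the full screening pipeline and harmonize the survivors.

    Stage order: p-value threshold → MAF floor → LD clumping → harmonization
    against the outcome → F-statistic floor → Steiger directionality.  The
    audit trail records, for every stage, counts in/out and the removed IDs;
    counts telescope (n_in = n_out + removed) at each stage.

    Raises
    ------
    EmptySelectionError
        naming the first stage that empties the candidate set.
    """
    config = config or SelectionConfig()
    audit: list[SelectionStage] = []

    def check_empty(stage: str, df: pd.DataFrame) -> None:
        if df.empty:
            raise EmptySelectionError(stage)

    # (1) genome-wide significance on the exposure side
    df = exposure.data
    keep = df["pval"] < config.pval_threshold
    audit.append(
        SelectionStage("pvalue", len(df), int(keep.sum()), df.loc[~keep, "variant_id"].tolist())
    )
    df = df.loc[keep].reset_index(drop=True)
    check_empty("pvalue", df)

    # (2) MAF floor; variants lacking eaf cannot be assessed and are removed
    maf = np.minimum(df["eaf"], 1.0 - df["eaf"])
    keep = (maf >= config.maf_min).fillna(False)
    audit.append(
        SelectionStage("maf", len(df), int(keep.sum()), df.loc[~keep, "variant_id"].tolist())
    )
    df = df.loc[keep].reset_index(drop=True)
    check_empty("maf", df)

    # (3) LD clumping
    stage_in = AssociationTable(df, trait_label=exposure.trait_label, trait_type=exposure.trait_type)
    clumped = ld_clump(stage_in, ld=ld, clump_r2=config.clump_r2, clump_kb=config.clump_kb)
    removed = sorted(set(df["variant_id"]) - set(clumped.variant_ids))
    audit.append(SelectionStage("clump", len(df), len(clumped), removed))
    check_empty("clump", clumped.data)

    # (4) harmonize the clumped exposure set against the outcome
    harmonized, exclusions = harmonize(
        clumped,
        outcome,
        ambiguity_window=config.ambiguity_window,
        palindromic_mode=config.palindromic_mode,
    )
    dropped = exclusions.loc[exclusions["variant_id"].isin(clumped.variant_ids)]
    audit.append(
        SelectionStage(
            "harmonize",
            len(clumped),
            len(harmonized),
            dropped["variant_id"].tolist(),
            dict(zip(dropped["variant_id"], dropped["reason"])),
        )
    )
    check_empty("harmonize", harmonized)

    # (5) per-SNP F floor on the exposure side
    exp_side = AssociationTable(
        harmonized.rename(
            columns={
                "beta_exp": "beta",
                "se_exp": "se",
                "eaf_exp": "eaf",
                "n_exp": "n",
            }
        ).assign(pval=1e-300)[
            ["variant_id", "chromosome", "position", "effect_allele", "other_allele",
             "eaf", "beta", "se", "pval", "n"]
        ],
        trait_label=exposure.trait_label,
        trait_type=exposure.trait_type,
    )
    diag = compute_f_statistics(exp_side)
    keep = diag["f_stat"] >= config.f_min
    audit.append(
        SelectionStage(
            "fstat", len(harmonized), int(keep.sum()), diag.loc[~keep, "variant_id"].tolist()
        )
    )
    harmonized = harmonized.loc[keep.to_numpy()].reset_index(drop=True)
    check_empty("fstat", harmonized)

    # (6) Steiger directionality
    if config.steiger:
        kept, _, excl = steiger_filter(harmonized)
        audit.append(
            SelectionStage(
                "steiger",
                len(harmonized),
                len(kept),
                excl["variant_id"].tolist(),
                dict(zip(excl["variant_id"], excl["reason"])),
            )
        )
        harmonized = kept
        check_empty("steiger", harmonized)

    return harmonized, audit
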