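"""Reading, validating and harmonizing GWAS summary statistics.

A summary-statistics table holds one row per variant with the per-allele
association estimate (beta), its standard error, p-value, effect-allele
frequency and sample size.  Two-sample MR needs the exposure and outcome
tables expressed on the *same* effect allele for every shared variant;
:func:`harmonize` performs that alignment, resolving swapped alleles, strand
complements and palindromic (A/T, G/C) variants.
"""

from __future__ import annotations

import dataclasses
import io
import os
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .exceptions import (
    EmptyTableError,
    MissingColumnError,
    NoOverlapError,
)

__all__ = [
    "VariantAssociation",
    "AssociationTable",
    "LDMatrix",
    "read_summary_stats",
    "write_summary_stats",
    "harmonize",
    "write_harmonized",
    "HARMONIZED_COLUMNS",
]

_BASES = frozenset("ACGT")
_COMPLEMENT = {"A": "T", "T": "A", "C": "G", "G": "C"}

#: canonical column -> accepted synonyms (matched case-insensitively)
COLUMN_SYNONYMS: dict[str, tuple[str, ...]] = {
    "variant_id": ("variant_id", "snp", "rsid", "id", "variant", "markername"),
    "chromosome": ("chromosome", "chr", "chrom"),
    "position": ("position", "pos", "bp", "base_pair_location"),
    "effect_allele": ("effect_allele", "ea", "a1", "allele1"),
    "other_allele": ("other_allele", "nea", "oa", "a2", "allele2", "non_effect_allele"),
    "eaf": ("eaf", "effect_allele_frequency", "freq", "af"),
    "beta": ("beta", "b", "effect", "effect_size"),
    "se": ("se", "standard_error", "stderr"),
    "pval": ("pval", "p", "pvalue", "p_value"),
    "n": ("n", "samplesize", "sample_size", "n_total"),
}

REQUIRED_COLUMNS = ("variant_id", "effect_allele", "other_allele", "beta", "se", "pval")
OPTIONAL_COLUMNS = ("chromosome", "position", "eaf", "n")
CANONICAL_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "eaf",
    "beta",
    "se",
    "pval",
    "n",
)

HARMONIZED_COLUMNS = (
    "variant_id",
    "chromosome",
    "position",
    "effect_allele",
    "other_allele",
    "beta_exp",
    "se_exp",
    "eaf_exp",
    "n_exp",
    "beta_out",
    "se_out",
    "eaf_out",
    "n_out",
    "wald_ratio",
    "wald_se",
)


@dataclass(frozen=True)
class VariantAssociation:
    """One variant's association record in one GWAS.

    ``beta`` is the per-allele effect of ``effect_allele``: a log-odds for a
    binary trait, standardized units for a continuous one.  ``chromosome``,
    ``position``, ``eaf`` and ``n`` may be absent (``None``) — operations that
    need them fail loudly instead of guessing.
    """

    variant_id: str
    effect_allele: str
    other_allele: str
    beta: float
    se: float
    pval: float
    chromosome: str | None = None
    position: int | None = None
    eaf: float | None = None
    n: int | None = None

    def problems(self) -> list[str]:
        """Return the list of invariant violations (empty if valid)."""
        out: list[str] = []
        if self.effect_allele not in _BASES:
            out.append(f"effect_allele {self.effect_allele!r} is not a single base")
        if self.other_allele not in _BASES:
            out.append(f"other_allele {self.other_allele!r} is not a single base")
        if self.effect_allele == self.other_allele:
            out.append("effect_allele equals other_allele")
        if not np.isfinite(self.beta):
            out.append("beta is not finite")
        if not (np.isfinite(self.se) and self.se > 0):
            out.append("se must be > 0")
        if not (np.isfinite(self.pval) and 0 < self.pval <= 1):
            out.append("pval must lie in (0, 1]")
        if self.eaf is not None and not (0 < self.eaf < 1):
            out.append("eaf must lie in (0, 1)")
        if self.n is not None and self.n < 2:
            out.append("n must be >= 2")
        return out


def _row_problems(row: pd.Series) -> list[str]:
    eaf = row["eaf"]
    n = row["n"]
    rec = VariantAssociation(
        variant_id=str(row["variant_id"]),
        effect_allele=str(row["effect_allele"]),
        other_allele=str(row["other_allele"]),
        beta=row["beta"],
        se=row["se"],
        pval=row["pval"],
        eaf=None if pd.isna(eaf) else float(eaf),
        n=None if pd.isna(n) else int(n),
    )
    return rec.problems()


@dataclass
class AssociationTable:
    """A validated GWAS summary-statistics table.

    ``data`` always carries the canonical columns (missing optional ones are
    NaN); ``rejected`` lists rows dropped at read time with a reason each.
    """

    data: pd.DataFrame
    trait_label: str = ""
    trait_type: str = "continuous"
    rejected: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=["variant_id", "reason"])
    )

    def __post_init__(self) -> None:
        if self.trait_type not in ("binary", "continuous"):
            raise ValueError(f"trait_type must be binary/continuous, got {self.trait_type!r}")
        df = self.data.copy()
        for col in REQUIRED_COLUMNS:
            if col not in df.columns:
                raise MissingColumnError(col)
        for col in OPTIONAL_COLUMNS:
            if col not in df.columns:
                df[col] = np.nan
        if df["variant_id"].duplicated().any():
            dups = df.loc[df["variant_id"].duplicated(), "variant_id"].tolist()
            raise ValueError(f"duplicate variant_id values: {dups}")
        self.data = df.loc[:, list(CANONICAL_COLUMNS)].reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.data)

    @property
    def variant_ids(self) -> list[str]:
        return self.data["variant_id"].tolist()

    def records(self) -> list[VariantAssociation]:
        out = []
        for _, row in self.data.iterrows():
            out.append(
                VariantAssociation(
                    variant_id=str(row["variant_id"]),
                    effect_allele=str(row["effect_allele"]),
                    other_allele=str(row["other_allele"]),
                    beta=float(row["beta"]),
                    se=float(row["se"]),
                    pval=float(row["pval"]),
                    chromosome=None if pd.isna(row["chromosome"]) else str(row["chromosome"]),
                    position=None if pd.isna(row["position"]) else int(row["position"]),
                    eaf=None if pd.isna(row["eaf"]) else float(row["eaf"]),
                    n=None if pd.isna(row["n"]) else int(row["n"]),
                )
            )
        return out


def _resolve_columns(
    columns: Iterable[str], column_map: Mapping[str, str] | None
) -> dict[str, str]:
    """Map canonical field names to source column names, honoring synonyms."""
    lower = {c.lower(): c for c in columns}
    resolved: dict[str, str] = {}
    for canonical, synonyms in COLUMN_SYNONYMS.items():
        if column_map and canonical in column_map:
            if column_map[canonical] in lower.values():
                resolved[canonical] = column_map[canonical]
            continue
        for syn in synonyms:
            if syn in lower:
                resolved[canonical] = lower[syn]
                break
    return resolved


def read_summary_stats(
    path: str | os.PathLike | io.IOBase,
    column_map: Mapping[str, str] | None = None,
    trait_type: str = "continuous",
    trait_label: str = "",
) -> AssociationTable:
    """Read a delimited (tab or comma) GWAS summary-statistics file.

    Column headers are matched case-insensitively against common synonyms
    (``rsid``/``SNP``, ``ea``/``effect_allele``, ``b``/``beta``, ``p``/``pval``,
    ...); ``column_map`` overrides the mapping per canonical name.  Rows whose
    values violate the record invariants (non-SNV alleles, se <= 0, p outside
    (0,1], eaf outside (0,1)) are rejected and listed, with reasons, on the
    returned table's ``rejected`` attribute.

    Raises
    ------
    MissingColumnError
        if a required field has no source column.
    EmptyTableError
        if no row survives validation.
    """
    raw = pd.read_csv(path, sep=None, engine="python", dtype=str)
    resolved = _resolve_columns(raw.columns, column_map)
    for col in REQUIRED_COLUMNS:
        if col not in resolved:
            raise MissingColumnError(col)

    df = pd.DataFrame({canon: raw[src] for canon, src in resolved.items()})
    for col in OPTIONAL_COLUMNS:
        if col not in df.columns:
            df[col] = np.nan

    df["variant_id"] = df["variant_id"].astype(str)
    for col in ("effect_allele", "other_allele"):
        df[col] = df[col].astype(str).str.strip().str.upper()
    for col in ("eaf", "beta", "se", "pval", "n"):
        df[col] = pd.to_numeric(df[col], errors="coerce")
    df["position"] = pd.to_numeric(df["position"], errors="coerce")

    keep_mask = np.ones(len(df), dtype=bool)
    reasons: list[tuple[str, str]] = []
    seen: set[str] = set()
    for i, row in df.iterrows():
        vid = row["variant_id"]
        if vid in seen:
            keep_mask[i] = False
            reasons.append((vid, "duplicate variant_id"))
            continue
        probs = []
        for col in ("beta", "se", "pval"):
            if pd.isna(row[col]):
                probs.append(f"{col} missing or non-numeric")
        if not probs:
            probs = _row_problems(row)
        if probs:
            keep_mask[i] = False
            reasons.append((vid, "; ".join(probs)))
        else:
            seen.add(vid)

    rejected = pd.DataFrame(reasons, columns=["variant_id", "reason"])
    valid = df.loc[keep_mask].reset_index(drop=True)
    if valid.empty:
        raise EmptyTableError(f"no valid rows in {path!r}")
    label = trait_label or (os.path.basename(str(path)) if not isinstance(path, io.IOBase) else "")
    return AssociationTable(valid, trait_label=label, trait_type=trait_type, rejected=rejected)


def write_summary_stats(table: AssociationTable, path: str | os.PathLike) -> None:
    """Write a table back to TSV with canonical headers."""
    table.data.to_csv(path, sep="\t", index=False)


@dataclass
class LDMatrix:
    """A square matrix of squared allele-dosage correlations (r²).

    Stored keyed by variant ID; symmetric within 1e-12, unit diagonal,
    entries in [0, 1].
    """

    ids: list[str]
    r2: np.ndarray

    def __post_init__(self) -> None:
        self.ids = [str(i) for i in self.ids]
        self.r2 = np.asarray(self.r2, dtype=float)
        m = len(self.ids)
        if self.r2.shape != (m, m):
            raise ValueError(f"r2 must be {m}x{m}, got {self.r2.shape}")
        if len(set(self.ids)) != m:
            raise ValueError("duplicate variant IDs in LD matrix")
        if not np.allclose(self.r2, self.r2.T, atol=1e-12, rtol=0):
            raise ValueError("LD matrix must be symmetric within 1e-12")
        if not np.allclose(np.diag(self.r2), 1.0, atol=1e-12, rtol=0):
            raise ValueError("LD matrix diagonal must be 1")
        if self.r2.min() < -1e-12 or self.r2.max() > 1 + 1e-12:
            raise ValueError("LD r2 entries must lie in [0, 1]")
        np.fill_diagonal(self.r2, 1.0)
        self.r2 = np.clip(self.r2, 0.0, 1.0)
        self._index = {v: i for i, v in enumerate(self.ids)}

    def __contains__(self, variant_id: str) -> bool:
        return variant_id in self._index

    def pairwise(self, a: str, b: str, default: float = 0.0) -> float:
        """r² between two variants; ``default`` if either is absent."""
        ia = self._index.get(a)
        ib = self._index.get(b)
        if ia is None or ib is None:
            return default
        return float(self.r2[ia, ib])

    @classmethod
    def read_tsv(cls, path: str | os.PathLike) -> "LDMatrix":
        df = pd.read_csv(path, sep="\t", index_col=0)
        return cls(ids=list(df.columns.astype(str)), r2=df.to_numpy(dtype=float))

    def to_tsv(self, path: str | os.PathLike) -> None:
        pd.DataFrame(self.r2, index=self.ids, columns=self.ids).to_csv(path, sep="\t")


def _is_palindromic(ea: pd.Series, oa: pd.Series) -> pd.Series:
    return oa == ea.map(_COMPLEMENT)


def harmonize(
    exposure: AssociationTable,
    outcome: AssociationTable,
    ambiguity_window: tuple[float, float] = (0.42, 0.58),
    palindromic_mode: str = "infer",
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Align outcome records to the exposure effect allele, variant by variant.

    For each variant shared between the two tables:

    * identical allele pair — kept as-is;
    * swapped alleles — outcome beta negated, outcome EAF replaced by 1−EAF;
    * strand complement — complemented, then the two rules above;
    * palindromic pair (A/T or G/C) — strand cannot be resolved from alleles,
      so the variant is kept (unflipped) only when both EAFs fall on the same
      side of 0.5 *outside* ``ambiguity_window``, else dropped as
      ``palindromic-ambiguous`` (``palindromic_mode="drop"`` drops them all);
    * incompatible allele pairs are dropped.

    The exposure orientation is never altered.  The function is idempotent:
    applied to already-aligned tables it returns them unchanged.

    Returns
    -------
    (harmonized, exclusions)
        ``harmonized`` has one row per retained variant with both-side
        quantities plus the per-SNP Wald ratio ``beta_out/beta_exp`` and its
        first-order SE ``se_out/|beta_exp|``; ``exclusions`` lists every
        dropped variant with a reason.  Every input variant appears in
        exactly one of the two frames.
    """
    if palindromic_mode not in ("infer", "drop"):
        raise ValueError(f"palindromic_mode must be 'infer' or 'drop', got {palindromic_mode!r}")
    lo, hi = ambiguity_window
    if not (0 < lo < 0.5 < hi < 1):
        raise ValueError("ambiguity_window must straddle 0.5 inside (0, 1)")

    exp = exposure.data
    out = outcome.data
    merged = exp.merge(out, on="variant_id", suffixes=("_exp", "_out"), how="inner")
    exclusions: list[tuple[str, str]] = []
    shared = set(merged["variant_id"])
    for vid in exp.loc[~exp["variant_id"].isin(shared), "variant_id"]:
        exclusions.append((vid, "missing-in-outcome"))
    for vid in out.loc[~out["variant_id"].isin(shared), "variant_id"]:
        exclusions.append((vid, "missing-in-exposure"))
    if merged.empty:
        raise NoOverlapError("exposure and outcome share no variant IDs")

    ea_x = merged["effect_allele_exp"]
    oa_x = merged["other_allele_exp"]
    ea_y = merged["effect_allele_out"]
    oa_y = merged["other_allele_out"]
    cea_y = ea_y.map(_COMPLEMENT)
    coa_y = oa_y.map(_COMPLEMENT)

    pal = _is_palindromic(ea_x, oa_x)
    same = (ea_y == ea_x) & (oa_y == oa_x)
    swapped = (ea_y == oa_x) & (oa_y == ea_x)
    csame = (cea_y == ea_x) & (coa_y == oa_x)
    cswap = (cea_y == oa_x) & (coa_y == ea_x)
    compatible = same | swapped | csame | cswap

    flip = (~pal) & (~same) & (~csame) & (swapped | cswap)
    keep = compatible.copy()
    reason = pd.Series("", index=merged.index)
    reason[~compatible] = "incompatible-alleles"

    if palindromic_mode == "drop":
        keep &= ~pal
        reason[pal & compatible] = "palindromic"
    else:
        eaf_x = merged["eaf_exp"]
        eaf_y = merged["eaf_out"]
        missing = pal & compatible & (eaf_x.isna() | eaf_y.isna())
        same_side = ((eaf_x < lo) & (eaf_y < lo)) | ((eaf_x > hi) & (eaf_y > hi))
        ambiguous = pal & compatible & ~missing & ~same_side
        keep &= ~(missing | ambiguous)
        reason[missing] = "palindromic-missing-eaf"
        reason[ambiguous] = "palindromic-ambiguous"

    zero = keep & (merged["beta_exp"] == 0)
    keep &= ~zero
    reason[zero] = "zero-exposure-effect"

    for vid, r in zip(merged.loc[~keep, "variant_id"], reason[~keep]):
        exclusions.append((vid, r))

    kept = merged.loc[keep].copy()
    do_flip = flip.loc[keep]
    kept.loc[do_flip, "beta_out"] = -kept.loc[do_flip, "beta_out"]
    kept.loc[do_flip, "eaf_out"] = 1.0 - kept.loc[do_flip, "eaf_out"]

    harmonized = pd.DataFrame(
        {
            "variant_id": kept["variant_id"],
            "chromosome": kept["chromosome_exp"],
            "position": kept["position_exp"],
            "effect_allele": kept["effect_allele_exp"],
            "other_allele": kept["other_allele_exp"],
            "beta_exp": kept["beta_exp"].astype(float),
            "se_exp": kept["se_exp"].astype(float),
            "eaf_exp": kept["eaf_exp"].astype(float),
            "n_exp": kept["n_exp"].astype(float),
            "beta_out": kept["beta_out"].astype(float),
            "se_out": kept["se_out"].astype(float),
            "eaf_out": kept["eaf_out"].astype(float),
            "n_out": kept["n_out"].astype(float),
        }
    ).reset_index(drop=True)
    harmonized["wald_ratio"] = harmonized["beta_out"] / harmonized["beta_exp"]
    harmonized["wald_se"] = harmonized["se_out"] / harmonized["beta_exp"].abs()

    exclusions_df = pd.DataFrame(exclusions, columns=["variant_id", "reason"])
    return harmonized, exclusions_df


def write_harmonized(harmonized: pd.DataFrame, path: str | os.PathLike) -> None:
    harmonized.to_csv(path, sep="\t", index=False)


def read_harmonized(path: str | os.PathLike) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in ("variant_id", "beta_exp", "se_exp", "beta_out", "se_out") if c not in df.columns]
    if missing:
        raise MissingColumnError(missing[0])
    return df


def split_harmonized(harmonized: pd.DataFrame) -> tuple[AssociationTable, AssociationTable]:
    """Rebuild per-sample tables from a harmonized frame (round-trip helper)."""

    def side(suffix: str) -> pd.DataFrame:
        df = pd.DataFrame(
            {
                "variant_id": harmonized["variant_id"],
                "chromosome": harmonized.get("chromosome", np.nan),
                "position": harmonized.get("position", np.nan),
                "effect_allele": harmonized["effect_allele"],
                "other_allele": harmonized["other_allele"],
                "eaf": harmonized[f"eaf_{suffix}"],
                "beta": harmonized[f"beta_{suffix}"],
                "se": harmonized[f"se_{suffix}"],
                "n": harmonized[f"n_{suffix}"],
            }
        )
        beta = df["beta"].to_numpy(dtype=float)
        se = df["se"].to_numpy(dtype=float)
        from scipy.stats import norm

        df["pval"] = np.clip(2 * norm.sf(np.abs(beta / se)), np.finfo(float).tiny, 1.0)
        return df

    return (
        AssociationTable(side("exp"), trait_label="exposure"),
        AssociationTable(side("out"), trait_label="outcome"),
    )


# dataclass helper: fields of VariantAssociation in canonical order
VARIANT_FIELDS = tuple(f.name for f in dataclasses.fields(VariantAssociation))
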