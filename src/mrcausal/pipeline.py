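"""End-to-end orchestration: selection → harmonization → estimation → sensitivity.

A run is fully specified by a :class:`RunConfig` (loadable from YAML) and a
seed; repeated runs with the same config produce byte-identical outputs.
The headline causal estimate is IVW, switching between the fixed-effect and
multiplicative-random-effect SE according to the Cochran Q heterogeneity
verdict at the configured alpha.
"""

from __future__ import annotations

import dataclasses
import json
import os
from dataclasses import dataclass, field
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import scipy
import yaml

from . import __version__
from .exceptions import InvalidConfigError, MRError
from .estimators import run_all_methods, wald_ratios, Z_975
from .gwas_io import LDMatrix, read_summary_stats, write_harmonized
from .selection import SelectionConfig, audit_frame, select_instruments
from .sensitivity import sensitivity_report

__all__ = ["RunConfig", "run_pipeline"]


@dataclass
class RunConfig:
    """Everything one reproducible pipeline run needs."""

    exposure_path: str
    outcome_path: str
    out_dir: str
    seed: int
    ld_path: str | None = None
    exposure_trait_type: str = "binary"
    outcome_trait_type: str = "continuous"
    selection: SelectionConfig = field(default_factory=SelectionConfig)
    n_boot: int = 1000
    phi: float = 1.0
    effects_model: str = "multiplicative_random"
    alpha: float = 0.05

    def __post_init__(self) -> None:
        if self.seed is None:
            raise InvalidConfigError("seed is mandatory")
        if not (0 < self.alpha < 1):
            raise InvalidConfigError("alpha must lie in (0, 1)")
        if self.n_boot < 0:
            raise InvalidConfigError("n_boot must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | os.PathLike) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        if "seed" not in raw:
            raise InvalidConfigError("config file must set a seed")
        sel = raw.pop("selection", {}) or {}
        if "ambiguity_window" in sel:
            sel["ambiguity_window"] = tuple(sel["ambiguity_window"])
        return cls(selection=SelectionConfig(**sel), **raw)

    def as_dict(self) -> dict[str, Any]:
        d = dataclasses.asdict(self)
        d["selection"]["ambiguity_window"] = list(d["selection"]["ambiguity_window"])
        return d


def _stage(name: str):
    """Decorator-free stage wrapper: re-raise MR errors tagged with the stage."""

    class _Ctx:
        def __enter__(self):
            return self

        def __exit__(self, exc_type, exc, tb):
            if exc is not None and isinstance(exc, MRError):
                exc.args = (f"[stage {name}] {exc}",) + exc.args[1:]
            return False

    return _Ctx()


def run_pipeline(config: RunConfig) -> dict[str, Any]:
    """Execute the full analysis and write all result files to ``out_dir``.

    Outputs: ``instruments.tsv`` (harmonized instruments), ``audit.tsv``
    (per-stage counts and removed IDs), ``estimates.tsv`` (the five methods,
    one row each), ``sensitivity.json``, ``loo.tsv``, ``scatter_data.tsv``
    (per-variant effect pairs plus per-method fitted lines), and
    ``forest_data.tsv`` (per-variant Wald ratios with 95% CIs plus pooled
    rows).  ``run_log.json`` records config, seed, library versions and
    stage counts.  Partial outputs are retained if a later stage fails.
    """
    out_dir = Path(config.out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)

    with _stage("read"):
        exposure = read_summary_stats(
            config.exposure_path, trait_type=config.exposure_trait_type
        )
        outcome = read_summary_stats(
            config.outcome_path, trait_type=config.outcome_trait_type
        )
        ld = LDMatrix.read_tsv(config.ld_path) if config.ld_path else None

    with _stage("select"):
        instruments, audit = select_instruments(
            exposure, outcome, ld=ld, config=config.selection
        )
    write_harmonized(instruments, out_dir / "instruments.tsv")
    audit_df = audit_frame(audit)
    audit_df.to_csv(out_dir / "audit.tsv", sep="\t", index=False)

    with _stage("estimate"):
        estimates = run_all_methods(
            instruments,
            n_boot=config.n_boot,
            phi=config.phi,
            seed=config.seed,
            effects_model=config.effects_model,
        )
    est_df = pd.DataFrame([e.as_row() for e in estimates])
    est_df.insert(0, "type", exposure.trait_label)
    est_df.to_csv(out_dir / "estimates.tsv", sep="\t", index=False, float_format="%.10g")

    with _stage("sensitivity"):
        report = sensitivity_report(
            instruments, alpha=config.alpha, effects_model=config.effects_model
        )
    with open(out_dir / "sensitivity.json", "w") as fh:
        json.dump(report.as_dict(), fh, indent=2, sort_keys=True)
        fh.write("\n")
    report.loo.to_csv(out_dir / "loo.tsv", sep="\t", index=False, float_format="%.10g")

    # headline IVW: random-effects SE when heterogeneity is detected
    headline_model = "multiplicative_random" if report.heterogeneous else "fixed"
    ivw_est = next(e for e in estimates if e.method == "IVW")
    headline = {
        "method": "IVW",
        "effects_model": headline_model,
        "b": ivw_est.b,
        "se": ivw_est.extras["se_random" if headline_model == "multiplicative_random" else "se_fixed"],
        "k": ivw_est.k,
    }

    # plot-data files: scatter (per-variant effect pairs + method lines) and
    # forest (per-variant Wald ratios + pooled estimates)
    scatter = instruments[
        ["variant_id", "beta_exp", "se_exp", "beta_out", "se_out"]
    ].copy()
    scatter["weight"] = 1.0 / scatter["se_out"] ** 2
    for e in estimates:
        scatter[f"slope_{e.method.replace(' ', '_')}"] = e.b
    scatter["intercept_MR-Egger"] = report.egger_intercept.estimate
    scatter.to_csv(out_dir / "scatter_data.tsv", sep="\t", index=False, float_format="%.10g")

    forest = wald_ratios(instruments)
    forest["ci_low"] = forest["wald_ratio"] - Z_975 * forest["wald_se"]
    forest["ci_high"] = forest["wald_ratio"] + Z_975 * forest["wald_se"]
    pooled = pd.DataFrame(
        [
            {
                "variant_id": f"All ({e.method})",
                "wald_ratio": e.b,
                "wald_se": e.se,
                "ci_low": e.b - Z_975 * e.se if np.isfinite(e.se) else np.nan,
                "ci_high": e.b + Z_975 * e.se if np.isfinite(e.se) else np.nan,
            }
            for e in estimates
        ]
    )
    forest = pd.concat([forest, pooled], ignore_index=True)
    forest.to_csv(out_dir / "forest_data.tsv", sep="\t", index=False, float_format="%.10g")

    run_log = {
        "config": config.as_dict(),
        "seed": config.seed,
        "versions": {
            "mrcausal": __version__,
            "numpy": np.__version__,
            "scipy": scipy.__version__,
            "pandas": pd.__version__,
        },
        "stages": [s.as_row() for s in audit],
        "headline": headline,
        "n_instruments": int(len(instruments)),
    }
    with open(out_dir / "run_log.json", "w") as fh:
        json.dump(run_log, fh, indent=2, sort_keys=True)
        fh.write("\n")

    return {
        "instruments": instruments,
        "audit": audit,
        "estimates": estimates,
        "sensitivity": report,
        "headline": headline,
        "out_dir": str(out_dir),
    }
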