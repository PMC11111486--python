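"""Heterogeneity, pleiotropy and leave-one-out diagnostics.

Cochran's Q measures dispersion of the per-variant estimates around the
fitted IVW (df k−1) or Egger (df k−2) line and is chi-square distributed
under homogeneity with correctly specified SEs.  The Egger intercept test
probes directional horizontal pleiotropy.  Leave-one-out refits the headline
estimator with each instrument removed in turn to expose single-variant
leverage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any

import numpy as np
import pandas as pd
from scipy import stats

from .exceptions import TooFewInstrumentsError
from .estimators import EggerEstimator, IVWEstimator

__all__ = [
    "QResult",
    "InterceptTest",
    "SensitivityReport",
    "cochran_q",
    "egger_intercept_test",
    "leave_one_out",
    "sensitivity_report",
]


@dataclass(frozen=True)
class QResult:
    q: float
    df: int
    pval: float

    def as_dict(self) -> dict[str, float]:
        return {"q": self.q, "df": self.df, "pval": self.pval}


@dataclass(frozen=True)
class InterceptTest:
    estimate: float
    se: float
    pval: float
    verdict: str
    exact_fit: bool = False

    def format(self) -> str:
        """Render in the conventional ``b = <est> (P = <p>)`` style."""
        return f"b = {self.estimate:.4f} (P = {self.pval:.4f})"

    def as_dict(self) -> dict[str, Any]:
        return {
            "estimate": self.estimate,
            "se": self.se,
            "pval": self.pval,
            "verdict": self.verdict,
            "exact_fit": self.exact_fit,
            "formatted": self.format(),
        }


def cochran_q(instruments: pd.DataFrame, model: str = "ivw") -> QResult:
    """Cochran's Q around the fixed-effect IVW line or the Egger line.

    Q = Σ w_j (beta_out_j − fitted_j)² with w_j = 1/se_out_j²; df is k−1
    (IVW, slope only) or k−2 (Egger, slope + intercept); p is the upper
    chi-square tail.
    """
    k = len(instruments)
    if model == "ivw":
        est = IVWEstimator(effects_model="fixed").fit(instruments)
        q, df = est.q_, k - 1
    elif model == "egger":
        est = EggerEstimator().fit(instruments)
        q, df = est.q_, k - 2
    else:
        raise ValueError(f"model must be 'ivw' or 'egger', got {model!r}")
    pval = float(stats.chi2.sf(q, df)) if df > 0 else float("nan")
    return QResult(q=float(q), df=df, pval=pval)


def egger_intercept_test(instruments: pd.DataFrame, alpha: float = 0.05) -> InterceptTest:
    """Directional-pleiotropy test on the MR-Egger intercept.

    The intercept estimates the average direct (pleiotropic) effect; its
    p-value comes from the t distribution with k−2 df.  Verdict is
    ``"pleiotropy"`` iff p < alpha.  An exact fit (zero residual Q) is
    flagged: the nominal p is then degenerate.
    """
    est = EggerEstimator().fit(instruments)
    return InterceptTest(
        estimate=est.intercept_,
        se=est.intercept_se_,
        pval=est.intercept_pval_,
        verdict="pleiotropy" if est.intercept_pval_ < alpha else "no pleiotropy",
        exact_fit=est.exact_fit_,
    )


def leave_one_out(
    instruments: pd.DataFrame,
    effects_model: str = "multiplicative_random",
) -> tuple[pd.DataFrame, bool]:
    """IVW re-estimates with each instrument dropped in turn.

    Returns a (k+1)-row frame — one row per dropped variant plus an ``All``
    row — and a flag reporting whether every leave-one-out slope shares the
    sign of the all-instrument slope (direction consistency).
    """
    k = len(instruments)
    if k < 3:
        raise TooFewInstrumentsError("leave-one-out", k, 3)
    rows = []
    for i in range(k):
        sub = instruments.drop(instruments.index[i])
        est = IVWEstimator(effects_model=effects_model).fit(sub)
        rows.append(
            {
                "variant_id": instruments.iloc[i]["variant_id"],
                "b": est.b_,
                "se": est.se_,
                "pval": est.pval_,
            }
        )
    full = IVWEstimator(effects_model=effects_model).fit(instruments)
    rows.append({"variant_id": "All", "b": full.b_, "se": full.se_, "pval": full.pval_})
    loo = pd.DataFrame(rows)
    direction_consistent = bool(np.all(np.sign(loo["b"]) == np.sign(full.b_)))
    return loo, direction_consistent


@dataclass
class SensitivityReport:
    """Bundle of heterogeneity, pleiotropy and leave-one-out diagnostics."""

    q_ivw: QResult
    q_egger: QResult
    egger_intercept: InterceptTest
    loo: pd.DataFrame
    direction_consistent: bool
    alpha: float = 0.05
    extras: dict[str, Any] = field(default_factory=dict)

    @property
    def heterogeneous(self) -> bool:
        """True when the IVW Q rejects homogeneity at ``alpha``."""
        return self.q_ivw.pval < self.alpha

    def as_dict(self) -> dict[str, Any]:
        return {
            "alpha": self.alpha,
            "q_ivw": self.q_ivw.as_dict(),
            "q_egger": self.q_egger.as_dict(),
            "egger_intercept": self.egger_intercept.as_dict(),
            "heterogeneous": self.heterogeneous,
            "direction_consistent": self.direction_consistent,
            "loo": self.loo.to_dict(orient="records"),
        }


def sensitivity_report(
    instruments: pd.DataFrame,
    alpha: float = 0.05,
    effects_model: str = "multiplicative_random",
) -> SensitivityReport:
    """Compute the full sensitivity suite on one instrument set."""
    q_i = cochran_q(instruments, model="ivw")
    q_e = cochran_q(instruments, model="egger")
    intercept = egger_intercept_test(instruments, alpha=alpha)
    loo, consistent = leave_one_out(instruments, effects_model=effects_model)
    return SensitivityReport(
        q_ivw=q_i,
        q_egger=q_e,
        egger_intercept=intercept,
        loo=loo,
        direction_consistent=consistent,
        alpha=alpha,
    )
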