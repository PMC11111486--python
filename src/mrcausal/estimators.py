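"""The five summary-data MR estimators.

All five methods aggregate per-variant Wald ratios ``beta_out/beta_exp``
under different assumptions about pleiotropy:

* **IVW** — inverse-variance-weighted regression of outcome on exposure
  effects through the origin; unbiased only when every instrument is valid.
  Fixed-effect and multiplicative-random-effect standard errors are both
  computed; the random-effect scale is floored at 1.
* **MR-Egger** — the same regression with a free intercept; the slope is
  consistent under directional pleiotropy provided instrument strength is
  independent of the direct effects (InSIDE), and the intercept estimates the
  average direct effect.
* **Weighted median** — the weighted median of the Wald ratios; consistent
  when at least half the total weight comes from valid instruments.
* **Simple / weighted mode** — the mode of a kernel-smoothed density of the
  Wald ratios; consistent when the largest homogeneous cluster of ratios is
  valid (ZEMPA).

Estimators follow the scikit-learn protocol: construct with hyperparameters,
``fit`` on a harmonized-instrument frame (or raw arrays), read fitted
attributes with trailing underscores.  The module-level functions
(:func:`ivw`, :func:`mr_egger`, ...) are thin wrappers returning
:class:`MREstimate` records.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import BaseEstimator

from .exceptions import (
    CollinearDesignError,
    TooFewInstrumentsError,
    ZeroExposureEffectError,
)

__all__ = [
    "MREstimate",
    "wald_ratios",
    "to_odds_ratio",
    "IVWEstimator",
    "EggerEstimator",
    "WeightedMedianEstimator",
    "ModeEstimator",
    "ivw",
    "mr_egger",
    "weighted_median",
    "mode_estimate",
    "run_all_methods",
    "METHOD_LABELS",
]

#: 97.5% standard-normal quantile used for all 95% intervals
Z_975 = 1.959964

#: canonical report order and labels
METHOD_LABELS = ("MR-Egger", "Weighted median", "IVW", "Simple mode", "Weighted mode")


@dataclass
class MREstimate:
    """One method's causal estimate on the log-odds (slope) scale."""

    method: str
    b: float
    se: float
    or_: float
    ci_low: float
    ci_high: float
    pval: float
    k: int
    extras: dict[str, Any] = field(default_factory=dict)

    def as_row(self) -> dict[str, Any]:
        return {
            "method": self.method,
            "b": self.b,
            "se": self.se,
            "or": self.or_,
            "ci_low": self.ci_low,
            "ci_high": self.ci_high,
            "pval": self.pval,
            "k": self.k,
        }


def to_odds_ratio(b: float, se: float) -> tuple[float, float, float]:
    """Exponentiate a log-odds estimate into an OR with its 95% CI.

    Returns ``(exp(b), exp(b − z·se), exp(b + z·se))`` with z = 1.959964.
    """
    if se < 0:
        raise ValueError("se must be non-negative")
    return float(np.exp(b)), float(np.exp(b - Z_975 * se)), float(np.exp(b + Z_975 * se))


def _extract(X, y=None, se=None, se_exposure=None):
    """Accept a harmonized frame or raw arrays; return (bx, sx, by, sy)."""
    if isinstance(X, pd.DataFrame):
        bx = X["beta_exp"].to_numpy(dtype=float)
        by = X["beta_out"].to_numpy(dtype=float)
        sy = X["se_out"].to_numpy(dtype=float)
        sx = (
            X["se_exp"].to_numpy(dtype=float)
            if "se_exp" in X.columns
            else np.zeros_like(bx)
        )
        return bx, sx, by, sy
    bx = np.asarray(X, dtype=float).ravel()
    if y is None or se is None:
        raise ValueError("array input requires y (outcome betas) and se (outcome SEs)")
    by = np.asarray(y, dtype=float).ravel()
    sy = np.asarray(se, dtype=float).ravel()
    sx = (
        np.zeros_like(bx)
        if se_exposure is None
        else np.asarray(se_exposure, dtype=float).ravel()
    )
    if not (len(bx) == len(by) == len(sy) == len(sx)):
        raise ValueError("beta_exp, beta_out, se arrays must share a length")
    return bx, sx, by, sy


def wald_ratios(instruments: pd.DataFrame | Sequence[float], **kw) -> pd.DataFrame:
    """Per-variant ratio estimates beta_out/beta_exp with first-order SEs.

    The first-order SE ``se_out/|beta_exp|`` ignores exposure-side sampling
    noise, appropriate when instruments are genome-wide significant.
    """
    bx, _, by, sy = _extract(instruments, **kw)
    if np.any(bx == 0):
        raise ZeroExposureEffectError("beta_exp is 0 for at least one instrument")
    out = pd.DataFrame({"wald_ratio": by / bx, "wald_se": sy / np.abs(bx)})
    if isinstance(instruments, pd.DataFrame) and "variant_id" in instruments.columns:
        out.insert(0, "variant_id", instruments["variant_id"].to_numpy())
    return out


class _BaseMREstimator(BaseEstimator):
    """Shared fit plumbing: input handling, OR transform, MREstimate export."""

    method: str = ""
    min_instruments: int = 2

    def fit(self, X, y=None, se=None, se_exposure=None):
        """Fit on a harmonized frame (or arrays beta_exp / beta_out / se_out)."""
        bx, sx, by, sy = _extract(X, y, se, se_exposure)
        k = len(bx)
        if k < self.min_instruments:
            raise TooFewInstrumentsError(self._label(), k, self.min_instruments)
        if np.any(sy <= 0):
            raise ValueError("all outcome SEs must be > 0")
        self.k_ = k
        self._fit(bx, sx, by, sy)
        self.or_, self.ci_low_, self.ci_high_ = (
            to_odds_ratio(self.b_, self.se_)
            if np.isfinite(self.se_)
            else (float(np.exp(self.b_)), float("nan"), float("nan"))
        )
        return self

    def _label(self) -> str:
        return self.method

    def _fit(self, bx, sx, by, sy):  # pragma: no cover - abstract
        raise NotImplementedError

    @property
    def estimate_(self) -> MREstimate:
        return MREstimate(
            method=self._label(),
            b=float(self.b_),
            se=float(self.se_),
            or_=self.or_,
            ci_low=self.ci_low_,
            ci_high=self.ci_high_,
            pval=float(self.pval_),
            k=self.k_,
            extras=dict(getattr(self, "extras_", {})),
        )


def _ivw_fixed(bx, by, sy):
    """Closed-form weighted regression through the origin, weights 1/se_out²."""
    w = 1.0 / sy**2
    sxx = np.sum(w * bx**2)
    if sxx == 0:
        raise ZeroExposureEffectError("all beta_exp are 0")
    b = np.sum(w * bx * by) / sxx
    se_fixed = sxx**-0.5
    q = float(np.sum(w * (by - b * bx) ** 2))
    return float(b), float(se_fixed), q


class IVWEstimator(_BaseMREstimator):
    """Inverse-variance-weighted estimator.

    Parameters
    ----------
    effects_model : {"multiplicative_random", "fixed"}
        With multiplicative random effects the SE is inflated by
        sqrt(max(1, Q/(k−1))); the floor at 1 means the random-effect SE can
        never undercut the fixed-effect one, and the two coincide whenever
        Q <= k−1.

    Attributes
    ----------
    b_, se_, pval_ : slope, SE under the chosen model, two-sided normal p.
    se_fixed_, se_random_, q_ : both SEs and the Cochran heterogeneity
        statistic around the fixed-effect line.
    """

    method = "IVW"
    min_instruments = 2

    def __init__(self, effects_model: str = "multiplicative_random"):
        self.effects_model = effects_model

    def _fit(self, bx, sx, by, sy):
        if self.effects_model not in ("multiplicative_random", "fixed"):
            raise ValueError(f"unknown effects_model {self.effects_model!r}")
        b, se_fixed, q = _ivw_fixed(bx, by, sy)
        scale = max(1.0, q / (self.k_ - 1))
        self.b_ = b
        self.se_fixed_ = se_fixed
        self.se_random_ = se_fixed * np.sqrt(scale)
        self.q_ = q
        self.se_ = self.se_random_ if self.effects_model == "multiplicative_random" else se_fixed
        self.pval_ = float(2 * stats.norm.sf(abs(b) / self.se_)) if self.se_ > 0 else 0.0
        self.extras_ = {
            "effects_model": self.effects_model,
            "q": self.q_,
            "se_fixed": self.se_fixed_,
            "se_random": self.se_random_,
        }


class EggerEstimator(_BaseMREstimator):
    """MR-Egger weighted regression with a free intercept.

    Every instrument is first oriented so beta_exp >= 0 (negating both sides
    where needed; the fit is invariant to that joint sign change).  Slope and
    intercept SEs are inflated by sqrt(max(1, Q_egger/(k−2))); p-values use
    the t distribution with k−2 degrees of freedom.
    """

    method = "MR-Egger"
    min_instruments = 3

    def _fit(self, bx, sx, by, sy):
        sign = np.where(bx < 0, -1.0, 1.0)
        x = bx * sign
        y = by * sign
        w = 1.0 / sy**2
        sw = np.sum(w)
        sx_ = np.sum(w * x)
        sy_ = np.sum(w * y)
        sxx = np.sum(w * x**2)
        sxy = np.sum(w * x * y)
        denom = sw * sxx - sx_**2
        # denom is sw^2 x weighted variance of x: zero iff all oriented
        # beta_exp coincide
        if denom <= 1e-10 * sw * sxx:
            raise CollinearDesignError("all exposure effects equal after orientation")
        slope = (sw * sxy - sx_ * sy_) / denom
        intercept = (sy_ - slope * sx_) / sw
        q = float(np.sum(w * (y - intercept - slope * x) ** 2))
        scale = max(1.0, q / (self.k_ - 2))
        se_slope = np.sqrt(sw / denom * scale)
        se_intercept = np.sqrt(sxx / denom * scale)
        df = self.k_ - 2
        self.b_ = float(slope)
        self.se_ = float(se_slope)
        self.pval_ = float(2 * stats.t.sf(abs(slope) / se_slope, df))
        self.intercept_ = float(intercept)
        self.intercept_se_ = float(se_intercept)
        self.intercept_pval_ = float(2 * stats.t.sf(abs(intercept) / se_intercept, df))
        self.q_ = q
        self.exact_fit_ = q < 1e-12
        self.extras_ = {
            "intercept": self.intercept_,
            "intercept_se": self.intercept_se_,
            "intercept_pval": self.intercept_pval_,
            "q": self.q_,
            "exact_fit": self.exact_fit_,
        }


def weighted_median_point(ratios: np.ndarray, weights: np.ndarray) -> float:
    """Weighted median by linear interpolation of the cumulative weight.

    With normalized weights w'_j over ascending ratios, breakpoints are
    s_j = cum(w')_j − w'_j/2 and the estimate interpolates the ratios at
    s = 1/2.
    """
    order = np.argsort(ratios, kind="mergesort")
    r = np.asarray(ratios, dtype=float)[order]
    w = np.asarray(weights, dtype=float)[order]
    wn = w / w.sum()
    s = np.cumsum(wn) - wn / 2
    return float(np.interp(0.5, s, r))


def _ratio_weights(bx, sy):
    """Inverse-variance weights of the first-order Wald-ratio SEs."""
    return bx**2 / sy**2


def _bootstrap_se(point_fn, bx, sx, by, sy, n_boot: int, rng: np.random.Generator):
    """Parametric bootstrap: resample both sides' betas from normals with
    their SEs, recompute the point estimate, return the SD over replicates."""
    if n_boot <= 0:
        return float("nan")
    est = np.empty(n_boot)
    for i in range(n_boot):
        bxs = rng.normal(bx, sx)
        bys = rng.normal(by, sy)
        est[i] = point_fn(bxs, bys)
    return float(np.std(est, ddof=1))


class WeightedMedianEstimator(_BaseMREstimator):
    """Weighted-median estimator with a parametric-bootstrap SE.

    ``n_boot = 0`` skips the bootstrap (se_, pval_ become NaN), useful in
    simulation loops that only need the point estimate.
    """

    method = "Weighted median"
    min_instruments = 3

    def __init__(self, n_boot: int = 1000, random_state: int | None = None):
        self.n_boot = n_boot
        self.random_state = random_state

    def _fit(self, bx, sx, by, sy):
        if np.any(bx == 0):
            raise ZeroExposureEffectError("beta_exp is 0 for at least one instrument")
        ratios = by / bx
        weights = _ratio_weights(bx, sy)
        self.b_ = weighted_median_point(ratios, weights)

        def point(bxs, bys):
            nz = bxs != 0
            return weighted_median_point(bys[nz] / bxs[nz], _ratio_weights(bxs[nz], sy[nz]))

        rng = np.random.default_rng(self.random_state)
        self.se_ = _bootstrap_se(point, bx, sx, by, sy, self.n_boot, rng)
        self.pval_ = (
            float(2 * stats.norm.sf(abs(self.b_) / self.se_))
            if np.isfinite(self.se_) and self.se_ > 0
            else float("nan")
        )
        self.extras_ = {"n_boot": self.n_boot, "seed": self.random_state}


def _mode_point(ratios: np.ndarray, weights: np.ndarray, phi: float) -> float:
    """Argmax of a weighted normal-kernel density over the Wald ratios.

    Bandwidth h = phi·0.9·min(SD, MAD/0.6745)·k^(−1/5); if that is zero the
    fallback is phi·(range/100), and if the range is also zero all ratios
    coincide and the mode is that value.  The density is evaluated on a
    512-point uniform grid over [min−3h, max+3h]; ties resolve to the
    smallest grid value.
    """
    r = np.asarray(ratios, dtype=float)
    k = len(r)
    lo, hi = r.min(), r.max()
    if lo == hi:
        return float(lo)
    sd = np.std(r, ddof=1)
    mad = np.median(np.abs(r - np.median(r)))
    h = phi * 0.9 * min(sd, mad / 0.6745) * k ** (-0.2)
    if h <= 0:
        h = phi * (hi - lo) / 100.0
    grid = np.linspace(lo - 3 * h, hi + 3 * h, 512)
    wn = np.asarray(weights, dtype=float)
    wn = wn / wn.sum()
    dens = (wn[None, :] * np.exp(-0.5 * ((grid[:, None] - r[None, :]) / h) ** 2)).sum(axis=1)
    return float(grid[int(np.argmax(dens))])


class ModeEstimator(_BaseMREstimator):
    """Mode-based estimator (simple or inverse-variance weighted).

    Parameters
    ----------
    weighted : bool
        Weighted mode uses normalized inverse-variance weights of the Wald
        ratios; simple mode uses uniform weights.
    phi : float
        Bandwidth multiplier on the Silverman-type rule.
    """

    min_instruments = 3

    def __init__(
        self,
        weighted: bool = True,
        phi: float = 1.0,
        n_boot: int = 1000,
        random_state: int | None = None,
    ):
        self.weighted = weighted
        self.phi = phi
        self.n_boot = n_boot
        self.random_state = random_state

    def _label(self) -> str:
        return "Weighted mode" if self.weighted else "Simple mode"

    def _fit(self, bx, sx, by, sy):
        if np.any(bx == 0):
            raise ZeroExposureEffectError("beta_exp is 0 for at least one instrument")
        ratios = by / bx

        def weights_of(bxs, sys_):
            return _ratio_weights(bxs, sys_) if self.weighted else np.ones(len(bxs))

        self.b_ = _mode_point(ratios, weights_of(bx, sy), self.phi)

        def point(bxs, bys):
            nz = bxs != 0
            return _mode_point(bys[nz] / bxs[nz], weights_of(bxs[nz], sy[nz]), self.phi)

        rng = np.random.default_rng(self.random_state)
        self.se_ = _bootstrap_se(point, bx, sx, by, sy, self.n_boot, rng)
        self.pval_ = (
            float(2 * stats.norm.sf(abs(self.b_) / self.se_))
            if np.isfinite(self.se_) and self.se_ > 0
            else float("nan")
        )
        self.extras_ = {
            "n_boot": self.n_boot,
            "seed": self.random_state,
            "phi": self.phi,
        }


# ---------------------------------------------------------------------------
# functional wrappers


def ivw(instruments, effects_model: str = "multiplicative_random", **kw) -> MREstimate:
    return IVWEstimator(effects_model=effects_model).fit(instruments, **kw).estimate_


def mr_egger(instruments, **kw) -> MREstimate:
    return EggerEstimator().fit(instruments, **kw).estimate_


def weighted_median(instruments, n_boot: int = 1000, seed: int | None = None, **kw) -> MREstimate:
    return WeightedMedianEstimator(n_boot=n_boot, random_state=seed).fit(instruments, **kw).estimate_


def mode_estimate(
    instruments,
    weighted: bool = True,
    phi: float = 1.0,
    n_boot: int = 1000,
    seed: int | None = None,
    **kw,
) -> MREstimate:
    est = ModeEstimator(weighted=weighted, phi=phi, n_boot=n_boot, random_state=seed)
    return est.fit(instruments, **kw).estimate_


def run_all_methods(
    instruments,
    n_boot: int = 1000,
    phi: float = 1.0,
    seed: int | None = None,
    effects_model: str = "multiplicative_random",
) -> list[MREstimate]:
    """Run all five methods, threading one seed across the three bootstraps.

    Results are returned in the canonical report order: MR-Egger, Weighted
    median, IVW, Simple mode, Weighted mode.  Estimator errors propagate
    annotated with the failing method.
    """
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(3)]
    jobs = [
        ("MR-Egger", lambda: mr_egger(instruments)),
        ("Weighted median", lambda: weighted_median(instruments, n_boot=n_boot, seed=seeds[0])),
        ("IVW", lambda: ivw(instruments, effects_model=effects_model)),
        (
            "Simple mode",
            lambda: mode_estimate(instruments, weighted=False, phi=phi, n_boot=n_boot, seed=seeds[1]),
        ),
        (
            "Weighted mode",
            lambda: mode_estimate(instruments, weighted=True, phi=phi, n_boot=n_boot, seed=seeds[2]),
        ),
    ]
    results = []
    for label, job in jobs:
        try:
            results.append(job())
        except Exception as exc:
            exc.args = (f"{label}: {exc}",) + exc.args[1:]
            raise
    return results
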