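"""Biphasic time-kill analysis: persister fraction, kill rates and MDK99.

Bactericidal killing of a population harbouring persisters follows a
two-compartment biexponential,

    S(t) = (1 - f) exp(-k_s t) + f exp(-k_p t),

with susceptible kill rate ``k_s``, persister kill rate ``k_p`` (< k_s) and
persister fraction ``f`` — the surviving plateau of the biphasic curve. The
model is fitted in log10-survival space (kill curves span many decades, so
equal weight per timepoint is only sensible on the log scale) with
multi-start least squares; points below the plating detection limit enter as
one-sided (censored) residuals rather than being dropped.

Tolerance is quantified by the MDK99 (minimum duration for killing of 99% of
the population) computed after persister subtraction: persisters are removed
from the survival function and the MDK99 is read off the logarithmic killing
phase of the remainder.
"""

from __future__ import annotations

import io
import math
from dataclasses import dataclass, field
from typing import Literal, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "KillCurve",
    "BiphasicKillModel",
    "BiphasicKillResults",
    "fit_biphasic",
    "persister_fraction",
    "mdk99",
    "compare_conditions",
    "ComparisonResult",
    "read_kill_curves",
    "write_kill_curves",
]

LN100 = math.log(100.0)


@dataclass
class KillCurve:
    """Replicate survival trajectory: CFU/ml over time under antibiotic.

    ``below_detection`` marks timepoints at the plating detection limit; those
    ``cfu`` entries carry the limit itself, never zero.
    """

    condition: str
    replicate: int
    time_h: np.ndarray
    cfu: np.ndarray
    below_detection: np.ndarray | None = None
    detection_limit: float = 10.0
    mic_multiple: float | None = None

    def __post_init__(self) -> None:
        self.time_h = np.asarray(self.time_h, float)
        self.cfu = np.asarray(self.cfu, float)
        if self.below_detection is None:
            self.below_detection = np.zeros(self.time_h.size, dtype=bool)
        else:
            self.below_detection = np.asarray(self.below_detection, bool)
        if self.time_h.size != self.cfu.size:
            raise ValueError("time and cfu must have equal length")
        if np.any(self.time_h < 0):
            raise ValueError("timepoints must be non-negative")
        if not np.any(self.time_h == 0):
            raise ValueError("a t=0 timepoint is required for survival normalization")
        if np.any(np.diff(self.time_h) <= 0):
            raise ValueError("timepoints must be strictly ascending")
        if np.any(self.cfu < 0):
            raise ValueError("CFU counts must be non-negative")
        if np.any(self.cfu[self.below_detection] == 0):
            raise ValueError("below-detection entries must carry the limit, not 0")

    @property
    def survival(self) -> np.ndarray:
        return self.cfu / self.cfu[self.time_h == 0][0]


def biexponential_survival(t, f, k_s, k_p):
    """Closed-form two-compartment survival S(t)."""
    t = np.asarray(t, float)
    return (1.0 - f) * np.exp(-k_s * t) + f * np.exp(-k_p * t)


# ---------------------------------------------------------------------------
# model / results


class BiphasicKillModel:
    """Two-compartment killing model for one replicate kill curve.

    Parameters are estimated by least squares on log10 survival with
    deterministic multi-start initialization over the persister fraction
    (8 starts spanning f = 1e-4 .. 1e-1; ties broken by RSS, then by smaller
    f). A single-exponential fit is compared by AIC; when the two-compartment
    model is not supported the fit is reported as non-biphasic with f pinned
    at the boundary.
    """

    N_STARTS = 8

    def __init__(self, curve: KillCurve):
        self.curve = curve
        quant = ~curve.below_detection
        if int(quant.sum()) < 4:
            raise ValueError("need >= 4 quantified timepoints to fit")
        if curve.time_h[quant].max() <= 1.0:
            raise ValueError("need at least one quantified timepoint past 1 h")

    @classmethod
    def from_curve(cls, curve: KillCurve) -> "BiphasicKillModel":
        return cls(curve)

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, condition: str | None = None,
                       replicate: int | None = None,
                       detection_limit: float = 10.0) -> "BiphasicKillModel":
        """Build from a tidy frame with columns time_h, cfu_per_ml
        [, below_detection]."""
        sub = df
        if condition is not None:
            sub = sub[sub["condition"] == condition]
        if replicate is not None:
            sub = sub[sub["replicate"] == replicate]
        bd = sub["below_detection"].to_numpy(bool) if "below_detection" in sub else None
        return cls(KillCurve(
            condition=condition or str(sub.get("condition", pd.Series(["?"])).iloc[0]),
            replicate=int(replicate or sub.get("replicate", pd.Series([1])).iloc[0]),
            time_h=sub["time_h"].to_numpy(float),
            cfu=sub["cfu_per_ml"].to_numpy(float),
            below_detection=bd,
            detection_limit=detection_limit,
        ))

    # residuals in log10-survival space; censored points one-sided
    def _residuals(self, theta: np.ndarray) -> np.ndarray:
        f, k_s, k_p = _untransform(theta)
        c = self.curve
        s_obs = c.survival
        s_mod = biexponential_survival(c.time_h, f, k_s, k_p)
        s_mod = np.maximum(s_mod, 1e-300)
        res = np.log10(s_obs) - np.log10(s_mod)
        cens = c.below_detection
        if cens.any():
            # model above the limit is penalized; at/below the limit is fine
            limit = c.detection_limit / c.cfu[c.time_h == 0][0]
            res = res.copy()
            res[cens] = np.maximum(np.log10(s_mod[cens]) - np.log10(limit), 0.0)
        return res

    def _fit_single_exponential(self) -> tuple[float, float]:
        c = self.curve
        quant = ~c.below_detection
        t, s = c.time_h[quant], c.survival[quant]

        def res(ln_k):
            return np.log10(np.maximum(np.exp(-np.exp(ln_k[0]) * t), 1e-300)) - np.log10(s)

        mask = (t > 0) & (s < 1)
        k0 = np.median(-np.log(s[mask]) / t[mask]) if mask.any() else 1.0
        sol = optimize.least_squares(lambda th: res(th), x0=[np.log(max(k0, 1e-6))])
        rss = float(np.sum(self._single_residuals(np.exp(sol.x[0])) ** 2))
        return float(np.exp(sol.x[0])), rss

    def _single_residuals(self, k: float) -> np.ndarray:
        c = self.curve
        s_mod = np.maximum(np.exp(-k * c.time_h), 1e-300)
        res = np.log10(c.survival) - np.log10(s_mod)
        cens = c.below_detection
        if cens.any():
            limit = c.detection_limit / c.cfu[c.time_h == 0][0]
            res = res.copy()
            res[cens] = np.maximum(np.log10(s_mod[cens]) - np.log10(limit), 0.0)
        return res

    def fit(self) -> "BiphasicKillResults":
        c = self.curve
        warnings: list[str] = []
        s = c.survival
        if np.any(s[c.time_h > 0] > 1.0):
            warnings.append("survival above 1 at a positive timepoint")
        if np.any(np.diff(np.log(np.maximum(s, 1e-300))) > 1.0):
            warnings.append("grossly non-monotone survival")

        # deterministic multi-start over the persister plateau
        f_starts = np.logspace(-4, -1, self.N_STARTS)
        quant = ~c.below_detection
        t_q, s_q = c.time_h[quant], s[quant]
        early = (t_q > 0) & (t_q <= np.quantile(t_q[t_q > 0], 0.5))
        k_s0 = float(np.clip(np.median(-np.log(np.maximum(s_q[early], 1e-300)) / t_q[early]),
                             1e-2, 50.0)) if early.any() else 2.0
        best = None
        for f0 in f_starts:
            theta0 = _transform(f0, k_s0, 0.02)
            sol = optimize.least_squares(self._residuals, x0=theta0,
                                         xtol=1e-12, ftol=1e-12, gtol=1e-12,
                                         max_nfev=2000)
            rss = float(np.sum(sol.fun ** 2))
            cand = (rss, _untransform(sol.x)[0], sol)
            if best is None or cand[:2] < best[:2]:
                best = cand
        rss_bi, _, sol = best
        f, k_s, k_p = _untransform(sol.x)
        if k_p > k_s:  # compartments swapped: relabel
            f, k_s, k_p = 1.0 - f, k_p, k_s

        n = c.time_h.size
        k_single, rss_single = self._fit_single_exponential()
        aic_bi = n * math.log(max(rss_bi, 1e-300) / n) + 2 * 3
        aic_single = n * math.log(max(rss_single, 1e-300) / n) + 2 * 1
        biphasic = aic_bi < aic_single
        if not biphasic:
            f, k_s, k_p = 0.0, k_single, 0.0
            rss = rss_single
        else:
            rss = rss_bi

        cov = _covariance(sol, rss_bi, n) if biphasic else None
        return BiphasicKillResults(
            model=self,
            f=float(f), k_s=float(k_s), k_p=float(k_p),
            N0=float(c.cfu[c.time_h == 0][0]),
            rss=float(rss), converged=bool(sol.status > 0 or not biphasic),
            biphasic=bool(biphasic),
            aic=float(aic_bi if biphasic else aic_single),
            cov_params=cov, warnings=warnings,
        )


def _transform(f, k_s, k_p):
    return np.array([math.log(f / (1 - f)), math.log(k_s), math.log(max(k_p, 1e-8))])


def _untransform(theta):
    f = 1.0 / (1.0 + math.exp(-float(theta[0])))
    return f, float(np.exp(theta[1])), float(np.exp(theta[2]))


def _covariance(sol, rss, n) -> np.ndarray | None:
    try:
        jtj = sol.jac.T @ sol.jac
        dof = max(n - 3, 1)
        return np.linalg.pinv(jtj) * (rss / dof)
    except Exception:
        return None


@dataclass
class BiphasicKillResults:
    """Fitted two-compartment killing parameters and diagnostics."""

    model: BiphasicKillModel
    f: float
    k_s: float
    k_p: float
    N0: float
    rss: float
    converged: bool
    biphasic: bool
    aic: float
    cov_params: np.ndarray | None = None
    warnings: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.biphasic and not (0.0 < self.f < 1.0):
            raise ValueError("fitted persister fraction outside (0, 1)")
        if self.biphasic and not (0.0 <= self.k_p < self.k_s):
            raise ValueError("fitted rates violate 0 <= k_p < k_s")

    @property
    def bse(self) -> dict[str, float]:
        """Approximate standard errors in the transformed (logit f, log k)
        coordinates, mapped back by the delta method."""
        if self.cov_params is None:
            return {}
        se = np.sqrt(np.diag(self.cov_params))
        return {
            "f": float(se[0] * self.f * (1 - self.f)),
            "k_s": float(se[1] * self.k_s),
            "k_p": float(se[2] * self.k_p),
        }

    def predict(self, t) -> np.ndarray:
        if not self.biphasic:
            return np.exp(-self.k_s * np.asarray(t, float))
        return biexponential_survival(t, self.f, self.k_s, self.k_p)

    @property
    def mdk99(self) -> float:
        return mdk99(self)

    def persister_fraction(self, method: Literal["plateau", "endpoint"] = "plateau",
                           endpoint_h: float = 5.0) -> float:
        return persister_fraction_from_fit(self, method, endpoint_h)

    def summary(self) -> str:
        c = self.model.curve
        se = self.bse
        lines = [
            "Biphasic kill-curve fit",
            "=" * 45,
            f"condition:   {c.condition}   replicate: {c.replicate}",
            f"status:      {'biphasic' if self.biphasic else 'non-biphasic (single exponential)'}",
            f"f (plateau): {self.f:.4g}" + (f"  (se {se['f']:.2g})" if se else ""),
            f"k_s:         {self.k_s:.4g} /h" + (f"  (se {se['k_s']:.2g})" if se else ""),
            f"k_p:         {self.k_p:.4g} /h" + (f"  (se {se['k_p']:.2g})" if se else ""),
            f"N0:          {self.N0:.4g} CFU/ml",
            f"MDK99:       {self.mdk99:.4g} h (persister-subtracted)",
            f"RSS(log10):  {self.rss:.4g}   AIC: {self.aic:.4g}",
        ]
        if self.warnings:
            lines += [f"warning:     {w}" for w in self.warnings]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# functional surface


def fit_biphasic(curve: KillCurve) -> BiphasicKillResults:
    """Fit the two-compartment killing model to one replicate curve."""
    if curve.below_detection.all():
        raise ValueError("all points below detection: curve cannot be fitted")
    return BiphasicKillModel(curve).fit()


def persister_fraction_from_fit(fit: BiphasicKillResults,
                                method: Literal["plateau", "endpoint"] = "plateau",
                                endpoint_h: float = 5.0) -> float:
    if method == "plateau":
        return fit.f
    return float(fit.predict(endpoint_h))


def persister_fraction(curve: KillCurve,
                       method: Literal["plateau", "endpoint"] = "plateau",
                       endpoint_h: float = 5.0) -> float:
    """Persister level of a kill curve.

    ``plateau`` returns the fitted biexponential plateau f; ``endpoint``
    returns observed survival at ``endpoint_h`` (default 5 h, the usual
    survivor-counting endpoint), log-interpolating between bracketing
    timepoints when the endpoint itself was not sampled.
    """
    if method == "plateau":
        return fit_biphasic(curve).f
    if method != "endpoint":
        raise ValueError("method must be 'plateau' or 'endpoint'")
    t, s = curve.time_h, curve.survival
    exact = np.isclose(t, endpoint_h)
    if exact.any():
        return float(s[exact][0])
    if t.min() < endpoint_h < t.max():
        return float(10 ** np.interp(endpoint_h, t, np.log10(np.maximum(s, 1e-300))))
    raise ValueError(f"endpoint {endpoint_h} h not bracketed by curve timepoints")


def mdk99(fit: BiphasicKillResults) -> float:
    """MDK99 with persister subtraction.

    The persister compartment is removed from the fitted survival,
    S_adj(t) = (S(t) - f exp(-k_p t)) / (1 - f), and the MDK99 is the time at
    which S_adj = 0.01 — the logarithmic killing phase of the susceptible
    compartment (closed form ln(100)/k_s when k_p = 0, solved numerically on
    S_adj otherwise).
    """
    if not fit.converged:
        raise ValueError("MDK99 requires a converged fit")
    if not fit.biphasic or fit.k_p == 0.0:
        return LN100 / fit.k_s

    f, k_s, k_p = fit.f, fit.k_s, fit.k_p

    def s_adj(t):
        return (biexponential_survival(t, f, k_s, k_p) - f * np.exp(-k_p * t)) / (1 - f)

    t_hi = LN100 / k_s * 4 + 1.0
    return float(optimize.brentq(lambda t: s_adj(t) - 0.01, 0.0, t_hi,
                                 xtol=1e-12, rtol=1e-14))


@dataclass
class ComparisonResult:
    metric: str
    fold_change: float
    p_value: float | None
    n_a: int
    n_b: int
    warnings: list[str] = field(default_factory=list)


def compare_conditions(fits_a: Sequence[BiphasicKillResults],
                       fits_b: Sequence[BiphasicKillResults],
                       metric: Literal["f", "mdk99", "endpoint"] = "f",
                       endpoint_h: float = 5.0) -> ComparisonResult:
    """Fold change (A relative to B) and unpaired two-tailed t-test.

    Fractions are compared on the log scale (geometric-mean fold change);
    MDK99 on the linear scale (arithmetic means).
    """
    warnings = []
    if min(len(fits_a), len(fits_b)) < 3:
        warnings.append("fewer than 3 replicates in a group")

    def values(fits):
        if metric == "f":
            return np.array([r.f for r in fits])
        if metric == "mdk99":
            return np.array([r.mdk99 for r in fits])
        if metric == "endpoint":
            return np.array([r.predict(endpoint_h) for r in fits])
        raise ValueError("metric must be f, mdk99 or endpoint")

    a, b = values(fits_a), values(fits_b)
    if metric in ("f", "endpoint"):
        la, lb = np.log(a), np.log(b)
        fold = float(np.exp(la.mean() - lb.mean()))
        xa, xb = la, lb
    else:
        fold = float(a.mean() / b.mean())
        xa, xb = a, b
    if np.std(xa) == 0 and np.std(xb) == 0:
        p = None if not np.isclose(xa.mean(), xb.mean()) else None
        warnings.append("zero variance in both groups: exact tie, no p-value")
        return ComparisonResult(metric, fold, p, len(a), len(b), warnings)
    p = float(stats.ttest_ind(xa, xb, equal_var=True).pvalue)
    return ComparisonResult(metric, fold, p, len(a), len(b), warnings)


# ---------------------------------------------------------------------------
# CSV I/O (documented schema: condition, replicate [1-based], time_h,
# cfu_per_ml, below_detection, detection_limit)


def write_kill_curves(curves: Sequence[KillCurve], path, seed: int | None = None,
                      scenario: str | None = None) -> None:
    rows = []
    for c in curves:
        for i in range(c.time_h.size):
            rows.append({
                "condition": c.condition, "replicate": c.replicate,
                "time_h": c.time_h[i], "cfu_per_ml": c.cfu[i],
                "below_detection": bool(c.below_detection[i]),
                "detection_limit": c.detection_limit,
            })
    df = pd.DataFrame(rows)
    header = f"# persisterkit kill curves; scenario={scenario}; seed={seed}\n"
    buf = io.StringIO()
    df.to_csv(buf, index=False)
    with open(path, "w") as fh:
        fh.write(header)
        fh.write(buf.getvalue())


def read_kill_curves(path) -> list[KillCurve]:
    df = pd.read_csv(path, comment="#")
    curves = []
    for (cond, rep), grp in df.groupby(["condition", "replicate"], sort=True):
        grp = grp.sort_values("time_h")
        curves.append(KillCurve(
            condition=str(cond), replicate=int(rep),
            time_h=grp["time_h"].to_numpy(float),
            cfu=grp["cfu_per_ml"].to_numpy(float),
            below_detection=grp["below_detection"].to_numpy(bool)
            if "below_detection" in grp else None,
            detection_limit=float(grp["detection_limit"].iloc[0])
            if "detection_limit" in grp else 10.0,
        ))
    return curves
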