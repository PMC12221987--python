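"""Condition-sweep statistics uncoupling persistence from tolerance.

For a set of growth conditions (e.g. carbon sources), each replicate yields a
row of population summaries: growth rate, tolerance (MDK99 after persister
subtraction), persistence (5-h survivors and fitted plateau), the gated
low-GTP fraction and the mean reporter fluorescence. Pairwise Pearson
correlations over replicate rows then test which population properties move
together: slower growth tracks tolerance, while persistence tracks the
low-GTP outlier fraction and not the bulk growth rate.

Persistence (and the low-GTP fraction) span decades across conditions and are
correlated on the log10 scale; growth rate, tolerance and mean fluorescence
on the linear scale.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats

from . import generators
from .cytometry import gate_low_gtp, subtract_autofluorescence
from .killcurve import fit_biphasic, persister_fraction
from .scenarios import ScenarioSpec, scenario_set

__all__ = [
    "build_condition_summary",
    "pearson",
    "UncouplingReport",
    "uncoupling_report",
]

_GROWTH_REP_CV = 0.05   # replicate-level scatter on the bulk growth rate


def build_condition_summary(
    scenarios: Sequence[ScenarioSpec] | str = "carbon_sources",
    n_reps: int = 3,
    seed: int = 0,
    n_events: int = 100_000,
    gate_fold: float = 5.0,
) -> pd.DataFrame:
    """One summary row per scenario x replicate.

    Each replicate runs the kill-curve generator through the biphasic fit
    (tolerance, persistence) and the cytometry generator through gating
    (low-GTP fraction, mean reporter fluorescence). Fit failures propagate as
    missing cells rather than aborting the sweep.
    """
    if isinstance(scenarios, str):
        scenarios = scenario_set(scenarios)
    root = np.random.SeedSequence(seed)
    rows = []
    for i, scen in enumerate(scenarios):
        for rep in range(n_reps):
            sub = np.random.SeedSequence(entropy=root.entropy,
                                          spawn_key=(i, rep))
            s_kill, s_cyto, s_misc = [int(s.generate_state(1)[0] % 2**31)
                                      for s in sub.spawn(3)]
            row = {"scenario": scen.name, "replicate": rep + 1}
            rng = np.random.default_rng(s_misc)
            row["growth_rate_per_h"] = scen.growth_rate_per_h * rng.lognormal(
                -0.5 * _GROWTH_REP_CV**2, _GROWTH_REP_CV)
            try:
                curve = generators.generate_kill_curve(scen, n_reps=1, seed=s_kill)[0]
                fit = fit_biphasic(curve)
                row["mdk99_h"] = fit.mdk99
                row["persistence_plateau"] = fit.f
                row["persistence_endpoint"] = persister_fraction(curve, "endpoint")
            except (ValueError, RuntimeError):
                row["mdk99_h"] = row["persistence_plateau"] = np.nan
                row["persistence_endpoint"] = np.nan
            try:
                sample, ctrl = generators.generate_cytometry(scen, n_events, seed=s_cyto)
                corrected = subtract_autofluorescence(sample, ctrl)
                gate = gate_low_gtp(corrected, fold=gate_fold)
                row["low_gtp_fraction"] = gate.fraction
                row["mean_fluor_au"] = gate.mean_au
            except (ValueError, RuntimeError):
                row["low_gtp_fraction"] = row["mean_fluor_au"] = np.nan
            rows.append(row)
    return pd.DataFrame(rows)


def pearson(x, y, log: bool = False) -> tuple[float, float]:
    """Pearson r with two-tailed t-distributed p-value.

    ``log=True`` correlates log10 of the values (for fractions spanning
    decades). Zero variance in either variable yields (nan, nan).
    """
    x = np.asarray(x, float)
    y = np.asarray(y, float)
    keep = np.isfinite(x) & np.isfinite(y)
    x, y = x[keep], y[keep]
    if x.size < 3:
        raise ValueError("Pearson correlation needs >= 3 paired values")
    if log:
        if np.any(x <= 0) or np.any(y <= 0):
            raise ValueError("log-scale correlation requires positive values")
        x, y = np.log10(x), np.log10(y)
    if np.std(x) == 0 or np.std(y) == 0:
        return float("nan"), float("nan")
    r, p = stats.pearsonr(x, y)
    return float(r), float(p)


# the six pairwise panels of the condition sweep: (x, y, x on log10, y on log10);
# fractions span decades and are correlated on the log scale
_PAIRS = [
    ("growth_rate_per_h", "mdk99_h", False, False),
    ("low_gtp_fraction", "mdk99_h", True, False),
    ("growth_rate_per_h", "low_gtp_fraction", False, True),
    ("growth_rate_per_h", "persistence_endpoint", False, True),
    ("low_gtp_fraction", "persistence_endpoint", True, True),
    ("growth_rate_per_h", "mean_fluor_au", False, False),
]


@dataclass
class UncouplingReport:
    correlations: pd.DataFrame
    alpha: float

    @property
    def verdicts(self) -> dict[str, bool]:
        """Headline significance verdicts of the sweep."""
        c = self.correlations.set_index(["x", "y"])

        def sig(x, y):
            return bool(c.loc[(x, y), "p"] < self.alpha)

        return {
            "growth_tolerance": sig("growth_rate_per_h", "mdk99_h"),
            "growth_persistence": sig("growth_rate_per_h", "persistence_endpoint"),
            "lowgtp_persistence": sig("low_gtp_fraction", "persistence_endpoint"),
            "lowgtp_tolerance": sig("low_gtp_fraction", "mdk99_h"),
        }

    def to_markdown(self) -> str:
        lines = ["| x | y | scale | r | p | significant |",
                 "|---|---|-------|---|---|-------------|"]
        for _, row in self.correlations.iterrows():
            lines.append(
                f"| {row.x} | {row.y} | {'log' if row.log else 'linear'} "
                f"| {row.r:+.3f} | {row.p:.3g} | {'yes' if row.p < self.alpha else 'no'} |")
        v = self.verdicts
        lines += [
            "",
            f"- growth rate ~ tolerance: {'significant' if v['growth_tolerance'] else 'not significant'}",
            f"- growth rate ~ persistence: {'significant' if v['growth_persistence'] else 'not significant'}",
            f"- low-GTP fraction ~ persistence: {'significant' if v['lowgtp_persistence'] else 'not significant'}",
            f"- low-GTP fraction ~ tolerance: {'significant' if v['lowgtp_tolerance'] else 'not significant'}",
        ]
        return "\n".join(lines)


def uncoupling_report(summary: pd.DataFrame, alpha: float = 0.05) -> UncouplingReport:
    """Pairwise correlation matrix of the sweep plus significance verdicts.

    Requires at least 4 conditions with >= 3 replicates each.
    """
    n_cond = summary["scenario"].nunique()
    min_reps = summary.groupby("scenario").size().min()
    if n_cond < 4 or min_reps < 3:
        raise ValueError(
            f"uncoupling report needs >= 4 conditions x >= 3 replicates "
            f"(got {n_cond} conditions, min {min_reps} replicates)")
    rows = []
    for x, y, xlog, ylog in _PAIRS:
        xv = summary[x].to_numpy(float)
        yv = summary[y].to_numpy(float)
        with np.errstate(divide="ignore", invalid="ignore"):
            if xlog:
                xv = np.where(xv > 0, np.log10(np.maximum(xv, 1e-300)), np.nan)
            if ylog:
                yv = np.where(yv > 0, np.log10(np.maximum(yv, 1e-300)), np.nan)
        r, p = pearson(xv, yv)
        rows.append({"x": x, "y": y, "log": xlog or ylog, "r": r, "p": p})
    return UncouplingReport(correlations=pd.DataFrame(rows), alpha=alpha)
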