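"""Flow-cytometry analysis: autofluorescence subtraction, low-GTP gating,
induced fractions and the in-silico sort-and-kill experiment.

The low-GTP reporter is bright in GTP-depleted cells; the bright subpopulation
is gated at five-fold (configurable) or higher above the mean population
fluorescence after autofluorescence subtraction. Latent dormancy labels exist
only on synthetic event tables and are never consulted by gating — they feed
only the sort-and-kill emulation, where survival of sorted fractions is
computed by two-rate killing of dormant vs susceptible events.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

__all__ = [
    "EventTable",
    "GateResult",
    "SortAndKillResult",
    "subtract_autofluorescence",
    "gate_low_gtp",
    "induced_fraction",
    "sort_and_kill",
    "read_event_table",
    "write_event_table",
]


@dataclass
class EventTable:
    """Per-event fluorescence with optional latent labels and scatter proxy."""

    sample_id: str
    fluorescence: np.ndarray
    is_control: bool = False
    dormant: np.ndarray | None = None   # latent, synthetic provenance only
    scatter: np.ndarray | None = None
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.fluorescence = np.asarray(self.fluorescence, float)
        if self.fluorescence.size == 0:
            raise ValueError("empty event table")
        if not np.all(np.isfinite(self.fluorescence)):
            raise ValueError("non-finite fluorescence values")
        if self.dormant is not None:
            self.dormant = np.asarray(self.dormant, bool)
            if self.dormant.size != self.fluorescence.size:
                raise ValueError("dormant labels must match event count")

    @property
    def n_events(self) -> int:
        return int(self.fluorescence.size)

    def size_gated(self, low_q: float = 0.05, high_q: float = 0.95) -> "EventTable":
        """Pass-through size gate on the scatter proxy (keeps a central
        quantile band of 'cell sizes'); identity when no scatter recorded."""
        if self.scatter is None:
            return self
        lo, hi = np.quantile(self.scatter, [low_q, high_q])
        keep = (self.scatter >= lo) & (self.scatter <= hi)
        return EventTable(
            sample_id=self.sample_id,
            fluorescence=self.fluorescence[keep],
            is_control=self.is_control,
            dormant=None if self.dormant is None else self.dormant[keep],
            scatter=self.scatter[keep],
            meta={**self.meta, "size_gate": (low_q, high_q)},
        )


@dataclass
class GateResult:
    threshold_au: float
    fraction: float
    gated_index: np.ndarray
    mean_au: float            # mean population fluorescence after subtraction
    fold: float
    n_events: int

    def __post_init__(self) -> None:
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("gated fraction outside [0, 1]")


def subtract_autofluorescence(sample: EventTable, control: EventTable) -> EventTable:
    """Subtract the control (autofluorescence) mean from every event.

    Negative corrected values are clamped to zero; the clamp count is kept in
    ``meta['n_clamped']``. A control brighter than the sample mean is allowed
    but flagged loudly in ``meta['warnings']``.
    """
    if control.n_events == 0:
        raise ValueError("control table is empty")
    bg = float(control.fluorescence.mean())
    corrected = sample.fluorescence - bg
    n_clamped = int((corrected < 0).sum())
    corrected = np.maximum(corrected, 0.0)
    warnings = []
    if bg > sample.fluorescence.mean():
        warnings.append(
            f"control mean ({bg:.3g} AU) exceeds sample mean "
            f"({sample.fluorescence.mean():.3g} AU): corrected signal mostly clamped"
        )
    return EventTable(
        sample_id=sample.sample_id,
        fluorescence=corrected,
        is_control=False,
        dormant=sample.dormant,
        scatter=sample.scatter,
        meta={**sample.meta, "background_au": bg, "n_clamped": n_clamped,
              "warnings": warnings},
    )


def gate_low_gtp(corrected: EventTable, fold: float = 5.0,
                 threshold_au: float | None = None) -> GateResult:
    """Gate bright (low-GTP) events at ``fold`` x mean population fluorescence.

    The default five-fold rule is applied to control-subtracted fluorescence.
    An explicit ``threshold_au`` overrides the rule (the override is recorded
    in the result via the ``fold`` field set to NaN).
    """
    fl = corrected.fluorescence
    mean = float(fl.mean())
    if threshold_au is None:
        threshold_au = fold * mean
    else:
        fold = float("nan")
    gated = np.flatnonzero(fl >= threshold_au) if threshold_au > 0 else np.arange(fl.size)
    # a zero threshold (all-zero signal) gates nothing, not everything
    if threshold_au <= 0:
        gated = np.array([], dtype=int)
    return GateResult(
        threshold_au=float(threshold_au),
        fraction=float(gated.size / fl.size),
        gated_index=gated,
        mean_au=mean,
        fold=float(fold),
        n_events=fl.size,
    )


def induced_fraction(before: GateResult, after: GateResult) -> tuple[float, bool]:
    """Induced low-GTP fraction: gated fraction after minus before induction.

    Returns (difference floored at 0, negative_flag). Gating configurations
    must match (same fold rule) — a mismatch is a usage error.
    """
    both_overridden = math.isnan(before.fold) and math.isnan(after.fold)
    if not both_overridden and before.fold != after.fold:
        raise ValueError("mismatched gating rules between samples")
    diff = after.fraction - before.fraction
    return max(diff, 0.0), diff < 0


@dataclass
class SortAndKillResult:
    top_fraction: float
    duration_h: float
    bright_survival: float
    dim_survival: float
    n_bright: int
    n_dim: int
    bright_dormant_purity: float
    warnings: list[str] = field(default_factory=list)


def sort_and_kill(events: EventTable, top_fraction: float = 0.001,
                  k_s: float = 4.6, k_p: float = 0.0446,
                  duration_h: float = 5.0,
                  seed: int | None = None) -> SortAndKillResult:
    """Emulate FACS sorting of the brightest events followed by killing.

    Events are partitioned into the top ``top_fraction`` by fluorescence and
    the remainder; each event then survives the ``duration_h`` antibiotic
    challenge with probability exp(-k_p t) if latently dormant and
    exp(-k_s t) otherwise (colony formation drawn binomially). Returns
    colony-forming survival per sorted fraction.
    """
    if events.dormant is None:
        raise ValueError("sort_and_kill requires latent dormancy labels (synthetic data)")
    if not (0.0 < top_fraction <= 1.0):
        raise ValueError("top_fraction must lie in (0, 1]")
    fl = events.fluorescence
    n = fl.size
    n_top = max(int(round(top_fraction * n)), 1)
    warnings = []
    if n_top < 100:
        warnings.append(f"only {n_top} sorted events: counting noise will dominate")
    order = np.argsort(fl, kind="stable")
    top_idx = order[-n_top:]
    bright = np.zeros(n, dtype=bool)
    bright[top_idx] = True

    rng = np.random.default_rng(seed)
    p_surv = np.where(events.dormant,
                      math.exp(-k_p * duration_h),
                      math.exp(-k_s * duration_h))
    formed = rng.random(n) < p_surv

    n_dim = n - n_top
    bright_surv = float(formed[bright].mean())
    dim_surv = float(formed[~bright].mean()) if n_dim else float("nan")
    purity = float(events.dormant[bright].mean())
    return SortAndKillResult(
        top_fraction=top_fraction, duration_h=duration_h,
        bright_survival=bright_surv, dim_survival=dim_surv,
        n_bright=n_top, n_dim=n_dim,
        bright_dormant_purity=purity, warnings=warnings,
    )


# ---------------------------------------------------------------------------
# CSV I/O (schema: fluorescence_au [, dormant, scatter]; metadata header line)


def write_event_table(table: EventTable, path, seed: int | None = None,
                      scenario: str | None = None) -> None:
    df = pd.DataFrame({"fluorescence_au": table.fluorescence})
    if table.dormant is not None:
        df["dormant"] = table.dormant
    if table.scatter is not None:
        df["scatter"] = table.scatter
    with open(path, "w") as fh:
        fh.write(f"# persisterkit events; sample={table.sample_id}; "
                 f"control={table.is_control}; scenario={scenario}; seed={seed}\n")
        df.to_csv(fh, index=False)


def read_event_table(path, sample_id: str | None = None,
                     is_control: bool = False) -> EventTable:
    df = pd.read_csv(path, comment="#")
    return EventTable(
        sample_id=sample_id or str(path),
        fluorescence=df["fluorescence_au"].to_numpy(float),
        is_control=is_control,
        dormant=df["dormant"].to_numpy(bool) if "dormant" in df else None,
        scatter=df["scatter"].to_numpy(float) if "scatter" in df else None,
    )
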