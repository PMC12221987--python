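"""Single-cell trace analysis: growth rates, dormancy-entrance detection,
threshold consistency and switch-vs-graded model discrimination.

The per-frame specific growth rate is mu = (1/l)(dl/dt), estimated as the
centred difference of log length (one-sided at the ends) with divisions
bridged by concatenating log length across the halving. A dormancy entrance
is an abrupt, sustained growth arrest in a cell whose low-GTP reporter has
crossed the bright gate: mu below a small fraction (default 10%) of the
population median for at least two consecutive frames while fluorescence is
at or above the gate threshold. Cells arrested only at the end of their
record cannot be distinguished from crowding stops and are censored.

Whether entry into dormancy is switch-like or graded is tested by comparing
a linear and a decreasing Hill (sigmoidal) regression of growth rate on
reporter fluorescence, preferring the lower AIC (differences below 2 are
flagged inconclusive).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .mechanistic import load_calibration

__all__ = [
    "CellTrace",
    "EntranceEvent",
    "specific_growth_rate",
    "population_mu_reference",
    "bright_gate_threshold",
    "detect_entrance",
    "detect_entrances",
    "threshold_consistency",
    "precedence_fraction",
    "GrowthFluorescenceModel",
    "GrowthFluorescenceResults",
    "fit_growth_fluorescence",
    "read_traces",
    "write_traces",
]


@dataclass
class CellTrace:
    """One cell's time series: frame times (min), length (um), background-
    subtracted reporter fluorescence (AU) and division flags."""

    cell_id: int
    time_min: np.ndarray
    length_um: np.ndarray
    fluor_au: np.ndarray
    division: np.ndarray | None = None
    own_start: int = 0                   # first frame that is the cell's own
                                         # record (earlier frames are stitched
                                         # ancestor history)
    latent: pd.DataFrame | None = None   # synthetic provenance only

    def __post_init__(self) -> None:
        self.time_min = np.asarray(self.time_min, float)
        self.length_um = np.asarray(self.length_um, float)
        self.fluor_au = np.asarray(self.fluor_au, float)
        if self.division is None:
            self.division = np.zeros(self.time_min.size, dtype=bool)
        else:
            self.division = np.asarray(self.division, bool)
        n = self.time_min.size
        if not (self.length_um.size == self.fluor_au.size == self.division.size == n):
            raise ValueError("trace columns must have equal length")
        if n >= 2:
            dt = np.diff(self.time_min)
            if not np.allclose(dt, dt[0]):
                raise ValueError("frame spacing must be constant")

    @property
    def n_frames(self) -> int:
        return int(self.time_min.size)


@dataclass
class EntranceEvent:
    cell_id: int
    arrest_time_min: float
    fluor_at_arrest_au: float
    rise_onset_min: float
    arrest_frames: int
    precedes: bool               # fluorescence rise began before arrest

    def __post_init__(self) -> None:
        if self.precedes and self.rise_onset_min > self.arrest_time_min:
            raise ValueError("precedence flag requires rise onset <= arrest time")


def specific_growth_rate(trace: CellTrace) -> np.ndarray:
    """Per-frame specific growth rate mu = (1/l)(dl/dt) in 1/min.

    Computed as the gradient of log length (centred interiorly, one-sided at
    the ends). Frames flagged as divisions halve the length; the series is
    made continuous by accumulating the log-length jump at each division, so
    mu is bridged across divisions rather than spiking negative.
    """
    n = trace.n_frames
    if n < 2:
        raise ValueError("need >= 2 frames to estimate growth rate")
    l = trace.length_um
    bad = np.flatnonzero(l <= 0)
    if bad.size:
        raise ValueError(f"non-positive length at frame {int(bad[0])}")
    logl = np.log(l)
    # bridge division resets: divisions halve the length, so adding log 2 back
    # at each division frame makes log length continuous across them
    offset = np.zeros(n)
    for i in np.flatnonzero(trace.division):
        if i > 0:
            offset[i:] += math.log(2.0)
    return np.gradient(logl + offset, trace.time_min)


def population_mu_reference(traces: Sequence[CellTrace]) -> float:
    """Median per-frame growth rate over all co-imaged cells (the growing-
    population reference for arrest calls)."""
    mus = [specific_growth_rate(tr) for tr in traces if tr.n_frames >= 2]
    if not mus:
        raise ValueError("no traces with >= 2 frames")
    return float(np.median(np.concatenate(mus)))


def bright_gate_threshold(traces: Sequence[CellTrace], fold: float = 5.0,
                          trim: float = 0.01) -> float:
    """Bright gate at ``fold`` x mean population fluorescence.

    Mirrors the cytometry gating rule, but with the top ``trim`` fraction of
    frames excluded from the mean: unlike a flow snapshot, time-lapse records
    over-sample arrested cells (they are retained for the full movie), and an
    untrimmed mean would drag the gate up with the very cells it is meant to
    capture.
    """
    allf = np.concatenate([tr.fluor_au for tr in traces])
    if trim > 0:
        allf = allf[allf <= np.quantile(allf, 1.0 - trim)]
    return fold * float(allf.mean())


def detect_entrance(
    trace: CellTrace,
    mu: np.ndarray | None = None,
    mu_ref: float | None = None,
    gate_threshold_au: float | None = None,
    eps_fraction: float = 0.1,
    eps_mu_abs: float | None = None,
    min_arrest_frames: int = 2,
) -> EntranceEvent | None:
    """Detect a dormancy entrance in one trace, if any.

    Arrest: mu < ``eps_fraction`` x population median (or the absolute
    fallback ``eps_mu_abs`` when no reference is available) for at least
    ``min_arrest_frames`` consecutive frames, with fluorescence at or above
    the bright gate at the arrest frame. The fluorescence-rise onset is found
    by scanning backward from arrest for the last frame below half the gate
    threshold. Arrests that do not complete the minimum run before the record
    ends are censored (returns None).
    """
    if trace.n_frames < 3:
        return None
    if gate_threshold_au is None:
        raise ValueError("a bright gate threshold is required")
    if mu is None:
        mu = specific_growth_rate(trace)
    if mu_ref is not None:
        eps = eps_fraction * mu_ref
    elif eps_mu_abs is not None:
        eps = eps_mu_abs
    else:
        raise ValueError("provide a population mu reference or eps_mu_abs fallback")

    below = mu < eps
    n = trace.n_frames
    i = 0
    while i < n:
        if not below[i]:
            i += 1
            continue
        j = i
        while j < n and below[j]:
            j += 1
        run = j - i
        # a run shorter than the minimum that hits the record end cannot be
        # called (censored); completed runs of >= min frames are events.
        # at least the minimum run must fall within the cell's own record:
        # arrests living entirely in stitched ancestor history belong to the
        # ancestor's trace, not this one
        own_frames = max(0, j - max(i, trace.own_start))
        if run >= min_arrest_frames and own_frames >= min_arrest_frames:
            if trace.fluor_au[i] >= gate_threshold_au:
                onset = _rise_onset(trace, i, gate_threshold_au)
                return EntranceEvent(
                    cell_id=trace.cell_id,
                    arrest_time_min=float(trace.time_min[i]),
                    fluor_at_arrest_au=float(trace.fluor_au[i]),
                    rise_onset_min=onset,
                    arrest_frames=run,
                    precedes=onset < float(trace.time_min[i]),
                )
        i = j
    return None


def _rise_onset(trace: CellTrace, arrest_idx: int, gate: float) -> float:
    half = 0.5 * gate
    k = arrest_idx
    while k > 0 and trace.fluor_au[k - 1] >= half:
        k -= 1
    # k is the first frame of the sustained rise ending >= gate
    return float(trace.time_min[k])


def detect_entrances(
    traces: Sequence[CellTrace],
    gate_fold: float = 5.0,
    eps_fraction: float = 0.1,
    min_arrest_frames: int = 2,
) -> list[EntranceEvent]:
    """Run entrance detection over a co-imaged trace collection, deriving the
    population growth reference and bright gate from the collection itself."""
    mu_ref = population_mu_reference(traces)
    gate = bright_gate_threshold(traces, gate_fold)
    events = []
    for tr in traces:
        ev = detect_entrance(tr, mu_ref=mu_ref, gate_threshold_au=gate,
                             eps_fraction=eps_fraction,
                             min_arrest_frames=min_arrest_frames)
        if ev is not None:
            events.append(ev)
    return events


def threshold_consistency(events: Sequence[EntranceEvent],
                          gtp_calib_au_mm: float | None = None) -> dict:
    """Mean and CV of fluorescence at arrest, plus the estimated GTP (mM) at
    entrance via the configured inverse calibration G = c / F."""
    if len(events) < 3:
        raise ValueError("threshold summary requires >= 3 entrance events")
    if gtp_calib_au_mm is None:
        gtp_calib_au_mm = load_calibration()["gtp_calib_au_mm"]
    f_arr = np.array([e.fluor_at_arrest_au for e in events])
    gtp = gtp_calib_au_mm / f_arr
    table = pd.DataFrame({
        "cell_id": [e.cell_id for e in events],
        "arrest_time_min": [e.arrest_time_min for e in events],
        "fluor_at_arrest_au": f_arr,
        "est_gtp_mm": gtp,
    })
    return {
        "n_events": len(events),
        "mean_fluor_au": float(f_arr.mean()),
        "cv_fluor": float(f_arr.std(ddof=1) / f_arr.mean()),
        "mean_est_gtp_mm": float(gtp.mean()),
        "median_est_gtp_mm": float(np.median(gtp)),
        "per_event": table,
    }


def precedence_fraction(events: Sequence[EntranceEvent]) -> float:
    """Fraction of entrances whose reporter rise began before growth arrest."""
    if not events:
        raise ValueError("no entrance events")
    return float(np.mean([e.precedes for e in events]))


# ---------------------------------------------------------------------------
# switch vs graded: growth rate ~ fluorescence


class GrowthFluorescenceModel:
    """Regression of single-cell growth rate on reporter fluorescence.

    Fits (a) a line mu = b0 + b1 F and (b) a decreasing Hill sigmoid
    mu = mu_top / (1 + (F/F_half)^h), compares by AIC, and reports the
    preferred relationship. A switch-like (steep sigmoidal) relationship is
    the wild-type signature; a linear one the signature of graded,
    feedback-free GTP depletion.
    """

    def __init__(self, fluor_au: np.ndarray, mu: np.ndarray):
        self.F = np.asarray(fluor_au, float)
        self.mu = np.asarray(mu, float)
        if self.F.size != self.mu.size or self.F.size < 10:
            raise ValueError("need >= 10 paired (F, mu) observations")
        if np.ptp(self.F) <= 0 or not np.isfinite(self.F).all():
            raise ValueError("degenerate fluorescence range: comparison withheld")

    @classmethod
    def from_traces(cls, traces: Sequence[CellTrace]) -> "GrowthFluorescenceModel":
        if len(traces) < 50:
            raise ValueError("need >= 50 traces for the pooled regression")
        fs, mus = [], []
        for tr in traces:
            if tr.n_frames < 2:
                continue
            fs.append(tr.fluor_au)
            mus.append(specific_growth_rate(tr))
        return cls(np.concatenate(fs), np.concatenate(mus))

    @staticmethod
    def sample_traces(traces: Sequence[CellTrace],
                      events: Sequence[EntranceEvent] | None = None,
                      n_total: int = 100, seed: int = 0) -> list[CellTrace]:
        """Subsample a trace collection to a typical imaging-study size.

        Keeps every entrance-containing trace (the rare, informative ones)
        and fills up with randomly chosen growing traces of >= 3 frames, for
        roughly ``n_total`` independent single-cell traces — the scale at
        which the growth-fluorescence relationship is usually summarized.
        """
        rng = np.random.default_rng(seed)
        keep_ids = {e.cell_id for e in events} if events else set()
        kept = [tr for tr in traces if tr.cell_id in keep_ids]
        pool = [tr for tr in traces
                if tr.cell_id not in keep_ids and tr.n_frames >= 3]
        n_fill = max(n_total - len(kept), 0)
        if len(pool) > n_fill:
            idx = rng.choice(len(pool), size=n_fill, replace=False)
            pool = [pool[i] for i in sorted(idx)]
        return kept + pool

    def fit(self) -> "GrowthFluorescenceResults":
        F, mu = self.F, self.mu
        n = F.size
        # (a) linear
        X = np.column_stack([np.ones(n), F])
        beta, res, *_ = np.linalg.lstsq(X, mu, rcond=None)
        rss_lin = float(np.sum((mu - X @ beta) ** 2))
        aic_lin = n * math.log(max(rss_lin, 1e-300) / n) + 2 * 2

        # (b) decreasing Hill sigmoid
        def hill(Fv, top, fhalf, h):
            return top / (1.0 + (Fv / fhalf) ** h)

        mu_top0 = float(np.percentile(mu, 90))
        fpos = F[F > 0]
        # multi-start over the half-point: the response often turns over far
        # into the bright tail, where a median start cannot reach
        f_half_starts = (np.quantile(fpos, [0.5, 0.9, 0.99]) if fpos.size
                         else np.array([1.0]))
        best = None
        for f0 in f_half_starts:
            for h0 in (1.0, 4.0):
                try:
                    popt_i, pcov_i = curve_fit(
                        hill, F, mu, p0=(max(mu_top0, 1e-6), max(f0, 1e-6), h0),
                        bounds=([1e-9, 1e-9, 0.05], [np.inf, np.inf, 50.0]),
                        maxfev=20000)
                except RuntimeError:
                    continue
                rss_i = float(np.sum((mu - hill(F, *popt_i)) ** 2))
                if best is None or rss_i < best[0]:
                    best = (rss_i, popt_i, pcov_i)
        fit_ok = best is not None
        if fit_ok:
            rss_hill, popt, pcov = best
        else:
            popt, pcov, rss_hill = (np.nan, np.nan, np.nan), None, np.inf
        aic_hill = n * math.log(max(rss_hill, 1e-300) / n) + 2 * 3 if fit_ok else np.inf

        preferred = "sigmoidal" if aic_hill < aic_lin else "linear"
        delta = abs(aic_lin - aic_hill)
        h_se = float(np.sqrt(pcov[2, 2])) if (fit_ok and pcov is not None
                                              and np.isfinite(pcov[2, 2])) else float("nan")
        return GrowthFluorescenceResults(
            n_obs=n,
            linear_params=(float(beta[0]), float(beta[1])), rss_linear=rss_lin,
            aic_linear=aic_lin,
            hill_params=tuple(float(v) for v in popt), rss_hill=rss_hill,
            aic_hill=aic_hill, hill_se=h_se,
            preferred=preferred, conclusive=delta > 2.0, delta_aic=delta,
        )


@dataclass
class GrowthFluorescenceResults:
    n_obs: int
    linear_params: tuple[float, float]
    rss_linear: float
    aic_linear: float
    hill_params: tuple[float, float, float]   # (mu_top, F_half, h)
    rss_hill: float
    aic_hill: float
    hill_se: float
    preferred: str
    conclusive: bool
    delta_aic: float

    @property
    def hill_coefficient(self) -> float:
        return self.hill_params[2]

    def hill_ci(self, z: float = 1.96) -> tuple[float, float]:
        h = self.hill_coefficient
        return (h - z * self.hill_se, h + z * self.hill_se)

    def summary(self) -> str:
        lo, hi = self.hill_ci()
        return "\n".join([
            "Growth-fluorescence relationship",
            "=" * 45,
            f"n observations:   {self.n_obs}",
            f"linear fit:       mu = {self.linear_params[0]:.4g} + "
            f"{self.linear_params[1]:.4g} * F   (AIC {self.aic_linear:.1f})",
            f"sigmoidal fit:    mu_top={self.hill_params[0]:.4g}, "
            f"F_half={self.hill_params[1]:.4g}, h={self.hill_params[2]:.3g} "
            f"[{lo:.3g}, {hi:.3g}]   (AIC {self.aic_hill:.1f})",
            f"preferred model:  {self.preferred}"
            + ("" if self.conclusive else "  (inconclusive: |dAIC| <= 2)"),
        ])


def fit_growth_fluorescence(traces: Sequence[CellTrace]) -> GrowthFluorescenceResults:
    """Pooled switch-vs-graded model comparison over a trace collection."""
    return GrowthFluorescenceModel.from_traces(traces).fit()


# ---------------------------------------------------------------------------
# CSV I/O (schema: cell_id, time_min, length_um, fluor_au, division)


def write_traces(traces: Sequence[CellTrace], path, seed: int | None = None,
                 scenario: str | None = None) -> None:
    rows = []
    for tr in traces:
        for i in range(tr.n_frames):
            rows.append({
                "cell_id": tr.cell_id, "time_min": tr.time_min[i],
                "length_um": tr.length_um[i], "fluor_au": tr.fluor_au[i],
                "division": bool(tr.division[i]),
            })
    df = pd.DataFrame(rows)
    with open(path, "w") as fh:
        fh.write(f"# persisterkit traces; scenario={scenario}; seed={seed}\n")
        df.to_csv(fh, index=False)


def read_traces(path) -> list[CellTrace]:
    df = pd.read_csv(path, comment="#")
    traces = []
    for cid, grp in df.groupby("cell_id", sort=True):
        grp = grp.sort_values("time_min")
        traces.append(CellTrace(
            cell_id=int(cid),
            time_min=grp["time_min"].to_numpy(float),
            length_um=grp["length_um"].to_numpy(float),
            fluor_au=grp["fluor_au"].to_numpy(float),
            division=grp["division"].to_numpy(bool) if "division" in grp else None,
        ))
    return traces
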