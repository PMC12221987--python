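"""Stochastic single-cell model of the alarmone-GTP persistence switch.

The model tracks four per-cell quantities: the alarmone (p)ppGpp ``P`` (uM,
tetra- and penta-phosphate collapsed into one species), GTP ``G`` (mM), cell
length ``l`` (um) and a low-GTP fluorescent reporter ``F`` (AU). Alarmone
synthesis combines a basal, self-activated Rel term, a cooperative (Hill)
SasB self-amplification term and an optional envelope-stress SasA term;
(p)ppGpp inhibits GTP supply and its synthesis consumes GTP; growth follows
GTP saturably; the reporter is derepressed when GTP is low (CodY logic) and
diluted by growth:

    dP/dt = Lam * [V_R (1 + a_R P/(K_B+P)) + V_B P^n / (K_B^n + P^n) + V_A s] - d_P P
    dG/dt = v_G / (1 + P/K_i) - s_PG * (P synthesis) - mu G c_dil
    mu    = mu_max * G/(K_G+G) * Lam
    dF/dt = alpha_F / (1 + (G/K_C)^h_C) - (mu + d_F) F

``Lam = exp(x - sigma_eta^2/2)`` is a lognormal-positive extrinsic noise
factor driven by an Ornstein-Uhlenbeck process x with standard deviation
``sigma_eta`` and autocorrelation time ``tau_eta``; it multiplies both
alarmone synthesis and growth. With cooperative SasB (n_B ~ 3) the alarmone
subsystem is bistable: rare sustained noise excursions flip single cells into
a self-maintaining high-(p)ppGpp / low-GTP state, producing abrupt growth
arrest (dormancy) — the single-cell persistence switch. With n_B = 1 the
feedback is non-cooperative and entry into slow growth is graded.

Integration is Euler-Maruyama at fixed ``dt`` (default 0.1 min); concentrations
are clamped at zero with a counted warning. Cells divide when length doubles
(5% CV threshold noise); division halves length and conserves concentrations.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from importlib import resources
from typing import Iterator

import numpy as np
import pandas as pd
import yaml
from scipy.optimize import curve_fit

from .scenarios import ScenarioSpec

__all__ = [
    "ModelParams",
    "CellState",
    "CellEnsemble",
    "LineageRecord",
    "load_default_params",
    "load_calibration",
    "params_for_scenario",
    "simulate_cells",
    "simulate_lineage",
    "sasb_synthesis_rate",
    "alarmone_synthesis_rate",
    "fit_hill_activation",
    "bimodality_coefficient",
]

_POSITIVE = (
    "K_B", "d_P", "v_G", "K_i", "mu_max", "K_G", "G_thr", "alpha_F",
    "K_C", "h_C", "tau_eta", "eps_mu", "tau_arrest", "l_birth", "dt",
    "frame_min",
)
_NONNEG = ("V_B", "V_R", "a_R", "V_A", "s_PG", "sigma_eta", "c_dil",
           "division_cv", "k_p", "d_F", "x_inherit")


@dataclass(frozen=True)
class ModelParams:
    """Parameters of the alarmone-GTP switch model (units in class docstring)."""

    V_B: float
    K_B: float
    n_B: float
    V_R: float
    a_R: float
    V_A: float
    d_P: float
    v_G: float
    K_i: float
    s_PG: float
    mu_max: float
    K_G: float
    G_thr: float
    alpha_F: float
    K_C: float
    h_C: float
    d_F: float
    sigma_eta: float
    tau_eta: float
    eps_mu: float
    tau_arrest: float
    k_s: float
    k_p: float
    c_dil: float = 1.0
    x_inherit: float = 1.0  # correlation of a daughter's noise state with the
                            # mother's at division (1 = fully inherited;
                            # lower values model partitioning noise)
    l_birth: float = 2.0
    division_cv: float = 0.05
    frame_min: float = 15.0
    dt: float = 0.1
    supply_noise: bool = False  # apply the noise factor to GTP supply as well
    seed: int = 0

    def __post_init__(self) -> None:
        for name in _POSITIVE:
            if getattr(self, name) <= 0:
                raise ValueError(f"ModelParams.{name} must be strictly positive")
        for name in _NONNEG:
            if getattr(self, name) < 0:
                raise ValueError(f"ModelParams.{name} must be non-negative")
        if self.n_B < 1:
            raise ValueError("Hill coefficient n_B must be >= 1")
        if not (0 < self.G_thr <= 1.0):
            raise ValueError("G_thr must lie in (0, 1] mM")
        if not (0 <= self.k_p < self.k_s):
            raise ValueError("require 0 <= k_p < k_s")

    def replace(self, **kw) -> "ModelParams":
        return replace(self, **kw)


@dataclass
class CellState:
    """Snapshot of one cell's dynamic state."""

    P: float
    G: float
    l: float
    F: float
    eta: float
    dormant: bool


def _load_yaml() -> dict:
    with resources.files("persisterkit.data").joinpath("model_params.yaml").open() as fh:
        return yaml.safe_load(fh)


def load_default_params(**overrides) -> ModelParams:
    """Wild-type defaults from the calibrated package config."""
    raw = dict(_load_yaml()["wild_type"])
    raw.update(overrides)
    return ModelParams(**raw)


def load_calibration() -> dict[str, float]:
    """Calibration constants (reporter AU -> estimated GTP in mM)."""
    return dict(_load_yaml()["calibration"])


def params_for_scenario(scenario: ScenarioSpec, base: ModelParams | None = None) -> ModelParams:
    """Resolve a scenario's genotype and environment into model parameters.

    Genotype flags switch off or rewire the corresponding synthesis terms;
    starvation inducers act through Rel activation, envelope stress through
    SasA, and GTP-synthesis lesions through the supply rate.
    """
    p = base if base is not None else load_default_params()
    g, env = scenario.genotype, scenario.environment
    kw: dict = {"k_s": scenario.kill_params.k_s, "k_p": scenario.kill_params.k_p}
    if g.ppGpp0:
        kw.update(V_R=0.0, a_R=0.0, V_B=0.0, V_A=0.0)
    else:
        if not g.rel:
            kw.update(V_R=0.0, a_R=0.0)
        if not g.sasB:
            kw.update(V_B=0.0)
        if g.sasB_F42A:
            # allosteric site broken: synthesis persists but cooperativity lost
            kw.update(n_B=1.0, V_B=p.V_B * 0.15)
        if not g.sasA:
            kw.update(V_A=0.0)
    if g.gmk_Q110R:
        kw.update(v_G=p.v_G * 0.45, supply_noise=True)
    if g.guaB_down:
        kw.update(v_G=p.v_G * 0.5)
    if env.inducer in ("RHX", "stationary", "CCCP", "arsenate") and not g.ppGpp0:
        kw.update(V_R=p.V_R * 20.0)  # strong starvation activation of Rel
    if env.inducer == "sublethal_bacitracin" and not g.ppGpp0 and g.sasA:
        kw.update(V_A=0.3)  # envelope-stress induction of SasA
    return p.replace(**kw)


# ---------------------------------------------------------------------------
# rate terms


def sasb_synthesis_rate(P, params: ModelParams):
    """Cooperative SasB (p)ppGpp synthesis rate, V_B P^n / (K_B^n + P^n)."""
    P = np.asarray(P, dtype=float)
    Pn = np.power(P, params.n_B)
    return params.V_B * Pn / (params.K_B ** params.n_B + Pn)


def alarmone_synthesis_rate(P, params: ModelParams, stress: bool = False):
    """Total deterministic (p)ppGpp synthesis rate (Rel + SasB + SasA)."""
    P = np.asarray(P, dtype=float)
    rel = params.V_R * (1.0 + params.a_R * P / (params.K_B + P))
    sas_a = params.V_A if stress else 0.0
    return rel + sasb_synthesis_rate(P, params) + sas_a


def fit_hill_activation(conc, rate, p0=None) -> tuple[float, float, float]:
    """Least-squares fit of a Hill activation curve v = V c^n/(K^n + c^n).

    Returns (V, K, n). Used to read the effective cooperativity off a
    synthesis-rate dose response.
    """
    conc = np.asarray(conc, float)
    rate = np.asarray(rate, float)

    def hill(c, V, K, n):
        cn = np.power(c, n)
        return V * cn / (np.power(K, n) + cn)

    if p0 is None:
        p0 = (float(rate.max()), float(np.median(conc)), 2.0)
    popt, _ = curve_fit(hill, conc, rate, p0=p0, maxfev=20000)
    return float(popt[0]), float(popt[1]), float(popt[2])


def bimodality_coefficient(x) -> float:
    """Sarle's bimodality coefficient, (skew^2 + 1)/kurtosis (>0.555 suggests
    more than one mode). The documented unimodality check for end-state GTP."""
    x = np.asarray(x, float)
    n = x.size
    m = x.mean()
    s2 = ((x - m) ** 2).mean()
    if s2 == 0:
        return 0.0
    skew = ((x - m) ** 3).mean() / s2 ** 1.5
    kurt = ((x - m) ** 4).mean() / s2 ** 2
    return (skew ** 2 + 1.0) / kurt


# ---------------------------------------------------------------------------
# vectorized integrator core


class _State:
    """Mutable struct-of-arrays for a set of live cells."""

    __slots__ = ("P", "G", "l", "F", "x", "arrest", "dormant", "entered",
                 "l_birth", "div_thresh", "log_growth", "clamp_count")

    def __init__(self, n: int, params: ModelParams, rng: np.random.Generator):
        self.P = np.full(n, params.V_R / params.d_P if params.d_P else 0.0)
        self.G = np.full(n, 1.8)  # near the growing-state fixed point
        # desynchronize the starting cell-cycle positions
        self.l_birth = np.full(n, params.l_birth)
        self.l = self.l_birth * rng.uniform(1.0, 1.9, n)
        self.F = np.full(n, 0.3)
        self.x = rng.normal(0.0, params.sigma_eta, n)
        self.arrest = np.zeros(n)
        self.dormant = np.zeros(n, dtype=bool)
        self.entered = np.full(n, np.nan)  # first entrance time, min
        self.div_thresh = 2.0 * self.l_birth * _div_noise(params, rng, n)
        self.log_growth = np.zeros(n)  # cumulative integral of mu dt
        self.clamp_count = 0


def _div_noise(params: ModelParams, rng: np.random.Generator, n: int) -> np.ndarray:
    if params.division_cv <= 0:
        return np.ones(n)
    return np.exp(rng.normal(0.0, params.division_cv, n))


def _divide_x(x_mother, params: ModelParams, rng: np.random.Generator):
    """Noise state passed to a daughter: partially inherited, partially
    redrawn (keeps the stationary variance sigma_eta^2)."""
    rho = params.x_inherit
    if rho >= 1.0:
        return x_mother
    fresh = rng.normal(0.0, params.sigma_eta, np.shape(x_mother))
    return rho * x_mother + math.sqrt(max(1.0 - rho**2, 0.0)) * fresh


def _check_finite(t: float, **arrays) -> None:
    for name, arr in arrays.items():
        if not np.all(np.isfinite(arr)):
            idx = int(np.flatnonzero(~np.isfinite(arr))[0])
            raise FloatingPointError(
                f"non-finite state in term {name!r} at t={t:.2f} min (cell {idx}); "
                f"reduce dt or check parameters"
            )


def _step(s: _State, params: ModelParams, dt: float, t: float,
          rng: np.random.Generator, stress: bool) -> np.ndarray:
    """Advance all cells by one Euler-Maruyama step; returns instantaneous mu."""
    lam = np.exp(s.x - 0.5 * params.sigma_eta ** 2)
    syn = alarmone_synthesis_rate(s.P, params, stress) * lam
    mu = params.mu_max * s.G / (params.K_G + s.G) * lam

    P_new = s.P + dt * (syn - params.d_P * s.P)
    supply = params.v_G / (1.0 + s.P / params.K_i)
    if params.supply_noise:
        supply = supply * lam
    G_new = s.G + dt * (supply - params.s_PG * syn - mu * s.G * params.c_dil)
    F_new = s.F + dt * (params.alpha_F / (1.0 + (s.G / params.K_C) ** params.h_C)
                        - (mu + params.d_F) * s.F)

    for arr_new in (P_new, G_new, F_new):
        neg = arr_new < 0.0
        if neg.any():
            s.clamp_count += int(neg.sum())
            np.clip(arr_new, 0.0, None, out=arr_new)
    s.P, s.G, s.F = P_new, G_new, F_new

    # growth: dormant cells do not elongate
    growing = ~s.dormant
    dlog = np.where(growing, mu * dt, 0.0)
    s.l = s.l * np.exp(dlog)
    s.log_growth += dlog

    # arrest bookkeeping: dormancy = mu below eps_mu for >= tau_arrest
    below = mu < params.eps_mu
    s.arrest = np.where(below, s.arrest + dt, 0.0)
    newly = (~s.dormant) & (s.arrest >= params.tau_arrest)
    if newly.any():
        s.dormant[newly] = True
        entry_t = t + dt - params.tau_arrest  # start of the qualifying run
        first = newly & np.isnan(s.entered)
        s.entered[first] = entry_t
    revived = s.dormant & (~below)
    if revived.any():
        s.dormant[revived] = False

    # OU noise update
    s.x = (s.x - dt * s.x / params.tau_eta
           + params.sigma_eta * math.sqrt(2.0 * dt / params.tau_eta)
           * rng.standard_normal(s.x.size))
    return mu


# ---------------------------------------------------------------------------
# ensemble simulation


@dataclass
class CellEnsemble:
    """Frame-sampled trajectories of independent single cells.

    Arrays are shaped (n_frames, n_cells). ``mu_frame`` is the per-frame
    average specific growth rate (change in log length over the frame
    interval), the latent ground truth the trace-based estimator targets.
    """

    params: ModelParams
    scenario_name: str | None
    time_min: np.ndarray
    P: np.ndarray
    G: np.ndarray
    l: np.ndarray
    F: np.ndarray
    mu_frame: np.ndarray
    dormant: np.ndarray
    entrance_time: np.ndarray       # first latent entrance per cell (min; NaN if none)
    divisions_per_cell: np.ndarray
    clamp_count: int

    @property
    def n_division_events(self) -> int:
        return int(self.divisions_per_cell.sum())

    def dormant_fraction(self) -> float:
        return float(self.dormant[-1].mean())

    def entry_rate_per_division(self) -> float:
        """Latent entrance events per recorded division event."""
        n_div = self.n_division_events
        if n_div == 0:
            return float("nan")
        return float(np.isfinite(self.entrance_time).sum() / n_div)

    def end_state(self, var: str = "G") -> np.ndarray:
        return getattr(self, var)[-1]


def simulate_cells(
    params: ModelParams,
    n_cells: int,
    duration_min: float,
    dt: float | None = None,
    scenario: ScenarioSpec | None = None,
    envelope_stress: bool = False,
    seed: int | None = None,
) -> CellEnsemble:
    """Simulate ``n_cells`` independent cell lineages for ``duration_min``.

    Each cell follows the stochastic switch dynamics, dividing when its length
    doubles (the simulation then follows one daughter). States are recorded at
    ``params.frame_min`` intervals. The step size must resolve the fastest
    relaxation: a stability check requires dt * max(d_P, mu_max, 1/tau_eta) < 0.2.
    """
    if n_cells < 1:
        raise ValueError("n_cells must be >= 1")
    if scenario is not None:
        params = params_for_scenario(scenario, params)
        envelope_stress = envelope_stress or scenario.environment.inducer == "sublethal_bacitracin"
    dt = params.dt if dt is None else dt
    fastest = max(params.d_P, params.mu_max, 1.0 / params.tau_eta)
    if dt * fastest >= 0.2:
        raise ValueError(
            f"dt={dt} min too large for stability: dt * fastest rate = {dt * fastest:.3f} >= 0.2"
        )
    rng = np.random.default_rng(params.seed if seed is None else seed)
    s = _State(n_cells, params, rng)

    steps_per_frame = max(1, round(params.frame_min / dt))
    n_steps = int(round(duration_min / dt))
    n_frames = n_steps // steps_per_frame + 1

    out = {k: np.empty((n_frames, n_cells)) for k in ("P", "G", "l", "F", "mu_frame")}
    dorm = np.empty((n_frames, n_cells), dtype=bool)
    divisions = np.zeros(n_cells, dtype=np.int64)

    def record(frame: int, elapsed: float) -> None:
        out["P"][frame] = s.P
        out["G"][frame] = s.G
        out["l"][frame] = s.l
        out["F"][frame] = s.F
        out["mu_frame"][frame] = s.log_growth / elapsed if elapsed > 0 else 0.0
        dorm[frame] = s.dormant
        s.log_growth[:] = 0.0

    record(0, 0.0)
    frame = 1
    for k in range(1, n_steps + 1):
        t = k * dt
        _step(s, params, dt, t - dt, rng, envelope_stress)
        # division at length doubling
        div = s.l >= s.div_thresh
        if div.any():
            divisions[div] += 1
            s.l[div] = s.l[div] / 2.0
            s.l_birth[div] = s.l[div]
            s.div_thresh[div] = 2.0 * s.l[div] * _div_noise(params, rng, int(div.sum()))
            s.x[div] = _divide_x(s.x[div], params, rng)
        if k % steps_per_frame == 0:
            _check_finite(t, P=s.P, G=s.G, F=s.F, l=s.l)
            record(frame, steps_per_frame * dt)
            frame += 1

    times = np.arange(n_frames) * steps_per_frame * dt
    return CellEnsemble(
        params=params,
        scenario_name=scenario.name if scenario is not None else None,
        time_min=times,
        P=out["P"], G=out["G"], l=out["l"], F=out["F"],
        mu_frame=out["mu_frame"], dormant=dorm,
        entrance_time=s.entered.copy(),
        divisions_per_cell=divisions,
        clamp_count=s.clamp_count,
    )


# ---------------------------------------------------------------------------
# lineage simulation


@dataclass
class LineageRecord:
    """Frame records of a growing lineage tree.

    ``frames`` has one row per live cell per 15-min frame with latent columns
    (``gtp_mm``, ``ppgpp_um``, ``mu_frame``, ``dormant``) flagged as synthetic
    provenance; analysis modules consume only (time, length, fluorescence)
    via :meth:`to_traces`.
    """

    frames: pd.DataFrame
    divisions: pd.DataFrame
    parents: dict[int, int]
    n_division_events: int
    target_division_events: int
    shortfall: bool
    params: ModelParams
    scenario_name: str | None = None
    clamp_count: int = 0

    def to_traces(self, include_latent: bool = False,
                  stitch_frames: int = 8,
                  length_noise_cv: float = 0.0,
                  fluor_noise_cv: float = 0.0,
                  noise_seed: int = 0) -> list["CellTrace"]:
        """Per-cell traces (time, length, fluorescence) for the analysis layer.

        With ``stitch_frames > 0`` up to that many ancestor frames are
        prepended to each cell's record (the frame after each division is
        flagged so growth rates bridge the halving): reporter induction often
        spans more than one division, so an entrance's rise history can live
        in the mother's record.

        ``length_noise_cv`` / ``fluor_noise_cv`` add per-frame lognormal
        measurement noise, emulating segmentation and photometry error of
        image-derived traces (off by default).
        """
        from .singlecell import CellTrace

        latent_cols = ["gtp_mm", "ppgpp_um", "mu_frame", "dormant"]
        df = self.frames.sort_values(["cell_id", "time_min"], kind="stable")
        cols = {c: df[c].to_numpy() for c in df.columns}
        if length_noise_cv > 0 or fluor_noise_cv > 0:
            nrng = np.random.default_rng(noise_seed)
            if length_noise_cv > 0:
                cols["length_um"] = cols["length_um"] * nrng.lognormal(
                    0.0, length_noise_cv, len(df))
            if fluor_noise_cv > 0:
                cols["fluor_au"] = cols["fluor_au"] * nrng.lognormal(
                    0.0, fluor_noise_cv, len(df))
        uniq, starts = np.unique(cols["cell_id"], return_index=True)
        bounds = {int(c): (int(s), int(e)) for c, s, e in
                  zip(uniq, starts, np.append(starts[1:], len(df)))}

        def segment(cid: int, max_frames: int) -> tuple[int, int] | None:
            se = bounds.get(cid)
            if se is None:
                return None
            s, e = se
            return max(s, e - max_frames), e

        traces = []
        for cid in bounds:
            segs = [bounds[cid]]
            anc = self.parents.get(cid, -1)
            n_hist = 0
            while stitch_frames and anc >= 0 and n_hist < stitch_frames:
                seg = segment(anc, stitch_frames - n_hist)
                if seg is None:
                    break
                segs.insert(0, seg)
                n_hist += seg[1] - seg[0]
                anc = self.parents.get(anc, -1)
            idx = np.concatenate([np.arange(s, e) for s, e in segs])
            division = np.zeros(idx.size, dtype=bool)
            pos = 0
            for s, e in segs[:-1]:
                pos += e - s
                division[pos] = True  # first frame after each stitched division
            tr = CellTrace(
                cell_id=cid,
                time_min=cols["time_min"][idx].astype(float),
                length_um=cols["length_um"][idx].astype(float),
                fluor_au=cols["fluor_au"][idx].astype(float),
                division=division,
                own_start=n_hist,
            )
            if include_latent:
                tr.latent = pd.DataFrame({c: cols[c][idx] for c in latent_cols})
            traces.append(tr)
        return traces

    def latent_entrances(self) -> pd.DataFrame:
        """First frame at which each cell is latently dormant (ground truth)."""
        d = self.frames[self.frames["dormant"]]
        if d.empty:
            return pd.DataFrame(columns=["cell_id", "time_min"])
        first = d.groupby("cell_id", sort=True)["time_min"].min().reset_index()
        return first


def simulate_lineage(
    params: ModelParams,
    n_division_events: int,
    scenario: ScenarioSpec | None = None,
    max_live: int = 400,
    max_duration_min: float = 100_000.0,
    seed: int | None = None,
) -> LineageRecord:
    """Grow a lineage tree from one cell until ``n_division_events`` divisions.

    Frames are recorded at 15-min spacing for every live cell. When the live
    population exceeds ``max_live``, non-dormant lineages are uniformly
    subsampled down to the cap (dormant cells are always retained), mirroring
    field-of-view crowding in time-lapse experiments. Division splits a mother
    exactly in half (threshold carries the 5% CV noise) and conserves
    concentrations. If every lineage goes dormant before the target count the
    partial record is returned with ``shortfall=True``.
    """
    if n_division_events < 1:
        raise ValueError("n_division_events must be >= 1")
    if scenario is not None:
        params = params_for_scenario(scenario, params)
    dt = params.dt
    rng = np.random.default_rng(params.seed if seed is None else seed)

    s = _State(1, params, rng)
    s.l[:] = params.l_birth
    s.l_birth[:] = s.l
    s.div_thresh = 2.0 * s.l_birth * _div_noise(params, rng, 1)
    cell_ids = np.array([0], dtype=np.int64)
    parents: dict[int, int] = {0: -1}
    next_id = 1
    last_frame_t = np.zeros(1)

    frame_rows: list[tuple] = []
    div_rows: list[tuple] = []
    n_div = 0
    steps_per_frame = max(1, round(params.frame_min / dt))
    t = 0.0
    frame_rows.extend(_lineage_frame_rows(s, cell_ids, t, np.zeros(1)))

    k = 0
    while n_div < n_division_events and t < max_duration_min:
        k += 1
        t = k * dt
        mu = _step(s, params, dt, t - dt, rng, False)

        div = s.l >= s.div_thresh
        if div.any():
            idx = np.flatnonzero(div)
            keep = np.ones(s.P.size, dtype=bool)
            new_states: list[tuple] = []
            for i in idx:
                n_div += 1
                d1, d2 = next_id, next_id + 1
                next_id += 2
                mother = int(cell_ids[i])
                parents[d1] = mother
                parents[d2] = mother
                div_rows.append((t, mother, d1, d2))
                keep[i] = False
                half = s.l[i] / 2.0
                for did in (d1, d2):
                    x_d = float(_divide_x(s.x[i], params, rng))
                    new_states.append((did, s.P[i], s.G[i], half, s.F[i], x_d,
                                       s.arrest[i], s.dormant[i], s.entered[i]))
                if n_div >= n_division_events:
                    break
            s_new_ids = np.array([ns[0] for ns in new_states], dtype=np.int64)
            _append_cells(s, new_states, params, rng)
            cell_ids = np.concatenate([cell_ids[keep], s_new_ids])
            last_frame_t = np.concatenate([last_frame_t[keep],
                                           np.full(len(new_states), t)])
            _drop_cells(s, keep, extra_new=len(new_states))

        # culling: cap the live population, always retaining dormant cells
        if s.P.size > max_live:
            dormant = s.dormant
            n_dorm = int(dormant.sum())
            n_keep_grow = max(max_live - n_dorm, 0)
            grow_idx = np.flatnonzero(~dormant)
            keep_idx = rng.choice(grow_idx, size=min(n_keep_grow, grow_idx.size),
                                  replace=False)
            keep = dormant.copy()
            keep[keep_idx] = True
            cell_ids = cell_ids[keep]
            last_frame_t = last_frame_t[keep]
            _drop_cells(s, keep, extra_new=0)

        if k % steps_per_frame == 0:
            _check_finite(t, P=s.P, G=s.G, F=s.F, l=s.l)
            elapsed = t - last_frame_t
            frame_rows.extend(_lineage_frame_rows(s, cell_ids, t, elapsed))
            last_frame_t[:] = t
            s.log_growth[:] = 0.0

        if s.dormant.all():
            break  # every live lineage dormant: cannot reach the target

    frames = pd.DataFrame(
        frame_rows,
        columns=["cell_id", "time_min", "length_um", "fluor_au",
                 "gtp_mm", "ppgpp_um", "mu_frame", "dormant"],
    )
    frames["cell_id"] = frames["cell_id"].astype(np.int64)
    frames["dormant"] = frames["dormant"].astype(bool)
    divisions = pd.DataFrame(div_rows, columns=["time_min", "mother", "daughter1", "daughter2"])
    return LineageRecord(
        frames=frames,
        divisions=divisions,
        parents=parents,
        n_division_events=n_div,
        target_division_events=n_division_events,
        shortfall=n_div < n_division_events,
        params=params,
        scenario_name=scenario.name if scenario is not None else None,
        clamp_count=s.clamp_count,
    )


def _lineage_frame_rows(s: _State, cell_ids: np.ndarray, t: float,
                        elapsed: np.ndarray) -> Iterator[tuple]:
    with np.errstate(invalid="ignore", divide="ignore"):
        mu_frame = np.where(elapsed > 0, s.log_growth / np.maximum(elapsed, 1e-12), 0.0)
    for j in range(s.P.size):
        yield (int(cell_ids[j]), t, float(s.l[j]), float(s.F[j]),
               float(s.G[j]), float(s.P[j]), float(mu_frame[j]), bool(s.dormant[j]))


def _append_cells(s: _State, new_states: list[tuple], params: ModelParams,
                  rng: np.random.Generator) -> None:
    if not new_states:
        return
    arr = {name: [] for name in ("P", "G", "l", "F", "x", "arrest", "dormant", "entered")}
    for (_cid, P, G, l, F, x, arrest, dormant, entered) in new_states:
        arr["P"].append(P); arr["G"].append(G); arr["l"].append(l); arr["F"].append(F)
        arr["x"].append(x); arr["arrest"].append(arrest)
        arr["dormant"].append(dormant); arr["entered"].append(entered)
    n_new = len(new_states)
    s.P = np.concatenate([s.P, arr["P"]])
    s.G = np.concatenate([s.G, arr["G"]])
    s.l = np.concatenate([s.l, arr["l"]])
    s.F = np.concatenate([s.F, arr["F"]])
    s.x = np.concatenate([s.x, arr["x"]])
    s.arrest = np.concatenate([s.arrest, arr["arrest"]])
    s.dormant = np.concatenate([s.dormant, np.asarray(arr["dormant"], bool)])
    s.entered = np.concatenate([s.entered, arr["entered"]])
    s.l_birth = np.concatenate([s.l_birth, arr["l"]])
    s.div_thresh = np.concatenate([s.div_thresh,
                                   2.0 * np.asarray(arr["l"]) * _div_noise(params, rng, n_new)])
    s.log_growth = np.concatenate([s.log_growth, np.zeros(n_new)])


def _drop_cells(s: _State, keep: np.ndarray, extra_new: int) -> None:
    """Keep `keep`-flagged old cells; the trailing `extra_new` cells are kept."""
    if extra_new:
        keep = np.concatenate([keep, np.ones(extra_new, dtype=bool)])
    for name in ("P", "G", "l", "F", "x", "arrest", "dormant", "entered",
                 "l_birth", "div_thresh", "log_growth"):
        setattr(s, name, getattr(s, name)[keep])
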