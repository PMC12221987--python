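"""Phenomenological synthetic-data generators.

Kill curves are drawn from the closed-form two-compartment survival of each
scenario with a serial-dilution plating emulation (Poisson colony counts in a
countable 30-300 range, a plating detection limit, lognormal replicate scatter
on the inoculum and mild per-point technical scatter). Cytometry event tables
are drawn from a three-part mixture: a lognormal bulk reporter signal, a rare
bright dormant component at the scenario's low-GTP weight, and additive
autofluorescence; the matched control table carries autofluorescence alone.
Latent dormancy labels are retained per event for the sort-and-kill emulation
only.
"""

from __future__ import annotations

import numpy as np

from .cytometry import EventTable
from .killcurve import KillCurve, biexponential_survival
from .scenarios import ScenarioSpec, cytometry_shape

__all__ = ["generate_kill_curve", "generate_cytometry", "DEFAULT_TIMEPOINTS_H"]

DEFAULT_TIMEPOINTS_H = (0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0)

# plating emulation constants
_PLATE_VOL_ML = 0.1
_MAX_COUNTABLE = 300
_N0_CV = 0.2          # replicate-level lognormal scatter on the inoculum
_POINT_CV = 0.05      # per-point technical (pipetting) scatter


def generate_kill_curve(
    scenario: ScenarioSpec,
    timepoints_h=DEFAULT_TIMEPOINTS_H,
    n_reps: int = 3,
    seed: int = 0,
    noise: bool = True,
) -> list[KillCurve]:
    """Replicate kill curves for a scenario.

    With ``noise=False`` the returned CFU equal ``N0 * S(t)`` exactly (the
    closed form to machine precision); otherwise CFU are obtained by plating
    emulation: each timepoint is serially ten-fold diluted to a countable
    range and the colony count drawn Poisson.
    """
    t = np.asarray(timepoints_h, float)
    if np.any(t < 0):
        raise ValueError("timepoints must be non-negative")
    if 0.0 not in t:
        raise ValueError("timepoints must include 0")
    if n_reps < 1:
        raise ValueError("n_reps must be >= 1")
    kp = scenario.kill_params
    seeds = np.random.SeedSequence(seed).spawn(n_reps)
    curves = []
    detection_limit = 1.0 / _PLATE_VOL_ML
    for rep in range(n_reps):
        rng = np.random.default_rng(seeds[rep])
        surv = biexponential_survival(t, kp.f, kp.k_s, kp.k_p)
        if not noise:
            cfu = kp.N0 * surv
            below = np.zeros(t.size, dtype=bool)
        else:
            s_n0 = np.sqrt(np.log(1 + _N0_CV**2))
            s_pt = np.sqrt(np.log(1 + _POINT_CV**2))
            n0 = kp.N0 * rng.lognormal(-0.5 * s_n0**2, s_n0)
            true_conc = n0 * surv * rng.lognormal(-0.5 * s_pt**2, s_pt, t.size)
            cfu = np.empty(t.size)
            below = np.zeros(t.size, dtype=bool)
            for i, conc in enumerate(true_conc):
                cfu[i], below[i] = _plate(conc, rng, detection_limit)
        curves.append(KillCurve(
            condition=scenario.name, replicate=rep + 1, time_h=t.copy(), cfu=cfu,
            below_detection=below, detection_limit=detection_limit,
            mic_multiple=scenario.mic_multiple,
        ))
    return curves


def _plate(conc: float, rng: np.random.Generator, limit: float) -> tuple[float, bool]:
    """Serial-dilution plating: pick the ten-fold dilution giving a countable
    plate, draw the colony count Poisson, convert back to CFU/ml."""
    dilution = 1.0
    while conc * _PLATE_VOL_ML / dilution > _MAX_COUNTABLE:
        dilution *= 10.0
    colonies = rng.poisson(conc * _PLATE_VOL_ML / dilution)
    if colonies == 0:
        return limit, True
    return colonies * dilution / _PLATE_VOL_ML, False


def generate_cytometry(
    scenario: ScenarioSpec,
    n_events: int,
    seed: int = 0,
    low_gtp_fraction: float | None = None,
) -> tuple[EventTable, EventTable]:
    """Synthetic reporter event table plus matched autofluorescence control.

    Events mix a lognormal bulk with a rare bright dormant component whose
    weight is the scenario's low-GTP fraction (location well above five-fold
    the bulk mean, so the population is heavy-tailed) and additive
    autofluorescence. Returns ``(sample, control)``; the sample carries latent
    per-event dormancy labels.
    """
    if n_events < 1000:
        raise ValueError("n_events must be >= 1000")
    w = scenario.low_gtp_fraction if low_gtp_fraction is None else low_gtp_fraction
    if not (0.0 <= w <= 1.0):
        raise ValueError("bright-component weight outside [0, 1]")
    shape = cytometry_shape()
    rng = np.random.default_rng(np.random.SeedSequence(seed))

    dormant = rng.random(n_events) < w
    bulk_mu = np.log(shape["bulk_median_au"])
    bulk_sig = shape["bulk_sigma_ln"]
    bulk_mean = np.exp(bulk_mu + 0.5 * bulk_sig**2)
    bright_mu = np.log(shape["bright_fold"] * bulk_mean)
    reporter = np.where(
        dormant,
        rng.lognormal(bright_mu, shape["bright_sigma_ln"], n_events),
        rng.lognormal(bulk_mu, bulk_sig, n_events),
    )
    auto = rng.lognormal(np.log(shape["autofluor_median_au"]),
                         shape["autofluor_sigma_ln"], n_events)
    control = rng.lognormal(np.log(shape["autofluor_median_au"]),
                            shape["autofluor_sigma_ln"], n_events)
    scatter = rng.lognormal(0.0, 0.2, n_events)

    sample = EventTable(
        sample_id=scenario.name,
        fluorescence=reporter + auto,
        dormant=dormant,
        scatter=scatter,
        meta={"scenario": scenario.name, "seed": seed, "low_gtp_weight": w},
    )
    ctrl = EventTable(
        sample_id=f"{scenario.name}_autofluorescence",
        fluorescence=control,
        is_control=True,
        meta={"scenario": scenario.name, "seed": seed},
    )
    return sample, ctrl
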