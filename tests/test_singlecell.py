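"""Single-cell growth rates, entrance detection, threshold consistency and
switch-vs-graded discrimination."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from persisterkit.mechanistic import simulate_lineage
from persisterkit.scenarios import get_scenario
from persisterkit.singlecell import (CellTrace, GrowthFluorescenceModel,
                                     detect_entrance, detect_entrances,
                                     precedence_fraction, read_traces,
                                     specific_growth_rate,
                                     threshold_consistency, write_traces)


def make_trace(l, F=None, cell_id=0, dt=15.0, division=None):
    l = np.asarray(l, float)
    t = np.arange(l.size) * dt
    F = np.zeros_like(l) if F is None else np.asarray(F, float)
    return CellTrace(cell_id, t, l, F, division=division)


def test_constant_length_has_zero_growth_rate():
    mu = specific_growth_rate(make_trace(np.full(6, 3.0)))
    assert np.allclose(mu, 0.0)


def test_exponential_elongation_recovers_the_rate():
    r = 0.02
    t = np.arange(8) * 15.0
    mu = specific_growth_rate(make_trace(2.0 * np.exp(r * t)))
    assert np.allclose(mu, r, rtol=1e-10)


@settings(derandomize=True, max_examples=25, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3))
def test_growth_rate_is_invariant_to_length_units(scale):
    rng = np.random.default_rng(5)
    l = 2.0 * np.exp(np.cumsum(rng.uniform(0.1, 0.4, 10)))
    mu1 = specific_growth_rate(make_trace(l))
    mu2 = specific_growth_rate(make_trace(l * scale))
    assert np.allclose(mu1, mu2, rtol=1e-12)


def test_division_frames_are_bridged_not_negative():
    """A division halves the length; the bridged estimator keeps mu smooth and
    positive across it."""
    r = 0.02
    t = np.arange(8) * 15.0
    l = 2.0 * np.exp(r * t)
    division = np.zeros(8, dtype=bool)
    l[4:] /= 2.0
    division[4] = True
    mu = specific_growth_rate(make_trace(l, division=division))
    assert np.allclose(mu, r, rtol=1e-10)


def test_nonpositive_length_is_an_error_naming_the_frame():
    with pytest.raises(ValueError, match="frame 2"):
        specific_growth_rate(make_trace([2.0, 2.1, 0.0, 2.3]))


def test_steadily_growing_trace_yields_no_entrance():
    t = np.arange(10) * 15.0
    tr = make_trace(2.0 * np.exp(0.02 * t), F=np.ones(10))
    ev = detect_entrance(tr, mu_ref=0.02, gate_threshold_au=5.0)
    assert ev is None


def test_arrest_without_bright_reporter_is_not_an_entrance():
    l = np.concatenate([2.0 * np.exp(0.02 * np.arange(5) * 15.0), np.full(4, 2.0 * np.exp(0.02 * 60))])
    tr = make_trace(l, F=np.full(9, 0.1))
    assert detect_entrance(tr, mu_ref=0.02, gate_threshold_au=5.0) is None


def test_detector_recovers_latent_entrances_within_two_frames(wt_lineage, wt_traces, wt_events):
    latent = wt_lineage.latent_entrances()
    assert len(latent) >= 3
    det = {e.cell_id: e.arrest_time_min for e in wt_events}
    hits = 0
    for _, row in latent.iterrows():
        t_det = det.get(int(row.cell_id))
        if t_det is not None and abs(t_det - row.time_min) <= 2 * 15.0:
            hits += 1
    assert hits / len(latent) >= 0.9


def test_detector_is_silent_on_feedback_free_low_noise_lineages(wt_params):
    """Specificity: no events over 10,000 division events when the switch is
    disabled and noise is minimal."""
    p = wt_params.replace(n_B=1.0, V_B=0.0, sigma_eta=0.01)
    rec = simulate_lineage(p, 10_000, seed=8)
    assert rec.n_division_events == 10_000
    assert len(detect_entrances(rec.to_traces())) == 0


def test_reporter_rise_precedes_arrest_in_wild_type(wt_events):
    assert len(wt_events) >= 3
    assert precedence_fraction(wt_events) >= 0.9


def test_randomized_flags_give_half_precedence():
    rng = np.random.default_rng(0)
    from persisterkit.singlecell import EntranceEvent
    events = [EntranceEvent(i, 100.0, 50.0, 100.0 - 15.0 * flag, 3, bool(flag))
              for i, flag in enumerate(rng.integers(0, 2, 2000))]
    assert precedence_fraction(events) == pytest.approx(0.5, abs=0.05)


def test_arrest_fluorescence_maps_into_the_gtp_threshold_band(wt_events):
    """Estimated GTP at entrance (configured AU->mM calibration) lands in the
    0.1-0.2 mM dormancy band, and thresholds are consistent across events."""
    summary = threshold_consistency(wt_events)
    assert 0.1 <= summary["median_est_gtp_mm"] <= 0.2
    assert summary["cv_fluor"] < 0.8


def test_threshold_summary_requires_three_events(wt_events):
    with pytest.raises(ValueError):
        threshold_consistency(wt_events[:2])


def test_linear_data_prefers_the_linear_model():
    rng = np.random.default_rng(3)
    F = rng.uniform(0, 50, 800)
    mu = 0.03 - 4e-4 * F + rng.normal(0, 1.5e-3, 800)
    res = GrowthFluorescenceModel(F, mu).fit()
    assert res.preferred == "linear"


def test_hill_generated_data_recovers_its_steepness():
    rng = np.random.default_rng(4)
    F = rng.uniform(1, 60, 1500)
    true_h = 6.0
    mu = 0.03 / (1 + (F / 20.0) ** true_h) + rng.normal(0, 1.5e-3, 1500)
    res = GrowthFluorescenceModel(F, mu).fit()
    assert res.preferred == "sigmoidal" and res.conclusive
    lo, hi = res.hill_ci()
    assert lo <= true_h <= hi
    assert res.hill_coefficient == pytest.approx(true_h, rel=0.25)


def test_wild_type_relationship_is_switch_like_and_mutant_graded(wt_traces, wt_events):
    """Wild-type traces show a steep (switch-like) growth-fluorescence
    relationship; the alarmone-free GTP-lowered mutant a shallow, graded one."""
    sub = GrowthFluorescenceModel.sample_traces(wt_traces, wt_events, n_total=100, seed=0)
    res_wt = GrowthFluorescenceModel.from_traces(sub).fit()
    assert res_wt.preferred == "sigmoidal" and res_wt.conclusive
    assert res_wt.hill_coefficient > 4.0

    from persisterkit.mechanistic import load_default_params

    gmk = get_scenario("ppGpp0_gmk_Q110R_VAN")
    rec = simulate_lineage(load_default_params(), 6000, scenario=gmk, seed=5)
    traces = rec.to_traces(length_noise_cv=0.05, fluor_noise_cv=0.2, noise_seed=5)
    ev = detect_entrances(traces)
    msub = GrowthFluorescenceModel.sample_traces(traces, ev, n_total=100, seed=5)
    res_m = GrowthFluorescenceModel.from_traces(msub).fit()
    graded = res_m.preferred == "linear" or res_m.hill_coefficient < 3.5
    assert graded
    assert res_m.hill_coefficient < res_wt.hill_coefficient


def test_degenerate_fluorescence_range_withholds_comparison():
    with pytest.raises(ValueError, match="degenerate"):
        GrowthFluorescenceModel(np.full(100, 2.0), np.full(100, 0.02))


def test_trace_round_trip(tmp_path, wt_traces):
    subset = [tr for tr in wt_traces if tr.n_frames >= 3][:5]
    path = tmp_path / "traces.csv"
    write_traces(subset, path, seed=1)
    back = read_traces(path)
    assert len(back) == len(subset)
    a, b = subset[0], back[0]
    assert np.allclose(a.length_um, b.length_um)
    assert np.allclose(a.fluor_au, b.fluor_au)
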