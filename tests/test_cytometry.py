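"""Gating, autofluorescence subtraction, induced fractions, sort-and-kill."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from persisterkit.cytometry import (EventTable, gate_low_gtp, induced_fraction,
                                    read_event_table, sort_and_kill,
                                    subtract_autofluorescence,
                                    write_event_table)
from persisterkit.generators import generate_cytometry
from persisterkit.killcurve import biexponential_survival
from persisterkit.scenarios import get_scenario


def table(values, dormant=None, sample_id="t"):
    return EventTable(sample_id=sample_id, fluorescence=np.asarray(values, float),
                      dormant=dormant)


def test_subtracting_a_matched_control_centers_the_bulk_near_zero():
    rng = np.random.default_rng(0)
    sample = table(rng.lognormal(3, 0.3, 50_000))
    control = table(rng.lognormal(3, 0.3, 50_000))
    corr = subtract_autofluorescence(sample, control)
    # clamping at zero biases the mean upward; the bulk (median) sits at zero
    # and the residual mean is a small fraction of the original signal
    assert np.median(corr.fluorescence) == 0.0
    assert corr.fluorescence.mean() < 0.2 * sample.fluorescence.mean()
    assert corr.meta["n_clamped"] > 0  # clamping happened and was counted


def test_subtraction_removes_a_known_shift():
    rng = np.random.default_rng(1)
    base = rng.lognormal(2, 0.2, 20_000)
    corr = subtract_autofluorescence(table(base + 5.0), table(np.full(1000, 5.0)))
    assert corr.fluorescence.mean() == pytest.approx(base.mean(), rel=0.02)
    assert corr.meta["background_au"] == pytest.approx(5.0)


def test_control_brighter_than_sample_warns_loudly():
    corr = subtract_autofluorescence(table(np.ones(100)), table(np.full(100, 10.0)))
    assert corr.meta["warnings"]


def test_uniform_population_gates_nothing():
    g = gate_low_gtp(table(np.full(1000, 7.0)))
    assert g.fraction == 0.0


def test_two_point_mixture_gates_the_bright_weight():
    w = 0.005
    n = 200_000
    rng = np.random.default_rng(3)
    bright = rng.random(n) < w
    fl = np.where(bright, 100.0, 1.0)
    g = gate_low_gtp(table(fl))
    assert g.fraction == pytest.approx(w, rel=0.15)


@settings(derandomize=True, max_examples=30, deadline=None)
@given(scale=st.floats(min_value=1e-3, max_value=1e3),
       w=st.floats(min_value=0.0, max_value=0.05))
def test_gating_is_scale_invariant(scale, w):
    """Multiplying all corrected fluorescence by c > 0 leaves the gated
    fraction unchanged (the 5x-mean rule is relative)."""
    rng = np.random.default_rng(7)
    n = 5000
    bright = rng.random(n) < w
    fl = np.where(bright, 50.0, 1.0) * rng.lognormal(0, 0.2, n)
    f1 = gate_low_gtp(table(fl)).fraction
    f2 = gate_low_gtp(table(fl * scale)).fraction
    assert f1 == f2


def test_gated_fraction_monotone_in_weight_and_fold():
    rng = np.random.default_rng(11)
    n = 100_000
    base = rng.lognormal(0, 0.3, n)

    def frac(w, fold=5.0):
        bright = rng.random(n) < w  # nested draw: weights strictly ordered
        fl = np.where(bright, 60.0, 1.0) * base
        return gate_low_gtp(table(fl), fold=fold).fraction

    assert frac(0.0005) <= frac(0.005) <= frac(0.05)
    fl = np.where(np.random.default_rng(12).random(n) < 0.01, 60.0, 1.0) * base
    fr = [gate_low_gtp(table(fl), fold=f).fraction for f in (2.0, 5.0, 20.0)]
    assert fr[0] >= fr[1] >= fr[2]


def test_induced_fraction_is_a_floored_difference():
    rng = np.random.default_rng(5)
    fl = rng.lognormal(0, 0.3, 10_000)
    g = gate_low_gtp(table(fl))
    assert induced_fraction(g, g) == (0.0, False)
    # before > after floors at zero with the negative flag raised
    fl_hi = np.where(rng.random(10_000) < 0.01, 60.0, 1.0) * fl
    g_hi = gate_low_gtp(table(fl_hi))
    diff, neg = induced_fraction(g_hi, g)
    assert diff == 0.0 and neg


def test_induced_fraction_of_sublethal_pretreatment_is_positive():
    before = get_scenario("WT_bacitracin")
    after = get_scenario("WT_bacitracin_pretreated")
    gb = gate_low_gtp(subtract_autofluorescence(*generate_cytometry(before, 200_000, seed=8)))
    ga = gate_low_gtp(subtract_autofluorescence(*generate_cytometry(after, 200_000, seed=9)))
    diff, neg = induced_fraction(gb, ga)
    assert diff > 5e-3 and not neg


def test_mismatched_gating_rules_are_rejected():
    fl = np.random.default_rng(6).lognormal(0, 0.3, 5000)
    a = gate_low_gtp(table(fl), fold=5.0)
    b = gate_low_gtp(table(fl), fold=3.0)
    with pytest.raises(ValueError, match="mismatched"):
        induced_fraction(a, b)


def test_all_dormant_population_survives_at_the_persister_rate():
    fl = np.random.default_rng(2).lognormal(0, 0.3, 50_000)
    ev = table(fl, dormant=np.ones(50_000, dtype=bool))
    r = sort_and_kill(ev, top_fraction=0.01, k_s=4.6, k_p=0.0446, duration_h=5, seed=0)
    expected = math.exp(-0.0446 * 5)
    assert r.bright_survival == pytest.approx(expected, abs=0.05)
    assert r.dim_survival == pytest.approx(expected, abs=0.01)


def test_shuffled_labels_equalize_sorted_survival():
    """With dormancy labels randomized, sorting by fluorescence carries no
    information and both fractions survive equally (binomial error)."""
    rng = np.random.default_rng(13)
    n = 400_000
    fl = rng.lognormal(0, 0.3, n)
    labels = rng.random(n) < 0.3
    ev = table(fl, dormant=labels)
    r = sort_and_kill(ev, top_fraction=0.05, k_s=2.0, k_p=0.01, duration_h=2, seed=1)
    p = 0.3 * math.exp(-0.02) + 0.7 * math.exp(-4.0)
    se = math.sqrt(p * (1 - p) / (0.05 * n))
    assert abs(r.bright_survival - r.dim_survival) < 4 * se + 0.005


def test_wild_type_sort_and_kill_reproduces_the_survival_contrast():
    """Top 0.1% bright events survive ~80%; the dim remainder ~0.1%."""
    scen = get_scenario("WT_exponential_VAN")
    sample, _ = generate_cytometry(scen, 1_000_000, seed=3)
    r = sort_and_kill(sample, top_fraction=0.001, k_s=scen.kill_params.k_s,
                      k_p=scen.kill_params.k_p, duration_h=5.0, seed=4)
    assert 0.70 < r.bright_survival < 0.90
    assert 3e-4 < r.dim_survival < 2e-3


def test_sorting_everything_reproduces_the_bulk_biphasic_survival():
    scen = get_scenario("WT_exponential_VAN")
    sample, _ = generate_cytometry(scen, 300_000, seed=5)
    kp = scen.kill_params
    r = sort_and_kill(sample, top_fraction=1.0, k_s=kp.k_s, k_p=kp.k_p,
                      duration_h=5.0, seed=6)
    # latent weight (0.002) stands in for f in the closed form
    expected = biexponential_survival(5.0, scen.low_gtp_fraction, kp.k_s, kp.k_p)
    assert r.bright_survival == pytest.approx(float(expected), rel=0.25)


def test_small_sorted_fraction_warns_of_counting_noise():
    fl = np.random.default_rng(1).lognormal(0, 0.3, 5000)
    ev = table(fl, dormant=np.zeros(5000, dtype=bool))
    r = sort_and_kill(ev, top_fraction=0.001, seed=0)
    assert r.warnings


def test_size_gate_passes_central_scatter_band():
    rng = np.random.default_rng(4)
    ev = EventTable("s", rng.lognormal(0, 0.3, 10_000), scatter=rng.lognormal(0, 0.2, 10_000))
    gated = ev.size_gated(0.05, 0.95)
    assert gated.n_events == pytest.approx(0.9 * ev.n_events, rel=0.02)


def test_event_table_round_trip(tmp_path):
    scen = get_scenario("WT_exponential_VAN")
    sample, _ = generate_cytometry(scen, 5000, seed=7)
    path = tmp_path / "events.csv"
    write_event_table(sample, path, seed=7, scenario=scen.name)
    back = read_event_table(path)
    assert np.allclose(back.fluorescence, sample.fluorescence)
    assert np.array_equal(back.dormant, sample.dormant)
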