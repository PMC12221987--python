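"""Biphasic kill-curve fitting, MDK99 and condition comparison."""

import math

import numpy as np
import pytest

from persisterkit.generators import generate_kill_curve
from persisterkit.killcurve import (BiphasicKillModel, KillCurve,
                                    biexponential_survival, compare_conditions,
                                    fit_biphasic, mdk99, persister_fraction,
                                    read_kill_curves, write_kill_curves)
from persisterkit.scenarios import get_scenario

T7 = np.array([0.0, 0.25, 0.5, 1.0, 2.0, 3.0, 5.0])


def curve_from(f, k_s, k_p, N0=1e7, t=T7, condition="synthetic", rep=1):
    cfu = N0 * biexponential_survival(t, f, k_s, k_p)
    return KillCurve(condition, rep, t, cfu)


def test_noiseless_parameters_are_recovered_to_high_precision():
    r = fit_biphasic(curve_from(0.001, 4.6, 0.01))
    assert r.biphasic
    assert abs(r.f - 0.001) / 0.001 < 1e-6
    assert abs(r.k_s - 4.6) / 4.6 < 1e-6
    assert abs(r.k_p - 0.01) / 0.01 < 1e-6


def test_single_exponential_input_reports_non_biphasic():
    t = T7
    c = KillCurve("single", 1, t, 1e7 * np.exp(-3.0 * t))
    r = fit_biphasic(c)
    assert not r.biphasic
    assert r.f == 0.0
    assert r.k_s == pytest.approx(3.0, rel=1e-6)


def test_wild_type_scenario_plateau_is_about_a_thousandth():
    curves = generate_kill_curve(get_scenario("WT_exponential_VAN"), n_reps=3, seed=0)
    fs = [fit_biphasic(c).f for c in curves]
    assert np.mean(fs) == pytest.approx(1e-3, rel=0.35)


def test_mdk99_closed_form_and_invariance():
    # persister-free limit: MDK99 equals ln(100)/k_s of the fit to 1e-9
    k_s = math.log(100) / 2.0
    r = fit_biphasic(curve_from(1e-9, k_s, 0.0))
    assert abs(r.mdk99 - math.log(100) / r.k_s) < 1e-9
    assert r.mdk99 == pytest.approx(2.0, rel=1e-6)
    # with persister subtraction, MDK99 is a pure k_s property: invariant to f
    mdks = [mdk99(fit_biphasic(curve_from(f, 4.6, 0.02))) for f in (1e-4, 1e-3, 1e-2, 0.2)]
    assert np.allclose(mdks, math.log(100) / 4.6, atol=1e-9)


def test_mdk99_decreases_with_faster_susceptible_killing():
    vals = [fit_biphasic(curve_from(1e-3, ks, 0.02)).mdk99 for ks in (2.0, 4.0, 8.0)]
    assert vals[0] > vals[1] > vals[2]


def test_fit_is_idempotent_on_its_own_parameters():
    r1 = fit_biphasic(curve_from(3e-3, 5.0, 0.03))
    r2 = fit_biphasic(curve_from(r1.f, r1.k_s, r1.k_p))
    assert r2.f == pytest.approx(r1.f, rel=1e-6)
    assert r2.k_s == pytest.approx(r1.k_s, rel=1e-6)
    assert r2.k_p == pytest.approx(r1.k_p, rel=1e-6)


def test_plateau_and_endpoint_agree_on_undying_persisters():
    c = curve_from(2e-3, 4.6, 0.0)
    plateau = persister_fraction(c, "plateau")
    endpoint = persister_fraction(c, "endpoint", endpoint_h=5.0)
    assert endpoint == pytest.approx(plateau, rel=1e-3)


def test_endpoint_without_five_hour_sample_interpolates_or_errors():
    c = curve_from(2e-3, 4.6, 0.0, t=np.array([0.0, 0.5, 1.0, 4.0, 6.0]))
    assert persister_fraction(c, "endpoint") == pytest.approx(2e-3, rel=0.05)
    c2 = curve_from(2e-3, 4.6, 0.0, t=np.array([0.0, 0.5, 1.0, 2.0]))
    with pytest.raises(ValueError, match="bracketed"):
        persister_fraction(c2, "endpoint")


def test_parameter_recovery_across_the_regime_grid():
    """Median relative error of the recovered persister fraction stays under
    25% across (f, k_s, k_p) regimes at 3 replicates x 6 timepoints with
    plating noise."""
    import dataclasses
    from persisterkit.scenarios import KillParams
    base = get_scenario("WT_exponential_VAN")
    t6 = (0.0, 0.5, 1.0, 2.0, 3.0, 5.0)
    rel_errs = []
    seed = 0
    for f in (1e-4, 1e-2, 0.5):
        for k_s in (1.5, 4.6, 9.0):
            for k_p in (0.0, 0.04):
                scen = dataclasses.replace(base, kill_params=KillParams(
                    f=f, k_s=k_s, k_p=k_p, N0=1e7))
                curves = generate_kill_curve(scen, t6, n_reps=3, seed=seed)
                seed += 1
                fhat = np.mean([fit_biphasic(c).f for c in curves])
                rel_errs.append(abs(fhat - f) / f)
    assert np.median(rel_errs) < 0.25


def test_fully_censored_curve_is_unfittable():
    t = np.array([0.0, 1.0, 2.0, 3.0, 5.0])
    c = KillCurve("dead", 1, t, np.full(t.size, 10.0),
                  below_detection=np.ones(t.size, dtype=bool))
    with pytest.raises(ValueError, match="detection"):
        fit_biphasic(c)


def test_censored_tail_still_recovers_the_kill_rate():
    t = T7
    true = 1e5 * np.exp(-4.0 * t)
    below = true < 10.0
    cfu = np.where(below, 10.0, true)
    r = fit_biphasic(KillCurve("cens", 1, t, cfu, below_detection=below))
    assert r.k_s == pytest.approx(4.0, rel=0.05)


def test_curve_validation_rules():
    with pytest.raises(ValueError, match="t=0"):
        KillCurve("x", 1, np.array([0.5, 1.0, 2.0, 5.0]), np.ones(4))
    with pytest.raises(ValueError, match="ascending"):
        KillCurve("x", 1, np.array([0.0, 2.0, 1.0]), np.ones(3))
    with pytest.raises(ValueError, match="limit"):
        KillCurve("x", 1, np.array([0.0, 1.0]), np.array([1e7, 0.0]),
                  below_detection=np.array([False, True]))


def test_comparison_of_identical_groups_is_a_unit_fold():
    fits = [fit_biphasic(curve_from(1e-3, 4.6, 0.02, rep=i)) for i in range(3)]
    res = compare_conditions(fits, fits, metric="f")
    assert res.fold_change == pytest.approx(1.0)


def test_alarmone_null_reduces_persistence_about_tenfold():
    wt = [fit_biphasic(c) for c in
          generate_kill_curve(get_scenario("WT_exponential_VAN"), n_reps=3, seed=21)]
    null = [fit_biphasic(c) for c in
            generate_kill_curve(get_scenario("ppGpp0_VAN"), n_reps=3, seed=22)]
    res = compare_conditions(wt, null, metric="f")
    assert 5 < res.fold_change < 18
    assert res.p_value < 0.05


def test_starvation_pretreatment_boosts_persistence_hundreds_fold():
    wt = [fit_biphasic(c) for c in
          generate_kill_curve(get_scenario("WT_exponential_VAN"), n_reps=3, seed=23)]
    rhx = [fit_biphasic(c) for c in
           generate_kill_curve(get_scenario("WT_RHX_VAN"), n_reps=3, seed=24)]
    res = compare_conditions(rhx, wt, metric="f")
    assert 300 < res.fold_change < 800
    assert res.p_value < 0.05


def test_csv_round_trip_preserves_curves(tmp_path):
    curves = generate_kill_curve(get_scenario("WT_exponential_VAN"), n_reps=2, seed=4)
    path = tmp_path / "curves.csv"
    write_kill_curves(curves, path, seed=4, scenario="WT_exponential_VAN")
    back = read_kill_curves(path)
    assert len(back) == 2
    for a, b in zip(curves, back):
        assert np.allclose(a.cfu, b.cfu)
        assert np.array_equal(a.below_detection, b.below_detection)


def test_summary_renders_the_fit(tmp_path):
    r = fit_biphasic(curve_from(1e-3, 4.6, 0.02))
    s = r.summary()
    assert "biphasic" in s and "MDK99" in s


def test_model_from_dataframe_matches_direct_fit():
    import pandas as pd
    c = curve_from(5e-3, 3.0, 0.01)
    df = pd.DataFrame({"condition": "synthetic", "replicate": 1,
                       "time_h": c.time_h, "cfu_per_ml": c.cfu})
    r = BiphasicKillModel.from_dataframe(df, condition="synthetic", replicate=1).fit()
    assert r.f == pytest.approx(5e-3, rel=1e-5)
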