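"""Decay-fit unit, oracle and property tests.

The window-selection rule (longest window whose fitted slope reproduces
the known air-exchange rate) is validated against a brute-force
enumeration of every candidate window, and the fit itself against exact
synthetic exponentials and simulator round-trips.
"""

import numpy as np
import pytest
from scipy import stats

from rmmeff import (ConcentrationTrace, EECEstimator, NoiseModel,
                    NoPreEventDataError, TransferEvent, UnfittableTraceError,
                    compute_eec, estimate_background, fit_decay,
                    mean_concentration_between, select_decay_window,
                    simulate_preset, summarize_scenario)
from rmmeff.simulate import NOISELESS, RoomModelParams, simulate_trace

from conftest import MULT_ONLY


# -- background ------------------------------------------------------------

def test_background_constant_trace(exp_trace):
    tr = exp_trace(eec=0.0, background=1.0)
    assert estimate_background(tr) == 1.0


def test_background_median_robust_to_spike(exp_trace):
    tr = exp_trace(eec=50.0, background=2.0)
    tr.conc_ppm[3] = 50.0  # one movement spike in the pre-event window
    assert estimate_background(tr) == 2.0


def test_background_simulator_round_trip():
    tr = simulate_preset(1, noise=NoiseModel(multiplicative_sd=0.05,
                                             spike_rate_per_min=0.0, seed=1),
                         background_ppm=1.5)
    assert estimate_background(tr) == pytest.approx(1.5, rel=0.05)


def test_background_requires_pre_event_samples(exp_trace):
    tr = exp_trace(t_start=60.0, t_end=300.0)  # only 3 pre-event samples
    with pytest.raises(NoPreEventDataError):
        estimate_background(tr)


# -- window selection ------------------------------------------------------

def brute_force_window(trace, background, target, tol=1.0, min_points=5,
                       max_offset=10, floor_abs=0.1, floor_frac=0.01):
    """Independent exhaustive enumeration of every candidate window."""
    i0 = int(np.searchsorted(trace.times_s, trace.event.t_end_s, "left"))
    excess = trace.conc_ppm[i0:] - background
    floor = max(floor_abs, floor_frac * excess.max())
    run = len(excess)
    for i, e in enumerate(excess):
        if e <= floor:
            run = i
            break
    best = None
    for s in range(0, min(max_offset, run - min_points) + 1):
        for n in range(min_points, run - s + 1):
            idx = slice(i0 + s, i0 + s + n)
            x = (trace.times_s[idx] - trace.event.t_end_s) / 60.0
            res = stats.linregress(x, np.log(trace.conc_ppm[idx] - background))
            ach = -res.slope * 60.0
            if abs(ach - target) <= tol:
                key = (n, res.rvalue ** 2, -s)
                if best is None or key > best[0]:
                    best = (key, (i0 + s, i0 + s + n))
    return None if best is None else best[1]


def test_perfect_data_selects_all_post_points(exp_trace):
    tr = exp_trace(eec=100.0, ach=11.0, background=0.0)
    bg = estimate_background(tr)
    i0 = int(np.searchsorted(tr.times_s, tr.event.t_end_s))
    win = select_decay_window(tr, bg)
    # all post-event points above the positivity floor (1 ppm = 1% of peak)
    expected_len = int(np.sum(tr.conc_ppm[i0:] - bg > 1.0))
    assert win == (i0, i0 + expected_len)


def test_wrong_decay_rate_is_unfittable(exp_trace):
    tr = exp_trace(eec=100.0, ach=22.0, target_ach=11.0)
    with pytest.raises(UnfittableTraceError) as exc:
        select_decay_window(tr, 0.0)
    assert exc.value.best_ach_fit == pytest.approx(22.0, abs=0.2)


def test_window_matches_exhaustive_oracle():
    tr = simulate_preset(2, noise=NoiseModel(seed=5))
    bg = estimate_background(tr)
    win = select_decay_window(tr, bg)
    assert win == brute_force_window(tr, bg, tr.target_ach)
    fit = fit_decay(tr, win, bg)
    assert abs(fit.ach_fit - 11.0) <= 1.0


@pytest.mark.parametrize("seed", range(6))
def test_selected_window_always_satisfies_constraint(seed):
    tr = simulate_preset(4, noise=NoiseModel(seed=seed))
    bg = estimate_background(tr)
    win = select_decay_window(tr, bg)
    assert abs(fit_decay(tr, win, bg).ach_fit - tr.target_ach) <= 1.0


# -- decay fit -------------------------------------------------------------

def test_exact_exponential_fit(exp_trace):
    # 100 * exp(-0.1833 t_min): ach = 11.0 to three significant figures
    tr = exp_trace(eec=100.0, ach=0.1833 * 60.0, background=0.0)
    bg = estimate_background(tr)
    fit = fit_decay(tr, select_decay_window(tr, bg), bg)
    assert fit.eec_ppm == pytest.approx(100.0, rel=1e-9)
    assert fit.ach_fit == pytest.approx(11.0, abs=0.005)
    assert fit.ach_fit == 60.0 * fit.k_per_min
    assert fit.r_squared == pytest.approx(1.0, abs=1e-9)


def test_background_shift_invariance(exp_trace):
    tr0 = exp_trace(eec=100.0, ach=11.0, background=0.0)
    tr2 = exp_trace(eec=100.0, ach=11.0, background=2.0)
    w0 = select_decay_window(tr0, 0.0)
    f0 = fit_decay(tr0, w0, 0.0)
    f2 = fit_decay(tr2, w0, 2.0)
    assert f2.eec_ppm == pytest.approx(f0.eec_ppm, rel=1e-12)
    assert f2.k_per_min == pytest.approx(f0.k_per_min, rel=1e-12)


def test_noisy_baseline_recovery():
    tr = simulate_preset(1, noise=MULT_ONLY)
    fit = compute_eec(tr)
    assert fit.eec_ppm == pytest.approx(454.0, rel=0.10)


def test_window_with_subbackground_sample_rejected(exp_trace):
    tr = exp_trace(eec=100.0, ach=11.0, background=5.0)
    i0 = int(np.searchsorted(tr.times_s, tr.event.t_end_s))
    with pytest.raises(ValueError):
        fit_decay(tr, (i0, i0 + 10), 200.0)  # background above the data


# -- compute_eec -----------------------------------------------------------

def test_compute_eec_scenario1_round_trip(baseline_noiseless):
    fit = compute_eec(baseline_noiseless)
    assert fit.eec_ppm == pytest.approx(454.0, rel=5e-3)


def test_flat_trace_is_noe(exp_trace):
    tr = exp_trace(eec=0.0, background=1.0)
    fit = compute_eec(tr)
    assert fit.is_noe
    assert np.isnan(fit.eec_ppm)


def test_zero_excursion_scenario_is_noe():
    # full enclosure: source fully captured, nothing above background
    tr = simulate_preset(3)  # noiseless preset with zero source
    assert compute_eec(tr).is_noe


def test_compute_eec_rejects_drain_flush_kind():
    tr = simulate_preset(9)
    with pytest.raises(ValueError, match="transfer"):
        compute_eec(tr)


# -- sklearn-style estimator ----------------------------------------------

def test_estimator_api(exp_trace):
    tr = exp_trace(eec=100.0, ach=11.0, background=0.0)
    est = EECEstimator(ach_tol=1.0)
    est.fit(tr.times_s, tr.conc_ppm, t_start_s=tr.event.t_start_s,
            t_end_s=tr.event.t_end_s, target_ach=11.0)
    assert est.eec_ppm_ == pytest.approx(100.0, rel=1e-9)
    assert est.ach_fit_ == pytest.approx(11.0, abs=1e-9)
    # predict reproduces the decay limb
    post = tr.times_s >= tr.event.t_end_s
    np.testing.assert_allclose(est.predict(tr.times_s[post]),
                               tr.conc_ppm[post], rtol=1e-9, atol=1e-9)
    # get_params/set_params round-trip (sklearn contract)
    params = est.get_params()
    assert params["ach_tol"] == 1.0
    est2 = EECEstimator().set_params(**params)
    assert est2.get_params() == params
    # (n, 2) single-argument form
    est3 = EECEstimator(ach_tol=1.0).fit(
        np.column_stack([tr.times_s, tr.conc_ppm]),
        t_start_s=tr.event.t_start_s, t_end_s=tr.event.t_end_s,
        target_ach=11.0)
    assert est3.eec_ppm_ == pytest.approx(est.eec_ppm_)


def test_estimator_nls_refinement_matches_on_clean_data(exp_trace):
    tr = exp_trace(eec=100.0, ach=11.0, background=0.0)
    est = EECEstimator(method="nls")
    est.fit_trace(tr, background_ppm=0.0)
    assert est.eec_ppm_ == pytest.approx(100.0, rel=1e-6)
    assert est.ach_fit_ == pytest.approx(11.0, rel=1e-6)


# -- scale / shift properties ---------------------------------------------

@pytest.mark.parametrize("c", [0.5, 2.0, 10.0])
def test_scale_equivariance(baseline_noiseless, c):
    f0 = compute_eec(baseline_noiseless)
    fc = compute_eec(baseline_noiseless.scaled(c))
    assert fc.eec_ppm == pytest.approx(c * f0.eec_ppm, rel=1e-9)
    assert fc.ach_fit == pytest.approx(f0.ach_fit, abs=1e-9)


def test_time_shift_invariance(baseline_noiseless):
    f0 = compute_eec(baseline_noiseless)
    fs = compute_eec(baseline_noiseless.shifted(600.0))
    assert fs.eec_ppm == pytest.approx(f0.eec_ppm, rel=1e-12)
    assert fs.k_per_min == pytest.approx(f0.k_per_min, abs=1e-12)


@pytest.mark.parametrize("eec", [1.0, 10.0, 100.0, 454.0])
@pytest.mark.parametrize("ach", [1.0, 11.0])
def test_noiseless_recovery_spot_checks(eec, ach):
    from rmmeff import calibrated_source_rate
    src = calibrated_source_rate(eec, ach, 4.0)
    params = RoomModelParams(ach=ach, background_ppm=1.0, source_rate=src,
                             duration_s=480 + (3600 if ach <= 2 else 1800))
    tr = simulate_trace(params, TransferEvent(240, 480), NOISELESS)
    fit = compute_eec(tr)
    assert fit.eec_ppm == pytest.approx(eec, rel=1e-3)
    assert fit.ach_fit == pytest.approx(ach, abs=1e-6)


# -- drain/flush mean ------------------------------------------------------

def test_mean_between_constant():
    t = np.arange(0, 1200, 20.0)
    c = np.full_like(t, 2.5)
    tr = ConcentrationTrace(t, c, TransferEvent(240, 480), target_ach=1.0,
                            trace_kind="drain_flush")
    assert mean_concentration_between(tr) == 2.5


def test_mean_between_arithmetic():
    t = np.arange(0, 200, 20.0)
    c = np.ones_like(t)
    c[[3, 4, 5]] = [2.0, 3.0, 4.0]
    tr = ConcentrationTrace(t, c, TransferEvent(60, 100), target_ach=1.0,
                            trace_kind="drain_flush")
    assert mean_concentration_between(tr) == pytest.approx(3.0)


def test_mean_between_simulator_round_trip():
    clean = simulate_preset(9)
    target = mean_concentration_between(clean)
    noisy = simulate_preset(9, noise=NoiseModel(seed=2))
    assert mean_concentration_between(noisy) == pytest.approx(target, rel=0.10)


def test_mean_between_rejects_transfer_kind(baseline_noiseless):
    with pytest.raises(ValueError, match="drain/flush"):
        mean_concentration_between(baseline_noiseless)


# -- replicate summary -----------------------------------------------------

@pytest.mark.parametrize("values, mean, cv", [
    ([12, 14, 13], 13.0, 7.7),
    ([5, 5, 5], 5.0, 0.0),
    ([454, 424, 410, 430, 553], 454.0, 12.7),
])
def test_summarize_scenario(values, mean, cv):
    s = summarize_scenario(values, 1)
    assert round(s.mean_ppm) == round(mean)
    assert round(s.cv_percent, 1) == cv
    assert s.min_ppm <= s.mean_ppm <= s.max_ppm


def test_summarize_rejects_bad_input():
    with pytest.raises(ValueError):
        summarize_scenario([5.0], 1)
    with pytest.raises(ValueError):
        summarize_scenario([1.0, -2.0], 1)
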