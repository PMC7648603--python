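import numpy as np
import pytest

from rugard.ruga_quant import (
    CalibrationCurves,
    ExpressionProfile,
    align_and_pair_shelves,
    build_kymograph,
    extract_ruga_calls,
    fit_calibration,
    onset_correlation_profile,
    shift_statistics,
    stage_from_weight_and_length,
)
from rugard.synthetic_data import SyntheticCohortSpec, synth_profile_series


def _profile(x, y, **kw):
    return ExpressionProfile(positions=np.asarray(x, float), intensity=np.asarray(y, float), **kw)


def test_triangular_stripe_boundaries_at_half_height():
    x = np.arange(0.0, 101.0)
    y = np.clip(1.0 - np.abs(x - 50.0) / 20.0, 0.0, 1.0)
    calls = extract_ruga_calls(_profile(x, y))
    assert len(calls) == 1
    c = calls[0]
    assert c.left == pytest.approx(40.0, abs=0.6)
    assert c.right == pytest.approx(60.0, abs=0.6)
    assert c.position == pytest.approx(50.0, abs=0.6)
    assert c.intensity == pytest.approx(1.0)


def _two_stripe_profile(trough_fill):
    x = np.arange(0.0, 201.0)
    bump = lambda c, w=12.0: np.exp(-0.5 * ((x - c) / w) ** 2)
    y = bump(70) + bump(130) + trough_fill * bump(100, 30.0)
    return x, np.clip(y / y.max(), 0, 1)


def test_fusion_threshold_separates_and_merges():
    deep = extract_ruga_calls(_profile(*_two_stripe_profile(0.0)))
    assert len(deep) == 2 and not any(c.fused for c in deep)
    shallow = extract_ruga_calls(_profile(*_two_stripe_profile(0.75)))
    assert len(shallow) == 2 and all(c.fused for c in shallow)


def test_synthetic_stripe_recovery():
    spec = SyntheticCohortSpec(n_specimens=1, noise_additive=0.0, noise_multiplicative=0.0, seed=1)
    age = 13.84  # between stripe onsets, so every stripe is fully switched on
    from rugard.synthetic_data import _specimen_profile

    rng = np.random.default_rng(0)
    prof = _specimen_profile(spec, rng, age, "Shh", "s0")
    truth = spec.stripe_positions(age)
    calls = extract_ruga_calls(prof)
    found = np.array(sorted(c.position for c in calls))
    assert len(found) == len(truth)
    assert np.all(np.abs(found - truth) <= spec.sample_step)
    # widths: half-height width of the raised-cosine bump is half its full width
    interior = [c for c in calls if not c.edge_unreliable][1:]
    for c in interior:
        assert c.width == pytest.approx(spec.stripe_width / 2.0, rel=0.2)


def test_identical_shelves_pair_with_zero_deltas():
    spec = SyntheticCohortSpec(n_specimens=1, noise_additive=0.0, noise_multiplicative=0.0, seed=2)
    from rugard.synthetic_data import _specimen_profile

    prof = _specimen_profile(spec, np.random.default_rng(1), 13.5, "Shh", "s")
    calls = extract_ruga_calls(prof)
    df = align_and_pair_shelves(calls, prof, calls, prof)
    assert np.allclose(df.d_position, 0.0)
    assert np.allclose(df.d_width, 0.0)
    assert np.allclose(df.d_intensity, 0.0)
    assert df.posterior.sum() == 2


def test_lost_ruga_recorded_with_zero_width():
    x = np.arange(0.0, 400.0)
    bump = lambda c: np.exp(-0.5 * ((x - c) / 10.0) ** 2)
    ctrl_y = bump(100) + bump(200) + bump(300)
    trt_y = bump(100) + bump(300)  # middle stripe lost under treatment
    ctrl = _profile(x, ctrl_y / ctrl_y.max(), ruga8=100.0)
    trt = _profile(x, trt_y / trt_y.max(), ruga8=100.0)
    df = align_and_pair_shelves(extract_ruga_calls(trt), trt, extract_ruga_calls(ctrl), ctrl)
    lost = df[df.status == "lost"]
    assert len(lost) == 1
    assert lost.iloc[0].treated_width == 0.0
    assert lost.iloc[0].treated_intensity < 0.2


def test_shift_statistics_null_and_inflated():
    rng = np.random.default_rng(3)
    import pandas as pd

    null = pd.DataFrame(
        {
            "d_position": rng.normal(0, 5, 400),
            "d_width": rng.normal(0, 4, 400),
            "d_intensity": rng.normal(0, 0.05, 400),
        }
    )
    inflated = null.copy()
    med = null.d_width.abs().median()
    inflated["d_width"] = 3.0 * med + rng.normal(0, 0.1, 400)
    stats = shift_statistics(null, {"null": null, "wide": inflated})
    w_null = stats[(stats.measurement == "width") & (stats.treatment == "null")].iloc[0]
    assert w_null.fraction_above == pytest.approx(0.25, abs=0.07)
    assert w_null.fraction_below == pytest.approx(0.25, abs=0.07)
    w_wide = stats[(stats.measurement == "width") & (stats.treatment == "wide")].iloc[0]
    assert w_wide.fraction_above > 0.95


def test_calibration_exact_at_knots_and_monotone():
    cal = CalibrationCurves(
        weight_knots=np.array([50.0, 100.0, 200.0]),
        weight_ages=np.array([12.5, 13.0, 14.0]),
        distance_knots=np.array([300.0, 600.0, 1200.0]),
        distance_ages=np.array([12.5, 13.0, 14.0]),
    )
    ages, flagged = stage_from_weight_and_length([100.0], [600.0], cal)
    assert ages[0] == pytest.approx(13.0)
    assert not flagged[0]
    d = np.linspace(300, 1200, 30)
    a, _ = stage_from_weight_and_length(np.full(30, 100.0), d, cal)
    assert np.all(np.diff(a) >= 0)


def test_synthetic_age_recovery_within_tolerance():
    spec = SyntheticCohortSpec(n_specimens=50, seed=9)
    profiles, truth = synth_profile_series(spec)
    cal = fit_calibration(truth.weight_mg, truth.d38, truth.age)
    ages, _ = stage_from_weight_and_length(truth.weight_mg, truth.d38, cal)
    rms = float(np.sqrt(np.mean((ages - truth.age) ** 2)))
    assert rms < 0.05


def test_kymograph_row_equals_profile_for_identical_specimens():
    x = np.arange(0.0, 500.0, 10.0)
    y = 0.5 + 0.4 * np.sin(2 * np.pi * x / 150.0)
    y = np.clip(y, 0, 1)
    p1 = _profile(x, y, ruga3=400.0, ruga8=50.0)
    p2 = _profile(x, y, ruga3=400.0, ruga8=50.0)
    kym = build_kymograph([p1, p2], ages=[13.0, 13.0], n_time=30, time_range=(12.9, 13.1))
    row = np.where(~kym.mask.all(axis=1))[0]
    assert row.size > 0
    ti = row[0]
    good = ~kym.mask[ti]
    expect = np.interp(kym.ap[good] + (50.0 - 400.0) + 400.0, x, y)
    assert np.allclose(kym.intensity[ti, good], expect, atol=1e-8)


def test_single_trace_windows_are_masked():
    x = np.arange(0.0, 300.0, 10.0)
    y = np.clip(0.5 + 0.4 * np.sin(x / 30.0), 0, 1)
    p1 = _profile(x, y, ruga3=250.0, ruga8=20.0)
    p2 = _profile(x, y, ruga3=250.0, ruga8=20.0)
    kym = build_kymograph([p1, p2], ages=[12.6, 13.9], n_time=40, time_range=(12.5, 14.0))
    assert kym.mask.all()  # no window ever holds two traces


def test_onset_correlation_identical_and_inverted():
    spec = SyntheticCohortSpec(n_specimens=40, seed=4)
    profiles, truth = synth_profile_series(spec)
    shh = [p for p in profiles if p.gene == "Shh"]
    ages = dict(zip(truth.specimen_id, truth.age))
    a = [ages[p.specimen_id] for p in shh]
    kym = build_kymograph(shh, a, n_time=120)
    res = onset_correlation_profile(kym, kym, n_boot=50, seed=0)
    good = ~np.isnan(res["rho"])
    assert np.allclose(res["rho"][good], 1.0)
    inverted = build_kymograph(shh, a, n_time=120)
    inverted.intensity = np.where(
        np.isnan(kym.intensity), np.nan, 1.0 - kym.intensity
    )
    res2 = onset_correlation_profile(inverted, kym, n_boot=50, seed=0)
    good2 = ~np.isnan(res2["rho"])
    assert np.allclose(res2["rho"][good2], -1.0)
    assert res2["onset_negative"] is not None


def test_bootstrap_ci_contains_point_estimate():
    spec = SyntheticCohortSpec(n_specimens=30, seed=5)
    profiles, truth = synth_profile_series(spec)
    ages = dict(zip(truth.specimen_id, truth.age))
    shh = [p for p in profiles if p.gene == "Shh"]
    gli = [p for p in profiles if p.gene == "Gli1"]
    a_s = [ages[p.specimen_id] for p in shh]
    a_g = [ages[p.specimen_id] for p in gli]
    k_s = build_kymograph(shh, a_s, n_time=100)
    k_g = build_kymograph(gli, a_g, n_time=100)
    res = onset_correlation_profile(k_g, k_s, n_boot=60, seed=1)
    good = ~np.isnan(res["rho"])
    lo, hi = res["ci"][good, 0], res["ci"][good, 1]
    inside = (res["rho"][good] >= lo - 1e-9) & (res["rho"][good] <= hi + 1e-9)
    assert inside.mean() > 0.9
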