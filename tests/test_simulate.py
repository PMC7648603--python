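import numpy as np
import pytest

from rugard.rd_core import SignedTopology, sample_parameter_set
from rugard.simulate import (
    detect_stable_pattern,
    integrate_batch,
    integrate_rd,
    measure_waves,
)
from rugard.stability import dispersion_relation, rescale_for_domain
from rugard.perturb import sample_ddi_sets
from tests.test_stability import _two_comp


def test_zero_reaction_conserves_mass():
    rng = np.random.default_rng(0)
    init = rng.uniform(0.5, 1.5, size=(1, 50, 2))
    snaps, _ = integrate_batch(
        a=np.zeros((1, 2, 2)),
        b=np.zeros((1, 2)),
        c=np.zeros((1, 2)),
        fmax=np.ones((1, 2)),
        D=np.array([[0.3, 0.05]]),
        T=200.0,
        init=init,
        production_scale=np.zeros((1, 2)),  # kill production entirely
    )
    total0 = snaps[0, 0].sum(axis=0)
    totalT = snaps[-1, 0].sum(axis=0)
    assert np.allclose(total0, totalT, rtol=0, atol=1e-10 * total0.max())


def test_stable_system_relaxes_to_uniform_equilibrium():
    p = _two_comp(0.4, -1.0, 1.0, -0.9, D1=1e-3, D2=1e-3)  # no DDI
    field = integrate_rd(p, T=300.0, seed=1)
    final = field.final
    assert np.allclose(final, 1.0, atol=1e-3)
    v = detect_stable_pattern(field)
    assert v["stable"] and not v["patterned"]
    assert v["metrics"].wave_count == 0.0


def test_wave_counting_on_sinusoids():
    x = np.linspace(0, 1, 400)
    assert measure_waves(np.sin(2 * np.pi * 3 * x))["wave_count"] == pytest.approx(3.0)
    assert measure_waves(np.full(50, 0.7))["wave_count"] == 0.0
    frac = measure_waves(np.sin(2 * np.pi * 3.5 * x))["wave_count"]
    assert abs(frac - 3.5) <= 0.5


def test_peaks_and_troughs_alternate():
    x = np.linspace(0, 1, 300)
    m = measure_waves(np.sin(2 * np.pi * 3 * x))
    merged = sorted(
        [(i, "p") for i in m["peak_positions"]] + [(i, "t") for i in m["trough_positions"]]
    )
    kinds = [k for _, k in merged]
    assert all(a != b for a, b in zip(kinds, kinds[1:]))


def test_identical_seeds_are_bit_reproducible():
    p = _two_comp(0.4, -1.0, 1.0, -0.9, D1=1e-3, D2=0.5)
    f1 = integrate_rd(p, T=50.0, seed=123)
    f2 = integrate_rd(p, T=50.0, seed=123)
    assert np.array_equal(f1.final, f2.final)


def test_halving_dt_barely_changes_the_pattern():
    p = rescale_for_domain(
        _two_comp(0.4, -1.0, 1.0, -0.9, D1=1e-3, D2=0.5), 100, 3.0, 0.1
    )
    from rugard.simulate import _stable_dt

    dt = _stable_dt(p.a[None], p.c[None], p.D[None], 1.0)
    f1 = integrate_rd(p, T=200.0, seed=5, dt=dt)
    f2 = integrate_rd(p, T=200.0, seed=5, dt=dt / 2)
    scale = np.max(np.abs(f1.final))
    assert np.max(np.abs(f1.final - f2.final)) / scale < 1e-3


def test_realised_wavelength_matches_dispersion_prediction():
    top = SignedTopology(sign=((1, -1), (1, 0)), autoreg=(True, False))
    sets = sample_ddi_sets(top, 14, seed=21)
    checked = 0
    for p in sets:
        s = rescale_for_domain(p, 100, 3.0, 0.1)
        from rugard.simulate import _stable_dt

        if 300.0 / _stable_dt(s.a[None], s.c[None], s.D[None], 1.0) > 60_000:
            continue
        field = integrate_rd(s, T=300.0, seed=3)
        v = detect_stable_pattern(field, tol=1e-2)
        if not v["patterned"]:
            continue
        lam = dispersion_relation(s).wavelength
        predicted_waves = 100.0 / lam
        assert abs(v["metrics"].wave_count - predicted_waves) <= 1.0
        checked += 1
    assert checked >= 2
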