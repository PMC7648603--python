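import numpy as np
import pytest

from rugard.rd_core import InhibitionSpec, SignedTopology
from rugard.examples import two_fgf_parameters
from rugard.perturb import (
    ALPHA_LADDER,
    apply_production_inhibition,
    apply_response_inhibition,
    classify_wave_shift,
    perturbation_screen,
)
from rugard.simulate import WaveMetrics


def test_response_inhibition_limits():
    p = two_fgf_parameters()
    assert np.array_equal(apply_response_inhibition(p, 1, 0.0).a, p.a)
    assert np.all(apply_response_inhibition(p, 1, 1.0).a[:, 1] == 0.0)


def test_response_inhibition_on_printed_set():
    # halving the response to eFGF halves its outgoing weights
    p = two_fgf_parameters()
    out = apply_response_inhibition(p, 1, 0.5)
    assert out.a[0, 1] == pytest.approx(-0.0095)
    assert out.a[2, 1] == pytest.approx(-0.011)


def test_response_inhibition_composes_multiplicatively():
    p = two_fgf_parameters()
    twice = apply_response_inhibition(apply_response_inhibition(p, 1, 0.4), 1, 0.5)
    once = apply_response_inhibition(p, 1, 1 - 0.6 * 0.5)
    assert np.allclose(twice.a, once.a)


def test_production_inhibition_scale_vector():
    p = two_fgf_parameters()
    p2, scale = apply_production_inhibition(p, 2, 0.75)
    assert np.array_equal(p2.a, p.a)
    assert np.allclose(scale, [1.0, 1.0, 0.25])


def test_complete_production_inhibition_decays_component():
    # with production fully blocked the component follows du/dt = -c u
    p = two_fgf_parameters()
    from rugard.simulate import integrate_rd

    field = integrate_rd(
        p, T=200.0, seed=0, production_scale=np.array([1.0, 1.0, 0.0])
    )
    assert field.final[:, 2].max() < 1e-2


def test_alpha_ladder_is_geometric():
    assert ALPHA_LADDER == (1.0, 0.25, 0.0625, 0.015625)


def _metrics(mean, peaks, troughs, amp=1.0, waves=3.0):
    n = len(mean)
    return WaveMetrics(
        wave_count=waves,
        mean_level=np.array(mean, float),
        peak_positions=[np.array([10, 40])] * n,
        trough_positions=[np.array([25])] * n,
        peak_levels=[np.array(p, float) for p in peaks],
        trough_levels=[np.array(t, float) for t in troughs],
        amplitude=np.full(n, amp),
    )


def test_wave_shift_classification():
    before = _metrics([1.0], peaks=[[2.0, 2.0]], troughs=[[0.2]])
    same = classify_wave_shift(before, before)
    assert same == ["none"]
    shifted_up = _metrics([1.1], peaks=[[2.1, 2.1]], troughs=[[0.3]])
    assert classify_wave_shift(before, shifted_up) == ["up"]
    bounded_up = _metrics([1.08], peaks=[[2.0, 2.0]], troughs=[[0.4]])
    assert classify_wave_shift(before, bounded_up) == ["up"]
    bounded_down = _metrics([0.9], peaks=[[1.8, 1.8]], troughs=[[0.2]])
    assert classify_wave_shift(before, bounded_down) == ["down"]


def test_wave_shift_requires_matching_wave_count():
    before = _metrics([1.0], peaks=[[2.0]], troughs=[[0.2]], waves=3.0)
    after = _metrics([1.0], peaks=[[2.0]], troughs=[[0.2]], waves=4.0)
    with pytest.raises(ValueError):
        classify_wave_shift(before, after)


def test_screen_is_reproducible(ai_topology):
    specs = [InhibitionSpec(target=1, mode="response", alpha=None)]
    r1 = perturbation_screen(ai_topology, specs, raw_sets=12, seed=5)
    r2 = perturbation_screen(ai_topology, specs, raw_sets=12, seed=5)
    assert r1["summary"].equals(r2["summary"])


def test_ai_screen_inhibitor_block_raises_activator(ai_topology):
    """Receptor-level block of the inhibitor raises the activator's level in
    the predominant fraction of valid parameterisations."""
    specs = [InhibitionSpec(target=1, mode="response", alpha=None)]
    res = perturbation_screen(ai_topology, specs, raw_sets=60, seed=17)
    summ = res["summary"]
    row = summ[(summ.target == "V") & (summ.component == "U")].iloc[0]
    assert row.n_valid_sets >= 5
    assert row.fraction_increase > 0.8
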