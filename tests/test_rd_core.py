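import json

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy.stats import kstest

from rugard.rd_core import (
    SignedTopology,
    RDParameterSet,
    ParameterError,
    clamp_production,
    compute_basal_inputs,
    reaction_rates,
    sample_parameter_set,
    sample_parameter_batch,
    materialize_parameter_set,
    topology_from_json,
    topology_to_json,
    uniform_steady_state,
)


@pytest.mark.parametrize(
    "z,fmax,expected",
    [(-0.5, 0.2, 0.0), (0.1, 0.2, 0.1), (0.3, 0.2, 0.2)],
)
def test_clamp_production_regions(z, fmax, expected):
    assert clamp_production(z, fmax) == pytest.approx(expected)


def test_clamp_rejects_nonpositive_ceiling():
    with pytest.raises(ParameterError):
        clamp_production(0.1, 0.0)


@settings(max_examples=200, deadline=None, derandomize=True)
@given(
    z1=st.floats(-5, 5),
    z2=st.floats(-5, 5),
    fmax=st.floats(0.01, 5),
)
def test_clamp_is_monotone_and_1lipschitz(z1, z2, fmax):
    y1, y2 = clamp_production(z1, fmax), clamp_production(z2, fmax)
    if z1 <= z2:
        assert y1 <= y2
    assert abs(y1 - y2) <= abs(z1 - z2) + 1e-12


def test_basal_inputs_no_interactions():
    b = compute_basal_inputs(np.zeros((2, 2)), np.array([0.5, 0.5]))
    assert np.allclose(b, [0.5, 0.5])


def test_basal_inputs_direct_formula():
    # row sums -0.053 with degradation 0.004 -> basal input 0.057
    a = np.array([[0.0, -0.019, -0.034], [0, 0, 0], [0, 0, 0]])
    c = np.array([0.004, 1.0, 1.0])
    assert compute_basal_inputs(a, c)[0] == pytest.approx(0.057)


def test_all_ones_is_equilibrium_after_normalisation(rng):
    top = SignedTopology(
        sign=((1, -1, 1), (1, 0, -1), (0, 1, 0)),
        autoreg=(True, False, False),
        labels=("x", "y", "z"),
    )
    for seed in range(5):
        p = sample_parameter_set(top, np.random.default_rng(seed))
        assert np.max(np.abs(reaction_rates(np.ones(3), p))) < 1e-12
        assert np.allclose(uniform_steady_state(p), 1.0)


def test_reaction_rates_match_scalar_oracle(rng):
    top = SignedTopology(sign=((1, -1), (1, 0)), autoreg=(True, False))
    p = sample_parameter_set(top, rng)
    u = rng.uniform(0, 2, size=2)
    expected = []
    for i in range(2):
        z = sum(p.a[i, j] * u[j] for j in range(2)) + p.b[i]
        z = min(max(z, 0.0), p.fmax[i])
        expected.append(z - p.c[i] * u[i])
    assert np.allclose(reaction_rates(u, p), expected)


def test_sampling_is_deterministic():
    top = SignedTopology(sign=((1, -1), (1, 0)), autoreg=(True, False))
    p1 = sample_parameter_set(top, 42)
    p2 = sample_parameter_set(top, 42)
    for f in ("a", "b", "c", "fmax", "D"):
        assert np.array_equal(getattr(p1, f), getattr(p2, f))


def test_sampled_sets_satisfy_invariants_in_bulk():
    top = SignedTopology(
        sign=((1, -1, 1), (1, 0, -1), (0, 1, 0)),
        autoreg=(True, False, False),
    )
    batch = sample_parameter_batch(top, 10_000, 7)
    sgn = top.sign_array()
    off = ~np.eye(3, dtype=bool)
    a = batch["a"]
    assert np.all(np.sign(a[:, off]) == sgn[off][None, :])
    assert np.all(np.abs(a[:, off]) <= 1.0)
    assert np.all(batch["c"] > 0)
    assert np.all(batch["D"] >= 1e-4) and np.all(batch["D"] <= 1.0)
    ratio = batch["fmax"] / batch["c"]
    assert np.all(ratio >= 1.5) and np.all(ratio <= 3.0)
    # composite self-weights: positive with autoregulation, negative without
    comp = a[:, np.arange(3), np.arange(3)] - batch["c"]
    assert np.all(comp[:, 0] > 0)
    assert np.all(comp[:, 1:] < 0)
    for i in range(50):  # spot-validate full object construction
        materialize_parameter_set(top, batch, i)


def test_interaction_magnitudes_are_uniform():
    top = SignedTopology(sign=((0, 1), (1, 0)), autoreg=(False, False))
    batch = sample_parameter_batch(top, 10_000, 11)
    mags = np.abs(batch["a"][:, 0, 1])
    assert kstest(mags, "uniform").pvalue > 0.01


def test_topology_json_roundtrip():
    top = SignedTopology(
        sign=((1, -1, 0), (1, 0, -1), (0, 1, 0)),
        autoreg=(True, False, False),
        labels=("Wnt", "BMP", "Hh"),
    )
    again = topology_from_json(json.dumps(topology_to_json(top)))
    assert again == top


def test_parameter_set_rejects_wrong_signs():
    top = SignedTopology(sign=((0, 1), (1, 0)), autoreg=(False, False))
    with pytest.raises(ParameterError):
        RDParameterSet(
            topology=top,
            a=np.array([[0.0, -0.5], [0.5, 0.0]]),
            b=np.ones(2),
            c=np.ones(2),
            fmax=np.ones(2) * 2,
            D=np.ones(2),
        )
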