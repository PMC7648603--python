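import numpy as np
import pytest

from rugard.rd_core import RDParameterSet, SignedTopology, compute_basal_inputs, sample_parameter_set
from rugard.stability import (
    classify_ddi,
    dispersion_relation,
    phase_signature,
    reaction_jacobian,
    rescale_for_domain,
)
from rugard.examples import two_fgf_parameters


def _two_comp(a, b, c, d, D1, D2, fscale=10.0):
    """2-component set with reaction Jacobian [[a, b], [c, d]] at all-ones."""
    autoreg = a > 0
    deg1 = 0.5 if autoreg else -a
    A = np.array([[a + deg1 if autoreg else 0.0, b], [c, 0.0]])
    C = np.array([deg1 if autoreg else -a, -d])
    top = SignedTopology(
        sign=tuple(tuple(int(np.sign(v)) for v in row) for row in A),
        autoreg=(autoreg, False),
    )
    B = compute_basal_inputs(A, C)
    return RDParameterSet(
        topology=top, a=A, b=B, c=C, fmax=C * fscale, D=np.array([D1, D2])
    )


def test_jacobian_no_interactions_is_minus_degradation():
    top = SignedTopology(sign=((0, 0), (0, 0)), autoreg=(False, False))
    p = RDParameterSet(
        topology=top,
        a=np.zeros((2, 2)),
        b=np.array([0.3, 0.7]),
        c=np.array([0.3, 0.7]),
        fmax=np.array([0.6, 1.4]),
        D=np.ones(2),
    )
    assert np.allclose(reaction_jacobian(p), -np.diag([0.3, 0.7]))


def test_jacobian_matches_finite_differences(rng):
    from rugard.rd_core import reaction_rates

    top = SignedTopology(
        sign=((1, -1, 1), (1, 0, -1), (0, 1, 0)), autoreg=(True, False, False)
    )
    p = sample_parameter_set(top, rng)
    J = reaction_jacobian(p)
    eps = 1e-7
    for j in range(3):
        u1, u2 = np.ones(3), np.ones(3)
        u1[j] -= eps
        u2[j] += eps
        col = (reaction_rates(u2, p) - reaction_rates(u1, p)) / (2 * eps)
        assert np.allclose(J[:, j], col, atol=1e-6)


def test_dispersion_at_zero_equals_reaction_eigenvalues(rng):
    top = SignedTopology(sign=((1, -1), (1, 0)), autoreg=(True, False))
    p = sample_parameter_set(top, rng)
    disp = dispersion_relation(p, k_grid=np.array([1e-9, 1.0]))
    lam0 = disp.leading_eigenvalue[0]
    expected = np.max(np.linalg.eigvals(reaction_jacobian(p)).real)
    assert abs(lam0.real - expected) < 1e-8


def _turing_threshold(a, b, c, d):
    """Closed-form diffusivity-ratio threshold for a 2-component system with
    Jacobian [[a, b], [c, d]] (a > 0 > d, bc < 0): instability requires
    d_ratio > ((sqrt(det) + sqrt(-b c)) / a)^2."""
    det = a * d - b * c
    return ((np.sqrt(det) + np.sqrt(-b * c)) / a) ** 2


def test_two_component_turing_threshold():
    a, b, c, d = 0.4, -1.0, 1.0, -0.9
    ratio = _turing_threshold(a, b, c, d)
    hi = _two_comp(a, b, c, d, D1=1e-3, D2=1e-3 * ratio * 2.0)
    lo = _two_comp(a, b, c, d, D1=1e-3, D2=1e-3 * ratio * 0.5)
    assert classify_ddi(hi)["ddi"] is True
    assert classify_ddi(lo)["ddi"] is False


def test_equal_diffusion_cannot_destabilise_stable_two_component():
    a, b, c, d = 0.4, -1.0, 1.0, -0.9
    p = _two_comp(a, b, c, d, D1=1e-3, D2=1e-3)
    assert classify_ddi(p)["ddi"] is False


def test_published_two_fgf_set_is_nonoscillating_ddi():
    cls = classify_ddi(two_fgf_parameters())
    assert cls["ddi"] is True
    assert cls["oscillatory"] is False
    # mFGF and Hh pattern together; eFGF out of phase
    assert cls["phase"] == (1, -1, 1)


def test_phase_signatures_of_canonical_pairs():
    a, b, c, d = 0.4, -1.0, 1.0, -0.9
    ai = _two_comp(a, b, c, d, D1=1e-3, D2=0.5)
    assert phase_signature(ai) == (1, 1)
    sd = _two_comp(0.4, 1.0, -1.0, -0.9, D1=1e-3, D2=0.5)
    assert phase_signature(sd) == (1, -1)


def test_rescaling_preserves_phase_and_targets_wavelength():
    p = two_fgf_parameters()
    before = dispersion_relation(p)
    scaled = rescale_for_domain(p, 100.0, 3.25, target_growth_rate=0.1)
    after = dispersion_relation(scaled)
    assert after.ddi and after.phase == before.phase
    assert after.growth_rate == pytest.approx(0.1, rel=0.05)
    assert after.wavelength == pytest.approx(100.0 / 3.25, rel=0.10)


def test_identity_rescale_is_identity():
    p = two_fgf_parameters()
    disp = dispersion_relation(p)
    scaled = rescale_for_domain(
        p, disp.wavelength * 2.0, 2.0, target_growth_rate=disp.growth_rate
    )
    assert np.allclose(scaled.a, p.a, rtol=1e-9)
    assert np.allclose(scaled.D, p.D, rtol=1e-9)
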