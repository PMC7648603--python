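"""Linear stability analysis of the piecewise-linear RD model.

Diffusion-driven instability (DDI) is diagnosed from the dispersion relation
of the linearisation about the all-ones uniform steady state: for each
wavenumber ``k`` the growth rate of mode ``k`` is the leading eigenvalue of
``J - k^2 diag(D)``, with ``J = a - diag(c)`` the reaction Jacobian.  A
parameter set supports a stable, spatially periodic, non-oscillating pattern
when

* the homogeneous system is stable (all eigenvalues of ``J`` have negative
  real part),
* a finite band of wavenumbers ``k > 0`` grows (``Re lambda(k) > 0``), and
* the fastest-growing mode is non-oscillatory (``Im lambda(k_max) = 0``
  within tolerance).

The sign pattern of the leading eigenvector at ``k_max`` gives the spatial
phase signature: components with the same sign peak together in the emerging
pattern.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .rd_core import RDParameterSet, ParameterError, steady_state_in_linear_region

__all__ = [
    "DispersionResult",
    "reaction_jacobian",
    "dispersion_relation",
    "classify_ddi",
    "phase_signature",
    "rescale_for_domain",
    "default_k_grid",
    "dispersion_to_frame",
]

#: |Im lambda| below this (relative) tolerance counts as real.
OSCILLATION_TOL = 1e-9
#: eigenvector entries below this fraction of the norm are phase-indeterminate
PHASE_ENTRY_TOL = 1e-6


class UndefinedPhaseError(ValueError):
    """Phase signature requested for a parameter set without DDI."""


@dataclass(frozen=True)
class DispersionResult:
    k_values: np.ndarray
    leading_eigenvalue: np.ndarray  # complex, per k
    k_max: float
    growth_rate: float
    oscillatory: bool
    ddi: bool
    phase: tuple or None  # +-1 per component; None when indeterminate/no DDI

    @property
    def wavelength(self) -> float:
        return float(2.0 * np.pi / self.k_max) if self.k_max > 0 else np.inf


def reaction_jacobian(params: RDParameterSet) -> np.ndarray:
    """Jacobian of the reaction terms at the all-ones steady state:
    ``J_ij = a_ij - delta_ij c_i`` (valid only in the linear region)."""
    if not steady_state_in_linear_region(params):
        raise ParameterError(
            "production clamp active at the uniform steady state; linearisation invalid"
        )
    return params.a - np.diag(params.c)


def default_k_grid(J: np.ndarray, D: np.ndarray, num: int = 128) -> np.ndarray:
    """Logarithmic wavenumber grid wide enough to bracket any unstable band.

    The most unstable mode satisfies ``k^2 D_i ~ |J|`` for some component,
    so the grid spans several decades either side of ``sqrt(max|J| / min D)``.
    """
    scale = np.sqrt(np.max(np.abs(J)) / np.min(D))
    return np.geomspace(1e-3 * scale, 1e3 * scale, num)


def _leading(vals: np.ndarray) -> np.ndarray:
    """Index of the leading eigenvalue: largest real part, ties broken by
    smaller |Im|.  ``vals`` has shape (..., n)."""
    re = vals.real
    im = np.abs(vals.imag)
    order = np.lexsort((im, -re), axis=-1)
    return order[..., 0]


def dispersion_relation(params: RDParameterSet, k_grid=None, refine: bool = True) -> DispersionResult:
    """Evaluate the dispersion relation on a wavenumber grid and classify DDI."""
    J = reaction_jacobian(params)
    D = params.D
    n = params.n
    if k_grid is None:
        k_grid = default_k_grid(J, D)
    k_grid = np.asarray(k_grid, dtype=float)
    if k_grid.size == 0:
        raise ValueError("empty wavenumber grid")

    mats = J[None, :, :] - (k_grid**2)[:, None, None] * np.eye(n) * D
    vals = np.linalg.eigvals(mats)
    lead_idx = _leading(vals)
    lead = vals[np.arange(vals.shape[0]), lead_idx]

    i_max = int(np.argmax(lead.real))
    k_max = float(k_grid[i_max])
    if refine and 0 < i_max < k_grid.size - 1:
        k_max = _quadratic_refine(J, D, k_grid, lead.real, i_max)
    lam_max, vec_max = _leading_pair(J - k_max**2 * np.diag(D))

    vals0 = np.linalg.eigvals(J)
    stable0 = bool(np.all(vals0.real < 0))
    band_grows = lam_max.real > 0
    tail_decays = lead.real[-1] < 0
    ddi = bool(stable0 and band_grows and tail_decays)

    oscillatory = bool(abs(lam_max.imag) > OSCILLATION_TOL * (1.0 + abs(lam_max.real)))
    phase = _phase_from_vector(vec_max) if (ddi and not oscillatory) else None

    return DispersionResult(
        k_values=k_grid,
        leading_eigenvalue=lead,
        k_max=k_max if ddi else (k_max if band_grows else 0.0),
        growth_rate=float(lam_max.real),
        oscillatory=oscillatory,
        ddi=ddi,
        phase=phase,
    )


def _quadratic_refine(J, D, k_grid, re_lead, i_max) -> float:
    """One quadratic interpolation step around the grid maximum (in log k)."""
    x = np.log(k_grid[i_max - 1 : i_max + 2])
    y = re_lead[i_max - 1 : i_max + 2]
    denom = (x[0] - x[1]) * (x[0] - x[2]) * (x[1] - x[2])
    if denom == 0:
        return float(k_grid[i_max])
    a = (x[2] * (y[1] - y[0]) + x[1] * (y[0] - y[2]) + x[0] * (y[2] - y[1])) / denom
    b = (x[2] ** 2 * (y[0] - y[1]) + x[1] ** 2 * (y[2] - y[0]) + x[0] ** 2 * (y[1] - y[2])) / denom
    if a >= 0:
        return float(k_grid[i_max])
    x_star = -b / (2 * a)
    x_star = min(max(x_star, x[0]), x[2])
    k_star = float(np.exp(x_star))
    lam_star, _ = _leading_pair(J - k_star**2 * np.diag(D))
    return k_star if lam_star.real >= y[1] else float(k_grid[i_max])


def _leading_pair(M: np.ndarray):
    vals, vecs = np.linalg.eig(M)
    idx = int(_leading(vals[None, :])[0])
    return vals[idx], vecs[:, idx]


def _phase_from_vector(vec: np.ndarray):
    """Canonical sign pattern of a (possibly complex) leading eigenvector.

    The vector is rotated in the complex plane to maximise the norm of its
    real part; near-zero entries make the phase indeterminate (None).
    """
    v = np.asarray(vec)
    if np.any(np.abs(v.imag) > 0):
        theta = 0.5 * np.angle(np.sum(v**2))
        cand = (v * np.exp(-1j * theta)).real
        alt = (v * np.exp(-1j * (theta + np.pi / 2))).real
        if np.linalg.norm(alt) > np.linalg.norm(cand):
            cand = alt
        v = cand
    else:
        v = v.real
    norm = np.linalg.norm(v)
    if norm == 0 or np.any(np.abs(v) < PHASE_ENTRY_TOL * norm):
        return None
    signs = np.sign(v).astype(int)
    nz = np.nonzero(signs)[0]
    if signs[nz[0]] < 0:
        signs = -signs
    return tuple(int(s) for s in signs)


def classify_ddi_batch(J: np.ndarray, D: np.ndarray, k_squared: np.ndarray = None):
    """Vectorised DDI classification for a stack of Jacobians.

    ``J`` is (B, n, n), ``D`` (B, n).  Returns a dict of arrays: ``ddi``
    (bool), ``oscillatory`` (bool), ``phase`` (B, n) ints with 0 rows where
    indeterminate, ``k_max`` and ``growth_rate``.  The wavenumber grid is a
    wide fixed logarithmic sweep; no local refinement is applied (screening
    resolution).
    """
    J = np.asarray(J, float)
    D = np.asarray(D, float)
    B, n = J.shape[0], J.shape[1]
    if k_squared is None:
        k_squared = np.geomspace(1e-8, 1e8, 120)
    K = k_squared.size
    out = {
        "ddi": np.zeros(B, bool),
        "oscillatory": np.zeros(B, bool),
        "phase": np.zeros((B, n), int),
        "k_max": np.zeros(B),
        "growth_rate": np.full(B, -np.inf),
    }
    ev0 = np.linalg.eigvals(J)
    stable = ev0.real.max(axis=1) < 0
    idx = np.where(stable)[0]
    if idx.size == 0:
        return out
    eye = np.eye(n)
    M = J[idx, None, :, :] - (k_squared[None, :, None] * D[idx, None, :])[..., None] * eye
    ev = np.linalg.eigvals(M.reshape(-1, n, n)).reshape(idx.size, K, n)
    re_lead = ev.real.max(axis=2)
    i_max = np.argmax(re_lead, axis=1)
    grows = re_lead[np.arange(idx.size), i_max] > 0
    tail_ok = re_lead[:, -1] < 0
    for pos in np.where(grows & tail_ok)[0]:
        b = idx[pos]
        km2 = k_squared[i_max[pos]]
        vals, vecs = np.linalg.eig(J[b] - km2 * np.diag(D[b]))
        li = int(_leading(vals[None, :])[0])
        lam = vals[li]
        out["k_max"][b] = np.sqrt(km2)
        out["growth_rate"][b] = lam.real
        osc = abs(lam.imag) > OSCILLATION_TOL * (1 + abs(lam.real))
        out["oscillatory"][b] = osc
        out["ddi"][b] = True
        if not osc:
            ph = _phase_from_vector(vecs[:, li])
            if ph is not None:
                out["phase"][b] = ph
    return out


def classify_ddi(params: RDParameterSet, k_grid=None) -> dict:
    """Convenience wrapper returning the DDI verdict as a plain mapping."""
    disp = dispersion_relation(params, k_grid=k_grid)
    return {
        "ddi": disp.ddi,
        "oscillatory": disp.oscillatory,
        "phase": disp.phase,
        "wavelength": disp.wavelength if disp.ddi else None,
        "growth_rate": disp.growth_rate,
    }


def dispersion_to_frame(disp: DispersionResult):
    """Dispersion curve as a table (k, Re lambda, Im lambda) for CSV export."""
    import pandas as pd

    return pd.DataFrame(
        {
            "k": disp.k_values,
            "re_lambda": disp.leading_eigenvalue.real,
            "im_lambda": disp.leading_eigenvalue.imag,
        }
    )


def phase_signature(params: RDParameterSet, k_grid=None):
    """Canonical sign vector of the pattern-forming mode (first entry +1)."""
    disp = dispersion_relation(params, k_grid=k_grid)
    if not disp.ddi:
        raise UndefinedPhaseError("phase signature is undefined without DDI")
    return disp.phase


def rescale_for_domain(
    params: RDParameterSet,
    domain_length: float,
    target_wave_count: float,
    target_growth_rate: float = 0.1,
) -> RDParameterSet:
    """Rescale time and space so the predicted pattern fits the simulation
    domain and grows at a convenient rate.

    A time rescale multiplies all rates (a, b, c, fmax, D) by ``sigma_t``;
    a space rescale multiplies diffusivities by ``sigma_x^2``.  Both leave
    the DDI verdict and phase signature unchanged, scaling only growth rate
    (by ``sigma_t``) and wavelength (by ``sigma_x``).
    """
    disp = dispersion_relation(params)
    if not disp.ddi:
        raise ParameterError("cannot rescale a parameter set without DDI")
    sigma_t = target_growth_rate / disp.growth_rate
    target_wavelength = domain_length / target_wave_count
    sigma_x = target_wavelength / disp.wavelength
    return params.with_(
        a=params.a * sigma_t,
        b=params.b * sigma_t,
        c=params.c * sigma_t,
        fmax=params.fmax * sigma_t,
        D=params.D * sigma_t * sigma_x**2,
    )
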