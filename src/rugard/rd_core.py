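"""Piecewise-linear reaction-diffusion model: types, production function,
steady-state normalisation and random parameterisation.

The model describes ``N`` interacting morphogen pathways on a 1-D tissue
axis.  Component ``i`` evolves as

    du_i/dt = Phi(sum_j a_ij * u_j + b_i; fmax_i) - c_i * u_i + D_i * u_i''

where ``Phi(z; fmax) = min(max(z, 0), fmax)`` is a piecewise-linear
production function, ``a_ij`` is the weight of the direct regulatory input
from component ``j`` to component ``i``, ``b_i`` a constant regulatory
input, ``c_i`` a first-order degradation rate and ``D_i`` a diffusion
coefficient.  The basal inputs ``b_i`` are chosen so that the spatially
uniform all-ones state is an equilibrium lying strictly inside the linear
region of every production function.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np

__all__ = [
    "SignedTopology",
    "RDParameterSet",
    "InhibitionSpec",
    "clamp_production",
    "compute_basal_inputs",
    "sample_parameter_set",
    "reaction_rates",
    "topology_from_json",
    "topology_to_json",
    "parameter_sets_to_frame",
]


class ParameterError(ValueError):
    """Raised when a parameter set violates the model's contracts."""


@dataclass(frozen=True)
class SignedTopology:
    """Qualitative form of an RD network: the sign of every direct interaction.

    ``sign[i, j]`` is +1, -1 or 0 for the regulatory input from component
    ``j`` to component ``i``.  ``autoreg[i]`` marks positive
    self-interaction; every component is additionally assumed to carry some
    degradation, so the absence of autoregulation means a net-negative
    self-interaction rather than none.
    """

    sign: tuple  # n x n nested tuple of {-1, 0, +1}
    autoreg: tuple  # n bools
    labels: tuple = field(default=None)

    def __post_init__(self):
        n = len(self.sign)
        sign = tuple(tuple(int(v) for v in row) for row in self.sign)
        if any(len(row) != n for row in sign):
            raise ValueError("sign matrix must be square")
        if any(v not in (-1, 0, 1) for row in sign for v in row):
            raise ValueError("interaction signs must be -1, 0 or +1")
        autoreg = tuple(bool(v) for v in self.autoreg)
        if len(autoreg) != n:
            raise ValueError("autoreg must have one flag per component")
        for i in range(n):
            if autoreg[i] and sign[i][i] != 1:
                sign = tuple(
                    tuple(1 if (r == c == i) else sign[r][c] for c in range(n))
                    for r in range(n)
                )
        labels = self.labels
        if labels is None:
            labels = tuple(f"u{i + 1}" for i in range(n))
        labels = tuple(str(x) for x in labels)
        if len(labels) != n or len(set(labels)) != n:
            raise ValueError("labels must be unique, one per component")
        object.__setattr__(self, "sign", sign)
        object.__setattr__(self, "autoreg", autoreg)
        object.__setattr__(self, "labels", labels)

    @property
    def n(self) -> int:
        return len(self.sign)

    def sign_array(self) -> np.ndarray:
        return np.array(self.sign, dtype=int)

    def index(self, label: str) -> int:
        return self.labels.index(label)

    def edges(self):
        """Directed interactions (j -> i, sign), diagonal included when autoregulating."""
        out = []
        for i in range(self.n):
            for j in range(self.n):
                if i == j and not self.autoreg[i]:
                    continue
                if self.sign[i][j] != 0:
                    out.append((j, i, self.sign[i][j]))
        return out


@dataclass(frozen=True)
class RDParameterSet:
    """One numerical instance of a topology: weights, degradation,
    production ceilings and diffusivities."""

    topology: SignedTopology
    a: np.ndarray
    b: np.ndarray
    c: np.ndarray
    fmax: np.ndarray
    D: np.ndarray

    def __post_init__(self):
        n = self.topology.n
        for name in ("a", "b", "c", "fmax", "D"):
            arr = np.asarray(getattr(self, name), dtype=float)
            object.__setattr__(self, name, arr)
        if self.a.shape != (n, n):
            raise ParameterError("a must be n x n")
        for name in ("b", "c", "fmax", "D"):
            if getattr(self, name).shape != (n,):
                raise ParameterError(f"{name} must have length n")
        if np.any(self.c <= 0) or np.any(self.fmax <= 0) or np.any(self.D <= 0):
            raise ParameterError("c, fmax and D must be positive")
        sgn = self.topology.sign_array()
        off = ~np.eye(n, dtype=bool)
        # a weight may be zero (e.g. fully inhibited) but never of the wrong sign
        bad = (np.sign(self.a) != sgn) & (self.a != 0)
        if np.any(bad[off]):
            raise ParameterError("off-diagonal weights must match topology signs")
        for i in range(n):
            if self.topology.autoreg[i]:
                if self.a[i, i] < 0:
                    raise ParameterError("autoregulating components need a_ii >= 0")
            elif self.a[i, i] != 0:
                raise ParameterError("a_ii must be 0 without autoregulation")

    @property
    def n(self) -> int:
        return self.topology.n

    def with_(self, **kw) -> "RDParameterSet":
        return replace(self, **kw)


@dataclass(frozen=True)
class InhibitionSpec:
    """An in-silico inhibition: which component, at which level, and whether
    the block acts on the *response* to the morphogen (receptor-level, e.g.
    cyclopamine, dorsomorphin, SU-5402) or on its *production*
    (ligand-synthesis level, e.g. IWP-2)."""

    target: int
    mode: str  # "response" | "production"
    alpha: float = None

    def __post_init__(self):
        if self.mode not in ("response", "production"):
            raise ValueError("mode must be 'response' or 'production'")
        if self.alpha is not None and not (0.0 <= self.alpha <= 1.0):
            raise ValueError("alpha must lie in [0, 1]")


def clamp_production(z, fmax):
    """Piecewise-linear production function Phi(z; fmax) = min(max(z, 0), fmax).

    Production cannot be negative and saturates at the ceiling ``fmax``;
    between the bounds it is the identity, so it is continuous, nondecreasing
    and 1-Lipschitz in ``z``.
    """
    fmax = np.asarray(fmax, dtype=float)
    if np.any(fmax <= 0):
        raise ParameterError("fmax must be positive")
    return np.minimum(np.maximum(z, 0.0), fmax)


def compute_basal_inputs(a, c):
    """Constant inputs ``b`` fixing the uniform steady state at all-ones.

    At ``u = 1`` the production of component ``i`` is
    ``Phi(sum_j a_ij + b_i)`` and its loss is ``c_i``; requiring balance in
    the linear region gives ``b_i = c_i - sum_j a_ij``.
    """
    a = np.asarray(a, dtype=float)
    c = np.asarray(c, dtype=float)
    return c - a.sum(axis=1)


def uniform_steady_state(params: RDParameterSet) -> np.ndarray:
    """The spatially uniform equilibrium of the reaction system (assuming
    production in the linear region): solves (a - diag(c)) u = -b.  Equals
    the all-ones state when b was set by compute_basal_inputs."""
    J = params.a - np.diag(params.c)
    return np.linalg.solve(J, -params.b)


def steady_state_in_linear_region(params: RDParameterSet) -> bool:
    """True when the uniform equilibrium is positive with production
    strictly inside (0, fmax) for every component."""
    try:
        u = uniform_steady_state(params)
    except np.linalg.LinAlgError:
        return False
    z = params.a @ u + params.b
    return bool(np.all(u > 0.0) and np.all(z > 0.0) and np.all(z < params.fmax))


def reaction_rates(state, params: RDParameterSet):
    """Reaction part of du/dt at the given concentration vector (or an
    array of vectors in the trailing axis convention ``(..., n)``)."""
    u = np.asarray(state, dtype=float)
    if u.shape[-1] != params.n:
        raise ParameterError("state dimension does not match parameter set")
    z = u @ params.a.T + params.b
    return clamp_production(z, params.fmax) - params.c * u


def sample_parameter_set(
    topology: SignedTopology,
    rng,
    max_retries: int = 100,
) -> RDParameterSet:
    """Draw one random parameter set for a topology.

    Interaction weights |a_ij| are uniform on (0, 1] with the topology's
    sign.  The composite self-weight a_ii - c_i is drawn from the same
    uniform distribution: negative with a_ii = 0 when the component does not
    autoregulate, positive when it does, in which case c_i is drawn from
    (0, 1] as well.  Diffusivities are reciprocals of uniform draws on
    [1, 10000], and each production ceiling is uniform on
    [1.5 c_i, 3 c_i].  Sets whose steady-state production leaves the linear
    region are rejected and redrawn (bounded retries).
    """
    rng = np.random.default_rng(rng)
    n = topology.n
    sgn = topology.sign_array()
    for _ in range(max_retries):
        a = np.zeros((n, n))
        c = np.zeros(n)
        for i in range(n):
            for j in range(n):
                if i == j:
                    continue
                if sgn[i, j] != 0:
                    a[i, j] = sgn[i, j] * _uniform_pos(rng)
            composite = _uniform_pos(rng)  # |a_ii - c_i|
            if topology.autoreg[i]:
                c[i] = _uniform_pos(rng)
                a[i, i] = composite + c[i]  # a_ii - c_i = +composite
            else:
                a[i, i] = 0.0
                c[i] = composite  # a_ii - c_i = -composite
        D = 1.0 / rng.uniform(1.0, 10_000.0, size=n)
        fmax = c * rng.uniform(1.5, 3.0, size=n)
        b = compute_basal_inputs(a, c)
        params = RDParameterSet(topology=topology, a=a, b=b, c=c, fmax=fmax, D=D)
        if steady_state_in_linear_region(params):
            return params
    raise ParameterError(
        "could not draw a parameter set with the steady state in the linear region"
    )


def sample_parameter_batch(topology: SignedTopology, B: int, rng) -> dict:
    """Vectorised draw of ``B`` parameter sets (same law as
    sample_parameter_set); returns stacked arrays keyed a, b, c, fmax, D.

    With the basal inputs set by the steady-state normalisation, production
    at the uniform equilibrium equals c_i, which always lies strictly inside
    (0, fmax_i); no rejection is needed.
    """
    rng = np.random.default_rng(rng)
    n = topology.n
    sgn = topology.sign_array().astype(float)
    autoreg = np.array(topology.autoreg)
    mag = np.abs(rng.uniform(-1.0, 1.0, (B, n, n)))
    a = mag * sgn[None, :, :]
    composite = np.abs(rng.uniform(-1.0, 1.0, (B, n)))
    c_auto = np.abs(rng.uniform(-1.0, 1.0, (B, n)))
    c = np.where(autoreg[None, :], c_auto, composite)
    diag = np.where(autoreg[None, :], composite + c_auto, 0.0)
    a[:, np.arange(n), np.arange(n)] = diag
    D = 1.0 / rng.uniform(1.0, 10_000.0, (B, n))
    fmax = c * rng.uniform(1.5, 3.0, (B, n))
    b = c - a.sum(axis=2)
    return {"a": a, "b": b, "c": c, "fmax": fmax, "D": D}


def materialize_parameter_set(topology: SignedTopology, batch: dict, i: int) -> RDParameterSet:
    """One RDParameterSet from a sampled batch."""
    return RDParameterSet(
        topology=topology,
        a=batch["a"][i],
        b=batch["b"][i],
        c=batch["c"][i],
        fmax=batch["fmax"][i],
        D=batch["D"][i],
    )


def parameter_set_from_jacobian(J, D, degradation: float = 0.3, fmax_ratio: float = 2.0) -> RDParameterSet:
    """Wrap an arbitrary reaction Jacobian as a normalised parameter set.

    Splits each diagonal entry as a_ii - c_i with c_i = |J_ii| + degradation
    (so a_ii > 0 and every component formally autoregulates), fixes the
    uniform steady state at one, and gives every production a ceiling of
    ``fmax_ratio`` times c_i.  Useful for simulating grid-screen witnesses.
    """
    J = np.asarray(J, float)
    n = J.shape[0]
    c = np.abs(np.diag(J)) + degradation
    a = J.copy()
    a[np.arange(n), np.arange(n)] = np.diag(J) + c
    top = SignedTopology(
        sign=tuple(tuple(int(np.sign(v)) for v in row) for row in a),
        autoreg=tuple(True for _ in range(n)),
    )
    return RDParameterSet(
        topology=top,
        a=a,
        b=compute_basal_inputs(a, c),
        c=c,
        fmax=fmax_ratio * c,
        D=np.asarray(D, float),
    )


def _uniform_pos(rng) -> float:
    """Magnitude of a uniform(-1, 1) draw, conditioned away from zero."""
    while True:
        v = abs(rng.uniform(-1.0, 1.0))
        if v > 0.0:
            return v


# ---------------------------------------------------------------------------
# External interfaces


def topology_from_json(text_or_obj) -> SignedTopology:
    """Build a topology from the edge-list JSON convention::

        {"labels": [...], "edges": [{"from": j, "to": i, "sign": +-1}, ...],
         "autoreg": [...]}

    ``from``/``to`` may be indices or labels.
    """
    obj = json.loads(text_or_obj) if isinstance(text_or_obj, str) else text_or_obj
    labels = list(obj["labels"])
    n = len(labels)

    def idx(x):
        return labels.index(x) if isinstance(x, str) else int(x)

    sign = [[0] * n for _ in range(n)]
    for e in obj.get("edges", []):
        sign[idx(e["to"])][idx(e["from"])] = int(e["sign"])
    autoreg = [bool(v) for v in obj.get("autoreg", [False] * n)]
    return SignedTopology(sign=tuple(map(tuple, sign)), autoreg=tuple(autoreg), labels=tuple(labels))


def topology_to_json(top: SignedTopology) -> dict:
    return {
        "labels": list(top.labels),
        "edges": [
            {"from": j, "to": i, "sign": s} for (j, i, s) in top.edges() if i != j
        ],
        "autoreg": [bool(v) for v in top.autoreg],
    }


def parameter_sets_to_frame(sets, seeds=None):
    """Flatten parameter sets to a table: a_ij row-major, then b, c, fmax, D."""
    import pandas as pd

    rows = []
    for k, p in enumerate(sets):
        n = p.n
        row = {}
        for i in range(n):
            for j in range(n):
                row[f"a_{i + 1}{j + 1}"] = p.a[i, j]
        for i in range(n):
            row[f"b_{i + 1}"] = p.b[i]
        for i in range(n):
            row[f"c_{i + 1}"] = p.c[i]
        for i in range(n):
            row[f"fmax_{i + 1}"] = p.fmax[i]
        for i in range(n):
            row[f"D_{i + 1}"] = p.D[i]
        if seeds is not None:
            row["seed"] = seeds[k]
        rows.append(row)
    return pd.DataFrame(rows)
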