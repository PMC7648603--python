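"""Systematic screens and enumerations over signed network topologies.

Two complementary machines live here:

* a *grid screen* that sweeps reaction coefficients through a symmetric
  value grid with discrete fast/slow diffusivity assignments and classifies
  every parameter set for stationary, non-oscillating diffusion-driven
  instability (DDI), aggregating the evidence per signed topology; and

* a *constructive enumeration* of minimal phase-consistent topologies:
  every way of composing a core (an all-positive cycle in phase-transformed
  coordinates plus a negative cycle that shares a node with it, covers at
  least one extra component, and delivers its inhibition into the positive
  loop from outside it) with minimal external wiring of the remaining
  components.  Unions are deduplicated and post-filtered so that no single
  interaction can be deleted without losing the embedded-core property.

The observational filter funnels (spatial phase, diffusivity, perturbation
response, temporal order) then cut these sets down to the topologies
compatible with the palatal ruga system.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from itertools import combinations, permutations

import numpy as np

from .rd_core import SignedTopology
from .loops import (
    CoreDecomposition,
    _chain_partitions,
    _simple_cycles_edges,
    response_signature,
)

__all__ = [
    "ScreenConfig",
    "RUGA3_LABELS",
    "RUGA3_PHASES",
    "RUGA5_LABELS",
    "RUGA5_PHASES",
    "MinimalTopology",
    "MinimalTopologySet",
    "topology_space_size",
    "reduced_space_size",
    "enumerate_minimal_topologies",
    "grid_screen_3node",
    "grid_admits_ddi",
    "filter_funnel_3node",
    "filter_by_observed_responses",
    "filter_by_temporal_constraints",
    "response_groups",
]

RUGA3_LABELS = ("Wnt", "BMP", "Hh")
RUGA3_PHASES = (1, -1, 1)
RUGA5_LABELS = ("Wnt", "BMP", "Hh", "eFGF", "mFGF")
RUGA5_PHASES = (1, -1, 1, -1, 1)

#: observed Shh-stripe responses: Wnt inhibition down, BMP up, Hh up,
#: epithelial and mesenchymal FGF inhibition with opposing effects
OBSERVED_HH_RESPONSES = {"Wnt": -1, "BMP": 1, "Hh": 1}


def topology_space_size(n: int) -> int:
    """All sign assignments of the n*n interactions: 3^(n^2)."""
    return 3 ** (n * n)


def reduced_space_size(n: int) -> int:
    """Self-interactions reduced to with/without positive autoregulation
    (degradation is universal): 2^n * 3^(n(n-1))."""
    return 2**n * 3 ** (n * (n - 1))


# ---------------------------------------------------------------------------
# constructive enumeration of minimal topologies


@dataclass(frozen=True)
class MinimalTopology:
    topology: SignedTopology  # real-space signs
    canonical_edges: frozenset  # {(u, v, sign)} in phase-transformed signs
    decompositions: tuple  # CoreDecomposition

    def signature(self, readout: int, phases) -> tuple:
        return response_signature(
            self.topology, phases, readout, decompositions=self.decompositions
        )


@dataclass
class MinimalTopologySet:
    labels: tuple
    phases: tuple
    records: list  # MinimalTopology

    def __len__(self):
        return len(self.records)

    def __iter__(self):
        return iter(self.records)

    def signatures(self, readout_label: str) -> dict:
        r = self.labels.index(readout_label)
        return {rec: rec.signature(r, self.phases) for rec in self.records}


def _directed_cycles(nodes):
    nodes = sorted(nodes)
    if len(nodes) == 1:
        a = nodes[0]
        return [((a, a),)]
    first = nodes[0]
    out = []
    for perm in permutations(nodes[1:]):
        seq = (first,) + perm
        out.append(tuple((seq[i], seq[(i + 1) % len(seq)]) for i in range(len(seq))))
    return out


def _subsets(items, minsize):
    items = list(items)
    for r in range(minsize, len(items) + 1):
        yield from combinations(items, r)


def _generate_unions(n: int) -> dict:
    """Canonical-space union graphs with their generating decompositions."""
    unions = {}
    nodes = list(range(n))
    for VP in _subsets(nodes, 1):
        sVP = set(VP)
        for pcyc in _directed_cycles(VP):
            pedges = set(pcyc)
            for VN in _subsets(nodes, 2):
                sVN = set(VN)
                if not (sVN & sVP) or not (sVN - sVP):
                    continue
                X = [x for x in nodes if x not in sVP | sVN]
                core = sorted(sVP | sVN)
                for ncyc in _directed_cycles(VN):
                    nedges = list(ncyc)
                    # inhibition is delivered into the positive loop from outside it
                    free = [
                        e
                        for e in nedges
                        if e not in pedges and e[1] in sVP and e[0] not in sVP
                    ]
                    if not free:
                        continue
                    base = {e: 1 for e in pedges}
                    for e in nedges:
                        if e not in pedges:
                            base[e] = 1
                    for r in range(1, len(free) + 1, 2):
                        for neg in combinations(free, r):
                            sign = dict(base)
                            for e in neg:
                                sign[e] = -1
                            psigned = tuple((u, v, 1) for (u, v) in pcyc)
                            nsigned = tuple((u, v, sign[(u, v)]) for (u, v) in nedges)
                            _wire_externals(
                                unions, sign, psigned, nsigned, X, core, n
                            )
    return unions


def _wire_externals(unions, sign, psigned, nsigned, X, core, n):
    for chains in _chain_partitions(X):
        opts = []
        for ch in chains:
            copts = []
            for a in core:
                for b in core:
                    for s_exit in (1, -1):
                        copts.append((a, b, s_exit))
            opts.append(copts)
        for combo in itertools.product(*opts):
            sign2 = dict(sign)
            chain_edges = []
            good = True
            for ch, (a, b, s_exit) in zip(chains, combo):
                es = [(a, ch[0], 1)]
                for i in range(len(ch) - 1):
                    es.append((ch[i], ch[i + 1], 1))
                es.append((ch[-1], b, s_exit))
                for (u, v, s) in es:
                    if sign2.get((u, v), s) != s:
                        good = False
                        break
                    sign2[(u, v)] = s
                if not good:
                    break
                chain_edges.append(tuple(es))
            if not good:
                continue
            key = frozenset((u, v, s) for (u, v), s in sign2.items())
            dec = CoreDecomposition(
                pos_edges=psigned, neg_edges=nsigned, chains=tuple(sorted(chain_edges))
            )
            unions.setdefault(key, set()).add(dec)


def _strongly_connected(es: dict, n: int) -> bool:
    adj = {u: set() for u in range(n)}
    radj = {u: set() for u in range(n)}
    for (u, v) in es:
        if u != v:
            adj[u].add(v)
            radj[v].add(u)

    def reach(a):
        seen, stack = {0}, [0]
        while stack:
            x = stack.pop()
            for y in a[x]:
                if y not in seen:
                    seen.add(y)
                    stack.append(y)
        return len(seen) == n

    return reach(adj) and reach(radj)


def _embeds_structure(es: dict, n: int) -> bool:
    """Realizability qualification used by the minimality filter: a valid
    embedded architecture, permitting inhibitory shortcuts between
    positive-loop members."""
    cycles = _simple_cycles_edges(es, n)
    pos_cands = [c for c in cycles if all(es[e] == 1 for e in c)]
    for P in pos_cands:
        VP = set(u for (u, v) in P)
        pedges = set(P)
        for N in cycles:
            if len(N) == 1:
                continue
            VN = set(u for (u, v) in N)
            if not (VN & VP) or not (VN - VP):
                continue
            prod, ok = 1, True
            for e in N:
                s = es[e]
                prod *= s
                if s == -1 and (e[1] not in VP or e in pedges):
                    ok = False
                    break
            if not ok or prod != -1:
                continue
            X = [x for x in range(n) if x not in VP | VN]
            if _chains_coverable(es, X, VP | VN):
                return True
    return False


def _chains_coverable(es, X, core) -> bool:
    if not X:
        return True
    for part in _chain_partitions(X):
        ok = True
        for ch in part:
            if not any(es.get((a, ch[0])) == 1 for a in core):
                ok = False
                break
            if not all(es.get((ch[i], ch[i + 1])) == 1 for i in range(len(ch) - 1)):
                ok = False
                break
            if not any((ch[-1], b) in es for b in core):
                ok = False
                break
        if ok:
            return True
    return False


def _canonical_to_topology(key: frozenset, labels, phases) -> SignedTopology:
    n = len(labels)
    sign = [[0] * n for _ in range(n)]
    autoreg = [False] * n
    for (u, v, s) in key:
        if u == v:
            autoreg[u] = True
            sign[u][u] = 1
        else:
            sign[v][u] = s * phases[u] * phases[v]
    return SignedTopology(
        sign=tuple(map(tuple, sign)), autoreg=tuple(autoreg), labels=tuple(labels)
    )


def enumerate_minimal_topologies(labels=RUGA5_LABELS, phases=RUGA5_PHASES) -> MinimalTopologySet:
    """All unique minimal phase-consistent RD topologies over the labelled,
    phase-assigned components.  Minimal: deleting any single interaction
    destroys strong connectivity or the embedded-core property."""
    n = len(labels)
    unions = _generate_unions(n)
    records = []
    for key, decs in unions.items():
        es = {(u, v): s for (u, v, s) in key}
        minimal = True
        for e in list(es):
            child = dict(es)
            del child[e]
            if _strongly_connected(child, n) and _embeds_structure(child, n):
                minimal = False
                break
        if minimal:
            records.append(
                MinimalTopology(
                    topology=_canonical_to_topology(key, labels, phases),
                    canonical_edges=key,
                    decompositions=tuple(decs),
                )
            )
    records.sort(key=lambda r: sorted(r.canonical_edges))
    return MinimalTopologySet(labels=tuple(labels), phases=tuple(phases), records=records)


# ---------------------------------------------------------------------------
# response grouping and observational filters


def response_groups(minset: MinimalTopologySet, readout_label: str = "Hh") -> dict:
    """Partition by predicted readout-response signature.

    Topologies whose alternative cores disagree on any entry are collected
    under the single key ``"core-dependent"``; all other keys are
    determinate sign tuples.
    """
    groups = {}
    for rec, sig in minset.signatures(readout_label).items():
        key = "core-dependent" if 0 in sig else sig
        groups.setdefault(key, []).append(rec)
    return groups


def filter_by_observed_responses(
    minset: MinimalTopologySet, readout_label: str = "Hh"
) -> tuple:
    """Topologies whose predicted readout responses match the explant
    experiments: Wnt inhibition lowers the readout, BMP and Hh inhibition
    raise it, and the two FGFs act with determinate opposing signs."""
    labels = minset.labels
    idx = {l: labels.index(l) for l in labels}
    keep = []
    for rec, sig in minset.signatures(readout_label).items():
        if (
            sig[idx["Wnt"]] == -1
            and sig[idx["BMP"]] == 1
            and sig[idx["Hh"]] == 1
            and sig[idx["eFGF"]] != 0
            and sig[idx["eFGF"]] == -sig[idx["mFGF"]]
        ):
            keep.append(rec)
    return keep, response_groups(minset, readout_label)


class ConflictingConsensusError(RuntimeError):
    """An interaction appears with both signs across the surviving set."""


def filter_by_temporal_constraints(records, labels=RUGA5_LABELS) -> dict:
    """Keep topologies possessing a core whose positive feedback loop is
    exactly {Wnt, eFGF} with Hh in the negative loop (BMP and mFGF, the
    late-incorporating components, necessarily outside the positive loop).

    Returns the survivors, the distinct Wnt-eFGF-Hh core structures among
    them, and the consensus network (union of interactions, which must be
    sign-unique across survivors)."""
    W, eF, H = labels.index("Wnt"), labels.index("eFGF"), labels.index("Hh")
    survivors, cores = [], set()
    for rec in records:
        hit = False
        for dec in rec.decompositions:
            if dec.pos_nodes == {W, eF} and H in dec.neg_nodes:
                hit = True
                cores.add((frozenset(dec.pos_edges), frozenset(dec.neg_edges)))
        if hit:
            survivors.append(rec)
    consensus = {}
    for rec in survivors:
        for (j, i, s) in rec.topology.edges():
            prev = consensus.setdefault((j, i), s)
            if prev != s:
                raise ConflictingConsensusError(
                    f"interaction {labels[j]}->{labels[i]} has conflicting signs"
                )
    return {
        "survivors": survivors,
        "cores": cores,
        "consensus_edges": consensus,
    }


# ---------------------------------------------------------------------------
# grid screen


@dataclass
class ScreenConfig:
    """Reaction-coefficient grid and diffusivity contrast for the screen.

    ``grid_values`` must be symmetric about zero and contain zero; for three
    components there are six fast/slow assignments (each component slow with
    the others fast, or fast with the others slow).
    """

    grid_values: tuple = (-0.75, -0.5, -0.25, 0.0, 0.25, 0.5, 0.75)
    d_fast: float = 1.0
    d_slow: float = 0.01
    k_squared: np.ndarray = field(
        default_factory=lambda: np.geomspace(1e-6, 1e6, 96)
    )

    def __post_init__(self):
        v = np.asarray(self.grid_values, float)
        if 0.0 not in v or not np.allclose(np.sort(v), np.sort(-v)):
            raise ValueError("grid values must be symmetric about zero and include 0")

    def diffusion_assignments(self, n: int = 3):
        out = []
        for odd in range(n):
            for odd_fast in (True, False):
                D = np.full(n, self.d_fast if not odd_fast else self.d_slow)
                D[odd] = self.d_fast if odd_fast else self.d_slow
                out.append(D)
        return out

    def grid_cardinality(self, n: int = 3) -> int:
        return len(self.grid_values) ** (n * n) * len(self.diffusion_assignments(n))


def _char_coeffs3(J):
    """Characteristic-polynomial coefficients lambda^3 + A l^2 + B l + C for
    a stack of 3x3 matrices."""
    A = -(J[..., 0, 0] + J[..., 1, 1] + J[..., 2, 2])
    B = (
        J[..., 0, 0] * J[..., 1, 1]
        - J[..., 0, 1] * J[..., 1, 0]
        + J[..., 0, 0] * J[..., 2, 2]
        - J[..., 0, 2] * J[..., 2, 0]
        + J[..., 1, 1] * J[..., 2, 2]
        - J[..., 1, 2] * J[..., 2, 1]
    )
    C = -np.linalg.det(J)
    return A, B, C


def _classify_stack(J, D, k2, phase_tol=1e-9):
    """Classify a stack (m, 3, 3) of Jacobians for stationary non-oscillating
    DDI with diffusivities D (length 3).  Returns (ddi mask, phase codes):
    phase code = index into the canonical sign patterns or -1."""
    m = J.shape[0]
    ddi = np.zeros(m, bool)
    phase = np.full(m, -1, int)
    A0, B0, C0 = _char_coeffs3(J)
    stable = (A0 > 0) & (C0 > 0) & (A0 * B0 - C0 > 0)
    idx = np.where(stable)[0]
    if idx.size == 0:
        return ddi, phase
    # stationary instability: det(J - k^2 D) > 0 for some k (C < 0)
    Jb = J[idx]
    M = Jb[:, None, :, :] - k2[None, :, None, None] * np.eye(3) * D
    C = -np.linalg.det(M)
    cand = np.where(np.any(C < 0, axis=1))[0]
    for c in cand:
        b = idx[c]
        ev = np.linalg.eigvals(M[c])
        re = ev.real.max(axis=1)
        i_max = int(np.argmax(re))
        if re[i_max] <= 0 or re[-1] >= 0:
            continue
        lead = ev[i_max][np.argmax(ev[i_max].real)]
        if abs(lead.imag) > 1e-9 * (1 + abs(lead.real)):
            continue
        vals, vecs = np.linalg.eig(Jb[c] - k2[i_max] * np.diag(D))
        v = vecs[:, int(np.argmax(vals.real))].real
        nv = np.linalg.norm(v)
        if nv == 0 or np.min(np.abs(v)) < phase_tol * nv:
            continue
        signs = np.sign(v).astype(int)
        if signs[0] < 0:
            signs = -signs
        ddi[b] = True
        phase[b] = _PHASE_CODES.get(tuple(signs), -1)
    return ddi, phase


#: canonical 3-component phase signatures (first entry positive)
_PHASE_CODES = {
    (1, 1, 1): 0,
    (1, 1, -1): 1,
    (1, -1, 1): 2,
    (1, -1, -1): 3,
}
PHASE_SIGNATURES = {v: k for k, v in _PHASE_CODES.items()}


def grid_screen_3node(config: ScreenConfig = None, stride: int = 1, chunk: int = 50_000):
    """Sweep the reaction-coefficient grid over every diffusivity assignment
    and aggregate DDI evidence per signed topology.

    ``stride`` subsamples the grid (every stride-th point of the full
    enumeration order) for desk-scale runs.  Returns a dict with the total
    number of parameter sets, the DDI count, and a per-topology table
    mapping the sign pattern (9 signs, diagonal reduced to autoregulation)
    to the set of achievable phase codes.
    """
    config = config or ScreenConfig()
    vals = np.asarray(config.grid_values, float)
    nv = len(vals)
    total = 0
    n_ddi = 0
    table = {}
    examples = {}
    assignments = config.diffusion_assignments(3)
    k2 = np.asarray(config.k_squared, float)

    n_points = nv**9
    point_ids = np.arange(0, n_points, stride, dtype=np.int64)
    for D in assignments:
        for start in range(0, point_ids.size, chunk):
            ids = point_ids[start : start + chunk]
            digits = np.empty((ids.size, 9), np.int64)
            rem = ids.copy()
            for d in range(9):
                digits[:, 8 - d] = rem % nv
                rem //= nv
            J = vals[digits].reshape(-1, 3, 3)
            total += J.shape[0]
            ddi, phase = _classify_stack(J, D, k2)
            n_ddi += int(ddi.sum())
            for b in np.where(ddi)[0]:
                key = _topology_key(J[b])
                table.setdefault(key, set()).add(int(phase[b]))
                examples.setdefault(key, (J[b].copy(), D.copy()))
    return {"total": total, "n_ddi": n_ddi, "topologies": table, "examples": examples}


def _topology_key(J):
    sgn = np.sign(J).astype(int)
    return tuple(sgn.ravel())


def grid_admits_ddi(
    top: SignedTopology,
    D,
    phases=None,
    grid_values=(0.25, 0.5, 0.75),
    k_squared=None,
) -> bool:
    """Does any point of the coefficient grid, restricted to the topology's
    sign pattern, give stationary non-oscillating DDI (optionally with the
    required phase signature) under diffusivities ``D``?

    Off-diagonal magnitudes run through ``grid_values`` with the topology's
    signs; diagonal entries take the values with positive sign when the
    component autoregulates and negative otherwise.
    """
    n = top.n
    k2 = np.geomspace(1e-6, 1e6, 96) if k_squared is None else np.asarray(k_squared)
    D = np.asarray(D, float)
    edges = [(j, i, s) for (j, i, s) in top.edges() if i != j]
    mags = list(grid_values)
    diag_choices = [[m if top.autoreg[i] else -m for m in mags] for i in range(n)]
    edge_choices = [[s * m for m in mags] for (_, _, s) in edges]
    combos = list(itertools.product(*diag_choices, *edge_choices))
    J = np.zeros((len(combos), n, n))
    for c, combo in enumerate(combos):
        for i in range(n):
            J[c, i, i] = combo[i]
        for (e, w) in zip(edges, combo[n:]):
            j, i, _ = e
            J[c, i, j] = w
    ddi, phase = _classify_stack(J, D, k2)
    if phases is None:
        return bool(ddi.any())
    signs = tuple(np.sign(phases).astype(int))
    if signs[0] < 0:
        signs = tuple(-s for s in signs)
    want = _PHASE_CODES.get(signs)
    return bool(np.any(ddi & (phase == want)))


# ---------------------------------------------------------------------------
# the three-component funnel


def filter_funnel_3node(
    labels=RUGA3_LABELS,
    phases=RUGA3_PHASES,
    fast_label: str = "Hh",
    d_fast: float = 1.0,
    d_slow: float = 0.01,
    grid_values=(0.25, 0.5, 0.75),
) -> dict:
    """The three-stage reduction of the three-component topology space.

    Stage 1: minimal strongly connected topologies capable of stationary
    non-oscillating DDI with the observed phase signature.  Stage 2: the
    subset recoverable on the coefficient grid with the named component
    diffusing fast and the other two slow.  Stage 3: the subset whose
    predicted readout responses match the inhibitor experiments
    (Hh-inhibition up, BMP-inhibition up, Wnt-inhibition down).
    """
    minset = enumerate_minimal_topologies(labels, phases)
    D = np.full(3, d_slow)
    D[labels.index(fast_label)] = d_fast
    canon_phases = (1,) * 3  # decompositions live in transformed coordinates
    stage2 = []
    for rec in minset.records:
        canon_top = _canonical_to_topology(rec.canonical_edges, labels, (1, 1, 1))
        if grid_admits_ddi(canon_top, D, phases=canon_phases, grid_values=grid_values):
            stage2.append(rec)
    idx = {l: labels.index(l) for l in labels}
    stage3 = []
    for rec in stage2:
        sig = rec.signature(idx["Hh"], phases)
        if sig[idx["Wnt"]] == -1 and sig[idx["BMP"]] == 1 and sig[idx["Hh"]] == 1:
            stage3.append(rec)
    return {"stage1": minset.records, "stage2": stage2, "stage3": stage3, "minset": minset}
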