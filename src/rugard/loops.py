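"""Signed-network feedback-loop analysis for reaction-diffusion capability.

A signed regulatory network can support diffusion-driven patterning only if
it embeds a *core*: a destabilising positive feedback loop together with a
stabilising negative feedback loop that shares at least one component with
it and runs through at least one additional component.  Components outside
the core must be wired in through further feedback loops, or the network is
not strongly connected and some inhibitions could not perturb the pattern.

The same loop decomposition predicts the direction in which an established
periodic pattern shifts when one component is inhibited.  Working in
phase-transformed coordinates (flip the sign of every edge incident to an
out-of-phase component, so that the patterned mode is nominally all-positive),
each component ``t`` carries a net activation sign ``sigma(t)`` onto the core
positive loop; inhibiting ``t`` shifts the whole transformed pattern in the
direction ``-sigma(t)``, and the real-space change of a readout ``r`` is
``-sigma(t) * s_r * s_t`` where ``s`` is the spatial phase vector.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from itertools import permutations

import networkx as nx

from .rd_core import SignedTopology

__all__ = [
    "FeedbackLoop",
    "RDCore",
    "CoreDecomposition",
    "LoopDecomposition",
    "enumerate_feedback_loops",
    "find_rd_cores",
    "find_core_decompositions",
    "check_strong_connectivity",
    "predict_inhibition_signs",
    "response_signature",
    "TopologyAtlas",
    "build_atlas",
    "atlas_to_graphml",
]


@dataclass(frozen=True)
class FeedbackLoop:
    """A simple directed cycle with the product of its edge signs."""

    nodes: tuple
    edges: tuple  # ((u, v, sign), ...) meaning u -> v
    sign: int

    def __len__(self):
        return len(self.nodes)


@dataclass(frozen=True)
class RDCore:
    """A positive loop and a negative loop that could drive RD patterning."""

    positive: FeedbackLoop
    negative: FeedbackLoop

    @property
    def pos_nodes(self):
        return frozenset(self.positive.nodes)

    @property
    def neg_nodes(self):
        return frozenset(self.negative.nodes)

    @property
    def nodes(self):
        return self.pos_nodes | self.neg_nodes


@dataclass(frozen=True)
class CoreDecomposition:
    """A full structural embedding: core loops plus external wiring.

    Edges are in *phase-transformed* (canonical) signs.  ``chains`` wire the
    non-core components: each chain is a tuple of edges running from a core
    node through external components back into the core.
    """

    pos_edges: tuple  # ((u, v, +1), ...)
    neg_edges: tuple
    chains: tuple  # tuple of chains; chain = ((u, v, s), ...)

    @property
    def pos_nodes(self):
        return frozenset(u for (u, v, s) in self.pos_edges)

    @property
    def neg_nodes(self):
        return frozenset(u for (u, v, s) in self.neg_edges)

    def sigma(self, n: int) -> dict:
        """Net activation sign of every component onto the positive loop."""
        VP, VN = self.pos_nodes, self.neg_nodes
        nsucc = {u: (v, s) for (u, v, s) in self.neg_edges}
        sig = {t: 1 for t in VP}

        def neg_path_sign(v):
            total, cur = 1, v
            for _ in range(n + 1):
                nxt, s = nsucc[cur]
                total *= s
                if nxt in VP:
                    return total
                cur = nxt
            raise ValueError("negative loop never re-enters the positive loop")

        for t in VN - VP:
            sig[t] = neg_path_sign(t)
        pending = {}
        for ch in self.chains:
            for (u, v, s) in ch:
                if u not in sig and u not in VP | VN:
                    pending[u] = (v, s)

        def resolve(x, depth=0):
            if x in sig:
                return sig[x]
            if depth > n:
                raise ValueError("cyclic chain resolution")
            v, s = pending[x]
            if v in VP:
                base = 1
            elif v in VN:
                base = neg_path_sign(v)
            else:
                base = resolve(v, depth + 1)
            sig[x] = s * base
            return sig[x]

        for x in list(pending):
            resolve(x)
        return sig


@dataclass
class LoopDecomposition:
    loops: list  # FeedbackLoop
    cores: list  # RDCore
    external_nodes: dict = field(default_factory=dict)  # node -> external loop sign(s)


# ---------------------------------------------------------------------------


def _graph(top: SignedTopology) -> nx.DiGraph:
    G = nx.DiGraph()
    G.add_nodes_from(range(top.n))
    for (j, i, s) in top.edges():
        G.add_edge(j, i, sign=s)
    return G


def enumerate_feedback_loops(top: SignedTopology) -> LoopDecomposition:
    """All simple directed cycles with signs, plus the RD cores they form."""
    G = _graph(top)
    loops = []
    for cyc in nx.simple_cycles(G):
        edges = []
        sign = 1
        for a, b in zip(cyc, cyc[1:] + cyc[:1]):
            s = G.edges[a, b]["sign"]
            sign *= s
            edges.append((a, b, s))
        loops.append(FeedbackLoop(nodes=tuple(cyc), edges=tuple(edges), sign=sign))
    cores = _cores_from_loops(loops)
    return LoopDecomposition(loops=loops, cores=cores)


def _cores_from_loops(loops):
    cores = []
    pos = [l for l in loops if l.sign > 0]
    neg = [l for l in loops if l.sign < 0]
    for p in pos:
        pn = set(p.nodes)
        for q in neg:
            qn = set(q.nodes)
            if pn & qn and qn - pn:
                cores.append(RDCore(positive=p, negative=q))
    return cores


def find_rd_cores(top: SignedTopology):
    """All (positive loop, negative loop) pairs satisfying the core rule:
    shared node, and the negative loop runs through at least one component
    outside the positive loop.  Empty list means the topology cannot support
    diffusion-driven instability."""
    return enumerate_feedback_loops(top).cores


def check_strong_connectivity(top: SignedTopology) -> bool:
    G = _graph(top)
    H = nx.DiGraph((u, v) for u, v in G.edges() if u != v)
    H.add_nodes_from(range(top.n))
    return nx.is_strongly_connected(H)


# ---------------------------------------------------------------------------
# canonical (phase-transformed) structural embeddings


def canonical_edge_signs(top: SignedTopology, phases) -> dict:
    """Edge signs after flipping every edge incident to an out-of-phase node."""
    return {
        (j, i): s * phases[i] * phases[j] for (j, i, s) in top.edges()
    }


def _simple_cycles_edges(es: dict, n: int):
    adj = {u: [] for u in range(n)}
    for (u, v) in es:
        if u != v:
            adj[u].append(v)
    cycles = []
    for s in range(n):
        if (s, s) in es:
            cycles.append(((s, s),))

    def dfs(start, u, path, visited):
        for v in adj[u]:
            if v == start:
                cycles.append(tuple(zip(path, path[1:] + [start])))
            elif v > start and v not in visited:
                visited.add(v)
                dfs(start, v, path + [v], visited)
                visited.remove(v)

    for s in range(n):
        dfs(s, s, [s], {s})
    return cycles


def _chain_partitions(items):
    items = list(items)
    if not items:
        yield ()
        return
    first, rest = items[0], items[1:]
    for part in _chain_partitions(rest):
        for i, block in enumerate(part):
            for pos in range(len(block) + 1):
                yield part[:i] + (block[:pos] + (first,) + block[pos:],) + part[i + 1:]
        yield ((first,),) + part


def find_core_decompositions(top: SignedTopology, phases, outside_inhibition: bool = True) -> list:
    """All structural embeddings of a valid patterning architecture.

    In canonical signs: a positive cycle with every edge positive; a negative
    cycle whose inhibitory edges all enter the positive loop and are not
    positive-cycle edges; the remaining components covered by vertex-disjoint
    chains running core -> externals -> core with positive entry/interior
    edges and an exit edge of either sign.

    With ``outside_inhibition`` (the default, matching the enumeration's sign
    rule) the negative loop's inhibitory edges must additionally originate
    outside the positive loop; without it, inhibitory shortcuts between
    positive-loop members are accepted as well (the realizability test used
    for minimality checks).
    """
    n = top.n
    es = canonical_edge_signs(top, phases)
    cycles = _simple_cycles_edges(es, n)
    out = []
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
            sign_prod, ok = 1, True
            for e in N:
                s = es[e]
                sign_prod *= s
                if s == -1 and (
                    e[1] not in VP
                    or e in pedges
                    or (outside_inhibition and e[0] in VP)
                ):
                    ok = False
                    break
            if not ok or sign_prod != -1:
                continue
            X = [x for x in range(n) if x not in VP | VN]
            core = VP | VN
            for chains in _cover_chains(es, X, core):
                out.append(
                    CoreDecomposition(
                        pos_edges=tuple((u, v, 1) for (u, v) in P),
                        neg_edges=tuple((u, v, es[(u, v)]) for (u, v) in N),
                        chains=chains,
                    )
                )
    return out


def _cover_chains(es, X, core):
    if not X:
        yield ()
        return
    for part in _chain_partitions(X):
        assignments = []
        ok = True
        for ch in part:
            opts = []
            entries = [a for a in core if es.get((a, ch[0])) == 1]
            exits = [(b, es[(ch[-1], b)]) for b in core if (ch[-1], b) in es]
            interior_ok = all(es.get((ch[i], ch[i + 1])) == 1 for i in range(len(ch) - 1))
            if interior_ok:
                for a in entries:
                    for b, s_exit in exits:
                        edges = [(a, ch[0], 1)]
                        for i in range(len(ch) - 1):
                            edges.append((ch[i], ch[i + 1], 1))
                        edges.append((ch[-1], b, s_exit))
                        opts.append(tuple(edges))
            if not opts:
                ok = False
                break
            assignments.append(opts)
        if not ok:
            continue
        # yield one representative wiring per partition (predictions depend
        # only on chain interiors and exit signs, enumerated below)
        from itertools import product

        seen = set()
        for combo in product(*assignments):
            sig_rel = tuple(
                tuple((u, v, s) for (u, v, s) in ch) for ch in combo
            )
            if sig_rel in seen:
                continue
            seen.add(sig_rel)
            yield tuple(sorted(combo))


def has_embedded_core(top: SignedTopology, phases, outside_inhibition: bool = False) -> bool:
    """Cheap qualification: does any valid embedding exist?  By default the
    permissive (realizability) rule is used."""
    for _ in find_core_decompositions(top, phases, outside_inhibition):
        return True
    return False


# ---------------------------------------------------------------------------
# perturbation-sign prediction


def predict_inhibition_signs(
    top: SignedTopology,
    phases,
    target: int,
    mode: str = "response",
    decompositions=None,
) -> list:
    """Predicted sign of each component's mean-level change under inhibition
    of ``target`` (+1 increase, -1 decrease, 0 core-dependent).

    Response- and production-mode inhibition shift the pattern in the same
    direction; the mode argument is kept for interface clarity.  Predictions
    are unioned over all structural embeddings; disagreement yields 0.
    Self-inhibition of a component that belongs to the negative loop
    (including both-loops components) raises that component's own level.
    """
    n = top.n
    if decompositions is None:
        decompositions = find_core_decompositions(top, phases)
    if not decompositions:
        raise ValueError("topology has no RD core; predictions undefined")
    out = []
    for r in range(n):
        out.append(_union_entry(decompositions, n, phases, target, r))
    return out


def _union_entry(decompositions, n: int, phases, t: int, r: int) -> int:
    # self-inhibition of a component with a stabilising (negative-loop) role
    # in any core raises its own level
    if t == r and any(t in dec.neg_nodes for dec in decompositions):
        return 1
    vals = {-dec.sigma(n)[t] * phases[r] * phases[t] for dec in decompositions}
    return vals.pop() if len(vals) == 1 else 0


def response_signature(
    top: SignedTopology,
    phases,
    readout: int,
    modes=None,
    decompositions=None,
) -> tuple:
    """Per-target predicted sign of the readout's change, one entry per
    component (the Hh-response signature when readout = the Hh node)."""
    n = top.n
    if decompositions is None:
        decompositions = find_core_decompositions(top, phases)
    if not decompositions:
        raise ValueError("topology has no RD core; predictions undefined")
    return tuple(
        _union_entry(decompositions, n, phases, t, readout) for t in range(n)
    )


# ---------------------------------------------------------------------------
# topology atlas ("stalactite" structure)


@dataclass
class TopologyAtlas:
    topologies: list  # SignedTopology
    links: list  # (i, j) index pairs differing by one interaction
    minimal_set: list  # indices of stalactite bases

    def rows_by_edge_count(self) -> dict:
        rows = {}
        for i, t in enumerate(self.topologies):
            rows.setdefault(len(t.edges()), []).append(i)
        return rows


def _interaction_set(top: SignedTopology) -> frozenset:
    return frozenset(top.edges())


def atlas_to_graphml(atlas: "TopologyAtlas", path):
    """Write the atlas as GraphML: one node per topology (edge list encoded
    as an attribute), links between single-interaction neighbours."""
    G = nx.DiGraph()
    for i, top in enumerate(atlas.topologies):
        G.add_node(
            i,
            interactions=";".join(f"{j}>{k}:{s}" for (j, k, s) in sorted(top.edges())),
            n_interactions=len(top.edges()),
            minimal=i in set(atlas.minimal_set),
        )
    G.add_edges_from(atlas.links)
    nx.write_graphml(G, path)


def build_atlas(topologies) -> TopologyAtlas:
    """Atlas linking topologies that differ by gain/loss of one interaction.

    The minimal set contains the topologies none of whose single-deletion
    children appear in the atlas — the stalactite bases.
    """
    if len({t.labels for t in topologies}) > 1:
        raise ValueError("atlas topologies must share one node set")
    keys = [_interaction_set(t) for t in topologies]
    index = {k: i for i, k in enumerate(keys)}
    links = []
    minimal = []
    for i, k in enumerate(keys):
        is_min = True
        for e in k:
            child = k - {e}
            j = index.get(child)
            if j is not None:
                links.append((j, i))
                is_min = False
        if is_min:
            minimal.append(i)
    return TopologyAtlas(topologies=list(topologies), links=links, minimal_set=minimal)
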