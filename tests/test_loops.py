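import numpy as np
import pytest

from rugard.rd_core import SignedTopology
from rugard.loops import (
    build_atlas,
    check_strong_connectivity,
    enumerate_feedback_loops,
    find_core_decompositions,
    find_rd_cores,
    predict_inhibition_signs,
    response_signature,
)
from rugard.examples import two_fgf_topology


def test_mutual_inhibition_is_a_positive_loop():
    top = SignedTopology(sign=((0, -1), (-1, 0)), autoreg=(False, False), labels=("W", "B"))
    dec = enumerate_feedback_loops(top)
    assert len(dec.loops) == 1
    assert dec.loops[0].sign == 1


def test_three_cycle_of_inhibitions_is_negative():
    top = SignedTopology(
        sign=((0, 0, -1), (-1, 0, 0), (0, -1, 0)),
        autoreg=(False, False, False),
        labels=("W", "B", "H"),
    )
    dec = enumerate_feedback_loops(top)
    three = [l for l in dec.loops if len(l) == 3]
    assert len(three) == 1 and three[0].sign == -1


def test_empty_graph_has_no_loops():
    top = SignedTopology(sign=((0, 0), (0, 0)), autoreg=(False, False))
    assert enumerate_feedback_loops(top).loops == []
    assert find_rd_cores(top) == []


def test_textbook_ai_core(ai_topology):
    cores = find_rd_cores(ai_topology)
    assert len(cores) == 1
    core = cores[0]
    assert core.pos_nodes == frozenset({0})  # the self-activation
    assert core.neg_nodes == frozenset({0, 1})  # the U-V two-cycle


def test_all_negative_topology_still_has_a_core():
    # mutual inhibition of W and B is the positive loop; the three-cycle of
    # inhibitions through Hh is the negative loop
    top = SignedTopology(
        sign=((0, -1, -1), (-1, 0, 0), (0, -1, 0)),
        autoreg=(False, False, False),
        labels=("W", "B", "H"),
    )
    cores = find_rd_cores(top)
    assert any(
        c.pos_nodes == frozenset({0, 1}) and c.neg_nodes == frozenset({0, 1, 2})
        for c in cores
    )


def test_acyclic_graph_has_no_core():
    top = SignedTopology(
        sign=((0, 0, 0), (1, 0, 0), (0, 1, 0)), autoreg=(False, False, False)
    )
    assert find_rd_cores(top) == []


def test_strong_connectivity():
    cyc = SignedTopology(
        sign=((0, 0, 1), (1, 0, 0), (0, 1, 0)), autoreg=(False, False, False)
    )
    assert check_strong_connectivity(cyc)
    dead_end = SignedTopology(
        sign=((0, 0, 0), (1, 0, 0), (1, 0, 0)), autoreg=(False, False, False)
    )
    assert not check_strong_connectivity(dead_end)


def test_ai_predictions_match_constraint_analysis(ai_topology):
    phases = (1, 1)  # classic AI patterns in phase
    signs = predict_inhibition_signs(ai_topology, phases, target=1, mode="response")
    assert signs[0] == 1  # blocking the inhibitor raises the activator
    signs_u = predict_inhibition_signs(ai_topology, phases, target=0, mode="response")
    assert signs_u[1] == -1  # blocking the activator lowers the inhibitor


def test_two_fgf_network_predicts_opposing_fgf_effects():
    top = two_fgf_topology()
    phases = (1, -1, 1)  # mF in phase with Hh, eF out of phase
    sig = response_signature(top, phases, readout=2)
    assert sig[0] != 0 and sig[1] != 0
    assert sig[0] == -sig[1]


def test_valid_wbh_topology_signature():
    # W-|B, B-|W, W->H, H-|W with phases (+,-,+): the experimentally
    # observed response pattern (Wnt down, BMP up, Hh up)
    top = SignedTopology(
        sign=((0, -1, -1), (-1, 0, 0), (1, 0, 0)),
        autoreg=(False, False, False),
        labels=("Wnt", "BMP", "Hh"),
    )
    assert response_signature(top, (1, -1, 1), readout=2) == (-1, 1, 1)


def test_decompositions_sigma_is_consistent(ai_topology):
    decs = find_core_decompositions(ai_topology, (1, 1))
    assert decs
    for dec in decs:
        sigma = dec.sigma(2)
        assert sigma[0] == 1  # the autoactivator drives the positive loop
        assert sigma[1] == -1  # the inhibitor's path into it is negative


def test_atlas_chain_and_minimality():
    base = SignedTopology(
        sign=((1, -1), (1, 0)), autoreg=(True, False), labels=("U", "V")
    )
    plus_one = SignedTopology(
        sign=((1, -1), (1, 1)), autoreg=(True, True), labels=("U", "V")
    )
    atlas = build_atlas([base, plus_one])
    assert atlas.links == [(0, 1)]
    assert atlas.minimal_set == [0]
    rows = atlas.rows_by_edge_count()
    assert sorted(rows) == [3, 4]


def test_minimal_topologies_lose_the_core_on_any_deletion(minset3, rng):
    sample = [minset3.records[i] for i in rng.choice(len(minset3), 6, replace=False)]
    from rugard.loops import has_embedded_core

    for rec in sample:
        top = rec.topology
        assert has_embedded_core(top, minset3.phases)
        for (j, i, s) in top.edges():
            sign = [list(row) for row in top.sign]
            sign[i][j] = 0
            autoreg = list(top.autoreg)
            if i == j:
                autoreg[i] = False
            child = SignedTopology(
                sign=tuple(map(tuple, sign)), autoreg=tuple(autoreg), labels=top.labels
            )
            assert not (
                check_strong_connectivity(child)
                and has_embedded_core(child, minset3.phases)
            )
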