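"""Geometric H-bond detection, water bridges, occupancy and graph sets."""

import numpy as np
import pytest

from conftest import make_frame, naive_bridges, naive_links, random_small_system

from phtitra.hbond import (
    FrameHBonds,
    GraphSet,
    GraphSpec,
    HBondCriteria,
    HBondEdge,
    TABLE1_THRESHOLDS,
    accumulate_occupancy,
    build_graph,
    detect_hbonds_frame,
    detect_water_bridges,
    graph_edges,
    summarize_frame,
    write_edge_list,
)


def _pair_frame(da_distance, deviation_deg):
    """Two hydroxyl groups with a donor–H···acceptor geometry at the given
    distance and angular deviation from linearity."""
    theta = np.radians(180.0 - deviation_deg)
    h = np.array([1.0, 0.0, 0.0])
    # acceptor positioned so that angle(D,H,A) = 180 - deviation
    direction = np.array([np.cos(np.pi - theta), np.sin(np.pi - theta), 0.0])
    # choose A on the cone so |D-A| equals da_distance
    a = None
    for r in np.linspace(0.5, 6.0, 2201):
        cand = h + r * direction
        if abs(np.linalg.norm(cand) - da_distance) < 2e-3:
            a = cand
            break
    assert a is not None, "could not realise requested geometry"
    return make_frame(
        [
            ("A", 1, "SER", "OG", "O", np.zeros(3)),
            ("A", 1, "SER", "HG", "H", h),
            ("A", 2, "SER", "OG", "O", a),
        ]
    )


# -- direct detection -------------------------------------------------------

def test_collinear_bond_detected_under_both_angles():
    frame = _pair_frame(2.9, 0.0)
    for angle in (20.0, 60.0):
        bonds = detect_hbonds_frame(frame, criteria=HBondCriteria(max_angle_deviation=angle))
        assert len(bonds) == 1
        assert bonds[0].distance == pytest.approx(2.9, abs=1e-2)


def test_long_distance_not_detected_despite_perfect_angle():
    frame = _pair_frame(3.6, 0.0)
    assert detect_hbonds_frame(frame) == []


def test_angular_deviation_criterion_ordering():
    frame = _pair_frame(3.0, 40.0)
    assert detect_hbonds_frame(frame, criteria=HBondCriteria(max_angle_deviation=60)) != []
    assert detect_hbonds_frame(frame, criteria=HBondCriteria(max_angle_deviation=20)) == []


def test_donor_without_hydrogen_skipped_not_fatal():
    frame = make_frame(
        [
            ("A", 1, "SER", "OG", "O", np.zeros(3)),
            ("A", 2, "SER", "OG", "O", np.array([2.9, 0.0, 0.0])),
        ]
    )
    assert detect_hbonds_frame(frame) == []


def test_criteria_validation():
    with pytest.raises(ValueError):
        HBondCriteria(max_da_distance=-1)
    with pytest.raises(ValueError):
        HBondCriteria(max_angle_deviation=120)
    with pytest.raises(ValueError):
        HBondCriteria(max_bridge_waters=4)


# -- water bridges ----------------------------------------------------------

def _chain_frame(n_waters):
    """Group A — w1..wk — group B, all links collinear at 2.9 Å."""
    atoms = [
        ("A", 1, "SER", "OG", "O", np.array([0.0, 0.0, 0.0])),
        ("A", 1, "SER", "HG", "H", np.array([1.0, 0.0, 0.0])),
    ]
    x = 0.0
    for w in range(n_waters):
        x += 2.9
        atoms += [
            ("W", 100 + w, "HOH", "O", "O", np.array([x, 0.0, 0.0])),
            ("W", 100 + w, "HOH", "H1", "H", np.array([x + 1.0, 0.0, 0.0])),
            ("W", 100 + w, "HOH", "H2", "H", np.array([x, 1.0, 0.0])),
        ]
    atoms.append(("A", 2, "SER", "OG", "O", np.array([x + 2.9, 0.0, 0.0])))
    return make_frame(atoms)


@pytest.mark.parametrize("n_waters", [1, 2, 3])
def test_water_chain_bridges_recovered(n_waters):
    bridges = detect_water_bridges(_chain_frame(n_waters))
    assert bridges == {("SER1", "SER2", n_waters)}


def test_four_water_chain_is_not_a_bridge():
    assert detect_water_bridges(_chain_frame(4)) == set()


def test_bridge_depth_respects_max_waters():
    assert detect_water_bridges(
        _chain_frame(2), criteria=HBondCriteria(max_bridge_waters=1)
    ) == set()


# -- occupancy accounting ---------------------------------------------------

def test_occupancy_arithmetic():
    present = FrameHBonds(direct_all={("A1", "B2")}, direct_sc={("A1", "B2")})
    absent = FrameHBonds()
    occ = accumulate_occupancy([present] * 1000 + [absent] * 1000)
    assert occ.occupancy(("A1", "B2"), "direct") == pytest.approx(50.0)
    full = accumulate_occupancy([present] * 10)
    assert full.occupancy(("A1", "B2"), "direct") == pytest.approx(100.0)
    assert occ.occupancy(("A1", "Z9"), "direct") == 0.0
    assert ("A1", "Z9") not in occ.direct_all


def test_occupancy_pooling_is_concatenation():
    present = FrameHBonds(direct_all={("A1", "B2")})
    occ1 = accumulate_occupancy([present] * 10)
    occ2 = accumulate_occupancy([FrameHBonds()] * 30)
    pooled = occ1 + occ2
    assert pooled.n_frames == 40
    assert pooled.occupancy(("A1", "B2"), "direct") == pytest.approx(25.0)


# -- graph sets and canonical thresholds ------------------------------------

def test_graph_spec_rejects_inconsistent_threshold():
    with pytest.raises(ValueError, match="canonical"):
        GraphSpec(GraphSet.SIDECHAIN_DIRECT, 60, occupancy_threshold=40.0)
    # canonical value and explicit override are both fine
    GraphSpec(GraphSet.SIDECHAIN_DIRECT, 60, occupancy_threshold=15.0)
    GraphSpec(GraphSet.SIDECHAIN_DIRECT, 60, occupancy_threshold=40.0, allow_override=True)


def test_graph_spec_resolves_canonical_thresholds():
    for (gs, angle), thr in TABLE1_THRESHOLDS.items():
        assert GraphSpec(GraphSet(gs), angle).resolved_threshold == thr


def test_edge_invariants():
    with pytest.raises(ValueError):
        HBondEdge("A1", "A1", "direct", 0, 50.0)
    with pytest.raises(ValueError):
        HBondEdge("A1", "B2", "direct", 0, 150.0)


def test_edge_symmetry_independent_of_direction():
    """B donating to A is recorded as the same sorted pair as A donating to B."""
    f1 = _pair_frame(2.9, 0.0)
    summary = summarize_frame(f1)
    assert summary.direct_all == {("SER1", "SER2")}
    # swap roles: donor on residue 2
    frame = make_frame(
        [
            ("A", 1, "SER", "OG", "O", np.zeros(3)),
            ("A", 2, "SER", "OG", "O", np.array([2.9, 0.0, 0.0])),
            ("A", 2, "SER", "HG", "H", np.array([1.9, 0.0, 0.0])),
        ]
    )
    assert summarize_frame(frame).direct_all == {("SER1", "SER2")}


def test_edge_list_export_deterministic(tmp_path):
    frame = _chain_frame(1)
    occ = accumulate_occupancy([summarize_frame(frame)] * 5)
    edges = graph_edges(occ, GraphSpec(GraphSet.SIDECHAIN_WATER, 60))
    p1, p2 = tmp_path / "a.csv", tmp_path / "b.csv"
    write_edge_list(edges, p1)
    write_edge_list(edges, p2)
    assert p1.read_bytes() == p2.read_bytes()
    assert b"water_bridged" in p1.read_bytes()


# -- oracle equivalence and nesting on random systems ------------------------

@pytest.mark.parametrize("seed", range(12))
def test_random_system_matches_bruteforce_oracle(seed):
    """Detection (direct + bridges) equals exhaustive enumeration."""
    rng = np.random.default_rng(seed)
    frame = random_small_system(rng, n_groups=int(rng.integers(4, 9)),
                                n_waters=int(rng.integers(3, 10)))
    criteria = HBondCriteria(max_angle_deviation=60.0)
    summary = summarize_frame(frame, criteria=criteria)
    direct, g2w, ww = naive_links(frame, criteria)
    assert summary.direct_all == direct
    assert summary.bridged_all == naive_bridges(g2w, ww, criteria.max_bridge_waters)


@pytest.mark.parametrize("seed", range(6))
def test_angle_and_set_nesting(seed):
    rng = np.random.default_rng(1000 + seed)
    frame = random_small_system(rng)
    occ20 = accumulate_occupancy(
        [summarize_frame(frame, criteria=HBondCriteria(max_angle_deviation=20))]
    )
    occ60 = accumulate_occupancy(
        [summarize_frame(frame, criteria=HBondCriteria(max_angle_deviation=60))]
    )

    def pairs(occ, gs, angle):
        spec = GraphSpec(GraphSet(gs), angle, occupancy_threshold=10.0,
                         allow_override=True)
        return {(e.group_a, e.group_b) for e in graph_edges(occ, spec)}

    # stricter angle yields a subset at equal threshold
    for gs in (1, 2, 3):
        assert pairs(occ20, gs, 20) <= pairs(occ60, gs, 60)
    # set 3 ⊆ set 2 ⊆ set 1 at equal criteria
    assert pairs(occ60, 3, 60) <= pairs(occ60, 2, 60) <= pairs(occ60, 1, 60)


def test_raising_threshold_never_adds_edges():
    frame = _chain_frame(1)
    occ = accumulate_occupancy(
        [summarize_frame(frame)] * 3 + [FrameHBonds()] * 7
    )
    lo = {
        (e.group_a, e.group_b)
        for e in graph_edges(occ, GraphSpec(GraphSet.SIDECHAIN_WATER, 60,
                                            occupancy_threshold=10, allow_override=True))
    }
    hi = {
        (e.group_a, e.group_b)
        for e in graph_edges(occ, GraphSpec(GraphSet.SIDECHAIN_WATER, 60,
                                            occupancy_threshold=50, allow_override=True))
    }
    assert hi <= lo and lo == {("SER1", "SER2")} and hi == set()


def test_build_graph_edge_attributes():
    frame = _chain_frame(1)
    occ = accumulate_occupancy([summarize_frame(frame)] * 4)
    g = build_graph(occ, GraphSpec(GraphSet.SIDECHAIN_WATER, 60))
    assert g.has_edge("SER1", "SER2")
    data = g.edges["SER1", "SER2"]
    assert data["bridged_occupancy"] == pytest.approx(100.0)
    assert data["min_waters"] == 1
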