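"""Geometric H-bond and water-bridge network analysis.

Re-implements the graph computation used for residue-level H-bond networks:
an H-bond exists when the donor/acceptor heavy-atom distance is ≤ 3.5 Å and
the donor–H···acceptor arrangement deviates from linearity by at most a
cutoff (20° strict, 60° permissive).  Two protein groups are water-bridged
when a path donor — w1 [— w2 [— w3]] — acceptor exists in which every
consecutive link is itself an H-bond; at most three waters are allowed and
water identities are ignored (a bridge is keyed by its endpoint pair).

Occupancy of an edge is the percentage of analysed frames in which it is
present.  Three residue-level graph sets are built, with occupancy
thresholds tied to the angle criterion:

    set 1 — backbone + side chains, direct and water-bridged   (20°: 10%, 60°: 50%)
    set 2 — side chains only, direct and water-bridged         (20°: 10%, 60°: 25%)
    set 3 — side chains only, direct only                      (20°: 10%, 60°: 15%)

Edges are undirected: donating and accepting are not distinguished.
"""

from __future__ import annotations

import enum
import logging
from collections import defaultdict
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import networkx as nx
from scipy.spatial import cKDTree

import biotite.structure as struc

from .chemistry import BACKBONE_ATOMS, DonorAcceptorTable, is_water
from .structures import ConformerEnsemble

__all__ = [
    "HBondCriteria",
    "AtomHBond",
    "FrameHBonds",
    "HBondOccupancies",
    "HBondEdge",
    "GraphSet",
    "GraphSpec",
    "TABLE1_THRESHOLDS",
    "detect_hbonds_frame",
    "detect_water_bridges",
    "summarize_frame",
    "accumulate_occupancy",
    "analyze_ensemble",
    "merge_occupancies",
    "build_graph",
    "graph_edges",
    "write_edge_list",
    "write_graphml",
]

logger = logging.getLogger(__name__)

Pair = tuple[str, str]

_H_COVALENT_CUTOFF = 1.25  # Å; H considered bonded to its donor heavy atom


@dataclass(frozen=True)
class HBondCriteria:
    """Geometric criteria: D–A distance, angular deviation, bridge depth."""

    max_da_distance: float = 3.5
    max_angle_deviation: float = 60.0
    max_bridge_waters: int = 3

    def __post_init__(self) -> None:
        if self.max_da_distance <= 0:
            raise ValueError("max_da_distance must be positive")
        if not (0.0 < self.max_angle_deviation <= 90.0):
            raise ValueError("max_angle_deviation must lie in (0, 90]")
        if self.max_bridge_waters not in (1, 2, 3):
            raise ValueError("max_bridge_waters must be 1, 2 or 3")


@dataclass(frozen=True)
class AtomHBond:
    """One atom-level H-bond in one frame."""

    donor_index: int
    hydrogen_index: int
    acceptor_index: int
    distance: float
    deviation: float


# --------------------------------------------------------------------------
# per-topology chemistry resolution (shared across frames of a stack)
# --------------------------------------------------------------------------

class _Topology:
    """Donor/acceptor/hydrogen bookkeeping for one atom array topology."""

    def __init__(
        self,
        frame: struc.AtomArray,
        table: DonorAcceptorTable,
        states: Mapping[str, str] | None,
    ):
        n = frame.array_length()
        res_names = frame.res_name.astype(str)
        atom_names = np.char.upper(frame.atom_name.astype(str))
        elements = np.char.upper(frame.element.astype(str))
        water_mask = np.array([is_water(rn) for rn in res_names])

        # residue instances: consecutive (chain, res_id, res_name) runs
        keys = list(zip(frame.chain_id.astype(str), frame.res_id, res_names))
        inst = np.zeros(n, dtype=int)
        current = 0
        for i in range(1, n):
            if keys[i] != keys[i - 1]:
                current += 1
            inst[i] = current
        self.instance = inst
        self.group_key = np.array(
            [f"{rn}{ri}" for rn, ri in zip(res_names, frame.res_id)], dtype=object
        )
        self.is_water = water_mask
        self.is_sidechain = ~water_mask & ~np.isin(atom_names, list(BACKBONE_ATOMS))

        # water molecule index per atom (-1 for protein)
        self.water_index = np.where(water_mask, inst, -1)

        states = states or {}
        donor_heavy: list[int] = []
        acceptor: list[int] = []
        h_mask = elements == "H"
        for i in range(n):
            if h_mask[i]:
                continue
            rn, an = res_names[i], atom_names[i]
            state = states.get(self.group_key[i])
            if an in table.donors(rn, state):
                donor_heavy.append(i)
            if an in table.acceptors(rn, state):
                acceptor.append(i)
        self.acceptor_indices = np.array(acceptor, dtype=int)

        # attach hydrogens geometrically (covalent distance, same residue)
        coords = frame.coord
        h_idx = np.flatnonzero(h_mask)
        self.donors: list[tuple[int, np.ndarray]] = []
        if h_idx.size:
            h_tree = cKDTree(coords[h_idx])
            for d in donor_heavy:
                near = h_tree.query_ball_point(coords[d], _H_COVALENT_CUTOFF)
                attached = np.array(
                    [h_idx[j] for j in near if inst[h_idx[j]] == inst[d]], dtype=int
                )
                if attached.size == 0:
                    logger.debug(
                        "donor %s:%s has no resolvable hydrogen; skipped",
                        self.group_key[d],
                        atom_names[d],
                    )
                    continue
                self.donors.append((d, attached))
        elif donor_heavy:
            logger.warning("no hydrogen atoms in topology; no donors resolvable")


def _deviation_deg(d: np.ndarray, h: np.ndarray, a: np.ndarray) -> float:
    """Deviation from donor–H···acceptor linearity; 0° for a linear bond."""
    v1 = d - h
    v2 = a - h
    cos = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    theta = np.degrees(np.arccos(np.clip(cos, -1.0, 1.0)))
    return 180.0 - theta


def _detect(topology: _Topology, coords: np.ndarray, criteria: HBondCriteria) -> list[AtomHBond]:
    bonds: list[AtomHBond] = []
    acc = topology.acceptor_indices
    if acc.size == 0 or not topology.donors:
        return bonds
    tree = cKDTree(coords[acc])
    for d, hydrogens in topology.donors:
        near = tree.query_ball_point(coords[d], criteria.max_da_distance)
        for j in near:
            a = int(acc[j])
            # same residue-level group (covers split residue blocks too)
            if topology.group_key[a] == topology.group_key[d]:
                continue
            best = None
            for h in hydrogens:
                dev = _deviation_deg(coords[d], coords[h], coords[a])
                if dev <= criteria.max_angle_deviation and (
                    best is None or dev < best[1]
                ):
                    best = (int(h), dev)
            if best is not None:
                bonds.append(
                    AtomHBond(
                        donor_index=int(d),
                        hydrogen_index=best[0],
                        acceptor_index=a,
                        distance=float(np.linalg.norm(coords[d] - coords[a])),
                        deviation=best[1],
                    )
                )
    return bonds


def detect_hbonds_frame(
    frame: struc.AtomArray,
    table: DonorAcceptorTable | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    states: Mapping[str, str] | None = None,
) -> list[AtomHBond]:
    """Atom-level H-bonds of one coordinate frame.

    A donor/acceptor pair is reported when the heavy-atom distance is within
    the cutoff and at least one donor hydrogen satisfies the deviation
    criterion.  Donors without a resolvable hydrogen are skipped (logged),
    not fatal.
    """
    table = table or DonorAcceptorTable.default()
    topo = _Topology(frame, table, states)
    return _detect(topo, frame.coord, criteria)


# --------------------------------------------------------------------------
# residue-level per-frame summary and water bridges
# --------------------------------------------------------------------------

@dataclass
class FrameHBonds:
    """Residue-level connections in one frame, by scope.

    ``direct_all`` includes backbone and side-chain bonds; ``direct_sc``
    keeps pairs with at least one bond whose two protein atoms are both
    side-chain.  Bridged dicts map endpoint pairs to the minimal number of
    bridging waters (1–3).
    """

    direct_all: set[Pair] = field(default_factory=set)
    direct_sc: set[Pair] = field(default_factory=set)
    bridged_all: dict[Pair, int] = field(default_factory=dict)
    bridged_sc: dict[Pair, int] = field(default_factory=dict)


def _pair(a: str, b: str) -> Pair:
    return (a, b) if a <= b else (b, a)


def _bridges(
    group_links: Mapping[str, set[int]],
    water_links: Mapping[int, set[str]],
    ww_adj: Mapping[int, set[int]],
    max_waters: int,
) -> dict[Pair, int]:
    """Minimal water counts for all bridged group pairs (BFS through waters)."""
    out: dict[Pair, int] = {}
    for group, seed_waters in group_links.items():
        depth = {w: 1 for w in seed_waters}
        frontier = set(seed_waters)
        for d in range(1, max_waters + 1):
            for w in frontier:
                for other in water_links.get(w, ()):
                    if other == group:
                        continue
                    p = _pair(group, other)
                    if d < out.get(p, 99):
                        out[p] = d
            if d == max_waters:
                break
            nxt = set()
            for w in frontier:
                for w2 in ww_adj.get(w, ()):
                    if w2 not in depth:
                        depth[w2] = d + 1
                        nxt.add(w2)
            frontier = nxt
            if not frontier:
                break
    return out


def summarize_frame(
    frame_or_topology,
    coords: np.ndarray | None = None,
    table: DonorAcceptorTable | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    states: Mapping[str, str] | None = None,
) -> FrameHBonds:
    """Residue-level direct bonds and water bridges for one frame."""
    if isinstance(frame_or_topology, _Topology):
        topo = frame_or_topology
        assert coords is not None
    else:
        table = table or DonorAcceptorTable.default()
        topo = _Topology(frame_or_topology, table, states)
        coords = frame_or_topology.coord
    bonds = _detect(topo, coords, criteria)

    direct_all: set[Pair] = set()
    direct_sc: set[Pair] = set()
    # water links: group -> waters, water -> groups, with side-chain variants
    g2w_all: dict[str, set[int]] = defaultdict(set)
    w2g_all: dict[int, set[str]] = defaultdict(set)
    g2w_sc: dict[str, set[int]] = defaultdict(set)
    w2g_sc: dict[int, set[str]] = defaultdict(set)
    ww: dict[int, set[int]] = defaultdict(set)

    for b in bonds:
        d, a = b.donor_index, b.acceptor_index
        d_wat, a_wat = topo.is_water[d], topo.is_water[a]
        if not d_wat and not a_wat:
            p = _pair(topo.group_key[d], topo.group_key[a])
            direct_all.add(p)
            if topo.is_sidechain[d] and topo.is_sidechain[a]:
                direct_sc.add(p)
        elif d_wat and a_wat:
            w1, w2 = int(topo.water_index[d]), int(topo.water_index[a])
            ww[w1].add(w2)
            ww[w2].add(w1)
        else:
            if d_wat:
                g, w, sc = topo.group_key[a], int(topo.water_index[d]), topo.is_sidechain[a]
            else:
                g, w, sc = topo.group_key[d], int(topo.water_index[a]), topo.is_sidechain[d]
            g2w_all[g].add(w)
            w2g_all[w].add(g)
            if sc:
                g2w_sc[g].add(w)
                w2g_sc[w].add(g)

    return FrameHBonds(
        direct_all=direct_all,
        direct_sc=direct_sc,
        bridged_all=_bridges(g2w_all, w2g_all, ww, criteria.max_bridge_waters),
        bridged_sc=_bridges(g2w_sc, w2g_sc, ww, criteria.max_bridge_waters),
    )


def detect_water_bridges(
    frame: struc.AtomArray,
    table: DonorAcceptorTable | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    states: Mapping[str, str] | None = None,
    sidechain_only: bool = False,
) -> set[tuple[str, str, int]]:
    """Water-bridged group pairs of one frame as (group_a, group_b, n_waters).

    ``n_waters`` is the minimal chain length (1–3); endpoint pairs are
    undirected and water identities are ignored.
    """
    summary = summarize_frame(frame, table=table, criteria=criteria, states=states)
    bridged = summary.bridged_sc if sidechain_only else summary.bridged_all
    return {(a, b, n) for (a, b), n in bridged.items()}


# --------------------------------------------------------------------------
# occupancy accounting over frames
# --------------------------------------------------------------------------

@dataclass
class HBondOccupancies:
    """Frame counts per residue pair, split by kind (direct / bridged) and
    scope (all groups / side chains only)."""

    n_frames: int
    criteria: HBondCriteria
    direct_all: dict[Pair, int] = field(default_factory=dict)
    direct_sc: dict[Pair, int] = field(default_factory=dict)
    bridged_all: dict[Pair, int] = field(default_factory=dict)
    bridged_sc: dict[Pair, int] = field(default_factory=dict)
    min_waters_all: dict[Pair, int] = field(default_factory=dict)
    min_waters_sc: dict[Pair, int] = field(default_factory=dict)

    def occupancy(self, pair: Pair, kind: str, sidechain_only: bool = False) -> float:
        """Occupancy in percent of the analysed frames; 0 if never seen."""
        table = {
            ("direct", False): self.direct_all,
            ("direct", True): self.direct_sc,
            ("water_bridged", False): self.bridged_all,
            ("water_bridged", True): self.bridged_sc,
        }[(kind, sidechain_only)]
        return 100.0 * table.get(_pair(*pair), 0) / self.n_frames

    def __add__(self, other: "HBondOccupancies") -> "HBondOccupancies":
        if self.criteria != other.criteria:
            raise ValueError("cannot pool occupancies computed with different criteria")
        merged = HBondOccupancies(
            n_frames=self.n_frames + other.n_frames, criteria=self.criteria
        )
        for attr in ("direct_all", "direct_sc", "bridged_all", "bridged_sc"):
            mine, theirs = getattr(self, attr), getattr(other, attr)
            out = dict(mine)
            for k, v in theirs.items():
                out[k] = out.get(k, 0) + v
            setattr(merged, attr, out)
        for attr in ("min_waters_all", "min_waters_sc"):
            mine, theirs = getattr(self, attr), getattr(other, attr)
            out = dict(mine)
            for k, v in theirs.items():
                out[k] = min(out.get(k, 99), v)
            setattr(merged, attr, out)
        return merged


def accumulate_occupancy(
    frame_summaries: Iterable[FrameHBonds], criteria: HBondCriteria = HBondCriteria()
) -> HBondOccupancies:
    """Fold per-frame detections into presence counts; direct and bridged
    occupancies are tracked separately."""
    summaries = list(frame_summaries)
    if not summaries:
        raise ValueError("no frames to accumulate")
    occ = HBondOccupancies(n_frames=len(summaries), criteria=criteria)
    for s in summaries:
        for p in s.direct_all:
            occ.direct_all[p] = occ.direct_all.get(p, 0) + 1
        for p in s.direct_sc:
            occ.direct_sc[p] = occ.direct_sc.get(p, 0) + 1
        for p, n in s.bridged_all.items():
            occ.bridged_all[p] = occ.bridged_all.get(p, 0) + 1
            occ.min_waters_all[p] = min(occ.min_waters_all.get(p, 99), n)
        for p, n in s.bridged_sc.items():
            occ.bridged_sc[p] = occ.bridged_sc.get(p, 0) + 1
            occ.min_waters_sc[p] = min(occ.min_waters_sc.get(p, 99), n)
    return occ


def analyze_ensemble(
    ensemble: ConformerEnsemble,
    table: DonorAcceptorTable | None = None,
    criteria: HBondCriteria = HBondCriteria(),
    states: Mapping[str, str] | None = None,
    frame_indices: Sequence[int] | None = None,
) -> HBondOccupancies:
    """Detect H-bonds in every (selected) frame and accumulate occupancies.

    The topology (donor/acceptor roles, hydrogen attachment) is resolved once
    on the first frame and reused, since the atom list is shared.
    """
    table = table or DonorAcceptorTable.default()
    topo = _Topology(ensemble.frame(0), table, states)
    indices = range(ensemble.n_frames) if frame_indices is None else frame_indices
    summaries = [
        summarize_frame(topo, ensemble.stack.coord[i], criteria=criteria)
        for i in indices
    ]
    return accumulate_occupancy(summaries, criteria)


def merge_occupancies(parts: Sequence[HBondOccupancies]) -> HBondOccupancies:
    """Pool replicas by concatenation: counts and frame totals add up."""
    if not parts:
        raise ValueError("nothing to merge")
    out = parts[0]
    for p in parts[1:]:
        out = out + p
    return out


# --------------------------------------------------------------------------
# graph construction (three sets, Table-1-style thresholds)
# --------------------------------------------------------------------------

class GraphSet(enum.IntEnum):
    BACKBONE_SIDECHAIN_WATER = 1
    SIDECHAIN_WATER = 2
    SIDECHAIN_DIRECT = 3


#: (graph set, angle criterion in degrees) -> occupancy threshold in percent
TABLE1_THRESHOLDS: dict[tuple[int, int], float] = {
    (1, 20): 10.0,
    (1, 60): 50.0,
    (2, 20): 10.0,
    (2, 60): 25.0,
    (3, 20): 10.0,
    (3, 60): 15.0,
}


@dataclass(frozen=True)
class GraphSpec:
    """Which graph set to build and at which angle/occupancy thresholds.

    ``occupancy_threshold=None`` resolves to the canonical threshold for the
    (set, angle) combination; an explicit non-canonical value is rejected
    unless ``allow_override`` is set.
    """

    graph_set: GraphSet
    angle_criterion: int
    occupancy_threshold: float | None = None
    allow_override: bool = False

    def __post_init__(self) -> None:
        if self.angle_criterion not in (20, 60):
            raise ValueError("angle_criterion must be 20 or 60 degrees")
        gs = GraphSet(self.graph_set)
        object.__setattr__(self, "graph_set", gs)
        canonical = TABLE1_THRESHOLDS[(int(gs), self.angle_criterion)]
        if (
            self.occupancy_threshold is not None
            and self.occupancy_threshold != canonical
            and not self.allow_override
        ):
            raise ValueError(
                f"occupancy threshold {self.occupancy_threshold}% is inconsistent "
                f"with the canonical mapping for graph set {int(gs)} at "
                f"{self.angle_criterion}° (expected {canonical}%); "
                "pass allow_override=True to use a non-standard threshold"
            )

    @property
    def resolved_threshold(self) -> float:
        if self.occupancy_threshold is not None:
            return float(self.occupancy_threshold)
        return TABLE1_THRESHOLDS[(int(self.graph_set), self.angle_criterion)]


@dataclass(frozen=True)
class HBondEdge:
    """A residue-pair connection in a graph set, with its occupancy."""

    group_a: str
    group_b: str
    kind: str  # "direct" or "water_bridged"
    min_waters_observed: int
    occupancy: float

    def __post_init__(self) -> None:
        if self.group_a == self.group_b:
            raise ValueError("self-edges are not allowed")
        if not (0.0 <= self.occupancy <= 100.0):
            raise ValueError("occupancy must lie in [0, 100]")
        if not (0 <= self.min_waters_observed <= 3):
            raise ValueError("min_waters_observed must be 0-3")


def graph_edges(occ: HBondOccupancies, spec: GraphSpec) -> list[HBondEdge]:
    """Edges of the requested graph set whose occupancy meets the threshold.

    A pair may contribute both a direct and a water-bridged edge; they carry
    independent occupancies.
    """
    thr = spec.resolved_threshold
    sc = spec.graph_set in (GraphSet.SIDECHAIN_WATER, GraphSet.SIDECHAIN_DIRECT)
    direct = occ.direct_sc if sc else occ.direct_all
    edges: list[HBondEdge] = []
    for pair, count in direct.items():
        pct = 100.0 * count / occ.n_frames
        if pct >= thr:
            edges.append(HBondEdge(pair[0], pair[1], "direct", 0, pct))
    if spec.graph_set != GraphSet.SIDECHAIN_DIRECT:
        bridged = occ.bridged_sc if sc else occ.bridged_all
        min_w = occ.min_waters_sc if sc else occ.min_waters_all
        for pair, count in bridged.items():
            pct = 100.0 * count / occ.n_frames
            if pct >= thr:
                edges.append(
                    HBondEdge(pair[0], pair[1], "water_bridged", min_w[pair], pct)
                )
    edges.sort(key=lambda e: (e.group_a, e.group_b, e.kind))
    return edges


def build_graph(occ: HBondOccupancies, spec: GraphSpec) -> nx.Graph:
    """Residue-level undirected graph of the requested set.

    Edge attributes: ``direct_occupancy`` / ``bridged_occupancy`` (percent,
    present when that kind qualifies), ``occupancy`` (max of the qualifying
    kinds) and ``min_waters``.
    """
    g = nx.Graph(graph_set=int(spec.graph_set), angle_criterion=spec.angle_criterion,
                 occupancy_threshold=spec.resolved_threshold)
    for e in graph_edges(occ, spec):
        a, b = e.group_a, e.group_b
        if not g.has_edge(a, b):
            g.add_edge(a, b, occupancy=0.0, min_waters=0)
        data = g.edges[a, b]
        if e.kind == "direct":
            data["direct_occupancy"] = e.occupancy
        else:
            data["bridged_occupancy"] = e.occupancy
            data["min_waters"] = e.min_waters_observed
        data["occupancy"] = max(data["occupancy"], e.occupancy)
    return g


def write_edge_list(edges: Sequence[HBondEdge], path) -> None:
    """Deterministic CSV export: node_a,node_b,kind,min_waters,occupancy."""
    import csv

    with open(path, "w", newline="\n") as fh:
        writer = csv.writer(fh, lineterminator="\n")
        writer.writerow(["node_a", "node_b", "kind", "min_waters", "occupancy"])
        for e in sorted(edges, key=lambda e: (e.group_a, e.group_b, e.kind)):
            writer.writerow(
                [e.group_a, e.group_b, e.kind, e.min_waters_observed, f"{e.occupancy:.4f}"]
            )


def write_graphml(graph: nx.Graph, path) -> None:
    """GraphML export for visualisation tools."""
    nx.write_graphml(graph, path)
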