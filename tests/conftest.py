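"""Shared fixtures: hand-built coordinate frames and an independent
brute-force H-bond/bridge oracle used to validate the graph pipeline."""

from __future__ import annotations

import itertools
import math

import numpy as np
import pytest
import biotite.structure as struc

from phtitra.chemistry import DonorAcceptorTable, is_water


def make_frame(atoms):
    """Build an AtomArray from (chain, res_id, res_name, atom_name, element, xyz)."""
    arr = struc.AtomArray(len(atoms))
    for i, (chain, res_id, res_name, atom_name, element, xyz) in enumerate(atoms):
        arr.chain_id[i] = chain
        arr.res_id[i] = res_id
        arr.res_name[i] = res_name
        arr.atom_name[i] = atom_name
        arr.element[i] = element
        arr.coord[i] = xyz
    arr.hetero[:] = [res_name == "HOH" for (_, _, res_name, _, _, _) in atoms]
    return arr


def random_small_system(rng, n_groups=None, n_waters=None, box=12.0):
    """Random arrangement of hydroxyl-bearing groups and waters in a box.

    Every group is a one-atom 'side chain' (Ser Oγ + hydrogen in a random
    direction) that can both donate and accept; waters carry two hydrogens.
    """
    if n_groups is None:
        n_groups = int(rng.integers(4, 13))
    if n_waters is None:
        n_waters = int(rng.integers(3, 16))
    atoms = []
    for g in range(n_groups):
        pos = rng.uniform(0, box, 3)
        u = rng.normal(size=3)
        u /= np.linalg.norm(u)
        atoms.append(("A", g + 1, "SER", "OG", "O", pos))
        atoms.append(("A", g + 1, "HG", "H", "H", pos + u))
    for w in range(n_waters):
        pos = rng.uniform(0, box, 3)
        u1 = rng.normal(size=3)
        u1 /= np.linalg.norm(u1)
        u2 = rng.normal(size=3)
        u2 /= np.linalg.norm(u2)
        atoms.append(("W", 100 + w, "HOH", "O", "O", pos))
        atoms.append(("W", 100 + w, "HOH", "H1", "H", pos + u1))
        atoms.append(("W", 100 + w, "HOH", "H2", "H", pos + u2))
    return make_frame(atoms)


# --------------------------------------------------------------------------
# independent naive oracle (plain double loops, no trees, no BFS)
# --------------------------------------------------------------------------

def _naive_angle_ok(d_xyz, h_xyz, a_xyz, max_dev):
    v1 = d_xyz - h_xyz
    v2 = a_xyz - h_xyz
    cos = float(np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2)))
    theta = math.degrees(math.acos(max(-1.0, min(1.0, cos))))
    return (180.0 - theta) <= max_dev


def naive_links(frame, criteria, table=None):
    """All pairwise H-bond links by exhaustive loops.

    Returns (direct protein pairs, group→water links, water-water links)
    with residue-level keys matching the package's group ids.
    """
    table = table or DonorAcceptorTable.default()
    n = frame.array_length()
    names = [str(a).upper() for a in frame.atom_name]
    res_names = [str(r) for r in frame.res_name]
    elements = [str(e).upper() for e in frame.element]
    keys = [f"{res_names[i]}{frame.res_id[i]}" for i in range(n)]
    coords = frame.coord

    donors = []
    for i in range(n):
        if elements[i] == "H":
            continue
        if names[i] in table.donors(res_names[i]):
            hs = [
                j
                for j in range(n)
                if elements[j] == "H"
                and keys[j] == keys[i]
                and np.linalg.norm(coords[j] - coords[i]) < 1.25
            ]
            if hs:
                donors.append((i, hs))
    acceptors = [
        i
        for i in range(n)
        if elements[i] != "H" and names[i] in table.acceptors(res_names[i])
    ]

    direct = set()
    g2w = {}
    ww = set()
    for d, hs in donors:
        for a in acceptors:
            if keys[a] == keys[d]:
                continue
            if np.linalg.norm(coords[d] - coords[a]) > criteria.max_da_distance:
                continue
            if not any(
                _naive_angle_ok(coords[d], coords[h], coords[a], criteria.max_angle_deviation)
                for h in hs
            ):
                continue
            d_wat, a_wat = is_water(res_names[d]), is_water(res_names[a])
            if not d_wat and not a_wat:
                direct.add(tuple(sorted((keys[d], keys[a]))))
            elif d_wat and a_wat:
                ww.add(tuple(sorted((keys[d], keys[a]))))
            else:
                g = keys[a] if d_wat else keys[d]
                w = keys[d] if d_wat else keys[a]
                g2w.setdefault(g, set()).add(w)
    return direct, g2w, ww


def naive_bridges(g2w, ww, max_waters):
    """Exhaustive path enumeration over ordered water tuples of length 1–3."""
    waters = sorted({w for ws in g2w.values() for w in ws} | {w for p in ww for w in p})
    groups = sorted(g2w)
    ww_ok = lambda a, b: tuple(sorted((a, b))) in ww
    out = {}
    for ga, gb in itertools.combinations(groups, 2):
        best = None
        for k in range(1, max_waters + 1):
            for tup in itertools.permutations(waters, k):
                if tup[0] not in g2w[ga] or tup[-1] not in g2w[gb]:
                    continue
                if all(ww_ok(tup[i], tup[i + 1]) for i in range(k - 1)):
                    best = k
                    break
            if best is not None:
                break
        if best is not None:
            out[tuple(sorted((ga, gb)))] = best
    return out


@pytest.fixture
def rng():
    return np.random.default_rng(20260922)
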