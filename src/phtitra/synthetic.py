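"""Synthetic inputs with known ground truth.

Two generators:

* :func:`simulate_titration_records` emulates a λ-dynamics titration: at each
  pH, pure-state frames are drawn deprotonated with probability
  S(pH) = 1/(1 + 10^{n(pKa − pH)}); pure λ values are drawn uniformly inside
  the matching cut-off band (so the classifier's band logic is exercised,
  not just point masses), χ near 0 or 1, and controllable fractions of
  mixed-χ and mid-λ frames are injected.  The generator keeps exact
  bookkeeping of what it injected, so filter audits can be bit-exact.

* :func:`build_toy_ensemble` produces a multi-frame ideal α-helix peptide
  (internal-coordinate construction with Gaussian dihedral noise) carrying
  engineered side-chain contacts — direct or bridged by 1–3 explicitly
  placed waters — realised in a Bernoulli-chosen fraction of frames, so the
  H-bond pipeline's occupancies can be compared against the construction.

Everything is reproducible from the spec's seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Sequence

import numpy as np
import pandas as pd
import biotite.structure as struc

from . import geometry
from .chemistry import DonorAcceptorTable
from .structures import ConformerEnsemble, _ONE_TO_THREE
from .titration import hill_curve

__all__ = [
    "SyntheticSpec",
    "TitrationSimulation",
    "simulate_titration_records",
    "EngineeredContact",
    "ToyStructureSpec",
    "ToyEnsemble",
    "build_toy_ensemble",
]


# --------------------------------------------------------------------------
# titration records
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class SyntheticSpec:
    """Ground-truth parameters of a synthetic titration experiment."""

    pka_true: float
    hill_true: float = 1.0
    ph_grid: tuple[float, ...] = (3.0, 4.0, 5.0, 6.0, 7.0)
    n_samples_per_ph: int = 10_000
    mixed_chi_fraction: float = 0.0
    mid_lambda_fraction: float = 0.0
    residue_id: str = "ASP6"
    has_chi: bool = True
    markov_flip_scale: float | None = None  # None = independent draws
    seed: int = 0

    def __post_init__(self) -> None:
        if self.hill_true <= 0:
            raise ValueError("hill_true must be positive")
        if not self.ph_grid:
            raise ValueError("ph_grid must be non-empty")
        for name in ("mixed_chi_fraction", "mid_lambda_fraction"):
            v = getattr(self, name)
            if not (0.0 <= v < 1.0):
                raise ValueError(f"{name} must lie in [0, 1)")
        if self.mixed_chi_fraction + self.mid_lambda_fraction >= 1.0:
            raise ValueError("injected impurity fractions must sum below 1")
        if self.n_samples_per_ph < 1:
            raise ValueError("n_samples_per_ph must be positive")
        if self.markov_flip_scale is not None and not (0.0 < self.markov_flip_scale <= 1.0):
            raise ValueError("markov_flip_scale must lie in (0, 1]")


@dataclass
class TitrationSimulation:
    """Records per pH plus the generator's exact bookkeeping."""

    spec: SyntheticSpec
    records: dict[float, pd.DataFrame]
    bookkeeping: dict[float, dict[str, int]] = field(default_factory=dict)

    def expected_discarded(self, ph: float) -> int:
        b = self.bookkeeping[ph]
        return b["n_mid_lambda"] + b["n_mixed_chi"]


def _pure_state_sequence(rng, n: int, p_deprot: float, flip_scale: float | None):
    """Deprotonated/protonated boolean sequence, i.i.d. or two-state Markov.

    The Markov chain has stationary deprotonated probability ``p_deprot``;
    ``flip_scale`` in (0, 1] shrinks the flip rates, lengthening dwell times
    without changing the stationary law — a stress test for cumulative
    convergence diagnostics.
    """
    if flip_scale is None:
        return rng.random(n) < p_deprot
    p_to_deprot = flip_scale * p_deprot
    p_to_prot = flip_scale * (1.0 - p_deprot)
    out = np.empty(n, dtype=bool)
    out[0] = rng.random() < p_deprot
    u = rng.random(n)
    for i in range(1, n):
        if out[i - 1]:
            out[i] = u[i] >= p_to_prot
        else:
            out[i] = u[i] < p_to_deprot
    return out


def simulate_titration_records(spec: SyntheticSpec) -> TitrationSimulation:
    """Generate λ/χ records at every pH of the grid (seed-deterministic)."""
    rng = np.random.default_rng(spec.seed)
    records: dict[float, pd.DataFrame] = {}
    bookkeeping: dict[float, dict[str, int]] = {}
    n = spec.n_samples_per_ph
    for ph in spec.ph_grid:
        p_deprot = float(hill_curve(ph, spec.pka_true, spec.hill_true))
        u = rng.random(n)
        is_mid = u < spec.mid_lambda_fraction
        is_mixed = (~is_mid) & (
            u < spec.mid_lambda_fraction + spec.mixed_chi_fraction
        ) & spec.has_chi
        is_pure = ~is_mid & ~is_mixed

        deprot = _pure_state_sequence(rng, n, p_deprot, spec.markov_flip_scale)

        lam = np.empty(n)
        lam[deprot] = rng.uniform(0.8, 1.0, int(deprot.sum()))
        lam[~deprot] = rng.uniform(0.0, 0.2, int((~deprot).sum()))
        # mid-λ frames fall strictly inside the discard band
        lam[is_mid] = rng.uniform(0.25, 0.75, int(is_mid.sum()))

        if spec.has_chi:
            chi = np.where(
                rng.random(n) < 0.5,
                rng.uniform(0.0, 0.15, n),
                rng.uniform(0.85, 1.0, n),
            )
            chi[is_mixed] = rng.uniform(0.25, 0.75, int(is_mixed.sum()))
        else:
            chi = np.full(n, np.nan)

        records[float(ph)] = pd.DataFrame(
            {
                "frame": np.arange(n, dtype=int),
                "residue_id": spec.residue_id,
                "lambda": lam,
                "chi": chi,
            }
        )
        bookkeeping[float(ph)] = {
            "n_pure_deprot": int((is_pure & deprot).sum()),
            "n_pure_prot": int((is_pure & ~deprot).sum()),
            "n_mid_lambda": int(is_mid.sum()),
            "n_mixed_chi": int(is_mixed.sum()),
        }
    return TitrationSimulation(spec=spec, records=records, bookkeeping=bookkeeping)


# --------------------------------------------------------------------------
# toy coordinate ensembles
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class EngineeredContact:
    """A donor→acceptor contact to realise at a target occupancy.

    ``n_waters = 0`` gives a direct H-bond; 1–3 insert an explicitly placed
    chain of bridging waters.  Atoms are pseudo side-chain atoms named so the
    default donor/acceptor chemistry recognises them (e.g. ``OG`` on Ser as
    donor, ``OD1`` on Asp as acceptor).
    """

    donor_res: int  # 1-based residue index in the sequence
    donor_atom: str
    acceptor_res: int
    acceptor_atom: str
    n_waters: int = 0
    target_occupancy: float = 100.0

    def __post_init__(self) -> None:
        if not (0 <= self.n_waters <= 3):
            raise ValueError("n_waters must be 0-3")
        if not (0.0 < self.target_occupancy <= 100.0):
            raise ValueError("target_occupancy must lie in (0, 100]")


@dataclass(frozen=True)
class ToyStructureSpec:
    """Specification of a toy helical peptide ensemble."""

    sequence: str
    n_frames: int = 10
    helix_span: tuple[int, int] | None = None  # 1-based inclusive; None = all
    dihedral_noise_sigma: float = 0.0  # degrees
    engineered_contacts: tuple[EngineeredContact, ...] = ()
    seed: int = 0

    def __post_init__(self) -> None:
        if len(self.sequence) < 2:
            raise ValueError("sequence must have at least 2 residues")
        bad = [c for c in self.sequence if c.upper() not in _ONE_TO_THREE]
        if bad:
            raise ValueError(f"unknown one-letter residues: {bad}")
        for c in self.engineered_contacts:
            for res in (c.donor_res, c.acceptor_res):
                if not (1 <= res <= len(self.sequence)):
                    raise ValueError(
                        f"engineered contact references residue {res} outside "
                        f"sequence of length {len(self.sequence)}"
                    )
        if self.n_frames < 1:
            raise ValueError("n_frames must be positive")


@dataclass
class ToyEnsemble:
    """Built ensemble plus the realised per-contact frame masks."""

    spec: ToyStructureSpec
    ensemble: ConformerEnsemble
    contact_masks: list[np.ndarray]  # bool (n_frames,) per engineered contact

    def realized_occupancy(self, contact_index: int) -> float:
        mask = self.contact_masks[contact_index]
        return 100.0 * float(mask.mean())


_HB_LINK = 2.9  # Å between consecutive heavy atoms of an engineered chain
_OFF_SHIFT = 12.0  # Å displacement of a chain in frames where the contact is off


def _validate_contact_chemistry(
    spec: ToyStructureSpec, table: DonorAcceptorTable
) -> None:
    seq = spec.sequence.upper()
    for c in spec.engineered_contacts:
        donor_rn = _ONE_TO_THREE[seq[c.donor_res - 1]]
        acceptor_rn = _ONE_TO_THREE[seq[c.acceptor_res - 1]]
        if c.donor_atom.upper() not in table.sidechain_donors(donor_rn):
            raise ValueError(
                f"contact unrealizable: {c.donor_atom!r} is not a side-chain donor "
                f"of {donor_rn} (residue {c.donor_res}) in its default state"
            )
        if c.acceptor_atom.upper() not in table.sidechain_acceptors(acceptor_rn):
            raise ValueError(
                f"contact unrealizable: {c.acceptor_atom!r} is not a side-chain "
                f"acceptor of {acceptor_rn} (residue {c.acceptor_res}) in its "
                "default state"
            )


def build_toy_ensemble(
    spec: ToyStructureSpec, table: DonorAcceptorTable | None = None
) -> ToyEnsemble:
    """Build the multi-frame toy peptide with engineered contacts.

    The backbone comes from ideal α-helix torsions (φ = −57°, ψ = −47°)
    inside ``helix_span`` (extended elsewhere), plus i.i.d. Gaussian noise of
    ``dihedral_noise_sigma`` degrees on every defined torsion.  Each
    engineered chain is collinear with 2.9 Å heavy-atom spacing and exact
    donor–H···acceptor linearity; in "off" frames it is rigidly displaced by
    12 Å so no criterion can hold.  Chains of different contacts extend along
    different directions so they cannot cross-link.
    """
    table = table or DonorAcceptorTable.default()
    _validate_contact_chemistry(spec, table)
    rng = np.random.default_rng(spec.seed)
    seq = spec.sequence.upper()
    n_res = len(seq)
    n_frames = spec.n_frames

    phi = np.full((n_frames, n_res), 180.0)
    psi = np.full((n_frames, n_res), 180.0)
    lo, hi = (1, n_res) if spec.helix_span is None else spec.helix_span
    phi[:, lo - 1 : hi] = geometry.IDEAL_HELIX_PHI
    psi[:, lo - 1 : hi] = geometry.IDEAL_HELIX_PSI
    if spec.dihedral_noise_sigma > 0:
        phi += rng.normal(0.0, spec.dihedral_noise_sigma, phi.shape)
        psi += rng.normal(0.0, spec.dihedral_noise_sigma, psi.shape)
    # wrap to (-180, 180]
    phi = (phi + 180.0) % 360.0 - 180.0
    psi = (psi + 180.0) % 360.0 - 180.0

    bb = geometry.build_backbone_frames(n_res, phi, psi)

    # contact on/off masks
    masks = [
        rng.random(n_frames) < (c.target_occupancy / 100.0)
        for c in spec.engineered_contacts
    ]

    # assemble atom annotations (shared topology) and per-frame coordinates
    atom_res_id: list[int] = []
    atom_res_name: list[str] = []
    atom_name: list[str] = []
    atom_element: list[str] = []
    atom_chain: list[str] = []
    coords_parts: list[np.ndarray] = []  # each (n_frames, 3)

    def add_atom(res_id, res_name, name, element, xyz, chain="A"):
        atom_res_id.append(res_id)
        atom_res_name.append(res_name)
        atom_name.append(name)
        atom_element.append(element)
        atom_chain.append(chain)
        coords_parts.append(np.asarray(xyz, dtype=float))

    for i in range(n_res):
        rn = _ONE_TO_THREE[seq[i]]
        add_atom(i + 1, rn, "N", "N", bb["N"][:, i])
        if i > 0 and rn != "PRO":
            add_atom(i + 1, rn, "H", "H", bb["H"][:, i])
        add_atom(i + 1, rn, "CA", "C", bb["CA"][:, i])
        add_atom(i + 1, rn, "C", "C", bb["C"][:, i])
        add_atom(i + 1, rn, "O", "O", bb["O"][:, i])

    # engineered chains: direction = radial from the helix axis, rotated per
    # contact so chains never approach each other
    ca = bb["CA"]  # (n_frames, n_res, 3)
    centroid = ca.mean(axis=1)  # (n_frames, 3)
    # helix axis ≈ first principal direction of the CA cloud (frame-wise)
    axis = ca[:, -1, :] - ca[:, 0, :]
    axis /= np.linalg.norm(axis, axis=-1, keepdims=True)

    def rotate_about(v, k, deg):
        """Rodrigues rotation of v about unit axis k (frame-wise)."""
        th = math.radians(deg)
        return (
            v * math.cos(th)
            + np.cross(k, v) * math.sin(th)
            + k * (np.sum(k * v, axis=-1, keepdims=True)) * (1 - math.cos(th))
        )

    water_serial = 0
    for ci, contact in enumerate(spec.engineered_contacts):
        d_ca = ca[:, contact.donor_res - 1, :]
        radial = d_ca - centroid
        radial -= axis * np.sum(radial * axis, axis=-1, keepdims=True)
        norms = np.linalg.norm(radial, axis=-1, keepdims=True)
        fallback = np.cross(axis, np.array([0.0, 0.0, 1.0]))
        fb_norm = np.linalg.norm(fallback, axis=-1, keepdims=True)
        fallback = np.where(fb_norm > 1e-6, fallback / np.maximum(fb_norm, 1e-12),
                            np.array([1.0, 0.0, 0.0]))
        u = np.where(norms > 1e-6, radial / np.maximum(norms, 1e-12), fallback)
        u = rotate_about(u, axis, 137.0 * ci)

        # the donor atom (and its H) stay anchored; in "off" frames the rest
        # of the chain is displaced so the donor→chain link is broken
        off = (~masks[ci]).astype(float)[:, None] * _OFF_SHIFT
        base = d_ca + u * 2.0  # donor heavy atom position

        donor_rn = _ONE_TO_THREE[seq[contact.donor_res - 1]]
        acceptor_rn = _ONE_TO_THREE[seq[contact.acceptor_res - 1]]

        # donor heavy atom + its hydrogen pointing along the chain
        add_atom(contact.donor_res, donor_rn, contact.donor_atom.upper(),
                 contact.donor_atom[0].upper(), base)
        add_atom(contact.donor_res, donor_rn, "HX", "H", base + u * 1.0)

        pos = base
        for w in range(contact.n_waters):
            water_serial += 1
            pos = pos + u * _HB_LINK
            add_atom(1000 + water_serial, "HOH", "O", "O", pos + u * off, chain="W")
            add_atom(1000 + water_serial, "HOH", "H1", "H",
                     pos + u * 1.0 + u * off, chain="W")
            add_atom(
                1000 + water_serial, "HOH", "H2", "H",
                pos + _perpendicular(u) * 1.0 + u * off, chain="W",
            )
        acceptor_pos = pos + u * _HB_LINK
        add_atom(contact.acceptor_res, acceptor_rn, contact.acceptor_atom.upper(),
                 contact.acceptor_atom[0].upper(), acceptor_pos + u * off)

    n_atoms = len(atom_name)
    coord = np.stack(coords_parts, axis=1)  # (n_frames, n_atoms, 3)
    stack = struc.AtomArrayStack(n_frames, n_atoms)
    stack.coord = coord
    stack.chain_id = np.array(atom_chain)
    stack.res_id = np.array(atom_res_id)
    stack.res_name = np.array(atom_res_name)
    stack.atom_name = np.array(atom_name)
    stack.element = np.array(atom_element)
    stack.hetero = np.array([rn == "HOH" for rn in atom_res_name])

    return ToyEnsemble(
        spec=spec,
        ensemble=ConformerEnsemble(stack, source="synthetic"),
        contact_masks=masks,
    )


def _perpendicular(u: np.ndarray) -> np.ndarray:
    """A unit vector perpendicular to u (frame-wise)."""
    ref = np.zeros_like(u)
    ref[..., 2] = 1.0
    swap = np.abs(u[..., 2:3]) > 0.9
    ref = np.where(swap, np.array([1.0, 0.0, 0.0]), ref)
    v = np.cross(u, ref)
    return v / np.linalg.norm(v, axis=-1, keepdims=True)
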