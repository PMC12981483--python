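"""Backbone conformation metrics: dihedrals, angular dispersion (PAD), helix content.

PAD quantifies per-residue backbone flexibility through the circular
dispersion of the (φ, ψ) torsions across an ensemble.  Each observed angle is
mapped to a unit vector, the vectors of each torsion are centred on that
torsion's circular mean, and the pooled mean resultant length R̄ of the
centred φ and ψ vectors (equivalently the average of the per-angle resultant
lengths) feeds the circular standard deviation

    PAD = (180/π) · sqrt(−2 ln R̄),   capped at 180°.

A rigid residue (identical torsions in every frame) has R̄ = 1 and PAD = 0;
angles spread uniformly around the circle drive R̄ → 0 and PAD to the cap.
The metric is pluggable (``pad_from_resultant``) so alternative dispersion
variants (φ-only, ψ-only) can be substituted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd
import biotite.structure as struc

from .structures import ConformerEnsemble

__all__ = [
    "BackboneDihedrals",
    "backbone_dihedrals",
    "pad_per_residue",
    "pad_profile",
    "pad_from_resultant",
    "HelixWindow",
    "assign_helix",
    "helical_content",
    "per_residue_helical_content",
]

PAD_MAX = 180.0


@dataclass
class BackboneDihedrals:
    """φ/ψ series (degrees, NaN where undefined) for every residue."""

    residue_ids: list[str]
    phi: np.ndarray  # (n_frames, n_residues)
    psi: np.ndarray

    @property
    def n_frames(self) -> int:
        return self.phi.shape[0]

    def for_residue(self, residue_id: str) -> tuple[np.ndarray, np.ndarray]:
        i = self.residue_ids.index(residue_id)
        return self.phi[:, i], self.psi[:, i]


def backbone_dihedrals(ensemble: ConformerEnsemble) -> BackboneDihedrals:
    """Standard φ = C(i−1)–N(i)–CA(i)–C(i), ψ = N(i)–CA(i)–C(i)–N(i+1).

    Angles at chain termini (or where a backbone atom is missing) are NaN.
    """
    stack = ensemble.stack
    frame0 = stack[0]
    water = np.isin(frame0.res_name, ["HOH", "WAT", "TIP", "TIP3", "SOL", "SPC"])
    # per-residue backbone atom indices, chain order
    seen: dict[str, dict[str, int]] = {}
    order: list[str] = []
    for i in range(frame0.array_length()):
        if water[i]:
            continue
        key = f"{frame0.res_name[i]}{frame0.res_id[i]}"
        if key not in seen:
            seen[key] = {}
            order.append(key)
        if frame0.atom_name[i] in ("N", "CA", "C"):
            seen[key][frame0.atom_name[i]] = i

    coords = stack.coord  # (n_frames, n_atoms, 3)
    n_frames = coords.shape[0]
    n_res = len(order)
    phi = np.full((n_frames, n_res), np.nan)
    psi = np.full((n_frames, n_res), np.nan)

    def atoms(k: str) -> dict[str, int]:
        return seen[order[k]]

    for k, key in enumerate(order):
        cur = atoms(k)
        if not all(a in cur for a in ("N", "CA", "C")):
            continue  # flagged absent via NaN
        if k > 0 and "C" in atoms(k - 1):
            phi[:, k] = np.degrees(
                struc.dihedral(
                    coords[:, atoms(k - 1)["C"]],
                    coords[:, cur["N"]],
                    coords[:, cur["CA"]],
                    coords[:, cur["C"]],
                )
            )
        if k < n_res - 1 and "N" in atoms(k + 1):
            psi[:, k] = np.degrees(
                struc.dihedral(
                    coords[:, cur["N"]],
                    coords[:, cur["CA"]],
                    coords[:, cur["C"]],
                    coords[:, atoms(k + 1)["N"]],
                )
            )
    return BackboneDihedrals(residue_ids=order, phi=phi, psi=psi)


def pad_from_resultant(r_bar: float) -> float:
    """Circular standard deviation in degrees from a mean resultant length."""
    if math.isnan(r_bar):
        return math.nan
    if r_bar >= 1.0:
        return 0.0
    if r_bar <= 0.0:
        return PAD_MAX
    return min(PAD_MAX, math.degrees(math.sqrt(-2.0 * math.log(r_bar))))


def _resultant_length(angles_deg: np.ndarray) -> float:
    """Mean resultant length of one torsion series (NaN entries ignored)."""
    a = np.deg2rad(angles_deg[~np.isnan(angles_deg)])
    if a.size == 0:
        return math.nan
    return float(np.abs(np.mean(np.exp(1j * a))))


def pad_per_residue(phi: np.ndarray, psi: np.ndarray) -> float:
    """PAD of one residue from its φ and ψ series.

    The two torsions are centred independently, so a rigid residue scores 0
    regardless of where its (φ, ψ) basin lies; a terminal residue with only
    one defined torsion is scored on that torsion alone.
    """
    parts = [r for r in (_resultant_length(phi), _resultant_length(psi)) if not math.isnan(r)]
    if not parts:
        return math.nan
    n_valid = sum(np.sum(~np.isnan(x)) for x in (phi, psi))
    if n_valid < 2:
        raise ValueError("PAD needs at least 2 frames with defined angles")
    return pad_from_resultant(float(np.mean(parts)))


def pad_profile(
    source: ConformerEnsemble | BackboneDihedrals,
) -> pd.Series:
    """Per-residue PAD values (degrees) over an ensemble."""
    dih = source if isinstance(source, BackboneDihedrals) else backbone_dihedrals(source)
    values = {}
    for k, rid in enumerate(dih.residue_ids):
        phi, psi = dih.phi[:, k], dih.psi[:, k]
        if np.all(np.isnan(phi)) and np.all(np.isnan(psi)):
            values[rid] = math.nan
        else:
            values[rid] = pad_per_residue(phi, psi)
    return pd.Series(values, name="PAD")


# --------------------------------------------------------------------------
# simplified dihedral-window helix assignment
# --------------------------------------------------------------------------

@dataclass(frozen=True)
class HelixWindow:
    """α-basin window in the Ramachandran plane and the minimum run length."""

    phi_min: float = -100.0
    phi_max: float = -30.0
    psi_min: float = -67.0
    psi_max: float = -7.0
    min_run: int = 4


def assign_helix(
    source: ConformerEnsemble | BackboneDihedrals,
    window: HelixWindow = HelixWindow(),
) -> pd.DataFrame:
    """Boolean helix mask, frames × residues.

    A residue is helical in a frame iff its (φ, ψ) lie in the α-window and it
    belongs to a run of at least ``min_run`` consecutive in-window residues.
    Residues with undefined φ or ψ (termini) are never helical.
    """
    dih = source if isinstance(source, BackboneDihedrals) else backbone_dihedrals(source)
    in_window = (
        (dih.phi >= window.phi_min)
        & (dih.phi <= window.phi_max)
        & (dih.psi >= window.psi_min)
        & (dih.psi <= window.psi_max)
    )
    mask = np.zeros_like(in_window, dtype=bool)
    n_res = in_window.shape[1]
    for f in range(in_window.shape[0]):
        row = in_window[f]
        start = 0
        while start < n_res:
            if not row[start]:
                start += 1
                continue
            end = start
            while end < n_res and row[end]:
                end += 1
            if end - start >= window.min_run:
                mask[f, start:end] = True
            start = end
    return pd.DataFrame(mask, columns=dih.residue_ids)


def helical_content(mask: pd.DataFrame) -> float:
    """Helical residue-frames as a percentage of all residue-frames."""
    total = mask.size
    if total == 0:
        raise ValueError("empty helix mask")
    return 100.0 * float(mask.to_numpy().sum()) / total


def per_residue_helical_content(mask: pd.DataFrame) -> pd.Series:
    """Per-residue helicity percentage across frames."""
    return 100.0 * mask.mean(axis=0).rename("helical_content")
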