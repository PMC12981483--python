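"""Internal-coordinate (NeRF) backbone construction.

Builds peptide backbones from bond lengths, bond angles and (φ, ψ, ω)
torsions, vectorised over trajectory frames.  Used by the synthetic module to
produce ideal α-helical ensembles with controlled dihedral noise.
"""

from __future__ import annotations

import numpy as np

__all__ = ["nerf_place", "build_backbone_frames", "IDEAL_HELIX_PHI", "IDEAL_HELIX_PSI"]

# standard peptide geometry (Engh–Huber-like averages, Å / degrees)
BOND_N_CA = 1.458
BOND_CA_C = 1.525
BOND_C_N = 1.329
BOND_C_O = 1.231
BOND_N_H = 1.020
ANGLE_N_CA_C = 111.2
ANGLE_CA_C_N = 116.2
ANGLE_C_N_CA = 121.7
ANGLE_CA_C_O = 120.8
ANGLE_H_N_C = 119.0

IDEAL_HELIX_PHI = -57.0
IDEAL_HELIX_PSI = -47.0


def nerf_place(
    a: np.ndarray,
    b: np.ndarray,
    c: np.ndarray,
    bond: float,
    angle_deg: float | np.ndarray,
    dihedral_deg: float | np.ndarray,
) -> np.ndarray:
    """Place atom D given chain A-B-C, |C-D|, angle(B,C,D) and dihedral(A,B,C,D).

    All inputs broadcast over a leading frames dimension: a/b/c are (..., 3).
    """
    a, b, c = (np.asarray(x, dtype=float) for x in (a, b, c))
    theta = np.deg2rad(np.asarray(angle_deg, dtype=float))
    chi = np.deg2rad(np.asarray(dihedral_deg, dtype=float))

    bc = c - b
    bc /= np.linalg.norm(bc, axis=-1, keepdims=True)
    ab = b - a
    n = np.cross(ab, bc)
    n /= np.linalg.norm(n, axis=-1, keepdims=True)
    m = np.cross(n, bc)

    d_local = np.stack(
        [
            -bond * np.cos(theta) * np.ones_like(chi),
            bond * np.sin(theta) * np.cos(chi),
            bond * np.sin(theta) * np.sin(chi),
        ],
        axis=-1,
    )
    rot = np.stack([bc, m, n], axis=-1)  # columns are the local basis
    return c + np.einsum("...ij,...j->...i", rot, d_local)


def build_backbone_frames(
    n_residues: int,
    phi_deg: np.ndarray,
    psi_deg: np.ndarray,
    omega_deg: float = 180.0,
) -> dict[str, np.ndarray]:
    """Build N/CA/C/O/H backbone coordinates for every frame.

    Parameters
    ----------
    phi_deg, psi_deg : ndarray, shape (n_frames, n_residues)
        Backbone torsions per frame.  φ of residue 0 and ψ of the last
        residue are ignored (undefined at chain termini).

    Returns
    -------
    dict with arrays of shape (n_frames, n_residues, 3) for keys
    ``"N", "CA", "C", "O"`` and ``"H"`` (amide H; NaN for residue 0).
    """
    phi = np.asarray(phi_deg, dtype=float)
    psi = np.asarray(psi_deg, dtype=float)
    if phi.ndim == 1:
        phi = phi[None, :]
        psi = psi[None, :]
    n_frames = phi.shape[0]
    if phi.shape != (n_frames, n_residues) or psi.shape != phi.shape:
        raise ValueError("phi/psi must have shape (n_frames, n_residues)")

    N = np.empty((n_frames, n_residues, 3))
    CA = np.empty_like(N)
    C = np.empty_like(N)
    O = np.empty_like(N)
    H = np.full_like(N, np.nan)

    # seed atoms of residue 0 (identical across frames; frames differ via torsions)
    N[:, 0] = np.array([0.0, 0.0, 0.0])
    CA[:, 0] = np.array([BOND_N_CA, 0.0, 0.0])
    ang = np.deg2rad(ANGLE_N_CA_C)
    C[:, 0] = CA[:, 0] + BOND_CA_C * np.array([-np.cos(ang), np.sin(ang), 0.0])

    for i in range(1, n_residues):
        # N(i): dihedral ψ(i-1) about CA(i-1)-C(i-1)
        N[:, i] = nerf_place(
            N[:, i - 1], CA[:, i - 1], C[:, i - 1],
            BOND_C_N, ANGLE_CA_C_N, psi[:, i - 1],
        )
        # CA(i): dihedral ω about C(i-1)-N(i)
        CA[:, i] = nerf_place(
            CA[:, i - 1], C[:, i - 1], N[:, i],
            BOND_N_CA, ANGLE_C_N_CA, omega_deg,
        )
        # C(i): dihedral φ(i) about N(i)-CA(i)
        C[:, i] = nerf_place(
            C[:, i - 1], N[:, i], CA[:, i],
            BOND_CA_C, ANGLE_N_CA_C, phi[:, i],
        )
        # amide H trans to CA(i) across the N(i)-C(i-1) bond (peptide plane)
        H[:, i] = nerf_place(
            CA[:, i], C[:, i - 1], N[:, i],
            BOND_N_H, ANGLE_H_N_C, 180.0,
        )

    # carbonyl O: anti to N(i+1) across the CA-C bond; last residue uses ψ=0
    for i in range(n_residues):
        psi_i = psi[:, i] if i < n_residues - 1 else np.zeros(n_frames)
        O[:, i] = nerf_place(
            N[:, i], CA[:, i], C[:, i],
            BOND_C_O, ANGLE_CA_C_O, psi_i + 180.0,
        )
    return {"N": N, "CA": CA, "C": C, "O": O, "H": H}
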