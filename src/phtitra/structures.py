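"""Coordinate ensembles and PDB input/output.

A :class:`ConformerEnsemble` is an ordered set of coordinate frames over one
shared topology — an NMR ensemble read from a multi-model PDB file, or a toy
trajectory from :mod:`phtitra.synthetic`.  It wraps a biotite
``AtomArrayStack``, which provides the PDB parsing/writing and the per-atom
annotation arrays (chain, residue number, residue name, atom name, element).
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from pathlib import Path

import numpy as np
import biotite.structure as struc
from biotite.structure.io.pdb import PDBFile

__all__ = [
    "ConformerEnsemble",
    "read_pdb_models",
    "measure_distance",
    "round_half_up",
    "AtomSelector",
]

_WATER_RES_NAMES = frozenset({"HOH", "WAT", "TIP", "TIP3", "SOL", "SPC"})


class ConformerEnsemble:
    """Ordered coordinate frames over a shared topology."""

    def __init__(self, stack: struc.AtomArrayStack, source: str = ""):
        if not isinstance(stack, struc.AtomArrayStack):
            raise TypeError("ConformerEnsemble requires an AtomArrayStack")
        self.stack = stack
        self.source = source

    # -- basic introspection -------------------------------------------------
    @property
    def n_frames(self) -> int:
        return self.stack.stack_depth()

    @property
    def n_atoms(self) -> int:
        return self.stack.array_length()

    def frame(self, index: int) -> struc.AtomArray:
        return self.stack[index]

    def __len__(self) -> int:
        return self.n_frames

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.stack[i]

    def select_frames(self, start=None, stop=None, stride=None) -> "ConformerEnsemble":
        """Frame subsampling (first/last/stride), returned as a new ensemble."""
        sl = slice(start, stop, stride)
        return ConformerEnsemble(self.stack[sl], source=self.source)

    def residue_ids(self, include_water: bool = False) -> list[str]:
        """Residue-level group ids like 'ASP16', in chain order."""
        arr = self.stack[0]
        seen: list[str] = []
        last = None
        for res_name, res_id in zip(arr.res_name, arr.res_id):
            if not include_water and res_name in _WATER_RES_NAMES:
                continue
            key = f"{res_name}{res_id}"
            if key != last:
                seen.append(key)
                last = key
        return seen

    # -- persistence ---------------------------------------------------------
    @classmethod
    def from_pdb(cls, path) -> "ConformerEnsemble":
        return read_pdb_models(path)

    def to_pdb(self, path) -> None:
        pdb = PDBFile()
        pdb.set_structure(self.stack)
        pdb.write(str(path))


def read_pdb_models(path) -> ConformerEnsemble:
    """Read a (possibly multi-model) PDB file into a ConformerEnsemble.

    One frame per MODEL record; a file without MODEL records yields a single
    frame.  Alternate locations are resolved to the highest-occupancy
    conformer.  Unreadable files are rejected with file context.
    """
    path = Path(path)
    try:
        pdb = PDBFile.read(str(path))
        stack = pdb.get_structure(model=None, altloc="occupancy")
    except Exception as exc:  # biotite raises InvalidFileError subclasses
        raise ValueError(f"cannot parse PDB file {path}: {exc}") from exc
    if not isinstance(stack, struc.AtomArrayStack):
        stack = struc.stack([stack])
    if not np.all(np.isfinite(stack.coord)):
        raise ValueError(f"{path}: non-finite coordinates")
    return ConformerEnsemble(stack, source=str(path))


@dataclass(frozen=True)
class AtomSelector:
    """Selects one atom: residue number + atom name, optional residue name/chain.

    String form: ``"S22:OG"`` / ``"SER22:OG"`` / ``"22:OG"``; a leading
    residue-name tag is validated against the model when present.
    """

    res_id: int
    atom_name: str
    res_name: str | None = None
    chain_id: str | None = None

    _PATTERN = re.compile(r"^(?P<res>[A-Za-z]*)(?P<num>-?\d+):(?P<atom>\S+)$")

    @classmethod
    def parse(cls, text: str) -> "AtomSelector":
        m = cls._PATTERN.match(text.strip())
        if m is None:
            raise ValueError(
                f"cannot parse atom selector {text!r}; expected e.g. 'S22:OG'"
            )
        res = m.group("res").upper() or None
        return cls(
            res_id=int(m.group("num")),
            atom_name=m.group("atom").upper(),
            res_name=res,
        )


_ONE_TO_THREE = {
    "A": "ALA", "R": "ARG", "N": "ASN", "D": "ASP", "C": "CYS",
    "Q": "GLN", "E": "GLU", "G": "GLY", "H": "HIS", "I": "ILE",
    "L": "LEU", "K": "LYS", "M": "MET", "F": "PHE", "P": "PRO",
    "S": "SER", "T": "THR", "W": "TRP", "Y": "TYR", "V": "VAL",
}


def _resolve(frame: struc.AtomArray, sel: AtomSelector, offset: int = 0) -> int:
    mask = (frame.res_id == sel.res_id + offset) & (
        np.char.upper(frame.atom_name.astype(str)) == sel.atom_name
    )
    if sel.chain_id is not None:
        mask &= frame.chain_id == sel.chain_id
    if sel.res_name is not None:
        want = _ONE_TO_THREE.get(sel.res_name, sel.res_name)
        mask &= np.char.upper(frame.res_name.astype(str)) == want
    idx = np.flatnonzero(mask)
    if idx.size == 1:
        return int(idx[0])
    if idx.size == 0:
        resmask = frame.res_id == sel.res_id + offset
        cands = sorted(set(frame.atom_name[resmask].tolist()))
        raise ValueError(
            f"selector {sel} matches no atom; atoms in residue "
            f"{sel.res_id + offset}: {cands}"
        )
    cands = [
        f"{frame.chain_id[i]}/{frame.res_name[i]}{frame.res_id[i]}:{frame.atom_name[i]}"
        for i in idx
    ]
    raise ValueError(f"selector {sel} is ambiguous; candidates: {cands}")


def round_half_up(value: float, ndigits: int = 1) -> float:
    """Round with ties away from zero-half-up, matching printed report precision."""
    q = Decimal(10) ** -ndigits
    return float(Decimal(repr(float(value))).quantize(q, rounding=ROUND_HALF_UP))


def measure_distance(
    frame: struc.AtomArray,
    selector_a: AtomSelector | str,
    selector_b: AtomSelector | str,
    ndigits: int | None = None,
    resid_offset: int = 0,
) -> float:
    """Euclidean distance (Å) between two uniquely-selected atoms.

    ``resid_offset`` maps a local residue numbering onto the deposited one
    when they differ.  With ``ndigits`` the result is rounded half-up to the
    requested decimals (1 matches the usual reporting precision).
    """
    if isinstance(selector_a, str):
        selector_a = AtomSelector.parse(selector_a)
    if isinstance(selector_b, str):
        selector_b = AtomSelector.parse(selector_b)
    ia = _resolve(frame, selector_a, resid_offset)
    ib = _resolve(frame, selector_b, resid_offset)
    dist = float(np.linalg.norm(frame.coord[ia] - frame.coord[ib]))
    if ndigits is not None:
        dist = round_half_up(dist, ndigits)
    return dist
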