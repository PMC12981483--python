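"""Donor/acceptor chemistry used by the geometric H-bond detection.

Protonation state matters: a protonated carboxylate gains a hydroxyl donor,
a deprotonated one is acceptor-only, and a neutral histidine donates on only
one ring nitrogen (its tautomer).  States are supplied per residue instance;
residues without an entry use the table's default state.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

__all__ = ["SiteDefinition", "DonorAcceptorTable", "BACKBONE_ATOMS", "WATER_RES_NAMES", "is_water"]

# atom names that belong to the peptide backbone (plus their hydrogens)
BACKBONE_ATOMS = frozenset(
    {"N", "CA", "C", "O", "OXT", "H", "HN", "H1", "H2", "H3", "HA", "HA1", "HA2", "HT1", "HT2", "HT3"}
)

WATER_RES_NAMES = frozenset({"HOH", "WAT", "TIP", "TIP3", "SOL", "SPC"})


def is_water(res_name: str) -> bool:
    return res_name in WATER_RES_NAMES


@dataclass(frozen=True)
class SiteDefinition:
    """Side-chain donor heavy atoms and acceptor heavy atoms for one state."""

    donors: frozenset[str] = frozenset()
    acceptors: frozenset[str] = frozenset()


def _site(donors=(), acceptors=()) -> SiteDefinition:
    return SiteDefinition(frozenset(donors), frozenset(acceptors))


# side-chain chemistry per residue type and protonation state; "default" is
# the single state of non-titratable residues
_SIDECHAIN_SITES: dict[str, dict[str, SiteDefinition]] = {
    "SER": {"default": _site(donors=["OG"], acceptors=["OG"])},
    "THR": {"default": _site(donors=["OG1"], acceptors=["OG1"])},
    "TYR": {"default": _site(donors=["OH"], acceptors=["OH"])},
    "CYS": {"default": _site(donors=["SG"], acceptors=["SG"])},
    "ASN": {"default": _site(donors=["ND2"], acceptors=["OD1"])},
    "GLN": {"default": _site(donors=["NE2"], acceptors=["OE1"])},
    "TRP": {"default": _site(donors=["NE1"])},
    "ARG": {"default": _site(donors=["NE", "NH1", "NH2"])},
    "LYS": {"default": _site(donors=["NZ"])},
    "ASP": {
        "deprotonated": _site(acceptors=["OD1", "OD2"]),
        "protonated": _site(donors=["OD2"], acceptors=["OD1", "OD2"]),
    },
    "GLU": {
        "deprotonated": _site(acceptors=["OE1", "OE2"]),
        "protonated": _site(donors=["OE2"], acceptors=["OE1", "OE2"]),
    },
    "HIS": {
        # neutral tautomers donate on exactly one ring nitrogen
        "neutral-ND1": _site(donors=["ND1"], acceptors=["NE2"]),
        "neutral-NE2": _site(donors=["NE2"], acceptors=["ND1"]),
        "protonated": _site(donors=["ND1", "NE2"]),
    },
}

_RESNAME_ALIASES = {
    "ASH": ("ASP", "protonated"),
    "GLH": ("GLU", "protonated"),
    "HSD": ("HIS", "neutral-ND1"),
    "HID": ("HIS", "neutral-ND1"),
    "HSE": ("HIS", "neutral-NE2"),
    "HIE": ("HIS", "neutral-NE2"),
    "HSP": ("HIS", "protonated"),
    "HIP": ("HIS", "protonated"),
}

_DEFAULT_STATES = {
    "ASP": "deprotonated",
    "GLU": "deprotonated",
    "HIS": "neutral-ND1",  # Nδ tautomer
}


@dataclass(frozen=True)
class DonorAcceptorTable:
    """Resolves donor/acceptor heavy atoms per residue name and state.

    Backbone N donates (amide H) and backbone O / OXT accept for every amino
    acid; water oxygen both donates (two hydrogens) and accepts.  Hydrogens
    are located geometrically (covalently within 1.25 Å of the donor heavy
    atom), so naming conventions for H atoms do not matter.
    """

    sidechain_sites: Mapping[str, Mapping[str, SiteDefinition]] = field(
        default_factory=lambda: _SIDECHAIN_SITES
    )
    default_states: Mapping[str, str] = field(default_factory=lambda: _DEFAULT_STATES)
    backbone_donor: bool = True
    backbone_acceptor: bool = True

    @classmethod
    def default(cls) -> "DonorAcceptorTable":
        return cls()

    def _resolve(self, res_name: str, state: str | None) -> tuple[str, str]:
        res_name = res_name.upper()
        if res_name in _RESNAME_ALIASES:
            base, implied = _RESNAME_ALIASES[res_name]
            return base, state or implied
        sites = self.sidechain_sites.get(res_name)
        if sites is None:
            return res_name, "default"
        if state is None:
            state = self.default_states.get(res_name, "default")
        if state not in sites:
            raise KeyError(
                f"unknown protonation state {state!r} for {res_name}; "
                f"known: {sorted(sites)}"
            )
        return res_name, state

    def sidechain_donors(self, res_name: str, state: str | None = None) -> frozenset[str]:
        base, st = self._resolve(res_name, state)
        sites = self.sidechain_sites.get(base)
        return sites[st].donors if sites else frozenset()

    def sidechain_acceptors(self, res_name: str, state: str | None = None) -> frozenset[str]:
        base, st = self._resolve(res_name, state)
        sites = self.sidechain_sites.get(base)
        return sites[st].acceptors if sites else frozenset()

    def donors(self, res_name: str, state: str | None = None) -> frozenset[str]:
        if is_water(res_name):
            return frozenset({"O", "OW", "OH2"})
        out = set(self.sidechain_donors(res_name, state))
        if self.backbone_donor:
            out.add("N")
        return frozenset(out)

    def acceptors(self, res_name: str, state: str | None = None) -> frozenset[str]:
        if is_water(res_name):
            return frozenset({"O", "OW", "OH2"})
        out = set(self.sidechain_acceptors(res_name, state))
        if self.backbone_acceptor:
            out.update({"O", "OXT"})
        return frozenset(out)
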