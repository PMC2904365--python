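"""Atom parameter table: radii, simplified charges, Lennard-Jones terms, H-bond roles.

Radii follow a NACCESS-style united-atom convention (C 1.87, N 1.65, O 1.40,
S 1.85 A). Charges are residue-level formal charges split over the terminal
heteroatoms of Asp/Glu/Lys/Arg side chains; all other atoms are neutral.
Lennard-Jones parameters are a compact per-element set; absolute interaction
energies computed with them are comparable only within this package.
"""
from __future__ import annotations

from dataclasses import dataclass
from importlib import resources
from typing import Dict, List, Tuple

__all__ = ["AtomParams", "ParamTable", "load_default_params", "SIDECHAIN_TOPOLOGY",
           "BACKBONE_ATOMS", "element_from_name"]

# Heavy side-chain atoms beyond CB, in build order, for the 20 standard residues.
SIDECHAIN_TOPOLOGY: Dict[str, List[str]] = {
    "GLY": [], "ALA": [],
    "SER": ["OG"], "CYS": ["SG"],
    "THR": ["OG1", "CG2"], "VAL": ["CG1", "CG2"],
    "LEU": ["CG", "CD1", "CD2"], "ILE": ["CG1", "CG2", "CD1"],
    "MET": ["CG", "SD", "CE"], "PRO": ["CG", "CD"],
    "PHE": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ"],
    "TYR": ["CG", "CD1", "CD2", "CE1", "CE2", "CZ", "OH"],
    "TRP": ["CG", "CD1", "CD2", "NE1", "CE2", "CE3", "CZ2", "CZ3", "CH2"],
    "ASP": ["CG", "OD1", "OD2"], "GLU": ["CG", "CD", "OE1", "OE2"],
    "ASN": ["CG", "OD1", "ND2"], "GLN": ["CG", "CD", "OE1", "NE2"],
    "LYS": ["CG", "CD", "CE", "NZ"],
    "ARG": ["CG", "CD", "NE", "CZ", "NH1", "NH2"],
    "HIS": ["CG", "ND1", "CD2", "CE1", "NE2"],
}

BACKBONE_ATOMS = frozenset({"N", "CA", "C", "O", "OXT", "H", "H1", "H2", "H3",
                            "HA", "HA2", "HA3"})


def element_from_name(name: str) -> str:
    """Infer the element from a PDB atom name (first alphabetic character;
    anything starting with H, including '1HG'-style names, is hydrogen)."""
    for ch in name:
        if ch.isalpha():
            return "H" if ch == "H" else ch.upper()
    return "C"


@dataclass(frozen=True)
class AtomParams:
    radius: float          # A
    charge: float          # e
    eps: float             # kcal/mol
    rmin_half: float       # A
    donor: bool
    acceptor: bool


class ParamTable:
    """Per-(residue, atom) parameter lookup with an element-level fallback.

    Raises ``KeyError`` only if neither a residue-specific row nor an element
    fallback exists for an atom.
    """

    def __init__(self, rows: Dict[Tuple[str, str], AtomParams],
                 fallback: Dict[str, AtomParams]):
        self._rows = rows
        self._fallback = fallback
        for key, p in list(rows.items()) + list(fallback.items()):
            if p.radius <= 0 or p.rmin_half <= 0 or p.eps < 0:
                raise ValueError(f"invalid parameters for {key}: {p}")

    @classmethod
    def from_tsv(cls, path) -> "ParamTable":
        rows: Dict[Tuple[str, str], AtomParams] = {}
        fallback: Dict[str, AtomParams] = {}
        with open(path) as fh:
            header = None
            for line in fh:
                line = line.rstrip("\n")
                if not line or line.startswith("#"):
                    continue
                if header is None:
                    header = line.split("\t")
                    continue
                res, atom, _elem, rad, q, eps, rh, don, acc = line.split("\t")
                p = AtomParams(float(rad), float(q), float(eps), float(rh),
                               bool(int(don)), bool(int(acc)))
                if res == "*":
                    fallback[atom] = p
                else:
                    rows[(res, atom)] = p
        return cls(rows, fallback)

    def lookup(self, residue_name: str, atom_name: str) -> AtomParams:
        key = (residue_name.upper(), atom_name.upper())
        if key in self._rows:
            return self._rows[key]
        elem = element_from_name(atom_name)
        if elem in self._fallback:
            return self._fallback[elem]
        raise KeyError(f"no parameters for atom {atom_name!r} of {residue_name!r} "
                       f"(element {elem!r})")

    def residues(self) -> set:
        return {res for res, _ in self._rows}


def load_default_params() -> ParamTable:
    """Load the parameter table shipped with the package."""
    ref = resources.files("groovedock").joinpath("data/atom_params.tsv")
    with resources.as_file(ref) as path:
        return ParamTable.from_tsv(path)
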