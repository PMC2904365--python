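"""Simplified computational alanine scanning.

Each interface residue is truncated to alanine (all side-chain atoms beyond
C-beta removed, no repacking) and the rigid inter-part interaction energy is
recomputed. The per-residue score is

    ddg_proxy = E(alanine mutant) - E(wild type)

so that destabilizing mutations are positive; residues with
``ddg_proxy >= threshold`` (default 1.0 kcal/mol) are flagged as hotspots.

This is a deterministic energy-difference proxy for binding free-energy
changes: it captures which side chains carry the interface, but the values are
not transferable to trained alanine-scanning energy functions. Glycine and
proline are not scannable (no side chain / ring into backbone) and are
reported flagged rather than scored.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Tuple

import numpy as np
import pandas as pd

from .interface import EnergyParams, interaction_energy, vdw_contacts
from .params import BACKBONE_ATOMS, load_default_params
from .structure import Structure

__all__ = ["HotspotReport", "NotScannableError", "mutate_to_alanine",
           "scan_interface"]

_KEEP_ON_MUTATION = set(BACKBONE_ATOMS) | {"CB"}


class NotScannableError(ValueError):
    """Residue has no truncatable side chain (Gly) or a backbone-fused ring
    (Pro)."""


@dataclass
class HotspotReport:
    table: pd.DataFrame          # chain, resnum, resname, ddg_proxy, is_hotspot
    threshold: float
    not_scannable: List[Tuple[str, int, str]]
    diagnostic: str = ""

    def hotspots(self) -> pd.DataFrame:
        return self.table[self.table.is_hotspot]


def mutate_to_alanine(structure: Structure, chain: str,
                      residue_number: int) -> Structure:
    """Return a copy with the residue truncated to alanine.

    Side-chain atoms beyond C-beta (including side-chain hydrogens) are
    removed; the backbone and C-beta stay in place, and the residue is
    re-typed (and re-parameterized) as ALA.
    """
    idx = structure.residue_atoms(chain, residue_number)
    resname = structure.residue_name[idx[0]]
    if resname == "GLY":
        raise NotScannableError(f"{chain}:{residue_number} is glycine (no CB)")
    if resname == "PRO":
        raise NotScannableError(f"{chain}:{residue_number} is proline "
                                f"(side chain fused to backbone)")
    if resname == "ALA":
        return structure.copy()

    drop = np.zeros(structure.n_atoms, dtype=bool)
    retype = np.zeros(structure.n_atoms, dtype=bool)
    for i in idx:
        if structure.name[i].upper() in _KEEP_ON_MUTATION:
            retype[i] = True
        else:
            drop[i] = True
    out = structure.select(~drop)
    # re-type surviving residue atoms as alanine and refresh their parameters
    table = load_default_params()
    keep_map = np.flatnonzero(~drop)
    inv = {orig: new for new, orig in enumerate(keep_map)}
    for i in np.flatnonzero(retype):
        j = inv[i]
        out.residue_name[j] = "ALA"
        p = table.lookup("ALA", out.name[j])
        out.radius[j] = p.radius
        out.charge[j] = p.charge
        out.eps[j] = p.eps
        out.rmin_half[j] = p.rmin_half
        out.donor[j] = p.donor
        out.acceptor[j] = p.acceptor
    out._index = None
    return out


def scan_interface(part_a: Structure, part_b: Structure,
                   params: EnergyParams = EnergyParams(),
                   threshold: float = 1.0, contact_cutoff: float = 4.0,
                   sides: str = "both") -> HotspotReport:
    """Alanine-scan every interface residue (those appearing in the van der
    Waals contact table at ``contact_cutoff``).

    ``sides`` restricts scanning to residues of part A (``"a"``), part B
    (``"b"``) or both. Rows are sorted by ddg_proxy descending.
    """
    if threshold <= 0:
        raise ValueError("threshold must be positive")
    contacts = vdw_contacts(part_a, part_b, contact_cutoff)
    if contacts.empty:
        return HotspotReport(_empty_table(), threshold, [],
                             diagnostic="no interface residues within "
                                        f"{contact_cutoff} A")
    residues = []
    if sides in ("both", "a"):
        residues += [("a", c, int(n)) for c, n in
                     sorted(set(zip(contacts.chain_a, contacts.resnum_a)))]
    if sides in ("both", "b"):
        residues += [("b", c, int(n)) for c, n in
                     sorted(set(zip(contacts.chain_b, contacts.resnum_b)))]
    if sides not in ("both", "a", "b"):
        raise ValueError(f"unknown sides {sides!r}")

    e_wt = interaction_energy(part_a, part_b, params)
    rows, not_scannable = [], []
    for side, chain, resnum in residues:
        host = part_a if side == "a" else part_b
        resname = host.residue_name[host.residue_atoms(chain, resnum)[0]]
        try:
            mutant = mutate_to_alanine(host, chain, resnum)
        except NotScannableError:
            not_scannable.append((chain, resnum, resname))
            continue
        if side == "a":
            e_mut = interaction_energy(mutant, part_b, params)
        else:
            e_mut = interaction_energy(part_a, mutant, params)
        ddg = e_mut - e_wt
        rows.append({"chain": chain, "residue_number": resnum,
                     "residue_name": resname, "ddg_proxy": ddg,
                     "is_hotspot": bool(ddg >= threshold)})
    table = pd.DataFrame(rows, columns=_COLUMNS) if rows else _empty_table()
    table = table.sort_values("ddg_proxy", ascending=False, ignore_index=True)
    return HotspotReport(table, threshold, not_scannable)


_COLUMNS = ["chain", "residue_number", "residue_name", "ddg_proxy",
            "is_hotspot"]


def _empty_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_COLUMNS)
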