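"""Biology-driven pose filters.

Two filters narrow docking candidates, mirroring the two-step picture of TCR
recognition of peptide-MHC: the receptor first docks onto the MHC helices via
its CDR1/CDR2 loops, then folds its CDR3 loop over the bound peptide.

* A distance-constraint filter expressed in a compact notation: ``30D:A``
  requires residue 30 of probe chain D to lie within the cutoff of any atom of
  target chain A; ``(97-98)D:P`` expands to one constraint per residue in the
  range. The default cutoff is 4.5 A, applied as a strict inequality.
* A register filter keeps only poses whose designated loop apex sits over an
  allowed stretch of the groove-bound peptide (e.g. the central P5-P6
  positions), operationalized as a nearest-residue rule.
"""
from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np

from .grid import Pose, apply_pose
from .structure import Structure

__all__ = ["Constraint", "ConstraintSet", "RegisterFilterSpec", "ConstraintError",
           "parse_constraints", "apply_constraints", "apply_register_filter",
           "min_residue_chain_distance"]


class ConstraintError(ValueError):
    pass


@dataclass(frozen=True)
class Constraint:
    """Residue ``residue_number`` of ``probe_chain`` must lie within ``cutoff``
    of any atom of ``target`` chain."""
    residue_number: int
    probe_chain: str
    target: str
    cutoff: float

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ConstraintError("cutoff must be positive")


@dataclass
class ConstraintSet:
    constraints: List[Constraint] = field(default_factory=list)

    def __len__(self):
        return len(self.constraints)

    def __iter__(self):
        return iter(self.constraints)

    def with_cutoff(self, cutoff: float) -> "ConstraintSet":
        return ConstraintSet([Constraint(c.residue_number, c.probe_chain,
                                         c.target, cutoff)
                              for c in self.constraints])

    def probe_chains(self) -> Set[str]:
        return {c.probe_chain for c in self.constraints}


# token: "30D:A" or "(97-98)D:P"; accept hyphen, en-dash and minus in ranges
_TOKEN = re.compile(
    r"^(?:(?P<num>\d+)|\((?P<lo>\d+)[-–−](?P<hi>\d+)\))"
    r"(?P<probe>[A-Za-z0-9])\:(?P<target>[A-Za-z0-9]+)$")


def parse_constraints(spec: str, cutoff: float = 4.5) -> ConstraintSet:
    """Parse a whitespace-separated constraint string.

    >>> parse_constraints("30D:A 30D:B 50D:A 50D:B (97-98)D:P").constraints[0]
    Constraint(residue_number=30, probe_chain='D', target='A', cutoff=4.5)
    """
    out: List[Constraint] = []
    for token in spec.split():
        m = _TOKEN.match(token)
        if not m:
            raise ConstraintError(f"malformed constraint token {token!r}")
        probe = m.group("probe")
        targets = list(m.group("target"))
        if m.group("num") is not None:
            numbers = [int(m.group("num"))]
        else:
            lo, hi = int(m.group("lo")), int(m.group("hi"))
            if lo > hi:
                raise ConstraintError(f"inverted range in token {token!r}")
            numbers = list(range(lo, hi + 1))
        for t in targets:
            for nres in numbers:
                out.append(Constraint(nres, probe, t, cutoff))
    return ConstraintSet(out)


def min_residue_chain_distance(res_coords: np.ndarray,
                               chain_coords: np.ndarray) -> float:
    d = np.linalg.norm(res_coords[:, None, :] - chain_coords[None, :, :], axis=-1)
    return float(d.min())


def _constraint_atoms(structure: Structure, chain: str, residue_number: int,
                      heavy_only: bool) -> np.ndarray:
    mask = (structure.chain_id == chain) & \
           (structure.residue_number == residue_number)
    if heavy_only:
        mask &= structure.heavy_mask()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ConstraintError(
            f"constraint references residue {residue_number} of chain "
            f"{chain!r}, which is absent")
    return idx


def _chain_atom_indices(structure: Structure, chain: str,
                        heavy_only: bool) -> np.ndarray:
    mask = structure.chain_id == chain
    if heavy_only:
        mask &= structure.heavy_mask()
    idx = np.flatnonzero(mask)
    if len(idx) == 0:
        raise ConstraintError(f"constraint references chain {chain!r}, "
                              f"which is absent")
    return idx


def apply_constraints(poses: Sequence[Pose], static: Structure,
                      mobile: Structure, constraints: ConstraintSet,
                      mode: str = "all", heavy_only: bool = False,
                      peptide_chains: Optional[Set[str]] = None,
                      ) -> Tuple[List[Pose], Dict]:
    """Keep poses satisfying every constraint (min any-atom distance strictly
    below the cutoff).

    Probe chains are looked up in the mobile structure, targets in the static
    one. ``mode="staged"`` applies receptor-facing (non-peptide) constraints
    first and reports per-stage survivor counts; the final survivor set is
    identical to ``mode="all"``. Returns ``(survivors, report)``.
    """
    if mode not in ("all", "staged"):
        raise ValueError(f"unknown mode {mode!r}")

    # resolve atom indices once; errors surface even with zero poses
    resolved = []
    static_chains = set(static.chains)
    for c in constraints:
        if c.probe_chain not in set(mobile.chains):
            raise ConstraintError(
                f"probe chain {c.probe_chain!r} not in mobile structure")
        probe_idx = _constraint_atoms(mobile, c.probe_chain, c.residue_number,
                                      heavy_only)
        target_idx = _chain_atom_indices(static, c.target, heavy_only)
        resolved.append((c, probe_idx, target_idx))

    peptide_like = {"P"} if peptide_chains is None else set(peptide_chains)
    if mode == "staged":
        stage1 = [r for r in resolved if r[0].target not in peptide_like]
        stages = [("receptor-facing", stage1),
                  ("peptide-facing",
                   [r for r in resolved if r[0].target in peptide_like])]
    else:
        stages = [("all", resolved)]

    static_coords = static.positions
    mobile_coords = mobile.positions
    survivors = list(poses)
    counts = {"input": len(survivors)}
    for stage_name, stage_constraints in stages:
        kept = []
        for pose in survivors:
            placed = pose.apply(mobile_coords)
            ok = True
            for c, probe_idx, target_idx in stage_constraints:
                dmin = min_residue_chain_distance(placed[probe_idx],
                                                 static_coords[target_idx])
                if not (dmin < c.cutoff):
                    ok = False
                    break
            if ok:
                kept.append(pose)
        survivors = kept
        counts[stage_name] = len(survivors)
    report = {"mode": mode, "stage_counts": counts,
              "n_constraints": len(constraints)}
    return survivors, report


@dataclass
class RegisterFilterSpec:
    """Keep poses whose loop apex focuses on allowed peptide register
    positions. ``register_map`` maps peptide residue numbers to labels such as
    'P5'; ``loop_residues`` are (chain, residue_number) pairs on the probe."""
    loop_residues: List[Tuple[str, int]]
    peptide_chain: str
    allowed_positions: Set[str]
    register_map: Dict[int, str]

    def __post_init__(self):
        labels = set(self.register_map.values())
        missing = set(self.allowed_positions) - labels
        if missing:
            raise ConstraintError(
                f"allowed positions {sorted(missing)} not in register map")


def apply_register_filter(poses: Sequence[Pose], static: Structure,
                          mobile: Structure, spec: RegisterFilterSpec
                          ) -> Tuple[List[Pose], Dict]:
    """A pose survives iff the peptide residue nearest (minimum heavy-atom
    distance) to the centroid of the loop residues carries an allowed register
    label. Returns ``(survivors, report)`` with the per-pose nearest labels."""
    pep_mask = static.chain_mask(spec.peptide_chain) & static.heavy_mask()
    if not pep_mask.any():
        raise ConstraintError(
            f"peptide chain {spec.peptide_chain!r} empty or absent")
    pep_idx = np.flatnonzero(pep_mask)
    pep_coords = static.positions[pep_idx]
    pep_resnum = static.residue_number[pep_idx]

    loop_idx = []
    for chain, resnum in spec.loop_residues:
        loop_idx.extend(_constraint_atoms(mobile, chain, resnum,
                                          heavy_only=True))
    loop_idx = np.asarray(loop_idx)

    mobile_coords = mobile.positions
    survivors, labels = [], []
    for pose in poses:
        centroid = pose.apply(mobile_coords[loop_idx]).mean(axis=0)
        d = np.linalg.norm(pep_coords - centroid, axis=1)
        nearest_resnum = int(pep_resnum[np.argmin(d)])
        label = spec.register_map.get(nearest_resnum)
        labels.append(label)
        if label in spec.allowed_positions:
            survivors.append(pose)
    report = {"input": len(list(poses)), "survivors": len(survivors),
              "nearest_labels": labels,
              "allowed": sorted(spec.allowed_positions),
              "note": "operationalizes visual register inspection as a "
                      "nearest-residue rule"}
    return survivors, report
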