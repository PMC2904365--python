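"""Interface characterization: accessible surface area, buried interface area,
pairwise interaction energy, van-der-Waals contacts, hydrogen bonds with
per-frame occupancy, and per-frame RMSD / per-atom RMSF for trajectories.

ASA uses quasi-uniform golden-spiral point sampling on each atom's
probe-expanded sphere (seed-free, so results are bit-reproducible at fixed
``n_points``). The interface ASA of a complex A:B is the total buried area
ASA(A) + ASA(B) - ASA(A u B), i.e. both sides of the interface are counted.

Interaction energy is a 6-12 Lennard-Jones plus Coulomb sum over inter-part
atom pairs within a cutoff, with a distance-dependent dielectric. The
parameter set is the compact one shipped with the package, so absolute
energies are comparable only between structures scored by this package.

Hydrogen bonds use the geometric criteria of standard trajectory analysis
tools: donor-acceptor distance <= 0.35 nm and hydrogen-donor-acceptor angle
<= 30 degrees; occupancy is the percentage of frames in which a bond exists.
"""
from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterable, List, Optional, Sequence, Set, Tuple

import numpy as np
import pandas as pd
from scipy.spatial import cKDTree

from .grid import COULOMB_CONSTANT
from .structure import Structure, superpose

__all__ = ["EnergyParams", "HBondCriteria", "InterfaceReport", "asa",
           "interface_asa", "interaction_energy", "vdw_contacts", "hbonds",
           "frame_rmsd", "frame_rmsf", "analyze_interface"]


@dataclass(frozen=True)
class EnergyParams:
    """Nonbonded model: eps(r) = dielectric_factor * r; pair terms beyond
    ``cutoff`` (A) are dropped."""
    cutoff: float = 12.0
    dielectric_factor: float = 4.0

    def __post_init__(self):
        if self.cutoff <= 0:
            raise ValueError("cutoff must be positive")


@dataclass(frozen=True)
class HBondCriteria:
    max_donor_acceptor_distance: float = 0.35   # nm
    max_angle: float = 30.0                     # degrees

    def __post_init__(self):
        if self.max_donor_acceptor_distance <= 0 or self.max_angle <= 0:
            raise ValueError("criteria must be positive")


@dataclass
class InterfaceReport:
    interface_asa: float
    interaction_energy: float
    contacts: pd.DataFrame
    hbonds: pd.DataFrame


# ------------------------------------------------------------------------ ASA
def _spiral_points(n: int) -> np.ndarray:
    """Deterministic quasi-uniform points on the unit sphere (golden spiral)."""
    k = np.arange(n)
    z = 1.0 - (2.0 * k + 1.0) / n
    phi = k * np.pi * (3.0 - np.sqrt(5.0))
    r = np.sqrt(np.clip(1.0 - z * z, 0.0, None))
    return np.stack([r * np.cos(phi), r * np.sin(phi), z], axis=1)


def asa(structure: Structure, probe_radius: float = 1.4,
        n_points: int = 960, frame: int = 0) -> np.ndarray:
    """Per-atom solvent-accessible surface area (A^2), Shrake-Rupley style.

    Each atom's area is 4 pi (r + probe)^2 times the fraction of sample points
    on its expanded sphere not buried inside any neighbor's expanded sphere.
    """
    if n_points < 100:
        raise ValueError("n_points must be >= 100 for a meaningful estimate")
    if (structure.radius <= 0).any():
        raise ValueError("ASA requires radii; assign a parameter table first")
    coords = structure.coords[frame]
    radii = structure.radius + probe_radius
    pts = _spiral_points(n_points)
    tree = cKDTree(coords)
    rmax = radii.max()
    areas = np.zeros(structure.n_atoms)
    neighbor_lists = tree.query_ball_point(coords, r=2.0 * rmax)
    for i in range(structure.n_atoms):
        sphere = coords[i] + radii[i] * pts
        nbr = [j for j in neighbor_lists[i]
               if j != i and np.linalg.norm(coords[j] - coords[i])
               < radii[i] + radii[j]]
        if nbr:
            nc = coords[nbr]
            nr = radii[nbr]
            d2 = ((sphere[:, None, :] - nc[None, :, :]) ** 2).sum(axis=-1)
            buried = (d2 < (nr ** 2)[None, :]).any(axis=1)
            frac = 1.0 - buried.mean()
        else:
            frac = 1.0
        areas[i] = 4.0 * np.pi * radii[i] ** 2 * frac
    return areas


def interface_asa(part_a: Structure, part_b: Structure,
                  probe_radius: float = 1.4, n_points: int = 960) -> float:
    """Total buried interface area (both sides):
    ASA(A) + ASA(B) - ASA(A u B)."""
    union = Structure.concat([part_a, part_b])
    a = asa(part_a, probe_radius, n_points).sum()
    b = asa(part_b, probe_radius, n_points).sum()
    ab = asa(union, probe_radius, n_points).sum()
    return float(a + b - ab)


# --------------------------------------------------------------------- energy
def interaction_energy(part_a: Structure, part_b: Structure,
                       params: EnergyParams = EnergyParams()) -> float:
    """Inter-part nonbonded energy (kcal/mol): 6-12 Lennard-Jones with
    Lorentz-Berthelot-style combination (eps_ij = sqrt(eps_i eps_j),
    Rmin_ij = rmin_half_i + rmin_half_j) plus Coulomb with eps(r) = f r."""
    if (part_a.eps < 0).any() or (part_a.rmin_half <= 0).any() or \
       (part_b.rmin_half <= 0).any():
        raise ValueError("missing Lennard-Jones parameters")
    ca, cb = part_a.positions, part_b.positions
    d = np.linalg.norm(ca[:, None, :] - cb[None, :, :], axis=-1)
    mask = d <= params.cutoff
    if not mask.any():
        return 0.0
    ia, ib = np.nonzero(mask)
    r = d[ia, ib]
    eps_ij = np.sqrt(part_a.eps[ia] * part_b.eps[ib])
    rmin_ij = part_a.rmin_half[ia] + part_b.rmin_half[ib]
    sr = rmin_ij / r
    lj = eps_ij * (sr ** 12 - 2.0 * sr ** 6)
    qq = part_a.charge[ia] * part_b.charge[ib]
    coul = COULOMB_CONSTANT * qq / (params.dielectric_factor * r * r)
    return float(lj.sum() + coul.sum())


# ------------------------------------------------------------------- contacts
def vdw_contacts(part_a: Structure, part_b: Structure,
                 cutoff: float = 4.0) -> pd.DataFrame:
    """Residue-pair contact table: rows where any inter-part heavy-atom
    distance is <= cutoff, with the minimum distance, grouped per part-A
    residue."""
    if cutoff <= 0:
        raise ValueError("cutoff must be positive")
    ha = np.flatnonzero(part_a.heavy_mask())
    hb = np.flatnonzero(part_b.heavy_mask())
    rows: Dict[Tuple, float] = {}
    if len(ha) and len(hb):
        d = np.linalg.norm(part_a.positions[ha][:, None, :] -
                           part_b.positions[hb][None, :, :], axis=-1)
        ia, ib = np.nonzero(d <= cutoff)
        for i, j, dist in zip(ia, ib, d[ia, ib]):
            ai, bj = ha[i], hb[j]
            key = (part_a.chain_id[ai], int(part_a.residue_number[ai]),
                   part_a.residue_name[ai],
                   part_b.chain_id[bj], int(part_b.residue_number[bj]),
                   part_b.residue_name[bj])
            rows[key] = min(rows.get(key, np.inf), float(dist))
    table = pd.DataFrame(
        [k + (v,) for k, v in rows.items()],
        columns=["chain_a", "resnum_a", "resname_a",
                 "chain_b", "resnum_b", "resname_b", "min_distance"])
    return table.sort_values(["chain_a", "resnum_a", "chain_b", "resnum_b"],
                             ignore_index=True)


# -------------------------------------------------------------- hydrogen bonds
def _attached_hydrogens(structure: Structure, donor_idx: int,
                        frame: int = 0) -> np.ndarray:
    """Hydrogens of the donor's residue within covalent range (1.25 A)."""
    res_atoms = structure.residue_atoms(structure.chain_id[donor_idx],
                                        int(structure.residue_number[donor_idx]),
                                        structure.insertion_code[donor_idx])
    hyd = [i for i in res_atoms if structure.element[i] == "H"]
    if not hyd:
        return np.array([], dtype=int)
    d = np.linalg.norm(structure.coords[frame, hyd] -
                       structure.coords[frame, donor_idx], axis=1)
    return np.asarray(hyd)[d < 1.25]


def _angle_deg(a: np.ndarray, vertex: np.ndarray, b: np.ndarray) -> float:
    v1 = a - vertex
    v2 = b - vertex
    cosang = np.dot(v1, v2) / (np.linalg.norm(v1) * np.linalg.norm(v2))
    return float(np.degrees(np.arccos(np.clip(cosang, -1.0, 1.0))))


def hbonds(structure: Structure, partition: Tuple[Iterable[str], Iterable[str]],
           criteria: HBondCriteria = HBondCriteria()) -> pd.DataFrame:
    """Inter-partition hydrogen bonds over all frames, with occupancy.

    A bond exists in a frame iff donor-acceptor distance <= the distance
    cutoff (nm) and some donor hydrogen gives an H-D-A angle <= the angle
    cutoff. Donors lacking hydrogens fall back to a heavy-atom criterion
    (donor-antecedent angle >= 120 deg at 3.5 A) and are marked ``inferred``.
    Occupancy is the percentage of frames (2 decimals).
    """
    if structure.n_frames < 1:
        raise ValueError("structure has no frames")
    set_a, set_b = set(partition[0]), set(partition[1])
    in_a = structure.chain_mask(set_a)
    in_b = structure.chain_mask(set_b)
    donors = np.flatnonzero(structure.donor)
    acceptors = np.flatnonzero(structure.acceptor)
    if len(donors) == 0 or len(acceptors) == 0:
        return _empty_hbond_table()
    dmax = criteria.max_donor_acceptor_distance * 10.0  # nm -> A

    # hydrogen/antecedent identity is frame-independent; resolve once
    donor_h = {int(di): _attached_hydrogens(structure, int(di), frame=0)
               for di in donors}
    donor_ante = {int(di): _donor_antecedent(structure, int(di), frame=0)
                  for di in donors}

    counts: Dict[Tuple[int, int], int] = {}
    inferred: Dict[Tuple[int, int], bool] = {}
    for f in range(structure.n_frames):
        coords = structure.coords[f]
        tree = cKDTree(coords[acceptors])
        near = tree.query_ball_point(coords[donors], r=dmax)
        for d_pos, ajs in enumerate(near):
            di = int(donors[d_pos])
            for a_pos in ajs:
                aj = int(acceptors[a_pos])
                if not ((in_a[di] and in_b[aj]) or (in_b[di] and in_a[aj])):
                    continue
                hyd = donor_h[di]
                if len(hyd):
                    ok = any(_angle_deg(coords[h], coords[di], coords[aj])
                             <= criteria.max_angle for h in hyd)
                    inf = False
                else:
                    ante = donor_ante[di]
                    r = float(np.linalg.norm(coords[di] - coords[aj]))
                    ok = (r <= 3.5 and
                          (ante is None or
                           _angle_deg(coords[ante], coords[di],
                                      coords[aj]) >= 120.0))
                    inf = True
                if ok:
                    counts[(di, aj)] = counts.get((di, aj), 0) + 1
                    inferred[(di, aj)] = inf

    rows = []
    nf = structure.n_frames
    for (di, aj), c in counts.items():
        occ = round(100.0 * c / nf, 2)
        rows.append({
            "donor_chain": structure.chain_id[di],
            "donor_resnum": int(structure.residue_number[di]),
            "donor_resname": structure.residue_name[di],
            "donor_atom": structure.name[di],
            "acceptor_chain": structure.chain_id[aj],
            "acceptor_resnum": int(structure.residue_number[aj]),
            "acceptor_resname": structure.residue_name[aj],
            "acceptor_atom": structure.name[aj],
            "occupancy": occ,
            "n_frames_present": c,
            "inferred": bool(inferred[(di, aj)]),
        })
    table = pd.DataFrame(rows, columns=_HBOND_COLUMNS)
    return table.sort_values("occupancy", ascending=False, ignore_index=True)


_HBOND_COLUMNS = ["donor_chain", "donor_resnum", "donor_resname", "donor_atom",
                  "acceptor_chain", "acceptor_resnum", "acceptor_resname",
                  "acceptor_atom", "occupancy", "n_frames_present", "inferred"]


def _empty_hbond_table() -> pd.DataFrame:
    return pd.DataFrame(columns=_HBOND_COLUMNS)


def _donor_antecedent(structure: Structure, donor_idx: int,
                      frame: int = 0) -> Optional[int]:
    """Nearest bonded heavy atom of the donor (for the heavy-atom fallback)."""
    res_atoms = structure.residue_atoms(structure.chain_id[donor_idx],
                                        int(structure.residue_number[donor_idx]),
                                        structure.insertion_code[donor_idx])
    heavy = [i for i in res_atoms
             if i != donor_idx and structure.element[i] != "H"]
    if not heavy:
        return None
    d = np.linalg.norm(structure.coords[frame, heavy] -
                       structure.coords[frame, donor_idx], axis=1)
    j = int(np.argmin(d))
    return heavy[j] if d[j] < 1.8 else None


# ------------------------------------------------------------ trajectory stats
def frame_rmsd(structure: Structure, reference_frame: int = 0,
               selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-frame best-fit RMSD (A) to a reference frame over a selection."""
    sel = _resolve_selection(structure, selection)
    ref = structure.coords[reference_frame, sel]
    out = np.empty(structure.n_frames)
    for f in range(structure.n_frames):
        out[f] = superpose(structure.coords[f, sel], ref)[2]
    return out


def frame_rmsf(structure: Structure,
               selection: Optional[np.ndarray] = None) -> np.ndarray:
    """Per-atom root-mean-square fluctuation (A) about the mean structure,
    after superposing every frame onto frame 0 over the selection."""
    sel = _resolve_selection(structure, selection)
    ref = structure.coords[0, sel]
    fitted = np.empty((structure.n_frames, len(sel), 3))
    for f in range(structure.n_frames):
        R, t, _ = superpose(structure.coords[f, sel], ref)
        fitted[f] = structure.coords[f, sel] @ R.T + t
    mean = fitted.mean(axis=0)
    return np.sqrt(((fitted - mean) ** 2).sum(axis=-1).mean(axis=0))


def _resolve_selection(structure: Structure, selection) -> np.ndarray:
    if selection is None:
        return np.arange(structure.n_atoms)
    sel = np.asarray(selection)
    if sel.dtype == bool:
        sel = np.flatnonzero(sel)
    if len(sel) == 0:
        raise ValueError("empty atom selection")
    return sel


# -------------------------------------------------------------------- summary
def analyze_interface(part_a: Structure, part_b: Structure,
                      energy_params: EnergyParams = EnergyParams(),
                      probe_radius: float = 1.4, n_points: int = 960,
                      contact_cutoff: float = 4.0,
                      criteria: HBondCriteria = HBondCriteria()
                      ) -> InterfaceReport:
    """Full interface report for a two-part complex (frame 0 for areas and
    energies; hydrogen bonds over all frames of the concatenated complex)."""
    union = Structure.concat([part_a, part_b])
    hb = hbonds(union, (list(part_a.chains), list(part_b.chains)), criteria)
    return InterfaceReport(
        interface_asa=interface_asa(part_a, part_b, probe_radius, n_points),
        interaction_energy=interaction_energy(part_a, part_b, energy_params),
        contacts=vdw_contacts(part_a, part_b, contact_cutoff),
        hbonds=hb,
    )
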