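"""Structures: PDB input/output, parameterization, superposition.

A :class:`Structure` is a columnar container: per-atom identity arrays shared
by all frames, plus an ``(n_frames, n_atoms, 3)`` coordinate array. Multi-model
PDB files (e.g. trajectory snapshots) load as multi-frame structures. Atom
radii, charges, Lennard-Jones terms and donor/acceptor flags are assigned from
a :class:`~groovedock.params.ParamTable` at load (or construction) time.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Dict, Iterable, List, Optional, Sequence, Tuple

import gemmi
import numpy as np

from .params import ParamTable, element_from_name, load_default_params

__all__ = ["Atom", "Structure", "StructureError", "load_structure",
           "save_structure", "superpose", "kabsch_rmsd"]


class StructureError(ValueError):
    """Malformed structure or structure file."""


@dataclass(frozen=True)
class Atom:
    """A single atom (a row view of a Structure, frame 0)."""
    serial: int
    name: str
    element: str
    residue_name: str
    residue_number: int
    insertion_code: str
    chain_id: str
    position: np.ndarray
    radius: float
    charge: float


class Structure:
    """Ordered atom table with one or more coordinate frames.

    Invariants: every frame has exactly one position per atom, and the
    (chain, residue number + insertion code, atom name) triple is unique.
    """

    def __init__(self, serial, name, residue_name, residue_number, insertion_code,
                 chain_id, element, coords, radius=None, charge=None, eps=None,
                 rmin_half=None, donor=None, acceptor=None):
        n = len(name)
        self.serial = np.asarray(serial, dtype=np.int64)
        self.name = np.asarray(name, dtype=object)
        self.residue_name = np.asarray(residue_name, dtype=object)
        self.residue_number = np.asarray(residue_number, dtype=np.int64)
        self.insertion_code = np.asarray(insertion_code, dtype=object)
        self.chain_id = np.asarray(chain_id, dtype=object)
        self.element = np.asarray(element, dtype=object)
        coords = np.asarray(coords, dtype=np.float64)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1] != n or coords.shape[2] != 3:
            raise StructureError(
                f"coordinate array {coords.shape} incongruent with {n} atoms")
        if not np.isfinite(coords).all():
            raise StructureError("non-finite coordinates")
        self.coords = coords

        def arr(x, default):
            return (np.full(n, default) if x is None
                    else np.asarray(x, dtype=type(default)))

        self.radius = arr(radius, 0.0)
        self.charge = arr(charge, 0.0)
        self.eps = arr(eps, 0.0)
        self.rmin_half = arr(rmin_half, 0.0)
        self.donor = arr(donor, False)
        self.acceptor = arr(acceptor, False)
        self._index: Optional[Dict[Tuple[str, int, str], np.ndarray]] = None

    # ---------------------------------------------------------------- basics
    @property
    def n_atoms(self) -> int:
        return len(self.name)

    @property
    def n_frames(self) -> int:
        return self.coords.shape[0]

    @property
    def positions(self) -> np.ndarray:
        """Frame-0 coordinates, shape (n_atoms, 3)."""
        return self.coords[0]

    @property
    def atoms(self) -> List[Atom]:
        return [Atom(int(self.serial[i]), self.name[i], self.element[i],
                     self.residue_name[i], int(self.residue_number[i]),
                     self.insertion_code[i], self.chain_id[i],
                     self.coords[0, i].copy(), float(self.radius[i]),
                     float(self.charge[i]))
                for i in range(self.n_atoms)]

    def copy(self) -> "Structure":
        return Structure(self.serial.copy(), self.name.copy(),
                         self.residue_name.copy(), self.residue_number.copy(),
                         self.insertion_code.copy(), self.chain_id.copy(),
                         self.element.copy(), self.coords.copy(),
                         self.radius.copy(), self.charge.copy(), self.eps.copy(),
                         self.rmin_half.copy(), self.donor.copy(),
                         self.acceptor.copy())

    def select(self, mask) -> "Structure":
        mask = np.asarray(mask)
        if mask.dtype != bool:
            idx = mask
        else:
            idx = np.flatnonzero(mask)
        return Structure(self.serial[idx], self.name[idx],
                         self.residue_name[idx], self.residue_number[idx],
                         self.insertion_code[idx], self.chain_id[idx],
                         self.element[idx], self.coords[:, idx],
                         self.radius[idx], self.charge[idx], self.eps[idx],
                         self.rmin_half[idx], self.donor[idx], self.acceptor[idx])

    def chain_mask(self, chains: Iterable[str] | str) -> np.ndarray:
        if isinstance(chains, str):
            chains = [chains]
        chains = set(chains)
        return np.array([c in chains for c in self.chain_id], dtype=bool)

    def subset_chains(self, chains) -> "Structure":
        return self.select(self.chain_mask(chains))

    @property
    def chains(self) -> List[str]:
        seen = dict.fromkeys(self.chain_id)
        return list(seen)

    def residue_index(self) -> Dict[Tuple[str, int, str], np.ndarray]:
        """(chain_id, residue_number, insertion_code) -> atom index array."""
        if self._index is None:
            idx: Dict[Tuple[str, int, str], list] = {}
            for i in range(self.n_atoms):
                key = (self.chain_id[i], int(self.residue_number[i]),
                       self.insertion_code[i])
                idx.setdefault(key, []).append(i)
            self._index = {k: np.asarray(v) for k, v in idx.items()}
        return self._index

    def residue_atoms(self, chain_id: str, residue_number: int,
                      insertion_code: str = "") -> np.ndarray:
        try:
            return self.residue_index()[(chain_id, residue_number, insertion_code)]
        except KeyError:
            raise KeyError(f"residue {residue_number}{insertion_code} of chain "
                           f"{chain_id!r} not in structure") from None

    def residue_keys(self) -> List[Tuple[str, int, str]]:
        return list(self.residue_index())

    def heavy_mask(self) -> np.ndarray:
        return np.array([e != "H" for e in self.element], dtype=bool)

    def centroid(self, frame: int = 0) -> np.ndarray:
        return self.coords[frame].mean(axis=0)

    # --------------------------------------------------------- modifications
    def assign_params(self, table: ParamTable) -> "Structure":
        """Assign radii/charges/LJ/H-bond roles in place; returns self."""
        for i in range(self.n_atoms):
            p = table.lookup(self.residue_name[i], self.name[i])
            self.radius[i] = p.radius
            self.charge[i] = p.charge
            self.eps[i] = p.eps
            self.rmin_half[i] = p.rmin_half
            self.donor[i] = p.donor
            self.acceptor[i] = p.acceptor
        return self

    def transformed(self, rotation: np.ndarray, translation: np.ndarray) -> "Structure":
        """Return a copy with every frame mapped through x -> R x + t."""
        out = self.copy()
        R = np.asarray(rotation, dtype=float)
        t = np.asarray(translation, dtype=float)
        out.coords = np.einsum("ij,fnj->fni", R, self.coords) + t
        out._index = None
        return out

    def with_coords(self, coords: np.ndarray) -> "Structure":
        out = self.copy()
        coords = np.asarray(coords, dtype=float)
        if coords.ndim == 2:
            coords = coords[None]
        if coords.shape[1:] != (self.n_atoms, 3):
            raise StructureError("replacement coordinates incongruent")
        out.coords = coords
        return out

    @staticmethod
    def concat(parts: Sequence["Structure"]) -> "Structure":
        if not parts:
            raise StructureError("nothing to concatenate")
        nf = {p.n_frames for p in parts}
        if len(nf) != 1:
            raise StructureError("frame-count mismatch in concat")
        return Structure(
            np.concatenate([p.serial for p in parts]),
            np.concatenate([p.name for p in parts]),
            np.concatenate([p.residue_name for p in parts]),
            np.concatenate([p.residue_number for p in parts]),
            np.concatenate([p.insertion_code for p in parts]),
            np.concatenate([p.chain_id for p in parts]),
            np.concatenate([p.element for p in parts]),
            np.concatenate([p.coords for p in parts], axis=1),
            np.concatenate([p.radius for p in parts]),
            np.concatenate([p.charge for p in parts]),
            np.concatenate([p.eps for p in parts]),
            np.concatenate([p.rmin_half for p in parts]),
            np.concatenate([p.donor for p in parts]),
            np.concatenate([p.acceptor for p in parts]),
        )


# ------------------------------------------------------------------ file I/O
def load_structure(path, param_table: Optional[ParamTable] = None,
                   keep_waters: bool = False) -> Structure:
    """Read a (possibly multi-model) PDB file into a Structure.

    Water HETATM records are skipped by default; alternate locations other
    than blank/'A' are dropped. Hydrogens are retained.
    """
    try:
        st = gemmi.read_structure(str(path), format=gemmi.CoorFormat.Pdb)
    except (RuntimeError, ValueError, FileNotFoundError) as exc:
        raise StructureError(f"cannot read PDB file {path}: {exc}") from exc

    frames = []
    meta = None
    for model in st:
        serial, name, resname, resnum, icode, chain, element, xyz = \
            [], [], [], [], [], [], [], []
        for ch in model:
            for res in ch:
                if not keep_waters and res.name in ("HOH", "WAT", "DOD"):
                    continue
                for at in res:
                    if at.altloc not in ("\0", "", "A"):
                        continue
                    serial.append(at.serial)
                    name.append(at.name)
                    resname.append(res.name)
                    resnum.append(res.seqid.num)
                    icode.append(res.seqid.icode.strip())
                    chain.append(ch.name)
                    el = at.element.name if at.element else ""
                    element.append(el if el and el != "X"
                                   else element_from_name(at.name))
                    xyz.append([at.pos.x, at.pos.y, at.pos.z])
        key = list(zip(chain, resnum, name))
        if meta is None:
            meta = (serial, name, resname, resnum, icode, chain, element, key)
        elif key != meta[7]:
            raise StructureError(
                f"{path}: MODEL blocks are not congruent (atom lists differ)")
        frames.append(np.asarray(xyz, dtype=float).reshape(-1, 3))

    if meta is None or len(meta[0]) == 0:
        raise StructureError(f"{path}: no ATOM records")
    serial, name, resname, resnum, icode, chain, element, _ = meta
    s = Structure(serial, name, resname, resnum, icode, chain, element,
                  np.stack(frames))
    if param_table is None:
        param_table = load_default_params()
    return s.assign_params(param_table)


def save_structure(structure: Structure, path) -> None:
    """Write a Structure as PDB text; multi-frame emits MODEL/ENDMDL blocks."""
    if structure.n_atoms == 0:
        raise StructureError("refusing to write an empty structure")
    # group atom indices per chain, then per residue (gemmi copies on add, so
    # containers must be fully built bottom-up before insertion)
    chain_order: List[str] = []
    chain_atoms: Dict[str, List[int]] = {}
    for i in range(structure.n_atoms):
        cid = structure.chain_id[i]
        if cid not in chain_atoms:
            chain_atoms[cid] = []
            chain_order.append(cid)
        chain_atoms[cid].append(i)

    st = gemmi.Structure()
    st.name = "groovedock"
    for f in range(structure.n_frames):
        model = gemmi.Model(f + 1)
        for cid in chain_order:
            chain_obj = gemmi.Chain(cid)
            res_obj = None
            last_res = None
            pending = []
            for i in chain_atoms[cid]:
                rkey = (int(structure.residue_number[i]),
                        structure.insertion_code[i],
                        structure.residue_name[i])
                if rkey != last_res:
                    if res_obj is not None:
                        chain_obj.add_residue(res_obj)
                    res_obj = gemmi.Residue()
                    res_obj.name = structure.residue_name[i]
                    res_obj.seqid = gemmi.SeqId(
                        int(structure.residue_number[i]),
                        structure.insertion_code[i] or " ")
                    last_res = rkey
                at = gemmi.Atom()
                at.name = structure.name[i]
                at.serial = int(structure.serial[i])
                at.element = gemmi.Element(structure.element[i])
                x, y, z = structure.coords[f, i]
                at.pos = gemmi.Position(float(x), float(y), float(z))
                at.occ = 1.0
                at.b_iso = 0.0
                res_obj.add_atom(at)
            if res_obj is not None:
                chain_obj.add_residue(res_obj)
            model.add_chain(chain_obj)
        st.add_model(model)
    st.setup_entities()
    try:
        st.write_pdb(str(path))
    except (RuntimeError, OSError) as exc:
        raise StructureError(f"cannot write PDB file {path}: {exc}") from exc


# -------------------------------------------------------------- superposition
def superpose(mobile: np.ndarray, reference: np.ndarray
              ) -> Tuple[np.ndarray, np.ndarray, float]:
    """Least-squares rigid superposition (Kabsch).

    Returns ``(rotation, translation, rmsd)`` such that
    ``rotation @ mobile.T + translation`` best fits ``reference``; the rotation
    is proper (determinant +1).
    """
    P = np.asarray(mobile, dtype=float)
    Q = np.asarray(reference, dtype=float)
    if P.shape != Q.shape:
        raise ValueError(f"point-count mismatch: {P.shape} vs {Q.shape}")
    if P.ndim != 2 or P.shape[1] != 3 or P.shape[0] < 3:
        raise ValueError("need at least 3 points of dimension 3")
    cp, cq = P.mean(axis=0), Q.mean(axis=0)
    P0, Q0 = P - cp, Q - cq
    H = P0.T @ Q0
    U, S, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    D = np.diag([1.0, 1.0, d])
    R = Vt.T @ D @ U.T
    t = cq - R @ cp
    diff = (P0 @ R.T) - Q0
    rmsd = float(np.sqrt((diff ** 2).sum() / len(P)))
    return R, t, rmsd


def kabsch_rmsd(a: np.ndarray, b: np.ndarray) -> float:
    """RMSD after optimal rigid superposition."""
    return superpose(a, b)[2]
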