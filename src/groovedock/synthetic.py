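"""Deterministic synthetic structures with planted ground truth.

The benchmark emulates, at toy scale, the geometry of a TCR-Vbeta domain
docking onto a peptide-MHC class II surface: the receptor is two parallel
alpha-helical rods flanking an open groove that holds an extended 13-residue
peptide (register labels P-2..P11, P1 being the third residue, as for a
class-II convention where flanking residues precede the P1 anchor); the probe
is a compact ~60-residue helical domain with three downward loops standing in
for CDR1, CDR2 and CDR3. The native pose places the CDR1/CDR2 apexes into the
groove against both helix walls and the CDR3 apex over the central peptide
positions (P5-P6), with

* a planted hydrogen bond (probe Ser OG-HG donating to the peptide P5 Ser OG)
  satisfying the 0.35 nm / 30 degree criteria exactly,
* a planted electrostatic anchor: the CDR3 arginine guanidinium over the
  buried carboxylate of the peptide P6 glutamate, placed so that the arginine
  is the unique interface hotspot of the alanine scan,
* chemically plausible packing: non-planted inter-part contacts stay near
  van-der-Waals distances (>= ~2.8 A); only the planted hydrogen bond's
  hydrogen approaches the acceptor more closely, as hydrogen bonds do. The
  clash floor asserted for the native pose is 1.5 A; decoys are generated
  clash-free at 2.5 A.

Structures use real amino-acid topologies so parameterization, hydrogen-bond
typing and alanine truncation work unchanged. Toy geometry is idealized
(helices are ideal cylinders, side chains extend radially); folding realism is
out of scope.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np

from .filters import ConstraintSet, RegisterFilterSpec, parse_constraints
from .grid import Pose
from .params import SIDECHAIN_TOPOLOGY, load_default_params
from .structure import Structure

__all__ = ["BenchmarkSpec", "Benchmark", "make_benchmark", "make_decoys",
           "make_trajectory"]

# geometry constants (Angstrom)
_HELIX_RADIUS = 2.3
_HELIX_RISE = 1.5
_HELIX_TWIST = 100.0
_CB_LENGTH = 1.53
_SIDE_STEP = 1.38
_BRANCH_OFFSET = 0.85

_GREEK_LEVEL = {"B": 0, "G": 1, "D": 2, "E": 3, "Z": 4, "H": 5}


def _unit(v: np.ndarray) -> np.ndarray:
    return v / np.linalg.norm(v)


def _perp(v: np.ndarray) -> np.ndarray:
    ref = np.array([0.0, 0.0, 1.0])
    if abs(np.dot(_unit(v), ref)) > 0.9:
        ref = np.array([1.0, 0.0, 0.0])
    return _unit(np.cross(v, ref))


class _ChainBuilder:
    """Accumulates atoms for one chain from CA traces + side-chain rules."""

    def __init__(self, chain_id: str):
        self.chain_id = chain_id
        self.rows: List[Tuple[str, str, int, np.ndarray, str]] = []
        # (atom name, resname, resnum, position, element)

    def add_residue(self, resnum: int, resname: str, ca: np.ndarray,
                    prev_ca: Optional[np.ndarray], next_ca: Optional[np.ndarray],
                    outward: np.ndarray, branch_dir: Optional[np.ndarray] = None,
                    backbone_h: bool = True,
                    o_dir: Optional[np.ndarray] = None,
                    h_dir: Optional[np.ndarray] = None) -> None:
        ca = np.asarray(ca, dtype=float)
        if prev_ca is None and next_ca is None:
            tangent = _perp(outward)
        elif prev_ca is None:
            tangent = _unit(next_ca - ca)
        elif next_ca is None:
            tangent = _unit(ca - prev_ca)
        else:
            tangent = _unit(next_ca - prev_ca)
        outward = _unit(np.asarray(outward, dtype=float))
        if branch_dir is None:
            branch_dir = _unit(np.cross(outward, tangent))

        n_pos = ca - 1.27 * tangent + 0.35 * outward
        c_pos = ca + 1.27 * tangent + 0.35 * outward
        o_pos = c_pos + 1.23 * (outward if o_dir is None else _unit(o_dir))
        self._add("N", resname, resnum, n_pos)
        self._add("CA", resname, resnum, ca)
        self._add("C", resname, resnum, c_pos)
        self._add("O", resname, resnum, o_pos)
        if backbone_h:
            if h_dir is None:
                if prev_ca is not None:
                    prev_c = prev_ca + 1.27 * _unit(ca - prev_ca) + 0.35 * outward
                    h_dir = _unit(n_pos - prev_c)
                else:
                    h_dir = outward
            self._add("H", resname, resnum, n_pos + 1.0 * _unit(h_dir))
        if resname == "GLY":
            return
        cb = ca + _CB_LENGTH * outward
        self._add("CB", resname, resnum, cb)
        for name in SIDECHAIN_TOPOLOGY[resname]:
            level = _GREEK_LEVEL[name[1]] if len(name) > 1 else 1
            pos = ca + (_CB_LENGTH + _SIDE_STEP * level) * outward
            if name.endswith("1"):
                pos = pos + _BRANCH_OFFSET * branch_dir
            elif name.endswith("2"):
                pos = pos - _BRANCH_OFFSET * branch_dir
            self._add(name, resname, resnum, pos)
        if resname == "SER":
            og = [r for r in self.rows
                  if r[2] == resnum and r[0] == "OG"][-1][3]
            self._add("HG", resname, resnum, og + 0.97 * outward)
        elif resname == "THR":
            og = [r for r in self.rows
                  if r[2] == resnum and r[0] == "OG1"][-1][3]
            self._add("HG1", resname, resnum, og + 0.97 * outward)

    def _add(self, name, resname, resnum, pos):
        element = "H" if name.startswith("H") else name[0]
        self.rows.append((name, resname, resnum, np.asarray(pos, float), element))

    def move_atom(self, resnum: int, name: str, pos: np.ndarray) -> None:
        for i, (n, rn, num, _, el) in enumerate(self.rows):
            if num == resnum and n == name:
                self.rows[i] = (n, rn, num, np.asarray(pos, float), el)
                return
        raise KeyError(f"{name} of residue {resnum} not in chain "
                       f"{self.chain_id}")

    def atom_pos(self, resnum: int, name: str) -> np.ndarray:
        for n, _, num, pos, _ in self.rows:
            if num == resnum and n == name:
                return pos.copy()
        raise KeyError(f"{name}/{resnum}")


def _assemble(builders: Sequence[_ChainBuilder], start_serial: int = 1,
              jitter_rng: Optional[np.random.Generator] = None,
              jitter_sigma: float = 0.0,
              frozen: Optional[set] = None) -> Structure:
    serial, name, resname, resnum, icode, chain, element, xyz = \
        [], [], [], [], [], [], [], []
    s = start_serial
    frozen = frozen or set()
    for b in builders:
        for (n, rn, num, pos, el) in b.rows:
            serial.append(s)
            s += 1
            name.append(n)
            resname.append(rn)
            resnum.append(num)
            icode.append("")
            chain.append(b.chain_id)
            element.append(el)
            p = pos.copy()
            if jitter_rng is not None and jitter_sigma > 0 and \
                    (b.chain_id, num, n) not in frozen:
                p = p + jitter_rng.normal(0.0, jitter_sigma, 3)
            xyz.append(p)
    st = Structure(serial, name, resname, resnum, icode, chain, element,
                   np.asarray(xyz))
    return st.assign_params(load_default_params())


def _helix_cas(n: int, start: np.ndarray, axis: np.ndarray,
               phase_deg: float = 0.0) -> Tuple[np.ndarray, np.ndarray]:
    """Ideal helix CA trace plus per-residue radial outward unit vectors."""
    axis = _unit(np.asarray(axis, float))
    u = _perp(axis)
    v = np.cross(axis, u)
    k = np.arange(n)
    theta = np.radians(phase_deg + _HELIX_TWIST * k)
    ca = (np.asarray(start, float)[None, :] + _HELIX_RISE * k[:, None] * axis
          + _HELIX_RADIUS * (np.cos(theta)[:, None] * u +
                             np.sin(theta)[:, None] * v))
    outward = np.cos(theta)[:, None] * u + np.sin(theta)[:, None] * v
    return ca, outward


def _add_trace(builder: _ChainBuilder, resnums: Sequence[int],
               resnames: Sequence[str], cas: np.ndarray,
               outwards: np.ndarray, axis: Optional[np.ndarray] = None) -> None:
    """Add residues along a CA path. For helical segments pass ``axis``: the
    carbonyl O points along the axis and the amide H against it, as in an
    alpha-helix, which keeps the rod surface smooth."""
    n = len(resnums)
    o_dir = None if axis is None else _unit(np.asarray(axis, float))
    h_dir = None if axis is None else -o_dir
    for i in range(n):
        builder.add_residue(
            resnums[i], resnames[i], cas[i],
            cas[i - 1] if i > 0 else None,
            cas[i + 1] if i < n - 1 else None,
            outwards[i], o_dir=o_dir, h_dir=h_dir)


# --------------------------------------------------------------- benchmark
@dataclass
class BenchmarkSpec:
    """Parameters of the synthetic docking benchmark.

    Defaults define the reference study conditions: a 16-residue helix on each
    groove wall (axis separation 16 A), a 13-residue peptide with P1 at the
    third residue, a 60-residue probe, and planted H-bond / charge-anchor
    geometry at ideal values.
    """
    seed: int = 0
    helix_len: int = 12
    helix_half_separation: float = 7.5
    helix_z: float = 3.0
    peptide_len: int = 13
    peptide_spacing: float = 3.4
    floor_z: float = -8.2
    probe_rod_x: float = 4.3     # raft rod offset from the groove axis
    probe_rod_z: float = 10.70   # raft rod height (rests on the helix walls)
    jitter_sigma: float = 0.02
    cdr1_resnum: int = 15
    cdr2_resnum: int = 33
    cdr3_resnums: Tuple[int, int] = (51, 52)
    constraint_cutoff: float = 4.5
    native_clearance: float = 1.5   # clash floor asserted for the native pose, A
    decoy_clearance: float = 2.5    # clash floor for decoys, A


@dataclass
class Benchmark:
    receptor: Structure
    probe: Structure
    native_pose: Pose
    truth: Dict

    def constraint_set(self) -> ConstraintSet:
        return parse_constraints(self.truth["constraints"],
                                 self.truth["constraint_cutoff"])

    def register_spec(self) -> RegisterFilterSpec:
        t = self.truth["register"]
        return RegisterFilterSpec(
            loop_residues=[tuple(x) for x in t["loop_residues"]],
            peptide_chain=t["peptide_chain"],
            allowed_positions=set(t["allowed_positions"]),
            register_map={int(k): v for k, v in t["register_map"].items()})


def make_benchmark(spec: BenchmarkSpec = BenchmarkSpec()) -> Benchmark:
    """Build the synthetic receptor/probe pair in the native pose.

    The probe coordinates are returned already in the native placement, so the
    native pose is the identity transform; rigid-body docking is translation/
    rotation invariant, so this is no loss of generality.
    """
    rng = np.random.default_rng(spec.seed)

    # ---- receptor helices (chains A and B): smooth glycine rods along +y.
    # Axial carbonyls/amides keep the tube surface uniform (radius ~2.3 A) so
    # wall proximity does not depend on side-chain phase.
    y0 = -0.5 * (spec.helix_len - 1) * _HELIX_RISE
    axis_y = np.array([0.0, 1.0, 0.0])
    cha = _ChainBuilder("A")
    cas, outw = _helix_cas(spec.helix_len,
                           np.array([-spec.helix_half_separation, y0,
                                     spec.helix_z]), axis_y, phase_deg=0.0)
    _add_trace(cha, list(range(1, spec.helix_len + 1)),
               ["GLY"] * spec.helix_len, cas, outw, axis=axis_y)
    chb = _ChainBuilder("B")
    cas, outw = _helix_cas(spec.helix_len,
                           np.array([spec.helix_half_separation, y0,
                                     spec.helix_z]), axis_y, phase_deg=180.0)
    _add_trace(chb, list(range(1, spec.helix_len + 1)),
               ["GLY"] * spec.helix_len, cas, outw, axis=axis_y)

    # ---- peptide (chain P): extended along y, centered; side chains point up
    # toward the probe except the P4/P6 anchors (Asp/Glu), which are buried
    # downward like class-II pocket anchors.
    pep_names = ["GLY", "ALA", "ALA", "GLY", "ALA", "ASP", "SER", "GLU",
                 "ALA", "GLY", "ALA", "GLY", "ALA"][: spec.peptide_len]
    npep = spec.peptide_len
    yp0 = -0.5 * (npep - 1) * spec.peptide_spacing
    chp = _ChainBuilder("P")

    def pep_ca(k):
        y = yp0 + spec.peptide_spacing * k
        x = 0.4 * (-1) ** k
        z = 0.0
        # peptide-flanking residues drape down over the platform edge instead
        # of extending straight out of the groove
        excess = abs(y) - 8.2
        if excess > 0:
            z = max(-1.05 * excess, -7.2)
            y = np.sign(y) * (8.2 + 0.55 * excess)
        return np.array([x, y, z])

    pep_cas = np.stack([pep_ca(k) for k in range(npep)])
    pep_out = np.tile(np.array([0.0, 0.0, 1.0]), (npep, 1))
    pep_out[5] = np.array([0.0, 0.0, -1.0])   # P4 Asp anchor
    pep_out[7] = np.array([0.0, 0.0, -1.0])   # P6 Glu anchor
    _add_trace(chp, list(range(1, npep + 1)), pep_names, pep_cas, pep_out)

    # ---- floor (chain M): beta-sheet-like glycine strands under the groove,
    # giving the receptor a solid interior (penetrating poses then hit core
    # cells) the way the MHC platform domain has a beta-sheet floor.
    # The floor spans only the region between the walls: no ledge protrudes
    # beyond them, so the receptor exterior offers no groove-like trench that
    # could rival the binding site in surface complementarity.
    chm = _ChainBuilder("M")
    n_floor_res = 6
    yf0 = -0.5 * (n_floor_res - 1) * 3.0
    strand_x = [x for x in range(-8, 9, 2)]
    res_counter = 0
    for si, xi in enumerate(strand_x):
        cas = np.stack([np.array([xi, yf0 + 3.0 * k,
                                  spec.floor_z + 0.3 * (-1) ** k])
                        for k in range(n_floor_res)])
        outs = np.tile(np.array([0.0, 0.0, -1.0]), (n_floor_res, 1))
        nums = list(range(res_counter + 1, res_counter + n_floor_res + 1))
        res_counter += n_floor_res
        _add_trace(chm, nums, ["GLY"] * n_floor_res, cas, outs)
    # swing the P5 Ser hydroxyl hydrogen sideways so the planted probe donor
    # can sit directly above the acceptor oxygen
    og_p5 = chp.atom_pos(7, "OG")
    chp.move_atom(7, "HG", og_p5 + 0.97 * _unit(np.array([0.8, -0.5, -0.2])))

    # registers: residues 1-2 flank; P1..P11 are residues 3..13
    register_map = {1: "P-2", 2: "P-1"}
    register_map.update({i: f"P{i - 2}" for i in range(3, npep + 1)})

    # ---- probe (chain D): a raft of two glycine rods lying parallel along
    # the receptor helices (long conformal line contacts), a capping helix on
    # top, and three CDR-like prongs reaching into the groove.
    zr = spec.probe_rod_z
    xr = spec.probe_rod_x
    chd = _ChainBuilder("D")
    segments: List[Tuple[List[int], List[str], np.ndarray, np.ndarray,
                         Optional[np.ndarray]]] = []

    def helix_seg(first, last, names, start, axis, phase):
        n = last - first + 1
        cas, outw = _helix_cas(n, np.asarray(start, float), axis, phase)
        segments.append((list(range(first, last + 1)), list(names), cas, outw,
                         np.asarray(axis, float)))

    def prong_seg(resnums, names, cas, out_dirs):
        segments.append((list(resnums), list(names), np.asarray(cas, float),
                         np.asarray(out_dirs, float), None))

    y0r = -0.5 * 11 * _HELIX_RISE          # center the 12-residue rods
    helix_seg(1, 12, ["GLY"] * 12, [-xr, y0r, zr], axis_y, 0.0)
    # CDR1 prong crossing the groove mouth at y ~ -5.25
    down = np.array([0.0, 0.0, -1.0])
    prong_seg([13, 14, 15, 16, 17],
              ["GLY", "GLY", "GLY", "GLY", "GLY"],
              [[-3.2, -6.2, 8.9], [-1.8, -5.7, 7.4], [0.0, -5.25, 6.2],
               [1.8, -5.7, 7.4], [3.2, -6.2, 8.9]],
              [down, down, down, down, down])
    helix_seg(19, 30, ["GLY"] * 12, [xr, y0r, zr], axis_y, 180.0)
    # CDR2 prong at y ~ +5.25
    prong_seg([31, 32, 33, 34, 35],
              ["GLY", "GLY", "GLY", "GLY", "GLY"],
              [[-3.2, 6.2, 8.9], [-1.8, 5.7, 7.4], [0.0, 5.25, 6.2],
               [1.8, 5.7, 7.4], [3.2, 6.2, 8.9]],
              [down, down, down, down, down])
    helix_seg(37, 48, ["ALA"] * 12, [0.0, y0r, zr + 3.6], axis_y, 90.0)
    # CDR3 prong: Arg (electrostatic anchor) + Ser (planted H-bond donor)
    prong_seg([49, 50, 51, 52, 53],
              ["GLY", "ALA", "ARG", "SER", "GLY"],
              [[2.8, -2.4, 11.4], [1.6, -1.4, 10.6], [0.15, -0.35, 10.3],
               [0.8, -0.9, 8.6], [-1.8, -0.1, 11.0]],
              [down, down, down, down, down])
    # top capping helix: varied side chains, all >10 A from the receptor
    helix_seg(54, 60, ["SER", "LEU", "VAL", "ALA", "LEU", "SER", "ALA"],
              [0.0, -4.5, zr + 10.4], axis_y, 45.0)

    for resnums, names, cas, outw, seg_axis in segments:
        _add_trace(chd, resnums, names, cas, outw, axis=seg_axis)

    # ---- plant exact geometries -----------------------------------------
    # H-bond: probe Ser52 OG-HG donates to peptide P5 (residue 7) Ser OG.
    acceptor = chp.atom_pos(7, "OG")
    og = acceptor + np.array([0.0, 0.0, 2.9])
    chd.move_atom(52, "OG", og)
    chd.move_atom(52, "HG", acceptor + np.array([0.0, 0.0, 1.92]))
    chd.move_atom(52, "CB", og + np.array([0.3, -0.6, 1.35]))

    # Electrostatic anchor: the Arg51 side chain descends over the peptide
    # with the guanidinium ~5 A above the backbone, poised between the two
    # buried anchor carboxylates (P4 Asp, P6 Glu) roughly 10.5 A below. With
    # the distance-dependent dielectric, each carboxylate contributes well
    # under the hotspot threshold while the arginine, summing both, exceeds it
    # and is the unique hotspot.
    arm = {
        "CB": np.array([0.15, 0.55, 9.40]),
        "CG": np.array([0.15, 1.00, 8.10]),
        "CD": np.array([0.15, 1.50, 6.80]),
        "NE": np.array([0.15, 2.40, 5.85]),
        "CZ": np.array([0.15, 3.30, 5.10]),
        "NH1": np.array([1.00, 3.40, 4.60]),
        "NH2": np.array([-0.70, 3.40, 4.60]),
    }
    for nm, pos in arm.items():
        chd.move_atom(51, nm, pos)

    frozen = {("D", 52, "OG"), ("D", 52, "HG"), ("D", 52, "CB"),
              ("P", 7, "OG"), ("P", 7, "HG"),
              ("P", 8, "OE1"), ("P", 8, "OE2"),
              ("P", 6, "OD1"), ("P", 6, "OD2")} | \
             {("D", 51, nm) for nm in arm}

    receptor = _assemble([cha, chb, chp, chm], start_serial=1,
                         jitter_rng=rng, jitter_sigma=spec.jitter_sigma,
                         frozen=frozen)
    probe = _assemble([chd], start_serial=receptor.n_atoms + 1,
                      jitter_rng=rng, jitter_sigma=spec.jitter_sigma,
                      frozen=frozen)

    native_pose = Pose(rotation=np.eye(3), translation=np.zeros(3),
                       shape_score=0, pose_id=0, rank=0)

    constraints = (f"{spec.cdr1_resnum}D:A {spec.cdr1_resnum}D:B "
                   f"{spec.cdr2_resnum}D:A {spec.cdr2_resnum}D:B "
                   f"({spec.cdr3_resnums[0]}-{spec.cdr3_resnums[1]})D:P")
    truth = {
        "seed": spec.seed,
        "constraints": constraints,
        "constraint_cutoff": spec.constraint_cutoff,
        "register": {
            "loop_residues": [["D", spec.cdr3_resnums[0]],
                              ["D", spec.cdr3_resnums[1]]],
            "peptide_chain": "P",
            "allowed_positions": ["P5", "P6"],
            "register_map": {str(k): v for k, v in register_map.items()},
        },
        "hbond": {"donor": ["D", 52, "OG"], "hydrogen": ["D", 52, "HG"],
                  "acceptor": ["P", 7, "OG"],
                  "distance_nm": 0.29, "angle_deg": 0.0},
        "salt_bridge": {"probe_residue": ["D", 51, "ARG"],
                        "partner_residue": ["P", 8, "GLU"],
                        "probe_atoms": ["NH1", "NH2"],
                        "partner_atoms": ["OE1", "OE2"]},
        "hotspot_residue": ["D", 51],
        "native_transform": {"rotation": np.eye(3).tolist(),
                             "translation": [0.0, 0.0, 0.0]},
        "native_clearance": spec.native_clearance,
        "decoy_clearance": spec.decoy_clearance,
    }

    _check_native(receptor, probe, spec)
    return Benchmark(receptor, probe, native_pose, truth)


def _check_native(receptor: Structure, probe: Structure,
                  spec: BenchmarkSpec) -> None:
    d = np.linalg.norm(receptor.positions[:, None, :] -
                       probe.positions[None, :, :], axis=-1)
    dmin = float(d.min())
    if dmin < spec.native_clearance:
        raise ValueError(f"native pose has a steric clash ({dmin:.2f} A)")
    cs = parse_constraints(
        f"{spec.cdr1_resnum}D:A {spec.cdr1_resnum}D:B "
        f"{spec.cdr2_resnum}D:A {spec.cdr2_resnum}D:B "
        f"({spec.cdr3_resnums[0]}-{spec.cdr3_resnums[1]})D:P",
        spec.constraint_cutoff)
    for c in cs:
        pm = (probe.chain_id == c.probe_chain) & \
             (probe.residue_number == c.residue_number)
        tm = receptor.chain_id == c.target
        dd = d[np.ix_(np.flatnonzero(tm), np.flatnonzero(pm))].min()
        if not dd < c.cutoff:
            raise ValueError(
                f"native pose violates planted constraint "
                f"{c.residue_number}{c.probe_chain}:{c.target} ({dd:.2f} A)")


# ------------------------------------------------------------------- decoys
def make_decoys(benchmark: Benchmark, n: int, seed: int = 0
                ) -> Tuple[List[Pose], Dict]:
    """Random clash-free rigid placements of the probe around the receptor.

    Each decoy is a uniform random rotation of the probe slid toward the
    receptor from a random direction until just clash-free (closest approach
    at the decoy clearance). The manifest reports how many decoys violate the
    planted distance constraints and the register rule, computed by direct
    distance checks inside this module.
    """
    if n < 1:
        raise ValueError("need n >= 1 decoys")
    rng = np.random.default_rng(seed)
    receptor, probe = benchmark.receptor, benchmark.probe
    rcoords = receptor.positions
    rcenter = rcoords.mean(axis=0)
    pcoords = probe.positions
    pcenter = pcoords.mean(axis=0)
    local = pcoords - pcenter
    clearance = benchmark.truth["decoy_clearance"]

    poses: List[Pose] = []
    n_violate_constraints = 0
    n_violate_register = 0
    cs = benchmark.constraint_set()
    reg = benchmark.register_spec()

    while len(poses) < n:
        R = _random_rotation(rng)
        direction = _random_unit(rng)
        rotated = local @ R.T
        # slide inward until contact (bisection on the clash-free predicate)
        lo, hi = 0.0, 80.0
        if _min_dist(rotated + rcenter + hi * direction, rcoords) < clearance:
            continue
        if _min_dist(rotated + rcenter, rcoords) >= clearance:
            s = 0.0
        else:
            for _ in range(40):
                mid = 0.5 * (lo + hi)
                if _min_dist(rotated + rcenter + mid * direction,
                             rcoords) >= clearance:
                    hi = mid
                else:
                    lo = mid
            s = hi
        t_abs = rcenter + s * direction - R @ pcenter
        pose = Pose(rotation=R, translation=t_abs, shape_score=0,
                    pose_id=len(poses) + 1, rank=len(poses) + 1)
        placed = pose.apply(pcoords)
        if _min_dist(placed, rcoords) < clearance - 1e-6:
            continue
        poses.append(pose)
        if not _satisfies_constraints(placed, probe, receptor, cs):
            n_violate_constraints += 1
        if not _satisfies_register(placed, probe, receptor, reg):
            n_violate_register += 1

    manifest = {"n": n, "seed": seed,
                "n_violate_constraints": n_violate_constraints,
                "n_violate_register": n_violate_register,
                "clearance": clearance}
    return poses, manifest


def _min_dist(a: np.ndarray, b: np.ndarray) -> float:
    from scipy.spatial import cKDTree
    return float(cKDTree(b).query(a, k=1)[0].min())


def _random_unit(rng: np.random.Generator) -> np.ndarray:
    v = rng.normal(size=3)
    return v / np.linalg.norm(v)


def _random_rotation(rng: np.random.Generator) -> np.ndarray:
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)],
    ])


def _satisfies_constraints(placed_probe: np.ndarray, probe: Structure,
                           receptor: Structure, cs: ConstraintSet) -> bool:
    for c in cs:
        pm = (probe.chain_id == c.probe_chain) & \
             (probe.residue_number == c.residue_number)
        tm = receptor.chain_id == c.target
        d = np.linalg.norm(placed_probe[pm][:, None, :] -
                           receptor.positions[tm][None, :, :], axis=-1)
        if not d.min() < c.cutoff:
            return False
    return True


def _satisfies_register(placed_probe: np.ndarray, probe: Structure,
                        receptor: Structure, reg: RegisterFilterSpec) -> bool:
    loop = np.zeros(probe.n_atoms, dtype=bool)
    for chain, num in reg.loop_residues:
        loop |= (probe.chain_id == chain) & (probe.residue_number == num) & \
                probe.heavy_mask()
    centroid = placed_probe[loop].mean(axis=0)
    pm = receptor.chain_mask(reg.peptide_chain) & receptor.heavy_mask()
    idx = np.flatnonzero(pm)
    d = np.linalg.norm(receptor.positions[idx] - centroid, axis=1)
    nearest = int(receptor.residue_number[idx[np.argmin(d)]])
    return reg.register_map.get(nearest) in reg.allowed_positions


# --------------------------------------------------------------- trajectory
def make_trajectory(structure: Structure, n_frames: int,
                    bond_occupancy: float, noise_sigma: float = 0.3,
                    seed: int = 0,
                    bond: Optional[Dict] = None) -> Structure:
    """Multi-frame copy of ``structure``: base coordinates plus Gaussian noise,
    with a designated hydrogen bond enforced in exactly
    ``round(n_frames * bond_occupancy)`` frames and broken (>0.4 nm) in the
    rest.

    ``bond`` is a mapping with "donor", "hydrogen", "acceptor" entries of the
    form (chain, resnum, atom name); a benchmark's ``truth["hbond"]`` fits
    directly.
    """
    if not 0.0 <= bond_occupancy <= 1.0:
        raise ValueError("bond_occupancy must be in [0, 1]")
    if n_frames < 1:
        raise ValueError("need at least one frame")
    rng = np.random.default_rng(seed)
    base = structure.coords[0]
    frames = base[None] + rng.normal(0.0, noise_sigma,
                                     (n_frames, structure.n_atoms, 3))

    if bond is not None:
        di = _atom_index(structure, *bond["donor"])
        hi = _atom_index(structure, *bond["hydrogen"])
        ai = _atom_index(structure, *bond["acceptor"])
        n_present = int(round(n_frames * bond_occupancy))
        order = rng.permutation(n_frames)
        present = set(order[:n_present].tolist())
        direction = _unit(base[ai] - base[di])
        for f in range(n_frames):
            frames[f, di] = base[di]
            frames[f, hi] = base[di] + 1.0 * direction
            if f in present:
                frames[f, ai] = base[di] + 3.0 * direction
            else:
                frames[f, ai] = base[di] + 4.6 * direction
    return structure.with_coords(frames)


def _atom_index(structure: Structure, chain: str, resnum: int,
                name: str) -> int:
    idx = structure.residue_atoms(chain, int(resnum))
    for i in idx:
        if structure.name[i] == name:
            return int(i)
    raise KeyError(f"atom {name} of {chain}:{resnum} not found")
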