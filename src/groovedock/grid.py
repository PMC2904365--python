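"""FFT shape-complementarity rigid-body docking with a Coulombic binary filter.

The geometric stage follows the Katchalski-Katzir grid-correlation scheme: the
larger (static) molecule is digitized with surface cells scoring 1 and core
cells a negative penalty; the smaller (mobile) molecule scores 1 everywhere it
occupies. The correlation of the two grids over all translations — evaluated
with forward/inverse FFTs — rewards surface-surface contact and penalizes core
penetration. A deterministic Euler-angle sweep covers rotations. Retained
poses are screened with a distance-dependent-dielectric Coulomb sum; only
electrostatically attractive complexes survive.
"""
from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import List, Optional, Sequence, Tuple

import numpy as np
import scipy.fft
from scipy import ndimage

from .structure import Structure

__all__ = ["DockParams", "DockGrid", "Pose", "discretize", "correlate",
           "rotation_set", "dock", "electrostatic_screen", "apply_pose",
           "GridError", "COULOMB_CONSTANT"]

COULOMB_CONSTANT = 332.0637  # kcal/mol * A / e^2


class GridError(ValueError):
    pass


@dataclass(frozen=True)
class DockParams:
    """Docking configuration.

    ``grid_dim``/``resolution`` define the search lattice; ``surface_thickness``
    the depth of the surface layer; ``core_penalty`` the (negative) weight of
    static core cells; ``rotation_step`` the Euler sweep granularity in degrees.
    """
    grid_dim: int = 64
    resolution: float = 1.0          # A per cell
    surface_thickness: float = 2.0   # A (covers contact_inflation + digitization slop)
    core_penalty: float = -30.0
    rotation_step: float = 15.0      # degrees
    n_poses_kept: int = 10000
    translations_per_rotation: int = 3
    electrostatic_filter: bool = True
    pad: bool = True                 # zero-pad so the mobile never wraps
    # contact-permissive envelope: the static occupancy radii are inflated by
    # this margin (A) during docking, so surfaces in van-der-Waals contact
    # share grid cells without requiring physical interpenetration
    contact_inflation: float = 1.2

    def __post_init__(self):
        if self.grid_dim <= 0 or self.resolution <= 0:
            raise ValueError("grid_dim and resolution must be positive")
        if self.core_penalty >= 0:
            raise ValueError("core_penalty must be negative")
        if self.n_poses_kept < 1:
            raise ValueError("n_poses_kept must be >= 1")


@dataclass
class DockGrid:
    values: np.ndarray          # (N, N, N)
    origin: np.ndarray          # Cartesian position of cell (0,0,0) center
    resolution: float
    role: str                   # "static" | "mobile"

    @property
    def n(self) -> int:
        return self.values.shape[0]


@dataclass
class Pose:
    """Rigid placement of the mobile structure: x' = rotation @ x + translation."""
    rotation: np.ndarray
    translation: np.ndarray
    shape_score: int = 0
    elec_energy: Optional[float] = None
    rank: int = 0
    pose_id: int = 0
    rotation_index: int = 0

    def apply(self, coords: np.ndarray) -> np.ndarray:
        return coords @ self.rotation.T + self.translation


def apply_pose(structure: Structure, pose: Pose) -> Structure:
    return structure.transformed(pose.rotation, pose.translation)


# ---------------------------------------------------------------- digitization
def _occupancy(coords: np.ndarray, radii: np.ndarray, n: int, origin: np.ndarray,
               resolution: float) -> np.ndarray:
    """Boolean occupancy: a cell is occupied iff its center is within some
    atom's radius."""
    occ = np.zeros((n, n, n), dtype=bool)
    # group atoms by radius so the lattice-offset stencil is built once each
    for r in np.unique(radii):
        m = int(np.ceil(r / resolution)) + 1   # covers fractional placement
        rng = np.arange(-m, m + 1)
        ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
        offsets = np.stack([ox, oy, oz], axis=-1).reshape(-1, 3)
        sel = radii == r
        centers = (coords[sel] - origin) / resolution
        base = np.rint(centers).astype(int)
        # candidate cells = stencil around the nearest cell; exact test below
        cells = base[:, None, :] + offsets[None, :, :]
        cell_centers = cells * resolution + origin
        d2 = ((cell_centers - coords[sel][:, None, :]) ** 2).sum(axis=-1)
        hit = cells[d2 <= r * r]
        if len(hit) == 0:
            continue
        if hit.min() < 0 or hit.max() >= n:
            raise GridError("structure exceeds the grid extent; increase "
                            "grid_dim or resolution")
        occ[hit[:, 0], hit[:, 1], hit[:, 2]] = True
    return occ


def _surface_core(occ: np.ndarray, surface_thickness: float,
                  resolution: float) -> Tuple[np.ndarray, np.ndarray]:
    """Split occupied cells into surface (within surface_thickness of an empty
    cell) and core."""
    m = max(1, int(np.floor(surface_thickness / resolution)))
    rng = np.arange(-m, m + 1)
    ox, oy, oz = np.meshgrid(rng, rng, rng, indexing="ij")
    dist = np.sqrt(ox ** 2 + oy ** 2 + oz ** 2) * resolution
    selem = dist <= surface_thickness
    core = ndimage.binary_erosion(occ, structure=selem, border_value=0)
    surface = occ & ~core
    return surface, core


def discretize(structure: Structure, params: DockParams, role: str,
               center: Optional[np.ndarray] = None,
               grid_dim: Optional[int] = None) -> DockGrid:
    """Digitize a structure onto an N^3 lattice.

    Static grids carry 1 on surface cells and ``core_penalty`` on core cells;
    mobile grids carry 1 on every occupied cell. ``center`` (default: the
    structure's bounding-box center) is mapped to the grid center.
    """
    if structure.n_atoms == 0:
        raise GridError("empty structure")
    if role not in ("static", "mobile"):
        raise ValueError(f"unknown grid role {role!r}")
    n = grid_dim if grid_dim is not None else params.grid_dim
    coords = structure.positions
    radii = structure.radius
    if center is None:
        center = 0.5 * (coords.min(axis=0) + coords.max(axis=0))
    origin = np.asarray(center, dtype=float) - params.resolution * (n - 1) / 2.0
    occ = _occupancy(coords, radii, n, origin, params.resolution)
    values = np.zeros((n, n, n), dtype=np.float64)
    if role == "static":
        surface, core = _surface_core(occ, params.surface_thickness,
                                      params.resolution)
        values[surface] = 1.0
        values[core] = params.core_penalty
    else:
        # mobile surface and core cells both score 1; no split needed
        values[occ] = 1.0
    return DockGrid(values, origin, params.resolution, role)


# ----------------------------------------------------------------- correlation
def correlate(static: DockGrid, mobile: DockGrid) -> np.ndarray:
    """Correlation score(t) = sum_c static(c) * mobile(c - t) for every cyclic
    lattice translation t, via FFT. Scores are rounded to the nearest integer
    (grid values are integers by construction)."""
    if static.n != mobile.n or static.resolution != mobile.resolution:
        raise GridError("incompatible grids: N or resolution differ")
    fs = scipy.fft.rfftn(static.values)
    fm = scipy.fft.rfftn(mobile.values)
    corr = scipy.fft.irfftn(fs * np.conj(fm), s=static.values.shape)
    return np.rint(corr).astype(np.int64)


# ------------------------------------------------------------------- rotations
def rotation_set(step_deg: float) -> np.ndarray:
    """Deterministic z-y-z Euler sweep with the given step, de-duplicated.

    The identity rotation is always first; ordering is the sweep order, which
    fixes tie-breaking downstream.
    """
    if step_deg <= 0:
        raise ValueError("rotation step must be positive")
    alphas = np.arange(0.0, 360.0, step_deg)
    betas = np.arange(0.0, 180.0 + 1e-9, step_deg)
    gammas = np.arange(0.0, 360.0, step_deg)
    seen = set()
    mats = []
    for b in betas:
        for a in alphas:
            for g in gammas:
                R = _euler_zyz(np.radians(a), np.radians(b), np.radians(g))
                key = (np.round(R, 6) + 0.0).tobytes()
                if key in seen:
                    continue
                seen.add(key)
                mats.append(R)
    return np.stack(mats)


def _euler_zyz(a: float, b: float, g: float) -> np.ndarray:
    ca, sa = np.cos(a), np.sin(a)
    cb, sb = np.cos(b), np.sin(b)
    cg, sg = np.cos(g), np.sin(g)
    Rz1 = np.array([[ca, -sa, 0], [sa, ca, 0], [0, 0, 1]])
    Ry = np.array([[cb, 0, sb], [0, 1, 0], [-sb, 0, cb]])
    Rz2 = np.array([[cg, -sg, 0], [sg, cg, 0], [0, 0, 1]])
    return Rz1 @ Ry @ Rz2


# ------------------------------------------------------------------------ dock
def _structure_diameter(s: Structure) -> float:
    c = s.positions
    lo, hi = c.min(axis=0), c.max(axis=0)
    return float(np.linalg.norm(hi - lo) + 2 * s.radius.max())


def _signed_cells(t: np.ndarray, n: int) -> np.ndarray:
    t = t.astype(int)
    return np.where(t > n // 2, t - n, t)


def dock(static: Structure, mobile: Structure, params: DockParams,
         seed: int = 0) -> List[Pose]:
    """Exhaustive rotation/translation search; returns the best poses by shape
    score (descending), ties broken by rotation index then translation.

    The search itself is deterministic; ``seed`` is accepted for interface
    symmetry with the stochastic stages and does not change the result.
    """
    if static.n_atoms == 0 or mobile.n_atoms == 0:
        raise GridError("empty structure")
    if mobile.n_atoms > static.n_atoms:
        import warnings
        warnings.warn("mobile structure is larger than static; swapping roles")
        static, mobile = mobile, static

    res = params.resolution
    n_work = params.grid_dim
    if params.pad:
        margin = int(np.ceil(_structure_diameter(mobile) / res)) + 2
        n_work = scipy.fft.next_fast_len(params.grid_dim + margin)

    static_center = 0.5 * (static.positions.min(axis=0) +
                           static.positions.max(axis=0))
    static_env = static
    if params.contact_inflation > 0:
        static_env = static.copy()
        static_env.radius = static_env.radius + params.contact_inflation
    sgrid = discretize(static_env, params, "static", center=static_center,
                       grid_dim=n_work)
    # float32 FFTs: grid sums are small integers, far inside float32's exact
    # range, and the transform pair is ~2x faster
    fs = scipy.fft.rfftn(sgrid.values.astype(np.float32))

    mob_coords = mobile.positions
    mob_centroid = mob_coords.mean(axis=0)
    local = mob_coords - mob_centroid

    rotations = rotation_set(params.rotation_step)
    k = params.translations_per_rotation
    candidates = []  # (score, rot_index, tz, ty, tx... ) kept per rotation

    grid_center_cart = sgrid.origin + res * (n_work - 1) / 2.0
    for ri, R in enumerate(rotations):
        rot = local @ R.T + grid_center_cart
        rot_struct = mobile.with_coords(rot)
        mgrid = discretize(rot_struct, params, "mobile",
                           center=grid_center_cart, grid_dim=n_work)
        fm = scipy.fft.rfftn(mgrid.values.astype(np.float32))
        corr = scipy.fft.irfftn(fs * np.conj(fm), s=sgrid.values.shape)
        flat = corr.reshape(-1)
        if len(flat) > k:
            top = np.argpartition(flat, -k)[-k:]
        else:
            top = np.arange(len(flat))
        for idx in top:
            score = int(np.rint(flat[idx]))
            if score <= 0:
                continue
            t = np.unravel_index(idx, corr.shape)
            candidates.append((score, ri, int(t[0]), int(t[1]), int(t[2])))

    # sort: score desc, then rotation index asc, then lexicographic translation
    candidates.sort(key=lambda c: (-c[0], c[1], c[2], c[3], c[4]))
    poses = []
    for pid, (score, ri, tx, ty, tz) in enumerate(
            candidates[: params.n_poses_kept], start=1):
        t_cells = _signed_cells(np.array([tx, ty, tz]), n_work)
        shift = t_cells * res
        R = rotations[ri]
        # placed coords: R (x - c_m) + grid_center + shift  =>  R x + t_abs
        t_abs = grid_center_cart + shift - R @ mob_centroid
        poses.append(Pose(rotation=R.copy(), translation=t_abs,
                          shape_score=score, rank=pid, pose_id=pid,
                          rotation_index=ri))
    return poses


# ------------------------------------------------------------- electrostatics
def coulomb_energy(coords_a: np.ndarray, charges_a: np.ndarray,
                   coords_b: np.ndarray, charges_b: np.ndarray,
                   dielectric_factor: float = 4.0) -> float:
    """Pairwise Coulomb sum with distance-dependent dielectric eps(r) = f * r:
    E = sum 332.0637 q_i q_j / (f r^2). Only charged atoms contribute."""
    ia = np.flatnonzero(charges_a != 0)
    ib = np.flatnonzero(charges_b != 0)
    if len(ia) == 0 or len(ib) == 0:
        return 0.0
    d = np.linalg.norm(coords_a[ia][:, None, :] - coords_b[ib][None, :, :],
                       axis=-1)
    qq = np.outer(charges_a[ia], charges_b[ib])
    with np.errstate(divide="ignore"):
        e = COULOMB_CONSTANT * qq / (dielectric_factor * d * d)
    return float(e.sum())


def electrostatic_screen(poses: Sequence[Pose], static: Structure,
                         mobile: Structure,
                         dielectric_factor: float = 4.0) -> List[Pose]:
    """Binary Coulombic filter: compute each pose's electrostatic energy and
    keep only attractive (elec_energy <= 0) complexes, re-ranking survivors."""
    sc, sq = static.positions, static.charge
    mc, mq = mobile.positions, mobile.charge
    kept = []
    for pose in poses:
        e = coulomb_energy(sc, sq, pose.apply(mc), mq, dielectric_factor)
        pose = replace(pose, elec_energy=e)
        if e <= 0.0:
            kept.append(pose)
    for i, p in enumerate(kept, start=1):
        p.rank = i
    return kept
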