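"""Grid digitization, FFT correlation against direct summation, docking."""
import numpy as np
import pytest

from groovedock import (DockParams, Pose, correlate, discretize, dock,
                        electrostatic_screen, rotation_set)
from groovedock.grid import DockGrid, GridError, coulomb_energy
from groovedock.structure import Structure


def _point_structure(coords, radii, charges=None):
    n = len(coords)
    charges = np.zeros(n) if charges is None else np.asarray(charges, float)
    return Structure(
        serial=np.arange(1, n + 1), name=["CA"] * n, residue_name=["GLY"] * n,
        residue_number=np.arange(1, n + 1), insertion_code=[""] * n,
        chain_id=["X"] * n, element=["C"] * n, coords=np.asarray(coords, float),
        radius=np.asarray(radii, float), charge=charges,
        eps=np.full(n, 0.1), rmin_half=np.full(n, 2.0))


def _brute_force_cells(center, radius, n, origin, res):
    count = 0
    for i in range(n):
        for j in range(n):
            for k in range(n):
                c = origin + res * np.array([i, j, k])
                if np.linalg.norm(c - center) <= radius:
                    count += 1
    return count


def test_discretize_single_atom_matches_lattice_enumeration():
    params = DockParams(grid_dim=16, resolution=1.0)
    s = _point_structure([[0.3, -0.2, 0.1]], [1.7])
    g = discretize(s, params, "mobile")
    occupied = int((g.values > 0).sum())
    expected = _brute_force_cells(np.array([0.3, -0.2, 0.1]), 1.7,
                                  16, g.origin, 1.0)
    assert occupied == expected


def test_discretize_additivity_for_distant_atoms():
    params = DockParams(grid_dim=40, resolution=1.0)
    both = _point_structure([[-10, 0, 0], [10, 0, 0]], [1.7, 1.7])
    g = discretize(both, params, "mobile")
    total = int((g.values > 0).sum())
    singles = 0
    for pos in ([-10, 0, 0], [10, 0, 0]):
        s1 = _point_structure([pos], [1.7])
        g1 = discretize(s1, params, "mobile", center=g.origin +
                        params.resolution * (g.n - 1) / 2.0)
        singles += int((g1.values > 0).sum())
    assert total == singles


def test_discretize_volume_scaling_with_resolution():
    s = _point_structure([[0.0, 0.0, 0.0]], [1.7])
    c1 = int((discretize(s, DockParams(grid_dim=25, resolution=1.0),
                         "mobile").values > 0).sum())
    c2 = int((discretize(s, DockParams(grid_dim=50, resolution=0.5),
                         "mobile").values > 0).sum())
    assert c2 / c1 == pytest.approx(8.0, rel=0.15)


def test_discretize_overflow_and_empty_errors():
    params = DockParams(grid_dim=8, resolution=1.0)
    big = _point_structure([[0, 0, 0], [40, 0, 0]], [1.7, 1.7])
    with pytest.raises(GridError):
        discretize(big, params, "mobile")


def test_static_grid_has_surface_and_core(receptor):
    params = DockParams(grid_dim=64, resolution=1.0)
    g = discretize(receptor, params, "static")
    vals = np.unique(g.values)
    assert set(vals) <= {params.core_penalty, 0.0, 1.0}
    assert (g.values == 1.0).any()
    assert (g.values == params.core_penalty).any()


def _direct_correlation(a, b):
    n = a.shape[0]
    out = np.zeros_like(a)
    nz = np.argwhere(b != 0)
    for t in np.ndindex(a.shape):
        acc = 0.0
        for c in nz:
            acc += a[tuple((c + t) % n)] * b[tuple(c)]
        out[t] = acc
    return out


def test_fft_correlation_equals_direct_summation(rng):
    """Integer-exact agreement between the FFT correlation and a triple-loop
    direct summation on small random grids."""
    for trial in range(6):
        n = int(rng.integers(4, 9))
        a = np.zeros((n, n, n))
        b = np.zeros((n, n, n))
        idx = rng.integers(0, n, size=(10, 3))
        a[idx[:5, 0], idx[:5, 1], idx[:5, 2]] = rng.choice([1.0, -15.0], 5)
        b[idx[5:, 0], idx[5:, 1], idx[5:, 2]] = 1.0
        ga = DockGrid(a, np.zeros(3), 1.0, "static")
        gb = DockGrid(b, np.zeros(3), 1.0, "mobile")
        scores = correlate(ga, gb)
        direct = _direct_correlation(a, b)
        assert np.array_equal(scores, np.rint(direct).astype(np.int64))


def test_correlation_trivial_cases():
    n = 8
    zero = DockGrid(np.zeros((n, n, n)), np.zeros(3), 1.0, "mobile")
    delta = np.zeros((n, n, n))
    delta[0, 0, 0] = 1.0
    gd_ = DockGrid(delta, np.zeros(3), 1.0, "static")
    assert (correlate(gd_, zero) == 0).all()
    out = correlate(gd_, DockGrid(delta.copy(), np.zeros(3), 1.0, "mobile"))
    assert out[0, 0, 0] == 1
    assert out.sum() == 1


def test_correlate_incompatible_grids():
    a = DockGrid(np.zeros((4, 4, 4)), np.zeros(3), 1.0, "static")
    b = DockGrid(np.zeros((8, 8, 8)), np.zeros(3), 1.0, "mobile")
    with pytest.raises(GridError):
        correlate(a, b)


def test_rotation_set_starts_with_identity():
    rots = rotation_set(30.0)
    assert np.allclose(rots[0], np.eye(3))
    # all orthonormal, det +1
    for R in rots[:: max(1, len(rots) // 20)]:
        assert np.allclose(R @ R.T, np.eye(3), atol=1e-9)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)


# ----------------------------------------------------------------- dock runs
COARSE = dict(grid_dim=48, resolution=1.5, rotation_step=60.0, n_poses_kept=10)


def test_dock_returns_sorted_unique_ranks(receptor, probe):
    poses = dock(receptor, probe, DockParams(**COARSE), seed=0)
    assert len(poses) == 10
    scores = [p.shape_score for p in poses]
    assert scores == sorted(scores, reverse=True)
    assert all(s > 0 for s in scores)
    assert [p.rank for p in poses] == list(range(1, 11))


def test_dock_deterministic(receptor, probe):
    a = dock(receptor, probe, DockParams(**COARSE), seed=3)
    b = dock(receptor, probe, DockParams(**COARSE), seed=3)
    for pa, pb in zip(a, b):
        assert pa.shape_score == pb.shape_score
        assert np.array_equal(pa.rotation, pb.rotation)
        assert np.array_equal(pa.translation, pb.translation)


def test_dock_frame_invariance(receptor, probe):
    """Pre-translating the mobile leaves the materialized poses unchanged
    within one lattice cell."""
    params = DockParams(**COARSE)
    a = dock(receptor, probe, params, seed=0)
    shifted = probe.transformed(np.eye(3), np.array([11.0, -7.0, 5.0]))
    b = dock(receptor, shifted, params, seed=0)
    pa = a[0].apply(probe.positions)
    pb = b[0].apply(shifted.positions)
    assert np.linalg.norm(pa - pb, axis=1).max() <= params.resolution + 1e-6


# ------------------------------------------------------------ electrostatics
def test_screen_keeps_attractive_removes_repulsive():
    static = _point_structure([[0, 0, 0]], [1.7], charges=[1.0])
    plus = _point_structure([[5, 0, 0]], [1.7], charges=[1.0])
    minus = _point_structure([[5, 0, 0]], [1.7], charges=[-1.0])
    pose = Pose(rotation=np.eye(3), translation=np.zeros(3), pose_id=1, rank=1)
    kept = electrostatic_screen([pose], static, minus)
    assert len(kept) == 1 and kept[0].elec_energy < 0
    kept = electrostatic_screen([pose], static, plus)
    assert kept == []


def test_screen_matches_direct_coulomb_oracle(receptor, probe, rng):
    poses = []
    for i in range(20):
        q = rng.normal(size=4)
        q /= np.linalg.norm(q)
        w, x, y, z = q
        R = np.array([
            [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
            [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
            [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])
        poses.append(Pose(rotation=R, translation=rng.normal(size=3) * 20,
                          pose_id=i + 1, rank=i + 1))
    kept = electrostatic_screen(poses, receptor, probe)
    kept_ids = {p.pose_id for p in kept}
    # direct per-pair oracle
    expected = set()
    CONST = 332.0637
    for p in poses:
        placed = probe.positions @ p.rotation.T + p.translation
        e = 0.0
        for i in np.flatnonzero(receptor.charge != 0):
            for j in np.flatnonzero(probe.charge != 0):
                r = np.linalg.norm(receptor.positions[i] - placed[j])
                e += CONST * receptor.charge[i] * probe.charge[j] / (4.0 * r * r)
        if e <= 0:
            expected.add(p.pose_id)
    assert kept_ids == expected
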