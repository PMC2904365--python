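"""ASA, interaction energy, contacts, hydrogen bonds, trajectory statistics."""
import numpy as np
import pytest

from groovedock import (EnergyParams, HBondCriteria, asa, frame_rmsd,
                        frame_rmsf, hbonds, interaction_energy, interface_asa,
                        make_trajectory, vdw_contacts)
from groovedock.structure import Structure


def _atoms(coords, radii=None, names=None, resnames=None, chains=None,
           charges=None, eps=None, rmin=None, resnums=None, elements=None,
           donors=None, acceptors=None):
    n = len(coords)
    return Structure(
        serial=np.arange(1, n + 1),
        name=names or ["CA"] * n,
        residue_name=resnames or ["GLY"] * n,
        residue_number=resnums if resnums is not None else np.arange(1, n + 1),
        insertion_code=[""] * n,
        chain_id=chains or ["X"] * n,
        element=elements or ["C"] * n,
        coords=np.asarray(coords, float),
        radius=np.asarray(radii if radii is not None else [1.7] * n, float),
        charge=np.asarray(charges if charges is not None else [0.0] * n, float),
        eps=np.asarray(eps if eps is not None else [0.1] * n, float),
        rmin_half=np.asarray(rmin if rmin is not None else [2.0] * n, float),
        donor=np.asarray(donors if donors is not None else [False] * n),
        acceptor=np.asarray(acceptors if acceptors is not None else [False] * n),
    )


# ------------------------------------------------------------------------ ASA
def test_asa_isolated_atom_analytic():
    s = _atoms([[0.0, 0.0, 0.0]], radii=[1.7])
    area = asa(s, probe_radius=1.4, n_points=960)[0]
    exact = 4.0 * np.pi * 3.1 ** 2
    assert area == pytest.approx(exact, rel=0.005)


def test_asa_tangent_spheres_unperturbed():
    d = 2 * (1.7 + 1.4)
    s = _atoms([[0, 0, 0], [d, 0, 0]], radii=[1.7, 1.7])
    areas = asa(s, probe_radius=1.4, n_points=960)
    exact = 4.0 * np.pi * 3.1 ** 2
    assert areas == pytest.approx([exact, exact], rel=0.005)


@pytest.mark.parametrize("d", [2.0, 3.5, 5.0])
def test_asa_two_overlapping_spheres_closed_form(d):
    """Total area of two equal intersecting spheres: each loses a spherical
    cap of height h = R - d/2 (area 2 pi R h)."""
    R = 1.7 + 1.4
    s = _atoms([[0, 0, 0], [d, 0, 0]], radii=[1.7, 1.7])
    total = asa(s, probe_radius=1.4, n_points=4000).sum()
    cap = 2.0 * np.pi * R * (R - d / 2.0)
    exact = 2 * (4.0 * np.pi * R ** 2 - cap)
    assert total == pytest.approx(exact, rel=0.01)


def test_asa_requires_radii_and_enough_points():
    s = _atoms([[0, 0, 0]], radii=[0.0])
    with pytest.raises(ValueError):
        asa(s)
    with pytest.raises(ValueError):
        asa(_atoms([[0, 0, 0]]), n_points=50)


def test_asa_self_convergence(rng):
    coords = rng.normal(size=(50, 3)) * 4.0
    s = _atoms(coords, radii=[1.7] * 50)
    a1 = asa(s, n_points=4000).sum()
    a2 = asa(s, n_points=16000).sum()
    assert abs(a1 - a2) / a2 < 0.01


def test_interface_asa_separated_parts_zero():
    a = _atoms([[0, 0, 0], [3, 0, 0]])
    b = _atoms([[100, 0, 0], [103, 0, 0]], chains=["Y", "Y"])
    assert interface_asa(a, b) == pytest.approx(0.0, abs=0.1)


def test_interface_asa_rigid_invariance(benchmark):
    rec = benchmark.receptor.subset_chains("P")
    probe = benchmark.probe
    base = interface_asa(rec, probe, n_points=2000)
    assert base > 0
    theta = 0.7
    R = np.array([[np.cos(theta), -np.sin(theta), 0],
                  [np.sin(theta), np.cos(theta), 0], [0, 0, 1]])
    t = np.array([5.0, -3.0, 8.0])
    base_rot = interface_asa(rec.transformed(R, t), probe.transformed(R, t),
                             n_points=2000)
    assert base_rot == pytest.approx(base, rel=0.005)


# --------------------------------------------------------------------- energy
def test_lj_pair_at_rmin_is_minus_eps():
    a = _atoms([[0, 0, 0]], eps=[0.12], rmin=[2.0])
    b = _atoms([[4.0, 0, 0]], eps=[0.12], rmin=[2.0], chains=["Y"])
    e = interaction_energy(a, b, EnergyParams(cutoff=12.0))
    assert e == pytest.approx(-0.12, abs=1e-12)


def test_energy_zero_beyond_cutoff():
    a = _atoms([[0, 0, 0]], charges=[1.0])
    b = _atoms([[30.0, 0, 0]], charges=[-1.0], chains=["Y"])
    assert interaction_energy(a, b, EnergyParams(cutoff=12.0)) == 0.0


def test_energy_matches_direct_double_loop(rng):
    ca = rng.normal(size=(20, 3)) * 4.0
    cb = rng.normal(size=(20, 3)) * 4.0 + np.array([6.0, 0, 0])
    qa, qb = rng.normal(size=20) * 0.3, rng.normal(size=20) * 0.3
    ea, eb = rng.uniform(0.05, 0.3, 20), rng.uniform(0.05, 0.3, 20)
    ra, rb = rng.uniform(1.6, 2.1, 20), rng.uniform(1.6, 2.1, 20)
    A = _atoms(ca, charges=qa, eps=ea, rmin=ra)
    B = _atoms(cb, charges=qb, eps=eb, rmin=rb, chains=["Y"] * 20)
    params = EnergyParams(cutoff=10.0, dielectric_factor=4.0)
    expected = 0.0
    for i in range(20):
        for j in range(20):
            r = np.linalg.norm(ca[i] - cb[j])
            if r > params.cutoff:
                continue
            eps_ij = np.sqrt(ea[i] * eb[j])
            rmin_ij = ra[i] + rb[j]
            expected += eps_ij * ((rmin_ij / r) ** 12 - 2 * (rmin_ij / r) ** 6)
            expected += 332.0637 * qa[i] * qb[j] / (4.0 * r * r)
    assert interaction_energy(A, B, params) == pytest.approx(expected,
                                                             abs=1e-8)


def test_energy_decays_with_separation(benchmark):
    rec, probe = benchmark.receptor, benchmark.probe
    params = EnergyParams()
    vals = []
    for dz in (0.0, 5.0, 15.0, 40.0):
        vals.append(abs(interaction_energy(
            rec, probe.transformed(np.eye(3), np.array([0, 0, dz])), params)))
    assert vals[0] > vals[1] > vals[2] >= vals[3] == 0.0


# ------------------------------------------------------------------- contacts
def test_vdw_contacts_boundary():
    a = _atoms([[0, 0, 0]])
    near = _atoms([[3.9, 0, 0]], chains=["Y"])
    far = _atoms([[4.1, 0, 0]], chains=["Y"])
    assert len(vdw_contacts(a, near, 4.0)) == 1
    assert vdw_contacts(a, far, 4.0).empty


def test_vdw_contacts_match_exhaustive_enumeration(benchmark):
    rec, probe = benchmark.receptor, benchmark.probe
    table = vdw_contacts(rec, probe, 4.0)
    got = {(r.chain_a, r.resnum_a, r.chain_b, r.resnum_b):
           pytest.approx(r.min_distance, abs=1e-9)
           for r in table.itertuples()}
    ha = np.flatnonzero(rec.heavy_mask())
    hb = np.flatnonzero(probe.heavy_mask())
    expected = {}
    d = np.linalg.norm(rec.positions[ha][:, None] -
                       probe.positions[hb][None, :], axis=-1)
    for i, j in zip(*np.nonzero(d <= 4.0)):
        key = (rec.chain_id[ha[i]], int(rec.residue_number[ha[i]]),
               probe.chain_id[hb[j]], int(probe.residue_number[hb[j]]))
        expected[key] = min(expected.get(key, np.inf), float(d[i, j]))
    assert set(got) == set(expected)
    for k in expected:
        assert got[k] == expected[k]
    assert (table.min_distance <= 4.0).all()


# -------------------------------------------------------------- hydrogen bonds
def _hbond_system(da_dist, angle_deg):
    """Donor O (chain X) with H, acceptor O (chain Y) at the given geometry."""
    h_dir = np.array([np.cos(np.radians(angle_deg)),
                      np.sin(np.radians(angle_deg)), 0.0])
    coords = [[0, 0, 0], list(1.0 * h_dir), [da_dist, 0.0, 0.0]]
    return _atoms(coords, radii=[1.4, 1.0, 1.4],
                  names=["OG", "HG", "OG"], resnames=["SER"] * 3,
                  chains=["X", "X", "Y"], elements=["O", "H", "O"],
                  resnums=[1, 1, 2],
                  donors=[True, False, False],
                  acceptors=[False, False, True])


def test_hbond_geometric_criteria():
    ok = hbonds(_hbond_system(3.0, 5.0), (["X"], ["Y"]))
    assert len(ok) == 1 and ok.occupancy[0] == 100.0
    too_far = hbonds(_hbond_system(3.6, 5.0), (["X"], ["Y"]))
    assert too_far.empty
    too_bent = hbonds(_hbond_system(3.0, 45.0), (["X"], ["Y"]))
    assert too_bent.empty


def test_hbond_planted_occupancies(benchmark):
    from groovedock.structure import Structure as S
    from groovedock import apply_pose
    complex_ = S.concat([benchmark.receptor, benchmark.probe])
    bond = benchmark.truth["hbond"]
    for occ, nframes, expect in ((1.0, 10, 100.0), (0.0, 10, None),
                                 (0.6, 50, 60.0)):
        traj = make_trajectory(complex_, nframes, occ, noise_sigma=0.25,
                               seed=3, bond=bond)
        table = hbonds(traj, (["A", "B", "P", "M"], ["D"]))
        rows = table[(table.donor_resnum == bond["donor"][1]) &
                     (table.donor_atom == bond["donor"][2]) &
                     (table.acceptor_resnum == bond["acceptor"][1]) &
                     (table.acceptor_atom == bond["acceptor"][2])]
        if expect is None:
            assert rows.empty
        else:
            assert len(rows) == 1
            assert rows.occupancy.iloc[0] == pytest.approx(expect, abs=1e-9)


def test_hbond_requires_frames(benchmark):
    s = benchmark.receptor
    with pytest.raises(ValueError):
        hbonds(s.with_coords(np.empty((0, s.n_atoms, 3))), (["A"], ["P"]))


# ------------------------------------------------------------------ RMSD/RMSF
def test_frame_rmsd_identical_and_rotated(benchmark, rng):
    base = benchmark.probe.positions
    theta = 0.9
    R = np.array([[np.cos(theta), 0, np.sin(theta)], [0, 1, 0],
                  [-np.sin(theta), 0, np.cos(theta)]])
    frames = np.stack([base, base, base @ R.T + np.array([4.0, 1.0, -2.0])])
    s = benchmark.probe.with_coords(frames)
    rmsd = frame_rmsd(s, reference_frame=0)
    assert rmsd == pytest.approx([0.0, 0.0, 0.0], abs=1e-8)


def test_frame_rmsf_oscillating_atom(benchmark, rng):
    base = benchmark.probe.positions.copy()
    n_frames, d = 40, 0.8
    frames = np.tile(base, (n_frames, 1, 1))
    frames[:, 0, 0] += d * np.where(np.arange(n_frames) % 2 == 0, 1.0, -1.0)
    s = benchmark.probe.with_coords(frames)
    rmsf = frame_rmsf(s)
    assert rmsf[0] == pytest.approx(d, rel=0.05)
    assert np.median(rmsf[1:]) < 0.05 * d


def test_empty_selection_raises(benchmark):
    with pytest.raises(ValueError):
        frame_rmsd(benchmark.probe, selection=np.array([], dtype=int))
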