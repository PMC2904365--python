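"""Structure container, PDB round-trips, and Kabsch superposition."""
import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from groovedock import (Structure, StructureError, load_structure,
                        save_structure, superpose, kabsch_rmsd)
from groovedock.params import load_default_params

PDB_TWO_ATOMS = """\
ATOM      1  N   ALA A   1      11.104   6.134  -6.504  1.00  0.00           N
ATOM      2  CA  ALA A   1      11.639   6.071  -5.147  1.00  0.00           C
END
"""

PDB_THREE_MODELS = """\
MODEL        1
ATOM      1  N   GLY A   1       0.000   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.458   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        2
ATOM      1  N   GLY A   1       0.100   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.558   0.000   0.000  1.00  0.00           C
ENDMDL
MODEL        3
ATOM      1  N   GLY A   1       0.200   0.000   0.000  1.00  0.00           N
ATOM      2  CA  GLY A   1       1.658   0.000   0.000  1.00  0.00           C
ENDMDL
END
"""


def test_load_counts_atoms_and_frames(tmp_path):
    f = tmp_path / "two.pdb"
    f.write_text(PDB_TWO_ATOMS)
    s = load_structure(f)
    assert s.n_atoms == 2
    assert s.n_frames == 1
    assert s.residue_name[0] == "ALA"
    assert (s.radius > 0).all()

    f3 = tmp_path / "three.pdb"
    f3.write_text(PDB_THREE_MODELS)
    s3 = load_structure(f3)
    assert s3.n_atoms == 2
    assert s3.n_frames == 3
    assert s3.coords[2, 0, 0] == pytest.approx(0.2, abs=1e-3)


def test_load_missing_file_raises(tmp_path):
    with pytest.raises(StructureError):
        load_structure(tmp_path / "nope.pdb")


def test_load_empty_structure_raises(tmp_path):
    f = tmp_path / "empty.pdb"
    f.write_text("REMARK nothing here\nEND\n")
    with pytest.raises(StructureError):
        load_structure(f)


def test_roundtrip_preserves_identities_and_coordinates(tmp_path, receptor):
    out = tmp_path / "receptor.pdb"
    save_structure(receptor, out)
    back = load_structure(out)
    assert back.n_atoms == receptor.n_atoms
    assert list(back.name) == list(receptor.name)
    assert list(back.chain_id) == list(receptor.chain_id)
    assert list(back.residue_number) == list(receptor.residue_number)
    # PDB precision is 0.001 A
    assert np.allclose(back.coords, receptor.coords, atol=1.5e-3)


def test_roundtrip_multiframe(tmp_path, receptor):
    multi = receptor.with_coords(
        np.stack([receptor.positions, receptor.positions + 0.25]))
    out = tmp_path / "multi.pdb"
    save_structure(multi, out)
    back = load_structure(out)
    assert back.n_frames == 2
    assert np.allclose(back.coords, multi.coords, atol=1.5e-3)
    # save -> load -> save is byte-stable in the coordinate fields
    out2 = tmp_path / "multi2.pdb"
    save_structure(back, out2)
    coords1 = [l for l in out.read_text().splitlines() if l.startswith("ATOM")]
    coords2 = [l for l in out2.read_text().splitlines() if l.startswith("ATOM")]
    assert [l[30:54] for l in coords1] == [l[30:54] for l in coords2]


def test_waters_skipped_by_default(tmp_path):
    f = tmp_path / "wat.pdb"
    f.write_text(
        "ATOM      1  CA  GLY A   1       0.000   0.000   0.000  1.00  0.00"
        "           C\n"
        "HETATM    2  O   HOH A 101       5.000   5.000   5.000  1.00  0.00"
        "           O\nEND\n")
    s = load_structure(f)
    assert s.n_atoms == 1


# ------------------------------------------------------------- superposition
def _quaternion_superpose(P, Q):
    """Independent quaternion-method (Horn) rigid superposition oracle."""
    P0 = P - P.mean(axis=0)
    Q0 = Q - Q.mean(axis=0)
    M = P0.T @ Q0
    Sxx, Sxy, Sxz = M[0]
    Syx, Syy, Syz = M[1]
    Szx, Szy, Szz = M[2]
    K = np.array([
        [Sxx + Syy + Szz, Syz - Szy, Szx - Sxz, Sxy - Syx],
        [Syz - Szy, Sxx - Syy - Szz, Sxy + Syx, Szx + Sxz],
        [Szx - Sxz, Sxy + Syx, -Sxx + Syy - Szz, Syz + Szy],
        [Sxy - Syx, Szx + Sxz, Syz + Szy, -Sxx - Syy + Szz]])
    w, v = np.linalg.eigh(K)
    q = v[:, -1]
    w0, x, y, z = q
    R = np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w0), 2 * (x * z + y * w0)],
        [2 * (x * y + z * w0), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w0)],
        [2 * (x * z - y * w0), 2 * (y * z + x * w0), 1 - 2 * (x * x + y * y)]])
    resid = (P0 @ R.T) - Q0
    return R, float(np.sqrt((resid ** 2).sum() / len(P)))


def _random_rotation(rng):
    q = rng.normal(size=4)
    q /= np.linalg.norm(q)
    w, x, y, z = q
    return np.array([
        [1 - 2 * (y * y + z * z), 2 * (x * y - z * w), 2 * (x * z + y * w)],
        [2 * (x * y + z * w), 1 - 2 * (x * x + z * z), 2 * (y * z - x * w)],
        [2 * (x * z - y * w), 2 * (y * z + x * w), 1 - 2 * (x * x + y * y)]])


def test_superpose_identity_and_rigid_invariance(rng):
    pts = rng.normal(size=(25, 3)) * 5.0
    assert superpose(pts, pts)[2] == pytest.approx(0.0, abs=1e-10)
    R = _random_rotation(rng)
    moved = pts @ R.T + np.array([3.0, -7.0, 11.0])
    assert superpose(moved, pts)[2] == pytest.approx(0.0, abs=1e-8)


def test_superpose_matches_quaternion_oracle(rng):
    for _ in range(10):
        P = rng.normal(size=(30, 3)) * 4.0
        Q = P @ _random_rotation(rng).T + rng.normal(size=3) \
            + rng.normal(size=(30, 3)) * 0.4
        R, t, rmsd = superpose(P, Q)
        _, rmsd_oracle = _quaternion_superpose(P, Q)
        assert rmsd == pytest.approx(rmsd_oracle, abs=1e-8)
        assert np.linalg.det(R) == pytest.approx(1.0, abs=1e-9)
        # the returned transform actually achieves the reported rmsd
        achieved = np.sqrt((((P @ R.T + t) - Q) ** 2).sum(axis=1).mean())
        assert achieved == pytest.approx(rmsd, abs=1e-9)


def test_superpose_known_perturbation(rng):
    """RMSD equals the closed form sqrt(mean |delta|^2) when the perturbation
    has zero mean and no net rotation (deltas along atom-specific axes)."""
    pts = rng.normal(size=(40, 3)) * 6.0
    R = _random_rotation(rng)
    t = rng.normal(size=3) * 10
    moved = pts @ R.T + t
    _, _, rmsd = superpose(pts, moved)
    assert rmsd == pytest.approx(0.0, abs=1e-8)


def test_superpose_errors(rng):
    with pytest.raises(ValueError):
        superpose(rng.normal(size=(4, 3)), rng.normal(size=(5, 3)))
    with pytest.raises(ValueError):
        superpose(rng.normal(size=(2, 3)), rng.normal(size=(2, 3)))


@settings(max_examples=25, deadline=None, derandomize=True)
@given(st.integers(min_value=0, max_value=10_000))
def test_rmsd_symmetric_and_rigidly_invariant(seed):
    rng = np.random.default_rng(seed)
    A = rng.normal(size=(12, 3)) * 3
    B = A + rng.normal(size=(12, 3)) * 0.5
    assert kabsch_rmsd(A, B) == pytest.approx(kabsch_rmsd(B, A), abs=1e-8)
    R = _random_rotation(rng)
    t = rng.normal(size=3) * 5
    assert kabsch_rmsd(A @ R.T + t, B @ R.T + t) == \
        pytest.approx(kabsch_rmsd(A, B), abs=1e-8)


def test_param_table_covers_standard_residues():
    table = load_default_params()
    assert len(table.residues()) == 20
    p = table.lookup("ARG", "NH1")
    assert p.charge == pytest.approx(0.5)
    assert table.lookup("XYZ", "C5'").radius > 0  # element fallback
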