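import numpy as np
import pytest
from Bio.SVDSuperimposer import SVDSuperimposer

from conftest import structure_from_coords
from tvp.errors import DegenerateFitError, FormatError
from tvp.structure import (
    Conformation,
    Selection,
    Trajectory,
    ca_rmsd,
    kabsch,
    read_structure,
    read_trajectory,
    superpose_trajectory,
    write_structure,
    write_trajectory,
)
from tvp.synthetic import BundleSpec, make_bundle_structure


def random_rigid(rng):
    """A uniform-ish random proper rotation plus translation."""
    A = rng.normal(size=(3, 3))
    Q, _ = np.linalg.qr(A)
    if np.linalg.det(Q) < 0:
        Q[:, 0] = -Q[:, 0]
    return Q, rng.normal(scale=20.0, size=3)


def test_minimal_single_residue_pdb(tmp_path):
    pdb = tmp_path / "one.pdb"
    pdb.write_text(
        "ATOM      1  CA  GLY A   1      11.104  13.207   2.100  1.00  0.00           C\n"
        "END\n"
    )
    s = read_structure(pdb)
    assert s.n_atoms == 1
    assert s.atoms[0].residue_number == 1
    assert s.atoms[0].xyz == pytest.approx((11.104, 13.207, 2.100))


def test_multi_model_file_uses_first_model(tmp_path, caplog):
    s = structure_from_coords([(0, 0, 0), (3.8, 0, 0), (7.6, 0, 0)])
    traj = Trajectory(s, np.stack([s.coords, s.coords + 5.0]))
    path = tmp_path / "two_models.pdb"
    write_trajectory(traj, path)
    with caplog.at_level("WARNING"):
        got = read_structure(path)
    assert got.n_atoms == 3
    assert np.allclose(got.coords, s.coords, atol=1e-3)
    assert any("MODEL" in r.message for r in caplog.records)


def test_structure_roundtrip_exact(tmp_path):
    s = make_bundle_structure(BundleSpec(n_helices=3, residues_per_helix=6))
    path = tmp_path / "bundle.pdb"
    write_structure(s, path)
    back = read_structure(path)
    assert [a.residue_number for a in back.atoms] == [a.residue_number for a in s.atoms]
    assert [a.residue_name for a in back.atoms] == [a.residue_name for a in s.atoms]
    assert np.abs(back.coords - s.coords).max() <= 1e-3


def test_duplicate_ca_rejected(tmp_path):
    s = structure_from_coords([(0, 0, 0), (3.8, 0, 0)])
    path = tmp_path / "dup.pdb"
    write_structure(s, path)
    # renumber residue 2 to 1: two CA records for the same residue
    path.write_text(path.read_text().replace("ALA A   2", "ALA A   1"))
    with pytest.raises(FormatError):
        read_structure(path)


def test_trajectory_roundtrip_and_frame_count(tmp_path, rng):
    s = make_bundle_structure(BundleSpec(n_helices=2, residues_per_helix=6))
    frames = s.coords + rng.normal(scale=0.5, size=(3, s.n_atoms, 3))
    traj = Trajectory(s, frames)
    path = tmp_path / "traj.pdb"
    write_trajectory(traj, path)
    back = read_trajectory(path, s)
    assert back.n_frames == 3
    assert np.abs(back.frames - frames).max() <= 1e-3


def test_trajectory_missing_atom_names_model_index(tmp_path):
    s = structure_from_coords([(0, 0, 0), (5, 0, 0), (9, 0, 0)])
    traj = Trajectory(s, np.stack([s.coords, s.coords]))
    path = tmp_path / "broken.pdb"
    write_trajectory(traj, path)
    lines = path.read_text().splitlines()
    # drop one ATOM line from the second model
    idx = max(i for i, l in enumerate(lines) if l.startswith("ATOM"))
    del lines[idx]
    path.write_text("\n".join(lines) + "\n")
    with pytest.raises(FormatError, match="model 2"):
        read_trajectory(path, s)


def test_superpose_recovers_rigidly_moved_frames(rng, small_bundle):
    sel = Selection(tuple(small_bundle.ca_residues()))
    frames = []
    for _ in range(4):
        R, t = random_rigid(rng)
        frames.append(small_bundle.coords @ R.T + t)
    traj = Trajectory(small_bundle, np.stack(frames))
    fitted = superpose_trajectory(traj, small_bundle, sel)
    for frame in fitted.frames:
        assert ca_rmsd(small_bundle, (small_bundle, frame), sel) <= 1e-6
    # idempotent
    again = superpose_trajectory(fitted, small_bundle, sel)
    assert np.allclose(again.frames, fitted.frames, atol=1e-9)


def test_superpose_preserves_internal_distances(rng, small_bundle):
    sel = Selection(tuple(small_bundle.ca_residues()[:6]))
    frames = small_bundle.coords + rng.normal(scale=1.0, size=(3, small_bundle.n_atoms, 3))
    traj = Trajectory(small_bundle, frames)
    fitted = superpose_trajectory(traj, small_bundle, sel)
    pairs = rng.integers(0, small_bundle.n_atoms, size=(100, 2))
    for f_in, f_out in zip(traj.frames, fitted.frames):
        d_in = np.linalg.norm(f_in[pairs[:, 0]] - f_in[pairs[:, 1]], axis=1)
        d_out = np.linalg.norm(f_out[pairs[:, 0]] - f_out[pairs[:, 1]], axis=1)
        assert np.abs(d_in - d_out).max() <= 1e-6


def test_superpose_needs_three_residues(small_bundle):
    sel = Selection(tuple(small_bundle.ca_residues()[:2]))
    traj = Trajectory(small_bundle, small_bundle.coords[None])
    with pytest.raises(DegenerateFitError):
        superpose_trajectory(traj, small_bundle, sel)


def test_rmsd_matches_independent_kabsch_oracle(rng):
    for _ in range(5):
        P = rng.normal(scale=10.0, size=(12, 3))
        Q = rng.normal(scale=10.0, size=(12, 3))
        R, t = kabsch(P, Q)
        ours = float(np.sqrt(((P @ R.T + t - Q) ** 2).sum(axis=1).mean()))
        sup = SVDSuperimposer()
        sup.set(Q, P)  # reference, mobile
        sup.run()
        assert ours == pytest.approx(sup.get_rms(), abs=1e-6)


def test_rmsd_symmetric_and_rigid_invariant(rng, small_bundle):
    sel = Selection(tuple(small_bundle.ca_residues()))
    other = small_bundle.with_coords(
        small_bundle.coords + rng.normal(scale=1.5, size=(small_bundle.n_atoms, 3))
    )
    d_ab = ca_rmsd(small_bundle, other, sel)
    assert d_ab == pytest.approx(ca_rmsd(other, small_bundle, sel), abs=1e-9)
    R, t = random_rigid(rng)
    moved = other.with_coords(other.coords @ R.T + t)
    assert ca_rmsd(small_bundle, moved, sel) == pytest.approx(d_ab, abs=1e-6)
    # identity and pure translation both give zero
    assert ca_rmsd(small_bundle, small_bundle, sel) <= 1e-9
    shifted = small_bundle.with_coords(small_bundle.coords + [1.0, -2.0, 3.0])
    assert ca_rmsd(small_bundle, shifted, sel) <= 1e-6


def test_conformation_label_attached(tmp_path, small_bundle):
    path = tmp_path / "s.pdb"
    write_structure(small_bundle, path)
    s = read_structure(path, Conformation.OF)
    assert s.conformation is Conformation.OF
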