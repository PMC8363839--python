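"""Trajectory I/O, leaflet assignment and periodic-boundary handling."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bilayerlab as bl
from tests.conftest import make_traj


# ----------------------------------------------------------------- CSV I/O

def test_csv_roundtrip_preserves_coordinates(tmp_path, rng):
    pos = rng.uniform(0, 10, (3, 7, 3))
    tags = np.array(["POPS-P"] * 3 + ["POPC-P"] * 3 + ["TFP"], dtype=object)
    traj = make_traj(pos, tags=tags)
    path = tmp_path / "traj.csv"
    bl.write_trajectory_csv(traj, path)
    back = bl.read_trajectory_csv(path)
    assert np.allclose(back.positions, traj.positions, atol=1e-6)
    assert np.allclose(back.times, traj.times)
    assert list(back.tags) == list(traj.tags)
    assert np.allclose(back.boxes, traj.boxes)


def test_csv_requires_box_header(tmp_path):
    path = tmp_path / "nobox.csv"
    path.write_text("frame,time_ns,tag,x,y,z\n0,0,POPC-P,1,1,1\n")
    with pytest.raises(bl.FormatError):
        bl.read_trajectory_csv(path)
    # explicit box argument rescues it
    traj = bl.read_trajectory_csv(path, box=(5, 5, 5))
    assert traj.n_particles == 1


def test_read_trajectory_selection(tmp_path, rng):
    traj = make_traj(rng.uniform(0, 10, (2, 4, 3)),
                     tags=["POPS-P", "POPS-P", "TFP", "POPC-P"])
    path = tmp_path / "traj.csv"
    bl.write_trajectory_csv(traj, path)
    sub = bl.read_trajectory(path, selection="POPS-P|TFP")
    assert sub.n_particles == 3
    with pytest.raises(bl.SelectionError):
        bl.read_trajectory(path, selection="CHOL")


# -------------------------------------------------- binary route (MDAnalysis)

def _write_gro_xtc(tmp_path, frames_nm, box_nm=5.0, angles=(90, 90, 90)):
    mda = pytest.importorskip("MDAnalysis")
    n = frames_nm[0].shape[0]
    u = mda.Universe.empty(n, n_residues=n,
                           atom_resindex=np.arange(n), trajectory=True)
    u.add_TopologyAttr("name", ["P"] * n)
    u.add_TopologyAttr("resname", ["POPC"] * n)
    u.add_TopologyAttr("resid", np.arange(1, n + 1))
    dims = [box_nm * 10] * 3 + list(angles)
    gro = tmp_path / "sys.gro"
    xtc = tmp_path / "sys.xtc"
    u.trajectory.ts.dimensions = dims
    u.atoms.positions = frames_nm[0] * 10.0
    u.atoms.write(str(gro))
    with mda.Writer(str(xtc), n) as w:
        for i, f in enumerate(frames_nm):
            u.atoms.positions = f * 10.0
            u.trajectory.ts.dimensions = dims
            u.trajectory.ts.time = i * 100.0  # ps
            u.trajectory.ts.frame = i
            w.write(u.atoms)
    return gro, xtc


def test_gro_xtc_and_csv_routes_agree(tmp_path, rng):
    frames = [rng.uniform(0.5, 4.5, (4, 3)) for _ in range(2)]
    gro, xtc = _write_gro_xtc(tmp_path, frames)
    traj = bl.read_trajectory(gro, xtc, selection="name P")
    assert traj.n_frames == 2 and traj.n_particles == 4
    assert list(traj.tags) == ["POPC-P"] * 4
    assert np.allclose(traj.times, [0.0, 0.1])

    csv = tmp_path / "same.csv"
    bl.write_trajectory_csv(traj, csv)
    again = bl.read_trajectory(csv, selection="POPC-P")
    # XTC stores positions on a 1e-3 A lattice; both routes already share it
    assert np.allclose(again.positions, traj.positions, atol=1e-6)
    assert np.allclose(np.stack(frames), traj.positions, atol=2e-4)


def test_mdanalysis_empty_selection_raises(tmp_path, rng):
    gro, xtc = _write_gro_xtc(tmp_path, [rng.uniform(1, 4, (4, 3))] * 2)
    with pytest.raises(bl.SelectionError):
        bl.read_trajectory(gro, xtc, selection="name XYZ")


def test_triclinic_box_rejected(tmp_path, rng):
    gro, xtc = _write_gro_xtc(tmp_path, [rng.uniform(1, 4, (4, 3))] * 2,
                              angles=(60, 90, 90))
    with pytest.raises(bl.FormatError):
        bl.read_trajectory(gro, xtc, selection="name P")


def test_unreadable_file_raises(tmp_path):
    bad = tmp_path / "garbage.gro"
    bad.write_text("this is not a structure file\n")
    with pytest.raises(bl.FormatError):
        bl.read_trajectory(bad)


# ------------------------------------------------------------ leaflet split

def test_leaflet_assignment_recovers_generative_labels(rng):
    n = 260
    pos = np.zeros((1, 2 * n, 3))
    pos[0, :, :2] = rng.uniform(0, 13, (2 * n, 2))
    pos[0, :n, 2] = 7.0 + rng.normal(0, 0.1, n)
    pos[0, n:, 2] = 3.0 + rng.normal(0, 0.1, n)
    traj = make_traj(pos, tags=["POPC-P"] * 2 * n)
    leaf = bl.assign_leaflets(traj)
    assert set(leaf.upper) == set(range(n))
    assert set(leaf.lower) == set(range(n, 2 * n))


def test_leaflet_assignment_degenerate_plane():
    pos = np.zeros((1, 10, 3))
    pos[0, :, :2] = np.arange(10)[:, None]
    with pytest.raises(bl.AmbiguousLeafletError):
        bl.assign_leaflets(make_traj(pos))


def test_leaflet_assignment_one_per_leaflet():
    pos = np.zeros((1, 2, 3))
    pos[0, 0, 2] = 6.0
    pos[0, 1, 2] = 4.0
    leaf = bl.assign_leaflets(make_traj(pos))
    assert list(leaf.upper) == [0] and list(leaf.lower) == [1]


@given(shift=st.floats(-50, 50))
@settings(derandomize=True, max_examples=20, deadline=None)
def test_leaflet_assignment_invariant_under_z_translation(shift):
    rng = np.random.default_rng(7)
    pos = np.zeros((1, 40, 3))
    pos[0, :, :2] = rng.uniform(0, 13, (40, 2))
    pos[0, :20, 2] = 7.0
    pos[0, 20:, 2] = 3.0
    base = bl.assign_leaflets(make_traj(pos, box=(13, 13, 1000)))
    shifted = pos.copy()
    shifted[0, :, 2] += shift
    moved = bl.assign_leaflets(make_traj(shifted, box=(13, 13, 1000)))
    assert np.array_equal(np.sort(base.upper), np.sort(moved.upper))


# -------------------------------------------------------------------- PBC

def test_unwrap_boundary_crossing_uses_minimum_image():
    L = 13.0
    pos = np.zeros((2, 1, 3))
    pos[0, 0] = [0.1, 1.0, 5.0]
    pos[1, 0] = [L - 0.1, 1.0, 5.0]
    out = bl.unwrap_lateral(make_traj(pos, box=(L, L, 10)))
    assert np.isclose(out.positions[1, 0, 0] - out.positions[0, 0, 0], -0.2)


def test_unwrap_stationary_is_identity(rng):
    pos = np.repeat(rng.uniform(0, 13, (1, 5, 3)), 4, axis=0)
    out = bl.unwrap_lateral(make_traj(pos))
    assert np.allclose(out.positions, pos)


def test_unwrap_constant_velocity_is_straight_line():
    L, v, dt = 13.0, 1.7, 1.0
    t = np.arange(40) * dt
    true_x = 2.0 + v * t
    pos = np.zeros((40, 1, 3))
    pos[:, 0, 0] = np.mod(true_x, L)
    pos[:, 0, 2] = 5.0
    out = bl.unwrap_lateral(make_traj(pos, box=(L, L, 10)))
    assert np.allclose(out.positions[:, 0, 0], true_x, atol=1e-9)


def test_unwrap_then_wrap_restores_wrapped_coordinates(rng):
    steps = rng.normal(0, 0.5, (20, 8, 3)).cumsum(axis=0)
    pos = np.mod(rng.uniform(0, 13, (1, 8, 3)) + steps, 13.0)
    traj = make_traj(pos)
    back = bl.wrap_lateral(bl.unwrap_lateral(traj))
    assert np.allclose(back.positions[:, :, :2], pos[:, :, :2], atol=1e-9)
    assert np.allclose(back.positions[:, :, 2], pos[:, :, 2])


def test_unwrap_warns_on_undersampled_jump():
    pos = np.zeros((2, 1, 3))
    pos[0, 0, 0] = 0.0
    pos[1, 0, 0] = 6.4  # just under half of 13: aliasing territory
    with pytest.warns(RuntimeWarning):
        bl.unwrap_lateral(make_traj(pos))
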