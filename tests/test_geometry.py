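import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy.spatial.transform import Rotation

import dynifp as d

from conftest import rotation_grid_search_rmsd


def random_rigid(seed):
    rng = np.random.default_rng(seed)
    R = Rotation.random(rng=rng).as_matrix()
    t = rng.normal(size=3) * 5
    return R, t


class TestKabsch:
    def test_identical_sets(self):
        P = np.random.default_rng(0).random((8, 3)) * 10
        tf, rmsd = d.kabsch_superpose(P, P)
        assert rmsd == pytest.approx(0.0, abs=1e-10)
        np.testing.assert_allclose(tf.rotation, np.eye(3), atol=1e-10)

    def test_recovers_rigid_transform(self):
        P = np.random.default_rng(1).random((8, 3)) * 10
        R = Rotation.from_euler("z", 90, degrees=True).as_matrix()
        Q = P @ R.T + np.array([1.0, -2.0, 3.0])
        tf, rmsd = d.kabsch_superpose(P, Q)
        assert rmsd == pytest.approx(0.0, abs=1e-8)
        np.testing.assert_allclose(tf.apply(P), Q, atol=1e-8)

    def test_matches_rotation_grid_search_oracle(self):
        P = np.array([[0.0, 0, 0], [3, 0, 0], [0, 3, 0], [0, 0, 3]])
        Q = P.copy()
        Q[3] += np.array([0.4, -0.2, 0.3])  # one displaced point
        _, rmsd = d.kabsch_superpose(P, Q)
        oracle = rotation_grid_search_rmsd(P, Q)
        assert rmsd == pytest.approx(oracle, abs=1e-3)
        assert rmsd <= oracle + 1e-9  # least-squares optimum is never worse

    def test_degenerate_inputs_rejected(self):
        with pytest.raises(ValueError):
            d.kabsch_superpose(np.zeros((2, 3)), np.zeros((2, 3)))
        line = np.array([[0.0, 0, 0], [1, 0, 0], [2, 0, 0], [3, 0, 0]])
        with pytest.raises(ValueError, match="collinear"):
            d.kabsch_superpose(line, line)

    @given(seed=st.integers(0, 500))
    @settings(max_examples=20)
    def test_rmsd_invariant_under_common_rigid_motion(self, seed):
        rng = np.random.default_rng(seed)
        P = rng.random((6, 3)) * 10
        Q = P + rng.normal(0, 0.5, size=P.shape)
        _, r0 = d.kabsch_superpose(P, Q)
        R, t = random_rigid(seed + 1)
        _, r1 = d.kabsch_superpose(P @ R.T + t, Q @ R.T + t)
        assert r1 == pytest.approx(r0, abs=1e-8)


class TestRmsdTrace:
    def _rigid_traj(self, topology, n=5, seed=0):
        base = topology.coords()
        frames = []
        for k in range(n):
            R, t = random_rigid(seed + k)
            frames.append(base @ R.T + t)
        return d.Trajectory(topology=topology, coords=np.stack(frames),
                            times_ns=tuple(0.1 * i for i in range(n)))

    def test_rigid_motions_give_zero_trace(self, small_topology):
        tr = self._rigid_traj(small_topology)
        sel = d.select(small_topology, "name CA")
        trace = d.rmsd_trace(tr, small_topology.coords(), sel)
        assert max(trace.rmsd) < 1e-8

    def test_rmsd_grows_with_noise(self, small_topology):
        base = small_topology.coords()
        sel = d.select(small_topology, "all")
        means = []
        for sigma in (0.1, 0.5, 1.0):
            rng = np.random.default_rng(42)
            frames = np.stack([base + rng.normal(0, sigma, base.shape)
                               for _ in range(20)])
            tr = d.Trajectory(topology=small_topology, coords=frames,
                              times_ns=tuple(0.1 * i for i in range(20)))
            trace = d.rmsd_trace(tr, base, sel)
            means.append(np.mean(trace.rmsd))
        assert means[0] < means[1] < means[2]

    def test_single_frame(self, small_topology):
        tr = d.Trajectory(topology=small_topology,
                          coords=small_topology.coords()[None],
                          times_ns=(0.0,))
        sel = d.select(small_topology, "name CA")
        trace = d.rmsd_trace(tr, small_topology.coords(), sel)
        assert len(trace.rmsd) == 1


class TestResidenceVolume:
    def test_static_atom_single_voxel(self):
        cloud = d.synth_ligand_cloud((0, 0, 0), (1e-9, 1e-9, 1e-9), 100, 1, seed=0)
        sel = d.select(cloud.topology, "ligand")
        grid = d.residence_volume([cloud], sel, spacing=1.0, stride_ns=0.1)
        assert grid.counts.max() == 100
        assert grid.counts.sum() == 100

    def test_count_conservation(self):
        cloud = d.synth_ligand_cloud((0, 0, 0), (10, 10, 10), 100, 10, seed=1)
        sel = d.select(cloud.topology, "ligand")
        grid = d.residence_volume([cloud], sel, spacing=1.0, stride_ns=0.1)
        assert grid.counts.sum() + grid.n_outside == 100 * 10
        assert grid.n_outside == 0  # padding keeps the box around the cloud

    def test_uniform_cloud_occupied_fraction(self):
        # 1000 atom positions into the 1000 voxels of a 10 A box: occupied
        # fraction ~ 1 - (1 - 1/1000)^1000 ~ 0.632
        cloud = d.synth_ligand_cloud((0, 0, 0), (10, 10, 10), 100, 10, seed=7)
        sel = d.select(cloud.topology, "ligand")
        grid = d.residence_volume([cloud], sel, spacing=1.0, stride_ns=0.1,
                                  padding=0.0, origin=(0, 0, 0), dims=(10, 10, 10))
        occupied = (grid.counts > 0).sum() / 1000
        expected = 1 - (1 - 1 / 1000) ** 1000
        # ~3 binomial sigmas
        assert abs(occupied - expected) < 3 * np.sqrt(expected * (1 - expected) / 1000)

    def test_stride_subsamples_frames(self):
        cloud = d.synth_ligand_cloud((0, 0, 0), (5, 5, 5), 100, 2, seed=3,
                                     frame_dt_ns=0.1)
        sel = d.select(cloud.topology, "ligand")
        grid = d.residence_volume([cloud], sel, spacing=1.0, stride_ns=0.5)
        assert grid.n_frames == 20
        assert grid.counts.sum() == 40

    def test_superposition_collapses_rigidly_moving_ligand(self, small_topology):
        base = small_topology.coords()
        frames = []
        for k in range(10):
            R, t = random_rigid(k)
            frames.append(base @ R.T + t)
        tr = d.Trajectory(topology=small_topology, coords=np.stack(frames),
                          times_ns=tuple(0.1 * i for i in range(10)))
        lig = d.select(small_topology, "ligand")
        fit = d.select(small_topology, "name CA and not ligand")
        grid = d.residence_volume([tr], lig, fit_selection=fit,
                                  reference_coords=base, spacing=1.0)
        # after fitting, each ligand atom sits in one voxel across all frames
        assert (grid.counts > 0).sum() <= 2 * len(lig)

    def test_empty_ligand_selection_errors(self, small_topology):
        with pytest.raises(ValueError, match="empty"):
            d.residence_volume([], d.Selection(atom_indices=()))


class TestGridOverlap:
    @staticmethod
    def box_grid(occupied_slice, n_frames=10):
        counts = np.zeros((4, 4, 4), dtype=int)
        counts[occupied_slice] = n_frames
        return d.OccupancyGrid(origin=(0, 0, 0), spacing=1.0, counts=counts,
                               n_frames=n_frames, n_ligand_atoms=1)

    def test_self_overlap_is_one(self):
        g = self.box_grid(np.s_[0:2, :, :])
        assert d.grid_overlap(g, g) == 1.0

    def test_disjoint_is_zero(self):
        a = self.box_grid(np.s_[0:2, :, :])
        b = self.box_grid(np.s_[2:4, :, :])
        assert d.grid_overlap(a, b) == 0.0

    def test_half_shared_is_one_third(self):
        a = self.box_grid(np.s_[0:2, :, :])   # slabs 0-1
        b = self.box_grid(np.s_[1:3, :, :])   # slabs 1-2; shared slab 1
        assert d.grid_overlap(a, b) == pytest.approx(1 / 3)

    def test_symmetry_and_geometry_check(self):
        a = self.box_grid(np.s_[0:2, :, :])
        b = self.box_grid(np.s_[1:3, :, :])
        assert d.grid_overlap(a, b) == d.grid_overlap(b, a)
        c = d.OccupancyGrid(origin=(1, 0, 0), spacing=1.0,
                            counts=np.zeros((4, 4, 4), dtype=int),
                            n_frames=1, n_ligand_atoms=1)
        with pytest.raises(ValueError):
            d.grid_overlap(a, c)


class TestGridExport:
    def test_round_trip(self):
        rng = np.random.default_rng(5)
        counts = rng.integers(0, 50, size=(3, 4, 5))
        g = d.OccupancyGrid(origin=(-2.0, 0.0, 1.5), spacing=0.5, counts=counts,
                            n_frames=60, n_ligand_atoms=7, n_outside=3)
        g2 = d.read_grid(d.export_grid(g))
        np.testing.assert_array_equal(g2.counts, g.counts)
        assert g2.origin == g.origin
        assert g2.spacing == g.spacing
        assert (g2.n_frames, g2.n_ligand_atoms, g2.n_outside) == (60, 7, 3)

    def test_data_order_z_fastest(self):
        counts = np.arange(8).reshape(2, 2, 2)
        g = d.OccupancyGrid(origin=(0, 0, 0), spacing=1.0, counts=counts,
                            n_frames=1, n_ligand_atoms=8)
        text = d.export_grid(g)
        data_lines = []
        seen = False
        for line in text.splitlines():
            if "data follows" in line:
                seen = True
                continue
            if seen and line and line[0].isdigit():
                data_lines.append(line)
        values = [int(v) for l in data_lines for v in l.split()]
        assert values == list(range(8))  # C order: z varies fastest

    def test_empty_grid_valid(self):
        g = d.OccupancyGrid(origin=(0, 0, 0), spacing=1.0,
                            counts=np.zeros((2, 2, 2), dtype=int),
                            n_frames=0, n_ligand_atoms=0)
        g2 = d.read_grid(d.export_grid(g))
        assert g2.counts.sum() == 0

    def test_readable_by_griddata(self, tmp_path):
        """Cross-check with the gridData OpenDX reader."""
        from gridData import Grid
        counts = np.arange(24).reshape(2, 3, 4)
        g = d.OccupancyGrid(origin=(1.0, 2.0, 3.0), spacing=1.0, counts=counts,
                            n_frames=1, n_ligand_atoms=24)
        p = tmp_path / "grid.dx"
        p.write_text(d.export_grid(g))
        ext = Grid(str(p))
        np.testing.assert_allclose(ext.grid, counts)
        np.testing.assert_allclose(ext.origin, (1.0, 2.0, 3.0))
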