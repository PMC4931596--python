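"""Coarse-grained order-parameter fields, angular deficit, defect detection."""

import numpy as np
import pytest

from rodconfine.errors import AnalysisError, ConfigError
from rodconfine.fields import (DirectorField, Grid2D, QField, angular_deficit,
                               detect_defects, local_packing_fraction,
                               local_q_field, ring_winding,
                               scalar_and_director, subsample_error,
                               total_charge, wrap_nematic)
from rodconfine.geometry import Confinement, spherocylinder_volume
from rodconfine.mc import Configuration
from rodconfine.synthetic import make_defect_field, rods_from_field


def _static_config(disk, pos, u, L=8.0):
    pos = np.atleast_2d(pos).astype(float)
    u = np.atleast_2d(u).astype(float)
    return Configuration(pos, u, disk, L, physical=False)


class TestGrid:
    def test_mask_matches_confinement(self, annulus, annulus_grid):
        X, Y = annulus_grid.meshgrid()
        r = np.hypot(X, Y)
        assert annulus_grid.mask[(r > annulus.R_inner + 1) & (r < annulus.R_outer - 1)].all()
        assert not annulus_grid.mask[r < annulus.R_inner - 1].any()

    def test_super_particle_cells_rejected(self, disk):
        with pytest.raises(ConfigError):
            Grid2D.for_confinement(disk, cell_size=2.0)


class TestLocalQField:
    def test_single_rod_gives_full_order_along_axis(self, disk, disk_grid):
        cfg = _static_config(disk, [0, 0, 3], [1, 0, 0])
        qf = local_q_field([cfg, cfg, cfg], disk_grid)
        s, d = scalar_and_director(qf)
        ix, iy = disk_grid.cell_of(np.array([0.0, 2.0, -2.0]), np.zeros(3))
        assert np.allclose(s.S[ix, iy], 1.0)
        assert np.allclose(np.minimum(d.theta[ix, iy],
                                      np.pi - d.theta[ix, iy]), 0.0, atol=1e-12)

    def test_crossed_rods_cancel(self, disk, disk_grid):
        cfg = _static_config(disk, [[0, 0, 3], [0, 0, 3]],
                             [[1, 0, 0], [0, 1, 0]])
        qf = local_q_field([cfg], disk_grid)
        s, _ = scalar_and_director(qf)
        ix, iy = disk_grid.cell_of(0.0, 0.0)
        assert s.S[ix, iy] == pytest.approx(0.0, abs=1e-12)

    def test_unvisited_cells_are_undefined(self, disk, disk_grid):
        cfg = _static_config(disk, [0, 0, 3], [1, 0, 0])
        qf = local_q_field([cfg], disk_grid)
        ix, iy = disk_grid.cell_of(0.0, 20.0)
        assert not qf.defined[ix, iy]

    def test_empty_snapshot_list_rejected(self, disk_grid):
        with pytest.raises(ConfigError):
            local_q_field([], disk_grid)


class TestScalarAndDirector:
    def test_closed_forms(self, disk_grid):
        n = disk_grid.n
        q1 = np.zeros((n, n))
        q2 = np.zeros((n, n))
        w = np.ones((n, n))
        q1[0, 0] = 1.0                      # Q = diag(1, -1): S = 1, theta = 0
        q1[0, 1] = 0.5                      # partial order along x
        # cell [1, 0] stays Q = 0: angle-doubled average of 0 and 90 degrees
        s, d = scalar_and_director(QField(disk_grid, q1, q2, w))
        assert s.S[0, 0] == 1.0 and d.theta[0, 0] == 0.0
        assert s.S[0, 1] == 0.5
        assert s.S[1, 0] == 0.0 and not d.defined[1, 0]
        assert ((0 <= d.theta) & (d.theta < np.pi)).all()


class TestAngularDeficit:
    def _ideal(self, grid, sign=+1):
        X, Y = grid.meshgrid()
        theta = np.mod(sign * 0.5 * np.arctan2(Y, X), np.pi)
        return DirectorField(grid, theta, np.ones_like(theta, bool))

    @pytest.mark.parametrize("sign", [+1, -1])
    def test_ideal_half_defect_scores_one_only_at_core(self, disk_grid, sign):
        deficit = angular_deficit(self._ideal(disk_grid, sign))
        n_hits = int((deficit.deficit > 0.5).sum())
        assert n_hits == 1
        assert deficit.deficit.max() == pytest.approx(1.0, abs=1e-9)

    def test_uniform_field_scores_zero(self, disk_grid):
        theta = np.full((disk_grid.n, disk_grid.n), 0.7)
        deficit = angular_deficit(
            DirectorField(disk_grid, theta, np.ones_like(theta, bool)))
        assert np.abs(deficit.deficit).max() == 0.0

    def test_undefined_cells_poison_their_vertices(self, disk_grid):
        d = self._ideal(disk_grid)
        d.defined[5, 5] = False
        deficit = angular_deficit(d)
        assert not deficit.defined[4:6, 4:6].any()

    def test_wrap_nematic_branch(self):
        assert wrap_nematic(np.pi / 2) == pytest.approx(np.pi / 2)
        assert wrap_nematic(np.pi / 2 + 0.1) == pytest.approx(-np.pi / 2 + 0.1)
        assert wrap_nematic(-np.pi / 2) == pytest.approx(np.pi / 2)


class TestDetectDefects:
    def test_single_planted_half_defect(self, disk_grid):
        d = make_defect_field([((3.3, -2.1), 0.5)], grid=disk_grid)
        defects = detect_defects(d, angular_deficit(d))
        assert len(defects) == 1
        assert defects[0].charge == 0.5
        assert np.hypot(*(defects[0].position - (3.3, -2.1))) <= 2.0

    def test_opposite_pair_sums_to_zero(self, disk_grid):
        d = make_defect_field([((-12, 0), 0.5), ((12, 0), -0.5)], grid=disk_grid)
        defects = detect_defects(d, angular_deficit(d))
        assert sorted(df.charge for df in defects) == [-0.5, 0.5]

    def test_uniform_field_yields_nothing(self, disk_grid):
        theta = np.full((disk_grid.n, disk_grid.n), 1.0)
        d = DirectorField(disk_grid, theta, disk_grid.mask.copy())
        assert detect_defects(d, angular_deficit(d)) == []

    def test_round_trip_many_random_multi_defect_fields(self, disk_grid, rng):
        """Every planted defect is recovered within 2 cells with its exact
        charge, for well-separated defects (the detector's core contract)."""
        n_fields = 25
        for _ in range(n_fields):
            k = rng.integers(1, 5)
            # rejection-sample positions at pairwise separation > 8 cells
            pts = []
            while len(pts) < k:
                p = rng.uniform(-25, 25, 2)
                if all(np.hypot(*(p - q)) > 8.0 for q in pts):
                    pts.append(p)
            charges = rng.choice([-1.0, -0.5, 0.5, 1.0], size=k)
            d = make_defect_field(
                [((p[0], p[1]), q) for p, q in zip(pts, charges)],
                background=rng.uniform(0, np.pi), grid=disk_grid)
            defects = detect_defects(d, angular_deficit(d))
            assert len(defects) == k
            for p, q in zip(pts, charges):
                match = min(defects, key=lambda df: np.hypot(*(df.position - p)))
                assert np.hypot(*(match.position - p)) <= 2.0
                assert match.charge == q
                assert match.residual < 0.1


class TestWindingAndTotalCharge:
    def test_tangential_disk_ring_carries_plus_one(self, disk, disk_grid):
        X, Y = disk_grid.meshgrid()
        theta = np.mod(np.arctan2(Y, X) + np.pi / 2, np.pi)
        d = DirectorField(disk_grid, theta, disk_grid.mask.copy())
        assert ring_winding(d, 0.95 * disk.R_outer) == pytest.approx(1.0, abs=1e-9)

    def test_uniform_field_carries_zero(self, disk, disk_grid):
        theta = np.full((disk_grid.n, disk_grid.n), 0.3)
        d = DirectorField(disk_grid, theta, disk_grid.mask.copy())
        assert total_charge([], d, disk) == pytest.approx(0.0, abs=1e-9)

    def test_annulus_tangential_rings_and_zero_interior(self, annulus, annulus_grid):
        X, Y = annulus_grid.meshgrid()
        theta = np.mod(np.arctan2(Y, X) + np.pi / 2, np.pi)
        d = DirectorField(annulus_grid, theta, annulus_grid.mask.copy())
        w_out = ring_winding(d, 0.95 * annulus.R_outer)
        w_in = ring_winding(d, annulus.R_inner + 2.0)
        assert w_out == pytest.approx(1.0, abs=1e-9)
        assert w_in == pytest.approx(1.0, abs=1e-9)
        assert w_out - w_in == pytest.approx(0.0, abs=1e-9)  # chi = 0

    def test_boundary_winding_is_homotopy_invariant(self, disk, disk_grid, rng):
        """Winding on the outer ring is +1 for any tangential-compatible
        interior defect arrangement (total interior charge +1)."""
        for _ in range(10):
            defects = [((0.0, 0.0), 1.0)]
            for _k in range(rng.integers(0, 3)):
                p = rng.uniform(-20, 20, 2)
                q = rng.choice([-0.5, 0.5])
                defects.append(((p[0], p[1]), q))
                # compensate to keep the total at +1
                defects.append(((-p[0] * 0.5, -p[1] * 0.5 + 5.0), -q))
            d = make_defect_field(defects, grid=disk_grid)
            assert ring_winding(d, 0.95 * disk.R_outer) == pytest.approx(
                1.0, abs=1e-9)

    def test_ring_through_undefined_region_errors(self, disk, disk_grid):
        theta = np.zeros((disk_grid.n, disk_grid.n))
        defined = disk_grid.mask.copy()
        X, Y = disk_grid.meshgrid()
        defined[np.hypot(X - 38, Y) < 3] = False
        d = DirectorField(disk_grid, theta, defined)
        with pytest.raises(AnalysisError):
            ring_winding(d, 0.95 * disk.R_outer)


class TestEquivariance:
    def test_rotating_snapshots_rotates_director_only(self, disk, disk_grid, rng):
        d_in = make_defect_field([((-10, 3), 0.5), ((11, -2), 0.5)],
                                 grid=disk_grid)
        cfg = rods_from_field(d_in, 4000, 0.0, disk, rng)
        alpha = np.pi / 2  # grid-exact rotation
        R = np.array([[np.cos(alpha), -np.sin(alpha), 0],
                      [np.sin(alpha), np.cos(alpha), 0], [0, 0, 1]])
        rot = Configuration((R @ cfg.positions.T).T,
                            (R @ cfg.orientations.T).T, disk, cfg.L,
                            physical=False)
        s0, d0 = scalar_and_director(local_q_field([cfg], disk_grid))
        s1, d1 = scalar_and_director(local_q_field([rot], disk_grid))
        # probe the two fields at matched points: theta1(R p) = theta0(p) + a
        probes = rng.uniform(-25, 25, (400, 2))
        rp = (R[:2, :2] @ probes.T).T
        i0, j0 = disk_grid.cell_of(probes[:, 0], probes[:, 1])
        i1, j1 = disk_grid.cell_of(rp[:, 0], rp[:, 1])
        ok = d0.defined[i0, j0] & d1.defined[i1, j1]
        assert ok.sum() > 200
        diff = wrap_nematic(d1.theta[i1, j1][ok] - d0.theta[i0, j0][ok] - alpha)
        assert np.abs(np.median(diff)) < np.deg2rad(3)
        assert np.median(np.abs(s1.S[i1, j1][ok] - s0.S[i0, j0][ok])) < 0.05


class TestPackingAndErrors:
    def test_empty_configuration_gives_zero(self, disk, disk_grid):
        cfg = Configuration(np.zeros((0, 3)), np.zeros((0, 3)), disk, 8.0)
        pf = local_packing_fraction([cfg], disk_grid)
        assert np.all(pf.phi == 0.0)

    def test_single_rod_footprint(self, disk, disk_grid):
        cfg = _static_config(disk, [0, 0, 3], [1, 0, 0])
        pf = local_packing_fraction([cfg], disk_grid)
        on_axis = pf.phi[disk_grid.cell_of(0.0, 0.0)]
        off_axis = pf.phi[disk_grid.cell_of(0.0, 15.0)]
        assert on_axis > 0 and off_axis == 0
        # total deposited volume is exact
        total = pf.phi.sum() * disk_grid.cell_size**2 * disk.H
        assert total == pytest.approx(spherocylinder_volume(8.0), rel=1e-9)

    def test_field_average_matches_global_eta(self, disk, disk_grid, rng):
        d = make_defect_field([((0, 0), 1.0)], grid=disk_grid)
        N = 400
        cfg = rods_from_field(d, N, 0.5, disk, rng)
        pf = local_packing_fraction([cfg], disk_grid)
        eta_field = pf.phi[disk_grid.mask].mean()
        eta_global = N * spherocylinder_volume(cfg.L) / disk.volume
        assert eta_field == pytest.approx(eta_global, rel=0.05)

    def test_subsample_error_identical_blocks(self, disk, disk_grid):
        cfg = _static_config(disk, [0, 0, 3], [1, 0, 0])
        snaps = [cfg] * 8
        err = subsample_error(snaps, lambda b: local_q_field(b, disk_grid).q1, 4)
        assert np.all(err == 0.0)

    def test_subsample_error_matches_iid_closed_form(self, rng):
        """Block standard error of i.i.d. normals approaches sigma/sqrt(n)."""
        sigma, n_tot, k = 2.0, 4096, 16
        reps = []
        for _ in range(40):
            xs = rng.normal(0.0, sigma, n_tot)
            reps.append(subsample_error(list(xs), lambda b: np.mean(b), k))
        est = np.mean(reps)
        assert est == pytest.approx(sigma / np.sqrt(n_tot), rel=0.15)

    def test_small_subsample_count_rejected(self, disk, disk_grid):
        cfg = _static_config(disk, [0, 0, 3], [1, 0, 0])
        with pytest.raises(ConfigError):
            subsample_error([cfg] * 4, lambda b: 0.0, 1)
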