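import numpy as np
import pytest

import corticompare as cc
from corticompare import template_registration as tr
from corticompare.mesh_core import TriangleMesh


class TestAverageSurface:
    def test_single_mesh_identity(self):
        m = cc.build_icosphere(2, radius=8.0)
        out = cc.average_surface([m])
        assert np.allclose(out.vertices, m.vertices)

    def test_linearity_under_translation(self):
        m = cc.build_icosphere(2, radius=8.0)
        shifted = TriangleMesh(m.vertices + [2.0, 0, 0], m.faces, m.hemisphere)
        out = cc.average_surface([m, shifted])
        assert np.allclose(out.vertices, m.vertices + [1.0, 0, 0])

    def test_thirty_subject_average_keeps_vertex_count(self):
        """Averaging the 10+10+10 subject surfaces leaves the template
        vertex count unchanged."""
        rng = np.random.default_rng(0)
        base = cc.build_icosphere(2, radius=20.0)
        meshes = [TriangleMesh(base.vertices * (1 + 0.02 * rng.standard_normal()),
                               base.faces, base.hemisphere) for _ in range(30)]
        out = cc.average_surface(meshes)
        assert out.n_vertices == base.n_vertices
        assert np.array_equal(out.faces, base.faces)

    def test_mismatched_connectivity_rejected(self):
        a = cc.build_icosphere(1)
        b = cc.build_icosphere(2)
        with pytest.raises(ValueError):
            cc.average_surface([a, b])


class TestEdgeMap:
    @pytest.fixture(scope="class")
    def sphere_edge(self):
        sphere = cc.build_icosphere(3, radius=15.0)
        return sphere, tr.voxelize_and_edge_map(sphere, spacing=1.0)

    def test_values_in_unit_interval(self, sphere_edge):
        _, edge = sphere_edge
        assert edge.data.min() >= 0 and edge.data.max() <= 1.0

    def test_unity_on_surface_voxels(self, sphere_edge):
        """Voxels the surface passes through carry f = exp(-d/sigma) with
        d the true sub-voxel distance, so f -> 1 as d -> 0."""
        sphere, edge = sphere_edge
        assert np.allclose(edge.data,
                           np.exp(-np.abs(edge.signed_distance) / edge.sigma))
        near = np.abs(edge.signed_distance) < 0.05
        assert near.sum() > 10
        assert edge.data[near].min() > np.exp(-0.05 / edge.sigma) - 1e-12

    def test_exp_decay_at_sigma(self, sphere_edge):
        """d = sigma gives f = 1/e; the distance estimate inverts it."""
        sphere, edge = sphere_edge
        pts = sphere.vertices * (1 + edge.sigma / 15.0)
        d_est = edge.distance_estimate(pts)
        assert d_est.mean() == pytest.approx(edge.sigma, rel=0.05)
        f = edge.sample(pts)
        assert f.mean() == pytest.approx(np.exp(-1.0), abs=0.04)

    def test_monotone_decay_with_distance(self, sphere_edge):
        sphere, edge = sphere_edge
        radial = sphere.vertices / 15.0
        f_prev = None
        for r in (15.0, 17.0, 19.0, 21.0):
            f = edge.sample(radial * r).mean()
            if f_prev is not None:
                assert f < f_prev
            f_prev = f

    def test_grid_size_guard(self):
        sphere = cc.build_icosphere(2, radius=50.0)
        with pytest.raises(MemoryError):
            tr.voxelize_and_edge_map(sphere, spacing=0.2)


class TestGVF:
    def test_constant_edge_map_gives_zero_field(self):
        edge = tr.EdgeMap(np.full((12, 12, 12), 0.5), 1.0,
                          np.zeros(3), 2.0)
        gvf = tr.compute_gvf(edge, tr.RegistrationConfig(), n_sweeps=10)
        assert np.allclose(gvf.data, 0.0)

    def test_energy_non_increasing_over_100_sweeps(self):
        sphere = cc.build_icosphere(2, radius=10.0)
        edge = tr.voxelize_and_edge_map(sphere, spacing=1.0)
        gvf = tr.compute_gvf(edge, tr.RegistrationConfig(), n_sweeps=100)
        assert len(gvf.energies) == 101
        assert np.all(np.diff(gvf.energies) <= 1e-9 * gvf.energies[0])

    def test_converged_field_matches_gradient_at_strong_edges(self):
        """Where |grad f| dominates the diffusion weight, the fixed point
        of the update is v = grad f (within 1%)."""
        sphere = cc.build_icosphere(3, radius=10.0)
        edge = tr.voxelize_and_edge_map(sphere, spacing=0.8, sigma=0.8)
        cfg = tr.RegistrationConfig(gvf_mu=5e-4)
        gvf = tr.compute_gvf(edge, cfg, n_sweeps=400)
        gx, gy, gz = np.gradient(edge.data, edge.spacing)
        grad = np.stack([gx, gy, gz], axis=-1)
        g2 = (grad ** 2).sum(-1)
        strong = g2 > 0.5 * g2.max()     # |grad f|^2 >> mu there
        assert strong.sum() > 100
        num = np.linalg.norm(gvf.data[strong] - grad[strong], axis=1)
        den = np.linalg.norm(grad[strong], axis=1)
        assert np.median(num / den) < 0.01

    def test_stability_bound_enforced(self):
        edge = tr.EdgeMap(np.zeros((8, 8, 8)), 1.0, np.zeros(3), 2.0)
        cfg = tr.RegistrationConfig(gvf_dt=10.0)
        with pytest.raises(tr.StabilityError):
            tr.compute_gvf(edge, cfg)


class TestApplyFFD:
    def _lattice(self, dims=(8, 8, 8)):
        return tr.make_lattice([-10] * 3, [10] * 3, dims=dims)

    def test_zero_lattice_is_identity(self):
        lat = self._lattice()
        pts = np.random.default_rng(0).uniform(-9, 9, (100, 3))
        assert np.allclose(tr.apply_ffd(lat, pts), pts)

    def test_uniform_displacement_is_rigid_translation(self):
        """Partition of unity: constant control displacement t translates
        every interior point by exactly t."""
        lat = self._lattice()
        lat.displacements[...] = [1.5, -0.5, 2.0]
        pts = np.random.default_rng(1).uniform(-8, 8, (200, 3))
        assert np.allclose(tr.apply_ffd(lat, pts), pts + [1.5, -0.5, 2.0],
                           atol=1e-10)

    def test_matches_brute_force_basis_summation(self):
        """Spot check against direct tensor-product summation over all
        control points with the full cubic B-spline basis."""
        rng = np.random.default_rng(2)
        lat = self._lattice(dims=(7, 8, 9))
        lat.displacements = rng.normal(scale=0.5,
                                       size=lat.dims + (3,))
        pts = rng.uniform(-6, 6, (10, 3))

        def bspline(u):
            au = abs(u)
            if au < 1:
                return (4 - 6 * au ** 2 + 3 * au ** 3) / 6
            if au < 2:
                return (2 - au) ** 3 / 6
            return 0.0

        out = tr.apply_ffd(lat, pts)
        for p, o in zip(pts, out):
            disp = np.zeros(3)
            u = (p - lat.origin) / lat.spacing
            for i in range(lat.dims[0]):
                for j in range(lat.dims[1]):
                    for k in range(lat.dims[2]):
                        w = bspline(u[0] - 1 - i + 1) * \
                            bspline(u[1] - 1 - j + 1) * \
                            bspline(u[2] - 1 - k + 1)
                        disp += w * lat.displacements[i, j, k]
            assert np.allclose(o, p + disp, atol=1e-10)

    def test_out_of_domain_clamped_with_warning(self):
        lat = self._lattice()
        with pytest.warns(UserWarning, match="clamp"):
            tr.apply_ffd(lat, np.array([[100.0, 0, 0]]))


class TestFFDRegister:
    @pytest.fixture(scope="class")
    def target_field(self):
        sphere = cc.build_icosphere(3, radius=15.0)
        edge = tr.voxelize_and_edge_map(sphere, spacing=1.0)
        gvf = tr.compute_gvf(edge, tr.RegistrationConfig())
        return sphere, edge, gvf

    def test_zero_field_keeps_source(self, target_field):
        sphere, edge, gvf = target_field
        zero = tr.VectorField3D(np.zeros_like(gvf.data), gvf.spacing,
                                gvf.origin)
        lat = tr.make_lattice(sphere.vertices.min(0) - 4,
                              sphere.vertices.max(0) + 4, dims=(8,) * 3)
        out, _ = tr.ffd_register(sphere, zero, lat,
                                 tr.RegistrationConfig(n_iterations=3))
        assert np.allclose(out.vertices, sphere.vertices)

    def test_huge_regularization_freezes_source(self, target_field):
        sphere, edge, gvf = target_field
        shrunk = TriangleMesh(sphere.vertices * 0.9, sphere.faces,
                              sphere.hemisphere)
        lat = tr.make_lattice(sphere.vertices.min(0) - 4,
                              sphere.vertices.max(0) + 4, dims=(8,) * 3)
        cfg = tr.RegistrationConfig(n_iterations=3, membrane_weight=1e9)
        out, _ = tr.ffd_register(shrunk, gvf, lat, cfg, edge=edge)
        assert np.abs(out.vertices - shrunk.vertices).max() < 1e-3

    def test_self_registration_barely_moves(self, target_field):
        """Registering a mesh onto itself displaces vertices by far less
        than a tenth of the voxel spacing."""
        sphere, edge, gvf = target_field
        lat = tr.make_lattice(sphere.vertices.min(0) - 4,
                              sphere.vertices.max(0) + 4, dims=(10,) * 3)
        out, _ = tr.ffd_register(sphere, gvf, lat, tr.RegistrationConfig(),
                                 edge=edge)
        disp = np.linalg.norm(out.vertices - sphere.vertices, axis=1)
        assert disp.mean() < edge.spacing / 10

    def test_topology_preserved_and_lattice_cumulative(self, target_field):
        sphere, edge, gvf = target_field
        shrunk = TriangleMesh(sphere.vertices * 0.93, sphere.faces,
                              sphere.hemisphere)
        lat = tr.make_lattice(sphere.vertices.min(0) - 4,
                              sphere.vertices.max(0) + 4, dims=(10,) * 3)
        out, total = tr.ffd_register(shrunk, gvf, lat,
                                     tr.RegistrationConfig(), edge=edge)
        assert np.array_equal(out.faces, shrunk.faces)
        out.validate()     # still a closed sphere per hemisphere
        assert np.any(total.displacements != 0)

    def test_known_warp_recovery_single_seed(self, target_field):
        """A synthetically warped sphere registers back onto the original
        well below the pre-registration distance."""
        res = tr.known_warp_recovery(seed=2, subdiv=3, radius=15.0,
                                     spacing=1.0, amplitude=2.0)
        assert res["ratio"] < 0.6
        assert res["post"] < res["pre"]
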