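"""Interface geometry: shapes, surface calculus, curvature, transport."""

import numpy as np
import pytest

from fm2d import (GeometryError, InterfaceMesh, curvature_init, diagnostics,
                  inner_product, make_shape, pushforward, segment_normals,
                  surface_divergence_p1, surface_gradient_p1, transport_scalar,
                  vertex_normals_omega, vertex_weights)

from conftest import random_simple_polygon


class TestShapes:
    def test_circle_k4_is_inscribed_square(self):
        g = make_shape("circle", 4, radius=1.0)
        assert np.allclose(np.linalg.norm(g.vertices, axis=1), 1.0)
        assert np.allclose(g.segment_lengths(), np.sqrt(2.0))

    @pytest.mark.parametrize("name,kwargs,a_r", [
        ("ellipse", {"axes": (1.0, 2.5)}, 0.745),   # shear-experiment shape
        ("stadium", {"width": 0.2, "length": 1.5}, 0.351),  # constriction tube
    ])
    def test_reduced_area_of_experiment_shapes(self, name, kwargs, a_r):
        g = make_shape(name, 513, **kwargs)
        assert round(diagnostics(g)["a_r"], 3) == a_r

    @pytest.mark.parametrize("n", [4, 16, 64])
    def test_regular_polygon_reduced_area_closed_form(self, n):
        g = make_shape("circle", n, radius=1.3)
        expected = (np.pi / n) / np.tan(np.pi / n)
        assert abs(diagnostics(g)["a_r"] - expected) < 1e-13

    @pytest.mark.parametrize("name,kwargs", [
        ("ellipse", {"axes": (1.0, 2.5)}),
        ("stadium", {"width": 0.2, "length": 1.5}),
        ("letter_c", {}),
    ])
    def test_generated_shapes_are_equidistributed_and_ccw(self, name, kwargs):
        g = make_shape(name, 257, **kwargs)
        h = g.segment_lengths()
        assert (h.max() - h.min()) / h.mean() < 1e-10
        assert g.enclosed_area() > 0  # counterclockwise
        assert g.is_simple()

    def test_shape_errors(self):
        with pytest.raises(GeometryError):
            make_shape("heptagram", 10)
        with pytest.raises(GeometryError):
            make_shape("circle", 2, radius=1.0)
        with pytest.raises(GeometryError):
            make_shape("circle", 10, radius=-1.0)
        with pytest.raises(GeometryError):
            make_shape("stadium", 10, width=0.5, length=0.4)


class TestNormalsAndWeights:
    def test_unit_square_bottom_edge_normal(self):
        g = InterfaceMesh(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        assert np.allclose(segment_normals(g)[0], (0.0, -1.0))

    def test_weighted_normals_sum_to_zero_on_any_closed_polygon(self, rng):
        for _ in range(10):
            g = random_simple_polygon(rng)
            nu = segment_normals(g)
            h = g.segment_lengths()
            assert np.abs((h[:, None] * nu).sum(axis=0)).max() < 1e-13

    @pytest.mark.parametrize("n", [8, 32])
    def test_regular_polygon_normals_are_radial(self, n):
        c = np.array([0.3, -0.2])
        g = make_shape("circle", n, radius=2.0, center=c)
        mids = g.segment_midpoints()
        radial = (mids - c) / np.linalg.norm(mids - c, axis=1)[:, None]
        assert np.abs(segment_normals(g) - radial).max() < 1e-12

    def test_vertex_normal_square_example(self, diamond):
        # at (1,0) the two adjacent edge normals average to (sqrt2/2, 0)
        assert np.allclose(vertex_normals_omega(diamond)[0],
                           (np.sqrt(2) / 2, 0.0))

    @pytest.mark.parametrize("n", [8, 64])
    def test_vertex_normal_magnitude_regular_polygon(self, n):
        g = make_shape("circle", n, radius=1.0)
        omega = vertex_normals_omega(g)
        assert np.abs(np.linalg.norm(omega, axis=1) - np.cos(np.pi / n)).max() < 1e-13
        radial = g.vertices / np.linalg.norm(g.vertices, axis=1)[:, None]
        assert np.abs(omega / np.cos(np.pi / n) - radial).max() < 1e-12

    def test_lumped_pairing_identity_nu_vs_omega(self, rng):
        """<z, w*nu>^h = <z, w*omega>^h for P1 z, w (the mechanism that makes
        the vertex normal a valid volume-constraint test direction)."""
        for _ in range(10):
            g = random_simple_polygon(rng)
            K = g.n_vertices
            z = rng.standard_normal((K, 2))
            wf = rng.standard_normal(K)
            wk = vertex_weights(g)
            nu = segment_normals(g)
            # lumped pairing with the P0 normal: one-sided limits per segment
            i, j = g.seg_start, g.seg_end
            h = g.segment_lengths()
            lhs = 0.5 * np.sum(h * (wf[i] * np.sum(z[i] * nu, axis=1)
                                    + wf[j] * np.sum(z[j] * nu, axis=1)))
            rhs = np.sum(wk * wf * np.sum(z * vertex_normals_omega(g), axis=1))
            assert abs(lhs - rhs) < 1e-12 * max(1.0, abs(lhs))

    def test_vertex_weights_sum_to_length(self, rng):
        g = random_simple_polygon(rng)
        assert abs(vertex_weights(g).sum() - g.length()) < 1e-13


class TestInnerProducts:
    def test_constant_fields_give_length(self, rng):
        g = random_simple_polygon(rng)
        one = np.ones(g.n_vertices)
        for mode in ("full", "lumped"):
            assert abs(inner_product(g, one, one, mode) - g.length()) < 1e-12

    def test_hat_vs_one_lumped_gives_weight(self, diamond):
        hat = np.array([1.0, 0, 0, 0])
        one = np.ones(4)
        assert abs(inner_product(diamond, hat, one, "lumped")
                   - vertex_weights(diamond)[0]) < 1e-14

    def test_hat_masses_on_equilateral_triangle(self):
        h = 0.7
        # equilateral 3-gon with side h
        g = make_shape("circle", 3, radius=h / np.sqrt(3.0))
        hat = np.array([1.0, 0, 0])
        assert abs(inner_product(g, hat, hat, "full") - 2 * h / 3) < 1e-12
        assert abs(inner_product(g, hat, hat, "lumped") - h) < 1e-12


class TestSurfaceGradient:
    def test_constant_field_zero(self, rng):
        g = random_simple_polygon(rng)
        grad = surface_gradient_p1(g, np.full(g.n_vertices, 3.7))
        assert np.abs(grad).max() < 1e-12

    def test_identity_map_gives_tangent_projector(self, rng):
        g = random_simple_polygon(rng)
        grad = surface_gradient_p1(g, g.vertices)  # (J, 2, 2)
        t = g.tangents()
        proj = np.einsum("ja,jb->jab", t, t)
        assert np.abs(grad - proj).max() < 1e-12

    def test_rigid_rotation_is_surface_divergence_free(self, rng):
        for _ in range(5):
            g = random_simple_polygon(rng)
            u = np.c_[-g.vertices[:, 1], g.vertices[:, 0]]
            assert np.abs(surface_divergence_p1(g, u)).max() < 1e-12


class TestCurvature:
    def test_square_inscribed_in_unit_circle(self, diamond):
        assert np.allclose(curvature_init(diamond), -diamond.vertices)

    @pytest.mark.parametrize("n", [16, 64, 256])
    def test_regular_polygon_curvature_magnitude(self, n):
        """The lumped discrete curvature of an equidistributed polygon on a
        circle of radius R equals 1/R (so the refinement error is well below
        second order) and points inward (negative sign convention)."""
        R = 1.7
        g = make_shape("circle", n, radius=R)
        kap = curvature_init(g)
        assert np.abs(np.linalg.norm(kap, axis=1) - 1.0 / R).max() < 1e-12
        radial = g.vertices / np.linalg.norm(g.vertices, axis=1)[:, None]
        assert np.abs(kap + radial / R).max() < 1e-12

    def test_collinear_vertices_have_zero_curvature(self):
        g = InterfaceMesh(np.array([
            [0.0, 0], [1, 0], [2, 0], [2, 2], [0, 2]]))  # vertex 1 is mid-edge
        assert np.abs(curvature_init(g)[1]).max() < 1e-13


class TestDiagnostics:
    def test_equidistributed_element_ratio_is_one(self):
        g = make_shape("ellipse", 129, axes=(1.0, 2.0))
        assert abs(diagnostics(g)["r_a"] - 1.0) < 1e-9

    def test_self_intersection_reported(self):
        bowtie = np.array([[0.0, 0], [1, 1], [1, 0], [0, 1]])
        with pytest.raises(GeometryError):
            InterfaceMesh(bowtie)
        g = InterfaceMesh(np.array([[0.0, 0], [1, 0], [1, 1], [0, 1]]))
        g.vertices[:] = bowtie  # corrupt in place, bypassing the constructor
        with pytest.raises(GeometryError):
            diagnostics(g)


class TestTransport:
    def test_pushforward_copies_values(self, rng):
        f = rng.standard_normal((7, 2))
        out = pushforward(f)
        assert np.array_equal(out, f) and out is not f

    def test_unchanged_geometry_is_identity(self, rng):
        g = random_simple_polygon(rng)
        psi = rng.uniform(0.5, 1.5, g.n_vertices)
        assert np.allclose(transport_scalar(psi, g, g), psi)

    def test_uniform_dilation_halves_field(self, rng):
        g = random_simple_polygon(rng)
        g2 = g.moved(2.0 * g.vertices)
        psi = np.ones(g.n_vertices)
        assert np.allclose(transport_scalar(psi, g, g2), 0.5)

    def test_transport_conserves_lumped_integral_over_many_steps(self, rng):
        g = random_simple_polygon(rng)
        psi = rng.uniform(0.5, 1.5, g.n_vertices)
        total0 = np.sum(psi * vertex_weights(g))
        for _ in range(50):
            g2 = g.moved(g.vertices
                         + 0.01 * rng.standard_normal(g.vertices.shape),
                         check_simple=False)
            psi = transport_scalar(psi, g, g2)
            g = g2
        assert abs(np.sum(psi * vertex_weights(g)) - total0) < 1e-12 * abs(total0)

    def test_connectivity_mismatch_raises(self, rng):
        g1 = random_simple_polygon(rng, n=10)
        g2 = random_simple_polygon(rng, n=12)
        with pytest.raises(GeometryError):
            transport_scalar(np.ones(10), g1, g2)
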