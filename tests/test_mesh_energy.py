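"""Elastic energy, gradients and relaxation of triangulated shells."""

import math

import numpy as np
import pytest
import trimesh

from dipid.assembly import relax, seed_mesh
from dipid.mesh import (ElasticParams, ShellMesh, _energy_impl,
                        dihedral_angles, shell_energy, shell_energy_gradient)


def make_icosphere(l0: float, subdivisions: int = 1) -> ShellMesh:
    tm = trimesh.creation.icosphere(subdivisions=subdivisions)
    scale = l0 / tm.edges_unique_length.mean()
    return ShellMesh(tm.vertices * scale, [tuple(f) for f in tm.faces])


class TestEnergy:
    def test_flat_hexamer_ground_state(self):
        """Six equilateral triangles around a hub cost nothing when the
        preferred dihedral is zero."""
        l0 = 1.0
        ang = np.arange(6) * math.pi / 3
        V = np.vstack([[0.0, 0, 0],
                       np.stack([np.cos(ang), np.sin(ang), np.zeros(6)], 1) * l0])
        tris = [(0, i + 1, (i + 1) % 6 + 1) for i in range(6)]
        m = ShellMesh(V, tris)
        assert shell_energy(m, ElasticParams(ks=1, kb=2, l0=l0, theta0=0)) == \
            pytest.approx(0.0, abs=1e-12)

    def test_quadratic_response_to_scaling(self, small_mesh):
        p = ElasticParams(ks=1.0, kb=1.0, l0=1.0, theta0=0.0)
        m = small_mesh
        relax(m, p, tol=1e-10, maxiter=5000)
        e0 = shell_energy(m, p)
        es = []
        for eps in (1e-3, 2e-3, 4e-3):
            m2 = ShellMesh(m.vertices * (1 + eps), list(m.triangles))
            es.append(shell_energy(m2, p) - e0)
        # doubling epsilon quadruples the energy increase
        assert es[1] / es[0] == pytest.approx(4.0, rel=0.05)
        assert es[2] / es[1] == pytest.approx(4.0, rel=0.05)

    def test_gradient_matches_finite_differences(self, small_mesh):
        p = ElasticParams(ks=1.3, kb=2.1, l0=1.0, theta0=12.0)
        X = small_mesh.vertices
        E, g = shell_energy_gradient(small_mesh, p)
        h = 1e-6
        for i in range(X.shape[0]):
            for j in range(3):
                Xp, Xm = X.copy(), X.copy()
                Xp[i, j] += h
                Xm[i, j] -= h
                num = (_energy_impl(small_mesh, p, Xp, False)[0]
                       - _energy_impl(small_mesh, p, Xm, False)[0]) / (2 * h)
                assert g[i, j] == pytest.approx(num, abs=1e-5)

    def test_kernel_matches_reference_path(self, small_mesh):
        p = ElasticParams(ks=0.7, kb=3.0, l0=1.1, theta0=-7.0)
        E1, g1 = _energy_impl(small_mesh, p, small_mesh.vertices, True,
                              use_numba=True)
        E2, g2 = _energy_impl(small_mesh, p, small_mesh.vertices, True,
                              use_numba=False)
        assert E1 == pytest.approx(E2, rel=1e-12)
        np.testing.assert_allclose(g1, g2, atol=1e-12)

    def test_rigid_motion_invariance(self, small_mesh):
        p = ElasticParams(ks=1.0, kb=2.0, l0=1.0, theta0=5.0)
        e0 = shell_energy(small_mesh, p)
        # rotation about an arbitrary axis plus translation
        th = 0.83
        R = np.array([[math.cos(th), -math.sin(th), 0],
                      [math.sin(th), math.cos(th), 0], [0, 0, 1.0]])
        m2 = ShellMesh(small_mesh.vertices @ R.T + [1.5, -2.0, 0.7],
                       list(small_mesh.triangles))
        assert shell_energy(m2, p) == pytest.approx(e0, abs=1e-9)

    def test_degenerate_triangle_raises(self):
        V = np.array([[0, 0, 0], [1.0, 0, 0], [2.0, 0, 0]])
        m = ShellMesh(V, [(0, 1, 2)])
        with pytest.raises(ValueError, match="degenerate"):
            shell_energy(m, ElasticParams())

    def test_sphere_energy_against_trimesh_term_sum(self):
        """Per-term oracle: stretching from unique edge lengths and bending
        from trimesh's face-adjacency angles on a convex shell."""
        l0 = 37.7
        p = ElasticParams(ks=1.0, l0=l0, theta0=8.0)
        tm = trimesh.creation.icosphere(subdivisions=2)
        tm.apply_scale(l0 / tm.edges_unique_length.mean())
        mesh = ShellMesh(tm.vertices, [tuple(f) for f in tm.faces])
        expected = 0.5 * p.ks * np.sum((tm.edges_unique_length - l0) ** 2)
        expected += p.kb * np.sum(1.0 - np.cos(tm.face_adjacency_angles
                                               - p.theta0_rad))
        assert shell_energy(mesh, p) == pytest.approx(expected, rel=1e-9)


class TestDihedrals:
    def test_closed_convex_shell_positive(self):
        m = make_icosphere(1.0)
        th = dihedral_angles(m.vertices, m.interior_edge_quads())
        assert np.all(th > 0)

    def test_flat_sheet_zero(self):
        m = seed_mesh(1.0)
        V = np.vstack([m.vertices, [[1.5, math.sqrt(3) / 2 * 1.0, 0.0]]])
        m2 = ShellMesh(V, [(0, 1, 2), (2, 1, 3)])
        th = dihedral_angles(m2.vertices, m2.interior_edge_quads())
        assert th == pytest.approx([0.0], abs=1e-12)


class TestRelax:
    def test_already_relaxed_unchanged(self):
        l0 = 1.0
        m = seed_mesh(l0)
        p = ElasticParams(l0=l0)
        before = m.vertices.copy()
        relax(m, p, tol=1e-8)
        np.testing.assert_allclose(m.vertices, before, atol=1e-7)

    def test_energy_never_increases(self, small_mesh, rng):
        p = ElasticParams(ks=1.0, kb=2.0, l0=1.0, theta0=0.0)
        e0 = shell_energy(small_mesh, p)
        _, info = relax(small_mesh, p, tol=1e-8, maxiter=2000)
        assert info["energy"] <= e0 + 1e-12
        assert info["grad_norm"] <= 1e-6

    def test_perturbed_flat_patch_returns_planar(self, rng):
        l0 = 1.0
        rows, cols = 4, 5
        V, tris = [], []
        for j in range(rows):
            for i in range(cols):
                V.append([i * l0 + (j % 2) * l0 / 2, j * l0 * math.sqrt(3) / 2, 0.0])
        for j in range(rows - 1):
            for i in range(cols - 1):
                a = j * cols + i
                if j % 2 == 0:
                    tris += [(a, a + 1, a + cols), (a + 1, a + cols + 1, a + cols)]
                else:
                    tris += [(a, a + cols + 1, a + cols), (a, a + 1, a + cols + 1)]
        m = ShellMesh(np.array(V), tris)
        m.vertices[:, 2] += 0.02 * rng.standard_normal(m.n_vertices)
        relax(m, ElasticParams(ks=1.0, l0=l0, theta0=0.0), tol=1e-9,
              maxiter=5000)
        th = dihedral_angles(m.vertices, m.interior_edge_quads())
        assert np.degrees(np.abs(th)).max() < 0.1

    def test_closed_shell_radius_matches_geometry(self):
        """A closed shell relaxed at the cone angle matching its size sits
        at radius ~ l0 / (sqrt(3) theta0)."""
        l0 = 37.7
        mesh = make_icosphere(l0, subdivisions=2)  # 162 vertices
        R_target = np.linalg.norm(mesh.vertices, axis=1).mean()
        theta0 = math.degrees(l0 / (math.sqrt(3) * R_target))
        p = ElasticParams(l0=l0, theta0=theta0)
        relax(mesh, p, tol=1e-6, maxiter=4000)
        radii = np.linalg.norm(mesh.vertices - mesh.vertices.mean(0), axis=1)
        R_pred = l0 / (math.sqrt(3) * math.radians(theta0))
        assert radii.mean() == pytest.approx(R_pred, rel=0.15)
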