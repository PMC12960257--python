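"""Triangulated elastic shell: topology, energy and gradients.

The assembly simulator represents a growing Dipid membrane as a
triangulated sheet whose vertices are monomer centres.  Its elastic
energy is a discrete stretching + bending functional,

    E = sum_edges 1/2 ks (l - l0)^2
      + sum_hinges kb (1 - cos(theta - theta0)),

where ``l0`` is the preferred monomer centre spacing, ``theta`` the
signed dihedral angle between the two triangles flanking an interior
edge (0 for a flat sheet) and ``theta0`` the spontaneous dihedral that
encodes the monomer cone angle.  Gradients are analytic (standard
four-point dihedral derivatives), so relaxation scales to a few hundred
monomers comfortably.
"""

from __future__ import annotations

import math

import numpy as np

__all__ = ["ShellMesh", "ElasticParams", "shell_energy", "shell_energy_gradient"]


class ElasticParams:
    """Elastic constants of the bead-spring shell.

    Parameters
    ----------
    ks : float
        Stretching modulus, energy / nm^2.
    kb : float
        Hinge bending modulus, energy.  Default keeps ks l0^2 / kb = 10.
    l0 : float
        Rest edge length (monomer centre spacing), nm.  Default 37.7 nm is
        the 30-nm barrel width plus the mean inter-monomer gap of the
        mid-sized designs.
    theta0 : float
        Preferred dihedral angle, degrees; the simulated cone angle.
    """

    def __init__(self, ks: float = 1.0, kb: float | None = None,
                 l0: float = 37.7, theta0: float = 0.0):
        if ks <= 0 or l0 <= 0:
            raise ValueError("ks and l0 must be positive")
        self.ks = float(ks)
        self.kb = float(kb) if kb is not None else ks * l0**2 / 10.0
        if self.kb <= 0:
            raise ValueError("kb must be positive")
        self.l0 = float(l0)
        self.theta0 = float(theta0)

    @property
    def theta0_rad(self) -> float:
        return math.radians(self.theta0)

    def __repr__(self) -> str:
        return (f"ElasticParams(ks={self.ks}, kb={self.kb}, l0={self.l0}, "
                f"theta0={self.theta0})")


class ShellMesh:
    """Mutable triangle mesh with oriented faces and rim bookkeeping.

    Faces are wound consistently (counter-clockwise seen from outside), so
    every interior edge appears once in each direction and the rim is the
    set of directed edges appearing exactly once.
    """

    def __init__(self, vertices, triangles):
        self.vertices = np.asarray(vertices, dtype=float).reshape(-1, 3).copy()
        self.triangles = [tuple(int(i) for i in t) for t in triangles]
        self._topo = None

    # -- topology ---------------------------------------------------------
    def _build_topology(self):
        edge_tris: dict = {}   # sorted pair -> [(tri_idx, wing, directed_as_sorted)]
        directed = {}          # directed edge -> tri index
        for ti, (a, b, c) in enumerate(self.triangles):
            for (u, v, w) in ((a, b, c), (b, c, a), (c, a, b)):
                key = (u, v) if u < v else (v, u)
                edge_tris.setdefault(key, []).append((ti, w, u < v))
                if (u, v) in directed:
                    raise ValueError(f"duplicate directed edge {(u, v)}: mesh not orientable")
                directed[(u, v)] = ti
        for key, lst in edge_tris.items():
            if len(lst) > 2:
                raise ValueError(f"non-manifold edge {key}")
        quads = []
        for (j, k), lst in edge_tris.items():
            if len(lst) == 2:
                (t1, w1, asc1), (t2, w2, asc2) = lst
                quads.append((w1, j, k, w2) if asc1 else (w1, k, j, w2))
        self._topo = {
            "edge_tris": edge_tris,
            "directed": directed,
            "edges_arr": np.asarray(sorted(edge_tris), dtype=int).reshape(-1, 2),
            "quads_arr": np.asarray(quads, dtype=int).reshape(-1, 4),
        }
        return self._topo

    @property
    def topology(self):
        if self._topo is None:
            self._build_topology()
        return self._topo

    def invalidate(self):
        self._topo = None

    @property
    def n_vertices(self) -> int:
        return len(self.vertices)

    @property
    def n_triangles(self) -> int:
        return len(self.triangles)

    @property
    def edges(self):
        return self.topology["edges_arr"]

    @property
    def n_edges(self) -> int:
        return len(self.topology["edge_tris"])

    def interior_edge_quads(self):
        """(E_int, 4) vertex quadruples (wing1, j, k, wing2) per hinge.

        The quad is ordered along triangle-1's traversal of the edge, which
        fixes the dihedral sign convention mesh-wide.
        """
        return self.topology["quads_arr"]

    def boundary_cycles(self):
        """Rim vertex cycles, each following the directed boundary edges."""
        edge_tris = self.topology["edge_tris"]
        directed = self.topology["directed"]
        nxt = {}
        for (u, v), lst in edge_tris.items():
            if len(lst) == 1:
                if (u, v) in directed:
                    nxt[u] = v
                else:
                    nxt[v] = u
        cycles, seen = [], set()
        for start in sorted(nxt):
            if start in seen:
                continue
            cyc, node = [], start
            while node not in seen:
                seen.add(node)
                cyc.append(node)
                node = nxt[node]
            cycles.append(cyc)
        return cycles

    @property
    def boundary(self):
        """Rim vertices of the (first) boundary cycle; [] when closed."""
        cycles = self.boundary_cycles()
        return cycles[0] if cycles else []

    @property
    def is_closed(self) -> bool:
        return not any(len(lst) == 1 for lst in self.topology["edge_tris"].values())

    def euler_characteristic(self) -> int:
        return self.n_vertices - self.n_edges + self.n_triangles

    def vertex_triangle_count(self):
        return np.bincount(np.asarray(self.triangles, dtype=int).ravel(),
                           minlength=self.n_vertices)

    def coordination(self):
        """Neighbour count per vertex and the set of interior vertices."""
        nbrs = [set() for _ in range(self.n_vertices)]
        boundary_v = set()
        for (u, v), lst in self.topology["edge_tris"].items():
            nbrs[u].add(v)
            nbrs[v].add(u)
            if len(lst) == 1:
                boundary_v.update((u, v))
        coord = np.array([len(s) for s in nbrs], dtype=int)
        interior = np.array([i for i in range(self.n_vertices) if i not in boundary_v],
                            dtype=int)
        return coord, interior

    def disclination_census(self):
        """Counts of 5-, 6-, 7-coordinated interior vertices (and others)."""
        coord, interior = self.coordination()
        census = {}
        for c in coord[interior]:
            census[int(c)] = census.get(int(c), 0) + 1
        return census

    def copy(self) -> "ShellMesh":
        return ShellMesh(self.vertices.copy(), list(self.triangles))


# -- energy ---------------------------------------------------------------

try:
    from numba import njit as _njit
    _HAVE_NUMBA = True
except ImportError:  # pragma: no cover - numba is a hard dependency in practice
    _HAVE_NUMBA = False

    def _njit(*a, **k):
        def deco(f):
            return f
        return deco


@_njit(cache=True, fastmath=False)
def _energy_grad_kernel(X, edges, quads, ks, kb, l0, th0):  # pragma: no cover
    n = X.shape[0]
    grad = np.zeros((n, 3))
    E = 0.0
    for i in range(edges.shape[0]):
        a = edges[i, 0]
        b = edges[i, 1]
        dx = X[b, 0] - X[a, 0]
        dy = X[b, 1] - X[a, 1]
        dz = X[b, 2] - X[a, 2]
        l = math.sqrt(dx * dx + dy * dy + dz * dz)
        dl = l - l0
        E += 0.5 * ks * dl * dl
        c = ks * dl / l
        grad[b, 0] += c * dx
        grad[b, 1] += c * dy
        grad[b, 2] += c * dz
        grad[a, 0] -= c * dx
        grad[a, 1] -= c * dy
        grad[a, 2] -= c * dz
    b1 = np.empty(3)
    b2 = np.empty(3)
    b3 = np.empty(3)
    n1 = np.empty(3)
    n2 = np.empty(3)
    m = np.empty(3)
    for i in range(quads.shape[0]):
        i1 = quads[i, 0]
        i2 = quads[i, 1]
        i3 = quads[i, 2]
        i4 = quads[i, 3]
        for k in range(3):
            b1[k] = X[i2, k] - X[i1, k]
            b2[k] = X[i3, k] - X[i2, k]
            b3[k] = X[i4, k] - X[i3, k]
        n1[0] = b1[1] * b2[2] - b1[2] * b2[1]
        n1[1] = b1[2] * b2[0] - b1[0] * b2[2]
        n1[2] = b1[0] * b2[1] - b1[1] * b2[0]
        n2[0] = b2[1] * b3[2] - b2[2] * b3[1]
        n2[1] = b2[2] * b3[0] - b2[0] * b3[2]
        n2[2] = b2[0] * b3[1] - b2[1] * b3[0]
        m[0] = n1[1] * n2[2] - n1[2] * n2[1]
        m[1] = n1[2] * n2[0] - n1[0] * n2[2]
        m[2] = n1[0] * n2[1] - n1[1] * n2[0]
        b2n = math.sqrt(b2[0] ** 2 + b2[1] ** 2 + b2[2] ** 2)
        sin_t = (m[0] * b2[0] + m[1] * b2[1] + m[2] * b2[2]) / b2n
        cos_t = n1[0] * n2[0] + n1[1] * n2[1] + n1[2] * n2[2]
        phi = math.atan2(sin_t, cos_t)
        theta = phi - math.pi
        if theta < -math.pi:
            theta += 2.0 * math.pi
        dth = theta - th0
        E += kb * (1.0 - math.cos(dth))
        dEdphi = kb * math.sin(dth)
        n1sq = n1[0] ** 2 + n1[1] ** 2 + n1[2] ** 2
        n2sq = n2[0] ** 2 + n2[1] ** 2 + n2[2] ** 2
        b2sq = b2n * b2n
        p = (b1[0] * b2[0] + b1[1] * b2[1] + b1[2] * b2[2]) / b2sq
        q = (b3[0] * b2[0] + b3[1] * b2[1] + b3[2] * b2[2]) / b2sq
        for k in range(3):
            F1k = -(b2n / n1sq) * n1[k]
            F4k = (b2n / n2sq) * n2[k]
            F2k = -(1.0 + p) * F1k + q * F4k
            F3k = p * F1k - (1.0 + q) * F4k
            grad[i1, k] += dEdphi * F1k
            grad[i2, k] += dEdphi * F2k
            grad[i3, k] += dEdphi * F3k
            grad[i4, k] += dEdphi * F4k
    return E, grad


def _cross(a, b):
    """Row-wise cross product without numpy's axis-juggling overhead."""
    out = np.empty_like(a)
    out[:, 0] = a[:, 1] * b[:, 2] - a[:, 2] * b[:, 1]
    out[:, 1] = a[:, 2] * b[:, 0] - a[:, 0] * b[:, 2]
    out[:, 2] = a[:, 0] * b[:, 1] - a[:, 1] * b[:, 0]
    return out


def _triangle_areas(X, tris):
    t = np.asarray(tris, dtype=int)
    v1 = X[t[:, 1]] - X[t[:, 0]]
    v2 = X[t[:, 2]] - X[t[:, 0]]
    return 0.5 * np.linalg.norm(_cross(v1, v2), axis=1)


def dihedral_angles(X, quads):
    """Signed hinge angles for (wing1, j, k, wing2) quadruples.

    0 for coplanar wings on opposite sides of the edge; positive when the
    hinge bends toward the face-normal side (convex, for outward normals).
    """
    if len(quads) == 0:
        return np.zeros(0)
    p1, p2, p3, p4 = (X[quads[:, i]] for i in range(4))
    b1 = p2 - p1
    b2 = p3 - p2
    b3 = p4 - p3
    n1 = _cross(b1, b2)
    n2 = _cross(b2, b3)
    b2n = np.linalg.norm(b2, axis=1)
    m = _cross(n1, n2)
    sin_term = np.einsum("ij,ij->i", m, b2) / np.maximum(b2n, 1e-300)
    cos_term = np.einsum("ij,ij->i", n1, n2)
    phi = np.arctan2(sin_term, cos_term)
    # phi = +-pi on a flat sheet; theta measures deviation from flatness,
    # positive for convex (outward-bulging) hinges under outward winding
    theta = phi - np.pi
    return np.where(theta < -np.pi, theta + 2 * np.pi, theta)


def shell_energy(mesh: ShellMesh, params: ElasticParams) -> float:
    return _energy_impl(mesh, params, mesh.vertices, want_grad=False, strict=True)[0]


def shell_energy_gradient(mesh: ShellMesh, params: ElasticParams, X=None):
    """(energy, gradient) with the gradient shaped like the vertex array."""
    return _energy_impl(mesh, params, mesh.vertices if X is None else X,
                        want_grad=True)


def _energy_impl(mesh: ShellMesh, params: ElasticParams, X, want_grad: bool,
                 strict: bool = False, edge_rows=None, quad_rows=None,
                 use_numba: bool = True):
    """Energy (and gradient) of the mesh; optionally restricted to subsets
    of edge/hinge terms, for local relaxation around a growth site.

    The compiled kernel and the vectorized numpy path implement the same
    functional; the numpy path doubles as the reference implementation.
    """
    X = np.asarray(X, dtype=float).reshape(-1, 3)
    if strict:
        areas = _triangle_areas(X, mesh.triangles)
        if np.any(areas < 1e-12):
            bad = int(np.argmin(areas))
            raise ValueError(f"degenerate (zero-area) triangle {mesh.triangles[bad]}")

    e = mesh.topology["edges_arr"]
    if edge_rows is not None:
        e = e[edge_rows]
    if use_numba and _HAVE_NUMBA:
        quads = mesh.interior_edge_quads()
        if quad_rows is not None:
            quads = quads[quad_rows]
        E, grad = _energy_grad_kernel(X, e, quads, params.ks, params.kb,
                                      params.l0, params.theta0_rad)
        return E, (grad if want_grad else None)

    grad = np.zeros_like(X) if want_grad else None
    d = X[e[:, 1]] - X[e[:, 0]]
    lens = np.linalg.norm(d, axis=1)
    dl = lens - params.l0
    E = 0.5 * params.ks * float(np.sum(dl**2))
    if want_grad:
        f = (params.ks * dl / lens)[:, None] * d
        np.add.at(grad, e[:, 1], f)
        np.add.at(grad, e[:, 0], -f)

    quads = mesh.interior_edge_quads()
    if quad_rows is not None:
        quads = quads[quad_rows]
    if len(quads):
        theta = dihedral_angles(X, quads)
        dth = theta - params.theta0_rad
        E += params.kb * float(np.sum(1.0 - np.cos(dth)))
        if want_grad:
            # theta = phi - pi, so dE/dphi = dE/dtheta
            dE_dphi = params.kb * np.sin(dth)
            p1, p2, p3, p4 = (X[quads[:, i]] for i in range(4))
            b1 = p2 - p1
            b2 = p3 - p2
            b3 = p4 - p3
            n1 = _cross(b1, b2)
            n2 = _cross(b2, b3)
            n1sq = np.einsum("ij,ij->i", n1, n1)
            n2sq = np.einsum("ij,ij->i", n2, n2)
            b2n = np.linalg.norm(b2, axis=1)
            b2sq = b2n**2
            # Blondel-Karplus dihedral derivatives
            F1 = (-(b2n / n1sq))[:, None] * n1
            F4 = ((b2n / n2sq))[:, None] * n2
            p = (np.einsum("ij,ij->i", b1, b2) / b2sq)[:, None]
            q = (np.einsum("ij,ij->i", b3, b2) / b2sq)[:, None]
            F2 = -(1.0 + p) * F1 + q * F4
            F3 = p * F1 - (1.0 + q) * F4
            c = dE_dphi[:, None]
            np.add.at(grad, quads[:, 0], c * F1)
            np.add.at(grad, quads[:, 1], c * F2)
            np.add.at(grad, quads[:, 2], c * F3)
            np.add.at(grad, quads[:, 3], c * F4)

    return E, grad
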