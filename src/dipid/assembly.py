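"""Growth simulation of Dipid membranes as bead-spring triangulated shells.

One bead is one monomer (centre spacing ``l0``); triangles are the bonds
of the close-packed lattice.  Growth proceeds at the rim of an open
sheet: wherever the 3D opening angle beta between the two rim edges at a
vertex with at least four incident triangles falls below ``beta_merge``
the wedge is closed by bonding the two rim edges (closure at four
triangles creates a five-coordinated disclination); otherwise a new
monomer is attached at the most-embracing rim wedge (smallest intrinsic
opening angle, the proxy for the lowest-binding-energy site), except
that with probability ``p_random`` a uniformly random rim site is used
instead.  The mesh is re-relaxed after every addition (locally, with
periodic full relaxations), so the sheet curls according to the
spontaneous hinge angle ``theta0`` that encodes the monomer cone angle.

Large cone angles close into spheroidal containers; small cone angles
leave elongated, tube-like sheets within the monomer budget, which is
the morphology progression observed for Dipid containers.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize

from .mesh import ElasticParams, ShellMesh, _energy_impl, dihedral_angles

__all__ = [
    "GrowthParams",
    "MorphologyReport",
    "AssemblyResult",
    "relax",
    "grow_step",
    "run_assembly",
    "sweep_alpha",
    "transition_angle",
    "mesh_aspect_ratio",
    "seed_mesh",
    "classify_morphology",
]


@dataclass
class GrowthParams:
    """Assembly-rule parameters.

    ``p_random`` is the probability per placement of choosing a uniformly
    random rim site instead of the most-embracing one; ``beta_merge`` is
    the 3D rim opening angle (degrees) below which an eligible wedge is
    bonded shut instead of adding a monomer; ``tube_aspect`` is the
    aspect-ratio threshold separating spheroids from tubes.  Relaxation
    after each step is restricted to ``local_rings`` graph hops around
    the modified site, with a full relaxation every
    ``full_relax_every``-th step.
    """

    seed: int
    max_monomers: int = 300
    p_random: float = 0.05
    beta_merge: float = 110.0
    relax_tol: float = 1e-4
    relax_maxiter: int = 50
    tube_aspect: float = 1.6
    local_rings: int = 3
    full_relax_every: int = 10

    def __post_init__(self) -> None:
        if not 0.0 <= self.p_random <= 1.0:
            raise ValueError("p_random must be in [0, 1]")
        if self.max_monomers < 1:
            raise ValueError("max_monomers must be >= 1")


@dataclass(frozen=True)
class MorphologyReport:
    closed: bool
    n_monomers: int
    d_major: float
    d_minor: float
    aspect_ratio: float
    coordination_census: dict
    classification: str  # spheroid | tube | open

    @property
    def net_disclination_charge(self) -> int:
        """sum(6 - coordination) over interior vertices; 12 for closed shells."""
        return sum((6 - c) * n for c, n in self.coordination_census.items())


@dataclass
class AssemblyResult:
    mesh: ShellMesh
    report: MorphologyReport
    energy: float
    converged: bool
    trajectory: list = field(default_factory=list)


def seed_mesh(l0: float) -> ShellMesh:
    """Single equilateral triangle of side ``l0`` in the z=0 plane."""
    V = np.array([
        [0.0, 0.0, 0.0],
        [l0, 0.0, 0.0],
        [0.5 * l0, 0.5 * math.sqrt(3.0) * l0, 0.0],
    ])
    return ShellMesh(V, [(0, 1, 2)])


def relax(mesh: ShellMesh, params: ElasticParams, tol: float = 1e-6,
          maxiter: int = 5000):
    """Minimize the shell energy in place (L-BFGS, analytic gradient).

    Returns ``(mesh, info)`` where ``info`` carries the final energy, the
    projected-gradient max-norm and a convergence flag.  The energy never
    increases relative to the input configuration.
    """
    x0 = mesh.vertices.ravel().copy()
    e0 = _energy_impl(mesh, params, x0, want_grad=False)[0]

    def fun(x):
        E, g = _energy_impl(mesh, params, x, want_grad=True)
        return E, g.ravel()

    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-14})
    if res.fun <= e0:
        mesh.vertices = res.x.reshape(-1, 3)
    _, g = _energy_impl(mesh, params, mesh.vertices, want_grad=True)
    gnorm = float(np.abs(g).max()) if g.size else 0.0
    info = {"energy": float(min(res.fun, e0)), "grad_norm": gnorm,
            "converged": bool(res.success or gnorm <= 10 * tol),
            "n_iter": int(res.nit)}
    return mesh, info


def _rim_openings(mesh: ShellMesh, cycle):
    """Opening angle (degrees) of the uncovered wedge at every rim vertex.

    Measured intrinsically as 360 minus the sum of the triangle corner
    angles meeting at the vertex, which distinguishes a tight wedge from a
    reflex (barely covered) one -- a chord angle cannot.
    """
    X = mesh.vertices
    t = np.asarray(mesh.triangles, dtype=int)
    P = X[t]  # (F, 3, 3)
    covered = np.zeros(mesh.n_vertices)
    for i in range(3):
        v = P[:, i]
        u1 = P[:, (i + 1) % 3] - v
        u2 = P[:, (i + 2) % 3] - v
        cc = (np.einsum("ij,ij->i", u1, u2)
              / (np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)))
        np.add.at(covered, t[:, i], np.degrees(np.arccos(np.clip(cc, -1.0, 1.0))))
    return [360.0 - covered[v] for v in cycle]


def relax_local(mesh: ShellMesh, params: ElasticParams, seeds, rings: int = 3,
                tol: float = 1e-4, maxiter: int = 100):
    """Relax only the vertices within ``rings`` graph hops of ``seeds``.

    Growth perturbs the sheet locally; restricting the minimization to the
    neighbourhood of the modified site keeps each step cheap.  Energy terms
    touching any free vertex are included, with the surrounding sheet held
    fixed.
    """
    topo = mesh.topology
    adj = {}
    for (u, v) in topo["edge_tris"]:
        adj.setdefault(u, []).append(v)
        adj.setdefault(v, []).append(u)
    free = set(seeds)
    frontier = set(seeds)
    for _ in range(rings):
        frontier = {w for u in frontier for w in adj.get(u, ())} - free
        free |= frontier
    free_idx = np.fromiter(sorted(free), dtype=int)
    in_free = np.zeros(mesh.n_vertices, dtype=bool)
    in_free[free_idx] = True
    e = topo["edges_arr"]
    edge_rows = np.flatnonzero(in_free[e].any(axis=1))
    q = topo["quads_arr"]
    quad_rows = np.flatnonzero(in_free[q].any(axis=1)) if len(q) else None

    base = mesh.vertices

    def fun(xf):
        X = base.copy()
        X[free_idx] = xf.reshape(-1, 3)
        E, g = _energy_impl(mesh, params, X, want_grad=True,
                            edge_rows=edge_rows, quad_rows=quad_rows)
        return E, g[free_idx].ravel()

    x0 = base[free_idx].ravel().copy()
    e0 = fun(x0)[0]
    res = minimize(fun, x0, jac=True, method="L-BFGS-B",
                   options={"maxiter": maxiter, "gtol": tol, "ftol": 1e-14})
    if res.fun <= e0:
        mesh.vertices = base.copy()
        mesh.vertices[free_idx] = res.x.reshape(-1, 3)
    return mesh


def _rim_chords(mesh: ShellMesh, cycle):
    """3-D angle (degrees) between the two rim edges at every rim vertex."""
    X = mesh.vertices
    idx = np.asarray(cycle, dtype=int)
    prv = np.roll(idx, 1)
    nxt = np.roll(idx, -1)
    u1 = X[prv] - X[idx]
    u2 = X[nxt] - X[idx]
    cc = (np.einsum("ij,ij->i", u1, u2)
          / (np.linalg.norm(u1, axis=1) * np.linalg.norm(u2, axis=1)))
    return np.degrees(np.arccos(np.clip(cc, -1.0, 1.0)))


def _placement_position(mesh: ShellMesh, u: int, v: int, params: ElasticParams):
    """Ideal position for a new monomer on rim edge u->v: an equilateral
    triangle tilted off the parent plane by the spontaneous angle."""
    X = mesh.vertices
    ti = mesh.topology["directed"][(u, v)]
    a, b, c = mesh.triangles[ti]
    wing = [w for w in (a, b, c) if w not in (u, v)][0]
    o = X[wing]
    m = 0.5 * (X[u] + X[v])
    e = X[v] - X[u]
    elen = np.linalg.norm(e)
    ehat = e / elen
    nvec = np.cross(X[b] - X[a], X[c] - X[a])
    nhat = nvec / np.linalg.norm(nvec)
    d = m - o
    d -= np.dot(d, ehat) * ehat
    dn = np.linalg.norm(d)
    dhat = d / dn if dn > 1e-12 else np.cross(ehat, nhat)
    h = math.sqrt(max(params.l0**2 - 0.25 * elen**2, (0.3 * params.l0) ** 2))
    th = params.theta0_rad
    return m + h * (math.cos(th) * dhat - math.sin(th) * nhat)


def grow_step(mesh: ShellMesh, eparams: ElasticParams, gparams: GrowthParams,
              rng: np.random.Generator, full_relax: bool = True) -> ShellMesh:
    """Add one triangle at the rim (wedge closure or new monomer), then relax.

    With ``full_relax`` False only the neighbourhood of the modified site is
    re-minimized (the caller is expected to interleave full relaxations).
    No-op on a closed mesh.
    """
    cycles = mesh.boundary_cycles()
    if not cycles:
        return mesh
    cycle = max(cycles, key=len)
    n = len(cycle)

    site = list(cycle[:3])
    did = False
    if n == 3 and {*cycle} not in [set(t) for t in mesh.triangles]:
        a, v, b = cycle
        mesh.triangles.append((b, v, a))
        mesh.invalidate()
        did = True

    if not did:
        tri_count = mesh.vertex_triangle_count()
        directed = mesh.topology["directed"]
        edge_tris = mesh.topology["edge_tris"]
        openings = _rim_openings(mesh, cycle)
        chords = _rim_chords(mesh, cycle)
        merges = []
        for i, v in enumerate(cycle):
            a, b = cycle[i - 1], cycle[(i + 1) % n]
            # closure must leave the vertex at least 5-coordinated, so it
            # needs >= 4 incident triangles already; the k = 4 case is the
            # pentagonal-disclination channel, reachable only where the rim
            # is strongly folded
            if chords[i] >= gparams.beta_merge or tri_count[v] < 4:
                continue
            key = (a, b) if a < b else (b, a)
            existing = edge_tris.get(key)
            if existing is not None:
                # wedge closure across an existing edge is only orientable if
                # that edge currently runs a->b on the rim
                if len(existing) > 1 or (a, b) not in directed:
                    continue
            merges.append((chords[i], v, a, b))
        if merges:
            merges.sort()
            _, v, a, b = merges[0]
            mesh.triangles.append((v, a, b))
            mesh.invalidate()
            site = [v, a, b]
            did = True

    if not did:
        if gparams.p_random > 0 and rng.random() < gparams.p_random:
            k = int(rng.integers(n))
            u, v = cycle[k], cycle[(k + 1) % n]
        else:
            # most-concave site: a new monomer binds into the tightest open
            # wedge, the proxy for the lowest-energy (most-bonded) placement
            i = int(np.argmin(openings))
            u, v = cycle[i - 1], cycle[i]
        pos = _placement_position(mesh, u, v, eparams)
        w = len(mesh.vertices)
        mesh.vertices = np.vstack([mesh.vertices, pos[None, :]])
        mesh.triangles.append((v, u, w))
        mesh.invalidate()
        site = [w, u, v]

    if full_relax:
        relax(mesh, eparams, tol=gparams.relax_tol, maxiter=gparams.relax_maxiter)
    else:
        relax_local(mesh, eparams, site, rings=gparams.local_rings,
                    tol=gparams.relax_tol, maxiter=gparams.relax_maxiter)
    return mesh


def mesh_aspect_ratio(mesh_or_points):
    """Principal extents of the vertex cloud and their ratio.

    Returns ``(d_major, d_minor, a)`` where the extents are the peak-to-peak
    spans along the principal axes of the vertex covariance, sorted
    descending; ``d_minor`` is the middle extent, so a flattened/collapsed
    object is still characterized by its two in-plane spans, and
    ``a = d_major / d_minor >= 1``.
    """
    X = mesh_or_points.vertices if isinstance(mesh_or_points, ShellMesh) \
        else np.asarray(mesh_or_points, dtype=float)
    if X.shape[0] < 4:
        raise ValueError("need at least 4 points for principal extents")
    Xc = X - X.mean(axis=0)
    cov = Xc.T @ Xc / len(Xc)
    _, vecs = np.linalg.eigh(cov)
    proj = Xc @ vecs
    extents = np.sort(proj.max(axis=0) - proj.min(axis=0))[::-1]
    if extents[1] < 1e-9:
        raise ValueError("degenerate (collinear) vertex cloud")
    return float(extents[0]), float(extents[1]), float(extents[0] / extents[1])


def classify_morphology(mesh: ShellMesh, tube_aspect: float = 1.6) -> str:
    _, _, a = mesh_aspect_ratio(mesh)
    if mesh.is_closed:
        return "spheroid" if a <= tube_aspect else "tube"
    return "tube" if a > tube_aspect else "open"


def _make_report(mesh: ShellMesh, gparams: GrowthParams) -> MorphologyReport:
    if mesh.n_vertices < 4:
        return MorphologyReport(
            closed=False, n_monomers=mesh.n_vertices, d_major=float("nan"),
            d_minor=float("nan"), aspect_ratio=float("nan"),
            coordination_census=mesh.disclination_census(),
            classification="open")
    d_major, d_minor, a = mesh_aspect_ratio(mesh)
    return MorphologyReport(
        closed=mesh.is_closed,
        n_monomers=mesh.n_vertices,
        d_major=d_major,
        d_minor=d_minor,
        aspect_ratio=a,
        coordination_census=mesh.disclination_census(),
        classification=classify_morphology(mesh, gparams.tube_aspect),
    )


def run_assembly(eparams: ElasticParams, gparams: GrowthParams,
                 record_trajectory: bool = False) -> AssemblyResult:
    """Grow a shell until closure or the monomer budget, then classify it."""
    rng = np.random.default_rng(gparams.seed)
    mesh = seed_mesh(eparams.l0)
    traj = []
    max_tris = 4 * gparams.max_monomers
    step = 0
    while (not mesh.is_closed and mesh.n_vertices < gparams.max_monomers
           and mesh.n_triangles < max_tris):
        step += 1
        full = (gparams.full_relax_every <= 1
                or step % gparams.full_relax_every == 0)
        grow_step(mesh, eparams, gparams, rng, full_relax=full)
        if record_trajectory:
            traj.append(mesh.vertices.copy())
    mesh, info = relax(mesh, eparams, tol=gparams.relax_tol, maxiter=2000)
    return AssemblyResult(mesh=mesh, report=_make_report(mesh, gparams),
                          energy=info["energy"], converged=info["converged"],
                          trajectory=traj)


def sweep_alpha(alphas, reps: int, gparams: GrowthParams,
                eparams: ElasticParams | None = None) -> pd.DataFrame:
    """Phase table over cone angles: morphology fractions and aspect ratios.

    Every (angle, replicate) pair gets an independent, reproducible seed
    derived from ``gparams.seed``.
    """
    if reps < 1:
        raise ValueError("reps must be >= 1")
    base = eparams or ElasticParams()
    rows = []
    for ia, alpha in enumerate(alphas):
        ep = ElasticParams(ks=base.ks, kb=base.kb, l0=base.l0, theta0=float(alpha))
        cls, aspects = [], []
        for rep in range(reps):
            seed = int(np.random.SeedSequence([gparams.seed, ia, rep])
                       .generate_state(1)[0] % (2**31))
            gp = GrowthParams(seed=seed, max_monomers=gparams.max_monomers,
                              p_random=gparams.p_random,
                              beta_merge=gparams.beta_merge,
                              relax_tol=gparams.relax_tol,
                              relax_maxiter=gparams.relax_maxiter,
                              tube_aspect=gparams.tube_aspect)
            res = run_assembly(ep, gp)
            cls.append(res.report.classification)
            aspects.append(res.report.aspect_ratio)
        aspects = np.asarray(aspects)
        n = len(cls)
        rows.append({
            "alpha_deg": float(alpha),
            "n_runs": n,
            "frac_spheroid": cls.count("spheroid") / n,
            "frac_tube": cls.count("tube") / n,
            "frac_open": cls.count("open") / n,
            "mean_aspect": float(aspects.mean()),
            "sem_aspect": float(aspects.std(ddof=1) / math.sqrt(n)) if n > 1 else float("nan"),
        })
    return pd.DataFrame(rows)


def transition_angle(phase_table: pd.DataFrame) -> float:
    """Smallest swept cone angle at which closed spheroids appear."""
    hit = phase_table[phase_table["frac_spheroid"] > 0]
    if hit.empty:
        return float("nan")
    return float(hit["alpha_deg"].iloc[0])
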