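"""Pore sizes between close-packed Dipid monomers.

Monomers are modelled as hard discs of the barrel radius centred on the
3D coordinates obtained from simulation or tomographic template
matching.  In a hexagonal lattice the openings are the interstices of
three mutually touching discs ("trimeric" pores); at a pentagonal
disclination five monomers ring an opening without a central monomer
("pentagonal" pores); missing monomers leave still larger "defect"
pores.  Every pore is measured as the largest inscribed circle: the
candidate centre inside the junction that maximizes the minimal distance
to any monomer disc edge, evaluated in the best-fit plane of the
junction members.

For three tangent discs of radius R the inscribed diameter is
``2 R (2 / sqrt(3) - 1)``; for a regular ring of five tangent discs it
is ``2 R (1 / sin(36 deg) - 1)`` -- the analytic references used in the
tests.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import networkx as nx
import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.spatial import cKDTree

__all__ = [
    "MonomerLayout",
    "PoreReport",
    "neighbour_graph",
    "junction_pore",
    "pore_census",
]

#: pores wider than this are attributed to missing monomers, nm
DEFECT_THRESHOLD_NM = 30.0


@dataclass
class MonomerLayout:
    """Monomer centre coordinates (nm) with the disc radius used for pore
    measurements and the neighbour cutoff of the bond network.

    ``radius_inflation`` optionally grows the effective disc radius to
    represent a strand corona; the default 0 measures bare barrels, which
    presumes strong electrostatic screening (high salt).
    """

    centres: np.ndarray
    monomer_radius: float = 14.25
    cutoff: float | None = None  # default: 1.35 x barrel diameter
    radius_inflation: float = 0.0

    def __post_init__(self) -> None:
        self.centres = np.asarray(self.centres, dtype=float).reshape(-1, 3)
        if self.monomer_radius <= 0:
            raise ValueError("monomer radius must be positive")
        if self.cutoff is None:
            self.cutoff = 1.35 * 2.0 * self.monomer_radius

    @property
    def effective_radius(self) -> float:
        return self.monomer_radius + self.radius_inflation


@dataclass
class PoreReport:
    junction_id: int
    kind: str  # trimeric | pentagonal | defect
    pore_diameter: float
    members: tuple = field(default_factory=tuple)
    plane_residual: float = 0.0
    flags: list = field(default_factory=list)


def neighbour_graph(layout: MonomerLayout):
    """Bond network within the cutoff plus a coordination census.

    Returns ``(graph, coordination, disclinations)`` where ``graph`` is an
    undirected networkx graph on centre indices, ``coordination`` maps
    index -> neighbour count and ``disclinations`` lists 5-coordinated
    sites.
    """
    X = layout.centres
    if len(X) < 3:
        raise ValueError("need at least 3 monomer centres")
    tree = cKDTree(X)
    pairs = tree.query_pairs(layout.cutoff, output_type="ndarray")
    g = nx.Graph()
    g.add_nodes_from(range(len(X)))
    g.add_edges_from(map(tuple, pairs))
    coordination = dict(g.degree())
    disclinations = [v for v, d in coordination.items()
                     if d == 5 and _is_interior(X, v, list(g[v]))]
    return g, coordination, disclinations


def _is_interior(X, v, nbrs, max_gap_deg: float = 100.0):
    """A site is interior when its neighbours surround it: projected onto
    the local best-fit plane, no angular gap between consecutive
    neighbours exceeds ``max_gap_deg`` (rim sites leave a wide gap)."""
    if len(nbrs) < 3:
        return False
    rel = X[nbrs] - X[v]
    _, _, vt = np.linalg.svd(rel)
    ang = np.sort(np.arctan2(rel @ vt[1], rel @ vt[0]))
    gaps = np.diff(np.concatenate([ang, [ang[0] + 2 * math.pi]]))
    return math.degrees(gaps.max()) < max_gap_deg


def _best_fit_plane(points: np.ndarray):
    centroid = points.mean(axis=0)
    _, s, vt = np.linalg.svd(points - centroid)
    normal = vt[-1]
    residual = s[-1] / math.sqrt(len(points)) if len(points) > 2 else 0.0
    return centroid, vt[0], vt[1], normal, float(residual)


def junction_pore(layout: MonomerLayout, cycle, planarity_tol: float = 5.0):
    """Largest-inscribed-circle diameter of the opening ringed by ``cycle``.

    The cycle members are projected onto their best-fit plane; within that
    plane the centre maximizing the minimal distance to any disc edge
    (centre distance minus effective radius) is found by Nelder-Mead from
    the centroid.  All discs of the layout near the junction constrain the
    pore, so a monomer sitting inside the ring correctly annihilates it.

    Returns ``(diameter_nm, plane_residual_nm)``; the diameter is clipped
    at zero.
    """
    cycle = list(cycle)
    if len(cycle) < 3:
        raise ValueError("a junction needs at least 3 members")
    X = layout.centres
    R = layout.effective_radius
    pts = X[cycle]
    centroid, e1, e2, normal, residual = _best_fit_plane(pts)

    # constrain with every disc near the junction, not only ring members
    tree = cKDTree(X)
    span = np.linalg.norm(pts - centroid, axis=1).max() + 2 * R
    near = tree.query_ball_point(centroid, span)
    discs = X[near]

    def clearance(uv):
        p = centroid + uv[0] * e1 + uv[1] * e2
        return np.linalg.norm(discs - p, axis=1).min() - R

    res = minimize(lambda uv: -clearance(uv), np.zeros(2),
                   method="Nelder-Mead",
                   options={"xatol": 1e-4, "fatol": 1e-10, "maxiter": 2000})
    diameter = max(0.0, 2.0 * (-res.fun))
    return diameter, residual


def _hole_rings(g: nx.Graph, layout: MonomerLayout, max_len: int = 5):
    """Chordless cycles of length 3..max_len that ring an actual opening
    (no monomer close to the ring centroid)."""
    X = layout.centres
    tree = cKDTree(X)
    rings = []
    seen = set()
    for cyc in nx.simple_cycles(g, length_bound=max_len):
        if len(cyc) < 3:
            continue
        key = frozenset(cyc)
        if key in seen:
            continue
        sub = g.subgraph(cyc)
        if sub.number_of_edges() != len(cyc):  # chords present
            continue
        if len(cyc) > 3:
            # a monomer sitting at the ring centre (e.g. a 5-coordinated
            # site ringed by its neighbours) means this is not an opening
            centroid = X[cyc].mean(axis=0)
            inside = tree.query_ball_point(centroid, 0.6 * layout.cutoff)
            if any(i not in key for i in inside):
                continue
        seen.add(key)
        rings.append(cyc)
    return rings


def pore_census(layout: MonomerLayout, max_ring: int = 6):
    """Enumerate junction openings and classify their pore sizes.

    3-rings are trimeric pores; 5-rings around vacancies are pentagonal
    disclination pores; any pore wider than 30 nm is labelled a defect
    (missing monomer).  Returns ``(reports, summary)`` with a per-type
    mean +- sd summary DataFrame.
    """
    g, coordination, disclinations = neighbour_graph(layout)
    rings = _hole_rings(g, layout, max_len=max_ring)
    reports = []
    for jid, cyc in enumerate(sorted(rings, key=lambda c: (len(c), sorted(c)))):
        d, resid = junction_pore(layout, cyc)
        if d > DEFECT_THRESHOLD_NM:
            kind = "defect"
        elif len(cyc) == 3:
            kind = "trimeric"
        elif len(cyc) == 5:
            kind = "pentagonal"
        else:
            kind = "defect"
        rep = PoreReport(jid, kind, d, tuple(sorted(cyc)), resid)
        if resid > 0.2 * layout.monomer_radius:
            rep.flags.append("non_planar")
        reports.append(rep)
    rows = []
    for kind in ("trimeric", "pentagonal", "defect"):
        ds = [r.pore_diameter for r in reports if r.kind == kind]
        if ds:
            rows.append({"kind": kind, "n": len(ds),
                         "mean_nm": float(np.mean(ds)),
                         "sd_nm": float(np.std(ds, ddof=1)) if len(ds) > 1 else 0.0})
    return reports, pd.DataFrame(rows)
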