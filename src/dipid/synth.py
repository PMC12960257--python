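"""Seeded generators for synthetic inputs to the analysis modules.

Three generators emulate the data the morphometry, pore and purity
pipelines consume:

* collapsed-container micrographs: filled ellipses with darker rims
  (negative-stain polarity) and additive Gaussian noise, with a ground
  truth table produced by the same circumference-preserving collapse
  model the analysis inverts (using the exact elliptic-integral
  perimeter, so the analysis' Ramanujan approximation is independently
  exercised);
* monomer-centre layouts: geodesic spheres (12 disclinations), rolled
  hexagonal-lattice tubes and planar sheets, with optional vacancies;
* two-channel membranes: a curvilinear band with labelled A/B segments,
  per-channel gains, cross-channel bleed and noise.

All generators are pure functions of their parameters including the
seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import ellipe
from skimage import draw

from .morphometry import Micrograph
from .pores import MonomerLayout

__all__ = [
    "SynthSpec",
    "SIZE_CLASSES",
    "BENCHMARK_IMAGING",
    "benchmark_spec",
    "exact_ellipse_perimeter",
    "render_collapsed_containers",
    "make_shell",
    "make_two_channel_membrane",
]

#: Measured container classes: mean and sd of the minor 3D diameter, nm.
SIZE_CLASSES = {
    "XS": (119.0, 14.0),
    "S": (166.0, 16.0),
    "M": (396.0, 51.0),
    "L": (513.0, 69.0),
    "XL": (862.0, 119.0),
    "XXL": (1200.0, 200.0),
}


#: Benchmark imaging conditions per class: (nm per pixel, image shape,
#: objects per field).  Magnification is chosen per class, as in TEM
#: practice, so that the monomer lattice is resolved (monomer radius
#: >= ~3 px) while a field holds several containers.
BENCHMARK_IMAGING = {
    "XS": (1.6, (600, 600), 5),
    "S": (2.2, (640, 640), 5),
    "M": (5.0, (900, 900), 6),
    "L": (5.0, (1100, 1100), 5),
    "XL": (5.0, (1500, 1500), 4),
    "XXL": (5.0, (1900, 1900), 3),
}


def benchmark_spec(size_class: str, seed: int) -> "SynthSpec":
    """Synthetic-micrograph spec for one of the six container classes
    under the standard benchmark imaging conditions."""
    mean, sd = SIZE_CLASSES[size_class]
    nm_per_px, shape, n = BENCHMARK_IMAGING[size_class]
    return SynthSpec(seed=seed, n_objects=n, d_minor_mean=mean,
                     d_minor_sd=sd, nm_per_pixel=nm_per_px,
                     image_shape=shape)


def exact_ellipse_perimeter(a: float, b: float) -> float:
    """Perimeter of an ellipse with semi-axes a >= b via the complete
    elliptic integral (the quadrature-grade reference for Ramanujan's
    approximation)."""
    if b > a:
        a, b = b, a
    if a == 0:
        return 0.0
    m = 1.0 - (b / a) ** 2
    return 4.0 * a * float(ellipe(m))


@dataclass
class SynthSpec:
    """Parameters of a synthetic collapsed-container micrograph."""

    seed: int
    n_objects: int = 8
    d_minor_mean: float = 396.0   # nm (M class)
    d_minor_sd: float = 51.0
    aspect_mean: float = 1.15
    aspect_sd: float = 0.1
    nm_per_pixel: float = 5.0
    image_shape: tuple = (900, 900)
    background: float = 0.8
    interior_contrast: float = -0.2    # interior relative to background
    rim_contrast: float = -0.5         # rim relative to background
    rim_width_nm: float = 15.0
    texture: bool = True               # monomer-lattice texture of the
    texture_contrast: float = -0.25    # collapsed membrane
    lattice_nm: float = 37.7
    monomer_radius_nm: float = 14.25
    noise_sd: float = 0.02
    margin_px: int = 8
    max_tries: int = 2000


def _forward_collapse(d_minor: float, d_major: float):
    """2D radii of a collapsed container (exact perimeter model)."""
    r_minor_2d = math.pi * d_minor / 4.0
    r_major_2d = exact_ellipse_perimeter(0.5 * d_major, 0.5 * d_minor) / 4.0
    return r_minor_2d, r_major_2d


def _draw_monomer_texture(img, spec: SynthSpec, rng, cy, cx, a_px, b_px, theta):
    """Stipple the collapsed membrane with a jittered hexagonal monomer
    lattice, the texture a monomer template-matching step keys on."""
    pitch = spec.lattice_nm / spec.nm_per_pixel
    r_mono = max(1.0, spec.monomer_radius_nm / spec.nm_per_pixel)
    n_u = int(2 * a_px / pitch) + 2
    n_v = int(2 * b_px / (pitch * math.sqrt(3) / 2)) + 2
    ct, st = math.cos(theta), math.sin(theta)
    for j in range(-n_v, n_v + 1):
        v = j * pitch * math.sqrt(3) / 2
        for i in range(-n_u, n_u + 1):
            u = (i + 0.5 * (j % 2)) * pitch
            uu = u + rng.normal(0, 0.08 * pitch)
            vv = v + rng.normal(0, 0.08 * pitch)
            if (uu / max(a_px - r_mono, 1)) ** 2 + (vv / max(b_px - r_mono, 1)) ** 2 > 1:
                continue
            # rotate by the skimage.draw.ellipse convention
            y = cy + vv * ct - uu * st
            x = cx + uu * ct + vv * st
            rr, cc = draw.disk((y, x), r_mono, shape=img.shape)
            img[rr, cc] += spec.texture_contrast * rng.uniform(0.6, 1.0)
    return img


def render_collapsed_containers(spec: SynthSpec):
    """Synthetic micrograph of collapsed containers plus ground truth.

    Returns ``(Micrograph, DataFrame)``; the table lists per object the
    true 3D diameters and the 2D radii implied by the collapse model.
    Raises if the requested objects cannot be placed without overlap.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_shape
    img = np.full((h, w), spec.background)
    rows = []
    placed = []  # (cy, cx, bounding radius px)
    for i in range(spec.n_objects):
        d_minor = max(spec.d_minor_mean + spec.d_minor_sd * rng.standard_normal(),
                      0.2 * spec.d_minor_mean)
        aspect = max(1.0, spec.aspect_mean + spec.aspect_sd * rng.standard_normal())
        d_major = aspect * d_minor
        r_min2d, r_maj2d = _forward_collapse(d_minor, d_major)
        a_px = r_maj2d / spec.nm_per_pixel
        b_px = r_min2d / spec.nm_per_pixel
        rim_px = max(1.0, spec.rim_width_nm / spec.nm_per_pixel)
        bound = a_px + rim_px + spec.margin_px
        theta = rng.uniform(0, math.pi)
        for attempt in range(spec.max_tries):
            cy = rng.uniform(bound, h - bound)
            cx = rng.uniform(bound, w - bound)
            if all((cy - py) ** 2 + (cx - px) ** 2 > (bound + pb) ** 2
                   for py, px, pb in placed):
                break
        else:
            raise RuntimeError(
                f"could not place object {i} without overlap; reduce "
                f"n_objects or enlarge the image")
        placed.append((cy, cx, bound))
        rr, cc = draw.ellipse(cy, cx, b_px + 0.5 * rim_px, a_px + 0.5 * rim_px,
                              shape=img.shape, rotation=theta)
        img[rr, cc] = spec.background + spec.rim_contrast
        rr, cc = draw.ellipse(cy, cx, b_px - 0.5 * rim_px, a_px - 0.5 * rim_px,
                              shape=img.shape, rotation=theta)
        img[rr, cc] = spec.background + spec.interior_contrast
        if spec.texture:
            _draw_monomer_texture(img, spec, rng, cy, cx, a_px, b_px, theta)
        rows.append({
            "object_id": i, "cy_px": cy, "cx_px": cx, "angle_rad": theta,
            "d_minor_nm": d_minor, "d_major_nm": d_major,
            "r_minor_2d_nm": r_min2d, "r_major_2d_nm": r_maj2d,
        })
    img += spec.noise_sd * rng.standard_normal(img.shape)
    return (Micrograph(img, spec.nm_per_pixel),
            pd.DataFrame(rows))


# -- monomer layouts ------------------------------------------------------

def _geodesic_sphere(freq: int):
    """Class-I geodesic subdivision of the icosahedron (frequency ``freq``):
    10 freq^2 + 2 vertices on the unit sphere, 12 of them 5-coordinated."""
    phi = (1 + math.sqrt(5)) / 2
    verts = np.array([
        [-1, phi, 0], [1, phi, 0], [-1, -phi, 0], [1, -phi, 0],
        [0, -1, phi], [0, 1, phi], [0, -1, -phi], [0, 1, -phi],
        [phi, 0, -1], [phi, 0, 1], [-phi, 0, -1], [-phi, 0, 1],
    ], dtype=float)
    verts /= np.linalg.norm(verts, axis=1)[:, None]
    faces = [(0, 11, 5), (0, 5, 1), (0, 1, 7), (0, 7, 10), (0, 10, 11),
             (1, 5, 9), (5, 11, 4), (11, 10, 2), (10, 7, 6), (7, 1, 8),
             (3, 9, 4), (3, 4, 2), (3, 2, 6), (3, 6, 8), (3, 8, 9),
             (4, 9, 5), (2, 4, 11), (6, 2, 10), (8, 6, 7), (9, 8, 1)]
    points = {}

    def key(p):
        return tuple(np.round(p, 9))

    for (ia, ib, ic) in faces:
        A, B, C = verts[ia], verts[ib], verts[ic]
        for i in range(freq + 1):
            for j in range(freq + 1 - i):
                p = (A * (freq - i - j) + B * i + C * j) / freq
                p = p / np.linalg.norm(p)
                points.setdefault(key(p), p)
    return np.array(list(points.values()))


def make_shell(kind: str, spacing: float = 37.7, size: int = 3,
               n_vacancies: int = 0, seed: int = 0,
               monomer_radius: float = 14.25, capped: bool = False,
               length: int = 10) -> MonomerLayout:
    """Monomer-centre layout of an ideal shell.

    Parameters
    ----------
    kind : str
        "sphere" (geodesic, ``size`` = subdivision frequency, giving
        ``10 size^2 + 2`` sites and exactly 12 disclinations), "tube"
        (rolled hexagonal lattice, ``size`` = monomers around the
        circumference, ``length`` rows; ``capped`` adds apex fans) or
        "sheet" (planar patch of ``size`` x ``length`` sites).
    spacing : float
        Nearest-neighbour centre distance, nm.
    n_vacancies : int
        Number of randomly removed sites (missing-monomer defects).
    """
    rng = np.random.default_rng(seed)
    if kind == "sphere":
        pts = _geodesic_sphere(size)
        # scale so the mean nearest-neighbour distance equals the spacing
        from scipy.spatial import cKDTree
        d, _ = cKDTree(pts).query(pts, k=2)
        pts = pts * (spacing / d[:, 1].mean())
    elif kind == "tube":
        m = size
        if m < 3:
            raise ValueError("tube circumference needs at least 3 monomers")
        radius = m * spacing / (2 * math.pi)
        rows = []
        for j in range(length):
            phase = (j % 2) * math.pi / m
            ang = 2 * math.pi * np.arange(m) / m + phase
            z = j * spacing * math.sqrt(3) / 2
            rows.append(np.stack([radius * np.cos(ang),
                                  radius * np.sin(ang),
                                  np.full(m, z)], axis=1))
        pts = np.concatenate(rows)
        if capped:
            z0, z1 = -spacing * math.sqrt(3) / 2, (length) * spacing * math.sqrt(3) / 2
            pts = np.concatenate([pts, [[0, 0, z0], [0, 0, z1]]])
    elif kind == "sheet":
        rows = []
        for j in range(length):
            x = np.arange(size) * spacing + (j % 2) * spacing / 2
            y = np.full(size, j * spacing * math.sqrt(3) / 2)
            rows.append(np.stack([x, y, np.zeros(size)], axis=1))
        pts = np.concatenate(rows)
    else:
        raise ValueError(f"unknown shell kind {kind!r}")

    if n_vacancies:
        if n_vacancies >= len(pts):
            raise ValueError("cannot remove more sites than exist")
        drop = rng.choice(len(pts), size=n_vacancies, replace=False)
        pts = np.delete(pts, drop, axis=0)
    # the generator knows its own lattice constant, so the bond cutoff sits
    # between first (1.0-1.15 x spacing on the geodesic) and second
    # (sqrt(3) x spacing) neighbour shells
    return MonomerLayout(pts, monomer_radius=monomer_radius,
                         cutoff=1.3 * spacing)


# -- two-channel membranes ------------------------------------------------

def make_two_channel_membrane(domains=(("A", 0.5), ("B", 0.5)),
                              gains=(1.0, 1.0), bleed: float = 0.0,
                              seed: int = 0, shape=(512, 512),
                              nm_per_pixel: float = 12.5,
                              thickness_px: int = 6,
                              noise_sd: float = 0.01,
                              amplitude: float = 0.25):
    """Synthetic two-channel image of a membrane with A/B domains.

    The membrane is a gently curved band crossing the image; ``domains``
    lists (label, arc fraction) segments along it.  B-type material emits
    in channel 1 and A-type in channel 2; ``bleed`` leaks a fraction of
    each species' signal into the other channel and ``gains`` scale the
    channels independently.  Returns ``(Micrograph, truth)`` where truth
    tabulates the domain label per membrane arc position.
    """
    if min(gains) <= 0:
        raise ValueError("channel gains must be positive")
    rng = np.random.default_rng(seed)
    h, w = shape
    t = np.linspace(0.05, 0.95, 4 * max(h, w))
    xs = t * (w - 1)
    ys = h * (0.5 + amplitude * np.sin(2 * math.pi * (t - 0.05) / 0.9))

    bounds = np.cumsum([0.0] + [frac for _, frac in domains])
    bounds /= bounds[-1]
    labels = []
    for u in t:
        frac = (u - t[0]) / (t[-1] - t[0])
        k = min(np.searchsorted(bounds, frac, side="right") - 1, len(domains) - 1)
        labels.append(domains[k][0])

    sig_b = np.zeros(shape)   # B-type material (channel-1 label)
    sig_a = np.zeros(shape)
    for x, y, lab in zip(xs, ys, labels):
        rr, cc = draw.disk((y, x), thickness_px, shape=shape)
        if lab == "B":
            sig_b[rr, cc] = 1.0
        elif lab == "A":
            sig_a[rr, cc] = 1.0
        else:  # "AA": the homogeneously mixed calibration control carries
            # both labels in equal amounts per pixel
            sig_a[rr, cc] = 0.5
            sig_b[rr, cc] = 0.5
    ch1 = gains[0] * (sig_b + bleed * sig_a)
    ch2 = gains[1] * (sig_a + bleed * sig_b)
    ch1 += noise_sd * rng.standard_normal(shape)
    ch2 += noise_sd * rng.standard_normal(shape)
    truth = pd.DataFrame({"t": t, "x_px": xs, "y_px": ys, "domain": labels})
    img = Micrograph(np.stack([ch1, ch2]), nm_per_pixel,
                     channel_labels=("ch488", "ch565"))
    return img, truth
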