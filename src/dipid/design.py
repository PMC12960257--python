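"""Curvature-to-sequence design engine for Dipid monomers.

A Dipid is a radially symmetric DNA origami barrel carrying 30 binding
strands arranged in alternating groups of two and three around its
circumference.  Each strand is built from three domains:

* a ``flex`` domain (oligo-dT, mT in {2, 4, 8, 16} nt) that provides
  monomer--monomer flexibility,
* an optional ``curvature`` domain (oligo-dT, nT in 0--52 nt) whose
  asymmetric extension turns the cylindrical monomer into a cone,
* a weak palindromic ``sticky`` domain (xN in {4, 6, 8} nt) that
  hybridizes with the identical domain on a neighbouring monomer.

The cone geometry is modelled as an annular wedge: a monomer of width
``w`` and height ``h`` plus half of the inter-monomer gap on each face.
With gap ``g = 2 l_strand`` per face (both partners contribute one
strand and share the hybridized sticky duplex) the wedge angle is

    alpha = 2 atan((g_out - g_in) / (2 h)),

and the mid-height radius of the assembled shell is

    r = s_mid / alpha_rad,   s_mid = w + (g_in + g_out) / 2.

Curvature extensions are applied to a fixed subset of 24 of the 30
strands (both strands of every group of two plus two of the three in
every group of three); the remaining six strands sit on the opposite
barrel face and never change, so switching between design classes
exchanges exactly 24 strands.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

from .wlc import WLCParams, wlc_end_to_end

__all__ = [
    "DomainSpec",
    "MonomerGeometry",
    "DipidDesign",
    "DesignRangeError",
    "validate_sticky",
    "reverse_complement",
    "strand_length",
    "cone_angle",
    "predict_radius_naive",
    "invert_diameter_to_angle",
    "angle_error",
    "solve_curvature_length",
    "enumerate_designs",
    "generate_variant",
    "VARIANT_TARGETS",
    "FLEX_MENU",
    "STICKY_MENU",
    "CURVATURE_MENU",
    "DEFAULT_STICKY",
    "GEOMETRY_30NM",
    "GEOMETRY_60NM",
]

FLEX_MENU = (2, 4, 8, 16)
STICKY_MENU = (4, 6, 8)
CURVATURE_MENU = tuple(range(0, 53))

#: Default weak (AT-rich) palindromic sticky sequences, one per menu length.
DEFAULT_STICKY = {4: "TATA", 6: "TATATA", 8: "TAATATTA"}

_COMPLEMENT = str.maketrans("ACGT", "TGCA")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (alphabet ACGT, uppercase)."""
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-DNA characters in sequence {seq!r}")
    return seq.translate(_COMPLEMENT)[::-1]


def validate_sticky(seq: str) -> bool:
    """True iff ``seq`` is an even-length palindrome (self-reverse-complementary).

    Only palindromic sticky domains hybridize with a copy of themselves,
    which is what allows a single monomer species to self-assemble.
    """
    seq = seq.upper()
    if set(seq) - set("ACGT"):
        raise ValueError(f"non-DNA characters in sequence {seq!r}")
    if len(seq) % 2:
        return False
    return seq == reverse_complement(seq)


@dataclass(frozen=True)
class DomainSpec:
    """One binding strand: flex + curvature (oligo-dT) + sticky domain.

    ``face`` records which barrel face the strand protrudes from; the
    inter-monomer gap on a face is twice the strand length on that face.
    """

    flex_len: int
    sticky_seq: str
    curvature_len: int = 0
    face: str = "outer"

    def __post_init__(self) -> None:
        if self.flex_len not in FLEX_MENU:
            raise ValueError(f"flex_len {self.flex_len} not in menu {FLEX_MENU}")
        if len(self.sticky_seq) not in STICKY_MENU:
            raise ValueError(
                f"sticky length {len(self.sticky_seq)} not in menu {STICKY_MENU}"
            )
        if not validate_sticky(self.sticky_seq):
            raise ValueError(f"sticky sequence {self.sticky_seq!r} is not palindromic")
        if not (0 <= self.curvature_len <= CURVATURE_MENU[-1]):
            raise ValueError(f"curvature_len {self.curvature_len} outside 0..52")
        if self.face not in ("inner", "outer"):
            raise ValueError(f"face must be 'inner' or 'outer', got {self.face!r}")

    @property
    def full_sequence(self) -> str:
        """Complete strand 5'->3': flex dT, curvature dT, sticky domain."""
        return "T" * self.flex_len + "T" * self.curvature_len + self.sticky_seq


@dataclass(frozen=True)
class MonomerGeometry:
    """Rigid dimensions of the origami barrel, nm."""

    barrel_diameter: float = 28.5
    height: float = 18.0
    internal_pore: float = 19.0
    n_binding: int = 30

    def __post_init__(self) -> None:
        if self.internal_pore >= self.barrel_diameter:
            raise ValueError("internal pore must be smaller than the barrel diameter")
        if self.barrel_diameter <= 0 or self.height <= 0:
            raise ValueError("barrel dimensions must be positive")


GEOMETRY_30NM = MonomerGeometry(barrel_diameter=28.5, height=18.0,
                                internal_pore=19.0, n_binding=30)
# 60-nm class: internal pore scaled from the 30-nm layout (assumption; the
# strand layout mirrors the 30-nm barrel).
GEOMETRY_60NM = MonomerGeometry(barrel_diameter=57.0, height=18.0,
                                internal_pore=38.0, n_binding=30)

# Strand groups: six groups of two and six of three, alternating around the
# barrel.  Outer-face strands (24 in total) carry the curvature extension;
# the third strand of every group of three sits on the inner face.
_GROUP_SIZES = (2, 3) * 6


def _build_strands(flex_len: int, sticky_seq: str, curvature_len: int) -> tuple:
    strands = []
    for size in _GROUP_SIZES:
        for k in range(size):
            inner = size == 3 and k == 2
            strands.append(
                DomainSpec(
                    flex_len=flex_len,
                    sticky_seq=sticky_seq,
                    curvature_len=0 if inner else curvature_len,
                    face="inner" if inner else "outer",
                )
            )
    return tuple(strands)


def strand_groups() -> tuple:
    """Group id of each of the 30 strands, following the alternating 2/3 layout."""
    out = []
    for gid, size in enumerate(_GROUP_SIZES):
        out.extend([gid] * size)
    return tuple(out)


@dataclass(frozen=True)
class DipidDesign:
    """A single monomer variant with derived cone angle and naive radius."""

    name: str
    geometry: MonomerGeometry
    strands: tuple  # 30 DomainSpec, grouped 2/3 alternating
    cone_angle_naive: float  # degrees
    radius_naive: float  # nm (inf for planar designs)
    diameter_calibrated: float | None = None
    wlc: WLCParams = field(default_factory=WLCParams)

    def __post_init__(self) -> None:
        if len(self.strands) != self.geometry.n_binding:
            raise ValueError(
                f"{len(self.strands)} strands != n_binding {self.geometry.n_binding}"
            )
        if self.cone_angle_naive > 0 and not self.radius_naive > 0:
            raise ValueError("positive cone angle requires a positive radius")

    @property
    def diameter_naive(self) -> float:
        return 2.0 * self.radius_naive

    @property
    def is_planar(self) -> bool:
        return self.cone_angle_naive == 0.0

    def face_strand(self, face: str) -> DomainSpec:
        for s in self.strands:
            if s.face == face:
                return s
        raise ValueError(f"no strand on face {face!r}")

    def gap(self, face: str, params: WLCParams | None = None) -> float:
        """Inter-monomer gap on ``face``: two strands share one sticky duplex."""
        return 2.0 * strand_length(self.face_strand(face), params or self.wlc)

    def s_mid(self, params: WLCParams | None = None) -> float:
        p = params or self.wlc
        return self.geometry.barrel_diameter + 0.5 * (self.gap("inner", p) + self.gap("outer", p))


def strand_length(domain: DomainSpec, params: WLCParams = WLCParams()) -> float:
    """Physical length of one binding strand, nm.

    WLC end-to-end length of the single-stranded flex+curvature part plus
    half the duplex length of the sticky domain (the duplex is shared
    between the two hybridized strands).
    """
    Lc_ss = (domain.flex_len + domain.curvature_len) * params.rise_ss
    return wlc_end_to_end(Lc_ss, params) + 0.5 * len(domain.sticky_seq) * params.rise_ds


def cone_angle(design: DipidDesign, params: WLCParams | None = None) -> float:
    """Wedge angle of the monomer plus its half-gaps, degrees.

    Negative when the inner gap exceeds the outer gap (inverted curvature);
    zero for a symmetric (cylindrical) monomer.
    """
    p = params or design.wlc
    g_out = design.gap("outer", p)
    g_in = design.gap("inner", p)
    return math.degrees(2.0 * math.atan((g_out - g_in) / (2.0 * design.geometry.height)))


def predict_radius_naive(design: DipidDesign, params: WLCParams | None = None) -> float:
    """Mid-height radius of the assembled shell, nm.

    ``r = s_mid / alpha_rad`` with ``s_mid`` the monomer width plus the mean
    gap.  Returns ``inf`` for planar designs (alpha == 0) and raises for
    inverted (negative-alpha) designs, which have no finite outward radius.
    """
    p = params or design.wlc
    alpha_rad = math.radians(cone_angle(design, p))
    if alpha_rad < 0:
        raise ValueError(f"design {design.name!r} has inverted curvature (alpha < 0)")
    if alpha_rad == 0:
        return math.inf
    return design.s_mid(p) / alpha_rad


def invert_diameter_to_angle(d_minor_exp: float, design: DipidDesign,
                             params: WLCParams | None = None) -> float:
    """Cone angle implied by a measured minor diameter, degrees.

    Exact inverse of :func:`predict_radius_naive` holding ``s_mid`` at the
    design value: ``alpha_exp = 2 s_mid / d_minor_exp`` (radians).
    """
    if d_minor_exp <= design.geometry.barrel_diameter:
        raise ValueError("measured diameter must exceed the barrel diameter")
    return math.degrees(2.0 * design.s_mid(params or design.wlc) / d_minor_exp)


def angle_error(d_minor_exp: float, design: DipidDesign) -> float:
    """Design-minus-experiment cone angle, degrees (positive when the
    assembled structure is larger than designed)."""
    return design.cone_angle_naive - invert_diameter_to_angle(d_minor_exp, design)


class DesignRangeError(ValueError):
    """Target diameter unreachable within the given domain-length menus."""

    def __init__(self, target: float, d_small: float, d_large: float):
        self.target = target
        self.nearest = (d_small, d_large)
        super().__init__(
            f"target diameter {target:.1f} nm is out of design range; achievable "
            f"naive diameters span [{d_small:.1f}, {d_large:.1f}] nm for these menus"
        )


def _design_for(nT: int, flex_len: int, sticky_seq: str, geometry: MonomerGeometry,
                params: WLCParams, name: str = "custom") -> DipidDesign:
    strands = _build_strands(flex_len, sticky_seq, nT)
    d = DipidDesign(name=name, geometry=geometry, strands=strands,
                    cone_angle_naive=0.0, radius_naive=math.inf, wlc=params)
    alpha = cone_angle(d, params)
    r = d.s_mid(params) / math.radians(alpha) if alpha > 0 else math.inf
    return replace(d, cone_angle_naive=alpha, radius_naive=r)


def solve_curvature_length(target_diameter: float, geometry: MonomerGeometry = GEOMETRY_30NM,
                           flex_len: int = 8, sticky_seq: str | None = None,
                           params: WLCParams = WLCParams(),
                           name: str = "custom") -> DipidDesign:
    """Find the integer curvature-domain length whose naive diameter is
    closest to ``target_diameter`` (ties broken toward smaller nT).

    Raises :class:`DesignRangeError` when the target lies outside the span
    of achievable naive diameters for the given flex/sticky choice.
    """
    if sticky_seq is None:
        sticky_seq = DEFAULT_STICKY[6]
    if target_diameter <= geometry.barrel_diameter:
        raise ValueError("target diameter must exceed the barrel diameter")
    candidates = [
        _design_for(nT, flex_len, sticky_seq, geometry, params, name)
        for nT in CURVATURE_MENU[1:]  # nT = 0 is planar, no finite diameter
    ]
    diameters = [c.diameter_naive for c in candidates]
    d_small, d_large = min(diameters), max(diameters)
    if not (d_small <= target_diameter <= d_large):
        raise DesignRangeError(target_diameter, d_small, d_large)
    # stable: scan in increasing-nT order, strict improvement only -> smaller
    # nT wins ties
    best = min(candidates, key=lambda c: abs(c.diameter_naive - target_diameter))
    return best


def enumerate_designs(flex_menu=FLEX_MENU, sticky_menu=STICKY_MENU,
                      curvature_menu=CURVATURE_MENU,
                      geometry: MonomerGeometry = GEOMETRY_30NM,
                      params: WLCParams = WLCParams(),
                      dedup_radius_nm: float = 0.0):
    """Enumerate designs over the full menu grid.

    Returns ``(designs, meta)`` where ``meta`` documents the raw grid size,
    the deduplication rule and the deduplicated count.  With
    ``dedup_radius_nm > 0`` designs whose predicted radii round to the same
    multiple of that resolution are collapsed (keeping the first in menu
    order); all planar designs collapse to one.
    """
    designs = []
    for flex in flex_menu:
        for xN in sticky_menu:
            sticky = DEFAULT_STICKY[xN]
            for nT in curvature_menu:
                designs.append(
                    _design_for(nT, flex, sticky, geometry, params,
                                name=f"m{flex}x{xN}n{nT}")
                )
    raw_count = len(designs)
    if dedup_radius_nm > 0:
        seen, kept = set(), []
        for d in designs:
            key = ("planar" if d.is_planar
                   else round(d.radius_naive / dedup_radius_nm))
            if key not in seen:
                seen.add(key)
                kept.append(d)
        designs = kept
    meta = {
        "raw_grid": raw_count,
        "dedup_rule": f"predicted radius rounded to {dedup_radius_nm} nm"
        if dedup_radius_nm > 0 else "none",
        "count": len(designs),
    }
    return designs, meta


#: Experimentally characterized classes: (geometry, flex length, sticky
#: length, target naive diameter in nm).  The 30-nm targets are the mean
#: measured container diameters of the six classes; for the two smallest
#: classes measured and designed diameters coincide.  The 60-nm variants
#: reuse the 30-nm targets of their namesakes with the larger barrel and
#: the 8T/16T flex split of that series.
VARIANT_TARGETS = {
    "XS": (GEOMETRY_30NM, 8, 6, 119.0),
    "S": (GEOMETRY_30NM, 8, 6, 166.0),
    "M": (GEOMETRY_30NM, 8, 6, 396.0),
    "L": (GEOMETRY_30NM, 8, 6, 513.0),
    "XL": (GEOMETRY_30NM, 8, 6, 862.0),
    "XXL": (GEOMETRY_30NM, 8, 6, 1200.0),
    "M60": (GEOMETRY_60NM, 8, 6, 396.0),
    "L60": (GEOMETRY_60NM, 8, 6, 513.0),
    "XL60": (GEOMETRY_60NM, 16, 6, 862.0),
    "XXL60": (GEOMETRY_60NM, 16, 6, 1200.0),
}


def generate_variant(name: str, params: WLCParams = WLCParams()) -> DipidDesign:
    """Return one of the named monomer classes (XS .. XXL, M60 .. XXL60).

    Deterministic: the class target diameter is solved through
    :func:`solve_curvature_length` with the class menus.
    """
    try:
        geometry, flex, xN, target = VARIANT_TARGETS[name]
    except KeyError:
        raise ValueError(
            f"unknown variant {name!r}; known: {sorted(VARIANT_TARGETS)}"
        ) from None
    return solve_curvature_length(target, geometry, flex, DEFAULT_STICKY[xN],
                                  params, name=name)
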