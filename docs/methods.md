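# Methods

This note documents the models implemented in `dipid`, their parameters
and the choices made where the underlying methodology leaves room.

## Strand-length model (worm-like chain)

Binding strands are single-stranded except for the hybridized sticky
duplex. The physical length of a strand is

    l_strand = sqrt(2 Lp^2 (Lc/Lp - 1 + exp(-Lc/Lp))) + 1/2 Lc(dsDNA),

the RMS end-to-end distance of a worm-like chain of contour length
`Lc(ssDNA) = (mT + nT) * 0.63 nm` plus half the duplex length
`xN * 0.34 nm` (the duplex is shared between the two bound strands).
Constants: 0.63 nm per ssDNA nucleotide, 0.34 nm per base pair,
persistence length Lp = 1.5 nm. The closed form is cross-checked in the
test suite against a discrete-chain Monte-Carlo sampler with
exponentially decaying tangent correlations.

The interpolation formula describes ideal chains; for the shortest
domains (a few nucleotides) excluded volume, base stacking and the
anchoring geometry are not represented. This is one reason measured
container diameters deviate from naive predictions, which the two-regime
calibration absorbs empirically.

## Cone model and diameter prediction

A monomer of width `w` (28.5 or 57 nm) and height `h = 18 nm` plus half
its inter-monomer gaps is treated as an annular wedge. With per-face
gaps `g = 2 l_strand` (each partner contributes one strand),

    alpha = 2 atan((g_out - g_in) / (2 h)),
    r     = s_mid / alpha_rad,   s_mid = w + (g_in + g_out) / 2.

`alpha` is the in-membrane wedge angle a monomer subtends and `r` the
mid-height radius of the closed assembly; `d_naive = 2 r`. Inverting at
fixed `s_mid` maps measured diameters back to experimental cone angles.

Strand layout: 30 strands in six groups of two and six of three. The 24
outer-face strands (both strands of each pair, two of three in each
triple) carry the curvature extension `nT`; the six inner-face strands
never change, so converting one class into another exchanges exactly 24
strands. Class menus: flex 8T and sticky 6N (`TATATA`) for the 30-nm
classes; the 60-nm series uses 8T (M60, L60) or 16T (XL60, XXL60).
With these menus the solver reproduces the known design classes from
their target diameters alone (e.g. a 119-nm target solves to nT = 50,
r = 59.7 nm).

Default sticky sequences are weak AT-rich palindromes (`TATA`,
`TATATA`, `TAATATTA`); sequence-level orthogonality screening is out of
scope and users may supply their own palindromes.

## Two-regime calibration

Measured diameters deviate from `d_naive` nearly linearly with a slope
change between small and large structures. The refinement is a
continuous piecewise-linear map `d_cal = c0 + c1 d + c2 max(0, d - b)`,
linear in `(c0, c1, c2)` at fixed breakpoint `b`; `b` is chosen by an
exhaustive scan (default 10-nm resolution) minimizing the summed squared
residual. Containers and tubes are calibrated separately.

## Assembly simulation

The growth simulator is a bead-spring model of a triangulated elastic
sheet: beads are monomer centres (rest spacing `l0 = 37.7 nm`, the
30-nm barrel plus the mean gap of the mid-sized designs), triangles the
local close packing. Energy:

    E = sum_edges 1/2 ks (l - l0)^2 + sum_hinges kb (1 - cos(theta - theta0)),

with `ks = 1` (arbitrary units), `kb = ks l0^2 / 10`, and the
spontaneous hinge angle `theta0` set equal to the simulated cone angle
`alpha_sim`. Note `alpha_sim` and the design-model `alpha_naive` are
different scales (they are also plotted as distinct axes in the
experimental aspect-ratio comparison); we do not convert between them.

Growth rules, per step:

1. If the rim opening at a vertex with at least four incident triangles
   falls below `beta_merge` — measured as the 3D angle between its two
   rim edges — the wedge is closed by bonding the rim edges. Closure at
   four triangles creates a pentagonal (5-coordinated) disclination;
   at five it completes an ordinary hexamer.
2. Otherwise one monomer is added on a rim edge, placed at the
   equilateral position tilted by `theta0`. The site is the wedge with
   the smallest intrinsic opening angle (360 minus the covered corner
   angles), i.e. the most-embracing, lowest-binding-energy site; with
   probability `p_random = 0.05` a uniformly random rim site is used
   instead, which reproduces morphological polymorphism at constant
   cone angle.
3. The sheet is re-relaxed (L-BFGS with analytic gradients; vertices
   within three rings of the modified site every step, the whole sheet
   every tenth step and at the end). Growth stops at closure or at
   `max_monomers` (default 300).

`beta_merge` defaults to 110°. The flat-lattice four-triangle wedge
measures 120° and must never close (flat sheets have no disclinations);
wedges folded well beyond the preferred curvature fall below 110° and
nucleate pentagons. This calibration controls where the tube-to-spheroid
transition sits; much stricter thresholds (say 70°) suppress
disclinations entirely and only hexagonal sheets and tubes form.

Classification: a closed mesh with principal-extent aspect ratio
`a = d_major/d_minor <= 1.6` is a spheroid, a closed elongated mesh a
tube; open meshes are tubes when elongated beyond 1.6 and "open"
otherwise. Extents are peak-to-peak spans along the principal axes of
the vertex covariance, with `d_minor` the middle extent.

At the default desk-scale conditions (sweep 4–12° in 0.3° steps, 10
seeded replicates, ≤300 monomers) the spheroid fraction rises from 0 to
1 between roughly 7.5° and 8.5°; the reported transition is the smallest
swept angle with any closed spheroid. The experimental boundary is
reported near 6.3°; the difference is within the uncertainty of the
merge-rule calibration, which the source methodology does not pin down.
Runs with a 700-monomer budget or with full relaxation every other step
do not close below 7.3°, so the onset is not a budget or relaxation
artefact. Heptamers (7-coordinated sites) occur occasionally next to
pentamers; the net charge `sum(6 - coordination)` is exactly 12 for
every closed shell (Euler), which the tests assert.

The model is athermal (deterministic gradient-flow relaxation, no
Langevin noise), has no excluded volume and no long-range rim fusion, so
rolled sheets cannot zip into tubes; at desk scale sub-transition runs
typically end as open curved sheets rather than closed tubes. It also
cannot reproduce amorphous packing of the smallest containers.

## Collapsed-projection morphometry

Containers flatten on the grid; flattening preserves circumference.
For the minor axis `d_minor = 4 r_minor_2D / pi`; for the major axis
`d_major` solves `P(d_major/2, d_minor/2) = 4 r_major_2D` with
Ramanujan's perimeter approximation (relative error < 0.1% for aspect
ratios up to 4, verified against the complete elliptic integral), by
bracketed root finding (`brentq`, bracket `[d_minor, 4 r_major_2D/pi +
d_minor]`). Tubes: `d = 2 w_2D / pi`.

Measurement pipeline: normalized cross-correlation with a dark-disc
monomer template (radius 14.25 nm), thresholded at
`clip(3/sqrt(Npix), 0.3, 0.5)` (three noise-floor standard deviations of
the template size), morphological closing at 0.75 lattice pitches, hole
filling, labelling; regions must exceed 2.5 lattice pitches squared, and
border-touching regions are excluded from statistics. The final ellipse
per region is fitted to rim-centerline points located as the outermost
intensity minimum along 180 radial rays (immune to the interior lattice
texture); the direct least-squares conic fit to the region contour is
the fallback and remains available as `fit_ellipse`. Size distributions
are summarized as mean ± sample SD plus a Gaussian KDE with Silverman
bandwidth.

Composition estimates model the container as a prolate spheroid
(closed-form surface area, verified against quadrature) tiled
hexagonally with footprint `sqrt(3)/2 s_mid^2`; the default monomer
mass is the 30-nm scaffold, 2,873 bp × 650 Da.

## Pore analysis

Monomers are hard discs of the barrel radius (14.25 nm by default; an
optional inflation parameter represents a strand corona under weak
screening). Bonds connect centres within 1.35 barrel diameters (the
synthetic generators, knowing their own lattice constant, use 1.3×
spacing). Junction openings are chordless rings of the bond graph with
no monomer at the ring centre: 3-rings are trimeric pores, 5-rings
pentagonal disclination pores, anything else — or any pore wider than
30 nm — a missing-monomer defect. The pore is the largest inscribed
circle: in the junction's best-fit plane, Nelder–Mead from the centroid
maximizes the minimal clearance to any nearby disc edge (tolerance
1e-4 nm). Reference values at R = 14.25 nm: three tangent discs
2R(2/sqrt(3)-1) ≈ 4.409 nm; a five-disc tangent ring
2R(1/sin 36° - 1) ≈ 19.99 nm. Five-coordinated sites are reported as
disclinations only when interior (their neighbours surround them with
no angular gap above 100°), so patch borders are not miscounted.

## Synthetic data

The generators are pure functions of their parameters including the
seed.

*Collapsed containers*: ellipses with a dark rim (negative-stain
polarity) and a jittered hexagonal monomer-lattice texture (pitch
37.7 nm), additive Gaussian noise (SD 0.02 on a 0.8 background),
non-overlapping placement by rejection sampling. Ground truth records
the true 3D diameters and the 2D radii of the collapse model computed
with the exact elliptic-integral perimeter, so the analysis' Ramanujan
route is exercised independently. The six benchmark classes use the
measured class means and SDs (119±14 … 1200±200 nm) with per-class
magnification chosen so the monomer radius is at least ~3 px.
Aspect ratios are drawn from N(1.15, 0.1) clipped at 1. What passing
the 3% recovery benchmark shows is that segmentation, ellipse fitting
and the collapse inversion are unbiased on well-separated, moderately
noisy structures; it does not certify performance on real micrographs
with CTF, uneven stain, overlaps or rupture.

*Shell layouts*: class-I geodesic spheres (frequency h, 10h²+2 sites,
exactly 12 five-coordinated), rolled hexagonal tubes (radius =
m·spacing/2π), planar sheets; optional random vacancies.

*Two-channel membranes*: a sinusoidal band with labelled segments; B
material emits in channel 1, A in channel 2, an "AA" label (the
homogeneously mixed calibration control) emits equally in both;
per-channel gains, symmetric bleed-through fraction, Gaussian noise.
Purity profiling averages each channel over ±20 px orthogonal to the
skeleton tangent and computes `I_c488/(I_c488+I_c565)`; gain factors are
recovered from the A–A control by equalizing the channel means.

## Numerical notes

- Dihedral angles are signed (positive = convex under outward winding);
  gradients use the standard four-point dihedral derivatives, verified
  against finite differences to 1e-5.
- The compiled (numba) energy kernel and the vectorized numpy path
  implement the same functional and are cross-asserted to 1e-12.
- Solver tie-breaks: integer `nT` ties resolve toward smaller nT;
  candidate merge wedges resolve toward the smallest opening.
- Degenerate inputs: zero-area triangles raise; collinear point clouds
  raise in aspect-ratio computation; sub-20-pixel regions are skipped;
  ellipse fits inconsistent with the collapse model are flagged and
  fall back to `d_major = d_minor`.

## Problem sizes

Defaults throughout are desk-scale: growth runs cap at 300 monomers,
the angle sweep uses 27 angles × 10 replicates, synthetic micrograph
benchmarks use 3–6 containers per class, and the discrete-chain WLC
check uses 4,000 chains of 400 segments.
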