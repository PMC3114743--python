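# Methods

## The representation

A 2D microscopy image is digitized into a *polygonal mesh*: a partition of
the image rectangle into convex Voronoi cells ("subcompartments") whose
corner coordinates are stored explicitly, so that meshes edited by hand —
including non-convex polygons — load and analyze identically to generated
ones. Working on an abstract mesh rather than on pixels lets the
digitization precision vary per compartment and gives the simulation and
the image the same discretization, so they can be compared cell by cell.

Conventions: 0-based pixel grid in image orientation (x right, y down);
pixel `(row r, col c)` has center `(c + 0.5, r + 0.5)`; the bounding box of
an `H×W` image is `(0, 0, W, H)`. "Volume" `V_i` is the polygon area
(px²) and "contact surface" `S_in` the shared-edge length (px) — the
consistent 2D reading of the finite-volume quantities.

### Meshing

Default seeds form a triangular lattice with spacing `d` (row pitch
`d·√3/2`, odd rows offset by `d/2`), whose Voronoi cells are equilateral
hexagons of area `(√3/2)·d²`; `d` is the resolution knob (default 4 px —
small enough that a ~45 px nucleus contains ~400 cells). Region rules
`(mask, spacing)` substitute denser or sparser lattices inside masked
regions, later rules overriding earlier ones where masks overlap.

Cells are clipped to the image rectangle by mirroring all seeds across the
four bbox edges before tessellating: the bisector between a seed and its
mirror image is exactly the edge, so every original cell is finite,
bounded by the bbox, and the partition invariant (areas summing to the
bbox area to 1e-9 relative) holds by construction. Seeds closer than
1e-9 px are deduplicated. Adjacency is computed from polygon boundary
intersections (an STR-tree prunes candidate pairs), so it is exact for
generated meshes and still correct for hand-edited ones; shared single
vertices (contact length ≤ 1e-9 px) are not neighbours — a point contact
carries no flux.

### Digitization

Pixel ownership is a containment test, polygons visited in ascending id so
that a pixel center on a shared edge — the equidistant tie of a Voronoi
mesh — deterministically belongs to the lower id. Typing applies binary
masks in user order: a subcompartment takes a mask's label when at least
half of its pixel centers lie in the mask, later masks overwriting earlier
assignments (the remedy for overlapping masks is reordering them);
subcompartments matched by no mask get the default label. A marker mask
smaller than half of every subcompartment it touches can never win a vote,
so the workflow layer applies such masks by point assignment
(`apply_point_masks`) — this is how a single marked pixel suffices to type
the shmoo tip. The same rule deliberately does *not* spread large-but-thin
unmatched masks (a 2 px membrane ring on a coarse mesh): retyping every
touched cell would inflate the compartment several-fold and can sever the
diffusion domain.

Signal acquisition stores the plain arithmetic mean of the raw sample
values (a.u., no rescaling) of a subcompartment's pixels. Subcompartments
owning no pixels get NaN and are excluded from all statistics, rather than
a silent zero that would bias compartment means.

### Analysis

Compartment means are area-weighted, `Σ(V_i·x_i)/Σ V_i`, which
approximates the per-pixel average a tool like ImageJ reports over the
same mask (polygon area stands in for pixel count). Axis profiles select
subcompartments by type whose centroid falls in a horizontal band and plot
value against centroid x; angular profiles use the signed CCW angle, in
[−π, π), between a reference direction (typically nucleus center → shmoo
tip) and the centroid direction. `fit_log_slope` recovers the decay
constant of an exponential profile by least squares on log values.

## The kinetic model

One species (Fus3PP), one scalar per subcompartment. Compartment types map
to four roles: **A** cytoplasm (diffusion + first-order dephosphorylation
at rate β, time⁻¹), **B** shmoo tip (diffusion + zeroth-order release at
rate α, a.u.·time⁻¹), **blocked** membranes (no equation — the Iverson
bracket removes flux into them, implementing impermeability), **outside**
(no equation). Diffusive exchange between i and n uses weight
`w_in = S_in` in `paper_literal` mode (γ in px·time⁻¹) or `S_in/d_in`
with the centroid distance `d_in` in `distance_normalized` mode (γ in
px²·time⁻¹). The literal form is the model's plain reading from the
contact-surface/volume symbols; the distance-normalized form is the
standard consistent cell-centered Laplacian and is the right choice when
cell sizes vary (its continuum limit is γ∇²C independent of resolution).
Both are kept because the choice changes γ's meaning, and published
parameter sets such as (α, β, γ) = (0.1, 0.1, 50) are mode-specific.
Time units are arbitrary; rates are bare numbers.

The assembled system is linear, `dC/dt = M C + b`, with `M` sparse and
rows of blocked/outside cells identically zero (their values are constants
of the motion, so digitized initial conditions persist there).
Integration uses SciPy's BDF with `M` as the exact Jacobian; default
tolerances rtol 1e-8 / atol 1e-10 (1e-10/1e-12 inside steady-state
detection). `steady_state` advances in geometrically growing chunks until
`max_i |dC_i/dt| / max(1, max_i C_i) < tol` (default 1e-8) within a time
budget of 1e6; exhaustion raises an error carrying the residual — which
is also the honest outcome for genuinely non-stationary systems such as an
isolated source cell, whose concentration grows linearly forever.
Properties verified in the test suite: exact mass conservation with
α = β = 0 (flux antisymmetry), non-negativity, blocked cells constant,
agreement with the direct sparse solve of `M C = −b` on small meshes, and
the closed forms `C_A = α/β`, `C_B = C_A + α V_B/(γ w)` (two cells) and
the geometric interior decay of a 1D chain with ratio the root in (0,1)
of `γw(x − 2 + 1/x) = βV`.

### Fitting rates to an image

`fit_to_image` estimates (α, β) at fixed γ from a digitized image: the
steady state is proportional to α, so α reduces to a scale factor fitted
in closed loop; β (which sets the decay length √(γ/β)) is found by a
log-spaced scan plus bounded 1D refinement, both minimizing the worst-case
deviation over cytoplasm subcompartments. Minimax rather than least
squares: the gradient spans two orders of magnitude, and a sup-norm fit
prevents the large near-tip values from dominating.

### Comparing simulation and image

`compare_to_image` produces `E_i = |C_i^sim − C_i^obs|` over roles A∪B,
the normalized map `E/max(E)`, and a scalar summary (max A∪B error over
the maximum observed value). Named blocked compartments — typically the
nucleus — can be included in the map: a membrane-blocking model keeps the
simulated nucleus at its initial value while the image shows signal there,
and that structural discrepancy is the interesting part of the picture.
The source subcompartment itself shows a known artifact: a discrete point
source is log-singular (the 2D Green's function), while measured or
generated images are finite at the tip, so the source cell's error says
nothing about the rest of the fit and is best read separately.

## The synthetic scene generator

`make_scene(preset, seed)` builds a deterministic mating-cell geometry: an
ellipse with a protrusion disk on its boundary (the shmoo), the direction
drawn from the seed within a cone around +x; a nuclear disk offset toward
the opposite side; 2 px membrane rings obtained by binary erosion; a
single tip pixel, the membrane pixel farthest along the protrusion
direction. The signal image is `I_max·exp(−dist(p, tip)/λ)` in the
cytoplasm and on the membranes, uniform `I_nuc` in the nucleus, zero
outside, quantized to 8 bits. Presets: `paper_like` (400×400 px,
semi-axes 150/110, nucleus radius 45, λ = 80 px, I_max = 255) and
`minimal` (100×100, λ = 24) for fast tests. `I_nuc` is derived from the
generated cytoplasm field so that the per-pixel cytoplasm/nucleus mean
ratio is exactly 0.80, placing the scene in the regime where the nucleus
is brighter than the average cytoplasm but dimmer than the near-tip
gradient.

What the generator does *not* emulate: optics (PSF blur, noise, bleed),
background, segmentation errors in the masks, and — importantly — the
exponential-in-Euclidean-distance field is not itself a solution of the
diffusion model (which would be Bessel-K0-like around a point source and
shadowed behind the nucleus). Passing tests therefore demonstrate correct
digitization, statistics and solver behavior, and qualitative
model-vs-image structure; they do not validate the kinetic model against
real microscopy.

## Problem sizes and observed numbers

The production-scale checks run the 400×400 scene with a 4 px mesh
(11,443 subcompartments) for digitization statistics, and a 16 px mesh
(~700 cells) for the repeated stiff solves of parameter fitting — sizes
chosen so the full suite completes in well under a minute per check while
keeping several hundred cells per compartment of interest. On the 4 px
mesh the area-weighted cytoplasm/nucleus ratio is 0.8059 against a
per-pixel 0.7956, a 1.3% digitization error; nucleus-typed cells are 98%
pixel-pure, and the residual error is boundary mixing — polygons
straddling the nuclear membrane average ~20–30 a.u. membrane pixels into
a 55 a.u. compartment. This is the intrinsic cost of uniform-spacing
majority-vote digitization; aligning cell edges to compartment boundaries
(hand editing) or refining the mesh locally reduces it.

## Known limitations

- Single species; the property map admits many species but the RHS models
  one. Nuclear import/export kinetics are deliberately absent.
- The mesh is static: no growth or topology changes over time.
- 2D only; "volume" and "contact surface" are area and edge length.
- Majority typing can leave thin structures (membrane rings) untyped on
  meshes coarser than the structure, and can type interior straddling
  cells as the default label when no mask reaches 50%.
- Steady-state detection assumes the system actually relaxes; it reports,
  but cannot repair, secularly growing configurations.
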