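# Methods

## Transport–decay model

Each growth factor is treated independently (no interactions, no secretion,
no matrix binding — concentrations are assumed to behave as in liquid
culture media) in the 2D plan view of the hydrogel culture compartment:

    dC/dt = D (d²C/dx² + d²C/dy²) + k C,    k = ln(1/2) / t_half  (< 0)

with C in ng/mL, D in µm²/s and t_half in s.  The default parameter table
(`gradientchip/data/growth_factors.yaml`) covers seven factors: FGF-α, EGF
and FGF-β (stromal medium), IGF-1 and VEGF (vascular medium; EGF and FGF-β
are supplemented in both), dexamethasone and insulin (adipogenic media,
approximated by their two identifiable components — IBMX has no published
transport/decay parameters and is not modelled).

**Geometry.** The compartment is a 1.3 mm × 7.9 mm rectangle.  Four media
channels interface with it along 2.6 mm segments at the four corners of the
long edges; both corner segments at one end share that end's reservoir.
All other boundary is impermeable wall.

**Boundary conditions.** A channel segment is a Dirichlet boundary for a
factor only while its reservoir's media contains that factor; the clamped
value is the reservoir concentration, which decays by the same half-life
between media exchanges (media sits in the channels for days).  Segments
whose media never carried the factor behave as walls — a channel is a
source, not an infinite sink.  Walls are zero-normal-gradient (mirrored
ghost cells).

**Feeding schedules.** A schedule is a list of timed full or half media
exchanges per reservoir.  A full exchange resets the reservoir to the fresh
composition; a half exchange mixes the decayed current contents 1:1 with
fresh media (so repeated half exchanges approach the fresh level
geometrically).  The default 31-day gradient protocol loads vascular media
on one side and stromal on the other, steps the stromal side to adipogenic
initiation then maturation media by half exchanges every 2–3 days (default
exchange days 0, 1, 3, 5, 7, 10, 12, 14, 17, 19, 21, 24, 26, 28, 31), and
swaps the two sides on day 17.  Design runs use the two-day single-loading
schedule.

## Numerics

Explicit forward-time central-space (FTCS) on a cell-centred uniform grid,
default spacing 0.05 mm (26 × 158 cells).  The step is chosen automatically
as dt = snapshot_interval / ceil(snapshot_interval / dt_stable) with
dt_stable = 0.9 h²/(4D), so snapshots land exactly and the diffusion number
stays at or below 0.225 per direction.  Decay is applied per substep as an
exact factor exp(k·dt) after the diffusion update (operator splitting), so
a pure-decay configuration is reproduced to machine precision regardless of
step size.  Dirichlet values are written into the edge cells overlapping a
segment before every substep.  The interior starts at zero (fresh hydrogel)
and the initial snapshot at t = 0 is recorded before any clamping.

Verified properties (see the test suite): pure-decay closed form, uniform
steady state under full clamping, exact mass conservation without decay in
an all-wall chamber, non-negativity and the maximum principle, linearity in
the supplemented concentration, left/right reflection symmetry, agreement
with an independent dense matrix-exponential solution of the semi-discrete
system on a 5×5 grid (< 0.5 % RMS), and grid convergence (halving the
spacing moves the two-day field by well under 2 % RMS).

## Design metrics and their conventions

* **Bioactive**: C ≥ EC50 (inclusive; ties are immaterial at float
  precision).
* **Distribution distance**: measured along the chamber length from the fed
  end to the *far edge* of the furthest bioactive cell, at any transverse
  position (a mid-width-only variant is available).  Full coverage thus
  reads exactly 7.9 mm.  Reported on the 0.05 mm grid, distances carry a
  half-cell quantisation.
* **Time of maximum**: the earliest snapshot attaining the maximum
  distance, at snapshot resolution (default 0.5 h).
* **Limiting factor** of a medium: the factor fed from that side with the
  smallest maximum distance.

A structural property of this model worth knowing: substituting
V = C·2^(t/t_half) turns the equation with a half-life-decaying Dirichlet
boundary into pure diffusion with a *constant* boundary, so
C(x, t) ≤ C₀·2^(−t/t_half) everywhere.  Consequently the bioactive extent
of a single loading rises from the channel reach, peaks, and provably falls
back to the channel reach by the boundary-exhaustion time
t_c = t_half·log₂(C₀/EC50); the peak itself occurs strictly before t_c.
Reach and especially peak timing are therefore quite sensitive to whether
interior decay is modelled and to the effective diffusivity.

## Image morphometry

Vessel segmentation: conversion to 8-bit grayscale,
intensity threshold (user value or Otsu), removal of connected components
below `min_particle_area` (default 500 µm²) and filling of 4-connected
enclosed holes below `max_hole_area` (default 100 µm²).

Skeleton metrics after `skeletonize`:

* cleanup to a fixpoint: spurs of ≤ 8 px that terminate at a branch point
  are deleted, redundant elbow pixels (degree-2 pixels whose two neighbours
  are mutually adjacent) removed, and the result re-thinned;
* **endpoints**: skeleton pixels with exactly one 8-neighbour;
* **junctions**: clusters of branch pixels (≥ 3 neighbours), where clusters
  within one local vessel half-width (median distance-transform value at
  branch pixels) are merged and counted once — a thick or slightly split
  crossing is a single junction.  Junctions closer together than a vessel
  width therefore merge; this is a deliberate divergence risk versus other
  skeleton tools;
* **total length**: adjacency chain length with Vossepoel–Smeulders
  corrected step weights (0.948 orthogonal, 1.340 diagonal) and redundant
  corner diagonals skipped.  The naive (1, √2) weighting overestimates
  oblique digital lines by up to 8 %, which would exceed the 5 %
  ground-truth budget on its own;
* **diameter**: 2 × Euclidean distance transform at mid-segment skeleton
  pixels (two neighbours, ≥ 3 px from any branch cluster) × pixel size —
  an automated analogue of drawing a width line midway between junctions.

Time-lapse stacks are analysed at every n-th frame starting at frame 0.  In
the default `truncate` mode a trailing group of fewer than n frames
contributes no frame (478 frames at n = 10 → 47 analyzed); an `inclusive`
mode analyses every n-th index to the end (→ 48).

Lipid coverage is the percentage of ROI pixels inside an inclusive dark
intensity band (default 0–120 on the 8-bit scale; droplets are dark on a
bright brightfield background), reported for the whole ROI, for each
length-third (labelled vasculogenesis / middle / adipogenesis from the
vasculogenic end, flippable), and in 370 µm bins along the length with a
possibly partial last bin.

## Synthetic data

The generators are pure functions of (spec, seed); ground truth always
derives from the generating geometry, never from rendered pixels.

* **Vessel networks**: nodes scattered with a minimum separation
  (default 300 µm in a 2 mm field), edges from the minimum spanning tree of
  the Delaunay triangulation plus a configurable fraction of extra Delaunay
  edges.  Candidate edges are rejected if they would pass within 2.5 tube
  widths of a non-incident node, within 2 tube widths of a non-adjacent
  edge, or meet an accepted edge at a shared node below 55° — these
  clearances guarantee the rendered tubes only touch where the graph says
  they do, which is what makes exact count recovery a fair test.  Tubes are
  capsules of 14–22 µm width, blurred (σ = 1.2 px) with Gaussian
  (σ = 8 intensity levels) and salt-and-pepper (0.05 %) noise.
* **Lipid images**: non-overlapping dark disks (6–16 µm radius) dart-thrown
  until the geometric pixel coverage reaches the target (achieved within
  about one droplet area; targets beyond the ~55 % packing limit error
  out).
* **Time-lapse**: a master network grown edge-by-edge to a peak over the
  rise phase, pruned to 60 % of its edges over the decline phase, constant
  in the plateau — mimicking early tube formation, anastomotic remodelling
  and maturation.  Per-frame truth trajectories come from each frame's
  subgraph.

What passing these tests shows — and does not.  Recovery of synthetic
truth validates the operator implementations (segmentation, topology,
length, coverage arithmetic) under controlled noise.  It does not establish
accuracy on real micrographs, whose illumination gradients, depth
blur, touching cells and biological debris are not emulated; threshold
choices in particular remain a per-dataset decision.

## Problem sizes and runtime

The full design run (7 factors × 2 days, 0.05 mm grid, 0.5 h snapshots)
takes about 10 s on one CPU; the test suite runs in under a minute.
Synthetic-image tests use 1.6–2 mm fields at 4–8 µm/px, sizes at which the
clearance guarantees hold with comfortable margins.

## Known limitations

* 2D plan-view transport only; no height-resolved diffusion, advection or
  perfusion, and no cellular consumption or release.
* Table parameters derive from liquid 2D culture; hydrogel tortuosity and
  binding would change both D and effective half-life.
* Morphometric parity with specific GUI tools is not claimed; pruning and
  junction-merging defaults are documented above and configurable.
* The bioactive-extent timing analysis above means maximum-reach timings
  cluster either well before boundary exhaustion (short half-lives) or at
  the end of the simulated window (long half-lives); intermediate reported
  timings from other implementations typically indicate a different
  effective diffusivity or decay treatment rather than a different
  geometry.
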