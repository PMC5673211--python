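# Methods

This note records the models implemented in `bctsim`, the parameters
that matter, and the numerical and design choices made where the
underlying recipes were open.  It states no result that the test suite
or `scripts/acceptance.py` does not itself compute.

## Random draws

All anatomical randomness uses one primitive, `bounded_gaussian(lo,
hi)`: a Gaussian with mean `(lo+hi)/2` and standard deviation
`(hi−lo)/4`, redrawn (rejection) until it falls inside `[lo, hi]`.
Quantities specified as "mean ± sd" are drawn on `[mean−2sd, mean+2sd]`;
an sd of zero returns the mean.  A single master seed spawns independent
substreams for the boundary, duct, ligament and texture stages
(`numpy.random.SeedSequence.spawn`), so changing one stage's parameters
never perturbs another stage's draws.  Re-draws after a rejected
construction (disconnected outline, self-intersecting profile) continue
the same substream; everything is bit-reproducible per seed.

## External boundary and skin

* Axial outline: a union of 3–4 disks; centers at
  `bounded_gaussian(−1,1)×10 mm` per coordinate, diameters 90 ± 20 mm.
  Disconnected unions are redrawn (≤100 tries).
* Sagittal profile: top and bottom polylines from the nipple.  Segment
  angles perform a random walk with increments `bounded_gaussian(0,1) ×
  10°`; on the top curve the increment sign flips at one quarter of the
  total depth (120 ± 10 mm) from the chest wall — the chest-wall
  deflection — while the bottom curve keeps growing monotonically.
  Two choices were open:
  * **Segment count, not segment length, is fixed** (12 segments, i.e.
    ~10 mm at the default depth).  With any fixed segment length the
    walk's total curvature grows with the number of steps, so profiles
    fold over at fine pitches and the geometry is not self-similar
    across breast sizes; with a fixed count, isotropically doubling the
    anatomical means scales the support volume by ~8×, as it should.
  * Angles are clamped to ±85° so every segment advances toward the
    chest wall (guaranteed termination, no overhangs).
* Slice mapping: for each axial slice the outline is isotropically
  rescaled so its maximal caliper width equals the profile's local
  width, recentered on the profile midline; profile widths are globally
  rescaled so the widest slice matches the drawn envelope diameter
  (140 ± 20 mm).  Sub-voxel slices are skipped.  The nipple is anchored
  near the +y grid face; if the drawn depth exceeds the grid, the
  breast is cropped on the chest-wall side but a margin of air is kept
  so the skin shell closes.
* Skin: all support voxels within 5 mm (Euclidean distance transform)
  of air are relabelled skin.

## Ductal network

A strictly binary tree per lobe (lobe count 17 ± 3).  A *branch* is a
chain of constant-radius cylinders; a redirected continuation stays in
the same branch, so internal nodes always have exactly two children.
Parameters (mm/deg): major duct length 1, radius 2; lactiferous segment
length 7 ± 7/3, radius from splits; differential polar angle 30 ± 10,
azimuth drawn uniformly; branch probability 0.4 per segment; maximum
depth 12 segments.  At a split the area fraction `f` is
`bounded_gaussian(0,1)` clipped to [0.2, 0.8] (guards against vanishing
children); child diameters follow the flow-conservation formula, so
summed leaf areas under any node equal that node's area exactly.
Growth stops when a child radius would fall below half a voxel or at
maximum depth; segments that would cross skin or air are re-angled (20
tries), then shortened, then the branch terminates.  Leaf branches are
terminal; their final cylinders gate the glandular distribution.
Angle/length spreads default to mean/3 where no spread is specified.

## Cooper's ligaments and glandular texture

* A ligament unit is the union of 5 ellipsoids (count configurable;
  never specified anatomically).  Each ellipsoid takes its mean
  parameter times an independent `bounded_gaussian(0,2)` factor:
  per-coordinate center offsets of 5 mm (random sign — a one-sided
  offset would bias every unit into one octant), semi-axes of 20 mm,
  rotations of 360° reduced modulo 360°.  The membrane is the one-voxel
  boundary shell of the union; interior and membrane are disjoint.
* Units are placed at uniformly drawn uncovered interior points until
  99% of the non-skin interior is covered; membranes are labelled
  ligament without ever overwriting skin.  A stall guard aborts if 50
  consecutive placements add no coverage.
* Texture: white Gaussian noise filtered in 3-D Fourier space by
  `α/f^β` with radial frequency in cycles/mm (α=1, β=2 defaults; higher
  β is smoother).  The undefined DC gain is set to zero, making the
  field zero-mean; the binarization threshold defaults to the field
  mean (the breast-density control knob) and must be raised/lowered
  explicitly to steer density.
* Assembly precedence: skin > ligament membrane > glandular > adipose.
  Glandular voxels are the AND of the binary texture with interiors of
  units traversed by a terminal duct, plus all duct cylinders.

What the generator emulates: organ-scale shape variability, a realistic
duct hierarchy, foam-like connective septa, and a power-law glandular
texture with adjustable density.  What it does not: gravity/compression
mechanics, chest-wall anatomy beyond the bending heuristic, sub-voxel
lobular microstructure, lesions, and real inter-subject covariance of
the drawn parameters — so passing tests certify the simulation chain,
not clinical realism of any single phantom.

### Glandular-fraction property

At the desk preset (128³ at 0.8 mm) the 140 mm-class breast is cropped
by the 102 mm grid and skin occupies a disproportionate share of the
non-air volume, biasing the glandular fraction upward.  The anatomical
plausibility check (fractions within roughly 5–30% across seeds) is
therefore measured on a grid that holds the whole organ (128³ at
1.6 mm); the projection workflows keep the finer desk preset.

## Physics data

Plain-text tables under `bctsim/data` are the normative source; the
generator script (`scripts/make_physics_tables.py`) documents their
provenance.

* Mass attenuation: elemental mixture rule over H/C/N/O/F/Al values at
  the canonical compilation energies, log-log PCHIP interpolated to a
  1-keV grid, 10–100 keV.  Compositions are ICRU-44/Hammerstein-style
  reduced to dominant elements and renormalized (trace elements <1% by
  mass omitted; sub-percent effect).  Densities (g/cm³): adipose 0.95,
  glandular 1.04, skin 1.09, connective 1.12, water 1.00, PMMA 1.19,
  PTFE 2.20, aluminum 2.699.  Lookups interpolate log-log; all tissue
  coefficients are positive and monotone decreasing on this range.
* Tungsten spectra: a Kramers bremsstrahlung continuum hardened by a
  fixed aluminium-equivalent inherent filtration, stored as per-bin
  polynomials in tube potential (TASMIP-style layout) plus a small
  K-fluorescence line table above the 69.5 keV edge.  The inherent
  filtration (2.843 mm Al) is the model's single calibration constant,
  solved so the unfiltered 60 kVp spectrum has a fluence-weighted mean
  energy of exactly 35 keV — the conventional anchor for this tube
  potential.  User filtration layers are applied by Beer attenuation.
* `uniform_spectrum(kvp)`: flat photon fluence per 1-keV bin up to the
  tube potential.  Feeding it to the projector reproduces an unweighted
  per-bin energy sum — the equal-fluence convention that some
  beam-hardening demonstrations use in place of an anode model.  Its
  mean energy at a 60 kV cutoff is exactly 35 keV.

## Projection

Siddon traversal is exact per ray (incremental Jacobs variant, numba
compiled); per-label lengths are accumulated in one pass.  The
polychromatic detector model is an ideal energy integrator,
`P = Σ Φ₀(ε)·ε·exp(−Σ_m μ_m(ε) t_m)`; no blur, scatter or noise, so
simulated image quality is an upper bound.  The conventional route — a
full re-trace per energy bin accumulating `μ·length` voxel by voxel —
is retained (`poly_project_per_bin`) as an independent cross-check; the
two agree to ~1e-13 relative (floating-point summation order only).

**Relative error maps** between mono and poly projections support two
domains.  `intensity` compares open-field-normalized transmissions
(error grows with path length; a uniform scaling of one image by
`1−x` yields a uniform `x·100%`).  `log` compares the log-transformed
images — attenuation line integrals, which puts the two in
commensurate units with no further scaling; there the error peaks on
thin boundary-grazing rays, where the un-hardened beam's effective
attenuation is farthest from its deep-tissue value, and decays into the
bulk.  The breast demonstrations use the log domain with the
equal-fluence 60 kV spectrum versus 35 keV mono; with the
fluence-weighted tungsten spectrum (which carries far less low-energy
fluence at the same 35 keV mean), the same map peaks near 7–12%.
Whether adipose-dominant rays err more than glandular-dominant ones
proved seed-dependent in this implementation and is not asserted.

## Reconstruction

Flat-detector fan-beam FBP, full 360° scan: detector coordinates
rebinned to the isocenter scale, cosine pre-weighting, band-limited
ramp kernel apodized by a Hanning window (cutoff 1.0 × Nyquist by
default), FFT convolution with 4× zero-padding, bilinear (1-D linear in
detector coordinate) interpolation and `1/U²` distance weighting in the
back-projection, with the factor ½ of the full-scan formula.  On a
monochromatic cylinder sinogram the reconstruction recovers the input
attenuation coefficient within a few tenths of a percent (verified in
tests against the analytic value and against an independent
parallel-beam FBP implementation in the near-parallel limit).  Cupping
between the aluminum and PTFE inserts of the validation fixture is
quantified as the drop of the segment-to-host mean ratio of the
polychromatic reconstruction relative to the monochromatic one.

## Problem sizes

Default study sizes were chosen so every workflow runs in seconds to a
few minutes on one CPU: desk preset 128³ voxels at 0.8 mm with a 256²
detector at 1.2 mm (same 307.2 mm active width as the full-scale
1024² × 0.3 mm flat panel, which remains available as a preset), 60–180
angles for fan sinograms, 64³ validation fixture.  The acceptance
script evaluates five phantom seeds for the stochastic error-map bound.

## Known limitations

* No scatter, detector MTF/noise, focal-spot blur or quantum noise.
* Fan-beam (single-row) reconstruction only; no cone-beam FDK.
* The anode model is semi-empirical (Kramers + equivalent filtration +
  schematic K lines), adequate for hardening studies but not for
  dosimetry-grade spectral work; measured spectra can be substituted as
  two-column text.
* Lesions/abnormalities are out of scope.
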