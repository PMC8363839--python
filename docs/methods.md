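# Methods

This note records the models behind `bilayerlab`, the defaults and why they
were chosen, the numerical conventions, and what validation on synthetic
data does and does not establish.

## Coordinate and unit conventions

All internal lengths are nm and times ns; conversions (Å, ps) happen only
at the I/O boundary. Boxes are orthorhombic with the origin at a corner and
wrapped coordinates in `[0, L)` per axis; triclinic boxes are rejected
rather than silently mishandled. Diffusivities convert as
1 nm²/ns = 1e-5 cm²/s, and the conversion is applied exactly once, at the
result object.

## Leaflet assignment

Headgroup particles (tags ending in `-P`) are split by a median-z cut in a
single reference frame (the first, by default) and the assignment is frozen
for the whole trajectory: lipid flip-flop times are orders of magnitude
longer than the sub-microsecond trajectories targeted here, and per-frame
relabeling only injects noise. The split is invariant under rigid
z-translations. If the gap between the two groups at the cut falls below
`min_gap` (default 0.5 nm) the geometry is declared ambiguous instead of
guessing. A leaflet that wraps through the periodic z boundary is not
handled; center the bilayer in the box first.

## Monge-gauge surface fit

Each leaflet is a height function z(x, y) over the periodic box, expanded
in a truncated Fourier basis with half-plane modes |m|, |n| ≤ M (one
wavevector per ±k pair, so the surface is real by construction;
(2M+1)² real coefficients). The fit is ordinary linear least squares of the
headgroup coordinates; the residual norm, an error-variance estimate and
coefficient standard errors are kept on the results object. Rank
deficiency (e.g. points collinear in x–y) raises rather than returning a
pseudo-inverse solution.

**Mode cutoff M.** Default 2 (25 coefficients for ~260 points per
leaflet). Protein-scale deformation in a ~13 nm box is long-wavelength, and
higher cutoffs mostly fit thermal headgroup noise. Two systematic effects
trade off when M grows at fixed point count: the truncation bias of the
representable surface shrinks, but (i) propagated coefficient noise in the
curvature scales as q² and so grows rapidly with mode order, and (ii) with
p = (2M+1)² parameters on n random points, least squares carries an
O(p/n) finite-sample bias against the unrepresentable remainder of the
surface. For the localized Gaussian-bump validation surface (width 2 nm in
a 13 nm box), M = 3 is the sweet spot at n = 260: measured field error is
about half that at M = 4, where the design bias dominates. M stays a
per-call parameter.

**Curvature.** H is evaluated analytically from the coefficients.
Default is the linearized form H = (z_xx + z_yy)/2; the full Monge-gauge
expression is available as a cross-check and agrees within 1% whenever
max |∇z| < 0.05, which bilayer undulations at these scales satisfy. Sign
convention: z increases toward the upper leaflet, so an indentation of the
upper leaflet has H > 0 at its center under this formula; the convention
string is attached to every curvature result, and footprints are reported
both signed and as magnitude.

**Time averaging.** Surfaces are fitted per frame and curvature fields
averaged afterwards. Single-frame curvature at realistic noise
(σ ≈ 0.1 nm on 260 points) carries ~30% RMS noise relative to a
protein-scale peak |H|; the averaged field converges as 1/√F. The
validation studies use several hundred statistically independent frames,
which brings recovery error below 2% of the peak; analyses default to the
terminal 40% of frames (the equilibrated-tail convention for 500 ns runs
analysed over their last 200 ns), configurable.

**Curvature footprint.** Scalar summary: area-weighted mean of H over a
region × the terminal time window, with mean ± SEM across replicas when
several trajectories are supplied. The region defaults to the protein's
lateral bounding disk (centroid + radius of gyration of `protein`-tagged
particles) when a protein is present, else the full box. Two caveats are
deliberate: the precise spatial definition of a published footprint scalar
varies between studies (region average vs extremum), so the region is
always recorded in the output; and the box average of the *linearized*
curvature of any periodic surface is identically zero, so a full-box
footprint of a protein-free patch measures numerical consistency
(float-level zero), not statistical fluctuation — a protein-scale disk
region is the right null when comparing against a protein system.

## Thickness and area per lipid

Thickness is z_upper − z_lower evaluated from the two fitted surfaces on a
common grid (headgroup-to-headgroup vertical distance); negative values
raise a leaflet-order error. The condition-level scalar is the area-weighted
mean over the terminal window, consistent by construction with the field
average. Area per lipid is Lx·Ly divided by lipids per leaflet — a pure
box/count quantity, independent of coordinates. Dose–effect orderings
(thickness decreasing, APL increasing with intercalant count) are checked
as strict inequalities with a configurable tolerance defaulting to 0.

## Lateral diffusion

MSD over x–y displacements only, averaged over the selected particles and
over time origins every 0.1 ns (configurable; rounded to the frame grid,
and rejected if below the frame spacing). Lags run to half the trajectory
by default — beyond that too few origins remain. The per-frame lateral
center of mass of the selection is removed by default so collective patch
drift does not masquerade as diffusion; the toggle is exposed because not
every published protocol states this step. The fit is a free-intercept
straight line over 0 < t ≤ t_max (default 50 ns): the intercept absorbs
short-time non-diffusive motion, and the slope/4 is D. The quoted error is
|D₁ − D₂| from fits over (0, t_max/2] and (t_max/2, t_max] — a protocol
error bar, not a confidence interval; it underestimates uncertainty when
the two halves are correlated. Validating the 0–50 ns window requires a
trajectory of ≥100 ns so the MSD covers the full window; the synthetic
recovery studies use 1000 walkers × 1001 frames × 0.1 ns, where recovery
is comfortably within 5%.

## Density maps

Per-frame 2D histograms in fractional coordinates (robust to a breathing
box), averaged over the window and normalized to count·nm⁻². Binning is
nearest-bin into half-open cells consistent with `[0, L)` wrapping, on a
26×26 default grid (~0.5 nm cells in a 13 nm box — fine enough to resolve
protein-scale enrichment, coarse enough to avoid single-occupancy noise).
Conservation (Σ values × cell area = mean selected count) holds to floating
point by construction and is asserted in tests.

## AFM step heights

Pipeline: robust background-plane subtraction → hole detection → ten
radial, five-pixel-thick cross sections across hole edges → per-profile
step → pooled mean ± SD/SEM. The plane is fitted by trimmed iterative least
squares that converges onto the dominant plateau; since both plateaus are
parallel, this removes scanner tilt regardless of the substrate fraction
(a plain Otsu-masked fit fails when strong tilt mixes the two levels in
the histogram). Per profile, the edge is the maximum-|gradient| sample,
each plateau level is the median of its side excluding a 2-px guard
(robust to edge rounding and debris), and a step must exceed 4× the
within-plateau robust noise, otherwise `NoStepError`. Automatic line
placement is deterministic (largest holes first, rays at fixed angles from
the hole centroid), so re-analysis of the same image is bit-reproducible,
and user-supplied lines take precedence. Estimates are invariant to global
offsets and, for symmetric images, to 90° rotations.

## Synthetic generators

The generators define the validation conditions and retain their ground
truth; a fixed spec + seed reproduces outputs bit-identically.

- **Bilayer patch**: 520 lipids, 20% POPS/80% POPC split equally between
  leaflets (52 POPS per leaflet), 0/24/48 TFP molecules (TFP/lipid 4.6% and
  9.2%), 13 × 13 nm lateral box, headgroup separation d₀ = 4.0 nm. Both
  leaflets ride one shared undulation surface (a bending mode — so
  thickness is exactly d₀ when noise is off), redrawn independently each
  frame with per-mode Gaussian amplitudes ∝ 1/q² normalized to an RMS
  roughness of 0.15 nm (within the 0.1–0.3 nm band typical of tensionless
  patches this size; membrane undulation relaxation at these wavelengths is
  faster than the 1 ns frame spacing, justifying independent redraws).
  Lipids do independent 2D Brownian motion with per-species D (POPS default
  9.9e-3 nm²/ns; POPC and TFP slightly faster); headgroup placement noise
  0.05 nm. A bound protein is emulated only by a static Gaussian dimple on
  the upper leaflet plus its footprint disk — no particle-level protein.
- **Brownian ensembles**: per-axis step variance exactly 2 D dt, optional
  wrapping to exercise the unwrapping code.
- **Analytic surfaces**: Fourier amplitudes and/or a Gaussian bump, with
  closed-form linearized curvature for oracle comparisons.
- **AFM images**: two exact levels with circular holes, plus optional tilt
  plane and Gaussian noise.

What passing on these inputs shows: the estimators are unbiased and
correctly implemented under their own model assumptions, at realistic
sample sizes and noise. What it does not show: behavior under features of
real MD/AFM data the generators omit — correlated headgroup dynamics,
anomalous (sub-diffusive) short-time lipid motion, protein-lipid coupling,
box breathing under pressure coupling, AFM scanner line noise and tip
convolution. Numbers from real 500 ns all-atom replicas (e.g. footprints
of order 0.01 nm⁻¹) are not reproducible from these idealized patches.

## Problem sizes in the validation suite

Chosen as the package's own validation design: curvature recovery uses 800
independent frames × 260 points (noise-limited error ≈ 1–1.5% of peak |H|);
diffusion recovery uses 1000 walkers × 100 ns; the protein-free baseline
uses 240 frames of the default patch; AFM recovery pools 30 profiles from
three images. The full suite runs in well under a minute on one core,
excluding the Brownian ensembles (~30 s).

## Known limitations

- No Helfrich spectrum/bending-modulus estimation, Gaussian curvature, or
  per-lipid curvature decomposition; no anomalous-diffusion exponents; no
  AFM tip deconvolution or force curves.
- Orthorhombic boxes only; no topology/bond information is used.
- The CSV trajectory dialect stores a single box (no per-frame breathing).
- The two-halves diffusion error bar is a reproducibility measure of the
  published protocol, not a statistically calibrated uncertainty.
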