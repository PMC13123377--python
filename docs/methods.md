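# Methods

`embryotfm` quantifies the mechanics of mouse embryo implantation on soft
hydrogel substrates: the traction stresses the embryo exerts on the gel,
their dynamics in time, the substrate and embryo elasticity measured by
nanoindentation, the embryo's shape and motility, and the
nuclear/cytoplasmic partitioning of the mechanosensor YAP.  Because the
raw microscope data are not redistributable, every input the pipeline
consumes can be forward-simulated with known ground truth; all tests are
parameter-recovery tests against that simulator.

## Elastic model

The gel is treated as a homogeneous, isotropic, linear-elastic half-space
with Young's modulus `E` (1–50 kPa for the GelMA formulations of
interest) and Poisson's ratio `ν = 0.5` (incompressible, the convention
for hydrated gels).  Surface tractions `T(x)` produce surface
displacements `u(x)` through the Boussinesq Green's function, which is
diagonal per Fourier mode `k = (kx, ky)`:

    G̃(k) = 2(1+ν) / (E k³) · [ (1−ν)k² + ν ky²,  −ν kx ky
                                −ν kx ky,          (1−ν)k² + ν kx² ]

    ũ(k) = G̃(k) T̃(k)

The half-space (infinite thickness) approximation is standard for TFM and
justified here because the gel (~150 μm) is two orders of magnitude
thicker than the bead displacements (≲ 3 μm).  The `k = 0` mode is
undefined for a half-space and set to zero, which removes rigid
translation and enforces a zero net force — appropriate for a
self-balanced contractile embryo.

**Periodicity.**  Both the forward simulation and the inverse
reconstruction treat the observation grid as one period of the spectral
model (`pad_factor = 1`).  We evaluated the alternative — zero-padding the
forward convolution and taper-padding the inverse by a factor 2 — and
found that the mismatch between the two paddings leaves a boundary
artifact of 12–20% relative L2 and ~10% spurious net force at realistic
grid sizes, whereas the self-consistent periodic operator round-trips to
machine precision and is exactly force-free.  Tapered padding remains
available (`pad_factor > 1`) for data where an isolated embryo sits near
the field edge and wrap-around is the dominant concern.

## Inverse problem (FTTC)

Traction reconstruction solves, per Fourier mode, the Tikhonov-regularized
normal equations

    T̃ = (G̃ᴴG̃ + λ²I)⁻¹ G̃ᴴ ũ ,

a 2×2 closed-form solve.  A Wiener-style variant replaces the global λ²
with a mode-dependent penalty `N/S(k)` estimated from the displacement
power spectrum.  λ can be chosen four ways (`select_lambda`):

* **fixed** — user value;
* **gcv** (default) — generalized cross-validation, computed in closed
  form from the kernel's per-mode eigenvalues; needs no noise estimate.
  Because overlapping PIV windows correlate neighbouring node errors —
  which GCV's independence assumption cannot tolerate — λ is selected on
  a 2×-decimated subgrid, which restores disjoint interrogation templates
  at the default 75% overlap;
* **lcurve** — corner of the (log residual, log solution norm) curve by
  the triangle method; good at high SNR, unreliable when noise dominates;
* **noise** — Morozov's discrepancy principle against displacement noise
  measured in a user-supplied embryo-free region.  Conservative: any real
  far-field displacement in the "noise" region inflates the estimate and
  over-smooths.

Residuals for the L-curve and discrepancy strategies are made mean-free
per component before comparison: the zeroed `k = 0` convention makes a
rigid offset (residual stage drift) unexplainable by any traction, so it
must not count against the fit.

## Force metrics and units

Internally all lengths are μm and stresses Pa.  The single hard-coded
unit conversion is `1 Pa·μm² = 10⁻³ nN` (`PA_UM2_TO_NN`), covered by a
unit test, since silent unit errors are the classic failure mode of TFM
code.  Per frame, over the embryo–substrate contact mask: max traction =
max |T| (Pa), mean traction = mean |T| (Pa), contact area = node count ×
node area (μm²), total force = mean traction × area × 10⁻³ (nN).  When no
embryo mask is supplied the contact mask falls back to |T| above the
noise floor (mean + 2 SD of |T| over an embryo-free region).

## Displacement estimation (PIV)

Displacements are measured loaded-relative-to-relaxed: the reference is
the bead image after the embryo has been removed and the gel has
recovered, so reconstructed tractions are those the embryo exerted.
Each 32 px interrogation window contributes one node; the central half of
the reference window is matched across the loaded window by normalized
cross-correlation (full-overlap template matching, which avoids the
toward-zero bias of circular correlation when beads cross window edges),
with subpixel refinement by a 2-D Gaussian fit to the 3×3 peak
neighbourhood (~0.05 px accuracy on rendered beads).  A second pass warps
the loaded image by the spline-interpolated first-pass field and measures
the residual, removing most gradient-induced bias.  Defaults: window
32 px, overlap 0.75 (4 μm node spacing at 0.5 μm/px — chosen because it
roughly halves peak-recovery error relative to 0.5 overlap at ~2.6 s per
frame), 2 passes.  Windows without texture or with a weak correlation
peak are masked invalid; a local median/MAD outlier test (threshold 3,
noise floor 0.02 μm) replaces spikes.

## Drift registration

Rigid stage drift is estimated by phase cross-correlation (full frame by
default, or a user template region) with Fourier-upsampled subpixel
refinement (0.01 px grid), and removed by bilinear resampling.  Accuracy
on rendered beads: integer shifts exact, subpixel within ~0.05 px.
Frames whose post-alignment correlation falls below 0.2 are flagged and
their shift interpolated from neighbours.  The reference frame defaults
to the first frame; registering against the relaxed reference instead is
a flag away.

## Synthetic scenes: what they emulate and what they do not

`make_contractile_traction` builds the embryo's force footprint as an
annulus of inward radial tractions with a cosine profile (peak 100 Pa,
radii 30–55 μm by default, matching a ~110 μm embryo pulling at its
periphery); discretization imbalance is subtracted out so every scene is
balanced to machine precision.  `make_scene` adds a monolayer of
Gaussian-spot beads (density 0.06 μm⁻², spot σ 1.5 px, amplitude 3000
counts on a 100-count background), per-frame rigid drift (SD 1.5 px) and
Poisson counting noise, on a 192 μm field at 0.5 μm/px.  All randomness
flows through one seed; identical seeds give bit-identical images.

`scene_for_stiffness` encodes the embryo's observed mechanical response
to substrate stiffness: a fixed total force output (600 nN by default)
redistributed over a contact annulus whose radii grow as
`(E/E_ref)^0.15`, so peak traction falls as the substrate stiffens while
total force is conserved.  This mirrors the experimental findings that
adhesion area rises and max traction falls with stiffness while total
traction force is statistically unchanged; a displacement-controlled
program would predict the opposite direction and a fixed-traction program
no direction at all.

The peak-train generator emulates the max-traction time course: a ramp to
a 100 Pa plateau over ~1 h (adhesion maturation), then 30 Pa Gaussian
peaks recurring every ~10 min with 1 min jitter, sampled at the
acquisition cadence (5 min for up to 4 h).  The trajectory generator is a
persistent random walk sampled every 20 min (the migration assay
cadence); persistence → ∞ gives ballistic motion, persistence 0 a
diffusive walk.

Not emulated: 3-D bead stacks and out-of-plane displacement,
gel viscoelasticity or stiffness changes during culture, photobleaching,
bead aggregation, non-rigid stage distortion, and segmentation errors in
the user-supplied masks.  Passing tests therefore demonstrate correctness
of the computational chain under these idealizations, not robustness to
every imaging pathology.

## Nanoindentation (Hertz)

Force–indentation curves from a spherical tip (radius 3.000 μm) are fit
with `F = (4/3)·E/(1−ν²)·√R·δ_eff^{3/2}`, `δ_eff = max(δ − δ₀, 0)`,
`ν = 0.5`, with the contact point δ₀ fit jointly with E — robust on soft
samples where contact is gradual; a threshold-based contact pre-detector
would be the alternative.  When sample thickness is provided the fit is
restricted to indentations below 10% of it (thin-sample validity).  QC
flags mirror the exclusion of irregular curves: adhesion dips beyond 3×
the baseline noise SD, non-monotone loading, baseline drift, and
non-contact; flagged curves are excluded from the group mean ± SEM.

## Morphometry conventions

Several reported quantities admit multiple definitions; the ones chosen
here are:

* **Perimeter / circularity** — perimeter is the length of the lightly
  smoothed marching-squares contour (window 5 samples), within ~1% on
  digital disks and ~2% on rectangles; circularity = 4πA/P².
* **Interface curvature** — the angle (degrees) subtended by the EPI/pTE
  interface polyline on its least-squares (Kåsa) circle, measured as the
  angular extent of the polyline around the fitted centre; a straightness
  guard reports 0° for interfaces within rasterization noise of a line.
* **Relative interface** — interface chord divided by EPI width (the EPI
  extent perpendicular to the EPI-centroid → pTE-centroid axis), so a
  full-width interface gives 1.  This quantity is not given an exact
  definition in the source literature; the choice is flagged here.
* **Core structure** — equivalent diameter `2√(A/π)` strictly greater
  than 80 μm.
* **Migration** — speed = path length / elapsed time; directionality
  ratio = net displacement / path length; MSD time-averaged over all
  start points, power-law exponent by log–log regression over lags up to
  ¼ of the track span.
* **Adhesion onset** — both the area and circularity time courses are
  z-scored and jointly fit with a continuous two-segment linear model
  sharing one breakpoint (searched over sample times); collinear data are
  flagged rather than assigned a breakpoint.

## YAP quantification

`YAP_Cyto = YAP_Cell − YAP_Nuc` and `ratio = YAP_Nuc / YAP_Cyto`, with
each term an ROI-integrated density in the YAP channel (nucleus ROI from
the DNA stain, cell ROI from the actin stain).  The cytoplasm is defined
by subtraction of densities, not by a mask (a mask-based alternative
exists but is non-default).  The ratio is invariant to multiplicative
intensity scaling but **not** to additive offsets; background subtraction
against a stated background ROI is available and off by default.

## Problem sizes and determinism

Tests and the acceptance script run on 96×96-node traction grids
(192 μm at 2 μm spacing), ~2,200-bead scenes, 50-seed Monte-Carlo batches
for Hertz noise studies and ~100-peak trains — sizes at which every
recovery statistic is stable across seeds while the whole suite completes
in well under a minute.  Every stochastic step draws from
`numpy.random.default_rng` with an explicit seed; pipeline runs embed the
config hash in every output table, and identical config + seed reproduce
outputs byte-for-byte.

## Known limitations

* 2-D projection: tractions are in-plane surface stresses; out-of-plane
  components of a tall embryo are invisible to the method.
* The contact-mask fallback (noise-floor threshold) underestimates the
  contact area of weakly adherent regions; supply an embryo mask when
  available.
* Interval-based periodicity at 5-min sampling of a ~10-min rhythm sits
  at the Nyquist limit; `detect_peaks` warns when the mean interval is
  below 3× the sampling interval, and no spectral estimator is provided.
* The Wiener filter's noise/signal split is a heuristic spectral
  estimate; for quantitative work prefer Tikhonov with GCV.
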