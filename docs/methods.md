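# Methods

## Physical model

Dye penetration into a rehydrating powder particle is modelled as Fickian
diffusion, ∂c/∂t = ∇·(D_eff ∇c), in a sphere of radius R whose surface is
held at the concentration of the surrounding dye solution.  The fluorescence
intensity is assumed proportional to local dye concentration, so the
min–max normalized intensity is the dimensionless concentration.  The
classical series solutions used throughout are:

* radial profile
  `C(r,τ)/C∞ = 1 + (2R/πr) Σ_{n≥1} ((−1)ⁿ/n) sin(nπr/R) exp(−n²π²τ)`,
  with the analytic r→0 limit `1 + 2 Σ (−1)ⁿ exp(−n²π²τ)`;
* volume-average fractional uptake
  `U(τ) = 1 − (6/π²) Σ (1/n²) exp(−n²π²τ)`;
* equatorial-slice average
  `S(τ) = 1 − (8/π²) Σ_{n odd} (1/n²) exp(−n²π²τ)`,
  obtained by integrating the radial profile over the equatorial disc.

Here τ = D_eff·t/R².  Series are truncated adaptively
(N = max(10, ⌈4/√(π²τ)⌉), capped at 10⁴ for the uptake forms), which keeps
the truncation error below 10⁻⁹; τ = 0 returns the analytic limit rather
than summing a series that converges only pointwise for τ > 0.  All three
forms are cross-checked in the test suite against an independent
Crank–Nicolson finite-difference solution of the radial PDE (substitution
v = r·u reduces it to the 1-D heat equation; 400 shells, Δτ = 10⁻⁵, a few
fully implicit startup steps to damp the boundary discontinuity); agreement
is ~2 × 10⁻⁵, far inside the 10⁻³ tolerance asserted.

### Slice vs volume average — why fits use S(τ)

A confocal section through the particle centre measures the mean intensity
of the equatorial disc, which under-weights the fast-saturating outer shell
of the sphere: at early times S(τ) ≈ (4/√π)√τ while U(τ) ≈ (6/√π)√τ.
Because both behave like √τ at leading order, fitting U to slice-averaged
data with a free amplitude does not merely rescale the result — it settles
on a systematically low D (about 3× low in simulation).  The image
pathways therefore fit S(τ) by default (`fit_geometry="slice"` in
`RunConfig`); the volume form U(τ) remains the default of the library-level
`fit_deff`/`crank_uptake` API for measurements that integrate the whole
particle.  This choice was validated by parameter recovery: with the slice
kernel the full pipeline recovers true diffusivities with median relative
error well under 15%; with the volume kernel the bias is ~3×.

## Estimators

* **Crank fit** (`fit_deff`): least squares of
  `i0 + (i_inf − i0)·kernel(Dt/R²)` over (D, i0, i_inf) with bounds D > 0,
  0 ≤ i0 < i_inf ≤ 1.  The affine pair is linear given D and is profiled
  out in closed form, reducing the search to one dimension; nine log-spaced
  starts over D ∈ 10⁻¹⁵…10⁻¹¹ m²/s each run a bounded Brent minimization
  over log₁₀D (±1.5 decades, xatol 10⁻⁴) and the best SSE wins.  The
  affine embedding is needed because measured traces start at a nonzero
  baseline (dye penetrates somewhat before the first capture; the
  benchmark table's initial relative intensities are 0.27–0.56) and
  plateau below 1.
* **Area/time** (`deff_eq1`): initial segmented particle area divided by
  the time at which the endpoint rules declare diffusion complete.  This
  is a conventional definition (dimensionally an area rate), retained
  because it mirrors the traditional manual workflow; it runs orders of
  magnitude above the Crank-fit scale by construction.
* **Nelder–Mead refinement** (`refine_deff_nm`): minimizes
  Σ(I_norm − I_theor)² over D alone, starting from the area/time value,
  with baseline/plateau frozen at the trace's first/last observed values.
  The simplex runs on log₁₀D so the 10⁻³ parameter tolerance is relative;
  fatol 10⁻¹², ≤ 500 iterations; non-convergence keeps the initial value
  and flags the estimate.  Freezing the plateau at the last *observed*
  value biases D for particles far from equilibrium — in simulation the
  refined estimates land within a factor ~1.2–4 of truth versus ~100× for
  the raw area/time values, which is the intended role of the refinement
  (scale correction, not a precision estimator; the Crank fit is the
  precision pathway).

## Image processing

* **Otsu threshold**: computed per frame on the 256-bin histogram by direct
  between-class-variance maximization; foreground is strictly above the
  threshold, ties break to the smallest maximizing value.  Verified against
  exhaustive search on 1,000 random histograms.
* **Segmentation**: threshold → `binary_fill_holes` (the advancing dye
  front leaves dark interiors that must count as particle area) →
  8-connected labeling → regions below 20 px or touching the border are
  discarded (border geometry is truncated, so R would be wrong).  Labels
  are ordered by decreasing area.  Morphology per region: area, equivalent
  diameter 2√(A/π) (whose half is the model's R), centroid, tight
  half-open bounding box (row-major, 0-based).
* **Tracking**: greedy one-to-one matching of adjacent frames by Euclidean
  distance in (corner row, corner col, width, height) bounding-box feature
  space, gated at 15 px centroid displacement (particle drift in the
  dispersion is negligible on the acquisition timescale).  No gap closing:
  an unmatched region ends its track; late appearances start tracks flagged
  incomplete and are excluded from estimation (the initial area would be
  unknown).  For the static, well-separated particles this workflow
  assumes, greedy equals the optimal assignment — asserted against
  brute-force enumeration on 200 random small instances.
* **Intensity**: the measurement domain is frozen at the first frame
  (static particles).  `matlab` mode measures the first-frame bounding box
  with per-particle min/max over the whole series; `ml` mode measures the
  mask with Int_min = the whole first frame's minimum and Int_max = 255,
  and additionally reports q1 (first quartile of raw pixel intensities;
  the threshold constants 80 and 100 are consistent with raw-intensity
  quartiles on an 8-bit scale) and the standard deviation of normalized
  pixel intensities.
* **Endpoint rules**: three criteria scanned in time order, all strict
  inequalities, earliest frame wins, priority I > II > III at ties —
  I: second difference of q1 < −4.99 and q1 > 80; II: q1 > 100;
  III: |Δ std_norm| < 10⁻⁴ and std_norm < 0.18 and q1 > 80.  "Decrement of
  the rate of change" is read as the discrete second difference; the
  constants are configuration (`RuleConstants`) with these defaults.
  Under pixel noise the rules are stochastic: which criterion fires first
  can swap between noise realizations, jittering the completion frame by a
  few frames.  Completion time is therefore monotone in D only in trend;
  the acceptance script summarizes it as a rank correlation while the test
  suite asserts strict monotonicity on a fixed seeded grid.

## Synthetic scenes

`SceneConfig` defaults emulate the acquisition this workflow targets:
512 × 512 px at 440 nm/px, 3 s frame spacing, 120 frames, 10 non-overlapping
particles with radii 5–20 µm and log-uniform D_eff in 10⁻¹⁴…10⁻¹³ m²/s,
background grey level 20, particle plateau 200, initial interior level 70
(35% of the plateau, reproducing the partial penetration seen at first
capture), Gaussian blur σ = 1 px standing in for the optical PSF, additive
Gaussian noise σ = 2 grey levels, then clipping and 8-bit quantization.
Particles are placed by rejection sampling (≤ 10⁴ attempts) with a 6 px
separation buffer and a border margin; the seed fully determines the scene.
Rendering paints each disc with the equatorial cross-section of the radial
solution, which is what a centred confocal slice sees.

What the generator does **not** emulate: irregular/hollow particle shapes,
particle motion or swelling, heterogeneous internal pore networks (real MPC
particles show route-like dye ingress), depth-dependent PSF, photobleaching,
or intensity–concentration nonlinearity.  Passing recovery tests therefore
demonstrate the correctness of the chain *given* the spherical homogeneous
model — they do not certify accuracy on particles that violate it.

## Numerical and design notes

* Degenerate inputs fail loudly with context (track/frame/annotation ids):
  single-valued frames yield zero regions; all-constant traces are rejected
  as unidentifiable; normalization with Int_max ≤ Int_min raises.
* Quantile definition: "q1" is the 25th percentile with linear
  interpolation; the quantile level is configurable.
* The equivalent-radius R enters the fit from the segmented area, so a few
  percent of blur-induced area inflation propagates as ≲ 8% on D (∝ R²);
  noiseless scenes recover diameters within 5%.
* COCO mask import rasterizes polygons with pixel centres
  inside-or-on-boundary as foreground and decodes uncompressed column-major
  RLE; imported masks pass through the same hole-fill and minimum-area
  filters as the built-in segmenter.
* Problem sizes in the test suite (10-particle 120-frame scenes, 400-shell
  PDE oracle, 200–1,000 randomized oracle cases) were chosen as the
  smallest sizes at which the statistical assertions are stable.

## Known limitations

* The area/time estimator is reported as-is for comparability; its scale is
  not commensurate with the diffusion-equation pathways.
* Touching or overlapping particles are not split (no watershed); the
  workflow assumes separated particles, as the acquisition protocol does.
* Uncertainty intervals on per-particle D are not provided; the SSE and
  convergence flags in the fit tables are the available diagnostics.
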