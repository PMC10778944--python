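# powderdiff

Automated measurement of **per-particle effective water diffusion
coefficients** in high-protein powders (e.g. milk protein concentrate, MPC)
from confocal time-lapse micrographs of rehydration.

When a dry powder particle meets water carrying a fluorescent dye
(Rhodamine B), the dye front moves radially inward and the particle's
fluorescence rises toward the level of the surrounding solution.  powderdiff
turns a stack of 8-bit greyscale micrographs into per-particle estimates of
the effective diffusivity `D_eff` (m²/s), via two independent pathways:

* **Crank-fit pathway** — Otsu segmentation → hole filling → connected-
  component labeling → nearest-neighbour tracking → bounding-box mean
  relative intensity `Int_rel = (Int − Int_min)/(Int_max − Int_min)` →
  least-squares fit of the spherical diffusion solution.
* **Rule-based pathway** — particle masks (built-in segmenter or imported
  COCO annotations) → per-mask intensity quartile `q1` and normalized-
  intensity standard deviation → empirical completion rules → area/time
  estimate `D_eff = A₀ / t_full` → single-parameter Nelder–Mead refinement
  against the diffusion model.

## Model

For Fickian diffusion into a sphere of radius `R` held at constant surface
concentration, the fractional uptake at dimensionless time `τ = D_eff t/R²`
is Crank's series

```
U(τ) = 1 − (6/π²) Σ_{n≥1} (1/n²) exp(−n²π²τ)
```

A confocal slice through the particle centre averages the concentration
over the **equatorial disc**, not the sphere volume; the corresponding
slice-average uptake has the closed form

```
S(τ) = 1 − (8/π²) Σ_{n odd} (1/n²) exp(−n²π²τ)
```

Image-derived traces are fitted with `S` by default (see
`docs/methods.md`); the measured trace is embedded as
`I(t) = i0 + (i_inf − i0)·S(τ)` with baseline `i0` and plateau `i_inf`
estimated jointly with `D_eff`.

A synthetic-scene generator (`powderdiff.synthetic`) renders rehydrating
particles with known radii and diffusivities — including optical blur,
detector noise and 8-bit quantization — so the whole pipeline is validated
by parameter recovery without any real micrographs.

## Worked example

```
$ powderdiff simulate --seed 3 --out scene_out
rendered 120 frames, 10 particles -> scene_out

$ powderdiff run scene_out/series.tif --mode both --out run_out
frames: 120  tracks: 10 (10 complete)
matlab: n=10  mean D_eff = 3.79e-14 m^2/s
ml_eq1: n=10  mean D_eff = 3.28e-12 m^2/s
ml_refined: n=10  mean D_eff = 8.53e-14 m^2/s
outputs written to run_out
```

The simulated scene has 10 particles (radii 5–20 µm, true `D_eff`
10⁻¹⁴–10⁻¹³ m²/s) imaged every 3 s for 6 min.  The Crank-fit mean
(3.79 × 10⁻¹⁴ m²/s) sits inside the true range; the raw area/time estimate
is about two orders of magnitude larger (it divides an area by a time — a
conventional definition, not the solution of the diffusion equation), and
Nelder–Mead refinement pulls it back to the model scale.  Per-particle
tables (`estimates.csv`, `traces_*.csv`, `endpoints.csv`) and a
`summary.json` with ensemble statistics and D-vs-diameter regressions are
written to the output directory.

```
$ powderdiff reference-check
particles: 18
max |computed - printed| equivalent diameter: 0.0046 um
mean D_eff: 3.39e-14 m^2/s
diameter: mean 19.2 um, sd 11.0 um, range 5.37-42.38 um
```

`reference-check` recomputes, with the package's own operations, the
summary statistics of a published 18-particle MPC benchmark table bundled
in `powderdiff.reference`.

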