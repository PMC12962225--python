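# Methods

This note documents the models, estimators and numerical choices in
`wfs-recon`, and what its synthetic experiments do and do not establish.

## Signal model

Each spin echo of a 2D FSE train carries `Nt = 7` bipolar gradient echoes at
signed times `t_j = (j − 4)·ΔTE` relative to the spin echo, `ΔTE = 1.0 ms`
by default (configurable, e.g. 1.06 ms for ramp-sampled blipped readouts).
Per pixel,

    x(t_j) = exp(μ t_j) · (ρ_w + Φ_f(t_j) ρ_f + Φ_s(t_j) ρ_s),
    μ = 2πi·f_B − R2′,

with the multi-peak fat phasor `Φ_f(t) = Σ_p α_p exp(2πi f_p t)` and the
single-peak silicone phasor at −4.9 ppm. The nine-peak fat table (water-
relative shifts 0.59 … −3.80 ppm; amplitudes summing to 1) is the standard
in-vivo characterization; it lives in a versioned constants module and can
be replaced from YAML, since sites calibrate their own models. The decay
term is implemented literally as `exp(μ t)` with signed `t`; the symmetric
alternative `exp(−R2′|t|)` describes reversible dephasing about the spin
echo more physically, but the signed form is the model stated with the
system matrix, and simulation and estimation use the same convention, so
all inversions are self-consistent. Spin-spin (R2) decay along the FSE
train is an acquisition contrast property and is not modeled.

Separation with known `μ` is per-pixel linear least squares via batched
3×3 normal equations; pixels whose normal matrix is numerically singular
(relative eigenvalue < 1e−12) return zero and are counted in a warning.

## Phantom

The phantom emulates an axial slice of a breast with a silicone implant:
an elliptical support holding predominantly adipose tissue (fat fraction
≈ 0.85), a compact fibroglandular region (fat fraction ≈ 0.22), a few small
bright fluid structures, a thin skin rim, and a disc of pure silicone.
The composition matters: the species-specific priors of the joint
reconstruction (identity transform on water) presuppose a water image that
is mostly dark with localized structure, which is the realistic regime for
breast tissue. Field maps are smooth (low-order polynomial + filtered noise
+ a Gaussian bump near the implant edge, scaled to ±120 Hz by default);
R2′ is smooth in 5–40 s⁻¹; coils are eight offset-Gaussian profiles with
smooth phases; the readout-polarity ghost phase is
`φ(x) = c₀ + c₁x + c₂x²` (defaults 0.2, 0.6, 0.15 rad across the FOV),
split symmetrically between polarities (`±φ/2`) because only the difference
is identifiable. Complex Gaussian noise is added to sampled k-space entries
only; its standard deviation is quoted relative to the peak image-domain
coil signal (the unitary DFT makes the two domains equivalent), so
`noise_sigma = 10^(−30/20)` realizes ≈30 dB peak SNR.

The simulator applies the same `JointOperator` the reconstructions invert
(shift → spectral encoding → coil/ghost weighting → unitary DFT → mask), so
a noiseless fully sampled acquisition is exactly invertible and adjoint
tests transfer to the simulator.

## Sampling

Acceleration `R` counts both polarities: `R = (2·Nt·Nky) / #samples`. All
patterns keep a centered ACS block fully sampled in both polarities. At the
desk-scale default `Nky = 128` the ACS is 12 lines — the same fraction as a
32-line ACS in a 360-line acquisition; a 32-line ACS would by itself exceed
the R = 6 budget at this matrix size, and generators raise on such
infeasible combinations.

* *uniform*: per-polarity comb with complementary half-stride offset; the
  outer stride is widened to keep the net R at nominal despite the ACS.
  With `alternate_te=True` the two combs alternate between odd/even echoes
  within each polarity — the pattern a blip-free bipolar train actually
  produces when grouped by readout polarity, and the uniform arm used in
  the undersampling comparison.
* *vd*: variable-density random ky, density ∝ (1 − |ky|/k_max)^p
  (p = 2 default; the literature rarely states its law, so the power is a
  parameter), identical across echoes within a polarity, disjoint draws
  between polarities.
* *incoherent ky–TE*: per-excitation ky trajectories across the echo train
  with |Δky| ≤ 12 steps between adjacent echoes (a per-readout gradient-blip
  constraint), even/odd echoes feeding the standard/flipped interleaf.
  Trajectory starts and steps prefer ky lines not yet covered at any echo,
  which spreads the aggregate encoding across the full ky axis; without
  this coverage preference the random walk resamples central lines and the
  joint reconstruction loses several dB in water PSNR.

`psf` reports per-(polarity, echo) PSFs (inverse DFT of each mask) and a
species-domain PSF: a centered delta in each species channel passed through
the joint normal operator with unit coils and zero field, isolating how
mask/spectral structure spreads aliasing across species and space.
Sidelobe ratios exclude a 3-pixel mainlobe neighborhood: the central skirt
contributed by the fully sampled ACS is resolution loss common to all
patterns, not aliasing, and would otherwise dominate the comparison.

## Ghost correction and calibration

Positive- and negative-polarity data are treated as a `2·n_c`-channel coil
array. ESPIRiT calibration (6×6 kernel shrunk if the ACS is narrow,
singular-value threshold 0.02·σ₁, single eigenmap, eigenvalue crop 0.9 —
standard published defaults, the source protocol states none) on the
spin-echo (t≈0) echo yields polarity-resolved maps S± with the ghost phase
absorbed; phases are referenced to the first positive-readout channel. The
t≈0 echo is used because all species phasors equal one there, making the
calibration data a pure coil-and-ghost weighted proton image. A cheap
`acs_phase_diff` fallback (smoothed low-resolution polarity phase
difference applied to reference coil maps) serves as a cross-check. The
ghost-corrected echo images solve the polarity-stacked SENSE least-squares
problem per echo by conjugate gradients on the normal equations
(tol 1e−9, max 60 iterations, final residual reported on non-convergence).

## Field and R2′ mapping

The f_B search minimizes the VARPRO residual — the norm of the echo vector
after projecting out the span of `A(2πi f)` with R2′ = 0 — normalized by
the echo-vector energy so the residual is scale-invariant and lies in
[0, 1]. Candidates span ±300 Hz at 2 Hz spacing by default (the protocol's
range is unstated; the grid must cover the phantom's ±120 Hz). A
4-neighbor MRF adds `w·|f_p − f_q|` (w = 1e−4 per Hz): large enough to
resolve exact spectral-swap ties of pure-species pixels, small enough not
to flatten genuine gradients — and an absolute-difference penalty adds no
shrinkage to monotone ramps. Optimization is iterated conditional modes
with checkerboard sweeps from three starts: per-pixel argmin (background at
the best constant), the best global constant, and a median-filtered argmin
that repairs compact swap islands single-pixel moves cannot escape; the
lowest-energy result wins, ties break toward the neighborhood median, and a
per-pixel parabolic fit refines f_B below the grid spacing. These choices
were validated on the module's own contract — noiseless smooth phantoms
across seeds recover f_B with RMS error below one grid step. This is a
deliberate single-layer simplification of graph-cut field mapping: its
contract is recovery on smooth maps, not performance near metal.

R2′ ≥ 0 is then fitted per pixel by a vectorized golden-section search on
[0, 100] s⁻¹ (40 shrinks ≈ 4×10⁻⁹ interval), re-solving the 3×3 linear
subproblem at each evaluation. In pipelines, both maps are estimated from
the ghost-corrected ACS reconstruction decimated 4×, then upsampled
bilinearly — field maps are low-resolution by design.

## Reconstructions

**Joint**: FISTA on the species-domain problem with step 1/L (L from 30
power iterations), water soft-thresholded in the image domain, fat and
silicone in an orthogonal Daubechies-4 wavelet (3 levels, periodized —
orthogonality keeps the prox exact; no wavelet family is prescribed by the
protocol). Adaptive thresholds scale each species' λ by the 99th percentile
of its current magnitude (robust to hot pixels), re-estimated over the
first five iterations and then frozen; with frozen thresholds, a restart
rule (discard momentum and take a plain proximal step whenever the
objective rises) makes the objective non-increasing afterwards. Divergence
(objective > 10× initial) aborts with diagnostics. Chemical-shift
displacement is one bulk shift per species (`Δx = f/BW_pixel`, fat using
the amplitude-weighted mean frequency), applied by unitary Fourier phase
ramps with opposite signs per polarity; pixel bandwidth defaults to
1000 Hz/pixel and is configurable. Defaults: max 300 iterations, relative
objective tolerance 1e−6.

**Two-stage**: per-echo FISTA with the polarity-stacked data term and a
single wavelet-L1 weight, then field/R2′ mapping on the echo images and
least-squares separation. It has no displacement correction — that is a
structural property the joint model adds.

**Grid search**: exhaustive 3-D λ evaluation scored by mean SSIM of the
species magnitudes against a reference; deterministic. The experiment
driver uses small grids (2 values per species for the joint problem, 3 for
the two-stage λ) at 40 search iterations, then reconstructs the winner at
full iterations.

## Metrics

All quality metrics act on magnitude images normalized to the reference's
99th percentile (the normalization used upstream is unstated), making them
invariant to common positive rescaling. SSIM uses the standard 11×11
Gaussian window (σ = 1.5, K₁ = 0.01, K₂ = 0.03); PSNR is relative to the
reference peak and capped at 200 dB; GMSD follows the original
formulation (2× average-downsampling, Prewitt gradients, c = 170 on a
0–255 scale, population standard deviation). Leakage ratios are means over
ROIs (the eroded ground-truth masks; erosion by 2 pixels avoids edge
ringing): SWFS = mean silicone-image signal in tissue / in implant;
WS, FS = mean water/fat signal in the implant relative to silicone there.
Ratios of means are used rather than ratios of sums so the numbers do not
depend on ROI sizes. Evaluation is per-slice (2D); volumetric aggregation
is out of scope.

## Experiment design and problem sizes

The retrospective comparison simulates one fully sampled noisy dataset
(128×128, 8 coils, 7 echoes, 30 dB), calibrates once, and retrospectively
masks it with each pattern at R = 6. The fully sampled reference is the
ghost-corrected SENSE reconstruction of the full data separated with the
same ACS-derived μ̂ the undersampled reconstructions use — references and
reconstructions must share calibration inputs, otherwise field-map
differences masquerade as reconstruction error. Comparisons against the
raw phantom truth are also emitted, labeled. These sizes keep the full
tuned comparison in the ten-minute range on one CPU; they are a
desk-scale analogue, not a replication of in-vivo acquisition dimensions.

## What the synthetic study shows — and what it does not

The simulator is model-matched by construction: the reconstruction inverts
the exact operator that generated the data (same shifts, same ghost model,
same spectral basis). Passing tests therefore establish correctness of the
operators and estimators and the *relative* behavior of sampling patterns
and reconstructions under realistic noise, field maps and calibration
error — they do not establish robustness to model mismatch (eddy-current
phase beyond a smooth polarity difference, motion, ramp-sampling
non-Cartesian effects, multi-peak silicone, temperature-shifted spectra) or
performance near metal, none of which are simulated. Absolute SSIM/PSNR
values depend strongly on matrix size, coil count and phantom texture and
are not comparable to in-vivo numbers; the directional findings (joint over
two-stage on all species; incoherent ky–TE over uniform for water and fat;
variable density blurring) are the transferable results.

## Known limitations

* 2D single-slice only; no kz sampling, no 3D reconstruction.
* ICM field mapping can in principle keep a large swap region a graph-cut
  would repair; the multi-start heuristic covers compact islands only.
* The uniform pattern's regularity makes it unusually strong at small
  matrix sizes with smooth simulated coils; comparisons at 128×128 are
  conservative for the incoherent pattern.
* Identity-transform water regularization biases water magnitude slightly
  downward at large λ_w (soft-threshold shrinkage), visible as a global
  intensity drop rather than structural loss.
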