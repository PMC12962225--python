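# wfs-recon

Simulation and reconstruction toolbox for **T2-weighted water–fat–silicone
(WFS) MRI** from bipolar multi-echo fast-spin-echo (FSE) acquisitions.

Breast MRI in patients with silicone implants needs water-, fat- and
silicone-specific T2-weighted images. Chemical-shift encoding acquires each
spin echo with a train of closely spaced bipolar gradient echoes, so the
three species — water at 0 ppm, fat (nine-peak model, bulk ≈ −3.4 ppm) and
silicone (single peak at −4.9 ppm) — accumulate distinct phase and can be
separated. This package implements the full computational chain on a digital
phantom, for method development without scanner data:

* **Signal model** — per pixel, echo images obey `x = A(μ) ρ` with
  `A(μ)` the `Nt×3` encoding matrix, rows
  `exp(μ t_j)·[1, Φ_f(t_j), Φ_s(t_j)]`, `μ = 2πi·f_B − R2′`, and species
  phasors `Φ_f(t) = Σ_p α_p e^{2πi f_p t}`, `Φ_s(t) = e^{2πi f_s t}`.
* **Bipolar simulator** — multi-coil k-space with readout-polarity ghost
  phase, opposing chemical-shift displacement per polarity, and sampled-line
  noise; it applies the *same* linear operator the reconstructions invert.
* **ky–TE undersampling** — uniform, variable-density and incoherent ky–TE
  patterns built from per-excitation ky trajectories with a bounded
  inter-echo jump (≤ 12 Δk), plus point-spread-function analysis.
* **Nyquist ghost correction** — positive/negative readouts stacked along
  the coil dimension, calibrated with an in-package ESPIRiT and combined by
  a SENSE-like least-squares solve.
* **Field mapping** — VARPRO residual over an f_B candidate grid with an
  ICM-optimized smoothness prior, then a per-pixel R2′ fit.
* **Reconstructions** — the joint species-domain compressed-sensing problem

  `min_ρ ‖D± F S± A(μ̂) M± ρ − y±‖² + λ_w‖ρ_w‖₁ + λ_f‖Wρ_f‖₁ + λ_s‖Wρ_s‖₁`

  solved by FISTA with adaptive per-species soft-thresholding, and the
  two-stage baseline (per-echo wavelet-CS reconstruction, then field mapping
  and least-squares separation).
* **Metrics** — SSIM, PSNR, GMSD and the species-leakage percentages
  (silicone signal outside/inside the implant; water/fat signal inside it).

## Worked example

```python
import numpy as np
from wfsrecon import (EchoTimes, FieldCandidates, KSpaceData, PhantomConfig,
                      ReconConfig, ShiftSet, SpectralModel,
                      build_joint_operator, joint_recon, make_incoherent_kyte,
                      make_phantom, make_uniform, simulate_kspace)
from wfsrecon.experiments import estimate_mu_from_acs, reference_reconstruction
from wfsrecon.metrics import evaluate_species
from wfsrecon.ngc import estimate_polarity_sensitivities

model, times = SpectralModel(), EchoTimes.symmetric()
cfg = PhantomConfig(shape=(128, 128), n_coils=8, seed=0,
                    noise_sigma=10 ** (-30 / 20))          # ~30 dB peak SNR
ph = make_phantom(cfg)
shifts = ShiftSet.from_model(model, 1000.0)

full = make_uniform(128, 7, 1.0, 12)
y_full = simulate_kspace(ph, full, times, model, cfg, shifts=shifts.as_tuple)
sens = estimate_polarity_sensitivities(y_full)              # stacked ESPIRiT
mu = estimate_mu_from_acs(y_full, sens, times, model, FieldCandidates())
ref, _, _ = reference_reconstruction(y_full, sens, times, model,
                                     FieldCandidates(), field=mu)

pat = make_incoherent_kyte(128, 7, 6.0, 12, seed=0)         # R = 6
y = KSpaceData(y=y_full.y * pat.mask[:, :, None, :, None], pattern=pat,
               times=times)
E = build_joint_operator(mu, sens, pat, times, model, shifts)
rho, rec = joint_recon(y, E, ReconConfig(lambda_w=2e-2, lambda_f=2e-2,
                                         lambda_s=2e-2, max_iter=250))
rep = evaluate_species(rho, ref, ph.roi_tissue, ph.roi_implant)
print(f"R = {pat.achieved_R:.2f}, {rec.n_iter} iterations")
print(f"SSIM  w/f/s: {rep.ssim_w:.3f} {rep.ssim_f:.3f} {rep.ssim_s:.3f}")
print(f"SWFS leakage: {rep.leakage_swfs:.1f}%")
```

prints (seed 0):

```
R = 5.99, 89 iterations
SSIM  w/f/s: 0.752 0.799 0.926
SWFS leakage: 0.8%
```

i.e. at six-fold acceleration the joint reconstruction retains ~0.75–0.93
structural similarity to the fully sampled reference for the three species,
and the silicone image carries under 1% residual signal outside the implant
relative to inside — the cross-contamination a radiologist would see as
background haze on the silicone-only image.

A command-line interface mirrors the pipeline
(`wfs phantom | sample | calib | fieldmap | recon | eval | compare | demo`);
`wfs demo out/` runs a small end-to-end example and writes the seven output
contrasts (W, F, S, W+F, F+S, W+S, W+F+S) as NIfTI plus a PNG montage.

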