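# usirhf

Under-sampled MR acquisition with **iterative reconstruction and a
high-frequency preserving transform** (Us-IRHF), together with the
phantom-based spatial-resolution metrics and paired clinical statistics
used to evaluate it. Everything runs on synthetic data: a digital slit
phantom stands in for the physical resolution phantom and a seeded
generator emulates paired per-patient contrast ratios and multi-reader
Likert scores.

## Who this is for

MR-physics and image-reconstruction researchers who want a
self-contained, testable reference implementation of:

* **Golden-Angle radial under-sampling** of the ky–kz (phase × slice
  encode) plane — successive diameters through the k-space centre rotated
  by ~111.25°, rasterized outside-in, giving dense central sampling;
* **split-Bregman reconstruction** of each coil image `x_i` from its
  under-sampled k-space data `y_i` by minimizing

  ```
  E_i(x) = ‖y_i − Φ F x_i‖₂² + λ₁‖Ψ_w x_i‖₁ + λ₂‖Ψ_h x_i‖₁
  ```

  where `Φ` restricts to sampled locations, `F` is the centred unitary
  Fourier transform, `Ψ_w` an orthonormal wavelet transform and `Ψ_h` the
  *high-frequency preserving transform*: a binary k-space low-pass whose
  tile spans half the k-space extent. Because only the low-pass output is
  penalized, fine structures (line-like shapes such as ducts or bar
  gauges) pass through the `λ₂` term unpenalized and survive the
  minimization. Default weights λ₁ = λ₂ = 0.5; the wavelet-only
  comparison ("Us-IR") uses λ₁ = 1, λ₂ = 0.
* **SENSE parallel imaging** (regular Cartesian under-sampling, exact
  per-pixel unfolding) with g-factor maps, and g-factor-weighted wavelet
  denoising of the combined magnitude image;
* **edge-method MTF** (oversampled edge-spread function → line-spread
  function → Fourier magnitude) and bar-pattern modulation depth
  `(peak − trough)/(peak + trough)` with a resolvability threshold;
* **paired non-inferiority / superiority analysis** of relative contrast
  ratios `RC = (SI_duct − SI_periduct)/(SI_duct + SI_periduct)` and
  Likert scores (two-sided 95% CI against prespecified margins), plus
  weighted-kappa inter-reader agreement.

## Worked example

```python
import usirhf as u

# 1. sampling geometry: factor-1.7 Golden-Angle mask on a 320 x 75 grid
mask = u.generate_golden_angle_mask(320, 75, 1.7)
print(u.sampling_fraction(mask))        # 0.589  (~60% of encodes, 86 lines)

# 2. three-arm phantom experiment (conventional / Us-IR / Us-IRHF)
report = u.run_phantom_experiment(u.ExperimentConfig(seed=1))
for arm, r in report["arms"].items():
    print(arm, r["matrix"], r["resolved_freqs"], round(r["mtf_area_to_5lpcm"], 2))
```

prints (about 15 s on one CPU):

```
conventional [288, 208] [1.0, 1.7, 2.5, 3.3] 3.81
us_ir        [320, 320] [1.0, 1.7, 2.5, 3.3, 5.0] 4.17
us_irhf      [320, 320] [1.0, 1.7, 2.5, 3.3, 5.0] 4.32
```

Reading: the 1.0–3.3 lp/cm gauges separate in every arm; the **5.0 lp/cm
gauge separates only in the two 320×320 under-sampled iterative arms**
(the 288×208 matrix cannot encode 5 lp/cm — its Nyquist limit along the
bar axis is 3.7 lp/cm); 6.7 and 10.0 lp/cm separate nowhere. The MTF
area up to 5 lp/cm orders Us-IRHF > Us-IR > conventional: the
high-frequency preserving transform shifts regularization pressure off
the fine scales.

The clinical layer, on synthetic paired data emulating a 41-patient
study:

```python
rc, scores = u.generate_clinical_dataset(seed=0)
for duct, c in u.noninferiority_report(rc).items():
    print(duct, f"({c.ci_low:+.3f}, {c.ci_high:+.3f})", c.verdict)
```

```
MPD (-0.014, +0.005) non_inferior
CBD (-0.002, +0.015) non_inferior
LHD (-0.009, +0.012) non_inferior
RHD (-0.018, +0.009) non_inferior
```

— every RC confidence interval lies above minus the prespecified margin
(0.07 / 0.06 / 0.07 / 0.11), the reader-score CIs lie above zero
(superior), and pairwise weighted kappas land at 0.63–0.73
("substantial").

## Command line

```
usirhf mask | phantom | acquire | recon | mtf | stats | experiment
```

e.g. `usirhf experiment --seed 1 --out-dir out/` writes the three
reconstructions (NIfTI), MTF and profile curves (CSV) and a JSON report.

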