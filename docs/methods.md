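# Methods

## Sampling geometry

Golden-Angle radial masks live on the Cartesian (ky, kz) encode grid.
Each acquisition unit is a full diameter through the exact grid centre
(index `n // 2` per axis, centred-spectrum convention, 0-based), at angle
`k · 111.246°` (mod 180°) for line k. Lines span the inscribed ellipse of
the grid, are rasterized by stepping at half-pixel increments and
rounding to the nearest index, with duplicates dropped, and are recorded
outermost-point-first (emulating outside-to-inside acquisition). Whole
lines are added until the sampled fraction first reaches `1/R` for
under-sampling factor R, so the fraction overshoots by at most one
line's worth of points. Factor 1 is special-cased to full sampling
(radial lines alone cannot reach grid corners). The construction is
fully deterministic; golden-angle equidistribution gives a maximum
angular gap below 15° by 50 lines (measured ≈ 6°).

Regular Cartesian (parallel-imaging) masks retain every
`round(R_phase)`-th phase row starting at the DC row; if rounding moves
the effective factor by more than 10% a warning is recorded in the mask
metadata. A helper composes masks by element-wise AND for hybrid
patterns; the simulated under-sampled arms use the radial mask alone,
and the conventional arm the Cartesian mask alone.

## Forward model and reconstruction

The acquisition model is `y_i = Φ F (s_i ⊙ x) + ε` per coil i: `F` the
centred unitary FFT, `Φ` restriction to the mask, `s_i` the coil
sensitivity, `ε` i.i.d. complex Gaussian noise on sampled points. The
per-coil objective

    E_i(x) = ‖y_i − Φ F x_i‖₂² + λ₁‖Ψ_w x_i‖₁ + λ₂‖Ψ_h x_i‖₁

is minimized by split-Bregman with two auxiliary variables (one per L1
branch), Bregman penalty μ = 1, one Fourier-diagonal solve per outer
iteration, at most 30 outer iterations, and termination on relative
image change < 1e-4. `Ψ_w` is Daubechies-4 at 3 levels with *periodized*
boundaries — exactly orthonormal, so `Ψ_wᴴΨ_w = I` and the quadratic
x-subproblem is exactly diagonal in k-space (symmetric extension would
break both properties; the boundary mode remains configurable). `Ψ_h` is
the binary central k-space tile of half the extent per axis (half-open
index range `[n/2 − L/2, n/2 − L/2 + L)`, DC-inclusive), applied as
filter-then-inverse-transform, i.e. the penalty acts on the image-domain
low-pass component. A signal whose spectrum lies outside the tile is
annihilated by `Ψ_h` and therefore never penalized by the λ₂ term —
the mechanism that preserves fine structure.

The tracked objective is non-increasing across outer iterations (a >10%
rise over three iterations raises a divergence error carrying the
trace).

### Regularization scale

λ₁ and λ₂ act as *penalty weights* (defaults 0.5/0.5; the wavelet-only
variant uses 1/0, so the total weight is 1 in both variants). The
absolute shrinkage scale is data-derived: per coil, k-space is
normalized so the zero-filled image has unit maximum magnitude, and the
base threshold is the Donoho–Johnstone universal threshold
`σ̂ · sqrt(2 ln N)`, where σ̂ is the MAD/0.6745 of the finest-scale
diagonal wavelet details of the zero-filled image (capturing noise and
aliasing-streak energy) and N the grid size. Effective thresholds are
`λ_i` times this base. Raw intensity-scale thresholds are meaningless
across data scalings; this calibration makes the weights dimensionless
and places the solver in the regime where wavelet regularization alone
visibly smooths fine detail and the high-frequency preserving branch
visibly rescues it — with plain σ̂ (no `sqrt(2 ln N)`) the penalties are
too weak for the mechanism to matter.

### Coil combination, g-factor, denoising

Per-coil solutions are combined by sensitivity-weighted least squares
`x = Σ s̄_i x_i / Σ |s_i|²`. The geometry-factor map uses the standard
SENSE expression `g = sqrt([(SᴴS)⁻¹]_mm [SᴴS]_mm)` over each aliasing
set of the *regular* (Cartesian) mask component — radial masks have
regular factor 1, hence g ≡ 1; singular sets are capped (default 100),
signal-free positions get g = 1. The final magnitude image is wavelet
soft-thresholded with a spatially varying threshold
`strength · σ̂ · g`, σ̂ again MAD-estimated from the finest diagonal
band; approximation coefficients are untouched and strength 0 is the
exact identity. Strength defaults to 0 at the solver API (keeping the
oracle identity full-sampling/zero-λ ≡ inverse FFT exact) and to 1 in
the experiment driver.

The conventional comparison arm is SENSE unfolding: with phase spacing s
dividing the phase dimension and the retained comb centred on DC, the
zero-filled coil image at row r is exactly
`(1/s) Σ_m s_i(r_m) x(r_m)` over the aliasing set, so a per-pixel
least-squares solve over coils recovers x; aliasing sets with condition
number above 1e8 are solved with Tikhonov regularization and counted in
the provenance; fewer coils than the factor raises an error.

## Digital phantom and acquisition simulation

The slit phantom has seven horizontal strips (20 mm tall, 5 mm apart,
200 mm wide) of vertical bars at 1.0, 1.7, 2.5, 3.3, 5.0, 6.7 and
10.0 lp/cm — gap width `10/(2f)` mm, i.e. 5.0 down to 0.5 mm — with
bright "saline" slits (SI 1.0) on a dimmer "NiCl₂" surround (SI 0.2,
nonzero so relative SI stays finite), inside a 280 mm FOV. Strip widths
give an integer cycle count at every gauge frequency. A dedicated
60 × 40 mm edge block with a 5°-slanted high-contrast edge supports MTF
estimation without ambiguity about which gauge edge to use.
Rasterization anti-aliases by area coverage (4 × 4 sub-pixel averaging);
pixel centres sit at `(i − n//2) · FOV/n` mm, matching the FFT
convention.

Acquisition is band-limited, as on a scanner: the phantom is rasterized
on a fine grid (3 × the largest acquisition matrix, i.e. 960²), its
k-space computed once per coil, and the central region matching the
acquisition matrix extracted (k-space sample spacing 1/FOV is matrix
independent; amplitudes are rescaled to preserve the intensity scale).
A 288 × 208 matrix therefore *truncates* frequencies above its Nyquist
limit instead of aliasing them — the mechanistic reason a 5.0 lp/cm
gauge (Nyquist of the 208 axis: 3.7 lp/cm) cannot be resolved there
while a 320 × 320 matrix (Nyquist 5.7 lp/cm) can. Noise is i.i.d.
complex Gaussian added at sampled points, with σ set by a target mean
k-space SNR (30 dB in the experiment). Coil sensitivities are smooth
complex Gaussian lobes on a ring around the FOV with random phase
ramps, defined in continuous mm coordinates so the same seed yields the
same physical coils at any matrix; the default is 8 channels, a
desk-scale stand-in for a high-count clinical array.

## Resolution metrics

Profiles are taken along the single pixel row through a gauge's centre
and expressed as relative SI against the mean of a pure-background
region. Modulation per gauge is the mean over full one-period windows
(anchored at the profile maximum) of `(max − min)/(max + min)`,
evaluated on the linear interpolant of the pixel profile so patterns
finer than the sampling read out as low modulation. A gauge counts as
"resolved" when modulation ≥ 0.1 — a fixed operationalization of a
human reader's separated/not-separated call, exposed as a config
parameter; with it, the noiseless Nyquist analysis reproduces the
expected pattern (≤ 3.3 lp/cm everywhere, 5.0 only at 320², ≥ 6.7
nowhere).

The edge-method MTF locates the sub-pixel edge crossing per row by a
gradient centroid confined to ±3 px around the strongest gradient
(background texture must not drag the estimate), fits a straight line,
projects pixels onto the edge normal, and bins them at 1/4-pixel pitch
into an oversampled ESF (region interior trimmed by 3 px so the block's
own boundary is excluded; empty bins interpolated). The LSF is the
finite difference of the ESF, windowed by a Tukey window (α = 0.5 —
flat over the LSF core, unlike a Hann window which measurably inflates
the MTF of wide spread functions), Fourier-transformed, normalized to 1
at DC, and corrected for the finite-difference and bin-average aperture
responses (division by sinc², floored to avoid noise blow-up).
Validation against closed forms: an ideal area-sampled step edge
reproduces the pixel-aperture `|sinc(π f Δ)|` within 5% up to 80% of
Nyquist, and Gaussian-blurred edges reproduce
`exp(−2π²σ²f²)·|sinc(π f Δ)|` within 5% where the ideal MTF ≥ 0.2.

## Clinical statistics

`RC = (SI_duct − SI_periduct)/(SI_duct + SI_periduct) ∈ [−1, 1]`.
Paired two-sided CIs are Student-t by default (percentile bootstrap
behind a flag, seeded). Non-inferiority of the per-duct RC difference
holds when the whole 95% CI lies strictly above minus the prespecified
margin (0.07, 0.06, 0.07, 0.11 for MPD, CBD, LHD, RHD — the reference
arm's standard deviations); superiority of score differences when the
CI lies strictly above zero; boundary cases are "inconclusive".
Weighted kappa (quadratic weights by default, linear available) is
computed pairwise across the three readers and reported as a range;
interpretation bands (after rounding to two decimals, half-up):
0.81–1.00 excellent, 0.61–0.80 substantial, 0.41–0.60 moderate,
0.21–0.40 fair, 0.00–0.20 poor. The Wilcoxon signed-rank comparison of
acquisition times is a thin scipy wrapper, deliberately off-the-shelf.

### Synthetic clinical generator

Per duct, paired RC values for the two arms are drawn from a bivariate
normal with equal means (0.80, 0.89, 0.88, 0.86 — the published
central values), per-duct SD equal to the margins above, inter-arm
correlation 0.9 (repeated measurement of the same patient), clipped to
(−1, 1); consistent SI pairs are emitted alongside. Likert scores come
from a latent-normal model: per patient-item latent (mean 3.3, SD 0.8),
arm shift +0.3 for the under-sampled arm (matching the published score
differences of ~0.3), per-reader noise SD 0.5, rounded and clipped to
1–5. These defaults reproduce the study's verdict pattern (all ducts
non-inferior in RC, all items superior in score, kappa "substantial")
and, with the shift set to 0, control the false-superiority rate at the
nominal level (≤ 7% over 500 replicates in the test suite). What the
generator does *not* model: consensus reads, ordinal floor/ceiling
asymmetries, reader-specific bias, missing data, or any real anatomy —
passing tests demonstrate correctness of the statistical machinery and
self-consistency of the simulation, not clinical performance.

## Experiment driver and problem sizes

The default experiment is a single 2D slice-plane problem per arm:
conventional 288 × 208 (Cartesian, phase factor 3 on the 288 axis —
divisible by 3, exact aliasing sets — with the 208 axis along the bar
modulation), Us-IR and Us-IRHF 320 × 320 with the factor-1.7
Golden-Angle mask and (λ₁, λ₂) = (1, 0) and (0.5, 0.5) respectively;
8 coils, 30 dB k-space SNR, truth rasterized at 960². These sizes keep
a full three-arm run around 15 s on one CPU while preserving every
mechanism of interest (the matrix-Nyquist contrast, parallel-imaging
unfolding, radial-streak behaviour and the regularization trade-off).
Reports are deterministic given the seed (child seeds for coils and
noise are spawned from it) and serialized with sorted keys so repeated
runs are byte-identical.

## Known limitations

* No pulse-sequence physics (TR/TE, T1/T2 contrast, respiratory
  triggering), no motion, no off-resonance or eddy currents.
* Coil sensitivities are known exactly; no self-calibration.
* The g-factor-weighted denoiser is a reasonable reading of
  "wavelet denoising with geometry-factor weighting", not a
  reimplementation of any vendor algorithm.
* The 2D slice-plane geometry conflates the bar-modulation axis with a
  phase-encode axis; a full 3D treatment (kx readout plus ky–kz
  encoding) is out of scope.
* Non-Cartesian readouts (true radial/spiral gridding, NUFFT) and
  Poisson-disk/variable-density random sampling are out of scope.
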