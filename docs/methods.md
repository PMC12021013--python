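# Methods

## The measurement model

`tiettd` measures the protein mass concentration **P** (g/ml), water content
**W** and dry mass of adherent cells from nothing but transmission images on
a standard brightfield microscope, by combining two channels:

1. **Quantitative phase (TIE).** A transparent cell delays light in
   proportion to the product of its thickness h and refractive index
   elevation Δn over the medium: Δφ = (2π/λ)·h·Δn. Because the refractive
   increment of protein is remarkably universal — Δn ≈ 0.185 ml/g · P for
   most proteins and nucleic acids, linear up to ~55% w/v — the *integrated*
   phase over the cell area is proportional to total protein mass, and
   dividing by cell volume gives P = 0.86·λ·ΣΔφ/V, where
   0.86 = 1/(2π·0.185).

   The phase itself is recovered from two brightfield images collected
   symmetrically about best focus. The transport-of-intensity equation links
   the axial intensity derivative to the transverse Laplacian of phase:

       (2π·n_imm/λ) · ΔI/(Ī·Δz′) = −∇²φ.

   `Δz′` is the *full* mechanical separation between the two planes as read
   from the focus drive; `n_imm` is the immersion index of the objective.
   The mounting-medium index n₀ affects both the refraction of rays and the
   axial foreshortening of the focal shift, and the two effects cancel, so
   the solver ignores it (it is recorded on `OpticalConfig` for provenance
   only, and a regression test asserts bit-identical output when it varies).

2. **Volume (TTD).** An impermeant absorbing dye (Acid Blue 9, absorbance
   peak 630 nm) surrounds the cells; an intact cell excludes it and thins
   the absorbing layer, so cells appear *brighter* in proportion to their
   height. Beer–Lambert inversion gives h = (ln I − ln I_bkg)/α per pixel
   and V = (A/α)(mean ln I − mean ln I_bkg) per ROI. Natural logarithms
   throughout; the background term is the mean of ln I over the background
   region, not the log of the mean.

Switching between channels is a wavelength switch (blue ≈ 486 nm for TIE,
where AB9 barely absorbs; red ≈ 630 nm for TTD), so both are acquired on the
same microscope with the cells in place, and ROI label images transfer
between them unchanged. W = 1 − 0.7·P converts the result to water content,
and P·V (with 1 g/ml ≡ 1 pg/µm³) is the dry mass in pg.

## The TIE solver

The solver (`solve_tie`) is deliberately concrete and fully specified:

* dark level subtracted from both frames, images promoted to float;
* mean-intensity equalization: BF1′ = BF1 + ½(mean BF2 − mean BF1) and
  symmetrically, which removes global exposure differences exactly from the
  difference term. (A constant offset on one frame still shifts the
  denominator Ī by half the offset, so the output changes by offset/2Ī —
  about 2.4% for 50 counts on a 1000-count base. Offsets are removed from
  the numerator, attenuated — not annihilated — overall.);
* source term S = (2π·n_imm/λ)·(BF1′−BF2′)/(Ī·Δz′), with Ī the pixelwise
  mean of the equalized pair, floor-clamped at 10⁻⁶ of the field mean;
* spectral inversion of −∇² in a DCT-II basis. The 5-point Laplacian with
  half-sample symmetric (Neumann/mirror) boundaries is exactly diagonal in
  DCT-II, with per-axis eigenvalues (2−2cos(πk/N))/Δx². The inverse transfer
  function 1/k² is damped to 1/(k² + ε·k²_max); the DC mode is the gauge and
  is set to zero;
* a 1-pixel border is trimmed on every side (output is 2 px smaller per
  dimension, matching the behavior users of the original plugin expect) and
  the trimmed field is re-centered to zero mean.

**Choice of ε.** Default ε = 1e-3 suppresses the low-frequency noise
amplification inherent in inverting a Laplacian (noise power in mode k grows
as 1/k⁴), at the cost of attenuating true low-frequency phase — which is
precisely why reconstructed values are *relative* (designated T, not φ) and
why the bead calibration exists. ε = 0 is the oracle mode: together with a
forward model built on the same discrete operator, `forward_tie_pair ∘
solve_tie` is an identity (minus mean) to machine precision, and the test
suite pins this at relative L2 < 1e-6.

**Sign convention.** BF1 is the overfocused frame. A positive-Δn object
(e.g. a bead denser than the oil) focuses light and appears bright in BF1,
giving positive integrated T. A calibration fit with the wrong sign aborts
with a hint that the frames are swapped.

**Gauge.** The TIE determines phase up to an additive constant. Two
resolutions coexist deliberately: the solver outputs a zero-mean field, and
quantification uses background-corrected ROI integrals A·(T̄ − T_bkg), which
are invariant under any constant offset. The latter is the path all
downstream numbers take.

## Calibration

**Bead-in-oil (s).** Beads of known diameter (default 7.7 µm, volume
(π/6)d³ ≈ 239 µm³) are imaged in a series of index oils. For each oil the
background-corrected integrated T per bead, divided by the bead volume, is
regressed against n_oil by ordinary least squares; g = −slope and
s = 1/(0.185·g) µm. Groups of N beads are divided by N before fitting. The
bead's own index only shifts the intercept, so it is metadata, not a fit
input. An end-to-end test simulates five oils spanning Δn ∈ [−0.10, +0.10]
and requires the fitted s to land within 5% of the theoretical
0.86·λ ≈ 0.418 µm at λ = 0.486 µm (the measured value is within 0.2%; the
residual is sphere-sampling discretization).

**Half-ball lens (α).** The dye layer depth under a lens of radius R resting
on the slide is h(d) = R − √(R² − d²). The radial intensity profile
(1-px annular means) is converted to depths, and ln(I − dark) is regressed
against h; α = −slope. The innermost 5% of the lens radius is excluded (the
near-zero depths are dominated by centering error; the protocol says "very
low h" without a number, 5% is this package's choice) and the last bin is
always dropped (an artifact of the original profiling plugin, kept for
drop-in compatibility). r² < 0.9999 warns but does not abort.

## Synthetic data: what it does and does not emulate

The generator produces the three study conditions used throughout the tests:

* **Phantoms.** Spheres (chord-thickness phase), spherical caps (adherent
  cell shape; footprint 20 µm, apex 5 µm by default), Gaussian bumps (1 rad,
  σ = 6 µm). Default field 256×256 px at 0.3 µm/px; noisy end-to-end checks
  use 128×128 crops, mirroring the protocol advice to crop cells closely —
  the lowest retained spatial frequency rises with 1/field size, and it is
  the lowest frequencies that the inverse Laplacian amplifies.
* **Brightfield pairs** via the discrete TIE read forward:
  BF1,2 = I₀(1 ± c/2) with c = −(λΔz′/2πn_imm)·∇²φ. A contrast |c| > 1 is
  rejected as unphysical with a hint to reduce Δz′. The sqrt-cusp at a
  sphere's rim makes the discrete Laplacian spike there, so phantom builders
  accept an integral-preserving Gaussian pre-blur (`edge_smooth_px`,
  1 px in the end-to-end tests) standing in for finite optical resolution.
* **TTD images** I = I_bkg·e^(αh) and **half-ball images**
  I = I₀·e^(−α·h(d)).
* **Noise**: multiplicative Gaussian with σ as a fraction of local intensity
  (the natural parameterization when sensitivity limits are quoted as ΔI/I),
  or scaled Poisson. Every generator is deterministic given a seed.

Not emulated: partial coherence and the objective OTF (images are formed by
the TIE itself, so solver accuracy statements are about the inversion, not
about how well the TIE approximates a real microscope), dust/flat-field
"blotchy" background structure, registration error between channels (crops
are assumed aligned), and dye leakage into damaged cells. Passing tests
therefore demonstrate the correctness and noise behavior of the *analysis*,
not the validity of the TIE approximation for any particular optic.

## Numerical and design choices

* Units: µm, counts, g/ml, pg; 1 g/ml = 1 pg/µm³ removes all unit juggling
  between the phase, volume and mass formulas.
* `roi_volume` raises (rather than clamps) on pixels at or below the dark
  level: a dark pixel in a TTD image signals membrane damage, saturation or
  a wrong dark level, and silently clamping would bias volumes.
* Constant radial profiles return α = 0 with r² = NaN and a warning, rather
  than an error: a flat profile is a meaningful "no absorption detected".
* Least squares via `scipy.stats.linregress`; spectral transforms via
  `scipy.fft` DCT-II with orthonormal scaling.
* Batch driver: ROIs are cropped to padded bounding boxes (16 px default)
  before TIE; per-ROI failures are logged and skipped; a failed triplet sets
  a non-zero process exit code but does not stop the run. CSV output uses a
  fixed `%.8g` float format so identical inputs give byte-identical files.
* Problem sizes: tests and the acceptance script run on 256×256 (clean) and
  128×128 (noisy) synthetic fields, which the full suite completes in a few
  seconds; the pipeline itself is O(N log N) per field and handles camera-
  sized frames comfortably.

## Known limitations

* The damped inversion at ε > 0 is one concrete choice of denoising; T
  values at ε > 0 are instrument- and ε-dependent by construction, and only
  calibrated quantities (s·T) are comparable across setups.
* One reported rule-of-thumb in the source protocol literature — that 0.4 µm
  of depth should be resolvable at ΔI/I = 0.01 with 10 mg/ml dye — is
  inconsistent with the stated relation (ΔI/I)/α ≈ 0.045 µm; this package
  encodes only the ratio rule, not the 0.4 µm figure.
* No automatic lens touch-point detection, ROI drawing, or image
  registration; these remain manual/upstream steps.
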