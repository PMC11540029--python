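# Methods notes

## Chromatic model

The wavelength dependence of the eye's refractive error is modelled with
the reduced-eye dispersion form `D(λ) = p − q/(λ − c)` (λ in µm), using the
published constants p = 1.68524 D, q = 0.63346 D·µm, c = 0.21410 µm. The
function is strictly increasing and concave over the visible range, crosses
zero near 590 nm, and spans ≈ 1.2 D between the default 450 nm and 650 nm
primaries. The constants are stored as ordinary model parameters so that
individual-eye variants can be substituted.

Design choices that were genuinely open:

* **DRD schedule.** The desired retinal defocus is a flat ±3 D at the red
  and blue primaries and exactly 0 at green. The alternative — letting DRD
  follow an LCA-shaped curve — was rejected because it breaks the defining
  property of the stimuli: a color-signed myopic stimulus must blur blue
  more than red (ICD_blue = 3 − (−0.80) = +3.80 D vs. ICD_red = 3 − 0.43 =
  +2.57 D), and the hyperopic stimulus the reverse.
* **Sign convention.** Positive defocus is myopic; the +3 D stimulus is the
  myopic (CSM) one.
* **Reference condition.** Nothing is imposed: the plan carries ICD = 0 in
  every channel (the LCA terms are zeroed in that plan so the bookkeeping
  identity ICD + LCA = DRD and the all-zero DRD both hold), and the
  renderer treats it as an exact passthrough.
* **Primaries.** Display primaries default to 450/550/650 nm and are
  configurable; only the 550 nm in-focus green anchor is fixed by the
  stimulus definition. Channel spectral power distributions are an opt-in:
  when supplied, a channel's PSF is the SPD-weighted mixture of
  monochromatic PSFs with each wavelength's defocus offset by its LCA
  relative to the channel primary.

## PSF synthesis

Kernels are computed as the squared modulus of the Fourier transform of a
circular pupil carrying a quadratic defocus phase, W20 = D·r²/2 at the
margin. Numerics:

* The pupil is sampled so that the steepest local phase (DFT tilt at the
  largest requested field angle plus the defocus phase slope at the margin)
  stays below Nyquist; if that would need more than 4096 samples per axis
  the computation refuses (`AliasingError`) rather than aliasing silently.
* The field is evaluated by a direct separable DFT on a fine angular grid
  (at least 4 samples per display pixel and ≥3 per Airy radius), squared,
  box-integrated onto display pixels and renormalized to unit sum. Display
  pixels are non-square in angle (28.5°/1920 ≈ 0.891′ horizontally,
  17°/1080 ≈ 0.944′ vertically) and the two plate scales are honored
  separately.
* Kernel support is auto-sized to the geometric blur diameter (|D|·pupil)
  plus two Airy radii, rounded up to odd side lengths; energy lost to
  truncation is restored by renormalization.
* Default pupil diameter is 4 mm — a typical photopic pupil for indoor
  video viewing — and configurable.

Verified properties: zero-defocus kernels place the first Airy zero at
1.22λ/d within a fraction of a display pixel; ±3 D kernels are identical
(pure defocus is sign-blind) and radially symmetric on isotropic grids; the
90%-energy diameter of the 3 D / 4 mm kernel sits within 15% of the
geometric blur circle (a uniform disk holds 90% of its energy within ≈0.95
of its diameter, so the slight undershoot is expected); blur diameter grows
monotonically with |defocus|.

`kernel_mtf` gives the radially averaged padded-FFT transfer curve for
inspection; `mtf_at` evaluates the transfer modulus exactly at arbitrary
radial frequencies (azimuth-averaged direct DFT) and is the tight oracle
used when comparing measured attenuation against theory.

## Rendering

Channels are convolved in **linear light**: frames are decoded with an
assumed display gamma of 2.2, convolved, re-encoded and re-quantized to the
input bit depth (optical blur combines linear intensities; a
`linearize=False` switch reproduces naive gamma-domain processing, and
float frames in [0, 1] bypass quantization entirely, which is what the
impulse-response tests use). Padding is reflective, so unit-sum kernels
conserve mean luminance without dark borders. Out-of-range values after
re-encoding are clipped and counted in the run log. Frame sequences are
rendered with kernels computed once; the run validates every input frame
before writing anything, so a bad frame cannot leave partial output, and
the JSON run log records the defocus plan, plate scale, options and
per-frame content hashes, making reruns byte-verifiable.

## Spectral characterization

Amplitude spectra use a Hann window, DC normalization, and log-spaced bins
(30 per decade) from 0.1 cyc/deg to the coarser-axis Nyquist, with every
2-D transform sample mapped to its true radial frequency before binning
(necessary with non-square angular pixels). Two conventions worth noting:

* bins report the **mean sample frequency** of their members rather than
  the geometric bin center — at low frequencies a log bin contains only a
  handful of discrete DFT samples and the nominal center can be off by most
  of a frequency step;
* samples inside the Hann window's DC mainlobe (< 2.5 frequency steps) are
  excluded, since they carry mean-luminance leakage rather than image
  structure.

The attenuation oracle compares the bin-wise rendered/original amplitude
ratio of 1/f noise frames against `mtf_at` of the corresponding kernel. On
512×512 frames the agreement is within ≈0.03 across the 0.4–1.2 cyc/deg
mid-band (inside the main lobe of every defocus MTF involved, where the
ordering "more defocus ⇒ more attenuation" is monotone); the tests assert
0.05. Above the first MTF null the ratio estimate is dominated by leakage
around near-zero transfer and is not asserted.

## Biometry reduction and statistics

* Replicate biometer readings (target five per session) are screened
  against physiological bounds (AL 15–35 mm, VCD 10–25 mm, LT 2–6 mm,
  AL > VCD) and averaged arithmetically.
* Choroidal thickness profiles live on a fixed fovea-centered grid of 91
  points at 100 µm spacing (±4.5 mm, nasal negative). Boundary traces must
  cover the full extent and keep the outer (choroid–sclera) boundary below
  the inner (RPE) one; thickness is interpolated linearly. The subfoveal
  summary is the mean of the 11 central points (±0.5 mm).
* The grader rule compares the two graders' **subfoveal summaries** against
  the 15 µm tolerance (a pointwise variant is available); within tolerance
  the consensus is the two-grader mean, otherwise a supplied third grader
  triggers a three-grader mean, and without one the result is an explicit
  `needs_adjudication` status with an audit record — never a silent value.
* Changes are post minus pre. `condition_statistics` reports per-condition
  mean ± SD with a one-sample t-test of the changes, a one-way
  repeated-measures ANOVA across conditions on complete cases, and
  Bonferroni-corrected pairwise paired t-tests on all available pairs, with
  every n disclosed — the natural design is unbalanced (17/15/10 sessions
  in the packaged roster), so complete-case and pairwise n's differ. All
  tests are two-sided at α = 0.05.

## Synthetic data

The generators encode the study conditions the analysis is meant to face:

* **Cohorts.** 17 subjects by default, with 8 completing all three
  conditions, 7 reference+CSM and 2 reference+CSH. Axial length is composed
  as AL = ACD + LT + VCD per replicate, so ΔAL ≡ ΔACD + ΔLT + ΔVCD holds
  exactly by construction. Baseline spreads (ACD 3.65 ± 0.25, LT 3.50 ±
  0.20, VCD 17.9 ± 0.9 mm; subfoveal ChT 236.3 ± 69.9 µm between subjects,
  7.55 µm across visits within a subject) and the default per-condition
  effects (e.g. ΔVCD +0.034 ± 0.03 mm and ΔLT −0.033 ± 0.03 mm for CSH,
  ΔVCD −0.024 ± 0.04 mm for CSM, near-zero drifts for reference) are
  configuration values chosen to be realistic for young adult myopic
  cohorts; replicate noise is 0.01–0.02 mm per component, consistent with
  optical-biometer repeatability. Every run emits a truth record of all
  generating parameters.
* **Frames.** 1/f-family noise (exact spectral envelope `f^slope` applied
  in the Fourier domain, RMS contrast 0.3, gamma-encoded to 8 bits),
  gratings, impulses, uniform fields and edge patterns. These reproduce
  natural scenes' broadband amplitude statistics but none of their phase
  structure, motion, or color correlation — passing tests therefore
  demonstrate correct linear-systems behavior of the pipeline, not
  perceptual equivalence to nature footage.
* **Boundary traces.** Grader noise is a smooth (1-mm correlation length)
  offset plus white jitter, split 0.8/0.6 of the requested SD so the two
  components add to it in quadrature, reflecting that human boundary
  tracing errs in spatially coherent strokes.
* `paired_test_rejection_mc` vectorizes thousands of simulated cohorts
  through the same replicate-averaging, differencing and paired t-test
  steps as the table pipeline (their p-values agree exactly on shared
  datasets; this is asserted in the tests) to measure type-I error and
  power cheaply. Under a null cohort of 17 subjects the per-contrast
  rejection rate matches α = 0.05 within binomial bounds and the
  Bonferroni family-wise rate stays at or below α.

Problem sizes used in the shipped tests — 5000 Monte-Carlo cohorts of 17
subjects, one recovery cohort of 1000 subjects, eight 512×512 frames for
the spectral oracle — keep the full suite under a few minutes on one CPU
while leaving Monte-Carlo error well inside every asserted tolerance.

## Known limitations

* No Stiles–Crawford apodization, higher-order aberrations, intraocular
  scatter, accommodation or eye-movement blur; the PSF model is pure
  defocus plus diffraction.
* Projector SPDs, colorimetry and compression are out of scope; frame I/O
  is lossless image sequences, and any video-container transcoding is left
  to external tools.
* The choroid module consumes boundary *traces*; OCT B-scan segmentation
  itself is an instrument/software concern outside this package.
* The repeated-measures ANOVA treats condition as the single within factor
  applied to post-minus-pre changes; a condition × time variant on raw
  values is possible with the same tables but is not wired in by default.
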