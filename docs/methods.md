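# Methods

## Problem and model

LED-based photoacoustic (PA) probes place two rectangular LED units beside
a linear ultrasound transducer, inclined toward the imaging plane.  The
light that reaches a tissue location r at wavelength λ is therefore
strongly depth- and wavelength-dependent, and the reconstructed PA
amplitude

    p(r, λ) = Γ μₐ(r, λ) Φ(r, λ),
    μₐ(r, λ) = ε_HbR(λ) c_HbR(r) + ε_HbO2(λ) c_HbO2(r)

confounds blood absorption with the fluence Φ.  The package models Φ with
a voxel Monte-Carlo simulation of the probe's LED source set in a medium
derived from the co-registered B-mode ultrasound image, divides the PA
images by the modeled fluence (after pulse-energy normalization), and
solves the per-pixel 2×2 system A x = b for the two hemoglobin
concentrations; oxygen saturation is sO2 = 100·c_HbO2/(c_HbO2 + c_HbR),
clipped to [0, 100] and masked by an amplitude gate.  Because sO2 is a
concentration ratio, it is invariant to the Grüneisen factor, to any
common rescaling of the two compensated images, and to the base-10 vs
natural-log extinction convention; the test suite asserts these
invariances exactly.

## Probe geometry

The default probe carries two 50 × 10 mm LED units, tilted 41.4° from the
transducer face, outer edges 0.15 mm in front of it, deep (advanced) edges
facing each other across a 9.56 mm gap.  Each unit holds four element rows
(1.72 mm row pitch, centered across the width, ordered 850/750/850/750
from the outer edge): 36-element rows at 850 nm and 24-element rows at
750 nm, 1.4 mm element pitch, rows centered along the unit.  Every element
emits uniformly into a 120° full-angle cone about the tilted face normal
(a cosine-weighted option exists); elements of one wavelength share its
pulse energy equally (850:750 delivered energy 2:1, 200 vs 100 µJ).  The
published row arrangement says only that the wavelengths alternate; the
chosen order and the equal per-element split are configuration, not
hard-coded.  With this geometry the advanced row tips reach ≈6.8 mm depth;
the usable-ROI start is nevertheless an independent parameter defaulting
to 9.2 mm, the advanced LED position quoted for the real probe, since the
two numbers cannot be reconciled from the published dimensions alone.

## Light transport

Photon transport is a weighted random walk with Woodcock (delta) tracking
against the majorant attenuation coefficient: free paths are sampled at
μ_t,max; tentative collisions are real with probability μ_t(voxel)/μ_t,max.
Real collisions deposit the fraction μₐ/μ_t of the weight (implicit
capture) and scatter the remainder through a Henyey–Greenstein deflection
with the table's anisotropy (g = 0.9 for tissue), using the full
scattering coefficient μ_s = μ_s′/(1−g).  Fluence is scored with the
expected-value collision estimator — every tentative collision deposits
w/μ_t,max, whose expectation is the path integral of the weight, equal to
absorbed-weight/μₐ per voxel and well defined where μₐ = 0.  Russian
roulette triggers below weight 1e-4 (survival 1/10).  Refractive index is
matched everywhere: no boundary reflection or refraction, and photons
leaving the grid are terminated.  Randomness is a counter-based
splitmix64 stream keyed on (seed, photon index), so maps are
bit-reproducible and independent of execution order.  An energy ledger
(launched + roulette gains = absorbed + escaped + roulette losses) is
returned with every map and holds to float round-off.

Three optional, exactness-preserving accelerations exist:

* **mirror fold** — the probe is mirror-symmetric about the imaging plane,
  so a half grid with one unit and a specular boundary at y = 0 is exactly
  equivalent to the full domain and doubles the scoring density;
* **scoring box** — fluence accumulation can be restricted to the region
  actually analyzed; trajectories are untouched, so in-box values are
  identical while the accumulator stays cache-resident;
* **importance roulette** — weight-compensated roulette outside a user
  box.  Unbiased in expectation but heavy-tailed; at ≲1e7 photons it
  visibly undersamples deep profiles, so it is off for all quantitative
  results here and documented as a caveat.

Background (label 0) is water: absorption from a bundled standard table
(0.026 cm⁻¹ at 750 nm, 0.043 cm⁻¹ at 850 nm), negligible scattering.
Tissue presets carry the published phantom/mouse/forearm values (the
mouse preset contains a duplicated 850 nm row exactly as published;
loading it warns and requires explicit reassignment).

## Ultrasound segmentation and medium construction

Segmentation is deliberately classical and fixed in order: square median
filter (default 5×5), global threshold (a required input — chosen
manually per tissue type; an Otsu suggestion is attached to the result but
never applied), Sobel edge map (diagnostic output), morphological hole
filling, largest connected component.  For two-slab scenes the water
region above a given row is forced to background.  The mask is centered
laterally on the simulation grid, edge-replicated to the grid width,
and extruded uniformly along elevation; in-footprint pixels transfer
exactly (mask pitch must equal grid spacing).

## Synthetic data

The generator reproduces the bench conditions the method was validated
with, not generic imagery:

* **media** — homogeneous tissue-mimicking medium (μₐ = 0.101/0.089 cm⁻¹,
  μ_s′ = 10.5/9 cm⁻¹ at 750/850 nm, g = 0.9) or a two-slab water-over-
  tissue phantom with a configurable interface depth;
* **tubes** — 0.5 mm inner-diameter cross-sections at chosen depths,
  filled with blood of a prescribed sO2 at 150 g/L total hemoglobin
  (converted with the 64.5 kg/mol tetramer weight; only ratios matter for
  sO2).  Tubes are optically transparent in the transport medium while
  their blood drives the PA signal, matching how thin-walled polythene
  tubes behave;
* **forward PA images** — initial-pressure maps Γ μₐ Φ E plus optional
  per-pixel Gaussian noise.  Acoustic propagation, band-limited detection
  and reconstruction are deliberately not simulated: the unmixing math
  operates on reconstructed amplitude proportional to p₀, and detector
  bandwidth effects are out of scope.  Consequently the synthetic loop
  validates the optics and algebra of the method, not transducer physics;
* **B-mode speckle** — dense complex-Gaussian scatterers convolved with a
  small Gaussian PSF and envelope-detected, giving Rayleigh-distributed
  tissue amplitudes (KS-tested), dark water and a bright interface line;
  the generator records the true boundary row per column.

Noise protocol for closed-loop experiments: the Gaussian sigma is set per
wavelength so that the mean |amplitude| of the weakest (deepest) tube sits
the requested SNR (dB) above the noise floor — every evaluated tube then
carries at least the nominal SNR — and 20 frames are averaged before
unmixing, the acquisition convention of the bench validation.  Display
validity in the closed loop is gated on *compensated* amplitude contrast
(pixels above 5× the median compensated amplitude, one shared mask for
both branches): blood absorbs ~30× more than the tissue background and
dividing by the fluence makes that contrast depth-independent, whereas a
raw-amplitude noise gate cannot separate bright shallow background from
dim deep tubes in a phantom whose background genuinely absorbs (real
systems suppress that smooth background through band-limited detection,
which is out of scope here).

## Validation experiments and scales

All validation runs are synthetic and reduced in scale relative to the
instrument rasters (148 µm voxels instead of 74 µm; laterally truncated
grids; these choices are insensitive for the measured quantities and keep
single-CPU runtimes in minutes):

* **penetration depths** — homogeneous phantom, default probe, 1e7
  photons per wavelength on a mirror-folded 55 × 15.4 × 37.9 mm half
  grid.  The axial profile is averaged over the central ±1.5 mm lateral
  band and taken through the elevational plane of the wavelength's most
  advanced LED row, where the illumination peak sits; reported is the
  depth below the 9.2 mm ROI start at which it first drops to 1/e.  On
  the imaging plane itself the deep decay tends to 1/μ_eff (≈5.6 mm at
  750 nm) for any geometry of a 50-mm-wide array, which cannot reproduce
  the known 3.6/4.2 mm figures; the through-row convention — consistent
  with the description of the fluence peak lying at the LED locations —
  does, and is the documented choice for this under-specified
  measurement.
* **physics oracles** — absorption-only Beer–Lambert decay within
  Poisson counting error; isotropic-source fluence versus the diffusion
  closed form exp(−μ_eff r)/r within 10% over 2–8 transport mean free
  paths (one fitted amplitude); HG sampler moments at g ∈ {0, 0.5, 0.9}.
* **closed loop** — tubes at 5/10/15 mm, truth 96%: generate → compensate
  with the same maps → unmix; ROI means over 0.6 mm squares.  Noise-free
  recovery is exact by construction up to ROI-edge pixels; the 10 dB /
  20-frame protocol tests noise robustness.  The uncompensated branch
  (unit fluence, energy normalization only) exhibits the depth-dependent
  spectral bias that compensation removes — here tens of percentage
  points, because the absolute Φ750/Φ850 ratio delivered by the probe is
  far from one.  Note the *direction* of the depth trend: with this
  probe's optics Φ750/Φ850 falls with depth (750 nm attenuates faster,
  consistent with the penetration depths), which pushes uncompensated
  sO2 *upward* with depth; a monotone *decrease*, as instrument data can
  show, emerges only when deeper tubes are noise-dominated or when
  band-limited detection reshapes the background — neither of which this
  optics-only forward model includes.  The comparison report carries the
  per-depth means and a monotone-trend statistic so the regime is
  visible.
* **segmentation recovery** — 20 seeded two-slab speckle images; the
  recovered boundary must sit within ±2 px of the generator's truth at
  every column.

## Numerical choices and degenerate inputs

Fluence floor: compensation marks pixels with Φ below 1e-3 of the map
maximum invalid instead of dividing (prevents noise blow-up at depth).
Amplitude gate: by default sO2 is shown where the mean energy-normalized
amplitude exceeds 2 × a robust noise scale (1.4826·MAD of the image); the
pipeline also offers the compensated-contrast gate described above
(``gate_mode="compensated"``), appropriate when the background itself
absorbs.  Negative
least-squares concentrations are kept for diagnostics; sO2 uses the ratio
then clips to [0, 100], and pixels with non-positive total hemoglobin are
invalid.  The 2×2 solve is closed-form; matrices with condition number
above 1e6 are rejected.  Median kernel, thresholds, photon counts, grid
shape/spacing and the ROI-start depth are all explicit parameters echoed
into the provenance record.  Ties and edges: the 1/e crossing is located
by linear interpolation between pixel centers; even-sized elevational
axes use the mean of the two central slices as the imaging plane.

## Known limitations

No acoustic modeling (bandlimited detection, reconstruction artifacts,
depth-dependent system gain) — the closed loop therefore understates the
biases a real system adds, and the uncompensated depth trend can differ
in sign from instrument data at high sO2.  Single tissue label from
segmentation (plus water): no multi-tissue media.  No refractive-index
mismatch or boundary reflections.  Monochromatic sources (no LED spectral
bandwidth).  The bundled extinction values are standard compiled numbers
at the two operating wavelengths with coarse interpolation elsewhere;
users with calibrated spectra should supply their own table.
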