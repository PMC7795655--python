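# oxylight

Fluence-compensated oxygen-saturation (sO2) imaging for dual-wavelength
LED photoacoustic probes.

LED-based photoacoustic systems illuminate tissue with two inclined LED
bars (750 nm and 850 nm here) flanking the ultrasound transducer.  The
delivered light field is oblique, divergent and wavelength-dependent, so
naive spectral unmixing of the two photoacoustic images misestimates
hemoglobin oxygenation more and more with depth.  `oxylight` implements
the model-based correction: segment the co-registered B-mode ultrasound
image into a tissue mask, run a Monte-Carlo simulation of the probe's
240-element LED source set through the masked medium, divide the
photoacoustic images by the simulated fluence maps, and unmix.  It is
aimed at photoacoustic-imaging researchers who have reconstructed,
co-registered US/PA rasters (or want fully synthetic phantoms) and need
quantitative sO2 maps with provenance.

## Model

The reconstructed photoacoustic amplitude at position r and wavelength λᵢ
is

    p(r, λᵢ) = Γ μₐ(r, λᵢ) Φ(r, λᵢ),
    μₐ = ε_HbR(λᵢ) c_HbR + ε_HbO2(λᵢ) c_HbO2 .

With fluence-compensated images b(r, λᵢ) = p/Φ and the 2×2 extinction
matrix A = [[ε_HbR(λ₁), ε_HbO2(λ₁)], [ε_HbR(λ₂), ε_HbO2(λ₂)]], the
concentrations are the per-pixel least-squares solution x = (AᵀA)⁻¹Aᵀb
(exact for two wavelengths), and

    sO2(r) = c_HbO2 / (c_HbO2 + c_HbR) × 100% .

Φ is computed by weighted-photon Monte-Carlo transport (Woodcock
tracking, Henyey–Greenstein scattering with g = 0.9, μs = μs′/(1−g),
matched refractive index) from the probe geometry: two 50 × 10 mm LED
units tilted 41.4° toward the imaging plane, four element rows per unit
(2 × 36 at 850 nm, 2 × 24 at 750 nm), 120° emission cones, 2:1 pulse
energy ratio.  sO2 is invariant to Γ and to the extinction-table scale
convention, which the test suite asserts exactly.  See `docs/methods.md`
for assumptions, parameters and limitations.

## Worked example

`examples/03_closed_loop_so2.py` generates a tube phantom (blood at 96%
sO2 crossing the imaging plane at 5, 10 and 15 mm depth in the
tissue-mimicking medium), synthesizes the dual-wavelength photoacoustic
images from simulated fluence, and recovers sO2 with and without
compensation:

```
ground-truth tube sO2: 96%

noise-free:
  depth   compensated   uncompensated
     5 mm      96.0%         44.2%
    10 mm      96.0%         38.4%
    15 mm      96.0%         62.0%

10 dB SNR, 20-frame average:
  depth   compensated   uncompensated
     5 mm      95.4%         43.3%
    10 mm      94.2%         35.8%
    15 mm      97.2%         67.7%
```

Compensated values sit at the ground truth at every depth; the
uncompensated branch is biased by tens of points and drifts with depth
because the 750 and 850 nm fluence fields decay differently — exactly the
artifact the compensation removes.  Other examples cover probe/fluence
simulation and penetration depth (`01`), ultrasound segmentation against
a known boundary (`02`), and the five-stage pipeline with persisted
intermediates and provenance (`04`).

A thin CLI mirrors the stages:

```
oxylight synth --depths 5,10,15 --out frame/
oxylight segment --us frame/us.tif --threshold 0.35 --out mask.tif
oxylight pipeline --us frame/us.tif --pa750 frame/pa750.tif \
    --pa850 frame/pa850.tif --threshold 0.35 --out run/
```

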