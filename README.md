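# dgemric

Quantitative-MRI analysis of lumbar intervertebral discs with delayed
gadolinium-enhanced imaging (dGEMRIC): inversion-recovery T1 mapping,
fat-reference intensity correction, elliptical 60-sector disc
segmentation, ΔT1 and glycosaminoglycan (GAG) estimation, and the
study-level factorial statistics — together with a synthetic phantom
generator that provides full ground truth for every stage.

The package is aimed at researchers analysing disc dGEMRIC series (for
example from bedrest or loading interventions) and at anyone who needs a
fully testable, simulation-backed reference implementation of the
measurement chain.

## The measurement model

In dGEMRIC the longitudinal relaxation time T1 is mapped before and
after administration of a gadolinium contrast agent. The agent
distributes into cartilage inversely to the fixed negative charge of the
glycosaminoglycans, so the contrast-induced T1 shortening

ΔT1 = T1(native) − T1(post-contrast)

is small where GAG content is high. T1 is estimated pixel-wise from a
seven-image magnitude inversion-recovery series (fixed TR = 1800 ms,
TI ∈ {50, 150, 350, 700, 1050, 1400, 2000} ms) by least-squares fitting
of

S(TI) = S0 · | 1 − 2 e^(−TI/T1) + e^(−TR/T1) |

over (S0, T1) with a Nelder–Mead simplex, seeded by a coarse grid over
T1 to step across the null-point minima of the magnitude signal. Fitted
T1 outside 400–1500 ms is excluded. Series recorded with the scanner's
per-image auto-scaling left on are corrected against subcutaneous fat,
whose T1 is constant across the study: per-image multipliers are
estimated that place the observed fat means back on the model curve.

For regional analysis an ellipse is fitted (direct least-squares conic
fit) to eight manually placed boundary points and partitioned into 60
sectors — 5 concentric rings of equal normalized radius × 12 wedges of
30°. Rings 1–2 cover the nucleus pulposus, rings 3–5 the annulus
fibrosus; anterior/posterior zones are 90° wedge windows of the annulus.
Regional means feed a factorial ANOVA (intervention × disc level ×
region) with Tukey HSD post-hoc tests, and ΔT1 maps to GAG content via
the published calibration GAG [µg/mg] = −1.38·ΔT1 + 238.

## Worked example

Simulate a small noisy disc phantom, run the full chain, and compare the
recovered ring-wise ΔT1 with the generating truth:

```python
from dgemric import (AcquisitionProtocol, PhantomSpec, simulate_series,
                     fit_t1_map, fit_ellipse, generate_landmarks,
                     assign_sectors, delta_t1, region_summary, gag_from_delta)
from dgemric.relaxometry import SeriesMeta

spec = PhantomSpec(grid_size=64, ellipse_center=(36., 32.), semi_axes=(18., 11.),
                   fat_region=(2, 8, 4, 60), noise_sigma=0.02, seed=7)
protocol = AcquisitionProtocol()
meta = SeriesMeta(subject="A", disc_level="L1/2", timepoint="pre-bedrest")
native_s, truth = simulate_series(spec, protocol, "native", meta)
post_s, _ = simulate_series(spec, protocol, "post-contrast", meta)
ellipse = fit_ellipse(generate_landmarks(spec), anterior_index=0)
labels = assign_sectors(ellipse, (64, 64))
native = fit_t1_map(native_s, roi_mask=labels.inside)
post = fit_t1_map(post_s, roi_mask=labels.inside)
summary = (region_summary(delta_t1(native, post), labels)
           .set_index(["region_type", "region"]))
```

Printed ring means for this seed:

```
ring 1: dT1 = 163.40 ms  (n= 27, true 159.06)
ring 2: dT1 = 139.28 ms  (n= 76, true 143.52)
ring 3: dT1 = 159.97 ms  (n=122, true 159.18)
ring 4: dT1 =  81.42 ms  (n=168, true  78.12)
ring 5: dT1 =  36.45 ms  (n=222, true  37.22)
disc:   dT1 =  91.52 ms -> GAG ~ 111.7 ug/mg
```

Each ring's recovered ΔT1 sits within sampling noise of the value used
to generate it (the nucleus rings carry larger ΔT1 than the outer
annulus, as in healthy discs); the disc-level ΔT1 converts to an
estimated GAG content via the linear calibration.

A complete synthetic bedrest study (subjects × disc levels × pre/post
intervention, two slices per disc) can be generated and analysed from
the shell:

```sh
dgemric simulate --out bundle --subjects 5 --seed 1
dgemric run-all --input bundle --out results
```

which writes the long study table, a wide per-region summary, the GAG
table, and ANOVA/Tukey tables, plus a run manifest for traceability.

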