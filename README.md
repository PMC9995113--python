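# glymphokit

Computational pipeline for multi-modal MRI studies of glymphatic function —
the perivascular CSF/interstitial-fluid exchange system of the brain — built
around the comparison of AQP4-knockout and wildtype mice. The package
implements, as a reusable and tested library, the five analysis stages such a
study needs, and exercises every one of them on synthetic phantoms with known
ground truth:

1. **CSF-space segmentation** from CISS-like cisternography volumes: an
   adaptive chain of variance-based bounding box, solitary-region removal,
   percentile seeding with the threshold-correcting factor
   `f_c = σ_d/(µ_d + σ_d)`, contrast-driven region growing slice-wise in
   three planes, and median filtering; plus compartment volumetry with the
   ratio `CSF_compartment / (brain − whole CSF) × 100%`.
2. **Diffusion fitting**: noise-floor normalization
   `DWI − (µ_noise − 6σ_noise)`, monoexponential `S = S0 e^{−b·ADC}`, and the
   two-step segmented IVIM fit of
   `S = S0(Fp e^{−bD*} + (1−Fp) e^{−bD})` over the 17-b scheme
   (40…3081 s/mm², threshold at the b closest to 250 → 238).
3. **DCE tracer kinetics**: Friedman mean ranks per group with Dunn
   baseline-vs-time contrasts, yielding arrival time, time-to-peak, peak
   intensity, accumulation duration and AUC per ROI.
4. **T1 mapping**: variable-TR saturation recovery
   `S(TR) = S0(1 − e^{−TR/T1})` with dual-angle B1 correction
   (`S45/S90 = sin(45κ)/sin(90κ)`), and percentile-based free-fluid
   estimation in microbead phantoms.
5. **Group statistics**: brain water content, the ±1.5 SD retention filter,
   exact Mann-Whitney U, correlations, and report assembly.

The synthetic-data module (`glymphokit.synthetic`) is first-class: every
phantom — CISS brain, multi-b DWI stack, DCE cohort, variable-TR stack, bead
pack — is generated from a seed with exact ground truth, so each stage's
recovery can be verified end to end.

## Worked example

```python
import numpy as np
from glymphokit.synthetic import PhantomSpec, gen_ciss_phantom
from glymphokit.ciss import segment_csf, compartment_report, dice

vol, truth = gen_ciss_phantom(PhantomSpec(seed=1, snr=3.5))
seg = segment_csf(vol, truth.brain_mask)
print(f"Dice vs ground truth: {dice(seg.final_mask, truth.csf_mask):.3f}")
volumes, ratios = compartment_report(seg, truth.compartment_labels, (0.1,) * 3)
print(f"whole-CSF ratio: {ratios['whole_csf']:.2f}%")
```

prints

```
Dice vs ground truth: 0.948
whole-CSF ratio: 4.46%
```

— the segmentation recovers 95% (Dice) of the true CSF space at the
acquisition-typical SNR of 3.5, and the segmented CSF amounts to 4.46% of
the brain-minus-CSF volume (the phantom is built with ≈4.7% CSF). On a
noiseless phantom the same call gives Dice 0.976. For scale: applying the
same ratio arithmetic to a wildtype group's mean volumes (17.7 mm³ CSF,
477 mm³ brain) gives 17.7/459.3 = 3.85%.

## Analysis scripts

The `analysis/` directory holds the numbered pipeline drivers, each a thin
narrative over the library that prints what it found and writes its tables
under `results/`:

```
analysis/01_simulate_phantoms.py   # every phantom modality + ground truth
analysis/02_segment_csf.py         # segmentation + volumetry tables
analysis/03_fit_diffusion.py       # ADC / IVIM recovery tables and maps
analysis/04_dce_metrics.py         # per-group kinetic metrics, group tests
analysis/05_t1_beads_phantom.py    # T1 + B1 + free-fluid phantom summary
analysis/06_group_statistics.py    # worked examples, cohort stats, report
```

Run them in order with `python analysis/01_simulate_phantoms.py` etc.; the
final script assembles `results/report/report.md` from all stage outputs.

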