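# maaspect

Quantitative ⁹⁹ᵐTc-MAA SPECT/CT volumetry and ⁹⁰Y-microsphere treatment
planning, as a tested Python pipeline.

## The problem

Radioembolization delivers ⁹⁰Y-loaded glass microspheres through the hepatic
artery, aiming a prescribed absorbed dose (typically 120 ± 20 Gy) at the
vascularized liver volume. Planning therefore hinges on two measurements made
from the pre-treatment ⁹⁹ᵐTc-MAA scintigraphy: the **volume of distribution**
of the tracer (the volume that will actually receive microspheres, which can
differ drastically from the angiographic impression in patients with variant
arterial anatomy), and the **partition of counts** between tumor and
non-tumoral liver.

Volumes are measured with isocontour thresholding: a volume of interest (VOI)
contains every voxel at or above a percentage of the reference maximum. The
threshold can be fitted two ways:

* **hot-spot only (SPECT alone)** — an observer contours the apparent edge of
  the emission hot spot; sensitive to display windowing, inaccurate for small
  or low-contrast objects;
* **anatomically guided (SPECT/CT)** — the threshold is adjusted until the
  isocontour matches the organ boundary on the fused anatomical image.

This package implements both strategies, a synthetic phantom laboratory to
validate them (multi-sphere cylinder phantom and liver+tumor configurations,
with Gaussian PSF blur and Poisson noise), the validation statistics
(stratified percent-error summaries, Bland–Altman limits, Lin's concordance),
and the MIRD-based partition dosimetry used for planning:

```
D [Gy]      = A_inj [GBq] · (1 − S) · 50 / M [kg],      M = V [L] · 1.03
A_tum [GBq] = A_inj · (1 − S) · CP_tum / (CP_tum + CP_HL)
D_tum [Gy]  = 50 · A_tum / W_tum        (and likewise for the healthy liver)
```

where `S` is the lung shunt fraction and `CP_tum`, `CP_HL` are the VOI count
integrals of tumor and healthy liver.

## Worked example

The planning arithmetic of a case with three hepatic arteries, where
quantitative MAA SPECT/CT revealed a 1829 mL vascularized volume against the
346 mL suggested by angiography + CT:

```bash
$ maaspect dose plan --target-gy 120 --volume-ml 346
A_inj = 0.855 GBq for 120 Gy to 346 mL (shunt 0.0%)

$ maaspect dose report --activity-gbq 5 --shunt 0 \
    --liver-ml 1829 --liver-counts 1000 --tumor-ml 610 --tumor-counts 691
D_treated = 133 Gy, D_tum = 275 Gy, D_HL = 62 Gy (tumor uptake 69.1%)
```

Planning on the angiographic volume would have called for 0.855 GBq; the
5 GBq actually indicated by the SPECT/CT volume delivers 132.7 Gy to the
whole vascularized liver, 275 Gy to a tumor holding 69.1% of hepatic counts,
and only ~62 Gy to the healthy injected liver.

The same numbers emerge end-to-end from images: a synthetic 1829 mL liver
with a 610 mL tumor, segmented with anatomically fitted isocontours
(`maaspect.pipeline.run_clinical_case`), recovers a tumor uptake fraction of
0.6911 and a whole-liver dose of 132.6 Gy.

## Analysis scripts

Numbered drivers under `analysis/` regenerate the package's result tables
into `results/`:

1. `01_fixture_statistics.py` — recomputes the stratified error summaries and
   interobserver agreement from the packaged phantom measurement tables
   (e.g. operator 1: 20.4% mean absolute error with SPECT alone vs 8.4% with
   SPECT/CT; concordance 0.9998, "excellent").
2. `02_phantom_study.py` — simulates the full phantom study (10 noise
   replicates): anatomically guided errors average ~4.4% against ~25–44% for
   hot-spot delineation.
3. `03_case_dosimetry.py` — the case-report planning numbers above, both from
   the closed-form model and end-to-end from synthetic images.

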