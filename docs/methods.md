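# Methods

## Scope and model

The package measures distribution volumes on single-photon emission images by
isocontour thresholding, validates the measurement on synthetic phantoms, and
feeds the resulting volumes and count integrals into the MIRD-based partition
dosimetry used to plan ⁹⁰Y microsphere therapy. Three ingredients are modeled:
the activity image (a voxelized count field), the anatomical truth (binary
reference masks standing in for the CT of SPECT/CT fusion), and the
acquisition chain (image-domain degradation).

## Phantom laboratory

Phantoms are lists of analytic shapes (spheres, cylinders, ellipsoids) with
uniform activity concentrations, rasterized by voxel-center membership: a
voxel belongs to an object iff its center lies inside the shape; nested
objects override their containers. Masks are purely geometric, so the big
cylinder's mask also covers the spheres it contains — exactly as a CT liver
contour contains the tumor.

The standard configurations mirror a physical validation set: a 6716 mL
cylinder (radius 108 mm) carrying four hot spheres of 55 / 20.5 / 16 / 8 mL
on a 50 mm ring at mid-height, with sphere/background concentration ratios per
activity level ranging from 2.8 to 114; standalone hot cylinders of 774 and
473 mL in a cold field; and a liver-like ellipsoid (proportions 1.4 : 1 : 0.7)
containing a tumor ellipsoid whose concentration is solved from the requested
tumor count fraction `f`: `c_tum / c_HL = f/(1−f) · V_HL / V_tum`. Large
tumors adopt the liver's proportions so the containment constraint stays
satisfiable.

**Acquisition surrogate.** Reconstruction is not simulated; instead the
pristine image is (1) convolved with an isotropic Gaussian PSF, default FWHM
15 mm — a typical reconstructed ⁹⁹ᵐTc SPECT resolution; (2) rescaled to an
expected whole-image count sum, default 1×10⁷, from sensitivity arithmetic
(~150 cps/MBq per head for a dual-head LEHR system, ~10² MBq in the field,
960 s total acquisition ≈ 1.4×10⁷ counts, rounded down); (3) optionally
replaced voxel-wise by Poisson draws from a seeded generator. The default
grid is 128³ at 4 mm isotropic voxels. What this surrogate does **not**
reproduce: attenuation and scatter gradients, OSEM noise correlations and
non-stationarity, dead time and decay. Consequences: our noise is white
(harsher per voxel than smoothed OSEM noise at matched counts), and absolute
quantification is in arbitrary concentration units — the printed MBq values
of the physical study appear only as configuration labels.

## Isocontour VOIs

A VOI at threshold fraction `t` is the 26-connected component, containing a
seed voxel, of all voxels with value ≥ `t` × reference maximum (ties
included). The reference maximum is read inside an explicit search region if
one is supplied, else inside a ball around the seed (used in multi-sphere
phantoms to avoid keying a sphere's threshold to a hotter neighbor), else
globally. Volume is member count × voxel volume; counts are the member sum.
26-connectivity was chosen because PSF-blurred hot objects are compact; it is
configurable.

**Anatomically guided fit.** The candidate grid is the integer percentages
1–99%. Each candidate VOI is scored by Dice overlap with the reference mask;
the best wins, ties break toward the smallest threshold (largest VOI). The
overlap metric is a design choice — the clinical procedure is a visual
superposition with no stated criterion. For speed candidates are evaluated on
a subgrid cropped 32 mm beyond the reference bounding box; components
flooding past the crop are truncated there, affecting only thresholds far
from the optimum. Degenerate cases: a reference with no activity, or all
candidates empty, raise a fitting failure rather than returning a guess.

**Hot-spot (SPECT-alone) observer surrogate.** Without anatomical truth the
threshold comes from an explicit model of visual contouring: the image is
shown to the "observer" lightly smoothed (Gaussian, FWHM 8 mm — screens
interpolate and viewers do not perceive single-voxel noise spikes), windowed
to saturate at the local reference maximum, and gamma-transformed
(`display_gamma`, the observer-variability dial: γ < 1 is a bright window
that pushes the perceived edge outward). Rays cast from the local peak over a
Fibonacci sphere of directions are scanned for the *outermost* descent run
whose steepest gradient reaches 30% of the strongest descent on that ray —
the outer boundary a human would contour even when the target encloses hotter
structures. The median display-image fraction at the detected edge points,
snapped to the integer grid, is the threshold; the VOI is flooded on the
display image at that level. The surrogate exists to reproduce the
qualitative SPECT vs SPECT/CT contrast (and it does: see below); it does not
emulate any particular human operator, and no printed per-object volume is
targeted.

## Validation statistics

Percent error is signed, `100·(measured − true)/true`. Summaries average the
**absolute** errors per (operator, method, stratum) with sample SD (n−1);
strata are all objects, true volume ≥ 16 mL, and ≥ 473 mL (inclusive).
Missing measurements are dropped and logged, never silently; an empty stratum
is emitted with n = 0. Absolute rather than signed averaging is what
reproduces the published operator summaries from the packaged per-object
tables.

Interobserver agreement reports Bland–Altman bias and 1.96-SD limits together
with Lin's concordance correlation coefficient (population moments;
symmetric; 1 iff identical pairs). The source study quotes a single
"Bland–Altman test" number with qualitative bands (≥ 0.8 excellent, < 0.4
very poor) that matches no standard Bland–Altman output; we interpret the
bands as concordance bands and assert only band membership for the
anatomically guided data. Note the concordance computed from the packaged
tables for SPECT-alone is high (~0.998) because the two operators agree on
the very large cylinders, which dominate the covariance; whatever statistic
produced the quoted "0.2" is not recoverable, so nothing is asserted there.

**Packaged tables.** The two operators' per-object measurements ship as CSVs
(decimal commas normalized, SHA-256 verified on load). The 20.5 mL sphere is
recorded with an alternative truth of 21.0 mL: every printed error for that
sphere re-derives (within 0.15 points) only under 21.0 mL, so both candidate
truths are kept and the reproduction test uses the alternative.

## Dosimetry

For ⁹⁰Y under local energy deposition, dose reduces to `D = 50 · A / M` with
`A` in GBq, `M` in kg; tissue mass is volume × 1.03 kg/L, applied to every
compartment. Hepatic delivery is reduced by the lung shunt fraction,
`S = lung counts / (lung + liver counts)` — the standard planar/SPECT
definition; the source names but never defines it. Injected activity splits
between tumor and healthy liver proportionally to their count integrals;
`CP_HL` and `V_HL` come from subtracting tumor from whole liver. Activity
conservation `A_tum + A_HL = A_inj(1−S)` is asserted, and the whole-volume
dose is always the mass-weighted mean of the compartment doses. Doses are
kept at full precision; the case report's printed 132 Gy corresponds to
132.71 Gy here (and the 0.8 GBq plan to 0.855 GBq) — formatting-layer
rounding only. The 610 mL default tumor volume of the clinical phantom is a
back-derived convenience (the case prints no tumor mass); it reproduces the
printed ~275 Gy tumor dose but is not asserted as ground truth.

## Study design choices

Two pseudo-operators are realized as two display gammas (1.0 and 0.4) in
hot-spot mode and independent noise streams throughout; seeds for every
(configuration, operator) cell derive deterministically from the base seed.
In hot-spot mode the observer "centers the display" on the target: focal hot
spots are contoured from their peak, organ-like compartments (the large
cylinders) from their centroid with the window referenced to the local
background maximum.

Problem sizes used by the shipped analyses: 10 noise replicates of the full
object set for the simulated study; 20 replicates of the sphere set for the
replicate-comparison test; a 128³ grid throughout.

## Known limitations

* At sphere/background ratio 114 the integer threshold grid cannot express a
  level below background (1/114 < 1%), so the anatomically fitted big-cylinder
  VOI at the hottest level underestimates by ~20–25%. (The physical study's
  own operator-1 measurement of that configuration is missing.) Spheres and
  the standalone cylinders are unaffected.
* The end-to-end clinical-phantom dosimetry check runs with an ideal
  acquisition (no PSF, no noise): it validates the pipeline wiring, not
  partial-volume robustness. Under the default 15 mm PSF, count spill-over
  biases the raw tumor count fraction low (≈ 0.64 vs 0.691); recovery-
  coefficient corrections are out of scope.
* Rasterization error at 4 mm voxels is itself several percent for the
  smallest (8 mL) sphere; measured-vs-analytic errors below that floor are
  not meaningful at the default grid.
* Passing tests on this synthetic laboratory demonstrate correctness of the
  measurement and dose arithmetic and the qualitative superiority of
  anatomical guidance — not clinical accuracy on reconstructed patient data.
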