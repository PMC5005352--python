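# Methods

This note documents the models, parameter choices and numerical conventions
behind `sedcell`, and what its synthetic studies do and do not establish
about real sediment samples.

## Morphotype classification

Cells are classified purely by aspect ratio AR = max(L, W)/min(L, W), making
the rule invariant to the order in which the two axes were measured. The
bands are: coccoid AR ≤ 1.3, filamentous AR ≥ 10, elongated in between.
Only the filament boundary is well established descriptively (filaments are
"AR > 10" objects); the coccoid/elongated boundary is a convention — cocci
are "AR ≈ 1" but no sharp cut exists in nature — so it is exposed as
`coccoid_max_ar` (default 1.3) everywhere the classification is used, and
sensitivity to it can be tested directly. Cells with 3 < AR < 10 are
treated as elongated: the observed populations concentrate at AR 1–3 with a
minor filament tail, and continuity is the least surprising treatment of
the gap.

## Shape models and volume formulas

* sphere (coccoid): V = (π/6)·d³ with d the measured width. Using the width
  rather than the mean axis makes coccoid volumes robust to slight
  elongation.
* capsule (elongated, filamentous): a cylinder of diameter W and *total*
  length L with hemispherical end caps, V = (π/4)·W²·(L − W/3). The capsule
  was chosen over a plain cylinder because rounded poles match electron
  micrographs of rods; it reduces exactly to the sphere at L = W.
* prolate spheroid: V = (π/6)·L·W², offered as an explicit alternative for
  SEM-measured rods; always ≤ the capsule volume for the same L, W.
* ellipsoid (AFM): V = (π/6)·L·W·H with the independently measured height.
  FM and SEM carry no height information; for them width = height is the
  implicit assumption of the L–W-only formulas.

All formulas are strictly increasing in every dimension and scale as k³
under uniform rescaling; these invariants are enforced by property tests.

## Correction cascade

Sample preparation biases measured volumes in known directions: chemical
fixation shrinks cells by ~22.5% of volume (factor 1/(1−0.225) = 1.29),
filtration onto membranes shrinks elongated cells (factor 1.13 from the
ratio of unfiltered to filtered mean volumes of cultured rods, 0.76/0.68
µm³; cocci showed no significant effect, factor 1), the fluorescence halo
around DNA-stained cells inflates FM volumes by a factor 2.1 (correction
1/2.1), and ethanol dehydration followed by critical point drying shrinks
SEM-imaged cells by ~58% (factor 1/(1−0.58) = 2.38).

Two conventions matter:

* **Corrections act on volumes, not linear dimensions.** The composite
  correction for a cell is the *product* of the factors for the treatments
  its modality underwent (FM: fixation × filtration × halo; SEM: fixation ×
  filtration × CPD; AFM: fixation × filtration), so it is order-independent.
* **The canonical factors are the tabled values, not re-derivations.** The
  tabled halo factor is 0.475 while the derivation 1/2.1 prints as 0.48, and
  the tabled filtration factor 1.13 differs from 0.76/0.68 = 1.1176 in the
  third decimal. The package applies the tabled values and keeps the
  derivation functions (`factor_from_shrinkage`, `factor_from_inflation`)
  separate, so the rounding gaps remain visible and testable rather than
  silently absorbed. Factors are overridable via a TOML table; the defaults
  ship in `sedcell/data/correction_factors.toml`.

AFM is corrected for fixation and filtration only (it images hydrated or
gently dried cells without staining or CPD).

## THAA carbon stoichiometry

THAA → THAA-C uses the free-amino-acid carbon counts of the 18 HPLC
analytes (Gly 2 … Tyr/Phe 9), weighted by the sample's mole-fraction
composition; acid hydrolysis restores the water lost in the peptide bond,
so free-residue stoichiometry is the right basis. Printed mole-% rows sum
to 99.8–100.2 after rounding and are renormalized to exact fractions before
weighting. The composition-weighted mean carbon number is bounded by [2, 9]
for any composition. Analytes below detection carry zero weight but remain
registered.

THAA-C → total carbon multiplies by the carbon molar mass (12.011 g mol⁻¹;
fmol × g mol⁻¹ = fg) and divides by the assumed amino-acid-carbon fraction
of total cell carbon, f_AA = 0.55 by default. The 0.55 value originates
from the macromolecular composition of cultured *E. coli* and is close to
the ~0.61 found for pelagic bacteria across a wide size range; 0.40 and
0.75 presets bracket the plausible range for environmental cells. Since the
conversion is a single division, estimates scale exactly as 1/f_AA.

Recomputing THAA-C from THAA × composition agrees with the measured THAA-C
column within ~6% for every packaged sample; the gap is consistent with the
inputs being reported to two significant figures, so the packaged measured
THAA-C column is the default source and the recomputation path is used for
consistency checks and synthetic data. All values are carried unrounded;
rounding to integer femtograms is presentation only.

The carbon density divides cell carbon by the morphotype-weighted mean cell
volume Σ fᵢ·V̄ᵢ of the sample (FM-based volumes, which are available for
every sample), and satisfies C_d × weighted mean volume = C_cell exactly.
Sediment-integrated carbon is C_cell × abundance × 10⁻⁹ (fg → µg per cm³).

## Profile statistics

* Percentiles use linear interpolation between order statistics (a fixed
  convention is needed for testability; nothing downstream is sensitive to
  the choice at realistic sample sizes).
* Depth trends use one-way fixed-effects ANOVA, by default on log₁₀
  volumes because within-sample volumes are lognormal-like with roughly an
  order of magnitude of spread. Both df_between and df_within are reported
  explicitly to avoid the ambiguity of a single-df convention. Grouping is
  by sample (each sampled depth is one group).
* Uncertainty intervals are percentile bootstrap (default 1000 replicates)
  with a mandatory explicit seed in the CLI, so every interval is
  reproducible from the run manifest.
* FM/SEM concordance is summarized by the mean log₁₀ volume ratio of paired
  cells and the least-squares slope through the origin; pairs are declared
  concordant when the mean log-ratio is within ±0.05 (≈ ±12% in volume).

## Synthetic studies

The generator emulates the statistical structure the analysis assumes,
with defaults fixed to the study conditions of the depth profiles:

| parameter | default | meaning |
|---|---|---|
| depths | 0.4 … 38.95, 60 mbsf | sample grid |
| n_cells_per_depth | 300 | cells measured per sample |
| surface/deep median volume | 0.05 / 0.005 µm³ | coccoid+elongated anchors, log-linear decline |
| volume_gsd | 2.0 | ≈ one order of magnitude within-sample spread |
| fractions | 0.45 / 0.50 / 0.05 | coccoid / elongated / filamentous |
| filament anchors, gsd | 0.3 / 0.08 µm³, 1.5 | filament volume profile, ≈ half-decade spread |
| AR ranges | 1–1.3, 1.3–3, 10–20 | per-morphotype aspect ratios |
| abundance | 10¹⁰ → 10⁸ cells cm⁻³ over 0–60 mbsf | log-linear |
| measurement_noise_gsd | 1.0 (off) | optional lognormal volume noise |

Volumes are drawn lognormally around the depth-interpolated median;
dimensions are then *back-solved* from (volume, aspect ratio) under the
morphotype's shape model, which guarantees exact consistency with the
analysis-side volume computation. Aspect ratio and volume are drawn
independently (their true joint distribution is unknown). Observation is
the exact inverse of the correction cascade: observed volume = true volume
÷ composite factor, dimensions scaled by the cube root — so the full
observe → classify → volume → correct round trip recovers true volumes to
machine precision, and corrected FM and SEM views of the same cells agree
exactly. With measurement noise enabled the round trip is unbiased but no
longer exact. AFM observation is not modeled: the generator's shape models
carry no independent height, and AFM was a calibration rather than a survey
modality; the analysis side nevertheless supports AFM input fully.

THAA profiles anchor to the packaged measured table (log-interpolated over
depth, clamped beyond 38.95 mbsf) with lognormal noise; compositions
perturb the packaged mole-% rows and renormalize to exactly 100, or
reproduce them verbatim at zero noise. All tables derive from one root seed
through independent per-table streams, so a fixed config is bit-for-bit
reproducible and regenerating one table never shifts another.

**What passing synthetic tests shows — and does not.** They establish that
the pipeline is self-consistent (it recovers what the generator put in,
including the 0.05 → 0.005 µm³ anchors within bootstrap CIs and a depth
trend detected at p < 0.01), and that the carbon chain reproduces the
packaged measured values. They cannot validate the correction factors
against reality, the lognormal family, or the independence assumptions —
those would require new measurements. Field-measured statistics from the
original study (its ANOVA F values, extraction efficiencies of ~5–50%, and
the exact carbon-density-vs-depth curve) depend on raw per-cell data that
is not public and are therefore not reproduced here; the property and
simulation suites cover the corresponding code paths instead. On a
noise-free synthetic study the carbon density rises from roughly 200 fg C
µm⁻³ at the surface to the 10³ scale at depth; past the deepest measured
THAA sample (38.95 mbsf) the THAA anchor is a flat extrapolation while
volumes keep declining, so densities below that depth are an artifact of
extrapolation and are excluded from shape assertions.

## Numerical conventions and degenerate inputs

* Lengths/widths are canonicalized (larger axis stored as length) rather
  than rejected; file readers log a warning with the affected row count.
* Classification boundaries are inclusive: AR = 1.3 is coccoid, AR = 10 is
  filamentous.
* Zero or negative dimensions, volumes, shrinkage ≥ 1, inflation < 1,
  all-zero compositions, empty samples and fraction sets not summing to 1
  (tolerance 10⁻⁶) are rejected with typed errors; the CLI maps schema
  errors to exit code 2 and configuration errors to exit code 3.
* Extraction efficiencies above 100% are flagged with a warning, not
  rejected — they occur in practice through counting error.
* Problem sizes in the test and acceptance runs (300 cells per depth, 20
  seeds for recovery rates, 400–1000 bootstrap replicates) are the
  generator's defaults and keep every statistical check well-powered at
  the configured effect sizes.
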