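# Methods

## Scope and model

`ftir_sputum` implements a complete discrimination analysis for cohorts of
mid-infrared (FTIR) absorbance spectra of sputum cell pellets, labelled
cancer / normal. The analysis operates entirely in the 950–1800 cm⁻¹
fingerprint region, where protein (amide I/II), nucleic-acid and
carbohydrate (glycogen) vibrations concentrate, and proceeds in four stages:

1. **Preprocessing** — two-point linear baseline subtraction anchored at 900
   and 1850 cm⁻¹ (both outside the region of interest), cropping to the
   fingerprint region, vector normalisation (unit Euclidean norm, removing
   multiplicative plating/gain differences), and a 9-point Savitzky–Golay
   second derivative, which resolves broad overlapping bands into individual
   band centres (appearing as local minima). Technical replicates are then
   collapsed to one spectrum per subject by the pointwise median.
2. **Wavenumber screen** — at each of the 442 fingerprint wavenumbers the
   per-subject second-derivative values are compared cancer-vs-normal with
   the two-sided Mann–Whitney U test; the 442 p-values are adjusted by
   Holm's step-down sequential Bonferroni procedure at α = 0.05, and
   surviving wavenumbers are ranked by ascending raw p (rank 1 = most
   significant). A per-wavenumber Shapiro–Wilk screen is computed and
   reported, but it is advisory only: the inference branch is always
   nonparametric, since per-wavenumber absorbance distributions in this kind
   of data are routinely non-normal.
3. **Peak matching and panel selection** — band centres are detected as
   strict local minima (with a prominence floor) of the per-class median
   second-derivative spectra; centres from the two classes closer than
   1.5 grid steps are collapsed into one chemical band (mean centre). A peak
   is *matched* if at least one Holm-significant wavenumber lies within two
   grid steps (≈3.9 cm⁻¹) of its centre. The multivariate panel is the
   top-six matched peaks by rank, minus any whose centre falls within
   10 cm⁻¹ of a known mucin C–O stretch wavenumber (1040, 1076, 1120 cm⁻¹);
   in sputum, residual airway mucins can confound glycogen-region bands, so
   a glycogen band near 1049 cm⁻¹ is deliberately sacrificed.
4. **Multivariate analysis** — on the per-subject panel features:
   hierarchical clustering with correlation distance (d = 1 − Pearson r
   between subject feature vectors) and unweighted pair-group average
   linkage (UPGMA), cut into two clusters to quantify class capture; and
   PCA (centred, unit-variance features by default) retaining every
   component that explains at least 5% of the variance.

## Grid convention

The canonical fingerprint grid has exactly 442 evenly spaced points on
[950, 1800] cm⁻¹ (step 850/441 ≈ 1.9274 cm⁻¹). The canonical raw grid
extends the same arithmetic sequence 26 steps below and above
(≈899.9–1850.1 cm⁻¹, 494 points) so both baseline anchors fall within half
a step of a grid point. Spectrometers emit descending wavenumbers; grids are
normalised to ascending order on input and all outputs are ascending.
Detected band centres are grid points, so every reported centre carries a
discretisation error of at most one grid step (<2 cm⁻¹).

## Synthetic cohort generator

No clinical spectra ship with the package; the generator produces cohorts
with the statistical structure the analysis assumes, so every downstream
stage is testable end to end. A raw spectrum is

    A(ν) = gain × [ baseline(ν) + Σ_b s_b · a_b(class) · G(ν; c_b(class), w_b) ] + ε(ν)

with Gaussian bands G (amplitude at the centre, FWHM w_b), a linear baseline
(intercept 0.05, slope 5 × 10⁻⁵ absorbance per cm⁻¹; optional curvature,
default 0, so the two-point correction removes it exactly), lognormal
replicate gain (sd 0.05 on the log scale; independent per plated replicate),
lognormal per-subject band-amplitude jitter s_b (sd 0.08; shared across a
subject's replicates — biological, not technical, variation), and additive
Gaussian noise ε (sd 0.004 absorbance units). Defaults: 25 subjects per
class, 3 replicates each.

Six class-differential bands are planted (centre normal → cancer, FWHM,
amplitude increase in cancer):

| band | centre (cm⁻¹) | FWHM | increase | assignment |
|------|---------------|------|----------|------------|
| A | 964 → 966  | 10 | +35% | PO₄²⁻ / C–C stretch (protein, nucleic acid) |
| B | 1024 → 1024 | 14 | +40% | C–O stretch/bend (glycogen) |
| C | 1049 → 1051 | 12 | +30% | C–O stretch/bend (glycogen) |
| D | 1417 → 1411 | 22 | +30% | COO⁻ stretch, C–H bend (protein) |
| E | 1577 → 1577 | 24 | +40% | amide II (protein, nucleic acid) |
| F | 1656 → 1654 | 20 | +30% | amide I (protein) |

Band D is planted as a 1417 → 1411 cm⁻¹ shift; published tabulations of
this region are internally inconsistent about the direction, and both
orientations are representable through `BandSpec`.

Six class-neutral distractor bands (1100, 1160, 1240, 1310, 1460,
1740 cm⁻¹, amplitudes 0.16–0.33) fill the rest of the region. Their mass is
deliberately large — about two thirds of the spectral norm. This matters
because vector normalisation observes only *relative* composition: a
uniform amplitude increase across all bands would vanish entirely, and any
band whose increase coincides with the cohort norm ratio is annihilated
(closure). Anchoring the norm in class-neutral mass keeps the norm ratio
near +13%, so the planted 30–40% increases survive normalisation with a
per-band standardized effect ≥ 2 — the regime in which the two-cluster
separation is near-perfect — while the closure-induced relative *decreases*
at neutral bands stay mostly below the Holm threshold. A consequence worth
knowing: some neutral-band wavenumbers do reach significance (two-sided
test, genuine relative decreases), which is why peak matching and the
ranked panel, not raw significance counts, drive feature selection.

Optional mucin bands (1040, 1076, 1120 cm⁻¹; `mucin_bands_enabled`,
default off) are class-neutral, with the 1076/1120 amplitudes set very low
(0.030/0.025) to mimic pellets from which mucus was largely removed. The
default is off because the emulated measurement found no distinct 1076/1120
peaks; the flag exists to test that the mucin-exclusion rule and the screen
are robust to their presence.

Per-subject metadata (smoking status, prior cancer, cough) is drawn with
class-specific rates typical of a bronchoscopy-referral cancer cohort vs
healthy volunteer controls (controls are screened cancer-free); the cough
rate for cancer subjects (0.5) is a convention. Metadata decorates the
dendrogram outputs and is carried through every stage; no statistic is
computed on it.

### What the generator does not emulate

Water-vapour and CO₂ artefacts, detector noise physics, scattering
baselines (only polynomial drift), Mie distortion, mucolysis chemistry,
plate position effects, and any histology substructure within the cancer
class. Band shapes are Gaussian, not Voigt. Passing tests therefore
demonstrate pipeline correctness and statistical calibration under the
stated model, not clinical performance on real sputum spectra.

## Numerical choices

- **Savitzky–Golay**: window 9, polynomial order 3, `scipy.signal.savgol_filter`
  with `mode="interp"` (boundary windows refitted, matching the stated edge
  rule), output scaled by 1/step² (units absorbance·cm²). Orders 2 and 3
  share identical second-derivative coefficients on symmetric windows, so
  the unstated order is immaterial (tested). The derivative keeps its true
  sign; bands are minima. Requires relative grid nonuniformity < 10⁻⁶.
- **Mann–Whitney U**: U = #{x_i > y_j} + ½·ties via rank sums; exact
  enumeration of all C(n₁+n₂, n₁) group assignments when n₁+n₂ ≤ 12
  (valid under ties), else tie-corrected normal approximation with
  continuity correction. Two-sided p = P(|U′ − n₁n₂/2| ≥ |U − n₁n₂/2|).
- **Holm**: adjusted p = running max over the sorted sequence of
  min(1, (m−i+1)·p₍ᵢ₎); reject iff adjusted ≤ α. Ranks break p ties by
  ascending wavenumber for determinism.
- **UPGMA**: arithmetic average of cross-pair leaf distances; ties broken by
  the lexicographically smallest pair of smallest-member leaf indices, so
  trees are invariant to input order. Output uses the scipy linkage layout;
  Newick branch lengths are parent height − child height.
- **PCA**: eigendecomposition of the covariance of centred (and by default
  unit-variance) features; loading signs fixed so each column's
  largest-magnitude entry is positive; retained = #components with variance
  fraction ≥ 0.05. Whether the original workflow standardised features is
  unknowable; both switches are exposed, standardised is the default because
  second-derivative magnitudes differ by an order of magnitude across the
  panel.
- **Peak prominence**: a minimum's depth below the lower of its two
  flanking local maxima (endpoints count as flanks). The pipeline default
  floor (5 × 10⁻⁵ on the normalised second-derivative scale) suppresses
  inter-band ripple while keeping every planted band; it is a free
  parameter, since "prominent" is ultimately a judgement call.
- **Replicate aggregation**: pointwise median (mean available). Whether to
  analyse replicates individually or per subject is a genuine design fork;
  per-subject aggregation avoids pseudo-replication in the screen and is
  recorded in the provenance output.

## Problem sizes

The default cohort is 50 subjects × 3 replicates × 494 points; a full
pipeline run (simulate → preprocess → screen → panel → HCA + PCA) completes
in roughly a second. Monte-Carlo calibration suites (family-wise error under
the global null, mucin-window quietness, label-mixing) use 20 seeded
cohorts each, chosen so the whole test suite runs in about a minute.

## Known limitations

- Correlation distance over only five features is fragile by construction
  (five-point Pearson r); it is the default for fidelity to the emulated
  workflow, with Euclidean distance available (`distance: euclidean`).
- With fewer than ~13 subjects per class, the smallest attainable
  Mann–Whitney p-value cannot clear the Holm threshold over 442 tests, so
  small cohorts legitimately report zero significant wavenumbers; the
  pipeline reports this and skips the multivariate stages gracefully.
- The two-cluster capture statistic is defined for the k = 2 cut; deeper
  sub-cluster structure is exported in the Newick tree but not quantified.
- Instrument formats (JCAMP-DX, OPUS) are not parsed; the wide/long CSV
  dialects are the interchange formats.
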