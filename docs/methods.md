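# Methods

## Problem and scope

`dpdquant` quantifies myocardial uptake of the bone-seeking tracer
⁹⁹ᵐTc-DPD on reconstructed SPECT/CT, for the work-up of suspected cardiac
transthyretin (ATTR) amyloidosis. Inputs are a co-registered attenuation CT
(Hounsfield units), a SPECT volume in activity concentration (kBq/ml), an
acquisition-metadata record, and an operator-drawn master VOI of the left
ventricle. Image acquisition and reconstruction (OSEM, motion/attenuation/
scatter corrections), planar imaging, and human visual grading are out of
scope: grades enter only as labels, and the phantom emulates
already-reconstructed volumes.

## Quantification chain

**SUV (body weight).** For voxel concentration C (kBq/ml), injected
activity A₀ (MBq) at injection time, injection-to-scan interval Δt, body
weight W (kg):

    SUV = C · (W · 1000) / (A₀ · 1000 · 2^(−Δt/T½))   [g/ml]

with tissue density 1 g/ml and T½ = 6.0067 h for ⁹⁹ᵐTc (configurable).
Only body-weight SUV is implemented; height is carried in the metadata but
unused, since lean-body-mass and body-surface-area variants are not
reported in this workflow. The stored-unit calibration factor (kBq/ml per
stored voxel unit) is applied before normalization, so SUV is invariant to
it. Percent injected dose in a VOI is 100 · ΣC·v_voxel / (decayed A₀).

**Myocardial segmentation.** The master VOI is contoured on CT and
necessarily includes the ventricular lumen; projecting it onto SPECT would
therefore admit blood-pool counts. Within the projected master VOI the
pipeline detects SUVmax (ties broken toward the first voxel in scan
order), then segments all voxels with SUV ≥ f·SUVmax at f = 0.20, 0.40,
0.60, with no connectivity filtering. The mean SUV over each segment is
the *SUV mean above threshold*, SMaT_f. The comparison is inclusive (≥):
the source description does not state strictness, and the inclusive rule
keeps the f → 1 limit non-empty (exactly the argmax voxels). For any
volume SMaT₂₀ ≤ SMaT₄₀ ≤ SMaT₆₀ ≤ SUVmax and SMaT_f ≥ f·SUVmax; the suite
asserts these on every phantom run.

**Reference regions.** Bone and lung masks come from CT windows — bone
HU ≥ 150; lung −950 ≤ HU ≤ −350 restricted to the two largest 6-connected
components (the two lung fields). The windows are conventional clinical
choices (the vendor tool's values are unpublished) and are configurable.
Liver and soft tissue use operator-placed spheres of 25 ml and 15 ml;
sphere membership is a voxel-center test against r = (3V/4π)^(1/3), so the
realized volume is within one surface-voxel layer of nominal. Masks drawn
on the CT grid are projected to the SPECT grid by nearest-neighbour
membership at target voxel centers (identity on a shared grid). World
coordinates are mm, RAS, voxel-center origin; partial-volume weighting of
boundary voxels is deliberately not used, matching clinical VOI tools.

**Normalization.** Each cardiac metric m ∈ {SUVmax, SMaT₂₀, SMaT₄₀,
SMaT₆₀} is divided by each organ mean and by two composites:
m/(liver/lung) = m·lung/liver and m/(bone/soft) = m·soft/bone — 24 ratios.
The per-organ ratios cancel a global calibration error exactly; the
composite ratios retain one net SUV power and scale linearly with such an
error. The tests assert each behaviour exactly (10⁻¹²) rather than
claiming blanket invariance.

## Diagnostic cut-offs

Test-positive means value ≥ cut-off (same inclusive convention as the
segmentation). Performance is TPR/FPR/PPV/NPV in percent from the
confusion counts; a zero-denominator rate is reported missing rather than
coerced to 0. "Highest TPR with lowest FPR" is operationalized as maximum
Youden J = TPR − FPR over midpoints between consecutive distinct sorted
values; ties break toward higher TPR, then the lower cut-off. Midpoints
keep the derived threshold off the observed values. The shipped defaults
carry the published decision thresholds: SUVmax 6.0 and SMaT 2.5/3.3/4.2
(grades 2–3 vs 0–1), SUVmax 3.0 and SMaT 1.3/1.5/2.1 (grade 0 vs rest),
and liver/lung-ratio thresholds 41.9/15.8/20.2/24.4. The grade-0-vs-rest
cut-offs are applied but not asserted to be perfect: the published grade-1
minimum SUVmax (2.25) lies below the 3.0 cut-off, so the claimed perfect
separation cannot be reproduced from the published summaries, and the
ratio thresholds require per-patient ratios that were not published.

## Agreement and comparison statistics

*Mann–Whitney U* uses the exact distribution when the pooled sample size
is ≤ 12 with no ties, otherwise the normal approximation with tie and
continuity corrections; p-values are two-sided with α = 0.05.
*ICC* defaults to ICC(2,1) — two-way random effects, absolute agreement,
single measures — from the two-way ANOVA mean squares; the software used
in the original analysis does not document its variant, so the consistency
variant ICC(3,1) is selectable. Zero between-subject variance returns 0
with a warning (agreement is undefined when subjects do not differ).
*Bland–Altman* reports bias = mean(a−b) and bias ± 1.96·SD_sample(a−b).
`describe` returns both the n−1 and n standard deviations: the published
per-grade table is internally inconsistent about its SD convention (the
two-value grade-1 row matches the population SD for SUVmax but the sample
SD for SMaT), so both are exposed and neither is asserted against the
ambiguous cells; reporting defaults to the sample SD.

## Cohort fixtures

The per-patient table ships the 22 uptake-positive patients (sex, age,
grade, SUVmax; SMaT where published) and the per-grade summary table the
mean/SD/min/max of each metric for all 28 analysed patients. Decisions
embedded in the fixtures:

- The grade-1 SUVmax values are stored at the summary table's full
  precision (2.25, 3.32) rather than the rounded per-patient printing
  (2.2, 3.3); the summary table is treated as authoritative for
  quantitative cells, which also fixes the grade-1 SMaT₆₀ pair at
  (1.59, 2.34).
- Two rows' grade digits are typographically ambiguous between 2 and 3;
  the stored assignment (both grade 3) is the unique one that reproduces
  both the grade-2 mean (14.05, n = 15) and the grade-3 mean (15.26,
  n = 5). They carry a `grade_ambiguous` flag, and membership-sensitive
  tests pool grades 2–3, where membership is certain.
- The grade-0 summary's SMaT₂₀ minimum is printed with an impossible
  leading digit (a minimum above its own mean); it is stored as 0.48, the
  only reading consistent with min ≤ mean.
- Grade-0 patients have no per-patient rows; they are interval-censored to
  the summary range, and cut-off application represents each by the range
  bound conservative for the false-positive rate.

## Digital phantom

The phantom generates the study conditions the analysis assumes, not
anatomy: an ellipsoidal-shell LV wall around a blood-pool lumen, two lung
ellipsoids, a liver block, a spine cylinder with two rib rods, and a
soft-tissue body, voxelized by voxel-center tests on a default 96³ grid at
4 mm isotropic spacing (any grid ≥ 48³ works; organ size scales with the
grid's physical extent, and an LV wall thinner than one voxel is an
explicit error). CT values per tissue: soft tissue 40, liver 55, lung
−750, bone 700, LV wall 40, blood 45 HU — only the ordering and the
bone/lung separability matter downstream. Default myocardial SUV per
grade is the corresponding cohort mean (1.85 / 2.79 / 14.05 / 15.26
g/ml). Blood-pool SUV defaults (0.25 / 0.40 / 1.00 / 1.00) are kept below
20% of the myocardial target, which makes the lowest threshold exclude
the lumen — the stated purpose of the SMaT design — and makes the
noiseless phantom an exact fixed point: every recovered metric equals the
target to 10⁻⁶ relative. Extracardiac defaults (bone 5.0→3.0, liver
2.0→1.2 falling with grade; lung 0.35→0.50, soft 0.60→0.75 rising) encode
the direction of the reported extracardiac trends; their magnitudes are
package choices, as no numeric extracardiac values were published.

The SPECT volume is built by inverting the SUV equation at the default
metadata (743 MBq injected, 75 kg, 3 h delay), then degraded: isotropic
Gaussian blur (default σ = 6 mm, a typical reconstructed SPECT PSF) and
Poisson noise on expected counts at `counts_per_suv` = 500 (high-count
regime, so fixture tests are tight); all randomness flows from one
integer seed and runs are bit-reproducible. Blur uses zero-padding with
organs kept away from the border, so total activity is conserved to
better than 1%. Reader variability is emulated by rigidly displacing the
master VOI (rounded to whole voxels) and the sphere-center suggestions by
a Gaussian draw; a sphere pushed outside its organ is flagged.

What the phantom does **not** emulate: anthropomorphic anatomy,
reconstruction artifacts (streaks, attenuation/scatter residuals),
respiratory/cardiac motion, spatially varying resolution, correlated
noise, and mis-registration between CT and SPECT. Passing tests therefore
demonstrate the correctness and internal consistency of the measurement
chain under controlled uptake contrasts — not clinical accuracy on real
patients.

## Numerical choices and problem sizes

Threshold fractions strictly inside (0,1); SUVmax ≤ 0 is an error (no
uptake to segment). Empty masks: error for means (undefined), 0 with a
warning for %ID. The suite runs phantoms at 64³ (48³ for the 100-phantom
ordering sweep) — above the generator's minimum and small enough that the
full suite completes in well under a minute; defaults remain 96³. The
acceptance script uses 64³ phantoms, a 4-phantom graded cohort, and a
6-subject × 3-reader jitter study at 4 mm placement SD.

## Known limitations

- The master VOI is consumed as a mask; interactive contouring is out of
  scope, so phantom truth or user-supplied masks stand in for the
  operator.
- Whether the vendor tool restricts segmentation to the connected
  component containing SUVmax is unknown; the description is taken
  literally (no connectivity filter).
- Published per-reader data and per-patient ratios are unavailable, so
  the reader-agreement and ratio-threshold numbers are exercised on
  synthetic studies only.
- DICOM ingestion is not implemented; volumes are NIfTI-1.
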