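# Methods

## Dose model

`torsodose` implements DLP-method CT dosimetry combined with
injected-activity PET dosimetry. The torso CT is treated as six contiguous
axial regions (head, neck, chest, abdomen, pelvis, femur). Writing `N` for
the total slice count, `n_i` for region *i*'s slice count, and `k_i` for its
DLP-to-ED conversion factor:

- irradiated length `L = DLP / CTDIvol` (cm). This is deliberately the
  *irradiated* length, not the prescribed scan range: helical acquisitions
  over-range, so apportioning by scan range would underestimate dose.
- regional DLP `DLP_i = (n_i / N) · L · CTDIvol`. Algebraically this equals
  `(n_i / N) · DLP`; the implementation computes the latter so the
  floating-point evaluation order is fixed and `Σ DLP_i = DLP` holds to
  machine precision for any partition.
- `ED_CT = Σ DLP_i · k_i`, `ED_PET = A · w(age)`, `ED_total = ED_CT + ED_PET`.

Assumptions inherited from the DLP method: dose is uniform along the scanned
length (CTDIvol is a single torso-level value — tube-current modulation is
averaged out), conversion factors are phantom-derived adult values, and no
organ-absorbed doses are produced. Where a dose report carries several
irradiation events, events without a DLP (localizers) are discarded, DLPs
are summed and CTDIvol is taken as the DLP-weighted mean, giving the single
torso-level pair the model needs.

## Parameters

| parameter | default | units | notes |
|---|---|---|---|
| conversion factors `k_i` | ICRP 102: head 0.0021, neck 0.0059, chest 0.014, abdomen 0.015, pelvis 0.015, femur 0.015 | mSv/(mGy·cm) | data, not constants; overridable per config |
| FDG weighting factors `w` | ICRP 128: 0.095 (0–1 y), 0.056 (2–5), 0.037 (6–10), 0.024 (11–15), 0.019 (≥16) | mSv/MBq | closed integer age bands, last open-ended |
| skull-top offset | 4 | slices | top of skull = 4 slices above the most superior brain slice; the skull label itself is never used because raised arms can mislabel the radius as skull |
| C1/T1 boundary rule | `superior` | — | which vertebra slice opens the region; `inferior`/`centroid` available since institutions are expected to tune segmentation standards |
| head-margin warning | 10 | slices | QC warning when more slices than this lie above the computed skull top |
| injected-dose unit heuristic | > 1e4 → Bq | — | the standard stores Bq but vendors vary; conversions are logged, and parsed doses outside (1, 1e4) MBq raise a unit-suspicion warning |
| LoA multiplier | 1.96 | — | Bland–Altman 95% limits of agreement |

Age handling: fractional ages are floored to whole years before band lookup
(the factor tables are defined on integer bands; flooring matches how DICOM
age strings truncate).

## Landmarks and the partition

All label volumes are reoriented on load to a canonical order (slice index 0
= most superior) using the NIfTI affine's axis codes, so the landmark logic
is orientation-independent; flipping or permuting the stored axes yields the
identical partition. Boundaries are: top of skull (rule above), most
superior slice of C1 and of T1, most superior liver slice (hepatic dome),
most superior and most inferior slice of the merged left+right hip (iliac
crest, pelvis bottom). A missing unilateral hip degrades to the present side
with a warning; both missing is fatal.

Each landmark slice opens the region inferior to it (half-open intervals),
so the six ranges tile the scan exactly — the partition property the DLP
apportionment requires (slice fractions summing to 1). Slices above the
computed skull top stay in the head region rather than being cropped, so no
dose is silently dropped; a QC warning flags unusually large margins.
Landmarks out of superior–inferior order (e.g. a liver segmented above T1)
abort the study with an anatomy-inconsistency error naming the offending
pair rather than producing a silently wrong partition.

## Agreement statistics

The validation analysis compares paired per-patient EDs between methods:
mean ± sample SD (n−1), squared Pearson correlation, least-squares
regression of the automated values on the reference values, Bland–Altman
mean difference with 1.96·SD limits of agreement, and Student's t-tests.
Both paired and unpaired t-tests are exposed: the paired form is the natural
choice for same-patient columns and is extremely sensitive to small
systematic offsets; mean-level comparisons between calculation methods are
reported with the unpaired form, which is the test the shipped table's
printed p-values correspond to. Percent differences between methods are
computed on column means, not as means of per-patient percentages.

The maximum allowed difference drawn on Bland–Altman plots defaults to
`1.96 · sqrt(cv_a² + cv_b²) · grand_mean` (cv = SD/mean). This is one
plausible coefficient-of-variation formula among several in the method-
comparison literature; it is pluggable and should be treated as a QC guide,
not a validated bound.

Repeatability uses the intraclass correlation coefficient in its two-way,
absolute-agreement, single-measurement form (ICC(2,1)), computed from the
ANOVA decomposition `(MSR − MSE) / (MSR + (k−1)MSE + k(MSC − MSE)/n)` and
cross-checked in the tests against an independent implementation
(pingouin's ICC(A,1)). Deterministic reruns of the pipeline produce
identical reports, so repeat ICCs equal 1.0 by construction; the ICC is
undefined (and flagged) when subjects do not vary.

## Synthetic phantoms

The phantom generator emulates exactly what the landmark logic consumes:
structures as axis-aligned boxes placed in correct anatomical order along
the superior–inferior axis, with the brain's most superior voxel exactly 4
slices below the intended skull top so the skull-top rule recovers it, and
the right hip starting one slice below the left so the iliac-crest landmark
genuinely requires the hip union. Matching dose metadata is written as a
JSON sidecar (default) or a minimal DICOM radiation-dose SR, plus a PET
header carrying the injected activity in Bq and a DICOM age string.
Sabotage options reproduce the failure modes seen in transferred studies
(missing dose report, missing injected-activity element, missing
demographics, missing structure).

Ground-truth doses are computed inside the generator by straight-line
arithmetic with the factor values written out literally — no code shared
with the dosimetry module — so pipeline-vs-truth comparisons are genuine
dual-route checks. Default parameters describe a realistic adult torso
study: 263 slices (20/25/75/40/40/63 per region), CTDIvol 2.9 mGy, DLP
308.5 mGy·cm (irradiated length ≈ 106 cm), 228.3 MBq, age 60; randomized
phantoms draw 200–450 slices, CTDIvol 2–8 mGy, irradiated length 95–115 cm,
150–400 MBq and adult ages. Test problem sizes — 100 random phantoms for
the exactness check, a 34-study batch (12 + 4 sabotaged) for the failure
taxonomy, 10 studies × 3 runs for repeatability — are chosen to exercise
every code path while keeping the suite fast.

What the phantoms do *not* emulate: realistic organ shapes or intensities,
segmentation errors (mislabelled or fragmented structures beyond complete
absence), attenuation or emission physics, and vendor-specific DICOM
quirks. Passing phantom tests therefore demonstrates the correctness of the
landmark→partition→dose chain and the failure taxonomy, not robustness to
imperfect real-world segmentations — the ordering sanity checks and QC
warnings are the guard rails there, and visual review of segmentations
remains advisable.

## Numerical choices and degenerate inputs

- All doses are carried in double precision; rounding to 2 decimals happens
  only at presentation time (CSV reports); JSON output keeps full precision.
- Regional DLP is evaluated as `fraction · DLP` (see above) so conservation
  is exact rather than tolerance-dependent.
- Input-file role ties (two dose reports in one folder) break
  lexicographically with a logged warning, keeping discovery deterministic.
- A skull top computed above the scan start clamps to slice 0 with a
  warning; a zero-slice region contributes zero DLP and zero ED.
- Identical paired columns return t = 0, p = 1 instead of the 0/0 form.
- Empty batch roots produce an empty report plus a warning, not an error.

## Design choices where the convention was open

- The C1/T1 boundary uses the vertebra's most superior slice by default;
  the alternative readings are a configuration option rather than a silent
  assumption.
- The regression is oriented automated ~ reference (slope ≈ 1 means
  agreement on scale), and the agreement panel's differences are
  automated − reference.
- Age bands are closed integer ranges; non-integer ages floor.
- The dose-report sidecar dialect exists because many institutions only
  archive rendered dose pages; OCR is out of scope, so transcription to the
  documented JSON schema is the supported path.

## Known limitations

- No organ-absorbed doses: the DLP method yields a single effective-dose
  figure per region; phantom-based or Monte-Carlo dosimetry is out of scope.
- Conversion factors are adult values; the DLP method is known to
  underestimate doses in small (especially pediatric) patients.
- Regression coefficients estimated from a table printed at 2 decimals
  differ from fits on the underlying unrounded data by more than the
  printed precision (rounding shifts the slope by roughly its standard
  error at n = 30); the shipped comparison table can therefore reproduce
  means, correlations, Bland–Altman limits and percent differences at
  printed precision, but not third-decimal regression coefficients.
- The external segmentation hook (`segment_command`) simply shells out and
  is disabled by default; segmentation quality is the upstream tool's
  responsibility.
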