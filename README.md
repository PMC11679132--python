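# torsodose

Automated effective-dose (ED) calculation for torso ¹⁸F-FDG PET/CT.

PET/CT delivers radiation from two sources — the injected radiopharmaceutical
and the low-dose CT used for attenuation correction and anatomy — and
estimating the combined effective dose per examination is tedious enough that
it is rarely reported to patients. The CT part is the hard one: torso scans
cross body regions with very different DLP-to-ED conversion factors, so the
scan has to be split anatomically before the scanner-reported dose metrics
can be converted. `torsodose` automates that split using a multi-structure
segmentation of the CT (TotalSegmentator structure names), reads the dose
metadata from the study's DICOM objects, and produces a per-region dose
breakdown plus the study total — deterministically, with no operator in the
loop. It is aimed at medical physicists and nuclear-medicine departments that
want per-patient PET/CT dose accounting from data they already archive.

## The calculation

The scan is partitioned into six regions along the superior–inferior axis —
head, neck, chest, abdomen, pelvis, femur — using landmarks taken from the
segmentation: the top of the skull (4 slices above the first brain slice; the
skull label itself is unreliable with raised arms), the most superior slices
of C1 and T1, the hepatic dome, the iliac crest (first slice of the merged
left+right hip) and the bottom of the pelvic bones (last hip slice). With
CTDIvol and DLP from the CT dose report,

```
L        = DLP / CTDIvol                      irradiated length (cm)
DLP_i    = (n_i / N) · L · CTDIvol            region i's share of the DLP
ED_CT    = Σ_i DLP_i · k_i                    k_i: ICRP 102 factor, mSv/(mGy·cm)
ED_PET   = A · w(age)                         A: injected activity (MBq),
                                              w: ICRP 128 factor, mSv/MBq
ED_total = ED_CT + ED_PET
```

where `n_i` is the region's slice count and `N` the total slice count. The
irradiated length is used instead of the nominal scan range because helical
over-ranging makes the exposed length longer than the prescribed range.
Default factors are ICRP 102 (head 0.0021, neck 0.0059, chest 0.014,
abdomen/pelvis/femur 0.015 mSv/(mGy·cm)) and ICRP 128 for ¹⁸F-FDG
(0.095/0.056/0.037/0.024/0.019 mSv/MBq for ages 0–1/2–5/6–10/11–15/≥16);
both tables are configuration, not constants.

## Worked example

No patient data is needed to try the package — the phantom module renders a
complete synthetic study folder (label volume, dose report, PET header) with
an independently computed analytic ground truth:

```python
from pathlib import Path
from torsodose import PhantomSpec, generate_phantom, run_study

study = Path("example_study")
spec = PhantomSpec()  # 263 slices, CTDIvol 2.9 mGy, DLP 308.5 mGy*cm, 228.3 MBq, age 60
truth = generate_phantom(spec, study)
row = run_study(study)
print(f"irradiated length : {row.irradiated_length_cm:.1f} cm")
for region, ed in row.region_ed.items():
    print(f"  {region:<8s} ED : {ed:5.2f} mSv")
print(f"CT ED  : {row.ct_ed:.2f} mSv")
print(f"PET ED : {row.pet_ed:.2f} mSv")
print(f"total  : {row.total_ed:.2f} mSv  (oracle: {truth.total_ed:.2f})")
```

prints

```
irradiated length : 106.4 cm
  head     ED :  0.05 mSv
  neck     ED :  0.17 mSv
  chest    ED :  1.23 mSv
  abdomen  ED :  0.70 mSv
  pelvis   ED :  0.70 mSv
  femur    ED :  1.11 mSv
CT ED  : 3.97 mSv
PET ED : 4.34 mSv
total  : 8.31 mSv  (oracle: 8.31)
```

The 308.5 mGy·cm DLP at CTDIvol 2.9 mGy spreads over 106.4 cm; most of the
CT dose comes from the chest and femur regions (most slices), while the head
contributes almost nothing despite its length because its conversion factor
is 7× smaller. The PET component (228.3 MBq × 0.019 mSv/MBq = 4.34 mSv) is
larger than the whole CT component — typical for low-dose protocols.

### Command line

```bash
torsodose run  <study-folder>          # one study  -> CSV row
torsodose batch <root-of-studies>      # all subfolders -> report + summary
torsodose stats <comparison.csv>       # method-agreement statistics
```

A study folder contains a multi-label NIfTI segmentation with a JSON
name→id label map (or a directory of per-structure binary masks), a CT dose
report (DICOM RDSR, or a JSON sidecar `{"ctdi_vol": <mGy>, "dlp": <mGy·cm>}`
transcribed from a dose page), and any PET DICOM file. `batch` exits 0 when
every study succeeded and 2 otherwise; each failed study gets exactly one
machine-readable reason code (`missing_dose_report`,
`missing_radionuclide_dose`, `missing_age`, `missing_structure`,
`anatomy_inconsistency`, `unreadable_file`).

Factor tables, the C1/T1 boundary convention and warning thresholds can be
overridden with `--config cfg.yaml` / `--cf-table factors.yaml`; the formats
are documented in `torsodose/config.py`.

### Validation statistics

The package ships the 30-patient table comparing the automated calculator
with a physician's manual calculation, the CT-Expo program and two
whole-body conversion factors, and `torsodose stats` reproduces the
agreement analysis (means ± SD, r², regression, Bland–Altman limits of
agreement, percent differences):

```bash
torsodose stats src/torsodose/data/method_comparison_group1.csv --format markdown
```

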