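# y90dosim

Multicompartment voxel dosimetry for trans-arterial radioembolization of
hepatocellular carcinoma with ⁹⁰Y glass microspheres — built for physicists
and statisticians who want to study, end to end and without any patient
data, how the two common segmentation strategies (anatomic contours vs.
activity-isocontour thresholding on the pre-treatment
[⁹⁹ᵐTc]TcMAA SPECT) propagate into absorbed doses and into dose–outcome
statistics.

The package provides:

* **Digital liver phantoms** (`y90dosim.phantom`) — liver/perfused-volume
  ellipsoids with spherical hypervascular lesions, tumor-to-normal uptake
  ratio T/N, Gaussian PSF blur, Poisson count noise, a post-treatment
  activity map with controllable pre/post discordance, and rigid
  misregistration shifts.
* **Segmentation** (`y90dosim.segmentation`) — the `% threshold` isocontour
  operation (voxels ≥ t × in-box maximum, clipped to liver or perfused
  volume) and the compartment algebra: perfused normal liver = perfused −
  tumors ≥ 2 cm; total perfused tumor = Σ tumors ≥ 3 cm ∩ perfused.
* **Dosimetry** (`y90dosim.dosimetry`) — MIRD-schema local deposition:
  a patient relative calibration factor *f* = A / Σ counts(perfused)
  (GBq/count), then D(v) = counts(v) · f · E / (ρ · V_voxel) with
  E = 49.67 J/GBq for full ⁹⁰Y decay and ρ = 1.05 g/cm³.
* **Outcome statistics** (`y90dosim.outcomes`) — ORR with Wilson 95% CI,
  TCP/NTCP logistic regression reporting odds ratios per 100 Gy,
  Cox proportional hazards (hazard ratio per 100 Gy, Efron ties),
  Kaplan–Meier overall survival, and a two-step multivariable logistic
  selection (screen at p < 0.1, then backward elimination at 10%).
* **Agreement** (`y90dosim.agreement`) — Bland–Altman bias and 95% limits of
  agreement (pre − post differences, 1.96 × SD) and Pearson correlation.
* **Cohort simulation** (`y90dosim.cohort`) — patient tables with log-normal
  doses and outcomes drawn from logistic / exponential proportional-hazards
  models, defaulting to OR 1.22 and HR 0.826 per 100 Gy.

## Worked example

```python
from y90dosim import orr_with_ci
from y90dosim.pipeline import preset_matched, run_pipeline

print(orr_with_ci(129, 209))   # (61.7, (55.0, 68.0))
print(orr_with_ci(72, 209))    # (34.4, (28.3, 41.1))

report = run_pipeline(preset_matched(seed=1)).report
comps = report["dose_reports"]["pre_anatomic"]["compartments"]
print(comps["total_perfused_tumor"]["mean_dose_Gy"])   # 900.4
print(comps["perfused_normal"]["mean_dose_Gy"])        # 135.1
print(report["statistics"]["cox_os_anat"]["hr_per_100gy"])  # 0.8607
```

The first two lines are the Wilson score intervals for 129 and 72
responders out of 209 patients: response rates of 61.7% and 34.4% with 95%
CIs (55.0, 68.0) and (28.3, 41.1). The pipeline run builds a well-matched
phantom (a 4 cm hypervascular tumor, T/N = 8), segments it both ways,
and computes local-deposition doses for 2.5 GBq: the anatomic-method total
perfused tumor dose is 900.4 Gy against 135.1 Gy to perfused normal tissue
(a selective, high-uptake scenario). It then simulates a 209-patient cohort
and fits the statistics battery; the fitted hazard ratio of 0.861 per
100 Gy of tumor dose recovers the generating value 0.826 to within sampling
error of a single cohort.

The same stages are available as CLI subcommands:

```bash
y90dosim run-all --seed 1 --out runs/demo
y90dosim simulate-cohort --config cohort.json --out cohort.csv
y90dosim dose-response --cohort cohort.csv --dose tad_anat_gy --outcome response_mrecist
```

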