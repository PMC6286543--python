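# batperm

Quantitative profiling of vascular permeability in the **brain adjacent to
tumor (BAT)** — the rim of histologically normal brain surrounding a
metastatic lesion. Brain-tumor vasculature (the blood–tumor barrier) is far
leakier than the intact blood–brain barrier; the question this toolkit
addresses is how far that leak extends *beyond* the tumor margin, and how
much drug therefore reaches tissue that is still normal brain.

`batperm` implements the complete image-analysis chain for experimental
brain-metastasis sections, plus a ground-truthed synthetic-data generator so
every stage is testable without animal data:

- **Segmentation** — tumor pixels by the binary-mask rule (eGFP intensity
  strictly > 3× background, background = robust median), cancer-cell
  clusters within 100 µm merged into one lesion, margins extracted from the
  closed lesion hull.
- **Ring analysis** — a signed Euclidean distance transform drives
  consecutive 8-µm circumferential ROIs to ±296 µm of the margin; per-ring
  sum intensity per unit area, normalised to a contralateral normal-brain
  reference, gives the fold-change permeability profile; the mean fold over
  0–100 µm summarises the BAT window.
- **Kinetics** — the unidirectional blood-to-tissue transfer constant by
  single-time uptake,

  `K_in = C_br(T) / ∫₀ᵀ C_bl(t) dt`  [mL s⁻¹ g⁻¹],

  with trapezoidal blood AUC, per-region mean ± SEM, one-way ANOVA and
  Holm–Šidák pairwise comparisons (α = 0.05). Values are reported on the
  conventional 10⁻⁵ mL/s/g scale.
- **Autoradiography** — quantitative autoradiography (QAR): a linear
  calibration `intensity = a + b·(ng/g)` fitted to co-exposed
  tissue-calibrated standards, per-pixel inversion to a concentration map
  (out-of-range pixels flagged, never silently clipped), square-ROI means
  (100 µm; 50 µm in BAT) and radial concentration profiles in 50-µm bins.
- **Synthetic data** — lesions as harmonically perturbed discs, tracer
  plateau + decaying BAT halo, Poisson + Gaussian camera noise, lognormal
  lesion-to-lesion heterogeneity, mono-exponential bolus blood curves;
  every output carries its ground truth.

## Worked example

```python
from batperm import (tracer_section_config, generate_section, analyze_section,
                     kin_recovery_cohort, autorad_recovery_cohort)

# one synthetic Texas Red (625 Da) section, full pipeline
cfg = tracer_section_config("tr625", seed=7)
section, truth = generate_section(cfg)
res = analyze_section(section)
print(res.background)       # 99.9  (AU; generator truth 100)
print(res.bat_fold[1])      # 1.73  (mean fold over 0-100 um)

# regional K_in cohort (n = 6 subjects, 10% CV measurement noise)
out = kin_recovery_cohort("tr625", seed=0)
for region, r in out["results"].items():
    print(region, r.mean_1e5, r.sem_1e5)
# normal 1.21 +- 0.02   x 1e-5 mL/s/g
# bat    4.30 +- 0.18
# tumor 10.29 +- 0.36

# 15-lesion QAR cohort: calibrate, invert, bin radially
qa = autorad_recovery_cohort(n_lesions=15, seed=1)
print(qa["recovered_ng_per_g"])
# {'tumor': 557.4, 'bat_0_50': 91.3, 'bat_50_100': 37.3, 'distant': 1.0}
```

The fold profile decays from ~2.4 at the margin to ~1.0 by 300 µm; the
recovered BAT fold (1.73) and the K_in / concentration summaries track the
generator's configured regional truths (normal 1.2, BAT 4.32, tumor 11.3
×10⁻⁵ mL/s/g; tumor 529, BAT 86.7 / 35.4, distant 1 ng/g) within the
cohort's sampling error.

A `batperm` console script exposes the same stages
(`simulate`, `segment`, `rings`, `kin`, `autorad`, `report`); every run
writes a provenance JSON and is byte-reproducible under a fixed seed.

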