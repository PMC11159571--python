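# meniscoq

Quantitative T2\*-mapping analysis of the knee menisci, built for researchers
working with multi-echo gradient-recalled-echo (GRE) acquisitions at 7 T.
Meniscal T2\* — the effective transverse relaxation time — rises when the
collagen network of the meniscus loses density and organization, so regional
T2\* maps can reveal intrasubstance degeneration that looks normal on surface
inspection. `meniscoq` provides the complete analysis chain as a testable
Python library:

- **phantom** — synthetic multi-echo knee volumes with two C-shaped menisci,
  exactly known per-region T2\*, Rician magnitude noise, and all landmarks,
  so every downstream stage can be validated against ground truth;
- **relaxometry** — voxel-wise fitting of the mono-exponential decay
  S(TE) = S₀·exp(−TE/T2\*) by bounded least squares, with the fit RMSE
  normalized to the fitted S₀ as a per-voxel quality map;
- **regions** — partition of a meniscus mask into anterior horn (0°–45°),
  anterior body (45°–90°), posterior body (90°–135°) and posterior horn
  (135°–180°) by angle relative to the line connecting the horns, plus
  pixel-count volumes and per-region median tables;
- **extrusion** — medial meniscal extrusion on a coronal reference plane,
  with the conventional ≥ 2 mm pathological threshold;
- **stats** — patient-vs-control contrasts via a linear mixed model with
  age/sex/BMI covariates, Bonferroni-adjusted pairwise comparisons, Pearson
  correlations with Fisher-z confidence intervals, and scan–rescan
  reproducibility via ICC(A,1) and Bland–Altman limits of agreement.

Image I/O is NIfTI-1 (nibabel); tables are tidy CSV (pandas); landmark files
are JSON in world millimetres.

## Worked example

Simulate a noisy patient-like knee (7 echoes, TE 3.1–21.4 ms, 0.44 × 0.44 ×
1.0 mm voxels, S₀/σ = 50, 3 mm prescribed medial extrusion), fit T2\* maps,
partition the medial meniscus and measure extrusion:

```python
import meniscoq as mq

spec = mq.patient_spec(extrusion_mm=3.0, noise_sigma=2.0, seed=7)
truth = mq.generate_phantom(spec)
vol = mq.simulate_multiecho(truth)
maps = mq.fit_monoexponential(vol, truth.combined_mask())

lm = truth.landmarks
part = mq.partition_regions(truth.mask("medial"), lm.anterior_horn_mm["medial"],
                            lm.posterior_horn_mm["medial"], truth.affine)
table = mq.region_table(maps, part, "example", "medial")
print(table[["region", "median_t2star_ms", "median_nrmse", "voxels"]].round(3))

ext = mq.measure_extrusion(truth.mask("medial"), lm.tibial_plateau_margin_mm,
                           lm.coronal_reference_index, truth.affine, lm.medial_direction)
print(f"extrusion: {ext.distance_mm:.2f} mm, extruded={ext.extruded}")
```

Output:

```
  region  median_t2star_ms  median_nrmse  voxels
0     AH             9.605         0.016    1638
1     AB             9.563         0.016    1746
2     PB            12.001         0.016    1854
3     PH            12.705         0.016    1764
extrusion: 2.98 mm, extruded=True
```

The regional medians recover the simulated ground truth (AH 9.57, AB 9.53,
PB 11.95, PH 12.68 ms) to within the Rician noise bias; the median
normalized RMSE of ~1.6% reflects the injected noise level; the measured
extrusion matches the prescribed 3 mm to within one in-plane voxel
(0.44 mm) and is correctly flagged by the ≥ 2 mm rule.

The same steps are available from the shell via the `meniscoq` command
(`simulate`, `fit`, `regions`, `extrude`, `stats`, `agree`, `run`); see
`meniscoq --help`.

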