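# sriloc

Outcome analysis for stereotactic radiotherapy (SRT/SRS/FSRT) of brain
metastases, built for studying how treatment-planning factors — in
particular whether the planning MRI was gradient-nonlinearity
distortion-corrected — affect **local control** in the presence of death as
a competing risk.

It is aimed at radiation-oncology outcome researchers who have (or want to
simulate) per-lesion cohorts: longitudinal tumor-volume measurements,
treatment plans, and survival follow-up.

## What it computes

* **Volumetric RANO-BM progression classification.** A lesion progresses at
  the first scan with a ≥ 72.8% volume increase over the running nadir
  (the cube of the 20% diameter criterion, (1+0.20)³−1) *and* an absolute
  gain ≥ 0.2 cm³ (a 5 mm sphere growing 3 mm). Enlargements that later
  regress spontaneously — back to the reference, or a ≥ 65% volumetric
  partial response from the peak — are pseudo-progression, not events.
* **Biologically effective dose.** BED = n·d·(1 + d/(α/β) − d²/(α/γ)) with
  α/β = 12 Gy, α/γ = 648 Gy² (LQC), plus an LQ sensitivity variant
  (α/β = 20 Gy SRT / 10 Gy WBRT); upfront WBRT is summed into the total.
* **Competing-risk inference, from scratch.** Aalen-Johansen cumulative
  incidence F̂₁(t); Gray's K-sample test (score form, with an exact-style
  permutation option for small samples); Fine-Gray proportional
  subdistribution hazards regression λ₁(t|x) = λ₁₀(t)·e^{x'β} with IPCW
  risk-set weights G(t−)/G(T_i−), Breslow ties and a robust sandwich
  variance; Kaplan-Meier + log-rank for patient-level overall survival.
* **Lesion geometry.** Minimum lesion-to-brain-surface distance from voxel
  masks (anisotropic distance transform); lesions within 1.5 cm of the
  brain surface are peripheral, the rest central.
* **Synthetic cohorts with known truth.** Latent outcomes drawn directly
  from the subdistribution model F₁(t|x) = 1 − [1 − p₁(1−e^{−λ₁t})]^{e^{x'β}},
  rendered into noisy volume trajectories on a 90-day visit grid — so the
  configured hazard ratios are exactly the estimands of the regression.

See `docs/methods.md` for assumptions, defaults and limitations.

## Worked example

Simulate a 300-lesion cohort under the default (study-emulating)
configuration, then run the full classify → analyze pipeline:

```bash
sriloc simulate --n 300 --seed 5 --out demo
sriloc analyze --lesions demo/lesions.csv --volumes demo/volumes.csv \
               --seed 5 --out demo/report
cat demo/report/summary.txt
```

prints

```
sriloc v0.1.0  (seed 5, config 7d3b77b88d43e2ae)
lesions: 300  patients: 300
local progressions: 87  deaths without progression: 191

Gray's test (local progression, 2D vs ND):
  all          n=   300  chi2=1.729  p=0.1885
  melanoma     n=   125  chi2=0.521  p=0.4703
  wbrt_yes     n=   125  chi2=0.031  p=0.8613
  wbrt_no      n=   175  chi2=2.630  p=0.1049

Fine-Gray regression (multivariate):
  correction         HR=0.769  p=0.2261
  wbrt               HR=0.328  p=0.1115
  total_bed          HR=1.011  p=0.5418
  mri_year           HR=1.002  p=0.9371
  mri_interval       HR=1.020  p=0.1191
  baseline_volume    HR=0.971  p=0.6794
  radioresistant     HR=0.975  p=0.9105

Overall survival log-rank: chi2=0.018 p=0.8933
```

Reading this: 87 of 300 lesions met the volumetric progression criteria;
the multivariate subdistribution hazard ratio for distortion correction is
0.77 — the generating value is 0.55, but a single n = 300 cohort with
classifier-discretized event times estimates it noisily (the acceptance
experiments below quantify recovery properly at n = 5,000 on exact event
times). The bundle also contains `cif_by_group.csv` (cumulative incidence
of progression and death per group at 6-monthly report times),
`fine_gray_table.csv` (univariate + multivariate), `os_km.csv`, an events
table with pseudo-progression annotations, and a manifest; the same seed
and config reproduce every file byte-identically.

Single computations are exposed too:

```bash
$ sriloc bed --fractions 10 --dose 4      # FSRT 10 x 4 Gy, LQC alpha/beta 12
52.3457
```

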