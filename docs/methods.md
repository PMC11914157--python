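# Methods

This note documents the models, estimators, conventions and defaults behind
`sriloc`, and what the synthetic experiments do and do not demonstrate.

## Outcome definition: volumetric response assessment

Each treated metastasis contributes a time-to-event outcome derived from its
volume trajectory. Walking the scans in chronological order, the *reference*
is the running nadir — the smallest volume seen so far, baseline included. A
scan is a progression *candidate* when both

* volume ≥ reference × 1.728 (a 72.8% increase, the volume equivalent of a
  20% diameter increase of a sphere), and
* volume − reference ≥ 0.2 cm³ (the volume a 5 mm sphere gains growing 3 mm
  in diameter; guards tiny lesions against noise-driven calls).

Both comparisons are inclusive. A candidate is demoted to
*pseudo-progression* if any later scan, with no salvage therapy on or before
that scan's day, returns to the reference at the call or drops ≥ 65% from
the candidate peak (the volumetric partial-response level, i.e. a 30%
diameter decrease cubed). The 65% is measured from the candidate peak — the
enlargement under adjudication — not from the reference; this is switchable
through `RanoThresholds`. Without such regression the candidate is
confirmed at the candidate scan's day; a candidate on the final scan is
confirmed (regression cannot be demonstrated) and flagged
`confirmed_on_last_scan` for sensitivity analyses. Lesions resected for
enlargement are classified by surgical histology: viable tumor confirms the
(first) candidate, pure necrosis refutes all candidates.

Times run from the start of radiotherapy; upfront whole-brain radiotherapy
(start on or before the stereotactic course) defines that start. Lesions
without a confirmed progression end in death (competing event) or are
censored at last follow-up.

## Dosimetry

The working fractionation correction is the linear-quadratic-cubic BED,

    BED = n·d·(1 + d/(α/β) − d²/(α/γ)),  α/β = 12 Gy, α/γ = 648 Gy²,

appropriate for radiosurgical fraction doses; the cubic bracket is guarded
(doses making it non-positive are outside the model's validity and raise).
A plain LQ sensitivity model uses α/β = 20 Gy for the stereotactic course
and 10 Gy for WBRT. With upfront WBRT, per-course BEDs are summed; salvage
WBRT is excluded.

## Competing-risk inference

Death precludes observing local progression, so naive 1 − KM overstates
incidence; all local-control inference is done on the cumulative incidence
scale.

* **Aalen-Johansen.** CIF_k(t) = Σ_{t_j ≤ t} S(t_j−)·d_kj/n_j with S the
  all-cause Kaplan-Meier. The conservation identity CIF₁ + CIF₂ + S = 1
  holds exactly at every event time and is asserted to 1e-12 in tests.
* **Fine-Gray regression.** The subdistribution hazard of cause 1 is
  modelled as λ₁(t|x) = λ₁₀(t)·exp(x'β). Subjects with a prior competing
  event remain in the risk set with inverse-probability-of-censoring weight
  G(t−)/G(T_i−), G being the covariate-free Kaplan-Meier of the censoring
  distribution. The weighted partial likelihood is maximized by
  Newton-Raphson from β = 0 with step-halving (gradient sup-norm < 1e-8,
  ≤ 100 iterations); ties are handled à la Breslow (day-resolution times
  from 90-day visit grids are heavily tied); the reported covariance is the
  robust sandwich built from per-subject score residuals, ignoring the
  variability of Ĝ — the standard approximation, adequate at the censoring
  levels simulated here. All risk-set sums factorize into prefix/suffix
  cumulative sums because the weight separates as G(t−)·(1/G(T_i−)), so a
  fit is O(n·p²) per iteration. Coefficients agree with `cmprsk::crr` to
  ~1e-7 on tie-free data (asserted at 1e-4 in the suite). Divergence of a
  coefficient path (|β|·sd > 50) is reported as separation.
* **Gray's K-sample test.** Implemented as the score test of the Fine-Gray
  model with K−1 group indicators at β = 0 (ρ = 0, unweighted), with the
  robust score variance; the reference is χ²(K−1). Null calibration was
  verified by simulation (rejection rate 0.0435 at α = 0.05 over 2,000
  null cohorts). On small samples the χ² approximation to the discrete
  permutation distribution is poor, so `gray_test(..., n_permutations=...)`
  reports a permutation p-value instead; at the null the score is a linear
  map of the design matrix, making each relabeling O(n²) cheap. The
  permutation p matches exact enumeration of all relabelings on an
  8-subject fixture.
* **Overall survival** uses Kaplan-Meier and the standard log-rank test at
  patient level, from the first stereotactic course; a patient's group is
  that of the first-treated lesion. Lesion day offsets are assumed
  comparable within a patient.

## Synthetic cohorts

The generator's purpose is parameter recovery with known truth, so latent
outcomes are drawn *directly from the subdistribution model*: the cause-1
(improper) distribution is

    F₁(t|x) = 1 − [1 − p₁(1 − e^(−λ₁ t))]^exp(x'β),

inverted analytically on the progressing branch; with probability
1 − F₁(∞|x) the lesion instead dies at an independent Exponential
(death_rate) time; administrative censoring truncates at
`admin_censor_day`. The configured exp(β) are therefore *exactly* the
subdistribution hazard ratios the Fine-Gray fit estimates — cause-specific
simulation would not give that. Continuous covariates enter centred at the
cohort mean (this shifts only the baseline, never the hazard ratios, and
keeps the cause-1 plateau in range).

Defaults emulate the study conditions: n = 419 lesions, 52.5%
distortion-corrected; histology frequencies, 41.3% upfront WBRT, 51.3% SRS
(18–20 Gy single fractions; FSRT schemes with median 4 Gy/fraction; WBRT
10×3 / 20×2 / 15×2.5) as in the emulated cohort's Table 1; log-HRs on the
seven-covariate set (correction 0.55, WBRT 0.61, BED 0.99/Gy, MRI year
0.99, MRI-treatment interval 1.02/day, baseline volume 1.02/cm³,
radioresistant 1.23) from its multivariate model. Baseline p₁ = 0.25,
λ₁ = 0.003/day give a ≈16.7% 12-month baseline incidence, between the two
reported arms; death_rate = 0.0016/day gives ≈55% one-year survival;
administrative censoring at 4 years. `calibrate_improper_exponential`
solves (p₁, λ₁) in closed form from a pair of 12/24-month incidences, used
to pin each arm to its reported values in the recovery experiments.

Volume dynamics are *not constrained by any reported data* and are free
config: exponential response (0.002/day) until the latent onset, regrowth
at 0.0077/day (≈ doubling per 90-day visit) afterwards, scans every 90 ± 7
days, 10% lognormal measurement noise, and transient pseudo-progression
bumps (probability 0.05, peak +90%, one-visit tent with a slight
undershoot) on non-progressing lesions only. A lesion whose follow-up ends
before the first scheduled visit is imaged once at the end of follow-up,
mirroring the inclusion requirement of at least one aftercare MRI.

**What passing tests show, and what they do not.** Noise-free
threshold-clearing cohorts verify that the classifier recovers every
observable latent progression exactly at the first visit where the
rendered trajectory clears both thresholds; calibrated cohorts verify that
the estimators recover configured hazard ratios and incidences. None of
this validates the volume-dynamics model against real tumor kinetics, nor
the classifier against human RANO reads; with noise and visit
discretization switched on, classifier-derived event times are interval-
censored to the visit grid and recovery is attenuated accordingly — which
is why the regression/CIF recovery experiments run on latent event times.

## Geometry

Lesion location is classified from voxel masks: the anisotropic Euclidean
distance transform of the brain mask gives each in-brain voxel's
center-to-center distance to the nearest exterior voxel; the minimum over
lesion voxels minus one voxel pitch (clamped at 0) is the surface-to-
surface distance, so a lesion flush against the brain boundary scores
exactly 0 mm. The convention is exact within one voxel diagonal of the
all-pairs voxel-center oracle — immaterial against the 15 mm
peripheral/central cutoff. This voxel rule replaces mesh-based distance
computations deliberately: it is reproducible bit-exactly and needs no
mesh dependency.

## Numerical and design choices

* Dates are integer day offsets from each lesion's baseline planning MRI;
  calendar parsing stays outside the package.
* Distortion-correction state is read from the multi-valued DICOM
  ImageType tokens with configurable vocabularies (defaults "DIS2D",
  "DIS3D", "ND"); correction tokens win over "ND".
* Analysis is lesion-level without within-patient correlation adjustment
  (most simulated patients carry one lesion; real multi-lesion clustering
  would make the sandwich variance optimistic).
* No multiple-testing adjustment is applied anywhere.
* Problem sizes in the shipped experiments: 2,000 null cohorts of n = 250
  for test calibration, 500 cohorts of n = 419 for interval coverage,
  n = 5,000 (×20 replicates in the acceptance script) for hazard-ratio
  recovery, n = 10,000 per arm for incidence recovery.

## Known limitations

* Ĝ is estimated without covariates; group-dependent censoring would bias
  the weights.
* The sandwich variance ignores the variability of Ĝ.
* Interval censoring of progression times (calls happen at scan days) is
  not modelled in the regression; event times are taken at the calling
  scan, as is conventional.
* The pseudo-progression mechanism is a stylized multiplicative bump; real
  treatment-effect kinetics are richer.
* `classify_lesion` treats a candidate followed immediately by death (no
  later scan) as confirmed progression; the alternative (censor at the
  candidate) is not currently switchable.
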