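# Methods

## DVH representation and query semantics

A differential DVH is stored as bin edges (Gy) plus per-bin volume fractions
summing to 1; a cumulative DVH stores one value per *edge* (fraction of the
structure receiving at least that dose), starting at 1 and ending at 0. The
two forms convert exactly in both directions.

Differential bins are interpreted as **point masses at bin centers**. All
dosimetric queries on differential DVHs are therefore exact finite sums:

- `Dx%` is the largest bin-center dose `d` with at least `x`% of the volume
  at doses ≥ `d` (the "minimum dose received by the hottest x%", with the
  plateau tie broken toward the higher dose);
- `V_RI` is 100 × the summed fraction of bins centered at or above RI;
- `D_min`/`D_max` are the lowest/highest occupied bin centers, with no
  near-extreme smoothing, and `D_mean` the weighted mean of centers.

When a DVH arrives already in cumulative form — the common export format of
planning systems — `Dx%` and `V_RI` interpolate linearly between edge
samples instead. The point-mass convention makes degenerate cases exact (a
single-bin "uniform" DVH has `HI = 0` and `D98% = D2%` identically, not up to
a bin width), at the cost that differential-form queries are
piecewise-constant between centers; at the default 0.1 Gy bin width the
difference from interpolation is below the quantization already incurred in
binning. To keep a bin centered exactly at 0 Gy representable, validation
constrains bin *centers* (the dose values) to be non-negative, allowing the
first edge to dip half a bin width below zero.

`rebin(factor)` refines the grid while keeping each bin's mass at its
original center; with an odd factor the center stays interior to a refined
bin and every statistic is exactly invariant, which is how refinement
invariance is tested.

## Radiobiological endpoints

Every endpoint first maps per-bin total dose to its 2-Gy-fraction equivalent
`EQD_i = D_i (α/β + D_i/n_f)/(α/β + 2)`, assuming each voxel is treated in
all `n_f` fractions at proportional per-fraction dose — the only reading
consistent with a single `(D, n_f)` prescription per arm. At exactly 2 Gy per
fraction the transform is the identity.

- **EUD** is the generalized mean with exponent `a`. It is computed in log
  space (`exp(logsumexp(ln v_i + a ln EQD_i)/a)`), stable down to `a = −100`
  and beyond, where it converges to the minimum EQD at rate `v_min^{1/a}`.
  For `a < 0` a zero-dose bin drives EUD to 0 in the limit; the function
  returns 0.0 with a warning, and a `dose_floor` argument (e.g. `1e-6` Gy)
  clamps per-bin EQD for users who want a cold-spot-robust value.
- **TCP** multiplies per-unit-volume Poisson-LQ responses; the product is
  evaluated as a volume-weighted sum of log-responses. `eγ` is Euler's number
  times the slope γ (not `exp(γ)`), which is what makes uniform dose at
  `EQD = D50` give exactly `exp(−ln 2) = 0.5`.
- **NTCP** uses the LKB probit `Φ(t)`, `t = (D_eff − D50)/(m D50)`, with the
  standard normal CDF (`scipy.special.ndtr`) — the only orientation for
  which NTCP is 0.5 at `D_eff = D50` and increases with dose. `D_eff` is the
  Kutcher–Burman reduction `(Σ v_i EQD_i^{1/n})^n`, the form for which
  uniform dose yields `D_eff = EQD` for every `n`.

Tissue constants ship as a YAML registry (breast target `α/β = 4` Gy,
`a = −7.2`, `γ = 1.3`, `D50 = 30.89` Gy; heart `D50 = 48` Gy, `m = 0.1`,
`n = 0.35`; lung `D50 = 37.6` Gy, `m = 0.35`, `n = 0.87`; `α/β = 4` Gy for
all three) and any entry can be overridden per run. EUD/TCP are evaluated
for the PTV only and NTCP for heart and lungs only; other structures are
volume-reported but receive no dose-response endpoint.

## Plan indices

`HI = (D2% − D98%)/prescription`. `CI = (V_RI,PTV)²/(100 Σ V_RI)` where the
sum runs over **all** contoured structures including the PTV and each `V` is
a percentage of that structure's own volume — the normalization under which
the ideal plan (full coverage, no other structure at RI) scores exactly 1 and
no plan can exceed 1. Structures not reaching RI contribute 0 rather than
being dropped. RI defaults to 95% of prescription (47.5 Gy CF, 40.43 Gy HF)
and is configurable. Note that with this all-structures normalization a plan
whose chest wall legitimately sits inside the treated volume scores CI near
0.5 even when conformal in the clinical sense; CI values are therefore
comparable within a convention, not across publications, which is also why
alternative CI definitions are out of scope.

## Cohort comparison

Per quantity: arithmetic mean, sample SD (n−1), and a two-sided
independent-sample t-test with pooled variance (Student); Welch's form is
available via `equal_var=False`. The t sign is `(CF − HF)/SE`. Zero
pooled-variance cases are resolved before calling scipy: equal means give
`t = 0, p = 1`, unequal means `t = ±∞, p = 0`. Significance is declared at
`p < 0.05` per quantity with no multiple-testing correction (noted in the
report footer); row order is the fixed quantity list (volumes, CI, HI, EUD,
TCP, NTCPs, V95/V100/V107). A patient missing a structure is excluded from
that quantity only, with a logged warning.

## Synthetic cohorts

`default_cf_spec()` / `default_hf_spec()` emulate the study conditions: arms
of 19 (CF, 50 Gy/25 fx) and 9 (HF, 42.56 Gy/16 fx) patients; per-structure
Gaussian volumes matching the clinical cohorts (e.g. CF heart 490 ± 79 cm³,
PTV 673 ± 206 cm³); and per-structure truncated-Gaussian voxel doses
(clipped at 0 Gy) around a structure-specific fraction of prescription,
histogrammed at 0.1 Gy. Defaults per structure:

| structure            | mean dose fraction (CF / HF) | voxel SD (Gy) | patient SD (Gy) |
|----------------------|------------------------------|---------------|-----------------|
| PTV                  | 1.036 / 1.028                | 1.0           | 0.25            |
| chest wall           | 1.035 / 1.027                | 1.2           | 0.6             |
| ipsilateral lung     | 0.25                         | 6.0 (scaled)  | 1.0             |
| contralateral lung   | 0.03                         | 1.2 (scaled)  | 0.3             |
| heart                | 0.05                         | 2.0 (scaled)  | 0.5             |

"Scaled" OAR voxel SDs shrink by the prescription ratio in the HF arm. The
PTV/chest-wall fractions were set so the arm-level HI (~0.08 / ~0.10), EUD
(~52 / ~49 Gy, i.e. ~105% / ~114% of prescription) and TCP (~95.5% / ~93%)
land in clinically reported ranges for these two schedules; the OAR fractions
encode the anatomical ordering ipsilateral lung ≫ heart ≈ contralateral lung
and are tuning constants, not clinical measurements. `patient SD` jitters a
structure's mean dose between patients — without it all patients in an arm
would be statistically identical and arm-level t-tests would degenerate. A
`bimodal_cold_spot` dose shape (default: 5% of voxels 15% colder) exercises
the cold-spot sensitivity of negative-exponent EUD.

What the generator does *not* emulate: spatial dose structure (no 3-D dose
grids or contours), inter-structure dose correlations within a patient,
planning-system-specific DVH binning, and setup/delivery uncertainty. Tests
passing on synthetic cohorts therefore validate the computational pipeline
and its statistical calibration, not the clinical magnitudes of any specific
planning technique: lung NTCP defaults, for instance, land near 1.5–1.9%
where published breast-IMRT cohorts report up to ~5%, a matter of the chosen
lung dose law, not of the NTCP model.

Randomness uses `numpy` `SeedSequence(seed, spawn_key=(patient_index,))`
substreams: patients are independent, order-independent, and individually
regenerable.

## Numerical choices and problem sizes

- Generalized means and TCP products are computed in log space; probit via
  `scipy.special.ndtr`.
- Differential volume fractions must sum to 1 within 1e-9; form conversion
  round-trips within 1e-12.
- Default histogram bin width 0.1 Gy, 4000 voxels per structure; binned
  endpoints agree with raw voxel-list evaluation to better than 1e-3
  relative at 0.01 Gy width (tested at 50 000 voxels).
- Statistical calibration uses PTV-only cohorts of 28 patients at 500
  voxels/structure: 500 null replicates for the type-I error check (empirical
  rate required in [0.02, 0.09] at α = 0.05) and 200 replicates for the power
  check (voxel SD 1 vs 3 Gy at n = 19 vs 9, >80% detection), sizes chosen so
  the whole suite runs in seconds while the binomial tolerance stays tight.
- Ties on flat cumulative segments resolve to the higher dose; `D_min`/
  `D_max` ignore zero-mass bins; degenerate inputs (empty DVH, zero total
  volume at RI, groups smaller than 2) raise typed exceptions rather than
  returning NaN.

## Known limitations

- No DVH smoothing, dose recomputation, or contour rasterization; DICOM
  ingestion is a thin adapter over dicompyler-core and requires the optional
  `dicom` extra.
- The LQ model carries no repopulation/time factor, so schedule duration
  beyond fraction count does not enter.
- CI follows the all-structures percentage normalization described above;
  Paddick/RTOG variants are intentionally not implemented.
- t-tests assume approximate normality of per-patient quantities; no
  non-parametric fallback is provided.
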