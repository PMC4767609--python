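# Methods

## Stepwise tests

All tests operate on marginal p-values. A step-up-down (SUD) test of order
`λ` with nondecreasing critical values `α_{1:m} ≤ … ≤ α_{m:m}` finds its
effective index `i*` as follows: if the λ-th ordered p-value passes its
critical value, `i*` is the largest `j ≥ λ` such that *every* ordered
p-value between `λ` and `j` passes (contiguous scan upward); otherwise `i*`
is the largest `j < λ` whose ordered p-value passes, if any. Hypothesis `i`
is rejected iff `p_i ≤ α_{i*:m}`. Comparisons are non-strict throughout, and
the rejection rule goes through the final cutoff comparison, so tied
p-values always receive identical decisions regardless of sort order. When
no index qualifies, the no-threshold case is an explicit sentinel and
nothing is rejected.

* **LSU (Benjamini–Hochberg):** `α_{i:m} = i·α/m`, `λ = m` (pure step-up).
* **AORC:** `α_{i:m} = i·α/(m − i(1−α))`, strictly increasing with
  `α_{m:m} = 1` exactly (the last value is pinned to 1.0 rather than left to
  floating-point cancellation). Because of that last value, a pure step-up
  application degenerates — any p-value ≤ 1 triggers total rejection — so
  callers always use `λ < m`; the two-stage procedure uses `λ = u_ℓ` and
  `flat` comparators default to `λ = 1`.

## Partial-conjunction screening

The screening null for family `ℓ` states that it contains fewer than `u_ℓ`
signals. Its Simes-type p-value (valid under PRDS) is
`min_i ((m−u+1)/i)·p_{u−1+i:m}`, capped at 1 (the cap can only bind at the
boundary; it never changes a decision at any level below 1). The signal
quota is `u_ℓ = ⌊m_ℓ/κ⌋ + 1`, clamped at `m_ℓ` so degenerate tiny families
cannot demand more signals than they have hypotheses; `κ > m_ℓ` reduces the
screening null to the intersection hypothesis.

The two-stage procedure screens at `α/κ` and requires `κ > k`: the union
bound then gives stage-1 FWER ≤ `k·α/κ < α`, which is precisely why the
threshold is read as `α/κ` (an `α·κ` threshold would exceed 1, and an `α/k`
threshold would make the `κ > k` condition irrelevant to validity). The
practical cost of this strict screen is reduced sensitivity to weak or
sparse family signals; see Limitations.

The selection-adjusted comparator screens the per-family Simes p-values with
LSU at level `α` and retests selected families with LSU. Its printed
within-family level `R·α/m_ℓ` is so strict (≈ 5·10⁻⁵ for `m_ℓ = 1000`) that
it cannot produce within-family FDRs of the order observed in the fMRI
study, so the default is the selection-adjusted level `R·α/k`; the stricter
variant remains available through `stage2_rule="R_alpha_over_m_ell"`.

## Error metrics

FDP is `V/(R ∨ 1)`; per-family FDP restricts both counts to one family, so a
fully null family's FDP is exactly the indicator of any rejection there.
The global FDR estimate is the mean over replications of the pooled FDP;
"mean FDR" is the mean over families of the per-family FDR estimates,
computed after per-family averaging. Power is `S/(m_A ∨ 1)`. Stage-1
family-wise error occurs when a selected family truly contains fewer than
`u_ℓ` signals; selecting a family with at least `u_ℓ` signals is correct.
Monte-Carlo standard errors are sample standard deviations over replications
divided by √B; all bound checks in the test suite allow 3 standard errors.

## Normal-means study

One observation `T ~ N_m(μ, I_m)` with `H_j: μ_j = 0` vs `K_j: μ_j > 0` and
`p_j = 1 − Φ(T_j)`; all signals share a common `μ* > 0`. `m = 2500`
hypotheses in `k = 2` block families with size proportions `π` and
per-family true-null proportions `q_N` from five study configurations,
`α = 0.05`, `κ = 1000`. Non-integer signal counts (e.g. `0.01·1250 = 12.5`)
are rounded half-up on the alternative count, deterministically. Signals
occupy the first indices of each family — irrelevant by exchangeability,
fixed for reproducibility. Each replication draws a fresh vector from a
per-replication substream spawned off the master seed, so increasing B
extends rather than reshuffles the sequence, and all procedures score the
same datasets (paired comparisons).

The full effect grid is 0.5 to 5 in steps of 0.5; the test suite evaluates
the five configurations on the subgrid {1, 2, 2.5, 3, 5} at B = 1000, which
resolves the power orderings to within ~0.01 while keeping the suite fast.

## Synthetic fMRI study

**Generator.** 105 volumes of 20×20×20 voxels at TR 2 s; task blocks of 15
volumes starting at volumes 16, 46 and 76; expected BOLD = block indicator
upsampled to 0.1 s, convolved with a double-gamma HRF (gamma kernels with
shape 6 and 16, scale 1, undershoot ratio 1/6, peak ≈ 5–6 s, normalized to
peak 1) and decimated at the TR. The activation region is a sphere of
radius 3 voxels (123 lattice points): centered at voxel (5,5,5) in scenario
A (entirely inside one octant family) and at (10,10,10) in scenario B
(touching all eight octants; per-octant signal counts 29/18/18/11/18/11/11/7).
Voxel coordinates are 1-based and the octant boundary places coordinate 10
in the low half.

Noise is Rician: the magnitude of a complex Gaussian around the clean
signal, `sqrt((clean + n₁)² + n₂²)`, with two independent fields that are
AR(1) in time (stationary initialization) and Gaussian-smoothed in space,
renormalized so the marginal standard deviation equals `noise_sd` in the
volume interior. With baseline ≫ noise this is approximately additive
Gaussian, which the analysis model assumes.

**Generator defaults.** The reference tool chain's noise and effect settings
are not printed, so these are fixed once as plausible single-subject values:
baseline 100 (arbitrary intensity units), `noise_sd` 4 (4% of baseline),
AR(1) coefficient 0.3, spatial FWHM 2 voxels. The effect amplitude (peak
signal change, same units as baseline) is set by a calibration routine to
the smallest candidate at which the two-stage procedure detects ≥ 99.5% of
active voxels — evaluated on the centered-sphere scenario, whose small
per-octant signal counts make the stage-1 screen the binding constraint
(pooled BH detects everything at much weaker signal). This matches the
intended regime in which every procedure detects essentially all true
activations, and yields the default amplitude 8.0.

**Analysis.** Per voxel, the series is regressed on [expected BOLD,
intercept, linear trend, quadratic trend]. Temporal autocorrelation is
corrected with one Cochrane–Orcutt step: lag-1 autocovariance and variance
of the OLS residuals are computed per voxel, both fields are spatially
smoothed (σ = 2 voxels) and their ratio is mapped through the exact
residual-projection bias curve `tr(P·Ls·P·A(ρ)) / tr(P·A(ρ))` (P the
residual-forming matrix, Ls the symmetrized lag operator, A(ρ) the AR(1)
correlation matrix) to a debiased ρ̂. Both sides are then first-differenced
with ρ̂ and refit; the one-sided p-value for positive activation uses the
t-distribution with `(n−1)−4` degrees of freedom. Two numerical details
matter: smoothing the two autocovariance fields *separately* (a smoothed
ratio retains an O(1/n) negative bias, and the low-frequency block regressor
makes the far t-tail sensitive to ρ̂ bias as small as 0.01), and treating a
numerically exact fit (relative residual sum below 1e−12) as p = 0 for a
positive coefficient and p = 1 otherwise, which makes the noiseless limit
exact. The whole GLM is vectorized: the prewhitened normal equations are
quadratic polynomials in ρ̂, so only batched 4×4 solves are needed per
volume.

The study runs the two-stage procedure (`κ = 1000`, so `u = 2` per
1000-voxel octant), pooled LSU and the selection-adjusted comparator at
`α = 0.05` on the octant partition, B = 200 replications (a deliberate
reduction of the reference 1000 to keep the full suite fast; standard
errors are reported alongside every estimate).

## What the generators do and do not emulate

The fMRI generator reproduces block-design BOLD structure, hemodynamic lag,
magnitude (Rician) noise, temporal autocorrelation and spatial smoothness.
It does not model motion, drift beyond a quadratic, field inhomogeneity,
physiological noise, partial-volume fading at the activation boundary, or
multi-subject variability; ground truth is a binary sphere. Passing tests
therefore demonstrate the statistical behavior of the procedures under a
clean, known-truth imaging model — not performance on real scanner data.
The normal-means study uses an identity covariance; dependence between test
statistics is exercised only through the fMRI study's spatial smoothing.

## Known limitations

* The screening threshold `α/κ` is strict. At weak effect sizes
  (`μ* ≈ 2` in the normal-means study) sparse or weak families often fail
  stage 1, and the two-stage procedure can then trail the selection-adjusted
  comparator in global power; its advantage at `μ* ∈ [2.5, 3]` under highly
  unbalanced configurations is large and reproducible.
* Within-family AORC testing exhausts the level: pooled FDP estimates in the
  centered-sphere scenario sit slightly above `α` (the finite-m,
  few-signals-per-family regime adds a small upward Jensen effect from
  pooling ratios, and plug-in prewhitening leaves a few percent of far-tail
  miscalibration), so bound checks there are tight rather than comfortable.
* The spatially smoothed ρ̂ assumes noise stationarity at the smoothing
  scale; strongly nonstationary autocorrelation would need a locally
  adaptive bandwidth.
* The pooled Kolmogorov–Smirnov uniformity check of null GLM p-values is run
  on spatially unsmoothed noise: smoothing correlates voxels and inflates
  the variance of the pooled empirical CDF without affecting marginal
  uniformity, which is what the check targets.
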