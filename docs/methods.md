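# Methods

## Model

For country i (i = 1..n) and year t (t = 1..T), let y_it be a mortality
rate (neonatal, infant or under-five, per 1,000 live births). The
observation model is

    ln y_it ~ Normal(mu_it, sigma_eps^2)
    mu_it = alpha + s_i + b0 * t~ + v_t + b1i * t~

where t~ = year − mean(year) is the midpoint-centred time covariate.
The pieces have distinct roles:

- `alpha` — overall log-rate at mid-period;
- `s_i = u_i + nu_i` — a country's stable departure from the global
  level, a BYM convolution of a spatially structured part `u`
  (intrinsic CAR on the binary queen-contiguity adjacency W) and an
  iid part `nu`;
- `b0` — the global linear trend of the log rate per year, so
  `100*(1 − exp(b0))` is the global percent decline per year;
- `b1i = ub_i + nub_i` — the country-specific slope departure, with the
  same BYM structure as `s_i`; `b0 + b1i` is a country's own trend;
- `v_t` — a common nonlinear temporal effect shared by all countries;
- `eps_it` — observation-level Gaussian noise. (Writing the noise
  inside `mu` and also giving `ln y` a variance would double-count it;
  a single observation variance `sigma_eps^2` is used.)

Priors: N(0, 1000) on `alpha` and `b0`; positive half-normal with
variance 10 on every random-effect standard deviation. Adjacency
weights are binary and never row-standardised. Each of the three
indicators is fitted as an independent model.

## Identifiability

The intrinsic CAR prior is improper (its precision (D − W)/sigma_u^2 is
singular), and `v_t` overlaps with both `alpha` and `b0 * t~`. The
resolution fixed here:

- `u` and `ub` sum to zero within each connected component of the
  adjacency graph; island countries (no neighbours) have both pinned at
  0 and are represented through `nu`/`nub` only.
- `v` satisfies sum(v) = 0 and sum(t~ * v) = 0, so the linear part of
  the common trend belongs to `b0` and the level to `alpha`.
- Time is midpoint-centred. Regressing on raw calendar years would make
  the intercept and slope nearly collinear; centring keeps `b0`'s
  per-year interpretation and makes `alpha` the mid-period level.

The synthetic-data generator applies the same two `v` constraints (it
draws `v_t` iid N(0, sigma_v^2) and projects), so the generator's `b0`
is exactly the estimand the fitted model identifies. Without the
projection, the random linear component of `v` would contaminate the
"true" `b0` by an arbitrary, unidentifiable amount.

## Sampler

A Gibbs scheme. `alpha`, `b0`, `nu`, `nub` have conjugate scalar/iid
Gaussian full conditionals. `u` and `ub` are updated *jointly* in the
positive eigenspace of the graph Laplacian: with L = V diag(lam) V', the
restricted full conditional in the coordinates z = V_pos' u is
independent Gaussian with precision lam_k/sigma_u^2 + T/sigma_eps^2, so
one matrix-vector product per sweep gives an exact draw that satisfies
the sum-to-zero constraints by construction (eigenvectors with positive
eigenvalue are orthogonal to every component indicator; islands get 0
automatically). This was chosen over node-wise conditional updates with
per-component recentring because recentring only approximately targets
the constrained posterior, while the joint update is exact and cheap at
the graph sizes involved (hundreds of nodes). The node-wise conditional
(neighbour mean, variance sigma^2/m_i) is still exposed as
`icar_full_conditional` and tested against the joint-precision oracle.

`v`'s full conditional is isotropic, so projecting an unconstrained draw
onto its constraint subspace is likewise an exact constrained draw.

Standard deviations are not conjugate under the half-normal prior; each
gets a univariate slice-sampling update (stepping-out + shrinkage) on
log(sd), which is tuning-free and exact. The log-sd is confined to
[−15, 5] as a numerical guard: with degenerate (noise-free) data the
target otherwise lets log(sd) drift without bound. The bound is far
outside any posterior mass seen in realistic data.

`log_joint_density` is the unnormalised log posterior *on the constraint
manifold*: the sd-dependent normalisations carry the dimension of the
subspace each block actually occupies — rank(D − W) for `u` and `ub`
(nodes in non-island components minus the number of such components),
T − 2 for `v`, n for `nu`/`nub`. With these powers the Gibbs
conditionals, the slice targets and the density are mutually
consistent, which is what makes an independent sampler targeting
`log_joint_density` (the random-walk Metropolis reference in
`bstmort.reference`, parameterised in free coordinates with log-sd
Jacobians) a valid oracle for the whole scheme.

Default MCMC schedule: 2 chains x 200,000 iterations, 180,000 burn-in,
thinning 10. The test suite and the calibration study use a desk-scale
schedule (2 x 4,000, 2,000 burn-in, thin 2, `ModelConfig.desk_scale()`)
chosen so a full parameter-recovery study of 50 replicates completes in
a few minutes; at the synthetic problem sizes below the chains mix well
at that length. Chains are initialised from data-driven values with
seeded jitter so the BGR diagnostic starts from dispersed points.

## Convergence diagnostic

The implemented statistic is the classic Gelman–Rubin potential scale
reduction factor: B = n/(m−1) * sum_j (mean_j − mean)^2, W = average
unbiased within-chain variance, Vhat = (n−1)/n W + (m+1)/(mn) B, ratio
= sqrt(Vhat/W), computed on whole post-burn-in chains (no split-chain
variant, no Brooks–Gelman df correction — the operative rule is the
share of parameters above 1.05, and the df correction is second order).
Parameters whose draws are exactly constant (island `u_i`) are skipped:
the ratio is undefined at zero within-chain variance and a constant
carries no convergence information. A fit is flagged non-converged in
its metadata when more than 10% of parameters exceed the threshold.

## Synthetic worlds

The generator emulates the cross-country setting on a queen-contiguity
lattice (default 6x6 = 36 units, years 1990–2019): log-normal rates,
spatially structured levels and slopes, a common wiggle, log-scale
noise. Defaults: alpha = 3 (≈ 20 per 1,000 at mid-period, a realistic
cross-country average), b0 = −0.034 (the ~3.4%/year global decline
scale), sigma_u = 0.3 and sigma_nu = 0.1 (strong, mostly spatially
structured level differences), sigma_ub = 0.01 and sigma_nub = 0.005
(slope departures an order of magnitude below the global trend),
sigma_v = 0.02, sigma_eps = 0.05. iCAR draws use the conditional-sd
parameterisation (full-conditional variance sigma^2/m_i), matching the
fitter, and are taken exactly by eigendecomposition of the Laplacian.
One master seed feeds six named substreams (u, nu, ub, nub, v, noise).

What the generator does **not** emulate: survey measurement error and
the smoothing of the estimation pipeline that produces real national
series (which induces autocorrelated, heteroscedastic errors), reporting
gaps, and the very skewed degree distribution of the real country
contiguity graph. Passing tests therefore demonstrate correctness of
the machinery and calibration under the stated generative model, not
robustness to those real-data features.

## Calibration study

Fifty replicates on the 6x6 lattice with 15 years and the desk-scale
schedule: the central 90% interval for b0 is required to cover the
truth in 80–98% of replicates and the median absolute error of the b0
posterior median to stay below 0.005 (the observed values are computed
fresh by `scripts/acceptance.py` and the acceptance test). 15 years
rather than 30 keeps per-replicate information about b0 from being so
overwhelming that the interval check degenerates, and halves runtime.

## Numerical choices

- Eigenvalues below 1e-9 are treated as null space when splitting the
  Laplacian spectrum; constraint checks use a 1e-8 tolerance.
- Quantiles everywhere are linear-interpolation quantiles; the
  five-number boxplot summaries and the 95% intervals both use them.
- `b0 + b1i` summaries are medians of per-draw sums, never sums of
  medians (the two differ on skewed posteriors).
- Trend classes: "rising" iff median(b0)+median(b1i) > 0, otherwise the
  sign of median(b1i) with a +/-1e-6 tolerance band mapping to
  faster/slower/at-global-rate. Classification uses posterior medians
  only; no posterior-probability significance rule is applied, and the
  output metadata says so.
- KDE: the standard normalised estimator (1/(n h)) sum K((x_i − x)/h)
  with the Epanechnikov kernel K(u) = 0.75(1 − u^2) on [−1, 1], so
  curves integrate to 1; bandwidth defaults to Silverman's rule
  0.9 min(sd, IQR/1.34) n^(−1/5).
- CV: population standard deviation (divisor n) over the mean.
- Regional trends are unweighted country means (no birth-count
  weighting); a "World" column is the mean over all countries.
- Output CSVs are written atomically (temp file + rename) with fixed
  column orders; floats round-trip to at least 12 significant digits.

## Limitations

- The Gaussian log-rate likelihood ignores the sampling variances that
  accompany real mortality estimates; countries with poor vital
  registration get the same weight as countries with complete data.
- Listwise deletion (dropping a country missing any year, per
  indicator) wastes partial series; no imputation is attempted.
- The iCAR eigendecomposition is dense (O(n^3) once per fit), fine for
  a few hundred areal units, not for thousands.
- The joint u/ub updates assume the binary-W iCAR; general weights
  would need the corresponding Laplacian but no code changes otherwise.
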