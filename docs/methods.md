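# Methods

## Estimators

All entropies are reported in energy units, as −TΔS in kJ/mol, with the
gas constant fixed at R = 8.31446×10⁻³ kJ/mol/K and a default
temperature of 300 K (each `EnergySeries` carries its own T).

**Interaction entropy (IE).** Given per-frame interaction energies
ΔE_IE = ΔE_el + ΔE_vdW,

−TΔS_IE = RT · ln ⟨ exp[(ΔE_IE − ⟨ΔE_IE⟩)/RT] ⟩,

with both the centering mean and the average taken over the same window
of frames (after any frame filtering the mean is recomputed on the
surviving frames). The average is evaluated in the log domain as a
log-sum-exp with an implicit shift by the maximum centered energy: at
σ_IE ≈ 70 kJ/mol a raw Boltzmann factor exp(ΔΔE/RT) overflows double
precision long before the average does, while the shifted form is exact
to rounding. Jensen's inequality makes the true value non-negative;
values within one ulp below zero are clamped to zero. A 50-digit direct
evaluation (mpmath) serves as the independent oracle in the tests; the
log-domain path agrees with it to 10⁻¹⁰ kJ/mol on small inputs with
fluctuations up to ±500 kJ/mol.

**Second-order cumulant (C2).** −TΔS_C2 = σ_IE²/(2RT), with σ_IE the
*population* (denominator-N) standard deviation. The population
convention makes the estimate exactly invariant under duplicating every
frame k times — the natural consistency requirement for oversampled
trajectories — and differs from the N−1 convention by far less than any
other error source at realistic sample sizes.

**Truncated IE.** A one-pass cutoff: frames with |ΔE_IE − mean| > k·σ
(mean and σ from the full sample, no iterative re-estimation) are
discarded, the mean is recomputed on the survivors, and the IE formula
is applied to them. The surviving count is reported as the estimate's
sample size. One-pass truncation is the variant actually used in
practice; an iterated cutoff would converge to a different (smaller)
window and is not implemented.

## The Gaussian convergence laboratory

If ΔE_IE ~ N(μ, σ²), the cumulant expansion of the exponential average
truncates at second order, so the converged IE value equals σ²/(2RT)
exactly. That closed form makes Gaussian streams the controlled
environment in which finite-sample behaviour can be measured.

**Reliability criterion.** An estimate is called reliable when it falls
within 4 kJ/mol of the analytic value in at least 95% of 1000
independent replicate streams. 4 kJ/mol corresponds to a factor
exp(4/RT) ≈ 5 in a binding constant at 300 K. Acceptance is two-sided
(absolute deviation); the minimum N is located to 0.1% relative
precision. All four numbers are fields of `ReliabilityCriterion` and
can be changed.

**Minimum-N search.** Success probability is (up to replicate noise) a
monotone function of N, so the search brackets geometrically (doubling
from N = 2) and then bisects until the bracket is within the requested
relative resolution or one frame. Each candidate N is evaluated with an
RNG seeded from (master seed, N), which makes the measured success
fraction a fixed function of N during one search: the bisection is
deterministic for a given master seed and cannot oscillate on replicate
noise. Replicates are evaluated vectorized, chunked so that at most
5×10⁷ draws are held in memory at once. The search is bounded by a
configurable ceiling (default 10⁷ — roughly where coordinate-file
storage becomes impractical in real applications); hitting the ceiling
returns a first-class non-converged result rather than raising, because
"IE cannot be converged at this σ" is the scientifically important
outcome for σ_IE ≳ 15 kJ/mol.

**Gaussian generation.** numpy's ziggurat normal generator by default;
a seed-reproducible Box–Muller implementation is selectable
(`method="box-muller"`) for parity with classical convergence studies.
The two produce different streams for the same seed but identical
statistics.

**Integrand decomposition.** ⟨exp(ΔE/RT)⟩ = ∫ G(ΔE)·B(ΔE) dΔE with G
the Gaussian density and B = exp(ΔE/RT). The product peaks at
ΔE = σ²/RT. The profile is computed on a uniform grid extended by
default to ±(σ²/RT + 8σ) — the integrand mass sits far in the tail, and
a narrower grid (below σ²/RT + 4σ) is rejected. The running tail
integral is accumulated in the log domain with trapezoid weights and
reported on the −TΔS scale; over the full grid it reproduces σ²/(2RT)
to better than 0.01 kJ/mol. The favorable tail is taken at positive
centered ΔE and magnitudes are reported; only |ΔE| is physically
meaningful here since the centered Gaussian is symmetric.

**Truncation bias.** For the converged k·σ-truncated IE under a
Gaussian, E[e^{x/RT} | |x| ≤ kσ] has the closed form
e^{s²/2}·[Φ(k−s) − Φ(−k−s)]/[2Φ(k) − 1] with s = σ/RT, evaluated via
`log_ndtr` for stability. The bias is σ²/(2RT) minus RT·ln of that
average. A direct quadrature of the truncated integrand (with the
exponential peak factored out) is kept as an independent cross-check;
the two agree to 10⁻⁶ kJ/mol.

## Series diagnostics

**Block averaging.** Contiguous, non-overlapping blocks with the
trailing remainder discarded; the reported uncertainty is
SD(per-block values)/√(number of blocks). Contiguity keeps blocks
approximately independent when the correlation time is short relative
to the block length. The diagnostic signature: on Gaussian data the C2
block-mean is flat in block size while the IE block-mean climbs
whenever σ_IE is large — a climbing IE curve on real data is the
primary symptom of an unconverged exponential average.

**Extrapolation.** S(N) = s∞ − a·N^(−c) fitted by linear least squares
with the exponent c held fixed; callers sweep c over a small grid
(conventionally 0.20–0.30). c is deliberately an input rather than a
third fitted parameter: the fit is strongly c-dependent and a free
exponent mostly fits noise.

**Autocorrelation and statistical inefficiency.** Biased (1/N)
autocovariances computed by FFT, normalized so lag 0 is exactly 1. The
statistical inefficiency is g = 1 + 2·Σρ_k with the sum truncated at
the first non-positive autocorrelation — the standard
positive-sequence estimator; windowed variants are out of scope. For an
AR(1) process the population value is (1+φ)/(1−φ): φ = 0.5 gives g ≈ 3
(the buried-binding-site regime at 10 fs sampling), φ = 0.95 gives
g ≈ 39 (strongly oversampled). For a stream in which every energy is
repeated k times the estimator returns g ≈ k, matching the fact that
k-fold duplication leaves the estimates unchanged while requiring k
times as many frames for the same precision.

**Gaussianity.** Histogram plus the normal density with matched mean
and population σ at the bin centers, with sample skewness and excess
kurtosis (uncorrected moment estimators — the bias correction is
immaterial at ≥10³ frames). Strong non-Gaussianity is the regime where
even C2 drifts with N on real data.

## Synthetic streams

The generator produces the statistical structures the analysis assumes
or must be robust to, each seeded and reproducible:

* `gaussian` — i.i.d. N(μ, σ²); σ defaults span the realistic 6–71
  kJ/mol range.
* `ar1` — stationary AR(1) with innovations scaled by √(1−φ²) so the
  marginal SD is exactly σ; the first draw initializes the chain at
  stationarity, so φ = 0 reproduces the Gaussian stream bit-for-bit
  under the same seed. AR(1) is the minimal model matching a single
  observed lag-1 correlation (0.74 is typical of 10-fs sampling);
  higher-order processes are out of scope.
* `mixture` — finite normal mixtures for skewed/heavy-tailed energy
  distributions; `skewed` — skew-normal standardized to the requested
  mean and σ.
* `duplicated` — each base energy repeated k times, the limiting model
  of oversampling.

Three presets span the binding-site regimes: `buried-site` (σ = 6
Gaussian), `intermediate` (σ = 13, mild skew, shape α = 4),
`surface-site` (two-component mixture, weights 0.75/0.25, means
+10/−30, SDs 35/100 kJ/mol, overall σ ≈ 61 with a heavy low-energy
tail). The surface-site preset is a qualitative emulation — no
quantitative parameterization of such distributions has been published
— chosen so that its IE/C2 divergence at N = 10⁵ reproduces the
surface-bound regime.

What the synthetic streams do *not* emulate: slow conformational
transitions (new states appearing as simulations lengthen),
non-stationarity, rmsd trajectories, or term-by-term MM/GBSA energy
decompositions. Tests passing on these streams therefore validate the
estimators and diagnostics under their stated statistical assumptions;
they do not certify convergence behaviour on trajectories whose energy
distribution drifts with time.

## I/O and verdicts

Energy tables are delimited text with columns from {frame, elec, vdw,
total, rmsd}; either `total` or `elec`+`vdw` must resolve. The energy
unit must be explicit (a `# unit:` header or an explicit dialect):
kcal/mol inputs are converted by ×4.184, and a missing unit is an
error, never a silent default, because mixing kcal- and kJ-based tables
is the most likely real-world failure. Written tables use shortest
round-trip float formatting and are read back with round-trip parsing,
so write/read cycles are bit-exact. Frames are 1-based; file order
defines time.

The report verdict maps σ_IE to three tiers with config-overridable
boundaries: below 15 kJ/mol both estimators are usable (below ~10 they
should agree within a few kJ/mol); 15–25 kJ/mol — IE cannot be
converged at practical N, use C2 only; above 25 kJ/mol — C2 still
converges but the value is most likely grossly overestimated, so
neither is reliable.

## Problem sizes and numerical choices

* Minimum-N searches in the test suite and acceptance script run the
  full 1000-replicate criterion at σ = 9 (IE) and σ = 15, 25 (C2);
  the IE monotonicity property uses 300 replicates over σ ∈ {3, 6, 9},
  a grid chosen to exercise the steep IE growth while keeping the
  suite fast.
* Distribution-level checks (IE≡C2 agreement, preset moments) use 10⁶
  draws; autocorrelation/inefficiency checks use 10⁵–10⁶.
* Integrand profiles use a 0.1 kJ/mol grid step for headline values
  and 0.5 for normalization checks.
* Degenerate inputs: constant series give IE = C2 = 0 and have no
  autocorrelation (error); series shorter than 2 frames are rejected;
  a cutoff that removes every frame is an error; an N-search that hits
  its ceiling is a non-converged result, not an exception.

## Known limitations

* The statistical-inefficiency estimator truncates at the first
  non-positive autocorrelation; for very slowly decaying correlations
  the estimate is noisy and modestly biased low.
* The extrapolation model is a single power law; real block curves
  with multiple relaxation scales will show c-dependent s∞, which is
  reported (via the residual across a c-grid) rather than resolved.
* The verdict tiers are marginal-σ heuristics: a small σ_IE does not
  guarantee convergence when the energy distribution drifts with
  simulation length.
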