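# Methods

## Model and estimators

The package fits a multi-trait threshold-linear mixed model: `c` ordinal
traits arise by thresholding latent Gaussian liabilities, `m` continuous
traits are observed directly, and both share one residual covariance `R`
per animal and an additive-genetic covariance `G0 ⊗ K` across animals,
where `K` is any relationship matrix (pedigree `A`, genomic, or single-step
`H`). Thresholds and covariance components are inputs, not estimates: the
solvers compute location parameters only, which is how large-scale genetic
evaluations are run (variances are re-estimated periodically on subsets by
MCMC). Identifiability on the liability scale is therefore the user's
responsibility; the simulator follows the standard probit convention
(categorical residual variances 1, first threshold 0).

Records of different animals are conditionally independent given `θ`, so
the log posterior is a sum over records of the log probability that the
liability vector falls in the observed category rectangle under
`N(μi, Σi)`, with `μi = W1iθ1 + R12R22⁻¹(y2i − W2iθ2)` and
`Σi = R11 − R12R22⁻¹R21`, plus the Gaussian likelihood of the continuous
records and the prior `−θ′Sθ/2`, `S = blockdiag(0, K⁻¹ ⊗ G0⁻¹)`.

**Newton–Raphson.** The gradient and Hessian contributions of a record
reduce to the truncated-MVN working quantities `Δi` (from the truncated
mean) and `Γi` (from the truncated covariance). The Newton step is
algebraically identical to solving linear mixed-model equations with a
working residual covariance whose inverse has the closed block form

```
R̃i⁻¹ = [  Γi        −Γi B       ]        B = R12 R22⁻¹,
        [ −B′Γi   B′Γi B + R22⁻¹ ]
```

and pseudo-data `ỹi = (μi + Γi⁻¹Δi, y2i)`. `R̃i⁻¹` is computed once per
outer round and reused by the inner solver. Convergence is declared when
the relative residual of the working equations at the current iterate
drops below `1e-12`.

**EM.** The E-step replaces each liability by its conditional expectation
given the observed category, the continuous traits and the current `θ`
(only the truncated *mean* is needed — the reason an EM round is much
cheaper than an NR round); the M-step solves the ordinary multi-trait MME
with the true `R` and `(l̃, y2)` as data. Its coefficient matrix does not
depend on `θ`, so one sparse factorization serves all rounds. The additive
constants of the expected complete-data log likelihood (conditional
liability variances) do not involve `θ` and are never materialized.
Convergence uses the same relative-residual criterion, evaluated on the NR
working system, so both algorithms share one stopping semantics.

**Gibbs benchmark.** A single-site sampler alternates truncated-normal
draws of each categorical liability (conditioning on the record's other
traits through `R`) with single-site normal draws of every MME equation.
Posterior means over the kept samples are the benchmark point estimates.
The benchmark is defined by its stationary distribution; no attempt is
made to match any particular sampler implementation sweep-for-sweep.

## Truncated-MVN numerics

Rectangle probabilities use closed forms in 1-D, a fixed-node
Gauss–Legendre evaluation of the arcsine-transformed correlation integral
in 2-D (absolute error ≲1e-13 for |ρ| ≤ 0.95, which covers the residual
correlations of interest), and scipy's Genz recursive quasi-Monte-Carlo
integrator above 2-D with absolute tolerance 1e-10 and a *fixed* internal
seed, so all solver runs are bit-reproducible.

Truncated means and covariances follow the classical reduction to marginal
densities of the truncated distribution: the mean needs the `c` univariate
marginal densities at the box faces
(`E_T[X] = μ + Σ(F(lower) − F(upper))`), the second moment additionally
needs the bivariate marginal densities at the box edges. The index
convention of the edge terms is the one that makes the pair
`(k, q), q ≠ k` run over ordered pairs with the shared corner factor
`σjq − σkq σjk/σkk`; it was verified three independent ways (rejection
sampling, finite differences of the mean in `μ` against `Γ`, and the
univariate closed forms at `c = 1`). Records sharing a missingness pattern
share `Σi`, so the solvers evaluate the 1-D and 2-D cases in vectorized
batches; the generic per-record path handles `c` up to the tested 4 and is
cross-checked against the fast paths.

Numerical safeguards: cell probabilities are floored at 1e-12 before any
division (boundary cells under extreme `θ` would otherwise produce
infinities); a numerically indefinite truncated covariance or `Γ` is
symmetrized and eigenvalue-floored, and each event is flagged on the
returned object. Infinite bounds are `numpy.inf` end to end and contribute
exact zeros to the face/edge terms.

## Solvers and linear algebra

Equations are ordered fixed-effects trait-major, then breeding values
trait-within-animal; `S = blockdiag(0, K⁻¹ ⊗ G0⁻¹)` in that layout.
Fixed effects use a full-rank design (first factor cell-means coded, later
factors drop their first level) so the coefficient matrix is SPD and
directly factorizable; breeding-value contrasts are unaffected by this
choice. Assembly sums per-record contributions `W′i Mi Wi` vectorized over
records within a pattern.

The default solve is a sparse LU with symmetric-pattern minimum-degree
ordering (`MMD_AT_PLUS_A`), which keeps fill-in modest on MME-structured
matrices; a Jacobi-preconditioned conjugate-gradient option is available,
also usable on singular-but-consistent systems. Newton–Raphson starts at
`θ = 0` and halves the step (up to 5 times) whenever a full step increases
the convergence metric — plain Newton can overshoot on non-quadratic
objectives; in practice the halving never triggers on well-posed data.
Prediction error variances come from selected diagonal entries of the
inverse coefficient matrix at convergence.

SQUAREM acceleration is applied after each pair of plain EM steps: with
`r = θ1 − θ0`, `v = θ2 − θ1 − r`, steplength `α = −‖r‖/‖v‖` clamped to
≤ −1, the extrapolated point is `θ0 − 2αr + α²v`, and it is discarded in
favor of the plain iterate whenever it worsens the convergence metric.
"Every other round" admits two phasings; accelerating after each pair was
chosen and the round counter counts E/M pairs, including those inside
acceleration cycles.

## Synthetic data

The simulator emulates the validation design: four traits (binary with
threshold 0; three categories with thresholds 0 and 0.8; two continuous),
sex and generation fixed effects, and an additive genetic effect over an
overlapping-generation pedigree without directional selection or selfing.
Defaults (all overridable in `SimConfig`):

| quantity | default | rationale |
|---|---|---|
| additive variances | 0.25, 0.40, 0.60, 1.00 | heritabilities 0.20–0.40, moderate values typical of fitness/production traits |
| genetic correlations | 0.2–0.5, all nonzero | exercises the multi-trait machinery |
| residual variances | 1, 1, 1.4, 1.5 | unit categorical variances = probit identification |
| residual correlations | 0.1–0.3 | nonzero `R12` so the conditional moments matter |
| sex effects / generation trends | ±0.2–0.5 / ±0.05–0.1 per trait | visible but not category-emptying systematic effects |
| generation overlap | 20% of parents from two generations back | overlap rate is a design choice; any positive rate exercises the same code |

Breeding values follow the infinitesimal model with no-inbreeding
Mendelian-sampling variance (`G0/2` for two known parents). The pedigree
inverse correspondingly defaults to the non-inbred Henderson rules, with
an inbreeding-aware option (tabular-method coefficients) for pedigrees
where that matters; tests accept either variant. Unknown parents are
treated as founders; unknown-parent groups, metafounders and repeated
records are out of scope.

What the simulator does *not* emulate: selection (which biases EBVs and
changes the MAP-vs-posterior-mean relationship), heterogeneous variances,
censoring, genotypes, or real-data missingness mechanisms (missingness is
supported by the model machinery and tested, but the validation scenario
generates complete records). Passing validation therefore demonstrates
agreement of the estimators with each other under the model, not
robustness to model misspecification — except for the explicit
sensitivity scenarios, which bias the categorical additive variances by
±10–20% and re-check agreement against the true-parameter benchmark. In
those scenarios only the diagonal `G0` entries are changed and
covariances are kept, matching the design of varying one component at a
time (the implied genetic correlations shift slightly).

## Problem sizes and statistical tolerances

The validation experiment runs at 3,000 animals over 6 generations with
10,000 Gibbs samples (1,000 burn-in) — large enough that per-trait
EBV correlations and regression slopes are stable to the third decimal,
small enough to run in about a minute. The Gibbs benchmark's Monte-Carlo
standard errors are estimated by batch means (20 batches). Monte-Carlo
comparisons in the test suite use 3-standard-error bands; across the
~500 comparisons of the truncated-moment oracle suite a small number of
chance exceedances is expected under the null, so that suite additionally
bounds the exceedance *fraction* (≤1%) and the maximum deviation (5 SE),
which a systematic error of any practical size would violate.

## Known limitations

* Thresholds and covariance components are never estimated.
* Dimensions of the categorical block above 4 are untested (the generic
  moment path has no hard limit but cost grows quickly); non-rectangular
  truncation and censored traits are unsupported.
* The single-site Gibbs sampler is a benchmark, not a production sampler:
  it mixes slowly on large or dense systems by construction.
* All solves are in-memory sparse; out-of-core iteration-on-data is not
  implemented, though the PCG path consumes the same per-record
  contributions and is matrix-free in spirit.
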