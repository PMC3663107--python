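# Methods

## Model

Somatic single-nucleotide variants from `M` tumors are reduced to a
count matrix `X` over the `Nc = 96` pyrimidine-collapsed trinucleotide
channels (six substitution classes × sixteen 5'/3' contexts). The
counts of tumor `m` are modeled as independent Poisson draws,

    X_j^m ~ Poisson( sum_a x_a^m * mu_aj * omega_j^m ),

with `n` elementary mutational processes: `mu` (n × 96, each row a
probability distribution over channels) are the process signatures,
`x` (M × n, non-negative) the per-tumor activities, and `omega`
(M × 96) the mutational opportunity — for every base with a complete,
unambiguous trinucleotide context, the three channels it can mutate
into are credited with that base's copy number. An activity confounds
the process's intrinsic rate, its active time and the genome fraction
attacked; these cannot be separated without time-resolved data.

Setting `omega = 1` everywhere gives the opportunity-blind variant of
the model. Note that this changes the *units* of activity (see "Units
and model selection" below).

## Inference

Signatures and activities are estimated by EM:

* **E-step.** Per tumor, maximize the conditional Poisson
  log-likelihood over the activity vector on the non-negative orthant.
  The objective is convex; we use KL-NMF-style multiplicative updates
  (guaranteed monotone) finished by damped Newton steps on
  log-activities, to a KKT residual of 1e-9 relative to the gradient
  scale. Optionally the objective is augmented with a pseudocount
  prior (below), making the estimate a MAP.
* **M-step.** Update `mu` under the row-simplex constraint. Each sweep
  allocates counts to processes by responsibility and then solves the
  resulting surrogate `max sum_j c_j log mu_j - d_j mu_j` on the
  simplex *exactly* through its Lagrange multiplier: `mu_j =
  c_j/(d_j + kappa)` with `kappa` found by a vectorized, bracketed
  (safeguarded-Newton) root-find, warm-started across sweeps. Solving
  the surrogate exactly keeps the EM monotonicity guarantee without a
  heuristic renormalization; with flat opportunity it reduces to the
  familiar proportional update.
* `fit()` alternates one activity and one signature sweep per
  iteration (generalized EM, still monotone), from signature rows
  drawn Dirichlet(1) with a per-restart seed; default 10 restarts,
  convergence when the relative change of the total log-likelihood
  falls below 1e-8 (the parameter-free `log X!` constant is excluded
  from the convergence test so the trajectory does not depend on
  whether it is reported), cap 10,000 iterations. The best restart by
  final likelihood is returned; process labels are arbitrary.

Processes whose total activity hits zero carry no information about
their row of `mu` and are reset to uniform with a warning. Channels
with zero opportunity but nonzero counts are rejected as input errors.

## Choosing the number of processes

For each candidate `n`, the latent activities are integrated out of the
likelihood per tumor with a Laplace (saddle-point) approximation at the
E-step optimum:

    log ∫ d^n x P(X^m|x, omega^m, mu) ≈ (d/2) log 2π − L(x̂) − ½ log det H(L)(x̂),

where `L` is the negative conditional log-likelihood, `H` its Hessian
(`H_ab = sum_j X_j G_aj G_bj / lambda_j^2`, `G = mu ∘ omega`), and `d`
the number of strictly positive activity components — boundary
components are removed from the integration dimension because the
Gaussian approximation is undefined there. Singular Hessians get a
jitter of 1e-10 × trace (logged) before failing. The model score is

    BIC = 2 log P(X|mu_hat) − n (Nc − 1) log M     (natural log),

maximized over `n`, ties broken toward smaller `n`.

### Units and model selection

The marginal above uses an (improper) uniform prior over activities,
so its value depends on the activity units, i.e. on the normalization
of `omega`. With whole-genome opportunity (raw base counts, total
~1.8e10 for a diploid human genome) activities are ≪ 1, the posterior
volume per active dimension is tiny, and the Laplace term *penalizes*
extra processes — the scan then recovers the true `n` and does not
overestimate. With `omega = 1`, activities are of order the mutation
burden (10³–10⁴), every active dimension is *rewarded* by the volume
term, and the scan consistently overestimates `n`. This single
mechanism reproduces both benchmark behaviors (correct recovery with
opportunity modeled; systematic overestimation when it is ignored),
and is why opportunity matrices should be kept on their natural
base-count scale rather than renormalized.

## Error bars on signatures

Standard errors for `mu_hat` come from the observed information of the
conditional log-likelihood in `mu` with activities fixed at their
estimates. Within one process the information over channels is
diagonal, `I_aj = sum_m X_j^m (x_a^m omega_j^m)^2 / (lambda_j^m)^2`;
the per-process block is projected onto the tangent space of the row
simplex (centering projector) and pseudo-inverted. Channels with zero
information get NaN errors and a warning. The construction is this
package's own; it obeys the expected 1/√k shrinkage under k-fold
sample replication, which the tests verify.

## Mutation assignment and local activity

Assignments follow the proportionality rule

    Xhat_aj^m = X^m · x_a mu_aj omega_j / sum_b x_b (mu·omega)_b,

which conserves the observed total exactly. Activity estimates used
for assignment are regularized by `n` pseudocounts distributed as
`Xt_aj = n w_a mu_aj omega_j / sum_b w_b (mu·omega)_b`, entering the
objective as `− sum_aj Xt_aj log(x_a mu_aj omega_j)`; `w = 1` for the
global fit, `w = x̂^{global}` (the informed prior) for per-window
inference. The pseudocount total is fixed at `n`, so the prior
dominates empty windows and washes out as counts grow.

Local analysis tiles the genome into non-overlapping windows (1 Mb by
default, configurable), computes per-window opportunity, runs the
penalized E-step per window with the informed prior, and assigns each
window's mutations with the local activities but the *global*
signatures. A consistency check compares summed local assignments with
the global assignment per process, as a relative deviation.

## Clustering and region statistics

Expected window counts under the homogeneous null are global activity
× window opportunity overlap, rescaled to the observed total per
(sample, process) — the tests are conditional on that total.

* **Dispersion index**: `D = sum_l (c_l − e_l)^2/e_l / (N'−1)` over
  windows with positive expectation — a Pearson-χ²/dof form of the
  variance-to-mean ratio that corrects for heterogeneous opportunity.
  `D ≈ 1` under the null (validated by simulation: mean 1.00 ± 0.01
  over 100 replicates of 500 windows); `D ≫ 1` flags clustering. The
  exact corrected form is this package's construction, validated by
  its defining null property.
* **Window scores**: one-sided Poisson tail in the direction of the
  deviation, reported as signed −log10 P capped at ±20 (positive =
  surplus). No doubling; the sign carries the direction. Windows with
  zero expectation but observed counts get +20 and a flag. Bonferroni
  across windows is the default multiple-testing control.
* **Region enrichment**: observed assigned counts per (region,
  process) against `expected_a(s) = Xhat_a^g (mu_a·omega^s)/(mu_a·omega^genome)`,
  with a two-sided Poisson cell test, plus opportunity-fraction vs
  mutation-fraction summaries per region label. The cell test is a
  stand-in for an unspecified original test.

## Synthetic data

`simulate_counts` draws sparse signatures (symmetric Dirichlet,
concentration 0.1, mimicking strongly peaked real spectra), assigns
tumors round-robin to cancer types (one type per block of five
processes when `n` is a multiple of five), and calibrates per-tumor
activities so expected burdens are log-normal (median 5000, log-sd
0.7 — a breast-cancer-like scale). Opportunity may be flat, a shared
96-vector, or per-tumor. The packaged 48 kb toy genome (three contigs,
fixed-seed first-order Markov chain, 41% GC, five-fold CpG depletion)
yields an opportunity profile with ~14-fold channel variation,
comparable to the real genome's ~17-fold; `toy_opportunity
(scale_total=1.8e10)` rescales it to a diploid whole-genome territory.

What the generator does *not* emulate: real signature shapes (flat
background vs APOBEC-like peaks), correlated copy-number segments
(per-tumor opportunity perturbations are log-normal per channel),
sequencing/calling artifacts, and selection. Passing tests therefore
demonstrate correctness of the inference machinery under the model,
not robustness to real-data misspecification.

`simulate_windowed_genome` adds Poisson background per window plus
optional injected clusters (a fixed number of extra mutations drawn
from a chosen process's opportunity-weighted channel distribution) —
the kataegis testbed. 50-mutation injections into windows expecting ~5
mutations are Bonferroni-detected with power > 0.9.

## Numerical choices

* Intensities are floored at 1e-150 × their maximum when used in
  ratios, so collapsed channels cannot produce NaN/Inf curvatures.
* `0 · log 0 = 0` throughout; `Pois(0|0) = 1`.
* Active-set threshold for the saddle point: `x_a > 1e-8 × sum(x)`.
* The `log X!` constant is included in reported likelihoods by default;
  model ranking is provably unaffected (tested).
* Matrix TSVs are written with 17 significant digits (lossless round
  trip); channel columns are validated and reordered to canonical
  order on read.

## Problem sizes used in the packaged benchmarks

The packaged recovery benchmarks use M = 20 tumors, 5 processes,
n-scan 3..7, 3 restarts and 20 replicates (recovery), 6 replicates of
the flat-vs-true comparison at n_true = 2, and 100 replicates of 500
windows for the dispersion null. These sizes reproduce the qualitative
and quantitative behaviors stably (the recovery benchmark selected
n = 5 in 20/20 replicates with the margin far from the tie line).

## Known limitations

* The saddle-point marginal uses an improper uniform activity prior;
  its absolute value is unit-dependent (see above). Comparisons are
  only meaningful at fixed `omega` normalization.
* Copy number is treated as static at its time-of-sequencing state;
  opportunity is attributed by the mutated base's position.
* Records with ambiguous context (N) or at contig edges are rejected,
  not imputed.
* No MCMC error estimates; analytic errors only.
* No strand- or timing-resolved channels, no indels/MNVs.
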