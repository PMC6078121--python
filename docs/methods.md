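# Methods

## Model and protocol

`dranet` fits one regression model across K sites holding horizontally
partitioned data (same variables, different patients). The estimator is
ordinary maximum likelihood (least squares for the linear family) computed
by exchanging only sufficient aggregates:

- **Linear.** Each site reports n, XᵀX, Xᵀy, yᵀy. These are the complete
  sufficient statistics for least squares, so the center's solution of the
  summed normal equations *is* the pooled OLS fit, exactly, in one round.
  Residual variance comes from the algebraic identity
  RSS = yᵀy − 2βᵀXᵀy + βᵀXᵀXβ, with σ̂² = RSS/(n − p).
- **Logistic.** Sites evaluate the Bernoulli score Xᵀ(y − π), the expected
  (= observed) information XᵀWX, and the log-likelihood at the broadcast β.
  Because patients are independent, these sum across sites to the pooled
  quantities at the same β, so the center's Newton–Raphson path is the
  pooled path, iteration by iteration, up to floating-point summation
  order.
- **Cox.** Sites evaluate the Breslow-tie partial-likelihood score,
  observed information, and log-likelihood *within their own stratum*.
  Site-stratification is a modelling decision, not an approximation: the
  distributed fit equals a pooled Cox model with one baseline hazard per
  site. Sharing cross-site risk sets would require exchanging per-event-time
  aggregates (a different, chattier protocol) and is intentionally out of
  scope; stratification is also the scientifically safer default when
  baseline hazards differ by site. A consequence worth knowing: with very
  few events per site, stratified estimates lose some efficiency relative
  to an unstratified pooled fit.

The intercept is always included for linear and logistic models and always
excluded for Cox (the partial likelihood absorbs any intercept into the
baseline hazard; an intercept column would make the information singular).

### Newton–Raphson details

- Initialization β₀ = 0 — conventional and reproducible.
- Convergence: max absolute coefficient change ≤ `tolerance`
  (default 1e-6), checked between successive *accepted* iterates;
  `max_iterations` defaults to 25. Both are config-overridable.
- Step-halving: if the aggregated log-likelihood at the candidate β is
  lower than at the last accepted β, the center re-broadcasts the halved
  step. Each halving costs one protocol round trip (the log-likelihood can
  only be evaluated by the sites); after 10 halvings the run fails. A
  "decrease" smaller than 1e-10·(1 + |ℓ|) is treated as rounding noise and
  accepted — without this floor, the one-ulp fluctuations near the optimum
  trigger spurious halving cascades.
- Aggregation always sums in ascending partner id, making runs
  bit-reproducible; partner relabeling changes nothing beyond that order.
- Singular information (collinearity, separation) and rank-deficient XᵀX
  are hard errors with advice in the message — never a silent
  pseudo-inverse.
- Missing values in model columns are an error at the site; complete-case
  filtering is an upstream data-curation decision, not something the
  engine does silently.
- Wald inference: cov = (ΣI)⁻¹ (σ̂²(ΣXᵀX)⁻¹ for linear), 95% CIs use the
  fixed normal quantile 1.959964 for every family.

### Transport contract

Payload files are labeled-section delimited text (header:
`format_version`, `kind`, `family`, `iteration`, `partner_id`, `p`;
sections of one number per line; symmetric matrices as upper triangles).
Numbers are printed with 17 significant digits, which round-trips IEEE
doubles exactly. Triggers (`files_done.ok`, `job_done.ok`) are zero-length;
all semantics live in payload content and file naming. Visibility is
atomic: write to a temporary name, fsync, rename; the trigger is written
after all payloads, so a poller that sees the trigger sees complete files.
Consume moves (never copies) payloads and deletes the trigger, giving
single-shot semantics; a stale answer (iteration index already served) gets
a structured error payload rather than silent reuse. Default poll interval
0.5 s and per-iteration timeout 300 s are protocol-neutral conveniences;
the demo configs use faster polling.

The privacy audit re-parses every archived transferred file and checks its
scalar count against the closed-form budget for its kind — p + p(p+1)/2 + 3
for a score/information payload, p(p+1)/2 + p + 2 for SSCP, p + 2 for a
parameter file, 4B + 3 for B diagnostic bins. Any file that does not parse
as one of these kinds, or carries more numbers than its dimension allows,
fails the audit; a patient-level table can never pass.

### Automation levels

`manual` invokes the approval callback before every deposit and every
consume; `semi_automated` only when files leave a partner's `msoc` folder
(the site's chance to review outbound statistics); `fully_automated` never.
Gating affects only whether a transfer happens, never the numbers: a
manual run with an all-approving gate is bitwise identical to a fully
automated one. A denial aborts before any file is written.

## Synthetic cohorts

The generator stands in for upstream cohort assembly: each partner gets an
independent, individually reproducible table (substream spawned from
`(seed, partner_id)`). Default design: 3 partners × 2000 patients with a
Bernoulli(0.5) exposure, a standard-normal standardized age, and a
Bernoulli(0.3) comorbidity flag — a deliberately generic
pharmacoepidemiology-shaped design with moderate effect sizes
(β = (−1.0, 0.5, 0.3, −0.4) including intercept for linear/logistic;
(0.5, 0.3, −0.4) for Cox). Outcomes: Gaussian noise with unit variance
(linear); Bernoulli(expit(Xβ)) (logistic); exponential event times with
rate exp(xβ) on a unit baseline hazard, independent exponential censoring
(rate 0.2 default, ≈60% events) for Cox. An optional per-site
N(0, `site_effect_sd`²) shift on the linear predictor creates real
between-site heterogeneity — the scenario that motivates the stratified
Cox model.

What the generator does *not* emulate: confounding structure beyond linear
covariate effects, non-proportional hazards, informative censoring,
site-specific measurement differences, missing data, or realistic claims
/EHR feature distributions. Passing tests therefore demonstrate the
*numerical* equivalence and protocol properties of the engine, not the
epidemiological validity of any particular study design.

## Problem sizes and simulation design

The headline checks run the standard 3 × 2000 design (p = 4 for
linear/logistic, p = 3 for Cox). The simulation study uses 200 replicates
for CI coverage (logistic) and log-hazard-ratio bias (Cox, combined
n = 6000); with 200 replicates the Monte-Carlo standard error of a 95%
coverage estimate is ≈1.5 percentage points, which is why the acceptance
band for coverage is [0.92, 0.98]. The Cox iteration-path check uses
3 × 120 patients because its independent oracle enumerates risk sets
brute-force (O(events × n) per evaluation).

## Design choices that were genuinely open

- **Linear in one shot.** SSCP statistics are β-independent, so the linear
  family answers the first broadcast and terminates; the same
  broadcast/collect/job-done machinery carries it, keeping one workflow
  for all families.
- **Diagnostics from fixed global bins.** Calibration and discrimination
  are computed from per-bin {count, Σy, Σπ̂} aggregates over 20 equal-width
  probability bins (default). Fixed edges avoid a second protocol round to
  agree on pooled quantiles; the binned Hosmer–Lemeshow-type statistic
  Σ(O−E)²/(E(1−E/n)) with df = nonempty bins − 2 is then *exactly* additive
  across sites, and the binned AUC (P(case bin > control bin) + ½ ties)
  converges to the exact rank AUC as bins refine. Exact AUC would need
  patient-level scores — excluded by the privacy contract. Cox diagnostics
  are the final stratified partial log-likelihood and event counts; linear
  runs report only counts.
- **Partner loops as threads.** The run command executes sites as daemon
  threads doing real folder polling against the center thread. Because the
  protocol is lockstep (the center waits for all partners each iteration),
  results are independent of scheduling; an interleaved single-process
  driver would produce byte-identical output.
- **All partners required.** The center aggregates only complete
  iterations; a silent or erroring partner fails the run with its name in
  the message rather than quietly fitting on a subset.
- **Stale-iteration rejection.** A partner answers each iteration index at
  most once and error-payloads any repeat; the center treats mixed
  iteration indices during aggregation as a protocol error naming the
  offender.

## Known limitations

- No restart/recovery: an interrupted run must be restarted from scratch.
- One request at a time per network; no queueing of concurrent analyses.
- No robust/sandwich variances, Efron ties, regularization, or
  time-varying covariates.
- The transport simulates folder monitoring on one filesystem; real
  deployments add networking, authentication, and governance that are out
  of scope here.
- Logistic separation and Cox monotone likelihood surface as singular
  information or repeated step-halving failures — correct but blunt; a
  production system would detect separation explicitly.
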