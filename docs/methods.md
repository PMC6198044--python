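# Methods

## Population and study design being emulated

The synthetic-data generator reproduces the structure of a closed maternal
rabbit line: a grandparental base generation, 332 sires and 849 dams (by
default) producing ~25,000 kits over repeated parities, weaning batches,
and allocation of kits from every second batch to a challenging environment
(97% of those males by default, matching the heavily male-biased
composition of challenged animals). Four percent of kits are cross-fostered
at birth; their maternal genetic, maternal environmental and common-litter
effects follow the adoptive doe while the additive effect follows the
biological pedigree. The generator returns true breeding values so
downstream estimators can be checked by parameter recovery.

Disease liabilities are `intercept + batch + sex (+ farm in Ch) + additive
+ common litter + logistic residual`; the binary trait is the indicator of
positive liability. The composite disorder (Resist) is the logical OR of
digestive signs, respiratory signs and a latent "other infectious"
disorder — the simplest generative rule under which any recorded syndrome
marks the animal as affected. Component intercepts are solved by
Gauss-Hermite quadrature so that marginal prevalences hit their targets
(26% S / 41% Ch for the composite; the "other" component's 3.3%/7.6%
targets are the values that close the OR under independence given shared
batch and farm effects). The S and Ch expressions of each disorder are
distinct genetic traits with a configurable cross-environment correlation.

What the generator does *not* emulate: infection transmission between cage
mates (disease outcomes are conditionally independent given litter and
genetics), longitudinal disease course, recording error, and non-random
allocation of related animals to farms. Passing recovery tests therefore
shows the estimators are consistent under the stated model, not that the
model captures every feature of real health records.

## Mixed models

Random terms are declared as sets of *channels* (a trait routed through an
incidence rule) sharing one covariance structure, so the direct-maternal
genetic covariance of weaning weight is a 2-channel pedigree term (direct
on the animal, maternal on the rearing dam). The pedigree inverse is built
by Henderson's rules with inbreeding-aware Mendelian-sampling variances
(Meuwissen-Luo ancestor walk), and `A^-1 = (I - P/2)' D^-1 (I - P/2)`
agrees with the dense tabular inverse to 1e-8 on every fixture.

REML maximizes the exact restricted log-likelihood evaluated through one
sparse LU factorization of the mixed-model equations per parameter vector
(`-2 logL = log|C| + log|R| + log|G| + y'Py`, with `log|A|` available in
closed form from the pedigree decomposition). Updates are Newton steps
whose curvature is the average-information matrix computed exactly from MME
solves; the score is evaluated by central finite differences of the exact
likelihood (machine-precision deterministic, so the 1e-6 relative
convergence tolerance is attainable). Rejected steps are halved; variances
are floored at 1e-8 with a boundary flag. The AI inverse at the optimum is
the sampling covariance used by the ratio-SE machinery. Identifiability
uses reference-level (corner) coding in file order; the cross-environment
residual covariance is structurally fixed at zero because no animal holds
records in both environments (the design builder freezes residual entries
for trait pairs with no co-observed unit).

Threshold (logit) fits: a short penalized quasi-likelihood phase (linear
mixed model on the working variate, working-scale residual fixed at 1.0)
provides starting values, then variance components are re-estimated by
maximizing the Laplace-approximate marginal likelihood with the fixed
effects integrated out. On an identical dataset this reproduces glmmTMB's
REML Laplace estimates to four decimals. Both approximations carry the
well-known downward bias for binary data with small cluster sizes
(~20-30% on the additive variance at prevalence ~0.4 with litters of 6);
liability heritability is nevertheless recovered within the stated +-0.04
band, and the bias is documented rather than corrected post hoc.

Wald F tests for fixed factors use the BLUE covariance from the MME with a
containment-style denominator df (observations minus fixed-effect rank);
backward stepwise elimination drops the largest-p factor until all retained
factors are significant.

## Scale conventions and reference parameters

For logit threshold traits the phenotypic variance convention is
`sigma2_a + sigma2_c + pi^2/3`; this reconstructs the reference
phenotypic-variance table to printed rounding and is used for every
liability-scale ratio. For weaning weight the phenotypic variance
decomposes as `sigma2_a + sigma2_c + sigma2_me + sigma2_m + sigma_a,m +
sigma2_e`; the reference components close this identity only with a
*negative* direct-maternal genetic covariance (−842 g², r = −0.71), which
also explains the uniformly unfavorable maternal weaning-weight responses
across schemes, so the package default uses the negative sign even though
the magnitude 0.71 is sometimes quoted positive.

The observed-scale (%) variance components of the composite disorder are
not fixed by the liability analysis; the default transfers the liability
ratios with the threshold-model factor `z^2 / (p(1-p))` and uses the
binomial phenotypic variance `p(1-p)·100^2`. Disease rows of the response
tables are therefore configuration-dependent; only their signs and
orderings are asserted.

## Selection-response predictor

Pseudo-BLUP is approximated as a selection index over family means: own
records, the full-sib mean (6 sibs), the half-sib mean (3 litters of 7),
with sib groups split between environments by fractional recording
intervals so overlapping group means get exact pair-count covariances, and
optional repeated dam litter-size records. Index weights are `b = P^-1 G
v`; responses are `i_bar cov(a, I)/sigma_I` averaged over the 15% male and
25% female selection paths (Burrows finite-candidate intensity correction,
~0.3% at 490 candidates per sex). Genetic covariances are iterated through
the Bulmer recursion `C' = G0/2 + (C - k g g'/sigma_I^2)/2` (path-averaged
k) to equilibrium, re-deriving the index each round.

Candidates are selected at 70 days and have no own litter-size record; the
default recording plan also attaches no dam record to the index, which
reproduces the reference production-scheme responses closely (litter-size
response −0.114 kits vs −0.118; direct weaning weight 34.56 g vs 34.99),
whereas adding a dam record pulls the correlated litter-size response
toward zero (−0.03). Dam records remain available through
`RecordingPlan(dam_records=n)`. Between-family covariance changes among
selected parents are not tracked (standard equilibrium approximation), and
inbreeding accumulation is not modelled.

The desired-gains weight search matches the *direction* of the predicted
response vector (responses are invariant to a common rescaling of index
weights), using damped ridge-guarded Gauss-Newton with finite-difference
sensitivities and a 2% default tolerance.

## Numerical choices and problem sizes

Parameter-recovery experiments run at the scale the analysis is designed
for: litter size at 35 sires × 140 dams × 5 parities (20 replicates) and
the threshold model at 300 sires / ~6,000 challenged kits (10 replicates),
with the remaining tests on smaller fixtures chosen to exercise the same
code paths quickly. Sampling-based SEs default to 10,000 draws in the API
and use fewer in tests where only consistency with the delta method is
checked. All randomness flows through explicit seeds; identical
configuration and seed give byte-identical simulation output and pipeline
manifests.

## Known limitations

- Laplace/PQL bias for binary traits (documented above); a fully Bayesian
  or adaptive-quadrature threshold fit is out of scope.
- The multi-trait REML path estimates covariances for traits observed on
  the same or related animals but has no specialized sampler for very
  large bivariate problems; study-scale bivariate disease fits are slow
  and are exercised at reduced size in the tests.
- The deterministic predictor assumes discrete generations, one-stage
  selection, equal information for both sexes, and multivariate normality
  of the index; observed-scale disease responses inherit the uncertainty
  of the observed-scale variance defaults.
- Genetic groups for unknown parents are not implemented; unknown parents
  are unrelated base animals.
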