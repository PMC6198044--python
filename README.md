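# cuniqg

Quantitative-genetic analysis of resistance to non-specific disease and
production traits in pedigreed rabbit populations reared in two contrasting
environments: a bio-secure selection nucleus (S) and challenging sib-testing
farms (Ch).

The package is aimed at breeding-program analysts who want to (i) estimate
variance components for binary disease traits and production traits with
pedigree-based mixed models, (ii) quantify genotype-by-environment
interaction as the cross-environment genetic correlation, and (iii) compare
breeding schemes by deterministic prediction of multi-trait selection
response. Because real breeding records of this kind are proprietary, a
synthetic-data generator reproduces the study design (two environments,
batch-wise allocation, cross-fostering, maternal and litter effects), so
every stage of the pipeline is testable end to end.

## Models

**Disease traits** (0/1 scored once per animal) are analyzed with a
threshold animal model with logit link: the latent liability is

    l = Xb + Z_a a + Z_c c + e,     a ~ N(0, A sigma2_a),
                                    c ~ N(0, I sigma2_c),

with `A` the pedigree numerator relationship matrix, `c` the common-litter
effect and a logistic residual, so the liability-scale phenotypic variance
is `sigma2_p = sigma2_a + sigma2_c + pi^2/3` and
`h2 = sigma2_a / sigma2_p`. Fits use penalized quasi-likelihood starting
values refined by a Laplace-approximate REML (validated against glmmTMB).

**Weaning weight** uses a linear animal model with direct and maternal
genetic effects (correlated via the pedigree), common litter and maternal
environmental effects; maternal and litter terms follow the *rearing* dam
for cross-fostered kits. **Litter size** (NBA) uses a repeatability animal
model on the doe with a permanent-environment effect. Variance components
are estimated by AI-REML on sparse Henderson mixed-model equations;
standard errors of ratios come from multivariate Gaussian sampling of the
components at the optimum (10,000 draws by default). Boundary hypotheses
(e.g. "is the cross-environment genetic correlation below 1?") use the
50:50 chi-square mixture likelihood-ratio test.

**Selection response** is predicted deterministically for truncation
selection on a pseudo-BLUP index (own record, full-sib and half-sib means
per environment, optional dam records), iterating genetic covariances to
the Bulmer equilibrium. Breeding objectives are linear in true breeding
values, e.g.

    H = 3 NBA + 0.15 WW_direct + 0.15 WW_maternal - 65 Resist_S - 65 Resist_Ch

with weights in EUR per trait unit (kits, g, %).

## Worked example

```python
from cuniqg import presets
from cuniqg.response import predict_response

params = presets.response_parameters()
objs = presets.standard_objectives()
scheme = presets.nucleus_scheme("HProduction")
pred = predict_response(scheme, params, objs["HProduction"])
for t, v in pred.responses.items():
    print(f"{t:12s} {v:8.3f}")
```

prints

```
NBA            -0.114
WW_direct      34.561
WW_maternal    -8.187
Resist_S       -1.722
Resist_Ch      -0.472
```

i.e. selecting on production alone is expected to gain ~34.6 g of direct
weaning weight per generation, lose a little litter size through the
negative NBA-growth correlation, erode the maternal weaning-weight
component, and still improve disease resistance slightly (negative = less
disease) through the favorable genetic correlations.

The same is available from the shell:

```bash
cuniqg respond --objective HResist_S_Ch --ch-records
cuniqg simulate --seed 42 --out sim/
cuniqg all --seed 1 --out run/
```

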