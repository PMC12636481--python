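# proteomediate

Proteome-wide mediation screening for CSF proteomics.

## The problem

Blood-derived proteins such as fibrinogen appear in cerebrospinal fluid when
the blood-brain barrier leaks, and their CSF levels track markers of synaptic
injury (pTau181, neurogranin, SNAP25, GAP43) in aging adults.  The question a
mediation screen answers is *which* of the thousands of proteins measured on
an aptamer array statistically carry that exposure-outcome relationship: for
each analyte M, is the exposure X associated with M (a-path), and does M
predict the outcome Y over and above X (b-path)?

`proteomediate` implements that screen end to end for sample x analyte
matrices (plain delimited tables or a caret-sectioned aptamer-array dialect),
together with the supporting stages a real study needs: Row/ColCheck QC
filtering and log transforms, technical-replicate CV summaries, Little's MCAR
test and chained-equations multiple imputation, PCA composite scores, signed
weighted co-expression modules with cross-cohort preservation, cross-platform
concordance and surrogate-marker selection with an abundance-matched
bootstrap sensitivity analysis, and one-vs-rest cell-type enrichment from a
cell x gene count matrix.  Because cohort-scale CSF proteomics is rarely
public, the package ships a synthetic-cohort generator with planted ground
truth so every stage can be scored against known answers.

## The model

For one (exposure X, mediator M, outcome Y) triple with covariates C
(age, sex):

    M = a·X + γᵀC + ε          (a-path)
    Y = b·M + c′·X + δᵀC + ε   (b-path and direct effect)
    Y = c·X + θᵀC + ε          (total effect)

The indirect effect is the product of coefficients a·b, and the same-sample
OLS identity c = c′ + a·b holds exactly.  Inference on a·b uses
nonparametric case resampling with bias-corrected and accelerated (BCa)
intervals; E-values (via RR ≈ exp(0.91·|β|)) quantify how strong unmeasured
confounding would have to be to explain the effect away.  The proteome-wide
screen tests every non-exposure analyte against each outcome marker,
BH-FDR-corrects the a- and b-path p-values within a screen, and passes an
analyte only if both q-values clear the FDR level, the BCa interval of a·b
excludes zero, and the bootstrap sign is consistent; candidates must pass
every outcome with one consistent sign, then validate against a PC1
composite of the outcome panel and replicate across independent cohorts.

## Worked example

```python
import numpy as np, pandas as pd
from proteomediate import MediationModel

rng = np.random.default_rng(0)
n = 120
age = rng.normal(70, 8, n)
sex = rng.integers(0, 2, n)
fib = 0.3 * (age - 70) / 8 + rng.standard_normal(n)
med = 0.5 * fib + 0.3 * (age - 70) / 8 + rng.standard_normal(n)
ptau = 0.5 * med + 0.2 * fib + rng.standard_normal(n)
data = pd.DataFrame({"fibrinogen": fib, "SMOC1": med, "pTau181": ptau,
                     "age": age, "sex": sex})

model = MediationModel.from_dataframe(
    data, outcome="pTau181", exposure="fibrinogen", mediator="SMOC1",
    covariates=("age", "sex"))
print(model.fit(n_boot=1000, seed=1).summary())
```

prints

```
Mediation (product of coefficients, BCa bootstrap)
======================================================
path            coef        se
a             0.3578    0.0748
b             0.3824    0.0955
c_prime       0.3373    0.0841
c_total       0.4741    0.0817
------------------------------------------------------
indirect (a*b)    0.1368
95% BCa CI      [ 0.0592,  0.2421]
bootstrap p      0.002   (B=1000)
E-value          1.520 (CI bound 1.297)
n                120
```

The paths are on the standardized (z) scale: one SD of fibrinogen predicts
0.36 SD of the mediator, which predicts 0.38 SD of pTau181 given fibrinogen,
so 0.137 SD of the total 0.474 SD association flows through the mediator.
The BCa interval excludes zero; an unmeasured confounder would need risk
ratios of ~1.5 with both exposure and outcome to nullify the point estimate.

The full study design runs from a config, either in Python
(`proteomediate.pipeline.run_discovery` / `run_validation`) or on the
command line:

```sh
proteomediate discover --seed 7 --out runs/discovery
proteomediate validate --config cfg.yaml --candidates runs/discovery/mediator_sets.json \
    --out runs/validation
```

`discover` simulates a cohort, runs QC, imputation, the four-marker
mediation screen, and composite validation, and reports the candidate and
validated mediator sets next to the planted truth.

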