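# esm-mtx

Differential expression analysis for **metatranscriptomic (MTX) abundance
data** using an exponential scale mixture (Lomax) model with metagenomic
(MGX) adjustment, Bayesian spike-and-slab testing and FDR control.

## The problem

Community RNA sequencing pipelines such as HUMAnN report length- and
depth-normalized abundances (CPM), not raw counts, so count-based RNA-seq
models do not apply. Gaussian models on log-transformed abundances need a
pseudocount to handle the overwhelming zeros of MTX data (median zero
fraction above 99% in real cohorts), and both their residual distributions
and their inference change with that arbitrary choice. This package is for
microbiome researchers who want per-gene differential expression calls with
respect to a binary phenotype (e.g. dysbiosis) that respect the actual
shape of MTX data: a spike of zeros, a decreasing density near zero, and
heavy tails.

## The model

For one gene family, each retained (sample *i*, taxon *j*) pair carries an
RNA abundance *y<sub>ij</sub>* and a DNA abundance *D<sub>ij</sub>* > 0.
The sampling distribution is a scale mixture of exponentials:

```
y_ij | U_ij ~ Exp(mu_ij * U_ij)          (Exp parameterized by its mean)
log mu_ij   = alpha*log D_ij + beta*s_i + gamma'X_i + eta_g(i)
U_ij        ~ rho*IG(theta1+1, theta1) + (1-rho)*IG(theta2+1, theta2)
```

Marginally over `U`, `y` follows a two-component **Lomax** (Pareto II)
mixture with mean `mu_ij`; each regression coefficient is a log fold change
of the mean. `theta` is a precision: small values concentrate mass at zero
while fattening the tail (tail index `theta+1`), which is exactly the MTX
regime; the second, near-degenerate component absorbs excess zeros.
Observed zeros are treated as left-censored below a threshold `C` (the
minimum detectable CPM). `s_i` is the binary DE variable; `beta` carries a
spike-and-slab prior whose inclusion indicator gives a **posterior
inclusion probability (PIP)** per gene. Genes are ranked by 1 − PIP and the
list truncated so the expected false-discovery proportion stays below a
target α. Inference is a Gibbs sampler with slice-sampling data
augmentation, run independently (and thus parallelizably) per gene.

A Gaussian mixed-model baseline (`log(y+pc) ~ log(D+pc) + s + covariates +
(1|subject)`, Benjamini–Hochberg correction) is included for comparison
and for demonstrating pseudocount sensitivity.

## Worked example

```python
import numpy as np
from esmmtx import ESMModel, PriorConfig, GenerativeSpec, generate_esm_gene

spec = GenerativeSpec(n_samples=300, n_subjects=75, taxa_per_sample=3,
                      alpha=1.0, beta=np.log(10), seed=7)
data, truth = generate_esm_gene(spec)
res = ESMModel(data, PriorConfig(C=spec.C, n_iter=2000, n_burn=800, seed=3)).fit()
print(res.summary())
```

```
Exponential scale mixture model
gene: synthetic   obs: 900 (122 censored)   subjects: 75   draws: 600
PIP (DE inclusion probability): 1.0000
beta | included: 2.3499  95% CI (2.118212715879963, 2.579572708820126)

parameter                   mean        sd      2.5%     97.5%
alpha (log MGX)           0.9908    0.0346    0.9227    1.0505
beta (DE, marginal)       2.3499    0.1204    2.1182    2.5796
gamma0 (intercept)       -0.2124    0.1689   -0.4852    0.1909
gamma[age]                0.0124    0.0034    0.0057    0.0198
gamma[antibiotic]        -0.5717    0.2499   -1.0377   -0.0822
theta1                    0.7427    0.1408    0.4881    1.0325
theta2                    0.0281    0.0071    0.0170    0.0498
rho                       0.6917    0.0467    0.5900    0.7815
MH acceptance (theta1, theta2): 0.34, 0.37
```

The gene was simulated with a 10× expression signal in group `s=1`
(true log fold change log 10 ≈ 2.303) and a unit MGX elasticity
(`alpha = 1`). The fitted PIP of 1.0 declares the gene differentially
expressed; the posterior mean of `beta` conditional on inclusion, 2.35,
recovers the signal within its credible interval, and `alpha` ≈ 0.99
recovers the DNA adjustment.

For file-based runs there is a thin CLI:

```bash
esm-mtx simulate --genes 100 --samples 200 --signal 10 --seed 1 --out sim/
esm-mtx fit --mtx sim/mtx.tsv --mgx sim/mgx.tsv --meta sim/metadata.tsv \
            --s-table sim/s_assignments.tsv --out run/
esm-mtx call --summaries run/genes --fdr 0.05 --out calls.tsv
esm-mtx evaluate --results calls.tsv --truth sim/truth.tsv --out calibration.tsv
```

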