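# asehmm

Hidden-Markov genotype and allele-specific-expression (ASE) calling from
RNA-seq allele counts, exploiting linkage disequilibrium.

## The problem

Calling coding-SNP (cSNP) genotypes directly from RNA-seq read counts is
hard when allelic imbalance is present: a heterozygote expressing one allele
much more than the other looks like a homozygote, especially at low
coverage, so single-site callers miss exactly the heterozygotes one needs
for ASE testing.  `asehmm` addresses this by modelling a *block* of closely
linked cSNPs jointly: the hidden genotype/ASE state of consecutive SNPs
forms a Markov chain, so linkage disequilibrium lets well-covered sites
rescue ambiguous or even zero-coverage neighbours, while the emission model
explicitly allows allelic imbalance and read-mapping error.

It is intended for statistical geneticists calling cSNP genotypes (and
screening for ASE) in outbred populations from low-coverage RNA-seq, after
SNP positions have been ascertained by standard upstream tools.

## The model

For individual *i* and SNP *l*, the observed base counts
**X**_il = (X_A, X_C, X_G, X_T) with total n_il are multinomial given the
ASE ratio δ_il (the probability a read carries allele A) and mapping-error
rate *e*:

    X_il | δ_il ~ Multinomial(n_il, p(δ_il, e)),
    p(δ, e) = ((1 − 4e/3) δ + e/3,  e/3,  e/3,  (4e/3 − 1) δ + 1 − e).

The hidden state G_il couples genotype and ASE status; in the five-state
ASE-aware variant

| k | state       | δ_il \| G_il = k                 |
|---|-------------|----------------------------------|
| 1 | AA          | point mass at 1                  |
| 2 | AT, no ASE  | point mass at 0.5                |
| 3 | AT, A-biased| rescaled Beta(α₁, β₁) on (0.5, 1)|
| 4 | AT, T-biased| rescaled Beta(α₂, β₂) on (0, 0.5)|
| 5 | TT          | point mass at 0                  |

and {G_il : l = 1..L} is a homogeneous Markov chain with transition matrix
A = (a_kk′) and initial distribution π shared across individuals.  The
three-state variant (states 1, 2, 5) ignores ASE.  Parameters are estimated
by EM (scaled forward–backward recursions; closed-form chain updates;
bounded numerical update of *e*), the marginal emission of the beta states
is computed by Gauss–Legendre quadrature, and genotypes are called from the
marginal posteriors P(G_il = k | X).  Posterior-mean ASE ratios
E[δ_il | X] are reported for downstream ASE testing.  See
`docs/methods.md` for estimation details and design choices.

## Worked example

```python
from asehmm import (SimulationScenario, simulate_dataset, make_state_space,
                    em_fit, call_genotypes, score_calls)

scenario = SimulationScenario(n=24, L=10, lambda_=8, ld=0.5, seed=1)
data = simulate_dataset(scenario)          # LD-linked genotypes, NB coverage
space = make_state_space("ASE")
fit = em_fit(data.counts, space)           # EM over the 24 chains
calls = call_genotypes(fit.posterior, data.counts, space, theta=fit.theta_hat)
report = score_calls(calls, data.true_genotypes)
print(report.efdr, report.efnr, report.sensitivity)
```

Running `python examples/01_simulate_fit_call.py` (the same computation)
prints:

```
simulated 24 individuals x 10 SNPs, mean coverage 11.9 reads/site
EM converged after 76 iterations, log-likelihood -465.59, estimated mapping error e = 0.0104
EFDR = 0.0490 (homozygotes wrongly called heterozygous)
EFNR = 0.0217 (heterozygotes wrongly called homozygous)
sensitivity = 0.970 (fraction of true heterozygotes recovered)
```

At a mean of only ~12 reads per site, 97% of heterozygotes are recovered —
the chain shares information across the linked SNPs — while about 5% of
called heterozygotes are false discoveries and about 2% of called
homozygotes hide a heterozygote.  The estimated mapping-error rate (0.0104)
recovers the generating value (0.01).  The other scripts in `examples/`
show ASE-ratio prediction, variant benchmarking, and count-table/block
workflows.

A thin CLI mirrors the library: `asehmm simulate`, `asehmm fit`,
`asehmm call`, `asehmm evaluate` (see `asehmm --help`).

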