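"""Predict allele-specific expression ratios at heterozygous sites.

The five-state model attaches to every site a posterior-mean ASE ratio
E[delta | reads] — the probability that a read carries the reference
allele — mixing the point ratios of the homozygous/balanced states with
posterior moments of the rescaled-beta ASE states.  Ratios near 0.5 mean
balanced expression; ratios near 1 (or 0) mean the reference (alternative)
allele dominates.
"""

import numpy as np

from asehmm import (
    SimulationScenario,
    call_genotypes,
    em_fit,
    make_state_space,
    simulate_dataset,
)
from asehmm.core_model import HET

scenario = SimulationScenario(n=12, L=10, lambda_=24, ld=0.8, seed=4)
data = simulate_dataset(scenario)
space = make_state_space("ASE")
fit = em_fit(data.counts, space)
calls = call_genotypes(fit.posterior, data.counts, space, theta=fit.theta_hat)

het = calls.calls == HET
true_delta = data.true_delta[het]
pred_delta = calls.ase_ratio_hat[het]
err = np.abs(pred_delta - true_delta)
print(f"{het.sum()} heterozygous calls")
print(f"mean |predicted - generating| ASE ratio: {err.mean():.3f}")
corr = np.corrcoef(pred_delta, true_delta)[0, 1]
print(f"correlation with the generating ratios: {corr:.3f}")
print("\nfive example heterozygous sites (ref reads, alt reads, "
      "true delta, predicted delta):")
idx = np.argwhere(het)[:5]
for i, l in idx:
    c = data.counts.counts[i, l]
    print(f"  {c[0]:3d} {c[3]:3d}   {data.true_delta[i, l]:.3f}   "
          f"{calls.ase_ratio_hat[i, l]:.3f}")
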