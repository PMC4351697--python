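"""Work with count-table files and SNP-block segmentation.

Writes a simulated dataset as a TSV count table, reads it back, segments
its SNPs into blocks of closely linked sites (at most 25 SNPs spanning at
most 2 kb) and fits the three-state model per block — the workflow used on
real data, where distant SNPs share too little disequilibrium to help each
other.
"""

import tempfile
from pathlib import Path

from asehmm import (
    SimulationScenario,
    em_fit,
    make_state_space,
    read_count_table,
    simulate_dataset,
    segment_blocks,
    write_count_table,
)
from asehmm.io import BlockSpec

scenario = SimulationScenario(n=6, L=40, lambda_=16, ld=0.8, seed=9,
                              position_spacing=150)
data = simulate_dataset(scenario)

with tempfile.TemporaryDirectory() as d:
    path = Path(d) / "counts.tsv"
    write_count_table(data.counts, path)
    acm = read_count_table(path)
    print(f"round-tripped {acm.n_individuals} individuals x {acm.n_snps} SNPs "
          f"through {path.name}")

blocks = segment_blocks(acm.positions, BlockSpec(max_snps=25, max_span=2000),
                        chroms=acm.chroms)
print(f"segmented into {len(blocks)} blocks of sizes "
      f"{[len(b) for b in blocks]}")

space = make_state_space("NASE")
for b, idx in enumerate(blocks):
    fit = em_fit(acm.subset_snps(idx), space)
    print(f"block {b}: {len(idx)} SNPs, {fit.n_iter} EM iterations, "
          f"log-likelihood {fit.posterior.loglik:.1f}, "
          f"e_hat {fit.theta_hat.e:.4f}")
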