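"""Detect positive selection on synthetic binding sites.

Builds a small three-species study with known selective regimes, runs the
deltaSVM selection test per site, and summarizes the proportion of positive
sites per category.  Directionally selected sites (categories gain/loss)
should be called positive far more often than conserved (neutral or
stabilizing) ones.
"""

import numpy as np

from bindsel import NullModel, SimulationConfig, simulate_sites, summarize_positive, test_sites

config = SimulationConfig(
    seed=1,
    k=8,
    site_length=120,
    n_sites={"neutral": 60, "directional_up": 30, "directional_down": 30, "stabilizing": 20},
)
triples, truth, table = simulate_sites(config)
results = test_sites(triples, table, NullModel(n_permutations=2000, seed=2))

n_tested = sum(r.tested for r in results)
print(f"tested {n_tested}/{len(results)} sites (>=2 substitutions required)")

# proportion of tested sites with p < 0.01, per peak category
for group, prop in summarize_positive(results, alpha_threshold=0.01).items():
    print(f"  {group:10s} proportion positive: {prop:.3f}")

regime = dict(zip(truth["site_id"], truth["regime"]))
for reg in ("directional_up", "neutral"):
    ps = [r.p_value for r in results if r.tested and regime[r.site_id] == reg]
    print(f"median p for {reg}: {np.median(ps):.4f}")
# directional sites accumulate consistent-direction affinity changes that a
# same-count random-mutagenesis null almost never reproduces, hence tiny p.
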