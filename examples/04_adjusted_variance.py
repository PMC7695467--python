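"""Mean-adjusted expression variance of binding-site target genes.

Expression variance depends strongly on the mean, so raw variances mislead.
The adjustment fits log(variance) as a polynomial in the (log-scale) mean,
choosing the degree by nested-model ANOVA, and divides each gene's variance
by the value the curve predicts.  Genes whose regulation is under recent
positive selection are expected to show *lower* adjusted variance.
"""

import numpy as np
from scipy import stats

from bindsel import SimulationConfig, adjusted_variance, compare_target_variance
from bindsel.simulate import simulate_expression

config = SimulationConfig(seed=3)
rng = np.random.default_rng(3)
# 800 genes; the first 200 get 0.4x residual variance (selected-site targets)
multipliers = np.array([0.4] * 200 + [1.0] * 600)
expr, _ = simulate_expression(800, config, rng, multipliers=multipliers)

adj, model = adjusted_variance(expr)
print(f"selected polynomial degree: {model.degree}")
rho = stats.spearmanr(expr.mean(axis=1), adj).statistic
print(f"Spearman rho(mean, adjusted variance): {rho:+.3f}  (mean dependence removed)")

labels = {f"site{i}": ("PBS" if i < 200 else "non-PBS") for i in range(800)}
targets = {f"site{i}": expr.index[i] for i in range(800)}
pbs, non, p = compare_target_variance(adj.to_dict(), labels, targets)
print(
    f"median adjusted variance: PBS targets {np.median(pbs):.3f}, "
    f"non-PBS {np.median(non):.3f} (Wilcoxon p = {p:.3g})"
)
# the planted 0.4x variance reduction in PBS targets is recovered.
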