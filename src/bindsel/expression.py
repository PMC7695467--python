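"""Target-gene assignment and mean-adjusted expression variance.

Gene expression variance across individuals depends strongly on the mean, so
raw variances of binding-site target genes cannot be compared directly.  The
adjustment fits a polynomial predicting log variance from log mean across
all genes, increasing the degree until an extra degree yields no significant
improvement (nested-model ANOVA F-test, p < 0.05), and reports each gene's
observed variance divided by the variance its mean predicts.  After the
adjustment, variance is uncorrelated with the mean and a rank test between
PBS-target and non-PBS-target genes is meaningful.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .ancestral import GenomicInterval


@dataclass(frozen=True)
class Tss:
    chrom: str
    pos: int
    gene_id: str


def nearest_gene(
    sites: Mapping[str, GenomicInterval], genes: Sequence[Tss]
) -> dict[str, str]:
    """Putative target gene per site: the gene whose TSS is closest.

    Distance is 0 when the TSS lies inside the site interval; equidistant
    ties break to the lexicographically smallest gene id.  Genes on other
    chromosomes are never assigned.
    """
    if not genes:
        raise ValueError("empty gene list")
    by_chrom: dict[str, list[Tss]] = {}
    for g in genes:
        by_chrom.setdefault(g.chrom, []).append(g)
    sorted_pos: dict[str, np.ndarray] = {}
    for chrom, gs in by_chrom.items():
        gs.sort(key=lambda g: (g.pos, g.gene_id))
        sorted_pos[chrom] = np.array([g.pos for g in gs])

    def distance(tss: Tss, iv: GenomicInterval) -> int:
        if iv.start <= tss.pos < iv.end:
            return 0
        return min(abs(tss.pos - iv.start), abs(tss.pos - (iv.end - 1)))

    targets: dict[str, str] = {}
    for site_id, iv in sites.items():
        gs = by_chrom.get(iv.chrom)
        if not gs:
            continue
        pos = sorted_pos[iv.chrom]
        # candidates around both interval edges; ties need every equidistant gene
        idxs = set()
        for edge in (iv.start, iv.end - 1):
            j = int(np.searchsorted(pos, edge))
            idxs.update(i for i in (j - 1, j, j + 1) if 0 <= i < len(gs))
        # expand to all genes at the winning distance for deterministic ties
        best_d = min(distance(gs[i], iv) for i in idxs)
        winners = [g.gene_id for g in gs if distance(g, iv) == best_d]
        targets[site_id] = min(winners)
    return targets


@dataclass
class MeanVarModel:
    """Polynomial log(var) ~ mean fit (log-scale data) with ANOVA-chosen degree.

    The expression matrix is log-transformed upstream, so the per-gene mean
    is already a log-scale quantity; the polynomial acts on it directly.
    Because polynomials are closed under an additive shift of the predictor,
    rescaling all expression values by a constant in linear space (a constant
    shift in log space) leaves the predicted variances — and hence the
    adjusted variances — exactly unchanged.
    """

    degree: int
    coefficients: np.ndarray  # numpy polyfit convention: highest degree first
    improvement_p: dict[int, float] = field(default_factory=dict)
    hit_max_degree: bool = False

    def predict_log_var(self, mean: np.ndarray) -> np.ndarray:
        return np.polyval(self.coefficients, mean)


def fit_mean_variance(
    means: np.ndarray,
    variances: np.ndarray,
    max_degree: int = 8,
    alpha: float = 0.05,
) -> MeanVarModel:
    """Fit log(var) as a polynomial in the (log-scale) mean, choosing the degree.

    Starting at degree 1, the degree is increased while the nested-model
    F-test for degree d+1 over d is significant (p < alpha); the first
    non-significant extension stops the search.  Variances must be strictly
    positive (the response is their log).
    """
    means = np.asarray(means, dtype=float)
    variances = np.asarray(variances, dtype=float)
    bad = np.flatnonzero(variances <= 0)
    if bad.size:
        raise ValueError(f"non-positive variance at indices {bad[:10].tolist()}")
    x = means
    y = np.log(variances)
    n = x.size

    def rss(deg: int) -> tuple[float, np.ndarray]:
        coef = np.polyfit(x, y, deg)
        resid = y - np.polyval(coef, x)
        return float(resid @ resid), coef

    if n < 4:
        raise ValueError("need at least degree+2 genes to fit")
    degree = 1
    rss_d, coef_d = rss(degree)
    tss = float(((y - y.mean()) ** 2).sum())
    improvement_p: dict[int, float] = {}
    hit_max = False
    while True:
        if degree + 1 > max_degree or n < degree + 3:
            hit_max = degree + 1 > max_degree
            break
        rss_d1, coef_d1 = rss(degree + 1)
        df_resid = n - (degree + 2)
        improvement = rss_d - rss_d1
        if rss_d <= 1e-10 * max(tss, 1e-300) or improvement <= 0:
            p = 1.0  # current fit is numerically exact or not improved
        elif rss_d1 <= 0 or df_resid <= 0:
            p = 0.0
        else:
            f = improvement / (rss_d1 / df_resid)
            p = float(stats.f.sf(f, 1, df_resid))
        improvement_p[degree + 1] = p
        if p >= alpha:
            break
        degree, rss_d, coef_d = degree + 1, rss_d1, coef_d1
    return MeanVarModel(
        degree=degree, coefficients=coef_d, improvement_p=improvement_p, hit_max_degree=hit_max
    )


def adjusted_variance(
    expr: pd.DataFrame, model: Optional[MeanVarModel] = None
) -> tuple[pd.Series, MeanVarModel]:
    """Observed variance over mean-predicted variance, per gene.

    ``expr`` is genes x samples, already log-transformed (log2 upstream).
    Zero-variance genes get adjusted variance 0 and are excluded from the fit.
    Returns the per-gene adjusted variance and the fitted model.
    """
    if expr.shape[1] < 3:
        raise ValueError("need at least 3 samples")
    means = expr.mean(axis=1)
    variances = expr.var(axis=1, ddof=1)
    usable = variances > 0
    if model is None:
        model = fit_mean_variance(means[usable].to_numpy(), variances[usable].to_numpy())
    adj = pd.Series(0.0, index=expr.index)
    predicted = np.exp(model.predict_log_var(means[usable].to_numpy()))
    adj[usable] = variances[usable].to_numpy() / predicted
    return adj, model


def compare_target_variance(
    adjvar: Mapping[str, float],
    site_labels: Mapping[str, str],
    targets: Mapping[str, str],
) -> tuple[np.ndarray, np.ndarray, float]:
    """Wilcoxon rank-sum on adjusted variances of PBS vs non-PBS target genes.

    Each gene enters once per group even when several sites target it; a gene
    targeted by both a PBS and a non-PBS site counts as a PBS target.
    Returns (pbs_values, non_pbs_values, two-sided p).
    """
    pbs_genes: set[str] = set()
    non_genes: set[str] = set()
    for site_id, label in site_labels.items():
        gene = targets.get(site_id)
        if gene is None or gene not in adjvar:
            continue
        (pbs_genes if label == "PBS" else non_genes).add(gene)
    non_genes -= pbs_genes  # PBS membership wins
    if not pbs_genes or not non_genes:
        raise ValueError("both PBS and non-PBS target-gene groups must be non-empty")
    a = np.array([adjvar[g] for g in sorted(pbs_genes)])
    b = np.array([adjvar[g] for g in sorted(non_genes)])
    _, p = stats.mannwhitneyu(a, b, alternative="two-sided")
    return a, b, float(p)
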