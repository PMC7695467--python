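"""Synthetic study generator with known ground truth.

Generates everything the pipeline consumes — a k-mer weight table derived
from a planted position-weight-matrix motif, aligned three-species site
triples evolved under explicit selective regimes, ChIP-seq-like peak
intervals, SNPs, and an expression matrix with a planted mean-variance law —
so the whole method can be exercised and validated without any external
download.

Regimes operationalize the selection hypotheses:

* ``neutral``          — focal substitutions drawn exactly by the null
                         process (uniform alternative base, distinct
                         positions); the calibration standard.
* ``directional_up``   — hill-climbing: random proposals accepted only when
                         they raise the affinity score by at least a minimum
                         effect (adaptive gain of binding — selection fixes
                         consequential changes, not near-neutral wobble);
                         ``directional_down`` mirrors it.
* ``stabilizing``      — proposals accepted only while the score stays
                         within a tolerance of the ancestral score.

Sister and outgroup branches always evolve neutrally, at per-bp divergences
echoing the human-chimpanzee range (~1-2%).  SNPs are planted at a lower
density in directionally selected sites than in neutral ones (a selective
sweep removes polymorphism), and expression of selected-site target genes
gets a reduced residual variance around the planted mean-variance law.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd

from .ancestral import AlignedSiteTriple, GenomicInterval
from .weights import BASES, KmerWeightTable, score_sequence

REGIMES = ("neutral", "directional_up", "directional_down", "stabilizing")


def _default_motif() -> np.ndarray:
    """Strong 8-bp motif (CEBP-like consensus TTGCGCAA).

    Column probabilities are heterogeneous, as in real position weight
    matrices: consensus-base probability varies by position and the residual
    mass is split unevenly.  Heterogeneity matters — a motif with identical
    columns makes every k-mer weight sit on a one-dimensional lattice, and
    the resulting massive deltaSVM ties are an artifact that trained SVM
    weight tables (continuous-valued) do not show.
    """
    consensus = "TTGCGCAA"
    p_cons = [0.95, 0.90, 0.86, 0.92, 0.88, 0.93, 0.87, 0.91]
    splits = ([0.5, 0.3, 0.2], [0.45, 0.35, 0.2], [0.55, 0.25, 0.2], [0.4, 0.35, 0.25])
    motif = np.zeros((len(consensus), 4))
    for i, b in enumerate(consensus):
        ib = BASES.index(b)
        motif[i, ib] = p_cons[i]
        rest = [j for j in range(4) if j != ib]
        for j, frac in zip(rest, splits[i % len(splits)]):
            motif[i, j] = (1.0 - p_cons[i]) * frac
    return motif


@dataclass
class SimulationConfig:
    """Study conditions for the synthetic bundle.

    Defaults mirror the scale of the real analyses where a desk-scale
    equivalent exists: k=10 weight tables, ~200 bp sites, sister/outgroup
    divergence of 1%/2% per bp, and 2-6 focal substitutions per site (at
    least 4 on directionally selected sites).
    """

    seed: int = 0
    k: int = 10
    site_length: int = 200
    motif: np.ndarray = field(default_factory=_default_motif)
    background: np.ndarray = field(default_factory=lambda: np.full(4, 0.25))
    n_sites: dict[str, int] = field(
        default_factory=lambda: {
            "neutral": 500,
            "directional_up": 150,
            "directional_down": 150,
            "stabilizing": 100,
        }
    )
    n_subs_neutral: tuple[int, int] = (2, 6)
    n_subs_selected: tuple[int, int] = (4, 6)
    n_subs_stabilizing: tuple[int, int] = (2, 5)
    divergence_internal: float = 0.005
    divergence_sister: float = 0.01
    divergence_outgroup: float = 0.02
    stabilizing_tolerance: float = 1.0
    # smallest score change an accepted directional substitution may have, in
    # log-odds units (~ one strong motif-position change); keeps the regime
    # clear of the near-neutral fluctuation range
    directional_min_effect: float = 2.0
    proposal_cap: int = 20_000
    snp_rate_neutral: float = 0.02  # per bp in neutral/stabilizing sites
    snp_rate_selected: float = 0.005  # sweep-depleted polymorphism
    n_expression_samples: int = 175  # matches a liver expression panel of 175 donors
    n_background_genes: int = 500
    # ln(var) = c2*mean^2 + c1*mean + c0, mean on the log2 expression scale
    meanvar_coeffs: tuple[float, float, float] = (-0.06, 0.8, -3.0)
    meanvar_residual_sd: float = 0.1
    selected_target_var_multiplier: float = 0.4

    def __post_init__(self) -> None:
        if self.motif.shape[0] > self.site_length:
            raise ValueError("motif longer than site")
        if not np.allclose(self.motif.sum(axis=1), 1.0):
            raise ValueError("motif columns must sum to 1")


def make_pwm_weight_table(
    motif: np.ndarray, k: int, background: Optional[np.ndarray] = None
) -> KmerWeightTable:
    """Weight table: each k-mer scores its best motif alignment in log-odds.

    weight(kmer) = max over offsets of sum_t log(motif[t, base] / background),
    a deterministic stand-in with the same shape as a trained SVM's k-mer
    weight list.
    """
    if k < 1:
        raise ValueError("k must be >= 1")
    m = motif.shape[0]
    if m > k:
        raise ValueError(f"motif length {m} exceeds k={k}")
    if background is None:
        background = np.full(4, 0.25)
    logodds = np.log(motif / background[None, :])
    n = 4**k
    codes = np.arange(n, dtype=np.int64)
    digits = np.empty((n, k), dtype=np.int8)
    for j in range(k):
        digits[:, k - 1 - j] = (codes >> (2 * j)) & 3
    best = np.full(n, -np.inf)
    for off in range(k - m + 1):
        s = np.zeros(n)
        for t in range(m):
            s += logodds[t, digits[:, off + t]]
        np.maximum(best, s, out=best)
    return KmerWeightTable(
        k=k, values=best, present=np.ones(n, dtype=bool), source="planted PWM log-odds"
    )


# ---------------------------------------------------------------------------
# sequence evolution
# ---------------------------------------------------------------------------


def random_root(config: SimulationConfig, rng: np.random.Generator) -> str:
    """Background sequence with one PWM-sampled motif instance at the center."""
    seq = rng.choice(list(BASES), size=config.site_length, p=config.background).tolist()
    m = config.motif.shape[0]
    start = (config.site_length - m) // 2
    for t in range(m):
        seq[start + t] = BASES[rng.choice(4, p=config.motif[t])]
    return "".join(seq)


def mutate_neutral(seq: str, rate: float, rng: np.random.Generator) -> str:
    """Independent per-position substitution at the given rate, uniform base."""
    out = list(seq)
    hits = np.flatnonzero(rng.random(len(seq)) < rate)
    for p in hits:
        alts = [b for b in BASES if b != out[p]]
        out[p] = alts[rng.integers(3)]
    return "".join(out)


class RegenerationNeeded(RuntimeError):
    """Raised when a selective regime cannot place enough accepted substitutions."""


def _evolve_focal(
    ancestor: str,
    n_subs: int,
    regime: str,
    config: SimulationConfig,
    table: KmerWeightTable,
    rng: np.random.Generator,
) -> str:
    seq = list(ancestor)
    if regime == "neutral":
        pos = rng.choice(len(seq), size=n_subs, replace=False)
        for p in pos:
            alts = [b for b in BASES if b != seq[p]]
            seq[p] = alts[rng.integers(3)]
        return "".join(seq)

    from .weights import delta_svm  # incremental: proposals touch <= k windows

    anchor = score_sequence(ancestor, table)
    drift = 0.0  # current score minus anchor
    used: set[int] = set()
    accepted = 0
    proposals = 0
    current_seq = ancestor
    while accepted < n_subs:
        proposals += 1
        if proposals > config.proposal_cap:
            raise RegenerationNeeded(f"{regime}: proposal cap reached at {accepted}/{n_subs}")
        p = int(rng.integers(len(seq)))
        if p in used:
            continue
        alts = [b for b in BASES if b != seq[p]]
        b = alts[rng.integers(3)]
        proposed = current_seq[:p] + b + current_seq[p + 1 :]
        dd = delta_svm(current_seq, proposed, table)
        if regime == "directional_up":
            ok = dd >= config.directional_min_effect
        elif regime == "directional_down":
            ok = dd <= -config.directional_min_effect
        elif regime == "stabilizing":
            ok = abs(drift + dd) < config.stabilizing_tolerance
        else:
            raise ValueError(f"unknown regime {regime!r}")
        if ok:
            used.add(p)
            seq[p] = b
            current_seq = proposed
            drift += dd
            accepted += 1
    return "".join(seq)


def evolve_triple(
    root: str,
    config: SimulationConfig,
    regime: str,
    table: KmerWeightTable,
    rng: np.random.Generator,
    site_id: str = "site",
    interval: Optional[GenomicInterval] = None,
) -> tuple[AlignedSiteTriple, dict]:
    """Evolve one aligned triple on ((focal, sister), outgroup).

    The outgroup diverges from the root; sister and focal diverge from an
    internal ancestor that itself drifted from the root.  The focal branch
    additionally accumulates ``n_subs`` regime-controlled substitutions.
    Substitution-only: the alignment carries no gaps.
    """
    lo, hi = {
        "neutral": config.n_subs_neutral,
        "directional_up": config.n_subs_selected,
        "directional_down": config.n_subs_selected,
        "stabilizing": config.n_subs_stabilizing,
    }[regime]
    n_subs = int(rng.integers(lo, hi + 1))
    outgroup = mutate_neutral(root, config.divergence_outgroup, rng)
    internal = mutate_neutral(root, config.divergence_internal, rng)
    sister = mutate_neutral(internal, config.divergence_sister, rng)
    focal = _evolve_focal(internal, n_subs, regime, config, table, rng)
    category = {"directional_down": "loss", "directional_up": "gain"}.get(regime, "conserved")
    triple = AlignedSiteTriple(
        site_id=site_id,
        focal=focal,
        sister=sister,
        outgroup=outgroup,
        interval=interval,
        category=category,
    )
    truth = {
        "site_id": site_id,
        "regime": regime,
        "n_subs_planted": n_subs,
        "true_delta": score_sequence(focal, table) - score_sequence(internal, table),
    }
    return triple, truth


def simulate_sites(
    config: SimulationConfig,
    table: Optional[KmerWeightTable] = None,
    rng: Optional[np.random.Generator] = None,
    chrom: str = "chr1",
    spacing: int = 100,
) -> tuple[list[AlignedSiteTriple], pd.DataFrame, KmerWeightTable]:
    """All site triples of the study, laid out on one synthetic chromosome."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if table is None:
        table = make_pwm_weight_table(config.motif, config.k, config.background)
    triples: list[AlignedSiteTriple] = []
    truth_rows: list[dict] = []
    idx = 0
    n_regenerated = 0
    for regime in REGIMES:
        for _ in range(config.n_sites.get(regime, 0)):
            site_id = f"site{idx:05d}"
            start = 1000 + idx * (config.site_length + spacing)
            interval = GenomicInterval(chrom, start, start + config.site_length)
            while True:
                root = random_root(config, rng)
                try:
                    triple, truth = evolve_triple(
                        root, config, regime, table, rng, site_id=site_id, interval=interval
                    )
                    break
                except RegenerationNeeded:
                    n_regenerated += 1
            truth["start"] = interval.start
            truth["end"] = interval.end
            truth_rows.append(truth)
            triples.append(triple)
            idx += 1
    truth = pd.DataFrame(truth_rows)
    truth.attrs["n_regenerated"] = n_regenerated
    return triples, truth, table


# ---------------------------------------------------------------------------
# downstream data: SNPs, peaks, expression
# ---------------------------------------------------------------------------


def simulate_snps(
    triples: list[AlignedSiteTriple],
    truth: pd.DataFrame,
    config: SimulationConfig,
    rng: np.random.Generator,
) -> list[tuple[str, int, str, str]]:
    """SNPs within sites, density depleted in directionally selected sites.

    Returns (chrom, 0-based pos, ref, alt) with ref the focal base.
    """
    regime_of = dict(zip(truth["site_id"], truth["regime"]))
    snps = []
    for t in triples:
        rate = (
            config.snp_rate_selected
            if regime_of[t.site_id].startswith("directional")
            else config.snp_rate_neutral
        )
        n = rng.binomial(len(t.focal), rate)
        if n == 0:
            continue
        pos = np.sort(rng.choice(len(t.focal), size=n, replace=False))
        for p in pos:
            ref = t.focal[p]
            alts = [b for b in BASES if b != ref]
            alt = alts[rng.integers(3)]
            snps.append((t.interval.chrom, t.interval.start + int(p), ref, alt))
    return snps


def write_vcf(snps: list[tuple[str, int, str, str]], path: str | Path, chrom_len: int) -> None:
    with open(path, "w") as fh:
        fh.write("##fileformat=VCFv4.2\n")
        fh.write("##source=bindsel-simulate\n")
        chroms = sorted({c for c, *_ in snps}) or ["chr1"]
        for c in chroms:
            fh.write(f"##contig=<ID={c},length={chrom_len}>\n")
        fh.write("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO\n")
        for i, (c, pos, ref, alt) in enumerate(sorted(snps)):
            fh.write(f"{c}\t{pos + 1}\tsnp{i}\t{ref}\t{alt}\t.\tPASS\t.\n")


def simulate_expression(
    n_genes: int,
    config: SimulationConfig,
    rng: np.random.Generator,
    multipliers: Optional[np.ndarray] = None,
    gene_ids: Optional[list[str]] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Expression matrix (genes x samples, log scale) with a planted law.

    Per-gene variance follows exp(c0 + c1*mean + c2*mean^2) — quadratic in
    the log-scale mean — times a lognormal residual and an optional per-gene
    multiplier (used to give selected-site target genes tighter expression).
    Returns (matrix, truth).
    """
    c2, c1, c0 = config.meanvar_coeffs
    if multipliers is None:
        multipliers = np.ones(n_genes)
    if gene_ids is None:
        gene_ids = [f"gene{i:05d}" for i in range(n_genes)]
    means = rng.uniform(1.0, 10.0, size=n_genes)
    law_var = np.exp(c0 + c1 * means + c2 * means**2)
    resid = np.exp(rng.normal(0.0, config.meanvar_residual_sd, size=n_genes))
    true_var = law_var * resid * multipliers
    mat = rng.normal(
        loc=means[:, None],
        scale=np.sqrt(true_var)[:, None],
        size=(n_genes, config.n_expression_samples),
    )
    expr = pd.DataFrame(
        mat, index=gene_ids, columns=[f"sample{j:03d}" for j in range(config.n_expression_samples)]
    )
    truth = pd.DataFrame(
        {"gene_id": gene_ids, "true_mean": means, "true_var": true_var, "multiplier": multipliers}
    ).set_index("gene_id")
    return expr, truth


# ---------------------------------------------------------------------------
# full bundle
# ---------------------------------------------------------------------------


def simulate_study(config: SimulationConfig, out_dir: str | Path) -> dict[str, Path]:
    """Write the full synthetic study bundle; byte-identical for a fixed config.

    Files: weights.txt, sites.fa (3 records per site: ``id|focal`` /
    ``id|sister`` / ``id|outgroup``), categories.tsv, truth.tsv, snps.vcf,
    sites.bed, genes_tss.bed, expression.tsv, and per-species plus per-tissue
    peak BEDs under peaks/.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "peaks").mkdir(exist_ok=True)
    rng = np.random.default_rng(config.seed)
    triples, truth, table = simulate_sites(config, rng=rng)
    paths: dict[str, Path] = {}

    paths["weights"] = out / "weights.txt"
    table.to_file(paths["weights"])

    paths["sites"] = out / "sites.fa"
    with open(paths["sites"], "w") as fh:
        for t in triples:
            for role, seq in (("focal", t.focal), ("sister", t.sister), ("outgroup", t.outgroup)):
                fh.write(f">{t.site_id}|{role}\n{seq}\n")

    paths["categories"] = out / "categories.tsv"
    pd.DataFrame(
        {"site_id": [t.site_id for t in triples], "category": [t.category for t in triples]}
    ).to_csv(paths["categories"], sep="\t", index=False)

    paths["truth"] = out / "truth.tsv"
    truth.to_csv(paths["truth"], sep="\t", index=False, float_format="%.6f")

    paths["sites_bed"] = out / "sites.bed"
    with open(paths["sites_bed"], "w") as fh:
        for t in triples:
            iv = t.interval
            fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.site_id}\t.\t+\n")

    chrom_len = max(t.interval.end for t in triples) + 1000
    snps = simulate_snps(triples, truth, config, rng)
    paths["snps"] = out / "snps.vcf"
    write_vcf(snps, paths["snps"], chrom_len)

    # species peak sets consistent with the planted categories
    species_peaks = {"focal": [], "sister": [], "outgroup": []}
    for t in triples:
        iv = t.interval
        row = (iv.chrom, iv.start, iv.end, t.site_id)
        if t.category == "conserved":
            for sp in species_peaks:
                species_peaks[sp].append(row)
        elif t.category == "gain":
            species_peaks["focal"].append(row)
        elif t.category == "loss":
            species_peaks["sister"].append(row)
            species_peaks["outgroup"].append(row)
    for sp, rows in species_peaks.items():
        p = out / "peaks" / f"species_{sp}.bed"
        paths[f"peaks_{sp}"] = p
        with open(p, "w") as fh:
            for chrom, s, e, name in rows:
                fh.write(f"{chrom}\t{s}\t{e}\t{name}_{sp}\t.\t+\n")

    # three synthetic tissues: each site active in a random subset
    n_tissues = 3
    active = rng.random((len(triples), n_tissues)) < 0.6
    for j in range(n_tissues):
        p = out / "peaks" / f"tissue_{j}.bed"
        paths[f"peaks_tissue_{j}"] = p
        with open(p, "w") as fh:
            for i, t in enumerate(triples):
                if active[i, j]:
                    iv = t.interval
                    fh.write(f"{iv.chrom}\t{iv.start}\t{iv.end}\t{t.site_id}_t{j}\t.\t+\n")

    # expression: one target gene per site (TSS just downstream), plus background
    regime_of = dict(zip(truth["site_id"], truth["regime"]))
    site_gene_ids = [f"gene_{t.site_id}" for t in triples]
    bg_gene_ids = [f"gene_bg{i:05d}" for i in range(config.n_background_genes)]
    mult = np.array(
        [
            config.selected_target_var_multiplier
            if regime_of[t.site_id].startswith("directional")
            else 1.0
            for t in triples
        ]
        + [1.0] * config.n_background_genes
    )
    expr, expr_truth = simulate_expression(
        len(mult), config, rng, multipliers=mult, gene_ids=site_gene_ids + bg_gene_ids
    )
    paths["expression"] = out / "expression.tsv"
    expr.to_csv(paths["expression"], sep="\t", float_format="%.6f")
    paths["expression_truth"] = out / "expression_truth.tsv"
    expr_truth.to_csv(paths["expression_truth"], sep="\t", float_format="%.6f")

    paths["genes_tss"] = out / "genes_tss.bed"
    far_offset = chrom_len + 10_000
    with open(paths["genes_tss"], "w") as fh:
        for t, gid in zip(triples, site_gene_ids):
            tss = t.interval.end + 10  # just downstream: nearest gene of its site
            fh.write(f"{t.interval.chrom}\t{tss}\t{tss + 1}\t{gid}\t.\t+\n")
        for i, gid in enumerate(bg_gene_ids):
            tss = far_offset + i * 5000
            fh.write(f"chr1\t{tss}\t{tss + 1}\t{gid}\t.\t+\n")

    return paths
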