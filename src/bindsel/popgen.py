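"""Divergence/polymorphism validation in the McDonald-Kreitman framework.

If the significant sites (PBSs) are truly under positive selection they
should show an excess of fixed interspecies differences (divergence, D)
relative to segregating intraspecies variants (polymorphism, P) compared
with non-significant sites: adaptive fixation raises divergence while the
accompanying sweeps deplete polymorphism.  The contrast is summarized as a
2x2 Fisher exact test and as alpha, the proportion of substitutions fixed by
positive selection:

    alpha = 1 - (D_np * P_p) / (D_p * P_np)

where subscripts p / np denote PBS / non-PBS sites.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from intervaltree import IntervalTree
from scipy import stats

from .ancestral import GenomicInterval, SubstitutionSet


@dataclass(frozen=True)
class Snp:
    chrom: str
    pos: int  # 0-based
    ref: str
    alt: str


def read_snps_vcf(path: str | Path) -> list[Snp]:
    """Read biallelic SNPs from a (plain or bgzipped) VCF via pysam.

    Positions are converted to 0-based; multi-allelic or non-SNP records are
    skipped.
    """
    import pysam

    snps: list[Snp] = []
    with pysam.VariantFile(str(path)) as vcf:
        for rec in vcf:
            if rec.alts is None or len(rec.alts) != 1:
                continue
            ref, alt = rec.ref, rec.alts[0]
            if len(ref) != 1 or len(alt) != 1:
                continue
            snps.append(Snp(rec.chrom, rec.pos, ref, alt))  # rec.pos is 0-based in pysam
    return snps


@dataclass
class MkCounts:
    """2x2 divergence/polymorphism table over PBS and non-PBS sites."""

    D_p: int = 0
    P_p: int = 0
    D_np: int = 0
    P_np: int = 0
    n_snps_outside_sites: int = 0

    def __post_init__(self) -> None:
        if min(self.D_p, self.P_p, self.D_np, self.P_np) < 0:
            raise ValueError("MK counts must be non-negative")

    def table(self) -> list[list[int]]:
        return [[self.D_p, self.P_p], [self.D_np, self.P_np]]


def count_div_poly(
    intervals: Mapping[str, GenomicInterval],
    substitutions: Mapping[str, SubstitutionSet],
    snps: Iterable[Snp],
    labels: Mapping[str, str],
) -> MkCounts:
    """Tally D and P for PBS and non-PBS sites.

    D is the total focal-branch substitution count of each labeled site; P is
    the number of SNPs whose position falls in a labeled site's interval (a
    SNP is counted once per distinct genomic position even under overlapping
    sites; SNPs outside every site are ignored but counted in the log field).
    Sites without a label (untested sites) contribute to neither class.
    """
    trees: dict[str, IntervalTree] = {}
    counts = MkCounts()
    for site_id, label in labels.items():
        if label not in ("PBS", "non-PBS"):
            raise ValueError(f"label for {site_id} must be 'PBS' or 'non-PBS', got {label!r}")
        iv = intervals[site_id]
        trees.setdefault(iv.chrom, IntervalTree()).addi(iv.start, iv.end, label)
        d = len(substitutions[site_id])
        if label == "PBS":
            counts.D_p += d
        else:
            counts.D_np += d
    seen: set[tuple[str, int]] = set()
    for snp in snps:
        key = (snp.chrom, snp.pos)
        if key in seen:
            continue
        seen.add(key)
        tree = trees.get(snp.chrom)
        hits = tree[snp.pos] if tree is not None else set()
        if not hits:
            counts.n_snps_outside_sites += 1
            continue
        hit_labels = {h.data for h in hits}
        # one count per distinct position; PBS membership wins on overlap
        if "PBS" in hit_labels:
            counts.P_p += 1
        else:
            counts.P_np += 1
    return counts


def ratio_test(counts: MkCounts) -> tuple[Optional[float], float]:
    """Two-sided Fisher exact test on [[D_p, P_p], [D_np, P_np]].

    Returns (odds ratio, p).  The odds ratio (D_p * P_np) / (P_p * D_np) is
    None when a zero margin makes it undefined, and inf when only the
    denominator vanishes.
    """
    table = counts.table()
    if min(sum(row) for row in table) == 0 or min(sum(col) for col in zip(*table)) == 0:
        return None, 1.0
    _, p = stats.fisher_exact(table, alternative="two-sided")
    num = counts.D_p * counts.P_np
    den = counts.P_p * counts.D_np
    if den == 0:
        odds: Optional[float] = float("inf") if num > 0 else None
    else:
        odds = num / den
    return odds, float(p)


def alpha_mk(counts: MkCounts) -> float:
    """Proportion of substitutions fixed by positive selection.

    alpha = 1 - (D_np * P_p) / (D_p * P_np); requires D_p > 0 and P_np > 0.
    """
    if counts.D_p <= 0 or counts.P_np <= 0:
        raise ValueError("alpha is undefined when D_p == 0 or P_np == 0")
    return 1.0 - (counts.D_np * counts.P_p) / (counts.D_p * counts.P_np)


BASES = "ACGT"


def substitution_rates(
    pairs: Sequence[tuple[str, str]], stratify_cpg: bool = False
) -> dict[str, "np.ndarray"]:
    """Per-base-pair substitution rate matrices from (ancestor, focal) pairs.

    rate(X->Y) = #(X->Y substitutions) / #(X in ancestors).  With
    ``stratify_cpg`` the tallies are split by ancestral CpG context (a C
    followed by G, or a G preceded by C).  Rows with zero ancestral count are
    NaN-flagged.  Returned as 4x4 arrays keyed by stratum ("all", or
    "cpg"/"non_cpg"), rows = ancestral base ACGT, columns = derived base.
    """
    strata = ("cpg", "non_cpg") if stratify_cpg else ("all",)
    sub_counts = {s: np.zeros((4, 4)) for s in strata}
    base_counts = {s: np.zeros(4) for s in strata}
    for anc, foc in pairs:
        if len(anc) != len(foc):
            raise ValueError("ancestor/focal length mismatch")
        L = len(anc)
        for i, (a, f) in enumerate(zip(anc.upper(), foc.upper())):
            ia = BASES.find(a)
            if ia < 0:
                continue
            if stratify_cpg:
                in_cpg = (a == "C" and i + 1 < L and anc[i + 1].upper() == "G") or (
                    a == "G" and i > 0 and anc[i - 1].upper() == "C"
                )
                stratum = "cpg" if in_cpg else "non_cpg"
            else:
                stratum = "all"
            base_counts[stratum][ia] += 1
            jf = BASES.find(f)
            if jf >= 0 and jf != ia:
                sub_counts[stratum][ia, jf] += 1
    out = {}
    for s in strata:
        with np.errstate(invalid="ignore", divide="ignore"):
            mat = sub_counts[s] / base_counts[s][:, None]
        np.fill_diagonal(mat, 0.0)
        mat[base_counts[s] == 0, :] = np.nan
        out[s] = mat
    return out


def per_group_rate(
    substitutions: Mapping[str, SubstitutionSet],
    lengths: Mapping[str, int],
    grouping: Mapping[str, str],
) -> dict[str, float]:
    """Substitutions per base pair per group of sites; empty groups absent."""
    subs_tot: dict[str, int] = {}
    len_tot: dict[str, int] = {}
    for site_id, group in grouping.items():
        subs_tot[group] = subs_tot.get(group, 0) + len(substitutions[site_id])
        len_tot[group] = len_tot.get(group, 0) + lengths[site_id]
    return {g: subs_tot[g] / len_tot[g] for g in subs_tot if len_tot[g] > 0}
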