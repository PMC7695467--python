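"""The positive-selection test on binding sites.

For each site the observed deltaSVM of the focal-branch substitutions is
compared against a site-specific empirical null: the same number of
substitutions is introduced at random into the inferred ancestor, the
deltaSVM of the pseudo-focal sequence recomputed, and the procedure repeated
(10,000 permutations by default).  The p-value is the tail probability that
a null deltaSVM is at least as extreme as the observed one — higher tail for
conserved/gain sites (selection for stronger binding), lower tail for loss
sites (selection for weaker binding).

Two null substitution models are available: ``uniform`` (each of the three
alternative bases equally likely) and ``ts_tv_weighted`` (transition favored
over each transversion by ``ts_tv_ratio``, default 4:1, reflecting the
genome-wide mutation spectrum).
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np

from .ancestral import (
    AlignedSiteTriple,
    extract_substitutions,
    infer_ancestor,
)
from .weights import KmerWeightTable, encode_sequence, window_codes

HIGHER = "higher"
LOWER = "lower"

#: tail used per site category: conserved and gained sites are tested for
#: affinity increase, lost sites for affinity decrease
TAIL_BY_CATEGORY = {"conserved": HIGHER, "gain": HIGHER, "unknown": HIGHER, "loss": LOWER}


@dataclass
class NullModel:
    """Configuration of the in-silico mutagenesis null."""

    kind: str = "uniform"  # uniform | ts_tv_weighted
    ts_tv_ratio: float = 4.0
    n_permutations: int = 10_000
    seed: int = 0

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "ts_tv_weighted"):
            raise ValueError(f"unknown null kind {self.kind!r}")
        if self.n_permutations < 1:
            raise ValueError("n_permutations must be >= 1")
        if self.ts_tv_ratio <= 0:
            raise ValueError("ts_tv_ratio must be > 0")


@dataclass
class SelectionTestResult:
    site_id: str
    category: str = "unknown"
    n_substitutions: int = 0
    observed_delta: Optional[float] = None
    tail: Optional[str] = None
    p_value: Optional[float] = None
    null_mean: Optional[float] = None
    null_sd: Optional[float] = None
    tested: bool = False
    filter_reason: Optional[str] = None
    has_cpg_substitution: bool = False
    has_dinucleotide_substitution: bool = False

    @property
    def positive(self) -> bool:
        return self.tested and self.p_value is not None and self.p_value < 0.01


def site_rng(global_seed: int, site_id: str) -> np.random.Generator:
    """One RNG stream per site: reproducible regardless of processing order."""
    return np.random.default_rng([global_seed & 0x7FFFFFFF, zlib.crc32(site_id.encode())])


def draw_null_substitutions(
    codes: np.ndarray,
    mutable: np.ndarray,
    n_sub: int,
    n_replicates: int,
    model: NullModel,
    rng: np.random.Generator,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Draw (positions, old base codes, new base codes) for every replicate.

    Positions are distinct within a replicate; the derived base is uniform
    over the three alternatives, or weighted (ts_tv_ratio, 1, 1) over
    (transition, transversion, transversion).  Base codes: A=0 C=1 G=2 T=3,
    so the transition partner is ``old ^ 2`` and the transversions are
    ``old ^ 1`` and ``old ^ 3``.
    """
    N = n_replicates
    if n_sub == mutable.size:
        pos = np.broadcast_to(mutable, (N, n_sub)).copy()
    else:
        u = rng.random((N, mutable.size))
        pos = mutable[np.argpartition(u, n_sub - 1, axis=1)[:, :n_sub]]
    old = codes[pos].astype(np.int64)
    if model.kind == "uniform":
        new = (old + rng.integers(1, 4, size=pos.shape)) % 4
    else:
        p_ts = model.ts_tv_ratio / (model.ts_tv_ratio + 2.0)
        is_ts = rng.random(pos.shape) < p_ts
        tv = old ^ np.where(rng.integers(0, 2, size=pos.shape) == 0, 1, 3)
        new = np.where(is_ts, old ^ 2, tv)
    return pos, old, new


def sample_null_deltas(
    ancestor: str,
    n_sub: int,
    table: KmerWeightTable,
    model: NullModel,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Empirical null: deltaSVM of ``n_sub`` random substitutions, repeated.

    Each replicate picks ``n_sub`` distinct positions uniformly (a position
    mutated twice would not preserve the observed substitution count) and
    draws the derived base from the three alternatives — uniformly, or with
    weights (ts_tv_ratio, 1, 1) on (transition, transversion, transversion).
    Deterministic given the RNG state.  Positions with non-ACGT bases are
    never mutated, and windows covering them score 0 before and after.
    """
    if rng is None:
        rng = np.random.default_rng(model.seed)
    codes = encode_sequence(ancestor)
    L = codes.shape[0]
    k = table.k
    if L < k:
        raise ValueError(f"ancestor length {L} < k={k}")
    mutable = np.flatnonzero(codes < 4)
    if n_sub > mutable.size:
        raise ValueError(f"n_sub={n_sub} exceeds {mutable.size} mutable positions")
    N = model.n_permutations
    if n_sub == 0:
        return np.zeros(N)

    anc_codes, valid = window_codes(codes, k)
    n_win = L - k + 1
    pos, old, new = draw_null_substitutions(codes, mutable, n_sub, N, model, rng)

    # accumulate base-4 code changes per (replicate, window); a window's code
    # delta is additive over substitutions at distinct positions and is zero
    # iff the window is unaffected (distinct-power base-4 digit changes cannot
    # cancel, so nonzero entries are exactly the affected windows)
    rep = np.broadcast_to(np.arange(N)[:, None, None], (N, n_sub, k))
    offs = np.arange(k)
    w = pos[:, :, None] - offs[None, None, :]
    ok = (w >= 0) & (w < n_win)
    add = (new - old)[:, :, None] * (4 ** (k - 1 - offs))[None, None, :]
    keys = (rep * n_win + w)[ok]
    # code deltas are < 4^k <= 2^24, exact in the float64 bincount
    delta_codes = np.bincount(keys, weights=add[ok], minlength=N * n_win).reshape(N, n_win)

    rr, ww = np.nonzero(delta_codes)
    base = anc_codes[ww]
    dw = table.values[base + delta_codes[rr, ww].astype(np.int64)] - table.values[base]
    dw[~valid[ww]] = 0.0
    return np.bincount(rr, weights=dw, minlength=N)


def selection_p_value(
    observed: float,
    null: Sequence[float] | np.ndarray,
    tail: str,
    pseudo_count: bool = True,
) -> float:
    """Tail probability of the observed deltaSVM under the empirical null.

    ``p = (1 + #{null >= observed}) / (1 + N)`` for the higher tail (mirrored
    for the lower tail); ties count toward the extreme tail.  The pseudo-count
    keeps p in (0, 1]; ``pseudo_count=False`` gives the plain proportion.
    """
    null = np.asarray(null, dtype=float)
    if null.size == 0:
        raise ValueError("empty null distribution")
    if tail == HIGHER:
        count = int((null >= observed).sum())
    elif tail == LOWER:
        count = int((null <= observed).sum())
    else:
        raise ValueError(f"unknown tail {tail!r}")
    if pseudo_count:
        return (1 + count) / (1 + null.size)
    return count / null.size


def test_site(
    triple: AlignedSiteTriple,
    table: KmerWeightTable,
    model: NullModel,
    min_subs: int = 2,
    max_ambiguous_fraction: float = 0.2,
    pseudo_count: bool = True,
    rng: Optional[np.random.Generator] = None,
) -> SelectionTestResult:
    """Run the full per-site test: ancestor, substitutions, deltaSVM, null, p.

    Sites failing filters (too few substitutions, ungapped length below k,
    too many parsimony-ambiguous columns) come back ``tested=False`` with a
    ``filter_reason``.
    """
    from .weights import delta_svm  # local import avoids cycle at module load

    rec = infer_ancestor(triple)
    result = SelectionTestResult(site_id=triple.site_id, category=triple.category)
    if len(rec.ancestor) < table.k:
        result.filter_reason = "short"
        return result
    if rec.ambiguous_fraction > max_ambiguous_fraction:
        result.filter_reason = "ambiguous"
        return result
    subs = extract_substitutions(
        rec.ancestor, rec.focal, triple.site_id, rec.n_ambiguous_positions, rec.n_indel_columns
    )
    result.n_substitutions = len(subs)
    result.has_cpg_substitution = any(s.on_cpg for s in subs.substitutions)
    result.has_dinucleotide_substitution = any(
        s.in_dinucleotide_cluster for s in subs.substitutions
    )
    if len(subs) < min_subs:
        result.filter_reason = "min_subs"
        return result

    observed = delta_svm(rec.ancestor, rec.focal, table)
    if rng is None:
        rng = site_rng(model.seed, triple.site_id)
    null = sample_null_deltas(rec.ancestor, len(subs), table, model, rng=rng)
    tail = TAIL_BY_CATEGORY.get(triple.category, HIGHER)
    result.observed_delta = observed
    result.tail = tail
    result.p_value = selection_p_value(observed, null, tail, pseudo_count=pseudo_count)
    result.null_mean = float(null.mean())
    result.null_sd = float(null.std(ddof=1)) if null.size > 1 else 0.0
    result.tested = True
    return result


def test_sites(
    triples: Iterable[AlignedSiteTriple],
    table: KmerWeightTable,
    model: NullModel,
    min_subs: int = 2,
    max_ambiguous_fraction: float = 0.2,
    pseudo_count: bool = True,
) -> list[SelectionTestResult]:
    """Test every site with an independent per-site RNG stream."""
    return [
        test_site(
            t,
            table,
            model,
            min_subs=min_subs,
            max_ambiguous_fraction=max_ambiguous_fraction,
            pseudo_count=pseudo_count,
        )
        for t in triples
    ]


def summarize_positive(
    results: Sequence[SelectionTestResult],
    alpha_threshold: float = 0.01,
    grouping: Optional[Mapping[str, str]] = None,
) -> dict[str, float]:
    """Per-group proportion of tested sites significant at the threshold.

    Untested sites are excluded from numerator and denominator; groups with
    no tested site are absent from the output.  Groups default to site
    categories.  Output ordered by descending proportion.
    """
    if not results:
        raise ValueError("no results to summarize")
    tested_n: dict[str, int] = {}
    pos_n: dict[str, int] = {}
    for r in results:
        if not r.tested:
            continue
        group = grouping[r.site_id] if grouping is not None else r.category
        tested_n[group] = tested_n.get(group, 0) + 1
        if r.p_value is not None and r.p_value < alpha_threshold:
            pos_n[group] = pos_n.get(group, 0) + 1
    props = {g: pos_n.get(g, 0) / n for g, n in tested_n.items()}
    return dict(sorted(props.items(), key=lambda kv: (-kv[1], kv[0])))


def robustness_partition(
    results: Sequence[SelectionTestResult], alpha_threshold: float = 0.01
) -> dict[str, float]:
    """Positive-site proportion stratified by mutational-bias exposure.

    Stratum "clean": tested sites with neither CpG nor dinucleotide-cluster
    substitutions; stratum "cpg_or_dinucleotide": the rest.  Strata with no
    tested sites are absent.
    """
    strata: dict[str, list[SelectionTestResult]] = {"clean": [], "cpg_or_dinucleotide": []}
    for r in results:
        if not r.tested:
            continue
        key = (
            "cpg_or_dinucleotide"
            if (r.has_cpg_substitution or r.has_dinucleotide_substitution)
            else "clean"
        )
        strata[key].append(r)
    out: dict[str, float] = {}
    for key, rs in strata.items():
        if rs:
            out[key] = sum(1 for r in rs if r.p_value < alpha_threshold) / len(rs)
    return out


def strict_retest(
    triples: Sequence[AlignedSiteTriple],
    table: KmerWeightTable,
    model: NullModel,
    min_subs: int = 2,
    alpha_threshold: float = 0.01,
) -> tuple[list[SelectionTestResult], dict[str, float]]:
    """Strict robustness mode: drop CpG/dinucleotide sites, ts/tv null.

    Whole sites containing any CpG-context or adjacent-pair substitution are
    excluded, and the remaining sites are retested under the
    transition/transversion-weighted null.
    """
    strict_model = NullModel(
        kind="ts_tv_weighted",
        ts_tv_ratio=model.ts_tv_ratio,
        n_permutations=model.n_permutations,
        seed=model.seed,
    )
    kept = []
    for t in triples:  # annotation-only pass; no nulls drawn here
        rec = infer_ancestor(t)
        if len(rec.ancestor) < table.k:
            continue
        subs = extract_substitutions(rec.ancestor, rec.focal, t.site_id)
        if any(s.on_cpg or s.in_dinucleotide_cluster for s in subs.substitutions):
            continue
        kept.append(t)
    results = test_sites(kept, table, strict_model, min_subs=min_subs)
    return results, summarize_positive(results, alpha_threshold=alpha_threshold)
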