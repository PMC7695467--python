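"""End-to-end orchestration: from input bundle to result tables.

``run_pipeline`` wires the stages together: load the weight table and the
aligned site triples, run the per-site selection test, and (when the
corresponding inputs are present) the McDonald-Kreitman contrast and the
target-gene adjusted-variance comparison.  Every threshold used is echoed
into the output headers, and every filter's exclusion count lands in the run
log — no timestamps, so reruns with the same seed are byte-identical.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Optional

import pandas as pd
from statsmodels.stats.multitest import multipletests

from . import io as bio
from .ancestral import extract_substitutions, infer_ancestor
from .expression import adjusted_variance, compare_target_variance, nearest_gene
from .popgen import MkCounts, alpha_mk, count_div_poly, ratio_test, read_snps_vcf
from .seltest import (
    NullModel,
    SelectionTestResult,
    robustness_partition,
    summarize_positive,
    test_sites,
)
from .weights import read_weight_table


class PipelineError(RuntimeError):
    def __init__(self, stage: str, message: str):
        super().__init__(f"[{stage}] {message}")
        self.stage = stage


@dataclass
class RunConfig:
    """Paths and thresholds for one pipeline run."""

    weights_path: Path
    sites_path: Path
    categories_path: Optional[Path] = None
    sites_bed_path: Optional[Path] = None
    snps_vcf_path: Optional[Path] = None
    expression_path: Optional[Path] = None
    tss_bed_path: Optional[Path] = None
    out_dir: Path = Path("bindsel_out")
    k: int = 10
    null_kind: str = "uniform"
    ts_tv_ratio: float = 4.0
    n_permutations: int = 10_000
    seed: int = 0
    p_threshold: float = 0.01
    min_subs: int = 2
    max_ambiguous_fraction: float = 0.2
    paper_compat_pvalue: bool = False  # plain proportion instead of pseudo-count

    def null_model(self) -> NullModel:
        return NullModel(
            kind=self.null_kind,
            ts_tv_ratio=self.ts_tv_ratio,
            n_permutations=self.n_permutations,
            seed=self.seed,
        )

    def header_lines(self) -> list[str]:
        keys = (
            "k null_kind ts_tv_ratio n_permutations seed p_threshold min_subs "
            "max_ambiguous_fraction paper_compat_pvalue"
        ).split()
        return [f"# {key}={getattr(self, key)}" for key in keys]


def results_to_frame(results: list[SelectionTestResult]) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "site_id": [r.site_id for r in results],
            "category": [r.category for r in results],
            "n_subs": [r.n_substitutions for r in results],
            "delta_svm": [r.observed_delta for r in results],
            "tail": [r.tail for r in results],
            "p_value": [r.p_value for r in results],
            "null_mean": [r.null_mean for r in results],
            "null_sd": [r.null_sd for r in results],
            "tested": [r.tested for r in results],
            "filter_reason": [r.filter_reason or "" for r in results],
            "has_cpg_sub": [r.has_cpg_substitution for r in results],
            "has_dinucleotide_sub": [r.has_dinucleotide_substitution for r in results],
        }
    )
    # optional BH-FDR column over tested sites (raw p at the stated threshold
    # remains the primary call, as in the original analysis)
    mask = df["tested"].to_numpy()
    df["q_value"] = float("nan")
    if mask.any():
        df.loc[mask, "q_value"] = multipletests(df.loc[mask, "p_value"], method="fdr_bh")[1]
    return df


def _write_tsv(df: pd.DataFrame, path: Path, header_lines: list[str]) -> None:
    with open(path, "w") as fh:
        for line in header_lines:
            fh.write(line + "\n")
        df.to_csv(fh, sep="\t", index=False, float_format="%.6g")


def run_pipeline(config: RunConfig) -> dict[str, Path]:
    """Run every stage the configured inputs allow; return output paths."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    log_lines: list[str] = list(config.header_lines())
    outputs: dict[str, Path] = {}

    try:
        table = read_weight_table(config.weights_path, k=config.k)
    except Exception as exc:
        raise PipelineError("weights", str(exc)) from exc
    log_lines.append(f"# weights_entries={len(table)}")

    try:
        categories = (
            bio.read_categories_tsv(config.categories_path) if config.categories_path else None
        )
        intervals = (
            bio.read_intervals_bed(config.sites_bed_path) if config.sites_bed_path else None
        )
        triples = bio.read_site_triples(config.sites_path, categories, intervals)
    except Exception as exc:
        raise PipelineError("sites", str(exc)) from exc
    log_lines.append(f"# sites_loaded={len(triples)}")

    try:
        results = test_sites(
            triples,
            table,
            config.null_model(),
            min_subs=config.min_subs,
            max_ambiguous_fraction=config.max_ambiguous_fraction,
            pseudo_count=not config.paper_compat_pvalue,
        )
    except Exception as exc:
        raise PipelineError("test", str(exc)) from exc

    df = results_to_frame(results)
    outputs["results"] = out / "results.tsv"
    _write_tsv(df, outputs["results"], config.header_lines())

    for reason in ("short", "ambiguous", "min_subs"):
        log_lines.append(f"# filtered_{reason}={int((df['filter_reason'] == reason).sum())}")
    log_lines.append(f"# tested={int(df['tested'].sum())}")

    summary_rows = [
        {"group": g, "proportion_positive": v}
        for g, v in summarize_positive(results, alpha_threshold=config.p_threshold).items()
    ]
    for stratum, v in robustness_partition(results, alpha_threshold=config.p_threshold).items():
        summary_rows.append({"group": f"stratum:{stratum}", "proportion_positive": v})
    summary = pd.DataFrame(summary_rows)

    # McDonald-Kreitman contrast, when SNPs and site intervals are available
    if config.snps_vcf_path and config.sites_bed_path:
        try:
            snps = read_snps_vcf(config.snps_vcf_path)
            intervals = bio.read_intervals_bed(config.sites_bed_path)
            counts = mk_from_results(triples, results, intervals, snps, config.p_threshold)
            odds, fisher_p = ratio_test(counts)
            summary = pd.concat(
                [
                    summary,
                    pd.DataFrame(
                        [
                            {"group": "mk:D_p", "proportion_positive": counts.D_p},
                            {"group": "mk:P_p", "proportion_positive": counts.P_p},
                            {"group": "mk:D_np", "proportion_positive": counts.D_np},
                            {"group": "mk:P_np", "proportion_positive": counts.P_np},
                            {"group": "mk:odds_ratio", "proportion_positive": odds},
                            {"group": "mk:fisher_p", "proportion_positive": fisher_p},
                            {
                                "group": "mk:alpha",
                                "proportion_positive": alpha_mk(counts)
                                if counts.D_p > 0 and counts.P_np > 0
                                else float("nan"),
                            },
                        ]
                    ),
                ],
                ignore_index=True,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("mk", str(exc)) from exc

    # adjusted-variance comparison, when expression and TSS are available
    if config.expression_path and config.tss_bed_path and config.sites_bed_path:
        try:
            expr = bio.read_expression_tsv(config.expression_path)
            adj, model = adjusted_variance(expr)
            genes = bio.read_tss_bed(config.tss_bed_path)
            intervals = bio.read_intervals_bed(config.sites_bed_path)
            tested = {r.site_id: r for r in results if r.tested}
            labels = {
                sid: ("PBS" if r.p_value < config.p_threshold else "non-PBS")
                for sid, r in tested.items()
            }
            site_ivs = {sid: intervals[sid] for sid in labels if sid in intervals}
            targets = nearest_gene(site_ivs, genes)
            a, b, wilcoxon_p = compare_target_variance(adj.to_dict(), labels, targets)
            summary = pd.concat(
                [
                    summary,
                    pd.DataFrame(
                        [
                            {"group": "expr:meanvar_degree", "proportion_positive": model.degree},
                            {"group": "expr:pbs_median_adjvar", "proportion_positive": float(pd.Series(a).median())},
                            {"group": "expr:nonpbs_median_adjvar", "proportion_positive": float(pd.Series(b).median())},
                            {"group": "expr:wilcoxon_p", "proportion_positive": wilcoxon_p},
                        ]
                    ),
                ],
                ignore_index=True,
            )
        except PipelineError:
            raise
        except Exception as exc:
            raise PipelineError("expression", str(exc)) from exc

    outputs["summary"] = out / "summary.tsv"
    _write_tsv(summary, outputs["summary"], config.header_lines())

    outputs["log"] = out / "run.log"
    with open(outputs["log"], "w") as fh:
        fh.write("\n".join(log_lines) + "\n")
    return outputs


def mk_from_results(triples, results, intervals, snps, p_threshold: float) -> MkCounts:
    """Assemble MK counts from tested sites: PBS = p below the threshold."""
    by_id = {t.site_id: t for t in triples}
    labels = {}
    subs = {}
    ivs = {}
    for r in results:
        if not r.tested or r.site_id not in intervals:
            continue
        labels[r.site_id] = "PBS" if r.p_value < p_threshold else "non-PBS"
        rec = infer_ancestor(by_id[r.site_id])
        subs[r.site_id] = extract_substitutions(rec.ancestor, rec.focal, r.site_id)
        ivs[r.site_id] = intervals[r.site_id]
    return count_div_poly(ivs, subs, snps, labels)
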