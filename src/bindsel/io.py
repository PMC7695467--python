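"""Readers for the external file formats the pipeline consumes.

Aligned site triples travel as multi-FASTA with three records per site,
``<site_id>|focal``, ``<site_id>|sister``, ``<site_id>|outgroup``.  Intervals
are BED (0-based half-open), categories and results are TSV.
"""

from __future__ import annotations

from pathlib import Path
from typing import Optional

import pandas as pd
from Bio import SeqIO

from .ancestral import AlignedSiteTriple, GenomicInterval
from .expression import Tss

ROLES = ("focal", "sister", "outgroup")


def read_site_triples(
    fasta_path: str | Path,
    categories: Optional[dict[str, str]] = None,
    intervals: Optional[dict[str, GenomicInterval]] = None,
) -> list[AlignedSiteTriple]:
    """Load aligned triples from FASTA, in file order of first appearance."""
    seqs: dict[str, dict[str, str]] = {}
    order: list[str] = []
    for rec in SeqIO.parse(str(fasta_path), "fasta"):
        if "|" not in rec.id:
            raise ValueError(f"{fasta_path}: record {rec.id!r} lacks '|role' suffix")
        site_id, role = rec.id.rsplit("|", 1)
        if role not in ROLES:
            raise ValueError(f"{fasta_path}: unknown role {role!r} in record {rec.id!r}")
        if site_id not in seqs:
            seqs[site_id] = {}
            order.append(site_id)
        if role in seqs[site_id]:
            raise ValueError(f"{fasta_path}: duplicate record {rec.id!r}")
        seqs[site_id][role] = str(rec.seq)
    triples = []
    for site_id in order:
        roles = seqs[site_id]
        missing = [r for r in ROLES if r not in roles]
        if missing:
            raise ValueError(f"{fasta_path}: site {site_id} missing roles {missing}")
        triples.append(
            AlignedSiteTriple(
                site_id=site_id,
                focal=roles["focal"],
                sister=roles["sister"],
                outgroup=roles["outgroup"],
                interval=intervals.get(site_id) if intervals else None,
                category=(categories or {}).get(site_id, "unknown"),
            )
        )
    return triples


def read_categories_tsv(path: str | Path) -> dict[str, str]:
    df = pd.read_csv(path, sep="\t", dtype=str)
    if not {"site_id", "category"} <= set(df.columns):
        raise ValueError(f"{path}: expected columns site_id, category")
    return dict(zip(df["site_id"], df["category"]))


def read_intervals_bed(path: str | Path) -> dict[str, GenomicInterval]:
    out: dict[str, GenomicInterval] = {}
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"iv{i}"
            out[name] = GenomicInterval(f[0], int(f[1]), int(f[2]))
    return out


def read_tss_bed(path: str | Path) -> list[Tss]:
    tss: list[Tss] = []
    with open(path) as fh:
        for i, line in enumerate(fh):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            f = line.split("\t")
            name = f[3] if len(f) > 3 else f"gene{i}"
            tss.append(Tss(chrom=f[0], pos=int(f[1]), gene_id=name))
    return tss


def read_expression_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col=0)
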