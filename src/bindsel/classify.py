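"""Cross-species peak classification and multi-tissue activity counts.

Binding-site categories come from ChIP-seq peak presence across three
species on a shared (focal) coordinate system, with >= 1 bp interval overlap
as the criterion throughout:

* conserved — focal peak overlapping peaks in both sister and outgroup
* gain      — focal peak overlapping neither
* loss      — sister peak overlapping an outgroup peak but no focal peak
              (reported on sister-peak coordinates)

Focal peaks overlapping exactly one of the other two sets fall in an
explicit "unclassified" bucket and are excluded downstream.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Optional, Sequence

import pandas as pd
from intervaltree import IntervalTree


@dataclass(frozen=True)
class Peak:
    chrom: str
    start: int
    end: int
    peak_id: str
    intensity: Optional[float] = None

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"peak {self.peak_id}: start must be < end ({self.start} >= {self.end})")


@dataclass
class PeakSet:
    """Peaks for one species or tissue, indexed for overlap queries."""

    label: str
    peaks: list[Peak] = field(default_factory=list)

    def __post_init__(self) -> None:
        ids = [p.peak_id for p in self.peaks]
        if len(ids) != len(set(ids)):
            raise ValueError(f"{self.label}: duplicate peak ids")
        self._trees: dict[str, IntervalTree] = {}
        for p in self.peaks:
            self._trees.setdefault(p.chrom, IntervalTree()).addi(p.start, p.end, p)

    def __len__(self) -> int:
        return len(self.peaks)

    def overlaps(self, chrom: str, start: int, end: int) -> bool:
        tree = self._trees.get(chrom)
        return bool(tree is not None and tree.overlap(start, end))

    @classmethod
    def from_bed(cls, path: str | Path, label: Optional[str] = None) -> "PeakSet":
        peaks = []
        with open(path) as fh:
            for i, line in enumerate(fh):
                line = line.rstrip("\n")
                if not line or line.startswith(("#", "track", "browser")):
                    continue
                f = line.split("\t")
                name = f[3] if len(f) > 3 and f[3] != "." else f"peak{i}"
                intensity = float(f[4]) if len(f) > 4 and f[4] != "." else None
                peaks.append(Peak(f[0], int(f[1]), int(f[2]), name, intensity))
        return cls(label=label or Path(path).stem, peaks=peaks)

    def to_bed(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            for p in self.peaks:
                score = "." if p.intensity is None else f"{p.intensity:g}"
                fh.write(f"{p.chrom}\t{p.start}\t{p.end}\t{p.peak_id}\t{score}\t+\n")


def classify_peaks(focal: PeakSet, sister: PeakSet, outgroup: PeakSet) -> dict[str, str]:
    """Label peaks conserved / gain / loss / unclassified by >=1 bp overlap.

    Conserved and gain (and unclassified) labels attach to focal peak ids;
    loss labels attach to sister peak ids.  All three sets must already be on
    focal coordinates (liftover is upstream of this package).
    """
    labels: dict[str, str] = {}
    for p in focal.peaks:
        in_sister = sister.overlaps(p.chrom, p.start, p.end)
        in_outgroup = outgroup.overlaps(p.chrom, p.start, p.end)
        if in_sister and in_outgroup:
            labels[p.peak_id] = "conserved"
        elif not in_sister and not in_outgroup:
            labels[p.peak_id] = "gain"
        else:
            labels[p.peak_id] = "unclassified"
    for p in sister.peaks:
        if outgroup.overlaps(p.chrom, p.start, p.end) and not focal.overlaps(p.chrom, p.start, p.end):
            labels[p.peak_id] = "loss"
    return labels


def classification_to_tsv(labels: dict[str, str], path: str | Path) -> None:
    df = pd.DataFrame(sorted(labels.items()), columns=["peak_id", "category"])
    df.to_csv(path, sep="\t", index=False)


def merge_peaks(peak_sets: Sequence[PeakSet], label: str = "merged") -> PeakSet:
    """Single-linkage union of >=1 bp-overlapping intervals across all sets.

    This reproduces the merged-site construction used when integrating peaks
    from many tissues into one reference set.
    """
    by_chrom: dict[str, list[tuple[int, int]]] = {}
    for ps in peak_sets:
        for p in ps.peaks:
            by_chrom.setdefault(p.chrom, []).append((p.start, p.end))
    merged: list[Peak] = []
    idx = 0
    for chrom in sorted(by_chrom):
        ivs = sorted(by_chrom[chrom])
        cur_s, cur_e = ivs[0]
        for s, e in ivs[1:]:
            if s < cur_e:  # >=1 bp overlap (half-open intervals)
                cur_e = max(cur_e, e)
            else:
                merged.append(Peak(chrom, cur_s, cur_e, f"site{idx}"))
                idx += 1
                cur_s, cur_e = s, e
        merged.append(Peak(chrom, cur_s, cur_e, f"site{idx}"))
        idx += 1
    return PeakSet(label=label, peaks=merged)


def count_active_tissues(
    site_intervals: PeakSet, per_tissue_peaks: Iterable[PeakSet]
) -> dict[str, int]:
    """Per merged site, the number of tissues with a >=1 bp overlapping peak."""
    tissues = list(per_tissue_peaks)
    if not tissues:
        raise ValueError("empty tissue list")
    counts: dict[str, int] = {}
    for site in site_intervals.peaks:
        counts[site.peak_id] = sum(
            1 for t in tissues if t.overlaps(site.chrom, site.start, site.end)
        )
    return counts
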