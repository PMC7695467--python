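"""Three-taxon parsimony ancestral reconstruction and substitution extraction.

The selection test polarizes sequence differences onto the focal branch of
the rooted topology ((focal, sister), outgroup): the ancestral base at each
aligned column is inferred by parsimony, and the differences between that
ancestor and the focal sequence are the focal-branch substitutions whose
aggregate affinity change the test evaluates.

Column rules, for bases (f, s, o):

* s == o         -> ancestor is s (outgroup agreement pins the ancestral state)
* f == o         -> ancestor is f (sister-branch substitution)
* f == s         -> ancestor is f (outgroup-branch substitution)
* all distinct   -> AMBIGUOUS: ancestor carries the focal base and no
                    substitution is recorded (conservative: the column
                    contributes zero to deltaSVM)

Columns with a gap in any taxon are INDEL columns: the model covers
substitutions only, so they are removed from both ancestor and focal before
scoring.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from enum import Enum
from typing import Optional


class ColumnFlag(str, Enum):
    OK = "ok"
    AMBIGUOUS = "ambiguous"


PURINES = {"A", "G"}
PYRIMIDINES = {"C", "T"}
GAP_CHARS = {"-", "."}


@dataclass(frozen=True)
class GenomicInterval:
    """0-based half-open interval (BED convention)."""

    chrom: str
    start: int
    end: int

    def __post_init__(self) -> None:
        if self.start >= self.end:
            raise ValueError(f"interval start must be < end: {self}")

    def __len__(self) -> int:
        return self.end - self.start


@dataclass
class AlignedSiteTriple:
    """One binding site with aligned focal / sister / outgroup sequences."""

    site_id: str
    focal: str
    sister: str
    outgroup: str
    interval: Optional[GenomicInterval] = None
    category: str = "unknown"  # conserved | gain | loss | unknown

    def __post_init__(self) -> None:
        if not (len(self.focal) == len(self.sister) == len(self.outgroup)):
            raise ValueError(
                f"{self.site_id}: aligned sequences have unequal lengths "
                f"({len(self.focal)}, {len(self.sister)}, {len(self.outgroup)})"
            )
        self.focal = self.focal.upper()
        self.sister = self.sister.upper()
        self.outgroup = self.outgroup.upper()


@dataclass
class Substitution:
    """One focal-branch substitution, in ungapped ancestor coordinates."""

    position: int
    ancestral: str
    derived: str
    is_transition: bool = False
    on_cpg: bool = False
    in_dinucleotide_cluster: bool = False


@dataclass
class SubstitutionSet:
    site_id: str
    substitutions: list[Substitution] = field(default_factory=list)
    n_ambiguous_positions: int = 0
    n_indel_columns: int = 0

    def __len__(self) -> int:
        return len(self.substitutions)

    def positions(self) -> list[int]:
        return [s.position for s in self.substitutions]


@dataclass
class AncestralReconstruction:
    """Parsimony ancestor in ungapped focal coordinates.

    ``ancestor`` and ``focal`` cover only the gap-free aligned columns, so
    they are equal-length and directly scoreable; ``flags`` marks each
    retained position OK or AMBIGUOUS.
    """

    site_id: str
    ancestor: str
    focal: str
    flags: list[ColumnFlag]
    n_indel_columns: int
    n_ambiguous_positions: int

    @property
    def ambiguous_fraction(self) -> float:
        if not self.flags:
            return 0.0
        return self.n_ambiguous_positions / len(self.flags)


def infer_ancestor(triple: AlignedSiteTriple) -> AncestralReconstruction:
    """Infer the focal-lineage ancestor by three-taxon parsimony.

    Raises if no gap-free columns remain.
    """
    anc: list[str] = []
    foc: list[str] = []
    flags: list[ColumnFlag] = []
    n_indel = 0
    n_amb = 0
    for f, s, o in zip(triple.focal, triple.sister, triple.outgroup):
        if f in GAP_CHARS or s in GAP_CHARS or o in GAP_CHARS:
            n_indel += 1
            continue
        if s == o:
            a = s
            flag = ColumnFlag.OK
        elif f == o or f == s:
            a = f
            flag = ColumnFlag.OK
        else:
            a = f  # three distinct bases: direction unresolvable
            flag = ColumnFlag.AMBIGUOUS
            n_amb += 1
        anc.append(a)
        foc.append(f)
        flags.append(flag)
    if not anc:
        raise ValueError(f"{triple.site_id}: no gap-free aligned columns")
    return AncestralReconstruction(
        site_id=triple.site_id,
        ancestor="".join(anc),
        focal="".join(foc),
        flags=flags,
        n_indel_columns=n_indel,
        n_ambiguous_positions=n_amb,
    )


def extract_substitutions(
    ancestor: str, focal: str, site_id: str = "", n_ambiguous: int = 0, n_indel: int = 0
) -> SubstitutionSet:
    """Per-position diff between gap-free ancestor and focal sequences.

    Annotations (ts/tv, CpG context, dinucleotide clustering) are filled by
    :func:`annotate_substitutions` against the ancestor.
    """
    if len(ancestor) != len(focal):
        raise ValueError(f"{site_id}: ancestor/focal length mismatch")
    subs = [
        Substitution(position=i, ancestral=a, derived=f)
        for i, (a, f) in enumerate(zip(ancestor, focal))
        if a != f
    ]
    out = SubstitutionSet(
        site_id=site_id,
        substitutions=subs,
        n_ambiguous_positions=n_ambiguous,
        n_indel_columns=n_indel,
    )
    return annotate_substitutions(out, ancestor)


def _is_transition(a: str, b: str) -> bool:
    return (a in PURINES and b in PURINES) or (a in PYRIMIDINES and b in PYRIMIDINES)


def annotate_substitutions(subs: SubstitutionSet, ancestor: str) -> SubstitutionSet:
    """Fill ts/tv, CpG and dinucleotide-cluster annotations in place.

    CpG context is judged on the ancestor (the pre-substitution state, where
    the hypermutable methyl-CpG sits): position i is on a CpG iff
    ancestor[i:i+2] == "CG" or ancestor[i-1:i+1] == "CG".  A substitution is
    in a dinucleotide cluster iff another substitution sits at an adjacent
    position.
    """
    pos_set = {s.position for s in subs.substitutions}
    L = len(ancestor)
    for s in subs.substitutions:
        i = s.position
        if not 0 <= i < L:
            raise ValueError(f"substitution position {i} outside ancestor of length {L}")
        s.is_transition = _is_transition(s.ancestral, s.derived)
        on_cpg = False
        if ancestor[i] == "C" and i + 1 < L and ancestor[i + 1] == "G":
            on_cpg = True
        if ancestor[i] == "G" and i - 1 >= 0 and ancestor[i - 1] == "C":
            on_cpg = True
        s.on_cpg = on_cpg
        s.in_dinucleotide_cluster = (i - 1 in pos_set) or (i + 1 in pos_set)
    return subs


def apply_substitutions(ancestor: str, subs: SubstitutionSet) -> str:
    """Apply recorded substitutions to the ancestor (round-trip check)."""
    seq = list(ancestor)
    for s in subs.substitutions:
        if seq[s.position] != s.ancestral:
            raise ValueError(
                f"ancestral base mismatch at {s.position}: {seq[s.position]} != {s.ancestral}"
            )
        seq[s.position] = s.derived
    return "".join(seq)
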