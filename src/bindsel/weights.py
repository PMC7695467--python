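"""k-mer weight tables and gapped k-mer SVM sequence scoring.

A trained gkm-SVM assigns every k-mer a weight: its contribution to the
predicted binding affinity of a sequence.  The affinity score of a sequence
is the sum of weights over all overlapping k-mer windows, and the predicted
affinity change of a set of substitutions (deltaSVM) is the score of the
derived sequence minus the score of the ancestral one.

Weight tables are read from the two-column plain-text format emitted by
LS-GKM's ``gkmpredict`` run on a FASTA of all 4^k k-mers (``<KMER>\\t<weight>``).
Internally the table is dense: a float64 vector indexed by the base-4
encoding of the k-mer, which is what makes scoring and the permutation null
fast.  Absent k-mers score 0 (the neutral contribution) and are counted.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Iterator, Mapping

import numpy as np

BASES = "ACGT"
_CODE = np.full(256, 4, dtype=np.int8)
for _i, _b in enumerate(BASES):
    _CODE[ord(_b)] = _i
    _CODE[ord(_b.lower())] = _i

#: largest supported k (dense table of 4^k float64 entries)
MAX_K = 12


def encode_sequence(seq: str) -> np.ndarray:
    """Encode a DNA string as int8 codes A=0, C=1, G=2, T=3; other chars -> 4.

    Case-insensitive (soft-masked genomes are uppercased implicitly).
    """
    return _CODE[np.frombuffer(seq.encode("ascii"), dtype=np.uint8)]


def decode_kmer(code: int, k: int) -> str:
    out = []
    for j in range(k):
        out.append(BASES[(code >> (2 * (k - 1 - j))) & 3])
    return "".join(out)


def encode_kmer(kmer: str) -> int:
    code = 0
    for ch in kmer.upper():
        idx = BASES.find(ch)
        if idx < 0:
            raise ValueError(f"non-ACGT character {ch!r} in k-mer {kmer!r}")
        code = (code << 2) | idx
    return code


class WeightTableError(ValueError):
    pass


@dataclass
class KmerWeightTable:
    """Dense k-mer -> SVM weight map.

    Parameters
    ----------
    k : k-mer length (LS-GKM default in this pipeline: 10).
    values : float64 array of length 4**k; weight of each k-mer by base-4 code.
    present : bool array marking which k-mers were explicitly provided.
        Lookups of absent k-mers return 0.0 and increment ``n_missing_lookups``.
    source : free-text provenance.
    """

    k: int
    values: np.ndarray
    present: np.ndarray
    source: str = ""
    n_missing_lookups: int = field(default=0, compare=False)

    def __post_init__(self) -> None:
        if self.k < 1:
            raise WeightTableError(f"k must be >= 1, got {self.k}")
        if self.k > MAX_K:
            raise WeightTableError(f"k={self.k} exceeds supported maximum {MAX_K}")
        if self.values.shape != (4**self.k,):
            raise WeightTableError("values must have length 4^k")
        if not self.present.any():
            raise WeightTableError("weight table is empty")

    # -- construction ----------------------------------------------------
    @classmethod
    def from_mapping(cls, weights: Mapping[str, float], k: int, source: str = "") -> "KmerWeightTable":
        values = np.zeros(4**k)
        present = np.zeros(4**k, dtype=bool)
        for kmer, w in weights.items():
            if len(kmer) != k:
                raise WeightTableError(f"k-mer {kmer!r} has length {len(kmer)}, expected {k}")
            code = encode_kmer(kmer)
            if present[code]:
                raise WeightTableError(f"duplicate k-mer {kmer!r}")
            values[code] = float(w)
            present[code] = True
        return cls(k=k, values=values, present=present, source=source)

    # -- mapping-ish interface -------------------------------------------
    def __len__(self) -> int:
        return int(self.present.sum())

    def __contains__(self, kmer: str) -> bool:
        return bool(self.present[encode_kmer(kmer)])

    def __getitem__(self, kmer: str) -> float:
        return self.weight(kmer)

    def weight(self, kmer: str) -> float:
        """Weight of one k-mer; absent k-mers yield 0.0 and are counted."""
        if len(kmer) != self.k:
            raise WeightTableError(f"k-mer length {len(kmer)} != k={self.k}")
        code = encode_kmer(kmer)
        if not self.present[code]:
            self.n_missing_lookups += 1
            return 0.0
        return float(self.values[code])

    def items(self) -> Iterator[tuple[str, float]]:
        for code in np.flatnonzero(self.present):
            yield decode_kmer(int(code), self.k), float(self.values[code])

    # -- I/O ---------------------------------------------------------------
    def to_file(self, path: str | Path) -> None:
        """Write the LS-GKM two-column dialect (``kmer<TAB>weight``)."""
        codes = np.flatnonzero(self.present).astype(np.int64)
        k = self.k
        digits = np.empty((codes.size, k), dtype=np.int64)
        for j in range(k):
            digits[:, k - 1 - j] = (codes >> (2 * j)) & 3
        letters = np.frombuffer(BASES.encode(), dtype="S1")
        kmers = letters[digits].view(f"S{k}").ravel()
        with open(path, "w") as fh:
            for kmer, w in zip(kmers, self.values[codes]):
                fh.write(f"{kmer.decode()}\t{w:.6f}\n")


def read_weight_table(path: str | Path, k: int) -> KmerWeightTable:
    """Parse a gkmpredict-style two-column weight file.

    Raises :class:`WeightTableError` with the line number on malformed lines,
    on k-mers whose length differs from ``k``, on duplicates, and on empty
    files.
    """
    values = np.zeros(4**k)
    present = np.zeros(4**k, dtype=bool)
    n = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 2:
                raise WeightTableError(f"{path}:{lineno}: expected 2 columns, got {len(parts)}")
            kmer, w_str = parts
            if len(kmer) != k:
                raise WeightTableError(
                    f"{path}:{lineno}: k-mer {kmer!r} has length {len(kmer)}, expected {k}"
                )
            try:
                code = encode_kmer(kmer)
                w = float(w_str)
            except ValueError as exc:
                raise WeightTableError(f"{path}:{lineno}: {exc}") from exc
            if present[code]:
                raise WeightTableError(f"{path}:{lineno}: duplicate k-mer {kmer!r}")
            values[code] = w
            present[code] = True
            n += 1
    if n == 0:
        raise WeightTableError(f"{path}: empty weight file")
    return KmerWeightTable(k=k, values=values, present=present, source=str(path))


# ---------------------------------------------------------------------------
# scoring
# ---------------------------------------------------------------------------

_POW4_CACHE: dict[int, np.ndarray] = {}


def _pow4(k: int) -> np.ndarray:
    # [4^(k-1), ..., 4, 1] so that codes @ pow4 gives the base-4 encoding
    if k not in _POW4_CACHE:
        _POW4_CACHE[k] = (4 ** np.arange(k - 1, -1, -1)).astype(np.int64)
    return _POW4_CACHE[k]


def window_codes(codes: np.ndarray, k: int) -> tuple[np.ndarray, np.ndarray]:
    """Base-4 codes of every k-window plus a validity mask.

    Windows containing any non-ACGT position are invalid: they contribute
    weight 0.  Invalid windows get code 0 (in-bounds placeholder).
    """
    L = codes.shape[0]
    if L < k:
        raise ValueError(f"sequence length {L} < k={k}")
    win = np.lib.stride_tricks.sliding_window_view(codes, k)
    valid = ~(win == 4).any(axis=1)
    wc = win.astype(np.int64) @ _pow4(k)
    wc[~valid] = 0
    return wc, valid


def score_sequence(seq: str, table: KmerWeightTable) -> float:
    """Affinity score: sum of k-mer weights over all overlapping windows.

    Non-ACGT characters zero out every window that covers them (counted via
    :func:`score_details`).  Raises on sequences shorter than k.
    """
    return score_details(seq, table)[0]


def score_details(seq: str, table: KmerWeightTable) -> tuple[float, int, int]:
    """Score plus (n_invalid_windows, n_missing_kmer_windows)."""
    codes = encode_sequence(seq)
    wc, valid = window_codes(codes, table.k)
    w = table.values[wc]
    w[~valid] = 0.0
    n_missing = int((~table.present[wc[valid]]).sum())
    if n_missing:
        table.n_missing_lookups += n_missing
    # fsum: order-independent, correctly rounded — keeps scores reproducible
    return math.fsum(w.tolist()), int((~valid).sum()), n_missing


def affected_windows(positions: Iterable[int], L: int, k: int) -> np.ndarray:
    """Sorted unique window starts whose k-window covers any given position."""
    starts: set[int] = set()
    n_win = L - k + 1
    for p in positions:
        lo = max(0, p - k + 1)
        hi = min(p, n_win - 1)
        starts.update(range(lo, hi + 1))
    return np.array(sorted(starts), dtype=np.int64)


def delta_svm(ancestor: str, focal: str, table: KmerWeightTable) -> float:
    """deltaSVM: affinity score of the focal sequence minus the ancestral one.

    Positive values mean the substitutions increased predicted binding
    affinity.  Computed incrementally over the windows that cover a differing
    position; because unaffected windows contribute an exact 0.0 difference,
    this equals the full-rescore definition exactly (fsum is correctly
    rounded).  Sequences must be equal length: the model covers substitutions
    only, indel columns are removed upstream.
    """
    if len(ancestor) != len(focal):
        raise ValueError(
            f"ancestor and focal lengths differ ({len(ancestor)} != {len(focal)}); "
            "indel sites must be excluded upstream"
        )
    k = table.k
    ca = encode_sequence(ancestor)
    cf = encode_sequence(focal)
    diff = np.flatnonzero(ca != cf)
    if diff.size == 0:
        return 0.0
    wa, va = window_codes(ca, k)
    wf, vf = window_codes(cf, k)
    starts = affected_windows(diff.tolist(), len(ancestor), k)
    w_anc = table.values[wa[starts]]
    w_anc[~va[starts]] = 0.0
    w_foc = table.values[wf[starts]]
    w_foc[~vf[starts]] = 0.0
    return math.fsum((w_foc - w_anc).tolist())
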