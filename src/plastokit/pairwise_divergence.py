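"""Pairwise alignment of homologous plastome regions and the
transition/transversion substitution spectrum.

Alignment is global with affine gap costs, tuned for the >95%-identity
sequences expected of congeneric chloroplast regions.  Inputs longer than
~20 kb are split by a chain of shared unique 31-mer anchors and aligned
piecewise; for near-identical sequences this reduces the problem to short
stretches around the actual differences and keeps the result deterministic.
"""

from __future__ import annotations

import logging
from bisect import bisect_left
from dataclasses import dataclass, field

from Bio import Align, SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .errors import AlignmentError

logger = logging.getLogger(__name__)

PURINES = frozenset("AG")
PYRIMIDINES = frozenset("CT")

#: the six unordered base pairs, transitions first
PAIR_LABELS = ("A/G", "C/T", "A/C", "A/T", "C/G", "G/T")


@dataclass
class RegionAlignment:
    """A two-row global alignment of one homologous region."""

    label: str
    rows: tuple[str, str]
    sources: tuple[str, str] = ("seq_a", "seq_b")
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        a, b = self.rows
        if len(a) != len(b):
            raise AlignmentError(f"{self.label}: rows differ in length")
        if any(x == "-" and y == "-" for x, y in zip(a, b)):
            raise AlignmentError(f"{self.label}: all-gap column")

    @property
    def length(self) -> int:
        return len(self.rows[0])


def _make_aligner(match, mismatch, gap_open, gap_extend) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = match
    aligner.mismatch_score = mismatch
    aligner.open_gap_score = -abs(gap_open)
    aligner.extend_gap_score = -abs(gap_extend)
    return aligner


def _align_small(a: str, b: str, aligner) -> tuple[str, str]:
    if not a and not b:
        return ("", "")
    if not a:
        return ("-" * len(b), b)
    if not b:
        return (a, "-" * len(a))
    aln = aligner.align(a, b)[0]
    return (str(aln[0]), str(aln[1]))


def _unique_kmers(s: str, k: int) -> dict[str, int]:
    seen: dict[str, int] = {}
    dup: set[str] = set()
    for i in range(len(s) - k + 1):
        km = s[i : i + k]
        if km in seen:
            dup.add(km)
        else:
            seen[km] = i
    for km in dup:
        del seen[km]
    return seen


def _anchor_chain(a: str, b: str, k: int) -> list[tuple[int, int]]:
    """Co-linear chain of shared unique k-mer start pairs (strictly increasing
    in both sequences), via longest-increasing-subsequence on b-positions."""
    ka = _unique_kmers(a, k)
    kb = _unique_kmers(b, k)
    shared = [(ia, kb[km]) for km, ia in ka.items() if km in kb]
    shared.sort()
    tails: list[int] = []          # tails[i] = smallest possible b-end of LIS of length i+1
    tail_idx: list[int] = []
    parents = [-1] * len(shared)
    for idx, (_, jb) in enumerate(shared):
        pos = bisect_left(tails, jb)
        if pos == len(tails):
            tails.append(jb)
            tail_idx.append(idx)
        else:
            tails[pos] = jb
            tail_idx[pos] = idx
        parents[idx] = tail_idx[pos - 1] if pos > 0 else -1
    if not tail_idx:
        return []
    chain = []
    cur = tail_idx[-1]
    while cur != -1:
        chain.append(shared[cur])
        cur = parents[cur]
    chain.reverse()
    return chain


def align_pair(
    seq_a: str,
    seq_b: str,
    label: str = "pair",
    match: float = 2,
    mismatch: float = -3,
    gap_open: float = 10,
    gap_extend: float = 0.5,
    anchor_threshold: int = 20_000,
    anchor_k: int = 31,
) -> RegionAlignment:
    """Global affine-gap alignment of two homologous DNA sequences.

    Below ``anchor_threshold`` the sequences go straight to the dynamic
    program; above it, shared unique ``anchor_k``-mers are chained and only
    the stretches between consecutive anchors are aligned, then concatenated.
    Deterministic for fixed inputs.  Raises :class:`AlignmentError` on empty
    input or when no consistent anchor chain exists (likely rearrangement).
    """
    if not seq_a or not seq_b:
        raise AlignmentError(f"{label}: empty input sequence")
    aligner = _make_aligner(match, mismatch, gap_open, gap_extend)
    if max(len(seq_a), len(seq_b)) <= anchor_threshold:
        rows = _align_small(seq_a, seq_b, aligner)
        return RegionAlignment(label=label, rows=rows)

    chain = _anchor_chain(seq_a, seq_b, anchor_k)
    if len(chain) < 2:
        raise AlignmentError(
            f"{label}: no consistent anchor chain for long inputs; the regions may be "
            "rearranged - align the whole region with a smaller anchor_threshold"
        )
    rows_a: list[str] = []
    rows_b: list[str] = []
    prev_a = prev_b = 0
    for ia, jb in chain:
        if ia < prev_a or jb < prev_b:
            continue  # anchor overlaps the previous one; keep the earlier
        ga, gb = seq_a[prev_a:ia], seq_b[prev_b:jb]
        if ga == gb:
            rows_a.append(ga)
            rows_b.append(gb)
        else:
            if max(len(ga), len(gb)) > anchor_threshold:
                raise AlignmentError(f"{label}: inter-anchor gap too large; likely rearrangement")
            sub = _align_small(ga, gb, aligner)
            rows_a.append(sub[0])
            rows_b.append(sub[1])
        rows_a.append(seq_a[ia : ia + anchor_k])
        rows_b.append(seq_b[jb : jb + anchor_k])
        prev_a, prev_b = ia + anchor_k, jb + anchor_k
    tail = _align_small(seq_a[prev_a:], seq_b[prev_b:], aligner)
    rows_a.append(tail[0])
    rows_b.append(tail[1])
    return RegionAlignment(label=label, rows=("".join(rows_a), "".join(rows_b)))


@dataclass
class SubstitutionSpectrum:
    """Unordered mismatch-pair counts with transition/transversion totals."""

    label: str
    pair_counts: dict[str, int]
    ts: int
    tv: int
    ratio: float | None  # None (reported NA) when tv == 0

    @property
    def total(self) -> int:
        return self.ts + self.tv


def classify_pair(x: str, y: str) -> str:
    """Unordered pair label for two distinct bases, e.g. ('G','A') -> 'A/G'."""
    a, b = sorted((x, y))
    return f"{a}/{b}"


def is_transition(x: str, y: str) -> bool:
    return (x in PURINES and y in PURINES) or (x in PYRIMIDINES and y in PYRIMIDINES)


def substitution_spectrum(alignment: RegionAlignment) -> SubstitutionSpectrum:
    """Count every column with two distinct A/C/G/T bases as its unordered
    pair; columns containing a gap or N are excluded.  Ts = A/G + C/T."""
    a, b = alignment.rows
    counts = dict.fromkeys(PAIR_LABELS, 0)
    for x, y in zip(a, b):
        if x == y or x not in "ACGT" or y not in "ACGT":
            continue
        counts[classify_pair(x, y)] += 1
    ts = counts["A/G"] + counts["C/T"]
    tv = counts["A/C"] + counts["A/T"] + counts["C/G"] + counts["G/T"]
    return SubstitutionSpectrum(
        label=alignment.label,
        pair_counts=counts,
        ts=ts,
        tv=tv,
        ratio=(ts / tv) if tv else None,
    )


def write_alignment_fasta(alignment: RegionAlignment, path) -> None:
    recs = [
        SeqRecord(Seq(row), id=src, description=alignment.label)
        for row, src in zip(alignment.rows, alignment.sources)
    ]
    SeqIO.write(recs, path, "fasta")


def read_alignment_fasta(path, label: str | None = None) -> RegionAlignment:
    recs = list(SeqIO.parse(path, "fasta"))
    if len(recs) != 2:
        raise AlignmentError(f"{path}: expected exactly 2 aligned rows, got {len(recs)}")
    return RegionAlignment(
        label=label or recs[0].description or "pair",
        rows=(str(recs[0].seq).upper(), str(recs[1].seq).upper()),
        sources=(recs[0].id, recs[1].id),
    )
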