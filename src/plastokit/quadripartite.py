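"""Inverted-repeat detection and LSC/SSC/IR partitioning of circular plastomes.

Plastid genomes of most land plants carry two exact reverse-complementary
copies of a ~25 kb segment (IRa/IRb) separating a large and a small
single-copy region (LSC/SSC).  Detection here is exact-match only: seeds are
k-mer anchors between the genome and its reverse complement, extended
base-by-base across the circular sequence to the longest exact match.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import QuadripartiteError
from .genome_io import PlastomeRecord, extract_feature_sequence, revcomp, rotate_record, flip_record

logger = logging.getLogger(__name__)

_COMP = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}


@dataclass(frozen=True)
class CircularInterval:
    """``(start, length)`` arc on a circle; ``start`` in [0, genome length)."""

    start: int
    length: int

    def end(self, n: int) -> int:
        """Exclusive end position modulo ``n``."""
        return (self.start + self.length) % n

    def contains(self, pos: int, n: int) -> bool:
        return (pos - self.start) % n < self.length


def circular_slice(sequence: str, interval: CircularInterval) -> str:
    n = len(sequence)
    s, ln = interval.start, interval.length
    if s + ln <= n:
        return sequence[s : s + ln]
    return sequence[s:] + sequence[: (s + ln) % n]


@dataclass(frozen=True)
class QuadripartitePartition:
    """Coordinates of the four plastome regions, in genome order LSC-IRb-SSC-IRa."""

    lsc: CircularInterval
    irb: CircularInterval
    ssc: CircularInterval
    ira: CircularInterval
    genome_length: int

    @property
    def lengths(self) -> tuple[int, int, int, int]:
        """(LSC, SSC, IRa, IRb) lengths in bp."""
        return (self.lsc.length, self.ssc.length, self.ira.length, self.irb.length)

    def region_of(self, pos: int) -> str:
        for label, iv in (("LSC", self.lsc), ("IRb", self.irb), ("SSC", self.ssc), ("IRa", self.ira)):
            if iv.contains(pos, self.genome_length):
                return label
        raise ValueError(f"position {pos} outside genome of length {self.genome_length}")

    def region_of_interval(self, start: int, end: int) -> str | None:
        """Region fully containing [start, end), or None if it straddles a junction."""
        r = self.region_of(start)
        return r if self.region_of((end - 1) % self.genome_length) == r else None


def _validate(partition: QuadripartitePartition, sequence: str) -> None:
    n = len(sequence)
    if sum(iv.length for iv in (partition.lsc, partition.irb, partition.ssc, partition.ira)) != n:
        raise QuadripartiteError("partition lengths do not sum to genome length")
    if partition.ira.length != partition.irb.length:
        raise QuadripartiteError("IR copies differ in length")
    ira = circular_slice(sequence, partition.ira)
    irb = circular_slice(sequence, partition.irb)
    if revcomp(ira) != irb:
        raise QuadripartiteError("IRa is not the exact reverse complement of IRb")


def detect_inverted_repeats(
    record: PlastomeRecord, min_ir_len: int = 10_000, k: int = 25
) -> QuadripartitePartition:
    """Find the maximal pair of exact reverse-complementary repeats and
    partition the genome into LSC/IRb/SSC/IRa.

    Seeds are ``k``-mer matches between the sequence and its reverse
    complement, extended outward base-by-base across the circular sequence.
    The longer single-copy gap is called LSC; the IR that follows LSC in
    genome order is IRb.

    Raises :class:`QuadripartiteError` when no repeat pair reaches
    ``min_ir_len`` or when the best candidate pair overlaps itself.
    """
    s = record.sequence
    n = len(s)
    if min_ir_len < 1000:
        raise QuadripartiteError("min_ir_len must be >= 1000")
    if n < 2 * min_ir_len + 2:
        raise QuadripartiteError("no quadripartite structure: sequence too short")

    ext = s + s[: k - 1]  # circular k-mer windows
    index: dict[str, list[int]] = {}
    for i in range(n):
        index.setdefault(ext[i : i + k], []).append(i)

    # A pair (a, b, m): s[a:a+m] == revcomp(s[b:b+m]) circularly.  Every seed
    # (i, j) of that pair satisfies (i + j) % n == (a + b + m - k) % n, so one
    # integer keys the whole anti-diagonal.
    found: dict[int, tuple[int, int, int]] = {}
    best: tuple[int, int, int] | None = None
    for j in range(n):
        kmer_rc = revcomp(ext[j : j + k])
        for i in index.get(kmer_rc, ()):
            diag = (i + j) % n
            hit = found.get(diag)
            if hit and ((i - hit[0]) % n <= hit[2] - k or (i - hit[1]) % n <= hit[2] - k):
                continue  # seed lies inside an already-extended pair (either copy)
            a, b, m = _extend(s, n, i, j, k)
            found[diag] = (a, b, m)
            if best is None or m > best[2]:
                best = (a, b, m)

    if best is None or best[2] < min_ir_len:
        raise QuadripartiteError(
            f"no quadripartite structure: no inverted repeat of >= {min_ir_len} bp"
        )
    a, b, m = best
    if m > n // 2:
        raise QuadripartiteError("candidate inverted repeats overlap")
    # gaps between the two repeat arcs
    gap1_start, gap1_len = (a + m) % n, (b - a - m) % n
    gap2_start, gap2_len = (b + m) % n, (a - b - m) % n
    if gap1_len == 0 or gap2_len == 0:
        raise QuadripartiteError("candidate inverted repeats are adjacent; no single-copy gaps")
    if gap1_len > gap2_len or (gap1_len == gap2_len and gap1_start < gap2_start):
        lsc = CircularInterval(gap1_start, gap1_len)
        irb = CircularInterval(b, m)
        ssc = CircularInterval(gap2_start, gap2_len)
        ira = CircularInterval(a, m)
    else:
        lsc = CircularInterval(gap2_start, gap2_len)
        irb = CircularInterval(a, m)
        ssc = CircularInterval(gap1_start, gap1_len)
        ira = CircularInterval(b, m)
    partition = QuadripartitePartition(lsc=lsc, irb=irb, ssc=ssc, ira=ira, genome_length=n)
    _validate(partition, s)
    return partition


def _extend(s: str, n: int, i: int, j: int, k: int) -> tuple[int, int, int]:
    """Extend seed s[i:i+k] == revcomp(s[j:j+k]) to the maximal exact pair."""
    # left of i pairs with right of j
    left = 0
    while left < n:
        ci = s[(i - left - 1) % n]
        cj = s[(j + k + left) % n]
        if _COMP[ci] != cj or ci == "N":
            break
        left += 1
    right = 0
    while right < n:
        ci = s[(i + k + right) % n]
        cj = s[(j - right - 1) % n]
        if _COMP[ci] != cj or ci == "N":
            break
        right += 1
    m = k + left + right
    a = (i - left) % n
    b = (j - right) % n
    if m > n:  # degenerate: whole circle palindromic
        m = n
    return a, b, m


def canonical_rotation(
    record: PlastomeRecord,
    partition: QuadripartitePartition,
    normalize_orientation: bool = False,
) -> PlastomeRecord:
    """Rotate a circular record so position 0 is the first base of LSC
    (region order LSC-IRb-SSC-IRa).

    With ``normalize_orientation`` the reverse-complemented genome is also
    canonicalized and the lexicographically smaller of the two rotated
    sequences is returned, making the result invariant to strand flips.
    Without it the operation is a pure rotation (identity on an
    already-canonical record).
    """
    rotated = rotate_record(record, partition.lsc.start)
    if not normalize_orientation:
        return rotated
    flipped = flip_record(record)
    flipped_part = detect_inverted_repeats(flipped, min_ir_len=min(10_000, partition.ira.length))
    rotated_flip = rotate_record(flipped, flipped_part.lsc.start)
    return min(rotated, rotated_flip, key=lambda r: r.sequence)


@dataclass(frozen=True)
class GCProfile:
    """GC fractions by region and by gene class (None where a class is absent)."""

    total: float
    lsc: float
    ssc: float
    ir: float
    per_class: dict  # {"CDS"|"tRNA"|"rRNA"|"all_genes": float | None}


def gc_fraction(seq: str) -> float | None:
    """GC over unambiguous bases; None for a sequence with no A/C/G/T."""
    gc = seq.count("G") + seq.count("C")
    acgt = gc + seq.count("A") + seq.count("T")
    return gc / acgt if acgt else None


def gc_profile(record: PlastomeRecord, partition: QuadripartitePartition) -> GCProfile:
    """Regional and gene-class GC content.

    Class values use the concatenated spliced sequences of unique genes (one
    copy per duplicated gene); the IR value is computed on one IR copy, the
    two being exact reverse complements.  N bases are excluded throughout.
    """
    seq = record.sequence
    per_class: dict[str, float | None] = {}
    seen: set[tuple[str, str]] = set()
    class_chunks: dict[str, list[str]] = {"CDS": [], "tRNA": [], "rRNA": []}
    for feat in record.features:
        key = (feat.name, feat.kind)
        if key in seen:
            continue
        seen.add(key)
        class_chunks[feat.kind].append(extract_feature_sequence(record, feat))
    all_genes: list[str] = []
    for kind, chunks in class_chunks.items():
        per_class[kind] = gc_fraction("".join(chunks)) if chunks else None
        all_genes.extend(chunks)
    per_class["all_genes"] = gc_fraction("".join(all_genes)) if all_genes else None
    return GCProfile(
        total=gc_fraction(seq),
        lsc=gc_fraction(circular_slice(seq, partition.lsc)),
        ssc=gc_fraction(circular_slice(seq, partition.ssc)),
        ir=gc_fraction(circular_slice(seq, partition.ira)),
        per_class=per_class,
    )
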