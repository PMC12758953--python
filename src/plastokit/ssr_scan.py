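"""Perfect-microsatellite (SSR) detection with MISA-style thresholds.

Only perfect tandem repeats of 1-6 bp units are reported, each at its
smallest period (a run of A's is one mononucleotide locus, never an "AA"
dinucleotide locus).  Default minimum repeat numbers follow the common
plastome survey settings: 10 (mono), 5 (di), 4 (tri), 3 (tetra/penta/hexa).
Compound-SSR merging is deliberately not implemented; loci are reported
individually.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from .errors import ConfigError
from .genome_io import revcomp
from .quadripartite import QuadripartitePartition

DEFAULT_THRESHOLDS: dict[int, int] = {1: 10, 2: 5, 3: 4, 4: 3, 5: 3, 6: 3}


@dataclass(frozen=True)
class SSRLocus:
    """One maximal perfect tandem repeat (0-based half-open coordinates)."""

    start: int
    end: int
    unit: str
    repeats: int
    region: str | None = None

    @property
    def length(self) -> int:
        return self.end - self.start


def smallest_period(unit: str) -> int:
    """Smallest p such that the unit is a repetition of its first p bases."""
    n = len(unit)
    for p in range(1, n):
        if n % p == 0 and unit == unit[:p] * (n // p):
            return p
    return n


def motif_class(unit: str) -> str:
    """Canonical motif class: lexicographically smallest rotation over the
    unit and its reverse complement, rendered "canon/revcomp(canon)".

    This is the MISA-style grouping under which e.g. "T" -> "A/T" and
    "AAG"/"CTT" collapse to one class.
    """
    candidates = []
    for u in (unit, revcomp(unit)):
        candidates.extend(u[i:] + u[:i] for i in range(len(u)))
    canon = min(candidates)
    return f"{canon}/{revcomp(canon)}"


def _check_thresholds(thresholds: dict[int, int]) -> None:
    missing = [p for p in range(1, 7) if p not in thresholds]
    if missing:
        raise ConfigError(f"threshold map missing unit lengths {missing}")
    if any(t < 1 for t in thresholds.values()):
        raise ConfigError("thresholds must be >= 1")


def find_ssrs(sequence: str, thresholds: dict[int, int] | None = None) -> list[SSRLocus]:
    """All maximal perfect tandem repeats of period 1-6 meeting the thresholds.

    A locus is reported only at the smallest period of its unit, starts where
    its maximal run starts, and spans whole unit copies.  N (or any non-ACGT
    symbol) breaks every run.  Loci are returned sorted by start.
    """
    thresholds = DEFAULT_THRESHOLDS if thresholds is None else thresholds
    _check_thresholds(thresholds)
    n = len(sequence)
    loci: list[SSRLocus] = []
    if n == 0:
        return loci
    arr = np.frombuffer(sequence.encode("ascii"), dtype=np.uint8)
    valid = (arr == ord("A")) | (arr == ord("C")) | (arr == ord("G")) | (arr == ord("T"))
    for p in range(1, 7):
        min_len = thresholds[p] * p
        if n < min_len:
            continue
        eq = (arr[p:] == arr[:-p]) & valid[p:] & valid[:-p]
        # maximal runs of True in eq: eq[i] means sequence[i+p] == sequence[i]
        padded = np.concatenate(([False], eq, [False]))
        edges = np.flatnonzero(padded[1:] != padded[:-1])
        for run_start, run_end in zip(edges[::2], edges[1::2]):
            total = (run_end - run_start) + p  # bases covered by the run
            repeats = total // p
            if repeats < thresholds[p]:
                continue
            unit = sequence[run_start : run_start + p]
            if smallest_period(unit) != p:
                continue  # reported at its smaller period instead
            loci.append(
                SSRLocus(start=int(run_start), end=int(run_start + repeats * p),
                         unit=unit, repeats=int(repeats))
            )
    loci.sort(key=lambda l: (l.start, len(l.unit)))
    return loci


def _drop_covered(loci: list[SSRLocus], n: int) -> list[SSRLocus]:
    """Remove loci whose circular footprint is contained in a longer locus of
    the same period (linear-scan duplicates of origin-spanning runs)."""
    out = []
    for l1 in loci:
        span1 = {(l1.start + i) % n for i in range(l1.length)}
        contained = any(
            l2 is not l1
            and len(l2.unit) == len(l1.unit)
            and l2.length >= l1.length
            and span1 <= {(l2.start + i) % n for i in range(l2.length)}
            for l2 in loci
        )
        if not contained:
            out.append(l1)
    return out


def find_ssrs_circular(sequence: str, thresholds: dict[int, int] | None = None,
                       overlap: int = 600) -> list[SSRLocus]:
    """SSR scan honouring circularity: loci spanning the origin are found by
    scanning an overlap window appended past the origin and de-duplicating.

    Returned coordinates are modulo the genome length (``end`` may exceed the
    length for an origin-spanning locus).
    """
    n = len(sequence)
    window = min(overlap, n)
    loci = [l for l in find_ssrs(sequence + sequence[:window], thresholds) if l.start < n]
    if any(l.end > n + window - 6 for l in loci):
        # a run might continue past the scan window; re-derive on a doubled
        # sequence to get the true extent (rare, very long origin repeat)
        loci = [l for l in find_ssrs(sequence + sequence, thresholds) if l.start < n]
    return sorted(_drop_covered(loci, n), key=lambda l: (l.start, len(l.unit)))


def assign_regions(loci: list[SSRLocus], partition: QuadripartitePartition) -> list[SSRLocus]:
    """Label each locus with the quadripartite region of its start position."""
    return [replace(l, region=partition.region_of(l.start % partition.genome_length))
            for l in loci]


def ssr_summary(loci: list[SSRLocus]) -> dict[str, pd.DataFrame]:
    """Contingency summaries: counts by unit length, motif class and region."""
    by_type = Counter(len(l.unit) for l in loci)
    type_rows = [{"unit_length": p, "count": by_type.get(p, 0)} for p in range(1, 7)]
    by_class = Counter(motif_class(l.unit) for l in loci)
    class_rows = [{"motif_class": c, "count": k}
                  for c, k in sorted(by_class.items(), key=lambda kv: (-kv[1], kv[0]))]
    by_region = Counter(l.region or "NA" for l in loci)
    region_rows = [{"region": r, "count": k} for r, k in sorted(by_region.items())]
    return {
        "by_type": pd.DataFrame(type_rows),
        "by_class": pd.DataFrame(class_rows, columns=["motif_class", "count"]),
        "by_region": pd.DataFrame(region_rows, columns=["region", "count"]),
        "total": pd.DataFrame([{"total_loci": len(loci)}]),
    }
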