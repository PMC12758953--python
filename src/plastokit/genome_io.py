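"""Annotated plastome records: GenBank/FASTA input-output and feature arithmetic.

The in-memory model is deliberately small: a :class:`PlastomeRecord` holds an
uppercase DNA string plus a flat list of :class:`FeatureAnnotation` objects.
All coordinates are 0-based half-open; the GenBank convention (1-based,
inclusive) exists only at the file boundary.  Feature parts are kept in
transcription order, so extracting a spliced gene is a plain concatenation of
its (strand-resolved) parts.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqFeature import CompoundLocation, SeqFeature, SimpleLocation
from Bio.SeqRecord import SeqRecord

from .errors import CoordinateError, ParseError

logger = logging.getLogger(__name__)

VALID_BASES = frozenset("ACGTN")
FEATURE_KINDS = ("CDS", "tRNA", "rRNA")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement over the {A,C,G,T,N} alphabet."""
    return seq.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class FeatureAnnotation:
    """One gene copy: symbol, class and exon intervals in transcription order.

    ``parts`` is an ordered tuple of ``(start, end, strand)`` with 0-based
    half-open coordinates; the first part holds the first transcribed exon.
    ``copy_index`` disambiguates multi-copy genes (0, 1, ... in genome order).
    """

    name: str
    kind: str
    parts: tuple[tuple[int, int, str], ...]
    copy_index: int = 0

    def __post_init__(self):
        if self.kind not in FEATURE_KINDS:
            raise ValueError(f"unknown feature kind {self.kind!r}")
        if not self.parts:
            raise ValueError(f"feature {self.name}: no parts")
        for start, end, strand in self.parts:
            if start >= end:
                raise ValueError(f"feature {self.name}: empty part {start}..{end}")
            if strand not in "+-":
                raise ValueError(f"feature {self.name}: bad strand {strand!r}")

    @property
    def span(self) -> tuple[int, int]:
        """Smallest genomic interval containing every part (min start, max end)."""
        return (min(p[0] for p in self.parts), max(p[1] for p in self.parts))

    @property
    def total_length(self) -> int:
        return sum(end - start for start, end, _ in self.parts)


@dataclass
class PlastomeRecord:
    """A (usually circular) plastid genome with its gene annotations."""

    id: str
    sequence: str
    circular: bool = True
    features: list[FeatureAnnotation] = field(default_factory=list)

    def __post_init__(self):
        bad = set(self.sequence) - VALID_BASES
        if bad:
            raise ParseError(
                f"{self.id}: sequence contains unsupported symbols {sorted(bad)}; "
                "only A/C/G/T/N are accepted"
            )
        for feat in self.features:
            for start, end, _ in feat.parts:
                if start < 0 or end > len(self.sequence):
                    raise CoordinateError(
                        f"feature {feat.name} part {start}..{end} outside "
                        f"sequence of length {len(self.sequence)}"
                    )

    @property
    def length(self) -> int:
        return len(self.sequence)

    def __eq__(self, other) -> bool:
        if not isinstance(other, PlastomeRecord):
            return NotImplemented
        return (
            self.id == other.id
            and self.sequence == other.sequence
            and self.circular == other.circular
            and self.features == other.features
        )


def _parts_from_location(location) -> tuple[tuple[int, int, str], ...]:
    parts = []
    for p in location.parts:
        strand = "-" if p.strand == -1 else "+"
        parts.append((int(p.start), int(p.end), strand))
    return tuple(parts)


def read_genbank(path) -> PlastomeRecord:
    """Read an annotated plastome from a GenBank flat file.

    Captures every CDS/tRNA/rRNA feature, preserving multi-interval joins in
    transcription order and complement strands.  Gene symbols come from the
    ``gene`` qualifier (falling back to ``locus_tag`` / ``product``).
    """
    try:
        seqrec = SeqIO.read(path, "genbank")
    except ValueError as exc:
        raise ParseError(f"{path}: not a readable GenBank record ({exc})") from exc
    seq = str(seqrec.seq).upper()
    if not seq:
        raise ParseError(f"{path}: GenBank record has no sequence block")
    circular = seqrec.annotations.get("topology", "circular") == "circular"

    features: list[FeatureAnnotation] = []
    copy_counter: dict[tuple[str, str], int] = {}
    for f in seqrec.features:
        if f.type not in FEATURE_KINDS:
            continue
        quals = f.qualifiers
        name = (quals.get("gene") or quals.get("locus_tag") or quals.get("product") or ["?"])[0]
        parts = _parts_from_location(f.location)
        for start, end, _ in parts:
            if start < 0 or end > len(seq):
                raise CoordinateError(
                    f"{path}: feature {name} interval {start}..{end} outside "
                    f"sequence of length {len(seq)}"
                )
        key = (name, f.type)
        idx = copy_counter.get(key, 0)
        copy_counter[key] = idx + 1
        features.append(FeatureAnnotation(name=name, kind=f.type, parts=parts, copy_index=idx))

    return PlastomeRecord(id=seqrec.id, sequence=seq, circular=circular, features=features)


def _location_from_parts(parts) -> SimpleLocation | CompoundLocation:
    locs = [
        SimpleLocation(start, end, -1 if strand == "-" else 1)
        for start, end, strand in parts
    ]
    if len(locs) == 1:
        return locs[0]
    return CompoundLocation(locs)


def write_genbank(record: PlastomeRecord, path) -> None:
    """Write a record back to GenBank; ``read_genbank`` round-trips it exactly."""
    seqrec = SeqRecord(
        Seq(record.sequence),
        id=record.id,
        name=record.id.split(".")[0][:16],
        description="plastome",
        annotations={
            "molecule_type": "DNA",
            "topology": "circular" if record.circular else "linear",
        },
    )
    for feat in record.features:
        seqrec.features.append(
            SeqFeature(
                _location_from_parts(feat.parts),
                type=feat.kind,
                qualifiers={"gene": [feat.name]},
            )
        )
    SeqIO.write(seqrec, path, "genbank")


def read_fasta(path) -> PlastomeRecord:
    """Read a single-sequence FASTA as an unannotated (circular) record."""
    seqrec = SeqIO.read(path, "fasta")
    return PlastomeRecord(id=seqrec.id, sequence=str(seqrec.seq).upper())


def write_fasta(record: PlastomeRecord, path) -> None:
    SeqIO.write(SeqRecord(Seq(record.sequence), id=record.id, description=""), path, "fasta")


def extract_feature_sequence(record: PlastomeRecord, feature: FeatureAnnotation) -> str:
    """Spliced sequence of a feature: parts concatenated in transcription order,
    minus-strand parts reverse-complemented.

    For a CDS the result therefore starts with the annotated first exon base.
    """
    chunks = []
    for start, end, strand in feature.parts:
        if end > record.length:
            raise CoordinateError(
                f"feature {feature.name}: part {start}..{end} beyond sequence end"
            )
        chunk = record.sequence[start:end]
        chunks.append(revcomp(chunk) if strand == "-" else chunk)
    out = "".join(chunks)
    if not out:
        raise CoordinateError(f"feature {feature.name}: zero-length extraction")
    return out


def gene_extent_blocks(record: PlastomeRecord) -> list[tuple[int, int, str]]:
    """Genomic extent blocks of every gene copy, introns included.

    A cis gene contributes one block spanning min(start)..max(end) of its
    exons; a trans-spliced copy (parts on both strands) contributes one block
    per part, since its exons are genuinely distant.
    """
    blocks = []
    for feat in record.features:
        strands = {p[2] for p in feat.parts}
        if len(strands) == 1:
            lo, hi = feat.span
            blocks.append((lo, hi, feat.name))
        else:
            for start, end, _ in feat.parts:
                blocks.append((start, end, feat.name))
    return blocks


@dataclass(frozen=True)
class Spacer:
    """A named intergenic interval (0-based half-open; may wrap the origin)."""

    name: str
    start: int
    end: int  # may exceed genome length for the origin-wrapping closure spacer

    @property
    def length(self) -> int:
        return self.end - self.start


def list_intergenic_spacers(record: PlastomeRecord) -> list[Spacer]:
    """Maximal intervals strictly between consecutive gene extents.

    Overlapping or touching genes are merged into one occupied cluster and
    yield no spacer between them.  For a circular record the closure interval
    between the last and first cluster is included; its ``end`` exceeds the
    genome length so that ``length`` stays meaningful.
    """
    blocks = sorted(gene_extent_blocks(record))
    if len(blocks) < 2:
        return []
    # merge into occupied clusters, remembering boundary gene names
    clusters: list[list] = []  # [start, end, first_name, last_name]
    for start, end, name in blocks:
        if clusters and start <= clusters[-1][1]:
            cl = clusters[-1]
            if end > cl[1]:
                cl[1] = end
                cl[3] = name
        else:
            clusters.append([start, end, name, name])
    spacers = []
    for prev, nxt in zip(clusters, clusters[1:]):
        if nxt[0] > prev[1]:
            spacers.append(Spacer(f"{prev[3]}-{nxt[2]}", prev[1], nxt[0]))
    if record.circular and len(clusters) >= 1:
        last, first = clusters[-1], clusters[0]
        gap = (first[0] + record.length) - last[1]
        if gap > 0 and not (len(clusters) == 1 and gap == record.length):
            spacers.append(Spacer(f"{last[3]}-{first[2]}", last[1], first[0] + record.length))
    return spacers


def rotate_record(record: PlastomeRecord, shift: int) -> PlastomeRecord:
    """Rotate a circular record so that old position ``shift`` becomes 0.

    Feature parts that would straddle the new origin are split in two.
    """
    n = record.length
    shift %= n
    if shift == 0:
        return record
    seq = record.sequence[shift:] + record.sequence[:shift]
    feats = []
    for feat in record.features:
        new_parts = []
        for start, end, strand in feat.parts:
            s = (start - shift) % n
            e = s + (end - start)
            if e <= n:
                new_parts.append((s, e, strand))
            else:  # straddles new origin: split, keeping transcription order
                first = (s, n, strand)
                second = (0, e - n, strand)
                if strand == "-":
                    new_parts.extend([second, first])
                else:
                    new_parts.extend([first, second])
        feats.append(replace(feat, parts=tuple(new_parts)))
    return PlastomeRecord(id=record.id, sequence=seq, circular=record.circular, features=feats)


def flip_record(record: PlastomeRecord) -> PlastomeRecord:
    """Reverse-complement a record, mirroring all feature coordinates."""
    n = record.length
    seq = revcomp(record.sequence)
    feats = []
    for feat in record.features:
        new_parts = tuple(
            (n - end, n - start, "-" if strand == "+" else "+")
            for start, end, strand in feat.parts
        )
        feats.append(replace(feat, parts=new_parts))
    return PlastomeRecord(id=record.id, sequence=seq, circular=record.circular, features=feats)
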