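"""Per-feature nucleotide diversity between two plastomes and ranking of
polymorphic loci as candidate barcoding markers.

For two sequences Nei's nucleotide diversity reduces to S/L: the number of
substitution columns divided by the gap-free alignment length.  No
multiple-hit correction is applied; the statistics are the directly
observable alignment quantities (substitutions, indel columns, lengths,
missing-data percentage)."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import pandas as pd

from .errors import PlastokitError
from .genome_io import PlastomeRecord, extract_feature_sequence, list_intergenic_spacers, revcomp
from .pairwise_divergence import RegionAlignment, align_pair, substitution_spectrum

logger = logging.getLogger(__name__)

CATEGORIES = ("CDS", "tRNA", "rRNA", "intron", "IGS")


@dataclass
class DiversityRecord:
    """Alignment statistics of one homologous region (two genomes)."""

    region_name: str
    category: str
    pi: float | None           # None when no gap-free columns exist
    substitutions: int
    indel_columns: int
    length_excl_indels: int
    alignment_length: int
    missing_pct: float

    def as_row(self) -> dict:
        return {
            "region": self.region_name,
            "category": self.category,
            "nucleotide_diversity": round(self.pi, 5) if self.pi is not None else None,
            "substitutions": self.substitutions,
            "indels": self.indel_columns,
            "length_excl_indels": self.length_excl_indels,
            "alignment_length": self.alignment_length,
            "missing_pct": round(self.missing_pct, 1),
        }


def diversity_stats(alignment: RegionAlignment, name: str, category: str) -> DiversityRecord:
    """Substitution, indel-column and diversity statistics of one alignment.

    substitutions = columns with two distinct A/C/G/T bases; indel columns =
    columns containing at least one gap; pi = substitutions / gap-free
    columns; missing % = 100 * indel columns / alignment length.
    """
    if category not in CATEGORIES:
        raise PlastokitError(f"unknown category {category!r}")
    a, b = alignment.rows
    indel_cols = sum(1 for x, y in zip(a, b) if x == "-" or y == "-")
    aln_len = alignment.length
    gap_free = aln_len - indel_cols
    subs = substitution_spectrum(alignment).total
    return DiversityRecord(
        region_name=name,
        category=category,
        pi=(subs / gap_free) if gap_free else None,
        substitutions=subs,
        indel_columns=indel_cols,
        length_excl_indels=gap_free,
        alignment_length=aln_len,
        missing_pct=(100.0 * indel_cols / aln_len) if aln_len else 0.0,
    )


def _unique_features(record: PlastomeRecord) -> dict[tuple[str, str], object]:
    """First copy of each (symbol, kind); trans-spliced handled like any other."""
    out = {}
    for feat in record.features:
        out.setdefault((feat.name.strip(), feat.kind), feat)
    return out


def _intron_sequences(record: PlastomeRecord, feat) -> list[str]:
    """Intron sequences of a cis-spliced gene, in transcription order."""
    strands = {p[2] for p in feat.parts}
    if len(strands) != 1 or len(feat.parts) < 2:
        return []
    strand = strands.pop()
    parts = sorted(feat.parts)  # genome order
    introns = []
    for (s1, e1, _), (s2, e2, _) in zip(parts, parts[1:]):
        if s2 <= e1:
            return []  # overlapping exons; annotation unusable for introns
        introns.append(record.sequence[e1:s2])
    if strand == "-":
        introns = [revcomp(i) for i in reversed(introns)]
    return introns


def run_all_features(
    rec_a: PlastomeRecord, rec_b: PlastomeRecord, **align_kwargs
) -> list[DiversityRecord]:
    """Diversity statistics for every homologous feature shared by two genomes.

    Shared CDS/tRNA/rRNA genes (matched by symbol, spliced exons), shared
    introns (gene + intron ordinal) and shared intergenic spacers (matched by
    flanking-gene pair, each genome using its own annotation) are extracted,
    aligned and summarised.  Unmatched features are logged and skipped.
    """
    feats_a = _unique_features(rec_a)
    feats_b = _unique_features(rec_b)
    records: list[DiversityRecord] = []

    shared = sorted(set(feats_a) & set(feats_b))
    for key in sorted(set(feats_a) ^ set(feats_b)):
        logger.info("feature %s/%s present in only one genome; skipped", *key)
    for name, kind in shared:
        fa, fb = feats_a[(name, kind)], feats_b[(name, kind)]
        seq_a = extract_feature_sequence(rec_a, fa)
        seq_b = extract_feature_sequence(rec_b, fb)
        aln = align_pair(seq_a, seq_b, label=name, **align_kwargs)
        records.append(diversity_stats(aln, name, kind))
        introns_a = _intron_sequences(rec_a, fa)
        introns_b = _intron_sequences(rec_b, fb)
        if introns_a and len(introns_a) == len(introns_b):
            for i, (ia, ib) in enumerate(zip(introns_a, introns_b), start=1):
                label = f"{name}_intron{i}" if len(introns_a) > 1 else f"{name}_intron"
                aln = align_pair(ia, ib, label=label, **align_kwargs)
                records.append(diversity_stats(aln, label, "intron"))

    igs_a = {s.name: s for s in list_intergenic_spacers(rec_a)}
    igs_b = {s.name: s for s in list_intergenic_spacers(rec_b)}
    for name in sorted(set(igs_a) & set(igs_b)):
        sa, sb = igs_a[name], igs_b[name]
        seq_a = _spacer_seq(rec_a, sa)
        seq_b = _spacer_seq(rec_b, sb)
        if not seq_a or not seq_b:
            continue
        aln = align_pair(seq_a, seq_b, label=name, **align_kwargs)
        records.append(diversity_stats(aln, name, "IGS"))

    if not records:
        raise PlastokitError(
            f"{rec_a.id} vs {rec_b.id}: no shared features; cannot compute diversity"
        )
    return records


def _spacer_seq(record: PlastomeRecord, spacer) -> str:
    n = record.length
    if spacer.end <= n:
        return record.sequence[spacer.start : spacer.end]
    return record.sequence[spacer.start :] + record.sequence[: spacer.end - n]


def rank_polymorphic(
    records: list[DiversityRecord], top_k: int | None = None
) -> pd.DataFrame:
    """Markers ranked per category by descending pi; ties broken by more
    substitutions, then alphabetical region name."""
    rows = []
    for category in CATEGORIES:
        cat = [r for r in records if r.category == category and r.pi is not None]
        cat.sort(key=lambda r: (-r.pi, -r.substitutions, r.region_name))
        if top_k is not None:
            cat = cat[:top_k]
        for rank, rec in enumerate(cat, start=1):
            row = rec.as_row()
            row["rank_in_category"] = rank
            rows.append(row)
    return pd.DataFrame(rows)


def category_summaries(records: list[DiversityRecord]) -> pd.DataFrame:
    """Mean diversity per category, by both aggregation conventions.

    ``mean_pi`` is the unweighted mean of per-feature pi values;
    ``pooled_pi`` is total substitutions over total gap-free length.  Both
    are reported because they answer different questions (typical feature
    vs. per-site average).
    """
    if not records:
        raise PlastokitError("no diversity records to summarise")
    rows = []
    for category in CATEGORIES:
        cat = [r for r in records if r.category == category and r.pi is not None]
        if not cat:
            continue
        total_l = sum(r.length_excl_indels for r in cat)
        rows.append({
            "category": category,
            "n_features": len(cat),
            "mean_pi": sum(r.pi for r in cat) / len(cat),
            "pooled_pi": (sum(r.substitutions for r in cat) / total_l) if total_l else None,
        })
    return pd.DataFrame(rows)


def diversity_table(records: list[DiversityRecord]) -> pd.DataFrame:
    """Long-format table of every record (plot-ready)."""
    return pd.DataFrame([r.as_row() for r in records])
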