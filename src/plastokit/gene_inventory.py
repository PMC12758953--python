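"""Gene accounting for annotated plastomes: unique genes, IR duplicates,
functional categories, intron counts and cis/trans splicing calls."""

from __future__ import annotations

import logging
from dataclasses import dataclass

from .errors import PlastokitError
from .genome_io import FeatureAnnotation, PlastomeRecord
from .quadripartite import QuadripartitePartition

logger = logging.getLogger(__name__)

# Functional classification of plastid genes: symbol -> (category, group).
# Standard land-plant gene complement; tRNA/rRNA symbols are matched by
# prefix so anticodon suffixes need not be enumerated.
_CDS_GROUPS: dict[str, tuple[str, str]] = {}
for _group, _cat, _names in [
    ("Large subunit of ribosome", "Self-replication",
     ["rpl2", "rpl14", "rpl16", "rpl20", "rpl22", "rpl23", "rpl32", "rpl33", "rpl36"]),
    ("Small subunit of ribosome", "Self-replication",
     ["rps2", "rps3", "rps4", "rps7", "rps8", "rps11", "rps12", "rps14", "rps15",
      "rps16", "rps18", "rps19"]),
    ("DNA dependent RNA polymerase", "Self-replication", ["rpoA", "rpoB", "rpoC1", "rpoC2"]),
    ("Photosystem I", "Photosynthesis", ["psaA", "psaB", "psaC", "psaI", "psaJ"]),
    ("Photosystem II", "Photosynthesis",
     ["psbA", "psbB", "psbC", "psbD", "psbE", "psbF", "psbH", "psbI", "psbJ",
      "psbK", "psbL", "psbM", "psbN", "psbT", "psbZ"]),
    ("NADPH dehydrogenase", "Photosynthesis",
     ["ndhA", "ndhB", "ndhC", "ndhD", "ndhE", "ndhF", "ndhG", "ndhH", "ndhI",
      "ndhJ", "ndhK"]),
    ("Cytochrome b/f complex", "Photosynthesis",
     ["petA", "petB", "petD", "petG", "petL", "petN"]),
    ("Subunits of ATP synthase", "Photosynthesis",
     ["atpA", "atpB", "atpE", "atpF", "atpH", "atpI"]),
    ("Photosystem I assembly proteins", "Photosynthesis", ["ycf3", "ycf4"]),
    ("Large subunit of Rubisco", "Photosynthesis", ["rbcL"]),
    ("Protease", "Other genes", ["clpP"]),
    ("Maturase", "Other genes", ["matK"]),
    ("Envelop membrane protein", "Other genes", ["cemA"]),
    ("Subunit of Acetyl-CoA-carboxylase", "Other genes", ["accD"]),
    ("C-type cytochrome synthesis gene", "Other genes", ["ccsA"]),
    ("Translation initiation factor", "Other genes", ["infA"]),
    ("Conserved open reading frames", "Other genes", ["ycf1", "ycf2", "ycf15"]),
]:
    for _n in _names:
        _CDS_GROUPS[_n] = (_cat, _group)


def gene_category(symbol: str, kind: str) -> tuple[str, str]:
    """(category, group) for a gene symbol; unknown symbols -> unclassified."""
    name = symbol.strip()
    if kind == "tRNA" or name.startswith("trn"):
        return ("Self-replication", "tRNA genes")
    if kind == "rRNA" or name.startswith("rrn"):
        return ("Self-replication", "rRNA genes")
    hit = _CDS_GROUPS.get(name)
    if hit is None:
        # tolerate case drift in the suffix only (rpoc1 -> rpoC1); base symbols
        # are case-sensitive otherwise (trnfM-CAU vs trnM-CAU stay distinct)
        for known, val in _CDS_GROUPS.items():
            if known.lower() == name.lower():
                hit = val
                break
    if hit is None:
        logger.warning("gene symbol %r not in the functional classification; "
                       "reporting as unclassified", symbol)
        return ("Unclassified", "Unclassified")
    return hit


@dataclass(frozen=True)
class IntronEntry:
    gene: str
    kind: str
    copy_index: int
    introns: int
    splicing: str  # "cis" | "trans" | "none"


@dataclass
class GeneInventory:
    """Table-style gene accounting for one plastome."""

    unique_genes: int
    cds_genes: int
    trna_genes: int
    rrna_genes: int
    duplicated_in_ir: list[str]
    intron_report: list[IntronEntry]
    categories: dict[str, tuple[str, str]]
    copy_numbers: dict[str, int]


def _part_region(partition: QuadripartitePartition, start: int, end: int) -> str | None:
    return partition.region_of_interval(start, end)


def classify_splicing(
    record: PlastomeRecord, partition: QuadripartitePartition | None = None
) -> list[IntronEntry]:
    """Intron count and cis/trans call for every gene copy.

    A copy is trans-spliced when its exons lie in different quadripartite
    regions, or sit on both strands, or are not colinear along the genome in
    transcription order.  Intron count is parts-1 (structural, per copy).
    """
    entries = []
    for feat in record.features:
        n_introns = len(feat.parts) - 1
        if n_introns == 0:
            entries.append(IntronEntry(feat.name, feat.kind, feat.copy_index, 0, "none"))
            continue
        strands = {p[2] for p in feat.parts}
        trans = len(strands) > 1
        if not trans:
            starts = [p[0] for p in feat.parts]
            colinear = starts == sorted(starts) if "+" in strands else starts == sorted(starts, reverse=True)
            trans = not colinear
        if not trans and partition is not None:
            regions = set()
            for start, end, _ in feat.parts:
                region = _part_region(partition, start, end)
                regions.add(region if region is not None else "junction")
            # the two IR copies host the same duplicated sequence; exons split
            # across IRa/IRb vs LSC/SSC is what signals trans-splicing
            collapsed = {("IR" if r in ("IRa", "IRb") else r) for r in regions}
            trans = len(collapsed - {"junction"}) > 1
        entries.append(
            IntronEntry(feat.name, feat.kind, feat.copy_index, n_introns, "trans" if trans else "cis")
        )
    return entries


def build_inventory(
    record: PlastomeRecord, partition: QuadripartitePartition
) -> GeneInventory:
    """Unique-gene, duplicate, category and intron accounting (one genome).

    Unique genes are distinct gene symbols (copies collapsed).  A gene is
    "duplicated in IR" when at least two of its copies lie entirely within
    IRa and IRb respectively.  A gene overlapping an IR junction stays
    single-copy unless a full second copy exists.
    """
    if not record.features:
        raise PlastokitError(f"{record.id}: record has no gene annotations")

    by_symbol: dict[str, list[FeatureAnnotation]] = {}
    for feat in record.features:
        by_symbol.setdefault(feat.name.strip(), []).append(feat)

    kinds = {sym: feats[0].kind for sym, feats in by_symbol.items()}
    cds = sum(1 for k in kinds.values() if k == "CDS")
    trna = sum(1 for k in kinds.values() if k == "tRNA")
    rrna = sum(1 for k in kinds.values() if k == "rRNA")

    duplicated = []
    for sym, feats in sorted(by_symbol.items()):
        if len(feats) < 2:
            continue
        copies_in = set()
        for feat in feats:
            regions = {_part_region(partition, s, e) for s, e, _ in feat.parts}
            if regions == {"IRa"}:
                copies_in.add("IRa")
            elif regions == {"IRb"}:
                copies_in.add("IRb")
        if {"IRa", "IRb"} <= copies_in:
            duplicated.append(sym)

    categories = {sym: gene_category(sym, kinds[sym]) for sym in by_symbol}
    return GeneInventory(
        unique_genes=len(by_symbol),
        cds_genes=cds,
        trna_genes=trna,
        rrna_genes=rrna,
        duplicated_in_ir=duplicated,
        intron_report=classify_splicing(record, partition),
        categories=categories,
        copy_numbers={sym: len(feats) for sym, feats in by_symbol.items()},
    )
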