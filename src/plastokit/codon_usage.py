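"""Codon-usage statistics over the protein-coding complement of a plastome.

RSCU (relative synonymous codon usage) is the observed count of a codon
divided by the mean count within its synonymous family, so 1 means no bias
and values above 1 mark preferred codons.  The bacterial/plastid genetic
code (translation table 11) is used throughout.
"""

from __future__ import annotations

import logging
import math
from collections import Counter
from dataclasses import dataclass

import pandas as pd
from Bio.Data import CodonTable

from .errors import PlastokitError
from .genome_io import PlastomeRecord, extract_feature_sequence

logger = logging.getLogger(__name__)

_TABLE = CodonTable.unambiguous_dna_by_id[11]

#: amino acid -> tuple of synonymous codons; "*" is the stop family
SYNONYMOUS_FAMILIES: dict[str, tuple[str, ...]] = {}
for _codon, _aa in _TABLE.forward_table.items():
    SYNONYMOUS_FAMILIES.setdefault(_aa, ())
    SYNONYMOUS_FAMILIES[_aa] += (_codon,)
SYNONYMOUS_FAMILIES["*"] = tuple(_TABLE.stop_codons)

CODON_TO_AA = {c: aa for aa, codons in SYNONYMOUS_FAMILIES.items() for c in codons}


def collect_cds_codons(
    record: PlastomeRecord,
    collapse_duplicates: bool = True,
    include_trans_spliced: bool = True,
) -> Counter:
    """Codon counts over the spliced CDS of a plastome.

    Duplicated genes contribute one copy (the first in genome order) unless
    ``collapse_duplicates`` is off.  Reading frame starts at the annotated
    first exon base; trailing partial codons are truncated with a log note,
    and codons containing N are skipped.
    """
    counts: Counter = Counter()
    seen: set[str] = set()
    n_cds = 0
    for feat in record.features:
        if feat.kind != "CDS":
            continue
        if collapse_duplicates:
            if feat.name in seen:
                continue
            seen.add(feat.name)
        if not include_trans_spliced and len({p[2] for p in feat.parts}) > 1:
            continue
        seq = extract_feature_sequence(record, feat)
        n_cds += 1
        if len(seq) % 3:
            logger.info("CDS %s length %d not divisible by 3; truncating to full codons",
                        feat.name, len(seq))
            seq = seq[: len(seq) - len(seq) % 3]
        for i in range(0, len(seq), 3):
            codon = seq[i : i + 3]
            if "N" in codon:
                continue
            counts[codon] += 1
    if n_cds == 0:
        raise PlastokitError(f"{record.id}: no CDS features to collect codons from")
    return counts


@dataclass
class CodonUsageTable:
    """Per-codon counts and RSCU plus per-amino-acid totals."""

    codon_counts: dict[str, int]
    rscu: dict[str, float]          # NaN where a family has zero total
    aa_counts: dict[str, int]       # 20 amino acids + "*"
    aa_fractions: dict[str, float]

    def to_codon_frame(self) -> pd.DataFrame:
        rows = [
            {"codon": c, "amino_acid": CODON_TO_AA[c],
             "count": self.codon_counts.get(c, 0), "rscu": self.rscu[c]}
            for aa in sorted(SYNONYMOUS_FAMILIES)
            for c in sorted(SYNONYMOUS_FAMILIES[aa])
        ]
        return pd.DataFrame(rows)

    def to_aa_frame(self) -> pd.DataFrame:
        rows = [
            {"amino_acid": aa, "count": self.aa_counts[aa], "fraction": self.aa_fractions[aa]}
            for aa in sorted(self.aa_counts, key=lambda a: -self.aa_counts[a])
        ]
        return pd.DataFrame(rows)


def rscu(codon_counts: Counter | dict) -> CodonUsageTable:
    """RSCU and amino-acid frequencies from raw codon counts.

    RSCU(c) = count(c) / mean(count over c's synonymous family).  Families
    with zero total get NaN.  Stop codons form their own 3-codon family and
    are tallied under "*".
    """
    unknown = set(codon_counts) - set(CODON_TO_AA)
    if unknown:
        logger.warning("ignoring %d non-standard codons: %s", len(unknown), sorted(unknown))
    values: dict[str, float] = {}
    aa_counts: dict[str, int] = {}
    for aa, codons in SYNONYMOUS_FAMILIES.items():
        total = sum(codon_counts.get(c, 0) for c in codons)
        aa_counts[aa] = total
        mean = total / len(codons)
        for c in codons:
            values[c] = codon_counts.get(c, 0) / mean if total > 0 else math.nan
    grand = sum(aa_counts.values())
    aa_fractions = {aa: (n / grand if grand else math.nan) for aa, n in aa_counts.items()}
    clean_counts = {c: int(codon_counts.get(c, 0)) for c in CODON_TO_AA}
    return CodonUsageTable(
        codon_counts=clean_counts, rscu=values, aa_counts=aa_counts, aa_fractions=aa_fractions
    )


def aa_frequency(codon_counts: Counter | dict) -> pd.DataFrame:
    """Amino-acid totals and fractions, ranked by abundance."""
    return rscu(codon_counts).to_aa_frame()
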