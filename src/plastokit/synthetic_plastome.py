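"""Synthetic annotated plastomes with full ground truth.

The generator emits a circular genome laid out LSC + IRb + SSC + IRa with the
two IRs exact reverse complements, AT-rich single-copy regions, annotated
CDS/tRNA/rRNA genes (some intron-containing, optionally one trans-spliced),
planted microsatellites, and — via :func:`mutate_genome` — a diverged partner
genome with exact per-region substitution and indel bookkeeping at a chosen
transition/transversion ratio.  Default dimensions and composition emulate a
typical Asteraceae plastome (~152 kb, ~63% AT, GC-rich IRs).

Rejection-style cleanup guarantees that no microsatellite at or above the
detection thresholds exists outside the planted set, so repeat-scanning
results on simulated genomes can be compared to truth exactly.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .errors import ConfigError, SimulationError
from .genome_io import FeatureAnnotation, PlastomeRecord, revcomp
from .quadripartite import CircularInterval, QuadripartitePartition
from .ssr_scan import DEFAULT_THRESHOLDS, SSRLocus, find_ssrs_circular, smallest_period

BASES = "ACGT"
_TRANSITION = {"A": "G", "G": "A", "C": "T", "T": "C"}
_TRANSVERSIONS = {"A": "CT", "G": "CT", "C": "AG", "T": "AG"}

# approximate amino-acid composition of land-plant plastid proteomes,
# leucine-rich and cysteine-poor
_AA_WEIGHTS = {
    "L": 0.105, "I": 0.085, "S": 0.080, "G": 0.070, "F": 0.052, "A": 0.060,
    "V": 0.060, "T": 0.055, "R": 0.055, "K": 0.050, "E": 0.050, "N": 0.045,
    "P": 0.045, "D": 0.040, "Q": 0.035, "Y": 0.033, "H": 0.025, "M": 0.022,
    "W": 0.018, "C": 0.011,
}

_LSC_CDS_POOL = [
    "psbA", "matK", "rps16", "psbK", "psbI", "atpA", "atpF", "atpH", "atpI",
    "rps2", "rpoC2", "rpoC1", "rpoB", "petN", "psbM", "psbD", "psbC", "psbZ",
    "rps14", "psaB", "psaA", "ycf3", "rps4", "ndhJ", "ndhK", "ndhC", "atpE",
    "atpB", "rbcL", "accD", "psaI", "ycf4", "cemA", "petA", "psbJ", "psbL",
    "psbF", "psbE", "petL", "petG", "psaJ", "rpl33", "rps18", "rpl20", "clpP",
    "psbB", "psbT", "psbN", "psbH", "petB", "petD", "rpoA", "rps11", "rpl36",
    "infA", "rps8", "rpl14", "rpl16", "rps3", "rpl22", "rps19",
]
_IR_CDS_POOL = ["rpl2", "rpl23", "ycf2", "ndhB", "rps7"]
_SSC_CDS_POOL = ["ndhF", "rpl32", "ccsA", "ndhD", "psaC", "ndhE", "ndhG",
                 "ndhI", "ndhA", "ndhH", "rps15", "ycf1"]
_LSC_TRNA_POOL = ["trnH-GUG", "trnK-UUU", "trnQ-UUG", "trnS-GCU", "trnG-UCC",
                  "trnR-UCU", "trnC-GCA", "trnD-GUC", "trnY-GUA", "trnE-UUC",
                  "trnS-UGA", "trnG-GCC", "trnfM-CAU", "trnS-GGA", "trnT-UGU",
                  "trnL-UAA", "trnF-GAA", "trnV-UAC", "trnM-CAU", "trnW-CCA",
                  "trnP-UGG"]
_IR_TRNA_POOL = ["trnI-CAU", "trnL-CAA", "trnV-GAC", "trnI-GAU", "trnA-UGC",
                 "trnR-ACG", "trnN-GUU"]
_SSC_TRNA_POOL = ["trnL-UAG"]
_RRNA_POOL = ["rrn16", "rrn23", "rrn4.5", "rrn5"]


def _default_ssr_plants() -> list[tuple[str, int, str]]:
    """Planted microsatellite set: mononucleotide-dominated and A/T-rich,
    with rare tetra- and hexanucleotide loci and no pentanucleotides."""
    plants: list[tuple[str, int, str]] = []
    mono = ["A", "T", "A", "T", "A", "T", "A", "T", "A", "T",
            "A", "T", "A", "T", "A", "T", "A", "T", "A", "C",
            "A", "T", "A", "T"]
    reps = [10, 11, 12, 10, 13, 10, 11, 14, 10, 12,
            11, 10, 16, 10, 12, 11, 10, 13, 10, 10,
            11, 10, 12, 10]
    regions = ["LSC"] * 16 + ["SSC"] * 8
    plants += list(zip(mono, reps, regions))
    plants += [("AT", 6, "LSC"), ("TA", 5, "LSC"), ("AT", 5, "SSC"), ("AG", 5, "LSC")]
    plants += [("AAT", 4, "LSC"), ("TTA", 5, "SSC")]
    plants += [("AATT", 3, "LSC")]
    plants += [("AATGCC", 3, "LSC")]
    return plants


@dataclass
class SimulationParams:
    """Knobs of the synthetic plastome; defaults emulate the study conditions
    of a ~152 kb Asteraceae plastome pair."""

    seed: int
    lsc_len: int = 83_911
    ssc_len: int = 18_248
    ir_len: int = 25_027
    at_fraction: float = 0.65          # single-copy A+T fraction
    ir_gc_uplift: float = 0.08         # additive GC increase inside the IRs
    n_cds: int = 24
    n_trna: int = 12
    n_rrna: int = 4
    intron_genes: int = 4              # LSC CDS genes given introns (first gets 2)
    include_trans_spliced: bool = True
    ssr_plants: list[tuple[str, int, str]] = field(default_factory=_default_ssr_plants)
    n_substitutions: dict = field(default_factory=lambda: {"LSC": 429, "SSC": 169, "IR": 20})
    ts_tv_target: float = 1.1
    n_indels: dict = field(default_factory=lambda: {"LSC": 8, "SSC": 4, "IR": 1})
    indel_len_range: tuple[int, int] = (1, 30)

    def __post_init__(self):
        if min(self.lsc_len, self.ssc_len, self.ir_len) <= 0:
            raise ConfigError("region lengths must be positive")
        if not 0 < self.at_fraction < 1:
            raise ConfigError("at_fraction must be in (0, 1)")
        if self.ts_tv_target <= 0:
            raise ConfigError("ts_tv_target must be > 0")
        for unit, repeats, region in self.ssr_plants:
            if smallest_period(unit) != len(unit):
                raise ConfigError(f"SSR unit {unit!r} is itself periodic")
            if repeats < DEFAULT_THRESHOLDS[len(unit)]:
                raise ConfigError(f"SSR plant {unit}x{repeats} below detection threshold")
            if region not in ("LSC", "SSC", "IRb"):
                raise ConfigError(f"SSR plant region {region!r} not one of LSC/SSC/IRb")


@dataclass(frozen=True)
class GeneTruth:
    name: str
    kind: str
    region: str
    strand: str
    parts: tuple[tuple[int, int, str], ...]
    introns: int
    trans: bool
    duplicated_in_ir: bool


@dataclass(frozen=True)
class SubstitutionEvent:
    position: int          # coordinate in the source (unmutated) genome
    region: str
    ref: str
    alt: str
    is_transition: bool

    @property
    def pair(self) -> str:
        a, b = sorted((self.ref, self.alt))
        return f"{a}/{b}"


@dataclass(frozen=True)
class IndelEvent:
    position: int          # coordinate in the source genome
    region: str
    kind: str              # "ins" | "del"
    length: int


@dataclass
class SimulationTruth:
    """Everything planted into a simulated genome, in genome coordinates."""

    partition: QuadripartitePartition
    genes: list[GeneTruth]
    ssr_loci: list[SSRLocus]
    substitutions: list[SubstitutionEvent] = field(default_factory=list)
    indels: list[IndelEvent] = field(default_factory=list)


# ---------------------------------------------------------------------------
# sequence building blocks


def _random_dna(rng, n: int, gc: float) -> np.ndarray:
    probs = [(1 - gc) / 2, gc / 2, gc / 2, (1 - gc) / 2]  # A C G T
    return rng.choice(np.frombuffer(b"ACGT", dtype=np.uint8), size=n, p=probs)


_CODON_MODEL: tuple | None = None


def _codon_model():
    """Flat sense-codon sampling distribution: plastid-like amino-acid
    weights combined with a 3:1 preference for A/T third positions."""
    global _CODON_MODEL
    if _CODON_MODEL is None:
        from .codon_usage import SYNONYMOUS_FAMILIES

        codons: list[str] = []
        weights: list[float] = []
        for aa, aa_w in _AA_WEIGHTS.items():
            fam = SYNONYMOUS_FAMILIES[aa]
            cw = np.array([3.0 if c[2] in "AT" else 1.0 for c in fam])
            cw = aa_w * cw / cw.sum()
            codons.extend(fam)
            weights.extend(cw)
        w = np.array(weights)
        _CODON_MODEL = (np.array(codons), w / w.sum())
    return _CODON_MODEL


def _random_cds(rng, n_codons: int) -> str:
    """ATG + biased sense codons + stop; third positions favour A/T."""
    codons, weights = _codon_model()
    body = codons[rng.choice(len(codons), size=n_codons - 2, p=weights)]
    stop = ["TAA", "TGA", "TAG"][rng.choice(3, p=[0.6, 0.25, 0.15])]
    return "ATG" + "".join(body) + stop


def _random_structural_rna(rng, n: int, gc: float) -> str:
    return _random_dna(rng, n, gc).tobytes().decode("ascii")


class _RegionBuilder:
    """Mutable byte array for one region plus free-interval bookkeeping."""

    def __init__(self, rng, name: str, length: int, gc: float, offset: int):
        self.name = name
        self.offset = offset
        self.length = length
        self.arr = _random_dna(rng, length, gc)
        self.cursor = 200
        self.occupied: list[tuple[int, int]] = []  # local coords, genes incl. introns

    def place(self, rng, span: int, min_gap: int = 150, max_gap: int = 420) -> int:
        gap = int(rng.integers(min_gap, max_gap))
        start = self.cursor + gap
        if start + span > self.length - 200:
            raise SimulationError(
                f"requested gene content exceeds {self.name} capacity "
                f"({self.length} bp)"
            )
        self.cursor = start + span
        self.occupied.append((start, start + span))
        return start

    def write(self, local_start: int, seq: str) -> None:
        self.arr[local_start : local_start + len(seq)] = np.frombuffer(
            seq.encode("ascii"), dtype=np.uint8
        )

    def free_intervals(self, margin: int = 10) -> list[tuple[int, int]]:
        out = []
        prev = 0
        for s, e in sorted(self.occupied):
            if s - margin > prev + margin:
                out.append((prev + margin, s - margin))
            prev = max(prev, e)
        if self.length - margin > prev + margin:
            out.append((prev + margin, self.length - margin))
        return out


def _plant_gene(rng, builder: _RegionBuilder, name: str, kind: str, strand: str,
                n_introns: int = 0, seq: str | None = None,
                length_range: tuple[int, int] = (300, 1500)) -> tuple:
    """Write one gene into a region; returns (parts in absolute coords, introns)."""
    if seq is None:
        if kind == "CDS":
            lo, hi = length_range
            n_codons = int(rng.integers(lo // 3, hi // 3 + 1))
            seq = _random_cds(rng, n_codons)
        elif kind == "tRNA":
            seq = _random_structural_rna(rng, int(rng.integers(72, 90)), 0.53)
        else:
            seq = _random_structural_rna(rng, int(rng.integers(800, 1500)), 0.55)
    if n_introns:
        cuts = sorted(rng.choice(np.arange(30, len(seq) - 30), size=n_introns, replace=False))
        exons = []
        prev = 0
        for c in cuts:
            exons.append(seq[prev:c])
            prev = int(c)
        exons.append(seq[prev:])
        intron_lens = [int(rng.integers(120, 420)) for _ in range(n_introns)]
    else:
        exons = [seq]
        intron_lens = []
    span = sum(len(e) for e in exons) + sum(intron_lens)
    start = builder.place(rng, span)
    # genomic layout: exon order along the genome follows strand
    genomic_exons = exons if strand == "+" else [revcomp(e) for e in reversed(exons)]
    genomic_lens = [len(e) for e in (exons if strand == "+" else list(reversed(exons)))]
    intron_iter = intron_lens if strand == "+" else list(reversed(intron_lens))
    pos = start
    intervals = []
    for i, gexon in enumerate(genomic_exons):
        builder.write(pos, gexon)
        intervals.append((builder.offset + pos, builder.offset + pos + len(gexon)))
        pos += genomic_lens[i]
        if i < len(intron_iter):
            pos += intron_iter[i]
    if strand == "-":
        intervals = list(reversed(intervals))  # back to transcription order
    parts = tuple((s, e, strand) for s, e in intervals)
    return parts, n_introns


def _mirror_interval(interval: tuple[int, int], irb: CircularInterval,
                     ira: CircularInterval) -> tuple[int, int]:
    """Map an absolute IRb interval to its reverse-complement image in IRa."""
    s, e = interval
    t0, t1 = s - irb.start, e - irb.start
    return (ira.start + irb.length - t1, ira.start + irb.length - t0)


def simulate_plastome(params: SimulationParams) -> tuple[PlastomeRecord, SimulationTruth]:
    """Generate one annotated synthetic plastome plus its ground truth.

    Deterministic for a fixed seed.  IR genes are annotated in both copies;
    the optional trans-spliced gene has exon 1 in LSC (minus strand) and
    exons 2-3 in IRb, mirroring the canonical plastid rps12 arrangement.
    """
    rng = np.random.default_rng(params.seed)
    lsc_len, ssc_len, ir_len = params.lsc_len, params.ssc_len, params.ir_len
    total = lsc_len + ssc_len + 2 * ir_len
    gc_sc = 1 - params.at_fraction
    gc_ir = min(0.95, gc_sc + params.ir_gc_uplift)

    lsc = _RegionBuilder(rng, "LSC", lsc_len, gc_sc, 0)
    irb = _RegionBuilder(rng, "IRb", ir_len, gc_ir, lsc_len)
    ssc = _RegionBuilder(rng, "SSC", ssc_len, gc_sc, lsc_len + ir_len)
    builders = {"LSC": lsc, "IRb": irb, "SSC": ssc}

    partition = QuadripartitePartition(
        lsc=CircularInterval(0, lsc_len),
        irb=CircularInterval(lsc_len, ir_len),
        ssc=CircularInterval(lsc_len + ir_len, ssc_len),
        ira=CircularInterval(lsc_len + ir_len + ssc_len, ir_len),
        genome_length=total,
    )

    # --- allocate gene names to regions -----------------------------------
    n_cds_ir = min(len(_IR_CDS_POOL), max(0, params.n_cds // 6))
    n_cds_ssc = min(len(_SSC_CDS_POOL), max(0, params.n_cds // 8))
    n_cds_lsc = params.n_cds - n_cds_ir - n_cds_ssc
    n_trna_ir = min(len(_IR_TRNA_POOL), max(0, params.n_trna // 6))
    n_trna_ssc = min(len(_SSC_TRNA_POOL), max(0, params.n_trna // 12))
    n_trna_lsc = params.n_trna - n_trna_ir - n_trna_ssc
    if n_cds_lsc > len(_LSC_CDS_POOL) or n_trna_lsc > len(_LSC_TRNA_POOL) \
            or params.n_rrna > len(_RRNA_POOL):
        raise ConfigError("requested gene counts exceed the built-in name pools")

    genes: list[GeneTruth] = []
    features: list[FeatureAnnotation] = []
    copy_counter: dict[tuple[str, str], int] = {}

    def add_feature(name, kind, parts, region, introns, trans, dup):
        idx = copy_counter.get((name, kind), 0)
        copy_counter[(name, kind)] = idx + 1
        features.append(FeatureAnnotation(name=name, kind=kind, parts=parts, copy_index=idx))
        strand = parts[0][2]
        genes.append(GeneTruth(name, kind, region, strand, parts, introns, trans, dup))

    # LSC protein-coding genes; the first `intron_genes` carry introns
    for gi in range(n_cds_lsc):
        name = _LSC_CDS_POOL[gi]
        strand = "+" if rng.random() < 0.6 else "-"
        n_introns = 0
        if gi < params.intron_genes:
            n_introns = 2 if gi == 0 else 1
        parts, ni = _plant_gene(rng, lsc, name, "CDS", strand, n_introns)
        add_feature(name, "CDS", parts, "LSC", ni, False, False)

    for gi in range(n_trna_lsc):
        name = _LSC_TRNA_POOL[gi]
        strand = "+" if rng.random() < 0.5 else "-"
        parts, _ = _plant_gene(rng, lsc, name, "tRNA", strand)
        add_feature(name, "tRNA", parts, "LSC", 0, False, False)

    for gi in range(n_cds_ssc):
        name = _SSC_CDS_POOL[gi]
        strand = "+" if rng.random() < 0.5 else "-"
        parts, _ = _plant_gene(rng, ssc, name, "CDS", strand)
        add_feature(name, "CDS", parts, "SSC", 0, False, False)
    for gi in range(n_trna_ssc):
        name = _SSC_TRNA_POOL[gi]
        parts, _ = _plant_gene(rng, ssc, name, "tRNA", "+")
        add_feature(name, "tRNA", parts, "SSC", 0, False, False)

    # IRb genes (duplicated into IRa after mirroring)
    ir_gene_plan: list[tuple[str, str, tuple]] = []
    for gi in range(params.n_rrna):
        name = _RRNA_POOL[gi]
        parts, _ = _plant_gene(rng, irb, name, "rRNA", "+")
        ir_gene_plan.append((name, "rRNA", parts))
    for gi in range(n_cds_ir):
        name = _IR_CDS_POOL[gi]
        parts, _ = _plant_gene(rng, irb, name, "CDS", "-", length_range=(300, 900))
        ir_gene_plan.append((name, "CDS", parts))
    for gi in range(n_trna_ir):
        name = _IR_TRNA_POOL[gi]
        parts, _ = _plant_gene(rng, irb, name, "tRNA", "+")
        ir_gene_plan.append((name, "tRNA", parts))

    # trans-spliced gene: exon 1 in LSC (minus strand), exons 2-3 in IRb
    if params.include_trans_spliced:
        cds = _random_cds(rng, 124)  # 372 bp
        e1, e2, e3 = cds[:114], cds[114:345], cds[345:]
        s1 = lsc.place(rng, len(e1))
        lsc.write(s1, revcomp(e1))
        s2 = irb.place(rng, len(e2) + 250 + len(e3))
        irb.write(s2, e2)
        irb.write(s2 + len(e2) + 250, e3)
        parts = (
            (s1, s1 + len(e1), "-"),
            (irb.offset + s2, irb.offset + s2 + len(e2), "+"),
            (irb.offset + s2 + len(e2) + 250, irb.offset + s2 + len(e2) + 250 + len(e3), "+"),
        )
        add_feature("rps12", "CDS", parts, "LSC/IR", 2, True, False)

    # --- plant microsatellites --------------------------------------------
    ssr_truth: list[SSRLocus] = []
    free = {name: b.free_intervals(margin=12) for name, b in builders.items()}
    for unit, repeats, region in params.ssr_plants:
        b = builders[region]
        span = len(unit) * repeats
        candidates = [iv for iv in free[region] if iv[1] - iv[0] >= span + 2]
        if not candidates:
            raise SimulationError(f"no room left in {region} for SSR {unit}x{repeats}")
        iv = candidates[int(rng.integers(len(candidates)))]
        start = int(rng.integers(iv[0] + 1, iv[1] - span - 1 + 1))
        b.write(start, unit * repeats)
        # flanks must break the repeat by a full unit on either side
        left_choices = [c for c in BASES if c != unit[-1]]
        right_choices = [c for c in BASES if c != unit[0]]
        b.write(start - 1, left_choices[int(rng.integers(len(left_choices)))])
        b.write(start + span, right_choices[int(rng.integers(len(right_choices)))])
        free[region] = _consume(free[region], (start - 14, start + span + 14))
        ssr_truth.append(SSRLocus(start=b.offset + start, end=b.offset + start + span,
                                  unit=unit, repeats=repeats, region=region))

    # --- assemble, mirror IRa, annotate IR duplicates ----------------------
    ira_arr = np.frombuffer(revcomp(irb.arr.tobytes().decode("ascii")).encode("ascii"),
                            dtype=np.uint8)
    seq_arr = np.concatenate([lsc.arr, irb.arr, ssc.arr, ira_arr])
    ira_iv, irb_iv = partition.ira, partition.irb

    for name, kind, parts in ir_gene_plan:
        add_feature(name, kind, parts, "IRb", len(parts) - 1, False, True)
        mirrored = tuple(
            (*_mirror_interval((s, e), irb_iv, ira_iv), "-" if st == "+" else "+")
            for s, e, st in parts
        )
        add_feature(name, kind, mirrored, "IRa", len(mirrored) - 1, False, True)

    # --- pin junctions and purge accidental microsatellites ----------------
    # The IR pair must be exactly maximal: a chance complementary base just
    # outside either junction would extend the detected repeat past the
    # planted coordinates.
    for _ in range(3):
        changed = _pin_junctions(rng, seq_arr, lsc_len, ir_len, ssc_len)
        seq_arr = _purge_accidental_ssrs(rng, seq_arr, ssr_truth, genes, partition)
        if not changed:
            break

    sequence = seq_arr.tobytes().decode("ascii")
    record = PlastomeRecord(
        id=f"SYN{params.seed:07d}", sequence=sequence, circular=True, features=features
    )
    truth = SimulationTruth(partition=partition, genes=genes, ssr_loci=ssr_truth)
    return record, truth


_COMP_BASE = {"A": "T", "T": "A", "C": "G", "G": "C"}


def _pin_junctions(rng, seq_arr, lsc_len: int, ir_len: int, ssc_len: int) -> bool:
    """Break chance reverse-complement matches flanking the planted IR pair.

    Returns True when a base had to be changed.  The four junction-adjacent
    bases are always in single-copy sequence well away from genes and
    planted repeats (placement keeps a >= 12 bp margin from region edges).
    """
    changed = False
    pairs = [
        (lsc_len - 1, 0),                                  # IRb left vs wrap past IRa
        (lsc_len + ir_len, lsc_len + ir_len + ssc_len - 1),  # IRb right vs IRa left
    ]
    for edit_pos, ref_pos in pairs:
        if chr(seq_arr[edit_pos]) == _COMP_BASE[chr(seq_arr[ref_pos])]:
            options = [b for b in BASES if b != _COMP_BASE[chr(seq_arr[ref_pos])]]
            seq_arr[edit_pos] = ord(options[int(rng.integers(len(options)))])
            changed = True
    return changed


def _consume(intervals: list[tuple[int, int]], used: tuple[int, int]) -> list[tuple[int, int]]:
    out = []
    us, ue = used
    for s, e in intervals:
        if ue <= s or us >= e:
            out.append((s, e))
            continue
        if s < us:
            out.append((s, us))
        if ue < e:
            out.append((ue, e))
    return [iv for iv in out if iv[1] - iv[0] > 0]


def _purge_accidental_ssrs(rng, seq_arr, ssr_truth, genes, partition,
                           max_rounds: int = 40):
    """Break every detectable repeat that was not deliberately planted.

    One base inside each stray locus is changed (symmetrically in both IR
    copies) and the scan repeats until only planted loci remain.
    """
    n = len(seq_arr)
    planted = {(l.start, l.end, l.unit) for l in ssr_truth}
    protected = np.zeros(n, dtype=bool)
    for l in ssr_truth:
        protected[max(0, l.start - 2) : min(n, l.end + 2)] = True
    cds_edges = np.zeros(n, dtype=bool)  # start/stop codons of CDS copies
    for g in genes:
        if g.kind != "CDS":
            continue
        first = g.parts[0]
        last = g.parts[-1]
        if first[2] == "+":
            cds_edges[first[0] : first[0] + 3] = True
        else:
            cds_edges[first[1] - 3 : first[1]] = True
        if last[2] == "+":
            cds_edges[last[1] - 3 : last[1]] = True
        else:
            cds_edges[last[0] : last[0] + 3] = True

    irb_iv, ira_iv = partition.irb, partition.ira

    for _ in range(max_rounds):
        seq = seq_arr.tobytes().decode("ascii")
        stray = [
            l for l in find_ssrs_circular(seq)
            if (l.start % n, l.start % n + l.length, l.unit) not in planted
        ]
        if not stray:
            return seq_arr
        for l in stray:
            pos = _pick_edit_pos(l, n, protected, cds_edges)
            if pos is None:
                continue
            p = len(l.unit)
            cur = chr(seq_arr[pos])
            banned = {cur, chr(seq_arr[pos - p]) if pos - p >= 0 else "",
                      chr(seq_arr[(pos + p) % n])}
            options = [b for b in BASES if b not in banned] or [b for b in BASES if b != cur]
            new = options[int(rng.integers(len(options)))]
            seq_arr[pos] = ord(new)
            if irb_iv.contains(pos, n):
                m0, _ = _mirror_interval((pos, pos + 1), irb_iv, ira_iv)
                seq_arr[m0] = ord(revcomp(new))
            elif ira_iv.contains(pos, n):
                m0 = irb_iv.start + (ira_iv.start + ira_iv.length - 1 - pos)
                seq_arr[m0] = ord(revcomp(new))
    raise SimulationError("could not purge accidental microsatellites")


def _pick_edit_pos(locus, n, protected, cds_edges):
    mid = (locus.start + locus.length // 2) % n
    for delta in range(locus.length):
        for cand in ((mid + delta) % n, (mid - delta) % n):
            if (locus.start <= cand < locus.start + locus.length or
                    locus.start <= cand + n < locus.start + locus.length):
                if not protected[cand] and not cds_edges[cand]:
                    return cand
    return None


# ---------------------------------------------------------------------------
# mutation


def mutate_genome(
    record: PlastomeRecord, truth: SimulationTruth, params: SimulationParams
) -> tuple[PlastomeRecord, SimulationTruth]:
    """Derive a diverged partner genome with exact mutation bookkeeping.

    Exactly ``n_substitutions[region]`` substitutions are applied per region,
    each a transition with probability R/(R+1) for R = ``ts_tv_target``; IR
    events are applied symmetrically to both copies so the IRs stay exact
    reverse complements.  Indels (``n_indels``, lengths in
    ``indel_len_range``) go into gene-free single-copy stretches at least
    10 bp from any substitution.  Truth lists every event in source-genome
    coordinates.
    """
    rng = np.random.default_rng([params.seed, 104729])
    seq = np.frombuffer(record.sequence.encode("ascii"), dtype=np.uint8).copy()
    n = len(seq)
    part = truth.partition
    region_ivs = {"LSC": part.lsc, "SSC": part.ssc, "IR": part.irb}

    blocked = np.zeros(n, dtype=bool)  # no substitutions inside planted SSRs
    for l in truth.ssr_loci:
        blocked[max(0, l.start - 2) : min(n, l.end + 2)] = True
    # keep junction-adjacent bases intact so the mutated IR pair stays
    # exactly maximal at the planted coordinates
    for junction in (0, part.irb.start, part.ssc.start, part.ira.start):
        blocked[(junction - 2) % n] = blocked[(junction - 1) % n] = True
        blocked[junction % n] = blocked[(junction + 1) % n] = True

    p_ts = params.ts_tv_target / (1 + params.ts_tv_target)
    subs: list[SubstitutionEvent] = []
    sub_positions: list[int] = []
    for region, iv in region_ivs.items():
        count = params.n_substitutions.get(region, 0)
        if count == 0:
            continue
        if count > iv.length // 10:
            raise SimulationError(f"{region}: {count} substitutions exceed length/10")
        pool = np.arange(iv.start, iv.start + iv.length)
        pool = pool[~blocked[pool]]
        chosen = rng.choice(pool, size=count, replace=False)
        for pos in sorted(int(p) for p in chosen):
            ref = chr(seq[pos])
            is_ts = bool(rng.random() < p_ts)
            alt = _TRANSITION[ref] if is_ts else _TRANSVERSIONS[ref][int(rng.integers(2))]
            seq[pos] = ord(alt)
            subs.append(SubstitutionEvent(pos, region, ref, alt, is_ts))
            sub_positions.append(pos)
            if region == "IR":
                m0, _ = _mirror_interval((pos, pos + 1), part.irb, part.ira)
                seq[m0] = ord(revcomp(alt))
                sub_positions.append(m0)

    # --- indels ------------------------------------------------------------
    gene_mask = np.zeros(n, dtype=bool)
    for g in truth.genes:
        lo = min(p[0] for p in g.parts)
        hi = max(p[1] for p in g.parts)
        gene_mask[lo:hi] = True
    sub_arr = np.array(sorted(sub_positions)) if sub_positions else np.array([], dtype=int)
    lo_len, hi_len = params.indel_len_range
    edits: list[tuple[int, int, str, str]] = []  # (pos, del_len, ins_seq, region)
    indel_events: list[IndelEvent] = []
    for region, iv in region_ivs.items():
        count = params.n_indels.get(region, 0)
        taken: list[int] = []
        for _ in range(count):
            length = int(rng.integers(lo_len, hi_len + 1))
            kind = "del" if rng.random() < 0.5 else "ins"
            pos = _find_indel_pos(rng, iv, n, gene_mask, blocked, sub_arr, taken,
                                  length, part if region == "IR" else None)
            taken.append(pos)
            if kind == "del":
                edits.append((pos, length, "", region))
                if region == "IR":
                    m0, m1 = _mirror_interval((pos, pos + length), part.irb, part.ira)
                    edits.append((m0, m1 - m0, "", region))
            else:
                ins = "".join(chr(b) for b in _random_dna(rng, length, 0.35))
                edits.append((pos, 0, ins, region))
                if region == "IR":
                    m0, _ = _mirror_interval((pos, pos), part.irb, part.ira)
                    edits.append((m0, 0, revcomp(ins), region))
            indel_events.append(IndelEvent(pos, region, kind, length))

    # apply indels from the highest coordinate down, shifting annotations
    edits.sort(key=lambda e: -e[0])
    out = record.sequence
    out = _apply_substitutions(out, seq)
    deltas: dict[str, int] = {"LSC": 0, "SSC": 0, "IR": 0}
    for pos, del_len, ins, region in edits:
        out = out[:pos] + ins + out[pos + del_len :]
        deltas[region] += len(ins) - del_len

    shift_edits = [(pos, del_len, len(ins) - del_len) for pos, del_len, ins, _ in edits]
    new_features = [
        replace(f, parts=_shift_parts(f.parts, shift_edits)) for f in record.features
    ]
    new_ssrs = [
        replace(l, start=_shift_pos(l.start, shift_edits),
                end=_shift_pos(l.start, shift_edits) + l.length)
        for l in truth.ssr_loci
    ]
    new_genes = [replace(g, parts=_shift_parts(g.parts, shift_edits)) for g in truth.genes]

    lsc_len = part.lsc.length + deltas["LSC"]
    ssc_len = part.ssc.length + deltas["SSC"]
    ir_len = part.irb.length + deltas["IR"] // 2 if deltas["IR"] else part.irb.length
    new_partition = QuadripartitePartition(
        lsc=CircularInterval(0, lsc_len),
        irb=CircularInterval(lsc_len, ir_len),
        ssc=CircularInterval(lsc_len + ir_len, ssc_len),
        ira=CircularInterval(lsc_len + ir_len + ssc_len, ir_len),
        genome_length=len(out),
    )
    mutated = PlastomeRecord(
        id=f"{record.id}m", sequence=out, circular=True, features=new_features
    )
    new_truth = SimulationTruth(
        partition=new_partition, genes=new_genes, ssr_loci=new_ssrs,
        substitutions=subs, indels=indel_events,
    )
    return mutated, new_truth


def _apply_substitutions(original: str, mutated_arr: np.ndarray) -> str:
    return mutated_arr.tobytes().decode("ascii")


def _shift_pos(x: int, edits: list[tuple[int, int, int]]) -> int:
    """New coordinate of ``x`` after indel edits (pos, del_len, delta).

    Edits never overlap annotated intervals, so a plain cumulative shift of
    everything downstream is exact.
    """
    return x + sum(delta for pos, _dl, delta in edits if pos < x)


def _shift_parts(parts, edits) -> tuple[tuple[int, int, str], ...]:
    return tuple(
        (_shift_pos(s, edits), _shift_pos(s, edits) + (e - s), strand)
        for s, e, strand in parts
    )


def _find_indel_pos(rng, iv, n, gene_mask, blocked, sub_arr, taken, length, part):
    for _ in range(3000):
        pos = int(rng.integers(iv.start + 60, iv.start + iv.length - 60 - length))
        window = slice(max(0, pos - 12), min(n, pos + length + 12))
        if gene_mask[window].any() or blocked[window].any():
            continue
        if sub_arr.size and np.min(np.abs(sub_arr - pos)) < 10 + length:
            continue
        if any(abs(t - pos) < 10 + 2 * length for t in taken):
            continue
        if part is not None:
            m0, m1 = _mirror_interval((pos, pos + length), part.irb, part.ira)
            if gene_mask[m0:m1 + 12].any() or (
                sub_arr.size and np.min(np.abs(sub_arr - m0)) < 10 + length
            ):
                continue
        return pos
    raise SimulationError("could not place an indel respecting spacing constraints")
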