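"""Cassette-exon annotation: microexons, reading frame, GC, NMD potential.

The NMD predictor rebuilds the inclusion and exclusion isoforms of a
cassette exon from a coding gene model, translates both from the annotated
start codon, and flags an isoform as decay-targeted when its first stop
codon lies more than ``rule_distance`` nt (default 50) upstream of the
isoform's last exon-exon junction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, NamedTuple, Sequence

import numpy as np
from scipy import stats

from .io_formats import SpliceEvent

STOP_CODONS = frozenset({"TAA", "TAG", "TGA"})
START_CODON = "ATG"

_COMPLEMENT = str.maketrans("ACGTNacgtn", "TGCANtgcan")


def reverse_complement(sequence: str) -> str:
    return sequence.translate(_COMPLEMENT)[::-1]


@dataclass(frozen=True)
class Transcript:
    """Ordered exon structure of one transcript (0-based half-open, genomic)."""

    transcript_id: str
    chrom: str
    strand: str
    exons: tuple[tuple[int, int], ...]  # sorted by genomic start
    cds: tuple[tuple[int, int], ...] = ()

    def __post_init__(self) -> None:
        for (s, e) in self.exons:
            if s >= e:
                raise ValueError(f"{self.transcript_id}: empty exon [{s},{e})")
        for (s1, e1), (s2, e2) in zip(self.exons, self.exons[1:]):
            if s2 < e1:
                raise ValueError(f"{self.transcript_id}: overlapping exons")

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.exons)

    @property
    def cds_length(self) -> int:
        return sum(e - s for s, e in self.cds)

    @property
    def is_coding(self) -> bool:
        return bool(self.cds)

    def spliced_sequence(self, genome: Mapping[str, str]) -> str:
        chrom_seq = genome[self.chrom]
        seq = "".join(chrom_seq[s:e] for s, e in self.exons)
        return reverse_complement(seq) if self.strand == "-" else seq

    def project(self, genomic_pos: int) -> int:
        """Map a genomic position inside an exon to transcript coordinates."""
        offset = 0
        for s, e in self.exons:
            if s <= genomic_pos < e:
                tpos = offset + (genomic_pos - s)
                if self.strand == "-":
                    return self.length - 1 - tpos
                return tpos
            offset += e - s
        raise ValueError(
            f"{self.transcript_id}: position {genomic_pos} is not exonic"
        )

    def junctions(self) -> list[int]:
        """Transcript coordinates just after each exon-exon junction, 5'->3'."""
        lengths = [e - s for s, e in self.exons]
        if self.strand == "-":
            lengths = lengths[::-1]
        return list(np.cumsum(lengths[:-1]))


@dataclass(frozen=True)
class GeneModel:
    """All transcripts of one gene."""

    gene_id: str
    transcripts: Sequence[Transcript]

    @property
    def is_coding(self) -> bool:
        return any(t.is_coding for t in self.transcripts)

    @property
    def chrom(self) -> str:
        return self.transcripts[0].chrom


class NmdCall(NamedTuple):
    nmd_isoform: str  # none / inclusion / exclusion / both
    ptc_distance_to_last_junction: int | None
    ambiguous: bool


@dataclass
class ExonAnnotation:
    """Per-cassette-exon annotation record."""

    event_id: str
    length: int
    is_microexon: bool
    frame_preserving: bool
    gc: float | None = None
    nmd_isoform: str | None = None
    ptc_distance_to_last_junction: int | None = None
    nmd_ambiguous: bool = False


def classify_microexon(length: int) -> bool:
    """True iff the exon is a microexon (3-27 nt, inclusive bounds)."""
    if length < 1:
        raise ValueError(f"exon length must be >= 1, got {length}")
    return 3 <= length <= 27


def gc_content(sequence: str) -> float:
    """GC fraction over ACGT; N is excluded from the denominator."""
    if not sequence:
        raise ValueError("empty sequence")
    seq = sequence.upper()
    bad = set(seq) - set("ACGTN")
    if bad:
        raise ValueError(f"unexpected characters in sequence: {sorted(bad)}")
    denom = sum(seq.count(b) for b in "ACGT")
    if denom == 0:
        raise ValueError("sequence contains no ACGT bases")
    return (seq.count("G") + seq.count("C")) / denom


class DistributionComparison(NamedTuple):
    statistic: float
    pvalue: float
    median_a: float
    median_b: float


def compare_distributions(a, b) -> DistributionComparison:
    """Two-sided Mann-Whitney U (normal approximation with tie correction)."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size < 3 or b.size < 3:
        raise ValueError("need at least 3 observations per sample")
    med_a, med_b = float(np.median(a)), float(np.median(b))
    if np.unique(np.concatenate([a, b])).size == 1:
        # degenerate all-tied input: U equals its null mean, no evidence
        return DistributionComparison(a.size * b.size / 2.0, 1.0, med_a, med_b)
    res = stats.mannwhitneyu(a, b, alternative="two-sided", method="asymptotic")
    return DistributionComparison(float(res.statistic), float(res.pvalue), med_a, med_b)


def _first_stop_end(transcript_seq: str, cds_start: int) -> int | None:
    """Transcript coordinate just past the first in-frame stop codon."""
    for i in range(cds_start, len(transcript_seq) - 2, 3):
        if transcript_seq[i : i + 3] in STOP_CODONS:
            return i + 3
    return None


def _isoform_nmd(
    transcript: Transcript,
    genome: Mapping[str, str],
    start_codon_genomic: int,
    rule_distance: int,
) -> tuple[bool, int | None]:
    """NMD status of one isoform: (targeted, distance of PTC to last junction)."""
    seq = transcript.spliced_sequence(genome)
    start = transcript.project(start_codon_genomic)
    stop_end = _first_stop_end(seq, start)
    junctions = transcript.junctions()
    if stop_end is None or not junctions:
        return False, None
    last_junction = junctions[-1]
    distance = last_junction - stop_end
    return distance > rule_distance, distance


def predict_nmd(
    model: GeneModel,
    event: SpliceEvent,
    genome: Mapping[str, str],
    rule_distance: int = 50,
) -> NmdCall:
    """Predict whether inclusion/exclusion of a cassette exon triggers NMD.

    The backbone is the transcript containing the cassette exon with the
    longest CDS; the exclusion isoform is the backbone minus the cassette.
    Cassette exons entirely in the UTR return ``none``; cassettes straddling
    a CDS boundary are flagged ambiguous and not called.
    """
    if not model.is_coding:
        raise ValueError(f"{model.gene_id}: gene model is non-coding")
    cassette = (event.exon_start, event.exon_end)
    candidates = [
        t
        for t in model.transcripts
        if t.is_coding and cassette in t.exons
    ]
    if not candidates:
        raise ValueError(
            f"{model.gene_id}: cassette exon {cassette} not found in any "
            f"coding transcript"
        )
    backbone = max(candidates, key=lambda t: t.cds_length)

    cds_min = min(s for s, _ in backbone.cds)
    cds_max = max(e for _, e in backbone.cds)
    if event.exon_end <= cds_min or event.exon_start >= cds_max:
        return NmdCall("none", None, False)
    if event.exon_start < cds_min < event.exon_end or event.exon_start < cds_max < event.exon_end:
        return NmdCall("none", None, True)

    # genomic position of the first base of the start codon
    if backbone.strand == "+":
        start_codon_genomic = cds_min
    else:
        start_codon_genomic = cds_max - 1
    inclusion = backbone
    exclusion = Transcript(
        transcript_id=backbone.transcript_id + "_excl",
        chrom=backbone.chrom,
        strand=backbone.strand,
        exons=tuple(x for x in backbone.exons if x != cassette),
        cds=tuple(x for x in backbone.cds if x != cassette),
    )
    inc_seq_ok = inclusion.spliced_sequence(genome)
    start_t = inclusion.project(start_codon_genomic)
    if inc_seq_ok[start_t : start_t + 3] != START_CODON:
        raise ValueError(
            f"{backbone.transcript_id}: annotated start codon is not ATG"
        )

    inc_nmd, inc_dist = _isoform_nmd(inclusion, genome, start_codon_genomic, rule_distance)
    exc_nmd, exc_dist = _isoform_nmd(exclusion, genome, start_codon_genomic, rule_distance)

    if inc_nmd and exc_nmd:
        label, dist = "both", exc_dist
    elif inc_nmd:
        label, dist = "inclusion", inc_dist
    elif exc_nmd:
        label, dist = "exclusion", exc_dist
    else:
        label, dist = "none", None
    return NmdCall(label, dist, False)


def annotate_event(
    event: SpliceEvent,
    genome: Mapping[str, str] | None = None,
    model: GeneModel | None = None,
    rule_distance: int = 50,
) -> ExonAnnotation:
    """Full annotation of one cassette exon (length/frame always; GC and NMD
    when sequence and gene model are available)."""
    length = event.exon_length
    record = ExonAnnotation(
        event_id=event.event_id,
        length=length,
        is_microexon=classify_microexon(length),
        frame_preserving=length % 3 == 0,
    )
    if genome is not None:
        exon_seq = genome[event.chrom][event.exon_start : event.exon_end]
        if event.strand == "-":
            exon_seq = reverse_complement(exon_seq)
        record.gc = gc_content(exon_seq)
    if genome is not None and model is not None:
        call = predict_nmd(model, event, genome, rule_distance=rule_distance)
        record.nmd_isoform = call.nmd_isoform
        record.ptc_distance_to_last_junction = call.ptc_distance_to_last_junction
        record.nmd_ambiguous = call.ambiguous
    return record


def annotate_events(
    events: Sequence[SpliceEvent],
    genome: Mapping[str, str] | None = None,
    models: Mapping[str, GeneModel] | None = None,
    rule_distance: int = 50,
):
    """Annotate many events; returns a pandas DataFrame."""
    import pandas as pd

    rows = []
    for event in events:
        model = models.get(event.gene_id) if models else None
        ann = annotate_event(event, genome=genome, model=model, rule_distance=rule_distance)
        rows.append(vars(ann))
    return pd.DataFrame(rows)
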