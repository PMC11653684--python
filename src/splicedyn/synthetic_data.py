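"""Synthetic junction counts, gene models and sequences with known truth.

Per event x sample, junction totals are negative-binomial and inclusion
counts are beta-binomial around a model-implied PSI, so downstream callers
can be exercised against planted ground truth without any external data.
All generators are seeded and deterministic.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
from scipy.special import expit

from .exon_annotation import (
    START_CODON,
    STOP_CODONS,
    GeneModel,
    Transcript,
)
from .io_formats import JunctionCountMatrix, SampleMetadata, SpliceEvent
from .motif_analysis import IUPAC_CODES, parse_pattern, pattern_length, scan_motif

PSI_CLAMP = (0.001, 0.999)

PSI_MODEL_KINDS = ("constant", "group_shift", "logistic_trajectory", "tissue_outlier")


@dataclass(frozen=True)
class PsiModel:
    """Ground-truth PSI pattern for one event.

    kinds:
      constant             base_psi everywhere
      group_shift          base_psi in GM, base_psi + delta in DM
      logistic_trajectory  base_psi + delta * expit(slope * (rank - midpoint))
      tissue_outlier       outlier_psi in outlier_tissue, base_psi elsewhere
    """

    kind: str = "constant"
    base_psi: float = 0.5
    delta: float = 0.0
    midpoint: float = 0.0
    slope: float = 1.0
    outlier_tissue: str | None = None
    outlier_psi: float | None = None

    def __post_init__(self) -> None:
        if self.kind not in PSI_MODEL_KINDS:
            raise ValueError(f"unknown PSI model kind {self.kind!r}")
        if not 0 < self.base_psi < 1:
            raise ValueError("base_psi must lie in (0, 1)")
        if self.kind == "tissue_outlier" and (
            self.outlier_tissue is None or self.outlier_psi is None
        ):
            raise ValueError("tissue_outlier model needs outlier_tissue and outlier_psi")

    def psi_for_samples(
        self, metadata: Sequence[SampleMetadata], stage_ranks: np.ndarray | None = None
    ) -> np.ndarray:
        if self.kind == "constant":
            psi = np.full(len(metadata), self.base_psi)
        elif self.kind == "group_shift":
            psi = np.array(
                [
                    self.base_psi + (self.delta if m.group == "DM" else 0.0)
                    for m in metadata
                ]
            )
        elif self.kind == "logistic_trajectory":
            if stage_ranks is None:
                raise ValueError("logistic_trajectory needs stage ranks")
            psi = self.base_psi + self.delta * expit(
                self.slope * (stage_ranks - self.midpoint)
            )
        else:  # tissue_outlier
            psi = np.array(
                [
                    self.outlier_psi if m.tissue == self.outlier_tissue else self.base_psi
                    for m in metadata
                ]
            )
        if np.any((psi < 0) | (psi > 1)):
            raise ValueError(
                f"PSI model {self.kind!r} implies values outside [0, 1]"
            )
        return np.clip(psi, *PSI_CLAMP)


@dataclass(frozen=True)
class NoiseParams:
    """Count-noise parameters.

    ``total_count_dispersion`` is the negative-binomial shape k of the
    junction totals (variance = mean + mean^2 / k); ``rho`` is the
    beta-binomial intra-class correlation (rho = 0 reduces to binomial).
    The default missing rate mirrors the ~0.6% missingness of real PSI
    tables.
    """

    total_count_mean: float = 100.0
    total_count_dispersion: float = 10.0
    rho: float = 0.02
    missing_rate: float = 0.006

    def __post_init__(self) -> None:
        if self.total_count_mean <= 0 or self.total_count_dispersion <= 0:
            raise ValueError("total-count mean and dispersion must be positive")
        if not 0 <= self.rho < 1:
            raise ValueError("rho must lie in [0, 1)")
        if not 0 <= self.missing_rate < 1:
            raise ValueError("missing_rate must lie in [0, 1)")


def _stage_ranks(metadata: Sequence[SampleMetadata]) -> np.ndarray | None:
    stages = [m.stage for m in metadata]
    if any(s is None for s in stages):
        return None
    from scipy.stats import rankdata

    return rankdata(np.asarray(stages, dtype=float), method="dense").astype(float)


def _beta_binomial(
    rng: np.random.Generator, n: np.ndarray, psi: np.ndarray, rho: float
) -> np.ndarray:
    if rho == 0:
        return rng.binomial(n, psi)
    scale = (1.0 - rho) / rho
    p = rng.beta(psi * scale, (1.0 - psi) * scale)
    return rng.binomial(n, p)


def _synthetic_events(n_events: int) -> list[SpliceEvent]:
    events = []
    for i in range(n_events):
        offset = 10_000 * i
        events.append(
            SpliceEvent(
                event_id=f"ev{i:05d}",
                gene_id=f"gene{i:05d}",
                event_type="SE",
                chrom="chrSim",
                strand="+",
                exon_start=offset + 2000,
                exon_end=offset + 2150,
                upstream_exon_start=offset + 1000,
                upstream_exon_end=offset + 1200,
                downstream_exon_start=offset + 3000,
                downstream_exon_end=offset + 3200,
            )
        )
    return events


def simulate_junction_counts(
    n_events: int,
    metadata: Sequence[SampleMetadata],
    psi_models: Sequence[PsiModel],
    noise: NoiseParams = NoiseParams(),
    seed: int = 0,
) -> tuple[JunctionCountMatrix, np.ndarray]:
    """Simulate an event x sample junction-count matrix with known truth.

    Returns the count matrix and the true (pre-noise) PSI matrix.  Cells
    drawn missing have both counts zeroed, which downstream PSI computation
    treats as missing.
    """
    if n_events < 1:
        raise ValueError("need at least 1 event")
    if len(metadata) < 2:
        raise ValueError("need at least 2 samples")
    if len(psi_models) != n_events:
        raise ValueError(
            f"{len(psi_models)} PSI models for {n_events} events"
        )
    rng = np.random.default_rng(seed)
    n_samples = len(metadata)
    ranks = _stage_ranks(metadata)
    true_psi = np.vstack(
        [model.psi_for_samples(metadata, ranks) for model in psi_models]
    )

    k = noise.total_count_dispersion
    p_nb = k / (k + noise.total_count_mean)
    totals = rng.negative_binomial(k, p_nb, size=(n_events, n_samples))
    inclusion = _beta_binomial(rng, totals, true_psi, noise.rho)
    skipping = totals - inclusion

    if noise.missing_rate > 0:
        mask = rng.random((n_events, n_samples)) < noise.missing_rate
        inclusion = np.where(mask, 0, inclusion)
        skipping = np.where(mask, 0, skipping)

    matrix = JunctionCountMatrix(
        events=_synthetic_events(n_events),
        sample_ids=[m.sample_id for m in metadata],
        inclusion=inclusion.astype(np.int64),
        skipping=skipping.astype(np.int64),
    )
    return matrix, true_psi


# ---------------------------------------------------------------------------
# gene model + sequence simulation
# ---------------------------------------------------------------------------

def random_sequence(length: int, gc: float, rng: np.random.Generator) -> str:
    """Random DNA with independent per-base GC probability ``gc``."""
    bases = np.where(
        rng.random(length) < gc,
        rng.choice(np.array(list("GC")), size=length),
        rng.choice(np.array(list("AT")), size=length),
    )
    return "".join(bases)


def _random_codon(rng: np.random.Generator, gc: float) -> str:
    while True:
        codon = random_sequence(3, gc, rng)
        if codon not in STOP_CODONS:
            return codon


def simulate_gene_model(
    exon_lengths: Sequence[int],
    cassette_index: int,
    cds_span: tuple[int, int],
    gc_target: float,
    seed: int = 0,
    intron_length: int = 500,
    flank: int = 200,
    chrom: str = "chrSim1",
    gene_id: str = "gsim",
) -> tuple[GeneModel, str]:
    """Build a single-cassette gene model plus its genomic sequence.

    ``cds_span`` is a (start, end) interval in inclusion-transcript
    coordinates (0-based half-open, length divisible by 3); a start codon is
    placed at its start and a stop codon at its end, with premature in-frame
    stops scrubbed from both the inclusion reading frame and, when the
    cassette preserves frame, the exclusion frame.  Realised GC is held
    within +-0.05 of ``gc_target`` by an acceptance loop.
    """
    exon_lengths = list(exon_lengths)
    if any(l < 1 for l in exon_lengths):
        raise ValueError("exon lengths must be >= 1")
    if not 0 < cassette_index < len(exon_lengths) - 1:
        raise ValueError("cassette exon must be flanked by at least one exon per side")
    cds_start, cds_end = cds_span
    transcript_length = sum(exon_lengths)
    if not (0 <= cds_start < cds_end <= transcript_length):
        raise ValueError("CDS span not fully inside the transcript")
    if (cds_end - cds_start) % 3 != 0 or cds_end - cds_start < 6:
        raise ValueError("CDS length must be a positive multiple of 3 (>= 6 nt)")

    # genomic layout (plus strand): flank, exons separated by fixed introns
    exons: list[tuple[int, int]] = []
    position = flank
    for length in exon_lengths:
        exons.append((position, position + length))
        position += length + intron_length
    genome_length = exons[-1][1] + flank
    cassette = exons[cassette_index]
    cassette_len = exon_lengths[cassette_index]

    # transcript -> genomic map for the inclusion isoform
    t2g = np.concatenate([np.arange(s, e) for s, e in exons])

    # exclusion-frame checkpoints (transcript coords of the inclusion isoform)
    cass_t_start = sum(exon_lengths[:cassette_index])
    cass_t_end = cass_t_start + cassette_len
    frame_preserving_in_cds = (
        cassette_len % 3 == 0 and cds_start <= cass_t_start and cass_t_end <= cds_end
    )

    rng = np.random.default_rng(seed)
    for _ in range(100):
        seq = list(random_sequence(genome_length, gc_target, rng))

        def write_transcript(t_pos: int, text: str) -> None:
            for offset, base in enumerate(text):
                seq[t2g[t_pos + offset]] = base

        def read_transcript(t_pos: int, n: int) -> str:
            return "".join(seq[g] for g in t2g[t_pos : t_pos + n])

        write_transcript(cds_start, START_CODON)
        write_transcript(cds_end - 3, "TAA")
        # scrub premature stops in the inclusion frame
        for _scrub in range(200):
            dirty = False
            for t in range(cds_start, cds_end - 3, 3):
                if read_transcript(t, 3) in STOP_CODONS:
                    write_transcript(t, _random_codon(rng, gc_target))
                    dirty = True
            if frame_preserving_in_cds:
                # exclusion transcript reads the same genomic bases minus the
                # cassette; check its frame (same phase, cassette spliced out)
                excl_cds = (
                    read_transcript(cds_start, cass_t_start - cds_start)
                    + read_transcript(cass_t_end, cds_end - cass_t_end)
                )
                for t in range(0, len(excl_cds) - 3, 3):
                    codon = excl_cds[t : t + 3]
                    if codon in STOP_CODONS:
                        # rewrite the genomic bases this exclusion-frame codon
                        # reads (skipping over the cassette interval)
                        replacement = _random_codon(rng, gc_target)
                        for offset in range(3):
                            pos = cds_start + t + offset
                            if pos >= cass_t_start:
                                pos += cassette_len
                            seq[t2g[pos]] = replacement[offset]
                        dirty = True
            if not dirty:
                break
        else:
            continue
        # protect the fixed codons (a scrub rewrite can never touch them, but
        # the cassette junction rewrite above may overlap the start codon)
        if read_transcript(cds_start, 3) != START_CODON:
            continue
        if read_transcript(cds_end - 3, 3) not in STOP_CODONS:
            continue
        realized_gc = (seq.count("G") + seq.count("C")) / len(seq)
        if abs(realized_gc - gc_target) <= 0.05:
            break
    else:
        raise RuntimeError("could not satisfy GC / stop-codon constraints")

    sequence = "".join(seq)

    def genomic_cds(exon_set: list[tuple[int, int]], lo: int, hi: int) -> tuple:
        intervals = []
        for s, e in exon_set:
            a, b = max(s, lo), min(e, hi)
            if a < b:
                intervals.append((a, b))
        return tuple(intervals)

    cds_lo, cds_hi = int(t2g[cds_start]), int(t2g[cds_end - 1]) + 1
    inclusion = Transcript(
        transcript_id=f"{gene_id}_inc",
        chrom=chrom,
        strand="+",
        exons=tuple(exons),
        cds=genomic_cds(exons, cds_lo, cds_hi),
    )
    exclusion_exons = [x for x in exons if x != cassette]
    exclusion = Transcript(
        transcript_id=f"{gene_id}_exc",
        chrom=chrom,
        strand="+",
        exons=tuple(exclusion_exons),
        cds=genomic_cds(exclusion_exons, cds_lo, cds_hi),
    )
    model = GeneModel(gene_id=gene_id, transcripts=[inclusion, exclusion])
    return model, sequence


def cassette_event_from_model(model: GeneModel, event_id: str = "evsim") -> SpliceEvent:
    """Derive the SpliceEvent of the (single) cassette exon of a model."""
    inclusion = max(model.transcripts, key=lambda t: len(t.exons))
    exclusion = min(model.transcripts, key=lambda t: len(t.exons))
    cassette = [x for x in inclusion.exons if x not in exclusion.exons]
    if len(cassette) != 1:
        raise ValueError("model does not contain exactly one cassette exon")
    (cs, ce) = cassette[0]
    idx = inclusion.exons.index((cs, ce))
    up = inclusion.exons[idx - 1]
    down = inclusion.exons[idx + 1]
    if inclusion.strand == "-":
        up, down = down, up
    return SpliceEvent(
        event_id=event_id,
        gene_id=model.gene_id,
        event_type="SE",
        chrom=inclusion.chrom,
        strand=inclusion.strand,
        exon_start=cs,
        exon_end=ce,
        upstream_exon_start=up[0],
        upstream_exon_end=up[1],
        downstream_exon_start=down[0],
        downstream_exon_end=down[1],
    )


# ---------------------------------------------------------------------------
# motif planting
# ---------------------------------------------------------------------------

def _concrete_motif(pattern: str) -> str:
    """Deterministic concrete expansion: first base (alphabetical) per position."""
    return "".join(sorted(allowed)[0] for allowed in parse_pattern(pattern))


def plant_motifs(
    sequence: str,
    motif: str,
    offsets: Sequence[int],
    seed: int = 0,
) -> str:
    """Plant a motif at given 0-based offsets and scrub all other matches.

    Accidental matches are broken by resampling a minimal number of
    positions outside the planted intervals, preserving background
    composition; the returned sequence matches the motif exactly at the
    planted offsets and nowhere else.
    """
    m = pattern_length(motif)
    positions = parse_pattern(motif)
    offsets = sorted(int(o) for o in offsets)
    for a, b in zip(offsets, offsets[1:]):
        if b < a + m:
            raise ValueError(f"planted offsets {a} and {b} overlap")
    for off in offsets:
        if off < 0 or off + m > len(sequence):
            raise ValueError(f"offset {off} out of range for motif of length {m}")

    rng = np.random.default_rng(seed)
    seq = list(sequence.upper())
    concrete = _concrete_motif(motif)
    planted = set()
    for off in offsets:
        seq[off : off + m] = concrete
        planted.update(range(off, off + m))

    alphabet = "ACGT"
    for _ in range(1000):
        matches = scan_motif("".join(seq), motif)
        extra = [x for x in matches if x not in offsets]
        if not extra:
            break
        for hit in extra:
            free = [
                i for i in range(hit, hit + m) if i not in planted
            ]
            if not free:  # cannot happen with non-overlapping plants
                raise RuntimeError("accidental match fully inside planted bases")
            target = free[rng.integers(len(free))]
            allowed = positions[target - hit]
            breaking = [b for b in alphabet if b not in allowed]
            seq[target] = breaking[rng.integers(len(breaking))]
    else:
        raise RuntimeError("could not scrub accidental motif matches")
    result = "".join(seq)
    assert scan_motif(result, motif) == offsets
    return result


# ---------------------------------------------------------------------------
# scenario driver (YAML-friendly dict in, full simulation out)
# ---------------------------------------------------------------------------

def models_from_config(blocks: Sequence[Mapping]) -> list[PsiModel]:
    """Expand scenario model blocks (each with an ``n`` multiplier)."""
    models: list[PsiModel] = []
    for block in blocks:
        block = dict(block)
        n = int(block.pop("n", 1))
        models.extend([PsiModel(**block)] * n)
    return models


def simulate_scenario(config: Mapping, seed: int = 0):
    """Run a full scenario: returns (counts, true_psi, metadata, models).

    ``config`` keys: ``samples`` (list of sample-metadata dicts),
    ``models`` (list of PSI-model blocks with ``n``), ``noise`` (optional
    NoiseParams fields).
    """
    metadata = [SampleMetadata(**s) for s in config["samples"]]
    models = models_from_config(config["models"])
    noise = NoiseParams(**config.get("noise", {}))
    counts, truth = simulate_junction_counts(
        len(models), metadata, models, noise=noise, seed=seed
    )
    return counts, truth, metadata, models
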