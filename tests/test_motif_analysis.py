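import numpy as np
import pytest

from splicedyn.exon_annotation import reverse_complement
from splicedyn.motif_analysis import (
    IUPAC_CODES,
    extract_flanks,
    parse_pattern,
    pearson_correlation,
    positional_enrichment,
    scan_event,
    scan_motif,
)
from splicedyn.synthetic_data import plant_motifs, random_sequence

from conftest import make_event


def scan_oracle(sequence, pattern):
    """Brute-force position-by-position IUPAC comparison."""
    seq = sequence.upper().replace("U", "T")
    positions = parse_pattern(pattern)
    hits = []
    for i in range(len(seq) - len(positions) + 1):
        if all(seq[i + j] in allowed for j, allowed in enumerate(positions)):
            hits.append(i)
    return hits


class TestScanMotif:
    def test_single_match(self):
        assert scan_motif("AAGTGTGAA", "GTGTG") == [2]

    def test_overlapping_matches_reported(self):
        assert scan_motif("GTGTGTG", "GTGTG") == [0, 2]

    def test_bracket_group_pattern(self):
        assert scan_motif("ATGACG", "A[CU]GAC[AG]") == [0]

    def test_u_equals_t(self):
        # an RNA-style pattern (with U) matches T in DNA sequence, and a
        # sequence containing U is normalised before scanning
        assert scan_motif("ATGACA", "AUGACA") == [0]
        assert scan_motif("AUGACA", "ATGACA") == [0]
        assert scan_motif("ATGACA", "A[CU]GAC[AG]") == [0]

    def test_invalid_code_rejected(self):
        with pytest.raises(ValueError, match="IUPAC"):
            scan_motif("ACGT", "AXGT")

    def test_unbalanced_bracket_rejected(self):
        with pytest.raises(ValueError, match="bracket"):
            scan_motif("ACGT", "A[CG")

    def test_matches_brute_force_oracle(self):
        rng = np.random.default_rng(81)
        codes = list(IUPAC_CODES)
        for _ in range(200):
            seq = "".join(rng.choice(list("ACGT"), size=60))
            pattern = "".join(rng.choice(codes, size=rng.integers(2, 7)))
            assert scan_motif(seq, pattern) == scan_oracle(seq, pattern)


def build_genome(event, seed=0):
    length = max(
        event.exon_end,
        event.upstream_exon_end,
        event.downstream_exon_end,
    ) + 2000
    return {event.chrom: random_sequence(length, 0.5, np.random.default_rng(seed))}


class TestExtractFlanks:
    def test_plus_strand_downstream_intron(self):
        event = make_event()  # introns of 800 nt
        genome = build_genome(event)
        regions = extract_flanks(event, genome, window=250)
        down = regions["downstream_intron"]
        assert down.genomic_start == event.exon_end
        assert len(down.sequence) == 250
        assert not down.truncated
        assert down.sequence == genome[event.chrom][event.exon_end : event.exon_end + 250]

    def test_minus_strand_mirror(self):
        plus = make_event()
        genome = build_genome(plus)
        plus_regions = extract_flanks(plus, genome, window=250)

        length = len(genome[plus.chrom])
        flip = lambda s, e: (length - e, length - s)
        minus = make_event(strand="-")
        # mirror the locus: flip every interval and reverse-complement the genome
        es, ee = flip(plus.exon_start, plus.exon_end)
        us, ue = flip(plus.upstream_exon_start, plus.upstream_exon_end)
        ds, de = flip(plus.downstream_exon_start, plus.downstream_exon_end)
        from splicedyn.io_formats import SpliceEvent

        minus = SpliceEvent(
            event_id="m", gene_id="g", event_type="SE", chrom=plus.chrom,
            strand="-", exon_start=es, exon_end=ee,
            upstream_exon_start=us, upstream_exon_end=ue,
            downstream_exon_start=ds, downstream_exon_end=de,
        )
        minus_genome = {plus.chrom: reverse_complement(genome[plus.chrom])}
        minus_regions = extract_flanks(minus, minus_genome, window=250)
        for name in plus_regions:
            assert minus_regions[name].sequence == plus_regions[name].sequence, name

    def test_short_intron_truncated(self):
        event = make_event()
        # shrink the downstream intron to 100 nt
        from splicedyn.io_formats import SpliceEvent

        short = SpliceEvent(
            event_id="s", gene_id="g", event_type="SE", chrom=event.chrom,
            strand="+", exon_start=event.exon_start, exon_end=event.exon_end,
            upstream_exon_start=event.upstream_exon_start,
            upstream_exon_end=event.upstream_exon_end,
            downstream_exon_start=event.exon_end + 100,
            downstream_exon_end=event.exon_end + 300,
        )
        genome = build_genome(short)
        region = extract_flanks(short, genome, window=250)["downstream_intron"]
        assert len(region.sequence) == 100
        assert region.truncated

    def test_off_sequence_rejected(self):
        event = make_event()
        tiny = {event.chrom: "ACGT" * 100}
        with pytest.raises(ValueError, match="outside"):
            extract_flanks(event, tiny, window=250)

    def test_strand_round_trip_with_scan(self):
        # planted motif offsets survive the minus-strand round trip
        event = make_event()
        genome = build_genome(event, seed=5)
        seq = genome[event.chrom]
        intron = seq[event.exon_end : event.exon_end + 250]
        planted_intron = plant_motifs(intron, "GTGTG", [99], seed=6)
        genome[event.chrom] = (
            seq[: event.exon_end] + planted_intron + seq[event.exon_end + 250 :]
        )
        hits = scan_event(event, genome, "GTGTG", window=250)
        down = [h for h in hits if h.region == "downstream_intron"]
        assert [h.offset for h in down] == [99]
        assert down[0].position_1based == 100


def planted_events(n, chrom, offset=100):
    events = []
    for i in range(n):
        base = 10_000 * i
        events.append(
            make_event(f"{chrom}_{i}", exon=(base + 2000, base + 2150), chrom=chrom)
        )
    return events


class TestPositionalEnrichment:
    def _genomes(self, n=50, plant_in="target", seed=90):
        rng = np.random.default_rng(seed)
        targets = planted_events(n, "chrT")
        backgrounds = planted_events(n, "chrB")
        genome = {
            "chrT": random_sequence(10_000 * n, 0.5, rng),
            "chrB": random_sequence(10_000 * n, 0.5, rng),
        }
        chrom = {"target": "chrT", "background": "chrB"}[plant_in]
        events = targets if plant_in == "target" else backgrounds
        seq = genome[chrom]
        for event in events:
            start = event.exon_end
            intron = seq[start : start + 250]
            seq = seq[:start] + plant_motifs(intron, "GTGTG", [100], seed=seed) + seq[start + 250 :]
        genome[chrom] = seq
        return targets, backgrounds, genome

    def test_planted_signal_recovered(self):
        targets, backgrounds, genome = self._genomes()
        profile = positional_enrichment(targets, backgrounds, "GTGTG", genome)
        peak = profile.peak
        assert peak["region"] == "downstream_intron"
        assert abs(peak["position"] - 100) <= 25
        assert peak["pvalue"] < 1e-4

    def test_null_identity(self):
        targets, _, genome = self._genomes()
        profile = positional_enrichment(targets, targets, "GTGTG", genome)
        assert profile.profile["fdr"].min() > 0.05

    def test_reversed_planting(self):
        targets, backgrounds, genome = self._genomes(plant_in="background")
        profile = positional_enrichment(targets, backgrounds, "GTGTG", genome)
        down = profile.profile[profile.profile.region == "downstream_intron"]
        row = down.loc[(down.position - 100).abs().idxmin()]
        assert row.background_score > row.target_score

    def test_empty_set_rejected(self):
        targets, backgrounds, genome = self._genomes(n=5)
        with pytest.raises(ValueError, match="non-empty"):
            positional_enrichment([], backgrounds, "GTGTG", genome)

    def test_small_set_warns(self):
        targets, backgrounds, genome = self._genomes(n=5)
        with pytest.warns(UserWarning, match="fewer than"):
            positional_enrichment(targets, backgrounds, "GTGTG", genome)

    def test_smoothed_coverage_integral(self):
        targets, backgrounds, genome = self._genomes(n=30)
        profile = positional_enrichment(targets, backgrounds, "GTGTG", genome).profile
        down = profile[profile.region == "downstream_intron"]
        raw_total = 0
        m = 5
        for event in targets:
            seq = genome["chrT"][event.exon_end : event.exon_end + 250]
            mask = np.zeros(250, dtype=bool)
            for off in scan_motif(seq, "GTGTG"):
                mask[off : off + m] = True
            raw_total += mask.sum()
        # smoothing preserves total coverage up to edge effects of the window
        smoothed_total = (down.target_score * down.n_target).sum()
        assert smoothed_total == pytest.approx(raw_total, rel=0.15)


class TestPearson:
    def test_identical_vectors(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, x) == pytest.approx(1.0)

    def test_anticorrelated(self):
        x = np.arange(10.0)
        assert pearson_correlation(x, -x) == pytest.approx(-1.0)

    def test_independent_near_zero(self):
        rng = np.random.default_rng(91)
        assert abs(pearson_correlation(rng.normal(size=5000), rng.normal(size=5000))) < 0.05
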