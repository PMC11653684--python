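"""Flanking-region extraction, IUPAC motif scanning and positional enrichment.

Motif patterns may mix IUPAC one-letter codes (R, Y, N, ...) with explicit
bracket groups (e.g. ``A[CU]GAC[AG]``).  U is treated as T so RNA-style
motifs scan DNA sequence.  Offsets are 0-based from the 5' end of each
region in transcript (pre-mRNA sense) orientation; 1-based positions for
"N nt downstream" phrasing are offset + 1.
"""

from __future__ import annotations

import re
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .exon_annotation import reverse_complement
from .io_formats import SpliceEvent

IUPAC_CODES: dict[str, frozenset[str]] = {
    "A": frozenset("A"),
    "C": frozenset("C"),
    "G": frozenset("G"),
    "T": frozenset("T"),
    "U": frozenset("T"),
    "R": frozenset("AG"),
    "Y": frozenset("CT"),
    "S": frozenset("CG"),
    "W": frozenset("AT"),
    "K": frozenset("GT"),
    "M": frozenset("AC"),
    "B": frozenset("CGT"),
    "D": frozenset("AGT"),
    "H": frozenset("ACT"),
    "V": frozenset("ACG"),
    "N": frozenset("ACGT"),
}

REGIONS = (
    "upstream_exon_flank",
    "upstream_intron",
    "cassette_exon",
    "downstream_intron",
    "downstream_exon_flank",
)


def parse_pattern(pattern: str) -> list[frozenset[str]]:
    """Expand a motif string into a per-position list of allowed bases."""
    positions: list[frozenset[str]] = []
    i = 0
    while i < len(pattern):
        ch = pattern[i]
        if ch == "[":
            end = pattern.find("]", i)
            if end == -1:
                raise ValueError(f"unbalanced bracket in pattern {pattern!r}")
            group: set[str] = set()
            for code in pattern[i + 1 : end].upper():
                if code not in IUPAC_CODES:
                    raise ValueError(f"invalid IUPAC code {code!r} in {pattern!r}")
                group |= IUPAC_CODES[code]
            if not group:
                raise ValueError(f"empty bracket group in {pattern!r}")
            positions.append(frozenset(group))
            i = end + 1
        else:
            code = ch.upper()
            if code not in IUPAC_CODES:
                raise ValueError(f"invalid IUPAC code {code!r} in {pattern!r}")
            positions.append(IUPAC_CODES[code])
            i += 1
    if not positions:
        raise ValueError("empty motif pattern")
    return positions


def pattern_length(pattern: str) -> int:
    return len(parse_pattern(pattern))


def _pattern_regex(pattern: str) -> re.Pattern:
    parts = ["[" + "".join(sorted(allowed)) + "]" for allowed in parse_pattern(pattern)]
    # lookahead so overlapping matches are all reported
    return re.compile("(?=" + "".join(parts) + ")")


def scan_motif(sequence: str, pattern: str) -> list[int]:
    """All (including overlapping) 0-based match offsets, ascending."""
    regex = _pattern_regex(pattern)
    return [m.start() for m in regex.finditer(sequence.upper().replace("U", "T"))]


@dataclass(frozen=True)
class FlankRegion:
    """One extracted meta-region, in transcript orientation."""

    region: str
    sequence: str
    truncated: bool
    genomic_start: int
    genomic_end: int


@dataclass(frozen=True)
class MotifHit:
    event_id: str
    pattern: str
    region: str
    offset: int  # 0-based from the region's 5' end

    @property
    def position_1based(self) -> int:
        return self.offset + 1


def _slice(genome: Mapping[str, str], chrom: str, start: int, end: int) -> str:
    seq = genome[chrom]
    if start < 0 or end > len(seq):
        raise ValueError(
            f"region [{start},{end}) falls outside {chrom} (length {len(seq)})"
        )
    return seq[start:end]


def extract_flanks(
    event: SpliceEvent,
    genome: Mapping[str, str],
    window: int = 250,
    exon_flank: int = 50,
) -> dict[str, FlankRegion]:
    """Extract the five meta-regions around a cassette exon.

    Intronic regions take the ``window`` nt adjacent to the cassette exon;
    exonic flanks take the ``exon_flank`` nt of each flanking exon adjacent
    to its intron.  Minus-strand events are reverse-complemented so all
    sequences read 5'->3' in transcript orientation; regions shorter than
    requested are returned truncated and flagged.
    """
    s = event
    if s.strand == "+":
        intervals = {
            "upstream_exon_flank": (
                max(s.upstream_exon_start, s.upstream_exon_end - exon_flank),
                s.upstream_exon_end,
            ),
            "upstream_intron": (max(s.upstream_exon_end, s.exon_start - window), s.exon_start),
            "cassette_exon": (s.exon_start, s.exon_end),
            "downstream_intron": (s.exon_end, min(s.downstream_exon_start, s.exon_end + window)),
            "downstream_exon_flank": (
                s.downstream_exon_start,
                min(s.downstream_exon_end, s.downstream_exon_start + exon_flank),
            ),
        }
        full = {
            "upstream_exon_flank": exon_flank,
            "upstream_intron": window,
            "cassette_exon": s.exon_end - s.exon_start,
            "downstream_intron": window,
            "downstream_exon_flank": exon_flank,
        }
    else:
        intervals = {
            "upstream_exon_flank": (
                s.upstream_exon_start,
                min(s.upstream_exon_end, s.upstream_exon_start + exon_flank),
            ),
            "upstream_intron": (s.exon_end, min(s.upstream_exon_start, s.exon_end + window)),
            "cassette_exon": (s.exon_start, s.exon_end),
            "downstream_intron": (max(s.downstream_exon_end, s.exon_start - window), s.exon_start),
            "downstream_exon_flank": (
                max(s.downstream_exon_start, s.downstream_exon_end - exon_flank),
                s.downstream_exon_end,
            ),
        }
        full = {
            "upstream_exon_flank": exon_flank,
            "upstream_intron": window,
            "cassette_exon": s.exon_end - s.exon_start,
            "downstream_intron": window,
            "downstream_exon_flank": exon_flank,
        }
    out = {}
    for region, (start, end) in intervals.items():
        seq = _slice(genome, s.chrom, start, end)
        if s.strand == "-":
            seq = reverse_complement(seq)
        out[region] = FlankRegion(
            region=region,
            sequence=seq,
            truncated=len(seq) < full[region],
            genomic_start=start,
            genomic_end=end,
        )
    return out


def scan_event(
    event: SpliceEvent,
    genome: Mapping[str, str],
    pattern: str,
    window: int = 250,
    exon_flank: int = 50,
) -> list[MotifHit]:
    """Scan all five meta-regions of one event for a motif."""
    hits = []
    for region_name, region in extract_flanks(event, genome, window, exon_flank).items():
        for offset in scan_motif(region.sequence, pattern):
            hits.append(MotifHit(event.event_id, pattern, region_name, offset))
    return hits


@dataclass
class PositionalEnrichment:
    """rMAPS-style positional motif-coverage comparison of two event sets."""

    profile: pd.DataFrame  # region, position, scores, pvalue, fdr
    pattern: str
    flank: int
    window: int

    @property
    def peak(self) -> pd.Series:
        return self.profile.loc[self.profile["pvalue"].idxmin()]


def _coverage(
    events: Sequence[SpliceEvent],
    genome: Mapping[str, str],
    pattern: str,
    flank: int,
    exon_flank: int,
    lengths: dict[str, int],
) -> tuple[dict[str, np.ndarray], dict[str, np.ndarray]]:
    m = pattern_length(pattern)
    covered = {r: np.zeros(n, dtype=float) for r, n in lengths.items()}
    present = {r: np.zeros(n, dtype=float) for r, n in lengths.items()}
    for event in events:
        regions = extract_flanks(event, genome, flank, exon_flank)
        for rname, n in lengths.items():
            seq = regions[rname].sequence
            k = min(len(seq), n)
            if k == 0:
                continue
            present[rname][:k] += 1
            mask = np.zeros(k, dtype=bool)
            for off in scan_motif(seq, pattern):
                mask[off : min(off + m, k)] = True
            covered[rname][:k] += mask
    return covered, present


def positional_enrichment(
    target_events: Sequence[SpliceEvent],
    background_events: Sequence[SpliceEvent],
    pattern: str,
    genome: Mapping[str, str],
    flank: int = 250,
    window: int = 50,
    exon_flank: int = 50,
    min_events: int = 20,
) -> PositionalEnrichment:
    """Per-position motif coverage of targets vs background with smoothing.

    Coverage fraction at a position is the share of events whose region
    covers that position and carries a motif overlapping it; fractions are
    smoothed with a centered ``window``-nt moving average and compared by a
    one-sided two-proportion z-test (target > background), BH-adjusted
    across positions.
    """
    if not target_events or not background_events:
        raise ValueError("target and background event sets must be non-empty")
    import warnings

    if len(target_events) < min_events or len(background_events) < min_events:
        warnings.warn(
            f"fewer than {min_events} events in a set; positional p-values "
            f"will be unstable",
            stacklevel=2,
        )
    max_cassette = max(
        e.exon_length for e in list(target_events) + list(background_events)
    )
    lengths = {
        "upstream_exon_flank": exon_flank,
        "upstream_intron": flank,
        "cassette_exon": max_cassette,
        "downstream_intron": flank,
        "downstream_exon_flank": exon_flank,
    }
    cov_t, n_t = _coverage(target_events, genome, pattern, flank, exon_flank, lengths)
    cov_b, n_b = _coverage(background_events, genome, pattern, flank, exon_flank, lengths)

    rows = []
    for rname in REGIONS:
        with np.errstate(invalid="ignore", divide="ignore"):
            frac_t = np.where(n_t[rname] > 0, cov_t[rname] / np.maximum(n_t[rname], 1), 0.0)
            frac_b = np.where(n_b[rname] > 0, cov_b[rname] / np.maximum(n_b[rname], 1), 0.0)
        smooth_t = (
            pd.Series(frac_t).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
        smooth_b = (
            pd.Series(frac_b).rolling(window, center=True, min_periods=1).mean().to_numpy()
        )
        for pos in range(lengths[rname]):
            nt, nb = n_t[rname][pos], n_b[rname][pos]
            xt, xb = cov_t[rname][pos], cov_b[rname][pos]
            pvalue = _two_proportion_pvalue(xt, nt, xb, nb)
            rows.append(
                {
                    "region": rname,
                    "position": pos,
                    "n_target": int(nt),
                    "n_background": int(nb),
                    "target_score": smooth_t[pos],
                    "background_score": smooth_b[pos],
                    "pvalue": pvalue,
                }
            )
    profile = pd.DataFrame(rows)
    from .differential_splicing import benjamini_hochberg

    profile["fdr"] = benjamini_hochberg(profile["pvalue"].to_numpy())
    return PositionalEnrichment(profile=profile, pattern=pattern, flank=flank, window=window)


def _two_proportion_pvalue(x1: float, n1: float, x2: float, n2: float) -> float:
    """One-sided (p1 > p2) pooled two-proportion z-test."""
    if n1 == 0 or n2 == 0:
        return 1.0
    p1, p2 = x1 / n1, x2 / n2
    pooled = (x1 + x2) / (n1 + n2)
    var = pooled * (1 - pooled) * (1 / n1 + 1 / n2)
    if var <= 0:
        return 0.5
    z = (p1 - p2) / np.sqrt(var)
    return float(stats.norm.sf(z))


def pearson_correlation(x, y) -> float:
    """Plain Pearson correlation of two vectors (expression-report plumbing)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape or x.size < 2:
        raise ValueError("vectors must share a length of at least 2")
    return float(np.corrcoef(x, y)[0, 1])


def hits_to_frame(hits: Sequence[MotifHit]) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "event_id": [h.event_id for h in hits],
            "pattern": [h.pattern for h in hits],
            "region": [h.region for h in hits],
            "offset": [h.offset for h in hits],
            "position_1based": [h.position_1based for h in hits],
        }
    )
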