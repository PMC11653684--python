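"""Data model, table readers/writers and summary reporting.

Internal coordinates are 0-based half-open everywhere; conversion to and
from 1-based conventions (GTF) happens only at file boundaries.

The event/count table dialect follows the junction-count (JC) layout of
common event callers: one row per skipped-exon event with the target exon,
its flanking exons, and comma-separated per-sample inclusion (IJC) and
skipping (SJC) junction counts.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field, replace
from decimal import Decimal, ROUND_HALF_UP
from pathlib import Path
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

EVENT_TYPES = ("SE", "MXE", "A5SS", "A3SS", "RI")

#: Canonical column order of the event/count TSV dialect.
EVENT_TABLE_COLUMNS = (
    "event_id",
    "GeneID",
    "chr",
    "strand",
    "eventType",
    "exonStart_0base",
    "exonEnd",
    "upstreamES",
    "upstreamEE",
    "downstreamES",
    "downstreamEE",
    "IJC_SAMPLE",
    "SJC_SAMPLE",
)

_JCEC_EXTRA_COLUMNS = ("IncFormLen", "SkipFormLen")


@dataclass(frozen=True)
class SpliceEvent:
    """One alternative-splicing event (target exon plus flanking exons).

    Coordinates are genomic, 0-based half-open.  ``upstream`` /
    ``downstream`` refer to transcript orientation: on the minus strand the
    upstream exon lies genomically to the right of the target exon.
    """

    event_id: str
    gene_id: str
    event_type: str
    chrom: str
    strand: str
    exon_start: int
    exon_end: int
    upstream_exon_start: int
    upstream_exon_end: int
    downstream_exon_start: int
    downstream_exon_end: int

    def __post_init__(self) -> None:
        if self.event_type not in EVENT_TYPES:
            raise ValueError(f"unknown event type {self.event_type!r}")
        if self.strand not in ("+", "-"):
            raise ValueError(f"strand must be '+' or '-', got {self.strand!r}")
        if not self.exon_start < self.exon_end:
            raise ValueError(
                f"{self.event_id}: exon_start must be < exon_end "
                f"({self.exon_start} >= {self.exon_end})"
            )
        if not self.upstream_exon_start < self.upstream_exon_end:
            raise ValueError(f"{self.event_id}: malformed upstream exon")
        if not self.downstream_exon_start < self.downstream_exon_end:
            raise ValueError(f"{self.event_id}: malformed downstream exon")
        if self.strand == "+":
            ok = (
                self.upstream_exon_end <= self.exon_start
                and self.downstream_exon_start >= self.exon_end
            )
        else:
            ok = (
                self.upstream_exon_start >= self.exon_end
                and self.downstream_exon_end <= self.exon_start
            )
        if not ok:
            raise ValueError(
                f"{self.event_id}: flanking exons are not on the expected "
                f"side of the target exon for strand {self.strand}"
            )

    @property
    def exon_length(self) -> int:
        return self.exon_end - self.exon_start


@dataclass(frozen=True)
class SampleMetadata:
    """Typed per-sample metadata (condition group, stage, tissue)."""

    sample_id: str
    group: str = "other"
    stage: float | None = None
    tissue: str | None = None
    replicate: int = 1


@dataclass
class JunctionCountMatrix:
    """Inclusion (L) and skipping (S) junction counts per event x sample."""

    events: list[SpliceEvent]
    sample_ids: list[str]
    inclusion: np.ndarray  # int, shape (n_events, n_samples)
    skipping: np.ndarray
    inc_form_len: np.ndarray | None = None  # per-event effective lengths (JCEC)
    skip_form_len: np.ndarray | None = None

    def __post_init__(self) -> None:
        shape = (len(self.events), len(self.sample_ids))
        self.inclusion = np.asarray(self.inclusion)
        self.skipping = np.asarray(self.skipping)
        if self.inclusion.shape != shape or self.skipping.shape != shape:
            raise ValueError(
                f"count matrices must have shape {shape}, got "
                f"{self.inclusion.shape} / {self.skipping.shape}"
            )
        if (self.inclusion < 0).any() or (self.skipping < 0).any():
            raise ValueError("negative junction counts are not allowed")
        if len({e.event_id for e in self.events}) != len(self.events):
            raise ValueError("duplicate event_ids in count matrix")

    @property
    def event_ids(self) -> list[str]:
        return [e.event_id for e in self.events]

    def total(self) -> np.ndarray:
        """Per-cell total junction support L + S."""
        return self.inclusion + self.skipping


def _parse_counts(text: str, n_samples: int, line_no: int, column: str) -> list[int]:
    parts = text.split(",")
    if len(parts) != n_samples:
        raise ValueError(
            f"line {line_no}: {column} has {len(parts)} counts for "
            f"{n_samples} samples"
        )
    counts = []
    for p in parts:
        try:
            value = int(p)
        except ValueError as exc:
            raise ValueError(f"line {line_no}: malformed count {p!r} in {column}") from exc
        if value < 0:
            raise ValueError(f"line {line_no}: negative count {value} in {column}")
        counts.append(value)
    return counts


def read_event_table(
    path: str | Path,
    dialect: str = "jc",
    sample_ids: Sequence[str] | None = None,
) -> tuple[list[SpliceEvent], JunctionCountMatrix]:
    """Read an event/count TSV into events plus a :class:`JunctionCountMatrix`.

    ``dialect`` is ``"jc"`` (plain junction counts) or ``"jcec"`` (junction
    counts plus ``IncFormLen``/``SkipFormLen`` effective lengths, retained
    for optional length normalisation downstream).
    """
    if dialect not in ("jc", "jcec"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    events: list[SpliceEvent] = []
    inc_rows: list[list[int]] = []
    skip_rows: list[list[int]] = []
    inc_lens: list[float] = []
    skip_lens: list[float] = []
    n_samples: int | None = None

    with path.open() as handle:
        reader = csv.reader(handle, delimiter="\t")
        try:
            header = next(reader)
        except StopIteration:
            raise ValueError(f"{path}: empty event table") from None
        missing = [c for c in EVENT_TABLE_COLUMNS if c not in header]
        if missing:
            raise ValueError(f"{path}: missing columns {missing}")
        idx = {name: header.index(name) for name in header}
        has_lens = all(c in idx for c in _JCEC_EXTRA_COLUMNS)
        if dialect == "jcec" and not has_lens:
            raise ValueError(f"{path}: jcec dialect requires {_JCEC_EXTRA_COLUMNS}")

        for line_no, row in enumerate(reader, start=2):
            if not row or (len(row) == 1 and not row[0].strip()):
                continue
            if len(row) != len(header):
                raise ValueError(
                    f"line {line_no}: expected {len(header)} fields, got {len(row)}"
                )
            try:
                event = SpliceEvent(
                    event_id=row[idx["event_id"]],
                    gene_id=row[idx["GeneID"]],
                    event_type=row[idx["eventType"]],
                    chrom=row[idx["chr"]],
                    strand=row[idx["strand"]],
                    exon_start=int(row[idx["exonStart_0base"]]),
                    exon_end=int(row[idx["exonEnd"]]),
                    upstream_exon_start=int(row[idx["upstreamES"]]),
                    upstream_exon_end=int(row[idx["upstreamEE"]]),
                    downstream_exon_start=int(row[idx["downstreamES"]]),
                    downstream_exon_end=int(row[idx["downstreamEE"]]),
                )
            except ValueError as exc:
                raise ValueError(f"line {line_no}: {exc}") from exc
            inc_text = row[idx["IJC_SAMPLE"]]
            if n_samples is None:
                n_samples = len(inc_text.split(","))
                if sample_ids is not None and len(sample_ids) != n_samples:
                    raise ValueError(
                        f"line {line_no}: {len(sample_ids)} sample_ids given but "
                        f"rows carry {n_samples} counts"
                    )
            inc_rows.append(_parse_counts(inc_text, n_samples, line_no, "IJC_SAMPLE"))
            skip_rows.append(
                _parse_counts(row[idx["SJC_SAMPLE"]], n_samples, line_no, "SJC_SAMPLE")
            )
            if has_lens:
                inc_lens.append(float(row[idx["IncFormLen"]]))
                skip_lens.append(float(row[idx["SkipFormLen"]]))
            events.append(event)

    if n_samples is None:
        raise ValueError(f"{path}: event table has no data rows")
    ids = list(sample_ids) if sample_ids is not None else [
        f"S{i + 1}" for i in range(n_samples)
    ]
    matrix = JunctionCountMatrix(
        events=events,
        sample_ids=ids,
        inclusion=np.array(inc_rows, dtype=np.int64),
        skipping=np.array(skip_rows, dtype=np.int64),
        inc_form_len=np.array(inc_lens) if inc_lens else None,
        skip_form_len=np.array(skip_lens) if skip_lens else None,
    )
    return events, matrix


def write_event_table(counts: JunctionCountMatrix, path: str | Path) -> None:
    """Write a :class:`JunctionCountMatrix` in the event/count TSV dialect."""
    path = Path(path)
    columns = list(EVENT_TABLE_COLUMNS)
    has_lens = counts.inc_form_len is not None and counts.skip_form_len is not None
    if has_lens:
        columns += list(_JCEC_EXTRA_COLUMNS)
    with path.open("w", newline="") as handle:
        writer = csv.writer(handle, delimiter="\t", lineterminator="\n")
        writer.writerow(columns)
        for i, e in enumerate(counts.events):
            row = [
                e.event_id,
                e.gene_id,
                e.chrom,
                e.strand,
                e.event_type,
                e.exon_start,
                e.exon_end,
                e.upstream_exon_start,
                e.upstream_exon_end,
                e.downstream_exon_start,
                e.downstream_exon_end,
                ",".join(str(v) for v in counts.inclusion[i]),
                ",".join(str(v) for v in counts.skipping[i]),
            ]
            if has_lens:
                row += [repr(float(counts.inc_form_len[i])),
                        repr(float(counts.skip_form_len[i]))]
            writer.writerow(row)


def read_sample_metadata(path: str | Path) -> list[SampleMetadata]:
    """Read the sample-metadata TSV (sample_id, group, stage, tissue, replicate)."""
    df = pd.read_csv(path, sep="\t", dtype={"sample_id": str, "tissue": str})
    if "sample_id" not in df.columns:
        raise ValueError(f"{path}: missing sample_id column")
    if df["sample_id"].duplicated().any():
        dupes = df.loc[df["sample_id"].duplicated(), "sample_id"].tolist()
        raise ValueError(f"{path}: duplicate sample_ids {dupes}")
    out = []
    for _, row in df.iterrows():
        stage = row.get("stage")
        tissue = row.get("tissue")
        out.append(
            SampleMetadata(
                sample_id=str(row["sample_id"]),
                group=str(row.get("group", "other")),
                stage=float(stage) if pd.notna(stage) else None,
                tissue=str(tissue) if pd.notna(tissue) else None,
                replicate=int(row.get("replicate", 1)) if pd.notna(row.get("replicate", 1)) else 1,
            )
        )
    return out


def write_sample_metadata(metadata: Sequence[SampleMetadata], path: str | Path) -> None:
    df = pd.DataFrame(
        {
            "sample_id": [m.sample_id for m in metadata],
            "group": [m.group for m in metadata],
            "stage": [m.stage for m in metadata],
            "tissue": [m.tissue for m in metadata],
            "replicate": [m.replicate for m in metadata],
        }
    )
    df.to_csv(path, sep="\t", index=False)


def write_bed(events: Iterable[SpliceEvent], path: str | Path) -> None:
    """Write the target exon of each event as BED6 (0-based half-open)."""
    with Path(path).open("w") as handle:
        for e in events:
            handle.write(
                f"{e.chrom}\t{e.exon_start}\t{e.exon_end}\t{e.event_id}\t0\t{e.strand}\n"
            )


def read_fasta(path: str | Path) -> dict[str, str]:
    """Load a FASTA file into an upper-cased {name: sequence} dict."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(str(path), "fasta")}


def write_fasta(sequences: Mapping[str, str], path: str | Path) -> None:
    with Path(path).open("w") as handle:
        for name, seq in sequences.items():
            handle.write(f">{name}\n")
            for i in range(0, len(seq), 70):
                handle.write(seq[i : i + 70] + "\n")


def read_gene_models(path: str | Path):
    """Read a GTF file (1-based inclusive) into :class:`GeneModel` objects.

    Returns a dict keyed by gene_id.  Exon/CDS coordinates are converted to
    the internal 0-based half-open convention.
    """
    # imported here to avoid a module cycle with exon_annotation
    from .exon_annotation import GeneModel, Transcript

    import gffutils

    path = Path(path)
    # validate attributes up front so errors can name the offending feature
    with path.open() as handle:
        for line_no, line in enumerate(handle, start=1):
            if not line.strip() or line.startswith("#"):
                continue
            fields = line.rstrip("\n").split("\t")
            if len(fields) < 9:
                raise ValueError(f"{path} line {line_no}: malformed GTF row")
            if fields[2] in ("exon", "CDS") and 'transcript_id "' not in fields[8]:
                raise ValueError(
                    f"{path} line {line_no}: {fields[2]} feature without transcript_id"
                )

    db = gffutils.create_db(
        str(path),
        dbfn=":memory:",
        force=True,
        keep_order=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
    )

    per_transcript: dict[str, dict] = {}
    for ftype in ("exon", "CDS"):
        for feat in db.features_of_type(ftype):
            tid = feat.attributes["transcript_id"][0]
            gid = feat.attributes.get("gene_id", [tid])[0]
            rec = per_transcript.setdefault(
                tid,
                {"gene_id": gid, "chrom": feat.seqid, "strand": feat.strand,
                 "exons": [], "cds": []},
            )
            # GTF is 1-based inclusive; internal is 0-based half-open
            interval = (feat.start - 1, feat.end)
            rec["exons" if ftype == "exon" else "cds"].append(interval)

    genes: dict[str, list] = {}
    for tid, rec in per_transcript.items():
        exons = tuple(sorted(rec["exons"]))
        cds = tuple(sorted(rec["cds"]))
        for (s1, e1), (s2, e2) in zip(cds, cds[1:]):
            if s2 < e1:
                raise ValueError(
                    f"transcript {tid}: overlapping CDS intervals "
                    f"[{s1},{e1}) and [{s2},{e2})"
                )
        transcript = Transcript(
            transcript_id=tid,
            chrom=rec["chrom"],
            strand=rec["strand"],
            exons=exons,
            cds=cds,
        )
        genes.setdefault(rec["gene_id"], []).append(transcript)

    return {
        gid: GeneModel(gene_id=gid, transcripts=sorted(ts, key=lambda t: t.transcript_id))
        for gid, ts in genes.items()
    }


def write_gene_models_gtf(models, path: str | Path) -> None:
    """Write gene models back to GTF (1-based inclusive coordinates)."""
    if not isinstance(models, dict):
        models = {m.gene_id: m for m in models}
    with Path(path).open("w") as handle:
        for gid, model in models.items():
            for tr in model.transcripts:
                attrs = f'gene_id "{gid}"; transcript_id "{tr.transcript_id}";'
                for s, e in tr.exons:
                    handle.write(
                        f"{tr.chrom}\tsplicedyn\texon\t{s + 1}\t{e}\t.\t{tr.strand}\t.\t{attrs}\n"
                    )
                for s, e in tr.cds:
                    handle.write(
                        f"{tr.chrom}\tsplicedyn\tCDS\t{s + 1}\t{e}\t.\t{tr.strand}\t0\t{attrs}\n"
                    )


# ---------------------------------------------------------------------------
# summary reporting
# ---------------------------------------------------------------------------

def summarize_overlap(n_intersection: int, n_total: int) -> float:
    """Percentage ``100 * n_intersection / n_total`` as an unrounded real.

    The multiplication is performed before the division so that exactly
    representable ratios (e.g. 21700/280 = 77.5) stay exact.
    """
    if n_total <= 0:
        raise ValueError("n_total must be positive")
    if not 0 <= n_intersection <= n_total:
        raise ValueError(
            f"n_intersection must be within [0, n_total], got "
            f"{n_intersection}/{n_total}"
        )
    return 100.0 * n_intersection / n_total


def round_percentage(percentage: float, ndigits: int = 2) -> float | int:
    """Presentation rounding (half-up, as in printed percentages).

    ``ndigits=0`` returns an int.
    """
    quantum = Decimal(1).scaleb(-ndigits)
    rounded = Decimal(repr(percentage)).quantize(quantum, rounding=ROUND_HALF_UP)
    return int(rounded) if ndigits == 0 else float(rounded)


def summarize_calls(results: pd.DataFrame) -> dict[str, int]:
    """Up/down/total counts from a result table with a ``direction`` column.

    If a boolean ``call`` (or ``is_dase``/``is_devse``) column is present,
    only called rows are counted.
    """
    if "direction" not in results.columns:
        raise ValueError("result table lacks a 'direction' column")
    table = results
    for col in ("call", "is_dase", "is_devse"):
        if col in table.columns:
            table = table[table[col].astype(bool)]
            break
    n_up = int((table["direction"] == "up").sum())
    n_down = int((table["direction"] == "down").sum())
    return {"up": n_up, "down": n_down, "total": n_up + n_down}


def read_result_table(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_result_table(results: pd.DataFrame, path: str | Path) -> None:
    results.to_csv(path, sep="\t", index=False)
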