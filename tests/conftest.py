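import numpy as np
import pytest

from splicedyn.io_formats import JunctionCountMatrix, SampleMetadata, SpliceEvent


def make_event(event_id="ev1", strand="+", exon=(2000, 2150), chrom="chr1"):
    """Toy SE event with 800-nt introns on both sides of the target exon."""
    s, e = exon
    up = (s - 1000, s - 800)
    down = (e + 800, e + 1000)
    if strand == "-":
        up, down = down, up
    return SpliceEvent(
        event_id=event_id,
        gene_id=f"g_{event_id}",
        event_type="SE",
        chrom=chrom,
        strand=strand,
        exon_start=s,
        exon_end=e,
        upstream_exon_start=up[0],
        upstream_exon_end=up[1],
        downstream_exon_start=down[0],
        downstream_exon_end=down[1],
    )


@pytest.fixture
def toy_events():
    return [make_event("ev1"), make_event("ev2", exon=(5000, 5100))]


@pytest.fixture
def toy_counts(toy_events):
    return JunctionCountMatrix(
        events=toy_events,
        sample_ids=["s1", "s2", "s3"],
        inclusion=np.array([[25, 5, 0], [10, 0, 7]]),
        skipping=np.array([[75, 0, 0], [30, 20, 3]]),
    )


@pytest.fixture
def two_group_metadata():
    return [
        SampleMetadata(f"gm{i}", group="GM", replicate=i + 1) for i in range(5)
    ] + [SampleMetadata(f"dm{i}", group="DM", replicate=i + 1) for i in range(5)]


@pytest.fixture
def stage_metadata():
    return [
        SampleMetadata(f"st{s}_{r}", stage=float(s), replicate=r + 1)
        for s in range(1, 28)
        for r in range(2)
    ]


@pytest.fixture
def tissue_metadata():
    tissues = [
        "muscle", "heart", "brain", "liver", "lung",
        "stomach", "pancreas", "adipose", "intestine", "cerebellum",
    ]
    return [
        SampleMetadata(f"{t}_{r}", tissue=t, replicate=r + 1)
        for t in tissues
        for r in range(5)
    ]
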