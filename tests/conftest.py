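import pandas as pd
import pytest

from juncsplice.annotation import TranscriptModel


def _tm(tid, gene, exons, chrom="chr1", strand="+", cds=None):
    return TranscriptModel(
        transcript_id=tid, gene_id=gene, chrom=chrom, strand=strand,
        exons=tuple(exons), cds=cds,
    )


@pytest.fixture
def toy_models():
    """One canonical instance of each event type, on the + strand.

    gIR:  intron [100,200) retained in the single-exon transcript.
    gES:  cassette exon [200,250) skipped by junction (100,400).
    gA5:  introns (100,400) vs (150,400) share the acceptor end.
    gA3:  introns (100,400) vs (100,350) share the donor start.
    """
    return [
        _tm("tIR.1", "gIR", [(0, 100), (200, 300)]),
        _tm("tIR.2", "gIR", [(0, 300)]),
        _tm("tES.1", "gES", [(0, 100), (200, 250), (400, 500)]),
        _tm("tES.2", "gES", [(0, 100), (400, 500)]),
        _tm("tA5.1", "gA5", [(0, 100), (400, 500)]),
        _tm("tA5.2", "gA5", [(0, 150), (400, 500)]),
        _tm("tA3.1", "gA3", [(0, 100), (400, 500)]),
        _tm("tA3.2", "gA3", [(0, 100), (350, 500)]),
    ]


@pytest.fixture
def two_condition_design():
    """Minimal paired design: control + one stress, one timepoint, 2 reps."""
    return pd.DataFrame(
        [
            {"sample_id": f"{c}_1h_r{r}", "condition": c, "timepoint": "1h", "replicate": r}
            for c in ("CK", "HS")
            for r in (1, 2)
        ]
    )


def make_transcript(tid, gene, exons, chrom="chr1", strand="+", cds=None):
    """Module-level helper so tests can build models without the fixture."""
    return _tm(tid, gene, exons, chrom=chrom, strand=strand, cds=cds)
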