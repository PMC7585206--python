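import numpy as np
import pytest

from spliceorder.annotation import GenomicInterval, TranscriptModel, parse_annotation

GTF_TEXT = "\n".join(
    [
        # 2-exon plus-strand transcript: one intron [200, 300)
        'chr1\ttest\texon\t101\t200\t.\t+\t.\tgene_id "g1"; transcript_id "t_plus";',
        'chr1\ttest\texon\t301\t400\t.\t+\t.\tgene_id "g1"; transcript_id "t_plus";',
        # same exons on the minus strand
        'chr1\ttest\texon\t101\t200\t.\t-\t.\tgene_id "g2"; transcript_id "t_minus";',
        'chr1\ttest\texon\t301\t400\t.\t-\t.\tgene_id "g2"; transcript_id "t_minus";',
        # 3-exon minus-strand transcript: genomic introns [200,300) and [400,500)
        'chr1\ttest\texon\t101\t200\t.\t-\t.\tgene_id "g3"; transcript_id "t_minus3";',
        'chr1\ttest\texon\t301\t400\t.\t-\t.\tgene_id "g3"; transcript_id "t_minus3";',
        'chr1\ttest\texon\t501\t600\t.\t-\t.\tgene_id "g3"; transcript_id "t_minus3";',
        # single-exon record: silently dropped (but counted)
        'chr1\ttest\texon\t701\t800\t.\t+\t.\tgene_id "g4"; transcript_id "t_single";',
    ]
)


@pytest.fixture(scope="session")
def parsed_models() -> dict:
    return {m.transcript_id: m for m in parse_annotation(GTF_TEXT)}


@pytest.fixture
def four_intron_transcript() -> TranscriptModel:
    """Plus-strand transcript with 5 exons / 4 introns on a compact locus."""
    exons = [
        GenomicInterval("chr1", s, e, "+")
        for s, e in [(0, 100), (200, 300), (400, 500), (600, 700), (800, 900)]
    ]
    return TranscriptModel("t4", "g4", "+", exons)


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20240917)
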