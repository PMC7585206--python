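"""Transcript models with strand-aware intron indexing.

Intron indices count in the direction of transcription: intron 1 is the
promoter-proximal intron. On minus-strand transcripts this means the intron
with the *largest* genomic coordinate carries index 1. All coordinates are
0-based half-open internally; GTF input (1-based inclusive) is converted on
read.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import gffutils

logger = logging.getLogger(__name__)

VALID_STRANDS = ("+", "-")


@dataclass(frozen=True)
class GenomicInterval:
    """A half-open genomic interval [start, end) on one strand."""

    chrom: str
    start: int
    end: int
    strand: str = "+"

    def __post_init__(self) -> None:
        if not (0 <= self.start < self.end):
            raise ValueError(f"invalid interval [{self.start}, {self.end})")
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"strand must be one of {VALID_STRANDS}, got {self.strand!r}")

    def __len__(self) -> int:
        return self.end - self.start

    def overlaps(self, other: "GenomicInterval") -> bool:
        return self.chrom == other.chrom and self.start < other.end and other.start < self.end


@dataclass(frozen=True)
class IntronRecord:
    """One intron of a transcript.

    ``index`` is 1-based in transcription direction; ``distance_to_tss`` is
    measured from the TSS to the intron's transcription-direction 5' end.
    """

    index: int
    interval: GenomicInterval
    distance_to_tss: int
    gc_fraction: float | None = None

    @property
    def length(self) -> int:
        return len(self.interval)


@dataclass
class TranscriptModel:
    """Ordered exon/intron structure of a single isoform.

    ``exons`` are kept in genomic order; ``introns`` are sorted by
    transcription-direction index (introns[0] has index 1).
    """

    transcript_id: str
    gene_id: str
    strand: str
    exons: list[GenomicInterval]
    introns: list[IntronRecord] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.strand not in VALID_STRANDS:
            raise ValueError(f"bad strand {self.strand!r}")
        self.exons = sorted(self.exons, key=lambda e: e.start)
        for a, b in zip(self.exons, self.exons[1:]):
            if a.end > b.start:
                raise ValueError(f"{self.transcript_id}: overlapping exons {a} / {b}")
        if not self.introns:
            self.introns = self._derive_introns()

    @property
    def chrom(self) -> str:
        return self.exons[0].chrom

    @property
    def n_introns(self) -> int:
        return len(self.introns)

    @property
    def tss(self) -> int:
        """Transcription start position (5' end of the transcript)."""
        return self.exons[0].start if self.strand == "+" else self.exons[-1].end

    @property
    def span(self) -> GenomicInterval:
        return GenomicInterval(self.chrom, self.exons[0].start, self.exons[-1].end, self.strand)

    def _derive_introns(self) -> list[IntronRecord]:
        gaps = [
            GenomicInterval(self.chrom, a.end, b.start, self.strand)
            for a, b in zip(self.exons, self.exons[1:])
        ]
        if self.strand == "-":
            gaps = gaps[::-1]  # transcription runs right-to-left
        records = []
        for k, gap in enumerate(gaps, start=1):
            if self.strand == "+":
                dist = gap.start - self.tss
            else:
                dist = self.tss - gap.end
            records.append(IntronRecord(index=k, interval=gap, distance_to_tss=dist))
        return records

    def intron_by_index(self, index: int) -> IntronRecord:
        if not 1 <= index <= self.n_introns:
            raise KeyError(f"intron index {index} out of range 1..{self.n_introns}")
        return self.introns[index - 1]


def parse_annotation(source: str, fmt: str | None = None) -> list[TranscriptModel]:
    """Parse a GTF/GFF3 file (or text) into :class:`TranscriptModel` objects.

    Parameters
    ----------
    source
        Path to a GTF/GFF3 file, or the annotation text itself.
    fmt
        ``"gtf"`` or ``"gff3"``; autodetected by gffutils when omitted.

    Only ``exon`` features are used; transcripts with overlapping exons are
    excluded with a warning, never silently reordered. 1-based inclusive
    coordinates are converted to 0-based half-open.
    """
    is_path = "\n" not in source
    db = gffutils.create_db(
        source,
        dbfn=":memory:",
        from_string=not is_path,
        force=True,
        merge_strategy="create_unique",
        disable_infer_genes=True,
        disable_infer_transcripts=True,
        keep_order=True,
    )
    per_transcript: dict[str, dict] = {}
    n_bad = 0
    for feat in db.features_of_type("exon"):
        try:
            tid = feat.attributes.get("transcript_id", [None])[0]
            if tid is None:
                parents = feat.attributes.get("Parent", [])
                tid = parents[0] if parents else None
            if tid is None:
                raise ValueError("exon without transcript_id/Parent")
            gid = feat.attributes.get("gene_id", [tid])[0]
            if feat.strand not in VALID_STRANDS:
                raise ValueError(f"unstranded exon for {tid}")
            iv = GenomicInterval(feat.seqid, feat.start - 1, feat.end, feat.strand)
        except (ValueError, IndexError) as exc:
            n_bad += 1
            logger.warning("rejected annotation record: %s", exc)
            continue
        rec = per_transcript.setdefault(tid, {"gene_id": gid, "strand": feat.strand, "exons": []})
        rec["exons"].append(iv)

    models: list[TranscriptModel] = []
    n_overlap = n_single = 0
    for tid, rec in per_transcript.items():
        if len(rec["exons"]) == 1:
            n_single += 1  # single-exon records carry no introns; dropped but counted
            continue
        try:
            models.append(
                TranscriptModel(
                    transcript_id=tid,
                    gene_id=rec["gene_id"],
                    strand=rec["strand"],
                    exons=rec["exons"],
                )
            )
        except ValueError as exc:
            n_overlap += 1
            logger.warning("excluded transcript %s: %s", tid, exc)
    logger.info(
        "parsed %d multi-exon transcripts (%d single-exon dropped, %d excluded, %d bad records)",
        len(models), n_single, n_overlap, n_bad,
    )
    return models


def select_transcripts(
    models: Iterable[TranscriptModel],
    min_introns: int = 3,
    expression: Mapping[str, float] | None = None,
    tpm_threshold: float = 0.1,
) -> list[TranscriptModel]:
    """Keep transcripts with >= ``min_introns`` introns and TPM > threshold.

    A transcript missing from a supplied expression table is treated as not
    expressed (and counted in the log summary).
    """
    if tpm_threshold < 0:
        raise ValueError("tpm_threshold must be >= 0")
    kept: list[TranscriptModel] = []
    n_few = n_unexpr = n_missing = 0
    for m in models:
        if m.n_introns < min_introns:
            n_few += 1
            continue
        if expression is not None:
            tpm = expression.get(m.transcript_id)
            if tpm is None:
                n_missing += 1
                continue
            if tpm <= tpm_threshold:
                n_unexpr += 1
                continue
        kept.append(m)
    logger.info(
        "selected %d transcripts (%d below intron minimum, %d below TPM, %d absent from table)",
        len(kept), n_few, n_unexpr, n_missing,
    )
    return kept


def read_expression_table(path: str) -> dict[str, float]:
    """Read a 2-column (transcript_id, TPM) TSV, header optional."""
    table: dict[str, float] = {}
    with open(path) as fh:
        for line in fh:
            line = line.strip()
            if not line or line.startswith("#"):
                continue
            tid, val = line.split("\t")[:2]
            try:
                table[tid] = float(val)
            except ValueError:
                continue  # header row
    return table
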