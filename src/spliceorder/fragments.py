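"""Per-fragment intron splicing status and order-pair detection.

A single sequenced molecule (one long read, or two mates merged) gives
simultaneous evidence on several introns: a splice gap matching an intron
exactly says that intron is already excised (SPLICED); aligned bases running
across an exon-intron boundary say it is still present (UNSPLICED). Every
(SPLICED i, UNSPLICED j) combination within one fragment is one observation
that intron i was spliced before intron j.
"""
from __future__ import annotations

import enum
import logging
from dataclasses import dataclass, field
from typing import Iterable, Iterator

import numpy as np

from .annotation import GenomicInterval, IntronRecord, TranscriptModel
from .matrix import PairCountMatrix

logger = logging.getLogger(__name__)


class IntronStatus(enum.Enum):
    SPLICED = "spliced"
    UNSPLICED = "unspliced"
    UNKNOWN = "unknown"


@dataclass
class AlignedFragment:
    """Merged alignment evidence for one sequenced molecule.

    ``blocks`` are intervals covered by aligned bases (both mates merged for
    paired-end data); ``gaps`` are splice gaps (CIGAR N operations).
    """

    fragment_id: str
    chrom: str
    blocks: list[tuple[int, int]]
    gaps: list[tuple[int, int]] = field(default_factory=list)
    strand: str | None = None

    def __post_init__(self) -> None:
        self.blocks = sorted(self.blocks)
        self.gaps = sorted(set(self.gaps))


@dataclass(frozen=True)
class OrderPairObservation:
    """Evidence from one fragment that ``earlier_intron`` was spliced first."""

    transcript_id: str
    earlier_intron: int
    later_intron: int
    fragment_id: str

    def __post_init__(self) -> None:
        if self.earlier_intron == self.later_intron:
            raise ValueError("an intron cannot precede itself")


def _blocks_and_gaps(read) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Aligned blocks and N-gap intervals of one pysam read."""
    blocks: list[tuple[int, int]] = []
    gaps: list[tuple[int, int]] = []
    pos = read.reference_start
    cur_start = pos
    have_block = False
    for op, length in read.cigartuples or []:
        if op in (0, 7, 8):  # M, =, X consume both
            if not have_block:
                cur_start = pos
                have_block = True
            pos += length
        elif op == 2:  # D: keep within the current block (small indel)
            pos += length
        elif op == 3:  # N: splice gap
            if have_block:
                blocks.append((cur_start, pos))
                have_block = False
            gaps.append((pos, pos + length))
            pos += length
        elif op in (1, 4, 5, 6):  # I, S, H, P consume no reference
            continue
    if have_block:
        blocks.append((cur_start, pos))
    return blocks, gaps


def extract_fragments(
    alignments, region: GenomicInterval | None = None
) -> Iterator[AlignedFragment]:
    """Yield merged :class:`AlignedFragment` records from a pysam AlignmentFile.

    Mates sharing a read name are merged into one fragment; secondary and
    supplementary alignments are dropped. ``region`` restricts the scan to one
    locus (requires an index for BAM input).
    """
    if region is not None:
        reads = alignments.fetch(region.chrom, region.start, region.end)
    else:
        reads = alignments.fetch(until_eof=True)

    pending: dict[str, AlignedFragment] = {}
    n_orphans = 0
    for read in reads:
        if read.is_unmapped or read.is_secondary or read.is_supplementary:
            continue
        blocks, gaps = _blocks_and_gaps(read)
        if not blocks:
            continue
        chrom = read.reference_name
        frag = pending.get(read.query_name)
        if frag is not None and frag.chrom == chrom:
            frag.blocks = sorted(frag.blocks + blocks)
            frag.gaps = sorted(set(frag.gaps) | set(gaps))
            del pending[read.query_name]
            yield frag
        else:
            new = AlignedFragment(read.query_name, chrom, blocks, gaps)
            if read.is_paired:
                pending[read.query_name] = new
            else:
                yield new
    if pending:
        n_orphans = len(pending)
        logger.info("emitting %d fragments built from a single orphan mate", n_orphans)
        yield from pending.values()


def classify_intron_status(
    fragment: AlignedFragment, intron: IntronRecord, min_anchor: int = 6
) -> IntronStatus:
    """Classify one intron's splicing status in one fragment.

    SPLICED: some gap matches the intron's boundaries exactly (0 tolerance).
    UNSPLICED: a block covers an exon-intron boundary with >= ``min_anchor``
    aligned bases on each side, and no gap matches the intron.
    Otherwise UNKNOWN.
    """
    if min_anchor < 1:
        raise ValueError("min_anchor must be >= 1")
    iv = intron.interval
    if fragment.chrom != iv.chrom:
        return IntronStatus.UNKNOWN
    if (iv.start, iv.end) in fragment.gaps:
        return IntronStatus.SPLICED
    for bs, be in fragment.blocks:
        for boundary in (iv.start, iv.end):
            if bs + min_anchor <= boundary <= be - min_anchor:
                return IntronStatus.UNSPLICED
    return IntronStatus.UNKNOWN


def fragment_matches_transcript(fragment: AlignedFragment, transcript: TranscriptModel) -> bool:
    """True iff every splice gap in the fragment matches an annotated intron.

    Fragments with unannotated junctions are discarded for this isoform — the
    guard against alternative 5'/3' splice-site artefacts.
    """
    annotated = {(i.interval.start, i.interval.end) for i in transcript.introns}
    return all(g in annotated for g in fragment.gaps)


def detect_order_pairs(
    fragment: AlignedFragment,
    transcript: TranscriptModel,
    min_anchor: int = 6,
) -> set[OrderPairObservation]:
    """Emit (i before j) observations for one fragment against one isoform.

    Returns the empty set when the fragment carries an unannotated junction,
    or when either the SPLICED or the UNSPLICED set is empty.
    """
    if not fragment_matches_transcript(fragment, transcript):
        return set()
    spliced: list[int] = []
    unspliced: list[int] = []
    for intron in transcript.introns:
        status = classify_intron_status(fragment, intron, min_anchor)
        if status is IntronStatus.SPLICED:
            spliced.append(intron.index)
        elif status is IntronStatus.UNSPLICED:
            unspliced.append(intron.index)
    return {
        OrderPairObservation(transcript.transcript_id, i, j, fragment.fragment_id)
        for i in spliced
        for j in unspliced
    }


def classify_fragment(
    fragment: AlignedFragment, transcript: TranscriptModel, min_anchor: int = 6
) -> tuple[list[int], list[int]]:
    """(spliced indices, unspliced indices) for one matching fragment."""
    if not fragment_matches_transcript(fragment, transcript):
        return [], []
    spliced, unspliced = [], []
    for intron in transcript.introns:
        status = classify_intron_status(fragment, intron, min_anchor)
        if status is IntronStatus.SPLICED:
            spliced.append(intron.index)
        elif status is IntronStatus.UNSPLICED:
            unspliced.append(intron.index)
    return spliced, unspliced


def accumulate_counts(
    observations: Iterable[OrderPairObservation], transcript: TranscriptModel
) -> PairCountMatrix:
    """Build the pair-count matrix A[i, j] = #fragments supporting i before j.

    Each fragment contributes at most one count per ordered pair even when
    both mates independently support it.
    """
    n = transcript.n_introns
    A = np.zeros((n, n))
    seen: set[tuple[str, int, int]] = set()
    for obs in observations:
        if obs.transcript_id != transcript.transcript_id:
            raise ValueError(
                f"observation for {obs.transcript_id} passed to {transcript.transcript_id}"
            )
        key = (obs.fragment_id, obs.earlier_intron, obs.later_intron)
        if key in seen:
            continue
        seen.add(key)
        A[obs.earlier_intron - 1, obs.later_intron - 1] += 1
    return PairCountMatrix(A, transcript_id=transcript.transcript_id)


def count_pairs_for_transcript(
    fragments: Iterable[AlignedFragment],
    transcript: TranscriptModel,
    min_anchor: int = 6,
) -> tuple[PairCountMatrix, np.ndarray]:
    """Full detection for one transcript.

    Returns the ordered pair-count matrix and a symmetric matrix counting
    fragments in which *both* introns of a pair were SPLICED (the ``d`` side
    table consumed by the retained-intron correction).
    """
    n = transcript.n_introns
    A = np.zeros((n, n))
    both = np.zeros((n, n))
    for frag in fragments:
        spliced, unspliced = classify_fragment(frag, transcript, min_anchor)
        for i in spliced:
            for j in unspliced:
                A[i - 1, j - 1] += 1
        for a_idx, i in enumerate(spliced):
            for j in spliced[a_idx + 1:]:
                both[i - 1, j - 1] += 1
                both[j - 1, i - 1] += 1
    return PairCountMatrix(A, transcript_id=transcript.transcript_id), both
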