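"""Synthetic transcriptomes, splicing intermediates, and simulated reads.

The generator emulates the nascent-RNA setting in which splicing order is
observable: each transcript is assigned a uniformly random true splicing
order theta; a transcript with n introns then has n+1 pre-mRNA intermediates
(species k lacks the first k introns of theta); fragments are sampled from
every intermediate at equal abundance and emitted as already-aligned records
(blocks plus splice gaps), directly consumable by the pair detector or
written as SAM for a full file round trip. Count matrices can also be
simulated directly: Poisson reads per pair in the theta-consistent
direction, with optional random pair erasure to emulate undetected pairs.
"""
from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np

from .annotation import GenomicInterval, TranscriptModel
from .fragments import AlignedFragment
from .matrix import PairCountMatrix
from .model import SplicingOrder

BASES = np.array(list("ACGT"))


@dataclass
class SimTranscriptomeConfig:
    """Synthetic multi-intron transcriptome.

    Defaults describe a compact fission-yeast-like gene architecture:
    ~150 bp exons, 50-100 bp introns, 3-8 introns per transcript.
    """

    n_transcripts: int = 100
    intron_count_min: int = 3
    intron_count_max: int = 8
    intron_count_mean: float | None = None
    exon_length_mean: float = 150.0
    exon_length_sd: float = 30.0
    exon_length_min: int = 30
    intron_length_min: int = 50
    intron_length_max: int = 100
    intergenic_gap: int = 300
    chrom: str = "simchr"

    def __post_init__(self) -> None:
        if self.intron_count_min < 2:
            raise ValueError("simulated transcripts need >= 2 introns")
        if min(self.exon_length_min, self.intron_length_min) < 1:
            raise ValueError("lengths must be >= 1")


@dataclass
class SimReadConfig:
    """Sequencing mode: short paired-end, mate-pair, or long single reads."""

    mode: str = "long_read"  # {"short_pe", "mate_pair", "long_read"}
    read_length: int = 5000
    fragment_mean: float = 6000.0
    fragment_sd: float | None = None  # default fragment_mean / 10
    depth: float = 100.0  # expected fragments per intermediate species

    def __post_init__(self) -> None:
        if self.mode not in ("short_pe", "mate_pair", "long_read"):
            raise ValueError(f"unknown mode {self.mode!r}")
        if self.fragment_sd is None:
            self.fragment_sd = self.fragment_mean / 10.0
        if self.mode != "long_read" and self.read_length > self.fragment_mean:
            raise ValueError("read_length must not exceed fragment_mean for paired modes")
        if self.depth <= 0:
            raise ValueError("depth must be positive")

    @property
    def paired(self) -> bool:
        return self.mode in ("short_pe", "mate_pair")


@dataclass
class MatrixSimConfig:
    """Direct count-matrix simulation: Poisson reads per theta-consistent pair."""

    reps: int = 1000
    mean_reads_per_pair: float = 15.0
    mean_intron_count: float = 7.0
    intron_count_min: int = 2
    intron_count_max: int = 11
    retained_fraction: float = 1.0

    def __post_init__(self) -> None:
        if self.reps < 1 or self.mean_reads_per_pair <= 0:
            raise ValueError("reps >= 1 and mean_reads_per_pair > 0 required")


@dataclass
class SimRead:
    """One simulated aligned read (a mate or a whole long read)."""

    name: str
    chrom: str
    blocks: list[tuple[int, int]]
    gaps: list[tuple[int, int]]
    strand: str
    mate: int = 0  # 0 = single-end, 1/2 = mate number


def _rng(seed) -> np.random.Generator:
    return seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)


def generate_transcriptome(
    config: SimTranscriptomeConfig, seed
) -> tuple[dict[str, str], list[TranscriptModel]]:
    """Deterministic synthetic contig plus non-overlapping transcript models."""
    rng = _rng(seed)
    models: list[TranscriptModel] = []
    pos = config.intergenic_gap
    pieces: list[str] = []
    for t in range(config.n_transcripts):
        if config.intron_count_mean is None:
            n_introns = int(rng.integers(config.intron_count_min, config.intron_count_max + 1))
        else:
            n_introns = int(np.clip(
                rng.poisson(config.intron_count_mean),
                config.intron_count_min, config.intron_count_max,
            ))
        strand = "+" if rng.random() < 0.5 else "-"
        exon_lens = np.maximum(
            config.exon_length_min,
            np.round(rng.normal(config.exon_length_mean, config.exon_length_sd, n_introns + 1)),
        ).astype(int)
        intron_lens = rng.integers(
            config.intron_length_min, config.intron_length_max + 1, n_introns
        )
        exons = []
        p = pos
        for k, elen in enumerate(exon_lens):
            exons.append(GenomicInterval(config.chrom, p, p + int(elen), strand))
            p += int(elen)
            if k < n_introns:
                p += int(intron_lens[k])
        tid = f"SIMT{t + 1:04d}"
        models.append(TranscriptModel(tid, f"SIMG{t + 1:04d}", strand, exons))
        pos = p + config.intergenic_gap
    genome = "".join(rng.choice(BASES, size=pos + config.intergenic_gap))
    return {config.chrom: genome}, models


def assign_random_orders(
    models: Iterable[TranscriptModel], seed
) -> dict[str, SplicingOrder]:
    """Uniformly random true splicing order per transcript, seed-reproducible."""
    rng = _rng(seed)
    orders: dict[str, SplicingOrder] = {}
    for m in models:
        if m.n_introns < 2:
            continue
        perm = rng.permutation(m.n_introns) + 1
        orders[m.transcript_id] = SplicingOrder(tuple(int(x) for x in perm))
    return orders


@dataclass
class Intermediate:
    """One pre-mRNA species: retained genomic segments + already-spliced introns."""

    k: int  # number of introns already removed
    segments: list[tuple[int, int]]  # retained genomic regions, sorted
    spliced_introns: list[tuple[int, int]]  # genomic intervals of removed introns

    @property
    def length(self) -> int:
        return sum(e - s for s, e in self.segments)


def enumerate_intermediates(
    transcript: TranscriptModel, theta: SplicingOrder
) -> list[Intermediate]:
    """The n+1 pre-mRNA species implied by splicing order theta.

    Species k is the transcript with the first k introns of theta removed;
    species 0 is the unspliced pre-mRNA, species n the mature mRNA.
    """
    if theta.n != transcript.n_introns:
        raise ValueError("order length does not match transcript intron count")
    span = transcript.span
    species: list[Intermediate] = []
    for k in range(theta.n + 1):
        removed = sorted(
            (transcript.intron_by_index(i).interval.start,
             transcript.intron_by_index(i).interval.end)
            for i in theta.sequence[:k]
        )
        segments: list[tuple[int, int]] = []
        cursor = span.start
        for s, e in removed:
            if s > cursor:
                segments.append((cursor, s))
            cursor = e
        if cursor < span.end:
            segments.append((cursor, span.end))
        species.append(Intermediate(k=k, segments=segments, spliced_introns=removed))
    return species


def _map_interval(
    species: Intermediate, a: int, b: int
) -> tuple[list[tuple[int, int]], list[tuple[int, int]]]:
    """Map species-coordinate interval [a, b) to genomic blocks and splice gaps.

    Between two consecutive retained segments lies exactly one already-spliced
    intron (exons always separate introns), so every crossed segment boundary
    emits one gap.
    """
    blocks: list[tuple[int, int]] = []
    offset = 0
    for s, e in species.segments:
        seg_len = e - s
        lo, hi = max(a, offset), min(b, offset + seg_len)
        if lo < hi:
            blocks.append((s + lo - offset, s + hi - offset))
        offset += seg_len
        if offset >= b:
            break
    gaps = [
        (b1_end, b2_start)
        for (b1_start, b1_end), (b2_start, b2_end) in zip(blocks, blocks[1:])
        if (b1_end, b2_start) in set(map(tuple, species.spliced_introns))
    ]
    return blocks, gaps


def simulate_reads(
    transcript: TranscriptModel,
    theta: SplicingOrder,
    read_config: SimReadConfig,
    seed,
) -> list[SimRead]:
    """Sample aligned reads from every intermediate of one transcript.

    Fragment counts are Poisson(depth) per species, fragment starts uniform,
    lengths rounded normal clipped to the species; paired modes emit two
    terminal mates of ``read_length``, long-read mode one read anchored at
    the fragment's 5' (transcription-direction) end.
    """
    rng = _rng(seed)
    cfg = read_config
    reads: list[SimRead] = []
    for species in enumerate_intermediates(transcript, theta):
        L = species.length
        n_frag = rng.poisson(cfg.depth)
        if L < 2 or n_frag == 0:
            continue
        min_len = 2 * cfg.read_length if cfg.paired else 2
        for f in range(n_frag):
            flen = int(round(rng.normal(cfg.fragment_mean, cfg.fragment_sd)))
            flen = max(min_len, flen)
            flen = min(flen, L)
            start = int(rng.integers(0, L - flen + 1))
            end = start + flen
            name = f"{transcript.transcript_id}:s{species.k}:f{f}"
            if cfg.paired:
                r1 = (start, min(start + cfg.read_length, end))
                r2 = (max(end - cfg.read_length, start), end)
                for mate, (a, b) in enumerate((r1, r2), start=1):
                    blocks, gaps = _map_interval(species, a, b)
                    if blocks:
                        reads.append(SimRead(name, transcript.chrom, blocks, gaps,
                                             transcript.strand, mate=mate))
            else:
                # unstranded cDNA: the read enters from either fragment end
                rlen = min(cfg.read_length, flen)
                if rng.random() < 0.5:
                    a, b = start, start + rlen
                else:
                    a, b = end - rlen, end
                blocks, gaps = _map_interval(species, a, b)
                if blocks:
                    reads.append(SimRead(name, transcript.chrom, blocks, gaps,
                                         transcript.strand, mate=0))
    return reads


def reads_to_fragments(reads: Iterable[SimRead]) -> list[AlignedFragment]:
    """Merge mates sharing a name into AlignedFragment records."""
    by_name: dict[str, AlignedFragment] = {}
    out: list[AlignedFragment] = []
    for r in reads:
        frag = by_name.get(r.name)
        if frag is None:
            frag = AlignedFragment(r.name, r.chrom, list(r.blocks), list(r.gaps), r.strand)
            by_name[r.name] = frag
            out.append(frag)
        else:
            frag.blocks = sorted(frag.blocks + list(r.blocks))
            frag.gaps = sorted(set(frag.gaps) | set(r.gaps))
    return out


def simulate_fragments(
    transcript: TranscriptModel,
    theta: SplicingOrder,
    read_config: SimReadConfig,
    seed,
) -> list[AlignedFragment]:
    """Simulated, already-merged fragments for one transcript."""
    return reads_to_fragments(simulate_reads(transcript, theta, read_config, seed))


def simulate_matrix(n: int, theta: SplicingOrder, mean_reads: float, seed) -> PairCountMatrix:
    """Poisson(mean_reads) counts in the theta-consistent direction of each pair."""
    if n < 2:
        raise ValueError("need n >= 2")
    rng = _rng(seed)
    rank = theta.rank
    A = np.zeros((n, n))
    for i in range(1, n + 1):
        for j in range(i + 1, n + 1):
            draw = rng.poisson(mean_reads)
            if rank[i - 1] < rank[j - 1]:
                A[i - 1, j - 1] = draw
            else:
                A[j - 1, i - 1] = draw
    return PairCountMatrix(A)


def erase_pairs(counts: PairCountMatrix, retained_fraction: float, seed) -> PairCountMatrix:
    """Zero a random subset of unordered pairs so a fraction remains observed."""
    if not 0.0 <= retained_fraction <= 1.0:
        raise ValueError("retained_fraction must be within [0, 1]")
    rng = _rng(seed)
    n = counts.n
    pairs = [(i, j) for i in range(n) for j in range(i + 1, n)]
    n_erase = round((1.0 - retained_fraction) * len(pairs))
    out = counts.copy()
    for k in rng.choice(len(pairs), size=n_erase, replace=False):
        i, j = pairs[int(k)]
        out.A[i, j] = out.A[j, i] = 0.0
    return out


# ---------------------------------------------------------------------------
# writers

def write_fasta(genome: dict[str, str], path: str, width: int = 60) -> None:
    with open(path, "w") as fh:
        for name, seq in genome.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def write_gtf(models: Sequence[TranscriptModel], path: str) -> None:
    """Minimal GTF (1-based inclusive) with exon features."""
    with open(path, "w") as fh:
        for m in models:
            attrs = f'gene_id "{m.gene_id}"; transcript_id "{m.transcript_id}";'
            span = m.span
            fh.write("\t".join([
                m.chrom, "sim", "transcript", str(span.start + 1), str(span.end),
                ".", m.strand, ".", attrs]) + "\n")
            for e in m.exons:
                fh.write("\t".join([
                    m.chrom, "sim", "exon", str(e.start + 1), str(e.end),
                    ".", m.strand, ".", attrs]) + "\n")


def write_true_orders(orders: dict[str, SplicingOrder], path: str) -> None:
    with open(path, "w") as fh:
        fh.write("transcript_id\ttrue_order\n")
        for tid, theta in orders.items():
            fh.write(f"{tid}\t{theta}\n")


def read_true_orders(path: str) -> dict[str, SplicingOrder]:
    orders: dict[str, SplicingOrder] = {}
    with open(path) as fh:
        for line in fh:
            if line.startswith(("#", "transcript_id")) or not line.strip():
                continue
            tid, text = line.rstrip("\n").split("\t")[:2]
            orders[tid] = SplicingOrder.from_string(text)
    return orders


def _cigar(blocks, gaps) -> list[tuple[int, int]]:
    cig: list[tuple[int, int]] = []
    for (s1, e1), (s2, e2) in zip(blocks, blocks[1:]):
        cig.append((0, e1 - s1))
        cig.append((3, s2 - e1))
    s, e = blocks[-1]
    cig.append((0, e - s))
    return cig


def write_sam(
    reads: Sequence[SimRead], chrom_lengths: dict[str, int], path: str
) -> None:
    """Write simulated reads as a SAM file (mates share a name, flagged 1/2)."""
    import pysam

    header = {
        "HD": {"VN": "1.6", "SO": "coordinate"},
        "SQ": [{"SN": c, "LN": ln} for c, ln in chrom_lengths.items()],
    }
    ordered = sorted(reads, key=lambda r: (r.chrom, r.blocks[0][0]))
    with pysam.AlignmentFile(path, "w", header=header) as out:
        for r in ordered:
            a = pysam.AlignedSegment(out.header)
            a.query_name = r.name
            a.reference_name = r.chrom
            a.reference_start = r.blocks[0][0]
            a.mapping_quality = 60
            a.cigartuples = _cigar(r.blocks, r.gaps)
            flag = 0
            if r.mate:
                flag |= 0x1 | 0x2  # paired, proper pair
                flag |= 0x40 if r.mate == 1 else 0x80
            if r.strand == "-":
                flag |= 0x10
            a.flag = flag
            qlen = sum(e - s for s, e in r.blocks)
            a.query_sequence = "A" * qlen
            a.query_qualities = pysam.qualitystring_to_array("I" * qlen)
            out.write(a)


def write_fastq(
    reads: Sequence[SimRead], genome: dict[str, str], path: str
) -> None:
    """Optional FASTQ export for users who want to run a real aligner."""
    with open(path, "w") as fh:
        for r in reads:
            seq = "".join(genome[r.chrom][s:e] for s, e in r.blocks)
            fh.write(f"@{r.name}/{r.mate or 1}\n{seq}\n+\n{'I' * len(seq)}\n")
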