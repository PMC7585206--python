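"""Glue between alignments, pair detection, and order inference.

Fragments are assigned to transcripts by genomic overlap; the per-isoform
unannotated-junction guard in the detector then drops fragments that do not
fit the isoform under consideration.
"""
from __future__ import annotations

import bisect
import logging
from dataclasses import dataclass, field
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd

from .annotation import TranscriptModel
from .fragments import AlignedFragment, count_pairs_for_transcript
from .matrix import PairCountMatrix, retention_percentage
from .model import EXHAUSTIVE_MAX_N, ILP_MAX_N, SplicingOrderModel, SplicingOrderResults

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """Thresholds of one pipeline run (all tunable from the CLI)."""

    min_introns: int = 3
    min_anchor: int = 6
    adjust_value: float = 0.1
    min_retention: float = 0.95
    tpm_threshold: float = 0.1
    ilp_threshold: int = EXHAUSTIVE_MAX_N
    max_n: int = ILP_MAX_N
    seed: int = 0

    def __post_init__(self) -> None:
        if self.adjust_value <= 0:
            raise ValueError("adjust_value must be > 0")
        if not 0.0 <= self.min_retention <= 1.0:
            raise ValueError("min_retention must be within [0, 1]")
        if self.ilp_threshold > self.max_n:
            raise ValueError("ilp_threshold must not exceed max_n")

    def header_lines(self) -> list[str]:
        items = ", ".join(f"{k}={v}" for k, v in vars(self).items())
        return [f"# run_config: {items}"]


def assign_fragments(
    fragments: Iterable[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
) -> dict[str, list[AlignedFragment]]:
    """Group fragments by overlapping transcript span (per chromosome)."""
    by_chrom: dict[str, list[TranscriptModel]] = {}
    for t in transcripts:
        by_chrom.setdefault(t.chrom, []).append(t)
    starts: dict[str, list[int]] = {}
    for chrom, ts in by_chrom.items():
        ts.sort(key=lambda t: t.span.start)
        starts[chrom] = [t.span.start for t in ts]
    out: dict[str, list[AlignedFragment]] = {t.transcript_id: [] for t in transcripts}
    for frag in fragments:
        ts = by_chrom.get(frag.chrom)
        if not ts:
            continue
        lo, hi = frag.blocks[0][0], frag.blocks[-1][1]
        k = bisect.bisect_right(starts[frag.chrom], hi)
        for t in ts[max(0, k - 50):k]:  # windows are small; transcripts don't nest deeply
            if t.span.end > lo and t.span.start < hi:
                out[t.transcript_id].append(frag)
    return out


def detect_all_pairs(
    fragments: Iterable[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
    min_anchor: int = 6,
) -> dict[str, tuple[PairCountMatrix, np.ndarray]]:
    """Pair-count matrix + both-spliced side matrix per transcript."""
    assigned = assign_fragments(fragments, transcripts)
    out = {}
    for t in transcripts:
        out[t.transcript_id] = count_pairs_for_transcript(
            assigned[t.transcript_id], t, min_anchor=min_anchor
        )
    return out


def infer_orders(
    counts_by_tid: Mapping[str, PairCountMatrix],
    config: RunConfig | None = None,
) -> tuple[dict[str, SplicingOrderResults], dict[str, str]]:
    """Fit the most-likely order per transcript, applying the retention filter.

    Returns (results, exclusions) where exclusions maps a skipped transcript
    to the reason it was skipped.
    """
    config = config or RunConfig()
    results: dict[str, SplicingOrderResults] = {}
    excluded: dict[str, str] = {}
    for tid, counts in counts_by_tid.items():
        n = counts.n
        if n < 2:
            excluded[tid] = "fewer than 2 introns"
            continue
        if n >= config.max_n:
            excluded[tid] = "too many introns"
            continue
        retention = retention_percentage(counts)
        if retention < config.min_retention:
            excluded[tid] = f"retention {retention:.3f} below {config.min_retention}"
            continue
        model = SplicingOrderModel(counts, adjust_value=config.adjust_value, transcript_id=tid)
        results[tid] = model.fit(ilp_threshold=config.ilp_threshold, max_n=config.max_n)
    if excluded:
        logger.info("excluded %d transcripts (%s...)",
                    len(excluded), list(excluded.items())[:3])
    return results, excluded


def infer_orders_from_fragments(
    fragments: Iterable[AlignedFragment],
    transcripts: Sequence[TranscriptModel],
    config: RunConfig | None = None,
) -> dict[str, SplicingOrderResults]:
    """detect -> count -> filter -> fit, returning only fitted transcripts."""
    config = config or RunConfig()
    detected = detect_all_pairs(fragments, transcripts, min_anchor=config.min_anchor)
    counts = {tid: cm for tid, (cm, _) in detected.items()}
    results, _ = infer_orders(counts, config)
    return results


def results_to_frame(
    results: Mapping[str, SplicingOrderResults],
    counts_by_tid: Mapping[str, PairCountMatrix] | None = None,
    with_entropy: bool = True,
) -> pd.DataFrame:
    """The orders table: one row per fitted transcript."""
    rows = []
    for tid, res in results.items():
        retention = (
            retention_percentage(counts_by_tid[tid])
            if counts_by_tid is not None and tid in counts_by_tid
            else res.retention
        )
        ent = res.normalized_entropy if (with_entropy and res.n < EXHAUSTIVE_MAX_N) else None
        rows.append(
            {
                "transcript_id": tid,
                "n_introns": res.n,
                "most_likely_order": str(res.theta_star),
                "log_likelihood": res.llf,
                "relative_log_likelihood": res.relative_log_likelihood,
                "unique": res.unique,
                "normalized_entropy": ent if ent is not None else float("nan"),
                "retention_percentage": retention if retention is not None else float("nan"),
                "method": res.method,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "transcript_id", "n_introns", "most_likely_order", "log_likelihood",
            "relative_log_likelihood", "unique", "normalized_entropy",
            "retention_percentage", "method",
        ],
    )


def pairs_to_frame(
    counts_by_tid: Mapping[str, PairCountMatrix]
) -> pd.DataFrame:
    """Long-format pairs table: transcript_id, earlier_intron, later_intron, read_count."""
    rows = []
    for tid, cm in counts_by_tid.items():
        n = cm.n
        for i in range(1, n + 1):
            for j in range(1, n + 1):
                if i != j and cm[i, j] > 0:
                    rows.append((tid, i, j, cm[i, j]))
    return pd.DataFrame(
        rows, columns=["transcript_id", "earlier_intron", "later_intron", "read_count"]
    )


def frame_to_counts(df: pd.DataFrame, n_by_tid: Mapping[str, int] | None = None
                    ) -> dict[str, PairCountMatrix]:
    """Inverse of :func:`pairs_to_frame`."""
    out: dict[str, PairCountMatrix] = {}
    for tid, sub in df.groupby("transcript_id"):
        n = (n_by_tid or {}).get(tid) or int(
            max(sub["earlier_intron"].max(), sub["later_intron"].max())
        )
        A = np.zeros((n, n))
        for row in sub.itertuples(index=False):
            A[int(row.earlier_intron) - 1, int(row.later_intron) - 1] = row.read_count
        out[str(tid)] = PairCountMatrix(A, transcript_id=str(tid))
    return out
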