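"""Downstream statistics on inferred splicing orders.

Recovery against a known truth (simulation), agreement with the direction of
transcription, relative first/last intron positions, split-half stability,
and correlation of splicing rank with per-intron features.
"""
from __future__ import annotations

import logging
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .model import SplicingOrder, SplicingOrderResults

logger = logging.getLogger(__name__)


def spearman_orders(a: SplicingOrder, b: SplicingOrder) -> float:
    """Spearman rho between the splicing ranks of two orders of the same introns."""
    if a.n != b.n:
        raise ValueError("orders must cover the same introns")
    return float(stats.spearmanr(a.rank, b.rank).statistic)


def spearman_vs_transcription(theta: SplicingOrder) -> float:
    """Spearman rho between splicing rank and intron (transcription) index.

    1 means perfectly in-order splicing, -1 perfectly reversed. Equals
    1 - 6*sum(d^2)/(n(n^2-1)) with d_i = rank(i) - i, since permutation
    ranks are tie-free.
    """
    return spearman_orders(theta, SplicingOrder.identity(theta.n))


def recovery_rate(
    true_orders: Mapping[str, SplicingOrder],
    inferred: Mapping[str, SplicingOrderResults],
) -> float:
    """Fraction of transcripts whose inferred order equals the truth exactly.

    A non-unique optimum counts as a failure even when the reported order
    happens to match.
    """
    if set(true_orders) != set(inferred):
        raise ValueError("true and inferred transcript sets differ")
    if not true_orders:
        raise ValueError("empty transcript set")
    hits = sum(
        1
        for tid, truth in true_orders.items()
        if inferred[tid].unique and inferred[tid].theta_star.sequence == truth.sequence
    )
    return hits / len(true_orders)


def relative_position(intron_rank: int, n: int) -> float:
    """Relative splicing order (rank-1)/(n-1) in [0, 1]; 0 = spliced first."""
    if n < 2:
        raise ValueError("relative position undefined for n < 2")
    if not 1 <= intron_rank <= n:
        raise ValueError(f"rank {intron_rank} out of range 1..{n}")
    return (intron_rank - 1) / (n - 1)


@dataclass
class ComparisonRow:
    transcript_id: str
    rho: float
    n: int


def compare_orders(
    true_orders: Mapping[str, SplicingOrder],
    inferred: Mapping[str, SplicingOrderResults],
) -> pd.DataFrame:
    """Per-transcript Spearman rho between inferred and true orders."""
    rows = []
    for tid in sorted(set(true_orders) & set(inferred)):
        rows.append(
            {
                "transcript_id": tid,
                "rho": spearman_orders(inferred[tid].theta_star, true_orders[tid]),
                "n_introns": true_orders[tid].n,
                "unique": inferred[tid].unique,
            }
        )
    return pd.DataFrame(rows, columns=["transcript_id", "rho", "n_introns", "unique"])


def split_half_stability(
    fragments: Sequence,
    transcripts: Sequence,
    seed,
    repeats: int = 5,
    **pipeline_kwargs,
) -> pd.DataFrame:
    """Bisect fragments at random, re-infer orders in each half, correlate.

    Repeated ``repeats`` times with derived seeds; transcripts failing the
    retention/uniqueness filters in either half are excluded (and counted in
    the log).
    """
    from .pipeline import infer_orders_from_fragments

    rng = np.random.default_rng(seed)
    rows = []
    n_excluded = 0
    for rep in range(repeats):
        mask = rng.random(len(fragments)) < 0.5
        halves = (
            [f for f, m in zip(fragments, mask) if m],
            [f for f, m in zip(fragments, mask) if not m],
        )
        results = [
            infer_orders_from_fragments(h, transcripts, **pipeline_kwargs) for h in halves
        ]
        shared = set(results[0]) & set(results[1])
        for tid in sorted(shared):
            a, b = results[0][tid], results[1][tid]
            if not (a.unique and b.unique):
                n_excluded += 1
                continue
            rows.append(
                {
                    "repeat": rep,
                    "transcript_id": tid,
                    "rho": spearman_orders(a.theta_star, b.theta_star),
                    "n_introns": a.n,
                }
            )
        n_excluded += len(set(results[0]) ^ set(results[1]))
    logger.info("split-half: %d transcript/repeat combinations excluded by filters", n_excluded)
    return pd.DataFrame(rows, columns=["repeat", "transcript_id", "rho", "n_introns"])


def feature_correlation(
    inferred: Mapping[str, SplicingOrderResults],
    features: pd.DataFrame,
) -> tuple[pd.DataFrame, pd.Series]:
    """Spearman rho between splicing rank and each per-intron feature.

    ``features`` has columns transcript_id, intron_index plus one column per
    feature. Returns (per-transcript table, pooled rho per feature). Missing
    values are handled pairwise-complete; constant features yield NaN.
    """
    feature_cols = [c for c in features.columns if c not in ("transcript_id", "intron_index")]
    per_rows = []
    pooled: dict[str, list[tuple[float, float]]] = {c: [] for c in feature_cols}
    n_missing = 0
    for tid, res in inferred.items():
        sub = features[features["transcript_id"] == tid]
        if sub.empty:
            continue
        rank = res.theta_star.rank
        for col in feature_cols:
            pairs = []
            for row in sub.itertuples(index=False):
                idx = int(row.intron_index)
                val = getattr(row, col)
                if not 1 <= idx <= res.n or pd.isna(val):
                    n_missing += 1
                    continue
                pairs.append((rank[idx - 1], float(val)))
            pooled[col].extend(pairs)
            if len(pairs) >= 3:
                x, y = zip(*pairs)
                rho = stats.spearmanr(x, y).statistic if np.std(y) > 0 else np.nan
            else:
                rho = np.nan
            per_rows.append({"transcript_id": tid, "feature": col, "rho": rho})
    if n_missing:
        logger.info("feature correlation: %d missing feature values skipped", n_missing)
    pooled_rho = {}
    for col, pairs in pooled.items():
        if len(pairs) >= 3:
            x, y = zip(*pairs)
            pooled_rho[col] = stats.spearmanr(x, y).statistic if np.std(y) > 0 else np.nan
        else:
            pooled_rho[col] = np.nan
    return pd.DataFrame(per_rows, columns=["transcript_id", "feature", "rho"]), pd.Series(pooled_rho)
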