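"""Pair-count and frequency matrices, retention, retained-intron correction.

The frequency matrix D turns directional read counts into per-pair splicing
probabilities: D[i, j] estimates P(intron i spliced before intron j). With a
pseudo count a on each side,

    D[i, j] = (A[i, j] + a) / (A[i, j] + A[j, i] + 2a),

the MAP estimate of a binomial proportion under a Beta(1 + a, 1 + a) prior,
so a = 0.1 corresponds to Beta(1.1, 1.1).
"""
from __future__ import annotations

from dataclasses import dataclass

import numpy as np

DEFAULT_ADJUST = 0.1


@dataclass
class PairCountMatrix:
    """n x n ordered pair counts; A[i-1, j-1] supports intron i before j."""

    A: np.ndarray
    transcript_id: str = ""

    def __post_init__(self) -> None:
        self.A = np.asarray(self.A, dtype=float)
        if self.A.ndim != 2 or self.A.shape[0] != self.A.shape[1]:
            raise ValueError("A must be square")
        if (self.A < 0).any():
            raise ValueError("counts must be non-negative")
        if np.diag(self.A).any():
            raise ValueError("diagonal must be zero")

    @property
    def n(self) -> int:
        return self.A.shape[0]

    def __getitem__(self, key: tuple[int, int]) -> float:
        """1-based intron-index access: counts[4, 1]."""
        i, j = key
        return float(self.A[i - 1, j - 1])

    def increment(self, earlier: int, later: int, by: float = 1.0) -> None:
        self.A[earlier - 1, later - 1] += by

    def copy(self) -> "PairCountMatrix":
        return PairCountMatrix(self.A.copy(), self.transcript_id)


@dataclass
class FrequencyMatrix:
    """Pseudo-count-adjusted pair probabilities; off-diagonal rows/cols sum to 1."""

    D: np.ndarray
    adjust_value: float = DEFAULT_ADJUST
    transcript_id: str = ""

    def __post_init__(self) -> None:
        self.D = np.asarray(self.D, dtype=float)
        if self.D.ndim != 2 or self.D.shape[0] != self.D.shape[1]:
            raise ValueError("D must be square")

    @property
    def n(self) -> int:
        return self.D.shape[0]

    def __getitem__(self, key: tuple[int, int]) -> float:
        i, j = key
        return float(self.D[i - 1, j - 1])


@dataclass(frozen=True)
class RetainedIntronEvent:
    """An annotated retained intron with its percent-spliced-in value."""

    transcript_id: str
    intron_index: int
    psi: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.psi <= 1.0:
            raise ValueError(f"PSI must be within [0, 1], got {self.psi}")


def frequency_matrix(
    counts: PairCountMatrix, adjust_value: float = DEFAULT_ADJUST
) -> FrequencyMatrix:
    """Build D from A with symmetric pseudo counts; diagonal stays 0.

    With ``adjust_value`` 0 a pair with no reads in either direction keeps
    D[i, j] = D[j, i] = 0, the no-evidence marker consumed by the likelihood.
    """
    if adjust_value < 0:
        raise ValueError("adjust_value must be >= 0")
    A = counts.A
    n = counts.n
    tot = A + A.T + 2.0 * adjust_value
    with np.errstate(invalid="ignore", divide="ignore"):
        D = np.where(tot > 0, (A + adjust_value) / np.where(tot > 0, tot, 1.0), 0.0)
    np.fill_diagonal(D, 0.0)
    return FrequencyMatrix(D, adjust_value=adjust_value, transcript_id=counts.transcript_id)


def retention_percentage(counts: PairCountMatrix) -> float:
    """Fraction of the n(n-1)/2 unordered intron pairs with any read support."""
    n = counts.n
    if n < 2:
        raise ValueError("retention needs at least 2 introns")
    sym = counts.A + counts.A.T
    observed = int(np.count_nonzero(np.triu(sym, k=1)))
    return observed / (n * (n - 1) / 2)


def correct_retained_intron(
    counts: PairCountMatrix,
    event: RetainedIntronEvent,
    other_intron: int,
    both_spliced: float = 0.0,
) -> PairCountMatrix:
    """Subtract mature-isoform reads that mimic late splicing of a retained intron.

    Reads from the fully spliced isoform that still retains the intron inflate
    the count supporting "retained intron spliced after the other intron",
    i.e. A[other, RI]. With b = A[other, RI], c = A[RI, other] and d the
    number of fragments where both introns are spliced, that entry becomes

        max(b - PSI * (b + c + d), 0).

    All other entries are unchanged; a new matrix is returned.
    """
    ri = event.intron_index
    if ri == other_intron:
        raise ValueError("retained intron and other intron must differ")
    b = counts[other_intron, ri]
    c = counts[ri, other_intron]
    d = float(both_spliced)
    corrected = counts.copy()
    corrected.A[other_intron - 1, ri - 1] = max(b - event.psi * (b + c + d), 0.0)
    return corrected


def apply_retained_intron_corrections(
    counts: PairCountMatrix,
    events: list[RetainedIntronEvent],
    both_spliced: np.ndarray | None = None,
) -> PairCountMatrix:
    """Apply the correction against every other intron, for every event.

    b, c and d are always read from the *uncorrected* matrix, so corrections
    for different events never compound.
    """
    out = counts.copy()
    for event in events:
        if event.transcript_id and counts.transcript_id and event.transcript_id != counts.transcript_id:
            continue
        ri = event.intron_index
        for other in range(1, counts.n + 1):
            if other == ri:
                continue
            d = float(both_spliced[other - 1, ri - 1]) if both_spliced is not None else 0.0
            fixed = correct_retained_intron(counts, event, other, both_spliced=d)
            out.A[other - 1, ri - 1] = fixed.A[other - 1, ri - 1]
    return out
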