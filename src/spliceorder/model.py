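"""Most-likely intron splicing order inference.

Given the frequency matrix D of a transcript with n introns, the likelihood
of a splicing order theta = (O_1, ..., O_n) is the product of D[i, j] over
the n(n-1)/2 ordered pairs (i spliced before j) that theta implies:

    L(theta | D) = prod_{rank(i) < rank(j)} D[i, j]

(pairs with no reads and no pseudo counts contribute a factor of 1).
Maximising this over all permutations is a linear ordering (Kemeny-type)
problem. For n < 12 the optimum over all n! orders is found exactly with a
dynamic program over intron subsets; for 12 <= n < 100 a binary integer
linear program with triangle (transitivity) constraints is solved with an
exact branch-and-cut backend (HiGHS via scipy).

The most unlikely order is the reverse of the most likely one; the in-order
relative log-likelihood R = ln L(identity)/L(theta*) <= 0 measures agreement
with the direction of transcription, and the normalised Shannon entropy of
the likelihood-weighted distribution over all n! orders (n < 12) measures
splicing-order heterogeneity.
"""
from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
from scipy.optimize import Bounds, LinearConstraint, milp
from scipy.special import logsumexp

from .matrix import DEFAULT_ADJUST, FrequencyMatrix, PairCountMatrix, frequency_matrix, retention_percentage

TIE_TOL = 1e-9
EXHAUSTIVE_MAX_N = 12  # exclusive bound: exhaustive/entropy apply to n < 12
ILP_MAX_N = 100

__all__ = [
    "SplicingOrder",
    "SplicingOrderModel",
    "SplicingOrderResults",
    "log_likelihood",
    "exhaustive_most_likely",
    "ilp_most_likely",
    "most_unlikely_order",
    "relative_log_likelihood",
    "normalized_entropy",
]


@dataclass(frozen=True)
class SplicingOrder:
    """A splicing order: ``sequence[0]`` is the intron spliced first."""

    sequence: tuple[int, ...]

    def __post_init__(self) -> None:
        n = len(self.sequence)
        if sorted(self.sequence) != list(range(1, n + 1)):
            raise ValueError(f"{self.sequence} is not a permutation of 1..{n}")

    @property
    def n(self) -> int:
        return len(self.sequence)

    @property
    def rank(self) -> tuple[int, ...]:
        """rank[i-1] = splicing position (1-based) of intron i."""
        r = [0] * self.n
        for pos, intron in enumerate(self.sequence, start=1):
            r[intron - 1] = pos
        return tuple(r)

    def reverse(self) -> "SplicingOrder":
        return SplicingOrder(self.sequence[::-1])

    @classmethod
    def identity(cls, n: int) -> "SplicingOrder":
        return cls(tuple(range(1, n + 1)))

    def __str__(self) -> str:
        return "->".join(str(i) for i in self.sequence)

    @classmethod
    def from_string(cls, text: str) -> "SplicingOrder":
        return cls(tuple(int(t) for t in text.split("->")))


def _as_order(theta: "SplicingOrder | Sequence[int]") -> SplicingOrder:
    return theta if isinstance(theta, SplicingOrder) else SplicingOrder(tuple(theta))


def _log_contrib(D: np.ndarray) -> np.ndarray:
    """log D with the no-evidence convention: pairs with D_ij + D_ji = 0 add 0."""
    with np.errstate(divide="ignore"):
        C = np.log(D)
    no_evidence = (D + D.T) == 0
    C[no_evidence] = 0.0
    np.fill_diagonal(C, 0.0)
    return C


def _freq_array(D: "FrequencyMatrix | np.ndarray") -> np.ndarray:
    return D.D if isinstance(D, FrequencyMatrix) else np.asarray(D, dtype=float)


def log_likelihood(D: "FrequencyMatrix | np.ndarray", theta) -> float:
    """ln L(theta | D): sum of ln D[i, j] over pairs ordered i-before-j by theta."""
    Dm = _freq_array(D)
    order = _as_order(theta)
    if order.n != Dm.shape[0]:
        raise ValueError("order length does not match matrix size")
    C = _log_contrib(Dm)
    seq = np.asarray(order.sequence) - 1
    total = 0.0
    for a in range(order.n):
        total += C[seq[a], seq[a + 1:]].sum()
    return float(total)


def _subset_dp(C: np.ndarray):
    """Exact optimum of the linear ordering objective over all n! orders.

    h[R] is the best achievable sum of pairwise terms when the introns in
    bitmask R are the ones not yet placed; placing intron k first among R
    contributes sum_{j in R, j != k} C[k, j]. Equivalent to enumerating all
    permutations, in O(2^n n^2).

    Returns (best value, number of optimal orders within TIE_TOL,
    lexicographically smallest optimal order as 0-based array).
    """
    n = C.shape[0]
    full = (1 << n) - 1
    h = np.full(1 << n, -np.inf)
    cnt = np.zeros(1 << n, dtype=np.int64)
    h[0] = 0.0
    cnt[0] = 1
    members_cache = [np.flatnonzero([(R >> k) & 1 for k in range(n)]) for R in range(1 << n)]
    for R in range(1, full + 1):
        sub = members_cache[R]
        gains = C[np.ix_(sub, sub)].sum(axis=1)  # diag of C is 0
        vals = gains + h[R ^ (1 << sub)]
        best = vals.max()
        h[R] = best
        cnt[R] = cnt[R ^ (1 << sub)][vals >= best - TIE_TOL].sum()
    # lexicographically smallest optimal order, chosen greedily front-to-back
    order = []
    R = full
    while R:
        sub = members_cache[R]
        gains = C[np.ix_(sub, sub)].sum(axis=1)
        vals = gains + h[R ^ (1 << sub)]
        best = vals.max()
        k = int(sub[np.flatnonzero(vals >= best - TIE_TOL)[0]])
        order.append(k)
        R ^= 1 << k
    return float(h[full]), int(cnt[full]), np.asarray(order)


def exhaustive_most_likely(
    D: "FrequencyMatrix | np.ndarray", adjust_value: float | None = None
) -> "SplicingOrderResults":
    """Maximum-likelihood order by exact search over all n! permutations (n < 12).

    Ties are counted, not broken silently: ``unique`` is False when more than
    one order attains the maximum, and the reported order is the
    lexicographically smallest optimum.
    """
    Dm = _freq_array(D)
    n = Dm.shape[0]
    if not 2 <= n < EXHAUSTIVE_MAX_N:
        raise ValueError(f"exhaustive search requires 2 <= n < {EXHAUSTIVE_MAX_N}, got n={n}")
    C = _log_contrib(Dm)
    best, n_optima, order0 = _subset_dp(C)
    theta = SplicingOrder(tuple(int(k) + 1 for k in order0))
    return SplicingOrderResults(
        theta_star=theta,
        llf=best,
        unique=n_optima == 1,
        n_optima=n_optima,
        method="exhaustive",
        D=Dm,
    )


def _ilp_solve(C: np.ndarray, forbid: np.ndarray | None = None):
    """One MILP solve of the linear ordering problem on log-contribution matrix C.

    Binary y[p, q] (p < q) means p is spliced before q; triangle constraints
    y_pq + y_qr - y_pr in [0, 1] for p < q < r enforce a total order. With
    ``forbid`` (a previous 0/1 solution) a no-good cut excludes exactly that
    solution, for the uniqueness check.
    """
    n = C.shape[0]
    pairs = [(p, q) for p in range(n) for q in range(p + 1, n)]
    idx = {pq: k for k, pq in enumerate(pairs)}
    m = len(pairs)
    # maximise sum y*C[p,q] + (1-y)*C[q,p]  ==  const + sum y*(C[p,q]-C[q,p])
    gain = np.array([C[p, q] - C[q, p] for p, q in pairs])
    const = sum(C[q, p] for p, q in pairs)
    rows, cols, data, lo, hi = [], [], [], [], []
    r = 0
    for p in range(n):
        for q in range(p + 1, n):
            for s in range(q + 1, n):
                for col, coef in ((idx[(p, q)], 1), (idx[(q, s)], 1), (idx[(p, s)], -1)):
                    rows.append(r)
                    cols.append(col)
                    data.append(coef)
                lo.append(0.0)
                hi.append(1.0)
                r += 1
    constraints = []
    if r:
        from scipy.sparse import csr_matrix

        Amat = csr_matrix((data, (rows, cols)), shape=(r, m))
        constraints.append(LinearConstraint(Amat, lo, hi))
    if forbid is not None:
        # sum_{y*=0} y - sum_{y*=1} y >= 1 - #ones excludes the previous solution
        coef = np.where(forbid > 0.5, -1.0, 1.0)
        constraints.append(LinearConstraint(coef, 1.0 - forbid.sum(), np.inf))
    res = milp(
        c=-gain,
        constraints=constraints,
        integrality=np.ones(m),
        bounds=Bounds(0, 1),
    )
    if res.status != 0 or res.x is None:
        return None, const, pairs
    return res, const, pairs


def ilp_most_likely(
    D: "FrequencyMatrix | np.ndarray", check_unique: bool = True
) -> "SplicingOrderResults":
    """Maximum-likelihood order via integer linear programming (2 <= n < 100)."""
    Dm = _freq_array(D)
    n = Dm.shape[0]
    if not 2 <= n < ILP_MAX_N:
        raise ValueError(f"ILP search requires 2 <= n < {ILP_MAX_N}, got n={n}")
    C = _log_contrib(Dm)
    # -inf only occurs with adjust_value 0 and one-sided evidence; keep finite
    C = np.where(np.isneginf(C), -1e12, C)
    res, const, pairs = _ilp_solve(C)
    if res is None:
        raise RuntimeError("ILP solver failed on a feasible linear ordering instance")
    y = np.round(res.x)
    wins = np.zeros(n)
    for k, (p, q) in enumerate(pairs):
        if y[k] > 0.5:
            wins[p] += 1
        else:
            wins[q] += 1
    order0 = np.argsort(-wins, kind="stable")
    theta = SplicingOrder(tuple(int(k) + 1 for k in order0))
    llf = log_likelihood(Dm, theta)
    unique = True
    if check_unique:
        z1 = -res.fun + const
        res2, _, _ = _ilp_solve(C, forbid=y)
        if res2 is not None:
            z2 = -res2.fun + const
            unique = z2 < z1 - 1e-6
    return SplicingOrderResults(
        theta_star=theta,
        llf=llf,
        unique=unique,
        n_optima=1 if unique else 2,
        method="ilp",
        D=Dm,
    )


def most_unlikely_order(theta_star) -> SplicingOrder:
    """The minimum-likelihood order: the reverse of the most likely one."""
    return _as_order(theta_star).reverse()


def relative_log_likelihood(D: "FrequencyMatrix | np.ndarray", theta_star) -> float:
    """R = ln L(in-order | D) - ln L(theta* | D); 0 iff splicing follows transcription."""
    Dm = _freq_array(D)
    n = Dm.shape[0]
    return log_likelihood(Dm, SplicingOrder.identity(n)) - log_likelihood(Dm, theta_star)


def _all_permutation_logliks(C: np.ndarray, chunk: int = 200_000):
    """Yield ln-likelihood arrays over all n! permutations, in chunks."""
    n = C.shape[0]
    perms = itertools.permutations(range(n))
    while True:
        block = list(itertools.islice(perms, chunk))
        if not block:
            return
        P = np.asarray(block)
        ll = np.zeros(len(block))
        for a in range(n):
            for b in range(a + 1, n):
                ll += C[P[:, a], P[:, b]]
        yield ll


def normalized_entropy(D: "FrequencyMatrix | np.ndarray") -> float:
    """Shannon entropy (bits) of p(theta | D) over all n! orders, over log2(n!).

    1 means all orders are equally likely (maximal splicing-order
    heterogeneity); 0 means a single dominant order. Defined for n < 12 only.
    """
    Dm = _freq_array(D)
    n = Dm.shape[0]
    if not 2 <= n < EXHAUSTIVE_MAX_N:
        raise ValueError(f"entropy requires 2 <= n < {EXHAUSTIVE_MAX_N}, got n={n}")
    C = _log_contrib(Dm)
    blocks = list(_all_permutation_logliks(C))
    log_z = logsumexp(np.concatenate([np.array([logsumexp(b)]) for b in blocks]))
    acc = 0.0  # sum p * ln p
    for b in blocks:
        logp = b - log_z
        acc += float(np.sum(np.exp(logp) * logp))
    entropy_bits = -acc / math.log(2.0)
    # mathematically within [0, 1]; clamp float accumulation error
    return float(np.clip(entropy_bits / math.log2(math.factorial(n)), 0.0, 1.0))


class SplicingOrderModel:
    """Most-likely splicing-order model for one multi-intron transcript.

    Parameters
    ----------
    counts
        Pair-count matrix A (``PairCountMatrix`` or square array), with
        A[i-1, j-1] the number of fragments supporting intron i spliced
        before intron j.
    adjust_value
        Symmetric pseudo count added to both directions of every pair
        (default 0.1, the Beta(1.1, 1.1) MAP).

    Examples
    --------
    >>> import numpy as np
    >>> A = np.zeros((3, 3)); A[2, 0] = 8; A[2, 1] = 7; A[0, 1] = 9
    >>> res = SplicingOrderModel(A).fit()
    >>> str(res.theta_star)
    '3->1->2'
    """

    def __init__(
        self,
        counts,
        adjust_value: float = DEFAULT_ADJUST,
        transcript_id: str = "",
    ) -> None:
        if not isinstance(counts, PairCountMatrix):
            counts = PairCountMatrix(np.asarray(counts, dtype=float), transcript_id)
        self.counts = counts
        self.transcript_id = transcript_id or counts.transcript_id
        self.adjust_value = adjust_value
        self.freq = frequency_matrix(counts, adjust_value)

    @classmethod
    def from_observations(cls, observations, transcript, adjust_value: float = DEFAULT_ADJUST):
        """Build from order-pair observations against one transcript model."""
        from .fragments import accumulate_counts

        counts = accumulate_counts(observations, transcript)
        return cls(counts, adjust_value=adjust_value, transcript_id=transcript.transcript_id)

    @classmethod
    def from_dataframe(cls, df, transcript_id: str, n: int | None = None,
                       adjust_value: float = DEFAULT_ADJUST):
        """Build from a pairs table with columns earlier_intron/later_intron/read_count."""
        sub = df[df["transcript_id"] == transcript_id]
        if n is None:
            n = int(max(sub["earlier_intron"].max(), sub["later_intron"].max()))
        A = np.zeros((n, n))
        for row in sub.itertuples(index=False):
            A[int(row.earlier_intron) - 1, int(row.later_intron) - 1] = row.read_count
        return cls(A, adjust_value=adjust_value, transcript_id=transcript_id)

    @property
    def n(self) -> int:
        return self.counts.n

    @property
    def retention(self) -> float:
        return retention_percentage(self.counts)

    def loglike(self, theta) -> float:
        return log_likelihood(self.freq, theta)

    def fit(
        self,
        method: str | None = None,
        ilp_threshold: int = EXHAUSTIVE_MAX_N,
        max_n: int = ILP_MAX_N,
    ) -> "SplicingOrderResults":
        """Find theta*; exhaustive for n < ``ilp_threshold``, ILP up to ``max_n``."""
        n = self.n
        if n >= max_n:
            raise ValueError(f"too many introns (n={n} >= {max_n})")
        if method is None:
            method = "exhaustive" if n < ilp_threshold else "ilp"
        if method == "exhaustive":
            res = exhaustive_most_likely(self.freq)
        elif method == "ilp":
            res = ilp_most_likely(self.freq)
        else:
            raise ValueError(f"unknown method {method!r}")
        res.model = self
        res.transcript_id = self.transcript_id
        return res


@dataclass
class SplicingOrderResults:
    """Fitted most-likely splicing order and its diagnostics."""

    theta_star: SplicingOrder
    llf: float
    unique: bool
    n_optima: int
    method: str
    D: np.ndarray
    transcript_id: str = ""
    model: "SplicingOrderModel | None" = field(default=None, repr=False)
    _entropy: float | None = field(default=None, repr=False)

    @property
    def n(self) -> int:
        return self.theta_star.n

    @property
    def relative_log_likelihood(self) -> float:
        """ln L(in-order) - ln L(theta*); 0 iff in-order splicing is optimal."""
        return relative_log_likelihood(self.D, self.theta_star)

    @property
    def most_unlikely(self) -> SplicingOrder:
        return most_unlikely_order(self.theta_star)

    @property
    def normalized_entropy(self) -> float | None:
        """Splicing-order heterogeneity in [0, 1]; None when n >= 12."""
        if self.n >= EXHAUSTIVE_MAX_N:
            return None
        if self._entropy is None:
            self._entropy = normalized_entropy(self.D)
        return self._entropy

    @property
    def retention(self) -> float | None:
        return self.model.retention if self.model is not None else None

    def summary(self) -> str:
        lines = [
            "Most likely intron splicing order",
            "=" * 44,
            f"transcript:              {self.transcript_id or '-'}",
            f"introns (n):             {self.n}",
            f"method:                  {self.method}",
            f"most likely order:       {self.theta_star}",
            f"most unlikely order:     {self.most_unlikely}",
            f"log-likelihood:          {self.llf:.4f}",
            f"relative log-likelihood: {self.relative_log_likelihood:.4f}",
            f"unique optimum:          {self.unique}",
        ]
        if self.retention is not None:
            lines.append(f"pair retention:          {self.retention:.3f}")
        ent = self.normalized_entropy
        lines.append(
            f"normalized entropy:      {ent:.4f}" if ent is not None else
            "normalized entropy:      n/a (n >= 12)"
        )
        return "\n".join(lines)
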