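"""Local likelihood-ratio statistics, the scale penalty, and the multiscale
statistic.

For a candidate per-leaf mean vector p~ the multiscale statistic is

    T_n(p~, Y) = max over intervals [i, j] on which p~ is constant of
                 sqrt(2 * T_ij) - sqrt(pen((j - i + 1) / n)),

where T_ij is the local log likelihood-ratio statistic for "all means on
[i, j] equal p~|[i,j]" against the unrestricted alternative, and
pen(x) = 2 log(e / x) balances the scales so that the maximum is equally
likely to be attained at every interval length.  Intervals shorter than a
configurable minimal scale are excluded; the null quantiles are computed
under the same restriction.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .tree import LeafOrdering

__all__ = [
    "LikelihoodFamily",
    "BernoulliFamily",
    "GaussianFamily",
    "get_family",
    "CladeSignal",
    "penalty",
    "local_lr",
    "multiscale_statistic",
    "default_min_segment",
]

_BISECT_ITERS = 64  # interval width 1 -> ~5e-20, well below the 1e-10 contract


def default_min_segment(n: int) -> int:
    """Default minimal segment length (in leaves) at sample size ``n``.

    The theory allows the minimal relative scale lambda to shrink with n as
    long as n * lambda grows faster than log(n)^3; the default uses
    ceil(log(n)^3) capped at n/10 and floored at 2, so small trees are still
    fully searchable while large trees ignore uninformatively short intervals.
    """
    if n < 2:
        raise ValueError("need at least two leaves")
    return int(max(2, min(np.ceil(np.log(n) ** 3), np.ceil(n / 10))))


def penalty(length: int | np.ndarray, n: int) -> float | np.ndarray:
    """Scale calibration term pen(m / n) = 2 log(e n / m) for an interval of
    ``length`` m out of ``n`` positions.  Equals 2 at full length and grows as
    intervals shrink, handicapping the many short intervals."""
    m = np.asarray(length, dtype=float)
    if np.any(m < 1) or np.any(m > n):
        raise ValueError("interval length must be in 1..n")
    out = 2.0 * (np.log(n / m) + 1.0)
    return float(out) if np.isscalar(length) else out


class LikelihoodFamily:
    """Observation model for the per-leaf responses.

    Concrete families implement the segment log-likelihood, the local LR
    statistic given the segment's sufficient statistics (observation count
    ``m`` and sum ``s``), and the inversion of ``lr(b) <= c`` into an
    admissible mean interval.  All three accept numpy arrays and broadcast.
    """

    kind: str

    def loglik(self, m, s, b):
        raise NotImplementedError

    def lr(self, m, s, b):
        """sup_p l(p; y) - l(b; y) for a segment with count m and sum s."""
        raise NotImplementedError

    def mean_bounds(self, m, s, c):
        """Admissible interval {b : lr(m, s, b) <= c}, elementwise."""
        raise NotImplementedError

    def mean_space(self) -> tuple[float, float]:
        raise NotImplementedError


class BernoulliFamily(LikelihoodFamily):
    """Independent Bernoulli responses; the core binary-trait model."""

    kind = "bernoulli"

    def mean_space(self):
        return (0.0, 1.0)

    @staticmethod
    def _xlogy(x, y):
        with np.errstate(divide="ignore", invalid="ignore"):
            out = np.where(x == 0, 0.0, x * np.log(np.maximum(y, 1e-320)))
        return out

    def loglik(self, m, s, b):
        m = np.asarray(m, dtype=float)
        s = np.asarray(s, dtype=float)
        b = np.asarray(b, dtype=float)
        return self._xlogy(s, b) + self._xlogy(m - s, 1.0 - b)

    def lr(self, m, s, b):
        m = np.asarray(m, dtype=float)
        s = np.asarray(s, dtype=float)
        ybar = np.divide(s, m, out=np.zeros_like(s, dtype=float), where=m > 0)
        out = self.loglik(m, s, ybar) - self.loglik(m, s, b)
        # b on the boundary with discordant data: the hypothesis is impossible
        b = np.broadcast_to(np.asarray(b, dtype=float), out.shape)
        out = np.where((b <= 0.0) & (s > 0), np.inf, out)
        out = np.where((b >= 1.0) & (s < m), np.inf, out)
        return np.maximum(out, 0.0)

    def mean_bounds(self, m, s, c):
        m = np.asarray(m, dtype=float)
        s = np.asarray(s, dtype=float)
        c = np.broadcast_to(np.asarray(c, dtype=float), m.shape).astype(float)
        ybar = s / m
        lo = _bisect_monotone(lambda b: self.lr(m, s, b), 0.0, ybar, c, rising=False)
        hi = _bisect_monotone(lambda b: self.lr(m, s, b), ybar, 1.0, c, rising=True)
        lo = np.where(s == 0, 0.0, lo)
        hi = np.where(s == m, 1.0, hi)
        # a poisoned threshold (c < 0) admits no mean at all
        lo = np.where(c < 0, np.inf, lo)
        hi = np.where(c < 0, -np.inf, hi)
        return lo, hi


class GaussianFamily(LikelihoodFamily):
    """Homoscedastic Gaussian responses with known or estimated noise scale.

    Covers continuous traits: the local LR for a segment of m observations
    with mean ybar against hypothesised mean b is m (ybar - b)^2 / (2 sigma^2),
    so the admissible interval inverts in closed form.
    """

    kind = "gaussian"

    def __init__(self, sigma: float = 1.0):
        if not sigma > 0:
            raise ValueError("gaussian noise scale must be positive")
        self.sigma = float(sigma)

    def mean_space(self):
        return (-np.inf, np.inf)

    @staticmethod
    def estimate_sigma(y: np.ndarray) -> float:
        """First-difference noise estimate, robust to piecewise-constant
        signal: sqrt(sum (y[i+1]-y[i])^2 / (2 (n-1)))."""
        y = np.asarray(y, dtype=float)
        d = np.diff(y)
        if d.size == 0:
            raise ValueError("need at least two observations to estimate sigma")
        return float(np.sqrt(np.sum(d**2) / (2 * d.size)))

    def loglik(self, m, s, b):
        # constant terms dropped; only the mean-dependent part matters
        m = np.asarray(m, dtype=float)
        s = np.asarray(s, dtype=float)
        b = np.asarray(b, dtype=float)
        return -(m * b**2 - 2 * s * b) / (2 * self.sigma**2)

    def lr(self, m, s, b):
        m = np.asarray(m, dtype=float)
        s = np.asarray(s, dtype=float)
        ybar = s / m
        return m * (ybar - np.asarray(b, dtype=float)) ** 2 / (2 * self.sigma**2)

    def mean_bounds(self, m, s, c):
        m = np.asarray(m, dtype=float)
        s = np.asarray(s, dtype=float)
        c = np.asarray(c, dtype=float)
        ybar = s / m
        half = self.sigma * np.sqrt(np.maximum(2 * c, 0.0) / m)
        lo = np.where(c < 0, np.inf, ybar - half)
        hi = np.where(c < 0, -np.inf, ybar + half)
        return lo, hi


def get_family(family: str | LikelihoodFamily, y: np.ndarray | None = None
               ) -> LikelihoodFamily:
    """Resolve a family spec; for ``"gaussian"`` without an explicit scale the
    noise is estimated from first differences of ``y``."""
    if isinstance(family, LikelihoodFamily):
        return family
    if family == "bernoulli":
        return BernoulliFamily()
    if family == "gaussian":
        if y is None:
            return GaussianFamily(1.0)
        return GaussianFamily(GaussianFamily.estimate_sigma(y))
    raise ValueError(f"unknown likelihood family: {family!r}")


def _bisect_monotone(fn, left, right, target, rising: bool):
    """Vectorised bisection for fn monotone on [left, right] crossing target.

    ``rising=True`` solves for the largest b with fn(b) <= target scanning a
    rising branch; ``rising=False`` the smallest such b on a falling branch.
    """
    left = np.broadcast_to(np.asarray(left, dtype=float), np.shape(target)).copy()
    right = np.broadcast_to(np.asarray(right, dtype=float), np.shape(target)).copy()
    for _ in range(_BISECT_ITERS):
        mid = 0.5 * (left + right)
        ok = fn(mid) <= target
        if rising:
            left = np.where(ok, mid, left)
            right = np.where(ok, right, mid)
        else:
            right = np.where(ok, mid, right)
            left = np.where(ok, left, mid)
    return right if rising else left


def local_lr(y_segment: np.ndarray, p_tilde: float,
             family: str | LikelihoodFamily = "bernoulli") -> float:
    """Local log likelihood-ratio statistic T for one segment.

    Tests "all means on the segment equal ``p_tilde``" against the
    unrestricted alternative; equals 0 iff ``p_tilde`` is the segment MLE and
    +inf for a boundary hypothesis contradicted by the data.  Missing values
    (NaN) are dropped.
    """
    y = np.asarray(y_segment, dtype=float)
    y = y[~np.isnan(y)]
    if y.size == 0:
        raise ValueError("segment has no observed values")
    fam = get_family(family, y)
    if fam.kind == "bernoulli" and not set(np.unique(y)) <= {0.0, 1.0}:
        raise ValueError("bernoulli family requires responses in {0, 1}")
    lo, hi = fam.mean_space()
    if not (lo <= p_tilde <= hi):
        raise ValueError(f"p_tilde={p_tilde} outside the family's mean space")
    return float(fam.lr(np.array(y.size), np.array(y.sum()), p_tilde))


@dataclass
class CladeSignal:
    """A tree-generable mean vector: baseline plus clade offsets.

    ``active`` lists (node, offset) pairs; leaf i's mean is the baseline plus
    the offsets of every active node whose clade contains i.  With k active
    nodes the implied vector takes k + 1 distinct values provided every
    active node has at least one offspring leaf at exactly its own level
    (the identifiability convention of the model).
    """

    baseline: float
    active: list[tuple[int, float]] = field(default_factory=list)

    @property
    def k(self) -> int:
        return len(self.active)

    @property
    def active_nodes(self) -> list[int]:
        return [v for v, _ in self.active]

    def implied_vector(self, ordering: LeafOrdering) -> np.ndarray:
        n = ordering.n
        p = np.full(n, self.baseline, dtype=float)
        for v, c in self.active:
            lo, hi = ordering.clade_interval[v]
            p[lo - 1: hi] += c
        return p


def multiscale_statistic(y: np.ndarray, signal: CladeSignal | np.ndarray,
                         ordering: LeafOrdering | None = None,
                         family: str | LikelihoodFamily = "bernoulli",
                         min_segment: int | None = None) -> float:
    """Evaluate T_n(p~, Y): the penalised maximum of local LR statistics over
    every interval on which the candidate signal is constant.

    ``signal`` may be a :class:`CladeSignal` (resolved against ``ordering``)
    or a ready-made per-leaf mean vector.  Leaves with missing response are
    dropped and the remaining observations re-indexed, so interval lengths,
    the penalty, and the minimal scale all refer to observed counts.  Returns
    -inf if no constancy interval reaches the minimal scale.
    """
    y = np.asarray(y, dtype=float)
    if isinstance(signal, CladeSignal):
        if ordering is None:
            raise ValueError("an ordering is required to resolve a CladeSignal")
        p = signal.implied_vector(ordering)
    else:
        p = np.asarray(signal, dtype=float)
    if p.shape != y.shape:
        raise ValueError("signal and responses must have equal length")

    keep = ~np.isnan(y)
    y, p = y[keep], p[keep]
    n = y.size
    if n == 0:
        raise ValueError("no observed responses")
    fam = get_family(family, y)
    if min_segment is None:
        min_segment = default_min_segment(n)

    best = -np.inf
    # maximal runs of constant candidate signal
    starts = np.flatnonzero(np.r_[True, p[1:] != p[:-1]])
    ends = np.r_[starts[1:], n]
    cum = np.r_[0.0, np.cumsum(y)]
    for a, b in zip(starts, ends):  # run = positions a..b-1 (0-based)
        L = b - a
        if L < min_segment:
            continue
        val = p[a]
        for m in range(min_segment, L + 1):
            i = np.arange(a, b - m + 1)
            s = cum[i + m] - cum[i]
            t = fam.lr(np.full(i.shape, m, dtype=float), s, val)
            stat = np.sqrt(2.0 * t) - np.sqrt(penalty(m, n))
            top = float(np.max(stat)) if stat.size else -np.inf
            if top > best:
                best = top
            if np.isinf(best):
                return float(np.inf)
    return float(best)
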