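"""Independent reference implementations used only by the tests.

Everything here is deliberately written from the definitions with plain
loops and scipy root-finding, sharing no code with the package internals it
checks: the multiscale statistic by exhaustive interval enumeration, and the
minimal-active-node problem by exhaustive enumeration over node subsets with
per-region admissible-level intervals refined by Brent root-finding.
"""

from __future__ import annotations

import itertools
import math

import numpy as np
from scipy.optimize import brentq


def bern_lr(y_seg, b: float) -> float:
    """Bernoulli log likelihood-ratio statistic, from the definition."""
    y_seg = list(y_seg)
    m = len(y_seg)
    s = sum(y_seg)
    ybar = s / m

    def ll(p):
        out = 0.0
        if s > 0:
            if p <= 0:
                return -math.inf
            out += s * math.log(p)
        if m - s > 0:
            if p >= 1:
                return -math.inf
            out += (m - s) * math.log(1 - p)
        return out

    return ll(ybar) - ll(b)


def brute_multiscale(y, p_vec, min_segment: int) -> float:
    """T_n by triple loop over every interval of every constancy run."""
    y = list(y)
    p_vec = list(p_vec)
    n = len(y)
    best = -math.inf
    for i in range(n):
        for j in range(i + min_segment - 1, n):
            if any(p_vec[t] != p_vec[i] for t in range(i, j + 1)):
                continue
            t_ij = bern_lr(y[i: j + 1], p_vec[i])
            pen = 2.0 * math.log(math.e * n / (j - i + 1))
            best = max(best, math.sqrt(2.0 * t_ij) - math.sqrt(pen))
    return best


def _interval_bounds(m: int, s: int, c: float) -> tuple[float, float]:
    """Admissible means for one interval: {b : LR(b) <= c} via brentq."""
    if c < 0:
        return (math.inf, -math.inf)
    ybar = s / m

    def g(b):
        out = 0.0
        if s > 0:
            out += s * math.log(ybar / b)
        if m - s > 0:
            out += (m - s) * math.log((1 - ybar) / (1 - b))
        return out - c

    tiny = 1e-14
    if s == 0:
        lo = 0.0
    else:
        lo = ybar if g(tiny) < 0 else brentq(g, tiny, ybar, xtol=1e-13)
    if s == m:
        hi = 1.0
    else:
        hi = ybar if g(1 - tiny) < 0 else brentq(g, ybar, 1 - tiny, xtol=1e-13)
    return (lo, hi)


class EnumerationOracle:
    """Exhaustive solver of the minimal-active-node problem on a small tree.

    Enumerates node subsets in increasing size, derives each subset's
    level-set regions by painting clade intervals innermost-last, and
    intersects per-interval admissible means over every sufficiently long
    sub-interval of every run of each region.
    """

    def __init__(self, ordering, y, q: float, min_segment: int = 2):
        self.ordering = ordering
        self.y = [float(v) for v in y]
        self.n = len(self.y)
        self.q = q
        self.min_segment = min_segment
        n = self.n
        self.bounds = {}
        for i in range(n):
            for j in range(i + min_segment - 1, n):
                m = j - i + 1
                s = int(sum(self.y[i: j + 1]))
                pen = 2.0 * math.log(math.e * n / m)
                root = q + math.sqrt(pen)
                c = 0.5 * root * root if root >= 0 else -1.0
                self.bounds[(i, j)] = _interval_bounds(m, s, c)
        tree = ordering.tree
        self.candidates = [
            v for v in range(1, tree.node_count + 1)
            if v != tree.root
            and ordering.clade_interval[v] != (1, self.n)
        ]

    def _regions(self, subset):
        """Per-position owner (innermost covering subset node, -1 baseline)."""
        owner = [-1] * self.n
        for v in sorted(subset,
                        key=lambda u: -(self.ordering.clade_interval[u][1]
                                        - self.ordering.clade_interval[u][0])):
            lo, hi = self.ordering.clade_interval[v]
            for p in range(lo - 1, hi):
                owner[p] = v
        return owner

    def region_interval(self, owner, who) -> tuple[float, float] | None:
        """Admissible level interval for one region, or None if empty."""
        pos = [p for p in range(self.n) if owner[p] == who]
        if not pos:
            return None
        lo_b, hi_b = 0.0, 1.0
        runs = []
        start = pos[0]
        for a, b in zip(pos, pos[1:]):
            if b != a + 1:
                runs.append((start, a))
                start = b
        runs.append((start, pos[-1]))
        for a, b in runs:
            for i in range(a, b + 1):
                for j in range(i + self.min_segment - 1, b + 1):
                    l, h = self.bounds[(i, j)]
                    lo_b, hi_b = max(lo_b, l), min(hi_b, h)
        if lo_b > hi_b:
            return None
        return (lo_b, hi_b)

    def feasible(self, subset):
        """Region intervals for a subset, or None if infeasible."""
        owner = self._regions(subset)
        out = {}
        for who in set(owner) | set(subset):
            iv = self.region_interval(owner, who)
            if iv is None:
                return None
            out[who] = iv
        return out

    def solve(self, max_k: int = 3):
        """(k_hat, feasible subsets, best log-likelihood, node set, band)."""
        for k in range(max_k + 1):
            feas = []
            for subset in itertools.combinations(self.candidates, k):
                iv = self.feasible(subset)
                if iv is not None:
                    feas.append((subset, iv))
            if feas:
                break
        else:
            raise RuntimeError(f"no feasible subset up to size {max_k}")

        best_ll = -math.inf
        band_lo = [math.inf] * self.n
        band_hi = [-math.inf] * self.n
        nodes = set()
        for subset, iv in feas:
            owner = self._regions(subset)
            ll = 0.0
            for who, (lo_b, hi_b) in iv.items():
                pos = [p for p in range(self.n) if owner[p] == who]
                m, s = len(pos), sum(self.y[p] for p in pos)
                level = min(max(s / m, lo_b), hi_b)
                if s > 0:
                    ll += s * math.log(level)
                if m - s > 0:
                    ll += (m - s) * math.log(1 - level)
            best_ll = max(best_ll, ll)
            nodes.update(subset)
            for p in range(self.n):
                lo_b, hi_b = iv[owner[p]]
                band_lo[p] = min(band_lo[p], lo_b)
                band_hi[p] = max(band_hi[p], hi_b)
        return k, feas, best_ll, nodes, (band_lo, band_hi)
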