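"""Minimal-active-node segmentation with confidence statements.

Given responses on the leaves of a rooted tree and a threshold q = q_{1-alpha}
for the multiscale statistic, this module computes

* ``k_hat(q)``  — the smallest number of active nodes for which some
  tree-generable mean vector passes every local likelihood-ratio test at
  threshold q,
* ``p_hat(q)``  — the constrained maximum-likelihood signal among those with
  exactly ``k_hat`` active nodes,
* the 1-alpha confidence set of tree nodes that could be the active ones, and
* a simultaneous confidence band for the per-leaf means.

The search works on the leaf ordering, where every clade is a contiguous
interval.  Each interval [i, j] of at least the minimal scale contributes the
constraint ``sqrt(2 T_ij(b)) - sqrt(pen) <= q`` on any candidate signal that
is constant with value b across it; inverting the LR gives an admissible mean
interval per [i, j].  A candidate active-node set partitions the leaves into
regions (innermost covering clade); it is feasible iff each region's
admissible intervals — intersected over all sufficiently long sub-intervals
of all its runs — are non-empty.  Running max/min tables over the interval
system make each such check O(#runs).

Leaves with missing responses are removed and the remaining observations
re-indexed before any of this; clades remain contiguous under deletion, so
the machinery is unchanged with observed counts in place of nominal lengths.
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .likelihood import (
    CladeSignal,
    LikelihoodFamily,
    default_min_segment,
    get_family,
    penalty,
)
from .quantiles import NullQuantileTable, get_quantile_table, quantile
from .tree import LeafOrdering, RootedTree, standard_ordering, random_ordering

__all__ = [
    "IntervalConstraintSet",
    "SegmentationResult",
    "interval_bounds",
    "estimate_k",
    "constrained_mle",
    "node_confidence_set",
    "confidence_band",
    "treeseg",
]

_TIE_RTOL = 1e-9
_NEG_INF = -np.inf


# ---------------------------------------------------------------------------
# interval constraint system


class IntervalConstraintSet:
    """Admissible mean intervals for every interval of the observed sequence,
    plus running max/min tables for O(1) run queries.

    ``lo_table[a, b]`` (1-based, inclusive) is the largest lower admissible
    bound over all sub-intervals of [a, b] of length >= ``min_segment``;
    ``hi_table`` the smallest upper bound.  A constant fit on [a, b] is
    q-feasible iff ``lo_table[a, b] <= hi_table[a, b]``.
    """

    def __init__(self, y: np.ndarray, q: float,
                 family: str | LikelihoodFamily = "bernoulli",
                 min_segment: int | None = None):
        y = np.asarray(y, dtype=float)
        y = y[~np.isnan(y)]
        n = y.size
        if n < 2:
            raise ValueError("need at least two observed responses")
        self.y = y
        self.n = n
        self.q = float(q)
        self.family = get_family(family, y)
        self.min_segment = default_min_segment(n) if min_segment is None else int(min_segment)
        if not 1 <= self.min_segment <= n:
            raise ValueError("min_segment must be in 1..n")
        self.cum = np.r_[0.0, np.cumsum(y)]
        self._build_tables()

    def _build_tables(self) -> None:
        n, q = self.n, self.q
        LO = np.full((n + 2, n + 2), -np.inf)
        HI = np.full((n + 2, n + 2), np.inf)
        a_all, b_all, m_all = [], [], []
        for m in range(self.min_segment, n + 1):
            a = np.arange(1, n - m + 2)
            a_all.append(a)
            b_all.append(a + m - 1)
            m_all.append(np.full(a.shape, m))
        a_all = np.concatenate(a_all)
        b_all = np.concatenate(b_all)
        m_all = np.concatenate(m_all).astype(float)
        s_all = self.cum[b_all] - self.cum[a_all - 1]
        root = q + np.sqrt(penalty(m_all, n))
        c_all = np.where(root >= 0, 0.5 * root**2, -1.0)  # c < 0 => poisoned
        lo, hi = self.family.mean_bounds(m_all, s_all, c_all)
        LO[a_all, b_all] = lo
        HI[a_all, b_all] = hi
        for d in range(1, n):
            a = np.arange(1, n - d + 1)
            b = a + d
            LO[a, b] = np.maximum(LO[a, b], np.maximum(LO[a, b - 1], LO[a + 1, b]))
            HI[a, b] = np.minimum(HI[a, b], np.minimum(HI[a, b - 1], HI[a + 1, b]))
        self.lo_table = LO
        self.hi_table = HI

    def run_bounds(self, a: int, b: int) -> tuple[float, float]:
        """Admissible interval for a constant fit on positions a..b
        (1-based, inclusive); unconstrained if the run is empty or short."""
        if a > b:
            return (-np.inf, np.inf)
        return (float(self.lo_table[a, b]), float(self.hi_table[a, b]))

    def segment_stats(self, a: int, b: int) -> tuple[float, float]:
        if a > b:
            return (0.0, 0.0)
        return (float(b - a + 1), float(self.cum[b] - self.cum[a - 1]))

    def greedy_min_segments(self) -> int:
        """Minimal number of blocks in any partition of 1..n whose every
        block admits a constant fit; leftmost-maximal extension is optimal
        because block feasibility is monotone under shrinking."""
        n = self.n
        pos, count = 1, 0
        while pos <= n:
            count += 1
            lo_j, hi_j = pos, n
            if self.lo_table[pos, pos] > self.hi_table[pos, pos]:
                raise RuntimeError("threshold q is poisoned: no constant fit "
                                   "is feasible on any interval")
            if self.lo_table[pos, n] <= self.hi_table[pos, n]:
                pos = n + 1
                continue
            while lo_j < hi_j:  # binary search for the last feasible end
                mid = (lo_j + hi_j + 1) // 2
                if self.lo_table[pos, mid] <= self.hi_table[pos, mid]:
                    lo_j = mid
                else:
                    hi_j = mid - 1
            pos = lo_j + 1
        return count


def interval_bounds(y: np.ndarray, q: float,
                    family: str | LikelihoodFamily = "bernoulli",
                    min_segment: int | None = None) -> IntervalConstraintSet:
    """Invert every per-interval test at threshold q into admissible mean
    bounds; the computable representation of the signal confidence set."""
    return IntervalConstraintSet(y, q, family=family, min_segment=min_segment)


# ---------------------------------------------------------------------------
# candidate active nodes and region decomposition


@dataclass(frozen=True)
class _Candidate:
    """A distinct clade interval usable as an active node.

    ``span`` is the interval in observed (compressed) coordinates, ``full``
    in tree positions; ``nodes`` lists every tree node whose clade induces
    this observed interval (several can coincide once missing leaves are
    dropped).
    """

    span: tuple[int, int]
    full: tuple[int, int]
    nodes: tuple[int, ...]


@dataclass
class _Region:
    """One level-set of a candidate signal: a member clade minus its member
    descendants (or the baseline)."""

    member: int  # candidate index, -1 for baseline
    parent: int  # region index of the enclosing region, -1 for none
    runs: list[tuple[int, int]]
    lo: float = -np.inf
    hi: float = np.inf
    m: float = 0.0
    s: float = 0.0

    @property
    def level(self) -> float:
        if self.m == 0:
            return 0.5 * (self.lo + self.hi)
        return float(np.clip(self.s / self.m, self.lo, self.hi))


def _decompose(cons: IntervalConstraintSet, cands: list[_Candidate],
               subset: tuple[int, ...]) -> list[_Region] | None:
    """Region decomposition of a laminar candidate subset; None if any region
    is empty (unidentifiable) or its admissible bounds are incompatible."""
    n = cons.n
    members = sorted(subset, key=lambda i: (cands[i].span[0],
                                            -(cands[i].span[1] - cands[i].span[0])))
    regions: list[_Region] = [_Region(member=-1, parent=-1, runs=[])]
    reg_of: dict[int, int] = {}
    children: dict[int, list[int]] = {-1: []}
    stack: list[int] = []  # candidate indices of currently open clades
    for ci in members:
        lo, hi = cands[ci].span
        while stack and cands[stack[-1]].span[1] < lo:
            stack.pop()
        parent = stack[-1] if stack else -1
        if parent != -1:
            plo, phi = cands[parent].span
            if not (plo <= lo and hi <= phi):
                raise AssertionError("candidate intervals are not laminar")
        reg_of[ci] = len(regions)
        regions.append(_Region(member=ci,
                               parent=reg_of.get(parent, 0) if parent != -1 else 0,
                               runs=[]))
        children.setdefault(ci, [])
        children[parent].append(ci)
        stack.append(ci)

    for reg in regions:
        if reg.member == -1:
            lo, hi = 1, n
        else:
            lo, hi = cands[reg.member].span
        cursor = lo
        for ch in children.get(reg.member, []):
            clo, chi = cands[ch].span
            if cursor <= clo - 1:
                reg.runs.append((cursor, clo - 1))
            cursor = chi + 1
        if cursor <= hi:
            reg.runs.append((cursor, hi))
        L, H, m, s = -np.inf, np.inf, 0.0, 0.0
        for a, b in reg.runs:
            rl, rh = cons.run_bounds(a, b)
            L, H = max(L, rl), min(H, rh)
            mm, ss = cons.segment_stats(a, b)
            m += mm
            s += ss
        if m < 1 or L > H:
            return None
        reg.lo, reg.hi, reg.m, reg.s = L, H, m, s
    return regions


def _region_loglik(cons: IntervalConstraintSet, regions: list[_Region]) -> float:
    total = 0.0
    for reg in regions:
        total += float(cons.family.loglik(reg.m, reg.s, reg.level))
    return total


def _run_lookup(table: np.ndarray, a: np.ndarray, b: np.ndarray,
                empty_val: float) -> np.ndarray:
    valid = a <= b
    aa = np.where(valid, a, 1)
    bb = np.where(valid, b, 1)
    return np.where(valid, table[aa, bb], empty_val)


def _feasible_k1(cons: IntervalConstraintSet, cands: list[_Candidate]
                 ) -> list[tuple[int, ...]]:
    if not cands:
        return []
    n = cons.n
    LO, HI = cons.lo_table, cons.hi_table
    lo = np.array([c.span[0] for c in cands])
    hi = np.array([c.span[1] for c in cands])
    base_size = (lo - 1) + (n - hi)
    Lb = np.maximum(_run_lookup(LO, np.ones_like(lo), lo - 1, _NEG_INF),
                    _run_lookup(LO, hi + 1, np.full_like(hi, n), _NEG_INF))
    Hb = np.minimum(_run_lookup(HI, np.ones_like(lo), lo - 1, np.inf),
                    _run_lookup(HI, hi + 1, np.full_like(hi, n), np.inf))
    feas = (base_size >= 1) & (Lb <= Hb) & (LO[lo, hi] <= HI[lo, hi])
    return [(int(i),) for i in np.flatnonzero(feas)]


def _feasible_k2(cons: IntervalConstraintSet, cands: list[_Candidate]
                 ) -> list[tuple[int, ...]]:
    C = len(cands)
    if C < 2:
        return []
    n = cons.n
    LO, HI = cons.lo_table, cons.hi_table
    lo = np.array([c.span[0] for c in cands])
    hi = np.array([c.span[1] for c in cands])
    i1, i2 = np.triu_indices(C, k=1)
    loA, hiA, loB, hiB = lo[i1], hi[i1], lo[i2], hi[i2]
    swap = (loB < loA) | ((loB == loA) & (hiB > hiA))
    loA, loB = np.where(swap, loB, loA), np.where(swap, loA, loB)
    hiA, hiB = np.where(swap, hiB, hiA), np.where(swap, hiA, hiB)
    disjoint = loB > hiA
    nested = ~disjoint  # laminar family: loA <= loB and hiB <= hiA

    ones = np.ones_like(loA)
    nn = np.full_like(loA, n)
    feas = np.zeros(i1.shape, dtype=bool)

    # two disjoint active clades on a common baseline
    d = disjoint
    if d.any():
        Lb = np.maximum.reduce([
            _run_lookup(LO, ones[d], loA[d] - 1, _NEG_INF),
            _run_lookup(LO, hiA[d] + 1, loB[d] - 1, _NEG_INF),
            _run_lookup(LO, hiB[d] + 1, nn[d], _NEG_INF)])
        Hb = np.minimum.reduce([
            _run_lookup(HI, ones[d], loA[d] - 1, np.inf),
            _run_lookup(HI, hiA[d] + 1, loB[d] - 1, np.inf),
            _run_lookup(HI, hiB[d] + 1, nn[d], np.inf)])
        base_size = (loA[d] - 1) + (loB[d] - 1 - hiA[d]) + (n - hiB[d])
        feas[d] = ((base_size >= 1) & (Lb <= Hb)
                   & (LO[loA[d], hiA[d]] <= HI[loA[d], hiA[d]])
                   & (LO[loB[d], hiB[d]] <= HI[loB[d], hiB[d]]))

    # nested pair: inner clade B inside outer clade A
    t = nested
    if t.any():
        Lb = np.maximum(_run_lookup(LO, ones[t], loA[t] - 1, _NEG_INF),
                        _run_lookup(LO, hiA[t] + 1, nn[t], _NEG_INF))
        Hb = np.minimum(_run_lookup(HI, ones[t], loA[t] - 1, np.inf),
                        _run_lookup(HI, hiA[t] + 1, nn[t], np.inf))
        base_size = (loA[t] - 1) + (n - hiA[t])
        Lr = np.maximum(_run_lookup(LO, loA[t], loB[t] - 1, _NEG_INF),
                        _run_lookup(LO, hiB[t] + 1, hiA[t], _NEG_INF))
        Hr = np.minimum(_run_lookup(HI, loA[t], loB[t] - 1, np.inf),
                        _run_lookup(HI, hiB[t] + 1, hiA[t], np.inf))
        ring_size = (loB[t] - loA[t]) + (hiA[t] - hiB[t])
        feas[t] = ((base_size >= 1) & (Lb <= Hb)
                   & (ring_size >= 1) & (Lr <= Hr)
                   & (LO[loB[t], hiB[t]] <= HI[loB[t], hiB[t]]))

    out = []
    for idx in np.flatnonzero(feas):
        pair = (int(i1[idx]), int(i2[idx]))
        out.append(pair)
    return out


class _Engine:
    """Shared state for one segmentation problem on the observed sequence."""

    def __init__(self, cons: IntervalConstraintSet, cands: list[_Candidate],
                 max_subsets: int = 5_000_000):
        self.cons = cons
        self.cands = cands
        self.max_subsets = max_subsets

    def feasible_subsets(self, k: int) -> list[tuple[int, ...]]:
        cons, cands = self.cons, self.cands
        if k == 0:
            lo, hi = cons.run_bounds(1, cons.n)
            return [()] if lo <= hi else []
        if k == 1:
            return _feasible_k1(cons, cands)
        if k == 2:
            return _feasible_k2(cons, cands)
        pool = list(range(len(cands)))
        if math.comb(len(pool), k) > self.max_subsets:
            pool = self._pruned_pool()
            if math.comb(len(pool), k) > self.max_subsets:
                raise RuntimeError(
                    f"active-node search at k={k} exceeds the subset cap "
                    f"({self.max_subsets}); raise max_subsets or alpha")
        out = []
        for subset in itertools.combinations(pool, k):
            if _decompose(cons, cands, subset) is not None:
                out.append(subset)
        return out

    def _pruned_pool(self) -> list[int]:
        """Restrict candidates to those with a boundary near a greedy
        change gap; used only when full enumeration would be too large."""
        cons = self.cons
        window = 2 * cons.min_segment
        gaps = []
        pos = 1
        while pos <= cons.n:
            lo_j, hi_j = pos, cons.n
            if cons.lo_table[pos, cons.n] <= cons.hi_table[pos, cons.n]:
                break
            while lo_j < hi_j:
                mid = (lo_j + hi_j + 1) // 2
                if cons.lo_table[pos, mid] <= cons.hi_table[pos, mid]:
                    lo_j = mid
                else:
                    hi_j = mid - 1
            if lo_j < cons.n:
                gaps.append(lo_j)
            pos = lo_j + 1
        keep = []
        for i, c in enumerate(self.cands):
            lo, hi = c.span
            for g in gaps:
                if abs(lo - 1 - g) <= window or abs(hi - g) <= window:
                    keep.append(i)
                    break
        return keep

    def estimate_k(self) -> tuple[int, list[tuple[int, ...]]]:
        m_hat = self.cons.greedy_min_segments()
        k = max(0, (m_hat - 1 + 1) // 2)  # any k-node signal has <= 2k+1 runs
        while True:
            subsets = self.feasible_subsets(k)
            if subsets:
                return k, subsets
            k += 1
            if k > len(self.cands):
                raise RuntimeError("no feasible signal found; threshold q may "
                                   "be poisoned (q + sqrt(pen) < 0)")


# ---------------------------------------------------------------------------
# result container and end-to-end driver


@dataclass
class SegmentationResult:
    """Everything the procedure reports for one response.

    Arrays are aligned to the leaf ordering (position 1..n of the full tree,
    including leaves whose response was missing).
    """

    tree: RootedTree
    ordering: LeafOrdering
    k_hat: int
    p_hat: CladeSignal
    fitted: np.ndarray
    band_lo: np.ndarray
    band_hi: np.ndarray
    active_nodes: list[int]
    node_confidence_set: list[int]
    alternatives: list[list[int]]
    alpha: float
    q_used: float
    family: str
    min_segment: int
    n_observed: int
    quantile_info: dict = field(default_factory=dict)
    log_likelihood: float = float("nan")

    @property
    def n_segments(self) -> int:
        return self.k_hat + 1

    def segment_ids(self) -> np.ndarray:
        """Per-position segment label: 0 for baseline, j for the j-th active
        clade (innermost wins)."""
        n = self.ordering.n
        ids = np.zeros(n, dtype=int)
        order = sorted(range(len(self.p_hat.active)),
                       key=lambda j: -(self._span(j)[1] - self._span(j)[0]))
        for rank, j in enumerate(order):
            lo, hi = self._span(j)
            ids[lo - 1: hi] = j + 1
        return ids

    def _span(self, j: int) -> tuple[int, int]:
        return self.ordering.clade_interval[self.p_hat.active[j][0]]

    def segments_frame(self) -> pd.DataFrame:
        labels = self.ordering.labels_in_order()
        return pd.DataFrame({
            "leaf": labels,
            "position": np.arange(1, self.ordering.n + 1),
            "segment": self.segment_ids(),
            "p_hat": self.fitted,
            "band_lo": self.band_lo,
            "band_hi": self.band_hi,
        })

    def summary(self) -> str:
        lines = [
            f"treeseg result: k_hat = {self.k_hat} active node(s), "
            f"{self.n_segments} segment(s), alpha = {self.alpha}",
            f"threshold q = {self.q_used:.4f}  family = {self.family}  "
            f"observed leaves = {self.n_observed}/{self.ordering.n}",
        ]
        for v, c in self.p_hat.active:
            lo, hi = self.ordering.clade_interval[v]
            lines.append(
                f"  active node {self.tree.node_label(v)}: positions "
                f"{lo}-{hi}, level {self.p_hat.baseline + c:.3f} "
                f"(offset {c:+.3f})")
        lines.append(f"  baseline level {self.p_hat.baseline:.3f}")
        lines.append(
            f"  confidence set: {len(self.node_confidence_set)} node(s)")
        return "\n".join(lines)


def _make_candidates(ordering: LeafOrdering, observed_pos: np.ndarray
                     ) -> list[_Candidate]:
    """Distinct clade intervals in observed coordinates for every non-root
    node with at least one observed offspring leaf, excluding full-span
    clades (which would leave no baseline leaf)."""
    n = ordering.n
    n_obs = int(observed_pos.sum())
    cum_obs = np.r_[0, np.cumsum(observed_pos)]  # cum_obs[p] = #observed <= p
    by_span: dict[tuple[int, int], list[int]] = {}
    for v, (lo, hi) in ordering.clade_interval.items():
        if v == ordering.tree.root:
            continue
        clo = int(cum_obs[lo - 1]) + 1
        chi = int(cum_obs[hi])
        if clo > chi:
            continue  # clade entirely missing: not identifiable
        if (clo, chi) == (1, n_obs):
            continue  # no baseline leaf would remain
        by_span.setdefault((clo, chi), []).append(v)
    cands = []
    for span in sorted(by_span):
        nodes = tuple(sorted(by_span[span]))
        # full-coordinate span of the smallest clade mapping to this interval
        best = min(nodes, key=lambda v: (ordering.clade_interval[v][1]
                                         - ordering.clade_interval[v][0], v))
        cands.append(_Candidate(span=span, full=ordering.clade_interval[best],
                                nodes=nodes))
    return cands


def _paint_regions(cands: list[_Candidate], subset: tuple[int, ...],
                   n_full: int) -> np.ndarray:
    """Innermost-covering member per full-tree position; -1 = baseline."""
    owner = np.full(n_full, -1, dtype=int)
    order = sorted(subset, key=lambda i: -(cands[i].full[1] - cands[i].full[0]))
    for ci in order:
        lo, hi = cands[ci].full
        owner[lo - 1: hi] = ci
    return owner


def _clip_to_space(x: float, fam: LikelihoodFamily) -> float:
    lo, hi = fam.mean_space()
    return float(min(max(x, lo), hi))


def _subset_signal(cons: IntervalConstraintSet, cands: list[_Candidate],
                   subset: tuple[int, ...], regions: list[_Region]
                   ) -> CladeSignal:
    level = {reg.member: reg.level for reg in regions}
    parent_member = {reg.member: (regions[reg.parent].member
                                  if reg.parent >= 0 else None)
                     for reg in regions}
    active = []
    for ci in subset:
        rep = min(cands[ci].nodes,
                  key=lambda v: (cands[ci].full[1] - cands[ci].full[0], v))
        pm = parent_member[ci]
        base = level[-1] if pm is None else level[pm]
        active.append((rep, level[ci] - base))
    return CladeSignal(baseline=level[-1], active=active)


def treeseg(tree: RootedTree, responses, alpha: float = 0.05,
            family: str | LikelihoodFamily = "bernoulli",
            ordering: str | LeafOrdering = "standard",
            ordering_seed: int = 0,
            min_segment: int | None = None,
            quantile_table: NullQuantileTable | None = None,
            n_draws: int = 5000, grid_size: int | None = None,
            quantile_seed: int = 0, cache_dir=None,
            max_subsets: int = 5_000_000) -> SegmentationResult:
    """End-to-end segmentation of a tree against a per-leaf response.

    Parameters
    ----------
    tree
        The fixed rooted tree.
    responses
        Mapping / pandas Series from leaf label to response, or an array
        aligned to leaf ids 1..n.  Absent labels and NaNs are treated as
        missing.
    alpha
        Significance level: the probability of reporting any spurious active
        node is asymptotically at most ``alpha``.
    ordering
        "standard" (canonical, input-order independent), "random" (seeded by
        ``ordering_seed``), or a prebuilt :class:`LeafOrdering`.
    min_segment
        Minimal tested interval length in observed leaves; default
        :func:`default_min_segment` of the observed count.
    quantile_table
        Reuse a precomputed null table (recommended when analysing many
        datasets of the same size); otherwise one is simulated (and cached in
        ``cache_dir`` if given) with ``n_draws`` draws on ``grid_size`` grid
        points (default ``max(n, 512)``).
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly in (0, 1)")
    if isinstance(ordering, LeafOrdering):
        ordg = ordering
    elif ordering == "standard":
        ordg = standard_ordering(tree)
    elif ordering == "random":
        ordg = random_ordering(tree, ordering_seed)
    else:
        raise ValueError(f"unknown ordering spec: {ordering!r}")

    n = tree.n_leaves
    y_pos = np.full(n, np.nan)
    if isinstance(responses, (dict, pd.Series)):
        resp = dict(responses)
        unknown = set(resp) - set(tree.leaf_labels.values())
        if unknown:
            raise ValueError(f"response labels not in tree: {sorted(unknown)[:10]}")
        for pos, leaf in enumerate(ordg.order):
            label = tree.leaf_labels[leaf]
            if label in resp and resp[label] is not None:
                y_pos[pos] = float(resp[label])
    else:
        arr = np.asarray(responses, dtype=float)
        if arr.shape != (n,):
            raise ValueError(f"response array must have length {n}")
        for pos, leaf in enumerate(ordg.order):
            y_pos[pos] = arr[leaf - 1]

    observed = ~np.isnan(y_pos)
    n_obs = int(observed.sum())
    if n_obs < 2:
        raise ValueError("need at least two observed responses")
    y_obs = y_pos[observed]
    fam = get_family(family, y_obs)
    if fam.kind == "bernoulli" and not set(np.unique(y_obs)) <= {0.0, 1.0}:
        raise ValueError("bernoulli family requires responses in {0, 1}; "
                         "use family='gaussian' for continuous traits")

    if min_segment is None:
        min_segment = default_min_segment(n_obs)
    if quantile_table is None:
        gs = grid_size if grid_size is not None else max(n_obs, 512)
        # the limit statistic M is the supremum over all scales; restricting
        # it to the data statistic's minimal scale is available via an
        # explicit quantile_table but the full sup is the stochastic bound
        # the calibration guarantee rests on
        quantile_table = get_quantile_table(
            grid_size=gs, n_draws=n_draws, seed=quantile_seed,
            min_scale=None, cache_dir=cache_dir)
    q = quantile(quantile_table, alpha)

    cons = IntervalConstraintSet(y_obs, q, family=fam, min_segment=min_segment)
    cands = _make_candidates(ordg, observed.astype(int))
    engine = _Engine(cons, cands, max_subsets=max_subsets)
    k_hat, subsets = engine.estimate_k()

    fits = []
    for subset in subsets:
        regions = _decompose(cons, cands, subset)
        fits.append((subset, regions, _region_loglik(cons, regions)))
    best_ll = max(ll for _, _, ll in fits)
    tol = _TIE_RTOL * max(1.0, abs(best_ll))
    winners = [f for f in fits if f[2] >= best_ll - tol]
    subset, regions, ll = winners[0]
    signal = _subset_signal(cons, cands, subset, regions)

    def rep_nodes(sub):
        return [min(cands[ci].nodes,
                    key=lambda v: (cands[ci].full[1] - cands[ci].full[0], v))
                for ci in sub]

    alternatives = [rep_nodes(s) for s, _, _ in winners[1:]]

    # confidence set: every tree node active in some feasible signal
    conf: set[int] = set()
    for sub in subsets:
        for ci in sub:
            conf.update(cands[ci].nodes)
    conf_set = sorted(conf, key=lambda v: (ordg.clade_interval[v][0],
                                           ordg.clade_interval[v][1]))

    # simultaneous band: envelope of region bounds over all feasible signals
    band_lo = np.full(n, np.inf)
    band_hi = np.full(n, -np.inf)
    for sub, regs, _ in fits:
        owner = _paint_regions(cands, sub, n)
        lo_of = {reg.member: _clip_to_space(reg.lo, fam) for reg in regs}
        hi_of = {reg.member: _clip_to_space(reg.hi, fam) for reg in regs}
        band_lo = np.minimum(band_lo, np.array([lo_of[o] for o in owner]))
        band_hi = np.maximum(band_hi, np.array([hi_of[o] for o in owner]))
    owner = _paint_regions(cands, subset, n)
    lvl_of = {reg.member: reg.level for reg in regions}
    fitted = np.array([lvl_of[o] for o in owner])
    band_lo = np.minimum(band_lo, fitted)
    band_hi = np.maximum(band_hi, fitted)

    return SegmentationResult(
        tree=tree, ordering=ordg, k_hat=k_hat, p_hat=signal, fitted=fitted,
        band_lo=band_lo, band_hi=band_hi,
        active_nodes=signal.active_nodes,
        node_confidence_set=sorted(set(conf_set) | set(signal.active_nodes),
                                   key=lambda v: ordg.clade_interval[v]),
        alternatives=alternatives, alpha=alpha, q_used=q, family=fam.kind,
        min_segment=min_segment, n_observed=n_obs,
        quantile_info={"kind": quantile_table.kind,
                       "grid_size": quantile_table.grid_size,
                       "n_draws": quantile_table.n_draws,
                       "seed": quantile_table.seed,
                       "min_scale": quantile_table.min_scale,
                       "key": quantile_table.key()},
        log_likelihood=ll,
    )


# ---------------------------------------------------------------------------
# spec-level operations (thin wrappers used by tests and power users)


def _engine_for(y: np.ndarray, ordering: LeafOrdering, q: float,
                family: str | LikelihoodFamily = "bernoulli",
                min_segment: int | None = None) -> tuple[_Engine, np.ndarray]:
    y = np.asarray(y, dtype=float)
    observed = ~np.isnan(y)
    y_obs = y[observed]
    fam = get_family(family, y_obs)
    cons = IntervalConstraintSet(y_obs, q, family=fam, min_segment=min_segment)
    cands = _make_candidates(ordering, observed.astype(int))
    return _Engine(cons, cands), observed


def estimate_k(y: np.ndarray, tree: RootedTree, ordering: LeafOrdering,
               q: float, family: str | LikelihoodFamily = "bernoulli",
               min_segment: int | None = None) -> tuple[int, CladeSignal]:
    """Smallest number of active nodes admitting a q-feasible signal, plus
    one such signal (levels at the clipped per-region MLE)."""
    engine, _ = _engine_for(y, ordering, q, family, min_segment)
    k_hat, subsets = engine.estimate_k()
    regions = _decompose(engine.cons, engine.cands, subsets[0])
    return k_hat, _subset_signal(engine.cons, engine.cands, subsets[0], regions)


def constrained_mle(y: np.ndarray, tree: RootedTree, ordering: LeafOrdering,
                    q: float, k_hat: int,
                    family: str | LikelihoodFamily = "bernoulli",
                    min_segment: int | None = None
                    ) -> tuple[CladeSignal, float, list[list[int]]]:
    """Maximum-likelihood signal among q-feasible signals with exactly
    ``k_hat`` active nodes; returns (signal, log-likelihood, alternatives)."""
    engine, _ = _engine_for(y, ordering, q, family, min_segment)
    subsets = engine.feasible_subsets(k_hat)
    if not subsets:
        raise ValueError(f"no feasible signal with k={k_hat}")
    fits = []
    for subset in subsets:
        regions = _decompose(engine.cons, engine.cands, subset)
        fits.append((subset, regions, _region_loglik(engine.cons, regions)))
    best = max(ll for *_, ll in fits)
    tol = _TIE_RTOL * max(1.0, abs(best))
    winners = [f for f in fits if f[2] >= best - tol]
    subset, regions, ll = winners[0]
    sig = _subset_signal(engine.cons, engine.cands, subset, regions)
    alts = [[min(engine.cands[ci].nodes) for ci in s] for s, _, _ in winners[1:]]
    return sig, ll, alts


def node_confidence_set(y: np.ndarray, tree: RootedTree,
                        ordering: LeafOrdering, q: float, k_hat: int,
                        family: str | LikelihoodFamily = "bernoulli",
                        min_segment: int | None = None) -> list[int]:
    """All tree nodes that are active in at least one q-feasible signal with
    ``k_hat`` active nodes (empty for k_hat = 0)."""
    if k_hat == 0:
        return []
    engine, _ = _engine_for(y, ordering, q, family, min_segment)
    conf: set[int] = set()
    for subset in engine.feasible_subsets(k_hat):
        for ci in subset:
            conf.update(engine.cands[ci].nodes)
    return sorted(conf, key=lambda v: ordering.clade_interval[v])


def confidence_band(y: np.ndarray, tree: RootedTree, ordering: LeafOrdering,
                    q: float, k_hat: int,
                    family: str | LikelihoodFamily = "bernoulli",
                    min_segment: int | None = None
                    ) -> tuple[np.ndarray, np.ndarray]:
    """Simultaneous per-leaf envelope of the admissible region bounds over
    every q-feasible signal with ``k_hat`` active nodes."""
    engine, _ = _engine_for(y, ordering, q, family, min_segment)
    subsets = engine.feasible_subsets(k_hat)
    if not subsets:
        raise ValueError(f"no feasible signal with k={k_hat}")
    n = ordering.n
    fam = engine.cons.family
    band_lo = np.full(n, np.inf)
    band_hi = np.full(n, -np.inf)
    for subset in subsets:
        regions = _decompose(engine.cons, engine.cands, subset)
        owner = _paint_regions(engine.cands, subset, n)
        lo_of = {reg.member: _clip_to_space(reg.lo, fam) for reg in regions}
        hi_of = {reg.member: _clip_to_space(reg.hi, fam) for reg in regions}
        band_lo = np.minimum(band_lo, np.array([lo_of[o] for o in owner]))
        band_hi = np.maximum(band_hi, np.array([hi_of[o] for o in owner]))
    return band_lo, band_hi
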