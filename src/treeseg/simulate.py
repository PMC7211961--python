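"""Synthetic trees and clade-structured responses; simulation study driver.

The generator realises exactly the data-generating model the method assumes:
a fixed rooted tree, a baseline success probability, a small number of
disjoint active clades with their own probabilities, and independent
Bernoulli draws per leaf.  The study driver loops tree -> signal -> responses
-> segmentation and aggregates type-I error, power, and localisation
statistics; every run is reproducible from (design, seed).

Tree models:

* ``yule``     — pure-birth topology (a uniformly chosen tip splits at each
  step), the standard neutral null for random phylogenies; default.
* ``coalescent`` — random sequential pairwise joining of lineages.
* ``perfect``  — balanced binary tree (requires a power-of-two leaf count).
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .likelihood import CladeSignal
from .quantiles import NullQuantileTable, get_quantile_table
from .segmentation import SegmentationResult, treeseg
from .tree import LeafOrdering, RootedTree, read_newick, standard_ordering

__all__ = [
    "SimulationDesign",
    "SimulationReport",
    "simulate_tree",
    "plant_signal",
    "run_study",
]


def _serialize(children: dict[int, tuple[int, int]], labels: dict[int, str],
               root: int) -> str:
    """Newick string from a child map (iterative to spare the recursion
    limit on caterpillar-like trees)."""
    out: list[str] = []
    stack: list[tuple[int, int]] = [(root, 0)]
    while stack:
        node, state = stack.pop()
        if node not in children:
            out.append(labels[node])
            continue
        left, right = children[node]
        if state == 0:
            out.append("(")
            stack.append((node, 1))
            stack.append((left, 0))
        elif state == 1:
            out.append(",")
            stack.append((node, 2))
            stack.append((right, 0))
        else:
            out.append(")")
    return "".join(out) + ";"


def simulate_tree(n_leaves: int, tree_model: str = "yule",
                  seed: int | np.random.Generator = 0) -> RootedTree:
    """Draw a random rooted binary tree with ``n_leaves`` labelled tips."""
    if n_leaves < 2:
        raise ValueError("need at least two leaves")
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)

    children: dict[int, tuple[int, int]] = {}
    if tree_model == "yule":
        # grow by splitting a uniformly random current tip
        children[0] = (1, 2)
        tips = [1, 2]
        next_id = 3
        while len(tips) < n_leaves:
            i = int(rng.integers(len(tips)))
            v = tips[i]
            children[v] = (next_id, next_id + 1)
            tips[i] = next_id
            tips.append(next_id + 1)
            next_id += 2
        root = 0
    elif tree_model == "coalescent":
        # join two uniformly chosen lineages until one remains
        lineages = list(range(n_leaves))
        tips = list(range(n_leaves))
        next_id = n_leaves
        while len(lineages) > 1:
            i, j = sorted(int(x) for x in
                          rng.choice(len(lineages), size=2, replace=False))
            children[next_id] = (lineages[i], lineages[j])
            lineages[i] = next_id
            lineages.pop(j)
            next_id += 1
        root = lineages[0]
    elif tree_model == "perfect":
        depth = int(np.log2(n_leaves))
        if 2**depth != n_leaves:
            raise ValueError("perfect trees require a power-of-two leaf count")
        tips = list(range(n_leaves))
        # heap layout: node i has children 2i+1, 2i+2; leaves are the last n
        total = 2 * n_leaves - 1
        for i in range((total - 1) // 2):
            children[i] = (2 * i + 1, 2 * i + 2)
        tips = list(range((total - 1) // 2, total))
        root = 0
    else:
        raise ValueError(f"unknown tree model: {tree_model!r}")

    labels = {v: f"t{i + 1}" for i, v in enumerate(sorted(tips))}
    return read_newick(_serialize(children, labels, root))


@dataclass
class SimulationDesign:
    """Parameters of one simulation study.

    ``clade_fraction`` gives the target fraction of leaves per active clade
    (clades are chosen disjoint); ``probs`` lists the baseline success
    probability followed by one probability per active clade.  ``size_tol``
    is the accepted relative deviation of a clade's size from its target.
    """

    n_leaves: int = 200
    tree_model: str = "yule"
    k_true: int = 0
    clade_fraction: tuple[float, ...] = ()
    probs: tuple[float, ...] = (0.5,)
    n_reps: int = 100
    seed: int = 0
    alpha: float = 0.1
    size_tol: float = 0.25
    max_tree_redraws: int = 100
    n_draws: int = 5000
    min_segment: int | None = None

    def __post_init__(self):
        self.clade_fraction = tuple(self.clade_fraction)
        self.probs = tuple(self.probs)
        if len(self.probs) != self.k_true + 1:
            raise ValueError("probs must list baseline + one value per clade")
        if len(self.clade_fraction) != self.k_true:
            raise ValueError("clade_fraction needs one entry per active clade")
        if not all(0.0 <= p <= 1.0 for p in self.probs):
            raise ValueError("probabilities must lie in [0, 1]")

    @property
    def delta(self) -> float:
        """Smallest pairwise gap between segment probabilities (0 if k=0)."""
        if len(self.probs) < 2:
            return 0.0
        ps = sorted(self.probs)
        return min(b - a for a, b in zip(ps, ps[1:]))


class SignalPlacementError(RuntimeError):
    """No clade of suitable size exists on the drawn tree."""


def plant_signal(tree: RootedTree, ordering: LeafOrdering,
                 design: SimulationDesign,
                 seed: int | np.random.Generator = 0
                 ) -> tuple[CladeSignal, np.ndarray]:
    """Select disjoint active clades matching the design's size targets,
    then draw independent Bernoulli responses.

    Returns the true signal and the responses aligned to leaf ids 1..n.
    """
    rng = seed if isinstance(seed, np.random.Generator) \
        else np.random.default_rng(seed)
    n = tree.n_leaves
    chosen: list[int] = []
    intervals: list[tuple[int, int]] = []
    for frac in design.clade_fraction:
        lo_sz = (1 - design.size_tol) * frac * n
        hi_sz = (1 + design.size_tol) * frac * n
        options = []
        for v in tree.inner_nodes:
            if v == tree.root:
                continue
            a, b = ordering.clade_interval[v]
            sz = b - a + 1
            if not lo_sz <= sz <= hi_sz:
                continue
            if any(not (b < c or d < a) for c, d in intervals):
                continue  # overlaps an already chosen clade
            if n - (sum(d - c + 1 for c, d in intervals) + sz) < 1:
                continue  # baseline must keep at least one leaf
            options.append(v)
        if not options:
            raise SignalPlacementError(
                f"no free clade within {design.size_tol:.0%} of "
                f"{frac:.0%} of {n} leaves")
        v = int(rng.choice(options))
        chosen.append(v)
        intervals.append(ordering.clade_interval[v])

    baseline = design.probs[0]
    signal = CladeSignal(
        baseline=baseline,
        active=[(v, design.probs[j + 1] - baseline)
                for j, v in enumerate(chosen)])
    p = signal.implied_vector(ordering)
    y_pos = rng.binomial(1, p).astype(float)
    y = np.empty(n)
    for pos, leaf in enumerate(ordering.order):
        y[leaf - 1] = y_pos[pos]
    return signal, y


@dataclass
class SimulationReport:
    """Per-replicate outcomes and their aggregates."""

    design: SimulationDesign
    rows: pd.DataFrame
    aggregates: dict = field(default_factory=dict)

    def recompute_aggregates(self) -> dict:
        r = self.rows
        n = len(r)
        agg = {
            "n_reps": int(n),
            "overestimation_rate": float((r.k_hat > r.k_true).mean()),
            "underestimation_rate": float((r.k_hat < r.k_true).mean()),
            "exact_recovery_rate": float((r.k_hat == r.k_true).mean()),
            "no_association_rate": float((r.k_hat == 0).mean()),
        }
        loc = r.localization_error.dropna()
        agg["mean_localization_error"] = float(loc.mean()) if len(loc) else None
        return agg

    def to_files(self, prefix: str) -> None:
        self.rows.to_csv(f"{prefix}.rows.tsv", sep="\t", index=False)
        blob = {"design": asdict(self.design), "aggregates": self.aggregates}
        with open(f"{prefix}.aggregates.json", "w") as fh:
            json.dump(blob, fh, indent=2)


def _change_gaps(signal: CladeSignal, ordering: LeafOrdering) -> list[int]:
    p = signal.implied_vector(ordering)
    return [int(g) for g in np.flatnonzero(p[1:] != p[:-1]) + 1]


def _localization_error(truth: CladeSignal, result: SegmentationResult
                        ) -> float:
    """Total leaf displacement between true and estimated change gaps,
    matched in sorted order; only defined when the counts agree."""
    tg = _change_gaps(truth, result.ordering)
    eg = [int(g) for g in
          np.flatnonzero(result.fitted[1:] != result.fitted[:-1]) + 1]
    if len(tg) != len(eg):
        return float("nan")
    if not tg:
        return 0.0
    return float(sum(abs(a - b) for a, b in zip(sorted(tg), sorted(eg))))


def run_study(design: SimulationDesign,
              quantile_table: NullQuantileTable | None = None,
              cache_dir=None, progress: bool = False) -> SimulationReport:
    """Run the full simulation loop for one design.

    A single null-quantile table (matched to the design's leaf count and
    minimal scale) is shared across replicates.  Per-replicate seeds are
    spawned deterministically from ``design.seed``.
    """
    from .likelihood import default_min_segment

    n = design.n_leaves
    min_seg = design.min_segment or default_min_segment(n)
    if quantile_table is None:
        quantile_table = get_quantile_table(
            grid_size=max(n, 512), n_draws=design.n_draws, seed=design.seed,
            min_scale=None, cache_dir=cache_dir)

    root_seq = np.random.SeedSequence(design.seed)
    rows = []
    for rep, child in enumerate(root_seq.spawn(design.n_reps)):
        rng = np.random.default_rng(child)
        truth = None
        tree = ordering = None
        for _ in range(design.max_tree_redraws):
            tree = simulate_tree(n, design.tree_model, rng)
            ordering = standard_ordering(tree)
            try:
                truth, y = plant_signal(tree, ordering, design, rng)
                break
            except SignalPlacementError:
                continue
        if truth is None:
            raise SignalPlacementError(
                "could not place the designed signal after "
                f"{design.max_tree_redraws} tree redraws")
        res = treeseg(tree, y, alpha=design.alpha, ordering=ordering,
                      min_segment=min_seg, quantile_table=quantile_table)
        rows.append({
            "rep": rep,
            "k_true": truth.k,
            "k_hat": res.k_hat,
            "true_nodes": ",".join(map(str, truth.active_nodes)),
            "estimated_nodes": ",".join(map(str, res.active_nodes)),
            "confidence_set_size": len(res.node_confidence_set),
            "active_in_confidence_set": bool(
                set(res.active_nodes) <= set(res.node_confidence_set)),
            "true_in_confidence_set": bool(
                set(truth.active_nodes) <= set(res.node_confidence_set))
            if truth.k == res.k_hat else None,
            "localization_error": _localization_error(truth, res),
        })
        if progress and (rep + 1) % 50 == 0:
            print(f"  replicate {rep + 1}/{design.n_reps}")
    report = SimulationReport(design=design, rows=pd.DataFrame(rows))
    report.aggregates = report.recompute_aggregates()
    return report
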