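"""Monte-Carlo null distribution of the multiscale statistic.

Under a correct candidate signal the statistic T_n is asymptotically
stochastically bounded by

    M = sup_{0 <= s < t <= 1} |B(t) - B(s)| / sqrt(t - s)
                              - sqrt(2 log(e / (t - s))),

a penalised supremum of standardised Brownian-motion increments.  M does not
depend on the unknown signal, so its quantiles q_{1-alpha} — the thresholds
the whole procedure runs on — are obtained once by simulation and cached.

Two simulators are provided: the Brownian limit on a grid (default) and a
finite-sample variant drawing Bernoulli noise at the actual n, useful when
the asymptotic calibration is in doubt for small samples.
"""

from __future__ import annotations

import hashlib
import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .likelihood import BernoulliFamily, penalty

__all__ = [
    "NullQuantileTable",
    "simulate_M",
    "simulate_finite_sample",
    "quantile",
    "get_quantile_table",
]

_DRAW_CHUNK = 64


@dataclass
class NullQuantileTable:
    """Sorted Monte-Carlo draws of the null statistic plus their provenance."""

    grid_size: int
    n_draws: int
    seed: int
    min_scale: float | None
    draws: np.ndarray
    kind: str = "brownian"
    params: dict = field(default_factory=dict)

    def __post_init__(self):
        self.draws = np.sort(np.asarray(self.draws, dtype=float))

    def key(self) -> str:
        payload = json.dumps(
            {
                "kind": self.kind,
                "grid_size": self.grid_size,
                "n_draws": self.n_draws,
                "seed": self.seed,
                "min_scale": self.min_scale,
                "params": self.params,
            },
            sort_keys=True,
        )
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


def simulate_M(grid_size: int = 512, n_draws: int = 5000, seed: int = 0,
               min_scale: float | None = None) -> NullQuantileTable:
    """Simulate M on a uniform grid of ``grid_size`` increments.

    Brownian motion is realised by cumulative sums of Gaussian increments;
    the penalised supremum runs over all grid intervals whose relative length
    is at least ``min_scale`` (every interval if None).  Deterministic under
    ``seed``.
    """
    if grid_size < 2:
        raise ValueError("grid_size must be >= 2")
    if n_draws < 1:
        raise ValueError("n_draws must be positive")
    N = grid_size
    min_gap = 1 if min_scale is None else max(1, int(np.ceil(min_scale * N - 1e-9)))
    if min_gap > N:
        raise ValueError("min_scale leaves no admissible interval")

    ii, jj = [], []
    for g in range(min_gap, N + 1):
        i = np.arange(0, N - g + 1)
        ii.append(i)
        jj.append(i + g)
    i_idx = np.concatenate(ii)
    j_idx = np.concatenate(jj)
    rel = (j_idx - i_idx) / N
    inv_sqrt = 1.0 / np.sqrt(rel)
    pen_term = np.sqrt(2.0 * (1.0 - np.log(rel)))  # sqrt(2 log(e / (t - s)))

    rng = np.random.default_rng(seed)
    draws = np.empty(n_draws)
    step = np.sqrt(1.0 / N)
    done = 0
    while done < n_draws:
        chunk = min(_DRAW_CHUNK, n_draws - done)
        incr = rng.standard_normal((chunk, N)) * step
        B = np.concatenate([np.zeros((chunk, 1)), np.cumsum(incr, axis=1)], axis=1)
        stat = np.abs(B[:, j_idx] - B[:, i_idx]) * inv_sqrt - pen_term
        draws[done: done + chunk] = stat.max(axis=1)
        done += chunk
    return NullQuantileTable(grid_size=N, n_draws=n_draws, seed=seed,
                             min_scale=min_scale, draws=draws, kind="brownian")


def simulate_finite_sample(n: int, n_draws: int = 5000, seed: int = 0,
                           min_segment: int = 2, p0: float = 0.5
                           ) -> NullQuantileTable:
    """Finite-sample null: T_n of the true constant signal under i.i.d.
    Bernoulli(p0) responses of length ``n``, intervals >= ``min_segment``."""
    if n < 2:
        raise ValueError("n must be >= 2")
    fam = BernoulliFamily()
    rng = np.random.default_rng(seed)
    lengths = np.arange(min_segment, n + 1)
    pen_terms = {int(m): np.sqrt(penalty(int(m), n)) for m in lengths}
    draws = np.empty(n_draws)
    for d in range(n_draws):
        y = rng.binomial(1, p0, size=n).astype(float)
        cum = np.r_[0.0, np.cumsum(y)]
        best = -np.inf
        for m in lengths:
            s = cum[m:] - cum[:-m]
            t = fam.lr(np.full(s.shape, float(m)), s, p0)
            best = max(best, float(np.max(np.sqrt(2 * t) - pen_terms[int(m)])))
        draws[d] = best
    return NullQuantileTable(grid_size=n, n_draws=n_draws, seed=seed,
                             min_scale=min_segment / n, draws=draws,
                             kind="bernoulli", params={"p0": p0, "n": n})


def quantile(table: NullQuantileTable, alpha: float) -> float:
    """The empirical (1 - alpha)-quantile q_{1-alpha} of the null draws.

    Uses the 'higher' interpolation so the threshold errs on the
    conservative (over-coverage) side.
    """
    if not 0.0 < alpha < 1.0:
        raise ValueError("alpha must lie strictly between 0 and 1")
    if table.draws.size == 0:
        raise ValueError("empty quantile table")
    return float(np.quantile(table.draws, 1.0 - alpha, method="higher"))


def get_quantile_table(grid_size: int = 512, n_draws: int = 5000, seed: int = 0,
                       min_scale: float | None = None,
                       cache_dir: str | Path | None = None,
                       refresh: bool = False) -> NullQuantileTable:
    """simulate_M with optional on-disk caching keyed by all parameters.

    The cache file is a small self-describing JSON (header + sorted draws);
    ``refresh=True`` forces regeneration.
    """
    probe = NullQuantileTable(grid_size=grid_size, n_draws=n_draws, seed=seed,
                              min_scale=min_scale, draws=np.empty(0))
    if cache_dir is not None:
        path = Path(cache_dir) / f"null-M-{probe.key()}.json"
        if path.exists() and not refresh:
            blob = json.loads(path.read_text())
            return NullQuantileTable(
                grid_size=blob["grid_size"], n_draws=blob["n_draws"],
                seed=blob["seed"], min_scale=blob["min_scale"],
                draws=np.asarray(blob["draws"]), kind=blob["kind"],
                params=blob.get("params", {}),
            )
    table = simulate_M(grid_size=grid_size, n_draws=n_draws, seed=seed,
                       min_scale=min_scale)
    if cache_dir is not None:
        Path(cache_dir).mkdir(parents=True, exist_ok=True)
        blob = {
            "kind": table.kind, "grid_size": table.grid_size,
            "n_draws": table.n_draws, "seed": table.seed,
            "min_scale": table.min_scale, "params": table.params,
            "draws": [float(x) for x in table.draws],
        }
        path.write_text(json.dumps(blob))
    return table
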