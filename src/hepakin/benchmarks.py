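"""Analytic benchmark functions for the population optimizers.

The usual trio: the convex sphere, the narrow-valley Rosenbrock and the
highly multimodal Rastrigin function, each with a known global minimum,
plus a small driver that runs GSA/DCGSA repeatedly and tabulates the
final fitness per repeat.
"""

from __future__ import annotations

from dataclasses import replace
from typing import Callable, Sequence

import numpy as np
import pandas as pd

from .optim import GsaConfig, SearchSpace, minimize

__all__ = ["sphere", "rosenbrock", "rastrigin", "BENCHMARKS", "run_benchmark"]


def sphere(x: np.ndarray) -> float:
    """Sum of squares; global minimum 0 at the origin."""
    x = np.asarray(x)
    return float(x @ x)


def rosenbrock(x: np.ndarray) -> float:
    """Banana valley; global minimum 0 at (1, ..., 1)."""
    x = np.asarray(x)
    return float(np.sum(100.0 * (x[1:] - x[:-1] ** 2) ** 2 + (1.0 - x[:-1]) ** 2))


def rastrigin(x: np.ndarray) -> float:
    """Cosine-rippled bowl; global minimum 0 at the origin."""
    x = np.asarray(x)
    return float(10.0 * x.size + np.sum(x**2 - 10.0 * np.cos(2.0 * np.pi * x)))


#: name -> (objective, default dimension, default symmetric bound)
BENCHMARKS: dict[str, tuple[Callable, int, float]] = {
    "sphere": (sphere, 5, 5.0),
    "rosenbrock": (rosenbrock, 2, 5.0),
    "rastrigin": (rastrigin, 5, 5.12),
}


def run_benchmark(
    functions: Sequence[str] = ("sphere", "rosenbrock", "rastrigin"),
    methods: Sequence[str] = ("gsa", "dcgsa"),
    repeats: int = 10,
    cfg: GsaConfig | None = None,
    seed: int = 0,
) -> pd.DataFrame:
    """Run each optimizer on each function ``repeats`` times.

    Returns one row per (function, method, repeat) with the final best
    fitness; repeat seeds are derived deterministically from ``seed``.
    """
    cfg = cfg or GsaConfig()
    rows = []
    for name in functions:
        fn, dim, bound = BENCHMARKS[name]
        space = SearchSpace(np.full(dim, -bound), np.full(dim, bound))
        for method in methods:
            for r in range(repeats):
                run_cfg = replace(cfg, variant=method, seed=(seed * 10007 + r) % 2**31)
                res = minimize(fn, space, run_cfg)
                rows.append(
                    {
                        "function": name,
                        "method": method,
                        "repeat": r,
                        "best_fitness": res.fun,
                        "n_iters": run_cfg.n_iters,
                        "n_particles": run_cfg.n_particles,
                    }
                )
    return pd.DataFrame(rows)
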