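"""Hyper-parameter grids for the benchmarked model families.

Candidate lists follow the benchmark protocol exactly: RFR searches the
minimum samples to split a node {2, 8, 16}, minimum samples per leaf
{1, 5, 10} and max features {sqrt, log2} with 500 trees and an MSE split
criterion; SVR searches only the cost C over {0.001, 0.01, 0.1, 1, 10, 100};
DNNs search learning rate {0.01, 0.001, 0.0001}, dropout {0.1, 0.25, 0.4},
batch size {64, 128}, 2-4 hidden layers with widths from
{100, 200, 1000, 2000} (restricted to non-increasing stacks, mirroring the
pyramid shape of the reference architecture) and batch normalization on/off.

Grids are plain lists of parameter dicts in a fixed enumeration order;
cross-validation ties are broken by that order.
"""

from __future__ import annotations

from itertools import combinations_with_replacement, product

import numpy as np

__all__ = [
    "rfr_grid",
    "svr_grid",
    "dnn_grid",
    "MT_DNN_REFERENCE",
    "subsample_grid",
]

#: Reference multi-task architecture: two hidden layers of 2000 and 1000
#: neurons, no batch normalization, batch size 128, dropout 0.1, lr 1e-4.
MT_DNN_REFERENCE: dict = {
    "hidden_layers": (2000, 1000),
    "batch_norm": False,
    "batch_size": 128,
    "dropout": 0.1,
    "learning_rate": 0.0001,
}


def rfr_grid() -> list[dict]:
    grid = []
    for mss, msl, mf in product([2, 8, 16], [1, 5, 10], ["sqrt", "log2"]):
        grid.append(
            {
                "min_samples_split": mss,
                "min_samples_leaf": msl,
                "max_features": mf,
                "n_estimators": 500,
                "criterion": "squared_error",
            }
        )
    return grid


def svr_grid() -> list[dict]:
    return [{"C": c} for c in (0.001, 0.01, 0.1, 1, 10, 100)]


def dnn_grid(
    width_choices: tuple[int, ...] = (100, 200, 1000, 2000),
    n_layers_choices: tuple[int, ...] = (2, 3, 4),
) -> list[dict]:
    """Full factorial DNN grid (2340 points at the default choices)."""
    widths_by_depth = {
        L: [
            tuple(sorted(ws, reverse=True))
            for ws in combinations_with_replacement(sorted(width_choices, reverse=True), L)
        ]
        for L in n_layers_choices
    }
    grid = []
    for lr, drop, bs, L in product(
        [0.01, 0.001, 0.0001], [0.1, 0.25, 0.4], [64, 128], n_layers_choices
    ):
        for widths in widths_by_depth[L]:
            for bn in (True, False):
                grid.append(
                    {
                        "learning_rate": lr,
                        "dropout": drop,
                        "batch_size": bs,
                        "hidden_layers": widths,
                        "batch_norm": bn,
                    }
                )
    return grid


def subsample_grid(grid: list[dict], max_candidates: int, seed: int = 0) -> list[dict]:
    """Budget-limited random subsample of a grid, preserving enumeration order."""
    if max_candidates >= len(grid):
        return list(grid)
    rng = np.random.default_rng(seed)
    idx = sorted(rng.choice(len(grid), size=max_candidates, replace=False))
    return [grid[i] for i in idx]
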