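"""Federated feature selection by averaged gradient-boosting gain importance.

Each client fits a LightGBM classifier on its own training split at library
default hyperparameters and reports per-feature total gain.  The server
averages importances across clients (unweighted), keeps only covariates
present (nonzero) in every client's training data, and ranks.  The number of
input features N is then chosen by walking an increasing grid, training the
federated model at each N, and applying two rules:

* **early stop** — abandon the search after 3 consecutive grid steps whose
  relative improvement of the weighted mean tuning AUC over the running best
  is at most 2%;
* **98%-of-best** — the chosen N is the smallest evaluated N whose AUC is at
  least 98% of the best AUC observed.

Both rules exist because local CPU training dominates cost: model size and
epoch time grow linearly in N while performance saturates early.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Mapping, Sequence

import lightgbm
import numpy as np

from .data_model import SiteDataset

__all__ = [
    "ImportanceVector",
    "SelectionTrace",
    "local_importance",
    "aggregate_importance",
    "search_top_n",
    "DEFAULT_GRID",
]

DEFAULT_GRID = (25, 50, 100, 200, 400, 800, 1600)

# map covariate_id -> nonnegative total gain; absent means 0
ImportanceVector = dict


@dataclass
class SelectionTrace:
    """Record of the top-N search."""

    grid: list[int]  # N values actually evaluated, in order
    auc: list[float]  # weighted mean tuning AUC per evaluated N
    stop_index: int  # index into grid of the last evaluated N
    chosen_n: int

    def __post_init__(self) -> None:
        if any(b <= a for a, b in zip(self.grid, self.grid[1:])):
            raise ValueError("grid must be strictly increasing")
        if self.chosen_n not in self.grid:
            raise ValueError("chosen_n must be an evaluated grid point")


def local_importance(client: SiteDataset, seed: int = 0) -> ImportanceVector:
    """Per-feature total gain from one client's boosted-tree model.

    LightGBM is trained on the client's *train* partition with every
    hyperparameter at its library default (only seeding and logging are
    pinned).  Features the booster never splits on get importance 0 and are
    omitted from the returned mapping.
    """
    X, y = client.partition("train")
    if len(np.unique(y)) < 2:
        raise ValueError(
            f"site {client.site_id}: training labels are single-class"
        )
    booster = lightgbm.train(
        {
            "objective": "binary",
            "verbosity": -1,
            "seed": seed,
            "deterministic": True,
            "force_row_wise": True,
        },
        lightgbm.Dataset(X.values.astype(np.float64), label=y),
    )
    gains = booster.feature_importance(importance_type="gain")
    return {
        str(cid): float(g)
        for cid, g in zip(X.covariates, gains)
        if g > 0
    }


def presence(client: SiteDataset) -> set:
    """Covariates with at least one nonzero entry in the client's train split."""
    X, _ = client.partition("train")
    nonzero = np.asarray((X.values != 0).sum(axis=0)).ravel() > 0
    return {str(c) for c, nz in zip(X.covariates, nonzero) if nz}


def aggregate_importance(
    vectors: Sequence[Mapping[str, float]],
    presences: Sequence[set],
) -> list[tuple[str, float]]:
    """Cross-client averaged ranking over the all-sites-present intersection.

    Score = unweighted mean of per-client gains (a feature missing from one
    client's model contributes 0 there).  Features absent from any client's
    data are excluded outright.  Ties break lexicographically on the
    covariate id for determinism.
    """
    if not vectors:
        raise ValueError("need at least one importance vector")
    if len(presences) != len(vectors):
        raise ValueError("one presence set per importance vector required")
    common = set.intersection(*[set(p) for p in presences])
    if not common:
        raise ValueError("no covariate is present in every client's data")
    n = len(vectors)
    scores = {
        cid: sum(float(v.get(cid, 0.0)) for v in vectors) / n for cid in common
    }
    return sorted(scores.items(), key=lambda kv: (-kv[1], kv[0]))


def search_top_n(
    grid: Sequence[int],
    fl_trainer: Callable[[int], Sequence[float]],
    weights: Sequence[float],
    rel_tol: float = 0.02,
    patience: int = 3,
    keep_fraction: float = 0.98,
) -> SelectionTrace:
    """Walk the N grid with early stopping and the 98%-of-best rule.

    ``fl_trainer(N)`` trains the federated model on the top-N features and
    returns per-client tuning AUCs; the search statistic is their weighted
    mean with ``weights`` = client tuning-set sizes.  The walk stops once
    ``patience`` consecutive steps each improve the running best by at most
    ``rel_tol`` (relative).  ``chosen_n`` is the smallest evaluated N whose
    AUC reaches ``keep_fraction`` of the best observed AUC.
    """
    grid = list(grid)
    if any(b <= a for a, b in zip(grid, grid[1:])):
        raise ValueError("grid must be strictly increasing")
    if not grid:
        raise ValueError("empty grid")
    w = np.asarray(weights, dtype=float)
    w = w / w.sum()

    evaluated: list[int] = []
    aucs: list[float] = []
    best = -np.inf
    stall = 0
    for n in grid:
        client_aucs = np.asarray(fl_trainer(n), dtype=float)
        auc = float(client_aucs @ w)
        evaluated.append(n)
        aucs.append(auc)
        if best > 0 and (auc - best) / best <= rel_tol:
            stall += 1
        elif auc <= best:  # covers best <= 0 edge
            stall += 1
        else:
            stall = 0
        best = max(best, auc)
        if stall >= patience:
            break
    threshold = keep_fraction * max(aucs)
    chosen = next(n for n, a in zip(evaluated, aucs) if a >= threshold)
    return SelectionTrace(evaluated, aucs, len(evaluated) - 1, chosen)
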