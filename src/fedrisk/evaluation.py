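"""Cross-site evaluation: AUC/Brier matrices, balanced bootstraps, Shapley.

Every trained model (federated + per-site local comparators) is scored on
every site's held-out test set, yielding a model x site metric matrix and
each model's unweighted mean AUC across sites — the headline comparison
statistic.  Because the outcome is rare, AUCs are additionally recomputed on
class-balanced bootstrap replicates (all cases kept, controls downsampled
without replacement to a fixed case:control ratio, 1000 replicates,
percentile 95% CI).  Model attributions use a Monte-Carlo permutation
Shapley estimator, which is model-agnostic and satisfies the efficiency
axiom up to Monte-Carlo error.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Callable, Mapping

import numpy as np
import pandas as pd
import sklearn.metrics

from .data_model import SiteDataset

__all__ = [
    "EvaluationMatrix",
    "BalancedEvalResult",
    "AttributionReport",
    "auc",
    "brier",
    "cross_site_evaluate",
    "balanced_bootstrap_auc",
    "shapley_attributions",
]

logger = logging.getLogger(__name__)


def auc(scores, labels) -> float:
    """Area under the ROC curve (Mann-Whitney; ties get half credit)."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("AUC undefined: only one class present")
    return float(sklearn.metrics.roc_auc_score(labels, np.asarray(scores, dtype=float)))


def brier(probs, labels) -> float:
    """Mean squared difference between predicted probability and outcome."""
    probs = np.asarray(probs, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probs.min() < 0 or probs.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    return float(np.mean((probs - labels) ** 2))


@dataclass
class EvaluationMatrix:
    """model x site table of {auc, brier, n, n_cases} plus mean AUC per model."""

    cells: pd.DataFrame  # MultiIndex (model, site) rows
    mean_auc: dict[str, float]  # unweighted across defined sites

    def cell(self, model: str, site: str) -> pd.Series:
        return self.cells.loc[(model, site)]


@dataclass
class BalancedEvalResult:
    ratio: int
    n_bootstrap: int
    mean_auc: float
    ci_lower: float
    ci_upper: float
    replicate_aucs: np.ndarray = field(repr=False)

    def __post_init__(self) -> None:
        if not self.ci_lower <= self.mean_auc <= self.ci_upper:
            raise ValueError("CI must bracket the mean")


@dataclass
class AttributionReport:
    """Per-instance Shapley values and the mean-|value| feature ranking."""

    feature_ids: list[str]
    values: np.ndarray  # (n_instances, n_features)
    base_value: float  # mean model output over the background
    instance_outputs: np.ndarray

    def ranking(self) -> list[tuple[str, float]]:
        mean_abs = np.abs(self.values).mean(axis=0)
        order = np.argsort(-mean_abs, kind="stable")
        return [(self.feature_ids[j], float(mean_abs[j])) for j in order]

    def to_frame(self) -> pd.DataFrame:
        """Long-format (instance, feature, value) export for beeswarm plotters."""
        n, k = self.values.shape
        return pd.DataFrame(
            {
                "instance": np.repeat(np.arange(n), k),
                "feature": np.tile(self.feature_ids, n),
                "value": self.values.ravel(),
            }
        )


def cross_site_evaluate(
    models: Mapping[str, Callable[[object], np.ndarray]],
    sites: list[SiteDataset],
    use_split: str = "test",
) -> EvaluationMatrix:
    """Score every model on every site; cells with one-class labels are NaN.

    ``models`` maps model name -> predictor taking a FeatureMatrix and
    returning probabilities (the predictor is responsible for projecting the
    site's columns onto its own feature list).  Development sites are scored
    on ``use_split`` (the held-out test split by default); pass
    ``use_split='all'`` for an external-validation site, whose every person
    is scored.  Single-class cells are excluded from the per-model mean AUC
    with a logged warning.
    """
    rows = []
    for name, predict in models.items():
        for site in sites:
            X, y = site.partition(use_split)
            p = np.asarray(predict(X), dtype=float)
            n, n_cases = len(y), int(y.sum())
            if len(np.unique(y)) < 2:
                logger.warning(
                    "site %s %s split has a single class; AUC undefined",
                    site.site_id,
                    use_split,
                )
                a = np.nan
            else:
                a = auc(p, y)
            rows.append(
                {
                    "model": name,
                    "site": site.site_id,
                    "auc": a,
                    "brier": brier(p, y),
                    "n": n,
                    "n_cases": n_cases,
                }
            )
    cells = pd.DataFrame(rows).set_index(["model", "site"])
    mean_auc = {
        name: float(cells.loc[name]["auc"].dropna().mean()) for name in models
    }
    return EvaluationMatrix(cells, mean_auc)


def balanced_bootstrap_auc(
    scores,
    labels,
    ratio: int,
    n_bootstrap: int = 1000,
    seed: int = 0,
) -> BalancedEvalResult:
    """AUC over class-balanced bootstrap replicates.

    Each replicate keeps every case and draws ``ratio * n_cases`` controls
    without replacement; the summary is the replicate mean and the
    percentile 2.5/97.5 interval.  Deterministic given ``seed``.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    case_idx = np.flatnonzero(labels == 1)
    ctrl_idx = np.flatnonzero(labels == 0)
    n_cases = len(case_idx)
    if n_cases < 1:
        raise ValueError("need at least one case")
    n_ctrl_draw = ratio * n_cases
    if len(ctrl_idx) < n_ctrl_draw:
        raise ValueError(
            f"need {n_ctrl_draw} controls for ratio 1:{ratio}, have {len(ctrl_idx)}"
        )
    rng = np.random.default_rng(seed)
    reps = np.empty(n_bootstrap)
    case_scores = scores[case_idx]
    for b in range(n_bootstrap):
        drawn = rng.choice(ctrl_idx, size=n_ctrl_draw, replace=False)
        s = np.concatenate([case_scores, scores[drawn]])
        y = np.concatenate([np.ones(n_cases), np.zeros(n_ctrl_draw)])
        reps[b] = auc(s, y)
    lo, hi = np.percentile(reps, [2.5, 97.5])
    return BalancedEvalResult(
        ratio, n_bootstrap, float(reps.mean()), float(lo), float(hi), reps
    )


def shapley_attributions(
    predict: Callable[[np.ndarray], np.ndarray],
    instances: np.ndarray,
    background: np.ndarray,
    feature_ids: list[str] | None = None,
    n_permutations: int = 64,
    seed: int = 0,
) -> AttributionReport:
    """Monte-Carlo permutation estimate of Shapley values of model output.

    For each instance and each sampled feature permutation, features are
    revealed one at a time (unrevealed features imputed from one sampled
    background row) and the marginal change in model output is credited to
    the revealed feature.  Averaging over permutations converges to the
    Shapley value; the efficiency identity
    ``sum_j phi_j = f(x) - E_background[f]`` holds up to Monte-Carlo error.
    """
    if n_permutations < 1:
        raise ValueError("n_permutations must be >= 1")
    instances = np.atleast_2d(np.asarray(instances, dtype=float))
    background = np.atleast_2d(np.asarray(background, dtype=float))
    if background.shape[0] == 0:
        raise ValueError("background must be nonempty")
    n, d = instances.shape
    if feature_ids is None:
        feature_ids = [f"f{j}" for j in range(d)]
    rng = np.random.default_rng(seed)
    values = np.zeros((n, d))
    for t in range(n_permutations):
        perm = rng.permutation(d)
        bg = background[rng.integers(background.shape[0], size=n)]
        current = bg.copy()
        prev_out = np.asarray(predict(current), dtype=float)
        for j in perm:
            current[:, j] = instances[:, j]
            out = np.asarray(predict(current), dtype=float)
            values[:, j] += out - prev_out
            prev_out = out
    values /= n_permutations
    base = float(np.mean(np.asarray(predict(background), dtype=float)))
    outs = np.asarray(predict(instances), dtype=float)
    return AttributionReport(list(feature_ids), values, base, outs)
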