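"""End-to-end workflow glue: simulate -> select -> train -> evaluate.

This module wires the stages together the way the study ran them:
per-client boosted-tree importances are aggregated and the input-feature
count N is searched with early stopping; a Deep & Cross Network is then
trained federatedly (and per-site locally as comparators) on the top-N
features with DP-SGD; finally all models are cross-site evaluated, the
external site is scored whole, and a baseline table is built.
"""

from __future__ import annotations

import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np

from .data_model import SiteDataset
from .dcn import DCNConfig, ModelParams, forward_proba
from .evaluation import auc, balanced_bootstrap_auc, cross_site_evaluate
from .federation import FederationConfig, train_federated, train_local
from .feature_selection import (
    DEFAULT_GRID,
    aggregate_importance,
    local_importance,
    presence,
    search_top_n,
)
from .privacy import PrivacySpec, compose_and_convert
from .synthetic_data import GeneratorConfig, generate_federation

__all__ = [
    "RunConfig",
    "subset_site",
    "make_predictor",
    "select_features",
    "train_all_models",
    "run_pipeline",
]

logger = logging.getLogger(__name__)


@dataclass
class RunConfig:
    """One document driving the whole workflow; one seed derives all stages."""

    generator: GeneratorConfig = field(default_factory=GeneratorConfig)
    federation: FederationConfig = field(default_factory=FederationConfig)
    grid: tuple[int, ...] = (25, 50, 100, 200)
    eval_ratios: tuple[int, ...] = (1, 3, 4, 9)
    n_bootstrap: int = 1000
    seed: int = 0

    def stage_seed(self, stage: str) -> int:
        ss = np.random.SeedSequence([self.seed, abs(hash(stage)) % (2**31)])
        return int(ss.generate_state(1)[0] % (2**31))


def subset_site(site: SiteDataset, feature_ids) -> SiteDataset:
    """Project one site onto an ordered feature list (absent columns -> 0)."""
    return SiteDataset(
        site.site_id, site.features.subset_columns(feature_ids), site.labels, site.split
    )


def make_predictor(params: ModelParams, feature_ids):
    """Closure scoring any site's FeatureMatrix through the model's features."""
    ids = list(feature_ids)

    def predict(fm):
        return forward_proba(params, fm.subset_columns(ids).values)

    return predict


def select_features(
    clients: list[SiteDataset],
    model_seed: int = 0,
) -> list[tuple[str, float]]:
    """Federated importance ranking (per-client LightGBM gain, averaged)."""
    vectors = [local_importance(c, seed=model_seed) for c in clients]
    presences = [presence(c) for c in clients]
    return aggregate_importance(vectors, presences)


def _tuning_aucs(
    params: ModelParams, clients: list[SiteDataset], feature_ids
) -> list[float]:
    out = []
    for c in clients:
        X, y = subset_site(c, feature_ids).partition("tune")
        if len(np.unique(y)) < 2:
            out.append(0.5)  # undefined; neutral contribution
        else:
            out.append(auc(forward_proba(params, X.values), y))
    return out


def search_n_features(
    clients: list[SiteDataset],
    ranking: list[tuple[str, float]],
    fed_config: FederationConfig,
    grid=DEFAULT_GRID,
):
    """Top-N search: trains the federated model at each grid N."""
    grid = [n for n in grid if n <= len(ranking)]
    if not grid:  # fewer shared features than the smallest N: use them all
        grid = [len(ranking)]
    weights = [int(np.sum(c.split == "tune")) for c in clients]

    def fl_trainer(n: int):
        ids = [cid for cid, _ in ranking[:n]]
        sub = [subset_site(c, ids) for c in clients]
        model_cfg = DCNConfig(input_dim=n, seed=fed_config.seed)
        params, _ = train_federated(sub, model_cfg, fed_config)
        return _tuning_aucs(params, clients, ids)

    return search_top_n(grid, fl_trainer, weights)


def train_all_models(
    clients: list[SiteDataset],
    feature_ids: list[str],
    fed_config: FederationConfig,
    local_epochs: int = 25,
):
    """Federated model + one 25-epoch local comparator per client."""
    sub = [subset_site(c, feature_ids) for c in clients]
    model_cfg = DCNConfig(input_dim=len(feature_ids), seed=fed_config.seed)
    fed_params, records = train_federated(sub, model_cfg, fed_config)
    models = {"federated": make_predictor(fed_params, feature_ids)}
    raw = {"federated": fed_params}
    for c in sub:
        p, _ = train_local(c, model_cfg, fed_config, epochs=local_epochs)
        models[f"local_{c.site_id}"] = make_predictor(p, feature_ids)
        raw[f"local_{c.site_id}"] = p
    return models, raw, records


def client_privacy_budgets(
    clients: list[SiteDataset], fed_config: FederationConfig, total_epochs: int
) -> dict[str, dict]:
    """Composed (epsilon, alpha*) per client under its own q and T."""
    out = {}
    for c in clients:
        n_train = int(np.sum(c.split == "train"))
        steps_per_epoch = int(np.ceil(n_train / fed_config.batch_size))
        q = min(1.0, fed_config.batch_size / n_train)
        spec = PrivacySpec(
            noise_multiplier=fed_config.privacy.noise_multiplier,
            clip_norm=fed_config.privacy.clip_norm,
            sample_rate=q,
            steps=total_epochs * steps_per_epoch,
            delta=fed_config.privacy.delta,
        )
        b = compose_and_convert(spec)
        out[c.site_id] = {
            "epsilon": b.epsilon,
            "delta": b.delta,
            "alpha_star": b.alpha_star,
            "q": q,
            "steps": spec.steps,
        }
    return out


def run_pipeline(config: RunConfig, out_dir) -> dict:
    """Execute the full workflow and write a JSON manifest + metrics.

    Stages: simulate -> feature selection (ranking + top-N search) ->
    federated + local training at the chosen N -> internal cross-site and
    external evaluation (with balanced bootstraps) -> per-client privacy
    budgets.  Deterministic given ``config.seed``; partial outputs are
    retained if a stage fails.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"seed": config.seed, "stages": {}}

    def stage(name):
        def deco(fn):
            t0 = time.time()
            try:
                result = fn()
            except Exception as e:
                manifest["stages"][name] = {"status": "failed", "error": str(e)}
                (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
                raise RuntimeError(f"stage {name!r} failed: {e}") from e
            manifest["stages"][name] = {
                "status": "ok",
                "seconds": round(time.time() - t0, 2),
            }
            logger.info("stage %s done in %.1fs", name, time.time() - t0)
            return result

        return deco

    gen_cfg = config.generator
    gen_cfg.seed = config.stage_seed("simulate")

    fed_data_truth = stage("simulate")(lambda: generate_federation(gen_cfg))
    fed_data, truth = fed_data_truth
    clients = fed_data.clients

    ranking = stage("select_features")(
        lambda: select_features(clients, model_seed=config.stage_seed("importance"))
    )

    fed_config = config.federation
    fed_config.seed = config.stage_seed("train")
    trace = stage("search_top_n")(
        lambda: search_n_features(clients, ranking, fed_config, config.grid)
    )
    feature_ids = [cid for cid, _ in ranking[: trace.chosen_n]]

    models_raw_records = stage("train")(
        lambda: train_all_models(clients, feature_ids, fed_config)
    )
    models, raw, records = models_raw_records

    internal = stage("evaluate_internal")(
        lambda: cross_site_evaluate(models, clients, use_split="test")
    )
    results: dict = {
        "chosen_n": trace.chosen_n,
        "selection_trace": {"grid": trace.grid, "auc": trace.auc},
        "round_losses": [r.aggregated_loss for r in records],
        "internal_mean_auc": internal.mean_auc,
        "internal_cells": internal.cells.reset_index().to_dict(orient="records"),
    }
    if fed_data.external is not None:
        external = stage("evaluate_external")(
            lambda: cross_site_evaluate(models, [fed_data.external], use_split="all")
        )
        results["external_mean_auc"] = external.mean_auc
        X, y = fed_data.external.partition("all")
        p = models["federated"](X)
        balanced = {}
        for r in config.eval_ratios:
            try:
                res = balanced_bootstrap_auc(
                    p, y, r, config.n_bootstrap, seed=config.stage_seed(f"boot{r}")
                )
                balanced[str(r)] = {
                    "mean_auc": res.mean_auc,
                    "ci": [res.ci_lower, res.ci_upper],
                }
            except ValueError as e:
                balanced[str(r)] = {"error": str(e)}
        results["external_balanced"] = balanced

    total_epochs = fed_config.rounds * fed_config.local_epochs
    results["privacy"] = client_privacy_budgets(clients, fed_config, total_epochs)
    results["true_informative"] = truth.informative_ids

    (out_dir / "results.json").write_text(json.dumps(results, indent=1))
    (out_dir / "manifest.json").write_text(json.dumps(manifest, indent=1))
    return results
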