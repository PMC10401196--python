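"""Simulated federated averaging with DP-SGD local updates.

The federation is simulated in-process with a sequential client loop; all
weight-flow semantics of the real deployment are preserved (broadcast global
weights, local DP-SGD epochs, size-weighted averaging), only the transport
is absent.  Defaults follow the study protocol: 5 rounds x 5 local epochs
for the federated model, and a 25-epoch local-only comparator per client.
The final federated model is the round snapshot with the lowest aggregated
tuning loss (size-weighted across clients); the local comparator keeps the
epoch snapshot with the lowest tuning loss.  Ties break to the earliest
round/epoch.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .data_model import SiteDataset
from .dcn import DCNConfig, ModelParams, bce_loss, forward_proba, init_params
from .privacy import PrivacySpec, dp_sgd_step

__all__ = [
    "FederationConfig",
    "RoundRecord",
    "local_update",
    "fedavg_aggregate",
    "train_federated",
    "train_local",
]


@dataclass
class FederationConfig:
    """Federated-training hyperparameters (5 rounds x 5 epochs by default)."""

    rounds: int = 5
    local_epochs: int = 5
    batch_size: int = 256
    lr: float = 1e-3
    lr_decay: float = 0.0  # inverse-time decay per global epoch: lr/(1+decay*t)
    privacy: PrivacySpec = field(default_factory=PrivacySpec)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rounds < 1:
            raise ValueError("rounds must be >= 1")
        if self.local_epochs < 0:
            raise ValueError("local_epochs must be >= 0")
        if self.batch_size < 1:
            raise ValueError("batch_size must be >= 1")


@dataclass
class RoundRecord:
    round_index: int
    client_losses: dict[str, float]
    client_tune_sizes: dict[str, int]
    aggregated_loss: float
    params: ModelParams


def _dense(X) -> np.ndarray:
    return X.toarray() if hasattr(X, "toarray") else np.asarray(X, dtype=float)


def _sgd_epochs(
    params: ModelParams,
    X: np.ndarray,
    y: np.ndarray,
    config: FederationConfig,
    epochs: int,
    rng: np.random.Generator,
    epoch_offset: int = 0,
) -> ModelParams:
    """``epochs`` passes of (DP-)SGD over shuffled minibatches.

    The learning rate follows an inverse-time schedule on the *global*
    epoch index (``epoch_offset`` carries the count from earlier rounds),
    so federated rounds and the local comparator share one schedule.
    """
    spec = config.privacy
    clip = spec.clip_norm if np.isfinite(spec.clip_norm) else np.inf
    n = X.shape[0]
    p = params
    for e in range(epochs):
        lr = config.lr / (1.0 + config.lr_decay * (epoch_offset + e))
        order = rng.permutation(n)
        for start in range(0, n, config.batch_size):
            idx = order[start : start + config.batch_size]
            p = dp_sgd_step(
                p, X[idx], y[idx], clip, spec.noise_multiplier, lr, rng
            )
    return p


def local_update(
    global_params: ModelParams,
    client: SiteDataset,
    config: FederationConfig,
    seed: int,
    epoch_offset: int = 0,
) -> tuple[ModelParams, int, float]:
    """One client's contribution to a round.

    Runs ``config.local_epochs`` epochs of DP-SGD from the broadcast global
    weights on the client's train split; returns the updated weights, the
    train-split size n_k (the FedAvg weight), and the tuning-split BCE loss
    of the *updated* weights.  Single-class training labels are tolerated
    with a warning (the loss is still well defined).
    """
    Xtr_fm, ytr = client.partition("train")
    if Xtr_fm.shape[0] == 0:
        raise ValueError(f"site {client.site_id}: empty train partition")
    if len(np.unique(ytr)) < 2:
        import warnings

        warnings.warn(
            f"site {client.site_id}: single-class training labels", stacklevel=2
        )
    Xtr = _dense(Xtr_fm.values)
    rng = np.random.default_rng(seed)
    updated = _sgd_epochs(
        global_params, Xtr, ytr, config, config.local_epochs, rng, epoch_offset
    )
    Xtu_fm, ytu = client.partition("tune")
    loss = bce_loss(forward_proba(updated, Xtu_fm.values), ytu)
    return updated, Xtr.shape[0], loss


def fedavg_aggregate(updates: list[tuple[ModelParams, int]]) -> ModelParams:
    """Federated averaging: coordinate-wise sample-size-weighted mean."""
    if not updates:
        raise ValueError("need at least one update")
    config = updates[0][0].config
    vecs = []
    ns = []
    for params, n_k in updates:
        v = params.flatten()
        if v.size != updates[0][0].flatten().size or params.config != config:
            raise ValueError("non-conformant parameter shapes")
        vecs.append(v)
        ns.append(float(n_k))
    w = np.asarray(ns) / np.sum(ns)
    avg = np.einsum("k,kp->p", w, np.stack(vecs))
    return ModelParams.unflatten(config, avg)


def train_federated(
    clients: list[SiteDataset],
    model_config: DCNConfig,
    config: FederationConfig,
) -> tuple[ModelParams, list[RoundRecord]]:
    """Run R rounds of broadcast -> local DP-SGD -> FedAvg; keep best round.

    Per round the tuning losses are aggregated with tune-set-size weights;
    the returned model is the round snapshot minimizing that aggregated
    loss (earliest round on ties).
    """
    if len(clients) < 1:
        raise ValueError("need at least one client")
    global_params = init_params(model_config)
    seed_seq = np.random.SeedSequence(config.seed)
    records: list[RoundRecord] = []
    for r in range(config.rounds):
        round_seeds = seed_seq.spawn(len(clients))
        updates: list[tuple[ModelParams, int]] = []
        losses: dict[str, float] = {}
        tune_sizes: dict[str, int] = {}
        for client, cs in zip(clients, round_seeds):
            try:
                upd, n_k, loss = local_update(
                    global_params,
                    client,
                    config,
                    seed=int(cs.generate_state(1)[0] % (2**31)),
                    epoch_offset=r * config.local_epochs,
                )
            except ValueError as e:
                raise ValueError(f"round {r}, client {client.site_id}: {e}") from e
            updates.append((upd, n_k))
            losses[client.site_id] = loss
            tune_sizes[client.site_id] = int(np.sum(client.split == "tune"))
        global_params = fedavg_aggregate(updates)
        # the aggregated model's tuning loss per client, size-weighted
        agg_losses = {}
        for client in clients:
            Xtu, ytu = client.partition("tune")
            agg_losses[client.site_id] = bce_loss(
                forward_proba(global_params, Xtu.values), ytu
            )
        wts = np.asarray([tune_sizes[c.site_id] for c in clients], dtype=float)
        wts = wts / wts.sum()
        agg = float(
            np.dot(wts, [agg_losses[c.site_id] for c in clients])
        )
        records.append(
            RoundRecord(r, agg_losses, tune_sizes, agg, global_params.copy())
        )
    best = select_best_round(records)
    return best.params, records


def select_best_round(records: list[RoundRecord]) -> RoundRecord:
    """Round snapshot with minimum aggregated tuning loss; earliest on ties."""
    if not records:
        raise ValueError("no rounds recorded")
    return min(records, key=lambda rec: (rec.aggregated_loss, rec.round_index))


def train_local(
    client: SiteDataset,
    model_config: DCNConfig,
    config: FederationConfig,
    epochs: int = 25,
) -> tuple[ModelParams, list[float]]:
    """Local-only comparator: DP-SGD for ``epochs`` epochs on one client.

    The tuning loss is recorded after every epoch and the epoch snapshot
    with the lowest loss is returned (earliest on ties), alongside the
    full loss trace.
    """
    Xtr_fm, ytr = client.partition("train")
    Xtu_fm, ytu = client.partition("tune")
    if Xtr_fm.shape[0] == 0 or Xtu_fm.shape[0] == 0:
        raise ValueError(f"site {client.site_id}: empty train or tune partition")
    Xtr = _dense(Xtr_fm.values)
    rng = np.random.default_rng(config.seed)
    params = init_params(model_config)
    best_params, best_loss = params.copy(), np.inf
    trace: list[float] = []
    for e in range(epochs):
        params = _sgd_epochs(params, Xtr, ytr, config, 1, rng, epoch_offset=e)
        loss = bce_loss(forward_proba(params, Xtu_fm.values), ytu)
        trace.append(loss)
        if loss < best_loss:
            best_loss, best_params = loss, params.copy()
    return best_params, trace
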