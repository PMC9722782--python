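"""Federated rounds: broadcast, local epochs, weighted FedAvg, validation.

One *federated round* is: the consensus model is broadcast to every
training site; each site trains it on its local training split for one
epoch (one optimizer step per case); the resulting model states are
combined by federated averaging weighted by each site's training-split
case count; the new consensus is then evaluated against every site's
local validation split and the round is recorded.

Randomness is governed by a single federation seed: the per-site,
per-round generator is derived by a stable hash of ``(seed, site_id,
round)``, so results are independent of site iteration order, and a run
can be resumed from any checkpoint bit-exactly by re-deriving the same
streams. Per-site Adam moment estimates persist locally across rounds and
are never aggregated (a reset-per-round flag is available).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .metrics import evaluate_case
from .model import (
    AdamState,
    ModelConfig,
    ModelParams,
    ResUNet3D,
    init_model,
    train_local_epoch,
)
from .phantom import FederationDataset, stable_seed
from .preprocess import AugmentConfig, crop_zero_planes, zscore_nonzero

__all__ = [
    "FederationConfig", "RoundRecord", "FederationRun",
    "fedavg", "preprocess_case", "prepare_dataset",
    "run_round", "run_federation", "train_centralized", "plateau_reached",
    "history_to_frame", "per_case_frame",
]

REGION_COLS = ("dsc_et", "dsc_tc", "dsc_wt")


@dataclass
class FederationConfig:
    max_rounds: int = 10
    plateau_window: int | None = None  # rounds; None disables plateau stopping
    plateau_epsilon: float = 0.0
    seed: int = 0
    checkpoint_every: int = 1
    reset_optimizer_each_round: bool = False

    def __post_init__(self) -> None:
        if self.max_rounds < 1:
            raise ValueError("max_rounds must be >= 1")
        if self.plateau_epsilon < 0:
            raise ValueError("plateau_epsilon must be >= 0")


@dataclass
class RoundRecord:
    """Validation summary of one round's consensus model."""

    round: int
    site_means: dict  # site_id -> {dsc_et, dsc_tc, dsc_wt, n_val}
    site_losses: dict  # site_id -> mean training loss
    pooled_region: dict  # region col -> mean across all cases of all sites
    pooled_collective: float  # per-case 3-region mean, then across cases
    per_case: pd.DataFrame  # case, site, dsc_et, dsc_tc, dsc_wt


@dataclass
class FederationRun:
    history: list
    checkpoints: dict  # round -> ModelParams
    final_params: ModelParams
    opt_states: dict  # site_id -> AdamState
    stopped_by_plateau: bool = False


def fedavg(updates) -> ModelParams:
    """Weighted elementwise mean of model states: Σ wᵢ·paramᵢ / Σ wᵢ.

    Scale-free in the weights; all states must share a config fingerprint
    and identical parameter names/shapes.
    """
    updates = list(updates)
    if not updates:
        raise ValueError("fedavg needs at least one update")
    weights = np.array([float(w) for _, w in updates], dtype=np.float64)
    if np.any(weights <= 0):
        raise ValueError("aggregation weights must be positive")
    ref, _ = updates[0]
    for other, _ in updates[1:]:
        ref.check_aggregable(other)
    wn = weights / weights.sum()
    out = {}
    for name, arr in ref.arrays.items():
        acc = np.zeros(arr.shape, dtype=np.float64)
        for (p, _), w in zip(updates, wn):
            acc += w * p.arrays[name].astype(np.float64)
        out[name] = acc.astype(arr.dtype)
    return ModelParams(out, ref.fingerprint)


def preprocess_case(case):
    """Crop all-zero border planes and z-score non-zero intensities, once."""
    img, lbl, _ = crop_zero_planes(case.image, case.labels)
    return replace(case, image=zscore_nonzero(img).astype(np.float32), labels=lbl)


def prepare_dataset(dataset: FederationDataset) -> FederationDataset:
    """Preprocessed copy of a federation; splits are preserved as-is."""
    sites = []
    for s in dataset.sites:
        sites.append(replace(s, cases=[preprocess_case(c) for c in s.cases]))
    return FederationDataset(sites=sites)


def _evaluate_consensus(params: ModelParams, model_cfg: ModelConfig,
                        dataset: FederationDataset, round_idx: int):
    model = ResUNet3D(model_cfg, params)
    rows, site_means = [], {}
    for site in dataset.training_sites:
        scores = []
        for case in site.val_cases:
            s = evaluate_case(model.predict_volume, case)
            scores.append(s.as_tuple())
            rows.append((case.case_id, site.site_id, round_idx) + s.as_tuple())
        arr = np.array(scores, dtype=float)
        site_means[site.site_id] = {
            "dsc_et": arr[:, 0].mean(), "dsc_tc": arr[:, 1].mean(),
            "dsc_wt": arr[:, 2].mean(), "n_val": len(scores),
        }
    per_case = pd.DataFrame(rows, columns=["case", "site", "round", *REGION_COLS])
    pooled_region = {c: float(per_case[c].mean()) for c in REGION_COLS}
    collective = float(per_case[list(REGION_COLS)].mean(axis=1).mean())
    return per_case, site_means, pooled_region, collective


def run_round(
    consensus: ModelParams,
    dataset: FederationDataset,
    round_idx: int,
    fed_cfg: FederationConfig,
    model_cfg: ModelConfig,
    aug_cfg: AugmentConfig,
    opt_states: dict,
) -> tuple[ModelParams, RoundRecord]:
    """One federated round; aborts whole if any site fails (no partial avg)."""
    updates, site_losses = [], {}
    for site in dataset.training_sites:
        if not site.train_ids:
            raise ValueError(f"site {site.site_id} has no training cases")
        local = ResUNet3D(model_cfg, consensus.copy())
        if site.site_id not in opt_states or fed_cfg.reset_optimizer_each_round:
            opt_states[site.site_id] = AdamState.for_params(local.params)
        rng = np.random.default_rng(stable_seed(fed_cfg.seed, "train", site.site_id, round_idx))
        try:
            loss = train_local_epoch(local, opt_states[site.site_id],
                                     site.train_cases, aug_cfg, rng)
        except Exception as exc:
            raise RuntimeError(f"round {round_idx} aborted: site {site.site_id} failed") from exc
        site_losses[site.site_id] = loss
        updates.append((local.params, len(site.train_ids)))
    new_consensus = fedavg(updates)
    per_case, site_means, pooled_region, collective = _evaluate_consensus(
        new_consensus, model_cfg, dataset, round_idx
    )
    record = RoundRecord(
        round=round_idx, site_means=site_means, site_losses=site_losses,
        pooled_region=pooled_region, pooled_collective=collective, per_case=per_case,
    )
    return new_consensus, record


def plateau_reached(history, window: int, epsilon: float) -> bool:
    """True iff the best pooled collective score of the last ``window``
    rounds improves on the best before them by less than ``epsilon``."""
    if not history:
        raise ValueError("history is empty")
    scores = [r.pooled_collective for r in history]
    if len(scores) <= window:
        return False
    return max(scores[-window:]) - max(scores[:-window]) < epsilon


def run_federation(
    fed_cfg: FederationConfig,
    model_cfg: ModelConfig,
    aug_cfg: AugmentConfig,
    dataset: FederationDataset,
    initial_params: ModelParams | None = None,
    start_round: int = 0,
    opt_states: dict | None = None,
) -> FederationRun:
    """Run rounds until max_rounds or plateau, checkpointing every consensus.

    ``initial_params`` stands in for the pre-trained public initial model;
    omitted, a fresh seeded initialization is used. Resuming: pass the
    stored consensus, ``start_round`` and the returned optimizer states —
    per-round streams are re-derived from the seed, so the continuation is
    bit-exact.
    """
    consensus = init_model(model_cfg) if initial_params is None else initial_params.copy()
    opt_states = {} if opt_states is None else opt_states
    history, checkpoints = [], {}
    stopped = False
    for round_idx in range(start_round, fed_cfg.max_rounds):
        consensus, record = run_round(
            consensus, dataset, round_idx, fed_cfg, model_cfg, aug_cfg, opt_states
        )
        history.append(record)
        if round_idx % fed_cfg.checkpoint_every == 0 or round_idx == fed_cfg.max_rounds - 1:
            checkpoints[round_idx] = consensus.copy()
        if fed_cfg.plateau_window is not None and plateau_reached(
            history, fed_cfg.plateau_window, fed_cfg.plateau_epsilon
        ):
            stopped = True
            break
    return FederationRun(history=history, checkpoints=checkpoints,
                         final_params=consensus, opt_states=opt_states,
                         stopped_by_plateau=stopped)


def train_centralized(
    initial_params: ModelParams,
    model_cfg: ModelConfig,
    aug_cfg: AugmentConfig,
    cases,
    n_epochs: int,
    seed: int,
    site_label: str = "pooled",
    start_epoch: int = 0,
) -> tuple[ModelParams, list]:
    """Plain (non-federated) training on pooled cases, one epoch per 'round'.

    Uses the same per-epoch stream derivation as a federation whose single
    site is named ``site_label`` — a one-site federation and this loop are
    the same algorithm, which the degenerate-equivalence test verifies
    bit-exactly.
    """
    model = ResUNet3D(model_cfg, initial_params.copy())
    opt = AdamState.for_params(model.params)
    losses = []
    for epoch in range(start_epoch, start_epoch + n_epochs):
        rng = np.random.default_rng(stable_seed(seed, "train", site_label, epoch))
        losses.append(train_local_epoch(model, opt, cases, aug_cfg, rng))
    return model.params, losses


def history_to_frame(history) -> pd.DataFrame:
    """Long-form round curves: one row per round × site plus a pooled row."""
    rows = []
    for rec in history:
        for site_id, m in rec.site_means.items():
            rows.append({
                "round": rec.round, "site": site_id,
                **{c: m[c] for c in REGION_COLS},
                "collective": float(np.mean([m[c] for c in REGION_COLS])),
                "n_val": m["n_val"],
                "train_loss": rec.site_losses.get(site_id, np.nan),
            })
        rows.append({
            "round": rec.round, "site": "pooled",
            **rec.pooled_region,
            "collective": rec.pooled_collective,
            "n_val": int(len(rec.per_case)),
            "train_loss": float(np.mean(list(rec.site_losses.values()))),
        })
    return pd.DataFrame(rows)


def per_case_frame(history) -> pd.DataFrame:
    """Concatenated per-case validation scores across rounds."""
    return pd.concat([r.per_case for r in history], ignore_index=True)
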