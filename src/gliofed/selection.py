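"""Singlet/triplet consensus-model selection and multi-model inference.

After a federation finishes, every round's consensus model is a
candidate. A *singlet* is the single round whose collective validation
score (mean DSC across the three sub-compartments per case, then across
all cases of all sites) ranks highest. A *triplet* is three rounds — one
specialist per region, each ranked by that region's pooled validation
DSC — whose outputs are assembled region-wise at inference (three times
the inference cost of a singlet). Ensembles of arbitrary model sets
average sigmoid outputs voxelwise before thresholding.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .federation import REGION_COLS
from .labels import RegionChannels
from .metrics import binarize

__all__ = ["SelectionResult", "score_rounds", "select_models", "predict"]


@dataclass
class SelectionResult:
    """Top-k singlet rounds and top-k (ET, TC, WT) specialist triples."""

    singlets: list  # k round indices, best first
    triplets: list  # k tuples (round_et, round_tc, round_wt)


def score_rounds(history) -> pd.DataFrame:
    """Per-round validation aggregates from federation history.

    Recomputed from the per-case scores (not the stored site means):
    collective = mean over all cases of the per-case 3-region mean;
    per-region = mean over all cases of that region's DSC. Pooling is at
    case level, so the result is invariant to how cases are partitioned
    into sites.
    """
    if not history:
        raise ValueError("history is empty")
    rows = []
    for rec in history:
        pc = rec.per_case
        rows.append({
            "round": rec.round,
            "collective": float(pc[list(REGION_COLS)].mean(axis=1).mean()),
            **{c: float(pc[c].mean()) for c in REGION_COLS},
        })
    return pd.DataFrame(rows).sort_values("round", ignore_index=True)


def _top_k(frame: pd.DataFrame, col: str, k: int) -> list:
    # stable sort: ties break toward the earlier round
    ordered = frame.sort_values(["round"]).sort_values(col, ascending=False, kind="stable")
    return ordered["round"].head(k).tolist()


def select_models(history, k: int = 5) -> SelectionResult:
    """Top-k rounds by collective score, and per-region top-k specialists."""
    if k < 1:
        raise ValueError("k must be >= 1")
    if k > len(history):
        raise ValueError(f"k={k} exceeds history length {len(history)}")
    scores = score_rounds(history)
    singlets = _top_k(scores, "collective", k)
    per_region = [_top_k(scores, c, k) for c in REGION_COLS]
    triplets = [tuple(per_region[r][i] for r in range(3)) for i in range(k)]
    return SelectionResult(singlets=singlets, triplets=triplets)


def predict(models, image: np.ndarray, mode: str, threshold: float = 0.5) -> RegionChannels:
    """Inference with a singlet (1 model), triplet (3 specialists in ET, TC,
    WT order) or ensemble (n models, voxelwise sigmoid mean).

    ``models`` expose ``predict_volume``; output is binarized region
    channels. Triplet outputs are assembled from each specialist's own
    region channel, then binarized.
    """
    models = list(models)
    if mode == "singlet":
        if len(models) != 1:
            raise ValueError(f"singlet mode needs exactly 1 model, got {len(models)}")
        sig = models[0].predict_volume(image)
    elif mode == "triplet":
        if len(models) != 3:
            raise ValueError(f"triplet mode needs exactly 3 models, got {len(models)}")
        outs = [m.predict_volume(image).channels for m in models]
        sig = RegionChannels(np.stack([outs[r][r] for r in range(3)]), kind="sigmoid")
    elif mode == "ensemble":
        if not models:
            raise ValueError("ensemble mode needs at least 1 model")
        acc = None
        for m in models:
            out = m.predict_volume(image).channels.astype(np.float64)
            acc = out if acc is None else acc + out
        sig = RegionChannels(acc / len(models), kind="sigmoid")
    else:
        raise ValueError(f"unknown mode {mode!r}")
    return binarize(sig, threshold)
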