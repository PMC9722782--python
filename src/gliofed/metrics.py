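"""Dice similarity, the mirrored-complement training loss, and thresholding.

The generalized DSC between a reference mask RL and a prediction PM
(binary or soft) is

    DSC = 2 |RL ⊙ PM|₁ / (|RL|₁ + |PM|₁)

with ⊙ the componentwise product and |·|₁ the sum of absolute values.
The training loss mirrors each region onto its complement — the DSC of
(1 − ref) against (1 − pred) — which weights small structures (ET) far
more heavily than the region itself would, and averages the three
per-region terms without penalties.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .labels import REGION_NAMES, RegionChannels, derive_region_channels

__all__ = [
    "RegionScores",
    "generalized_dsc",
    "binarize",
    "mirrored_dsc_loss",
    "jsc_from_dsc",
    "evaluate_case",
]


@dataclass
class RegionScores:
    """Per-case DSC for the three sub-compartments."""

    dsc_et: float
    dsc_tc: float
    dsc_wt: float
    case_id: str = ""

    def as_tuple(self) -> tuple[float, float, float]:
        return (self.dsc_et, self.dsc_tc, self.dsc_wt)

    @property
    def collective(self) -> float:
        """Mean over the three regions (the per-case collective score)."""
        return float(np.mean(self.as_tuple()))


def generalized_dsc(rl: np.ndarray, pm: np.ndarray) -> float:
    """Generalized Dice similarity between reference and prediction.

    Accepts binary masks or soft values in [0, 1]. When both inputs are
    empty the score is defined as 1.0 (perfect agreement on absence, the
    community convention); empty reference vs nonempty prediction is 0.
    """
    rl = np.asarray(rl, dtype=np.float64)
    pm = np.asarray(pm, dtype=np.float64)
    if rl.shape != pm.shape:
        raise ValueError(f"shape mismatch: reference {rl.shape} vs prediction {pm.shape}")
    denom = np.abs(rl).sum() + np.abs(pm).sum()
    if denom == 0.0:
        return 1.0
    return float(2.0 * np.abs(rl * pm).sum() / denom)


def binarize(rc: RegionChannels, threshold: float = 0.5) -> RegionChannels:
    """Threshold sigmoid channels to hard masks (strictly greater than).

    Nesting is *not* enforced here; decoding to a label map does that.
    """
    if rc.kind != "sigmoid":
        raise ValueError("binarize expects sigmoid-kind channels")
    if not (0.0 < threshold < 1.0):
        raise ValueError(f"threshold must lie in (0, 1), got {threshold}")
    return RegionChannels((rc.channels > threshold).astype(np.uint8), kind="binary")


def mirrored_dsc_loss(
    ref: RegionChannels, pred: RegionChannels, include_region_term: bool = False
) -> float:
    """Mean over regions of 1 − DSC(1 − ref, 1 − pred), soft prediction values.

    ``include_region_term`` averages in the un-mirrored DSC of each region
    as well (for comparison runs); the default is the complement alone.
    """
    if ref.channels.shape != pred.channels.shape:
        raise ValueError(
            f"shape mismatch: reference {ref.channels.shape} vs prediction {pred.channels.shape}"
        )
    total = 0.0
    for c in range(3):
        r = np.asarray(ref.channels[c], dtype=np.float64)
        p = np.asarray(pred.channels[c], dtype=np.float64)
        term = 1.0 - generalized_dsc(1.0 - r, 1.0 - p)
        if include_region_term:
            term = 0.5 * (term + 1.0 - generalized_dsc(r, p))
        total += term
    return total / 3.0


def jsc_from_dsc(dsc: float) -> float:
    """Jaccard similarity from a Dice score: jsc = dsc / (2 − dsc)."""
    return dsc / (2.0 - dsc)


def evaluate_case(predict_fn, case, threshold: float = 0.5) -> RegionScores:
    """Whole-volume inference followed by per-region DSC against the reference.

    ``predict_fn`` maps a ``(4, D, H, W)`` image to sigmoid-kind
    :class:`RegionChannels`; ``case`` carries ``image``, ``labels`` (a
    LabelMap) and ``case_id``.
    """
    ref = derive_region_channels(case.labels)
    try:
        pred = predict_fn(case.image)
    except Exception as exc:  # noqa: BLE001 - annotate with the case id
        raise RuntimeError(f"inference failed on case {case.case_id!r}") from exc
    if pred.kind == "sigmoid":
        pred = binarize(pred, threshold)
    scores = [generalized_dsc(ref.channels[c], pred.channels[c]) for c in range(3)]
    return RegionScores(*scores, case_id=case.case_id)


def scores_frame_columns() -> list[str]:
    """Column order used by per-case score CSVs."""
    return ["case", "site", "round"] + [f"dsc_{n.lower()}" for n in REGION_NAMES]
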