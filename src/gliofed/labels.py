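"""BraTS-convention label maps and the three nested tumor sub-compartments.

The annotation convention encodes, per voxel, one of four codes:

* ``0`` — background / healthy tissue,
* ``1`` — necrotic tumor core (NCR),
* ``2`` — peritumoral edematous / infiltrated tissue (ED),
* ``4`` — Gd-enhancing tumor (ET).

The network does not predict these codes directly; it predicts three
*overlapping* regions whose clinical relevance drives evaluation:

* ET — enhancing tumor, label 4,
* TC — tumor core, ET plus NCR (labels 1 and 4),
* WT — whole tumor, TC plus ED (labels 1, 2 and 4),

with the containment ET ⊆ TC ⊆ WT holding by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

import nibabel as nib
import numpy as np

VALID_LABELS = (0, 1, 2, 4)
LABEL_BACKGROUND, LABEL_NCR, LABEL_ED, LABEL_ET = 0, 1, 2, 4
REGION_NAMES = ("ET", "TC", "WT")


def _default_affine(spacing: tuple[float, float, float]) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


@dataclass
class LabelMap:
    """Integer 3D volume of BraTS label codes with voxel geometry."""

    voxels: np.ndarray
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0)
    affine: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.voxels = np.asarray(self.voxels)
        if self.voxels.ndim != 3:
            raise ValueError(f"label map must be 3D, got shape {self.voxels.shape}")
        if not np.issubdtype(self.voxels.dtype, np.integer):
            raise ValueError(f"label map must be integer-typed, got {self.voxels.dtype}")
        if self.affine is None:
            self.affine = _default_affine(self.spacing)

    @property
    def shape(self) -> tuple[int, ...]:
        return self.voxels.shape

    def __eq__(self, other: object) -> bool:
        if not isinstance(other, LabelMap):
            return NotImplemented
        return bool(np.array_equal(self.voxels, other.voxels))


@dataclass
class RegionChannels:
    """Stacked ET/TC/WT channels, binary masks or sigmoid scores.

    ``channels`` has shape ``(3, D, H, W)`` in the fixed region order
    ``(ET, TC, WT)``. ``kind`` distinguishes hard masks from network
    outputs; only binary channels may be decoded back to a label map.
    """

    channels: np.ndarray
    kind: str = "binary"

    def __post_init__(self) -> None:
        self.channels = np.asarray(self.channels)
        if self.channels.ndim != 4 or self.channels.shape[0] != 3:
            raise ValueError(
                f"region channels must have shape (3, D, H, W), got {self.channels.shape}"
            )
        if self.kind not in ("binary", "sigmoid"):
            raise ValueError(f"kind must be 'binary' or 'sigmoid', got {self.kind!r}")

    @property
    def et(self) -> np.ndarray:
        return self.channels[0]

    @property
    def tc(self) -> np.ndarray:
        return self.channels[1]

    @property
    def wt(self) -> np.ndarray:
        return self.channels[2]


@dataclass
class LabelReport:
    """Outcome of :func:`validate_label_map`."""

    counts: Mapping[int, int]
    offending: tuple[int, ...] = field(default_factory=tuple)

    @property
    def valid(self) -> bool:
        return len(self.offending) == 0


def validate_label_map(label_map: LabelMap | np.ndarray) -> LabelReport:
    """Count voxels per label code and report codes outside the convention."""
    voxels = label_map.voxels if isinstance(label_map, LabelMap) else np.asarray(label_map)
    codes, counts = np.unique(voxels, return_counts=True)
    count_map = {int(c): int(n) for c, n in zip(codes, counts)}
    offending = tuple(sorted(c for c in count_map if c not in VALID_LABELS))
    return LabelReport(counts=count_map, offending=offending)


def derive_region_channels(label_map: LabelMap) -> RegionChannels:
    """Split a label map into the three nested sub-compartment masks.

    Raises ``ValueError`` naming any label code outside {0, 1, 2, 4}.
    """
    report = validate_label_map(label_map)
    if not report.valid:
        raise ValueError(f"unknown label code(s) {list(report.offending)}; expected {VALID_LABELS}")
    v = label_map.voxels
    et = v == LABEL_ET
    tc = et | (v == LABEL_NCR)
    wt = tc | (v == LABEL_ED)
    return RegionChannels(np.stack([et, tc, wt]).astype(np.uint8), kind="binary")


def channels_to_label_map(
    rc: RegionChannels,
    spacing: tuple[float, float, float] = (1.0, 1.0, 1.0),
    affine: np.ndarray | None = None,
) -> LabelMap:
    """Decode binary region channels back to a BraTS label map.

    Predicted channels can violate containment (an ET voxel the TC channel
    missed); nesting is first enforced upward (TC := TC ∨ ET, WT := WT ∨ TC)
    so every positive ET/TC prediction survives, then the nested masks are
    mapped to codes: ET→4, TC-only→1 (NCR), WT-only→2 (ED), else 0.
    """
    if rc.kind != "binary":
        raise ValueError("sigmoid channels must be binarized before decoding to a label map")
    et = rc.et.astype(bool)
    tc = rc.tc.astype(bool) | et
    wt = rc.wt.astype(bool) | tc
    out = np.zeros(et.shape, dtype=np.int16)
    out[wt & ~tc] = LABEL_ED
    out[tc & ~et] = LABEL_NCR
    out[et] = LABEL_ET
    return LabelMap(out, spacing=spacing, affine=affine)


def load_label_map(path) -> LabelMap:
    """Read a label map from a NIfTI file, bit-exact codes preserved."""
    img = nib.load(str(path))
    voxels = np.asarray(img.dataobj).astype(np.int16)
    spacing = tuple(float(z) for z in img.header.get_zooms()[:3])
    return LabelMap(voxels, spacing=spacing, affine=np.asarray(img.affine))


def save_label_map(label_map: LabelMap, path) -> None:
    img = nib.Nifti1Image(label_map.voxels.astype(np.int16), label_map.affine)
    img.header.set_zooms(label_map.spacing)
    nib.save(img, str(path))


def save_region_masks(rc: RegionChannels, prefix, affine: np.ndarray | None = None) -> None:
    """Write one binary NIfTI mask per region as ``<prefix>_{et,tc,wt}.nii.gz``."""
    if rc.kind != "binary":
        raise ValueError("only binary region channels can be written as masks")
    aff = np.eye(4) if affine is None else affine
    for i, name in enumerate(REGION_NAMES):
        img = nib.Nifti1Image(rc.channels[i].astype(np.uint8), aff)
        nib.save(img, f"{prefix}_{name.lower()}.nii.gz")
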