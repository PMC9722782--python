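"""Synthetic multi-site mpMRI phantoms with nested tumors.

Every other module is exercised on these phantoms, so they emulate the
features of a real multi-site glioblastoma federation that matter to the
training protocol, and nothing else:

* 4-channel volumes (T1, T1Gd, T2, T2-FLAIR) — a brain ellipsoid of
  non-zero intensity on an exactly-zero background;
* a concentric tumor: necrotic core (NCR) inside an enhancing shell (ET)
  inside an edema envelope (ED), giving the nested ET ⊆ TC ⊆ WT regions;
* tissue contrast in the expected directions (ET brightest on T1Gd, NCR
  dark on T1Gd, ED brightest on T2-FLAIR);
* per-site intensity shifts/scales and heavily skewed per-site case
  counts;
* optional annotation corruption at chosen sites (swapped codes,
  morphological damage, random voxel flips), leaving images untouched.

Anything resembling MR physics, deformable anatomy or acquisition
artifacts is out of scope.
"""

from __future__ import annotations

import hashlib
from dataclasses import dataclass, field, replace

import numpy as np
from scipy import ndimage

from .labels import (
    LABEL_ED,
    LABEL_ET,
    LABEL_NCR,
    LabelMap,
    validate_label_map,
)
from .preprocess import split_cases

CHANNEL_NAMES = ("t1", "t1gd", "t2", "flair")
TISSUES = ("brain", "ncr", "et", "ed")
ROLES = ("training", "out_of_sample", "public_initial")

# mean intensity per channel x tissue class (arbitrary units)
DEFAULT_INTENSITY_TABLE = {
    "t1": {"brain": 100.0, "ncr": 80.0, "et": 110.0, "ed": 90.0},
    "t1gd": {"brain": 100.0, "ncr": 40.0, "et": 180.0, "ed": 90.0},
    "t2": {"brain": 100.0, "ncr": 130.0, "et": 120.0, "ed": 140.0},
    "flair": {"brain": 100.0, "ncr": 110.0, "et": 120.0, "ed": 170.0},
}


def stable_seed(*parts) -> int:
    """Deterministic 31-bit seed from arbitrary labels, independent of
    iteration order and of Python's randomized string hashing."""
    key = "|".join(str(p) for p in parts).encode()
    return int.from_bytes(hashlib.blake2s(key, digest_size=4).digest(), "big") >> 1


@dataclass
class PhantomConfig:
    """Geometry, contrast and noise of a synthetic case."""

    volume_shape: tuple[int, int, int] = (48, 48, 48)
    brain_radius_range: tuple[float, float] = (0.36, 0.44)  # fraction of volume extent
    ncr_radius_range: tuple[float, float] = (2.0, 3.5)  # voxels
    et_radius_range: tuple[float, float] = (4.5, 6.5)
    ed_radius_range: tuple[float, float] = (7.5, 10.0)
    intensity_table: dict = field(default_factory=lambda: {
        c: dict(v) for c, v in DEFAULT_INTENSITY_TABLE.items()
    })
    noise_sd: float = 4.0
    tumor_presence_prob: float = 1.0

    def __post_init__(self) -> None:
        if not (self.ncr_radius_range[1] < self.et_radius_range[0]
                and self.et_radius_range[1] < self.ed_radius_range[0]):
            raise ValueError("tumor radius ranges must be strictly increasing NCR < ET < ED")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be non-negative")
        for c in CHANNEL_NAMES:
            for t in TISSUES:
                if not np.isfinite(self.intensity_table[c][t]):
                    raise ValueError(f"non-finite intensity for ({c}, {t})")


@dataclass
class CorruptionSpec:
    """Annotation damage injected at a site.

    ``mode``: label_swap (ET and ED codes exchanged), dilate / erode
    (morphological change of the whole tumor by ``magnitude`` voxels), or
    random_flip (each tumor voxel re-drawn uniformly from the tumor codes
    with probability ``magnitude``). ``fraction`` is the share of the
    site's cases affected.
    """

    mode: str
    fraction: float = 1.0
    magnitude: float = 1.0

    def __post_init__(self) -> None:
        if self.mode not in ("label_swap", "dilate", "erode", "random_flip"):
            raise ValueError(f"unknown corruption mode {self.mode!r}")
        if not (0.0 <= self.fraction <= 1.0):
            raise ValueError("fraction must lie in [0, 1]")


@dataclass
class SiteSpec:
    """One collaborating site: size, acquisition effect, optional corruption."""

    site_id: str
    n_cases: int
    intensity_shift: tuple[float, float, float, float] = (0.0, 0.0, 0.0, 0.0)
    intensity_scale: tuple[float, float, float, float] = (1.0, 1.0, 1.0, 1.0)
    corruption: CorruptionSpec | None = None
    role: str = "training"

    def __post_init__(self) -> None:
        if self.n_cases < 2:
            raise ValueError(f"site {self.site_id}: need n_cases >= 2 for a 4:1 split")
        if any(s <= 0 for s in self.intensity_scale):
            raise ValueError(f"site {self.site_id}: intensity_scale must be positive")
        if self.role not in ROLES:
            raise ValueError(f"site {self.site_id}: unknown role {self.role!r}")


@dataclass
class Case:
    case_id: str
    site_id: str
    image: np.ndarray  # (4, D, H, W) float32, raw intensities
    labels: LabelMap


@dataclass
class SiteData:
    """A realized site: its cases plus the preserved train/val split."""

    spec: SiteSpec
    cases: list
    train_ids: list
    val_ids: list
    split_seed: int | None = None

    @property
    def site_id(self) -> str:
        return self.spec.site_id

    @property
    def role(self) -> str:
        return self.spec.role

    def case(self, case_id: str) -> Case:
        for c in self.cases:
            if c.case_id == case_id:
                return c
        raise KeyError(case_id)

    @property
    def train_cases(self) -> list:
        return [self.case(i) for i in self.train_ids]

    @property
    def val_cases(self) -> list:
        return [self.case(i) for i in self.val_ids]


@dataclass
class FederationDataset:
    """Registry of realized sites with globally unique case ids."""

    sites: list

    def __post_init__(self) -> None:
        ids = [c.case_id for s in self.sites for c in s.cases]
        if len(ids) != len(set(ids)):
            raise ValueError("case ids must be globally unique")

    @property
    def training_sites(self) -> list:
        return [s for s in self.sites if s.role in ("training", "public_initial")]

    @property
    def out_of_sample_sites(self) -> list:
        return [s for s in self.sites if s.role == "out_of_sample"]

    def site(self, site_id: str) -> SiteData:
        for s in self.sites:
            if s.site_id == site_id:
                return s
        raise KeyError(site_id)

    def total_cases(self) -> int:
        return sum(len(s.cases) for s in self.sites)

    def role_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for s in self.sites:
            counts[s.role] = counts.get(s.role, 0) + len(s.cases)
        return counts


def _ellipsoid_mask(shape, center, radii) -> np.ndarray:
    grids = np.ogrid[tuple(slice(0, s) for s in shape)]
    acc = sum(((g - c) / r) ** 2 for g, c, r in zip(grids, center, radii))
    return acc <= 1.0


def generate_case(cfg: PhantomConfig, site: SiteSpec, rng: np.random.Generator,
                  case_id: str = "case") -> Case:
    """One synthetic mpMRI volume set with its BraTS-convention label map."""
    shape = cfg.volume_shape
    center = tuple((s - 1) / 2.0 for s in shape)
    brain_radii = [rng.uniform(*cfg.brain_radius_range) * s for s in shape]

    labels = np.zeros(shape, dtype=np.int16)
    brain = _ellipsoid_mask(shape, center, brain_radii)

    tumor_masks = {}
    if rng.random() < cfg.tumor_presence_prob:
        r_ncr = rng.uniform(*cfg.ncr_radius_range)
        r_et = rng.uniform(*cfg.et_radius_range)
        r_ed = rng.uniform(*cfg.ed_radius_range)
        if r_ed >= min(brain_radii):
            raise ValueError(
                f"tumor radius {r_ed:.1f} exceeds brain radius {min(brain_radii):.1f}"
            )
        # uniform center such that the ED envelope stays inside the brain
        frac = [1.0 - r_ed / br for br in brain_radii]
        while True:
            u = rng.uniform(-1.0, 1.0, size=3)
            if (u ** 2).sum() <= 1.0:
                break
        t_center = [c + f * br * ui for c, f, br, ui in zip(center, frac, brain_radii, u)]
        ed = _ellipsoid_mask(shape, t_center, (r_ed,) * 3)
        et = _ellipsoid_mask(shape, t_center, (r_et,) * 3)
        ncr = _ellipsoid_mask(shape, t_center, (r_ncr,) * 3)
        labels[ed] = LABEL_ED
        labels[et] = LABEL_ET
        labels[ncr] = LABEL_NCR
        tumor_masks = {"ed": ed & ~et, "et": et & ~ncr, "ncr": ncr}

    image = np.zeros((4,) + shape, dtype=np.float64)
    for ci, cname in enumerate(CHANNEL_NAMES):
        chan = image[ci]
        chan[brain] = cfg.intensity_table[cname]["brain"]
        for tissue, mask in tumor_masks.items():
            chan[mask] = cfg.intensity_table[cname][tissue]
        chan[brain] = chan[brain] * site.intensity_scale[ci] + site.intensity_shift[ci]
        if cfg.noise_sd > 0:
            chan[brain] += rng.normal(0.0, cfg.noise_sd, size=int(brain.sum()))
    return Case(
        case_id=case_id,
        site_id=site.site_id,
        image=image.astype(np.float32),
        labels=LabelMap(labels),
    )


def corrupt_site_labels(cases, spec: CorruptionSpec, rng: np.random.Generator) -> list:
    """Damage the annotations of a fraction of cases; images are untouched."""
    cases = list(cases)
    n_affected = int(round(spec.fraction * len(cases)))
    if n_affected == 0:
        return cases
    affected = set(rng.choice(len(cases), size=n_affected, replace=False).tolist())
    out = []
    for i, case in enumerate(cases):
        if i not in affected:
            out.append(case)
            continue
        v = case.labels.voxels.copy()
        if spec.mode == "label_swap":
            et = v == LABEL_ET
            ed = v == LABEL_ED
            v[et] = LABEL_ED
            v[ed] = LABEL_ET
        elif spec.mode in ("dilate", "erode"):
            mag = int(spec.magnitude)
            if mag >= min(v.shape):
                raise ValueError(f"corruption magnitude {mag} exceeds volume extent {v.shape}")
            wt = v > 0
            if spec.mode == "dilate":
                grown = ndimage.binary_dilation(wt, iterations=mag)
                v[grown & ~wt] = LABEL_ED
            else:
                kept = ndimage.binary_erosion(wt, iterations=mag)
                v[wt & ~kept] = 0
        elif spec.mode == "random_flip":
            tumor = np.flatnonzero(v > 0)
            flip = tumor[rng.random(tumor.size) < spec.magnitude]
            v.flat[flip] = rng.choice([LABEL_NCR, LABEL_ED, LABEL_ET], size=flip.size)
        assert validate_label_map(v).valid
        out.append(replace(case, labels=LabelMap(v, case.labels.spacing, case.labels.affine)))
    return out


def generate_federation(
    site_specs,
    cfg: PhantomConfig,
    seed: int,
    split_seed: int | None = None,
) -> FederationDataset:
    """Realize a federation: per-site cases, corruption, preserved 4:1 splits.

    Per-site randomness derives from a stable hash of (seed, site_id), so
    the result is independent of site ordering and bit-reproducible.
    """
    ids = [s.site_id for s in site_specs]
    if len(ids) != len(set(ids)):
        raise ValueError("duplicate site_id in federation")
    if not any(s.role in ("training", "public_initial") for s in site_specs):
        raise ValueError("federation needs at least one training site")
    split_seed = seed if split_seed is None else split_seed

    sites = []
    for spec in site_specs:
        rng = np.random.default_rng(stable_seed(seed, "site", spec.site_id))
        cases = [
            generate_case(cfg, spec, rng, case_id=f"{spec.site_id}_c{i:03d}")
            for i in range(spec.n_cases)
        ]
        if spec.corruption is not None:
            cases = corrupt_site_labels(cases, spec.corruption, rng)
        case_ids = [c.case_id for c in cases]
        if spec.role in ("training", "public_initial"):
            s_seed = stable_seed(split_seed, "split", spec.site_id)
            train_ids, val_ids = split_cases(case_ids, s_seed)
        else:
            s_seed, train_ids, val_ids = None, [], list(case_ids)
        sites.append(SiteData(spec=spec, cases=cases, train_ids=train_ids,
                              val_ids=val_ids, split_seed=s_seed))
    return FederationDataset(sites=sites)


def skewed_site_specs(
    n_sites: int,
    seed: int,
    median_cases: int = 10,
    sigma: float = 0.8,
    shift_sd: float = 5.0,
    scale_sd: float = 0.05,
) -> list[SiteSpec]:
    """Site specs with log-normal case counts and mild acquisition effects,
    mimicking the heavy skew of real per-site contributions."""
    rng = np.random.default_rng(seed)
    specs = []
    for i in range(n_sites):
        n = max(2, int(round(median_cases * rng.lognormal(0.0, sigma))))
        specs.append(SiteSpec(
            site_id=f"site{i:02d}",
            n_cases=n,
            intensity_shift=tuple(rng.normal(0.0, shift_sd, size=4)),
            intensity_scale=tuple(np.exp(rng.normal(0.0, scale_sd, size=4))),
        ))
    return specs
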