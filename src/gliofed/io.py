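"""On-disk federation layout: BraTS-style NIfTI files plus a manifest.

Each case is written into its site's directory as five NIfTI volumes —
``<case>_t1``, ``<case>_t1gd``, ``<case>_t2``, ``<case>_flair`` and
``<case>_seg`` — and a top-level ``manifest.csv`` records case id, site,
role and split assignment. Real BraTS-format data arranged the same way
loads through the same reader.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .labels import LabelMap, load_label_map, save_label_map
from .phantom import (
    CHANNEL_NAMES,
    Case,
    FederationDataset,
    SiteData,
    SiteSpec,
)

__all__ = ["write_federation", "load_federation", "load_case"]


def write_federation(dataset: FederationDataset, root) -> Path:
    """Write all cases and the manifest under ``root``; returns the path."""
    root = Path(root)
    rows = []
    for site in dataset.sites:
        site_dir = root / site.site_id
        site_dir.mkdir(parents=True, exist_ok=True)
        for case in site.cases:
            aff = case.labels.affine
            for ci, cname in enumerate(CHANNEL_NAMES):
                img = nib.Nifti1Image(case.image[ci].astype(np.float32), aff)
                nib.save(img, site_dir / f"{case.case_id}_{cname}.nii.gz")
            save_label_map(case.labels, site_dir / f"{case.case_id}_seg.nii.gz")
            if case.case_id in site.train_ids:
                split = "train"
            elif case.case_id in site.val_ids:
                split = "val"
            else:
                split = ""
            rows.append({"case_id": case.case_id, "site_id": site.site_id,
                         "role": site.role, "split": split,
                         "split_seed": site.split_seed if site.split_seed is not None else ""})
    pd.DataFrame(rows).to_csv(root / "manifest.csv", index=False)
    return root


def load_case(site_dir, case_id: str, site_id: str) -> Case:
    site_dir = Path(site_dir)
    channels = []
    for cname in CHANNEL_NAMES:
        img = nib.load(site_dir / f"{case_id}_{cname}.nii.gz")
        channels.append(np.asarray(img.dataobj, dtype=np.float32))
    labels = load_label_map(site_dir / f"{case_id}_seg.nii.gz")
    return Case(case_id=case_id, site_id=site_id,
                image=np.stack(channels), labels=labels)


def load_federation(root) -> FederationDataset:
    """Rebuild a federation (cases, roles, preserved splits) from disk."""
    root = Path(root)
    manifest = pd.read_csv(root / "manifest.csv", dtype={"case_id": str, "site_id": str},
                           keep_default_na=False)
    sites = []
    for site_id, group in manifest.groupby("site_id", sort=True):
        role = group["role"].iloc[0]
        cases = [load_case(root / site_id, cid, site_id) for cid in group["case_id"]]
        train_ids = group.loc[group["split"] == "train", "case_id"].tolist()
        val_ids = group.loc[group["split"] == "val", "case_id"].tolist()
        seed_vals = [s for s in group["split_seed"] if s != ""]
        spec = SiteSpec(site_id=site_id, n_cases=len(cases), role=role)
        sites.append(SiteData(spec=spec, cases=cases, train_ids=train_ids,
                              val_ids=val_ids,
                              split_seed=int(float(seed_vals[0])) if seed_vals else None))
    return FederationDataset(sites=sites)
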