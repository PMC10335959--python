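"""Readers and writers shared by all stages.

Volumes are NIfTI-1 (.nii / .nii.gz) with the affine honored for mm
coordinates; matrices go into compressed .npz containers with an embedded
JSON header; tables are TSV. Synthetic datasets round-trip through a
directory of NIfTI volumes plus a JSON sidecar holding the planted ground
truth and the generating configuration.
"""
from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import nibabel as nib
import numpy as np

from .connectivity import BoldGroupMatrix
from .spatial_stats import SeedMap
from .synthetic import SyntheticConfig, SyntheticDataset, hemisphere_labels

__all__ = [
    "read_volume",
    "write_volume",
    "save_matrix",
    "load_matrix",
    "seed_map_from_volume",
    "write_dataset",
    "load_dataset",
]


def write_volume(data: np.ndarray, affine: np.ndarray, path) -> None:
    img = nib.Nifti1Image(np.asarray(data, dtype=np.float64), affine)
    nib.save(img, str(path))


def read_volume(path):
    """Return (data, affine) of a NIfTI volume."""
    img = nib.load(str(path))
    return np.asanyarray(img.dataobj), img.affine


def save_matrix(path, values: np.ndarray, header: dict | None = None, **arrays) -> None:
    """Persist a matrix plus named index arrays and a JSON header."""
    np.savez_compressed(
        str(path),
        values=values,
        _header=np.array(json.dumps(header or {})),
        **arrays,
    )


def load_matrix(path):
    """Return (values, header dict, dict of extra arrays)."""
    with np.load(str(path), allow_pickle=False) as z:
        values = z["values"]
        header = json.loads(str(z["_header"]))
        arrays = {k: z[k] for k in z.files if k not in ("values", "_header")}
    return values, header, arrays


def seed_map_from_volume(volume: np.ndarray, seed_mask: np.ndarray, affine: np.ndarray) -> SeedMap:
    """Sample a 3D volume at seed-mask voxels into a SeedMap (world mm)."""
    seed_mask = np.asarray(seed_mask, dtype=bool)
    idx = np.argwhere(seed_mask)
    coords = idx @ np.asarray(affine)[:3, :3].T + np.asarray(affine)[:3, 3]
    return SeedMap(
        values=np.asarray(volume, dtype=float)[seed_mask],
        coords_mm=coords,
        hemisphere=hemisphere_labels(idx, seed_mask.shape),
    )


def _bold_volume(bold: BoldGroupMatrix) -> np.ndarray:
    vol = np.zeros(bold.grid_shape + (bold.n_timepoints,))
    vol[tuple(bold.voxel_index.T)] = bold.data.T
    return vol


def write_dataset(ds: SyntheticDataset, out_dir) -> None:
    """Write a synthetic dataset as NIfTI volumes + ground-truth sidecar."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = ds.affine
    write_volume(ds.seed_mask.astype(np.float64), aff, out / "seed_mask.nii.gz")
    write_volume(ds.brain_mask.astype(np.float64), aff, out / "brain_mask.nii.gz")
    write_volume(ds.network_labels.astype(np.float64), aff, out / "network_labels.nii.gz")
    write_volume(ds.gmv_map, aff, out / "gmv.nii.gz")
    nib.save(nib.Nifti1Image(_bold_volume(ds.bold), aff), str(out / "bold.nii.gz"))
    terms_dir = out / "terms"
    terms_dir.mkdir(exist_ok=True)
    manifest = []
    for i, (name, vol) in enumerate(ds.term_maps.items()):
        fname = f"term_{i:03d}.nii.gz"
        write_volume(vol, aff, terms_dir / fname)
        manifest.append(f"{name}\t{fname}")
    (terms_dir / "manifest.tsv").write_text("term\tfile\n" + "\n".join(manifest) + "\n")
    truth = {
        "config": dataclasses.asdict(ds.config),
        "network_names": ds.network_names,
        "planted_g1": ds.planted_g1.tolist(),
        "planted_g2": ds.planted_g2.tolist(),
        "planted_seed_labels": ds.planted_seed_labels.tolist(),
        "standardized": bool(ds.bold.standardized),
    }
    (out / "ground_truth.json").write_text(json.dumps(truth, indent=1))


def load_dataset(in_dir) -> SyntheticDataset:
    """Load a dataset written by :func:`write_dataset`."""
    d = Path(in_dir)
    truth = json.loads((d / "ground_truth.json").read_text())
    cfg_dict = dict(truth["config"])
    cfg_dict["grid_shape"] = tuple(cfg_dict["grid_shape"])
    cfg_dict["gradient_axes"] = tuple(tuple(a) for a in cfg_dict["gradient_axes"])
    config = SyntheticConfig(**cfg_dict)

    seed_mask = read_volume(d / "seed_mask.nii.gz")[0] > 0.5
    brain_mask = read_volume(d / "brain_mask.nii.gz")[0] > 0.5
    labels = np.rint(read_volume(d / "network_labels.nii.gz")[0]).astype(int)
    gmv = np.asarray(read_volume(d / "gmv.nii.gz")[0], dtype=float)

    bold_vol = np.asarray(nib.load(str(d / "bold.nii.gz")).dataobj, dtype=float)
    seed_ijk = np.argwhere(seed_mask)
    targ_ijk = np.argwhere(brain_mask)
    voxel_index = np.concatenate([seed_ijk, targ_ijk], axis=0)
    data = bold_vol[tuple(voxel_index.T)].T
    bold = BoldGroupMatrix(
        data=data,
        voxel_index=voxel_index,
        standardized=bool(truth["standardized"]),
        grid_shape=seed_mask.shape,
    )

    term_maps = {}
    manifest = (d / "terms" / "manifest.tsv").read_text().strip().splitlines()[1:]
    for line in manifest:
        name, fname = line.split("\t")
        term_maps[name] = np.asarray(read_volume(d / "terms" / fname)[0], dtype=float)

    return SyntheticDataset(
        bold=bold,
        seed_mask=seed_mask,
        brain_mask=brain_mask,
        network_labels=labels,
        gmv_map=gmv,
        term_maps=term_maps,
        planted_g1=np.asarray(truth["planted_g1"], dtype=float),
        planted_g2=np.asarray(truth["planted_g2"], dtype=float),
        planted_seed_labels=np.asarray(truth["planted_seed_labels"], dtype=int),
        network_names=list(truth["network_names"]),
        config=config,
    )
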