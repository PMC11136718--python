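"""NIfTI and table IO for on-disk pipeline runs.

Volumes are written as NIfTI with a diagonal affine built from the voxel
size: atlas labels as int32, FA/MD/PV as float32, CL masks as uint8. The
region lookup goes to TSV, the cohort to CSV, the simulation config to
YAML — everything a run needs to be re-loaded and re-analyzed.
"""

from __future__ import annotations

from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .atlas import ParcellationAtlas
from .config import SimulationConfig
from .simulate import SubjectImageSet, SyntheticStudy


def _affine(voxel_size) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = voxel_size
    return aff


def save_volume(data: np.ndarray, voxel_size, path, dtype=None) -> None:
    arr = np.asarray(data, dtype=dtype) if dtype else np.asarray(data)
    nib.save(nib.Nifti1Image(arr, _affine(voxel_size)), str(path))


def load_volume(path) -> tuple[np.ndarray, tuple[float, float, float]]:
    img = nib.load(str(path))
    zooms = tuple(float(z) for z in img.header.get_zooms()[:3])
    return np.asarray(img.dataobj), zooms


def save_atlas(atlas: ParcellationAtlas, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(atlas.labels, atlas.voxel_size, outdir / "atlas.nii.gz", np.int32)
    atlas.lookup_table().to_csv(outdir / "regions.tsv", sep="\t")


def load_atlas(nifti_path, lookup_path) -> ParcellationAtlas:
    labels, zooms = load_volume(nifti_path)
    lut = pd.read_csv(lookup_path, sep="\t").set_index("region_id")
    return ParcellationAtlas(
        labels=np.asarray(labels, dtype=np.int32),
        voxel_size=zooms,
        region_networks={int(r): str(v) for r, v in lut["network"].items()},
        region_hemispheres={int(r): str(v) for r, v in lut["hemisphere"].items()},
    )


def save_subject(img: SubjectImageSet, voxel_size, outdir: Path) -> None:
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_volume(img.fa, voxel_size, outdir / "fa.nii.gz", np.float32)
    save_volume(img.md, voxel_size, outdir / "md.nii.gz", np.float32)
    save_volume(img.pv, voxel_size, outdir / "pv.nii.gz", np.float32)
    save_volume(img.cl_mask, voxel_size, outdir / "cl_mask.nii.gz", np.uint8)


def save_study(study: SyntheticStudy, outdir: Path) -> None:
    """Write a whole simulated study: atlas, subjects, cohort CSV, config."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    save_atlas(study.atlas, outdir / "atlas")
    for subj, img in study.images.items():
        save_subject(img, study.atlas.voxel_size, outdir / "subjects" / subj)
    study.cohort.to_csv(outdir / "cohort.csv")
    study.config.to_yaml(outdir / "config.yaml")


def load_config(path) -> SimulationConfig:
    return SimulationConfig.from_yaml(path)
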