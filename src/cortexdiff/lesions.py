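"""Cortical-lesion topography: intersect CL masks with the parcellation.

A region is *lesional* when at least one lesion voxel falls inside it.
Lesion load per network is summarized as the CL volume relative to the
total network volume, reported in units of 1e-3 % to match the magnitudes
cortical lesions typically reach. Lesion voxels falling outside every
atlas region are never dropped silently: they are tallied and reported,
since a large out-of-atlas count flags mask/atlas misregistration.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage

from .atlas import ParcellationAtlas
from .errors import EmptyNetworkError, GridMismatchError, MaskError


@dataclass
class LesionTopography:
    """Per-subject lesion summary at region and network granularity."""

    subject: str
    region_table: pd.DataFrame  # index region_id: network, hemisphere, n_voxels, cl_voxel_count, cl_volume_mm3, lesional
    network_table: pd.DataFrame  # index network: cl_volume_mm3, network_volume_mm3, has_cl, cl_fraction_e3pct
    total_cl_count: int
    total_cl_volume_ml: float
    out_of_atlas_voxels: int
    voxel_volume: float

    @property
    def lesional_regions(self) -> set[int]:
        t = self.region_table
        return set(t.index[t["lesional"]].astype(int))

    @property
    def n_lesional_regions(self) -> int:
        return len(self.lesional_regions)


def _check_grids(atlas: ParcellationAtlas, mask: np.ndarray) -> np.ndarray:
    if mask.shape != atlas.labels.shape:
        raise GridMismatchError(
            f"mask grid {mask.shape} != atlas grid {atlas.labels.shape}"
        )
    vals = np.unique(mask)
    if not np.isin(vals, (0, 1)).all():
        raise MaskError(f"lesion mask must be binary; found values {vals[:5]}")
    return mask.astype(bool)


def count_components(
    cl_mask: np.ndarray, connectivity: int = 26
) -> int:
    """Number of connected lesion components (default 26-connectivity)."""
    if connectivity == 26:
        structure = np.ones((3, 3, 3), dtype=bool)
    elif connectivity == 6:
        structure = ndimage.generate_binary_structure(3, 1)
    elif connectivity == 18:
        structure = ndimage.generate_binary_structure(3, 2)
    else:
        raise ValueError("connectivity must be 6, 18 or 26")
    _, n = ndimage.label(np.asarray(cl_mask) > 0, structure=structure)
    return int(n)


def intersect_lesions(
    atlas: ParcellationAtlas, cl_mask: np.ndarray, subject: str = "sub"
) -> LesionTopography:
    """Tabulate CL presence/volume per region and per network.

    Requires identical voxel grids (no resampling); the mask must be
    binary. ``total_cl_count`` is the number of 26-connected components of
    the whole mask; per-region tallies are voxel counts.
    """
    mask = _check_grids(atlas, cl_mask)
    lab = atlas.labels
    vv = atlas.voxel_volume
    lut = atlas.lookup_table()

    hits = np.bincount(lab[mask], minlength=int(lab.max()) + 1)
    region = lut.copy()
    region["cl_voxel_count"] = hits[region.index.to_numpy()]
    region["cl_volume_mm3"] = region["cl_voxel_count"] * vv
    region["lesional"] = region["cl_voxel_count"] >= 1

    net = region.groupby("network").agg(
        cl_volume_mm3=("cl_volume_mm3", "sum"),
        network_volume_mm3=("volume_mm3", "sum"),
    )
    net["has_cl"] = net["cl_volume_mm3"] > 0
    net["cl_fraction_e3pct"] = (
        100.0 * net["cl_volume_mm3"] / net["network_volume_mm3"] * 1e3
    )

    out_of_atlas = int(mask.sum() - region["cl_voxel_count"].sum())
    return LesionTopography(
        subject=subject,
        region_table=region,
        network_table=net,
        total_cl_count=count_components(mask),
        total_cl_volume_ml=float(mask.sum() * vv / 1000.0),
        out_of_atlas_voxels=out_of_atlas,
        voxel_volume=vv,
    )


def network_cl_fraction(topography: LesionTopography, network: str) -> float:
    """CL volume relative to network volume, in 1e-3 % units.

    1 mm^3 of lesion in a 100,000 mm^3 network is 0.001 %, i.e. 1.0 in
    these units.
    """
    try:
        row = topography.network_table.loc[network]
    except KeyError:
        raise EmptyNetworkError(f"unknown network {network!r}") from None
    if row["network_volume_mm3"] <= 0:
        raise EmptyNetworkError(f"network {network!r} has zero volume")
    return float(row["cl_fraction_e3pct"])


def lesional_region_split(
    topography: LesionTopography,
) -> tuple[set[int], set[int]]:
    """Disjoint, exhaustive split of regions into (lesional, non-lesional)."""
    t = topography.region_table
    with_voxels = t.index[t["n_voxels"] >= 1]
    lesional = set(int(r) for r in with_voxels[t.loc[with_voxels, "lesional"]])
    nonlesional = set(int(r) for r in with_voxels) - lesional
    return lesional, nonlesional
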