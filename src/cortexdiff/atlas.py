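"""Cortical parcellation atlas: a 3D label volume with network/hemisphere lookups.

The analysis works on a 212-region cortical parcellation (210 cortical
regions plus both hippocampi) in which every region belongs to exactly one
of seven distributed functional networks: sensorimotor (SMN), ventral
attention (VAN), dorsal attention (DAN), frontoparietal (FPN), default mode
(DMN), visual and limbic. Only the label bookkeeping matters downstream;
region geometry never enters the statistics.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AtlasError

#: Canonical network order used throughout the package.
NETWORKS = ("SMN", "VAN", "DAN", "FPN", "DMN", "visual", "limbic")

HEMISPHERES = ("L", "R")


@dataclass(frozen=True)
class ParcellationAtlas:
    """A 3D integer label volume with region -> network / hemisphere maps.

    Parameters
    ----------
    labels
        3D integer array; 0 is background, positive labels are regions.
    voxel_size
        Edge lengths of a voxel in mm per axis.
    region_networks
        Mapping from region label to network name (one of :data:`NETWORKS`).
    region_hemispheres
        Mapping from region label to ``"L"`` or ``"R"``.
    """

    labels: np.ndarray
    voxel_size: tuple[float, float, float] = (1.0, 1.0, 1.0)
    region_networks: dict[int, str] = field(default_factory=dict)
    region_hemispheres: dict[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if self.labels.ndim != 3:
            raise AtlasError("label volume must be 3D")
        if any(v <= 0 for v in self.voxel_size):
            raise AtlasError("voxel_size entries must be positive")
        ids = self.region_ids
        missing = [int(r) for r in ids if int(r) not in self.region_networks]
        if missing:
            raise AtlasError(f"regions without a network assignment: {missing[:5]}")

    @property
    def region_ids(self) -> np.ndarray:
        """Sorted unique nonzero labels present in the volume."""
        ids = np.unique(self.labels)
        return ids[ids > 0]

    @property
    def n_regions(self) -> int:
        return int(self.region_ids.size)

    @property
    def voxel_volume(self) -> float:
        """Volume of one voxel in mm^3."""
        return float(np.prod(self.voxel_size))

    @property
    def networks(self) -> tuple[str, ...]:
        """Networks present, in canonical order."""
        present = set(self.region_networks.values())
        return tuple(n for n in NETWORKS if n in present) + tuple(
            sorted(present - set(NETWORKS))
        )

    def region_sizes(self) -> pd.Series:
        """Voxel count per region, indexed by region id."""
        counts = np.bincount(self.labels.ravel())
        ids = self.region_ids
        return pd.Series(counts[ids], index=ids, name="n_voxels")

    def network_volume(self, network: str) -> float:
        """Total volume (mm^3) of all regions in ``network``."""
        regions = [r for r, n in self.region_networks.items() if n == network]
        if not regions:
            raise AtlasError(f"network {network!r} has no regions")
        sizes = self.region_sizes()
        return float(sizes.loc[regions].sum() * self.voxel_volume)

    def lookup_table(self) -> pd.DataFrame:
        """Region table: id, network, hemisphere, voxel count, volume.

        Cached per atlas (the label volume is immutable by convention).
        """
        cached = self.__dict__.get("_lut")
        if cached is not None:
            return cached
        sizes = self.region_sizes()
        lut = pd.DataFrame(
            {
                "region_id": sizes.index,
                "network": [self.region_networks[int(r)] for r in sizes.index],
                "hemisphere": [self.region_hemispheres.get(int(r), "?") for r in sizes.index],
                "n_voxels": sizes.to_numpy(),
                "volume_mm3": sizes.to_numpy() * self.voxel_volume,
            }
        ).set_index("region_id")
        object.__setattr__(self, "_lut", lut)
        return lut
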