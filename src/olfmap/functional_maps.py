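"""Virtual odor activity maps in higher brain centers.

A functional map predicts the spatial activity an odor evokes at the input
of the mushroom-body calyx or the lateral horn: for each neuron class the
axonal density map is weighted by the class's response intensity to the
odor (negative intensities rectified to zero) and the weighted maps are
summed voxelwise,

    F_odor = Σ_c max(r_{c,odor}, 0) · D_c .

Maps of different odors are compared with correlation distances over the
flattened voxel arrays and clustered by Ward's method with a fixed
linkage-distance cut, asking whether odors of like valence activate like
regions. ``regional_summary`` quantifies where a map's mass falls.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from . import odor_space
from .morphology import VoxelMap

logger = logging.getLogger(__name__)


@dataclass
class FunctionalMap:
    """Response-weighted activity map for one odor."""

    voxels: VoxelMap
    odor_id: str
    contributing_class_ids: list

    @property
    def values(self) -> np.ndarray:
        return self.voxels.values

    @property
    def mass(self) -> float:
        return self.voxels.mass


def functional_map(density: dict, responses, odor_id: str) -> FunctionalMap:
    """Sum of rectified-response-weighted class density maps for one odor.

    ``density`` maps class_id → VoxelMap, all on one grid. Every class with
    a density map must have a response row (else an error naming them);
    classes with responses but no density map are skipped and logged —
    reconstruction coverage is typically incomplete.
    """
    frame = getattr(responses, "frame", responses)
    if odor_id not in frame.columns:
        raise ValueError(f"odor {odor_id!r} not in the response matrix")
    grids = {m.grid for m in density.values()}
    if len(grids) != 1:
        raise ValueError("all density maps must share a GridSpec")
    grid = next(iter(grids))

    no_response = [c for c in density if c not in frame.index]
    if no_response:
        raise ValueError(f"classes with density maps but no response row: {no_response}")
    skipped = [c for c in frame.index if c not in density]
    if skipped:
        logger.info("classes without density maps skipped: %s", skipped)

    total = np.zeros(grid.shape, dtype=float)
    used = []
    for class_id, dmap in density.items():
        weight = max(float(frame.loc[class_id, odor_id]), 0.0)
        if weight > 0:
            total += weight * dmap.values
        used.append(class_id)
    vm = VoxelMap(grid=grid, values=total, kind="functional", label=odor_id)
    return FunctionalMap(voxels=vm, odor_id=odor_id, contributing_class_ids=used)


def functional_maps_for_panel(density: dict, responses,
                              odor_ids=None) -> dict:
    """One functional map per odor (columns of the response matrix)."""
    frame = getattr(responses, "frame", responses)
    odor_ids = list(frame.columns) if odor_ids is None else list(odor_ids)
    return {o: functional_map(density, responses, o) for o in odor_ids}


def functional_map_clustering(maps: dict, cut: float = 0.6):
    """Cluster odors by the similarity of their functional maps.

    Correlation distances between flattened 3D maps, Ward linkage, and a
    flat cut at the given linkage distance. Constant (e.g., all-zero) maps
    have undefined correlation; their distances are set to 1 with a warning.

    Returns ``(DistanceMatrix, Dendrogram, cluster labels)``.
    """
    odors = list(maps)
    grids = {maps[o].voxels.grid for o in odors}
    if len(grids) != 1:
        raise ValueError("functional maps must share a grid")
    flat = np.stack([maps[o].values.ravel() for o in odors])
    dmat = odor_space.correlation_distance_rows(flat, odors)
    dend = odor_space.hierarchical_cluster(dmat)
    labels = odor_space.cut_dendrogram(dend, cut, mode="absolute")
    return dmat, dend, labels


def regional_summary(fmap: FunctionalMap, region_masks: dict) -> dict:
    """Fraction of a map's total mass inside each named boolean mask.

    Masks must match the map grid shape. A zero-mass map has undefined
    fractions and raises. If the masks partition the grid the fractions
    sum to 1.
    """
    total = fmap.mass
    if total <= 0:
        raise ValueError("functional map has no mass; fractions undefined")
    out = {}
    for name, mask in region_masks.items():
        mask = np.asarray(mask, dtype=bool)
        if mask.shape != fmap.values.shape:
            raise ValueError(f"mask {name!r} shape does not match the map grid")
        out[name] = float(fmap.values[mask].sum() / total)
    return out
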