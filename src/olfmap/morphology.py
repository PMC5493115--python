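"""Neuron skeletons and 3D voxel density maps.

A projection-neuron axonal arbor, reconstructed as an SWC tree in template
space, is turned into a density map in four steps: the polyline is resampled
into segments of fixed length (0.5 μm), segment midpoints are binned onto an
isotropic voxel grid (1 μm³ voxels, 135 × 135 × 105 by default), the histogram
is smoothed with a normalized 3D boxcar kernel (9 voxels wide), and, for
display, columns of voxels are integrated along a projection axis.

Density maps of different neuron classes are compared with correlation
distances over the flattened voxel arrays, followed by Ward clustering
(delegated to :mod:`olfmap.odor_space`).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, replace

import numpy as np
from scipy import ndimage

logger = logging.getLogger(__name__)

#: Default template grid (voxels) shared by the calyx and lateral-horn maps.
DEFAULT_GRID_SHAPE = (135, 135, 105)

#: Axis-aligned bounding-box sizes of the neuropil regions, μm.
REGION_SIZES = {
    "calyx": (55.0, 46.0, 32.0),
    "LH": (52.0, 53.0, 43.0),
}

_AXES = {"x": 0, "y": 1, "z": 2}


# ---------------------------------------------------------------------------
# Grid and voxel-map containers
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class GridSpec:
    """Isotropic voxel grid: world position of voxel (0,0,0) corner and shape.

    Voxels are half-open intervals: point ``p`` falls in voxel
    ``floor((p - origin) / voxel_size)``.
    """

    origin: tuple[float, float, float] = (0.0, 0.0, 0.0)
    shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE
    voxel_size: float = 1.0

    def __post_init__(self) -> None:
        if self.voxel_size <= 0:
            raise ValueError("voxel_size must be positive")
        if any(n <= 0 for n in self.shape):
            raise ValueError("grid shape must be positive")

    @property
    def extent(self) -> np.ndarray:
        """World-space size of the grid along each axis, μm."""
        return np.asarray(self.shape, dtype=float) * self.voxel_size


@dataclass
class VoxelMap:
    """Dense non-negative 3D histogram on a :class:`GridSpec`.

    ``kind`` distinguishes anatomical density maps from response-weighted
    functional maps; both use the same container.
    """

    grid: GridSpec
    values: np.ndarray
    kind: str = "density"  # "density" | "functional"
    label: str | None = None
    n_out_of_bounds: int = 0

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.shape != tuple(self.grid.shape):
            raise ValueError(
                f"values shape {self.values.shape} does not match grid {self.grid.shape}"
            )
        if not np.all(np.isfinite(self.values)):
            raise ValueError("voxel values must be finite")

    @property
    def mass(self) -> float:
        return float(self.values.sum())


def region_grid(region: str, *, grid_shape: tuple[int, int, int] = DEFAULT_GRID_SHAPE,
                voxel_size: float = 1.0) -> GridSpec:
    """Template grid for a neuropil region, with the region box centered.

    The grid origin is placed so that the region bounding box
    (:data:`REGION_SIZES`) sits at the center of the grid; world coordinates
    of synthetic skeletons are generated in this frame.
    """
    size = np.asarray(REGION_SIZES[region])
    extent = np.asarray(grid_shape, dtype=float) * voxel_size
    origin = -(extent - size) / 2.0
    return GridSpec(origin=tuple(origin), shape=tuple(grid_shape), voxel_size=voxel_size)


def region_box(region: str) -> tuple[np.ndarray, np.ndarray]:
    """(lower corner, size) of a region bounding box in its own frame (μm).

    The region frame puts the box lower corner at the origin, so a locus is
    inside the region iff all its coordinates are within ``[0, size)``.
    """
    size = np.asarray(REGION_SIZES[region])
    return np.zeros(3), size


# ---------------------------------------------------------------------------
# Skeletons and SWC I/O
# ---------------------------------------------------------------------------

@dataclass
class NeuronSkeleton:
    """SWC-style tree: integer node ids, 3D coordinates in μm, parent links.

    Exactly one node has parent -1 (the root); every other node's parent must
    be a node of the tree. ``region_of_node`` tags nodes by neuropil
    membership ("calyx", "LH", "other") when known.
    """

    node_ids: np.ndarray          # (N,) int
    xyz: np.ndarray               # (N, 3) float, μm
    radius: np.ndarray            # (N,) float
    parent_ids: np.ndarray        # (N,) int, -1 for the root
    node_type: np.ndarray | None = None  # (N,) int SWC structure codes
    class_id: str | None = None
    region_of_node: np.ndarray | None = None  # (N,) object/str

    def __post_init__(self) -> None:
        self.node_ids = np.asarray(self.node_ids, dtype=int)
        self.xyz = np.asarray(self.xyz, dtype=float)
        self.radius = np.asarray(self.radius, dtype=float)
        self.parent_ids = np.asarray(self.parent_ids, dtype=int)
        if self.node_type is None:
            self.node_type = np.full(len(self.node_ids), 2, dtype=int)
        self._validate()

    def _validate(self) -> None:
        ids = self.node_ids
        if len(np.unique(ids)) != len(ids):
            raise ValueError("duplicate node ids")
        if not np.all(np.isfinite(self.xyz)):
            raise ValueError("non-finite coordinates")
        roots = np.flatnonzero(self.parent_ids == -1)
        if len(roots) != 1:
            raise ValueError(f"skeleton must have exactly one root, found {len(roots)}")
        id_set = set(ids.tolist())
        for pid in self.parent_ids:
            if pid != -1 and pid not in id_set:
                raise ValueError(f"orphan parent id {pid}")
        # acyclicity: walk each node to the root
        parent_of = dict(zip(ids.tolist(), self.parent_ids.tolist()))
        for nid in ids.tolist():
            seen = set()
            cur = nid
            while cur != -1:
                if cur in seen:
                    raise ValueError(f"cycle detected at node {nid}")
                seen.add(cur)
                cur = parent_of[cur]

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def edges(self) -> np.ndarray:
        """(E, 2, 3) array of (parent_xyz, child_xyz) for every non-root node."""
        pos = {nid: p for nid, p in zip(self.node_ids.tolist(), self.xyz)}
        out = [
            (pos[pid], pos[nid])
            for nid, pid in zip(self.node_ids.tolist(), self.parent_ids.tolist())
            if pid != -1
        ]
        return np.asarray(out) if out else np.empty((0, 2, 3))

    def tag_regions(self, boxes: dict[str, tuple[np.ndarray, np.ndarray]]) -> None:
        """Label each node with the first region box containing it, else "other"."""
        tags = np.full(self.n_nodes, "other", dtype=object)
        for name, (lo, size) in boxes.items():
            lo = np.asarray(lo, dtype=float)
            hi = lo + np.asarray(size, dtype=float)
            inside = np.all((self.xyz >= lo) & (self.xyz < hi), axis=1)
            tags[inside & (tags == "other")] = name
        self.region_of_node = tags


class SWCParseError(ValueError):
    """Malformed SWC input; the message names the offending line."""


def read_swc(path) -> NeuronSkeleton:
    """Read a 7-column SWC file (``id type x y z radius parent``).

    Comment lines start with ``#``. Raises :class:`SWCParseError` naming the
    line for non-numeric fields, wrong column counts, duplicate ids, orphan
    parents, multiple roots or cycles.
    """
    ids, types, coords, radii, parents = [], [], [], [], []
    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line or line.startswith("#"):
                continue
            parts = line.split()
            if len(parts) != 7:
                raise SWCParseError(f"line {lineno}: expected 7 columns, got {len(parts)}")
            try:
                ids.append(int(parts[0]))
                types.append(int(parts[1]))
                coords.append([float(parts[2]), float(parts[3]), float(parts[4])])
                radii.append(float(parts[5]))
                parents.append(int(parts[6]))
            except ValueError as exc:
                raise SWCParseError(f"line {lineno}: non-numeric field ({exc})") from exc
    if not ids:
        raise SWCParseError("empty SWC file")
    try:
        return NeuronSkeleton(
            node_ids=np.array(ids), xyz=np.array(coords), radius=np.array(radii),
            parent_ids=np.array(parents), node_type=np.array(types),
        )
    except ValueError as exc:
        raise SWCParseError(str(exc)) from exc


def write_swc(skeleton: NeuronSkeleton, path) -> None:
    """Write a skeleton as 7-column SWC with fixed (6-decimal) precision.

    The fixed format makes output byte-reproducible and round-trips
    coordinates to the printed precision.
    """
    with open(path, "w") as fh:
        fh.write("# id type x y z radius parent\n")
        for nid, typ, (x, y, z), r, pid in zip(
            skeleton.node_ids, skeleton.node_type, skeleton.xyz,
            skeleton.radius, skeleton.parent_ids,
        ):
            fh.write(f"{nid} {typ} {x:.6f} {y:.6f} {z:.6f} {r:.6f} {pid}\n")


# ---------------------------------------------------------------------------
# Resampling, voxelization, smoothing, projection
# ---------------------------------------------------------------------------

def resample_skeleton(skeleton: NeuronSkeleton, step: float = 0.5) -> np.ndarray:
    """Midpoints of equal-length sub-segments of every edge.

    Each parent→child edge of length L is divided into ``ceil(L / step)``
    equal pieces (each ≤ ``step`` long) and the piece midpoints are returned
    as an (M, 3) array. Zero-length edges are skipped. Total polyline length
    is preserved: the number of midpoints per edge times the piece length
    equals the edge length.
    """
    if step <= 0:
        raise ValueError("step must be positive")
    mids = []
    for (p, c) in skeleton.edges():
        delta = c - p
        length = float(np.linalg.norm(delta))
        if length == 0.0:
            continue
        n = int(np.ceil(length / step))
        frac = (np.arange(n) + 0.5) / n
        mids.append(p + frac[:, None] * delta[None, :])
    if not mids:
        return np.empty((0, 3))
    return np.concatenate(mids, axis=0)


def voxelize(points: np.ndarray, grid: GridSpec, *, kind: str = "density",
             label: str | None = None) -> VoxelMap:
    """Bin points into voxels by the floor convention.

    Each in-bounds point adds 1 to the voxel containing it; out-of-bounds
    points are counted on the returned map (``n_out_of_bounds``) and logged,
    never fatal.
    """
    points = np.asarray(points, dtype=float).reshape(-1, 3)
    values = np.zeros(grid.shape, dtype=float)
    if len(points):
        idx = np.floor((points - np.asarray(grid.origin)) / grid.voxel_size).astype(int)
        shape = np.asarray(grid.shape)
        in_bounds = np.all((idx >= 0) & (idx < shape), axis=1)
        np.add.at(values, tuple(idx[in_bounds].T), 1.0)
        n_oob = int((~in_bounds).sum())
    else:
        n_oob = 0
    if n_oob:
        logger.warning("voxelize: %d of %d points outside the grid", n_oob, len(points))
    return VoxelMap(grid=grid, values=values, kind=kind, label=label,
                    n_out_of_bounds=n_oob)


def boxcar_smooth(vmap: VoxelMap, width_voxels: int = 9) -> VoxelMap:
    """Convolve with a normalized ``width³`` uniform (boxcar) kernel.

    Boundaries are zero-padded, so mass within ``width // 2`` voxels of an
    edge is attenuated; interior mass is conserved. Width must be odd so the
    kernel is centered.
    """
    if width_voxels % 2 == 0 or width_voxels < 1:
        raise ValueError("boxcar width must be a positive odd integer")
    smoothed = ndimage.uniform_filter(vmap.values, size=width_voxels, mode="constant", cval=0.0)
    return replace(vmap, values=smoothed)


def project2d(vmap: VoxelMap, axis: str = "z") -> np.ndarray:
    """Integrate columns of voxels along a world axis; sums are conserved."""
    if axis not in _AXES:
        raise ValueError(f"axis must be one of {sorted(_AXES)}")
    return vmap.values.sum(axis=_AXES[axis])


# ---------------------------------------------------------------------------
# Per-neuron and per-class density maps
# ---------------------------------------------------------------------------

def density_map(skeleton: NeuronSkeleton, grid: GridSpec, *, step: float = 0.5,
                boxcar_width: int = 9, smooth: bool = True) -> VoxelMap:
    """Full pipeline for one skeleton: resample → voxelize → (boxcar smooth)."""
    mids = resample_skeleton(skeleton, step=step)
    vmap = voxelize(mids, grid, kind="density", label=skeleton.class_id)
    if smooth:
        vmap = boxcar_smooth(vmap, boxcar_width)
    return vmap


def class_density_maps(skeletons_by_class: dict[str, list[NeuronSkeleton]],
                       grid: GridSpec, *, step: float = 0.5, boxcar_width: int = 9,
                       pick: str = "mean") -> dict[str, VoxelMap]:
    """One representative density map per neuron class.

    With ``pick="mean"`` (default) the unsmoothed histograms of all sister
    skeletons of a class are averaged before smoothing; ``pick="first"``
    mimics single-exemplar use by taking the first skeleton only.
    """
    if pick not in ("mean", "first"):
        raise ValueError("pick must be 'mean' or 'first'")
    out: dict[str, VoxelMap] = {}
    for class_id, skels in skeletons_by_class.items():
        chosen = skels[:1] if pick == "first" else skels
        raw = [voxelize(resample_skeleton(s, step=step), grid) for s in chosen]
        mean_values = np.mean([m.values for m in raw], axis=0)
        vmap = VoxelMap(grid=grid, values=mean_values, kind="density", label=class_id)
        out[class_id] = boxcar_smooth(vmap, boxcar_width)
    return out


def density_map_similarity(maps: dict[str, VoxelMap]):
    """Correlation-distance matrix between density maps plus a Ward dendrogram.

    Maps must share a grid. A constant (zero-variance) map has undefined
    correlation; its distance to every other map is defined as 1 with a
    logged warning.

    Returns ``(DistanceMatrix, Dendrogram)`` from :mod:`olfmap.odor_space`.
    """
    from . import odor_space  # deferred: odor_space is independent of morphology

    labels = list(maps)
    grids = {maps[k].grid for k in labels}
    if len(grids) != 1:
        raise ValueError("all maps must share a GridSpec")
    flat = np.stack([maps[k].values.ravel() for k in labels])
    dmat = odor_space.correlation_distance_rows(flat, labels)
    dend = odor_space.hierarchical_cluster(dmat)
    return dmat, dend
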