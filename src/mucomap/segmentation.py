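"""Airway lumen and mucus segmentation.

The airway interior is found with a marker-constrained watershed: lumen and
background seed markers flood the gradient magnitude of a Gaussian-smoothed
volume, which places the airway/tissue boundary on the gradient ridge.
Because intraluminal mucus sits in its own gradient basin (bounded by the
air|mucus and mucus|tissue edges), mucus voxels are recovered afterwards by
band binarisation restricted to components touching the watershed air
region; the airway interior is the union of both.  The interior is then
decomposed into branch labels by skeleton branch-point splitting and
nearest-skeleton-branch assignment, recording parent/child adjacency.

Mucus is segmented inside the airway interior by intensity-band
binarisation (multi-Otsu by default) followed by morphological opening,
closing and small-component removal.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.filters import threshold_multiotsu
from skimage.morphology import ball
from skimage.segmentation import watershed

from .cross_section import SkeletonGraph, skeletonize

__all__ = [
    "Marker",
    "MarkerSet",
    "MucusSegParams",
    "LumenLabelMap",
    "segment_lumen",
    "segment_mucus",
    "exclude_unconnected",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)


@dataclass(frozen=True)
class Marker:
    marker_id: int
    position: tuple[int, int, int]  # (z, y, x)
    role: str  # "lumen-seed" | "background-seed"

    def __post_init__(self):
        if self.role not in ("lumen-seed", "background-seed"):
            raise ValueError(f"unknown marker role {self.role!r}")


@dataclass(frozen=True)
class MarkerSet:
    markers: tuple[Marker, ...]

    def __post_init__(self):
        object.__setattr__(self, "markers", tuple(self.markers))

    def validate(self, shape: tuple[int, int, int]) -> None:
        if not any(m.role == "lumen-seed" for m in self.markers):
            raise ValueError("marker set must contain at least one lumen-seed")
        for m in self.markers:
            if any(not 0 <= c < s for c, s in zip(m.position, shape)):
                raise ValueError(
                    f"marker {m.marker_id} at {m.position} outside volume {shape}"
                )

    def lumen_seeds(self) -> list[tuple[int, int, int]]:
        return [m.position for m in self.markers if m.role == "lumen-seed"]

    def background_seeds(self) -> list[tuple[int, int, int]]:
        return [m.position for m in self.markers if m.role == "background-seed"]


@dataclass(frozen=True)
class MucusSegParams:
    """Binarisation band and morphology settings for mucus segmentation.

    ``threshold_mode`` is "otsu" (multi-Otsu, 3 classes; the middle band is
    mucus) or "fixed" with an explicit (lo, hi) gray band.  Defaults are
    artifact choices, all configurable.
    """

    threshold_mode: str = "otsu"
    band: tuple[float, float] | None = None
    opening_radius: int = 1
    closing_radius: int = 2
    min_component_size: int = 27
    smoothing_sigma: float = 1.0

    def __post_init__(self):
        if self.threshold_mode not in ("otsu", "fixed"):
            raise ValueError(f"unknown threshold_mode {self.threshold_mode!r}")
        if self.threshold_mode == "fixed" and self.band is None:
            raise ValueError("fixed threshold_mode requires a (lo, hi) band")
        if self.opening_radius < 0 or self.closing_radius < 0:
            raise ValueError("morphology radii must be >= 0")
        if self.min_component_size < 1:
            raise ValueError("min_component_size must be >= 1")


@dataclass
class LumenLabelMap:
    """Branch-labelled airway interior.

    ``labels`` assigns contiguous integer branch labels (0 = background) that
    partition the interior mask; ``parent`` records branch adjacency as a
    child -> parent mapping (root maps to None).
    """

    labels: np.ndarray
    parent: dict[int, int | None]
    skeleton: SkeletonGraph | None = None

    @property
    def mask(self) -> np.ndarray:
        return self.labels > 0

    @property
    def branch_ids(self) -> list[int]:
        return sorted(self.parent)


def _branch_decompose(mask: np.ndarray, root_point: tuple[int, int, int]) -> LumenLabelMap:
    """Split a mask into branch labels via its skeleton branch points."""
    skel = skeletonize(mask)
    skel_img = np.zeros(mask.shape, dtype=np.int32)
    for bid, path in skel.paths.items():
        for idx in path:
            skel_img[tuple(skel.nodes[idx])] = bid

    # junction nodes (branch_id -1) inherit the smallest neighbouring branch
    # id so every skeleton voxel carries a label for nearest-branch assignment
    node_adjacency = {i: set() for i in range(len(skel.nodes))}
    for a, b in skel.edges:
        node_adjacency[a].add(b)
        node_adjacency[b].add(a)
    # junction voxels can form 26-connected clusters; treat each cluster as
    # one branch point touching every adjacent branch path
    junctions = set(np.nonzero(skel.branch_id == -1)[0].tolist())
    junction_touch: dict[int, set[int]] = {}
    unvisited = set(junctions)
    cluster_id = 0
    while unvisited:
        start = unvisited.pop()
        cluster = {start}
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in node_adjacency[int(cur)]:
                if nb in unvisited:
                    unvisited.discard(nb)
                    cluster.add(nb)
                    stack.append(nb)
        neigh = {
            int(skel.branch_id[k])
            for j in cluster
            for k in node_adjacency[int(j)]
            if skel.branch_id[k] > 0
        }
        junction_touch[cluster_id] = neigh
        cluster_id += 1
        fill = min(neigh) if neigh else 0
        for j in cluster:
            skel_img[tuple(skel.nodes[j])] = fill

    on_skel = skel_img > 0
    if not np.any(on_skel):
        labels = np.where(mask, 1, 0).astype(np.int32)
        return LumenLabelMap(labels, {1: None}, skel)
    _, (iz, iy, ix) = ndimage.distance_transform_edt(~on_skel, return_indices=True)
    labels = np.zeros(mask.shape, dtype=np.int32)
    labels[mask] = skel_img[iz[mask], iy[mask], ix[mask]]

    # relabel contiguously
    ids = np.unique(labels[labels > 0])
    remap = {int(old): new for new, old in enumerate(ids, start=1)}
    out = np.zeros_like(labels)
    for old, new in remap.items():
        out[labels == old] = new

    # adjacency between branches: direct skeleton edges and shared junctions
    adjacency: dict[int, set[int]] = {remap[int(i)]: set() for i in ids}
    for a, b in skel.edges:
        la, lb = int(skel.branch_id[a]), int(skel.branch_id[b])
        if la > 0 and lb > 0 and la != lb and la in remap and lb in remap:
            adjacency[remap[la]].add(remap[lb])
            adjacency[remap[lb]].add(remap[la])
    for neigh in junction_touch.values():
        mapped = sorted(remap[b] for b in neigh if b in remap)
        for a in mapped:
            for b in mapped:
                if a != b:
                    adjacency[a].add(b)

    labels = out
    root_label = int(labels[tuple(root_point)])
    if root_label == 0:
        present = np.unique(labels[labels > 0])
        root_label = int(present[0]) if present.size else 0
    parent: dict[int, int | None] = {}
    if root_label:
        parent[root_label] = None
        frontier = [root_label]
        seen = {root_label}
        while frontier:
            nxt = []
            for cur in frontier:
                for nb in sorted(adjacency.get(cur, ())):
                    if nb not in seen:
                        seen.add(nb)
                        parent[nb] = cur
                        nxt.append(nb)
            frontier = nxt
        for bid in adjacency:
            if bid not in parent:
                parent[bid] = None  # disconnected piece
    return LumenLabelMap(labels, parent, skel)


def segment_lumen(
    volume: np.ndarray,
    markers: MarkerSet,
    sigma: float = 1.0,
    max_fill_fraction: float = 0.5,
) -> LumenLabelMap:
    """Marked-watershed airway segmentation with branch decomposition.

    Raises if the marker set has no lumen seed or the flooded airway region
    exceeds ``max_fill_fraction`` of the volume (suggesting marker revision).
    """
    markers.validate(volume.shape)
    smooth = ndimage.gaussian_filter(volume.astype(float), sigma)
    grad = ndimage.gaussian_gradient_magnitude(volume.astype(float), sigma)
    t_lo, t_hi = threshold_multiotsu(smooth, classes=3)

    marker_img = np.zeros(volume.shape, dtype=np.int32)
    for pos in markers.lumen_seeds():
        marker_img[pos] = 1
    bg = markers.background_seeds()
    if not bg:
        # fall back to the volume corners, which are tissue in this contrast
        zc, yc, xc = (s - 1 for s in volume.shape)
        bg = [(0, 0, 0), (0, 0, xc), (0, yc, 0), (zc, 0, 0), (zc, yc, xc)]
    for pos in bg:
        if marker_img[pos] == 0:
            marker_img[pos] = 2

    # air basins fully occluded by mucus are unreachable from the user seeds;
    # promote solid dark regions to additional lumen markers before flooding
    dark = smooth < t_lo
    dark_lab, n_dark = ndimage.label(dark, structure=_STRUCT26)
    if n_dark:
        sizes = np.bincount(dark_lab.ravel())
        keep = np.nonzero(sizes >= 27)[0]
        solid = np.isin(dark_lab, keep[keep > 0])
        marker_img[solid & (marker_img == 0)] = 1
    ws = watershed(grad, markers=marker_img)
    air = ws == 1
    if air.sum() > max_fill_fraction * volume.size:
        raise ValueError(
            "watershed flooded more than "
            f"{max_fill_fraction:.0%} of the volume; revise the seed markers"
        )

    # recover intraluminal mucus: intermediate-band components touching air.
    # Opening suppresses the one-voxel partial-volume shell that the band
    # picks up along every air/tissue boundary.
    band = (smooth > t_lo) & (smooth < t_hi)
    band = ndimage.binary_opening(band, structure=ball(1))
    cand = band | air
    lab, _ = ndimage.label(cand, structure=_STRUCT26)
    air_labels = np.unique(lab[air])
    air_labels = air_labels[air_labels > 0]
    interior = np.isin(lab, air_labels)

    # keep only the component(s) reachable from the lumen seeds
    lab2, _ = ndimage.label(interior, structure=_STRUCT26)
    seed_labels = {int(lab2[pos]) for pos in markers.lumen_seeds() if lab2[pos] > 0}
    if not seed_labels:
        raise ValueError("no lumen seed falls inside the segmented airway interior")
    interior = np.isin(lab2, sorted(seed_labels))

    root_point = markers.lumen_seeds()[0]
    return _branch_decompose(interior, root_point)


def segment_mucus(
    volume: np.ndarray,
    interior: np.ndarray,
    params: MucusSegParams = MucusSegParams(),
) -> np.ndarray:
    """Mucus mask inside the airway interior.

    Band binarisation on the (optionally smoothed) volume, restricted to the
    interior, then opening, closing and 26-connected small-component removal.
    """
    if not np.any(interior):
        raise ValueError("airway interior mask is empty")
    if volume.shape != interior.shape:
        raise ValueError("volume and interior mask must have the same shape")
    img = volume.astype(float)
    if params.smoothing_sigma > 0:
        img = ndimage.gaussian_filter(img, params.smoothing_sigma)
    if params.threshold_mode == "fixed":
        lo, hi = params.band
    else:
        lo, hi = threshold_multiotsu(img, classes=3)
    mucus = (img > lo) & (img < hi) & interior
    if params.opening_radius > 0:
        mucus = ndimage.binary_opening(mucus, structure=ball(params.opening_radius))
    if params.closing_radius > 0:
        mucus = ndimage.binary_closing(mucus, structure=ball(params.closing_radius))
    mucus &= interior
    lab, n = ndimage.label(mucus, structure=_STRUCT26)
    if n:
        sizes = np.bincount(lab.ravel())
        small = np.nonzero(sizes < params.min_component_size)[0]
        mucus[np.isin(lab, small[small > 0])] = False
    return mucus


def exclude_unconnected(
    mask: np.ndarray, seed_region: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Partition a mask into seed-reachable and unreachable parts.

    Components are 26-connected; the returned (connected, excluded) masks are
    disjoint and their union equals the input mask.
    """
    seed = np.asarray(seed_region, dtype=bool)
    if not np.any(seed & mask):
        raise ValueError("seed region is disjoint from the mask")
    lab, _ = ndimage.label(mask, structure=_STRUCT26)
    keep = np.unique(lab[seed & mask])
    keep = keep[keep > 0]
    connected = np.isin(lab, keep)
    return connected, mask & ~connected
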