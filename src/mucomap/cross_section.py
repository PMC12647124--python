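"""Airway cross-section extraction: slice, skeleton and geodesic methods.

All three methods produce comparable :class:`CrossSectionRecord` objects
carrying integer voxel counts (lumen, wall perimeter, mucus, mucus-on-wall),
so downstream ratio computation is identical regardless of method.

* slice — original z-planes of the branch label map; no resampling.
* skeleton — planes orthogonal to the local tangent of a topology-preserving
  3-D skeleton, sampled at voxel pitch by nearest-neighbour lookup.  Nodes at
  bifurcations (degree >= 3) emit no record.
* geodesic — level-set bins of the chamfer-weighted geodesic distance from a
  seed slice; records are non-planar (the area ratio is effectively a volume
  ratio) and mask components unreachable from the seed are excluded.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from skimage.graph import MCP_Geometric
from skimage.morphology import skeletonize as _sk_skeletonize

__all__ = [
    "CrossSectionRecord",
    "SkeletonGraph",
    "slice_cross_sections",
    "skeletonize",
    "skeleton_cross_sections",
    "geodesic_cross_sections",
    "perimeter_mask",
    "main_branch_seed_slice",
]

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)
_OFFSETS26 = np.array(
    [
        (dz, dy, dx)
        for dz in (-1, 0, 1)
        for dy in (-1, 0, 1)
        for dx in (-1, 0, 1)
        if (dz, dy, dx) != (0, 0, 0)
    ]
)


@dataclass
class CrossSectionRecord:
    """One airway cross-section with its voxel counts.

    ``lumen_count`` counts airway-interior voxels (air + mucus) of the
    station; ``perimeter_count`` the wall-adjacent subset; ``mucus_count``
    and ``mucus_perimeter_count`` the mucus-occupied subsets of each.
    ``voxels`` optionally holds (n, 3) integer voxel coordinates for map
    rendering (rounded plane samples for the skeleton method).
    """

    method: str
    branch_id: int
    station: int
    lumen_count: int
    perimeter_count: int
    mucus_count: int
    mucus_perimeter_count: int
    planar: bool
    voxels: np.ndarray | None = None
    node: tuple[int, int, int] | None = None

    def __post_init__(self):
        if self.lumen_count < 1:
            raise ValueError("cross-section lumen set must be non-empty")
        if self.mucus_count > self.lumen_count:
            raise ValueError("mucus set must be a subset of the lumen set")
        if self.perimeter_count > self.lumen_count:
            raise ValueError("perimeter set must be a subset of the lumen set")
        if self.mucus_perimeter_count > min(self.perimeter_count, self.mucus_count):
            raise ValueError("inconsistent mucus-on-perimeter count")


def perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Wall perimeter: mask voxels with a 6-neighbour outside the mask."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return mask & ~eroded


def _grouped_records(
    method: str,
    coords: np.ndarray,
    branch_ids: np.ndarray,
    stations: np.ndarray,
    mucus_vals: np.ndarray,
    perim_vals: np.ndarray,
    planar: bool,
    keep_voxels: bool,
) -> list[CrossSectionRecord]:
    """Group voxels by (branch, station) and emit one record per group."""
    order = np.lexsort((stations, branch_ids))
    coords = coords[order]
    branch_ids = branch_ids[order]
    stations = stations[order]
    mucus_vals = mucus_vals[order]
    perim_vals = perim_vals[order]
    keys = np.stack([branch_ids, stations], axis=1)
    boundaries = np.nonzero(np.any(np.diff(keys, axis=0) != 0, axis=1))[0] + 1
    starts = np.concatenate([[0], boundaries])
    ends = np.concatenate([boundaries, [len(keys)]])
    records = []
    for s, e in zip(starts, ends):
        records.append(
            CrossSectionRecord(
                method=method,
                branch_id=int(branch_ids[s]),
                station=int(stations[s]),
                lumen_count=int(e - s),
                perimeter_count=int(np.sum(perim_vals[s:e])),
                mucus_count=int(np.sum(mucus_vals[s:e])),
                mucus_perimeter_count=int(np.sum(perim_vals[s:e] & mucus_vals[s:e])),
                planar=planar,
                voxels=coords[s:e].copy() if keep_voxels else None,
            )
        )
    return records


def slice_cross_sections(
    labels: np.ndarray,
    mucus: np.ndarray,
    keep_voxels: bool = False,
) -> list[CrossSectionRecord]:
    """One record per (z-plane, branch label); the station index is z."""
    if labels.shape != mucus.shape:
        raise ValueError("label map and mucus mask must have the same shape")
    coords = np.argwhere(labels > 0)
    if coords.size == 0:
        return []
    idx = tuple(coords.T)
    perim = perimeter_mask(labels > 0)
    return _grouped_records(
        "slice",
        coords,
        labels[idx],
        coords[:, 0],
        mucus[idx],
        perim[idx],
        planar=True,
        keep_voxels=keep_voxels,
    )


@dataclass
class SkeletonGraph:
    """Voxel-centred centerline graph.

    ``nodes`` are skeleton voxel coordinates; ``branch_id`` assigns each node
    to a skeleton branch (-1 for junction nodes of degree >= 3); ``paths``
    maps branch ids to ordered node-index sequences; ``tangent`` holds local
    unit tangents (NaN where undefined).
    """

    nodes: np.ndarray  # (n, 3) int
    degree: np.ndarray  # (n,) int
    branch_id: np.ndarray  # (n,) int, -1 at junctions
    tangent: np.ndarray  # (n, 3) float
    paths: dict[int, list[int]]
    edges: list[tuple[int, int]]

    def __len__(self) -> int:
        return len(self.nodes)


def skeletonize(mask: np.ndarray) -> SkeletonGraph:
    """Topology-preserving 3-D thinning plus branch decomposition.

    Junction nodes (degree >= 3) split the skeleton into branch paths;
    tangents are central differences over a 5-node window (one-sided at path
    ends) along each path.
    """
    if not np.any(mask):
        raise ValueError("cannot skeletonize an empty mask")
    skel = _sk_skeletonize(mask.astype(bool))
    # thinning can annihilate perfectly symmetric even-width components;
    # guarantee at least one skeleton voxel per mask component (deepest voxel)
    comp_lab, n_comp = ndimage.label(mask, structure=_STRUCT26)
    if n_comp:
        have = np.unique(comp_lab[skel])
        missing = sorted(set(range(1, n_comp + 1)) - set(int(v) for v in have))
        if missing:
            edt = ndimage.distance_transform_edt(mask)
            for comp_id in missing:
                comp_edt = np.where(comp_lab == comp_id, edt, -1.0)
                skel[np.unravel_index(np.argmax(comp_edt), mask.shape)] = True
    nodes = np.argwhere(skel)
    index_of = {tuple(p): i for i, p in enumerate(map(tuple, nodes))}
    n = len(nodes)
    adjacency: list[list[int]] = [[] for _ in range(n)]
    edges: list[tuple[int, int]] = []
    for i, p in enumerate(nodes):
        for off in _OFFSETS26:
            q = tuple(p + off)
            j = index_of.get(q)
            if j is not None and j > i:
                adjacency[i].append(j)
                adjacency[j].append(i)
                edges.append((i, j))
    degree = np.array([len(a) for a in adjacency])

    branch_id = np.full(n, -1, dtype=int)
    is_junction = degree >= 3
    # connected components of the skeleton minus junction nodes = branch paths
    paths: dict[int, list[int]] = {}
    visited = np.zeros(n, dtype=bool)
    next_id = 1
    for start in range(n):
        if visited[start] or is_junction[start]:
            continue
        comp = [start]
        visited[start] = True
        stack = [start]
        while stack:
            cur = stack.pop()
            for nb in adjacency[cur]:
                if not visited[nb] and not is_junction[nb]:
                    visited[nb] = True
                    comp.append(nb)
                    stack.append(nb)
        ordered = _order_path(comp, adjacency, is_junction)
        for node_idx in ordered:
            branch_id[node_idx] = next_id
        paths[next_id] = ordered
        next_id += 1

    tangent = np.full((n, 3), np.nan)
    for ordered in paths.values():
        pts = nodes[ordered].astype(float)
        m = len(ordered)
        for k in range(m):
            a = max(k - 2, 0)
            b = min(k + 2, m - 1)
            if a == b:
                continue
            vec = pts[b] - pts[a]
            nrm = np.linalg.norm(vec)
            if nrm > 0:
                tangent[ordered[k]] = vec / nrm
    return SkeletonGraph(nodes, degree, branch_id, tangent, paths, edges)


def _order_path(
    comp: list[int], adjacency: list[list[int]], is_junction: np.ndarray
) -> list[int]:
    """Order a junction-free component by walking from an endpoint."""
    comp_set = set(comp)
    sub_deg = {i: sum(1 for nb in adjacency[i] if nb in comp_set) for i in comp}
    start = next((i for i in comp if sub_deg[i] <= 1), comp[0])
    ordered = [start]
    seen = {start}
    cur = start
    while True:
        nxt = next(
            (nb for nb in adjacency[cur] if nb in comp_set and nb not in seen), None
        )
        if nxt is None:
            break
        ordered.append(nxt)
        seen.add(nxt)
        cur = nxt
    # small cycles or Y-shaped residue: append stragglers in stable order
    for i in comp:
        if i not in seen:
            ordered.append(i)
            seen.add(i)
    return ordered


def _plane_basis(tangent: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(tangent, ref))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(tangent, ref)
    u /= np.linalg.norm(u)
    v = np.cross(tangent, u)
    return u, v


def skeleton_cross_sections(
    mask: np.ndarray,
    skeleton: SkeletonGraph,
    mucus: np.ndarray,
    keep_voxels: bool = False,
) -> list[CrossSectionRecord]:
    """Orthogonal cross-sections at non-junction skeleton nodes.

    At each node the plane orthogonal to the local tangent is sampled on a
    voxel-pitch grid by nearest-neighbour lookup; the record's lumen set is
    the 4-connected in-plane region containing the node.  Nodes without a
    defined tangent are skipped (their count is reported via logging by the
    pipeline layer); junction nodes emit no record by design.
    """
    if mask.shape != mucus.shape:
        raise ValueError("mask and mucus mask must have the same shape")
    mask_u8 = mask.astype(np.uint8)
    mucus_u8 = mucus.astype(np.uint8)
    edt = ndimage.distance_transform_edt(mask)
    max_extent = int(np.ceil(np.linalg.norm(mask.shape)))
    records: list[CrossSectionRecord] = []
    skipped = 0
    for bid, path in skeleton.paths.items():
        for station, node_idx in enumerate(path):
            tangent = skeleton.tangent[node_idx]
            if not np.all(np.isfinite(tangent)):
                skipped += 1
                continue
            node = skeleton.nodes[node_idx].astype(float)
            extent = int(np.ceil(3.0 * edt[tuple(skeleton.nodes[node_idx])])) + 4
            result = None
            while result is None:
                result = _sample_plane(
                    mask_u8, mucus_u8, node, tangent, extent
                )
                if result is None:
                    extent *= 2
                    if extent > max_extent:
                        break
            if result is None or result[0] == 0:
                skipped += 1
                continue
            lumen_n, per_n, muc_n, muc_per_n, vox = result
            records.append(
                CrossSectionRecord(
                    method="skeleton",
                    branch_id=int(bid),
                    station=station,
                    lumen_count=lumen_n,
                    perimeter_count=per_n,
                    mucus_count=muc_n,
                    mucus_perimeter_count=muc_per_n,
                    planar=True,
                    voxels=vox if keep_voxels else None,
                    node=tuple(int(c) for c in skeleton.nodes[node_idx]),
                )
            )
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "skeleton method: skipped %d nodes without usable tangent/plane", skipped
        )
    return records


def _sample_plane(
    mask_u8: np.ndarray,
    mucus_u8: np.ndarray,
    node: np.ndarray,
    tangent: np.ndarray,
    extent: int,
):
    """Sample the orthogonal plane; None if the lumen region hits the border."""
    u, v = _plane_basis(tangent)
    rng = np.arange(-extent, extent + 1)
    ii, jj = np.meshgrid(rng, rng, indexing="ij")
    pts = (
        node[None, None, :]
        + ii[..., None] * u[None, None, :]
        + jj[..., None] * v[None, None, :]
    )
    coords = np.round(pts).astype(int)
    shape = mask_u8.shape
    in_bounds = np.all((coords >= 0) & (coords < np.array(shape)), axis=-1)
    plane = np.zeros(ii.shape, dtype=bool)
    cb = coords[in_bounds]
    plane[in_bounds] = mask_u8[cb[:, 0], cb[:, 1], cb[:, 2]].astype(bool)
    lab, _ = ndimage.label(plane, structure=ndimage.generate_binary_structure(2, 1))
    centre_label = lab[extent, extent]
    if centre_label == 0:
        # node rounded off-lumen (thin structures): take nearest labelled pixel
        fg = np.argwhere(lab > 0)
        if fg.size == 0:
            return (0, 0, 0, 0, None)
        d2 = np.sum((fg - np.array([extent, extent])) ** 2, axis=1)
        centre_label = lab[tuple(fg[np.argmin(d2)])]
    region = lab == centre_label
    # grow the grid until the region clears the border
    border = np.zeros_like(region)
    border[0, :] = border[-1, :] = border[:, 0] = border[:, -1] = True
    if np.any(region & border):
        return None
    mucus_plane = np.zeros(ii.shape, dtype=bool)
    mucus_plane[in_bounds] = mucus_u8[cb[:, 0], cb[:, 1], cb[:, 2]].astype(bool)
    mucus_plane &= region
    per = region & ~ndimage.binary_erosion(
        plane, structure=ndimage.generate_binary_structure(2, 1), border_value=0
    )
    lumen_n = int(np.sum(region))
    if lumen_n == 0:
        return (0, 0, 0, 0, None)
    vox = np.unique(coords[region], axis=0)
    return (
        lumen_n,
        int(np.sum(per)),
        int(np.sum(mucus_plane)),
        int(np.sum(per & mucus_plane)),
        vox,
    )


def main_branch_seed_slice(labels: np.ndarray) -> np.ndarray:
    """Default geodesic seed: lowest-z slice intersecting the largest branch."""
    ids, counts = np.unique(labels[labels > 0], return_counts=True)
    if ids.size == 0:
        raise ValueError("label map is empty")
    main_id = int(ids[np.argmax(counts)])
    zs = np.nonzero(np.any(labels == main_id, axis=(1, 2)))[0]
    z0 = int(zs.min())
    seed = np.zeros(labels.shape, dtype=bool)
    seed[z0] = labels[z0] > 0
    return seed


def geodesic_cross_sections(
    mask: np.ndarray,
    seed: np.ndarray | int,
    mucus: np.ndarray,
    bin_width: float = 1.0,
    labels: np.ndarray | None = None,
    keep_voxels: bool = False,
) -> tuple[list[CrossSectionRecord], np.ndarray]:
    """Level-set bins of the in-mask geodesic distance from a seed region.

    The distance is computed on the 26-neighbour graph with chamfer weights
    (1, sqrt 2, sqrt 3); voxels are binned by ``floor(distance / bin_width)``
    and grouped by branch label (all voxels form one branch when ``labels``
    is None).  Returns the records and the excluded mask of voxels
    unreachable from the seed.
    """
    if mask.shape != mucus.shape:
        raise ValueError("mask and mucus mask must have the same shape")
    if bin_width <= 0:
        raise ValueError("bin_width must be > 0")
    if isinstance(seed, (int, np.integer)):
        seed_mask = np.zeros(mask.shape, dtype=bool)
        seed_mask[int(seed)] = mask[int(seed)]
    else:
        seed_mask = np.asarray(seed, dtype=bool) & mask
    if not np.any(seed_mask):
        raise ValueError("seed region is disjoint from the mask")

    costs = np.where(mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    dist, _ = mcp.find_costs(np.argwhere(seed_mask))
    reachable = mask & np.isfinite(dist)
    excluded = mask & ~reachable

    coords = np.argwhere(reachable)
    idx = tuple(coords.T)
    stations = np.floor(dist[idx] / bin_width).astype(int)
    if labels is not None:
        branch_ids = labels[idx].astype(int)
    else:
        branch_ids = np.ones(len(coords), dtype=int)
    perim = perimeter_mask(mask)
    records = _grouped_records(
        "geodesic",
        coords,
        branch_ids,
        stations,
        mucus[idx],
        perim[idx],
        planar=False,
        keep_voxels=keep_voxels,
    )
    return records, excluded
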