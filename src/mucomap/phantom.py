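"""Synthetic airway-tree phantoms with programmable mucus deposits.

Voxel phantoms of monopodial branching airway trees are built from an
explicit :class:`TreeSpec` (branch axes, radii, generations, lobes).  Mucus
is carved into the lumen as plug / crescent / annulus deposits defined in
polar coordinates about the true branch axis, and exact per-station
ground-truth area and contact ratios are computed by voxel counting, so
every downstream stage of the analysis can be validated against known
truth.  Phantom intensity volumes emulate osmium-stained lung contrast:
dark air-filled lumen, intermediate mucus, bright tissue.

All generators are pure functions of their inputs and an explicit seed.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage

__all__ = [
    "LOBES",
    "LEVEL_AIR",
    "LEVEL_MUCUS",
    "LEVEL_TISSUE",
    "Branch",
    "TreeSpec",
    "Deposit",
    "TreePhantom",
    "PhantomGroundTruth",
    "build_tree_volume",
    "carve_mucus",
    "render_intensity",
    "generate_cohort_ratio_table",
    "generate_score_table",
    "deposit_for_ratios",
]

LOBES = ("RUL", "RML", "RLL", "RCL", "LL")

# Nominal gray levels on the unit scale (artifact constants chosen so that
# multi-Otsu thresholds separate the three classes at noise sd <= 0.1).
LEVEL_AIR = 0.10
LEVEL_MUCUS = 0.60
LEVEL_TISSUE = 0.85

_STRUCT26 = np.ones((3, 3, 3), dtype=bool)
_STRUCT6 = ndimage.generate_binary_structure(3, 1)


@dataclass(frozen=True)
class Branch:
    """One airway branch: a cylinder along ``direction`` from ``origin``.

    ``origin`` is in voxel coordinates (z, y, x); ``length`` and ``radius``
    are metric (µm) and are converted with the phantom voxel size.
    """

    branch_id: int
    parent_id: int | None
    origin: tuple[float, float, float]
    direction: tuple[float, float, float]
    length: float
    radius: float
    generation: int
    lobe: str

    def unit_direction(self) -> np.ndarray:
        d = np.asarray(self.direction, dtype=float)
        nrm = np.linalg.norm(d)
        if nrm == 0:
            raise ValueError(f"branch {self.branch_id}: zero direction vector")
        return d / nrm


@dataclass(frozen=True)
class TreeSpec:
    """A validated collection of branches forming one rooted tree."""

    branches: tuple[Branch, ...]

    def __post_init__(self):
        object.__setattr__(self, "branches", tuple(self.branches))
        self._validate()

    def _validate(self) -> None:
        ids = [b.branch_id for b in self.branches]
        if len(set(ids)) != len(ids):
            raise ValueError("branch_ids must be unique")
        by_id = {b.branch_id: b for b in self.branches}
        roots = [b for b in self.branches if b.parent_id is None]
        if self.branches and len(roots) != 1:
            raise ValueError(f"expected exactly one root branch, found {len(roots)}")
        for b in self.branches:
            if b.radius <= 0:
                raise ValueError(f"branch {b.branch_id}: radius must be > 0")
            if b.length <= 0:
                raise ValueError(f"branch {b.branch_id}: length must be > 0")
            if not 1 <= b.generation <= 11:
                raise ValueError(
                    f"branch {b.branch_id}: generation {b.generation} outside 1-11"
                )
            if b.lobe not in LOBES:
                raise ValueError(f"branch {b.branch_id}: unknown lobe {b.lobe!r}")
            if b.parent_id is not None:
                if b.parent_id not in by_id:
                    raise ValueError(
                        f"branch {b.branch_id}: unknown parent {b.parent_id}"
                    )
                parent = by_id[b.parent_id]
                if b.generation != parent.generation + 1:
                    raise ValueError(
                        f"branch {b.branch_id}: generation must be parent's + 1"
                    )

    def __len__(self) -> int:
        return len(self.branches)

    def branch(self, branch_id: int) -> Branch:
        for b in self.branches:
            if b.branch_id == branch_id:
                return b
        raise KeyError(branch_id)


@dataclass(frozen=True)
class Deposit:
    """One mucus deposit on a branch.

    ``axial_span`` is a pair of fractional positions along the branch axis.
    ``kind`` is plug (full occlusion), crescent (angular sector against the
    wall) or annulus (full ring against the wall).  Crescent radial extent is
    driven either by ``thickness`` (voxels inward from the wall) or, when
    ``thickness`` is None, by ``fill_fraction`` (target area fraction of the
    disc); see :func:`deposit_for_ratios`.
    """

    branch_id: int
    axial_span: tuple[float, float]
    kind: str
    fill_fraction: float | None = None
    angular_coverage: float = 360.0
    thickness: float | None = None
    angle_offset: float = 0.0

    def __post_init__(self):
        lo, hi = self.axial_span
        if not (0.0 <= lo < hi <= 1.0):
            raise ValueError(f"axial_span {self.axial_span} not an ordered pair in [0,1]")
        if self.kind not in ("plug", "crescent", "annulus"):
            raise ValueError(f"unknown deposit kind {self.kind!r}")
        if not 0.0 <= self.angular_coverage <= 360.0:
            raise ValueError("angular_coverage outside [0, 360]")
        if self.fill_fraction is not None and not 0.0 <= self.fill_fraction <= 1.0:
            raise ValueError("fill_fraction outside [0, 1]")
        if self.kind == "plug" and self.fill_fraction not in (None, 1.0):
            raise ValueError("plug deposits require fill_fraction = 1")
        if self.kind == "annulus" and self.angular_coverage != 360.0:
            raise ValueError("annulus deposits require angular_coverage = 360")
        if self.kind in ("crescent", "annulus"):
            if self.thickness is None and self.fill_fraction is None:
                raise ValueError(f"{self.kind} deposit needs thickness or fill_fraction")


def deposit_for_ratios(
    branch_id: int,
    area_fraction: float,
    contact_fraction: float,
    axial_span: tuple[float, float] = (0.0, 1.0),
) -> Deposit:
    """Deposit whose programmed area and wall-contact fractions are given.

    A wall-adherent angular sector provides the contact fraction; when the
    requested area exceeds the sector area a concentric core (clear of the
    wall) makes up the difference.  ``area_fraction`` = 1 forces a plug.
    """
    if not 0.0 < contact_fraction <= 1.0:
        raise ValueError("contact_fraction must be in (0, 1]")
    if not 0.0 < area_fraction <= 1.0:
        raise ValueError("area_fraction must be in (0, 1]")
    if area_fraction >= 1.0:
        return Deposit(branch_id, axial_span, "plug", fill_fraction=1.0)
    kind = "annulus" if contact_fraction >= 1.0 else "crescent"
    return Deposit(
        branch_id,
        axial_span,
        kind,
        fill_fraction=area_fraction,
        angular_coverage=360.0 * contact_fraction,
    )


@dataclass
class TreePhantom:
    """Digitised tree: lumen mask, branch label map and true centerlines."""

    lumen: np.ndarray  # bool (z, y, x)
    labels: np.ndarray  # int32, 0 = background
    centerline: dict[int, np.ndarray]  # branch_id -> (n, 3) polyline, voxel coords
    spec: TreeSpec
    voxel_size: float

    @property
    def shape(self) -> tuple[int, int, int]:
        return self.lumen.shape


@dataclass
class PhantomGroundTruth:
    """Exact voxel-counted truth per (branch, axial station).

    ``table`` columns: branch_id, station, lumen_voxels, perimeter_voxels,
    true_area_ratio, true_contact_ratio.
    """

    table: pd.DataFrame
    centerline: dict[int, np.ndarray]
    labels: np.ndarray


def _branch_frame(direction: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Deterministic orthonormal basis (u, v) perpendicular to direction."""
    ref = np.array([1.0, 0.0, 0.0])
    if abs(float(np.dot(direction, ref))) > 0.9:
        ref = np.array([0.0, 1.0, 0.0])
    u = np.cross(direction, ref)
    u /= np.linalg.norm(u)
    v = np.cross(direction, u)
    return u, v


def _branch_coords(
    branch: Branch, voxel_size: float, coords: np.ndarray
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Axial position t (voxels), radial distance, polar angle (deg) of voxels."""
    d = branch.unit_direction()
    origin = np.asarray(branch.origin, dtype=float)
    rel = coords - origin
    t = rel @ d
    radial_vec = rel - np.outer(t, d)
    dist = np.linalg.norm(radial_vec, axis=1)
    u, v = _branch_frame(d)
    angle = np.degrees(np.arctan2(radial_vec @ v, radial_vec @ u)) % 360.0
    return t, dist, angle


def build_tree_volume(
    spec: TreeSpec,
    volume_shape: tuple[int, int, int],
    voxel_size: float,
    seed: int = 0,
) -> TreePhantom:
    """Digitise a tree spec into a lumen mask and branch label map.

    A voxel belongs to the lumen iff its centre lies strictly within the
    radius of some branch axis segment; each lumen voxel is labelled with the
    branch whose axis is nearest.  Raises if a branch does not fit inside
    ``volume_shape``; warns if the digitised tree is not a single 26-connected
    component.
    """
    if voxel_size <= 0:
        raise ValueError("voxel_size must be > 0")
    shape = tuple(int(s) for s in volume_shape)
    lumen = np.zeros(shape, dtype=bool)
    labels = np.zeros(shape, dtype=np.int32)
    best_dist = np.full(shape, np.inf, dtype=np.float64)
    centerline: dict[int, np.ndarray] = {}

    for branch in spec.branches:
        d = branch.unit_direction()
        origin = np.asarray(branch.origin, dtype=float)
        length_v = branch.length / voxel_size
        radius_v = branch.radius / voxel_size
        end = origin + d * length_v
        # per-axis half-extent of the end discs: radius scaled by the disc tilt
        disc_extent = radius_v * np.sqrt(np.clip(1.0 - d**2, 0.0, 1.0))
        for point, name in ((origin, "origin"), (end, "end")):
            lo = point - disc_extent
            hi = point + disc_extent
            if np.any(lo < -0.5) or np.any(hi > np.asarray(shape) - 0.5):
                raise ValueError(
                    f"branch {branch.branch_id} ({name}) extends outside the "
                    f"volume of shape {shape}"
                )
        # bounding box of the capped cylinder, padded by one voxel
        lo = np.floor(np.minimum(origin, end) - radius_v - 1).astype(int)
        hi = np.ceil(np.maximum(origin, end) + radius_v + 2).astype(int)
        lo = np.maximum(lo, 0)
        hi = np.minimum(hi, shape)
        grids = np.meshgrid(
            *(np.arange(lo[k], hi[k]) for k in range(3)), indexing="ij"
        )
        coords = np.stack([g.ravel() for g in grids], axis=1).astype(float)
        t, dist, _ = _branch_coords(branch, voxel_size, coords)
        inside = (t >= 0.0) & (t < length_v) & (dist < radius_v)
        if not np.any(inside):
            continue
        vox = coords[inside].astype(int)
        idx = tuple(vox.T)
        lumen[idx] = True
        # axis distance with t clamped to the segment, for nearest-axis labels
        t_cl = np.clip(t[inside], 0.0, length_v)
        axis_pts = origin + np.outer(t_cl, d)
        seg_dist = np.linalg.norm(coords[inside] - axis_pts, axis=1)
        closer = seg_dist < best_dist[idx]
        upd = tuple(vox[closer].T)
        best_dist[upd] = seg_dist[closer]
        labels[upd] = branch.branch_id

        n_samples = max(int(math.ceil(length_v)) + 1, 2)
        ts = np.linspace(0.0, length_v, n_samples)
        centerline[branch.branch_id] = origin + np.outer(ts, d)

    if lumen.any():
        _, n_comp = ndimage.label(lumen, structure=_STRUCT26)
        if n_comp != 1:
            warnings.warn(
                f"digitised tree has {n_comp} 26-connected components "
                "(branches may be disconnected or overlapping)",
                stacklevel=2,
            )
    return TreePhantom(lumen, labels, centerline, spec, float(voxel_size))


def _deposit_mask(
    deposit: Deposit,
    branch: Branch,
    voxel_size: float,
    t: np.ndarray,
    dist: np.ndarray,
    angle: np.ndarray,
) -> np.ndarray:
    """Boolean selector over branch voxels for one deposit."""
    length_v = branch.length / voxel_size
    radius_v = branch.radius / voxel_size
    lo, hi = deposit.axial_span
    sel = (t >= lo * length_v) & (t < hi * length_v)
    if deposit.kind == "plug":
        return sel

    cov = deposit.angular_coverage
    half = cov / 2.0
    rel_angle = (angle - deposit.angle_offset + half) % 360.0
    in_sector = rel_angle <= cov

    if deposit.thickness is not None:
        r_in = max(radius_v - deposit.thickness, 0.0)
        return sel & in_sector & (dist >= r_in)

    # fill_fraction-driven geometry: wall-adherent sector, plus a concentric
    # core (kept clear of the wall) when the sector alone cannot reach the
    # requested area fraction.
    f = float(deposit.fill_fraction)
    c = cov / 360.0
    if f <= c:
        r_in = radius_v * math.sqrt(max(1.0 - f / c, 0.0))
        return sel & in_sector & (dist >= r_in)
    r_core = radius_v * math.sqrt((f - c) / (1.0 - c))
    r_core = min(r_core, radius_v - 2.0)  # keep the core off the wall
    return sel & (in_sector | (dist < r_core))


def _perimeter_mask(mask: np.ndarray) -> np.ndarray:
    """Voxels of ``mask`` with a 6-neighbour outside the mask (or the volume)."""
    eroded = ndimage.binary_erosion(mask, structure=_STRUCT6, border_value=0)
    return mask & ~eroded


def carve_mucus(
    phantom: TreePhantom,
    deposits: Sequence[Deposit],
    seed: int = 0,
) -> tuple[np.ndarray, PhantomGroundTruth]:
    """Carve mucus deposits into the phantom lumen and count ground truth.

    Returns the mucus mask (subset of the lumen) and exact per-station truth:
    area ratio = mucus / lumen voxels of the station, contact ratio =
    mucus-occupied perimeter voxels / all perimeter voxels, where the
    perimeter is the 6-boundary of the airway interior.
    """
    known = {b.branch_id for b in phantom.spec.branches}
    for dep in deposits:
        if dep.branch_id not in known:
            raise ValueError(f"deposit references unknown branch_id {dep.branch_id}")

    mucus = np.zeros(phantom.shape, dtype=bool)
    coords_cache: dict[int, tuple[np.ndarray, ...]] = {}

    def branch_voxels(branch_id: int):
        if branch_id not in coords_cache:
            vox = np.argwhere(phantom.labels == branch_id)
            branch = phantom.spec.branch(branch_id)
            t, dist, angle = _branch_coords(
                branch, phantom.voxel_size, vox.astype(float)
            )
            coords_cache[branch_id] = (vox, t, dist, angle)
        return coords_cache[branch_id]

    for dep in deposits:
        branch = phantom.spec.branch(dep.branch_id)
        vox, t, dist, angle = branch_voxels(dep.branch_id)
        if vox.size == 0:
            continue
        sel = _deposit_mask(dep, branch, phantom.voxel_size, t, dist, angle)
        mucus[tuple(vox[sel].T)] = True

    perimeter = _perimeter_mask(phantom.lumen)
    rows = []
    for branch in phantom.spec.branches:
        vox, t, dist, angle = branch_voxels(branch.branch_id)
        if vox.size == 0:
            continue
        idx = tuple(vox.T)
        station = np.floor(t).astype(int)
        muc = mucus[idx]
        per = perimeter[idx]
        for st in np.unique(station):
            m = station == st
            lumen_n = int(np.sum(m))
            mucus_n = int(np.sum(muc & m))
            per_n = int(np.sum(per & m))
            per_muc_n = int(np.sum(per & muc & m))
            rows.append(
                {
                    "branch_id": branch.branch_id,
                    "station": int(st),
                    "lumen_voxels": lumen_n,
                    "perimeter_voxels": per_n,
                    "true_area_ratio": mucus_n / lumen_n,
                    "true_contact_ratio": per_muc_n / per_n if per_n else 0.0,
                }
            )
    table = pd.DataFrame(
        rows,
        columns=[
            "branch_id",
            "station",
            "lumen_voxels",
            "perimeter_voxels",
            "true_area_ratio",
            "true_contact_ratio",
        ],
    )
    truth = PhantomGroundTruth(table, dict(phantom.centerline), phantom.labels.copy())
    return mucus, truth


def render_intensity(
    lumen: np.ndarray,
    mucus: np.ndarray,
    noise_sd: float,
    seed: int = 0,
) -> np.ndarray:
    """Render an intensity volume: tissue 0.85, air 0.10, mucus 0.60 + noise.

    Deterministic given ``seed``; output clipped to [0, 1], float64.
    """
    if lumen.shape != mucus.shape:
        raise ValueError("lumen and mucus masks must have the same shape")
    if np.any(mucus & ~lumen):
        raise ValueError("mucus mask must be a subset of the lumen mask")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    volume = np.full(lumen.shape, LEVEL_TISSUE, dtype=np.float64)
    volume[lumen] = LEVEL_AIR
    volume[mucus] = LEVEL_MUCUS
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        volume = volume + rng.normal(0.0, noise_sd, size=volume.shape)
    return np.clip(volume, 0.0, 1.0)


def generate_cohort_ratio_table(
    n_samples: int,
    slope: float = 3.204,
    intercept: float = 7.243,
    noise_sd: float = 5.0,
    x_range: tuple[float, float] = (0.7, 15.5),
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic cohort of per-sample mean ratios (percent units).

    Mean area ratio x is uniform on ``x_range``; mean contact ratio is
    ``slope * x + intercept`` plus Gaussian noise of ``noise_sd``.  Defaults
    reproduce the reference regression (slope 3.204, intercept 7.243, x on
    0.7-15.5 %).
    """
    if n_samples < 2:
        raise ValueError("n_samples must be >= 2")
    if noise_sd < 0:
        raise ValueError("noise_sd must be >= 0")
    lo, hi = x_range
    if not (0.0 <= lo < hi <= 100.0):
        raise ValueError("x_range must be an ordered pair within [0, 100]")
    rng = np.random.default_rng(seed)
    x = rng.uniform(lo, hi, size=n_samples)
    y = slope * x + intercept + rng.normal(0.0, noise_sd, size=n_samples)
    return pd.DataFrame(
        {
            "sample_id": [f"S{i:03d}" for i in range(n_samples)],
            "mean_area_ratio_pct": x,
            "mean_contact_ratio_pct": y,
        }
    )


def generate_score_table(
    catalog: pd.DataFrame,
    group_probs: Mapping[tuple[str, str], object],
    n_animals: int,
    seed: int = 0,
) -> pd.DataFrame:
    """Synthetic ordinal score table over a nomenclature catalog.

    ``group_probs`` maps (genotype, age_group) to either one probability
    triple (p0, p1, p2) used for every generation, or a mapping from
    generation to triples.  Each animal of each group receives one score per
    catalog segment, drawn independently.  Deterministic given ``seed``.
    """
    if n_animals < 1:
        raise ValueError("n_animals must be >= 1")

    def triple_for(probs: object, generation: int) -> np.ndarray:
        if isinstance(probs, Mapping):
            p = probs[generation]
        else:
            p = probs
        arr = np.asarray(p, dtype=float)
        if arr.shape != (3,):
            raise ValueError("probability entries must be triples (p0, p1, p2)")
        if abs(float(arr.sum()) - 1.0) > 1e-9:
            raise ValueError(f"probabilities {arr.tolist()} do not sum to 1")
        if np.any(arr < 0):
            raise ValueError("probabilities must be non-negative")
        return arr

    rng = np.random.default_rng(seed)
    rows = []
    animal_counter = 0
    for (genotype, age_group), probs in group_probs.items():
        for _ in range(n_animals):
            animal_id = f"A{animal_counter:03d}"
            animal_counter += 1
            for rec in catalog.itertuples(index=False):
                p = triple_for(probs, int(rec.generation))
                score = int(rng.choice(3, p=p))
                rows.append(
                    {
                        "animal_id": animal_id,
                        "genotype": genotype,
                        "age_group": age_group,
                        "segment_label": rec.segment_label,
                        "lobe": rec.lobe,
                        "generation": int(rec.generation),
                        "score": score,
                    }
                )
    return pd.DataFrame(rows)
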