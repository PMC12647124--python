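"""Mucus area ratio and mucus contact ratio, with per-branch and
per-sample aggregation and the area/contact correlation analysis.

The area ratio is the fraction of the airway lumen (air + mucus) occupied by
mucus in a cross-section; the contact ratio is the fraction of the airway
wall perimeter covered by mucus.  The wall is operationalised as the
6-boundary of the airway interior.  Ratios are fractions internally and
percentages in sample summaries.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from .cross_section import CrossSectionRecord
from .stats import RegressionResult, pearson_r, simple_linreg

__all__ = [
    "RatioRecord",
    "SampleSummary",
    "CorrelationReport",
    "area_ratio",
    "contact_ratio",
    "ratio_records",
    "records_frame",
    "branch_profile",
    "sample_summary",
    "correlate_summaries",
]


@dataclass(frozen=True)
class RatioRecord:
    method: str
    branch_id: int
    station: int
    area_ratio: float
    contact_ratio: float
    lumen_voxel_count: int
    perimeter_voxel_count: int

    def __post_init__(self):
        if not (0.0 <= self.area_ratio <= 1.0 and 0.0 <= self.contact_ratio <= 1.0):
            raise ValueError("ratios must lie in [0, 1]")
        if self.lumen_voxel_count < 1:
            raise ValueError("lumen_voxel_count must be >= 1")
        if self.area_ratio == 0.0 and self.contact_ratio != 0.0:
            raise ValueError("contact ratio must be 0 where area ratio is 0")


@dataclass(frozen=True)
class SampleSummary:
    """Per-sample means in percent."""

    sample_id: str
    method: str
    mean_area_ratio_pct: float
    mean_contact_ratio_pct: float
    n_cross_sections: int


@dataclass(frozen=True)
class CorrelationReport:
    pearson_r: float
    slope: float
    intercept: float
    r_squared: float
    p_value: float
    n: int


def area_ratio(cs: CrossSectionRecord) -> float:
    """|mucus voxels| / |lumen voxels| of the station."""
    if cs.lumen_count < 1:
        raise ValueError("empty lumen set")
    return cs.mucus_count / cs.lumen_count


def contact_ratio(cs: CrossSectionRecord) -> float:
    """|perimeter voxels occupied by mucus| / |perimeter voxels|."""
    if cs.perimeter_count < 1:
        raise ValueError("empty perimeter set")
    return cs.mucus_perimeter_count / cs.perimeter_count


def ratio_records(records: Iterable[CrossSectionRecord]) -> list[RatioRecord]:
    """Compute both ratios for every cross-section record."""
    out = []
    for cs in records:
        out.append(
            RatioRecord(
                method=cs.method,
                branch_id=cs.branch_id,
                station=cs.station,
                area_ratio=area_ratio(cs),
                contact_ratio=contact_ratio(cs) if cs.perimeter_count else 0.0,
                lumen_voxel_count=cs.lumen_count,
                perimeter_voxel_count=cs.perimeter_count,
            )
        )
    return out


def records_frame(records: Sequence[RatioRecord]) -> pd.DataFrame:
    return pd.DataFrame(
        [
            {
                "method": r.method,
                "branch_id": r.branch_id,
                "station": r.station,
                "area_ratio": r.area_ratio,
                "contact_ratio": r.contact_ratio,
                "lumen_voxels": r.lumen_voxel_count,
                "perimeter_voxels": r.perimeter_voxel_count,
            }
            for r in records
        ]
    )


def branch_profile(records: Sequence[RatioRecord]) -> pd.DataFrame:
    """Ordered per-branch ratio sequences (proximal to distal).

    Returns a tidy frame sorted by (branch_id, station).  Gaps — e.g. skipped
    bifurcation stations of the skeleton method — remain absent rows rather
    than being filled.  All records must come from one method.
    """
    if not records:
        return pd.DataFrame(
            columns=["branch_id", "station", "area_ratio", "contact_ratio"]
        )
    methods = {r.method for r in records}
    if len(methods) > 1:
        raise ValueError(f"records mix methods: {sorted(methods)}")
    df = records_frame(records)
    return (
        df[["branch_id", "station", "area_ratio", "contact_ratio"]]
        .sort_values(["branch_id", "station"], kind="stable")
        .reset_index(drop=True)
    )


def sample_summary(
    records: Sequence[RatioRecord],
    sample_id: str,
    mean_over: str = "stations",
) -> SampleSummary:
    """Unweighted mean ratios of one sample, in percent.

    ``mean_over="stations"`` averages over cross-section records (default);
    ``"branches"`` averages per-branch means so long and short branches weigh
    equally.
    """
    if not records:
        raise ValueError("sample_summary requires at least one record")
    if mean_over not in ("stations", "branches"):
        raise ValueError(f"unknown mean_over {mean_over!r}")
    methods = {r.method for r in records}
    if len(methods) > 1:
        raise ValueError(f"records mix methods: {sorted(methods)}")
    df = records_frame(records)
    if mean_over == "branches":
        per_branch = df.groupby("branch_id")[["area_ratio", "contact_ratio"]].mean()
        mean_area = float(per_branch["area_ratio"].mean())
        mean_contact = float(per_branch["contact_ratio"].mean())
    else:
        mean_area = float(df["area_ratio"].mean())
        mean_contact = float(df["contact_ratio"].mean())
    return SampleSummary(
        sample_id=sample_id,
        method=methods.pop(),
        mean_area_ratio_pct=100.0 * mean_area,
        mean_contact_ratio_pct=100.0 * mean_contact,
        n_cross_sections=len(records),
    )


def correlate_summaries(summaries) -> CorrelationReport:
    """Pearson r and OLS of mean contact (%) on mean area (%).

    Accepts a sequence of :class:`SampleSummary` or a DataFrame with columns
    ``mean_area_ratio_pct`` and ``mean_contact_ratio_pct``.
    """
    if isinstance(summaries, pd.DataFrame):
        x = summaries["mean_area_ratio_pct"].to_numpy(dtype=float)
        y = summaries["mean_contact_ratio_pct"].to_numpy(dtype=float)
    else:
        x = np.array([s.mean_area_ratio_pct for s in summaries], dtype=float)
        y = np.array([s.mean_contact_ratio_pct for s in summaries], dtype=float)
    if x.size < 3:
        raise ValueError("correlate_summaries requires at least 3 samples")
    r = pearson_r(x, y)
    reg: RegressionResult = simple_linreg(x, y)
    return CorrelationReport(
        pearson_r=r,
        slope=reg.slope,
        intercept=reg.intercept,
        r_squared=reg.r_squared,
        p_value=reg.p_value,
        n=reg.n,
    )
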