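"""End-to-end orchestration: segmentation -> cross-sections -> ratios ->
summaries -> correlation, and the ordinal scoring study with group stats.

Runs are manifest-first (the config echo and seeds are written before any
computation) and fully deterministic given the config and seed; ground truth
is never read during analysis.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .cross_section import (
    geodesic_cross_sections,
    main_branch_seed_slice,
    skeleton_cross_sections,
    skeletonize,
    slice_cross_sections,
)
from .metrics import correlate_summaries, ratio_records, records_frame, sample_summary
from .segmentation import (
    Marker,
    MarkerSet,
    MucusSegParams,
    exclude_unconnected,
    segment_lumen,
    segment_mucus,
)
from .stats import bonferroni_dunn_adjust, dunn_posthoc, kruskal_wallis, mann_whitney_u
from .volume_io import read_volume, write_ratio_map

logger = logging.getLogger("mucomap.pipeline")

METHODS = ("slice", "skeleton", "geodesic")


@dataclass
class SampleInput:
    sample_id: str
    volume_path: str
    lumen_seeds: list[tuple[int, int, int]]
    background_seeds: list[tuple[int, int, int]] = field(default_factory=list)
    voxel_size_um: float | None = None


@dataclass
class PipelineConfig:
    """Round-trippable configuration for ``run_microanalysis``."""

    samples: list[SampleInput]
    out_dir: str
    methods: tuple[str, ...] = METHODS
    watershed_sigma: float = 1.0
    mucus_params: MucusSegParams = field(default_factory=MucusSegParams)
    geodesic_bin_width: float = 1.0
    mean_over: str = "stations"
    area_scale_max: float = 0.30
    contact_scale_max: float = 1.00
    write_maps: bool = False
    seed: int = 0

    def to_dict(self) -> dict:
        d = dataclasses.asdict(self)
        d["methods"] = list(self.methods)
        return d

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        d = dict(d)
        d["samples"] = [
            SampleInput(
                sample_id=s["sample_id"],
                volume_path=s["volume_path"],
                lumen_seeds=[tuple(p) for p in s["lumen_seeds"]],
                background_seeds=[tuple(p) for p in s.get("background_seeds", [])],
                voxel_size_um=s.get("voxel_size_um"),
            )
            for s in d["samples"]
        ]
        if "mucus_params" in d and isinstance(d["mucus_params"], dict):
            mp = dict(d["mucus_params"])
            if mp.get("band") is not None:
                mp["band"] = tuple(mp["band"])
            d["mucus_params"] = MucusSegParams(**mp)
        d["methods"] = tuple(d.get("methods", METHODS))
        return cls(**d)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(self.to_dict(), fh, sort_keys=False)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        with open(path) as fh:
            return cls.from_dict(yaml.safe_load(fh))


def _marker_set(sample: SampleInput) -> MarkerSet:
    markers = [
        Marker(i, tuple(p), "lumen-seed") for i, p in enumerate(sample.lumen_seeds)
    ]
    offset = len(markers)
    markers += [
        Marker(offset + i, tuple(p), "background-seed")
        for i, p in enumerate(sample.background_seeds)
    ]
    return MarkerSet(tuple(markers))


def analyze_sample(
    volume: np.ndarray,
    markers: MarkerSet,
    config: PipelineConfig,
    sample_id: str,
    keep_voxels: bool = False,
):
    """Segment one volume and extract ratio records for each method.

    Returns (records per method, summaries per method, label map, mucus mask,
    excluded mask).
    """
    t0 = time.perf_counter()
    label_map = segment_lumen(volume, markers, sigma=config.watershed_sigma)
    interior = label_map.mask
    mucus = segment_mucus(volume, interior, config.mucus_params)
    seed_region = np.zeros(volume.shape, dtype=bool)
    for pos in markers.lumen_seeds():
        seed_region[pos] = True
    connected, excluded = exclude_unconnected(interior, seed_region)
    labels = np.where(connected, label_map.labels, 0)
    mucus = mucus & connected
    logger.info(
        "[%s] segmentation done in %.1fs (%d interior voxels, %d excluded)",
        sample_id,
        time.perf_counter() - t0,
        int(connected.sum()),
        int(excluded.sum()),
    )

    per_method_records = {}
    per_method_summaries = {}
    for method in config.methods:
        t1 = time.perf_counter()
        if method == "slice":
            cs = slice_cross_sections(labels, mucus, keep_voxels=keep_voxels)
        elif method == "skeleton":
            skel = skeletonize(connected)
            cs = skeleton_cross_sections(connected, skel, mucus, keep_voxels=keep_voxels)
        elif method == "geodesic":
            seed_slice = main_branch_seed_slice(labels)
            cs, geo_excluded = geodesic_cross_sections(
                connected,
                seed_slice,
                mucus,
                bin_width=config.geodesic_bin_width,
                labels=labels,
                keep_voxels=keep_voxels,
            )
        else:
            raise ValueError(f"unknown cross-section method {method!r}")
        recs = ratio_records(cs)
        per_method_records[method] = (cs, recs)
        if recs:
            per_method_summaries[method] = sample_summary(
                recs, sample_id, mean_over=config.mean_over
            )
        logger.info(
            "[%s] %s method: %d records in %.1fs",
            sample_id,
            method,
            len(recs),
            time.perf_counter() - t1,
        )
    return per_method_records, per_method_summaries, label_map, mucus, excluded


def run_microanalysis(config: PipelineConfig) -> dict:
    """Run the full microanalysis over all configured samples.

    Writes per-sample ratio-record CSVs, per-method summary CSVs, an
    area/contact correlation report per method (when >= 3 samples), optional
    RGB ratio maps, and a machine-readable run manifest.  Returns the paths
    and correlation reports.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = {
        "tool": "mucomap",
        "version": __version__,
        "seed": config.seed,
        "config": config.to_dict(),
    }
    (out / "manifest.json").write_text(json.dumps(manifest, indent=2))

    for sample in config.samples:
        if not Path(sample.volume_path).exists():
            raise FileNotFoundError(
                f"sample {sample.sample_id}: missing input volume {sample.volume_path}"
            )

    summaries: dict[str, list] = {m: [] for m in config.methods}
    for sample in config.samples:
        volume, meta = read_volume(sample.volume_path, sample.voxel_size_um)
        markers = _marker_set(sample)
        per_method, per_summary, label_map, mucus, excluded = analyze_sample(
            volume.astype(float),
            markers,
            config,
            sample.sample_id,
            keep_voxels=config.write_maps,
        )
        for method, (cs, recs) in per_method.items():
            df = records_frame(recs)
            df.insert(0, "sample_id", sample.sample_id)
            df.to_csv(
                out / f"records_{sample.sample_id}_{method}.csv", index=False
            )
            if config.write_maps and recs:
                for which, scale in (
                    ("area", config.area_scale_max),
                    ("contact", config.contact_scale_max),
                ):
                    vals = [
                        r.area_ratio if which == "area" else r.contact_ratio
                        for r in recs
                    ]
                    write_ratio_map(
                        volume.shape,
                        cs,
                        vals,
                        which,
                        out / f"map_{sample.sample_id}_{method}_{which}.tif",
                        excluded_mask=excluded,
                        scale_max=scale,
                        force=True,
                    )
        for method, summ in per_summary.items():
            summaries[method].append(summ)

    reports = {}
    for method, rows in summaries.items():
        if not rows:
            continue
        df = pd.DataFrame(
            [
                {
                    "sample_id": s.sample_id,
                    "method": s.method,
                    "mean_area_ratio_pct": s.mean_area_ratio_pct,
                    "mean_contact_ratio_pct": s.mean_contact_ratio_pct,
                    "n_cross_sections": s.n_cross_sections,
                }
                for s in rows
            ]
        )
        df.to_csv(out / f"summaries_{method}.csv", index=False)
        if len(rows) >= 3:
            rep = correlate_summaries(df)
            reports[method] = rep
            (out / f"correlation_{method}.json").write_text(
                json.dumps(dataclasses.asdict(rep), indent=2)
            )
    return {"out_dir": str(out), "correlations": reports}


def run_scoring_study(
    scores: pd.DataFrame, out_dir: str | Path, min_group_n: int = 2
) -> dict:
    """Aggregate an ordinal score table and run the group comparisons.

    Produces per-animal whole-organ / per-lobe / per-generation mean scores;
    genotype comparisons within each age group (Mann-Whitney U, Bonferroni-
    Dunn adjusted over age groups); age comparisons within each genotype
    (Kruskal-Wallis plus Dunn's post-hoc).  Groups with fewer than
    ``min_group_n`` animals are skipped with a warning (means still
    reported).
    """
    from .scoring import aggregate_scores

    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aggregates = {}
    for by in ("whole", "lobe", "generation"):
        agg = aggregate_scores(scores, by=by)
        agg.to_csv(out / f"mean_scores_{by}.csv", index=False)
        aggregates[by] = agg

    whole = aggregates["whole"]
    comparisons = []
    age_groups = sorted(whole["age_group"].unique())
    genotypes = sorted(whole["genotype"].unique())

    if len(genotypes) == 2:
        g0, g1 = genotypes
        raw_results = []
        for age in age_groups:
            a = whole[(whole.age_group == age) & (whole.genotype == g0)][
                "mean_score"
            ].to_numpy()
            b = whole[(whole.age_group == age) & (whole.genotype == g1)][
                "mean_score"
            ].to_numpy()
            if len(a) < min_group_n or len(b) < min_group_n:
                logger.warning(
                    "skipping genotype comparison for age group %r "
                    "(group sizes %d vs %d)",
                    age,
                    len(a),
                    len(b),
                )
                continue
            raw_results.append((age, mann_whitney_u(a, b)))
        if raw_results:
            adjusted = bonferroni_dunn_adjust(
                [res.p_value for _, res in raw_results], len(raw_results)
            )
            for (age, res), p_adj in zip(raw_results, adjusted):
                comparisons.append(
                    {
                        "comparison": f"{genotypes[0]} vs {genotypes[1]}",
                        "stratum": age,
                        "test": res.method,
                        "statistic": res.statistic,
                        "p_raw": res.p_value,
                        "p_adjusted": p_adj,
                        "n": "/".join(map(str, res.n)),
                    }
                )

    for genotype in genotypes:
        groups = []
        names = []
        for age in age_groups:
            vals = whole[(whole.genotype == genotype) & (whole.age_group == age)][
                "mean_score"
            ].to_numpy()
            if len(vals) >= min_group_n:
                groups.append(vals)
                names.append(age)
        if len(groups) < 2:
            logger.warning(
                "skipping age comparison for genotype %r (too few groups)", genotype
            )
            continue
        kw = kruskal_wallis(groups)
        comparisons.append(
            {
                "comparison": f"age groups within {genotype}",
                "stratum": "|".join(names),
                "test": kw.method,
                "statistic": kw.statistic,
                "p_raw": kw.p_value,
                "p_adjusted": np.nan,
                "n": "/".join(map(str, kw.n)),
            }
        )
        for res in dunn_posthoc(groups):
            i, j = res.groups
            comparisons.append(
                {
                    "comparison": f"{names[i]} vs {names[j]} within {genotype}",
                    "stratum": "dunn-posthoc",
                    "test": res.method,
                    "statistic": res.statistic,
                    "p_raw": res.p_value,
                    "p_adjusted": res.p_adjusted,
                    "n": "/".join(map(str, res.n)),
                }
            )
    comp_df = pd.DataFrame(
        comparisons,
        columns=["comparison", "stratum", "test", "statistic", "p_raw", "p_adjusted", "n"],
    )
    comp_df.to_csv(out / "group_comparisons.csv", index=False)
    return {"aggregates": aggregates, "comparisons": comp_df}
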