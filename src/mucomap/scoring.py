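"""Ordinal mucus scoring over an 11-generation murine airway nomenclature.

Ships a monopodial nomenclature catalog covering all five lung lobes (RUL,
RML, RLL, RCL, LL) and airway generations 1-11 (the trachea, generation 0,
is excluded by design).  Labels follow the systematic convention of cycling
capital letters, lowercase letters and Roman numerals over successive
branching levels.  The exact segment inventory below the lobar level is an
artifact construction; the catalog is a plain CSV so users can substitute
their own.

Scores are ordinal: 0 = no mucus, 1 = mucus obstructing up to (and
including) 50 % of the lumen, 2 = more than 50 %.
"""

from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

__all__ = [
    "LOBES",
    "GENERATIONS",
    "default_catalog",
    "build_default_catalog",
    "validate_catalog",
    "auto_score",
    "aggregate_scores",
]

LOBES = ("RUL", "RML", "RLL", "RCL", "LL")
GENERATIONS = tuple(range(1, 12))

_UPPER = "ABCDEFGH"
_LOWER = "abcdefgh"
_ROMAN = ("I", "II", "III", "IV", "V", "VI", "VII", "VIII")
_ALPHABETS = (_UPPER, _LOWER, _ROMAN)


def _symbol(depth: int, child_index: int) -> str:
    return _ALPHABETS[depth % 3][child_index]


def build_default_catalog() -> pd.DataFrame:
    """Construct the default catalog programmatically.

    Per lobe: a continuing trunk spanning generations 1-11, one lateral
    daughter budding off the trunk at every generation >= 2 (monopodial
    branching), and one continuation of each lateral one generation deeper.
    """
    rows = []
    for lobe in LOBES:
        trunk_code = ""
        trunk_labels: dict[int, str] = {}
        for gen in GENERATIONS:
            depth = gen - 1
            trunk_code += _symbol(depth, 0)
            label = f"{lobe}.{trunk_code}"
            parent = trunk_labels.get(gen - 1)
            rows.append(
                {
                    "segment_label": label,
                    "lobe": lobe,
                    "generation": gen,
                    "parent": parent if parent is not None else "",
                }
            )
            trunk_labels[gen] = label
        for gen in range(2, 12):
            depth = gen - 1
            parent_label = trunk_labels[gen - 1]
            lat_label = f"{parent_label.split('.', 1)[1]}{_symbol(depth, 1)}"
            lat_full = f"{lobe}.{lat_label}"
            rows.append(
                {
                    "segment_label": lat_full,
                    "lobe": lobe,
                    "generation": gen,
                    "parent": parent_label,
                }
            )
            if gen + 1 <= 11:
                child = f"{lat_full}{_symbol(depth + 1, 0)}"
                rows.append(
                    {
                        "segment_label": child,
                        "lobe": lobe,
                        "generation": gen + 1,
                        "parent": lat_full,
                    }
                )
    df = pd.DataFrame(rows)
    validate_catalog(df)
    return df


def default_catalog() -> pd.DataFrame:
    """Load the packaged nomenclature catalog CSV."""
    with resources.files("mucomap").joinpath("data/airway_catalog.csv").open() as fh:
        df = pd.read_csv(fh, keep_default_na=False)
    df["generation"] = df["generation"].astype(int)
    validate_catalog(df)
    return df


def validate_catalog(catalog: pd.DataFrame) -> None:
    """Check catalog invariants; raises ValueError on violation."""
    labels = catalog["segment_label"]
    if labels.duplicated().any():
        dupes = labels[labels.duplicated()].tolist()
        raise ValueError(f"duplicate segment labels: {dupes[:5]}")
    if set(catalog["lobe"]) != set(LOBES):
        raise ValueError(f"catalog must cover exactly the lobes {LOBES}")
    gens = set(catalog["generation"].astype(int))
    if gens != set(GENERATIONS):
        raise ValueError(f"catalog must cover exactly generations 1-11, found {sorted(gens)}")
    gen_of = dict(zip(catalog["segment_label"], catalog["generation"].astype(int)))
    for rec in catalog.itertuples(index=False):
        gen = int(rec.generation)
        parent = rec.parent if isinstance(rec.parent, str) else ""
        if gen == 1:
            if parent:
                raise ValueError(f"{rec.segment_label}: generation-1 entries have no parent")
        else:
            if parent not in gen_of:
                raise ValueError(f"{rec.segment_label}: parent {parent!r} not in catalog")
            if gen_of[parent] != gen - 1:
                raise ValueError(
                    f"{rec.segment_label}: parent generation must be {gen - 1}"
                )


def auto_score(area_ratio: float, tolerance: float = 1e-6) -> int:
    """Map a mucus area ratio to the ordinal 0/1/2 score.

    0 for no mucus (ratio 0 within tolerance), 1 for obstruction up to and
    including 50 %, 2 for more than 50 %.
    """
    if not -tolerance <= area_ratio <= 1.0 + tolerance:
        raise ValueError(f"area_ratio {area_ratio} outside [0, 1]")
    if area_ratio <= tolerance:
        return 0
    if area_ratio <= 0.5:
        return 1
    return 2


def aggregate_scores(table: pd.DataFrame, by: str = "whole") -> pd.DataFrame:
    """Per-animal mean scores over the requested stratum.

    ``by`` is "whole" (one mean per animal), "lobe" or "generation".  Only
    scored segments enter the mean; strata with no scored segments are simply
    absent (missing, not zero).  Output columns: animal_id, genotype,
    age_group, [lobe | generation], mean_score, n_segments.
    """
    if table.empty:
        raise ValueError("score table is empty")
    if by not in ("whole", "lobe", "generation"):
        raise ValueError(f"unknown stratification {by!r}")
    keys = ["animal_id", "genotype", "age_group"]
    if by != "whole":
        keys = keys + [by]
    grouped = (
        table.groupby(keys, sort=True)["score"]
        .agg(mean_score="mean", n_segments="count")
        .reset_index()
    )
    return grouped
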