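"""Scenario ranking and population-level connectivity maps.

Each individual (animal-season-year) gets five current maps, one per
suitability-to-resistance scenario; the scenario whose map accumulates the
highest summed current at the individual's observed in-window fixes ranks
best.  Top-ranked maps, each standardized to sum to one so every individual
carries equal weight, sum into the population connectivity surface.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import RasterGrid
from .rsf import _binned_spearman

__all__ = [
    "ScenarioRanking",
    "PopulationMap",
    "score_scenario",
    "rank_individual",
    "tabulate_support",
    "population_map",
    "validate_population_map",
]

#: fixed tie-break preference, simplest transform first
TIE_ORDER = ["r0", "r3", "r1", "r4", "r2"]


@dataclass
class ScenarioRanking:
    individual: str
    scores: dict[str, float]
    ordering: list[str]
    top_scenario: str
    tied: bool = False


@dataclass
class PopulationMap:
    raster: RasterGrid
    season: str
    n_individuals: int
    roads_variant: str = "baseline"  # or "with_proposed"


def score_scenario(current_map: RasterGrid, fixes: np.ndarray) -> float:
    """Summed current at the containing cell of each fix.

    Each fix contributes its cell's value (repeat fixes in one cell count
    once per fix); fixes on nodata cells contribute zero and are counted in
    a warning.
    """
    fixes = np.asarray(fixes, dtype=float)
    if len(fixes) == 0:
        return 0.0
    inside = current_map.contains(fixes[:, 0], fixes[:, 1])
    if not inside.all():
        raise ValueError(f"{(~inside).sum()} fixes fall outside the raster extent")
    row, col = current_map.xy_to_rowcol(fixes[:, 0], fixes[:, 1])
    vals = current_map.data[row, col]
    n_nodata = int(np.isnan(vals).sum())
    if n_nodata:
        warnings.warn(f"{n_nodata} fixes on nodata cells contributed 0 current")
    return float(np.nansum(vals))


def rank_individual(
    maps: dict[str, RasterGrid], fixes: np.ndarray, individual: str = ""
) -> ScenarioRanking:
    """Rank the five scenario current maps by summed current at fixes."""
    missing = [s for s in TIE_ORDER if s not in maps]
    if missing:
        raise ValueError(f"missing scenario maps: {missing}")
    scores = {sid: score_scenario(m, fixes) for sid, m in maps.items()}
    # sort by descending score; equal scores fall back to the fixed tie order
    ordering = sorted(
        scores, key=lambda s: (-scores[s], TIE_ORDER.index(s))
    )
    top = ordering[0]
    tied = any(
        scores[s] == scores[top] for s in ordering[1:]
    )
    return ScenarioRanking(
        individual=individual, scores=scores, ordering=ordering,
        top_scenario=top, tied=tied,
    )


def tabulate_support(rankings: list[ScenarioRanking]) -> pd.DataFrame:
    """Counts and proportions of top-ranked scenarios across individuals."""
    if not rankings:
        raise ValueError("no rankings to tabulate")
    counts = {sid: 0 for sid in TIE_ORDER}
    for r in rankings:
        counts[r.top_scenario] += 1
    df = pd.DataFrame(
        {
            "scenario": sorted(counts),
            "count": [counts[s] for s in sorted(counts)],
        }
    )
    df["proportion"] = df["count"] / df["count"].sum()
    return df


def population_map(
    top_maps: list[RasterGrid],
    season: str,
    roads_variant: str = "baseline",
) -> PopulationMap:
    """Sum per-individual top maps after standardizing each to sum 1."""
    if not top_maps:
        raise ValueError("no individual maps supplied")
    template = top_maps[0]
    acc = np.zeros(template.shape)
    for m in top_maps:
        if not template.same_grid(m):
            raise ValueError("individual maps are not co-registered")
        total = np.nansum(m.data)
        if not total > 0:
            raise ValueError("individual map with zero total current")
        acc += np.where(m.valid, m.data / total, 0.0)
    out = np.where(template.valid, acc, np.nan)
    return PopulationMap(
        raster=template.like(out),
        season=season,
        n_individuals=len(top_maps),
        roads_variant=roads_variant,
    )


def validate_population_map(
    maps_by_individual: dict[str, RasterGrid],
    fixes_by_individual: dict[str, np.ndarray],
    season: str = "",
    k: int = 10,
    bins: int = 10,
    rng: np.random.Generator | int | None = None,
) -> tuple[float, float, float]:
    """Individual-blocked k-fold validation of the population map.

    Folds split individuals (never fixes) to avoid leakage: each fold's map
    is rebuilt from training individuals only, withheld individuals' fixes
    are scored, and the binned area-adjusted Spearman rho computed against
    the map's valid-cell score distribution.  Returns (mean rho, mean map
    value at all fixes, mean map value over the study area) with the means
    taken on the full-population map.
    """
    ids = sorted(maps_by_individual)
    if set(ids) != set(fixes_by_individual):
        raise ValueError("maps and fixes must cover the same individuals")
    if k < 2:
        raise ValueError("k must be >= 2")
    if len(ids) < k:
        warnings.warn(f"only {len(ids)} individuals; reducing folds to that")
        k = len(ids)
    rng = np.random.default_rng(rng) if not isinstance(rng, np.random.Generator) else rng
    perm = rng.permutation(ids)
    folds = np.array_split(perm, k)
    rhos = []
    for fold in folds:
        train = [i for i in perm if i not in set(fold)]
        if not train:
            continue
        pm = population_map([maps_by_individual[i] for i in train], season)
        test_fixes = np.vstack([fixes_by_individual[i] for i in fold])
        row, col = pm.raster.xy_to_rowcol(test_fixes[:, 0], test_fixes[:, 1])
        row = np.clip(row, 0, pm.raster.nrows - 1)
        col = np.clip(col, 0, pm.raster.ncols - 1)
        s_used = pm.raster.data[row, col]
        s_used = s_used[np.isfinite(s_used)]
        s_area = pm.raster.data[pm.raster.valid]
        if len(s_used) == 0:
            continue
        rhos.append(_binned_spearman(s_used, s_area, bins))

    full = population_map([maps_by_individual[i] for i in ids], season)
    all_fixes = np.vstack([fixes_by_individual[i] for i in ids])
    row, col = full.raster.xy_to_rowcol(all_fixes[:, 0], all_fixes[:, 1])
    row = np.clip(row, 0, full.raster.nrows - 1)
    col = np.clip(col, 0, full.raster.ncols - 1)
    at_fixes = full.raster.data[row, col]
    mean_at_fixes = float(np.nanmean(at_fixes))
    mean_area = float(np.nanmean(full.raster.data[full.raster.valid]))
    return float(np.mean(rhos)) if rhos else np.nan, mean_at_fixes, mean_area
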