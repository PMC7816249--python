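"""Suitability-to-resistance scenario transforms.

Whether movement resistance is the inverse of habitat suitability is a
testable hypothesis, not an assumption.  Five candidate links between
relative habitat suitability ``hs`` (in (0, 1]) and raw resistance ``r``
are carried through the pipeline and ranked per individual against the
telemetry:

==========  ====================  ===================
scenario    relationship          transform
==========  ====================  ===================
r0          neutral               r = 1
r1          positive linear       r = hs
r2          negative exponential  r = (1/hs)^2
r3          negative linear       r = 1/hs
r4          negative logarithmic  r = ln(1/hs)
==========  ====================  ===================

Every non-neutral raw surface is then linearly stretched to the 1-1,000
range; circuit solutions depend only on resistance ratios, so it is the
shape of the transform, not its absolute scale, that the ranking compares.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable

import numpy as np

from .raster import RasterGrid

__all__ = [
    "SCENARIOS",
    "SCENARIO_ORDER",
    "ResistanceScenario",
    "ResistanceSurface",
    "apply_scenario",
    "stretch",
    "build_surface",
    "rebuild_with_roads",
]


@dataclass(frozen=True)
class ResistanceScenario:
    id: str
    label: str
    transform: Callable[[np.ndarray], np.ndarray]
    neutral: bool = False


SCENARIOS: dict[str, ResistanceScenario] = {
    "r0": ResistanceScenario("r0", "neutral", lambda hs: np.ones_like(hs), neutral=True),
    "r1": ResistanceScenario("r1", "positive linear", lambda hs: hs),
    "r2": ResistanceScenario("r2", "negative exponential", lambda hs: (1.0 / hs) ** 2),
    "r3": ResistanceScenario("r3", "negative linear", lambda hs: 1.0 / hs),
    "r4": ResistanceScenario("r4", "negative logarithmic", lambda hs: np.log(1.0 / hs)),
}

SCENARIO_ORDER = ["r0", "r1", "r2", "r3", "r4"]


@dataclass
class ResistanceSurface:
    """A scenario-transformed (and optionally stretched) resistance raster."""

    raster: RasterGrid
    scenario_id: str
    hs_source: str = ""
    stretched: bool = False
    clamp_epsilon: float = 1e-3


def apply_scenario(
    hs: RasterGrid, scenario: ResistanceScenario | str, clamp_epsilon: float = 1e-3
) -> RasterGrid:
    """Raw (unstretched) resistance under one scenario transform.

    ``hs`` must lie in (0, 1]; values below ``clamp_epsilon`` are clamped
    up before division/log so the reciprocal transforms stay finite.  The
    subsequent stretch makes results insensitive to the exact clamp.
    """
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    if not 0 < clamp_epsilon < 0.1:
        raise ValueError("clamp_epsilon must be in (0, 0.1)")
    vals = hs.data[hs.valid]
    if len(vals) and (vals.max() > 1.0 + 1e-12 or vals.min() <= 0):
        raise ValueError("hs must lie in (0, 1]; normalization contract violated")
    clamped = np.clip(hs.data, clamp_epsilon, 1.0)
    out = np.where(hs.valid, scenario.transform(clamped), np.nan)
    return hs.like(out)


def stretch(raw: RasterGrid, lo: float = 1.0, hi: float = 1000.0) -> RasterGrid:
    """Linear rescale of valid cells to [lo, hi], order-preserving.

    A constant raster (max = min) maps entirely to ``lo``.
    """
    v = raw.data[raw.valid]
    if len(v) == 0:
        raise ValueError("cannot stretch an all-nodata raster")
    if not np.isfinite(v).all():
        raise ValueError("raw resistance must be finite on valid cells")
    vmin, vmax = float(v.min()), float(v.max())
    if vmax == vmin:
        out = np.where(raw.valid, lo, np.nan)
    else:
        out = lo + (hi - lo) * (raw.data - vmin) / (vmax - vmin)
        out = np.where(raw.valid, out, np.nan)
    return raw.like(out)


def build_surface(
    hs: RasterGrid,
    scenario: ResistanceScenario | str,
    clamp_epsilon: float = 1e-3,
    lo: float = 1.0,
    hi: float = 1000.0,
    hs_source: str = "",
) -> ResistanceSurface:
    """Scenario transform + stretch in one step (neutral is never stretched)."""
    if isinstance(scenario, str):
        scenario = SCENARIOS[scenario]
    raw = apply_scenario(hs, scenario, clamp_epsilon=clamp_epsilon)
    if scenario.neutral:
        return ResistanceSurface(
            raster=raw, scenario_id=scenario.id, hs_source=hs_source,
            stretched=False, clamp_epsilon=clamp_epsilon,
        )
    return ResistanceSurface(
        raster=stretch(raw, lo=lo, hi=hi),
        scenario_id=scenario.id,
        hs_source=hs_source,
        stretched=True,
        clamp_epsilon=clamp_epsilon,
    )


def rebuild_with_roads(
    fit,
    stack,
    proposed,
    scenario: ResistanceScenario | str,
    bundle,
    clamp_epsilon: float = 1e-3,
    lo: float = 1.0,
    hi: float = 1000.0,
) -> ResistanceSurface:
    """Rebuild a resistance surface with proposed roads added.

    Recomputes the road-decay covariate from the union of existing and
    proposed roads, re-predicts suitability with the *unchanged* fitted
    coefficients and decay parameter, and re-applies the given scenario and
    stretch.  An empty proposed set reproduces the baseline surface.
    """
    from .covariates import build_stack
    from .rsf import predict_suitability

    roads = list(bundle.roads_existing) + list(proposed)
    new_stack = build_stack(bundle, alpha=stack.alpha, grain=stack.grain, roads=roads)
    hs = predict_suitability(fit, new_stack)
    tag = "with_proposed" if len(list(proposed)) else "baseline"
    return build_surface(
        hs, scenario, clamp_epsilon=clamp_epsilon, lo=lo, hi=hi,
        hs_source=f"refit-roads:{tag}",
    )
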