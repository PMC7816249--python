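"""End-to-end pipeline: simulate -> detect -> fit -> resist -> solve ->
rank -> aggregate -> impact.

Every stage reads and writes plain-format artifacts (ASCII grids, GeoJSON,
CSV, JSON) in a workspace directory, so stages are independently runnable
and re-runnable; a manifest records the configuration hash, seed, and
checksums of every artifact, and a rerun with an identical configuration
reproduces all stochastic outputs bit for bit.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .aggregation import (
    population_map,
    rank_individual,
    tabulate_support,
    validate_population_map,
)
from .circuit import (
    DisconnectedTerminalsError,
    SnapError,
    build_graph,
    individual_current_map,
)
from .covariates import build_stack
from .impact import buffer_extract, effect_size
from .migration import (
    NoMigrationError,
    detect_track_migration,
    read_tracks_csv,
    write_tracks_csv,
)
from .raster import RasterGrid
from .resistance import SCENARIO_ORDER, build_surface
from .rsf import (
    RSFFit,
    best_alpha,
    bootstrap_response,
    build_table,
    fit_rsf,
    kfold_validate,
    predict_suitability,
    select_decay_alpha,
    select_model,
    vif,
)
from .synthetic import LandscapeBundle, SimulationConfig, generate_landscape, simulate_tracks
from .vector import (
    read_geojson_lines,
    read_geojson_points,
    write_geojson_lines,
    write_geojson_points,
)

log = logging.getLogger("circuitmig")

__all__ = ["PipelineConfig", "Pipeline", "run_pipeline"]


@dataclass
class PipelineConfig:
    """Configuration of a full pipeline run.

    Defaults mirror the method's standard settings: 20 available points per
    used location, 1-1,000 resistance stretch, 8-neighbour circuits, 20-km
    community buffers, 10 validation folds, 500 bootstrap draws.  The
    simulation block controls the synthetic study system used when no real
    inputs are supplied.
    """

    seed: int = 1
    season: str = "fall"
    # synthetic study system
    extent: tuple[float, float, float, float] = (0.0, 0.0, 60.0, 60.0)
    cell_size_km: float = 1.0
    n_animals: int = 8
    selection_strength: float = 1.5
    generating_scenario: str = "r3"
    true_coefficients: dict[str, float] = field(
        default_factory=lambda: {
            "ruggedness": -0.5,
            "river": -0.6,
            "road_decay": 2.5,
            "dense": -1.2,
            "burned": -0.3,
            "coastal": -2.8,
        }
    )
    true_alpha_km: float = 10.0
    start_region: tuple[float, float, float, float] | None = None
    end_region: tuple[float, float, float, float] | None = None
    # analysis settings
    availability_ratio: int = 20
    alpha_candidates: tuple[float, ...] | None = None
    scenario_list: tuple[str, ...] = tuple(SCENARIO_ORDER)
    stretch_bounds: tuple[float, float] = (1.0, 1000.0)
    clamp_epsilon: float = 1e-3
    solver_tolerance: float = 1e-8
    buffer_radius_km: float = 20.0
    k_folds: int = 10
    n_boot: int = 500
    random_effects: bool = False

    def __post_init__(self) -> None:
        if self.availability_ratio < 1:
            raise ValueError("availability_ratio must be >= 1")
        if self.buffer_radius_km <= 0:
            raise ValueError("buffer_radius_km must be positive")
        if not 0 < self.clamp_epsilon < 0.1:
            raise ValueError("clamp_epsilon must be in (0, 0.1)")
        if self.k_folds < 2:
            raise ValueError("k_folds must be >= 2")
        if self.n_boot < 1:
            raise ValueError("n_boot must be >= 1")
        if self.solver_tolerance <= 0:
            raise ValueError("solver_tolerance must be positive")
        lo, hi = self.stretch_bounds
        if not lo < hi:
            raise ValueError("stretch bounds must satisfy lo < hi")
        unknown = set(self.scenario_list) - set(SCENARIO_ORDER)
        if unknown:
            raise ValueError(f"unknown scenarios {sorted(unknown)}")

    @classmethod
    def from_dict(cls, d: dict) -> "PipelineConfig":
        known = set(cls.__dataclass_fields__)
        unknown = set(d) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        d = dict(d)
        for key in ("extent", "start_region", "end_region", "stretch_bounds"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        for key in ("alpha_candidates", "scenario_list"):
            if key in d and d[key] is not None:
                d[key] = tuple(d[key])
        return cls(**d)

    def to_dict(self) -> dict:
        return asdict(self)

    def digest(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True, default=list).encode()
        ).hexdigest()[:16]


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


class Pipeline:
    """Stage-per-method pipeline over a workspace directory."""

    def __init__(self, config: PipelineConfig, workspace: str | Path):
        self.cfg = config
        self.ws = Path(workspace)
        self.ws.mkdir(parents=True, exist_ok=True)

    # -- helpers --------------------------------------------------------

    def _path(self, name: str) -> Path:
        return self.ws / name

    def _seed(self, stage: str) -> int:
        """Stage-specific deterministic sub-seed below 2**31."""
        h = hashlib.sha256(f"{self.cfg.seed}:{stage}".encode()).digest()
        return int.from_bytes(h[:4], "big") % (2**31 - 1)

    def _load_bundle(self) -> LandscapeBundle:
        elev = RasterGrid.read_ascii(self._path("elevation.asc"))
        lc = RasterGrid.read_ascii(self._path("landcover.asc"))
        return LandscapeBundle(
            elevation=elev,
            landcover=lc,
            rivers=read_geojson_lines(self._path("rivers.geojson")),
            roads_existing=read_geojson_lines(self._path("roads_existing.geojson")),
            roads_proposed=read_geojson_lines(self._path("roads_proposed.geojson")),
            communities=read_geojson_points(self._path("communities.geojson")),
            extent=elev.extent,
            cell_size=elev.cell_size,
        )

    def _sim_regions(self):
        xmin, ymin, xmax, ymax = self.cfg.extent
        w, h = xmax - xmin, ymax - ymin
        start = self.cfg.start_region or (
            xmin + 0.08 * w, ymin + 0.08 * h, xmin + 0.35 * w, ymin + 0.25 * h
        )
        end = self.cfg.end_region or (
            xmin + 0.65 * w, ymin + 0.75 * h, xmin + 0.92 * w, ymin + 0.92 * h
        )
        return start, end

    # -- stages ---------------------------------------------------------

    def simulate(self) -> None:
        """Generate the landscape, a generating resistance truth, and tracks."""
        cfg = self.cfg
        start, end = self._sim_regions()
        sim = SimulationConfig(
            seed=self._seed("simulate"),
            n_animals=cfg.n_animals,
            season=cfg.season,
            selection_strength=cfg.selection_strength,
            start_region=start,
            end_region=end,
        )
        bundle = generate_landscape(sim, extent=cfg.extent, cell_size=cfg.cell_size_km)
        stack = build_stack(bundle, alpha=cfg.true_alpha_km, grain=cfg.cell_size_km)
        truth = RSFFit(
            params=pd.Series({"intercept": 0.0, **cfg.true_coefficients}),
            bse=pd.Series(dtype=float),
            cov=pd.DataFrame(),
            loglik=np.nan,
            n=2,
            k=1,
            formula=tuple(cfg.true_coefficients),
        )
        hs_true = predict_suitability(truth, stack)
        lo, hi = cfg.stretch_bounds
        surface = build_surface(
            hs_true, cfg.generating_scenario, clamp_epsilon=cfg.clamp_epsilon,
            lo=lo, hi=hi, hs_source="generating-truth",
        )
        tracks = simulate_tracks(bundle, surface.raster, sim)

        bundle.elevation.write_ascii(self._path("elevation.asc"))
        bundle.landcover.write_ascii(self._path("landcover.asc"))
        write_geojson_lines(bundle.rivers, self._path("rivers.geojson"))
        write_geojson_lines(bundle.roads_existing, self._path("roads_existing.geojson"))
        write_geojson_lines(bundle.roads_proposed, self._path("roads_proposed.geojson"))
        write_geojson_points(bundle.communities, self._path("communities.geojson"))
        hs_true.write_ascii(self._path("hs_true.asc"))
        write_tracks_csv(tracks, self._path("tracks.csv"))
        log.info("simulate: %d tracks over %s grid", len(tracks), bundle.elevation.shape)

    def detect(self) -> None:
        """NSD migration windows per track."""
        tracks = read_tracks_csv(self._path("tracks.csv"))
        rows = []
        windows = {}
        for t in tracks:
            try:
                win = detect_track_migration(t)
            except NoMigrationError as err:
                log.warning("detect: %s skipped (%s)", t.label, err)
                continue
            windows[t.label] = win
            rows.append(
                {
                    "individual": t.label,
                    "animal_id": t.animal_id,
                    "season": t.season,
                    "year": t.year,
                    "start_index": win.start_index,
                    "end_index": win.end_index,
                    "start_time": t.timestamps[win.start_index].isoformat(),
                    "end_time": t.timestamps[win.end_index].isoformat(),
                    "start_x_km": win.start_point[0],
                    "start_y_km": win.start_point[1],
                    "end_x_km": win.end_point[0],
                    "end_y_km": win.end_point[1],
                }
            )
        if not rows:
            raise RuntimeError("detect: no migratory tracks found")
        pd.DataFrame(rows).to_csv(self._path("migrations.csv"), index=False)

    def _used_points(self) -> pd.DataFrame:
        """In-window fixes of all individuals, one row per used point."""
        tracks = {t.label: t for t in read_tracks_csv(self._path("tracks.csv"))}
        mig = pd.read_csv(self._path("migrations.csv"))
        rows = []
        for _, m in mig.iterrows():
            t = tracks[m["individual"]]
            seg = t.fixes[int(m["start_index"]) : int(m["end_index"]) + 1]
            rows.append(
                pd.DataFrame(
                    {
                        "individual": m["individual"],
                        "animal_id": t.animal_id,
                        "year": t.year,
                        "x_km": seg[:, 0],
                        "y_km": seg[:, 1],
                    }
                )
            )
        return pd.concat(rows, ignore_index=True)

    def fit_rsf_stage(self) -> None:
        """Alpha scan, factorial model selection, fit, validation, bootstrap."""
        cfg = self.cfg
        bundle = self._load_bundle()
        used = self._used_points()
        rng = np.random.default_rng(self._seed("rsf"))
        stack0 = build_stack(bundle, alpha=cfg.true_alpha_km, grain=cfg.cell_size_km)
        table = build_table(
            stack0, used, ratio=cfg.availability_ratio, rng=rng
        )
        candidates = cfg.alpha_candidates  # None -> the full default grid
        scan = select_decay_alpha(table, candidates=candidates)
        scan.to_csv(self._path("alpha_scan.csv"), index=False)
        alpha = best_alpha(scan)
        if alpha is None:
            log.warning("fit-rsf: linear distance model won; falling back to "
                        "smallest candidate alpha for the decay covariate")
            alpha = float(scan["label"].iloc[1].split("=")[1])
        stack = stack0.with_alpha(alpha)
        table = build_table(
            stack, used, ratio=cfg.availability_ratio,
            rng=np.random.default_rng(self._seed("rsf-table")),
        )
        model_sel = select_model(table)
        model_sel.to_csv(self._path("model_selection.csv"), index=False)
        best_label = model_sel["label"].iloc[0]
        formula = () if best_label == "intercept-only" else tuple(best_label.split(" + "))
        fit = fit_rsf(table, formula=formula, random_effects=cfg.random_effects)
        fit.to_json(self._path("rsf_fit.json"))
        if len(formula) >= 2:
            vif(table[list(formula)]).to_csv(self._path("vif.csv"), header=["vif"])
        rho = kfold_validate(
            table, formula or ("road_decay",), k=cfg.k_folds,
            rng=np.random.default_rng(self._seed("rsf-kfold")),
        )
        if "road_decay" in formula:
            curve = bootstrap_response(
                fit, alpha, n_boot=cfg.n_boot, seed=self._seed("rsf-boot")
            )
            curve.to_csv(self._path("road_response.csv"), index=False)
        json.dump(
            {"alpha": alpha, "formula": list(formula), "kfold_rho": rho},
            open(self._path("rsf_summary.json"), "w"), indent=1,
        )

    def resist(self) -> None:
        """Five scenario surfaces, baseline and with proposed roads."""
        cfg = self.cfg
        bundle = self._load_bundle()
        fit = RSFFit.from_json(self._path("rsf_fit.json"))
        summary = json.load(open(self._path("rsf_summary.json")))
        alpha = summary["alpha"]
        lo, hi = cfg.stretch_bounds
        for variant, roads in (
            ("baseline", list(bundle.roads_existing)),
            ("with_proposed", list(bundle.roads_existing) + list(bundle.roads_proposed)),
        ):
            stack = build_stack(bundle, alpha=alpha, grain=cfg.cell_size_km, roads=roads)
            hs = predict_suitability(fit, stack)
            hs.write_ascii(self._path(f"hs_{variant}.asc"))
            for sid in cfg.scenario_list:
                surf = build_surface(
                    hs, sid, clamp_epsilon=cfg.clamp_epsilon, lo=lo, hi=hi,
                    hs_source=variant,
                )
                surf.raster.write_ascii(self._path(f"resistance_{variant}_{sid}.asc"))

    def solve_stage(self) -> None:
        """Per-individual current maps for every scenario and road variant."""
        cfg = self.cfg
        mig = pd.read_csv(self._path("migrations.csv"))
        (self.ws / "current").mkdir(exist_ok=True)
        skipped = []
        for variant in ("baseline", "with_proposed"):
            for sid in cfg.scenario_list:
                surface = RasterGrid.read_ascii(
                    self._path(f"resistance_{variant}_{sid}.asc")
                )
                graph = build_graph(surface)
                for _, m in mig.iterrows():
                    name = f"current/{m['individual']}_{variant}_{sid}.asc"
                    try:
                        sol = individual_current_map(
                            surface,
                            (m["start_x_km"], m["start_y_km"]),
                            (m["end_x_km"], m["end_y_km"]),
                            graph=graph,
                            tolerance=cfg.solver_tolerance,
                        )
                    except (SnapError, DisconnectedTerminalsError, ValueError) as err:
                        log.warning("solve: %s %s %s skipped (%s)",
                                    m["individual"], variant, sid, err)
                        skipped.append(
                            {"individual": m["individual"], "variant": variant,
                             "scenario": sid, "reason": str(err)}
                        )
                        continue
                    sol.current_map.write_ascii(self._path(name))
        pd.DataFrame(skipped).to_csv(self._path("solve_skipped.csv"), index=False)

    def rank(self) -> None:
        """Rank scenarios per individual by summed current at fixes."""
        cfg = self.cfg
        used = self._used_points()
        rankings = []
        rows = []
        for indiv, grp in used.groupby("individual", sort=True):
            fixes = grp[["x_km", "y_km"]].to_numpy()
            maps = {}
            complete = True
            for sid in cfg.scenario_list:
                p = self._path(f"current/{indiv}_baseline_{sid}.asc")
                if not p.exists():
                    log.warning("rank: %s missing scenario %s; skipped", indiv, sid)
                    complete = False
                    break
                maps[sid] = RasterGrid.read_ascii(p)
            if not complete:
                continue
            r = rank_individual(maps, fixes, individual=str(indiv))
            rankings.append(r)
            rows.append(
                {"individual": indiv, "top_scenario": r.top_scenario,
                 "tied": r.tied, **{f"sum_{s}": r.scores[s] for s in cfg.scenario_list}}
            )
        if not rankings:
            raise RuntimeError("rank: no complete individuals")
        pd.DataFrame(rows).to_csv(self._path("rankings.csv"), index=False)
        support = tabulate_support(rankings)
        support["season"] = cfg.season
        support.to_csv(self._path("scenario_support.csv"), index=False)

    def aggregate_stage(self) -> None:
        """Population maps (both road variants) and their validation."""
        cfg = self.cfg
        ranks = pd.read_csv(self._path("rankings.csv"))
        used = self._used_points()
        fixes_by_ind = {
            str(i): g[["x_km", "y_km"]].to_numpy()
            for i, g in used.groupby("individual")
        }
        results = {}
        for variant in ("baseline", "with_proposed"):
            maps = {}
            for _, row in ranks.iterrows():
                p = self._path(
                    f"current/{row['individual']}_{variant}_{row['top_scenario']}.asc"
                )
                if p.exists():
                    maps[str(row["individual"])] = RasterGrid.read_ascii(p)
            pm = population_map(
                [maps[i] for i in sorted(maps)], cfg.season, roads_variant=variant
            )
            pm.raster.write_ascii(self._path(f"population_{variant}.asc"))
            rho, at_fix, at_area = validate_population_map(
                maps, {i: fixes_by_ind[i] for i in maps}, season=cfg.season,
                k=cfg.k_folds, rng=np.random.default_rng(self._seed(f"agg-{variant}")),
            )
            results[variant] = {
                "kfold_rho": rho,
                "mean_current_at_fixes": at_fix,
                "mean_current_study_area": at_area,
                "n_individuals": pm.n_individuals,
            }
        json.dump(results, open(self._path("population_validation.json"), "w"), indent=1)

    def impact_stage(self) -> None:
        """Per-community standardized change in current flow."""
        cfg = self.cfg
        communities = read_geojson_points(self._path("communities.geojson"))
        base = population_map_from_ascii(
            self._path("population_baseline.asc"), cfg.season, "baseline"
        )
        withr = population_map_from_ascii(
            self._path("population_with_proposed.asc"), cfg.season, "with_proposed"
        )
        rows = []
        for name, pt in sorted(communities.items()):
            try:
                b_vals, idx = buffer_extract(base, pt, cfg.buffer_radius_km)
            except ValueError as err:
                log.warning("impact: %s skipped (%s)", name, err)
                continue
            w_vals = withr.raster.data.ravel()[idx]
            res = effect_size(
                w_vals, b_vals, community=name, season=cfg.season,
                seed=self._seed(f"impact-{name}"),
            )
            rows.append(
                {
                    "community": name, "season": cfg.season, "d": res.d_effect,
                    "ci_low": res.ci_low, "ci_high": res.ci_high,
                    "n_cells": res.n_cells, "class": res.classification,
                    "sign": res.sign,
                }
            )
        pd.DataFrame(rows).to_csv(self._path("effect_sizes.csv"), index=False)

    def manifest(self) -> dict:
        arts = sorted(
            p for p in self.ws.rglob("*")
            if p.is_file() and p.name != "manifest.json"
        )
        man = {
            "version": __version__,
            "seed": self.cfg.seed,
            "config_digest": self.cfg.digest(),
            "artifacts": {str(p.relative_to(self.ws)): _sha256(p) for p in arts},
        }
        json.dump(man, open(self._path("manifest.json"), "w"), indent=1, sort_keys=True)
        return man

    def run_all(self) -> dict:
        self.simulate()
        self.detect()
        self.fit_rsf_stage()
        self.resist()
        self.solve_stage()
        self.rank()
        self.aggregate_stage()
        self.impact_stage()
        return self.manifest()


def population_map_from_ascii(path, season, variant):
    from .aggregation import PopulationMap

    raster = RasterGrid.read_ascii(path)
    return PopulationMap(raster=raster, season=season, n_individuals=0,
                         roads_variant=variant)


def run_pipeline(config: PipelineConfig, workspace: str | Path) -> dict:
    """Execute every stage and return the artifact manifest."""
    return Pipeline(config, workspace).run_all()
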