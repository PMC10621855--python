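"""End-to-end experiment orchestration.

Runs the model sweep (wall models x delivered currents), collects
lesion metrics into a results table, fits the linear size-vs-current
trends, and optionally exports field maps and isolines.  Everything is
deterministic for a fixed configuration and seed.
"""

from __future__ import annotations

import logging
import time
from dataclasses import asdict, dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .conductivity import TissueProperties
from .geometry import MODEL_IDS, GeometrySpec, ScarSpec, build_model
from .lesion import lesion_size
from .mesh import generate_mesh
from .solver import SolverSettings, solve_at_current

__all__ = ["RunConfig", "run_experiment", "fit_trends", "load_config",
           "dump_config"]

log = logging.getLogger("pfafield.pipeline")

RESULT_COLUMNS = ["model", "current_A", "V_applied", "I_delivered",
                  "depth_mm", "surface_width_mm", "clamped_to_fat",
                  "n_satellites", "picard_iters", "error"]


@dataclass
class RunConfig:
    models: tuple[str, ...] = MODEL_IDS
    currents: tuple[float, ...] = (19.0, 22.0, 25.0)
    threshold_Vcm: float = 1000.0
    geometry: GeometrySpec = field(default_factory=GeometrySpec)
    scar: ScarSpec = field(default_factory=ScarSpec)
    tissues: TissueProperties = field(default_factory=TissueProperties)
    solver: SolverSettings = field(default_factory=SolverSettings)
    seed: int = 1
    h_fine: float = 0.05
    h_coarse: float = 3.0
    resample_h: float = 0.025
    output_dir: str | None = None
    export_fields: bool = False

    def __post_init__(self) -> None:
        bad = [m for m in self.models if m not in MODEL_IDS]
        if bad:
            raise ValueError(f"unknown models {bad}")
        if any(c <= 0 for c in self.currents) or self.threshold_Vcm <= 0:
            raise ValueError("currents and threshold must be > 0")


def dump_config(cfg: RunConfig) -> str:
    d = asdict(cfg)
    d["models"] = list(cfg.models)
    d["currents"] = [float(c) for c in cfg.currents]
    d["scar"]["fat_blob_size_range"] = list(d["scar"]["fat_blob_size_range"])
    d["tissues"] = {
        "sigmas_S_per_m": {k: list(v) for k, v in cfg.tissues.sigmas.items()},
        "E_center_V_per_m": cfg.tissues.E_center,
        "E_slope_V_per_m": cfg.tissues.E_slope,
        "prefactor": cfg.tissues.prefactor,
    }
    return yaml.safe_dump(d, sort_keys=True)


def load_config(text: str) -> RunConfig:
    d = yaml.safe_load(text)
    kw = dict(d)
    kw["models"] = tuple(d.get("models", MODEL_IDS))
    kw["currents"] = tuple(float(c) for c in d.get("currents", (19, 22, 25)))
    if "geometry" in d:
        kw["geometry"] = GeometrySpec(**d["geometry"])
    if "scar" in d:
        sc = dict(d["scar"])
        sc["fat_blob_size_range"] = tuple(sc["fat_blob_size_range"])
        kw["scar"] = ScarSpec(**sc)
    if "tissues" in d:
        kw["tissues"] = TissueProperties(
            sigmas={k: tuple(v) for k, v in d["tissues"]["sigmas_S_per_m"].items()},
            E_center=float(d["tissues"]["E_center_V_per_m"]),
            E_slope=float(d["tissues"]["E_slope_V_per_m"]),
            prefactor=float(d["tissues"]["prefactor"]))
    if "solver" in d:
        kw["solver"] = SolverSettings(**d["solver"])
    return RunConfig(**kw)


def run_experiment(cfg: RunConfig) -> pd.DataFrame:
    """One row of lesion metrics per (model, current).

    Solver failures are recorded in the row's ``error`` column and the
    sweep continues.  If ``cfg.output_dir`` is set, writes
    ``results.csv``, ``trends.csv``, per-run isoline VTK files and
    (with ``export_fields``) field-map VTK files.
    """
    rows = []
    out = Path(cfg.output_dir) if cfg.output_dir else None
    if out:
        out.mkdir(parents=True, exist_ok=True)
        (out / "config.yaml").write_text(dump_config(cfg))
    for model in cfg.models:
        tmap = build_model(model, cfg.geometry,
                           cfg.scar if model in "CDEF" else None,
                           seed=cfg.seed)
        mesh = generate_mesh(tmap, cfg.h_fine, cfg.h_coarse)
        log.info("model %s: %d nodes", model, mesh.n_nodes)
        for I in cfg.currents:
            t0 = time.perf_counter()
            row = {c: None for c in RESULT_COLUMNS}
            row.update(model=model, current_A=float(I), error="")
            try:
                sol = solve_at_current(mesh, cfg.tissues, float(I), cfg.solver)
                met = lesion_size(sol, cfg.threshold_Vcm, cfg.resample_h)
                row.update(V_applied=round(sol.V_applied, 3),
                           I_delivered=round(sol.I_delivered, 6),
                           depth_mm=round(met.depth, 4),
                           surface_width_mm=round(met.surface_width, 4),
                           clamped_to_fat=bool(met.clamped_to_fat),
                           n_satellites=int(met.n_satellites),
                           picard_iters=int(sol.picard_iters))
                if out:
                    from .vtk_io import write_isolines_vtk, write_solution_vtk
                    write_isolines_vtk(met.isoline,
                                       out / f"isoline_{model}_{I:g}A.vtk")
                    if cfg.export_fields:
                        write_solution_vtk(sol,
                                           out / f"field_{model}_{I:g}A.vtk")
            except Exception as exc:  # per-row failure, sweep continues
                log.error("model %s at %g A failed: %s", model, I, exc)
                row["error"] = str(exc)
            log.info("model %s %g A done in %.1f s", model, I,
                     time.perf_counter() - t0)
            rows.append(row)
    df = pd.DataFrame(rows, columns=RESULT_COLUMNS)
    if out:
        df.to_csv(out / "results.csv", index=False)
        try:
            fit_trends(df).to_csv(out / "trends.csv", index=False)
        except ValueError:
            pass
    return df


def fit_trends(results: pd.DataFrame) -> pd.DataFrame:
    """Least-squares slopes of depth and width versus delivered current.

    One row per model plus a ``pooled_mean_excl_D`` row averaging the
    per-model slopes over every model except the fat-deposition model D,
    whose depth is clamped by the fat and does not scale with current.
    """
    ok = results[results["error"].fillna("") == ""]
    rows = []
    for model, g in ok.groupby("model"):
        if g["current_A"].nunique() < 2:
            raise ValueError(f"model {model}: need >= 2 currents for a trend")
        d_slope = np.polyfit(g["current_A"], g["depth_mm"], 1)[0]
        w_slope = np.polyfit(g["current_A"], g["surface_width_mm"], 1)[0]
        rows.append({"model": model, "depth_slope_mm_per_A": d_slope,
                     "width_slope_mm_per_A": w_slope})
    df = pd.DataFrame(rows)
    pool = df[df["model"] != "D"]
    if len(pool):
        rows.append({"model": "pooled_mean_excl_D",
                     "depth_slope_mm_per_A": pool["depth_slope_mm_per_A"].mean(),
                     "width_slope_mm_per_A": pool["width_slope_mm_per_A"].mean()})
    return pd.DataFrame(rows)
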