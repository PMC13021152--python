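"""Pipeline configuration: YAML/JSON parsing, validation, and execution.

A pipeline config mirrors the simulation stages in their fixed order
(pattern -> tissue -> holes -> positivity -> distributions -> export ->
stats); stages whose section is absent are skipped.  All numeric fields are
validated up front so a bad config fails before any computation starts, with
every problem reported at once.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import yaml

from . import __version__
from .assignment import (
    DistributionSpec,
    assign_cell_positivity,
    assign_continuous,
    assign_holes,
    assign_tissue,
)
from .core import Window, create_simulation_object, generate_spatial_pattern
from .export import create_spatial_list, summarise_spatial, write_tables

__all__ = ["PipelineConfig", "load_config", "run_pipeline", "parse_radii"]


def parse_radii(spec: str) -> np.ndarray:
    """Parse a "start:stop:step" radius grid, inclusive of stop."""
    try:
        start, stop, step = (float(v) for v in spec.split(":"))
    except ValueError as exc:
        raise ValueError(f"radii must look like '0:0.5:0.01', got {spec!r}") from exc
    if step <= 0 or stop < start:
        raise ValueError(f"bad radius grid {spec!r}")
    n = int(round((stop - start) / step))
    return np.round(start + step * np.arange(n + 1), 10)


@dataclass
class PipelineConfig:
    """Validated pipeline parameters, one attribute per stage section."""

    n_sims: int = 1
    n_cell_types: int = 1
    lam: float = 250.0
    window: Window = field(default_factory=lambda: Window(-1, 1, -1, 1))
    seed: int = 0
    tissue: dict | None = None
    holes: dict | None = None
    cells: dict | None = None
    distributions: list[DistributionSpec] | None = None
    export: dict = field(default_factory=lambda: {"dialect": "simple",
                                                  "drop_holes": False})
    summary_marker: str | None = None

    def to_manifest(self) -> dict:
        d = asdict(self)
        d["window"] = asdict(self.window)
        if self.distributions is not None:
            d["distributions"] = [asdict(s) for s in self.distributions]
        d["version"] = __version__
        return d


def _require(cond: bool, msg: str, errors: list[str]) -> None:
    if not cond:
        errors.append(msg)


def load_config(path: str | Path) -> PipelineConfig:
    """Load and validate a YAML (or JSON) pipeline config file."""
    raw = yaml.safe_load(Path(path).read_text())
    if not isinstance(raw, dict):
        raise ValueError("config must be a mapping")
    errors: list[str] = []
    core = raw.get("core", {})
    win = core.get("window", {"xmin": -1, "xmax": 1, "ymin": -1, "ymax": 1})
    try:
        window = Window(win["xmin"], win["xmax"], win["ymin"], win["ymax"])
    except (KeyError, ValueError) as exc:
        errors.append(f"core.window: {exc}")
        window = Window(-1, 1, -1, 1)
    n_sims = int(core.get("n_sims", 1))
    n_cell_types = int(core.get("n_cell_types", 1))
    lam = float(core.get("lambda", core.get("lam", 250.0)))
    _require(n_sims >= 1, "core.n_sims must be >= 1", errors)
    _require(n_cell_types >= 1, "core.n_cell_types must be >= 1", errors)
    _require(lam >= 0, "core.lambda must be >= 0", errors)

    def check_surface(name: str, sec: dict | None) -> dict | None:
        if sec is None:
            return None
        out = dict(sec)
        _require(out.get("k", 1) >= 0, f"{name}.k must be >= 0", errors)
        sdmin = out.get("sdmin", 0.1)
        sdmax = out.get("sdmax", 0.3)
        _require(0 < sdmin <= sdmax, f"{name}: need 0 < sdmin <= sdmax", errors)
        lo = out.get("prob_min", 0.0)
        hi = out.get("prob_max", 1.0)
        _require(0 <= lo <= hi <= 1,
                 f"{name}: need 0 <= prob_min <= prob_max <= 1", errors)
        shift = out.get("shift", 0.0)
        _require(0 <= shift <= 1, f"{name}.shift must lie in [0, 1]", errors)
        return out

    tissue = check_surface("tissue", raw.get("tissue"))
    holes = check_surface("holes", raw.get("holes"))
    cells = check_surface("cells", raw.get("cells"))

    distributions = None
    if "distributions" in raw:
        specs = raw["distributions"]
        if isinstance(specs, dict):
            specs = [specs] * n_cell_types
        distributions = []
        for j, s in enumerate(specs):
            try:
                distributions.append(DistributionSpec(
                    mean_pos=float(s["mean_pos"]), sd_pos=float(s["sd_pos"]),
                    mean_neg=float(s["mean_neg"]), sd_neg=float(s["sd_neg"]),
                ))
            except (KeyError, ValueError) as exc:
                errors.append(f"distributions[{j}]: {exc}")

    export = dict(raw.get("export", {}))
    export.setdefault("dialect", "simple")
    export.setdefault("drop_holes", False)
    _require(export["dialect"] in ("simple", "halo-like"),
             "export.dialect must be 'simple' or 'halo-like'", errors)

    if errors:
        raise ValueError("invalid config:\n  - " + "\n  - ".join(errors))
    return PipelineConfig(
        n_sims=n_sims, n_cell_types=n_cell_types, lam=lam, window=window,
        seed=int(raw.get("seed", 0)), tissue=tissue, holes=holes, cells=cells,
        distributions=distributions, export=export,
        summary_marker=raw.get("summary_marker"),
    )


def _surface_kwargs(sec: dict) -> dict:
    kw = {}
    if "k" in sec:
        kw["k"] = int(sec["k"])
    if "sdmin" in sec:
        kw["sdmin"] = float(sec["sdmin"])
    if "sdmax" in sec:
        kw["sdmax"] = float(sec["sdmax"])
    if "prob_min" in sec or "prob_max" in sec:
        kw["prob_range"] = (float(sec.get("prob_min", 0.0)),
                            float(sec.get("prob_max", 1.0)))
    return kw


def run_pipeline(config: PipelineConfig, outdir: str | Path) -> Path:
    """Execute the configured stages in order and write tables + manifest.

    Returns the output directory.  The manifest records the package version,
    the seed, and every parameter, so a config + manifest pair fully
    determines the outputs.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    obj = create_simulation_object(config.n_sims, config.window,
                                   config.n_cell_types, seed=config.seed)
    generate_spatial_pattern(obj, config.lam)
    if config.tissue is not None:
        assign_tissue(obj, **_surface_kwargs(config.tissue))
    if config.holes is not None:
        sec = dict(config.holes)
        drop = bool(sec.pop("drop", False))
        assign_holes(obj, drop=drop, **_surface_kwargs(sec))
    if config.cells is not None:
        sec = dict(config.cells)
        shift = float(sec.pop("shift", 0.0))
        assign_cell_positivity(obj, shift=shift, **_surface_kwargs(sec))
    if config.distributions is not None:
        assign_continuous(obj, config.distributions)

    tables = create_spatial_list(obj, drop_holes=config.export["drop_holes"])
    table_dir = outdir / "tables"
    write_tables(tables, table_dir, dialect=config.export["dialect"])
    if config.cells is not None:
        marker = config.summary_marker or "Cell 1 Assignment"
        summary = summarise_spatial(tables, marker)
        summary.to_csv(outdir / "summary.csv", index=False)
    manifest = config.to_manifest()
    manifest["n_tables"] = len(tables)
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=2,
                                                     sort_keys=True) + "\n")
    return outdir
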