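"""Configuration, result serialization and figure rendering.

One seed in the run configuration feeds every engine through named
sub-streams, so multi-engine pipelines are reproducible piecewise.  CSV is
the exchange format for tables, JSON for structured results (12 significant
digits, deterministic key/column order, resolved-config echo embedded or as
a sidecar), PNG for figures.
"""

from __future__ import annotations

import dataclasses
import json
import warnings
from dataclasses import dataclass, field as dc_field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

__all__ = ["RunConfig", "ConfigError", "load_config", "validate_config",
           "write_results", "render_surface"]

ENGINES = ("barrier", "flux", "fp", "simulate", "scan", "exponents", "histogram")

_COMMON_KEYS = {"engine", "seed", "out"}
ENGINE_KEYS: dict[str, set[str]] = {
    "barrier": {"N", "kT", "delta_mu", "gamma1", "gamma2", "preset",
                "m_lo", "m_hi", "n_samples"},
    "flux": {"N", "b1", "b2", "b3", "c1", "c2", "beta", "a", "P0", "method"},
    "fp": {"N", "k0", "beta", "a", "b1", "b2", "b3", "P0", "boundary",
           "t_final", "n_grid", "dt", "m_start", "drive_force"},
    "simulate": {"N", "dim", "bond_k", "bond_length", "gamma", "kT", "mass",
                 "dt", "noise", "mode", "E", "q", "end_force_f",
                 "reduced_force", "max_time", "events", "pore_radius",
                 "wall_thickness"},
    "scan": {"E_values", "N_values", "replicates", "gamma", "kT", "mass",
             "dt", "mode", "max_time"},
    "exponents": {"which", "m_values", "N_values", "samples_per_N",
                  "dimension", "force", "replicates"},
    "histogram": {"N", "n_events", "mode", "E", "reduced_force",
                  "end_force_f", "max_time", "bins", "gamma", "kT", "mass",
                  "dt"},
}


class ConfigError(ValueError):
    """Invalid run configuration; ``errors`` lists every violation found."""

    def __init__(self, errors: list[str]):
        self.errors = list(errors)
        super().__init__("invalid configuration:\n  - " + "\n  - ".join(errors))


@dataclass(frozen=True)
class RunConfig:
    """Validated engine run: engine name, parameter block, seed, output path."""

    engine: str
    parameters: dict = dc_field(default_factory=dict)
    seed: int = 0
    out: str | None = None

    def echo(self) -> dict:
        """Fully resolved config as a plain JSON-serializable mapping."""
        return {"engine": self.engine, "seed": self.seed, "out": self.out,
                "parameters": dict(sorted(self.parameters.items()))}


def validate_config(raw: dict) -> RunConfig:
    """Validate a raw mapping; every schema violation is reported at once."""
    errors: list[str] = []
    if not isinstance(raw, dict):
        raise ConfigError([f"top level must be a mapping, got {type(raw).__name__}"])
    engine = raw.get("engine")
    if engine is None:
        errors.append("missing required key 'engine'")
    elif engine not in ENGINES:
        errors.append(f"unknown engine {engine!r}; valid engines: {sorted(ENGINES)}")
    seed = raw.get("seed", 0)
    if not isinstance(seed, int) or isinstance(seed, bool):
        errors.append(f"'seed' must be an integer, got {seed!r}")
    params = {k: v for k, v in raw.items() if k not in _COMMON_KEYS}
    if engine in ENGINE_KEYS:
        valid = ENGINE_KEYS[engine]
        unknown = sorted(set(params) - valid)
        if unknown:
            errors.append(
                f"unknown keys for engine {engine!r}: {unknown}; "
                f"valid keys: {sorted(valid)}"
            )
        if engine in ("flux", "fp") and "b1" in params:
            try:
                if float(params["b1"]) < 0:
                    errors.append(
                        "b1 must be positive: the parabolic barrier "
                        "F(m) = -b1 m^2 + b2 m + b3 requires b1 > 0 (concave top)"
                    )
            except (TypeError, ValueError):
                errors.append(f"b1 must be a number, got {params['b1']!r}")
    if errors:
        raise ConfigError(errors)
    return RunConfig(engine=engine, parameters=params, seed=seed,
                     out=raw.get("out"))


def load_config(path) -> RunConfig:
    """Load and validate a YAML or JSON run configuration."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    text = path.read_text()
    if not text.strip():
        raise ConfigError([f"{path}: empty configuration file"])
    try:
        raw = yaml.safe_load(text)
    except yaml.YAMLError as exc:
        raise ConfigError([f"{path}: parse error: {exc}"]) from exc
    return validate_config(raw)


def _round_floats(obj, sig: int = 12):
    if isinstance(obj, dict):
        return {k: _round_floats(v, sig) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, sig) for v in obj]
    if isinstance(obj, (np.floating, float)):
        x = float(obj)
        return float(f"{x:.{sig}g}") if np.isfinite(x) else x
    if isinstance(obj, np.integer):
        return int(obj)
    if isinstance(obj, np.ndarray):
        return _round_floats(obj.tolist(), sig)
    return obj


def _as_mapping(result) -> dict:
    if dataclasses.is_dataclass(result) and not isinstance(result, type):
        out = {}
        for f in dataclasses.fields(result):
            v = getattr(result, f.name)
            if isinstance(v, np.ndarray):
                v = v.tolist()
            elif dataclasses.is_dataclass(v):
                v = _as_mapping(v)
            out[f.name] = v
        return out
    if isinstance(result, dict):
        return result
    raise TypeError(f"cannot serialize result of type {type(result).__name__}")


def write_results(result, path, format: str = "json",
                  config: RunConfig | None = None) -> None:
    """Serialize a result deterministically.

    JSON: floats at 12 significant digits, sorted keys, config echo under
    "config".  CSV (for DataFrames): stable column order as given, floats
    at 12 significant digits, config echo in a ``<path>.config.json``
    sidecar.
    """
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    if format == "csv":
        if not isinstance(result, pd.DataFrame):
            raise TypeError("CSV output expects a pandas DataFrame")
        result.to_csv(path, index=False, float_format="%.12g")
        if config is not None:
            sidecar = path.with_suffix(path.suffix + ".config.json")
            sidecar.write_text(json.dumps(_round_floats(config.echo()),
                                          indent=2, sort_keys=True) + "\n")
    elif format == "json":
        payload = _round_floats(_as_mapping(result))
        if config is not None:
            payload = {"config": _round_floats(config.echo()), "result": payload}
        path.write_text(json.dumps(payload, indent=2, sort_keys=True,
                                   default=str) + "\n")
    else:
        raise ValueError(f"unknown output format {format!r}")


def render_surface(surface, out_png, elev_azim=((25, -60), (25, 30))) -> None:
    """Two-angle 3-D surface of mean escape time over the (E, N) grid.

    ``surface`` is the long-format table from ``escape_time_surface`` (or a
    path to its CSV).  Purely presentational; no numbers are asserted.
    """
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    if not isinstance(surface, pd.DataFrame):
        surface = pd.read_csv(surface)
    required = {"E", "N", "mean_tau"}
    missing = required - set(surface.columns)
    if missing:
        raise ConfigError([f"surface table missing columns: {sorted(missing)}"])
    if surface.empty:
        raise ConfigError(["surface table is empty"])
    piv = surface.pivot_table(index="N", columns="E", values="mean_tau")
    if piv.size < 4:
        warnings.warn("degenerate surface (fewer than 2x2 cells); plotting points")
    Egrid, Ngrid = np.meshgrid(piv.columns.to_numpy(float), piv.index.to_numpy(float))
    Z = piv.to_numpy(float)
    fig = plt.figure(figsize=(11, 4.5))
    for panel, (elev, azim) in enumerate(elev_azim, start=1):
        ax = fig.add_subplot(1, len(elev_azim), panel, projection="3d")
        if piv.size >= 4:
            ax.plot_surface(Egrid, Ngrid, Z, cmap="viridis")
        else:
            ax.scatter(Egrid.ravel(), Ngrid.ravel(), Z.ravel())
        ax.set_xlabel("E [V/m]")
        ax.set_ylabel("N [monomers]")
        ax.set_zlabel(r"mean $\tau$ [reduced time]")
        ax.view_init(elev=elev, azim=azim)
    fig.tight_layout()
    fig.savefig(out_png, dpi=120)
    plt.close(fig)
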