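"""Run configuration: defaults, YAML loading, validation, report writing.

An empty (or absent) configuration reproduces the nominal closed-loop
experiment end to end: nominal process and controller rates, the step-up /
step-down reference, stiff solver tolerances and the Chernoff-sized Monte
Carlo settings.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from .analysis import ReferenceSignal, chernoff_sample_size
from .controller import MODES, ControllerConfig
from .crn import Trajectory
from .plant import ProcessParams

__all__ = ["RunConfig", "SolverSettings", "AnalysisSettings", "DSDSettings",
           "ConfigError", "load_config", "write_report"]


class ConfigError(ValueError):
    """Aggregated configuration validation failure."""

    def __init__(self, errors: list[str]):
        super().__init__("invalid configuration:\n" + "\n".join(f"  - {e}" for e in errors))
        self.errors = errors


@dataclass(frozen=True)
class SolverSettings:
    rtol: float = 1e-8
    atol: float = 1e-10
    method: str = "LSODA"


@dataclass(frozen=True)
class AnalysisSettings:
    scale: float = 0.1
    n: int = field(default_factory=lambda: chernoff_sample_size(0.05, 0.99))
    seed: int = 0
    factor_min: float = 0.5
    factor_max: float = 2.0
    factor_step: float = 0.1
    divergence_bound: float = 1e6
    tracking_threshold: float = 10.0

    def factors(self) -> tuple[float, ...]:
        n = int(round((self.factor_max - self.factor_min) / self.factor_step)) + 1
        return tuple(round(self.factor_min + i * self.factor_step, 10) for i in range(n))


@dataclass(frozen=True)
class DSDSettings:
    c_max: float | None = None  # None -> derived from signal scale
    q_max: float | None = None  # None -> derived from the largest rate


@dataclass(frozen=True)
class RunConfig:
    process: ProcessParams = field(default_factory=ProcessParams)
    controller: ControllerConfig = field(default_factory=ControllerConfig)
    mode: str = "full_ff"
    retroactivity: bool = False
    reference: ReferenceSignal = field(default_factory=ReferenceSignal)
    solver: SolverSettings = field(default_factory=SolverSettings)
    analysis: AnalysisSettings = field(default_factory=AnalysisSettings)
    dsd: DSDSettings = field(default_factory=DSDSettings)


_SECTION_TYPES = {
    "process": ProcessParams,
    "controller": ControllerConfig,
    "solver": SolverSettings,
    "analysis": AnalysisSettings,
    "dsd": DSDSettings,
}

# YAML keys accepted for controller rates (aliases for the dataclass fields)
_CONTROLLER_ALIASES = {
    "gGa": "g_Ga", "gGd": "g_Gd", "gSbI": "g_SbI", "gD": "g_D",
    "gGKP": "g_GKP", "gSmI": "g_SmI", "gSbII": "g_SbII", "gSmII": "g_SmII",
    "gG": "g_G",
}


def _build_section(cls, data: dict, section: str, errors: list[str]):
    fields = {f.name for f in dataclasses.fields(cls)}
    kwargs = {}
    for key, value in data.items():
        name = _CONTROLLER_ALIASES.get(key, key) if cls is ControllerConfig else key
        if name not in fields:
            errors.append(f"{section}.{key}: unknown key")
            continue
        kwargs[name] = value
    try:
        return cls(**kwargs)
    except (TypeError, ValueError) as exc:
        errors.append(f"{section}: {exc}")
        return cls()


def load_config(path: str | Path | None = None) -> RunConfig:
    """Load a YAML config; missing keys fall back to the nominal defaults.

    All validation problems are collected and reported at once via
    :class:`ConfigError`, each naming the offending key.
    """
    data: dict = {}
    if path is not None:
        raw = Path(path).read_text()
        loaded = yaml.safe_load(raw)
        if loaded is None:
            loaded = {}
        if not isinstance(loaded, dict):
            raise ConfigError(["top level must be a mapping of sections"])
        data = loaded

    errors: list[str] = []
    kwargs: dict = {}
    for section, cls in _SECTION_TYPES.items():
        sec_data = data.pop(section, {})
        if sec_data is None:
            sec_data = {}
        if not isinstance(sec_data, dict):
            errors.append(f"{section}: must be a mapping")
            sec_data = {}
        kwargs[section] = _build_section(cls, sec_data, section, errors)

    mode = data.pop("mode", "full_ff")
    if mode not in MODES:
        errors.append(f"mode: {mode!r} is not one of {MODES}")
        mode = "full_ff"
    retro = bool(data.pop("retroactivity", False))

    ref_data = data.pop("reference", None)
    if ref_data is None:
        reference = ReferenceSignal()
    else:
        try:
            segments = tuple((float(t), float(v)) for t, v in ref_data.get("segments", [[0, 4], [40000, 1]]))
            t_end = float(ref_data.get("t_end", 80000.0))
            reference = ReferenceSignal(segments=segments, t_end=t_end)
        except (TypeError, ValueError) as exc:
            errors.append(f"reference: {exc}")
            reference = ReferenceSignal()

    for key in data:
        errors.append(f"{key}: unknown top-level key")
    if errors:
        raise ConfigError(errors)
    return RunConfig(mode=mode, retroactivity=retro, reference=reference, **kwargs)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if hasattr(obj, "tolist"):
        return obj.tolist()
    if hasattr(obj, "item"):
        return obj.item()
    return obj


def write_report(report, path: str | Path, fmt: str | None = None) -> Path:
    """Persist a report: trajectories/tables as CSV, summaries as JSON.

    The format is inferred from the extension unless given explicitly.
    Field ordering is deterministic.
    """
    path = Path(path)
    if fmt is None:
        fmt = path.suffix.lstrip(".").lower() or "json"
    if fmt not in ("csv", "json"):
        raise ValueError(f"unsupported report format {fmt!r}")

    if isinstance(report, Trajectory):
        if fmt != "csv":
            raise ValueError("trajectories are written as CSV")
        report.to_csv(path)
        return path
    if isinstance(report, pd.DataFrame):
        if fmt == "csv":
            report.to_csv(path)
        else:
            path.write_text(report.to_json(orient="index", indent=2))
        return path
    if hasattr(report, "to_frame") and fmt == "csv":
        report.to_frame().to_csv(path, index=False)
        return path
    if hasattr(report, "summary"):
        report = report.summary()
    elif hasattr(report, "to_dict"):
        report = report.to_dict()
    path.write_text(json.dumps(_jsonable(report), indent=2, sort_keys=True) + "\n")
    return path
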