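"""Run configuration and trace serialization shared by all protocols.

Configs and reports are JSON; time series are CSV with a unit-annotated
header and a deterministic column order.
"""
from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from pathlib import Path

import numpy as np

from .integrators import (SolverSettings, SUPPORTED_DT_MS,
                          SUPPORTED_E_TRISEG, METHODS)
from .metrics import Trace
from .steady_state import THRESHOLD_LADDER

PROTOCOLS = ("single_beat", "multi_beat", "pfc", "multistart")


@dataclass
class RunConfig:
    """Validated configuration of one protocol run."""
    protocol: str
    seed: int = 1
    n_samples: int | None = None       # protocol default when None
    n_starts: int = 10                 # multistart only
    methods: list = field(default_factory=lambda: [["adams_moulton", 2]])
    dt_grid_ms: list = field(default_factory=lambda: [1.0, 2.0])
    e_triseg_grid: list = field(default_factory=lambda: [1e-4])
    e_steady: float = 1e-4
    e_steady_ladder: list = field(
        default_factory=lambda: list(THRESHOLD_LADDER))
    max_beats: int | None = None       # protocol default when None
    full_scale: bool = False
    out_dir: str = "results"

    def validate(self) -> None:
        errors = []
        if self.protocol not in PROTOCOLS:
            errors.append(f"protocol: {self.protocol!r} not one of "
                          f"{PROTOCOLS}")
        for m, o in self.methods:
            if m not in METHODS:
                errors.append(f"methods: unknown method {m!r}")
            elif not 1 <= int(o) <= 4:
                errors.append(f"methods: order {o} outside 1..4")
        for dt in self.dt_grid_ms:
            if not any(np.isclose(dt, s) for s in SUPPORTED_DT_MS):
                errors.append(f"dt_grid_ms: {dt} not in supported set "
                              f"{SUPPORTED_DT_MS}")
        for e in self.e_triseg_grid:
            if not any(np.isclose(e, s) for s in SUPPORTED_E_TRISEG):
                errors.append(f"e_triseg_grid: {e} not in supported set "
                              f"{SUPPORTED_E_TRISEG}")
        if not 0.0 <= self.e_steady < 1.0:
            errors.append(f"e_steady: {self.e_steady} outside [0, 1)")
        if self.n_samples is not None and self.n_samples < 1:
            errors.append("n_samples must be >= 1")
        if errors:
            raise ValueError("invalid configuration: " + "; ".join(errors))

    def to_dict(self) -> dict:
        return asdict(self)


def load_config(path: str | Path) -> RunConfig:
    """Load and validate a JSON run configuration, filling defaults.

    Unknown keys are rejected by name so typos surface immediately.
    """
    d = json.loads(Path(path).read_text())
    known = set(RunConfig.__dataclass_fields__)
    unknown = set(d) - known
    if unknown:
        raise ValueError(f"unknown configuration keys: {sorted(unknown)}")
    if "protocol" not in d:
        raise ValueError("configuration must name a protocol")
    cfg = RunConfig(**d)
    cfg.validate()
    return cfg


def save_config(cfg: RunConfig, path: str | Path) -> None:
    Path(path).write_text(json.dumps(cfg.to_dict(), indent=1))


# ---------------------------------------------------------------------
# traces
# ---------------------------------------------------------------------
def write_trace(trace: Trace, path: str | Path) -> None:
    """CSV, one row per timestep; the header carries the units."""
    cols = trace.columns
    data = np.column_stack([trace.time]
                           + [trace.signals[c] for c in cols[1:]]) \
        if trace.time.size else np.empty((0, len(cols)))
    header = ",".join(cols)
    np.savetxt(path, data, delimiter=",", header=header, comments="",
               fmt="%.17g")


def read_trace(path: str | Path) -> Trace:
    path = Path(path)
    with path.open() as fh:
        header = fh.readline().strip()
    if not header:
        raise ValueError(f"{path}: empty trace file (line 1)")
    cols = header.split(",")
    if cols[0] != "time_s":
        raise ValueError(f"{path}: first column must be time_s (line 1)")
    try:
        data = np.loadtxt(path, delimiter=",", skiprows=1, ndmin=2)
    except ValueError as exc:
        raise ValueError(f"{path}: malformed CSV ({exc})") from exc
    if data.size == 0:
        data = np.empty((0, len(cols)))
    if data.shape[1] != len(cols):
        raise ValueError(f"{path}: column count mismatch")
    return Trace(time=data[:, 0],
                 signals={c: data[:, i] for i, c in
                          enumerate(cols) if i > 0})


def write_report(report, path: str | Path) -> None:
    """Protocol report as JSON (rows inline) next to a CSV row table."""
    path = Path(path)
    path.write_text(json.dumps(report.to_json_dict(), indent=1,
                               default=_json_default))
    report.rows.to_csv(path.with_suffix(".csv"), index=False)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, (np.bool_,)):
        return bool(o)
    raise TypeError(f"not JSON serializable: {type(o)}")
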