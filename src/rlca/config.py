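"""Declarative run configuration.

A single YAML file can carry every option the command line accepts
(penalty family/strategy, lambda grids, class counts, tolerances, seeds,
paths); explicit command-line flags override config values.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields
from typing import Any, Optional

import yaml

__all__ = ["RunConfig", "load_config"]


@dataclass
class RunConfig:
    classes: int = 4
    family: str = "mcp"
    strategy: str = "fused_classes"
    lambda1: float = 0.0
    lambda2: float = 0.0
    grid1: Optional[str] = None  # "start:stop:step" strings
    grid2: Optional[str] = None
    criterion: str = "bic"
    concavity: Optional[float] = None
    smooth_eps: float = 1e-4
    fuse_tol: float = 0.01
    iota: int = 0
    seed: int = 0
    n_starts: int = 10
    max_iter: int = 500
    tol: float = 1e-6
    data: Optional[str] = None
    out: Optional[str] = None

    def merged(self, overrides: dict[str, Any]) -> "RunConfig":
        """New config with non-None overrides applied on top."""
        values = {f.name: getattr(self, f.name) for f in fields(self)}
        for k, v in overrides.items():
            if v is not None and k in values:
                values[k] = v
        return RunConfig(**values)


def load_config(path: Optional[str]) -> RunConfig:
    if path is None:
        return RunConfig()
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    flat: dict[str, Any] = {}
    for key, val in raw.items():
        if isinstance(val, dict):  # nested sections are flattened
            flat.update(val)
        else:
            flat[key] = val
    known = {f.name for f in fields(RunConfig)}
    unknown = set(flat) - known
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    return RunConfig(**flat)


def parse_grid(text: Optional[str]) -> Optional[list[float]]:
    """Parse 'start:stop:step' (inclusive) or comma-separated values."""
    if text is None or text == "":
        return None
    if ":" in text:
        parts = [float(p) for p in text.split(":")]
        if len(parts) != 3:
            raise ValueError("grid must be 'start:stop:step'")
        start, stop, step = parts
        if step <= 0 or stop < start:
            raise ValueError("grid requires step > 0 and stop >= start")
        n = int(round((stop - start) / step)) + 1
        return [round(start + j * step, 10) for j in range(n)]
    return [float(p) for p in text.split(",")]
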