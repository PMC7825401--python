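"""Run configuration shared by the CLI commands and report writers.

Every report embeds the fully resolved configuration together with the
package version, so any output file states exactly how it was produced.
"""

from __future__ import annotations

import json
from dataclasses import asdict, dataclass, field
from pathlib import Path

from . import __version__
from .sequences import ScoringScheme
from .structures import DEFAULT_SG_DISTANCE
from .surface import (
    DEFAULT_GRID,
    DEFAULT_INTERFACE_CUTOFF,
    DEFAULT_N_POINTS,
    DEFAULT_PROBE,
)
from .conservation import DEFAULT_SURFACE_THRESHOLD


@dataclass
class RunConfig:
    scheme: ScoringScheme = field(default_factory=ScoringScheme)
    denominator_mode: str = "shorter-sequence"
    probe_radius: float = DEFAULT_PROBE
    n_sphere_points: int = DEFAULT_N_POINTS
    grid_spacing: float = DEFAULT_GRID
    sg_threshold: float = DEFAULT_SG_DISTANCE
    interface_cutoff: float = DEFAULT_INTERFACE_CUTOFF
    surface_threshold: float = DEFAULT_SURFACE_THRESHOLD
    radii_set: str = "bondi"
    seed: int = 0

    def to_dict(self) -> dict:
        out = {
            "package": "arisc",
            "version": __version__,
            "scoring": self.scheme.to_dict(),
            "denominator_mode": self.denominator_mode,
            "probe_radius": self.probe_radius,
            "n_sphere_points": self.n_sphere_points,
            "grid_spacing": self.grid_spacing,
            "sg_threshold": self.sg_threshold,
            "interface_cutoff": self.interface_cutoff,
            "surface_threshold": self.surface_threshold,
            "radii_set": self.radii_set,
            "seed": self.seed,
        }
        return out


def write_report(payload: dict, config: RunConfig, path: str | Path) -> dict:
    """Write a JSON report with the resolved config embedded; returns the
    full document."""
    doc = {"config": config.to_dict(), **payload}
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_jsonable)
    return doc


def _jsonable(obj):
    try:
        import numpy as np

        if isinstance(obj, (np.integer,)):
            return int(obj)
        if isinstance(obj, (np.floating,)):
            return float(obj)
        if isinstance(obj, np.ndarray):
            return obj.tolist()
    except ImportError:  # pragma: no cover
        pass
    if isinstance(obj, tuple):
        return list(obj)
    raise TypeError(f"not JSON serializable: {type(obj)}")
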