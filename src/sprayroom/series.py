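"""Concentration time-series container and its CSV + sidecar persistence.

A :class:`ConcentrationSeries` holds a strictly increasing time grid (hours)
and one concentration column per compartment (mg m^-3), together with a
processing ``stage`` tag and free-form provenance metadata (applied product
mass, background levels, scenario, replicate id, seed).  Series are written
as plain CSV (columns ``time_h``, ``C_<label>``) with a JSON sidecar holding
the stage and metadata, so every module exchanges the same dialect.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd

#: Processing stages in pipeline order.
STAGES = ("raw_signal", "calibrated", "background_subtracted", "smoothed",
          "normalized")


def stage_index(stage: str) -> int:
    try:
        return STAGES.index(stage)
    except ValueError:
        raise ValueError(f"unknown stage {stage!r}; expected one of {STAGES}") from None


@dataclass
class ConcentrationSeries:
    """Per-compartment concentration traces on a common time grid.

    Attributes
    ----------
    times : numpy.ndarray
        Strictly increasing sample times, hours.
    values : numpy.ndarray
        Shape ``(n_times, n_compartments)``; mg m^-3 (or raw instrument
        signal for stage ``raw_signal``).
    compartments : tuple of str
        Column labels, e.g. ``("111", ..., "222")`` or ``("WHOLE_ROOM",)``.
    stage : str
        One of :data:`STAGES`.
    meta : dict
        Provenance: applied mass (g), background level(s), scenario tag,
        replicate id, seed, etc.
    """

    times: np.ndarray
    values: np.ndarray
    compartments: tuple[str, ...]
    stage: str = "calibrated"
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim == 1:
            self.values = self.values[:, None]
        if self.times.ndim != 1 or self.values.shape[0] != self.times.size:
            raise ValueError("values must have one row per time point")
        if self.values.shape[1] != len(self.compartments):
            raise ValueError("values must have one column per compartment")
        if self.times.size >= 2 and not np.all(np.diff(self.times) > 0):
            raise ValueError("time grid must be strictly increasing")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("concentration values must be finite")
        stage_index(self.stage)
        self.compartments = tuple(self.compartments)

    @property
    def n_compartments(self) -> int:
        return len(self.compartments)

    def column(self, compartment: str) -> np.ndarray:
        """The trace of one compartment as a 1-D array."""
        try:
            j = self.compartments.index(compartment)
        except ValueError:
            raise KeyError(f"no compartment {compartment!r} in series") from None
        return self.values[:, j]

    def with_values(self, values: np.ndarray, stage: str | None = None,
                    **meta_updates) -> "ConcentrationSeries":
        """Copy with new values and (optionally) a new stage; metadata merged."""
        new = replace(self, values=np.asarray(values, dtype=float),
                      stage=self.stage if stage is None else stage,
                      meta={**self.meta, **meta_updates})
        return new

    def to_frame(self) -> pd.DataFrame:
        """As a DataFrame with ``time_h`` plus one ``C_<label>`` column each."""
        data = {"time_h": self.times}
        for j, lab in enumerate(self.compartments):
            data[f"C_{lab}"] = self.values[:, j]
        return pd.DataFrame(data)

    # ------------------------------------------------------------------ I/O
    def write_csv(self, path: str | Path) -> Path:
        """Write the CSV and a ``<name>.meta.json`` sidecar next to it."""
        path = Path(path)
        self.to_frame().to_csv(path, index=False, float_format="%.10g")
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        payload = {"stage": self.stage, "compartments": list(self.compartments),
                   "meta": _jsonable(self.meta)}
        sidecar.write_text(json.dumps(payload, indent=1, sort_keys=True))
        return path

    @classmethod
    def read_csv(cls, path: str | Path) -> "ConcentrationSeries":
        """Read a series CSV written by :meth:`write_csv` (sidecar optional)."""
        path = Path(path)
        frame = pd.read_csv(path)
        if "time_h" not in frame.columns:
            raise ValueError(f"{path}: missing time_h column")
        comps = tuple(c[2:] for c in frame.columns if c.startswith("C_"))
        stage, meta = "calibrated", {}
        sidecar = path.with_suffix(path.suffix + ".meta.json")
        if sidecar.exists():
            payload = json.loads(sidecar.read_text())
            stage = payload.get("stage", stage)
            meta = payload.get("meta", {})
        values = frame[[f"C_{c}" for c in comps]].to_numpy()
        return cls(times=frame["time_h"].to_numpy(), values=values,
                   compartments=comps, stage=stage, meta=meta)


def _jsonable(obj):
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
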