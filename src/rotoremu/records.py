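"""Episode records: probe traces, tip observations, stimulus log, termination.

A :class:`SimulationRecord` is the single artifact produced by one simulated
episode and the only thing downstream analysis (biomarkers, classification)
needs.  Persistence is plain text: CSV tables plus a JSON metadata sidecar in
a directory, so records diff cleanly and survive any platform.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

__all__ = ["SimulationRecord"]


@dataclass
class SimulationRecord:
    """Everything observed during one simulated episode."""

    probe_times: np.ndarray | None = None
    probes: dict[str, np.ndarray] = field(default_factory=dict)
    probe_positions: dict[str, tuple[float, float]] = field(default_factory=dict)
    #: per-frame tip observations: list of (t_ms, array of (x, y) in cm)
    tip_frames: list[tuple[float, np.ndarray]] = field(default_factory=list)
    stimuli: list[dict] = field(default_factory=list)
    s1_time: float | None = None
    s2_time: float | None = None
    t_end: float = 0.0
    termination_reason: str = "completed"
    no_propagation: bool = False
    valid: bool = True
    meta: dict = field(default_factory=dict)

    # -- persistence ---------------------------------------------------
    def save(self, path: str | Path) -> None:
        path = Path(path)
        path.mkdir(parents=True, exist_ok=True)
        if self.probe_times is not None:
            df = pd.DataFrame({"t": self.probe_times, **self.probes})
            df.to_csv(path / "probes.csv", index=False)
        rows = [(t, x, y) for t, obs in self.tip_frames for x, y in np.atleast_2d(obs)
                if len(obs)]
        pd.DataFrame(rows, columns=["t", "x", "y"]).to_csv(path / "tips.csv",
                                                           index=False)
        tip_times = [float(t) for t, _ in self.tip_frames]
        meta = {
            "probe_positions": {k: list(v) for k, v in self.probe_positions.items()},
            "stimuli": self.stimuli,
            "s1_time": self.s1_time,
            "s2_time": self.s2_time,
            "t_end": self.t_end,
            "termination_reason": self.termination_reason,
            "no_propagation": self.no_propagation,
            "valid": self.valid,
            "tip_frame_times": tip_times,
            "meta": _jsonable(self.meta),
        }
        (path / "record.json").write_text(json.dumps(meta, indent=1))

    @classmethod
    def load(cls, path: str | Path) -> "SimulationRecord":
        path = Path(path)
        meta = json.loads((path / "record.json").read_text())
        rec = cls(
            probe_positions={k: tuple(v) for k, v in meta["probe_positions"].items()},
            stimuli=meta["stimuli"],
            s1_time=meta["s1_time"],
            s2_time=meta["s2_time"],
            t_end=meta["t_end"],
            termination_reason=meta["termination_reason"],
            no_propagation=meta["no_propagation"],
            valid=meta["valid"],
            meta=meta["meta"],
        )
        probes_csv = path / "probes.csv"
        if probes_csv.exists():
            df = pd.read_csv(probes_csv)
            rec.probe_times = df["t"].to_numpy()
            rec.probes = {c: df[c].to_numpy() for c in df.columns if c != "t"}
        tips = pd.read_csv(path / "tips.csv")
        by_t = {t: g[["x", "y"]].to_numpy() for t, g in tips.groupby("t")}
        rec.tip_frames = [(t, by_t.get(t, np.empty((0, 2))))
                          for t in meta["tip_frame_times"]]
        return rec


def _jsonable(obj):
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, np.generic):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    return obj
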