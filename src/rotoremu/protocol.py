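"""S1-S2 cross-field stimulation and the episode driver.

S1 excites a thin strip along the left edge at t = 0, launching a planar
wave rightward.  The domain center is monitored; when its potential falls
back below ``u_crit`` (the waveback of the S1 wave reaches the middle of the
domain) the S2 stimulus excites the whole lower-left quadrant — the region
behind the wave.  Directional block at the quadrant's corner then curls into
a single rotor at the domain center.  The episode continues for
``post_induction_T`` ms after S2, or until all activity dies out.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .analysis import AnalysisConfig, TipTracker, cv_apd_from_record
from .fk import FKParams
from .records import SimulationRecord
from .solver import (BLOWUP_LIMIT, GridSpec, ProbeRecorder, TissueState,
                     _active_stim, strang_step)

__all__ = ["StimulusEvent", "EpisodeConfig", "probe_layout",
           "run_s1s2_episode", "measure_planar_cv_apd", "measure_cable_cv"]


@dataclass(frozen=True)
class StimulusEvent:
    """Rectangular additive stimulus: du/dt += amplitude inside region."""

    t_on: float          # ms
    duration: float      # ms
    amplitude: float     # 1/ms
    region: tuple[float, float, float, float]  # (x0, x1, y0, y1) cm

    def __post_init__(self):
        if not self.duration > 0:
            raise ValueError("stimulus duration must be positive")


@dataclass(frozen=True)
class EpisodeConfig:
    """Settings of the induction protocol."""

    u_crit: float = 0.05           # waveback detection level (dimensionless)
    s1_strip_width: float = 0.5    # cm
    s2_quadrant: str = "lower_left"
    post_induction_T: float = 8000.0  # ms simulated after S2
    stim_amplitude: float = 1.0    # 1/ms
    stim_duration: float = 2.0     # ms
    s1_timeout: float = 1500.0     # ms to wait for the S1 upstroke at center
    probe_interval: float = 1.0    # ms
    quiet_duration: float = 50.0   # ms of global quiescence => terminated
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)


def probe_layout(grid: GridSpec) -> dict[str, tuple[float, float]]:
    """Virtual probe array plus CV/APD markers.

    A 5x5 regular array inset 10% from each edge; its four corner probes are
    named ``corner_*`` (used by the no-rotor rule), the rest ``probe_*``.
    CV markers sit on the horizontal midline at Lx/3 and 2Lx/3, the APD
    marker at Lx/2.
    """
    fracs = 0.1 + 0.8 * np.arange(5) / 4.0
    probes = {}
    k = 0
    for i, fx in enumerate(fracs):
        for j, fy in enumerate(fracs):
            pos = (fx * grid.Lx, fy * grid.Ly)
            if i in (0, 4) and j in (0, 4):
                name = f"corner_{(i // 4) * 2 + j // 4}"
            else:
                name = f"probe_{k}"
                k += 1
            probes[name] = pos
    ymid = grid.Ly / 2.0
    probes["cv_a"] = (grid.Lx / 3.0, ymid)
    probes["cv_b"] = (2.0 * grid.Lx / 3.0, ymid)
    probes["apd_mid"] = (grid.Lx / 2.0, ymid)
    return probes


def _s2_region(grid: GridSpec, quadrant: str):
    half_x, half_y = grid.Lx / 2.0, grid.Ly / 2.0
    regions = {
        "lower_left": (0.0, half_x, 0.0, half_y),
        "upper_left": (0.0, half_x, half_y, grid.Ly),
        "lower_right": (half_x, grid.Lx, 0.0, half_y),
        "upper_right": (half_x, grid.Lx, half_y, grid.Ly),
    }
    return regions[quadrant]


def run_s1s2_episode(p: FKParams, grid: GridSpec,
                     cfg: EpisodeConfig = EpisodeConfig(),
                     observers=None) -> SimulationRecord:
    """Run one full induction episode and return its record.

    The S2 time is determined on the fly from the center monitor (first
    downward ``u_crit`` crossing after the S1 upstroke).  If the S1 wave
    never depolarizes the center within ``s1_timeout`` ms the record is
    flagged ``no_propagation`` and S2 is never delivered.
    """
    s1 = StimulusEvent(t_on=0.0, duration=cfg.stim_duration,
                       amplitude=cfg.stim_amplitude,
                       region=(0.0, cfg.s1_strip_width, 0.0, grid.Ly))
    if observers is None:
        observers = [ProbeRecorder(probe_layout(grid), cfg.probe_interval),
                     TipTracker(cfg.analysis)]
    ci, cj = grid.nearest_index(grid.Lx / 2.0, grid.Ly / 2.0)

    state = TissueState.rest(grid)
    for obs in observers:
        obs(state, grid)

    record = SimulationRecord(s1_time=0.0)
    stimuli = [s1]
    center_up = False
    s2_time = None
    quiet_since = None
    reason = "completed"
    T_total = None  # set once S2 fires
    while True:
        stim = _active_stim(stimuli, state.t, grid)
        state = strang_step(state, p, grid, stim)
        if np.max(np.abs(state.u)) > BLOWUP_LIMIT:
            record.valid = False
            reason = "blow_up"
            break
        for obs in observers:
            obs(state, grid)
        u_center = float(state.u[ci, cj])
        if s2_time is None:
            if not center_up:
                if u_center >= cfg.u_crit and state.t > cfg.stim_duration:
                    center_up = True
                elif state.t >= cfg.s1_timeout:
                    record.no_propagation = True
                    reason = "no_propagation"
                    break
            elif u_center < cfg.u_crit:
                s2_time = state.t
                stimuli.append(StimulusEvent(
                    t_on=s2_time, duration=cfg.stim_duration,
                    amplitude=cfg.stim_amplitude,
                    region=_s2_region(grid, cfg.s2_quadrant)))
                T_total = s2_time + cfg.post_induction_T
        else:
            if state.t >= T_total:
                break
            if state.t >= s2_time + cfg.stim_duration:
                if float(state.u.max()) < p.u_c:
                    if quiet_since is None:
                        quiet_since = state.t
                    elif state.t - quiet_since >= cfg.quiet_duration:
                        reason = "died_out"
                        break
                else:
                    quiet_since = None

    record.s2_time = s2_time
    record.t_end = state.t
    record.termination_reason = reason
    record.stimuli = [dict(t_on=ev.t_on, duration=ev.duration,
                           amplitude=ev.amplitude, region=list(ev.region))
                      for ev in stimuli]
    for obs in observers:
        fin = getattr(obs, "finalize", None)
        if fin is not None:
            fin(record)
    record.meta["grid"] = dict(Lx=grid.Lx, Ly=grid.Ly, nx=grid.nx,
                               ny=grid.ny, D=grid.D, dt=grid.dt)
    record.meta["params"] = p.to_dict()
    record.meta["scheduled_T"] = T_total if T_total is not None else state.t
    return record


def measure_planar_cv_apd(record: SimulationRecord, grid: GridSpec,
                          cfg: EpisodeConfig = EpisodeConfig()
                          ) -> tuple[float | None, float | None]:
    """Planar-wave CV (cm/s) and APD (ms) of the S1 wave; nulls when the
    relevant ``u_crit`` crossings never occur."""
    return cv_apd_from_record(record, grid.Lx / 3.0, cfg.u_crit)


def measure_cable_cv(p: FKParams, grid: GridSpec, T: float = 500.0,
                     u_crit: float = 0.05, stim_amplitude: float = 1.0,
                     stim_duration: float = 2.0) -> float | None:
    """Conduction velocity (cm/s) of a single pulse on a 1D cable.

    Stimulates the left end and times the upward ``u_crit`` crossings at
    markers placed at Lx/3 and 2Lx/3.
    """
    if grid.ny != 1:
        raise ValueError("measure_cable_cv expects a 1D cable grid (ny = 1)")
    state = TissueState.rest(grid)
    s1 = StimulusEvent(t_on=0.0, duration=stim_duration,
                       amplitude=stim_amplitude,
                       region=(0.0, 0.5, -1.0, 1.0))
    ia, _ = grid.nearest_index(grid.Lx / 3.0, 0.0)
    ib, _ = grid.nearest_index(2.0 * grid.Lx / 3.0, 0.0)
    prev_a = prev_b = 0.0
    t_a = t_b = None
    n_steps = int(round(T / grid.dt))
    for _ in range(n_steps):
        stim = _active_stim([s1], state.t, grid)
        state = strang_step(state, p, grid, stim)
        ua, ub = float(state.u[ia, 0]), float(state.u[ib, 0])
        if t_a is None and prev_a < u_crit <= ua:
            frac = (u_crit - prev_a) / (ua - prev_a)
            t_a = state.t - grid.dt + frac * grid.dt
        if t_b is None and prev_b < u_crit <= ub:
            frac = (u_crit - prev_b) / (ub - prev_b)
            t_b = state.t - grid.dt + frac * grid.dt
            break
        prev_a, prev_b = ua, ub
    if t_a is None or t_b is None or t_b <= t_a:
        return None
    sep = (ib - ia) * grid.dx
    return sep / (t_b - t_a) * 1000.0
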