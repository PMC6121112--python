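"""Reduced three-variable Fenton-Karma ionic dynamics.

The model describes a cardiac cell by a dimensionless membrane potential
``u`` and two gating variables: ``v`` gates the fast inward (excitation)
current and ``w`` gates the slow inward (plateau) current.  Three
phenomenological currents drive ``u``:

* fast inward  ``J_fi = -g_fi * v * H(u - u_c) * (1 - u) * (u - u_c)``
* slow outward ``J_so =  g_so_rest * u * H(u_c - u) + g_so * H(u - u_c)``
* slow inward  ``J_si = -g_si * w * (1 + tanh(k * (u - u_si))) / 2``

with ``H`` the Heaviside step (convention ``H(0) = 1``: the threshold value
counts as activated).  Conductances are expressed in mS/cm^2 and, divided by
the fixed membrane capacitance ``c_m = 1`` uF/cm^2, act numerically as rates
in 1/ms.  Gates relax with piecewise-constant-in-``u`` time constants and are
integrated by the Rush-Larsen exponential scheme, which keeps them in [0, 1]
by construction.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, fields, replace
from importlib import resources

import numpy as np
from numba import njit

__all__ = [
    "FKParams",
    "CellState",
    "REST_STATE",
    "ionic_current",
    "gate_derivatives",
    "gate_step",
    "reaction_substep",
    "single_cell_ap",
    "ActionPotential",
    "load_base_params",
    "load_variability",
]


@dataclass(frozen=True)
class FKParams:
    """Ionic parameters of the reduced Fenton-Karma model.

    Defaults are the modified Beeler-Reuter parameterization.  Conductances
    in mS/cm^2, time constants in ms, thresholds dimensionless.
    """

    g_fi: float = 3.0
    g_so: float = 0.02
    g_so_rest: float = 0.12
    g_si: float = 0.0223
    tau_v_plus: float = 3.33
    tau_v1_minus: float = 1000.0
    tau_v2_minus: float = 19.6
    tau_w_plus: float = 667.0
    tau_w_minus: float = 11.0
    u_c: float = 0.13
    u_si: float = 0.85
    u_v: float = 0.055
    k: float = 10.0
    c_m: float = 1.0

    def __post_init__(self) -> None:
        for name in ("g_fi", "g_so", "g_so_rest", "g_si", "tau_v_plus",
                     "tau_v1_minus", "tau_v2_minus", "tau_w_plus",
                     "tau_w_minus", "c_m"):
            if not getattr(self, name) > 0:
                raise ValueError(f"FKParams.{name} must be strictly positive")
        if not (0.0 < self.u_v < self.u_c < self.u_si < 1.0):
            raise ValueError("thresholds must satisfy 0 < u_v < u_c < u_si < 1")

    def replace(self, **kw) -> "FKParams":
        return replace(self, **kw)

    def to_dict(self) -> dict:
        return {f.name: getattr(self, f.name) for f in fields(self)}

    @classmethod
    def from_dict(cls, d: dict) -> "FKParams":
        return cls(**d)


@dataclass
class CellState:
    """State of a single cell: potential ``u`` and gates ``v``, ``w``."""

    u: float
    v: float
    w: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.u) and math.isfinite(self.v)
                and math.isfinite(self.w)):
            raise ValueError("CellState fields must be finite")


REST_STATE = CellState(u=0.0, v=1.0, w=1.0)


def _currents(u, v, w, p: FKParams):
    """The three FK currents, vectorized over array-valued states."""
    u = np.asarray(u, dtype=float)
    active = u >= p.u_c  # H(0) = 1
    j_fi = np.where(active, -p.g_fi * v * (1.0 - u) * (u - p.u_c), 0.0)
    j_so = np.where(active, p.g_so, p.g_so_rest * u)
    j_si = -p.g_si * w * (1.0 + np.tanh(p.k * (u - p.u_si))) / 2.0
    return j_fi, j_so, j_si


def ionic_current(state, p: FKParams):
    """du/dt contribution of the ionic currents, in 1/ms.

    ``state`` may be a :class:`CellState` or a tuple of arrays ``(u, v, w)``.
    """
    u, v, w = _unpack(state)
    if not (np.all(np.isfinite(u)) and np.all(np.isfinite(v))
            and np.all(np.isfinite(w))):
        raise ValueError("non-finite state passed to ionic_current")
    j_fi, j_so, j_si = _currents(u, v, w, p)
    return -(j_fi + j_so + j_si) / p.c_m


def _unpack(state):
    if isinstance(state, CellState):
        return state.u, state.v, state.w
    u, v, w = state
    return np.asarray(u, float), np.asarray(v, float), np.asarray(w, float)


def _tau_v_minus(u, p: FKParams):
    # recovery of the fast-inward gate switches rate at u_v (H(0)=1)
    return np.where(np.asarray(u) >= p.u_v, p.tau_v1_minus, p.tau_v2_minus)


def gate_derivatives(state, p: FKParams):
    """(dv/dt, dw/dt) in 1/ms for the two gates."""
    u, v, w = _unpack(state)
    active = np.asarray(u) >= p.u_c
    dv = np.where(active, -v / p.tau_v_plus, (1.0 - v) / _tau_v_minus(u, p))
    dw = np.where(active, -w / p.tau_w_plus, (1.0 - w) / p.tau_w_minus)
    return dv, dw


def gate_step(state, dt: float, p: FKParams):
    """Rush-Larsen update of the gates over ``dt`` at frozen ``u``.

    Each gate relaxes exponentially toward its local steady state (0 above
    the activation threshold, 1 below) with the local time constant, so the
    update is exact for piecewise-constant ``u`` and unconditionally keeps
    gates in [0, 1].
    """
    if not dt > 0:
        raise ValueError("dt must be positive")
    u, v, w = _unpack(state)
    active = np.asarray(u) >= p.u_c
    v_new = np.where(active,
                     v * math.exp(-dt / p.tau_v_plus),
                     1.0 + (v - 1.0) * np.exp(-dt / _tau_v_minus(u, p)))
    w_new = np.where(active,
                     w * math.exp(-dt / p.tau_w_plus),
                     1.0 + (w - 1.0) * math.exp(-dt / p.tau_w_minus))
    if isinstance(state, CellState):
        return CellState(u=float(u), v=float(v_new), w=float(w_new))
    return v_new, w_new


@njit(cache=True)
def _reaction_kernel(u, v, w, dt, stim, uniform_stim, g_fi, g_so, g_so_rest,
                     g_si, u_c, u_si, u_v, k, c_m,
                     dec_v_plus, dec_v1, dec_v2, dec_w_plus, dec_w_minus):
    """Fused reaction update over a flat field, second order in dt.

    Strang composition within the reaction: Rush-Larsen gate half-step at
    the initial u, modified-Euler (Heun) full step on u at the half-stepped
    gates, Rush-Larsen gate half-step at the updated u.  ``dec_*`` are the
    precomputed half-step gate decay factors ``exp(-dt / (2 tau))``.  The
    tanh gate of the slow inward current is short-circuited once saturated
    (|arg| > 9.2, where 1 + tanh is within 2e-8 of its limit), which roughly
    halves the cost on mostly-resting tissue.
    """
    n = u.size
    u_new = np.empty_like(u)
    v_new = np.empty_like(v)
    w_new = np.empty_like(w)
    for i in range(n):
        ui, vi, wi = u[i], v[i], w[i]
        st = uniform_stim if stim.size == 1 else stim[i]
        # gate half-step at the initial u
        if ui >= u_c:
            vi = vi * dec_v_plus
            wi = wi * dec_w_plus
        else:
            dv = dec_v1 if ui >= u_v else dec_v2
            vi = 1.0 + (vi - 1.0) * dv
            wi = 1.0 + (wi - 1.0) * dec_w_minus
        # Heun predictor
        if ui >= u_c:
            j = -g_fi * vi * (1.0 - ui) * (ui - u_c) + g_so
        else:
            j = g_so_rest * ui
        a = k * (ui - u_si)
        if a < -9.2:
            si = 0.0
        elif a > 9.2:
            si = 1.0
        else:
            si = (1.0 + math.tanh(a)) / 2.0
        j += -g_si * wi * si
        f0 = -j / c_m + st
        up = ui + dt * f0
        # Heun corrector
        if up >= u_c:
            j = -g_fi * vi * (1.0 - up) * (up - u_c) + g_so
        else:
            j = g_so_rest * up
        a = k * (up - u_si)
        if a < -9.2:
            si = 0.0
        elif a > 9.2:
            si = 1.0
        else:
            si = (1.0 + math.tanh(a)) / 2.0
        j += -g_si * wi * si
        f1 = -j / c_m + st
        un = ui + 0.5 * dt * (f0 + f1)
        u_new[i] = un
        # gate half-step at the updated u
        if un >= u_c:
            v_new[i] = vi * dec_v_plus
            w_new[i] = wi * dec_w_plus
        else:
            dv = dec_v1 if un >= u_v else dec_v2
            v_new[i] = 1.0 + (vi - 1.0) * dv
            w_new[i] = 1.0 + (wi - 1.0) * dec_w_minus
    return u_new, v_new, w_new


def reaction_substep(u, v, w, dt: float, p: FKParams, stim=0.0):
    """One reaction step: modified-Euler (Heun) on ``u``, Rush-Larsen gates.

    The predictor-corrector acts on the ionic current plus the additive
    stimulus term; gate rates are evaluated at the step's initial ``u``.
    Works identically on scalars and on full tissue fields (both paths run
    the same compiled kernel).
    """
    scalar = np.isscalar(u) or np.ndim(u) == 0
    ua = np.atleast_1d(np.asarray(u, dtype=np.float64)).ravel()
    shape = np.shape(u) if not scalar else None
    va = np.atleast_1d(np.asarray(v, dtype=np.float64)).ravel()
    wa = np.atleast_1d(np.asarray(w, dtype=np.float64)).ravel()
    if np.isscalar(stim) or np.ndim(stim) == 0:
        sa, s0 = _ZERO_STIM, float(stim)
    else:
        sa, s0 = np.asarray(stim, dtype=np.float64).ravel(), 0.0
    h = 0.5 * dt
    un, vn, wn = _reaction_kernel(
        ua, va, wa, dt, sa, s0, p.g_fi, p.g_so, p.g_so_rest, p.g_si,
        p.u_c, p.u_si, p.u_v, p.k, p.c_m,
        math.exp(-h / p.tau_v_plus), math.exp(-h / p.tau_v1_minus),
        math.exp(-h / p.tau_v2_minus), math.exp(-h / p.tau_w_plus),
        math.exp(-h / p.tau_w_minus))
    if scalar:
        return float(un[0]), float(vn[0]), float(wn[0])
    return un.reshape(shape), vn.reshape(shape), wn.reshape(shape)


_ZERO_STIM = np.zeros(1)


@dataclass
class ActionPotential:
    """Sampled 0D voltage trace with its measured action potential duration."""

    t: np.ndarray
    u: np.ndarray
    apd: float | None = None
    v: np.ndarray = field(default=None, repr=False)
    w: np.ndarray = field(default=None, repr=False)


def _crossing_times(t, x, level):
    """(upward, downward) linear-interpolated crossing times of ``level``."""
    x = np.asarray(x)
    above = x >= level
    ups, downs = [], []
    for i in np.nonzero(above[1:] != above[:-1])[0]:
        frac = (level - x[i]) / (x[i + 1] - x[i])
        tc = t[i] + frac * (t[i + 1] - t[i])
        (ups if above[i + 1] else downs).append(tc)
    return ups, downs


def single_cell_ap(p: FKParams, stim_amplitude: float = 0.2,
                   stim_duration: float = 2.0, dt: float = 0.1,
                   T: float = 600.0, u_crit: float = 0.05,
                   ap_threshold: float = 0.5) -> ActionPotential:
    """Integrate the space-clamped cell and measure APD at ``u_crit``.

    A constant stimulus of ``stim_amplitude`` (1/ms) is applied for
    ``stim_duration`` ms from t = 0.  APD is the time from the upward to the
    following downward crossing of ``u_crit``.  An action potential counts
    as elicited only when the upstroke is regenerative — the trace must
    exceed ``ap_threshold``, well above anything the stimulus alone
    produces at the default amplitude; otherwise APD is ``None``.
    """
    if not T > stim_duration:
        raise ValueError("T must exceed stim_duration")
    n = int(round(T / dt))
    t = np.arange(n + 1) * dt
    u = np.empty(n + 1)
    vs = np.empty(n + 1)
    ws = np.empty(n + 1)
    uu, vv, ww = 0.0, 1.0, 1.0
    u[0], vs[0], ws[0] = uu, vv, ww
    for i in range(n):
        stim = stim_amplitude if t[i] < stim_duration else 0.0
        uu, vv, ww = reaction_substep(uu, vv, ww, dt, p, stim)
        u[i + 1], vs[i + 1], ws[i + 1] = uu, vv, ww
    apd = None
    if u.max() >= ap_threshold:
        ups, downs = _crossing_times(t, u, u_crit)
        if ups:
            later = [d for d in downs if d > ups[0]]
            if later:
                apd = later[0] - ups[0]
    return ActionPotential(t=t, u=u, apd=apd, v=vs, w=ws)


def _load_json(name: str) -> dict:
    return json.loads(resources.files("rotoremu.data").joinpath(name).read_text())


def load_base_params() -> FKParams:
    """Base parameter set shipped with the package."""
    return FKParams.from_dict(_load_json("table1_base.json"))


def load_variability() -> dict[str, float]:
    """Fractional variability (+/-) of each variable parameter."""
    return _load_json("table1_ranges.json")
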