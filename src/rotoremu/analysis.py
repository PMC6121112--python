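"""Rotor analysis: tip tracking, spectral biomarkers, behavior classification.

A rotor tip (phase singularity) is located as the intersection of the
iso-potential contour ``u = u_iso`` with the instantaneous ``du/dt = 0``
contour, following the classic wavefront/waveback intersection construction.
Tips observed frame-by-frame are linked into trajectories, from which the
spatial biomarkers are computed:

* CV, APD — planar-wave conduction velocity and action potential duration
  measured from the initial (S1) wave at midline markers;
* maximum distance — diameter of the tip trajectory after stabilization;
* dominant frequency (DF) and organization indices (OI1, OI4) — spectral
  summaries of virtual-probe voltage signals and of the tip trajectory.

Episodes are classified as no-rotor, stable rotor, transient rotor, or
fibrillation (wave breakup) from the tip tracks and corner-probe activity.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass, field

import numpy as np
from scipy import signal as ssig
from scipy.optimize import linear_sum_assignment
from scipy.spatial import ConvexHull, QhullError

from .records import SimulationRecord
from .solver import GridSpec, TissueState

__all__ = [
    "AnalysisConfig", "BehaviorClass", "BiomarkerSet", "TipTrack",
    "detect_tips", "link_tips", "TipTracker", "dominant_frequency",
    "organization_index", "max_distance", "track_winding",
    "classify_behavior", "compute_biomarkers", "cv_apd_from_record",
]


class BehaviorClass(str, enum.Enum):
    """Episode-level behavior label."""

    NO_ROTOR = "no_rotor"
    STABLE = "stable"
    TRANSIENT = "transient"
    FIBRILLATION = "fibrillation"
    #: merged label used by classifiers: transient + fibrillation
    CHAOTIC = "chaotic"

    def merged(self) -> "BehaviorClass":
        if self in (BehaviorClass.TRANSIENT, BehaviorClass.FIBRILLATION):
            return BehaviorClass.CHAOTIC
        return self


@dataclass(frozen=True)
class AnalysisConfig:
    """Tunable settings for tip tracking and spectral biomarkers."""

    u_iso: float = 0.5            # iso-potential level for tip detection
    delta_t: float = 2.0          # ms between snapshots for du/dt contour
    gate_distance: float = 0.75   # cm, max frame-to-frame tip displacement
    tracker_interval: float = 1.0  # ms between tip-detection frames
    band: tuple[float, float] = (0.5, 30.0)  # Hz, spectral analysis band
    peak_halfwidth: float = 0.5   # Hz, integration half-width around peaks
    welch_window_ms: float = 2048.0
    min_signal_ms: float = 2000.0  # minimum signal length for spectra
    discard_initial: float = 1000.0  # ms of trajectory discarded before MD
    oi1_coord: str = "x"          # trajectory coordinate fed to OI1
    fib_min_tips: int = 5
    fib_min_lifetime: float = 50.0  # ms
    u_crit: float = 0.05


@dataclass
class TipTrack:
    """One linked tip trajectory."""

    id: int
    t: np.ndarray
    xy: np.ndarray  # (n, 2) in cm

    @property
    def lifetime(self) -> float:
        return float(self.t[-1] - self.t[0])


@dataclass
class BiomarkerSet:
    """The six nullable spatial biomarkers of one episode."""

    cv: float | None = None                  # cm/s
    apd: float | None = None                 # ms
    max_distance: float | None = None        # cm
    dominant_frequency: float | None = None  # Hz
    oi1: float | None = None                 # [0, 1]
    oi4: float | None = None                 # [0, 1]

    NAMES = ("cv", "apd", "max_distance", "dominant_frequency", "oi1", "oi4")

    def to_dict(self) -> dict:
        return {k: getattr(self, k) for k in self.NAMES}


# ---------------------------------------------------------------------------
# tip detection and linking
# ---------------------------------------------------------------------------

def _edge_crossings(c00, c10, c11, c01):
    """Zero crossings of a bilinear field on the four edges of a unit cell.

    Returns a list of (s, t) points in cell coordinates.  Edges are walked
    bottom, right, top, left; exact zeros are nudged off zero.
    """
    eps = 1e-300
    vals = [x if x != 0.0 else eps for x in (c00, c10, c11, c01)]
    c00, c10, c11, c01 = vals
    pts = []
    if c00 * c10 < 0:
        pts.append((c00 / (c00 - c10), 0.0))
    if c10 * c11 < 0:
        pts.append((1.0, c10 / (c10 - c11)))
    if c01 * c11 < 0:
        pts.append((c01 / (c01 - c11), 1.0))
    if c00 * c01 < 0:
        pts.append((0.0, c00 / (c00 - c01)))
    return pts


def _segments(pts, center_val):
    """Pair edge crossings into line segments (marching-squares style)."""
    if len(pts) == 2:
        return [(pts[0], pts[1])]
    if len(pts) == 4:
        # saddle cell: resolve pairing with the cell-center sign
        pts = sorted(pts, key=lambda p: np.arctan2(p[1] - 0.5, p[0] - 0.5))
        if center_val >= 0:
            return [(pts[0], pts[1]), (pts[2], pts[3])]
        return [(pts[1], pts[2]), (pts[3], pts[0])]
    return []


def _seg_intersection(a, b):
    """Intersection point of two 2D segments, or None."""
    (p0, p1), (q0, q1) = a, b
    p0, p1, q0, q1 = map(np.asarray, (p0, p1, q0, q1))
    r, s = p1 - p0, q1 - q0
    denom = r[0] * s[1] - r[1] * s[0]
    if abs(denom) < 1e-14:
        return None
    d = q0 - p0
    t = (d[0] * s[1] - d[1] * s[0]) / denom
    u = (d[0] * r[1] - d[1] * r[0]) / denom
    if -1e-9 <= t <= 1 + 1e-9 and -1e-9 <= u <= 1 + 1e-9:
        return p0 + t * r
    return None


def detect_tips(u_now: np.ndarray, u_prev: np.ndarray, grid: GridSpec,
                u_iso: float = 0.5) -> np.ndarray:
    """Phase singularities from two snapshots ``delta_t`` apart.

    Returns an (k, 2) array of tip positions in cm: intersections of the
    contour ``u_now = u_iso`` with the contour ``u_now - u_prev = 0``,
    located per grid cell from bilinear interpolation of both fields.
    """
    f = u_now - u_iso
    g = u_now - u_prev
    f00, f10, f01, f11 = f[:-1, :-1], f[1:, :-1], f[:-1, 1:], f[1:, 1:]
    g00, g10, g01, g11 = g[:-1, :-1], g[1:, :-1], g[:-1, 1:], g[1:, 1:]

    def _has_sign_change(a, b, c, d):
        mx = np.maximum(np.maximum(a, b), np.maximum(c, d))
        mn = np.minimum(np.minimum(a, b), np.minimum(c, d))
        return (mx > 0) & (mn < 0)

    cand = _has_sign_change(f00, f10, f01, f11) & \
        _has_sign_change(g00, g10, g01, g11)
    tips = []
    for i, j in np.argwhere(cand):
        fpts = _edge_crossings(f[i, j], f[i + 1, j], f[i + 1, j + 1],
                               f[i, j + 1])
        gpts = _edge_crossings(g[i, j], g[i + 1, j], g[i + 1, j + 1],
                               g[i, j + 1])
        fc = 0.25 * (f[i, j] + f[i + 1, j] + f[i + 1, j + 1] + f[i, j + 1])
        gc = 0.25 * (g[i, j] + g[i + 1, j] + g[i + 1, j + 1] + g[i, j + 1])
        for seg_f in _segments(fpts, fc):
            for seg_g in _segments(gpts, gc):
                pt = _seg_intersection(seg_f, seg_g)
                if pt is not None:
                    x = (i + 0.5 + pt[0]) * grid.dx
                    y = (j + 0.5 + pt[1]) * grid.dy
                    tips.append((x, y))
    return np.asarray(tips).reshape(-1, 2)


def link_tips(frames, gate_distance: float = 0.75) -> list[TipTrack]:
    """Link per-frame tip observations into trajectories.

    ``frames`` is a time-ordered sequence of ``(t, (k, 2) array)``.  Matching
    between consecutive frames minimizes the summed displacement (Hungarian
    assignment); pairs farther apart than ``gate_distance`` cm are rejected,
    ending the old track and starting a new one.
    """
    next_id = 0
    active: list[dict] = []
    done: list[dict] = []
    for t, obs in frames:
        obs = np.asarray(obs, float).reshape(-1, 2)
        matched_obs = set()
        still_active = []
        if active and len(obs):
            ends = np.array([tr["xy"][-1] for tr in active])
            cost = np.linalg.norm(ends[:, None, :] - obs[None, :, :], axis=2)
            rows, cols = linear_sum_assignment(cost)
            assigned = {}
            for r, c in zip(rows, cols):
                if cost[r, c] <= gate_distance:
                    assigned[r] = c
                    matched_obs.add(c)
            for r, tr in enumerate(active):
                if r in assigned:
                    c = assigned[r]
                    tr["t"].append(t)
                    tr["xy"].append(obs[c])
                    still_active.append(tr)
                else:
                    done.append(tr)
        else:
            done.extend(active)
        for c in range(len(obs)):
            if c not in matched_obs:
                still_active.append({"id": next_id, "t": [t],
                                     "xy": [obs[c]]})
                next_id += 1
        active = still_active
    done.extend(active)
    done.sort(key=lambda tr: tr["id"])
    return [TipTrack(id=tr["id"], t=np.asarray(tr["t"]),
                     xy=np.asarray(tr["xy"]).reshape(-1, 2)) for tr in done]


class TipTracker:
    """Observer that detects tips every ``interval`` ms during a run."""

    def __init__(self, cfg: AnalysisConfig = AnalysisConfig()):
        self.cfg = cfg
        self.frames: list[tuple[float, np.ndarray]] = []
        self._snaps: list[tuple[float, np.ndarray]] = []
        self._next = 0.0
        self._lag = max(1, int(round(cfg.delta_t / cfg.tracker_interval)))

    def __call__(self, state: TissueState, grid: GridSpec) -> None:
        if state.t + 1e-9 < self._next:
            return
        self._next += self.cfg.tracker_interval
        self._snaps.append((state.t, state.u.copy()))
        if len(self._snaps) <= self._lag:
            return
        t_prev, u_prev = self._snaps[-1 - self._lag]
        tips = detect_tips(state.u, u_prev, grid, self.cfg.u_iso)
        self.frames.append((state.t, tips))
        del self._snaps[0]

    def finalize(self, record: SimulationRecord) -> None:
        record.tip_frames = self.frames


# ---------------------------------------------------------------------------
# spectral biomarkers
# ---------------------------------------------------------------------------

def _welch(x: np.ndarray, fs: float, window_ms: float):
    x = np.asarray(x, float)
    x = x - x.mean()
    nper = min(len(x), int(round(window_ms * fs / 1000.0)))
    return ssig.welch(x, fs=fs, window="hann", nperseg=nper,
                      noverlap=nper // 2)


def averaged_power_spectrum(signals, fs: float,
                            window_ms: float = 2048.0):
    """Welch PSD of each signal, averaged across signals."""
    psds = []
    f = None
    for x in signals:
        f, p = _welch(x, fs, window_ms)
        psds.append(p)
    return f, np.mean(psds, axis=0)


def _df_from_psd(f, psd, band):
    mask = (f >= band[0]) & (f <= band[1])
    if not mask.any() or not np.any(psd[mask] > 0):
        return None
    fb, pb = f[mask], psd[mask]
    return float(fb[np.argmax(pb)])


def _oi_from_psd(f, psd, band, n_peaks, halfwidth):
    mask = (f >= band[0]) & (f <= band[1])
    fb, pb = f[mask], psd[mask]
    total = pb.sum()
    if total <= 0 or len(pb) < 3:
        return None
    idx, _ = ssig.find_peaks(pb)
    if len(idx) == 0:
        idx = np.array([int(np.argmax(pb))])
    order = idx[np.argsort(pb[idx])[::-1]]
    chosen: list[int] = []
    for i in order:
        if all(abs(fb[i] - fb[j]) > 2 * halfwidth for j in chosen):
            chosen.append(i)
        if len(chosen) == n_peaks:
            break
    in_peaks = np.zeros(len(fb), dtype=bool)
    for i in chosen:
        in_peaks |= np.abs(fb - fb[i]) <= halfwidth
    return float(pb[in_peaks].sum() / total)


def dominant_frequency(x: np.ndarray, fs: float,
                       band: tuple[float, float] = (0.5, 30.0),
                       window_ms: float = 2048.0) -> float | None:
    """Frequency (Hz) of the largest Welch-spectrum peak within ``band``."""
    x = np.asarray(x, float)
    if not np.any(x != x.mean()):
        return None
    f, psd = _welch(x, fs, window_ms)
    return _df_from_psd(f, psd, band)


def organization_index(x: np.ndarray, fs: float, n_peaks: int = 4,
                       peak_halfwidth: float = 0.5,
                       band: tuple[float, float] = (0.5, 30.0),
                       window_ms: float = 2048.0) -> float | None:
    """Fraction of in-band power within +-``peak_halfwidth`` of the
    ``n_peaks`` largest non-overlapping spectral peaks."""
    x = np.asarray(x, float)
    if not np.any(x != x.mean()):
        return None
    f, psd = _welch(x, fs, window_ms)
    return _oi_from_psd(f, psd, band, n_peaks, peak_halfwidth)


# ---------------------------------------------------------------------------
# trajectory biomarkers
# ---------------------------------------------------------------------------

def max_distance(track: TipTrack, discard_initial: float = 1000.0
                 ) -> float | None:
    """Greatest pairwise distance (cm) on the trajectory after discarding the
    first ``discard_initial`` ms (stabilization)."""
    keep = track.t >= track.t[0] + discard_initial
    pts = track.xy[keep]
    if len(pts) < 2:
        return None
    if len(pts) > 50:
        try:
            pts = pts[ConvexHull(pts).vertices]
        except QhullError:
            pass  # degenerate (collinear) cloud: brute-force below
    d = np.linalg.norm(pts[:, None, :] - pts[None, :, :], axis=2)
    return float(d.max())


def track_winding(track: TipTrack) -> float:
    """Maximum accumulated rotation angle (radians) about the running
    centroid of the trajectory; a full rotor rotation contributes 2*pi."""
    if len(track.xy) < 3:
        return 0.0
    centroids = np.cumsum(track.xy, axis=0) / \
        np.arange(1, len(track.xy) + 1)[:, None]
    rel = track.xy - centroids
    ang = np.arctan2(rel[:, 1], rel[:, 0])
    r = np.linalg.norm(rel, axis=1)
    ok = r > 1e-9
    ang = ang[ok]
    if len(ang) < 3:
        return 0.0
    dth = np.angle(np.exp(1j * np.diff(ang)))
    return float(np.max(np.abs(np.concatenate([[0.0], np.cumsum(dth)]))))


# ---------------------------------------------------------------------------
# classification and biomarker assembly
# ---------------------------------------------------------------------------

def _upward_crossing_after(t, x, level, t_after):
    x = np.asarray(x)
    sel = t >= t_after
    xs, ts = x[sel], t[sel]
    up = (xs[:-1] < level) & (xs[1:] >= level)
    return bool(up.any()), ts


def classify_behavior(record: SimulationRecord, T: float,
                      cfg: AnalysisConfig = AnalysisConfig(),
                      tracks: list[TipTrack] | None = None) -> BehaviorClass:
    """Assign the episode behavior label.

    Fibrillation: at least ``fib_min_tips`` tracks each living at least
    ``fib_min_lifetime`` ms.  No rotor: propagation failed, or the rotor
    never completes one rotation (judged both by corner-probe silence after
    S2 and by trajectory winding < 2*pi).  Stable: activity persists to the
    scheduled end; otherwise transient.
    """
    if not record.valid:
        raise ValueError("cannot classify an invalid (blown-up) record")
    if record.no_propagation or record.s2_time is None:
        return BehaviorClass.NO_ROTOR
    if tracks is None:
        tracks = link_tips(record.tip_frames, cfg.gate_distance)
    long_tracks = [tr for tr in tracks if tr.lifetime >= cfg.fib_min_lifetime]
    if len(long_tracks) >= cfg.fib_min_tips:
        return BehaviorClass.FIBRILLATION
    corners = [k for k in record.probes if k.startswith("corner_")]
    corner_silent = False
    if corners and record.probe_times is not None:
        for k in corners:
            seen, _ = _upward_crossing_after(record.probe_times,
                                             record.probes[k],
                                             record.meta.get("params", {})
                                             .get("u_c", 0.13),
                                             record.s2_time)
            if not seen:
                corner_silent = True
                break
    completes_rotation = any(track_winding(tr) >= 2 * np.pi for tr in tracks)
    if corner_silent or not completes_rotation:
        return BehaviorClass.NO_ROTOR
    if record.termination_reason == "completed" and record.t_end >= T - 1e-6:
        return BehaviorClass.STABLE
    return BehaviorClass.TRANSIENT


def cv_apd_from_record(record: SimulationRecord, marker_sep: float,
                       u_crit: float = 0.05
                       ) -> tuple[float | None, float | None]:
    """Planar CV (cm/s) and APD (ms) from the S1 wave at midline markers.

    CV uses the first upward ``u_crit`` crossings at probes ``cv_a`` and
    ``cv_b`` separated by ``marker_sep`` cm; APD is the first
    upward-to-downward crossing interval at probe ``apd_mid``.
    """
    t = record.probe_times
    if t is None:
        return None, None

    def _first_up(x):
        x = np.asarray(x)
        up = np.nonzero((x[:-1] < u_crit) & (x[1:] >= u_crit))[0]
        if len(up) == 0:
            return None
        i = up[0]
        frac = (u_crit - x[i]) / (x[i + 1] - x[i])
        return t[i] + frac * (t[i + 1] - t[i])

    def _first_down(x, after):
        x = np.asarray(x)
        dn = np.nonzero((x[:-1] >= u_crit) & (x[1:] < u_crit))[0]
        for i in dn:
            frac = (x[i] - u_crit) / (x[i] - x[i + 1])
            tc = t[i] + frac * (t[i + 1] - t[i])
            if tc > after:
                return tc
        return None

    cv = apd = None
    if "cv_a" in record.probes and "cv_b" in record.probes:
        ta = _first_up(record.probes["cv_a"])
        tb = _first_up(record.probes["cv_b"])
        if ta is not None and tb is not None and tb > ta:
            cv = marker_sep / (tb - ta) * 1000.0  # ms -> s
    if "apd_mid" in record.probes:
        up = _first_up(record.probes["apd_mid"])
        if up is not None:
            dn = _first_down(record.probes["apd_mid"], up)
            if dn is not None:
                apd = dn - up
    return cv, apd


def compute_biomarkers(record: SimulationRecord, grid: GridSpec,
                       cfg: AnalysisConfig = AnalysisConfig(),
                       T: float | None = None) -> tuple[BiomarkerSet,
                                                        BehaviorClass]:
    """Assemble the six biomarkers and the behavior class for one episode.

    Nullability follows the class: CV/APD are null only when the S1 wave
    fails; DF/OI4 require rotor activity; maximum distance and OI1 are
    defined for stable rotors only.
    """
    if T is None:
        T = record.meta.get("scheduled_T", record.t_end)
    marker_sep = grid.Lx / 3.0
    cv, apd = cv_apd_from_record(record, marker_sep, cfg.u_crit)
    bm = BiomarkerSet(cv=cv, apd=apd)
    tracks = link_tips(record.tip_frames, cfg.gate_distance)
    label = classify_behavior(record, T, cfg, tracks=tracks)

    fs = 1000.0 / cfg.tracker_interval
    if label is not BehaviorClass.NO_ROTOR and record.probe_times is not None \
            and record.s2_time is not None:
        sel = record.probe_times >= record.s2_time
        if sel.sum() * cfg.tracker_interval >= cfg.min_signal_ms:
            sigs = [record.probes[k][sel] - record.probes[k][sel].mean()
                    for k in record.probes if k.startswith(("probe_",
                                                            "corner_"))]
            if sigs:
                f, psd = averaged_power_spectrum(sigs, fs,
                                                 cfg.welch_window_ms)
                bm.dominant_frequency = _df_from_psd(f, psd, cfg.band)
                bm.oi4 = _oi_from_psd(f, psd, cfg.band, 4,
                                      cfg.peak_halfwidth)
    if label is BehaviorClass.STABLE and tracks:
        longest = max(tracks, key=lambda tr: tr.lifetime)
        bm.max_distance = max_distance(longest, cfg.discard_initial)
        coord = {"x": longest.xy[:, 0], "y": longest.xy[:, 1],
                 "complex": longest.xy[:, 0] + 1j * longest.xy[:, 1]}
        sig = coord[cfg.oi1_coord]
        if longest.lifetime >= cfg.min_signal_ms and cfg.oi1_coord != "complex":
            bm.oi1 = organization_index(np.real(sig), fs, n_peaks=1,
                                        peak_halfwidth=cfg.peak_halfwidth,
                                        band=cfg.band,
                                        window_ms=cfg.welch_window_ms)
    return bm, label
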