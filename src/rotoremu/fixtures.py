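"""Synthetic generators with known ground truth for testing the pipeline.

None of these aim at physiological realism: they provide constructed rotor
fields with a singularity at a known position, probe signals with known
spectra, and response surfaces with known smooth/discontinuous/nullable
structure shaped exactly like campaign output, so every downstream stage can
be exercised through its production interfaces in milliseconds.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .design import BIOMARKER_COLS, CampaignDataset, ParameterSpace, lhs_design
from .solver import GridSpec

__all__ = ["SpiralFieldSpec", "make_spiral_field", "make_probe_signal",
           "make_test_surface"]


@dataclass(frozen=True)
class SpiralFieldSpec:
    """Rigidly rotating Archimedean-spiral voltage pattern."""

    grid: GridSpec
    center: tuple[float, float]    # cm
    frequency: float = 5.0         # Hz (rotations per second)
    pitch: float = 2.0             # cm between successive wavefronts

    def __post_init__(self):
        if not self.frequency > 0:
            raise ValueError("rotation frequency must be positive")
        x0, y0 = self.center
        if not (0 < x0 < self.grid.Lx and 0 < y0 < self.grid.Ly):
            raise ValueError("spiral center must lie inside the domain")


def make_spiral_field(spec: SpiralFieldSpec, t: float,
                      mirror: bool = False) -> np.ndarray:
    """Snapshot u(x, y, t) of the spiral; the unique phase singularity sits
    at the spiral center (a mirrored pair straddles the vertical midline
    when ``mirror`` is set)."""
    g = spec.grid
    X, Y = np.meshgrid(g.x, g.y, indexing="ij")

    def phase(x0, y0, chirality=1.0):
        dx, dy = X - x0, Y - y0
        r = np.hypot(dx, dy)
        return chirality * np.arctan2(dy, dx) - 2 * np.pi * r / spec.pitch \
            + 2 * np.pi * spec.frequency * (t / 1000.0)

    if not mirror:
        return 0.5 * (1.0 + np.cos(phase(*spec.center)))
    # combined phase winds +1 about the center and -1 about its mirror
    # image, so the smooth field has exactly two singularities
    x0, y0 = spec.center
    phi = phase(x0, y0, 1.0) + phase(g.Lx - x0, y0, -1.0)
    return 0.5 * (1.0 + np.cos(phi))


def make_probe_signal(tones, noise_sd: float, fs: float, T: float,
                      seed: int = 0) -> np.ndarray:
    """Sum of sinusoids plus seeded white Gaussian noise.

    ``tones`` is a list of (frequency_hz, amplitude); ``T`` in seconds.
    """
    for f, _ in tones:
        if f >= fs / 2:
            raise ValueError("tone frequency above Nyquist")
    n = int(round(T * fs))
    t = np.arange(n) / fs
    x = np.zeros(n)
    for f, a in tones:
        x += a * np.sin(2 * np.pi * f * t)
    if noise_sd > 0:
        x += np.random.default_rng(seed).normal(0.0, noise_sd, n)
    return x


# --- synthetic response surfaces ------------------------------------------

def _unit_space() -> ParameterSpace:
    return ParameterSpace(names=("x0", "x1"), base=(0.5, 0.5),
                          low=(0.0, 0.0), high=(1.0, 1.0))


def _boundary(x0):
    """Curved class boundary in the unit square."""
    return 0.5 + 0.15 * np.sin(2 * np.pi * x0)


def _smooth(x0, x1):
    return np.sin(3.0 * x0) + x1 ** 2


#: half-width of the exclusion band around the class boundary.  The
#: partitioning method presumes behavior regions that are well-separated in
#: parameter space; the band encodes that premise so the fixture tests the
#: emulation mechanism, not boundary estimation from ambiguous data.
BOUNDARY_MARGIN = 0.08

#: jump of the discontinuous surface across the boundary, in units of the
#: smooth component's order-1 variation
SURFACE_JUMP = 5.0


def make_test_surface(kind: str, seed: int = 0, n: int = 400
                      ) -> CampaignDataset:
    """Synthetic campaign dataset with a known response surface.

    kinds:
      ``smooth``     one class, one analytic surface — a single GP suffices;
      ``two_region`` two classes split by a known curved boundary (with a
                     thin separation band, see :data:`BOUNDARY_MARGIN`);
                     the dominant-frequency surface jumps by
                     :data:`SURFACE_JUMP` across it on top of order-1 smooth
                     variation, and max_distance is smooth everywhere;
      ``nullable``   as two_region, but max_distance is defined only in the
                     'stable' region (null elsewhere).

    The frame carries the same columns as real campaign output, so emulator
    training and evaluation run unchanged on it.
    """
    if kind not in ("smooth", "two_region", "nullable"):
        raise ValueError(f"unknown surface kind: {kind}")
    space = _unit_space()
    X = lhs_design(space, n, seed)
    x0, x1 = X[:, 0], X[:, 1]
    if kind != "smooth":
        b = _boundary(x0)
        d = x1 - b
        x1 = np.clip(np.where(np.abs(d) < BOUNDARY_MARGIN,
                              b + BOUNDARY_MARGIN * np.sign(d + 1e-12), x1),
                     0.0, 1.0)
        X = np.column_stack([x0, x1])
    df = pd.DataFrame({"x0": x0, "x1": x1})
    for c in BIOMARKER_COLS:
        df[c] = np.nan
    if kind == "smooth":
        df["label"] = "stable"
        df["dominant_frequency"] = _smooth(x0, x1)
        df["cv"] = 40.0 + 10.0 * x0
    else:
        stable = x1 < _boundary(x0)
        df["label"] = np.where(stable, "stable", "chaotic")
        df["dominant_frequency"] = _smooth(x0, x1) + SURFACE_JUMP * (~stable)
        df["cv"] = 40.0 + 10.0 * x0
        md = 1.0 + np.cos(2.0 * x0) + 0.5 * x1
        if kind == "nullable":
            df["max_distance"] = np.where(stable, md, np.nan)
        else:
            df["max_distance"] = md
    df["valid"] = True
    prov = dict(kind=kind, seed=seed, n=n, synthetic=True)
    return CampaignDataset(df=df, space=space, provenance=prov)
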