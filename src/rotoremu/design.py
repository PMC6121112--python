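"""Latin hypercube experiment design, campaign execution and dataset storage.

A campaign maps an LHS design over the ionic-parameter space through the
S1-S2 episode pipeline (simulate, track, classify, measure biomarkers) and
collects one labeled row per design point.  Datasets are stored as a CSV
table plus a JSON provenance sidecar so they remain diff-able and
language-neutral.
"""

from __future__ import annotations

import hashlib
import json
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import qmc

from .analysis import AnalysisConfig, BiomarkerSet, compute_biomarkers
from .fk import FKParams, load_base_params, load_variability
from .protocol import EpisodeConfig, run_s1s2_episode
from .solver import GridSpec

__all__ = ["ParameterSpace", "CampaignDataset", "lhs_design", "run_campaign",
           "split_dataset"]

BIOMARKER_COLS = list(BiomarkerSet.NAMES)

#: the eight parameters analyzed in the multi-parameter study; the resting
#: slow-outward conductance is held at base by default.
MULTI_PARAM_NAMES = ("g_fi", "g_so", "g_si", "tau_v_plus", "tau_v1_minus",
                     "tau_v2_minus", "tau_w_plus", "tau_w_minus")


@dataclass(frozen=True)
class ParameterSpace:
    """Ordered box of varied parameters with base values and bounds."""

    names: tuple[str, ...]
    base: tuple[float, ...]
    low: tuple[float, ...]
    high: tuple[float, ...]

    def __post_init__(self):
        lo, b, hi = map(np.asarray, (self.low, self.base, self.high))
        if not (np.all(lo < b) and np.all(b < hi)):
            raise ValueError("bounds must satisfy low < base < high")

    @property
    def dims(self) -> int:
        return len(self.names)

    @classmethod
    def from_fractions(cls, names, fractions: dict[str, float] | None = None,
                       base_params: FKParams | None = None
                       ) -> "ParameterSpace":
        """Bounds = base * (1 +- fraction) for each named parameter."""
        if fractions is None:
            fractions = load_variability()
        if base_params is None:
            base_params = load_base_params()
        base = tuple(getattr(base_params, n) for n in names)
        frac = tuple(fractions[n] for n in names)
        low = tuple(b * (1 - f) for b, f in zip(base, frac))
        high = tuple(b * (1 + f) for b, f in zip(base, frac))
        return cls(tuple(names), base, low, high)

    @classmethod
    def two_param(cls) -> "ParameterSpace":
        """g_fi (+-30%) and g_so (+-20%): excitability vs repolarization."""
        return cls.from_fractions(("g_fi", "g_so"))

    @classmethod
    def multi_param(cls, include_g_so_rest: bool = False) -> "ParameterSpace":
        names = MULTI_PARAM_NAMES + (("g_so_rest",) if include_g_so_rest
                                     else ())
        return cls.from_fractions(names)

    def to_fk_params(self, row, base_params: FKParams | None = None
                     ) -> FKParams:
        if base_params is None:
            base_params = load_base_params()
        return base_params.replace(**dict(zip(self.names, map(float, row))))

    def normalize(self, X: np.ndarray) -> np.ndarray:
        lo, hi = np.asarray(self.low), np.asarray(self.high)
        return (np.asarray(X, float) - lo) / (hi - lo)

    def denormalize(self, U: np.ndarray) -> np.ndarray:
        lo, hi = np.asarray(self.low), np.asarray(self.high)
        return lo + np.asarray(U, float) * (hi - lo)

    def to_dict(self) -> dict:
        return dict(names=list(self.names), base=list(self.base),
                    low=list(self.low), high=list(self.high))

    @classmethod
    def from_dict(cls, d: dict) -> "ParameterSpace":
        return cls(tuple(d["names"]), tuple(d["base"]), tuple(d["low"]),
                   tuple(d["high"]))


def lhs_design(space: ParameterSpace, n: int, seed: int) -> np.ndarray:
    """Latin hypercube sample of ``n`` points in physical units.

    Each marginal is stratified into ``n`` equal-probability bins with
    exactly one point per bin, uniform within its bin; stratum pairing
    across dimensions is random but fully determined by ``seed``.
    """
    if n < 2:
        raise ValueError("LHS design needs n >= 2")
    sampler = qmc.LatinHypercube(d=space.dims, seed=seed)
    return space.denormalize(sampler.random(n))


@dataclass
class CampaignDataset:
    """Design matrix + labels + biomarkers with provenance."""

    df: pd.DataFrame
    space: ParameterSpace
    provenance: dict = field(default_factory=dict)

    @property
    def n(self) -> int:
        return len(self.df)

    def X(self) -> np.ndarray:
        return self.df[list(self.space.names)].to_numpy(float)

    def labels(self) -> np.ndarray:
        return self.df["label"].to_numpy()

    def biomarkers(self) -> pd.DataFrame:
        return self.df[BIOMARKER_COLS]

    def save(self, csv_path: str | Path) -> None:
        csv_path = Path(csv_path)
        csv_path.parent.mkdir(parents=True, exist_ok=True)
        self.df.to_csv(csv_path, index=False)
        sidecar = csv_path.with_suffix(".json")
        sidecar.write_text(json.dumps(
            {"space": self.space.to_dict(), "provenance": self.provenance},
            indent=1))

    @classmethod
    def load(cls, csv_path: str | Path) -> "CampaignDataset":
        csv_path = Path(csv_path)
        df = pd.read_csv(csv_path)
        meta = json.loads(csv_path.with_suffix(".json").read_text())
        return cls(df=df, space=ParameterSpace.from_dict(meta["space"]),
                   provenance=meta["provenance"])


def _row_seed(campaign_seed: int, index: int) -> int:
    h = hashlib.sha256(f"{campaign_seed}:{index}".encode()).digest()
    return int.from_bytes(h[:4], "little") % (2 ** 31)


def _run_one(index: int, theta, space: ParameterSpace, grid: GridSpec,
             cfg: EpisodeConfig, seed: int) -> dict:
    row = {name: float(v) for name, v in zip(space.names, theta)}
    row["index"] = index
    row["seed"] = _row_seed(seed, index)
    try:
        p = space.to_fk_params(theta)
        rec = run_s1s2_episode(p, grid, cfg)
        bm, label = compute_biomarkers(rec, grid, cfg.analysis,
                                       T=rec.meta["scheduled_T"])
        row.update(bm.to_dict())
        row["label"] = label.value
        row["valid"] = bool(rec.valid)
        row["t_end"] = rec.t_end
        row["termination"] = rec.termination_reason
    except Exception as exc:  # episode failures never abort the campaign
        row.update({k: None for k in BIOMARKER_COLS})
        row["label"] = None
        row["valid"] = False
        row["t_end"] = np.nan
        row["termination"] = f"error: {exc}"
    return row


def run_campaign(space: ParameterSpace, n: int, grid: GridSpec,
                 cfg: EpisodeConfig = EpisodeConfig(), seed: int = 0,
                 workers: int = 1,
                 checkpoint: str | Path | None = None,
                 progress: bool = False) -> CampaignDataset:
    """Simulate and analyze one episode per LHS design point.

    Deterministic given ``(space, n, grid, cfg, seed)``.  With a
    ``checkpoint`` CSV path, completed rows are appended as they finish and
    an interrupted campaign resumes where it left off, producing the same
    final table as an uninterrupted run.
    """
    design = lhs_design(space, n, seed)
    done: dict[int, dict] = {}
    ckpt = Path(checkpoint) if checkpoint else None
    if ckpt is not None and ckpt.exists():
        prev = pd.read_csv(ckpt)
        done = {int(r["index"]): r.to_dict() for _, r in prev.iterrows()}
    todo = [i for i in range(n) if i not in done]

    if workers > 1 and todo:
        from joblib import Parallel, delayed
        results = Parallel(n_jobs=workers)(
            delayed(_run_one)(i, design[i], space, grid, cfg, seed)
            for i in todo)
        for row in results:
            done[row["index"]] = row
            if ckpt is not None:
                _append_checkpoint(ckpt, row)
    else:
        for i in todo:
            t0 = time.time()
            row = _run_one(i, design[i], space, grid, cfg, seed)
            done[i] = row
            if ckpt is not None:
                _append_checkpoint(ckpt, row)
            if progress:
                print(f"[campaign] {i + 1}/{n} label={row['label']} "
                      f"({time.time() - t0:.1f}s)", flush=True)

    rows = [done[i] for i in range(n)]
    df = pd.DataFrame(rows)
    prov = dict(seed=seed, n=n,
                grid=dict(Lx=grid.Lx, Ly=grid.Ly, nx=grid.nx, ny=grid.ny,
                          D=grid.D, dt=grid.dt),
                episode=dict(post_induction_T=cfg.post_induction_T,
                             u_crit=cfg.u_crit,
                             stim_amplitude=cfg.stim_amplitude,
                             stim_duration=cfg.stim_duration))
    return CampaignDataset(df=df, space=space, provenance=prov)


def _append_checkpoint(path: Path, row: dict) -> None:
    df = pd.DataFrame([row])
    path.parent.mkdir(parents=True, exist_ok=True)
    df.to_csv(path, mode="a", header=not path.exists(), index=False)


def split_dataset(ds: CampaignDataset, n_train: int, seed: int
                  ) -> tuple[CampaignDataset, CampaignDataset]:
    """Uniform random train/test partition without replacement."""
    if not 0 < n_train < ds.n:
        raise ValueError(f"n_train must be in (0, {ds.n})")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(ds.n)
    tr, te = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    prov = dict(ds.provenance, split_seed=seed, n_train=n_train)
    return (CampaignDataset(ds.df.iloc[tr].reset_index(drop=True), ds.space,
                            dict(prov, part="train")),
            CampaignDataset(ds.df.iloc[te].reset_index(drop=True), ds.space,
                            dict(prov, part="test")))
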