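"""Tip tracking, spectral biomarkers and behavior classification tests."""

import itertools

import numpy as np
import pytest

from rotoremu.analysis import (AnalysisConfig, BehaviorClass, TipTrack,
                               classify_behavior, compute_biomarkers,
                               detect_tips, dominant_frequency, link_tips,
                               max_distance, organization_index,
                               track_winding)
from rotoremu.fixtures import (SpiralFieldSpec, make_probe_signal,
                               make_spiral_field)
from rotoremu.records import SimulationRecord
from rotoremu.solver import GridSpec


@pytest.fixture(scope="module")
def spiral_grid():
    return GridSpec(Lx=4.0, Ly=4.0, nx=64, ny=64)


class TestDetectTips:
    def test_planar_wave_has_no_singularity(self, spiral_grid):
        g = spiral_grid
        X = np.meshgrid(g.x, g.y, indexing="ij")[0]
        u_now = 1.0 / (1.0 + np.exp(-(X - 2.0) / 0.2))
        u_prev = 1.0 / (1.0 + np.exp(-(X - 1.9) / 0.2))
        assert len(detect_tips(u_now, u_prev, g, 0.5)) == 0

    def test_spiral_singularity_localized_within_two_cells(self, spiral_grid):
        spec = SpiralFieldSpec(grid=spiral_grid, center=(1.8, 2.1),
                               frequency=5.0, pitch=2.0)
        tips = detect_tips(make_spiral_field(spec, 0.0),
                           make_spiral_field(spec, -2.0), spiral_grid, 0.5)
        assert len(tips) == 1
        err = np.hypot(tips[0, 0] - 1.8, tips[0, 1] - 2.1)
        assert err < 2 * spiral_grid.dx

    def test_mirrored_pair_gives_two_symmetric_tips(self, spiral_grid):
        spec = SpiralFieldSpec(grid=spiral_grid, center=(1.3, 2.1),
                               frequency=5.0, pitch=2.0)
        tips = detect_tips(make_spiral_field(spec, 0.0, mirror=True),
                           make_spiral_field(spec, -2.0, mirror=True),
                           spiral_grid, 0.5)
        assert len(tips) == 2
        tips = tips[np.argsort(tips[:, 0])]
        # created in pairs, mirror-symmetric about x = Lx/2
        assert tips[0, 0] + tips[1, 0] == pytest.approx(spiral_grid.Lx,
                                                        abs=0.05)
        assert tips[0, 1] == pytest.approx(tips[1, 1], abs=0.05)


class TestLinkTips:
    def test_stationary_tip_forms_single_track(self):
        frames = [(float(t), np.array([[1.0, 1.0]])) for t in range(10)]
        tracks = link_tips(frames, gate_distance=0.75)
        assert len(tracks) == 1
        assert tracks[0].lifetime == 9.0

    def test_distant_tips_never_merge(self):
        frames = [(float(t), np.array([[0.5, 0.5], [3.0, 3.0]]))
                  for t in range(5)]
        tracks = link_tips(frames, gate_distance=0.75)
        assert len(tracks) == 2
        assert all(tr.lifetime == 4.0 for tr in tracks)

    def test_gated_separation_starts_new_track(self):
        frames = [(0.0, np.array([[1.0, 1.0]])),
                  (1.0, np.array([[2.5, 1.0]]))]  # jump beyond the gate
        tracks = link_tips(frames, gate_distance=0.75)
        assert len(tracks) == 2

    def test_crossing_assignment_matches_brute_force(self):
        # two tips approach within the gate for one frame; the linker must
        # pick the pairing that minimizes summed displacement
        prev = np.array([[1.0, 1.0], [1.4, 1.0], [2.4, 2.0]])
        cur = np.array([[1.1, 1.05], [1.35, 0.9], [2.5, 2.0]])
        frames = [(0.0, prev), (1.0, cur)]
        tracks = link_tips(frames, gate_distance=0.75)
        assert len(tracks) == 3  # count preserved

        def total(perm):
            return sum(np.linalg.norm(prev[i] - cur[j])
                       for i, j in enumerate(perm))

        best = min(itertools.permutations(range(3)), key=total)
        got = {}
        for tr in tracks:
            i = int(np.argmin(np.linalg.norm(prev - tr.xy[0], axis=1)))
            j = int(np.argmin(np.linalg.norm(cur - tr.xy[1], axis=1)))
            got[i] = j
        assert tuple(got[i] for i in range(3)) == best


class TestSpectra:
    fs = 500.0

    def test_dominant_frequency_of_pure_tone(self):
        x = make_probe_signal([(8.0, 1.0)], 0.0, self.fs, 64.0, seed=0)
        df = dominant_frequency(x, self.fs)
        assert abs(df - 8.0) <= self.fs / 1024  # one Welch bin

    def test_dominant_frequency_picks_larger_peak(self):
        x = make_probe_signal([(6.0, 2.0), (12.0, 1.0)], 0.0, self.fs, 64.0)
        assert abs(dominant_frequency(x, self.fs) - 6.0) <= 0.5

    def test_df_invariant_to_dc_offset(self):
        x = make_probe_signal([(8.0, 1.0)], 0.0, self.fs, 64.0)
        assert dominant_frequency(x + 17.3, self.fs) == \
            dominant_frequency(x, self.fs)

    def test_all_zero_signal_gives_null(self):
        assert dominant_frequency(np.zeros(4096), self.fs) is None
        assert organization_index(np.zeros(4096), self.fs) is None

    def test_oi1_of_pure_tone_near_one(self):
        x = make_probe_signal([(5.0, 1.0)], 0.0, self.fs, 64.0)
        assert organization_index(x, self.fs, n_peaks=1) >= 0.95

    def test_oi1_of_two_equal_tones_is_half(self):
        # Parseval: each tone carries half the total band power
        x = make_probe_signal([(5.0, 1.0), (11.0, 1.0)], 0.0, self.fs, 64.0)
        assert organization_index(x, self.fs, n_peaks=1) == \
            pytest.approx(0.5, abs=0.05)

    def test_oi4_of_white_noise_matches_flat_spectrum_share(self):
        x = make_probe_signal([], 1.0, self.fs, 64.0, seed=3)
        oi4 = organization_index(x, self.fs, n_peaks=4)
        # flat-spectrum accounting at the Welch bin width: 4 windows of
        # (2*floor(hw/bin)+1) bins out of the band's bins
        nper = 1024
        bin_w = self.fs / nper
        f = np.arange(nper // 2 + 1) * bin_w
        band = (f >= 0.5) & (f <= 30.0)
        per_window = 2 * int(0.5 / bin_w) + 1
        expected = 4 * per_window / band.sum()
        assert oi4 == pytest.approx(expected, abs=0.05)

    def test_oi_invariant_to_amplitude_scaling(self):
        x = make_probe_signal([(5.0, 1.0), (9.0, 0.5)], 0.1, self.fs, 32.0,
                              seed=4)
        a = organization_index(x, self.fs, n_peaks=4)
        b = organization_index(123.0 * x, self.fs, n_peaks=4)
        assert a == pytest.approx(b, rel=1e-9)


class TestTrajectory:
    def circular_track(self, r=1.2, f=4.0, T=3000.0, center=(3.0, 3.0)):
        t = np.arange(0.0, T, 1.0)
        ang = 2 * np.pi * f * t / 1000.0
        xy = np.column_stack([center[0] + r * np.cos(ang),
                              center[1] + r * np.sin(ang)])
        return TipTrack(id=0, t=t, xy=xy)

    def test_circle_diameter(self):
        tr = self.circular_track(r=1.2)
        assert max_distance(tr, discard_initial=1000.0) == \
            pytest.approx(2.4, abs=0.01)

    def test_repeated_point_gives_zero(self):
        tr = TipTrack(id=0, t=np.arange(2000.0),
                      xy=np.tile([1.0, 2.0], (2000, 1)))
        assert max_distance(tr, discard_initial=1000.0) == 0.0

    def test_too_short_track_gives_null(self):
        tr = TipTrack(id=0, t=np.arange(500.0),
                      xy=np.random.default_rng(0).random((500, 2)))
        assert max_distance(tr, discard_initial=1000.0) is None

    def test_matches_brute_force_pairwise_oracle(self, rng):
        xy = rng.random((100, 2)) * 5.0
        tr = TipTrack(id=0, t=np.arange(100.0), xy=xy)
        got = max_distance(tr, discard_initial=0.0)
        brute = max(np.linalg.norm(a - b) for a, b in
                    itertools.combinations(xy, 2))
        assert got == brute

    def test_monotone_in_discard_window(self, rng):
        xy = np.cumsum(rng.standard_normal((300, 2)) * 0.05, axis=0)
        tr = TipTrack(id=0, t=np.arange(300.0), xy=xy)
        vals = [max_distance(tr, discard_initial=d) for d in (200, 100, 0)]
        assert vals[0] <= vals[1] <= vals[2]

    def test_winding_counts_rotations(self):
        tr = self.circular_track(f=4.0, T=1000.0)  # 4 turns
        assert track_winding(tr) == pytest.approx(8 * np.pi, rel=0.1)
        straight = TipTrack(id=1, t=np.arange(100.0),
                            xy=np.column_stack([np.linspace(0, 5, 100),
                                                np.ones(100)]))
        assert track_winding(straight) < 2 * np.pi


def surrogate_record(tracks, probe_fn, T=4000.0, fs=1000.0, s2=0.0,
                     reason="completed"):
    t = np.arange(0.0, T + 1.0)
    rec = SimulationRecord(probe_times=t, s1_time=0.0, s2_time=s2,
                           t_end=T, termination_reason=reason)
    for k in [f"probe_{i}" for i in range(21)] + [f"corner_{i}"
                                                  for i in range(4)]:
        rec.probes[k] = probe_fn(t)
    rec.probes["cv_a"] = probe_fn(t)
    rec.probes["cv_b"] = probe_fn(t)
    rec.probes["apd_mid"] = probe_fn(t)
    frames = {}
    for tr in tracks:
        for ti, xy in zip(tr.t, tr.xy):
            frames.setdefault(ti, []).append(xy)
    rec.tip_frames = [(ti, np.array(frames[ti])) for ti in sorted(frames)]
    rec.meta["params"] = {"u_c": 0.13}
    rec.meta["scheduled_T"] = T
    return rec


class TestClassification:
    cfg = AnalysisConfig()

    def make_circle(self, tid, T, f=4.0, r=0.8, center=(3.0, 3.0), t0=0.0):
        t = np.arange(t0, t0 + T, 1.0)
        ang = 2 * np.pi * f * t / 1000.0
        return TipTrack(id=tid, t=t,
                        xy=np.column_stack([center[0] + r * np.cos(ang),
                                            center[1] + r * np.sin(ang)]))

    @staticmethod
    def ap_like(t):
        return 0.5 * (1.0 + np.sin(2 * np.pi * 4.0 * t / 1000.0))

    def test_five_long_tips_classify_as_fibrillation(self):
        lifetimes = [60, 70, 80, 90, 100, 55]
        tracks = [TipTrack(id=i, t=np.arange(0.0, lt + 1),
                           xy=np.tile([1.0 + 0.3 * i, 1.0], (lt + 1, 1)))
                  for i, lt in enumerate(lifetimes)]
        rec = surrogate_record(tracks, self.ap_like, T=4000.0,
                               reason="died_out")
        assert classify_behavior(rec, 4000.0, self.cfg) is \
            BehaviorClass.FIBRILLATION

    def test_persistent_rotor_classifies_as_stable(self):
        rec = surrogate_record([self.make_circle(0, 4000.0)], self.ap_like)
        assert classify_behavior(rec, 4000.0, self.cfg) is \
            BehaviorClass.STABLE

    def test_four_long_tips_ending_early_classify_as_transient(self):
        tracks = [self.make_circle(i, 2000.0, center=(2.0 + 0.5 * i, 3.0))
                  for i in range(4)]
        rec = surrogate_record(tracks, self.ap_like, T=4000.0,
                               reason="died_out")
        rec.t_end = 2000.0
        assert classify_behavior(rec, 4000.0, self.cfg) is \
            BehaviorClass.TRANSIENT

    def test_silent_corner_probe_means_no_rotor(self):
        rec = surrogate_record([self.make_circle(0, 4000.0)], self.ap_like)
        rec.probes["corner_2"] = np.zeros_like(rec.probe_times)
        assert classify_behavior(rec, 4000.0, self.cfg) is \
            BehaviorClass.NO_ROTOR

    def test_incomplete_rotation_means_no_rotor(self):
        # a short arc: the tip never completes one rotation
        tr = self.make_circle(0, 100.0, f=1.0)
        rec = surrogate_record([tr], self.ap_like, reason="died_out")
        rec.t_end = 150.0
        assert classify_behavior(rec, 4000.0, self.cfg) is \
            BehaviorClass.NO_ROTOR

    def test_invalid_record_raises(self):
        rec = surrogate_record([self.make_circle(0, 1000.0)], self.ap_like)
        rec.valid = False
        with pytest.raises(ValueError):
            classify_behavior(rec, 4000.0, self.cfg)

    def test_merged_label(self):
        assert BehaviorClass.TRANSIENT.merged() is BehaviorClass.CHAOTIC
        assert BehaviorClass.FIBRILLATION.merged() is BehaviorClass.CHAOTIC
        assert BehaviorClass.STABLE.merged() is BehaviorClass.STABLE


class TestComputeBiomarkers:
    def test_stable_circular_surrogate_biomarkers(self):
        cfg = AnalysisConfig()
        grid = GridSpec(Lx=7.5, Ly=7.5, nx=64, ny=64)
        f = 4.0
        t_all = np.arange(0.0, 4001.0)
        track = TipTrack(
            id=0, t=t_all,
            xy=np.column_stack([3.0 + 1.1 * np.cos(2 * np.pi * f * t_all
                                                   / 1000.0),
                                3.0 + 1.1 * np.sin(2 * np.pi * f * t_all
                                                   / 1000.0)]))
        rec = surrogate_record([track], TestClassification.ap_like, T=4000.0)
        bm, label = compute_biomarkers(rec, grid, cfg, T=4000.0)
        assert label is BehaviorClass.STABLE
        assert bm.max_distance == pytest.approx(2.2, abs=0.02)
        assert bm.dominant_frequency == pytest.approx(f, abs=0.5)
        assert bm.oi1 is not None and bm.oi1 >= 0.9
        assert bm.oi4 is not None and bm.oi4 >= 0.8

    def test_broadband_fibrillation_less_organized_than_stable(self, rng):
        cfg = AnalysisConfig()
        grid = GridSpec(Lx=7.5, Ly=7.5, nx=64, ny=64)
        tracks = [TipTrack(id=i, t=np.arange(0.0, 101.0),
                           xy=np.tile([1.0 + 0.4 * i, 2.0], (101, 1)))
                  for i in range(6)]

        def noisy(t):
            return 0.3 * (1 + np.sin(2 * np.pi * 5 * t / 1000.0)) \
                + rng.standard_normal(len(t))

        rec = surrogate_record(tracks, noisy, T=4000.0, reason="died_out")
        bm_f, label_f = compute_biomarkers(rec, grid, cfg, T=4000.0)
        assert label_f is BehaviorClass.FIBRILLATION
        rec_s = surrogate_record(
            [TestClassification().make_circle(0, 4000.0)],
            TestClassification.ap_like, T=4000.0)
        bm_s, _ = compute_biomarkers(rec_s, grid, cfg, T=4000.0)
        assert bm_f.oi4 < bm_s.oi4
        # md and oi1 are defined for stable episodes only
        assert bm_f.max_distance is None and bm_f.oi1 is None

    def test_no_rotor_episode_keeps_only_tissue_biomarkers(
            self, smoke_episode_record):
        rec, grid, cfg = smoke_episode_record
        bm, label = compute_biomarkers(rec, grid, cfg.analysis)
        if label is BehaviorClass.NO_ROTOR:
            assert bm.dominant_frequency is None and bm.oi4 is None
            assert bm.max_distance is None and bm.oi1 is None
        assert bm.cv is not None and bm.apd is not None
        assert 10.0 < bm.cv < 80.0
        assert 30.0 < bm.apd < 400.0


class TestStableRotorEpisode:
    """Checks against one real simulated rotor that persists to the end."""

    def test_classified_stable_with_defined_biomarkers(
            self, stable_rotor_record):
        rec, grid, cfg = stable_rotor_record
        assert rec.termination_reason == "completed"
        bm, label = compute_biomarkers(rec, grid, cfg.analysis)
        assert label is BehaviorClass.STABLE
        assert bm.dominant_frequency is not None
        assert bm.oi4 is not None
        assert bm.max_distance is not None and bm.max_distance > 0.5

    def test_dominant_frequency_matches_cycle_counting(
            self, stable_rotor_record):
        # independent oracle: DF should equal the mean inter-AP rate at a
        # probe, counted from threshold crossings of the same trace
        rec, grid, cfg = stable_rotor_record
        bm, _ = compute_biomarkers(rec, grid, cfg.analysis)
        sel = rec.probe_times >= rec.s2_time
        x = rec.probes["probe_10"][sel]
        t = rec.probe_times[sel]
        up = np.nonzero((x[:-1] < 0.5) & (x[1:] >= 0.5))[0]
        assert len(up) >= 5
        rate = 1000.0 / np.mean(np.diff(t[up]))
        assert bm.dominant_frequency == pytest.approx(rate, abs=0.75)
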