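import logging

import numpy as np
import pytest

import beeland as bl
from beeland.segment_detection import monotone_selections


def _hybrid_kt(cfg, seed, sigma=1e-4, **kw):
    # idealized bouts-plus-transitions geometry: a small 5% lead-in only
    K = kw.get("n_bouts", 2)
    params = dict(strategy="hybrid", y0=0.3, V0=0.3, r_set=1.5, c=-0.87,
                  n_bouts=K, bout_fraction=0.7 / K,
                  transition_fraction=0.25 / max(K - 1, 1))
    params.update(kw)
    tr, anns = bl.simulate_hybrid(bl.StrategyParams(**params), f"h{seed}")
    noisy = bl.add_tracking_noise(tr, sigma, seed)
    return bl.compute_state_variables(noisy, cfg), anns


class TestDetect:
    def test_clean_constant_r_yields_one_full_segment(self, const_r_kt):
        segs = bl.detect_constant_r_segments(const_r_kt, 1.0)
        assert len(segs) == 1
        phase, = bl.deceleration_phases(const_r_kt)
        covered = segs[0].n_samples / (phase[1] - phase[0] + 1)
        assert covered >= 0.95
        assert 1.99 <= segs[0].r_star <= 2.01
        assert segs[0].dy1 > 0

    def test_two_bout_track_yields_two_clean_segments(self, cfg):
        kt, anns = _hybrid_kt(cfg, seed=3)
        segs = bl.detect_constant_r_segments(kt, 1.0)
        assert len(segs) == 2
        for seg, ann in zip(segs, anns):
            assert seg.r_star == pytest.approx(ann.r_set, rel=0.05)
        # the transition between the bouts stays uncovered
        assert segs[0].i_end < anns[0].i_end + 5
        assert segs[1].i_start > anns[1].i_start - 5

    def test_constant_taudot_track_has_low_coverage(self, taudot_kt):
        """r drifts continuously on a constant-tau-dot track; at f = 0.25
        almost no window passes the admissibility rule."""
        segs = bl.detect_constant_r_segments(
            taudot_kt, 0.25)
        phases = bl.deceleration_phases(taudot_kt)
        total = sum(b - a + 1 for a, b in phases)
        assert bl.covered_samples(segs) <= 0.2 * total

    def test_invalid_f_rejected(self, const_r_kt):
        with pytest.raises(bl.ParameterError):
            bl.detect_constant_r_segments(const_r_kt, -1.0)

    def test_detection_is_deterministic(self, cfg):
        kt, _ = _hybrid_kt(cfg, seed=9, sigma=2e-4)
        a = bl.detect_constant_r_segments(kt, 1.0)
        b = bl.detect_constant_r_segments(kt, 1.0)
        assert [(s.i_start, s.i_end, s.r_star) for s in a] == \
               [(s.i_start, s.i_end, s.r_star) for s in b]

    def test_segments_never_overlap_and_stay_in_phases(self, small_kts):
        for kt in small_kts:
            segs = bl.detect_constant_r_segments(kt, 1.0)
            phases = bl.deceleration_phases(kt)
            prev_end = -1
            for s in segs:
                assert s.i_start > prev_end
                prev_end = s.i_end
                assert any(a <= s.i_start and s.i_end <= b for a, b in phases)
                assert s.residual <= 1.0 * kt.config.tol_r / np.sqrt(3) + 1e-12


class TestBruteForce:
    def test_constant_r_identical_between_methods(self, const_r_kt):
        g = bl.detect_constant_r_segments(const_r_kt, 1.0)
        b = bl.brute_force_segments(const_r_kt, 1.0)
        assert [(s.i_start, s.i_end) for s in g] == \
               [(s.i_start, s.i_end) for s in b]

    def test_no_deceleration_gives_empty_both_ways(self, cfg):
        t = np.arange(300) / 200.0
        y = 0.5 - 0.05 * t - 0.05 * t ** 2
        tr = bl.RawTrack("acc", t=t, x=np.zeros_like(t), y=y,
                         z=np.zeros_like(t))
        kt = bl.compute_state_variables(tr, cfg)
        assert bl.detect_constant_r_segments(kt, 1.0) == []
        assert bl.brute_force_segments(kt, 1.0) == []

    def test_overlong_track_refused(self, cfg):
        n = 2500
        t = np.arange(n) / 200.0
        tr = bl.RawTrack("long", t=t, x=np.zeros(n),
                         y=0.4 * np.exp(-0.4 * t), z=np.zeros(n))
        kt = bl.compute_state_variables(tr, cfg)
        with pytest.raises(bl.TrackTooLongError):
            bl.brute_force_segments(kt)

    def test_greedy_close_to_optimal_coverage(self, cfg):
        """Greedy selection recovers nearly the brute-force maximum
        admissible coverage over random noisy hybrid tracks."""
        rng = np.random.default_rng(12)
        g_tot = b_tot = 0
        for k in range(25):
            kt, _ = _hybrid_kt(cfg, seed=int(rng.integers(2 ** 31)),
                               sigma=2e-4,
                               n_bouts=int(rng.integers(2, 4)),
                               y0=float(rng.uniform(0.25, 0.41)),
                               r_set=float(rng.uniform(0.8, 2.0)))
            g = bl.covered_samples(bl.detect_constant_r_segments(kt, 1.0))
            b = bl.covered_samples(bl.brute_force_segments(kt, 1.0))
            assert g <= b + 1e-9
            if b:
                assert g / b >= 0.8
            g_tot += g
            b_tot += b
        assert g_tot / b_tot >= 0.9


class TestSweep:
    def test_sweep_table_and_monotone_coverage(self, small_kts):
        grid = [0.25, 0.5, 1.0, 1.5, 2.0, 2.5]
        tab = bl.sweep_f(small_kts, grid)
        assert len(tab) == 6
        assert list(tab.f) == grid
        assert (tab.coverage_fraction.diff().dropna() >= -1e-12).all()
        assert (tab.n_tracks_with_segments.diff().dropna() >= 0).all()

    def test_per_track_covered_samples_nondecreasing(self, small_kts):
        grid = [0.25, 0.5, 1.0, 1.5, 2.0, 2.5]
        for kt in small_kts:
            sel = monotone_selections(kt, grid)
            cov = [bl.covered_samples(sel[f]) for f in grid]
            assert all(b >= a for a, b in zip(cov, cov[1:]))

    def test_single_f_equals_direct_detection(self, small_kts):
        tab = bl.sweep_f(small_kts, [1.0])
        direct = [s for kt in small_kts
                  for s in bl.detect_constant_r_segments(kt, 1.0)]
        assert tab.n_segments.iloc[0] == len(direct)

    def test_duplicate_f_values_collapsed_with_warning(self, small_kts, caplog):
        with caplog.at_level(logging.WARNING, logger="beeland"):
            tab = bl.sweep_f(small_kts[:2], [1.0, 1.0, 2.0])
        assert len(tab) == 2
        assert any("duplicate" in r.message for r in caplog.records)


class TestPairs:
    def test_adjacent_segments_pair_up(self, cfg):
        kt, anns = _hybrid_kt(cfg, seed=3)
        segs = bl.detect_constant_r_segments(kt, 1.0)
        pairs = bl.pair_consecutive_segments(kt, segs)
        assert len(pairs) == len(segs) - 1
        p = pairs[0]
        assert p.second.i_start > p.first.i_end
        assert p.dr_star == pytest.approx(
            anns[1].r_set - anns[0].r_set, rel=0.1)
        assert p.dy2 >= p.first.dy1 + p.second.dy1

    def test_single_segment_yields_no_pairs(self, const_r_kt):
        segs = bl.detect_constant_r_segments(const_r_kt, 1.0)
        assert bl.pair_consecutive_segments(const_r_kt, segs) == []

    def test_three_bout_pair_displacements_match_annotations(self, cfg):
        kt, anns = _hybrid_kt(cfg, seed=21, sigma=5e-5, n_bouts=3,
                              bout_fraction=0.15, transition_fraction=0.18,
                              y0=0.38, r_set=1.0, c=-0.75)
        segs = bl.detect_constant_r_segments(kt, 1.0)
        pairs = bl.pair_consecutive_segments(kt, segs)
        assert len(pairs) == 2
        for p, (a, b) in zip(pairs, [(0, 1), (1, 2)]):
            dy2_ann = anns[a].y_start - anns[b].y_end
            assert p.dy2 == pytest.approx(dy2_ann, rel=0.1)
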