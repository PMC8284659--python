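import itertools
import math

import numpy as np
import pytest

import cometkit as ck
from cometkit.evaluate import match_2d_tracks, apparent_peak_offset_um
from cometkit.tracking import TrackingParams, _classify_step
from conftest import make_comets


def _line(f, speed=7.0, x0=10.0, y0=20.0):
    return np.array([[x0 + speed * f, y0]])


class TestDetectParticles:
    def test_blank_frame_empty(self):
        assert len(ck.detect_particles(ck.Image2D(np.full((40, 40), 5.0), 0.1))) == 0

    def test_noiseless_comets_near_tips(self, clean_config, straight_trace):
        # short-tailed comets: the apparent peak sits within a pixel of the tip
        clean_config.comet_tail_length_um = 0.5
        truth = [6.0, 14.0, 22.0]
        img = ck.render_still(straight_trace,
                              make_comets(truth, tail_um=0.5), 1.0, clean_config)
        det = ck.detect_particles(img)
        assert len(det) == 3
        for s, (x, y, _) in zip(truth, det):
            tip = straight_trace.point_at_arclength_um(s)
            assert np.hypot(x - tip[0], y - tip[1]) <= 1.0

    def test_apparent_peak_localisation(self, clean_config, straight_trace):
        # longer tails shift the apparent peak; localisation still matches it
        img = ck.render_still(straight_trace, make_comets([15.0]), 1.0,
                              clean_config)
        det = ck.detect_particles(img)
        off = apparent_peak_offset_um(clean_config) / clean_config.pixel_size_um
        tip = straight_trace.point_at_arclength_um(15.0)
        assert len(det) == 1
        assert abs(det[0, 0] - (tip[0] - off)) <= 1.0

    def test_deterministic(self, clean_config, straight_trace):
        img = ck.render_still(straight_trace, make_comets([8.0, 20.0]), 1.0,
                              clean_config)
        d1, d2 = ck.detect_particles(img), ck.detect_particles(img)
        np.testing.assert_array_equal(d1, d2)


class TestGapSemantics:
    def test_eight_frame_gap_merges(self):
        det = [(f, _line(f)) for f in [*range(0, 5), *range(13, 18)]]
        tracks = ck.link_tracks(det)
        assert len(tracks) == 1
        assert tracks[0].gap_frames == 8

    def test_nine_frame_gap_splits(self):
        det = [(f, _line(f)) for f in [*range(0, 5), *range(14, 19)]]
        tracks = ck.link_tracks(det)
        assert len(tracks) == 2

    def test_two_frame_particle_discarded(self):
        det = [(f, _line(f)) for f in range(2)]
        assert ck.link_tracks(det) == []

    def test_unsorted_frames_rejected(self):
        det = [(1, _line(1)), (0, _line(0))]
        with pytest.raises(ValueError, match="increasing"):
            ck.link_tracks(det)


class TestConstraints:
    def test_every_emitted_track_passes_checker(self, snr5):
        for seed in (0, 1):
            cfg = snr5(ck.SimConfig(axon_length_um=40.0, frame_interval_s=2.0,
                                    n_frames=30, comet_velocity_um_s=0.4,
                                    comet_lifetime_mean_s=16.0,
                                    comet_nucleation_rate_per_um_min=0.4,
                                    rng_seed=seed, lattice_intensity=0.0))
            trace, _ = ck.simulate_axon_trace(cfg)
            stack, _ = ck.simulate_comet_movie(trace, cfg)
            dets = [ck.detect_particles(stack.frame(t))[:, :2]
                    for t in range(stack.n_frames)]
            for tr in ck.link_tracks(dets, pixel_size_um=cfg.pixel_size_um):
                assert ck.check_track_constraints(tr) == []

    def test_checker_flags_oversized_gap(self):
        tr = ck.Track(points=[(0, 0.0, 0.0), (1, 7.0, 0.0), (12, 80.0, 0.0)])
        msgs = ck.check_track_constraints(tr)
        assert any("gap" in m for m in msgs)

    def test_step_classification(self):
        p = TrackingParams()
        heading = np.array([1.0, 0.0])
        assert _classify_step(heading, 7.0, np.array([1.0, 0.5]), p) == "pause"
        assert _classify_step(heading, 7.0, np.array([7.0, 1.0]), p) == "forward"
        assert _classify_step(heading, 10.0, np.array([-7.0, 0.2]), p) == "backward"
        assert _classify_step(heading, 7.0, np.array([-7.0, 0.2]), p) is None
        assert _classify_step(heading, 7.0, np.array([0.0, 7.0]), p) is None
        assert _classify_step(heading, 7.0, np.array([20.0, 0.0]), p) is None


class TestPartitionProperties:
    def test_rotation_invariance(self):
        rng = np.random.default_rng(3)
        frames = []
        for f in range(6):
            pts = np.stack([10 + 7 * f + rng.normal(0, 0.3, 3),
                            np.array([10.0, 40.0, 70.0])], axis=1)
            frames.append(pts)
        rot = np.array([[0.0, -1.0], [1.0, 0.0]])
        base = ck.link_tracks([p.copy() for p in frames])
        rotated = ck.link_tracks([p @ rot.T for p in frames])
        sig = lambda tracks: sorted(tuple(p[0] for p in t.points) for t in tracks)
        assert sig(base) == sig(rotated)

    def test_gap_parameter_monotonicity(self):
        # frames 0-3 then 6-9: two missing frames in between
        det = [(f, _line(f)) for f in [*range(0, 4), *range(6, 10)]]
        n_merged = lambda gap: len(ck.link_tracks(
            det, TrackingParams(max_gap_frames=gap)))
        assert n_merged(1) == 2
        assert n_merged(2) == 1
        assert n_merged(8) == 1

    def test_min_track_frames_monotonicity(self):
        det = [(f, _line(f)) for f in range(4)]
        n = lambda mtf: len(ck.link_tracks(
            det, TrackingParams(min_track_frames=mtf)))
        assert n(5) == 0 and n(4) == 1 and n(2) == 1


def _oracle_link(frames, params):
    """Exhaustive minimum-cost enumeration of feasible frame-to-frame
    matchings (maximum links first, then minimal summed displacement)."""
    n_frames = len(frames)

    def all_matchings(na, nb):
        for k in range(min(na, nb) + 1):
            for rows in itertools.combinations(range(na), k):
                for cols in itertools.permutations(range(nb), k):
                    yield dict(zip(rows, cols))

    def fresh(f, j):
        return {"pts": [(f, float(frames[f][j][0]), float(frames[f][j][1]))],
                "heading": None, "fwd": []}

    choices = [list(all_matchings(len(frames[i]), len(frames[i + 1])))
               for i in range(n_frames - 1)]
    best = None
    for combo in itertools.product(*choices):
        tracks = []
        open_by_idx = {j: fresh(0, j) for j in range(len(frames[0]))}
        feasible = True
        cost, n_links = 0.0, 0
        for f in range(n_frames - 1):
            matching = combo[f]
            next_open = {}
            for i, tr in open_by_idx.items():
                j = matching.get(i)
                if j is None:
                    tracks.append(tr)
                    continue
                disp = np.asarray(frames[f + 1][j][:2]) - \
                    np.asarray(tr["pts"][-1][1:])
                mean_fwd = float(np.mean(tr["fwd"])) if tr["fwd"] else None
                kind = _classify_step(tr["heading"], mean_fwd, disp, params)
                if kind is None:
                    feasible = False
                    break
                d = float(np.linalg.norm(disp))
                cost += d
                n_links += 1
                tr = {"pts": tr["pts"] + [(f + 1, float(frames[f + 1][j][0]),
                                           float(frames[f + 1][j][1]))],
                      "heading": (disp / d if kind == "forward" and d > 0
                                  else tr["heading"]),
                      "fwd": tr["fwd"] + [d] if kind == "forward" else tr["fwd"]}
                next_open[j] = tr
            if not feasible:
                break
            for j in range(len(frames[f + 1])):
                if j not in next_open:
                    next_open[j] = fresh(f + 1, j)
            open_by_idx = next_open
        if not feasible:
            continue
        tracks.extend(open_by_idx.values())
        final = sorted(tuple(tr["pts"]) for tr in tracks
                       if len(tr["pts"]) >= params.min_track_frames)
        key = (-n_links, cost)
        if best is None or key < best[0]:
            best = (key, final)
    return best[1] if best else []


class TestOracleEquivalence:
    @pytest.mark.parametrize("seed", range(5))
    def test_matches_exhaustive_enumeration(self, seed):
        # small instances: 2 lanes of straight movers with jitter, no gaps
        rng = np.random.default_rng(seed)
        params = TrackingParams(min_track_frames=3)
        n_frames = rng.integers(4, 6)
        lanes = [(10.0, 10.0), (15.0, 24.0)]
        frames = []
        for f in range(n_frames):
            pts = [[x0 + 7.5 * f + rng.normal(0, 0.4), y0 + rng.normal(0, 0.4)]
                   for x0, y0 in lanes]
            frames.append(np.asarray(pts))
        ours = sorted(tuple(p for p in t.points)
                      for t in ck.link_tracks(frames, params))
        oracle = _oracle_link(frames, params)
        assert _rounded(ours) == _rounded(oracle)


def _rounded(partition):
    return [tuple((f, round(x, 6), round(y, 6)) for f, x, y in tr)
            for tr in partition]


class TestTrackSummary:
    def test_single_track_velocity(self):
        pts = [(f, 1.0 * f, 0.0) for f in range(5)]
        tracks = ck.link_tracks([np.array([[1.0 * f, 0.0]]) for f in range(5)],
                                TrackingParams(fluctuation_radius_px=2.5))
        s = ck.track_summary(tracks, pixel_size_um=0.1)
        assert s.n_tracks == 1
        assert s.median_velocity_um_s == pytest.approx(0.05)
        assert s.median_lifetime_s == pytest.approx(8.0)

    def test_empty(self):
        s = ck.track_summary([], pixel_size_um=0.1)
        assert s.n_tracks == 0 and s.median_velocity_um_s is None

    def test_recovered_lifetimes_within_one_frame(self, snr5):
        cfg = snr5(ck.SimConfig(axon_length_um=40.0, frame_interval_s=2.0,
                                n_frames=30, comet_velocity_um_s=0.4,
                                comet_lifetime_mean_s=20.0,
                                comet_nucleation_rate_per_um_min=0.3,
                                rng_seed=4, lattice_intensity=0.0))
        trace, _ = ck.simulate_axon_trace(cfg)
        stack, truth = ck.simulate_comet_movie(trace, cfg)
        dets = [ck.detect_particles(stack.frame(t))[:, :2]
                for t in range(stack.n_frames)]
        tracks = ck.link_tracks(dets, pixel_size_um=cfg.pixel_size_um)
        off = apparent_peak_offset_um(cfg)

        def truth_xy(g, t_s):
            if not (g.birth_time_s <= t_s <= g.death_time_s):
                return None
            s = g.position_um(t_s) - off
            if not (0 <= s <= trace.arclength_um):
                return None
            return trace.point_at_arclength_um(s)

        matches = match_2d_tracks(tracks, truth, truth_xy, cfg.frame_interval_s)
        assert matches
        errs = []
        for m in matches:
            dt = cfg.frame_interval_s
            first = math.ceil(m.truth.birth_time_s / dt)
            last = math.floor(min(m.truth.death_time_s,
                                  (cfg.n_frames - 1) * dt) / dt - 1e-9)
            errs.append(abs(m.track.lifetime_s - (last - first) * dt))
        assert np.median(errs) <= cfg.frame_interval_s
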