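"""Linking, speeds, ensemble MSD, power-law fits and morphology binning."""

import itertools

import numpy as np
import pandas as pd
import pytest

from monolayer_mech.synthgen import gen_tracks
from monolayer_mech.tracking import (
    LinkConfig,
    MsdCurve,
    Track,
    bin_and_fit,
    ensemble_msd,
    fit_power_law,
    link,
    mean_speed,
)


def detections_from_positions(positions_by_frame):
    rows = []
    for f, pts in enumerate(positions_by_frame):
        for x, y in pts:
            rows.append((f, x, y))
    return pd.DataFrame(rows, columns=["frame", "x_um", "y_um"])


class TestLink:
    def test_two_stationary_points(self):
        df = detections_from_positions([[(0, 0), (20, 0)]] * 10)
        tracks = link(df, LinkConfig(4.6, 4, 5))
        assert len(tracks) == 2 and all(len(t) == 10 for t in tracks)

    def test_gap_within_memory_bridged(self):
        frames = [[(0.0, 0.0)] if f not in (3, 4, 5) else [] for f in range(10)]
        tracks = link(detections_from_positions(frames), LinkConfig(4.6, 4, 5))
        assert len(tracks) == 1 and len(tracks[0]) == 7

    def test_gap_beyond_memory_splits(self):
        frames = [[(0.0, 0.0)] if f not in range(3, 8) else [] for f in range(16)]
        tracks = link(detections_from_positions(frames), LinkConfig(4.6, 4, 3))
        assert len(tracks) == 2

    def test_min_length_filter(self):
        # a 10-frame walker plus a planted 3-frame spur far away
        frames = [[(0.0, 0.0)] for _ in range(10)]
        for f in range(3):
            frames[f].append((500.0, 500.0))
        tracks = link(detections_from_positions(frames), LinkConfig(4.6, 0, 5))
        assert len(tracks) == 1 and len(tracks[0]) == 10

    def test_permutation_invariance_within_frame(self):
        rng = np.random.default_rng(3)
        pos = rng.uniform(0, 100, size=(8, 2))
        frames = [
            [tuple(p) for p in pos + f * np.array([0.5, 0.0])] for f in range(6)
        ]
        df1 = detections_from_positions(frames)
        shuffled = [list(fr) for fr in frames]
        for fr in shuffled:
            rng.shuffle(fr)
        df2 = detections_from_positions(shuffled)
        t1 = sorted(link(df1, LinkConfig(5, 0, 5)), key=lambda t: tuple(t.xy[0]))
        t2 = sorted(link(df2, LinkConfig(5, 0, 5)), key=lambda t: tuple(t.xy[0]))
        assert len(t1) == len(t2) == 8
        for a, b in zip(t1, t2):
            assert np.allclose(a.xy, b.xy)

    def test_links_match_exhaustive_assignment_oracle(self):
        # 6 walkers: compare each frame-pair matching against brute-force
        # minimal-cost assignment by permutation enumeration
        rng = np.random.default_rng(7)
        n, nf = 6, 8
        pos = rng.uniform(0, 60, size=(n, 2))
        traj = [pos]
        for _ in range(nf - 1):
            traj.append(traj[-1] + rng.normal(0, 0.8, size=(n, 2)))
        tracks = link(
            detections_from_positions([[tuple(p) for p in fr] for fr in traj]),
            LinkConfig(5.0, 0, 2),
        )
        assert len(tracks) == n
        got_pairs = set()
        for t in tracks:
            for k in range(len(t) - 1):
                got_pairs.add((t.frames[k], tuple(t.xy[k]), tuple(t.xy[k + 1])))
        for f in range(nf - 1):
            a, b = traj[f], traj[f + 1]
            best = min(
                itertools.permutations(range(n)),
                key=lambda p: sum(np.sum((a[i] - b[p[i]]) ** 2) for i in range(n)),
            )
            for i in range(n):
                assert (f, tuple(a[i]), tuple(b[best[i]])) in got_pairs

    def test_ground_truth_links_recovered_for_separated_walkers(self):
        # 50 walkers, mean spacing >> step: >= 99% of true links recovered
        df, _ = gen_tracks(n=50, n_frames=40, dt_min=1.0, model="brownian",
                           D_um2_per_min=0.125, box_um=700.0, seed=0)
        # step sd = sqrt(2*0.125) = 0.5 µm; spacing ~ 100 µm
        tracks = link(df, LinkConfig(5.0, 4, 5), dt_min=1.0)
        truth = {
            (int(r.frame), float(r.x_um), float(r.y_um)): int(r.cell_id)
            for r in df.itertuples()
        }
        correct = total = 0
        for t in tracks:
            for k in range(len(t) - 1):
                i = truth[(int(t.frames[k]), float(t.xy[k][0]), float(t.xy[k][1]))]
                j = truth[(int(t.frames[k + 1]), float(t.xy[k + 1][0]), float(t.xy[k + 1][1]))]
                total += 1
                correct += i == j
        assert total >= 50 * 39 * 0.99
        assert correct / total >= 0.99


class TestMeanSpeed:
    def test_straight_line(self):
        t = Track(0, np.arange(10), np.column_stack([np.arange(10.0), np.zeros(10)]),
                  dt_min=6.0)
        assert mean_speed(t) == pytest.approx(10.0)  # 1 µm / 6 min = 10 µm/h

    def test_stationary(self):
        t = Track(0, np.arange(5), np.zeros((5, 2)), dt_min=6.0)
        assert mean_speed(t) == 0.0

    def test_zigzag_speed_ignores_direction(self):
        xy = np.array([[0, 0], [1, 0], [1, 1], [2, 1], [2, 2]], float)
        t = Track(0, np.arange(5), xy, dt_min=6.0)
        assert mean_speed(t) == pytest.approx(10.0)

    def test_single_point_raises(self):
        t = Track(0, np.array([0]), np.zeros((1, 2)), dt_min=6.0)
        with pytest.raises(ValueError):
            mean_speed(t)


class TestEnsembleMsd:
    def test_single_ballistic_track_closed_form(self):
        frames = np.arange(30)
        xy = np.column_stack([frames * 1.0, np.zeros(30)])  # 1 µm / 6 min = 10 µm/h
        curve = ensemble_msd([Track(0, frames, xy, dt_min=6.0)])
        tau_h = curve.lag_min / 60.0
        assert np.allclose(curve.msd_um2, 100.0 * tau_h**2)

    def test_stationary_identically_zero(self):
        t = Track(0, np.arange(10), np.zeros((10, 2)), dt_min=6.0)
        curve = ensemble_msd([t])
        assert np.all(curve.msd_um2 == 0.0)

    def test_msd_zero_at_lag_zero_and_nobs_nonincreasing(self):
        df, _ = gen_tracks(n=10, n_frames=30, model="brownian", seed=2)
        tracks = link(df, LinkConfig(50, 0, 5))
        curve = ensemble_msd(tracks)
        assert curve.lag_min[0] == 0.0 and curve.msd_um2[0] == 0.0
        assert np.all(np.diff(curve.n_obs) <= 0)

    def test_union_equals_weighted_average(self):
        df1, _ = gen_tracks(n=5, n_frames=20, model="brownian", seed=3)
        df2, _ = gen_tracks(n=7, n_frames=20, model="brownian", seed=4)
        t1 = link(df1, LinkConfig(50, 0, 5))
        t2 = link(df2, LinkConfig(50, 0, 5))
        c1, c2 = ensemble_msd(t1), ensemble_msd(t2)
        cu = ensemble_msd(t1 + t2)
        merged = (c1.msd_um2 * c1.n_obs + c2.msd_um2 * c2.n_obs) / (c1.n_obs + c2.n_obs)
        assert np.allclose(cu.msd_um2[1:], merged[1:])

    def test_brownian_matches_4dtau(self):
        df, _ = gen_tracks(n=200, n_frames=100, dt_min=1.0, model="brownian",
                           D_um2_per_min=1.0, box_um=20000.0, seed=5)
        tracks = link(df, LinkConfig(20, 0, 5), dt_min=1.0)
        curve = ensemble_msd(tracks, max_lag=20)
        sel = curve.lag_min > 0
        assert np.allclose(curve.msd_um2[sel], 4.0 * curve.lag_min[sel], rtol=0.10)


class TestPowerLawFit:
    def test_exact_power_law_machine_precision(self):
        lag = np.arange(0.0, 30.0)
        curve = MsdCurve(lag, 2.0 * lag**1.5, np.ones_like(lag))
        fit = fit_power_law(curve, (0.0, 30.0))
        assert fit.a_um2 == pytest.approx(2.0, rel=1e-12)
        assert fit.n == pytest.approx(1.5, rel=1e-12)

    def test_ballistic_exponent_two(self):
        frames = np.arange(60)
        xy = np.column_stack([frames * 0.7, np.zeros(60)])
        fit = fit_power_law(ensemble_msd([Track(0, frames, xy, dt_min=6.0)]), (0, 120))
        assert fit.n == pytest.approx(2.0, abs=0.01)

    def test_nonpositive_points_excluded_then_error(self):
        lag = np.array([0.0, 1.0, 2.0, 3.0])
        curve = MsdCurve(lag, np.array([0.0, 0.0, 0.0, 1.0]), np.ones(4))
        with pytest.raises(ValueError):
            fit_power_law(curve, (0.0, 3.0))


class TestBinAndFit:
    def _mixed_population(self):
        small, _ = gen_tracks(n=40, n_frames=60, dt_min=6.0, model="brownian",
                              D_um2_per_min=0.2, box_um=5000, seed=10,
                              areas_um2=np.full(40, 50.0))
        large, _ = gen_tracks(n=40, n_frames=60, dt_min=6.0, model="ballistic",
                              v_um_per_h=15.0, box_um=5000, seed=11,
                              areas_um2=np.full(40, 250.0))
        large["cell_id"] += 1000
        df = pd.concat([small, large], ignore_index=True)
        return link(df, LinkConfig(30.0, 0, 5), dt_min=6.0)

    def test_subpopulations_separated_by_area_bin(self):
        res = bin_and_fit(self._mixed_population(), "area_um2", 100.0,
                          fit_window_min=(0.0, 120.0))
        assert set(res) == {0, 2}
        assert res[0]["n"] == pytest.approx(1.0, abs=0.15)
        assert res[2]["n"] == pytest.approx(2.0, abs=0.05)
        assert res[2]["msd_at"] > res[0]["msd_at"]

    def test_identical_attribute_single_bin_equals_global(self):
        df, _ = gen_tracks(n=10, n_frames=30, dt_min=6.0, model="brownian", seed=1,
                           areas_um2=np.full(10, 120.0))
        tracks = link(df, LinkConfig(50, 0, 5), dt_min=6.0)
        res = bin_and_fit(tracks, "area_um2", 100.0, fit_window_min=(0, 120))
        assert list(res) == [1]
        glob = fit_power_law(ensemble_msd(tracks), (0, 120))
        assert res[1]["n"] == pytest.approx(glob.n, rel=1e-9)

    def test_edge_value_goes_to_upper_bin(self):
        df, _ = gen_tracks(n=4, n_frames=20, dt_min=6.0, model="brownian", seed=2,
                           areas_um2=np.full(4, 100.0))
        tracks = link(df, LinkConfig(50, 0, 5), dt_min=6.0)
        res = bin_and_fit(tracks, "area_um2", 100.0, fit_window_min=(0, 120))
        assert list(res) == [1]

    def test_missing_attribute_raises(self):
        df, _ = gen_tracks(n=4, n_frames=20, model="brownian", seed=3)
        tracks = link(df, LinkConfig(50, 0, 5))
        with pytest.raises(KeyError):
            bin_and_fit(tracks, "area_um2")
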