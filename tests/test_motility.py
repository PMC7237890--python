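import numpy as np
import pandas as pd
import pytest

from perivax.motility import (cohort_summary, displacement_curve,
                              metrics_from_arrays, track_metrics)


def _table(tracks, dt=30.0, animal=None):
    rows = []
    for cid, xy in enumerate(tracks):
        for f, (x, y) in enumerate(xy):
            rows.append({"cell_id": cid, "frame": f, "t_s": f * dt,
                         "x_um": x, "y_um": y})
    df = pd.DataFrame(rows)
    if animal is not None:
        df["animal"] = [animal[cid] for cid in df.cell_id]
    return df


def test_collinear_track_arithmetic():
    m = metrics_from_arrays(np.array([0.0, 30.0, 60.0]),
                            np.array([[0, 0], [10, 0], [20, 0.0]]))
    assert m["mean_velocity"] == pytest.approx(20.0)   # 20 µm in 1 min
    assert m["straightness"] == pytest.approx(1.0)


def test_closed_loop_zero_straightness():
    sq = np.array([[0, 0], [10, 0], [10, 10], [0, 10], [0, 0.0]])
    m = metrics_from_arrays(np.arange(5) * 60.0, sq)
    assert m["straightness"] == 0.0
    assert m["net_displacement"] == 0.0


def test_short_track_flagged_not_dropped():
    tab = _table([[(0, 0), (5, 0)]], dt=30.0)  # 0.5 min
    rec = track_metrics(tab, min_duration=10.0)
    assert len(rec) == 1 and bool(rec.excluded.iloc[0])


def test_random_walk_straightness_matches_monte_carlo_oracle():
    """E[straightness] of a 40-step isotropic Gaussian walk, implementation
    vs an independent vectorised Monte-Carlo estimate."""
    n_walks, n_steps, s = 100_000, 40, 3.0

    rng = np.random.default_rng(77)
    steps = rng.normal(0, s, (n_walks, n_steps, 2))
    xy = np.cumsum(steps, axis=1)
    net = np.linalg.norm(xy[:, -1], axis=1)
    path = np.linalg.norm(steps, axis=2).sum(axis=1)
    oracle = float((net / path).mean())

    rng2 = np.random.default_rng(78)
    sample = rng2.normal(0, s, (n_walks, n_steps, 2))
    vals = np.empty(n_walks)
    t = np.arange(n_steps + 1) * 30.0
    for i in range(n_walks):
        walk = np.vstack([[0.0, 0.0], np.cumsum(sample[i], axis=0)])
        vals[i] = metrics_from_arrays(t, walk)["straightness"]
    assert vals.mean() == pytest.approx(oracle, rel=0.01)


def test_velocity_time_reversal_invariant():
    rng = np.random.default_rng(5)
    xy = np.cumsum(rng.normal(0, 2, (20, 2)), axis=0)
    t = np.arange(20) * 20.0
    fwd = metrics_from_arrays(t, xy)
    rev = metrics_from_arrays(t, xy[::-1])
    assert fwd["mean_velocity"] == pytest.approx(rev["mean_velocity"])


class TestDisplacementCurve:
    def test_ballistic_curve_exact(self):
        v = 12.0  # µm/min, straight lines
        dt = 30.0
        tracks = [[(v * dt / 60.0 * f, cid * 100.0) for f in range(41)]
                  for cid in range(12)]
        curve = displacement_curve(_table(tracks, dt=dt), horizon=10.0)
        tau = curve.sqrt_t**2
        assert np.allclose(curve.mean_displacement, v * tau, rtol=1e-9)

    def test_stationary_curve_zero(self):
        tracks = [[(50.0, 50.0)] * 41 for _ in range(12)]
        curve = displacement_curve(_table(tracks), horizon=10.0)
        assert np.allclose(curve.mean_displacement, 0.0)
        assert curve.motility_coefficient == 0.0

    def test_no_spanning_track_raises(self):
        with pytest.raises(ValueError):
            displacement_curve(_table([[(0, 0), (1, 0)]]), horizon=10.0)

    def test_diffusive_slope_matches_oracle(self):
        """Slope of mean displacement vs sqrt(t) for Gaussian steps, against
        an independent Monte-Carlo estimate of the same functional."""
        s, dt, n_frames, n_tracks = 3.0, 30.0, 41, 400
        rng = np.random.default_rng(11)
        tracks = [np.vstack([[0, 0], np.cumsum(rng.normal(0, s, (n_frames - 1, 2)), axis=0)])
                  + rng.uniform(0, 500, 2) for _ in range(n_tracks)]
        curve = displacement_curve(_table([list(map(tuple, tr)) for tr in tracks],
                                          dt=dt), horizon=10.0)

        rng2 = np.random.default_rng(12)
        walks = np.cumsum(rng2.normal(0, s, (20_000, n_frames - 1, 2)), axis=1)
        walks = np.concatenate([np.zeros((20_000, 1, 2)), walks], axis=1)
        lags = np.arange(1, int(10.0 / (dt / 60.0)) + 1)
        sq, md = [0.0], [0.0]
        for lag in lags:
            d = np.linalg.norm(walks[:, lag:] - walks[:, :-lag], axis=2)
            sq.append(np.sqrt(lag * dt / 60.0))
            md.append(d.mean())
        sq, md = np.array(sq), np.array(md)
        slope_oracle = float((sq * md).sum() / (sq**2).sum())
        assert curve.motility_coefficient == pytest.approx(slope_oracle, rel=0.03)


class TestCohortSummary:
    def test_identical_records_zero_sd(self):
        rec = pd.DataFrame({"mean_velocity": [5.0] * 4, "straightness": [0.5] * 4,
                            "animal": ["m1"] * 4, "excluded": [False] * 4})
        summ = cohort_summary(rec)
        assert summ.set_index("metric").loc["mean_velocity", "sd"] == 0.0

    def test_two_group_arithmetic(self):
        rec = pd.DataFrame({"mean_velocity": [1.0, 3.0, 5.0],
                            "straightness": [0.1, 0.3, 0.5],
                            "animal": ["a", "a", "b"],
                            "excluded": [False] * 3})
        summ = cohort_summary(rec)
        per = summ.attrs["per_group"]
        assert per.loc["a", "mean_velocity"] == 2.0
        assert per.loc["b", "mean_velocity"] == 5.0
        assert summ.set_index("metric").loc["mean_velocity", "mean"] == 3.5

    def test_sem_shrinks_with_more_groups(self):
        rng = np.random.default_rng(3)

        def summ_for(n_groups):
            rec = pd.DataFrame({
                "mean_velocity": rng.normal(10, 1, n_groups * 30),
                "straightness": rng.uniform(0, 1, n_groups * 30),
                "animal": np.repeat([f"m{i}" for i in range(n_groups)], 30),
                "excluded": False,
            })
            return cohort_summary(rec).set_index("metric").loc["mean_velocity", "sem"]

        small = np.mean([summ_for(4) for _ in range(20)])
        large = np.mean([summ_for(16) for _ in range(20)])
        assert large < small / 1.5  # expected 1/2, allow Monte-Carlo slack
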