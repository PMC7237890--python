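import numpy as np
import pandas as pd
import pytest
from skimage.draw import disk

from perivax.detect import circularity, link_tracks, segment_frame, detect_stack
from perivax.render import render_stack
from perivax.agents import simulate_cohort
from perivax.motility import track_metrics
from perivax.scenarios import preset_cohort


def _disc_mask(r, shape=None, center=None):
    shape = shape or (2 * r + 21, 2 * r + 21)
    center = center or (shape[0] // 2, shape[1] // 2)
    m = np.zeros(shape, bool)
    rr, cc = disk(center, r + 0.5, shape=shape)
    m[rr, cc] = True
    return m


class TestSegmentFrame:
    def test_single_disc_detected_at_center(self):
        frame = np.zeros((100, 100))
        frame[_disc_mask(8, (100, 100), (40, 60))] = 100.0
        det = segment_frame(frame, pixel_size=1.0, min_area=10)
        assert len(det) == 1
        assert det.x_um.iloc[0] == pytest.approx(60.5, abs=0.5)
        assert det.y_um.iloc[0] == pytest.approx(40.5, abs=0.5)

    def test_blank_frame_no_detections(self):
        det = segment_frame(np.zeros((50, 50)), pixel_size=1.0)
        assert len(det) == 0

    def test_min_area_filter(self):
        frame = np.zeros((300, 300))
        centers = [(50, 50), (50, 150), (50, 250), (150, 50), (150, 150)]
        for c in centers:
            frame[_disc_mask(6, (300, 300), c)] = 100.0
        frame[_disc_mask(1, (300, 300), (250, 250))] = 100.0  # too small
        det = segment_frame(frame, pixel_size=1.0, min_area=20)
        assert len(det) == 5


class TestCircularity:
    def test_disc_is_circular(self):
        c = circularity(_disc_mask(30)).circularity
        assert c == pytest.approx(1.0, abs=0.05)

    def test_square_is_pi_over_4(self):
        m = np.zeros((50, 50), bool)
        m[10:40, 10:40] = True
        c = circularity(m).circularity
        assert c == pytest.approx(np.pi / 4, abs=0.05)

    def test_bar_less_circular_than_square_of_equal_area(self):
        bar = np.zeros((25, 120), bool)
        bar[10:15, 10:110] = True          # 100 x 5 = 500 px
        sq = np.zeros((43, 43), bool)
        side = int(round(np.sqrt(bar.sum())))
        sq[10:10 + side, 10:10 + side] = True
        assert circularity(bar).circularity < circularity(sq).circularity

    def test_empty_mask_raises(self):
        with pytest.raises(ValueError):
            circularity(np.zeros((10, 10), bool))

    def test_invariance_translation_rotation(self):
        m = np.zeros((80, 80), bool)
        m[20:50, 30:45] = True
        c0 = circularity(m).circularity
        assert circularity(np.roll(m, (7, -5), (0, 1))).circularity == \
               pytest.approx(c0, rel=0.01)
        assert circularity(np.rot90(m)).circularity == pytest.approx(c0, rel=0.01)

    def test_disc_error_stays_small_over_scales(self):
        errs = [abs(circularity(_disc_mask(r)).circularity - 1.0)
                for r in (10, 20, 40, 80)]
        assert max(errs) < 0.05
        assert errs[-1] < 0.02  # bias stays bounded at large radius

    def test_physical_units(self):
        m = _disc_mask(20)
        met = circularity(m, pixel_size=2.0)
        assert met.area == pytest.approx(m.sum() * 4.0)
        assert met.circularity == pytest.approx(circularity(m).circularity)


class TestLinkTracks:
    def _det(self, tracks):
        rows = []
        for f, pts in enumerate(tracks):
            for x, y in pts:
                rows.append((f, x, y, 30.0, 20.0))
        return pd.DataFrame(rows, columns=["frame", "x_um", "y_um",
                                           "area_um2", "perimeter_um"])

    def test_parallel_cells_no_swap(self):
        det = self._det([[(x, 100.0), (x, 200.0)] for x in np.arange(0, 50, 5.0)])
        linked = link_tracks(det, frame_interval=20.0, max_speed=60.0)
        assert linked.cell_id.nunique() == 2
        for _, g in linked.groupby("cell_id"):
            assert g.y_um.nunique() == 1

    def test_gap_spanning(self):
        pts = [[(x, 100.0)] for x in np.arange(0, 50, 5.0)]
        pts[4] = []  # missed detection
        linked = link_tracks(self._det(pts), frame_interval=20.0,
                             max_speed=60.0, max_gap=1)
        assert linked.cell_id.nunique() == 1
        assert linked.frame.tolist() == [0, 1, 2, 3, 5, 6, 7, 8, 9]

    def test_gap_beyond_max_terminates(self):
        pts = [[(x, 100.0)] for x in np.arange(0, 50, 5.0)]
        pts[4] = pts[5] = []
        linked = link_tracks(self._det(pts), frame_interval=20.0,
                             max_speed=60.0, max_gap=1)
        assert linked.cell_id.nunique() == 2


def test_linking_recovers_ground_truth(spread_geometry):
    """Noise-free render of a modest cohort: linked tracks match the
    simulator's ground truth with >= 99% frame-wise assignment accuracy."""
    cfg = preset_cohort("control", n_track_guided=40, seed=21, n_frames=25)
    tab = simulate_cohort(spread_geometry, cfg)
    stk = render_stack(tab, spread_geometry, noise_sd=0.0, texture_sd=0.0)
    det = detect_stack(stk)
    linked = link_tracks(det, stk.frame_interval)

    correct = total = 0
    for cid, g in tab.groupby("cell_id"):
        g = g.sort_values("frame")
        # the linked track claiming this cell: best overlap at frame 0
        f0 = g.iloc[0]
        cand = linked[linked.frame == f0.frame]
        if cand.empty:
            total += len(g)
            continue
        d0 = np.hypot(cand.x_um - f0.x_um, cand.y_um - f0.y_um)
        lid = cand.cell_id.iloc[int(np.argmin(d0))]
        lg = linked[linked.cell_id == lid].set_index("frame")
        for _, row in g.iterrows():
            total += 1
            if row.frame in lg.index:
                lr = lg.loc[row.frame]
                if np.hypot(lr.x_um - row.x_um, lr.y_um - row.y_um) < 4.0:
                    correct += 1
    assert correct / total >= 0.99


def test_detection_closes_speed_loop(spread_geometry):
    """Mean speed from detect+link on a rendered control cohort recovers the
    ground-truth mean speed within 10%."""
    cfg = preset_cohort("control", n_track_guided=60, seed=22, n_frames=40)
    tab = simulate_cohort(spread_geometry, cfg)
    stk = render_stack(tab, spread_geometry, seed=23)
    linked = link_tracks(detect_stack(stk), stk.frame_interval)
    rec = track_metrics(linked)
    got = rec[~rec.excluded].mean_velocity.mean()
    truth = track_metrics(tab).mean_velocity.mean()
    assert got == pytest.approx(truth, rel=0.10)
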