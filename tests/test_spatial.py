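"""Neighbourhood-metric checks: approach distances, associations, summaries."""

import numpy as np
import pandas as pd
import pytest

from gridtrack import spatial


def _track(tag, wins, xs, ys, window_s=30.0):
    return pd.DataFrame(
        {"tag_id": tag, "window_index": wins,
         "t_mid_s": (np.asarray(wins) + 0.5) * window_s,
         "x_m": xs, "y_m": ys}
    )


def _manifest(rows):
    return pd.DataFrame(rows, columns=["bird_id", "sex", "mate_id"])


TRIAL = spatial.TrialWindows(focal_id=0, site=(0.0, 0.0), t_start=3600.0,
                             t_end=3720.0)


class TestTrialWindows:
    def test_windows_are_disjoint_hours(self):
        t = np.array([0.0, 3599.9, 3600.0, 3700.0, 3720.0, 3720.1, 7320.0, 7321.0])
        pre, post = TRIAL.in_pre(t), TRIAL.in_post(t)
        assert pre.tolist() == [True, True, False, False, False, False, False, False]
        assert post.tolist() == [False, False, False, False, False, True, True, False]
        assert not np.any(pre & post)

    def test_bad_windows_rejected(self):
        with pytest.raises(ValueError):
            spatial.TrialWindows(0, (0, 0), 100.0, 50.0)


class TestMinApproachDistance:
    def test_fix_at_site_is_zero(self):
        tr = _track(1, [10], [0.0], [0.0])
        d = spatial.min_approach_distance(tr, (0.0, 0.0), np.array([True]))
        assert d == 0.0

    def test_minimum_of_multiple_fixes(self):
        tr = _track(1, [0, 1, 2], [120.0, 85.0, 240.0], [0.0, 0.0, 0.0])
        d = spatial.min_approach_distance(tr, (0.0, 0.0), np.ones(3, bool))
        assert d == 85.0

    def test_no_fixes_gives_none(self):
        tr = _track(1, [0], [1.0], [1.0])
        assert spatial.min_approach_distance(tr, (0, 0), np.array([False])) is None

    def test_matches_bruteforce_scan(self, rng):
        wins = np.arange(100)
        tr = _track(1, wins, rng.normal(0, 50, 100), rng.normal(0, 50, 100))
        mask = rng.random(100) < 0.5
        site = (10.0, -20.0)
        expected = min(
            np.hypot(x - site[0], y - site[1])
            for x, y, m in zip(tr["x_m"], tr["y_m"], mask) if m
        )
        assert spatial.min_approach_distance(tr, site, mask) == pytest.approx(expected)


class TestClosestNeighborDelta:
    def test_single_female_attraction(self):
        # female at 100 m pre, 60 m post: delta = -40 (came closer)
        tracks = {
            1: _track(1, [10, 130], [100.0, 60.0], [0.0, 0.0]),
        }
        man = _manifest([(0, "M", -1), (1, "F", -1)])
        out = spatial.closest_neighbor_delta(tracks, man, TRIAL).set_index("conspecific_sex")
        assert out.loc["F", "delta_min_dist_m"] == pytest.approx(-40.0)
        assert not out.loc["M", "complete"]

    def test_identical_tracks_give_zero_delta(self):
        tracks = {1: _track(1, [10, 130], [70.0, 70.0], [5.0, 5.0])}
        man = _manifest([(0, "M", -1), (1, "F", -1)])
        out = spatial.closest_neighbor_delta(tracks, man, TRIAL).set_index("conspecific_sex")
        assert out.loc["F", "delta_min_dist_m"] == pytest.approx(0.0)

    def test_closest_individual_may_differ_between_windows(self):
        tracks = {
            1: _track(1, [10, 130], [50.0, 90.0], [0.0, 0.0]),
            2: _track(2, [10, 130], [80.0, 40.0], [0.0, 0.0]),
        }
        man = _manifest([(0, "M", -1), (1, "F", -1), (2, "F", -1)])
        out = spatial.closest_neighbor_delta(tracks, man, TRIAL).set_index("conspecific_sex")
        # pre minimum from bird 1 (50), post minimum from bird 2 (40)
        assert out.loc["F", "min_dist_pre_m"] == 50.0
        assert out.loc["F", "min_dist_post_m"] == 40.0

    def test_focal_excluded(self):
        tracks = {0: _track(0, [10, 130], [1.0, 1.0], [0.0, 0.0])}
        man = _manifest([(0, "M", -1)])
        out = spatial.closest_neighbor_delta(tracks, man, TRIAL).set_index("conspecific_sex")
        assert not out["complete"].any()

    def test_widening_post_window_only_decreases_minimum(self, rng):
        """Monotonicity: a longer post window can only lower min distance."""
        wins = np.arange(125, 400)
        tr = _track(1, wins, rng.normal(0, 80, len(wins)), rng.normal(0, 80, len(wins)))
        man = _manifest([(0, "M", -1), (1, "F", -1)])
        prev = np.inf
        for length in (1800.0, 3600.0, 7200.0):
            trial = spatial.TrialWindows(0, (0.0, 0.0), 3600.0, 3720.0, length=length)
            out = spatial.closest_neighbor_delta({1: tr}, man, trial)
            post = out.set_index("conspecific_sex").loc["F", "min_dist_post_m"]
            if not np.isnan(post):
                assert post <= prev + 1e-12
                prev = post


def _random_fixture(rng, n_birds=10, n_windows=120, spread=30.0):
    rows = []
    for b in range(n_birds):
        wins = np.sort(rng.choice(n_windows, size=rng.integers(n_windows // 2, n_windows),
                                  replace=False))
        for w in wins:
            rows.append((b, w, (w + 0.5) * 30.0,
                         rng.normal(0, spread), rng.normal(0, spread)))
    return pd.DataFrame(rows, columns=["tag_id", "window_index", "t_mid_s",
                                       "x_m", "y_m"])


def _bruteforce_events(fixes, focal, radius, mate=None):
    """All-pairs enumeration, the independent oracle."""
    out = []
    foc = fixes[fixes["tag_id"] == focal]
    for _, fr in foc.iterrows():
        same = fixes[(fixes["window_index"] == fr["window_index"])
                     & (fixes["tag_id"] != focal)]
        for _, pr in same.iterrows():
            d = np.hypot(pr["x_m"] - fr["x_m"], pr["y_m"] - fr["y_m"])
            if d <= radius and pr["tag_id"] != mate:
                out.append((pr["tag_id"], pr["window_index"], d))
    return sorted(out)


class TestBuildAssociations:
    def _all(self, t):
        return np.ones(len(np.atleast_1d(t)), bool)

    def test_radius_threshold(self):
        for dist, expected in ((9.9, 1), (10.1, 0)):
            fixes = pd.concat([
                _track(0, [0], [0.0], [0.0]),
                _track(1, [0], [dist], [0.0]),
            ], ignore_index=True)
            ev = spatial.build_associations(fixes, 0, self._all, radius=10.0)
            assert len(ev) == expected

    def test_repeated_partner_counts_windows_once_each(self):
        fixes = pd.concat([
            _track(0, [0, 1, 2, 3], [0.0] * 4, [0.0] * 4),
            _track(1, [0, 1, 2, 3], [5.0] * 4, [0.0] * 4),
        ], ignore_index=True)
        ev = spatial.build_associations(fixes, 0, self._all, radius=10.0)
        assert len(ev) == 4
        assert ev["partner_id"].nunique() == 1

    def test_mate_excluded(self):
        fixes = pd.concat([
            _track(0, [0], [0.0], [0.0]),
            _track(7, [0], [5.0], [0.0]),
        ], ignore_index=True)
        man = pd.DataFrame({"bird_id": [0, 7], "sex": ["M", "F"], "mate_id": [7, 0]})
        ev = spatial.build_associations(fixes, 0, self._all, 10.0, manifest=man)
        assert len(ev) == 0

    def test_symmetry_before_mate_exclusion(self, rng):
        fixes = _random_fixture(rng, n_birds=6, n_windows=40, spread=10.0)
        for a, b in [(0, 1), (2, 3)]:
            ev_a = spatial.build_associations(fixes, a, self._all, 10.0)
            ev_b = spatial.build_associations(fixes, b, self._all, 10.0)
            in_a = set(ev_a[ev_a["partner_id"] == b]["window_index"])
            in_b = set(ev_b[ev_b["partner_id"] == a]["window_index"])
            assert in_a == in_b

    @pytest.mark.parametrize("seed", range(5))
    def test_matches_bruteforce(self, seed):
        rng = np.random.default_rng(seed)
        fixes = _random_fixture(rng, spread=15.0)
        ev = spatial.build_associations(fixes, 0, self._all, 10.0)
        got = sorted(zip(ev["partner_id"], ev["window_index"], ev["distance_m"]))
        expected = _bruteforce_events(fixes, 0, 10.0)
        assert len(got) == len(expected)
        for g, e in zip(got, expected):
            assert g[:2] == e[:2] and g[2] == pytest.approx(e[2])

    def test_bad_radius(self):
        with pytest.raises(ValueError):
            spatial.build_associations(pd.DataFrame(), 0, self._all, 0.0)


class TestAssociationSummary:
    def test_time_arithmetic(self):
        man = _manifest([(0, "M", -1), (1, "M", -1), (2, "M", -1), (3, "M", -1)])
        ev = pd.DataFrame({
            "focal_id": 0,
            "partner_id": [1] * 5 + [2] * 3 + [3] * 2,
            "window_index": range(10),
            "distance_m": 5.0,
        })
        s = spatial.association_summary(ev, man, window_s=30.0)
        assert s["M"]["n_associates"] == 3
        assert s["M"]["mean_assoc_time_s"] == pytest.approx(100.0)

    def test_zero_partners_is_missing_not_zero(self):
        man = _manifest([(0, "M", -1)])
        ev = pd.DataFrame(columns=["focal_id", "partner_id", "window_index",
                                   "distance_m"])
        s = spatial.association_summary(ev, man)
        assert s["F"]["n_associates"] == 0
        assert np.isnan(s["F"]["mean_assoc_time_s"])

    def test_two_bird_hand_enumerated_fixture(self):
        # focal 0 meets female 2 in windows {3, 5, 8} and male 1 in {5}
        fixes = pd.concat([
            _track(0, [3, 5, 8], [0.0] * 3, [0.0] * 3),
            _track(1, [5, 9], [4.0, 50.0], [0.0, 0.0]),
            _track(2, [3, 5, 8], [3.0] * 3, [0.0] * 3),
        ], ignore_index=True)
        man = _manifest([(0, "M", -1), (1, "M", -1), (2, "F", -1)])
        ev = spatial.build_associations(fixes, 0, lambda t: np.ones(len(t), bool), 10.0)
        s = spatial.association_summary(ev, man)
        assert s["F"] == {"n_associates": 1, "mean_assoc_time_s": pytest.approx(90.0)}
        assert s["M"] == {"n_associates": 1, "mean_assoc_time_s": pytest.approx(30.0)}
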