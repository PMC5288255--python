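"""Neighbourhood outcomes around a simulated territory intrusion.

Two families of metrics, both computed from half-minute position fixes in
a 60-min window before and a 60-min window after the intrusion:

* approach distances — per conspecific sex, the minimum distance to the
  intrusion site of the closest individual in each window (the closest
  bird may differ between windows), and the post − pre change; negative
  change means conspecifics came closer;
* the focal male's close-range proximity network — associates are
  conspecifics within 10 m in the same half-minute window; per sex we
  count unique partners and the mean association time (total co-located
  time divided by the number of unique partners), crediting one fix
  window (30 s) per co-located window.  The focal's mate is excluded
  from the female associates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

__all__ = [
    "TrialWindows",
    "min_approach_distance",
    "closest_neighbor_delta",
    "build_associations",
    "association_summary",
    "neighbor_response",
]

NEIGHBOR_COLUMNS = [
    "focal_id",
    "conspecific_sex",
    "min_dist_pre_m",
    "min_dist_post_m",
    "delta_min_dist_m",
    "n_assoc_pre",
    "n_assoc_post",
    "mean_time_pre_s",
    "mean_time_post_s",
    "complete",
]


@dataclass(frozen=True)
class TrialWindows:
    """Pre/post observation windows flanking one intrusion.

    pre = [t_start − length, t_start), post = (t_end, t_end + length].
    """

    focal_id: int
    site: tuple[float, float]
    t_start: float
    t_end: float
    length: float = 3600.0

    def __post_init__(self) -> None:
        if self.t_end <= self.t_start:
            raise ValueError("t_end must exceed t_start")
        if self.length <= 0:
            raise ValueError("window length must be > 0")

    def in_pre(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return (t >= self.t_start - self.length) & (t < self.t_start)

    def in_post(self, t: np.ndarray) -> np.ndarray:
        t = np.asarray(t, float)
        return (t > self.t_end) & (t <= self.t_end + self.length)


def min_approach_distance(
    track: pd.DataFrame, site: tuple[float, float], in_window: np.ndarray
) -> float | None:
    """Minimum Euclidean distance of a bird's in-window fixes to the site.

    ``track`` needs columns ``t_mid_s, x_m, y_m``; ``in_window`` is a
    boolean mask over its rows.  None when the bird has no fix in the
    window.
    """
    if not np.any(in_window):
        return None
    x = track["x_m"].to_numpy(float)[in_window]
    y = track["y_m"].to_numpy(float)[in_window]
    return float(np.hypot(x - site[0], y - site[1]).min())


def closest_neighbor_delta(
    tracks: dict, manifest: pd.DataFrame, trial: TrialWindows
) -> pd.DataFrame:
    """Per conspecific sex: closest-individual distance pre/post and its change.

    The minimum is taken over all non-focal birds of that sex with at
    least one fix in the window, so the identity of the closest bird may
    differ pre vs post.  A record is flagged incomplete (delta = NaN)
    when either window holds no fix for that sex.
    """
    sexes = manifest.set_index("bird_id")["sex"]
    rows = []
    for sex in ("M", "F"):
        pre_min: float | None = None
        post_min: float | None = None
        for bid, track in tracks.items():
            if bid == trial.focal_id or sexes.get(bid) != sex:
                continue
            t = track["t_mid_s"].to_numpy(float)
            d_pre = min_approach_distance(track, trial.site, trial.in_pre(t))
            d_post = min_approach_distance(track, trial.site, trial.in_post(t))
            if d_pre is not None:
                pre_min = d_pre if pre_min is None else min(pre_min, d_pre)
            if d_post is not None:
                post_min = d_post if post_min is None else min(post_min, d_post)
        complete = pre_min is not None and post_min is not None
        rows.append(
            {
                "focal_id": trial.focal_id,
                "conspecific_sex": sex,
                "min_dist_pre_m": np.nan if pre_min is None else pre_min,
                "min_dist_post_m": np.nan if post_min is None else post_min,
                "delta_min_dist_m": (post_min - pre_min) if complete else np.nan,
                "complete": complete,
            }
        )
    return pd.DataFrame(rows)


def build_associations(
    fixes: pd.DataFrame,
    focal_id: int,
    in_window,
    radius: float = 10.0,
    manifest: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Proximity events: partners within ``radius`` of the focal, per fix window.

    ``fixes`` is a fix table for all birds (columns ``tag_id,
    window_index, t_mid_s, x_m, y_m``); ``in_window`` is a callable
    mapping times to a boolean mask (e.g. ``trial.in_pre``).  One event
    per (partner, window_index) where both the focal and the partner have
    a fix in that half-minute window at distance <= radius.  If a
    manifest with mates is given, the focal's mate is dropped from the
    (female) partners.
    """
    if radius <= 0:
        raise ValueError("radius must be > 0")
    sel = fixes[np.asarray(in_window(fixes["t_mid_s"].to_numpy(float)))]
    foc = sel[sel["tag_id"] == focal_id]
    oth = sel[sel["tag_id"] != focal_id]
    merged = oth.merge(
        foc[["window_index", "x_m", "y_m"]],
        on="window_index",
        suffixes=("", "_focal"),
    )
    if len(merged) == 0:
        return pd.DataFrame(columns=["focal_id", "partner_id", "window_index", "distance_m"])
    d = np.hypot(
        merged["x_m"] - merged["x_m_focal"], merged["y_m"] - merged["y_m_focal"]
    )
    ev = merged.loc[d.to_numpy() <= radius, ["tag_id", "window_index"]].copy()
    ev["distance_m"] = d[d <= radius].to_numpy()
    ev = ev.rename(columns={"tag_id": "partner_id"})
    ev.insert(0, "focal_id", focal_id)
    if manifest is not None and "mate_id" in manifest.columns:
        mates = manifest.set_index("bird_id")["mate_id"]
        mate = mates.get(focal_id, -1)
        if mate is not None and mate >= 0:
            ev = ev[ev["partner_id"] != mate]
    return ev.reset_index(drop=True)


def association_summary(
    events: pd.DataFrame, manifest: pd.DataFrame, window_s: float = 30.0
) -> dict:
    """Per-sex partner counts and mean association time from one window's events.

    Each event credits one fix window of association time.  Mean time is
    total credited time over unique partners; with zero partners it is
    missing (NaN), never 0.
    """
    sexes = manifest.set_index("bird_id")["sex"]
    out = {}
    for sex in ("M", "F"):
        if len(events):
            sub = events[events["partner_id"].map(sexes).eq(sex)]
        else:
            sub = events
        n_partners = int(sub["partner_id"].nunique()) if len(sub) else 0
        total = len(sub) * window_s
        out[sex] = {
            "n_associates": n_partners,
            "mean_assoc_time_s": (total / n_partners) if n_partners else np.nan,
        }
    return out


def neighbor_response(
    fixes: pd.DataFrame,
    tracks: dict,
    manifest: pd.DataFrame,
    trial: TrialWindows,
    radius: float = 10.0,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Assemble the full per-trial outcome table (one row per conspecific sex)."""
    dist = closest_neighbor_delta(tracks, manifest, trial)
    ev_pre = build_associations(fixes, trial.focal_id, trial.in_pre, radius, manifest)
    ev_post = build_associations(fixes, trial.focal_id, trial.in_post, radius, manifest)
    s_pre = association_summary(ev_pre, manifest, window_s)
    s_post = association_summary(ev_post, manifest, window_s)
    dist = dist.set_index("conspecific_sex")
    rows = []
    for sex in ("M", "F"):
        r = dist.loc[sex]
        rows.append(
            {
                "focal_id": trial.focal_id,
                "conspecific_sex": sex,
                "min_dist_pre_m": r["min_dist_pre_m"],
                "min_dist_post_m": r["min_dist_post_m"],
                "delta_min_dist_m": r["delta_min_dist_m"],
                "n_assoc_pre": s_pre[sex]["n_associates"],
                "n_assoc_post": s_post[sex]["n_associates"],
                "mean_time_pre_s": s_pre[sex]["mean_assoc_time_s"],
                "mean_time_post_s": s_post[sex]["mean_assoc_time_s"],
                "complete": bool(r["complete"]),
            }
        )
    return pd.DataFrame(rows, columns=NEIGHBOR_COLUMNS)
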