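"""Synthetic receiver grids, territories, movement and radio detections.

This module generates data with the statistical structure the downstream
analysis assumes, so the whole chain — multilateration, neighbourhood
metrics, response scoring, mixed models — is testable without field data.

The world it emulates is a woodland study plot instrumented with a
triangular grid of radio receiver stations ("base nodes") logging beacons
from tagged birds.  Birds hold territories; movement is an
Ornstein–Uhlenbeck (OU) walk around a territory anchor, which is
stationary and has closed-form moments that the tests use as oracles.
A simulated territory intrusion (song playback at a site inside a focal
male's territory) perturbs the neighbourhood: during the response window
the anchors of non-focal birds shift along the anchor→site axis, females
toward the site and males away, proportionally to the focal male's vocal
response score.  Radio propagation is log-distance path loss with i.i.d.
Gaussian dB noise and a logistic detection probability in distance.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import signal as _signal

__all__ = [
    "NodeGrid",
    "WorldConfig",
    "IntrusionScenario",
    "TrueTrack",
    "DEFAULT_LOADINGS",
    "generate_grid",
    "simulate_track",
    "simulate_detections",
    "simulate_response_table",
    "build_manifest",
    "simulate_trial",
]


# --------------------------------------------------------------------------- #
# domain types
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class NodeGrid:
    """Receiver-station map: ids, planar coordinates (m) and extent."""

    node_ids: np.ndarray  # (n,) int
    xy: np.ndarray  # (n, 2) float, metres
    spacing: float
    area_bounds: tuple[float, float, float, float]  # xmin, ymin, xmax, ymax

    def __post_init__(self) -> None:
        if len(np.unique(self.node_ids)) != len(self.node_ids):
            raise ValueError("node_ids must be unique")
        xmin, ymin, xmax, ymax = self.area_bounds
        x, y = self.xy[:, 0], self.xy[:, 1]
        if not ((x >= xmin) & (x <= xmax) & (y >= ymin) & (y <= ymax)).all():
            raise ValueError("all nodes must lie within area_bounds")

    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"node_id": self.node_ids, "x_m": self.xy[:, 0], "y_m": self.xy[:, 1]}
        )

    @classmethod
    def from_frame(cls, df: pd.DataFrame, spacing: float = 40.0) -> "NodeGrid":
        xy = df[["x_m", "y_m"]].to_numpy(float)
        pad = spacing
        bounds = (
            xy[:, 0].min() - pad,
            xy[:, 1].min() - pad,
            xy[:, 0].max() + pad,
            xy[:, 1].max() + pad,
        )
        return cls(df["node_id"].to_numpy(), xy, spacing, bounds)


@dataclass(frozen=True)
class WorldConfig:
    """Parameters of movement, radio propagation and detection.

    Movement is OU per axis: ``dX = theta (mu - X) dt + sigma dW`` with
    stationary per-axis s.d. ``sigma / sqrt(2 theta)`` (~20 m at the
    defaults, a songbird territory scale).  RSSI at distance d follows
    ``rssi0 - 10 * path_loss_exponent * log10(d / d0)`` plus Gaussian dB
    noise; a beacon is received by a node with logistic probability in
    distance, 0.5 at ``detect_range_50`` with scale ``detect_scale``.
    """

    n_males: int = 21
    n_females: int = 23
    ou_theta: float = 0.01  # 1/s, mean reversion (timescale ~100 s)
    ou_sigma: float = 2.8  # m/sqrt(s); stationary sd ~= 19.8 m
    beacon_period: float = 5.0  # s
    rssi0: float = -40.0  # dB at reference distance d0
    d0: float = 1.0  # m
    path_loss_exponent: float = 2.5
    rssi_noise_sd: float = 4.0  # dB
    detect_range_50: float = 80.0  # m, 50% detection probability
    detect_scale: float = 10.0  # m, logistic scale
    seed: int = 0

    def __post_init__(self) -> None:
        if self.ou_theta <= 0:
            raise ValueError("ou_theta must be > 0")
        if self.ou_sigma < 0:
            raise ValueError("ou_sigma must be >= 0")
        if self.beacon_period <= 0:
            raise ValueError("beacon_period must be > 0")
        if self.path_loss_exponent <= 0:
            raise ValueError("path_loss_exponent must be > 0")
        if self.rssi_noise_sd < 0:
            raise ValueError("rssi_noise_sd must be >= 0")

    @property
    def stationary_sd(self) -> float:
        """Per-axis stationary s.d. of the OU position process (m)."""
        return self.ou_sigma / np.sqrt(2.0 * self.ou_theta)

    def max_detect_range(self, p_floor: float = 1e-6) -> float:
        """Distance beyond which detection probability < ``p_floor``."""
        return self.detect_range_50 + self.detect_scale * np.log((1.0 - p_floor) / p_floor)


@dataclass(frozen=True)
class IntrusionScenario:
    """A simulated territory intrusion and the neighbourhood response it drives.

    ``attract_female`` / ``repel_male`` are anchor displacements in metres
    per unit of the focal male's standardized vocal score, measured along
    the anchor→site axis with positive = away from the site (so a negative
    ``attract_female`` moves females toward the site).  The defaults imply
    a sex x vocal-score interaction of ``repel_male - attract_female`` =
    13.5 m on the closest-neighbour distance change.
    """

    focal_id: int
    site: tuple[float, float]
    t_start: float
    t_end: float
    vocal_score: float = 0.0
    attract_female: float = -9.0
    repel_male: float = 4.5
    post_window: float = 3600.0

    def __post_init__(self) -> None:
        if not self.t_end > self.t_start:
            raise ValueError("t_end must exceed t_start")
        if not (np.isfinite(self.attract_female) and np.isfinite(self.repel_male)):
            raise ValueError("effect magnitudes must be finite")


@dataclass(frozen=True)
class TrueTrack:
    """Ground-truth movement path of one bird: (t, x, y) samples."""

    bird_id: int
    sex: str  # 'M' or 'F'
    t: np.ndarray  # (k,) s, strictly increasing
    xy: np.ndarray  # (k, 2) m

    def __post_init__(self) -> None:
        if len(self.t) > 1 and not (np.diff(self.t) > 0).all():
            raise ValueError("track times must be strictly increasing")
        if not np.isfinite(self.xy).all():
            raise ValueError("track coordinates must be finite")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"bird_id": self.bird_id, "t_s": self.t, "x_m": self.xy[:, 0], "y_m": self.xy[:, 1]}
        )


# --------------------------------------------------------------------------- #
# receiver grid
# --------------------------------------------------------------------------- #


def generate_grid(
    spacing: float = 40.0,
    n_nodes: int = 166,
    jitter_sd: float = 3.0,
    seed: int = 0,
    origin: tuple[float, float] = (0.0, 0.0),
) -> NodeGrid:
    """Triangular receiver lattice with Gaussian placement jitter.

    Rows are offset by ``spacing / 2`` and separated by ``spacing *
    sqrt(3) / 2``, the equilateral-triangle lattice; the lattice is built
    row-major in a near-square block and truncated to ``n_nodes``.
    ``jitter_sd`` perturbs each coordinate independently, emulating
    nodes strapped to whichever tree is nearest the ideal point.
    """
    if spacing <= 0:
        raise ValueError("spacing must be > 0")
    if n_nodes < 3:
        raise ValueError("need at least 3 nodes")
    rng = np.random.default_rng(seed)
    n_cols = max(3, int(np.ceil(np.sqrt(n_nodes))))
    n_rows = int(np.ceil(n_nodes / n_cols))
    row_h = spacing * np.sqrt(3.0) / 2.0
    pts = []
    for r in range(n_rows):
        x0 = origin[0] + (spacing / 2.0 if r % 2 else 0.0)
        for c in range(n_cols):
            pts.append((x0 + c * spacing, origin[1] + r * row_h))
    xy = np.asarray(pts[:n_nodes], float)
    if jitter_sd > 0:
        xy = xy + rng.normal(0.0, jitter_sd, xy.shape)
    pad = spacing
    bounds = (
        xy[:, 0].min() - pad,
        xy[:, 1].min() - pad,
        xy[:, 0].max() + pad,
        xy[:, 1].max() + pad,
    )
    return NodeGrid(np.arange(n_nodes), xy, spacing, bounds)


# --------------------------------------------------------------------------- #
# movement
# --------------------------------------------------------------------------- #


def _response_anchor(
    anchor: np.ndarray, scenario: IntrusionScenario, sex: str, is_focal: bool
) -> np.ndarray:
    """Anchor during the response window (shifted along the anchor→site axis)."""
    if is_focal:
        return anchor
    site = np.asarray(scenario.site, float)
    v = anchor - site  # axis pointing away from the site
    norm = np.hypot(*v)
    if norm == 0.0:
        return anchor
    u = v / norm
    mag = scenario.attract_female if sex == "F" else scenario.repel_male
    shift = mag * scenario.vocal_score
    # do not let a strong attraction push the anchor past the site
    shift = max(shift, -norm)
    return anchor + shift * u


def simulate_track(
    anchor: tuple[float, float],
    config: WorldConfig,
    t0: float,
    t1: float,
    dt: float,
    scenario: IntrusionScenario | None = None,
    sex: str = "M",
    seed: int = 0,
    bird_id: int = 0,
    start: tuple[float, float] | None = None,
) -> TrueTrack:
    """Euler-discretized OU track around a (possibly time-varying) anchor.

    ``X(t+dt) = X(t) + theta (mu(t) - X(t)) dt + sigma sqrt(dt) eps``.
    Outside the response window ``mu`` is the territory anchor; during
    ``[t_start, t_end + post_window]`` of a scenario it is the shifted
    anchor (see :class:`IntrusionScenario`).  The focal bird keeps its own
    anchor (the intrusion site lies inside its territory).  If ``start``
    is None the track starts at a draw from the stationary distribution,
    so no burn-in is needed.
    """
    if not t1 > t0:
        raise ValueError("t1 must exceed t0")
    if dt <= 0:
        raise ValueError("dt must be > 0")
    if dt >= 1.0 / config.ou_theta:
        warnings.warn(
            f"dt={dt} >= 1/theta={1.0 / config.ou_theta:.1f}: Euler OU step is unstable",
            RuntimeWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    t = t0 + np.arange(int(np.floor((t1 - t0) / dt)) + 1) * dt
    n = len(t)
    anchor = np.asarray(anchor, float)
    mu = np.broadcast_to(anchor, (n, 2)).copy()
    if scenario is not None:
        in_resp = (t >= scenario.t_start) & (t <= scenario.t_end + scenario.post_window)
        if in_resp.any():
            mu[in_resp] = _response_anchor(
                anchor, scenario, sex, bird_id == scenario.focal_id
            )

    phi = 1.0 - config.ou_theta * dt  # AR(1) coefficient of the Euler step
    if start is None:
        x0 = anchor + rng.normal(0.0, config.stationary_sd, 2)
    else:
        x0 = np.asarray(start, float)
    noise = rng.normal(0.0, config.ou_sigma * np.sqrt(dt), (n - 1, 2)) if n > 1 else np.empty((0, 2))
    # X_k = phi X_{k-1} + (1-phi) mu_{k-1} + eps_k  ==  AR(1) filter
    drive = (1.0 - phi) * mu[:-1] + noise
    xy = np.empty((n, 2))
    xy[0] = x0
    if n > 1:
        zi = phi * x0  # lfilter initial condition carrying X_0 into step 1
        for ax in (0, 1):
            out, _ = _signal.lfilter([1.0], [1.0, -phi], drive[:, ax], zi=[zi[ax]])
            xy[1:, ax] = out
    return TrueTrack(bird_id=bird_id, sex=sex, t=t, xy=xy)


# --------------------------------------------------------------------------- #
# radio detections
# --------------------------------------------------------------------------- #


def rssi_model(d: np.ndarray, config: WorldConfig) -> np.ndarray:
    """Expected RSSI (dB) at distance ``d`` under log-distance path loss."""
    d = np.maximum(np.asarray(d, float), 1e-3)
    return config.rssi0 - 10.0 * config.path_loss_exponent * np.log10(d / config.d0)


def detection_probability(d: np.ndarray, config: WorldConfig) -> np.ndarray:
    """Logistic detection probability in distance (0.5 at detect_range_50)."""
    z = (np.asarray(d, float) - config.detect_range_50) / config.detect_scale
    return 1.0 / (1.0 + np.exp(z))


def simulate_detections(
    track: TrueTrack,
    grid: NodeGrid,
    config: WorldConfig,
    seed: int = 0,
    p_floor: float = 1e-6,
) -> pd.DataFrame:
    """Beacon reception log for one track: columns tag_id, node_id, t_s, rssi_db.

    One beacon per ``beacon_period`` (beacon times interpolated on the
    track); each node receives it independently with logistic probability
    in distance, and records RSSI = path-loss mean + Gaussian dB noise.
    Nodes beyond the distance where detection probability < ``p_floor``
    never produce records (truncation contract).
    """
    if grid.n_nodes == 0:
        raise ValueError("grid has no nodes")
    span = track.t[-1] - track.t[0]
    if span < config.beacon_period:
        raise ValueError("track must span at least one beacon period")
    rng = np.random.default_rng(seed)
    n_beacons = int(np.floor(span / config.beacon_period)) + 1
    tb = track.t[0] + np.arange(n_beacons) * config.beacon_period
    bx = np.interp(tb, track.t, track.xy[:, 0])
    by = np.interp(tb, track.t, track.xy[:, 1])
    # (n_beacons, n_nodes) distance matrix
    dx = bx[:, None] - grid.xy[None, :, 0]
    dy = by[:, None] - grid.xy[None, :, 1]
    d = np.hypot(dx, dy)
    dmax = config.max_detect_range(p_floor)
    cand = d <= dmax
    p = detection_probability(d, config)
    hit = cand & (rng.random(d.shape) < p)
    bi, ni = np.nonzero(hit)
    rssi = rssi_model(d[bi, ni], config)
    if config.rssi_noise_sd > 0:
        rssi = rssi + rng.normal(0.0, config.rssi_noise_sd, rssi.shape)
    return pd.DataFrame(
        {
            "tag_id": np.full(len(bi), track.bird_id),
            "node_id": grid.node_ids[ni],
            "t_s": tb[bi],
            "rssi_db": rssi,
        }
    )


# --------------------------------------------------------------------------- #
# playback response tables
# --------------------------------------------------------------------------- #

# rows: n_overlaps, n_songs_total, n_songs_during, sing_duration_s,
#       time_within_5m_s, latency_s;  columns: (vocal, spatial) latents.
DEFAULT_LOADINGS = np.array(
    [
        [0.9, 0.0],
        [0.9, 0.0],
        [0.9, 0.0],
        [0.9, 0.0],
        [0.0, 0.9],
        [0.0, -0.9],  # latency: strong spatial responders approach sooner
    ]
)

RESPONSE_COLUMNS = [
    "n_overlaps",
    "n_songs_total",
    "n_songs_during",
    "sing_duration_s",
    "time_within_5m_s",
    "latency_s",
]

# affine scales mapping standardized variables onto field-realistic units
_RESPONSE_SCALE = {
    "n_overlaps": (5.0, 3.0),
    "n_songs_total": (20.0, 8.0),
    "n_songs_during": (10.0, 4.0),
    "sing_duration_s": (60.0, 25.0),
    "time_within_5m_s": (100.0, 45.0),
    "latency_s": (150.0, 60.0),
}


def simulate_response_table(
    n_subjects: int = 14,
    loadings: np.ndarray | None = None,
    age_effect: float = 0.8,
    condition_effect: float = 0.7,
    noise_sd: float = 0.4,
    seed: int = 0,
) -> pd.DataFrame:
    """Playback-response table with a two-factor latent structure.

    Each subject has latent vocal and spatial response strengths; the
    vocal latent is driven by age (second-calendar-year vs older) and
    body condition, emulating stronger vocal responses from older birds
    in better condition.  Six observed variables are
    ``loadings @ latents + noise`` mapped onto field-realistic scales
    (counts and seconds are kept continuous so the correlation structure
    is exact).  Columns include the generating latents
    (``latent_q_vocal``/``latent_q_spatial``) as ground truth for tests;
    the analysis never reads them.
    """
    if n_subjects < 6:
        raise ValueError("need at least 6 subjects (one per response variable)")
    L = DEFAULT_LOADINGS if loadings is None else np.asarray(loadings, float)
    if L.shape != (6, 2):
        raise ValueError(f"loadings must be 6x2, got {L.shape}")
    if n_subjects < 3 * 6:
        warnings.warn(
            f"n_subjects={n_subjects} < 3 x 6 variables: component retention is fragile",
            UserWarning,
            stacklevel=2,
        )
    rng = np.random.default_rng(seed)
    age_older = rng.random(n_subjects) < 0.5
    condition_z = rng.normal(0.0, 1.0, n_subjects)
    resid_sd = 0.8
    q_vocal = age_effect * age_older + condition_effect * condition_z + rng.normal(
        0.0, resid_sd, n_subjects
    )
    q_vocal = (q_vocal - np.mean([0.5 * age_effect])) / np.sqrt(
        age_effect**2 * 0.25 + condition_effect**2 + resid_sd**2
    )
    q_spatial = rng.normal(0.0, 1.0, n_subjects)
    latents = np.column_stack([q_vocal, q_spatial])
    z = latents @ L.T + rng.normal(0.0, noise_sd, (n_subjects, 6))

    tarsus = rng.normal(19.5, 0.8, n_subjects)
    weight = -1.5 + 1.0 * tarsus + 0.8 * condition_z + rng.normal(0.0, 0.1, n_subjects)

    df = pd.DataFrame({"subject_id": np.arange(n_subjects)})
    for j, col in enumerate(RESPONSE_COLUMNS):
        loc, scale = _RESPONSE_SCALE[col]
        df[col] = loc + scale * z[:, j]
    df["age_class"] = np.where(age_older, "older", "2cy")
    df["weight_g"] = weight
    df["tarsus_mm"] = tarsus
    df["latent_q_vocal"] = q_vocal
    df["latent_q_spatial"] = q_spatial
    df["latent_condition"] = condition_z
    return df


# --------------------------------------------------------------------------- #
# colonies and trials
# --------------------------------------------------------------------------- #


def build_manifest(
    grid: NodeGrid,
    config: WorldConfig,
    seed: int = 0,
    response_table: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Bird roster: ids, sexes, territory anchors, morphometrics and mates.

    Male anchors are spread over the grid interior with a minimum
    separation of about two grid spacings (territoriality); female anchors
    are placed near males.  Each male's mate is the female with the
    nearest anchor (greedy, each female at most once).
    """
    rng = np.random.default_rng(seed)
    xmin, ymin, xmax, ymax = grid.area_bounds
    pad = grid.spacing
    lo = np.array([xmin + pad, ymin + pad])
    hi = np.array([xmax - pad, ymax - pad])

    def _scatter(n: int, min_sep: float) -> np.ndarray:
        pts: list[np.ndarray] = []
        tries = 0
        while len(pts) < n and tries < 20000:
            cand = lo + rng.random(2) * (hi - lo)
            if all(np.hypot(*(cand - p)) >= min_sep for p in pts):
                pts.append(cand)
            tries += 1
        while len(pts) < n:  # relax if the plot is crowded
            pts.append(lo + rng.random(2) * (hi - lo))
        return np.asarray(pts)

    m_anchor = _scatter(config.n_males, 2.0 * grid.spacing)
    # females roost in the neighbourhood of male territories, offset at
    # territory scale (one to two grid spacings) rather than on the anchor
    host = m_anchor[rng.integers(0, config.n_males, config.n_females)]
    ang = rng.uniform(0.0, 2.0 * np.pi, config.n_females)
    rad = grid.spacing * rng.uniform(1.5, 3.0, config.n_females)
    f_anchor = host + rad[:, None] * np.column_stack([np.cos(ang), np.sin(ang)])
    f_anchor = np.clip(f_anchor, lo, hi)

    n = config.n_males + config.n_females
    bird_id = np.arange(n)
    sex = np.array(["M"] * config.n_males + ["F"] * config.n_females)
    anchors = np.vstack([m_anchor, f_anchor])

    tarsus = rng.normal(19.5, 0.8, n)
    weight = -1.5 + 1.0 * tarsus + rng.normal(0.0, 0.8, n)
    age = np.where(rng.random(n) < 0.5, "older", "2cy")

    mate = np.full(n, -1)
    taken: set[int] = set()
    order = np.argsort([min(np.hypot(*(ma - fa)) for fa in f_anchor) for ma in m_anchor])
    for mi in order:
        d = np.hypot(f_anchor[:, 0] - m_anchor[mi, 0], f_anchor[:, 1] - m_anchor[mi, 1])
        for fi in np.argsort(d):
            fid = config.n_males + int(fi)
            if fid not in taken:
                mate[mi] = fid
                mate[fid] = mi
                taken.add(fid)
                break

    df = pd.DataFrame(
        {
            "bird_id": bird_id,
            "sex": sex,
            "age_class": age,
            "weight_g": weight,
            "tarsus_mm": tarsus,
            "mate_id": mate,
            "anchor_x_m": anchors[:, 0],
            "anchor_y_m": anchors[:, 1],
        }
    )
    if response_table is not None:
        # subjects keep the morphometrics that generated their vocal latent
        sub = response_table.set_index("subject_id")
        ids = sub.index.to_numpy()
        df.loc[df["bird_id"].isin(ids), "age_class"] = sub["age_class"].reindex(
            df.loc[df["bird_id"].isin(ids), "bird_id"]
        ).to_numpy()
        df.loc[df["bird_id"].isin(ids), "weight_g"] = sub["weight_g"].reindex(
            df.loc[df["bird_id"].isin(ids), "bird_id"]
        ).to_numpy()
        df.loc[df["bird_id"].isin(ids), "tarsus_mm"] = sub["tarsus_mm"].reindex(
            df.loc[df["bird_id"].isin(ids), "bird_id"]
        ).to_numpy()
    return df


@dataclass(frozen=True)
class TrialData:
    """Everything one intrusion trial produces: truth, detections, scenario."""

    scenario: IntrusionScenario
    grid: NodeGrid
    manifest: pd.DataFrame
    tracks: dict[int, TrueTrack]
    detections: pd.DataFrame


def simulate_trial(
    grid: NodeGrid,
    manifest: pd.DataFrame,
    config: WorldConfig,
    scenario: IntrusionScenario,
    seed: int = 0,
    bird_ids: np.ndarray | None = None,
    session_pad: float = 0.0,
) -> TrialData:
    """Simulate one intrusion session: tracks + detections for all birds.

    The session runs from one hour before the intrusion to one hour after
    it (the pre/post observation windows), optionally padded.  ``bird_ids``
    restricts simulation to a subset (e.g. the focal's neighbourhood).
    """
    t0 = scenario.t_start - 3600.0 - session_pad
    t1 = scenario.t_end + scenario.post_window + session_pad
    rng = np.random.default_rng(seed)
    if bird_ids is None:
        bird_ids = manifest["bird_id"].to_numpy()
    rows = manifest.set_index("bird_id").loc[bird_ids]
    tracks: dict[int, TrueTrack] = {}
    dets: list[pd.DataFrame] = []
    for bid, row in rows.iterrows():
        s_track = int(rng.integers(0, 2**31 - 1))
        s_det = int(rng.integers(0, 2**31 - 1))
        tr = simulate_track(
            (row["anchor_x_m"], row["anchor_y_m"]),
            config,
            t0,
            t1,
            dt=config.beacon_period,
            scenario=scenario,
            sex=row["sex"],
            seed=s_track,
            bird_id=int(bid),
        )
        tracks[int(bid)] = tr
        dets.append(simulate_detections(tr, grid, config, seed=s_det))
    detections = pd.concat(dets, ignore_index=True) if dets else pd.DataFrame(
        columns=["tag_id", "node_id", "t_s", "rssi_db"]
    )
    return TrialData(scenario, grid, manifest, tracks, detections)
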