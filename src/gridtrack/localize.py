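"""RSSI multilateration: detection logs → half-minute position fixes.

Beacons received by the node grid are binned into half-minute windows per
tag; within a window, repeated beacons at one node are summarized by their
mean RSSI (in dB).  A window with fewer than three distinct receiving
nodes yields no fix.  Otherwise the position estimate is two-stage:

1. an RSSI-weighted centroid of the contributing nodes (weights linear in
   RSSI above the weakest node in the window), and
2. nonlinear least squares on the dB scale, minimizing
   ``sum_j (rssi_j - [rssi0 - 10 n log10(d_j(x)/d0)])^2``
   started from the centroid (Levenberg–Marquardt, vectorized over all
   windows at once).

If the refinement fails to improve on its start, the fix falls back to
the centroid (``method='weighted_centroid'``) rather than being dropped,
so fix density stays comparable across windows.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .world import NodeGrid, WorldConfig

__all__ = [
    "PositionFix",
    "window_detections",
    "rssi_to_distance",
    "estimate_position",
    "estimate_positions",
    "build_tracks",
]

FIX_COLUMNS = [
    "tag_id",
    "window_index",
    "t_mid_s",
    "x_m",
    "y_m",
    "n_nodes",
    "rms_residual_db",
    "method",
]


@dataclass(frozen=True)
class PositionFix:
    """One triangulated location: tag, half-minute window, (x, y), quality."""

    tag_id: int
    window_index: int
    t_mid: float
    x: float
    y: float
    n_nodes: int
    rms_residual: float
    method: str  # 'nls' or 'weighted_centroid'

    def __post_init__(self) -> None:
        if self.n_nodes < 3:
            raise ValueError("a fix requires >= 3 contributing nodes")
        if self.rms_residual < 0:
            raise ValueError("rms_residual must be >= 0")


def window_detections(records: pd.DataFrame, window_s: float = 30.0) -> pd.DataFrame:
    """Bin detections into half-open windows ``[k*w, (k+1)*w)`` per tag.

    Multiple beacons from the same node within one window are aggregated
    by their mean RSSI in dB.  Returns one row per (tag, window, node)
    with columns ``tag_id, window_index, node_id, rssi_db, n_beacons``.
    """
    if window_s <= 0:
        raise ValueError("window_s must be > 0")
    if len(records) == 0:
        return pd.DataFrame(columns=["tag_id", "window_index", "node_id", "rssi_db", "n_beacons"])
    win = np.floor(records["t_s"].to_numpy(float) / window_s).astype(np.int64)
    df = records.assign(window_index=win)
    out = (
        df.groupby(["tag_id", "window_index", "node_id"], sort=True)["rssi_db"]
        .agg(rssi_db="mean", n_beacons="size")
        .reset_index()
    )
    return out


def rssi_to_distance(
    rssi: np.ndarray | float,
    rssi0: float = -40.0,
    d0: float = 1.0,
    exponent: float = 2.5,
    flag_beyond: float | None = None,
) -> np.ndarray | float:
    """Invert log-distance path loss: ``d = d0 * 10^((rssi0 - rssi)/(10 n))``."""
    if exponent <= 0:
        raise ValueError("exponent must be > 0")
    d = d0 * 10.0 ** ((rssi0 - np.asarray(rssi, float)) / (10.0 * exponent))
    if flag_beyond is not None and np.any(d > flag_beyond):
        import warnings

        warnings.warn(
            f"{int(np.sum(d > flag_beyond))} inverted distance(s) exceed {flag_beyond} m "
            "(beyond the calibration range)",
            RuntimeWarning,
            stacklevel=2,
        )
    return float(d) if np.isscalar(rssi) else d


def _weighted_centroid(xy: np.ndarray, rssi: np.ndarray, mask: np.ndarray) -> np.ndarray:
    """RSSI-weighted centroid; weights = rssi - min_rssi_in_window + 1."""
    neg = np.where(mask, rssi, np.inf)
    w = rssi - neg.min(axis=1, keepdims=True) + 1.0
    w = np.where(mask, w, 0.0)
    sw = w.sum(axis=1, keepdims=True)
    return (w[..., None] * xy).sum(axis=1) / sw


def _objective(pos: np.ndarray, xy: np.ndarray, rssi: np.ndarray, mask: np.ndarray,
               config: WorldConfig) -> np.ndarray:
    """Sum of squared dB residuals at candidate positions, per window."""
    d = np.hypot(pos[:, None, 0] - xy[..., 0], pos[:, None, 1] - xy[..., 1])
    d = np.maximum(d, 1e-3)
    pred = config.rssi0 - 10.0 * config.path_loss_exponent * np.log10(d / config.d0)
    r = np.where(mask, rssi - pred, 0.0)
    return (r**2).sum(axis=1)


def _batch_lm(
    xy: np.ndarray,
    rssi: np.ndarray,
    mask: np.ndarray,
    start: np.ndarray,
    config: WorldConfig,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Levenberg–Marquardt over many windows at once.

    ``xy``: (m, k, 2) padded node coordinates; ``rssi``: (m, k) padded mean
    RSSI; ``mask``: (m, k) validity.  Returns (positions, objective,
    converged).  Step tolerance is in metres.
    """
    c = 10.0 * config.path_loss_exponent / np.log(10.0)
    pos = start.copy()
    lam = np.full(len(pos), 1e-3)
    obj = _objective(pos, xy, rssi, mask, config)
    converged = np.zeros(len(pos), bool)
    active = np.ones(len(pos), bool)
    for _ in range(max_iter):
        if not active.any():
            break
        idx = np.nonzero(active)[0]
        p = pos[idx]
        dx = p[:, None, 0] - xy[idx, :, 0]
        dy = p[:, None, 1] - xy[idx, :, 1]
        d2 = np.maximum(dx**2 + dy**2, 1e-6)
        d = np.sqrt(d2)
        pred = config.rssi0 - 10.0 * config.path_loss_exponent * np.log10(d / config.d0)
        r = np.where(mask[idx], rssi[idx] - pred, 0.0)
        # d pred / d pos = -c * (pos - node) / d^2  -> residual jacobian = +c (pos-node)/d^2
        jx = np.where(mask[idx], c * dx / d2, 0.0)
        jy = np.where(mask[idx], c * dy / d2, 0.0)
        a11 = (jx * jx).sum(axis=1)
        a12 = (jx * jy).sum(axis=1)
        a22 = (jy * jy).sum(axis=1)
        g1 = -(jx * r).sum(axis=1)
        g2 = -(jy * r).sum(axis=1)
        l = lam[idx]
        b11 = a11 * (1.0 + l)
        b22 = a22 * (1.0 + l)
        det = b11 * b22 - a12**2
        det = np.where(np.abs(det) < 1e-12, 1e-12, det)
        s1 = (b22 * g1 - a12 * g2) / det
        s2 = (b11 * g2 - a12 * g1) / det
        cand = p + np.column_stack([s1, s2])
        new_obj = _objective(cand, xy[idx], rssi[idx], mask[idx], config)
        better = new_obj <= obj[idx]
        pos[idx[better]] = cand[better]
        obj[idx[better]] = new_obj[better]
        lam[idx[better]] *= 0.5
        lam[idx[~better]] *= 10.0
        step = np.hypot(s1, s2)
        done = (better & (step < tol)) | (lam[idx] > 1e8)
        converged[idx[better & (step < tol)]] = True
        active[idx[done]] = False
    return pos, obj, converged


def estimate_positions(
    windowed: pd.DataFrame,
    grid: NodeGrid,
    config: WorldConfig,
    window_s: float = 30.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> pd.DataFrame:
    """Multilaterate every (tag, window) with >= 3 distinct nodes.

    Returns a fix table (see ``FIX_COLUMNS``); windows with fewer than
    three nodes are silently dropped, reproducing the tracking system's
    triangulation requirement.
    """
    if len(windowed) == 0:
        return pd.DataFrame(columns=FIX_COLUMNS)
    node_rows = pd.Index(grid.node_ids).get_indexer(windowed["node_id"])
    if (node_rows < 0).any():
        bad = windowed["node_id"].to_numpy()[node_rows < 0]
        raise ValueError(f"detections reference unknown nodes: {sorted(set(bad))[:5]}")

    df = windowed.sort_values(["tag_id", "window_index"], kind="stable")
    order = df.index.to_numpy()
    node_rows = node_rows[windowed.index.get_indexer(df.index)]
    tag_arr = df["tag_id"].to_numpy()
    win_arr = df["window_index"].to_numpy(np.int64)
    n = len(df)
    new_grp = np.ones(n, bool)
    new_grp[1:] = (tag_arr[1:] != tag_arr[:-1]) | (win_arr[1:] != win_arr[:-1])
    gid = np.cumsum(new_grp) - 1
    counts = np.bincount(gid)
    keep_grp = counts >= 3
    if not keep_grp.any():
        return pd.DataFrame(columns=FIX_COLUMNS)
    m = int(keep_grp.sum())
    kmax = int(counts[keep_grp].max())
    # row position within its group, then scatter into padded arrays
    offsets = np.concatenate([[0], np.cumsum(counts)[:-1]])
    pos_in_grp = np.arange(n) - offsets[gid]
    new_gid = np.cumsum(keep_grp) - 1  # compact index among kept groups
    row_keep = keep_grp[gid]
    gi = new_gid[gid[row_keep]]
    pi = pos_in_grp[row_keep]
    xy = np.zeros((m, kmax, 2))
    rs = np.full((m, kmax), -np.inf)
    mask = np.zeros((m, kmax), bool)
    xy[gi, pi] = grid.xy[node_rows[row_keep]]
    rs[gi, pi] = df["rssi_db"].to_numpy(float)[row_keep]
    mask[gi, pi] = True
    first = np.nonzero(new_grp)[0]
    tags = tag_arr[first[keep_grp]]
    wins = win_arr[first[keep_grp]]
    start = _weighted_centroid(xy, rs, mask)
    start_obj = _objective(start, xy, rs, mask, config)
    pos, obj, conv = _batch_lm(xy, rs, mask, start, config, max_iter=max_iter, tol=tol)
    # never worse than the centroid start; fall back when LM did not converge
    worse = obj > start_obj
    use_centroid = worse | ~conv
    pos[use_centroid] = start[use_centroid]
    obj[use_centroid] = start_obj[use_centroid]
    n_nodes = mask.sum(axis=1)
    return pd.DataFrame(
        {
            "tag_id": tags,
            "window_index": wins,
            "t_mid_s": (wins + 0.5) * window_s,
            "x_m": pos[:, 0],
            "y_m": pos[:, 1],
            "n_nodes": n_nodes,
            "rms_residual_db": np.sqrt(obj / n_nodes),
            "method": np.where(use_centroid, "weighted_centroid", "nls"),
        }
    )


def estimate_position(
    summary: pd.DataFrame,
    grid: NodeGrid,
    config: WorldConfig,
    window_s: float = 30.0,
    max_iter: int = 100,
    tol: float = 1e-6,
) -> PositionFix | None:
    """Multilaterate a single (tag, window) summary; None if < 3 nodes.

    ``summary`` is the slice of :func:`window_detections` output for one
    tag and window.
    """
    if summary["node_id"].nunique() < 3:
        return None
    sub = grid.to_frame().set_index("node_id").loc[summary["node_id"]]
    if len(np.unique(sub[["x_m", "y_m"]].to_numpy(), axis=0)) == 1:
        raise ValueError("degenerate geometry: all contributing nodes coincide")
    fixes = estimate_positions(summary, grid, config, window_s, max_iter, tol)
    if len(fixes) == 0:
        return None
    r = fixes.iloc[0]
    return PositionFix(
        tag_id=r["tag_id"],
        window_index=int(r["window_index"]),
        t_mid=float(r["t_mid_s"]),
        x=float(r["x_m"]),
        y=float(r["y_m"]),
        n_nodes=int(r["n_nodes"]),
        rms_residual=float(r["rms_residual_db"]),
        method=str(r["method"]),
    )


def localize(
    detections: pd.DataFrame,
    grid: NodeGrid,
    config: WorldConfig,
    window_s: float = 30.0,
) -> pd.DataFrame:
    """Full stage: window the raw log, then multilaterate every window."""
    return estimate_positions(window_detections(detections, window_s), grid, config, window_s)


def build_tracks(fixes: pd.DataFrame) -> dict:
    """Split a fix table into per-bird series, gaps preserved.

    Raises on duplicate (tag, window) fixes — upstream must aggregate.
    """
    if fixes.duplicated(["tag_id", "window_index"]).any():
        raise ValueError("duplicate (tag_id, window_index) fixes")
    return {
        tag: g.sort_values("window_index").reset_index(drop=True)
        for tag, g in fixes.groupby("tag_id", sort=True)
    }
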