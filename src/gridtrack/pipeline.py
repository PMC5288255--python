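"""End-to-end orchestration: simulate → localize → metrics → score → analyze.

A single :class:`PipelineConfig` carries every stage's parameters with
defaults reproducing the study design constants: a 40-m triangular grid
of 166 receiver nodes, 5-s beacons, half-minute localization windows,
a 10-m association radius and 60-min pre/post observation windows.

Two trial geometries are available:

* ``global`` — one colony (21 males, 23 females) on the full grid; every
  intrusion session re-simulates all birds.  This is the demo/default.
* ``local`` — each trial simulates only the focal male's neighbourhood
  (a handful of male and female neighbours on a local grid patch).
  Intrusion trials are territories apart, so distant birds never supply
  the closest-neighbour minimum; the local design is what the
  Monte-Carlo power studies use.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import localize as loc
from . import models, scoring, spatial, world

__all__ = ["AnalysisConfig", "PipelineConfig", "run_trial", "run_study", "run_all"]


@dataclass(frozen=True)
class AnalysisConfig:
    """Windowing and network parameters of the analysis stages."""

    window_s: float = 30.0  # localization window
    association_radius_m: float = 10.0
    observation_window_s: float = 3600.0  # pre/post length
    intrusion_duration_s: float = 120.0
    posthoc_gate_p: float = 0.05

    def __post_init__(self) -> None:
        for name in ("window_s", "association_radius_m", "observation_window_s",
                     "intrusion_duration_s"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be > 0")


@dataclass(frozen=True)
class PipelineConfig:
    """Everything one run needs; see module docstring for the defaults' origin."""

    world: world.WorldConfig = field(default_factory=world.WorldConfig)
    analysis: AnalysisConfig = field(default_factory=AnalysisConfig)
    grid_spacing_m: float = 40.0
    n_nodes: int = 166
    grid_jitter_sd_m: float = 3.0
    n_subjects: int = 13
    trial_mode: str = "global"  # or "local"
    n_neighbor_males: int = 3
    n_neighbor_females: int = 3
    seed: int = 0

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "PipelineConfig":
        known_top = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known_top
        if unknown:
            raise ValueError(f"unknown config key(s): {sorted(unknown)}")
        kwargs = dict(raw)
        for section, typ in (("world", world.WorldConfig), ("analysis", AnalysisConfig)):
            if section in kwargs:
                sub = kwargs[section] or {}
                fields = {f.name for f in dataclasses.fields(typ)}
                bad = set(sub) - fields
                if bad:
                    raise ValueError(f"unknown {section} config key(s): {sorted(bad)}")
                kwargs[section] = typ(**sub)
        return cls(**kwargs)

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def config_hash(self) -> str:
        return hashlib.sha256(
            json.dumps(self.to_dict(), sort_keys=True).encode()
        ).hexdigest()[:12]


# --------------------------------------------------------------------------- #
# trial construction
# --------------------------------------------------------------------------- #


def _local_trial_world(
    cfg: PipelineConfig, rng: np.random.Generator
) -> tuple[world.NodeGrid, pd.DataFrame, tuple[float, float]]:
    """A focal neighbourhood: local grid patch, focal + neighbour roster."""
    side = max(9, int(np.ceil(400.0 / cfg.grid_spacing_m)))
    grid = world.generate_grid(
        cfg.grid_spacing_m, side * side, cfg.grid_jitter_sd_m,
        seed=int(rng.integers(2**31 - 1)),
    )
    cx = grid.xy[:, 0].mean()
    cy = grid.xy[:, 1].mean()
    site = (float(cx), float(cy))
    n_m, n_f = cfg.n_neighbor_males, cfg.n_neighbor_females
    ids = np.arange(1 + n_m + n_f)
    sex = np.array(["M"] + ["M"] * n_m + ["F"] * n_f)
    # focal holds the intruded territory; neighbours one-to-two territories out
    ang = rng.uniform(0, 2 * np.pi, n_m + n_f)
    dist = np.concatenate([
        rng.uniform(80.0, 150.0, n_m),
        rng.uniform(60.0, 140.0, n_f),
    ])
    anchors = np.vstack([
        np.array(site) + rng.normal(0.0, 10.0, 2),
        np.column_stack([site[0] + dist * np.cos(ang), site[1] + dist * np.sin(ang)]),
    ])
    tarsus = rng.normal(19.5, 0.8, len(ids))
    weight = -1.5 + 1.0 * tarsus + rng.normal(0.0, 0.8, len(ids))
    mate = np.full(len(ids), -1)
    f_ids = ids[sex == "F"]
    if len(f_ids):
        fa = anchors[sex == "F"]
        j = int(np.argmin(np.hypot(fa[:, 0] - anchors[0, 0], fa[:, 1] - anchors[0, 1])))
        mate[0] = f_ids[j]
        mate[f_ids[j]] = 0
    manifest = pd.DataFrame(
        {
            "bird_id": ids,
            "sex": sex,
            "age_class": np.where(rng.random(len(ids)) < 0.5, "older", "2cy"),
            "weight_g": weight,
            "tarsus_mm": tarsus,
            "mate_id": mate,
            "anchor_x_m": anchors[:, 0],
            "anchor_y_m": anchors[:, 1],
        }
    )
    return grid, manifest, site


def run_trial(
    grid: world.NodeGrid,
    manifest: pd.DataFrame,
    cfg: PipelineConfig,
    scenario: world.IntrusionScenario,
    seed: int,
    bird_ids: np.ndarray | None = None,
) -> tuple[pd.DataFrame, world.TrialData, pd.DataFrame]:
    """One intrusion session through the full chain up to outcome rows.

    Returns (neighbour-response rows, raw trial data, fix table).
    """
    trial_data = world.simulate_trial(grid, manifest, cfg.world, scenario,
                                      seed=seed, bird_ids=bird_ids)
    fixes = loc.localize(trial_data.detections, grid, cfg.world, cfg.analysis.window_s)
    tracks = loc.build_tracks(fixes)
    tw = spatial.TrialWindows(
        focal_id=scenario.focal_id,
        site=scenario.site,
        t_start=scenario.t_start,
        t_end=scenario.t_end,
        length=cfg.analysis.observation_window_s,
    )
    resp = spatial.neighbor_response(
        fixes, tracks, manifest, tw,
        radius=cfg.analysis.association_radius_m,
        window_s=cfg.analysis.window_s,
    )
    return resp, trial_data, fixes


def run_study(
    cfg: PipelineConfig,
    seed: int,
    inject_effect: bool = True,
    keep_artifacts: bool = False,
) -> dict:
    """Simulate a full intrusion study and return every analysis table.

    One playback trial per subject; the focal male's vocal strength (the
    latent driving the six observed response variables) scales the
    neighbourhood movement response when ``inject_effect`` is true.  The
    analysis then proceeds exactly as it would on field data: score the
    response table, compute neighbour outcomes from localized fixes, fit
    the sex-interaction models.
    """
    rng = np.random.default_rng(seed)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        responses = world.simulate_response_table(
            n_subjects=cfg.n_subjects, seed=int(rng.integers(2**31 - 1))
        )
        scored, diagnostics = scoring.score_subjects(responses)

    if cfg.trial_mode == "global":
        grid = world.generate_grid(cfg.grid_spacing_m, cfg.n_nodes,
                                   cfg.grid_jitter_sd_m, seed=int(rng.integers(2**31 - 1)))
        manifest = world.build_manifest(grid, cfg.world, seed=int(rng.integers(2**31 - 1)),
                                        response_table=responses)

    rows = []
    artifacts = {"detections": [], "fixes": []} if keep_artifacts else None
    t_start = cfg.analysis.observation_window_s
    t_end = t_start + cfg.analysis.intrusion_duration_s
    for i in range(cfg.n_subjects):
        if cfg.trial_mode == "local":
            grid, manifest, site = _local_trial_world(cfg, rng)
            focal_id = 0
        else:
            focal_id = int(manifest.loc[manifest["sex"] == "M", "bird_id"].iloc[i])
            frow = manifest.set_index("bird_id").loc[focal_id]
            off = rng.normal(0.0, 10.0, 2)
            site = (float(frow["anchor_x_m"] + off[0]), float(frow["anchor_y_m"] + off[1]))
        vocal = float(responses["latent_q_vocal"].iloc[i]) if inject_effect else 0.0
        scenario = world.IntrusionScenario(
            focal_id=focal_id,
            site=site,
            t_start=t_start,
            t_end=t_end,
            vocal_score=vocal,
            post_window=cfg.analysis.observation_window_s,
        )
        resp, trial_data, fixes = run_trial(
            grid, manifest, cfg, scenario, seed=int(rng.integers(2**31 - 1))
        )
        resp = resp.assign(subject_id=i)
        rows.append(resp)
        if keep_artifacts:
            artifacts["detections"].append(trial_data.detections.assign(trial=i))
            artifacts["fixes"].append(fixes.assign(trial=i))

    neighbor = pd.concat(rows, ignore_index=True)
    model_tab = neighbor.merge(
        scored[["subject_id", "pc1_vocal", "pc2_spatial", "condition_g",
                "n_overlaps", "n_songs_total", "n_songs_during", "sing_duration_s"]],
        on="subject_id",
    )
    model_tab["delta_n_assoc"] = model_tab["n_assoc_post"] - model_tab["n_assoc_pre"]
    model_tab["delta_mean_time_s"] = (
        model_tab["mean_time_post_s"] - model_tab["mean_time_pre_s"]
    )
    out = {
        "responses": responses,
        "scored": scored,
        "diagnostics": diagnostics,
        "neighbor": neighbor,
        "model_table": model_tab,
    }
    if keep_artifacts:
        out["detections"] = pd.concat(artifacts["detections"], ignore_index=True)
        out["fixes"] = pd.concat(artifacts["fixes"], ignore_index=True)
    return out


def analyze(model_tab: pd.DataFrame, cfg: PipelineConfig) -> dict:
    """Fit the three outcome families and (gated) per-sex post hoc slopes."""
    results: dict = {}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        for outcome, rank in (
            ("delta_min_dist_m", False),
            ("delta_n_assoc", False),
            ("delta_mean_time_s", True),
        ):
            tab = model_tab.rename(columns={"subject_id": "focal"})
            spec = models.ModelSpec(
                outcome=outcome, predictor="pc1_vocal", grouping="focal",
                rank_outcome=False,
            )
            try:
                fit = models.fit_sex_interaction(tab, spec)
            except ValueError as e:  # e.g. too few complete subjects
                results[outcome] = {"error": str(e)}
                continue
            flags = models.influence_check(fit.full)
            if rank or flags["flagged"].any():
                spec = dataclasses.replace(spec, rank_outcome=True)
                fit = models.fit_sex_interaction(tab, spec)
                used_rank = True
            else:
                used_rank = False
            entry = {
                "estimate": fit.estimate,
                "se": fit.se,
                "lrt_chi2": fit.lrt_chi2,
                "lrt_p": fit.lrt_p,
                "n_obs": fit.n_obs,
                "n_groups": fit.n_groups,
                "rank_transformed": used_rank,
                "coefficients": {
                    n: {"estimate": float(b), "se": float(s)}
                    for n, b, s in zip(fit.full.names, fit.full.beta, fit.full.se)
                },
            }
            if fit.lrt_p < cfg.analysis.posthoc_gate_p:
                ph = models.posthoc_by_sex(fit, gate_p=None)
                entry["posthoc"] = {
                    "female": {"estimate": ph.female_estimate, "chi2": ph.female_chi2,
                               "p": ph.female_p},
                    "male": {"estimate": ph.male_estimate, "chi2": ph.male_chi2,
                             "p": ph.male_p},
                }
            results[outcome] = entry
    return results


def run_all(cfg: PipelineConfig, outdir: str | Path, seed: int | None = None) -> Path:
    """The one-command pipeline: artifacts + results.json + report.md."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    seed = cfg.seed if seed is None else seed
    study = run_study(cfg, seed=seed, keep_artifacts=True)

    from . import __version__

    log: dict = {
        "package_version": __version__,
        "seed": seed,
        "config_hash": cfg.config_hash(),
        "n_subjects": cfg.n_subjects,
    }
    study["detections"].to_csv(outdir / "detections.csv", index=False)
    study["fixes"].to_csv(outdir / "fixes.csv", index=False)
    study["neighbor"].to_csv(outdir / "neighbor_response.csv", index=False)
    study["scored"].to_csv(outdir / "scored.csv", index=False)
    log["n_detections"] = len(study["detections"])
    log["n_fixes"] = len(study["fixes"])
    n_windows = study["detections"].assign(
        w=(study["detections"]["t_s"] // 30).astype(int)
    ).groupby(["trial", "tag_id", "w"]).ngroups
    log["n_windows_dropped_lt3_nodes"] = int(n_windows - len(study["fixes"]))

    results = analyze(study["model_table"], cfg)
    payload = {
        "log": log,
        "pca_diagnostics": study["diagnostics"],
        "models": results,
        "univariate": univariate_report(study),
    }
    (outdir / "results.json").write_text(json.dumps(payload, indent=2, default=float))
    (outdir / "report.md").write_text(_report_md(payload))
    return outdir


def univariate_report(study: dict) -> dict:
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", UserWarning)
        try:
            return models.univariate_tests(study["scored"], study["neighbor"])
        except ValueError as e:  # e.g. an age class with < 3 subjects
            return {"error": str(e)}


def _report_md(payload: dict) -> str:
    lines = ["# Intrusion-response analysis report", ""]
    log = payload["log"]
    lines += [f"Seed {log['seed']}, config {log['config_hash']}, "
              f"{log['n_subjects']} subjects, {log['n_detections']} detections, "
              f"{log['n_fixes']} fixes "
              f"({log['n_windows_dropped_lt3_nodes']} windows below 3 nodes).", ""]
    d = payload["pca_diagnostics"]
    lines += [
        "## Response scoring",
        f"KMO = {d['kmo']:.2f}; Bartlett chi2({d['bartlett_df']}) = "
        f"{d['bartlett_chi2']:.1f}, p = {d['bartlett_p']:.2g}; "
        f"{d['n_retained']} components retained "
        f"(eigenvalues {', '.join(f'{e:.2f}' for e in d['eigenvalues'][:3])} ...).",
        "",
        "## Sex x vocal-response models",
    ]
    for outcome, m in payload["models"].items():
        if "error" in m:
            lines.append(f"- **{outcome}**: not fitted ({m['error']})")
            continue
        lines.append(
            f"- **{outcome}**: interaction = {m['estimate']:.2f} "
            f"(SE {m['se']:.2f}), LRT chi2(1) = {m['lrt_chi2']:.2f}, "
            f"p = {m['lrt_p']:.3g}"
            + (" [rank-transformed]" if m["rank_transformed"] else "")
        )
        if "posthoc" in m:
            ph = m["posthoc"]
            lines.append(
                f"  - females: {ph['female']['estimate']:.2f} "
                f"(chi2 {ph['female']['chi2']:.2f}, p {ph['female']['p']:.3g}); "
                f"males: {ph['male']['estimate']:.2f} "
                f"(chi2 {ph['male']['chi2']:.2f}, p {ph['male']['p']:.3g})"
            )
    return "\n".join(lines) + "\n"
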