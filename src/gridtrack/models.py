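"""Sex x signal inference on the neighbourhood outcomes.

The central model is a linear mixed model with a random intercept per
focal subject,

    outcome ~ predictor + conspecific_sex + predictor:conspecific_sex
              + (1 | subject),

fitted by maximum likelihood (not REML: the likelihood-ratio test
compares models with different fixed effects).  The sex interaction is
tested by a 1-df LRT against the model without the interaction; when it
is significant, per-sex slopes are obtained as linear contrasts of the
fixed effects with Wald chi-square tests (reference level: female, so
the female slope is the predictor coefficient and the male slope adds
the interaction).

The fitter profiles the likelihood over the variance ratio
``lambda = sigma_b^2 / sigma_e^2``: given lambda, the GLS estimates and
the error variance are closed-form, leaving a 1-D optimization.  This is
exact for the random-intercept model and fast enough for the Monte-Carlo
calibration studies.  Influence diagnostics follow the subject-deletion
convention (Cook's distance by group, threshold 4/N) paired with
standardized conditional residuals (threshold 2).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import optimize, stats

__all__ = [
    "ModelSpec",
    "LMMFit",
    "InteractionFit",
    "PosthocFit",
    "fit_random_intercept",
    "fit_sex_interaction",
    "posthoc_by_sex",
    "influence_check",
    "rank_transform",
    "univariate_tests",
]

OUTCOMES = {"delta_min_dist_m", "delta_n_assoc", "rank_delta_mean_time"}


@dataclass(frozen=True)
class ModelSpec:
    """Which outcome is regressed on which subject-level predictor."""

    outcome: str = "delta_min_dist_m"
    predictor: str = "pc1_vocal"
    grouping: str = "focal_id"
    sex_column: str = "conspecific_sex"
    rank_outcome: bool = False


# --------------------------------------------------------------------------- #
# random-intercept LMM by profiled maximum likelihood
# --------------------------------------------------------------------------- #


@dataclass
class LMMFit:
    """A fitted random-intercept model (ML)."""

    beta: np.ndarray
    cov_beta: np.ndarray
    sigma2_e: float
    sigma2_b: float
    loglik: float
    n_obs: int
    n_groups: int
    singular: bool
    converged: bool
    names: list[str] = field(default_factory=list)
    X: np.ndarray | None = None
    y: np.ndarray | None = None
    group_codes: np.ndarray | None = None

    @property
    def se(self) -> np.ndarray:
        return np.sqrt(np.diag(self.cov_beta))

    def blups(self) -> np.ndarray:
        """Empirical-Bayes random intercepts per group."""
        lam = self.sigma2_b / self.sigma2_e if self.sigma2_e > 0 else 0.0
        resid = self.y - self.X @ self.beta
        ng = np.bincount(self.group_codes)
        sums = np.bincount(self.group_codes, weights=resid)
        return (lam / (1.0 + lam * ng)) * sums

    def conditional_residuals(self) -> np.ndarray:
        return self.y - self.X @ self.beta - self.blups()[self.group_codes]


def _profiled_neg2ll(
    lam: float,
    XtX: np.ndarray,
    Xty: np.ndarray,
    yty: float,
    S: np.ndarray,
    t: np.ndarray,
    ng: np.ndarray,
    n: int,
) -> tuple[float, np.ndarray, float]:
    """-2 log L profiled over beta and sigma_e^2, at variance ratio lam.

    Uses per-group sufficient statistics: S (groups x q) row sums of X,
    t (groups,) sums of y, ng group sizes.
    """
    c = lam / (1.0 + lam * ng)
    A = XtX - (S * c[:, None]).T @ S
    b = Xty - S.T @ (c * t)
    beta = np.linalg.solve(A, b)
    quad = yty - float(c @ t**2)
    rss = quad - float(beta @ b)
    rss = max(rss, 1e-12)
    sigma2 = rss / n
    neg2ll = n * np.log(2.0 * np.pi * sigma2) + float(np.log1p(lam * ng).sum()) + n
    return neg2ll, beta, sigma2


def fit_random_intercept(
    y: np.ndarray,
    X: np.ndarray,
    groups: np.ndarray,
    names: list[str] | None = None,
) -> LMMFit:
    """ML fit of ``y = X beta + b_group + eps`` with scalar random intercepts.

    The likelihood is profiled to a bounded 1-D problem in
    ``log(lambda)``; the boundary ``lambda = 0`` (singular fit, zero
    random-effect variance) is checked explicitly and retained with a
    flag rather than raised.
    """
    y = np.asarray(y, float)
    X = np.asarray(X, float)
    codes, _ = pd.factorize(np.asarray(groups))
    n, q = X.shape
    ng = np.bincount(codes).astype(float)
    XtX = X.T @ X
    Xty = X.T @ y
    yty = float(y @ y)
    k = len(ng)
    S = np.zeros((k, q))
    np.add.at(S, codes, X)
    t = np.bincount(codes, weights=y)

    def f(u: float) -> float:
        return _profiled_neg2ll(np.exp(u), XtX, Xty, yty, S, t, ng, n)[0]

    res = optimize.minimize_scalar(f, bounds=(-12.0, 12.0), method="bounded",
                                   options={"xatol": 1e-10})
    n2_opt = res.fun
    n2_zero, _, _ = _profiled_neg2ll(0.0, XtX, Xty, yty, S, t, ng, n)
    if n2_zero <= n2_opt:
        lam = 0.0
        n2 = n2_zero
    else:
        lam = float(np.exp(res.x))
        n2 = n2_opt
    _, beta, sigma2 = _profiled_neg2ll(lam, XtX, Xty, yty, S, t, ng, n)
    c = lam / (1.0 + lam * ng)
    A = XtX - (S * c[:, None]).T @ S
    cov = sigma2 * np.linalg.inv(A)
    return LMMFit(
        beta=beta,
        cov_beta=cov,
        sigma2_e=sigma2,
        sigma2_b=lam * sigma2,
        loglik=-0.5 * n2,
        n_obs=n,
        n_groups=k,
        singular=(lam == 0.0),
        converged=bool(res.success),
        names=names or [f"b{i}" for i in range(q)],
        X=X,
        y=y,
        group_codes=codes,
    )


# --------------------------------------------------------------------------- #
# the sex-interaction model family
# --------------------------------------------------------------------------- #


@dataclass(frozen=True)
class InteractionFit:
    """Full vs reduced sex-interaction fits and their likelihood-ratio test."""

    spec: ModelSpec
    full: LMMFit
    reduced: LMMFit
    estimate: float  # interaction coefficient (male minus female slope)
    se: float
    lrt_chi2: float
    lrt_p: float
    n_obs: int
    n_groups: int
    clamped: bool = False  # tiny negative chi2 clamped to 0

    @property
    def coefficients(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"estimate": self.full.beta, "se": self.full.se}, index=self.full.names
        )


@dataclass(frozen=True)
class PosthocFit:
    """Per-sex slopes (Wald contrasts on the full model)."""

    female_estimate: float
    female_chi2: float
    female_p: float
    male_estimate: float
    male_chi2: float
    male_p: float


def _design(data: pd.DataFrame, spec: ModelSpec, interaction: bool):
    pred = data[spec.predictor].to_numpy(float)
    sex = data[spec.sex_column].to_numpy()
    if not set(np.unique(sex)) <= {"M", "F"}:
        raise ValueError("conspecific sex must be coded M/F")
    male = (sex == "M").astype(float)  # reference level: female
    cols = [np.ones(len(data)), pred, male]
    names = ["intercept", spec.predictor, "sexM"]
    if interaction:
        cols.append(pred * male)
        names.append(f"{spec.predictor}:sexM")
    return np.column_stack(cols), names


def fit_sex_interaction(data: pd.DataFrame, spec: ModelSpec) -> InteractionFit:
    """Fit outcome ~ predictor * sex + (1 | subject) and LRT the interaction.

    Each subject contributes at most two rows (one per conspecific sex);
    rows with a missing outcome or predictor are dropped listwise.  The
    outcome is optionally rank-transformed (pooled average ranks) before
    fitting, the fallback used when influence diagnostics flag outliers.
    """
    cols = [spec.outcome, spec.predictor, spec.grouping, spec.sex_column]
    d = data[cols].dropna()
    n_dropped = len(data) - len(d)
    if n_dropped:
        warnings.warn(
            f"{n_dropped} incomplete row(s) dropped listwise", UserWarning, stacklevel=2
        )
    if d.groupby([spec.grouping, spec.sex_column]).size().max() > 1:
        raise ValueError("each subject may contribute at most one row per conspecific sex")
    if d[spec.grouping].nunique() < 5:
        raise ValueError("need >= 5 subjects")
    y = d[spec.outcome].to_numpy(float)
    if spec.rank_outcome:
        y = rank_transform(y)
    groups = d[spec.grouping].to_numpy()
    Xf, names_f = _design(d, spec, interaction=True)
    Xr, names_r = _design(d, spec, interaction=False)
    full = fit_random_intercept(y, Xf, groups, names_f)
    reduced = fit_random_intercept(y, Xr, groups, names_r)
    chi2 = 2.0 * (full.loglik - reduced.loglik)
    clamped = chi2 < 0
    if clamped and chi2 < -1e-4:
        warnings.warn(
            f"LRT chi2 = {chi2:.3g} < 0 beyond optimizer noise", RuntimeWarning, stacklevel=2
        )
    chi2 = max(chi2, 0.0)
    return InteractionFit(
        spec=spec,
        full=full,
        reduced=reduced,
        estimate=float(full.beta[3]),
        se=float(full.se[3]),
        lrt_chi2=chi2,
        lrt_p=float(stats.chi2.sf(chi2, 1)),
        n_obs=full.n_obs,
        n_groups=full.n_groups,
        clamped=clamped,
    )


def posthoc_by_sex(fit: InteractionFit, gate_p: float | None = 0.05) -> PosthocFit:
    """Per-sex slopes from the interaction fit, gated on the LRT.

    With female as the reference level, the female slope is the
    predictor coefficient and the male slope is predictor + interaction.
    ``gate_p=None`` disables the significance gate.
    """
    if gate_p is not None and fit.lrt_p >= gate_p:
        raise ValueError(
            f"post hoc requested but interaction LRT p = {fit.lrt_p:.3f} >= {gate_p}"
        )
    beta, cov = fit.full.beta, fit.full.cov_beta
    cf = np.array([0.0, 1.0, 0.0, 0.0])
    cm = np.array([0.0, 1.0, 0.0, 1.0])
    out = {}
    for label, c in (("female", cf), ("male", cm)):
        est = float(c @ beta)
        var = float(c @ cov @ c)
        chi2 = est**2 / var
        out[label] = (est, chi2, float(stats.chi2.sf(chi2, 1)))
    return PosthocFit(
        female_estimate=out["female"][0],
        female_chi2=out["female"][1],
        female_p=out["female"][2],
        male_estimate=out["male"][0],
        male_chi2=out["male"][1],
        male_p=out["male"][2],
    )


def influence_check(fit: LMMFit, threshold_resid: float = 2.0) -> pd.DataFrame:
    """Flag rows with large standardized residuals in influential subjects.

    Cook's distance is computed at the group (subject) level by deleting
    each subject and refitting: ``D_g = (beta - beta_(-g))' Cov(beta)^{-1}
    (beta - beta_(-g)) / q``, thresholded at ``4 / n_groups`` (strict).
    A row is flagged iff its |standardized conditional residual| exceeds
    ``threshold_resid`` AND its subject's Cook's D exceeds the threshold.
    """
    resid = fit.conditional_residuals()
    std_resid = resid / np.sqrt(fit.sigma2_e)
    q = len(fit.beta)
    cov_inv = np.linalg.inv(fit.cov_beta)
    cooks = np.zeros(fit.n_groups)
    for g in range(fit.n_groups):
        keep = fit.group_codes != g
        sub = fit_random_intercept(fit.y[keep], fit.X[keep], fit.group_codes[keep])
        db = fit.beta - sub.beta
        cooks[g] = float(db @ cov_inv @ db) / q
    thresh_d = 4.0 / fit.n_groups
    flagged = (np.abs(std_resid) > threshold_resid) & (cooks[fit.group_codes] > thresh_d)
    return pd.DataFrame(
        {
            "row": np.arange(fit.n_obs),
            "group": fit.group_codes,
            "std_residual": std_resid,
            "cooks_d_group": cooks[fit.group_codes],
            "flagged": flagged,
        }
    )


def rank_transform(values: np.ndarray) -> np.ndarray:
    """Average ranks (ties shared), NaNs excluded and returned as NaN."""
    v = np.asarray(values, float)
    if v.size == 0:
        raise ValueError("cannot rank an empty array")
    out = np.full(v.shape, np.nan)
    ok = ~np.isnan(v)
    out[ok] = stats.rankdata(v[ok], method="average")
    return out


# --------------------------------------------------------------------------- #
# univariate tests
# --------------------------------------------------------------------------- #


def welch_t(x: np.ndarray, y: np.ndarray) -> dict:
    """Welch's unequal-variance t test with Welch–Satterthwaite df."""
    x, y = np.asarray(x, float), np.asarray(y, float)
    if len(x) < 3 or len(y) < 3:
        raise ValueError("need >= 3 observations per group")
    res = stats.ttest_ind(x, y, equal_var=False)
    return {"t": float(res.statistic), "df": float(res.df), "p": float(res.pvalue)}


def paired_wilcoxon(pre: np.ndarray, post: np.ndarray) -> dict:
    """Paired Wilcoxon signed-rank with normal-approximation Z.

    All-zero differences yield Z = 0 (with a warning) rather than an
    error, mirroring the degenerate no-change case.
    """
    pre, post = np.asarray(pre, float), np.asarray(post, float)
    ok = ~(np.isnan(pre) | np.isnan(post))
    d = post[ok] - pre[ok]
    if np.all(d == 0):
        warnings.warn("all paired differences are zero; Z = 0", UserWarning, stacklevel=2)
        return {"z": 0.0, "p": 1.0, "n": int(ok.sum())}
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.wilcoxon(d, method="approx", correction=False)
    z = float(abs(res.zstatistic))
    return {"z": z, "p": float(res.pvalue), "n": int(ok.sum())}


def univariate_tests(
    scored: pd.DataFrame, neighbor: pd.DataFrame | None = None
) -> dict:
    """The battery of simple tests on scored subjects and network outcomes.

    Per vocal/spatial score and response variable: Welch t across age
    classes and Pearson correlation with body condition (Spearman for an
    ``exploration`` column if present).  If a neighbour-response table is
    given, paired Wilcoxon signed-rank tests compare pre vs post
    associate counts and mean association times per conspecific sex.
    """
    report: dict = {"age": {}, "condition": {}, "exploration": {}, "network": {}}
    targets = [c for c in ("pc1_vocal", "pc2_spatial", "n_overlaps", "n_songs_total",
                           "n_songs_during", "sing_duration_s", "time_within_5m_s")
               if c in scored.columns]
    young = scored["age_class"] == "2cy"
    for col in targets:
        v = scored[col].to_numpy(float)
        report["age"][col] = welch_t(v[young.to_numpy()], v[~young.to_numpy()])
        r, p = stats.pearsonr(scored["condition_g"], scored[col])
        report["condition"][col] = {"r": float(r), "p": float(p), "n": len(scored)}
        if "exploration" in scored.columns:
            rs, ps = stats.spearmanr(scored["exploration"], scored[col])
            report["exploration"][col] = {"r_s": float(rs), "p": float(ps)}
    if neighbor is not None:
        for sex in ("M", "F"):
            sub = neighbor[neighbor["conspecific_sex"] == sex]
            report["network"][sex] = {
                "n_associates": paired_wilcoxon(sub["n_assoc_pre"], sub["n_assoc_post"]),
                "mean_assoc_time": paired_wilcoxon(
                    sub["mean_time_pre_s"], sub["mean_time_post_s"]
                ),
            }
    return report
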