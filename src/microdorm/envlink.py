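"""Environment–community linkage procedures.

Covariate groups that are strongly collinear are collapsed to their first
principal component ("index variables", e.g. a soil-organic-matter index
from total organic carbon, cation exchange capacity and calcium). A
pluggable tree-ensemble regressor screens covariate importance with
permutation importance and partial-dependence curves; a first-difference
scan of the partial-dependence curve localizes threshold responses. Scale
dependence of a linear association is tested by comparing a common-slope
model against a per-site-slope model with a likelihood ratio, and presence
of a taxon group is modeled with a logistic GLM.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats as sps

from .model import EnvMatrix, SampleMetadata, ValidationError


# ---------------------------------------------------------------------------
# covariate collapsing
# ---------------------------------------------------------------------------

@dataclass
class IndexVariable:
    name: str
    member_covariates: list[str]
    loadings: np.ndarray
    scores: pd.Series
    variance_explained: float


def collapse_covariates(
    env: EnvMatrix, groups: dict[str, list[str]]
) -> tuple[EnvMatrix, dict[str, IndexVariable]]:
    """Replace each named covariate group by its first principal component.

    Members are standardized before the PCA; the index's sign is fixed so
    that it correlates positively with the group's first-named member.
    Scores have zero mean and unit variance.
    """
    df = env.data.copy()
    indices: dict[str, IndexVariable] = {}
    for name, members in groups.items():
        if len(members) < 2:
            raise ValidationError(f"index group {name!r} needs >= 2 covariates")
        missing = [m for m in members if m not in df.columns]
        if missing:
            raise ValidationError(f"covariates not in EnvMatrix: {missing}")
        x = df[members].to_numpy(dtype=float)
        sd = x.std(axis=0, ddof=1)
        if (sd == 0).any():
            const = [m for m, s in zip(members, sd) if s == 0]
            raise ValidationError(f"constant covariate(s) in group {name!r}: {const}")
        z = (x - x.mean(axis=0)) / sd
        # PCA via SVD of the standardized matrix
        u, s, vt = np.linalg.svd(z, full_matrices=False)
        loadings = vt[0]
        scores = z @ loadings
        if np.corrcoef(scores, z[:, 0])[0, 1] < 0:
            loadings, scores = -loadings, -scores
        var_explained = float(s[0] ** 2 / (s**2).sum())
        scores = (scores - scores.mean()) / scores.std(ddof=1)
        df = df.drop(columns=members)
        df[name] = scores
        indices[name] = IndexVariable(
            name=name,
            member_covariates=list(members),
            loadings=loadings,
            scores=pd.Series(scores, index=env.data.index),
            variance_explained=var_explained,
        )
    return EnvMatrix(df), indices


# ---------------------------------------------------------------------------
# importance screening and partial dependence
# ---------------------------------------------------------------------------

@dataclass
class ImportanceReport:
    importances: pd.DataFrame        # mean, sd over repeats; covariates ranked
    pd_curves: dict[str, pd.DataFrame]  # covariate -> grid/value curve
    n_plots: int


def _default_regressor(seed: int):
    from sklearn.ensemble import RandomForestRegressor

    return RandomForestRegressor(n_estimators=300, random_state=seed)


def aggregate_response(
    response: pd.Series, meta: SampleMetadata | pd.DataFrame, env: EnvMatrix
) -> tuple[np.ndarray, np.ndarray, pd.DataFrame]:
    """Mean response per plot, joined to the plot-level covariates."""
    design = meta.data if isinstance(meta, SampleMetadata) else meta
    design = design.loc[[s for s in response.index if s in design.index]]
    resp = response.loc[design.index]
    per_plot = (
        pd.DataFrame({"y": resp, "site": design["site"].astype(str),
                      "plot": design["plot"].astype(str)})
        .groupby(["site", "plot"], observed=True)["y"].mean()
    )
    envdf = env.data.copy()
    envdf["site"] = envdf["site"].astype(str)
    envdf["plot"] = envdf["plot"].astype(str)
    merged = envdf.set_index(["site", "plot"]).join(per_plot, how="inner").dropna(subset=["y"])
    if merged.empty:
        raise ValidationError("no plots shared between response and EnvMatrix")
    x = merged[env.covariates].to_numpy(dtype=float)
    y = merged["y"].to_numpy(dtype=float)
    return x, y, merged


def screen_importance(
    response: pd.Series,
    env: EnvMatrix,
    meta: SampleMetadata | pd.DataFrame,
    regressor=None,
    n_repeats: int = 10,
    seed: int = 0,
    pd_grid_size: int = 50,
) -> ImportanceReport:
    """Permutation importance + partial-dependence curves for each covariate.

    The response (per sample) is averaged to plot level before regression.
    The regressor only needs ``fit``/``predict``; the default is a random
    forest. Partial-dependence grids span the 2.5th–97.5th covariate
    percentiles so edge extrapolation does not dominate the threshold search.
    """
    x, y, merged = aggregate_response(response, meta, env)
    covariates = env.covariates
    if x.shape[0] < len(covariates) and regressor is None:
        raise ValidationError(
            f"{x.shape[0]} plots for {len(covariates)} covariates: supply a "
            "regularizing regressor"
        )
    reg = regressor if regressor is not None else _default_regressor(seed)
    reg.fit(x, y)

    rng = np.random.default_rng(seed)
    base_mse = float(np.mean((y - reg.predict(x)) ** 2))
    rows = []
    for j, cov in enumerate(covariates):
        drops = []
        for _ in range(n_repeats):
            xp = x.copy()
            xp[:, j] = xp[rng.permutation(len(y)), j]
            drops.append(float(np.mean((y - reg.predict(xp)) ** 2)) - base_mse)
        rows.append({"covariate": cov, "importance": np.mean(drops), "sd": np.std(drops, ddof=1)})
    imp = (
        pd.DataFrame(rows).set_index("covariate").sort_values("importance", ascending=False)
    )
    imp["rank"] = np.arange(1, len(imp) + 1)

    curves = {}
    for j, cov in enumerate(covariates):
        lo, hi = np.percentile(x[:, j], [2.5, 97.5])
        grid = np.linspace(lo, hi, pd_grid_size)
        vals = np.empty(pd_grid_size)
        for k, gv in enumerate(grid):
            xg = x.copy()
            xg[:, j] = gv
            vals[k] = float(reg.predict(xg).mean())
        curves[cov] = pd.DataFrame({"grid": grid, "value": vals})
    return ImportanceReport(importances=imp, pd_curves=curves, n_plots=len(y))


def locate_threshold(
    grid: np.ndarray, values: np.ndarray, min_jump: float = 0.1
) -> tuple[float, float] | None:
    """Locate a threshold response in a partial-dependence curve.

    Returns the grid interval containing the largest absolute first
    difference when that difference exceeds ``min_jump`` times the IQR of
    the curve values; otherwise None (no threshold).
    """
    grid = np.asarray(grid, dtype=float)
    values = np.asarray(values, dtype=float)
    if len(grid) < 3:
        raise ValidationError("locate_threshold needs >= 3 grid points")
    if np.any(np.diff(grid) <= 0):
        raise ValidationError("grid must be strictly increasing")
    diffs = np.abs(np.diff(values))
    iqr = float(np.subtract(*np.percentile(values, [75, 25])))
    if iqr == 0:
        return None
    k = int(np.argmax(diffs))
    if diffs[k] <= min_jump * iqr:
        return None
    return (float(grid[k]), float(grid[k + 1]))


# ---------------------------------------------------------------------------
# scale dependence
# ---------------------------------------------------------------------------

@dataclass
class ScaleDependenceResult:
    pooled_slope: float
    per_site_slopes: pd.Series
    lrt_statistic: float
    df: int
    p: float
    scale_dependent: bool


def scale_dependence_test(
    response: pd.Series,
    covariate: pd.Series,
    site: pd.Series,
    alpha: float = 0.05,
) -> ScaleDependenceResult:
    """Likelihood-ratio test of per-site slopes against a common slope.

    Model A: site intercepts + one pooled slope. Model B: site intercepts +
    one slope per site. Both are Gaussian least-squares fits; the reported
    LRT statistic is 2(lB - lA) = n log(RSS_A / RSS_B) with
    (n_sites - 1) degrees of freedom. The p-value comes from the exact
    finite-sample F reference for this nested Gaussian comparison (the
    monotone transform of the LRT), because the asymptotic chi-squared
    reference is anticonservative at typical plot counts. A significant
    result indicates the within-site and among-site associations differ.
    """
    df = pd.DataFrame({"y": response, "x": covariate, "site": site.astype(str)}).dropna()
    sites = df["site"].unique()
    if len(sites) < 2:
        raise ValidationError("scale_dependence_test needs >= 2 sites")
    for s in sites:
        sub = df[df["site"] == s]
        if len(sub) < 3:
            raise ValidationError(f"site {s!r} has fewer than 3 observations")
        if sub["x"].nunique() < 2:
            raise ValidationError(f"covariate is constant within site {s!r}")

    n = len(df)
    intercepts = pd.get_dummies(df["site"]).to_numpy(float)
    x = df["x"].to_numpy(float)
    y = df["y"].to_numpy(float)

    xa = np.hstack([intercepts, x[:, None]])
    xb = np.hstack([intercepts, intercepts * x[:, None]])
    beta_a, _, _, _ = np.linalg.lstsq(xa, y, rcond=None)
    beta_b, _, _, _ = np.linalg.lstsq(xb, y, rcond=None)
    rss_a = float(((y - xa @ beta_a) ** 2).sum())
    rss_b = float(((y - xb @ beta_b) ** 2).sum())
    lrt = max(0.0, n * np.log(rss_a / max(rss_b, 1e-300)))
    ddf = len(sites) - 1
    p_b = xb.shape[1]
    df_resid = n - p_b
    if df_resid < 1:
        raise ValidationError("no residual degrees of freedom for the per-site-slope model")
    f_stat = ((rss_a - rss_b) / ddf) / (rss_b / df_resid)
    p = float(sps.f.sf(max(f_stat, 0.0), ddf, df_resid))
    return ScaleDependenceResult(
        pooled_slope=float(beta_a[-1]),
        per_site_slopes=pd.Series(beta_b[len(sites):], index=sorted(sites)),
        lrt_statistic=float(lrt),
        df=ddf,
        p=p,
        scale_dependent=p < alpha,
    )


# ---------------------------------------------------------------------------
# logistic presence model
# ---------------------------------------------------------------------------

@dataclass
class PresenceGlmResult:
    intercept: float
    slope: float
    slope_ci: tuple[float, float]
    p: float
    separation: bool
    curve: pd.DataFrame  # grid, probability
    converged: bool = True


def presence_glm(
    presence: pd.Series,
    covariate: pd.Series,
    block: pd.Series | None = None,
    grid_size: int = 100,
) -> PresenceGlmResult:
    """Logistic regression of presence/absence on a covariate.

    Fit by IRLS (statsmodels binomial GLM). Complete separation is detected
    (single-covariate threshold check plus diverging coefficients) and
    flagged; no Wald inference is reported for separated fits.
    """
    import statsmodels.api as sm

    df = pd.DataFrame({"y": presence.astype(float), "x": covariate}).dropna()
    if block is not None:
        df["block"] = block.loc[df.index].astype(str)
    y = df["y"].to_numpy()
    if len(np.unique(y)) < 2:
        raise ValidationError("presence outcome has a single class")
    if df["x"].nunique() < 2:
        raise ValidationError("covariate is constant: slope inestimable")

    x0, x1 = df.loc[df["y"] == 0, "x"], df.loc[df["y"] == 1, "x"]
    separated = bool(x0.max() < x1.min() or x1.max() < x0.min())

    cols = [np.ones(len(df)), df["x"].to_numpy(float)]
    names = ["intercept", "x"]
    if block is not None:
        dummies = pd.get_dummies(df["block"], drop_first=True)
        for c in dummies.columns:
            cols.append(dummies[c].to_numpy(float))
            names.append(f"block[{c}]")
    xmat = np.column_stack(cols)

    model = sm.GLM(y, xmat, family=sm.families.Binomial())
    converged = True
    try:
        fit = model.fit(maxiter=100)
        converged = bool(fit.converged)
    except Exception:
        fit = None
        converged = False
    if fit is not None and (not converged or np.abs(fit.params[1]) > 50):
        separated = True

    grid = np.linspace(df["x"].min(), df["x"].max(), grid_size)
    if fit is not None:
        b0, b1 = float(fit.params[0]), float(fit.params[1])
        prob = 1.0 / (1.0 + np.exp(-(b0 + b1 * grid)))
        if separated:
            ci, p = (np.nan, np.nan), np.nan
        else:
            se = float(fit.bse[1])
            ci = (b1 - 1.959963984540054 * se, b1 + 1.959963984540054 * se)
            p = float(fit.pvalues[1])
    else:
        b0, b1, ci, p, prob = np.nan, np.nan, (np.nan, np.nan), np.nan, np.full(grid_size, np.nan)
    return PresenceGlmResult(
        intercept=b0,
        slope=b1,
        slope_ci=ci,
        p=p,
        separation=separated,
        curve=pd.DataFrame({"grid": grid, "probability": prob}),
        converged=converged,
    )


# ---------------------------------------------------------------------------
# dormancy–environment linkage
# ---------------------------------------------------------------------------

@dataclass
class DormancyEnvReport:
    importance: ImportanceReport
    associations: pd.DataFrame  # per covariate: slope, p, sign; scale dependence


def dormancy_env_link(
    profile: pd.DataFrame,
    env: EnvMatrix,
    meta: SampleMetadata | pd.DataFrame,
    regressor=None,
    seed: int = 0,
) -> DormancyEnvReport:
    """Link per-pair dormant fractions to environmental covariates.

    Runs the importance screen with the dormant fraction as response, then a
    per-covariate linear association (slope, t-test p) and — where the
    design allows — the scale-dependence LRT.
    """
    frac = profile["dormant_fraction"].dropna()
    if frac.empty:
        raise ValidationError("all dormant fractions are undefined")
    design = meta.data if isinstance(meta, SampleMetadata) else meta
    # map pair ids to a metadata row (either assay; design fields are shared)
    pair_rows = design.drop_duplicates(subset=["pair_id"]).set_index("pair_id")
    common = [p for p in frac.index if p in pair_rows.index]
    if not common:
        raise ValidationError("no pair ids shared between profile and metadata")
    frac = frac.loc[common]
    pair_meta = pair_rows.loc[common]

    imp = screen_importance(
        frac, env, pair_meta, regressor=regressor, seed=seed
    )
    x, y, merged = aggregate_response(frac, pair_meta, env)
    merged = merged.reset_index()
    rows = []
    for cov in env.covariates:
        res = sps.linregress(merged[cov].to_numpy(float), y)
        row = {
            "covariate": cov,
            "slope": res.slope,
            "p": res.pvalue,
            "sign": "positive" if res.slope > 0 else "negative",
        }
        try:
            sd = scale_dependence_test(
                pd.Series(y), pd.Series(merged[cov].to_numpy(float)), merged["site"]
            )
            row["scale_dependent"] = sd.scale_dependent
            row["lrt_p"] = sd.p
        except ValidationError:
            row["scale_dependent"] = np.nan
            row["lrt_p"] = np.nan
        rows.append(row)
    assoc = pd.DataFrame(rows).set_index("covariate")
    return DormancyEnvReport(importance=imp, associations=assoc)
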