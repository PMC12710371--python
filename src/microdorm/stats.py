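"""Permutational community-ecology statistics.

All procedures here operate on a :class:`skbio.stats.distance.DistanceMatrix`
(symmetric, zero-diagonal, id-indexed) and are implemented natively:

* Bray–Curtis dissimilarity  d(i,j) = sum|x-y| / sum(x+y)
* Shannon diversity (nats)
* principal-coordinates analysis (classical scaling)
* PERMANOVA with sequential (Type-I) sums of squares over an ordered term
  list, free or within-strata permutations
* multivariate homogeneity of group dispersions (distance to group centroid
  in PCoA space with the negative-eigenvalue correction) with a permutation
  F-test
* Mantel and partial Mantel tests, and the distance-decay analysis built on
  them.

Permutation p-values are reported as (b + 1) / (m + 1) where b counts
permutation statistics at least as extreme as the observed one.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats as sps
from scipy.spatial.distance import squareform
from skbio.stats.distance import DistanceMatrix

from .model import ValidationError


# ---------------------------------------------------------------------------
# distances and diversity
# ---------------------------------------------------------------------------

def bray_curtis(matrix) -> DistanceMatrix:
    """Bray–Curtis dissimilarities between the columns (samples) of a
    non-negative abundance matrix."""
    df = pd.DataFrame(matrix) if not isinstance(matrix, pd.DataFrame) else matrix
    x = df.to_numpy(dtype=float)
    if (x < 0).any():
        raise ValidationError("Bray–Curtis requires non-negative abundances")
    col_sums = x.sum(axis=0)
    if (col_sums == 0).sum() >= 1 and len(col_sums) > 1:
        zeros = [str(c) for c, s in zip(df.columns, col_sums) if s == 0]
        raise ValidationError(f"all-zero sample(s) make Bray–Curtis undefined: {zeros}")
    # sum|x-y| = sum(x+y) - 2*sum(min(x,y)); vectorized via the min trick
    n = x.shape[1]
    d = np.zeros((n, n))
    for i in range(n):
        mins = np.minimum(x[:, i][:, None], x[:, i + 1 :]).sum(axis=0)
        tots = col_sums[i] + col_sums[i + 1 :]
        d[i, i + 1 :] = 1.0 - 2.0 * mins / tots
    d = d + d.T
    return DistanceMatrix(d, ids=[str(c) for c in df.columns])


def shannon(counts) -> float:
    """Shannon diversity H = -sum p ln p (nats) of one sample."""
    x = np.asarray(counts, dtype=float)
    if (x < 0).any():
        raise ValidationError("counts must be non-negative")
    total = x.sum()
    if total == 0:
        raise ValidationError("Shannon diversity undefined for an all-zero sample")
    p = x[x > 0] / total
    return float(-(p * np.log(p)).sum())


# ---------------------------------------------------------------------------
# ordination
# ---------------------------------------------------------------------------

@dataclass
class OrdinationResult:
    coordinates: pd.DataFrame      # samples x axes (positive-eigenvalue axes)
    eigenvalues: np.ndarray        # positive eigenvalues, descending
    proportion_explained: np.ndarray
    negative_eigenvalues: np.ndarray  # diagnostic: discarded negative part


def _gower_center(d2: np.ndarray) -> np.ndarray:
    n = d2.shape[0]
    j = np.eye(n) - np.ones((n, n)) / n
    return -0.5 * j @ d2 @ j


def pcoa(dm: DistanceMatrix) -> OrdinationResult:
    """Classical scaling of the Gower-centered squared-distance matrix.

    Axes with negative eigenvalues (non-Euclidean distances) are reported as
    a diagnostic and dropped from the coordinates.
    """
    n = dm.shape[0]
    if n < 3:
        raise ValidationError("PCoA requires at least 3 samples")
    g = _gower_center(dm.data**2)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = max(1e-10, 1e-10 * abs(eigvals[0])) if n else 1e-10
    pos = eigvals > tol
    neg = eigvals < -tol
    coords = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    total = eigvals[pos].sum()
    prop = eigvals[pos] / total if total > 0 else eigvals[pos]
    cols = [f"PC{i+1}" for i in range(coords.shape[1])]
    return OrdinationResult(
        coordinates=pd.DataFrame(coords, index=list(dm.ids), columns=cols),
        eigenvalues=eigvals[pos],
        proportion_explained=prop,
        negative_eigenvalues=eigvals[neg],
    )


# ---------------------------------------------------------------------------
# PERMANOVA
# ---------------------------------------------------------------------------

@dataclass
class PermanovaResult:
    table: pd.DataFrame  # rows: terms, Residual, Total; cols: df, SS, R2, F, p
    n_permutations: int
    seed: int

    def r2(self, term: str) -> float:
        return float(self.table.loc[term, "R2"])

    def p(self, term: str) -> float:
        return float(self.table.loc[term, "p"])


def _model_columns(design: pd.DataFrame, term: str) -> np.ndarray:
    col = design[term]
    if pd.api.types.is_numeric_dtype(col):
        return col.to_numpy(dtype=float)[:, None]
    dummies = pd.get_dummies(col.astype(str), drop_first=True)
    if dummies.shape[1] == 0:
        raise ValidationError(f"term {term!r} has a single level")
    return dummies.to_numpy(dtype=float)


def _hat(x: np.ndarray) -> tuple[np.ndarray, int]:
    """Orthogonal projector onto the column space of x and its rank."""
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(1.0, diag.max())).sum())
    q = q[:, :rank]
    return q @ q.T, rank


def permanova(
    dm: DistanceMatrix,
    design: pd.DataFrame,
    terms: list[str],
    n_perm: int = 999,
    seed: int = 0,
    strata: str | None = None,
) -> PermanovaResult:
    """Permutational MANOVA with sequential (Type-I) sums of squares.

    Terms are fit in the order given; each term's sum of squares is the
    increment in explained (Gower-centered) squared distance over the model
    containing the preceding terms. Permutations shuffle the sample rows of
    the design, freely or within the levels of ``strata``.
    """
    if n_perm < 1:
        raise ValidationError("n_perm must be >= 1")
    design = design.loc[list(dm.ids)]
    for term in terms:
        col = design[term]
        if not pd.api.types.is_numeric_dtype(col) and col.nunique() < 2:
            raise ValidationError(f"term {term!r} has a single level")

    g = _gower_center(dm.data**2)
    n = g.shape[0]
    ss_total = float(np.trace(g))

    def term_stats(perm: np.ndarray):
        """Sequential term SS and F for a row permutation of the design."""
        x = np.ones((n, 1))
        h_prev, rank_prev = _hat(x)
        ss_terms, dfs = [], []
        for term in terms:
            cols = _model_columns(design, term)[perm]
            x = np.hstack([x, cols])
            h, rank = _hat(x)
            ss_terms.append(float(np.sum(h * g.T)) - float(np.sum(h_prev * g.T)))
            dfs.append(rank - rank_prev)
            h_prev, rank_prev = h, rank
        ss_model = float(np.sum(h_prev * g.T))
        ss_res = ss_total - ss_model
        df_res = n - rank_prev
        # a numerically zero residual (perfect separation) gives an infinite F
        degenerate = ss_res <= 1e-10 * max(ss_total, 1e-300)
        fs = [
            np.nan
            if df_t == 0 or df_res == 0
            else (np.inf if degenerate and ss_t > 0 else (ss_t / df_t) / (ss_res / df_res))
            for ss_t, df_t in zip(ss_terms, dfs)
        ]
        return np.array(ss_terms), np.array(dfs), ss_res, df_res, np.array(fs)

    identity = np.arange(n)
    ss_terms, dfs, ss_res, df_res, f_obs = term_stats(identity)

    rng = np.random.default_rng(seed)
    if strata is not None:
        groups = design[strata].to_numpy()
        group_idx = [np.flatnonzero(groups == gval) for gval in pd.unique(groups)]

    exceed = np.zeros(len(terms))
    for _ in range(n_perm):
        if strata is None:
            perm = rng.permutation(n)
        else:
            perm = identity.copy()
            for idx in group_idx:
                perm[idx] = idx[rng.permutation(len(idx))]
        _, _, _, _, f_perm = term_stats(perm)
        exceed += f_perm >= f_obs - 1e-12
    pvals = (exceed + 1) / (n_perm + 1)

    rows = {}
    for i, term in enumerate(terms):
        rows[term] = [dfs[i], ss_terms[i], ss_terms[i] / ss_total, f_obs[i], pvals[i]]
    rows["Residual"] = [df_res, ss_res, ss_res / ss_total, np.nan, np.nan]
    rows["Total"] = [n - 1, ss_total, 1.0, np.nan, np.nan]
    table = pd.DataFrame.from_dict(
        rows, orient="index", columns=["df", "SS", "R2", "F", "p"]
    )
    return PermanovaResult(table=table, n_permutations=n_perm, seed=seed)


# ---------------------------------------------------------------------------
# beta dispersion
# ---------------------------------------------------------------------------

@dataclass
class BetaDispersionResult:
    distances: pd.Series          # per-sample distance to its group centroid
    group_means: pd.Series
    f_statistic: float
    p: float
    n_permutations: int
    seed: int


def beta_dispersion(
    dm: DistanceMatrix,
    groups: pd.Series,
    n_perm: int = 999,
    seed: int = 0,
) -> BetaDispersionResult:
    """Multivariate homogeneity of group dispersions.

    Each sample's dispersion is its distance to its group centroid in the
    full PCoA space, correcting for non-Euclidean distances by subtracting
    the squared distance along negative-eigenvalue axes. Group differences
    are tested by a one-way F statistic on those distances with a label
    permutation reference.
    """
    groups = pd.Series(groups).loc[list(dm.ids)]
    sizes = groups.value_counts()
    singletons = sizes[sizes < 2]
    if len(singletons):
        warnings.warn(f"excluding singleton group(s): {list(singletons.index)}", stacklevel=2)
        keep = groups.isin(sizes[sizes >= 2].index)
        dm = dm.filter([i for i, k in zip(dm.ids, keep) if k])
        groups = groups[keep]
    if groups.nunique() < 2:
        raise ValidationError("beta_dispersion needs >= 2 groups with >= 2 members")

    g = _gower_center(dm.data**2)
    eigvals, eigvecs = np.linalg.eigh(g)
    order = np.argsort(eigvals)[::-1]
    eigvals, eigvecs = eigvals[order], eigvecs[:, order]
    tol = 1e-10 * max(1.0, abs(eigvals).max())
    pos, neg = eigvals > tol, eigvals < -tol
    c_pos = eigvecs[:, pos] * np.sqrt(eigvals[pos])
    c_neg = eigvecs[:, neg] * np.sqrt(-eigvals[neg])

    z = np.empty(len(groups))
    for gval in groups.unique():
        idx = np.flatnonzero(groups.to_numpy() == gval)
        cen_pos = c_pos[idx].mean(axis=0)
        cen_neg = c_neg[idx].mean(axis=0) if c_neg.shape[1] else np.zeros(0)
        d2 = ((c_pos[idx] - cen_pos) ** 2).sum(axis=1)
        if c_neg.shape[1]:
            d2 = d2 - ((c_neg[idx] - cen_neg) ** 2).sum(axis=1)
        z[idx] = np.sqrt(np.maximum(d2, 0.0))

    labels = groups.to_numpy()

    def anova_f(zvals: np.ndarray) -> float:
        grand = zvals.mean()
        ss_b = sum(
            len(idx := np.flatnonzero(labels == gval)) * (zvals[idx].mean() - grand) ** 2
            for gval in np.unique(labels)
        )
        ss_w = sum(
            ((zvals[idx := np.flatnonzero(labels == gval)] - zvals[idx].mean()) ** 2).sum()
            for gval in np.unique(labels)
        )
        k = len(np.unique(labels))
        if ss_w == 0:
            return np.inf if ss_b > 0 else 0.0
        return (ss_b / (k - 1)) / (ss_w / (len(zvals) - k))

    f_obs = anova_f(z)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        if anova_f(z[rng.permutation(len(z))]) >= f_obs - 1e-12:
            exceed += 1
    p = (exceed + 1) / (n_perm + 1)

    dist = pd.Series(z, index=list(dm.ids), name="dispersion")
    means = dist.groupby(groups).mean()
    return BetaDispersionResult(
        distances=dist, group_means=means, f_statistic=float(f_obs), p=float(p),
        n_permutations=n_perm, seed=seed,
    )


# ---------------------------------------------------------------------------
# Mantel tests
# ---------------------------------------------------------------------------

def _triangle(dm: DistanceMatrix) -> np.ndarray:
    return squareform(dm.data, checks=False)


def _corr(a: np.ndarray, b: np.ndarray, method: str) -> float:
    if method == "spearman":
        a, b = sps.rankdata(a), sps.rankdata(b)
    elif method != "pearson":
        raise ValidationError(f"unknown correlation method {method!r}")
    if np.std(a) == 0 or np.std(b) == 0:
        raise ValidationError("constant distance triangle: correlation undefined")
    return float(np.corrcoef(a, b)[0, 1])


def mantel(
    d1: DistanceMatrix,
    d2: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Mantel correlation between two distance matrices over the same ids.

    p-value from permuting the sample ids of the second matrix; two-sided
    alternatives are not used — the test is one-sided on r >= r_obs, the
    convention for distance-decay analyses.
    """
    if list(d1.ids) != list(d2.ids):
        raise ValidationError("distance matrices must share ids in the same order")
    a = _triangle(d1)
    b_mat = d2.data
    r_obs = _corr(a, _triangle(d2), method)
    rng = np.random.default_rng(seed)
    n = d1.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b = squareform(b_mat[np.ix_(perm, perm)], checks=False)
        if _corr(a, b, method) >= r_obs - 1e-12:
            exceed += 1
    return r_obs, (exceed + 1) / (n_perm + 1)


def partial_mantel(
    d_comm: DistanceMatrix,
    d_geo: DistanceMatrix,
    d_env: DistanceMatrix,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> tuple[float, float]:
    """Partial Mantel correlation of d_comm and d_geo conditioned on d_env.

    The partial r is the first-order partial correlation of the unfolded
    triangles; the reference distribution permutes the ids of d_geo and
    recomputes the partial statistic.
    """
    for other in (d_geo, d_env):
        if list(other.ids) != list(d_comm.ids):
            raise ValidationError("distance matrices must share ids in the same order")

    a, c = _triangle(d_comm), _triangle(d_env)

    def partial_r(b: np.ndarray) -> float:
        r_ab, r_ac, r_bc = _corr(a, b, method), _corr(a, c, method), _corr(b, c, method)
        num = r_ab - r_ac * r_bc
        denom = np.sqrt(max((1 - r_ac**2) * (1 - r_bc**2), 0.0))
        if denom < 1e-12:
            # fully confounded (|r| = 1 with the covariate): nothing left to
            # correlate, the partial association is zero by convention
            if abs(num) < 1e-9:
                return 0.0
            raise ValidationError("degenerate partial correlation (|r| = 1 with covariate)")
        return num / denom

    r_obs = partial_r(_triangle(d_geo))
    rng = np.random.default_rng(seed)
    n = d_comm.shape[0]
    exceed = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        b = squareform(d_geo.data[np.ix_(perm, perm)], checks=False)
        if partial_r(b) >= r_obs - 1e-12:
            exceed += 1
    return float(r_obs), (exceed + 1) / (n_perm + 1)


# ---------------------------------------------------------------------------
# distance decay
# ---------------------------------------------------------------------------

def geographic_distances(coords: pd.DataFrame) -> DistanceMatrix:
    """Euclidean distances between (x, y) coordinates (same length unit)."""
    xy = coords[["x", "y"]].to_numpy(dtype=float)
    d = np.sqrt(((xy[:, None, :] - xy[None, :, :]) ** 2).sum(axis=-1))
    return DistanceMatrix(d, ids=[str(i) for i in coords.index])


def distance_decay(
    comm_dm: DistanceMatrix,
    geo_dm: DistanceMatrix,
    seasons: pd.Series | None = None,
    env_dm: DistanceMatrix | None = None,
    method: str = "pearson",
    n_perm: int = 999,
    seed: int = 0,
) -> pd.DataFrame:
    """Mantel distance decay of community dissimilarity against log distance.

    Runs a Mantel test of community dissimilarity versus log10 geographic
    distance, overall and within each season, with an optional partial test
    conditioning on an environmental distance matrix. Zero geographic
    distances are an error (log undefined); supply distinct locations.
    """
    if list(geo_dm.ids) != list(comm_dm.ids):
        raise ValidationError("community and geographic matrices must share ids")
    off_diag = _triangle(geo_dm)
    if (off_diag <= 0).any():
        raise ValidationError("geographic distances must be positive between distinct samples")
    log_geo = DistanceMatrix(
        np.log10(np.where(np.eye(geo_dm.shape[0], dtype=bool), 1.0, geo_dm.data)),
        ids=list(geo_dm.ids),
    )

    strata: dict[str, list[str]] = {"overall": list(comm_dm.ids)}
    if seasons is not None:
        seasons = pd.Series(seasons).loc[list(comm_dm.ids)]
        for season in seasons.unique():
            strata[str(season)] = list(seasons.index[seasons == season])

    rows = []
    for label, ids in strata.items():
        if len(ids) < 4:
            continue
        c = comm_dm.filter(ids)
        lg = log_geo.filter(ids)
        r, p = mantel(c, lg, method=method, n_perm=n_perm, seed=seed)
        row = {"stratum": label, "n": len(ids), "mantel_r": r, "p": p}
        if env_dm is not None:
            e = env_dm.filter(ids)
            pr, pp = partial_mantel(c, lg, e, method=method, n_perm=n_perm, seed=seed)
            row["partial_r"], row["partial_p"] = pr, pp
        rows.append(row)
    return pd.DataFrame(rows).set_index("stratum")
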