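"""Compositional differential-abundance screening.

Counts are CLR-transformed (with pseudocount); each taxon is fit by a linear
model with the blocking factor (site, or pair id for the paired active/total
contrast) as a fixed additive effect, and the term of interest (assay, site
type or season) tested by an F statistic whose reference distribution comes
from permuting the term's labels *within blocks*. Benjamini–Hochberg
controls the FDR across the tested taxa. The active-vs-total screen
additionally applies a minimum fold-change rule (default 2x, i.e.
|log2FC| >= 1) mirroring how "differed in abundance by at least 2x" is
commonly operationalized.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .model import FeatureTable, PairedCommunity, SampleMetadata, ValidationError
from .preprocess import clr_transform

LN2 = np.log(2.0)


@dataclass
class DiffAbundConfig:
    min_prevalence: float = 0.10
    min_fold_change: float = 2.0
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    pseudocount: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.alpha < 1):
            raise ValidationError("alpha must be in (0, 1)")
        if self.min_fold_change < 1:
            raise ValidationError("min_fold_change must be >= 1")


@dataclass
class DiffAbundResult:
    """Per-taxon test table and the configuration that produced it."""

    table: pd.DataFrame  # log2FC, statistic, p, p_adj, max_group, tested
    term: str
    block: str
    config: DiffAbundConfig

    @property
    def significant(self) -> pd.Index:
        t = self.table
        return t.index[t["tested"] & (t["p_adj"] < self.config.alpha)]


def _projector(x: np.ndarray) -> tuple[np.ndarray, int]:
    q, r = np.linalg.qr(x)
    diag = np.abs(np.diag(r))
    rank = int((diag > 1e-10 * max(1.0, diag.max())).sum())
    q = q[:, :rank]
    return q, rank


def da_test(
    table: FeatureTable,
    meta: SampleMetadata | pd.DataFrame,
    term: str,
    block: str,
    config: DiffAbundConfig | None = None,
) -> DiffAbundResult:
    """Permutation F-test per taxon on CLR values, blocked and BH-adjusted.

    ``log2FC`` is the difference of CLR group means on the log2 scale; for
    terms with more than two levels it is the spread between the highest and
    lowest group mean, and ``max_group`` records the level of peak abundance.
    """
    config = config or DiffAbundConfig()
    design = meta.data if isinstance(meta, SampleMetadata) else meta
    design = design.loc[list(table.sample_ids)]
    term_labels = design[term].astype(str).to_numpy()
    block_labels = design[block].astype(str).to_numpy()

    levels = pd.unique(term_labels)
    if len(levels) < 2:
        raise ValidationError(f"term {term!r} has fewer than 2 levels")
    # confounding: term must vary within at least one block
    varies = any(
        len(np.unique(term_labels[block_labels == b])) > 1 for b in np.unique(block_labels)
    )
    if not varies:
        raise ValidationError(f"term {term!r} is confounded with block {block!r}")

    n = len(term_labels)
    prevalence = (table.data > 0).mean(axis=1)
    tested = prevalence >= config.min_prevalence
    if not tested.any():
        raise ValidationError("no taxon passes the prevalence filter")

    clr = clr_transform(table, config.pseudocount)
    y = clr.loc[tested].to_numpy().T  # samples x tested taxa

    x_block = pd.get_dummies(pd.Series(block_labels), drop_first=False).to_numpy(float)
    x_block = np.hstack([np.ones((n, 1)), x_block[:, 1:]])
    q_block, rank_block = _projector(x_block)
    h_block = q_block @ q_block.T

    def term_f(labels: np.ndarray) -> tuple[np.ndarray, int, int]:
        dummies = pd.get_dummies(pd.Series(labels), drop_first=True).to_numpy(float)
        x_full = np.hstack([x_block, dummies])
        q_full, rank_full = _projector(x_full)
        h_full = q_full @ q_full.T
        df_t = rank_full - rank_block
        df_r = n - rank_full
        fit_diff = (h_full - h_block) @ y
        resid = y - h_full @ y
        ss_t = (fit_diff**2).sum(axis=0)
        ss_r = (resid**2).sum(axis=0)
        with np.errstate(divide="ignore", invalid="ignore"):
            f = (ss_t / df_t) / np.maximum(ss_r / df_r, 1e-300)
        return f, df_t, df_r

    f_obs, df_t, df_r = term_f(term_labels)
    if df_t < 1:
        raise ValidationError(f"term {term!r} adds no degrees of freedom over block {block!r}")

    rng = np.random.default_rng(config.seed)
    block_index = {b: np.flatnonzero(block_labels == b) for b in np.unique(block_labels)}
    exceed = np.zeros(y.shape[1])
    for _ in range(config.n_perm):
        perm_labels = term_labels.copy()
        for idx in block_index.values():
            perm_labels[idx] = term_labels[idx][rng.permutation(len(idx))]
        f_perm, _, _ = term_f(perm_labels)
        exceed += f_perm >= f_obs - 1e-12
    pvals = (exceed + 1) / (config.n_perm + 1)
    p_adj = multipletests(pvals, method="fdr_bh")[1]

    # CLR group means -> log2 fold change and peak-abundance group
    means = pd.DataFrame(
        {lvl: y[term_labels == lvl].mean(axis=0) for lvl in levels},
        index=clr.index[tested],
    )
    max_group = means.idxmax(axis=1)
    if len(levels) == 2:
        log2fc = (means[levels[1]] - means[levels[0]]) / LN2
    else:
        log2fc = (means.max(axis=1) - means.min(axis=1)) / LN2

    out = pd.DataFrame(
        {
            "log2FC": np.nan,
            "statistic": np.nan,
            "p": np.nan,
            "p_adj": np.nan,
            "max_group": pd.Series("", index=table.data.index, dtype=object),
            "tested": tested,
            "prevalence": prevalence,
        },
        index=pd.Index(table.taxon_ids, name="taxon_id"),
    )
    out.loc[tested, "log2FC"] = log2fc
    out.loc[tested, "statistic"] = f_obs
    out.loc[tested, "p"] = pvals
    out.loc[tested, "p_adj"] = p_adj
    out.loc[tested, "max_group"] = max_group
    return DiffAbundResult(table=out, term=term, block=block, config=config)


def active_vs_total_enrichment(
    pc: PairedCommunity, config: DiffAbundConfig | None = None
) -> DiffAbundResult:
    """Active-vs-total screen: assay term, pair blocking, fold rule applied.

    A taxon is called enriched when BH-adjusted p < alpha AND the CLR fold
    change satisfies |log2FC| >= log2(min_fold_change). Direction labels:
    "active-enriched" (higher in RNA) / "total-enriched" (higher in DNA).
    """
    config = config or DiffAbundConfig()
    rna, dna = pc.active.data, pc.total.data
    combined = pd.concat(
        [rna.add_suffix(":RNA"), dna.add_suffix(":DNA")], axis=1
    )
    table = FeatureTable(combined, pc.marker, "DNA")  # container only; assays in design
    design = pd.DataFrame(
        {
            "assay": ["RNA"] * len(pc.pair_ids) + ["DNA"] * len(pc.pair_ids),
            "pair_id": list(pc.pair_ids) * 2,
        },
        index=list(combined.columns),
    )
    result = da_test(table, design, term="assay", block="pair_id", config=config)
    t = result.table
    # two-level term with levels ordered (RNA first seen): log2FC = level2 - level1
    # = DNA - RNA under the combined layout, so flip to active-minus-total.
    first_level = design["assay"].iloc[0]
    if first_level == "RNA":
        t["log2FC"] = -t["log2FC"]
    min_l2fc = np.log2(config.min_fold_change)
    enriched = t["tested"] & (t["p_adj"] < config.alpha) & (t["log2FC"].abs() >= min_l2fc)
    t["enriched"] = enriched
    t["direction"] = np.where(
        ~enriched, "", np.where(t["log2FC"] > 0, "active-enriched", "total-enriched")
    )
    return result


def overlap_summary(
    result_a: DiffAbundResult, result_b: DiffAbundResult, labels: tuple[str, str] = ("a", "b")
) -> pd.DataFrame:
    """Cross-tabulation of significant taxa between two screens (Venn counts)."""
    if list(result_a.table.index) != list(result_b.table.index):
        raise ValidationError("results cover different taxon universes")
    sig_a = set(result_a.significant)
    sig_b = set(result_b.significant)
    universe = set(result_a.table.index)
    both = sig_a & sig_b
    return pd.DataFrame(
        {
            "count": [
                len(sig_a - sig_b),
                len(sig_b - sig_a),
                len(both),
                len(universe - sig_a - sig_b),
            ]
        },
        index=pd.Index(
            [f"{labels[0]}_only", f"{labels[1]}_only", "both", "neither"], name="category"
        ),
    )


def seasonal_delta_contrast(
    table: FeatureTable,
    meta: SampleMetadata | pd.DataFrame,
    taxon_group: list[str],
    from_season: str,
    to_season: str,
    site_partition: dict,
) -> dict:
    """Per-site seasonal abundance change of a taxon group, contrasted
    between two site classes (e.g. warm vs cool sites).

    For each site, plots sampled in both seasons contribute the difference
    of the taxon group's relative abundance (``to_season`` minus
    ``from_season``); sites missing a season are excluded with a warning.
    The two site classes are compared with a Welch t-test.
    """
    import warnings as _warnings

    from scipy import stats as sps

    design = meta.data if isinstance(meta, SampleMetadata) else meta
    design = design.loc[[s for s in table.sample_ids if s in design.index]]
    missing_taxa = [t for t in taxon_group if t not in table.data.index]
    if missing_taxa:
        raise ValidationError(f"taxa not in table: {missing_taxa}")
    rel = table.data / table.data.sum(axis=0)
    group_ab = rel.loc[taxon_group].sum(axis=0)

    per_site = {}
    for site in design["site"].unique():
        rows = design[design["site"] == site]
        deltas = []
        for plot in rows["plot"].unique():
            sel = rows[rows["plot"] == plot]
            s_from = sel.index[sel["season"] == from_season]
            s_to = sel.index[sel["season"] == to_season]
            if len(s_from) and len(s_to):
                deltas.append(
                    group_ab[s_to].mean() - group_ab[s_from].mean()
                )
        if not deltas:
            _warnings.warn(f"site {site!r} missing a season; excluded", stacklevel=2)
            continue
        deltas = np.asarray(deltas)
        per_site[site] = {
            "mean_delta": float(deltas.mean()),
            "se": float(deltas.std(ddof=1) / np.sqrt(len(deltas))) if len(deltas) > 1 else np.nan,
            "n_plots": len(deltas),
            "class": site_partition.get(site),
        }

    classes = sorted({v["class"] for v in per_site.values() if v["class"] is not None})
    if len(classes) != 2:
        raise ValidationError(f"site_partition must define exactly 2 classes, got {classes}")
    a = [v["mean_delta"] for v in per_site.values() if v["class"] == classes[0]]
    b = [v["mean_delta"] for v in per_site.values() if v["class"] == classes[1]]
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each site class needs >= 2 sites for a variance estimate")
    stat, p = sps.ttest_ind(a, b, equal_var=False)
    return {
        "per_site": per_site,
        "classes": classes,
        "welch_t": float(stat),
        "p": float(p),
        "class_means": {classes[0]: float(np.mean(a)), classes[1]: float(np.mean(b))},
    }
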