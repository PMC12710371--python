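"""Synthetic paired active/total community generator.

The generator emulates a hierarchical field design — site types along an
elevation gradient, replicate sites within type, plots within site, repeat
sampling across seasons — with paired RNA (active) and DNA (total) libraries
per physical sample. True taxon abundances follow a log-normal hierarchy
(site-type > site > plot offsets) with per-taxon seasonal modulation of
*population* abundance; metabolic activity is a per-taxon, per-sample
Bernoulli state whose probability is modulated by season (typically more
strongly than the population is) and optionally by an environmental
covariate, plus a continuous activity-intensity multiplier. Libraries are
fixed-depth multinomial draws, which induces compositionality the same way
amplicon sequencing does.

Planted structure is recorded in a ground-truth ledger: core taxa with a
target occupancy and activity probability (including "core but frequently
inactive" taxa), active/total enriched taxa with a known RNA:DNA ratio, and
the dormancy–covariate slope.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
import pandas as pd

from .model import (
    EnvMatrix,
    FeatureTable,
    PairedCommunity,
    SampleMetadata,
    SEASONS,
    SITE_TYPES,
    ValidationError,
)

_LOGIT_CLIP = 1e-9


@dataclass
class PlantedCore:
    """A block of planted core taxa: target occupancy and activity prob."""

    n: int
    occupancy: float = 1.0
    activity_prob: float = 0.9


@dataclass
class PlantedEnriched:
    """A block of planted taxa with a known RNA:DNA abundance ratio."""

    n: int
    ratio: float = 4.0


@dataclass
class SyntheticParams:
    """Generator configuration; defaults mirror the emulated field design
    (3 site types x 3 sites x 5 plots x 3 seasons x 2 assays = 270 libraries
    from 135 physical samples)."""

    n_site_types: int = 3
    n_sites_per_type: int = 3
    n_plots_per_site: int = 5
    seasons: tuple = SEASONS
    n_taxa: int = 500
    depth: int = 20000
    base_abundance_sd: float = 1.5
    site_type_effect: float = 1.0
    site_effect: float = 0.6
    plot_effect: float = 0.4
    season_population_amplitude: float = 0.25
    season_activity_amplitude: float = 1.5
    activity_prob_range: tuple = (0.3, 0.9)
    activity_intensity_sd: float = 0.5
    core_taxa: list = field(
        default_factory=lambda: [
            PlantedCore(n=8, occupancy=1.0, activity_prob=0.9),
            PlantedCore(n=2, occupancy=1.0, activity_prob=0.05),
            PlantedCore(n=5, occupancy=0.5, activity_prob=0.9),
        ]
    )
    enriched_taxa: list = field(default_factory=lambda: [PlantedEnriched(n=10, ratio=4.0)])
    core_log_abundance: float = 2.5
    core_effect_damping: float = 0.25
    dormancy_covariate_slope: float = 0.0
    marker: str = "ITS2"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.depth < 1:
            raise ValidationError("depth must be >= 1")
        if not (0 <= self.activity_prob_range[0] <= self.activity_prob_range[1] <= 1):
            raise ValidationError("activity_prob_range must be within [0, 1] and ordered")
        for c in self.core_taxa:
            if not (0 <= c.occupancy <= 1 and 0 <= c.activity_prob <= 1):
                raise ValidationError("core taxon occupancy/activity_prob must be in [0, 1]")
        n_planted = sum(c.n for c in self.core_taxa) + sum(e.n for e in self.enriched_taxa)
        if n_planted > self.n_taxa:
            raise ValidationError("planted taxa exceed n_taxa")


@dataclass
class SyntheticDataset:
    """Generator output: aligned pairs, raw per-library tables, design
    metadata, plot covariates and coordinates, and the truth ledger."""

    paired: PairedCommunity
    active_table: FeatureTable
    total_table: FeatureTable
    metadata: SampleMetadata
    env: EnvMatrix
    coords: pd.DataFrame
    truth: dict


def _logit(p: np.ndarray) -> np.ndarray:
    p = np.clip(p, _LOGIT_CLIP, 1 - _LOGIT_CLIP)
    return np.log(p / (1 - p))


def _sigmoid(x: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + np.exp(-x))


def _design_frame(params: SyntheticParams) -> pd.DataFrame:
    rows = []
    site_no = 0
    for t in range(params.n_site_types):
        site_type = SITE_TYPES[t % len(SITE_TYPES)]
        for _ in range(params.n_sites_per_type):
            site_no += 1
            site = f"S{site_no}"
            for p in range(1, params.n_plots_per_site + 1):
                for season in params.seasons:
                    rows.append(
                        {
                            "site_type": site_type,
                            "site": site,
                            "plot": f"P{p}",
                            "season": season,
                            "pair_id": f"{site}-P{p}-{season}",
                        }
                    )
    return pd.DataFrame(rows)


def _environment(params: SyntheticParams, design: pd.DataFrame, rng) -> tuple[EnvMatrix, pd.DataFrame]:
    """Plot covariates (sensor variables at site level, chemistry at plot
    level) and plot coordinates (meters; sites km apart, plots tens of m)."""
    plots = design[["site_type", "site", "plot"]].drop_duplicates().reset_index(drop=True)
    sites = plots[["site_type", "site"]].drop_duplicates().reset_index(drop=True)
    type_temp = {"riparian": 15.0, "mid_elevation": 13.5, "high_elevation": 11.5}
    type_om = {"riparian": -0.8, "mid_elevation": 0.0, "high_elevation": 0.8}
    site_rows = {}
    for _, row in sites.iterrows():
        site_rows[row["site"]] = {
            "soil_temp_mean": type_temp[row["site_type"]] + rng.normal(0, 0.7),
            "soil_moisture": 0.25 + rng.normal(0, 0.05),
            "x": rng.uniform(0, 10000.0),
            "y": rng.uniform(0, 10000.0),
            "om_base": type_om[row["site_type"]],
        }
    env_rows, coord_rows = [], []
    for _, row in plots.iterrows():
        s = site_rows[row["site"]]
        om = s["om_base"] + rng.normal(0, 0.5)
        ph = 5.8 - 0.4 * s["om_base"] + rng.normal(0, 0.2)
        env_rows.append(
            {
                "site": row["site"],
                "plot": row["plot"],
                "soil_temp_mean": s["soil_temp_mean"],
                "soil_moisture": s["soil_moisture"],
                "organic_matter": om,
                "pH": ph,
                "base_saturation": 40 + 25 * (ph - 5.8) + rng.normal(0, 3),
                "iron": np.exp(rng.normal(2.0, 0.4)),
                "nitrate_flux": np.exp(rng.normal(0.0, 0.8)),
                "vegetation_cover": float(np.clip(55 + rng.normal(0, 18), 0, 100)),
            }
        )
        coord_rows.append(
            {
                "site": row["site"],
                "plot": row["plot"],
                "x": s["x"] + rng.uniform(-50, 50),
                "y": s["y"] + rng.uniform(-50, 50),
            }
        )
    return EnvMatrix(pd.DataFrame(env_rows)), pd.DataFrame(coord_rows)


def generate(params: SyntheticParams | None = None) -> SyntheticDataset:
    """Draw one paired active/total dataset under the configured model.

    Same seed, same params => bit-identical output.
    """
    params = params or SyntheticParams()
    rng = np.random.default_rng(params.seed)
    design = _design_frame(params)
    n_samples = len(design)
    n_taxa = params.n_taxa
    taxa = [f"T{i:04d}" for i in range(n_taxa)]

    # planted blocks occupy the leading taxon indices
    core_ids, core_occ, core_delta = [], {}, {}
    idx = 0
    for blk in params.core_taxa:
        for _ in range(blk.n):
            tid = taxa[idx]
            core_ids.append(tid)
            core_occ[tid] = blk.occupancy
            core_delta[tid] = blk.activity_prob
            idx += 1
    enriched_ids, enriched_ratio = [], {}
    for blk in params.enriched_taxa:
        for _ in range(blk.n):
            tid = taxa[idx]
            enriched_ids.append(tid)
            enriched_ratio[tid] = blk.ratio
            idx += 1
    is_core = np.zeros(n_taxa, dtype=bool)
    is_core[: len(core_ids)] = True

    # per-taxon baseline activity probability delta
    lo, hi = params.activity_prob_range
    delta = rng.uniform(lo, hi, size=n_taxa)
    for i, tid in enumerate(core_ids):
        delta[i] = core_delta[tid]
    for j, tid in enumerate(enriched_ids):
        delta[len(core_ids) + j] = 1.0  # enriched taxa are always active

    # log-abundance hierarchy; core taxa get dampened offsets so their
    # detection matches the planted occupancy rather than sampling noise
    damp = np.where(is_core, params.core_effect_damping, 1.0)
    base = rng.normal(0.0, params.base_abundance_sd, size=n_taxa)
    base[: len(core_ids)] = params.core_log_abundance

    site_types = design["site_type"].unique()
    sites = design["site"].unique()
    seasons = list(params.seasons)
    eff_type = {
        st: rng.normal(0.0, params.site_type_effect, size=n_taxa) * damp for st in site_types
    }
    eff_site = {s: rng.normal(0.0, params.site_effect, size=n_taxa) * damp for s in sites}
    eff_plot = {
        (s, f"P{p}"): rng.normal(0.0, params.plot_effect, size=n_taxa) * damp
        for s in sites
        for p in range(1, params.n_plots_per_site + 1)
    }
    seas_pop = {
        se: rng.normal(0.0, params.season_population_amplitude, size=n_taxa) * damp
        for se in seasons
    }
    seas_act = {
        se: rng.normal(0.0, params.season_activity_amplitude, size=n_taxa) for se in seasons
    }

    env, coords = _environment(params, design, rng)
    om = env.data.set_index(["site", "plot"])["organic_matter"]
    om_z = (om - om.mean()) / om.std(ddof=0)

    dna = np.zeros((n_taxa, n_samples), dtype=np.int64)
    rna = np.zeros((n_taxa, n_samples), dtype=np.int64)
    true_dormant = np.full(n_samples, np.nan)
    ratio_vec = np.ones(n_taxa)
    for j, tid in enumerate(enriched_ids):
        ratio_vec[len(core_ids) + j] = enriched_ratio[tid]
    base_logit = _logit(delta)

    for k, row in enumerate(design.itertuples(index=False)):
        lam = np.exp(
            base
            + eff_type[row.site_type]
            + eff_site[row.site]
            + eff_plot[(row.site, row.plot)]
            + seas_pop[row.season]
        )
        # planted occupancy: core taxa absent from a Bernoulli(1 - occupancy)
        # subset of samples
        present = np.ones(n_taxa, dtype=bool)
        for i, tid in enumerate(core_ids):
            if core_occ[tid] < 1.0:
                present[i] = rng.random() < core_occ[tid]
        lam = lam * present

        eta = (
            base_logit
            + seas_act[row.season]
            - params.dormancy_covariate_slope * om_z[(row.site, row.plot)]
        )
        prob = np.where(delta >= 1.0, 1.0, np.where(delta <= 0.0, 0.0, _sigmoid(eta)))
        state = rng.random(n_taxa) < prob
        intensity = np.exp(rng.normal(0.0, params.activity_intensity_sd, size=n_taxa))
        w = lam * state * intensity * ratio_vec

        dna[:, k] = rng.multinomial(params.depth, lam / lam.sum())
        if w.sum() > 0:
            rna[:, k] = rng.multinomial(params.depth, w / w.sum())
        n_present = int((lam > 0).sum())
        if n_present:
            true_dormant[k] = 1.0 - (state & (lam > 0)).sum() / n_present

    pair_ids = design["pair_id"].tolist()
    rna_ids = [f"{p}-RNA" for p in pair_ids]
    dna_ids = [f"{p}-DNA" for p in pair_ids]
    active_table = FeatureTable(
        pd.DataFrame(rna, index=taxa, columns=rna_ids), params.marker, "RNA"
    )
    total_table = FeatureTable(
        pd.DataFrame(dna, index=taxa, columns=dna_ids), params.marker, "DNA"
    )
    meta_rows = []
    for assay, ids in (("RNA", rna_ids), ("DNA", dna_ids)):
        block = design.copy()
        block["assay"] = assay
        block["marker"] = params.marker
        block.index = ids
        meta_rows.append(block)
    metadata = SampleMetadata(pd.concat(meta_rows))

    aligned = PairedCommunity(
        active=FeatureTable(pd.DataFrame(rna, index=taxa, columns=pair_ids), params.marker, "RNA"),
        total=FeatureTable(pd.DataFrame(dna, index=taxa, columns=pair_ids), params.marker, "DNA"),
        pair_ids=pair_ids,
    )
    truth = {
        "core_taxa": {t: {"occupancy": core_occ[t], "activity_prob": core_delta[t]} for t in core_ids},
        "enriched_taxa": {t: {"ratio": enriched_ratio[t]} for t in enriched_ids},
        "activity_prob": dict(zip(taxa, delta.tolist())),
        "true_dormant_fraction": dict(zip(pair_ids, true_dormant.tolist())),
        "dormancy_covariate_slope": params.dormancy_covariate_slope,
        "params": {
            k: v
            for k, v in asdict(params).items()
            if not isinstance(v, list)
        },
    }
    return SyntheticDataset(
        paired=aligned,
        active_table=active_table,
        total_table=total_table,
        metadata=metadata,
        env=env,
        coords=coords,
        truth=truth,
    )


def expected_dormant_fraction(
    params: SyntheticParams, depth: int | None = None, n_rep: int = 200, seed: int = 12345
) -> dict:
    """Monte-Carlo oracle for the mean per-pair dormant fraction.

    Independently re-draws single paired samples from the generative model
    (fresh hierarchical offsets each time, no shared bookkeeping with
    :func:`generate`) and computes 1 - |RNA-detected| / |union-detected| at
    the sequencing depth. Returns the mean, its Monte-Carlo standard error
    and the replicate count.
    """
    if params.core_taxa or params.enriched_taxa:
        raise ValidationError(
            "expected_dormant_fraction covers the background model; pass params "
            "without planted core/enriched blocks"
        )
    depth = depth or params.depth
    rng = np.random.default_rng(seed)
    n_taxa = params.n_taxa
    lo, hi = params.activity_prob_range
    vals = []
    for _ in range(n_rep):
        delta = rng.uniform(lo, hi, size=n_taxa)
        log_lam = rng.normal(0.0, params.base_abundance_sd, size=n_taxa)
        for sd in (params.site_type_effect, params.site_effect, params.plot_effect,
                   params.season_population_amplitude):
            log_lam = log_lam + rng.normal(0.0, sd, size=n_taxa)
        lam = np.exp(log_lam)
        eta = _logit(delta) + rng.normal(0.0, params.season_activity_amplitude, size=n_taxa)
        prob = np.where(delta >= 1.0, 1.0, np.where(delta <= 0.0, 0.0, _sigmoid(eta)))
        state = rng.random(n_taxa) < prob
        intensity = np.exp(rng.normal(0.0, params.activity_intensity_sd, size=n_taxa))
        dna_counts = rng.multinomial(depth, lam / lam.sum())
        w = lam * state * intensity
        rna_counts = (
            rng.multinomial(depth, w / w.sum()) if w.sum() > 0 else np.zeros(n_taxa, dtype=int)
        )
        union = (dna_counts > 0) | (rna_counts > 0)
        if union.sum() == 0:
            continue
        vals.append(1.0 - (rna_counts > 0).sum() / union.sum())
    vals = np.asarray(vals)
    return {
        "mean": float(vals.mean()),
        "se": float(vals.std(ddof=1) / np.sqrt(len(vals))),
        "n_rep": int(len(vals)),
    }
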