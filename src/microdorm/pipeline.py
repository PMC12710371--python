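"""End-to-end pipeline: preprocess -> activity/core -> community statistics
-> differential abundance -> environment linkage.

Every report is stamped with the configuration hash and the seeds actually
used; per-stage seeds are derived deterministically from the global seed by
hashing the stage name, so reruns with the same configuration are
bit-identical for the deterministic stages.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import io as mio
from .activity import CoreConfig, core_report, dormancy_profile, shared_fraction
from .diffabund import DiffAbundConfig, active_vs_total_enrichment
from .envlink import dormancy_env_link
from .model import FeatureTable, SampleMetadata, ValidationError
from .preprocess import rarefy, sqrt_wisconsin
from .stats import bray_curtis, distance_decay, geographic_distances, pcoa, permanova

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    active_table: str | None = None
    total_table: str | None = None
    metadata: str | None = None
    env_matrix: str | None = None
    out_dir: str = "microdorm-out"
    marker: str = "ITS2"
    rarefaction_depth: int = 17182
    occupancy_threshold: float = 0.95
    min_fold_change: float = 2.0
    min_prevalence: float = 0.10
    alpha: float = 0.05
    n_perm: int = 999
    seed: int = 0
    permanova_terms: tuple = ("site_type", "site", "season")

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        import yaml

        with open(path) as fh:
            doc = yaml.safe_load(fh) or {}
        known = {k: v for k, v in doc.items() if k in cls.__dataclass_fields__}
        cfg = cls(**known)
        for name in ("active_table", "total_table", "metadata"):
            p = getattr(cfg, name)
            if p is None:
                raise ValidationError(f"pipeline config missing required path: {name}")
            if not Path(p).exists():
                raise ValidationError(f"configured {name} does not exist: {p}")
        if cfg.env_matrix is not None and not Path(cfg.env_matrix).exists():
            raise ValidationError(f"configured env_matrix does not exist: {cfg.env_matrix}")
        return cfg

    def content_hash(self) -> str:
        doc = {k: getattr(self, k) for k in sorted(self.__dataclass_fields__)}
        return hashlib.sha256(json.dumps(doc, default=str).encode()).hexdigest()[:16]


def stage_seed(global_seed: int, stage: str) -> int:
    """Deterministic per-stage seed below 2**31, derived by stage-name hash."""
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).digest()
    return int.from_bytes(h[:4], "big") % (2**31)


def run_pipeline(config: PipelineConfig) -> Path:
    """Execute the full analysis and write reports to the output directory."""
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stamp = {"config_hash": config.content_hash(), "seed": config.seed}

    def _stage(name):
        logger.info("stage %s", name)
        return stage_seed(config.seed, name)

    active = mio.read_feature_table(config.active_table, marker=config.marker, assay="RNA")
    total = mio.read_feature_table(config.total_table, marker=config.marker, assay="DNA")
    meta = mio.read_metadata(config.metadata)

    # preprocess: rarefy both assays of the marker jointly to one depth
    seed = _stage("rarefy")
    active_r, dropped_a = rarefy(active, config.rarefaction_depth, seed, return_dropped=True)
    total_r, dropped_t = rarefy(total, config.rarefaction_depth, seed + 1, return_dropped=True)
    mio.write_report(
        {**stamp, "stage": "rarefy", "depth": config.rarefaction_depth,
         "dropped_active": dropped_a, "dropped_total": dropped_t},
        out / "rarefaction.json",
    )

    pc = mio.align_pairs(active_r, total_r, meta)

    # activity / cores
    profile = dormancy_profile(pc)
    per_pair, summary = shared_fraction(pc)
    profile.to_csv(out / "dormancy_profile.tsv", sep="\t")
    report = core_report(pc, CoreConfig(occupancy_threshold=config.occupancy_threshold))
    mio.write_report(
        {**stamp, "stage": "activity",
         "dormant_fraction_mean": float(profile["dormant_fraction"].mean()),
         "shared_fraction": summary, "core": report.to_dict()},
        out / "activity_core.json",
    )

    # community statistics per assay
    meta_pairs = meta.data.drop_duplicates(subset=["pair_id"]).set_index("pair_id")
    seed = _stage("permanova")
    perm_out = {}
    for label, table in (("active", pc.active), ("total", pc.total)):
        std = sqrt_wisconsin(table.data)
        dm = bray_curtis(std)
        mio.write_distance_matrix(dm, out / f"bray_curtis_{label}.tsv")
        ord_res = pcoa(dm)
        ord_res.coordinates.to_csv(out / f"pcoa_{label}.tsv", sep="\t")
        design = meta_pairs.loc[list(dm.ids)]
        res = permanova(dm, design, list(config.permanova_terms),
                        n_perm=config.n_perm, seed=seed)
        perm_out[label] = res.table.to_dict(orient="index")
    mio.write_report({**stamp, "stage": "permanova", "results": perm_out},
                     out / "permanova.json")

    # differential abundance: active vs total
    seed = _stage("diffabund")
    da_cfg = DiffAbundConfig(
        min_prevalence=config.min_prevalence, min_fold_change=config.min_fold_change,
        alpha=config.alpha, n_perm=config.n_perm, seed=seed,
    )
    enr = active_vs_total_enrichment(pc, da_cfg)
    enr.table.to_csv(out / "enrichment.tsv", sep="\t")
    mio.write_report(
        {**stamp, "stage": "diffabund",
         "n_enriched": int(enr.table["enriched"].sum()),
         "n_active_enriched": int((enr.table["direction"] == "active-enriched").sum()),
         "n_total_enriched": int((enr.table["direction"] == "total-enriched").sum())},
        out / "enrichment_summary.json",
    )

    # environment linkage (optional)
    if config.env_matrix is not None:
        env = mio.read_env_matrix(config.env_matrix)
        seed = _stage("envlink")
        rep = dormancy_env_link(profile, env, meta, seed=seed)
        rep.associations.to_csv(out / "dormancy_env_associations.tsv", sep="\t")
        rep.importance.importances.to_csv(out / "dormancy_env_importance.tsv", sep="\t")

    mio.write_report({**stamp, "stage": "done"}, out / "pipeline.json")
    return out


__all__ = [
    "PipelineConfig",
    "run_pipeline",
    "stage_seed",
    "distance_decay",
    "geographic_distances",
]
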