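"""Activity and dormancy statistics on paired RNA/DNA communities.

Detection in the RNA (cDNA) library marks a taxon as metabolically active in
that sample; detection only in the DNA library marks it as dormant (or relic
DNA). The per-sample dormant fraction is

    1 - |RNA-detected| / |RNA-detected U DNA-detected|,

and the active/total *core microbiomes* are the taxa detected in at least a
threshold fraction (default 95%) of the samples of the respective assay.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .model import FeatureTable, PairedCommunity, ValidationError


def occupancy(table: FeatureTable, presence_threshold: int = 1) -> pd.Series:
    """Per-taxon fraction of samples in which the taxon is detected."""
    if table.n_samples == 0:
        raise ValidationError("occupancy requires at least one sample")
    return table.presence(presence_threshold).mean(axis=1)


def dormancy_profile(pc: PairedCommunity, presence_threshold: int = 1) -> pd.DataFrame:
    """Per-pair active richness, union richness and dormant fraction.

    A pair with an empty RNA-union-DNA taxon set is flagged undefined
    (``dormant_fraction`` = NaN), never imputed as 0 or 1.
    """
    rna = pc.active.presence(presence_threshold).to_numpy()
    dna = pc.total.presence(presence_threshold).to_numpy()
    active = rna.sum(axis=0)
    union = (rna | dna).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(union > 0, 1.0 - active / np.maximum(union, 1), np.nan)
    return pd.DataFrame(
        {
            "active_richness": active,
            "union_richness": union,
            "dormant_fraction": frac,
            "defined": union > 0,
        },
        index=pd.Index(pc.pair_ids, name="pair_id"),
    )


def shared_fraction(pc: PairedCommunity, presence_threshold: int = 1):
    """Fraction of DNA-detected taxa also detected in the paired RNA library.

    Returns ``(per_pair, summary)`` where ``summary`` holds the mean and sd
    over pairs with a nonempty DNA detection set; DNA-empty pairs are
    undefined and excluded with a warning.
    """
    rna = pc.active.presence(presence_threshold).to_numpy()
    dna = pc.total.presence(presence_threshold).to_numpy()
    n_dna = dna.sum(axis=0)
    n_both = (rna & dna).sum(axis=0)
    with np.errstate(invalid="ignore", divide="ignore"):
        frac = np.where(n_dna > 0, n_both / np.maximum(n_dna, 1), np.nan)
    per_pair = pd.Series(frac, index=pd.Index(pc.pair_ids, name="pair_id"), name="shared_fraction")
    if np.isnan(frac).any():
        warnings.warn(
            f"{int(np.isnan(frac).sum())} pair(s) with empty DNA detection excluded from summary",
            stacklevel=2,
        )
    valid = per_pair.dropna()
    summary = {
        "mean": float(valid.mean()) if len(valid) else float("nan"),
        "sd": float(valid.std(ddof=1)) if len(valid) > 1 else float("nan"),
        "n_pairs": int(len(valid)),
    }
    return per_pair, summary


@dataclass
class CoreConfig:
    """Occupancy threshold tau and detection threshold for core membership."""

    occupancy_threshold: float = 0.95
    presence_threshold: int = 1
    frequently_inactive_cutoff: float = 0.5

    def __post_init__(self) -> None:
        if not (0 < self.occupancy_threshold <= 1):
            raise ValidationError("occupancy_threshold must be in (0, 1]")
        if self.presence_threshold < 1:
            raise ValidationError("presence_threshold must be >= 1")


@dataclass
class CoreReport:
    """Per-taxon occupancy/core/activity table plus the derived listings."""

    taxa: pd.DataFrame
    occupancy_threshold: float
    frequently_inactive: list[str] = field(default_factory=list)
    active_core_only: list[str] = field(default_factory=list)

    @property
    def core_total(self) -> list[str]:
        return list(self.taxa.index[self.taxa["is_core_total"]])

    @property
    def core_active(self) -> list[str]:
        return list(self.taxa.index[self.taxa["is_core_active"]])

    def to_dict(self) -> dict:
        return {
            "occupancy_threshold": self.occupancy_threshold,
            "n_core_total": len(self.core_total),
            "n_core_active": len(self.core_active),
            "frequently_inactive": self.frequently_inactive,
            "active_core_only": self.active_core_only,
            "taxa": self.taxa.reset_index().to_dict(orient="records"),
        }


def core_report(pc: PairedCommunity, config: CoreConfig | None = None) -> CoreReport:
    """Total and active core microbiomes plus per-taxon activity frequency.

    Occupancies are computed within each assay over that assay's samples.
    ``activity_frequency`` is the fraction of a taxon's total-community
    (DNA) occurrences in which it was also RNA-detected; it is NaN for taxa
    never DNA-detected. The report lists total-core taxa that are frequently
    inactive (activity frequency below the configured cutoff) and active-core
    taxa absent from the total core.
    """
    config = config or CoreConfig()
    tau = config.occupancy_threshold
    thr = config.presence_threshold

    occ_total = occupancy(pc.total, thr)
    occ_active = occupancy(pc.active, thr)
    rna = pc.active.presence(thr).to_numpy()
    dna = pc.total.presence(thr).to_numpy()
    n_dna = dna.sum(axis=1)
    n_both = (rna & dna).sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        act_freq = np.where(n_dna > 0, n_both / np.maximum(n_dna, 1), np.nan)

    taxa = pd.DataFrame(
        {
            "occupancy_total": occ_total,
            "occupancy_active": occ_active,
            "is_core_total": occ_total >= tau,
            "is_core_active": occ_active >= tau,
            "activity_frequency": act_freq,
            "n_occurrences_total": n_dna,
        },
        index=pd.Index(pc.taxon_universe, name="taxon_id"),
    )
    freq_inactive = list(
        taxa.index[
            taxa["is_core_total"]
            & (taxa["activity_frequency"] < config.frequently_inactive_cutoff)
        ]
    )
    active_only = list(taxa.index[taxa["is_core_active"] & ~taxa["is_core_total"]])
    return CoreReport(
        taxa=taxa,
        occupancy_threshold=tau,
        frequently_inactive=freq_inactive,
        active_core_only=active_only,
    )
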