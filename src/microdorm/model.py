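"""Core containers for paired RNA/DNA (active vs total) amplicon studies.

A physical sample yields two amplicon libraries: one from DNA, profiling the
*total* community (active + dormant + relic DNA), and one from cDNA/RNA,
profiling the *active* community. The containers here hold one count table
per library (:class:`FeatureTable`), the sampling design
(:class:`SampleMetadata`), the aligned pair structure
(:class:`PairedCommunity`), plot-level environmental covariates
(:class:`EnvMatrix`) and a ranked taxonomy (:class:`TaxonomyMap`).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

MARKERS = ("ITS2", "16S")
ASSAYS = ("RNA", "DNA")
SITE_TYPES = ("riparian", "mid_elevation", "high_elevation")
SEASONS = ("June", "August", "October")

REQUIRED_METADATA_COLUMNS = ("site_type", "site", "plot", "season", "assay", "pair_id")

TAXONOMY_RANKS = ("kingdom", "phylum", "class", "order", "family", "genus", "species")


class ValidationError(ValueError):
    """Raised when a container violates one of its invariants."""


@dataclass
class FeatureTable:
    """Integer count matrix, taxa as rows, samples as columns, for one assay.

    Parameters
    ----------
    data : pandas.DataFrame
        Non-negative integer counts; index = taxon ids, columns = sample ids.
    marker : {"ITS2", "16S"}
    assay : {"RNA", "DNA"}
    """

    data: pd.DataFrame
    marker: str
    assay: str

    def __post_init__(self) -> None:
        if not isinstance(self.data, pd.DataFrame):
            self.data = pd.DataFrame(self.data)
        if self.marker not in MARKERS:
            raise ValidationError(f"marker must be one of {MARKERS}, got {self.marker!r}")
        if self.assay not in ASSAYS:
            raise ValidationError(f"assay must be one of {ASSAYS}, got {self.assay!r}")
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate taxon ids: {dups}")
        if self.data.columns.has_duplicates:
            dups = self.data.columns[self.data.columns.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids: {dups}")
        values = self.data.to_numpy()
        if values.size and not np.issubdtype(values.dtype, np.integer):
            rounded = np.rint(values)
            if not np.allclose(values, rounded, rtol=0, atol=1e-9):
                bad = np.argwhere(values != rounded)
                t, s = bad[0]
                raise ValidationError(
                    "non-integral count at taxon "
                    f"{self.data.index[t]!r}, sample {self.data.columns[s]!r}: {values[t, s]}"
                )
            self.data = self.data.astype(np.int64)
            values = self.data.to_numpy()
        if values.size and values.min() < 0:
            bad = np.argwhere(values < 0)
            t, s = bad[0]
            raise ValidationError(
                "negative count at taxon "
                f"{self.data.index[t]!r}, sample {self.data.columns[s]!r}: {values[t, s]}"
            )

    @property
    def taxon_ids(self) -> list[str]:
        return list(self.data.index)

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.columns)

    @property
    def counts(self) -> np.ndarray:
        return self.data.to_numpy()

    @property
    def n_taxa(self) -> int:
        return self.data.shape[0]

    @property
    def n_samples(self) -> int:
        return self.data.shape[1]

    def sample_sums(self) -> pd.Series:
        return self.data.sum(axis=0)

    def presence(self, threshold: int = 1) -> pd.DataFrame:
        """Boolean detection matrix: count >= ``threshold``."""
        if threshold < 1:
            raise ValidationError("presence threshold must be >= 1")
        return self.data >= threshold

    def select_samples(self, sample_ids) -> "FeatureTable":
        missing = [s for s in sample_ids if s not in self.data.columns]
        if missing:
            raise KeyError(f"samples not in table: {missing}")
        return FeatureTable(self.data.loc[:, list(sample_ids)].copy(), self.marker, self.assay)

    def reindex_taxa(self, taxon_universe) -> "FeatureTable":
        """Zero-fill onto a taxon universe (superset of current taxa)."""
        data = self.data.reindex(index=list(taxon_universe), fill_value=0)
        return FeatureTable(data, self.marker, self.assay)

    def copy(self) -> "FeatureTable":
        return FeatureTable(self.data.copy(), self.marker, self.assay)


@dataclass
class SampleMetadata:
    """Per-library sample annotations keyed by sample id.

    Required columns: site_type, site, plot, season, assay, pair_id.
    Unknown extra columns are preserved as opaque covariates.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            dups = self.data.index[self.data.index.duplicated()].unique().tolist()
            raise ValidationError(f"duplicate sample ids in metadata: {dups}")
        missing = [c for c in REQUIRED_METADATA_COLUMNS if c not in self.data.columns]
        if missing:
            raise ValidationError(f"metadata missing required columns: {missing}")
        bad_assay = set(self.data["assay"]) - set(ASSAYS)
        if bad_assay:
            raise ValidationError(f"invalid assay values {sorted(bad_assay)}; allowed: {ASSAYS}")
        bad_season = set(self.data["season"]) - set(SEASONS)
        if bad_season:
            raise ValidationError(
                f"invalid season values {sorted(bad_season)}; allowed levels: {SEASONS}"
            )
        bad_type = set(self.data["site_type"]) - set(SITE_TYPES)
        if bad_type:
            raise ValidationError(
                f"invalid site_type values {sorted(bad_type)}; allowed: {SITE_TYPES}"
            )
        # each pair id carries at most one library per assay (per marker when given)
        keys = ["pair_id", "assay"] + (["marker"] if "marker" in self.data.columns else [])
        counts = self.data.groupby(keys, observed=True).size()
        if (counts > 1).any():
            offending = counts[counts > 1].index.tolist()
            raise ValidationError(f"pair_id with multiple libraries for one assay: {offending}")

    @property
    def sample_ids(self) -> list[str]:
        return list(self.data.index)

    def for_samples(self, sample_ids) -> pd.DataFrame:
        missing = [s for s in sample_ids if s not in self.data.index]
        if missing:
            raise ValidationError(f"samples without metadata rows: {missing}")
        return self.data.loc[list(sample_ids)]

    def pairs(self) -> pd.DataFrame:
        """Pair table: one row per pair_id with ``rna_sample``/``dna_sample``
        columns (NaN when an assay is missing)."""
        wide = (
            self.data.reset_index(names="sample_id")
            .pivot_table(index="pair_id", columns="assay", values="sample_id", aggfunc="first")
            .rename(columns={"RNA": "rna_sample", "DNA": "dna_sample"})
        )
        for col in ("rna_sample", "dna_sample"):
            if col not in wide.columns:
                wide[col] = np.nan
        return wide[["rna_sample", "dna_sample"]]


@dataclass
class PairedCommunity:
    """RNA and DNA feature tables aligned on pair ids over a shared taxon set.

    Columns of both tables are relabeled to pair ids and ordered identically;
    rows span the union taxon universe (zero-filled).
    """

    active: FeatureTable
    total: FeatureTable
    pair_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.active.assay != "RNA" or self.total.assay != "DNA":
            raise ValidationError("active table must be RNA, total table must be DNA")
        if self.active.marker != self.total.marker:
            raise ValidationError("active and total tables must share a marker")
        if list(self.active.data.columns) != list(self.pair_ids) or list(
            self.total.data.columns
        ) != list(self.pair_ids):
            raise ValidationError("table columns must be aligned to pair_ids")
        if list(self.active.data.index) != list(self.total.data.index):
            raise ValidationError("tables must share an identical taxon universe ordering")

    @property
    def taxon_universe(self) -> list[str]:
        return list(self.active.data.index)

    @property
    def marker(self) -> str:
        return self.active.marker

    @property
    def n_pairs(self) -> int:
        return len(self.pair_ids)


@dataclass
class EnvMatrix:
    """Numeric environmental covariates attached at plot level.

    ``data`` has one row per plot with ``site`` and ``plot`` columns plus
    named numeric covariates. Covariates measured at site level (e.g. sensor
    temperature) are simply constant within a site.
    """

    data: pd.DataFrame

    def __post_init__(self) -> None:
        for col in ("site", "plot"):
            if col not in self.data.columns:
                raise ValidationError(f"EnvMatrix missing required column {col!r}")
        if self.data.duplicated(subset=["site", "plot"]).any():
            raise ValidationError("duplicate (site, plot) rows in EnvMatrix")
        if self.data.columns.has_duplicates:
            raise ValidationError("duplicate covariate names in EnvMatrix")

    @property
    def covariates(self) -> list[str]:
        return [c for c in self.data.columns if c not in ("site", "plot")]

    def plot_index(self) -> pd.DataFrame:
        return self.data.set_index(["site", "plot"])


@dataclass
class TaxonomyMap:
    """Taxon id -> ranked lineage (kingdom..species; missing ranks allowed)."""

    data: pd.DataFrame

    def __post_init__(self) -> None:
        if self.data.index.has_duplicates:
            raise ValidationError("duplicate taxon ids in taxonomy map")
        unknown = [c for c in self.data.columns if c not in TAXONOMY_RANKS]
        if unknown:
            raise ValidationError(f"unknown taxonomy ranks: {unknown}")
        # keep canonical rank order
        ordered = [r for r in TAXONOMY_RANKS if r in self.data.columns]
        self.data = self.data[ordered]

    def lineage(self, taxon_id: str) -> dict:
        return self.data.loc[taxon_id].to_dict()

    def rank(self, rank: str) -> pd.Series:
        if rank not in self.data.columns:
            raise ValidationError(f"rank {rank!r} not present in taxonomy map")
        return self.data[rank]
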