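"""Count-table preprocessing: rarefaction, proportions, the square-root +
Wisconsin double-standardization chain, CLR, and taxonomy-level aggregation.

Rarefaction subsamples each library without replacement to a common depth
(multivariate hypergeometric draw), dropping libraries below the depth.
Wisconsin double standardization divides each taxon row by its maximum and
then each sample column by its total — exactly in that order, the convention
of the classical ecology packages.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .model import FeatureTable, TaxonomyMap, ValidationError

logger = logging.getLogger(__name__)

# marker-specific default depths for surveys of this design
DEFAULT_DEPTHS = {"16S": 13407, "ITS2": 17182}


@dataclass
class PreprocessConfig:
    """Rarefaction depth, RNG seed and detection threshold."""

    rarefaction_depth: int = 17182
    seed: int = 0
    presence_threshold: int = 1

    def __post_init__(self) -> None:
        if self.rarefaction_depth < 1:
            raise ValidationError("rarefaction_depth must be >= 1")
        if self.presence_threshold < 1:
            raise ValidationError("presence_threshold must be >= 1")


def rarefy(
    table: FeatureTable,
    depth: int,
    seed: int = 0,
    return_dropped: bool = False,
):
    """Subsample every library to ``depth`` reads without replacement.

    Samples whose total is below ``depth`` are dropped (and logged); samples
    exactly at depth pass through unchanged. Deterministic for a given seed.
    """
    if depth < 1:
        raise ValidationError("rarefaction depth must be >= 1")
    sums = table.sample_sums()
    keep = [s for s in table.sample_ids if sums[s] >= depth]
    dropped = [s for s in table.sample_ids if sums[s] < depth]
    if not keep:
        raise ValidationError(f"all {table.n_samples} samples are below depth {depth}")
    if dropped:
        logger.info(
            "rarefy: dropped %d of %d samples below depth %d: %s",
            len(dropped), table.n_samples, depth, dropped,
        )
    rng = np.random.default_rng(seed)
    out = np.empty((table.n_taxa, len(keep)), dtype=np.int64)
    counts = table.data[keep].to_numpy()
    for j in range(len(keep)):
        col = counts[:, j]
        if col.sum() == depth:
            out[:, j] = col
        else:
            out[:, j] = rng.multivariate_hypergeometric(col, depth)
    result = FeatureTable(
        pd.DataFrame(out, index=table.taxon_ids, columns=keep), table.marker, table.assay
    )
    if return_dropped:
        return result, dropped
    return result


def relative_abundance(table) -> pd.DataFrame:
    """Column-wise proportions (each sample sums to 1)."""
    df = table.data if isinstance(table, FeatureTable) else pd.DataFrame(table)
    sums = df.sum(axis=0)
    zero = sums[sums == 0]
    if len(zero):
        raise ValidationError(f"all-zero sample(s): {list(zero.index)}")
    return df / sums


def sqrt_wisconsin(matrix) -> pd.DataFrame:
    """Element-wise square root, then Wisconsin double standardization.

    Order is fixed: (1) sqrt; (2) divide each taxon row by its row maximum;
    (3) divide each sample column by its column total. All-zero taxon rows
    are dropped with a warning; an all-zero sample is an error.
    """
    df = matrix.data if isinstance(matrix, FeatureTable) else pd.DataFrame(matrix)
    if (df.to_numpy() < 0).any():
        raise ValidationError("sqrt_wisconsin requires non-negative entries")
    zero_rows = df.index[(df == 0).all(axis=1)]
    if len(zero_rows):
        warnings.warn(f"dropping {len(zero_rows)} all-zero taxon rows", stacklevel=2)
        df = df.drop(index=zero_rows)
    zero_cols = df.columns[(df == 0).all(axis=0)]
    if len(zero_cols):
        raise ValidationError(f"all-zero sample(s): {list(zero_cols)}")
    out = np.sqrt(df.astype(float))
    out = out.div(out.max(axis=1), axis=0)
    out = out.div(out.sum(axis=0), axis=1)
    return out


def clr_transform(matrix, pseudocount: float = 0.5) -> pd.DataFrame:
    """Centered log-ratio transform of counts with a pseudocount.

    Per sample: log(x + pseudocount) centered by the sample mean log, so each
    column sums to zero.
    """
    if pseudocount <= 0:
        raise ValidationError("pseudocount must be positive")
    df = matrix.data if isinstance(matrix, FeatureTable) else pd.DataFrame(matrix)
    logs = np.log(df.astype(float) + pseudocount)
    return logs - logs.mean(axis=0)


def aggregate_taxonomy(
    table: FeatureTable,
    taxonomy: TaxonomyMap,
    rank: str,
    min_mean_abundance: float = 0.0,
) -> FeatureTable:
    """Sum counts within a taxonomic rank.

    Groups whose mean relative abundance across samples falls below
    ``min_mean_abundance`` are pooled into ``"other"``; taxa missing from the
    map (or unannotated at the rank) are pooled into ``"unassigned"``.
    Total counts are conserved.
    """
    if taxonomy.data.empty:
        raise ValidationError("taxonomy map is empty")
    lineage = taxonomy.rank(rank)
    labels = pd.Series(
        [
            lineage.get(t) if pd.notna(lineage.get(t)) and lineage.get(t) else "unassigned"
            for t in table.taxon_ids
        ],
        index=table.data.index,
    ).fillna("unassigned")
    grouped = table.data.groupby(labels).sum()
    if min_mean_abundance > 0:
        rel = relative_abundance(grouped)
        low = rel.mean(axis=1) < min_mean_abundance
        low = low & (grouped.index != "unassigned")
        if low.any():
            other = grouped.loc[low].sum(axis=0)
            grouped = grouped.loc[~low]
            grouped.loc["other"] = other
    return FeatureTable(grouped, table.marker, table.assay)
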