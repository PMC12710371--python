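"""Readers and writers for the plain-text formats the pipeline touches.

Feature tables are TSV (taxa as rows, header = sample ids) or BIOM 1.0 JSON
(dense or sparse); metadata follows the QIIME-style convention of a
``#SampleID`` (or ``sample_id``) first column; distance matrices are square
TSV with matching row/column ids; reports are JSON stamped with a
``schema_version`` field.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
from skbio.stats.distance import DistanceMatrix

from .model import (
    EnvMatrix,
    FeatureTable,
    PairedCommunity,
    SampleMetadata,
    TaxonomyMap,
    ValidationError,
)

SCHEMA_VERSION = "microdorm/1"


def read_feature_table(
    path, format: str = "tsv", marker: str = "ITS2", assay: str = "DNA"
) -> FeatureTable:
    """Read a taxa x samples count table from TSV or BIOM 1.0 JSON."""
    path = Path(path)
    if format == "tsv":
        df = pd.read_csv(path, sep="\t", index_col=0)
        df.index = df.index.astype(str)
        df.columns = df.columns.astype(str)
        df.index.name = None
        df.columns.name = None
        return FeatureTable(df, marker=marker, assay=assay)
    if format == "biom_json":
        return _read_biom_json(path, marker=marker, assay=assay)
    raise ValueError(f"unknown feature-table format {format!r}")


def _read_biom_json(path: Path, marker: str, assay: str) -> FeatureTable:
    with open(path) as fh:
        doc = json.load(fh)
    rows = [r["id"] for r in doc["rows"]]
    cols = [c["id"] for c in doc["columns"]]
    shape = tuple(doc["shape"])
    if shape != (len(rows), len(cols)):
        raise ValidationError(f"BIOM shape {shape} does not match id lists")
    mat = np.zeros(shape)
    if doc["matrix_type"] == "dense":
        mat[:] = np.asarray(doc["data"], dtype=float)
    elif doc["matrix_type"] == "sparse":
        for i, j, v in doc["data"]:
            mat[int(i), int(j)] = v
    else:
        raise ValidationError(f"unsupported BIOM matrix_type {doc['matrix_type']!r}")
    return FeatureTable(pd.DataFrame(mat, index=rows, columns=cols), marker=marker, assay=assay)


def write_feature_table(table: FeatureTable, path) -> None:
    df = table.data.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def write_biom_json(table: FeatureTable, path, sparse: bool = True) -> None:
    """Write a FeatureTable as BIOM 1.0 JSON."""
    mat = table.counts
    if sparse:
        nz = np.argwhere(mat != 0)
        data = [[int(i), int(j), int(mat[i, j])] for i, j in nz]
        matrix_type = "sparse"
    else:
        data = mat.tolist()
        matrix_type = "dense"
    doc = {
        "id": None,
        "format": "Biological Observation Matrix 1.0.0",
        "format_url": "http://biom-format.org",
        "type": "OTU table",
        "generated_by": SCHEMA_VERSION,
        "date": "",
        "matrix_type": matrix_type,
        "matrix_element_type": "int",
        "shape": list(mat.shape),
        "rows": [{"id": t, "metadata": None} for t in table.taxon_ids],
        "columns": [{"id": s, "metadata": None} for s in table.sample_ids],
        "data": data,
    }
    with open(path, "w") as fh:
        json.dump(doc, fh)


def read_metadata(path) -> SampleMetadata:
    """Read a sample metadata TSV (first column ``#SampleID`` or ``sample_id``)."""
    df = pd.read_csv(path, sep="\t", dtype=str)
    first = df.columns[0]
    if first not in ("#SampleID", "sample_id"):
        raise ValidationError(
            f"first metadata column must be '#SampleID' or 'sample_id', got {first!r}"
        )
    df = df.rename(columns={first: "sample_id"}).set_index("sample_id")
    return SampleMetadata(df)


def write_metadata(meta: SampleMetadata, path) -> None:
    df = meta.data.copy()
    df.index.name = "#SampleID"
    df.to_csv(path, sep="\t")


def read_env_matrix(path) -> EnvMatrix:
    df = pd.read_csv(path, sep="\t", dtype={"site": str, "plot": str})
    return EnvMatrix(df)


def write_env_matrix(env: EnvMatrix, path) -> None:
    env.data.to_csv(path, sep="\t", index=False)


def read_taxonomy(path) -> TaxonomyMap:
    df = pd.read_csv(path, sep="\t", index_col=0, dtype=str)
    return TaxonomyMap(df)


def write_taxonomy(tax: TaxonomyMap, path) -> None:
    df = tax.data.copy()
    df.index.name = "taxon_id"
    df.to_csv(path, sep="\t")


def read_distance_matrix(path) -> DistanceMatrix:
    df = pd.read_csv(path, sep="\t", index_col=0)
    if list(df.index) != list(df.columns):
        raise ValidationError("distance matrix row and column ids differ")
    return DistanceMatrix(df.to_numpy(), ids=[str(i) for i in df.index])


def write_distance_matrix(dm: DistanceMatrix, path) -> None:
    pd.DataFrame(dm.data, index=dm.ids, columns=dm.ids).to_csv(path, sep="\t")


def write_report(obj: dict, path) -> None:
    """Write a JSON report stamped with the schema version."""
    doc = {"schema_version": SCHEMA_VERSION}
    doc.update(obj)
    with open(path, "w") as fh:
        json.dump(doc, fh, indent=2, default=_json_default)


def read_report(path) -> dict:
    with open(path) as fh:
        return json.load(fh)


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    if isinstance(o, pd.DataFrame):
        return o.to_dict(orient="index")
    if isinstance(o, pd.Series):
        return o.to_dict()
    raise TypeError(f"cannot serialize {type(o)}")


def align_pairs(
    active: FeatureTable, total: FeatureTable, meta: SampleMetadata
) -> PairedCommunity:
    """Align an RNA and a DNA table into a :class:`PairedCommunity`.

    Only pair ids with both assays present in the respective tables are kept;
    both tables are zero-filled onto the union taxon universe and their
    columns relabeled to the pair ids, identically ordered.
    """
    if active.assay != "RNA":
        raise ValidationError(f"active table must be RNA, got {active.assay}")
    if total.assay != "DNA":
        raise ValidationError(f"total table must be DNA, got {total.assay}")
    if active.marker != total.marker:
        raise ValidationError("tables have different markers")

    pairs = meta.pairs()
    keep = pairs[
        pairs["rna_sample"].isin(active.sample_ids) & pairs["dna_sample"].isin(total.sample_ids)
    ]
    if keep.empty:
        raise ValidationError("no pair_id has both an RNA and a DNA library present")
    pair_ids = sorted(keep.index)

    universe = sorted(set(active.taxon_ids) | set(total.taxon_ids))
    rna = active.select_samples(keep.loc[pair_ids, "rna_sample"]).reindex_taxa(universe)
    dna = total.select_samples(keep.loc[pair_ids, "dna_sample"]).reindex_taxa(universe)
    rna.data.columns = pair_ids
    dna.data.columns = pair_ids
    return PairedCommunity(active=rna, total=dna, pair_ids=pair_ids)
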