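import numpy as np
import pandas as pd
import pytest

from microdorm.model import FeatureTable, PairedCommunity, SampleMetadata


def make_paired(rna_sets, dna_sets, taxa=None, count=5, marker="ITS2"):
    """Build a PairedCommunity from per-pair detection sets."""
    pairs = [f"p{i}" for i in range(len(rna_sets))]
    if taxa is None:
        taxa = sorted(set().union(*rna_sets, *dna_sets))

    def table(sets, assay):
        m = pd.DataFrame(0, index=list(taxa), columns=pairs)
        for p, s in zip(pairs, sets):
            for t in s:
                m.loc[t, p] = count
        return FeatureTable(m, marker, assay)

    return PairedCommunity(table(rna_sets, "RNA"), table(dna_sets, "DNA"), pairs)


def random_feature_table(rng, n_taxa=8, n_samples=6, assay="DNA", lam=5.0):
    counts = rng.poisson(lam, size=(n_taxa, n_samples))
    return FeatureTable(
        pd.DataFrame(
            counts,
            index=[f"t{i}" for i in range(n_taxa)],
            columns=[f"s{j}" for j in range(n_samples)],
        ),
        "ITS2",
        assay,
    )


@pytest.fixture
def tiny_metadata():
    """Two pairs x two assays with a full design block."""
    rows = []
    for pid, (st, site, plot, season) in {
        "pA": ("riparian", "S1", "P1", "June"),
        "pB": ("mid_elevation", "S2", "P1", "August"),
    }.items():
        for assay in ("RNA", "DNA"):
            rows.append(
                {
                    "sample_id": f"{pid}-{assay}",
                    "site_type": st,
                    "site": site,
                    "plot": plot,
                    "season": season,
                    "assay": assay,
                    "pair_id": pid,
                }
            )
    return SampleMetadata(pd.DataFrame(rows).set_index("sample_id"))


@pytest.fixture
def vegan_fixture():
    """Deterministic 8-taxa x 12-sample fixture with a 2-factor design.

    Expected statistics for this fixture were computed independently with R
    vegan 2.7 (adonis2 by="terms", betadisper type="centroid", mantel) and
    are frozen in the tests that consume it.
    """
    rng = np.random.default_rng(42)
    counts = rng.integers(0, 50, size=(8, 12))
    ids = [f"s{i}" for i in range(12)]
    df = pd.DataFrame(counts, index=[f"t{i}" for i in range(8)], columns=ids)
    meta = pd.DataFrame({"g": ["a"] * 6 + ["b"] * 6, "h": ["x", "y"] * 6}, index=ids)
    return df, meta
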