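import numpy as np
import pandas as pd
import pytest
from statsmodels.stats.multitest import multipletests

from microdorm.diffabund import (
    DiffAbundConfig,
    active_vs_total_enrichment,
    da_test,
    overlap_summary,
    seasonal_delta_contrast,
)
from microdorm.model import FeatureTable, PairedCommunity, ValidationError
from microdorm.simulate import SyntheticParams, PlantedEnriched, generate


def bh_stepup(pvals):
    """Independent hand implementation of the Benjamini-Hochberg step-up."""
    p = np.asarray(pvals, dtype=float)
    order = np.argsort(p)
    n = len(p)
    adj = np.empty(n)
    running = 1.0
    for rank in range(n, 0, -1):
        i = order[rank - 1]
        running = min(running, p[i] * n / rank)
        adj[i] = running
    return adj


def make_site_table(rng, n_taxa=12, n_sites=3, n_per=8, effect=None):
    """Counts for n_sites blocks with a 2-level condition inside each."""
    samples, cond, site = [], [], []
    for s in range(n_sites):
        for k in range(n_per):
            samples.append(f"S{s}-{k}")
            site.append(f"S{s}")
            cond.append("early" if k < n_per // 2 else "late")
    base = rng.lognormal(3, 0.5, size=(n_taxa, 1))
    lam = np.tile(base, (1, len(samples)))
    if effect is not None:
        for taxon, mult in effect.items():
            lam[taxon, np.array(cond) == "late"] *= mult
    counts = rng.poisson(lam)
    table = FeatureTable(
        pd.DataFrame(counts, index=[f"t{i}" for i in range(n_taxa)], columns=samples),
        "ITS2",
        "DNA",
    )
    meta = pd.DataFrame({"condition": cond, "site": site}, index=samples)
    return table, meta


class TestBenjaminiHochberg:
    def test_textbook_step_up_case(self):
        # (0.01, 0.02, 0.03, 0.04) all adjust to 0.04
        adj = multipletests([0.01, 0.02, 0.03, 0.04], method="fdr_bh")[1]
        np.testing.assert_allclose(adj, 0.04)
        np.testing.assert_allclose(bh_stepup([0.01, 0.02, 0.03, 0.04]), adj)

    def test_matches_hand_oracle_on_random_p(self):
        rng = np.random.default_rng(0)
        for _ in range(100):
            p = rng.random(rng.integers(2, 15))
            np.testing.assert_allclose(
                multipletests(p, method="fdr_bh")[1], bh_stepup(p), atol=1e-12
            )

    def test_adjusted_monotone_in_rank_and_bounded(self):
        rng = np.random.default_rng(1)
        p = rng.random(30)
        adj = multipletests(p, method="fdr_bh")[1]
        order = np.argsort(p)
        assert (np.diff(adj[order]) >= -1e-12).all()
        assert (adj >= p - 1e-12).all() and (adj <= 1.0).all()


class TestDaTest:
    def test_null_identical_groups(self):
        rng = np.random.default_rng(2)
        table, meta = make_site_table(rng)
        res = da_test(table, meta, "condition", "site",
                      DiffAbundConfig(n_perm=99, seed=0, min_prevalence=0.0))
        t = res.table[res.table["tested"]]
        assert np.abs(t["log2FC"]).mean() < 0.5
        assert (t["p_adj"] < 0.05).sum() <= 2

    def test_planted_effect_detected_with_direction(self):
        rng = np.random.default_rng(3)
        table, meta = make_site_table(rng, effect={0: 6.0, 1: 6.0})
        res = da_test(table, meta, "condition", "site",
                      DiffAbundConfig(n_perm=199, seed=0))
        t = res.table
        assert (t.loc[["t0", "t1"], "p_adj"] < 0.05).all()
        assert (t.loc[["t0", "t1"], "log2FC"].abs() > 1).all()
        assert (t.loc[["t0", "t1"], "max_group"] == "late").all()

    def test_prevalence_filter_marks_untested(self):
        rng = np.random.default_rng(4)
        table, meta = make_site_table(rng)
        table.data.iloc[5, :] = 0
        table.data.iloc[5, 0] = 1  # present in 1/24 samples < 10%
        res = da_test(table, meta, "condition", "site", DiffAbundConfig(n_perm=19, seed=0))
        row = res.table.loc["t5"]
        assert not row["tested"]
        assert np.isnan(row["p"])

    def test_confounded_term_rejected(self):
        rng = np.random.default_rng(5)
        table, meta = make_site_table(rng)
        meta = meta.assign(condition=meta["site"])  # term == block
        with pytest.raises(ValidationError, match="confounded"):
            da_test(table, meta, "condition", "site", DiffAbundConfig(n_perm=9))


@pytest.fixture(scope="module")
def planted():
    # n_perm must outrun the BH floor: smallest achievable adjusted p is
    # roughly n_tested / (k_true * (n_perm + 1))
    params = SyntheticParams(
        n_taxa=150, depth=8000, core_taxa=[],
        enriched_taxa=[PlantedEnriched(n=6, ratio=4.0)],
        season_activity_amplitude=0.0, activity_prob_range=(1.0, 1.0), seed=7,
    )
    ds = generate(params)
    cfg = DiffAbundConfig(n_perm=1999, seed=1)
    return ds, active_vs_total_enrichment(ds.paired, cfg)


class TestEnrichment:

    def test_planted_ratio_recovered_as_active_enriched(self, planted):
        ds, res = planted
        ids = list(ds.truth["enriched_taxa"])
        rows = res.table.loc[ids]
        assert (rows["direction"] == "active-enriched").all()
        # RNA:DNA = 4 => log2FC close to 2 on the CLR scale
        np.testing.assert_allclose(rows["log2FC"], 2.0, atol=0.5)

    def test_false_enrichment_rare(self, planted):
        ds, res = planted
        ids = set(ds.truth["enriched_taxa"])
        false = [t for t in res.table.index[res.table["enriched"]] if t not in ids]
        assert len(false) <= max(1, int(0.05 * (1 + res.table["enriched"].sum())))

    def test_label_swap_negates_log2fc(self):
        params = SyntheticParams(n_taxa=60, depth=4000, core_taxa=[], enriched_taxa=[], seed=9)
        ds = generate(params)
        pc = ds.paired
        swapped = PairedCommunity(
            active=FeatureTable(pc.total.data.copy(), pc.marker, "RNA"),
            total=FeatureTable(pc.active.data.copy(), pc.marker, "DNA"),
            pair_ids=pc.pair_ids,
        )
        cfg = DiffAbundConfig(n_perm=9, seed=0)
        a = active_vs_total_enrichment(pc, cfg).table["log2FC"]
        b = active_vs_total_enrichment(swapped, cfg).table["log2FC"]
        np.testing.assert_allclose(a, -b, atol=1e-10)

    def test_rna_absent_taxon_is_total_enriched(self):
        # taxon abundant in DNA, absent in RNA everywhere
        pairs = [f"p{i}" for i in range(20)]
        taxa = [f"t{i}" for i in range(5)]
        rng = np.random.default_rng(11)
        dna = pd.DataFrame(rng.poisson(50, (5, 20)) + 1, index=taxa, columns=pairs)
        rna = dna.copy()
        rna.loc["t0"] = 0
        pc = PairedCommunity(
            FeatureTable(rna, "ITS2", "RNA"), FeatureTable(dna, "ITS2", "DNA"), pairs
        )
        res = active_vs_total_enrichment(pc, DiffAbundConfig(n_perm=99, seed=0))
        row = res.table.loc["t0"]
        assert row["direction"] == "total-enriched"
        assert row["log2FC"] == res.table["log2FC"].min()


class TestOverlapSummary:
    def _result(self, taxa, sig):
        t = pd.DataFrame(
            {"p_adj": [0.01 if x in sig else 0.9 for x in taxa],
             "tested": True, "log2FC": 0.0, "p": 0.5, "max_group": "", "statistic": 1.0},
            index=pd.Index(taxa, name="taxon_id"),
        )
        from microdorm.diffabund import DiffAbundResult
        return DiffAbundResult(t, "x", "b", DiffAbundConfig())

    def test_venn_counts(self):
        taxa = [f"t{i}" for i in range(10)]
        a = self._result(taxa, {"t0", "t1", "t2", "t3"})
        b = self._result(taxa, {"t3", "t4", "t5"})
        out = overlap_summary(a, b, labels=("site", "season"))
        assert out.loc["site_only", "count"] == 3
        assert out.loc["season_only", "count"] == 2
        assert out.loc["both", "count"] == 1
        assert out.loc["neither", "count"] == 4

    def test_identical_and_disjoint_sets(self):
        taxa = [f"t{i}" for i in range(6)]
        a = self._result(taxa, {"t0", "t1"})
        assert overlap_summary(a, a).loc["both", "count"] == 2
        b = self._result(taxa, {"t2"})
        assert overlap_summary(a, b).loc["both", "count"] == 0

    def test_mismatched_universe_rejected(self):
        a = self._result(["t0"], set())
        b = self._result(["t1"], set())
        with pytest.raises(ValidationError):
            overlap_summary(a, b)


class TestSeasonalDeltaContrast:
    def _dataset(self, rng, decline_sites=(), n_sites=6, n_plots=4):
        samples, rows = [], []
        counts = {}
        for s in range(n_sites):
            site = f"S{s}"
            for p in range(n_plots):
                for season in ("June", "August"):
                    sid = f"{site}-P{p}-{season}"
                    samples.append(sid)
                    rows.append(
                        {"site_type": "riparian", "site": site, "plot": f"P{p}",
                         "season": season, "assay": "DNA", "pair_id": sid}
                    )
                    depth = 1000
                    frac = 0.30
                    if season == "August" and site in decline_sites:
                        frac = 0.10
                    target = rng.binomial(depth, frac)
                    counts[sid] = [target, depth - target]
        table = FeatureTable(
            pd.DataFrame(counts, index=["focal", "rest"]), "ITS2", "DNA"
        )
        meta = pd.DataFrame(rows, index=samples)
        return table, meta

    def test_no_change_gives_null(self):
        part = {f"S{s}": ("warm" if s < 3 else "cool") for s in range(6)}
        rejections = 0
        for seed in range(20):
            rng = np.random.default_rng(seed)
            table, meta = self._dataset(rng)
            out = seasonal_delta_contrast(table, meta, ["focal"], "June", "August", part)
            assert abs(out["class_means"]["warm"]) < 0.05
            rejections += out["p"] < 0.05
        assert rejections <= 4

    def test_planted_decline_in_warm_sites_detected(self):
        hits = 0
        for seed in range(20):
            rng = np.random.default_rng(100 + seed)
            warm = {f"S{s}" for s in range(3)}
            table, meta = self._dataset(rng, decline_sites=warm)
            part = {f"S{s}": ("warm" if s < 3 else "cool") for s in range(6)}
            out = seasonal_delta_contrast(table, meta, ["focal"], "June", "August", part)
            hits += out["p"] < 0.05
        assert hits >= 18

    def test_single_site_partition_rejected(self):
        rng = np.random.default_rng(13)
        table, meta = self._dataset(rng, n_sites=3)
        part = {"S0": "warm", "S1": "cool", "S2": "cool"}
        with pytest.raises(ValidationError, match="2 sites"):
            seasonal_delta_contrast(table, meta, ["focal"], "June", "August", part)
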