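# microdorm

Paired RNA/DNA ("active" vs "total") amplicon community analysis: microbial
dormancy, core microbiomes, compositional enrichment screening, and the
permutational community statistics that paired metabarcoding designs call
for.

## The problem

Sequencing a DNA amplicon library profiles the **total** microbial community
of a sample — active cells, dormant cells, and relic DNA alike. Sequencing a
cDNA (RNA) library from the same physical sample profiles the **active**
community, because ribosomal RNA decays quickly outside living, metabolically
active cells. Comparing the two libraries per sample turns a standard
metabarcoding survey into an activity assay:

- a taxon detected in RNA is *active* in that sample;
- a taxon detected only in DNA is *dormant* (or relic);
- the per-sample **dormant fraction** is
  `1 − |RNA-detected| / |RNA-detected ∪ DNA-detected|`;
- the **shared fraction** is the proportion of DNA-detected taxa that are
  also RNA-detected;
- **total** and **active core microbiomes** are the taxa with occupancy
  ≥ τ (default 95%) in the DNA and RNA data sets respectively, and a
  taxon's **activity frequency** is the fraction of its total-community
  occurrences in which it was also active.

`microdorm` implements this activity framework together with the standard
community-ecology machinery it is embedded in: rarefaction, square-root +
Wisconsin double standardization, Bray–Curtis dissimilarity, PCoA, PERMANOVA
with sequential (Type-I) sums of squares and optional within-strata
permutations, beta dispersion, Mantel / partial Mantel distance decay, a
CLR-based differential-abundance screen with blocking and
Benjamini–Hochberg control, and environment-linkage procedures (index
covariates via PCA, tree-ensemble importance screening with
partial-dependence threshold localization, a scale-dependence likelihood
ratio, and logistic presence models). A hierarchical synthetic generator of
paired communities with planted ground truth makes every stage testable end
to end. See `docs/methods.md` for the models and their assumptions.

## Worked example

```python
from microdorm import (SyntheticParams, generate, dormancy_profile,
                       shared_fraction, core_report, sqrt_wisconsin,
                       bray_curtis, permanova)

ds = generate(SyntheticParams(seed=1))      # 3 site types x 3 sites x 5 plots
prof = dormancy_profile(ds.paired)          # x 3 seasons, paired RNA/DNA
print("mean dormant fraction: %.3f" % prof["dormant_fraction"].mean())

per_pair, s = shared_fraction(ds.paired)
print("shared fraction: %.2f +/- %.2f" % (s["mean"], s["sd"]))

rep = core_report(ds.paired)                # occupancy threshold 0.95
print("core: total=%d active=%d frequently_inactive=%d"
      % (len(rep.core_total), len(rep.core_active), len(rep.frequently_inactive)))

meta = ds.metadata.data.drop_duplicates(subset=["pair_id"]).set_index("pair_id")
for label, tab in (("active", ds.paired.active), ("total", ds.paired.total)):
    dm = bray_curtis(sqrt_wisconsin(tab.data))
    res = permanova(dm, meta.loc[list(dm.ids)], ["site_type", "season"],
                    n_perm=199, seed=0)
    print(label, "R2(site_type)=%.3f  R2(season)=%.3f  p(season)=%.3f"
          % (res.r2("site_type"), res.r2("season"), res.p("season")))
```

prints

```
mean dormant fraction: 0.430
shared fraction: 0.55 +/- 0.02
core: total=213 active=9 frequently_inactive=69
active R2(site_type)=0.167  R2(season)=0.176  p(season)=0.005
total R2(site_type)=0.473  R2(season)=0.031  p(season)=0.005
```

Under the generator's defaults, seasonal modulation acts on *activity* more
strongly than on population abundance, so season explains far more
compositional variance in the active community (R² 0.18 vs 0.03) while site
effects — which act on abundance — dominate the total community. The active
core is a small subset of the total core, and many total-core taxa are
frequently inactive: exactly the qualitative structure this kind of paired
survey is designed to expose.

There is also a CLI (`microdorm simulate | dormancy | core | betadiv |
permanova | dispersion | mantel | diffabund | envlink | run`) over the same
functions; `microdorm run --config config.yaml` executes the full pipeline
and writes seed- and hash-stamped reports.

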