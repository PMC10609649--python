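# fraclift

Community-dynamics analysis for **size-fractionated bacterioplankton**:
paired free-living (FL) and particle-attached (PA) 16S OTU tables from
exposure time courses, such as algal cultures treated with the
biosurfactant surfactin. The package is aimed at microbial ecologists
who have an OTU count table, per-sample design metadata, and taxonomy,
and want the standard fraction-aware analysis battery with explicit,
testable definitions.

## What it computes

* **Rarity classes** — abundant (reaches ≥ 1 % in some sample, never
  < 0.01 %), rare (< 0.01 % somewhere, never ≥ 1 %), intermediate.
* **Sensitive OTUs** — OTUs whose mean relative abundance at one
  cultivation period changes more than 10-fold (or below 0.1-fold)
  against another period, per fraction × treatment stratum, with an
  ε-guard for vanishing taxa; plus the `log10`-transformed heatmap
  matrix of the flagged OTUs.
* **PAN index** — the particle-association niche index, an
  abundance-weighted mean of the 0/1 fraction indicator per OTU,

      pan_i = Σ_s w_is · 1[fraction_s = PA] / Σ_s w_is ∈ [0, 1],

  0 = fully free-living, 1 = fully particle-attached, 0.5 = evenly
  spread; with taxon-level mean ± s.e. summaries and FL↔PA
  lifestyle-shift trajectories across periods.
* **Alpha diversity** — richness, Shannon–Wiener H, Simpson (dominance
  D and 1 − D), Pielou evenness, Chao1 — and a one-way ANOVA screen of
  each index against size fraction, period, surfactin concentration and
  algal-cell change.
* **Community inference** — Bray–Curtis dissimilarities on
  Hellinger-transformed counts, non-metric multidimensional scaling
  (Kruskal stress-1, monotone regression + majorisation, 20 restarts,
  stress < 0.20 reliability flag), one-factor PERMANOVA (pseudo-F, R²)
  and ANOSIM (global R), both with seeded label-permutation p-values.
* **Synthetic communities** — a Dirichlet-multinomial generator with a
  log-normal baseline, per-OTU binomial FL/PA thinning driven by
  `π_i(c, t) = logistic(β0_i + slope·c·t)`, injectable single-period
  fold effects, and full ground truth for recovery testing.

See `docs/methods.md` for the definitions, defaults and their
rationale.

## Worked example

```python
import fraclift as fl

cfg = fl.SimulationConfig(seed=42)          # 28-sample paired FL/PA design
table, meta, tax, truth = fl.simulate_tables(cfg)

rarity = fl.classify_rarity(table)
records = fl.detect_sensitive_otus(table, meta)
pan = fl.pan_index(table, meta)

d = fl.bray_curtis(fl.hellinger_transform(table))
fractions = meta.for_samples(table.sample_ids)["fraction"].to_numpy()
res = fl.permanova(d, fractions, n_permutations=999, seed=1)
```

Output of the session above (plus a few print statements):

```
table: 300 OTUs x 28 samples; depths 13233 - 109628
rarity: {'rare': 235, 'intermediate': 42, 'abundant': 23}
abundant OTUs cover 88.39% of all reads
sensitive OTUs: PA 152 | FL 149
PAN scored for 254 OTUs; community mean 0.451
PERMANOVA fraction: R2=0.600 F=38.99 p=0.001
ANOSIM    fraction: R=1.000 p=0.001
```

Reading this: the simulated community is dominated by a couple of dozen
abundant OTUs carrying ~88 % of reads over a long rare tail, as real
fraction-filtered amplicon data are. The huge sensitive sets are
dominated by rare OTUs flickering around the detection limit — cross
them with the rarity labels before interpreting (the heatmap output
does this for you). The PAN index is computed for the 254 OTUs with
more than 10 reads; a community mean below 0.5 reflects the simulated
free-living preference (`β0` mean −0.75). The fraction identity
explains 60 % of the Bray–Curtis variation (PERMANOVA R² = 0.60) and
separates samples perfectly in rank terms (ANOSIM R = 1.0); both
permutation p-values sit at the 999-permutation floor of 0.001. An
`fl.nmds(d, seed=1)` on the same matrix warns that its near-zero stress
is a degenerate two-cluster collapse — ordinate within a fraction when
one factor separates samples this strongly.

The same pipeline is scriptable from the shell:

```sh
fraclift simulate --seed 42 --out-dir data/
fraclift classify  --table data/table.tsv --meta data/metadata.tsv --out-dir out/
fraclift pan       --table data/table.tsv --meta data/metadata.tsv \
                   --taxonomy data/taxonomy.tsv --group-by treatment --out-dir out/
fraclift diversity --table data/table.tsv --meta data/metadata.tsv --out-dir out/
fraclift ordinate  --table data/table.tsv --meta data/metadata.tsv --seed 1 --out-dir out/
fraclift permanova --table data/table.tsv --meta data/metadata.tsv \
                   --factor fraction --seed 1 --out out/permanova.tsv
```

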