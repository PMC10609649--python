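# Methods

`fraclift` analyses paired free-living (FL, small filter fraction) and
particle-attached (PA, large filter fraction) 16S OTU count tables from
a chemical-exposure time course — the motivating system is a diatom
culture exposed to the biosurfactant surfactin — and ships a synthetic
community generator with known ground truth so every estimator can be
scored against the quantity it targets.

## Data model

The single source of abundance truth is an integer OTU × sample count
matrix (`OtuTable`). Validation is strict: non-negative integral
counts, unique identifiers, and positive depth for every sample —
zero-depth samples are rejected at load rather than silently dropped,
because a vanished sample is a data error, not an analysis choice.
Sample metadata carries the design factors (fraction FL/PA, treatment,
surfactin dose in mg/L, cultivation period in hours, replicate, and the
algal-cell change over the preceding 24 h, undefined at 0 h). The
metadata join is strict by default (`subset=True` opts into dropping
unmatched samples). Missing taxonomy ranks are represented by an
explicit `Unclassified` token so taxon aggregation is total.

Two transforms underlie everything downstream: per-sample **relative
abundance** `p_is = n_is / N_s` and the **Hellinger transform**
`sqrt(p_is)`, which damps the leverage of dominant taxa in
distance-based analyses. Distances are computed on Hellinger profiles
by default; raw relative-abundance mode is retained.

Rarefaction is available (`rarefy`, seeded subsampling without
replacement) but off by default: all the statistics here operate on
relative abundances, which are depth-invariant.

## Rarity classes

Per-sample relative abundances, thresholds `upper = 1 %` and
`lower = 0.01 %`:

* **abundant** — reaches ≥ `upper` in at least one sample and never
  falls below `lower` in any sample;
* **rare** — falls below `lower` somewhere and never reaches `upper`;
* **intermediate** — everything else (e.g. an OTU that is both ≥ 1 %
  in one sample and < 0.01 % in another, or one that sits strictly
  between the thresholds everywhere).

The "never" clauses are evaluated over *all* samples, the standard
abundant/rare dichotomy; the three labels partition the OTU set.
Absence (0 reads) counts as being below `lower`.

## Sensitive OTUs

Within each stratum of the design (fraction × treatment by default),
the mean relative abundance of each OTU is computed per cultivation
period. An OTU is *sensitive* when the largest pairwise ratio of its
period means exceeds `fold = 10`; because the maximum pairwise ratio is
taken over ordered pairs, a rise above 10× and a drop below 0.1× are
flagged symmetrically. A pseudo-abundance `ε = 1e-6` is added to
numerator and denominator so that OTUs vanishing entirely at some
period — the rule's motivating case — yield finite ratios, and the OTU
must be detected (> 0 reads) in at least two distinct periods of the
stratum. Strata observed at a single period are skipped with a warning.

A consequence worth knowing: for OTUs hovering near the sequencing
detection limit, presence/absence sampling noise alone produces period
means of ~1e-5 against 0, i.e. ε-dominated ratios above 10. The
sensitive set among *rare* OTUs is therefore large and largely reflects
sampling sporadicity; the biologically interpretable subset is obtained
by crossing the sensitive flags with the rarity labels, which is what
the heatmap output does (rows annotated abundant/rare/intermediate,
entries `log10(relative abundance + ε)`, columns ordered by fraction,
treatment, period).

## PAN index

The particle-association niche index places OTU *i* on a continuum from
completely free-living (0) to completely particle-attached (1) as the
abundance-weighted mean of the PA indicator over samples:

    pan_i = Σ_s w_is · 1[fraction_s = PA] / Σ_s w_is .

Only OTUs with more than `min_sequences = 10` total reads are scored
(the threshold applies to the OTU's total over the analysed sample
subset; per-group computation applies it within the group).

**Weighting modes.** With `weight="relative"` (default) the weights are
per-sample relative abundances, so a deeply sequenced sample does not
dominate the mean. The relative-weight index measures association
*relative to the community*: if the entire community shifts mass toward
the PA fraction uniformly, per-sample renormalisation cancels the shift
and every OTU stays near 0.5. With `weight="raw"` the index is the
OTU's PA share of raw reads — the absolute mass share, which under the
generator below is an unbiased estimate of the simulated allocation
probability π. Consequently: use `relative` for cross-sample-depth
robustness and differential association, use `raw` (or an equal-depth
design) for absolute lifestyle-preference statements and trajectory
analyses. The recovery experiments in the test suite use `raw` for
exactly this reason.

Taxon-level summaries report mean ± standard error (`sd/sqrt(n)`,
ddof = 1; singletons get se = 0) of member OTUs' PAN per phylum/class,
optionally crossed with rarity stratum and design group.
`lifestyle_shift` orders the groups (periods by default), reports each
taxon's mean-PAN trajectory and its least-squares slope, and classifies
the taxon as shifting "toward PA" (positive slope) or "toward FL"
(negative).

## Alpha diversity and the ANOVA screen

Per sample: observed richness S; Shannon–Wiener `H = −Σ p_i log p_i`
(natural log by default; base 2 available because legacy amplicon
pipelines used bits); Simpson reported as **both** dominance
`D = Σ p_i²` and diversity `1 − D`, with D the headline column — when
Simpson values of ~0.2 are reported alongside Shannon ~2.2 for a
community with a few dominant taxa, the dominance form is the one that
produces that magnitude; Pielou evenness `H / log S` (undefined at
S = 1, base-invariant); and Chao1, bias-corrected by default,

    chao1 = S + F1·(F1 − 1) / (2·(F2 + 1)),

with the classic `S + F1²/(2·F2)` form optional (the bias-corrected
form is defined even when no doubletons are observed). F1 and F2 are
singleton and doubleton counts, so Chao1 is only meaningful on
unrarefied integer counts.

One-way ANOVA (classical between/within sums of squares; F = 0, p = 1
when all observations are identical) screens each index against size
fraction, cultivation period, surfactin treatment, and the algal-cell
change. The last is a continuous covariate; it enters the one-way
layout after sign-binning into decline / stable / increase (the
`stable` band defaults to width 0, making the binning purely
sign-based — an explicit, documented simplification rather than a
hidden regression).

## Community inference

**Bray–Curtis** `d(a,b) = Σ|x_a − x_b| / Σ(x_a + x_b)` on Hellinger (or
relative-abundance) profiles; a pair of all-zero samples is an error.

**NMDS** minimises Kruskal stress-1,

    stress = sqrt( Σ (d_ij − d̂_ij)² / Σ d_ij² ),

alternating isotonic regression of the configuration distances on the
dissimilarity order (ties broken toward the current configuration —
the "primary" treatment, letting tied dissimilarities take unequal
disparities) with a Guttman majorisation update of the coordinates.
The first start is classical (Torgerson) scaling, the remaining
`n_restarts − 1 = 19` are random Gaussian configurations; the lowest
final stress wins; convergence is a stress change below `tol = 1e-6`
within `max_iter = 300` iterations. Coordinates are centred and rotated
to principal axes with a sign convention, so seeded runs are exactly
reproducible. Stress ≥ 0.20 triggers an interpretability warning.
Near-zero stress (< 1e-3) also warns: with unconstrained disparities,
strongly clustered data (e.g. a dominant FL/PA split) admit the classic
degenerate solution that collapses clusters to points — reference
implementations behave identically, and the warning tells the user to
ordinate within clusters instead.

**PERMANOVA** (one factor): with squared dissimilarities,
`SS_total = Σ_{i<j} d²_ij / n`, `SS_within` the analogous per-group
sum, `SS_among = SS_total − SS_within`,

    pseudo-F = (SS_among/(k−1)) / (SS_within/(n−k)),   R² = SS_among/SS_total,

identical to the Gower-centred inner-product formulation (the test
suite checks the trace-form equivalence). Significance comes from
permuting sample labels: `p = (1 + #{F_perm ≥ F_obs}) / (1 + n_perm)`,
floored at `1/(n_perm+1)`; the default 999 permutations make the floor
0.001. One factor at a time — multi-factor or nested designs are out of
scope.

**ANOSIM** is provided alongside, because community studies often
report a "global R": dissimilarities are rank-transformed once (average
ranks for ties) and

    R = (mean between-group rank − mean within-group rank) / (M/2),  M = n(n−1)/2,

with the same permutation convention. PERMANOVA R² and ANOSIM R are
different statistics on different scales; the package reports both and
does not conflate them.

All permutation and restart machinery requires an explicit seed and is
bit-reproducible given it.

## Synthetic communities

The generator emulates the statistical structure the analysis assumes,
with every target quantity recorded as ground truth.

* **Design.** The default is 14 paired FL/PA design cells = 28 samples,
  one replicate per cell: a pure-seawater control at 0/24/48/72/96 h,
  0 and 2 mg/L surfactin at 24–96 h, and 3 mg/L at 24 h only (the
  highest dose collapses the culture and is not carried further). The
  full grid over treatments × periods, replicate counts, and any other
  design are configurable.
* **Baseline community.** Per-OTU baseline abundances are normalised
  log-normal draws with shape `base_abundance_sigma = 2.5`, giving the
  skew the rarity classifier expects: of ~300 OTUs, a couple of dozen
  exceed 1 % somewhere and the long tail sits below 0.01 %.
* **Counts.** For each design cell the pair's composition is drawn
  Dirichlet-multinomial: Dirichlet weights `overdispersion × baseline`
  (gamma draws, zero-safe for tiny weights), then a multinomial at the
  pair's total depth. The concentration default 5000 gives a
  percent-level taxon a replicate CV of ~15 % — calibrated so that
  > 10-fold period-to-period swings are the signature of injected
  effects rather than routine replicate noise, consistent with systems
  where fold-change-sensitive taxa are a small minority of the
  community. (At concentration ~500 a 1 %-abundance taxon swings more
  than 10-fold between periods purely by noise, which would make the
  sensitive-OTU rule meaningless.)
* **Fraction split.** Each OTU's pair total is thinned binomially into
  the PA sample with probability

      π_i(c, t) = logistic(β0_i + pan_shift_slope · c · t_days),

  `c` the surfactin dose (mg/L), `t_days` the period in days; the FL
  sample keeps the remainder. Thinning gives the PAN index an exact
  simulated target: the OTU's expected raw PA mass share is π_i.
  Defaults `β0 ~ N(−0.75, 1)` (community-wide FL preference at time
  zero, mean π ≈ 0.33) and `pan_shift_slope = 0.25` per mg/L·day (at
  2 mg/L the logit shifts by 2 over four days — a strong but not
  saturating FL→PA transition).
* **Depths.** The pair total is the sum of two uniform draws from
  `depth_range = (10,819, 94,695)` reads. Because the thinning split is
  stochastic, *realised* per-sample depths scatter around this range
  (roughly 0.3–1.4× its bounds at the default π) rather than being
  bounded by it; what is preserved is the order of magnitude and the
  uniform draw per sample pair. The default range is an observed
  min–max over a 28-sample sequencing run, so only its scale is
  meaningful.
* **Period effects.** `inject_sensitive_otus` gives k chosen OTUs one
  period at which their expected relative abundance is multiplied or
  divided by `fold`, recording flags, periods and multipliers in the
  ground truth. Eligibility can be restricted by a baseline floor so
  effects land in the abundant pool, where detection is a meaningful
  question; direction "down" emulates the observed pattern of sensitive
  taxa declining with dose and time.
* **Covariates and taxonomy.** The algal-cell change is a
  dose-dependent noisy covariate (positive growth at low dose,
  reversing around 2.5 mg/L; near-zero in the control; undefined at
  0 h) — no algal growth model is attempted. Taxonomy labels partition
  OTUs among the dominant marine classes (Alpha-/Gammaproteobacteria,
  Actinobacteria, Sphingobacteriia, Flavobacteriia, Cytophagia,
  Unclassified) with configurable weights; they are tokens for
  aggregation tests, not biological claims.

**What the generator does not emulate** — phylogenetic correlation
between taxonomically related OTUs, temporal autocorrelation of the
succession (periods are conditionally independent given the injected
effects and the π drift), chimeras/contaminants, taxon-specific copy
number, or any algal-bacterial feedback. Passing recovery tests
therefore demonstrate estimator correctness under the stated
statistical model, not robustness to everything real amplicon data do.

## Numerical choices and problem sizes

Tolerances: relative-abundance columns sum to 1 within 1e-12; oracle
equivalence checks are asserted at 1e-12; NMDS convergence tolerance
1e-6 on stress. Ratios are guarded by ε = 1e-6; coincident NMDS points
are nudged to 1e-12 before the Guttman update. Simulation-based checks
use: 1000 null data sets (10 samples, 2 groups, 199 permutations) for
PERMANOVA calibration; 20 replicates of a 250-OTU / 28-sample community
for sensitive-OTU recovery; a 100-OTU dose-zero design with 3
replicates for π recovery; 15-sample matrices for the NMDS reference
comparison — sizes chosen so the full suite runs in well under a
minute per experiment while keeping Monte-Carlo error far from the
asserted margins.

## Known limitations

* PERMANOVA/ANOSIM are one-factor with raw label permutations; no
  strata, covariates, or sequential decomposition.
* The sensitive-OTU rule is descriptive (no error control); among
  sporadically detected rare OTUs it mostly measures sampling noise.
* NMDS on strongly clustered data finds the degenerate collapsed
  solution (flagged by a warning), as reference implementations do.
* Chao1 requires unrarefied integer counts; feeding it normalised data
  is meaningless.
* The ANOVA screen treats the algal-cell covariate by sign-binning; a
  regression treatment is deliberately out of scope.
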