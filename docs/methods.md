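# Methods

This note documents the models implemented in `mycodyn`, the defaults and
why they were chosen, what the synthetic-data generator does and does not
emulate, and the numerical conventions.

## Absolute abundance from qPCR

Apparent rRNA-gene copies per ng DNA are converted to genomes per stool
pellet as

* bacteria: `copies/ng × yield_ng × f_taqman / c_16S`
* fungi (microeukaryotes): `copies/ng × yield_ng / c_18S`

Parameters (`CorrectionParams`):

| parameter | default | units | rationale |
|---|---|---|---|
| `copies_per_genome_bacteria` (`c_16S`) | 5 | copies/genome | mean 16S operon number across sequenced bacterial genomes |
| `copies_per_genome_fungi` (`c_18S`) | 100 | copies/genome | mean 18S rDNA repeat number; **tentative** — tandem repeats are poorly assembled and copy number varies widely between and within species |
| `taqman_underestimation_factor` (`f_taqman`) | 11 | — | average shortfall of probe-based 16S quantification vs dye-based chemistry in mixed communities (probe-site mismatches); applied to the 16S assay only |

The conversion is put on a per-pellet basis (multiply by DNA yield) because
total DNA collapses under antibiotics; pellet wet/dry weights are treated
as equal across arms and carried only as optional metadata.  Group
summaries report arithmetic means and sample SDs (ddof=1); the
microeukaryote proportion `euk/(euk+bact)` of the group means is rounded to
3 decimals in reporting mode and kept at full precision internally.
Samples lacking either assay raise an error naming the sample; nothing is
imputed.

**Caveat.** The estimator cannot distinguish live organisms from free DNA:
food-derived *Lactococcus* 16S copies are counted as bacteria.  The ground
truth of the simulator therefore carries both the true and the *apparent*
(true + food) bacterial count, and estimator recovery is defined against
the apparent value — which is also the quantity the assay measures in a
real experiment.

## Taxonomy-derived trees and UniFrac

Lineage strings (semicolon-delimited, positional ranks, empty intermediate
names allowed) are merged into a rooted tree: shared name-path prefixes
share nodes, a synthetic root joins the top-level taxa, each OTU is a leaf
one edge below its deepest named taxon, and **every edge has length 1**.
Node identity is the full name-path, so homonym taxa under different
parents stay distinct (merging NCBI-style homonyms would distort the
tree).  No manual curation of classifications is applied.

* Unweighted UniFrac: (branch length covered by exactly one sample) /
  (branch length covered by either), presence = count > 0, computed on
  rarefied tables so presence is depth-comparable.
* Weighted UniFrac: `Σ_b |A_b − B_b|` where `A_b` is the fraction of a
  sample's reads descending through branch `b`; the default normalized
  variant divides by the maximum attainable for the pair
  (`Σ_leaves depth_leaf × (A_leaf + B_leaf)`), so both variants live on
  [0, 1].

PCoA is classical scaling (double-centered −D²/2, `eigh`, axes kept for
eigenvalues above a relative 1e-12 tolerance; negative eigenvalues are
reported but contribute no axis).  The Procrustes concordance test scales
both configurations to unit total variance, allows reflection, and permutes
the sample labels of the second ordination; p = (b+1)/(m+1) with the
identity permutation excluded from the draws (it is the observed labeling,
already counted by the +1).

## Rarefaction and richness

Rarefaction subsamples without replacement (multivariate hypergeometric),
conserving depth exactly; defaults are 200 reads and 10 replicates per
sample, reporting mean and min–max range of observed richness.  Samples
below depth are excluded with a logged warning rather than crashing.  The
closed form `E[S_d] = Σ_i (1 − C(N−n_i, d)/C(N, d))` is exposed as
`expected_rarefied_richness` and used to calibrate the sampler in tests.

## Interval testing scheme

The default scheme encodes six comparisons of the time course (days in
parentheses refer to the default calendar, overridable):

1. Baseline — treated arms vs control over pre-treatment days (−7, −4, −1);
2. Early ABX vs Control — first two on-treatment days (1, 2), same days;
3. Late ABX vs Control — remaining on-treatment days of the short-term arm
   (6, 8, 15), same days;
4. Recovery vs Control — short-term arm after cessation (22–76), same days;
5. Last Day Recovery vs Control — day 76 only;
6. Early ABX vs Late ABX — the same treated mice across the two intervals
   (paired).

Between-group contrasts use Mann–Whitney U on per-sample values with
control samples restricted to the same days; the paired contrast uses the
Friedman test with mice as blocks and per-interval mean counts as the two
treatments.  Bonferroni multiplies by the number of lineages actually
tested (non-n/a) within each comparison; lineages absent from both sides
are reported not-applicable.  All tests are two-sided.

**Mann–Whitney U** is exact by full enumeration of all C(n+m, n) labelings
of the pooled midranks when n+m ≤ 12 (two-sided p = share of labelings at
least as far from nm/2 as observed; valid under ties because the
enumeration conditions on the observed value multiset), otherwise the
normal approximation with tie and continuity corrections.

**Friedman** uses within-block midranks, the standard statistic with tie
correction, and (`method="auto"`) the exact conditional permutation
distribution when the number of arrangements k!^n ≤ 20 000, else the
chi-square reference with k−1 df.  The exact path exists because the
chi-square approximation misstates p by up to ~0.18 for designs as small as
4 blocks; the package's own cohort analyses (10–20 mice) take the
chi-square path.  k = 2 treatments is supported.

**Distance-based group test** (per day): Mann–Whitney on within-control
pairwise distances vs control-to-treatment pairwise distances.  The
pairwise distances are mutually dependent, so the p-value is a screening
heuristic, not an exact error rate; this is deliberate — the procedure is
reproduced as practiced — and is flagged in the function's docstring.

## Synthetic cohort generator

The generator emulates the statistical structure the analysis assumes: 3
treatment arms (control, antibiotics days 0–15, antibiotics days 0–76) × 2
cages × 5 mice, sampled on days −7, −4, −1, 1, 2, 6, 8, 15, 22, 29, 43,
61, 76.  Key defaults and what they encode:

| parameter | default | meaning |
|---|---|---|
| `bacterial_baseline` | 5×10⁸ genomes/pellet | untreated bacterial load |
| `bacterial_crash_factor` | 10⁴ | fold-drop of live bacteria on antibiotics |
| `fungal_baseline` | 7×10⁵ genomes/pellet | untreated fungal load (~0.1% of microbes) |
| `fungal_bloom_factor` | 50 | on-antibiotics fungal fold-increase |
| `food_16s_copies_per_pellet` | 1.2×10⁵ | constant chow-derived *Lactococcus* 16S flux; additive, treatment-independent (food intake does not depend on arm) |
| `read_depth` | 500 | reads per sample per amplicon |
| `qpcr_cv` | 0.2 | lognormal qPCR noise CV; free choice (replicate variance is rarely reported), typical of inter-run qPCR variability |
| `recovery_half_life_days` | 7 | log-scale exponential relaxation to baseline after cessation; gives essentially full recovery 61 days after stopping, matching an ~8-week recovery horizon |
| `abx_susceptible_weight` | 10⁻³ | relative suppression of non-tolerant OTUs under antibiotics (see below) |

Mechanisms:

* **Load dynamics**: antibiotic "intensity" is 1 during a group's treatment
  window, 0 before, and decays as 2^(−Δt/half-life) after cessation; loads
  are baseline × crash^(−intensity) (bacteria) and baseline ×
  bloom^(intensity) (fungi).  With noise off, fold-changes are exact by
  construction.
* **Surviving composition**: under antibiotics the bacterial composition is
  reweighted toward a small antibiotic-tolerant OTU subset (Enterococcus,
  Escherichia, Paenibacillus OTUs in the default pool) while the total
  still follows the crash factor.  This is the package's own modeling
  choice: without it, observed richness barely moves under treatment,
  because a uniform 10⁴-fold crash rescales read proportions of live taxa
  not at all.  With it, richness falls from ~40–55 to ~10 OTUs at 200
  reads and recovers after cessation.
* **Fungal succession**: piecewise-constant per-cage regimes.  At each
  event day the single most abundant baseline phylotype of the named
  lineage takes the event's dominance fraction; residual mass is spread
  uniformly over all other OTUs; all mice in a cage follow the same regime
  (coprophagia synchronizes cage-mates).  The default event calendar walks
  the six cages through distinct waves (Wickerhamomyces → Debaryomyces →
  Eurotiales in control cages; Clavispora/Cyberlindnera → Candida in
  treated cages), with dominance fractions 0.3–1.0.
* **Reads**: multinomial at fixed depth from the true proportions; the 16S
  table's expected proportions include the food *Lactococcus* copies, so
  as live bacteria vanish the table converges to pure *Lactococcus*.
* **qPCR**: true copies per ng times mean-one lognormal noise; the 16S
  value is additionally divided by `f_taqman` (the estimator multiplies it
  back).
* **DNA yield**: floor (host/food debris, 100 ng) + 5×10⁻⁷ ng per
  bacterial genome + 10⁻⁶ ng per fungal genome — chosen so baseline and
  on-antibiotics yields sit at the hundreds-of-ng and ~10² ng scales seen
  in practice.
* **Randomness**: every (sample, stream) pair derives its own generator
  from the global seed via `SeedSequence(entropy=seed, spawn_key=...)`;
  identical seeds give bitwise-identical cohorts and subsetting days or
  mice never shifts other samples' draws.

`null_config()` produces the matching no-effect cohort (no antibiotic
windows, crash/bloom = 1, no succession), under which all mice are
exchangeable across arms — the null used for calibration testing.
`plant_fold_change` injects a controlled fold-change into selected
group/day samples for power studies.

**What the generator does not emulate**: sequencing error, chimeras and
OTU-picking artifacts; overdispersion beyond multinomial sampling;
mouse-level biological variation in total loads (group SDs in simulated
summary tables are narrower than in real data, reflecting only measurement
noise); food ITS signal; day-to-day autocorrelation within a mouse beyond
the deterministic regime structure.  Passing tests therefore demonstrate
correctness of the estimators and tests under the stated model, not
robustness to those real-data features.

## Numerical conventions and edge cases

* Proportions: 3-dp rounding only in reporting mode; `euk = bact = 0`
  raises (undefined proportion).
* Distance matrices validate symmetry to 1e-12 and zero diagonals; TSV
  round-trips symmetrize away serialization noise below that tolerance.
* Floats are serialized with 17 significant digits so write∘read is the
  identity.
* Rarefaction below depth drops the sample with a logged warning, never
  silently.
* Friedman with every block fully tied returns statistic 0, p 1.
* All-zero samples are rejected by both UniFrac variants; an all-zero OTU
  (uncovered branch) never affects a distance.
* Pipeline outputs carry `# seed=…` and `# config_hash=…` headers; the
  hash excludes output location and log level so identical computations
  hash identically.

## Problem sizes used in the test suite

Monte-Carlo checks run at sizes chosen to keep the full suite under a
minute on one core while leaving comfortable statistical margins: 100-seed
replication for parameter-recovery coverage and planted-effect power,
40 null cohorts (~4 000 pooled tests) for type-I calibration, 10⁴
rarefaction replicates per calibration sample, and exhaustive enumeration
(not sampling) for the exact-test oracles.

## Known limitations

* The 18S copies-per-genome correction is a single scalar; real communities
  mix species with very different rDNA repeat counts, so fungal absolute
  abundances are order-of-magnitude estimates.
* The 11-fold Taqman correction is a community average, not a per-taxon
  mismatch model.
* No per-OTU 16S copy-number correction and no standard-curve fitting
  (copies are taken as reported by the instrument).
* Permanova and mixed-effects models are out of scope; Bonferroni is the
  only multiplicity correction offered.
* The distance-based group test inherits the dependence caveat above.
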