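# mycodyn

Quantitative analysis of longitudinal antibiotic-perturbation experiments on
the gut **bacterial and fungal (mycobiome) communities** of caged mice:
absolute abundance estimation from qPCR, taxonomy-tree UniFrac community
comparison, rarefaction richness, and an interval-structured nonparametric
testing scheme — plus a synthetic-cohort generator so the whole pipeline is
testable without sequence data.

The package is aimed at microbiome researchers who have, per stool pellet:
sample metadata (mouse, cage, treatment arm, study day, DNA yield), qPCR
results (apparent rRNA-gene copies per ng DNA), and OTU count tables with
taxonomic lineage strings.

## The science in brief

**Absolute abundance.** qPCR reports apparent rRNA-gene copies per ng of
template; organisms per pellet require three corrections:

```
bacteria/pellet = copies_per_ng_16S × yield_ng × f_taqman / c_16S
fungi/pellet    = copies_per_ng_18S × yield_ng / c_18S
```

with `c_16S ≈ 5` 16S copies per bacterial genome, `c_18S ≈ 100` 18S copies
per fungal genome (tentative — rDNA tandem repeats are hard to assemble),
and `f_taqman ≈ 11`, the average shortfall of probe-based 16S detection in
mixed communities due to probe-site mismatches.  Normalizing to the pellet
(not to DNA mass) matters because antibiotics collapse total DNA: without
it, fungi appear to bloom merely because the denominator shrank.  The
headline statistic is the **microeukaryote proportion**
`p = euk / (euk + bact)`, which moves from ~0.001 at baseline to >0.99
under an effective antibiotic cocktail.

A subtlety this package models explicitly: sterile chow carries
*Lactococcus* 16S DNA, a constant food-derived copy flux that dominates the
16S signal once live bacteria are cleared, so the on-antibiotics "bacterial
count" is an overestimate of live organisms.

**Community comparison.** ITS amplicons cannot be aligned into a de novo
phylogeny (length variation), so communities are compared on a
**taxonomy-derived tree**: lineage strings share internal nodes along shared
prefixes, every edge has length 1, and each OTU hangs as a leaf below its
deepest named taxon.  On this tree the package computes unweighted UniFrac
(unique / covered branch length from presence–absence) and normalized
weighted UniFrac (Σ_b |A_b − B_b| over branches, scaled to [0,1]), classical
PCoA, and a permutation Procrustes test for concordance of two ordinations.

**Richness and statistics.** Richness is observed OTUs after rarefying each
sample to a common depth (default 200 reads, 10 replicates).  Lineage
abundances are tested between named intervals of the time course (baseline,
early/late antibiotics, recovery, last day) with exact-enumeration
Mann–Whitney U between groups, Friedman tests (mice as blocks) within
animals, and Bonferroni correction over the lineages tested per comparison.

## Worked example

Simulate the default cohort (3 arms × 2 cages × 5 mice, 13 sampling days
from a week before treatment to day 76; the short-term arm is treated days
0–15, the continuous arm throughout) and estimate absolute abundances:

```python
import numpy as np, pandas as pd, mycodyn as md

config = md.SimulationConfig(seed=1)
pool = md.default_pool()
records, measurements, t16, tits = md.simulate_experiment(config, pool)

abund = md.abundance_table(records, measurements)
summary = md.group_summary(records, abund)
print(summary[summary["day"].isin([-7, 15, 76])][
    ["group", "day", "bacterial_mean", "eukaryote_mean",
     "microeukaryote_proportion"]])
```

```
        group  day  bacterial_mean  eukaryote_mean  microeukaryote_proportion
AbxContinuous   -7        5.13e+08        7.06e+05                      0.001
AbxContinuous   15        7.95e+04        3.37e+07                      0.998
AbxContinuous   76        7.02e+04        3.17e+07                      0.998
 AbxShortTerm   -7        4.51e+08        7.06e+05                      0.002
 AbxShortTerm   15        6.92e+04        3.04e+07                      0.998
 AbxShortTerm   76        4.46e+08        7.55e+05                      0.002
      Control   -7        4.61e+08        7.94e+05                      0.002
      Control   15        5.65e+08        6.72e+05                      0.001
      Control   76        4.78e+08        7.31e+05                      0.002
```

Treated arms crash from ~5×10⁸ to ~10⁵ apparent bacteria per pellet (mostly
food-derived 16S at that point) while fungi bloom ~50-fold, flipping the
microeukaryote proportion from ~0.001–0.002 to ~0.998; the short-term arm
recovers by day 76.  Bacterial richness tells the same story:

```python
rich = md.rarefied_richness(t16, depth=200, reps=10,
                            rng=np.random.default_rng(1))
```

mean richness in the short-term arm: ~42 OTUs at baseline, ~10 during
treatment (days 1–15), back to ~43 by day 76.

The same objects feed the rest of the pipeline: `md.build_taxonomy_tree` +
`md.unifrac_matrix` + `md.pcoa` for ordination, `md.lineage_interval_tests`
for the interval testing scheme, `md.distance_group_test` for per-day
community displacement.  Or run everything at once from a shell:

```sh
mycodyn run --seed 1 --out results_dir
```

which writes metadata, qPCR, OTU tables, the abundance summary, richness,
UniFrac matrices, PCoA coordinates and test tables as TSV, each with a
provenance header (seed, config hash, version).

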