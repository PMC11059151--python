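# interlab-mgs

Compositional statistics for **interlaboratory metagenomic sequencing
comparisons**: when many labs profile the same microbiome samples with
their own protocols, how much do methodological choices bias the results,
and how unstable do they make them?

The package is written for microbiome scientists running (or reanalyzing)
ring trials: it takes per-lab taxonomic profiles plus a protocol
questionnaire and quantifies per-parameter effects on compositionally
valid measurands, scores labs against ddPCR-anchored mock-community
ground truth, and runs the submission QC (roster filtering, sample-label
transposition detection, aliquot homogeneity, spike-in constancy) that
such studies need.  A first-class synthetic-data generator produces
complete studies with known injected effects, so every estimator can be
validated against ground truth.

## The statistics at the core

Relative abundances are closed to 1, so a single taxon's abundance is not
comparable across samples or labs.  Within-profile **taxa ratios** cancel
the closure: the package's default measurand is the phylum-level
Firmicutes:Bacteroidetes ratio, `r = p_F / p_B`, used purely as a
compositional measurand.

For a protocol parameter level `L` and one sample, the **parameter
effect** is

```
effect_log2(L) = log2( mean_{labs reporting L}(r)  /  mean_{all labs}(r) )
```

with arithmetic means on the ratio scale and a 99% confidence interval
from a nonparametric bootstrap that resamples the whole lab roster once
per replicate and recomputes both means (a t-interval cross-check mode is
available).  A **variability ratio** `sd_group(log2 r) / sd_all(log2 r)`
measures whether a protocol choice stabilizes results even when it does
not shift them, and a replication screen keeps only levels whose CI
excludes 0 in ≥ 2 samples.

For DNA mock communities, ddPCR genome-copy measurements are scaled by
16S rRNA copy number (amplicon) or genome size (shotgun) to give the
expected pairwise signal ratios; each lab's observed ratios yield
`bias_log2 = log2(observed / truth)`, and per-pair summaries separate
**consensus** (interquartile spread of labs' log ratios) from
**accuracy** (offset of their consensus from truth) — flagging the
"consensus with bias" signature where labs agree tightly on a wrong
value.

Supporting statistics: Bray–Curtis dissimilarity and classical PCoA,
inverse Simpson diversity, rank aggregation, rarefaction (multivariate
hypergeometric), and an exhaustive permutation search that detects
sample-label transpositions from leave-one-lab-out consensus profiles.

## Worked example

```python
from interlab_mgs import (aggregate, generate_stool_study, normalize,
                          sweep, taxa_ratio)
from interlab_mgs.interlab import estimates_to_frame
from interlab_mgs.synthetic_data import StudyConfig

study = generate_stool_study(StudyConfig(seed=7))   # 30 amplicon + 14 shotgun labs
phy = aggregate(normalize(study.observed), "phylum")
ratios = taxa_ratio(phy, "Firmicutes", "Bacteroidetes")
ests = sweep(ratios, study.metadata, "S1", stratum="all", n_boot=2000, seed=1)
print(estimates_to_frame(ests).head(4).round(3))
```

prints (largest effects first):

```
     parameter       level  effect_log2  ci_low  ci_high  n_labs  significant
      strategy     shotgun       -1.555  -1.947   -1.230      14         True
 target_region        V3V4        0.403   0.136    0.729      14         True
      strategy    amplicon        0.387   0.153    0.682      30         True
 target_region          V4        0.373   0.129    0.698      16         True
```

The generator injected a +2 log2 amplicon-vs-shotgun contrast on the
ratio; the sweep recovers it (shotgun labs sit 2^-1.56 ≈ 3x below the
overall mean, amplicon labs 2^0.39 ≈ 1.3x above — the asymmetry reflects
the 30/14 roster imbalance, since the overall mean contains the group
itself).  `target_region` is answered only by amplicon labs, so in the
all-labs sweep it inherits the strategy effect; re-sweeping within
`stratum="amplicon"` makes it vanish.  That hierarchical confounding is
why downstream parameters are analyzed within one strategy stratum.

The `examples/` directory has one narrative script per capability:
simulation, ordination, parameter effects, mock-community bias scoring,
and QC.  A thin CLI wraps the same pipeline:

```
interlab-mgs all --config run.yaml --seed 17 --out results/
```

(subcommands `simulate`, `qc`, `ordinate`, `ratios`, `sweep`, `truth`,
`all`; exit codes 0 ok, 2 validation failure, 3 QC rejection).

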