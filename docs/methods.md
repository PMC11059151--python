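# Methods

This note documents the statistical model behind `interlab_mgs`, the
choices made where the design was genuinely open, and what the synthetic
data do and do not establish about real interlaboratory studies.

## Setting and measurand

An interlaboratory sequencing comparison distributes identical aliquots
of a few samples to many labs, each of which applies its own wet-lab and
sequencing protocol and returns a taxonomic profile (relative abundances
per taxon).  Profiles are compositional: each sums to 1, so any protocol
step that inflates one taxon's signal deflates every other taxon's
share.  Statistics on single abundances therefore confound the taxon of
interest with everything else.  Ratios of two taxa within one profile
are invariant to the closure and to rescaling of unrelated taxa, which
makes them valid measurands for between-lab comparison; the package
defaults to the phylum-level Firmicutes:Bacteroidetes ratio, used purely
as a compositional measurand, and any numerator/denominator pair at any
rank can be substituted.

Zeros break ratios.  The pseudocount policy is: add a pseudocount to
both terms only in profiles where either abundance is zero, default half
the smallest nonzero abundance of that profile, and flag every affected
value in the output.  Spike-in nondetects are the one exception — they
are reported as nondetects and never converted to ratios, because a
control organism silently absent from a classifier's database produces
pseudocounted values that look like data while measuring nothing.

## Parameter effects

For parameter level `L`, sample `s`:

    effect_log2 = log2( mean_{labs with L}(r_s) / mean_{all labs}(r_s) )

* **Mean scale.** Arithmetic means of raw ratios, then the log2 of their
  quotient.  The geometric alternative (means of log ratios) is more
  natural for compositional data and is available via
  `mean_scale="geometric"`; the two differ whenever the between-lab
  distribution is skewed.  The arithmetic scale is the default because
  it is the definition of the group-vs-overall quotient this package
  implements and reports; results produced under one scale should never
  be compared with results under the other.
* **The overall mean includes the group.**  Effects of a level reported
  by most labs therefore shrink toward 0; with two levels of sizes
  n_A, n_B the two effects are deterministically linked through the
  weighted-mean identity n_A·mean_A + n_B·mean_B = N·overall.  The
  two-level *contrast* log2(mean_A/mean_B) (`level_contrast`) is free of
  this shrinkage and equals the injected group shift in expectation; use
  it when two levels partition the roster.
* **Confidence intervals.**  Percentile bootstrap over labs, default
  B = 2000, seeded.  Each replicate resamples the *full roster* once and
  recomputes both means from the same resample; resampling group and
  overall independently would treat overlapping means as independent and
  misstate the variance.  Replicates whose resample contains no group
  member are dropped (an error is raised if more than half are).  A
  normal-theory t-interval on log2 ratios is provided as a cross-check
  mode; it ignores the overall mean's (smaller) sampling error and is
  approximate.  Percentile intervals at n ≈ 25 labs undercover mildly
  (measured false-exclusion rate of the 99% interval ≈ 1.2% under the
  null design below), which is inherent to the method, not a bug.
* **Missing answers.**  A lab that skipped a question joins no level
  group for that parameter but stays in the overall mean, keeping one
  common reference across levels.
* **Groups of one.**  The point estimate is returned with an
  undefined-wide CI and `ci_defined=False`; it is never significant.
* **Stratified sweeps.**  Protocol choices are hierarchical: amplicon
  labs answer amplicon-only questions, so in a pooled sweep such
  parameters inherit the strategy effect (their answering labs *are* the
  amplicon labs).  `sweep(..., stratum="amplicon"|"shotgun")` restricts
  both groups and the overall mean to one strategy; parameters never
  answered within the stratum are skipped.  No multiple-testing
  correction is applied; the replication screen
  (`significant_across_samples`, CI excluding 0 in ≥ 2 samples) is the
  package's only guard against per-level false positives.
* **Robustness.**  `robustness` compares the SD of log2 ratios within a
  conjunction of protocol conditions to the overall SD.  A variability
  ratio well below 1 identifies protocol combinations that stabilize the
  measurand without shifting it.

## Mock-community ground truth

ddPCR measures genome copies/µL per taxon with replicates.  Sequencing
does not observe genome copies: amplicon read share scales with
copies × 16S rRNA gene copies per genome, shotgun share with
copies × genome size.  `scale_truth` forms the strategy-specific
expected signal and all C(n,2) pairwise ratios.  The truth CI reflects
replicate variability only: a t-interval on the log ratio of replicate
means with delta-method standard errors (se ≈ cv/√n per taxon, pooled
df), or a seeded bootstrap over replicates.  Under lognormal replicate
noise at the CVs typical of ddPCR (~5%) the two agree closely.

Bias scoring separates two questions.  *Consensus*: the interquartile
range of labs' log2 observed ratios per pair.  *Accuracy*: the absolute
median bias (offset of the labs' consensus from truth).  A pair is
flagged **consensus-with-bias** when the spread is below `s_max`
(default 1 log2 unit) *and* the truth CI, widened by the consensus
center's own lab-sampling standard error (1.2533·sd/√n, the normal
approximation for a median, at the truth CI's t-quantile), excludes the
center.  The widening term is deliberate: without it the flag fires on
center sampling noise whenever between-lab spread is non-negligible
relative to ddPCR replicate error, and the flag would not be calibrated
to the CI's nominal error rate under unbiased labs.  The flag rule and
`s_max` are this package's constructs and are configurable.

Only taxa unambiguous at genus level enter the pair panel, and panel
membership is explicit input — genus-level profiles cannot attribute
signal among congeneric strains, so mixed genera would make the "truth"
ill-defined.

## QC procedures

* **Roster filtering** drops incomplete-metadata submissions first, then
  duplicates of retained datasets (keeping the first); an entry that is
  both counts once, under incomplete.  Output size is always
  input − incomplete − (duplicates not already incomplete).
* **Label-transposition detection.**  For each lab, each of its profiles
  is compared (Bray–Curtis) to the leave-that-lab-out mean profile of
  every sample; the assignment of claimed labels to samples minimizing
  the total dissimilarity is found by exhaustive search (5 samples →
  120 permutations; the cost matrix makes each permutation O(n)).  A lab
  is reported when a non-identity assignment beats the identity by more
  than a relative margin δ (default 20%), which suppresses noise-level
  improvements; the reported permutation is the *correction* (claimed
  label → inferred true sample), i.e. the inverse of the relabeling that
  produced the data.  δ trades sensitivity against false alarms and has
  no principled universal value; at the generator's default noise the
  detector is effectively perfect (100/100 seeds), so the default sits
  well inside a wide plateau.
* **Aliquot homogeneity** summarizes within-sample pairwise Bray–Curtis
  over replicate aliquots of one lab (mean and max, pass flag against a
  configurable threshold, default mean ≤ 0.1).
* **Spike-in constancy.**  Two exogenous organisms added at fixed
  fractions should yield a between-sample-constant ratio within each
  lab.  The per-lab summary is the SD and CV of log2(a/b) across
  samples; with only counting noise the SD shrinks as depth^-1/2.

## Composition statistics

Bray–Curtis is computed by scipy's pairwise machinery; on relative
profiles it equals half the total-variation distance.  PCoA is the
classical Gower construction: double-center −D²/2, symmetric
eigendecomposition, axes ordered by eigenvalue.  Bray–Curtis is
non-Euclidean, so negative eigenvalues occur; they are reported but
excluded from coordinates, and proportion explained divides by the sum
of positive eigenvalues (no Lingoes/Cailliez correction is applied —
with one the proportions would change, the configuration only slightly).
A scikit-bio cross-check in the test suite confirms coordinate
agreement.  Rarefaction subsamples without replacement (multivariate
hypergeometric), matching the classic behavior of rarefying pipelines,
deterministic under seed.

## The synthetic-data generator

`generate_stool_study` emulates the structure of a multi-lab stool
comparison: 5 samples, 30 amplicon + 14 shotgun labs, ~30 gut genera
with real lineages, two spike-ins, depth 100,000 reads — the scale of
the study design this package targets.

The generative model: each sample's true composition is Dirichlet with
concentration 0.5·n·template, where the template is a geometric decay
(0.8^k) permuted per sample — skewed, genus-dominated profiles that
separate cleanly in ordination.  Each lab draws protocol levels per the
configured prevalences (a parameter named `strategy` takes the lab's
assigned strategy; `balanced=True` assigns levels round-robin for
controlled experiments), then perturbs log2 abundances by the sum of its
levels' injected ratio effects — split +e/2 on numerator-phylum taxa and
−e/2 on denominator-phylum taxa — plus a per-taxon lab effect
N(0, `lab_noise_sd`), re-closes, adds the spike-ins at fixed fractions,
and draws multinomial counts.  Injecting effects *before* closure means
downstream estimators face the same compositional coupling as real
profiles, while the designated ratio still moves by exactly the injected
log2 amount in expectation.  Per-lab RNG substreams are keyed by a CRC
of the lab ID, so enlarging the roster never changes existing labs'
data.

Defaults that are choices, not measurements:

* `lab_noise_sd = 0.3` log2 per taxon.  No variance decomposition of
  real between-lab noise is available to calibrate against; 0.3 gives
  between-lab ratio spreads of the visual order seen in published
  ring-trial figures.  It is a placeholder to be tuned, and conclusions
  about absolute power at this noise level do not transfer to real data.
* Strategy contrast +2 log2 (amplicon +1, shotgun −1) on the F:B ratio.
  Published comparisons report amplicon labs measuring the ratio
  markedly higher, most above 1 where shotgun labs sit below 1; a 4×
  contrast is a realistic magnitude, not an estimate.
* Spike-in fractions (0.010, 0.005).  Targets of ~1% each are realistic
  for whole-cell spike-ins, but equal fractions would make the log2
  spike ratio 0 and its CV undefined, so distinct defaults are used.
  By default amplicon labs never detect the second spike-in (emulating
  a reference-database gap), so spike-in constancy is evaluable only
  from shotgun labs; set `amplicon_detects_spikein_b=True` to disable.

`generate_mock_community` builds a 13-strain DNA mixture (12 strains of
the classic clinical panel plus *Achromobacter xylosoxidans*), either
equigenomic or a tenfold log-dilution series spanning three orders of
magnitude, with lognormal ddPCR replicates (CV 5%, 6 replicates, mean
exactly the truth) for the four genus-unique assayed genera, and per-lab
profiles whose expected signal follows the strategy's scaling law with
per-strain lab noise (default 0.1 log2) and multinomial depth.

What the generator does **not** emulate: read-level artifacts (chimeras,
contamination, classifier confusion between related genera),
compositional lab effects correlated across taxa, depth variation
between labs, lab-by-sample interactions, and the cross-contamination
known to affect prototype DNA materials.  Passing tests therefore
establish that the estimators recover known effects under the stated
noise model — not that real interlab effects of a given size will be
detected at these rosters.

## Problem sizes and numerical choices

Monte-Carlo validations run at the following sizes, chosen to make
binomial noise small relative to the bands they check: effect recovery
and CI coverage, 100 study replicates of 2×25 labs (bootstrap B = 2000);
null calibration, 100 replicates (200 level tests); bias-flag null, 200
mock communities of 12 labs (1200 pair tests); transposition detection,
100 studies of 8 labs.  Relative-abundance closure is enforced to 1e-9,
with profiles summing within [0.99, 1.01] renormalized under a warning
(classifier exports often drop an unclassified remainder); ties in the
transposition search resolve to the identity assignment; eigenvalues
below 1e-12 of the largest count as non-positive in PCoA.

## Known limitations

Lab effects are treated as fixed per (parameter, level) grouping —
no mixed-effects decomposition, no interactions, and no causal claim:
levels are chosen by labs, not randomized, and protocol choices
correlate.  The arithmetic-mean effect definition is sensitive to
heavy-tailed between-lab ratio distributions (a single extreme lab moves
the group mean); the geometric mode is the robust alternative.  Truth
CIs ignore ddPCR's droplet-level Poisson structure, and with very few
replicates (2–3) the delta-method t-interval is approximate.
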