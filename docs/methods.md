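# Methods

## Clonal architecture model

A subject's tumor is a rooted tree of clones. Each clone introduces exactly
one new mutation cluster and inherits every ancestor's clusters; clone
frequencies plus a non-tumor fraction must sum to 1. The cumulative
prevalence of a cluster is the frequency of its introducing clone plus all
descendants, and — under the diploid-heterozygous assumption used
throughout — its expected bulk VAF is half that prevalence. Prevalence is
automatically non-increasing from ancestor to descendant clusters because a
descendant's carrier set is a subset of its ancestor's.

Three built-in architectures reproduce the secondary-AML study setting:

| subject   | non-tumor | clone frequencies (nested)      |
|-----------|-----------|---------------------------------|
| UPN461282 | 0.10      | 0.06 / 0.04 / 0.33 / 0.33 / 0.14 |
| UPN182896 | 0.35      | 0.13 / 0.52                     |
| UPN288033 | 0.07      | 0.62 / 0.31                     |

The rare fifth clone of UPN461282 is attached to clone 4, the parentage
supported by single-cell colocalization (its bulk origin was ambiguous).
The complex karyotype of that subject is *not* modeled: the simulator is
diploid everywhere, so copy-number-driven VAF distortion is out of scope.

The locus catalog carries 872 + 777 + 304 = 1,953 targeted somatic SNVs.
Only the rare cluster's size (60 SNVs in UPN461282) is known; the remaining
SNVs are split evenly across each subject's other clusters. Germline SNP
panels (defaults 200 het / 100 hom-ref / 50 hom-var per subject) provide
truth for benchmarking, and a configurable fraction of somatic SNVs
(default 0.09) has its cluster label masked to emulate bulk-unclusterable
"outlier" variants; the simulator retains the true label for scoring.

## WGA noise model

Parameters of `WgaNoiseModel`, with defaults and rationale:

* `ado_prob` = 0.24 — per-allele-pair dropout probability at heterozygous
  sites. A dropout converts the site to an apparent homozygote; direction
  is uniform, so the heterozygous-site false-negative rate is ≈ d/2 = 0.12,
  the level observed at germline heterozygous SNPs in the reference cohort. ADO is i.i.d. per
  (cell, locus): locus-specific dropout explains only a minority of
  variance in observed data, so the default has no positional effect. An
  optional per-locus multiplier (`locus_ado_multiplier`) can induce a
  shared locus effect; it defaults off. Dropout is modeled
  pre-amplification (whole-allele loss), not as read-level skew, matching
  the homozygous-appearing error calls it must explain.
* `seq_error` = 0.01 — per-read miscall probability, applied after dropout
  via p = f(1 − e) + (1 − f)e. Chosen inside the observed false-positive
  budget (~0.02) once the variant-read floor is applied.
* `depth_mean` = 113, `depth_dispersion` = 0.8, `locus_dropout_prob` = 0.27
  — zero-inflated negative-binomial coverage. The reference cohort shows
  mean on-target single-cell coverage ≈ 113× with ~55% of targets callable
  at ≥25×; with r = 0.8 the NB tail gives P(depth ≥ 25) = 0.753, and the 0.27
  zero mass brings the callable fraction to 0.55. These two parameters were
  fixed analytically from the NB survival function, not tuned on test
  outcomes. Locus dropout is implemented as depth exactly 0; any "near
  zero" depth below the 25× gate is indistinguishable downstream.

Two-cell samples pool the four alleles of two cells with equal
amplification (a weighting knob exists, default 0.5/0.5): loci heterozygous
in exactly one cell have expected VAF 0.25, shared het loci 0.5. ADO acts
on each cell independently before pooling.

All randomness flows from one master seed through deterministic child
streams (`numpy` SeedSequence spawning); identical configurations give
bit-identical outputs.

## Genotyping

Per site, the maximum-likelihood genotype among Bin(n, e), Bin(n, 0.5),
Bin(n, 1 − e); NOCALL below 25× (configurable); ties resolve toward
homozygous reference (conservative, matching the asymmetric tolerance of
the application: non-reference calls must be trustworthy). A non-reference
call additionally requires ≥3 variant reads so that sequencing error alone
cannot produce variant calls at high depth. Joint calling across cells is
approximated by sharing a single error rate across the cohort rather than
re-estimating per cell.

Benchmarking uses allele-level confusion accounting at callable sites with
known truth: a call is positive if ≥1 non-reference allele is called.
Sensitivity is undefined at homozygous-reference truth and specificity at
variant-carrying truth, so rates are stratified by truth zygosity and
undefined cells reported as NaN.

## Cellularity likelihood-ratio test

Candidate sources are {clones ∪ non-tumor}; hypotheses are unordered pairs
with replacement. Identical pairs form the pure null — the model cannot
distinguish one cell from two cells of the same clone, and does not try.
Per-cluster source VAF is carriers/4 ∈ {0, 0.25, 0.5}. Log-likelihoods sum
`binom.logpmf` over somatic cluster loci with depth > 0 (depth-0 loci
contribute nothing; an empty selection is log-likelihood 0 and the sample
is reported indeterminate). Germline heterozygous loci are excluded: f =
0.5 under every hypothesis, so they carry no signal. The error rate e is
per-cluster, estimated as the pooled VAF of other-subject cells at the
cluster's loci, clipped to [1e-6, 0.5); per-locus summation with
per-cluster f is the literal model. The statistic is floored at 0 before
the one-sided χ²₁ tail; mixtures of three or more cells are not modeled.

Under study-like noise, ≥90% of simulated single cells classify pure at
α = 0.05 and ≥80% of distinct-clone doublets with ≥20 private loci at deep
coverage classify mixed (verified in the acceptance suite at 200
simulations each).

## Clone assignment and substructure

A cluster is observed in a cell iff ≥3 of its SNVs are callable and the
variant fraction among them is ≥ `tau_detect` = 0.5 — with FNR ≈ 0.12 a
majority rule cleanly separates presence from dropout. The assigned clone
is the deepest clone whose entire cluster lineage is observed; cells with a
descendant cluster observed but an ancestor missing are flagged
inconsistent rather than force-assigned.

Excess reference calls at expected-variant sites are tested per cell by an
exact one-sided binomial tail against the germline-estimated FNR. Candidate
substructure blocks are SNVs sharing the same multi-cell reference pattern;
a block's probability under independent dropout, fnr^(snvs×cells), is
Bonferroni-scaled by the ~C(m,2)·C(n,2) minimal-block positions the scan
could have hit, so 2×2 coincidences (near-certain at study scale) are never
flagged while genuine 5-SNV × 3-cell blocks pass easily.

Branch detection joins a cluster's SNVs into co-occurrence components (edge
= variant together in ≥1 cell); distinct components necessarily have
disjoint supporting cells. A pair of components, each supported by
≥ `min_cells` = 2 cells, is a candidate branch; under the no-substructure
null every off-side reference call must be a dropout, giving null
probability fnr^m, Bonferroni-corrected over tested pairs. On strictly
linear simulations the family-wise false-branch rate stays below α
(verified over 200 replicates).

Outlier rescue matches an outlier SNV's presence/absence pattern to each
cluster's carrier set: any variant call in a non-carrier cell disqualifies
the cluster outright (a false positive is not ADO-explainable); reference
calls among carriers are tolerated up to ⌈fnr × carriers⌉. A unique
surviving cluster is assigned; several (no informative cell separates
nested clusters) is ambiguous; fewer than 4 callable cells spanning ≥2
clones is uninformative. On study-shaped simulations roughly 35–50% of
outliers are confidently assigned.

Clone-frequency concordance pairs each clone's bulk predictor — the mean
VAF of its defining cluster — with the fraction of cells *carrying* that
cluster (the clone plus its descendants), because the cluster's reads come
from every carrier cell, not only cells whose latest cluster it is. The
plain assigned-fraction reading is available by omitting the architecture
argument. With ~12 cells per subject the squared Pearson correlation is
noticeably below 1 (sampling noise at n = 12 dominates); study-scale runs
typically land between 0.6 and 1.0 depending on seed.

## Phylogenies

Genotypes are reduced to binary characters (reference vs. variant allele
present): at validated somatic SNV sites presence/absence is the
biologically meaningful state, and this replaces nucleotide-level
substitution modeling, which is out of scope along with ML topology
search. Distances are mismatch fractions over sites callable in both cells
(pairwise deletion — with ~45% of sites uncallable per cell, listwise
deletion would leave almost nothing); pairs sharing fewer than `min_shared`
= 20 sites are flagged, and a pair with zero shared sites is an error
naming the pair. Neighbor joining follows the Saitou–Nei Q-criterion with
deterministic lexicographic tie-breaks (internal nodes ordered by the
smallest leaf beneath them, making the result invariant to input order) and
negative branch-length estimates clamped to zero after estimation.
Bootstrap support resamples loci with replacement, rebuilds the tree, and
reports bipartition frequencies as percentages on the full-data tree;
replicates in which some pair loses all shared sites are skipped and the
denominator is successful replicates. The two-state likelihood scorer uses
Felsenstein pruning with transition probability (1 − exp(−2·rate·t))/2,
stationary frequencies (0.5, 0.5), and missing calls marginalized; it
scores fixed trees only.

## Pipeline and problem sizes

The default `RunConfig` mirrors the reference cohort: 3 subjects, 12 single cells + 2
two-cell samples each over the 1,953-SNV catalog, bulk depth 500×, 25×
gate, 1,000 bootstrap iterations; it completes in well under a minute on
one CPU. The test suite uses scaled-down catalogs (30-SNV clusters,
5–20 cells) chosen so every statistical check retains clear resolution;
calibration-style checks (type-I control, doublet power) use 200
replicates.

## What the simulator does and does not capture

It emulates the statistical structure the analysis depends on: nested
clone frequencies, diploid het VAFs, ADO symmetry and stochasticity,
overdispersed coverage with locus dropout, doublet dilution, and
cross-subject error levels. It does not model copy-number variation or
aneuploidy, capture-bait or positional biases (coverage is exchangeable
across loci), read-level errors correlated within fragments, or mixtures of
more than two cells. Passing tests therefore demonstrate correctness of the
inference machinery under the stated generative model, not robustness to
artifacts outside it — in particular, CNV-distorted VAFs and
locus-correlated dropout would weaken the cellularity LRT and the
branch-detection null in ways these tests do not measure.
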