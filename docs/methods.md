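# Methods

This note documents the models, estimators, numerical conventions and design
choices behind `scntx`, and what the synthetic-data experiments do and do not
demonstrate about real data.

## Data model

A study consists of several donors' probe-level log2 microarray intensities,
each probe annotated with an integer Entrez gene ID (possibly missing) and a
per-sample presence/absence (PA) flag marking expression above background.
Samples carry a stereotactic MNI coordinate (mm), a structure acronym, and a
hemisphere label. Networks are binary masks on a shared voxel grid with a
voxel-to-mm affine. Gene identity is integer Entrez throughout; gene symbols
are display metadata. Missing Entrez IDs are represented as nullable missing
values, never 0, so the filtering step can remove them explicitly.

## Probe filtering and collapsing

* Probes with missing Entrez IDs are removed.
* The PA-presence fraction of each probe is computed over **all samples
  pooled across donors**; probes below the `pa_fraction` threshold (default
  0.01) are removed. The comparison is `fraction >= threshold` to retain, so
  a probe present in exactly 1% of samples survives.
* Collapsing to one probe per gene follows the probe count: one probe is kept
  as is; of two probes the one with larger sample variance (unbiased, n−1)
  wins; of three or more, the winner maximizes connectivity, defined here as
  the row sum of the **signed** Pearson correlation matrix among the gene's
  probes, excluding self. Correlations involving a constant probe are
  treated as 0. Exact ties are broken by the lexicographically smallest
  probe ID so the choice is order-independent and reproducible.
* All selection statistics use the donor-concatenated raw log2 values
  (computed once), so the chosen probe is identical for every donor. Whether
  to pool or select per donor is genuinely open; pooling was fixed because
  the filtering step is already defined on pooled samples and it guarantees
  a common gene matrix across donors.

## Sample-to-network mapping

Millimetre coordinates are transformed by the inverse affine and rounded to
the nearest voxel with **half-away-from-zero** rounding — chosen over
banker's rounding to avoid platform-dependent assignment of coordinates that
land exactly on voxel boundaries. There is no mask interpolation and no
tolerance radius: a sample is in a network iff its nearest voxel is. Voxels
belonging to more than one mask are a configuration error by default; the
`first` policy resolves them by atlas order with a logged warning. Hemisphere
is metadata only — both hemispheres map through the same rule.

## Donor-level differential expression

Welch's unequal-variance t test compares the target network's samples with
the pooled comparison networks within each donor. The effect size is the raw
mean difference of log2 intensities (the log2 fold-change); its sampling
variance is `s²₁/n₁ + s²₂/n₂`, with Welch–Satterthwaite degrees of freedom.
Welch was chosen over the pooled-variance t because network sample sizes are
highly unbalanced (tens vs hundreds) and group variances cannot be assumed
equal. A donor contributes no records when either group has fewer than two
samples; genes with zero variance in both groups yield invalid records that
are excluded from meta-analysis.

## DerSimonian–Laird meta-analysis

The moment estimator of between-donor variance is

    τ² = max(0, (Q − (k−1)) / C),   C = Σw − Σw²/Σw,   w_i = 1/v_i,

with the summary effect the inverse-variance-weighted mean under weights
`1/(v_i + τ²)` and standard error `(Σ 1/(v_i+τ²))^(−1/2)`. The default
summary significance test is the two-sided z test on `FC/se` — standard
practice for DL summaries. A donor-level one-sample t test of the k donor
fold-changes against zero (df = k−1) is available as
`summary_test="donor-t"`; the two options bracket the ambiguity in how a
"t test with unequal variances" can be applied to a summary effect. A gene
observed in a single donor is passed through with τ² = 0 and flagged via
k = 1. Donors with non-positive variance are excluded with a warning.

Multiple testing uses the Benjamini–Hochberg step-up procedure across all
tested genes (one shared implementation, reused by every enrichment family
and by EWCE). Differential expression requires `|FC| > 1` **and** BH-adjusted
`p < .05`, both strict, so boundary values are never called.

## Differential stability

Expression is averaged per structure acronym within each donor; for each
donor pair the per-gene Pearson correlation is computed across structures
present in both donors. A pair is skipped for a gene when fewer than
`min_shared` (default 3) structures are shared or either profile is
constant. The DS value is the mean over retained pairs; deciles rank all
scored genes with decile 10 the most stable. Structure-level averaging
defines "shared samples" across donors because samples themselves are
donor-specific.

## Enrichment statistics

The universe for every family is the set of genes surviving probe collapsing
— one consistent background for pathways, cell types and diseases. Sets
whose in-universe size falls below the family minimum (pathways 10, cell
types 6, diseases 1) are excluded **before** testing, and BH correction runs
across exactly the tested sets of that family. The p-value is the upper-tail
hypergeometric probability of the observed overlap; the odds ratio is the
unconditional cross-product `(a·d)/(b·c)` of the 2×2 table, reported as +inf
when `b·c = 0` with `a·d > 0` (no continuity correction) and missing when
both products vanish.

Mouse marker sets are converted to human through an explicit homology table.
Markers without a homology row are dropped; any human gene claimed by two or
more distinct mouse source genes is ambiguous and removed from **every**
cell type before testing.

## EWCE bootstrap

Specificity is each gene's mean linear-scale expression in a cell type
divided by its summed mean expression over all cell types (log-scale input
must be de-logged upstream; all-zero genes are flagged and excluded). The
test statistic is the target list's mean specificity per cell type, compared
with `reps` random gene lists of the same size drawn uniformly without
replacement from the specificity matrix — no expression-level or
transcript-length matching, since the sampling null is defined as uniform.
The p-value uses the add-one rule `(1 + #{null ≥ observed})/(1 + reps)`, so
p is never exactly 0 and the null p distribution is super-uniform. When the
number of distinct lists `C(n, |target|)` does not exceed `reps`, the null
is enumerated exhaustively instead of sampled; the reported effective
replicate count is then the number of enumerated lists, and the estimator is
within `1/(#lists + 1)` of the exact enumeration probability. Given a seed,
results are bitwise reproducible.

## Reporting

Z-scores are computed per gene across each donor's samples with the n−1
standard deviation; constant genes become all-zero rows and are flagged.
The cell-type × network matrix averages in a fixed order — marker genes,
then samples within a network, then donors — because the three means do not
commute when group sizes differ. All aggregations are permutation-invariant
in donors, samples and genes.

## Synthetic data generator

The generator emulates the *structure* of a six-donor brain-wide microarray
survey at reduced scale. Expression is additive Gaussian on the log2 scale:
gene baseline (N(8, 2²)) + per-donor gene shift (sd 0.3) + planted network
effect + structure effect + residual noise (sd 0.5). This is the minimal
model under which the Welch-t + DL-meta machinery is correctly specified:
the tests validate the statistical pipeline, not microarray biology.

* **Planted effects** (default 25 up + 25 down in each of networks C and D,
  |log2 FC| uniform in [1.2, 2.0]) are realized per donor as
  nominal + N(0, τ) with τ = 0.15, so between-donor variance estimation is
  exercised.
* **Structure effects** give a configurable set of genes donor-consistent
  regional profiles (hence high differential stability). They are
  mean-centered within each network's structure group so these genes remain
  null for network contrasts and do not contaminate the planted-effect
  ground truth.
* **Probes** replicate the gene signal plus probe noise; one designated
  high-fidelity probe (noise sd 0.1) per gene is recorded in the truth,
  others draw noise sd from [0.3, 0.8]. Extra never-present probes and
  missing-Entrez probes exercise the filters.
* **Geometry.** Nine disjoint axis-aligned boxes tile a 3×3 arrangement on a
  16×32×32 grid at 2 mm, built mirror-symmetric about the mid-sagittal
  plane; bi-hemispheric donors' right-hemisphere samples are x-mirrored left
  draws, so every sample maps back to its generating mask exactly. Samples
  sit at a voxel center plus sub-voxel jitter (< half a voxel), making
  mapping closure exact by construction.
* **Resources.** One positive marker set / pathway / disease draws most of
  its genes from the planted up-regulated genes; the homology table plants a
  configurable number of two-mouse-to-one-human collisions and omits some
  markers entirely; two cell types are generated below the 6-marker testing
  minimum.

Default scale is about 2,000 genes and 9×40 samples per donor (versus
~20,000 genes and ~3,700 samples in a full atlas); full scale is a config
change. The reference conditions (6 donors, 2 bi-hemispheric, noise 0.5,
100 planted genes) are what the acceptance script runs. The generator makes
no attempt to mimic real spatial autocorrelation, anatomical geometry, or
array normalization artifacts — so passing tests demonstrate correctness of
the estimators under the stated model, not robustness to spatially
autocorrelated expression, and enrichment results on real atlas data can
still be biased toward co-expressed gene sets.

## Seeding and determinism

All randomness derives from explicit seeds: generator streams are
`default_rng([seed, stream_index])` with fixed stream indices (0 for
allocation, 1+i per donor, 1000 for resources), and the pipeline derives its
EWCE seed from the run seed via a seed sequence. Reruns with identical
config are byte-identical; outputs never embed timestamps, and NIfTI masks
are written uncompressed for stable bytes.

## Known limitations

* The sample-to-network rule is nearest-voxel only; no native-to-MNI warping
  or partial-volume handling.
* No moderated variance shrinkage or covariate adjustment in DE; no
  permutation p-values.
* The DL z test is slightly anti-conservative for very few donors; the
  donor-t option is more conservative but loses the inverse-variance
  weighting.
* Disease enrichment treats associations as unweighted memberships.
* EWCE's uniform null does not control for expression level or gene length.
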