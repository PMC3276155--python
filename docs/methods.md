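# Methods

This note records the models, defaults and design decisions behind
`poolfit`, in the order the pipeline runs.

## Synthetic pooled-fermentation screens (`simpool`)

The generator emulates a competitive-growth screen of a pooled deletion
collection sampled through a closed fermentation.

**Growth model.** Each in-pool strain starts at equal frequency.  Strain
*i* with relative fitness *s<sub>i</sub>* (dimensionless deviation of its
growth rate per population doubling; 0 = neutral, bounds ±1) has
abundance *a<sub>i</sub>(t) = a<sub>i</sub>(1)·2^((1+s<sub>i</sub>)·D(t))*
where *D(t)* is the cumulative number of population doublings by sampling
day *t*; frequencies are abundances renormalized per day.  The default is
deterministic — recovery tests need a controllable signal — with optional
multinomial resampling of the sampled aliquot (`sample_cells`) to model
drift.  The default doublings schedule `[0, 1, 2, 3, 3.7, 4.2, 4.5]` for
days 1, 2, 4, 6, 8, 10, 14 is a saturating curve: rapid early growth that
flattens as sugars deplete and ethanol accumulates.  Day 1 is the
hybridization control on every array (two-color design), so *D*(day 1) = 0.

**Viability.** Only live cells are sampled; frequencies are of live cells
and no dead-cell compartment is modeled.

**Array model.** Every strain (false barcodes included) contributes
`n_replicate_spots` spots per existing tag.  For a live in-pool tag the
experimental-channel foreground is
`scale · f(t) · tag_efficiency · 2^bias(A₀) · 2^η + background` and the
control channel uses the day-1 frequency; η ~ N(0, `noise_sd_log2`) is
multiplicative log-normal noise per channel per spot, and the dye bias
`bias(a) = amplitude·sin(a) + trend·(a − a_mid)` is a smooth function of
the spot's noise-free mean log2 intensity (trend defaults to 0, so the
injected artifact is exactly a sinusoid of the stated amplitude).  Tag
efficiencies are log-normal (SD 0.25 log2) per tag, constant across days,
creating the per-tag intensity spread the thresholding stage must handle.
Dead tags and false barcodes emit `background · 2^η` in both channels:
their expected foreground is the background level (exactly so at zero
noise) and their *A* values sample the noise floor.

**Reference conditions.** The validation experiments use 4000 in-pool
strains with 300 planted at s = −0.4 and 150 at s = +0.4, 200 false
barcodes, 4 replicate spots per tag, a 5% dead-tag rate and 0.3 log2
noise.  Effect sizes of |s| = 0.4 over 4.5 doublings produce ~1.8 log2
units of depletion by day 14 — a clear but not trivial signal, the regime
a well-powered screen operates in.  Array `scale` (4×10⁷) and
`background` (200) are synthetic conventions chosen to give realistic
four-digit foregrounds; no published values exist for them.

**What the generator does not emulate.** Print-tip/block spatial
structure, saturation of the scanner, carry-over between arrays,
cross-hybridization between similar barcodes, biological replicates and
batch effects.  Passing recovery tests therefore demonstrates the
statistical machinery is correct under the stated noise model, not that
real arrays meet that model.

## Normalization (`normalize`)

Background is subtracted per channel and values below 1 floored at 1;
spots then get M = log2(exp/ctl) and A = 0.5·log2(exp·ctl).  The floor
makes A well defined for empty spots (A = 0) and caps how negative a
ratio can get.

The dye-bias trend is removed by subtracting a loess fit of M on A,
estimated on usable in-pool spots (false barcodes sit at the noise floor
and would drag the curve down) and applied to all spots, flat beyond the
fitted range.  The smoother is a tri-cube-weighted local **quadratic**
(span 0.3 of the data, 3 bisquare robustness iterations), evaluated at
anchor points thinned to 0.3% of the A range with isolated extreme points
always anchored.  Degree 2 is deliberate: spots in the sparse intensity
tails see strongly one-sided neighbor windows, where a local line cannot
follow the curvature of a smooth bias and leaves a residual of ~0.1 log2
exactly on the outlying spots; the quadratic term removes it (worst-case
residual 0.01 log2 on a noise-free null array with an amplitude-0.6
sinusoidal bias).  With fewer than 50 usable spots the array passes
through unnormalized with a warning.

## Tag statistics (`tagstats`)

**Thresholds.**  One intensity threshold on A per (array, tag kind),
because the two tag sets hybridize with different efficiency.  In
homozygous-pool mode the threshold is the smallest observed false-barcode
A such that at most 5% (the `target_fpr`) of false-barcode values lie
strictly above it — false barcodes estimate the noise floor, so this
bounds the false-positive rate among significant spots.  Heterozygous
pools have few false barcodes; there a two-component Gaussian mixture is
fitted to all A values and the threshold is the equal-posterior crossing
between the component means.  The mixture is rejected as degenerate —
falling back to the histogram-valley minimum, then to the 1st percentile
with a warning — when a component weight is < 0.05, the means are closer
than 0.5, or the mixture density at the crossing is not at least 30%
below both component peaks (a split of one unimodal bulk produces a
"crossing" with no real valley).

**Sparse tags.** A (strain, tag) row is excluded when significant spots
make up less than 40% of all its replicate spots across all arrays;
exactly 40% is kept (the exclusion rule is a strict inequality).

**Standardization.** Significant M values are converted to Z scores per
(array, tag kind): mean 0, *population* SD 1 — the population SD ties the
"SD of 1" contract to an exact testable identity.  Location and scale are
estimated from significant in-pool spots only, so false barcodes cannot
distort them.

**Combination order.** Z-standardize at spot level → average significant
replicates within (strain, tag, array) → unweighted mean of the UP and DN
tag values.  The alternative (combining tags before averaging replicates)
differs only when replicate counts are unequal between tags; the
per-tag-first order keeps each tag's replicate structure from dominating
the other tag.  A strain-day cell is missing when no spot was
significant.  False-barcode rows are then purged using the key.

The 2-fold call threshold is applied to these standardized values by
default (`value_scale="z"`), matching the workflow order in which
standardization precedes selection; `value_scale="m"` applies it to raw
normalized log2 ratios instead, for users who want the literal 2-fold
reading.  On the reference screens the per-array SD is ~0.45–0.7 log2, so
|z| ≥ 1 and |M| ≥ 1 select similar but not identical strain sets.

## Calls (`calls`)

Depletion is evaluated on values ≤ −1 and enrichment on values ≥ +1
(inclusive), independently; `min_timepoints` defaults to 3.  `any` mode
counts qualifying days; `sequential` mode requires a run of consecutive
*sampled* days, and a missing measurement breaks a run (conservative: an
unobserved day never extends evidence).  Strains passing both directions
are reported as `both` and excluded from per-direction overlaps.  Strains
with fewer than 3 non-missing days are `none` with an insufficiency flag.

## Clustering (`cluster`)

Row filters: `any_change` keeps profiles with at least one |value| ≥ 1;
`half_significant` requires |value| ≥ 1 in ≥ 50% of non-missing cells.
The filters read "no significant change (all log2 values < 1)" as a
statement about absolute values; a signed interpretation is selectable
(`absolute=False`).

Similarity is the uncentered correlation Σxy/√(Σx²Σy²) over pairwise
non-missing positions (the matrix may have missing cells; pairs with no
overlap or a zero-norm profile raise an error naming the rows).  Linkage
is average (UPGMA): inter-cluster distance is the unweighted mean of
1 − similarity over all cross-pair leaves, implemented with the
Lance–Williams update, which is exact for this linkage.  Ties in the
minimum distance are broken on the lexicographically smallest pair of
cluster representatives (each cluster represented by its smallest
original row index), making the merge sequence deterministic.  Merge
distances are asserted nonnegative but not monotone.  Output is a
CDT/GTR pair (similarity = 1 − distance; missing cells serialized empty).

## Enrichment (`enrich`)

P(X ≥ k) is summed in log space (log-binomials via `gammaln`, combined
with `logsumexp`) so tails near 10⁻³⁰⁰ survive; k ≤ 0 returns exactly 1.
Bonferroni multiplies by m, the number of categories with K ≥ 1 in the
current universe — a fixed catalogue size can be forced via
`m_override`.  Manual gene additions are unioned into a category before
counting (both k and K move) and flagged; a switch restricts the test to
pre-addition counts.  Only enrichment (upper tail) is tested.

The synthetic catalogue used for calibration has 459 categories with
log-normal sizes (median ≈ 60, clipped to [10, 300]), matching the span
of a genome-scale functional catalogue (pathway-sized through broad
processes).  Categories below ~10 genes make tail probabilities so
discrete that a calibration check loses meaning at the 5% level, which is
why the clip bound sits there.

## Validation experiments (`benchmarks`, `scripts/acceptance.py`)

All validation numbers are recomputed at run time: planted-effect
recovery and null call rates over five reference screens (4000 strains
each), false-barcode threshold leakage, the loess worst-case residual,
the planted-pathway enrichment (19 of 23 category genes in a 300-gene
hit set from a 3734-gene universe, Bonferroni m = 459), and the fraction
of (category, random-hit-set) pairs at nominal p ≤ 0.05 / 0.01 over
10,000 draws.  These sizes keep the whole script under a minute on one
CPU while leaving the statistics stable to well under a percentage point.

## Known limitations

* The loess span/iterations and the mixture-threshold heuristics are
  conventional defaults, not fitted to any published array set.
* The UP/DN combination rule (unweighted mean) is a choice; weighting by
  replicate count or tag variance would differ for noisy tags.
* Sequential runs are defined over sampled days, not calendar days: days
  4 and 6 are consecutive samples even though two calendar days apart.
* Enrichment treats categories as flat sets; no ontology propagation.
* The pipeline assumes one biological replicate per time point, as in the
  screen design it models; it provides no replicate-level variance model.
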