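# Methods

## Problem setting

Somatic mutations are present in a tumor but absent from the patient's
matched normal genome. Callers detect them by contrasting tumor and normal
sequencing evidence, and they disagree: each embodies different assumptions
about contamination, allele-frequency priors and artifact filtering. This
package treats the per-caller verdicts as features. The union of all calls
bounds the attainable sensitivity; a supervised classifier trained on
candidates with known status then separates true somatic mutations from the
pooled false positives.

## Candidate representation

Candidates are keyed by `(chrom, pos, ref, alt)` with 1-based VCF
coordinates. Multi-allelic records are split per alternate allele at
ingest, since votes and evidence are per-allele. Indels are reduced to a
canonical anchored form by trimming shared trailing then leading bases
(advancing the position), which merges the common padding differences
between callers. Full left-alignment against a reference genome is *not*
performed: the merge stage deliberately has no FASTA dependency, so indels
shifted across a repeat by different callers remain distinct keys. Variant
class is SNV iff both alleles are single bases, INDEL otherwise; models and
metrics treat the two classes separately.

## Feature vector

Per candidate: one binary `called_<id>` and one `score_<id>` per configured
caller; tumor/normal depth, stranded ref/alt counts and implied VAF;
root-mean-square mapping and base quality per sample; mismatch counts; mean
tail distance of variant bases (distance from read end, normalized);
strand-bias odds ratio and two-sided Fisher exact p-value on
`[[ref_fwd, ref_rev], [alt_fwd, alt_rev]]`; the Phred-scaled Fisher p-value
of the strand-summed normal-vs-tumor allele table (capped at 255); and an
optional binary dbSNP membership.

Choices that the field leaves open, fixed here:

- **Missing values** are sentinels, not NaN: −1 for scores and qualities,
  0 for counts. Decision trees split on sentinels like any other value, so
  "caller did not score this site" is itself learnable signal.
- **Fisher's exact test** is two-sided by hypergeometric enumeration (sum of
  point probabilities ≤ the observed one, with a 1e−9 relative tolerance in
  the comparison), computed with log-binomials via `gammaln`. No normal
  approximation is used; determinism and exactness matter more than speed
  at pileup scale.
- **Odds ratio** uses the Haldane–Anscombe +0.5 correction in all cells
  whenever any cell is zero; an all-zero table is defined as unbiased
  (OR = 1, p = 1) so the learner always sees finite features.
- A "tail distance bias" statistic (a contrast between alleles) has no
  agreed definition; the mean tail distance of the variant allele is
  exposed instead.

## Classifier

Discrete AdaBoost with exponential loss, stochastic subsampling, and
depth-limited CART trees as weak learners:

- At round *m*, a tree is grown on a uniformly drawn subsample (default
  50 % of rows, without replacement) under the current example weights, by
  exhaustive weighted-Gini search over midpoints of consecutive distinct
  sorted feature values. Ties break toward the lowest feature index, then
  the lowest threshold, making fits deterministic given the seed.
- ε_m is the tree's weighted error on the **full** training set;
  α_m = learning_rate · ½·ln((1−ε_m)/ε_m), with ε clamped to
  [1e−10, 0.5−1e−10]. A subsample tree worse than chance therefore gets
  ~zero weight and training continues (with a warning) rather than halting.
  ε_m = 0 ends training early, as further rounds cannot change anything.
- Weights update as w ← w·exp(−α_m·y·h_m(x)), renormalized.
- Probability map: P = 1/(1+exp(−2F)) with margin F = Σ α_m h_m — the
  logistic correspondence of the exponential-loss population minimizer.
  With `subsample_fraction=1`, `learning_rate=1` the training exponential
  loss is non-increasing per round (asserted as a test property).

Defaults: 500 rounds, depth 3, subsample 0.5, learning rate 1. These echo
the conventional stochastic-boosting defaults; all are exposed. No class
reweighting is applied by default. Feature importance is the
stage-weight-weighted Gini impurity decrease summed per feature and
normalized to 1.

Tiers: PASS iff P ≥ 0.7, REJECT iff P ≤ 0.1, LowQual between; the 0.7
default slightly favors precision over sensitivity and both thresholds are
configurable. Models serialize to versioned JSON (trees, stage weights,
feature names, config, seed) and reload to bit-identical predictions.

## Evaluation

A truth set is a disjoint partition into somatic, reference and ambiguous
site keys. tp = |calls ∩ somatic|, fp = |calls ∩ reference|; ambiguous
calls — and calls outside the partition — are ignored entirely. Undefined
ratios (precision of an empty call set, F1 at zero/zero) are reported as
missing rather than zero, so averages over cross-validation repeats are not
silently deflated. Matching is exact on the normalized candidate key.

The benchmarking protocol is twofold cross-validation repeated ten times:
each repeat splits rows 50/50 (redrawing if a half is single-class), trains
on each half and scores the other. Twofold is preferred over tenfold so the
validation half is never too small.

## Titration simulator

The simulator emulates, at allele-count level, the construction of virtual
tumor–normal pairs by mixing two genomes:

- **Truth rules.** Normal hom-ref + tumor het → somatic; hom-ref in both →
  reference; every other genotype pair → ambiguous. `enforce_prior_rate`
  downsamples the somatic truth to round(rate × interrogated sites) entries
  and masks the remainder into the ambiguous class, reproducing the
  enforcement of a realistic (~1e−6) somatic prior when two germline
  genomes (which differ at ~1 site in 2700) stand in for a tumor pair.
- **VAF dilution.** A subclone of pure VAF v in a sample with tumor
  fraction f has expected VAF v·f, because contaminating reads carry the
  reference allele at somatic sites. Defaults model the standard scenarios:
  clean (fractions 1/0) and cross-contaminated (tumor fraction 0.70 in the
  tumor, 0.05 in the normal), with subclone VAFs (0.50, 0.33, 0.20) and
  30× target depth.
- **Counts.** Depth ~ Poisson(target) (or fixed); alt reads ~
  Binomial(depth, VAF + (1−VAF)·e) with base error rate e = 0.001; strands
  split Binomial(0.5). 30 % of reference sites carry an artifact: a
  Beta(1.5, 15) alt fraction (mean ≈ 9 %, mostly confined to the tumor
  library), 85 % forward-strand bias, degraded mapping (μ 40 vs 58) and
  base (μ 26 vs 34) qualities, elevated mismatches, and variant bases near
  read ends. These are the sites that generate caller false positives and
  that the classifier must learn to reject.
- **Virtual callers.** Five profiles echo the qualitative characters of
  widely used tools: a sensitive low-VAF caller that collapses to 5 %
  sensitivity when the normal shows >1 alt read; a genotype-change caller
  tolerant of impure normals but germline-leaky; a Fisher-test caller with
  built-in minimum-VAF (10 %) and depth (8×) filters; a joint-genotype
  over-caller (highest sensitivity, FP rate 0.25 on artifact sites); and a
  permissive Fisher-test caller. Scores are emitted as noisy Phred
  genotype-change statistics or Fisher p-values per profile. Reference-site
  definitions can be frozen and reused across the mixture configs of one
  experiment so the same artifact sites supply the false positives in every
  setting.

What the simulator does **not** model: read sequences, alignment and
mapping artifacts in low-complexity regions, indel realignment error, GC
and coverage waves, or correlated errors across sites. Passing tests show
that the pipeline's statistics and learning machinery behave correctly on
data with this structure; they do not certify accuracy on real tumors,
where feature distributions are harsher and artifact classes are more
diverse.

## Problem sizes used in the test suite

The simulation-backed properties run on 2,000 somatic + 20,000 reference
candidates with the five default caller profiles, using 50 boosting rounds
of depth-2 trees at 50 % subsampling for the cross-validated experiments —
ample for separation on these conditions while keeping the suite quick.
The training-size experiment averages three seeds per size over
{10, 20, 100, 200, 1000} somatic training examples (with 10× as many
reference rows), evaluated on a fixed held-out half.

## Known limitations

- Indel merging is trimming-based; repeat-shifted representations from
  different callers are not unified without a reference.
- The BAM evidence extractor counts indel support from pileup indel flags
  only (no local reassembly); complex indels may be undercounted.
- Caller scores in the simulator are derived from the same evidence the
  feature extractor sees, so simulated score features are more redundant
  with count features than real caller scores would be.
- The probability calibration is the fixed logistic map; no post-hoc
  calibration curve is fitted.
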