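# somatic-ensemble

Ensemble somatic mutation calling for tumor–normal pairs.

No single somatic variant caller works well on every cancer sample: strict
Bayesian callers lose sensitivity the moment the matched normal is
contaminated with tumor cells, genotype-change callers leak germline
variants, and permissive callers drown their true calls in artifacts. This
package implements the ensemble strategy that turns that diversity into an
advantage:

1. **Union merge** — per-caller somatic VCFs are normalized (shared-flank
   trimming, per-allele splitting of multi-allelic records) and merged into
   a union candidate set keyed by `(chrom, pos, ref, alt)`, with one binary
   vote and optional native score per caller per candidate. The union
   maximizes sensitivity; the classifier restores precision.
2. **Feature extraction** — each candidate becomes a numeric vector: caller
   votes/scores, tumor and normal depth, stranded ref/alt read counts,
   root-mean-square mapping and base qualities, mismatch load, tail
   distance, the strand-bias odds ratio and Fisher exact p
   (`[[ref_fwd, ref_rev], [alt_fwd, alt_rev]]`), the Phred-scaled
   genotype-change Fisher p (`[[n_ref, n_alt], [t_ref, t_alt]]`), and
   optional dbSNP membership.
3. **Stochastic adaptive boosting** — a natively implemented discrete
   AdaBoost over depth-limited CART trees. At round *m* a tree *h_m* is fit
   to a weighted subsample; its weighted error ε_m gives the stage weight
   α_m = ½·ln((1−ε_m)/ε_m), examples are reweighted by exp(−α_m·y·h_m(x)),
   and the margin F(x) = Σ_m α_m·h_m(x) is calibrated to a probability
   P = 1/(1 + e^(−2F)). Candidates are tiered **PASS** (P ≥ 0.7),
   **LowQual** (0.1 < P < 0.7) or **REJECT** (P ≤ 0.1).
4. **Evaluation** — sensitivity, precision, F1 = 2sp/(s+p) and NPV against a
   truth set partitioned into somatic / reference / ambiguous sites
   (ambiguous sites never enter any count), plus repeated twofold
   cross-validation and PASS-cutoff sweeps.
5. **In silico titration simulator** — virtual tumor–normal mixtures at the
   allele-count level: het sites dilute to VAF = 0.5 × (tumor fraction),
   read counts are binomial at Poisson depth, a configurable fraction of
   reference sites carry strand-biased low-quality artifacts, and five
   virtual callers with distinct error profiles vote on every site. The
   whole pipeline is therefore testable with no BAMs, no external callers
   and no downloads.

The boosting core is an sklearn-style estimator
(`StochasticAdaBoostClassifier`, with `fit` / `predict_proba` /
`get_params` / `feature_importances_`) and composes with sklearn model
selection.

## Worked example

Simulate a cross-contaminated pair (tumor carrying 30 % normal cells,
normal carrying 5 % tumor cells — het subclone VAFs 50/33/20 % dilute to
35/23/14 % in the tumor and 2.5 % in the normal), score each virtual caller,
and cross-validate the ensemble:

```python
import numpy as np
from somatic_ensemble import (
    generate_dataset, cross_contaminated_pair_config,
    cross_validate, evaluate, TrainingConfig,
)

ds = generate_dataset(cross_contaminated_pair_config(seed=7),
                      n_somatic=1000, n_reference=10000, seed=7)
for cid in ds.caller_ids:
    r = evaluate(ds.caller_calls(cid), ds.truth)
    print(f"{cid:18s} sens={r.sensitivity:.3f} prec={r.precision:.3f} F1={r.f1:.3f}")
cv = cross_validate(ds.features, ds.labels.to_numpy(),
                    TrainingConfig(n_iterations=50, max_depth=2),
                    n_repeats=10, seed=3)
print(f"ensemble (2-fold x10 CV)   F1={cv.mean_f1:.3f} +/- {cv.std_f1:.3f}")
```

prints

```
mutect_like        sens=0.796 prec=0.951 F1=0.867
sniper_like        sens=0.754 prec=0.904 F1=0.822
varscan_like       sens=0.842 prec=0.856 F1=0.849
jointsnvmix_like   sens=0.957 prec=0.694 F1=0.805
vardict_like       sens=0.875 prec=0.805 F1=0.839
ensemble (2-fold x10 CV)   F1=0.982 +/- 0.003
```

Every virtual caller trades sensitivity against precision in its own way
(the contamination-intolerant caller loses recall, the permissive caller
loses precision); the cross-validated ensemble clearly beats the best of
them. Individual trees of the fitted model can be printed with
`export_tree(model, 0)`:

```
tumor_tail_distance_mean < 0.2906094029862186
  tumor_alt_rev < 6.0
    -1 *
    +1 *
  tumor_vaf < 0.053571428571428575
    -1 *
    +1 *
```

(internal nodes read "feature < threshold", the left block is where the
condition holds, and `*` marks terminal nodes voting −1 = artifact /
+1 = somatic).

## Command line

```bash
somatic-ensemble simulate --out-dir data --n-somatic 500 --n-reference 5000 --seed 1
somatic-ensemble merge --vcf data/callers/mutect_like.vcf:mutect_like \
                       --vcf data/callers/vardict_like.vcf:vardict_like \
                       --out union.vcf
somatic-ensemble extract-features --union union.vcf --pileup data/pileup.tsv --out features.tsv
somatic-ensemble train --features features.tsv --truth data/truth.vcf --out model.json
somatic-ensemble predict --features features.tsv --model model.json --out calls.vcf
somatic-ensemble evaluate --calls calls.vcf --truth data/truth.vcf --out metrics.tsv
somatic-ensemble sweep --features features.tsv --labels data/labels.tsv --out sweep.tsv
```

All formats are plain text (VCF 4.2, TSV, JSON models, YAML configs) and
every stage is deterministic given its seed.

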