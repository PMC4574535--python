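"""End-to-end orchestration: merge -> features -> train/predict -> tier -> evaluate.

Thin glue over the library modules, driven by a YAML-serializable RunConfig.
SNV and indel candidates are modelled separately: `split_by_class` partitions
a feature matrix so a model can be trained and applied per variant class.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Optional, Sequence

import numpy as np
import pandas as pd
import pysam
import yaml

from . import boosting, evaluation, features as feat, variants
from .boosting import (
    ClassifiedCall,
    StochasticAdaBoostClassifier,
    TrainingConfig,
    assign_tier,
)
from .variants import UnionCallSet, VariantCandidate

__all__ = [
    "CallerSpec",
    "RunConfig",
    "derive_labels",
    "run_train",
    "run_predict",
    "write_classified_vcf",
    "read_classified_vcf",
    "split_by_class",
    "evaluate_calls_by_class",
]

logger = logging.getLogger("somatic_ensemble")


@dataclass
class CallerSpec:
    caller_id: str
    vcf: str
    score_key: Optional[str] = None


@dataclass
class RunConfig:
    """Full configuration of one pipeline run."""

    callers: list = field(default_factory=list)        # list[CallerSpec]
    truth_vcf: Optional[str] = None
    dbsnp: Optional[str] = None
    include_dbsnp: bool = False
    training: TrainingConfig = field(default_factory=TrainingConfig)
    pass_threshold: float = boosting.PASS_THRESHOLD
    reject_threshold: float = boosting.REJECT_THRESHOLD
    seed: int = 0

    @staticmethod
    def from_yaml(path: str | Path) -> "RunConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        callers = [CallerSpec(**c) for c in raw.pop("callers", [])]
        training = TrainingConfig(**raw.pop("training", {}))
        return RunConfig(callers=callers, training=training, **raw)

    def to_yaml(self, path: str | Path) -> None:
        payload = asdict(self)
        with open(path, "w") as fh:
            yaml.safe_dump(payload, fh, sort_keys=False)


def derive_labels(feature_index: Sequence[str], truth_somatic: set,
                  truth_ambiguous: Optional[set] = None) -> pd.Series:
    """Binary labels for feature rows by truth membership.

    Rows at ambiguous truth sites get label -1 (to be excluded from
    training); somatic sites 1; everything else 0.
    """
    truth_ambiguous = truth_ambiguous or set()
    som_keys = {_as_key_string(k) for k in truth_somatic}
    amb_keys = {_as_key_string(k) for k in truth_ambiguous}
    labels = []
    for key in feature_index:
        if key in amb_keys:
            labels.append(-1)
        else:
            labels.append(1 if key in som_keys else 0)
    return pd.Series(labels, index=list(feature_index), name="label")


def _as_key_string(key) -> str:
    if isinstance(key, str):
        return key
    chrom, pos, ref, alt = key
    return f"{chrom}:{pos}:{ref}:{alt}"


def run_train(
    features: pd.DataFrame,
    truth_somatic: set,
    config: RunConfig,
    model_path: str | Path,
    report_path: Optional[str | Path] = None,
    truth_ambiguous: Optional[set] = None,
    cross_validate: bool = False,
) -> StochasticAdaBoostClassifier:
    """Train a model from a feature matrix and a somatic truth set.

    Writes the model JSON (byte-reproducible given config + seed) and an
    optional training report with class counts, ranked feature importances
    and, on request, repeated twofold CV metrics.
    """
    labels = derive_labels(features.index, truth_somatic, truth_ambiguous)
    usable = labels >= 0
    X = features.loc[usable]
    y = labels[usable].to_numpy()
    n_pos = int(y.sum())
    if n_pos == 0 or n_pos == len(y):
        raise ValueError(
            "truth set and candidates do not overlap into two classes "
            f"(positives: {n_pos} of {len(y)})"
        )
    logger.info("training on %d candidates (%d somatic, %d other)",
                len(y), n_pos, len(y) - n_pos)

    cfg = config.training
    model = StochasticAdaBoostClassifier.from_config(
        TrainingConfig(cfg.n_iterations, cfg.max_depth,
                       cfg.subsample_fraction, cfg.learning_rate,
                       seed=config.seed)
    )
    model.fit(X, y)
    boosting.save_model(model, model_path)

    report = {
        "n_candidates": int(len(y)),
        "n_somatic": n_pos,
        "n_other": int(len(y) - n_pos),
        "n_excluded_ambiguous": int((~usable).sum()),
        "seed": config.seed,
        "feature_importance": [
            {"feature": name, "importance": imp}
            for name, imp in boosting.feature_importance(model)
        ],
    }
    if cross_validate:
        cv = evaluation.cross_validate(
            X, y, cfg, seed=config.seed,
            pass_threshold=config.pass_threshold,
        )
        report["cross_validation"] = cv.summary()
    if report_path is not None:
        with open(report_path, "w") as fh:
            json.dump(report, fh, indent=1)
            fh.write("\n")
    return model


def run_predict(
    features: pd.DataFrame,
    model: StochasticAdaBoostClassifier,
    config: Optional[RunConfig] = None,
) -> list[ClassifiedCall]:
    """Classify candidates, returning per-candidate P and confidence tier."""
    config = config or RunConfig()
    if len(features) == 0:
        return []
    P = model.somatic_probability(features)
    calls = []
    for key, p in zip(features.index, P):
        cand = VariantCandidate.from_key_string(key)
        calls.append(ClassifiedCall(
            candidate=cand,
            P=float(p),
            tier=assign_tier(float(p), config.pass_threshold,
                             config.reject_threshold),
        ))
    return calls


def write_classified_vcf(
    calls: Sequence[ClassifiedCall],
    path: str | Path,
    union: Optional[UnionCallSet] = None,
) -> None:
    """VCF 4.2 output: FILTER carries the tier, INFO P the probability.

    When the union call set is supplied, per-caller vote flags are retained
    in INFO. An empty call list still yields a valid, fully headered VCF.
    """
    header = pysam.VariantHeader()
    contigs = list(dict.fromkeys(c.candidate.chrom for c in calls))
    if union is not None:
        contigs = union.contig_order or contigs
    for contig in contigs or ["chr1"]:
        header.contigs.add(contig)
    for call in calls:
        if call.candidate.chrom not in header.contigs:
            header.contigs.add(call.candidate.chrom)
    header.add_line('##FILTER=<ID=LowQual,Description="0.1 < P < 0.7">')
    header.add_line('##FILTER=<ID=REJECT,Description="P <= 0.1, likely false positive">')
    header.add_line('##INFO=<ID=P,Number=1,Type=Float,'
                    'Description="Probability of true somatic mutation">')
    header.add_line('##INFO=<ID=VC,Number=1,Type=String,'
                    'Description="Variant class (SNV or INDEL)">')
    if union is not None:
        for cid in union.caller_ids:
            header.add_line(
                f'##INFO=<ID=CALLED_{cid},Number=1,Type=Integer,'
                f'Description="Called by {cid} (0/1)">'
            )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for call in calls:
            cand = call.candidate
            rec = out.new_record(
                contig=cand.chrom, start=cand.pos - 1,
                alleles=(cand.ref, cand.alt),
            )
            rec.filter.add(call.tier)
            rec.info["P"] = call.P
            rec.info["VC"] = cand.var_class
            if call.P > 0:
                rec.qual = float(min(-10.0 * np.log10(max(1.0 - call.P, 1e-26)), 255.0))
            if union is not None and cand.key in union.votes:
                for cid in union.caller_ids:
                    rec.info[f"CALLED_{cid}"] = union.votes[cand.key][cid].called
            out.write(rec)


def read_classified_vcf(path: str | Path) -> list[ClassifiedCall]:
    calls = []
    with pysam.VariantFile(str(path)) as vf:
        for rec in vf:
            for alt in rec.alts or ():
                cand = variants.normalize_variant(rec.chrom, rec.pos, rec.ref, alt)
                tier = next(iter(rec.filter), "PASS")
                calls.append(ClassifiedCall(
                    candidate=cand,
                    P=float(rec.info.get("P", 0.0)),
                    tier=tier,
                ))
    return calls


def split_by_class(features: pd.DataFrame) -> dict[str, pd.DataFrame]:
    """Partition a feature matrix into SNV and INDEL row subsets by key."""
    classes = {
        key: VariantCandidate.from_key_string(key).var_class
        for key in features.index
    }
    out = {}
    for cls in ("SNV", "INDEL"):
        keys = [k for k, c in classes.items() if c == cls]
        if keys:
            out[cls] = features.loc[keys]
    return out


def evaluate_calls_by_class(
    calls: Sequence[ClassifiedCall],
    truth: evaluation.TruthSet,
    pass_threshold: float = boosting.PASS_THRESHOLD,
) -> pd.DataFrame:
    """Per-variant-class metrics TSV content for a classified call set."""
    rows = []
    for cls in ("SNV", "INDEL"):
        passing = {
            c.candidate.key for c in calls
            if c.candidate.var_class == cls and c.P >= pass_threshold
        }
        truth_cls = evaluation.TruthSet(
            somatic={k for k in truth.somatic
                     if VariantCandidate(*k).var_class == cls},
            reference={k for k in truth.reference
                       if VariantCandidate(*k).var_class == cls},
            ambiguous={k for k in truth.ambiguous
                       if VariantCandidate(*k).var_class == cls},
        )
        if len(truth_cls) == 0 and not passing:
            continue
        res = evaluation.evaluate(passing, truth_cls)
        rows.append({"var_class": cls, **res.as_dict()})
    return pd.DataFrame(rows)
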