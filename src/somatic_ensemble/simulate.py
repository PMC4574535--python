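"""In silico tumor-normal titration simulator.

Emulates, at the genotype/allele-count level, the construction of virtual
tumor-normal pairs by computationally mixing two genomes: sites where the
designated normal genome is homozygous reference and the designated tumor
genome is heterozygous are true somatic mutations; sites homozygous
reference in both are reference; every other genotype combination is
ambiguous and excluded from scoring. Cross-contamination is modelled through
mixture fractions: a subclone with pure VAF v sequenced in a sample whose
tumor fraction is f has expected VAF v*f, because contaminating reads carry
the reference allele at somatic sites.

Read counts are sampled per site: depth ~ Poisson(target depth) (or fixed),
alt reads ~ Binomial(depth, effective VAF plus base-error leakage), strands
split binomially. A configurable fraction of reference sites carry a
low-level sequencing artifact (strand-biased alt reads with degraded mapping
and base qualities) — these are what make callers emit false positives and
what the classifier learns to reject.

Virtual callers with distinct, qualitatively realistic error profiles vote
on each site; together with per-site evidence this yields a complete
feature matrix and truth set, so the whole pipeline is exercisable with no
external callers or sequencing data.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Optional, Sequence

import numpy as np
import pandas as pd

from .evaluation import TruthSet
from .features import SampleEvidence, assemble_features, feature_matrix
from .variants import CallerVote, VariantCandidate

__all__ = [
    "Genotype",
    "GenotypeSite",
    "MixtureConfig",
    "CallerProfile",
    "SimulatedDataset",
    "expected_vaf",
    "prior_mutation_rate",
    "build_truth",
    "enforce_prior_rate",
    "sample_evidence",
    "simulate_caller_votes",
    "generate_dataset",
    "default_caller_profiles",
    "clean_pair_config",
    "cross_contaminated_pair_config",
]

HOM_REF = "hom_ref"
HET = "het"
HOM_ALT = "hom_alt"
OTHER = "other"

#: het pure VAF in an unmixed genome
_HET_VAF = 0.5

_BASES = "ACGT"


@dataclass(frozen=True)
class GenotypeSite:
    """Genotypes of the two virtual genomes at one site."""

    chrom: str
    pos: int
    ref: str
    alt: str
    genotype_normal: str
    genotype_tumor: str

    def __post_init__(self) -> None:
        for g in (self.genotype_normal, self.genotype_tumor):
            if g not in (HOM_REF, HET, HOM_ALT, OTHER):
                raise ValueError(f"unknown genotype {g!r}")

    @property
    def key(self) -> tuple:
        return (self.chrom, self.pos, self.ref, self.alt)


@dataclass
class MixtureConfig:
    """Mixing fractions, depths and noise for one virtual tumor-normal pair.

    ``tumor_fraction_in_tumor_sample`` is 1 minus the normal contamination of
    the tumor; ``tumor_fraction_in_normal_sample`` is the tumor contamination
    of the normal. Subclone VAFs are the pure (unmixed) variant allele
    fractions present in the tumor genome. Depths default to 30x, typical of
    whole-genome benchmarks; the base error rate is a per-read chance of a
    miscalled alternate allele.
    """

    tumor_fraction_in_tumor_sample: float = 1.0
    tumor_fraction_in_normal_sample: float = 0.0
    subclone_vafs: tuple = (0.5, 0.33, 0.2)
    depth_tumor: int = 30
    depth_normal: int = 30
    base_error_rate: float = 0.001
    fixed_depth: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        for name in ("tumor_fraction_in_tumor_sample",
                     "tumor_fraction_in_normal_sample", "base_error_rate"):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{name}={v} outside [0, 1]")
        if self.base_error_rate >= 1.0:
            raise ValueError("base_error_rate must be < 1")
        if not all(0.0 < v <= 1.0 for v in self.subclone_vafs):
            raise ValueError("subclone VAFs must be in (0, 1]")
        if self.depth_tumor < 1 or self.depth_normal < 1:
            raise ValueError("depths must be positive")


def clean_pair_config(seed: int = 0) -> MixtureConfig:
    """Pure normal / pure tumor with three subclones (VAF 50/33/20%)."""
    return MixtureConfig(seed=seed)


def cross_contaminated_pair_config(seed: int = 0) -> MixtureConfig:
    """Cross-contaminated pair: tumor 30% normal cells, normal 5% tumor cells."""
    return MixtureConfig(
        tumor_fraction_in_tumor_sample=0.70,
        tumor_fraction_in_normal_sample=0.05,
        seed=seed,
    )


def expected_vaf(pure_vaf: float, tumor_fraction: float) -> float:
    """Expected VAF of a somatic allele after dilution by mixing.

    Contaminating reads carry the reference allele at somatic sites, so the
    expectation is simply the product of the pure VAF and the sample's tumor
    fraction — e.g. a het (50%) allele in a 70% tumor sample reads at 35%.
    """
    for name, v in (("pure_vaf", pure_vaf), ("tumor_fraction", tumor_fraction)):
        if not 0.0 <= v <= 1.0:
            raise ValueError(f"{name}={v} outside [0, 1]")
    return pure_vaf * tumor_fraction


def prior_mutation_rate(n_mutations: int, n_sites: int) -> float:
    """Somatic mutation rate implied by a truth set over interrogated sites."""
    if n_sites <= 0:
        raise ValueError("n_sites must be positive")
    return n_mutations / n_sites


def build_truth(
    sites: Sequence[GenotypeSite],
    callable_mask: Optional[set] = None,
) -> TruthSet:
    """Partition genotype sites into somatic / reference / ambiguous.

    (hom_ref normal, het tumor) -> somatic; (hom_ref, hom_ref) -> reference;
    every other genotype combination -> ambiguous. Sites outside the callable
    mask (when given) are dropped entirely.
    """
    somatic, reference, ambiguous = set(), set(), set()
    for site in sites:
        if callable_mask is not None and site.key not in callable_mask:
            continue
        pair = (site.genotype_normal, site.genotype_tumor)
        if pair == (HOM_REF, HET):
            somatic.add(site.key)
        elif pair == (HOM_REF, HOM_REF):
            reference.add(site.key)
        else:
            ambiguous.add(site.key)
    return TruthSet(somatic=somatic, reference=reference, ambiguous=ambiguous)


def enforce_prior_rate(
    truth: TruthSet,
    interrogated_sites: int,
    rate: float,
    seed: int = 0,
) -> TruthSet:
    """Downsample the somatic truth to a realistic prior mutation rate.

    Keeps round(rate * interrogated_sites) somatic entries chosen uniformly
    with the seeded RNG; the remainder are masked into the ambiguous class
    (excluded from scoring, not relabelled as reference).
    """
    target = round(rate * interrogated_sites)
    if target < 1:
        raise ValueError(
            f"rate {rate} over {interrogated_sites} sites keeps < 1 mutation"
        )
    somatic = sorted(truth.somatic)
    if target >= len(somatic):
        if target > len(somatic):
            warnings.warn(
                f"target of {target} exceeds {len(somatic)} available somatic "
                f"sites; keeping all"
            )
        return TruthSet(set(somatic), set(truth.reference), set(truth.ambiguous))
    rng = np.random.default_rng(seed)
    keep_idx = rng.choice(len(somatic), size=target, replace=False)
    keep = {somatic[i] for i in keep_idx}
    masked = set(somatic) - keep
    return TruthSet(keep, set(truth.reference), set(truth.ambiguous) | masked)


# ---------------------------------------------------------------------------
# evidence sampling

# quality profiles: (mapq mean/sd, baseq mean/sd, tail mean/sd, strand_p)
_CLEAN_PROFILE = (58.0, 3.0, 34.0, 3.0, 0.45, 0.08, 0.5)
_ARTIFACT_PROFILE = (40.0, 8.0, 26.0, 5.0, 0.12, 0.06, 0.85)


def sample_evidence(
    truth_class: str,
    config: MixtureConfig,
    sample_role: str,
    rng: np.random.Generator,
    subclone_vaf: float = _HET_VAF,
    artifact_vaf: float = 0.0,
) -> SampleEvidence:
    """Draw a pileup summary for one site in one sample.

    ``truth_class`` is "somatic" or "reference". Somatic sites read at
    expected_vaf(subclone_vaf, sample tumor fraction); reference sites read
    at the artifact VAF (scaled down in the normal) plus base-error leakage.
    Artifact sites get strand-biased alt reads and degraded quality draws.
    """
    if sample_role not in ("tumor", "normal"):
        raise ValueError("sample_role must be 'tumor' or 'normal'")
    target_depth = (config.depth_tumor if sample_role == "tumor"
                    else config.depth_normal)
    depth = target_depth if config.fixed_depth else int(rng.poisson(target_depth))
    if depth == 0:
        return SampleEvidence.empty()

    if truth_class == "somatic":
        fraction = (config.tumor_fraction_in_tumor_sample
                    if sample_role == "tumor"
                    else config.tumor_fraction_in_normal_sample)
        vaf = expected_vaf(subclone_vaf, fraction)
        artifact = False
    elif truth_class == "reference":
        # sequencing artifacts show mostly in the tumor library
        vaf = artifact_vaf if sample_role == "tumor" else 0.25 * artifact_vaf
        artifact = artifact_vaf > 0.0
    else:
        raise ValueError(f"unknown truth class {truth_class!r}")

    p_alt = min(vaf + (1.0 - vaf) * config.base_error_rate, 1.0)
    alt = int(rng.binomial(depth, p_alt))
    rest = depth - alt
    other = int(rng.binomial(rest, config.base_error_rate)) if rest else 0
    ref = rest - other

    mq_m, mq_s, bq_m, bq_s, tail_m, tail_s, strand_p = (
        _ARTIFACT_PROFILE if artifact else _CLEAN_PROFILE
    )
    alt_fwd = int(rng.binomial(alt, strand_p)) if alt else 0
    ref_fwd = int(rng.binomial(ref, 0.5)) if ref else 0
    mapq = np.clip(rng.normal(mq_m, mq_s, size=depth), 0.0, 60.0)
    baseq = np.clip(rng.normal(bq_m, bq_s, size=depth), 2.0, 41.0)
    mismatches = int(rng.binomial(depth, 0.01))
    if artifact:
        mismatches += int(rng.binomial(depth, 0.05))
    tail = (float(np.clip(rng.normal(tail_m, tail_s), 0.01, 0.99))
            if alt > 0 else None)
    return SampleEvidence(
        depth=depth,
        ref_fwd=ref_fwd, ref_rev=ref - ref_fwd,
        alt_fwd=alt_fwd, alt_rev=alt - alt_fwd,
        mapq_values=mapq.tolist(), baseq_values=baseq.tolist(),
        mismatches=mismatches, tail_distance_mean=tail,
    )


# ---------------------------------------------------------------------------
# virtual callers


@dataclass
class CallerProfile:
    """Error profile of one virtual somatic caller.

    Detection requires the evidence gates (minimum alt reads, VAF and depth
    in the tumor) to pass; a gated somatic site is then called with
    probability ``sensitivity``, except that callers with a finite
    ``normal_alt_tolerance`` collapse to ``contaminated_floor`` sensitivity
    when the matched normal shows more alt reads than tolerated (the
    contamination-intolerant behaviour of strict Bayesian callers).
    Reference sites are false-called at ``fp_rate_artifact`` when they carry
    a gated artifact signal, else at ``fp_rate_clean``; ``germline_leak``
    adds calls at ambiguous/germline-like sites when such sites are present.
    ``score_kind`` selects the native score emitted with a positive call:
    "phred" (a noisy Phred-scaled genotype-change statistic), "fet_p" (a
    noisy Fisher p-value), or "none" (binary caller).
    """

    caller_id: str
    sensitivity: float = 0.95
    min_alt_reads: int = 2
    min_vaf: float = 0.0
    min_depth: int = 0
    normal_alt_tolerance: Optional[int] = None
    contaminated_floor: float = 0.05
    fp_rate_artifact: float = 0.1
    fp_rate_clean: float = 0.002
    germline_leak: float = 0.0
    score_kind: str = "none"

    def call_probability(
        self,
        tumor: SampleEvidence,
        normal: SampleEvidence,
        truth_class: str,
        artifact: bool,
    ) -> float:
        gated = (
            tumor.alt_count >= self.min_alt_reads
            and tumor.vaf >= self.min_vaf
            and tumor.depth >= self.min_depth
        )
        if truth_class == "somatic":
            if not gated:
                return 0.0
            if (self.normal_alt_tolerance is not None
                    and normal.alt_count > self.normal_alt_tolerance):
                return self.contaminated_floor
            return self.sensitivity
        if truth_class == "reference":
            if artifact and gated:
                return self.fp_rate_artifact
            return self.fp_rate_clean if tumor.alt_count >= 1 else 0.0
        # germline-like / ambiguous site
        return self.germline_leak if gated else 0.0


def default_caller_profiles() -> list[CallerProfile]:
    """Five virtual callers echoing the qualitative behaviour of the field's
    common tools: a sensitive low-VAF Bayesian caller intolerant of normal
    contamination; a genotype-change caller tolerant of impure normals but
    germline-leaky; a Fisher-test caller with a built-in minimum-VAF/depth
    filter; a joint-genotype caller with very high sensitivity but heavy
    over-calling; and a permissive Fisher-test caller tuned for hard variants.
    """
    return [
        CallerProfile(
            "mutect_like", sensitivity=0.97, min_alt_reads=3,
            normal_alt_tolerance=1, contaminated_floor=0.05,
            fp_rate_artifact=0.04, fp_rate_clean=0.001, score_kind="none",
        ),
        CallerProfile(
            "sniper_like", sensitivity=0.90, min_alt_reads=4,
            normal_alt_tolerance=None, fp_rate_artifact=0.10,
            fp_rate_clean=0.004, germline_leak=0.3, score_kind="phred",
        ),
        CallerProfile(
            "varscan_like", sensitivity=0.95, min_alt_reads=2, min_vaf=0.10,
            min_depth=8, normal_alt_tolerance=None, fp_rate_artifact=0.12,
            fp_rate_clean=0.003, germline_leak=0.25, score_kind="phred",
        ),
        CallerProfile(
            "jointsnvmix_like", sensitivity=0.98, min_alt_reads=2,
            normal_alt_tolerance=None, fp_rate_artifact=0.25,
            fp_rate_clean=0.01, germline_leak=0.15, score_kind="none",
        ),
        CallerProfile(
            "vardict_like", sensitivity=0.90, min_alt_reads=2,
            normal_alt_tolerance=None, fp_rate_artifact=0.12,
            fp_rate_clean=0.004, score_kind="fet_p",
        ),
    ]


def _native_score(
    profile: CallerProfile,
    tumor: SampleEvidence,
    normal: SampleEvidence,
    rng: np.random.Generator,
) -> Optional[float]:
    from .features import genotype_change_phred

    if profile.score_kind == "none":
        return None
    phred = genotype_change_phred(normal, tumor)
    if profile.score_kind == "phred":
        return float(max(phred + rng.normal(0.0, 3.0), 0.0))
    if profile.score_kind == "fet_p":
        noisy = min(max(phred + rng.normal(0.0, 3.0), 0.0), 255.0)
        return float(10.0 ** (-noisy / 10.0))
    raise ValueError(f"unknown score kind {profile.score_kind!r}")


def simulate_caller_votes(
    tumor: SampleEvidence,
    normal: SampleEvidence,
    truth_class: str,
    caller_profiles: Sequence[CallerProfile],
    rng: np.random.Generator,
    artifact: bool = False,
) -> list[CallerVote]:
    """Draw one vote per virtual caller for a site's evidence."""
    if not caller_profiles:
        raise ValueError("at least one caller profile required")
    votes = []
    for profile in caller_profiles:
        p = profile.call_probability(tumor, normal, truth_class, artifact)
        called = int(rng.random() < p)
        score = _native_score(profile, tumor, normal, rng) if called else None
        votes.append(CallerVote(profile.caller_id, called, score))
    return votes


# ---------------------------------------------------------------------------
# end-to-end dataset generation


@dataclass
class SimulatedDataset:
    """Everything downstream modules consume, from one simulated experiment."""

    candidates: list
    truth: TruthSet
    evidence: dict                      # key -> {"tumor": ev, "normal": ev}
    votes: dict                         # key -> list[CallerVote]
    features: pd.DataFrame              # indexed by candidate key string
    labels: pd.Series                   # 1 somatic / 0 reference
    config: MixtureConfig
    caller_ids: list
    reference_specs: list = field(default_factory=list)

    def union_callset(self):
        from .variants import merge_union

        callsets = {cid: [] for cid in self.caller_ids}
        for cand in self.candidates:
            for vote in self.votes[cand.key]:
                if vote.called:
                    callsets[vote.caller_id].append((cand, vote))
        return merge_union(callsets)

    def caller_calls(self, caller_id: str) -> set:
        return {
            key for key, votes in self.votes.items()
            if any(v.caller_id == caller_id and v.called for v in votes)
        }

    # -- file emission (same formats the real pipeline consumes) ----------

    def write_truth_vcf(self, path: str | Path) -> None:
        _write_sites_vcf(
            path,
            [VariantCandidate.from_key_string(k) if isinstance(k, str)
             else VariantCandidate(*k) for k in sorted(self.truth.somatic)],
        )

    def write_caller_vcfs(self, out_dir: str | Path) -> dict[str, Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        paths = {}
        for cid in self.caller_ids:
            cands = []
            for cand in self.candidates:
                vote = next(v for v in self.votes[cand.key]
                            if v.caller_id == cid)
                if vote.called:
                    cands.append((cand, vote.score))
            path = out_dir / f"{cid}.vcf"
            _write_sites_vcf(path, [c for c, _ in cands],
                             scores=[s for _, s in cands])
            paths[cid] = path
        return paths

    def write_pileup_tsv(self, path: str | Path) -> None:
        from .features import write_pileup_tsv

        write_pileup_tsv(self.evidence, path)

    def write_feature_tsv(self, path: str | Path) -> None:
        from .features import write_feature_tsv

        write_feature_tsv(self.features, path)


def _write_sites_vcf(path, candidates, scores=None) -> None:
    import pysam

    header = pysam.VariantHeader()
    for contig in dict.fromkeys(c.chrom for c in candidates):
        header.contigs.add(contig)
    if not list(header.contigs):
        header.contigs.add("chr1")
    header.add_line(
        '##INFO=<ID=SCORE,Number=1,Type=Float,Description="Caller-native score">'
    )
    order = sorted(
        range(len(candidates)),
        key=lambda i: (candidates[i].chrom, candidates[i].pos,
                       candidates[i].ref, candidates[i].alt),
    )
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for i in order:
            cand = candidates[i]
            rec = out.new_record(
                contig=cand.chrom, start=cand.pos - 1,
                alleles=(cand.ref, cand.alt),
            )
            if scores is not None and scores[i] is not None:
                rec.info["SCORE"] = float(scores[i])
            out.write(rec)


@dataclass(frozen=True)
class _ReferenceSiteSpec:
    """Frozen definition of a reference candidate site, reusable across
    mixture configs of one experiment so the same artifact sites produce
    the false positives in every setting."""

    candidate: VariantCandidate
    artifact_vaf: float


def _random_candidate(pos: int, rng: np.random.Generator) -> VariantCandidate:
    ref = _BASES[rng.integers(4)]
    alt = rng.choice([b for b in _BASES if b != ref])
    return VariantCandidate("chr1", pos, ref, str(alt))


def generate_dataset(
    config: Optional[MixtureConfig] = None,
    n_somatic: int = 2000,
    n_reference: int = 20000,
    caller_profiles: Optional[Sequence[CallerProfile]] = None,
    seed: Optional[int] = None,
    artifact_fraction: float = 0.3,
    include_dbsnp: bool = False,
    reference_specs: Optional[Sequence[_ReferenceSiteSpec]] = None,
) -> SimulatedDataset:
    """Generate a complete candidate-level tumor-normal dataset.

    Sites -> truth -> evidence -> votes -> features. Somatic sites are
    assigned a subclone VAF uniformly from the config; ``artifact_fraction``
    of reference sites carry an artifact signal (Beta(1.5, 15) VAF, mean
    ~9%). dbSNP membership is excluded by default, matching in silico runs
    where database membership carries no signal. Deterministic given seed.
    """
    if config is None:
        config = MixtureConfig()
    if caller_profiles is None:
        caller_profiles = default_caller_profiles()
    if n_somatic < 0 or n_reference < 0 or n_somatic + n_reference == 0:
        raise ValueError("need a positive number of sites")
    rng = np.random.default_rng(config.seed if seed is None else seed)
    caller_ids = [p.caller_id for p in caller_profiles]

    sites: list[GenotypeSite] = []
    pos = 1000
    somatic_meta: list[tuple[VariantCandidate, float]] = []
    for _ in range(n_somatic):
        cand = _random_candidate(pos, rng)
        pos += int(rng.integers(50, 200))
        vaf = float(rng.choice(config.subclone_vafs))
        somatic_meta.append((cand, vaf))
        sites.append(GenotypeSite(cand.chrom, cand.pos, cand.ref, cand.alt,
                                  HOM_REF, HET))

    if reference_specs is None:
        reference_specs = []
        for _ in range(n_reference):
            cand = _random_candidate(pos, rng)
            pos += int(rng.integers(50, 200))
            is_artifact = rng.random() < artifact_fraction
            avaf = float(rng.beta(1.5, 15.0)) if is_artifact else 0.0
            reference_specs.append(_ReferenceSiteSpec(cand, avaf))
    else:
        reference_specs = list(reference_specs)
    for spec in reference_specs:
        c = spec.candidate
        sites.append(GenotypeSite(c.chrom, c.pos, c.ref, c.alt,
                                  HOM_REF, HOM_REF))

    truth = build_truth(sites)

    candidates: list[VariantCandidate] = []
    evidence: dict = {}
    votes: dict = {}
    rows: dict = {}
    labels: dict = {}

    def add_site(cand, truth_class, subclone_vaf, artifact_vaf):
        tumor = sample_evidence(truth_class, config, "tumor", rng,
                                subclone_vaf, artifact_vaf)
        normal = sample_evidence(truth_class, config, "normal", rng,
                                 subclone_vaf, artifact_vaf)
        site_votes = simulate_caller_votes(
            tumor, normal, truth_class, caller_profiles, rng,
            artifact=artifact_vaf > 0.0,
        )
        dbsnp = 0
        if include_dbsnp:
            base = {"somatic": 0.01, "reference": 0.02}[truth_class]
            if artifact_vaf > 0.0:
                base = 0.3
            dbsnp = int(rng.random() < base)
        candidates.append(cand)
        evidence[cand.key] = {"tumor": tumor, "normal": normal}
        votes[cand.key] = site_votes
        rows[cand.key_string()] = assemble_features(
            cand, site_votes, tumor, normal,
            dbsnp_member=dbsnp, include_dbsnp=include_dbsnp,
        )
        labels[cand.key_string()] = 1 if truth_class == "somatic" else 0

    for cand, vaf in somatic_meta:
        add_site(cand, "somatic", vaf, 0.0)
    for spec in reference_specs:
        add_site(spec.candidate, "reference", _HET_VAF, spec.artifact_vaf)

    features = feature_matrix(rows)
    return SimulatedDataset(
        candidates=candidates,
        truth=truth,
        evidence=evidence,
        votes=votes,
        features=features,
        labels=pd.Series(labels, name="label"),
        config=config,
        caller_ids=list(caller_ids),
        reference_specs=list(reference_specs),
    )
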