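"""Per-candidate feature extraction from tumor/normal pileup evidence.

Each merged candidate is summarized as a flat numeric feature vector built
from three sources: the per-caller votes and native scores, pileup-level
sequencing evidence in both samples (depth, stranded allele counts, mapping
and base qualities, mismatch load, tail distance), and optional prior
knowledge (dbSNP membership). Statistics that the constituent callers
compute internally — the strand-bias odds ratio and Fisher tests on allele
count tables, and the Phred-scaled genotype-change p-value — are recomputed
here directly from the evidence so the feature set is self-contained.

Missing values are encoded with sentinels rather than NaN: -1 for scores and
qualities, 0 for counts. Boosted decision trees treat a sentinel as an
ordinary split value, so no imputation step is needed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy.special import gammaln

from .variants import CallerVote, VariantCandidate

__all__ = [
    "MISSING",
    "SampleEvidence",
    "rms_quality",
    "fisher_exact_2x2",
    "strand_bias_features",
    "genotype_change_phred",
    "assemble_features",
    "feature_matrix",
    "feature_names",
    "write_feature_tsv",
    "read_feature_tsv",
    "write_pileup_tsv",
    "read_pileup_tsv",
    "read_dbsnp_sites",
    "evidence_from_alignment",
]

#: sentinel for undefined score/quality features
MISSING = -1.0

#: Phred cap for -10*log10(p) features
PHRED_CAP = 255.0


@dataclass
class SampleEvidence:
    """Pileup summary for one sample at one candidate site.

    Stranded ref/alt counts need not exhaust the depth: reads carrying other
    alleles or ambiguous bases account for the remainder.
    """

    depth: int
    ref_fwd: int = 0
    ref_rev: int = 0
    alt_fwd: int = 0
    alt_rev: int = 0
    mapq_values: list = field(default_factory=list)
    baseq_values: list = field(default_factory=list)
    mismatches: int = 0
    tail_distance_mean: Optional[float] = None

    def __post_init__(self) -> None:
        counts = (self.depth, self.ref_fwd, self.ref_rev, self.alt_fwd,
                  self.alt_rev, self.mismatches)
        if any(c < 0 for c in counts):
            raise ValueError("evidence counts must be non-negative")
        if self.ref_count + self.alt_count > self.depth:
            raise ValueError("ref + alt read counts exceed depth")

    @property
    def ref_count(self) -> int:
        return self.ref_fwd + self.ref_rev

    @property
    def alt_count(self) -> int:
        return self.alt_fwd + self.alt_rev

    @property
    def vaf(self) -> float:
        """Variant allele frequency; 0 at zero depth."""
        return self.alt_count / self.depth if self.depth > 0 else 0.0

    @staticmethod
    def empty() -> "SampleEvidence":
        return SampleEvidence(depth=0)


def rms_quality(values: Sequence[float]) -> float:
    """Root-mean-square of quality scores; MISSING sentinel for an empty list."""
    if len(values) == 0:
        return MISSING
    arr = np.asarray(values, dtype=float)
    return float(np.sqrt(np.mean(arr * arr)))


def fisher_exact_2x2(table) -> float:
    """Two-sided Fisher's exact test p-value for a 2x2 count table.

    Computed by hypergeometric enumeration with fixed margins: the p-value is
    the total probability of tables whose point probability does not exceed
    that of the observed table (with a small relative tolerance to absorb
    floating-point noise in the comparison).
    """
    (a, b), (c, d) = table
    cells = (a, b, c, d)
    if any(int(x) != x or x < 0 for x in cells):
        raise ValueError(f"2x2 table cells must be non-negative integers: {cells}")
    a, b, c, d = (int(x) for x in cells)
    n = a + b + c + d
    if n == 0:
        return 1.0
    r1, r2 = a + b, c + d
    c1 = a + c
    lo = max(0, c1 - r2)
    hi = min(r1, c1)
    k = np.arange(lo, hi + 1)

    def log_comb(nn, kk):
        return gammaln(nn + 1) - gammaln(kk + 1) - gammaln(nn - kk + 1)

    log_pmf = log_comb(r1, k) + log_comb(r2, c1 - k) - log_comb(n, c1)
    pmf = np.exp(log_pmf)
    p_obs = pmf[a - lo]
    p = float(pmf[pmf <= p_obs * (1.0 + 1e-9)].sum())
    return min(p, 1.0)


def strand_bias_features(tumor: SampleEvidence) -> tuple[float, float]:
    """Strand-bias odds ratio and Fisher p from tumor stranded allele counts.

    The 2x2 table is [[ref_fwd, ref_rev], [alt_fwd, alt_rev]]. When any cell
    is zero the odds ratio uses the Haldane-Anscombe +0.5 correction in every
    cell; a fully empty table is defined as unbiased (1.0, 1.0).
    """
    rf, rr = tumor.ref_fwd, tumor.ref_rev
    af, ar = tumor.alt_fwd, tumor.alt_rev
    if rf == rr == af == ar == 0:
        return 1.0, 1.0
    fet_p = fisher_exact_2x2([[rf, rr], [af, ar]])
    if 0 in (rf, rr, af, ar):
        rf, rr, af, ar = (x + 0.5 for x in (rf, rr, af, ar))
    odds_ratio = (rf * ar) / (rr * af)
    return float(odds_ratio), fet_p


def genotype_change_phred(
    normal: SampleEvidence, tumor: SampleEvidence, cap: float = PHRED_CAP
) -> float:
    """Phred-scaled Fisher p-value for a normal-vs-tumor allele shift.

    The table is strand-summed [[normal_ref, normal_alt], [tumor_ref,
    tumor_alt]]; identical allele proportions give p = 1 hence score 0. The
    score is capped (default 255) to keep the feature finite.
    """
    p = fisher_exact_2x2(
        [[normal.ref_count, normal.alt_count], [tumor.ref_count, tumor.alt_count]]
    )
    if p >= 1.0 - 1e-12:  # enumeration round-off at proportional tables
        return 0.0
    return float(min(-10.0 * math.log10(p), cap))


_EVIDENCE_FEATURES = [
    "tumor_depth", "normal_depth",
    "tumor_ref_fwd", "tumor_ref_rev", "tumor_alt_fwd", "tumor_alt_rev",
    "normal_ref_fwd", "normal_ref_rev", "normal_alt_fwd", "normal_alt_rev",
    "tumor_vaf", "normal_vaf",
    "tumor_mapq_rms", "normal_mapq_rms",
    "tumor_baseq_rms", "normal_baseq_rms",
    "tumor_mismatches", "normal_mismatches",
    "tumor_tail_distance_mean",
    "strand_bias_or", "strand_bias_fet_p",
    "genotype_change_phred",
]


def feature_names(caller_ids: Sequence[str], include_dbsnp: bool = True) -> list[str]:
    """Ordered feature registry for a caller configuration."""
    names = [f"called_{cid}" for cid in caller_ids]
    names += [f"score_{cid}" for cid in caller_ids]
    names += list(_EVIDENCE_FEATURES)
    if include_dbsnp:
        names.append("dbsnp")
    return names


def assemble_features(
    candidate: VariantCandidate,
    votes: Iterable[CallerVote],
    tumor: SampleEvidence,
    normal: SampleEvidence,
    dbsnp_member: int = 0,
    include_dbsnp: bool = True,
) -> dict[str, float]:
    """Build the full named feature vector for one candidate.

    Total by construction: every registered feature name is present, with
    sentinel values where the underlying evidence is undefined.
    """
    fv: dict[str, float] = {}
    caller_ids = []
    for vote in votes:
        caller_ids.append(vote.caller_id)
        fv[f"called_{vote.caller_id}"] = float(vote.called)
        fv[f"score_{vote.caller_id}"] = (
            MISSING if vote.score is None else float(vote.score)
        )
    sb_or, sb_p = strand_bias_features(tumor)
    fv.update({
        "tumor_depth": float(tumor.depth),
        "normal_depth": float(normal.depth),
        "tumor_ref_fwd": float(tumor.ref_fwd),
        "tumor_ref_rev": float(tumor.ref_rev),
        "tumor_alt_fwd": float(tumor.alt_fwd),
        "tumor_alt_rev": float(tumor.alt_rev),
        "normal_ref_fwd": float(normal.ref_fwd),
        "normal_ref_rev": float(normal.ref_rev),
        "normal_alt_fwd": float(normal.alt_fwd),
        "normal_alt_rev": float(normal.alt_rev),
        "tumor_vaf": tumor.vaf,
        "normal_vaf": normal.vaf,
        "tumor_mapq_rms": rms_quality(tumor.mapq_values),
        "normal_mapq_rms": rms_quality(normal.mapq_values),
        "tumor_baseq_rms": rms_quality(tumor.baseq_values),
        "normal_baseq_rms": rms_quality(normal.baseq_values),
        "tumor_mismatches": float(tumor.mismatches),
        "normal_mismatches": float(normal.mismatches),
        "tumor_tail_distance_mean": (
            MISSING if tumor.tail_distance_mean is None
            else float(tumor.tail_distance_mean)
        ),
        "strand_bias_or": sb_or,
        "strand_bias_fet_p": sb_p,
        "genotype_change_phred": genotype_change_phred(normal, tumor),
    })
    if include_dbsnp:
        fv["dbsnp"] = float(dbsnp_member)
    expected = feature_names(caller_ids, include_dbsnp)
    missing = set(expected) - set(fv)
    if missing:  # pragma: no cover - registry and assembly move together
        raise RuntimeError(f"feature assembly incomplete: {sorted(missing)}")
    return fv


def feature_matrix(rows: Mapping[str, Mapping[str, float]]) -> pd.DataFrame:
    """Stack per-candidate feature dicts (keyed by candidate key string)."""
    df = pd.DataFrame.from_dict(rows, orient="index")
    df.index.name = "candidate"
    return df


def write_feature_tsv(features: pd.DataFrame, path: str | Path) -> None:
    features.to_csv(path, sep="\t", index=True)


def read_feature_tsv(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", index_col="candidate")


# ---------------------------------------------------------------------------
# pileup-summary interchange format


def _fmt_quals(values) -> str:
    return ",".join(f"{v:g}" for v in values)


def write_pileup_tsv(
    evidence: Mapping[tuple, Mapping[str, SampleEvidence]], path: str | Path
) -> None:
    """One row per candidate per sample role (tumor/normal)."""
    cols = [
        "chrom", "pos", "ref", "alt", "sample_role", "depth",
        "ref_fwd", "ref_rev", "alt_fwd", "alt_rev",
        "mapq", "baseq", "mismatches", "tail_distance_mean",
    ]
    rows = []
    for key, roles in evidence.items():
        chrom, pos, ref, alt = key
        for role, ev in roles.items():
            rows.append({
                "chrom": chrom, "pos": pos, "ref": ref, "alt": alt,
                "sample_role": role, "depth": ev.depth,
                "ref_fwd": ev.ref_fwd, "ref_rev": ev.ref_rev,
                "alt_fwd": ev.alt_fwd, "alt_rev": ev.alt_rev,
                "mapq": _fmt_quals(ev.mapq_values),
                "baseq": _fmt_quals(ev.baseq_values),
                "mismatches": ev.mismatches,
                "tail_distance_mean": (
                    "" if ev.tail_distance_mean is None
                    else f"{ev.tail_distance_mean:g}"
                ),
            })
    pd.DataFrame(rows, columns=cols).to_csv(path, sep="\t", index=False)


def _parse_quals(cell) -> list[float]:
    if cell is None or (isinstance(cell, float) and math.isnan(cell)) or cell == "":
        return []
    return [float(x) for x in str(cell).split(",") if x != ""]


def read_pileup_tsv(path: str | Path) -> dict[tuple, dict[str, SampleEvidence]]:
    df = pd.read_csv(path, sep="\t", dtype={"chrom": str})
    out: dict[tuple, dict[str, SampleEvidence]] = {}
    for row in df.itertuples(index=False):
        key = (row.chrom, int(row.pos), row.ref, row.alt)
        tail = getattr(row, "tail_distance_mean", None)
        if tail is not None and (tail == "" or (isinstance(tail, float) and math.isnan(tail))):
            tail = None
        ev = SampleEvidence(
            depth=int(row.depth),
            ref_fwd=int(row.ref_fwd), ref_rev=int(row.ref_rev),
            alt_fwd=int(row.alt_fwd), alt_rev=int(row.alt_rev),
            mapq_values=_parse_quals(row.mapq),
            baseq_values=_parse_quals(row.baseq),
            mismatches=int(row.mismatches),
            tail_distance_mean=None if tail is None else float(tail),
        )
        out.setdefault(key, {})[row.sample_role] = ev
    return out


def read_dbsnp_sites(path: str | Path) -> set:
    """Known-polymorphism sites from a VCF (allele-keyed) or BED (position-keyed).

    Membership lookups should use (chrom, pos, ref, alt) keys for VCF input
    and (chrom, pos) keys for BED input.
    """
    path = Path(path)
    sites: set = set()
    if path.suffix.lower() == ".bed":
        with open(path) as fh:
            for line in fh:
                if not line.strip() or line.startswith(("#", "track", "browser")):
                    continue
                fields = line.split("\t")
                chrom, start, end = fields[0], int(fields[1]), int(fields[2])
                for pos in range(start + 1, end + 1):  # BED is 0-based half-open
                    sites.add((chrom, pos))
        return sites
    import pysam

    with pysam.VariantFile(str(path)) as vf:
        for record in vf:
            for alt in record.alts or ():
                sites.add((record.chrom, record.pos, record.ref, alt))
    return sites


def dbsnp_member(candidate: VariantCandidate, sites: set) -> int:
    key = candidate.key
    return int(key in sites or (candidate.chrom, candidate.pos) in sites)


# ---------------------------------------------------------------------------
# optional BAM/SAM-backed evidence extraction


def evidence_from_alignment(
    path: str | Path,
    candidates: Sequence[VariantCandidate],
    min_mapq: int = 20,
    min_baseq: int = 10,
) -> dict[tuple, SampleEvidence]:
    """Pileup-derived evidence for candidate sites from an indexed BAM.

    SNVs are counted per strand at the site; for indels, reads whose pileup
    entry shows an insertion/deletion at the anchor are counted as alt. The
    mismatch count sums NM tags over reads covering the site.
    """
    import pysam

    out: dict[tuple, SampleEvidence] = {}
    with pysam.AlignmentFile(str(path)) as bam:
        for cand in candidates:
            out[cand.key] = SampleEvidence.empty()
            for column in bam.pileup(
                cand.chrom, cand.pos - 1, cand.pos,
                truncate=True, min_base_quality=0,
            ):
                # the column must be consumed inside the pileup iteration
                out[cand.key] = _column_evidence(
                    column, cand, min_mapq, min_baseq
                )
    return out


def _column_evidence(column, cand, min_mapq, min_baseq) -> SampleEvidence:
    depth = 0
    rf = rr = af = ar = 0
    mapqs: list[float] = []
    baseqs: list[float] = []
    mismatches = 0
    tails: list[float] = []
    is_snv = cand.var_class == "SNV"
    ins_len = len(cand.alt) - len(cand.ref)
    for read in column.pileups:
        aln = read.alignment
        if aln.mapping_quality < min_mapq or aln.is_unmapped:
            continue
        depth += 1
        mapqs.append(float(aln.mapping_quality))
        if aln.has_tag("NM"):
            mismatches += int(aln.get_tag("NM"))
        qpos = read.query_position
        rev = aln.is_reverse
        if is_snv:
            if qpos is None:
                continue
            baseq = aln.query_qualities[qpos]
            if baseq < min_baseq:
                continue
            baseqs.append(float(baseq))
            base = aln.query_sequence[qpos].upper()
            if base == cand.alt:
                af, ar = (af, ar + 1) if rev else (af + 1, ar)
                rlen = aln.query_length
                tails.append(min(qpos, rlen - 1 - qpos) / max(rlen - 1, 1))
            elif base == cand.ref[0]:
                rf, rr = (rf, rr + 1) if rev else (rf + 1, rr)
        else:
            indel = read.indel  # >0 insertion, <0 deletion after this pos
            if indel == ins_len and indel != 0:
                af, ar = (af, ar + 1) if rev else (af + 1, ar)
            elif indel == 0 and not read.is_del:
                rf, rr = (rf, rr + 1) if rev else (rf + 1, rr)
            if qpos is not None:
                baseqs.append(float(aln.query_qualities[qpos]))
    return SampleEvidence(
        depth=depth, ref_fwd=rf, ref_rev=rr, alt_fwd=af, alt_rev=ar,
        mapq_values=mapqs, baseq_values=baseqs, mismatches=mismatches,
        tail_distance_mean=float(np.mean(tails)) if tails else None,
    )
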