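"""Union merging of per-caller somatic call sets.

A tumor-normal somatic calling pipeline typically runs several callers, each
with its own statistical model and blind spots. The first stage of the
ensemble approach is to merge the per-caller VCFs into a single candidate
table: the set union of all calls keyed by (chrom, pos, ref, alt), with one
binary vote per configured caller per candidate, plus the caller-native score
when one is reported. The union maximizes sensitivity; downstream
classification restores precision.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence

import pysam

__all__ = [
    "VariantCandidate",
    "CallerVote",
    "UnionCallSet",
    "VcfParseError",
    "normalize_variant",
    "read_caller_vcf",
    "vcf_contig_order",
    "merge_union",
    "consensus_baseline",
    "write_union_vcf",
    "read_union_vcf",
    "write_union_tsv",
]

_VALID_BASES = frozenset("ACGT")

SNV = "SNV"
INDEL = "INDEL"


class VcfParseError(ValueError):
    """Raised when a caller VCF record cannot be parsed."""


@dataclass(frozen=True, order=True)
class VariantCandidate:
    """A normalized tumor-normal mutation candidate.

    Coordinates are 1-based VCF-style; indels are anchored (ref and alt share
    their first base) and trimmed of shared flanking bases so equivalent
    representations from different callers collapse to one key.
    """

    chrom: str
    pos: int
    ref: str
    alt: str

    def __post_init__(self) -> None:
        if not self.ref or not self.alt:
            raise ValueError("ref and alt must be non-empty")
        for allele in (self.ref, self.alt):
            if not set(allele) <= _VALID_BASES:
                raise ValueError(f"allele {allele!r} contains non-ACGT characters")
        if self.ref == self.alt:
            raise ValueError(f"ref and alt are identical at {self.chrom}:{self.pos}")
        if self.pos < 1:
            raise ValueError("pos is 1-based and must be >= 1")

    @property
    def var_class(self) -> str:
        """SNV iff both alleles are single bases, otherwise INDEL."""
        return SNV if len(self.ref) == 1 and len(self.alt) == 1 else INDEL

    @property
    def key(self) -> tuple[str, int, str, str]:
        return (self.chrom, self.pos, self.ref, self.alt)

    def key_string(self) -> str:
        return f"{self.chrom}:{self.pos}:{self.ref}:{self.alt}"

    @staticmethod
    def from_key_string(key: str) -> "VariantCandidate":
        chrom, pos, ref, alt = key.rsplit(":", 3)
        return VariantCandidate(chrom, int(pos), ref, alt)


@dataclass(frozen=True)
class CallerVote:
    """One caller's verdict on a candidate: a binary call plus optional score.

    The score is the caller's native statistic (e.g. a Phred-scaled genotype
    change p-value, or a somatic Fisher test p-value); its meaning is
    caller-specific and it is consumed downstream as an opaque feature.
    """

    caller_id: str
    called: int
    score: Optional[float] = None

    def __post_init__(self) -> None:
        if self.called not in (0, 1):
            raise ValueError("called must be 0 or 1")


def normalize_variant(chrom: str, pos: int, ref: str, alt: str) -> VariantCandidate:
    """Trim shared flanking bases, keeping VCF-style anchored representation.

    Trailing shared bases are removed first, then leading shared bases
    (advancing pos), always leaving at least one base in each allele.
    """
    ref, alt = ref.upper(), alt.upper()
    while len(ref) > 1 and len(alt) > 1 and ref[-1] == alt[-1]:
        ref, alt = ref[:-1], alt[:-1]
    while len(ref) > 1 and len(alt) > 1 and ref[0] == alt[0]:
        ref, alt = ref[1:], alt[1:]
        pos += 1
    return VariantCandidate(chrom, pos, ref, alt)


def vcf_contig_order(path: str | Path) -> list[str]:
    """Contig names in header order of a VCF file."""
    with pysam.VariantFile(str(path)) as vf:
        return list(vf.header.contigs)


def _record_score(record, score_key: Optional[str], alt_index: int):
    if score_key is None:
        return None
    if score_key.upper() == "QUAL":
        return None if record.qual is None else float(record.qual)
    try:
        value = record.info.get(score_key)
    except (KeyError, ValueError):  # key not declared in the header
        return None
    if value is None:
        return None
    if isinstance(value, tuple):
        if alt_index < len(value):
            value = value[alt_index]
        else:
            value = value[0]
    try:
        return float(value)
    except (TypeError, ValueError):
        return None


def read_caller_vcf(
    path: str | Path,
    caller_id: str,
    score_key: Optional[str] = None,
) -> list[tuple[VariantCandidate, CallerVote]]:
    """Read one caller's somatic VCF into (candidate, vote) pairs.

    Multi-allelic records are split into one candidate per alternate allele.
    ``score_key`` names the INFO field (or the literal ``QUAL``) holding the
    caller's native score; if the key is configured but absent from a record
    the vote is kept with score=None and a warning is emitted once.
    """
    out: list[tuple[VariantCandidate, CallerVote]] = []
    warned_missing = False
    with pysam.VariantFile(str(path)) as vf:
        if score_key is not None and score_key.upper() != "QUAL":
            if score_key not in vf.header.info:
                warnings.warn(
                    f"score key {score_key!r} not declared in {path}; "
                    f"votes for {caller_id} will carry no score"
                )
        for i, record in enumerate(vf, start=1):
            try:
                alts = record.alts or ()
                for alt_index, alt in enumerate(alts):
                    if set(alt.upper()) - _VALID_BASES:
                        continue  # symbolic / spanning-deletion alleles
                    cand = normalize_variant(
                        record.chrom, record.pos, record.ref, alt
                    )
                    score = _record_score(record, score_key, alt_index)
                    if score is None and score_key is not None and not warned_missing:
                        warned_missing = True
                    out.append((cand, CallerVote(caller_id, 1, score)))
            except ValueError as exc:
                raise VcfParseError(
                    f"{path}: malformed record #{i} "
                    f"({record.chrom}:{record.pos}): {exc}"
                ) from exc
    return out


@dataclass
class UnionCallSet:
    """Set union of per-caller calls with a full vote matrix.

    Every candidate carries exactly one vote per configured caller; a caller
    that did not report a candidate contributes an explicit called=0 vote.
    """

    caller_ids: list[str]
    candidates: list[VariantCandidate]
    votes: dict[tuple, dict[str, CallerVote]] = field(default_factory=dict)
    contig_order: list[str] = field(default_factory=list)

    def __len__(self) -> int:
        return len(self.candidates)

    def vote_count(self, candidate: VariantCandidate) -> int:
        return sum(v.called for v in self.votes[candidate.key].values())

    def consensus(self, n: int) -> list[VariantCandidate]:
        return consensus_baseline(self, n)

    def to_frame(self):
        import pandas as pd

        rows = []
        for cand in self.candidates:
            row = {
                "chrom": cand.chrom,
                "pos": cand.pos,
                "ref": cand.ref,
                "alt": cand.alt,
                "var_class": cand.var_class,
            }
            for cid in self.caller_ids:
                vote = self.votes[cand.key][cid]
                row[f"called_{cid}"] = vote.called
                row[f"score_{cid}"] = vote.score
            rows.append(row)
        return pd.DataFrame(rows)


def merge_union(
    callsets: Mapping[str, Sequence[tuple[VariantCandidate, CallerVote]]],
    contig_order: Optional[Sequence[str]] = None,
) -> UnionCallSet:
    """Merge per-caller call lists into a union candidate set.

    ``callsets`` maps caller_id to that caller's (candidate, vote) pairs.
    The result is keyed by (chrom, pos, ref, alt); candidates are sorted by
    (contig order, pos, ref, alt), contigs defaulting to first-seen order.
    """
    if not callsets:
        raise ValueError("merge_union requires at least one caller call set")
    caller_ids = list(callsets)

    contig_sets = {
        cid: {cand.chrom for cand, _ in calls} for cid, calls in callsets.items()
    }
    nonempty = [s for s in contig_sets.values() if s]
    if len(nonempty) > 1:
        # Disjoint contig naming (e.g. "chr1" vs "1") indicates mixed conventions.
        first, *rest = nonempty
        if any(not (first & s) for s in rest):
            warnings.warn(
                "caller VCFs use disjoint contig sets; "
                "check for mixed chr-prefix conventions"
            )

    merged: dict[tuple, VariantCandidate] = {}
    vote_map: dict[tuple, dict[str, CallerVote]] = {}
    seen_contigs: list[str] = []
    for cid, calls in callsets.items():
        for cand, vote in calls:
            if cand.chrom not in seen_contigs:
                seen_contigs.append(cand.chrom)
            if cand.key not in merged:
                merged[cand.key] = cand
                vote_map[cand.key] = {}
            # keep the first called vote per caller (duplicate records collapse)
            existing = vote_map[cand.key].get(cid)
            if existing is None or (existing.called == 0 and vote.called == 1):
                vote_map[cand.key][cid] = vote

    for key in merged:
        for cid in caller_ids:
            vote_map[key].setdefault(cid, CallerVote(cid, 0))

    order = list(contig_order) if contig_order else seen_contigs
    rank = {c: i for i, c in enumerate(order)}

    def sort_key(cand: VariantCandidate):
        return (rank.get(cand.chrom, len(rank)), cand.chrom, cand.pos, cand.ref, cand.alt)

    candidates = sorted(merged.values(), key=sort_key)
    return UnionCallSet(caller_ids, candidates, vote_map, order)


def consensus_baseline(union: UnionCallSet, n: int) -> list[VariantCandidate]:
    """Candidates called by at least ``n`` callers (the >=N-tools baseline)."""
    if not 1 <= n <= len(union.caller_ids):
        raise ValueError(
            f"consensus level n={n} outside [1, {len(union.caller_ids)}]"
        )
    return [c for c in union.candidates if union.vote_count(c) >= n]


def _union_header(union: UnionCallSet) -> pysam.VariantHeader:
    header = pysam.VariantHeader()
    contigs = union.contig_order or sorted({c.chrom for c in union.candidates})
    for contig in contigs:
        header.contigs.add(contig)
    for cand in union.candidates:
        if cand.chrom not in header.contigs:
            header.contigs.add(cand.chrom)
    header.add_line(
        '##INFO=<ID=VC,Number=1,Type=String,Description="Variant class (SNV or INDEL)">'
    )
    for cid in union.caller_ids:
        header.add_line(
            f'##INFO=<ID=CALLED_{cid},Number=1,Type=Integer,'
            f'Description="Called by {cid} (0/1)">'
        )
        header.add_line(
            f'##INFO=<ID=SCORE_{cid},Number=1,Type=Float,'
            f'Description="Native score reported by {cid}">'
        )
    return header


def write_union_vcf(union: UnionCallSet, path: str | Path) -> None:
    """Write the merged candidate set as a VCF with per-caller INFO flags."""
    header = _union_header(union)
    with pysam.VariantFile(str(path), "w", header=header) as out:
        for cand in union.candidates:
            rec = out.new_record(
                contig=cand.chrom,
                start=cand.pos - 1,
                alleles=(cand.ref, cand.alt),
            )
            rec.info["VC"] = cand.var_class
            for cid in union.caller_ids:
                vote = union.votes[cand.key][cid]
                rec.info[f"CALLED_{cid}"] = vote.called
                if vote.score is not None:
                    rec.info[f"SCORE_{cid}"] = vote.score
            out.write(rec)


def read_union_vcf(path: str | Path) -> UnionCallSet:
    """Re-read a union VCF written by :func:`write_union_vcf`."""
    with pysam.VariantFile(str(path)) as vf:
        caller_ids = [
            key[len("CALLED_"):]
            for key in vf.header.info
            if key.startswith("CALLED_")
        ]
        contigs = list(vf.header.contigs)
        candidates: list[VariantCandidate] = []
        votes: dict[tuple, dict[str, CallerVote]] = {}
        for record in vf:
            for alt in record.alts or ():
                cand = normalize_variant(record.chrom, record.pos, record.ref, alt)
                candidates.append(cand)
                votes[cand.key] = {}
                for cid in caller_ids:
                    called = int(record.info.get(f"CALLED_{cid}", 0) or 0)
                    score = record.info.get(f"SCORE_{cid}")
                    score = None if score is None else float(score)
                    votes[cand.key][cid] = CallerVote(cid, called, score)
    return UnionCallSet(caller_ids, candidates, votes, contigs)


def write_union_tsv(union: UnionCallSet, path: str | Path) -> None:
    """TSV dump: one row per candidate with per-caller called/score columns."""
    union.to_frame().to_csv(path, sep="\t", index=False)
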