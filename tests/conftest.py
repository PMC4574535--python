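import numpy as np
import pytest

from somatic_ensemble.variants import CallerVote, VariantCandidate


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


def make_candidate(chrom="chr1", pos=100, ref="C", alt="T"):
    return VariantCandidate(chrom, pos, ref, alt)


def make_callset(candidates, caller_id, score=None):
    return [(c, CallerVote(caller_id, 1, score)) for c in candidates]


@pytest.fixture
def toy_candidates():
    return [
        VariantCandidate("chr1", 100, "C", "T"),
        VariantCandidate("chr1", 200, "G", "A"),
        VariantCandidate("chr2", 50, "A", "AT"),
        VariantCandidate("chr2", 75, "TAC", "T"),
    ]


def write_vcf(path, records, contigs=("chr1", "chr2"), info_lines=()):
    """Write a minimal VCF 4.2 text file for parser tests.

    records: iterable of (chrom, pos, ref, alt_field, info_string) tuples.
    """
    lines = ["##fileformat=VCFv4.2"]
    lines += [f"##contig=<ID={c}>" for c in contigs]
    lines += list(info_lines)
    lines.append("#CHROM\tPOS\tID\tREF\tALT\tQUAL\tFILTER\tINFO")
    for chrom, pos, ref, alt, info in records:
        lines.append(f"{chrom}\t{pos}\t.\t{ref}\t{alt}\t.\t.\t{info}")
    path.write_text("\n".join(lines) + "\n")
    return path
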