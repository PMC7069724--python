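"""Barcode-to-variant association from paired-end reads.

Read 1 carries the 18-mer barcode, read 2 the mutagenized ORF window.  Reads
are quality-filtered (any base below Phred 10 discards the pair), grouped by
barcode, and each group with at least three supporting reads is collapsed to a
strict per-base majority consensus.  The consensus is compared codon-by-codon
to the wild type: identical sequences are wild-type lineages, exactly one
changed codon is a variant call, anything else (multiple codons, length
mismatch, no majority at some base) rejects the barcode.  Requiring the same
misread to occur in the majority of independent reads suppresses sequencing
errors.
"""

from __future__ import annotations

from collections import Counter, defaultdict
from dataclasses import dataclass

import pandas as pd

from .orf import translate_codon
from .tables import WT_CODON

DEFAULT_MIN_PHRED = 10
DEFAULT_MIN_READS = 3


def _phred(qual: str) -> list[int]:
    return [ord(c) - 33 for c in qual]


def filter_association_reads(
    reads, min_phred: int = DEFAULT_MIN_PHRED
) -> list[tuple]:
    """Drop read pairs with any base below `min_phred` in either mate.

    `reads` is an iterable of (barcode_seq, barcode_qual, orf_seq, orf_qual).
    """
    out = []
    for i, rec in enumerate(reads):
        try:
            r1, q1, r2, q2 = rec
        except (TypeError, ValueError) as exc:
            raise ValueError(f"malformed read record at index {i}") from exc
        if len(r1) != len(q1) or len(r2) != len(q2):
            raise ValueError(f"malformed FASTQ record at index {i}: length mismatch")
        if min_phred <= 0:
            out.append(rec)
            continue
        if min(_phred(q1), default=0) < min_phred or min(_phred(q2), default=0) < min_phred:
            continue
        out.append(rec)
    return out


def group_by_barcode(reads) -> dict:
    """Group filtered pairs by exact barcode sequence -> list of (orf_seq, qual)."""
    groups: dict = defaultdict(list)
    for r1, _q1, r2, q2 in reads:
        groups[r1].append((r2, q2))
    return dict(groups)


@dataclass
class ConsensusResult:
    sequence: str | None
    support: int
    reason: str | None = None  # None if accepted


def build_consensus(reads: list[tuple], min_reads: int = DEFAULT_MIN_READS) -> ConsensusResult:
    """Strict per-base majority consensus of a barcode group.

    Rejects groups with fewer than `min_reads` reads, with unequal read
    lengths, or with any position lacking a strict (> half) majority base.
    """
    if not reads:
        raise ValueError("empty barcode group")
    support = len(reads)
    if support < min_reads:
        return ConsensusResult(None, support, "low_support")
    lengths = {len(seq) for seq, _ in reads}
    if len(lengths) != 1:
        return ConsensusResult(None, support, "length_mismatch")
    (length,) = lengths
    out = []
    half = support / 2.0
    for pos in range(length):
        counts = Counter(seq[pos] for seq, _ in reads)
        base, n = counts.most_common(1)[0]
        if n <= half:
            return ConsensusResult(None, support, "no_majority")
        out.append(base)
    return ConsensusResult("".join(out), support)


@dataclass
class VariantCall:
    position: int | None  # 1-based codon position; None for wild type
    wt_codon: str | None
    mut_codon: str | None
    reason: str | None = None  # rejection reason; None if accepted

    @property
    def accepted(self) -> bool:
        return self.reason is None

    @property
    def is_wild_type(self) -> bool:
        return self.accepted and self.position is None


def call_variant(consensus: str, wt_segment: str, frame_offset: int = 0) -> VariantCall:
    """Compare a consensus to the wild-type segment and call 0 or 1 codon changes.

    `frame_offset` is the 0-based nucleotide offset of the segment within the
    ORF and must fall on a codon boundary (the library is substitution-only,
    so no indels are tolerated and multi-codon differences are rejected).
    """
    if frame_offset % 3 != 0:
        raise ValueError(f"frame offset {frame_offset} is not a codon boundary")
    if len(consensus) != len(wt_segment):
        return VariantCall(None, None, None, reason="length_mismatch")
    if consensus == wt_segment:
        return VariantCall(None, None, None)
    n_codons = len(wt_segment) // 3
    diffs = []
    for k in range(n_codons):
        a, b = consensus[3 * k : 3 * k + 3], wt_segment[3 * k : 3 * k + 3]
        if a != b:
            diffs.append((k, a, b))
    # differences outside whole codons (trailing partial codon) also reject
    if len(wt_segment) % 3 and consensus[3 * n_codons :] != wt_segment[3 * n_codons :]:
        diffs.append((n_codons, consensus[3 * n_codons :], wt_segment[3 * n_codons :]))
    if len(diffs) != 1 or len(diffs[0][1]) != 3:
        return VariantCall(None, None, None, reason="multi_mutation")
    k, mut, wt = diffs[0]
    return VariantCall(position=frame_offset // 3 + k + 1, wt_codon=wt, mut_codon=mut)


def build_barcode_map(
    reads,
    wt_orf: str,
    frame_offset: int = 0,
    min_phred: int = DEFAULT_MIN_PHRED,
    min_reads: int = DEFAULT_MIN_READS,
) -> tuple[pd.DataFrame, dict]:
    """Quality-filter, group, build consensi, call variants; return map + report.

    The returned map has one row per accepted barcode (barcode, position,
    wt_codon, codon, aa, support); wild-type lineages carry position 0 and the
    ``WT`` codon marker.  The report tallies rejections by cause.  The result
    is independent of read order (groups are processed in sorted barcode
    order and consensus is a per-position vote).
    """
    reads = list(reads)
    filtered = filter_association_reads(reads, min_phred=min_phred)
    groups = group_by_barcode(filtered)
    report = Counter(
        input_reads=len(reads),
        filtered_reads=len(filtered),
        barcodes_seen=len(groups),
    )
    rows = []
    wt_segment = wt_orf[frame_offset:]
    for barcode in sorted(groups):
        cons = build_consensus(groups[barcode], min_reads=min_reads)
        if cons.reason is not None:
            report[cons.reason] += 1
            continue
        call = call_variant(cons.sequence, wt_segment[: len(cons.sequence)], frame_offset)
        if not call.accepted:
            report[call.reason] += 1
            continue
        if call.is_wild_type:
            rows.append(
                {
                    "barcode": barcode,
                    "position": 0,
                    "wt_codon": WT_CODON,
                    "codon": WT_CODON,
                    "aa": WT_CODON,
                    "support": cons.support,
                }
            )
        else:
            rows.append(
                {
                    "barcode": barcode,
                    "position": call.position,
                    "wt_codon": call.wt_codon,
                    "codon": call.mut_codon,
                    "aa": translate_codon(call.mut_codon),
                    "support": cons.support,
                }
            )
        report["accepted"] += 1
    columns = ["barcode", "position", "wt_codon", "codon", "aa", "support"]
    barcode_map = pd.DataFrame(rows, columns=columns)
    return barcode_map, dict(report)


def read_fastq_pairs(path1, path2) -> list[tuple]:
    """Load mate pairs from two FASTQ files into association-read records."""
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    with open(path1) as f1, open(path2) as f2:
        it1, it2 = FastqGeneralIterator(f1), FastqGeneralIterator(f2)
        return [
            (s1, q1, s2, q2) for (_, s1, q1), (_, s2, q2) in zip(it1, it2, strict=True)
        ]


def write_barcode_map(barcode_map: pd.DataFrame, path) -> None:
    barcode_map.to_csv(path, sep="\t", index=False)


def read_barcode_map(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"barcode": str, "codon": str, "wt_codon": str})


def map_as_dict(barcode_map: pd.DataFrame) -> dict:
    """barcode -> (position, codon) lookup used by the counting stage."""
    return {
        r.barcode: (int(r.position), r.codon) for r in barcode_map.itertuples()
    }
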