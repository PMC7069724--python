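"""Competition FASTQ -> per-variant count tables.

Single-end 100-base reads carry the lineage barcode at bases 1-18 and an
8-base sample identifier at bases 91-98.  A read is kept only if every
interpreted base (barcode, identifier, checked template anchors) has Phred
score strictly above 20 and the template anchors match the expected constant
sequence exactly.  Kept reads are demultiplexed by identifier, barcodes are
counted per sample, and counts are summed over each variant's barcodes using
the association map; barcodes absent from the map are discarded (misreads of
a true barcode almost never collide with another valid barcode, so this is
the error-suppression step of the barcoded design).
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .orf import translate_codon
from .simulate import BARCODE_SLICE, COMPETITION_TEMPLATE, IDENTIFIER_SLICE
from .tables import WT_CODON, CountTable, SampleSheet, VARIANT_COLUMNS

DEFAULT_MIN_PHRED = 20
#: template anchor spans checked by default (0-based, end-exclusive): the
#: bases flanking the barcode and the identifier
DEFAULT_ANCHORS = ((18, 26), (98, 100))


@dataclass
class ParsedRead:
    identifier: str | None
    barcode: str | None
    reason: str | None = None

    @property
    def accepted(self) -> bool:
        return self.reason is None


def parse_competition_read(
    seq: str,
    qual: str,
    min_phred: int = DEFAULT_MIN_PHRED,
    template: str = COMPETITION_TEMPLATE,
    anchors: tuple = DEFAULT_ANCHORS,
    full_template_check: bool = False,
) -> ParsedRead:
    """Extract (identifier, barcode) from one read, or a rejection reason.

    Quality is strict: a base at exactly `min_phred` fails.  Only interpreted
    bases are checked; `full_template_check=True` extends the template match
    to every constant base of the scaffold.
    """
    if len(seq) < IDENTIFIER_SLICE.stop:
        return ParsedRead(None, None, "too_short")
    if len(seq) != len(qual):
        return ParsedRead(None, None, "malformed")
    if full_template_check:
        spans = [(18, 90), (98, min(len(template), len(seq)))]
    else:
        spans = list(anchors)
    for lo, hi in spans:
        if seq[lo:hi] != template[lo:hi]:
            return ParsedRead(None, None, "template_mismatch")
    check = [BARCODE_SLICE, IDENTIFIER_SLICE] + [slice(lo, hi) for lo, hi in spans]
    for span in check:
        for c in qual[span]:
            if ord(c) - 33 <= min_phred:
                return ParsedRead(None, None, "low_quality")
    return ParsedRead(seq[IDENTIFIER_SLICE], seq[BARCODE_SLICE])


def parse_competition_fastq(path, **kwargs) -> tuple[list[ParsedRead], Counter]:
    from Bio.SeqIO.QualityIO import FastqGeneralIterator

    parsed: list[ParsedRead] = []
    tally: Counter = Counter()
    with open(path) as fh:
        for _, seq, qual in FastqGeneralIterator(fh):
            p = parse_competition_read(seq, qual, **kwargs)
            tally["accepted" if p.accepted else p.reason] += 1
            parsed.append(p)
    return parsed, tally


def count_barcodes(parsed_reads, sheet: SampleSheet) -> tuple[dict, Counter]:
    """Per-sample barcode counts keyed by (condition, time_h, replicate).

    Reads with identifiers absent from the sheet are dropped and tallied.
    Counting is a pure tally, so it is invariant to read order.
    """
    lookup = sheet.identifier_to_sample
    counts: dict = {sample: Counter() for sample in lookup.values()}
    tally: Counter = Counter()
    for p in parsed_reads:
        if not p.accepted:
            tally["rejected_reads"] += 1
            continue
        sample = lookup.get(p.identifier)
        if sample is None:
            tally["unknown_identifier"] += 1
            continue
        counts[sample][p.barcode] += 1
        tally["counted"] += 1
    return counts, tally


def aggregate_to_variants(
    sample_counts: dict,
    barcode_lookup: dict,
    condition: str,
    times_h,
    doubling_time_h: float = 4.0,
    replicate: int = 1,
) -> CountTable:
    """Sum barcode counts over each variant's barcodes into a CountTable.

    `sample_counts` is the output of :func:`count_barcodes`; `barcode_lookup`
    maps barcode -> (position, codon).  Barcodes not in the lookup contribute
    to the discard tally, not to any variant.
    """
    times_h = np.asarray(sorted(float(t) for t in times_h))
    variant_keys = sorted(set(barcode_lookup.values()), key=lambda k: (k[0], str(k[1])))
    index = {k: i for i, k in enumerate(variant_keys)}
    counts = np.zeros((len(variant_keys), len(times_h)), dtype=np.int64)
    discarded = 0
    for j, th in enumerate(times_h):
        sample = (condition, float(th), replicate)
        ctr = sample_counts.get(sample, Counter())
        for bc, n in ctr.items():
            key = barcode_lookup.get(bc)
            if key is None:
                discarded += n
            else:
                counts[index[key], j] += n
    rows = []
    for pos, codon in variant_keys:
        if codon == WT_CODON:
            rows.append(
                {
                    "position": 0,
                    "wt_codon": WT_CODON,
                    "codon": WT_CODON,
                    "aa": WT_CODON,
                    "wt_aa": WT_CODON,
                    "is_stop": False,
                    "is_wt_synonym": False,
                    "is_reference": True,
                }
            )
        else:
            aa = translate_codon(codon)
            rows.append(
                {
                    "position": pos,
                    "wt_codon": "",
                    "codon": codon,
                    "aa": aa,
                    "wt_aa": "",
                    "is_stop": aa == "*",
                    "is_wt_synonym": False,
                    "is_reference": False,
                }
            )
    variants = pd.DataFrame(rows, columns=VARIANT_COLUMNS)
    return CountTable(
        variants=variants,
        counts=counts,
        times=times_h / doubling_time_h,
        times_h=times_h,
        condition=condition,
        replicate=replicate,
        discarded_barcode_reads=discarded,
    )


def annotate_wt_codons(table: CountTable, wt_orf: str) -> CountTable:
    """Fill wt_codon / wt_aa / synonym flags from the wild-type ORF."""
    v = table.variants.copy()
    for i, row in v.iterrows():
        if row["is_reference"]:
            continue
        pos = int(row["position"])
        wt = wt_orf[(pos - 1) * 3 : pos * 3]
        v.at[i, "wt_codon"] = wt
        v.at[i, "wt_aa"] = translate_codon(wt)
        v.at[i, "is_wt_synonym"] = v.at[i, "aa"] == v.at[i, "wt_aa"]
    table.variants = v
    return table


def filter_low_t0(table: CountTable, min_t0: int = 100) -> CountTable:
    """Drop variants with fewer than `min_t0` reads at the first timepoint.

    Low-abundance lineages at t=0 give noisy trajectories; the default keeps
    a variant only if it starts with at least 100 reads.
    """
    if not len(table.times) or table.times[0] != 0:
        raise ValueError("count table has no t=0 timepoint")
    keep = table.counts[:, 0] >= min_t0
    return CountTable(
        variants=table.variants.loc[keep].reset_index(drop=True),
        counts=table.counts[keep],
        times=table.times,
        times_h=table.times_h,
        condition=table.condition,
        replicate=table.replicate,
        discarded_barcode_reads=table.discarded_barcode_reads,
    )
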