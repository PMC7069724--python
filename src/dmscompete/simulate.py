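"""Synthetic barcoded bulk-competition data with known ground truth.

Emulates the statistical structure of a single-codon-substitution library
competed in bulk: every codon variant carries 10-20 unique 18-mer barcodes,
lineages grow exponentially at variant-specific rates, and sequencing samples
reads multinomially at each timepoint.  The distribution of fitness effects is
a three-component mixture (neutral peak at s=0, null peak at s=-1, small
beneficial tail), matching the bimodal shape observed for an essential
chaperone under selection.

Time is measured in wild-type generations with the wild-type rate pinned at
r_wt = 1, so a complete loss-of-function allele has rate ~0 (s = -1).  The
anchor normalization applied downstream removes any affine ambiguity in this
convention.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .orf import STOP_CODONS, CODONS, orf_codons, random_orf, translate_codon
from .tables import WT_CODON, CountTable, SampleSheet, VARIANT_COLUMNS

#: Constant 100-base competition read scaffold.  Positions 1-18 (1-based) hold
#: the N18 barcode, positions 91-98 the 8-base sample identifier; the rest is
#: fixed template sequence shared by every read.
COMPETITION_TEMPLATE = (
    "NNNNNNNNNNNNNNNNNN"  # 1-18: barcode
    "GCTAGCACGTGTCGACTTAAGGCTGCAACGGTCATTGCAGGTCTAGAGCATCCGTAACTGGTCAAGCTTGCA"  # 19-90
    "NNNNNNNN"  # 91-98: identifier
    "AC"  # 99-100
)
BARCODE_SLICE = slice(0, 18)
IDENTIFIER_SLICE = slice(90, 98)

#: default Phred for clean bases / injected low-quality bases (Sanger +33)
HIGH_Q = 35
LOW_Q = 5


@dataclass
class DfeMixture:
    """Mixture over selection coefficients: (neutral, null, beneficial).

    Each component is Gaussian with a location and sd.  Stop codons are drawn
    from the null component regardless of the weights, except within the
    dispensable C-terminal window where they are drawn from the neutral one.
    """

    weights: tuple = (0.60, 0.35, 0.05)
    locs: tuple = (0.0, -1.0, 0.03)
    sds: tuple = (0.02, 0.05, 0.02)

    def __post_init__(self) -> None:
        if len(self.weights) != 3 or len(self.locs) != 3 or len(self.sds) != 3:
            raise ValueError("mixture needs exactly three components")
        if abs(sum(self.weights) - 1.0) > 1e-9:
            raise ValueError(f"mixture weights must sum to 1, got {self.weights}")
        if any(w < 0 for w in self.weights) or any(s < 0 for s in self.sds):
            raise ValueError("weights and sds must be non-negative")


@dataclass
class SimulationConfig:
    protein_length: int = 709
    mutagenized_range: tuple = (2, 709)  # inclusive, 1-based
    barcodes_per_variant_mean: float = 15.0
    dfe: DfeMixture = field(default_factory=DfeMixture)
    timepoints_h: tuple = (0.0, 4.0, 8.0, 12.0, 16.0, 20.0, 24.0, 28.0)
    doubling_time_h: float = 4.0
    #: total reads per timepoint; None -> 500 reads per variant on average
    depth_per_timepoint: int | None = None
    base_error_rate: float = 0.0
    #: fraction of reads given one base below the relevant quality filter
    low_quality_fraction: float = 0.0
    #: association reads emitted per barcode
    read_multiplicity: int = 5
    #: generations of growth before the t=0 sample (partial stop depletion)
    pre_selection_generations: float = 0.0
    #: length of the dispensable C-terminal window (stops behave neutrally)
    dispensable_c_terminal: int = 32
    #: reference lineage abundance relative to the median variant
    reference_abundance: float = 20.0
    n0_log_sd: float = 0.3
    seed: int = 0

    def __post_init__(self) -> None:
        lo, hi = self.mutagenized_range
        if not (1 <= lo <= hi <= self.protein_length):
            raise ValueError(
                f"invalid mutagenized range {self.mutagenized_range} for "
                f"protein of {self.protein_length} codons"
            )
        tp = np.asarray(self.timepoints_h, dtype=float)
        if tp[0] != 0 or (np.diff(tp) <= 0).any():
            raise ValueError("timepoints must be strictly increasing and start at 0")
        if self.depth_per_timepoint is not None and self.depth_per_timepoint <= 0:
            raise ValueError("depth_per_timepoint must be positive")
        # the dispensable tail is a property of the full-length chaperone; a
        # short synthetic protein has none unless explicitly configured
        if self.dispensable_c_terminal >= self.protein_length / 2:
            self.dispensable_c_terminal = 0

    @property
    def times_gen(self) -> np.ndarray:
        return np.asarray(self.timepoints_h, dtype=float) / self.doubling_time_h

    @property
    def stop_neutral_min_pos(self) -> int:
        """First position whose stop codons draw from the neutral component."""
        return self.protein_length - self.dispensable_c_terminal + 1


@dataclass
class TrueVariant:
    """Ground-truth lineage: identity, growth rate, initial size, barcodes."""

    position: int
    wt_codon: str
    codon: str
    aa: str
    wt_aa: str
    true_rate: float
    true_s: float
    n0: float
    barcodes: list = field(default_factory=list)

    @property
    def is_reference(self) -> bool:
        return self.codon == WT_CODON

    @property
    def is_stop(self) -> bool:
        return self.aa == "*"

    @property
    def is_wt_synonym(self) -> bool:
        return (not self.is_reference) and self.aa == self.wt_aa

    def __post_init__(self) -> None:
        if self.n0 <= 0:
            raise ValueError("n0 must be positive")
        if not self.is_reference and self.codon == self.wt_codon:
            raise ValueError(
                f"mutant codon equals wild type at position {self.position}"
            )


@dataclass
class LibrarySummary:
    n_codon_variants: int
    n_aa_variants: int
    variants: pd.DataFrame  # position, wt_codon, codon, aa, wt_aa, is_stop, is_wt_synonym


def enumerate_library(
    protein_length: int,
    mutagenized_range: tuple,
    wt_orf: str | None = None,
    orf_seed: int = 0,
) -> LibrarySummary:
    """Enumerate every single-codon substitution over the mutagenized range.

    Each position contributes the 63 codons that differ from wild type
    (synonymous codons included) and 20 amino-acid variants (19 substitutions
    plus stop); wild-type synonyms are flagged, not counted as amino-acid
    variants.
    """
    lo, hi = mutagenized_range
    if not (1 <= lo <= hi <= protein_length):
        raise ValueError(
            f"invalid mutagenized range {mutagenized_range} for "
            f"protein of {protein_length} codons"
        )
    if wt_orf is None:
        wt_orf = random_orf(protein_length, seed=orf_seed)
    codons = orf_codons(wt_orf)
    if len(codons) < protein_length:
        raise ValueError("wild-type ORF shorter than protein_length")
    rows = []
    for pos in range(lo, hi + 1):
        wt = codons[pos - 1]
        wt_aa = translate_codon(wt)
        for alt in CODONS:
            if alt == wt:
                continue
            aa = translate_codon(alt)
            rows.append(
                {
                    "position": pos,
                    "wt_codon": wt,
                    "codon": alt,
                    "aa": aa,
                    "wt_aa": wt_aa,
                    "is_stop": aa == "*",
                    "is_wt_synonym": aa == wt_aa,
                }
            )
    variants = pd.DataFrame(rows)
    n_codon = len(variants)
    n_aa = len(
        variants.loc[~variants["is_wt_synonym"], ["position", "aa"]].drop_duplicates()
    )
    return LibrarySummary(n_codon_variants=n_codon, n_aa_variants=n_aa, variants=variants)


def _draw_barcodes(n: int, rng: np.random.Generator, seen: set) -> list[str]:
    out: list[str] = []
    while len(out) < n:
        bc = "".join("ACGT"[b] for b in rng.integers(0, 4, size=18))
        if bc not in seen:
            seen.add(bc)
            out.append(bc)
    return out


def sample_true_dfe(
    config: SimulationConfig,
    variants: pd.DataFrame,
    rng: np.random.Generator | None = None,
) -> list[TrueVariant]:
    """Assign ground-truth selection coefficients, n0 and barcodes to a library.

    Returns the variant lineages plus one reference (unmutated wild-type)
    lineage, seeded at ``config.reference_abundance`` times the median variant
    abundance.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    dfe = config.dfe
    weights = np.asarray(dfe.weights, dtype=float)
    seen: set[str] = set()
    out: list[TrueVariant] = []
    n0s = np.exp(rng.normal(0.0, config.n0_log_sd, size=len(variants)))
    comp_choices = rng.choice(3, size=len(variants), p=weights)
    for i, row in enumerate(variants.itertuples()):
        if row.is_wt_synonym:
            s = 0.0
        elif row.is_stop:
            comp = 0 if row.position >= config.stop_neutral_min_pos else 1
            s = rng.normal(dfe.locs[comp], dfe.sds[comp])
        else:
            comp = comp_choices[i]
            s = rng.normal(dfe.locs[comp], dfe.sds[comp])
        n_bc = max(1, int(rng.poisson(config.barcodes_per_variant_mean)))
        out.append(
            TrueVariant(
                position=int(row.position),
                wt_codon=row.wt_codon,
                codon=row.codon,
                aa=row.aa,
                wt_aa=row.wt_aa,
                true_rate=1.0 + s,
                true_s=s,
                n0=float(n0s[i]),
                barcodes=_draw_barcodes(n_bc, rng, seen),
            )
        )
    ref_n0 = config.reference_abundance * float(np.median(n0s)) if len(n0s) else 1.0
    n_bc = max(1, int(rng.poisson(config.barcodes_per_variant_mean)))
    out.append(
        TrueVariant(
            position=0,
            wt_codon=WT_CODON,
            codon=WT_CODON,
            aa=WT_CODON,
            wt_aa=WT_CODON,
            true_rate=1.0,
            true_s=0.0,
            n0=ref_n0,
            barcodes=_draw_barcodes(n_bc, rng, seen),
        )
    )
    return out


def variants_frame(true_variants: list[TrueVariant]) -> pd.DataFrame:
    """Variant metadata table (``VARIANT_COLUMNS``) for a set of lineages."""
    return pd.DataFrame(
        [
            {
                "position": tv.position,
                "wt_codon": tv.wt_codon,
                "codon": tv.codon,
                "aa": tv.aa,
                "wt_aa": tv.wt_aa,
                "is_stop": tv.is_stop,
                "is_wt_synonym": tv.is_wt_synonym,
                "is_reference": tv.is_reference,
            }
            for tv in true_variants
        ]
    )[VARIANT_COLUMNS]


def expected_frequencies(
    true_variants: list[TrueVariant], times_gen: np.ndarray
) -> np.ndarray:
    """Deterministic lineage frequencies n_i exp(r_i t) / sum_j n_j exp(r_j t)."""
    r = np.array([tv.true_rate for tv in true_variants])
    n0 = np.array([tv.n0 for tv in true_variants])
    t = np.asarray(times_gen, dtype=float)
    if not len(true_variants):
        raise ValueError("no variants to simulate")
    # offset by the reference rate for numerical headroom; cancels in the ratio
    w = n0[:, None] * np.exp((r[:, None] - 1.0) * t[None, :])
    z = w.sum(axis=0)
    if (z <= 0).any():
        raise ValueError("degenerate population: total size is zero")
    return w / z


def simulate_competition_counts(
    true_variants: list[TrueVariant],
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    condition: str = "standard",
) -> CountTable:
    """Multinomial read counts at each timepoint under exponential growth."""
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times = config.times_gen
    tv = true_variants
    if config.pre_selection_generations > 0:
        tv = [
            replace(
                v, n0=v.n0 * float(np.exp((v.true_rate - 1.0) * config.pre_selection_generations))
            )
            for v in tv
        ]
    freqs = expected_frequencies(tv, times)
    depth = config.depth_per_timepoint
    if depth is None:
        depth = 500 * len(tv)
    counts = np.empty((len(tv), len(times)), dtype=np.int64)
    for j in range(len(times)):
        counts[:, j] = rng.multinomial(depth, freqs[:, j])
    return CountTable(
        variants=variants_frame(tv),
        counts=counts,
        times=times,
        times_h=np.asarray(config.timepoints_h, dtype=float),
        condition=condition,
    )


def _apply_errors(seq: str, rate: float, rng: np.random.Generator) -> str:
    if rate <= 0:
        return seq
    arr = list(seq)
    n_err = rng.binomial(len(arr), rate)
    if n_err == 0:
        return seq
    for pos in rng.choice(len(arr), size=n_err, replace=False):
        old = arr[pos]
        choices = [b for b in "ACGT" if b != old]
        arr[pos] = choices[rng.integers(0, 3)]
    return "".join(arr)


def _qual_string(length: int) -> str:
    return chr(HIGH_Q + 33) * length


def _inject_low_quality(
    qual: str, rng: np.random.Generator, span: slice | None = None
) -> str:
    """Set one base (within `span` if given) to a low Phred score."""
    lo, hi = (span.start, span.stop) if span is not None else (0, len(qual))
    pos = int(rng.integers(lo, hi))
    return qual[:pos] + chr(LOW_Q + 33) + qual[pos + 1 :]


def mutant_orf(wt_orf: str, tv: TrueVariant) -> str:
    if tv.is_reference:
        return wt_orf
    i = (tv.position - 1) * 3
    return wt_orf[:i] + tv.codon + wt_orf[i + 3 :]


def simulate_association_reads(
    true_variants: list[TrueVariant],
    wt_orf: str,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
    multiplicity: int | None = None,
) -> list[tuple]:
    """Paired association reads: (barcode read, qual, ORF read, qual) per record.

    Read 1 carries the 18-mer barcode; read 2 the (single-window) mutagenized
    ORF segment.  Substitution errors at ``base_error_rate``; a
    ``low_quality_fraction`` of read pairs get one base pushed below the
    quality filter.
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    if len(wt_orf) < 3 * config.protein_length:
        raise ValueError("wild-type ORF shorter than the protein length")
    mult = config.read_multiplicity if multiplicity is None else multiplicity
    reads = []
    for tv in true_variants:
        orf = mutant_orf(wt_orf, tv)
        for bc in tv.barcodes:
            for _ in range(mult):
                r1 = _apply_errors(bc, config.base_error_rate, rng)
                r2 = _apply_errors(orf, config.base_error_rate, rng)
                q1 = _qual_string(len(r1))
                q2 = _qual_string(len(r2))
                if config.low_quality_fraction > 0 and rng.random() < config.low_quality_fraction:
                    if rng.random() < 0.5:
                        q1 = _inject_low_quality(q1, rng)
                    else:
                        q2 = _inject_low_quality(q2, rng)
                reads.append((r1, q1, r2, q2))
    return reads


def write_fastq_pair(reads: list[tuple], path1, path2, prefix: str = "assoc") -> None:
    with open(path1, "w") as f1, open(path2, "w") as f2:
        for i, (r1, q1, r2, q2) in enumerate(reads):
            f1.write(f"@{prefix}_{i}/1\n{r1}\n+\n{q1}\n")
            f2.write(f"@{prefix}_{i}/2\n{r2}\n+\n{q2}\n")


def emit_competition_fastq(
    table: CountTable,
    barcode_map: dict,
    sheet: SampleSheet,
    path,
    config: SimulationConfig,
    rng: np.random.Generator | None = None,
) -> None:
    """Write 100-base competition reads reproducing a CountTable.

    ``barcode_map`` maps variant (position, codon) keys to barcode lists.  A
    variant's count at each timepoint is split across its barcodes uniformly
    at random; each read is the constant template with the barcode at bases
    1-18 and the sample identifier at 91-98.  The sample sheet must contain
    one row per timepoint of the table's condition (collisions are rejected by
    ``SampleSheet`` itself).
    """
    if rng is None:
        rng = np.random.default_rng(config.seed)
    times_h = table.times_h if table.times_h is not None else table.times
    sub = sheet.rows[
        (sheet.rows["condition"] == table.condition)
        & (sheet.rows["replicate"] == table.replicate)
    ]
    ident_for_time = {float(r.time_h): r.identifier for r in sub.itertuples()}
    missing = [t for t in times_h if float(t) not in ident_for_time]
    if missing:
        raise ValueError(f"sample sheet has no identifier for timepoints {missing}")
    template = COMPETITION_TEMPLATE
    read_no = 0
    with open(path, "w") as fh:
        for j, th in enumerate(times_h):
            ident = ident_for_time[float(th)]
            for i, row in table.variants.iterrows():
                count = int(table.counts[i, j])
                if count == 0:
                    continue
                key = (int(row["position"]), row["codon"])
                barcodes = barcode_map.get(key)
                if not barcodes:
                    raise ValueError(f"variant {key} has no barcodes")
                split = rng.multinomial(count, np.full(len(barcodes), 1.0 / len(barcodes)))
                for bc, n_reads in zip(barcodes, split):
                    base = bc + template[18:90] + ident + template[98:]
                    for _ in range(int(n_reads)):
                        seq = _apply_errors(base, config.base_error_rate, rng)
                        qual = _qual_string(100)
                        if (
                            config.low_quality_fraction > 0
                            and rng.random() < config.low_quality_fraction
                        ):
                            qual = _inject_low_quality(qual, rng, BARCODE_SLICE)
                        fh.write(f"@comp_{read_no}\n{seq}\n+\n{qual}\n")
                        read_no += 1


def barcode_map_from_truth(true_variants: list[TrueVariant]) -> dict:
    """Ground-truth (position, codon) -> barcode list mapping."""
    return {(tv.position, tv.codon): list(tv.barcodes) for tv in true_variants}


def write_truth_tsv(true_variants: list[TrueVariant], path) -> None:
    pd.DataFrame(
        [
            {
                "position": tv.position,
                "wt_codon": tv.wt_codon,
                "mut_codon": tv.codon,
                "aa": tv.aa,
                "true_rate": tv.true_rate,
                "true_s": tv.true_s,
                "n0": tv.n0,
                "barcodes": ";".join(tv.barcodes),
            }
            for tv in true_variants
        ]
    ).to_csv(path, sep="\t", index=False)


def read_truth_tsv(path) -> list[TrueVariant]:
    df = pd.read_csv(path, sep="\t")
    out = []
    for row in df.itertuples():
        wt_aa = WT_CODON if row.wt_codon == WT_CODON else translate_codon(row.wt_codon)
        aa = row.aa
        out.append(
            TrueVariant(
                position=int(row.position),
                wt_codon=row.wt_codon,
                codon=row.mut_codon,
                aa=aa,
                wt_aa=wt_aa,
                true_rate=float(row.true_rate),
                true_s=float(row.true_s),
                n0=float(row.n0),
                barcodes=str(row.barcodes).split(";"),
            )
        )
    return out
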