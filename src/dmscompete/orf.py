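"""Wild-type ORF utilities: codon enumeration, translation, deterministic test ORFs."""

from __future__ import annotations

import itertools

import numpy as np
from Bio.Seq import Seq

BASES = "ACGT"
CODONS = ["".join(c) for c in itertools.product(BASES, repeat=3)]
STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate_codon(codon: str) -> str:
    """One-letter amino acid for a DNA codon; '*' for stop."""
    codon = codon.upper()
    if len(codon) != 3 or any(b not in BASES for b in codon):
        raise ValueError(f"not a DNA codon: {codon!r}")
    return str(Seq(codon).translate())


def random_orf(n_codons: int, seed: int = 0, start_with_atg: bool = True) -> str:
    """Random ORF of `n_codons` codons with no internal stop codons.

    Deterministic for a given seed; used as the synthetic wild-type sequence.
    """
    if n_codons < 1:
        raise ValueError("n_codons must be >= 1")
    rng = np.random.default_rng(seed)
    sense = [c for c in CODONS if c not in STOP_CODONS]
    codons = [sense[i] for i in rng.integers(0, len(sense), size=n_codons)]
    if start_with_atg:
        codons[0] = "ATG"
    return "".join(codons)


def orf_codons(orf: str) -> list[str]:
    if len(orf) % 3 != 0:
        raise ValueError(f"ORF length {len(orf)} is not a multiple of 3")
    return [orf[i : i + 3] for i in range(0, len(orf), 3)]


def read_fasta_orf(path) -> str:
    from Bio import SeqIO

    rec = next(SeqIO.parse(str(path), "fasta"))
    return str(rec.seq).upper()


def write_fasta_orf(orf: str, path, name: str = "wt_orf") -> None:
    with open(path, "w") as fh:
        fh.write(f">{name}\n")
        for i in range(0, len(orf), 70):
            fh.write(orf[i : i + 70] + "\n")
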