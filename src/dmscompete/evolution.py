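"""Natural sequence variation and structural annotations versus fitness classes.

Covers: per-column amino-acid entropy of a multiple sequence alignment mapped
to reference coordinates, extraction of naturally occurring variants, BLOSUM62
substitution scores, two-sample Kolmogorov-Smirnov comparisons, pooled
two-proportion z-tests with Benjamini-Hochberg adjustment, and joined
class-versus-feature comparisons (SASA, distance to the ATP gamma-phosphate,
predicted stability change, conservation) consumed from a precomputed
per-position annotation table.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from Bio import AlignIO
from Bio.Align import substitution_matrices
from scipy.stats import ks_2samp, norm, pearsonr
from statsmodels.stats.multitest import multipletests

AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"
GAP_CHARS = set("-.")

_BLOSUM62 = substitution_matrices.load("BLOSUM62")


def column_entropy(frequencies) -> float:
    """Shannon entropy, in nats, of an amino-acid frequency vector."""
    p = np.asarray(frequencies, dtype=float)
    if (p < 0).any():
        raise ValueError("negative frequency")
    total = p.sum()
    if total <= 0:
        raise ValueError("empty frequency vector")
    p = p / total
    nz = p[p > 0]
    return float(-(nz * np.log(nz)).sum())


@dataclass
class AlignmentColumnStats:
    position: int  # 1-based reference coordinate
    frequencies: dict
    entropy: float
    n_sequences: int


def alignment_column_stats(alignment, reference_id: str) -> list[AlignmentColumnStats]:
    """Per-column amino-acid frequencies and entropy in reference coordinates.

    Columns that are gaps in the reference row are skipped; gaps in other
    rows are excluded from the frequency vector (not a 21st state).
    """
    ref_row = None
    for rec in alignment:
        if rec.id == reference_id:
            ref_row = str(rec.seq).upper()
            break
    if ref_row is None:
        raise ValueError(f"reference id {reference_id!r} absent from the alignment")
    out = []
    ref_pos = 0
    for col in range(alignment.get_alignment_length()):
        if ref_row[col] in GAP_CHARS:
            continue
        ref_pos += 1
        counts: dict = {}
        for rec in alignment:
            aa = str(rec.seq[col]).upper()
            if aa in GAP_CHARS or aa not in AMINO_ACIDS:
                continue
            counts[aa] = counts.get(aa, 0) + 1
        n = sum(counts.values())
        freqs = {aa: c / n for aa, c in counts.items()} if n else {}
        out.append(
            AlignmentColumnStats(
                position=ref_pos,
                frequencies=freqs,
                entropy=column_entropy(list(freqs.values())) if freqs else 0.0,
                n_sequences=n,
            )
        )
    return out


def read_alignment(path):
    return AlignIO.read(str(path), "fasta")


def extract_natural_variants(alignment, reference_id: str) -> pd.DataFrame:
    """(position, amino_acid, n_species) for every non-reference residue.

    Positions are 1-based reference coordinates; columns that are gaps in
    the reference are skipped, gap characters in other sequences ignored.
    The result is independent of sequence order.
    """
    ref_row = None
    for rec in alignment:
        if rec.id == reference_id:
            ref_row = str(rec.seq).upper()
            break
    if ref_row is None:
        raise ValueError(f"reference id {reference_id!r} absent from the alignment")
    counts: dict = {}
    ref_pos = 0
    for col in range(alignment.get_alignment_length()):
        ref_aa = ref_row[col]
        if ref_aa in GAP_CHARS:
            continue
        ref_pos += 1
        for rec in alignment:
            if rec.id == reference_id:
                continue
            aa = str(rec.seq[col]).upper()
            if aa in GAP_CHARS or aa not in AMINO_ACIDS or aa == ref_aa:
                continue
            counts[(ref_pos, aa)] = counts.get((ref_pos, aa), 0) + 1
    rows = [
        {"position": pos, "amino_acid": aa, "n_species": n}
        for (pos, aa), n in sorted(counts.items())
    ]
    return pd.DataFrame(rows, columns=["position", "amino_acid", "n_species"])


def blosum_score(wt_aa: str, mut_aa: str) -> int:
    """BLOSUM62 log-odds score for an amino-acid exchange (symmetric)."""
    wt_aa, mut_aa = wt_aa.upper(), mut_aa.upper()
    if wt_aa not in AMINO_ACIDS or mut_aa not in AMINO_ACIDS:
        raise ValueError(f"nonstandard amino acid in ({wt_aa!r}, {mut_aa!r})")
    return int(_BLOSUM62[wt_aa, mut_aa])


def ks_two_sample(a, b) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: exact D, asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if len(a) == 0 or len(b) == 0:
        raise ValueError("both samples must be nonempty")
    res = ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def two_proportion_z_bh(
    pairs: list[tuple], adaptive: bool = False
) -> pd.DataFrame:
    """Pooled two-proportion z-tests with Benjamini-Hochberg adjustment.

    `pairs` is a list of ((success_a, total_a), (success_b, total_b)).
    Two-sided p-values; a degenerate pooled variance gives p = 1.  Set
    `adaptive=True` for the two-stage (adaptive) BH variant.
    """
    rows = []
    for (xa, na), (xb, nb) in pairs:
        if na <= 0 or nb <= 0:
            raise ValueError("totals must be positive")
        pa, pb = xa / na, xb / nb
        pool = (xa + xb) / (na + nb)
        var = pool * (1 - pool) * (1 / na + 1 / nb)
        if var <= 0:
            z, p = 0.0, 1.0
        else:
            z = (pa - pb) / np.sqrt(var)
            p = float(2 * norm.sf(abs(z)))
        rows.append({"prop_a": pa, "prop_b": pb, "z": z, "p_raw": p})
    df = pd.DataFrame(rows)
    method = "fdr_tsbh" if adaptive else "fdr_bh"
    _, adj, _, _ = multipletests(df["p_raw"], method=method)
    df["p_adj"] = adj
    return df


def class_feature_comparison(
    classes: pd.DataFrame,
    features: pd.DataFrame,
    feature_col: str,
    class_col: str = "fitness_class",
    on: str = "position",
    interface_col: str | None = None,
) -> dict:
    """Compare a per-position feature across fitness classes.

    Joins classes to features on `on`, returns per-class feature
    distributions, all pairwise KS tests, optional per-class interface
    fractions, and the Pearson correlation between position means of the
    class table's ``s`` column (if present) and the feature.
    """
    merged = classes.merge(features, on=on, how="inner")
    groups = {
        str(lab): sub[feature_col].dropna().to_numpy()
        for lab, sub in merged.groupby(class_col)
    }
    empty = [lab for lab, v in groups.items() if len(v) == 0]
    if empty or not groups:
        raise ValueError(f"empty class after join: {empty or class_col}")
    ks = {}
    labs = sorted(groups)
    for i, la in enumerate(labs):
        for lb in labs[i + 1 :]:
            d, p = ks_two_sample(groups[la], groups[lb])
            ks[f"{la}|{lb}"] = {"D": d, "p": p}
    out = {"distributions": groups, "ks": ks}
    if interface_col is not None and interface_col in merged.columns:
        out["interface_fraction"] = {
            lab: float(sub[interface_col].mean())
            for lab, sub in merged.groupby(class_col)
        }
    s_col = "s_norm" if "s_norm" in merged.columns else None
    if s_col:
        pos_means = merged.groupby(on).agg({s_col: "mean", feature_col: "mean"}).dropna()
        if len(pos_means) >= 3 and pos_means[feature_col].nunique() > 1:
            r, p = pearsonr(pos_means[s_col], pos_means[feature_col])
            out["pearson"] = {"r": float(r), "r2": float(r) ** 2, "p": float(p)}
    return out


def read_annotation_tsv(path) -> pd.DataFrame:
    """Per-position structural/conservation annotations (computed externally)."""
    df = pd.read_csv(path, sep="\t")
    if "position" not in df.columns:
        raise ValueError("annotation table needs a 'position' column")
    if "sasa" in df.columns and (df["sasa"].dropna() < 0).any():
        raise ValueError("SASA must be non-negative")
    if "dist_atp" in df.columns and (df["dist_atp"].dropna() <= 0).any():
        raise ValueError("distances must be positive")
    return df
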