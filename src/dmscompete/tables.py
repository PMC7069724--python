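"""Shared containers: per-variant count tables and sequencing sample sheets.

A :class:`CountTable` holds read counts for every library variant (rows) at every
competition timepoint (columns) for one condition, at codon resolution.  The
amino-acid level table used for most downstream analyses is a view obtained by
summing synonymous codons (:meth:`CountTable.to_aa`).
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

#: Sentinel codon string for the unmutated wild-type (reference) lineage.
WT_CODON = "WT"

VARIANT_COLUMNS = [
    "position",
    "wt_codon",
    "codon",
    "aa",
    "wt_aa",
    "is_stop",
    "is_wt_synonym",
    "is_reference",
]


def variant_key(df: pd.DataFrame) -> pd.Index:
    """(position, codon) identity used to join tables from different stages."""
    return pd.MultiIndex.from_arrays([df["position"], df["codon"]])


@dataclass
class CountTable:
    """Variant x timepoint read counts for one condition.

    Parameters
    ----------
    variants : DataFrame with the columns in ``VARIANT_COLUMNS``.
    counts : integer array of shape (n_variants, n_timepoints).
    times : sampling times in wild-type generations, strictly increasing from 0.
    times_h : optional wall-clock sampling times in hours (same length).
    condition : label of the environment (e.g. ``"standard"``, ``"37C"``).
    """

    variants: pd.DataFrame
    counts: np.ndarray
    times: np.ndarray
    times_h: np.ndarray | None = None
    condition: str = "standard"
    replicate: int = 1
    discarded_barcode_reads: int = 0

    def __post_init__(self) -> None:
        self.variants = self.variants.reset_index(drop=True)
        self.counts = np.asarray(self.counts)
        self.times = np.asarray(self.times, dtype=float)
        if self.counts.ndim != 2:
            raise ValueError("counts must be 2-D (variants x timepoints)")
        if self.counts.shape != (len(self.variants), len(self.times)):
            raise ValueError(
                f"counts shape {self.counts.shape} does not match "
                f"{len(self.variants)} variants x {len(self.times)} timepoints"
            )
        if (self.counts < 0).any():
            raise ValueError("counts must be non-negative")
        if len(self.times) and (np.diff(self.times) <= 0).any():
            raise ValueError("times must be strictly increasing")

    @property
    def depths(self) -> np.ndarray:
        """Total reads per timepoint (sum over counted variants)."""
        return self.counts.sum(axis=0)

    @property
    def n_variants(self) -> int:
        return len(self.variants)

    @property
    def reference_index(self) -> int | None:
        idx = np.flatnonzero(self.variants["is_reference"].to_numpy())
        return int(idx[0]) if len(idx) else None

    def to_aa(self) -> "CountTable":
        """Collapse synonymous codons: counts summed over codons per (position, aa).

        The reference lineage stays its own row; a wild-type synonym keeps
        ``is_wt_synonym`` so anchor sets survive the aggregation.
        """
        v = self.variants.copy()
        v["_grp"] = list(
            zip(v["position"], v["aa"].where(~v["is_reference"], WT_CODON), v["is_reference"])
        )
        order: list[tuple] = []
        rows = []
        counts = []
        for key, sub in v.groupby("_grp", sort=False):
            idx = sub.index
            first = sub.iloc[0]
            rows.append(
                {
                    "position": first["position"],
                    "wt_codon": first["wt_codon"],
                    "codon": WT_CODON if first["is_reference"] else str(first["aa"]),
                    "aa": first["aa"],
                    "wt_aa": first["wt_aa"],
                    "is_stop": bool(first["is_stop"]),
                    "is_wt_synonym": bool(first["is_wt_synonym"]),
                    "is_reference": bool(first["is_reference"]),
                }
            )
            counts.append(self.counts[np.asarray(idx)].sum(axis=0))
            order.append(key)
        return CountTable(
            variants=pd.DataFrame(rows).reset_index(drop=True),
            counts=np.asarray(counts),
            times=self.times,
            times_h=self.times_h,
            condition=self.condition,
            replicate=self.replicate,
            discarded_barcode_reads=self.discarded_barcode_reads,
        )

    def to_tsv(self, path) -> None:
        """Write the long-format table (one row per variant/timepoint)."""
        long = self.to_long()
        long.to_csv(path, sep="\t", index=False)

    def to_long(self) -> pd.DataFrame:
        recs = []
        times_h = self.times_h if self.times_h is not None else self.times
        for j, (t, th) in enumerate(zip(self.times, times_h)):
            for i, row in self.variants.iterrows():
                recs.append(
                    {
                        "condition": self.condition,
                        "replicate": self.replicate,
                        "time_gen": t,
                        "time_h": th,
                        "position": row["position"],
                        "wt_codon": row["wt_codon"],
                        "codon": row["codon"],
                        "aa": row["aa"],
                        "count": int(self.counts[i, j]),
                    }
                )
        return pd.DataFrame(recs)

    @classmethod
    def from_tsv(cls, path) -> "CountTable":
        long = pd.read_csv(path, sep="\t")
        return cls.from_long(long)

    @classmethod
    def from_long(cls, long: pd.DataFrame) -> "CountTable":
        times = np.sort(long["time_gen"].unique())
        wide = long.pivot_table(
            index=["position", "wt_codon", "codon", "aa"],
            columns="time_gen",
            values="count",
            aggfunc="sum",
            fill_value=0,
        ).sort_index()
        variants = wide.index.to_frame(index=False)
        variants["is_reference"] = variants["codon"] == WT_CODON
        variants["is_stop"] = variants["aa"] == "*"
        variants["wt_aa"] = [
            _safe_translate(c) for c in variants["wt_codon"]
        ]
        variants["is_wt_synonym"] = (
            (variants["aa"] == variants["wt_aa"]) & ~variants["is_reference"]
        )
        th = None
        if "time_h" in long.columns:
            th = (
                long.drop_duplicates("time_gen").sort_values("time_gen")["time_h"].to_numpy()
            )
        condition = str(long["condition"].iloc[0]) if "condition" in long.columns else "standard"
        replicate = int(long["replicate"].iloc[0]) if "replicate" in long.columns else 1
        return cls(
            variants=variants[VARIANT_COLUMNS].reset_index(drop=True),
            counts=wide.to_numpy(),
            times=times,
            times_h=th,
            condition=condition,
            replicate=replicate,
        )


def _safe_translate(codon: str) -> str:
    from .orf import translate_codon

    try:
        return translate_codon(codon)
    except ValueError:
        return ""


@dataclass
class SampleSheet:
    """Maps 8-mer identifier sequences to (condition, timepoint, replicate) samples."""

    rows: pd.DataFrame = field(default_factory=pd.DataFrame)

    def __post_init__(self) -> None:
        required = {"identifier", "condition", "time_h", "replicate"}
        missing = required - set(self.rows.columns)
        if missing:
            raise ValueError(f"sample sheet missing columns: {sorted(missing)}")
        ids = self.rows["identifier"]
        if ids.duplicated().any():
            dup = ids[ids.duplicated()].iloc[0]
            raise ValueError(f"identifier collision across samples: {dup}")
        if (ids.str.len() != 8).any():
            raise ValueError("identifiers must be 8-mers")
        for cond, sub in self.rows.groupby("condition"):
            if not (sub["time_h"] == 0).any():
                raise ValueError(f"condition {cond!r} has no timepoint 0")

    @property
    def identifier_to_sample(self) -> dict[str, tuple]:
        return {
            r.identifier: (r.condition, float(r.time_h), int(r.replicate))
            for r in self.rows.itertuples()
        }

    def to_tsv(self, path) -> None:
        self.rows.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "SampleSheet":
        return cls(pd.read_csv(path, sep="\t", dtype={"identifier": str}))


def make_sample_sheet(
    conditions: list[str], times_h, replicate: int = 1, seed: int = 0
) -> SampleSheet:
    """Deterministically assign distinct 8-mer identifiers to each sample."""
    rng = np.random.default_rng(seed)
    n = len(conditions) * len(times_h)
    seen: set[str] = set()
    idents: list[str] = []
    while len(idents) < n:
        ident = "".join("ACGT"[b] for b in rng.integers(0, 4, size=8))
        if ident not in seen:
            seen.add(ident)
            idents.append(ident)
    rows = [
        {
            "identifier": idents[k],
            "condition": cond,
            "time_h": float(t),
            "replicate": replicate,
        }
        for k, (cond, t) in enumerate(itertools.product(conditions, times_h))
    ]
    return SampleSheet(pd.DataFrame(rows))
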