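"""Fitness classes for variants and positions, within and across conditions.

Per condition, variants are binned against the empirical distributions of the
two anchor classes: wild-type-like (within k SD of the wild-type-synonym
mean), beneficial (above that band), strongly deleterious (within k SD of the
stop-codon mean), intermediate (between the bands); k = 2 by default.
Temperature-sensitive (ts) variants are wild-type-like under standard
conditions but null-like under heat stress, operationalized by two explicit
cutoffs on the selection coefficient.  Position-level categories (critical /
environmentally responsive / tolerant) summarize the mean non-stop selection
coefficient per position across environments.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass

import numpy as np
import pandas as pd

WT_LIKE = "wild_type_like"
BENEFICIAL = "beneficial"
DELETERIOUS = "strongly_deleterious"
INTERMEDIATE = "intermediate"

#: reference cutoffs for the heat-stress ts screen: the lower limit of
#: wild-type synonyms under standard conditions and the upper limit of stops
#: at 37C
TS_STANDARD_FLOOR = -0.11
TS_STRESS_CEILING = -0.47


@dataclass
class ClassThresholds:
    """Anchor-distribution parameters driving the classification bands."""

    wt_mean: float
    wt_sd: float
    stop_mean: float
    stop_sd: float
    k_sd: float = 2.0
    ts_standard_floor: float = TS_STANDARD_FLOOR
    ts_stress_ceiling: float = TS_STRESS_CEILING

    def __post_init__(self) -> None:
        if self.wt_mean <= self.stop_mean:
            raise ValueError("wild-type anchor mean must exceed stop anchor mean")

    @classmethod
    def from_anchors(cls, anchors, s_norm: np.ndarray, **kw) -> "ClassThresholds":
        """Thresholds on the normalized scale from an AnchorSets object."""
        s = np.asarray(s_norm, dtype=float)
        wt = s[anchors.wt_index]
        stop = s[anchors.stop_index]
        return cls(
            wt_mean=float(wt.mean()),
            wt_sd=float(wt.std(ddof=1)) if len(wt) > 1 else 0.0,
            stop_mean=float(stop.mean()),
            stop_sd=float(stop.std(ddof=1)) if len(stop) > 1 else 0.0,
            **kw,
        )

    @property
    def wt_low(self) -> float:
        return self.wt_mean - self.k_sd * self.wt_sd

    @property
    def wt_high(self) -> float:
        return self.wt_mean + self.k_sd * self.wt_sd

    @property
    def stop_high(self) -> float:
        return self.stop_mean + self.k_sd * self.stop_sd

    @property
    def stop_low(self) -> float:
        return self.stop_mean - self.k_sd * self.stop_sd


def classify_variants(s: np.ndarray, thresholds: ClassThresholds) -> np.ndarray:
    """Label each selection coefficient; every variant gets exactly one label.

    Precedence when the anchor bands overlap: strongly deleterious, then
    beneficial, then wild-type-like, then intermediate.
    """
    th = thresholds
    if th.wt_low < th.stop_high:
        import warnings

        warnings.warn(
            "wild-type and stop bands overlap; precedence rule applied",
            RuntimeWarning,
            stacklevel=2,
        )
    s = np.asarray(s, dtype=float)
    labels = np.full(len(s), INTERMEDIATE, dtype=object)
    in_stop = np.abs(s - th.stop_mean) <= th.k_sd * th.stop_sd
    above_wt = s > th.wt_high
    in_wt = np.abs(s - th.wt_mean) <= th.k_sd * th.wt_sd
    # later assignments win: deleterious > beneficial > wild-type-like
    labels[in_wt] = WT_LIKE
    labels[above_wt] = BENEFICIAL
    labels[in_stop] = DELETERIOUS
    return labels


def classify_table(
    selection: pd.DataFrame, thresholds: ClassThresholds, s_col: str = "s_norm"
) -> pd.DataFrame:
    """Attach a ``fitness_class`` column (reference rows excluded from classes)."""
    out = selection.copy()
    out["fitness_class"] = classify_variants(out[s_col].to_numpy(), thresholds)
    return out


def identify_ts(
    standard: pd.DataFrame,
    stress: pd.DataFrame,
    thresholds: ClassThresholds | None = None,
    s_col: str = "s_norm",
    keys: tuple = ("position", "aa"),
) -> tuple[pd.DataFrame, dict]:
    """Temperature-sensitive screen across two conditions.

    A variant is ts when its standard-condition coefficient is at or above
    the wild-type floor and its stress-condition coefficient at or below the
    stop ceiling.  Stops are excluded; variants missing from either condition
    are excluded and tallied.
    """
    floor = thresholds.ts_standard_floor if thresholds else TS_STANDARD_FLOOR
    ceiling = thresholds.ts_stress_ceiling if thresholds else TS_STRESS_CEILING
    a = standard[~standard["is_stop"] & ~standard["is_reference"]]
    b = stress[~stress["is_stop"] & ~stress["is_reference"]]
    merged = a.merge(
        b[list(keys) + [s_col]], on=list(keys), suffixes=("_standard", "_stress")
    )
    sa = merged[f"{s_col}_standard"].to_numpy()
    sb = merged[f"{s_col}_stress"].to_numpy()
    is_ts = (sa >= floor) & (sb <= ceiling)
    tally = {
        "standard_only": len(a) - len(merged),
        "stress_only": len(b) - len(merged),
        "evaluated": len(merged),
        "ts": int(is_ts.sum()),
    }
    return merged.loc[is_ts].reset_index(drop=True), tally


def summarize_positions(
    tables: dict,
    thresholds: dict,
    standard: str = "standard",
    s_col: str = "s_norm",
    min_shifted_conditions: int = 3,
) -> pd.DataFrame:
    """Position categories across environments.

    Position mean = mean selection coefficient of all mutations at the
    position, excluding stop codons.  Critical: null-like (within k SD of the
    stop mean) in every environment.  Environmentally responsive: mean
    differs from standard by more than one wild-type-synonym SD (standard
    condition) in at least `min_shifted_conditions` stress environments.
    Tolerant: shifted in none.
    """
    if standard not in tables:
        raise ValueError(f"no table for the standard condition {standard!r}")
    means = {}
    for cond, tab in tables.items():
        sub = tab[~tab["is_stop"] & ~tab["is_reference"] & ~tab["is_wt_synonym"]]
        means[cond] = sub.groupby("position")[s_col].mean()
    df = pd.DataFrame(means).dropna()
    stress_conditions = [c for c in tables if c != standard]
    wt_sd = thresholds[standard].wt_sd
    rows = []
    for pos, row in df.iterrows():
        deltas = {c: row[c] - row[standard] for c in stress_conditions}
        n_shifted = sum(abs(d) > wt_sd for d in deltas.values())
        critical = all(
            abs(row[c] - thresholds[c].stop_mean) <= thresholds[c].k_sd * thresholds[c].stop_sd
            for c in tables
        )
        if critical:
            cat = "critical"
        elif n_shifted >= min_shifted_conditions:
            cat = "environmentally_responsive"
        elif n_shifted == 0:
            cat = "tolerant"
        else:
            cat = "other"
        rec = {"position": pos, "category": cat, "n_shifted": n_shifted}
        rec.update({f"mean_{c}": row[c] for c in tables})
        rec.update({f"delta_{c}": deltas[c] for c in stress_conditions})
        rows.append(rec)
    return pd.DataFrame(rows)


def condition_sets(
    classified: dict,
    standard: str = "standard",
    s_col: str = "s_norm",
    keys: tuple = ("position", "aa"),
    deleterious_labels: tuple = (INTERMEDIATE, DELETERIOUS),
) -> dict:
    """Cross-condition overlap of deleterious variants plus mean shifts.

    Deleterious here means below the wild-type-like band (intermediate or
    strongly deleterious).  Returns per-condition counts, per-condition
    exclusive counts, all k-way intersection counts, and each condition's
    mean selection coefficient over all mutations minus the standard one.
    """
    sets = {}
    for cond, tab in classified.items():
        sub = tab[~tab["is_reference"] & ~tab["is_stop"] & ~tab["is_wt_synonym"]]
        dele = sub[sub["fitness_class"].isin(deleterious_labels)]
        sets[cond] = set(map(tuple, dele[list(keys)].to_numpy()))
    conds = list(classified)
    counts = {c: len(sets[c]) for c in conds}
    exclusive = {
        c: len(sets[c] - set().union(*(sets[o] for o in conds if o != c)))
        if len(conds) > 1
        else len(sets[c])
        for c in conds
    }
    intersections = {}
    for k in range(2, len(conds) + 1):
        for combo in itertools.combinations(conds, k):
            intersections["&".join(combo)] = len(
                set.intersection(*(sets[c] for c in combo))
            )
    shifts = {}
    if standard in classified:
        base = classified[standard]
        base_mean = base.loc[
            ~base["is_reference"] & ~base["is_wt_synonym"], s_col
        ].mean()
        for cond, tab in classified.items():
            m = tab.loc[~tab["is_reference"] & ~tab["is_wt_synonym"], s_col].mean()
            shifts[cond] = float(m - base_mean)
    return {
        "deleterious_counts": counts,
        "exclusive_counts": exclusive,
        "intersections": intersections,
        "mean_shift_vs_standard": shifts,
    }
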