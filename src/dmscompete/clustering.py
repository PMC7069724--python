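"""Positional clustering of a mutation class versus a random-placement null.

Observed data are summarized as a histogram of positions by mutation count.
The null places the same number of mutations uniformly at random over the
positions (respecting the cap of 19 distinct amino-acid changes per
position), 1000 times by default, and the per-bin mean and SD of the
simulated histograms give one-tailed z-score p-values for enrichment.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import norm

DEFAULT_N_SIM = 1000
DEFAULT_CAP = 19  # distinct amino-acid changes possible at one position


def observed_histogram(positions) -> dict:
    """{mutation count b: number of positions carrying exactly b mutations}."""
    per_pos = Counter(positions)
    return dict(sorted(Counter(per_pos.values()).items()))


@dataclass
class ClusteringNull:
    bins: np.ndarray  # mutation-count bins 1..max observed in any draw
    mean: np.ndarray
    sd: np.ndarray
    n_sim: int
    seed: int
    n_mutations: int
    draws: np.ndarray = field(repr=False, default=None)  # (n_sim, len(bins))


def null_distribution(
    n_mutations: int,
    positions,
    max_per_position: int = DEFAULT_CAP,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> ClusteringNull:
    """Random-placement null for the per-position count histogram.

    `positions` is the candidate position list (or an integer count).  Each
    simulation drops `n_mutations` mutations uniformly over the positions;
    a draw landing on a position already holding `max_per_position`
    mutations is re-drawn (observed data cannot exceed the cap either).
    """
    n_pos = positions if isinstance(positions, (int, np.integer)) else len(list(positions))
    if n_pos <= 0:
        raise ValueError("need at least one position")
    if n_mutations > n_pos * max_per_position:
        raise ValueError(
            f"cannot place {n_mutations} mutations on {n_pos} positions "
            f"with at most {max_per_position} each"
        )
    rng = np.random.default_rng(seed)
    max_bin = min(n_mutations, max_per_position)
    tallies = np.zeros((n_sim, max_bin + 1), dtype=np.int64)
    for s in range(n_sim):
        load = np.zeros(n_pos, dtype=np.int64)
        for _ in range(n_mutations):
            p = int(rng.integers(0, n_pos))
            while load[p] >= max_per_position:
                p = int(rng.integers(0, n_pos))
            load[p] += 1
        binc = np.bincount(load[load > 0], minlength=max_bin + 1)
        tallies[s, : len(binc)] = binc[: max_bin + 1]
    draws = tallies[:, 1:]  # drop the 0-mutation bin
    return ClusteringNull(
        bins=np.arange(1, max_bin + 1),
        mean=draws.mean(axis=0),
        sd=draws.std(axis=0, ddof=1),
        n_sim=n_sim,
        seed=seed,
        n_mutations=n_mutations,
        draws=draws,
    )


def clustering_pvalues(observed: dict, null: ClusteringNull) -> pd.DataFrame:
    """One-tailed enrichment p per bin from (observed - mean) / sd z-scores.

    Bins where the null never varied (sd = 0) but the observation exceeds the
    mean are reported at the simulation resolution, p = 1 / n_sim.
    """
    rows = []
    for b, mean, sd in zip(null.bins, null.mean, null.sd):
        obs = observed.get(int(b), 0)
        if sd > 0:
            z = (obs - mean) / sd
            p = float(norm.sf(z))
        else:
            z = np.inf if obs > mean else (0.0 if obs == mean else -np.inf)
            p = 1.0 / null.n_sim if obs > mean else (0.5 if obs == mean else 1.0)
        rows.append(
            {"bin": int(b), "observed": obs, "null_mean": mean, "null_sd": sd, "z": z, "p": p}
        )
    # observed bins beyond anything the null produced are maximally surprising
    top = int(null.bins[-1]) if len(null.bins) else 0
    for b, obs in observed.items():
        if b > top:
            rows.append(
                {
                    "bin": int(b),
                    "observed": obs,
                    "null_mean": 0.0,
                    "null_sd": 0.0,
                    "z": np.inf,
                    "p": 1.0 / null.n_sim,
                }
            )
    return pd.DataFrame(rows).sort_values("bin").reset_index(drop=True)


def cluster_test(
    positions,
    candidate_positions,
    max_per_position: int = DEFAULT_CAP,
    n_sim: int = DEFAULT_N_SIM,
    seed: int = 0,
) -> pd.DataFrame:
    """Observed histogram + null + p-values in one call."""
    obs = observed_histogram(positions)
    null = null_distribution(
        len(list(positions)), candidate_positions, max_per_position, n_sim, seed
    )
    return clustering_pvalues(obs, null)
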