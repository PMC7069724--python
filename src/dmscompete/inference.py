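"""Selection-coefficient inference for bulk competitions.

The generative model: lineage i grows exponentially at rate r_i from initial
size n_i(0), and sequencing draws reads multinomially at each timepoint with
probabilities

    p_i(t) = n_i exp(r_i t) / sum_j n_j exp(r_j t).

:class:`SelectionModel` fits all (r_i, log n_i) jointly by Metropolis-Hastings
with the wild-type reference pinned (r = 1, log n = 0 in wild-type-generation
units), which resolves the likelihood's invariance to a common shift of all
rates and a common rescaling of all sizes.  Priors are improper flat on r and
on log n0.  By default 10,000 post-burn-in samples are retained and the point
estimate is the median of 1,000 thinned samples (every 10th).

Raw selection coefficients s = median(r) - 1 are then anchor-scaled so the
wild-type-synonym mean maps to 0 and the stop-codon mean to -1:

    s_norm = (s_raw - mean_wt) / (mean_wt - mean_stop).

The scaling is invariant to any affine transform of raw s, so the arbitrary
time-unit convention cannot affect normalized results.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from numba import njit
from scipy.special import gammaln
from scipy.stats import linregress

from .tables import CountTable

DEFAULT_STOP_ANCHOR_MAX_POS = 677  # stops beyond this are in the dispensable tail


def log_likelihood(
    counts: np.ndarray, times: np.ndarray, r: np.ndarray, log_n0: np.ndarray
) -> float:
    """Multinomial log-likelihood of a count table under exponential growth.

    Includes the multinomial coefficient, so a single timepoint with two
    indistinguishable variants and counts (1, 1) gives log(1/2).
    """
    counts = np.asarray(counts, dtype=float)
    if (counts < 0).any():
        raise ValueError("negative counts")
    times = np.asarray(times, dtype=float)
    r = np.asarray(r, dtype=float)
    log_n0 = np.asarray(log_n0, dtype=float)
    lw = log_n0[:, None] + r[:, None] * times[None, :]
    lw = lw - lw.max(axis=0, keepdims=True)
    logz = np.log(np.exp(lw).sum(axis=0))
    logp = lw - logz
    depths = counts.sum(axis=0)
    ll = gammaln(depths + 1).sum() - gammaln(counts + 1).sum()
    with np.errstate(invalid="ignore"):
        terms = np.where(counts > 0, counts * logp, 0.0)
    return float(ll + terms.sum())


@njit(cache=True)
def _mh_kernel(
    counts,
    depths,
    tc,
    r,
    ln0,
    ref,
    n_burn,
    n_samples,
    adapt_interval,
    seed,
):  # pragma: no cover - exercised via SelectionModel.fit
    np.random.seed(seed)
    V, T = counts.shape
    W = np.empty((V, T))
    Z = np.zeros(T)
    for t in range(T):
        z = 0.0
        for i in range(V):
            W[i, t] = np.exp(ln0[i] + (r[i] - 1.0) * tc[t])
            z += W[i, t]
        Z[t] = z
    step_r = np.full(V, 0.05)
    step_n = np.full(V, 0.1)
    acc_r = np.zeros(V)
    acc_n = np.zeros(V)
    out = np.empty((n_samples, V))
    target = 0.25
    total = n_burn + n_samples
    for sweep in range(total):
        for i in range(V):
            if i == ref:
                continue
            # --- rate update ---
            rn = r[i] + step_r[i] * np.random.normal()
            dll = 0.0
            ok = True
            for t in range(T):
                lw_new = ln0[i] + (rn - 1.0) * tc[t]
                if lw_new > 60.0:
                    ok = False
                    break
                w_new = np.exp(lw_new)
                lw_old = ln0[i] + (r[i] - 1.0) * tc[t]
                zn = Z[t] - W[i, t] + w_new
                dll += counts[i, t] * (lw_new - lw_old) - depths[t] * (
                    np.log(zn) - np.log(Z[t])
                )
            if ok and np.log(np.random.random()) < dll:
                for t in range(T):
                    w_new = np.exp(ln0[i] + (rn - 1.0) * tc[t])
                    Z[t] += w_new - W[i, t]
                    W[i, t] = w_new
                r[i] = rn
                acc_r[i] += 1.0
            # --- log-size update ---
            ln_new = ln0[i] + step_n[i] * np.random.normal()
            if ln_new <= 60.0:
                dll = 0.0
                dl = ln_new - ln0[i]
                f = np.exp(dl)
                csum = 0.0
                for t in range(T):
                    w_new = W[i, t] * f
                    zn = Z[t] - W[i, t] + w_new
                    dll += counts[i, t] * dl - depths[t] * (np.log(zn) - np.log(Z[t]))
                if np.log(np.random.random()) < dll:
                    for t in range(T):
                        w_new = W[i, t] * f
                        Z[t] += w_new - W[i, t]
                        W[i, t] = w_new
                    ln0[i] = ln_new
                    acc_n[i] += 1.0
        if sweep < n_burn and (sweep + 1) % adapt_interval == 0:
            for i in range(V):
                fr = np.exp((acc_r[i] / adapt_interval - target))
                fn = np.exp((acc_n[i] / adapt_interval - target))
                step_r[i] = min(max(step_r[i] * fr, 1e-4), 10.0)
                step_n[i] = min(max(step_n[i] * fn, 1e-4), 10.0)
                acc_r[i] = 0.0
                acc_n[i] = 0.0
        if sweep == n_burn - 1:
            for i in range(V):
                acc_r[i] = 0.0
                acc_n[i] = 0.0
        if sweep >= n_burn:
            for i in range(V):
                out[sweep - n_burn, i] = r[i]
        if (sweep + 1) % 1000 == 0:  # refresh Z against float drift
            for t in range(T):
                z = 0.0
                for i in range(V):
                    z += W[i, t]
                Z[t] = z
    return out, acc_r / max(n_samples, 1), acc_n / max(n_samples, 1)


def _regression_init(counts: np.ndarray, times: np.ndarray, ref: int):
    """Log-linear regression of each lineage against the reference.

    Slope + 1 initializes r; the intercept at the mean timepoint initializes
    the centered log-size.
    """
    tc = times - times.mean()
    c = counts.astype(float) + 0.5
    y = np.log(c / c[ref])
    tbar = tc
    denom = (tbar**2).sum()
    slope = (y * tbar).sum(axis=1) / denom
    intercept = y.mean(axis=1)
    return 1.0 + slope, intercept


@dataclass
class AnchorSets:
    """Neutral and null anchor classes used to scale selection coefficients."""

    wt_index: np.ndarray
    stop_index: np.ndarray
    mean_wt: float
    sd_wt: float
    mean_stop: float
    sd_stop: float

    @classmethod
    def from_table(
        cls,
        variants: pd.DataFrame,
        s_raw: np.ndarray,
        stop_anchor_max_pos: int = DEFAULT_STOP_ANCHOR_MAX_POS,
        position_mask: tuple | None = None,
    ) -> "AnchorSets":
        """Build anchors from variant flags.

        Stops beyond `stop_anchor_max_pos` are excluded (dispensable
        C-terminal tail behaves neutrally).  `position_mask=(lo, hi)`
        restricts both anchor sets to that inclusive position window, for
        conditions where one anchor class misbehaves in part of the gene.
        """
        pos = variants["position"].to_numpy()
        wt = variants["is_wt_synonym"].to_numpy(dtype=bool)
        stop = variants["is_stop"].to_numpy(dtype=bool) & (pos <= stop_anchor_max_pos)
        if position_mask is not None:
            lo, hi = position_mask
            in_win = (pos >= lo) & (pos <= hi)
            wt = wt & in_win
            stop = stop & in_win
        wt_idx = np.flatnonzero(wt)
        stop_idx = np.flatnonzero(stop)
        if len(wt_idx) == 0 or len(stop_idx) == 0:
            raise ValueError("anchor sets must be nonempty (wild-type synonyms and stops)")
        s_raw = np.asarray(s_raw, dtype=float)
        return cls(
            wt_index=wt_idx,
            stop_index=stop_idx,
            mean_wt=float(s_raw[wt_idx].mean()),
            sd_wt=float(s_raw[wt_idx].std(ddof=1)) if len(wt_idx) > 1 else 0.0,
            mean_stop=float(s_raw[stop_idx].mean()),
            sd_stop=float(s_raw[stop_idx].std(ddof=1)) if len(stop_idx) > 1 else 0.0,
        )


def normalize_selection(s_raw: np.ndarray, anchors: AnchorSets) -> np.ndarray:
    """Affine rescaling sending the wild-type anchor mean to 0, stop mean to -1."""
    span = anchors.mean_wt - anchors.mean_stop
    if span == 0:
        raise ValueError("wild-type and stop anchor means coincide: no selection signal")
    return (np.asarray(s_raw, dtype=float) - anchors.mean_wt) / span


def summarize_posterior(samples: np.ndarray, thin: int = 10) -> pd.DataFrame:
    """Median and central 95% interval per variant from thinned samples."""
    if samples.size == 0:
        raise ValueError("no posterior samples")
    thinned = samples[::thin]
    return pd.DataFrame(
        {
            "r_median": np.median(thinned, axis=0),
            "r_ci_low": np.quantile(thinned, 0.025, axis=0),
            "r_ci_high": np.quantile(thinned, 0.975, axis=0),
            "n_thinned": len(thinned),
        }
    )


def _split_rhat(samples: np.ndarray) -> np.ndarray:
    n = (len(samples) // 2) * 2
    if n < 4:
        return np.full(samples.shape[1], np.nan)
    half = n // 2
    chains = np.stack([samples[:half], samples[half:n]])  # (2, half, V)
    w = chains.var(axis=1, ddof=1).mean(axis=0)
    b = half * chains.mean(axis=1).var(axis=0, ddof=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        var_hat = (half - 1) / half * w + b / half
        return np.sqrt(var_hat / w)


class SelectionModel:
    """Exponential-growth/multinomial model for one condition's count table.

    Parameters
    ----------
    table : CountTable with a reference (unmutated wild-type) row.
    reference : optional row index of the reference lineage; defaults to the
        row flagged ``is_reference``.
    """

    def __init__(self, table: CountTable, reference: int | None = None):
        if len(table.times) < 2:
            raise ValueError("need at least two timepoints")
        self.table = table
        ref = reference if reference is not None else table.reference_index
        if ref is None:
            raise ValueError("no wild-type reference row in the table")
        self.reference = int(ref)

    def loglike(self, r: np.ndarray, log_n0: np.ndarray) -> float:
        return log_likelihood(self.table.counts, self.table.times, r, log_n0)

    def fit(
        self,
        samples: int = 10_000,
        burn_frac: float = 0.1,
        thin: int = 10,
        seed: int = 0,
        adapt_interval: int = 50,
        rhat_threshold: float = 1.2,
    ) -> "SelectionResults":
        """Run the Metropolis-Hastings sampler and summarize the posterior.

        `samples` sweeps are retained after a burn-in of `burn_frac` of the
        total; proposal scales adapt during burn-in toward ~25% acceptance.
        """
        counts = self.table.counts.astype(np.float64)
        times = self.table.times.astype(np.float64)
        tc = times - times.mean()
        depths = counts.sum(axis=0)
        r0, ln0 = _regression_init(self.table.counts, times, self.reference)
        # express pinning in centered coordinates relative to the reference
        r0[self.reference] = 1.0
        ln0 = ln0 - ln0[self.reference]
        ln0[self.reference] = 0.0
        n_burn = int(round(samples * burn_frac / (1.0 - burn_frac)))
        chain, acc_r, acc_n = _mh_kernel(
            counts,
            depths,
            tc,
            r0.copy(),
            ln0.copy(),
            self.reference,
            n_burn,
            samples,
            adapt_interval,
            int(seed) % (2**31 - 1),
        )
        rhat = _split_rhat(chain)
        bad = np.flatnonzero(np.nan_to_num(rhat, nan=1.0) > rhat_threshold)
        bad = bad[bad != self.reference]
        if len(bad):
            warnings.warn(
                f"split-chain diagnostic above {rhat_threshold} for "
                f"{len(bad)} variants; consider more iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        return SelectionResults(
            model=self,
            samples_r=chain,
            thin=thin,
            acceptance_r=acc_r,
            acceptance_n=acc_n,
            rhat=rhat,
        )


class SelectionResults:
    """Posterior summaries and anchor-scaled selection coefficients."""

    def __init__(self, model, samples_r, thin, acceptance_r, acceptance_n, rhat):
        self.model = model
        self.samples_r = samples_r
        self.thin = thin
        self.acceptance_r = acceptance_r
        self.acceptance_n = acceptance_n
        self.rhat = rhat
        summ = summarize_posterior(samples_r, thin=thin)
        params = model.table.variants.copy()
        params[["r_median", "r_ci_low", "r_ci_high", "n_thinned"]] = summ[
            ["r_median", "r_ci_low", "r_ci_high", "n_thinned"]
        ].to_numpy()
        params["s_raw"] = params["r_median"] - 1.0
        params["acceptance_r"] = acceptance_r
        params["rhat"] = rhat
        self.params = params
        self.anchors: AnchorSets | None = None

    @property
    def condition(self) -> str:
        return self.model.table.condition

    def normalize(
        self,
        stop_anchor_max_pos: int = DEFAULT_STOP_ANCHOR_MAX_POS,
        position_mask: tuple | None = None,
    ) -> pd.DataFrame:
        """Anchor-scale raw s; returns the per-variant selection table.

        Adds ``s_norm`` plus scaled credible bounds to :attr:`params`.
        """
        anchors = AnchorSets.from_table(
            self.params, self.params["s_raw"].to_numpy(), stop_anchor_max_pos, position_mask
        )
        self.anchors = anchors
        span = anchors.mean_wt - anchors.mean_stop
        self.params["s_norm"] = normalize_selection(self.params["s_raw"].to_numpy(), anchors)
        self.params["s_norm_ci_low"] = (
            self.params["r_ci_low"] - 1.0 - anchors.mean_wt
        ) / span
        self.params["s_norm_ci_high"] = (
            self.params["r_ci_high"] - 1.0 - anchors.mean_wt
        ) / span
        return self.selection_table()

    def selection_table(self) -> pd.DataFrame:
        cols = [
            "position",
            "wt_codon",
            "codon",
            "aa",
            "is_stop",
            "is_wt_synonym",
            "is_reference",
            "s_raw",
        ]
        if "s_norm" in self.params:
            cols += ["s_norm", "s_norm_ci_low", "s_norm_ci_high"]
        out = self.params[cols].copy()
        out.insert(0, "condition", self.condition)
        out.insert(1, "replicate", self.model.table.replicate)
        return out

    def summary(self) -> str:
        p = self.params
        lines = [
            "Selection inference (exponential growth / multinomial sampling, MH)",
            "=" * 68,
            f"condition: {self.condition}   variants: {len(p)}   "
            f"timepoints: {len(self.model.table.times)}",
            f"posterior samples: {len(self.samples_r)} (thin {self.thin} -> "
            f"{len(self.samples_r[:: self.thin])} for summaries)",
            f"median acceptance (r): {np.median(self.acceptance_r[self.acceptance_r > 0]):.2f}",
        ]
        if self.anchors is not None:
            a = self.anchors
            lines += [
                f"anchors: {len(a.wt_index)} wild-type synonyms "
                f"(mean s_raw {a.mean_wt:+.4f}), {len(a.stop_index)} stops "
                f"(mean s_raw {a.mean_stop:+.4f})",
                f"normalized: wt-synonym mean {p['s_norm'].to_numpy()[a.wt_index].mean():+.3f}, "
                f"stop mean {p['s_norm'].to_numpy()[a.stop_index].mean():+.3f}",
            ]
        lines.append("-" * 68)
        show = p[~p["is_reference"]].head(8)
        cols = ["position", "codon", "aa", "s_raw"] + (
            ["s_norm"] if "s_norm" in p else []
        )
        lines.append(show[cols].to_string(index=False, float_format=lambda x: f"{x:+.3f}"))
        return "\n".join(lines)

    def plot_dfe(self, ax=None, bins: int = 60):
        """Histogram of normalized selection coefficients (the DFE)."""
        import matplotlib.pyplot as plt

        if "s_norm" not in self.params:
            raise ValueError("call normalize() first")
        if ax is None:
            _, ax = plt.subplots()
        sel = self.params[~self.params["is_reference"]]
        ax.hist(sel["s_norm"], bins=bins, color="steelblue")
        ax.set_xlabel("selection coefficient (anchor-scaled)")
        ax.set_ylabel("variants")
        ax.set_title(f"DFE, {self.condition}")
        return ax


def fit_exponential_growth(times, densities, min_points: int = 4):
    """Exponential growth rate from a culture density time series.

    Least-squares fit of log-density against time; returns (rate, stderr).
    """
    times = np.asarray(times, dtype=float)
    densities = np.asarray(densities, dtype=float)
    if len(times) < min_points:
        raise ValueError(f"need at least {min_points} timepoints")
    if (densities <= 0).any():
        raise ValueError("densities must be positive")
    res = linregress(times, np.log(densities))
    return float(res.slope), float(res.stderr)
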