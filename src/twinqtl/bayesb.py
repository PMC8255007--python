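"""BayesB whole-genome regression and genomic-window variance partitioning.

All markers are fitted simultaneously with a per-locus mixture prior: with
probability pi a locus has no effect, otherwise its effect is normal with
a locus-specific variance under a scaled inverse chi-square prior.  The
locus variance (including the zero state) is sampled by Metropolis-
Hastings with the effect integrated out, the effect by its normal full
conditional, and the residual variance by its scaled inverse chi-square
full conditional.  Post burn-in, the genetic variance is partitioned into
genomic windows each iteration; a window's share of variance and the
posterior probabilities p>0 (any effect in the window) and p>Average
(share above 1/n_windows) summarise the evidence per window.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Tuple

import numpy as np
import pandas as pd
from numba import njit

from .config import ConfigError


@dataclass
class BayesBConfig:
    pi: float = 0.989
    chain_length: int = 21_000
    burn_in: int = 1_000
    thinning: int = 1
    prior_df: float = 4.2
    prior_scale: Optional[float] = None   # derived from genetic variance if None
    genetic_variance_fraction: float = 0.5  # of var(y), used to derive the scale
    seed: int = 0
    window_mode: str = "megabase"         # {"megabase", "snp_count"}
    window_size: int = 1_000_000          # bp, or SNP count in snp_count mode
    n_mh: int = 10                        # MH proposals per locus per iteration

    def validate(self) -> "BayesBConfig":
        if not (0.0 < self.pi < 1.0):
            raise ConfigError("pi must be in (0, 1)")
        if self.chain_length <= self.burn_in:
            raise ConfigError("chain length must exceed burn-in")
        if self.window_mode not in ("megabase", "snp_count"):
            raise ConfigError("window_mode must be 'megabase' or 'snp_count'")
        if self.prior_df <= 2.0:
            raise ConfigError("prior df must exceed 2 for a finite prior mean")
        return self


@dataclass
class BayesBSamples:
    """Posterior summaries of one chain.

    ``window_*`` arrays are accumulated over post-burn-in iterations with
    windows in map order; per-locus arrays follow marker order.
    """

    config: BayesBConfig
    windows: pd.DataFrame                 # chrom, start, end, n_snps
    n_kept: int
    inclusion_frequency: np.ndarray       # per locus
    posterior_mean_effect: np.ndarray     # per locus
    window_share_sum: np.ndarray          # sum over iterations of variance share
    window_p_gt0_count: np.ndarray
    window_p_gt_avg_count: np.ndarray
    residual_variance_trace: np.ndarray


class BayesBError(RuntimeError):
    pass


@njit(cache=False)
def _chain(X, y, pi, nu, S2, se_init, nu_e, S2e, n_iter, burn_in, n_mh,
           win_of, n_win, seed):
    n, p = X.shape
    np.random.seed(seed)
    xtx = np.empty(p)
    for j in range(p):
        s = 0.0
        for i in range(n):
            s += X[i, j] * X[i, j]
        xtx[j] = s
    beta = np.zeros(p)
    sig2 = np.zeros(p)      # locus variances, 0 = excluded
    e = y.copy()
    se = se_init

    incl_freq = np.zeros(p)
    beta_mean = np.zeros(p)
    share_sum = np.zeros(n_win)
    gt0 = np.zeros(n_win)
    gtavg = np.zeros(n_win)
    se_trace = np.zeros(n_iter - burn_in)
    n_kept = 0
    win_val = np.zeros((n_win, n))

    for it in range(n_iter):
        for j in range(p):
            if xtx[j] <= 0.0:
                continue
            # rhs of the locus, data adjusted for all other effects
            r = 0.0
            for i in range(n):
                r += X[i, j] * e[i]
            r += xtx[j] * beta[j]

            # MH on the locus variance with the effect integrated out;
            # proposals come from the prior mixture, so prior and proposal
            # densities cancel and the acceptance ratio is the marginal
            # likelihood ratio along the locus direction (ll(0) = 0)
            cur = sig2[j]
            if cur > 0.0:
                ll_cur = (
                    -0.5 * np.log(1.0 + xtx[j] * cur / se)
                    + 0.5 * cur * r * r / (se * (se + cur * xtx[j]))
                )
            else:
                ll_cur = 0.0
            for _ in range(n_mh):
                if np.random.random() < pi:
                    prop = 0.0
                    ll_prop = 0.0
                else:
                    prop = S2 * nu / np.random.chisquare(nu)
                    ll_prop = (
                        -0.5 * np.log(1.0 + xtx[j] * prop / se)
                        + 0.5 * prop * r * r / (se * (se + prop * xtx[j]))
                    )
                if np.log(np.random.random() + 1e-300) < ll_prop - ll_cur:
                    cur = prop
                    ll_cur = ll_prop
            # sample the effect given the variance state
            old = beta[j]
            if cur > 0.0:
                prec = xtx[j] / se + 1.0 / cur
                mean = (r / se) / prec
                new = mean + np.random.normal() / np.sqrt(prec)
            else:
                new = 0.0
            sig2[j] = cur
            if new != old:
                diff = old - new
                for i in range(n):
                    e[i] += X[i, j] * diff
                beta[j] = new

        # residual variance: scaled inverse chi-square full conditional
        sse = 0.0
        for i in range(n):
            sse += e[i] * e[i]
        se = (sse + nu_e * S2e) / np.random.chisquare(n + nu_e)
        if not np.isfinite(se) or se <= 0.0:
            return (-it - 1, incl_freq, beta_mean, share_sum, gt0, gtavg,
                    se_trace, n_kept)

        if it >= burn_in:
            n_kept += 1
            se_trace[it - burn_in] = se
            for w in range(n_win):
                for i in range(n):
                    win_val[w, i] = 0.0
            any_eff = np.zeros(n_win)
            for j in range(p):
                if beta[j] != 0.0:
                    w = win_of[j]
                    any_eff[w] = 1.0
                    incl_freq[j] += 1.0
                    beta_mean[j] += beta[j]
                    for i in range(n):
                        win_val[w, i] += X[i, j] * beta[j]
            tot = 0.0
            var_w = np.zeros(n_win)
            for w in range(n_win):
                if any_eff[w] > 0.0:
                    m = 0.0
                    for i in range(n):
                        m += win_val[w, i]
                    m /= n
                    v = 0.0
                    for i in range(n):
                        d = win_val[w, i] - m
                        v += d * d
                    var_w[w] = v / n
                    tot += var_w[w]
            if tot > 0.0:
                thresh = 1.0 / n_win
                for w in range(n_win):
                    share = var_w[w] / tot
                    share_sum[w] += share
                    if any_eff[w] > 0.0:
                        gt0[w] += 1.0
                    if share > thresh:
                        gtavg[w] += 1.0
    return (0, incl_freq, beta_mean, share_sum, gt0, gtavg, se_trace, n_kept)


def make_windows(marker_map: pd.DataFrame, config: BayesBConfig) -> Tuple[pd.DataFrame, np.ndarray]:
    """Window table and per-marker window index, in map order.

    Megabase mode tiles each chromosome in fixed ``window_size``-bp
    segments aligned at zero (windows without markers are kept, with
    n_snps = 0); snp_count mode chunks consecutive markers.
    """
    chrom = marker_map["chrom"].to_numpy()
    pos = marker_map["pos"].to_numpy()
    win_of = np.zeros(len(marker_map), dtype=np.int64)
    rows = []
    k = 0
    for c in pd.unique(chrom):
        sel = np.nonzero(chrom == c)[0]
        if config.window_mode == "megabase":
            w = config.window_size
            first = int(pos[sel].min()) // w
            last = int(pos[sel].max()) // w
            for b in range(first, last + 1):
                lo, hi = b * w, (b + 1) * w - 1
                members = sel[(pos[sel] >= lo) & (pos[sel] <= hi)]
                win_of[members] = k
                rows.append((c, lo, hi, len(members)))
                k += 1
        else:
            for lo in range(0, len(sel), config.window_size):
                members = sel[lo:lo + config.window_size]
                win_of[members] = k
                rows.append(
                    (c, int(pos[members].min()), int(pos[members].max()),
                     len(members))
                )
                k += 1
    windows = pd.DataFrame(rows, columns=["chrom", "start", "end", "n_snps"])
    return windows, win_of


def bayesb_sample(
    response: np.ndarray,
    dosages: np.ndarray,
    marker_map: pd.DataFrame,
    config: Optional[BayesBConfig] = None,
) -> BayesBSamples:
    """Run one BayesB Gibbs chain and accumulate window statistics.

    The effect-variance prior scale, when not given, is derived from an
    assumed total genetic variance (``genetic_variance_fraction`` of the
    response variance) spread over the expected (1-pi) fraction of loci:
    S2 = sigma2_g (nu-2) / (nu (1-pi) sum 2 p q).
    """
    config = (config or BayesBConfig()).validate()
    y = np.asarray(response, dtype=float)
    X = np.asarray(dosages, dtype=np.float64)
    n, p = X.shape
    if len(y) != n:
        raise BayesBError("response and dosages are not conformable")
    if len(marker_map) != p:
        raise BayesBError("marker map and dosages are not conformable")

    y = y - y.mean()
    vary = float(np.var(y))
    freq = X.mean(axis=0) / 2.0
    sum2pq = float(np.sum(2.0 * freq * (1.0 - freq)))
    S2 = config.prior_scale
    if S2 is None:
        s2g = config.genetic_variance_fraction * vary
        S2 = s2g * (config.prior_df - 2.0) / (
            config.prior_df * (1.0 - config.pi) * max(sum2pq, 1e-12)
        )
    windows, win_of = make_windows(marker_map, config)

    Xf = np.asfortranarray(X)
    status, incl, bmean, share_sum, gt0, gtavg, se_trace, n_kept = _chain(
        Xf, y, config.pi, config.prior_df, S2,
        vary * (1.0 - config.genetic_variance_fraction), 4.0, vary / 2.0,
        config.chain_length, config.burn_in, config.n_mh,
        win_of, len(windows), config.seed,
    )
    if status < 0:
        raise BayesBError(
            f"divergent chain: non-finite residual variance at iteration {-status - 1}"
        )
    return BayesBSamples(
        config=config,
        windows=windows,
        n_kept=int(n_kept),
        inclusion_frequency=incl / max(n_kept, 1),
        posterior_mean_effect=bmean / max(n_kept, 1),
        window_share_sum=share_sum,
        window_p_gt0_count=gt0,
        window_p_gt_avg_count=gtavg,
        residual_variance_trace=se_trace,
    )


def window_variance(samples: BayesBSamples) -> pd.DataFrame:
    """Posterior window-variance table, ranked by explained share.

    Columns: chrom, start, end, n_snps, proportion (%), cumulative (%),
    p_gt0, p_gt_average; sorted by proportion descending with the
    cumulative column accumulated in that order.
    """
    k = max(samples.n_kept, 1)
    tab = samples.windows.copy()
    tab["proportion"] = 100.0 * samples.window_share_sum / k
    tab["p_gt0"] = samples.window_p_gt0_count / k
    tab["p_gt_average"] = samples.window_p_gt_avg_count / k
    tab = tab.sort_values(
        ["proportion", "chrom", "start"], ascending=[False, True, True]
    ).reset_index(drop=True)
    tab["cumulative"] = tab["proportion"].cumsum()
    return tab[
        ["chrom", "start", "end", "n_snps", "proportion", "cumulative",
         "p_gt0", "p_gt_average"]
    ]


def significant_windows(
    wv: pd.DataFrame, level: float = 0.05
) -> pd.DataFrame:
    """Windows significant at ``level``: p_gt_average >= 1 - level."""
    if len(wv) == 0:
        raise BayesBError("empty window table")
    return wv[wv["p_gt_average"] >= 1.0 - level].copy()
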