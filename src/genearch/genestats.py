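"""Rank statistics, sliding-window medians, and the IpE randomization test.

All reported correlation coefficients operate on raw data; the sliding-
window medians exist purely to visualize trends. The randomization test
asks whether observed intron-plus-next-exon (IpE) unit sizes could arise
from independent pairing of introns and exons drawn from the same
positional group.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from scipy import stats


@dataclass
class SlidingWindowSeries:
    """Rolling medians of tracked variables after sorting by a key.

    Each point is supported by exactly ``window`` observations; with
    step 1 the series has N - window + 1 points.
    """

    sort_key: str
    window: int
    step: int
    frame: pd.DataFrame  # one column per tracked variable (median), plus sort key median

    @property
    def n_points(self) -> int:
        return len(self.frame)


def sliding_window_median(
    records: pd.DataFrame,
    sort_key: str,
    tracked_vars: Sequence[str],
    window: int = 2000,
    step: int = 1,
) -> SlidingWindowSeries:
    """Stable-sort by ``sort_key`` (input order breaks ties), then compute
    rolling medians of the sort key and each tracked variable."""
    n = len(records)
    if n < window:
        raise ValueError(f"need at least window={window} records, got {n}")
    ordered = records.sort_values(sort_key, kind="stable")
    cols = {}
    for var in dict.fromkeys([sort_key, *tracked_vars]):
        roll = ordered[var].rolling(window).median().iloc[window - 1 :: step]
        cols[var] = roll.to_numpy()
    frame = pd.DataFrame(cols)
    frame["n"] = window
    return SlidingWindowSeries(sort_key=sort_key, window=window, step=step, frame=frame)


def kendall_tau_b(x: Sequence[float], y: Sequence[float]) -> tuple[float, float]:
    """Kendall's tau-b (tie-corrected) with its p-value.

    Returns (nan, nan) when either vector has zero variance. The p-value
    follows scipy's policy: exact enumeration for small tie-free samples,
    normal approximation otherwise.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("x and y must have equal length")
    if x.size < 2:
        raise ValueError("need at least two observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.kendalltau(x, y, variant="b")
    return float(res.statistic), float(res.pvalue)


def partial_kendall_tau(
    x: Sequence[float], y: Sequence[float], z: Sequence[float]
) -> tuple[float, float]:
    """Partial Kendall correlation of x and y controlling for z:

        tau_xy.z = (tau_xy - tau_xz * tau_yz) / sqrt((1-tau_xz^2)(1-tau_yz^2))

    Undefined (nan) when |tau_xz| or |tau_yz| is 1. The p-value uses the
    normal approximation for tau's null variance applied to the partial
    statistic, and is approximate.
    """
    t_xy, _ = kendall_tau_b(x, y)
    t_xz, _ = kendall_tau_b(x, z)
    t_yz, _ = kendall_tau_b(y, z)
    if any(np.isnan(t) for t in (t_xy, t_xz, t_yz)):
        return float("nan"), float("nan")
    denom = (1 - t_xz**2) * (1 - t_yz**2)
    if denom <= 0:
        return float("nan"), float("nan")
    tau_p = (t_xy - t_xz * t_yz) / np.sqrt(denom)
    n = len(np.asarray(x))
    var = 2.0 * (2 * n + 5) / (9.0 * n * (n - 1))
    zstat = tau_p / np.sqrt(var)
    p = 2.0 * stats.norm.sf(abs(zstat))
    return float(tau_p), float(p)


def kruskal_wallis(groups: Sequence[Sequence[float]]) -> tuple[float, float]:
    """Kruskal-Wallis H (tie-corrected) with chi-square p on k-1 df.

    By convention H = 0 (p = 1) when every observation across all groups
    is identical, where the tie correction is degenerate.
    """
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    if any(len(g) == 0 for g in groups):
        raise ValueError("all groups must be non-empty")
    flat = np.concatenate([np.asarray(g, dtype=float) for g in groups])
    if np.ptp(flat) == 0:
        return 0.0, 1.0
    h, p = stats.kruskal(*groups)
    return float(h), float(p)


def ks_two_sample(a: Sequence[float], b: Sequence[float]) -> tuple[float, float]:
    """Two-sample Kolmogorov-Smirnov: sup-norm ECDF distance, asymptotic p."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.size == 0 or b.size == 0:
        raise ValueError("both samples must be non-empty")
    res = stats.ks_2samp(a, b, method="asymp")
    return float(res.statistic), float(res.pvalue)


def chi_square_independence(table) -> tuple[float, int, float]:
    """Pearson chi-square of independence, no continuity correction."""
    arr = np.asarray(table, dtype=float)
    if (arr < 0).any():
        raise ValueError("counts must be non-negative")
    chi2, p, dof, expected = stats.chi2_contingency(arr, correction=False)
    if (expected <= 0).any():
        raise ValueError("zero expected cell")
    return float(chi2), int(dof), float(p)


def chi_square_gof(observed, expected) -> tuple[float, int, float]:
    """Pearson goodness-of-fit chi-square on k-1 df."""
    obs = np.asarray(observed, dtype=float)
    exp = np.asarray(expected, dtype=float)
    if (exp <= 0).any():
        raise ValueError("zero expected cell")
    chi2, p = stats.chisquare(obs, f_exp=exp)
    return float(chi2), len(obs) - 1, float(p)


@dataclass
class RandomizationResult:
    """Outcome of the intron/exon re-pairing randomization test.

    ``overall_p`` is the fraction of null re-pairings whose size
    distribution is statistically indistinguishable (KS p >= alpha) from
    the observed one; a value near 0 means almost every random pairing
    differs from the data.
    """

    n_sim: int
    alpha: float
    p_values: np.ndarray
    overall_p: float
    seed: int
    n_units: int


def ipe_randomization_test(
    actual_unit_sizes: Sequence[float],
    intron_pool: Sequence[float],
    exon_pool: Sequence[float],
    n_sim: int = 100_000,
    alpha: float = 0.05,
    seed: int | np.random.Generator = 0,
) -> RandomizationResult:
    """Compare observed IpE sizes with null distributions built by random
    intron/exon pairing.

    Each simulation draws ``len(actual)`` introns and exons uniformly with
    replacement from the positional group's pools, sums their lengths, and
    KS-tests the simulated sizes against the observed ones. The overall P
    is #{simulations with KS p >= alpha} / n_sim.
    """
    actual = np.asarray(actual_unit_sizes, dtype=float)
    introns = np.asarray(intron_pool, dtype=float)
    exons = np.asarray(exon_pool, dtype=float)
    if actual.size == 0 or introns.size == 0 or exons.size == 0:
        raise ValueError("actual sizes and both pools must be non-empty")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    seed_repr = -1 if isinstance(seed, np.random.Generator) else int(seed)
    n = actual.size
    pvals = np.empty(n_sim)
    for s in range(n_sim):
        sim = introns[rng.integers(0, introns.size, n)] + exons[
            rng.integers(0, exons.size, n)
        ]
        pvals[s] = stats.ks_2samp(actual, sim, method="asymp").pvalue
    overall = float(np.mean(pvals >= alpha))
    return RandomizationResult(
        n_sim=n_sim,
        alpha=alpha,
        p_values=pvals,
        overall_p=overall,
        seed=seed_repr,
        n_units=n,
    )
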