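"""Bootstrap stability analysis of the causal-direction statistics.

Participants (rows) are resampled with replacement, keeping the two
scores of a participant together; each resample yields one value of the
chosen direction statistic. The summary reports how often each direction
was chosen, the median statistic, and a bias-corrected and accelerated
(BCa) confidence interval.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats

from .causality import PairedSample, compute_statistic
from .exceptions import DegenerateInputError, InputError

__all__ = ["BootstrapSummary", "bca_interval", "bootstrap_causality"]


@dataclass(frozen=True)
class BootstrapSummary:
    """Direction percentages and BCa interval over B paired resamples."""

    method: str
    B: int
    pct_first: float
    pct_second: float
    pct_tie: float
    median_value: float
    ci_low: float
    ci_high: float
    level: float
    point_value: float
    n_redrawn: int = 0

    def __post_init__(self):
        if self.B < 2:
            raise InputError("B must be >= 2")
        if self.ci_low > self.ci_high:
            raise InputError("interval endpoints out of order")
        total = self.pct_first + self.pct_second + self.pct_tie
        if abs(total - 100.0) > 1e-6:
            raise InputError(f"direction percentages sum to {total}, not 100")


def bca_interval(
    replicate_values,
    point_estimate: float,
    jackknife_values,
    level: float = 0.95,
) -> tuple[float, float]:
    """Bias-corrected and accelerated bootstrap confidence interval.

    The bias correction z0 is the normal quantile of the fraction of
    replicates below the point estimate; the acceleration a is the
    jackknife skewness coefficient. Adjusted percentile endpoints are
    clipped to the range of the replicates. When every replicate falls on
    one side of the point estimate (z0 infinite) the plain percentile
    interval is returned with a warning.
    """
    theta = np.asarray(replicate_values, dtype=float).ravel()
    if theta.size < 10:
        raise InputError("need at least 10 bootstrap replicates for a BCa interval")
    if not 0.0 < level < 1.0:
        raise InputError("level must be in (0, 1)")
    if np.ptp(theta) == 0.0:
        return float(theta[0]), float(theta[0])
    alpha = (1.0 - level) / 2.0
    prop = np.mean(theta < point_estimate)
    if prop == 0.0 or prop == 1.0:
        warnings.warn("all bootstrap replicates on one side of the point "
                      "estimate; falling back to the percentile interval")
        lo, hi = np.quantile(theta, [alpha, 1.0 - alpha])
        return float(lo), float(hi)
    z0 = stats.norm.ppf(prop)
    jack = np.asarray(jackknife_values, dtype=float).ravel()
    dev = jack.mean() - jack
    denom = np.sum(dev**2) ** 1.5
    a = 0.0 if denom == 0.0 else float(np.sum(dev**3) / (6.0 * denom))
    out = []
    for q in (alpha, 1.0 - alpha):
        zq = stats.norm.ppf(q)
        adj = stats.norm.cdf(z0 + (z0 + zq) / (1.0 - a * (z0 + zq)))
        out.append(float(np.quantile(theta, np.clip(adj, 0.0, 1.0))))
    lo, hi = min(out), max(out)
    lo = max(lo, float(theta.min()))
    hi = min(hi, float(theta.max()))
    return lo, hi


def bootstrap_causality(
    sample: PairedSample,
    method: str,
    B: int = 2000,
    level: float = 0.95,
    seed=0,
    jackknife_subsample: int | None = 200,
    **stat_kwargs,
) -> BootstrapSummary:
    """Direction-stability bootstrap for one statistic on one pair.

    Parameters
    ----------
    sample : PairedSample
    method : {"lingam", "skew", "tanh"}
    B : int
        Number of paired resamples with replacement (>= 100).
    level : float
        Confidence level of the BCa interval.
    seed : int or Generator
        Source of resampling randomness; the same seed reproduces the
        summary bit for bit.
    jackknife_subsample : int or None
        The acceleration constant comes from leave-one-out re-estimation;
        with an expensive statistic this may be evaluated on a seeded
        subsample of this many leave-one-out points (None = exact, all n).

    Notes
    -----
    Resamples in which either column is constant carry no direction
    information and are redrawn (counted in ``n_redrawn``; a warning is
    emitted past 1% of B). Replicates exactly at zero count as ties and
    appear in neither direction column.
    """
    if B < 100:
        raise InputError("B must be >= 100 for interval estimation")
    rng = np.random.default_rng(seed)
    n = sample.n
    point = compute_statistic(sample, method, **stat_kwargs).value

    values = np.empty(B)
    n_redrawn = 0
    for b in range(B):
        while True:
            idx = rng.integers(0, n, size=n)
            try:
                s = PairedSample(sample.x[idx], sample.y[idx],
                                 sample.x_label, sample.y_label)
            except DegenerateInputError:
                n_redrawn += 1
                continue
            break
        values[b] = compute_statistic(s, method, **stat_kwargs).value
    if n_redrawn > 0.01 * B:
        warnings.warn(f"{n_redrawn} degenerate resamples redrawn (> 1% of B)")

    if jackknife_subsample is not None and jackknife_subsample < n:
        loo = rng.choice(n, size=jackknife_subsample, replace=False)
    else:
        loo = np.arange(n)
    jack = np.empty(loo.size)
    mask = np.ones(n, dtype=bool)
    for i, drop in enumerate(loo):
        mask[drop] = False
        s = PairedSample(sample.x[mask], sample.y[mask])
        jack[i] = compute_statistic(s, method, **stat_kwargs).value
        mask[drop] = True

    lo, hi = bca_interval(values, point, jack, level=level)
    pct_first = 100.0 * np.mean(values > 0)
    pct_second = 100.0 * np.mean(values < 0)
    pct_tie = 100.0 - pct_first - pct_second
    return BootstrapSummary(
        method=method,
        B=B,
        pct_first=float(pct_first),
        pct_second=float(pct_second),
        pct_tie=float(pct_tie),
        median_value=float(np.median(values)),
        ci_low=lo,
        ci_high=hi,
        level=level,
        point_value=float(point),
        n_redrawn=n_redrawn,
    )
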