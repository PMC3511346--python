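"""Pairwise causal-direction statistics for linear non-Gaussian models.

Under a linear non-Gaussian acyclic model (LiNGAM) for a pair of
variables — ``y = b*x + e`` with ``e`` independent of ``x`` and
non-Gaussian — the causal direction is identifiable from observational
data. Three signed statistics implement the direction decision; for each
of them a positive value means the *first* argument is the estimated
cause, a negative value the opposite, and exactly zero a tie.

* ``lingam`` — the DirectLiNGAM pairwise criterion: difference of kernel
  mutual informations between each candidate cause and the residual of
  regressing it out of the other variable.
* ``skew`` — a cubic-moment approximation to the likelihood ratio between
  the two orderings, informative when the variables are skewed.
* ``tanh`` — a hyperbolic-tangent approximation to the same likelihood
  ratio, informative for non-Gaussian (sparse) kurtosis.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Literal
import warnings

import numpy as np

from .dependence import kernel_mutual_information
from .exceptions import DegenerateInputError, InputError

__all__ = [
    "PairedSample",
    "RegressionFit",
    "DirectionStatistic",
    "standardize",
    "ols_fit",
    "stat_skew",
    "stat_tanh",
    "stat_lingam",
    "compute_statistic",
    "decide_direction",
    "METHODS",
]

Direction = Literal["first_causes_second", "second_causes_first", "tie"]
METHODS = ("lingam", "skew", "tanh")


@dataclass(frozen=True)
class PairedSample:
    """Two equal-length numeric vectors: putative cause and putative effect."""

    x: np.ndarray
    y: np.ndarray
    x_label: str = "x"
    y_label: str = "y"

    def __post_init__(self):
        object.__setattr__(self, "x", np.asarray(self.x, dtype=float).ravel())
        object.__setattr__(self, "y", np.asarray(self.y, dtype=float).ravel())
        if self.x.size != self.y.size:
            raise InputError("x and y must have equal length")
        if self.x.size < 20:
            raise InputError("paired sample needs at least 20 observations")
        if not (np.all(np.isfinite(self.x)) and np.all(np.isfinite(self.y))):
            raise InputError("paired sample contains non-finite values")
        for v, name in ((self.x, self.x_label), (self.y, self.y_label)):
            if np.ptp(v) == 0.0:
                raise DegenerateInputError(f"variable {name!r} is constant")

    @property
    def n(self) -> int:
        return self.x.size

    def swapped(self) -> "PairedSample":
        return PairedSample(self.y, self.x, self.y_label, self.x_label)


@dataclass(frozen=True)
class RegressionFit:
    """OLS fit of effect on cause with mean-zero residuals."""

    slope: float
    intercept: float
    residuals: np.ndarray


@dataclass(frozen=True)
class DirectionStatistic:
    """A signed pairwise causality statistic and the direction it implies."""

    method: str
    value: float
    direction: Direction = field(init=False)
    standardized: bool = True

    def __post_init__(self):
        if not np.isfinite(self.value):
            raise InputError("direction statistic must be finite")
        if self.value > 0:
            d: Direction = "first_causes_second"
        elif self.value < 0:
            d = "second_causes_first"
        else:
            d = "tie"
        object.__setattr__(self, "direction", d)


def standardize(v) -> np.ndarray:
    """Center to mean 0 and scale to unit standard deviation (ddof=1)."""
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 2 or np.ptp(arr) == 0.0:
        raise DegenerateInputError("cannot standardize a constant vector")
    return (arr - arr.mean()) / arr.std(ddof=1)


def ols_fit(x, y) -> RegressionFit:
    """Simple least-squares regression of y on x."""
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise InputError("x and y must have equal length")
    vx = np.var(xa)
    if vx == 0.0:
        raise DegenerateInputError("predictor has zero variance")
    slope = float(np.cov(xa, ya, bias=True)[0, 1] / vx)
    intercept = float(ya.mean() - slope * xa.mean())
    resid = ya - intercept - slope * xa
    resid = resid - resid.mean()  # exact mean-zero despite rounding
    return RegressionFit(slope=slope, intercept=intercept, residuals=resid)


def _corr(x: np.ndarray, y: np.ndarray) -> float:
    return float(np.corrcoef(x, y)[0, 1])


def _skew_sign(v: np.ndarray) -> float:
    m3 = np.mean((v - v.mean()) ** 3)
    if abs(m3) < 1e-12:
        warnings.warn("sample skewness numerically zero; skew statistic sign "
                      "is not identifiable", stacklevel=3)
        return 1.0
    return float(np.sign(m3))


def stat_skew(x, y) -> DirectionStatistic:
    """Skewness-based likelihood-ratio approximation.

    Both variables are standardized and flipped to be (effectively)
    right-skewed; the statistic is ``rho * (E[x^2 y] - E[x y^2])`` with
    plain sample-mean expectations. Exactly antisymmetric in its
    arguments.
    """
    s = PairedSample(x, y)
    xs = standardize(s.x) * _skew_sign(s.x)
    ys = standardize(s.y) * _skew_sign(s.y)
    rho = _corr(xs, ys)
    value = rho * float(np.mean(xs**2 * ys) - np.mean(xs * ys**2))
    return DirectionStatistic(method="skew", value=value)


def stat_tanh(x, y) -> DirectionStatistic:
    """Tanh-based likelihood-ratio approximation for non-Gaussian kurtosis.

    Statistic ``rho * E[x*tanh(y) - tanh(x)*y]`` on standardized
    variables; exactly antisymmetric.
    """
    s = PairedSample(x, y)
    xs = standardize(s.x)
    ys = standardize(s.y)
    rho = _corr(xs, ys)
    value = rho * float(np.mean(xs * np.tanh(ys) - np.tanh(xs) * ys))
    return DirectionStatistic(method="tanh", value=value)


def stat_lingam(
    x,
    y,
    standardize_first: bool = True,
    width: float | None = None,
    reg: float = 2e-3,
) -> DirectionStatistic:
    """DirectLiNGAM pairwise criterion via kernel mutual information.

    Computes the OLS residual of each variable on the other and compares
    how dependent each candidate cause is on the residual it would leave:
    ``MI(y, e_{x|y}) - MI(x, e_{y|x})``. A positive value means the first
    argument's residual is the less dependent one, i.e. the first argument
    is the estimated exogenous cause.

    With ``standardize_first=False`` the variables are centered but kept on
    their original scales (the "non-standardized" table variant).
    """
    s = PairedSample(x, y)
    if standardize_first:
        xs, ys = standardize(s.x), standardize(s.y)
    else:
        xs, ys = s.x - s.x.mean(), s.y - s.y.mean()
    e_y_given_x = ols_fit(xs, ys).residuals
    e_x_given_y = ols_fit(ys, xs).residuals
    mi_forward = kernel_mutual_information(xs, e_y_given_x, width=width, reg=reg)
    mi_backward = kernel_mutual_information(ys, e_x_given_y, width=width, reg=reg)
    return DirectionStatistic(
        method="lingam",
        value=mi_backward - mi_forward,
        standardized=standardize_first,
    )


_STAT_FUNCS = {"lingam": stat_lingam, "skew": stat_skew, "tanh": stat_tanh}


def compute_statistic(sample: PairedSample, method: str, **kwargs) -> DirectionStatistic:
    """Dispatch one of the three direction statistics by label."""
    try:
        func = _STAT_FUNCS[method]
    except KeyError:
        raise InputError(f"unknown method {method!r}; choose from {METHODS}") from None
    return func(sample.x, sample.y, **kwargs)


def decide_direction(stat: DirectionStatistic) -> Direction:
    """Map the sign of a direction statistic to its direction label."""
    return stat.direction
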