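"""Assumption diagnostics for an estimated causal direction.

After a direction has been chosen, the linear non-Gaussian model behind
it is checked on three fronts: linearity of the cause-effect link
(quadratic-term t-test), non-Gaussianity of the residual (Lilliefors),
and independence of the residual from the estimated cause (L1 partition
test and Hoeffding's D). The battery is summarized per model in the
"Y = f(X) + e" naming convention.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import statsmodels.api as sm

from .causality import PairedSample, ols_fit
from .dependence import (
    hoeffding_d_test,
    l1_independence_test,
    lilliefors_test,
    TestResult,
)
from .exceptions import InputError

__all__ = ["AssumptionReport", "quadratic_term_test", "assumption_report"]


@dataclass(frozen=True)
class AssumptionReport:
    """Table row of assumption-check p-values for one oriented model."""

    model_label: str
    p_quadratic: float
    p_normality: float
    p_l1: float
    p_hoeffding: float
    hoeffding_D: float
    ks_distance: float
    n: int

    def __post_init__(self):
        for name in ("p_quadratic", "p_normality", "p_l1", "p_hoeffding"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise InputError(f"{name}={p} outside [0, 1]")

    def as_dict(self) -> dict:
        return {
            "model": self.model_label,
            "p_quadratic": self.p_quadratic,
            "p_normality": self.p_normality,
            "p_l1": self.p_l1,
            "p_hoeffding": self.p_hoeffding,
            "hoeffding_D": self.hoeffding_D,
            "ks_distance": self.ks_distance,
            "n": self.n,
        }


def quadratic_term_test(x, y) -> TestResult:
    """Two-sided t-test of the quadratic coefficient in y ~ 1 + x + x^2.

    A significant quadratic term rejects the linearity assumption of the
    causal model.
    """
    xa = np.asarray(x, dtype=float).ravel()
    ya = np.asarray(y, dtype=float).ravel()
    if xa.size != ya.size:
        raise InputError("x and y must have equal length")
    if xa.size < 10:
        raise InputError("need at least 10 observations")
    design = sm.add_constant(np.column_stack([xa, xa**2]))
    if np.linalg.matrix_rank(design) < 3:
        raise InputError("design matrix is collinear: x and x^2 are linearly "
                         "dependent (e.g. binary x)")
    fit = sm.OLS(ya, design).fit()
    return TestResult(statistic=float(fit.tvalues[2]),
                      p_value=float(fit.pvalues[2]),
                      method="quadratic_term", n=xa.size)


def assumption_report(
    sample: PairedSample,
    direction: str = "first_causes_second",
    seed=0,
    hoeffding_permutations: int = 2000,
    lilliefors_mc: int = 10_000,
    l1_mode: str = "distribution_free",
) -> AssumptionReport:
    """Run the full assumption battery for one oriented model.

    The pair is oriented per ``direction`` (cause, effect); the effect is
    regressed on the cause; then the quadratic-term, Lilliefors (on the
    residual), L1 and Hoeffding (both cause vs residual) tests are run.
    Independence is always tested between the *exogenous* variable and
    the residual — the effect-residual pairing is dependent by
    construction and carries no diagnostic content.
    """
    if direction == "first_causes_second":
        cause, effect = sample.x, sample.y
        cause_label, effect_label = sample.x_label, sample.y_label
    elif direction == "second_causes_first":
        cause, effect = sample.y, sample.x
        cause_label, effect_label = sample.y_label, sample.x_label
    else:
        raise InputError("direction must name a cause (no ties)")

    resid = ols_fit(cause, effect).residuals
    quad = quadratic_term_test(cause, effect)
    norm = lilliefors_test(resid, n_mc=lilliefors_mc, seed=seed)
    l1 = l1_independence_test(cause, resid, mode=l1_mode, seed=seed)
    hoeff = hoeffding_d_test(cause, resid,
                             n_permutations=hoeffding_permutations, seed=seed)
    return AssumptionReport(
        model_label=f"{effect_label} = f({cause_label}) + e",
        p_quadratic=quad.p_value,
        p_normality=norm.p_value,
        p_l1=l1.p_value,
        p_hoeffding=hoeff.p_value,
        hoeffding_D=hoeff.statistic,
        ks_distance=norm.statistic,
        n=sample.n,
    )
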