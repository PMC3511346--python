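"""Perturbation study of the direction statistics on a fitted model.

A tractable generative model — shifted-exponential cause, four-component
Gaussian-mixture residual, linear link — is fitted to an observed pair
and then systematically perturbed: ordinal discretization of both
margins, latent confounding (linear mixing or proportional contamination
by an unobserved common cause), and Gaussian measurement error on the
cause. For each perturbed condition the "estimation success" is the
proportion of simulated datasets in which a direction statistic recovers
the generating direction.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable

import numpy as np
import pandas as pd
from sklearn.mixture import GaussianMixture

from .causality import PairedSample, compute_statistic, ols_fit
from .exceptions import DegenerateInputError, InputError

__all__ = [
    "ShiftedExponentialSpec",
    "GaussianMixtureSpec",
    "DataGeneratingModel",
    "PerturbationCondition",
    "SuccessResult",
    "fit_shifted_exponential",
    "fit_gaussian_mixture",
    "fit_data_model",
    "draw_pair",
    "discretize",
    "perturb_confound",
    "add_measurement_error",
    "estimation_success",
    "run_experiment_grid",
    "SETTINGS",
]

SETTINGS = ("GM_residual", "Exp_residual", "Different_residuals", "All_GM")


@dataclass(frozen=True)
class ShiftedExponentialSpec:
    """Location-shifted exponential distribution: shift + Exp(rate)."""

    shift: float
    rate: float

    def __post_init__(self):
        if self.rate <= 0:
            raise InputError("rate must be positive")

    @property
    def mean(self) -> float:
        return self.shift + 1.0 / self.rate

    @property
    def sd(self) -> float:
        return 1.0 / self.rate

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        return self.shift + rng.exponential(scale=1.0 / self.rate, size=size)

    def centered(self) -> "ShiftedExponentialSpec":
        """Same shape translated to zero mean (residual role)."""
        return ShiftedExponentialSpec(shift=-1.0 / self.rate, rate=self.rate)


@dataclass(frozen=True)
class GaussianMixtureSpec:
    """Univariate Gaussian mixture with fixed component order."""

    weights: tuple[float, ...]
    means: tuple[float, ...]
    sds: tuple[float, ...]

    def __post_init__(self):
        w = np.asarray(self.weights)
        if abs(w.sum() - 1.0) > 1e-9 or np.any(w <= 0):
            raise InputError("mixture weights must be positive and sum to 1")
        if np.any(np.asarray(self.sds) <= 0):
            raise InputError("mixture sds must be positive")
        if not len(self.weights) == len(self.means) == len(self.sds):
            raise InputError("mixture parameter lengths differ")

    @property
    def mean(self) -> float:
        return float(np.dot(self.weights, self.means))

    @property
    def var(self) -> float:
        w = np.asarray(self.weights)
        mu = np.asarray(self.means)
        s = np.asarray(self.sds)
        return float(w @ (s**2 + mu**2) - self.mean**2)

    @property
    def sd(self) -> float:
        return float(np.sqrt(self.var))

    def centered(self) -> "GaussianMixtureSpec":
        m = self.mean
        return GaussianMixtureSpec(self.weights,
                                   tuple(mu - m for mu in self.means),
                                   self.sds)

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        comp = rng.choice(len(self.weights), size=size, p=self.weights)
        z = rng.standard_normal(size)
        mu = np.asarray(self.means)[comp]
        s = np.asarray(self.sds)[comp]
        return mu + s * z


@dataclass(frozen=True)
class DataGeneratingModel:
    """Ground truth of the simulation: y = intercept + beta*x + e."""

    beta: float
    exo: ShiftedExponentialSpec | GaussianMixtureSpec
    resid: GaussianMixtureSpec
    n: int
    intercept: float = 0.0

    def __post_init__(self):
        if self.n < 20:
            raise InputError("n must be >= 20")
        if abs(self.resid.mean) > 1e-10:
            raise InputError("residual distribution must have zero mean")


@dataclass(frozen=True)
class PerturbationCondition:
    """One cell of the perturbation grid."""

    kind: str  # none | discretize | linear_confound | proportional_confound | noise
    k: int = 2
    lam: float = 0.0
    noise_sd: float = 0.0
    setting: str = "GM_residual"

    def __post_init__(self):
        if self.kind not in ("none", "discretize", "linear_confound",
                             "proportional_confound", "noise"):
            raise InputError(f"unknown perturbation kind {self.kind!r}")
        if not 0.0 <= self.lam <= 1.0:
            raise InputError("lam must lie in [0, 1]")
        if self.k < 2:
            raise InputError("k must be >= 2")
        if self.noise_sd < 0:
            raise InputError("noise_sd must be nonnegative")
        if self.setting not in SETTINGS:
            raise InputError(f"unknown setting {self.setting!r}")


@dataclass(frozen=True)
class SuccessResult:
    """Proportion of replicates recovering the generating direction."""

    condition: PerturbationCondition
    method: str
    reps: int
    n_correct: int

    @property
    def success(self) -> float:
        return self.n_correct / self.reps


# ---------------------------------------------------------------------------
# Model fitting
# ---------------------------------------------------------------------------

def fit_shifted_exponential(v) -> ShiftedExponentialSpec:
    """Moment/support fit of a location-shifted exponential.

    The shift sits just below the sample minimum by the small-sample
    correction (mean - min)/n, and the rate is then chosen so the fitted
    mean reproduces the sample mean exactly.
    """
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 20:
        raise InputError("need at least 20 observations")
    if np.ptp(arr) == 0.0:
        raise DegenerateInputError("input is constant")
    m, lo = arr.mean(), arr.min()
    shift = lo - (m - lo) / arr.size
    return ShiftedExponentialSpec(shift=float(shift), rate=float(1.0 / (m - shift)))


def fit_gaussian_mixture(v, components: int = 4, seed=0,
                         n_restarts: int = 10) -> GaussianMixtureSpec:
    """Univariate Gaussian-mixture fit by multi-start EM.

    Components are returned sorted by mean. A variance floor (1e-6 times
    the sample variance) prevents component collapse. ``components=1``
    reduces exactly to the sample maximum-likelihood Gaussian.
    """
    arr = np.asarray(v, dtype=float).ravel()
    if arr.size < 10 * components:
        raise InputError(f"need at least {10 * components} observations")
    if components == 1:
        return GaussianMixtureSpec((1.0,), (float(arr.mean()),),
                                   (float(arr.std(ddof=0)),))
    gm = GaussianMixture(
        n_components=components,
        covariance_type="full",
        reg_covar=1e-6 * float(np.var(arr)),
        n_init=n_restarts,
        random_state=np.random.default_rng(seed).integers(2**31 - 1),
        max_iter=500,
    ).fit(arr[:, None])
    if not gm.converged_:
        raise RuntimeError(
            f"EM failed to converge in {n_restarts} restarts "
            f"(lower bound {gm.lower_bound_:.4g})")
    order = np.argsort(gm.means_.ravel())
    w = gm.weights_.ravel()[order]
    w = w / w.sum()
    return GaussianMixtureSpec(
        weights=tuple(w),
        means=tuple(gm.means_.ravel()[order]),
        sds=tuple(np.sqrt(gm.covariances_.ravel()[order])),
    )


def fit_data_model(sample: PairedSample, components: int = 4,
                   seed=0) -> DataGeneratingModel:
    """Fit the full generating model to an observed pair.

    Slope and intercept by OLS of effect on cause; shifted exponential to
    the cause; a Gaussian mixture (translated to zero mean) to the OLS
    residual.
    """
    fit = ols_fit(sample.x, sample.y)
    exo = fit_shifted_exponential(sample.x)
    resid = fit_gaussian_mixture(fit.residuals, components, seed=seed).centered()
    return DataGeneratingModel(beta=fit.slope, exo=exo, resid=resid,
                               n=sample.n, intercept=fit.intercept)


# ---------------------------------------------------------------------------
# Drawing and perturbing
# ---------------------------------------------------------------------------

def draw_pair(model: DataGeneratingModel, seed=0):
    """Draw (x, e, y) from the model; y = intercept + beta*x + e exactly."""
    rng = np.random.default_rng(seed)
    x = model.exo.draw(rng, model.n)
    e = model.resid.draw(rng, model.n)
    y = model.intercept + model.beta * x + e
    return x, e, y


def discretize(v, k: int) -> np.ndarray:
    """Snap values onto a k-interval equal-width lattice of lower edges.

    The range [min, max] is split into k equal intervals; each value maps
    to the lower limit of its interval, the maximum joining the last one.
    Emulates ordinal sum-score scales over an underlying continuum.
    """
    arr = np.asarray(v, dtype=float).ravel()
    if k < 2:
        raise InputError("k must be >= 2")
    if np.ptp(arr) == 0.0:
        raise DegenerateInputError("cannot discretize a constant vector")
    lo, hi = arr.min(), arr.max()
    width = (hi - lo) / k
    idx = np.minimum(np.floor((arr - lo) / width).astype(int), k - 1)
    return lo + idx * width


def _setting_distributions(model: DataGeneratingModel, setting: str):
    """Distributions of (x, z) and (e, e_z) under one confounding setting.

    Residual-role draws are always translated to zero mean. Where the
    Gaussian mixture plays the cause role it is used as fitted (the
    statistics are location-invariant).
    """
    exp_spec = model.exo if isinstance(model.exo, ShiftedExponentialSpec) \
        else ShiftedExponentialSpec(0.0, 1.0)
    gm_spec = model.resid
    exp_resid = exp_spec.centered()
    gm_resid = gm_spec.centered()
    if setting == "GM_residual":        # x, z ~ Exp; e, e_z ~ GM
        return exp_spec, exp_spec, gm_resid, gm_resid
    if setting == "Exp_residual":       # roles reversed
        return gm_spec, gm_spec, exp_resid, exp_resid
    if setting == "Different_residuals":  # x, z, e_z ~ Exp; e ~ GM
        return exp_spec, exp_spec, gm_resid, exp_resid
    if setting == "All_GM":
        return gm_spec, gm_spec, gm_resid, gm_resid
    raise InputError(f"unknown setting {setting!r}")


def perturb_confound(model: DataGeneratingModel, lam: float, mode: str,
                     setting: str = "GM_residual", seed=0):
    """Draw a confounded pair (x_conf, y_conf) of length n.

    ``mode='linear'`` mixes the unconfounded structural model with a model
    driven by an unobserved common cause z:

        y_conf = (1-lam)*beta*x + lam*beta*z + e
        x_conf = (1-lam)*x + lam*(beta*z + e_z)

    ``mode='proportional'`` instead draws a Bernoulli(lam) mask per
    observation choosing the fully confounded generator. lam=0 reproduces
    the unconfounded draw exactly; lam=1 makes both variables functions
    of z only.
    """
    if not 0.0 <= lam <= 1.0:
        raise InputError("lam must lie in [0, 1]")
    if mode not in ("linear", "proportional"):
        raise InputError("mode must be 'linear' or 'proportional'")
    rng = np.random.default_rng(seed)
    n, beta = model.n, model.beta
    dist_x, dist_z, dist_e, dist_ez = _setting_distributions(model, setting)
    # x and e first so the lam=0 case consumes the stream like draw_pair
    x = dist_x.draw(rng, n)
    e = dist_e.draw(rng, n)
    z = dist_z.draw(rng, n)
    e_z = dist_ez.draw(rng, n)
    if mode == "linear":
        y_conf = model.intercept + (1 - lam) * beta * x + lam * beta * z + e
        x_conf = (1 - lam) * x + lam * (beta * z + e_z)
    else:
        mask = rng.random(n) < lam
        x_conf = np.where(mask, beta * z + e_z, x)
        y_conf = model.intercept + np.where(mask, beta * z + e, beta * x + e)
    return x_conf, y_conf


def add_measurement_error(x, noise_sd: float, seed=0) -> np.ndarray:
    """Add iid Gaussian noise of the given s.d.; sd=0 returns x unchanged."""
    if noise_sd < 0:
        raise InputError("noise_sd must be nonnegative")
    arr = np.asarray(x, dtype=float).ravel()
    if noise_sd == 0:
        return arr
    rng = np.random.default_rng(seed)
    return arr + rng.normal(0.0, noise_sd, size=arr.size)


# ---------------------------------------------------------------------------
# Estimation success
# ---------------------------------------------------------------------------

def _one_replicate(model: DataGeneratingModel, condition: PerturbationCondition,
                   method: str, rep_seed, **stat_kwargs) -> bool:
    kind = condition.kind
    if kind in ("linear_confound", "proportional_confound"):
        mode = "linear" if kind == "linear_confound" else "proportional"
        x, y = perturb_confound(model, condition.lam, mode,
                                condition.setting, seed=rep_seed)
    else:
        x, e, y = draw_pair(model, seed=rep_seed)
        if kind == "discretize":
            x = discretize(x, condition.k)
            y = discretize(y, condition.k)
        elif kind == "noise" and condition.noise_sd > 0:
            # noise comes after y = beta*x + e, from its own substream
            noise_seed = np.random.SeedSequence([7, hash_seed(rep_seed)])
            x = add_measurement_error(x, condition.noise_sd, seed=noise_seed)
    try:
        stat = compute_statistic(PairedSample(x, y), method, **stat_kwargs)
    except DegenerateInputError:
        return False
    return stat.direction == "first_causes_second"


def hash_seed(seed) -> int:
    """Collapse any seed-like object to a stable 31-bit integer."""
    ss = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    return int(ss.generate_state(1)[0] % (2**31 - 1))


def estimation_success(model: DataGeneratingModel,
                       condition: PerturbationCondition, method: str,
                       reps: int = 1000, seed=0, **stat_kwargs) -> SuccessResult:
    """Proportion of simulated datasets with a correct direction estimate.

    Each replicate simulates one dataset of n observations under the
    condition, applies the statistic, and counts the replicate correct if
    the estimated direction is the generating x -> y (ties count as
    incorrect). Replicates use independent seeded substreams, so the
    result does not depend on execution order.
    """
    if reps < 1:
        raise InputError("reps must be >= 1")
    root = seed if isinstance(seed, np.random.SeedSequence) \
        else np.random.SeedSequence(seed)
    children = root.spawn(reps)
    n_correct = sum(
        _one_replicate(model, condition, method, child, **stat_kwargs)
        for child in children
    )
    return SuccessResult(condition=condition, method=method, reps=reps,
                         n_correct=int(n_correct))


def default_grid(model: DataGeneratingModel,
                 n_lambda: int = 15, n_noise: int = 15,
                 k_range: Iterable[int] = range(2, 16)) -> list[PerturbationCondition]:
    """The full perturbation grid: 14 discretization levels, linear and
    proportional confounding at 15 lambdas under 4 settings each, and 15
    noise levels from 0 to 3 cause-standard-deviations (149 conditions)."""
    conditions = [PerturbationCondition("discretize", k=k) for k in k_range]
    lams = np.linspace(0.0, 1.0, n_lambda)
    for mode in ("linear_confound", "proportional_confound"):
        for setting in SETTINGS:
            conditions += [PerturbationCondition(mode, lam=float(l), setting=setting)
                           for l in lams]
    sd_x = model.exo.sd
    for sd in np.linspace(0.0, 3.0 * sd_x, n_noise):
        conditions.append(PerturbationCondition("noise", noise_sd=float(sd)))
    return conditions


def run_experiment_grid(model: DataGeneratingModel, methods=("lingam", "skew", "tanh"),
                        reps: int = 1000, seed=0,
                        conditions: list[PerturbationCondition] | None = None,
                        **stat_kwargs) -> pd.DataFrame:
    """Estimation success over the full perturbation grid for each method.

    Returns a long-format table with one row per (condition, method);
    deterministic given the master seed, independent of evaluation order.
    """
    if conditions is None:
        conditions = default_grid(model)
    root = np.random.SeedSequence(hash_seed(seed))
    cond_seeds = root.spawn(len(conditions))
    rows = []
    for cond, cseed in zip(conditions, cond_seeds):
        method_seeds = cseed.spawn(len(methods))
        for method, mseed in zip(methods, method_seeds):
            res = estimation_success(model, cond, method, reps=reps,
                                     seed=mseed, **stat_kwargs)
            rows.append({
                "kind": cond.kind, "k": cond.k, "lam": cond.lam,
                "noise_sd": cond.noise_sd, "setting": cond.setting,
                "method": method, "reps": reps,
                "n_correct": res.n_correct, "success": res.success,
            })
    return pd.DataFrame(rows)
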