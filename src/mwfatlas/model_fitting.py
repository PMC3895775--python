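"""Nonlinear least-squares fitting of growth models and BIC model selection.

Regional myelin trajectories — mean MWF per region plotted against each
subject's gestation-corrected age — are fit cross-sectionally by
Levenberg–Marquardt nonlinear least squares.  Because sigmoid fitting is
basin-sensitive, each fit combines a moment-style heuristic initialization
with a seeded Latin-hypercube multi-start; the least-RSS solution over all
starts is returned and is never worse than its starting point.

Competing models are ranked by the Bayesian Information Criterion in its
Gaussian-error nonlinear-regression form,

    BIC = n * ln(RSS / n) + k * ln(n),

with ``k`` the free-parameter count.  The constant term involving the noise
variance is identical across models for shared data and cannot change the
ranking, so it is omitted.  Lower BIC wins; ties are broken by fewer
parameters, then lexicographic model name.
"""

from __future__ import annotations

import dataclasses
import logging
import warnings
from typing import Dict, List, Optional, Sequence, Tuple

import numpy as np
import pandas as pd
from scipy import optimize
from scipy.stats import qmc

from .growth_models import (
    GrowthModel,
    MODEL_REGISTRY,
    evaluate,
    get_model,
    gradient,
)

logger = logging.getLogger(__name__)

__all__ = [
    "TrajectoryData",
    "FitResult",
    "FitOptions",
    "ModelRanking",
    "initialize_params",
    "fit_model",
    "compute_bic",
    "select_model",
    "read_trajectories",
    "write_ranking_csv",
]


@dataclasses.dataclass
class TrajectoryData:
    """Paired (age, MWF) observations for one region.

    Ages are gestation-corrected postnatal ages in days; values are regional
    mean MWF fractions in [0, 1].
    """

    ages: np.ndarray
    values: np.ndarray
    region_label: str = ""
    subject_ids: Optional[Sequence] = None

    def __post_init__(self):
        self.ages = np.asarray(self.ages, dtype=float)
        self.values = np.asarray(self.values, dtype=float)
        if self.ages.shape != self.values.shape or self.ages.ndim != 1:
            raise ValueError("ages and values must be 1-D arrays of equal length")
        if not np.all(np.isfinite(self.ages)) or not np.all(np.isfinite(self.values)):
            raise ValueError("ages and values must be finite")
        if np.any(self.ages <= 0):
            raise ValueError("ages must be positive (days)")
        if np.any((self.values < 0) | (self.values > 1)):
            raise ValueError("MWF values must lie in [0, 1]")

    @property
    def n(self) -> int:
        return self.ages.size


@dataclasses.dataclass
class FitResult:
    """Outcome of fitting one growth model to one trajectory."""

    model: GrowthModel
    params: np.ndarray
    residuals: np.ndarray
    rss: float
    n_obs: int
    bic: float
    converged: bool
    n_iterations: int
    #: post-fit sanity flags (no constraints are imposed during LM; fits
    #: with an implausible scale or a non-monotone trajectory over the data
    #: range are reported, not rejected)
    flags: Tuple[str, ...] = ()

    def predict(self, ages) -> np.ndarray:
        return evaluate(self.model, self.params, ages)

    @property
    def residual_sd(self) -> float:
        """Residual standard deviation, RSS-based with df = n - k."""
        dof = max(self.n_obs - self.model.n_params, 1)
        return float(np.sqrt(self.rss / dof))


@dataclasses.dataclass
class FitOptions:
    """Tolerances and multi-start configuration for Levenberg–Marquardt.

    ``n_starts`` counts the heuristic initialization plus Latin-hypercube
    perturbations of it (log-uniform scale factors in [1/2, 2]); ``ftol``
    is the relative-RSS-change stopping tolerance; ``max_nfev`` caps
    function evaluations per start.
    """

    n_starts: int = 10
    ftol: float = 1e-10
    xtol: float = 1e-12
    max_nfev: int = 2000
    seed: int = 0


@dataclasses.dataclass
class ModelRanking:
    """BIC ranking of candidate models for one region."""

    region_label: str
    entries: List[Tuple[str, float, np.ndarray]]  # (model name, bic, params)
    best_model: str

    @property
    def fits(self) -> Dict[str, float]:
        return {name: bic for name, bic, _ in self.entries}


# ---------------------------------------------------------------------------
# Initialization heuristics
# ---------------------------------------------------------------------------


def _half_rise_age(ages: np.ndarray, values: np.ndarray, plateau: float) -> float:
    """First age at which the trajectory crosses half its plateau."""
    order = np.argsort(ages)
    a, v = ages[order], values[order]
    half = plateau / 2.0
    above = np.flatnonzero(v >= half)
    if above.size == 0:
        return float(a[-1])
    j = above[0]
    if j == 0:
        return float(a[0])
    # linear interpolation between the bracketing observations
    a0, a1, v0, v1 = a[j - 1], a[j], v[j - 1], v[j]
    if v1 == v0:
        return float(a1)
    return float(a0 + (half - v0) * (a1 - a0) / (v1 - v0))


def _gompertz_style_init(data: TrajectoryData, with_delta: bool) -> np.ndarray:
    ages, values = data.ages, data.values
    alpha0 = 1.05 * float(np.max(values))
    # Gompertz linearization: -ln(v/alpha) = exp(beta - gamma*x), so
    # ln(-ln(v/alpha)) is linear in age with slope -gamma.  Use the central
    # tertile of the age range, where the rise is steepest.
    ratio = np.clip(values / alpha0, 1e-9, 1.0 - 1e-9)
    w = np.log(-np.log(ratio))
    lo = ages.min() + (ages.max() - ages.min()) / 3.0
    hi = ages.min() + 2.0 * (ages.max() - ages.min()) / 3.0
    sel = (ages >= lo) & (ages <= hi)
    if sel.sum() < 3:
        sel = np.ones_like(sel)
    slope = np.polyfit(ages[sel], w[sel], 1)[0]
    gamma0 = -slope
    if not np.isfinite(gamma0) or gamma0 <= 0:
        gamma0 = 4.0 / (ages.max() - ages.min())
    beta0 = gamma0 * _half_rise_age(ages, values, alpha0)
    if not with_delta:
        return np.array([alpha0, beta0, gamma0])
    # Late growth: slope of values vs age on the final age quartile.
    q = ages >= ages.min() + 0.75 * (ages.max() - ages.min())
    delta0 = 0.0
    if q.sum() >= 3:
        delta0 = max(0.0, float(np.polyfit(ages[q], values[q], 1)[0]) / alpha0)
    return np.array([alpha0, beta0, gamma0, delta0])


def _logistic_init(data: TrajectoryData) -> np.ndarray:
    ages, values = data.ages, data.values
    alpha0 = 1.05 * float(np.max(values))
    # logit linearization: ln(alpha/v - 1) = beta - gamma*x
    ratio = np.clip(values / alpha0, 1e-9, 1.0 - 1e-9)
    w = np.log(1.0 / ratio - 1.0)
    slope, intercept = np.polyfit(ages, w, 1)
    gamma0 = -slope
    if not np.isfinite(gamma0) or gamma0 <= 0:
        gamma0 = 4.0 / (ages.max() - ages.min())
        intercept = gamma0 * _half_rise_age(ages, values, alpha0)
    return np.array([alpha0, float(intercept), gamma0])


def initialize_params(model: GrowthModel, data: TrajectoryData) -> np.ndarray:
    """Heuristic starting values for Levenberg–Marquardt.

    Moment-style linearizations per family (Gompertz log-log slope, logistic
    logit slope), with the other forms seeded from the logistic solution via
    their approximate reparameterizations.  Returned values are finite and
    evaluable at every observed age.
    """
    if np.ptp(data.values) <= 0:
        raise ValueError("degenerate trajectory: constant MWF values")
    if data.n < model.n_params + 1:
        raise ValueError(
            f"need at least n_params + 1 = {model.n_params + 1} observations "
            f"to fit {model.name} (got {data.n})"
        )
    name = model.name
    if name == "modified_gompertz":
        return _gompertz_style_init(data, with_delta=True)
    if name == "gompertz":
        return _gompertz_style_init(data, with_delta=False)
    aL, bL, gL = _logistic_init(data)
    if name == "logistic":
        return np.array([aL, bL, gL])
    if name == "tanh":
        # alpha/(1+exp(b-gx)) == (alpha/2)*(1 + tanh((gx-b)/2))
        return np.array([aL / 2.0, aL / 2.0, gL / 2.0, bL / 2.0])
    if name == "richards":
        # delta=1 reduces the printed form to a shifted logistic
        return np.array([aL, float(np.exp(np.clip(bL - gL, -50, 50))), gL, 1.0])
    if name == "stannard":
        # delta=1: alpha*(1+exp(-(beta+gamma*x)))^-1 -> beta = -bL
        return np.array([aL, -bL, gL, 1.0])
    if name == "bleasdale_nelder":
        # gamma=1, delta=-1: f = 1/(a + b/x), rising to plateau 1/a
        x_half = _half_rise_age(data.ages, data.values, aL)
        a0 = 1.0 / aL
        return np.array([a0, a0 * max(x_half, 1.0), 1.0, -1.0])
    if name == "general_logistic":
        # beta is both rate and plateau term as printed; choosing beta = rate
        # and gamma = beta - plateau reproduces a logistic curve shape.
        x_half = bL / gL if gL > 0 else float(np.median(data.ages))
        return np.array([1e-3, gL, gL - aL, x_half, 1.0, 1.0])
    raise ValueError(f"no initialization rule for model {name!r}")


# ---------------------------------------------------------------------------
# Levenberg–Marquardt fitting
# ---------------------------------------------------------------------------

_BIG = 1e6  # residual stand-in outside the model's domain


def _residual_fn(model: GrowthModel, x: np.ndarray, y: np.ndarray):
    def fun(p):
        f = evaluate(model, p, x, check_domain=False)
        r = y - f
        r[~np.isfinite(r)] = _BIG
        return r

    return fun


def _jacobian_fn(model: GrowthModel, x: np.ndarray):
    if not model.has_analytic_gradient:
        return "2-point"

    def jac(p):
        J = -gradient(model, p, x, check_domain=False)
        J[~np.isfinite(J)] = 0.0
        return J

    return jac


def _single_fit(
    model: GrowthModel,
    x: np.ndarray,
    y: np.ndarray,
    p0: np.ndarray,
    options: FitOptions,
):
    """One LM solve from one start; returns (params, rss, converged, nfev) or None."""
    fun = _residual_fn(model, x, y)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            res = optimize.least_squares(
                fun,
                p0,
                jac=_jacobian_fn(model, x),
                method="lm",
                ftol=options.ftol,
                xtol=options.xtol,
                max_nfev=options.max_nfev,
            )
    except Exception:
        return None
    if not np.all(np.isfinite(res.x)):
        return None
    rss = float(np.sum(res.fun**2))
    if not np.isfinite(rss) or rss >= _BIG:
        return None
    return res.x, rss, res.status > 0, res.nfev


def _multi_starts(p0: np.ndarray, n_starts: int, seed: int) -> List[np.ndarray]:
    starts = [p0]
    if n_starts > 1:
        sampler = qmc.LatinHypercube(d=p0.size, seed=seed)
        u = sampler.random(n_starts - 1)
        scale = 2.0 ** (2.0 * u - 1.0)  # log-uniform in [1/2, 2]
        for row in scale:
            p = p0 * row
            zero = p0 == 0.0
            p[zero] = (row[zero] - 1.0) * 1e-5  # additive jitter where start is 0
            starts.append(p)
    return starts


def fit_model(
    model: GrowthModel,
    data: TrajectoryData,
    init: Optional[np.ndarray] = None,
    options: Optional[FitOptions] = None,
) -> FitResult:
    """Fit one growth model to one trajectory by multi-start LM least squares.

    Returns the least-RSS solution over all starts; the result is never
    worse than the initialization itself.  ``converged`` is False when no
    start met the stopping tolerance.

    Raises
    ------
    RuntimeError
        If every start produced a non-finite objective.
    """
    options = options or FitOptions()
    if init is None:
        init = initialize_params(model, data)
    init = np.asarray(init, dtype=float)
    if data.n < model.n_params + 1:
        raise ValueError(
            f"need at least {model.n_params + 1} observations to fit {model.name}"
        )
    x, y = data.ages, data.values

    best = None
    total_nfev = 0
    for p0 in _multi_starts(init, options.n_starts, options.seed):
        out = _single_fit(model, x, y, p0, options)
        if out is None:
            continue
        total_nfev += out[3]
        if best is None or out[1] < best[1]:
            best = out
    if best is None:
        raise RuntimeError(
            f"{model.name}: all {options.n_starts} starts produced a "
            "non-finite objective"
        )
    params, rss, converged, _ = best

    # LM must not return a point worse than the initialization.
    r_init = _residual_fn(model, x, y)(init.copy())
    rss_init = float(np.sum(r_init**2))
    if np.isfinite(rss_init) and rss_init < rss:
        params, rss, converged = init, rss_init, False

    residuals = y - evaluate(model, params, x, check_domain=False)
    rss = float(np.sum(residuals**2))
    bic = compute_bic_values(rss, data.n, model.n_params)

    flags = []
    if model.param_symbols[0] == "alpha" and not (0.0 < params[0] < 1.0):
        flags.append("alpha_outside_unit_interval")
    grid = np.linspace(x.min(), x.max(), 200)
    curve = evaluate(model, params, grid, check_domain=False)
    if np.any(np.diff(curve) < -1e-9):
        flags.append("non_monotone_trajectory")
    if flags:
        logger.info("fit sanity flags for %s: %s", data.region_label, flags)

    return FitResult(
        model=model,
        params=np.asarray(params, dtype=float),
        residuals=residuals,
        rss=rss,
        n_obs=data.n,
        bic=bic,
        converged=bool(converged),
        n_iterations=int(total_nfev),
        flags=tuple(flags),
    )


# ---------------------------------------------------------------------------
# BIC
# ---------------------------------------------------------------------------


def compute_bic_values(rss: float, n_obs: int, n_params: int) -> float:
    """BIC = n*ln(RSS/n) + k*ln(n) for Gaussian-error least squares."""
    if n_obs <= n_params:
        raise ValueError("BIC requires n_obs > n_params")
    if rss < 0:
        raise ValueError("RSS must be non-negative")
    if rss == 0:
        logger.warning("perfect fit (RSS=0): BIC is degenerate (-inf)")
        return float("-inf")
    return float(n_obs * np.log(rss / n_obs) + n_params * np.log(n_obs))


def compute_bic(fit: FitResult) -> float:
    """BIC of a fit (see :func:`compute_bic_values`)."""
    return compute_bic_values(fit.rss, fit.n_obs, fit.model.n_params)


# ---------------------------------------------------------------------------
# Model selection
# ---------------------------------------------------------------------------


def select_model(
    data: TrajectoryData,
    models: Optional[Sequence[GrowthModel]] = None,
    options: Optional[FitOptions] = None,
) -> ModelRanking:
    """Fit every candidate model and rank by BIC (ascending).

    Failed fits are kept in the ranking with BIC = +inf.  The best model has
    the minimum BIC; ties are broken by fewer parameters, then name.
    """
    if models is None:
        models = list(MODEL_REGISTRY.values())
    models = [get_model(m) if isinstance(m, str) else m for m in models]
    if len(models) < 2:
        raise ValueError("model selection requires at least 2 candidate models")
    entries = []
    n_failed = 0
    for model in models:
        try:
            fit = fit_model(model, data, options=options)
            entries.append((model.name, fit.bic, fit.params))
        except (ValueError, RuntimeError) as exc:
            logger.info("fit failed for %s on %s: %s", model.name, data.region_label, exc)
            entries.append((model.name, float("inf"), np.full(model.n_params, np.nan)))
            n_failed += 1
    if n_failed == len(models):
        raise RuntimeError(f"all {len(models)} model fits failed for {data.region_label}")
    entries.sort(key=lambda e: (e[1], MODEL_REGISTRY[e[0]].n_params, e[0]))
    return ModelRanking(
        region_label=data.region_label, entries=entries, best_model=entries[0][0]
    )


# ---------------------------------------------------------------------------
# CSV interfaces
# ---------------------------------------------------------------------------


def read_trajectories(path) -> Dict[str, TrajectoryData]:
    """Read a long-format trajectory CSV (subject_id, age_days, region, mwf)."""
    df = pd.read_csv(path)
    required = {"subject_id", "age_days", "region", "mwf"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory CSV missing columns: {sorted(missing)}")
    out = {}
    for region, grp in df.groupby("region", sort=True):
        out[str(region)] = TrajectoryData(
            ages=grp["age_days"].to_numpy(float),
            values=grp["mwf"].to_numpy(float),
            region_label=str(region),
            subject_ids=grp["subject_id"].tolist(),
        )
    return out


def write_ranking_csv(rankings: Sequence[ModelRanking], path) -> pd.DataFrame:
    """Write a regions-by-models BIC table with the best model flagged."""
    rows = []
    for r in rankings:
        row = {"region": r.region_label, **{name: bic for name, bic, _ in r.entries}}
        row["best_model"] = r.best_model
        rows.append(row)
    df = pd.DataFrame(rows).set_index("region")
    df.to_csv(path)
    return df
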