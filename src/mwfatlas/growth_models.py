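"""Sigmoidal growth models for myelin water fraction (MWF) maturation.

Eight functional forms commonly used to describe saturating growth are
registered here, each mapping a gestation-corrected age ``x`` (days) to an
MWF value (dimensionless fraction).  All share the qualitative sigmoid
anatomy — an initial lag, a period of rapid quasi-exponential growth, and a
period of reduced growth — but differ in parameterization and flexibility.

The modified Gompertz,

    f(x) = alpha * exp(-exp(beta - gamma*x) + delta*x),

is the workhorse: the extra linear term ``delta*x`` inside the exponent lifts
the hard asymptote of the classic Gompertz and allows slow continued growth
after the rapid phase, which matches observed myelination beyond ~24 months.
Its four parameters carry direct biological readings (see
:func:`derived_metrics`): ``alpha`` the MWF scale at the transition from
rapid to slow growth, ``beta`` the developmental lag, ``gamma`` the rapid
growth rate (per day), ``delta`` the late slow growth rate (per day).

Two of the registered forms are kept exactly as conventionally printed even
though their parameterizations are awkward: the Richards form reuses
``delta`` as both location and shape, and the general logistic reuses
``beta`` as both plateau term and rate.  They are fit as-is; no silently
"corrected" textbook variants are substituted.
"""

from __future__ import annotations

import dataclasses
from typing import Callable, Dict, Optional, Sequence, Tuple

import numpy as np

__all__ = [
    "GrowthModel",
    "GrowthModelDomainError",
    "DerivedMetrics",
    "MODEL_REGISTRY",
    "MODEL_NAMES",
    "get_model",
    "evaluate",
    "gradient",
    "derived_metrics",
]


class GrowthModelDomainError(ValueError):
    """Raised when a functional form is undefined for given (params, ages).

    Carries ``bad_indices``, the positions in the age vector at which the
    closed form produced an undefined value (typically a fractional power of
    a negative base in the Bleasdale–Nelder, Richards or Stannard forms).
    """

    def __init__(self, model_name: str, bad_indices: np.ndarray):
        self.model_name = model_name
        self.bad_indices = np.asarray(bad_indices)
        shown = self.bad_indices[:10].tolist()
        super().__init__(
            f"{model_name}: functional form undefined at {self.bad_indices.size} "
            f"age element(s), indices {shown}{'...' if self.bad_indices.size > 10 else ''}"
        )


@dataclasses.dataclass(frozen=True)
class GrowthModel:
    """A named sigmoid functional form.

    Attributes
    ----------
    name : str
        Registry name, one of :data:`MODEL_NAMES`.
    param_symbols : tuple of str
        Ordered free-parameter symbols (Greek letters as used in the field).
    """

    name: str
    param_symbols: Tuple[str, ...]
    _func: Callable[[np.ndarray, np.ndarray], np.ndarray] = dataclasses.field(
        repr=False, compare=False
    )
    _grad: Optional[Callable[[np.ndarray, np.ndarray], np.ndarray]] = dataclasses.field(
        default=None, repr=False, compare=False
    )

    @property
    def n_params(self) -> int:
        return len(self.param_symbols)

    @property
    def has_analytic_gradient(self) -> bool:
        return self._grad is not None

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return f"GrowthModel({self.name!r}, params={self.param_symbols})"


@dataclasses.dataclass(frozen=True)
class DerivedMetrics:
    """Biological reading of (modified) Gompertz parameters.

    ``late_growth_rate`` is ``None`` for the classic Gompertz, which has no
    post-transition growth term.
    """

    transition_amplitude: float  # alpha, MWF fraction
    lag_descriptor: float  # beta, dimensionless
    rapid_growth_rate: float  # gamma, per day
    late_growth_rate: Optional[float]  # delta, per day (modified Gompertz only)


# ---------------------------------------------------------------------------
# Functional forms.  Each takes (params, x) with x an ndarray and returns an
# ndarray; domain checking happens in evaluate().
# ---------------------------------------------------------------------------


def _f_gompertz(p, x):
    a, b, g = p
    return a * np.exp(-np.exp(b - g * x))


def _g_gompertz(p, x):
    a, b, g = p
    E = np.exp(b - g * x)
    core = np.exp(-E)
    f = a * core
    return np.stack([core, -f * E, f * x * E], axis=-1)


def _f_modified_gompertz(p, x):
    a, b, g, d = p
    return a * np.exp(-np.exp(b - g * x) + d * x)


def _g_modified_gompertz(p, x):
    a, b, g, d = p
    E = np.exp(b - g * x)
    core = np.exp(-E + d * x)
    f = a * core
    return np.stack([core, -f * E, f * x * E, f * x], axis=-1)


def _f_bleasdale_nelder(p, x):
    a, b, g, d = p
    base = a + b * np.power(x, d)
    return np.power(base, -1.0 / g)


def _f_richards(p, x):
    # As conventionally printed: delta serves as both location and shape.
    a, b, g, d = p
    return a * np.power(1.0 + b * np.exp(g * (d - x)), -1.0 / d)


def _f_stannard(p, x):
    a, b, g, d = p
    return a * np.power(1.0 + np.exp(-(b + g * x) / d), -d)


def _f_tanh(p, x):
    a, b, g, d = p
    return a + b * np.tanh(g * x - d)


def _g_tanh(p, x):
    a, b, g, d = p
    t = np.tanh(g * x - d)
    sech2 = 1.0 - t * t
    ones = np.ones_like(x)
    return np.stack([ones, t, b * x * sech2, -b * sech2], axis=-1)


def _f_logistic(p, x):
    a, b, g = p
    return a / (1.0 + np.exp(b - g * x))


def _g_logistic(p, x):
    a, b, g = p
    s = 1.0 / (1.0 + np.exp(b - g * x))
    asq = a * s * (1.0 - s)
    return np.stack([s, -asq, x * asq], axis=-1)


def _f_general_logistic(p, x):
    # As printed: beta appears both in the plateau term and as the rate.
    a, b, g, d, z, e = p
    return a + (b - g) * np.power(1.0 + z * np.exp(-b * (x - d)), -1.0 / e)


_SPECS = [
    ("gompertz", ("alpha", "beta", "gamma"), _f_gompertz, _g_gompertz),
    (
        "modified_gompertz",
        ("alpha", "beta", "gamma", "delta"),
        _f_modified_gompertz,
        _g_modified_gompertz,
    ),
    ("bleasdale_nelder", ("alpha", "beta", "gamma", "delta"), _f_bleasdale_nelder, None),
    ("richards", ("alpha", "beta", "gamma", "delta"), _f_richards, None),
    ("stannard", ("alpha", "beta", "gamma", "delta"), _f_stannard, None),
    ("tanh", ("alpha", "beta", "gamma", "delta"), _f_tanh, _g_tanh),
    ("logistic", ("alpha", "beta", "gamma"), _f_logistic, _g_logistic),
    (
        "general_logistic",
        ("alpha", "beta", "gamma", "delta", "zeta", "epsilon"),
        _f_general_logistic,
        None,
    ),
]

MODEL_REGISTRY: Dict[str, GrowthModel] = {
    name: GrowthModel(name, symbols, func, grad) for name, symbols, func, grad in _SPECS
}
MODEL_NAMES: Tuple[str, ...] = tuple(MODEL_REGISTRY)


def get_model(name: str) -> GrowthModel:
    """Look up a growth model by its registry name."""
    try:
        return MODEL_REGISTRY[name]
    except KeyError:
        raise KeyError(
            f"unknown growth model {name!r}; available: {', '.join(MODEL_NAMES)}"
        ) from None


def _check_params(model: GrowthModel, params) -> np.ndarray:
    p = np.asarray(params, dtype=float)
    if p.shape != (model.n_params,):
        raise ValueError(
            f"{model.name} expects {model.n_params} parameters, got shape {p.shape}"
        )
    if not np.all(np.isfinite(p)):
        raise ValueError(f"{model.name}: non-finite parameter values {p}")
    return p


def evaluate(model: GrowthModel, params, ages, *, check_domain: bool = True) -> np.ndarray:
    """Evaluate a growth model at the given ages.

    Parameters
    ----------
    model : GrowthModel
    params : array-like of length ``model.n_params``
    ages : array-like
        Gestation-corrected ages in days.
    check_domain : bool
        If True (default), raise :class:`GrowthModelDomainError` listing the
        offending elements when the closed form is undefined (NaN) at finite
        inputs.  Fitting code disables the check and handles non-finite
        residuals itself.

    Returns
    -------
    ndarray of MWF fractions, same shape as ``ages``.
    """
    p = _check_params(model, params)
    x = np.asarray(ages, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
        y = model._func(p, x)
    if check_domain:
        bad = np.flatnonzero(np.isnan(y) & np.isfinite(x))
        if bad.size:
            raise GrowthModelDomainError(model.name, bad)
    return y[0] if scalar else y


def _finite_difference_gradient(model: GrowthModel, p: np.ndarray, x: np.ndarray) -> np.ndarray:
    # Central differences with steps scaled to parameter magnitude.
    out = np.empty(x.shape + (p.size,), dtype=float)
    for i in range(p.size):
        h = 1e-6 * max(abs(p[i]), 1e-3)
        pp, pm = p.copy(), p.copy()
        pp[i] += h
        pm[i] -= h
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out[..., i] = (model._func(pp, x) - model._func(pm, x)) / (2.0 * h)
    return out


def gradient(model: GrowthModel, params, ages, *, check_domain: bool = True) -> np.ndarray:
    """Partial derivatives of the model with respect to its parameters.

    Returns a matrix of shape ``(n_ages, n_params)`` whose entry ``[j, i]``
    is ∂f/∂a_i evaluated at ``ages[j]``.  These are the sensitivities needed
    for first-order (delta-method) propagation of parameter uncertainty into
    predicted-MWF uncertainty.

    Analytic forms are used for gompertz, modified_gompertz, logistic and
    tanh; the remaining forms use verified central finite differences.
    """
    p = _check_params(model, params)
    x = np.asarray(ages, dtype=float)
    scalar = x.ndim == 0
    x = np.atleast_1d(x)
    if model._grad is not None:
        with np.errstate(over="ignore", invalid="ignore", divide="ignore"):
            out = model._grad(p, x)
    else:
        out = _finite_difference_gradient(model, p, x)
    if check_domain:
        bad = np.flatnonzero(np.any(np.isnan(out), axis=-1) & np.isfinite(x))
        if bad.size:
            raise GrowthModelDomainError(model.name, bad)
    return out[0] if scalar else out


def derived_metrics(model: GrowthModel, params) -> DerivedMetrics:
    """Relabel (modified) Gompertz parameters by their biological role.

    A pure identity mapping: ``alpha`` → transition amplitude (the MWF value
    at the transition from rapid to slow growth), ``beta`` → developmental
    lag descriptor, ``gamma`` → rapid growth rate, ``delta`` → late growth
    rate (absent for the classic Gompertz).
    """
    p = _check_params(model, params)
    if model.name == "modified_gompertz":
        return DerivedMetrics(p[0], p[1], p[2], p[3])
    if model.name == "gompertz":
        return DerivedMetrics(p[0], p[1], p[2], None)
    raise ValueError(
        f"derived metrics are defined only for gompertz/modified_gompertz, "
        f"not {model.name!r}"
    )
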