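"""Parametric time-to-event distributions used for survival extrapolation.

Six families are supported, each parameterised the way health-economic
survival extrapolations usually report them:

============  =========================  =============================================
family        parameters                 survival function S(t)
============  =========================  =============================================
exponential   rate λ                     exp(−λt)
weibull       shape k, scale b           exp(−(t/b)^k)
gamma         shape k, scale θ           1 − P(k, t/θ)   (regularised lower gamma)
gompertz      shape a, rate b            exp(−(b/a)(e^{at} − 1))
lognormal     meanlog μ, sdlog σ         1 − Φ((ln t − μ)/σ)
loglogistic   shape a, scale b           1 / (1 + (t/b)^a)
============  =========================  =============================================

Times are in months throughout.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Tuple

import numpy as np
from scipy import special, stats

FAMILIES: Tuple[str, ...] = (
    "exponential",
    "weibull",
    "gamma",
    "gompertz",
    "lognormal",
    "loglogistic",
)

_ARITY = {f: (1 if f == "exponential" else 2) for f in FAMILIES}

# parameter names per family, in order
PARAM_NAMES = {
    "exponential": ("rate",),
    "weibull": ("shape", "scale"),
    "gamma": ("shape", "scale"),
    "gompertz": ("shape", "rate"),
    "lognormal": ("meanlog", "sdlog"),
    "loglogistic": ("shape", "scale"),
}


@dataclass(frozen=True)
class DistSpec:
    """A parametric survival distribution: family name plus ordered parameters.

    ``params`` follows :data:`PARAM_NAMES`; e.g. lognormal is
    ``(meanlog, sdlog)`` and log-logistic is ``(shape, scale)``. The meanlog
    of a lognormal may be any real; every other parameter must be strictly
    positive. The time unit is months.
    """

    family: str
    params: Tuple[float, ...]
    time_unit: str = "months"

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValueError(
                f"unknown distribution family {self.family!r}; "
                f"expected one of {FAMILIES}"
            )
        params = tuple(float(p) for p in self.params)
        object.__setattr__(self, "params", params)
        if len(params) != _ARITY[self.family]:
            raise ValueError(
                f"{self.family} takes {_ARITY[self.family]} parameter(s), "
                f"got {len(params)}"
            )
        for name, value in zip(PARAM_NAMES[self.family], params):
            if not math.isfinite(value):
                raise ValueError(f"{self.family} {name} must be finite")
            # meanlog is a location on the log scale and may be negative
            if name != "meanlog" and value <= 0:
                raise ValueError(
                    f"{self.family} {name} must be strictly positive, got {value}"
                )

    @property
    def n_params(self) -> int:
        return len(self.params)


def survival_at(dist: DistSpec, t) -> np.ndarray | float:
    """Survival probability S(t) at time ``t`` (months, scalar or array).

    S(0) = 1 for every family; raises on negative times.
    """
    t_arr = np.asarray(t, dtype=float)
    if np.any(t_arr < 0):
        raise ValueError("survival requested at negative time")
    with np.errstate(divide="ignore", over="ignore"):
        out = np.exp(-cumulative_hazard(dist, t_arr))
    return out if isinstance(t, np.ndarray) else float(out)


def cumulative_hazard(dist: DistSpec, t) -> np.ndarray:
    """Cumulative hazard H(t) = −ln S(t)."""
    t = np.asarray(t, dtype=float)
    f, p = dist.family, dist.params
    if f == "exponential":
        return p[0] * t
    if f == "weibull":
        return (t / p[1]) ** p[0]
    if f == "gamma":
        sf = special.gammaincc(p[0], t / p[1])
        return -np.log(np.clip(sf, 1e-320, 1.0))
    if f == "gompertz":
        a, b = p
        return (b / a) * np.expm1(a * t)
    if f == "lognormal":
        mu, sd = p
        with np.errstate(divide="ignore"):
            z = (np.log(t) - mu) / sd
        return -stats.norm.logsf(z)
    if f == "loglogistic":
        a, b = p
        return np.log1p((t / b) ** a)
    raise AssertionError(f)


def log_density(dist: DistSpec, t) -> np.ndarray:
    """log f(t), used by the censored likelihood."""
    t = np.asarray(t, dtype=float)
    f, p = dist.family, dist.params
    if f == "exponential":
        return np.log(p[0]) - p[0] * t
    if f == "weibull":
        k, b = p
        return np.log(k / b) + (k - 1) * np.log(t / b) - (t / b) ** k
    if f == "gamma":
        return stats.gamma.logpdf(t, p[0], scale=p[1])
    if f == "gompertz":
        a, b = p
        return np.log(b) + a * t - (b / a) * np.expm1(a * t)
    if f == "lognormal":
        return stats.lognorm.logpdf(t, p[1], scale=math.exp(p[0]))
    if f == "loglogistic":
        a, b = p
        z = np.log(t / b)
        return np.log(a / b) + (a - 1) * z - 2 * np.logaddexp(0.0, a * z)
    raise AssertionError(f)


def log_survival(dist: DistSpec, t) -> np.ndarray:
    return -cumulative_hazard(dist, t)


def quantile(dist: DistSpec, q) -> np.ndarray | float:
    """Inverse CDF: the time t with 1 − S(t) = q."""
    q_arr = np.asarray(q, dtype=float)
    if np.any((q_arr < 0) | (q_arr >= 1)):
        raise ValueError("quantile level must lie in [0, 1)")
    f, p = dist.family, dist.params
    if f == "exponential":
        out = -np.log1p(-q_arr) / p[0]
    elif f == "weibull":
        out = p[1] * (-np.log1p(-q_arr)) ** (1.0 / p[0])
    elif f == "gamma":
        out = stats.gamma.ppf(q_arr, p[0], scale=p[1])
    elif f == "gompertz":
        a, b = p
        out = np.log1p(-np.log1p(-q_arr) * a / b) / a
    elif f == "lognormal":
        out = stats.lognorm.ppf(q_arr, p[1], scale=math.exp(p[0]))
    elif f == "loglogistic":
        a, b = p
        out = b * (q_arr / (1.0 - q_arr)) ** (1.0 / a)
    else:  # pragma: no cover
        raise AssertionError(f)
    return out if isinstance(q, np.ndarray) else float(out)


def median_survival(dist: DistSpec) -> float:
    """The time at which S(t) = 0.5.

    Closed form where available (exponential, weibull, lognormal,
    log-logistic, gompertz); the gamma median comes from the inverse
    regularised incomplete gamma function.
    """
    f, p = dist.family, dist.params
    if f == "exponential":
        return math.log(2.0) / p[0]
    if f == "weibull":
        return p[1] * math.log(2.0) ** (1.0 / p[0])
    if f == "lognormal":
        return math.exp(p[0])
    if f == "loglogistic":
        return p[1]
    if f == "gompertz":
        a, b = p
        return math.log1p(a * math.log(2.0) / b) / a
    return float(quantile(dist, 0.5))
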