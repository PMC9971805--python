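"""Synthetic inputs with known ground truth.

The published analysis starts from digitised Kaplan–Meier curves and a
national life table, neither of which ships with the package. This module
generates stand-ins for every external input — individual patient data
drawn from a known parametric distribution, the Kaplan–Meier curve a
digitiser would trace, digitisation jitter, and a smooth synthetic life
table — so the fitting, selection and cohort stages are testable end to
end with no downloads.

Simulated progression and death times are coupled (death never precedes
progression) so that the implied PFS curve never exceeds the OS curve,
as the partitioned-survival formalism assumes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from lifelines import KaplanMeierFitter

from .distributions import DistSpec, quantile, survival_at
from .survival import KmCurve, LifeTable, PseudoIPD

__all__ = [
    "SimSpec",
    "simulate_ipd",
    "simulate_arm_ipd",
    "km_from_ipd",
    "digitize_noise",
    "synthetic_life_table",
    "default_life_table",
]


@dataclass(frozen=True)
class SimSpec:
    """One simulation recipe: generating distribution, size and censoring.

    ``censoring`` is one of ``none``, ``uniform`` (independent censoring
    times on (0, c)) or ``administrative`` (everyone still at risk is
    censored at T).
    """

    dist: DistSpec
    n: int
    censoring: str = "none"
    censor_param: float | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n < 1:
            raise ValueError("n must be at least 1")
        if self.censoring not in ("none", "uniform", "administrative"):
            raise ValueError(f"unknown censoring scheme {self.censoring!r}")
        if self.censoring != "none":
            if self.censor_param is None or self.censor_param <= 0:
                raise ValueError(
                    "uniform/administrative censoring needs a positive parameter"
                )


def simulate_ipd(spec: SimSpec) -> PseudoIPD:
    """Draw event times by inverse-CDF and apply the censoring scheme."""
    rng = np.random.default_rng(spec.seed)
    u = rng.uniform(size=spec.n)
    times = np.asarray(quantile(spec.dist, u))
    times = np.maximum(times, 1e-12)
    if spec.censoring == "none":
        return PseudoIPD(tuple(times), tuple([True] * spec.n))
    if spec.censoring == "uniform":
        c = rng.uniform(0.0, spec.censor_param, size=spec.n)
    else:  # administrative
        c = np.full(spec.n, float(spec.censor_param))
    c = np.maximum(c, 1e-12)
    events = times <= c
    observed = np.minimum(times, c)
    return PseudoIPD(tuple(observed), tuple(events))


def simulate_arm_ipd(
    pfs_dist: DistSpec,
    os_dist: DistSpec,
    n: int,
    seed: int = 0,
    administrative_censor: float | None = None,
) -> tuple[PseudoIPD, PseudoIPD]:
    """Coupled PFS/OS records for one arm.

    A common uniform draw per subject puts the pair on the same latent
    rank, and the PFS time is clipped at the death time, so per subject
    PFS <= OS and in expectation S_pfs <= S_os.
    """
    rng = np.random.default_rng(seed)
    u_os = rng.uniform(size=n)
    t_os = np.maximum(np.asarray(quantile(os_dist, u_os)), 1e-12)
    u_prog = rng.uniform(size=n)
    t_pfs = np.minimum(np.maximum(np.asarray(quantile(pfs_dist, u_prog)), 1e-12), t_os)
    if administrative_censor is None:
        return (
            PseudoIPD(tuple(t_pfs), tuple([True] * n)),
            PseudoIPD(tuple(t_os), tuple([True] * n)),
        )
    T = float(administrative_censor)
    return (
        PseudoIPD(tuple(np.minimum(t_pfs, T)), tuple(t_pfs <= T)),
        PseudoIPD(tuple(np.minimum(t_os, T)), tuple(t_os <= T)),
    )


def km_from_ipd(data: PseudoIPD) -> KmCurve:
    """Product-limit estimate of the survival curve."""
    if data.n_events < 1:
        raise ValueError("need at least one event for a Kaplan-Meier estimate")
    kmf = KaplanMeierFitter()
    kmf.fit(np.asarray(data.times), np.asarray(data.events, dtype=int))
    sf = kmf.survival_function_
    times = sf.index.to_numpy(dtype=float)
    surv = sf.iloc[:, 0].to_numpy(dtype=float)
    keep = times >= 0
    return KmCurve(tuple(times[keep]), tuple(surv[keep]))


def _isotonic_decreasing(y: np.ndarray) -> np.ndarray:
    """Project onto non-increasing sequences (pool adjacent violators)."""
    y = -np.asarray(y, dtype=float)
    # PAVA for non-decreasing on the negated series
    values = y.copy()
    weights = np.ones_like(y)
    idx = np.arange(y.size)
    blocks = [[v, w, i, i] for v, w, i in zip(values, weights, idx)]
    merged: list[list[float]] = []
    for b in blocks:
        merged.append(list(b))
        while len(merged) > 1 and merged[-2][0] > merged[-1][0]:
            v2, w2, _, e2 = merged.pop()
            v1, w1, s1, _ = merged.pop()
            merged.append([(v1 * w1 + v2 * w2) / (w1 + w2), w1 + w2, s1, e2])
    out = np.empty_like(y)
    for v, _, s, e in merged:
        out[int(s): int(e) + 1] = v
    return -out


def digitize_noise(curve: KmCurve, sd: float, seed: int = 0) -> KmCurve:
    """Emulate digitisation error: Gaussian jitter on the survival
    ordinates, then isotonic projection back onto a valid curve.

    The origin (0, 1) is pinned; output is monotone non-increasing and
    clipped to [0, 1]. ``sd == 0`` is the identity.
    """
    if sd < 0:
        raise ValueError("sd must be non-negative")
    s = np.asarray(curve.survival, dtype=float)
    if sd == 0:
        return curve
    rng = np.random.default_rng(seed)
    noisy = s + rng.normal(0.0, sd, size=s.size)
    noisy[0] = 1.0
    noisy = np.clip(noisy, 0.0, 1.0)
    mono = np.clip(_isotonic_decreasing(noisy), 0.0, 1.0)
    mono[0] = 1.0
    return KmCurve(curve.times, tuple(mono))


def synthetic_life_table(
    age_min: int = 0,
    age_max: int = 110,
    annual_q: float | None = None,
    gompertz_a: float = 3e-5,
    gompertz_b: float = 0.095,
) -> LifeTable:
    """A synthetic life table: constant q if ``annual_q`` is given, else a
    Gompertz schedule q(a) = min(1, a0 * exp(b * age)).

    The default Gompertz coefficients roughly track US adult mortality
    (q ~ 0.01 at age 61 rising to ~0.026 at 71); this is a synthetic
    stand-in for a national table, not published data.
    """
    ages = tuple(range(age_min, age_max + 1))
    if annual_q is not None:
        if not 0.0 <= annual_q <= 1.0:
            raise ValueError("annual_q must lie in [0, 1]")
        q = tuple([float(annual_q)] * len(ages))
    else:
        q = tuple(min(1.0, gompertz_a * math.exp(gompertz_b * a)) for a in ages)
    return LifeTable(ages, q)


def default_life_table() -> LifeTable:
    """The synthetic Gompertz table used by the shipped base case."""
    return synthetic_life_table()


def survival_curve_from_dist(
    dist: DistSpec, t_max_months: float, n_points: int = 120
) -> KmCurve:
    """An exact (noise-free) curve sampled from a parametric distribution,
    shaped like a digitised KM export."""
    times = np.linspace(0.0, t_max_months, n_points + 1)
    surv = np.asarray(survival_at(dist, times))
    return KmCurve(tuple(times), tuple(surv))
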