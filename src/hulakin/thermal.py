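"""Thermal atropisomerization kinetics and Eyring barrier analysis.

Reversible first-order interconversion of an atropisomer pair (the only
thermal chemistry open to the switch; the double bond never isomerizes
thermally) follows

    x(t) = x_eq + (x0 - x_eq) * exp(-(k_fwd + k_rev) * t),

with ``x`` the mole fraction of the starting isomer and
``x_eq = k_rev / (k_fwd + k_rev)``.  Rates convert to free-energy barriers
through the Eyring equation with transmission coefficient 1:

    k = (k_B * T / h) * exp(-dG / (R * T))   <=>   dG = R T ln(k_B T / (h k))

Non-observation of a reaction over a duration ``t_obs`` down to a detection
fraction ``f`` bounds the rate by ``k <= -ln(1 - f) / t_obs`` and hence the
barrier from below.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy.optimize import curve_fit

from .errors import ValidationError

__all__ = [
    "KB",
    "PLANCK_H",
    "GAS_R",
    "KCAL_PER_KJ",
    "ReversibleRatePair",
    "EyringBarrier",
    "ThermalFitResult",
    "fit_reversible_first_order",
    "eyring_barrier",
    "rate_from_barrier",
    "half_life_s",
    "half_life_years",
    "barrier_lower_bound",
    "eyring_regression",
    "celsius_to_kelvin",
]

# CODATA 2018, pinned
KB = 1.380649e-23        # J/K
PLANCK_H = 6.62607015e-34  # J s
GAS_R = 8.31446          # J/(mol K)
KCAL = 4184.0            # J per kcal (thermochemical)
KCAL_PER_KJ = 4.184
SECONDS_PER_YEAR = 365.25 * 86400.0


def celsius_to_kelvin(t_c: float) -> float:
    return t_c + 273.15


@dataclass(frozen=True)
class ReversibleRatePair:
    """Forward/backward first-order rate constants of one atropisomer pair."""

    k_fwd: float  # s^-1, starting isomer -> partner
    k_rev: float  # s^-1, partner -> starting isomer
    temperature_k: float

    def __post_init__(self):
        if self.k_fwd < 0 or self.k_rev < 0:
            raise ValidationError("rate constants must be >= 0")
        if self.temperature_k <= 0:
            raise ValidationError("temperature must be positive")

    @property
    def k_sum(self) -> float:
        return self.k_fwd + self.k_rev

    @property
    def equilibrium_constant(self) -> float:
        if self.k_rev <= 0:
            raise ValidationError("K_eq undefined for k_rev = 0")
        return self.k_fwd / self.k_rev

    @property
    def equilibrium_fraction_start(self) -> float:
        """Equilibrium mole fraction of the starting isomer."""
        return self.k_rev / self.k_sum


@dataclass(frozen=True)
class EyringBarrier:
    """Free energy of activation at a reference temperature (kappa = 1)."""

    delta_g_kj: float
    temperature_k: float

    def __post_init__(self):
        if self.temperature_k <= 0:
            raise ValidationError("temperature must be positive")

    @property
    def delta_g_kcal(self) -> float:
        return self.delta_g_kj / KCAL_PER_KJ

    def rate(self, temperature_k: float | None = None) -> float:
        """First-order rate constant, assuming temperature-independent dG."""
        t = self.temperature_k if temperature_k is None else temperature_k
        return (KB * t / PLANCK_H) * math.exp(-self.delta_g_kj * 1e3 / (GAS_R * t))

    def half_life_s(self, temperature_k: float | None = None) -> float:
        return half_life_s(self.rate(temperature_k))

    def to_dict(self) -> dict:
        return {
            "delta_g_kj_per_mol": self.delta_g_kj,
            "delta_g_kcal_per_mol": self.delta_g_kcal,
            "temperature_k": self.temperature_k,
        }


def eyring_barrier(k: float, temperature_k: float) -> EyringBarrier:
    """Free-energy barrier for a first-order rate constant (exact inverse pair
    with :func:`rate_from_barrier`)."""
    if not (k > 0):
        raise ValidationError("rate constant must be strictly positive")
    if temperature_k <= 0:
        raise ValidationError("temperature must be positive")
    dg = GAS_R * temperature_k * math.log(KB * temperature_k / (PLANCK_H * k))
    return EyringBarrier(dg / 1e3, temperature_k)


def rate_from_barrier(barrier: EyringBarrier, temperature_k: float | None = None) -> float:
    return barrier.rate(temperature_k)


def half_life_s(rate) -> float:
    """Half-life of a first-order process; for a reversible pair this is the
    half-life of the approach to equilibrium, ln 2 / (k_fwd + k_rev)."""
    k = rate.k_sum if isinstance(rate, ReversibleRatePair) else float(rate)
    if k < 0:
        raise ValidationError("rate must be >= 0")
    return math.inf if k == 0 else math.log(2.0) / k


def half_life_years(rate) -> float:
    return half_life_s(rate) / SECONDS_PER_YEAR


def half_life_hours(rate) -> float:
    return half_life_s(rate) / 3600.0


@dataclass
class ThermalFitResult:
    rates: ReversibleRatePair
    x0: float
    x_eq: float
    stderr_k_sum: float
    rss: float
    unidentifiable: bool
    warnings: list


def fit_reversible_first_order(
    times_s,
    x_start,
    temperature_k: float,
) -> ThermalFitResult:
    """Fit a reversible first-order decay to the starting isomer's fraction.

    ``x_start`` is the mole fraction of the starting isomer of the pair at
    the times ``times_s``.  Fits ``x0``, ``x_eq`` and the relaxation rate
    ``k_sum = k_fwd + k_rev``; the individual rates follow from
    ``x_eq = k_rev / k_sum``.  Data that never decay (flat, or starting at
    equilibrium) leave ``k_sum`` unidentifiable; the result is flagged with
    a wide-uncertainty warning instead of raising.
    """
    t = np.asarray(times_s, dtype=float)
    x = np.asarray(x_start, dtype=float)
    if t.ndim != 1 or t.shape != x.shape or t.size < 3:
        raise ValidationError("need >= 3 paired (time, fraction) observations")
    if np.any(np.diff(t) <= 0):
        raise ValidationError("times must be strictly increasing")
    if np.any((x < -1e-9) | (x > 1 + 1e-9)):
        raise ValidationError("fractions must lie in [0, 1]")
    warnings: list = []

    span = float(x.max() - x.min())
    if span < 1e-10:
        warnings.append("non-decaying data: rate unidentifiable, returning k ~ 0")
        pair = ReversibleRatePair(0.0, 0.0, temperature_k)
        return ThermalFitResult(pair, float(x[0]), float(x[-1]), math.inf,
                                0.0, True, warnings)

    def model(tt, x0, x_eq, k_sum):
        return x_eq + (x0 - x_eq) * np.exp(-k_sum * tt)

    k_guess = 1.0 / max(t[-1] / 3.0, 1e-12)
    # crude guess: time to cover ~2/3 of the observed span
    idx = np.argmin(np.abs((x - x[-1]) / (x[0] - x[-1] + 1e-30) - math.exp(-1)))
    if t[idx] > 0:
        k_guess = 1.0 / t[idx]
    p0 = [float(x[0]), float(x[-1]), k_guess]
    popt, pcov = curve_fit(
        model, t, x, p0=p0,
        bounds=([0.0, 0.0, 0.0], [1.0, 1.0, np.inf]),
        maxfev=20000,
    )
    x0_fit, xeq_fit, k_sum = map(float, popt)
    stderr = float(np.sqrt(max(pcov[2, 2], 0.0))) if np.all(np.isfinite(pcov)) else math.inf
    rss = float(np.sum((model(t, *popt) - x) ** 2))
    unident = not math.isfinite(stderr) or (k_sum > 0 and stderr / k_sum > 10)
    if unident:
        warnings.append("relaxation rate poorly identified (wide uncertainty)")
    k_rev = k_sum * xeq_fit
    k_fwd = k_sum - k_rev
    pair = ReversibleRatePair(max(k_fwd, 0.0), max(k_rev, 0.0), temperature_k)
    return ThermalFitResult(pair, x0_fit, xeq_fit, stderr, rss, unident, warnings)


def barrier_lower_bound(
    duration_s: float,
    temperature_k: float,
    detection_fraction: float = 0.05,
) -> EyringBarrier:
    """Minimum barrier consistent with seeing no reaction.

    If a conversion of at least ``detection_fraction`` would have been
    detected over ``duration_s`` at ``temperature_k`` but none was, the rate
    is at most ``-ln(1 - f)/duration`` and the barrier at least the returned
    value.  The bound grows with duration (by R T ln 2 per doubling) and
    shrinks as the detection limit loosens.
    """
    if not (0.0 < detection_fraction < 1.0):
        raise ValidationError("detection_fraction must lie strictly in (0, 1)")
    if duration_s <= 0:
        raise ValidationError("duration must be positive")
    k_max = -math.log(1.0 - detection_fraction) / duration_s
    return eyring_barrier(k_max, temperature_k)


def eyring_regression(rates, temperatures_k) -> tuple[float, float]:
    """Enthalpy/entropy of activation from rates at >= 2 temperatures.

    Linear regression of ``ln(k h / (k_B T))`` on ``1/T`` gives
    ``dH`` (kJ/mol) from the slope and ``dS`` (J/(mol K)) from the intercept.
    """
    k = np.asarray(rates, dtype=float)
    temp = np.asarray(temperatures_k, dtype=float)
    if k.shape != temp.shape or k.size < 2:
        raise ValidationError("need rates at >= 2 temperatures")
    if np.any(k <= 0) or np.any(temp <= 0):
        raise ValidationError("rates and temperatures must be positive")
    y = np.log(k * PLANCK_H / (KB * temp))
    slope, intercept = np.polyfit(1.0 / temp, y, 1)
    delta_h_kj = -slope * GAS_R / 1e3
    delta_s = intercept * GAS_R
    return float(delta_h_kj), float(delta_s)
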