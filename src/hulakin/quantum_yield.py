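"""Quantum-yield determination from composition time courses.

A quantum yield Phi_ij is defined operationally: moles of product j formed
per einstein of photons absorbed by reactant i.  Two estimators are offered.

``early_slope`` mirrors the early-time product-identification argument: while
the photoproducts are still too dilute to absorb appreciably, every absorbed
photon is attributed to the starting isomer, and Phi_ij is the regression
slope of product moles against cumulative absorbed einsteins within that
window.

``full_ode_fit`` (default) fits the full photokinetic master equation to all
series simultaneously with every off-diagonal Phi as a free parameter; it
inherently accounts for photoproduct absorption and back-reaction and is
therefore preferred once conversion leaves the early-time regime.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ValidationError
from .photokin import (
    CompositionSeries,
    PhotoConditions,
    QuantumYieldMatrix,
    excitation_rates,
    simulate_photokinetics,
)
from .states import ISOMERS, Isomer

__all__ = [
    "PhotonLedger",
    "build_photon_ledger",
    "early_time_window",
    "QuantumYieldEstimate",
    "estimate_quantum_yields",
]


@dataclass(frozen=True)
class PhotonLedger:
    """Per-interval photon bookkeeping for one irradiation series.

    ``absorbed`` attributes the einsteins absorbed in each observation
    interval to the four isomers via the absorbance-partition formula
    (trapezoidal in time); ``delta_moles`` is the net mole change of each
    isomer over the same interval.
    """

    interval_times_s: np.ndarray  # (n-1, 2) interval boundaries
    absorbed: np.ndarray          # (n-1, 4) einsteins per isomer
    delta_moles: np.ndarray       # (n-1, 4) net mole change per isomer

    def __post_init__(self):
        if np.any(self.absorbed < -1e-15):
            raise ValidationError("absorbed photon counts must be non-negative")


def build_photon_ledger(
    series: CompositionSeries, cond: PhotoConditions, mode: str = "partition"
) -> PhotonLedger:
    """Count absorbed photons per isomer per observation interval."""
    t_s = series.times_min * 60.0
    rates = np.array([excitation_rates(x, cond, mode=mode) for x in series.fractions])
    dt = np.diff(t_s)[:, None]
    absorbed = 0.5 * (rates[:-1] + rates[1:]) * dt  # trapezoid, einstein
    delta = np.diff(series.fractions, axis=0) * cond.total_moles
    bounds = np.column_stack([t_s[:-1], t_s[1:]])
    return PhotonLedger(bounds, absorbed, delta)


def early_time_window(
    series: CompositionSeries,
    cond: PhotoConditions,
    threshold: float = 0.05,
) -> slice:
    """Maximal initial window where photoproducts stay optically negligible.

    Requires the series to start at least 99% pure in one isomer.  Returns
    the index slice of the leading time points in which the photoproducts'
    share of the total absorbance stays below ``threshold``; the first point
    is always included, so ``threshold = 0`` yields a length-1 window.
    """
    x0 = series.fractions[0]
    start_idx = int(np.argmax(x0))
    if x0[start_idx] < 0.99:
        raise ValidationError(
            f"series must start >= 99% pure in one isomer, got {x0[start_idx]:.3f}"
        )
    a = series.fractions * (cond.epsilon * cond.path_length_cm * cond.total_conc)
    a_tot = a.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        product_share = np.where(a_tot > 0, (a_tot - a[:, start_idx]) / a_tot, 0.0)
    end = 1
    for k in range(1, len(series)):
        if product_share[k] >= threshold:
            break
        end = k + 1
    return slice(0, end)


@dataclass
class QuantumYieldEstimate:
    matrix: QuantumYieldMatrix
    stderr: np.ndarray | None
    method: str
    rss: float = 0.0
    warnings: list[str] = field(default_factory=list)
    fitted_rows: list[Isomer] = field(default_factory=list)

    def channel(self, src, dst) -> float:
        return self.matrix.channel(src, dst)


def _early_slope_row(
    series: CompositionSeries, cond: PhotoConditions, threshold: float, mode: str
) -> tuple[int, np.ndarray, list[str]]:
    """Estimate one source row of Phi from a single pure-start series."""
    warnings: list[str] = []
    win = early_time_window(series, cond, threshold)
    n_win = win.stop - win.start
    if n_win < 3:
        raise ValidationError(
            f"early-time window has {n_win} point(s); need >= 3 for a slope regression"
        )
    sub = CompositionSeries(
        series.times_min[win] - series.times_min[win.start],
        series.fractions[win],
    )
    src = int(np.argmax(series.fractions[0]))
    ledger = build_photon_ledger(sub, cond, mode=mode)
    absorbed_src = np.cumsum(ledger.absorbed[:, src])
    formed = np.cumsum(ledger.delta_moles, axis=0)  # moles of each product
    denom = float(np.sum(absorbed_src ** 2))
    row = np.zeros(4)
    if denom <= 0:
        return src, row, warnings  # nothing absorbed -> all yields zero
    for j in range(4):
        if j == src:
            continue
        phi = float(np.sum(absorbed_src * formed[:, j]) / denom)
        if phi < 0:
            warnings.append(f"negative early-slope yield clamped to 0 for channel {j}")
            phi = 0.0
        row[j] = min(phi, 1.0)
    return src, row, warnings


def estimate_quantum_yields(
    series_list: "list[CompositionSeries]",
    cond: PhotoConditions,
    method: str = "full_ode_fit",
    threshold: float = 0.05,
    mode: str = "partition",
    n_boot: int = 0,
    seed: int = 0,
) -> QuantumYieldEstimate:
    """Estimate the per-channel quantum-yield matrix from irradiation series.

    Each series must start from (nearly) pure isomer; together they constrain
    the rows of Phi corresponding to the isomers that become populated.  See
    the module docstring for the two methods.  ``n_boot > 0`` adds a seeded
    residual-bootstrap standard error on each entry (full_ode_fit only);
    otherwise full_ode_fit reports Jacobian-based standard errors.
    """
    if not series_list:
        raise ValidationError("at least one series is required")
    if method == "early_slope":
        phi = np.zeros((4, 4))
        warnings: list[str] = []
        fitted = []
        for s in series_list:
            src, row, w = _early_slope_row(s, cond, threshold, mode)
            phi[src] = row
            fitted.append(ISOMERS[src])
            warnings.extend(w)
        return QuantumYieldEstimate(QuantumYieldMatrix(phi), None, method,
                                    warnings=warnings, fitted_rows=fitted)
    if method != "full_ode_fit":
        raise ValidationError(f"unknown method {method!r}")
    return _full_ode_fit(series_list, cond, threshold, mode, n_boot, seed)


_OFFDIAG = [(i, j) for i in range(4) for j in range(4) if i != j]


def _phi_from_params(p: np.ndarray, channels: list[tuple[int, int]]) -> np.ndarray:
    phi = np.zeros((4, 4))
    for val, (i, j) in zip(p, channels):
        phi[i, j] = val
    return phi


def _full_ode_fit(
    series_list, cond, threshold, mode, n_boot, seed
) -> QuantumYieldEstimate:
    warnings: list[str] = []
    # only rows of isomers that ever appear can be constrained
    populated = np.zeros(4, dtype=bool)
    for s in series_list:
        populated |= s.fractions.max(axis=0) >= 0.01
    channels = [(i, j) for (i, j) in _OFFDIAG if populated[i]]
    fitted_rows = [ISOMERS[i] for i in range(4) if populated[i]]
    if len(fitted_rows) < 4:
        warnings.append(
            "rows never populated left at zero: "
            + ",".join(iso.value for iso in ISOMERS if iso not in fitted_rows)
        )

    # initial guess from the early-slope estimator where available
    p0 = np.full(len(channels), 1e-3)
    for s in series_list:
        try:
            src, row, _ = _early_slope_row(s, cond, threshold, mode)
        except ValidationError:
            continue
        for k, (i, j) in enumerate(channels):
            if i == src:
                p0[k] = np.clip(row[j], 1e-6, 0.99)

    def residuals(p: np.ndarray) -> np.ndarray:
        phi = _phi_from_params(p, channels)
        out = []
        for s in series_list:
            sim = simulate_photokinetics(s.fractions[0], phi, cond, s.times_min, mode=mode)
            out.append((sim.fractions - s.fractions).ravel())
        return np.concatenate(out)

    res = least_squares(
        residuals, p0, bounds=(0.0, 1.0), method="trf",
        x_scale="jac", diff_step=1e-6,
        ftol=1e-14, xtol=1e-14, gtol=1e-14, max_nfev=400,
    )
    phi = _phi_from_params(res.x, channels)
    rss = float(2.0 * res.cost)

    stderr = np.zeros((4, 4))
    m_obs, n_par = res.jac.shape
    if m_obs > n_par:
        s2 = rss / (m_obs - n_par)
        try:
            cov = np.linalg.pinv(res.jac.T @ res.jac) * s2
            for k, (i, j) in enumerate(channels):
                stderr[i, j] = np.sqrt(max(cov[k, k], 0.0))
        except np.linalg.LinAlgError:  # pragma: no cover
            stderr = None

    if n_boot > 0:
        rng = np.random.default_rng(seed)
        resid = residuals(res.x)
        draws = np.empty((n_boot, len(channels)))
        lengths = [s.fractions.size for s in series_list]
        for b in range(n_boot):
            shuffled = rng.choice(resid, size=resid.size, replace=True)
            synth, pos = [], 0
            for s, n in zip(series_list, lengths):
                pert = s.fractions + shuffled[pos:pos + n].reshape(s.fractions.shape)
                synth.append(CompositionSeries.normalized(s.times_min, pert))
                pos += n
            def boot_res(p, synth=synth):
                phi_b = _phi_from_params(p, channels)
                out = []
                for s in synth:
                    sim = simulate_photokinetics(s.fractions[0], phi_b, cond, s.times_min, mode=mode)
                    out.append((sim.fractions - s.fractions).ravel())
                return np.concatenate(out)
            rb = least_squares(boot_res, res.x, bounds=(0.0, 1.0), method="trf",
                               x_scale="jac", diff_step=1e-6, max_nfev=100)
            draws[b] = rb.x
        stderr = np.zeros((4, 4))
        sd = draws.std(axis=0, ddof=1)
        for k, (i, j) in enumerate(channels):
            stderr[i, j] = sd[k]

    return QuantumYieldEstimate(
        QuantumYieldMatrix(phi), stderr, "full_ode_fit",
        rss=rss, warnings=warnings, fitted_rows=fitted_rows,
    )
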