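"""Continuous-time photokinetics of the four-state switch under monochromatic light.

The forward model tracks the mole-fraction vector ``x = (x_A, x_B, x_C, x_D)``
of a closed, well-stirred solution under constant irradiation.  Photons enter
at a flux ``F`` (einstein/s); a fraction ``1 - 10^(-A_tot)`` of them is
absorbed (the photokinetic factor) and partitioned among the isomers in
proportion to their absorbance contribution ``A_i = eps_i * l * c_tot * x_i``:

    rate_i = F * (A_i / A_tot) * (1 - 10^(-A_tot))        [einstein/s]

Each isomer then branches into its photoproducts with the per-channel quantum
yields ``phi[i][j]`` (molecules converted per einstein absorbed by i):

    dn_i/dt = sum_{j != i} ( phi[j][i] * rate_j - phi[i][j] * rate_i )

Total moles are conserved exactly by this master equation, so the model is
integrated directly in mole fractions.  Times are minutes at the interface
and seconds internally; photon flux is einstein/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import solve_ivp

from .errors import ConvergenceError, ValidationError
from .states import ISOMERS, Isomer, as_isomer

__all__ = [
    "PhotoConditions",
    "QuantumYieldMatrix",
    "CompositionSeries",
    "excitation_rates",
    "simulate_photokinetics",
    "photostationary_state",
]

_LN10 = np.log(10.0)


@dataclass(frozen=True)
class PhotoConditions:
    """Irradiation condition descriptor.

    Parameters
    ----------
    wavelength_nm : irradiation wavelength (bookkeeping only).
    photon_flux : photon flux entering the sample, einstein/s.
    path_length_cm : optical path length, cm.
    volume_l : sample volume, L.
    epsilon : per-isomer molar absorption coefficients at the irradiation
        wavelength, L mol^-1 cm^-1, in A,B,C,D order.
    total_conc : total chromophore concentration, mol/L.
    """

    wavelength_nm: float
    photon_flux: float
    path_length_cm: float
    volume_l: float
    epsilon: np.ndarray
    total_conc: float

    def __post_init__(self):
        eps = np.asarray(self.epsilon, dtype=float)
        if eps.shape != (4,):
            raise ValidationError("epsilon must be a length-4 vector (A,B,C,D order)")
        if np.any(eps < 0) or not np.all(np.isfinite(eps)):
            raise ValidationError("epsilon entries must be finite and >= 0")
        object.__setattr__(self, "epsilon", eps)
        for name in ("wavelength_nm", "photon_flux", "path_length_cm", "volume_l", "total_conc"):
            v = getattr(self, name)
            if not (np.isfinite(v) and v > 0):
                raise ValidationError(f"{name} must be strictly positive, got {v!r}")

    @property
    def total_moles(self) -> float:
        """Total chromophore amount, mol."""
        return self.total_conc * self.volume_l

    def to_dict(self) -> dict:
        return {
            "wavelength_nm": self.wavelength_nm,
            "photon_flux": self.photon_flux,
            "path_length_cm": self.path_length_cm,
            "volume_l": self.volume_l,
            "epsilon": list(map(float, self.epsilon)),
            "total_conc": self.total_conc,
        }

    @classmethod
    def from_dict(cls, d: dict) -> "PhotoConditions":
        return cls(
            wavelength_nm=float(d["wavelength_nm"]),
            photon_flux=float(d["photon_flux"]),
            path_length_cm=float(d["path_length_cm"]),
            volume_l=float(d["volume_l"]),
            epsilon=np.asarray(d["epsilon"], dtype=float),
            total_conc=float(d["total_conc"]),
        )


@dataclass(frozen=True)
class QuantumYieldMatrix:
    """Per-channel photoisomerization quantum yields Phi[i][j] (fractions).

    ``phi[i, j]`` is the probability that a photon absorbed by isomer ``i``
    converts it into isomer ``j``.  Diagonal entries are 0 by convention;
    each row sum must not exceed 1 (the remainder is unreactive decay).
    """

    phi: np.ndarray

    def __post_init__(self):
        p = np.asarray(self.phi, dtype=float)
        if p.shape != (4, 4):
            raise ValidationError("phi must be a 4x4 matrix")
        if np.any(p < 0) or np.any(p > 1) or not np.all(np.isfinite(p)):
            raise ValidationError("phi entries must be finite and in [0, 1]")
        if np.any(np.abs(np.diag(p)) > 0):
            raise ValidationError("diagonal quantum yields must be 0")
        if np.any(p.sum(axis=1) > 1 + 1e-12):
            raise ValidationError("quantum-yield row sums must not exceed 1")
        object.__setattr__(self, "phi", p)

    @classmethod
    def from_channels(cls, channels: dict) -> "QuantumYieldMatrix":
        """Build from a ``{(src, dst): value}`` mapping (fractions)."""
        p = np.zeros((4, 4))
        for (src, dst), val in channels.items():
            i, j = as_isomer(src).index, as_isomer(dst).index
            if i == j:
                raise ValidationError("diagonal channel not allowed")
            p[i, j] = float(val)
        return cls(p)

    def channel(self, src: "Isomer | str", dst: "Isomer | str") -> float:
        return float(self.phi[as_isomer(src).index, as_isomer(dst).index])


@dataclass(frozen=True)
class CompositionSeries:
    """Time-stamped mole-fraction vectors in A,B,C,D order (the NMR observable).

    ``times_min`` is monotone increasing and starts at 0; every row of
    ``fractions`` is non-negative and sums to 1 within 1e-9.
    """

    times_min: np.ndarray
    fractions: np.ndarray
    start: Isomer | None = None
    label: str | None = None

    def __post_init__(self):
        t = np.asarray(self.times_min, dtype=float)
        x = np.asarray(self.fractions, dtype=float)
        if t.ndim != 1 or x.shape != (t.size, 4):
            raise ValidationError("times must be 1-D and fractions (n, 4)")
        if t.size == 0:
            raise ValidationError("series must contain at least one time point")
        if abs(t[0]) > 1e-12:
            raise ValidationError("first time point must be 0")
        if np.any(np.diff(t) <= 0):
            raise ValidationError("times must be strictly increasing")
        if np.any(x < -1e-9):
            raise ValidationError("negative mole fraction")
        x = np.clip(x, 0.0, None)
        sums = x.sum(axis=1)
        if np.any(np.abs(sums - 1.0) > 1e-9):
            raise ValidationError(
                "mole-fraction rows must sum to 1 within 1e-9 "
                "(use CompositionSeries.normalized to renormalize)"
            )
        object.__setattr__(self, "times_min", t)
        object.__setattr__(self, "fractions", x)
        if self.start is not None:
            object.__setattr__(self, "start", as_isomer(self.start))

    @classmethod
    def normalized(cls, times_min, fractions, start=None, label=None) -> "CompositionSeries":
        """Construct after clipping to [0, 1] and renormalizing each row."""
        x = np.clip(np.asarray(fractions, dtype=float), 0.0, 1.0)
        sums = x.sum(axis=1, keepdims=True)
        if np.any(sums <= 0):
            raise ValidationError("cannot normalize an all-zero composition row")
        return cls(np.asarray(times_min, dtype=float), x / sums, start=start, label=label)

    def __len__(self) -> int:
        return int(self.times_min.size)

    def fraction_of(self, label: "Isomer | str") -> np.ndarray:
        return self.fractions[:, as_isomer(label).index]


def _as_composition(x) -> np.ndarray:
    x = np.asarray(x, dtype=float)
    if x.shape != (4,):
        raise ValidationError("composition must be a length-4 vector")
    if np.any(x < -1e-12):
        raise ValidationError("negative composition entry")
    x = np.clip(x, 0.0, None)
    if abs(x.sum() - 1.0) > 1e-6:
        raise ValidationError(f"composition must sum to 1, got {x.sum():.8f}")
    return x


def excitation_rates(
    x, cond: PhotoConditions, mode: str = "partition"
) -> np.ndarray:
    """Per-isomer absorbed-photon rates, einstein/s.

    ``mode="partition"`` (default) applies the photokinetic factor
    ``1 - 10^(-A_tot)`` to the incident flux before partitioning by the
    absorbance fractions ``A_i / A_tot``; ``mode="total"`` assumes every
    incident photon is absorbed (optically thick sample).  A fully
    transparent sample (A_tot = 0) absorbs nothing in either mode.
    """
    x = _as_composition(x)
    a = cond.epsilon * cond.path_length_cm * cond.total_conc * x
    a_tot = float(a.sum())
    if a_tot <= 0.0:
        return np.zeros(4)
    if mode == "partition":
        absorbed = cond.photon_flux * (1.0 - 10.0 ** (-a_tot))
    elif mode == "total":
        absorbed = cond.photon_flux
    else:
        raise ValidationError(f"unknown absorption mode {mode!r}")
    return absorbed * (a / a_tot)


def _rates_raw(x: np.ndarray, cond: PhotoConditions, mode: str) -> np.ndarray:
    # validation-free hot path used inside the ODE right-hand side
    a = cond.epsilon * cond.path_length_cm * cond.total_conc * np.clip(x, 0.0, None)
    a_tot = a.sum()
    if a_tot <= 0.0:
        return np.zeros(4)
    absorbed = cond.photon_flux if mode == "total" else cond.photon_flux * (1.0 - 10.0 ** (-a_tot))
    return absorbed * (a / a_tot)


def _rhs_factory(phi: np.ndarray, cond: PhotoConditions, mode: str):
    n_tot = cond.total_moles
    loss = phi.sum(axis=1)  # total reactive yield per isomer

    def rhs(_t, x):
        r = _rates_raw(x, cond, mode)
        return (phi.T @ r - loss * r) / n_tot

    return rhs


def simulate_photokinetics(
    x0,
    phi: "QuantumYieldMatrix | np.ndarray",
    cond: PhotoConditions,
    times_min,
    mode: str = "partition",
    rtol: float = 1e-8,
    atol: float = 1e-10,
    start: "Isomer | str | None" = None,
    label: str | None = None,
) -> CompositionSeries:
    """Integrate the photokinetic master equation and sample at ``times_min``.

    Quantum yields span orders of magnitude, so a stiff-safe LSODA
    integration with tight tolerances (rtol 1e-8, atol 1e-10) is used.
    Total moles are conserved by construction; output fractions are clamped
    at 0 and renormalized at the 1e-12 level.
    """
    x0 = _as_composition(x0)
    p = phi.phi if isinstance(phi, QuantumYieldMatrix) else QuantumYieldMatrix(np.asarray(phi, float)).phi
    t = np.asarray(times_min, dtype=float)
    if t.ndim != 1 or t.size == 0 or abs(t[0]) > 1e-12 or np.any(np.diff(t) <= 0):
        raise ValidationError("times must be monotone increasing from 0")
    t_s = t * 60.0
    if t_s[-1] == 0.0 or not np.any(p):
        frac = np.tile(x0, (t.size, 1))
        return CompositionSeries(t, frac, start=start, label=label)
    sol = solve_ivp(
        _rhs_factory(p, cond, mode),
        (0.0, t_s[-1]),
        x0,
        t_eval=t_s,
        method="LSODA",
        rtol=rtol,
        atol=atol,
    )
    if not sol.success:
        raise ConvergenceError(
            f"photokinetic integration failed: {sol.message}",
            diagnostics={"status": sol.status, "t_reached": float(sol.t[-1]) if sol.t.size else 0.0},
        )
    return CompositionSeries.normalized(t, sol.y.T, start=start, label=label)


def photostationary_state(
    phi: "QuantumYieldMatrix | np.ndarray",
    cond: PhotoConditions,
    x0=None,
    tol: float = 1e-10,
    max_chunks: int = 60,
    mode: str = "partition",
) -> np.ndarray:
    """Composition at which opposing photoreactions balance (dx/dt = 0).

    Found by integrating from ``x0`` (uniform by default) over geometrically
    growing time chunks until the composition change per chunk falls below
    ``tol``.  Raises :class:`ConvergenceError` if the cap is reached, e.g.
    when the chain on the reachable set is not settling.
    """
    p = phi.phi if isinstance(phi, QuantumYieldMatrix) else QuantumYieldMatrix(np.asarray(phi, float)).phi
    x = _as_composition(x0) if x0 is not None else np.full(4, 0.25)
    if not np.any(p):
        return x
    # characteristic conversion rate sets the initial chunk length
    k_scale = cond.photon_flux * max(p.sum(axis=1).max(), 1e-30) / cond.total_moles
    chunk = 10.0 / k_scale
    rhs = _rhs_factory(p, cond, mode)
    for _ in range(max_chunks):
        sol = solve_ivp(rhs, (0.0, chunk), x, method="LSODA", rtol=1e-10, atol=1e-12)
        if not sol.success:
            raise ConvergenceError(f"integration failed: {sol.message}")
        x_new = np.clip(sol.y[:, -1], 0.0, None)
        x_new = x_new / x_new.sum()
        delta = float(np.abs(x_new - x).max())
        x = x_new
        if delta < tol and float(np.abs(rhs(0.0, x)).max()) * chunk < tol:
            return x
        chunk *= 2.0
    raise ConvergenceError(
        "photostationary state did not converge",
        diagnostics={"last_delta": delta, "x": x.tolist()},
    )
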