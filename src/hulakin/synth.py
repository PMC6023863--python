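"""Seeded synthetic-data generation for every input the fitters consume.

The generators emulate the study design: irradiation of each pure isomer
followed by periodic composition readings (NMR integrals, modelled as
Gaussian mole-fraction noise with clip-and-renormalize), reversible
first-order thermal decays, per-condition single-source datasets defined by
motion-type shares, and two-component spectra series with isosbestic points.

Shipped presets encode the published benzene quantum-yield set and the
per-condition motion shares (solvent, temperature, and rigid-matrix
variations) as ground truths for recovery tests.  All generators are
bit-reproducible for a fixed seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ValidationError
from .markov import TransitionMatrix, propagate
from .photokin import (
    CompositionSeries,
    PhotoConditions,
    QuantumYieldMatrix,
    simulate_photokinetics,
)
from .spectra import SpectraSeries
from .states import ISOMERS, Isomer, Motion, as_isomer, motion_partner

__all__ = [
    "NoiseModel",
    "ConditionPreset",
    "BENZENE_PHOTO",
    "BENZENE_PHI",
    "PRESETS",
    "SHARE_PRESETS",
    "SharePreset",
    "generate_photokinetic_dataset",
    "generate_share_dataset",
    "generate_thermal_dataset",
    "generate_two_component_spectra",
]

DEFAULT_SEED = 20180628


@dataclass(frozen=True)
class NoiseModel:
    """Gaussian mole-fraction (NMR-integration) noise, clip-and-renormalized."""

    sigma: float = 0.01
    seed: int = DEFAULT_SEED

    def __post_init__(self):
        if self.sigma < 0:
            raise ValidationError("sigma must be >= 0")

    def apply(self, fractions: np.ndarray, stream: int = 0) -> np.ndarray:
        """Perturb an (n, k) fraction table; deterministic per (seed, stream)."""
        if self.sigma == 0:
            return np.asarray(fractions, dtype=float)
        rng = np.random.default_rng([self.seed, stream])
        noisy = fractions + rng.normal(0.0, self.sigma, size=np.shape(fractions))
        noisy = np.clip(noisy, 0.0, 1.0)
        return noisy / noisy.sum(axis=1, keepdims=True)


# --- condition presets ------------------------------------------------------

# Published per-channel quantum yields in benzene under 405 nm irradiation
# (fractions; rows = source A..D, columns = target A..D).
BENZENE_PHI = QuantumYieldMatrix(np.array([
    [0.0,    0.09,   0.31,   0.008],
    [0.009,  0.0,    0.08,   0.09],
    [0.0009, 0.001,  0.0,    0.0007],
    [0.003,  0.0006, 0.0001, 0.0],
]))

# Generic NMR-tube irradiation geometry: equal molar absorptivities at the
# irradiation wavelength, optically thick-ish sample (A_tot = 1).
BENZENE_PHOTO = PhotoConditions(
    wavelength_nm=405.0,
    photon_flux=1.0e-10,     # einstein/s delivered into the tube
    path_length_cm=1.0,
    volume_l=5.0e-4,
    epsilon=np.full(4, 8000.0),
    total_conc=1.25e-4,
)


@dataclass(frozen=True)
class ConditionPreset:
    """Photokinetic ground truth for one solvent/temperature condition."""

    label: str
    phi: QuantumYieldMatrix
    photo: PhotoConditions
    sigma: float = 0.01


@dataclass(frozen=True)
class SharePreset:
    """Motion-share ground truth for one (source, condition) combination.

    ``shares`` maps SBR/DBI/HT to the fraction of photoreactions of
    ``source`` proceeding by that motion.  ``pairwise_only`` marks presets
    where only a two-motion ratio was reported, so the third share is set
    to 0 by construction.
    """

    label: str
    source: Isomer
    shares: dict
    pairwise_only: bool = False
    note: str = ""

    def __post_init__(self):
        total = sum(self.shares.values())
        if abs(total - 1.0) > 1e-9:
            raise ValidationError(f"shares must sum to 1, got {total}")
        if any(v < 0 for v in self.shares.values()):
            raise ValidationError("shares must be non-negative")


PRESETS: dict[str, ConditionPreset] = {
    "benzene_27C": ConditionPreset("benzene_27C", BENZENE_PHI, BENZENE_PHOTO),
}

SHARE_PRESETS: dict[str, SharePreset] = {
    p.label: p
    for p in [
        SharePreset("A_benzene_27C", Isomer.A,
                    {Motion.SBR: 0.09 / 0.408, Motion.DBI: 0.31 / 0.408, Motion.HT: 0.008 / 0.408},
                    note="three-way shares implied by the benzene quantum-yield set"),
        SharePreset("B_MeOHd4_27C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.30, Motion.HT: 0.70},
                    pairwise_only=True, note="70:30 HT:DBI reported"),
        SharePreset("B_CD2Cl2_27C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.45, Motion.HT: 0.55},
                    pairwise_only=True),
        SharePreset("B_CD2Cl2_-80C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.24, Motion.HT: 0.76},
                    pairwise_only=True, note="HT strongly favored at -80 C"),
        SharePreset("B_EPA_-80C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.18, Motion.HT: 0.82},
                    pairwise_only=True, note="cold liquid EPA"),
        SharePreset("B_toluene_60C", Isomer.B,
                    {Motion.SBR: 0.07 / 0.99, Motion.DBI: 0.56 / 0.99, Motion.HT: 0.36 / 0.99},
                    note="printed 7/56/36 renormalized from 99% to 1"),
        SharePreset("B_toluene_20C", Isomer.B,
                    {Motion.SBR: 0.03, Motion.DBI: 0.54, Motion.HT: 0.43}),
        SharePreset("B_toluene_-78C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.29, Motion.HT: 0.71},
                    pairwise_only=True),
        SharePreset("A_toluene_ice_-196C", Isomer.A,
                    {Motion.SBR: 0.01, Motion.DBI: 0.83, Motion.HT: 0.16}),
        SharePreset("A_CD2Cl2_ice_-196C", Isomer.A,
                    {Motion.SBR: 0.0, Motion.DBI: 0.99, Motion.HT: 0.01},
                    note="only the 99% DBI share is reported; remainder assigned to HT"),
        SharePreset("B_CD2Cl2_ice_-196C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.93, Motion.HT: 0.07},
                    pairwise_only=True),
        SharePreset("B_EPA_glass_-196C", Isomer.B,
                    {Motion.SBR: 0.0, Motion.DBI: 0.87, Motion.HT: 0.13},
                    pairwise_only=True, note="about 13% HT in rigid EPA glass"),
    ]
}


# --- generators -------------------------------------------------------------


def generate_photokinetic_dataset(
    preset: ConditionPreset,
    starting_isomers=ISOMERS,
    times_min=None,
    noise: NoiseModel | None = None,
) -> dict[Isomer, CompositionSeries]:
    """One irradiation time course per pure starting isomer.

    Each series is the deterministic photokinetic simulation under the
    preset's quantum yields and irradiation conditions, followed by seeded
    noise injection (stream = starting-isomer index, so series are
    independent but jointly reproducible).
    """
    if times_min is None:
        times_min = np.arange(0.0, 31.0)
    noise = noise or NoiseModel(sigma=preset.sigma)
    out: dict[Isomer, CompositionSeries] = {}
    for iso in map(as_isomer, starting_isomers):
        x0 = np.zeros(4)
        x0[iso.index] = 1.0
        clean = simulate_photokinetics(x0, preset.phi, preset.photo, times_min,
                                       start=iso, label=f"{preset.label}:{iso.value}")
        frac = noise.apply(clean.fractions, stream=iso.index)
        out[iso] = CompositionSeries.normalized(clean.times_min, frac,
                                                start=iso, label=clean.label)
    return out


def share_transition_matrix(
    source: "Isomer | str", shares: dict, overall_rate: float, dt_min: float = 1.0
) -> TransitionMatrix:
    """Single-active-row transition matrix encoding per-motion shares.

    The source row loses ``overall_rate`` probability per step, split among
    the three motion-defined targets by ``shares``; products are inert
    (identity rows), matching an experiment read out before secondary
    photochemistry matters.
    """
    source = as_isomer(source)
    if not (0.0 < overall_rate < 1.0):
        raise ValidationError("overall_rate must lie strictly in (0, 1)")
    total = sum(shares.values())
    if abs(total - 1.0) > 1e-9:
        raise ValidationError("shares must sum to 1")
    m = np.eye(4)
    m[source.index, source.index] = 1.0 - overall_rate
    for motion, share in shares.items():
        tgt = motion_partner(source, Motion(motion))
        m[source.index, tgt.index] = overall_rate * share
    return TransitionMatrix(m, dt_min)


def generate_share_dataset(
    source: "Isomer | str",
    shares: dict,
    overall_rate: float = 0.05,
    times_min=None,
    noise: NoiseModel | None = None,
    label: str | None = None,
) -> CompositionSeries:
    """Single-source composition series built from motion-type shares."""
    source = as_isomer(source)
    if times_min is None:
        times_min = np.arange(0.0, 31.0)
    t = np.asarray(times_min, dtype=float)
    steps = np.round(t)
    if np.max(np.abs(t - steps)) > 1e-9:
        raise ValidationError("share datasets are generated on whole-minute steps")
    tm = share_transition_matrix(source, shares, overall_rate)
    x0 = np.zeros(4)
    x0[source.index] = 1.0
    frac = np.vstack([propagate(tm, x0, int(k)) for k in steps])
    noise = noise or NoiseModel(sigma=0.0)
    frac = noise.apply(frac, stream=source.index)
    return CompositionSeries.normalized(t, frac, start=source,
                                        label=label or f"shares:{source.value}")


def generate_thermal_dataset(
    k_fwd: float,
    k_rev: float,
    temperature_k: float,
    times_s,
    noise: NoiseModel | None = None,
) -> tuple[np.ndarray, np.ndarray]:
    """Reversible first-order decay of the starting isomer's mole fraction.

    Returns ``(times_s, x_start)``; the partner's fraction is ``1 - x_start``.
    """
    if k_fwd < 0 or k_rev < 0 or k_fwd + k_rev == 0:
        raise ValidationError("need non-negative rates with k_fwd + k_rev > 0")
    t = np.asarray(times_s, dtype=float)
    k_sum = k_fwd + k_rev
    x_eq = k_rev / k_sum
    x = x_eq + (1.0 - x_eq) * np.exp(-k_sum * t)
    noise = noise or NoiseModel(sigma=0.0)
    pair = noise.apply(np.column_stack([x, 1.0 - x]), stream=97)
    return t, pair[:, 0]


def generate_two_component_spectra(
    wavelengths_nm=None,
    conversions=None,
    centers=(380.0, 450.0),
    widths=(28.0, 36.0),
    amplitudes=(1.0, 0.8),
    noise_sigma: float = 0.0,
    seed: int = DEFAULT_SEED,
) -> SpectraSeries:
    """Spectra of a two-species interconversion with Gaussian surrogate bands.

    Spectrum at conversion ``x`` is ``(1 - x) S1 + x S2``; any pair of
    crossing bands produces an isosbestic point at the wavelength where
    ``S1 = S2``.
    """
    wl = np.arange(300.0, 551.0) if wavelengths_nm is None else np.asarray(wavelengths_nm, float)
    conv = np.linspace(0.0, 0.8, 9) if conversions is None else np.asarray(conversions, float)
    s1 = amplitudes[0] * np.exp(-0.5 * ((wl - centers[0]) / widths[0]) ** 2)
    s2 = amplitudes[1] * np.exp(-0.5 * ((wl - centers[1]) / widths[1]) ** 2)
    ab = np.outer(1.0 - conv, s1) + np.outer(conv, s2)
    if noise_sigma > 0:
        rng = np.random.default_rng([seed, 311])
        ab = np.clip(ab + rng.normal(0.0, noise_sigma, size=ab.shape), -0.009, None)
    return SpectraSeries(wl, ab, times=tuple(f"x={c:.3f}" for c in conv))
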