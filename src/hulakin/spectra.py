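"""Two-state analysis of absorption-spectra series from matrix irradiation.

A clean interconversion of exactly two absorbing species shows isosbestic
points — wavelengths where the absorbance does not change with irradiation
time — and a mean-centered spectra matrix of numerical rank one.  Both
signatures are used as evidence against thermally labile intermediates.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ValidationError

__all__ = ["SpectraSeries", "RankTestResult", "isosbestic_points", "two_state_rank_test"]


@dataclass(frozen=True)
class SpectraSeries:
    """Absorption spectra on a common wavelength grid at successive times."""

    wavelengths_nm: np.ndarray  # (m,)
    absorbance: np.ndarray      # (n_times, m)
    times: tuple = ()           # ordered labels, optional

    def __post_init__(self):
        wl = np.asarray(self.wavelengths_nm, dtype=float)
        ab = np.asarray(self.absorbance, dtype=float)
        if wl.ndim != 1 or ab.ndim != 2 or ab.shape[1] != wl.size:
            raise ValidationError("absorbance must be (n_times, n_wavelengths)")
        if np.any(np.diff(wl) <= 0):
            raise ValidationError("wavelength grid must be strictly increasing")
        if not np.all(np.isfinite(ab)) or np.any(ab < -0.01):
            raise ValidationError("absorbance must be finite and >= -0.01")
        object.__setattr__(self, "wavelengths_nm", wl)
        object.__setattr__(self, "absorbance", ab)
        labels = tuple(self.times) if self.times else tuple(range(ab.shape[0]))
        if len(labels) != ab.shape[0]:
            raise ValidationError("one time label per spectrum required")
        object.__setattr__(self, "times", labels)

    @property
    def n_times(self) -> int:
        return self.absorbance.shape[0]


def isosbestic_points(series: SpectraSeries, tol: float = 0.002) -> np.ndarray:
    """Wavelengths where absorbance is time-invariant (within ``tol``).

    A wavelength qualifies if the standard deviation of absorbance across
    time is below ``tol`` while the mean absorbance exceeds ``tol`` (which
    excludes flat baseline).  Contiguous qualifying grid points are merged
    to the single wavelength of minimum deviation.  Note that if all spectra
    are identical every non-baseline wavelength qualifies.
    """
    if series.n_times < 3:
        raise ValidationError("need at least 3 spectra to locate isosbestic points")
    std = series.absorbance.std(axis=0)
    mean = series.absorbance.mean(axis=0)
    hits = (std < tol) & (mean > tol)
    points: list[float] = []
    k = 0
    m = hits.size
    while k < m:
        if not hits[k]:
            k += 1
            continue
        j = k
        while j + 1 < m and hits[j + 1]:
            j += 1
        seg = slice(k, j + 1)
        best = k + int(np.argmin(std[seg]))
        points.append(float(series.wavelengths_nm[best]))
        k = j + 1
    return np.asarray(points)


@dataclass(frozen=True)
class RankTestResult:
    ratio: float          # second / first singular value of centered matrix
    singular_values: np.ndarray
    zero_variance: bool

    def __float__(self) -> float:
        return self.ratio


def two_state_rank_test(series: SpectraSeries) -> RankTestResult:
    """Singular-value ratio test for effectively two-component behaviour.

    The spectra matrix is centered by the time-mean spectrum; a closed
    two-species system then has rank one, so the ratio of the second to the
    first singular value is ~0 (values below 0.01 indicate two-state
    conversion).  The ratio is invariant under wavelength-independent
    baseline shifts and global intensity rescaling.  Zero total variance
    (all spectra identical) leaves the ratio undefined and is flagged.
    """
    if series.n_times < 3:
        raise ValidationError("need at least 3 spectra for the rank test")
    centered = series.absorbance - series.absorbance.mean(axis=0, keepdims=True)
    s = np.linalg.svd(centered, compute_uv=False)
    if s[0] <= 1e-14 * max(1.0, float(np.abs(series.absorbance).max())):
        return RankTestResult(float("nan"), s, True)
    return RankTestResult(float(s[1] / s[0]), s, False)
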