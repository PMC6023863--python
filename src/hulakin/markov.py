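"""Discrete-time Markov analysis of photoisomerization time courses.

The central inference: the composition measured every ``dt`` minutes of
irradiation is modelled as a Markov chain ``x_{k+1} = x_k M`` with a
row-stochastic transition matrix ``M`` whose entry (i, j) is the probability
that a molecule starting the step as isomer i ends it as isomer j.  ``M`` is
estimated by global least squares over all time courses simultaneously, with
rows parameterized through a normalized-exponential (softmax) transform so
every iterate is exactly row-stochastic.  The off-diagonal elements of a row,
mapped onto the motion type of each source->target transition, give the
propensity shares of single-bond rotation (SBR), double-bond isomerization
(DBI) and hula twist (HT) for that source isomer.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import least_squares

from .errors import ConvergenceError, ValidationError
from .photokin import CompositionSeries, QuantumYieldMatrix
from .states import ISOMERS, Isomer, Motion, as_isomer, classify_motion

__all__ = [
    "TransitionMatrix",
    "MarkovFitResult",
    "PropensityShares",
    "propagate",
    "fit_transition_matrix",
    "quantum_yield_ratio_check",
    "propensity_shares",
    "propensity_table",
]

DEFAULT_SEED = 20180628


@dataclass(frozen=True)
class TransitionMatrix:
    """Row-stochastic 4x4 phototransition-probability matrix per ``dt_min`` step.

    Diagonal entries are the probability of the starting isomer surviving
    one irradiation step unchanged.
    """

    M: np.ndarray
    dt_min: float = 1.0

    def __post_init__(self):
        m = np.asarray(self.M, dtype=float)
        if m.shape != (4, 4):
            raise ValidationError("transition matrix must be 4x4")
        if np.any(m < -1e-12) or np.any(m > 1 + 1e-12) or not np.all(np.isfinite(m)):
            raise ValidationError("transition probabilities must lie in [0, 1]")
        if np.any(np.abs(m.sum(axis=1) - 1.0) > 1e-9):
            raise ValidationError("each row must sum to 1 within 1e-9")
        m = np.clip(m, 0.0, 1.0)
        object.__setattr__(self, "M", m / m.sum(axis=1, keepdims=True))
        if self.dt_min <= 0:
            raise ValidationError("dt_min must be positive")

    def entry(self, src: "Isomer | str", dst: "Isomer | str") -> float:
        return float(self.M[as_isomer(src).index, as_isomer(dst).index])

    def off_diagonal_row(self, src: "Isomer | str") -> dict[Isomer, float]:
        i = as_isomer(src).index
        return {t: float(self.M[i, t.index]) for t in ISOMERS if t.index != i}


def propagate(tm: "TransitionMatrix | np.ndarray", x0, steps: int) -> np.ndarray:
    """Advance a composition ``steps`` whole steps: ``x0 . M^steps``."""
    m = tm.M if isinstance(tm, TransitionMatrix) else np.asarray(tm, float)
    if not float(steps).is_integer() or steps < 0:
        raise ValidationError(f"steps must be a non-negative integer, got {steps!r}")
    x0 = np.asarray(x0, dtype=float)
    return x0 @ np.linalg.matrix_power(m, int(steps))


# ---------------------------------------------------------------------------
# Global least-squares estimation


@dataclass
class MarkovFitResult:
    matrix: TransitionMatrix
    rss: float
    per_series_rmsd: list[float]
    fitted_rows: list[Isomer]
    identity_rows: list[Isomer]
    interpolated: bool
    warnings: list[str] = field(default_factory=list)
    n_restarts: int = 0
    best_restart: int = 0

    def to_dict(self) -> dict:
        return {
            "dt_min": self.matrix.dt_min,
            "rss": self.rss,
            "per_series_rmsd": self.per_series_rmsd,
            "fitted_rows": [r.value for r in self.fitted_rows],
            "identity_rows": [r.value for r in self.identity_rows],
            "interpolated": self.interpolated,
            "warnings": self.warnings,
            "n_restarts": self.n_restarts,
            "best_restart": self.best_restart,
        }


def _rows_to_matrix(z: np.ndarray, fitted: list[int]) -> np.ndarray:
    """Softmax rows with the diagonal logit pinned at 0; others are identity."""
    m = np.eye(4)
    z = z.reshape(len(fitted), 3)
    for r, i in enumerate(fitted):
        logits = np.zeros(4)
        logits[[j for j in range(4) if j != i]] = z[r]
        logits -= logits.max()
        e = np.exp(logits)
        m[i] = e / e.sum()
    return m


def _series_steps(series: CompositionSeries, dt_min: float) -> tuple[np.ndarray, np.ndarray, bool]:
    """Observation steps and fractions on the integer step grid."""
    steps = series.times_min / dt_min
    rounded = np.round(steps)
    if np.max(np.abs(steps - rounded)) <= 1e-6:
        return rounded.astype(int), series.fractions, False
    # interpolate each component onto the integer grid spanned by the data
    grid = np.arange(0, int(math.floor(steps[-1])) + 1)
    interp = np.column_stack(
        [np.interp(grid, steps, series.fractions[:, j]) for j in range(4)]
    )
    return grid, interp, True


def fit_transition_matrix(
    datasets: "list[CompositionSeries]",
    dt_min: float = 1.0,
    populated_threshold: float = 0.01,
    n_restarts: int = 8,
    seed: int = DEFAULT_SEED,
    fit_rows=None,
) -> MarkovFitResult:
    """Globally fit a row-stochastic transition matrix to composition series.

    Minimizes the sum of squared deviations between observed mole fractions
    and ``x0 M^k`` over all series and time points, all weighted equally.
    Rows of states never populated above ``populated_threshold`` in any
    series are unidentifiable; they are returned as identity rows and
    flagged rather than fitted.  ``fit_rows`` restricts fitting to the named
    source isomers (remaining rows are held at identity) — appropriate for
    single-source early-irradiation series where the photoproducts are known
    to be effectively inert, which removes the confounding between direct
    and two-step routes to the same product.  ``n_restarts`` seeded restarts
    of the softmax parameterization guard against local minima.
    """
    if not datasets:
        raise ValidationError("at least one composition series is required")
    prepared = [_series_steps(s, dt_min) for s in datasets]
    # known starting isomer -> propagate from the exact pure-start vector,
    # keeping the (noisy) first observation as an ordinary data point
    x0s = []
    for s, (steps, frac, _) in zip(datasets, prepared):
        if s.start is not None and steps[0] == 0:
            e = np.zeros(4)
            e[s.start.index] = 1.0
            x0s.append(e)
        else:
            x0s.append(frac[0])
    interpolated = any(p[2] for p in prepared)
    warnings: list[str] = []
    if interpolated:
        warnings.append("observations at non-integer steps were interpolated onto the step grid")

    populated = np.zeros(4, dtype=bool)
    for _, frac, _ in prepared:
        populated |= frac.max(axis=0) >= populated_threshold
    if fit_rows is not None:
        allowed = {as_isomer(r).index for r in fit_rows}
        populated &= np.array([i in allowed for i in range(4)])
    fitted = [i for i in range(4) if populated[i]]
    identity_rows = [ISOMERS[i] for i in range(4) if not populated[i]]
    if identity_rows:
        warnings.append(
            "rows never populated above threshold returned as identity: "
            + ",".join(r.value for r in identity_rows)
        )

    flat = all(np.max(np.abs(frac - frac[0])) < 1e-12 for _, frac, _ in prepared)
    if flat or not fitted:
        warnings.append("flat (all-constant) data: likelihood is flat, returning identity")
        tm = TransitionMatrix(np.eye(4), dt_min)
        rmsd = [0.0 for _ in prepared]
        return MarkovFitResult(tm, 0.0, rmsd, [ISOMERS[i] for i in fitted], identity_rows, interpolated, warnings)

    n_par = 3 * len(fitted)
    # param p = 3*r + c acts on row fitted[r], off-diagonal position c
    src_of_par = np.repeat([i for i in fitted], 3)
    col_of_par = np.array([
        [j for j in range(4) if j != i][c] for i in fitted for c in range(3)
    ])

    def residuals(z: np.ndarray) -> np.ndarray:
        m = _rows_to_matrix(z, fitted)
        out = []
        for x0, (steps, frac, _) in zip(x0s, prepared):
            pred = np.empty_like(frac)
            pred[0] = x0
            v = x0.copy()
            idx = 1
            for k in range(int(steps[0]) + 1, int(steps[-1]) + 1):
                v = v @ m
                if idx < len(steps) and steps[idx] == k:
                    pred[idx] = v
                    idx += 1
            out.append((pred - frac).ravel())
        return np.concatenate(out)

    def jacobian(z: np.ndarray) -> np.ndarray:
        # forward sensitivity: d(x0 M^k)/dz via S_k = S_{k-1} M + x_{k-1}[i_p] dRow_p
        m = _rows_to_matrix(z, fitted)
        drow = np.empty((n_par, 4))  # softmax row derivative per parameter
        for p in range(n_par):
            row = m[src_of_par[p]]
            drow[p] = -row * row[col_of_par[p]]
            drow[p, col_of_par[p]] += row[col_of_par[p]]
        blocks = []
        for x0, (steps, frac, _) in zip(x0s, prepared):
            sens = np.zeros((n_par, 4))
            v = x0.copy()
            jac_rows = [np.zeros((n_par, 4))]
            idx = 1
            for k in range(int(steps[0]) + 1, int(steps[-1]) + 1):
                sens = sens @ m + v[src_of_par][:, None] * drow
                v = v @ m
                if idx < len(steps) and steps[idx] == k:
                    jac_rows.append(sens.copy())
                    idx += 1
            blocks.append(np.concatenate([j.T for j in jac_rows], axis=0))
        return np.concatenate(blocks, axis=0)

    rng = np.random.default_rng(seed)
    base = np.full(3 * len(fitted), math.log(0.02 / 0.94))
    best = None
    best_cost = np.inf
    best_restart = 0
    for r in range(max(1, n_restarts)):
        z0 = base if r == 0 else base + rng.normal(0.0, 2.0, size=base.size)
        try:
            res = least_squares(
                residuals, z0, jac=jacobian, method="trf",
                bounds=(-20.0, 20.0),  # probability floor ~2e-9 keeps identity rows terminating
                ftol=1e-12, xtol=1e-12, gtol=1e-12, max_nfev=1000,
            )
        except Exception as exc:  # pragma: no cover - defensive
            warnings.append(f"restart {r} failed: {exc}")
            continue
        if res.cost < best_cost:
            best, best_cost, best_restart = res, res.cost, r
        if best_cost < 1e-10:  # essentially exact (noise-free data); restarts add nothing
            break
    if best is None:
        raise ConvergenceError("transition-matrix fit failed in every restart")

    m = _rows_to_matrix(best.x, fitted)
    tm = TransitionMatrix(m, dt_min)
    rmsd = []
    resid = residuals(best.x)
    pos = 0
    for steps, frac, _ in prepared:
        n = frac.size
        block = resid[pos:pos + n]
        rmsd.append(float(np.sqrt(np.mean(block ** 2))))
        pos += n
    return MarkovFitResult(
        tm, float(np.sum(resid ** 2)), rmsd,
        [ISOMERS[i] for i in fitted], identity_rows, interpolated, warnings,
        n_restarts=max(1, n_restarts), best_restart=best_restart,
    )


# ---------------------------------------------------------------------------
# Consistency with measured quantum yields


@dataclass
class RatioCheckResult:
    max_relative_deviation: float
    worst: tuple | None  # (src, dst_a, dst_b)
    skipped: list[tuple]

    def __float__(self) -> float:
        return self.max_relative_deviation


def quantum_yield_ratio_check(
    tm: TransitionMatrix, qy: QuantumYieldMatrix
) -> RatioCheckResult:
    """Compare off-diagonal ratios of ``M`` with quantum-yield ratios row-wise.

    For every source row with at least two open channels the ratio
    ``M[i,j]/M[i,k]`` should mirror ``phi[i,j]/phi[i,k]``; returns the worst
    relative deviation and the channel pair realizing it.  Pairs with a zero
    denominator in either matrix are skipped and reported.
    """
    worst = 0.0
    worst_pair = None
    skipped: list[tuple] = []
    for src in ISOMERS:
        i = src.index
        targets = [j for j in range(4) if j != i]
        for a_pos, j in enumerate(targets):
            for k in targets[a_pos + 1:]:
                if tm.M[i, k] == 0 or qy.phi[i, k] == 0:
                    if tm.M[i, j] or qy.phi[i, j]:
                        skipped.append((src, ISOMERS[j], ISOMERS[k]))
                    continue
                r_m = tm.M[i, j] / tm.M[i, k]
                r_p = qy.phi[i, j] / qy.phi[i, k]
                if r_p == 0:
                    skipped.append((src, ISOMERS[j], ISOMERS[k]))
                    continue
                dev = abs(r_m - r_p) / abs(r_p)
                if dev > worst:
                    worst, worst_pair = dev, (src, ISOMERS[j], ISOMERS[k])
    return RatioCheckResult(worst, worst_pair, skipped)


# ---------------------------------------------------------------------------
# Motion-type propensities


@dataclass(frozen=True)
class PropensityShares:
    """Fraction of photoreactions of one source isomer per motion type."""

    source: Isomer
    mode: str  # "three_way" or "pairwise"
    shares: dict  # Motion -> fraction; sums to 1 over the included motions

    def share(self, motion: Motion) -> float:
        return float(self.shares.get(motion, 0.0))


def _weights_by_target(source: Isomer, weights) -> dict[Isomer, float]:
    others = [t for t in ISOMERS if t is not source]
    if isinstance(weights, dict):
        return {as_isomer(t): float(w) for t, w in weights.items() if as_isomer(t) is not source}
    w = np.asarray(weights, dtype=float)
    if w.shape == (4,):
        return {t: float(w[t.index]) for t in others}
    if w.shape == (3,):
        return dict(zip(others, map(float, w)))
    raise ValidationError("weights must be a dict, a length-4 row, or 3 off-diagonals")


def propensity_shares(
    source: "Isomer | str",
    weights,
    mode: str = "three_way",
    pair: "tuple[Motion, Motion] | None" = None,
) -> PropensityShares:
    """Partition a row of channel weights into motion-type shares.

    ``weights`` may be a quantum-yield row, an off-diagonal transition-matrix
    row (length 4 with the source entry ignored, length 3 in target order, or
    a ``{target: weight}`` dict).  ``three_way`` normalizes over SBR, DBI and
    HT together; ``pairwise`` renormalizes over the two motions in ``pair``
    only.  Shares are invariant under positive rescaling of the weights.
    """
    source = as_isomer(source)
    by_target = _weights_by_target(source, weights)
    if any(w < 0 for w in by_target.values()):
        raise ValidationError("channel weights must be non-negative")
    by_motion = {classify_motion(source, t): w for t, w in by_target.items()}
    if mode == "three_way":
        motions = (Motion.SBR, Motion.DBI, Motion.HT)
    elif mode == "pairwise":
        if pair is None or len(pair) != 2:
            raise ValidationError("pairwise mode requires a pair of motion types")
        motions = tuple(Motion(m) for m in pair)
    else:
        raise ValidationError(f"unknown mode {mode!r}")
    total = sum(by_motion.get(m, 0.0) for m in motions)
    if total <= 0:
        raise ValidationError("all channel weights are zero; shares undefined")
    return PropensityShares(
        source, mode, {m: by_motion.get(m, 0.0) / total for m in motions}
    )


def propensity_table(
    matrix: "TransitionMatrix | QuantumYieldMatrix", mode: str = "three_way",
    pair: "tuple[Motion, Motion] | None" = None,
) -> dict[Isomer, PropensityShares]:
    """Per-source motion shares for every row with at least one open channel."""
    arr = matrix.M if isinstance(matrix, TransitionMatrix) else matrix.phi
    out: dict[Isomer, PropensityShares] = {}
    for src in ISOMERS:
        row = arr[src.index].copy()
        row[src.index] = 0.0
        if row.sum() > 0:
            out[src] = propensity_shares(src, row, mode=mode, pair=pair)
    return out
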