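# Methods

## State space and motion classification

The four diastereomers are encoded as the product of two binary
stereodescriptors: double-bond configuration (Z/E) and axial chirality
(ax1/ax2), with A = (Z, ax1), B = (Z, ax2), C = (E, ax1), D = (E, ax2).
The axis labels are abstract: absolute P/M (or R/S) assignment affects no
computation, so it is not modelled. A transition is classified by which
descriptors change — axis only (SBR), double bond only (DBI), or both (HT).
With the assignment above the DBI pairs are {A,C} and {B,D}, the SBR pairs
{A,B} and {C,D}, and the HT pairs {A,D} and {B,C}; for every source state
the three targets realize exactly one motion of each type, which the test
suite verifies by enumeration. The alphabetical order A<B<C<D fixes
row/column indices in every matrix.

## Photokinetic forward model

The sample is treated as a closed, well-stirred solution under constant
monochromatic irradiation. Incident photons (flux `F`, einstein/s) are
absorbed with the photokinetic factor `1 − 10^(−A_tot)` and partitioned
among isomers by their absorbance contributions `A_i = ε_i·l·c_tot·x_i`:

    rate_i = F · (A_i / A_tot) · (1 − 10^(−A_tot))

An alternative `total` mode (`rate_i = F·A_i/A_tot`) assumes an optically
thick sample; the partition mode is the default because it remains correct
at any absorbance. A fully transparent sample (`A_tot = 0`) absorbs nothing
and is handled as the physical limit, not an error.

Each absorbed photon converts isomer i to j with probability Φ_ij, giving
the master equation `dn_i/dt = Σ_{j≠i}(Φ_ji·rate_j − Φ_ij·rate_i)`, which
conserves total moles identically; the model is therefore integrated
directly in mole fractions. Because channel yields span roughly 0.01%–31%
— three orders of magnitude — integration uses stiff-safe LSODA with
rtol 1e-8 / atol 1e-10. Interfaces use minutes; internals use seconds;
flux is einstein/s. Output fractions are clamped at zero and renormalized
at the 1e-12 level.

The photostationary state is found by integrating over geometrically
growing time chunks until the per-chunk composition change and the residual
derivative fall below 1e-10, which handles both fast photoequilibria and
nearly absorbing states without a Jacobian-based root find on the simplex.

## Markov transition-matrix estimation

Compositions sampled every `dt` minutes (default 1, matching the
one-minute irradiation step of the reported matrix) are modelled as
`x_{k+1} = x_k M` with row-stochastic `M`. Rows are parameterized by a
normalized-exponential (softmax) transform with the diagonal logit pinned
at zero, so every iterate satisfies the constraints exactly; the logits are
bounded to ±20 (a probability floor near 2e-9) so rows whose optimum is the
identity terminate cleanly. The objective is the unweighted sum of squared
deviations over all series and time points (the study conditions state no
weighting scheme); it is minimized with `scipy.optimize.least_squares`
using an analytic Jacobian obtained by forward sensitivity propagation,
under 8 seeded restarts (default seed 20180628) to guard against local
minima. A restart reaching essentially zero cost (< 1e-10) ends the search
early, since further restarts cannot improve on noise-free data.

Identifiability rules: rows of states never populated above 1% in any
series are returned as identity rows and flagged rather than fitted.
When the starting isomer of a series is declared, propagation starts from
the exact pure-start vector and the (possibly noisy) first observation is
treated as an ordinary data point; this uses the known experimental design
and reduces variance. For single-source early-irradiation series whose
photoproducts are known to be inert, `fit_rows` restricts estimation to
the source row — otherwise a direct source→product channel and a two-step
route through another product are confounded under noise. Observations at
non-integer multiples of `dt` are interpolated onto the step grid and
flagged rather than handled with fractional matrix powers. All-constant
data yield a flat objective; the exact identity matrix is returned with a
warning instead of running the optimizer.

The consistency diagnostic compares all off-diagonal ratios `M_ij/M_ik`
within each row against the corresponding quantum-yield ratios and reports
the worst relative deviation, skipping (and listing) pairs with zero
denominators. Propensity shares divide a row of non-negative channel
weights (a Φ row or an `M` row's off-diagonals) by motion type, either
over all three motions or renormalized over a named pair — both styles in
which condition-dependent selectivities are commonly quoted. Shares are
invariant under positive rescaling of the weights.

## Quantum-yield estimation

Φ_ij is defined operationally as moles of j formed per einstein absorbed
by i, with absorbed photons attributed by the partition formula above.
Two estimators are provided:

- `early_slope` mirrors the early-time product-identification argument:
  within the maximal initial window in which the photoproducts' share of
  total absorbance stays below a threshold (default 5%, the first point
  always included), Φ is the through-origin regression slope of product
  moles on cumulative absorbed einsteins. At least 3 window points are
  required; negative slopes are clamped to zero with a warning.
- `full_ode_fit` (default) fits the master equation to all series with all
  off-diagonal Φ of populated source rows free, box-bounded to [0,1]
  (`least_squares`, trf, `x_scale='jac'` to handle the dynamic range),
  initialized from the early-slope estimates. It inherently corrects for
  photoproduct absorption and back-reaction, so the early-slope estimator
  systematically reads low once conversion leaves the linear regime (a
  directional property the tests check).

Standard errors come from the Jacobian-based covariance at the optimum; a
seeded residual bootstrap (`n_boot`) is available when resampling-based
uncertainties are wanted, and is off by default because hundreds of ODE
refits are rarely warranted for the deterministic recovery studies this
package targets.

## Thermal kinetics and Eyring analysis

Atropisomer interconversion is reversible first order:
`x(t) = x_eq + (x0 − x_eq)·e^(−(k_f+k_r)t)` with
`x_eq = k_r/(k_f+k_r)`. The fit estimates `x0`, `x_eq` and the relaxation
rate by bounded `curve_fit`; non-decaying data are returned flagged as
unidentifiable with k ≈ 0 rather than raising. Rates convert to barriers
via Eyring with transmission coefficient 1 (the universal convention when
unstated): `ΔG‡ = RT·ln(k_B T/(h k))`, an exact round-trip pair with the
inverse. Constants are pinned at CODATA 2018 values (k_B = 1.380649e-23
J/K, h = 6.62607015e-34 J·s, R = 8.31446 J/(mol·K)); 1 kcal = 4.184 kJ;
T(K) = T(°C) + 273.15 exactly; half-lives use ln 2 over the decay (or
relaxation) rate, with a year of 365.25 days.

Non-observation of a reaction over duration `t` down to a detection
fraction `f` bounds the rate by `k ≤ −ln(1−f)/t` and hence the barrier
from below. The default detection fraction is 5%, a conservative NMR
integration limit; the resulting ≥30 kcal/mol conclusion for the thermal
double-bond rotation (25 h at 100 °C) is robust — any detection fraction
up to ~50% still clears 30 kcal/mol. Doubling the duration raises the
bound by exactly RT·ln 2, which the tests verify. Temperature
extrapolation assumes a temperature-independent ΔG‡ unless rates at two or
more temperatures are supplied, in which case `eyring_regression` returns
ΔH‡ and ΔS‡.

## Spectral two-state diagnostics

A wavelength is isosbestic if the absorbance standard deviation across
time is below `tol` while the mean absorbance exceeds `tol` (excluding
baseline); contiguous qualifying grid points merge to the
minimum-deviation wavelength. The default `tol` of 0.002 absorbance units
reflects a typical spectrophotometer noise floor on a 1 nm grid. If all
spectra are identical every non-baseline wavelength qualifies — a
documented degenerate case. The rank test mean-centers the spectra matrix
over time — a closed two-species system is then rank one — and reports the
ratio of the second to the first singular value; ratios below 0.01
indicate two-component behaviour, and the ratio is invariant under
wavelength-independent baseline shifts and global rescaling. Zero total
variance leaves the ratio undefined and flagged.

## Synthetic data: what it emulates, and what it does not

The generators emulate the experimental designs the estimators were built
for: irradiation of each pure isomer with periodic composition readings,
single-source condition datasets specified by motion shares and a
per-minute loss probability (products inert, matching early-stage
irradiation before secondary photochemistry), reversible thermal decays,
and two-component spectra built from Gaussian surrogate bands (the true
molar-absorption spectra are not reproduced here). NMR integration error
is modelled as additive Gaussian noise on mole fractions (σ default 0.01)
followed by clip-to-[0,1] and renormalization — the simplest model
consistent with integral-reading error. Real data additionally contain
baseline/phasing artifacts, peak-overlap correlations, and drift in lamp
flux, none of which are simulated; passing recovery tests therefore
demonstrate correctness of the inference chain under the stated noise
model, not robustness to every instrumental pathology.

The benzene preset uses equal molar absorptivities at the irradiation
wavelength (total absorbance 1.0, photon flux 1e-10 einstein/s into a
0.5 mL, 1.25e-4 M sample), chosen to give a few-percent-per-minute initial
conversion — comparable to an NMR-tube LED irradiation. Recovery studies
use 30 one-minute steps per series, with the weakly converting D-start
series extended to 200 steps so its 0.01–0.3% channels are identified;
these problem sizes resolve every shipped channel yield while keeping each
full fit to a few seconds. Where a condition's printed selectivity is only
a two-motion ratio, the third share is set to zero and the preset flagged
`pairwise_only`; for frozen dichloromethane only the 99% DBI share of **A**
is printed, and the 1% remainder is assigned to HT by analogy with frozen
toluene, where HT dominates the minor channels (the three-way DBI share is
unaffected). The printed 7/56/36 toluene split for **B** at 60 °C sums to
99% and is renormalized. All generators take explicit seeds (master
default 20180628) and are bit-reproducible.

## Known limitations

- The Markov model is discrete-time by design; no continuous-time
  generator is fitted (a matrix logarithm can disagree with the data model
  when steps are coarse).
- Polychromatic light sources, excited-state dynamics, fluorescence and
  inner-filter effects beyond the partition formula are out of scope.
- Quantum yields are treated as wavelength-independent across 305–405 nm,
  consistent with the marginal wavelength dependence reported for this
  switch class.
- Single-series datasets identify only the rows exercised by the data;
  the fitter flags, rather than invents, the rest.
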