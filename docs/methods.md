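# Methods

## Models

All rate laws are functions of the coldness β = 1/(k<sub>B</sub>T), the
canonical Lagrange multiplier, expressed in a declared energy unit
(default kJ/mol, k<sub>B</sub> = 0.0083144626 kJ/mol/K; kcal/mol, eV and
thermal k<sub>B</sub>·K units are supported).  The pre-exponential A is a
pass-through in arbitrary positive rate units: every objective function
acts on ln k, so A's unit only shifts an intercept.

* **Arrhenius**: k = A e^(−ε‡β); E<sub>a</sub> = ε‡, γ = 1/ε‡ constant.
* **Deformed exponential (AM)**: k = A(1 − dε‡β)^(1/d).  Exact identities
  used throughout: E<sub>a</sub> = ε‡/(1 − dε‡β) and γ = 1/ε‡ − dβ (linear,
  slope −d, intercept 1/ε‡).  d = 0 is Arrhenius exactly; d < 0
  sub-Arrhenius (tunneling propensity, d = −⅓(hν‡/2ε‡)² for small barrier
  transparency); d > 0 super-Arrhenius with domain β < β† = 1/(dε‡).
  The thermal limit is ε† = dε‡ = k<sub>B</sub>T†.  For d < 0 the law
  approaches the power law A(|d|ε‡β)^(1/d) at large β (Wigner-threshold
  behaviour); this is exposed as a residual diagnostic
  k/asymptote → 1 rather than as an equality, since it is an asymptotic
  statement only.
* **VFT**: k = A exp[−ε‡β/(1 − β/β†)]; E<sub>a</sub> = ε‡/(1 − β/β†)².
* **Fowler–Guggenheim unimolecular model**: k = A e^(−x) Σ_{r<s} x^r/r!
  with x = ε‡β, evaluated in closed form as A·Γ(s, x)/Γ(s) (regularized
  upper incomplete gamma); E<sub>a</sub> = ε‡ x^(s−1) e^(−x)/Γ(s, x).
  s counts the internal degrees of freedom pooling the activation energy.
* **Generalized transitivity law**: γ(β) = (1/ε‡)(1 − β/β†)^ζ, with the
  reference coldness fixed at β₀ = 0 so γ(0) = 1/ε‡.  The rate law follows
  from ln k = ln A − ∫₀^β E<sub>a</sub>; closed forms are used for
  ζ ∈ {0, 1, 2} (Arrhenius, AM with β† = 1/(dε‡), VFT) and adaptive
  quadrature (absolute/relative tolerance 1e−10) otherwise.

Statistical-limit module: binomial subvolume occupancy and its Poisson
limit; stars-and-bars oscillator-quanta counting
P(n) = W(s, M−n)/C(s+M, M) and its Boltzmann-factor limit
P(n+1)/P(n) → m̄/(1+m̄) (the implied coldness is
β = ln(1+1/m̄)/hν); the deformed Boltzmann factor (1 − x/N)^N with the
Tsallis mapping q = 1 − 1/N; the Planck-oscillator mean energy
hν/(e^{hνβ} − 1) and its reciprocal's power series.  The counting
denominator is the finite total-energy-constrained sum over subsystem
energies 0..M (an unconstrained sum diverges), which collapses to
C(s+M, M); combinatorics switch from exact integers to log-gamma above
s+m = 60.  The reciprocal-energy expansion is the series of the exact
reciprocal (e^{hνβ} − 1)/hν, i.e. terms j = 1..order; asymptotic statements
of this expansion sometimes include an extra constant 1/hν (expanding
e^{hνβ} instead), which is negligible at low temperature but breaks
exactness at small β and is therefore omitted.

## Estimation

**Arrhenius-plane fits** minimise Σ(ln k_model − ln k_obs)² (rate data span
orders of magnitude; multiplicative noise is additive in ln k).  The
Arrhenius line (closed-form weighted least squares) seeds all nonlinear
fits; the deformation d is multi-started at {0, ±0.01, ±0.1}, the VFT
divergence at {1.2, 1.5, 2.5, 5}× the largest observed β, and the FG
oscillator count is profiled over integer s = 1..30.  The optimiser is
deterministic trust-region least squares (tolerances 1e−14) with an
optional seedable stochastic-restart supplement; a stochastic global search
is deliberately avoided for reproducibility.  Standard errors come from the
Jacobian at the solution, cov = RSS/(n−p)·(JᵀJ)⁻¹.  Inside the AM
objective, ln(1 − dε‡β)/d is evaluated with `log1p` (a raw power loses
|1/d|·machine-epsilon accuracy near d = 0) and is continued linearly with a
steep penalty ramp outside the domain so optimisation remains finite.

**Empirical transitivity** estimates E<sub>a</sub> = −d ln k/dβ from data.
Three estimators are provided: a cubic smoothing spline of ln k versus β
with the penalty chosen by generalized cross-validation (default — intended
for noisy data), second-order central differences (one-sided at the ends;
the estimator of choice for dense, low-noise data, since GCV is known to
oversmooth in the noise-free limit), and a local-quadratic least-squares
window (default width 7, for noisy nonuniform grids).  Points with
|E<sub>a</sub>| below 1e−10 energy units are masked, never inverted.
Closed-form activation energies are independently validated against
adaptive central differences with step h = max(1e−6, 1e−4·β).

**Universality-class selection** fits γ(β) = γ₀(1 − β/β†)^ζ for each
candidate ζ on a grid 0..4 in steps of 0.05 (always including the integer
classes 0, 1, 2), initialised through the linearisation γ^(1/ζ) and refined
by bounded least squares (β† above the observed range).  ζ = 0 degenerates
to the one-parameter constant-γ model.  The winner minimises AICc on γ
residuals, n·ln(RSS/n) + 2p + 2p(p+1)/(n−p−1); RSS values below
n·(1e−10·max|γ|)² are treated as numerically zero (ties), in which case
fewer parameters and then the smaller exponent win.  For ζ = 1 the fit also
reports the implied deformation d = γ₀/β†.

**Crossover detection** searches every interior grid point β_c (≥ 3 points
per side) as the joint of two independently fitted straight lines in the
transitivity plane; the joint point belongs to both segments, matching the
γ-continuous crossover construction.  The best two-regime candidate
(5 parameters: two lines plus the breakpoint) is compared with the single
line (2 parameters) by AICc; the single line is preferred unless the
two-regime model improves the criterion by at least 2 *and* lowers the RSS,
so a reported breakpoint can never have a higher RSS than the single-line
fit.  Caveats: the AICc comparison assumes roughly independent residuals.
On *smoothed* empirical curves (GCV spline of noiseless or low-noise data)
residuals are strongly correlated and slowly varying, and the two-line
model can win spuriously — crossover searches on noiseless data should use
the central-difference estimator, whose residuals sit at the numerical
floor.  Under genuinely independent noise the margin-2 rule still admits
roughly a 5–10 % false-positive rate per dataset, as any fixed
information-criterion threshold does.

**Classification** of a deformed-law fit: sub-Arrhenius (d below −tol),
super-Arrhenius (d above tol with ε‡ > 0), anti-Arrhenius (d > 0 with
ε‡ < 0), else Arrhenius; tol defaults to 1e−3, widened to two standard
errors of d when available.

## Synthetic data

The generator emulates rate tables as they arise in practice: a temperature
grid (linear in T or in β) strictly inside the law's domain, exact rates
from the closed form, and multiplicative lognormal noise — σ is the
relative standard deviation of k, i.e. additive Gaussian noise on ln k,
matching the fitting objective.  A fixed spec + seed is bit-reproducible.
What it does *not* emulate: temperature-dependent (heteroscedastic) error
structures, correlated instrument drift, or temperature-calibration error;
passing tests therefore demonstrate estimator correctness under the stated
noise model, not robustness to arbitrary experimental pathologies.

Reference study conditions used in the tests:

* Single-law recovery: A = 10¹³, ε‡ = 40 kJ/mol, d = 0.05, 30 points,
  250–400 K (the coldest point sits just above T† ≈ 240.5 K, the regime
  where curvature is informative); 100 replicates at σ = 0.02 for the noisy
  study.  VFT uses ε‡ = 10 kJ/mol with the divergence at 150 K.
* Two-regime crossover: transitivity slopes −0.02 and −0.10 joined at the
  midpoint of a 41-point β-linear grid spanning 200–400 K, with
  ε‡ = 35 kJ/mol in the hot regime; the second regime's barrier follows
  from γ-continuity at the joint and its prefactor from ln k continuity.
  The window is sized so the cold regime stays above its own thermal limit
  (β† ≈ 0.86 > β(200 K) ≈ 0.60) and the per-grid-step kink deflection
  exceeds the 2 % noise scale, which is what makes one-grid-step
  localisation feasible.  Two-regime noise enters either through the rates
  (then differentiated) or directly on γ, emulating pointwise activation
  energy determinations; both routes are exercised.

## Numerical conventions

* k_am at exactly β = β† returns the continuous extension 0 for d > 0
  (the operative lower-limit reading); `strict_domain=True` raises instead.
* Non-integer ζ reconstruction uses `scipy.integrate.quad` with
  1e−10/1e−10 tolerances and raises on non-convergence.
* Duplicate β rows in input tables are averaged in ln k (with a logged
  warning); non-positive rates are rejected row by row.
* The truncated deformed-law expansion
  A e^(−x)[1 − (d/2)x² − (d²/3)x³ − ((2d−1)d²/8)x⁴] has error O(x⁵); the
  scaling is verifiable in double precision only for x ≳ 1e−2 (below that
  the error underflows machine epsilon relative to k ≈ A).
* Reports serialise with deterministic field order; identical inputs,
  configuration and seed give byte-identical reports apart from an optional
  timestamp.

## Known limitations

* The exponent search treats ζ as a grid parameter; no continuous
  profile-likelihood confidence interval for ζ is reported.
* Breakpoint uncertainty is not quantified (no bootstrap); the reported
  β_c is the grid argmin of the two-segment RSS.
* The FG fit profiles integer s only up to 30 (the closed-form/series
  equivalence is guaranteed in that range).
* Anti-Arrhenius data (negative apparent activation energy) are fitted in
  the Arrhenius plane, but the power-law transitivity fit assumes γ > 0
  when initialising and is not designed for mixed-sign γ curves.
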