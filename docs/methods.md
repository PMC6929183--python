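# Methods

This note records the models implemented, the conventions chosen where more
than one is in circulation, and what the synthetic generators do and do not
emulate. It states no empirical result that the test suite or
`scripts/acceptance.py` does not itself compute.

## Units and constants

Geometry in Å, masses in amu, Cartesian Hessians in hartree/bohr² (the
convention of quantum-chemistry program output), wavenumbers in cm⁻¹, molar
energies in kcal/mol. All constants are pinned to CODATA-2014 in
`isokie.constants` and every formula — engines and closed-form oracles alike
— draws from that single module, so cross-checks are constant-exact. The two
numbers that matter most: the second radiation constant
hc/k_B = 1.438777 cm·K (entering u = hcν̃/k_BT) and the conversion
√(hartree/(bohr²·amu)) → 5140.49 cm⁻¹ for Hessian eigenvalues.

Default temperature is 298.15 K. The batch hydrolysis experiments the
simulator emulates ran at 30 °C (303.15 K); pass
`ThermoSettings(temperature=303.15)` or set `temperature:` in the run config
to use it. The predicted-KIE temperature is not pinned to the experimental
one anywhere in the chain.

## Frequency analysis

The Hessian is mass-weighted, three translations and two (linear) or three
(nonlinear) rotation vectors are built in the Eckart frame, orthonormalized
by QR, and projected out; the projected matrix is diagonalized and
eigenvalues map to wavenumbers with the sign carrying curvature. Modes with
|ν̃| < 1 cm⁻¹ after projection are dropped and counted — for block-composite
toys this also removes the relative rigid-body motions of the mechanically
uncoupled fragments. Exactly one negative eigenvalue marks a first-order
saddle; two or more raise `HigherOrderSaddleError`.

Isotopologs share the Hessian (a Born–Oppenheimer property) and differ only
in the mass vector. Modes are matched across isotopologs by sorted order.
That is safe for the shipped symmetry-free toys; it is **unsafe under mode
crossing**, so a warning fires when adjacent non-degenerate modes sit within
1 cm⁻¹ (exactly degenerate bend doublets are fine — either assignment gives
the same product).

## Semiclassical KIEs

The Bigeleisen form used is the plain harmonic one: no anharmonicity, no
frequency scaling (factor 1.0), and no Wigner tunneling correction — this is
deliberately the *semiclassical* reference that the path-integral route is
meant to improve on, so adding a tunneling fudge here would blur the
comparison. The per-mode factor

g_i = (u_L/u_H)·e^{(u_H−u_L)/2}·(1−e^{−u_H})/(1−e^{−u_L})

is the light/heavy ratio of quantum-to-classical partition-function
corrections of one matched mode; the species product g, together with the
imaginary-frequency ratio, gives KIE = (ν̃‡_L/ν̃‡_H)·g(TS)/g(R).

A point worth recording because it bit us once: the brute-force TST ratio of
raw partition functions (translation × rotation × vibration, reaction
coordinate excluded) **already equals** this factorized expression — the
imaginary-frequency ratio is produced implicitly by the Teller–Redlich
product rule, not multiplied on top. The oracle test verifies the identity
to < 10⁻⁶ on collinear toys whose analytic Hessians are exactly translation-
and rotation-invariant (the bend rows use the curvilinear gradient
(1/r₁, −(1/r₁+1/r₂), 1/r₂), which is what makes the rotational zero modes
exact).

## Fractionation conventions

Averaging over positions is unweighted arithmetic; symmetry-equivalent
positions are entered individually (six of each element for the
hexachlorocyclohexane case, so `n = 6` is the default position count). The
enrichment factor is reported as ε = (1 − KIE_av)·1000 ‰ — normal KIE means
negative ε. Bulk-H assemblies more negative than −300 ‰ are flagged as
overestimated relative to typical measured bulk-H fractionation, since that
regime is where assumed-secondary bookkeeping, not the primary effect, is
usually at fault.

`infer_secondary_average` inverts the hybrid assembly exactly:
s̄ = (n·(1 − ε/1000) − primary)/(n − 1), flagged inverse when s̄ < 1. It is
the robust alternative to the AKIE dilution correction
AKIE = 1/(1 + n·ε/1000), which is linearized and breaks down spectacularly
for large effects (at ε = −160 ‰, n = 6 it returns 25); `epsilon_to_akie`
warns once its denominator drops below 0.2.

## Batch simulator and the Rayleigh convention

Two ε-like conventions coexist in the literature: ε = (1 − KIE)·1000 (the
form used for predicted bulk effects here) and ε = (α − 1)·1000 with
α = k_H/k_L the slope convention of the Rayleigh regression. They agree to
first order but diverge for large effects. For the chain to be
self-consistent — generator KIEs in, the same ε out of the regression,
exactly — the simulator sets the heavy-pool rate as
k_H = k_L·(1 + ε/1000) with ε = (1 − KIE_av)·1000, so noise-free data lie on
ln(R_t/R₀) = (ε/1000)·ln(C_t/C₀) with residuals at machine precision. The
heavy isotopolog is treated as trace (concentration ≈ light pool), correct
for natural-abundance CSIA.

Noise: multiplicative lognormal on concentrations (mean-preserving),
additive Gaussian on δ-values — the simplest model consistent with batch
measurement practice; replicate counts and noise magnitudes are not
documented for the emulated experiments, so the defaults (10 time points to
~97 % conversion, δ noise 0.5 ‰, concentration noise off) are package
choices exposed in the config.

**Regression variant and CI calibration.** The default fit runs through the
origin, which is exact for noise-free data (both axes are identically zero
at t = 0). With noise on *every* δ measurement, however, the t = 0 value is
itself noisy and its error is shared by all points of ln(R_t/R₀); a
through-origin fit then attributes part of that shared offset to the slope
and its standard error is substantially optimistic (simulated 95 % CI
coverage drops toward ~0.5). The free-intercept variant
(`through_origin=False`) absorbs the shared error and is calibrated
(coverage ≈ 0.93–0.95 in the suite's 100-replicate study); it is the variant
to use — and the one the calibration test uses — whenever real, noisy data
are fit. Slopes are invariant under rescaling concentrations by any positive
constant, and δ-arithmetic cancels the reference ratios, so the placeholder
standards shipped never influence results.

## Umbrella sampling and WHAM

The window sampler is plain 1D Metropolis on A(z) + ½k_b(z − z_k)² with the
step auto-tuned to 30–50 % acceptance during a discarded burn-in (10 % of
the request) and chain thinning (default every 5th state) so stored samples
are only weakly correlated — without thinning, correlated-chain histogram
noise dominates the reconstruction error at the 2000-samples-per-window
study size. Acceptance rate, step and seed are logged per window;
non-overlapping adjacent windows raise a warning and mark the profile
ill-conditioned.

WHAM iterates the standard self-consistent equations on a shared histogram
grid (Freedman–Diaconis on the pooled samples by default, overridable),
gauge-fixed by F₁ = 0, to max|ΔF_k| < 10⁻⁶ kcal/mol within 10⁵ iterations;
`method="mle"` instead maximizes the WHAM log-likelihood directly with
L-BFGS-B (the two agree to the convergence tolerance and the MLE path is
the fallback for stiff cases). The PMF is min-shifted for reporting.
Exhausting max_iter raises an error that carries the partial profile.

The reaction coordinate is the antisymmetric proton-transfer combination
z = r(C–H) − r(H–O); the C–Cl cleavage variable is intentionally not part of
the coordinate and 2D WHAM is out of scope. Barrier extraction takes the
highest *interior* local maximum beyond the reactant-basin minimum, so a
monotone profile raises a no-barrier error and an additive shift changes
nothing.

## Path-integral machinery

Primitive (Trotter) discretization throughout. Free-particle ring paths are
built by recursive bisection (which is why bead counts must be powers of
two): the ring is pinned at bead 0, Brownian-bridge midpoints are sampled
level by level, and subtracting the centroid yields the exact
centroid-constrained distribution — the centroid of the pinned Gaussian ring
is a linear functional, so conditioning equals projection. The quantized
classical path estimator is

exp(−βΔF_qm) = ⟨⟨exp(−βΔŪ)⟩_paths⟩_classical,  ΔŪ = (1/P)Σᵢ V(xᵢ) − V(x_c),

with classical configurations from a built-in Metropolis sampler (an
optional harmonic restraint holds transition-structure sampling near the
barrier top). Standard errors are 10-block jackknives over classical
configurations, the correlated unit for this estimator.

Isotope differences use single-ensemble mass perturbation: heavy paths are
the light paths contracted about their centroid by √(m_L/m_H), a map that
carries the light free-path measure exactly onto the heavy one, so
ΔF_qm(heavy) − ΔF_qm(light) is a log-ratio of exponential averages over
shared samples (jackknifed as a ratio, since numerator and denominator are
strongly correlated — that correlation *reduces* the variance). The overlap
guard is the effective sample size of each weight set separately, not of
their pointwise ratio; below 10 % of nominal an `OverlapError` fires.

`pi_kie` composes corrections as
ln KIE = −β[ΔΔG_qm^≠(light) − ΔΔG_qm^≠(heavy)]; the classical-PMF TST factor
is mass-independent and contributes a factor of one.
`pi_kie_from_frequency_sets` maps each matched mode pair onto a 1D harmonic
mode with effective mass ratio (ν_L/ν_H)² and sums per-mode FEP differences;
for harmonic systems this reproduces the Bigeleisen g-ratio within Monte
Carlo error as P → ∞, which is exactly how the demo's route-consistency
check is constructed.

Bead convergence is judged in closed form:
F_P = k_BT·ln(2·sinh(Pθ/2)) with cosh θ = 1 + (βħω)²/(2P²), increasing
monotonically in P toward k_BT·ln(2·sinh(u/2)). For a 2900 cm⁻¹ mode at
298 K the deviations are 0.40, 0.12, 0.032 and 0.008 kcal/mol at
P = 8, 16, 32, 64, so 64 beads are the smallest converged count at the
package's 0.02 kcal/mol criterion. That criterion is a design choice — what
counts as "converged" was open — picked as roughly chemical-accuracy/50 on a
free energy, i.e. ~1 % of a typical H/D correction; a soft 100 cm⁻¹ mode
converges already at 8 beads under the same rule.

## The demo and its problem sizes

The end-to-end demo builds a four-atom collinear Cl–C–H···O toy: bonds
Cl–C (0.16), C–H (0.30) and H···O (0.05 hartree/bohr²) with a 0.15 coupling
between the transfer bonds that makes the internal curvature indefinite by
exactly one eigenvalue, plus small bends (0.02 hartree). These numbers were
set once to place the C–H stretch near 3100 cm⁻¹, the C–Cl stretch near
700 cm⁻¹ and the primary H KIE in the 4–5 range characteristic of proton
abstraction, with C and Cl effects at the few-per-mil level — a cartoon of
the dehydrochlorination transition state, not a fit to any measured value.
Assumed secondary KIEs default to 1.0029 (C), 1.0008 (Cl) and 1.0156 (H),
the model-averaged secondary contributions reported for the real system.

Default sampling sizes: 2000 classical configurations × 10 path-integral
steps at P = 64 for the PI route; 14 umbrella windows × 2000 samples;
10 batch time points with 0.5 ‰ δ noise, fit with the free intercept. The
whole demo runs in about a second; the acceptance-scale BQCP checks use the
full 8000 × 10 sampling. All randomness derives from one master seed through
a `SeedSequence`, making reports byte-identical across reruns.

## What the generators do not emulate

The toys are 1D-coupled collinear springs: no electronic structure, no
explicit solvent, no anharmonicity, no mode crossing, no real γ-HCH
geometry. The batch simulator draws independent noise per time point —
no drift, no autocorrelated instrument error, no replicate structure. The
umbrella generator samples the stated profile directly — there is no
molecular dynamics, so WHAM is validated against known ground truth rather
than against a simulation it cannot see. Passing tests therefore demonstrate
the *inference machinery* is correct and calibrated under its stated
assumptions; they say nothing about whether a harmonic, tunneling-free,
1D-reduced model is adequate for a given real molecule — on the real system,
semiclassical hydrogen KIEs are known to overshoot measurements badly, which
is precisely the kind of model inadequacy this package helps diagnose, not
one it removes.

## Known limitations

- Sorted-order mode matching fails under crossing; only flagged, not solved.
- WHAM is 1D; free energies are only as good as window overlap, and the
  Freedman–Diaconis default can over-coarsen sharply peaked pooled samples.
- The BQCP estimator's exponential averaging degrades for βħω ≫ 15 at the
  shipped sample sizes; the ESS guard catches gross failure, not slow bias.
- `epsilon_to_akie` is intentionally naive; use the secondary back-inference
  for large effects.
- The free-intercept Rayleigh fit is calibrated but mildly less efficient
  than through-origin on truly noise-free anchors; choose per data quality.
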