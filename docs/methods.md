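# Methods

## Model

A bent dsDNA fragment of length l_cb, isolated from a longer chain, is
modeled as an axially loaded elastic column with elastic end restraints.
Buckling occurs when the axial compressive load reaches the Euler critical
load P_cr = π²EI/(μ l_cb)², with flexural rigidity EI = k_B T l_p (the
wormlike-chain identity) and effective length factor μ set by the end
constraints.  The load is the sum of two statistical support reactions:

- **Electrostatic.**  Manning's counterion-condensation force for a linearly
  charged polyion,
  F_ele = (k_B T / Z² l_B)[(2Zξ−1) κb e^(−κb)/(1−e^(−κb)) − 1 − ln(1−e^(−κb))],
  with κb = b/λ_D and ξ = l_B/b.  At 0.1 M monovalent salt and 298 K this is
  ≈ 47 pN, decreasing monotonically with salt; it diverges logarithmically
  as c → 0 and approaches −k_B T/(Z² l_B) at extreme ionic strength.
- **Thermal.**  F_tf = √(EA k_B T / l_cb).  With EA eliminated through
  EI = k_B T l_p and I = A R²/4 this is (2 k_B T / R)·√(l_p/l_cb).  The
  square-root form is the one consistent with the polynomial form of the
  model: substituting it into the critical-load balance and eliminating the
  radical yields the quartic below, whose zero-electrostatics limit is
  exactly the null-isomer law (see *Algebraic form*).

### Algebraic form

Writing f = F_ele/k_B T (units 1/m), the load balance squares to

    f² l_cb⁴ − (4 l_p/R²) l_cb³ − (2π² f l_p/μ²) l_cb² + (π⁴/μ⁴) l_p² = 0,

quartic in l_cb and quadratic in l_p.  The physical (larger) quadratic root
expands exactly into three additive terms

    l_p = (1/π⁴R²)[ 2μ⁴l_cb³
                    + 2μ³l_cb^{5/2} √(μ²l_cb + π²R²f)
                    + π²μ²R²l_cb² f ],

labelled TODC (constraint-only), TWDE (square-root environment coupling) and
TSDE (linear environment coupling).  Consistency checks built into the test
suite: at f = 0 the map reduces to l_p = 4μ⁴l_cb³/(π⁴R²) — the null-isomer
law l_cb³/(4π⁴R²) at μ = 1/2 — and dropping the thermal reaction leaves
l_p = μ²l_cb²f/π², which is identically the TSDE term.  Note that at f = 0
the TWDE term collapses onto the TODC value rather than to zero; the
environment-*dependence* of TWDE vanishes, not the term itself.

### Numerical choices

- The forward map uses the stable quadratic formula (the + root); it is
  vectorized over concentration for fitting.  The discriminant is
  16 l_cb⁵/R² (l_cb/R² + π²f/μ²); a negative value (possible only for
  strongly negative F_ele, i.e. far beyond the modeled 0.001–4 M range)
  raises with the offending inputs echoed.
- The inverse map solves the quartic through the numpy companion matrix in
  nanometer scale (SI-scale coefficients span ~60 orders of magnitude and
  destroy the eigenvalue conditioning).  The physical branch is selected by
  round-trip consistency: among positive real roots, the one mapping back to
  the input l_p within 1e-6 relative (ties by smallest round-trip error);
  no heuristic root ordering.  At f = 0 the quartic degenerates and the
  closed-form cube root is used.
- Uncertainty bands on predicted curves propagate only the spread of μ
  (band endpoints at μ ± σ_μ, l_cb held fixed) to avoid double-counting the
  statistical scatter of the per-class parameters.

## Effective length factors from end springs

The spring-to-μ map is a convenience layer built on standard column theory:
deflection y = A sin kx + B cos kx + Cx + D, one end held laterally with a
rotational spring, the other carrying a rotational spring and a lateral
sway spring.  The characteristic function is the 4×4 boundary-condition
determinant (rows normalized to O(1)); the smallest positive root α₁ = k₁L
of a sign-change scan (4000 points up to 2π + 0.5) refined by Brent's method
gives μ = π/α₁.  Dimensionless stiffnesses above 1e8 (or `inf`) substitute
the exact clamped/held boundary rows, avoiding overflow in the spring terms.
The four classical anchors (1.0, 0.5, 0.699, 2.0) are reproduced to 1e-3,
and μ is monotone non-increasing in each stiffness.  The case of all three
springs zero is a rigid-body mechanism (P_cr = 0) and is rejected.  Only μ
is consumed downstream, so alternative spring topologies that realize the
same μ are equivalent for the rest of the package.

## Fitting

(μ, l_cb) are fitted to (c, l_p) data by bounded nonlinear least squares
(`scipy.optimize.least_squares`) on unweighted residuals in nm, with the
parameters scaled to (μ, l_cb/nm) so both are O(1).  Default bounds
μ ∈ [0.3, 2.5] and l_cb ∈ [1, 30] nm bracket the range fitted across the
reference experiments (0.489–1.256; 4.18–15.83 nm).  Because the SSR
surface is a curved, nearly flat valley along the (μ, l_cb) trade-off, the
optimizer is restarted from a seeded Latin hypercube of initial points
(l_cb log-uniform; default 8 starts) and the lowest-SSR solution returned;
identical data + seed give bit-identical results.  r² = 1 − SSR/TSS, with
NaN (not an exception) when TSS = 0.

The flat valley has a practical consequence quantified by the recovery
study in the acceptance script: with 5% multiplicative noise on 12
concentrations, the *curve* is recovered tightly (median relative RMSE
≈ 0.02) while the individual parameters scatter strongly along the valley
(median relative errors ≈ 0.4–0.5).  This is a property of the model's
identifiability, not of the optimizer — noiseless data are recovered to
1e-13 — and it is mirrored in the large per-class standard deviations of
the reference fitted parameters (e.g. μ = 1.021 ± 0.250).

Per-class aggregation uses the arithmetic mean and the *sample* (n−1)
standard deviation: that convention reproduces the published per-class
aggregates (1.021 ± 0.250, 5.95 ± 2.20 nm; 0.718 ± 0.075, 8.43 ± 1.25 nm)
at printed precision, which the population form does not.

## Temperature procedure

1. The empirical cyclization law l_p(T) = (3.19 − 0.00414 T)×10⁻¹⁹/(k_B T)
   nm (≈ 47.6 nm at 298 K — the physiological scale, confirming the nm
   reading of the formula) is inverted through the map at μ = 0.5
   (cyclized fragments taken as clamp-clamp) to give l_cb(T).
2. An OLS line l_cb(T) = a + gT is fitted over 278–313 K (1 K steps, the
   no-denaturation window).  The ionic buffer behind the original empirical
   law is not stated, so the medium is a required argument; under a declared
   0.1 M monovalent test medium the pipeline gives g ≈ −0.0275 nm/K, the
   same sign and order as the reference gradient −0.0359 nm/K used for
   transfer (the acceptance script computes both).
3. The reference gradient is transferred to other constraint classes by
   anchoring at each class's 298 K mean: intercepts
   5.95 + 0.0359·298 = 16.65 nm (suspended) and 8.43 + 0.0359·298 =
   19.13 nm (fix-bead).  Predicted l_p(T) then follows by pushing the
   linear l_cb(T) through the map with ε_r recomputed at each temperature.

## Wormlike-chain ensemble estimator

The mean square end-to-end distance of a wormlike chain,
⟨h²⟩ = 2 l_p L [1 − (l_p/L)(1 − e^(−L/l_p))], is strictly increasing in l_p
at fixed contour length L (from 0 to the rod limit L²), so l_p is recovered
from an ensemble by Brent root finding (relative tolerance 1e-10).
⟨h²⟩ > L² is a domain error; within 1e-12 of L² the rigid-rod sentinel
`inf` is returned.  Contour length is measured along the polyline per
conformation and the ensemble mean is used; a per-frame mode (invert each
conformation, then average) and a burn-in index for trajectory-ordered
ensembles are provided, with the ensemble mode as default.

### Synthetic conformations

The sampler emulates simulation-derived helical axes with a discrete
wormlike chain: fixed bond length Δs = L/n_segments, successive bond angles
drawn from p(cos θ) ∝ exp(κ cos θ) with κ solved from the Langevin function
so that ⟨cos θ⟩ = e^(−Δs/l_p) *exactly* (hence tangent correlations decay as
e^(−s/l_p) in expectation), azimuth uniform, first tangent uniform on the
sphere.  Defaults mirror the simulation scale the estimator is meant for:
L = 17 nm (50 bp × 0.34 nm), 50 segments, 2000 chains.  What the synthetic
ensembles do **not** emulate: sequence-dependent bending, static curvature,
backbone elasticity (bond lengths are fixed), and the temporal correlation
of frames from a real trajectory — so passing recovery tests demonstrates
the estimator's correctness on ideal-WLC statistics, not the fidelity of
any molecular-dynamics protocol.  At the 17 nm scale the chain is far from
the Gaussian regime and the estimator is noticeably sensitive to ensemble
size; with 2000 chains the recovery of a 50 nm input is within a few
percent (the acceptance script recomputes it each run).

## Synthetic salt-curve generator

Study conditions for the fitting recovery: true parameters μ* = 0.8,
l_cb* = 7 nm (mid-range of the fitted experiments), 12 concentrations
log-spaced over 0.001–4 M (the modeled coverage), multiplicative lognormal
noise with 5% coefficient of variation (measurement scatter across
techniques is roughly proportional), 200 replicates.  The generator shares
the forward map with the fitting code by construction (it *is* the model);
what the recovery study validates is the optimizer and the identifiability
structure, not the physics.

## Known limitations

- Single-salt media only; no mixed buffers, no Poisson–Boltzmann level
  electrostatics (Debye–Hückel/Manning screening only).
- No sequence dependence; the fragment is a homogeneous elastic column.
- The spring parameterization behind μ is a reconstruction; only μ itself
  is identifiable from data.
- Distributed substrate interaction (adsorbed molecules on mica/carbon) is
  not modeled; the adsorbed reference row is carried as data but the
  per-class analysis covers the suspended and fix-bead classes.
- Model constants are fixed at the reference precision (k_B = 1.38e-23 J/K
  etc.) for consistency with the published arithmetic, not at CODATA
  precision.
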