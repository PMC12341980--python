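# Methods

## The surrogate construction

`specex` builds meta-models of deterministic biological models whose
parameters are uncertain.  A model response `Y(k)` with independently
distributed parameters `k_j` is represented by a truncated series in basis
functions `phi_n` orthonormal with respect to the distribution of the
standardised parameter `theta` (Legendre polynomials for uniform parameters,
probabilists' Hermite for normal/lognormal, Charlier for Poisson counts,
optionally Haar wavelets composed with the parameter CDF).  The expansion
coefficients are obtained without modifying the model ("non-intrusive"):
the key object is the symmetric matrix

    B_nm = ∫ phi_n(θ) θ phi_m(θ) P(θ) dθ,

the matrix of multiplication by θ in the orthonormal basis.  Its
eigenvalues λ^(l) are the model-evaluation nodes, and with orthonormal
eigenvectors u^(l) (sign-fixed so the first component is non-negative) the
surrogate reads

    Y_s(θ) = Σ_l Y(λ^(l)) u1^(l) ψ_l(θ),      ψ_l(θ) = Σ_n u_{n+1}^(l) phi_n(θ).

For polynomial bases B is the Jacobi matrix of the three-term recurrence, so
nodes and weights (u1^(l))² coincide with Gaussian quadrature — the
construction is the Golub–Welsch algorithm, but it applies verbatim to any
orthonormal family (we use it for Haar wavelets, where the nodes come out as
the dyadic cell midpoints with equal weights).  Multivariate surrogates are
full tensor products: Π_j N_j model evaluations, coefficients
c_{n1..nM} = Σ_l Y(λ^(l1..lM)) Π_j u1^(lj) u_{nj+1}^(lj).  Mean and variance
follow from the coefficients (mean = c_0..0, variance = Σ c² − c_0..0²), and
Sobol sensitivity indices are ratios of coefficient-square sums.  Two Sobol
readings are provided: `sobol_first_order` (multi-indices exclusive to one
dimension — the classical first-order index) and `sobol_total_like`
(all multi-indices whose i-th entry is positive — the total-effect index).

### Numerical choices

* Analytic `B` uses the standard orthonormal recurrence coefficients
  (off-diagonal `(n+1)/sqrt((2n+1)(2n+3))` for Legendre, `sqrt(n+1)` for
  Hermite, diagonal `n+λ` / off-diagonal `−sqrt((n+1)λ)` for Charlier).
  The numeric path (`build_B_numeric`) integrates in θ-space with composite
  Gauss–Legendre panels, doubling the subdivision until entries are stable
  to 1e−8.  Unbounded supports are truncated where
  `pdf(θ)·|θ|^(2N+1)/(N−1)!` — a bound on the orthonormal-basis integrand —
  drops below 1e−12; discrete supports are extended until added terms
  change nothing at 1e−10.  Both paths agree with the analytic matrices to
  ~1e−14 for N ≤ 12.
* Eigenvectors are sign-fixed (first component ≥ 0); zero first components
  (possible for non-polynomial bases) only remove zero-weight terms and
  trigger a warning.
* Node tuples are visited in row-major order over ascending eigenvalues;
  refitting with the same inputs is bit-reproducible.
* Non-finite model outputs abort a fit immediately with the offending
  physical parameter vector in the error message.

## Segmentation

For responses needing high order (bifurcations, steep fronts) the standard
interval `[−L, L]` is split into `2M+1` equal segments via the affine map
`g_m(θ) = 2mL/(2M+1) + θ/(2M+1)` and an independent order-N expansion is
fitted per segment tuple; reconstruction locates the segment with
`z(y) = floor((2M+1)y/(2L) + 1/2)` (clamped so `y = ±L` falls in the outer
segments) and evaluates that segment's expansion at `g_m^{-1}(y)`.  Fitting
costs `(2M+1)^K N^K` model runs; the naive reconstruction sum has
`n_outputs · N^(2K)` terms, which is why a small N with modest M is vastly
cheaper to post-process than one large-N expansion (e.g. 3·2¹⁰ = 3,072 vs
3·6¹⁰ ≈ 1.8e8 terms at equal model-run budgets).

**Truncation for unbounded dimensions.**  Segmentation needs a bounded
domain.  For Hermite dimensions we truncate at `L = 2` (95.4% of the mass)
by default.  This is a real trade-off, not a free parameter: within a
segment the expansion is evaluated at local coordinates spanning all of
`[−L, L]`, far outside the node set (the order-3 Hermite nodes sit within
±1.73), so segment-edge accuracy decays rapidly with L.  Measured on the
dimer network (N=3, M=1, distribution-typical draws): max relative error
1.2% at L=2, 15% at L=3, ~150% at L=5, against 2.8% for the unsegmented
N=6 expansion.  Widen `L` only when tail coverage matters more than
pointwise accuracy.

## Haar wavelets

The Haar family on a reference CDF F comprises the constant plus wavelets
`2^(j/2) ψ(2^j F(θ) − k)` for scales j = 0..J — `2^(J+1)` functions at
resolution level J (level 3 → 16, level 6 → 128).  The eigenvalue scheme
applied to this basis yields the 2^(J+1) dyadic cell midpoints as nodes
with equal weights, i.e. the expansion reproduces cell averages: functions
piecewise-constant on the dyadic cells are reconstructed exactly away from
breakpoints, and discontinuous responses (pattern/no-pattern transitions)
are captured without Gibbs oscillation at the price of first-order
convergence for smooth responses.

## Correlated counts

Correlated plasmid uptake is modelled by the bivariate Poisson distribution
built by trivariate reduction: `n = n' + c`, `m = m'' + c` with independent
`n', m'' ~ Poisson(λ−ξ)` and shared `c ~ Poisson(ξ)`, giving Poisson(λ)
marginals and correlation ξ/λ.  The PMF is evaluated by the terminating
reduction series in log-space; an equivalent closed form through Kummer's
confluent hypergeometric function U (computed via its terminating 2F0
series) serves as a cross-check oracle, and both agree to ~1e−16 on the
printed parameter sets.  The support is truncated where the Poisson(λ)
tail drops below 1e−10.

The correlated expansion transforms the product basis by
`ψ~_{l1,l2}(n,m) = sqrt(P(n)P(m)/P(n,m)) ψ_l1(n) ψ_l2(m)` — orthonormal
under the joint distribution — and uses weights
`w_{l1,l2} = E_joint[ψ~_{l1,l2}]`, the joint-expectation analogue of
`u1^(l) = E[ψ_l]`; at ξ = 0 this reduces exactly to the independent
two-dimensional fit.  **Known limitation:** at strong correlation the
`sqrt(P(n)P(m)/P(n,m))` factor is sharply ridged and its projection onto a
low-order polynomial span converges slowly; at λ=3, ξ=2.4 (corr 0.8) the
order-6 expansion carries O(10–30%) relative errors at individual
compositions (amplified at improbable pairs where the prefactor is large),
decreasing monotonically with order.  The test suite asserts the exact
ξ=0 reduction, the convergence trend, and documents the order-6 accuracy
as measured rather than assumed.

## Quasi-Monte-Carlo reference

Reference solutions use scrambled Sobol sequences mapped through each
parameter's standard distribution (deterministic given the scramble seed).
Moment errors come from the blocking method: the sample is cut into
consecutive blocks (default 16), the moment computed per block, and the
error taken as the standard deviation of block values over sqrt(blocks).
Output PDFs are Gaussian-kernel KDEs with the robust Silverman bandwidth
`0.9·min(sd, IQR/1.34)·n^(−1/5)`.

## The example systems

All six fixtures are deterministic given (parameters, seed) and are
generated in code — no stored data.

1. **Exponential decay** `A(t) = A0 e^(−kt)`, k ~ Lognormal(mean 0.5,
   sd 0.2).  The exact output PDF follows by change of variables
   (`P_A(a) = P_k(−ln(a/A0)/t)/(at)`) and anchors the KDE comparisons.
   Note the lognormal is parameterised by its arithmetic mean/sd.
2. **Dimer network**: monomers x1, x2 produced at k1, k4 bind (k2) into a
   dimer x3, unbind (k3), all degraded at k5; zero initial conditions;
   k1,k4,k5 ~ Lognormal(0.1, 0.1), k2,k3 ~ Lognormal(0.4, 0.1).  The exact
   identity d(x1+x3)/dt = k1 − k5(x1+x3) is used as an integration check.
3. **Glycolytic oscillator** (ADP/F6P two-variable model) with
   α ~ U(0.1, 0.5), β ~ Lognormal(0.3, 0.1): a Hopf bifurcation separates
   sustained oscillation (α=0.1, β=0.46) from a stable fixed point
   (α=0.5, β=0.46); the mixed Legendre×Hermite expansion and time-resolved
   Sobol indices are exercised here.
4. **Schnakenberg reaction–diffusion** on a 20-cell line (unit spacing,
   zero-flux): β=1, γ=5, d=20, α ~ U(0.001, 0.45).  The Turing-space test
   evaluates the classical conditions on the discrete Laplacian spectrum;
   simulations start from the homogeneous steady state with 1% seeded
   noise and integrate until the relative state change over a 10-time-unit
   window falls below 1e−6.  α=0.22 patterns (the boundary sits at
   α ≈ 0.23), α=0.24 stays flat; close to the boundary the pattern
   amplitude is small (v-field CV ≈ 0.07 at α=0.22, > 0.1 for α ≤ 0.20).
5. **Trichome patterning**: substrate-depletion model for TTG1/GL3/AC on a
   20×20 periodic hexagonal lattice (6-neighbour Laplacian, axial
   coordinates); only TTG1 diffuses.  α ~ U(0.4, 0.9); the remaining
   non-dimensional parameters are fixed at λ=0.3, β=6, δ=1, chosen by a
   linear-stability scan so the Turing boundary (α ≈ 0.60) lies inside the
   fixture range — the cited model does not pin these values, so they are
   package defaults, exposed as arguments.  The response is the trichome
   density (fraction of cells with AC above half the field maximum), gated
   to 0 outside the Turing space; the "direct" expansion expands this
   gated scalar, the "indirect" expansion reconstructs the 400-cell AC
   field and thresholds afterwards.
6. **Plasmid transfection**: per-composition reporter dynamics
   (x: induced protein, y: reporter, saturating production) with the cell
   pool tensor Q_{n,m} growing logistically (ω=0.034/h, i.e. 20 h doubling)
   while binomial partition (q=0.5) dilutes plasmids at division; uptake is
   the bivariate Poisson above.  Defaults: α=2, β=2, γ=6, η=0.5, μ=1.5,
   κ=0 (single-cell readout; κ=3, δ=0.01, v=1e−8 for the secreted bulk
   reporter), N0=1e5, Nmax=1e6, histogram bin width g=5.  Because
   y_{n,m} = m·w_n, only the n-indexed profiles are integrated.  The
   single-cell readout histogram `P(z,t)` bins `z = g·floor(y/g)` with
   weights Q/‖Q‖₁; both the "6 h after induction" and late-time readouts
   are available as arguments since the appropriate measurement time is
   protocol-dependent.

## What the fixtures do and do not show

The fixtures emulate the qualitative regimes that stress the method —
skewed parameter distributions, bifurcations, spatial discontinuities,
correlated counts — with exactly reproducible dynamics.  They do not
emulate measurement noise, model misspecification, gene-expression
stochasticity, or reporter maturation, so passing tests demonstrate
correctness of the surrogate machinery on clean deterministic responses,
not robustness of conclusions drawn from noisy data.

## Problem sizes used in the test suite

The accuracy tests run the full printed configurations where they are the
point of the claim (59,049 dimer solves for the N=3/M=1 segmented check;
16 trichome lattice relaxations for the level-3 Haar comparison; 10^5 QMC
draws for the KDE comparisons) and small representative sizes elsewhere;
each test states its configuration in code.
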