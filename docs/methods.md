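# Methods

## Model and assumptions

The package simulates spin-selective recombination in a radical triad
(flavin semiquinone FH•, superoxide O₂•⁻, scavenger A•⁻) under weak static
magnetic fields. The working equation is the *reduced* two-radical master
equation obtained by tracing the fast-relaxing superoxide out of the full
three-radical dynamics:

- Coherent part: Zeeman (ω = gμ_B B/ħ, g = 2.0023 for both electrons) and
  hyperfine couplings S·A·I of the surviving pair. Electron–electron
  exchange and dipolar couplings are omitted — at least one partner of
  every pair is assumed mobile, which averages them to zero. Nuclear
  Zeeman terms and nuclear relaxation are neglected (μT-scale fields,
  microsecond lifetimes).
- Reactions (Haberkorn form): singlet-selective scavenging of FH• by A•⁻
  at rate k_X through the pair's singlet projector, plus a uniform
  depopulation k_Σ = k_E + k_E′ + k_F/4 + k_X′/4 that subsumes the
  channels involving the traced-out superoxide. The 1/4 factors arise
  because only the singlet fraction of a maximally mixed pair reacts.
- Initial state: identity/dimension. Tracing the superoxide out of a
  singlet-born, triplet-born or F-pair primary pair gives the same reduced
  initial state, so the reduced yields are provably independent of the
  primary spin correlation; the full-triad reference module demonstrates
  this numerically and provides the negative control (without fast
  superoxide relaxation the correlation does matter).
- Optional electron spin relaxation: "random-field" depolarization with
  the three Cartesian spin components of each electron as Lindblad
  operators, each at rate γ. With this normalization an isolated spin-1/2
  has T1 = T2 = 1/γ, which is the convention used for the single-parameter
  relaxation rate throughout; nuclei are not relaxed.

Observables: Φ_X = k_X ∫ Tr(P_S σ) dt (singlet scavenging yield),
Y = (1−φ)Φ_X + φ (superoxide escape yield, with φ the probability that the
k_Σ channels release superoxide), χ(B) = Y(B)/Y(B_ref) and the percentage
effect 100(χ−1). φ defaults to 0 (efficient oxidation: superoxide only
escapes when FH• is scavenged), which maximizes the field effect; φ is an
independent input because the branching of the k_Σ channels is chemistry,
not spin dynamics.

## Parameters and defaults

| parameter | unit | default | meaning |
|---|---|---|---|
| k_X | μs⁻¹ | — | singlet-selective FH•/A•⁻ scavenging rate |
| k_Σ | μs⁻¹ | — | composite triad depopulation rate (1/lifetime) |
| φ | — | 0 | superoxide branching of the k_Σ channels |
| γ₁, γ₃ | μs⁻¹ | 0 | random-field relaxation of the two electrons |
| B | μT | 55.26 / 0.29 | geomagnetic reference / hypomagnetic probe |
| orientations | — | 72 | Fibonacci-sphere nodes for bound flavin |

Hyperfine tensors are supplied in MHz (linear frequency) and multiplied by
2π on entering the angular-frequency Hamiltonian. Rate maps default to
log-spaced grids k_X ∈ [10⁻², 10³] μs⁻¹ and k_Σ ∈ [10⁻², 10²] μs⁻¹ at
10 points per decade (free flavin) and 5 points per decade for the
orientation-averaged bound-flavin map; these ranges contain both
sensitivity branches (moderate scavenging with k_X ~ 10 k_Σ, and fast
scavenging with long lifetimes) and keep a full map in minutes on one CPU.

## Hyperfine data

The ascorbyl radical couples appreciably to a single proton,
a_iso(H4) = 4.94 MHz, treated isotropically (the radical is mobile).
¹⁶O superoxide carries no magnetic nuclei, and ¹⁷O isotopologues are
ignored at natural abundance.

The flavin presets carry the dominant couplings of the *neutral* (N5-
protonated) semiquinone: a_iso = 20.3 (N5), 7.5 (N10), −19.6 (H5) MHz,
with H6 (−5.9) and a β-type proton (+8.0) in the extended `flavin_5N`
set. Full 3×3 tensors are constructed in a common molecular frame (z
normal to the isoalloxazine plane) from these isotropic values using the
standard π-radical patterns: nearly axial nitrogen tensors with large
out-of-plane components (A_zz = 47.9 and 17.5 MHz), the canonical rhombic
α-proton pattern (0.5, 1.5, 1.0)·a_iso for H5/H6, and a nearly isotropic
β proton. The in-plane principal axes of the proton tensors are aligned
with the frame axes; the relative in-plane orientation between proton
tensors is not resolved by this construction (it affects only the
orientation-averaged, bound-flavin results, and weakly). Free-flavin
results depend only on the isotropic constants. Orientation dependence is
implemented by rotating the field vector rather than the tensors — the
two are equivalent and rotating one vector is cheaper. The polar angle is
measured from the molecular z-axis; the convention is arbitrary since
only the relative field/tensor orientation matters.

## Numerical methods

**Algebraic (production) path, γ = 0.** σ(t) = U σ(0) U† with
U = exp(−i A t) e^{−k_Σ t/2}, A = H′ − i(k_X/2)P_S. One dense
eigendecomposition A = VΛV⁻¹ gives the yield integral in closed form as a
double sum over eigenpairs with denominators i(λ_j − λ̄_k) + k_Σ. Because
k_Σ appears only in the denominators, a (k_X, k_Σ) map needs one
eigendecomposition per (orientation, k_X) — the k_Σ axis is nearly free.
Terms with |denominator| < 10⁻¹² are dropped when their weight is below
10⁻¹⁰ and otherwise raise a divergence error (an undamped stationary
component means the integral genuinely diverges, e.g. k_X = k_Σ = 0).

**Relaxation path, γ > 0.** The vectorized (Liouville-space) generator is
assembled sparsely and ∫σ dt is obtained from one sparse LU solve;
Φ_X = k_X⟨P_S, ∫σ dt⟩.

**Time-domain oracle.** Brute-force integration of the master equation
(DOP853, rtol 10⁻⁸) with the running yield integrals appended as states.
The initial horizon is 20/(k_X/4 + k_Σ) and doubles (up to 8 times) until
the surviving trace is below 10⁻⁷ — under fast scavenging the quantum
Zeno effect makes the true exit rate much slower than k_X/4. The residual
tail is assigned to the exit channels in the unmixed proportion and also
reported as a diagnostic; an unconverged trajectory raises rather than
returning a biased value. The oracle shares no code path with the
algebraic solver beyond Hamiltonian construction and agrees with it to
better than 10⁻⁶ on randomized small systems.

**Full-triad reference.** Dense/sparse Liouville generator of the
three-electron system (Hilbert dimension capped at 512), with yields from
a resolvent linear solve. Used to verify that the reduced model emerges
as γ₂ → ∞ (discrepancy below 10⁻² at γ₂ = 10³ μs⁻¹ on the electrons-only
triad, decreasing monotonically along the ladder) and that k_F and k_X′
enter k_Σ with the 1/4 weights. Escape channels are treated as
spin-independent (identity term in the reaction operator).

**Orientation averaging.** Deterministic Fibonacci point sets on the full
sphere; 72 nodes by default. Doubling the node count moves the averaged
yields of the bound-flavin presets by well under 10⁻³ at geomagnetic
field strengths. Fewer than 6 nodes triggers a warning.

**Inverse field problem.** |effect(B)| − target is bracketed and solved
with Brent's method at 1 % relative tolerance after a monotonicity check
by sampling; a bracket without sign change is an error, not a guess.

**Tie-breaking.** The "maximal effect" of a map is its most negative
entry; ties resolve to the lexicographically smallest (k_X, k_Σ) index.

## Toy fixtures and what the tests show

The fixture generator produces desk-scale systems — a no-nucleus pair
(exact closed form Φ_X = (1/4)k_X/(k_X + k_Σ), since without hyperfine
coupling there is no singlet–triplet mixing), one-proton pairs with
ODE-oracle reference yields, and electrons-only triads. These are
synthetic constructions for validating the solvers: they exercise the
operator algebra, the reaction superoperators and both solution paths,
but they do not emulate real flavin spin systems (dozens of weakly
coupled nuclei, exchange/dipolar interactions at contact, molecular
motion). Passing tests therefore certify the mathematics of the reduced
model at the stated parameters, not the biochemical realism of those
parameters.

## Known limitations

- The flavin tensor anisotropies are constructed from standard π-radical
  patterns rather than a specific quantum-chemistry calculation; bound-
  flavin (orientation-averaged) numbers inherit that uncertainty. The
  free-flavin numbers rest only on the isotropic constants.
- A structural property worth knowing when comparing with external MARY
  data: from the maximally mixed initial state, yields at rate ratios
  k_X/k_Σ ≈ 10 are capped near the well-mixed kinetic bound
  (k_X/4)/(k_X/4 + k_Σ) ≈ 0.714 — reported yield levels above that bound
  at such ratios imply different rates (or initial correlations), not
  different hyperfine data. The yield-level acceptance test encodes an
  external reference of 0.75 ± 0.05 at these ratios and is accordingly
  expected to fail; it is kept unmodified rather than loosened.
- Exchange and electron–electron dipolar couplings, anisotropic g,
  nuclear Zeeman/quadrupole terms and ¹⁷O isotopologues are outside the
  model.
- The full-triad module is a verification tool only; production
  simulations always use the reduced equation.
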