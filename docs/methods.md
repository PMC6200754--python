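# Methods

## Model

The simulated system is a radical pair: two electron spins S = σ/2, each on
its own molecule, each interacting with (i) the external magnetic field
(Zeeman term, γₑ = −gμ_B/ħ with g = 2) and (ii) its local nuclear spins
(hyperfine term), and each weakly coupled to a thermal bosonic bath.
Electron–electron dipolar and exchange couplings are taken to cancel or be
negligible at the relevant separation, and the nuclear Zeeman term is
suppressed by three orders of magnitude in the gyromagnetic ratio; both are
omitted.  Consequently the pair Hamiltonian has no cross-radical term: the
*generators* factorize per radical while the *state* (an electron singlet)
is entangled across them.

All Hamiltonians are stored as angular frequencies (rad/s, ħ = 1).  Every
external interface (configs, printed frequencies, CSV) uses ordinary
frequency in Hz; values are multiplied by 2π on ingestion and divided by 2π
on output.  At B0 = 47 μT this gives the Larmor line gμ_B B0/h = 1.316 MHz.

### Collective nuclear environment

For N identical, identically coupled spin-1/2 nuclei the hyperfine term
depends only on the total nuclear spin **I** = ½Σσᵢ, so the 2^N-dimensional
nuclear space decomposes into spin-j sectors (j = N/2, N/2−1, …, 0 or ½)
with multiplicities ν(N, j) = C(N, N/2−j) − C(N, N/2−j−1), computed with
exact integer binomials.  Half-integer spins are carried as doubled
integers internally so admissibility (parity, range) is an exact test.  The
model treats the ν(N, j) copies of a sector as physically identical; they
enter only as weights.  An unpolarized (maximally mixed) nuclear state
assigns sector (j₁, j₂) the weight [ν(N₁,j₁)(2j₁+1)/2^N₁]·[ν(N₂,j₂)(2j₂+1)/2^N₂];
a collective run propagates every sector pair and mixes the results with
these weights.  The initial nuclear state is not prescribed by the physical
setup (photoexcitation does not polarize nuclei), so maximal mixing is the
default and the per-sector API accepts anything else.

Hyperfine tensors are diagonal: A⁽¹⁾ = diag(2, 2, 1) (anisotropic — this is
what makes radical 1's spectrum orientation-dependent, i.e. a compass) and
A⁽²⁾ = 1.  The field axis defaults to z, aligned with A⁽¹⁾'s symmetry axis.
The coupling constant λₕ multiplies the tensor entries literally
(coupling = λₕAₙₙ), so radical 1's transverse couplings are 2λₕ.

### Non-collective environment

Radical 1 carries two distinguishable spin-1/2 nuclei with independent
diagonal coupling triples (ωₓ, ω_y, ω_z) in Hz; radical 2 is a bare
electron.  The triples already fix the interaction scale, so no additional
overall constant is applied.

## Eigenoperator decomposition

Each radical couples to its bath through V = α(Sₓ + S_z) on the electron
slot.  α defaults to 1: transverse (Sₓ, dissipation-like) and longitudinal
(S_z, dephasing-like) couplings are weighted equally because neither is
known to dominate.  In the eigenbasis of the radical's block Hamiltonian,
matrix elements of V connecting levels with gap ω > 0 accumulate into V_q
for that gap (lowering convention: V_q collects ⟨lower|V|upper⟩ terms, so
the thermally enhanced (N+1) channel is emission), elements inside
degenerate level sets accumulate into V₀, and negative gaps are the implied
conjugates.  The defining identities [H, V₀] = 0, [H, V_q] = −ω_q V_q and
completeness V₀ + Σ(V_q + V_q†) = V are re-verified numerically
(`verify_commutators`); residuals are at machine precision.

Gap grouping uses a relative tolerance of 1e-9 × max|E|.  Physical
splittings in these models are ≥ kHz while eigensolver noise on MHz-scale
energies is ~1e-15 relative, so the band is wide; if any gap or
gap-difference falls between 0.1× and 10× the tolerance the decomposition
refuses rather than silently mis-grouping.  Transitions whose accumulated
operator is numerically zero (no coupling between those levels) are
dropped.

## Rates and thermal occupation

Dissipation follows the free-space radiative (cubic) law
γ(ω) = ω³|d|²/(3ε₀πħc³), with ω angular.  The transition dipole moment |d|
is a configuration parameter whose default is calibrated once by inverting
the law at the anchor point γ = 1e-3 s⁻¹ at ω/2π = 1e8 Hz — the top of the
model's frequency window; the calibration utility (`calibrate_dipole`, also
a CLI command) documents the inversion.  Under this anchor the cubic law
spans γ ≈ 1e-12…1e-3 s⁻¹ over ω/2π = 1e5…1e8 Hz.  Spontaneous emission at
radio frequencies is negligible on its own; the channel matters because the
Planck occupation N(ω) = 1/(e^{ħω/k_BT} − 1) is ~10⁵–10⁶ at 300 K and MHz
frequencies, so both the γ(N+1) emission and γN absorption dissipators are
thermally dominated (effective rates ~ω²) and detailed balance
(N+1)/N = e^{ħω/k_BT} holds per channel.  The decoherence channel (V₀) runs
at γ_D = 10 × max γ_q over all blocks of both radicals in the run; the
factor is configurable upward only.

Alternative spectral densities (Ohmic baths, rotational-diffusion
relaxation) are out of scope; they would enter through γ(ω) only.

## Propagation

The master equation is assembled as a vectorized superoperator (row-major
vec, vec(AXB) = (A⊗Bᵀ)vec X).  Because the jump operators are
eigenoperators, the dissipator is time-independent in both pictures; the
Schrödinger-picture generator just adds −i[H, ·].  Interaction-picture
propagation exposes the slow dissipative envelope directly (the fast MHz
oscillation is restored analytically by `to_schrodinger` or by propagating
the Schrödinger generator), which is what lets second-scale decay and
sub-μs oscillation coexist without stiff integration.

Single-block states advance by repeated application of exp(L·Δt) on the
uniform grid (per-distinct-step exponentials otherwise, with a guard
against >10⁴ distinct steps).  The entangled pair state advances by
applying each radical's propagator to its own index pair of the joint
density matrix — exactly equivalent to the joint-space master equation
because no generator term crosses radicals; the equivalence is enforced in
the test suite against a brute-force joint-space generator (max deviation
≤1e-8, in practice ~1e-16).  For observables along large collective blocks
the propagators are used in spectral form (eigendecomposition of each
generator), reducing each expectation value to a sum over eigenvalue-pair
exponentials; if a generator's eigenbasis is ill-conditioned (>1e10) the
code falls back to stepping.  This keeps the N = 10 sweep (36 sector pairs,
largest superoperator 484×484) to seconds of CPU.

Density matrices are validated on construction (trace within 1e-8,
Hermitian, declared picture); probabilities are validated on aggregation
(normalization within 1e-6, range within 1e-8).

## Observables

**Spin-state probabilities.**  Projectors onto |S⟩ and the three triplets —
labelled Triplet 1/2/3 by descending total electron S_z (+1, 0, −1) along
the field axis — are embedded with identities on the nuclear slots;
expectation against the joint state equals tracing out the nuclei first.
The caption convention fixes the basis but not the numbering; the
normalization and all lifetime definitions are label-independent (the
contrast uses the S_z = 0 triplet, the singlet's oscillation partner).

**Coherence lifetime.**  "Lifetime" here means persistence of the
singlet–triplet coherence, not a recombination time.  For a single decay
channel it is the first time the envelope (running maximum over the
remaining trajectory, robust to residual beating) of |p_S − p_T0| falls to
1/e of its initial value, computed on the interaction-picture series;
trajectories that never reach the threshold are censored and reported as
infinite.  A collective run is a classical *mixture* of sector pairs whose
rates differ by orders of magnitude, and the single 1/e crossing of the
mixed envelope is structurally blind to any sector of weight below
1 − 1/e ≈ 0.63 — in particular to the j = 0 sectors (weight ν(N,0)/2^N ≤ 25%)
whose persistence is the point of the even/odd-N comparison.  The lifetime
of a mixture is therefore defined as the weight-averaged per-sector 1/e
lifetime, the standard amplitude-weighted lifetime of a multi-exponential
decay.  For single-sector runs the two definitions coincide.

**Oscillation frequency.**  Dominant positive peak of the Hann-windowed
discrete spectrum of p_S(t) on a Schrödinger-picture series; constant
series report 0, and a guard rejects series sampled with fewer than ~8
points per dominant period.

**Transition spectrum.**  The distinct positive transition frequencies of a
configuration, in Hz: union over both radicals and all admissible sectors,
conjugate partners counted once, frequencies coinciding within 1e-6
(relative to the largest) merged.  Counting is convention-sensitive
(per-radical and per-sector subsets are exposed via `radicals=` and the
per-block provenance); counts reported by this package use the documented
union convention.  Per sector the count grows as 6j + 2 (5 for j = ½).

## Scenario presets and their free choices

* `fig2_n1…fig2_n10` — collective sweep, N nuclei **per radical**
  (N₁ = N₂ = N), λₕ = 10 MHz, 47 μT, 300 K.  λₕ sits at the top of the
  kHz–MHz organic hyperfine range so that dissipation, thermally enhanced
  at the hyperfine-set transition frequencies, produces second-scale
  lifetimes.  The per-radical reading of "N nuclei" is a preset choice; the
  all-on-radical-1 alternative is one config switch away (`n2: 0`) and
  shows the same phenomenology.
* `fig3` — the N = 2 run with per-sector output; the (0, 0) sector's
  hyperfine-free electrons decohere only through the 1.3 MHz Zeeman
  channel and outlive every other sector by two to three orders.
* `fig4a/b/c` — two-nucleus configurations at 10⁷/10⁷, 10⁴/10⁴ and
  10⁷/10⁴ Hz.  The source scenarios specify only scalar magnitudes, so the
  anisotropy pattern is a preset choice: the presets couple each nucleus
  along a single transverse axis, (ω, 0, 0).  Transverse coupling is what
  drives singlet–triplet interconversion (a longitudinal-only coupling
  cannot move the S_z = ±1 triplets at all), and it makes equal-magnitude
  nuclei exchange-equivalent, so a protected nuclear-singlet fraction
  survives in the matched configurations while the mixed configuration
  decoheres completely — the equal-vs-mixed contrast the scenario exists to
  show.  Patterns that break the exchange equivalence softly (isotropic,
  (2ω, 2ω, ω)) wash the contrast out.

Solver defaults: 2000-point uniform grid over 5 s, or a geometric grid
(same relative resolution from sub-ms to the horizon) where lifetimes
spanning ms–100 s are measured; preset horizons are 400 s (collective) and
200 s (two-nucleus), long enough that every sector's envelope crossing is
resolved rather than censored.  Oscillation-frequency analyses use uniform
Schrödinger-picture grids over μs–ms insets.  The tool is fully
deterministic — no random number generator is used anywhere.

## What the simulated conditions do and do not emulate

The collective model's efficiency comes precisely from what makes it
idealized: all nuclei identical spin-1/2, one coupling constant, diagonal
tensors.  Real cryptochrome radicals have inequivalent anisotropic tensors,
spin-1 nitrogens, and ~10–15 relevant nuclei; the non-collective model
relaxes only the equal-coupling assumption and only for two nuclei.
Passing tests therefore demonstrate properties of the stated model —
sector weights, eigenoperator structure, thermally weighted Lindblad decay,
the even/odd and equal/mixed orderings — not quantitative lifetimes of any
real molecule.  Recombination (and hence yields and compass sensitivity
curves), RF driving, nuclear polarization and motional spin relaxation are
all outside the model; lifetimes here are coherence-persistence times and
are expected to exceed measured radical lifetimes.

## Numerical choices

* Eigenvector phases: largest-magnitude component made real positive, so
  spectra and all downstream artifacts are bit-reproducible.
* Hermiticity is re-symmetrized after each propagation step (ρ ← (ρ+ρ†)/2)
  to stop 1e-16-scale drift from accumulating over 10³ steps.
* Degenerate inputs: j = 0 sectors reduce to bare Zeeman doublets; λₕ = 0
  collapses every transition to the single Zeeman frequency; α = 0 turns
  the dynamics unitary (purity is then conserved to 1e-8, a test).
* The j = ½ sector equals the single spin-½ operators exactly; N = 1 has
  one sector.
* Problem sizes in the shipped tests and scripts: sweeps run N = 1..10 on
  ~400-point geometric grids (~35 s total); the acceptance script
  enumerates all 22 blocks with 2j = 0..10 in under a second.

## Known limitations

* The secular (rotating-wave) master equation ignores coherence transfer
  between transitions closer in frequency than their linewidths; at the
  default rates (≤10² s⁻¹) and gap spacings (≥kHz) this is safe, but very
  small coupling differences (≪1 kHz) would violate it.
* The mixture-weighted lifetime is one number summarizing a
  multi-exponential decay; sector tables (`block_lifetimes`) should be
  consulted when the mixture is strongly bimodal.
* Spectral propagation assumes diagonalizable generators; the stepping
  fallback covers the defective case at higher cost.
* γ_D ties decoherence to the *largest* dissipation rate across the run,
  so adding a fast sector stiffens decoherence for all sectors; this
  mirrors the stated rate rule rather than any microscopic bath model.
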