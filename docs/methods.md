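# Methods

## Model

The package simulates a two-site excitonic system (a spin-boson model)
with Hamiltonian

    H_S = (ε/2) σ_z + (Δ/2) σ_x,        ħ = k_B = 1,

site |1⟩ at the Bloch north pole, |2⟩ at the south pole, energy bias ε and
tunnelling (electronic coupling) Δ. All internal energies are measured in
units of Δ and time in 1/Δ; spectroscopic inputs are converted with
ω[rad/ps] = 0.188365·ν̃[cm⁻¹] and k_B = 0.695035 cm⁻¹/K. An external
drive modulates the tunnelling, Δ(t) = Δ + B₀cos(ω_B t); the eigenbasis
and the dissipation channels are built from the static (ε, Δ) and the
drive enters only the coherent precession field. Δ may alternatively be
computed from a point-dipole geometry (d₁·d₂/r³ − 3(d₁·r)(d₂·r)/r⁵ with
4πε₀ = 1).

Two system-bath coupling operators are supported:

* transition (dipole-like): L_T = c σ_x — promotes population transfer;
* asymmetric local: L_AL = c₁|1⟩⟨1| + c₂|2⟩⟨2| — site-resolved dephasing
  mimicking pigment-specific exciton-phonon coupling. In Pauli form
  L_AL = (c₁+c₂)/2·I + (c₁−c₂)/2·σ_z, so its dynamically active part is a
  σ_z coupling of strength (c₁−c₂)/2.

The bath is a single continuum of harmonic modes with the underdamped
Brownian spectral density

    J(ω) = γ λ² ω / [(ω² − ω₀²)² + γ²ω²],

resonance ω₀, width γ, coupling strength λ. The reorganization energy is
E_ren = πλ²/(2ω₀²) and the regime classifier uses E_ren,eff/Ω with
λ_eff = cλ (transition) or |c₁−c₂|λ/2 (local; the Pauli-vector magnitude)
and fixed cutoffs: weak < 0.1 ≤ intermediate < 1.0 ≤ strong.

## Bath correlation function and dissipation coefficients

For γ < 2ω₀ the finite-temperature correlation function
C(τ) = ∫J(ω)[coth(βω/2)cos ωτ − i sin ωτ]dω has the exact pole expansion
(residues at ±Ω₀ − iγ/2 with Ω₀ = √(ω₀² − γ²/4), plus Matsubara poles
ν_n = 2πn/β):

    C(t) = a[(coth(βw₁/2)+1)e^{−iΩ₀t} + (coth(βw₁/2)*−1)e^{+iΩ₀t}]e^{−γt/2}
           − Σ_n (2πγλ²/β) ν_n / [(ν_n²+ω₀²)² − γ²ν_n²] e^{−ν_n t},

with a = πλ²/(4Ω₀) and w₁ = Ω₀ − iγ/2. The imaginary part is
temperature-independent. The decomposition is validated against adaptive
quadrature of the defining integral (relative agreement better than 1e−4
with a handful of Matsubara terms at T ≳ Δ).

The time-dependent dissipation coefficient Γ(ω,t) = ∫₀ᵗ e^{iωτ}C(τ)dτ =
γ(ω,t)/2 + iS(ω,t) is evaluated term by term in closed form,
Σ_k c_k(1 − e^{−(ν_k−iω)t})/(ν_k − iω), rather than by cumulative
quadrature: it is exact for the represented C, costs nothing on long
grids, and gives the t→∞ (Markovian) limit directly. The long-time rates
obey detailed balance γ(Ω)/γ(−Ω) = e^{βΩ} to the accuracy of the
Matsubara truncation.

## Redfield propagator (Bloch form)

The channel-diagonal (secular) time-convolutionless generator

    dρ/dt = −i[H_S, ρ] + Σ_μ Γ_μ(ω_μ,t)(L_μ ρ L_μ† − L_μ†L_μ ρ) + h.c.

uses the three eigenoperators of the coupling operator: lowering (ω=+Ω),
raising (ω=−Ω) and traceless diagonal (ω=0), with Ω = √(ε²+Δ²). Mapping
ρ = (I + n·σ)/2 gives the exact Bloch image

    dn/dt = B×n + η·n + T,
    B = 2H_S + 4 Σ_μ Im[Γ_μ a₀_μ a_μ*],
    η = Σ_μ 4Re[Γ_μ a_μ a_μ*ᵀ] − 2γ_μ|a_μ|² I,
    T = Σ_μ 2iγ_μ (a_μ × a_μ*),

(a_μ the channel Pauli vectors) — precession, relaxation and torque. The
identity components of the channels vanish by construction, so B carries
only the coherent field; the torque T is the inhomogeneous term that
drives thermalization. The implementation is verified against a direct
2×2 density-matrix evaluation of the generator to machine precision, and
its long-time state is the eigenbasis Gibbs state,
n_z → −(ε/Ω)tanh(βΩ/2).

Integration is fixed-step RK4, default dt = (1/Ω)/200, with Γ_μ
evaluated analytically at nodes and half-nodes. A `markovian` flag
freezes Γ_μ at its long-time value.

Two known limitations of the secular channel form, both checked
numerically: (i) cross-channel (non-secular) terms are dropped, so
agreement with HEOM requires rates ≪ Ω, which near a vibronic resonance
is a stronger condition than E_ren/Ω ≪ 1; (ii) the identity component of
L_AL, which HEOM retains exactly, is discarded, so the dependence of the
steady state on the sign of c₁−c₂ is reproduced only by HEOM.

## HEOM propagator

The hierarchy couples auxiliary density operators (ADOs) indexed by a
multi-index over the expansion terms (N_R = 2 + n_matsubara real terms,
N_I = 2 imaginary terms), with commutator couplings upward and
cβR-weighted commutator / cβI-weighted anticommutator couplings downward,
damping Σ n_k ν_k, and total-tier truncation Σn_k ≤ N_c (a per-index cap
is available behind a flag). Truncated Matsubara terms are closed
Markovian-fashion with the terminator coefficient Γ_T = Σ_{tail} c_k/ν_k
folded into the Liouvillian as Γ_T(2LρL − {L²,ρ}). ADOs carry the
standard √(n_k!|c_k|^{n_k}) scaling for stability.

Because the hierarchy is linear, the whole generator is assembled once as
a sparse matrix over the flattened ADO stack (the oscillatory drive
contributes a separate sparse term multiplied by B₀cos(ω_B t)); RK4 then
costs four sparse matrix-vector products per step. The step is
stability-limited by the deepest-tier damping, dt ≈ 1.5/(N_c·max Re ν).

Validation: zero-coupling Rabi and driven closed forms; trace and
Hermiticity preservation; the exact nonperturbative pure-dephasing law
|ρ₀₁(t)| = |ρ₀₁(0)|exp[−4c²Re∫₀ᵗ(t−s)C(s)ds] for a commuting coupling;
monotone N_c convergence (N_c = 5 changes by < 1e−3 against N_c = 6 on
the study grid); and weak-coupling agreement with the Redfield propagator.

## Stochastic (Langevin-Itô) unravelling

Each trajectory is a normalized pure state driven per channel by a
continuous-measurement contraction and a feedback term,

    ζ̂_μ = (γ_μ/2)|L_μ − ℓ_μ|²,
    χ̂_μ = (γ_μ/2)(L_μ†ℓ_μ − L_μℓ_μ*),
    ℓ_μ dt = ⟨L_μ⟩dt + dξ_μ/√(2γ_μ),

with complex Wiener increments M(dξ*dξ) = 2dt, M(dξ²) = 0, plus the
coherent evolution under H_S(t) + Σ_μ S_μ L_μ†L_μ. The γ_μ/2 prefactor
(the real part of Γ_μ) and the √(2γ_μ) record scaling are fixed by
requiring that the noise average of the pure-state projectors reproduces
the master equation with channel rates γ_μ exactly; this is the package's
normalization of the measurement-unravelling structure and is verified
against the deterministic propagator (ensemble mean within Monte-Carlo
error). Scalar (identity) parts of the step generator only rescale the
ray and are projected out before the Euler-Maruyama update; the state is
renormalized each step. Default step (1/Ω)/500; the weak-order bias of
the ensemble mean scales linearly with the step and the three-propagator
cross-validation uses (1/Ω)/1500, where it is well below the
2000-trajectory standard error.

Negative transient rates: during the slippage transient of Γ_μ(ω,t) the
rates γ_μ(ω,t) dip below zero over a sizeable fraction of the window for
structured baths. A diffusive unravelling cannot represent a
negative-rate (non-CP-divisible) generator; while γ_μ ≤ 0 the channel's
noise is suspended and only its deterministic part acts, which keeps
trajectories finite but biases the ensemble mean (measured ~0.03,
step-independent). Quantitative mean-recovery statements therefore use
the Markovian (frozen-rate) generator, where the unravelling is exact;
time-dependent-rate ensembles are exploratory.

Per-trajectory seeds derive deterministically from the master seed
(SeedSequence spawn keys), single runs are bitwise reproducible, and the
ensemble is propagated in vectorized blocks that are mathematically
identical to stepping each trajectory alone.

## Corridor analytics

The environment's monitoring confines quantum paths to a corridor around
the reference trajectory. Per Bloch component η the corridor width is

    δ_η(t) = [Σ_μ S*_{ημ} γ̃_μ(t) S_{μη}]^{−1/2},

where S is the 3×3 rotation (about y by the mixing angle θ, tanθ = Δ/ε)
between site and eigenbasis Pauli components and γ̃_μ are effective
per-axis monitoring rates: each channel contributes its γ_μ(ω_μ,t)
weighted by twice its squared eigen-frame Pauli components (the
transverse decay rate of a channel with vector a is 2γ|a|²). This
axis-weighting is the package's reconstruction of the channel-to-
component bookkeeping; it preserves the exact √2 homogeneity (doubling
all rates divides every width by √2), diverges when nothing is monitored,
and narrows pointwise with coupling strength. Instantaneous rates are the
default; where the monitored sum is ≤ 0 (early slippage) the width is the
+∞ sentinel and is excluded from crossover detection.

The quantum-to-classical crossover time τ_c(η) is the earliest time at
which |∂δ_η/∂t| < ε or δ_η = 0 (central differences; default ε = 1% of
the largest finite |∂δ/∂t|, detection starting at that maximum so the
pre-onset plateau does not trigger). Comparisons across coupling
strengths use one common ε.

Displaced path families follow n(t) = n_ref(t) + κ·dt·(dn_ref/dt) with κ
counted in grid steps (κ ∈ {0, 1, 5, 10, 20}). The weighting functional

    |w[n; ξ]| = exp[−Σ_μ ∫₀ᵗ ζ_μ dt'],   ζ_μ = (γ_μ/2)|L_μ(n) − ℓ_μ|²,

evaluates the channel expectation along a Bloch path through the Pauli
decomposition L_μ(n) = L₀_μ + L⃗_μ·n; χ_μ is purely imaginary along a
path (a phase) and is recorded separately. With no record supplied the
noiseless record along the reference path is used, so κ = 0 carries
weight exactly 1 and |w| decreases pointwise with |κ| and with time.
Rates are clipped at zero in the functional, consistent with the noise
suspension. The coupling-free reference amplitude is
ψ₀(t) = ψ₀(0)exp[−(i/2)∫B₀·n dt'].

## Steady-state observables

P₁(t) = (1+n_z)/2. The steady probability P_sd is the mean of P₁ over
the final window (default last 20%), accepted only if that window is
quasi-stationary (max − min < 2·tol, default tol = 0.01); the steady time
τ_sd is the earliest time after which |P₁ − P_sd| ≤ tol permanently.
This operationalization makes τ_sd mildly horizon-dependent when the
tail is still drifting, so sweeps scale the horizon with the expected
relaxation time (∝ 1/λ² along coupling axes) and can auto-extend it.
Sweeps default to the HEOM propagator (N_c = 5) with Redfield as a fast
preview; failed cells are recorded and skipped.

## Study conditions (what the defaults emulate)

The dimensionless study uses ε = 0.5Δ, bath ω₀ = 3Δ, γ = 1Δ, λ = 1Δ,
T ∈ {1, 3}Δ, couplings g_k = c·λ ∈ [0, 2]Δ (transition) or
Δg_k = g_k(1) − g_k(2) ∈ [−2, 2]Δ (local, g_k(1) = 2Δ). ε = 0.5Δ makes
the eigenbasis thermal state reproduce steady probabilities ≈ 0.46 (T =
3Δ) and ≈ 0.39 (T = 1Δ). The moderately off-resonant, moderately broad
bath places these couplings in the weak-to-intermediate regime, where
stronger coupling accelerates the transition, heating accelerates it
further, and τ_sd ∝ λ⁻² at high temperature — the regime the package's
steady-state phenomenology describes. Near-resonant narrow baths
(ω₀ ≈ Ω, γ ≪ ω₀) reverse these trends (polaron-like slowdown at strong
coupling, captured by HEOM only) — physically interesting, but not the
default study conditions.

The weak-coupling cross-validation fixture places the mode further off
resonance (ω₀ = 5Δ, γ = 0.5Δ) with λ set by E_ren/Ω = 0.01, so that the
secular/perturbative validity condition rate/Ω ≪ 1 holds and the three
propagators agree: Redfield vs HEOM within 2% sup-norm, and the
stochastic ensemble mean within Monte-Carlo error.

The PC645 preset (donor DBVc = |1⟩, acceptor PCB82c = |2⟩) encodes the
printed values Δ = 24.3 cm⁻¹, donor/acceptor couplings g_k = c_mλ = 180
and 500 cm⁻¹ (λ = Δ), Δg_k = −13.17Δ, T ∈ {230, 300} K. The site bias
and bath shape are package choices: a 400 cm⁻¹ downhill step with a
quasi-resonant 400 cm⁻¹ mode of width 50 cm⁻¹, giving picosecond-scale,
near-total donor→acceptor transfer with strong early-time oscillation of
the dissipation coefficients (transient re-widening of the corridor).
N_c = 3 suffices there (verified against N_c = 5).

## What the synthetic conditions do and do not show

The generator emulates a two-site exciton coupled to one structured
vibrational continuum at equilibrium. Passing tests demonstrate internal
consistency of the three propagators, correct closed-form limits and the
corridor phenomenology under these conditions. They do not validate
multi-site exciton networks, multiple independent baths, anharmonic or
non-equilibrium environments, or quantitative transfer times in real
PC645 — the preset's unpinned parameters are literature-informed choices,
not fits.

## Numerical choices and degenerate inputs

RK4 steps: deterministic (1/Ω)/200; HEOM stability-limited as above;
SSE (1/Ω)/500. Quadrature: adaptive Gauss-Kronrod on [0, ω₀+40γ] with
analytic ω→0 limit and oscillatory-weighted tails. ε = Δ = 0 is rejected
(degenerate system); overdamped baths (γ ≥ 2ω₀) are rejected; |n| > 1
inputs are rejected rather than projected; Bloch-norm overshoot beyond
1+1e−6 aborts with advice to refine the step; hierarchies above 10⁶ ADOs
are refused. Fixture generation solves λ for a sampled E_ren,eff/Ω target
inside the requested regime band, so classification holds by
construction.
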