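# Models and methods

`thetaflow` studies how the *connectivity* of a spiking network — and in
particular the breaking of its symmetry — sculpts the slow, low-dimensional
flow that the network's collective state follows.  This note documents the
model equations, the reductions, the numerical procedures, and the design
choices, in the package's own conventions.

## The spiking network

Each neuron carries a spiking phase θ_i on the circle [0, 2π) and a
synaptic-drive variable ω_i (rad²·ms⁻²):

    τ_θ dθ_i/dt = (1 − cos θ_i) + (1 + cos θ_i) ρ_i,
    ρ_i = I_i + Σ_j c_ij ω_j,
    dω_i/dt = −ω_i / τ_s   between spikes,
    ω_i → ω_i + k (b − ω_i)   at each of neuron i's own spikes.

This is the theta-neuron (saddle-node-on-invariant-circle) normal form: a
spike is the upward crossing of θ = π, where the velocity equals 2/τ_θ
regardless of drive, so threshold and reset coincide on the circle and the
phase passes through smoothly.  The closed-form period at constant drive is
T = π τ_θ / √ρ; for ρ ≤ 0 the square root is taken to be zero, the period is
infinite, and the neuron rests at a fixed point of the phase equation.
Firing rate is the reciprocal period, hence ∝ √ρ.

ω_i integrates the neuron's **own** spike train — it is a running proxy for
the neuron's firing rate (equivalently, the synaptic current it exports) —
and the directed weight c_ij (row = postsynaptic) feeds presynaptic drives
into the postsynaptic phase velocity.  The spike-triggered increment is a
Dirac pulse applied as the discrete jump k (b − ω): a fixed fraction of the
remaining headroom below the saturation level b, so repeated spikes drive ω
toward b without overshoot.  The saturation matters qualitatively: without
it, rate feedback is pure positive feedback and strong coupling always
destabilizes the collective mode.

Defaults: τ_θ = 1 ms, τ_s = 20 ms, k = 0.1, b = 1.  τ_s separates the fast
spiking timescale from the slow drive timescale; k = 0.1 makes a single
spike perturb the drive by a few percent of its range, small enough for the
mean-field reduction to be meaningful yet large enough that a neuron's rate
feeds back within a few interspike intervals.

**Integrator.**  Classical fixed-step RK4 (default dt = 0.05 ms) on the
smooth part, with the spike time located inside a step by linear
interpolation of the θ = π crossing and the drive jump applied at the end of
that step.  The crossing is always transversal (velocity 2/τ_θ at
threshold), so no root polishing is needed; simulated interspike intervals
match the closed-form period to ~10⁻⁹ relative at dt = 0.01 ms.  Adaptive
solvers are avoided because of the delta-pulse jumps.  Simulations are
bit-reproducible given seed, initial state and step.

## Firing-rate reduction

Replacing each neuron's own spike train by its mean rate
f(ρ) = √(ρ)₊ / (π τ_θ) closes the drive dynamics:

    dω_i/dt = −ω_i/τ_s + k (b − ω_i) f(I_i + Σ_j c_ij ω_j).

The *simplified* variant drops the square root (f = ρ₊/(π τ_θ)); in the
operating regime it produces the same qualitative flows and makes the
3-node phase reduction tractable.  The clipping at ρ = 0 is retained in both
variants — it is the nonlinearity that lets inhibition silence a node.

**Homogeneous mode.**  With identical coupling c everywhere and identical
input, all nodes share one nullcline equation; the largest nonnegative
solution on [0, b] (bracketed root-finding) is the mode amplitude ω*.  The
Jacobian there is μI + k(b−ω*)f′(ρ*) c J with J the all-ones matrix, so the
spectrum has n−1 degenerate transverse eigenvalues μ = −1/τ_s − k f(ρ*) and
one unique eigenvalue μ + n c k (b−ω*) f′(ρ*) along the uniform direction.
Strong coupling of either sign pushes the system against one of its rails
(saturation b for excitation, quiescence for inhibition), which both
stabilizes the unique eigenvalue relative to weak coupling and shrinks the
steady-state dispersion under dispersed inputs.  In a small neighborhood of
zero coupling the unique eigenvalue is not strictly monotone in |c| (rate
gain and saturation compete); the tests assert the robust strong-vs-weak
ordering.

**Flow classification.**  `classify_flow` runs a fixed protocol:
1. global fixed-point search (grid of Newton seeds, dedup 10⁻⁶, stability
   from the finite-difference Jacobian);
2. no stable fixed point + sustained late-time oscillation (peak-to-peak
   above 10⁻³ after a 10 τ_s transient, with a repeating autocorrelation
   period) → limit cycle;
3. two / more stable fixed points → bistable / multistable;
4. one stable fixed point → graded kicks (0.25 b, 0.5 b — the attractor
   scale is the saturation level b, since ω lives in [0, b]) in eight
   directions.  If a kick is answered by a transient that takes ≥ 3 τ_s to
   re-enter a 0.1 b ball around the fixed point, a separatrix is nearby and
   the flow is monostable (excitable); otherwise a plain fixed point.

The return-*time* criterion was chosen over excursion size because
winner-take-all ghost transients are long-lived but short in path length;
in this model family plain relaxation always returns within ~2 τ_s, so the
3 τ_s threshold separates cleanly.  A spiking-side twin
(`classify_spiking_flow`, and `classify_gated` for mode subsets of the
composed network) applies the same decisions to 25 ms-smoothed drive
trajectories of full spiking simulations, with the extra rule that a kicked
run settling at a *different* stationary state reveals a second attractor
(bistability).

**Canonical two-node flows.**  The four flow classes are realized by frozen
canonical matrices (in the (s, c, a, d) decomposition s·cross + c·self +
a·anti-cross + d·anti-self):

| flow        | matrix                        | inputs       | mechanism |
|-------------|-------------------------------|--------------|-----------|
| fixed point | [[0.2, 0.3], [0.3, 0.2]]      | (0.15, 0.15) | weak symmetric excitation |
| limit cycle | [[3, −2], [2, 0]]             | (0.10, 0.00) | activator–inhibitor rotation |
| bistable    | [[0, −2.5], [−2.5, 0]]        | (0.25, 0.25) | winner-take-all inhibition |
| monostable  | [[2.6, −1.8], [3.6, −0.4]]    | (0.29, 0.11) | activator–inhibitor just below cycle onset |

Each was located once by a parameter exploration of the rate system and
validated in both descriptions; they are package canonical examples.

## Three-node reduction and bifurcation

The canonical 3-node family is C(α) = s (J − I) + α A_cyc with mutual
inhibition s = −2.5, per-node input 0.35, and the circulant antisymmetric
pattern A_cyc favouring 1 → 2 → 3 → 1.  The right singular vectors of the
antisymmetric component provide the projection: the null axis (1,1,1)/√3 is
the normal, the orthogonal plane carries the slow flow.  In polar
coordinates on that plane, the radius and normal are replaced by the values
(r̄, n̄) at which their phase averages vanish (512-point trapezoid average;
2-D Newton from a coarse scan, with the trivial r = 0 solution excluded),
leaving the scalar 2π-periodic phase flow dφ/dt.

At α = 0 the flow has three stable zeros 2π/3 apart — the winner-take-all
states, whose angles match the full system's stable fixed points to better
than 0.05 rad.  Zeros annihilate pairwise as α grows; bisection on the
zero count locates α_c ≈ 0.317 for the canonical parameters, and at α = 1
the flow is a pure rotation (heteroclinic-cycle-turned-limit-cycle).  An
additional pairwise asymmetry γ on the (1,2) pair (α = 0.2, γ = 1.5) leaves
exactly one stable zero with one nearby unstable zero — the monostable flow
with its separatrix.  The full (square-root) rate system and the spiking
network bifurcate later than the simplified system (cycle at α ≈ 1.5,
canonical cycle example α = 1.8; monostable at α = 1.3, γ = 0.5); the same
three regimes are reproduced there and verified by the flow classifiers.

The two-dimensional excitable reference system (position x, recovery y,
cubic restoring nullcline; `manifold.ExcitatorParams`) provides the
flow-class templates: canonical parameter sets give its bistable,
limit-cycle, and monostable regimes.

## Spike-timing reduction

On timescales short against τ_s each neuron is a bare oscillator with
frozen effective drive η (period π/√η).  The package's phase convention
places the SNIC bottleneck **adjacent to the threshold/reset point** — the
π-rotated form of the phase equation, velocity (1 + cos θ) + (1 − cos θ) η,
slow (2η) at θ = ±π and fast (2) at mid-cycle — so the oscillator dwells
just before firing.  A presynaptic spike is idealized as one instantaneous
phase increment κ (in the full model the extra drive persists for ~τ_s,
i.e. many cycles; the accumulated rotation compresses into a single kick).
A pulse reaching across threshold discharges the neuron immediately
(absorption, with the overshoot carried into the next cycle); a strong
inhibitory pulse can carry the phase backwards past the reset point, which
delays the neuron by up to a full cycle.

In the linear phase φ (fraction of period × 2π) the closed-form phase
response curve is g(φ; κ, η) = Φ(θ(φ) + κ) − φ (± 2π across the wrap), with
Φ the phase-to-linear-phase map.  Because the velocity rises from the
bottleneck toward mid-cycle and falls again, g is concentrated near the
cycle ends and *late-skewed*: late-cycle excitation advances the laggard
more than early-cycle excitation advances the leader.  Consequences, all
verified by event-driven simulation:

- homogeneous **excitatory** coupling synchronizes a population completely
  (absorbed volleys; order parameter → 1 from random phases),
- zero coupling leaves the initial dispersion,
- **inhibitory** coupling disperses the phases (order parameter < 0.2 at
  the canonical strength −0.5).  Near-synchronous states under inhibition
  are only marginally attracting with a vanishing basin, so random initial
  conditions never reach them.

The independent check of the closed form integrates the theta equation
through a narrow rectangular velocity pulse (RK4, exact flow elsewhere) and
reads the spike-time shift ten cycles later; agreement is ~4·10⁻⁴ rad.

**Synchrony eigenvalue.**  The linearization of the volley return map about
synchrony: a straggler at spread ε behind the synchronized cluster evolves
per period with multiplier λ = (1 + G′(2π − ε))(1 + g′(ε)), where G is the
PRC under the cluster's compound pulse and g under a single pairwise pulse;
when the compound pulse absorbs the straggler the map is superstable
(λ = 0).  The perturbation matrix I + (λ−1)(I − J/n) has one neutral
eigenvalue (uniform time shift) and the unique eigenvalue λ with
multiplicity n−1; the closed form is checked against its dense eigensolve,
and — in the weak-coupling smooth regime only, where no absorption or wrap
occurs — against a finite-difference Jacobian of the exact event-driven
volley map (loose tolerance: the rigid-cluster approximation neglects
cluster-internal rearrangement).

**Two-neuron locking.**  The analysis object is the exact two-dimensional
section return map: the pair of phases immediately after a spike of neuron
A, tracking every intervening event (multiple or missing B spikes,
cascaded absorptions).  Stable locked states are convergence points of the
iterated map; unstable ones come from Newton root-finding on the map
displacement; each carries the spectral radius λ of the 2×2 map Jacobian,
stable iff |λ| < 1.  Identical neurons with balancing coupling leave a
neutral continuum of offsets, reported as a single degenerate state.  The
three canonical regimes (frozen in `presets.TIMING_PRESETS`): synchronous
lock (2% detuning, mutual excitation 0.3), slow relative-phase drift (22%
detuning, weak mixed coupling), and a monostable lock — one stable offset
with a nearby unstable offset, where a small kick relocks directly and a
large kick triggers one slow rotation of the relative phase, passing
through synchrony, before relocking.

## The composed circuit

Four modes share one 25-neuron network (split 7/6/6/6; skeleton weights
divided by the presynaptic block size so block-constant states evolve
exactly like the 4-mode skeleton).  The canonical skeleton fixes modes
(1,2) as the winner-take-all pair, modes (1,3,4) as the heteroclinic triple
at cycle asymmetry, and closes modes (1,2,3) into the excitable circuit
through the two remaining free entries; entries of the never-co-active
(2,4) pair are mildly inhibitory.  Active modes receive drive 0.35,
inactive modes −0.8; each sub-circuit's flow label (bistable / monostable /
limit cycle) is verified on the spiking network's active-mode mean fields.

The canonical scripted run settles 400 ms on the limit-cycle flow, records
from 0–1600 ms, switches to the bistable pair at 500 ms (mode 2 released
30 ms late so the entry winner is deterministic), flips the winner with
0.8 × 30 ms pulses at 700 and 1000 ms, switches to the monostable circuit
at 1100 ms, and triggers its large transient with a pulse at 1350 ms.

**Transition statistic.**  Sliding-window PCA of the drive traces (1 ms
sampling, 160 ms windows, 100 ms overlap, ten leading eigenvectors, signs
fixed by the largest-loading convention, optional 10 ms pre-smoothing) and
the consecutive-pair dissimilarity Σ(E_aᵀE_b − I)².  The statistic is
exactly the printed formula and therefore compares *ordered, signed bases*:
with only ~4 well-conditioned covariance directions in a 4-mode network,
the remaining six prescribed components are sampling noise of the per-spike
sawtooth, giving the series a high floor everywhere; pulse-driven winner
flips also reorganize the active subspace as strongly as the scheduled flow
switches.  In this implementation the series' largest peaks therefore do
*not* reliably single out the two flow switches — the 1100 ms switch
usually ranks near the top while the 500 ms switch is masked by the
limit-cycle segment's intrinsic rotation — and the corresponding acceptance
test documents this as a failing assertion rather than a weakened one.

## What the canonical conditions do and do not show

All experiments are synthetic and desk-scale: networks of 1–50 units,
noise-free dynamics with seeded random initial conditions, piecewise-
constant inputs.  Passing tests show internal consistency of the model,
its reductions and its analyses — not robustness to biophysical
heterogeneity, conduction delays, or stochastic input, none of which are
modeled.  Known limitations: the rate reduction degrades at low firing
rates (few spikes per τ_s); the phase-pulse idealization compresses a
τ_s-long drive transient into one kick and so overstates the suddenness of
interactions; the locking analysis assumes a 1:1 firing pattern between
section returns; and the subspace statistic inherits the conditioning
problems described above.
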