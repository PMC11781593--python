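# Methods

## The model and what the package computes

`resetdyn` studies how stochastic resetting accelerates rare barrier
crossings in Langevin dynamics, and how kinetic observables of the
*unbiased* process can be recovered from the accelerated runs.

A single particle (mass 40 g/mol, representing argon) moves on an analytic
2D landscape under underdamped Langevin dynamics at 300 K with friction
0.01 fs^-1 and a 1 fs time step. The work landscape is a modified
Faradjian–Elber surface,

    U(x, y) = A1 (x^8 + y'^8)
            + A2 exp(-x^2 / (2 s1^2)) (1 - B exp(-y^2 / (2 s2^2))),
    y' = 0.1 y,

with A1 = 1.2e-5, A2 = 12, B = 0.75, s1 = 1 Å, s2 = 0.5 Å, energies in
k_BT. Two symmetric wells near x = ±3 Å are separated by a 12 k_BT
Gaussian ridge pierced at y ≈ 0 by a saddle channel of only 3 k_BT. The
soft y'^8 confinement reaches 1 k_BT near |y| ≈ 41 Å, so a walker spends
most of its first-passage time diffusing along y in search of the narrow
channel; this search phase makes the first-passage time (FPT) distribution
broad (coefficient of variation above 1), which is precisely the regime in
which resetting helps. All trajectories start at (3, 0) with thermal
velocities and stop at x < -1 Å.

The closed form above is this package's reconstruction: the published
description of the potential pins the x-profile tightly (minima at ±3 Å,
the 3/12 k_BT barriers), but the y-geometry less so. Of the transcription-consistent readings, the one adopted here
(confinement stretched by the 0.1 rescale, channel at its bare s2 width)
is the only one that reproduces the reported first-passage phenomenology —
a multi-nanosecond unbiased MFPT and order 10-50 resetting speedups.
The remaining quantitative offsets of the dynamic observables (the
unbiased MFPT comes out near 13 ns rather than 7.6 ns, and speedups run
some tens of percent below the published ones) are consistent with a
slightly different channel/confinement aspect ratio in the original
surface, and are documented next to each affected check rather than
absorbed into parameter tweaks.

## Integrator

BAOAB splitting of underdamped Langevin dynamics: half kick, half drift,
exact Ornstein–Uhlenbeck velocity refresh with multiplier exp(-γΔt), half
drift, half kick. At γ = 0 it reduces to velocity Verlet (tested via
energy conservation and bit-exact agreement between the compiled kernel
and the pure-Python single-step path). Equipartition and positional
Boltzmann marginals are verified against quadrature of exp(-U).

Units are Å, fs, g/mol; potentials are dimensionless multiples of k_BT, so
the gas constant enters once, as the velocity scale sqrt(RT/m).

Each walker owns an RNG stream seeded via `numpy.random.SeedSequence`
spawned from the ensemble seed, so ensembles are bit-reproducible and
independent of batching. First passage is checked every step by default
(configurable stride). Walkers exceeding `max_steps` (default 4e8 steps =
400 ns, roughly 30 times the unbiased MFPT scale) are flagged censored,
reported, and excluded from means with a warning — never silently dropped.

## Resetting protocols

Resetting epochs are drawn from an exponential distribution with rate r.
At each epoch the protocol's condition is evaluated on the instantaneous
state: standard stochastic resetting (SR) has the always-true condition;
informed stochastic resetting (ISR) fires only when the collective
variable exceeds a threshold c (for a target at smaller CV). On a reset
the position returns exactly to the start point, momenta are resampled
thermally, any MetaD bias is zeroed, and the clock keeps running — the FPT
includes everything before the last segment. Epochs falling inside one
time step are handled by checking the condition once at the step boundary,
equivalent (by memorylessness) to per-step Bernoulli trials with
p = 1 - exp(-rΔt). A `portal` mode replaces the clock with a deterministic
every-step check, the r → ∞ limit in which the threshold teleports every
walker that touches it.

The CV is x rotated by θ about the start point (θ = 0 gives raw x; the
anchoring means thresholds quoted in x carry over unchanged to rotated
CVs, matching a threshold line rotated about the initial position). The
first-passage criterion never rotates — only the CV the protocol and the
bias see.

## Well-tempered Metadynamics

A 1D bias on the same CV, accumulated on a uniform grid (default
[-8, 8] Å, 0.01 Å spacing, clamped outside), Gaussians of width 0.15 Å and
initial height 0.5 k_BT deposited every 100 steps, damped by
exp(-V(s)/(γ_b - 1)) with bias factor γ_b = 10. Hills are truncated at six
widths (relative error below 2e-8 of the hill height). The bias is
linearly interpolated; its derivative uses central differences at the grid
nodes, interpolated between nodes, so the force is continuous and vanishes
at an isolated hill centre. Convergence of V(s) toward -(1 - 1/γ_b) F(s)
is tested on a harmonic well. On every
resetting event the bias table and the deposition clock are zeroed, making
each post-reset segment a statistically fresh replica — the property the
predictor machinery needs.

## Predicting resetting outcomes from reset-free trajectories

The MFPT under resetting decomposes per trajectory into M - 1 segments
ending in a reset plus a final segment ending in passage:

    <τ>_r = (<M> - 1) <t̄^r> + <t^f>.

From N reset-free trajectories (CV series stored every S steps, exact step
counts n_i), the hypothetical per-step reset probability
p_j = (1 - e^{-rΔt}) I_j (indicator I_j: condition holds at step j) gives
each trajectory a survival Ψ_i(k) = Π_{j≤k} (1 - p_j). The ensemble
survival to passage yields <M> = 1/<Ψ>; survival-weighted means of τ_i and
of the reset-step distribution Ψ_i(j) p_j give <t^f> and <t̄^r>. An entire
(rate, threshold) grid costs a few vector passes — no new simulations.

Conventions fixed here (and shared by the simulator): a walker that passes
at step n is never reset at step n, so reset trials run over steps
1..n_i - 1; the condition is the strict inequality cv > c; strided storage
aggregates the hazard as p = 1 - e^{-rSΔt} with the indicator treated as
constant across the stride (the default stride keeps rSΔt ≤ 0.1 at the
largest screened rate; a consistency test bounds the stride error).
Trajectories whose survival underflows to zero contribute nothing; if all
do, the sample cannot constrain the protocol and the prediction errors
out. When screening a grid, a cell is additionally reported only while
enough effective trajectories back it — the effective sample size
(sum Ψ_i)² / sum Ψ_i² of the survival weights must reach 5 — because at
aggressive (r, c) the averages collapse onto one or two surviving
trajectories and the resulting numbers are noise; such cells are marked
invalid rather than reported. Averages use trajectory-level weights
exactly as written above, with no small-sample bias correction.
Correctness is gated two ways: exact agreement with an exhaustive
enumeration oracle over the reset-outcome tree on hand-sized series, and
statistical agreement with direct resetting simulations on the fast
fixture surface. Standard errors come from a trajectory-level bootstrap of
the cached survival terms.

## Inference of unbiased kinetics

*MFPT extrapolation.* For an ensemble run with ISR at rate r*, the
superposition of independent exponential clocks means dynamics at any
r > r* equals the recorded dynamics plus an extra clock at r - r*. The
recorded trajectories (their actual resets included) therefore act as the
reset-free sample for the predictor at rate r - r*, giving <τ>_r at probe
rates without new simulations. log <τ>_r is then fitted by a quadratic in
r over probes in [r*, 3 r*] (weighted by bootstrap variances) and
evaluated at r = 0. The functional form is this package's choice, gated by
a closed-form oracle: probe curves synthesised from drift–diffusion with
resetting (inverse-Gaussian FPT) extrapolate back to the known x0/v within
5%. The full loop (simulate at r*, probe, extrapolate) is additionally
checked against the directly simulated unbiased MFPT on the fixture
surface. Accuracy degrades as r* (and the speedup) grows — the expected
speedup/accuracy trade-off.

*Direct transit times.* The committed part of a crossing: from the last
stored sample beyond an entry surface to the first sample past an exit
surface (no sub-step interpolation). Re-crossings of the entry surface
discard earlier excursions; a completed transit re-arms only after the
series returns past the entry surface. On the toy surface the default
surfaces are x = +1 and x = -1 around the barrier. Mean DTTs are pooled
over trajectories. Because transits are short and only weakly coupled to
the bias that accelerated the trajectory, the mean DTT is insensitive to
the MetaD deposition pace across paces where the FPT speedup varies more
than tenfold — verified on the fixture.

## Synthetic fixtures

`generate_fixture` builds a scaled surface for tests: ridge 3 k_BT, saddle
1 k_BT, channel width 1.5 Å, confinement ±8 Å, giving an unbiased MFPT
near 0.05 ns so whole property suites run in seconds. It preserves what
the tests rely on — a broad FPT distribution, plateauing speedups for
thresholds at or beyond the start, unimodal speedups for standard SR — but
not the absolute scales: a passing fixture test validates protocol logic
and estimators, not the published numbers (those are recomputed at full
scale by the acceptance checks). The generator verifies the MFPT band and
rescales barriers if missed. A quartic double well (barrier 3 k_BT,
harmonic in y) provides the complementary regime: near-exponential FPTs
(CV ≈ 1) where standard SR cannot accelerate but ISR with the threshold at
the start still does.

## Ensemble sizes and runtimes

The original studies used 10^3-10^4 trajectories per condition. The
acceptance script reduces this to 200 unbiased trajectories, and sizes
each accelerated ensemble under a fixed compute budget of 3e8 steps using
the predictor's own MFPT estimate for that protocol (between 120 and 300
walkers; 150 for MetaD runs, which are far shorter). The test suite uses
120/250/150. Means are unbiased by the reduction and tolerances are
stated as three combined standard errors; because every speedup shares
the one baseline, its ~7% standard error moves all speedups coherently
between runs. The unbiased baseline dominates the cost (about
3e9 Langevin steps); accelerated ensembles are 10-100x cheaper. CV series
for the predictor are stored every 20 steps (every 5 for MetaD runs),
keeping the stride hazard small at all screened rates.

## Known limitations

- The y-geometry of the work surface is a reconstruction (see above);
  absolute dynamic numbers carry a systematic offset relative to the
  published ones even though every landscape fact and all qualitative
  resetting phenomenology are reproduced.
- Only exponential resetting-time distributions and threshold conditions
  on a linear CV are implemented; the survival machinery accepts any
  per-step probability in principle, but no other condition is wired in.
- MetaD is 1D on the rotated-x CV; multi-dimensional CVs, adaptive hills
  and OPES-style variants are out of scope.
- No constraints, periodic boundaries, or many-particle systems.
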