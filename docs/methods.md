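# Methods

This note documents the models, numerical choices and limitations of
`hopfbrain`, in the spirit of the methods documentation of simulation
packages: what is computed, under which assumptions, and what the
synthetic benchmarks do and do not establish.

## Whole-brain model

Regional dynamics are the normal form of a supercritical Hopf bifurcation
(Stuart–Landau oscillator). The model's key assumption is that macroscopic
neural-mass dynamics captured by fMRI range between two regimes — a stable
fixed point governed by noise and a limit cycle of self-sustained
oscillation at the region's intrinsic low frequency — with the interesting
physiology occurring near the bifurcation, where additive noise induces
switching between regimes. The real part `x_j` serves directly as the BOLD
proxy; no hemodynamic (balloon/Windkessel) convolution is applied, since
the intrinsic frequencies are already estimated in BOLD band (0.04–0.07
Hz) from the band-passed signals themselves.

Coupling is diffusive, `G Σ_i C_ij (x_i − x_j)`, through a symmetric
non-negative structural connectome with zero diagonal. Loaders symmetrize
(tractography is seed-direction dependent; the equations use one coupling
per edge) and rescale so `max(C) = 0.2`, keeping the network in the
weak-coupling regime where `a > 0` still yields oscillation. No
streamline-count threshold is applied by the loader; whether thresholding
should precede or follow cross-subject averaging of tractography is left
to the data provider.

### Parameters

| parameter | meaning | default | origin |
|---|---|---|---|
| `a_j` | bifurcation parameter (dimensionless) | fitted | per-region, `a = M g` |
| `ω_j` | intrinsic angular frequency (rad/s) | estimated | Welch peak of band-passed signals, averaged over subjects |
| `G` | global coupling | 0.5 | fixed; optimal `G` and `a` trade off monotonically, so fixing `G` preserves between-state differences in `a` |
| `β` | noise amplitude | 0.04 | fixed |
| `dt` | Euler–Maruyama step (s) | 0.1 | fixed |
| ceiling | max structural weight | 0.2 | weak-coupling condition |
| band | analysis band (Hz) | 0.04–0.07 | most reliable resting-state band |

### Integration

Euler–Maruyama with increment
`x ← x + f(x) dt + β √dt 𝒩(0,1)`, independent Gaussian draws per node and
per equation (the governing equations reuse the noise symbol between the
two equations without specifying sharing; independent draws are the
conservative reading and are documented here as a deliberate choice).
The first 100 s are discarded as transient; the initial state is
`x, y ~ 𝒩(0, 0.1²)` per node from the run's seed; samples are recorded
every `TR/dt` steps (default TR = 2 s). Trajectories are checked for
non-finite values and abort with the failing step.

A numba kernel executes the inner loop. Batched integration shares one
noise realization per simulated subject across all parameter candidates in
a batch (common random numbers), so optimizers see a deterministic
objective surface; a standalone evaluation with the same seed reproduces
the batched value exactly.

## Observation pipeline

Simulated and empirical signals pass through the identical pipeline:
zero-phase 2nd-order Butterworth band-pass (forward–backward, avoiding
phase distortion of correlations), z-scoring (population sd), Pearson
correlation between all region pairs, and fixed-effect group averaging via
Fisher's R-to-z (correlations clipped to ±(1−10⁻⁶) before `atanh`;
diagonal excluded and reset to 1). Intrinsic frequencies are the Welch
periodogram peak (segment length `min(T, 128)`) of the band-passed signal,
constrained to the analysis band and averaged across subjects.

Goodness of fit between FC matrices is the mean structural similarity
index with the standard reference configuration: Gaussian-weighted 11×11
window (σ = 1.5), K₁ = 0.01, K₂ = 0.03, data range 2 (FC entries span
[−1, 1]). SSIM is windowed, so it is sensitive to the arrangement of the
matrix, not only its value distribution; matrices smaller than the window
(N < 11) are rejected.

## Fitting

Regional bifurcation parameters are constrained by binary RSN membership,
`a = M g`; overlapping memberships sum and regions in no network receive
`a = 0` (with a warning). The optimizer is a real-coded genetic algorithm
minimizing `1 − GoF`: tournament selection (size 2), uniform crossover
(per-gene rate 0.5), Gaussian mutation (σ = 0.02, per-gene rate 0.2),
single-individual elitism, gene bounds `g_k ∈ [−0.3, 0.3]` bracketing the
near-bifurcation regime. The full-scale protocol is population 10, 200
generations, 100 independent runs, keeping the solution with the highest
SSIM across runs; all three sizes scale down for desk-scale work. Each
run draws one simulation seed used for every candidate and generation
(common random numbers); the simulated cohort mirrors the empirical one
(same subjects, samples and TR). Blow-ups during fitting score a penalty
objective (default 2, the maximum of `1 − GoF`) so the GA can continue.

## Perturbation protocol

Forcing `F₀ cos(ω_j t)` is added to the real-part equation of both
members of one homotopic pair, each node at its own intrinsic frequency
(optionally to both components via `force_both_components`). The sweep
covers all homotopic pairs × amplitudes 0 to 2 in steps of 0.1, averaging
`n_reps` (default 100) independent simulated-FC realizations per grid
point by Fisher-z averaging — the same operation as the empirical group
FC — before a single GoF against the target's empirical FC. The unforced
baseline is computed once per sweep with the same rep count and reused
everywhere, which makes the amplitude-0 column exactly 1 and removes
Monte-Carlo asymmetry from the ΔGoF normalization. Negative ΔGoF
(forced model fitting the target better than the target's own fit) is
reported unclipped. State pairs whose initial model already fits the
target as well as the target's own fit (degenerate denominator,
tolerance 10⁻⁶) raise an error instructing their exclusion.

The perturbational distance is the global grid minimum (over pairs *and*
amplitudes); per-pair minima feed the regional rankings. Transition
graphs use an inclusive threshold (edge iff ΔGoF ≤ 0.3); instability is
the out-degree. Regional rankings use average ranks (rank 1 = best ΔGoF,
ties averaged) across the transitions of a group; the "top" selection
keeps `⌊fraction × P⌋` pairs, ties broken by pair index.

## Distance metrics

* **Connectivity correlation distance**: per region, the FC-change
  profile relative to the state's own wakefulness baseline (row of
  `FC_state − FC_wake`, diagonal excluded) is correlated between two
  states. The indicator requires both `|R| > 0.5` *and* p < 0.05 after
  Bonferroni correction over the N regions (the absolute value admits
  strong anti-correlation; the signed R is returned so either convention
  can be audited). Distance = fraction of regions failing the test.
* **Classification distance**: `1 − ⟨AUC⟩` of a random forest (1000
  trees, √features per split, Gini, unbounded depth) on vectorized
  upper-triangle FC features. Self-distance uses stratified 5-fold CV;
  transfer distance trains one forest per repeat (default 10 seeds) on the
  full training cohort and evaluates on the second cohort, since the
  source of the reported transfer variability is otherwise unspecified.
  Significance via label permutation (default 1000 shuffles), add-one
  p-value. With small cohorts and large effects the permutation null is
  broad and can be bimodal — shuffled labels occasionally align with the
  true ones — which is expected behavior, not a defect.
* **Model parameter distance**: Euclidean distance between fitted
  regional `a` vectors.
* Distance matrices are z-scored over their informative entries (unique
  pairs when symmetric, all off-diagonal entries otherwise); similarity
  graphs keep the smallest `fraction` of pairwise distances.

In the full-study runner, wakefulness states are excluded from the two
purely data-driven matrices by default: a wake state differenced against
its own baseline yields an exactly-zero profile, making Eq-style
correlations and classifier labels degenerate. The model-parameter and
perturbational matrices include wakefulness.

## Synthetic data

The generator stands in for clinical recordings that are not publicly
deposited, using the forward model itself so every pipeline stage has a
known ground truth. The connectome is modular with mirrored hemispheres
(homotopic pairs strongly connected; the matrix is exactly invariant under
the hemisphere swap), the network partition is hemisphere-symmetric with
optional overlap, and intrinsic frequencies are drawn uniformly in the
analysis band, shared within each homotopic pair. The default desk scale —
20 regions, 3 networks, 20 subjects/state, 200 samples at TR 2 s, and a
graded state family whose contributions `g` move from mildly positive
(wake) towards negative values (deep states) — was chosen so the full
pipeline including a scaled GA runs in minutes while preserving the
ordinal structure the distance metrics should detect.

What the synthetic benchmarks establish: the integrator reproduces the
analytic Hopf limits; the fitting machinery recovers generating
parameters; the perturbational protocol closes on states constructed by
forcing and dissociates them from orthogonal states. What they do not
establish: behavior under real-data nuisances (motion, scanner
differences, hemodynamic variability, lesioned anatomy) — none of which
the generator emulates — or the clinical conclusions themselves.

A note on a switching signature: near the bifurcation (`a ≈ 0`),
across-subject variability of the *mean FC strength* is several-fold
larger than deep in the fixed-point regime, because subjects catch
different mixes of synchronized/desynchronized epochs. Entrywise FC
dispersion is *not* a reliable signature at this scale — deep states'
FC estimates are dominated by finite-sample noise, which inflates
entrywise dispersion. The test suite asserts the former.

## Numerical choices and degenerate inputs

* Determinism: every stochastic entry point takes a seed; batched and
  standalone evaluations share the same draw order. Study stages derive
  seeds from the master seed by fixed offsets.
* Tie-breaking is by index order everywhere a sort can tie (extreme-edge
  lists, top-fraction graphs, rank selections).
* Zero-variance signals (constant columns) are rejected with the region
  named; zero-variance FC-change profiles set that region's indicator to
  0 with a warning rather than failing an entire distance.
* `tr` must be an integer multiple of `dt`; amplitude grids must start at
  0 and increase strictly.
* Halving `dt` changes noiseless trajectories at first order, as expected
  of Euler integration; the default `dt = 0.1 s` is two orders below the
  oscillation period (~20 s), where the discretization error is
  negligible relative to the driving noise.

## Problem sizes used in the shipped benchmarks

The acceptance script and end-to-end tests run the desk scale: the
20-region fixture with the scaled GA (population 10, 50 generations, 5
runs), perturbation sweeps at 10 reps, and transfer classifiers with the
full 1000-tree forests; structural constants are computed on the standard
90-region configuration. These sizes are the package's reference
benchmark configuration; all of them are plain config fields and scale up
to the full protocol (200 generations, 100 runs, 100 reps, 1000
shuffles) unchanged.

## Known limitations

* The Hopf normal form has a single oscillatory mode per region; richer
  local dynamics (multi-band, mean-field with receptor maps) are out of
  scope.
* Only homotopic-pair stimulation is implemented — the protocol mirrors
  experimentally plausible bilateral stimulation — not arbitrary node
  sets.
* Group FC is a static (time-averaged) observable; dynamic FC fitting is
  not implemented.
* The GA optimizes a Monte-Carlo objective frozen by common random
  numbers; with few runs the selected optimum can inherit a small bias
  from the shared noise realization. Increasing runs (the full protocol
  uses 100) averages this out.
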