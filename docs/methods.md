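# Methods

This note records the model, the numerical choices, and the reasoning behind
the defaults, in the order the pipeline runs.

## Periodic-gene detection

Each gene's series is fit to `x(t) = a e^(-bt) cos(omega t - phi) + x0` with
scipy's trust-region-reflective least squares. The surface is multimodal in
(omega, phi), so the fit is seeded from the dominant nonzero component of
the series' discrete Fourier transform (omega from the bin frequency, phi
from the bin's complex phase corrected for the start time), x0 from the
series mean, a from half the range, and b from 0. Bounds: a >= 0, b >= 0,
0 < omega < pi / min(Delta t) (the Nyquist limit for the coarsest sampling
step), phi free and wrapped into [0, 2pi) afterwards. A fitted negative
amplitude would be folded into the phase (cos(theta + pi) = -cos theta);
with the a >= 0 bound this arises only for externally constructed fits.

One-sigma parameter uncertainties come from the covariance of the fit. The
quality score is the maximum relative uncertainty r_max (phi is normalized
by 2pi rather than its own value, since a phase near zero is not a small
quantity). Conventions: a zero-valued denominator makes its ratio infinite;
non-convergence or a non-finite covariance yields r_max = +inf, so such
genes can never pass a finite threshold — degenerate fits are data, not
exceptions. For short series covering barely one period the decay rate is
unidentifiable (b ~ 0 with huge db/b while everything else is well
determined); the `drop_decay_term` switch removes that ratio from r_max and
simultaneously lets b go negative during optimization (|b| is taken after),
since pinning b at zero would bias the other parameters.

Selection is two-pass: free-frequency fits, keep genes with
r_max < threshold (default 0.3; per-dataset tuning expected), then refit the
kept genes with omega fixed at their mean frequency to obtain a coherent
phase set. The first `transient_skip` time points (default 2) are excluded
from all fits: synchronization protocols chemically perturb early samples.

## Attractor extraction

The fitted curve is discretized as sign(x(t) - x0), which for a canonical
fit equals sign(cos(omega t - phi)); sign(0) maps to +1 (arbitrary but
fixed; exact zeros have measure zero for generic phases). One period is
sampled at p = 8 uniformly spaced times starting at `t_start` (default: the
first post-transient time point; the data do not single out a phase origin,
so it is configuration). Because the envelope a e^(-bt) is positive, states
half a period apart are exact negations; for even p the second half of the
pattern set is therefore built by explicit negation of the first, making
xi^(mu+p/2) = -xi^mu machine-exact independent of the sign(0) convention.
Colliding patterns within the first p/2 (degenerate phase sets) raise an
error naming the indices. p = 8 is the default: larger p crowds the
patterns and the stored cycle loses stability to the network's finite
capacity.

## Couplings

The pseudo-inverse (projection) rule is used because phase-shifted sign
patterns are strongly correlated; the Hebbian outer-product rule would not
store them. For antisymmetric sets the overlap matrix Q is rank-deficient
on all p patterns, so Q and both couplings are built from the first p/2
patterns only; the negated half is stored automatically by the global
spin-flip symmetry of the model. The cyclic variant maps each pattern to
its successor (mod p, crossing the antipode at mu = p/2 - 1). Both
constructions are linear-algebra identities and are tested to 1e-10.

The working coupling is the convex blend (1-lambda) J' + lambda J~,
sparsified afterwards by zeroing entries strictly below the median of |J|
over all N^2 entries, diagonal included (the rule is stated for "all
elements", and the median is insensitive to this choice at realistic N).
Exactly floor(N^2/2) entries are zeroed for generic continuous-valued
matrices. Sparsification is applied to the blended matrix, i.e. to the
coupling in its final form. No stricter threshold is offered: pruning more
than half the edges destroys the stored cycle (diluted-network capacity
loss), which the test suite demonstrates is *not* the case at the median.

## Dynamics

Stochastic Glauber-style updates at effective temperature T (a noise scale,
not a physical temperature): P(sigma = +1) = logistic(2h/T), computed with
`expit` for stability. The T = 0 limit is the sign rule with probability
1/2 at h = 0 (the symmetric limit; the rule itself is undefined there).
Updates are asynchronous: each node is selected independently with
probability `update_prob` per step (Bernoulli per node, not a fixed-size
subset), and all selected nodes update in parallel from the pre-step state.
Parallel-within-step semantics are a deliberate choice — they are exactly
reproducible, vectorize over cells, and match the t -> t+1 form of the
update rule; sequential within-step re-evaluation is a different, equally
defensible convention.

Full inhibition (the h_ext -> -infinity limit) is realized as a clamp:
the gene's spin is forced to -1 every step and its field is irrelevant.
This avoids non-finite arithmetic and is dynamically identical. Finite
external biases are also supported.

The population simulator runs kappa independent cells as one (kappa, N)
spin array; per-cell trajectories are statistically identical to the
single-cell `step` function. Fields are computed in single precision —
entries are sums of N terms of size ~1/N, roughly unit magnitude, far from
float32 resolution; state assignments (argmax of overlaps, ties to the
lowest index) are insensitive to this at the 1e-7 level. Memory: the
assigned-state history (kappa × steps, int16) is always kept; the full spin
history is opt-in, costing O(kappa N steps) bytes.

## Working point (defaults T = 0.035, lambda = 0.3, update_prob = 0.2)

These reproduce, on the default synthetic fixture (N = 300, p = 8), the
edge-of-chaos phenomenology the model is meant to operate in: the cycle is
preserved (>99% of single-cell transitions are forward mu -> mu+1), dwell
times are roughly constant (CV ~ 0.3, mean ~ 40 steps per state), cells sit
deep in their basins between hops (max overlap > 0.8 on > 90% of steps),
relaxed ensembles occupy all eight states uniformly, and coherent clamps
visibly redistribute the occupancy. Larger lambda shortens dwell but
shallows the basins: at lambda = 0.5 the ~2/p of genes that differ between
consecutive patterns feel exactly zero field and stay randomized, capping
the overlap near 0.75. Smaller lambda (< ~0.2) freezes the cycle at this T.
Temperatures are per-dataset quantities; anyone encoding a real matrix
should rescan T (and lambda) for the same qualitative behavior.

A practical consequence of the deeper basins is slower phase diffusion:
after releasing a control field, the repopulation of the uniform state
takes ~1400 steps, so the trap-and-release protocol in the tests and the
acceptance script runs 2400 steps with the steady-state window at the end.

Simulation time is in iterations. Any conversion to minutes (for overlaying
simulated on experimental curves) is a display-only scale factor and enters
no computation.

## Control search

A candidate target set is scored by <P_mu>_T: random initial states,
`relax_steps` unperturbed (the ensemble settles into the cycle with uniform
phases), then the clamp field for `control_steps`; the score averages the
objective state's occupancy over the final window (default: the whole
control window). All candidates within a GA generation share one evaluation
seed (common random numbers), so within-generation comparisons reflect the
target sets, not noise realizations.

The GA is a conventional generational scheme over fixed-size index sets:
tournament selection (k = 3), uniform set crossover repaired to size
n_targ, single-swap mutation (rate 0.1 per candidate), elitism (2).
Because the objective is stochastic, surviving elites are re-scored under
fresh seeds each generation and ranked by their accumulated mean — a lucky
evaluation cannot hold the top spot. The reported best-ever history is the
running maximum of those means, hence nondecreasing by construction.

The exhaustive enumerator (capped at 5000 subsets) is the independent
optimum for validating the GA on small pools. Two caveats learned from this
comparison: (1) among targets equally coherent with the objective state the
true landscape is nearly flat, and the enumeration's "optimum" is then
dominated by selection of extreme noise (winner's curse); a meaningful
comparison needs a pool with genuine structure, e.g. mixing genes that are
off in the objective state with genes that are on. (2) The GA's mean-based
score and the enumeration's single-seed maximum are not commensurable;
like-for-like comparison re-scores the GA winner under the enumeration's
seed. A `robustness_scores` helper re-scores a final candidate with T,
lambda and update_prob each varied by ±5%, to flag hits that are artifacts
of one parameter choice.

## Synthetic data

The generator emulates a synchronized budding-yeast-like time course:
300 periodic genes (shared omega = 2pi/70 rad/min and decay b = 0.005/min;
per-gene amplitudes uniform on [1, 3], baselines on [4, 8], phases uniform
on [0, 2pi)) plus 700 aperiodic genes (white noise with SD 0.5–1.5 around a
constant), 40 samples over 2.5 periods, additive Gaussian measurement noise
of 0.1 expression units (5% of a typical amplitude) everywhere, clipped at
zero. Ground-truth labels and parameters are returned for accuracy
measurement. What it does not emulate: batch effects, saturation,
heteroscedastic count noise, missing samples, non-sinusoidal periodic
shapes, or correlated gene programs — so passing tests demonstrate the
machinery is correct under the model's own assumptions, not that any real
dataset satisfies them. The attractor generator (`generate_attractors`)
bypasses fitting and draws sign(cos(2pi mu/p - phi_i)) patterns directly;
it is the workhorse fixture for dynamics tests.

## Problem sizes

Defaults used by the test suite and acceptance script: N = 300 genes for
population phenomenology (5000 cells for steady-state occupancy, 1000 for
the control protocol), N = 256 for storage algebra, N = 60 with 12-gene
pools for search validation. These mirror the scale of a typical encoded
yeast dataset while keeping a full run in the low minutes on one CPU.

## Known limitations

Two-state expression only (no multi-level spins); homogeneous,
non-interacting cells; no resting (G0) attractor, so model cells cycle
perpetually; inhibition only (no activating fields); couplings derive from
pairwise pattern structure and may encode indirect or spurious gene-gene
relationships; annotation of attractor states to named cell-cycle phases
requires external marker/ontology resources and is out of scope.
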