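# Methods

`neuromass` models whole-brain resting-state dynamics on individual
structural connectomes and relates the fitted long-range coupling
parameter to graph-theoretic properties of the same connectomes.  This
note records the model, the conventions the implementation fixes where
the underlying protocol leaves choices open, the synthetic-data design,
and the numerical decisions.

## Structural connectomes

A subject is a pair of symmetric, zero-diagonal, non-negative matrices:
`weights` (fractional anisotropy × streamline count per pathway,
dimensionless) and `lengths` (tract length, mm), with one label per
region at the 83-region cortical/subcortical (Lausanne-2008) scale.
Inputs with floating-point asymmetry below 1e-9 are symmetrized by
averaging with the transpose; larger asymmetry is rejected with the
offending cell named.  Binary graphs are derived as `a_ij = 1` iff
`weights_ij > threshold`; the default threshold is 0 (any traced pathway
is an edge), because deterministic tractography already prunes weak
pathways upstream via its FA (0.20) and turning-angle stopping rules.

## Local model

Each region hosts coupled excitatory and inhibitory populations of
Hindmarsh–Rose neurons with dispersed input current I ~ N(mu, sigma²),
reduced to `n_modes` representatives by partitioning the current
distribution into equal-mass quantile bins and applying a bin-wise
mean-field closure.  The six per-mode equations and the derivation are
documented in `local_model.py`.  Defaults: a=1, b=3, c=1, d=5, r=0.006,
s=4, x0=−1.6 (the classical bursting regime), mu=3.3, sigma=0.3,
n_modes=3; the coupling constants K11 (exc→exc), K12 (exc→inh), K21
(inh→exc) are explored in [0, 1].  Conventions fixed here, not given by
the protocol:

- The inhibitory population uses the same intrinsic constants and input
  dispersion as the excitatory one; the populations differ only through
  the K couplings.
- Cross- and self-population couplings are difference couplings
  (`K (mean_field − own_state)`), with inhibition entering negatively.
- The long-range input enters additively on the fast excitatory
  variable of every mode, scaled by the mode mass.  This preserves
  exact linearity of the derivative in the coupling input.
- With `n_modes=1` and a silent inhibitory population the model reduces
  exactly to the textbook 3-equation Hindmarsh–Rose system (tested
  against an independent implementation).

## Network simulation

Region j's fast excitatory mean field propagates to region i with delay
`L_ij / v` (v in mm/ms ≡ m/s, explored in [1, 100]) and enters as
`c_i(t) = G · Σ_j w_ij x_j(t − L_ij/v)` with G explored in
[0.001, 0.1].  Delays round to integer steps with a 1-step floor; the
delay ring buffer is initialized by replicating the initial mean field.
Initial states are the local model's resting condition plus uniform
perturbations of scale 0.05.

Integration uses stochastic Heun (predictor–corrector; the same
additive Gaussian increment `sd·√dt·ξ` in both stages; deterministic
Heun exactly when sd=0) at dt = 0.0122 ms by default, with white
Gaussian noise of mean 0 and SD 1 applied to all state variables
(configurable mask).  A divergence guard (default 1e6) aborts with the
offending step named; grid sweeps record such cells as invalid.  The
inner loop is numba-compiled; a test verifies one compiled step against
the pure-NumPy derivative/coupling/Heun composition.

**Weight scaling.** Coupling acts on the raw FA × streamline weights
(`weight_norm="none"`, default).  Dividing by the maximum weight was
considered and is available (`weight_norm="max"`), but it shrinks the
coupling term to under 1% of the intrinsic drive across the entire
G range, making the variance objective insensitive to G — the
exploration stage would be fitting noise.  The raw scale is also what
lets a lesioned (weaker) connectome demand a larger fitted G, the
compensation effect the analysis is designed to expose.

**Hemodynamics.** The protocol names no forward model; we adopt the
balloon–windkessel ODE system with canonical constants (kappa=0.65/s,
gamma=0.41/s, tau=0.98 s, alpha=0.32, E0=0.34, V0=0.02), driven by the
demeaned fast excitatory mean field (gain 0.1), integrated by Euler at
the 1 ms decimated resolution with positivity clamps on f, v, q that
engage only under extreme drive.  A double-gamma HRF convolution is
available as a faster configuration alternative.  BOLD covers 4 minutes
at TR = 2 s (120 samples) after a transient discard (default 10 s,
simulated in addition to the output duration).

## Parameter exploration

The objective is the mean over regions of the unbiased temporal
variance of the simulated signal.  The staged order is fixed: joint
(G, v) sweep, then K12 at the fitted (G, v), then K21, then K11, each
stage pinning previously fitted values.  Grid defaults: 10 points per
axis, 3 replicate seeds per cell (cell seeds are pure functions of the
cell coordinates, so results are independent of evaluation order); ties
break toward the smallest parameter value.  Diverged cells are NaN and
excluded; a stage with no valid cell raises, naming the stage.  Whether
the variance is taken on BOLD or on the raw neural trajectory is
configurable (`objective_on`); BOLD is the default, while the neural
signal gives a far better-resolved objective per simulated second
(tens of thousands of samples instead of tens) and is what the
scaled-down recovery test uses.

## Validation

Amplitude: global min/max over regions and times, plus the mean of
per-region temporal means.  Frequency: one-sided FFT power after mean
removal at fs = 1/TR = 0.5 Hz, grid topping out at 0.25 Hz; the peak is
the maximal mean power excluding DC.  Phase: functional connectivity as
pairwise Pearson correlation (the bounded choice; covariance is the
stated alternative), compared between matrices by correlating strict
upper triangles, with significance via Fisher Z = atanh(r) and standard
error 1/√(m−3) over the m triangle entries — treating entries as
independent is a known simplification.  Zero-variance regions (fully
lesioned nodes can be silent) get correlation 0 with a logged warning.
No hard amplitude/frequency acceptance rule is imposed; a ±50% relative
difference triggers a warning flag only.

## Graph metrics and statistics

Degree `k_i = Σ_j a_ij`; betweenness with fractional counting over
multiple shortest paths and normalization 2/((n−1)(n−2)); global
efficiency as the mean inverse shortest-path length with disconnected
pairs contributing 0 (complete graph ⇒ E = 1).  Isolated nodes remain
in n.  Shortest-path machinery is delegated to networkx; tests verify
against brute-force Floyd–Warshall path-counting oracles.

Group comparison: two-sided Wilcoxon rank-sum per metric — exact null
when min(n) ≤ 10 without ties, tie-corrected normal approximation
(no continuity correction) otherwise — against the Bonferroni threshold
0.05/3 ≈ 0.017; and OLS regression of each metric on fitted G with the
slope t statistic on n−2 df.  A degenerate cohort in which every
subject fits the same G yields a recorded "constant predictor" entry
instead of a regression.

## Synthetic data

The generator emulates deterministic-tractography outputs: region
positions uniform in a 70 mm sphere, lengths = Euclidean distances,
streamline counts `S = round(S_max · exp(−L/λ))` with λ = 40 mm and
S_max = 200, FA uniform in [0.2, 0.8], weights = FA × S, and the
weakest pairs pruned to an edge density of 0.3 (never below a spanning
tree's worth of edges; a disconnected draw regenerates with the next
seed, noted in the subject id).  Lesions act on matrices: damage
fraction f scales incident streamline counts by 1−f (f = 1 removes the
row/column), lengths of surviving pathways unchanged.  Cohorts default
to 10 controls and 20 stroke subjects with one lesion each spanning 1–8
regions at damage 0.3–1.0.  Surrogate "empirical" BOLD is band-limited
(≤ 0.25 Hz, exact frequency-domain construction) correlated Gaussian
noise with a block community structure.

What the generator does not emulate: cortical geometry, image-space
lesion masks, distance-dependent FA, hemispheric asymmetry, empirical
degree distributions, or any quantitative mapping from lesion volume to
connectome damage.  Passing tests therefore demonstrate correctness of
the pipeline's computations and the qualitative lesion→efficiency→
coupling logic, not fidelity to any patient population.

## Problem sizes used by the test suite

The full protocol (83 regions, dt = 0.0122 ms, 4-minute BOLD, 10-point
grids, 3 seeds per cell) is the package default.  The test suite and
the scaled recovery check run a reduced configuration chosen once:
10–12 regions, n_modes = 1, dt = 0.05 ms, 8–20 s of signal, 2–7-point
grids, with the test connectome generated at S_max = 50 so the entire
G range integrates stably at the coarser step.  The parameter-recovery
check compares the staged fit's G against an exhaustive 7-point,
4-replicate oracle sweep on the neural-variance objective, within one
step of the fit's 4-point G grid, across 5 master seeds.

## Known limitations

- The SJ3D mode reduction here is a quantile-bin closure; other
  published reductions use polynomial basis projections and will not
  agree numerically, though both reduce to classical Hindmarsh–Rose in
  the single-mode limit.
- dt = 0.05 ms (used in tests) is near the stability margin at strong
  coupling; production runs should keep the 0.0122 ms default.
- The Fisher-Z p-value for FC similarity ignores dependence among
  matrix entries.
- Exact Wilcoxon inference is limited to tie-free samples.
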