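# Methods

## Residue communication network

### Features

Each residue contributes two per-frame features: the Cα position and
the mass-weighted center of mass of its side-chain heavy atoms
(hydrogens are ignored because many trajectories omit them; glycine and
any residue without side-chain heavy atoms falls back to its Cα — users
who consider that a poor proxy can exclude such residues via the
selection). Residues are keyed by `(chain_id, residue_number)` with
author numbering preserved, so results can be read directly against
published mutant names (e.g. W563).

Before displacements are computed, every frame is superposed onto a
common reference by a rigid-body Kabsch fit on the Cα atoms of the
analyzed selection. The default reference is the time-average
structure, re-estimated once after a first alignment pass (two
iterations total); a fixed frame index can be chosen instead. Without
this, whole-body drift would masquerade as correlated internal motion.
Input coordinates are assumed whole — no periodic-boundary unwrapping
is attempted. The frame window and stride are configurable; defaults
analyze every frame.

The displacement of residue *i* in frame *n* is the Euclidean norm of
the deviation of its side-chain COM from its time-average position.
Using the scalar magnitude is the minimal reading consistent with a
double sum over a discretized scalar pair distribution; a
`per_component=True` flag returns the raw 3-vector deviations for
sensitivity checks.

### Contact map

`C_ij` is the truncated Gaussian kernel of the Cα–Cα distance averaged
over frames: 1 inside the cut-off `c = 7.0 Å`, `exp(−(d²−c²)/2σ²)`
outside, continuous at `d = c`. The width is not free: it is calibrated
by requiring the kernel to reach a negligible value (10⁻⁵ by default)
at `d_cut = 10 Å`, giving the closed form
`σ = √((d_cut²−c²)/(−2 ln target)) = 1.4883 Å` for the defaults
(quoted rounded as 1.48 in the literature this mirrors).

### Mutual information

`M_ij` is the plug-in estimate from a joint histogram of the two
displacement series. Each residue's series is discretized on equal-
width bins spanning its own observed range; `n_bins = 20` by default.
`M = H_i + H_j − H_ij` and the normalization is by the joint entropy,
`M′ = M/H_ij ∈ [0, 1]` (defined as 0 when the joint entropy vanishes,
i.e. constant series, with a logged warning). Natural log is the
default base; the minimal-path *identity* is invariant to the base
(a global scale on all weights), only d_min magnitudes change.

No bias correction is applied. The plug-in estimator has a positive
finite-sample bias of order `(n_bins−1)²/(2 N_frames)`; the test suite
demonstrates the resulting baseline decays as frames grow, and the
planted-signal tests show the defaults separate true coupling from that
baseline at 1000–2000 frames. Users analyzing short trajectories should
reduce `n_bins`.

### Weights, edges, block uncertainty

`w_ij = −log(C_ij · M′_ij)` is non-negative because both factors are in
`[0, 1]` — the precondition for Dijkstra. Pairs whose product falls
below `floor_eps = 1e-12` carry **no** edge rather than a huge finite
weight: −log of numerical zero is undefined and the physical meaning is
"no communication". The diagonal is excluded (no self-loops).

Edge-weight variability is estimated by re-running the entire
contact/MI/weight pipeline on `N_B` contiguous blocks of the trajectory
and applying, exactly as stated,

    σ(w_ij) = sqrt( 1/(N_B(N_B−1)) · Σ_B (w_ij^B − w̄_ij)² )

i.e. the standard-error-of-the-mean form (the prefactor is genuinely
ambiguous between SD-of-blocks and SE-of-mean conventions; the printed
form is implemented verbatim). Block length is expressed in frames,
with a convenience conversion from nanoseconds (default 25 ns) when the
frame time is configured; with neither given, five equal blocks are
used. Edges missing in any block get σ = NaN rather than a fabricated
number.

### Paths, centrality, mutant comparison

Region-to-region distance is the minimum over all member pairs (a
mean-over-pairs aggregation was considered and rejected as the default
because a single well-coupled pair is what carries the signal; the
minimum is also what "shortest path between regions" means
operationally). Per-subunit mode restricts source and target members to
the same chain while keeping the whole graph, so paths may legitimately
detour through a neighboring subunit; a tetramer-global mode returns
the single minimum. Ties among equal-length paths are broken by fewer
hops, then lexicographically smallest node sequence — determinism for
regression tests, no scientific content.

Betweenness centrality is Brandes's algorithm on the weighted graph,
endpoints excluded, reported raw and normalized by `(n−1)(n−2)/2`.
Unreachable region pairs produce a typed no-path record and are
excluded (with a warning) from Δd_min averages instead of injecting
infinities. `Δd_min = d_min(MUT) − d_min(WT)` is aggregated as mean ±
SD (ddof = 1) over subunits.

## Gating energetics

Activation (G-V) and steady-state inactivation (availability) curves
are fitted by unweighted least squares (lmfit/Levenberg–Marquardt) with
the two-state forms

    G(V)      = 1 / (1 + exp( z_G F/(RT) (V_G½ − V)))
    I/I_max(V)= 1 / (1 + exp(−z_I F/(RT) (V_I½ − V)))

Temperature enters only the steepness (default 290.65 K, the ~17–18 °C
recording condition); the energies contain no RT:
`ΔG = z F V½` with `F = 23.061 kcal mol⁻¹ V⁻¹` and V½ in volts — this
constant reproduces the published energy tables from the published fit
values at printed precision. Standard errors are the asymptotic ones
from the fit covariance. `δΔΔG = F √((δz V½)² + (δV½ z)²)` is evaluated
per channel exactly as printed; because that formula involves a single
(z, V½) pair and the WT contribution is ambiguous, the table reports
both the per-channel value (`ddG_err`) and the WT⊕mutant quadrature
combination (`ddG_err_combined`).

Tail-current G-V points: the peak is the sign-aware extremum inside a
guard-delayed window (default 2 ms) after the repolarizing step — the
guard excludes residual capacitive transients; exact windows were never
published and are config parameters. Peaks are normalized per
experiment by their maximum magnitude, then averaged across experiments
at each test voltage (so absolute scale cancels).

Triple-pulse availability: the raw signal is the test-pulse (P3) peak.
Below a deactivation threshold (default −120 mV) channels deactivate
during the short conditioning pulse, attenuating P3; the falling phase
of the conditioning-pulse current is fitted mono-exponentially (on its
last 70 % by default) and the ratio extrapolated-start/fitted-end
rescales the raw peak. When the fit fails (non-decaying segment) the
raw peak is kept with a warning; the correction can only increase the
availability estimate. Normalization per experiment means the fitted
top of the availability curve can sit slightly below 1 when even the
most hyperpolarized conditioning voltage is not fully de-inactivating —
the same bias the experimental procedure has.

## Synthetic data

The trajectory generator plants a chain of residues along the x axis at
6.0 Å spacing (inside the 7 Å contact cut-off); decoy residues sit on
four rails 6.5 Å off the chain axis at the same spacing. Chain residues'
side-chain pseudo-atoms (one per residue, 1.5 Å from the Cα) share a
latent motion: `coupling_strength × latent(t)` along x plus isotropic
Gaussian noise (0.3 Å per component by default); decoys and all Cα
carry noise only. The latent signal is a stationary AR(1) process with
lag-1 correlation 0.9 and unit SD, not white noise, so trajectory
blocks see realistic autocorrelation and the block analysis is
exercised meaningfully. This geometry makes the planted chain both the
minimal endpoint-to-endpoint path and the main thoroughfare for
decoy-to-decoy traffic (hence high interior betweenness) — emulating
exactly the property the network method is supposed to detect. It does
**not** emulate membrane, solvent, realistic protein geometry or
state-dependent gating, so passing tests show the *method* recovers
planted coupling, not that any particular channel has it. Fixtures are
written as PDB + DCD (two pseudo-atoms per residue) so the real readers
are exercised end-to-end; a JSON sidecar records the ground truth.

The clamp generator's defaults mirror the published wild-type fits
(z_G = 2.8, V_G½ = −24.6 mV; inactivation z_I = 0.9,
V_I½ = −61.8 mV), Gaussian noise of 0.02 of full scale, four sweeps
per voltage (the recordings averaged n = 4 cells), a 10 ms decay
constant for the conditioning-pulse deactivation, and the
−180…+60 mV / 10 mV voltage grid of the triple-pulse protocol
(P1 +20 mV 1 s, P2 30 ms, P3 +20 mV 0.6 s). Test-pulse currents
plateau for 5 ms before re-inactivating so the peak picker sees the
true amplitude. All generators are bit-reproducible given a seed.

## Numerical choices and degenerate inputs

* Matrices are symmetrized exactly (averaged with their transpose) and
  their range constraints are enforced at construction, not assumed.
* Weights are clipped at 0 to remove −0.0/round-off where the coupling
  product is exactly 1.
* Constant displacement series ⇒ zero entropy ⇒ M′ = 0 (warning), no
  NaNs propagate.
* Boltzmann fits seed V½ at the observed 0.5-crossing and constrain
  z > 0; non-convergence raises with a residual report rather than
  returning garbage.
* Path-length ties use a 1e-9 tolerance before the deterministic
  tie-break.

## Problem sizes

The shipped test and acceptance computations use 30-residue,
2000-frame synthetic ensembles (40 seeds for the recovery study) and
100-seed fit-bias studies — sizes chosen so the full statistical suite
re-runs in well under a minute per study on one CPU while leaving the
estimators in the regime where their finite-sample behavior is visible.
Real 500-ns trajectories of a tetrameric channel run through the same
code path; the MI stage is the expensive one (O(R²) histograms) and is
the natural target for striding.

## Known limitations

* The MI discretization (bin count, scalar displacements) and the
  pre-displacement alignment protocol are assumptions — the source
  analyses never specified them; both are configurable and flagged.
* Plug-in MI bias means absolute d_min values depend on n_bins and
  trajectory length; comparisons (Δd_min, path identity, BC ranking)
  are the robust outputs.
* No PBC unwrapping, no k-shortest-path ensembles, no current-flow
  betweenness, no kinetic (time-constant) modelling, no Q-V analysis,
  no multi-state Markov gating.
* Checksum-keyed caching of intermediates was deliberately omitted:
  runs at the supported problem sizes are cheap enough that a manifest
  with input/output checksums gives reproducibility without a cache
  layer.
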