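# Methods

## Model

Each cortical area is a three-population mean-field circuit: two
stimulus-selective excitatory populations A and B coupled through slow NMDA
gating variables (τ_N = 60 ms), and one shared inhibitory population C with
fast GABA gating (τ_G = 5 ms). Firing rates relax toward static transfer
functions with τ_r = 2 ms, so on the timescale of the gating variables the
rates are effectively slaved to the currents. The excitatory transfer
function is the smooth rectifier φ_E(I) = (aI−b)/(1−exp(−d(aI−b))) — strictly
increasing, positive for any finite current, with a removable singularity at
aI = b whose value is 1/d; the inhibitory one is threshold-linear,
φ_I(I) = [(c1·I−c0)/g_I + r0_I]_+.

Inhibitory currents enter the total-current equations subtractively
(−g_EI·S_C on excitatory populations, −g_II·S_C on the inhibitory one).
This convention is load-bearing: with the reference parameter set it yields
a stable low-activity baseline whose inhibitory eigenvalue is
−1/τ_G − γ_I(c1/g_I)·g_II — an identity we use as an analytic anchor for
the Jacobian implementation.

Two anatomical gradients break the symmetry between areas:

* **PV gradient.** The local inhibitory weights scale linearly with the
  normalized PV interneuron fraction of each area,
  g_EI,i = g_EI,0(1 + g_EI,scaling·PV_i) (and likewise g_II,i). Sensory
  areas, PV-rich, are more strongly stabilized than association areas.
* **Counterstream inhibitory bias (CIB).** Long-range connections are split
  by target cell type with the feedforwardness coefficient
  m_ij = σ(β(h_i−h_j)) of the normalized hierarchy scores: climbing
  projections excite mostly excitatory cells (m > 0.5), descending ones
  mostly interneurons. The split conserves weight exactly, W_E + W_I = W.

Both gradients have mean-replacement controls (PV fraction replaced by its
cortical mean; m replaced by 0.5) used by the heatmap sweeps.

## Connectivity preprocessing

Matrices are target-by-source throughout (`W[i, j]` = projection from j to
i); diagonals are forced to zero on load since self-projections are not part
of the model. Raw tracer weights are converted to per-neuron input by
multiplying by source volume and dividing by target neuron density, missing
hierarchy scores are imputed as an affine function (α_h = 1.33,
β_h = −0.22) of the connectivity-weighted mean of the known scores (a
least-squares refit of the two coefficients is available but off by
default), and the weight range — several orders of magnitude — is compressed
by the power law W ↦ W^k_scale (k_scale = 0.3) followed by
max-normalization to exactly 1. The power law is monotone, so the ordering
of connections is preserved.

The cell type-specific variants used by the graph measures follow the same
printed definitions as the dynamics: the celltype matrix weighs each edge by
k_cell = m_ij − PV_i(1−m_ij) and is max-normalized; the sign-only variant
keeps magnitudes and flips the sign of feedback edges; the noPV variant uses
the graded factor 2m_ij−1. Only the celltype variant is renormalized — the
other two are not, following their definitions literally. Note that the
celltype variant with PV ≡ 0 reduces to the CIB weighting m∘W (not to the
noPV variant): the PV discount and the hierarchy bias are distinct factors.

## Simulation

Integration is forward Euler–Maruyama at dt = 0.5 ms with all state
variables initialized to zero; the 2 s pre-stimulus interval doubles as
burn-in to the baseline fixed point. (The parameter table's "initial firing
rate" constants are kept as documentation; r0_I genuinely enters φ_I.) The
NMDA gating increment is proportional to (1−S), which keeps S in [0, 1] for
any nonnegative rate at this step size; the integrator asserts this and
finiteness at regular intervals and aborts with the step index on violation.
Noise is an Ornstein–Uhlenbeck current per population
(x ← x(1−dt/τ_noise) + σ√dt·N(0,1)), stationary s.d. σ√(τ_noise/2); σ = 5 pA
on excitatory populations, zero on inhibitory ones. Every analysis that
feeds exact tests runs with `deterministic=True` (σ ≡ 0), and stochastic
runs are bit-reproducible from the protocol seed.

Protocol conventions: the stimulus window is half-open [T_on, T_off);
delay-phase inhibition starts 2 s after stimulus offset and lasts until
trial end; the delay rate of an area is the mean of its stimulated
population's rate from 2 s before trial end to 0.5 s before trial end; an
area is persistent when that mean strictly exceeds θ = 5 Hz. The 5 Hz
threshold is used uniformly (persistence counts, heatmaps, attractor
census); sub-1-Hz display cutoffs in published figures are treated as
presentation choices, not analysis logic.

## Thalamocortical extension

Thalamic areas carry two excitatory populations with AMPA gating
(τ_A = 2 ms, steady state γ_A·r·τ_A, linear in the rate — unlike saturating
NMDA), no interneurons and no thalamo-thalamic recurrence; the reticular
nucleus is folded into a constant background current I_th0. Thalamic raw
weights skip the volume/density normalization (the per-neuron data are not
available for the thalamus) and go straight to power-law rescaling.
Thalamic hierarchy scores are normalized with the *cortical* min/max so the
two hierarchies share a scale; values outside [0, 1] are legitimate. The
corticothalamic inhibitory-targeting matrix is computed and stored for
completeness but is unused by the dynamics, since thalamic areas have no
inhibitory population. Thalamic "optogenetic inhibition" is a
hyperpolarizing current applied to both excitatory populations. I_th0
defaults to 0.3 nA, chosen so an isolated thalamic population settles at
φ_E(I_th0) ≈ 0.3 Hz — quiet but responsive; it is a calibrated constant of
this package, recorded in the configuration, not a published value. In the
thalamocortical regime the cortico-cortical couplings are weakened tenfold
(μ_EE = 0.01 nA), so delay activity survives only through the
thalamocortical loop — inhibiting the thalamus during the delay collapses
it.

## Stability analysis

For an isolated area the rates are adiabatically eliminated (τ_r ≪ τ_N) and
the circuit reduces to a 3-D system in (S_A, S_B, S_C). Fixed points are
found with a Newton-type root finder from a low (origin) or high initial
guess, accepted only below a 1e-10 residual, and cross-checked against
noise-free forward integration. The Jacobian is analytic (chain rule through
the transfer functions; φ_I' is c1/g_I on the active branch and 0 below
threshold) and is validated against central finite differences; fixed points
within 1e-6 nA of the φ_I kink are rejected as non-differentiable.
Eigenvalues are reported sorted by descending real part, evaluated at the
low-activity baseline whose stability the scenario battery interrogates,
with PV = 0 (the minimum of the normalized gradient) as the reference local
circuit.

The five-scenario battery evaluates isolated circuits analytically
(scenarios: intact; local inhibition removed) and the coupled network by
noise-free simulation (intact; long-range E→I removed; local inhibition
removed), calling a scenario stable when no area's late-trial rate exceeds
θ. Saddle-node scans bisect g_EI,0 to 1e-4 nA on the predicate "the
low-activity state exists", which requires either root-finder convergence
to a low state or relaxation from the origin staying below θ — so the
critical point is only declared when both fail.

## Synthetic data

The generators emulate the statistical structure of the anatomical inputs
rather than any particular dataset: hierarchy scores uniform on [0, 1]; PV
fractions built as ρ·z_h + √(1−ρ²)·z_ε with the noise orthogonalized
in-sample, so the PV-hierarchy Pearson correlation equals the target
(default −0.35) exactly up to rare positivity clipping; log-normal volumes
and neuron densities; weights log-uniform over 5 decades with 97% of
off-diagonal entries nonzero. Generators are pure functions of a frozen spec
(including its seed): reruns are bit-identical.

What the fixtures do **not** reproduce: the real connectome's community
structure and degree sequence, the identities of individual areas, layer-
resolved PV densities, or interhemispheric projections. Tests passing on
these fixtures therefore demonstrate that the *mechanisms* behave as
designed (hierarchy-gated persistence, global inhibition stabilization,
coupling-dependent attractor counts), not that any data-specific headline
number is reproduced; quantities that depend on the real anatomical tables
(specific correlation values, the exact attractor count, specific core-area
identities) require those tables as input.

## Problem sizes and numerical choices

The default synthetic cortex has 43 areas and trials last 10 s at
dt = 0.5 ms. Unit and acceptance tests use this full size where the
phenomenon requires it (scenario battery, persistence motif, thalamocortical
collapse) and smaller instances (4–12 areas) where it does not; the
attractor census in tests enumerates 2^k subsets for k ≤ 4 candidates,
chosen by the default (hierarchy − PV) rank-sum scoring. Exhaustive
enumeration beyond ~16 candidates should use the seeded sampling mode.
Cycle enumeration for loop strength is exact (simple directed cycles,
rotations identified, both orientations counted for length ≥ 3) and is
validated against a brute-force permutation oracle for n ≤ 7.

Other deliberate choices: eigenvector centrality on signed matrices has no
Perron theory behind it, so a deterministic convention is imposed (largest
real part, real part of the eigenvector, sign fixed by the
largest-magnitude entry, unit norm) and ties in the leading eigenvalue are
an error rather than an arbitrary pick. The persistence comparison is
strict (rate > θ), so rates exactly at threshold are not persistent.
Logistic-regression accuracy for the binary predictors is in-sample and
unregularized, with perfectly separated data short-circuited to accuracy
1.0 under a flag, and constant measures falling back to the majority class.
Inhibited areas are always excluded from inhibition-effect averages. The
four-way classification assigns "input" first; an area with both strong
stimulus-phase and strong delay-phase effects is labeled input.

## Known limitations

* The mean-field reduction is taken as given; no spiking-network validation
  is included.
* Single-trial analyses only: no trial-averaged statistics or decoding.
* The thalamic background current is calibrated, not measured; conclusions
  about absolute thalamic rates should not be drawn from it.
* Attractor patterns are distinguished by the stimulated (A) population
  only, matching the census protocol in which all stimuli target A.
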