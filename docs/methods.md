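# Methods

## The model

cryofit treats fitting an atomic model into a cryo-EM reconstruction as
Bayesian inference over conformational degrees of freedom θ and nuisance
parameters ξ = (σ, α, λ).

**Forward model.** The theoretical density is a sum of identical,
normalized spherical Gaussians centered at the atoms,

    ρ(x; θ, σ) = Σ_k (2πσ²)^(−3/2) exp(−‖x − x_k(θ)‖² / 2σ²),

evaluated at voxel centers. Equivalently, it is the infinitely sharp atomic
map convolved with a Gaussian blur kernel of bandwidth σ. The model is
deliberately minimal — equal atom weights, no scattering or temperature
factors — and is appropriate for intermediate-to-low resolution maps of
protein assemblies. The bandwidth defaults to σ = 0.225 × resolution (the
Chimera convention). Each atom's kernel is evaluated only within 5σ
(configurable); the neglected Gaussian tail is below 4 × 10⁻⁶ of the peak,
i.e. relative truncation error < 10⁻⁵.

**Likelihood.** Observed voxel values are the rendered density scaled by a
calibration factor α plus i.i.d. Gaussian noise with precision λ,
restricted to voxels whose binary mask flag marks them as signal:

    log Pr(ρ | θ, ξ) = (N₁/2) log(λ/2π) − λ E_map(θ, α),
    E_map = ½ Σ_n m_n (ρ_n − α ρ(x_n; θ, σ))².

E_map is the sufficient statistic; λ E_map acts as the map-restraint term
of the hybrid energy E(θ) + λ E_map. Because λ multiplies the restraint, a
realistic λ estimate matters: inflating the voxel count with zero-density
background voxels inflates λ̂ = N₁ / (2 E_map) and over-weights the map.

**Nuisance conditionals.** With a flat prior on α and Jeffreys's 1/λ prior
on λ, both conditionals are conjugate: α | λ, θ is Gaussian with mean equal
to the no-intercept least-squares slope of observed on rendered density and
precision λ‖ρ_model‖²; λ | α, θ is Gamma(N₁/2, rate = E_map). Draws of α
are truncated to α > 0 (a negative calibration is physically meaningless):
rejection sampling against the untruncated Gaussian with an exact
`truncnorm` tail draw as fallback. Marginalizing α analytically yields a
likelihood that depends on θ only through the cross-correlation C between
observed and rendered maps and is maximal at C = 1; the additive constant
is kept so the value equals the log of the actual α-integral (directly
checkable by quadrature). σ is normally fixed from the stated resolution;
an optional random-walk Metropolis step on log σ can be enabled in the
Gibbs sweep.

## Map preparation

Four deterministic operators precede fitting:

1. **Threshold-shift** at a user-supplied ρ_min: values below the threshold
   become 0, values above are shifted down by ρ_min, so the background is
   exactly zero.
2. **Autocrop** to the minimal subgrid containing all positive voxels;
   voxel-center world coordinates are preserved by moving the origin.
3. **Downsample** by block-mean decimation with the smallest integer factor
   reaching the target spacing (default target 2σ — coarser voxels keep the
   independent-noise assumption tenable; the rounding rule is round-up).
   Edge blocks average over the voxels that exist; the output grid stays
   regular with origin at the first full block's center.
4. **Mask** voxels with value above a level (default 0 after thresholding),
   applied last. Masked-out voxels are excluded from E_map, C and all
   nuisance estimates.

Each step removes low-information voxels and therefore lowers λ̂, which the
`precision_diagnostics` report makes visible stage by stage.

## Priors

- **Non-bonded force field**: either a purely repulsive quartic contact
  term k (r_ij − d_ij)⁴ for r_ij < d_ij (contact distance = sum of per-atom
  radii; pairs found by KD-tree), or a 12-6 Lennard-Jones well whose core
  below 0.9 r₀ is replaced by its tangent line, keeping energy and gradient
  continuous and bounded for clashed starting structures. The functional
  forms are the minimal ones matching "quartic repulsion" and "linearly
  ramped Lennard-Jones"; k, ε, radii and the switch fraction are
  configurable. Default contact radii for the coarse bead fixtures are
  1.8–2.0 Å; for all-atom work van-der-Waals radii should be supplied.
- **Soft box**: each atom coordinate contributes logistic-wall factors
  log s(γ(x − l)) + log s(γ(u − x)) per axis with the box equal to the
  thresholded map's bounding box and γ = 1 Å⁻¹ by default. Implemented with
  log-sigmoids via `logaddexp`, so atoms far outside the box give a finite,
  linearly decaying log-probability instead of overflow.

## Tempering and sampling

Two temperature-like parameters control replica exchange. β ∈ [0, 1] raises
the likelihood to a power (β = 0 switches the data off). q ≥ 1 flattens the
non-bonded prior through the Tsallis transformation
u_q(E) = E_min + q/(q−1) log[1 + (q−1)(E − E_min)], with u₁(E) = E; its
gradient weight q / [1 + (q−1)(E − E_min)] vanishes for strongly clashed
configurations, which is what lets hot replicas cross packing barriers. The
box prior is not tempered: confinement must hold at every rung, otherwise
hot replicas drift out of the map volume and never return. E_min defaults
to 0 and must lie below the prior energy of every visited configuration
(it is a shared reference, not a fitted quantity).

**HMC.** Conformations are updated by leapfrog trajectories of the tempered
posterior energy with Gaussian momenta (unit masses by default,
configurable per block), Metropolis-accepted with min(1, e^(−ΔH)). A
non-finite energy or gradient rejects outright. |ΔH| scales as step² (an
integrator-order check in the tests). During the first half of a
replica-exchange run, each rung's step size is adapted multiplicatively
(×1.1 on acceptance, ×0.6 on rejection — equilibrium acceptance ≈ 0.8,
inside the usual 60–90% window) and then frozen so detailed balance holds
for the collected samples. Adaptation is essential here because λ is
estimated self-consistently: on a nearly noise-free map λ̂ reaches 10⁵ and
the posterior over poses becomes extremely sharp.

**Gibbs sweep.** One HMC update of θ at fixed ξ, then α and λ drawn from
their exact conditionals (α first, then λ), tempered by β (Gaussian
precision scaled by β, Gamma shape/rate scaled by β). At β = 0 the nuisance
parameters are left unchanged — their tempered conditionals are improper.

**Replica exchange.** Each rung of a (β, q) ladder runs its own Gibbs
chain with its own nuisance state; rung 0 is always the target (1, 1).
Neighbor swaps exchange conformations only, alternating even/odd pairs,
with Δ = [U_i(x_j) + U_j(x_i)] − [U_i(x_i) + U_j(x_j)] on the cross-
evaluated tempered energies — the standard criterion that preserves the
product distribution for any ladder. Default ladders are geometric in β
(1 → β_min) and linear in q (1 → q_max); swap rates and round-trip
statistics are reported so users can judge ladder adequacy.

## Degrees of freedom

- **Rigid**: translation plus an axis-angle rotation vector (Lie algebra
  coordinates). Gradients are pulled back through the exact right Jacobian
  of the exponential map (series expansion below ‖φ‖ = 10⁻⁴); rotation
  vectors are canonicalized to ‖φ‖ ≤ π to stay clear of the 2π singularity.
- **Torsions**: a rooted tree of covalent bonds (built per chain, rooted at
  the lowest-index atom — for a polypeptide chain that is the N-terminal
  side; the choice of anchor end is a convention, not a constraint).
  Setting an angle rotates exactly the downstream subtree about the bond
  axis, preserving bond lengths and angles; the axis is oriented
  child→parent so a positive increment increases the measured 4-point
  dihedral. Gradient projection accumulates subtree force and torque sums
  in one leaf-to-root pass — no Jacobian matrix is built.
- **Symmetry**: cyclic C_n, dihedral D_n (2n mates; the 2-fold axis
  defaults to an arbitrary fixed perpendicular of the main axis,
  configurable) and helical (rise, twist) screw groups. Mates are virtual:
  only the fundamental subunit carries DoF; mate forces are rotated back
  (S_mᵀ g_m), summed and projected. Helical (rise, twist) can be exposed as
  two extra DoF when they are to be estimated.

## Workflows

- `fit_flexible`: local HMC-within-Gibbs refinement in torsion space from a
  given start — no replica exchange, by design: flexible fitting is a local
  refinement problem and global torsion sampling would wander to arbitrary
  compact shapes that also fit the density. Traces C, RMSD-to-start,
  RMSD-to-target and per-domain RMSD per iteration.
- `fit_rigid_symmetric` / `fit_multibody`: replica-exchange rigid-body
  sampling, with prior-only (packing) mode when no map is given, and an
  optional staged protocol (non-bonded terms off, then on) for multibody
  problems. Samples are clustered by single-linkage in pairwise-RMSD space
  (default cutoff 1.0 Å), reporting population, mean non-bonded energy
  (box terms excluded) and ensemble RMSD (mean within-cluster pairwise
  RMSD) per cluster.
- RMSD convention: raw (common-frame) RMSD for assemblies, where the pose
  is the quantity of interest; least-squares superposed RMSD for
  single-chain flexible fitting. Both are available and labeled.

## Synthetic data

The generator produces self-avoiding bead polymers (bond length 3.8 Å,
direction changes restricted to 20–100° so 1-3 distances stay beyond the
4 Å contact distance; clash-free by rejection), hinge pairs differing by
one inter-domain torsion, symmetric assemblies with recorded ground-truth
poses, and simulated maps rendered by the forward model on a grid padded
5σ around the structure, with optional i.i.d. Gaussian voxel noise of
known precision λ*. The noise model matches the likelihood exactly, so
estimator-recovery tests are well posed. What this does **not** emulate:
spatially correlated reconstruction errors, CTF/projection artifacts,
per-atom scattering weights, or solvent — passing tests demonstrate
correctness of the inference machinery under its own assumptions, not
robustness to the ways real maps violate them (correlated errors in
particular are known to inflate λ̂).

## Problem sizes and numerical choices

Test and acceptance runs use toy systems chosen so the statistics are
decisive: nuisance recovery uses a 150-residue chain at 2 Å resolution
with 0.9 Å spacing (≈ 7.5 × 10⁵ voxels, ‖ρ_model‖² ≈ 52, so the posterior
σ of α is ≈ 0.4% of the true value); pose-recovery fixtures use 10–12
residue subunits at 8–10 Å resolution with 2–3 Å spacing and two to three
replicas. Gradient checks use central finite differences at ε = 10⁻⁵–10⁻⁶
with relative tolerance 10⁻⁵. Degenerate inputs fail loudly: all-zero maps
cannot be cropped, empty masks and zero-norm model maps raise, a perfect
fit makes the λ posterior degenerate (error rather than a silent infinite
precision), and E < E_min is rejected in the Tsallis transform.

## Known limitations

- No model-evidence computation; model comparison across priors is out of
  scope.
- The mask is fixed user input, not inferred, and errors are assumed
  voxel-independent.
- Gaussian kernels with equal weights limit validity to
  intermediate/low-resolution maps.
- Single-linkage clustering with a fixed cutoff is simple and
  deterministic but merges clusters connected by sparse bridges.
- The CLI covers preparation, simulation and the two most common fitting
  modes; multibody runs are driven through the Python API.
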