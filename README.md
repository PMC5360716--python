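# cryofit

Bayesian fitting of atomic structures into cryo-EM density maps.

cryofit is for structural modelers who have an atomic model (or subunits of
an assembly) and a density volume at intermediate-to-low resolution, and
want posterior ensembles of conformations rather than a single optimized
fit — with the weight of the map determined by the data instead of chosen
by hand.

## The model

A theoretical map is rendered from atom positions by placing a normalized
spherical Gaussian of bandwidth σ at every atom (σ = 0.225 × resolution by
default):

    ρ(x; θ, σ) = Σ_k (2πσ²)^(−3/2) exp(−‖x − x_k(θ)‖² / 2σ²)

Observed voxel values ρ_n are modelled as α·ρ(x_n; θ, σ) plus i.i.d.
Gaussian noise of precision λ, over the voxels marked as signal by a binary
mask m_n:

    log Pr(ρ | θ, ξ) = (N₁/2) log(λ/2π) − λ·E_map,
    E_map(θ, α) = ½ Σ_n m_n (ρ_n − α ρ(x_n; θ, σ))²

The three nuisance parameters ξ = (σ, α, λ) are inferred jointly with the
conformation θ: α (calibration) and λ (precision, the weight of the map
restraint in the hybrid energy E(θ) + λ·E_map) have conjugate
Gaussian/Gamma conditionals and are Gibbs-sampled; θ is sampled with
Hamiltonian Monte Carlo over Cartesian, rigid-body (Lie-algebra rotations)
or torsion-angle coordinates, with cyclic/dihedral/helical symmetry mates
generated virtually and their forces backprojected onto the fundamental
subunit. Multimodal pose posteriors are handled by replica exchange over a
ladder of (β, q) rungs: β tempers the likelihood, q flattens the non-bonded
prior through the Tsallis transformation. Map preparation (threshold-shift
at ρ_min, autocrop, block-mean decimation to ≈ 2σ spacing, masking) keeps
the precision estimate λ̂ = N₁/(2·E_map) honest — zero-density border
voxels would otherwise inflate it.

See `docs/methods.md` for the full account.

## Worked example

Fit a hinge-opened toy protein into the simulated 10 Å map of its closed
conformation (everything synthetic, nothing to download):

```python
import numpy as np
from cryofit.synthetic import make_toy_protein, make_hinge_pair, simulate_map, toy_domains
from cryofit.maps import build_mask
from cryofit.forward import default_bandwidth
from cryofit.workflows import fit_flexible

protein = make_toy_protein(20, seed=1)
start, target = make_hinge_pair(protein, 0.9)          # 1.9 Å apart
dmap = build_mask(simulate_map(target, resolution=10.0, spacing=3.0), 1e-9)

result = fit_flexible(
    start, dmap, sigma=default_bandwidth(10.0),
    n_iterations=60, step_size=0.02, seed=0,
    target=target, domains=toy_domains(protein.n_atoms),
)
tr = result.trace
print(tr[["iteration", "cross_correlation", "rmsd_to_target", "lambda"]]
      .iloc[[0, 9, 29, 59]].to_string(index=False, float_format=lambda v: f"{v:.4g}"))
```

Output:

```
 iteration  cross_correlation  rmsd_to_target    lambda
         0             0.8618           1.919 1.047e+06
         9             0.8618           1.919 9.784e+05
        29             0.9697          0.7762  4.49e+06
        59             0.9943          0.2585 2.231e+07
```

The chain starts 1.9 Å from the target with a cross-correlation C = 0.86;
torsion-space HMC closes the hinge to 0.26 Å with C = 0.994. λ is sampled
from its Gamma conditional and sharpens as the fit improves — it is the
data-determined weight of the map restraint, so the map pulls harder
exactly when it is being reproduced well. Per-domain RMSD columns (also in
the trace) stay near zero: the two rigid domains move as units, only the
hinge bends.

Rigid fitting of symmetric assemblies works the same way from the shell:

```sh
cryofit make-fixture --n-residues 10 toy.pdb
cryofit simulate-map --resolution 10 --spacing 3 toy.pdb toy.mrc
cryofit prep-map --threshold 1e-4 --resolution 10 toy.mrc prepped.mrc
cryofit fit-rigid --symmetry C3 --resolution 10 toy.pdb prepped.mrc fitted.pdb
```

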