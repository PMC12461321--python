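# desgp

Gaussian-process prediction of deep-eutectic-solvent (DES) properties —
density, viscosity and melting temperature — from COSMO-RS sigma-profile
mixture descriptors, with tools for enumerating and screening the binary
design space for new liquid formulations and for mapping it in 2-D with
probabilistic PCA.

## The problem

DESs are liquids formed by mixing solid precursors (typically a hydrogen
bond acceptor and a hydrogen bond donor) whose melting point drops far
below that of either component. With hundreds of candidate precursors and
free compositions, finding formulations with target density, viscosity and
a sub-ambient melting point by trial and error is hopeless. This package
implements a surrogate-model workflow: learn each property from data,
then scan every candidate combination *in silico* and keep only the
predicted room-temperature liquids.

## The model

Each compound is described by its sigma profile — the 61-bin unnormalized
histogram P(σ)·A of its COSMO screened surface charge density σ on the
standard grid (−0.030 … +0.030 e·Å⁻², 0.001 steps). A mixture of up to
three components with mole fractions *xᵢ* gets the concatenated,
mole-fraction-weighted descriptor

    SP = [SP₁·x₁, SP₂·x₂, SP₃·x₃]     (183 entries; unused slots zero)

with the temperature in kelvin appended as a 184th entry for the
temperature-dependent properties (density, viscosity).

Properties are modelled by zero-mean Gaussian-process regression with a
stationary kernel of the Euclidean distance ‖xᵢ − xⱼ‖ — RBF,
rational-quadratic or Matérn-3/2 — plus a White noise term σ_W²·δ(i,j).
Predictions are the usual Gaussian conditionals,

    μ′ = Σ*ᵀ Σ⁻¹ Y,    Σ′ = Σ** − Σ*ᵀ Σ⁻¹ Σ*,

through a cached Cholesky factorization. Hyperparameters (σ², ℓ, α, σ_W²)
are fitted by maximizing the log marginal likelihood with L-BFGS-B in
log-space, with restarts. Features and labels can be standardized or
log-standardized (a 10⁻³ buffer keeps zero-valued sigma bins finite);
normalizer moments always come from the training split only.

The screening step enumerates all C(n,2) binary 1:1 pairs, predicts all
three properties at 298 K, gates on predicted melting temperature
(< 275 K for the low-density/low-viscosity search, < 300 K for the
high/high search) and ranks by a rank-sum over the two objectives.

## Worked example

Everything below runs on synthetic data generated by the package itself
(Gaussian-bump sigma profiles and labels from a documented latent
function), so no external data are needed:

```bash
desgp simulate --out demo --seed 5 --n-compounds 20 --n-rows 300
desgp train --profiles demo/profiles --dataset demo/viscosity.csv \
      --property viscosity --seed 5 --out demo/vis_model
```

which prints, per split (numbers from this exact invocation):

```
{
  "train":      {"r2": 0.9791, "mae": 16.97, "male": 0.0373, "n": 210},
  "validation": {"r2": 0.9506, "mae": 21.39, "male": 0.0432, "n": 60},
  "test":       {"r2": 0.9736, "mae": 21.75, "male": 0.0436, "n": 30}
}
```

R² is the coefficient of determination in label units, MAE the mean
absolute error (cP here), and MALE the mean absolute log₁₀ error used for
viscosity's multi-decade range — 0.044 means held-out predictions are
typically off by about 11%, across labels spanning several orders of
magnitude. Training the other two properties and then

```bash
desgp screen --profiles demo/profiles --models demo/models \
      --mode low --out demo/screen
```

writes all 190 candidate pairs with predicted ρ, η, T_m, uncertainty and
gate flags (`screening.csv`), and the gated, ranked selection
(`selected.json`). `desgp map` projects the 183-D descriptors to a 2-D
probabilistic-PCA chemical-space map and exports property surfaces for
plotting. `desgp benchmark` reproduces the kernel × normalization model
comparison on any dataset.

The same workflow runs on real data: a directory of two-column
sigma-profile text files plus a CSV with columns
`comp1,comp2,comp3,x1,x2,x3,temperature_K,label`.

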