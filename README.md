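# pnndiffusion

Diffusion constants from single-molecule microscopy **without particle
tracking**.

Time-lapse imaging of fluorescently labelled molecules on cell surfaces
(e.g. by TIRF microscopy) yields per-frame tables of detected particle
positions. The standard analysis — single-particle tracking (SPT) followed
by mean-square-displacement regression, MSD = 4DΔt — silently fails when the
particle density ρ becomes comparable to the inverse diffusion area
1/(4πDΔt): indistinguishable neighbours get linked instead of the true
particle and the diffusion constant D is biased low. `pnndiffusion`
estimates D directly from the distance of each particle to its *nearest*
detected point in the subsequent frame, never committing to an identity.

## The model

The nearest point after a lag Δt is either the particle itself, diffused
with survival exp(−Δr²/(4DΔt)), or one of the surrounding particles, treated
as a locally uniform Poisson background of density ρ with survival
exp(−ρπΔr²). The product

    P_nn(r > Δr | ρ, D) = exp(−ρπΔr² − Δr²/(4DΔt))

is the probabilistic nearest-neighbour (PNN) model. Its second moment, the
mean square displacement to the nearest neighbour,

    MSDN = 4DΔt / (1 + 4ρπDΔt),

generalises the MSD (its ρ → 0 limit) and inverts in closed form,
D = MSDN / (4Δt(1 − ρπ·MSDN)). For per-particle local densities ρ_i and for
mixtures of diffusive states (D_s, α_s), D is fitted by maximum likelihood
with an EM algorithm over the latent origin of each nearest neighbour
(background vs. self) and the latent state. A state with D = ∞ absorbs
particles that disappear between frames — false detections, bleaching —
and model order is compared by AIC. Local densities for inhomogeneous data
come from a k-nearest-neighbour estimator pooled over frames.

The package also ships the comparison estimators (nearest-neighbour "local"
SPT, globally optimal one-to-one SPT linking, and PICS — particle image
correlation spectroscopy), a pairwise Monte-Carlo generator with uniform,
Gaussian, annulus and Gaussian-mixture spatial distributions, and a
benchmark harness.

## Worked example

Simulate ten frame pairs of a three-state population — slow (0.2 μm²/s) and
fast (2 μm²/s) molecules in equal shares plus 20% false detections — at a
total density of 1 particle/μm², then fit a three-state PNN model:

```sh
$ pnn simulate --density 1.0 -D 0.2 -D 2.0 --weights 0.5,0.5 \
      --false-fraction 0.2 --seed 11 --out demo.csv
wrote 20 frames (10 pairs), 3920 detections, false-detection share 0.199 -> demo.csv

$ pnn estimate demo.csv --method pnn_multi --states 2 --infinite-state \
      --area 0,0,10,10 --seed 0 --out report.json
method=pnn_multi D=[0.1953, 1.92, inf] um^2/s weights=[0.426, 0.375, 0.198] \
n_obs=996 iterations=158 converged=True
```

The 996 particles inside the 10×10 μm area of interest recover the two
diffusion constants (0.195 vs 0.2, 1.92 vs 2 μm²/s) and the false-detection
share (0.198 vs 0.2, reported as the weight of the infinite-D state). For
comparison, a single-state fit of the same data returns D = 2.05 μm²/s with
AIC = −377 against −888 for the three-state model, so AIC prefers the
mixture. Each particle can then be labelled with its most probable state for
3D time-course visualisation:

```sh
$ pnn assign demo.csv --model report.json --area 0,0,10,10 --out assigned.csv
state counts: 1: 511, 2: 368, 3: 117
```

The same machinery is available as a scikit-learn-style estimator on
records of (Δr, ρ):

```python
from pnndiffusion import (SimScenario, make_pairwise_dataset,
                          build_record_table, PNNEstimator)

dataset, truth = make_pairwise_dataset(SimScenario.uniform(1.0, seed=11))
records = build_record_table(dataset, density_mode="uniform")
est = PNNEstimator(n_states=2, noise_state=True, dt=0.02,
                   random_state=0).fit(records[["delta_r", "rho"]])
est.diffusion_constants_   # ascending, infinite-D state last
est.weights_               # mixture weights, sum to 1
est.predict(records[["delta_r", "rho"]])  # per-particle state labels
```

A density benchmark across estimators (box plots of replicate estimates):

```sh
pnn benchmark --densities 0.1,1,10 --estimators pnn,local_spt,global_spt,pics \
    --replicates 20 --seed 1 --out bench.csv --plot bench.png
```

At ρ = 10/μm² the local-SPT mean falls to ≈0.3 μm²/s while PNN stays within
a few percent of the true 1 μm²/s.

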