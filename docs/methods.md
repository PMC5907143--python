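# Methods

## The model

Single-molecule time-lapse microscopy (e.g. TIRF) yields, after spot
detection, a table of particle positions per frame. The classical route to a
diffusion constant — link detections into trajectories (single-particle
tracking, SPT) and regress the mean square displacement (MSD = 4DΔt in 2D) —
breaks down when the particle density ρ becomes comparable to the inverse
diffusion area 1/(4πDΔt): indistinguishable neighbours get linked in place of
the true particle, and D is biased low.

`pnndiffusion` instead models the distance Δr from each particle in a frame
to its *nearest* detected point in the subsequent frame, without deciding
which point that is. Two independent mechanisms can produce the nearest
point:

* the particle itself, diffused for one lag: P_dif(r > Δr) = exp(−Δr²/(4DΔt));
* some background particle, treated in mean field as a locally uniform
  Poisson field of density ρ: P_bg(r > Δr) = exp(−ρπΔr²).

Their product is the nearest-neighbour survival function, and its second
moment — the mean square displacement to the nearest neighbour (MSDN) —

    MSDN = 4DΔt / (1 + 4ρπDΔt) ≤ MSD,

inverts in closed form, D = MSDN / (4Δt(1 − ρπ·MSDN)). The MSDN saturates at
1/(ρπ) for large Δt; beyond that point the data carry no information about D
and the closed form raises instead of extrapolating.

For per-particle densities ρ_i and for mixtures of diffusive states the fit
is by maximum likelihood with EM over two latent variables: q (nearest point
is background vs. the particle itself) and s (the diffusive state, with
constant D_s and weight α_s). A state with D = ∞ represents particles that
disappear between frames — false detections, bleaching, internalisation. It
is implemented as the analytic limit (its diffusion survival factor is 1 and
its q = 1 branch vanishes), never as a large finite D, which would
ill-condition the M-step. Model order can be compared by AIC = 2k − 2 log L,
where k counts the finite diffusion constants plus M − 1 free weights; the
infinite state's D is fixed by construction and is not a parameter.

One published form of the multi-state posterior carries an ambiguous state
subscript (a summed index appears where the free index is expected); we use
the self-consistent reading — each state's own D inside its numerator — which
is the only variant that keeps EM monotone.

## Parameters that matter

| parameter | unit | default | why |
|---|---|---|---|
| `dt` | s | 0.02 | typical single-molecule frame interval (20 ms) |
| `margin` | μm | data-driven, 3·√(4·D̂·Δt) | width of the halo around the area of interest searched in the subsequent frame; D̂ from the closed-form estimator. Edge particles then find their true nearest neighbour; the estimate depends on this only weakly |
| `n_restarts` | – | 5 | the multi-state likelihood is multimodal; restarts jitter the initial D's log-normally (σ = 0.5) |
| `tol` | – | 1e-8 | relative log-likelihood change declaring convergence; 500 iterations cap |
| `init_D` | μm²/s | MSD guess spread ×10^±1 | the MSD estimator is the ρ→0 limit of the model, a decade either side covers well-separated states |
| k-NN `correction` | – | `unbiased` | see below |

Initialisation and restarts are the package's own choices; the likelihood
and update rules are the model's.

## Density estimation

Every record needs a local density ρ_i for the background term. Three modes:

* **uniform** — subsequent-frame count inside the area of interest divided
  by its area (the frame in which neighbours are sought is the one whose
  density matters). Per-pair counts are used; pooling across pairs changes
  results negligibly.
* **knn** — for inhomogeneous data. The subsequent frames of all *other*
  pairs are merged; with k = number of merged frames, the density at x is
  (k−1)/(N_merged·π·d_k(x)²), rescaled by the pair's own subsequent-frame
  count. Merging buys a k-fold variance reduction at the length scale of a
  single nearest neighbour within one frame. The (k−1) numerator is chosen
  over the plug-in k because λπd_k² is Gamma(k,1) for a Poisson background
  and E[1/Gamma(k,1)] = 1/(k−1): the plug-in form overshoots by k/(k−1)
  (+12.5% at the default ten pairs), which would leak straight into D. The
  plug-in variant remains available as `correction="plugin"`.
* **theoretical** — a known density field (e.g. the generator's own), for
  separating density-estimation error from estimation error in benchmarks.

No edge correction is applied; benchmarks evaluate inside an interior area
of interest. Densities are evaluated at the preceding-frame particle's
position.

## The synthetic-data generator

`SimScenario`/`make_pairwise_dataset` emulate the pairwise benchmarking
protocol: every frame pair is an independent experiment. Positions are drawn
from a spatial distribution (uniform rectangle, isotropic Gaussian, annulus,
or Gaussian mixture); the subsequent frame displaces each particle by a
Gaussian step of per-axis variance 2DΔt, with the state of each particle
drawn from the mixture weights. False detections are extra points drawn
independently per frame from the same spatial distribution; the configured
fraction f is the share of *all* detections, so round(f/(1−f)·n_true) points
are added per frame.

Defaults are the standard benchmarking conditions: Δt = 20 ms, 10 pairs per
experiment, a 10×10 μm area of interest, densities on a 0.1–10 /μm² grid,
f = 20% where false detections are studied, and (for the three-state
scenario) false detections at 20% with the remaining population split
equally between the slow (0.2 μm²/s) and fast (2 μm²/s) states. Uniform
scenarios sample a window padded by five diffusion lengths √(4·D_max·Δt)
beyond the area of interest so the density stays uniform after the diffusion
step.

What the generator does **not** emulate: localisation error (positions are
exact, so no diffraction-limited convolution of the displacement kernel),
photophysics (blinking, bleaching kinetics), motion blur, drift or
confinement, state interconversion within a lag, and temporal correlation
across pairs (each pair is regenerated; `simulate_trajectories` provides a
persistent-position time course for multi-lag MSDN checks only). Passing
tests therefore validate the estimator under its own assumptions — detection
is solved and motion is free Brownian — not robustness to optics-induced
artefacts.

## Baselines

* **Local SPT**: each particle links to its nearest subsequent-frame
  detection, conflicts allowed; D then comes from the 2D Brownian MLE
  ΣΔr²/(4NΔt). Severely biased low once ρ approaches 1/(4πDΔt).
* **Global SPT**: conflict-free linking minimising total squared
  displacement. We solve the assignment exactly (Hungarian algorithm on the
  distance-capped cost matrix) rather than by greedy hill climbing with
  pairwise swaps: 2-exchange descent on an assignment problem can stall in
  local optima (optimality requires alternating cycles of arbitrary length),
  and the exact optimum is cheap at these problem sizes. `max_distance`
  forbids long links; by default both linkers search the margin-expanded
  halo around the area of interest, since clipping the subsequent frame to
  the bare area of interest forces spurious long links for edge particles.
* **PICS**: the empirical cumulative cross-frame correlation — mean number
  of subsequent-frame detections within l of a preceding particle — fitted
  with A(1 − e^{−l²/(4DΔt)}) + ρπl² by unweighted least squares over the
  whole curve at once. Bin size defaults to 0.02 μm; the fit range defaults
  to three background nearest-neighbour scales 3/√(ρπ), capped by the halo
  of data available beyond the area of interest (counts truncated by the
  field edge would otherwise corrupt the quadratic term). No diffraction
  correction is implemented.

## Numerical choices

* All mixture computations run in log space (`logsumexp`); the q = 1 branch
  of the infinite-D state is −∞ exactly.
* Records with Δr = 0 are rejected with guidance (log Δr enters the
  likelihood; exactly coincident detections indicate duplicates upstream).
* A state whose responsibility Σ_i p(q=1, s) vanishes keeps its previous D,
  and the fit is flagged `degenerate_`.
* Nearest-neighbour queries use an exact k-d tree; ties resolve to the
  lowest index.
* States are reported sorted by ascending D, the infinite-D state last.
* The EM stopping rule compares the log-likelihood change against
  tol·max(1, |log L|); at default tolerance the single-state fixed point
  agrees with the closed-form estimator to ~1e-8 relative, and with an
  effectively-zero tolerance it reaches the floating-point fixed point.

## Benchmark sizes and observed behaviour

The test suite and `scripts/acceptance.py` rerun the benchmark at desk
scale: 50 replicates for single-state recovery and false-detection-weight
recovery, 100 replicates (the standard replicate count for this protocol)
for the three-state scenario, ~1e5 records for the distribution-level
survival check (99.9% Dvoretzky–Kiefer–Wolfowitz band). At the default
three-state conditions (~1 250 records per replicate) the fast state is
weakly identified against the disappearing-particle state — the two compete
for the long-distance tail — so single-replicate estimates of the fast D
scatter widely (sd ≈ 0.7 μm²/s) and their mean carries a small upward
finite-sample bias (~+5–8%); the slow state is recovered essentially
unbiased. This is a property of the maximum-likelihood estimator at this
data size, not of the optimiser (fits converge, restarts agree).

## Known limitations

* The mean-field background assumes surrounding particles are Poisson with
  a locally constant density; strong small-scale clustering violates this.
* No localisation-error model: at displacement scales comparable to the
  localisation precision, D estimates absorb the error variance.
* The closed-form and EM estimators condition on a nearest neighbour
  existing; preceding particles with an empty search region are dropped and
  counted (negligible at the densities considered).
* k-NN density estimation needs at least three frame pairs (k ≥ 2 merged
  frames) in unbiased mode.
* State interconversion within a lag is not modelled; states are assumed
  frozen over Δt.
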