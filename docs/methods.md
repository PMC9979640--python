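# Methods

## Forward model

The stationary extracellular proton field is a superposition of monopole
point sources,

    c(r) = c0 + Σᵢ uᵢ / (4πD |r − rᵢ|) + U · G_B(r),

evaluated with positions in μm, D in μm²/s, native fluxes in mol/s and
concentrations in mol/L (an explicit 10¹⁵ μm³/L factor lives inside the
kernel). pH = −log₁₀ c. The model rests on three assumptions: (i)
stationarity within a frame — diffusion across a 500 μm field equilibrates
in seconds while frames are 10 min apart; (ii) truncation of the multipole
expansion at the monopole term, so each cell is characterized by one net
flux (separate import/export routes or intracellular shuttling would need
higher-order terms and far denser probing); (iii) planar observation of a
three-dimensional diffusion field — cells and probes sit in the z = 0
plane but the kernel is the 3D Green function (1/r, not log r). The
field is checked against an independent finite-difference solve of the
radial Laplace operator and against the 7-point discrete Laplacian (the
in-plane restriction of a 3D monopole is not harmonic under a 2D 5-point
stencil, so the 3D stencil is the meaningful test).

Two regularizations of the idealized point-source model:

* **Background c0.** A pure superposition of monopoles decays to zero far
  from the cells, but the far field must be the medium's concentration, so
  an additive per-frame constant c0 is included. At inference time c0
  defaults to the concentration of the median probe pH of the frame
  (sources of either sign perturb roughly half the probes each way);
  it can be fixed explicitly when known.
* **Distance clamp.** Probe–cell distances below 5 μm (the cell radius;
  cells are ~10 μm disks) are clamped to 5 μm: the monopole diverges as
  r → 0, and the clamp encodes finite cell size. Exactly coincident
  positions are a hard error naming the pair.

The boundary flux U is discretized as n = 64 virtual sources equally
spaced along the frame perimeter, each carrying U/n; the boundary kernel
column is their average monopole kernel. Far from the frame this reduces
to a single monopole of strength U.

### Units

Native fluxes (mol/s) convert to the reporting unit mmol/gdw/h by
×3.6×10⁶ (mol/s → mmol/h) and ÷5×10⁻¹⁰ g (0.5 ng dry weight), i.e.
1 mmol/gdw/h = 1.3889×10⁻¹⁶ mol/s. All user-facing fluxes, thresholds and
priors are in mmol/gdw/h; the inference layer folds the conversion into
the kernel so the sampled state is O(1).

## Inference

Per frame, χ²_t = Σ_μ (pH_μ − pĤ_μ(u))²/σ_μ² + λ₁ Σ_{i=1..N} uᵢ² (the
boundary flux is unpenalized, following the index range of the prior
term). Frames couple through λ₂ Σ (uᵢ(t+1) − uᵢ(t))² over tracked cells
and λ₃ Σ_t (ū(t) − u_b(t))² against the bulk efflux. Any flux vector that
predicts a non-positive concentration at a probe has infinite cost.

* **Posterior temperature.** The data term sums r²/σ², so the Gaussian
  measurement model has density exp(−χ²/2); the sampler targets
  exp(−χ²_tot/2). This is what makes the 68% credible intervals cover at
  their nominal rate (sampling exp(−χ²) would shrink every interval by
  √2 and drive coverage to ~52%). The MAP, an argmin, is unaffected.
* **Warm start.** The pH prediction is linearized around the current
  expansion point, turning the cost into a coupled ridge regression; the
  quadratic is solved by block coordinate descent over frames (each frame
  a dense Cholesky solve, neighbours fixed) iterated to a fixed point,
  with a halving line search on the exact cost guarding each Gauss–Newton
  step. Verified to reach the exact joint quadratic optimum.
* **λ defaults.** λ₁: generalized cross-validation on the linearized
  problem at u = 0 (ridge applied to all columns for the selection only).
  λ₂ = λ₁/10. λ₃: chosen so the bulk term starts at ~10% of the
  warm-start data misfit, 0 without bulk data. All overridable; when the
  generative process is known (synthetic studies) the matched values are
  λ₁ = 1/(T σ_u²) per frame for a near-constant series of stationary
  variance σ_u² observed over T frames, and λ₂ = 1/(1 − ρ²) for AR(1)
  dynamics with per-frame correlation ρ.
* **Sampling.** Metropolis–Hastings with per-frame block proposals
  preconditioned by the warm-start Gauss–Newton Hessians (the
  over-relaxation that tames ill-conditioned directions). Step scales
  adapt toward ~30% acceptance during burn-in only and are frozen for the
  recorded chain, preserving detailed balance. Acceptance rates outside
  [1%, 99%] are flagged in the diagnostics.
* **Annealing.** The MAP search runs the same block moves on χ²/T with
  geometric cooling (default T: 100 → 1, factor 0.95, 200 sweeps per
  temperature) and returns the best configuration ever visited, so it can
  never end worse than the warm start. The chain minimum is also checked.
* **Credible intervals.** Central chain quantiles at the requested level
  (default 68%), 1σ errors from the chain standard deviation. Intervals
  are anchored to contain the MAP (the annealed optimum can sit slightly
  off the chain quantiles in finite chains).
* **Tracking.** Greedy mutual-nearest-neighbour matching between
  consecutive frames with a 30 μm displacement gate (~3× the typical
  10-min migration step); the λ₂ penalty applies only within tracks, so
  cells appearing or disappearing incur no penalty at track ends.
* **Bulk efflux.** Bulk pH converts to [H⁺], is differentiated by central
  finite differences, scaled by the medium volume (default 1 mL) and
  divided by the cell count.

## Exchange network

A proton released by donor i (uᵢ > 0) is absorbed by acceptor j
(u_j < 0) with probability proportional to |u_j|/d_ij (absorption
probabilities solve the Laplace equation, hence decay with distance; the
exponent on d_ij is configurable, default 1). Pairwise fluxes

    F_ij = uᵢ · (|u_j|/d_ij) / Zᵢ,   Zᵢ = Σ_{k: u_k<0} |u_k|/d_ik

conserve each donor's flux exactly (Σ_j F_ij = uᵢ, pre-threshold). The
boundary flux never enters the network; the per-frame difference between
total export and total import is reported as leakage — the acidification
that spills into the bulk. Edges survive a threshold strictly above
0.5 mmol/gdw/h (the sensitivity scale); degrees, components and the
degree histogram with its same-mean Poisson null are computed on the
undirected projection (in/out degrees are also exported). These summaries
are provably non-increasing in the threshold, and the network is exactly
covariant under a joint rescaling of fluxes and threshold.

## Synthetic study conditions

The generator emulates the target experimental regime: up to 100–200
cells and a comparable number of static probes in a 500 μm square field,
36 frames at 10 min spacing. Defaults, chosen once:

* **Background medium pH 6.5** (c0 = 10⁻⁶·⁵ mol/L). An acidified
  tumor-microenvironment value; it is also near the highest background at
  which a sign-balanced ensemble of ~1 mmol/gdw/h importers is physically
  representable by the linear monopole model (at physiological pH 7.4 the
  implied uptake would exceed what diffusion can supply).
* **Flux scale.** Typical |u| = 1 mmol/gdw/h; hubs at 100×; additive
  jitter floor ~0.05 — spanning three orders of magnitude.
* **Temporal dynamics.** Stationary AR(1) per cell with per-frame
  correlation ρ = 0.999: consecutive-frame changes of a few percent,
  matching the slow evolution of the pH landscape that motivates the
  temporal penalty. Scenario envelopes (hub decay in `crossover`) are
  deterministic multipliers on top.
* **Scenarios.** `uniform` (zero-mean Gaussian), `dipoles` (±a pairs
  placed 15–35 μm apart), `hubs` (5% exporters at ~100×), `crossover`
  (hub amplitudes decaying with time constant n_frames/4 over a dipole
  background).
* **Geometry.** Cells ≥ 10 μm apart (rejection sampling; overpacking is
  an error reporting the feasible maximum), performing a reflected random
  walk of 3 μm per frame. Probes uniform, ≥ 5 μm from frame-0 cells,
  static thereafter (sensors are immobilized in the scaffold).
* **Noise.** Probe pH = forward prediction + N(0, 0.02); the recorded
  per-probe σ equals the generating value (10⁻⁴ floor when generating
  noise-free data). Every noise draw is stored, so readouts are exactly
  prediction + recorded noise.
* **Positivity guard.** The linear superposition has no saturation, so an
  importer close to a probe could push the predicted concentration
  negative, which real (diffusion-limited) uptake cannot. Where a probe
  concentration would fall below 5% of c0, the importing cell most
  responsible is capped — its whole time series scaled down — until the
  field is physical everywhere. The per-cell factors are recorded. This is
  a local, deterministic rule; it leaves the rest of the ensemble intact.
* **Bulk series.** u_b(t) is the mean ground-truth flux per frame (plus
  optional observation noise); the bulk pH trace integrates the total
  native efflux into the configured medium volume.
* Cell-type labels are assigned at random with no flux dependence.

What the generator does **not** emulate: image segmentation errors and
probe calibration drift, buffering chemistry, probe σ heterogeneity, cell
division/death (cell count is constant), and saturating transport
kinetics beyond the capping rule. Passing the synthetic round-trip
therefore validates the inverse machinery under a well-specified forward
model; it does not bound the additional systematic errors real imaging
pipelines introduce.

## Problem sizes and checks

The test suite and the acceptance script use desk-scale instances chosen
to exercise every claim: forward-model agreement (<1%) against a 20 000
node radial finite-difference solve; recovery on `uniform` at 50 cells /
50 probes / 10 frames / σ = 0.02 (median Pearson r over three seeded
replicates; the exact linear-Gaussian Bayes estimate on the same data
reaches r ≈ 0.90, so the implementation operates at the information
ceiling of these conditions); MAP agreement within 1% per component with
a derivative-free minimizer of the exact cost on a 3-cell instance;
posterior calibration over 50 replicates (68% intervals, residual
fractions); 1000-case network conservation at machine precision;
threshold monotonicity and exact scale covariance; the crossover trend at
100 cells / 18 frames (Spearman of max degree and LCC vs time strongly
negative); and the heavy-tail contrast of the hub scenario versus i.i.d.
Gaussian data.

## Known limitations

* Recovery degrades for cells far (≳ 2× the mean probe spacing) from
  every probe; their posteriors shrink toward the prior, as they should.
* The monopole truncation cannot separate import and export occurring
  simultaneously on one cell, nor resolve which transport route carries
  the flux.
* The median-pH c0 estimate biases slightly when exporters and importers
  are very unbalanced; supply c0 explicitly in that case.
* The exchange network is a redistribution model consistent with the
  inferred monopole fluxes, not a tracer measurement: Z-normalization
  enforces donor conservation but ignores multi-absorber competition
  beyond the pairwise weights.
* GCV calibrates λ₁ on the linearized problem; for strongly nonlinear
  (hub-dominated) fields it tends to over-smooth faint cells.
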