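# Methods

This note documents the models and procedures implemented in `mam`, the
choices made where the construction left freedom, and what the desk-scale
fixtures do and do not show about the full-scale system.

## Network model

Neurons are leaky integrate-and-fire with exponential postsynaptic currents:

    tau_m dV/dt = -(V - E_L) + R I_s(t),   tau_s dI_s/dt = -I_s + inputs,

with an absolute refractory clamp at V_r.  Defaults (units in parentheses):
tau_m = 10 ms, tau_r = 2 ms, tau_s = 0.5 ms, C_m = 250 pF, V_r = E_L =
-65 mV, theta = -50 mV.  Excitatory weights are Gaussian with mean J such
that the peak PSP is 0.15 mV (J = 87.8 pA in closed form) and SD 0.1 J;
inhibitory weights are -g J (g = 11 by default); the intra-areal 4E -> 2/3E
projection is doubled.  Delays are Gaussian (SD = mean/2), local means
1.5 ms (E) and 0.75 ms (I), inter-area means s / v_t with v_t = 3.5 m/s;
draws below 0.1 ms are redrawn and all delays are rounded to the 0.1 ms grid.

Population sizes are neuron density x layer thickness x patch area (1 mm^2),
rounded half-to-even (unbiased across many populations).  Local indegree
blocks rescale a reference laminar microcircuit template by one area-specific
factor, preserving every indegree ratio; the default factor is
(template density / area density), expressing constant synaptic volume —
indegree inversely proportional to neuron density.  External drive is an
independent Poisson process per neuron at rate k_ext * nu_bg (nu_bg =
10 spikes/s) and weight J.  Within an area k_ext is uniform except for the
deep-layer boost: K_ext,5E = kappa K_ext, and K_ext,6E = [1 + (10/3)(kappa-1)]
K_ext.  The 6E rule is the unique linear form anchored at (kappa, ratio) =
(1, 1) and (1.15, 1.5); only the anchors are given by the construction, the
linearity is this package's reading and is exposed as `kappa_ratio_6e`.  In
areas lacking layer 4 the 2/3E and 5E drives get a further 20% to compensate
the missing granular input.  Cortico-cortical weights onto excitatory targets
scale with chi, onto inhibitory targets with chi_I * chi; chi = 1 forces
chi_I = 1, and chi > 1 defaults to chi_I = 2.

### Synthetic connectome generator

Real tracing databases are out of scope; `synth_connectome` emulates the
construction regularities instead, so that everything downstream can be
exercised on realistic structure.  Per area list (n_areas >= 2):

- architectural types span 8..2 evenly; type-2 areas lack layer 4;
- neuron density increases linearly with type over 35k–80k /mm^3 (layer 4
  denser by 25%); the per-neuron synapse budget scales inversely with
  density from a 9,500-synapse baseline, so total indegree *decreases* with
  type (V1-like areas lean, TH-like areas synapse-rich);
- inter-area distances are sampled uniformly on 5–60 mm and inter-area
  connection strength decays as exp(-0.19 /mm x s) (the exponential distance
  rule), spanning several orders of magnitude across the sampled range;
- the supragranular-origin fraction (SLN) is logistic in the source-minus-
  target architectural-type difference (slope 1, midpoint 0, configurable):
  feedforward-like projections originate in 2/3E and target layer 4,
  feedback-like ones originate in 5E/6E and target extragranular layers; the
  target pattern is an SLN-weighted blend of the two motifs, with equal
  indegree for E and I neurons within a target layer;
- the external budget completes each area's total to its synapse budget and
  is distributed by the kappa rule (default kappa = 1.125).

The budget split defaults to 35% external and 15% cortico-cortical, leaving
half of the synapses local.  Distances, and hence delays, are the only
sampled quantities; the generator is bit-reproducible from its seed.

### Downscaling

Fixtures preserve *indegrees*, not connection probabilities, when shrinking
population sizes; `indegree_scale` optionally thins all indegrees with the
variance-compensating weight rescale J -> J / sqrt(scale).  This keeps input
fluctuations comparable but enlarges individual PSPs (0.67 mV at the default
scale 0.05), which weakens the diffusion approximation — the documented,
deliberate distortion of downscaling.  Tests that check mean-field agreement
tightly therefore use the *downscale-safe* balanced network
(`make_balanced_ei`, unscaled 87.8 pA weights), where 10 s simulated rates
match theory within a few percent; the multi-area fixture at compensated
weights deviates by ~10-20% and is used for structural and workflow checks.

## Simulation scheme

Subthreshold dynamics are propagated exactly: the one-step map of (V - E_L,
I_s) is the closed-form matrix exponential of the coupled linear system.
Spikes are delivered at step boundaries after their delay (ring buffer);
threshold detection happens after propagation within a step; during
refractoriness V is clamped at V_r while I_s keeps evolving, so the minimum
inter-spike interval is tau_r + h.  External input is realized as per-step
Poisson-distributed counts times J — statistically identical to individual
events at grid resolution and far cheaper.  Membrane potentials start
uniformly in [V_r, theta) (seed-controlled); the construction itself does not
fix initial conditions.

Randomness: synapse drawing uses one child stream per ordered population pair
(spawned from the master seed), so a pair's realization is independent of all
others; the simulation loop runs single-threaded with one seeded generator,
which makes runs bit-reproducible without per-neuron counter-based streams.
Weights with the wrong sign and delays below the floor are redrawn
iteratively until in range (the alternative — one redraw then clipping — is
not distinguishable at the published parameters, where wrong-sign draws are
10-sigma events).

## Mean-field theory

Stationary rates solve nu = Phi(nu) with the Siegert function evaluated
between the reduced bounds (V - mu)/sigma shifted by gamma sqrt(tau_s/tau_m),
gamma = |zeta(1/2)|/sqrt(2) (synaptic-filtering correction to linear order in
tau_s/tau_m).  The unit convention — the one genuinely open choice — takes
the weight entering mu and sigma^2 as the membrane-potential jump of one
spike through an exponential PSC, J_hat = tau_s J / C_m (0.176 mV for
87.8 pA):

    mu_i = tau_m sum_j K_ij J_hat_ij nu_j + tau_m k_ext,i J_hat_ext nu_bg,
    sigma_i^2 likewise with J_hat^2.

This convention is validated against simulation: a single neuron under
matched Poisson drive fires within ~1% of the predicted rate across
1–40 spikes/s.

Numerics.  The integrand e^{x^2}(1 + erf x) equals erfcx(-x) for x <= 0 and
2 e^{x^2} - erfcx(x) for x > 0.  The exponential part integrates exactly via
the Dawson function; the erfcx part uses a degree-320 Chebyshev
antiderivative on [0, 30] (asymptotic series beyond), giving ~1e-13 relative
accuracy against 40-digit quadrature.  For upper bounds beyond 25 the rate is
assembled in log space and underflows cleanly to zero instead of overflowing.
sigma = 0 falls back to the deterministic LIF rate.

Fixed points are found by exponential-Euler integration of dnu/ds =
Phi(nu) - nu (step 0.1 in dimensionless pseudo-time) until the residual
max|Phi(nu) - nu| falls below tolerance; because the max-norm residual is not
strictly monotone along the flow, a trajectory is only frozen once it is 20x
below tolerance.  Distinct fixed points are deduplicated at relative
L-infinity distance 1e-3 (relative to max(1 spike/s, rate scale)).  When two
or more fixed points coexist, the smallest-mean-rate one is labeled LA and
the largest HA.  Local stability uses the analytic Jacobian

    G_ij = dPhi_i/dmu_i tau_m K_ij J_hat_ij + dPhi_i/dsigma_i^2 tau_m K_ij J_hat_ij^2,

whose entries match central finite differences to < 1e-6.  Global stability
of the LA point is the fraction of initial rate vectors, i.i.d. uniform on
[0, 200] spikes/s (the construction says only "random"), converging to it.

### Bistable toy network

`make_toy_bistable` is a 400E/100I network (K_EE = 240, K_EI = 35, K_IE =
190, K_II = 30, g = 5, K_ext = 640/580 at nu_bg = 10) whose mean-field map
has exactly two stable fixed points: a near-silent LA state (~0.04 spikes/s)
and an HA state at ~135/103 spikes/s (verified at generation time).
Multiplying the recurrent E->E weight by an excitation scale erodes the LA
basin (fractions 0.29 / 0.24 / 0.20 at scales 1.0 / 1.15 / 1.3, 300 initial
conditions) and, in simulation, produces a fluctuation-driven transition to
the HA state (scale 1.8 transitions within ~5 s; 2.5 immediately; 1.0 stays
low) — the attractor-landscape phenomenology of the full model at toy scale.

## Analysis suite

Rates are 1 ms spike histograms averaged over a population or area.  The
MISE-optimal Gaussian kernel width is chosen on a log-spaced grid by the
unbiased cost C(w) = n^-2 [sum_{ij} k_{sqrt2 w}(dt_ij) - 2 sum_{i != j}
k_w(dt_ij)], evaluated through the histogram autocorrelation; the kernel is
normalized to unit sum on the grid so smoothing conserves spike count up to
edge effects.  LvR uses the published revised-local-variation formula with
refractoriness constant R = 5 ms by default (0 for the Poisson calibration
tests); it needs at least three spikes and is excluded from averages
otherwise.  Pairwise correlations are Pearson coefficients of 1 ms
single-cell histograms over a seeded subsample (default 2000 neurons with at
least one spike).  Spectra use Welch's method with a boxcar window, segment
1024, overlap 1000 on the 1 kHz grid; series shorter than a segment fall back
to one periodogram with a warning.  Fluctuation phases integrate the PSD up
to 40 Hz in consecutive 10 s intervals; the threshold is an explicit argument
because the published constant presupposes an unstated normalization and
neuron count.  Per-neuron rate distributions exclude neurons below
0.56 spikes/s and subsample across populations by largest-remainder
apportionment (the rounding rule is unstated; largest-remainder is exact in
total and deterministic).

Temporal hierarchy.  Lags come from cross-covariances of area rates smoothed
with a 2 ms Gaussian; candidate extrema are found after additional smoothing
at the 5 ms characteristic width (a smoothing-plus-local-extremum scan rather
than a specific wavelet family, which was a library choice, not an
algorithmic contract) and the largest-|value| extremum within +-100 ms is the
lag.  Sign convention: tau_AB is the extremum location of cov(A(t + tau),
B(t)), so the leading area carries negative lags toward followers and later
areas obtain higher levels.  The level fit minimizes sum |h(A) - h(B) -
tau_AB| over valid pairs; the signed sum printed in the source description is
unbounded below, so absolute deviation is used (squared deviation available).
Least absolute deviations is a linear program and is solved exactly
(HiGHS); "restarts" re-solve under permuted variable orderings and the
objective spread (asserted < 1e-6) documents solver determinism.  Levels are
affinely normalized to [0, 1]; the reported objective is the raw-scale
minimum.  Violations count unordered valid pairs whose lag sign contradicts
the level order (zero lags never violate); surrogates shuffle the
upper-triangle lags, mirror them with a sign flip (preserving antisymmetry)
and re-fit.

Functional connectivity and BOLD.  The area signal is the population-size-
weighted mean of K |J|-weighted source rates convolved with the unit-mass
exponential PSC kernel; FC is the zero-lag Pearson matrix after discarding a
500 ms transient.  The Balloon model drives flow and oxygen metabolism by
gamma-kernel convolutions (k = 3; the kernel order is not printed and k is
configurable; the printed prefactor already normalizes the kernel to unit
integral), integrates deoxyhemoglobin q and volume v with the outflow law
f_out = v^{1/alpha} + tau dv/dt solved explicitly for dv/dt, by fixed-step
RK4 at 10 ms on block-averaged input (hemodynamic time scales are seconds;
the trajectory matches an adaptive solver to < 1e-6), and reports dS/S =
V0 [a1 (1 - q) - a2 (1 - v)] with tau_MTT = 3 s, tau = 10 s, alpha = 0.4,
E0 = 0.4, a1 = 3.4, a2 = 1, V0 = 0.03.  FC clustering optimizes signed
modularity with the Q* weighting (positive weights weighted more strongly
than negative) by greedy agglomeration plus single-node moves over seeded
restarts.

Interactions and paths.  Conditional Granger causality fits, per target, a
VAR with 25 lags of the target and of every eligible source (eligible:
> 1 synapse per target neuron, strictly) by OLS, and flags a source when
Levene's test (mean-centered; median-centering available) declares the
residual variances of the full and the source-omitted fit different at
p < 0.05 (no multiple-testing correction by default, matching the per-pair
rule; BH-FDR available).  A calibration caveat is documented in the
limitations below.  The gain matrix evaluates K |J| and K J^2 against the
mean-field slopes at supplied rates; dividing by Re(lambda_max) places the
leading eigenvalue at criticality, and Bellman–Ford on d = log(1/w) distances
(negative for w > 1; negative cycles detected and reported) yields dominant
paths whose distances are minus the log of the path weight product.

## Problem sizes used by the tests

Simulations in the suite are 10 s of biological time on networks of 2–2.3k
neurons (the 4-area fixture and the balanced E-I network) plus a 100 s
single-neuron run; mean-field basin estimates use 300–10,000 initial
conditions; Granger calibration uses 500 null tests at T = 3 s and planted
recovery 100 replicates at T = 50 s of 1 ms samples.  These sizes were chosen
so the whole suite completes in minutes while keeping every statistical
assertion at 3-sigma or better.

## Known limitations

- The desk-scale fixtures cannot reproduce full-scale quantities (overall
  mean rate, FC correlation against experimental fMRI, published violation
  counts): those depend on the 4.13-million-neuron connectome and on
  experimental comparison data.  What the tests do show is that every
  operation is correct against independent oracles and that the qualitative
  attractor phenomenology survives downscaling.
- The Levene-based Granger significance test is strongly conservative under
  the null: the residual samples of the nested fits are computed on the same
  data and are nearly identical, which deflates the between-group statistic
  (measured type-I error ~0 at alpha = 0.05 over 500 null tests).  Detection
  of strong planted edges is nonetheless reliable (100% at coefficient 0.5,
  T = 50k samples, with no reverse-direction false flags).  Interpret
  significant pairs as a high-precision, low-recall set.
- The synthetic connectome reproduces construction *regularities*, not the
  published matrices; analyses of its output characterize the pipeline, not
  macaque anatomy.
- The Balloon-model input is in arbitrary units; drives of order one are
  assumed (the pipeline normalizes by the series maximum).  Strongly larger
  drives leave the physiological regime and are rejected rather than
  integrated.
- tau_m = tau_s is rejected rather than special-cased (it cannot occur with
  the default parameters).
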