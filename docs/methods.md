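# Methods

This note records the model, the numerical and statistical choices, and
what the synthetic generators do and do not emulate. Nothing here states a
number that the test suite or `scripts/acceptance.py` does not itself
compute.

## Ionic model

The reduced Fenton–Karma model describes a cardiac cell by a dimensionless
potential `u` and two gates: `v` (availability of the fast inward,
sodium-like current) and `w` (availability of the slow inward,
calcium-like current). The currents are

- `J_fi = −g_fi · v · H(u − u_c) · (1 − u)(u − u_c)` — regenerative
  upstroke above the activation threshold `u_c`;
- `J_so = g_so_rest · u · H(u_c − u) + g_so · H(u − u_c)` — linear leak at
  rest, constant repolarizing drive when activated;
- `J_si = −g_si · w · (1 + tanh(k (u − u_si)))/2` — plateau current gated
  by a smooth step centered at `u_si`.

Conventions that matter and could hide a discrepancy with other write-ups
of the model:

- **Conductance-to-rate mapping.** Currents are written with conductances
  (mS/cm²) multiplying dimensionless driving terms and divided by
  `c_m = 1` µF/cm², so `g` acts numerically as a rate in 1/ms
  (`g_fi = 3` ⇒ upstroke time scale 1/3 ms). This reproduces the tabulated
  magnitudes without introducing the original time-constant symbols
  (τ_d = c_m/g_fi and so on).
- **The ½ in `J_si`** makes its maximum magnitude `g_si · w`. It is
  centralized in one place (`fk._currents` and the fused kernel) should a
  variant without the half be needed.
- **Heaviside tie-break:** `H(0) = 1` — the threshold value counts as
  activated — applied consistently at `u_c` and at the recovery switch
  `u_v`.
- `u` is not clamped; overshoot above 1 is self-limited by the `(1 − u)`
  factor.
- The rest state (0, 1, 1) is quiescent only to ≈1e−9: the tanh tail of
  `J_si` leaves `−g_si(1 + tanh(−k·u_si))/2 ≈ −9e−10` per ms, which the
  resting leak immediately balances. Tests assert |current| < 1e−8 rather
  than exact zero.

Gate dynamics are piecewise-linear in the gate with piecewise-constant (in
`u`) rates; `τ_v⁻(u)` switches between the slow (`τ_v1⁻`) and fast
(`τ_v2⁻`) recovery branch at `u_v`. Gates are integrated by Rush–Larsen
(exponential relaxation toward the local steady state), which is exact for
frozen `u` and keeps gates in [0, 1] unconditionally.

## Tissue solver

Strang composition per step `dt`: half diffusion, full reaction, half
diffusion.

- **Diffusion** is integrated exactly in the half-sample-offset cosine
  basis (DCT-II on the cell-centered grid): mode (i, j) is damped by
  `exp(−D(κᵢ² + κⱼ²) dt)` with `κᵢ = π i / Lx`. This imposes homogeneous
  Neumann boundaries exactly, conserves the spatial mean, and is a
  contraction. The unit system is ms/cm internally; `D` is configured in
  cm²/s (the field's convention) and converted once.
- **Reaction** is itself a symmetric composition: Rush–Larsen half-step on
  the gates at the initial `u`, modified-Euler (Heun) full step on `u` at
  the half-stepped gates, Rush–Larsen half-step at the updated `u`. The
  symmetrization is what makes the overall scheme genuinely second order;
  the asymmetric variant (gates and `u` both advanced from the step's
  start) measures first order in the same Richardson test.
- The fused reaction kernel (numba) short-circuits the saturated tanh tail
  (|k(u − u_si)| > 9.2, where `1 + tanh` is within 2e−8 of its limit);
  this perturbs the gate factor by < 1e−7 relative and roughly halves the
  kernel cost on mostly-resting tissue. The 0D cell path and the tissue
  path share this kernel bit-for-bit.
- Early termination: after the last stimulus, a run stops once
  `max(u) < u_c` has held for 50 ms — all activity has died out. Blow-up
  (|u| > 50, far above physiological overshoot ~1.1) aborts with the
  record flagged invalid.
- Presets: the full-scale domain is 15 × 15 cm at 512² (dx ≈ 0.03 cm),
  dt = 0.1 ms, D = 1 cm²/s. Reduced presets keep dx ≤ 0.06 cm, above
  which wavefronts visibly distort on this model.

## Induction protocol

S1 stimulates a 0.5 cm strip at the left edge (additive `I_stim = 1.0`/ms
for 2 ms — comfortably suprathreshold after diffusive dilution, bounded
well below blow-up). The domain-center cell is monitored every step; when
its `u` falls back through `u_crit = 0.05` after the S1 upstroke — the
waveback has cleared the center — S2 stimulates the whole lower-left
quadrant (the region behind a rightward wave). Directional block at the
quadrant's corner curls into a single rotor near the center. If the center
never depolarizes within a timeout the record is flagged
`no_propagation` and S2 is withheld. The episode continues
`post_induction_T` (8,000 ms at full scale) after S2.

The 0D `single_cell_ap` uses a weaker default stimulus (0.2/ms); in the
space-clamped setting the stimulus is undiluted, and near-threshold
amplitudes make the upstroke latency dt-sensitive. An AP counts as
elicited only when the trace exceeds 0.5 — a regenerative upstroke —
so subthreshold stimulus artifacts do not report an APD.

## Tip tracking and biomarkers

- **Tip detection**: intersections of the iso-potential contour
  `u = 0.5` with the `du/dt = 0` contour (`u(t) − u(t − 2 ms) = 0`),
  located per grid cell by marching-squares segments of both bilinear
  fields and exact segment–segment intersection. Saddle cells are resolved
  with the cell-center sign.
- **Linking**: frame-to-frame Hungarian assignment (minimum summed
  displacement) gated at 0.75 cm; unmatched observations open new tracks.
  Sampling every 1 ms.
- **CV/APD**: first upward `u_crit` crossings of the S1 wave at midline
  markers at Lx/3 and 2Lx/3 (CV), and the first upward-to-downward
  crossing interval at Lx/2 (APD). Measured from the single S1 planar wave
  (no pre-pacing).
- **Spectra**: mean-removed signals, Welch estimate (2,048 ms Hann
  windows, 50 % overlap), analysis band 0.5–30 Hz. DF is the largest-peak
  frequency of the probe-array-averaged spectrum; OI_n is the fraction of
  band power within ±0.5 Hz of the n largest non-overlapping peaks. The
  probe array is a 5 × 5 grid inset 10 % from each edge; its four corners
  double as the corner probes of the no-rotor rule. Probe signals are
  taken from S2 onward; spectra require ≥ 2 s of signal, else null.
- **OI₁** is computed from the x-coordinate of the longest-lived track
  (configurable to y or x + iy); the trajectory coordinate is not uniquely
  dictated by the method, so it is a config choice.
- **Maximum distance**: largest pairwise distance over the trajectory
  after discarding the first 1,000 ms post-formation (stabilization);
  computed exactly (convex hull for long tracks, identical to the O(n²)
  scan).
- **Classification**: fibrillation if ≥ 5 tracks each live ≥ 50 ms;
  no-rotor if propagation failed, any corner probe sees no AP after S2, or
  no track accumulates 2π of winding about its running centroid (one full
  rotation); stable if activity persists to the scheduled end; else
  transient. Classifiers operate on the merged 3-class labeling
  (transient ∪ fibrillation = chaotic) by default.

Nullability is class-dependent: CV/APD are null only when S1 fails;
DF/OI₄ require rotor activity; max-distance/OI₁ are defined for stable
rotors only. At desk-scale episode lengths (2 s post-S2) OI₁ is usually
null because the track itself must span ≥ 2 s.

## Design, campaigns, emulation

- **Variability**: uniform distributions over ±20–50 % of the base values
  per the packaged table (`table1_ranges.json`). The multi-parameter space
  varies eight parameters — three conductances and five gate time
  constants; the resting slow-outward conductance is held at base by
  default (config-switchable to nine), since the analysis focuses on the
  eight properties governing excitability and its recovery.
- **LHS** via `scipy.stats.qmc.LatinHypercube`; one point per marginal
  stratum, seeded. Campaigns derive per-row seeds by hashing
  (campaign seed, row index), are checkpointed row-by-row to CSV, and
  resume deterministically.
- **GP**: inputs affinely normalized to [0, 1]^D, targets standardized per
  (class, biomarker). Linear mean profiled out by GLS; marginal likelihood
  maximized by L-BFGS-B with analytic gradients, 10 restarts drawn
  log-uniformly from l ∈ [0.05, 5], σ ∈ [0.1, 3], σ_n ∈ [1e−4, 0.5]
  (normalized scale). σ_n is fitted — the data are deterministic, but a
  fitted nugget regularizes the fit — with a 1e−8 jitter floor; Cholesky
  failures escalate jitter before erroring. Predictive variance excludes
  the nugget, so it vanishes at training points at the floor and reverts
  to σ² far away. A (class, biomarker) GP requires ≥ 15 non-null rows,
  else the pair is undefined (null predictions).
- **SVM**: RBF kernels; grid search over box constraint
  C ∈ {0.1 … 1000}, kernel scale γ ∈ {0.1 … 30} and coding design
  (one-against-one / one-against-rest), scored by stratified 5-fold CV;
  fold count degrades gracefully (logged) when a class has < 5 members.
- **Baseline**: the unpartitioned comparison trains one GP per biomarker
  on all rows with nulls encoded as −1; the RMSE ratio scores both models
  against the null-coded truth so the comparison is on a common footing.
- **Mean effects**: one N-point LHS over the full space is drawn once and
  shared across all curves and grid values; the varied parameter's column
  is overwritten by each grid value. Sharing λ removes Monte-Carlo noise
  from differences of non-interacting curves (an asserted invariant) and
  makes LHS convergence faster than N^{−1/2} for smooth integrands, so
  the √N error test asserts the plain-MC rate as a floor. Nullable
  outputs are averaged over their non-null support, with the support
  count reported per grid value.

## Synthetic generators (what they do and do not show)

- The spiral-field generator produces rigidly rotating Archimedean
  spirals with singularities at known positions — an exact oracle for tip
  detection, but with none of the wavefront curvature dynamics, meander
  or breakup of simulated tissue.
- Probe-signal generators (tones + seeded noise) give closed-form
  DF/OI expectations; discretization of the peak windows to Welch bins is
  accounted for in the flat-spectrum check.
- The response-surface generators emit datasets with the exact campaign
  CSV schema. The `two_region`/`nullable` kinds place a jump (5× the
  smooth variation) across a curved boundary **with a thin exclusion band
  (half-width 0.08 of the unit cube) around it**: the partitioning method
  presumes behavior regions that are well-separated in parameter space,
  and the band encodes that premise. With ambiguous data straddling the
  boundary, held-out RMSE of *both* emulators is dominated by
  boundary-classification error and the comparison measures boundary
  estimation, not emulation. Passing these tests therefore shows the
  partitioned machinery is correct and superior across clean
  discontinuities; it does not bound classifier error on real campaign
  data, which the scaled campaign test measures separately.

## Problem sizes used by the test suite

Desk-scale study conditions, chosen as the package's own defaults for
one-CPU runs: convergence checks on a 10 cm cable at dx ≈ 0.031 cm →
0.0156 cm; one stable-rotor episode and a 30-episode two-parameter
campaign on the quarter-size 7.5 cm domain at 128² (the coarsest grid
satisfying dx ≤ 0.06 cm) with 2,000 ms post-induction windows and a 21/9
train/test split; emulator tests on 300–400-point synthetic surfaces; the
full 8 × 100 × 100,000 mean-effect budget against an analytic stub. The
full-scale experiments (15 cm/512², 8 s episodes, thousands of episodes)
use identical code paths through the same interfaces.

## Known limitations

- Isotropic 2D monodomain only: no anisotropy, bidomain, 3D or realistic
  geometry; conclusions about boundary-collision behavior are
  domain-size-dependent, and small desk-scale domains bias the class map
  toward no-rotor/transient outcomes.
- The S2 timing/geometry rule (waveback at center, lower-left quadrant)
  is one realization of cross-field induction; other quadrant/timing
  choices produce mirrored rotor chirality.
- Biomarker spectra depend on episode length; desk-scale windows make
  OI₁ and transient-episode DF frequently null.
- The emulator interpolates within the sampled box; extrapolation reverts
  to the GP linear trend and the classifier's nearest regions.
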