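# rotoremu

Rotor-driven re-entry in 2D cardiac tissue: Fenton–Karma monodomain
simulation, spatial biomarkers of arrhythmia, and partitioned
Gaussian-process emulation with mean-effect sensitivity analysis.

## The problem

Functional re-entries (rotors) — spiral waves of electrical excitation
rotating about a phase singularity — underlie tachycardia and, when they
break up, fibrillation. Whether a rotor forms, persists, meanders or
fragments depends sensitively on cell-level electrophysiology: channel
conductances and the time constants of gate recovery. Exploring that
dependence by direct tissue simulation is expensive (one long 2D episode
costs minutes to hours), so `rotoremu` couples the simulator to a
supervised *partitioned emulator* that, once trained on a campaign of
simulated episodes, predicts behavior class and biomarkers anywhere in
parameter space in microseconds.

The package is aimed at computational electrophysiologists and at
statisticians interested in emulating simulators with discontinuous
response surfaces.

## The model and method

**Tissue model.** Monodomain reaction–diffusion on an isotropic 2D sheet,

∂u/∂t = D ∇²u + I_ion + I_stim,

with the reduced three-variable Fenton–Karma ionic model (membrane
potential `u`, fast-inward gate `v`, slow-inward gate `w`; fast inward,
slow outward and slow inward phenomenological currents in the
modified-Beeler–Reuter parameterization). The solver uses second-order
Strang splitting: diffusion integrated *exactly* in a cosine (DCT-II)
basis — which imposes no-flux Neumann boundaries exactly — and reaction by
a symmetrized modified-Euler / Rush–Larsen composition.

**Episodes.** An S1–S2 cross-field protocol launches a planar wave, then
stimulates the quadrant behind its waveback to create directional block
and a single rotor at the domain center. Each episode is classified
(no rotor / stable rotor / transient rotor / fibrillation, the latter two
merged as "chaotic" for classification) and summarized by six nullable
biomarkers: planar CV and APD, tip-trajectory maximum distance, dominant
frequency (DF), and organization indices OI₁ and OI₄.

**Emulation.** Parameter designs are Latin hypercube samples over the
tabulated variability ranges. A multi-class RBF-kernel SVM (hyperparameters
by stratified 5-fold CV) partitions parameter space into behavior regions;
each (class, biomarker) pair gets its own Gaussian process with a linear
mean and Matérn-5/2 ARD covariance

k(θ, θ′) = σ² (1 + √5 r + 5r²/3) exp(−√5 r) + σ_n² δ_{θ,θ′},
r² = Σᵢ (θᵢ − θ′ᵢ)² / lᵢ²,

fitted by maximizing the (profiled) marginal likelihood. Routing
predictions through the classifier avoids smoothing across the sharp
behavioral transitions that defeat a single GP.

**Sensitivity.** Mean effects ȳ(θᵢ) ≈ (1/N) Σⱼ Y(λⱼ, θᵢ) are computed by
Monte-Carlo integration through the emulator with one shared LHS λ-sample
(N = 100,000 by default), averaging nullable outputs over the non-null
support only.

## Worked example

```bash
python examples/02_planar_wave_cv_apd.py
```

prints

```
CV (dx=0.031 cm, dt=0.1 ms) : 37.00 cm/s
CV (halved steps)           : 37.23 cm/s
relative change             : 0.618 %
```

— a planar wave at base parameters conducts at ~37 cm/s, and halving both
integration steps changes the measurement by well under 1 %, the solver's
convergence check. `examples/03_s1s2_rotor_episode.py` induces and
analyzes a full rotor episode; `examples/04_...` and `examples/05_...`
demonstrate partitioned emulation and mean-effect curves. The
`rotoremu` command-line tool exposes the long-running pieces
(`simulate`, `campaign`, `train`, `predict`, `mean-effects`, `fixtures`).

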