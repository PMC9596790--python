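# Methods

`atriasim` simulates electrical impulse propagation in a two-dimensional
sheet of human atrial tissue containing diffusely scattered fibroblasts,
under antiarrhythmic drug block, across a calibrated population of
electrophysiological profiles, and trains classifiers that predict whether a
given (profile, fibrosis, drug) combination conducts or blocks.  This note
records the model, its assumptions, the parameters that matter, the
numerical choices, and what the synthetic fixtures do and do not emulate.

## Cell models

**Myocyte.**  The cardiomyocyte is a human atrial ionic model of the
Nygren lineage, the family from which later Koivumäki-type formulations
descend (the canonical intracellular starting values Na_i = 8.5547 mM,
K_i = 129.43 mM are this family's resting state).  Membrane currents: I_Na
(GHK form), I_CaL, I_t, I_Kur, I_Ks, I_Kr, I_K1, a small-conductance
Ca²⁺-activated K⁺ current I_KCa (Hill activation in [Ca]_i, EC50 0.7 µM),
I_NaK, I_NaCa, I_CaP, background Na/Ca currents and a constant electroneutral
Na influx.  Calcium handling keeps the Nygren compartment structure: a
diffusion-restricted subspace under the L-type channels, cytosol, SR uptake
and release compartments, RyR activation/inactivation, and troponin /
calmodulin / calsequestrin buffers.  Intracellular Na⁺, K⁺ and all Ca²⁺
compartments are dynamic; extracellular concentrations are fixed parameters
(they are population-varied inputs).

The baseline is an *AF-remodelled* variant: I_CaL and I_t reduced, I_K1
increased, SERCA reduced, with the remaining conductances calibrated once so
that the model reproduces the study's stated baseline operating point —
resting potential −79.83 mV, single-cell APD90 ≈ 185 ms at 1 Hz, and a
0%-fibrosis conduction velocity in the 60–75 cm/s band (baseline lands near
69 cm/s).  Because the stated membrane capacitance is 66 pF while the
ancestral formulation is a 50 pF cell, the Na⁺ permeability was raised
(P_Na = 0.004 nL/s) during this calibration so that planar conduction at a
stable explicit time step reaches that CV band.  A side effect is a large
upstroke: the model's AP amplitude (~140 mV above RMP at the single cell) is
higher than typical microelectrode values, so the population-calibration
band for the amplitude biomarker is centred on the model's own baseline
rather than on literature values.  All baseline constants ship in
`atriasim/data/myocyte_baseline.json`.

**Fibroblast.**  The active fibroblast carries four currents — the time- and
voltage-dependent K⁺ current I_Kv, an inward-rectifier I_K1, the Na⁺/K⁺ pump
and a background Na⁺ current — with fixed intracellular concentrations and
C_m = 6.3 pF.  The background-Na conductance is solved analytically so the
uncoupled cell rests at exactly −47.75 mV; the cell is non-excitable (no
regenerative inward current), so sustained depolarizing input produces a
monotone rise to a plateau.

**Gap coupling.**  A myocyte–fibroblast contact exchanges I_Gap, carried
independently by Na⁺ and K⁺ as two ohmic components in the membrane-potential
difference, G_gap = G_gap,Na + G_gap,K = 0.5 nS per neighbour pair (default
split 0.25/0.25 nS, configurable — the split is not constrained by the
study's description; sensitivity to the split is small because the total
conductance drives the electrotonic load).  Both species contribute to the
corresponding myocyte ion budgets, and the current entering the fibroblast
equals the current leaving the myocyte by construction.

## Tissue model

The monodomain reaction–diffusion equation
∂V/∂t = ∇·(D∇V) − (I_ion + I_applied)/C_m is discretized on a regular
nx×ny grid (study size 200×200, dx = 2 cm / 200 = 100 µm) with a 5-point
Laplacian and no-flux outer boundaries.  Diffuse fibrosis replaces
`round(fraction · nx · ny)` uniformly drawn nodes by fibroblasts
(deterministic in the mask seed; one mask per fibrosis level is shared by
all profiles).  Fibroblast nodes do not participate in diffusion — each face
between a myocyte and a fibroblast is a zero-flux face — and couple to each
von-Neumann myocyte neighbour through one I_Gap pair.  Probes for CV sit at
2.5% and 97.5% of the plane side on the central row (columns 5 and 195 of
the full plane, i.e. the 0.5 mm / 19.5 mm convention, 1.9 cm apart),
clamped outside the stimulated edge column on small planes; CV = distance /
activation-time difference, averaged over the last two beats.

**Stimulation.**  The S1 protocol is 4 pulses, 4000 pA/pF, 3 ms, 1 Hz,
applied to the left edge column.  The amplitude is used literally as a
per-capacitance current density on full-size planes; the edge column
transiently overshoots during the 3 ms pulse but the scheme remains stable
and the launched wave is insensitive to the overdrive.  On down-scaled
planes the same per-cell amplitude would recharge the entire domain, so
`StimulusProtocol.scaled(nx)` rescales the amplitude by nx/200, preserving
the full-size protocol's injected charge per unit area.  Isolated cells
(no diffusive sink) are paced at 20 pA/pF.

**Numerics.**  Forward Euler for the membrane potential and concentrations,
Rush–Larsen exponential updates for the gates, in a staggered arrangement:
gates are advanced first and the ionic currents of the step use the updated
gate values.  The plain simultaneous update changes CV by ~1.4% when the
step is halved at dt = 10 µs; the staggered variant reduces that to ~0.4%,
which is why it is the default.  Gate steady states, per-step decay factors
and the GHK exponential are pre-tabulated on a 0.05 mV grid over
[−200, 150] mV and linearly interpolated.  The desk default dt = 10 µs (the
full-scale study step is 1 µs) satisfies the explicit diffusion bound
dt ≤ dx²/4D for the baseline D = 0.0016 cm²/ms; profiles scaling D upward
need a finer step, provided by `NumericsConfig.for_diffusion` (0.9 safety
factor).  The stability bound is checked at start and violations raise
immediately; non-finite states abort the run with the failure time.
Per-node, per-beat AP markers (diastolic minimum, activation = maximum
dV/dt validated by dV/dt > 1 mV/ms plus an overshoot crossing, peak, APD90
end with linear interpolation, repolarization flag) are extracted online
inside the kernel, so biomarkers are independent of the trace recording
stride.  The overshoot criterion defaults to a 0 mV crossing in tissue:
on down-scaled planes the rescaled edge stimulus can passively lift even
remote nodes to about −19 mV when the Na current is almost fully blocked,
while genuine action potentials in this model overshoot far above 0 mV, so
0 mV cleanly separates passive charging from propagation (both thresholds
are configuration; the trace-based analyzer, which never sees that
artifact, uses −20 mV).

## Biomarkers and conduction classification

APD90 runs from the activation time to the crossing of
RMP + 0.1·(peak − RMP).  "Peak" is reported as the AP amplitude
(V_max − RMP); the absolute maximum is stored alongside.  Plane-level
biomarkers average myocyte nodes only over the last two beats.  A run
*conducts* iff, after the final stimulus, the right probe cell both
depolarizes and repolarizes before the record ends — failure to be
stimulated, to conduct, or to repolarize all classify as block.  Drug
effects are quantified as ΔBiomarker = drug − basal per profile, defined
only when both conditions conduct (profiles blocking in either condition are
excluded from delta summaries).  Group statistics (two-sided t-tests,
one-way ANOVA, Kruskal–Wallis, chi-square on conduction proportions, α =
0.05) are wrappers over scipy.stats.

## Population of models

Nine parameters are varied as multiplicative percent modifiers in
[−50%, +100%]: gNa, INaK, gK1, gCaL, gKur, IKCa, D, Ko, Nao (the pump and
I_KCa modifiers act on the current magnitude).  Latin Hypercube sampling
(scipy's `qmc.LatinHypercube`, seeded) places exactly one sample per
equal-width stratum per dimension.  Candidates are simulated on a
0%-fibrosis calibration strip (8×256 default) and accepted iff all four
biomarkers fall inside the shipped acceptance ranges
(`data/biomarker_ranges.json`: APD90 100–350 ms, CV 35–100 cm/s, RMP −90
to −65 mV, amplitude 90–220 mV — an editable, versioned part of the
configuration; the amplitude band is centred on this model's baseline as
discussed above).  Acceptance is deterministic, monotone in range width,
and candidates whose integration fails are rejected with reason "numerical
failure" rather than dropped.  Fibroblast parameters carry no variability.

## Drug model

Single-pore-channel block: G_i = G_0 / (1 + [C_d]/IC50) per target channel.
The shipped table (concentration; IC50 for IKr/ICaL/INa, µM): amiodarone
0.8; 0.9/1.3/4.6 — dofetilide 0.005; 0.002/0.006/0.006 — sotalol 86.3;
2100/2100/2.1.  With these constants sotalol is a near-total Na-channel
block (factor ≈ 0.024), which abolishes propagation; amiodarone and
dofetilide slow conduction.  Block applies to myocyte channels only, is
multiplicative, and therefore commutes with profile scaling.

## Classifiers

Feature rows carry the nine profile modifiers, the three drug conductance
factors (1.0 without drug) and the fibrosis percentage; the label is the
conduction flag.  Four families are trained: polynomial-kernel SVMs of
degree 2 and 3, a decision tree and KNN, each inside a standardization
pipeline.  The data are split stratified 80:20 with the test-set size
floored (e.g. 1032 rows → 826 train / 206 test) and hyperparameters chosen
by 10-fold cross-validation on the training side; all reported metrics
(sensitivity, specificity, PPV, NPV, accuracy — with Wilson 95% intervals —
and ROC AUC from the decision function, uncalibrated) come from the held-out
test set.  Ratios with zero denominators are reported as not-applicable.
Feature importance is reported two ways: (a) the per-feature magnitude of
the signed aggregate of dual coefficient × standardized support-vector
feature value (the linear component of the polynomial expansion, so
uninformative features cancel), and (b) seeded permutation importance on
the held-out split; disagreement between the two top features is flagged.
No class rebalancing is applied.

## Synthetic fixtures

`synthetic_ap_trace` builds AP-like waveforms with exactly known biomarkers
(half-cosine upstroke, so the maximum-slope time is analytic; linear
repolarization placing the 90% crossing exactly APD90 after activation) —
they validate the biomarker extractors, not the ionic model.
`surrogate_ml_dataset` emits feature tables with the study schema and labels
from a known rule (a sodium-availability product rule, or a single-feature
threshold for separability tests) with an optional label-flip rate, so the
Bayes accuracy is known; an exclusion margin around the decision boundary
makes the separable variants genuinely separable.  `toy_plane` bundles a
down-scaled geometry with proportionally mapped probes and the rescaled
stimulus.  Fixtures share the production schemas and validators.  What they
do not emulate: realistic fibrosis textures (only uniform random masks),
beat-to-beat variability, and any correlation structure between profile
parameters — passing fixture-based tests validates the machinery, not the
physiology of real atria.

## Desk-scale problem sizes

The full study (200×200 plane, 1 µs step, 500 LHS candidates, ~10³ tissue
simulations) was designed for GPU hardware.  The package's default test and
reproduction sizes are chosen for a single CPU: toy planes of 14–24 nodes
per side with 2 beats, calibration strips of 4×40–48 nodes with 2–3 beats,
LHS populations of ~24 candidates, and surrogate classifier datasets of
~1500 rows.  `scripts/acceptance.py` runs the whole pipeline at these sizes;
every stage scales up by configuration only (geometry, pulses, candidate
count), not by code changes.

## Known limitations

- The myocyte is a calibrated Nygren-family formulation, not a line-by-line
  port of the study's exact supplementary code; quantitative biomarkers
  (notably AP amplitude) differ even though the calibrated operating point
  (RMP, APD90, CV band) and every direction-of-effect match.
- Fibroblasts replace myocytes at masked nodes (cell-per-node); the
  alternative composite-node reading (fibroblasts attached alongside
  myocytes) is not implemented.
- No 3D anatomy, fibre anisotropy, reentry protocols, restitution or
  rate-dependent drug block.
- The monodomain assumption ignores extracellular potential gradients.
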