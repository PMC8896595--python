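# Methods

This note records the model equations, the parameter choices that matter,
how they were calibrated, and what the simulations do and do not capture.

## Striatal geometry and the arbor network

The putamen is an ellipsoid with semi-axes (14, 9, 9) mm (volume
≈ 4,750 mm³). Human putamen dimensions vary and the model only needs a
volume scale; these axes were fixed, once, so that 10⁵ arbors of radius
0.5 mm produce a mean overlap count of ≈ 11 (the closed form
n·(4/3)πr³/V = 11.0), a fully covered striatum (zero isolated volume), and
a random-denervation percolation collapse near 75 % loss. All three are
tied to the same density, so the ellipsoid volume is the single calibrated
geometric quantity. Axes, arbor count and radius are configurable;
heterogeneous arbor radii are available as a lognormal with median 0.5 mm
(`radius_spread` = log-scale σ), our stand-in for volume heterogeneity.

Arbor centers are i.i.d. uniform (rejection sampling from the bounding
box; one seeded generator per operation). Two live arbors overlap
"considerably" when their centers are < 0.5 mm apart (strict inequality,
applied to centers regardless of radius variants); contiguous arbor
classes (CACs) are connected components of this graph, computed with a
union-find/sparse-graph routine — communication classes of a symmetric
reachability relation are exactly connected components. A point is
*isolated* when its distance to the nearest live arbor **surface** exceeds
0.1 mm (center distance > radius + 0.1 mm). Measuring from the center
instead would label ~90 % of the healthy striatum isolated, contradicting
full coverage; the surface reading reproduces it. The 0.1 mm margin is
taken as a given diffusion length scale, not re-derived.

One consequence of the calibrated density deserves emphasis: with a mean
degree of 11, a handful (~10 of 10⁵) of boundary arbors have no neighbor
within 0.5 mm, so the healthy network is a single giant CAC holding
> 99.98 % of arbors plus a few boundary singletons, not literally one
class. Driving the singleton count to zero would require roughly doubling
the density, which would break the mean-overlap and tipping-point
calibrations; we accept the boundary singletons and state coverage as the
largest-CAC fraction.

`most_isolated_points` uses the Voronoi vertices of the live centers
(clipped to the ellipsoid, plus sampled boundary points — the maximum can
sit on the boundary) as candidate local maxima of the nearest-center
distance; with fewer than four live arbors the Voronoi diagram is
degenerate and a dense Monte-Carlo search is used and flagged.

## Denervation mechanisms

All mechanisms are continuous-time death processes simulated exactly
(Gillespie); time is in arbitrary units with the base rate = 1 defining
the clock. Deaths flip the `alive` mask only, so any structural quantity
can be re-measured on any snapshot.

**RD.** Every live neuron dies at the same rate. The death order is an
exchangeable permutation and the survival curve is exp(−t); simulated as a
permutation plus exponential gaps, which is the exact Gillespie
realization.

**PLD.** One seed neuron is infected; only infected neurons die (equal
rates), and a dying neuron first infects its two nearest living uninfected
*contacts* — neurons whose arbors physically touch its own (center
distance < rᵢ + rⱼ, i.e. 1.0 mm at the default radius). Restricting the
spread to arbor contacts is what makes the infection a compact traveling
wave: regions swallowed early are essentially cleared before the front
reaches distant ones, which is what produces the large isolated fractions
and the strongly polarized activity maps. (We verified that letting an
infected neuron infect its globally nearest uninfected peers instead lets
interior neurons jump to the frontier, smears the wave, and caps the
isolated fraction near 10 % — losing the phenomenology.) If the infected
set burns out while neurons remain, a fresh random seed is infected.

**SID.** Neuron i dies at rate 1/(1 + exp((kᵢ − 9)/1)), where kᵢ is its
neighbor count **in the healthy network**. Rates are static: the mechanism
models a fixed vulnerability set by how much compensation load a neuron's
neighborhood imposes. Static heterogeneous rates make the survival curve a
mixture of exponentials, which is always decelerating — the stretched
exponent c < 1 and the survivor clustering both follow. We also examined
the variant in which kᵢ is recomputed as neighbors die; the positive
feedback (deaths lower neighbors' counts, raising their rates) makes the
decay *accelerate*, and across a wide (midpoint, slope) grid that variant
never produces c < 1 together with ~20 % isolated volume, so the static
reading is the one retained.

**Summaries.** Survival curves are fitted with least squares on
ln N(t) = ln N₀ − b·tᶜ over the 2–98 % survival range (t = 0 excluded;
initial c from the log–log slope; bounded `curve_fit`). The network
tipping point is operationalized as the first denervation level (1 %
grid) at which the largest CAC holds fewer than half of the surviving
arbors — 0.5 is the usual giant-component convention; the qualitative
"transition" has no formal definition otherwise.

## Dopamine dynamics

dM/dt = Δ·ν·N − V_M·N·M/(K_M + M), with Δ = 1.5·10⁻³ µM per impulse per
terminal, V_M = 0.04 µM/s per terminal, K_M = 0.21 µM. These are standard
mean-field kinetics calibrated to a tonic (4 Hz) plateau of 37 nM and a
phasic (20 Hz) plateau of 0.63 µM. Degradation (ε = 0.05 /s) and
inter-subvolume diffusion are dropped wherever N > 0 — they are orders of
magnitude below uptake there, and keeping ε would spuriously break the
N-invariance of the plateau; a subvolume with N = 0 keeps only
dM/dt = −εM and receives no DA. Firing protocols are piecewise-constant
sequences over {0, 4, 20} Hz; the default is tonic 3 s → phasic 0.5 s →
tonic 3 s → pause 0.5 s → tonic 3 s (segment durations are free
parameters; every downstream result carries its protocol). Integration is
LSODA with rtol 10⁻⁸, 1 ms output grid, clamped at M ≥ 0.

Terminal counts: 0.1 terminals per model volume unit × 10³-unit subvolume
= 100 terminals in a healthy subvolume. A spatial point's effective N is
its live arbor cover times 100 / (healthy mean cover ≈ 11), so the healthy
spatial mean is 100 by construction.

## cAMP in D1- and D2-SPNs

d[cAMP]_D1/dt = α + λ₁·DAʰ/(DAʰ + κ₁ʰ) − δ₁·cAMP and the mirrored D2 form
with κ₂ʰ/(DAʰ + κ₂ʰ). Defaults: α = 0.1 µM/s, λ₁ = λ₂ = 1 µM/s,
δ₁ = δ₂ = 1 /s (α, δ taken equal across cell types absent evidence
otherwise), Hill h = 4, κ₁ = 0.5 µM, κ₂ = 0.03 µM. The affinity pair puts
tonic DA (0.037 µM) well below D1 activation and near the D2 transition,
so D1 cells read out phasic peaks and D2 cells read out pauses — the
regime the defaults were chosen to produce. Initial conditions are the
steady state at the trace's initial DA.

Readouts: D1 = maximal cAMP in the phasic window; D2 = maximal cAMP in the
pause window. The cAMP peak lags the window end by up to ~0.1–0.2 s
(τ = 1/δ); we deliberately do **not** extend the D2 window beyond the
pause, because the post-pause DA-recovery transient is faster at high
terminal counts and folding it in makes the D2 readout non-monotone in N
(≈1 % inversions above N ≈ 60). With the pause-proper window both
readouts are monotone non-decreasing in N for N > 0; N = 0 is a genuine
discontinuity (DA ≡ 0 pins D1 at its minimum α/δ = 0.1 µM and D2 at its
maximum (α+λ)/δ = 1.1 µM).

## SPN models

The Hodgkin–Huxley-type SPN is a single compartment (C = 1 µF/cm²) with
fast Na⁺ (instantaneous m³, gated h), persistent Na⁺, delayed-rectifier,
inward-rectifier (KIR), fast A-type, slowly inactivating (K_SI) and
Ca²⁺-dependent (K_Ca) K⁺ currents, N- and P-type high-threshold Ca²⁺
currents feeding a first-order Ca²⁺ pool, and a leak. Exact published
kinetic constants for this cell type are not reproduced; instead the model
is held to a behavioral contract — down-state −80 ± 5 mV, barrage-evoked
up-state −55 ± 5 mV, zero spikes without a barrage, 2–15 spikes per 500 ms
barrage with cAMP — and the default conductances in `SPNChannelSet` are
the calibration that meets it. KIR anchors the down-state; its closure
under depolarizing drive, against K_SI activation near −40 mV, produces
the up-state plateau. Integration: forward Euler for V with exponential
Euler for gates at dt = 0.025 ms, V clamped to [−110, 60] mV (which makes
the integrator non-divergent by construction); spikes are upward crossings
of −20 mV with a 2 ms lockout.

Synaptic barrages are an Ornstein–Uhlenbeck current (correlation time
5 ms) plus a proportional mean (mean = 1.5 × amplitude): a barrage is
4 × the baseline amplitude inside a 500 ms window, and the analysis window
is the barrage window. cAMP enters as a **static** level per simulation —
the maximum from the relevant protocol window — scaling the Ca_V(N),
Ca_V(P), K_SI and K_Ca conductances by (1 − m·c/(c + k_c)) with
half-effect k_c = 0.08 µM (half the healthy D1 phasic maximum of
0.163 µM). The modulation depth m = 0.7 (identical for D1 and D2 targets)
was calibrated jointly with the barrage amplitude against the contract
plus the compensation benchmark below: shallower modulation compresses
the healthy/denervated firing contrast until no mechanism separates from
the 15 % band, deeper modulation pushes spike counts past the contract
ceiling.

The Izhikevich variant uses the published spiny-neuron set (C = 50, k = 1,
v_r = −80, v_t = −25, a = 0.01, b = −20, c = −55, d = 150, v_peak = 40)
with the same OU drive scaled by 35 and cAMP applied as a drive gain
1 + c/(c + k_c). It reproduces the ordering of the barrage / cAMP /
barrage+cAMP conditions and rank-correlates with the conductance model
across terminal counts, which is the level at which model-invariance is
testable here.

## Spatial pipeline

The expensive neuron simulations run once per value of a terminal-count
grid (default 0…200, 12 values; 100 noise seeds per value, identical seed
vector across values so that differences reflect cAMP alone), producing a
firing lookup. Activity maps draw 10,000 uniform striatal points, convert
live arbor cover to N, and linearly interpolate the lookup (clamped at the
grid edges; a warning fires if > 1 % of points fall outside). Denervation
sweeps snapshot a trajectory at each level and reuse one lookup. D2 in
isolated areas uses the N = 0 row (maximal firing); the
`d2_homeostasis` flag drops that row instead, emulating D2-SPNs that
downregulate when deprived of DA (off by default).

## Compensation

δ(n) = δ_max / (1 + exp((n − n_half)/s)) of the local arbor cover n, with
δ_max = 0.9, n_half = half the healthy mean cover, s = 2. δ_max < 1 caps
release amplification at 10× — a δ reaching exactly 1 would diverge.
ERC maps Δ → Δ/(1−δ); DUC maps V_M → V_M(1−δ); DEC maps both Δ and V_M to
themselves divided by (1−δ), which is algebraically a rescaling of N by
1/(1−δ): the whole DA trajectory, not just the plateau, is preserved.
`exact_recovery_mode` (δ = clip(1 − n/n_healthy, 0, δ_max)) exists to
exercise that identity exactly. Compensation is evaluated from the local
cover at each grid N, so it is spatially heterogeneous. Postsynaptic
variants rescale the cAMP parameters: increased D2 expression multiplies
λ₂, receptor sensitization divides κ₁ and κ₂, phosphodiesterase
inhibition divides δ₁ and δ₂.

## Problem sizes and reproducibility

Full-scale analyses (healthy structure, survival fits, isolated volumes,
tipping point, compensation sweeps) use the complete 10⁵-arbor network;
the acceptance script averages five independent full-scale runs and
completes in a few minutes on one core. Unit and property tests use
density-preserving scaled networks (10–20 × 10³ arbors in a
proportionally shrunk ellipsoid), which keep the mean overlap, CAC
structure and percolation behavior of the full system. Every stochastic
operation takes an explicit seed; run configs derive per-stage seeds
deterministically from one master seed.

## What the synthetic system does and does not capture

The generator realizes the model's own idealizations: uniform arbor
centers (no anatomical gradients or patch/matrix structure), spheres for
arbors, mean-field DA without stochastic vesicular release or explicit
diffusion, single-compartment neurons without interneuron circuits,
autoreceptor feedback or synaptic plasticity, and denervation mechanisms
run in isolation although they are not mutually exclusive. Passing tests
therefore validate the implementation of this model class, not anatomical
realism.

Known limitations of the calibration:

* The healthy network carries ~10 boundary singleton CACs (see above);
  "one coherent network" holds at the 99.98 % level.
* The D1 cAMP dose–response is nearly flat below N ≈ 40, so under *random*
  thinning the spatial SD of D1 firing falls with denervation instead of
  rising as it does for the spatially structured mechanisms (PLD, SID,
  where DA-rich and DA-poor regions coexist); the SD-rise signature is
  asserted only for the structured mechanisms.
* The D1 cAMP peak can lag the phasic burst by up to ~0.2 s (second-
  messenger lag); timing assertions allow that margin.
* Under strong release compensation (ERC at low coverage) phasic release
  can exceed uptake capacity; no steady state exists and the DA excursion
  is bounded only by the window length. The integrator handles this; the
  closed-form steady state deliberately raises an error there.
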