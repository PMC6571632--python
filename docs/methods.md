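# Methods

## Model overview and assumptions

The simulator advances a 14-cell CA3–CA1 microcircuit in discrete 0.5 ms
cycles. Neurons are *shift-register compartmental* models rather than
conductance-based ones: each of the 16 compartments per cell holds three
registers (E = AMPA, M = NMDA, I = GABA-A) whose boxes are future membrane
potentials at that postsynaptic site, pre-filled with the resting
potential ReP = −80 mV. A presynaptic action potential adds a fixed PSP
waveform into the relevant register; the register head is the
compartment's contribution to the current cycle. This trades biophysical
detail (no cable equations, no Hodgkin–Huxley channels, no dendritic
nonlinearities beyond the NMDA plasticity gate) for complete transparency
and speed: a 10 s network run takes about a second.

The update loop is stage-synchronous: all deliveries, potential reads,
plasticity updates and threshold checks within a cycle use the previous
cycle's spikes, so the iteration order over cells cannot affect results.
Runs are bit-reproducible from (configuration, seed).

## Cells and wiring

Compartment layout (identical template for every cell): index 0 axon,
1 soma, 2–5 proximal dendrites, 6–10 medium dendrites, 11–14 distal
apical dendrites, 15 basal dendrite. Pyramidal cells carry 13 excitatory
synapses — 4 distal (entorhinal), 5 medium (mossy fibers in CA3, Schaffer
collaterals in CA1; AMPA+NMDA co-localized and counted as one synapse)
and 4 proximal (recurrent) — giving 8 × 13 = 104 excitatory synapses over
the eight pyramidal cells. Basket cells receive entorhinal drive distally,
pyramidal feedback on medium dendrites, and septal plus reciprocal basket
inhibition at the soma; O-LM cells receive local pyramidal excitation and
septal inhibition, and inhibit the distal apical tufts of their region's
pyramidal cells (a choice based on standard O-LM anatomy; the source
material does not state their targets). The mossy cell is a pure relay of
dentate input onto CA3 medium dendrites.

Synaptic base weights fall linearly with distance from the soma, from 1.0
at the most proximal dendritic compartment to the cell-type-specific LSW
("low significant weight") at the most distal. Initial parameters per
cell: pyramidal LSW 0.2 (CA1) / 0.6 (CA3), EPSPd 4.5 mV, IPSPd −6 mV;
basket LSW 1.0, EPSPd 4 mV, IPSPd −4.5 / −5.5 mV; O-LM LSW 0.6, EPSPd
4 mV, IPSPd −4 mV.

## PSP kinetics, thresholds, registers

Only PSP peak amplitudes are part of the cell tables, so the time course
is a modeling choice: dual-exponential (alpha-like) templates with
2 ms rise / 6 ms decay for AMPA and GABA-A and 5 ms rise / 25 ms decay
for NMDA (the slower kinetics are what make a separate NMDA register
meaningful). Templates are truncated when the amplitude falls below 0.1%
of the peak; register length is twice the longest template support.
Registers do not saturate — no floor or ceiling clipping is applied.

Spike thresholds are likewise free parameters: −55 mV for pyramidal
cells and −58 mV for the faster-spiking interneurons, configurable per
cell type. The refractory period of 1.5 ms is three whole cycles, during
which the cell neither spikes nor accepts synaptic injections; together
with the spike cycle itself this enforces a minimum ISI of 2.0 ms. Axonal
conduction delay is one box (0.5 ms) per connection.

## The memory (LTP) rule

Per excitatory compartment k, a dimensionless charge C ≥ 0 integrates
NMDA-gated events: when a presynaptic spike arrives in a cycle where the
local potential S_k exceeds CaMT = −68 mV (the Mg-unblock threshold,
strict inequality), C increases by exp(10·ΔV) − 1 with ΔV the NMDA-head
depolarization above rest *in volts*. Expressed in millivolts the
exponent would overflow for any physiological depolarization, so the
volts reading is adopted; it makes single-event increments O(0.1),
commensurate with the forgetting quantum FQ ≥ 1. Forgetting is the
conditional step "if C > FQ then C ← C − FQ", applied once per simulated
second by default (`decay_every` = 2000 cycles) — the slow cadence
implements the rule's signature rapid-rise / very-slow-decay asymmetry.
Whether the subtraction should run autonomously or only on gated cycles
is not specified by the rule's source; it is exposed as a parameter and
defaults to autonomous.

The weight multiplier is M = 1 + ln(C+1)/6, so M = 1 exactly at C = 0 and
M = 2 at C = e⁶ − 1; the reported "time of memory" is log10(C+1)
(computed as ln(C+1)/clog with clog = 2.3026). The printed form of this
expression in the source material is typographically corrupted; this
reading was chosen because it is dimensionally coherent and anchors
M to 1 at zero charge. The informal "local threshold (ca. 70 mV)" for
plasticity induction is unified with the formal CaMT = −68 mV gate, the
formal statement taking precedence. Effective weight = base weight × M,
never below the base weight; FQ can be set per neuron.

## Inputs

Each external source cell fires as an inhomogeneous Poisson process
(sampled by thinning) with rate r(t) = rate_peak · max(0, cos(2πft + φ)),
f = 8 Hz. EC2 (φ = 0) and EC3 (φ = π) are antiphase; the dentate
population follows EC2's phase; the six septal pacemaker cells are in
antiphase with EC2 so interneuron somatic inhibition is strongest when
EC2 drive is weak. The Poisson family, the per-cell peak rates and the
fan-in are free choices (see Calibration). Each input-driven synapse is
assigned `fan_in` = 2 distinct source cells from its 100-cell population
by a seeded draw, since per-synapse fan-in is not specified anywhere.

## Lesion protocol

Pathology runs progressively delete the 44 CA3 afferent connections
(EC2→PC ×16, EC2→BC ×8, mossy→PC ×20) at uniformly spaced times within
[500, 7500] ms, in construction ("listed") order by default or seeded
random order. Deletion is irreversible; a deleted synapse injects no PSPs
and accumulates no charge. CA1 connections are never lesioned. With an
empty schedule the pathology path is bit-identical to the control run.

## Calibration

The published experiment reports group spike counts but not the
calibration that produced them (thresholds, PSP kinetics, input rates,
lesion timing), so the model's free drive parameters were fixed once by a
coarse-to-fine grid search over EC/DG peak rates, fan-in and the lesion
window, targeting the reported region means (CA1 control ≈ 92.25, CA1
degraded ≈ 24.0, CA3 degraded ≈ 42.75 spikes per 10 s), and then frozen:
ec_rate_peak = 30 Hz, dg_rate_peak = 16 Hz, ms_rate_peak = 60 Hz,
fan_in = 2, lesion window [500, 7500] ms. Under these defaults,
seed-averaged runs give ≈ 92 / ≈ 22 / ≈ 42 for the three quantities, and
the direction, significance and correlation structure of the
healthy-vs-degraded comparison are reproduced for every seed tested.
These are simultaneously the defaults of the synthetic-input generator —
they define the study conditions, not tuning knobs per run.

## Analysis conventions

Mean frequency defaults to the mean of instantaneous 1/ISI frequencies
per cell (whose SD can exceed the mean for bursty theta-locked trains);
the count rate spikes/duration is reported alongside. "Final frequency"
uses the last 1000 ms (configurable). Group comparisons auto-select
Student t vs Mann-Whitney U by a Shapiro-Wilk pre-check at α = 0.05 when
the caller does not specify. Multi-group tests (Kruskal-Wallis, F) and
chi-squared are out of scope: no reported result exercises them.

## Nonlinear suite

The analyzed signal is the per-cell ISI sequence (configurable to binned
counts). Delay τ = first lag where the autocorrelation drops to 1/e
(fallback: first local minimum). Embedding dimension = smallest m with
< 1% false nearest neighbors, using both Kennel criteria (distance-ratio
threshold Rtol = 15 and amplitude threshold Atol = 2 attractor radii;
without the amplitude test, noise spuriously "embeds" at moderate m).
The correlation dimension is the Grassberger–Procaccia slope of
log C(r) vs log r with a Theiler window of τ, fitted over the middle
quartiles of a radius grid spanning the 0.1–10% quantiles of pairwise
distances — the small-radius scaling region, below attractor-size
saturation. Shannon entropy uses a 16-bin amplitude histogram.
Recurrence matrices are all pairwise Euclidean distances between 3-D
delay-embedded points. Periodic test fixtures use frequencies
incommensurate with the sampling grid; a commensurate sine revisits a
finite point set and is genuinely zero-dimensional under pairwise
counting.

## What the synthetic inputs do and do not emulate

The generators reproduce theta-band modulation, antiphase layer
structure, Poisson irregularity and seed determinism. They do not model
grid/place-field structure, dentate pattern separation, theta-gamma
nesting, or slow non-stationarities of real entorhinal drive, so passing
tests demonstrate the circuit's response to idealized rhythmic drive,
not to in vivo spike statistics.

## Numerical choices and degenerate inputs

Floating-point: register arithmetic accumulates at the −80 mV baseline,
so equality checks against superposition oracles hold to ~1e−12 of a
millivolt rather than bit-exactness. Zero-variance series raise on
correlation and autocorrelation; empty spike trains yield zero-count
summaries; identical constant samples in group tests return p = 1 with a
warning; a lesion count exceeding the 44 lesionable connections raises an
error naming the limit. Problem sizes for the seed-averaged experiments
(ten seed pairs of 10 s runs) keep the full suite and the acceptance
script to well under a minute each on one core.

## Known limitations

- Point-template PSPs and linear summation: no shunting inhibition, no
  NMDA voltage dependence beyond the binary plasticity gate.
- The CA3 "control" spike report in the source experiment is internally
  inconsistent (its quoted range excludes its quoted mean), so healthy
  CA3 counts are constrained only qualitatively here.
- Synaptic compensation (upscaling of surviving synapses) is deliberately
  absent; the lesion model is pure deletion.
- Embedding-dimension and correlation-dimension group values for
  simulated ISI series are reported but have no quantitative external
  anchor; stochastic ISI sequences are often flagged as noise-dominated
  by the FNN criterion, which the suite reports honestly via a warning.
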