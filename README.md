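# hipposim

A spiking simulator of a small CA3–CA1 hippocampal microcircuit, built to
study how progressive synaptic deletion — the connectivity loss
characteristic of Alzheimer-type degeneration — degrades firing and
synaptic memory, and to characterize the resulting spike trains with both
classical statistics and nonlinear (chaos-theoretic) measures.

It is intended for computational neuroscientists who want a compact,
fully deterministic (seeded) model in which every mechanism is inspectable:
no compiled simulator, no hidden state.

## The model

**Cells.** 14 neurons: 4 CA3 pyramidal cells (P5–P8), 2 CA3 basket cells,
1 CA3 O-LM cell, 4 CA1 pyramidal cells (P1–P4), 2 CA1 basket cells and
1 CA1 O-LM cell. Each cell has 16 compartments (axon, soma, 14 dendritic
segments); each dendritic compartment carries one excitatory or inhibitory
synapse and three *shift registers* — E (AMPA), M (NMDA) and I (GABA-A) —
whose boxes each hold 0.5 ms of future membrane potential, initialized to
the resting potential ReP = −80 mV. A presynaptic spike stamps a
postsynaptic-potential template (peak EPSPd/IPSPd from the per-cell
parameter tables) into the register; every cycle the register heads are
read into a local potential S_k, summed with proximity-dependent weights
(1.0 proximally down to the cell's LSW distally) and compared with the
spike threshold. A spike resets all registers to ReP and imposes a 1.5 ms
refractory period.

**Memory rule.** Plasticity is compartment-local and NMDA-gated: whenever
a spike arrives while S_k exceeds the Mg-unblock threshold CaMT = −68 mV,
a charge accumulator grows as

    C(i+1) = C(i) + exp(10·ΔV) − 1,      ΔV = (M_head − ReP) in volts

and, on a slow cadence, C decreases by the forgetting coefficient FQ ≥ 1
while C > FQ. The synaptic weight is scaled by the memory multiplier
M = 1 + ln(C+1)/6 (so M ≥ 1 always), and log10(C+1) is reported as the
"time of memory". Rise is fast, decay is slow and stepwise.

**Inputs.** 100-cell entorhinal populations (EC2 → CA3, EC3 → CA1) firing
as inhomogeneous Poisson processes with 8 Hz half-wave-rectified cosine
rate envelopes in antiphase, dentate mossy-fiber drive onto CA3 PC medium
dendrites, and six medial-septum GABAergic pacemaker cells onto basket and
O-LM somas.

**Lesion protocol.** The pathology condition switches off, one after
another, the EC2→CA3-PC, EC2→CA3-BC and mossy-fiber→CA3-PC synapses
(44 connections; CA1 wiring is never touched) at uniformly spaced times.
The intact pyramidal cells carry 8 × 13 = 104 excitatory synapses.

**Analysis.** Per-cell spike counts, ISI series, mean/final frequencies,
memory-vs-deletion pairings, Pearson/Spearman correlations, t /
Mann-Whitney group tests, and a nonlinear suite: autocorrelation delay,
false-nearest-neighbors embedding dimension, Grassberger–Procaccia
correlation dimension, Shannon entropy and recurrence-distance matrices.

## Worked example

```bash
python examples/control_vs_pathology.py
```

prints (seed 1):

```
  cell  control  pathology
    P1       88         16
    ...
    P8      165         65
CA1: control mean 89.0 vs pathology 16.0 spikes/10 s (t test, p = 0.0000)
CA3: control mean 162.2 vs pathology 42.5 spikes/10 s (t test, p = 0.0000)
```

i.e. deleting the CA3 afferents collapses CA3 firing directly and CA1
firing through the lost Schaffer drive. The other examples demonstrate
the theta inputs (`theta_inputs.py`), the memory rule in isolation
(`ltp_rule.py`), memory/deletion coupling (`memory_and_deletion.py`) and
the nonlinear suite (`nonlinear_analysis.py`).

A thin CLI wraps the same library:

```bash
hipposim run --seed 1 --out results/control
hipposim lesion-run --seed 1 --out results/pathology
hipposim compare --control results/control --pathology results/pathology
```

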