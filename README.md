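# colsim

A desk-scale simulator for networks of multicompartment, conductance-based
neurons organised into repeated cortical microcolumns. It reproduces the
computational semantics of large parallel compartmental-network benchmarks —
implicit Crank–Nicolson integration with Hines-ordered O(N) elimination,
reproducible probabilistic connectivity, density-preserving probability
scaling, independent Poisson drive, partitioned spike exchange with
overflow-safe counters, and point-electrode LFP recording — in a form small
enough to test exhaustively on one machine.

## Who it is for

Researchers who care about the *correctness contracts* of large neural
simulations — repeatability of network instantiation, partition-invariant
spike exchange, solver accuracy — rather than about reproducing any specific
published physiology. All cell parameters come from a seeded synthetic
fixture generator that mimics the structure of a thalamocortical benchmark
model (12 cell types, 6 excitatory and 6 inhibitory, layers 2–6, 50–74
compartments per cell, up to 14 voltage-gated channels per compartment,
61-neuron microcolumns), not its published channel kinetics.

## The model

Each compartment obeys the cable/membrane equation

```
C_m dV/dt = −g_L (V − E_L) − Σ_c ḡ_c x₁^p₁ x₂^p₂ (V − E_c)
            − Σ_s g_s(t) (V − E_s) + Σ_adjacent g_a (V_adj − V)
```

with Hodgkin–Huxley gating `dx/dt = α(V)(1−x) − β(V)x` (rate functions from
the exponential / sigmoid / linoid family) and difference-of-exponentials
synaptic conductances. Time integration is the trapezoidal (Crank–Nicolson)
rule: gates advance by their exact exponential update, then the voltage
system `(C/dt + G/2 + L/2)V₁ = (C/dt − G/2 − L/2)V₀ + Σ gE` is solved
exactly in O(N) per cell by Hines elimination on the compartment tree
(`parent[i] < i`). The default step is 25 µs.

Networks tile a 61-neuron microcolumn in the XY plane. Connection
probabilities are distance-independent and are rescaled by a single factor
`f = K_target / K_expected(N)` so the expected synapses per neuron stay
constant as the network grows. The uniform variate deciding each candidate
connection is a pure function of `(seed, rule, source gid, target gid)`
drawn from a counter-keyed stream, so the realised table is identical across
runs, across enumeration orders, and across any partitioning of the columns
onto logical ranks. Spikes cross ranks through sorted delivery queues with
64-bit message counters; the local field potential is the point-source sum
`φ = Σ_k I_k / (4πσ r_k)` over all transmembrane currents.

The weak-scaling harness times full build-and-run cycles at fixed problem
size per rank and reports `E(n) = T_m / T_n`.

## Worked example

Run one microcolumn for 50 ms of simulated time with the default study
conditions (25 µs step, K = 2,000 target synapses/neuron, 10 Hz Poisson
drive, recurrent weight 10⁻⁹):

```
$ cat ex.json
{"duration": 0.05, "seed": 1, "nx": 1, "ny": 1, "record_v_gids": [0]}
$ colsim run ex.json --out ex-out
outputs written to ex-out
```

`ex-out/report.json` then contains

```
n_neurons      61
n_synapses     10980
n_spikes       91
mean_rate_hz   29.84
```

61 neurons form the single microcolumn; 10,980 synapses are realised (at
N = 61 the density-preserving scaling saturates every candidate pair, which
the build reports as a clamping warning); 91 somatic threshold crossings in
50 ms give a mean rate of ~30 Hz — the drive makes every neuron fire a short
burst per input event, and because recurrent weights are 10⁻⁹ the raster is
indistinguishable from that of an unconnected population. `spikes.tsv`
(gid, time_s), `lfp.csv` (time_s, lfp_v) and `v_0.csv` hold the raster, the
electrode trace ~6 µm above the patch, and the recorded soma voltage:

```
$ head -3 ex-out/spikes.tsv
gid   time_s
48    0.001275
49    0.001275
```

Re-running the same config gives byte-identical outputs. Other entry points:
`colsim make-cells --seed S --out DIR` writes the 12 synthetic cell
templates, microcolumn and rule table as JSON; `colsim bench --preset
fig5-mini --seed S --out report.json` runs a weak-scaling suite.

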