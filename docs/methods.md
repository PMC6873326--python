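# Methods

## Scope and intent

colsim is a correctness-first, desk-scale reimplementation of the
computational core of a large parallel compartmental-network benchmark:
the integration scheme, the reproducible network-instantiation algorithm,
the spike-exchange semantics, the LFP recorder and the weak-scaling
harness. It does not attempt to reproduce any published physiology; the
cell parameters are synthetic (see *Fixture generator* below).

## Units and conventions

Strict SI throughout: volts, seconds, metres, siemens, farads, amperes.
Indices are 0-based; gids are global and contiguous
(`gid = column*61 + slot`); times are seconds. Membrane currents are
positive outward. Compartment surface area is the open cylinder `π·d·L`
(no end caps). The axial conductance joining compartment *i* to its parent
is `π d_i² / (4 R_a,i L_i)`, from the child compartment's own geometry.

## Integration scheme

The membrane equations are discretised with the trapezoidal
(Crank–Nicolson) rule. Within one step of size `dt` (default 25 µs):

1. **Synaptic deliveries** arriving this step add their weight to both
   states of the target receptor's difference-of-exponentials pair.
2. **Gates** advance by the exact exponential update
   `x ← x_∞ + (x − x_∞)·exp(−dt/τ)` with `x_∞, τ` evaluated at the
   pre-step voltage. This is the staggered-grid practice of hsolve-style
   solvers; it is unconditionally stable and keeps `x ∈ [0,1]` for any
   `dt`. (How the original simulator interleaves channel and voltage
   updates internally is not documented; this ordering is our own,
   documented choice.)
3. **Voltages** solve
   `(C/dt + G/2 + L/2) V₁ = (C/dt − G/2 − L/2) V₀ + Σ gE + I_inj`,
   where `G` collects membrane conductances frozen at their post-update
   values and `L` is the axial Laplacian. Because compartments are in
   Hines order (`parent[i] < i`, single root), one leaf-to-root
   elimination sweep and one root-to-leaf substitution solve the system
   exactly in O(N). The implementation works on flat arrays describing a
   *forest*, so one cell and a 976-neuron population run identical code;
   elimination is scheduled by tree depth so each sweep is a short
   sequence of vectorised gather/scatter operations.
4. **Receptor states** decay by their closed-form factors
   `exp(−dt/τ_rise)`, `exp(−dt/τ_decay)`.

The voltage step is second-order accurate (verified against the analytic
RC decay with observed order ≈ 2 under dt-halving); the overall scheme
with frozen conductances is first-order in the gating coupling, which is
the standard trade-off at 25 µs. Initial condition: `V = E_leak`, gates at
steady state for that voltage, receptors silent.

Transmembrane current per compartment is computed as capacitive plus
ionic, `I_m = C(V₁−V₀)/dt + G·V̄ − B` with `V̄` the step midpoint; by the
discrete equations this equals the net axial inflow, so `Σ I_m ≈ 0` per
cell to solver precision (Kirchhoff), making each cell a pure multipole
source for the LFP.

Spikes are upward crossings of the soma voltage through a threshold
(default 0 V): `V_before < θ ≤ V_after`, so a cell held above threshold
emits exactly once.

## Synapse model

Receptor conductance after a delivery of weight *w* is a
difference of exponentials normalised to peak exactly at *w*:
`g(t) = w·[exp(−t/τ_d) − exp(−t/τ_r)] / [exp(−t_p/τ_d) − exp(−t_p/τ_r)]`
with `t_p = τ_rτ_d/(τ_d−τ_r)·ln(τ_d/τ_r)`. Receptor slots per
compartment: 0 = excitatory input (τ 0.5/3 ms, E = 0 V), 1 = inhibitory
input (τ 1/8 ms, E = −80 mV), 2 = somatic drive (τ 0.2/1.5 ms,
E = +50 mV). Deliveries are applied in globally sorted order
(source gid, target gid, target compartment), so floating-point
accumulation is deterministic and partition-independent.

## Reproducible connectivity

The historical failure mode this package guards against is
instantiation-order-dependent connectivity: when the *target* side of a
candidate pair draws the random number, message arrival order changes the
draw sequence and the network differs run to run. Here the accept/reject
variate of every candidate pair is a pure function of
`(seed, rule index, source gid, target gid)`: a counter-based stream is
keyed by `(seed, rule, source)` and indexed by target gid, with a second
variate selecting the target compartment within the rule's compartment
class. Consequently the realised table is invariant to enumeration order
and to the partitioning — a deliberate strengthening over guaranteeing
repeatability only for a fixed partitioning. Self-connections are
excluded; multiple synapses between a pair are allowed only on distinct
target compartments. The table is written as sorted TSV and is
byte-identical across repeated builds.

**Density-preserving scaling.** For population size N, every base
probability is multiplied by the single factor
`f = K_target·N / Σ_rules p₀·(candidate pairs)`, clamped at `p = 1`; if
clamping occurs the achievable expected degree is reported in a warning.
Delays are a single configurable value (default 1 ms = 40 steps at
25 µs), rounded to the nearest step at routing with a warning if inexact.

## Partitioned execution

Microcolumns are assigned to logical ranks in contiguous blocks (presets:
1, 4 or 16 columns per rank = 61, 244, 976 neurons per rank). Ranks
execute sequentially in-process; spike exchange nevertheless goes through
per-rank delivery queues with stable sorted pop order and 64-bit
send/receive counters (the historical overflow appeared when narrow
counters met ~4.9 million synapses per rank). Simulating one network on
1, 2 or 4 logical ranks produces bit-identical rasters, voltage traces
and LFPs (tested).

## Stimulus

Each neuron receives an independent homogeneous Poisson train (default
10 Hz; 100 Hz preset) from its own `(seed, gid)`-keyed stream, delivered
to the soma's dedicated drive receptor. Drive weight (3×10⁻⁷ S) was
chosen once so that a single event reliably drives every fixture cell
type past the spike threshold: firing then tracks the input process while
recurrent synapses stay at the near-zero default weight (10⁻⁹), making
the spike rate independent of network sparsity. Fixture cells typically
emit a short burst (1–3 spikes) per drive event, so the output rate is a
small multiple of the input rate; matching any particular published
output rate would require the original (unpublished here) excitability
parameters and is explicitly not a goal.

## LFP

Point-source (monopole) superposition in a homogeneous ohmic medium:
`φ = Σ_k I_k/(4πσ r_k)`, σ = 0.3 S/m, electrode by default 6 µm above the
somata plane at the patch centroid (configurable); an error is raised if
the electrode comes within 1 nm of a compartment midpoint. Compartment
midpoints come from a deterministic embedding (somata on the XY grid with
a small per-slot splay, dendrites stacked by cable path distance with a
golden-angle splay); the embedding only affects LFP geometry, not the
dynamics.

## Fixture generator

All cell and connectivity parameters are produced by a seeded generator
that emulates the *structure* of the benchmark's thalamocortical model
family: 12 types (6 excitatory, 6 inhibitory) across layers 2–6; 50–74
compartments per cell with random branchy trees; compartment classes
soma/proximal/distal by tree depth; per-class modulatory channel counts
drawn uniformly in [4, 14] (soma capped so the total stays ≤ 14);
modulatory kinetics drawn from the exponential/sigmoid/linoid family with
small peak densities (0.05–1.5 S/m²). Every soma carries the classic
squid-axon Na⁺/K⁺ pair (1200 / 360 S/m², SI-converted rates) so that
spike initiation is robust. The 61-slot microcolumn has a fixed
pyramidal-heavy composition with every type present. The rule table holds
one rule per ordered type pair and target class (432 rules) with base
probabilities drawn near-uniformly in [0.10, 0.14]; absolute levels are
set by the density-preserving scaling.

What the fixtures deliberately do **not** emulate: published channel
kinetics and anatomical probability tables, calcium dynamics, gap
junctions (absent from the benchmark network too), distance-dependent
connectivity, and realistic output firing rates. Passing tests therefore
demonstrate the correctness of the *algorithms* (solver accuracy,
repeatability, partition invariance, scaling arithmetic), not fidelity to
any biological dataset.

## Benchmark harness

`run_suite` holds neurons-per-rank fixed, sweeps an ascending rank list,
and times each point (setup = fixtures + tiling + connection +
compilation; run = integration), recording process peak RSS per logical
rank as the closest portable analogue of per-core memory. Efficiency is
`E(n) = T_m/T_n` with `E(m) = 1` by definition. Linear growth of memory
or setup time in N is summarised by ordinary least squares with a
projected crossover at a configurable limit. Two conventions for the
minimum rank count m are recorded side by side (minimum network of 976
vs 3,904 neurons), because the source material states both without
reconciling them; the guiding rule is that the minimum network should
have about as many neurons as each neuron has connections. Desk-scale
suites (the `fig5-mini`, `fig6-mini` and `smoke` presets) use seconds-long
problems — ranks ≤ 16, 2–50 ms simulated — sized so a full suite runs in
minutes on one core; absolute times are machine-bound and never asserted.

## Numerical and degenerate-input choices

- Zero pivot in elimination → `SingularSystemError` (cannot occur for
  passive trees with `dt > 0`, where the system is strictly diagonally
  dominant).
- `α+β = 0` at some voltage: the gate has no dynamics there; the exact
  update leaves `x` unchanged, and the scalar query path raises a
  degenerate-gate error.
- Linoid rate functions patch their removable singularity with the limit
  `A·k` inside |x| < 10⁻⁹.
- NaN/Inf in a state vector aborts with the first offending compartment
  named.
- Delays are multiples of the step by construction of the defaults;
  non-multiples are rounded with a warning.

## Known limitations

- Logical ranks are sequential; the harness measures single-core cost,
  not real communication. The exchange *contracts* (ordering, counting,
  conservation) are what carries over to a message-passing backend.
- Conductances are frozen over each voltage step; very stiff synthetic
  channel mixes could demand smaller steps than 25 µs (not observed with
  the generator's density caps).
- The point-source LFP ignores line sources, frequency-dependent media
  and electrode geometry.
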