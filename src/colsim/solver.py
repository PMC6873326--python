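"""Crank-Nicolson / Hines integration of compartmental neurons.

The membrane equation of each compartment,

    C dV/dt = -g_leak (V - E_leak) - sum_c g_c(t) (V - E_c)
              - sum_s g_s(t) (V - E_s) + axial coupling,

is discretised with the trapezoidal (Crank-Nicolson) rule.  Ionic and
synaptic conductances are frozen over the step at their start-of-step
values (gates are advanced first, by their exact exponential update, so
they effectively live on a staggered half-step grid), which leaves a
linear system in the unknown voltages:

    (C/dt + G/2 + L/2) V1 = (C/dt - G/2 - L/2) V0 + sum g E + I_inj

where G collects membrane conductances and L is the axial Laplacian of
the tree.  Because compartments are in Hines order (parent[i] < i) the
system is solved exactly in O(N) with one leaf-to-root elimination sweep
and one root-to-leaf substitution sweep.

All of this is implemented over flat arrays describing a *forest* of
cells, so a single template and a whole heterogeneous population run
through identical code.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .cells import CellTemplate, synapse_peak_norm
from .errors import (
    ConfigurationError,
    NumericDivergenceError,
    SingularSystemError,
)

__all__ = [
    "SolverState",
    "TreeSystem",
    "CompiledForest",
    "SynapticEvent",
    "compile_forest",
    "initial_state",
    "assemble_system",
    "hines_solve",
    "advance_step",
    "detect_spikes",
    "DEFAULT_DT",
    "SPIKE_THRESHOLD",
]

DEFAULT_DT = 25e-6  # s
SPIKE_THRESHOLD = 0.0  # V

_FORM_CODE = {"const": 0, "exp": 1, "sigmoid": 2, "linoid": 3}


@dataclass(frozen=True)
class SynapticEvent:
    """Delivery of one synaptic weight to a receptor slot of a compartment."""

    compartment: int
    receptor: int
    weight: float  # S (peak conductance added)


@dataclass
class SolverState:
    """Voltages, gate values and receptor state pairs of a forest at one step."""

    V: np.ndarray  # volts, per compartment
    gates: np.ndarray  # dimensionless in [0, 1], per gate
    syn_rise: np.ndarray  # S, per receptor
    syn_decay: np.ndarray  # S, per receptor
    time: float = 0.0
    step_count: int = 0

    def copy(self) -> "SolverState":
        return SolverState(
            self.V.copy(),
            self.gates.copy(),
            self.syn_rise.copy(),
            self.syn_decay.copy(),
            self.time,
            self.step_count,
        )


@dataclass
class TreeSystem:
    """Symmetric tree-structured linear system in Hines ordering.

    ``off[i]`` is the single stored coefficient coupling compartment i to
    its parent (used for both directions); ``schedule`` groups indices by
    tree depth, deepest first, so that within a group every node's
    children have already been eliminated.
    """

    diag: np.ndarray
    off: np.ndarray
    rhs: np.ndarray
    parent: np.ndarray
    schedule: list = field(default_factory=list)

    def dense(self) -> np.ndarray:
        """Materialise the full matrix (for tests and small systems)."""
        n = self.diag.size
        A = np.zeros((n, n))
        A[np.arange(n), np.arange(n)] = self.diag
        for i in range(n):
            p = self.parent[i]
            if p >= 0:
                A[i, p] = self.off[i]
                A[p, i] = self.off[i]
        return A


def _elimination_schedule(parent: np.ndarray) -> list:
    """Index groups by depth, deepest first; roots excluded."""
    n = parent.size
    depth = np.zeros(n, dtype=np.int64)
    for i in range(n):
        if parent[i] >= 0:
            depth[i] = depth[parent[i]] + 1
    groups = []
    for d in range(int(depth.max()) if n else 0, 0, -1):
        idx = np.flatnonzero(depth == d)
        if idx.size:
            groups.append(idx)
    return groups


class CompiledForest:
    """Flat-array form of one or more cell templates, ready to integrate.

    Compartments of successive cells are concatenated; ``parent`` uses
    global indices with -1 at each cell's root.  Channels are grouped by
    gate count so per-channel open fractions vectorise without ragged
    indexing.
    """

    def __init__(self, templates: list[CellTemplate]):
        self.templates = templates
        self.n_cells = len(templates)
        self.comp_offset = np.zeros(self.n_cells + 1, dtype=np.int64)
        for c, t in enumerate(templates):
            self.comp_offset[c + 1] = self.comp_offset[c] + t.n_comp
        n = int(self.comp_offset[-1])
        self.n_comp = n

        parent = np.empty(n, dtype=np.int64)
        cap = np.empty(n)
        g_leak = np.empty(n)
        e_leak = np.empty(n)
        g_ax = np.empty(n)
        area = np.empty(n)
        self.cell_of_comp = np.empty(n, dtype=np.int64)
        self.soma = np.empty(self.n_cells, dtype=np.int64)

        chan_comp, chan_gmax_area, chan_erev, chan_ngates = [], [], [], []
        gate_exp, gate_comp = [], []
        a_form, a_A, a_Vh, a_k = [], [], [], []
        b_form, b_A, b_Vh, b_k = [], [], [], []
        rec_comp, rec_erev, rec_norm, rec_tr, rec_td = [], [], [], [], []
        self.rec_lookup: dict[tuple[int, int, int], int] = {}

        for c, t in enumerate(templates):
            o = self.comp_offset[c]
            tr = t.tree
            parent[o : o + t.n_comp] = np.where(tr.parent < 0, -1, tr.parent + o)
            cap[o : o + t.n_comp] = tr.capacitance()
            g_leak[o : o + t.n_comp] = tr.leak_conductance()
            e_leak[o : o + t.n_comp] = tr.leak_reversal
            g_ax[o : o + t.n_comp] = tr.axial_conductance()
            area[o : o + t.n_comp] = tr.surface_area()
            self.cell_of_comp[o : o + t.n_comp] = c
            self.soma[c] = o + t.soma
            ar = tr.surface_area()
            for comp in range(t.n_comp):
                for ch in t.channels[comp]:
                    chan_comp.append(o + comp)
                    chan_gmax_area.append(ch.max_conductance_density * ar[comp])
                    chan_erev.append(ch.reversal)
                    chan_ngates.append(len(ch.gates))
                    for g in ch.gates:
                        gate_exp.append(g.exponent)
                        gate_comp.append(o + comp)
                        a_form.append(_FORM_CODE[g.alpha.form])
                        a_A.append(g.alpha.A)
                        a_Vh.append(g.alpha.Vh)
                        a_k.append(g.alpha.k)
                        b_form.append(_FORM_CODE[g.beta.form])
                        b_A.append(g.beta.A)
                        b_Vh.append(g.beta.Vh)
                        b_k.append(g.beta.k)
                for slot, spec in enumerate(t.receptors[comp]):
                    self.rec_lookup[(c, comp, slot)] = len(rec_comp)
                    rec_comp.append(o + comp)
                    rec_erev.append(spec.reversal)
                    rec_norm.append(synapse_peak_norm(spec))
                    rec_tr.append(spec.rise_tau)
                    rec_td.append(spec.decay_tau)

        self.parent = parent
        self.cap = cap
        self.g_leak = g_leak
        self.e_leak = e_leak
        self.g_ax = g_ax
        self.area = area
        self.schedule = _elimination_schedule(parent)
        self.backsub = [g for g in reversed(self.schedule)]
        self.roots = np.flatnonzero(parent < 0)

        self.chan_comp = np.asarray(chan_comp, dtype=np.int64)
        self.chan_gmax_area = np.asarray(chan_gmax_area, dtype=float)
        self.chan_erev = np.asarray(chan_erev, dtype=float)
        self.n_chan = self.chan_comp.size
        self.gate_comp = np.asarray(gate_comp, dtype=np.int64)
        self.gate_exp = np.asarray(gate_exp, dtype=float)
        self.n_gates = self.gate_comp.size
        self.alpha_form = np.asarray(a_form, dtype=np.int8)
        self.alpha_params = np.asarray([a_A, a_Vh, a_k], dtype=float)
        self.beta_form = np.asarray(b_form, dtype=np.int8)
        self.beta_params = np.asarray([b_A, b_Vh, b_k], dtype=float)
        # per-form gate groups, precomputed so each step evaluates every
        # rate family on one contiguous gather
        self._alpha_groups = self._form_groups(self.alpha_form, self.alpha_params)
        self._beta_groups = self._form_groups(self.beta_form, self.beta_params)

        # group channels by gate count: (chan indices, gate indices [nk, k])
        chan_ngates = np.asarray(chan_ngates, dtype=np.int64)
        gate_start = np.concatenate([[0], np.cumsum(chan_ngates)])
        self.gate_groups = []
        for k in range(1, int(chan_ngates.max()) + 1 if self.n_chan else 1):
            ci = np.flatnonzero(chan_ngates == k)
            if ci.size:
                gi = gate_start[ci][:, None] + np.arange(k)[None, :]
                self.gate_groups.append((ci, gi))
        self.chan_zero_gates = np.flatnonzero(chan_ngates == 0)

        self.rec_comp = np.asarray(rec_comp, dtype=np.int64)
        self.rec_erev = np.asarray(rec_erev, dtype=float)
        self.rec_norm = np.asarray(rec_norm, dtype=float)
        self.rec_rise_tau = np.asarray(rec_tr, dtype=float)
        self.rec_decay_tau = np.asarray(rec_td, dtype=float)
        self.n_rec = self.rec_comp.size

    # -- rate-function evaluation ------------------------------------------

    def _form_groups(self, form, params):
        groups = []
        for code in range(4):
            idx = np.flatnonzero(form == code)
            if idx.size:
                groups.append((code, idx, params[0, idx], params[1, idx], params[2, idx]))
        return groups

    @staticmethod
    def _eval_groups(groups, Vg, out):
        for code, idx, A, Vh, k in groups:
            if code == 0:
                out[idx] = A
                continue
            x = Vg[idx]
            x = (x - Vh) / k
            if code == 1:
                out[idx] = A * np.exp(x)
            elif code == 2:
                out[idx] = A / (1.0 + np.exp(-x))
            else:  # linoid, singularity at x == 0 patched with its limit A*k
                with np.errstate(divide="ignore", invalid="ignore"):
                    v = A * k * x / (1.0 - np.exp(-x))
                out[idx] = np.where(np.abs(x) < 1e-9, A * k, v)
        return out

    def gate_rates(self, V_comp: np.ndarray):
        """alpha and beta (1/s) of every gate at the given compartment voltages."""
        Vg = V_comp[self.gate_comp]
        a = self._eval_groups(self._alpha_groups, Vg, np.empty(self.n_gates))
        b = self._eval_groups(self._beta_groups, Vg, np.empty(self.n_gates))
        return a, b

    def channel_conductance(self, gates: np.ndarray) -> np.ndarray:
        """Open conductance (S) of every channel given current gate values."""
        g = np.empty(self.n_chan)
        if self.chan_zero_gates.size:
            g[self.chan_zero_gates] = self.chan_gmax_area[self.chan_zero_gates]
        for ci, gi in self.gate_groups:
            open_frac = np.prod(gates[gi] ** self.gate_exp[gi], axis=1)
            g[ci] = self.chan_gmax_area[ci] * open_frac
        return g

    def membrane_conductances(self, state: SolverState):
        """Per-compartment total conductance G and driving term B = sum g*E."""
        G = self.g_leak.copy()
        B = self.g_leak * self.e_leak
        n = self.n_comp
        if self.n_chan:
            gc = self.channel_conductance(state.gates)
            G += np.bincount(self.chan_comp, weights=gc, minlength=n)
            B += np.bincount(self.chan_comp, weights=gc * self.chan_erev, minlength=n)
        if self.n_rec:
            gs = self.rec_norm * (state.syn_decay - state.syn_rise)
            G += np.bincount(self.rec_comp, weights=gs, minlength=n)
            B += np.bincount(self.rec_comp, weights=gs * self.rec_erev, minlength=n)
        return G, B


def compile_forest(templates: list[CellTemplate] | CellTemplate) -> CompiledForest:
    """Compile one template or a list of templates into flat solver arrays."""
    if isinstance(templates, CellTemplate):
        templates = [templates]
    return CompiledForest(list(templates))


def _compiled(template: CellTemplate) -> CompiledForest:
    cf = getattr(template, "_compiled", None)
    if cf is None:
        cf = compile_forest(template)
        template._compiled = cf
    return cf


def initial_state(forest: CompiledForest) -> SolverState:
    """Quiescent start: V at leak reversal, gates at steady state, receptors silent."""
    V = forest.e_leak.copy()
    if forest.n_gates:
        a, b = forest.gate_rates(V)
        s = a + b
        gates = np.where(s > 0, a / np.where(s > 0, s, 1.0), 0.0)
    else:
        gates = np.zeros(0)
    return SolverState(
        V=V,
        gates=gates,
        syn_rise=np.zeros(forest.n_rec),
        syn_decay=np.zeros(forest.n_rec),
        time=0.0,
        step_count=0,
    )


# ---------------------------------------------------------------------------
# operations


def _assemble(forest: CompiledForest, state: SolverState, dt: float,
              I_inj: np.ndarray | None = None):
    """Build the Crank-Nicolson tree system for one step of size dt."""
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    G, B = forest.membrane_conductances(state)
    V = state.V
    # axial Laplacian action y = L V and its diagonal
    n = forest.n_comp
    child = np.flatnonzero(forest.parent >= 0)
    par = forest.parent[child]
    gax = forest.g_ax[child]
    lap_diag = np.bincount(child, weights=gax, minlength=n) + np.bincount(
        par, weights=gax, minlength=n
    )
    y = lap_diag * V
    y -= np.bincount(child, weights=gax * V[par], minlength=n)
    y -= np.bincount(par, weights=gax * V[child], minlength=n)

    c_dt = forest.cap / dt
    diag = c_dt + 0.5 * G + 0.5 * lap_diag
    off = np.zeros(forest.n_comp)
    off[child] = -0.5 * gax
    rhs = (c_dt - 0.5 * G) * V - 0.5 * y + B
    if I_inj is not None:
        rhs = rhs + I_inj
    return TreeSystem(diag=diag, off=off, rhs=rhs, parent=forest.parent,
                      schedule=forest.schedule), G, B


def assemble_system(template: CellTemplate, state: SolverState, dt: float) -> TreeSystem:
    """Crank-Nicolson system ``A V1 = rhs`` for one cell and one step.

    Conductances are evaluated from the gate and receptor values carried
    by ``state``; the tree must be in Hines order (guaranteed by
    :class:`~colsim.cells.CompartmentTree`).
    """
    system, _, _ = _assemble(_compiled(template), state, dt)
    return system


def hines_solve(system: TreeSystem) -> np.ndarray:
    """Exact O(N) solve of a tree system: leaf-to-root elimination, then
    root-to-leaf substitution."""
    diag = system.diag.copy()
    rhs = system.rhs.copy()
    off = system.off
    parent = system.parent
    schedule = system.schedule or _elimination_schedule(parent)
    for idx in schedule:
        d = diag[idx]
        if np.any(d == 0.0):
            raise SingularSystemError("zero pivot during Hines elimination")
        f = off[idx] / d
        np.add.at(diag, parent[idx], -off[idx] * f)
        np.add.at(rhs, parent[idx], -rhs[idx] * f)
    V = np.empty_like(rhs)
    roots = np.flatnonzero(parent < 0)
    if np.any(diag[roots] == 0.0):
        raise SingularSystemError("zero pivot at tree root")
    V[roots] = rhs[roots] / diag[roots]
    for idx in reversed(schedule):
        V[idx] = (rhs[idx] - off[idx] * V[parent[idx]]) / diag[idx]
    return V


def step_forest(
    forest: CompiledForest,
    state: SolverState,
    dt: float,
    deliveries: tuple[np.ndarray, np.ndarray] | None = None,
    I_inj: np.ndarray | None = None,
):
    """Advance a whole forest by one step.

    ``deliveries`` is ``(receptor_indices, weights)`` for synaptic events
    arriving at this step.  Returns ``(new_state, I_membrane)`` where
    ``I_membrane`` is the transmembrane current per compartment (A,
    positive outward), computed as capacitive + ionic current; by
    construction it equals the net axial inflow, so it sums to ~0 over
    each cell (Kirchhoff).
    """
    if dt <= 0:
        raise ConfigurationError("dt must be > 0")
    new = state.copy()

    # 1. deposit synaptic events onto receptor state pairs
    if deliveries is not None and len(deliveries[0]):
        idx, w = deliveries
        np.add.at(new.syn_rise, idx, w)
        np.add.at(new.syn_decay, idx, w)

    # 2. exact exponential gate update at the pre-step voltage
    if forest.n_gates:
        a, b = forest.gate_rates(state.V)
        s = a + b
        safe = s > 0
        x_inf = np.where(safe, a / np.where(safe, s, 1.0), new.gates)
        decay = np.where(safe, np.exp(-dt * s), 1.0)
        new.gates = x_inf + (new.gates - x_inf) * decay

    # 3. implicit voltage step with conductances frozen at their
    #    start-of-step (post-delivery, post-gate-update) values
    system, G, B = _assemble(forest, new, dt, I_inj=I_inj)
    V1 = hines_solve(system)
    if not np.all(np.isfinite(V1)):
        bad = int(np.flatnonzero(~np.isfinite(V1))[0])
        raise NumericDivergenceError(
            f"non-finite voltage at compartment {bad} "
            f"(cell {int(forest.cell_of_comp[bad])}) at t={state.time:.6g}s"
        )
    V_mid = 0.5 * (state.V + V1)
    I_mem = forest.cap * (V1 - state.V) / dt + G * V_mid - B
    if I_inj is not None:
        I_mem = I_mem - I_inj

    # 4. closed-form receptor propagation over the step
    if forest.n_rec:
        new.syn_rise *= np.exp(-dt / forest.rec_rise_tau)
        new.syn_decay *= np.exp(-dt / forest.rec_decay_tau)

    new.V = V1
    new.step_count = state.step_count + 1
    new.time = new.step_count * dt
    return new, I_mem


def advance_step(
    template: CellTemplate,
    state: SolverState,
    dt: float,
    synaptic_events: list[SynapticEvent] = (),
) -> SolverState:
    """Advance one cell by one Crank-Nicolson step.

    ``synaptic_events`` are deliveries arriving at this step; each adds
    its weight to the named receptor slot's rising and decaying states.
    """
    forest = _compiled(template)
    idx = []
    w = []
    for ev in synaptic_events:
        key = (0, ev.compartment, ev.receptor)
        if key not in forest.rec_lookup:
            raise ConfigurationError(
                f"no receptor slot {ev.receptor} on compartment {ev.compartment}"
            )
        idx.append(forest.rec_lookup[key])
        w.append(ev.weight)
    deliveries = (np.asarray(idx, dtype=np.int64), np.asarray(w, dtype=float))
    new, _ = step_forest(forest, state, dt, deliveries=deliveries)
    return new


def detect_spikes(
    soma_v_before: np.ndarray,
    soma_v_after: np.ndarray,
    threshold: float = SPIKE_THRESHOLD,
    gids: np.ndarray | None = None,
) -> list[int]:
    """Gids whose soma voltage crossed ``threshold`` upward between steps.

    A crossing requires ``V_before < threshold <= V_after``, so a cell
    held above threshold emits exactly once, at its first crossing.
    """
    vb = np.atleast_1d(np.asarray(soma_v_before, dtype=float))
    va = np.atleast_1d(np.asarray(soma_v_after, dtype=float))
    if vb.shape != va.shape:
        raise ConfigurationError("before/after soma voltage shapes differ")
    hit = np.flatnonzero((vb < threshold) & (va >= threshold))
    if gids is not None:
        return [int(g) for g in np.asarray(gids)[hit]]
    return [int(i) for i in hit]
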