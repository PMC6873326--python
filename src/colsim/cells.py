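"""Cell morphologies, passive cable properties, channels and receptors.

All quantities are strict SI: volts, seconds, metres, siemens, farads,
amperes.  A neuron is a tree of isopotential cylindrical compartments in
Hines order (``parent[i] < i``, root sentinel ``-1``); voltage-gated
channels follow the standard Hodgkin-Huxley formalism with rate functions
drawn from the exponential / sigmoid / linoid family, and synaptic
receptors are difference-of-exponentials conductances.

Surface area uses the open-cylinder convention ``pi * d * L`` (no end
caps); the axial conductance of the cable section joining compartment
``i`` to its parent is ``pi * d_i**2 / (4 * Ra_i * L_i)``, computed from
the child compartment's own geometry.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np

from .errors import ConfigurationError, DegenerateGateError, OrderingError

__all__ = [
    "RateFunction",
    "GateSpec",
    "ChannelSpec",
    "SynapseSpec",
    "CompartmentTree",
    "CellTemplate",
    "gate_steady_state",
    "membrane_current",
    "synapse_peak_norm",
    "compartment_positions",
    "SQUID_NA",
    "SQUID_K",
    "MAX_CHANNELS_PER_COMPARTMENT",
    "COMPARTMENT_RANGE",
]

#: caps inherited from the benchmark network family this package emulates
MAX_CHANNELS_PER_COMPARTMENT = 14
COMPARTMENT_RANGE = (50, 74)

# receptor-slot convention used by templates, the network builder and the
# engine: slot 0 receives synapses from excitatory sources, slot 1 from
# inhibitory sources, slot 2 (soma only) the external Poisson drive.
RECEPTOR_EXC = 0
RECEPTOR_INH = 1
RECEPTOR_DRIVE = 2

_RATE_FORMS = ("const", "exp", "sigmoid", "linoid")


@dataclass(frozen=True)
class RateFunction:
    """One alpha(V) or beta(V) opening/closing rate, in 1/s with V in volts.

    form 'const':   rate = A
    form 'exp':     rate = A * exp((V - Vh) / k)
    form 'sigmoid': rate = A / (1 + exp(-(V - Vh) / k))
    form 'linoid':  rate = A * (V - Vh) / (1 - exp(-(V - Vh) / k)), k > 0
                    (removable singularity at V == Vh, value A * k)

    A >= 0 keeps every form non-negative on the physiological range; the
    linoid additionally requires k > 0 for positivity on both sides.
    """

    form: str
    A: float
    Vh: float = 0.0
    k: float = 1.0

    def __post_init__(self) -> None:
        if self.form not in _RATE_FORMS:
            raise ConfigurationError(f"unknown rate form {self.form!r}")
        if self.A < 0:
            raise ConfigurationError("rate amplitude A must be >= 0")
        if self.form == "linoid" and self.k <= 0:
            raise ConfigurationError("linoid rate requires k > 0")
        if self.form in ("exp", "sigmoid", "linoid") and self.k == 0:
            raise ConfigurationError("rate slope k must be nonzero")

    def __call__(self, V):
        """Evaluate the rate at membrane potential ``V`` (volts)."""
        V = np.asarray(V, dtype=float)
        if self.form == "const":
            return np.broadcast_to(np.float64(self.A), V.shape).copy() if V.shape else float(self.A)
        x = (V - self.Vh) / self.k
        if self.form == "exp":
            return self.A * np.exp(x)
        if self.form == "sigmoid":
            return self.A / (1.0 + np.exp(-x))
        # linoid, with the removable singularity patched
        with np.errstate(divide="ignore", invalid="ignore", over="ignore"):
            out = self.A * (V - self.Vh) / (1.0 - np.exp(-x))
        out = np.where(np.abs(x) < 1e-9, self.A * self.k, out)
        return float(out) if out.ndim == 0 else out


@dataclass(frozen=True)
class GateSpec:
    """One activation/inactivation particle: x' = alpha(1-x) - beta x, power `exponent`."""

    exponent: int
    alpha: RateFunction
    beta: RateFunction

    def __post_init__(self) -> None:
        if self.exponent < 0:
            raise ConfigurationError("gate exponent must be >= 0")


@dataclass(frozen=True)
class ChannelSpec:
    """A voltage-gated channel population on one compartment."""

    name: str
    max_conductance_density: float  # S/m^2
    reversal: float  # V
    gates: tuple[GateSpec, ...] = ()

    def __post_init__(self) -> None:
        if self.max_conductance_density < 0:
            raise ConfigurationError("max_conductance_density must be >= 0")


@dataclass(frozen=True)
class SynapseSpec:
    """Difference-of-exponentials conductance receptor.

    The conductance after a single delivery of weight w (siemens) rises
    with ``rise_tau``, decays with ``decay_tau`` and peaks at exactly w.
    """

    rise_tau: float  # s
    decay_tau: float  # s
    reversal: float  # V
    base_weight: float = 1e-9

    def __post_init__(self) -> None:
        if not 0 < self.rise_tau < self.decay_tau:
            raise ConfigurationError("require 0 < rise_tau < decay_tau")
        if self.base_weight < 0:
            raise ConfigurationError("base_weight must be >= 0")


def synapse_peak_norm(spec: SynapseSpec) -> float:
    """Normalisation factor so a unit-weight event peaks at conductance 1."""
    tr, td = spec.rise_tau, spec.decay_tau
    tp = tr * td / (td - tr) * math.log(td / tr)
    return 1.0 / (math.exp(-tp / td) - math.exp(-tp / tr))


class CompartmentTree:
    """Branched passive morphology in Hines order.

    Parameters are scalars (uniform over the cell) or per-compartment
    sequences.  ``parent[i] == -1`` marks the single root; every other
    compartment satisfies ``parent[i] < i`` so that a single leaf-to-root
    sweep eliminates the implicit-step linear system exactly.
    """

    def __init__(
        self,
        parent: Sequence[int],
        length,
        diameter,
        axial_resistivity,
        membrane_resistivity,
        membrane_capacitance,
        leak_reversal,
    ) -> None:
        self.parent = np.asarray(parent, dtype=np.int64)
        n = self.parent.size
        if not 1 <= n <= 10_000:
            raise ConfigurationError(f"compartment count {n} outside [1, 10000]")
        roots = np.flatnonzero(self.parent < 0)
        if roots.size != 1 or roots[0] != 0:
            raise OrderingError("tree must have exactly one root at index 0")
        if np.any(self.parent[1:] >= np.arange(1, n)):
            raise OrderingError("parent[i] < i violated: tree not in Hines order")

        def _arr(x, name, positive=True):
            a = np.broadcast_to(np.asarray(x, dtype=float), (n,)).copy()
            if positive and np.any(a <= 0):
                raise ConfigurationError(f"{name} must be strictly positive")
            return a

        self.length = _arr(length, "length")
        self.diameter = _arr(diameter, "diameter")
        self.axial_resistivity = _arr(axial_resistivity, "axial_resistivity")
        self.membrane_resistivity = _arr(membrane_resistivity, "membrane_resistivity")
        self.membrane_capacitance = _arr(membrane_capacitance, "membrane_capacitance")
        self.leak_reversal = np.broadcast_to(
            np.asarray(leak_reversal, dtype=float), (n,)
        ).copy()

    @property
    def n_comp(self) -> int:
        return int(self.parent.size)

    def surface_area(self) -> np.ndarray:
        """Open-cylinder membrane area per compartment, m^2."""
        return math.pi * self.diameter * self.length

    def axial_conductance(self) -> np.ndarray:
        """Axial conductance linking each compartment to its parent, S.

        Entry 0 (the root) is 0 by convention.
        """
        g = math.pi * self.diameter**2 / (4.0 * self.axial_resistivity * self.length)
        g[0] = 0.0
        return g

    def leak_conductance(self) -> np.ndarray:
        """Leak conductance per compartment (area / Rm), S."""
        return self.surface_area() / self.membrane_resistivity

    def capacitance(self) -> np.ndarray:
        """Membrane capacitance per compartment, F."""
        return self.surface_area() * self.membrane_capacitance

    def depth(self) -> np.ndarray:
        """Distance (in edges) from the root, per compartment."""
        d = np.zeros(self.n_comp, dtype=np.int64)
        for i in range(1, self.n_comp):
            d[i] = d[self.parent[i]] + 1
        return d

    def to_dict(self) -> dict:
        return {
            "parent": self.parent.tolist(),
            "length": self.length.tolist(),
            "diameter": self.diameter.tolist(),
            "axial_resistivity": self.axial_resistivity.tolist(),
            "membrane_resistivity": self.membrane_resistivity.tolist(),
            "membrane_capacitance": self.membrane_capacitance.tolist(),
            "leak_reversal": self.leak_reversal.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CompartmentTree":
        return cls(**d)


@dataclass
class CellTemplate:
    """Morphology plus per-compartment channel and receptor complement.

    ``comp_class`` labels compartments ('soma', 'proximal', 'distal') for
    the connection rules; ``receptors[c]`` is the ordered receptor-slot
    list for compartment ``c`` (see RECEPTOR_* constants).
    """

    type_name: str
    layer: int
    excitatory: bool
    tree: CompartmentTree
    channels: list[list[ChannelSpec]]
    receptors: list[list[SynapseSpec]]
    soma: int = 0
    comp_class: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        n = self.tree.n_comp
        if not 2 <= self.layer <= 6:
            raise ConfigurationError("layer must be in 2..6")
        if len(self.channels) != n or len(self.receptors) != n:
            raise ConfigurationError("channels/receptors must have one entry per compartment")
        if not 0 <= self.soma < n:
            raise ConfigurationError("soma index out of range")
        for c, chans in enumerate(self.channels):
            if len(chans) > MAX_CHANNELS_PER_COMPARTMENT:
                raise ConfigurationError(
                    f"compartment {c} carries {len(chans)} channels "
                    f"(max {MAX_CHANNELS_PER_COMPARTMENT})"
                )
        if not self.comp_class:
            self.comp_class = ["soma" if i == self.soma else "distal" for i in range(n)]
        if len(self.comp_class) != n:
            raise ConfigurationError("comp_class must have one label per compartment")

    @property
    def n_comp(self) -> int:
        return self.tree.n_comp

    def compartments_of_class(self, label: str) -> np.ndarray:
        return np.flatnonzero(np.asarray(self.comp_class) == label)

    # -- JSON round trip ---------------------------------------------------

    def to_dict(self) -> dict:
        def _rate(r: RateFunction) -> dict:
            return {"form": r.form, "A": r.A, "Vh": r.Vh, "k": r.k}

        def _chan(ch: ChannelSpec) -> dict:
            return {
                "name": ch.name,
                "max_conductance_density": ch.max_conductance_density,
                "reversal": ch.reversal,
                "gates": [
                    {"exponent": g.exponent, "alpha": _rate(g.alpha), "beta": _rate(g.beta)}
                    for g in ch.gates
                ],
            }

        def _syn(s: SynapseSpec) -> dict:
            return {
                "rise_tau": s.rise_tau,
                "decay_tau": s.decay_tau,
                "reversal": s.reversal,
                "base_weight": s.base_weight,
            }

        return {
            "type_name": self.type_name,
            "layer": self.layer,
            "excitatory": self.excitatory,
            "soma": self.soma,
            "comp_class": list(self.comp_class),
            "tree": self.tree.to_dict(),
            "channels": [[_chan(ch) for ch in comp] for comp in self.channels],
            "receptors": [[_syn(s) for s in comp] for comp in self.receptors],
        }

    @classmethod
    def from_dict(cls, d: dict) -> "CellTemplate":
        def _rate(r: dict) -> RateFunction:
            return RateFunction(**r)

        def _chan(c: dict) -> ChannelSpec:
            return ChannelSpec(
                name=c["name"],
                max_conductance_density=c["max_conductance_density"],
                reversal=c["reversal"],
                gates=tuple(
                    GateSpec(g["exponent"], _rate(g["alpha"]), _rate(g["beta"]))
                    for g in c["gates"]
                ),
            )

        return cls(
            type_name=d["type_name"],
            layer=d["layer"],
            excitatory=d["excitatory"],
            tree=CompartmentTree.from_dict(d["tree"]),
            channels=[[_chan(c) for c in comp] for comp in d["channels"]],
            receptors=[[SynapseSpec(**s) for s in comp] for comp in d["receptors"]],
            soma=d["soma"],
            comp_class=list(d["comp_class"]),
        )

    def to_json(self, path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=1, sort_keys=True))

    @classmethod
    def from_json(cls, path) -> "CellTemplate":
        return cls.from_dict(json.loads(Path(path).read_text()))


# ---------------------------------------------------------------------------
# operations


def gate_steady_state(gate: GateSpec, V: float):
    """Steady state and time constant of one gating particle at voltage V.

    Returns ``(x_inf, tau)`` with ``x_inf = alpha / (alpha + beta)`` and
    ``tau = 1 / (alpha + beta)``.  Raises :class:`DegenerateGateError`
    where ``alpha + beta == 0`` (the gate has no dynamics there).
    """
    if not np.all(np.isfinite(V)):
        raise ConfigurationError("V must be finite")
    a = gate.alpha(V)
    b = gate.beta(V)
    s = a + b
    if np.any(np.asarray(s) == 0.0):
        raise DegenerateGateError("alpha + beta == 0: gate time constant undefined")
    return a / s, 1.0 / s


def membrane_current(
    template: CellTemplate,
    compartment: int,
    V: float,
    gate_states: Sequence[Sequence[float]],
    synapse_states: Sequence[tuple[float, float]],
) -> float:
    """Total transmembrane ionic current of one compartment, positive outward.

    ``gate_states[j]`` holds the gate values of channel j on this
    compartment (same order as the template's gate list);
    ``synapse_states[r]`` is the ``(rise, decay)`` state pair of receptor
    slot r, in siemens, so the receptor conductance is
    ``peak_norm * (decay - rise)``.
    """
    chans = template.channels[compartment]
    recs = template.receptors[compartment]
    if len(gate_states) != len(chans):
        raise ConfigurationError(
            f"expected {len(chans)} channel state vectors, got {len(gate_states)}"
        )
    if len(synapse_states) != len(recs):
        raise ConfigurationError(
            f"expected {len(recs)} synapse state pairs, got {len(synapse_states)}"
        )
    area = float(template.tree.surface_area()[compartment])
    e_leak = float(template.tree.leak_reversal[compartment])
    g_leak = float(template.tree.leak_conductance()[compartment])
    current = g_leak * (V - e_leak)
    for ch, states in zip(chans, gate_states):
        if len(states) != len(ch.gates):
            raise ConfigurationError(f"channel {ch.name}: gate state length mismatch")
        open_frac = 1.0
        for gate, x in zip(ch.gates, states):
            if not 0.0 <= x <= 1.0:
                raise ConfigurationError("gate states must lie in [0, 1]")
            open_frac *= x**gate.exponent
        current += ch.max_conductance_density * area * open_frac * (V - ch.reversal)
    for spec, (xr, xd) in zip(recs, synapse_states):
        g = synapse_peak_norm(spec) * (xd - xr)
        current += g * (V - spec.reversal)
    return current


def compartment_positions(template: CellTemplate, origin=(0.0, 0.0, 0.0)) -> np.ndarray:
    """3-D midpoints of every compartment, m.

    A simple deterministic embedding used by the LFP model: the soma sits
    at ``origin`` and each child is stacked along +z above its parent at
    the cable path distance, with a small deterministic XY splay per
    branch so that distinct compartments never coincide.
    """
    tree = template.tree
    n = tree.n_comp
    pos = np.zeros((n, 3))
    # path length from root to compartment midpoint
    path = np.zeros(n)
    for i in range(1, n):
        p = tree.parent[i]
        path[i] = path[p] + 0.5 * (tree.length[p] + tree.length[i])
    for i in range(n):
        angle = 2.399963229728653 * i  # golden-angle splay
        r = 0.15 * path[i]
        pos[i] = (r * math.cos(angle), r * math.sin(angle), path[i])
    return pos + np.asarray(origin, dtype=float)


# standard squid-axon channel pair (SI units, resting potential -65 mV),
# used at the soma of every fixture template so that strong drive input
# reliably evokes action potentials
SQUID_NA = ChannelSpec(
    name="na_squid",
    max_conductance_density=1200.0,  # S/m^2
    reversal=0.050,
    gates=(
        GateSpec(
            3,
            RateFunction("linoid", A=1.0e5, Vh=-0.040, k=0.010),
            RateFunction("exp", A=4000.0, Vh=-0.065, k=-0.018),
        ),
        GateSpec(
            1,
            RateFunction("exp", A=70.0, Vh=-0.065, k=-0.020),
            RateFunction("sigmoid", A=1000.0, Vh=-0.035, k=0.010),
        ),
    ),
)

SQUID_K = ChannelSpec(
    name="k_squid",
    max_conductance_density=360.0,  # S/m^2
    reversal=-0.077,
    gates=(
        GateSpec(
            4,
            RateFunction("linoid", A=1.0e4, Vh=-0.055, k=0.010),
            RateFunction("exp", A=125.0, Vh=-0.065, k=-0.080),
        ),
    ),
)
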