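"""Seeded generator of synthetic cell templates and connection rules.

The thalamocortical model family this benchmark network emulates keeps
its channel kinetics and anatomical probability tables in external
model archives; this generator reproduces the *structure* of that
model — 12 cell types (6 excitatory, 6 inhibitory) across layers 2-6,
50-74 compartments per cell, up to 14 voltage-gated channels per
compartment, a 61-neuron microcolumn with every type present — with
synthetic parameters drawn reproducibly from a seed.  It makes no claim
of fidelity to the published channel parameters.

Every soma carries the classic squid-axon Na/K pair so that a strong
drive event reliably evokes an action potential; the remaining channels
are randomly parameterised modulatory conductances from the standard
exponential/sigmoid/linoid rate family with small peak densities.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path

import numpy as np

from .cells import (
    SQUID_K,
    SQUID_NA,
    CellTemplate,
    ChannelSpec,
    CompartmentTree,
    GateSpec,
    RateFunction,
    SynapseSpec,
)
from .network import Microcolumn, ConnectionRule
from .stimulus import DEFAULT_DRIVE_WEIGHT

__all__ = ["FixtureSet", "generate_fixture_set", "CELL_TYPES"]

# (name, layer, excitatory) for the 12 types: 6 excitatory pyramidal-like,
# 6 inhibitory interneuron-like, spanning cortical layers 2-6
CELL_TYPES = [
    ("pyr_l2", 2, True),
    ("pyr_l3", 3, True),
    ("pyr_l4", 4, True),
    ("pyr_l5a", 5, True),
    ("pyr_l5b", 5, True),
    ("pyr_l6", 6, True),
    ("bask_l2", 2, False),
    ("bask_l3", 3, False),
    ("bask_l4", 4, False),
    ("bask_l5", 5, False),
    ("bask_l6", 6, False),
    ("chand_l23", 3, False),
]

# fixed 61-slot microcolumn composition (sums to 61, every type present;
# pyramidal-heavy as in cortex)
COLUMN_COMPOSITION = {
    "pyr_l2": 10, "pyr_l3": 8, "pyr_l4": 8, "pyr_l5a": 7, "pyr_l5b": 6, "pyr_l6": 5,
    "bask_l2": 4, "bask_l3": 3, "bask_l4": 3, "bask_l5": 3, "bask_l6": 2, "chand_l23": 2,
}

TARGET_CLASSES = ("soma", "proximal", "distal")

# receptor kinetics: slot 0 excitatory, slot 1 inhibitory, slot 2 drive (soma)
_EXC_RECEPTOR = SynapseSpec(rise_tau=0.5e-3, decay_tau=3e-3, reversal=0.0)
_INH_RECEPTOR = SynapseSpec(rise_tau=1e-3, decay_tau=8e-3, reversal=-0.080)
_DRIVE_RECEPTOR = SynapseSpec(
    rise_tau=0.2e-3, decay_tau=1.5e-3, reversal=0.05, base_weight=DEFAULT_DRIVE_WEIGHT
)


@dataclass
class FixtureSet:
    """The 12 templates, the microcolumn and the base connection rules."""

    templates: dict[str, CellTemplate]
    column: Microcolumn
    rules: list[ConnectionRule]
    seed: int

    def write(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, t in self.templates.items():
            t.to_json(outdir / f"{name}.json")
        (outdir / "microcolumn.json").write_text(
            json.dumps({"slot_types": self.column.slot_types}, indent=1)
        )
        (outdir / "rules.json").write_text(
            json.dumps(
                [
                    {
                        "source_type": r.source_type,
                        "source_class": r.source_class,
                        "target_type": r.target_type,
                        "target_class": r.target_class,
                        "p0": r.p0,
                    }
                    for r in self.rules
                ],
                indent=1,
            )
        )


def _random_rate(rng: np.random.Generator) -> RateFunction:
    form = rng.choice(["exp", "sigmoid", "linoid"])
    if form == "linoid":
        return RateFunction(
            "linoid",
            A=float(rng.uniform(1e3, 5e4)),
            Vh=float(rng.uniform(-0.070, -0.020)),
            k=float(rng.uniform(0.005, 0.020)),
        )
    k = float(rng.uniform(0.005, 0.030)) * (1 if rng.random() < 0.5 else -1)
    return RateFunction(
        form,
        A=float(rng.uniform(10.0, 500.0)),
        Vh=float(rng.uniform(-0.080, -0.020)),
        k=k,
    )


def _modulatory_channel(rng: np.random.Generator, idx: int) -> ChannelSpec:
    reversal = float(rng.choice([-0.090, -0.077, -0.030, 0.050]))
    gates = tuple(
        GateSpec(int(rng.integers(1, 4)), _random_rate(rng), _random_rate(rng))
        for _ in range(int(rng.integers(1, 3)))
    )
    return ChannelSpec(
        name=f"mod_{idx}",
        max_conductance_density=float(rng.uniform(0.05, 1.5)),
        reversal=reversal,
        gates=gates,
    )


def _make_template(name: str, layer: int, excitatory: bool,
                   rng: np.random.Generator) -> CellTemplate:
    n = int(rng.integers(50, 75))
    parent = [-1]
    for i in range(1, n):
        # mostly chain-like with occasional branching: realistic depth range
        parent.append(i - 1 if rng.random() < 0.7 else int(rng.integers(0, i)))
    length = np.concatenate([[30e-6], rng.uniform(30e-6, 120e-6, n - 1)])
    diameter = np.concatenate([[20e-6], rng.uniform(1e-6, 3e-6, n - 1)])
    tree = CompartmentTree(
        parent=parent,
        length=length,
        diameter=diameter,
        axial_resistivity=1.0,
        membrane_resistivity=float(rng.uniform(0.5, 2.0)),
        membrane_capacitance=0.01,
        leak_reversal=-0.065,
    )
    depth = tree.depth()
    split = max(1, int(np.median(depth[1:]))) if n > 1 else 1
    comp_class = [
        "soma" if i == 0 else ("proximal" if depth[i] <= split else "distal")
        for i in range(n)
    ]
    # guarantee both dendritic classes exist
    if "distal" not in comp_class[1:]:
        comp_class[n - 1] = "distal"
    if "proximal" not in comp_class[1:]:
        comp_class[1] = "proximal"

    # one modulatory channel set per compartment class, count ~ U[4, 14]
    class_channels: dict[str, list[ChannelSpec]] = {}
    for cls in TARGET_CLASSES:
        n_mod = int(rng.integers(4, 15))
        if cls == "soma":
            n_mod = min(n_mod, 12)  # soma also carries the Na/K pair
        class_channels[cls] = [_modulatory_channel(rng, j) for j in range(n_mod)]

    channels = []
    receptors = []
    for i in range(n):
        cls = comp_class[i]
        chans = list(class_channels[cls])
        if i == 0:
            chans = [SQUID_NA, SQUID_K] + chans
        channels.append(chans)
        recs = [_EXC_RECEPTOR, _INH_RECEPTOR]
        if i == 0:
            recs.append(_DRIVE_RECEPTOR)
        receptors.append(recs)

    return CellTemplate(
        type_name=name,
        layer=layer,
        excitatory=excitatory,
        tree=tree,
        channels=channels,
        receptors=receptors,
        soma=0,
        comp_class=comp_class,
    )


def generate_fixture_set(seed: int) -> FixtureSet:
    """Deterministically generate the 12 templates, column and rule table."""
    templates: dict[str, CellTemplate] = {}
    for name, layer, exc in CELL_TYPES:
        # independent stream per type keeps templates stable under reordering
        rng = np.random.default_rng(
            np.random.SeedSequence(entropy=int(seed), spawn_key=(3, CELL_TYPES.index((name, layer, exc))))
        )
        templates[name] = _make_template(name, layer, exc, rng)

    slot_types: list[str] = []
    for name, _, _ in CELL_TYPES:
        slot_types.extend([name] * COLUMN_COMPOSITION[name])
    column = Microcolumn(slot_types)

    rule_rng = np.random.default_rng(np.random.SeedSequence(entropy=int(seed), spawn_key=(4,)))
    rules = []
    for s_name, _, _ in CELL_TYPES:
        for t_name, _, _ in CELL_TYPES:
            for cls in TARGET_CLASSES:
                # near-uniform base probabilities; the density-preserving
                # scaling sets the absolute level for a given K and N
                rules.append(
                    ConnectionRule(
                        source_type=s_name,
                        source_class="soma",
                        target_type=t_name,
                        target_class=cls,
                        p0=float(rule_rng.uniform(0.10, 0.14)),
                    )
                )
    return FixtureSet(templates=templates, column=column, rules=rules, seed=int(seed))
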