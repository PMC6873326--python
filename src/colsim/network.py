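"""Microcolumn tiling and reproducible probabilistic connectivity.

Networks are tilings of a 61-neuron microcolumn in the XY plane.
Connection probabilities are distance-independent and are rescaled by a
single factor so that the expected number of synapses per neuron stays
at a target K as the network grows.

Reproducibility is the central contract here: the uniform variate that
decides each candidate connection is a *pure function* of
``(seed, rule index, source gid, target gid)``, generated from a
counter-based keyed stream rather than one shared sequential stream.
The realised table is therefore identical no matter how candidate pairs
are enumerated or how the population is partitioned across ranks.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import CellTemplate
from .errors import ConfigurationError

__all__ = [
    "Microcolumn",
    "ConnectionRule",
    "ConnectionTable",
    "Population",
    "NEURONS_PER_COLUMN",
    "tile_network",
    "scale_probabilities",
    "probability_scale_factor",
    "expected_synapse_count",
    "connect",
    "pair_uniforms",
    "DEFAULT_DELAY",
    "DEFAULT_WEIGHT",
    "DEFAULT_COLUMN_SPACING",
]

NEURONS_PER_COLUMN = 61
DEFAULT_DELAY = 1e-3  # s; 40 steps at the default 25 us step
DEFAULT_WEIGHT = 1e-9  # arb. conductance units, the near-zero recurrent weight
DEFAULT_COLUMN_SPACING = 50e-6  # m between microcolumn centres

TABLE_COLUMNS = ["src_gid", "dst_gid", "dst_comp", "weight", "delay_s"]


@dataclass
class Microcolumn:
    """The repeating 61-neuron unit: an ordered list of cell-type slots."""

    slot_types: list[str]

    def __post_init__(self) -> None:
        if len(self.slot_types) != NEURONS_PER_COLUMN:
            raise ConfigurationError(
                f"a microcolumn has exactly {NEURONS_PER_COLUMN} neuron slots, "
                f"got {len(self.slot_types)}"
            )

    def type_counts(self) -> dict[str, int]:
        counts: dict[str, int] = {}
        for t in self.slot_types:
            counts[t] = counts.get(t, 0) + 1
        return counts

    def validate_against(self, templates: dict[str, CellTemplate]) -> None:
        missing = set(templates) - set(self.slot_types)
        unknown = set(self.slot_types) - set(templates)
        if unknown:
            raise ConfigurationError(f"column references unknown cell types {sorted(unknown)}")
        if missing:
            raise ConfigurationError(f"column omits cell types {sorted(missing)}")


@dataclass(frozen=True)
class ConnectionRule:
    """Distance-independent connection probability for one (source, target) class pair."""

    source_type: str
    source_class: str
    target_type: str
    target_class: str
    p0: float

    def __post_init__(self) -> None:
        if not 0.0 <= self.p0 <= 1.0:
            raise ConfigurationError("base probability p0 must lie in [0, 1]")

    def scaled(self, factor: float) -> "ConnectionRule":
        return ConnectionRule(
            self.source_type,
            self.source_class,
            self.target_type,
            self.target_class,
            min(1.0, self.p0 * factor),
        )


class Population:
    """Neurons produced by tiling microcolumns on a regular XY grid.

    gids are assigned column-major over grid position (x outer, y inner),
    then by slot order within each column, so gid
    ``= column_index * 61 + slot``.
    """

    def __init__(
        self,
        templates: dict[str, CellTemplate],
        column: Microcolumn,
        nx: int,
        ny: int,
        spacing: float = DEFAULT_COLUMN_SPACING,
    ) -> None:
        column.validate_against(templates)
        self.templates = templates
        self.column = column
        self.nx, self.ny = nx, ny
        self.spacing = spacing
        self.n_columns = nx * ny
        self.n_neurons = self.n_columns * NEURONS_PER_COLUMN
        self.type_of_gid = np.asarray(column.slot_types * self.n_columns)
        self.column_of_gid = np.repeat(np.arange(self.n_columns), NEURONS_PER_COLUMN)
        cx = np.repeat(np.arange(nx), ny) * spacing
        cy = np.tile(np.arange(ny), nx) * spacing
        self.column_xy = np.column_stack([cx, cy])

    def gids_of_type(self, type_name: str) -> np.ndarray:
        return np.flatnonzero(self.type_of_gid == type_name)

    def template_of_gid(self, gid: int) -> CellTemplate:
        return self.templates[self.type_of_gid[gid]]

    def type_counts(self) -> dict[str, int]:
        counts = self.column.type_counts()
        return {k: v * self.n_columns for k, v in counts.items()}

    def neuron_xy(self, gid: int) -> np.ndarray:
        """XY position of a neuron: its column centre plus a small slot offset."""
        col = self.column_of_gid[gid]
        slot = gid % NEURONS_PER_COLUMN
        # deterministic sub-column splay so somata never coincide
        angle = 2.399963229728653 * slot
        r = 0.2 * self.spacing * np.sqrt(slot / NEURONS_PER_COLUMN)
        return self.column_xy[col] + np.array([r * np.cos(angle), r * np.sin(angle)])


class ConnectionTable:
    """Realised synapses, one row per (source gid, target gid, target compartment).

    Rows are kept sorted by (src_gid, dst_gid, dst_comp); self-connections
    are forbidden and multiple synapses between a pair must land on
    distinct target compartments.
    """

    def __init__(self, df: pd.DataFrame, n_neurons: int | None = None) -> None:
        df = df.reset_index(drop=True)[TABLE_COLUMNS].astype(
            {"src_gid": np.int64, "dst_gid": np.int64, "dst_comp": np.int64,
             "weight": float, "delay_s": float}
        )
        df = df.sort_values(["src_gid", "dst_gid", "dst_comp"], kind="mergesort")
        df = df.drop_duplicates(["src_gid", "dst_gid", "dst_comp"]).reset_index(drop=True)
        if len(df):
            if (df["src_gid"] == df["dst_gid"]).any():
                raise ConfigurationError("self-connections are not allowed")
            if (df["delay_s"] <= 0).any():
                raise ConfigurationError("delays must be > 0")
            if n_neurons is not None:
                if df["src_gid"].min() < 0 or df[["src_gid", "dst_gid"]].to_numpy().max() >= n_neurons:
                    raise ConfigurationError("gid out of range in connection table")
        self.df = df

    def __len__(self) -> int:
        return len(self.df)

    def __eq__(self, other) -> bool:
        return isinstance(other, ConnectionTable) and self.df.equals(other.df)

    @classmethod
    def empty(cls) -> "ConnectionTable":
        return cls(pd.DataFrame(columns=TABLE_COLUMNS))

    def out_degree(self, n_neurons: int) -> np.ndarray:
        deg = np.zeros(n_neurons, dtype=np.int64)
        np.add.at(deg, self.df["src_gid"].to_numpy(), 1)
        return deg

    def to_tsv(self, path) -> None:
        self.df.to_csv(path, sep="\t", index=False)

    @classmethod
    def from_tsv(cls, path) -> "ConnectionTable":
        return cls(pd.read_csv(path, sep="\t", float_precision="round_trip"))


# ---------------------------------------------------------------------------
# operations


def tile_network(
    nx: int,
    ny: int,
    column_template: Microcolumn,
    templates: dict[str, CellTemplate],
    spacing: float = DEFAULT_COLUMN_SPACING,
) -> Population:
    """Repeat the microcolumn on an nx-by-ny grid; gids are deterministic."""
    if nx < 1 or ny < 1:
        raise ConfigurationError("nx and ny must be >= 1")
    return Population(templates, column_template, nx, ny, spacing)


def _expected_total_synapses(
    rules: list[ConnectionRule], N: int, type_counts: dict[str, int] | None
) -> float:
    """Expected synapse count over the whole population under unscaled rules."""
    total = 0.0
    for r in rules:
        if type_counts is None:
            n_src, n_tgt, same = N, N, True
        else:
            n_src = type_counts.get(r.source_type, 0)
            n_tgt = type_counts.get(r.target_type, 0)
            same = r.source_type == r.target_type
        pairs = n_src * n_tgt - (n_src if same else 0)
        total += r.p0 * max(pairs, 0)
    return total


def probability_scale_factor(
    rules: list[ConnectionRule],
    N: int,
    K_target: float,
    type_counts: dict[str, int] | None = None,
) -> float:
    """The single factor f with which every p0 is multiplied so the
    expected out-degree equals K_target at population size N."""
    if N < 2:
        raise ConfigurationError("N must be >= 2")
    if K_target <= 0:
        raise ConfigurationError("K_target must be > 0")
    k_expected = _expected_total_synapses(rules, N, type_counts) / N
    if k_expected <= 0:
        raise ConfigurationError("rules give zero expected connectivity")
    return K_target / k_expected


def scale_probabilities(
    rules: list[ConnectionRule],
    N: int,
    K_target: float,
    type_counts: dict[str, int] | None = None,
) -> list[ConnectionRule]:
    """Rescale all base probabilities by one density-preserving factor.

    Every ``p0`` is multiplied by ``f = K_target / K_expected(N)`` and
    clamped at 1.  If clamping occurs the expected degree falls short of
    ``K_target``; a warning reports the achievable value.
    """
    f = probability_scale_factor(rules, N, K_target, type_counts)
    scaled = [r.scaled(f) for r in rules]
    if any(r.p0 * f > 1.0 for r in rules):
        k_achievable = _expected_total_synapses(scaled, N, type_counts) / N
        warnings.warn(
            f"probability scaling clamped at p=1; achievable expected "
            f"out-degree {k_achievable:.1f} < target {K_target:.1f}",
            stacklevel=2,
        )
    return scaled


def expected_synapse_count(N: int, K: float) -> float:
    """Total synapses in a network of N neurons at K synapses per neuron."""
    if N <= 0 or K <= 0:
        raise ConfigurationError("N and K must be > 0")
    return float(N) * float(K)


def pair_uniforms(seed: int, rule_index: int, src_gid: int, n_neurons: int) -> np.ndarray:
    """The (2, n_neurons) block of uniforms keyed by (seed, rule, source).

    Row 0 decides acceptance for each candidate target gid; row 1 picks
    the target compartment within the rule's compartment class.  Keying
    the stream on (seed, rule, source) and indexing it by target gid
    makes each variate a pure function of (seed, rule, src, tgt),
    independent of enumeration or partition order.
    """
    # domain tag 2 = connectivity; keeps these streams disjoint from the
    # Poisson-drive streams (tag 1) derived from the same run seed
    ss = np.random.SeedSequence(
        entropy=int(seed), spawn_key=(2, int(rule_index), int(src_gid))
    )
    return np.random.default_rng(ss).random((2, n_neurons))


def connect(
    population: Population,
    rules: list[ConnectionRule],
    seed: int,
    weight: float | None = None,
    delay: float = DEFAULT_DELAY,
) -> ConnectionTable:
    """Realise the probabilistic connectivity; a pure function of
    (seed, rules, population).

    For every ordered candidate pair (src, tgt) matching a rule, a
    connection exists iff the pair's keyed uniform variate is below the
    rule's (scaled) probability.  The target compartment is drawn from
    the rule's target compartment class with a second keyed variate.
    ``weight=None`` uses the base weight of the target receptor slot.
    """
    N = population.n_neurons
    rows: list[pd.DataFrame] = []
    for ri, rule in enumerate(rules):
        if rule.p0 <= 0.0:
            continue
        src_gids = population.gids_of_type(rule.source_type)
        tgt_gids = population.gids_of_type(rule.target_type)
        if src_gids.size == 0 or tgt_gids.size == 0:
            continue
        tmpl = population.templates[rule.target_type]
        class_comps = tmpl.compartments_of_class(rule.target_class)
        if class_comps.size == 0:
            continue
        src_exc = population.templates[rule.source_type].excitatory
        slot = 0 if src_exc else 1
        if weight is None:
            w = tmpl.receptors[int(class_comps[0])][slot].base_weight
        else:
            w = weight
        for src in src_gids:
            u = pair_uniforms(seed, ri, int(src), N)
            accept = u[0, tgt_gids] < rule.p0
            chosen = tgt_gids[accept]
            chosen = chosen[chosen != src]
            if chosen.size == 0:
                continue
            comp_pick = class_comps[
                np.minimum(
                    (u[1, chosen] * class_comps.size).astype(np.int64),
                    class_comps.size - 1,
                )
            ]
            rows.append(
                pd.DataFrame(
                    {
                        "src_gid": np.full(chosen.size, src, dtype=np.int64),
                        "dst_gid": chosen,
                        "dst_comp": comp_pick,
                        "weight": np.full(chosen.size, w, dtype=float),
                        "delay_s": np.full(chosen.size, delay, dtype=float),
                    }
                )
            )
    if not rows:
        return ConnectionTable.empty()
    return ConnectionTable(pd.concat(rows, ignore_index=True), n_neurons=N)
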