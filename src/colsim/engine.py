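"""End-to-end simulation driver.

``Simulation`` binds a population, its connection table, a partition
map, the Poisson drive and the recorders, and advances everything with
the Crank-Nicolson/Hines solver.  Logical ranks execute sequentially,
but spike exchange goes through the same routing and delivery-queue
contracts a message-passing backend would use, and deliveries are
re-merged into one globally sorted order before they touch the state,
so results are bit-identical no matter how the columns are partitioned.

``run_simulation`` is the configuration-driven entry point: it builds
the fixture set from the run seed, tiles and connects the network, runs
it, and writes spikes (TSV), traces (CSV) and a JSON report.
"""

from __future__ import annotations

import json
import time as _time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .cells import RECEPTOR_DRIVE, compartment_positions
from .config import RunConfig
from .errors import ConfigurationError
from .fixtures import generate_fixture_set
from .network import (
    ConnectionTable,
    Population,
    connect,
    scale_probabilities,
    tile_network,
)
from .partition import (
    DELIVERY_DTYPE,
    DeliveryQueue,
    ExchangeStats,
    PartitionMap,
    SpikeEvent,
    assign_partitions,
    deliver,
    route_spikes,
)
from .recording import LFPConfig, electrode_weights, write_spikes_tsv, write_trace_csv
from .solver import compile_forest, detect_spikes, initial_state, step_forest
from .stimulus import PoissonDrive

__all__ = ["Simulation", "SimulationResult", "run_simulation"]


@dataclass
class SimulationResult:
    """Everything one run produced."""

    spikes: pd.DataFrame  # columns gid, time_s
    lfp: np.ndarray | None
    lfp_time: np.ndarray | None
    v_traces: dict[int, np.ndarray]
    trace_time: np.ndarray
    stats: ExchangeStats
    final_state: object
    timings: dict = field(default_factory=dict)

    @property
    def n_spikes(self) -> int:
        return len(self.spikes)

    def mean_rate(self, n_neurons: int, duration: float) -> float:
        return self.n_spikes / (n_neurons * duration)


class Simulation:
    """A compiled, connected network ready to integrate."""

    def __init__(
        self,
        population: Population,
        table: ConnectionTable,
        pmap: PartitionMap,
        dt: float,
        drive: PoissonDrive | None = None,
        lfp: LFPConfig | None = None,
        record_v_gids: list[int] | None = None,
        spike_threshold: float = 0.0,
    ) -> None:
        self.population = population
        self.table = table
        self.pmap = pmap
        self.dt = float(dt)
        self.drive = drive
        self.spike_threshold = float(spike_threshold)
        self.record_v_gids = list(record_v_gids or [])

        templates = [population.template_of_gid(g) for g in range(population.n_neurons)]
        self.forest = compile_forest(templates)

        # receptor addressing: receptors of a compartment are contiguous in
        # slot order, so slot r of (gid, comp) sits at first_rec[comp]+r
        self.first_rec_of_comp = np.searchsorted(self.forest.rec_comp,
                                                 np.arange(self.forest.n_comp))
        self.exc_of_gid = np.array(
            [population.template_of_gid(g).excitatory for g in range(population.n_neurons)]
        )

        self.lfp_cfg = lfp
        self.lfp_weights = None
        if lfp is not None:
            pos = np.concatenate(
                [
                    compartment_positions(
                        templates[g],
                        origin=(*population.neuron_xy(g), 0.0),
                    )
                    for g in range(population.n_neurons)
                ]
            )
            self.positions = pos
            self.lfp_weights = electrode_weights(pos, lfp)

    # -- helpers -----------------------------------------------------------

    def _receptor_index(self, dst_gid: np.ndarray, dst_comp: np.ndarray,
                        slot: np.ndarray) -> np.ndarray:
        comp_global = self.forest.comp_offset[dst_gid] + dst_comp
        return self.first_rec_of_comp[comp_global] + slot

    def _drive_schedule(self, n_steps: int) -> dict[int, np.ndarray]:
        """step -> sorted array of drive-receptor indices hit at that step."""
        if self.drive is None or self.drive.rate == 0:
            return {}
        per_step: dict[int, list[int]] = {}
        duration = n_steps * self.dt
        soma_comp = self.forest.soma  # global soma compartment per cell
        for gid in range(self.population.n_neurons):
            rec = self.first_rec_of_comp[soma_comp[gid]] + RECEPTOR_DRIVE
            for s in self.drive.event_steps(gid, duration, self.dt):
                per_step.setdefault(int(s), []).append(int(rec))
        return {s: np.asarray(sorted(v), dtype=np.int64) for s, v in per_step.items()}

    # -- main loop ---------------------------------------------------------

    def run(self, duration: float) -> SimulationResult:
        n_steps = int(round(duration / self.dt))
        if n_steps < 1:
            raise ConfigurationError("duration must cover at least one step")
        forest = self.forest
        state = initial_state(forest)
        queues = {r: DeliveryQueue() for r in range(self.pmap.n_ranks)}
        stats = ExchangeStats.zeros(self.pmap.n_ranks)
        drive_sched = self._drive_schedule(n_steps)
        drive_w = self.drive.weight if self.drive is not None else 0.0

        lfp = np.empty(n_steps) if self.lfp_weights is not None else None
        v_rec = {g: np.empty(n_steps) for g in self.record_v_gids}
        spike_gids: list[int] = []
        spike_steps: list[int] = []

        for s in range(n_steps):
            # merge this step's synaptic deliveries across ranks and re-sort
            # globally so the application order is partition-independent
            chunks = [deliver(queues[r], s) for r in sorted(queues)]
            chunks = [c for c in chunks if len(c)]
            rec_idx = np.empty(0, dtype=np.int64)
            weights = np.empty(0)
            if chunks:
                entries = np.concatenate(chunks)
                entries = entries[
                    np.argsort(entries, order=("src_gid", "dst_gid", "dst_comp"),
                               kind="stable")
                ]
                slot = np.where(self.exc_of_gid[entries["src_gid"]], 0, 1)
                rec_idx = self._receptor_index(entries["dst_gid"], entries["dst_comp"], slot)
                weights = entries["weight"].copy()
            if s in drive_sched:
                didx = drive_sched[s]
                rec_idx = np.concatenate([didx, rec_idx])
                weights = np.concatenate([np.full(didx.size, drive_w), weights])

            new_state, i_mem = step_forest(forest, state, self.dt, (rec_idx, weights))

            gids = detect_spikes(
                state.V[forest.soma], new_state.V[forest.soma], self.spike_threshold
            )
            if gids:
                events = [SpikeEvent(g, s + 1) for g in gids]
                route_spikes(events, self.table, self.pmap, self.dt, queues, stats)
                spike_gids.extend(gids)
                spike_steps.extend([s + 1] * len(gids))

            if lfp is not None:
                lfp[s] = i_mem @ self.lfp_weights
            for g in self.record_v_gids:
                v_rec[g][s] = new_state.V[forest.soma[g]]
            state = new_state

        t = self.dt * np.arange(1, n_steps + 1)
        spikes = pd.DataFrame(
            {"gid": np.asarray(spike_gids, dtype=np.int64),
             "time_s": self.dt * np.asarray(spike_steps, dtype=float)}
        ).sort_values(["time_s", "gid"], kind="mergesort").reset_index(drop=True)
        return SimulationResult(
            spikes=spikes,
            lfp=lfp,
            lfp_time=t if lfp is not None else None,
            v_traces=v_rec,
            trace_time=t,
            stats=stats,
            final_state=state,
        )


def build_simulation(config: RunConfig):
    """Construct the fixture set, population, scaled connectivity, partition
    map and Simulation for a run configuration."""
    fx = generate_fixture_set(config.seed)
    population = tile_network(
        config.nx, config.ny, fx.column, fx.templates, spacing=config.column_spacing
    )
    rules = scale_probabilities(
        fx.rules, population.n_neurons, config.k_per_neuron, population.type_counts()
    )
    table = connect(
        population, rules, config.seed,
        weight=config.recurrent_weight, delay=config.delay,
    )
    pmap = assign_partitions(config.n_columns, config.ranks, config.columns_per_rank)
    drive = PoissonDrive(rate=config.drive_rate, weight=config.drive_weight,
                         seed=config.seed)
    lfp = LFPConfig(position=config.lfp_electrode, sigma=config.lfp_sigma) \
        if config.record_lfp else None
    sim = Simulation(
        population, table, pmap, config.dt,
        drive=drive, lfp=lfp,
        record_v_gids=config.record_v_gids,
        spike_threshold=config.spike_threshold,
    )
    return sim, table, fx


def run_simulation(config: RunConfig, outdir) -> Path:
    """Run one configured simulation and write its outputs.

    Writes ``connections.tsv``, ``spikes.tsv``, ``lfp.csv``, one
    ``v_<gid>.csv`` per recorded neuron and ``report.json`` into
    ``outdir``; all outputs are a pure function of (config, seed).
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    t0 = _time.perf_counter()
    sim, table, _ = build_simulation(config)
    t_setup = _time.perf_counter() - t0

    t0 = _time.perf_counter()
    result = sim.run(config.duration)
    t_run = _time.perf_counter() - t0

    table.to_tsv(outdir / "connections.tsv")
    write_spikes_tsv(outdir / "spikes.tsv", result.spikes["gid"], result.spikes["time_s"])
    if result.lfp is not None:
        write_trace_csv(outdir / "lfp.csv", result.lfp_time, result.lfp, "lfp_v")
    for g, trace in result.v_traces.items():
        write_trace_csv(outdir / f"v_{g}.csv", result.trace_time, trace, "soma_v")
    report = {
        "config": config.to_dict(),
        "n_neurons": sim.population.n_neurons,
        "n_synapses": len(table),
        "n_spikes": result.n_spikes,
        "mean_rate_hz": result.mean_rate(sim.population.n_neurons, config.duration),
        "timings": {"setup_s": t_setup, "run_s": t_run},
        "exchange": result.stats.to_dict(),
    }
    (outdir / "report.json").write_text(json.dumps(report, indent=1, sort_keys=True))
    return outdir
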