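"""Partitioning of microcolumns onto logical ranks and spike routing.

Ranks are *logical*: they execute sequentially in-process, but spike
exchange honours the same contracts a message-passing backend would —
deterministic delivery order, per-rank send/receive accounting with
overflow-safe (64-bit) counters, and exact conservation of
(spike x out-degree) deliveries.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .errors import PartitioningError, RoutingError, SchedulingError
from .network import NEURONS_PER_COLUMN, ConnectionTable

__all__ = [
    "PartitionMap",
    "SpikeEvent",
    "ExchangeStats",
    "DeliveryQueue",
    "assign_partitions",
    "route_spikes",
    "deliver",
    "table_rows_per_rank",
]

DELIVERY_DTYPE = np.dtype(
    [
        ("step", np.int64),
        ("src_gid", np.int64),
        ("dst_gid", np.int64),
        ("dst_comp", np.int64),
        ("weight", np.float64),
    ]
)


@dataclass(frozen=True)
class SpikeEvent:
    """A spike of one neuron at one integration step."""

    source_gid: int
    step: int

    def __post_init__(self) -> None:
        if self.step < 0:
            raise PartitioningError("spike step must be >= 0")


@dataclass
class PartitionMap:
    """Assignment of microcolumns to logical ranks (contiguous blocks)."""

    rank_of_column: np.ndarray
    per_rank: int

    @property
    def n_ranks(self) -> int:
        return int(self.rank_of_column.max()) + 1 if self.rank_of_column.size else 0

    @property
    def neurons_per_rank(self) -> int:
        return NEURONS_PER_COLUMN * self.per_rank

    def rank_of_gid(self, gid) -> np.ndarray:
        gid = np.asarray(gid, dtype=np.int64)
        col = gid // NEURONS_PER_COLUMN
        if np.any(col < 0) or np.any(col >= self.rank_of_column.size):
            raise RoutingError("gid outside the partitioned population")
        return self.rank_of_column[col]

    def gids_of_rank(self, rank: int) -> np.ndarray:
        cols = np.flatnonzero(self.rank_of_column == rank)
        return (
            cols[:, None] * NEURONS_PER_COLUMN + np.arange(NEURONS_PER_COLUMN)[None, :]
        ).ravel()


@dataclass
class ExchangeStats:
    """Per-rank counts of remote spike messages, with 64-bit counters.

    The counters deliberately use a width that cannot wrap at the
    message volumes reachable here (the historical failure mode was
    16-bit counters wrapping near 4.9 million synapses per rank).
    """

    sent: np.ndarray
    received: np.ndarray

    @classmethod
    def zeros(cls, n_ranks: int) -> "ExchangeStats":
        return cls(
            sent=np.zeros(n_ranks, dtype=np.int64),
            received=np.zeros(n_ranks, dtype=np.int64),
        )

    def to_dict(self) -> dict:
        return {"sent": self.sent.tolist(), "received": self.received.tolist()}


class DeliveryQueue:
    """Future synaptic deliveries for one rank, bucketed by step."""

    def __init__(self) -> None:
        self._by_step: dict[int, list[np.ndarray]] = {}
        self.total_enqueued = 0
        self.total_delivered = 0

    def push(self, entries: np.ndarray) -> None:
        for step in np.unique(entries["step"]):
            self._by_step.setdefault(int(step), []).append(entries[entries["step"] == step])
        self.total_enqueued += len(entries)

    def pop(self, step: int) -> np.ndarray:
        overdue = [s for s in self._by_step if s < step]
        if overdue:
            raise SchedulingError(
                f"delivery queue holds past-due entries for step {min(overdue)} "
                f"while delivering step {step}"
            )
        chunks = self._by_step.pop(step, [])
        if not chunks:
            return np.empty(0, dtype=DELIVERY_DTYPE)
        out = np.concatenate(chunks)
        out = out[np.argsort(out, order=("step", "src_gid", "dst_gid", "dst_comp"),
                             kind="stable")]
        self.total_delivered += len(out)
        return out

    def pending(self) -> int:
        return self.total_enqueued - self.total_delivered


# ---------------------------------------------------------------------------
# operations


def assign_partitions(columns: int, ranks: int, per_rank: int) -> PartitionMap:
    """Contiguous blocks of ``per_rank`` microcolumns per rank, in gid order."""
    n_columns = columns if isinstance(columns, int) else len(columns)
    if n_columns != ranks * per_rank:
        raise PartitioningError(
            f"{n_columns} microcolumns cannot be split onto {ranks} ranks "
            f"of {per_rank} columns each"
        )
    return PartitionMap(
        rank_of_column=np.repeat(np.arange(ranks, dtype=np.int64), per_rank),
        per_rank=per_rank,
    )


def route_spikes(
    events: list[SpikeEvent],
    table: ConnectionTable,
    pmap: PartitionMap,
    dt: float,
    queues: dict[int, DeliveryQueue] | None = None,
    stats: ExchangeStats | None = None,
):
    """Fan each spike out along its synapses into per-rank delivery queues.

    Every (event, synapse) pair becomes one delivery at step
    ``emission + round(delay / dt)`` on the rank owning the target gid.
    Delays are rounded to the nearest step; a warning is emitted if the
    rounding is not exact.  Returns ``(queues, stats)``.
    """
    if queues is None:
        queues = {r: DeliveryQueue() for r in range(pmap.n_ranks)}
    if stats is None:
        stats = ExchangeStats.zeros(pmap.n_ranks)
    if not events:
        return queues, stats

    df = table.df
    src_sorted = df["src_gid"].to_numpy()
    for ev in events:
        src_rank = int(pmap.rank_of_gid(ev.source_gid))
        lo = np.searchsorted(src_sorted, ev.source_gid, side="left")
        hi = np.searchsorted(src_sorted, ev.source_gid, side="right")
        if lo == hi:
            continue
        rows = df.iloc[lo:hi]
        delay_steps = np.rint(rows["delay_s"].to_numpy() / dt).astype(np.int64)
        if np.any(np.abs(delay_steps * dt - rows["delay_s"].to_numpy()) > 1e-12):
            warnings.warn("synaptic delays rounded to the nearest step", stacklevel=2)
        if np.any(delay_steps < 1):
            delay_steps = np.maximum(delay_steps, 1)
        entries = np.empty(hi - lo, dtype=DELIVERY_DTYPE)
        entries["step"] = ev.step + delay_steps
        entries["src_gid"] = ev.source_gid
        entries["dst_gid"] = rows["dst_gid"].to_numpy()
        entries["dst_comp"] = rows["dst_comp"].to_numpy()
        entries["weight"] = rows["weight"].to_numpy()
        dst_ranks = pmap.rank_of_gid(entries["dst_gid"])
        for r in np.unique(dst_ranks):
            sub = entries[dst_ranks == r]
            queues[int(r)].push(sub)
            if int(r) != src_rank:
                stats.sent[src_rank] += len(sub)
                stats.received[int(r)] += len(sub)
    return queues, stats


def deliver(queue: DeliveryQueue, step: int) -> np.ndarray:
    """Pop exactly the deliveries scheduled at ``step``, in stable sorted
    order (source gid, target gid, target compartment)."""
    return queue.pop(step)


def table_rows_per_rank(table: ConnectionTable, pmap: PartitionMap) -> np.ndarray:
    """Synapse (table-row) count held by each rank, keyed by the rank that
    owns the *target* neuron; 64-bit so multi-million counts cannot wrap."""
    counts = np.zeros(pmap.n_ranks, dtype=np.int64)
    if len(table):
        ranks = pmap.rank_of_gid(table.df["dst_gid"].to_numpy())
        np.add.at(counts, ranks, 1)
    return counts
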