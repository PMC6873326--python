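"""Independent Poisson spike-train drive.

Every neuron receives its own homogeneous Poisson process (default mean
rate 10 Hz).  Each train comes from a counter-keyed stream derived from
``(seed, gid)``, so trains are reproducible, statistically independent
across neurons, and independent of how the population is partitioned.

The drive enters through a dedicated strong-weight receptor slot on the
soma: network activity is set by the drive, not by recurrence, whose
weights stay at the near-zero default.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import ParameterError

__all__ = ["PoissonDrive", "poisson_train", "DEFAULT_DRIVE_RATE", "DEFAULT_DRIVE_WEIGHT"]

DEFAULT_DRIVE_RATE = 10.0  # Hz
#: peak conductance (S) added to the somatic drive receptor per input
#: spike; sized so a single event reliably drives the fixture soma past
#: the spike threshold
DEFAULT_DRIVE_WEIGHT = 3e-7


def _rng_for_key(key) -> np.random.Generator:
    if isinstance(key, np.random.SeedSequence):
        return np.random.default_rng(key)
    if isinstance(key, tuple):
        seed, *rest = key
        # domain tag 1 = stimulus; disjoint from connectivity streams (tag 2)
        ss = np.random.SeedSequence(entropy=int(seed), spawn_key=(1, *map(int, rest)))
        return np.random.default_rng(ss)
    return np.random.default_rng(np.random.SeedSequence(entropy=int(key), spawn_key=(1,)))


def poisson_train(rate: float, duration: float, key) -> np.ndarray:
    """Sorted spike times of a homogeneous Poisson process on [0, duration).

    ``key`` may be an integer seed, a ``(seed, gid)`` tuple, or a
    ``SeedSequence``; a fixed key always reproduces the same train.
    """
    if rate < 0:
        raise ParameterError("rate must be >= 0")
    if duration <= 0:
        raise ParameterError("duration must be > 0")
    if rate == 0:
        return np.empty(0)
    rng = _rng_for_key(key)
    times = []
    t = 0.0
    block = max(16, int(rate * duration * 1.2) + 16)
    while t < duration:
        gaps = rng.exponential(1.0 / rate, size=block)
        chunk = t + np.cumsum(gaps)
        times.append(chunk[chunk < duration])
        t = chunk[-1]
    return np.concatenate(times) if times else np.empty(0)


@dataclass
class PoissonDrive:
    """Per-neuron independent Poisson input description."""

    rate: float = DEFAULT_DRIVE_RATE
    weight: float = DEFAULT_DRIVE_WEIGHT
    seed: int = 0

    def __post_init__(self) -> None:
        if self.rate < 0:
            raise ParameterError("rate must be >= 0")
        if self.weight < 0:
            raise ParameterError("weight must be >= 0")

    def train(self, gid: int, duration: float) -> np.ndarray:
        """Spike times for one neuron's private stream."""
        return poisson_train(self.rate, duration, (self.seed, gid))

    def event_steps(self, gid: int, duration: float, dt: float) -> np.ndarray:
        """The train quantised to integration steps (one entry per spike)."""
        t = self.train(gid, duration)
        return np.floor(t / dt).astype(np.int64)
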