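"""Run configuration: JSON loading, validation, presets.

Configurations are plain JSON documents; every field has a default
matching the benchmark study conditions (25 us step, 2,000 synapses per
neuron, 10 Hz Poisson drive, near-zero recurrent weight).  Unknown keys
are rejected by name.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field, fields
from pathlib import Path

from .errors import ConfigurationError
from .network import DEFAULT_COLUMN_SPACING, DEFAULT_DELAY, DEFAULT_WEIGHT
from .recording import DEFAULT_SIGMA
from .solver import DEFAULT_DT, SPIKE_THRESHOLD
from .stimulus import DEFAULT_DRIVE_RATE, DEFAULT_DRIVE_WEIGHT

__all__ = ["RunConfig", "load_config", "PRESETS"]

log = logging.getLogger("colsim")


@dataclass
class RunConfig:
    """Validated parameters of one end-to-end simulation."""

    dt: float = DEFAULT_DT  # s
    duration: float = 0.05  # s simulated
    seed: int = 0
    nx: int = 1  # microcolumn grid
    ny: int = 1
    k_per_neuron: float = 2000.0  # target synapses per neuron
    drive_rate: float = DEFAULT_DRIVE_RATE  # Hz
    drive_weight: float = DEFAULT_DRIVE_WEIGHT  # S
    recurrent_weight: float = DEFAULT_WEIGHT  # arb. (S) between neurons
    delay: float = DEFAULT_DELAY  # s
    ranks: int = 1
    columns_per_rank: int | None = None
    spike_threshold: float = SPIKE_THRESHOLD  # V
    column_spacing: float = DEFAULT_COLUMN_SPACING  # m
    lfp_sigma: float = DEFAULT_SIGMA  # S/m
    lfp_electrode: tuple[float, float, float] | None = None  # m; None = patch centroid
    record_lfp: bool = True
    record_v_gids: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if self.dt <= 0:
            raise ConfigurationError("dt must be > 0")
        if self.duration < self.dt:
            raise ConfigurationError("duration must be >= dt")
        if self.nx < 1 or self.ny < 1:
            raise ConfigurationError("nx and ny must be >= 1")
        if self.k_per_neuron <= 0:
            raise ConfigurationError("k_per_neuron must be > 0")
        if self.drive_rate < 0:
            raise ConfigurationError("drive_rate must be >= 0")
        if self.ranks < 1:
            raise ConfigurationError("ranks must be >= 1")
        n_columns = self.nx * self.ny
        if self.columns_per_rank is None:
            if n_columns % self.ranks:
                raise ConfigurationError(
                    f"{n_columns} columns not divisible into {self.ranks} ranks"
                )
            self.columns_per_rank = n_columns // self.ranks
        if self.ranks * self.columns_per_rank != n_columns:
            raise ConfigurationError(
                f"ranks ({self.ranks}) x columns_per_rank ({self.columns_per_rank}) "
                f"!= columns ({n_columns})"
            )

    @property
    def n_columns(self) -> int:
        return self.nx * self.ny

    @property
    def n_steps(self) -> int:
        return int(round(self.duration / self.dt))

    def to_dict(self) -> dict:
        return asdict(self)


#: named configurations of the scaling study conditions
PRESETS: dict[str, dict] = {
    # 16 microcolumns = 976 neurons, the largest per-core block of the study
    "traub-like-16col": {"nx": 4, "ny": 4},
    "traub-like-4col": {"nx": 2, "ny": 2},
    "traub-like-1col": {"nx": 1, "ny": 1},
}


def load_config(source) -> RunConfig:
    """Load and validate a RunConfig from a JSON file path, dict or str.

    A ``"preset"`` key applies a named preset before explicit keys.
    Unknown keys raise :class:`ConfigurationError` by name; the resolved
    configuration is echoed to the ``colsim`` logger.
    """
    if isinstance(source, (str, Path)) and Path(source).exists():
        raw = json.loads(Path(source).read_text())
    elif isinstance(source, str):
        raw = json.loads(source)
    elif isinstance(source, dict):
        raw = dict(source)
    else:
        raise ConfigurationError(f"cannot load config from {source!r}")
    if not isinstance(raw, dict):
        raise ConfigurationError("config root must be a JSON object")

    merged: dict = {}
    preset = raw.pop("preset", None)
    if preset is not None:
        if preset not in PRESETS:
            raise ConfigurationError(
                f"unknown preset {preset!r}; available: {sorted(PRESETS)}"
            )
        merged.update(PRESETS[preset])
    known = {f.name for f in fields(RunConfig)}
    unknown = set(raw) - known
    if unknown:
        raise ConfigurationError(f"unknown config keys: {sorted(unknown)}")
    merged.update(raw)
    if "lfp_electrode" in merged and merged["lfp_electrode"] is not None:
        merged["lfp_electrode"] = tuple(merged["lfp_electrode"])
    cfg = RunConfig(**merged)
    log.info("resolved config: %s", cfg.to_dict())
    return cfg
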