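"""Spike rasters, voltage traces and a point-electrode LFP.

The local field potential is the point-source (monopole) superposition
of every compartment's transmembrane current in a homogeneous ohmic
medium:

    phi = sum_k I_k / (4 pi sigma r_k)

with ``r_k`` the distance from the compartment midpoint to the
electrode.  Transmembrane current per compartment is capacitive plus
ionic, which in the discretisation used here equals the negative net
axial inflow, so the currents of each cell sum to ~0 (Kirchhoff) and
the cell is a pure multipole source.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import AlignmentError, ConfigurationError, ProximityError

__all__ = [
    "LFPConfig",
    "lfp_sample",
    "electrode_weights",
    "trace_difference",
    "write_spikes_tsv",
    "read_spikes_tsv",
    "write_trace_csv",
    "read_trace_csv",
]

#: default electrode height above the somata plane, m
DEFAULT_ELECTRODE_HEIGHT = 6e-6
#: default extracellular conductivity, S/m (cortical grey matter)
DEFAULT_SIGMA = 0.3
_MIN_DISTANCE = 1e-9  # m


@dataclass
class LFPConfig:
    """Point electrode position and medium conductivity.

    ``position=None`` places the electrode ``DEFAULT_ELECTRODE_HEIGHT``
    above the centroid of the patch (resolved when the electrode weights
    are built, since the centroid depends on the population).
    """

    position: tuple[float, float, float] | None = None
    sigma: float = DEFAULT_SIGMA

    def __post_init__(self) -> None:
        if self.sigma <= 0:
            raise ConfigurationError("extracellular conductivity must be > 0")

    def resolve_position(self, positions: np.ndarray) -> np.ndarray:
        if self.position is not None:
            return np.asarray(self.position, dtype=float)
        centroid = positions[:, :2].mean(axis=0)
        return np.array([centroid[0], centroid[1], DEFAULT_ELECTRODE_HEIGHT])


def electrode_weights(positions: np.ndarray, cfg: LFPConfig) -> np.ndarray:
    """Per-compartment factor 1 / (4 pi sigma r); phi = I . w."""
    positions = np.asarray(positions, dtype=float)
    elec = cfg.resolve_position(positions)
    r = np.linalg.norm(positions - elec[None, :], axis=1)
    if np.any(r < _MIN_DISTANCE):
        raise ProximityError(
            f"electrode within {_MIN_DISTANCE} m of compartment "
            f"{int(np.flatnonzero(r < _MIN_DISTANCE)[0])}"
        )
    return 1.0 / (4.0 * math.pi * cfg.sigma * r)


def lfp_sample(membrane_currents: np.ndarray, positions: np.ndarray, cfg: LFPConfig) -> float:
    """Extracellular potential (V) at the electrode for one time step."""
    currents = np.asarray(membrane_currents, dtype=float)
    if currents.shape[0] != np.asarray(positions).shape[0]:
        raise ConfigurationError("currents and positions must align")
    return float(currents @ electrode_weights(positions, cfg))


def trace_difference(a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Pointwise a - b of two equally sampled traces."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise AlignmentError(f"trace shapes differ: {a.shape} vs {b.shape}")
    return a - b


# ---------------------------------------------------------------------------
# plain-text writers (shortest-repr floats: write -> read round-trips exactly)


def write_spikes_tsv(path, gids, times) -> None:
    pd.DataFrame({"gid": np.asarray(gids, dtype=np.int64),
                  "time_s": np.asarray(times, dtype=float)}).to_csv(
        path, sep="\t", index=False
    )


def read_spikes_tsv(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", dtype={"gid": np.int64, "time_s": float},
                       float_precision="round_trip")


def write_trace_csv(path, time_s, value, value_name: str = "value") -> None:
    pd.DataFrame({"time_s": np.asarray(time_s, dtype=float),
                  value_name: np.asarray(value, dtype=float)}).to_csv(path, index=False)


def read_trace_csv(path) -> pd.DataFrame:
    return pd.read_csv(path, float_precision="round_trip")
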