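"""Annihilation-event generator.

Emulates the two measurement setups used for sensitivity profiling: a thin
axial line source (1 mm diameter, 250 cm long) centred on the scanner axis,
optionally surrounded by a water-filled cylinder (20 cm diameter, 183 cm
long) standing in for a patient body.

Each sampled decay yields exactly one back-to-back 511 keV photon pair with
an isotropic direction; positron range and acollinearity are neglected, so
both photons share one line through the annihilation point.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Iterator, Union

import numpy as np
import pandas as pd

from .materials import MU_WATER_511


@dataclass(frozen=True)
class SourceSpec:
    """Axial line source.

    ``L_mean`` is the source length (cm), ``diameter`` its diameter (cm),
    ``A_mean`` the initial activity in kBq and ``axial_center`` the z of the
    source midpoint (cm).
    """

    L_mean: float = 250.0
    diameter: float = 0.1
    A_mean: float = 1000.0
    axial_center: float = 0.0

    def __post_init__(self) -> None:
        if self.L_mean <= 0:
            raise ValueError("L_mean must be positive")
        if self.diameter < 0:
            raise ValueError("diameter must be non-negative")
        if self.A_mean <= 0:
            raise ValueError("A_mean must be positive")

    @property
    def decays_per_second(self) -> float:
        return self.A_mean * 1e3  # kBq -> decays/s


@dataclass(frozen=True)
class PhantomSpec:
    """Water-filled cylinder surrounding the source."""

    diameter: float = 20.0
    length: float = 183.0
    mu_water: float = MU_WATER_511
    axial_center: float = 0.0

    def __post_init__(self) -> None:
        if self.diameter <= 0 or self.length <= 0:
            raise ValueError("phantom dimensions must be positive")
        if self.mu_water < 0:
            raise ValueError("mu_water must be non-negative")

    @property
    def radius(self) -> float:
        return self.diameter / 2.0


@dataclass(frozen=True)
class AnnihilationEvent:
    """One annihilation: position and the direction of photon A.

    Photon B travels along ``-direction``.
    """

    position: np.ndarray
    direction: np.ndarray


class EventBatch:
    """Column-oriented sequence of :class:`AnnihilationEvent`.

    ``positions`` and ``directions`` are ``(n, 3)`` float arrays; the batch
    supports ``len()``, indexing and iteration over single events.
    """

    def __init__(self, positions: np.ndarray, directions: np.ndarray) -> None:
        positions = np.atleast_2d(np.asarray(positions, dtype=float))
        directions = np.atleast_2d(np.asarray(directions, dtype=float))
        if positions.shape != directions.shape or positions.shape[1] != 3:
            raise ValueError("positions and directions must both be (n, 3)")
        self.positions = positions
        self.directions = directions

    def __len__(self) -> int:
        return self.positions.shape[0]

    def __getitem__(self, i: int) -> AnnihilationEvent:
        return AnnihilationEvent(self.positions[i], self.directions[i])

    def __iter__(self) -> Iterator[AnnihilationEvent]:
        for i in range(len(self)):
            yield self[i]

    @property
    def z(self) -> np.ndarray:
        """Annihilation axial positions (cm)."""
        return self.positions[:, 2]

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "x": self.positions[:, 0],
                "y": self.positions[:, 1],
                "z": self.positions[:, 2],
                "dx": self.directions[:, 0],
                "dy": self.directions[:, 1],
                "dz": self.directions[:, 2],
            }
        )

    def to_csv(self, path: Union[str, Path]) -> None:
        """Write the list-mode event stream (columns x,y,z,dx,dy,dz)."""
        self.to_frame().to_csv(path, index=False, float_format="%.8f")

    @classmethod
    def from_csv(cls, path: Union[str, Path]) -> "EventBatch":
        df = pd.read_csv(path)
        return cls(df[["x", "y", "z"]].to_numpy(), df[["dx", "dy", "dz"]].to_numpy())


def sample_events(
    source: SourceSpec,
    n: int,
    seed: Union[int, np.random.Generator, np.random.SeedSequence] = 0,
) -> EventBatch:
    """Sample ``n`` annihilations uniformly inside the source cylinder.

    Directions are isotropic on the unit sphere.  Identical ``(n, seed)``
    give identical output.
    """
    if n < 0:
        raise ValueError("n must be non-negative")
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    r = source.diameter / 2.0 * np.sqrt(rng.random(n))
    phi = rng.uniform(0.0, 2.0 * np.pi, n)
    z = source.axial_center + rng.uniform(-source.L_mean / 2.0, source.L_mean / 2.0, n)
    positions = np.column_stack([r * np.cos(phi), r * np.sin(phi), z])

    uz = rng.uniform(-1.0, 1.0, n)
    psi = rng.uniform(0.0, 2.0 * np.pi, n)
    s = np.sqrt(1.0 - uz**2)
    directions = np.column_stack([s * np.cos(psi), s * np.sin(psi), uz])
    return EventBatch(positions, directions)


def duration_for(n: int, source: SourceSpec) -> float:
    """Simulated acquisition time (s) for ``n`` decays at the source activity."""
    if n <= 0:
        raise ValueError("n must be positive")
    rate = source.decays_per_second
    if rate <= 0:
        raise ValueError("source activity must be positive")
    return n / rate
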