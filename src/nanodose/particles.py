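"""Particle state carrier shared by the macroscopic and microscopic stages."""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

__all__ = ["ParticleState"]

_SPECIES = ("photon", "electron", "proton")


@dataclass
class ParticleState:
    """One transported particle.

    Positions are in mm in the macroscopic frame and in nm in the
    microscopic frame; the frame is set by the transport engine that owns
    the particle.  Energy is kinetic, in keV.  ``weight`` is the
    statistical weight used by variance-reduced estimators.
    """

    species: str
    energy_keV: float
    position: np.ndarray
    direction: np.ndarray
    weight: float = 1.0

    def __post_init__(self) -> None:
        if self.species not in _SPECIES:
            raise ValueError(f"unknown species {self.species!r}")
        if self.energy_keV < 0:
            raise ValueError("kinetic energy must be non-negative")
        if self.weight <= 0:
            raise ValueError("statistical weight must be positive")
        self.position = np.asarray(self.position, dtype=float)
        self.direction = np.asarray(self.direction, dtype=float)
        norm = float(np.linalg.norm(self.direction))
        if abs(norm - 1.0) > 1e-9:
            if norm == 0:
                raise ValueError("direction must be a unit vector")
            self.direction = self.direction / norm
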