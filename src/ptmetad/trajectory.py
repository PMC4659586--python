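"""Time-ordered coordinate trajectories.

A single container serves both low-dimensional model-system runs (positions
shaped ``(n_frames, ndim)``) and pseudo-protein Cartesian trajectories
(positions shaped ``(n_frames, n_atoms, 3)``).
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class Trajectory:
    """Frames of particle coordinates with time and temperature metadata.

    Parameters
    ----------
    positions : ndarray
        ``(n_frames, ndim)`` for model-potential coordinates or
        ``(n_frames, n_atoms, 3)`` for Cartesian pseudo-protein frames.
        Lengths in Angstrom.
    dt_ps : float
        Time between consecutive saved frames, in ps.
    temperature : float, optional
        Thermostat temperature in K.
    energies : ndarray, optional
        Potential energy (kJ/mol) at each saved frame.
    time0_ps : float
        Time stamp of the first frame.
    """

    positions: np.ndarray
    dt_ps: float
    temperature: float | None = None
    energies: np.ndarray | None = None
    time0_ps: float = 0.0
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim < 2:
            raise ValueError("positions must be at least 2-D (frames x coords)")
        if self.dt_ps <= 0:
            raise ValueError(f"dt_ps must be positive, got {self.dt_ps}")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def times(self) -> np.ndarray:
        """Frame time stamps in ps."""
        return self.time0_ps + self.dt_ps * np.arange(self.n_frames)

    @property
    def duration_ns(self) -> float:
        """Total spanned time in ns, counting one spacing per frame."""
        return self.n_frames * self.dt_ps / 1000.0
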