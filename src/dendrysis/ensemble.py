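"""In-memory containers for coordinate ensembles.

One bead per residue: every analysis in this package consumes geometric
centers and residue selections, so frames are stored as a dense
``(n_frames, n_beads, 3)`` float array in Angstrom, with bead *i*
corresponding to residue id *i* of the attached topology.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .topology import DendrimerTopology

__all__ = ["Frame", "Ensemble"]


@dataclass
class Frame:
    """A single conformation: per-bead coordinates plus the residue map."""

    coordinates: np.ndarray  # (n_beads, 3), Angstrom
    topology: DendrimerTopology | None = None
    box: np.ndarray | None = None  # (3,) or None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 2 or self.coordinates.shape[1] != 3:
            raise ValueError("coordinates must have shape (n_beads, 3)")
        if (self.topology is not None
                and len(self.coordinates) != self.topology.n_residues):
            raise ValueError(
                f"{len(self.coordinates)} beads for a topology of "
                f"{self.topology.n_residues} residues")

    @property
    def n_beads(self) -> int:
        return len(self.coordinates)

    def select(self, residue_ids) -> np.ndarray:
        return self.coordinates[np.asarray(list(residue_ids), dtype=int)]


@dataclass
class Ensemble:
    """Per-(system, pH, replicate) stack of frames sharing one topology."""

    coordinates: np.ndarray  # (n_frames, n_beads, 3), Angstrom
    topology: DendrimerTopology | None = None
    system: str = ""
    pH: float | None = None
    replicate: int | None = None
    box: np.ndarray | None = None

    def __post_init__(self):
        self.coordinates = np.asarray(self.coordinates, dtype=float)
        if self.coordinates.ndim != 3 or self.coordinates.shape[2] != 3:
            raise ValueError("coordinates must have shape (n_frames, n_beads, 3)")

    @property
    def n_frames(self) -> int:
        return self.coordinates.shape[0]

    @property
    def n_beads(self) -> int:
        return self.coordinates.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.coordinates[i], topology=self.topology, box=self.box)

    def __iter__(self):
        for i in range(self.n_frames):
            yield self.frame(i)

    def __len__(self) -> int:
        return self.n_frames
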