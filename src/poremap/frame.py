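"""In-memory containers for coarse-grained membrane snapshots.

A :class:`MembraneFrame` stores one time point of a bilayer system as flat
numpy arrays: per-lipid headgroup position, optional phosphate/amine bead
positions (for the headgroup dipole of zwitterionic lipids), tail-bead
chains, residue name, leaflet label and headgroup charge, plus the water
bead coordinates and the periodic box. A :class:`Trajectory` is an ordered
list of frames sharing lipid identities, with a fixed frame spacing ``dt``
in nanoseconds.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np


@dataclass
class MembraneFrame:
    box: np.ndarray                 # (3,) nm
    time: float                     # ns
    resnames: np.ndarray            # (n,) str
    leaflets: np.ndarray            # (n,) 'inner' | 'outer'
    head_pos: np.ndarray            # (n, 3) nm
    phosphate_pos: np.ndarray       # (n, 3) nm, NaN if absent
    amine_pos: np.ndarray           # (n, 3) nm, NaN if absent
    tails: np.ndarray               # (n, n_tails, n_beads, 3) nm, NaN if absent
    charges: np.ndarray             # (n,) e
    water: np.ndarray               # (m, 3) nm
    lipid_ids: np.ndarray = field(default=None)  # (n,) stable across frames

    def __post_init__(self) -> None:
        self.box = np.asarray(self.box, dtype=float)
        if self.lipid_ids is None:
            self.lipid_ids = np.arange(len(self.resnames))

    @property
    def n_lipids(self) -> int:
        return len(self.resnames)

    def leaflet_index(self, leaflet: str) -> np.ndarray:
        return np.flatnonzero(self.leaflets == leaflet)

    def copy(self) -> "MembraneFrame":
        return replace(
            self,
            head_pos=self.head_pos.copy(),
            phosphate_pos=self.phosphate_pos.copy(),
            amine_pos=self.amine_pos.copy(),
            tails=self.tails.copy(),
            charges=self.charges.copy(),
            water=self.water.copy(),
            leaflets=self.leaflets.copy(),
            resnames=self.resnames.copy(),
            lipid_ids=self.lipid_ids.copy(),
        )


@dataclass
class Trajectory:
    frames: list[MembraneFrame]
    dt: float = 0.1  # ns between frames

    def __len__(self) -> int:
        return len(self.frames)

    def __getitem__(self, i: int) -> MembraneFrame:
        return self.frames[i]

    def __iter__(self):
        return iter(self.frames)

    def time_of(self, frame_index: int) -> float:
        return frame_index * self.dt


def wrap_xy(points: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Wrap x,y coordinates into [0, L) for each lateral dimension."""
    out = np.array(points, dtype=float, copy=True)
    out[..., 0] %= box[0]
    out[..., 1] %= box[1]
    return out


def min_image_dxy(a: np.ndarray, b: np.ndarray, box: np.ndarray) -> np.ndarray:
    """Minimum-image lateral displacement a - b under periodic boundaries."""
    d = np.asarray(a, dtype=float)[..., :2] - np.asarray(b, dtype=float)[..., :2]
    L = np.asarray(box, dtype=float)[:2]
    return d - L * np.round(d / L)
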