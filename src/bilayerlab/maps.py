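"""Two-dimensional number-density maps of selected species.

Each frame's selected particles are binned into an ``nx x ny`` lattice of
half-open cells over the lateral box (consistent with the ``[0, L)``
wrapping convention) using fractional coordinates, so a slowly breathing
box does not smear the histogram.  The averaged counts are normalized to
count nm^-2; by construction ``sum(values) * cell_area`` equals the mean
particle count per frame (conservation), exactly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .errors import AggregationError
from .fields import Field2D
from .surface import terminal_window
from .trajectory import LeafletAssignment, ParticleTrajectory, select_mask


@dataclass
class DensityMap:
    """A density :class:`Field2D` plus the selection it was built from."""

    field: Field2D
    selection: str
    leaflet: str
    n_frames_used: int
    mean_count: float

    @property
    def values(self) -> np.ndarray:
        return self.field.values

    @property
    def cell_area(self) -> float:
        return self.field.cell_area


def density_map(traj: ParticleTrajectory, selection, leaflet: str = "both",
                leaflets: LeafletAssignment | None = None, grid=(26, 26),
                window: float = 0.4) -> DensityMap:
    """Time-averaged 2D number density of ``selection`` in count nm^-2.

    Parameters
    ----------
    selection : str
        Tag expression (``"POPS-P"``, ``"POPS-P|TFP"``, ``"all"``).
    leaflet : {"both", "upper", "lower"}
        Restrict to one leaflet (requires ``leaflets``).
    grid : (nx, ny)
        Bin counts; the default 26 x 26 gives ~0.5 nm bins in a 13 nm box.
    window : float
        Terminal fraction of frames averaged, following the curvature
        analysis window.
    """
    mask = select_mask(traj, selection)
    if leaflet != "both":
        if leaflets is None:
            raise AggregationError("leaflet filtering requires a LeafletAssignment")
        keep = {"upper": leaflets.upper, "lower": leaflets.lower}[leaflet]
        lmask = np.zeros(traj.n_particles, dtype=bool)
        lmask[keep] = True
        mask = mask & lmask
        if not mask.any():
            raise AggregationError(
                f"selection {selection!r} is empty in the {leaflet} leaflet")
    sel = np.flatnonzero(mask)
    frames = range(traj.n_frames)[terminal_window(traj.n_frames, window)]
    if len(frames) == 0:
        raise AggregationError("empty frame window")

    nx, ny = grid
    counts = np.zeros((nx, ny))
    for i in frames:
        Lx, Ly = traj.boxes[i, 0], traj.boxes[i, 1]
        u = np.mod(traj.positions[i, sel, 0] / Lx, 1.0)
        v = np.mod(traj.positions[i, sel, 1] / Ly, 1.0)
        ix = np.minimum((u * nx).astype(int), nx - 1)
        iy = np.minimum((v * ny).astype(int), ny - 1)
        np.add.at(counts, (ix, iy), 1.0)
    counts /= len(frames)

    mean_box = traj.boxes[list(frames), :2].mean(axis=0)
    cell_area = (mean_box[0] / nx) * (mean_box[1] / ny)
    field = Field2D(values=counts / cell_area, box=tuple(mean_box),
                    units="nm^-2", kind="density",
                    meta={"selection": str(selection), "leaflet": leaflet,
                          "n_frames": len(frames)})
    return DensityMap(field=field, selection=str(selection), leaflet=leaflet,
                      n_frames_used=len(frames), mean_count=float(sel.size))
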