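"""Scalar fields on a regular x-y grid over the periodic membrane plane.

A :class:`Field2D` holds one scalar per node of an ``nx x ny`` lattice of
cell centers spanning ``[0, Lx) x [0, Ly)``.  The same container carries
mean-curvature fields (nm^-1), thickness fields (nm) and number-density
maps (count nm^-2); ``kind`` and ``units`` record which.
"""

from __future__ import annotations

import io
from dataclasses import dataclass, field

import numpy as np

from .errors import AggregationError, FormatError

VALID_KINDS = ("curvature", "thickness", "density", "height", "generic")


@dataclass(frozen=True)
class DiskRegion:
    """Disk of radius ``r`` centered at ``(cx, cy)``, all in nm."""

    cx: float
    cy: float
    r: float

    def describe(self) -> str:
        return f"disk(cx={self.cx:.3f}, cy={self.cy:.3f}, r={self.r:.3f})"


@dataclass(frozen=True)
class RectRegion:
    """Axis-aligned rectangle ``[x0, x1] x [y0, y1]`` in nm."""

    x0: float
    x1: float
    y0: float
    y1: float

    def describe(self) -> str:
        return f"rect(x=[{self.x0:.3f},{self.x1:.3f}], y=[{self.y0:.3f},{self.y1:.3f}])"


@dataclass
class Field2D:
    """Scalar field sampled at cell centers of a regular lattice.

    Parameters
    ----------
    values : ndarray, shape (nx, ny)
        Node values; axis 0 runs along x, axis 1 along y.
    box : (Lx, Ly)
        Lateral box lengths in nm.
    units : str
        Physical units of the values (``"nm^-1"``, ``"nm"``, ``"nm^-2"``).
    kind : str
        One of ``curvature | thickness | density | height | generic``.
    meta : dict
        Free-form provenance (selection, window, sign convention, ...).
    """

    values: np.ndarray
    box: tuple[float, float]
    units: str
    kind: str = "generic"
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("values must be 2-D (nx, ny)")
        if not np.all(np.isfinite(self.values)):
            raise ValueError("field values must be finite")
        if self.kind not in VALID_KINDS:
            raise ValueError(f"unknown field kind {self.kind!r}")
        if len(self.box) != 2 or min(self.box) <= 0:
            raise ValueError("box must be two positive lengths")
        self.box = (float(self.box[0]), float(self.box[1]))

    @property
    def shape(self) -> tuple[int, int]:
        return self.values.shape

    @property
    def cell_area(self) -> float:
        nx, ny = self.shape
        return (self.box[0] / nx) * (self.box[1] / ny)

    @property
    def x_centers(self) -> np.ndarray:
        nx = self.shape[0]
        return (np.arange(nx) + 0.5) * (self.box[0] / nx)

    @property
    def y_centers(self) -> np.ndarray:
        ny = self.shape[1]
        return (np.arange(ny) + 0.5) * (self.box[1] / ny)

    def mean(self, region=None) -> float:
        """Area-weighted mean over the whole box or a sub-region."""
        mask = self.region_mask(region)
        return float(self.values[mask].mean())

    def region_mask(self, region=None) -> np.ndarray:
        """Boolean node mask for ``region`` (``None`` selects every node)."""
        if region is None:
            return np.ones(self.shape, dtype=bool)
        X, Y = np.meshgrid(self.x_centers, self.y_centers, indexing="ij")
        if isinstance(region, DiskRegion):
            # minimum-image distance: the region may straddle the periodic box
            dx = X - region.cx
            dy = Y - region.cy
            dx -= self.box[0] * np.round(dx / self.box[0])
            dy -= self.box[1] * np.round(dy / self.box[1])
            mask = dx**2 + dy**2 <= region.r**2
        elif isinstance(region, RectRegion):
            mask = (
                (X >= region.x0) & (X <= region.x1)
                & (Y >= region.y0) & (Y <= region.y1)
            )
        else:
            raise TypeError(f"unsupported region type {type(region).__name__}")
        if not mask.any():
            raise AggregationError("region does not intersect the field grid")
        return mask

    # ---------------------------------------------------------------- I/O
    def to_csv(self, path) -> None:
        """Write as a CSV matrix preceded by a small ``#``-header block."""
        nx, ny = self.shape
        with open(path, "w") as fh:
            fh.write(f"# kind: {self.kind}\n")
            fh.write(f"# units: {self.units}\n")
            fh.write(f"# box_nm: {self.box[0]:.10g} {self.box[1]:.10g}\n")
            fh.write(f"# shape: {nx} {ny}\n")
            np.savetxt(fh, self.values, delimiter=",", fmt="%.10g")

    @classmethod
    def from_csv(cls, path) -> "Field2D":
        header = {}
        body = io.StringIO()
        with open(path) as fh:
            for line in fh:
                if line.startswith("#"):
                    key, _, rest = line[1:].partition(":")
                    header[key.strip()] = rest.strip()
                else:
                    body.write(line)
        try:
            box = tuple(float(v) for v in header["box_nm"].split())
            units = header["units"]
            kind = header["kind"]
        except KeyError as exc:
            raise FormatError(f"field CSV is missing header entry {exc}") from exc
        body.seek(0)
        values = np.loadtxt(body, delimiter=",", ndmin=2)
        return cls(values=values, box=box, units=units, kind=kind)


def mean_field(fields: "list[Field2D]") -> Field2D:
    """Node-wise average of fields sharing one grid and box."""
    if not fields:
        raise AggregationError("cannot average an empty list of fields")
    first = fields[0]
    for f in fields[1:]:
        if f.shape != first.shape or not np.allclose(f.box, first.box):
            raise ValueError("fields must share grid shape and box")
    values = np.mean([f.values for f in fields], axis=0)
    return Field2D(values=values, box=first.box, units=first.units,
                   kind=first.kind, meta=dict(first.meta, averaged_over=len(fields)))
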