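"""Trajectory I/O, particle selection, leaflet assignment and periodic
boundary bookkeeping.

All coordinates are stored in nm and all times in ns, regardless of the
native unit of the source format; conversions happen here and only here.
Boxes are orthorhombic with the origin at a box corner and wrapped
coordinates in ``[0, L)`` per axis.  Structure/trajectory files
(PDB/GRO + XTC/TRR/DCD) are read through MDAnalysis; a plain-text CSV
dialect (``frame,time_ns,tag,x,y,z`` plus a ``# box_nm:`` header line) is
the fallback and round-trip format.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .errors import (
    AmbiguousLeafletError,
    FormatError,
    ParameterError,
    SelectionError,
)

#: fraction of the box length beyond which a minimum-image step is treated
#: as a symptom of temporal undersampling
_UNDERSAMPLING_FRACTION = 0.45

_PROTEIN_RESNAMES = frozenset(
    "ALA ARG ASN ASP CYS GLN GLU GLY HIS HSD HSE HSP ILE LEU LYS MET PHE "
    "PRO SER THR TRP TYR VAL".split()
)


@dataclass(frozen=True)
class Frame:
    """One stored time point: positions (n, 3) nm, box (3,) nm, time ns."""

    positions: np.ndarray
    box: np.ndarray
    time: float


@dataclass
class ParticleTrajectory:
    """Time-ordered positions of a fixed set of tagged particles.

    Attributes
    ----------
    positions : ndarray, shape (n_frames, n_particles, 3)
        Coordinates in nm.
    boxes : ndarray, shape (n_frames, 3)
        Orthorhombic box lengths in nm per frame.
    times : ndarray, shape (n_frames,)
        Strictly increasing times in ns.
    tags : ndarray of str, shape (n_particles,)
        Species label per particle, e.g. ``POPC-P``, ``POPS-P``, ``TFP``,
        ``protein``.
    source : str
        Provenance string.
    """

    positions: np.ndarray
    boxes: np.ndarray
    times: np.ndarray
    tags: np.ndarray
    source: str = ""

    def __post_init__(self):
        self.positions = np.asarray(self.positions, dtype=float)
        self.boxes = np.asarray(self.boxes, dtype=float)
        self.times = np.asarray(self.times, dtype=float)
        self.tags = np.asarray(self.tags, dtype=object)
        if self.positions.ndim != 3 or self.positions.shape[2] != 3:
            raise ValueError("positions must have shape (n_frames, n_particles, 3)")
        f, n, _ = self.positions.shape
        if self.boxes.shape != (f, 3):
            raise ValueError("boxes must have shape (n_frames, 3)")
        if self.times.shape != (f,):
            raise ValueError("times must have shape (n_frames,)")
        if self.tags.shape != (n,):
            raise ValueError("one tag per particle required")
        if np.any(self.boxes <= 0):
            raise ValueError("box lengths must be positive")
        if f > 1 and np.any(np.diff(self.times) <= 0):
            raise ValueError("times must be strictly increasing")

    @property
    def n_frames(self) -> int:
        return self.positions.shape[0]

    @property
    def n_particles(self) -> int:
        return self.positions.shape[1]

    def frame(self, i: int) -> Frame:
        return Frame(self.positions[i], self.boxes[i], float(self.times[i]))

    @property
    def frames(self):
        return [self.frame(i) for i in range(self.n_frames)]

    @property
    def time_step(self) -> float:
        """Spacing between stored frames in ns (frames must be uniform)."""
        if self.n_frames < 2:
            raise ParameterError("time step undefined for a single frame")
        dts = np.diff(self.times)
        if not np.allclose(dts, dts[0], rtol=1e-6, atol=1e-9):
            raise ParameterError("frames are not uniformly spaced in time")
        return float(dts[0])

    def subset(self, mask: np.ndarray, source_suffix: str = "") -> "ParticleTrajectory":
        """New trajectory restricted to particles where ``mask`` is True."""
        mask = np.asarray(mask)
        return ParticleTrajectory(
            positions=self.positions[:, mask, :].copy(),
            boxes=self.boxes.copy(),
            times=self.times.copy(),
            tags=self.tags[mask].copy(),
            source=self.source + source_suffix,
        )


@dataclass(frozen=True)
class LeafletAssignment:
    """Index sets of headgroup particles in the upper and lower leaflet."""

    upper: np.ndarray
    lower: np.ndarray

    def __post_init__(self):
        up = np.asarray(self.upper, dtype=int)
        lo = np.asarray(self.lower, dtype=int)
        object.__setattr__(self, "upper", up)
        object.__setattr__(self, "lower", lo)
        if up.size == 0 or lo.size == 0:
            raise AmbiguousLeafletError("each leaflet must contain at least one particle")
        if np.intersect1d(up, lo).size:
            raise ValueError("leaflet index sets must be disjoint")


# --------------------------------------------------------------- selection

def select_mask(traj: ParticleTrajectory, selection) -> np.ndarray:
    """Boolean particle mask for the tag mini-language.

    ``selection`` is a single tag (``"POPS-P"``), a ``|``-joined union
    (``"POPS-P|TFP"``), an iterable of tags, or ``None``/``"all"`` for every
    particle.  Matching is exact string equality on tags; nothing else.
    """
    if selection is None or selection == "all":
        return np.ones(traj.n_particles, dtype=bool)
    if isinstance(selection, str):
        wanted = {s.strip() for s in selection.split("|") if s.strip()}
    else:
        wanted = set(selection)
    if not wanted:
        raise SelectionError("empty selection expression")
    mask = np.isin(np.asarray(traj.tags, dtype=str), sorted(wanted))
    if not mask.any():
        raise SelectionError(f"selection {selection!r} matched no particles")
    return mask


def _tag_for_atom(resname: str, name: str) -> str:
    if resname.upper() in _PROTEIN_RESNAMES:
        return "protein"
    return f"{resname}-{name}"


# --------------------------------------------------------------------- I/O

def read_trajectory(structure_path, trajectory_path=None, selection: str = "all",
                    ) -> ParticleTrajectory:
    """Read a structure (+ optional trajectory) into a :class:`ParticleTrajectory`.

    ``structure_path`` may be a PDB/GRO file (read through MDAnalysis, with
    ``selection`` interpreted as an MDAnalysis selection string) or a CSV file
    in the package dialect (then ``selection`` uses the tag mini-language).
    Lengths are converted to nm and times to ns on the way in; triclinic
    boxes are rejected.
    """
    spath = str(structure_path)
    if spath.lower().endswith(".csv"):
        traj = read_trajectory_csv(spath)
        return traj.subset(select_mask(traj, selection))

    import MDAnalysis as mda

    try:
        if trajectory_path is None:
            u = mda.Universe(spath)
        else:
            u = mda.Universe(spath, str(trajectory_path))
    except Exception as exc:  # MDAnalysis raises a zoo of types
        raise FormatError(f"could not read {spath}: {exc}") from exc

    try:
        ag = u.select_atoms(selection if selection not in (None, "all") else "all")
    except Exception as exc:
        raise SelectionError(f"bad selection {selection!r}: {exc}") from exc
    if len(ag) == 0:
        raise SelectionError(f"selection {selection!r} matched no atoms")

    tags = np.array([_tag_for_atom(a.resname, a.name) for a in ag.atoms], dtype=object)
    pos, boxes, times = [], [], []
    for i, ts in enumerate(u.trajectory):
        dims = ts.dimensions
        if dims is None or np.any(dims[:3] <= 0):
            raise FormatError("frame has no valid box dimensions")
        if not np.allclose(dims[3:6], 90.0, atol=1e-3):
            raise FormatError("triclinic boxes are not supported")
        box = dims[:3] / 10.0  # A -> nm
        pos.append(np.mod(ag.positions / 10.0, box))
        boxes.append(box)
        times.append(ts.time / 1000.0 if ts.time is not None else float(i))
    times = np.asarray(times, dtype=float)
    if len(times) > 1 and np.any(np.diff(times) <= 0):
        # some single-frame formats carry no usable time stamps
        times = np.arange(len(times), dtype=float)
    return ParticleTrajectory(
        positions=np.asarray(pos), boxes=np.asarray(boxes), times=times,
        tags=tags, source=f"{spath}+{trajectory_path or ''}",
    )


def read_trajectory_csv(path, box=None) -> ParticleTrajectory:
    """Read the CSV dialect: ``# box_nm: Lx Ly Lz`` header + columns
    ``frame,time_ns,tag,x,y,z``.  ``box`` overrides the header if given."""
    header_box = None
    with open(path) as fh:
        for line in fh:
            if not line.startswith("#"):
                break
            key, _, rest = line[1:].partition(":")
            if key.strip() == "box_nm":
                header_box = tuple(float(v) for v in rest.split())
    if box is None:
        box = header_box
    if box is None:
        raise FormatError("CSV trajectory needs a '# box_nm: Lx Ly Lz' header "
                          "or an explicit box argument")
    try:
        df = pd.read_csv(path, comment="#")
    except Exception as exc:
        raise FormatError(f"could not parse CSV trajectory {path}: {exc}") from exc
    required = ["frame", "time_ns", "tag", "x", "y", "z"]
    if list(df.columns) != required:
        raise FormatError(f"CSV trajectory must have columns {required}, "
                          f"got {list(df.columns)}")
    frames = np.sort(df["frame"].unique())
    n_per = df.groupby("frame").size()
    if n_per.nunique() != 1:
        raise FormatError("all frames must contain the same number of particles")
    df = df.sort_values(["frame"], kind="stable")
    n = int(n_per.iloc[0])
    tags0 = df[df["frame"] == frames[0]]["tag"].to_numpy()
    pos = df[["x", "y", "z"]].to_numpy().reshape(len(frames), n, 3)
    times = df.groupby("frame")["time_ns"].first().to_numpy()
    boxes = np.tile(np.asarray(box, dtype=float), (len(frames), 1))
    return ParticleTrajectory(positions=pos, boxes=boxes, times=times,
                              tags=tags0.astype(object), source=str(path))


def write_trajectory_csv(traj: ParticleTrajectory, path) -> None:
    """Write the CSV dialect (see :func:`read_trajectory_csv`).

    The box of the first frame is recorded in the header; per-frame box
    variation is not representable in this dialect.
    """
    with open(path, "w") as fh:
        b = traj.boxes[0]
        fh.write(f"# box_nm: {b[0]:.10g} {b[1]:.10g} {b[2]:.10g}\n")
        fh.write("frame,time_ns,tag,x,y,z\n")
        for i in range(traj.n_frames):
            t = traj.times[i]
            for j in range(traj.n_particles):
                x, y, z = traj.positions[i, j]
                fh.write(f"{i},{t:.10g},{traj.tags[j]},{x:.10g},{y:.10g},{z:.10g}\n")


# ----------------------------------------------------------- leaflet split

def assign_leaflets(traj: ParticleTrajectory, selection=None,
                    reference_frame: int = 0, min_gap: float = 0.5,
                    ) -> LeafletAssignment:
    """Split headgroup particles into upper/lower leaflets by a median-z cut.

    The split uses a single reference frame and is then fixed for the whole
    trajectory: lipid flip-flop is far slower than the sub-microsecond
    trajectories this package targets.  ``selection`` defaults to particles
    whose tag ends in ``-P`` (phosphorus headgroup beads), falling back to
    all particles if none match.  If the inter-leaflet gap at the cut is
    below ``min_gap`` (nm) the geometry is ambiguous and an error is raised.
    The result is invariant under any rigid z-translation of the system.
    """
    if selection is None:
        ends_p = np.array([str(t).endswith("-P") for t in traj.tags])
        mask = ends_p if ends_p.any() else np.ones(traj.n_particles, dtype=bool)
    else:
        mask = select_mask(traj, selection)
    idx = np.flatnonzero(mask)
    z = traj.positions[reference_frame, idx, 2]
    zmed = np.median(z)
    upper = idx[z > zmed]
    lower = idx[z <= zmed]
    if upper.size == 0 or lower.size == 0:
        raise AmbiguousLeafletError(
            "headgroup z values do not separate into two leaflets")
    gap = z[z > zmed].min() - z[z <= zmed].max()
    if gap < min_gap:
        raise AmbiguousLeafletError(
            f"inter-leaflet gap {gap:.3f} nm is below min_gap={min_gap} nm")
    return LeafletAssignment(upper=upper, lower=lower)


# ------------------------------------------------------------------ PBC

def unwrap_lateral(traj: ParticleTrajectory) -> ParticleTrajectory:
    """Remove lateral periodic jumps, producing continuous x-y coordinates.

    Consecutive-frame displacements are minimized under periodic images in
    x and y and accumulated; z is left untouched.  Steps longer than
    ~half a box after correction indicate temporal undersampling and raise
    a warning (they cannot be distinguished from aliased longer jumps).
    """
    pos = traj.positions.copy()
    for ax in (0, 1):
        L = traj.boxes[:, ax]  # (F,)
        raw = np.diff(traj.positions[:, :, ax], axis=0)  # (F-1, N)
        shift = np.round(raw / L[1:, None])
        disp = raw - shift * L[1:, None]
        if np.any(np.abs(disp) > _UNDERSAMPLING_FRACTION * L[1:, None]):
            warnings.warn(
                "per-frame displacement close to half a box length: the "
                "trajectory is likely undersampled and unwrapping may alias",
                RuntimeWarning, stacklevel=2)
        pos[1:, :, ax] = traj.positions[0, :, ax] + np.cumsum(disp, axis=0)
    return ParticleTrajectory(positions=pos, boxes=traj.boxes.copy(),
                              times=traj.times.copy(), tags=traj.tags.copy(),
                              source=traj.source + "|unwrapped")


def wrap_lateral(traj: ParticleTrajectory) -> ParticleTrajectory:
    """Wrap x and y back into ``[0, L)``; inverse of :func:`unwrap_lateral`
    up to periodic images."""
    pos = traj.positions.copy()
    for ax in (0, 1):
        pos[:, :, ax] = np.mod(pos[:, :, ax], traj.boxes[:, ax, None])
    return ParticleTrajectory(positions=pos, boxes=traj.boxes.copy(),
                              times=traj.times.copy(), tags=traj.tags.copy(),
                              source=traj.source + "|wrapped")
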