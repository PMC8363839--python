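"""Leaflet surface fitting in the Monge gauge and derived curvature /
thickness fields.

Each leaflet's headgroup coordinates are fitted per frame to a truncated
two-dimensional Fourier series over the periodic box,

    z(x, y) = a_00 + sum_{(m,n)} [ c_mn cos(th_mn) + s_mn sin(th_mn) ],
    th_mn  = 2 pi (m x / Lx + n y / Ly),

with modes restricted to the half-plane |m|, |n| <= M (so the surface is
real and each wavevector counted once; (2M+1)^2 real coefficients in
total).  The mean-curvature field is evaluated analytically from the
coefficients, either linearized, H = (z_xx + z_yy) / 2, or with the full
Monge-gauge expression.  The sign convention is that z increases toward
the upper leaflet, so a dimple in the upper leaflet has H < 0 at its
center under the linearized formula.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import AggregationError, FitError, LeafletOrderError
from .fields import DiskRegion, Field2D, mean_field
from .trajectory import LeafletAssignment, ParticleTrajectory, select_mask

SIGN_CONVENTION = ("z increases toward the upper leaflet; "
                   "H = +(z_xx + z_yy)/2 in the linearized form")


def half_plane_modes(n_modes: int) -> list[tuple[int, int]]:
    """Non-DC wavevectors (m, n), |m|,|n| <= M, one per +-k pair."""
    modes = []
    for m in range(0, n_modes + 1):
        for n in range(-n_modes, n_modes + 1):
            if m == 0 and n <= 0:
                continue
            modes.append((m, n))
    return modes


def design_matrix(x, y, box, n_modes: int) -> np.ndarray:
    """Least-squares design: a constant column then cos/sin per mode."""
    x = np.asarray(x, dtype=float).ravel()
    y = np.asarray(y, dtype=float).ravel()
    modes = half_plane_modes(n_modes)
    cols = [np.ones_like(x)]
    for m, n in modes:
        th = 2.0 * np.pi * (m * x / box[0] + n * y / box[1])
        cols.append(np.cos(th))
        cols.append(np.sin(th))
    return np.column_stack(cols)


@dataclass
class FourierSurface:
    """Fitted truncated Fourier surface for one leaflet (a results object).

    Produced by :meth:`FourierSurfaceModel.fit`; carries the coefficient
    vector, its covariance estimate and the fit residual, and evaluates
    heights, analytic derivatives and curvature anywhere in the box.
    """

    params: np.ndarray          # (1 + 2*len(modes),): [a00, c1, s1, c2, s2, ...]
    box: tuple[float, float]
    n_modes: int
    resid_norm: float = 0.0
    nobs: int = 0
    sigma2: float = 0.0
    bse: np.ndarray | None = None
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.params = np.asarray(self.params, dtype=float)
        self.box = (float(self.box[0]), float(self.box[1]))
        if self.params.shape != (1 + 2 * len(self.modes),):
            raise ValueError("coefficient vector has the wrong length for n_modes")

    @property
    def modes(self) -> list[tuple[int, int]]:
        return half_plane_modes(self.n_modes)

    @property
    def n_params(self) -> int:
        return self.params.size

    def amplitude(self, m: int, n: int) -> tuple[float, float]:
        """(cos, sin) amplitude of wavevector (m, n) (half-plane indexing)."""
        if (m, n) == (0, 0):
            return float(self.params[0]), 0.0
        try:
            k = self.modes.index((m, n))
            sign = 1.0
        except ValueError:
            k = self.modes.index((-m, -n))  # conjugate pair: cos even, sin odd
            sign = -1.0
        return float(self.params[1 + 2 * k]), sign * float(self.params[2 + 2 * k])

    def derivative(self, x, y, dx: int = 0, dy: int = 0) -> np.ndarray:
        """Evaluate d^(dx+dy) z / dx^dx dy^dy analytically at (x, y)."""
        x = np.asarray(x, dtype=float)
        y = np.asarray(y, dtype=float)
        out = np.zeros(np.broadcast(x, y).shape)
        if dx == 0 and dy == 0:
            out += self.params[0]
        for k, (m, n) in enumerate(self.modes):
            c = self.params[1 + 2 * k]
            s = self.params[2 + 2 * k]
            kx = 2.0 * np.pi * m / self.box[0]
            ky = 2.0 * np.pi * n / self.box[1]
            th = kx * x + ky * y
            # d/dx of (c - i s) e^{i th} picks up (i kx); take the real part
            amp = (c - 1j * s) * (1j * kx) ** dx * (1j * ky) ** dy
            out += np.real(amp * np.exp(1j * th))
        return out

    def evaluate(self, x, y) -> np.ndarray:
        """Surface height z(x, y) in nm (periodic in both directions)."""
        return self.derivative(x, y, 0, 0)

    __call__ = evaluate

    def mean_curvature(self, x, y, mode: str = "linearized") -> np.ndarray:
        """Mean curvature H(x, y) in nm^-1."""
        zxx = self.derivative(x, y, 2, 0)
        zyy = self.derivative(x, y, 0, 2)
        if mode == "linearized":
            return 0.5 * (zxx + zyy)
        if mode == "full":
            zx = self.derivative(x, y, 1, 0)
            zy = self.derivative(x, y, 0, 1)
            zxy = self.derivative(x, y, 1, 1)
            num = (1 + zy**2) * zxx - 2 * zx * zy * zxy + (1 + zx**2) * zyy
            return num / (2.0 * (1 + zx**2 + zy**2) ** 1.5)
        raise ValueError("mode must be 'linearized' or 'full'")

    def summary(self) -> str:
        lines = [
            "Fourier surface fit",
            "=" * 47,
            f"box (nm)        : {self.box[0]:.4f} x {self.box[1]:.4f}",
            f"mode cutoff M   : {self.n_modes}  ({self.n_params} real coefficients)",
            f"observations    : {self.nobs}",
            f"residual norm   : {self.resid_norm:.6g} nm",
            f"rms residual    : {np.sqrt(self.sigma2):.6g} nm",
            "-" * 47,
            f"{'mode':>8} {'cos amp (nm)':>14} {'sin amp (nm)':>14}",
            f"{'(0,0)':>8} {self.params[0]:>14.6g} {'-':>14}",
        ]
        for k, (m, n) in enumerate(self.modes):
            lines.append(f"{f'({m},{n})':>8} {self.params[1 + 2 * k]:>14.6g} "
                         f"{self.params[2 + 2 * k]:>14.6g}")
        return "\n".join(lines)


class FourierSurfaceModel:
    """Least-squares model for one leaflet surface.

    Parameters
    ----------
    points : ndarray, shape (n, 3)
        Headgroup coordinates (x, y, z) in nm.
    box : (Lx, Ly)
        Lateral box lengths in nm.
    n_modes : int
        Mode cutoff M; the default 2 resolves protein-scale (long-wavelength)
        deformation while leaving thermal noise to the residual.
    """

    def __init__(self, points, box, n_modes: int = 2):
        points = np.asarray(points, dtype=float)
        if points.ndim != 2 or points.shape[1] != 3:
            raise ValueError("points must have shape (n, 3)")
        if min(box) <= 0:
            raise ValueError("box lengths must be positive")
        self.points = points
        self.box = (float(box[0]), float(box[1]))
        self.n_modes = int(n_modes)
        self.k_params = 1 + 2 * len(half_plane_modes(self.n_modes))
        if points.shape[0] < self.k_params:
            raise FitError(
                f"{points.shape[0]} points cannot constrain {self.k_params} "
                f"coefficients (M={self.n_modes})")

    def fit(self) -> FourierSurface:
        X = design_matrix(self.points[:, 0], self.points[:, 1], self.box,
                          self.n_modes)
        z = self.points[:, 2]
        params, _, rank, _ = np.linalg.lstsq(X, z, rcond=None)
        if rank < self.k_params:
            raise FitError("rank-deficient design: points are degenerate in x-y")
        resid = z - X @ params
        nobs = z.size
        dof = max(nobs - self.k_params, 1)
        sigma2 = float(resid @ resid) / dof
        try:
            cov = sigma2 * np.linalg.inv(X.T @ X)
            bse = np.sqrt(np.diag(cov))
        except np.linalg.LinAlgError:  # pragma: no cover - guarded by rank check
            bse = None
        return FourierSurface(
            params=params, box=self.box, n_modes=self.n_modes,
            resid_norm=float(np.linalg.norm(resid)), nobs=nobs,
            sigma2=sigma2, bse=bse,
        )


def fit_fourier_surface(points, box, n_modes: int = 2) -> FourierSurface:
    """Fit headgroup points to the truncated Fourier surface (see module doc)."""
    return FourierSurfaceModel(points, box, n_modes=n_modes).fit()


# ------------------------------------------------------------- grid fields

def _grid_centers(box, grid):
    nx, ny = grid
    x = (np.arange(nx) + 0.5) * (box[0] / nx)
    y = (np.arange(ny) + 0.5) * (box[1] / ny)
    return np.meshgrid(x, y, indexing="ij")


def mean_curvature_field(surface: FourierSurface, grid=(26, 26),
                         mode: str = "linearized") -> Field2D:
    """Sample H on a regular lattice of cell centers; units nm^-1."""
    X, Y = _grid_centers(surface.box, grid)
    H = surface.mean_curvature(X, Y, mode=mode)
    return Field2D(values=H, box=surface.box, units="nm^-1", kind="curvature",
                   meta={"mode": mode, "sign_convention": SIGN_CONVENTION,
                         "n_modes": surface.n_modes})


def thickness_field(upper: FourierSurface, lower: FourierSurface,
                    grid=(26, 26)) -> Field2D:
    """Vertical headgroup-to-headgroup distance z_upper - z_lower in nm."""
    if not np.allclose(upper.box, lower.box):
        raise ValueError("leaflet surfaces were fitted over different boxes")
    X, Y = _grid_centers(upper.box, grid)
    t = upper.evaluate(X, Y) - lower.evaluate(X, Y)
    if np.any(t < 0):
        raise LeafletOrderError("negative thickness: leaflet surfaces cross "
                                "(upper/lower swapped?)")
    return Field2D(values=t, box=upper.box, units="nm", kind="thickness")


@dataclass(frozen=True)
class CurvatureSummary:
    """Region- and time-averaged mean curvature ("curvature footprint")."""

    footprint_mean: float      # signed, nm^-1
    footprint_abs: float       # magnitude, nm^-1
    stderr: float              # across-replica SEM, 0 for a single replica
    region: str
    n_frames_used: int
    n_replicas: int
    sign_convention: str = SIGN_CONVENTION

    def to_dict(self) -> dict:
        return {
            "footprint_mean_nm^-1": self.footprint_mean,
            "footprint_abs_nm^-1": self.footprint_abs,
            "stderr_nm^-1": self.stderr,
            "region": self.region,
            "n_frames_used": self.n_frames_used,
            "n_replicas": self.n_replicas,
            "sign_convention": self.sign_convention,
        }


def terminal_window(n_frames: int, window: float) -> slice:
    """Slice selecting the terminal ``window`` fraction of ``n_frames``."""
    if not 0 < window <= 1:
        raise AggregationError("window fraction must lie in (0, 1]")
    start = n_frames - max(1, int(round(window * n_frames)))
    return slice(start, n_frames)


def curvature_footprint(fields, region=None, window: float = 0.4,
                        ) -> CurvatureSummary:
    """Average curvature fields over a region and a terminal time window.

    ``fields`` is a time series of curvature :class:`Field2D` (one replica)
    or a list of such series (several replicas).  The terminal ``window``
    fraction of each series is used — mirroring the convention of analysing
    only the equilibrated tail of a trajectory — and the scalar is the
    area-weighted mean of H over ``region`` (``None`` = whole box).  Across
    replicas the mean and standard error are reported.
    """
    if not fields:
        raise AggregationError("no curvature fields supplied")
    replicas = fields if isinstance(fields[0], (list, tuple)) else [fields]
    per_replica = []
    n_used = 0
    for series in replicas:
        if not series:
            raise AggregationError("empty replica series")
        sel = list(series[terminal_window(len(series), window)])
        n_used = len(sel)
        avg = mean_field(sel)
        per_replica.append(avg.mean(region))
    per_replica = np.asarray(per_replica)
    mean = float(per_replica.mean())
    stderr = float(per_replica.std(ddof=1) / np.sqrt(len(per_replica))) \
        if len(per_replica) > 1 else 0.0
    region_desc = region.describe() if region is not None else "full box"
    return CurvatureSummary(footprint_mean=mean, footprint_abs=abs(mean),
                            stderr=stderr, region=region_desc,
                            n_frames_used=n_used, n_replicas=len(per_replica))


# ------------------------------------------------- trajectory-level helpers

def leaflet_surfaces(traj: ParticleTrajectory, leaflets: LeafletAssignment,
                     n_modes: int = 2):
    """Per-frame (upper, lower) Fourier surfaces from a trajectory."""
    out = []
    for i in range(traj.n_frames):
        box = traj.boxes[i][:2]
        up = FourierSurfaceModel(traj.positions[i, leaflets.upper], box,
                                 n_modes=n_modes).fit()
        lo = FourierSurfaceModel(traj.positions[i, leaflets.lower], box,
                                 n_modes=n_modes).fit()
        out.append((up, lo))
    return out


def curvature_series(traj: ParticleTrajectory, leaflets: LeafletAssignment,
                     leaflet: str = "upper", n_modes: int = 2, grid=(26, 26),
                     mode: str = "linearized") -> list[Field2D]:
    """Per-frame mean-curvature fields of one leaflet."""
    idx = {"upper": leaflets.upper, "lower": leaflets.lower}[leaflet]
    out = []
    for i in range(traj.n_frames):
        surf = FourierSurfaceModel(traj.positions[i, idx], traj.boxes[i][:2],
                                   n_modes=n_modes).fit()
        out.append(mean_curvature_field(surf, grid=grid, mode=mode))
    return out


def thickness_series(traj: ParticleTrajectory, leaflets: LeafletAssignment,
                     n_modes: int = 2, grid=(26, 26)) -> list[Field2D]:
    """Per-frame thickness fields."""
    return [thickness_field(up, lo, grid=grid)
            for up, lo in leaflet_surfaces(traj, leaflets, n_modes=n_modes)]


def protein_footprint_region(traj: ParticleTrajectory, frame: int = -1,
                             selection: str = "protein") -> DiskRegion:
    """Bounding disk of the protein in the membrane plane: lateral centroid
    plus radius of gyration of the selected particles."""
    mask = select_mask(traj, selection)
    xy = traj.positions[frame, mask, :2]
    c = xy.mean(axis=0)
    rg = float(np.sqrt(((xy - c) ** 2).sum(axis=1).mean()))
    return DiskRegion(cx=float(c[0]), cy=float(c[1]), r=max(rg, 1e-6))
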