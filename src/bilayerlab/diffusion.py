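"""Lateral diffusion from mean-squared displacement (Einstein relation).

The MSD is accumulated over x-y displacements only,

    MSD(t) = < (r(t0 + t) - r(t0))^2 >,

averaged over the selected particles and over time origins t0 spaced
``origin_spacing`` apart (default 0.1 ns).  A straight line fitted through
MSD(t) for 0 < t <= t_max (default 50 ns) gives D = slope / 4 via
MSD = 4 D t for two-dimensional diffusion; the error estimate is the
difference between D fitted over the first and the second half of the fit
interval.  1 nm^2/ns = 1e-5 cm^2/s.
"""

from __future__ import annotations

from dataclasses import dataclass, field as dc_field

import numpy as np

from .errors import FitError, ParameterError
from .trajectory import ParticleTrajectory, select_mask

#: multiply a diffusivity in nm^2/ns by this to get cm^2/s
NM2_PER_NS_TO_CM2_PER_S = 1e-5


def nm2_ns_to_cm2_s(d: float) -> float:
    return d * NM2_PER_NS_TO_CM2_PER_S


def cm2_s_to_nm2_ns(d: float) -> float:
    return d / NM2_PER_NS_TO_CM2_PER_S


@dataclass
class MSDSeries:
    """Lag-indexed lateral MSD.

    ``lags`` (ns, starting at 0) strictly increase, ``msd`` (nm^2) is
    non-negative with ``msd[0] == 0``, and ``n_origins`` counts the time
    origins contributing at each lag.
    """

    lags: np.ndarray
    msd: np.ndarray
    n_origins: np.ndarray
    selection: str = "all"
    n_particles: int = 0
    meta: dict = dc_field(default_factory=dict)

    def __post_init__(self):
        self.lags = np.asarray(self.lags, dtype=float)
        self.msd = np.asarray(self.msd, dtype=float)
        self.n_origins = np.asarray(self.n_origins, dtype=int)
        if np.any(np.diff(self.lags) <= 0):
            raise ValueError("lags must be strictly increasing")
        if self.lags[0] != 0 or self.msd[0] != 0:
            raise ValueError("the zero-lag MSD must be present and zero")
        if np.any(self.msd < 0):
            raise ValueError("MSD must be non-negative")

    def to_csv(self, path) -> None:
        with open(path, "w") as fh:
            fh.write("lag_ns,msd_nm2\n")
            for t, m in zip(self.lags, self.msd):
                fh.write(f"{t:.10g},{m:.10g}\n")


def compute_msd(traj: ParticleTrajectory, selection="all",
                origin_spacing: float = 0.1, max_lag: float | None = None,
                remove_com: bool = True) -> MSDSeries:
    """Multi-origin lateral MSD of ``selection`` on an unwrapped trajectory.

    Parameters
    ----------
    origin_spacing : float
        Time between reference points t0, in ns; must be at least the frame
        spacing (it is rounded to a whole number of frames).
    max_lag : float, optional
        Largest lag in ns; defaults to half the trajectory length, beyond
        which too few origins remain for a stable average.
    remove_com : bool
        Subtract the per-frame lateral center of mass of the selection
        before accumulating displacements, so collective drift of the patch
        does not inflate the apparent diffusivity.
    """
    if traj.n_frames < 2:
        raise ParameterError("MSD needs at least two frames")
    dt = traj.time_step
    if origin_spacing < dt - 1e-12:
        raise ParameterError(
            f"origin_spacing={origin_spacing} ns is below the frame spacing "
            f"{dt} ns")
    stride = max(1, int(round(origin_spacing / dt)))

    mask = select_mask(traj, selection)
    xy = traj.positions[:, mask, :2].astype(float)
    if remove_com:
        xy = xy - xy.mean(axis=1, keepdims=True)

    F = traj.n_frames
    span = (F - 1) // 2 if max_lag is None else min(F - 1, int(round(max_lag / dt)))
    if span < 1:
        raise ParameterError("trajectory too short for the requested max_lag")

    lags = np.arange(span + 1) * dt
    msd = np.zeros(span + 1)
    n_origins = np.zeros(span + 1, dtype=int)
    n_origins[0] = (F - 1) // stride + 1
    origins = np.arange(0, F, stride)
    for ell in range(1, span + 1):
        o = origins[origins + ell < F]
        if o.size == 0:
            lags, msd, n_origins = lags[:ell], msd[:ell], n_origins[:ell]
            break
        if stride == 1:
            d = xy[ell:] - xy[:-ell]
        else:
            d = xy[o + ell] - xy[o]
        msd[ell] = np.mean(np.sum(d * d, axis=-1))
        n_origins[ell] = o.size
    return MSDSeries(lags=lags, msd=msd, n_origins=n_origins,
                     selection=str(selection), n_particles=int(mask.sum()),
                     meta={"origin_spacing_ns": origin_spacing,
                           "remove_com": remove_com})


@dataclass
class DiffusionResults:
    """Fitted lateral diffusion constant with the two-halves error bar."""

    D: float                    # cm^2/s
    D_error: float              # cm^2/s, |D_first_half - D_second_half|
    slope: float                # nm^2/ns
    intercept: float            # nm^2
    fit_window: tuple[float, float]
    halves: tuple[float, float]  # (D over (0, t/2], D over (t/2, t]) in cm^2/s
    n_points: int
    selection: str = "all"

    @property
    def D_nm2_ns(self) -> float:
        return cm2_s_to_nm2_ns(self.D)

    def to_dict(self) -> dict:
        return {
            "D_cm2_s": self.D,
            "D_error_cm2_s": self.D_error,
            "slope_nm2_ns": self.slope,
            "intercept_nm2": self.intercept,
            "fit_window_ns": list(self.fit_window),
            "halves_cm2_s": list(self.halves),
            "n_points": self.n_points,
            "selection": self.selection,
        }

    def summary(self) -> str:
        return "\n".join([
            "Lateral diffusion (Einstein relation, MSD = 4 D t)",
            "=" * 50,
            f"selection       : {self.selection}",
            f"fit window (ns) : ({self.fit_window[0]:g}, {self.fit_window[1]:g}]"
            f"  ({self.n_points} lags)",
            f"D               : {self.D:.4g} cm^2/s  ({self.D_nm2_ns:.4g} nm^2/ns)",
            f"two-halves error: {self.D_error:.4g} cm^2/s",
            f"half-window fits: {self.halves[0]:.4g} / {self.halves[1]:.4g} cm^2/s",
            f"intercept       : {self.intercept:.4g} nm^2",
        ])


class LateralDiffusionModel:
    """Straight-line Einstein-relation fit to an :class:`MSDSeries`.

    The fit has a free intercept: short-time ballistic/cage motion shifts
    the MSD but does not change the diffusive slope, which is the physical
    quantity.  Setting ``intercept=False`` forces the line through the
    origin instead.
    """

    def __init__(self, msd: MSDSeries, intercept: bool = True):
        self.msd = msd
        self.intercept = intercept

    def _line_fit(self, t, y) -> tuple[float, float]:
        """(slope, intercept) of the least-squares line (nm^2/ns, nm^2)."""
        if self.intercept:
            A = np.column_stack([t, np.ones_like(t)])
        else:
            A = t[:, None]
        coef, *_ = np.linalg.lstsq(A, y, rcond=None)
        return float(coef[0]), (float(coef[1]) if self.intercept else 0.0)

    def fit(self, t_max: float = 50.0) -> DiffusionResults:
        lags, msd = self.msd.lags, self.msd.msd
        if lags[-1] < t_max - 1e-9:
            raise FitError(
                f"MSD reaches only {lags[-1]:g} ns but t_max={t_max:g} ns")
        win = (lags > 0) & (lags <= t_max + 1e-12)
        if win.sum() < 3:
            raise FitError("fewer than 3 lag points in the fit window")
        slope, inter = self._line_fit(lags[win], msd[win])

        halves = []
        for lo, hi in ((0.0, t_max / 2), (t_max / 2, t_max)):
            m = (lags > lo + 1e-12) & (lags <= hi + 1e-12)
            if m.sum() < 2:
                raise FitError("a half-interval contains fewer than 2 lag points")
            s, _ = self._line_fit(lags[m], msd[m])
            halves.append(nm2_ns_to_cm2_s(s / 4.0))

        D = nm2_ns_to_cm2_s(slope / 4.0)
        return DiffusionResults(
            D=D, D_error=abs(halves[0] - halves[1]), slope=slope,
            intercept=inter, fit_window=(0.0, t_max),
            halves=(halves[0], halves[1]), n_points=int(win.sum()),
            selection=self.msd.selection,
        )


def fit_diffusion(msd: MSDSeries, t_max: float = 50.0,
                  intercept: bool = True) -> DiffusionResults:
    """Fit D (cm^2/s) from an MSD series; see :class:`LateralDiffusionModel`."""
    return LateralDiffusionModel(msd, intercept=intercept).fit(t_max=t_max)
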