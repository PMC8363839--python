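"""End-to-end analysis pipelines used by the CLI and convenient in scripts."""

from __future__ import annotations

import numpy as np

from . import surface as surf
from .diffusion import compute_msd, fit_diffusion
from .fields import DiskRegion
from .maps import density_map
from .metrics import ConditionSummary, area_per_lipid, mean_thickness
from .trajectory import ParticleTrajectory, assign_leaflets, select_mask, unwrap_lateral


def membrane_analysis(traj: ParticleTrajectory, label: str = "membrane",
                      n_modes: int = 2, grid=(26, 26), window: float = 0.4,
                      region: DiskRegion | None = None,
                      curvature_mode: str = "linearized",
                      origin_spacing: float = 0.1,
                      fit_tmax: float | None = None,
                      msd_selection: str = "POPS-P",
                      remove_com: bool = True) -> dict:
    """Run surface -> curvature/thickness -> maps -> diffusion -> metrics.

    ``region`` defaults to the protein's lateral bounding disk when protein
    particles are present, else the full box.  The diffusion stage runs only
    when the trajectory is long enough for at least three lag points in the
    fit window; ``fit_tmax`` defaults to half the trajectory length.
    Returns a dict with the per-stage artifacts and a
    :class:`ConditionSummary`.
    """
    leaflets = assign_leaflets(traj)

    if region is None and "protein" in set(map(str, traj.tags)):
        region = surf.protein_footprint_region(traj)

    curv = surf.curvature_series(traj, leaflets, leaflet="upper",
                                 n_modes=n_modes, grid=grid, mode=curvature_mode)
    footprint = surf.curvature_footprint(curv, region=region, window=window)
    thick = surf.thickness_series(traj, leaflets, n_modes=n_modes, grid=grid)
    w = surf.terminal_window(len(thick), window)
    from .fields import mean_field
    curv_mean = mean_field(curv[w])
    thick_mean = mean_field(thick[w])

    maps = {}
    tags = set(map(str, traj.tags))
    if "POPS-P" in tags:
        maps["pops_upper"] = density_map(traj, "POPS-P", leaflet="upper",
                                         leaflets=leaflets, grid=grid, window=window)
    if "TFP" in tags:
        maps["tfp"] = density_map(traj, "TFP", leaflet="both",
                                  leaflets=leaflets, grid=grid, window=window)

    n_head = int(sum(str(t).endswith("-P") for t in traj.tags))
    apl = area_per_lipid(traj.frame(traj.n_frames - 1), max(n_head // 2, 1))

    diffusion = None
    msd = None
    if traj.n_frames >= 8 and msd_selection in tags:
        try:
            unwrapped = unwrap_lateral(traj.subset(select_mask(traj, msd_selection)))
            msd = compute_msd(unwrapped, "all", origin_spacing=origin_spacing,
                              remove_com=remove_com)
            tmax = fit_tmax if fit_tmax is not None else float(msd.lags[-1])
            diffusion = fit_diffusion(msd, t_max=tmax)
        except Exception:
            diffusion = None

    summary = ConditionSummary(label=label, apl=apl,
                               mean_thickness=mean_thickness(thick_mean),
                               footprint=footprint, D=diffusion)
    return {
        "summary": summary,
        "leaflets": leaflets,
        "curvature_mean_field": curv_mean,
        "thickness_mean_field": thick_mean,
        "density_maps": maps,
        "msd": msd,
        "region": region,
        "window": window,
    }


def protein_free_baseline(spec=None, n_modes: int = 2, grid=(26, 26),
                          window: float = 1.0):
    """Time-averaged patch curvature of a protein-free fluctuating membrane.

    Generates an undulating bilayer (no dimple), runs the per-frame Fourier
    curvature pipeline on the upper leaflet, and returns the
    :class:`CurvatureSummary` of the time-averaged field over the full box.
    This is the null against which a protein's curvature footprint is
    judged.
    """
    from .fields import mean_field
    from .synthetic import BilayerSpec, gen_bilayer_trajectory

    if spec is None:
        spec = BilayerSpec(n_frames=240)
    traj, truth = gen_bilayer_trajectory(spec)
    leaflets = assign_leaflets(traj)
    per_leaflet = [surf.curvature_series(traj, leaflets, leaflet=which,
                                         n_modes=n_modes, grid=grid)
                   for which in ("upper", "lower")]
    curv = [mean_field([a, b]) for a, b in zip(*per_leaflet)]
    footprint = surf.curvature_footprint(curv, region=None, window=window)
    return footprint, truth


def afm_condition_height(images, lines=None, n_lines: int = 10):
    """Pool per-image step estimates into one per-condition height.

    ``images`` is a list of :class:`HeightImage` (conventionally three
    locations per sample, ten lines each -> 30 profiles per condition).
    """
    from .afm import StepEstimate, bilayer_height

    heights = []
    for img in images:
        est = bilayer_height(img, lines=lines, n_lines=n_lines)
        heights.extend(est.heights.tolist())
    heights = np.asarray(heights)
    sd = float(heights.std(ddof=1)) if heights.size > 1 else 0.0
    return StepEstimate(heights=heights, mean=float(heights.mean()), sd=sd,
                        n_lines=int(heights.size))
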