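"""Synthetic generators for every input class the analysis consumes.

Each generator is driven by a frozen spec dataclass (YAML round-trippable)
whose seed fully determines the output, and returns its ground truth
alongside the data, so every estimator in the package can be validated
against known parameters without MD runs or downloads.

The default bilayer composition mirrors a 520-lipid 80:20 POPC:POPS patch
in a ~13 x 13 nm periodic box with 0, 24 or 48 intercalated TFP molecules;
protein-free thermal undulations use per-mode Gaussian amplitudes with a
1/q^2 spectrum scaled to a given RMS roughness, and a bound protein is
emulated by a static Gaussian dimple in the upper leaflet.
"""

from __future__ import annotations

from dataclasses import asdict, dataclass, field as dc_field
from typing import Callable, Optional

import numpy as np
import yaml

from .errors import GeometryError, ParameterError
from .fields import DiskRegion, Field2D
from .trajectory import ParticleTrajectory
from .afm import HeightImage
from .surface import half_plane_modes


# ------------------------------------------------------------------ specs

class _YamlSpec:
    def to_yaml(self, path=None) -> str:
        doc = {"kind": self.kind, **asdict(self)}
        text = yaml.safe_dump(doc, sort_keys=False)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_yaml(cls, path_or_text):
        text = path_or_text
        try:
            with open(path_or_text) as fh:
                text = fh.read()
        except (OSError, TypeError):
            pass
        doc = yaml.safe_load(text)
        return spec_from_dict(doc)


@dataclass
class SurfaceSpec(_YamlSpec):
    """Static leaflet surface sampled by noisy points.

    ``amplitudes`` lists ``[m, n, cos_amp, sin_amp]`` entries (nm);
    ``dimple`` is ``[depth, width, cx, cy]`` (nm, signed depth) or None.
    """

    kind: str = "surface"
    box: tuple = (13.0, 13.0)
    n_points: int = 260
    amplitudes: list = dc_field(default_factory=list)
    dimple: Optional[list] = None
    noise_sigma: float = 0.0
    z0: float = 0.0
    seed: int = 0


@dataclass
class BilayerSpec(_YamlSpec):
    """Fluctuating two-leaflet patch with lateral Brownian lipid motion."""

    kind: str = "bilayer_traj"
    n_lipids: int = 520
    pops_fraction: float = 0.2
    n_tfp: int = 0
    box: tuple = (13.0, 13.0, 10.0)
    d0: float = 4.0                  # headgroup-to-headgroup distance, nm
    n_frames: int = 50
    dt_ns: float = 1.0
    d_pops: float = 9.9e-3           # nm^2/ns (= 9.9e-8 cm^2/s)
    d_popc: float = 1.1e-2
    d_tfp: float = 1.2e-2
    undulation_rms: float = 0.15     # nm
    undulation_modes: int = 2
    noise_sigma: float = 0.05        # headgroup z placement noise, nm
    dimple: Optional[list] = None    # [depth, width, cx, cy] on the upper leaflet
    seed: int = 0


@dataclass
class BrownianSpec(_YamlSpec):
    """Free 2-D random walkers with known diffusivity."""

    kind: str = "brownian"
    n: int = 1000
    d_nm2_ns: float = 9.9e-3
    dt_ns: float = 0.1
    n_frames: int = 1001
    box: tuple = (50.0, 50.0, 10.0)
    wrap: bool = False
    tag: str = "POPS-P"
    seed: int = 0


@dataclass
class AFMSpec(_YamlSpec):
    """Bilayer-on-mica topograph with circular holes to the substrate."""

    kind: str = "afm_image"
    shape: tuple = (256, 256)
    pixel_size: float = 4.0          # nm/px
    height: float = 4.0              # bilayer step, nm
    holes: Optional[list] = None     # [(cx, cy, r), ...] in px; None -> centered
    n_holes: int = 1
    tilt: tuple = (0.0, 0.0)         # nm/px along (x, y)
    noise_sigma: float = 0.0
    seed: int = 0


_SPEC_KINDS = {
    "surface": SurfaceSpec,
    "bilayer_traj": BilayerSpec,
    "brownian": BrownianSpec,
    "afm_image": AFMSpec,
}


def spec_from_dict(doc: dict):
    doc = dict(doc)
    kind = doc.pop("kind", None)
    if kind not in _SPEC_KINDS:
        raise ParameterError(f"unknown synthetic spec kind {kind!r}")
    cls = _SPEC_KINDS[kind]
    try:
        spec = cls(**doc)
    except TypeError as exc:
        raise ParameterError(f"bad {kind} spec: {exc}") from exc
    for tup_field in ("box", "shape", "tilt"):
        if hasattr(spec, tup_field):
            setattr(spec, tup_field, tuple(getattr(spec, tup_field)))
    return spec


def generate(spec):
    """Dispatch a spec to its generator."""
    return {
        "surface": gen_surface_points,
        "bilayer_traj": gen_bilayer_trajectory,
        "brownian": gen_brownian,
        "afm_image": gen_afm_image,
    }[spec.kind](spec)


# ------------------------------------------------------- analytic surfaces

def _fourier_eval(amplitudes, box, x, y, d2: bool = False):
    """Evaluate sum of cos/sin terms (or its Laplacian) at (x, y)."""
    out = np.zeros(np.broadcast(x, y).shape)
    for m, n, c, s in amplitudes:
        kx = 2.0 * np.pi * m / box[0]
        ky = 2.0 * np.pi * n / box[1]
        th = kx * x + ky * y
        val = c * np.cos(th) + s * np.sin(th)
        out += -(kx**2 + ky**2) * val if d2 else val
    return out


def _dimple_eval(dimple, x, y, d2: bool = False):
    depth, width, cx, cy = dimple
    r2 = (np.asarray(x) - cx) ** 2 + (np.asarray(y) - cy) ** 2
    g = depth * np.exp(-r2 / (2.0 * width**2))
    if not d2:
        return g
    return g * (r2 - 2.0 * width**2) / width**4


@dataclass
class SurfaceSample:
    """Noisy point sample of an analytic surface, with closed-form truth."""

    points: np.ndarray                       # (n, 3)
    z_func: Callable                         # z(x, y), noiseless
    curvature_func: Callable                 # linearized H(x, y) = lap(z)/2
    spec: SurfaceSpec

    def curvature_field(self, grid=(26, 26)) -> Field2D:
        nx, ny = grid
        x = (np.arange(nx) + 0.5) * (self.spec.box[0] / nx)
        y = (np.arange(ny) + 0.5) * (self.spec.box[1] / ny)
        X, Y = np.meshgrid(x, y, indexing="ij")
        return Field2D(values=self.curvature_func(X, Y), box=self.spec.box[:2],
                       units="nm^-1", kind="curvature", meta={"analytic": True})


def gen_surface_points(spec: SurfaceSpec) -> SurfaceSample:
    """Sample ``n_points`` noisy headgroup positions on an analytic surface.

    Points are uniform in x-y; z follows the Fourier amplitudes plus the
    optional Gaussian dimple, with i.i.d. Gaussian z-noise.  The returned
    closed-form curvature is the linearized mean curvature lap(z)/2 (the
    dimple term is analytic but not periodic; keep it well inside the box).
    """
    if spec.noise_sigma < 0:
        raise ParameterError("noise_sigma must be non-negative")
    rng = np.random.default_rng(spec.seed)
    box = spec.box

    def z_func(x, y):
        z = spec.z0 + _fourier_eval(spec.amplitudes, box, x, y)
        if spec.dimple is not None:
            z = z + _dimple_eval(spec.dimple, x, y)
        return z

    def curvature_func(x, y):
        h = 0.5 * _fourier_eval(spec.amplitudes, box, x, y, d2=True)
        if spec.dimple is not None:
            h = h + 0.5 * _dimple_eval(spec.dimple, x, y, d2=True)
        return h

    x = rng.uniform(0, box[0], spec.n_points)
    y = rng.uniform(0, box[1], spec.n_points)
    z = z_func(x, y)
    if spec.noise_sigma > 0:
        z = z + rng.normal(0, spec.noise_sigma, spec.n_points)
    return SurfaceSample(points=np.column_stack([x, y, z]), z_func=z_func,
                         curvature_func=curvature_func, spec=spec)


# ------------------------------------------------------ bilayer trajectory

def undulation_sigmas(n_modes: int, box, rms: float) -> dict:
    """Per-mode amplitude SD with a 1/q^2 spectrum normalized to ``rms``.

    The half-plane modes up to ``n_modes`` each get independent Gaussian
    cos/sin amplitudes of SD sigma_q proportional to 1/q^2 (soft, bending-
    dominated long wavelengths), scaled so the expected spatial RMS height
    equals ``rms``.
    """
    modes = half_plane_modes(n_modes)
    q1sq = (2.0 * np.pi / max(box[0], box[1])) ** 2
    raw = {}
    for m, n in modes:
        qsq = (2.0 * np.pi * m / box[0]) ** 2 + (2.0 * np.pi * n / box[1]) ** 2
        raw[(m, n)] = q1sq / qsq
    norm = np.sqrt(sum(v**2 for v in raw.values()))
    if norm == 0 or rms == 0:
        return {k: 0.0 for k in raw}
    return {k: rms * v / norm for k, v in raw.items()}


@dataclass
class BilayerTruth:
    """Generative ground truth retained with a synthetic bilayer trajectory."""

    upper: np.ndarray
    lower: np.ndarray
    d0: float
    D: dict                       # nm^2/ns per tag
    undulation_draws: list        # per frame: list of (m, n, c, s)
    dimple: Optional[list]
    footprint_region: Optional[DiskRegion]
    spec: BilayerSpec


def gen_bilayer_trajectory(spec: BilayerSpec):
    """Two-leaflet tagged particle trajectory plus its ground truth.

    Headgroups sit at ``midplane +- d0/2`` on a shared (bending-mode)
    undulation surface redrawn each frame, with per-species lateral Brownian
    motion wrapped into the periodic box and optional placement noise.  The
    optional dimple deforms the upper leaflet only, emulating the static
    footprint of a bound protein.
    """
    n_per = spec.n_lipids // 2
    if spec.n_lipids % 2:
        raise ParameterError("n_lipids must split evenly between leaflets")
    n_pops = spec.pops_fraction * n_per
    if abs(n_pops - round(n_pops)) > 1e-9:
        raise ParameterError("pops_fraction * lipids-per-leaflet must be integral")
    n_pops = int(round(n_pops))
    if spec.n_tfp % 2:
        raise ParameterError("n_tfp must split evenly between leaflets")
    n_tfp_per = spec.n_tfp // 2

    rng = np.random.default_rng(spec.seed)
    box = spec.box
    leaf_tags = (["POPS-P"] * n_pops + ["POPC-P"] * (n_per - n_pops)
                 + ["TFP"] * n_tfp_per)
    tags = np.array(leaf_tags * 2, dtype=object)
    n_leaf = len(leaf_tags)
    upper = np.arange(n_leaf)
    lower = np.arange(n_leaf, 2 * n_leaf)

    d_by_tag = {"POPS-P": spec.d_pops, "POPC-P": spec.d_popc, "TFP": spec.d_tfp}
    step_sd = np.array([np.sqrt(2.0 * d_by_tag[str(t)] * spec.dt_ns) for t in tags])

    sigmas = undulation_sigmas(spec.undulation_modes, box, spec.undulation_rms)
    mid = box[2] / 2.0
    sign = np.where(np.isin(np.arange(2 * n_leaf), upper), 1.0, -1.0)

    xy = rng.uniform(0, 1, (2 * n_leaf, 2)) * np.array(box[:2])
    pos = np.empty((spec.n_frames, 2 * n_leaf, 3))
    draws = []
    for f in range(spec.n_frames):
        if f > 0:
            xy = np.mod(xy + rng.normal(0, 1, xy.shape) * step_sd[:, None],
                        np.array(box[:2]))
        amps = [(m, n, rng.normal(0, s), rng.normal(0, s))
                for (m, n), s in sigmas.items()]
        draws.append(amps)
        z = mid + sign * (spec.d0 / 2.0) \
            + _fourier_eval(amps, box, xy[:, 0], xy[:, 1])
        if spec.dimple is not None:
            z[upper] += _dimple_eval(spec.dimple, xy[upper, 0], xy[upper, 1])
        if spec.noise_sigma > 0:
            z = z + rng.normal(0, spec.noise_sigma, z.shape)
        pos[f, :, :2] = xy
        pos[f, :, 2] = z

    traj = ParticleTrajectory(
        positions=pos,
        boxes=np.tile(np.asarray(box, dtype=float), (spec.n_frames, 1)),
        times=np.arange(spec.n_frames) * spec.dt_ns,
        tags=tags, source=f"synthetic:bilayer(seed={spec.seed})",
    )
    region = None
    if spec.dimple is not None:
        depth, width, cx, cy = spec.dimple
        region = DiskRegion(cx=cx, cy=cy, r=width)
    truth = BilayerTruth(upper=upper, lower=lower, d0=spec.d0, D=d_by_tag,
                         undulation_draws=draws, dimple=spec.dimple,
                         footprint_region=region, spec=spec)
    return traj, truth


# ------------------------------------------------------------ random walks

def gen_brownian(spec: BrownianSpec):
    """Unwrapped 2-D random walk trajectory and its generative diffusivity.

    Per-axis step variance is 2 * D * dt.  With ``wrap=True`` the returned
    coordinates are wrapped into the box (exercising lateral unwrapping);
    otherwise they are continuous.
    """
    if spec.d_nm2_ns < 0 or spec.dt_ns <= 0:
        raise ParameterError("need D >= 0 and dt > 0")
    rng = np.random.default_rng(spec.seed)
    box = np.asarray(spec.box, dtype=float)
    sd = np.sqrt(2.0 * spec.d_nm2_ns * spec.dt_ns)
    start = rng.uniform(0, 1, (spec.n, 2)) * box[:2]
    steps = rng.normal(0, sd, (spec.n_frames - 1, spec.n, 2))
    xy = np.concatenate([start[None], start[None] + np.cumsum(steps, axis=0)])
    pos = np.zeros((spec.n_frames, spec.n, 3))
    pos[:, :, :2] = np.mod(xy, box[:2]) if spec.wrap else xy
    pos[:, :, 2] = box[2] / 2.0
    traj = ParticleTrajectory(
        positions=pos, boxes=np.tile(box, (spec.n_frames, 1)),
        times=np.arange(spec.n_frames) * spec.dt_ns,
        tags=np.array([spec.tag] * spec.n, dtype=object),
        source=f"synthetic:brownian(seed={spec.seed})",
    )
    return traj, spec.d_nm2_ns


# -------------------------------------------------------------- AFM images

def gen_afm_image(spec: AFMSpec):
    """Synthetic topograph: substrate at 0, plateau at ``height``, circular
    holes to the substrate, optional tilt plane and Gaussian noise."""
    h, w = spec.shape
    rng = np.random.default_rng(spec.seed)
    if spec.holes is not None:
        holes = [tuple(map(float, hole)) for hole in spec.holes]
    elif spec.n_holes == 1:
        holes = [(w / 2.0, h / 2.0, min(h, w) / 6.0)]
    else:
        holes = []
        r = min(h, w) / 10.0
        for _ in range(spec.n_holes):
            holes.append((rng.uniform(r + 2, w - r - 2),
                          rng.uniform(r + 2, h - r - 2), r))
    C, R = np.meshgrid(np.arange(w), np.arange(h))
    data = np.full((h, w), float(spec.height))
    hole_mask = np.zeros((h, w), dtype=bool)
    for cx, cy, radius in holes:
        if 2 * radius > min(h, w):
            raise GeometryError("hole diameter exceeds the image")
        if not (0 <= cx <= w - 1 and 0 <= cy <= h - 1):
            raise GeometryError("hole center lies outside the image")
        hole_mask |= (C - cx) ** 2 + (R - cy) ** 2 <= radius**2
    data[hole_mask] = 0.0
    data = data + spec.tilt[0] * C + spec.tilt[1] * R
    if spec.noise_sigma > 0:
        data = data + rng.normal(0, spec.noise_sigma, data.shape)
    image = HeightImage(data=data, pixel_size=spec.pixel_size,
                        label=f"synthetic:afm(seed={spec.seed})")
    truth = {"height": spec.height, "holes": holes,
             "hole_fraction": float(hole_mask.mean())}
    return image, truth
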