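"""Fourier surface fitting, curvature and thickness fields."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

import bilayerlab as bl
from bilayerlab.surface import design_matrix, half_plane_modes
from tests.conftest import make_traj

BOX = (13.0, 13.0)
Q1 = 2 * np.pi / 13.0


def _sample(rng, n=260):
    return rng.uniform(0, BOX[0], n), rng.uniform(0, BOX[1], n)


# ------------------------------------------------------------------- fits

def test_dc_only_surface():
    rng = np.random.default_rng(0)
    x, y = _sample(rng)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, np.full_like(x, 1.7)]),
                                  BOX, 2)
    assert np.isclose(surf.params[0], 1.7)
    assert np.all(np.abs(surf.params[1:]) < 1e-9)


def test_noiseless_sinusoid_amplitude_recovered_exactly():
    rng = np.random.default_rng(1)
    x, y = _sample(rng)
    z = 0.5 * np.sin(Q1 * x)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 2)
    c, s = surf.amplitude(1, 0)
    assert abs(s - 0.5) < 1e-9 and abs(c) < 1e-9
    others = [a for k, (m, n) in enumerate(surf.modes) if (m, n) != (1, 0)
              for a in surf.params[1 + 2 * k: 3 + 2 * k]]
    assert np.all(np.abs(others) < 1e-9)


@given(seed=st.integers(0, 10_000),
       n=st.integers(30, 64), m_cut=st.integers(1, 2))
@settings(derandomize=True, max_examples=40, deadline=None)
def test_fit_equals_normal_equations_oracle(seed, n, m_cut):
    """The lstsq solution must agree with brute-force normal equations."""
    rng = np.random.default_rng(seed)
    x = rng.uniform(0, BOX[0], n)
    y = rng.uniform(0, BOX[1], n)
    z = rng.normal(0, 1, n)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, m_cut)
    X = design_matrix(x, y, BOX, m_cut)
    oracle = np.linalg.solve(X.T @ X, X.T @ z)
    assert np.linalg.norm(surf.params - oracle) <= 1e-8 * max(
        np.linalg.norm(oracle), 1.0)


def test_amplitude_estimates_unbiased_under_noise():
    """Monte Carlo: noisy fits of a sinusoid are unbiased within 3 SE."""
    draws = []
    for seed in range(50):
        rng = np.random.default_rng(seed)
        x, y = _sample(rng)
        z = 0.5 * np.sin(Q1 * x) + rng.normal(0, 0.1, x.size)
        surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 2)
        draws.append(surf.amplitude(1, 0)[1])
    draws = np.asarray(draws)
    sem = draws.std(ddof=1) / np.sqrt(draws.size)
    assert abs(draws.mean() - 0.5) < 3 * sem


def test_too_few_points_raises():
    with pytest.raises(bl.FitError):
        bl.FourierSurfaceModel(np.zeros((10, 3)), BOX, n_modes=2)


def test_collinear_points_rank_deficient():
    y = np.linspace(0, 12, 80)
    pts = np.column_stack([np.full_like(y, 3.0), y, np.sin(y)])
    with pytest.raises(bl.FitError):
        bl.fit_fourier_surface(pts, BOX, 2)


# -------------------------------------------------------------- curvature

def test_flat_surface_zero_curvature():
    rng = np.random.default_rng(2)
    x, y = _sample(rng)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, np.zeros_like(x)]),
                                  BOX, 2)
    field = bl.mean_curvature_field(surf, (26, 26))
    assert np.all(np.abs(field.values) < 1e-12)


def test_sinusoid_curvature_extremum_and_finite_differences():
    rng = np.random.default_rng(3)
    x, y = _sample(rng)
    z = 0.5 * np.sin(Q1 * x)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 2)
    field = bl.mean_curvature_field(surf, (260, 4))
    peak = 0.5 * Q1**2 / 2  # 0.0584 nm^-1
    assert np.isclose(field.values.min(), -peak, rtol=1e-3)
    assert np.isclose(field.values.max(), peak, rtol=1e-3)
    # central finite differences of the evaluated surface as an oracle
    h = 1e-4
    xs = np.linspace(0, 13, 40)
    for x0 in xs:
        zxx = (surf.evaluate(x0 + h, 1.0) - 2 * surf.evaluate(x0, 1.0)
               + surf.evaluate(x0 - h, 1.0)) / h**2
        zyy = (surf.evaluate(x0, 1.0 + h) - 2 * surf.evaluate(x0, 1.0)
               + surf.evaluate(x0, 1.0 - h)) / h**2
        assert np.isclose(surf.mean_curvature(x0, 1.0), 0.5 * (zxx + zyy),
                          atol=1e-6)


def test_gaussian_bump_curvature_at_center():
    """Projected bump: H(center) ~ -A/s^2 within the mode-truncation error."""
    rng = np.random.default_rng(4)
    A, s, c = 1.0, 2.0, 6.5
    x = rng.uniform(0, 13, 2000)
    y = rng.uniform(0, 13, 2000)
    z = A * np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2 * s**2))
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 4)
    h_center = float(surf.mean_curvature(c, c))
    assert np.isclose(h_center, -A / s**2, rtol=0.02)


def test_linearized_and_full_curvature_agree_for_small_slopes():
    rng = np.random.default_rng(5)
    x, y = _sample(rng)
    amp = 0.05  # max slope = amp * q1 ~ 0.024 < 0.05
    z = amp * np.sin(Q1 * x)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 2)
    g = np.linspace(0, 13, 50)
    X, Y = np.meshgrid(g, g)
    lin = surf.mean_curvature(X, Y, mode="linearized")
    full = surf.mean_curvature(X, Y, mode="full")
    scale = np.abs(lin).max()
    assert np.all(np.abs(full - lin) <= 0.01 * scale)


def test_curvature_has_zero_box_mean():
    rng = np.random.default_rng(6)
    x, y = _sample(rng)
    z = rng.normal(0, 0.3, x.size)
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 2)
    field = bl.mean_curvature_field(surf, (26, 26))
    assert abs(field.values.mean()) < 1e-10


# -------------------------------------------------------------- thickness

def _surface_from_func(fn, seed, n_modes=2):
    rng = np.random.default_rng(seed)
    x, y = _sample(rng)
    return bl.fit_fourier_surface(np.column_stack([x, y, fn(x, y)]), BOX,
                                  n_modes)


def test_flat_leaflets_constant_thickness():
    up = _surface_from_func(lambda x, y: np.full_like(x, 2.0), 7)
    lo = _surface_from_func(lambda x, y: np.full_like(x, -2.0), 8)
    field = bl.thickness_field(up, lo, (26, 26))
    assert np.allclose(field.values, 4.0)


def test_parallel_undulation_cancels_in_thickness():
    up = _surface_from_func(lambda x, y: 2 + 0.5 * np.sin(Q1 * x), 9)
    lo = _surface_from_func(lambda x, y: -2 + 0.5 * np.sin(Q1 * x), 10)
    field = bl.thickness_field(up, lo, (26, 26))
    assert np.allclose(field.values, 4.0, atol=1e-9)


def test_one_sided_undulation_thickness_extremes():
    up = _surface_from_func(lambda x, y: 2 + 0.2 * np.sin(Q1 * x), 11)
    lo = _surface_from_func(lambda x, y: np.full_like(x, -2.0), 12)
    field = bl.thickness_field(up, lo, (260, 4))
    assert np.isclose(field.values.max(), 4.2, atol=1e-3)
    assert np.isclose(field.values.min(), 3.8, atol=1e-3)


def test_crossing_leaflets_raise_order_error():
    up = _surface_from_func(lambda x, y: np.full_like(x, -2.0), 13)
    lo = _surface_from_func(lambda x, y: np.full_like(x, 2.0), 14)
    with pytest.raises(bl.LeafletOrderError):
        bl.thickness_field(up, lo, (26, 26))


# -------------------------------------------------------------- footprint

def test_footprint_of_flat_surfaces_is_zero():
    fields = []
    for seed in range(5):
        surf = _surface_from_func(lambda x, y: np.zeros_like(x), 20 + seed)
        fields.append(bl.mean_curvature_field(surf, (26, 26)))
    fp = bl.curvature_footprint(fields, region=None, window=0.4)
    assert abs(fp.footprint_mean) < 1e-12
    assert fp.stderr == 0.0


def test_footprint_matches_numeric_disk_average_of_analytic_curvature():
    A, s, c = -1.0, 2.0, 6.5
    rng = np.random.default_rng(30)
    x = rng.uniform(0, 13, 4000)
    y = rng.uniform(0, 13, 4000)
    z = A * np.exp(-((x - c) ** 2 + (y - c) ** 2) / (2 * s**2))
    surf = bl.fit_fourier_surface(np.column_stack([x, y, z]), BOX, 5)
    field = bl.mean_curvature_field(surf, (80, 80))
    region = bl.DiskRegion(cx=c, cy=c, r=s)
    fp = bl.curvature_footprint([field], region=region, window=1.0)
    # oracle: quasi-uniform numeric average of the analytic H over the disk
    gr = np.linspace(c - s, c + s, 400)
    GX, GY = np.meshgrid(gr, gr)
    inside = (GX - c) ** 2 + (GY - c) ** 2 <= s**2
    r2 = (GX - c) ** 2 + (GY - c) ** 2
    H = A * np.exp(-r2 / (2 * s**2)) * (r2 - 2 * s**2) / (2 * s**4)
    oracle = H[inside].mean()
    assert np.isclose(fp.footprint_mean, oracle, rtol=0.05)
    assert fp.footprint_abs == abs(fp.footprint_mean)


def test_footprint_across_replicas_reports_stderr():
    replicas = []
    for r in range(3):
        series = []
        for seed in range(4):
            surf = _surface_from_func(
                lambda x, y: (0.1 + 0.02 * r) * np.sin(Q1 * x), 40 + 10 * r + seed)
            series.append(bl.mean_curvature_field(surf, (26, 26)))
        replicas.append(series)
    region = bl.RectRegion(x0=2, x1=5, y0=0, y1=13)
    fp = bl.curvature_footprint(replicas, region=region, window=0.5)
    assert fp.n_replicas == 3 and fp.n_frames_used == 2
    assert fp.stderr > 0


def test_footprint_empty_window_raises():
    with pytest.raises(bl.AggregationError):
        bl.curvature_footprint([], region=None)


def test_protein_footprint_region_from_tagged_particles(rng):
    pos = np.zeros((1, 50, 3))
    pos[0, :, :2] = rng.normal(6.5, 1.0, (50, 2))
    traj = make_traj(pos, tags=["protein"] * 50)
    region = bl.protein_footprint_region(traj)
    assert np.isclose(region.cx, 6.5, atol=0.5)
    assert 0.5 < region.r < 2.5
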