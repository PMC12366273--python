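"""Diffusion-decay solver: closed forms, conservation, and a dense oracle."""

import numpy as np
import pytest
from scipy.linalg import expm

import gradientchip as gc
from gradientchip.device import ChannelSegment
from gradientchip.synthetic import NO_DECAY, generate_pde_testcase
from gradientchip.transport import Grid


def _single_loading(reservoirs, conc, name="X", duration=2 * 86400.0):
    media = gc.MediaComposition("m", {name: conc})
    return gc.FeedingSchedule(
        tuple(gc.MediaEvent(0.0, (r,), "full", media) for r in reservoirs),
        duration=duration)


def test_pure_decay_matches_closed_form():
    """With no transport, a uniform field halves every half-life (0.1%)."""
    case = generate_pde_testcase("pure_decay")
    field = gc.simulate_factor(
        case.factor, case.geometry, case.schedule, grid=case.grid,
        duration=case.duration, snapshot_interval=case.snapshot_interval,
        initial=case.initial, clamp_boundaries=case.clamp_boundaries)
    expected = case.expected(field.times)
    for i, c_exp in enumerate(expected):
        assert field.values[i] == pytest.approx(c_exp, rel=1e-3)


def test_steady_state_uniform_at_clamped_value():
    """Fully clamped long edges, no decay: the field relaxes to the boundary."""
    case = generate_pde_testcase("steady_uniform")
    field = gc.simulate_factor(
        case.factor, case.geometry, case.schedule, grid=case.grid,
        duration=case.duration, snapshot_interval=case.snapshot_interval,
        clamp_boundaries=True)
    final = field.values[-1]
    assert final == pytest.approx(case.expected(field.times)[-1], rel=0.01)


def test_mass_conservation_no_flux():
    """All-wall chamber without decay conserves total mass to 1e-6 relative."""
    factor = gc.GrowthFactor("X", 10.0, 1000.0, 150.0, NO_DECAY, 1.0)
    geometry = gc.ChipGeometry(length=2.0, width=1.0, channel_segment_length=0.8)
    grid = Grid(spacing=0.05, nx=40, ny=20)
    rng = np.random.default_rng(0)
    initial = rng.uniform(0.0, 10.0, size=(grid.ny, grid.nx))
    # snapshot_interval/dt ~ 600 substeps x 20 snapshots > 1e4 steps
    field = gc.simulate_factor(
        factor, geometry, _single_loading((), 0.0), grid=grid,
        duration=7.5e4, snapshot_interval=3750.0,
        initial=initial, clamp_boundaries=False)
    masses = field.values.sum(axis=(1, 2))
    assert np.all(np.abs(masses - masses[0]) / masses[0] < 1e-6)


def test_maximum_principle_and_nonnegativity(factors):
    """0 <= C <= supplemented concentration on every snapshot."""
    igf = factors["IGF-1"]
    geometry = gc.ChipGeometry()
    field = gc.simulate_factor(
        igf, geometry, _single_loading(("left",), igf.supplemented_conc,
                                       name="IGF-1", duration=6 * 3600.0),
        grid=Grid(spacing=0.1, nx=79, ny=13),
        duration=6 * 3600.0, snapshot_interval=1800.0, factors=factors)
    assert field.values.min() >= 0.0
    assert field.values.max() <= igf.supplemented_conc * (1 + 1e-12)


def test_linearity_in_supplemented_concentration():
    """Scaling the boundary concentration scales the whole field (1e-9 rel)."""
    geometry = gc.ChipGeometry(length=2.0, width=1.0, channel_segment_length=0.8)
    grid = Grid(spacing=0.1, nx=20, ny=10)
    f1 = gc.GrowthFactor("X", 10.0, 1000.0, 150.0, 7200.0, 1.0)
    alpha = 3.7
    f2 = gc.GrowthFactor("X", 10.0 * alpha, 1000.0, 150.0, 7200.0, 1.0)
    kw = dict(grid=grid, duration=2 * 3600.0, snapshot_interval=1800.0)
    c1 = gc.simulate_factor(f1, geometry, _single_loading(("left",), 10.0), **kw)
    c2 = gc.simulate_factor(f2, geometry,
                            _single_loading(("left",), 10.0 * alpha), **kw)
    scale = np.abs(c2.values - alpha * c1.values)
    assert scale.max() <= 1e-9 * max(1.0, alpha * c1.values.max())


def test_reflection_symmetry():
    """A right-fed chip mirrors the left-fed chip about mid-length."""
    case = generate_pde_testcase("reflection_symmetry")
    kw = dict(grid=case.grid, duration=case.duration,
              snapshot_interval=case.snapshot_interval)
    left = gc.simulate_factor(case.factor, case.geometry,
                              _single_loading(("left",), 10.0), **kw)
    right = gc.simulate_factor(case.factor, case.mirror_geometry,
                               _single_loading(("right",), 10.0), **kw)
    assert np.allclose(left.values, right.values[:, :, ::-1], atol=1e-10)


def test_monotone_decay_after_boundary_exhaustion(factors):
    """Once the reservoir is weaker than every cell, cells only lose mass."""
    igf = factors["IGF-1"]
    geometry = gc.ChipGeometry(length=2.0, width=1.0, channel_segment_length=0.8)
    field = gc.simulate_factor(
        igf, geometry, _single_loading(("left",), 15.0, name="IGF-1",
                                       duration=8 * 3600.0),
        grid=Grid(spacing=0.1, nx=20, ny=10),
        duration=8 * 3600.0, snapshot_interval=1800.0, factors=factors)
    boundary = 15.0 * 2.0 ** (-field.times / igf.half_life)
    interior_min = field.values.reshape(len(field.times), -1).min(axis=1)
    late = np.flatnonzero(boundary < interior_min)
    late = late[late > 0]
    if late.size >= 2:
        diffs = np.diff(field.values[late], axis=0)
        assert diffs.max() <= 1e-12


def test_against_dense_matrix_exponential_oracle():
    """FTCS agrees with an independent dense ODE solution on a 5x5 grid.

    The semi-discrete system dc/dt = A c + s (diffusion with mirrored walls,
    Dirichlet source cells folded into s, first-order decay) is solved exactly
    with the matrix exponential and compared with the stepped field.
    """
    n = 5
    h_mm = 0.1
    h_um = 100.0
    D = 120.0
    half_life = 7200.0
    k = np.log(0.5) / half_life
    c0 = 10.0
    geometry = gc.ChipGeometry(length=0.5, width=0.5, channel_segment_length=0.25,
                               segments=(ChannelSegment("top", "left", "left"),
                                         ChannelSegment("bottom", "left", "left")))
    grid = Grid(spacing=h_mm, nx=n, ny=n)
    factor = gc.GrowthFactor("X", c0, 1000.0, D, half_life, 1.0)
    T = 3600.0
    field = gc.simulate_factor(
        factor, geometry, _single_loading(("left",), c0, duration=T),
        grid=grid, duration=T, snapshot_interval=T, safety=0.2)

    # clamped cells: top and bottom rows where x <= 0.25 mm (cols 0..2)
    x = (np.arange(n) + 0.5) * h_mm
    clamped = np.zeros((n, n), dtype=bool)
    clamped[0, x <= 0.25] = True
    clamped[-1, x <= 0.25] = True

    interior = ~clamped
    idx = {tuple(p): i for i, p in enumerate(np.argwhere(interior))}
    m = len(idx)
    A = np.zeros((m, m))
    s0 = np.zeros(m)  # source coefficient multiplying the decaying boundary
    coef = D / (h_um * h_um)
    for (r, c), i in idx.items():
        A[i, i] += k
        for dr, dc in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            rr, cc = r + dr, c + dc
            if not (0 <= rr < n and 0 <= cc < n):
                continue  # mirrored wall: zero flux, no coupling
            A[i, i] -= coef
            if clamped[rr, cc]:
                s0[i] += coef
            else:
                A[i, idx[(rr, cc)]] += coef
    # boundary decays as c0 * exp(k t): solve the augmented linear system
    # d/dt [c; b] = [[A, s0], [0, k]] [c; b], c(0)=0, b(0)=c0
    M = np.zeros((m + 1, m + 1))
    M[:m, :m] = A
    M[:m, m] = s0
    M[m, m] = k
    z0 = np.zeros(m + 1)
    z0[m] = c0
    z = expm(M * T) @ z0
    oracle = np.full((n, n), np.nan)
    for (r, c), i in idx.items():
        oracle[r, c] = z[i]
    oracle[clamped] = c0 * np.exp(k * T)

    diff = field.values[-1] - oracle
    rms = np.sqrt(np.mean(diff ** 2))
    assert rms < 0.005 * c0


def test_grid_convergence():
    """Halving the spacing changes the field by < 2% RMS of its peak."""
    geometry = gc.ChipGeometry(length=2.0, width=1.0, channel_segment_length=0.8)
    factor = gc.GrowthFactor("X", 10.0, 1000.0, 120.0, 14400.0, 1.0)
    sched = _single_loading(("left",), 10.0, duration=6 * 3600.0)
    kw = dict(duration=6 * 3600.0, snapshot_interval=6 * 3600.0)
    coarse = gc.simulate_factor(factor, geometry, sched,
                                grid=Grid(spacing=0.1, nx=20, ny=10), **kw)
    fine = gc.simulate_factor(factor, geometry, sched,
                              grid=Grid(spacing=0.05, nx=40, ny=20), **kw)
    fine_avg = fine.values[-1].reshape(10, 2, 20, 2).mean(axis=(1, 3))
    diff = coarse.values[-1] - fine_avg
    assert np.sqrt(np.mean(diff ** 2)) < 0.02 * 10.0


def test_simulate_media_runs_all_factors(factors, media):
    geometry = gc.ChipGeometry()
    sched = gc.FeedingSchedule(
        (gc.MediaEvent(0.0, ("left",), "full", media["vascular"]),
         gc.MediaEvent(0.0, ("right",), "full", media["adipogenic_initiation"])),
        duration=1 * 86400.0)
    result = gc.simulate_media(
        {"left": media["vascular"], "right": media["adipogenic_initiation"]},
        geometry, sched, factors=factors,
        grid=Grid(spacing=0.2, nx=40, ny=7),
        duration=4 * 3600.0, snapshot_interval=3600.0)
    assert set(result.fields) == {"IGF-1", "VEGF", "EGF", "FGF-b", "DEX", "insulin"}
    assert result.fed_from["IGF-1"] == "left"
    assert result.fed_from["DEX"] == "right"


def test_simulate_media_rejects_empty_pair(factors):
    with pytest.raises(ValueError):
        gc.simulate_media({}, gc.ChipGeometry(),
                          _single_loading((), 0.0), factors=factors)


def test_coarse_grid_rejected():
    with pytest.raises(ValueError):
        Grid(spacing=1.0, nx=8, ny=1)
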