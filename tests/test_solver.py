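import numpy as np
import pytest

from gliofront.models import ModelParams
from gliofront.solver import (DensityProfile, FrontAbsentError, Grid1D,
                              SolverError, front_position, front_speed,
                              integrate, tail_decay_rate, total_mass)

ALLEE0 = ModelParams(beta=0.0, kind="allee")
LOGISTIC = ModelParams(kind="logistic")


def _grid(L=40.0, dx=0.1, x0=0.0):
    return Grid1D(x0=x0, L=L, nx=int(round(L / dx)))


def test_grid_validation_and_geometry():
    g = _grid(L=10.0, dx=0.5)
    assert g.dx == pytest.approx(0.5)
    # cell-centred nodes: first at x0 + dx/2
    assert g.x[0] == pytest.approx(0.25)
    assert len(g.x) == 20
    with pytest.raises(ValueError):
        Grid1D(x0=0.0, L=1.0, nx=8)


def test_uniform_carrying_capacity_is_fixed_point():
    g = _grid()
    for p in (LOGISTIC, ALLEE0, ModelParams(beta=-0.1, kind="allee")):
        init = DensityProfile(g, np.full(g.nx, p.K), 0.0)
        traj = integrate(init, p, 5.0)
        assert np.max(np.abs(traj.final.C - p.K)) < 1e-12


def test_positivity_and_nonnegativity():
    g = _grid()
    init = DensityProfile.seed(g, ALLEE0)
    traj = integrate(init, ALLEE0, 6.0)
    assert np.all(traj.profiles >= 0)
    assert traj.clamped_nodes == 0 or traj.clamped_nodes < g.nx


def test_cfl_refusal():
    g = _grid(dx=0.1)
    init = DensityProfile.seed(g, LOGISTIC)
    with pytest.raises(SolverError):
        integrate(init, LOGISTIC, 1.0, dt=0.1)  # dt >> 0.4 dx^2 / 2D


def test_timestep_refinement_oracle():
    """Halving dt twice changes the solution by < 1e-3 K (explicit Euler
    is O(dt); the auto step is already well inside the stable region)."""
    g = _grid(L=60.0)
    init = DensityProfile.seed(g, LOGISTIC, centre=1.0, width=2.0)
    dt0 = 0.4 * g.dx**2 / 2.0
    a = integrate(init, LOGISTIC, 4.0, dt=dt0)
    b = integrate(init, LOGISTIC, 4.0, dt=dt0 / 10.0)
    assert np.max(np.abs(a.final.C - b.final.C)) < 1e-3


def test_front_position_interpolates_exactly():
    g = _grid(L=10.0, dx=0.5)
    # linear ramp crossing 0.5 exactly once
    C = np.clip(1.0 - g.x / 8.0, 0.0, 1.0)
    prof = DensityProfile(g, C, 0.0)
    assert front_position(prof, level=0.5) == pytest.approx(4.0, abs=1e-12)
    with pytest.raises(FrontAbsentError):
        front_position(DensityProfile(g, np.zeros(g.nx), 0.0), level=0.5)


def test_front_speed_needs_enough_samples():
    g = _grid(L=30.0)
    init = DensityProfile.seed(g, LOGISTIC, centre=1.0, width=2.0)
    traj = integrate(init, LOGISTIC, 1.0)
    with pytest.raises(ValueError):
        front_speed(traj, window=(0.99, 1.0))


def test_tail_decay_rate_trivial_exponential():
    g = _grid(L=40.0, dx=0.02)
    C = np.exp(-2.0 * g.x)
    rate = tail_decay_rate(DensityProfile(g, C, 0.0))
    assert rate == pytest.approx(2.0, rel=1e-6)


def test_tail_decay_rate_rejects_unknown_model():
    g = _grid(L=40.0, dx=0.02)
    prof = DensityProfile(g, np.exp(-g.x), 0.0)
    with pytest.raises(ValueError):
        tail_decay_rate(prof, model="algebraic")


def test_total_mass_quadrature():
    g = _grid(L=50.0, dx=0.01)
    C = 0.3 * np.exp(-0.5 * g.x)
    m = total_mass(DensityProfile(g, C, 0.0))
    assert m == pytest.approx(0.6, rel=5e-3)
    m_half = total_mass(DensityProfile(g, C, 0.0), region=(0.0, np.log(2) / 0.5))
    assert m_half == pytest.approx(0.3, rel=1e-2)


def test_total_mass_empty_region_warns_and_zero():
    g = _grid()
    prof = DensityProfile(g, np.ones(g.nx), 0.0,
                          active=np.zeros(g.nx, dtype=bool))
    with pytest.warns(UserWarning):
        assert total_mass(prof) == 0.0


def test_symmetric_profile_stays_symmetric():
    g = _grid(L=60.0)
    init = DensityProfile.seed(g, ALLEE0)  # centred seed
    traj = integrate(init, ALLEE0, 6.0)
    C = traj.final.C
    assert np.max(np.abs(C - C[::-1])) < 1e-12


def test_three_grid_speed_convergence():
    """Measured FK front speed increases monotonically toward 2 under grid
    refinement (discrete fronts of pulled type travel slower than the
    continuum limit)."""
    speeds = []
    for dx in (0.2, 0.1, 0.05):
        g = _grid(L=150.0, dx=dx)
        init = DensityProfile.seed(g, LOGISTIC, centre=1.0, width=2.0)
        traj = integrate(init, LOGISTIC, 60.0)
        v, r2 = front_speed(traj)
        speeds.append(v)
        assert r2 > 0.999
    assert speeds[0] < speeds[1] < speeds[2] < 2.0
    assert speeds[2] == pytest.approx(2.0, rel=0.05)


def test_seed_validation():
    g = _grid()
    with pytest.raises(ValueError):
        DensityProfile.seed(g, LOGISTIC, shape="triangle")
    prof = DensityProfile.seed(g, LOGISTIC, shape="gaussian")
    assert prof.C.max() == pytest.approx(LOGISTIC.K, rel=5e-3)


def test_trajectory_bookkeeping():
    g = _grid(L=30.0)
    init = DensityProfile.seed(g, LOGISTIC, centre=1.0, width=2.0)
    traj = integrate(init, LOGISTIC, 5.0)
    assert traj.times[0] == 0.0
    assert traj.times[-1] == pytest.approx(5.0, abs=1e-6)
    assert traj.profiles.shape == (len(traj.times), g.nx)
    assert np.all(np.diff(traj.mass) > 0)  # growing tumour
    p2 = traj.profile_at(2)
    assert p2.t == pytest.approx(traj.times[2])
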