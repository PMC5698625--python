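"""Generalized mean-field solver, gamma hot-spot model, weak-erosion limit."""

import warnings

import numpy as np
import pytest
from scipy.integrate import quad

from redqueen.meanfield_general import (WeakSelectionWarning,
                                        calibration_table, gamma_activity,
                                        mouse_calibration_rows, solve_general,
                                        weak_erosion_approx)
from redqueen.meanfield_linear import solve_selfconsistent_R
from redqueen.model import FitnessSpec, GammaHotspots, ModelParams


def params(eps=1e-3, alpha=0.01, Ne=100_000, mu=None, a=None):
    u = 1e-6 if mu is None else mu / (4 * Ne)
    return ModelParams(Ne=Ne, u=u, v=1e-7, g=eps * u / 1e-7,
                       fitness=FitnessSpec("power", alpha), a=a)


def quiet_solve(p, **kw):
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", WeakSelectionWarning)
        return solve_general(p, **kw)


# -- gamma hot-spot activity --------------------------------------------------

def test_gamma_activity_at_zero_dose():
    assert gamma_activity(0.0, 2.0) == (1.0, 1.0)


def test_gamma_activity_unit_shape_closed_form():
    th, r = gamma_activity(1.0, 1.0)
    assert th == pytest.approx(0.5, rel=1e-14)
    assert r == pytest.approx(0.25, rel=1e-14)


def test_gamma_activity_rejects_negative_dose():
    with pytest.raises(ValueError):
        gamma_activity(-0.1, 1.0)


def test_gamma_activity_matches_mixture_quadrature():
    """theta and r against direct integration over the gamma strength density."""
    from scipy.stats import gamma as gamma_dist
    rng = np.random.default_rng(0)
    for _ in range(15):
        a = 10 ** rng.uniform(-0.5, 1.0)
        y = 10 ** rng.uniform(-2, 1)
        dist = gamma_dist(a, scale=1.0 / a)   # mean 1, shape a
        th_num, _ = quad(lambda c: dist.pdf(c) * np.exp(-c * y), 0, np.inf,
                         epsabs=1e-13, epsrel=1e-12)
        r_num, _ = quad(lambda c: c * dist.pdf(c) * np.exp(-c * y), 0, np.inf,
                        epsabs=1e-13, epsrel=1e-12)
        th, r = gamma_activity(y, a)
        assert th == pytest.approx(th_num, abs=1e-10)
        assert r == pytest.approx(r_num, abs=1e-10)


def test_strong_hotspots_die_first():
    # r < theta for any finite shape and positive dose
    for a in (0.5, 1.0, 5.0):
        th, r = gamma_activity(0.7, a)
        assert r < th < 1.0


# -- generalized solver -------------------------------------------------------

def test_agrees_with_linear_solver_in_near_linear_regime():
    p = params(eps=1e-3, alpha=0.01)
    lin = solve_selfconsistent_R(p)
    gen = quiet_solve(p)
    assert gen.R == pytest.approx(lin.R, rel=0.01)
    # s0 keeps a small genuine linearization offset even when R agrees closely
    assert gen.s0 == pytest.approx(lin.s0, rel=0.05)


def test_large_shape_limit_recovers_uniform_model():
    p = params(eps=1e-2, alpha=0.05)
    uni = quiet_solve(p)
    gam = quiet_solve(p, model=GammaHotspots(1e6))
    assert gam.R == pytest.approx(uni.R, rel=1e-3)
    assert gam.H == pytest.approx(uni.H, rel=1e-3)
    assert gam.D == pytest.approx(uni.D, rel=1e-3)


@pytest.mark.parametrize("a", [0.5, 1.0, 5.0])
def test_active_fraction_exceeds_mean_rate_under_gamma(a):
    sol = quiet_solve(params(eps=1e-2, alpha=0.01, a=a))
    assert sol.H > sol.R


def test_active_fraction_rises_as_variance_grows():
    hs = [quiet_solve(params(eps=1e-2, alpha=0.01, a=a)).H
          for a in (5.0, 1.0, 0.5)]
    assert hs[0] < hs[1] < hs[2]


def test_uniform_model_has_identical_H_and_R():
    sol = quiet_solve(params(eps=1e-2, alpha=0.05))
    assert sol.H == pytest.approx(sol.R, rel=1e-12)


def test_fixed_point_internal_consistency():
    p = params(eps=1e-2, alpha=0.05, a=1.0)
    sol = quiet_solve(p)
    assert sol.tau * p.mu * sol.s0 == pytest.approx(1.0, rel=1e-12)
    assert sol.L == pytest.approx(p.eps / sol.s0, rel=1e-12)
    assert sol.diagnostics["residual"] < 1e-10
    # typical-allele frequency returns to zero exactly at dose L
    assert abs(sol.diagnostics["w_end"]) < 1e-8 * sol.L


def test_population_size_scaling_is_exact():
    lo = quiet_solve(params(eps=1e-3, alpha=0.01, Ne=100_000, a=1.0))
    hi = quiet_solve(params(eps=1e-3, alpha=0.01, Ne=1_000_000, mu=4.0, a=1.0))
    assert hi.R == pytest.approx(lo.R, rel=1e-12)
    assert hi.s0 == pytest.approx(lo.s0, rel=1e-12)
    assert hi.tau / lo.tau == pytest.approx(0.1, rel=1e-12)
    assert hi.D / lo.D == pytest.approx(10.0, rel=1e-12)
    assert hi.T == pytest.approx(lo.T, rel=1e-12)


def test_weak_selection_advisory_emitted():
    rows = mouse_calibration_rows()
    with pytest.warns(WeakSelectionWarning):
        solve_general(rows[3])   # alpha = 1e-5: S0 ~ 2.6 < 10


# -- weak-erosion first-order approximation -----------------------------------

def test_weak_erosion_gap_formula():
    p = params(eps=1e-8, alpha=0.01)
    full = solve_selfconsistent_R(p)
    wk = weak_erosion_approx(p)
    assert 1 - wk.R == pytest.approx(np.sqrt(p.eps / 0.01), rel=1e-12)
    assert 1 - full.R == pytest.approx(1 - wk.R, rel=0.01)
    assert full.s0 == pytest.approx(wk.s0, rel=0.01)


def test_weak_erosion_diversity_prefactor_against_both_solvers():
    """Polymorphic D -> 6*mu as eps -> 0 (first-order trajectory integrals)."""
    p = params(eps=1e-8, alpha=0.01, mu=4.0)
    wk = weak_erosion_approx(p)
    assert wk.D == pytest.approx(6 * p.mu, rel=1e-12)
    assert solve_selfconsistent_R(p).D == pytest.approx(wk.D, rel=0.01)
    assert quiet_solve(p).D == pytest.approx(wk.D, rel=0.01)


def test_weak_erosion_depends_only_on_compound_parameters():
    a = weak_erosion_approx(params(eps=1e-6, alpha=0.01, Ne=10_000))
    b = weak_erosion_approx(params(eps=1e-6, alpha=0.01, Ne=1_000_000))
    assert a.R == b.R and a.s0 == b.s0
    # polymorphic D proportional to Ne*u at fixed eps
    pa = params(eps=1e-6, alpha=0.01, Ne=10_000, mu=2.0)
    pb = params(eps=1e-6, alpha=0.01, Ne=1_000_000, mu=200.0)
    assert (weak_erosion_approx(pb).D / weak_erosion_approx(pa).D
            == pytest.approx(100.0, rel=1e-12))


def test_weak_erosion_advisory_when_gap_is_large():
    p = params(eps=6.25e-4, alpha=0.01)   # predicted gap = 0.25 > 0.2
    wk = weak_erosion_approx(p)
    assert wk.diagnostics["accuracy_advisory"] is True
    ok = weak_erosion_approx(params(eps=1e-6, alpha=0.01))
    assert ok.diagnostics["accuracy_advisory"] is False


def test_weak_erosion_requires_power_law():
    p = ModelParams(Ne=1000, u=1e-5, v=1e-7, g=1e-2,
                    fitness=FitnessSpec("exponential", 1.0))
    with pytest.raises(ValueError):
        weak_erosion_approx(p)


# -- calibration --------------------------------------------------------------

def test_mouse_calibration_scenarios():
    table = calibration_table()
    assert len(table) == 4
    assert (table["error"] == "").all()
    # weaker conversion erodes less
    assert table.loc[1, "H"] > table.loc[0, "H"]
    # selection ordering across scenarios
    assert table.loc[0, "S0"] > table.loc[1, "S0"] > table.loc[3, "S0"]
    # lowering u and g together pushes into the succession regime
    assert table.loc[2, "regime"] == "succession"
    assert table.loc[2, "D"] == 1.0


def test_calibration_table_survives_row_failure():
    rows = mouse_calibration_rows()
    bad = ModelParams(Ne=10, u=0.9, v=1e-7, g=1e-12,
                      fitness=FitnessSpec("power", 1e-12))
    table = calibration_table([rows[0], bad])
    assert table.loc[0, "error"] == ""
    assert np.isfinite(table.loc[0, "D"])
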