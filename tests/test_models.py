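"""The six built-in example systems."""

import numpy as np
import pytest
from scipy import stats
from scipy.integrate import odeint

from specex import BivariatePoissonDist
from specex.models import (DECAY_SPEC, DIMER_SPECS, PlasmidFixture,
                           decay_model, decay_pdf_analytic, dimer_model,
                           glycolysis_fixed_point, glycolysis_model,
                           partition_matrix, plasmid_model, schnakenberg_model,
                           trichome_density, trichome_steady_state,
                           trichome_turing_test, turing_space_test,
                           y_steady_state)
from specex.models.schnakenberg import laplacian_1d
from specex.models.trichome import TRICHOME_DEFAULTS, hex_laplacian, _jacobian


# -- exponential decay -------------------------------------------------------

def test_decay_initial_value():
    assert decay_model(1.0, 0.5, 0.0) == 1.0


def test_decay_pdf_integrates_to_one():
    a = np.linspace(1e-6, 1.0, 20001)
    dens = decay_pdf_analytic(1.0, DECAY_SPEC, a)
    assert np.trapezoid(dens, a) == pytest.approx(1.0, abs=1e-6)


def test_decay_pdf_matches_mc_density_estimate(rng):
    """Binned density of 1e6 MC draws of A(1) vs the bin-averaged analytic
    change-of-variables PDF."""
    t = 1.0
    k = DECAY_SPEC.to_physical(rng.standard_normal(10**6))
    a = np.exp(-k * t)
    edges = np.linspace(0.0, 1.0, 11)
    emp = np.histogram(a, bins=edges)[0] / (len(a) * np.diff(edges))
    fine = np.linspace(1e-6, 1.0, 20001)
    dens = decay_pdf_analytic(t, DECAY_SPEC, fine)
    cdf = np.concatenate([[0.0], np.cumsum(0.5 * (dens[1:] + dens[:-1]) * np.diff(fine))])
    exact = np.diff(np.interp(edges, fine, cdf)) / np.diff(edges)
    assert np.abs(emp - exact).max() < 0.02


def test_decay_pdf_degenerate_at_time_zero():
    with pytest.raises(ValueError):
        decay_pdf_analytic(0.0, DECAY_SPEC, np.linspace(0, 1, 10))


# -- dimer network -----------------------------------------------------------

def test_dimer_decoupled_steady_state():
    # k2 = k3 = 0 decouples x1: linear birth-death with x1(inf) = k1/k5
    k = np.array([0.2, 1e-12, 1e-12, 0.3, 0.5])
    x = dimer_model(k, np.linspace(0, 200, 11))
    assert x[0, -1] == pytest.approx(0.2 / 0.5, rel=1e-6)


def test_dimer_mass_balance_identity():
    """d(x1+x3)/dt = k1 - k5 (x1+x3) along the numeric solution."""
    k = np.array([0.1, 0.4, 0.4, 0.1, 0.1])
    tg = np.linspace(0, 10, 201)
    x1, x2, x3 = dimer_model(k, tg)
    total = x1 + x3
    deriv = np.gradient(total, tg)
    residual = deriv - (k[0] - k[4] * total)
    assert np.abs(residual[2:-2]).max() < 1e-3


def test_dimer_rejects_bad_rates():
    with pytest.raises(ValueError):
        dimer_model(np.array([0.1, 0.4, 0.4, 0.1]))
    with pytest.raises(ValueError):
        dimer_model(np.array([0.1, -0.4, 0.4, 0.1, 0.1]))


# -- glycolytic oscillator ---------------------------------------------------

def test_glycolysis_fixed_point_zeroes_rhs():
    alpha, beta = 0.3, 0.46
    x, y = glycolysis_fixed_point(alpha, beta)
    assert -x + alpha * y + x**2 * y == pytest.approx(0.0, abs=1e-14)
    assert beta - alpha * y - x**2 * y == pytest.approx(0.0, abs=1e-14)


def test_glycolysis_limit_cycle_vs_stable_fixed_point():
    tg = np.linspace(0, 100, 2001)
    _, y_osc = glycolysis_model(0.1, 0.46, tg)
    late = y_osc[tg > 60]
    assert late.max() - late.min() > 0.1        # sustained oscillation
    _, y_fp = glycolysis_model(0.5, 0.46, tg)
    late = y_fp[tg > 50]
    assert late.max() - late.min() < 0.01       # decay to the fixed point


# -- Schnakenberg reaction-diffusion ----------------------------------------

def test_laplacian_rows_sum_to_zero():
    assert np.abs(laplacian_1d(20).sum(axis=1)).max() == 0.0
    assert np.abs(hex_laplacian(6).sum(axis=1)).max() == 0.0


def test_turing_space_membership():
    assert turing_space_test(0.22) is True
    assert turing_space_test(0.24) is False


def test_equal_diffusion_never_turing_unstable():
    # d = 1: differential transport vanishes, no diffusion-driven instability
    assert not any(turing_space_test(a, d=1.0) for a in np.linspace(0.01, 0.45, 45))


def test_schnakenberg_pattern_contrast():
    v_in = schnakenberg_model(0.22, seed=3)
    v_out = schnakenberg_model(0.24, seed=3)
    cv_in = v_in.std() / v_in.mean()
    cv_out = v_out.std() / v_out.mean()
    assert cv_in > 0.05
    assert cv_out < 1e-3


def test_schnakenberg_deterministic_given_seed():
    a = schnakenberg_model(0.2, seed=7)
    b = schnakenberg_model(0.2, seed=7)
    assert np.array_equal(a, b)


# -- trichome patterning -----------------------------------------------------

def test_trichome_steady_state_zeroes_reaction_rhs():
    p = TRICHOME_DEFAULTS
    T, G, A = trichome_steady_state(0.7, p["lam"], p["beta"])
    assert 0.7 - p["lam"] * T - T * G == pytest.approx(0.0, abs=1e-12)
    assert p["beta"] * A**2 - G - T * G == pytest.approx(0.0, abs=1e-12)
    assert T * G - A == pytest.approx(0.0, abs=1e-12)


def test_trichome_turing_boundary_inside_fixture_range():
    inside = [trichome_turing_test(a) for a in np.linspace(0.4, 0.9, 26)]
    assert not inside[0]          # no pattern at the low end
    assert inside[-1]             # pattern at the high end
    assert any(inside) and not all(inside)


def test_trichome_density_counting():
    field = np.zeros(400)
    field[:37] = 1.0
    rho = trichome_density(field)
    assert rho == 37 / 400
    assert (rho * 400) == int(rho * 400)
    assert 0 < rho <= 1


def test_trichome_hex_laplacian_has_six_neighbours():
    L = hex_laplacian(5)
    assert np.all(np.diag(L) == -6.0)
    off = L - np.diag(np.diag(L))
    assert np.all(off.sum(axis=1) == 6.0)


# -- plasmid transfection ----------------------------------------------------

def test_partition_probabilities_binomial():
    P = partition_matrix(6)
    assert P[:4, 3] == pytest.approx(stats.binom.pmf(np.arange(4), 3, 0.5))
    assert P.sum(axis=0) == pytest.approx(np.ones(7))
    assert np.all(P[4:, 3] == 0.0)   # daughters cannot exceed the mother


def test_y_steady_state_formula():
    fix = PlasmidFixture()
    xs = 4 * fix.alpha / fix.beta
    expected = 2 * fix.gamma * xs / ((1 + fix.eta * xs) * (fix.mu + fix.kappa))
    assert y_steady_state(fix, 4, 2) == pytest.approx(expected)


@pytest.fixture(scope="module")
def plasmid_solution():
    fix = PlasmidFixture()
    uptake = BivariatePoissonDist(3.0, 2.4)
    return fix, plasmid_model(fix, uptake, np.linspace(0.0, 50.0, 51))


def test_plasmid_population_follows_logistic_growth(plasmid_solution):
    fix, sol = plasmid_solution
    norm = sol.Q.sum(axis=(1, 2))
    ref = odeint(lambda n, t: fix.omega * (1 - n / fix.Nmax) * n, fix.N0, sol.t)[:, 0]
    assert np.abs(norm - ref).max() / ref.max() < 1e-6
    assert norm.max() <= fix.Nmax * (1 + 1e-9)


def test_plasmid_pool_tensor_stays_nonnegative(plasmid_solution):
    _, sol = plasmid_solution
    assert sol.Q.min() > -1e-6


def test_plasmid_y_reaches_steady_state(plasmid_solution):
    fix, sol = plasmid_solution
    assert sol.y(4, 2)[-1] == pytest.approx(y_steady_state(fix, 4, 2), rel=1e-5)


def test_plasmid_readout_histogram_is_distribution(plasmid_solution):
    _, sol = plasmid_solution
    levels, probs = sol.readout_histogram(-1)
    assert probs.sum() == pytest.approx(1.0, abs=1e-10)
    assert np.all(probs >= 0)
    assert np.all(levels % sol.fixture.g == 0)


def test_plasmid_deterministic():
    fix = PlasmidFixture()
    uptake = BivariatePoissonDist(1.0, 0.9)
    tg = np.linspace(0, 10, 11)
    a = plasmid_model(fix, uptake, tg)
    b = plasmid_model(fix, uptake, tg)
    assert np.array_equal(a.Q, b.Q) and np.array_equal(a.S, b.S)
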