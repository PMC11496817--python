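"""Circular statistics: closed-form checks, brute-force oracles, and
calibration under null models."""

import numpy as np
import pytest
from scipy.special import i0, i1

from thetashift import circstats as cs


# ---------------------------------------------------------------------------
# resultant length and circular median
# ---------------------------------------------------------------------------

@pytest.mark.parametrize("phases, expected", [
    (np.full(10, 0.7), 1.0),
    (np.array([0.0, np.pi / 2, np.pi, 3 * np.pi / 2]), 0.0),
])
def test_resultant_length_closed_forms(phases, expected):
    assert cs.resultant_length(phases) == pytest.approx(expected, abs=1e-12)


def test_resultant_length_von_mises_expectation():
    """For a von Mises sample, E[R] -> I1(k)/I0(k)."""
    rng = np.random.default_rng(11)
    sample = rng.vonmises(0.3, 1.0, 10_000)
    assert cs.resultant_length(sample) == pytest.approx(
        i1(1.0) / i0(1.0), abs=0.02)


def test_circ_median_matches_brute_force():
    rng = np.random.default_rng(3)
    for n in (5, 17, 101):
        x = rng.uniform(-np.pi, np.pi, n)
        med = cs.circ_median(x)
        # brute force: total geodesic distance at every sample point
        d = np.abs(x[:, None] - x[None, :])
        d = np.minimum(d, 2 * np.pi - d)
        best = x[np.argmin(d.sum(axis=1))]
        assert med == pytest.approx(best)


# ---------------------------------------------------------------------------
# Hodges-Ajne
# ---------------------------------------------------------------------------

def test_hodges_ajne_fully_concentrated():
    res = cs.hodges_ajne(np.full(60, 1.2))
    assert res.statistic == 0
    assert res.p_value < 1e-6


def test_hodges_ajne_uniform_grid_is_balanced():
    grid = np.linspace(-np.pi, np.pi, 60, endpoint=False)
    res = cs.hodges_ajne(grid)
    assert res.statistic == 30
    assert res.p_value == pytest.approx(1.0)


def _ajne_brute(phases):
    """Min count over closed half circles, dense direction scan plus
    data-anchored boundaries."""
    phases = np.asarray(phases)
    dirs = np.concatenate([np.linspace(0, 2 * np.pi, 4096, endpoint=False),
                           phases, phases + np.pi,
                           phases + 1e-9, phases - 1e-9])
    counts = [(np.cos(phases - d) >= -1e-12).sum() for d in dirs]
    return int(min(counts))


def test_hodges_ajne_statistic_matches_brute_force():
    rng = np.random.default_rng(7)
    for _ in range(5):
        x = rng.vonmises(rng.uniform(-np.pi, np.pi), rng.uniform(0, 2), 100)
        assert cs.hodges_ajne(x).statistic == _ajne_brute(x)


def test_hodges_ajne_small_sets_not_testable():
    res = cs.hodges_ajne(np.linspace(0, 1, 40))
    assert not res.testable
    assert np.isnan(res.p_value)


def test_rotation_and_order_invariance():
    rng = np.random.default_rng(5)
    x = rng.vonmises(0.0, 1.5, 120)
    base = cs.hodges_ajne(x)
    for rot in (0.7, -2.1, np.pi):
        r = cs.hodges_ajne(np.mod(x + rot + np.pi, 2 * np.pi) - np.pi)
        assert r.statistic == base.statistic
        assert r.p_value == pytest.approx(base.p_value, rel=1e-9)
    shuffled = cs.hodges_ajne(rng.permutation(x))
    assert shuffled.p_value == pytest.approx(base.p_value)
    assert cs.resultant_length(x + 1.0) == pytest.approx(
        cs.resultant_length(x), abs=1e-12)


# ---------------------------------------------------------------------------
# enhanced-locking bootstrap
# ---------------------------------------------------------------------------

def test_enhanced_locking_degenerate_subset_is_population():
    rng = np.random.default_rng(1)
    pop = rng.vonmises(0.0, 1.0, 200)
    res = cs.enhanced_locking_bootstrap(pop, pop, n_rep=200, seed=0)
    assert res.p_value == 0.0


def test_enhanced_locking_detects_concentrated_mode():
    """The tighter mode of a bimodal population out-locks the whole."""
    rng = np.random.default_rng(2)
    tight = rng.vonmises(0.0, 8.0, 150)
    broad = rng.vonmises(np.pi, 0.5, 150)
    pop = np.concatenate([tight, broad])
    hits = 0
    for s in range(20):
        res = cs.enhanced_locking_bootstrap(tight, pop, n_rep=500, seed=s)
        hits += res.p_value < 0.05
    assert hits >= 19


def test_enhanced_locking_null_calibration():
    """Random same-size subsets reject at about the nominal rate."""
    rng = np.random.default_rng(3)
    pop = rng.vonmises(0.0, 1.0, 400)
    pvals = []
    for s in range(200):
        idx = np.random.default_rng(1000 + s).choice(400, 80, replace=False)
        pvals.append(cs.enhanced_locking_bootstrap(pop[idx], pop, n_rep=200,
                                                   seed=s).p_value)
    assert 0.0 <= np.mean(np.array(pvals) < 0.05) <= 0.12
    assert 0.35 < np.mean(pvals) < 0.65


def test_enhanced_locking_subset_larger_than_population_errors():
    with pytest.raises(ValueError):
        cs.enhanced_locking_bootstrap(np.zeros(10), np.zeros(5))


# ---------------------------------------------------------------------------
# circular Kruskal-Wallis (common-median test)
# ---------------------------------------------------------------------------

def test_circ_kw_null_calibration():
    rng = np.random.default_rng(4)
    rej = 0
    n_sim = 400
    for _ in range(n_sim):
        g1 = rng.vonmises(0.5, 2.0, 100)
        g2 = rng.vonmises(0.5, 2.0, 100)
        rej += cs.circ_kruskal_wallis([g1, g2]).p_value < 0.05
    assert 0.015 <= rej / n_sim <= 0.09


def test_circ_kw_power_for_shifted_medians():
    """A quarter-cycle median shift at kappa=2 is detected essentially
    always.  (The common-median statistic is by construction blind to an
    exactly antipodal shift, where both groups straddle any diameter
    symmetrically, so power is probed at pi/2.)"""
    rng = np.random.default_rng(5)
    hits = 0
    n_sim = 200
    for _ in range(n_sim):
        g1 = rng.vonmises(0.0, 2.0, 100)
        g2 = rng.vonmises(np.pi / 2, 2.0, 100)
        hits += cs.circ_kruskal_wallis([g1, g2]).p_value < 0.05
    assert hits / n_sim > 0.99


def test_circ_kw_permutation_symmetry():
    """Randomly permuted group labels give roughly uniform p-values."""
    rng = np.random.default_rng(6)
    pooled = rng.vonmises(1.0, 1.5, 240)
    pvals = []
    for _ in range(300):
        perm = rng.permutation(pooled)
        pvals.append(cs.circ_kruskal_wallis([perm[:120], perm[120:]]).p_value)
    pvals = np.array(pvals)
    assert 0.35 < pvals.mean() < 0.65
    assert np.mean(pvals < 0.05) < 0.11


def test_circ_kw_needs_two_groups():
    with pytest.raises(ValueError):
        cs.circ_kruskal_wallis([np.zeros(60)])


# ---------------------------------------------------------------------------
# circular-linear correlation (phase precession)
# ---------------------------------------------------------------------------

def test_circ_linear_perfect_precession():
    x = np.linspace(0, 50, 120)
    for slope in (0.02, -0.02):
        ph = np.mod(2 * np.pi * slope * x + np.pi, 2 * np.pi) - np.pi
        res = cs.circ_linear_corr(ph, x)
        assert abs(res.statistic) > 0.99
        assert np.sign(res.statistic) == np.sign(slope)
        assert res.p_value < 1e-6
        assert res.extra["slope"] == pytest.approx(slope, abs=1e-3)


def test_circ_linear_slope_matches_dense_grid_oracle():
    rng = np.random.default_rng(8)
    x = rng.uniform(0, 40, 50)
    ph = np.mod(2 * np.pi * (-0.015) * x + rng.vonmises(0, 4.0, 50) + np.pi,
                2 * np.pi) - np.pi
    res = cs.circ_linear_corr(ph, x)
    grid = np.linspace(-0.1, 0.1, 20001)
    R = np.abs(np.exp(1j * (ph[None, :] - 2 * np.pi * grid[:, None]
                            * x[None, :])).mean(axis=1))
    assert res.extra["slope"] == pytest.approx(grid[np.argmax(R)], abs=5e-4)


def test_circ_linear_null_calibration():
    rng = np.random.default_rng(9)
    rej = 0
    n_sim = 400
    for _ in range(n_sim):
        x = rng.uniform(0, 50, 60)
        ph = rng.uniform(-np.pi, np.pi, 60)
        rej += cs.circ_linear_corr(ph, x).p_value < 0.05
    assert 0.01 <= rej / n_sim <= 0.12


def test_circ_linear_constant_positions_error():
    with pytest.raises(ValueError):
        cs.circ_linear_corr(np.linspace(-1, 1, 20), np.full(20, 3.0))


# ---------------------------------------------------------------------------
# Benjamini-Hochberg
# ---------------------------------------------------------------------------

def test_benjamini_hochberg_step_up_by_hand():
    mask = cs.benjamini_hochberg([0.01, 0.02, 0.04, 0.9], alpha=0.05)
    assert mask.tolist() == [True, True, False, False]
    assert cs.benjamini_hochberg([0.001] * 10, 0.05).all()
    assert cs.benjamini_hochberg([], 0.05).size == 0


def test_benjamini_hochberg_ignores_nan():
    mask = cs.benjamini_hochberg([0.001, np.nan, 0.9], alpha=0.05)
    assert mask.tolist() == [True, False, False]


# ---------------------------------------------------------------------------
# Hartigan dip
# ---------------------------------------------------------------------------

def _dip_brute_force_4(x):
    """Exhaustive grid search over monotone piecewise-linear cdf candidates
    for a 4-point sample."""
    x = np.sort(np.asarray(x, dtype=float))
    grid = np.linspace(0.0, 1.0, 51)
    G = np.array(np.meshgrid(grid, grid, grid, grid,
                             indexing="ij")).reshape(4, -1).T
    mono = np.all(np.diff(G, axis=1) >= 0, axis=1)
    G = G[mono]
    n = 4
    chi = np.arange(1, n + 1) / n
    clo = np.concatenate(([0.0], chi[:-1]))
    dev = np.maximum(np.max(G - clo[None, :], axis=1),
                     np.max(chi[None, :] - G, axis=1))
    dx = np.diff(x)
    best = np.inf
    second = (G[:, 2:] - G[:, 1:-1]) * dx[:-1][None, :] \
        - (G[:, 1:-1] - G[:, :-2]) * dx[1:][None, :]
    for k in range(-1, n):
        ok = np.ones(G.shape[0], dtype=bool)
        for i in (1, 2):
            if i + 1 <= k:
                ok &= second[:, i - 1] >= -1e-12   # convex
            elif i - 1 >= k + 1:
                ok &= second[:, i - 1] <= 1e-12    # concave
        if ok.any():
            best = min(best, dev[ok].min())
    return float(best)


def test_dip_matches_brute_force_on_tiny_samples():
    rng = np.random.default_rng(10)
    for _ in range(4):
        x = rng.uniform(0, 1, 4)
        assert cs.dip_statistic(x) == pytest.approx(
            _dip_brute_force_4(x), abs=0.011)


def test_dip_lower_bound_and_invariance():
    rng = np.random.default_rng(11)
    x = rng.standard_normal(40)
    d = cs.dip_statistic(x)
    assert d >= 1.0 / (2 * 40) - 1e-9
    assert cs.dip_statistic(3.0 * x + 7.0) == pytest.approx(d, abs=1e-6)


def test_dip_separated_modes_reject_unimodality():
    rng = np.random.default_rng(12)
    x = np.concatenate([rng.normal(0, 0.5, 30), rng.normal(8, 0.5, 30)])
    res = cs.dip_bimodality(x, n_boot=120, seed=0)
    assert res.p_value < 0.01


def test_dip_single_gaussian_is_unimodal():
    rng = np.random.default_rng(13)
    x = rng.standard_normal(60)
    res = cs.dip_bimodality(x, n_boot=120, seed=0)
    assert res.p_value > 0.05
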