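"""Phase-shift coding analyses: locking, shift tests, contrasts, decoding,
rate-phase co-occurrence, theta-lag changes, and session summaries."""

import numpy as np
import pandas as pd
import pytest
from scipy import stats

from thetashift import coding
from thetashift.io_core import TrialTable
from thetashift.lfp import EpochSet


def _vm(mu, kappa, n, seed):
    return np.mod(np.random.default_rng(seed).vonmises(mu, kappa, n) + np.pi,
                  2 * np.pi) - np.pi


# ---------------------------------------------------------------------------
# instantaneous rate
# ---------------------------------------------------------------------------

def test_instantaneous_rate_periodic_train():
    st = np.arange(0.0, 50.0, 0.5)  # 2 Hz
    r = coding.instantaneous_rate(st)
    interior = r[5:-5]
    assert np.allclose(interior, 2.0, rtol=0.05)


def test_instantaneous_rate_two_spike_closed_form():
    st = np.array([0.0, 1.0])
    sigma = 0.5  # mean ISI / 2
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    expected = norm * (1.0 + np.exp(-0.5 * (1.0 / sigma) ** 2))
    r = coding.instantaneous_rate(st)
    assert np.allclose(r, expected, rtol=1e-9)


def test_instantaneous_rate_time_rescaling():
    rng = np.random.default_rng(0)
    st = np.sort(rng.uniform(0, 20, 100))
    r1 = coding.instantaneous_rate(st)
    r2 = coding.instantaneous_rate(st * 2.0)
    assert np.allclose(r2, r1 / 2.0, rtol=1e-9)


def test_instantaneous_rate_needs_two_spikes():
    with pytest.raises(ValueError):
        coding.instantaneous_rate(np.array([1.0]))


# ---------------------------------------------------------------------------
# phase locking by context
# ---------------------------------------------------------------------------

def test_locking_flags_planted_locked_assembly():
    locked = _vm(0.5, 4.0, 120, 1)
    uniform = np.random.default_rng(2).uniform(-np.pi, np.pi, 800)
    df = coding.phase_locking_by_context(
        {(0, "A"): locked}, {0: np.concatenate([locked, uniform])}, seed=0)
    row = df.iloc[0]
    assert row["testable"] and row["locked"] and row["enhanced"]
    fr = coding.locking_unit_fractions(df)
    assert fr["frac_locked"] == 1.0 and fr["frac_enhanced"] == 1.0


def test_small_context_sets_are_not_testable():
    ph = _vm(0.0, 4.0, 40, 3)
    df = coding.phase_locking_by_context({(0, "A"): ph}, {0: ph}, seed=0)
    assert not df.iloc[0]["testable"]
    assert coding.locking_unit_fractions(df)["n_units"] == 0


def test_enhanced_flag_calibrated_for_random_subsets():
    rng = np.random.default_rng(4)
    pop = _vm(0.0, 1.5, 600, 5)
    hits = 0
    n_rep = 60
    for s in range(n_rep):
        sub = pop[rng.choice(600, 120, replace=False)]
        df = coding.phase_locking_by_context({(0, "A"): sub}, {0: pop},
                                             n_rep=400, seed=s)
        hits += bool(df.iloc[0]["p_enh"] < 0.05)
    assert hits / n_rep <= 0.15


# ---------------------------------------------------------------------------
# phase shift tests
# ---------------------------------------------------------------------------

def test_phase_shift_detected_between_fields():
    hits = 0
    for s in range(20):
        sets = {0: {"f0": _vm(0.0, 2.0, 200, 10 + s),
                    "f1": _vm(np.pi / 2, 2.0, 200, 300 + s)}}
        df = coding.phase_shift_test(sets, mode="by-field")
        hits += bool(df.iloc[0]["shift"])
    assert hits >= 19


def test_phase_shift_null_calibrated():
    rej = 0
    n_sim = 150
    for s in range(n_sim):
        sets = {0: {"f0": _vm(1.0, 2.0, 150, 1000 + s),
                    "f1": _vm(1.0, 2.0, 150, 5000 + s)}}
        df = coding.phase_shift_test(sets, mode="by-field", alpha=0.05)
        rej += bool(df.iloc[0]["p"] < 0.05)
    assert 0.005 <= rej / n_sim <= 0.10


def test_units_with_one_eligible_set_are_excluded():
    sets = {0: {"f0": _vm(0, 2, 200, 1), "f1": _vm(0, 2, 30, 2)},
            1: {"f0": _vm(0, 2, 200, 3), "f1": _vm(2, 2, 200, 4)}}
    df = coding.phase_shift_test(sets, mode="by-field")
    assert not df[df["unit"] == 0]["tested"].iloc[0]
    frac, n = coding.shift_fraction(df)
    assert n == 1  # only unit 1 enters the denominator


def test_trialtype_contrast_localizes_planted_contrast():
    """A shift planted only between left and right choice trials shows up in
    the choice-LR family and not in the guided families."""
    cats = ["choice-left", "choice-right", "guided-LL", "guided-LR",
            "guided-RL", "guided-RR"]
    sets = {}
    for u in range(4):
        d = {}
        for i, c in enumerate(cats):
            mu = 0.0
            if c == "choice-right":
                mu = np.pi / 2
            d[("f0", c)] = _vm(mu, 3.0, 120, 17 * u + i)
        sets[u] = d
    df = coding.trialtype_contrasts(sets)
    fr = coding.contrast_fractions(df)
    assert fr["choice-LR"][0] == 1.0
    assert fr["guided-origin"][0] <= 0.25
    assert fr["guided-turn"][0] <= 0.25


def test_trialtype_contrast_identical_sets_not_significant():
    base = _vm(0.3, 2.0, 150, 9)
    sets = {0: {("f0", c): base for c in
                ["choice-left", "choice-right", "guided-LL", "guided-LR",
                 "guided-RL", "guided-RR"]}}
    df = coding.trialtype_contrasts(sets)
    assert not df["shift"].any()


# ---------------------------------------------------------------------------
# decoding
# ---------------------------------------------------------------------------

def test_svm_decodes_separable_phases():
    rng = np.random.default_rng(6)
    ph0 = _vm(0.0, 4.0, 120, 20)
    ph1 = _vm(np.pi, 4.0, 120, 21)
    X = np.column_stack([np.cos(np.concatenate([ph0, ph1])),
                         np.sin(np.concatenate([ph0, ph1]))])
    y = np.array([0] * 120 + [1] * 120)
    acc, p = coding.svm_decode(X, y, folds=10, n_shuffle=60, seed=0)
    assert acc > 0.95
    assert p <= 1.0 / 60


def test_svm_no_signal_accuracy_near_chance():
    rng = np.random.default_rng(7)
    X = np.ones((100, 2))
    y = np.array([0] * 60 + [1] * 40)
    acc, p = coding.svm_decode(X, y, folds=5, n_shuffle=30, seed=0)
    assert acc == pytest.approx(0.6, abs=0.05)
    assert p > 0.1


def test_svm_single_class_errors():
    with pytest.raises(ValueError):
        coding.svm_decode(np.ones((10, 2)), np.zeros(10))


# ---------------------------------------------------------------------------
# rate-phase co-occurrence
# ---------------------------------------------------------------------------

def test_chi2_closed_form_diagonal_table():
    tab = pd.DataFrame({
        "family": ["fields"] * 20,
        "phase_p": [0.01] * 10 + [0.5] * 10,
        "rate_p": [0.01] * 10 + [0.5] * 10,
    })
    res = coding.rate_phase_cooccurrence(tab).iloc[0]
    assert res["chi2"] == pytest.approx(20.0)
    assert res["p"] < 1e-4


def test_chi2_independent_labels_calibrated():
    rng = np.random.default_rng(8)
    rej = 0
    n_sim = 200
    for _ in range(n_sim):
        tab = pd.DataFrame({"family": "f",
                            "phase_p": rng.uniform(0, 1, 80),
                            "rate_p": rng.uniform(0, 1, 80)})
        res = coding.rate_phase_cooccurrence(tab).iloc[0]
        rej += bool(res["tested"] and res["p"] < 0.05)
    assert rej / n_sim <= 0.09


def test_chi2_zero_margin_skipped():
    tab = pd.DataFrame({"family": "f", "phase_p": [0.5] * 10,
                        "rate_p": [0.01] * 10})
    assert not coding.rate_phase_cooccurrence(tab).iloc[0]["tested"]


def test_rate_difference_ranksum():
    rng = np.random.default_rng(9)
    a = rng.normal(5, 1, 200)
    b = rng.normal(7, 1, 200)
    assert coding.rate_difference_test(a, b) < 1e-6
    assert coding.rate_difference_test(a, a) == pytest.approx(1.0)


# ---------------------------------------------------------------------------
# theta-cycle lag changes
# ---------------------------------------------------------------------------

def _lag_trials(n_per=8):
    rows = []
    t = 0.0
    for k in range(2 * n_per):
        cat = "choice-left" if k % 2 == 0 else "guided-LL"
        rows.append({"trial_id": k, "category": cat, "t_start": t,
                     "t_end": t + 10.0, "correct": True})
        t += 12.0
    return TrialTable(pd.DataFrame(rows))


def _train_in_trials(trials, rng, shift_by_cat):
    base, partner = [], []
    for _, row in trials.df.iterrows():
        t0 = row["t_start"]
        spikes = np.sort(rng.uniform(t0, row["t_end"] - 0.2, 40))
        base.append(spikes)
        partner.append(spikes + shift_by_cat[row["category"]])
    return np.sort(np.concatenate(base)), np.sort(np.concatenate(partner))


def test_constant_shift_gives_constant_lag():
    trials = _lag_trials()
    rng = np.random.default_rng(10)
    a, b = _train_in_trials(trials, rng, {"choice-left": 0.04,
                                          "guided-LL": 0.04})
    la, lb, p = coding.xcorr_lag_change(a, b, trials, "choice-left",
                                        "guided-LL")
    assert set(la) == {2} and set(lb) == {2}
    assert p == 1.0 or p > 0.9


def test_opposite_shifts_detected_as_lag_change():
    trials = _lag_trials()
    rng = np.random.default_rng(11)
    a, b = _train_in_trials(trials, rng, {"choice-left": 0.02,
                                          "guided-LL": -0.02})
    la, lb, p = coding.xcorr_lag_change(a, b, trials, "choice-left",
                                        "guided-LL")
    assert set(la) == {1} and set(lb) == {-1}
    assert p < 0.01


def test_independent_trains_lag_change_calibrated():
    trials = _lag_trials()
    rej = 0
    n_sim = 60
    for s in range(n_sim):
        rng = np.random.default_rng(100 + s)
        a = np.sort(rng.uniform(0, 190, 600))
        b = np.sort(rng.uniform(0, 190, 600))
        _, _, p = coding.xcorr_lag_change(a, b, trials, "choice-left",
                                          "guided-LL")
        rej += bool(np.isfinite(p) and p < 0.05)
    assert rej / n_sim <= 0.12


# ---------------------------------------------------------------------------
# summaries and exclusions
# ---------------------------------------------------------------------------

def test_weighted_session_fraction_arithmetic():
    assert coding.weighted_session_fraction(
        [(0.2, 1.0), (0.8, 3.0)])["weighted_mean"] == pytest.approx(0.65)
    assert coding.weighted_session_fraction(
        [(0.4, 2.0)])["weighted_mean"] == 0.4
    eq = coding.weighted_session_fraction([(0.1, 1), (0.5, 1), (0.9, 1)])
    assert eq["weighted_mean"] == pytest.approx(0.5)
    with pytest.raises(ValueError):
        coding.weighted_session_fraction([])


def test_exclusion_rerun_identity_and_total_mask():
    from thetashift.synth import SynthConfig, generate_session
    bundle, _ = generate_session(SynthConfig(n_units=3, trials_per_choice=3,
                                             trials_per_guided=1, seed=21))
    same = coding.apply_exclusion(bundle, [EpochSet(np.zeros((0, 2)), "swr")])
    for a, b in zip(bundle.spike_trains, same.spike_trains):
        assert np.array_equal(a.times, b.times)
    lo, hi = bundle.time_bounds()
    gone = coding.apply_exclusion(bundle,
                                  [EpochSet(np.array([[lo, hi + 1]]), "swr")])
    assert all(st.n == 0 for st in gone.spike_trains)
    n = coding.exclusion_rerun(bundle, [], lambda b: len(b.spike_trains))
    assert n == 3
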