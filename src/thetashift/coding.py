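"""Phase-shift coding analyses.

Orchestrates the statistical pipeline on spike-phase sets grouped by context
(assembly membership, place field, or trial type within a field):

* phase locking of assembly-spikes (Hodges-Ajne) and *enhanced* locking
  relative to all the unit's spikes (resultant-length bootstrap),
* phase-shift tests across contexts (circular Kruskal-Wallis analog) with
  Benjamini-Hochberg control and per-session weighted fractions,
* the four trial-type contrast families within a place field,
* SVM decoding of trial type from spike phase / instantaneous rate,
* rate-phase co-occurrence contingency tests,
* per-trial theta cross-correlogram lags and their change between trial types,
* sensitivity reruns excluding spikes in given epochs (SWR, low theta).

Every reported fraction's denominator is the number of units passing that
test's eligibility rules (per-set n > 50 spikes, phase locking where
required), never the full unit count.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.model_selection import StratifiedKFold, cross_val_score
from sklearn.svm import SVC

from . import circstats as cs
from .lfp import EpochSet

logger = logging.getLogger(__name__)

__all__ = [
    "instantaneous_rate",
    "spike_categories",
    "phase_locking_by_context",
    "phase_shift_test",
    "trialtype_contrasts",
    "svm_decode",
    "rate_phase_cooccurrence",
    "xcorr_trial_lags",
    "xcorr_lag_change",
    "weighted_session_fraction",
    "apply_exclusion",
    "exclusion_rerun",
    "CONTRAST_FAMILIES",
]

MIN_SET = cs.MIN_PHASE_SAMPLES  # 50-spike eligibility floor


def instantaneous_rate(spike_times, eval_times=None) -> np.ndarray:
    """Gaussian-kernel intensity estimate at spike times (Hz).

    Kernel SD = half the unit's mean interspike interval.  Rescaling time by
    a factor c scales all values by 1/c.
    """
    st = np.asarray(spike_times, dtype=float)
    if st.size < 2:
        raise ValueError("instantaneous rate needs at least two spikes")
    et = st if eval_times is None else np.asarray(eval_times, dtype=float)
    sigma = np.diff(st).mean() / 2.0
    lo = np.searchsorted(st, et - 5 * sigma)
    hi = np.searchsorted(st, et + 5 * sigma)
    norm = 1.0 / (sigma * np.sqrt(2 * np.pi))
    out = np.empty(et.size)
    for i, (a, b) in enumerate(zip(lo, hi)):
        d = et[i] - st[a:b]
        out[i] = norm * np.exp(-0.5 * (d / sigma) ** 2).sum()
    return out


def spike_categories(spike_times, trials) -> np.ndarray:
    """Trial category of each spike (None outside any trial)."""
    st = np.asarray(spike_times, dtype=float)
    out = np.array([None] * st.size, dtype=object)
    for _, row in trials.df.iterrows():
        sel = (st >= row["t_start"]) & (st < row["t_end"])
        out[sel] = row["category"]
    return out


# ---------------------------------------------------------------------------
# Phase locking of context spikes
# ---------------------------------------------------------------------------

def phase_locking_by_context(context_phases: dict, unit_phases: dict,
                             alpha: float = 0.05, n_rep: int = 1000,
                             min_n: int = MIN_SET, seed: int = 0) -> pd.DataFrame:
    """Phase locking and enhanced locking per (unit, context).

    ``context_phases`` maps (unit, context) -> phases of the unit's spikes in
    that context (e.g. assembly-spikes); ``unit_phases`` maps unit -> all its
    spike phases.  Hodges-Ajne tests the context set; the bootstrap compares
    its resultant length with same-size draws from all the unit's spikes.
    BH correction is applied across all testable sets, separately per test
    family.  Sets of <= ``min_n`` spikes are not testable and excluded from
    any denominator.
    """
    rows = []
    for k, ((unit, ctx), ph) in enumerate(sorted(context_phases.items(),
                                                 key=lambda kv: str(kv[0]))):
        ph = np.asarray(ph, dtype=float)
        res = cs.hodges_ajne(ph, min_n=min_n)
        row = {"unit": unit, "context": ctx, "n": ph.size,
               "testable": res.testable, "p_lock": res.p_value,
               "R": cs.resultant_length(ph) if ph.size else np.nan,
               "p_enh": np.nan}
        if res.testable:
            boot = cs.enhanced_locking_bootstrap(ph, unit_phases[unit],
                                                 n_rep=n_rep, seed=seed + k)
            row["p_enh"] = boot.p_value
        rows.append(row)
    df = pd.DataFrame(rows, columns=["unit", "context", "n", "testable",
                                     "p_lock", "R", "p_enh"])
    df["locked"] = cs.benjamini_hochberg(df["p_lock"].to_numpy(), alpha)
    df["enhanced"] = cs.benjamini_hochberg(df["p_enh"].to_numpy(), alpha)
    return df


def locking_unit_fractions(df: pd.DataFrame) -> dict:
    """Fraction of units locked / enhanced in >= 1 tested context."""
    tested = df[df["testable"]]
    units = tested["unit"].unique()
    if units.size == 0:
        return {"n_units": 0, "frac_locked": np.nan, "frac_enhanced": np.nan}
    locked = tested.groupby("unit")["locked"].any()
    enh = tested.groupby("unit")["enhanced"].any()
    return {"n_units": int(units.size),
            "frac_locked": float(locked.mean()),
            "frac_enhanced": float(enh.mean())}


# ---------------------------------------------------------------------------
# Phase-shift tests
# ---------------------------------------------------------------------------

def phase_shift_test(unit_sets: dict, mode: str = "by-field",
                     alpha: float = 0.05, min_n: int = MIN_SET,
                     require_locking: bool = False,
                     lock_alpha: float = 0.05) -> pd.DataFrame:
    """Test, per unit, whether its phase sets share a median direction.

    ``unit_sets`` maps unit -> {context: phases}.  Sets smaller than
    ``min_n`` (and, for by-assembly mode, sets not phase-locked at
    ``lock_alpha``) are discarded; units with < 2 eligible sets are not
    tested and excluded from denominators.  BH across tested units.
    """
    if mode not in ("by-assembly", "by-field", "by-field-and-trialtype"):
        raise ValueError(f"unknown mode {mode!r}")
    rows = []
    for unit in sorted(unit_sets, key=str):
        eligible = []
        for ctx, ph in unit_sets[unit].items():
            ph = np.asarray(ph, dtype=float)
            if ph.size <= min_n:
                continue
            if require_locking:
                lock = cs.hodges_ajne(ph, min_n=min_n)
                if not (lock.testable and lock.p_value < lock_alpha):
                    continue
            eligible.append(ph)
        if len(eligible) < 2:
            rows.append({"unit": unit, "n_sets": len(eligible),
                         "tested": False, "p": np.nan})
            continue
        res = cs.circ_kruskal_wallis(eligible)
        rows.append({"unit": unit, "n_sets": len(eligible), "tested": True,
                     "p": res.p_value})
    df = pd.DataFrame(rows, columns=["unit", "n_sets", "tested", "p"])
    df["shift"] = cs.benjamini_hochberg(df["p"].to_numpy(), alpha)
    df.attrs["mode"] = mode
    return df


def shift_fraction(df: pd.DataFrame) -> tuple:
    """(fraction of tested units shifting, number tested) for one session."""
    tested = df[df["tested"]]
    if len(tested) == 0:
        return np.nan, 0
    return float(tested["shift"].mean()), int(len(tested))


#: trial-type contrast families within a place field
CONTRAST_FAMILIES = {
    "choice-LR": [(("choice-left",), ("choice-right",))],
    "choice-vs-guided": [(("choice-left", "choice-right"),
                          ("guided-LL", "guided-LR", "guided-RL",
                           "guided-RR"))],
    "guided-origin": [(("guided-LL", "guided-LR"),
                       ("guided-RL", "guided-RR"))],
    "guided-turn": [(("guided-LL",), ("guided-LR",)),
                    (("guided-RL",), ("guided-RR",))],
}


def trialtype_contrasts(unit_field_tt_sets: dict, alpha: float = 0.05,
                        min_n: int = MIN_SET) -> pd.DataFrame:
    """Pairwise phase contrasts between trial-type groups within each field.

    ``unit_field_tt_sets`` maps unit -> {(field, category): phases}.  For
    each contrast family the categories on each side are pooled per field;
    a unit enters a family's denominator when at least one of its fields has
    both pools above the eligibility floor.  BH across every (unit, field,
    family, pair) test; a unit counts as shifting in a family when any of its
    tests in the family survives.
    """
    rows = []
    for unit in sorted(unit_field_tt_sets, key=str):
        sets = unit_field_tt_sets[unit]
        fields = sorted({f for (f, _) in sets})
        for fld in fields:
            for family, pairs in CONTRAST_FAMILIES.items():
                for gi, (cats_a, cats_b) in enumerate(pairs):
                    a = np.concatenate([np.asarray(sets.get((fld, c),
                                                            np.zeros(0)))
                                        for c in cats_a])
                    b = np.concatenate([np.asarray(sets.get((fld, c),
                                                            np.zeros(0)))
                                        for c in cats_b])
                    if a.size <= min_n or b.size <= min_n:
                        continue
                    res = cs.circ_kruskal_wallis([a, b])
                    rows.append({"unit": unit, "field": fld,
                                 "family": family, "pair": gi,
                                 "n_a": a.size, "n_b": b.size,
                                 "p": res.p_value})
    df = pd.DataFrame(rows, columns=["unit", "field", "family", "pair",
                                     "n_a", "n_b", "p"])
    if len(df):
        df["shift"] = cs.benjamini_hochberg(df["p"].to_numpy(), alpha)
    else:
        df["shift"] = pd.Series(dtype=bool)
    return df


def contrast_fractions(df: pd.DataFrame) -> dict:
    """Per-family fraction of eligible units with a surviving contrast."""
    out = {}
    for family in CONTRAST_FAMILIES:
        sub = df[df["family"] == family]
        if not len(sub):
            out[family] = (np.nan, 0)
            continue
        per_unit = sub.groupby("unit")["shift"].any()
        out[family] = (float(per_unit.mean()), int(per_unit.size))
    return out


# ---------------------------------------------------------------------------
# Decoding
# ---------------------------------------------------------------------------

def svm_decode(X, y, folds: int = 50, n_shuffle: int = 500,
               C: float = 1.0, seed: int = 0, shuffle_groups=None):
    """Linear-SVM decoding of trial type from per-spike features.

    Phases must be passed as [cos(theta), sin(theta)] columns.  Accuracy is
    stratified k-fold cross-validation (fold count reduced with a log entry
    when a class is smaller than the fold count).  The null shuffles labels
    (at the level of ``shuffle_groups``, e.g. trial ids, when given) and the
    original fit uses jointly shuffled sample order so that autocorrelation
    in the label sequence does not bias the comparison.  Returns
    (accuracy, p_value).
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if classes.size < 2:
        raise ValueError("decoding needs at least two classes")
    k = int(min(folds, counts.min()))
    if k < folds:
        logger.info("fold count reduced from %d to %d", folds, k)
    if k < 2:
        raise ValueError("smallest class has fewer than 2 samples")
    rng = np.random.default_rng(seed)

    def cv_accuracy(Xs, ys, rs):
        clf = SVC(kernel="linear", C=C)
        cv = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        return float(cross_val_score(clf, Xs, ys, cv=cv).mean())

    order = rng.permutation(y.size)  # joint spike-label order shuffle
    acc = cv_accuracy(X[order], y[order], 0)
    null = np.empty(n_shuffle)
    for s in range(n_shuffle):
        if shuffle_groups is not None:
            g = np.asarray(shuffle_groups)
            ug = np.unique(g)
            gmap = dict(zip(ug, ug[rng.permutation(ug.size)]))
            glabel = {grp: y[g == grp][0] for grp in ug}
            ys = np.array([glabel[gmap[gi]] for gi in g])
            if np.unique(ys).size < 2:
                null[s] = acc  # degenerate shuffle counts against signal
                continue
            null[s] = cv_accuracy(X, ys, s + 1)
        else:
            ys = y[rng.permutation(y.size)]
            null[s] = cv_accuracy(X, ys, s + 1)
    p = float(np.mean(null >= acc))
    return acc, p


# ---------------------------------------------------------------------------
# Rate-phase co-occurrence
# ---------------------------------------------------------------------------

def rate_difference_test(rates_a, rates_b) -> float:
    """Two-sided rank-sum on per-spike instantaneous rates."""
    return float(stats.ranksums(rates_a, rates_b).pvalue)


def rate_phase_cooccurrence(pair_table: pd.DataFrame,
                            alpha: float = 0.05) -> pd.DataFrame:
    """Chi-square independence of phase-shift and rate-change significance.

    ``pair_table`` columns: family, phase_p, rate_p (one row per spike-set
    pair).  Builds per family the 2x2 table of (phase_p < alpha) x
    (rate_p < alpha) and tests independence (no continuity correction).
    Families with a zero margin are skipped with a marker.
    """
    rows = []
    for family, sub in pair_table.groupby("family"):
        a = sub["phase_p"].to_numpy() < alpha
        b = sub["rate_p"].to_numpy() < alpha
        table = np.array([[np.sum(a & b), np.sum(a & ~b)],
                          [np.sum(~a & b), np.sum(~a & ~b)]])
        if (table.sum(0) == 0).any() or (table.sum(1) == 0).any():
            rows.append({"family": family, "n": len(sub), "chi2": np.nan,
                         "p": np.nan, "tested": False})
            continue
        chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
        rows.append({"family": family, "n": len(sub), "chi2": float(chi2),
                     "p": float(p), "tested": True})
    return pd.DataFrame(rows, columns=["family", "n", "chi2", "p", "tested"])


# ---------------------------------------------------------------------------
# Theta-cycle lag changes
# ---------------------------------------------------------------------------

def xcorr_trial_lags(times_a, times_b, trials, bin_width: float = 0.02,
                     max_bins: int = 3) -> dict:
    """Per-trial lag (bins in [-max_bins, max_bins]) of maximal
    cross-correlation between two units; trials with all-zero correlograms
    are skipped."""
    ta = np.asarray(times_a, dtype=float)
    tb = np.asarray(times_b, dtype=float)
    lags = np.arange(-max_bins, max_bins + 1)
    out = {}
    for _, row in trials.df.iterrows():
        a = ta[(ta >= row["t_start"]) & (ta < row["t_end"])]
        b = tb[(tb >= row["t_start"]) & (tb < row["t_end"])]
        if a.size == 0 or b.size == 0:
            continue
        nb = int(np.ceil((row["t_end"] - row["t_start"]) / bin_width)) + 1
        ca = np.bincount(((a - row["t_start"]) / bin_width).astype(int),
                         minlength=nb)
        cb = np.bincount(((b - row["t_start"]) / bin_width).astype(int),
                         minlength=nb)
        cc = np.array([np.dot(ca[max(0, -l): nb - max(0, l)],
                              cb[max(0, l): nb - max(0, -l)]) for l in lags])
        if cc.sum() == 0:
            continue
        best = lags[np.lexsort((np.abs(lags), -cc))[0]]
        out.setdefault(row["category"], []).append(int(best))
    return {c: np.asarray(v) for c, v in out.items()}


def xcorr_lag_change(times_a, times_b, trials, cat_a, cat_b,
                     bin_width: float = 0.02, max_bins: int = 3,
                     min_trials: int = 5):
    """Two-sided rank-sum test for a lag change between two trial types.

    Returns (lags_a, lags_b, p); p is NaN when either type has fewer than
    ``min_trials`` usable trials.
    """
    lags = xcorr_trial_lags(times_a, times_b, trials, bin_width, max_bins)
    la = lags.get(cat_a, np.zeros(0))
    lb = lags.get(cat_b, np.zeros(0))
    if la.size < min_trials or lb.size < min_trials:
        return la, lb, np.nan
    if np.array_equal(np.unique(la), np.unique(lb)) and np.unique(la).size == 1:
        return la, lb, 1.0
    return la, lb, float(stats.mannwhitneyu(la, lb,
                                            alternative="two-sided").pvalue)


# ---------------------------------------------------------------------------
# Session summaries and sensitivity reruns
# ---------------------------------------------------------------------------

def weighted_session_fraction(per_session) -> dict:
    """Weighted mean/SE and order statistics of per-session fractions.

    ``per_session`` is a list of (fraction, weight) with weights = the number
    of tested units (or assemblies) in that session.
    """
    fr = np.array([f for f, _ in per_session], dtype=float)
    w = np.array([x for _, x in per_session], dtype=float)
    keep = np.isfinite(fr) & (w > 0)
    fr, w = fr[keep], w[keep]
    if fr.size == 0:
        raise ValueError("no sessions with positive weight")
    mean = float(np.average(fr, weights=w))
    if fr.size > 1:
        var = np.average((fr - mean) ** 2, weights=w)
        se = float(np.sqrt(var / fr.size))
    else:
        se = np.nan
    q = np.percentile(fr, [25, 50, 75])
    return {"weighted_mean": mean, "weighted_se": se, "median": float(q[1]),
            "q25": float(q[0]), "q75": float(q[2]),
            "min": float(fr.min()), "max": float(fr.max()),
            "n_sessions": int(fr.size)}


def apply_exclusion(bundle, epoch_sets):
    """Copy of the bundle with spikes inside any given epoch removed."""
    from .io_core import SessionBundle, SpikeTrain
    trains = []
    for st in bundle.spike_trains:
        keep = np.ones(st.n, dtype=bool)
        for es in epoch_sets:
            keep &= ~es.contains(st.times)
        trains.append(SpikeTrain(st.unit_id, st.times[keep], st.session_id))
    return SessionBundle(trains, bundle.lfp, bundle.track, bundle.trials,
                         session_id=bundle.session_id,
                         ground_truth=bundle.ground_truth)


def exclusion_rerun(bundle, epoch_sets, analysis, **kwargs):
    """Run ``analysis(bundle, **kwargs)`` on the masked bundle."""
    return analysis(apply_exclusion(bundle, epoch_sets), **kwargs)
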