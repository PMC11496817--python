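"""Multi-timescale detection of recurring lagged multi-unit coincidence patterns.

The detector scans binned parallel spike trains for unit pairs whose joint
(possibly lagged) activations reoccur more often than expected from their
marginal rates, agglomerates significant pairs into larger patterns by
recursively testing the pattern's activation series against the remaining
units, scans a ladder of temporal resolutions, and prunes each member set to
the resolution where it was detected with the lowest p-value.  Two timescale
families are distinguished: *spike-assemblies* (bin widths 0.005-0.06 s,
theta-sequence/replay precision) and *rate-assemblies* (0.07-5 s, place-field
traversal precision).

The pair statistic: with counts n_A(t), n_B(t), the joint activation count at
lag l is ``n_AB(l) = sum_t min(n_A(t), n_B(t + l))``.  The candidate lag l*
maximizes n_AB.  Slow comodulation (behavioral nonstationarity) inflates
n_AB at *every* lag, so the test contrasts n_AB(l*) with the counts at the
reference-lag-shifted alignments l* +/- r (r = 2 bins by default): under the
no-fine-structure null the candidate and reference alignments are
exchangeable, giving a conditional binomial test of n_AB(l*) against the mean
reference count at probability 1/2.  The best-lag search over the 2L+1
scanned lags is corrected Sidak-style, and Benjamini-Hochberg is applied
across pairs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
from scipy import stats

from .circstats import benjamini_hochberg

__all__ = [
    "BinnedSpikes",
    "AssemblyPattern",
    "AssemblySet",
    "DEFAULT_BIN_SIZES",
    "DEFAULT_MAX_LAGS",
    "SPIKE_WINDOW",
    "RATE_WINDOW",
    "bin_spikes",
    "detect_pair_assemblies",
    "agglomerate",
    "multiresolution_scan",
    "prune_best_resolution",
    "assembly_activations",
    "assembly_spikes",
    "classify_timescale",
    "overlap_chance_bootstrap",
]

# full resolution ladder and per-resolution maximum lags (bins)
DEFAULT_BIN_SIZES = [0.0058, 0.007, 0.009, 0.011, 0.014, 0.018, 0.022, 0.028,
                     0.035, 0.044, 0.055, 0.07, 0.09, 0.11, 0.14, 0.17, 0.21,
                     0.27, 0.33, 0.42, 0.52, 0.65, 0.82, 1.0, 1.3, 1.6, 2.0,
                     2.5, 3.2, 4.0, 5.0]
DEFAULT_MAX_LAGS = [4, 5, 5, 5, 5, 4, 4, 4, 3, 3, 3, 2, 2, 2, 2, 2, 1, 1, 1,
                    1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1, 1]

SPIKE_WINDOW = (0.005, 0.06)
RATE_WINDOW = (0.07, 5.0)


@dataclass
class BinnedSpikes:
    counts: np.ndarray          # units x bins, int
    bin_width: float
    t0: float
    unit_ids: list

    @property
    def n_units(self) -> int:
        return self.counts.shape[0]

    @property
    def n_bins(self) -> int:
        return self.counts.shape[1]


@dataclass
class AssemblyPattern:
    members: list               # unit ids, ordered by activation (first = lag 0)
    lags: list                  # bins relative to the first-active member
    bin_width: float
    p_value: float
    activation_times: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    activation_strengths: np.ndarray = field(default_factory=lambda: np.zeros(0, int))
    t0: float = 0.0

    def __post_init__(self):
        if self.lags and self.lags[0] != 0:
            raise ValueError("lags must be relative to the first-active member")
        if len(set(self.members)) != len(self.members):
            raise ValueError("assembly members must be distinct")

    @property
    def member_set(self) -> frozenset:
        return frozenset(self.members)

    @property
    def lag_seconds(self) -> np.ndarray:
        return np.asarray(self.lags, dtype=float) * self.bin_width

    @property
    def n_occurrences(self) -> int:
        return int(self.activation_times.size)


@dataclass
class AssemblySet:
    patterns: list
    detection_config: dict = field(default_factory=dict)

    def __iter__(self):
        return iter(self.patterns)

    def __len__(self):
        return len(self.patterns)


def _extract_trains(spikes):
    """Normalize spike input to an ordered {unit_id: times array} mapping."""
    if isinstance(spikes, dict):
        items = list(spikes.items())
    else:
        items = []
        for tr in spikes:
            if hasattr(tr, "unit_id"):
                items.append((tr.unit_id, np.asarray(tr.times, float)))
            else:
                uid, times = tr
                items.append((uid, np.asarray(times, float)))
    return {uid: np.asarray(t, float) for uid, t in items}


def bin_spikes(spikes, bin_width: float, t0: float = None,
               t_end: float = None) -> BinnedSpikes:
    """Count spikes in half-open bins [t0 + b*D, t0 + (b+1)*D)."""
    if bin_width <= 0:
        raise ValueError("bin_width must be positive")
    trains = _extract_trains(spikes)
    all_t = [t for t in trains.values() if t.size]
    if t0 is None:
        t0 = 0.0 if not all_t else float(min(t.min() for t in all_t))
    if t_end is None:
        t_end = t0 + bin_width if not all_t else float(max(t.max() for t in all_t))
    n_bins = max(int(np.floor((t_end - t0) / bin_width)) + 1, 1)
    counts = np.zeros((len(trains), n_bins), dtype=np.int64)
    for i, (uid, t) in enumerate(trains.items()):
        if t.size == 0:
            continue
        b = np.floor((t - t0) / bin_width).astype(np.int64)
        b = b[(b >= 0) & (b < n_bins)]
        np.add.at(counts[i], b, 1)
    return BinnedSpikes(counts, float(bin_width), float(t0), list(trains.keys()))


def _joint_counts(a: np.ndarray, b: np.ndarray, lags: np.ndarray) -> np.ndarray:
    out = np.zeros(lags.size, dtype=np.int64)
    for i, lag in enumerate(lags):
        lag = int(lag)
        if lag >= 0:
            n = min(a.size, b.size - lag)
            if n > 0:
                out[i] = np.minimum(a[:n], b[lag:lag + n]).sum()
        else:
            n = min(b.size, a.size + lag)
            if n > 0:
                out[i] = np.minimum(b[:n], a[-lag:-lag + n]).sum()
    return out


def _pair_test(a: np.ndarray, b: np.ndarray, max_lag: int,
               reference_lag: int):
    """Best lag and Sidak-corrected conditional binomial p for one pair.

    Returns (p, best_lag, joint_count).  The candidate count is contrasted
    with the mean of the counts at the two reference-shifted lags; both are
    computed even if they fall outside the scanned lag range.
    """
    lags = np.arange(-max_lag, max_lag + 1)
    counts = _joint_counts(a, b, lags)
    # deterministic tie-break: smallest |lag|, then positive lag
    order = np.lexsort((lags < 0, np.abs(lags), -counts))
    best_idx = order[0]
    l_star = int(lags[best_idx])
    n_star = int(counts[best_idx])
    refs = _joint_counts(a, b, np.array([l_star - reference_lag,
                                         l_star + reference_lag]))
    m_ref = float(refs.mean())
    n_tot = n_star + int(round(m_ref))
    if n_tot == 0:
        p_raw = 1.0
    else:
        p_raw = float(stats.binom.sf(n_star - 1, n_tot, 0.5))
    n_scanned = lags.size
    p = float(-np.expm1(n_scanned * np.log1p(-min(p_raw, 1.0 - 1e-16))))
    return min(p, 1.0), l_star, n_star


def detect_pair_assemblies(binned: BinnedSpikes, max_lag: int,
                           reference_lag: int = 2,
                           alpha: float = 0.05) -> list:
    """Scan all unit pairs for significantly recurring lagged coactivation."""
    if max_lag < 0 or reference_lag < 1:
        raise ValueError("max_lag must be >= 0 and reference_lag >= 1")
    U = binned.n_units
    if U < 2:
        return []
    results = []
    for i, j in itertools.combinations(range(U), 2):
        p, l_star, n_star = _pair_test(binned.counts[i], binned.counts[j],
                                       max_lag, reference_lag)
        results.append((i, j, p, l_star, n_star))
    pvals = np.array([r[2] for r in results])
    reject = benjamini_hochberg(pvals, alpha)
    patterns = []
    for keep, (i, j, p, l_star, n_star) in zip(reject, results):
        if not keep:
            continue
        if l_star >= 0:
            members, lags = [binned.unit_ids[i], binned.unit_ids[j]], [0, l_star]
        else:
            members, lags = [binned.unit_ids[j], binned.unit_ids[i]], [0, -l_star]
        pat = AssemblyPattern(members, lags, binned.bin_width, p, t0=binned.t0)
        assembly_activations(pat, binned)
        patterns.append(pat)
    return patterns


def assembly_activations(pattern: AssemblyPattern,
                         binned: BinnedSpikes) -> np.ndarray:
    """Activation strength series: min over members of the lag-aligned counts.

    An occurrence of strength n at origin bin t means every member m fired at
    least n spikes in bin t + lag_m.  Updates the pattern in place and returns
    the full strength series (length n_bins - max lag).
    """
    if abs(pattern.bin_width - binned.bin_width) > 1e-12:
        raise ValueError("bin widths of pattern and binned spikes differ")
    idx = [binned.unit_ids.index(m) for m in pattern.members]
    span = max(pattern.lags)
    T = binned.n_bins - span
    if T <= 0:
        series = np.zeros(0, dtype=np.int64)
    else:
        series = binned.counts[idx[0], :T].copy()
        for k, lag in zip(idx[1:], pattern.lags[1:]):
            np.minimum(series, binned.counts[k, lag:lag + T], out=series)
    occ = np.nonzero(series >= 1)[0]
    pattern.activation_times = occ
    pattern.activation_strengths = series[occ]
    return series


def agglomerate(seeds: list, binned: BinnedSpikes, alpha: float = 0.05,
                max_lag: int = None, reference_lag: int = 2) -> list:
    """Extend significant pair patterns one unit at a time.

    At each round the pattern's activation series is paired against every
    non-member unit with the same lagged-coincidence test; among the
    Benjamini-Hochberg survivors the lowest-p extension is accepted, the
    series rebuilt, and the scan repeated until no extension is significant.
    Patterns agglomerating to the same member set are deduplicated, keeping
    the lowest p.
    """
    if max_lag is None:
        max_lag = max((max(s.lags) for s in seeds), default=0) or 1
    out = []
    for seed in seeds:
        members = list(seed.members)
        lags = list(seed.lags)
        p_val = seed.p_value
        while len(members) < binned.n_units:
            series_pat = AssemblyPattern(members, lags, binned.bin_width,
                                         p_val, t0=binned.t0)
            series = assembly_activations(series_pat, binned)
            if series.size == 0 or series.sum() == 0:
                break
            cands = [u for u in binned.unit_ids if u not in members]
            tests = []
            for u in cands:
                row = binned.counts[binned.unit_ids.index(u)][: series.size +
                                                             max(lags)]
                p, l_star, _ = _pair_test(series, row, max_lag, reference_lag)
                tests.append((p, l_star, u))
            if not tests:
                break
            rej = benjamini_hochberg(np.array([t[0] for t in tests]), alpha)
            sig = [t for t, r in zip(tests, rej) if r]
            if not sig:
                break
            p, l_star, u = min(sig, key=lambda t: t[0])
            if l_star >= 0:
                members, lags = members + [u], lags + [l_star]
            else:
                members = [u] + members
                lags = [0] + [lg - l_star for lg in lags]
            # keep canonical order: sort members by lag, first = 0
            order = np.argsort(lags, kind="stable")
            members = [members[k] for k in order]
            lags = [lags[k] - lags[order[0]] for k in order]
            p_val = p
        pat = AssemblyPattern(members, lags, binned.bin_width, p_val,
                              t0=binned.t0)
        assembly_activations(pat, binned)
        out.append(pat)
    best = {}
    for pat in out:
        key = pat.member_set
        if key not in best or pat.p_value < best[key].p_value:
            best[key] = pat
    return list(best.values())


def multiresolution_scan(spikes, bin_sizes=None, max_lags=None,
                         reference_lag: int = 2, alpha: float = 0.05,
                         window=None, agglomerate_patterns: bool = True,
                         t0: float = None, t_end: float = None) -> AssemblySet:
    """Run the detector at every temporal resolution and pool the patterns."""
    if bin_sizes is None:
        bin_sizes, max_lags = DEFAULT_BIN_SIZES, DEFAULT_MAX_LAGS
    if len(bin_sizes) != len(max_lags):
        raise ValueError("bin_sizes and max_lags must have equal length")
    patterns = []
    for width, L in zip(bin_sizes, max_lags):
        if window is not None and not (window[0] <= width <= window[1]):
            continue
        binned = bin_spikes(spikes, width, t0=t0, t_end=t_end)
        seeds = detect_pair_assemblies(binned, L, reference_lag, alpha)
        pats = (agglomerate(seeds, binned, alpha, L, reference_lag)
                if agglomerate_patterns else seeds)
        patterns.extend(pats)
    return AssemblySet(patterns, {
        "bin_sizes": list(bin_sizes), "max_lags": list(max_lags),
        "reference_lag": reference_lag, "alpha": alpha, "window": window})


def classify_timescale(pattern: AssemblyPattern) -> str:
    """'spike' for bin widths <= 0.06 s, 'rate' for 0.07-5 s."""
    w = pattern.bin_width
    if SPIKE_WINDOW[0] - 1e-9 <= w <= SPIKE_WINDOW[1] + 1e-9:
        return "spike"
    if RATE_WINDOW[0] - 1e-9 <= w <= RATE_WINDOW[1] + 1e-9:
        return "rate"
    raise ValueError(f"bin width {w} s outside the scanned timescale range")


def prune_best_resolution(aset: AssemblySet) -> AssemblySet:
    """Keep, per member set and per timescale window, only the lowest-p
    resolution.  The same member set may survive
    once in the spike window and once in the rate window."""
    best = {}
    for pat in aset.patterns:
        key = (pat.member_set, classify_timescale(pat))
        if key not in best or pat.p_value < best[key].p_value:
            best[key] = pat
    return AssemblySet(list(best.values()), dict(aset.detection_config))


def assembly_spikes(pattern: AssemblyPattern, spikes) -> dict:
    """Flag each member unit's spikes fired during assembly activations.

    A spike of member m is an assembly-spike iff its bin (at the pattern's
    resolution) equals t + lag_m for some occurrence origin t.  Returns
    {unit_id: boolean mask over that unit's spikes}.
    """
    trains = _extract_trains(spikes)
    flags = {}
    occ = pattern.activation_times
    for m, lag in zip(pattern.members, pattern.lags):
        t = trains[m]
        bins = np.floor((t - pattern.t0) / pattern.bin_width).astype(np.int64)
        match_bins = occ + lag
        flags[m] = np.isin(bins, match_bins)
    return flags


def overlap_chance_bootstrap(spike_pairs, rate_pairs, all_units_per_session,
                             n_boot: int = 100_000, seed=None):
    """Chance level for spike-assembly pairs also appearing as rate-assembly
    pairs.

    ``all_units_per_session`` is a list of per-session unit-id lists; the
    candidate pool is every within-session unordered pair.  Each bootstrap
    draw samples len(rate_pairs) pairs from the pool and measures the fraction
    of the observed spike pairs contained in the draw.  Returns
    (p_observed, chance, p_value) with p_value the fraction of draws whose
    overlap is at least the observed one.
    """
    spike_pairs = [frozenset(p) for p in spike_pairs]
    rate_pairs = {frozenset(p) for p in rate_pairs}
    if not spike_pairs or not rate_pairs:
        raise ValueError("empty pair sets")
    pool = []
    for units in all_units_per_session:
        pool.extend(frozenset(p) for p in itertools.combinations(units, 2))
    pool = list(dict.fromkeys(pool))
    n_draw = min(len(rate_pairs), len(pool))
    p_obs = float(np.mean([p in rate_pairs for p in spike_pairs]))
    rng = np.random.default_rng(seed)
    pool_idx = {p: i for i, p in enumerate(pool)}
    spike_idx = np.array([pool_idx[p] for p in spike_pairs if p in pool_idx])
    n_pool = len(pool)
    boots = np.empty(int(n_boot))
    member = np.zeros(n_pool, dtype=bool)
    for b in range(int(n_boot)):
        draw = rng.choice(n_pool, size=n_draw, replace=False)
        member[:] = False
        member[draw] = True
        boots[b] = member[spike_idx].mean() if spike_idx.size else 0.0
    chance = float(boots.mean())
    p_value = float(np.mean(boots >= p_obs))
    return p_obs, chance, p_value
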