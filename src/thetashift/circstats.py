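"""Circular statistics for theta-phase analyses.

Implements the test battery used throughout the phase-shift analyses:
non-uniformity of spike-phase samples (Hodges–Ajne), multi-sample equality of
median direction (nonparametric circular analog of the Kruskal–Wallis test,
i.e. Fisher's common-median test), circular–linear correlation for phase
precession (Kempter-style slope fit + Jammalamadaka circular correlation),
a resampling test for *enhanced* phase locking of a spike subset relative to
all spikes of a unit, Hartigan's dip statistic for bimodality of timescale
distributions, and Benjamini–Hochberg control used on every test family.

All phases are radians; results are invariant to a global phase rotation.
Sample-size eligibility (the n > 50 floor for the Hodges–Ajne approximation)
is reported through ``CircTestResult.testable`` rather than by raising, so
callers can keep ineligible sets out of their denominators.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import optimize, stats
from statsmodels.stats.multitest import multipletests

__all__ = [
    "CircTestResult",
    "wrap_angles",
    "resultant_length",
    "circ_mean",
    "circ_median",
    "hodges_ajne",
    "enhanced_locking_bootstrap",
    "circ_kruskal_wallis",
    "circ_linear_corr",
    "benjamini_hochberg",
    "dip_statistic",
    "dip_bimodality",
]

#: minimum per-set sample size for the Hodges–Ajne large-n approximation
MIN_PHASE_SAMPLES = 50


@dataclass
class CircTestResult:
    statistic: float
    p_value: float
    n: int
    method: str
    R: float = np.nan
    testable: bool = True
    extra: dict = field(default_factory=dict)

    @property
    def significant(self) -> bool:
        return bool(self.testable and self.p_value < 0.05)


def wrap_angles(phases):
    """Wrap angles to [-pi, pi)."""
    phases = np.asarray(phases, dtype=float)
    return np.mod(phases + np.pi, 2.0 * np.pi) - np.pi


def _check_phases(phases, min_n=1):
    phases = wrap_angles(phases)
    if phases.ndim != 1:
        phases = phases.ravel()
    if phases.size < min_n:
        raise ValueError(f"need at least {min_n} phase samples, got {phases.size}")
    return phases


def resultant_length(phases) -> float:
    """Length R of the mean resultant vector, R = |mean(exp(i*theta))|."""
    phases = _check_phases(phases, min_n=1)
    return float(np.abs(np.exp(1j * phases).mean()))


def circ_mean(phases) -> float:
    phases = _check_phases(phases, min_n=1)
    return float(np.angle(np.exp(1j * phases).mean()))


def circ_median(phases) -> float:
    """Circular median: the sample angle minimizing the mean geodesic deviation.

    Uses an O(n log n) prefix-sum evaluation of the total circular distance at
    every sample point. Ties broken by the first minimizer in sorted order.
    """
    phases = _check_phases(phases, min_n=1)
    s = np.sort(phases)
    n = s.size
    if n == 1:
        return float(s[0])
    csum = np.concatenate(([0.0], np.cumsum(s)))
    total = csum[-1]
    # for candidate s_i, points are split at the antipode s_i + pi (mod 2pi);
    # enumerate in unwrapped coordinates on [s_0, s_0 + 2pi)
    ext = np.concatenate([s, s + 2.0 * np.pi])
    cext = np.concatenate(([0.0], np.cumsum(ext)))
    # index of first point (in ext) at angle > s_i + pi
    b = np.searchsorted(ext, s + np.pi, side="right")
    idx = np.arange(n)
    # points j in [i, b): same half -> distance (s_j - s_i); includes j = i (0)
    cnt_near = b - idx
    sum_near = (cext[b] - cext[idx]) - cnt_near * s
    # points in [b, i + n): opposite half -> distance 2pi - (s_j - s_i)
    cnt_far = n - cnt_near
    sum_far = cnt_far * (2.0 * np.pi + s) - (cext[idx + n] - cext[b])
    tot = sum_near + sum_far
    return float(s[int(np.argmin(tot))])


# ---------------------------------------------------------------------------
# Hodges–Ajne test for non-uniformity
# ---------------------------------------------------------------------------

def _ajne_m(phases) -> int:
    """Minimum number of sample points in any closed half circle.

    Equals n minus the maximum count over open half circles; that count is a
    piecewise-constant function of the arc rotation whose breakpoints sit at
    the data points and their antipodes, so evaluating the limit-from-above
    at those 2n angles is exhaustive.
    """
    s = np.sort(wrap_angles(phases))
    n = s.size
    ext = np.concatenate([s, s + 2.0 * np.pi, s + 4.0 * np.pi])
    cand = np.concatenate([s, s - np.pi]) + 2.0 * np.pi  # shift into ext range
    eps = 1e-9  # tolerate float ties at exactly antipodal points
    counts = (np.searchsorted(ext, cand + np.pi + eps, side="right")
              - np.searchsorted(ext, cand + eps, side="right"))
    return int(counts.min())


def hodges_ajne(phases, min_n: int = MIN_PHASE_SAMPLES) -> CircTestResult:
    """Hodges–Ajne omnibus test for circular non-uniformity.

    Does not assume unimodality.  The statistic m is the minimum number of
    sample points falling in any closed half circle; the p-value uses the
    large-n approximation, which is why sets of ``min_n`` or fewer samples are
    flagged ``testable=False`` (distinct from non-significant) and carry a NaN
    p-value.
    """
    phases = _check_phases(phases, min_n=1)
    n = phases.size
    m = _ajne_m(phases)
    R = resultant_length(phases)
    if n <= min_n:
        return CircTestResult(float(m), np.nan, n, "hodges-ajne", R, testable=False)
    if n - 2 * m <= 0:
        return CircTestResult(float(m), 1.0, n, "hodges-ajne", R)
    A = np.pi * np.sqrt(n) / (2.0 * (n - 2.0 * m))
    p = np.sqrt(2.0 * np.pi) / A * np.exp(-np.pi ** 2 / (8.0 * A ** 2))
    return CircTestResult(float(m), float(min(p, 1.0)), n, "hodges-ajne", R)


# ---------------------------------------------------------------------------
# Enhanced phase locking of a spike subset (bootstrap on R)
# ---------------------------------------------------------------------------

def enhanced_locking_bootstrap(subset_phases, all_phases, n_rep: int = 1000,
                               seed=None) -> CircTestResult:
    """Test whether a subset of a unit's spikes is more phase-locked than the
    unit overall.

    ``n_rep`` replica sets of ``len(subset)`` phases are drawn *without
    replacement* from all of the unit's spike phases; the p-value is the
    fraction of replicas whose resultant length strictly exceeds the subset's
    (ties count against significance, a conservative convention).
    """
    sub = _check_phases(subset_phases, min_n=1)
    pop = _check_phases(all_phases, min_n=1)
    if sub.size > pop.size:
        raise ValueError("subset larger than the population of unit spikes")
    rng = np.random.default_rng(seed)
    r_orig = resultant_length(sub)
    n, N = sub.size, pop.size
    cosp, sinp = np.cos(pop), np.sin(pop)
    if n == N:
        r_rep = np.full(n_rep, r_orig)
    else:
        keys = rng.random((n_rep, N))
        idx = np.argpartition(keys, n - 1, axis=1)[:, :n]
        r_rep = np.hypot(cosp[idx].mean(axis=1), sinp[idx].mean(axis=1))
    p = float(np.mean(r_rep > r_orig))
    return CircTestResult(r_orig, p, n, "enhanced-locking-bootstrap", r_orig,
                          extra={"n_rep": n_rep})


# ---------------------------------------------------------------------------
# Multi-sample test on median direction (circular Kruskal–Wallis analog)
# ---------------------------------------------------------------------------

def circ_kruskal_wallis(groups, min_n: int = 0) -> CircTestResult:
    """Nonparametric multi-sample test of equal median direction.

    Circular analog of the Kruskal–Wallis test (Fisher's common-median
    P-test): counts per group how many observations fall on each side of the
    pooled circular median and refers the resulting statistic to a chi-square
    distribution with k-1 degrees of freedom.

    ``min_n`` > 0 marks the result not-testable when any group is smaller;
    the eligibility rule itself (n > 50 and phase-locked groups) is enforced
    by callers.
    """
    groups = [_check_phases(g, min_n=1) for g in groups]
    if len(groups) < 2:
        raise ValueError("need at least two groups")
    ns = np.array([g.size for g in groups], dtype=float)
    N = int(ns.sum())
    k = len(groups)
    if min_n and any(g.size < min_n for g in groups):
        return CircTestResult(np.nan, np.nan, N, "circ-kruskal-wallis",
                              testable=False)
    pooled = np.concatenate(groups)
    med = circ_median(pooled)
    m = np.array([np.sum(wrap_angles(g - med) < 0) for g in groups], dtype=float)
    M = m.sum()
    if M <= 0 or M >= N:
        # pooled median leaves nothing on one side: no evidence of different
        # medians; degenerate but defined as non-significant
        return CircTestResult(0.0, 1.0, N, "circ-kruskal-wallis")
    P = N ** 2 / (M * (N - M)) * np.sum(m ** 2 / ns) - N * M / (N - M)
    p = float(stats.chi2.sf(P, k - 1))
    return CircTestResult(float(P), p, N, "circ-kruskal-wallis",
                          extra={"df": k - 1, "group_n": ns.astype(int).tolist()})


# ---------------------------------------------------------------------------
# Circular–linear correlation (phase precession)
# ---------------------------------------------------------------------------

def _resultant_of_slope(phases, x, slopes):
    ph = phases[None, :] - 2.0 * np.pi * slopes[:, None] * x[None, :]
    return np.abs(np.exp(1j * ph).mean(axis=1))


def circ_linear_corr(phases, positions, slope_bounds=None,
                     n_grid: int = 512) -> CircTestResult:
    """Circular–linear correlation between spike phase and linear position.

    Fits the precession slope s (cycles per position unit) maximizing the
    resultant length of ``phase - 2*pi*s*x``, then computes the circular
    correlation between the measured phases and the fitted linear phase
    (Jammalamadaka), with the usual normal approximation for the two-sided
    p-value.  The returned coefficient carries the sign of the fitted slope,
    so negative values indicate phase precession (phase advancing with
    position).
    """
    phases = _check_phases(phases, min_n=2)
    x = np.asarray(positions, dtype=float).ravel()
    if x.size != phases.size:
        raise ValueError("phases and positions must have equal length")
    if phases.size < 10:
        return CircTestResult(np.nan, np.nan, phases.size, "circ-linear",
                              testable=False)
    span = x.max() - x.min()
    if span <= 0 or not np.all(np.isfinite(x)):
        raise ValueError("positions are constant or non-finite")
    if slope_bounds is None:
        slope_bounds = (-2.0 / span, 2.0 / span)
    grid = np.linspace(slope_bounds[0], slope_bounds[1], n_grid)
    rg = _resultant_of_slope(phases, x, grid)
    i = int(np.argmax(rg))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, n_grid - 1)]
    res = optimize.minimize_scalar(
        lambda a: -_resultant_of_slope(phases, x, np.array([a]))[0],
        bounds=(lo, hi), method="bounded")
    s_hat = float(res.x)
    psi = wrap_angles(2.0 * np.pi * s_hat * x)
    sphi = np.sin(phases - circ_mean(phases))
    spsi = np.sin(psi - circ_mean(psi))
    denom = np.sqrt(np.sum(sphi ** 2) * np.sum(spsi ** 2))
    if denom == 0:
        return CircTestResult(0.0, 1.0, phases.size, "circ-linear",
                              extra={"slope": s_hat})
    rho_cc = float(np.sum(sphi * spsi) / denom)
    n = phases.size
    l20 = np.mean(sphi ** 2)
    l02 = np.mean(spsi ** 2)
    l22 = np.mean(sphi ** 2 * spsi ** 2)
    if l22 <= 0:
        p = 1.0
        z = 0.0
    else:
        z = rho_cc * np.sqrt(n * l20 * l02 / l22)
        p = float(2.0 * stats.norm.sf(abs(z)))
    rho_signed = float(np.sign(s_hat) * rho_cc) if s_hat != 0 else rho_cc
    return CircTestResult(rho_signed, p, n, "circ-linear",
                          extra={"slope": s_hat, "z": float(z),
                                 "phi0": circ_mean(phases - psi)})


# ---------------------------------------------------------------------------
# Multiple comparisons
# ---------------------------------------------------------------------------

def benjamini_hochberg(p_values, alpha: float = 0.05) -> np.ndarray:
    """Benjamini–Hochberg step-up rejection mask at level ``alpha``.

    NaN p-values (not-testable sets) are never rejected and do not count
    toward the number of tests.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return np.zeros(0, dtype=bool)
    mask = np.zeros(p.shape, dtype=bool)
    ok = np.isfinite(p)
    if ok.any():
        mask[ok] = multipletests(p[ok], alpha=alpha, method="fdr_bh")[0]
    return mask


# ---------------------------------------------------------------------------
# Hartigan's dip statistic (bimodality of assembly timescales)
# ---------------------------------------------------------------------------

def _gcm(x, y):
    """Greatest convex minorant of points (x, y), evaluated at x (lower hull)."""
    hull = [0]
    for i in range(1, x.size):
        while len(hull) >= 2:
            i0, i1 = hull[-2], hull[-1]
            # pop i1 while slope(i0, i1) >= slope(i1, i): not on the lower hull
            if ((y[i1] - y[i0]) * (x[i] - x[i1])
                    >= (y[i] - y[i1]) * (x[i1] - x[i0])):
                hull.pop()
            else:
                break
        hull.append(i)
    return np.interp(x, x[hull], y[hull])


def _prefix_convex_ok(u, lo, hi, k):
    """Does a convex nondecreasing g with lo <= g <= hi exist on knots 0..k?"""
    if k < 0:
        return True
    g = _gcm(u[:k + 1], hi[:k + 1])
    i_min = int(np.argmin(g))
    g[:i_min] = g[i_min]           # largest convex *nondecreasing* minorant
    return bool(np.all(g >= lo[:k + 1] - 1e-12))


def _suffix_concave_ok(u, lo, hi, j):
    """Does a concave nondecreasing g with lo <= g <= hi exist on knots
    j..m-1?  Mirror of the prefix check."""
    m = u.size
    if j >= m:
        return True
    ur = -u[j:][::-1]
    lr = -hi[j:][::-1]
    hr = -lo[j:][::-1]
    g = _gcm(ur, hr)
    i_min = int(np.argmin(g))
    g[:i_min] = g[i_min]
    return bool(np.all(g >= lr - 1e-12))


def _dip_prepare(values):
    x = np.sort(np.asarray(values, dtype=float).ravel())
    if x.size < 4:
        raise ValueError("dip requires at least 4 observations")
    u, counts = np.unique(x, return_counts=True)
    n = x.size
    chi = np.cumsum(counts) / n              # F_n(u_j)
    clo = np.concatenate(([0.0], chi[:-1]))  # F_n(u_j^-)
    return u, counts, n, chi, clo


def _split_lower_bound(u, chi, clo, counts, n, k) -> float:
    """Tube lower bound on the dip for one mode split: bisect the tube
    half-width d for convex feasibility of knots 0..k and concave
    feasibility of k+1..m-1 (necessary conditions; the junction between the
    two sides is settled by the exact LP)."""
    def ok(d):
        lo = np.maximum(chi - d, 0.0)
        hi = np.minimum(clo + d, 1.0)
        if np.any(lo > hi + 1e-15):
            return False
        return (_prefix_convex_ok(u, lo, hi, k)
                and _suffix_concave_ok(u, lo, hi, k + 1))
    d_lo = counts.max() / (2.0 * n)
    if ok(d_lo):
        return float(d_lo)
    d_hi = 0.30
    for _ in range(16):
        mid = 0.5 * (d_lo + d_hi)
        if ok(mid):
            d_hi = mid
        else:
            d_lo = mid
    return float(d_lo)


def dip_statistic(values) -> float:
    """Hartigan's dip: min over (continuous) unimodal cdfs G of sup|F_n - G|.

    Exact for the formulation with continuous G: for every candidate mode
    interval the best piecewise-linear cdf convex left / concave right of
    the mode is a small linear program; splits are pruned by a fast
    greatest-convex-minorant tube bound, so only a handful of LPs are
    actually solved.
    """
    u, counts, n, chi, clo = _dip_prepare(values)
    m = u.size
    if m == 1:
        return 0.5 - 0.5 / n
    bounds = np.array([_split_lower_bound(u, chi, clo, counts, n, k)
                       for k in range(-1, m)])
    order = np.argsort(bounds)
    best = np.inf
    for idx in order:
        if bounds[idx] >= best - 1e-12:
            break
        d = _dip_split_lp(u, n, chi, clo, int(idx) - 1)
        best = min(best, d)
    return float(best)


def _dip_split_lp(u, n, chi, clo, k) -> float:
    """Exact minimal tube half-width for one mode split (LP)."""
    m = u.size
    du = np.diff(u)

    nv = m + 1  # G_0..G_{m-1}, d
    c = np.zeros(nv)
    c[-1] = 1.0
    rows = []
    rhs = []
    for j in range(m):
        # G_j >= chi_j - d   ->  -G_j - d <= -chi_j
        r = np.zeros(nv); r[j] = -1.0; r[-1] = -1.0
        rows.append(r); rhs.append(-chi[j])
        # G_j <= clo_j + d
        r = np.zeros(nv); r[j] = 1.0; r[-1] = -1.0
        rows.append(r); rhs.append(clo[j])
    for j in range(m - 1):
        # monotone: G_j - G_{j+1} <= 0
        r = np.zeros(nv); r[j] = 1.0; r[j + 1] = -1.0
        rows.append(r); rhs.append(0.0)
    # mode in (u_k, u_{k+1}): convex on knots 0..k, concave on k+1..m-1
    for i in range(1, m - 1):
        if i + 1 <= k:
            # convexity: (G_i-G_{i-1})*du_i - (G_{i+1}-G_i)*du_{i-1} <= 0
            r = np.zeros(nv)
            r[i - 1] = -du[i]
            r[i] = du[i] + du[i - 1]
            r[i + 1] = -du[i - 1]
            rows.append(r); rhs.append(0.0)
        elif i - 1 >= k + 1:
            r = np.zeros(nv)
            r[i - 1] = du[i]
            r[i] = -(du[i] + du[i - 1])
            r[i + 1] = du[i - 1]
            rows.append(r); rhs.append(0.0)
    res = optimize.linprog(c, A_ub=np.array(rows), b_ub=np.array(rhs),
                           bounds=[(0.0, 1.0)] * m + [(0.0, 0.5)],
                           method="highs")
    return float(res.fun) if res.status == 0 else np.inf


_DIP_NULL_CACHE: dict = {}


def dip_bimodality(values, n_boot: int = 100_000, seed=None) -> CircTestResult:
    """Hartigan dip test with bootstrap p-value under the least-favorable
    unimodal (uniform) null.  A reported p of 0 means p < 1/n_boot.  The
    null dip distribution depends only on the sample size, so it is cached
    per (n, n_boot, seed)."""
    x = np.asarray(values, dtype=float).ravel()
    d = dip_statistic(x)
    n = x.size
    key = (n, int(n_boot), seed)
    if key not in _DIP_NULL_CACHE:
        rng = np.random.default_rng(seed)
        _DIP_NULL_CACHE[key] = np.sort(
            [dip_statistic(rng.random(n)) for _ in range(int(n_boot))])
    null = _DIP_NULL_CACHE[key]
    p = float(np.mean(null >= d))
    return CircTestResult(d, p, n, "hartigan-dip",
                          extra={"n_boot": int(n_boot)})
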