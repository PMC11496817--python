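"""Ground-truth synthetic session generator.

Emulates the structure of a CA1 T-maze recording session so every pipeline
stage can be tested without real data: ~10 theta-modulated place cells with
multiple Gaussian place fields on the maze skeleton, von Mises phase
preferences that may differ per field and per trial type, planted lagged
coincidence assemblies at the spike (tens of ms) and rate (0.1-5 s)
timescales, an LFP with amplitude-modulated theta, pink noise, and planted
sharp-wave ripples, and a full 6-category trial schedule.

Spiking is an inhomogeneous Poisson process thinned by a von Mises phase
acceptance profile normalized to preserve the marginal rate, so field rate
and phase concentration are controlled independently.  The generator phase
convention equals the Hilbert phase of the theta LFP, so planted preferred
phases are recovered directly by the phase-extraction stage.

Everything is driven by one seeded RNG; a byte-identical bundle results from
the same config and seed.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np
from scipy.special import i0

from .io_core import (PositionTrack, SessionBundle, SpikeTrain, TrialTable,
                      default_maze_spec)
from .lfp import LFPTrace
import pandas as pd

__all__ = ["SynthConfig", "PlantedAssembly", "generate_session",
           "generate_calibration_set"]


@dataclass
class PlantedAssembly:
    members: list                # unit indices
    timescale: str               # 'spike' or 'rate'
    bin_width: float             # s; lag unit
    lags: list                   # integer bins per member, first = 0
    rate: float = 0.2            # occurrences per second of trial time
    jitter_frac: float = 0.5     # jitter, fraction of bin_width/2
    spikes_per_occurrence: int = 1


@dataclass
class SynthConfig:
    n_units: int = 10
    n_noise_units: int = 0          # high-rate non-place units (8 Hz)
    trials_per_choice: int = 10     # per choice category
    trials_per_guided: int = 5      # per guided category
    run_speed: float = 20.0         # cm/s
    intertrial_gap: float = 2.0     # s
    position_rate: float = 50.0     # Hz
    theta_freq: float = 7.0         # Hz
    theta_amp: float = 100.0        # uV
    lfp_rate: float = 2000.0        # Hz
    noise_amp: float = 30.0         # pink-noise SD, uV
    fields_per_unit: tuple = (3, 5)  # inclusive range; median 4
    field_width: float = 8.0        # cm (Gaussian SD)
    peak_rate: float = 4.0          # Hz
    baseline_rate: float = 0.05     # Hz
    phase_kappa: float = 2.0
    frac_field_shift: float = 0.0   # fraction of units with per-field mu shift
    field_shift: float = np.pi / 2  # rad
    frac_trialtype_shift: float = 0.0
    trialtype_shift: float = np.pi / 2
    assemblies: tuple = ()          # PlantedAssembly instances
    swr_rate: float = 0.1           # per second of inter-trial gap
    swr_amp: float = 250.0          # uV
    swr_freq: float = 150.0         # Hz
    swr_dur: float = 0.08           # s
    seed: int = 0


def _pink_noise(n, rng):
    white = rng.standard_normal(n)
    f = np.fft.rfftfreq(n)
    f[0] = f[1]
    spec = np.fft.rfft(white) / np.sqrt(f)
    x = np.fft.irfft(spec, n)
    return x / x.std()


def _path_points(path, dists):
    """2D points at given arc distances along a polyline."""
    pts = np.asarray(path, dtype=float)
    seg = np.diff(pts, axis=0)
    seglen = np.hypot(seg[:, 0], seg[:, 1])
    cum = np.concatenate(([0.0], np.cumsum(seglen)))
    d = np.clip(dists, 0.0, cum[-1])
    i = np.clip(np.searchsorted(cum, d, side="right") - 1, 0, len(seglen) - 1)
    frac = (d - cum[i]) / seglen[i]
    return pts[i] + seg[i] * frac[:, None], cum[-1]


def _schedule(cfg: SynthConfig, rng):
    """Interleaved trial schedule (category, t_start, t_end, path)."""
    maze = default_maze_spec()
    cats = (["choice-left", "choice-right"] * cfg.trials_per_choice)[
        : 2 * cfg.trials_per_choice]
    guided = [c for c in ("guided-LL", "guided-LR", "guided-RL", "guided-RR")
              for _ in range(cfg.trials_per_guided)]
    rng.shuffle(guided)
    order = []
    gi = 0
    for c in cats:
        order.append(c)
        if gi < len(guided):
            order.append(guided[gi])
            gi += 1
    order.extend(guided[gi:])
    trials = []
    t = cfg.intertrial_gap
    for k, cat in enumerate(order):
        _, L = _path_points(maze[cat], np.array([0.0]))
        dur = L / cfg.run_speed
        trials.append({"trial_id": k, "category": cat, "t_start": t,
                       "t_end": t + dur, "correct": True})
        t += dur + cfg.intertrial_gap
    return trials, maze, t


def generate_session(cfg: SynthConfig = None):
    """Generate one synthetic session.  Returns (SessionBundle, ground_truth).

    The ground-truth dict records the planted field geometry and phase
    preferences, per-unit shift flags, planted assemblies with their
    occurrence times, planted SWR intervals, and the trial schedule.
    """
    cfg = cfg or SynthConfig()
    rng = np.random.default_rng(cfg.seed)
    trials, maze, T = _schedule(cfg, rng)
    categories = sorted(maze)

    # --- position track -------------------------------------------------
    tp = np.arange(0.0, T, 1.0 / cfg.position_rate)
    x = np.full(tp.size, maze["choice-left"][0][0])
    y = np.full(tp.size, maze["choice-left"][0][1])
    for tr in trials:
        sel = (tp >= tr["t_start"]) & (tp < tr["t_end"])
        d = (tp[sel] - tr["t_start"]) * cfg.run_speed
        pts, _ = _path_points(maze[tr["category"]], d)
        x[sel], y[sel] = pts[:, 0], pts[:, 1]
        after = tp >= tr["t_end"]
        x[after] = pts[-1, 0] if len(pts) else x[after]
        y[after] = pts[-1, 1] if len(pts) else y[after]
    track = PositionTrack(tp, x, y)

    # --- per-unit fields and phase preferences --------------------------
    n_total = cfg.n_units + cfg.n_noise_units
    units = []
    shift_field_units = set(
        rng.choice(cfg.n_units,
                   size=int(round(cfg.frac_field_shift * cfg.n_units)),
                   replace=False)) if cfg.frac_field_shift > 0 else set()
    shift_tt_units = set(
        rng.choice(cfg.n_units,
                   size=int(round(cfg.frac_trialtype_shift * cfg.n_units)),
                   replace=False)) if cfg.frac_trialtype_shift > 0 else set()
    for u in range(cfg.n_units):
        nf = int(rng.integers(cfg.fields_per_unit[0],
                              cfg.fields_per_unit[1] + 1))
        fields = []
        mu0 = float(rng.uniform(-np.pi, np.pi))
        for fidx in range(nf):
            cat = categories[int(rng.integers(len(categories)))]
            _, L = _path_points(maze[cat], np.array([0.0]))
            dist = float(rng.uniform(0.1 * L, 0.9 * L))
            center, _ = _path_points(maze[cat], np.array([dist]))
            mu = mu0
            if u in shift_field_units and fidx % 2 == 1:
                # alternate fields by the planted shift (stacking shifts
                # would produce antipodal pairs, outside the planted design)
                mu = float(np.mod(mu0 + cfg.field_shift + np.pi,
                                  2 * np.pi) - np.pi)
            mu_tt = {}
            for c in categories:
                m = mu
                if u in shift_tt_units and c == "choice-right":
                    m = float(np.mod(mu + cfg.trialtype_shift + np.pi,
                                     2 * np.pi) - np.pi)
                mu_tt[c] = m
            fields.append({"center": center[0].tolist(), "mu": mu,
                           "mu_by_trialtype": mu_tt,
                           "width": cfg.field_width,
                           "peak_rate": cfg.peak_rate})
        units.append({"unit": u, "fields": fields, "mu0": mu0,
                      "field_shift": u in shift_field_units,
                      "trialtype_shift": u in shift_tt_units})

    # --- spike generation (thinned inhomogeneous Poisson) ---------------
    dt = 0.005
    tg = np.arange(0.0, T, dt)
    xg = np.interp(tg, tp, x)
    yg = np.interp(tg, tp, y)
    phase = np.mod(2 * np.pi * cfg.theta_freq * tg - np.pi / 2 + np.pi,
                   2 * np.pi) - np.pi
    cat_at = np.array([None] * tg.size, dtype=object)
    for tr in trials:
        cat_at[(tg >= tr["t_start"]) & (tg < tr["t_end"])] = tr["category"]
    spike_trains = {}
    kap = cfg.phase_kappa
    norm = i0(kap)
    for info in units:
        lam = np.full(tg.size, cfg.baseline_rate)
        best = np.zeros(tg.size)
        mu_t = np.full(tg.size, info["mu0"])
        for f in info["fields"]:
            d2 = (xg - f["center"][0]) ** 2 + (yg - f["center"][1]) ** 2
            contrib = f["peak_rate"] * np.exp(-d2 / (2 * f["width"] ** 2))
            lam += contrib
            upd = contrib > best
            if upd.any():
                best = np.maximum(best, contrib)
                mus = np.array([f["mu_by_trialtype"].get(c, f["mu"])
                                if c is not None else f["mu"]
                                for c in cat_at[upd]])
                mu_t[upd] = mus
        accept = np.exp(kap * np.cos(phase - mu_t)) / norm
        lam_eff = lam * accept
        counts = rng.poisson(lam_eff * dt)
        idx = np.nonzero(counts)[0]
        times = np.concatenate([
            tg[i] + rng.uniform(0, dt, counts[i]) for i in idx]) \
            if idx.size else np.zeros(0)
        spike_trains[info["unit"]] = times
    for u in range(cfg.n_units, n_total):
        n = rng.poisson(8.0 * T)
        spike_trains[u] = np.sort(rng.uniform(0, T, n))

    # --- planted assemblies ---------------------------------------------
    trial_iv = np.array([[tr["t_start"], tr["t_end"]] for tr in trials])
    trial_total = float((trial_iv[:, 1] - trial_iv[:, 0]).sum())
    gt_assemblies = []
    for pa in cfg.assemblies:
        n_occ = rng.poisson(pa.rate * trial_total)
        # occurrence times uniform over concatenated trial time
        u01 = np.sort(rng.uniform(0, trial_total, n_occ))
        occ = np.empty(n_occ)
        edges = np.concatenate(([0.0], np.cumsum(trial_iv[:, 1]
                                                 - trial_iv[:, 0])))
        ti = np.searchsorted(edges, u01, side="right") - 1
        occ = trial_iv[ti, 0] + (u01 - edges[ti])
        for m, lag in zip(pa.members, pa.lags):
            jit = rng.uniform(-0.5, 0.5, n_occ) * pa.bin_width * pa.jitter_frac
            extra = np.repeat(occ + lag * pa.bin_width + jit,
                              pa.spikes_per_occurrence)
            spike_trains[m] = np.concatenate([spike_trains[m], extra])
        gt_assemblies.append({**asdict(pa),
                              "occurrence_times": occ.tolist()})

    for u in spike_trains:
        st = np.sort(spike_trains[u])
        st = st[(st >= 0) & (st < T)]
        # enforce strictly increasing times
        while st.size > 1 and np.any(np.diff(st) <= 0):
            st[1:][np.diff(st) <= 0] += 1e-5
            st = np.sort(st)
        spike_trains[u] = st

    # --- LFP --------------------------------------------------------------
    tl = np.arange(0.0, T, 1.0 / cfg.lfp_rate)
    moving = np.interp(tl, tp, (track.speed > 5.0).astype(float))
    amp = cfg.theta_amp * (0.45 + 0.55 * moving)
    lfp_sig = amp * np.sin(2 * np.pi * cfg.theta_freq * tl)
    lfp_sig += cfg.noise_amp * _pink_noise(tl.size, rng)
    swr_truth = []
    gaps = [(0.0, trials[0]["t_start"])] + [
        (trials[k]["t_end"], trials[k + 1]["t_start"])
        for k in range(len(trials) - 1)]
    for g0, g1 in gaps:
        span = g1 - g0 - cfg.swr_dur
        if span <= 0:
            continue
        for _ in range(rng.poisson(cfg.swr_rate * (g1 - g0))):
            s = g0 + rng.uniform(0, span)
            sel = (tl >= s) & (tl < s + cfg.swr_dur)
            tt = tl[sel] - s
            env = np.exp(-0.5 * ((tt - cfg.swr_dur / 2)
                                 / (cfg.swr_dur / 4)) ** 2)
            lfp_sig[sel] += cfg.swr_amp * env * np.sin(
                2 * np.pi * cfg.swr_freq * tt)
            swr_truth.append([float(s), float(s + cfg.swr_dur)])
    lfp = LFPTrace(lfp_sig, cfg.lfp_rate)

    trains = [SpikeTrain(u, spike_trains[u], "synth") for u in
              sorted(spike_trains)]
    ttable = TrialTable(pd.DataFrame(trials)[
        ["trial_id", "category", "t_start", "t_end", "correct"]])
    ground_truth = {
        "units": units,
        "place_cell_ids": list(range(cfg.n_units)),
        "noise_unit_ids": list(range(cfg.n_units, n_total)),
        "assemblies": gt_assemblies,
        "swr_intervals": sorted(swr_truth),
        "theta_freq": cfg.theta_freq,
        "trials": trials,
    }
    bundle = SessionBundle(trains, lfp, track, ttable, session_id="synth",
                           ground_truth=ground_truth)
    return bundle, ground_truth


def generate_calibration_set(kind: str, params: dict = None, seed: int = 0):
    """Minimal seeded fixtures for calibration tests.

    Kinds: 'uniform-phases', 'von-mises', 'poisson-pairs', 'ripple-lfp',
    'precessing-unit'.
    """
    params = dict(params or {})
    rng = np.random.default_rng(seed)
    if kind == "uniform-phases":
        n = int(params.get("n", 100))
        return {"phases": rng.uniform(-np.pi, np.pi, n)}
    if kind == "von-mises":
        n = int(params.get("n", 100))
        mu = float(params.get("mu", 0.0))
        kappa = float(params.get("kappa", 1.0))
        return {"phases": np.mod(rng.vonmises(mu, kappa, n) + np.pi,
                                 2 * np.pi) - np.pi, "mu": mu, "kappa": kappa}
    if kind == "poisson-pairs":
        T = float(params.get("duration", 1000.0))
        rate = float(params.get("rate", 1.0))
        lag = params.get("lag", None)          # seconds, planted lag
        n_coinc = int(params.get("n_coincidences", 0))
        a = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
        b = np.sort(rng.uniform(0, T, rng.poisson(rate * T)))
        if n_coinc and lag is not None:
            occ = rng.uniform(0, T - abs(lag) - 1e-6, n_coinc)
            a = np.sort(np.concatenate([a, occ]))
            b = np.sort(np.concatenate([b, occ + lag]))
        return {"a": a, "b": b, "duration": T}
    if kind == "ripple-lfp":
        T = float(params.get("duration", 100.0))
        rate = float(params.get("rate", 2000.0))
        n_ripples = int(params.get("n_ripples", 1))
        amp_sd = float(params.get("amp_sd", 5.0))
        dur = float(params.get("dur", 0.1))
        t = np.arange(0.0, T, 1.0 / rate)
        x = rng.standard_normal(t.size) * 20.0
        truth = []
        for k in range(n_ripples):
            s = (k + 0.5) * T / n_ripples
            sel = (t >= s) & (t < s + dur)
            tt = t[sel] - s
            x[sel] += amp_sd * 20.0 * np.sin(2 * np.pi * 150.0 * tt)
            truth.append((s, s + dur))
        return {"lfp": LFPTrace(x, rate), "truth": truth}
    if kind == "precessing-unit":
        n = int(params.get("n", 200))
        slope = float(params.get("slope", -0.02))  # cycles per cm
        kappa = float(params.get("kappa", 4.0))
        length = float(params.get("length", 50.0))
        pos = rng.uniform(0, length, n)
        phases = np.mod(2 * np.pi * slope * pos
                        + rng.vonmises(0.0, kappa, n) + np.pi,
                        2 * np.pi) - np.pi
        return {"phases": phases, "positions": pos, "slope": slope}
    raise ValueError(f"unknown calibration kind {kind!r}")
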