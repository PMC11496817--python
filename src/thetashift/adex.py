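"""Adaptive exponential integrate-and-fire (AdEx) simulation of assembly
recruitment.

Membrane dynamics (per unit):

    C dV/dt = -g_L (V - E_L) + g_L D_T exp((V - V_T)/D_T)
              - g_e(t) (V - E_e) - g_i(t) (V - E_i) - w + eps
    tau_w dw/dt = a (V - E_L) - w

with spike emission when V reaches 0 mV, then V -> V_r and w -> w + b.
Theta-modulated conductance drive, with the inhibitory oscillation offset by
pi and the excitatory drive gated by a Gaussian retrieval envelope:

    g_i(t) = k_i (sin(2 pi f t - pi) + 1)
    g_e(t) = k_e (sin(2 pi f t) + 4) exp(-(t - c)^2 / (2 sigma^2))

An assembly assigns each member unit its own excitatory gain k_e; retrieving
the assembly therefore depolarizes members to different degrees, which sets
each member's firing phase within the theta cycle and hence the activation
order of the assembly sequence.

Integration is forward Euler-Maruyama.  The per-step current noise is
specified as a variance at the reference step of 0.05 ms and rescaled with
sqrt(dt) so that halving the step leaves the noise statistics consistent;
with the noise turned off the integrator converges (spike times move by
< 0.5 ms when the step is halved, covered by tests).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace

import numpy as np
from numba import njit

from . import assemblies as asm
from .circstats import wrap_angles

__all__ = [
    "AdExParams",
    "DriveConfig",
    "SimResult",
    "AssemblyExperimentReport",
    "conductance_drive",
    "simulate_unit",
    "simulate_assembly_retrievals",
    "spike_phase_wrt_drive",
    "run_assembly_experiment",
    "ADEX_BIN_SIZES",
    "ADEX_MAX_LAGS",
]

#: detector settings for the assembly-recruitment experiment (spike window,
#: wide lag ranges so multi-bin theta offsets remain in reach)
ADEX_BIN_SIZES = [0.0058, 0.007, 0.009, 0.011, 0.014, 0.018, 0.022, 0.028,
                  0.035, 0.044, 0.055]
ADEX_MAX_LAGS = [18, 21, 22, 22, 22, 20, 18, 17, 15, 13, 11]

#: reference integration step (s) at which the noise variance is defined
DT_REF = 5e-5


@dataclass
class AdExParams:
    """AdEx cell parameters (SI units).

    The default set is calibrated for the assembly-recruitment regime: a cell
    whose resting state sits close enough to threshold that the weakest
    assembly gain (k_e = 0.7 nS) drives firing near the retrieval envelope
    peak, while stronger gains recruit the cell progressively earlier in the
    theta cycle.
    """
    C: float = 0.8e-9           # membrane capacitance, F (slow integration)
    g_L: float = 5e-9           # leak conductance, S
    E_L: float = -54e-3         # resting potential, V (near threshold)
    delta_T: float = 2e-3       # threshold slope factor, V
    V_T: float = -50e-3         # threshold potential, V
    tau_w: float = 1.0          # adaptation time constant, s
    a: float = 0.0              # subthreshold adaptation, S
    b: float = 1.2e-9           # spike-triggered adaptation increment, A
    V_r: float = -62e-3         # reset potential, V
    V_s: float = 20e-3          # spike display value, V
    E_e: float = 0.0            # excitatory reversal, V
    E_i: float = -60e-3         # inhibitory reversal, V
    noise_var: float = 1.6e-19  # per-step current noise variance at DT_REF, A^2

    def validate(self):
        if min(self.C, self.g_L, self.tau_w) <= 0:
            raise ValueError("C, g_L and tau_w must be positive")
        if not (self.E_i < self.E_L < self.V_T < 0):
            raise ValueError("require E_i < E_L < V_T < 0 V")


@dataclass
class DriveConfig:
    theta_freq: float = 7.0     # Hz
    k_i: float = 17e-9          # inhibitory gain, S (all units, all assemblies)
    c: float = 2.5              # retrieval envelope center, s
    sigma: float = 0.4          # retrieval envelope SD, s
    phase_offset: float = math.pi  # g_i offset relative to g_e (fixed)

    def validate(self):
        if abs(self.phase_offset - math.pi) > 1e-12:
            raise ValueError("the g_e/g_i phase offset is fixed at pi rad")


@dataclass
class SimResult:
    spikes: np.ndarray
    t: np.ndarray = None
    V: np.ndarray = None
    w: np.ndarray = None
    g_e: np.ndarray = None
    g_i: np.ndarray = None
    seed: int = None


def conductance_drive(t, k_e: float, cfg: DriveConfig = None):
    """Evaluate (g_e, g_i) in siemens at times ``t`` for one unit."""
    cfg = cfg or DriveConfig()
    cfg.validate()
    t = np.asarray(t, dtype=float)
    s = np.sin(2.0 * np.pi * cfg.theta_freq * t)
    g_i = cfg.k_i * (np.sin(2.0 * np.pi * cfg.theta_freq * t - cfg.phase_offset)
                     + 1.0)
    g_e = k_e * (s + 4.0) * np.exp(-((t - cfg.c) ** 2) / (2.0 * cfg.sigma ** 2))
    return g_e, g_i


@njit(cache=True, fastmath=True)
def _integrate_batch(ke, duration, dt, C, gL, EL, DT, VT, tauw, a, b, Vr,
                     Ee, Ei, ki, theta, c, sigma, noise_step_sd, seed,
                     record, max_spikes, t_lo, t_hi):
    """Euler-Maruyama integration of independent AdEx lanes sharing the theta
    drive; lane i has excitatory gain ke[i].  Returns spike times per lane and
    (optionally) the full V and w traces.  Integration may be restricted to
    [t_lo, t_hi) when the excitatory envelope is negligible outside."""
    np.random.seed(seed)
    n = ke.size
    nsteps = int(round(duration / dt))
    k_lo = max(int(t_lo / dt), 0)
    k_hi = min(int(t_hi / dt), nsteps) if t_hi > 0.0 else nsteps
    V = np.full(n, EL)
    w = np.zeros(n)
    spikes = np.full((n, max_spikes), np.nan)
    cnt = np.zeros(n, dtype=np.int64)
    if record:
        Vtr = np.full((n, nsteps), EL)
        wtr = np.zeros((n, nsteps))
    else:
        Vtr = np.empty((1, 1))
        wtr = np.empty((1, 1))
    two_pi_f = 2.0 * math.pi * theta
    inv2s2 = 1.0 / (2.0 * sigma * sigma)
    for k in range(k_lo, k_hi):
        t = k * dt
        s = math.sin(two_pi_f * t)
        env = math.exp(-(t - c) * (t - c) * inv2s2)
        gi = ki * (1.0 - s)
        gfac = (s + 4.0) * env
        for i in range(n):
            ge = ke[i] * gfac
            arg = (V[i] - VT) / DT
            if arg > 30.0:
                arg = 30.0
            I = (-gL * (V[i] - EL) + gL * DT * math.exp(arg)
                 - ge * (V[i] - Ee) - gi * (V[i] - Ei) - w[i])
            if noise_step_sd > 0.0:
                I += noise_step_sd * np.random.standard_normal() / math.sqrt(dt)
            dV = I * dt / C
            dw = (a * (V[i] - EL) - w[i]) * dt / tauw
            V[i] += dV
            w[i] += dw
            if V[i] >= 0.0:
                if cnt[i] < max_spikes:
                    spikes[i, cnt[i]] = t
                cnt[i] += 1
                V[i] = Vr
                w[i] += b
            if record:
                Vtr[i, k] = V[i]
                wtr[i, k] = w[i]
    return spikes, cnt, Vtr, wtr


def _noise_step_sd(params: AdExParams, dt: float) -> float:
    # per-step current SD such that the variance matches noise_var at DT_REF;
    # expressed as a diffusion, so the kernel multiplies by sqrt(dt) again
    return math.sqrt(params.noise_var * DT_REF)


def simulate_unit(params: AdExParams, k_e: float, cfg: DriveConfig = None,
                  duration: float = 5.0, dt: float = DT_REF, seed: int = 0,
                  record: bool = True, noise: bool = True) -> SimResult:
    """Simulate a single unit under the theta + retrieval-envelope drive."""
    params.validate()
    cfg = cfg or DriveConfig()
    cfg.validate()
    if dt > 1e-4 + 1e-12:
        raise ValueError("dt must be <= 0.1 ms")
    sd = _noise_step_sd(params, dt) if noise else 0.0
    spikes, cnt, Vtr, wtr = _integrate_batch(
        np.array([k_e], dtype=float), duration, dt, params.C, params.g_L,
        params.E_L, params.delta_T, params.V_T, params.tau_w, params.a,
        params.b, params.V_r, params.E_e, params.E_i, cfg.k_i,
        cfg.theta_freq, cfg.c, cfg.sigma, sd, int(seed) % (2 ** 31),
        record, 100_000, 0.0, duration)
    if not np.all(np.isfinite(Vtr)) and record:
        raise FloatingPointError("membrane potential diverged")
    st = spikes[0, : min(cnt[0], 100_000)]
    t = np.arange(int(round(duration / dt))) * dt
    g_e, g_i = conductance_drive(t, k_e, cfg)
    return SimResult(st, t=t if record else None,
                     V=Vtr[0] if record else None,
                     w=wtr[0] if record else None,
                     g_e=g_e if record else None,
                     g_i=g_i if record else None, seed=seed)


def simulate_assembly_retrievals(params: AdExParams, k_e_per_unit,
                                 cfg: DriveConfig = None,
                                 n_retrievals: int = 400,
                                 retrieval_len: float = 5.0,
                                 dt: float = DT_REF, seed: int = 0,
                                 max_spikes_per_lane: int = 3000,
                                 support_sd: float = None) -> dict:
    """Concatenated retrievals of one assembly.

    Every retrieval is an independent ``retrieval_len`` s episode (the theta
    drive is cycle-continuous across the concatenation since
    retrieval_len * theta_freq is an integer).  ``support_sd`` restricts
    integration to c +/- support_sd * sigma, where the excitatory envelope is
    non-negligible; spiking outside that range is impossible by construction
    (g_e < 1e-4 of peak at 4.3 SD).  Returns
    {unit_index: spike-time array on the concatenated time axis}.
    """
    params.validate()
    cfg = cfg or DriveConfig()
    cfg.validate()
    ke = np.asarray(k_e_per_unit, dtype=float)
    n_units = ke.size
    lanes = np.repeat(ke, n_retrievals)
    sd = _noise_step_sd(params, dt)
    if support_sd is None:
        t_lo, t_hi = 0.0, retrieval_len
    else:
        t_lo = max(cfg.c - support_sd * cfg.sigma, 0.0)
        t_hi = min(cfg.c + support_sd * cfg.sigma, retrieval_len)
    spikes, cnt, _, _ = _integrate_batch(
        lanes, retrieval_len, dt, params.C, params.g_L, params.E_L,
        params.delta_T, params.V_T, params.tau_w, params.a, params.b,
        params.V_r, params.E_e, params.E_i, cfg.k_i, cfg.theta_freq,
        cfg.c, cfg.sigma, sd, int(seed) % (2 ** 31), False,
        max_spikes_per_lane, t_lo, t_hi)
    trains = {}
    for u in range(n_units):
        parts = []
        for r in range(n_retrievals):
            lane = u * n_retrievals + r
            st = spikes[lane, : min(cnt[lane], max_spikes_per_lane)]
            parts.append(st + r * retrieval_len)
        trains[u] = np.concatenate(parts) if parts else np.zeros(0)
    return trains


def spike_phase_wrt_drive(spike_times, cfg: DriveConfig = None) -> np.ndarray:
    """Phase of each spike relative to the sin(2 pi f t) modulation of g_e,
    in [-pi, pi).  Drive maxima sit at +pi/2."""
    cfg = cfg or DriveConfig()
    t = np.asarray(spike_times, dtype=float)
    return wrap_angles(2.0 * np.pi * cfg.theta_freq * t)


@dataclass
class AssemblyExperimentReport:
    order_recovery_fraction: float
    mean_lag_second: float
    mean_lag_third: float
    se_lag_second: float
    se_lag_third: float
    per_sim: list = field(default_factory=list)
    phase_samples: dict = field(default_factory=dict)
    n_sims: int = 0

    def summary(self) -> dict:
        return {
            "order_recovery_fraction": self.order_recovery_fraction,
            "mean_lag_second_s": self.mean_lag_second,
            "mean_lag_third_s": self.mean_lag_third,
            "se_lag_second_s": self.se_lag_second,
            "se_lag_third_s": self.se_lag_third,
            "n_sims": self.n_sims,
        }


def run_assembly_experiment(params: AdExParams = None,
                            cfg: DriveConfig = None,
                            k_e_assemblies=((2.7e-9, 1.7e-9, 0.7e-9),
                                            (1.0e-9, 2.0e-9, 3.0e-9)),
                            n_retrievals: int = 400,
                            n_sims: int = 100,
                            bin_sizes=None, max_lags=None,
                            reference_lag: int = 2, alpha: float = 0.05,
                            retrieval_len: float = 5.0, dt: float = 1e-4,
                            seed: int = 0, support_sd: float = 4.3,
                            collect_phases: bool = False) -> AssemblyExperimentReport:
    """Assembly-recruitment experiment: simulate both assemblies, detect the
    fine-timescale activation pattern per assembly, and score whether the
    detected order matches the descending-k_e ranking.

    A simulation counts as an order recovery only if *both* assemblies yield a
    3-unit pattern whose member order (by lag) matches that assembly's
    descending excitatory gains; missing patterns count as non-recoveries.
    Lags of the 2nd and 3rd active units are pooled across assemblies and
    simulations.
    """
    params = params or AdExParams()
    cfg = cfg or DriveConfig()
    if bin_sizes is None:
        bin_sizes, max_lags = ADEX_BIN_SIZES, ADEX_MAX_LAGS
    n_units = len(k_e_assemblies[0])
    lag2, lag3 = [], []
    per_sim = []
    phases = {}
    n_recovered = 0
    total_time = n_retrievals * retrieval_len
    for s in range(n_sims):
        sim_ok = True
        rec = {"sim": s, "assemblies": []}
        for a_idx, ke in enumerate(k_e_assemblies):
            trains = simulate_assembly_retrievals(
                params, ke, cfg, n_retrievals, retrieval_len, dt,
                seed=(seed * 7919 + s * 131 + a_idx) % (2 ** 31),
                support_sd=support_sd)
            aset = asm.multiresolution_scan(
                trains, bin_sizes, max_lags, reference_lag, alpha,
                t0=0.0, t_end=total_time)
            aset = asm.prune_best_resolution(aset)
            full = [p for p in aset.patterns if len(p.members) == n_units]
            if collect_phases:
                for u, st in trains.items():
                    phases[(a_idx, u)] = spike_phase_wrt_drive(st, cfg)
            if not full:
                sim_ok = False
                rec["assemblies"].append(None)
                continue
            pat = min(full, key=lambda p: p.p_value)
            expected = list(np.argsort(-np.asarray(ke), kind="stable"))
            ok = list(pat.members) == expected
            sim_ok = sim_ok and ok
            secs = pat.lag_seconds
            lag2.append(secs[1])
            lag3.append(secs[2])
            rec["assemblies"].append({
                "members": list(pat.members), "lags_bins": list(pat.lags),
                "bin_width": pat.bin_width, "p": pat.p_value,
                "order_ok": bool(ok)})
        n_recovered += sim_ok
        rec["recovered"] = bool(sim_ok)
        per_sim.append(rec)
    lag2 = np.asarray(lag2)
    lag3 = np.asarray(lag3)

    def _se(x):
        return float(x.std(ddof=1) / math.sqrt(x.size)) if x.size > 1 else np.nan

    return AssemblyExperimentReport(
        order_recovery_fraction=n_recovered / float(n_sims),
        mean_lag_second=float(lag2.mean()) if lag2.size else np.nan,
        mean_lag_third=float(lag3.mean()) if lag3.size else np.nan,
        se_lag_second=_se(lag2), se_lag_third=_se(lag3),
        per_sim=per_sim, phase_samples=phases, n_sims=n_sims)
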