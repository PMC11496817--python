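"""LFP processing: theta-band phase extraction, high-theta-power epochs,
movement-artifact rejection, and sharp-wave-ripple (SWR) detection.

Spike phases are the angle of the analytic (Hilbert) signal of the 4-10 Hz
band-passed LFP interpolated at spike times.  Filters are zero-phase
least-squares FIR designs (symmetric taps applied with delay compensation),
with order chosen for >= 40 dB stopband rejection one octave outside the
band.  The SWR detector down-samples to 1 kHz, notch-filters mains, band
passes 120-220 Hz, z-scores the analytic envelope, and applies the
3.5 SD / 2 SD candidate/boundary thresholds with 50 ms gap merging and
50-500 ms duration limits.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy import signal

__all__ = [
    "LFPTrace",
    "ThetaPhaseSeries",
    "EpochSet",
    "theta_filter",
    "theta_phase_series",
    "spike_phases",
    "high_theta_epochs",
    "detect_swr",
    "mask_spikes",
]


@dataclass
class LFPTrace:
    samples: np.ndarray         # microvolts
    rate: float                 # Hz
    channel_id: str = "lfp0"
    t0: float = 0.0

    def __post_init__(self):
        self.samples = np.asarray(self.samples, dtype=float)
        if self.rate <= 0:
            raise ValueError("sampling rate must be positive")
        if not np.all(np.isfinite(self.samples)):
            raise ValueError("LFP samples must be finite")

    @property
    def t(self) -> np.ndarray:
        return self.t0 + np.arange(self.samples.size) / self.rate

    @property
    def duration(self) -> float:
        return self.samples.size / self.rate


@dataclass
class ThetaPhaseSeries:
    t: np.ndarray
    phase: np.ndarray           # radians in [-pi, pi)
    envelope: np.ndarray        # analytic amplitude, microvolts
    filtered: np.ndarray = None
    rate: float = None


@dataclass
class EpochSet:
    intervals: np.ndarray       # (n, 2) seconds, sorted, non-overlapping
    label: str = ""

    def __post_init__(self):
        iv = np.asarray(self.intervals, dtype=float).reshape(-1, 2)
        if iv.size and (np.any(iv[:, 1] <= iv[:, 0])
                        or np.any(np.diff(iv[:, 0]) < 0)):
            raise ValueError("intervals must be sorted with t_end > t_start")
        self.intervals = iv

    def __len__(self):
        return self.intervals.shape[0]

    def contains(self, t) -> np.ndarray:
        """Boolean mask: which times fall inside any interval."""
        t = np.asarray(t, dtype=float)
        if not len(self):
            return np.zeros(t.shape, dtype=bool)
        starts = self.intervals[:, 0]
        ends = self.intervals[:, 1]
        idx = np.searchsorted(starts, t, side="right") - 1
        ok = idx >= 0
        out = np.zeros(t.shape, dtype=bool)
        out[ok] = t[ok] < ends[idx[ok]]
        return out

    def total_duration(self) -> float:
        return float(np.diff(self.intervals, axis=1).sum()) if len(self) else 0.0

    def to_bed(self, path):
        """Write as 3-column interval text (label, start s, end s)."""
        with open(path, "w") as fh:
            for a, b in self.intervals:
                fh.write(f"{self.label}\t{a:.6f}\t{b:.6f}\n")


def _fir_bandpass(lo: float, hi: float, rate: float, attenuation_db: float = 40.0):
    """Least-squares linear-phase FIR band-pass with one-octave transitions."""
    nyq = rate / 2.0
    width = min(lo / 2.0, (nyq - hi) / 2.0)
    numtaps = int(3.3 * rate / width * attenuation_db / 40.0)
    numtaps |= 1  # odd length -> integer group delay, type-I linear phase
    bands = [0.0, lo - width, lo, hi, hi + width, nyq]
    desired = [0.0, 0.0, 1.0, 1.0, 0.0, 0.0]
    return signal.firls(numtaps, bands, desired, fs=rate)


def _zero_phase(x: np.ndarray, taps: np.ndarray) -> np.ndarray:
    """Apply a symmetric FIR with group-delay compensation (zero phase)."""
    pad = (taps.size - 1) // 2
    xp = np.pad(x, pad, mode="reflect")
    y = signal.oaconvolve(xp, taps, mode="same")
    return y[pad:pad + x.size]


def theta_filter(lfp: LFPTrace, band=(4.0, 10.0)) -> LFPTrace:
    """Zero-phase band-pass of the LFP in the theta band; length preserved."""
    lo, hi = band
    if not (0.0 < lo < hi < lfp.rate / 2.0):
        raise ValueError(f"band {band} outside (0, Nyquist={lfp.rate / 2}) Hz")
    taps = _fir_bandpass(lo, hi, lfp.rate)
    return LFPTrace(_zero_phase(lfp.samples, taps), lfp.rate,
                    channel_id=lfp.channel_id, t0=lfp.t0)


def theta_phase_series(lfp: LFPTrace, band=(4.0, 10.0)) -> ThetaPhaseSeries:
    """Instantaneous theta phase and envelope from the analytic signal."""
    filt = theta_filter(lfp, band)
    analytic = signal.hilbert(filt.samples)
    return ThetaPhaseSeries(t=lfp.t, phase=np.angle(analytic),
                            envelope=np.abs(analytic),
                            filtered=filt.samples, rate=lfp.rate)


def spike_phases(theta: ThetaPhaseSeries, spike_times) -> np.ndarray:
    """Theta phase at each spike time, in [-pi, pi).

    Interpolates the unwrapped phase; spikes outside the LFP time support are
    dropped (count reported via warning).
    """
    st = np.asarray(spike_times, dtype=float)
    inside = (st >= theta.t[0]) & (st <= theta.t[-1])
    n_out = int((~inside).sum())
    if n_out:
        warnings.warn(f"{n_out} spikes outside the LFP support were dropped")
    unwrapped = np.unwrap(theta.phase)
    ph = np.interp(st[inside], theta.t, unwrapped)
    return np.mod(ph + np.pi, 2.0 * np.pi) - np.pi


def _intervals_from_mask(mask: np.ndarray, t: np.ndarray) -> np.ndarray:
    """Convert a boolean sample mask into half-open time intervals."""
    if not mask.any():
        return np.zeros((0, 2))
    d = np.diff(mask.astype(np.int8))
    starts = np.nonzero(d == 1)[0] + 1
    ends = np.nonzero(d == -1)[0] + 1
    if mask[0]:
        starts = np.concatenate(([0], starts))
    if mask[-1]:
        ends = np.concatenate((ends, [mask.size]))
    dt = t[1] - t[0]
    return np.column_stack([t[starts], t[ends - 1] + dt])


def high_theta_epochs(theta: ThetaPhaseSeries,
                      artifact_pad: float = 0.25) -> tuple:
    """High-theta-power epochs with movement-artifact rejection.

    Two passes: (1) sigma_0 is the SD of the full filtered trace; samples with
    |LFP_theta| > 2 sigma_0 (padded by ``artifact_pad`` s) are artifacts;
    (2) sigma is recomputed on the artifact-free remainder and high-theta
    epochs are where the envelope exceeds 1 sigma.  Returns
    (high_theta: EpochSet, artifacts: EpochSet).
    """
    x = theta.filtered
    t = theta.t
    rate = theta.rate
    sigma0 = x.std()
    art = np.abs(x) > 2.0 * sigma0
    if art.any():
        pad = int(round(artifact_pad * rate))
        kernel = np.ones(2 * pad + 1, dtype=bool)
        art = np.convolve(art, kernel, mode="same") > 0
    clean = ~art
    if not clean.any():
        warnings.warn("entire trace flagged as artifact; no high-theta epochs")
        return (EpochSet(np.zeros((0, 2)), "high-theta"),
                EpochSet(_intervals_from_mask(art, t), "artifact"))
    sigma = x[clean].std()
    high = (theta.envelope > sigma) & clean
    return (EpochSet(_intervals_from_mask(high, t), "high-theta"),
            EpochSet(_intervals_from_mask(art, t), "artifact"))


def detect_swr(lfp: LFPTrace, band=(120.0, 220.0), detect_sd: float = 3.5,
               boundary_sd: float = 2.0, min_dur: float = 0.05,
               max_dur: float = 0.5, merge_gap: float = 0.05,
               notch: float = 50.0) -> EpochSet:
    """Sharp-wave-ripple detection on a single LFP channel.

    Down-samples to 1 kHz, notch-filters, band-passes 120-220 Hz, z-scores the
    analytic envelope, takes candidate events at ``detect_sd`` crossings with
    boundaries at ``boundary_sd``, merges events separated by gaps shorter
    than ``merge_gap`` and rejects events shorter than ``min_dur`` or longer
    than ``max_dur``.
    """
    if lfp.rate < 1000.0:
        raise ValueError("SWR detection needs at least 1 kHz sampling")
    target = 1000.0
    q = int(round(lfp.rate / target))
    x = signal.decimate(lfp.samples, q, ftype="fir", zero_phase=True) \
        if q > 1 else lfp.samples.astype(float)
    rate = lfp.rate / q
    if x.size < int(rate):
        raise ValueError("trace shorter than the filter settle time")
    b_notch, a_notch = signal.iirnotch(notch, Q=30.0, fs=rate)
    x = signal.filtfilt(b_notch, a_notch, x)
    taps = _fir_bandpass(band[0], band[1], rate)
    xf = _zero_phase(x, taps)
    env = np.abs(signal.hilbert(xf))
    z = (env - env.mean()) / env.std()
    t = lfp.t0 + np.arange(x.size) / rate

    above_lo = z > boundary_sd
    # boundary-level segments that contain at least one detect-level crossing
    iv = _intervals_from_mask(above_lo, t)
    events = []
    for a, bnd in iv:
        i0 = int((a - lfp.t0) * rate)
        i1 = max(int((bnd - lfp.t0) * rate), i0 + 1)
        if np.any(z[i0:i1] > detect_sd):
            events.append([a, bnd])
    # reject sub-threshold-duration candidates, then merge short gaps
    events = [ev for ev in events if ev[1] - ev[0] >= min_dur]
    merged = []
    for ev in events:
        if merged and ev[0] - merged[-1][1] < merge_gap:
            merged[-1][1] = ev[1]
        else:
            merged.append(ev)
    keep = [ev for ev in merged if ev[1] - ev[0] <= max_dur]
    return EpochSet(np.asarray(keep).reshape(-1, 2), "swr")


def mask_spikes(spike_times, exclude: EpochSet) -> np.ndarray:
    """Boolean mask of spikes to KEEP (those outside the excluded epochs)."""
    return ~exclude.contains(np.asarray(spike_times, dtype=float))
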