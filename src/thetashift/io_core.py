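"""Session data model, readers/writers, place-cell selection, position
linearization, and trial categorization.

A recording session bundles sorted spike trains, a continuous LFP channel,
the animal's position track on an end-to-end T-maze (170 x 130 cm), and a
trial table with six categories: two free-choice runs (G -> C, the animal
picks the turn at the open T-junction) and four guided runs (C -> G, both
turns forced by doors), labeled by their entry/exit turn directions.

Time is seconds (float64) from session start; all intervals are half-open
[t0, t1).  Speed is estimated by central differences on positions smoothed
with a 0.25 s boxcar, which removes tracker jitter without lagging turns.
"""

from __future__ import annotations

import json
import logging
import os
from dataclasses import dataclass, field

import h5py
import numpy as np
import pandas as pd
from shapely.geometry import LineString, Point

from . import placefields
from .lfp import LFPTrace

logger = logging.getLogger(__name__)

__all__ = [
    "TRIAL_CATEGORIES",
    "SpikeTrain",
    "PositionTrack",
    "TrialTable",
    "SessionBundle",
    "default_maze_spec",
    "save_session",
    "load_session",
    "select_place_cells",
    "linearize_position",
    "categorize_trials",
]

TRIAL_CATEGORIES = ("choice-left", "choice-right",
                    "guided-LL", "guided-LR", "guided-RL", "guided-RR")

#: projection tolerance for on-path position samples, cm
OFF_PATH_TOL = 5.0


@dataclass
class SpikeTrain:
    unit_id: object
    times: np.ndarray           # seconds, strictly increasing
    session_id: str = ""

    def __post_init__(self):
        self.times = np.asarray(self.times, dtype=float)
        if self.times.size and np.any(np.diff(self.times) <= 0):
            raise ValueError(
                f"unit {self.unit_id}: spike times must be strictly increasing")

    @property
    def n(self) -> int:
        return int(self.times.size)


def _boxcar_smooth(x: np.ndarray, width: int) -> np.ndarray:
    if width <= 1:
        return x.astype(float)
    kernel = np.ones(width) / width
    pad = width // 2
    xp = np.pad(x.astype(float), pad, mode="edge")
    return np.convolve(xp, kernel, mode="same")[pad:pad + x.size]


@dataclass
class PositionTrack:
    t: np.ndarray
    x: np.ndarray               # cm
    y: np.ndarray               # cm
    speed: np.ndarray = None    # cm/s, derived if not given
    linpos: np.ndarray = None   # cm along trial-specific path; NaN off-path

    def __post_init__(self):
        self.t = np.asarray(self.t, dtype=float)
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        if np.any(np.diff(self.t) <= 0):
            raise ValueError("position timestamps must be strictly increasing")
        if self.speed is None:
            dt = np.median(np.diff(self.t))
            w = max(int(round(0.25 / dt)), 1)
            xs = _boxcar_smooth(self.x, w)
            ys = _boxcar_smooth(self.y, w)
            vx = np.gradient(xs, self.t)
            vy = np.gradient(ys, self.t)
            self.speed = np.hypot(vx, vy)
        else:
            self.speed = np.asarray(self.speed, dtype=float)
        if np.any(self.speed < 0):
            raise ValueError("speed must be non-negative")


@dataclass
class TrialTable:
    df: pd.DataFrame            # trial_id, category, t_start, t_end, correct

    def __post_init__(self):
        req = {"trial_id", "category", "t_start", "t_end", "correct"}
        missing = req - set(self.df.columns)
        if missing:
            raise ValueError(f"trial table missing columns {sorted(missing)}")
        bad = ~self.df["category"].isin(TRIAL_CATEGORIES)
        if bad.any():
            raise ValueError(
                f"unknown trial categories: {self.df.loc[bad, 'category'].unique()}")
        d = self.df.sort_values("t_start")
        if (d["t_end"].values[:-1] > d["t_start"].values[1:]).any():
            raise ValueError("trial intervals overlap")

    def __len__(self):
        return len(self.df)

    def intervals(self, categories=None) -> np.ndarray:
        d = self.df
        if categories is not None:
            d = d[d["category"].isin(categories)]
        return d[["t_start", "t_end"]].to_numpy(dtype=float)

    def total_duration(self) -> float:
        iv = self.intervals()
        return float((iv[:, 1] - iv[:, 0]).sum())


@dataclass
class SessionBundle:
    spike_trains: list
    lfp: LFPTrace
    track: PositionTrack
    trials: TrialTable
    session_id: str = "session0"
    ground_truth: dict = None

    def __post_init__(self):
        self.validate()

    def validate(self):
        t_lo, t_hi = self.time_bounds()
        for st in self.spike_trains:
            if st.n and (st.times[0] < t_lo - 1e-9 or st.times[-1] > t_hi + 1e-9):
                raise ValueError(
                    f"unit {st.unit_id}: spikes outside the session time base")
        iv = self.trials.intervals()
        if iv.size and (iv.min() < t_lo - 1e-9 or iv.max() > t_hi + 1e-9):
            raise ValueError("trials outside the session time base")

    def time_bounds(self):
        lo = min(self.track.t[0], self.lfp.t0)
        hi = max(self.track.t[-1], self.lfp.t0 + self.lfp.duration)
        return float(lo), float(hi)

    def unit_ids(self):
        return [st.unit_id for st in self.spike_trains]

    def train(self, unit_id) -> SpikeTrain:
        for st in self.spike_trains:
            if st.unit_id == unit_id:
                return st
        raise KeyError(unit_id)

    def spikes_dict(self) -> dict:
        return {st.unit_id: st.times for st in self.spike_trains}


# ---------------------------------------------------------------------------
# Maze geometry and linearization
# ---------------------------------------------------------------------------

def default_maze_spec() -> dict:
    """Ordered 2D segment chains (cm) per trial category on the 170 x 130 cm
    end-to-end T-maze.  Choice runs go G -> C, guided runs C -> G; guided-XY
    encodes the forced entry turn X and exit turn Y."""
    G1, G2 = (35.0, 10.0), (35.0, 120.0)
    C1, C2 = (135.0, 10.0), (135.0, 120.0)
    jG, jC = (35.0, 65.0), (135.0, 65.0)
    return {
        "choice-left": [G1, jG, jC, C2],
        "choice-right": [G2, jG, jC, C1],
        "guided-LL": [C1, jC, jG, G1],
        "guided-LR": [C1, jC, jG, G2],
        "guided-RL": [C2, jC, jG, G1],
        "guided-RR": [C2, jC, jG, G2],
    }


def linearize_position(track: PositionTrack, maze_spec: dict, category: str,
                       t_start: float = None, t_end: float = None,
                       tol: float = OFF_PATH_TOL) -> np.ndarray:
    """Distance along the category's path (cm) for each track sample in
    [t_start, t_end); NaN for samples farther than ``tol`` from the path or
    outside the window."""
    if category not in maze_spec:
        raise KeyError(f"trial category {category!r} absent from maze spec")
    path = LineString(maze_spec[category])
    out = np.full(track.t.size, np.nan)
    sel = np.ones(track.t.size, dtype=bool)
    if t_start is not None:
        sel &= track.t >= t_start
    if t_end is not None:
        sel &= track.t < t_end
    for i in np.nonzero(sel)[0]:
        p = Point(track.x[i], track.y[i])
        if path.distance(p) <= tol:
            out[i] = path.project(p)
    return out


def linearize_spikes(spike_times, track: PositionTrack, maze_spec: dict,
                     trials: TrialTable, tol: float = OFF_PATH_TOL):
    """Linearized position of each spike along its own trial's path.

    Returns (linpos, category) arrays; NaN / None for spikes outside trials
    or off-path.
    """
    st = np.asarray(spike_times, dtype=float)
    lin = np.full(st.size, np.nan)
    cat = np.array([None] * st.size, dtype=object)
    sx = np.interp(st, track.t, track.x)
    sy = np.interp(st, track.t, track.y)
    paths = {c: LineString(maze_spec[c]) for c in maze_spec}
    for _, row in trials.df.iterrows():
        path = paths.get(row["category"])
        if path is None:
            raise KeyError(f"trial category {row['category']!r} absent from maze spec")
        inside = (st >= row["t_start"]) & (st < row["t_end"])
        for i in np.nonzero(inside)[0]:
            p = Point(sx[i], sy[i])
            if path.distance(p) <= tol:
                lin[i] = path.project(p)
                cat[i] = row["category"]
    return lin, cat


# ---------------------------------------------------------------------------
# Trial categorization
# ---------------------------------------------------------------------------

def categorize_trials(raw_events: pd.DataFrame) -> TrialTable:
    """Build the 6-category trial table from a door/turn event log.

    ``raw_events`` columns: trial_id, t_start, t_end, kind ('choice' or
    'guided'), entry_turn, exit_turn ('L'/'R').  Choice trials are labeled by
    the exit (chosen) turn and marked correct when the exit turn matches the
    entry turn; guided trials are labeled guided-<entry><exit>.  Trials with
    incomplete events are excluded with a log entry.
    """
    rows = []
    for _, ev in raw_events.iterrows():
        ok = (pd.notna(ev.get("t_start")) and pd.notna(ev.get("t_end"))
              and ev.get("kind") in ("choice", "guided")
              and ev.get("entry_turn") in ("L", "R")
              and ev.get("exit_turn") in ("L", "R"))
        if not ok:
            logger.warning("trial %s uncategorizable, excluded",
                           ev.get("trial_id"))
            continue
        if ev["kind"] == "choice":
            category = ("choice-left" if ev["exit_turn"] == "L"
                        else "choice-right")
            correct = ev["exit_turn"] == ev["entry_turn"]
        else:
            category = f"guided-{ev['entry_turn']}{ev['exit_turn']}"
            correct = True
        rows.append({"trial_id": ev["trial_id"], "category": category,
                     "t_start": float(ev["t_start"]),
                     "t_end": float(ev["t_end"]), "correct": bool(correct)})
    return TrialTable(pd.DataFrame(
        rows, columns=["trial_id", "category", "t_start", "t_end", "correct"]))


# ---------------------------------------------------------------------------
# Place-cell selection
# ---------------------------------------------------------------------------

def select_place_cells(bundle: SessionBundle, rate_lo: float = 0.2,
                       rate_hi: float = 4.0, si_min: float = 0.5,
                       speed_min: float = 12.0) -> list:
    """Units with on-maze mean rate in [rate_lo, rate_hi] Hz and spatial
    information above ``si_min`` bits/s.  On-maze = within any trial
    interval.  Empty sessions yield an empty list."""
    iv = bundle.trials.intervals()
    total = bundle.trials.total_duration()
    if total <= 0:
        return []
    keep = []
    for st in bundle.spike_trains:
        n_on = sum(int(((st.times >= a) & (st.times < b)).sum())
                   for a, b in iv)
        rate = n_on / total
        if not (rate_lo <= rate <= rate_hi):
            continue
        try:
            rmap = placefields.rate_map(st.times, bundle.track,
                                        speed_min=speed_min)
        except ValueError:
            continue
        if placefields.spatial_information(rmap) > si_min:
            keep.append(st.unit_id)
    return keep


# ---------------------------------------------------------------------------
# Serialization: HDF5 bundle and CSV/TSV directory dialect
# ---------------------------------------------------------------------------

def save_session(bundle: SessionBundle, path: str, fmt: str = "hdf5"):
    """Write a session bundle; ``fmt`` is 'hdf5' or 'csv' (a directory)."""
    if fmt == "hdf5":
        with h5py.File(path, "w") as f:
            f.attrs["session_id"] = bundle.session_id
            g = f.create_group("spikes")
            for st in bundle.spike_trains:
                d = g.create_dataset(str(st.unit_id), data=st.times)
                d.attrs["unit_id"] = str(st.unit_id)
            gl = f.create_group("lfp")
            gl.create_dataset("samples", data=bundle.lfp.samples)
            gl.attrs["rate"] = bundle.lfp.rate
            gl.attrs["channel_id"] = bundle.lfp.channel_id
            gl.attrs["t0"] = bundle.lfp.t0
            gp = f.create_group("position")
            for name in ("t", "x", "y", "speed"):
                gp.create_dataset(name, data=getattr(bundle.track, name))
            f.create_dataset(
                "trials",
                data=bundle.trials.df.to_csv(index=False).encode())
            if bundle.ground_truth is not None:
                f.attrs["ground_truth"] = json.dumps(bundle.ground_truth)
    elif fmt == "csv":
        os.makedirs(path, exist_ok=True)
        rows = [{"unit_id": st.unit_id, "time": t}
                for st in bundle.spike_trains for t in st.times]
        pd.DataFrame(rows, columns=["unit_id", "time"]).to_csv(
            os.path.join(path, "spikes.csv"), index=False)
        pd.DataFrame({"sample": bundle.lfp.samples}).to_csv(
            os.path.join(path, "lfp.csv"), index=False)
        with open(os.path.join(path, "lfp_meta.json"), "w") as fh:
            json.dump({"rate": bundle.lfp.rate, "t0": bundle.lfp.t0,
                       "channel_id": bundle.lfp.channel_id,
                       "session_id": bundle.session_id}, fh)
        pd.DataFrame({"t": bundle.track.t, "x": bundle.track.x,
                      "y": bundle.track.y,
                      "speed": bundle.track.speed}).to_csv(
            os.path.join(path, "position.csv"), index=False)
        bundle.trials.df.to_csv(os.path.join(path, "trials.csv"), index=False)
        if bundle.ground_truth is not None:
            with open(os.path.join(path, "ground_truth.json"), "w") as fh:
                json.dump(bundle.ground_truth, fh)
    else:
        raise ValueError(f"unknown format {fmt!r}")


class SessionLoadError(RuntimeError):
    def __init__(self, member, detail=""):
        self.member = member
        super().__init__(f"missing or invalid session member {member!r}"
                         + (f": {detail}" if detail else ""))


def load_session(path: str, fmt: str = None) -> SessionBundle:
    """Load and validate a session bundle from HDF5 or a CSV directory."""
    if fmt is None:
        fmt = "csv" if os.path.isdir(path) else "hdf5"
    if fmt == "hdf5":
        if not os.path.exists(path):
            raise FileNotFoundError(path)
        with h5py.File(path, "r") as f:
            for member in ("spikes", "lfp", "position", "trials"):
                if member not in f:
                    raise SessionLoadError(member)
            trains = [SpikeTrain(_maybe_int(k), f["spikes"][k][()],
                                 f.attrs.get("session_id", ""))
                      for k in sorted(f["spikes"], key=_sort_key)]
            gl = f["lfp"]
            lfp = LFPTrace(gl["samples"][()], float(gl.attrs["rate"]),
                           str(gl.attrs.get("channel_id", "lfp0")),
                           float(gl.attrs.get("t0", 0.0)))
            gp = f["position"]
            track = PositionTrack(gp["t"][()], gp["x"][()], gp["y"][()],
                                  gp["speed"][()])
            import io as _io
            raw = f["trials"][()]
            raw = raw.tobytes() if hasattr(raw, "tobytes") else bytes(raw)
            tdf = pd.read_csv(_io.BytesIO(raw))
            gt = (json.loads(f.attrs["ground_truth"])
                  if "ground_truth" in f.attrs else None)
            sid = str(f.attrs.get("session_id", "session0"))
    elif fmt == "csv":
        names = {"spikes": "spikes.csv", "lfp": "lfp.csv",
                 "position": "position.csv", "trials": "trials.csv"}
        for member, fn in names.items():
            if not os.path.exists(os.path.join(path, fn)):
                raise SessionLoadError(member)
        sdf = pd.read_csv(os.path.join(path, names["spikes"]))
        trains = [SpikeTrain(uid, np.sort(g["time"].to_numpy()))
                  for uid, g in sdf.groupby("unit_id")]
        with open(os.path.join(path, "lfp_meta.json")) as fh:
            meta = json.load(fh)
        lfp = LFPTrace(pd.read_csv(os.path.join(path, names["lfp"]))
                       ["sample"].to_numpy(), meta["rate"],
                       meta.get("channel_id", "lfp0"), meta.get("t0", 0.0))
        pdf = pd.read_csv(os.path.join(path, names["position"]))
        track = PositionTrack(pdf["t"].to_numpy(), pdf["x"].to_numpy(),
                              pdf["y"].to_numpy(), pdf["speed"].to_numpy())
        tdf = pd.read_csv(os.path.join(path, names["trials"]))
        gt_path = os.path.join(path, "ground_truth.json")
        gt = json.load(open(gt_path)) if os.path.exists(gt_path) else None
        sid = meta.get("session_id", "session0")
    else:
        raise ValueError(f"unknown format {fmt!r}")
    tdf["correct"] = tdf["correct"].astype(bool)
    try:
        return SessionBundle(trains, lfp, track, TrialTable(tdf),
                             session_id=sid, ground_truth=gt)
    except ValueError as e:
        raise SessionLoadError("bundle", str(e)) from e


def _maybe_int(k):
    try:
        return int(k)
    except ValueError:
        return k


def _sort_key(k):
    try:
        return (0, int(k))
    except ValueError:
        return (1, k)
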