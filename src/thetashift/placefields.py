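"""Occupancy-normalized rate maps, spatial information, and place-field
isolation.

Five segmentation methods are provided, spanning rate-map thresholding and
spike-position density clustering:

``rm-ww``       threshold mu+sigma, require a bin above mu+2*sigma
``rm``          threshold 0.7*mu, no peak requirement (captures low-rate fields)
``rm-gmm``      threshold mu, then Gaussian-mixture refinement of memberships
``dbscan``      density clustering of spike positions (eps on axis-normalized
                coordinates)
``dbscan-gmm``  DBSCAN first stage, Gaussian-mixture refinement

All methods use only epochs in which the animal ran faster than the speed
floor (12 cm/s default).  The mixture refinements fit full-covariance 2D
Gaussians initialized from first-stage memberships, fit on first-stage member
spikes only, then classify *all* the unit's (speed-filtered) spikes by
maximum posterior, discarding spikes with mixture log-density below a floor.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage
from sklearn.cluster import DBSCAN
from sklearn.mixture import GaussianMixture

logger = logging.getLogger(__name__)

__all__ = [
    "RateMap",
    "FieldDetectionConfig",
    "PlaceField",
    "PlaceFieldSet",
    "rate_map",
    "spatial_information",
    "detect_fields",
    "fields_per_unit_summary",
    "METHODS",
]

METHODS = ("rm-ww", "rm", "rm-gmm", "dbscan", "dbscan-gmm")


@dataclass
class RateMap:
    rate: np.ndarray            # Hz per bin; NaN where never visited
    occupancy: np.ndarray       # seconds per bin
    x_edges: np.ndarray
    y_edges: np.ndarray
    bin_size: float
    smoothing: float            # Gaussian SD, cm

    @property
    def valid(self) -> np.ndarray:
        return self.occupancy > 0

    def mean_rate(self) -> float:
        """Occupancy-weighted mean firing rate."""
        p = self.occupancy / self.occupancy.sum()
        return float(np.nansum(p * np.nan_to_num(self.rate)))


@dataclass
class FieldDetectionConfig:
    method: str = "dbscan-gmm"
    min_field_length: float = 15.0   # cm
    dbscan_eps: float = 0.05         # on axis-normalized coordinates
    dbscan_minpts: int = 15
    gmm_logpdf_cut: float = -20.0
    bin_size: float = 2.0            # cm
    smoothing: float = 10.0          # cm
    speed_min: float = 12.0          # cm/s
    seed: int = 0

    def __post_init__(self):
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")


@dataclass
class PlaceField:
    field_id: int
    spike_indices: np.ndarray    # indices into the unit's full spike array
    center: tuple                # cm
    extent: float                # cm, max axis-aligned span

    @property
    def n_spikes(self) -> int:
        return int(self.spike_indices.size)


@dataclass
class PlaceFieldSet:
    unit_id: object
    fields: list
    method: str
    unassigned: np.ndarray = field(default_factory=lambda: np.zeros(0, int))

    def __len__(self):
        return len(self.fields)

    def labels(self, n_spikes: int) -> np.ndarray:
        """Per-spike field labels (-1 = unassigned)."""
        lab = np.full(n_spikes, -1, dtype=int)
        for f in self.fields:
            lab[f.spike_indices] = f.field_id
        return lab


def _spike_positions(spike_times, track):
    st = np.asarray(spike_times, dtype=float)
    x = np.interp(st, track.t, track.x)
    y = np.interp(st, track.t, track.y)
    v = np.interp(st, track.t, track.speed)
    return x, y, v


def rate_map(spike_times, track, bin_size: float = 2.0,
             smoothing: float = 10.0, speed_min: float = 12.0) -> RateMap:
    """Firing rate per 2 cm spatial bin, Gaussian-smoothed (10 cm SD).

    Only epochs faster than ``speed_min`` contribute to both occupancy and
    spike counts; never-visited bins are NaN.
    """
    t = np.asarray(track.t, dtype=float)
    dt = np.median(np.diff(t))
    moving = track.speed > speed_min
    if not moving.any():
        raise ValueError("no occupancy above the speed floor")
    xm, ym = track.x[moving], track.y[moving]
    x_edges = np.arange(np.floor(track.x.min()), np.ceil(track.x.max())
                        + bin_size, bin_size)
    y_edges = np.arange(np.floor(track.y.min()), np.ceil(track.y.max())
                        + bin_size, bin_size)
    occ = np.histogram2d(xm, ym, bins=(x_edges, y_edges))[0] * dt
    sx, sy, sv = _spike_positions(spike_times, track)
    keep = sv > speed_min
    cnt = np.histogram2d(sx[keep], sy[keep], bins=(x_edges, y_edges))[0]
    sig = smoothing / bin_size
    occ_s = ndimage.gaussian_filter(occ, sig)
    cnt_s = ndimage.gaussian_filter(cnt, sig)
    with np.errstate(invalid="ignore", divide="ignore"):
        rate = np.where(occ_s > 1e-12, cnt_s / np.maximum(occ_s, 1e-12), np.nan)
    rate[occ_s <= 1e-12] = np.nan
    return RateMap(rate, occ, x_edges, y_edges, bin_size, smoothing)


def spatial_information(rmap: RateMap) -> float:
    """Skaggs spatial information rate, bits/s.

    I = sum_i p_i * lambda_i * log2(lambda_i / lambda_bar), with p_i the
    occupancy share of bin i and lambda_bar the occupancy-weighted mean rate.
    Zero mean rate returns 0 by convention.
    """
    occ = rmap.occupancy
    lam = np.nan_to_num(rmap.rate)
    p = occ / occ.sum()
    lam_bar = float((p * lam).sum())
    if lam_bar <= 0:
        return 0.0
    with np.errstate(divide="ignore", invalid="ignore"):
        term = p * lam * np.log2(np.where(lam > 0, lam / lam_bar, 1.0))
    return float(np.nansum(term))


def _threshold_fields(rmap: RateMap, theta1: float, require_peak: float,
                      min_length: float):
    """Connected suprathreshold regions (8-connectivity) of the rate map."""
    rate = np.nan_to_num(rmap.rate)
    above = rate > theta1
    lab, n = ndimage.label(above, structure=np.ones((3, 3), dtype=int))
    regions = []
    xc = (rmap.x_edges[:-1] + rmap.x_edges[1:]) / 2.0
    yc = (rmap.y_edges[:-1] + rmap.y_edges[1:]) / 2.0
    for r in range(1, n + 1):
        sel = lab == r
        if require_peak is not None and rate[sel].max() <= require_peak:
            continue
        ii, jj = np.nonzero(sel)
        extent = max(xc[ii].max() - xc[ii].min(),
                     yc[jj].max() - yc[jj].min()) + rmap.bin_size
        if extent < min_length:
            continue
        regions.append(sel)
    return regions


def _assign_to_regions(regions, rmap, sx, sy):
    """Per-spike region index (-1 if in none)."""
    ix = np.clip(np.searchsorted(rmap.x_edges, sx, side="right") - 1, 0,
                 rmap.rate.shape[0] - 1)
    iy = np.clip(np.searchsorted(rmap.y_edges, sy, side="right") - 1, 0,
                 rmap.rate.shape[1] - 1)
    lab = np.full(sx.size, -1, dtype=int)
    for k, sel in enumerate(regions):
        inside = sel[ix, iy]
        lab[inside] = k
    return lab


def _gmm_refine(xy_all, first_labels, cfg: FieldDetectionConfig):
    """Fit a GMM initialized from first-stage memberships (members only),
    then classify all spikes; low-density spikes are unassigned."""
    ks = np.unique(first_labels[first_labels >= 0])
    if ks.size == 0:
        return np.full(xy_all.shape[0], -1, dtype=int)
    means, weights, precisions = [], [], []
    member = first_labels >= 0
    for k in ks:
        pts = xy_all[first_labels == k]
        means.append(pts.mean(axis=0))
        weights.append(pts.shape[0])
        cov = np.cov(pts.T) + np.eye(2) * 1e-2
        precisions.append(np.linalg.inv(cov))
    weights = np.asarray(weights, dtype=float)
    weights /= weights.sum()
    gmm = GaussianMixture(n_components=ks.size, covariance_type="full",
                          weights_init=weights, means_init=np.asarray(means),
                          precisions_init=np.asarray(precisions),
                          random_state=cfg.seed, reg_covar=1e-4)
    gmm.fit(xy_all[member])
    labels = gmm.predict(xy_all)
    logpdf = gmm.score_samples(xy_all)
    labels[logpdf < cfg.gmm_logpdf_cut] = -1
    for k in range(ks.size):
        nk = int((labels == k).sum())
        if 0 < nk < cfg.dbscan_minpts:
            logger.info("dropping mixture component %d with %d members", k, nk)
            labels[labels == k] = -1
    return labels


def detect_fields(spike_times, track, config: FieldDetectionConfig = None,
                  unit_id=None) -> PlaceFieldSet:
    """Partition a unit's spikes into place fields with the configured method.

    Returns a PlaceFieldSet whose spike indices refer to the unit's full
    spike-time array; spikes below the speed floor or outside every field are
    unassigned.  An empty field list is a valid outcome.
    """
    cfg = config or FieldDetectionConfig()
    st = np.asarray(spike_times, dtype=float)
    sx, sy, sv = _spike_positions(st, track)
    fast = sv > cfg.speed_min
    idx_fast = np.nonzero(fast)[0]
    labels_fast = np.full(idx_fast.size, -1, dtype=int)

    if idx_fast.size:
        if cfg.method in ("rm-ww", "rm", "rm-gmm"):
            rmap = rate_map(st, track, cfg.bin_size, cfg.smoothing,
                            cfg.speed_min)
            valid = rmap.valid & np.isfinite(rmap.rate)
            mu = float(rmap.rate[valid].mean())
            sd = float(rmap.rate[valid].std())
            if cfg.method == "rm-ww":
                theta1, peak = mu + sd, mu + 2.0 * sd
            elif cfg.method == "rm":
                theta1, peak = 0.7 * mu, None
            else:
                theta1, peak = mu, None
            regions = _threshold_fields(rmap, theta1, peak,
                                        cfg.min_field_length)
            labels_fast = _assign_to_regions(regions, rmap, sx[idx_fast],
                                             sy[idx_fast])
            if cfg.method == "rm-gmm":
                xy = np.column_stack([sx[idx_fast], sy[idx_fast]])
                labels_fast = _gmm_refine(xy, labels_fast, cfg)
        else:
            xy = np.column_stack([sx[idx_fast], sy[idx_fast]])
            span = np.maximum(xy.max(axis=0) - xy.min(axis=0), 1e-9)
            norm = (xy - xy.min(axis=0)) / span
            db = DBSCAN(eps=cfg.dbscan_eps, min_samples=cfg.dbscan_minpts)
            labels_fast = db.fit_predict(norm)
            if cfg.method == "dbscan-gmm":
                labels_fast = _gmm_refine(xy, labels_fast, cfg)

    fields = []
    for fid, k in enumerate(np.unique(labels_fast[labels_fast >= 0])):
        sel = idx_fast[labels_fast == k]
        fx, fy = sx[sel], sy[sel]
        fields.append(PlaceField(
            field_id=fid, spike_indices=sel,
            center=(float(fx.mean()), float(fy.mean())),
            extent=float(max(fx.max() - fx.min(), fy.max() - fy.min()))))
    assigned = (np.concatenate([f.spike_indices for f in fields])
                if fields else np.zeros(0, int))
    unassigned = np.setdiff1d(np.arange(st.size), assigned)
    return PlaceFieldSet(unit_id, fields, cfg.method, unassigned)


def fields_per_unit_summary(field_sets) -> dict:
    """Distribution of place-field counts per unit."""
    counts = np.array([len(fs) for fs in field_sets], dtype=float)
    if counts.size == 0:
        return {"n_units": 0, "median": np.nan, "min": np.nan, "max": np.nan,
                "counts": []}
    return {"n_units": int(counts.size), "median": float(np.median(counts)),
            "min": float(counts.min()), "max": float(counts.max()),
            "counts": counts.astype(int).tolist()}
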