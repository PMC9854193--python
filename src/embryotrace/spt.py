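"""Single-particle tracking analysis: MSD curves, motion-model fits, and
classification of mRNP trajectories into stationary / corralled / diffusive /
directed motion, plus detection of nuclear-export events.

Trajectories are 2-D particle positions in micrometres sampled at a fixed
frame interval.  The mean squared displacement (MSD) of each track is fitted
with three models:

* directed      ``MSD(t) = (v t)^2``
* power law     ``MSD(t) = 2 m D t^alpha``   (m = 2 spatial dimensions)
* confined      ``MSD(t) = (L^2 / 3) (1 - exp(-t / tau))``, with the
  effective diffusion coefficient ``D = L^2 / (12 tau)``

The four-class decision protocol mirrors common live-imaging practice:
a near-perfectly linear track (minor/major gyration-radius ratio < 1e-3 and
span > 2 um) is *directed*; otherwise the power-law and confined models
compete on weighted residual sum of squares; finally tracks whose span is
below 0.4 um and whose fitted D is below 0.03 um^2/s are overridden to
*stationary*.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

__all__ = [
    "Trajectory",
    "MSDCurve",
    "MotionFit",
    "ExportEvent",
    "filter_tracks",
    "compute_msd",
    "gyration_ratio",
    "max_displacement",
    "fit_models",
    "fit_directed",
    "classify_motion",
    "classify_cohort",
    "export_transit",
    "directed_transit_estimate",
]

#: decision thresholds of the four-class protocol
GYRATION_RATIO_DIRECTED = 1e-3
MAX_DISP_DIRECTED_UM = 2.0
MAX_DISP_STATIONARY_UM = 0.4
D_STATIONARY_UM2_S = 0.03


@dataclass
class Trajectory:
    """A single 2-D particle track.

    Parameters
    ----------
    track_id : str or int
    positions : ndarray, shape (n_frames, 2)
        x, y coordinates in micrometres.
    dt : float
        Frame interval in seconds.
    """

    track_id: object
    positions: np.ndarray
    dt: float

    def __post_init__(self) -> None:
        self.positions = np.asarray(self.positions, dtype=float)
        if self.positions.ndim != 2 or self.positions.shape[1] != 2:
            raise ValueError("positions must have shape (n_frames, 2)")
        if not np.all(np.isfinite(self.positions)):
            raise ValueError(f"track {self.track_id}: non-finite coordinates")
        if self.dt <= 0:
            raise ValueError("dt must be positive")

    @property
    def n_frames(self) -> int:
        return len(self.positions)

    @property
    def times(self) -> np.ndarray:
        return self.dt * np.arange(self.n_frames)

    def to_dataframe(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "track_id": self.track_id,
                "frame": np.arange(self.n_frames),
                "t_s": self.times,
                "x_um": self.positions[:, 0],
                "y_um": self.positions[:, 1],
            }
        )


@dataclass
class MSDCurve:
    """Time-averaged MSD of one track: lag times (s), values (um^2), counts."""

    lags_s: np.ndarray
    msd: np.ndarray
    counts: np.ndarray
    dt: float


@dataclass
class MotionFit:
    """Fitted motion parameters and class label for one track."""

    track_id: object = None
    motion_class: str = "unclassified"
    D: float = np.nan            # um^2/s (power-law fit, or L^2/(12 tau))
    alpha: float = np.nan        # anomalous exponent
    v: float = np.nan            # um/s (directed only)
    L: float = np.nan            # um (corralled only)
    tau: float = np.nan          # s (corralled only)
    rss_powerlaw: float = np.nan
    rss_confined: float = np.nan
    gyration_ratio: float = np.nan
    max_displacement: float = np.nan
    notes: list = field(default_factory=list)


@dataclass
class ExportEvent:
    """One mRNP nuclear-export event."""

    track_id: object
    dock_frame: int
    release_frame: int
    transit_s: float
    mode: str  # fast (<1 s), slow (>=1 s), or directed


# ---------------------------------------------------------------------------
# track table handling

def filter_tracks(tracks: pd.DataFrame, min_frames: int = 20) -> pd.DataFrame:
    """Keep tracks with at least ``min_frames`` consecutive frames.

    ``tracks`` is a long table with columns track_id, frame, t_s, x_um, y_um.
    Tracks whose longest run of consecutive frame numbers is shorter than
    ``min_frames`` are dropped.
    """
    required = {"track_id", "frame", "x_um", "y_um"}
    missing = required - set(tracks.columns)
    if missing:
        raise ValueError(f"track table missing columns: {sorted(missing)}")
    bad = tracks[["frame", "x_um", "y_um"]].isna().any(axis=1)
    if bad.any():
        lines = (tracks.index[bad] + 2).tolist()  # 1-based + header
        raise ValueError(f"malformed track rows at lines {lines[:20]}")
    if tracks.empty:
        warnings.warn("empty track table", stacklevel=2)
        return tracks

    def longest_run(frames: pd.Series) -> int:
        f = np.sort(frames.to_numpy())
        if len(f) == 0:
            return 0
        breaks = np.flatnonzero(np.diff(f) != 1)
        edges = np.concatenate([[-1], breaks, [len(f) - 1]])
        return int(np.max(np.diff(edges)))

    keep = tracks.groupby("track_id")["frame"].apply(longest_run) >= min_frames
    return tracks[tracks["track_id"].map(keep)].reset_index(drop=True)


def tracks_from_table(tracks: pd.DataFrame, dt: float | None = None) -> list[Trajectory]:
    """Split a long track table into Trajectory objects (sorted by frame)."""
    out = []
    for tid, grp in tracks.groupby("track_id", sort=False):
        grp = grp.sort_values("frame")
        if dt is None:
            ts = grp["t_s"].to_numpy()
            step = np.median(np.diff(ts)) if len(ts) > 1 else 1.0
        else:
            step = dt
        out.append(Trajectory(tid, grp[["x_um", "y_um"]].to_numpy(), float(step)))
    return out


# ---------------------------------------------------------------------------
# MSD and track geometry

def compute_msd(traj: Trajectory, max_lag_frames: int | None = None) -> MSDCurve:
    """Time-averaged MSD over all overlapping position pairs at each lag."""
    n = traj.n_frames
    if n < 2:
        raise ValueError("need at least 2 frames for an MSD")
    if max_lag_frames is None:
        max_lag_frames = n - 1
    if max_lag_frames >= n:
        warnings.warn(
            f"max_lag {max_lag_frames} >= n_frames {n}; truncating", stacklevel=2
        )
        max_lag_frames = n - 1
    pos = traj.positions
    msd = np.empty(max_lag_frames)
    counts = np.empty(max_lag_frames, dtype=int)
    for lag in range(1, max_lag_frames + 1):
        disp = pos[lag:] - pos[:-lag]
        msd[lag - 1] = np.mean(np.einsum("ij,ij->i", disp, disp))
        counts[lag - 1] = n - lag
    lags = traj.dt * np.arange(1, max_lag_frames + 1)
    return MSDCurve(lags, msd, counts, traj.dt)


def gyration_ratio(traj: Trajectory) -> float:
    """Minor/major principal radius-of-gyration ratio, in [0, 1].

    Radii are square roots of the eigenvalues of the 2x2 positional
    covariance.  A degenerate track (all points identical) is defined as
    isotropic (ratio 1).
    """
    if traj.n_frames < 3:
        raise ValueError("need at least 3 frames")
    centred = traj.positions - traj.positions.mean(axis=0)
    cov = centred.T @ centred / traj.n_frames
    evals = np.linalg.eigvalsh(cov)
    if evals[1] <= 0:
        warnings.warn("degenerate track: all points identical", stacklevel=2)
        return 1.0
    return float(np.sqrt(max(evals[0], 0.0) / evals[1]))


def max_displacement(traj: Trajectory) -> float:
    """Largest Euclidean distance between any two positions of the track."""
    pos = traj.positions
    n = len(pos)
    if n <= 1500:
        d2 = np.sum((pos[:, None, :] - pos[None, :, :]) ** 2, axis=-1)
        return float(np.sqrt(d2.max()))
    # diameter of the point set is attained on the convex hull
    try:
        from scipy.spatial import ConvexHull

        hull = pos[ConvexHull(pos).vertices]
    except Exception:  # collinear or otherwise degenerate
        centred = pos - pos.mean(axis=0)
        _, _, vt = np.linalg.svd(centred, full_matrices=False)
        proj = centred @ vt[0]
        return float(proj.max() - proj.min())
    d2 = np.sum((hull[:, None, :] - hull[None, :, :]) ** 2, axis=-1)
    return float(np.sqrt(d2.max()))


# ---------------------------------------------------------------------------
# model fitting

def _msd_powerlaw(t, D, alpha):
    return 4.0 * D * np.power(t, alpha)


def _msd_confined(t, L, tau):
    return (L * L / 3.0) * (1.0 - np.exp(-t / tau))


def _fit_weights(lags_s: np.ndarray) -> np.ndarray:
    # variance of the time-averaged MSD estimator grows ~ t^3 for short lags,
    # so weight residuals by 1/t^1.5
    return lags_s ** 1.5


def fit_directed(msd: MSDCurve, fit_lags: int | None = None) -> MotionFit:
    """Least-squares speed of the ballistic model MSD = (v t)^2 (closed form)."""
    k = min(fit_lags or len(msd.msd), len(msd.msd))
    t, m = msd.lags_s[:k], msd.msd[:k]
    v = float(np.sqrt(max(np.sum(m * t ** 2), 0.0) / np.sum(t ** 4)))
    fit = MotionFit(motion_class="directed", v=v)
    fit.notes.append("v from MSD=(vt)^2")
    return fit


def fit_models(
    msd: MSDCurve,
    fit_lags: int | None = 10,
    tau_max: float | None = None,
) -> dict[str, MotionFit]:
    """Fit the power-law and confined MSD models over the first ``fit_lags``.

    Returns a dict with keys ``"powerlaw"`` and ``"confined"`` (a model that
    fails to converge is omitted).  Fits are weighted least squares with
    sigma ~ t^1.5; the confined model's tau can be bounded above via
    ``tau_max`` so that confinement is only declared when equilibration is
    observable within the fit window.
    """
    k = min(fit_lags or len(msd.msd), len(msd.msd))
    if k < 4:
        raise ValueError("need at least 4 lag points to fit")
    t, m = msd.lags_s[:k], msd.msd[:k]
    w = _fit_weights(t)
    out: dict[str, MotionFit] = {}

    D0 = max(m[0] / (4.0 * msd.dt), 1e-12)
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, _ = curve_fit(
                _msd_powerlaw, t, m, p0=[D0, 1.0], sigma=w,
                bounds=([0.0, 1e-6], [np.inf, 2.0]), maxfev=20000,
            )
        rss = float(np.sum(((_msd_powerlaw(t, *p) - m) / w) ** 2))
        out["powerlaw"] = MotionFit(
            motion_class="diffusive", D=float(p[0]), alpha=float(p[1]),
            rss_powerlaw=rss,
        )
    except RuntimeError:
        pass

    L0 = max(np.sqrt(3.0 * m.max()), 1e-9)
    half = m.max() / 2.0
    above = np.nonzero(m >= half)[0]
    tau0 = t[above[0]] if len(above) else t[-1] / 2.0
    hi_tau = tau_max if tau_max is not None else np.inf
    tau0 = min(tau0, hi_tau * 0.9) if np.isfinite(hi_tau) else tau0
    try:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            p, _ = curve_fit(
                _msd_confined, t, m, p0=[L0, max(tau0, 1e-5)], sigma=w,
                bounds=([0.0, 1e-6], [np.inf, hi_tau]), maxfev=20000,
            )
        rss = float(np.sum(((_msd_confined(t, *p) - m) / w) ** 2))
        L, tau = float(p[0]), float(p[1])
        out["confined"] = MotionFit(
            motion_class="corralled", D=L * L / (12.0 * tau), L=L, tau=tau,
            rss_confined=rss,
        )
    except RuntimeError:
        pass
    return out


# ---------------------------------------------------------------------------
# classification

def classify_motion(
    traj: Trajectory,
    fit_lag_fraction: float = 0.1,
    max_fit_lags: int = 100,
) -> MotionFit:
    """Classify one track as stationary, corralled, diffusive or directed.

    Decision order: (1) near-linear anisotropic tracks spanning > 2 um are
    directed; (2) otherwise the power-law and confined MSD models compete on
    weighted rss over the first ~10% of lags; (3) tracks spanning < 0.4 um
    with power-law D < 0.03 um^2/s are overridden to stationary.
    """
    ratio = gyration_ratio(traj)
    span = max_displacement(traj)
    nlags = int(np.clip(traj.n_frames * fit_lag_fraction, 4, max_fit_lags))
    nlags = min(nlags, traj.n_frames - 1)
    msd = compute_msd(traj, nlags)

    if ratio < GYRATION_RATIO_DIRECTED and span > MAX_DISP_DIRECTED_UM:
        fit = fit_directed(msd, nlags)
        # report the power-law exponent too (approaches 2 for ballistic motion)
        try:
            aux = fit_models(msd, nlags).get("powerlaw")
            if aux is not None:
                fit.alpha, fit.D = aux.alpha, aux.D
                fit.rss_powerlaw = aux.rss_powerlaw
        except ValueError:
            pass
        fit.track_id = traj.track_id
        fit.gyration_ratio, fit.max_displacement = ratio, span
        return fit

    tau_max = nlags * traj.dt / 2.0
    fits = fit_models(msd, nlags, tau_max=tau_max)
    pl, cf = fits.get("powerlaw"), fits.get("confined")
    if pl is None and cf is None:
        fit = MotionFit(track_id=traj.track_id, motion_class="unclassified")
        fit.notes.append("both model fits failed")
        fit.gyration_ratio, fit.max_displacement = ratio, span
        return fit
    if cf is None or (pl is not None and pl.rss_powerlaw <= cf.rss_confined):
        fit = pl
    else:
        fit = cf
        if pl is not None:
            fit.alpha = pl.alpha
            fit.rss_powerlaw = pl.rss_powerlaw
    if pl is not None and cf is not None:
        fit.rss_powerlaw, fit.rss_confined = pl.rss_powerlaw, cf.rss_confined

    d_for_override = pl.D if pl is not None else fit.D
    if span < MAX_DISP_STATIONARY_UM and d_for_override < D_STATIONARY_UM2_S:
        fit.motion_class = "stationary"
        fit.notes.append("stationary override (span and D below thresholds)")
    fit.track_id = traj.track_id
    fit.gyration_ratio, fit.max_displacement = ratio, span
    return fit


def classify_cohort(trajectories: list[Trajectory], **kwargs) -> pd.DataFrame:
    """Classify a list of tracks; returns one row per track."""
    rows = []
    for traj in trajectories:
        fit = classify_motion(traj, **kwargs)
        rows.append(
            {
                "track_id": fit.track_id,
                "class": fit.motion_class,
                "D_um2_s": fit.D,
                "alpha": fit.alpha,
                "v_um_s": fit.v,
                "L_um": fit.L,
                "tau_s": fit.tau,
                "rss_powerlaw": fit.rss_powerlaw,
                "rss_confined": fit.rss_confined,
                "gyration_ratio": fit.gyration_ratio,
                "max_displacement_um": fit.max_displacement,
            }
        )
    return pd.DataFrame(rows)


# ---------------------------------------------------------------------------
# nuclear export

def _point_segment_distance(p: np.ndarray, a: np.ndarray, b: np.ndarray) -> np.ndarray:
    """Distances from points p (n,2) to segment a-b."""
    ab = b - a
    denom = float(ab @ ab)
    if denom == 0.0:
        return np.linalg.norm(p - a, axis=1)
    t = np.clip((p - a) @ ab / denom, 0.0, 1.0)
    proj = a + t[:, None] * ab
    return np.linalg.norm(p - proj, axis=1)


def _distance_to_polyline(p: np.ndarray, poly: np.ndarray, closed: bool) -> np.ndarray:
    segs = len(poly) if closed else len(poly) - 1
    d = np.full(len(p), np.inf)
    for i in range(segs):
        a, b = poly[i], poly[(i + 1) % len(poly)]
        d = np.minimum(d, _point_segment_distance(p, a, b))
    return d


def _points_in_polygon(p: np.ndarray, poly: np.ndarray) -> np.ndarray:
    """Even-odd-rule point-in-polygon test (polygon implicitly closed)."""
    x, y = p[:, 0], p[:, 1]
    inside = np.zeros(len(p), dtype=bool)
    n = len(poly)
    for i in range(n):
        x1, y1 = poly[i]
        x2, y2 = poly[(i + 1) % n]
        crosses = (y1 > y) != (y2 > y)
        with np.errstate(divide="ignore", invalid="ignore"):
            xint = x1 + (y - y1) * (x2 - x1) / (y2 - y1)
        inside ^= crosses & (x < xint)
    return inside


def export_transit(
    traj: Trajectory,
    boundary: np.ndarray,
    dock_radius_um: float = 0.2,
    release_increase_frames: int = 2,
) -> ExportEvent | None:
    """Detect one nuclear-export event on a track crossing the nuclear edge.

    ``boundary`` is a closed polygon (vertices, shape (m, 2)) outlining the
    nucleus; its interior is the nuclear side.  The dock is the first frame
    of the final nuclear-side dwell within ``dock_radius_um`` of the edge
    before the crossing; the release is the first cytoplasmic frame from
    which the distance to the edge increases for ``release_increase_frames``
    consecutive frames.  The transit time is release - dock.  Events faster
    than 1 s are *fast*, others *slow*; an event whose dock-to-release
    sub-track is nearly linear (gyration ratio < 1e-3) is *directed*.
    """
    boundary = np.asarray(boundary, dtype=float)
    pos = traj.positions
    inside = _points_in_polygon(pos, boundary)
    dist = _distance_to_polyline(pos, boundary, closed=True)

    crossings = np.nonzero(inside[:-1] & ~inside[1:])[0]
    if len(crossings) == 0:
        return None
    c = int(crossings[0])  # last nuclear frame index

    # dock: beginning of the contiguous near-edge dwell ending at the crossing
    dock = c
    while dock > 0 and inside[dock - 1] and dist[dock - 1] <= dock_radius_um:
        dock -= 1
    if dist[dock] > dock_radius_um:
        dock = c  # crossed without dwelling

    release = None
    for j in range(c + 1, traj.n_frames - release_increase_frames):
        if not inside[j] and np.all(np.diff(dist[j : j + release_increase_frames + 1]) > 0):
            release = j
            break
    if release is None:
        return None

    transit = (release - dock) * traj.dt
    mode = "fast" if transit < 1.0 else "slow"
    sub = pos[dock : release + 1]
    if len(sub) >= 3:
        sub_traj = Trajectory(traj.track_id, sub, traj.dt)
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            if gyration_ratio(sub_traj) < GYRATION_RATIO_DIRECTED:
                mode = "directed"
    return ExportEvent(traj.track_id, dock, release, float(transit), mode)


def directed_transit_estimate(v: float, npc_length_um: float = 0.2) -> float:
    """Transit time (s) of a directed export event crossing the NPC.

    The nuclear pore complex spans roughly 200 nm (nuclear basket ~75 nm,
    central framework ~70 nm, cytoplasmic filaments ~50 nm); a particle
    moving at speed ``v`` crosses it in ``npc_length_um / v`` seconds.
    """
    if v <= 0:
        raise ValueError("speed must be positive")
    return npc_length_um / v
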