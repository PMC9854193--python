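"""Quantification of transcription-site traces from ROI measurements.

A transcription site is measured with two concentric circular regions:
ROI-1 (the puncta) yields the maximum intensity, ROI-2 (three times the
radius, minus ROI-1) yields the local-background mean and SD.  The
normalized transcription activity

    (ROI1_max - ROI2_mean) / ROI2_mean

cancels any multiplicative gain shared by signal and background — in
particular photobleaching.  From normalized per-allele traces this module
derives initiation times, activation-pattern classes (one allele / same
time / sequential / none), plateau times, and the transcriptional-memory
statistics comparing de novo transcription with post-mitotic re-activation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "RoiMeasurement",
    "AlleleTracePair",
    "ActivationRecord",
    "normalized_intensity",
    "normalize_table",
    "snr",
    "measure_movie",
    "detect_initiation",
    "mad_threshold",
    "classify_activation",
    "plateau_time",
    "memory_statistics",
    "traces_from_table",
]

ACTIVATION_PATTERNS = ("none", "one_allele", "same_time", "sequential")


@dataclass
class RoiMeasurement:
    """One time point of a two-ROI intensity measurement (a.u.)."""

    t: float
    roi1_max: float
    roi2_mean: float
    roi2_sd: float = np.nan
    identified: bool = True


@dataclass
class AlleleTracePair:
    """Normalized activity of both alleles of one cell on a shared grid."""

    cell_id: str
    cycle: str
    t_min: np.ndarray
    allele1: np.ndarray
    allele2: np.ndarray
    t0: float = 0.0

    def __post_init__(self) -> None:
        self.t_min = np.asarray(self.t_min, dtype=float)
        self.allele1 = np.asarray(self.allele1, dtype=float)
        self.allele2 = np.asarray(self.allele2, dtype=float)
        if not (len(self.t_min) == len(self.allele1) == len(self.allele2)):
            raise ValueError("alleles must share the time grid")
        if not (np.all(np.isfinite(self.allele1)) and np.all(np.isfinite(self.allele2))):
            raise ValueError("normalized values must be finite")


@dataclass
class ActivationRecord:
    """Initiation times of both alleles and the resulting pattern class."""

    cell_id: str
    cycle: str
    init1_min: float | None
    init2_min: float | None
    pattern: str
    time_difference_min: float | None


def normalized_intensity(m: RoiMeasurement) -> float:
    """Background-normalized activity (ROI1_max - ROI2_mean) / ROI2_mean.

    An unidentified puncta is assigned to the local background (activity 0).
    """
    if not m.identified:
        return 0.0
    if m.roi2_mean <= 0:
        raise ValueError("roi2_mean must be positive for normalization")
    return (m.roi1_max - m.roi2_mean) / m.roi2_mean


def normalize_table(df: pd.DataFrame) -> pd.Series:
    """Vectorized normalized intensity for a trace table."""
    if (df["roi2_mean"] <= 0).any():
        raise ValueError("roi2_mean must be positive for normalization")
    norm = (df["roi1_max"] - df["roi2_mean"]) / df["roi2_mean"]
    if "identified" in df.columns:
        norm = norm.where(df["identified"].astype(bool), 0.0)
    return norm


def snr(puncta_max: float, bg_mean: float, bg_sd: float) -> float:
    """Signal-to-noise ratio (puncta_max - bg_mean) / bg_sd."""
    if bg_sd <= 0:
        raise ValueError("background SD must be positive")
    return (puncta_max - bg_mean) / bg_sd


def measure_movie(
    movie,
    centers: list[tuple[float, float]],
    roi1_diameter_um: float = 2.0,
    pixel_size_um: float = 0.5,
) -> pd.DataFrame:
    """Measure ROI-1 max and ROI-2 (annulus) mean/SD per frame per center.

    ``movie`` is a SpotMovie or a raw (n, h, w) array; ``centers`` are
    (x, y) pixel coordinates.  ROI-2's radius is three times ROI-1's and the
    annulus excludes the ROI-1 disc.  ROIs clipped by the frame edge are
    measured on the clipped masks with a warning.
    """
    frames = movie.frames if hasattr(movie, "frames") else np.asarray(movie)
    _, h, w = frames.shape
    r1 = roi1_diameter_um / 2.0 / pixel_size_um
    r2 = 3.0 * r1
    yy, xx = np.mgrid[0:h, 0:w]
    rows = []
    for ci, (x0, y0) in enumerate(centers):
        if not (0 <= x0 < w and 0 <= y0 < h):
            raise ValueError(f"center {ci} outside frame")
        if x0 - r2 < 0 or x0 + r2 >= w or y0 - r2 < 0 or y0 + r2 >= h:
            warnings.warn(f"ROI of center {ci} clipped by frame edge", stacklevel=2)
        d2 = (xx - x0) ** 2 + (yy - y0) ** 2
        disc = d2 <= r1**2
        annulus = (d2 <= r2**2) & ~disc
        if not disc.any() or not annulus.any():
            raise ValueError(f"empty ROI for center {ci}")
        for f in range(len(frames)):
            img = frames[f]
            rows.append(
                {
                    "center": ci,
                    "frame": f,
                    "roi1_max": float(img[disc].max()),
                    "roi2_mean": float(img[annulus].mean()),
                    "roi2_sd": float(img[annulus].std()),
                }
            )
    return pd.DataFrame(rows)


def mad_threshold(
    values: np.ndarray, t: np.ndarray, t0: float, factor: float = 3.0
) -> float:
    """Per-trace threshold: ``factor`` x 1.4826 x MAD of the pre-t0 baseline.

    Falls back to the baseline SD when the MAD degenerates to zero, and to
    the whole-trace early points (first three) when nothing precedes t0.
    """
    baseline = values[np.asarray(t) < t0]
    if baseline.size < 3:
        baseline = np.asarray(values)[:3]
    mad = np.median(np.abs(baseline - np.median(baseline)))
    scale = 1.4826 * mad if mad > 0 else float(np.std(baseline))
    return factor * scale


def detect_initiation(
    values: np.ndarray,
    t: np.ndarray,
    threshold: float,
    min_consecutive: int = 2,
) -> float | None:
    """First time the trace exceeds ``threshold`` for ``min_consecutive``
    consecutive points; None if it never does."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    if values.size == 0:
        raise ValueError("empty trace")
    if len(values) != len(t):
        raise ValueError("trace and time grid lengths differ")
    above = values > threshold
    run = 0
    for i, flag in enumerate(above):
        run = run + 1 if flag else 0
        if run >= min_consecutive:
            return float(t[i - min_consecutive + 1])
    return None


def classify_activation(
    pair: AlleleTracePair,
    threshold: float,
    same_time_window: float = 5.0,
    min_consecutive: int = 2,
) -> ActivationRecord:
    """Classify one allele pair as none / one_allele / same_time / sequential.

    ``same_time_window`` (min) is the largest inter-allele initiation-time
    difference still counted as simultaneous; it defaults to one sampling
    interval of the slower acquisition mode.
    """
    i1 = detect_initiation(pair.allele1, pair.t_min, threshold, min_consecutive)
    i2 = detect_initiation(pair.allele2, pair.t_min, threshold, min_consecutive)
    if i1 is None and i2 is None:
        pattern, diff = "none", None
    elif i1 is None or i2 is None:
        pattern, diff = "one_allele", None
    else:
        diff = abs(i2 - i1)
        pattern = "same_time" if diff <= same_time_window else "sequential"
    return ActivationRecord(pair.cell_id, pair.cycle, i1, i2, pattern, diff)


def plateau_time(
    values: np.ndarray,
    t: np.ndarray,
    fraction: float = 0.9,
    smooth_window: int = 3,
) -> float | None:
    """First time the moving-average-smoothed trace reaches ``fraction`` of
    its maximum; None for a trace with no positive maximum."""
    values = np.asarray(values, dtype=float)
    t = np.asarray(t, dtype=float)
    if smooth_window > 1:
        kernel = np.ones(smooth_window) / smooth_window
        pad = smooth_window // 2
        padded = np.pad(values, pad, mode="edge")
        smoothed = np.convolve(padded, kernel, mode="valid")[: len(values)]
    else:
        smoothed = values
    peak = smoothed.max()
    if peak <= 0:
        return None
    idx = np.nonzero(smoothed >= fraction * peak)[0]
    return float(t[idx[0]]) if idx.size else None


def memory_statistics(
    records: list[ActivationRecord],
    group_by: str = "cycle",
) -> tuple[pd.DataFrame, float | None]:
    """Per-group mean +/- SD of inter-allele initiation-time differences.

    Groups records by cycle label, summarizes the |t2 - t1| differences of
    cells where both alleles fired, and runs a two-sample two-tailed t test
    between the first two groups (p is None with fewer than two groups).
    """
    rows = [
        {"group": getattr(r, group_by), "diff_min": r.time_difference_min}
        for r in records
        if r.time_difference_min is not None
    ]
    df = pd.DataFrame(rows, columns=["group", "diff_min"])
    summary = (
        df.groupby("group")["diff_min"]
        .agg(n="count", mean_min="mean", sd_min=lambda s: s.std(ddof=1))
        .reset_index()
    )
    summary.loc[summary["n"] < 2, "sd_min"] = np.nan
    pval = None
    groups = summary["group"].tolist()
    if len(groups) >= 2:
        a = df.loc[df["group"] == groups[0], "diff_min"]
        b = df.loc[df["group"] == groups[1], "diff_min"]
        if len(a) >= 2 and len(b) >= 2:
            pval = float(stats.ttest_ind(a, b).pvalue)
    return summary, pval


def traces_from_table(raw: pd.DataFrame) -> list[AlleleTracePair]:
    """Build AlleleTracePair objects from a long ROI trace table.

    Expects columns cell_id, cycle, t_min, allele (1/2), roi1_max,
    roi2_mean and optionally identified; normalization is applied here.
    """
    df = raw.copy()
    df["norm"] = normalize_table(df)
    pairs = []
    for (cell, cycle), grp in df.groupby(["cell_id", "cycle"], sort=False):
        a1 = grp[grp["allele"] == 1].sort_values("t_min")
        a2 = grp[grp["allele"] == 2].sort_values("t_min")
        if len(a1) != len(a2) or not np.allclose(
            a1["t_min"].to_numpy(), a2["t_min"].to_numpy()
        ):
            raise ValueError(f"cell {cell}: alleles do not share the time grid")
        pairs.append(
            AlleleTracePair(
                cell_id=cell,
                cycle=cycle,
                t_min=a1["t_min"].to_numpy(),
                allele1=a1["norm"].to_numpy(),
                allele2=a2["norm"].to_numpy(),
            )
        )
    return pairs
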