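"""Intrinsic/extrinsic noise decomposition of allelic transcription.

Fluctuations shared by the two alleles of one cell (cell-cycle phase,
inherited transcriptional state, cytoplasmic factors) are *extrinsic* noise;
allele-autonomous stochasticity is *intrinsic*.  The two are separated by
correlating the cumulative transcriptional outputs of allele pairs within
cells: purely extrinsic variation puts cells on the scatterplot diagonal
(r -> 1, slope -> 1), intrinsic variation scatters them off it.  Randomly
re-paired alleles from different cells serve as the null control.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .trace_quant import AlleleTracePair

__all__ = [
    "CorrelationReport",
    "cumulative_output",
    "allele_outputs",
    "allele_correlation",
    "random_pair_control",
    "per_timepoint_correlation",
    "compare_correlation_series",
    "allele_difference_series",
]


@dataclass
class CorrelationReport:
    r: float          # Pearson
    rho: float        # Spearman
    k: float          # least-squares slope of output2 on output1
    n: int
    p: float          # two-tailed p for Pearson r
    degenerate: bool = False


def cumulative_output(values: np.ndarray, dt: float | None = None) -> float:
    """Total transcriptional output of one trace.

    Plain sum of the normalized intensities over the cycle's time points
    (the grids are uniform, so the sum is proportional to the integrated
    area); pass ``dt`` for a delta-t-weighted variant.
    """
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("empty trace")
    total = float(values.sum())
    return total * dt if dt is not None else total


def allele_outputs(pairs: list[AlleleTracePair], dt: float | None = None) -> pd.DataFrame:
    """Cumulative output of both alleles per cell."""
    return pd.DataFrame(
        {
            "cell_id": [p.cell_id for p in pairs],
            "cycle": [p.cycle for p in pairs],
            "output1": [cumulative_output(p.allele1, dt) for p in pairs],
            "output2": [cumulative_output(p.allele2, dt) for p in pairs],
        }
    )


def _correlate(x: np.ndarray, y: np.ndarray) -> CorrelationReport:
    x, y = np.asarray(x, float), np.asarray(y, float)
    n = len(x)
    if n < 3:
        raise ValueError("need at least 3 pairs")
    if np.std(x) == 0 or np.std(y) == 0:
        warnings.warn("zero variance: correlation undefined", stacklevel=3)
        return CorrelationReport(np.nan, np.nan, np.nan, n, np.nan, degenerate=True)
    pear = stats.pearsonr(x, y)
    rho = stats.spearmanr(x, y).statistic
    slope = stats.linregress(x, y).slope
    return CorrelationReport(
        float(pear.statistic), float(rho), float(slope), n, float(pear.pvalue)
    )


def allele_correlation(outputs: pd.DataFrame) -> CorrelationReport:
    """Pearson r, Spearman rho, slope and p for paired allele outputs."""
    return _correlate(outputs["output1"].to_numpy(), outputs["output2"].to_numpy())


def random_pair_control(
    outputs: pd.DataFrame, seed: int = 0, n_shuffles: int = 1
) -> CorrelationReport:
    """Correlation of allele 1 of cell i with allele 2 of a random cell j != i.

    The pairing is a seeded derangement (no cell keeps its own partner
    allele).  With ``n_shuffles`` > 1 the statistics are averaged over
    independent derangements.
    """
    x = outputs["output1"].to_numpy(float)
    y = outputs["output2"].to_numpy(float)
    n = len(x)
    if n < 2:
        raise ValueError("need at least 2 cells to shuffle")
    rng = np.random.default_rng(seed)
    reports = []
    for _ in range(n_shuffles):
        perm = rng.permutation(n)
        while np.any(perm == np.arange(n)):
            perm = rng.permutation(n)
        reports.append(_correlate(x, y[perm]))
    if n_shuffles == 1:
        return reports[0]
    return CorrelationReport(
        r=float(np.nanmean([c.r for c in reports])),
        rho=float(np.nanmean([c.rho for c in reports])),
        k=float(np.nanmean([c.k for c in reports])),
        n=n,
        p=float(np.nanmean([c.p for c in reports])),
        degenerate=any(c.degenerate for c in reports),
    )


def per_timepoint_correlation(
    pairs: list[AlleleTracePair], min_cells: int = 3
) -> pd.DataFrame:
    """Pearson r across cells between the two alleles at each time point.

    Time points sampled in fewer than ``min_cells`` cells, or with zero
    variance in either allele, are skipped with a warning.
    """
    frames = {}
    for p in pairs:
        for t, a1, a2 in zip(p.t_min, p.allele1, p.allele2):
            frames.setdefault(float(t), []).append((a1, a2))
    rows = []
    for t in sorted(frames):
        arr = np.asarray(frames[t])
        if len(arr) < min_cells:
            warnings.warn(f"t={t}: fewer than {min_cells} cells; skipped", stacklevel=2)
            continue
        if np.std(arr[:, 0]) == 0 or np.std(arr[:, 1]) == 0:
            warnings.warn(f"t={t}: zero variance; skipped", stacklevel=2)
            continue
        res = stats.pearsonr(arr[:, 0], arr[:, 1])
        rows.append(
            {"t_min": t, "r": float(res.statistic), "p": float(res.pvalue),
             "n_cells": len(arr)}
        )
    return pd.DataFrame(rows, columns=["t_min", "r", "p", "n_cells"])


def compare_correlation_series(
    series_a: pd.DataFrame, series_b: pd.DataFrame, fisher_z: bool = False
) -> float:
    """Unpaired two-tailed t test between two per-timepoint r series.

    By default the raw correlation coefficients are compared (mirroring the
    published procedure); ``fisher_z=True`` applies the variance-stabilizing
    arctanh transform first.
    """
    a = series_a["r"].to_numpy(float)
    b = series_b["r"].to_numpy(float)
    if fisher_z:
        a, b = np.arctanh(np.clip(a, -0.999999, 0.999999)), np.arctanh(
            np.clip(b, -0.999999, 0.999999)
        )
    return float(stats.ttest_ind(a, b).pvalue)


def allele_difference_series(pairs: list[AlleleTracePair]) -> pd.DataFrame:
    """Mean |allele1 - allele2| across cells per time point, with the paired
    two-tailed t-test p value between the alleles at that time point."""
    frames = {}
    for p in pairs:
        for t, a1, a2 in zip(p.t_min, p.allele1, p.allele2):
            frames.setdefault(float(t), []).append((a1, a2))
    rows = []
    for t in sorted(frames):
        arr = np.asarray(frames[t])
        diff = np.abs(arr[:, 0] - arr[:, 1])
        if len(arr) >= 2 and np.std(arr[:, 0] - arr[:, 1]) > 0:
            p_val = float(stats.ttest_rel(arr[:, 0], arr[:, 1]).pvalue)
        else:
            p_val = np.nan
        rows.append(
            {
                "t_min": t,
                "mean_abs_diff": float(diff.mean()),
                "p_paired": p_val,
                "n_cells": len(arr),
            }
        )
    return pd.DataFrame(rows, columns=["t_min", "mean_abs_diff", "p_paired", "n_cells"])
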