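"""Cohort-level recovery benchmarks tying the generators to the estimators.

These routines generate a synthetic cohort under stated conditions, run the
corresponding analysis stage, and return the recovered quantity, so that
ground-truth recovery (diffusion coefficients, drift speeds, confinement,
initiation-time offsets, classification recall) can be measured end to end.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from . import spt, synth, trace_quant

__all__ = [
    "ensemble_msd",
    "recover_diffusive_D",
    "recover_directed_v",
    "recover_corralled_D",
    "classification_recall",
    "memory_recovery",
]


def ensemble_msd(trajectories: list[spt.Trajectory], max_lag: int) -> spt.MSDCurve:
    """Average the time-averaged MSD curves of a cohort of equal-length tracks."""
    curves = [spt.compute_msd(t, max_lag) for t in trajectories]
    msd = np.mean([c.msd for c in curves], axis=0)
    counts = np.sum([c.counts for c in curves], axis=0)
    return spt.MSDCurve(curves[0].lags_s, msd, counts, curves[0].dt)


def recover_diffusive_D(
    D: float, n_tracks: int = 200, n_frames: int = 100, dt: float = 0.01,
    seed: int = 0, fit_lags: int = 10,
) -> float:
    """Fit the power-law MSD model to a noiseless Brownian cohort's ensemble
    MSD and return the recovered diffusion coefficient (um^2/s)."""
    params = synth.TrajectoryParams(
        "diffusive", D_micro=D, n_frames=n_frames, dt=dt, seed=seed
    )
    trajs = synth.gen_trajectories(params, n_tracks)
    fits = spt.fit_models(ensemble_msd(trajs, fit_lags), fit_lags)
    return fits["powerlaw"].D


def recover_directed_v(
    v: float, n_tracks: int = 200, n_frames: int = 100, dt: float = 0.01,
    seed: int = 0, fit_lags: int = 10,
) -> float:
    """Fit the ballistic MSD model to a cohort of directed tracks and return
    the recovered speed (um/s)."""
    params = synth.TrajectoryParams(
        "directed", D_micro=0.0, v=v, n_frames=n_frames, dt=dt, seed=seed
    )
    trajs = synth.gen_trajectories(params, n_tracks)
    return spt.fit_directed(ensemble_msd(trajs, fit_lags), fit_lags).v


def recover_corralled_D(
    D: float, L: float = 0.5, n_tracks: int = 200, n_frames: int = 100,
    dt: float = 0.01, seed: int = 0, fit_lags: int = 10,
) -> float:
    """Fit the confined MSD model to a corralled cohort's ensemble MSD and
    return the derived diffusion coefficient L^2 / (12 tau)."""
    params = synth.TrajectoryParams(
        "corralled", D_micro=D, L_box=L, n_frames=n_frames, dt=dt, seed=seed
    )
    trajs = synth.gen_trajectories(params, n_tracks)
    fits = spt.fit_models(ensemble_msd(trajs, fit_lags), fit_lags)
    return fits["confined"].D


#: cohort conditions of the classification benchmark.  Diffusive, corralled
#: and stationary tracks run 1000 frames (10 s at the 10-ms interval) so the
#: confinement equilibration (tau ~ 0.07 s) is observable within the fit
#: window; directed tracks are ballistic (the near-linearity gate admits
#: only tracks with negligible transverse spread) and span ~1 s.
RECALL_COHORT = {
    "stationary": dict(motion_class="stationary", sigma_loc=0.02, n_frames=1000),
    "corralled": dict(motion_class="corralled", D_micro=0.2818, L_box=0.5,
                      n_frames=1000),
    "diffusive": dict(motion_class="diffusive", D_micro=0.2839, n_frames=1000),
    "directed": dict(motion_class="directed", D_micro=0.0, v=3.1715,
                     n_frames=100),
}


def classification_recall(
    n_per_class: int = 100, dt: float = 0.01, seed: int = 0
) -> pd.DataFrame:
    """Confusion matrix of the four-class motion classifier on synthetic
    cohorts at nuclear Table-like parameters; returns rows true-class,
    columns predicted-class, values counts."""
    rows = []
    for i, (truth, kw) in enumerate(RECALL_COHORT.items()):
        params = synth.TrajectoryParams(dt=dt, seed=seed + 1000 * i, **kw)
        for traj in synth.gen_trajectories(params, n_per_class):
            fit = spt.classify_motion(traj)
            rows.append({"true": truth, "predicted": fit.motion_class})
    df = pd.DataFrame(rows)
    return pd.crosstab(df["true"], df["predicted"])


def memory_recovery(
    offset_mean: float,
    offset_sd: float,
    n_cells: int,
    cycle: str,
    plateau_time: float,
    first_init_mean: float,
    seed: int = 0,
    dt_min: float = 2.0,
    n_timepoints: int = 130,
    threshold: float = 0.15,
    same_time_window: float | None = None,
) -> tuple[pd.DataFrame, list]:
    """Generate an allelic trace cohort with gamma initiation offsets, run
    initiation detection, and return the memory statistics plus records."""
    params = synth.TracePairParams(
        n_cells=n_cells,
        n_timepoints=n_timepoints,
        dt_min=dt_min,
        offset_mean=offset_mean,
        offset_sd=offset_sd,
        plateau_time=plateau_time,
        first_init_mean=first_init_mean,
        p_silent_second_allele=0.0,
        seed=seed,
        cycle=cycle,
    )
    cohort = synth.gen_trace_pairs(params)
    window = dt_min if same_time_window is None else same_time_window
    records = [
        trace_quant.classify_activation(pair, threshold, same_time_window=window)
        for pair in cohort.pairs
    ]
    summary, _ = trace_quant.memory_statistics(records)
    return summary, records
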