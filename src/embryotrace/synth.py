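"""Seeded synthetic-data generators for every input the pipeline consumes.

The generators emulate the statistical structure of live dCas13 RNA-imaging
data in early zebrafish embryos:

* 2-D mRNP trajectories in the four motion modes (stationary, corralled,
  diffusive, directed) with localization noise;
* paired allelic transcription traces with a shared (extrinsic) per-cell
  output multiplier, independent (intrinsic) per-allele multipliers,
  gamma-distributed inter-allele initiation-time offsets, and multiplicative
  photobleaching applied to signal and background alike;
* spot movies (2-D Gaussian puncta over constant background plus Gaussian
  read noise);
* transcriptomes with planted near-identical repeat clusters plus random
  decoy transcripts.

All generators are deterministic for a fixed seed and return ground truth
alongside the synthetic observations.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .spt import Trajectory
from .trace_quant import AlleleTracePair, traces_from_table

__all__ = [
    "TrajectoryParams",
    "TracePairParams",
    "PlantedRepeatSpec",
    "SpotMovie",
    "TraceCohort",
    "gen_trajectory",
    "gen_trajectories",
    "gen_trace_pairs",
    "gen_spot_movie",
    "gen_transcriptome",
]

MOTION_CLASSES = ("stationary", "corralled", "diffusive", "directed")


@dataclass
class TrajectoryParams:
    """Parameters of one simulated 2-D track.

    ``D_micro`` is the microscopic diffusion coefficient (um^2/s), ``v`` the
    drift speed for directed motion (um/s), ``L_box`` the confinement length
    scale for corralled motion (um), ``sigma_loc`` the localization-noise SD
    added to every reported coordinate (um), ``dt`` the frame interval (s).

    Corralled motion defaults to a harmonic tether (a discrete
    Ornstein-Uhlenbeck process) whose MSD is exactly
    ``(L^2/3)(1 - exp(-t/tau))`` with ``tau = L^2/(12 D)`` — i.e. it inverts
    the confined-motion model used downstream, with the same plateau
    ``L^2/3`` and the same per-axis stationary variance ``L^2/12`` as a
    uniform distribution in a box of side L.  ``corral_model="box"``
    switches to literal Brownian motion reflected at the walls of a square
    box of side ``L_box``.
    """

    motion_class: str
    D_micro: float = 0.28
    v: float = 0.0
    L_box: float = 0.5
    sigma_loc: float = 0.0
    n_frames: int = 100
    dt: float = 0.01
    seed: int = 0
    corral_model: str = "tether"

    def __post_init__(self) -> None:
        if self.motion_class not in MOTION_CLASSES:
            raise ValueError(
                f"unknown motion class {self.motion_class!r}; "
                f"expected one of {MOTION_CLASSES}"
            )
        for name in ("D_micro", "v", "L_box", "sigma_loc", "dt"):
            val = getattr(self, name)
            if not math.isfinite(val):
                raise ValueError(f"{name} must be finite")
            if val < 0:
                raise ValueError(f"{name} must be non-negative")
        if self.motion_class == "corralled" and self.L_box <= 0:
            raise ValueError("L_box must be positive for corralled motion")
        if self.n_frames < 2:
            raise ValueError("n_frames must be >= 2")
        if self.dt <= 0:
            raise ValueError("dt must be positive")
        if self.corral_model not in ("tether", "box"):
            raise ValueError("corral_model must be 'tether' or 'box'")


def gen_trajectory(params: TrajectoryParams, track_id: object = 0) -> Trajectory:
    """Simulate one track according to ``params`` (seeded, reproducible)."""
    rng = np.random.default_rng(params.seed)
    n, dt = params.n_frames, params.dt
    step_sd = np.sqrt(2.0 * params.D_micro * dt)

    if params.motion_class == "stationary":
        pos = np.zeros((n, 2))
    elif params.motion_class == "diffusive":
        steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
    elif params.motion_class == "directed":
        steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
        pos = np.vstack([np.zeros(2), np.cumsum(steps, axis=0)])
        theta = rng.uniform(0.0, 2.0 * np.pi)
        drift = params.v * dt * np.arange(n)
        pos = pos + np.column_stack([drift * np.cos(theta), drift * np.sin(theta)])
    else:  # corralled
        L = params.L_box
        if params.corral_model == "box":
            steps = rng.normal(0.0, step_sd, size=(n - 1, 2))
            raw = rng.uniform(0.0, L, size=2) + np.vstack(
                [np.zeros(2), np.cumsum(steps, axis=0)]
            )
            folded = np.mod(raw, 2.0 * L)
            pos = np.where(folded > L, 2.0 * L - folded, folded)
        else:
            sigma = L / np.sqrt(12.0)
            if params.D_micro == 0:
                pos = np.tile(rng.normal(0.0, sigma, 2), (n, 1))
            else:
                tau = L * L / (12.0 * params.D_micro)
                a = np.exp(-dt / tau)
                innov_sd = sigma * np.sqrt(1.0 - a * a)
                pos = np.empty((n, 2))
                pos[0] = rng.normal(0.0, sigma, 2)
                innov = rng.normal(0.0, innov_sd, size=(n - 1, 2))
                for i in range(1, n):
                    pos[i] = a * pos[i - 1] + innov[i - 1]

    if params.sigma_loc > 0:
        pos = pos + rng.normal(0.0, params.sigma_loc, size=pos.shape)
    return Trajectory(track_id, pos, dt)


def gen_trajectories(
    params: TrajectoryParams, n_tracks: int, seed: int | None = None
) -> list[Trajectory]:
    """Simulate a cohort of independent tracks; per-track seeds are derived
    from ``seed`` (defaults to ``params.seed``)."""
    base = params.seed if seed is None else seed
    ss = np.random.SeedSequence(base).spawn(n_tracks)
    out = []
    for i, child in enumerate(ss):
        sub_seed = int(child.generate_state(1)[0] % (2**31))
        p = TrajectoryParams(
            params.motion_class, params.D_micro, params.v, params.L_box,
            params.sigma_loc, params.n_frames, params.dt, sub_seed,
            params.corral_model,
        )
        out.append(gen_trajectory(p, track_id=i))
    return out


# ---------------------------------------------------------------------------
# allelic transcription traces

@dataclass
class TracePairParams:
    """Parameters of a cohort of paired allelic transcription traces.

    Times are minutes from the cycle start (t0 = 0).  The first allele
    initiates at a gamma-distributed time (``first_init_mean/sd``); the
    second allele is offset by a gamma draw with ``offset_mean/sd``
    (``offset_sd = 0`` gives a point mass).  Each cell carries a shared
    log-normal extrinsic multiplier exp(N(0, extrinsic_sd^2)) on the output
    of both alleles; each allele additionally carries an independent
    intrinsic multiplier.  Traces ramp linearly from initiation to plateau
    over ``plateau_time`` minutes, then fluctuate multiplicatively.  Both the
    raw puncta signal and the local background decay by exp(-t/bleach_tau),
    so the background-normalized activity is bleach-free by construction.
    """

    n_cells: int = 50
    n_timepoints: int = 90
    dt_min: float = 2.0
    offset_mean: float = 44.2
    offset_sd: float = 33.5
    extrinsic_sd: float = 0.4
    intrinsic_sd: float = 0.2
    plateau_time: float = 45.0
    bleach_tau: float = np.inf
    p_silent_second_allele: float = 0.0
    seed: int = 0
    cycle: str = "de_novo"
    first_init_mean: float = 20.0
    first_init_sd: float = 8.0
    amplitude: float = 2.0
    background: float = 100.0
    background_sd: float = 5.0
    fluct_sd: float = 0.05
    measurement_noise: float = 2.0

    def __post_init__(self) -> None:
        for name in (
            "offset_mean", "offset_sd", "extrinsic_sd", "intrinsic_sd",
            "first_init_mean", "first_init_sd", "fluct_sd", "measurement_noise",
        ):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be non-negative")
        if not 0.0 <= self.p_silent_second_allele <= 1.0:
            raise ValueError("p_silent_second_allele must be in [0, 1]")
        if self.n_cells < 1 or self.n_timepoints < 2:
            raise ValueError("need at least 1 cell and 2 time points")
        if self.dt_min <= 0 or self.plateau_time <= 0:
            raise ValueError("dt_min and plateau_time must be positive")


@dataclass
class TraceCohort:
    """Synthetic trace cohort: raw ROI table, ground truth, parsed pairs."""

    raw: pd.DataFrame
    ground_truth: pd.DataFrame
    params: TracePairParams
    pairs: list[AlleleTracePair] = field(default_factory=list)


def _gamma_draw(rng: np.random.Generator, mean: float, sd: float, size: int):
    """Gamma draws parameterized by mean and SD; SD=0 is a point mass."""
    if mean == 0.0 or sd == 0.0:
        return np.full(size, mean)
    shape = (mean / sd) ** 2
    scale = sd * sd / mean
    return rng.gamma(shape, scale, size=size)


def gen_trace_pairs(params: TracePairParams) -> TraceCohort:
    """Simulate a cohort of paired allelic ROI traces (seeded)."""
    rng = np.random.default_rng(params.seed)
    t = params.dt_min * np.arange(params.n_timepoints)
    bleach = (
        np.exp(-t / params.bleach_tau)
        if np.isfinite(params.bleach_tau)
        else np.ones_like(t)
    )

    t1 = _gamma_draw(rng, params.first_init_mean, params.first_init_sd, params.n_cells)
    offsets = _gamma_draw(rng, params.offset_mean, params.offset_sd, params.n_cells)
    silent2 = rng.uniform(size=params.n_cells) < params.p_silent_second_allele
    extr = np.exp(rng.normal(0.0, params.extrinsic_sd, params.n_cells))
    intr = np.exp(rng.normal(0.0, params.intrinsic_sd, (params.n_cells, 2)))

    raw_rows, gt_rows = [], []
    for c in range(params.n_cells):
        inits = (t1[c], t1[c] + offsets[c])
        for allele in (1, 2):
            t_init = inits[allele - 1]
            fires = not (allele == 2 and silent2[c])
            amp = params.amplitude * extr[c] * intr[c, allele - 1]
            if fires:
                ramp = np.clip((t - t_init) / params.plateau_time, 0.0, 1.0)
                fluct = 1.0 + params.fluct_sd * rng.normal(size=len(t))
                activity = amp * ramp * np.clip(fluct, 0.0, None)
            else:
                activity = np.zeros_like(t)
            roi1 = params.background * (1.0 + activity) * bleach
            roi1 = roi1 + params.measurement_noise * rng.normal(size=len(t))
            raw_rows.append(
                pd.DataFrame(
                    {
                        "cell_id": f"cell{c:03d}",
                        "cycle": params.cycle,
                        "t_min": t,
                        "allele": allele,
                        "roi1_max": roi1,
                        "roi2_mean": params.background * bleach,
                        "roi2_sd": params.background_sd * bleach,
                        "identified": True,
                    }
                )
            )
        gt_rows.append(
            {
                "cell_id": f"cell{c:03d}",
                "t_init_allele1_min": t1[c],
                "t_init_allele2_min": np.nan if silent2[c] else t1[c] + offsets[c],
                "offset_min": offsets[c],
                "silent_allele2": bool(silent2[c]),
                "extrinsic_mult": extr[c],
                "intrinsic_mult_allele1": intr[c, 0],
                "intrinsic_mult_allele2": intr[c, 1],
            }
        )
    raw = pd.concat(raw_rows, ignore_index=True)
    cohort = TraceCohort(raw=raw, ground_truth=pd.DataFrame(gt_rows), params=params)
    cohort.pairs = traces_from_table(raw)
    return cohort


# ---------------------------------------------------------------------------
# spot movies

@dataclass
class SpotMovie:
    """2-D image stack with its ground-truth spot parameters."""

    frames: np.ndarray                    # (n_frames, h, w)
    spots: list                           # (x, y, amplitude, width) tuples
    background_mean: float
    noise_sd: float


def gen_spot_movie(
    spots: list[tuple[float, float, float, float]],
    background_mean: float = 100.0,
    noise_sd: float = 0.0,
    n_frames: int = 1,
    seed: int = 0,
    shape: tuple[int, int] = (64, 64),
    bleach_tau_frames: float = np.inf,
) -> SpotMovie:
    """Render frames of 2-D Gaussian spots over background plus read noise.

    Each spot is ``(x, y, amplitude, width)`` in pixel units; ``width`` is
    the Gaussian SD.  A finite ``bleach_tau_frames`` decays spots *and*
    background by exp(-frame/tau), emulating photobleaching of the whole
    field.  Spots outside the frame are clipped with a warning.
    """
    if noise_sd < 0:
        raise ValueError("noise_sd must be non-negative")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    base = np.zeros((h, w))
    for x0, y0, amp, width in spots:
        if width <= 0:
            raise ValueError("spot width must be positive")
        if not (0 <= x0 < w and 0 <= y0 < h):
            warnings.warn(f"spot at ({x0}, {y0}) outside image; clipped", stacklevel=2)
            x0 = float(np.clip(x0, 0, w - 1))
            y0 = float(np.clip(y0, 0, h - 1))
        base += amp * np.exp(-((xx - x0) ** 2 + (yy - y0) ** 2) / (2.0 * width**2))

    rng = np.random.default_rng(seed)
    frames = np.empty((n_frames, h, w))
    for i in range(n_frames):
        decay = (
            np.exp(-i / bleach_tau_frames) if np.isfinite(bleach_tau_frames) else 1.0
        )
        frame = (base + background_mean) * decay
        if noise_sd > 0:
            frame = frame + rng.normal(0.0, noise_sd, size=(h, w))
        frames[i] = frame
    return SpotMovie(frames, list(spots), background_mean, noise_sd)


# ---------------------------------------------------------------------------
# transcriptomes with planted repeats

@dataclass
class PlantedRepeatSpec:
    """A repeat cluster to plant: ``n_copies`` of ``motif`` in one transcript,
    optionally carrying substitutions (copy index, offset, base)."""

    transcript_id: str
    motif: str
    n_copies: int
    mismatch_positions: list = field(default_factory=list)
    spacing: int = 10
    gene_id: str | None = None

    def __post_init__(self) -> None:
        self.motif = self.motif.upper().replace("U", "T")
        if set(self.motif) - set("ACGTN"):
            raise ValueError(f"invalid bases in motif {self.motif!r}")
        if self.n_copies < 1:
            raise ValueError("n_copies must be >= 1")
        k = len(self.motif)
        for copy_idx, offset, base in self.mismatch_positions:
            if not 0 <= offset < k:
                raise ValueError("mismatch offset must be < motif length")
            if not 0 <= copy_idx < self.n_copies:
                raise ValueError("mismatch copy index out of range")
            if base.upper() not in "ACGTN":
                raise ValueError(f"invalid substituted base {base!r}")
        if self.gene_id is None:
            self.gene_id = self.transcript_id


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(np.array(list("ACGT"))[rng.integers(0, 4, size=length)])


def gen_transcriptome(
    specs: list[PlantedRepeatSpec],
    n_decoys: int = 10,
    length_range: tuple[int, int] = (500, 2000),
    seed: int = 0,
) -> tuple[list[SeqRecord], pd.DataFrame]:
    """Build a synthetic transcriptome with planted repeat clusters.

    Returns Biopython records (planted transcripts first, then random
    decoys) and a ground-truth occurrence table with one row per planted
    copy (transcript_id, gene_id, start, end, sequence, n_mismatches).
    """
    rng = np.random.default_rng(seed)
    records, gt_rows = [], []
    lo, hi = length_range
    for spec in specs:
        k = len(spec.motif)
        needed = spec.n_copies * (k + spec.spacing) + spec.spacing
        length = max(int(rng.integers(lo, hi + 1)), needed)
        if k > length:
            raise ValueError(f"motif longer than transcript {spec.transcript_id}")
        seq = list(_random_seq(rng, length))
        # evenly spread start slots, then jitter within the slack
        slack = length - needed
        offset = int(rng.integers(0, slack + 1)) if slack > 0 else 0
        starts = [
            offset + spec.spacing + i * (k + spec.spacing)
            for i in range(spec.n_copies)
        ]
        mismatches = {}
        for copy_idx, off, base in spec.mismatch_positions:
            mismatches.setdefault(copy_idx, []).append((off, base.upper()))
        for i, start in enumerate(starts):
            copy_seq = list(spec.motif)
            for off, base in mismatches.get(i, []):
                copy_seq[off] = base
            seq[start : start + k] = copy_seq
            n_mm = sum(a != b for a, b in zip(copy_seq, spec.motif))
            gt_rows.append(
                {
                    "transcript_id": spec.transcript_id,
                    "gene_id": spec.gene_id,
                    "copy_index": i,
                    "start": start,
                    "end": start + k,
                    "sequence": "".join(copy_seq),
                    "n_mismatches": n_mm,
                }
            )
        records.append(
            SeqRecord(
                Seq("".join(seq)),
                id=spec.transcript_id,
                description=f"gene={spec.gene_id} planted_copies={spec.n_copies}",
            )
        )
    for d in range(n_decoys):
        length = int(rng.integers(lo, hi + 1))
        records.append(
            SeqRecord(
                Seq(_random_seq(rng, length)),
                id=f"decoy{d:04d}",
                description=f"gene=decoy{d:04d} planted_copies=0",
            )
        )
    return records, pd.DataFrame(
        gt_rows,
        columns=[
            "transcript_id", "gene_id", "copy_index", "start", "end",
            "sequence", "n_mismatches",
        ],
    )
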