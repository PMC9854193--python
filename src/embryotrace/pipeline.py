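"""Configuration-driven pipeline driver.

A single YAML/dict config selects stages (simulate -> screen / trace /
noise / spt / denoise) and their parameters; every randomized stage takes a
seed from the config so that a rerun with the same config is bit-identical.
A JSON manifest records the package version, the full config, and the
artifacts written by each stage.
"""

from __future__ import annotations

import logging
from pathlib import Path

import numpy as np
import yaml

from . import __version__, io
from . import denoise as _denoise
from . import noise_decomp, repeat_screen, spt, synth, trace_quant

logger = logging.getLogger("embryotrace")

STAGES = (
    "simulate_traj", "simulate_traces", "simulate_movie",
    "simulate_transcriptome", "screen", "trace", "noise", "spt", "denoise",
)

_SCHEMA: dict[str, set[str]] = {
    "": {"seed", "stages", "trajectories", "traces", "movie", "transcriptome",
         "screen", "trace", "noise", "spt", "denoise"},
    "trajectories": {"motion_class", "n_tracks", "D_micro", "v", "L_box",
                     "sigma_loc", "n_frames", "dt", "corral_model"},
    "traces": {"n_cells", "n_timepoints", "dt_min", "offset_mean", "offset_sd",
               "extrinsic_sd", "intrinsic_sd", "plateau_time", "bleach_tau",
               "p_silent_second_allele", "cycle", "first_init_mean",
               "first_init_sd", "amplitude", "background", "fluct_sd",
               "measurement_noise"},
    "movie": {"spots", "background_mean", "noise_sd", "n_frames", "shape",
              "bleach_tau_frames"},
    "transcriptome": {"specs", "n_decoys", "length_range"},
    "screen": {"fasta", "gene_map", "k", "max_mismatch", "min_repeats",
               "topology", "tolerant_cross_gene"},
    "trace": {"traces", "threshold", "same_time_window", "min_consecutive"},
    "noise": {"traces", "shuffle_seed", "n_shuffles"},
    "spt": {"tracks", "dt", "min_frames"},
    "denoise": {"movie", "lam", "mu", "psf_sigma", "max_iter"},
}


class ConfigError(ValueError):
    pass


def load_config(path) -> dict:
    config = yaml.safe_load(Path(path).read_text())
    validate_config(config)
    return config


def validate_config(config: dict) -> None:
    if not isinstance(config, dict):
        raise ConfigError("config must be a mapping")
    unknown = set(config) - _SCHEMA[""]
    if unknown:
        raise ConfigError(f"unknown config keys: {sorted(unknown)}")
    for stage in config.get("stages", []):
        if stage not in STAGES:
            raise ConfigError(f"unknown stage: {stage!r}")
    for section, allowed in _SCHEMA.items():
        if section and section in config:
            if not isinstance(config[section], dict):
                raise ConfigError(f"section {section!r} must be a mapping")
            bad = set(config[section]) - allowed
            if bad:
                raise ConfigError(
                    f"unknown keys in section {section!r}: {sorted(bad)}"
                )
    # inputs referenced by analysis stages must exist before anything runs
    for stage, key in (("screen", "fasta"), ("trace", "traces"),
                       ("noise", "traces"), ("spt", "tracks"),
                       ("denoise", "movie")):
        if stage in config.get("stages", []):
            section = config.get(stage, {})
            path = section.get(key)
            if path is not None and not Path(path).exists():
                raise ConfigError(f"stage {stage!r}: missing input {path}")


def run_pipeline(config: dict, out_dir) -> Path:
    """Execute the configured stages; returns the artifact directory."""
    validate_config(config)
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    seed = int(config.get("seed", 0))
    manifest = {"version": __version__, "seed": seed, "config": config,
                "stages": {}}

    for stage in config.get("stages", []):
        artifacts = _run_stage(stage, config, out, seed)
        manifest["stages"][stage] = artifacts
        logger.info("stage %s -> %s", stage, artifacts)
    io.write_json(manifest, out / "manifest.json")
    return out


def _run_stage(stage: str, config: dict, out: Path, seed: int) -> dict:
    section = dict(config.get(_section_name(stage), {}))
    if stage == "simulate_traj":
        n_tracks = int(section.pop("n_tracks", 10))
        params = synth.TrajectoryParams(seed=seed, **section)
        trajs = synth.gen_trajectories(params, n_tracks)
        path = out / "tracks.csv"
        io.write_tracks(io.trajectories_to_table(trajs), path)
        return {"tracks": str(path), "n_tracks": n_tracks}
    if stage == "simulate_traces":
        cohort = synth.gen_trace_pairs(synth.TracePairParams(seed=seed, **section))
        path, gt = out / "traces.csv", out / "traces_ground_truth.csv"
        io.write_traces(cohort.raw, path)
        cohort.ground_truth.to_csv(gt, index=False)
        return {"traces": str(path), "ground_truth": str(gt)}
    if stage == "simulate_movie":
        spots = [tuple(s) for s in section.pop("spots", [])]
        if "shape" in section:
            section["shape"] = tuple(section["shape"])
        movie = synth.gen_spot_movie(spots, seed=seed, **section)
        path = out / "movie.tif"
        io.write_movie(movie.frames, path)
        gt = out / "movie_ground_truth.csv"
        import pandas as pd

        pd.DataFrame(movie.spots, columns=["x", "y", "amplitude", "width"]).to_csv(
            gt, index=False
        )
        return {"movie": str(path), "ground_truth": str(gt)}
    if stage == "simulate_transcriptome":
        specs = [synth.PlantedRepeatSpec(**s) for s in section.pop("specs", [])]
        if "length_range" in section:
            section["length_range"] = tuple(section["length_range"])
        records, gt = synth.gen_transcriptome(specs, seed=seed, **section)
        path = out / "transcriptome.fasta"
        io.write_fasta(records, path)
        gt_path = out / "transcriptome_ground_truth.csv"
        gt.to_csv(gt_path, index=False)
        return {"fasta": str(path), "ground_truth": str(gt_path)}
    if stage == "screen":
        records = io.read_fasta(section["fasta"])
        gene_map = io.read_gene_map(section["gene_map"]) if section.get("gene_map") else {}
        transcripts = [
            repeat_screen.Transcript(r.id, str(r.seq), gene_map.get(r.id))
            for r in records
        ]
        result = repeat_screen.screen_transcripts(
            transcripts,
            k=int(section.get("k", 20)),
            max_mismatch=int(section.get("max_mismatch", 1)),
            topology=section.get("topology", "pairwise"),
        )
        result = repeat_screen.cross_gene_uniqueness_filter(
            result, tolerant=bool(section.get("tolerant_cross_gene", True))
        )
        result = repeat_screen.select_candidates(
            result, min_repeats=int(section.get("min_repeats", 8))
        )
        path = out / "clusters.tsv"
        io.write_clusters(result, path)
        io.write_json(result.summary, out / "screen_summary.json")
        return {"clusters": str(path), "summary": result.summary}
    if stage == "trace":
        raw = io.read_traces(section["traces"])
        pairs = trace_quant.traces_from_table(raw)
        thr = section.get("threshold", "auto")
        records = []
        for pair in pairs:
            threshold = (
                trace_quant.mad_threshold(
                    np.concatenate([pair.allele1, pair.allele2]),
                    np.concatenate([pair.t_min, pair.t_min]),
                    pair.t0 + 1e-9,
                )
                if thr == "auto"
                else float(thr)
            )
            records.append(
                trace_quant.classify_activation(
                    pair,
                    threshold,
                    same_time_window=float(section.get("same_time_window", 5.0)),
                    min_consecutive=int(section.get("min_consecutive", 2)),
                )
            )
        import pandas as pd

        table = pd.DataFrame([r.__dict__ for r in records])
        path = out / "activation_records.csv"
        table.to_csv(path, index=False)
        summary, pval = trace_quant.memory_statistics(records)
        io.write_json(
            {"groups": summary.to_dict("records"), "t_test_p": pval},
            out / "memory_summary.json",
        )
        return {"records": str(path)}
    if stage == "noise":
        raw = io.read_traces(section["traces"])
        pairs = trace_quant.traces_from_table(raw)
        outputs = noise_decomp.allele_outputs(pairs)
        report = noise_decomp.allele_correlation(outputs)
        control = noise_decomp.random_pair_control(
            outputs,
            seed=int(section.get("shuffle_seed", seed)),
            n_shuffles=int(section.get("n_shuffles", 1)),
        )
        series = noise_decomp.per_timepoint_correlation(pairs)
        series.to_csv(out / "per_timepoint_r.csv", index=False)
        outputs.to_csv(out / "allele_outputs.tsv", sep="\t", index=False)
        io.write_json(
            {"paired": report.__dict__, "shuffled": control.__dict__},
            out / "correlation_report.json",
        )
        return {"report": str(out / "correlation_report.json")}
    if stage == "spt":
        tracks = io.read_tracks(section["tracks"])
        tracks = spt.filter_tracks(tracks, int(section.get("min_frames", 20)))
        trajs = spt.tracks_from_table(tracks, dt=section.get("dt"))
        table = spt.classify_cohort(trajs)
        path = out / "motion_classes.csv"
        table.to_csv(path, index=False)
        return {"classes": str(path), "n_tracks": len(trajs)}
    if stage == "denoise":
        frames = io.read_movie(section["movie"])
        den = _denoise.denoise_stack(
            frames,
            psf_sigma=float(section.get("psf_sigma", 1.3)),
            lam=float(section.get("lam", 0.01)),
            mu=float(section.get("mu", 0.1)),
            max_iter=int(section.get("max_iter", 200)),
        )
        path = out / "denoised.tif"
        io.write_movie(den, path)
        return {"denoised": str(path)}
    raise ConfigError(f"unknown stage: {stage!r}")


def _section_name(stage: str) -> str:
    return {
        "simulate_traj": "trajectories",
        "simulate_traces": "traces",
        "simulate_movie": "movie",
        "simulate_transcriptome": "transcriptome",
    }.get(stage, stage)
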