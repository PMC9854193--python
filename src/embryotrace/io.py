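"""Readers and writers for the pipeline's on-disk formats.

Tables are CSV/TSV with unit-suffixed column names (t_s, x_um, t_min, ...)
to prevent unit drift; sequences are 60-column-wrapped FASTA; movies are
multi-page TIFF stacks.  Every writer's output round-trips through the
corresponding reader.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd
import tifffile
from Bio import SeqIO

TRACK_COLUMNS = ["track_id", "frame", "t_s", "x_um", "y_um"]
TRACE_COLUMNS = [
    "cell_id", "cycle", "t_min", "allele", "roi1_max", "roi2_mean", "roi2_sd",
    "identified",
]


def write_tracks(tracks: pd.DataFrame, path) -> None:
    tracks[TRACK_COLUMNS].to_csv(path, index=False)


def read_tracks(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    missing = set(TRACK_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing track columns {sorted(missing)}")
    return df


def trajectories_to_table(trajectories) -> pd.DataFrame:
    return pd.concat([t.to_dataframe() for t in trajectories], ignore_index=True)


def write_traces(traces: pd.DataFrame, path) -> None:
    cols = [c for c in TRACE_COLUMNS if c in traces.columns]
    traces[cols].to_csv(path, index=False)


def read_traces(path) -> pd.DataFrame:
    df = pd.read_csv(path)
    required = set(TRACE_COLUMNS) - {"identified", "roi2_sd"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"{path}: missing trace columns {sorted(missing)}")
    return df


def write_fasta(records, path) -> None:
    # Biopython's default fasta writer wraps at 60 columns
    SeqIO.write(records, str(path), "fasta")


def read_fasta(path):
    return list(SeqIO.parse(str(path), "fasta"))


def read_gene_map(path) -> dict:
    """Two-column TSV transcript_id -> gene_id."""
    df = pd.read_csv(path, sep="\t", header=None, names=["transcript_id", "gene_id"])
    return dict(zip(df["transcript_id"], df["gene_id"]))


def write_clusters(result, path) -> None:
    result.to_table().to_csv(path, sep="\t", index=False)


def write_movie(frames: np.ndarray, path) -> None:
    tifffile.imwrite(
        str(path), np.asarray(frames, dtype=np.float32), photometric="minisblack"
    )


def read_movie(path) -> np.ndarray:
    frames = tifffile.imread(str(path))
    return frames[None] if frames.ndim == 2 else frames


def write_json(obj, path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, default=_json_default) + "\n")


def read_json(path):
    return json.loads(Path(path).read_text())


def _json_default(o):
    if isinstance(o, (np.integer,)):
        return int(o)
    if isinstance(o, (np.floating,)):
        return float(o)
    if isinstance(o, np.ndarray):
        return o.tolist()
    raise TypeError(f"not JSON serializable: {type(o)}")
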