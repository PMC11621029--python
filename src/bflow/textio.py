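"""Plain-text persistence for label sequences and transition matrices."""

from __future__ import annotations

import numpy as np
import pandas as pd
import yaml

from bflow.flow import LabelSequence, TransitionMatrix


def write_labels(seq: LabelSequence, path) -> None:
    """Two-column CSV: frame (original index) and cluster id."""
    frames = np.arange(len(seq)) + seq.frame_offset
    pd.DataFrame({"frame": frames, "cluster": seq.labels}).to_csv(path, index=False)


def read_labels(path, alphabet=None, fps: float = 25.0,
                recording_id: str | None = None) -> LabelSequence:
    """Read a two-column (frame, cluster) CSV; external labels welcome."""
    df = pd.read_csv(path)
    if "cluster" not in df.columns:
        raise ValueError("label CSV needs a 'cluster' column")
    labels = df["cluster"].to_numpy()
    offset = int(df["frame"].iloc[0]) if "frame" in df.columns else 0
    rid = recording_id or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    if alphabet is None:
        alphabet = np.unique(labels)
    return LabelSequence(recording_id=rid, labels=labels, alphabet=alphabet,
                         fps=fps, frame_offset=offset)


def write_matrix(T: TransitionMatrix, path) -> None:
    """Square CSV with cluster-id header and index."""
    pd.DataFrame(T.counts, index=T.alphabet, columns=T.alphabet).to_csv(path)


def read_matrix(path, recording_id: str | None = None) -> TransitionMatrix:
    df = pd.read_csv(path, index_col=0)
    alphabet = np.array([int(c) for c in df.columns])
    rid = recording_id or str(path).rsplit("/", 1)[-1].rsplit(".", 1)[0]
    return TransitionMatrix(counts=df.to_numpy(), alphabet=alphabet,
                            recording_id=rid)


def read_group_manifest(path) -> pd.DataFrame:
    """CSV manifest with columns recording_id, group and optionally path/dose."""
    df = pd.read_csv(path)
    for col in ("recording_id", "group"):
        if col not in df.columns:
            raise ValueError(f"manifest is missing column {col!r}")
    return df


def load_arena_config(path) -> dict:
    """YAML arena/zone config: corner names, real size, thresholds."""
    with open(path) as fh:
        cfg = yaml.safe_load(fh)
    cfg.setdefault("corner_names", list(cfg.get("corners", [])))
    return cfg
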