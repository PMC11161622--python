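"""Readers and writers for the pipeline's plain-text formats.

* word2vec text embeddings: a header line ``vocab_size dim`` followed by
  ``word v1 ... vD`` lines;
* thought-stream tables: CSV with participant_id, item_id, position, word;
* atlas lookups: TSV with node_id (1-based), network_label, optional
  x/y/z coordinates;
* connectivity matrices: one whitespace-delimited square matrix per
  participant plus a manifest CSV (participant_id, path);
* behavior, rating and trial tables: CSV with the column names documented
  on the consuming functions.
"""

from __future__ import annotations

import os

import numpy as np
import pandas as pd

from .connectome import Atlas
from .semantic import EmbeddingSpace, ThoughtStream

__all__ = [
    "read_word2vec_text",
    "write_word2vec_text",
    "read_streams_csv",
    "write_streams_csv",
    "read_atlas_tsv",
    "write_atlas_tsv",
    "read_fc_matrix",
    "write_fc_matrix",
    "write_fc_cohort",
    "read_fc_cohort",
]


def read_word2vec_text(path) -> EmbeddingSpace:
    vectors: dict[str, np.ndarray] = {}
    with open(path) as fh:
        header = fh.readline().split()
        if len(header) != 2:
            raise ValueError("expected a 'vocab_size dim' header line")
        vocab_size, dim = int(header[0]), int(header[1])
        for line in fh:
            parts = line.rstrip("\n").split(" ")
            if len(parts) != dim + 1:
                raise ValueError(
                    f"bad vector line for {parts[0]!r}: expected {dim} values"
                )
            vectors[parts[0]] = np.array(parts[1:], dtype=float)
    if len(vectors) != vocab_size:
        raise ValueError(
            f"header promised {vocab_size} words, file contains {len(vectors)}"
        )
    return EmbeddingSpace(vectors)


def write_word2vec_text(space: EmbeddingSpace, path) -> None:
    with open(path, "w") as fh:
        fh.write(f"{len(space)} {space.dim}\n")
        for word in sorted(space.vocabulary):
            vec = " ".join(f"{v:.8g}" for v in space[word])
            fh.write(f"{word} {vec}\n")


def write_streams_csv(streams: list[ThoughtStream], path) -> None:
    rows = [
        (s.participant_id, s.item_id, s.cue, pos + 1, word)
        for s in streams
        for pos, word in enumerate(s.responses)
    ]
    pd.DataFrame(
        rows, columns=["participant_id", "item_id", "cue", "position", "word"]
    ).to_csv(path, index=False)


def read_streams_csv(path) -> list[ThoughtStream]:
    df = pd.read_csv(path)
    streams = []
    for (pid, item), grp in df.groupby(["participant_id", "item_id"], sort=False):
        grp = grp.sort_values("position")
        streams.append(
            ThoughtStream(
                participant_id=str(pid),
                item_id=str(item),
                cue=str(grp["cue"].iloc[0]) if "cue" in grp else str(item),
                responses=[str(w) for w in grp["word"]],
            )
        )
    return streams


def write_atlas_tsv(atlas: Atlas, path) -> None:
    pd.DataFrame(
        {
            "node_id": np.arange(1, atlas.n_nodes + 1),  # 1-based in files
            "network_label": atlas.network_labels,
        }
    ).to_csv(path, sep="\t", index=False)


def read_atlas_tsv(path) -> Atlas:
    df = pd.read_csv(path, sep="\t")
    if not {"node_id", "network_label"} <= set(df.columns):
        raise ValueError("atlas TSV needs node_id and network_label columns")
    df = df.sort_values("node_id")
    expected = np.arange(1, len(df) + 1)
    if not np.array_equal(df["node_id"].to_numpy(), expected):
        raise ValueError("node_id must be contiguous 1-based ids")
    return Atlas(list(df["network_label"]), name=os.path.basename(str(path)))


def write_fc_matrix(matrix: np.ndarray, path) -> None:
    np.savetxt(path, np.asarray(matrix, dtype=float), fmt="%.8g")


def read_fc_matrix(path) -> np.ndarray:
    m = np.loadtxt(path)
    if m.ndim != 2 or m.shape[0] != m.shape[1]:
        raise ValueError(f"{path}: expected a square matrix")
    return m


def write_fc_cohort(matrices: np.ndarray, ids: list[str], directory) -> str:
    """One matrix file per participant plus a manifest CSV; returns the
    manifest path."""
    os.makedirs(directory, exist_ok=True)
    records = []
    for pid, mat in zip(ids, matrices):
        fname = f"fc_{pid}.txt"
        write_fc_matrix(mat, os.path.join(directory, fname))
        records.append({"participant_id": pid, "path": fname})
    manifest = os.path.join(directory, "manifest.csv")
    pd.DataFrame(records).to_csv(manifest, index=False)
    return manifest


def read_fc_cohort(manifest_path) -> tuple[np.ndarray, list[str]]:
    manifest = pd.read_csv(manifest_path)
    base = os.path.dirname(str(manifest_path))
    mats, ids = [], []
    for _, row in manifest.iterrows():
        mats.append(read_fc_matrix(os.path.join(base, row["path"])))
        ids.append(str(row["participant_id"]))
    return np.stack(mats), ids
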