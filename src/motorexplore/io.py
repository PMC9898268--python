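"""File formats: angle CSV, label TSV, CRP matrices, manifests, FASTA.

The angle CSV dialect is UTF-8, comma-separated, with the header
``learner,session,trial,speed,t_s,elbow_deg,knee_deg``; times in seconds,
angles in degrees, one trial contiguous.  Labels travel as a tab-separated
table ``learner<TAB>speed<TAB>cycle_index<TAB>session<TAB>trial<TAB>pattern``
with a 0-based chronological cycle index per learner x speed.  Every output
directory gets a JSON manifest naming the package version, the config hash
and the seeds used.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .kinematics import JointAngleTrace

ANGLE_COLUMNS = ["learner", "session", "trial", "speed", "t_s",
                 "elbow_deg", "knee_deg"]
LABEL_COLUMNS = ["learner", "speed", "cycle_index", "session", "trial",
                 "pattern"]

__all__ = [
    "write_angle_csv", "read_angle_csv", "write_labels_tsv",
    "read_labels_tsv", "write_crp_csv", "read_crp_csv",
    "write_manifest", "config_hash", "read_fasta_sequences",
]


def write_angle_csv(traces: list[JointAngleTrace], path) -> None:
    frames = []
    for tr in traces:
        frames.append(pd.DataFrame({
            "learner": tr.meta.get("learner", 0),
            "session": tr.meta.get("session", 0),
            "trial": tr.meta.get("trial", 0),
            "speed": tr.meta.get("speed", "low"),
            "t_s": tr.t,
            "elbow_deg": tr.elbow,
            "knee_deg": tr.knee,
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_angle_csv(path) -> list[JointAngleTrace]:
    """Read the angle CSV dialect back into one trace per trial."""
    df = pd.read_csv(path)
    missing = set(ANGLE_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"angle CSV missing columns: {sorted(missing)}")
    traces = []
    keys = ["learner", "speed", "session", "trial"]
    for key, grp in df.groupby(keys, sort=True):
        meta = dict(zip(keys, key))
        traces.append(JointAngleTrace(grp["t_s"].to_numpy(),
                                      grp["elbow_deg"].to_numpy(),
                                      grp["knee_deg"].to_numpy(), meta=meta))
    return traces


def write_labels_tsv(df: pd.DataFrame, path) -> None:
    df[LABEL_COLUMNS].to_csv(path, sep="\t", index=False)


def read_labels_tsv(path) -> pd.DataFrame:
    df = pd.read_csv(path, sep="\t")
    missing = set(LABEL_COLUMNS) - set(df.columns)
    if missing:
        raise ValueError(f"labels TSV missing columns: {sorted(missing)}")
    return df


def write_crp_csv(crp: np.ndarray, path, meta: pd.DataFrame | None = None
                  ) -> None:
    """Per-cycle CRP matrix: rows are cycles in chronological order,
    columns the L grid points.  A metadata sidecar goes next to it."""
    path = Path(path)
    pd.DataFrame(crp).to_csv(path, index=False,
                             header=[f"p{i}" for i in range(crp.shape[1])])
    if meta is not None:
        meta.to_csv(path.with_suffix(".meta.csv"), index=False)


def read_crp_csv(path) -> np.ndarray:
    return pd.read_csv(path).to_numpy(dtype=float)


def config_hash(config: dict) -> str:
    text = json.dumps(config, sort_keys=True, default=str)
    return hashlib.sha256(text.encode()).hexdigest()[:12]


def write_manifest(outdir, config: dict, seed, stages: dict) -> Path:
    from . import __version__

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest = {
        "package": "motorexplore",
        "version": __version__,
        "config_hash": config_hash(config),
        "seed": seed,
        "config": config,
        "stages": stages,
    }
    path = outdir / "manifest.json"
    path.write_text(json.dumps(manifest, indent=1, default=str))
    return path


def read_fasta_sequences(path) -> dict[str, str]:
    """Read sequences from a FASTA file (lowercased), e.g. to model
    nucleotide chains with the drifting Markov machinery."""
    from Bio import SeqIO

    return {rec.id: str(rec.seq).lower()
            for rec in SeqIO.parse(str(path), "fasta")}
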