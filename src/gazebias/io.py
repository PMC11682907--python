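"""Tidy TSV readers/writers with provenance headers and column validation.

All files are UTF-8, tab-separated, with a mandatory header row.  Writers
prepend '#'-prefixed provenance lines (package version, seed, config hash);
readers skip them.  Times are milliseconds throughout.
"""

from __future__ import annotations

import hashlib
import json
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from . import __version__

EXPECTED_COLUMNS = {
    "samples": ["subject_id", "trial_id", "t_ms", "x_px", "y_px", "valid"],
    "trials": ["subject_id", "trial_id", "condition", "emotional_side", "left_image", "right_image"],
    "participants": ["subject_id", "group", "age", "bdi_sum"]
    + [f"erq_r{i}" for i in range(1, 7)]
    + [f"erq_s{i}" for i in range(1, 5)],
    "manifest": ["subject_id", "trial_id", "artifact"],
    "dwell": [
        "subject_id",
        "trial_id",
        "condition",
        "emotional_side",
        "dwell_left_ms",
        "dwell_right_ms",
        "dwell_emotional_ms",
        "dwell_neutral_ms",
        "first_saccade_latency_ms",
        "n_samples_total",
        "start_in_aoi",
    ],
    "bias": ["subject_id", "trial_id", "condition", "bias", "dwell_total_ms"],
}


class IoError(ValueError):
    pass


def config_hash(config: Mapping) -> str:
    return hashlib.sha256(json.dumps(config, sort_keys=True, default=str).encode()).hexdigest()[:12]


def write_tsv(
    frame: pd.DataFrame,
    path: str | Path,
    provenance: Mapping[str, object] | None = None,
) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    with open(path, "w", encoding="utf-8", newline="\n") as fh:
        fh.write(f"# gazebias {__version__}\n")
        for key, value in (provenance or {}).items():
            fh.write(f"# {key}: {value}\n")
        frame.to_csv(fh, sep="\t", index=False, float_format="%.6g", lineterminator="\n")


def read_tsv(path: str | Path, kind: str | None = None) -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise IoError(f"input file not found: {path}")
    frame = pd.read_csv(path, sep="\t", comment="#")
    if kind is not None:
        expected = EXPECTED_COLUMNS[kind]
        missing = [c for c in expected if c not in frame.columns]
        if missing:
            raise IoError(
                f"{path}: malformed {kind} table, missing columns {missing}; expected header {expected}"
            )
    return frame


def validate_sorted_samples(samples: pd.DataFrame, path: str | Path = "<samples>") -> None:
    """Raise naming the offending trial if timestamps run backwards."""
    for (subj, trial), g in samples.groupby(["subject_id", "trial_id"], sort=False):
        t = g["t_ms"].to_numpy()
        if (t[1:] < t[:-1]).any():
            raise IoError(f"{path}: samples of subject {subj} trial {trial} are not sorted by t_ms")
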