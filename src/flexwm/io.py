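"""Reading and writing the package's on-disk formats.

Trial tables travel as delimited text; BOLD-like datasets as a binary
matrix (.npy, voxels x trials x time) next to the trial table and a JSON
ground-truth sidecar.  Generic matrix inputs (trials x voxels x time
with a label table) can be loaded into a BoldDataset for analysis.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .synthetic_bold import BoldDataset


def write_trial_table(trials: pd.DataFrame, path) -> None:
    trials.to_csv(path, sep="\t", index=False)


def read_trial_table(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t")


def write_dataset(dataset: BoldDataset, prefix) -> None:
    """Write <prefix>.npy, <prefix>.trials.tsv and <prefix>.json."""
    prefix = Path(prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    np.save(prefix.with_suffix(".npy"), dataset.signal)
    write_trial_table(dataset.trials, prefix.with_suffix(".trials.tsv"))
    meta = {"subject_id": dataset.subject_id, "tr": dataset.tr}
    gt = dataset.ground_truth
    if gt is not None:
        meta["ground_truth"] = {
            "n_voxels": gt.n_voxels,
            "tuning_exponent": gt.tuning_exponent,
            "seed": gt.seed,
            "profile": gt.profile.name,
        }
    prefix.with_suffix(".json").write_text(json.dumps(meta, indent=2))


def read_dataset(prefix) -> BoldDataset:
    prefix = Path(prefix)
    signal = np.load(prefix.with_suffix(".npy"))
    trials = read_trial_table(prefix.with_suffix(".trials.tsv"))
    meta = json.loads(prefix.with_suffix(".json").read_text())
    return BoldDataset(
        signal=signal, trials=trials, subject_id=meta.get("subject_id", "sub-00"),
        tr=meta.get("tr", 1.0),
    )


def from_matrix(matrix: np.ndarray, labels: pd.DataFrame, order: str = "trials_first") -> BoldDataset:
    """Wrap a generic matrix (trials x voxels x time, or voxels x trials x
    time with ``order='voxels_first'``) and a label table for analysis."""
    m = np.asarray(matrix, dtype=float)
    if m.ndim != 3:
        raise ValueError("matrix must be 3-dimensional")
    if order == "trials_first":
        m = np.transpose(m, (1, 0, 2))
    elif order != "voxels_first":
        raise ValueError("order must be 'trials_first' or 'voxels_first'")
    return BoldDataset(signal=m, trials=labels)
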