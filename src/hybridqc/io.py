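"""Readers and writers for the pipeline's tabular and volumetric formats.

Conventions: participants as BIDS-style TSV, ratings/metrics/profiles
as CSV, volumes as NIfTI (4 channels in a 4D image), JSON sidecars for
configuration and seeds.
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

__all__ = [
    "SCORE_COLUMNS",
    "read_participants",
    "write_participants",
    "read_expert_ratings",
    "write_expert_ratings",
    "save_volume",
    "load_volume",
    "write_sidecar",
]

#: Released QC score columns, all bounded in [0, 1] when present.
SCORE_COLUMNS = [
    "expert_qc_score",
    "xgb_qc_score",
    "xgb_qsiprep_qc_score",
    "dl_qc_score",
]


def _validate_participants(table: pd.DataFrame) -> None:
    if "participant_id" not in table.columns:
        raise ValueError("participants table requires a participant_id column")
    duplicated = table["participant_id"].duplicated()
    if duplicated.any():
        rows = (table.index[duplicated] + 1).tolist()
        raise ValueError(f"duplicate participant_id at rows {rows}")
    for column in SCORE_COLUMNS:
        if column not in table.columns:
            continue
        values = pd.to_numeric(table[column], errors="coerce")
        bad = values.notna() & ((values < 0) | (values > 1))
        if bad.any():
            rows = (table.index[bad] + 1).tolist()
            raise ValueError(
                f"{column} outside [0, 1] at rows {rows}"
            )


def read_participants(path: str | Path) -> pd.DataFrame:
    """Read a participants TSV, validating ids and score bounds.

    Unknown columns are preserved; score columns parse as floats with
    blanks as missing.
    """
    table = pd.read_csv(path, sep="\t")
    _validate_participants(table)
    for column in SCORE_COLUMNS:
        if column in table.columns:
            table[column] = pd.to_numeric(table[column])
    return table


def write_participants(table: pd.DataFrame, path: str | Path) -> None:
    _validate_participants(table.reset_index(drop=True))
    table.to_csv(path, sep="\t", index=False)


def read_expert_ratings(path: str | Path, form: str = "wide") -> pd.DataFrame:
    """Read expert ratings from CSV.

    ``wide``: participant_id index, one column per rater, blanks
    missing.  ``long``: columns participant_id, rater_id, rating,
    pivoted to wide on read.
    """
    if form == "wide":
        return pd.read_csv(path, index_col="participant_id")
    if form == "long":
        long = pd.read_csv(path)
        return long.pivot(
            index="participant_id", columns="rater_id", values="rating"
        )
    raise ValueError("form must be 'wide' or 'long'")


def write_expert_ratings(
    ratings: pd.DataFrame, path: str | Path, form: str = "wide"
) -> None:
    if form == "wide":
        ratings.to_csv(path)
    elif form == "long":
        long = ratings.reset_index(names="participant_id").melt(
            id_vars="participant_id", var_name="rater_id", value_name="rating"
        )
        long.dropna(subset=["rating"]).to_csv(path, index=False)
    else:
        raise ValueError("form must be 'wide' or 'long'")


def save_volume(volume: np.ndarray, path: str | Path) -> None:
    """Write a (channels, D, H, W) volume as a 4D NIfTI (channels last)."""
    img = nib.Nifti1Image(
        np.moveaxis(np.asarray(volume), 0, -1).astype(np.float32), affine=np.eye(4)
    )
    nib.save(img, str(path))


def load_volume(path: str | Path) -> np.ndarray:
    img = nib.load(str(path))
    data = np.asarray(img.dataobj, dtype=np.float32)
    if data.ndim != 4:
        raise ValueError(f"expected a 4D (D, H, W, channels) image, got {data.ndim}D")
    return np.moveaxis(data, -1, 0)


def write_sidecar(payload: dict, path: str | Path) -> None:
    """JSON sidecar with run provenance (config, seeds, versions)."""
    Path(path).write_text(json.dumps(payload, indent=2, sort_keys=True, default=str))
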