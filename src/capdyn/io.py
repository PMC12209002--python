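"""Readers and writers for every on-disk artifact of the pipeline.

Parcel-level BOLD time series travel as tab-separated text (frames x
parcels, header row of parcel IDs); censored frames are stored as all-NaN
rows.  Tabular artifacts (manifest, behavior, metrics) are UTF-8 CSV with
header; configuration and ground truth are YAML/JSON.  Optional NIfTI
support (4D image + 3D integer-label atlas -> parcel time series) is
isolated here so the rest of the pipeline never needs imaging libraries.
"""

from __future__ import annotations

import json
import logging
import warnings
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

log = logging.getLogger(__name__)

#: Known neuropsychological scores and the direction of impairment.
SCORE_ORIENTATION = {
    "TMTA": "higher_worse",
    "TMTB": "higher_worse",
    "TMTBA": "higher_worse",
    "AttentionalMatrices": "higher_better",
}

TIMEPOINTS = ("pre", "1w", "3m")


class ParseError(ValueError):
    """Malformed on-disk artifact (carries file/line context in message)."""


@dataclass
class ParcelTimeSeries:
    """One subject-session matrix of BOLD values (frames x parcels).

    ``censor_mask`` marks usable frames (True = usable); transitions across
    censored gaps are never counted downstream.
    """

    values: np.ndarray
    tr_seconds: float = 2.0
    censor_mask: np.ndarray | None = None
    subject_id: str = ""
    session_id: str = ""
    parcel_ids: list[str] = field(default_factory=list)

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("time series must be a 2-D frames x parcels matrix")
        if self.censor_mask is None:
            self.censor_mask = np.ones(self.values.shape[0], dtype=bool)
        self.censor_mask = np.asarray(self.censor_mask, dtype=bool)
        if self.censor_mask.shape[0] != self.values.shape[0]:
            raise ValueError("censor_mask length must equal frame count")
        if not self.parcel_ids:
            self.parcel_ids = [f"p{j:03d}" for j in range(self.values.shape[1])]
        if len(self.parcel_ids) != self.values.shape[1]:
            raise ValueError("parcel_ids length must equal parcel count")
        if len(set(self.parcel_ids)) != len(self.parcel_ids):
            raise ValueError("parcel_ids must be unique")
        if self.tr_seconds <= 0:
            raise ValueError("tr_seconds must be positive")
        usable = self.values[self.censor_mask]
        if usable.size and not np.all(np.isfinite(usable)):
            bad = np.argwhere(~np.isfinite(usable))
            raise ValueError(
                f"non-finite value among usable frames (first at usable frame "
                f"{bad[0][0]}, parcel {bad[0][1]})"
            )

    @property
    def n_frames(self) -> int:
        return self.values.shape[0]

    @property
    def n_parcels(self) -> int:
        return self.values.shape[1]

    @property
    def n_usable(self) -> int:
        return int(self.censor_mask.sum())


@dataclass
class SeedDefinition:
    """A named set of parcel indices acting as the seed region (FPN, DAN, ...)."""

    name: str
    parcel_indices: np.ndarray

    def __post_init__(self) -> None:
        self.parcel_indices = np.asarray(self.parcel_indices, dtype=int)
        if self.parcel_indices.size == 0:
            raise ValueError(f"seed '{self.name}' has no parcels")
        if len(np.unique(self.parcel_indices)) != self.parcel_indices.size:
            raise ValueError(f"seed '{self.name}' has duplicate parcel indices")
        if np.any(self.parcel_indices < 0):
            raise ValueError(f"seed '{self.name}' has negative parcel indices")

    def validate_against(self, n_parcels: int) -> None:
        if np.any(self.parcel_indices >= n_parcels):
            raise ValueError(
                f"seed '{self.name}' references parcel >= {n_parcels}"
            )


def write_timeseries(series: ParcelTimeSeries, path: str | Path) -> None:
    """Write frames x parcels TSV; censored frames become all-NaN rows."""
    path = Path(path)
    out = series.values.astype(float).copy()
    out[~series.censor_mask] = np.nan
    with open(path, "w", encoding="utf-8") as fh:
        fh.write("\t".join(series.parcel_ids) + "\n")
        for row in out:
            fh.write("\t".join(f"{v:.17g}" for v in row) + "\n")


def read_timeseries(
    path: str | Path,
    tr_seconds: float = 2.0,
    subject_id: str = "",
    session_id: str = "",
) -> ParcelTimeSeries:
    """Read a frames x parcels TSV written by :func:`write_timeseries`.

    An all-NaN row is interpreted as a censored frame; a NaN in a partially
    finite row is a parse error (NaN in a usable frame).
    """
    path = Path(path)
    with open(path, encoding="utf-8") as fh:
        lines = [ln.rstrip("\n") for ln in fh]
    lines = [ln for ln in lines if ln != ""]
    if not lines:
        raise ParseError(f"{path}: empty file")
    parcel_ids = lines[0].split("\t")
    n_parcels = len(parcel_ids)
    rows: list[list[float]] = []
    mask: list[bool] = []
    for lineno, ln in enumerate(lines[1:], start=2):
        cells = ln.split("\t")
        if len(cells) != n_parcels:
            raise ParseError(
                f"{path}:{lineno}: expected {n_parcels} columns, got {len(cells)}"
            )
        vals = []
        for col, cell in enumerate(cells):
            try:
                vals.append(float(cell))
            except ValueError as exc:
                raise ParseError(
                    f"{path}:{lineno}: non-numeric cell in column {col} "
                    f"({parcel_ids[col]}): {cell!r}"
                ) from exc
        arr = np.array(vals)
        nan = ~np.isfinite(arr)
        if nan.all():
            mask.append(False)
            rows.append([0.0] * n_parcels)
        elif nan.any():
            col = int(np.argmax(nan))
            raise ParseError(
                f"{path}:{lineno}: non-finite value in usable frame, column "
                f"{col} ({parcel_ids[col]})"
            )
        else:
            mask.append(True)
            rows.append(vals)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    return ParcelTimeSeries(
        values=np.array(rows),
        tr_seconds=tr_seconds,
        censor_mask=np.array(mask),
        subject_id=subject_id,
        session_id=session_id,
        parcel_ids=parcel_ids,
    )


def parcellate_nifti(
    image_path: str | Path,
    atlas_path: str | Path,
    tr_seconds: float | None = None,
    expected_labels: list[int] | None = None,
) -> ParcelTimeSeries:
    """Reduce a 4D NIfTI to parcel means under a 3D integer-label atlas.

    Column j holds the unweighted mean over voxels with label j at each
    frame; parcels are ordered by ascending label; label 0 is background.
    """
    import nibabel as nib

    img = nib.load(str(image_path))
    atlas = nib.load(str(atlas_path))
    data = np.asarray(img.dataobj, dtype=float)
    labels_vol = np.asarray(atlas.dataobj)
    if data.ndim != 4:
        raise ValueError(f"image must be 4D, got shape {data.shape}")
    if labels_vol.shape != data.shape[:3]:
        raise ValueError(
            f"voxel grid mismatch: image {data.shape[:3]} vs atlas {labels_vol.shape}"
        )
    if not np.allclose(labels_vol, np.round(labels_vol)):
        raise ValueError("atlas labels must be integers")
    labels_vol = np.round(labels_vol).astype(int)
    if labels_vol.min() < 0:
        raise ValueError("atlas labels must be non-negative")
    present = [int(l) for l in np.unique(labels_vol) if l > 0]
    labels = present
    if expected_labels is not None:
        missing = sorted(set(expected_labels) - set(present))
        for lab in missing:
            warnings.warn(
                f"atlas label {lab} covers 0 voxels; parcel omitted", stacklevel=2
            )
        labels = [l for l in sorted(expected_labels) if l in set(present)]
    n_frames = data.shape[3]
    flat = data.reshape(-1, n_frames)
    lab_flat = labels_vol.reshape(-1)
    cols = []
    for lab in labels:
        sel = lab_flat == lab
        cols.append(flat[sel].mean(axis=0))
    if tr_seconds is None:
        zooms = img.header.get_zooms()
        tr_seconds = float(zooms[3]) if len(zooms) > 3 and zooms[3] > 0 else 2.0
    return ParcelTimeSeries(
        values=np.column_stack(cols),
        tr_seconds=tr_seconds,
        parcel_ids=[f"parcel{lab:03d}" for lab in labels],
    )


@dataclass
class CohortIndex:
    """Parsed cohort manifest: one row per subject-session."""

    table: pd.DataFrame

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject"].unique())

    @property
    def sessions(self) -> list[str]:
        return sorted(self.table["session"].unique())

    def incomplete_subjects(self, required: tuple[str, ...] = ("pre", "post3m")) -> list[str]:
        """Subjects missing any required session (unusable for longitudinal deltas)."""
        out = []
        for s in self.subjects:
            have = set(self.table.loc[self.table["subject"] == s, "session"])
            if not set(required) <= have:
                out.append(s)
        return out

    def group_of(self, subject: str) -> str:
        return str(self.table.loc[self.table["subject"] == subject, "group"].iloc[0])


def load_manifest(path: str | Path) -> CohortIndex:
    df = pd.read_csv(path, dtype={"subject": str, "session": str, "group": str})
    required = {"subject", "session", "group", "path"}
    missing = sorted(required - set(df.columns))
    if missing:
        raise ParseError(f"{path}: manifest missing required columns: {missing}")
    if df.duplicated(["subject", "session"]).any():
        dup = df[df.duplicated(["subject", "session"])].iloc[0]
        raise ParseError(
            f"{path}: duplicate manifest row for {dup['subject']}/{dup['session']}"
        )
    return CohortIndex(table=df)


@dataclass
class BehavioralTable:
    """Tidy neuropsychological scores: one row per subject-timepoint-score.

    Columns: subject, timepoint (pre/1w/3m), score, value (age/education-
    adjusted scale), cutoff (clinical impairment threshold on the same
    scale), orientation (higher_worse / higher_better).
    """

    table: pd.DataFrame

    def __post_init__(self) -> None:
        required = {"subject", "timepoint", "score", "value", "cutoff"}
        missing = sorted(required - set(self.table.columns))
        if missing:
            raise ValueError(f"behavior table missing columns: {missing}")
        if "orientation" not in self.table.columns:
            self.table = self.table.assign(
                orientation=self.table["score"].map(SCORE_ORIENTATION)
            )
        if self.table["orientation"].isna().any():
            bad = self.table.loc[self.table["orientation"].isna(), "score"].unique()
            raise ValueError(f"unknown score orientation for: {sorted(bad)}")
        if self.table.duplicated(["subject", "timepoint", "score"]).any():
            raise ValueError("duplicate (subject, timepoint, score) rows")
        self._check_tmt_identity()

    def _check_tmt_identity(self) -> None:
        # TMTBA must equal TMTB - TMTA wherever all three are present.
        wide = self.table.pivot_table(
            index=["subject", "timepoint"], columns="score", values="value"
        )
        cols = set(wide.columns)
        if {"TMTA", "TMTB", "TMTBA"} <= cols:
            sub = wide.dropna(subset=["TMTA", "TMTB", "TMTBA"])
            resid = sub["TMTBA"] - (sub["TMTB"] - sub["TMTA"])
            if len(sub) and np.abs(resid).max() > 1e-6:
                bad = resid.abs().idxmax()
                raise ValueError(
                    f"TMTBA != TMTB - TMTA for subject/timepoint {bad}"
                )

    def wide(self, timepoint: str) -> pd.DataFrame:
        sub = self.table[self.table["timepoint"] == timepoint]
        return sub.pivot(index="subject", columns="score", values="value")

    @property
    def subjects(self) -> list[str]:
        return sorted(self.table["subject"].unique())


def load_behavior(path: str | Path) -> BehavioralTable:
    df = pd.read_csv(path, dtype={"subject": str, "timepoint": str, "score": str})
    return BehavioralTable(table=df)


def write_behavior(behavior: BehavioralTable, path: str | Path) -> None:
    behavior.table.to_csv(path, index=False)


def load_seeds(path: str | Path) -> dict[str, SeedDefinition]:
    """Read seed definitions from JSON: ``{"FPN": [0, 1, ...], ...}``."""
    with open(path, encoding="utf-8") as fh:
        raw = json.load(fh)
    return {name: SeedDefinition(name=name, parcel_indices=np.array(idx)) for name, idx in raw.items()}


def write_seeds(seeds: dict[str, SeedDefinition], path: str | Path) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(
            {name: [int(i) for i in sd.parcel_indices] for name, sd in sorted(seeds.items())},
            fh,
            indent=1,
            sort_keys=True,
        )
        fh.write("\n")


def write_json(obj, path: str | Path) -> None:
    """Deterministic JSON writer (sorted keys, no timestamps)."""

    def _default(o):
        if isinstance(o, (np.integer,)):
            return int(o)
        if isinstance(o, (np.floating,)):
            return float(o)
        if isinstance(o, np.ndarray):
            return o.tolist()
        raise TypeError(f"not JSON serializable: {type(o)}")

    with open(path, "w", encoding="utf-8") as fh:
        json.dump(obj, fh, indent=1, sort_keys=True, default=_default)
        fh.write("\n")
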