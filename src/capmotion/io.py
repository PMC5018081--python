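"""Dataset schema, CSV readers/writers and summary counts.

The on-disk contract is plain CSV with a header row, mirroring the "Spots"
statistics export dialect of common tracking software.  Four table roles
exist:

``cells``
    one row per tracked cell per time step:
    ``sample, crop, track, branch, time, pos_x, pos_y, pos_z``.
    ``branch`` is typically unassigned on input (the acquisition export does
    not distinguish daughter cells after a mitosis) and is filled in by
    :mod:`capmotion.branching`.
``tip_cloud``
    arbitrary points filling each ureteric tip volume, exported without
    track information: ``crop, time, pos_x, pos_y, pos_z``.
``tip_ends``
    manually tracked tip extremities used as the moving reference for drift
    correction: ``crop, tip_track, time, pos_x, pos_y, pos_z``.
``attachment``
    periods during which a cell shows a process attached to the ureteric
    epithelium: ``track, first, last`` (time-step interval, inclusive).

Positions are physical micrometres; time is an integer step index with the
step length (15 or 20 minutes) held per sample in metadata — all downstream
statistics are per-step quantities.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .errors import ParseError, SchemaError, ValidationError

logger = logging.getLogger("capmotion.io")

#: required columns per table role
ROLE_COLUMNS: dict[str, list[str]] = {
    "cells": ["sample", "crop", "track", "branch", "time", "pos_x", "pos_y", "pos_z"],
    "tip_cloud": ["crop", "time", "pos_x", "pos_y", "pos_z"],
    "tip_ends": ["crop", "tip_track", "time", "pos_x", "pos_y", "pos_z"],
    "attachment": ["track", "first", "last"],
}

_COORD_COLUMNS = ("pos_x", "pos_y", "pos_z")

#: file names used by :func:`read_dataset` / :func:`write_dataset`
DATASET_FILES = {
    "cells": "cells.csv",
    "tip_cloud": "tip_cloud.csv",
    "tip_ends": "tip_ends.csv",
    "attachment": "attachment.csv",
}
ANNOTATED_FILE = "annotated_tracks.csv"
METADATA_FILE = "metadata.yaml"


@dataclass
class Dataset:
    """In-memory dataset: spot tables plus annotations and metadata.

    Attributes
    ----------
    cells, tip_clouds, tip_ends, attachments : pandas.DataFrame
        Tables with the columns listed in :data:`ROLE_COLUMNS`.
    annotated_tracks : list
        Track (unbranched-segment) ids annotated for attachment; tracks in
        this list but absent from ``attachments`` were observed never to
        attach.
    metadata : dict
        ``step_minutes``: mapping sample id -> 15 or 20;
        ``crop_bounds``: optional mapping ``(sample, crop)`` ->
        ``(xmin, xmax, ymin, ymax, zmin, zmax)`` in µm.
    """

    cells: pd.DataFrame
    tip_clouds: pd.DataFrame
    tip_ends: pd.DataFrame
    attachments: pd.DataFrame = field(
        default_factory=lambda: pd.DataFrame(columns=ROLE_COLUMNS["attachment"])
    )
    annotated_tracks: list = field(default_factory=list)
    metadata: dict = field(default_factory=dict)

    def step_minutes(self, sample) -> int:
        sm = self.metadata.get("step_minutes", {})
        if sample in sm:
            return int(sm[sample])
        raise KeyError(f"step_minutes unknown for sample {sample!r}")

    def crop_bounds(self, sample, crop) -> tuple:
        """Axis-aligned bounds of a crop in µm.

        Uses metadata when supplied, otherwise the bounding box of all cell
        spots and tip points in the crop (the edge-exclusion rule needs
        bounds even when the acquisition never recorded them).
        """
        declared = self.metadata.get("crop_bounds", {})
        key = (sample, crop)
        if key in declared:
            return tuple(declared[key])
        cel = self.cells[(self.cells["sample"] == sample) & (self.cells["crop"] == crop)]
        tip = self.tip_clouds[self.tip_clouds["crop"] == crop]
        pts = np.vstack(
            [cel[list(_COORD_COLUMNS)].to_numpy(float), tip[list(_COORD_COLUMNS)].to_numpy(float)]
        )
        if pts.size == 0:
            raise ValidationError(f"no points to infer bounds for sample {sample!r} crop {crop!r}")
        lo, hi = pts.min(axis=0), pts.max(axis=0)
        return (lo[0], hi[0], lo[1], hi[1], lo[2], hi[2])

    def validate(self) -> None:
        """Check dataset invariants; raise :class:`ValidationError` on failure."""
        key = ["sample", "crop", "track", "branch", "time"]
        if self.cells.duplicated(subset=key).any():
            dup = self.cells[self.cells.duplicated(subset=key, keep=False)].head()
            raise ValidationError(f"duplicate spot keys, e.g.\n{dup}")
        for name, df in (("cells", self.cells), ("tip_cloud", self.tip_clouds),
                         ("tip_ends", self.tip_ends)):
            coords = df[list(_COORD_COLUMNS)].to_numpy(float)
            if not np.isfinite(coords).all():
                raise ValidationError(f"non-finite coordinates in {name} table")
        # every cell spot needs a tip cloud at its crop/time step
        if len(self.cells):
            have = set(map(tuple, self.tip_clouds[["crop", "time"]].drop_duplicates().itertuples(index=False)))
            need = set(map(tuple, self.cells[["crop", "time"]].drop_duplicates().itertuples(index=False)))
            missing = need - have
            if missing:
                raise ValidationError(
                    f"{len(missing)} (crop, time) combinations have cells but no tip cloud, "
                    f"e.g. {sorted(missing)[:3]}"
                )


def read_track_table(path, role: str) -> pd.DataFrame:
    """Read one CSV table and validate it for the given *role*.

    Raises :class:`SchemaError` naming any missing column and
    :class:`ParseError` with the row number of a non-numeric coordinate.
    A tip-cloud file carrying track columns has them dropped with a warning
    (those points are exported without track identity by design).
    """
    if role not in ROLE_COLUMNS:
        raise ValueError(f"unknown table role {role!r}; expected one of {sorted(ROLE_COLUMNS)}")
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str).rename(columns=lambda c: c.strip())
    required = ROLE_COLUMNS[role]
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path.name}: missing required column(s) {missing} for role {role!r}")
    if role == "tip_cloud":
        extra = [c for c in ("track", "branch", "tip_track") if c in df.columns]
        if extra:
            logger.warning("%s: ignoring track column(s) %s in tip_cloud table", path.name, extra)
            df = df.drop(columns=extra)
    df = df[required].copy()
    numeric = [c for c in required if c in _COORD_COLUMNS or c in ("time", "first", "last")]
    for col in numeric:
        converted = pd.to_numeric(df[col], errors="coerce")
        bad = converted.isna() & df[col].notna()
        if bad.any():
            row = int(np.flatnonzero(bad.to_numpy())[0])
            raise ParseError(
                f"{path.name}: non-numeric value {df[col].iloc[row]!r} in column {col!r} "
                f"at data row {row + 1}"
            )
        if converted.isna().any():
            row = int(np.flatnonzero(converted.isna().to_numpy())[0])
            raise ParseError(f"{path.name}: empty value in column {col!r} at data row {row + 1}")
        df[col] = converted
    for col in ("time", "first", "last"):
        if col in df.columns:
            df[col] = df[col].astype(np.int64)
    return df.reset_index(drop=True)


def write_track_table(df: pd.DataFrame, path, role: str) -> None:
    """Write a table in the canonical column order for *role*."""
    cols = [c for c in ROLE_COLUMNS[role] if c in df.columns]
    extras = [c for c in df.columns if c not in cols]
    df[cols + extras].to_csv(path, index=False)


def read_dataset(directory) -> Dataset:
    """Load a dataset directory written by :func:`write_dataset`."""
    directory = Path(directory)
    cells = read_track_table(directory / DATASET_FILES["cells"], "cells")
    tips = read_track_table(directory / DATASET_FILES["tip_cloud"], "tip_cloud")
    ends = read_track_table(directory / DATASET_FILES["tip_ends"], "tip_ends")
    att_path = directory / DATASET_FILES["attachment"]
    attachments = (
        read_track_table(att_path, "attachment")
        if att_path.exists()
        else pd.DataFrame(columns=ROLE_COLUMNS["attachment"])
    )
    annotated: list = []
    ann_path = directory / ANNOTATED_FILE
    if ann_path.exists():
        annotated = pd.read_csv(ann_path)["track"].tolist()
    metadata: dict = {}
    meta_path = directory / METADATA_FILE
    if meta_path.exists():
        raw = yaml.safe_load(meta_path.read_text()) or {}
        metadata["step_minutes"] = dict(raw.get("step_minutes", {}))
        metadata["crop_bounds"] = {
            tuple(k.split("/", 1)): tuple(v) for k, v in raw.get("crop_bounds", {}).items()
        }
    ds = Dataset(cells, tips, ends, attachments, annotated, metadata)
    ds.validate()
    return ds


def write_dataset(dataset: Dataset, directory) -> None:
    """Write all dataset tables and metadata under *directory*."""
    directory = Path(directory)
    directory.mkdir(parents=True, exist_ok=True)
    write_track_table(dataset.cells, directory / DATASET_FILES["cells"], "cells")
    write_track_table(dataset.tip_clouds, directory / DATASET_FILES["tip_cloud"], "tip_cloud")
    write_track_table(dataset.tip_ends, directory / DATASET_FILES["tip_ends"], "tip_ends")
    write_track_table(dataset.attachments, directory / DATASET_FILES["attachment"], "attachment")
    pd.DataFrame({"track": dataset.annotated_tracks}).to_csv(
        directory / ANNOTATED_FILE, index=False
    )
    raw = {
        "step_minutes": dict(dataset.metadata.get("step_minutes", {})),
        "crop_bounds": {
            f"{s}/{c}": list(map(float, b))
            for (s, c), b in dataset.metadata.get("crop_bounds", {}).items()
        },
    }
    (directory / METADATA_FILE).write_text(yaml.safe_dump(raw, sort_keys=True))


def summarize(dataset: Dataset) -> pd.DataFrame:
    """Per-sample summary: crops, step length, duration, track/segment/spot counts.

    The unbranched-segment column counts distinct ``(track, branch)`` pairs
    and is meaningful once branch resolution has assigned branch ids.  The
    final ``total`` row holds column sums (counts are additive over samples).
    """
    cells = dataset.cells
    rows = []
    for sample, grp in cells.groupby("sample", sort=True):
        step_min = None
        try:
            step_min = dataset.step_minutes(sample)
        except KeyError:
            pass
        duration_h = np.nan
        if step_min is not None and len(grp):
            duration_h = (grp["time"].max() - grp["time"].min()) * step_min / 60.0
        rows.append(
            {
                "sample": sample,
                "crops": grp["crop"].nunique(),
                "step_minutes": step_min,
                "duration_hours": duration_h,
                "tracks": grp["track"].nunique(),
                "unbranched_segments": len(grp[["track", "branch"]].drop_duplicates()),
                "spots": len(grp),
            }
        )
    out = pd.DataFrame(
        rows,
        columns=["sample", "crops", "step_minutes", "duration_hours", "tracks",
                 "unbranched_segments", "spots"],
    )
    total = {
        "sample": "total",
        "crops": out["crops"].sum() if len(out) else 0,
        "step_minutes": None,
        "duration_hours": np.nan,
        "tracks": out["tracks"].sum() if len(out) else 0,
        "unbranched_segments": out["unbranched_segments"].sum() if len(out) else 0,
        "spots": out["spots"].sum() if len(out) else 0,
    }
    return pd.concat([out, pd.DataFrame([total])], ignore_index=True)
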