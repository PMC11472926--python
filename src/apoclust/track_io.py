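"""Read/write nucleus-tracking spot tables and derive per-cell fates.

The pipeline's lingua franca is the *track table*: a long-format
:class:`pandas.DataFrame` with one row per cell per frame, carrying the
columns

``cell_id``
    opaque track identifier (int or str),
``frame``
    non-negative integer frame index, contiguous per cell,
``t_min``
    time in minutes, ``frame * frame_interval_min``,
``x_um``, ``y_um``
    nucleus centroid position in micrometres,

plus any number of numeric intensity-channel columns (e.g. ``nuclear``,
``cytoplasmic``) and an optional categorical ``segment_label``.  The frame
interval is stored in ``df.attrs["frame_interval_min"]``.

Cell death is *track termination*: nuclear breakdown ends the track, so a
cell's death frame is the last frame it appears in.  Cells still present at
the final movie frame are censored survivors, not deaths.
"""

from __future__ import annotations

import logging
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

#: Core (non-channel) columns of a track table.
CORE_COLUMNS = ("cell_id", "frame", "t_min", "x_um", "y_um")

#: Bookkeeping columns that are not intensity channels.
_NON_CHANNEL = set(CORE_COLUMNS) | {"segment_label", "interpolated"}

#: Default source-column mapping, following the TrackMate spot-export dialect.
DEFAULT_COLUMN_MAP: dict[str, str] = {
    "TRACK_ID": "cell_id",
    "FRAME": "frame",
    "POSITION_X": "x_um",
    "POSITION_Y": "y_um",
}

#: Fields that must be present after applying the column map.
MANDATORY_FIELDS = ("cell_id", "frame", "x_um", "y_um")

DEFAULT_FRAME_INTERVAL_MIN = 10.0


def channel_names(tracks: pd.DataFrame) -> list[str]:
    """Names of the intensity-channel columns of a track table."""
    return [c for c in tracks.columns if c not in _NON_CHANNEL]


def validate_tracks(tracks: pd.DataFrame) -> None:
    """Raise ``ValueError`` if a track table violates its invariants.

    Checks: mandatory columns present, unique (cell_id, frame), contiguous
    per-cell frame runs, finite positions, non-negative intensities.
    """
    for col in CORE_COLUMNS:
        if col not in tracks.columns:
            raise ValueError(f"track table is missing mandatory column {col!r}")
    if tracks.duplicated(subset=["cell_id", "frame"]).any():
        dup = tracks[tracks.duplicated(subset=["cell_id", "frame"], keep=False)]
        ids = sorted(dup["cell_id"].unique().tolist(), key=str)[:5]
        raise ValueError(f"duplicate (cell_id, frame) rows, e.g. for cells {ids}")
    if len(tracks) and not np.isfinite(tracks[["x_um", "y_um"]].to_numpy(float)).all():
        raise ValueError("non-finite positions in track table")
    for ch in channel_names(tracks):
        vals = tracks[ch].to_numpy(float)
        if len(vals) and np.nanmin(vals) < 0:
            raise ValueError(f"negative intensities in channel {ch!r}")
    for cid, sub in tracks.groupby("cell_id", sort=False):
        frames = np.sort(sub["frame"].to_numpy(int))
        if len(frames) and (frames[0] < 0 or np.any(np.diff(frames) != 1)):
            raise ValueError(f"frames of cell {cid!r} are not a contiguous run")


def _autodetect_sep(path) -> str:
    with open(path, "r", encoding="utf-8", errors="replace") as fh:
        header = fh.readline()
    return "\t" if header.count("\t") > header.count(",") else ","


def read_spot_table(
    path,
    column_map: Mapping[str, str] | None = None,
    frame_interval_min: float = DEFAULT_FRAME_INTERVAL_MIN,
) -> pd.DataFrame:
    """Read a delimited spot/track export into a validated track table.

    Parameters
    ----------
    path
        Comma- or tab-separated text file with a header row (autodetected).
    column_map
        Source-column -> track-table-field mapping.  Defaults to the
        TrackMate spot-export names (``TRACK_ID``, ``FRAME``,
        ``POSITION_X/Y``).  Unmapped numeric columns are kept as intensity
        channels; a ``segment_label`` column (mapped or literal) is kept as
        a categorical.
    frame_interval_min
        Imaging cadence used to compute ``t_min = frame * interval``.

    Rows whose mandatory fields fail numeric parsing are reported on the
    logger and dropped.  Single-frame gaps inside a track are filled by
    linear interpolation of position and intensities and flagged in the
    ``interpolated`` column; gaps of two or more frames split the track into
    separate cells (suffix ``/1``, ``/2`` ...) with a logged warning,
    because an unsplit gap would otherwise hide a spurious death.
    """
    cmap = dict(DEFAULT_COLUMN_MAP if column_map is None else column_map)
    raw = pd.read_csv(path, sep=_autodetect_sep(path))
    raw = raw.rename(columns=cmap)
    for field in MANDATORY_FIELDS:
        if field not in raw.columns:
            raise ValueError(
                f"mandatory column {field!r} not found after applying column map "
                f"(source columns: {list(raw.columns)})"
            )

    numeric_cols = ["frame", "x_um", "y_um"]
    channels = [
        c
        for c in raw.columns
        if c not in _NON_CHANNEL and c != "cell_id"
        and pd.to_numeric(raw[c], errors="coerce").notna().any()
    ]
    for c in numeric_cols + channels:
        raw[c] = pd.to_numeric(raw[c], errors="coerce")
    bad = raw[numeric_cols].isna().any(axis=1) | raw["cell_id"].isna()
    if bad.any():
        logger.warning("dropping %d unparseable row(s)", int(bad.sum()))
        raw = raw[~bad]

    keep = ["cell_id"] + numeric_cols + channels
    if "segment_label" in raw.columns:
        keep.append("segment_label")
    df = raw[keep].copy()
    df["frame"] = df["frame"].astype(int)
    if df.duplicated(subset=["cell_id", "frame"]).any():
        raise ValueError("duplicate (cell_id, frame) rows in input")

    if len(df) == 0:
        logger.warning("spot table %s contains a header but no rows", path)
    df = _fill_and_split_gaps(df, channels)
    df["t_min"] = df["frame"] * float(frame_interval_min)
    order = list(CORE_COLUMNS) + channels
    if "segment_label" in df.columns:
        order.append("segment_label")
    if "interpolated" in df.columns:
        order.append("interpolated")
    # natural order for numeric ids; lexicographic only for string ids
    sort_key = (
        (lambda s: s.map(str) if s.name == "cell_id" and s.dtype == object else s)
    )
    df = df[order].sort_values(["cell_id", "frame"], key=sort_key)
    df = df.reset_index(drop=True)
    df.attrs["frame_interval_min"] = float(frame_interval_min)
    validate_tracks(df)
    return df


def _fill_and_split_gaps(df: pd.DataFrame, channels: Sequence[str]) -> pd.DataFrame:
    """Fill single-frame gaps by interpolation; split tracks at longer gaps."""
    pieces = []
    interp_cols = ["x_um", "y_um", *channels]
    for cid, sub in df.groupby("cell_id", sort=False):
        sub = sub.sort_values("frame").reset_index(drop=True)
        frames = sub["frame"].to_numpy()
        gaps = np.flatnonzero(np.diff(frames) > 1)
        # Fill 1-frame gaps (midpoint of the flanking samples).
        fill_rows = []
        split_after = []
        for g in gaps:
            width = frames[g + 1] - frames[g] - 1
            if width == 1:
                row = {"cell_id": cid, "frame": int(frames[g]) + 1, "interpolated": True}
                for c in interp_cols:
                    row[c] = 0.5 * (sub.at[g, c] + sub.at[g + 1, c])
                if "segment_label" in sub.columns:
                    row["segment_label"] = sub.at[g, "segment_label"]
                fill_rows.append(row)
                logger.info("cell %r: interpolated gap frame %d", cid, int(frames[g]) + 1)
            else:
                split_after.append(g)
                logger.warning(
                    "cell %r: gap of %d frames after frame %d; splitting track",
                    cid, int(width), int(frames[g]),
                )
        if fill_rows:
            sub = pd.concat([sub, pd.DataFrame(fill_rows)], ignore_index=True)
            sub = sub.sort_values("frame").reset_index(drop=True)
        if split_after:
            bounds = [sub.index[sub["frame"] == int(frames[g])][0] for g in split_after]
            start = 0
            for k, b in enumerate(bounds):
                part = sub.iloc[start : b + 1].copy()
                if k > 0:
                    part["cell_id"] = f"{cid}/{k}"
                pieces.append(part)
                start = b + 1
            tail = sub.iloc[start:].copy()
            tail["cell_id"] = f"{cid}/{len(bounds)}"
            pieces.append(tail)
        else:
            pieces.append(sub)
    if not pieces:
        out = df.copy()
    else:
        out = pd.concat(pieces, ignore_index=True)
    if "interpolated" in out.columns:
        out["interpolated"] = out["interpolated"].eq(True)
    return out


def write_spot_table(tracks: pd.DataFrame, path, sep: str = ",") -> None:
    """Write a track table as delimited text; round-trips through
    :func:`read_spot_table` up to float formatting (1e-6)."""
    validate_tracks(tracks)
    cols = [c for c in tracks.columns if c != "t_min"]
    out = tracks[cols].rename(columns={})
    out.to_csv(path, sep=sep, index=False, float_format="%.8g")


def derive_fates(tracks: pd.DataFrame, movie_end_frame: int) -> pd.DataFrame:
    """Per-cell fates: first/last frame, censoring, and first-frame position.

    Returns a DataFrame indexed by ``cell_id`` with columns ``first_frame``,
    ``last_frame``, ``censored`` (present at ``movie_end_frame``, i.e. a
    survivor rather than a death) and ``x0_um``/``y0_um`` (position at
    ``first_frame``).  For non-censored cells, ``last_frame`` is the death
    frame (nuclear breakdown ends the track).
    """
    max_frame = int(tracks["frame"].max()) if len(tracks) else 0
    if len(tracks) and movie_end_frame < max_frame:
        raise ValueError(
            f"movie_end_frame={movie_end_frame} < max frame {max_frame} in table"
        )
    recs = []
    for cid, sub in tracks.groupby("cell_id", sort=False):
        i0 = sub["frame"].idxmin()
        first = int(sub["frame"].min())
        last = int(sub["frame"].max())
        recs.append(
            dict(
                cell_id=cid,
                first_frame=first,
                last_frame=last,
                censored=last == int(movie_end_frame),
                x0_um=float(sub.at[i0, "x_um"]),
                y0_um=float(sub.at[i0, "y_um"]),
            )
        )
    fates = pd.DataFrame.from_records(
        recs, columns=["cell_id", "first_frame", "last_frame", "censored", "x0_um", "y0_um"]
    ).set_index("cell_id")
    fates.attrs["movie_end_frame"] = int(movie_end_frame)
    fates.attrs["frame_interval_min"] = tracks.attrs.get(
        "frame_interval_min", DEFAULT_FRAME_INTERVAL_MIN
    )
    return fates


def death_frames(fates: pd.DataFrame) -> pd.Series:
    """Death frame per cell (NaN for censored survivors)."""
    df = fates["last_frame"].astype(float).copy()
    df[fates["censored"]] = np.nan
    return df


def alive_at(fates: pd.DataFrame, frame: int) -> pd.Index:
    """Cells alive at ``frame`` (first_frame <= frame <= last_frame)."""
    m = (fates["first_frame"] <= frame) & (frame <= fates["last_frame"])
    return fates.index[m]


def filter_region(
    tracks: pd.DataFrame,
    bbox_um: tuple[float, float, float, float] | None = None,
    segments: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Keep whole tracks whose *first-frame* position/segment passes the rule.

    ``bbox_um`` is ``(xmin, xmax, ymin, ymax)``; ``segments`` is a whitelist
    of ``segment_label`` values.  A cell is kept or removed for all its
    frames, judged at its first frame (cells migrate, and the randomized
    null uses initial positions).  Idempotent.
    """
    if bbox_um is None and segments is None:
        return tracks.copy()
    first = tracks.loc[tracks.groupby("cell_id")["frame"].idxmin()]
    keep = pd.Series(True, index=first["cell_id"].values)
    if bbox_um is not None:
        xmin, xmax, ymin, ymax = bbox_um
        ok = (
            (first["x_um"] >= xmin)
            & (first["x_um"] <= xmax)
            & (first["y_um"] >= ymin)
            & (first["y_um"] <= ymax)
        )
        keep &= pd.Series(ok.values, index=first["cell_id"].values)
    if segments is not None:
        if "segment_label" not in tracks.columns:
            raise ValueError("segment whitelist given but table has no segment_label")
        ok = first["segment_label"].isin(list(segments))
        keep &= pd.Series(ok.values, index=first["cell_id"].values)
    kept_ids = keep.index[keep.values]
    out = tracks[tracks["cell_id"].isin(kept_ids)].reset_index(drop=True)
    if len(out) == 0:
        logger.warning("region rule excluded every cell")
    out.attrs.update(tracks.attrs)
    return out
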