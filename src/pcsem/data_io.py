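"""I/O for per-frame surgical tool-presence annotations (Cholec80 dialect).

Each video has one tab-separated text file: a header line naming the frame
column and the tools, then one row per annotated frame with the source frame
index and a binary presence flag per tool.  Video is recorded at 25 Hz and
annotated once per second, so native frame indices step by 25; a second-index
variant (step 1) also circulates and is accepted via ``frame_step``.

The canonical tool order used throughout the package is::

    Grasper, Bipolar, Hook, Scissors, Clipper, Irrigator, SpecimenBag

Files with permuted tool columns are reordered on read; unknown (foreign)
tool columns are kept so cross-dataset class filtering can drop the frames
that contain them.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

TOOL_NAMES = ["Grasper", "Bipolar", "Hook", "Scissors", "Clipper",
              "Irrigator", "SpecimenBag"]
N_TOOLS = len(TOOL_NAMES)
FRAME_COLUMN = "Frame"


class AnnotationFormatError(ValueError):
    """Malformed annotation file; the message names the offending line."""


@dataclass
class AnnotationTable:
    """Per-frame multi-label presence flags for one video."""

    video_id: str
    frames: np.ndarray                       # strictly increasing source indices
    flags: pd.DataFrame                      # columns: canonical tools (+ foreign)

    def __post_init__(self):
        self.frames = np.asarray(self.frames, dtype=np.int64)
        if np.any(np.diff(self.frames) <= 0):
            raise AnnotationFormatError(
                f"{self.video_id}: frame indices must be strictly increasing")
        self.flags = self.flags.reset_index(drop=True)

    def __len__(self) -> int:
        return len(self.frames)

    @property
    def tool_columns(self) -> list[str]:
        return list(self.flags.columns)

    def canonical_matrix(self) -> np.ndarray:
        """(n_frames, 7) int8 matrix in canonical tool order."""
        return self.flags[TOOL_NAMES].to_numpy(dtype=np.int8)

    def __eq__(self, other) -> bool:
        return (isinstance(other, AnnotationTable)
                and self.video_id == other.video_id
                and np.array_equal(self.frames, other.frames)
                and list(self.flags.columns) == list(other.flags.columns)
                and self.flags.equals(other.flags))


@dataclass
class DatasetSplit:
    train_videos: list = field(default_factory=list)
    test_videos: list = field(default_factory=list)


def read_tool_annotations(path, video_id: str | None = None) -> AnnotationTable:
    """Parse one annotation file; canonical tools are reordered to the front."""
    path = Path(path)
    video_id = video_id or path.stem.replace("-tool", "")
    lines = path.read_text().splitlines()
    if not lines:
        raise AnnotationFormatError(f"{path}: empty file")
    header = lines[0].rstrip("\n").split("\t")
    if header[0].strip() != FRAME_COLUMN:
        raise AnnotationFormatError(
            f"{path}, line 1: expected header starting with {FRAME_COLUMN!r}, "
            f"got {header[0]!r}")
    tools = [h.strip() for h in header[1:]]
    missing = [t for t in TOOL_NAMES if t not in tools]
    if missing:
        raise AnnotationFormatError(
            f"{path}, line 1: header is missing tool columns {missing}")
    frames, rows = [], []
    for lineno, line in enumerate(lines[1:], start=2):
        if not line.strip():
            continue
        parts = line.split("\t")
        if len(parts) != len(header):
            raise AnnotationFormatError(
                f"{path}, line {lineno}: expected {len(header)} fields, got {len(parts)}")
        try:
            frames.append(int(parts[0]))
        except ValueError:
            raise AnnotationFormatError(
                f"{path}, line {lineno}: non-integer frame index {parts[0]!r}") from None
        row = []
        for name, val in zip(tools, parts[1:]):
            v = val.strip()
            if v not in ("0", "1"):
                raise AnnotationFormatError(
                    f"{path}, line {lineno}: non-binary flag {val!r} for {name}")
            row.append(int(v))
        rows.append(row)
    frames = np.asarray(frames, dtype=np.int64)
    if np.any(np.diff(frames) <= 0):
        bad = int(np.flatnonzero(np.diff(frames) <= 0)[0]) + 3  # header + 1-base + next row
        raise AnnotationFormatError(
            f"{path}, line {bad}: frame indices must be strictly increasing")
    df = pd.DataFrame(rows, columns=tools, dtype=np.int8)
    order = TOOL_NAMES + [t for t in tools if t not in TOOL_NAMES]
    return AnnotationTable(video_id, frames, df[order])


def write_tool_annotations(table: AnnotationTable, path) -> None:
    path = Path(path)
    cols = table.tool_columns
    with open(path, "w") as fh:
        fh.write("\t".join([FRAME_COLUMN] + cols) + "\n")
        mat = table.flags.to_numpy()
        for i, frame in enumerate(table.frames):
            fh.write("\t".join([str(int(frame))] + [str(int(v)) for v in mat[i]]) + "\n")


def class_distribution(tables: list[AnnotationTable]) -> dict:
    """Per-tool frame counts and the total number of annotated frames.

    A frame with k tools present contributes to k per-class counts but only
    once to the frame total (the multi-label counting rule).
    """
    counts = {t: 0 for t in TOOL_NAMES}
    total = 0
    for table in tables:
        mat = table.canonical_matrix()
        total += len(table)
        for j, t in enumerate(TOOL_NAMES):
            counts[t] += int(mat[:, j].sum())
    return {"per_class": counts, "total_frames": total}


def filter_foreign_classes(table: AnnotationTable, allowed: set[str]) -> AnnotationTable:
    """Drop every frame that contains a tool outside ``allowed``.

    Mirrors the cross-dataset rule: classes absent from the training corpus
    — and, consequently, the frames showing them — are removed from
    processing.  Foreign columns themselves are dropped from the result.
    """
    unknown = [t for t in allowed if t not in table.tool_columns]
    if unknown:
        raise ValueError(f"allowed classes not present in the table: {unknown}")
    foreign = [t for t in table.tool_columns if t not in allowed]
    if not foreign:
        return AnnotationTable(table.video_id, table.frames.copy(), table.flags.copy())
    keep = table.flags[foreign].to_numpy().sum(axis=1) == 0
    return AnnotationTable(
        table.video_id,
        table.frames[keep],
        table.flags.loc[keep, [t for t in table.tool_columns if t in allowed]],
    )


def make_split(video_ids: list, train_fraction: float = 0.5,
               expect_80: bool = True) -> DatasetSplit:
    """First-half / second-half video split (first 40 train, last 40 test).

    ``expect_80=False`` relaxes the 80-video requirement for toy corpora;
    the ids must be supplied in natural (sorted) order either way.
    """
    ids = list(video_ids)
    if sorted(ids) != ids:
        raise ValueError("video ids must be supplied in natural sorted order")
    if len(set(ids)) != len(ids):
        raise ValueError("duplicate video ids")
    if expect_80 and len(ids) != 80:
        raise ValueError(f"expected 80 video ids, got {len(ids)}; "
                         "pass expect_80=False for toy corpora")
    k = int(round(len(ids) * train_fraction))
    return DatasetSplit(train_videos=ids[:k], test_videos=ids[k:])


def frame_image_path(root, video_id: str, frame_index: int,
                     template: str = "{video_id}/{frame_index}.png") -> Path:
    """Map an annotation row to its image file via a configurable template."""
    return Path(root) / template.format(video_id=video_id, frame_index=frame_index)
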