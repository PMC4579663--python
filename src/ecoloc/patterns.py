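"""Classified cell point patterns and their CSV dialect.

A *slide pattern* is the set of classified cells of one tumor section:
μm coordinates plus a class label in {cancer, immune, stromal_other},
as produced by an upstream nucleus classifier.  Patterns are stored
column-wise in numpy arrays; the CSV dialect is

    patient_id,section_id,x_um,y_um,cell_class

with one row per cell and an arbitrary per-slide coordinate origin.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable

import numpy as np
import pandas as pd

CELL_CLASSES = ("cancer", "immune", "stromal_other")

CELL_TABLE_COLUMNS = ["patient_id", "section_id", "x_um", "y_um", "cell_class"]


@dataclass(frozen=True)
class CellPoint:
    """A single classified cell at μm coordinates."""

    x: float
    y: float
    cell_class: str

    def __post_init__(self) -> None:
        if not (np.isfinite(self.x) and np.isfinite(self.y)):
            raise ValueError("cell coordinates must be finite")
        if self.cell_class not in CELL_CLASSES:
            raise ValueError(
                f"unknown cell_class {self.cell_class!r}; expected one of {CELL_CLASSES}"
            )


@dataclass
class SlidePattern:
    """All classified cells of one tumor section.

    Parameters
    ----------
    patient_id, section_id
        Identifiers; a patient typically owns around three sections taken
        from different tumor locations.
    x, y
        Cell coordinates in μm (parallel arrays).
    cell_class
        Per-cell label, one of ``CELL_CLASSES``.
    window
        Axis-aligned bounding rectangle ``(xmin, ymin, xmax, ymax)`` in μm.
        Defaults to the tight bounding box of the cells.
    """

    patient_id: str
    section_id: str
    x: np.ndarray
    y: np.ndarray
    cell_class: np.ndarray
    window: tuple[float, float, float, float] | None = None

    def __post_init__(self) -> None:
        self.x = np.asarray(self.x, dtype=float)
        self.y = np.asarray(self.y, dtype=float)
        self.cell_class = np.asarray(self.cell_class, dtype=object)
        if not (len(self.x) == len(self.y) == len(self.cell_class)):
            raise ValueError("x, y and cell_class must have equal length")
        if len(self.x) and not (np.isfinite(self.x).all() and np.isfinite(self.y).all()):
            raise ValueError("cell coordinates must be finite")
        bad = set(np.unique(self.cell_class)) - set(CELL_CLASSES)
        if bad:
            raise ValueError(f"unknown cell_class values: {sorted(bad)}")
        if self.window is None:
            if len(self.x):
                self.window = (
                    float(self.x.min()),
                    float(self.y.min()),
                    float(self.x.max()),
                    float(self.y.max()),
                )
            else:
                self.window = (0.0, 0.0, 0.0, 0.0)
        xmin, ymin, xmax, ymax = self.window
        if len(self.x) and (
            (self.x < xmin).any()
            or (self.x > xmax).any()
            or (self.y < ymin).any()
            or (self.y > ymax).any()
        ):
            raise ValueError("all cells must lie inside the window")

    def __len__(self) -> int:
        return len(self.x)

    @property
    def n_cells(self) -> int:
        return len(self.x)

    def class_mask(self, cls: str) -> np.ndarray:
        return self.cell_class == cls

    def class_counts(self) -> dict[str, int]:
        return {c: int((self.cell_class == c).sum()) for c in CELL_CLASSES}

    @classmethod
    def from_points(
        cls,
        patient_id: str,
        section_id: str,
        points: Iterable[CellPoint],
        window: tuple[float, float, float, float] | None = None,
    ) -> "SlidePattern":
        pts = list(points)
        return cls(
            patient_id=patient_id,
            section_id=section_id,
            x=np.array([p.x for p in pts], dtype=float),
            y=np.array([p.y for p in pts], dtype=float),
            cell_class=np.array([p.cell_class for p in pts], dtype=object),
            window=window,
        )

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "patient_id": self.patient_id,
                "section_id": self.section_id,
                "x_um": self.x,
                "y_um": self.y,
                "cell_class": self.cell_class,
            }
        )


def read_cell_table(path: str | Path) -> list[SlidePattern]:
    """Read a cell-table CSV into one :class:`SlidePattern` per section."""
    df = pd.read_csv(path)
    missing = [c for c in CELL_TABLE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"cell table {path} is missing columns {missing}")
    return patterns_from_frame(df)


def patterns_from_frame(df: pd.DataFrame) -> list[SlidePattern]:
    patterns = []
    for (pid, sid), grp in df.groupby(["patient_id", "section_id"], sort=True):
        patterns.append(
            SlidePattern(
                patient_id=str(pid),
                section_id=str(sid),
                x=grp["x_um"].to_numpy(dtype=float),
                y=grp["y_um"].to_numpy(dtype=float),
                cell_class=grp["cell_class"].to_numpy(dtype=object),
            )
        )
    return patterns


def write_cell_table(patterns: Iterable[SlidePattern], path: str | Path) -> None:
    frames = [p.to_frame() for p in patterns]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)
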