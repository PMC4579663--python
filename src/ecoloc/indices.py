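"""Colocalization indices on quadrat counts.

The Morisita-Horn similarity index compares the spatial distributions of two
cell populations across the tessellation polygons,

    MH = 2 Σ_i x_i y_i / ((Σ_i x_i²/X² + Σ_i y_i²/Y²) · X · Y),

with X = Σx_i, Y = Σy_i.  MH = 1 when the two populations have identical
relative distributions (x_i/X = y_i/Y everywhere, e.g. an equal number of
cancer and immune cells in every square), and MH = 0 when their supports are
disjoint.  It is symmetric in the two populations and invariant to scaling
either one, so it measures co-location, not abundance.  Pearson correlation
of the paired per-polygon counts is the second, simpler statistic, and the
immune-abundance fraction (dichotomized at 8 % by default) is the
non-spatial comparator.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Iterable, Sequence

import numpy as np
from scipy import stats

from .patterns import SlidePattern
from .tessellation import QuadratCounts

DEFAULT_IMMUNE_ABUNDANCE_CUTOFF = 0.08


@dataclass
class ColocalizationScore:
    """Per-tumor colocalization values plus provenance of how they were made."""

    morisita: float | None
    pearson: float | None
    n_polygons_used: int
    tessellation_kind: str
    polygon_scale: float
    min_tissue_threshold: int
    aggregation: str = "single_section"

    def __post_init__(self) -> None:
        if self.morisita is not None and not (-1e-12 <= self.morisita <= 1 + 1e-12):
            raise ValueError("Morisita-Horn index must lie in [0, 1]")


def morisita_horn(counts: QuadratCounts) -> float | None:
    """Morisita-Horn similarity of the cancer and immune count vectors.

    Returns ``None`` (with a warning) when the index is undefined: fewer
    than two polygons, or one population absent altogether.
    """
    x = counts.x.astype(float)
    y = counts.y.astype(float)
    if len(x) < 2:
        warnings.warn("Morisita-Horn undefined: fewer than 2 polygons after filtering")
        return None
    X, Y = x.sum(), y.sum()
    if X == 0 or Y == 0:
        warnings.warn("Morisita-Horn undefined: a cell class is absent from all polygons")
        return None
    num = 2.0 * float(np.dot(x, y))
    den = (float(np.dot(x, x)) / X**2 + float(np.dot(y, y)) / Y**2) * X * Y
    return float(num / den)


def pearson_colocalization(counts: QuadratCounts) -> float | None:
    """Pearson correlation of paired per-polygon cancer and immune counts."""
    x = counts.x.astype(float)
    y = counts.y.astype(float)
    if len(x) < 2:
        warnings.warn("Pearson colocalization undefined: fewer than 2 polygons")
        return None
    if np.var(x) == 0 or np.var(y) == 0:
        warnings.warn("Pearson colocalization undefined: zero variance in a cell class")
        return None
    return float(stats.pearsonr(x, y).statistic)


def immune_abundance(pattern: SlidePattern) -> float | None:
    """Fraction of all cells classified as immune; ``None`` on an empty pattern."""
    n = len(pattern)
    if n == 0:
        warnings.warn("immune abundance undefined on an empty pattern")
        return None
    return float(pattern.class_mask("immune").sum() / n)


def dichotomize_abundance(
    fraction: float, cutoff: float = DEFAULT_IMMUNE_ABUNDANCE_CUTOFF
) -> str:
    """High/low immune-abundance call at the configured cutoff (default 8 %)."""
    return "high" if fraction > cutoff else "low"


def aggregate_patient_score(
    sections: Sequence[QuadratCounts],
    strategy: str = "pool",
) -> ColocalizationScore:
    """Combine the retained quadrat counts of one patient's sections.

    ``strategy="pool"`` (default) concatenates the retained polygons of all
    sections into one count table before computing the indices, maximizing
    the number of sampling units.  ``strategy="mean"`` computes the indices
    per section and averages the defined values.
    """
    if len(sections) == 0:
        raise ValueError("need at least one section")
    if strategy not in ("pool", "mean"):
        raise ValueError(f"unknown aggregation strategy {strategy!r}")
    kind = sections[0].tessellation_kind
    scale = sections[0].polygon_scale
    min_cells = max(s.min_cells for s in sections)

    if strategy == "pool":
        pooled = QuadratCounts(
            polygon_ids=np.arange(sum(s.n_polygons for s in sections)),
            x=np.concatenate([s.x for s in sections]) if sections else np.array([]),
            y=np.concatenate([s.y for s in sections]),
            t=np.concatenate([s.t for s in sections]),
            centroids=np.vstack([s.centroids for s in sections]),
            tessellation_kind=kind,
            polygon_scale=scale,
            min_cells=min_cells,
        )
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mh = morisita_horn(pooled)
            pr = pearson_colocalization(pooled)
        n_used = pooled.n_polygons
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            mhs = [morisita_horn(s) for s in sections]
            prs = [pearson_colocalization(s) for s in sections]
        mhs = [v for v in mhs if v is not None]
        prs = [v for v in prs if v is not None]
        mh = float(np.mean(mhs)) if mhs else None
        pr = float(np.mean(prs)) if prs else None
        n_used = sum(s.n_polygons for s in sections)

    if mh is None and pr is None:
        warnings.warn("all sections degenerate: missing colocalization score")
    return ColocalizationScore(
        morisita=mh,
        pearson=pr,
        n_polygons_used=n_used,
        tessellation_kind=kind,
        polygon_scale=scale,
        min_tissue_threshold=min_cells,
        aggregation=strategy,
    )
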