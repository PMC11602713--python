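"""Contour geometry for laser microdissection and per-cell fluorescence stats.

Contours are ordered vertex lists in micrometres. Cuttable contours are
simple polygons with shoelace area between 30 and 200 square micrometres
(inclusive); outlines are simplified by removing 99% of vertices at a
uniform index stride, and for fragile membranes at most every second shape
(in input order) is randomly selected. Per-cell STAT1 is normalized by the
cell's own Hoechst signal to cancel slide-level staining variation.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats
from shapely.geometry import Polygon

from ._rng import stream
from .errors import ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "Contour",
    "shoelace_area",
    "filter_contours_by_area",
    "simplify_contour",
    "subsample_alternating",
    "normalize_stat1",
    "sample_nuclei",
    "compare_cohorts",
    "cytotoxicity_fraction",
]


def shoelace_area(vertices: np.ndarray) -> float:
    """Absolute polygon area from the shoelace formula."""
    v = np.asarray(vertices, dtype=float)
    x, y = v[:, 0], v[:, 1]
    return float(np.abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1))) / 2)


@dataclass
class Contour:
    """An ordered polygon outline in micrometres with an optional label."""

    vertices: np.ndarray
    cell_type: str | None = None
    contour_id: str | None = None

    def __post_init__(self):
        self.vertices = np.asarray(self.vertices, dtype=float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2:
            raise ValidationError("contour vertices must be an (n, 2) array")
        if len(self.vertices) < 3:
            raise ValidationError("a polygon needs at least 3 vertices")

    @property
    def area(self) -> float:
        return shoelace_area(self.vertices)

    def is_simple(self) -> bool:
        return Polygon(self.vertices).is_valid

    def with_vertices(self, vertices) -> "Contour":
        return Contour(vertices=vertices, cell_type=self.cell_type,
                       contour_id=self.contour_id)


def filter_contours_by_area(contours, min_area: float = 30.0,
                            max_area: float = 200.0) -> list[Contour]:
    """Keep simple polygons with min_area <= area <= max_area (inclusive).

    Self-intersecting polygons are rejected with a logged reason.
    """
    if min_area <= 0 or max_area < min_area:
        raise ValidationError(f"degenerate area bounds ({min_area}, {max_area})")
    kept, n_invalid = [], 0
    for contour in contours:
        if not contour.is_simple():
            n_invalid += 1
            logger.warning("rejected self-intersecting contour %s",
                           contour.contour_id)
            continue
        if min_area <= contour.area <= max_area:
            kept.append(contour)
    if n_invalid:
        logger.info("rejected %d invalid contours", n_invalid)
    return kept


def simplify_contour(contour: Contour, keep_fraction: float = 0.01) -> Contour:
    """Drop vertices, retaining max(3, round(keep_fraction * n)) at a uniform
    index stride starting from vertex 0 (keep_fraction 0.01 removes 99%)."""
    if not 0 < keep_fraction <= 1:
        raise ValidationError(f"keep_fraction must be in (0, 1], got {keep_fraction}")
    n = len(contour.vertices)
    n_keep = max(3, round(keep_fraction * n))
    if n_keep >= n:
        return contour.with_vertices(contour.vertices.copy())
    idx = (np.arange(n_keep) * n) // n_keep  # starts at 0, uniform stride
    return contour.with_vertices(contour.vertices[idx])


def subsample_alternating(contours, seed: int = 0) -> list[Contour]:
    """Randomly select contours so no two input-adjacent ones are both kept.

    Greedy over a random order: a contour is accepted if neither input
    neighbour was already accepted. The selection therefore has at most
    ceil(n/2) members and is reproducible from the seed.
    """
    n = len(contours)
    if n == 0:
        return []
    rng = stream(seed, "subsample_alternating")
    selected = np.zeros(n, dtype=bool)
    for i in rng.permutation(n):
        left = selected[i - 1] if i > 0 else False
        right = selected[i + 1] if i < n - 1 else False
        if not left and not right:
            selected[i] = True
    return [c for c, keep in zip(contours, selected) if keep]


def normalize_stat1(cells: pd.DataFrame, stat1_col: str = "stat1_mean",
                    hoechst_col: str = "hoechst_mean") -> pd.DataFrame:
    """Per-cell STAT1 / Hoechst ratio; cells without Hoechst signal excluded.

    Returns a copy with a ``stat1_norm`` column; the number of excluded
    cells is logged and stored in ``df.attrs['n_excluded']``.
    """
    for col in (stat1_col, hoechst_col):
        if col not in cells.columns:
            raise ValidationError(f"cell table lacks column {col!r}")
    valid = cells[hoechst_col] > 0
    n_excluded = int((~valid).sum())
    if n_excluded:
        logger.info("normalize_stat1: excluded %d cells with Hoechst <= 0",
                    n_excluded)
    out = cells[valid].copy()
    out["stat1_norm"] = out[stat1_col] / out[hoechst_col]
    out.attrs["n_excluded"] = n_excluded
    return out


def sample_nuclei(cells: pd.DataFrame, n: int = 5000,
                  seed: int = 0) -> pd.DataFrame:
    """Exactly ``n`` nuclei per individual; individuals with fewer are excluded.

    The number of excluded individuals is stored in
    ``df.attrs['n_excluded_individuals']``.
    """
    if n < 1:
        raise ValidationError("n must be >= 1")
    rng = stream(seed, "sample_nuclei")
    frames, n_excluded = [], 0
    for individual, grp in cells.groupby("individual", sort=True):
        if len(grp) < n:
            n_excluded += 1
            logger.info("excluded individual %s with %d < %d cells",
                        individual, len(grp), n)
            continue
        idx = rng.choice(len(grp), size=n, replace=False)
        frames.append(grp.iloc[np.sort(idx)])
    if not frames:
        raise ValidationError(f"all individuals have fewer than {n} cells")
    out = pd.concat(frames, ignore_index=True)
    out.attrs["n_excluded_individuals"] = n_excluded
    return out


def compare_cohorts(cells: pd.DataFrame, cohort_a: str, cohort_b: str,
                    value_col: str = "stat1_norm") -> dict:
    """Unpaired two-sided t-test on per-individual mean normalized values."""
    means = cells.groupby(["cohort", "individual"])[value_col].mean()
    try:
        a = means.loc[cohort_a].to_numpy()
        b = means.loc[cohort_b].to_numpy()
    except KeyError as exc:
        raise ValidationError(f"cohort {exc.args[0]!r} not present") from exc
    if len(a) < 2 or len(b) < 2:
        raise ValidationError("each cohort needs >= 2 individuals")
    if np.ptp(a) == 0 and np.ptp(b) == 0:
        # degenerate spread: identical means -> no evidence of difference
        t_stat, p = (0.0, 1.0) if a[0] == b[0] else (np.inf, 0.0)
    else:
        t_stat, p = stats.ttest_ind(a, b, equal_var=True)
    return {"cohort_a": cohort_a, "cohort_b": cohort_b,
            "mean_a": float(a.mean()), "mean_b": float(b.mean()),
            "t": float(t_stat), "p_value": float(p),
            "n_a": len(a), "n_b": len(b)}


def cytotoxicity_fraction(n_double_positive: int, n_tracker_positive: int) -> float:
    """Dead-keratinocyte fraction: double-positive / total tracker-positive."""
    if n_tracker_positive <= 0:
        raise ValidationError("n_tracker_positive must be > 0")
    if not 0 <= n_double_positive <= n_tracker_positive:
        raise ValidationError(
            "n_double_positive must be within [0, n_tracker_positive]")
    return n_double_positive / n_tracker_positive
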