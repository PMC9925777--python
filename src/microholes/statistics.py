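"""Per-patch persistence statistics.

The informative quadrants of the SEDT persistence diagram are quadrant 2 of
H0 (one point per disconnected micro-hole: |birth| is the radius of the
largest inscribed circle, death is half the distance to the nearest other
micro-hole) and quadrant 1 of H1 (one point per bone region enclosed by a
ring of micro-holes).  Each patch is summarised by a fixed panel of named
statistics over those two point sets; the essential class is always excluded
(on real patches it is the exterior background component).

Statistics are computed on the raw signed (birth, death) coordinates, so
e.g. "mean birth" of H0-Q2 is negative and *more* negative means larger
micro-holes.  Only the two radius-thresholded counts convert birth to a
radius (r = -birth).

The canonical 28-statistic panel (``PANEL28``) omits the 75th birth
percentile and total persistence, which the full computed table still
carries as extra columns.
"""

from __future__ import annotations

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, TransformerMixin

from .persistence import PersistenceDiagram, split_quadrants

__all__ = [
    "persistent_entropy",
    "quadrant_statistics",
    "compute_panel",
    "panel_table",
    "restrict_scale",
    "score_patches",
    "PersistenceStatistics",
    "PANEL28",
    "STAT_COLUMNS",
]

_MOMENTS = [
    "mean_birth", "median_birth", "p25_birth", "p75_birth", "iqr_birth", "sd_birth",
    "mean_death", "median_death", "p25_death", "p75_death", "iqr_death", "sd_death",
]

#: every statistic computed per quadrant
_PER_QUADRANT = ["n_points", "entropy", "total_persistence", *_MOMENTS]

#: all computed columns, keyed "<quadrant>_<statistic>"
STAT_COLUMNS = (
    [f"h0q2_{s}" for s in _PER_QUADRANT]
    + ["h0q2_n_radius_ge_2", "h0q2_n_radius_lt_2"]
    + [f"h1q1_{s}" for s in _PER_QUADRANT]
)

_PANEL28_PER_QUADRANT = [
    "n_points", "entropy",
    "mean_birth", "median_birth", "p25_birth", "iqr_birth", "sd_birth",
    "mean_death", "median_death", "p25_death", "p75_death", "iqr_death", "sd_death",
]

#: the canonical 28-statistic panel used for hypothesis testing
PANEL28 = (
    [f"h0q2_{s}" for s in _PANEL28_PER_QUADRANT]
    + ["h0q2_n_radius_ge_2", "h0q2_n_radius_lt_2"]
    + [f"h1q1_{s}" for s in _PANEL28_PER_QUADRANT]
)


def persistent_entropy(points: np.ndarray) -> float:
    """Shannon entropy (natural log) of normalised persistence lifetimes.

    With lifetimes p_i = d_i - b_i and P = sum p_i, the entropy is
    sum_i -(p_i/P) log(p_i/P): 0 for a single point, log n when all
    lifetimes are equal.  Empty input yields NaN (undefined, not zero).
    """
    points = np.asarray(points, dtype=float)
    if points.size == 0:
        return np.nan
    p = points[:, 1] - points[:, 0]
    if (p <= 0).any():
        raise ValueError("all lifetimes must be positive")
    q = p / p.sum()
    return float(-(q * np.log(q)).sum())


def quadrant_statistics(points: np.ndarray, prefix: str) -> dict[str, float]:
    """Summary statistics of one quadrant's (birth, death) point set.

    Empty quadrants yield n_points = 0, total persistence 0 and NaN moments.
    Quartiles use linear interpolation between order statistics; the standard
    deviation is the population one (ddof=0), so a single point yields 0.
    """
    points = np.asarray(points, dtype=float)
    out = {f"{prefix}_n_points": float(points.shape[0])}
    if points.shape[0] == 0:
        out[f"{prefix}_entropy"] = np.nan
        out[f"{prefix}_total_persistence"] = 0.0
        for m in _MOMENTS:
            out[f"{prefix}_{m}"] = np.nan
        return out
    b, d = points[:, 0], points[:, 1]
    out[f"{prefix}_entropy"] = persistent_entropy(points)
    out[f"{prefix}_total_persistence"] = float((d - b).sum())
    for name, x in (("birth", b), ("death", d)):
        q25, q50, q75 = np.percentile(x, [25, 50, 75])
        out[f"{prefix}_mean_{name}"] = float(x.mean())
        out[f"{prefix}_median_{name}"] = float(q50)
        out[f"{prefix}_p25_{name}"] = float(q25)
        out[f"{prefix}_p75_{name}"] = float(q75)
        out[f"{prefix}_iqr_{name}"] = float(q75 - q25)
        out[f"{prefix}_sd_{name}"] = float(x.std())
    return out


def compute_panel(diag: PersistenceDiagram, radius_threshold: float = 2.0) -> dict[str, float]:
    """Full statistic panel of one patch's diagram (essential class excluded).

    ``radius_threshold`` splits the micro-hole count by inscribed radius
    (r = -birth of an H0-Q2 point): holes with r >= threshold vs r < threshold.
    """
    quads = split_quadrants(diag)
    out = quadrant_statistics(quads[("h0", "q2")], "h0q2")
    births = quads[("h0", "q2")][:, 0] if quads[("h0", "q2")].size else np.zeros(0)
    out["h0q2_n_radius_ge_2"] = float((-births >= radius_threshold).sum())
    out["h0q2_n_radius_lt_2"] = float((-births < radius_threshold).sum())
    out.update(quadrant_statistics(quads[("h1", "q1")], "h1q1"))
    return out


def panel_table(
    diags: list[PersistenceDiagram], radius_threshold: float = 2.0
) -> pd.DataFrame:
    """One row per patch: statistics plus provenance/label columns."""
    rows = []
    for i, dg in enumerate(diags):
        row = compute_panel(dg, radius_threshold=radius_threshold)
        row["source"] = dg.source or str(i)
        row["origin_row"], row["origin_col"] = dg.origin
        for k, v in (dg.labels or {}).items():
            row[k] = v
        rows.append(row)
    return pd.DataFrame(rows)


def restrict_scale(
    diag: PersistenceDiagram,
    birth_window: tuple[float, float] = (-np.inf, np.inf),
    death_window: tuple[float, float] = (-np.inf, np.inf),
) -> PersistenceDiagram:
    """Sub-diagram of points whose birth and death lie in the given closed
    windows, for focusing the panel on features at a scale of interest."""
    b_lo, b_hi = birth_window
    d_lo, d_hi = death_window

    def _keep(pts):
        if pts.size == 0:
            return np.zeros(0, dtype=bool)
        return (
            (pts[:, 0] >= b_lo) & (pts[:, 0] <= b_hi)
            & (pts[:, 1] >= d_lo) & (pts[:, 1] <= d_hi)
        )

    k0, k1 = _keep(diag.h0), _keep(diag.h1)
    return PersistenceDiagram(
        h0=diag.h0[k0],
        h1=diag.h1[k1],
        h0_pixels=diag.h0_pixels[k0],
        h1_pixels=diag.h1_pixels[k1],
        essential_birth=diag.essential_birth,
        essential_pixel=diag.essential_pixel,
        degenerate=diag.degenerate,
        origin=diag.origin,
        source=diag.source,
        labels=dict(diag.labels or {}),
    )


def score_patches(panels: pd.DataFrame, statistic: str, side: int = 300) -> np.ma.MaskedArray:
    """Patch-grid map of one statistic over a single source image.

    ``panels`` must carry ``origin_row``/``origin_col`` columns from one
    source image; missing tiles (discarded background patches) come back
    masked.  Useful for highlighting regions of interest within a sample.
    """
    if statistic not in panels.columns:
        valid = [c for c in panels.columns if c in STAT_COLUMNS]
        raise ValueError(f"unknown statistic {statistic!r}; valid names: {valid}")
    pr = (panels["origin_row"] // side).astype(int)
    pc = (panels["origin_col"] // side).astype(int)
    grid = np.ma.masked_all((pr.max() + 1, pc.max() + 1), dtype=float)
    for r, c, v in zip(pr, pc, panels[statistic]):
        grid[r, c] = v
    return grid


class PersistenceStatistics(BaseEstimator, TransformerMixin):
    """Transformer: list of persistence diagrams -> panel DataFrame."""

    def __init__(self, radius_threshold: float = 2.0):
        self.radius_threshold = radius_threshold

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return panel_table(X, radius_threshold=self.radius_threshold)

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)
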