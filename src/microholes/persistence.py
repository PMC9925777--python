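"""Cubical sublevel-set persistent homology of 2-D scalar fields.

The complex is the V-construction: pixels are vertices, orthogonally adjacent
pixels are joined by edges, and 2x2 blocks of pixels whose four edges are all
present are filled by squares.  A cell enters the filtration at the maximum of
its vertices' values (lower-star rule), so the sublevel complex at level delta
is exactly the 4-connected pixel set {value <= delta} with its induced edges
and squares.

H0 pairs are computed by union-find over the vertex/edge order with the elder
rule.  H1 pairs are computed by union-find on the dual face-adjacency graph
processed from the highest filtration value downwards: a 1-cycle in the
sublevel complex encloses a bounded component of the complement, which is a
connected set of not-yet-included squares; running time backwards turns each
loop birth/death into a dual component merge/birth.  For planar cubical
complexes this yields the same pairs as boundary-matrix reduction over the
2-element field, in near-linear time.

Exactly one class never dies: the connected component born at the global
minimum.  It is reported separately as the *essential* class (death = +inf)
and is excluded from all downstream statistics, since on real patches it is
usually the exterior background region.

Ties in the filtration value are broken by flat pixel position; any valid
order yields the same diagram multiset, which the tests assert by comparing
against transposed inputs and against an explicit Betti-curve oracle.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field as dataclass_field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import ndimage
from sklearn.base import BaseEstimator, TransformerMixin

from .sedt import SEDTField

__all__ = [
    "PersistenceDiagram",
    "build_filtration",
    "compute_persistence",
    "oracle_betti_curve",
    "split_quadrants",
    "write_diagrams_csv",
    "read_diagrams_csv",
    "CubicalPersistence",
]

_FOUR_CONNECTED = np.array([[0, 1, 0], [1, 1, 1], [0, 1, 0]], dtype=bool)


@dataclass(frozen=True)
class PersistenceDiagram:
    """H0/H1 persistence pairs of one patch, with birth-pixel tracking.

    ``h0``/``h1`` are (n, 2) float arrays of (birth, death) with birth < death;
    ``h0_pixels``/``h1_pixels`` are the matching (n, 2) integer (row, col)
    arrays of the pixel whose inclusion created each class.  The single
    essential H0 class (death = +inf) is stored separately.
    """

    h0: np.ndarray
    h1: np.ndarray
    h0_pixels: np.ndarray
    h1_pixels: np.ndarray
    essential_birth: float = np.nan
    essential_pixel: tuple[int, int] | None = None
    degenerate: bool = False
    origin: tuple[int, int] = (0, 0)
    source: str = ""
    labels: dict = dataclass_field(default_factory=dict)

    def points(self, dim: int) -> np.ndarray:
        return self.h0 if dim == 0 else self.h1

    @classmethod
    def empty(cls, **kwargs) -> "PersistenceDiagram":
        z = np.zeros((0, 2))
        zi = np.zeros((0, 2), dtype=int)
        return cls(h0=z, h1=z.copy(), h0_pixels=zi, h1_pixels=zi.copy(), **kwargs)


class QuadrantLawError(AssertionError):
    """A persistence point landed in a quadrant the filtration forbids (a bug)."""


def build_filtration(field: SEDTField | np.ndarray) -> pd.DataFrame:
    """Explicit cell list of the cubical filtration, in filtration order.

    Intended for small fields (tests, teaching); :func:`compute_persistence`
    never materialises this table.  Columns: dim, value, anchor row/col (the
    minimum vertex of the cell), and the order index.  Cells are sorted by
    (value, dim, row, col): faces always follow their cofaces' vertices and
    edges at equal value, so the order is a valid filtration.
    """
    values = field.values if isinstance(field, SEDTField) else np.asarray(field, float)
    degenerate = isinstance(field, SEDTField) and field.degenerate
    if degenerate:
        return pd.DataFrame(columns=["dim", "value", "row", "col"])
    h, w = values.shape
    rows = []
    for i in range(h):
        for j in range(w):
            rows.append((0, values[i, j], i, j))
    for i in range(h):
        for j in range(w - 1):
            rows.append((1, max(values[i, j], values[i, j + 1]), i, j))
    for i in range(h - 1):
        for j in range(w):
            rows.append((1, max(values[i, j], values[i + 1, j]), i, j))
    for i in range(h - 1):
        for j in range(w - 1):
            rows.append((2, values[i : i + 2, j : j + 2].max(), i, j))
    df = pd.DataFrame(rows, columns=["dim", "value", "row", "col"])
    df = df.sort_values(["value", "dim", "row", "col"], kind="stable").reset_index(drop=True)
    return df


def _find(parent: np.ndarray, x: int) -> int:
    # path halving
    while parent[x] != x:
        parent[x] = parent[parent[x]]
        x = parent[x]
    return x


def _h0_pairs(rank: np.ndarray, h: int, w: int):
    """Elder-rule union-find over vertices and edges; returns finite pairs
    (as rank indices) and the essential birth rank."""
    n = h * w
    idx = np.arange(n).reshape(h, w)
    eu = np.concatenate([idx[:, :-1].ravel(), idx[:-1, :].ravel()])
    ev = np.concatenate([idx[:, 1:].ravel(), idx[1:, :].ravel()])
    etime = np.maximum(rank[eu], rank[ev])
    eorder = np.argsort(etime, kind="stable")
    eu, ev, etime = eu[eorder], ev[eorder], etime[eorder]

    parent = np.arange(n, dtype=np.int64)
    birth = rank.astype(np.int64).copy()  # birth rank of the component rooted here
    births, deaths = [], []
    for k in range(eu.shape[0]):
        ru = _find(parent, eu[k])
        rv = _find(parent, ev[k])
        if ru == rv:
            continue
        if birth[ru] > birth[rv]:
            ru, rv = rv, ru  # ru is now the elder
        births.append(birth[rv])
        deaths.append(etime[k])
        parent[rv] = ru
    return np.asarray(births, dtype=np.int64), np.asarray(deaths, dtype=np.int64)


def _h1_pairs(rank: np.ndarray, h: int, w: int):
    """H1 pairs via union-find on the dual face graph, processed in
    decreasing filtration order.  Returns (birth_rank, death_rank) arrays
    where birth_rank indexes the primal edge's max vertex and death_rank the
    face's max vertex."""
    if h < 2 or w < 2:
        return np.zeros(0, dtype=np.int64), np.zeros(0, dtype=np.int64)
    rank2 = rank.reshape(h, w)
    # face value rank = max of its 4 vertices
    ftime = np.maximum(
        np.maximum(rank2[:-1, :-1], rank2[:-1, 1:]),
        np.maximum(rank2[1:, :-1], rank2[1:, 1:]),
    )
    nf = (h - 1) * (w - 1)
    fidx = np.arange(nf).reshape(h - 1, w - 1)
    unbounded = nf  # dual vertex for the unbounded face

    # vertical primal edges (between rows i,i+1 at column j) separate the
    # faces to their left and right; border columns face the unbounded region
    vt = np.maximum(rank2[:-1, :], rank2[1:, :])  # (h-1, w)
    va = np.full((h - 1, w), unbounded, dtype=np.int64)
    vb = np.full((h - 1, w), unbounded, dtype=np.int64)
    va[:, 1:] = fidx
    vb[:, : w - 1] = fidx

    # horizontal primal edges (between columns j,j+1 at row i)
    ht_ = np.maximum(rank2[:, :-1], rank2[:, 1:])  # (h, w-1)
    ha = np.full((h, w - 1), unbounded, dtype=np.int64)
    hb = np.full((h, w - 1), unbounded, dtype=np.int64)
    ha[1:, :] = fidx
    hb[: h - 1, :] = fidx

    da = np.concatenate([va.ravel(), ha.ravel()])
    db = np.concatenate([vb.ravel(), hb.ravel()])
    dtime = np.concatenate([vt.ravel(), ht_.ravel()])
    dorder = np.argsort(-dtime, kind="stable")
    da, db, dtime = da[dorder], db[dorder], dtime[dorder]

    parent = np.arange(nf + 1, dtype=np.int64)
    birth = np.empty(nf + 1, dtype=np.int64)
    birth[:nf] = ftime.ravel()
    birth[nf] = np.iinfo(np.int64).max  # unbounded face is the eternal elder
    births, deaths = [], []
    for k in range(da.shape[0]):
        ra = _find(parent, da[k])
        rb = _find(parent, db[k])
        if ra == rb:
            continue
        if birth[ra] < birth[rb]:
            ra, rb = rb, ra  # ra elder (born at larger value, backwards time)
        births.append(dtime[k])
        deaths.append(birth[rb])
        parent[rb] = ra
    return np.asarray(births, dtype=np.int64), np.asarray(deaths, dtype=np.int64)


def compute_persistence(field: SEDTField | np.ndarray) -> PersistenceDiagram:
    """H0 and H1 persistence diagram of the sublevel filtration of ``field``.

    Zero-persistence pairs (birth value == death value) are discarded.  The
    essential H0 class is returned with its birth and pixel but kept out of
    the finite point arrays.  Degenerate (single-phase) SEDT fields yield an
    empty, flagged diagram.
    """
    if isinstance(field, SEDTField):
        meta = dict(origin=field.origin, source=field.source, labels=dict(field.labels or {}))
        if field.degenerate:
            return PersistenceDiagram.empty(degenerate=True, **meta)
        values = field.values
    else:
        values = np.asarray(field, dtype=float)
        meta = dict(origin=(0, 0), source="", labels={})
    if values.ndim != 2 or values.size == 0:
        raise ValueError("expected a non-empty 2-D field")
    h, w = values.shape
    flat = values.ravel()
    order = np.argsort(flat, kind="stable")
    rank = np.empty(flat.shape[0], dtype=np.int64)
    rank[order] = np.arange(flat.shape[0])

    b0r, d0r = _h0_pairs(rank, h, w)
    b1r, d1r = _h1_pairs(rank, h, w)

    def _finite(br, dr):
        b = flat[order[br]]
        d = flat[order[dr]]
        keep = b < d
        pix = np.stack(np.unravel_index(order[br[keep]], (h, w)), axis=1)
        return np.column_stack([b[keep], d[keep]]), pix.astype(int)

    h0, h0_pix = _finite(b0r, d0r)
    h1, h1_pix = _finite(b1r, d1r)
    ess_flat = order[0]
    return PersistenceDiagram(
        h0=h0,
        h1=h1,
        h0_pixels=h0_pix,
        h1_pixels=h1_pix,
        essential_birth=float(flat[ess_flat]),
        essential_pixel=tuple(int(x) for x in np.unravel_index(ess_flat, (h, w))),
        degenerate=False,
        **meta,
    )


def oracle_betti_curve(field: SEDTField | np.ndarray, thresholds) -> list[tuple[int, int]]:
    """Brute-force Betti numbers of the sublevel complex at each threshold.

    beta0 is the number of 4-connected components of the included pixels
    (edges join included orthogonal neighbours, matching the V-construction);
    beta1 follows from the Euler characteristic of the 2-complex:
    beta1 = beta0 - (V - E + F).  Intended for small fields only — this is the
    independent oracle the reduction algorithm is tested against.
    """
    values = field.values if isinstance(field, SEDTField) else np.asarray(field, float)
    out = []
    for delta in thresholds:
        included = values <= delta
        v = int(included.sum())
        if v == 0:
            out.append((0, 0))
            continue
        e = int((included[:, :-1] & included[:, 1:]).sum()) + int(
            (included[:-1, :] & included[1:, :]).sum()
        )
        f = int(
            (included[:-1, :-1] & included[:-1, 1:] & included[1:, :-1] & included[1:, 1:]).sum()
        )
        _, beta0 = ndimage.label(included, structure=_FOUR_CONNECTED)
        beta1 = beta0 - (v - e + f)
        out.append((int(beta0), int(beta1)))
    return out


def split_quadrants(diag: PersistenceDiagram) -> dict[tuple[str, str], np.ndarray]:
    """Partition the diagram by the sign quadrants of the (birth, death) plane.

    Quadrants are numbered 1-4 anticlockwise from the top right: Q1 has
    b >= 0 < d (features of the signal phase), Q2 has b < 0 < d (individual
    micro-holes, and micro-hole loops for H1), Q3 has b < 0 and d <= 0
    (micro-hole components that merge before the full black phase appears).
    The filtration forbids H0 in Q1, H1 in Q3, and anything in Q4; a
    violation raises :class:`QuadrantLawError` since it can only be a bug.
    The essential class belongs to Q2 but is tracked separately.
    """
    h0, h1 = diag.h0, diag.h1
    if h0.size and (h0[:, 0] >= 0).any():
        raise QuadrantLawError("H0 point with non-negative birth (quadrant 1)")
    if h1.size and (h1[:, 1] <= 0).any():
        raise QuadrantLawError("H1 point with non-positive death (quadrant 3)")
    empty = np.zeros((0, 2))
    out = {
        ("h0", "q2"): h0[(h0[:, 0] < 0) & (h0[:, 1] > 0)] if h0.size else empty,
        ("h0", "q3"): h0[(h0[:, 0] < 0) & (h0[:, 1] <= 0)] if h0.size else empty,
        ("h1", "q1"): h1[(h1[:, 0] >= 0) & (h1[:, 1] > 0)] if h1.size else empty,
        ("h1", "q2"): h1[(h1[:, 0] < 0) & (h1[:, 1] > 0)] if h1.size else empty,
    }
    return out


def write_diagrams_csv(diags: list[PersistenceDiagram], path) -> None:
    """One row per point: patch id, dim, birth, death, essential flag, birth pixel."""
    rows = []
    for i, dg in enumerate(diags):
        pid = dg.source or str(i)
        for dim, pts, pix in ((0, dg.h0, dg.h0_pixels), (1, dg.h1, dg.h1_pixels)):
            for (b, d), (r, c) in zip(pts, pix):
                rows.append((pid, dg.origin[0], dg.origin[1], dim, b, d, 0, r, c))
        if not dg.degenerate and dg.essential_pixel is not None:
            r, c = dg.essential_pixel
            rows.append((pid, dg.origin[0], dg.origin[1], 0, dg.essential_birth, np.inf, 1, r, c))
    pd.DataFrame(
        rows,
        columns=[
            "patch", "origin_row", "origin_col", "dim", "birth", "death",
            "essential", "birth_row", "birth_col",
        ],
    ).to_csv(path, index=False)


def read_diagrams_csv(path) -> list[PersistenceDiagram]:
    df = pd.read_csv(path)
    diags = []
    for (pid, orow, ocol), grp in df.groupby(["patch", "origin_row", "origin_col"], sort=False):
        fin = grp[grp["essential"] == 0]
        ess = grp[grp["essential"] == 1]
        h0 = fin[fin["dim"] == 0]
        h1 = fin[fin["dim"] == 1]
        diags.append(
            PersistenceDiagram(
                h0=h0[["birth", "death"]].to_numpy(float),
                h1=h1[["birth", "death"]].to_numpy(float),
                h0_pixels=h0[["birth_row", "birth_col"]].to_numpy(int),
                h1_pixels=h1[["birth_row", "birth_col"]].to_numpy(int),
                essential_birth=float(ess["birth"].iloc[0]) if len(ess) else np.nan,
                essential_pixel=(
                    (int(ess["birth_row"].iloc[0]), int(ess["birth_col"].iloc[0]))
                    if len(ess)
                    else None
                ),
                degenerate=len(grp) == 0,
                origin=(int(orow), int(ocol)),
                source=str(pid),
            )
        )
    return diags


class CubicalPersistence(BaseEstimator, TransformerMixin):
    """Stateless transformer: list of SEDT fields -> list of persistence diagrams."""

    def fit(self, X, y=None):
        return self

    def transform(self, X):
        return [compute_persistence(f) for f in X]

    def fit_transform(self, X, y=None, **kwargs):
        return self.fit(X, y).transform(X)
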