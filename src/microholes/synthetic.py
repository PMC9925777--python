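"""Synthetic binary micro-hole patches with planted ground truth.

The generator emulates the binarized bone patches the pipeline consumes: a
white (signal) canvas perforated by black disks ("micro-holes") with a
controllable count, radius distribution and minimum spacing, optionally with
an exterior black border emulating the background region that real samples
contribute (and which becomes the essential H0 class).  Because disks are
rasterized with an exact rule (pixel black iff its centre lies within
radius r of the disk centre), every planted hole's largest-inscribed-circle
radius and every pairwise gap is known exactly, so pipeline recovery of
radii, counts and crowding can be asserted to pixel tolerance.

Two-group datasets mirror the pathological-vs-control contrast reported for
the bone model this method was developed on: the test-like group has half as
many holes, doubled mean radius and doubled spacing relative to the
control-like group.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np

from .preprocess import BinaryPatch

__all__ = [
    "HoleSpec",
    "GroupParams",
    "WT_LIKE",
    "KO_LIKE",
    "NULL_A",
    "NULL_B",
    "PRESETS",
    "make_disk_field",
    "make_annulus_field",
    "sample_spec",
    "make_group_dataset",
]


@dataclass(frozen=True)
class HoleSpec:
    """Planted ground truth for one synthetic patch."""

    centers: np.ndarray  # (k, 2) float (row, col)
    radii: np.ndarray  # (k,) float
    canvas: int = 300
    border: int = 0  # width of exterior black frame (0 = none)

    @property
    def n_holes(self) -> int:
        return len(self.radii)

    def pairwise_gaps(self) -> np.ndarray:
        """Boundary-to-boundary gap for each pair: ||ci - cj|| - ri - rj."""
        k = self.n_holes
        if k < 2:
            return np.zeros((0,))
        d = np.linalg.norm(self.centers[:, None, :] - self.centers[None, :, :], axis=-1)
        gaps = d - self.radii[:, None] - self.radii[None, :]
        iu = np.triu_indices(k, 1)
        return gaps[iu]

    def nearest_gap(self) -> np.ndarray:
        """Per-hole gap to its nearest neighbour hole."""
        k = self.n_holes
        if k < 2:
            return np.full((k,), np.inf)
        d = np.linalg.norm(self.centers[:, None, :] - self.centers[None, :, :], axis=-1)
        gaps = d - self.radii[:, None] - self.radii[None, :]
        np.fill_diagonal(gaps, np.inf)
        return gaps.min(axis=1)


def make_disk_field(
    spec: HoleSpec, labels: dict | None = None, source: str = ""
) -> tuple[BinaryPatch, HoleSpec]:
    """Rasterize a hole specification onto a white canvas.

    A pixel (i, j) is black iff ||(i, j) - c|| <= r for some hole (c, r);
    the largest inscribed circle of each rasterized hole then has radius r by
    construction.  All-white output (k = 0 holes, no border) is legitimate
    and flagged downstream by the SEDT as degenerate.
    """
    n = spec.canvas
    mask = np.ones((n, n), dtype=bool)
    ii, jj = np.mgrid[0:n, 0:n]
    for (r0, c0), r in zip(spec.centers, spec.radii):
        mask &= (ii - r0) ** 2 + (jj - c0) ** 2 > r**2
    if spec.border > 0:
        b = spec.border
        mask[:b, :] = False
        mask[-b:, :] = False
        mask[:, :b] = False
        mask[:, -b:] = False
    return BinaryPatch(mask=mask, labels=dict(labels or {}), source=source), spec


def make_annulus_field(
    center: tuple[float, float],
    outer: float,
    inner: float,
    canvas: int = 60,
    labels: dict | None = None,
) -> BinaryPatch:
    """A single black ring (white core, white exterior): one micro-hole loop."""
    if not 0 < inner < outer:
        raise ValueError("need 0 < inner < outer")
    ii, jj = np.mgrid[0:canvas, 0:canvas]
    d2 = (ii - center[0]) ** 2 + (jj - center[1]) ** 2
    black = (d2 <= outer**2) & (d2 > inner**2)
    return BinaryPatch(mask=~black, labels=dict(labels or {}))


@dataclass(frozen=True)
class GroupParams:
    """Sampling distribution for one experimental group's patches.

    ``n_holes`` is the Poisson mean of the per-patch hole count; radii are
    normal (mean, sd) clipped at 1.5 px so every hole survives rasterization;
    ``min_gap`` is the smallest allowed boundary-to-boundary spacing in
    pixels.  ``border`` > 0 adds an exterior black frame so the essential
    class is the background, as on real trimmed samples.
    """

    n_holes: float = 40.0
    radius_mean: float = 3.0
    radius_sd: float = 0.8
    min_gap: float = 8.0
    canvas: int = 300
    border: int = 0
    margin: int = 4  # keep holes clear of the canvas edge / border


#: control-like: many small crowded holes
WT_LIKE = GroupParams(n_holes=40, radius_mean=3.0, radius_sd=0.8, min_gap=8.0)
#: test-like: half the holes, doubled radius, doubled spacing
KO_LIKE = GroupParams(n_holes=20, radius_mean=6.0, radius_sd=1.6, min_gap=16.0)
#: identical null pair for calibration
NULL_A = WT_LIKE
NULL_B = replace(WT_LIKE)

PRESETS = {"wt-like": WT_LIKE, "ko-like": KO_LIKE, "null": NULL_A}


def sample_spec(params: GroupParams, rng: np.random.Generator,
                max_tries: int = 10_000) -> HoleSpec:
    """Rejection-sample a hole packing honouring the minimum gap.

    Raises if the packing is infeasible within the retry budget.
    """
    k = int(rng.poisson(params.n_holes))
    k = max(k, 1)
    radii = np.clip(rng.normal(params.radius_mean, params.radius_sd, size=k), 1.5, None)
    lo = params.border + params.margin
    centers: list[np.ndarray] = []
    placed: list[float] = []
    tries = 0
    for r in radii:
        hi = params.canvas - lo - r
        if hi <= lo + r:
            raise ValueError("canvas too small for requested holes")
        while True:
            tries += 1
            if tries > max_tries:
                raise ValueError(
                    f"packing infeasible: could not place {k} holes with "
                    f"min_gap {params.min_gap} in {max_tries} tries"
                )
            c = rng.uniform(lo + r, hi, size=2)
            ok = all(
                np.linalg.norm(c - cj) - r - rj >= params.min_gap
                for cj, rj in zip(centers, placed)
            )
            if ok:
                centers.append(c)
                placed.append(r)
                break
    return HoleSpec(
        centers=np.asarray(centers), radii=np.asarray(placed),
        canvas=params.canvas, border=params.border,
    )


def make_group_dataset(
    params_a: GroupParams,
    params_b: GroupParams,
    n_patches: int = 50,
    seed=None,
    label_a: dict | None = None,
    label_b: dict | None = None,
    samples_per_group: int = 3,
) -> tuple[list[BinaryPatch], list[HoleSpec]]:
    """Two labelled patch collections drawn from two parameter sets.

    Default labels mimic the study design: group A = {genotype KO}, group
    B = {genotype WT}, both sex M, modality SHG, patches assigned round-robin
    to ``samples_per_group`` sample ids per group.  Fully reproducible from
    the seed.
    """
    rng = np.random.default_rng(seed)
    label_a = dict(label_a or {"genotype": "KO", "sex": "M", "modality": "SHG"})
    label_b = dict(label_b or {"genotype": "WT", "sex": "M", "modality": "SHG"})
    patches, specs = [], []
    for g, (params, labels) in enumerate([(params_a, label_a), (params_b, label_b)]):
        for i in range(n_patches):
            spec = sample_spec(params, rng)
            lab = dict(labels)
            lab.setdefault("sample", f"g{g}s{i % samples_per_group}")
            patch, spec = make_disk_field(spec, labels=lab, source=f"g{g}p{i:03d}")
            patches.append(patch)
            specs.append(spec)
    return patches, specs
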