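"""End-to-end workflow: images (or synthetic presets) to panel, tests,
classifier report and figures, with a JSON manifest for reproducibility."""

from __future__ import annotations

import json
import platform
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .classify import evaluate_classifier
from .group_tests import run_comparison_suite
from .persistence import CubicalPersistence, write_diagrams_csv
from .preprocess import BinaryPatch, binarize_and_patch, load_image
from .sedt import SignedDistanceTransform
from .statistics import PersistenceStatistics, score_patches
from .viz import plot_diagram, plot_group_boxes, plot_scoremap

__all__ = ["PipelineConfig", "run_pipeline", "patches_to_panel"]


@dataclass
class PipelineConfig:
    """Validated knobs for the whole pipeline."""

    patch_size: int = 300
    stride: int | None = None
    radius_threshold: float = 2.0
    n_shuffles: int = 10_000
    alpha: float = 0.05
    svc_c: float = 3.0
    folds: int = 10
    repeats: int = 100
    seed: int | None = None
    feature_set: str = "panel10"
    out_dir: str = "microholes_out"
    make_figures: bool = True

    def __post_init__(self):
        if self.patch_size < 1:
            raise ValueError("patch_size must be >= 1")
        if self.stride is not None and self.stride < 1:
            raise ValueError("stride must be >= 1")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        for name in ("n_shuffles", "folds", "repeats"):
            if getattr(self, name) < 1:
                raise ValueError(f"{name} must be >= 1")
        if self.svc_c <= 0:
            raise ValueError("svc_c must be positive")


def patches_to_panel(patches: list[BinaryPatch], radius_threshold: float = 2.0,
                     return_diagrams: bool = False):
    """SEDT + persistence + statistics for a patch collection."""
    fields = SignedDistanceTransform().transform(patches)
    diagrams = CubicalPersistence().transform(fields)
    panel = PersistenceStatistics(radius_threshold=radius_threshold).transform(diagrams)
    return (panel, diagrams) if return_diagrams else panel


def run_pipeline(config: PipelineConfig, manifest: pd.DataFrame | None = None,
                 patches: list[BinaryPatch] | None = None) -> dict:
    """Run the full workflow and write all artifacts under ``config.out_dir``.

    Input is either a label manifest DataFrame with columns
    (path, sample, sex, genotype, modality) pointing at greyscale images, or
    an already-built patch list (e.g. from the synthetic generator).
    Returns a dict with the panel, test report, classifier reports and the
    manifest of everything written.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    stage = "input"
    try:
        if patches is None:
            if manifest is None or len(manifest) == 0:
                raise ValueError("no input images or patches supplied")
            patches = []
            for _, row in manifest.iterrows():
                stage = f"preprocess:{row['path']}"
                img = load_image(row["path"])
                labels = {k: row[k] for k in ("sample", "sex", "genotype", "modality")
                          if k in manifest.columns}
                _, new = binarize_and_patch(
                    img, side=config.patch_size, stride=config.stride,
                    source=str(row.get("sample", row["path"])), labels=labels,
                )
                patches.extend(new)
        if not patches:
            raise ValueError("no non-background patches produced")

        stage = "persistence"
        panel, diagrams = patches_to_panel(
            patches, radius_threshold=config.radius_threshold, return_diagrams=True
        )
        panel.to_csv(out / "panel.csv", index=False)
        write_diagrams_csv(diagrams, out / "diagrams.csv")

        stage = "group_tests"
        report = None
        if {"sex", "genotype", "modality"} <= set(panel.columns):
            report = run_comparison_suite(
                panel, n_shuffles=config.n_shuffles, seed=config.seed, alpha=config.alpha
            )
            report.to_csv(out / "tests.csv", index=False)

        stage = "classify"
        clf_reports = []
        if {"sex", "genotype", "modality"} <= set(panel.columns):
            for modality in pd.unique(panel["modality"]):
                for sex in pd.unique(panel["sex"]):
                    sub = panel[(panel["modality"] == modality) & (panel["sex"] == sex)]
                    counts = sub["genotype"].value_counts()
                    if len(counts) == 2 and counts.min() >= config.folds:
                        clf_reports.append(
                            evaluate_classifier(
                                panel, modality=modality, sex=sex,
                                feature_set=config.feature_set, C=config.svc_c,
                                folds=config.folds, repeats=config.repeats,
                                seed=config.seed,
                            ).as_dict()
                        )
            if clf_reports:
                pd.DataFrame(clf_reports).to_csv(out / "classifier.csv", index=False)

        stage = "figures"
        if config.make_figures:
            plot_diagram(diagrams[0], out / "diagram_patch0.png")
            if report is not None and len(report):
                tested = report[report["p_value"].notna()]
                if len(tested):
                    best = tested.sort_values("p_adjusted").iloc[0]
                    plot_group_boxes(panel, best["statistic"], "genotype",
                                     out / "boxplot_top_statistic.png",
                                     p_adjusted=float(best["p_adjusted"]))
            by_source = panel.groupby("source")
            first = next(iter(by_source.groups))
            smap = score_patches(by_source.get_group(first), "h0q2_n_points",
                                 side=config.patch_size)
            plot_scoremap(smap, out / "scoremap_n_points.png", label="h0q2_n_points")
    except Exception as err:
        raise RuntimeError(f"pipeline failed at stage {stage!r}: {err}") from err

    run_manifest = {
        "version": __version__,
        "python": platform.python_version(),
        "config": asdict(config),
        "n_patches": len(patches),
        "artifacts": sorted(p.name for p in out.iterdir()),
    }
    (out / "manifest.json").write_text(json.dumps(run_manifest, indent=2))
    return {
        "panel": panel,
        "tests": report,
        "classifier": clf_reports,
        "manifest": run_manifest,
    }
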