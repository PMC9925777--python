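"""Permutation hypothesis tests for panel statistics, with FDR control.

Two-group comparisons use the unpaired permutation test on the absolute
difference of group means: patches are pooled and randomly re-assigned to
groups of the original sizes, and the pseudo p-value is the proportion of
shuffled |mean differences| at least as large as the observed one (ties
qualify).  A pseudo p of exactly zero is reportable and should be read as
"smaller than 1/n_shuffles".

Modality comparisons (e.g. SHG vs TPaF) are paired per patch: each pair's
two values swap columns independently with probability 1/2 per shuffle, the
test statistic is mean(differences)/sd(differences), and the test is
two-tailed on its absolute value.

Families of tests are adjusted with the Benjamini-Hochberg step-up, which
controls the false discovery rate; adjustment is applied separately within
each family (one family per comparison and modality).

Patches are treated as exchangeable units; within-sample (per-mouse)
correlation is ignored, which is a deliberate statistical simplification —
see the methods note.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

from .statistics import PANEL28

__all__ = [
    "TestResult",
    "permutation_test",
    "paired_modality_test",
    "benjamini_hochberg",
    "run_comparison_suite",
]

# relative tolerance when counting shuffled statistics "at least as large as"
# the observed one: exact ties must qualify despite float roundoff
_TIE_RTOL = 1e-9


@dataclass
class TestResult:
    statistic: str
    comparison: str
    observed: float
    p_value: float
    n_shuffles: int
    seed: int | None = None
    p_adjusted: float | None = None


def _clean(x) -> np.ndarray:
    x = np.asarray(x, dtype=float).ravel()
    return x[~np.isnan(x)]


def permutation_test(
    values_a,
    values_b,
    n_shuffles: int = 10_000,
    seed=None,
    absolute: bool = True,
    statistic: str = "",
    comparison: str = "",
) -> TestResult:
    """Unpaired permutation test of equal distributions via the mean difference.

    ``absolute=True`` (default) tests |mean(A) - mean(B)| (two-sided);
    ``absolute=False`` tests the signed difference mean(A) - mean(B) against
    shuffled differences falling at or above it (one-sided).  Missing values
    are dropped before testing.
    """
    a, b = _clean(values_a), _clean(values_b)
    if a.size == 0 or b.size == 0:
        raise ValueError("both groups must be non-empty after missing-value exclusion")
    rng = np.random.default_rng(seed)
    pooled = np.concatenate([a, b])
    n, na = pooled.size, a.size
    observed = a.mean() - b.mean()
    if absolute:
        observed = abs(observed)
    count = 0
    # chunked so memory stays bounded for large n_shuffles * n
    chunk = max(1, int(2e6) // max(n, 1))
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        perm = rng.permuted(np.broadcast_to(pooled, (m, n)), axis=1)
        diffs = perm[:, :na].mean(axis=1) - perm[:, na:].mean(axis=1)
        if absolute:
            diffs = np.abs(diffs)
        tol = _TIE_RTOL * max(1.0, abs(observed))
        count += int((diffs >= observed - tol).sum())
        done += m
    return TestResult(
        statistic=statistic,
        comparison=comparison,
        observed=float(observed),
        p_value=count / n_shuffles,
        n_shuffles=n_shuffles,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
    )


def paired_modality_test(
    values_x,
    values_y,
    n_shuffles: int = 10_000,
    seed=None,
    statistic: str = "",
    comparison: str = "paired",
) -> TestResult:
    """Paired two-tailed permutation test between two matched columns.

    The statistic is mean(x - y) normalised by the standard deviation of the
    differences; each shuffle flips every pair's column assignment
    independently with probability 1/2.  If the differences have zero
    variance the statistic is 0 when all differences vanish (every shuffle
    ties, p = 1) and signed infinity otherwise; infinite shuffled ties
    qualify.
    """
    x = np.asarray(values_x, dtype=float).ravel()
    y = np.asarray(values_y, dtype=float).ravel()
    if x.shape != y.shape:
        raise ValueError("paired vectors must have equal length")
    keep = ~(np.isnan(x) | np.isnan(y))
    x, y = x[keep], y[keep]
    if x.size == 0:
        raise ValueError("no complete pairs after missing-value exclusion")
    d = x - y
    rng = np.random.default_rng(seed)

    def _stat(diffs: np.ndarray) -> np.ndarray:
        mean = diffs.mean(axis=-1)
        sd = diffs.std(axis=-1, ddof=1) if diffs.shape[-1] > 1 else np.zeros_like(mean)
        with np.errstate(divide="ignore", invalid="ignore"):
            t = np.where(sd > 0, mean / np.where(sd > 0, sd, 1.0), np.where(mean == 0, 0.0, np.sign(mean) * np.inf))
        return t

    observed = abs(float(_stat(d)))
    count = 0
    chunk = max(1, int(2e6) // max(d.size, 1))
    done = 0
    while done < n_shuffles:
        m = min(chunk, n_shuffles - done)
        signs = rng.integers(0, 2, size=(m, d.size)) * 2 - 1
        t = np.abs(_stat(signs * d))
        tol = _TIE_RTOL * max(1.0, observed if np.isfinite(observed) else 1.0)
        if np.isfinite(observed):
            count += int((t >= observed - tol).sum())
        else:
            count += int(np.isinf(t).sum())
        done += m
    return TestResult(
        statistic=statistic,
        comparison=comparison,
        observed=observed,
        p_value=count / n_shuffles,
        n_shuffles=n_shuffles,
        seed=int(seed) if isinstance(seed, (int, np.integer)) else None,
    )


def benjamini_hochberg(pvalues, families=None) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values, per family.

    ``families`` is an optional label per p-value; adjustment is computed
    independently within each family (default: one family).
    """
    p = np.asarray(pvalues, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    if families is None:
        return multipletests(p, method="fdr_bh")[1] if p.size else p.copy()
    families = np.asarray(families)
    adjusted = np.empty_like(p)
    for fam in pd.unique(families):
        m = families == fam
        adjusted[m] = multipletests(p[m], method="fdr_bh")[1]
    return adjusted


_GROUP_COMPARISONS = [
    # (name, filter column, filter value, split column, level A, level B)
    ("M: KO v WT", "sex", "M", "genotype", "KO", "WT"),
    ("F: KO v WT", "sex", "F", "genotype", "KO", "WT"),
    ("KO: M v F", "genotype", "KO", "sex", "M", "F"),
    ("WT: M v F", "genotype", "WT", "sex", "M", "F"),
]


def run_comparison_suite(
    panel: pd.DataFrame,
    statistics: list[str] | None = None,
    n_shuffles: int = 10_000,
    seed=None,
    alpha: float = 0.05,
    absolute: bool = True,
) -> pd.DataFrame:
    """All group comparisons over the statistic panel, with per-family BH.

    For each modality present, runs the four unpaired comparisons
    (M KO v WT, F KO v WT, KO M v F, WT M v F) over every statistic; if both
    SHG and TPaF are present, adds the paired modality comparison (pairing
    patches on sample and patch origin).  Each (comparison, modality) pair is
    one BH family.  Returns a tidy DataFrame with raw and adjusted p-values
    and a 5%-level significance flag; comparisons whose label combinations
    are missing are reported as gaps in the ``note`` column.
    """
    statistics = list(statistics or [c for c in PANEL28 if c in panel.columns])
    missing = [s for s in statistics if s not in panel.columns]
    if missing:
        raise ValueError(f"panel lacks statistic columns: {missing}")
    for col in ("sex", "genotype", "modality"):
        if col not in panel.columns:
            raise ValueError(f"panel lacks label column {col!r}")
    ss = np.random.SeedSequence(seed)
    rows = []
    modalities = list(pd.unique(panel["modality"]))
    child_iter = iter(ss.spawn(4096))

    for modality in modalities:
        sub = panel[panel["modality"] == modality]
        for name, fcol, fval, scol, la, lb in _GROUP_COMPARISONS:
            grp = sub[sub[fcol] == fval]
            a_all = grp[grp[scol] == la]
            b_all = grp[grp[scol] == lb]
            if len(a_all) < 2 or len(b_all) < 2:
                rows.append(
                    dict(statistic="*", comparison=name, modality=modality,
                         observed=np.nan, p_value=np.nan, p_adjusted=np.nan,
                         significant=False,
                         note=f"gap: needs >=2 patches per group, got {len(a_all)}/{len(b_all)}")
                )
                continue
            for stat in statistics:
                res = permutation_test(
                    a_all[stat], b_all[stat], n_shuffles=n_shuffles,
                    seed=next(child_iter), absolute=absolute,
                    statistic=stat, comparison=name,
                )
                rows.append(
                    dict(statistic=stat, comparison=name, modality=modality,
                         observed=res.observed, p_value=res.p_value,
                         p_adjusted=np.nan, significant=False, note="")
                )

    if {"SHG", "TPaF"} <= set(modalities):
        keys = ["source", "origin_row", "origin_col"]
        shg = panel[panel["modality"] == "SHG"]
        tpaf = panel[panel["modality"] == "TPaF"]
        merged = shg.merge(tpaf, on=keys, suffixes=("_shg", "_tpaf"))
        if len(merged) >= 2:
            for stat in statistics:
                res = paired_modality_test(
                    merged[f"{stat}_shg"], merged[f"{stat}_tpaf"],
                    n_shuffles=n_shuffles, seed=next(child_iter),
                    statistic=stat, comparison="SHG v TPaF",
                )
                rows.append(
                    dict(statistic=stat, comparison="SHG v TPaF", modality="paired",
                         observed=res.observed, p_value=res.p_value,
                         p_adjusted=np.nan, significant=False, note="")
                )
        else:
            rows.append(
                dict(statistic="*", comparison="SHG v TPaF", modality="paired",
                     observed=np.nan, p_value=np.nan, p_adjusted=np.nan,
                     significant=False, note="gap: no matched SHG/TPaF patches")
            )

    report = pd.DataFrame(rows)
    tested = report["p_value"].notna()
    if tested.any():
        fam = report.loc[tested, "comparison"] + "|" + report.loc[tested, "modality"]
        report.loc[tested, "p_adjusted"] = benjamini_hochberg(
            report.loc[tested, "p_value"].to_numpy(), fam.to_numpy()
        )
        report.loc[tested, "significant"] = report.loc[tested, "p_adjusted"] <= alpha
    return report
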