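"""Protein roll-up and case/control differential statistics.

Protein abundance in a sample is the arithmetic mean of the normalised
intensities of that protein's detected peptides (0 when none is detected).
Per protein, a two-sided variance-ratio F-test at alpha = 0.05 gates the
choice of location test: variances compatible -> equal-variance t-test,
otherwise Mann-Whitney. Raw p-values are corrected across all tested
proteins with the Benjamini-Hochberg step-up procedure; the fold change is
the ratio of group means (case / control).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import Assignment

__all__ = [
    "DifferentialResult",
    "protein_abundance_matrix",
    "differential_test",
    "bh_adjust",
    "fold_change",
    "summarize_results",
    "results_frame",
]


@dataclass(frozen=True)
class DifferentialResult:
    """Per-protein differential-abundance summary (one report row)."""

    protein: str
    fold_change: float
    fold_sd: float
    raw_p: float
    adj_p: float
    test_used: str  # "t" or "ranksum"
    significant_raw: bool
    significant_adj: bool


def protein_abundance_matrix(
    assignments: Iterable[Assignment],
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    proteins: Iterable[str] | None = None,
) -> pd.DataFrame:
    """Protein x sample abundance table from annotated consensus peptides.

    ``matrix`` is the consensus x sample intensity matrix (NaN = not
    detected). For each protein and sample the abundance is the mean over
    that protein's peptides detected in the sample; a protein with no
    detected peptide in a sample gets 0. ``proteins`` restricts the roll-up
    (e.g. to those passing the minimum-peptides rule).
    """
    sample_cols = [c for c in matrix.columns if c in labels]
    missing = [c for c in matrix.columns if c not in labels and c not in ("mass", "time", "frequency")]
    if missing:
        raise KeyError(f"samples without manifest label: {missing}")
    keep = set(proteins) if proteins is not None else None
    by_protein: dict[str, list[str]] = {}
    for a in assignments:
        prot = a.peptide.protein
        if keep is not None and prot not in keep:
            continue
        if a.consensus_id in matrix.index:
            by_protein.setdefault(prot, []).append(a.consensus_id)
    rows = {}
    for prot in sorted(by_protein):
        block = matrix.loc[by_protein[prot], sample_cols]
        rows[prot] = block.mean(axis=0, skipna=True).fillna(0.0)
    out = pd.DataFrame(rows).T
    out.index.name = "protein"
    return out


def differential_test(
    case: Sequence[float], control: Sequence[float], alpha: float = 0.05
) -> tuple[float, str]:
    """Two-sided location test with an F-test gate on the variances.

    Returns ``(raw_p, test_used)`` where ``test_used`` is ``"t"``
    (equal-variance t-test; variance-ratio F-test p >= alpha) or
    ``"ranksum"`` (Mann-Whitney; the gate rejected). Two constant, equal
    groups give p = 1 by convention.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    if x.size < 3 or y.size < 3:
        raise ValueError("need at least 3 values per group")
    vx, vy = x.var(ddof=1), y.var(ddof=1)
    if vx == 0.0 and vy == 0.0:
        if np.mean(x) == np.mean(y):
            return 1.0, "t"
        # perfectly separated constants: fall through to the rank test
        p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
        return p, "ranksum"
    f = vx / vy if vy > 0 else np.inf
    if np.isfinite(f):
        cdf = stats.f.cdf(f, x.size - 1, y.size - 1)
        p_f = 2.0 * min(cdf, 1.0 - cdf)
    else:
        p_f = 0.0
    if p_f >= alpha:
        p = float(stats.ttest_ind(x, y, equal_var=True).pvalue)
        return p, "t"
    p = float(stats.mannwhitneyu(x, y, alternative="two-sided").pvalue)
    return p, "ranksum"


def bh_adjust(p_values: Sequence[float], m_total: int | None = None) -> list[float]:
    """Benjamini-Hochberg step-up adjusted p-values, in input order.

    ``adjusted(i) = min_{j >= i} p_(j) * m / j`` over the ascending order
    statistics, capped at 1. ``m_total`` sets the number of tests m; it may
    exceed ``len(p_values)`` when additional tests were performed but their
    (non-significant) p-values are not listed.
    """
    p = np.asarray(p_values, dtype=float)
    if p.size == 0:
        return []
    if np.any((p <= 0) | (p > 1)) or not np.all(np.isfinite(p)):
        raise ValueError("p-values must lie in (0, 1]")
    m = p.size if m_total is None else int(m_total)
    if m < p.size:
        raise ValueError(f"m_total ({m}) smaller than number of p-values ({p.size})")
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, p.size + 1)
    adjusted_sorted = np.minimum.accumulate(ranked[::-1])[::-1]
    adjusted_sorted = np.minimum(adjusted_sorted, 1.0)
    out = np.empty_like(adjusted_sorted)
    out[order] = adjusted_sorted
    return out.tolist()


def fold_change(
    case: Sequence[float], control: Sequence[float]
) -> tuple[float, float]:
    """Case/control ratio of group means, with its dispersion.

    ``fold = mean(case) / mean(control)``; ``fold_sd`` is the standard
    deviation of the per-case-sample values divided by the control mean,
    i.e. the spread of single-sample fold estimates around the reported
    ratio.
    """
    x = np.asarray(case, dtype=float)
    y = np.asarray(control, dtype=float)
    mc = float(np.mean(y))
    if mc <= 0:
        raise ValueError("control mean must be positive for a fold change")
    fold = float(np.mean(x)) / mc
    fold_sd = float(np.std(x, ddof=1)) / mc if x.size > 1 else float("nan")
    return fold, fold_sd


def summarize_results(
    table: pd.DataFrame,
    labels: Mapping[str, str],
    alpha: float = 0.05,
    m_total: int | None = None,
) -> list[DifferentialResult]:
    """Full differential report over a protein x sample abundance table.

    Runs the gated location test and fold change per protein, adjusts the
    raw p-values across all tested proteins (``m_total`` defaults to the
    number tested) and returns results sorted by raw p-value.
    """
    sample_cols = [c for c in table.columns if c in labels]
    case_cols = [c for c in sample_cols if labels[c] == "case"]
    ctrl_cols = [c for c in sample_cols if labels[c] == "control"]
    if not case_cols or not ctrl_cols:
        return []
    proteins: list[str] = []
    raw_ps: list[float] = []
    tests: list[str] = []
    folds: list[tuple[float, float]] = []
    for prot, row in table.iterrows():
        x = row[case_cols].to_numpy(dtype=float)
        y = row[ctrl_cols].to_numpy(dtype=float)
        p, used = differential_test(x, y, alpha=alpha)
        try:
            fc, fsd = fold_change(x, y)
        except ValueError:
            fc, fsd = float("nan"), float("nan")
        proteins.append(str(prot))
        raw_ps.append(p)
        tests.append(used)
        folds.append((fc, fsd))
    adj = bh_adjust(raw_ps, m_total=m_total if m_total is not None else len(raw_ps))
    results = [
        DifferentialResult(
            protein=prot,
            fold_change=fc,
            fold_sd=fsd,
            raw_p=p,
            adj_p=a,
            test_used=used,
            significant_raw=p < alpha,
            significant_adj=a < alpha,
        )
        for prot, p, a, used, (fc, fsd) in zip(proteins, raw_ps, adj, tests, folds)
    ]
    results.sort(key=lambda r: (r.raw_p, r.protein))
    return results


def results_frame(results: Sequence[DifferentialResult]) -> pd.DataFrame:
    """Serialise differential results to the report table."""
    return pd.DataFrame(
        {
            "protein": [r.protein for r in results],
            "fold_change": [r.fold_change for r in results],
            "fold_sd": [r.fold_sd for r in results],
            "raw_p": [r.raw_p for r in results],
            "adj_p": [r.adj_p for r in results],
            "test_used": [r.test_used for r in results],
            "significant_adj": [r.significant_adj for r in results],
        }
    )
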