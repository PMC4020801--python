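"""Migration-time/mass calibration and internal-standard intensity scaling.

Each sample is mapped into a cohort reference frame: features detected in at
least 35% of samples (after a provisional cross-sample clustering) define
reference signals whose canonical coordinates are across-sample medians;
each sample's observed coordinates are regressed onto the canonical ones by
ordinary least squares, separately for time and mass, and the fitted map is
applied to all of that sample's features.

Signal intensities are normalised with internal standards: consensus
peptides detected consistently across the cohort and not associated with
the case/control contrast. Each sample is scaled so its median standard
intensity matches the cohort-wide reference median.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .matching import DEFAULT_TOLERANCES, ToleranceModel, match_features

__all__ = [
    "CalibrationError",
    "ReferenceMap",
    "AlignmentModel",
    "IntensityScaler",
    "select_reference_features",
    "fit_alignment",
    "apply_alignment",
    "select_internal_standards",
    "normalize_intensities",
]

logger = logging.getLogger(__name__)


class CalibrationError(RuntimeError):
    """Raised when a sample or cohort cannot be calibrated."""


@dataclass
class ReferenceMap:
    """Canonical (mass, time) coordinates of high-frequency reference signals."""

    references: pd.DataFrame  # columns: canonical_mass, canonical_time
    frequency_threshold: float = 0.35


@dataclass
class AlignmentModel:
    """Linear observed -> canonical map for one sample.

    ``time_slope``/``time_intercept`` map observed migration time to the
    canonical frame (minutes); ``mass_slope``/``mass_intercept`` likewise
    for neutral mass (Da). ``n_support`` is the number of matched
    references the fit rests on.
    """

    sample_id: str
    time_slope: float
    time_intercept: float
    mass_slope: float
    mass_intercept: float
    n_support: int

    def __post_init__(self) -> None:
        for name, slope in (("time", self.time_slope), ("mass", self.mass_slope)):
            if not 0.5 < slope < 2.0:
                raise CalibrationError(
                    f"{self.sample_id}: {name} slope {slope:.4f} outside (0.5, 2.0); "
                    "calibration failure"
                )
        if self.n_support < 5:
            raise CalibrationError(
                f"{self.sample_id}: only {self.n_support} matched references (< 5)"
            )

    @property
    def drift_estimate(self) -> tuple[float, float]:
        """Implied forward drift (slope, intercept): canonical -> observed time."""
        return 1.0 / self.time_slope, -self.time_intercept / self.time_slope


@dataclass
class IntensityScaler:
    """Per-sample multiplicative factors derived from internal standards."""

    standards: list[str]
    factors: dict[str, float]
    reference_median: float
    flagged_samples: list[str] = field(default_factory=list)


def select_reference_features(
    feature_tables: Mapping[str, pd.DataFrame],
    threshold: float = 0.35,
    tolerances: ToleranceModel = DEFAULT_TOLERANCES,
) -> ReferenceMap:
    """Pick cross-sample reference signals with detection frequency >= threshold.

    A provisional clustering of the (still unaligned) feature tables is
    computed with the standard identity tolerances; clusters passing the
    frequency threshold become references with canonical coordinates equal
    to the across-sample medians of their member features.
    """
    if len(feature_tables) < 3:
        raise CalibrationError("need at least 3 samples to select references")
    n = len(feature_tables)
    clusters = match_features(feature_tables, tolerances)
    refs = [cp for cp in clusters if cp.n_samples / n >= threshold]
    if not refs:
        raise CalibrationError(
            f"no cluster reaches detection frequency {threshold:.2f}; "
            "calibration impossible"
        )
    df = pd.DataFrame(
        {
            "canonical_mass": [
                float(np.median([m for _, m, _, _ in cp.members])) for cp in refs
            ],
            "canonical_time": [
                float(np.median([t for _, _, t, _ in cp.members])) for cp in refs
            ],
        }
    ).sort_values("canonical_mass", ignore_index=True)
    return ReferenceMap(references=df, frequency_threshold=threshold)


def _match_references(
    features: pd.DataFrame,
    refmap: ReferenceMap,
    tolerances: ToleranceModel,
    time_slack: float = 3.0,
) -> pd.DataFrame:
    """Pair each reference with its nearest in-tolerance sample feature.

    The time window is widened by ``time_slack`` relative to the identity
    window: pre-calibration drift can exceed the post-calibration identity
    criterion, and the mass tolerance disambiguates candidates.
    """
    fm = features["neutral_mass"].to_numpy(dtype=float)
    ft = features["migration_time_min"].to_numpy(dtype=float)
    order = np.argsort(fm)
    fm_sorted = fm[order]
    rows = []
    for ref in refmap.references.itertuples(index=False):
        tol = tolerances.mass_tolerance_da(ref.canonical_mass)
        win = time_slack * tolerances.ce_window_min(ref.canonical_time)
        lo = np.searchsorted(fm_sorted, ref.canonical_mass - tol)
        hi = np.searchsorted(fm_sorted, ref.canonical_mass + tol)
        best = None
        best_d = np.inf
        for j in order[lo:hi]:
            dt = abs(ft[j] - ref.canonical_time)
            if dt > win:
                continue
            d = np.hypot((fm[j] - ref.canonical_mass) / tol, dt / win)
            if d < best_d:
                best, best_d = j, d
        if best is not None:
            rows.append(
                (
                    fm[best],
                    ft[best],
                    ref.canonical_mass,
                    ref.canonical_time,
                )
            )
    return pd.DataFrame(
        rows,
        columns=["observed_mass", "observed_time", "canonical_mass", "canonical_time"],
    )


def fit_alignment(
    features: pd.DataFrame,
    refmap: ReferenceMap,
    sample_id: str = "",
    tolerances: ToleranceModel = DEFAULT_TOLERANCES,
    trim_outliers: bool = True,
) -> AlignmentModel:
    """OLS fit of observed (time, mass) onto the canonical reference frame.

    An optional single trim pass removes matches with time residuals beyond
    3 SD before refitting. Fewer than 5 matched references is an alignment
    failure: the sample must be flagged, never silently passed through.
    """
    matched = _match_references(features, refmap, tolerances)
    if len(matched) < 5:
        raise CalibrationError(
            f"{sample_id or 'sample'}: only {len(matched)} matched references (< 5)"
        )

    def _ols(x: np.ndarray, y: np.ndarray) -> tuple[float, float]:
        res = stats.linregress(x, y)
        return float(res.slope), float(res.intercept)

    x_t = matched["observed_time"].to_numpy()
    y_t = matched["canonical_time"].to_numpy()
    x_m = matched["observed_mass"].to_numpy()
    y_m = matched["canonical_mass"].to_numpy()
    ts, ti = _ols(x_t, y_t)
    if trim_outliers:
        resid = y_t - (ts * x_t + ti)
        sd = resid.std(ddof=1)
        if sd > 0:
            keep = np.abs(resid) <= 3 * sd
            if keep.sum() >= 5 and keep.sum() < len(keep):
                x_t, y_t = x_t[keep], y_t[keep]
                x_m, y_m = x_m[keep], y_m[keep]
                ts, ti = _ols(x_t, y_t)
    ms, mi = _ols(x_m, y_m)
    return AlignmentModel(
        sample_id=sample_id,
        time_slope=ts,
        time_intercept=ti,
        mass_slope=ms,
        mass_intercept=mi,
        n_support=len(x_t),
    )


def apply_alignment(features: pd.DataFrame, model: AlignmentModel) -> pd.DataFrame:
    """Transform a sample's coordinates into the canonical frame.

    Intensities and the feature count are untouched.
    """
    out = features.copy()
    out["migration_time_min"] = (
        model.time_slope * features["migration_time_min"] + model.time_intercept
    )
    out["neutral_mass"] = model.mass_slope * features["neutral_mass"] + model.mass_intercept
    return out


def select_internal_standards(
    matrix: pd.DataFrame,
    labels: Mapping[str, str],
    k: int = 22,
    min_frequency: float = 0.8,
    p_floor: float = 0.5,
) -> list[str]:
    """Choose internal-standard consensus peptides from the intensity matrix.

    Candidates are consensuses detected in at least ``min_frequency`` of
    samples whose case/control rank-sum p-value exceeds ``p_floor`` (i.e.
    peptides showing no hint of disease association); the ``k`` most
    consistently detected candidates are returned.
    """
    sample_cols = [c for c in matrix.columns if c in labels]
    case_cols = [c for c in sample_cols if labels[c] == "case"]
    ctrl_cols = [c for c in sample_cols if labels[c] == "control"]
    candidates: list[tuple[float, float, str]] = []
    for cid, row in matrix.iterrows():
        vals = row[sample_cols]
        freq = float(vals.notna().mean())
        if freq < min_frequency:
            continue
        case_vals = row[case_cols].dropna().to_numpy(dtype=float)
        ctrl_vals = row[ctrl_cols].dropna().to_numpy(dtype=float)
        if len(case_vals) < 3 or len(ctrl_vals) < 3:
            continue
        p = float(
            stats.mannwhitneyu(case_vals, ctrl_vals, alternative="two-sided").pvalue
        )
        if p <= p_floor:
            continue
        candidates.append((freq, p, str(cid)))
    candidates.sort(key=lambda c: (-c[0], -c[1], c[2]))
    return [cid for _, _, cid in candidates[:k]]


def normalize_intensities(
    matrix: pd.DataFrame,
    standards: Sequence[str],
    labels: Mapping[str, str] | None = None,
    min_detected: int = 3,
) -> tuple[pd.DataFrame, IntensityScaler]:
    """Scale each sample so its median standard intensity hits the cohort median.

    The cohort reference is the median over samples of the per-sample median
    standard intensity; each sample's factor is reference / sample median. A
    sample with fewer than ``min_detected`` detected standards is flagged
    and left unscaled (factor 1).
    """
    standards = list(standards)
    if not standards:
        raise ValueError("no internal standards supplied")
    sample_cols = (
        [c for c in matrix.columns if c in labels]
        if labels is not None
        else [c for c in matrix.columns if c not in ("mass", "time", "frequency")]
    )
    std_block = matrix.loc[standards, sample_cols]
    per_sample_median = std_block.median(axis=0, skipna=True)
    n_detected = std_block.notna().sum(axis=0)
    reference = float(per_sample_median.dropna().median())
    factors: dict[str, float] = {}
    flagged: list[str] = []
    for sid in sample_cols:
        if n_detected[sid] < min_detected or not np.isfinite(per_sample_median[sid]):
            factors[sid] = 1.0
            flagged.append(sid)
            logger.warning(
                "sample %s: %d detected standards (< %d); factor imputed as 1",
                sid,
                int(n_detected[sid]),
                min_detected,
            )
        else:
            factors[sid] = reference / float(per_sample_median[sid])
    out = matrix.copy()
    for sid in sample_cols:
        out[sid] = matrix[sid] * factors[sid]
    return out, IntensityScaler(
        standards=standards,
        factors=factors,
        reference_median=reference,
        flagged_samples=flagged,
    )
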