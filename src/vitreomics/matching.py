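"""Peptide-identity tolerances and cross-sample consensus clustering.

Two deconvoluted features (neutral mass, CE migration time) are considered
the same peptide when their mass deviation and migration-time deviation both
fall inside mass- and time-dependent windows:

* mass tolerance grows linearly from +/-50 ppm at 800 Da to +/-75 ppm at
  15 kDa (clamped outside the anchors);
* the CE time window grows linearly from 2% of the migration time at 19 min
  to 5% at 50 min (clamped), interpreted as a symmetric half-width.

Features from all samples are clustered greedily in descending intensity
order into consensus peptides; consensuses observed in only one sample are
discarded as sporadic.
"""

from __future__ import annotations

import bisect
import math
from dataclasses import dataclass, field
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

__all__ = [
    "ToleranceModel",
    "DEFAULT_TOLERANCES",
    "mass_tolerance",
    "ce_window",
    "ConsensusPeptide",
    "match_features",
    "filter_singletons",
    "consensus_matrix",
]


def _linear_clamped(x: float, x0: float, y0: float, x1: float, y1: float) -> float:
    if x <= x0:
        return y0
    if x >= x1:
        return y1
    return y0 + (y1 - y0) * (x - x0) / (x1 - x0)


@dataclass(frozen=True)
class ToleranceModel:
    """Piecewise-linear identity tolerances for mass (ppm) and CE time (%).

    Anchors are ``(abscissa, value)`` pairs; the tolerance is linear between
    them and clamped to the anchor value outside.
    """

    mass_anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (800.0, 50.0),
        (15000.0, 75.0),
    )
    time_anchors: tuple[tuple[float, float], tuple[float, float]] = (
        (19.0, 2.0),
        (50.0, 5.0),
    )

    def mass_tolerance_ppm(self, mass: float) -> float:
        """Half-width mass tolerance in ppm at the given neutral mass (Da)."""
        if mass <= 0:
            raise ValueError(f"mass must be positive, got {mass}")
        (x0, y0), (x1, y1) = self.mass_anchors
        return _linear_clamped(mass, x0, y0, x1, y1)

    def mass_tolerance_da(self, mass: float) -> float:
        """Half-width mass tolerance in Da at the given neutral mass."""
        return mass * self.mass_tolerance_ppm(mass) * 1e-6

    def ce_window_percent(self, time: float) -> float:
        """Half-width CE time window as a percentage of the migration time."""
        if time <= 0:
            raise ValueError(f"migration time must be positive, got {time}")
        (x0, y0), (x1, y1) = self.time_anchors
        return _linear_clamped(time, x0, y0, x1, y1)

    def ce_window_min(self, time: float) -> float:
        """Half-width CE time window in minutes at the given migration time."""
        return time * self.ce_window_percent(time) / 100.0


DEFAULT_TOLERANCES = ToleranceModel()


def mass_tolerance(mass: float) -> float:
    """Mass identity tolerance (ppm) of the default model."""
    return DEFAULT_TOLERANCES.mass_tolerance_ppm(mass)


def ce_window(time: float) -> float:
    """CE time identity window (percent) of the default model."""
    return DEFAULT_TOLERANCES.ce_window_percent(time)


@dataclass
class ConsensusPeptide:
    """A cross-sample cluster of features treated as one molecular species.

    ``mass`` and ``time`` are intensity-weighted centroids over the member
    features; ``intensities`` maps sample id to that sample's feature
    intensity (absent key = not detected).
    """

    id: str
    mass: float
    time: float
    intensities: dict[str, float] = field(default_factory=dict)
    charges: set[int] = field(default_factory=set)
    # (sample_id, mass, time, intensity) per member feature
    members: list[tuple[str, float, float, float]] = field(default_factory=list)

    @property
    def n_samples(self) -> int:
        return len(self.intensities)

    @property
    def total_intensity(self) -> float:
        return sum(self.intensities.values())

    def frequency(self, n_total_samples: int) -> float:
        return self.n_samples / n_total_samples


def _parse_charges(val) -> set[int]:
    if isinstance(val, (set, frozenset, list, tuple)):
        return {int(v) for v in val}
    if isinstance(val, str):
        return {int(tok) for tok in val.split(";") if tok}
    return {int(val)}


def match_features(
    feature_tables: Mapping[str, pd.DataFrame],
    tolerances: ToleranceModel = DEFAULT_TOLERANCES,
) -> list[ConsensusPeptide]:
    """Cluster aligned per-sample feature tables into consensus peptides.

    Greedy centroid clustering: features are visited in descending intensity
    order (ties broken by mass, time, sample id so the result is
    deterministic). Each feature joins the nearest existing consensus whose
    centroid lies within both the mass tolerance and the CE window evaluated
    at the centroid, provided that consensus has no feature from the same
    sample yet; otherwise it seeds a new consensus. Centroids are
    intensity-weighted means; "nearest" is the smallest Euclidean distance in
    tolerance-normalised (mass, time) units, ties resolved toward the lower
    centroid mass.

    Parameters
    ----------
    feature_tables
        Mapping sample id -> DataFrame with columns ``neutral_mass``,
        ``migration_time_min``, ``intensity`` and optionally ``charges``.
    """
    rows: list[tuple[float, float, float, str, set[int]]] = []
    for sample_id, df in feature_tables.items():
        has_z = "charges" in df.columns
        for rec in df.itertuples(index=False):
            charges = _parse_charges(getattr(rec, "charges")) if has_z else set()
            rows.append(
                (
                    float(rec.intensity),
                    float(rec.neutral_mass),
                    float(rec.migration_time_min),
                    str(sample_id),
                    charges,
                )
            )
    rows.sort(key=lambda r: (-r[0], r[1], r[2], r[3]))

    consensuses: list[ConsensusPeptide] = []
    # parallel sorted structure over centroid masses for windowed lookup
    sorted_masses: list[float] = []
    sorted_refs: list[ConsensusPeptide] = []

    def _reinsert(cp: ConsensusPeptide, old_mass: float) -> None:
        i = bisect.bisect_left(sorted_masses, old_mass)
        while sorted_refs[i] is not cp:
            i += 1
        del sorted_masses[i], sorted_refs[i]
        j = bisect.bisect_left(sorted_masses, cp.mass)
        sorted_masses.insert(j, cp.mass)
        sorted_refs.insert(j, cp)

    for intensity, m, t, sample_id, charges in rows:
        # generous bracket: tolerance never exceeds 75 ppm
        half = m * 80e-6
        lo = bisect.bisect_left(sorted_masses, m - half)
        hi = bisect.bisect_right(sorted_masses, m + half)
        best: ConsensusPeptide | None = None
        best_key: tuple[float, float] | None = None
        for cp in sorted_refs[lo:hi]:
            if sample_id in cp.intensities:
                continue
            dm = abs(m - cp.mass)
            if dm > tolerances.mass_tolerance_da(cp.mass):
                continue
            dt = abs(t - cp.time)
            win = tolerances.ce_window_min(cp.time)
            if dt > win:
                continue
            dist = math.hypot(dm / tolerances.mass_tolerance_da(cp.mass), dt / win)
            key = (dist, cp.mass)
            if best_key is None or key < best_key:
                best, best_key = cp, key
        if best is None:
            cp = ConsensusPeptide(id="", mass=m, time=t)
            cp.intensities[sample_id] = intensity
            cp.charges |= charges
            cp.members.append((sample_id, m, t, intensity))
            consensuses.append(cp)
            j = bisect.bisect_left(sorted_masses, m)
            sorted_masses.insert(j, m)
            sorted_refs.insert(j, cp)
        else:
            old_mass = best.mass
            w_old = best.total_intensity
            w_new = w_old + intensity
            best.mass = (best.mass * w_old + m * intensity) / w_new
            best.time = (best.time * w_old + t * intensity) / w_new
            best.intensities[sample_id] = intensity
            best.charges |= charges
            best.members.append((sample_id, m, t, intensity))
            _reinsert(best, old_mass)

    consensuses.sort(key=lambda cp: (cp.mass, cp.time))
    for i, cp in enumerate(consensuses):
        cp.id = f"cp{i:05d}"
    return consensuses


def filter_singletons(
    consensuses: Iterable[ConsensusPeptide],
) -> list[ConsensusPeptide]:
    """Drop consensus peptides observed in a single sample only.

    Sporadically observed peptides carry no cross-sample information and are
    removed before any further analysis.
    """
    kept = [cp for cp in consensuses if cp.n_samples >= 2]
    return kept


def consensus_matrix(
    consensuses: Iterable[ConsensusPeptide], sample_ids: Iterable[str]
) -> pd.DataFrame:
    """Consensus x sample intensity matrix; NaN marks 'not detected'.

    Index = consensus ids; extra columns ``mass``, ``time`` and ``frequency``
    precede the per-sample intensity columns.
    """
    sample_ids = list(sample_ids)
    consensuses = list(consensuses)
    data = {
        "mass": [cp.mass for cp in consensuses],
        "time": [cp.time for cp in consensuses],
        "frequency": [cp.n_samples / len(sample_ids) for cp in consensuses],
    }
    mat = pd.DataFrame(data, index=[cp.id for cp in consensuses])
    for sid in sample_ids:
        mat[sid] = [cp.intensities.get(sid, np.nan) for cp in consensuses]
    mat.index.name = "id"
    return mat
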