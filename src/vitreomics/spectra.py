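"""Per-sample spectral processing: noise floor, charge inference, deconvolution.

A raw peak list (m/z, intensity, migration time) is reduced to deconvoluted
neutral-mass features in three steps:

1. a robust noise floor is estimated from the sub-median intensities and
   peaks with signal-to-noise <= 4 are discarded;
2. co-migrating peaks spaced by 1.00235/z are grouped into isotope
   envelopes and their charge inferred; singly charged envelopes are
   discarded;
3. envelopes of the same molecule at different charge states (neutral
   masses within the identity tolerance, times within the CE window) are
   merged into one feature with summed intensity.

Neutral masses are monoisotopic: M = z * (m/z) - z * 1.00728.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .constants import ISOTOPE_SPACING, PROTON_MASS, SNR_THRESHOLD
from .matching import DEFAULT_TOLERANCES, ToleranceModel

__all__ = [
    "RawPeak",
    "Feature",
    "InsufficientDataError",
    "estimate_noise",
    "infer_charge",
    "deconvolute_peaks",
    "features_to_frame",
]

#: ppm tolerance on isotope spacings when inferring charge.
SPACING_PPM_TOL = 20.0
#: charge states searched during envelope detection.
CHARGE_RANGE = range(1, 11)


class InsufficientDataError(ValueError):
    """Raised when a peak list is too small for a robust estimate."""


@dataclass(frozen=True)
class RawPeak:
    """One detected ion signal: m/z (Th), intensity (counts), time (min)."""

    mz: float
    intensity: float
    migration_time: float


@dataclass
class Feature:
    """A deconvoluted neutral-mass signal in one sample."""

    neutral_mass: float
    migration_time: float
    intensity: float
    charges: set[int] = field(default_factory=set)
    snr: float = 0.0


def estimate_noise(intensities: Sequence[float] | np.ndarray) -> float:
    """Robust random-noise floor: 1.4826 x MAD of the sub-median intensities.

    Only intensities strictly below the overall median enter the estimate, so
    abundant analyte peaks cannot inflate it. A degenerate (constant) peak
    list yields machine epsilon rather than zero.
    """
    x = np.asarray(intensities, dtype=float)
    if x.size < 10:
        raise InsufficientDataError(
            f"need at least 10 peaks to estimate noise, got {x.size}"
        )
    floor = x[x < np.median(x)]
    if floor.size == 0:  # all intensities identical
        return float(np.finfo(float).eps)
    mad = np.median(np.abs(floor - np.median(floor)))
    est = 1.4826 * float(mad)
    if est <= 0.0:
        return float(np.finfo(float).eps)
    return est


def infer_charge(
    peak_mzs: Sequence[float],
    ppm_tol: float = SPACING_PPM_TOL,
) -> int | None:
    """Infer the charge of a co-migrating isotope envelope from its spacings.

    ``peak_mzs`` must be sorted ascending. Returns the charge z in [1, 10]
    whose expected spacing 1.00235/z matches every successive m/z difference
    within ``ppm_tol`` of the base (lowest) m/z, or None when no charge fits
    or the envelope has fewer than two peaks.
    """
    mzs = np.asarray(peak_mzs, dtype=float)
    if mzs.size < 2:
        return None
    diffs = np.diff(mzs)
    tol = ppm_tol * 1e-6 * mzs[0]
    best_z: int | None = None
    best_err = math.inf
    for z in CHARGE_RANGE:
        expected = ISOTOPE_SPACING / z
        if np.all(np.abs(diffs - expected) <= tol):
            err = float(np.max(np.abs(diffs - expected)))
            if err < best_err:
                best_z, best_err = z, err
    return best_z


def _build_envelopes(
    mz: np.ndarray,
    intensity: np.ndarray,
    time: np.ndarray,
    tolerances: ToleranceModel,
) -> list[tuple[int | None, np.ndarray]]:
    """Group peaks into isotope envelopes; returns (charge, member indices).

    Greedy: seeds are visited in descending intensity; for each charge the
    chain of peaks spaced 1.00235/z (within 20 ppm of the seed m/z) and
    co-migrating with the seed is collected, and the longest chain wins
    (ties toward higher charge). A peak that could extend two envelopes goes
    to the one whose seed is processed first, i.e. the more intense one.
    """
    order = np.lexsort((time, mz, -intensity))
    mz_order = np.argsort(mz, kind="stable")
    mz_sorted = mz[mz_order]
    used = np.zeros(mz.size, dtype=bool)
    envelopes: list[tuple[int | None, np.ndarray]] = []

    for seed in order:
        if used[seed]:
            continue
        seed_mz = mz[seed]
        seed_t = time[seed]
        tol = SPACING_PPM_TOL * 1e-6 * seed_mz
        t_win = tolerances.ce_window_min(max(seed_t, 1e-6))
        best_chain: list[int] = [seed]
        best_z: int | None = None
        for z in CHARGE_RANGE:
            step = ISOTOPE_SPACING / z
            chain = [seed]
            for direction in (1, -1):
                k = 1
                while True:
                    target = seed_mz + direction * k * step
                    lo = np.searchsorted(mz_sorted, target - tol)
                    hi = np.searchsorted(mz_sorted, target + tol)
                    cand = [
                        int(mz_order[i])
                        for i in range(lo, hi)
                        if not used[mz_order[i]]
                        and abs(time[mz_order[i]] - seed_t) <= t_win
                    ]
                    if not cand:
                        break
                    # closest in m/z to the expected isotope position
                    pick = min(cand, key=lambda i: abs(mz[i] - target))
                    chain.append(pick)
                    k += 1
            if len(chain) > len(best_chain) or (
                len(chain) == len(best_chain) and len(chain) > 1 and best_z is None
            ):
                best_chain = chain
                best_z = z
        members = np.array(sorted(best_chain, key=lambda i: mz[i]))
        used[members] = True
        if len(members) >= 2:
            z = infer_charge(mz[members])
            envelopes.append((z, members))
        else:
            envelopes.append((None, members))
    return envelopes


def deconvolute_peaks(
    peaks: pd.DataFrame,
    noise: float,
    tolerances: ToleranceModel = DEFAULT_TOLERANCES,
    snr_threshold: float = SNR_THRESHOLD,
) -> list[Feature]:
    """Deconvolute a peak table into neutral-mass features.

    Peaks with intensity/noise <= ``snr_threshold`` are discarded, isotope
    envelopes are assembled and charged, envelopes with inferred charge <= 1
    (or indeterminate charge) are dropped, and envelopes whose neutral
    masses agree within the identity tolerance and whose times fall within
    the CE window are merged into a single feature carrying the summed
    intensity and the union of charge states.

    ``peaks`` columns: ``mz``, ``intensity``, ``migration_time_min``.
    """
    if noise <= 0:
        raise ValueError(f"noise must be positive, got {noise}")
    if len(peaks) == 0:
        return []
    mz = peaks["mz"].to_numpy(dtype=float)
    intensity = peaks["intensity"].to_numpy(dtype=float)
    time = peaks["migration_time_min"].to_numpy(dtype=float)

    keep = intensity / noise > snr_threshold
    mz, intensity, time = mz[keep], intensity[keep], time[keep]
    if mz.size == 0:
        return []

    envelopes = _build_envelopes(mz, intensity, time, tolerances)

    # one provisional feature per multiply charged envelope
    provisional: list[Feature] = []
    for z, members in envelopes:
        if z is None or z <= 1:
            continue
        mono_mz = float(mz[members[0]])  # lowest m/z = monoisotopic peak
        mass = z * mono_mz - z * PROTON_MASS
        total = float(intensity[members].sum())
        t = float(np.average(time[members], weights=intensity[members]))
        provisional.append(
            Feature(
                neutral_mass=mass,
                migration_time=t,
                intensity=total,
                charges={z},
                snr=float(intensity[members].max() / noise),
            )
        )

    # merge charge states of the same molecule (greedy, intensity-descending)
    provisional.sort(key=lambda f: (-f.intensity, f.neutral_mass))
    merged: list[Feature] = []
    for f in provisional:
        best = None
        best_key = None
        for g in merged:
            dm = abs(f.neutral_mass - g.neutral_mass)
            if dm > tolerances.mass_tolerance_da(g.neutral_mass):
                continue
            dt = abs(f.migration_time - g.migration_time)
            win = tolerances.ce_window_min(g.migration_time)
            if dt > win:
                continue
            key = (dm / tolerances.mass_tolerance_da(g.neutral_mass), g.neutral_mass)
            if best_key is None or key < best_key:
                best, best_key = g, key
        if best is None:
            merged.append(
                Feature(
                    neutral_mass=f.neutral_mass,
                    migration_time=f.migration_time,
                    intensity=f.intensity,
                    charges=set(f.charges),
                    snr=f.snr,
                )
            )
        else:
            w = best.intensity + f.intensity
            best.neutral_mass = (
                best.neutral_mass * best.intensity + f.neutral_mass * f.intensity
            ) / w
            best.migration_time = (
                best.migration_time * best.intensity + f.migration_time * f.intensity
            ) / w
            best.intensity = w
            best.charges |= f.charges
            best.snr = max(best.snr, f.snr)
    merged.sort(key=lambda f: (f.neutral_mass, f.migration_time))
    return merged


def features_to_frame(features: Sequence[Feature]) -> pd.DataFrame:
    """Serialise features to the tabular interchange form."""
    return pd.DataFrame(
        {
            "neutral_mass": [f.neutral_mass for f in features],
            "migration_time_min": [f.migration_time for f in features],
            "intensity": [f.intensity for f in features],
            "charges": [";".join(str(z) for z in sorted(f.charges)) for f in features],
            "snr": [f.snr for f in features],
        }
    )
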