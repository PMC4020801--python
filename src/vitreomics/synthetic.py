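"""Ground-truth synthetic CE-MS cohort generator.

Emulates the statistical structure of a tryptic-digest vitreous peptidome
measured by CE-TOF: per-sample peak lists built from isotope-resolved charge
envelopes of tryptic peptides of a random protein database, with

* case/control fold changes on a subset of proteins (effect sizes drawn
  from the published differential-protein fold changes, all upregulated);
* invariant internal-standard peptides detected at high frequency;
* per-sample linear drift in migration time and mass plus small
  measurement jitter;
* multiplicative lognormal intensity noise and per-sample gain;
* peptide-level Bernoulli missingness;
* a uniform low-intensity decoy noise floor below the SNR threshold.

The migration model places a peptide of neutral mass M and charge z at a
time proportional to M^(2/3)/z (classical electrophoretic mobility
scaling), affinely mapped onto the 19-50 min window. Everything is
deterministic given the cohort seed.
"""

from __future__ import annotations

import os
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

from .annotation import cleavage_fragments, peptide_mass, predict_charge
from .constants import (
    CE_TIME_MAX,
    CE_TIME_MIN,
    ISOTOPE_SPACING,
    MZ_MAX,
    MZ_MIN,
    PEPTIDE_MASS_MAX,
    PEPTIDE_MASS_MIN,
    PROTON_MASS,
)
from .reference_data import DIFFERENTIAL_FOLD_CHANGES, STUDY_GROUP_SIZES

__all__ = [
    "DriftParams",
    "TruthPeptide",
    "GroundTruthCohort",
    "SimulatedSample",
    "generate_protein_db",
    "build_cohort",
    "simulate_sample_peaks",
    "simulate_cohort",
    "peptide_peak_coordinates",
]

#: intensity share of the primary and secondary charge state of a peptide
CHARGE_SHARES = (0.7, 0.3)
#: binomial isotope model: trials per Da and per-trial heavy probability
ISO_TRIALS_PER_DA = 0.0445
ISO_P_HEAVY = 0.011
#: isotope peaks below this fraction of the envelope are not emitted
ISO_MIN_FRACTION = 0.01


@dataclass(frozen=True)
class DriftParams:
    """Per-sample linear distortion of migration time and neutral mass."""

    time_slope: float = 1.0
    time_intercept: float = 0.0  # minutes
    mass_slope: float = 1.0
    mass_intercept: float = 0.0  # Da


@dataclass(frozen=True)
class TruthPeptide:
    """One ground-truth tryptic peptide of the simulated proteome."""

    sequence: str
    protein: str
    mass: float  # monoisotopic, carbamidomethyl-C included, Da
    predicted_charge: int
    base_abundance: float  # pre-noise intensity in the control condition
    detection_prob: float
    is_standard: bool = False


@dataclass
class GroundTruthCohort:
    """Complete description of a simulated case/control CE-MS cohort."""

    protein_db: list[tuple[str, str]]
    true_fold_changes: dict[str, float]
    internal_standard_peptides: list[str]
    drift_params: dict[str, DriftParams]
    noise_cv: float
    detection_prob: float
    group_sizes: tuple[int, int]
    seed: int
    peptides: list[TruthPeptide] = field(default_factory=list)
    manifest: pd.DataFrame = field(default_factory=pd.DataFrame)
    sample_gains: dict[str, float] = field(default_factory=dict)
    time_map: tuple[float, float] = (0.0, 34.5)  # t = a * M^(2/3)/z + b
    mass_jitter_ppm: float = 2.0
    time_jitter_min: float = 0.05
    gain_sigma: float = 0.3
    noise_level: float = 30.0  # decoy floor scale (counts)
    n_decoys: int | None = None  # None -> match the real peak count

    @property
    def sample_ids(self) -> list[str]:
        return list(self.manifest["sample_id"])

    def group_of(self, sample_id: str) -> str:
        m = self.manifest.set_index("sample_id")["group"]
        if sample_id not in m.index:
            raise KeyError(f"unknown sample id {sample_id!r}")
        return str(m.loc[sample_id])


@dataclass
class SimulatedSample:
    """One simulated sample: its peak list and the peak-level truth map."""

    sample_id: str
    group: str
    peaks: pd.DataFrame  # mz, intensity, migration_time_min
    truth: pd.DataFrame  # peak_index, sequence, protein, charge, isotope


def _tryptic_in_range(sequence: str) -> list[str]:
    """Fully cleaved fragments whose modified mass is in the sequenced range."""
    return [
        frag
        for frag in cleavage_fragments(sequence)
        if PEPTIDE_MASS_MIN <= peptide_mass(frag) <= PEPTIDE_MASS_MAX
    ]


def generate_protein_db(
    n_proteins: int, mean_length: int, seed: int
) -> list[tuple[str, str]]:
    """Random protein records whose tryptic digests behave like real ones.

    Residues are drawn i.i.d. with K/R enriched so the average tryptic
    fragment is ~10 residues; each protein is redrawn until its digest
    yields at least two fully cleaved peptides in the sequenced mass range.
    """
    if n_proteins < 2:
        raise ValueError(f"n_proteins must be >= 2, got {n_proteins}")
    if mean_length < 50:
        raise ValueError(f"mean_length must be >= 50, got {mean_length}")
    rng = np.random.default_rng([seed, 17])
    alphabet = np.array(list("ACDEFGHIKLMNPQRSTVWY"))
    probs = np.full(20, (1.0 - 0.11) / 18)
    probs[alphabet == "K"] = 0.055
    probs[alphabet == "R"] = 0.055
    probs /= probs.sum()
    records: list[tuple[str, str]] = []
    for i in range(n_proteins):
        for _ in range(1000):
            length = max(50, int(round(rng.normal(mean_length, 0.15 * mean_length))))
            seq = "".join(rng.choice(alphabet, size=length, p=probs))
            if len(_tryptic_in_range(seq)) >= 2:
                records.append((f"SYN{i:04d}", seq))
                break
        else:  # pragma: no cover - astronomically unlikely
            raise RuntimeError("could not generate a digestible protein")
    return records


def build_cohort(
    n_proteins: int = 97,
    mean_length: int = 300,
    group_sizes: tuple[int, int] = STUDY_GROUP_SIZES,
    seed: int = 0,
    fraction_differential: float = 0.2,
    n_standards: int = 22,
    detection_prob: float = 0.8,
    standard_detection_prob: float = 0.95,
    noise_cv: float = 0.2,
    mass_jitter_ppm: float = 2.0,
    time_jitter_min: float = 0.05,
    gain_sigma: float = 0.3,
    drift_time_slope_sd: float = 0.01,
    drift_time_intercept_sd: float = 0.1,
    drift_mass_ppm_sd: float = 5.0,
    spike_folds: dict[str, float] | None = None,
) -> GroundTruthCohort:
    """Assemble a ground-truth cohort: proteins, folds, standards, drifts.

    ``spike_folds`` overrides the fold change of named proteins (accessions
    ``SYN0000`` ...), e.g. to plant a known effect for recovery tests.
    """
    if min(group_sizes) < 3:
        raise ValueError("each group needs at least 3 samples")
    rng = np.random.default_rng([seed, 29])
    protein_db = generate_protein_db(n_proteins, mean_length, seed)

    # fold changes: a fraction of proteins upregulated in cases, effect
    # sizes resampled from the published differential-protein magnitudes
    accs = [acc for acc, _ in protein_db]
    n_diff = int(round(fraction_differential * n_proteins))
    diff_accs = set(rng.choice(accs, size=n_diff, replace=False))
    folds = {
        acc: float(rng.choice(DIFFERENTIAL_FOLD_CHANGES)) if acc in diff_accs else 1.0
        for acc in accs
    }
    if spike_folds:
        unknown = set(spike_folds) - set(accs)
        if unknown:
            raise KeyError(f"spike_folds for unknown proteins: {sorted(unknown)}")
        folds.update({k: float(v) for k, v in spike_folds.items()})

    # truth peptides: fully cleaved, in the sequenced mass range
    peptides: list[TruthPeptide] = []
    for acc, seq in protein_db:
        base_prot = float(rng.lognormal(np.log(5e4), 0.7))
        for frag in _tryptic_in_range(seq):
            peptides.append(
                TruthPeptide(
                    sequence=frag,
                    protein=acc,
                    mass=peptide_mass(frag),
                    predicted_charge=predict_charge(frag),
                    base_abundance=base_prot * float(rng.lognormal(0.0, 0.4)),
                    detection_prob=detection_prob,
                )
            )

    # drop peptides whose every charge envelope falls outside the
    # acquisition window: the instrument can never observe them
    peptides = [
        p
        for p in peptides
        if any(
            MZ_MIN <= (p.mass + z * PROTON_MASS) / z <= MZ_MAX
            for z in _emitted_charges(p.predicted_charge)
        )
    ]

    # internal standards: multiply charged peptides of non-differential
    # proteins, spiked at invariant abundance and high detection frequency
    candidates = [
        i
        for i, p in enumerate(peptides)
        if folds[p.protein] == 1.0 and p.predicted_charge >= 2
    ]
    std_idx = set(
        int(i)
        for i in rng.choice(
            candidates, size=min(n_standards, len(candidates)), replace=False
        )
    )
    peptides = [
        TruthPeptide(
            sequence=p.sequence,
            protein=p.protein,
            mass=p.mass,
            predicted_charge=p.predicted_charge,
            base_abundance=p.base_abundance,
            detection_prob=standard_detection_prob if i in std_idx else p.detection_prob,
            is_standard=i in std_idx,
        )
        for i, p in enumerate(peptides)
    ]

    # manifest, per-sample drift and gain
    n_case, n_control = group_sizes
    sample_ids = [f"case{i + 1:02d}" for i in range(n_case)] + [
        f"ctrl{i + 1:02d}" for i in range(n_control)
    ]
    groups = ["case"] * n_case + ["control"] * n_control
    manifest = pd.DataFrame({"sample_id": sample_ids, "group": groups})
    drifts: dict[str, DriftParams] = {}
    gains: dict[str, float] = {}
    for sid in sample_ids:
        drifts[sid] = DriftParams(
            time_slope=float(1.0 + rng.normal(0.0, drift_time_slope_sd)),
            time_intercept=float(rng.normal(0.0, drift_time_intercept_sd)),
            mass_slope=float(1.0 + rng.normal(0.0, drift_mass_ppm_sd * 1e-6)),
            mass_intercept=float(rng.normal(0.0, 0.002)),
        )
        gains[sid] = float(rng.lognormal(0.0, gain_sigma))

    # affine map of M^(2/3)/z onto the CE time window; the solution-phase
    # (predicted) charge drives mobility, not the ESI charge states
    us = [p.mass ** (2.0 / 3.0) / p.predicted_charge for p in peptides]
    if us and max(us) > min(us):
        a = (CE_TIME_MAX - CE_TIME_MIN) / (max(us) - min(us))
        b = CE_TIME_MIN - a * min(us)
    else:
        a, b = 0.0, (CE_TIME_MIN + CE_TIME_MAX) / 2
    return GroundTruthCohort(
        protein_db=protein_db,
        true_fold_changes=folds,
        internal_standard_peptides=[p.sequence for p in peptides if p.is_standard],
        drift_params=drifts,
        noise_cv=noise_cv,
        detection_prob=detection_prob,
        group_sizes=group_sizes,
        seed=seed,
        peptides=peptides,
        manifest=manifest,
        sample_gains=gains,
        time_map=(a, b),
        mass_jitter_ppm=mass_jitter_ppm,
        time_jitter_min=time_jitter_min,
        gain_sigma=gain_sigma,
    )


def _emitted_charges(predicted_charge: int) -> tuple[int, ...]:
    """Charge states a peptide ionises at: the predicted one and one above."""
    return (predicted_charge, predicted_charge + 1)


def peptide_peak_coordinates(
    cohort: GroundTruthCohort, peptide: TruthPeptide, charge: int
) -> tuple[float, float]:
    """Drift-free model coordinates (monoisotopic m/z, migration time).

    The migration time is set by the solution-phase charge (the predicted
    CE charge), so every ESI charge state of a peptide co-migrates.
    """
    a, b = cohort.time_map
    mz = (peptide.mass + charge * PROTON_MASS) / charge
    t = a * peptide.mass ** (2.0 / 3.0) / peptide.predicted_charge + b
    return mz, t


def _isotope_fractions(mass: float) -> np.ndarray:
    """Binomial isotope envelope; index k = number of heavy isotopes."""
    n = max(1, int(round(mass * ISO_TRIALS_PER_DA)))
    fracs = stats.binom.pmf(np.arange(5), n, ISO_P_HEAVY)
    return fracs[fracs >= ISO_MIN_FRACTION]


def simulate_sample_peaks(
    cohort: GroundTruthCohort, sample_id: str
) -> SimulatedSample:
    """Emit one sample's peak list (plus truth map) from the cohort model."""
    ids = cohort.sample_ids
    if sample_id not in ids:
        raise KeyError(f"unknown sample id {sample_id!r}")
    idx = ids.index(sample_id)
    group = cohort.group_of(sample_id)
    drift = cohort.drift_params[sample_id]
    gain = cohort.sample_gains[sample_id]
    rng = np.random.default_rng([cohort.seed, 1000 + idx])
    sigma_noise = float(np.sqrt(np.log1p(cohort.noise_cv**2)))

    mzs: list[float] = []
    intens: list[float] = []
    times: list[float] = []
    truth_rows: list[tuple[int, str, str, int, int]] = []
    a, b = cohort.time_map

    for p in cohort.peptides:
        if rng.random() >= p.detection_prob:
            continue
        fold = cohort.true_fold_changes[p.protein] if group == "case" else 1.0
        abundance = (
            p.base_abundance * fold * gain * float(rng.lognormal(0.0, sigma_noise))
        )
        # one migration time per peptide: all ESI charge states co-migrate
        t_model = a * p.mass ** (2.0 / 3.0) / p.predicted_charge + b
        t_obs = (
            drift.time_slope * t_model
            + drift.time_intercept
            + rng.normal(0.0, cohort.time_jitter_min)
        )
        for z, share in zip(_emitted_charges(p.predicted_charge), CHARGE_SHARES):
            mass_drifted = drift.mass_slope * p.mass + drift.mass_intercept
            mass_obs = mass_drifted * (
                1.0 + rng.normal(0.0, cohort.mass_jitter_ppm * 1e-6)
            )
            fracs = _isotope_fractions(p.mass)
            mono_mz = (mass_obs + z * PROTON_MASS) / z
            for k, frac in enumerate(fracs):
                mz = mono_mz + k * ISOTOPE_SPACING / z
                if not (MZ_MIN <= mz <= MZ_MAX):
                    continue
                truth_rows.append((len(mzs), p.sequence, p.protein, z, k))
                mzs.append(float(mz))
                intens.append(float(abundance * share * frac))
                times.append(float(t_obs))

    # decoy noise floor: uniform intensities below the SNR threshold
    n_decoys = cohort.n_decoys if cohort.n_decoys is not None else len(mzs)
    decoy_mz = rng.uniform(MZ_MIN, MZ_MAX, size=n_decoys)
    decoy_t = rng.uniform(CE_TIME_MIN, CE_TIME_MAX, size=n_decoys)
    decoy_i = rng.uniform(0.0, 4.0 * cohort.noise_level, size=n_decoys)
    mzs.extend(decoy_mz.tolist())
    intens.extend(decoy_i.tolist())
    times.extend(decoy_t.tolist())

    peaks = pd.DataFrame(
        {"mz": mzs, "intensity": intens, "migration_time_min": times}
    )
    truth = pd.DataFrame(
        truth_rows, columns=["peak_index", "sequence", "protein", "charge", "isotope"]
    )
    return SimulatedSample(sample_id=sample_id, group=group, peaks=peaks, truth=truth)


def simulate_cohort(
    cohort: GroundTruthCohort, outdir: str | os.PathLike | None = None
) -> list[SimulatedSample]:
    """Simulate every sample; optionally write the full file bundle.

    Writes, under ``outdir``: one peak table per sample (``peaks/*.tsv``),
    the protein database (``database.fasta``), the cohort manifest
    (``manifest.csv``), the protein-level truth table
    (``truth_proteins.csv``) and per-sample peak truth maps
    (``truth/*.tsv``).
    """
    samples = [simulate_sample_peaks(cohort, sid) for sid in cohort.sample_ids]
    if outdir is not None:
        out = Path(outdir)
        (out / "peaks").mkdir(parents=True, exist_ok=True)
        (out / "truth").mkdir(parents=True, exist_ok=True)
        for s in samples:
            s.peaks.to_csv(
                out / "peaks" / f"{s.sample_id}.tsv",
                sep="\t",
                index=False,
                float_format="%.6f",
            )
            s.truth.to_csv(
                out / "truth" / f"{s.sample_id}.tsv", sep="\t", index=False
            )
        with open(out / "database.fasta", "w") as fh:
            for acc, seq in cohort.protein_db:
                fh.write(f">{acc}\n")
                for i in range(0, len(seq), 60):
                    fh.write(seq[i : i + 60] + "\n")
        cohort.manifest.to_csv(out / "manifest.csv", index=False)
        pep_by_prot: dict[str, list[str]] = {}
        for p in cohort.peptides:
            pep_by_prot.setdefault(p.protein, []).append(p.sequence)
        pd.DataFrame(
            {
                "protein": [acc for acc, _ in cohort.protein_db],
                "true_fold_change": [
                    cohort.true_fold_changes[acc] for acc, _ in cohort.protein_db
                ],
                "n_peptides": [
                    len(pep_by_prot.get(acc, [])) for acc, _ in cohort.protein_db
                ],
                "peptides": [
                    ";".join(pep_by_prot.get(acc, [])) for acc, _ in cohort.protein_db
                ],
            }
        ).to_csv(out / "truth_proteins.csv", index=False)
    return samples
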