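"""End-to-end orchestration: simulate -> deconvolute -> calibrate -> match
-> annotate -> differential statistics.

Every stage writes its tabular output under the configured output
directory, and a provenance log records the configuration hash, seed and
per-stage counts (the analysis funnel: peaks -> features -> consensus
peptides -> annotated -> proteins -> significant).
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd

from . import __version__
from .annotation import (
    annotate_features,
    build_digest_database,
    enforce_min_peptides,
)
from .calibration import (
    CalibrationError,
    apply_alignment,
    fit_alignment,
    normalize_intensities,
    select_internal_standards,
    select_reference_features,
)
from .diffstats import protein_abundance_matrix, results_frame, summarize_results
from .io import PipelineConfig, read_fasta, read_manifest, read_peak_table
from .matching import (
    ToleranceModel,
    consensus_matrix,
    filter_singletons,
    match_features,
)
from .spectra import deconvolute_peaks, estimate_noise, features_to_frame
from .synthetic import build_cohort, simulate_cohort

__all__ = ["PipelineResult", "run_pipeline"]

logger = logging.getLogger(__name__)


@dataclass
class PipelineResult:
    """Outputs of one full pipeline run."""

    config: PipelineConfig
    report: pd.DataFrame
    consensus: pd.DataFrame
    protein_table: pd.DataFrame
    provenance: dict
    flagged_samples: list[str] = field(default_factory=list)


def run_pipeline(config: PipelineConfig) -> PipelineResult:
    """Run the complete analysis described by ``config``.

    When ``config.peaks_dir`` is unset, a synthetic cohort is generated
    first and its files written under ``<out_dir>/input``.
    """
    out = Path(config.out_dir)
    out.mkdir(parents=True, exist_ok=True)
    tolerances = ToleranceModel(
        mass_anchors=tuple(tuple(a) for a in config.mass_anchors),
        time_anchors=tuple(tuple(a) for a in config.time_anchors),
    )
    counts: dict[str, int] = {}

    # stage 0: inputs
    if config.peaks_dir is None:
        if not config.simulate:
            raise ValueError("peaks_dir unset and simulation disabled")
        cohort = build_cohort(
            n_proteins=config.n_proteins,
            group_sizes=(config.n_case, config.n_control),
            seed=config.seed,
            fraction_differential=config.fraction_differential,
            noise_cv=config.noise_cv,
            detection_prob=config.detection_prob,
            n_standards=config.n_standards,
        )
        simulate_cohort(cohort, out / "input")
        peaks_dir = out / "input" / "peaks"
        fasta = out / "input" / "database.fasta"
        manifest_path = out / "input" / "manifest.csv"
    else:
        peaks_dir = Path(config.peaks_dir)
        if config.fasta is None or config.manifest is None:
            raise ValueError("fasta and manifest paths are required with peaks_dir")
        fasta = Path(config.fasta)
        manifest_path = Path(config.manifest)

    labels = read_manifest(manifest_path)
    if min(
        sum(1 for g in labels.values() if g == "case"),
        sum(1 for g in labels.values() if g == "control"),
    ) < 5:
        logger.warning("fewer than 5 samples in a group; statistics will be weak")
    proteins = read_fasta(fasta)
    counts["samples"] = len(labels)
    counts["proteins_in_database"] = len(proteins)

    # stage 1: deconvolution
    feature_tables: dict[str, pd.DataFrame] = {}
    n_peaks = 0
    for sid in sorted(labels):
        peaks = read_peak_table(peaks_dir / f"{sid}.tsv")
        n_peaks += len(peaks)
        noise = estimate_noise(peaks["intensity"])
        features = deconvolute_peaks(
            peaks, noise, tolerances, snr_threshold=config.snr
        )
        feature_tables[sid] = features_to_frame(features)
    counts["raw_peaks"] = n_peaks
    counts["features"] = sum(len(df) for df in feature_tables.values())
    logger.info("deconvolution: %d peaks -> %d features", n_peaks, counts["features"])

    # stage 2: calibration
    refmap = select_reference_features(feature_tables, config.ref_freq, tolerances)
    counts["reference_signals"] = len(refmap.references)
    aligned: dict[str, pd.DataFrame] = {}
    flagged: list[str] = []
    alignment_rows = []
    for sid, df in feature_tables.items():
        try:
            model = fit_alignment(df, refmap, sample_id=sid, tolerances=tolerances)
        except CalibrationError as exc:
            logger.warning("alignment failed, sample excluded: %s", exc)
            flagged.append(sid)
            continue
        aligned[sid] = apply_alignment(df, model)
        alignment_rows.append(
            {
                "sample_id": sid,
                "time_slope": model.time_slope,
                "time_intercept": model.time_intercept,
                "mass_slope": model.mass_slope,
                "mass_intercept": model.mass_intercept,
                "n_support": model.n_support,
            }
        )
    pd.DataFrame(alignment_rows).to_csv(out / "alignment.csv", index=False)
    refmap.references.to_csv(out / "references.csv", index=False)
    labels = {k: v for k, v in labels.items() if k in aligned}

    # stage 3: matching + normalization
    consensuses = filter_singletons(match_features(aligned, tolerances))
    counts["consensus_peptides"] = len(consensuses)
    matrix = consensus_matrix(consensuses, sorted(aligned))
    standards = select_internal_standards(
        matrix,
        labels,
        k=config.n_standards,
        min_frequency=config.standard_min_freq,
    )
    counts["internal_standards"] = len(standards)
    matrix, scaler = normalize_intensities(matrix, standards, labels)
    flagged.extend(scaler.flagged_samples)
    pd.DataFrame(
        {"sample_id": list(scaler.factors), "factor": list(scaler.factors.values())}
    ).to_csv(out / "scaler.csv", index=False)
    matrix.to_csv(out / "consensus_matrix.csv")

    # stage 4: annotation
    digest_db = build_digest_database(proteins, max_missed=config.max_missed)
    assignments = annotate_features(consensuses, digest_db, tolerances)
    counts["annotated_peptides"] = len(assignments)
    kept_proteins = enforce_min_peptides(assignments, k=config.min_peptides)
    counts["proteins_quantified"] = len(kept_proteins)
    pd.DataFrame(
        {
            "consensus_id": [a.consensus_id for a in assignments],
            "sequence": [a.peptide.sequence for a in assignments],
            "protein": [a.peptide.protein for a in assignments],
            "mass_error_ppm": [a.mass_error_ppm for a in assignments],
            "charge_consistent": [a.charge_consistent for a in assignments],
        }
    ).to_csv(out / "assignments.csv", index=False)

    # stage 5: differential statistics
    protein_table = protein_abundance_matrix(
        assignments, matrix, labels, proteins=kept_proteins
    )
    results = summarize_results(protein_table, labels, alpha=config.alpha)
    report = results_frame(results)
    counts["proteins_significant_adj"] = int(report["significant_adj"].sum())
    protein_table.to_csv(out / "protein_matrix.csv")
    report.to_csv(out / "report.csv", index=False)
    logger.info(
        "funnel: %d peaks -> %d features -> %d consensus -> %d annotated -> "
        "%d proteins -> %d significant",
        counts["raw_peaks"],
        counts["features"],
        counts["consensus_peptides"],
        counts["annotated_peptides"],
        counts["proteins_quantified"],
        counts["proteins_significant_adj"],
    )

    provenance = {
        "config_hash": config.digest(),
        "seed": config.seed,
        "version": __version__,
        "counts": counts,
        "flagged_samples": flagged,
    }
    (out / "provenance.json").write_text(json.dumps(provenance, indent=2))
    return PipelineResult(
        config=config,
        report=report,
        consensus=matrix,
        protein_table=protein_table,
        provenance=provenance,
        flagged_samples=flagged,
    )
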