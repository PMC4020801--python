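"""File formats and pipeline configuration.

Interchange dialect: UTF-8 plain text, '.' decimal separator. Peak tables
are tab-separated with header ``mz  intensity  migration_time_min``; the
protein database is FASTA; matrices and reports are CSV; configuration is
YAML.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
from dataclasses import dataclass
from pathlib import Path
import pandas as pd
import yaml
from Bio import SeqIO

__all__ = [
    "SchemaError",
    "PipelineConfig",
    "read_peak_table",
    "write_peak_table",
    "read_fasta",
    "read_manifest",
]

PEAK_COLUMNS = ("mz", "intensity", "migration_time_min")


class SchemaError(ValueError):
    """A file does not match its expected schema."""


def read_peak_table(path: str | Path) -> pd.DataFrame:
    """Read a per-sample peak table (TSV: mz, intensity, migration_time_min).

    Malformed values are reported with 1-based data line numbers.
    """
    path = Path(path)
    df = pd.read_csv(path, sep="\t")
    missing = [c for c in PEAK_COLUMNS if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing column(s) {missing}")
    for col in PEAK_COLUMNS:
        numeric = pd.to_numeric(df[col], errors="coerce")
        bad = df.index[numeric.isna() & df[col].notna()]
        if len(bad):
            raise SchemaError(
                f"{path}: non-numeric {col!r} at line(s) {[int(i) + 2 for i in bad[:5]]}"
            )
        df[col] = numeric
    if df[list(PEAK_COLUMNS)].isna().any().any():
        bad = df.index[df[list(PEAK_COLUMNS)].isna().any(axis=1)]
        raise SchemaError(
            f"{path}: missing value(s) at line(s) {[int(i) + 2 for i in bad[:5]]}"
        )
    neg = df.index[df["intensity"] < 0]
    if len(neg):
        raise SchemaError(
            f"{path}: negative intensity at line(s) {[int(i) + 2 for i in neg[:5]]}"
        )
    return df[list(PEAK_COLUMNS)]


def write_peak_table(df: pd.DataFrame, path: str | Path) -> None:
    df[list(PEAK_COLUMNS)].to_csv(path, sep="\t", index=False, float_format="%.6f")


def read_fasta(path: str | Path) -> list[tuple[str, str]]:
    """Protein records (accession, sequence) from a FASTA file."""
    return [(rec.id, str(rec.seq)) for rec in SeqIO.parse(str(path), "fasta")]


def read_manifest(path: str | Path) -> dict[str, str]:
    """Cohort manifest CSV (sample_id, group) -> mapping."""
    df = pd.read_csv(path)
    for col in ("sample_id", "group"):
        if col not in df.columns:
            raise SchemaError(f"{path}: missing column {col!r}")
    bad = set(df["group"]) - {"case", "control"}
    if bad:
        raise SchemaError(f"{path}: unknown group label(s) {sorted(bad)}")
    return dict(zip(df["sample_id"].astype(str), df["group"].astype(str)))


@dataclass
class PipelineConfig:
    """All thresholds, paths and the seed of one pipeline run.

    Defaults follow the study constants: SNR > 4, reference frequency >=
    0.35, 22 internal standards, minimum two peptides per protein, alpha =
    0.05, one missed cleavage.
    """

    # paths (None -> simulate the inputs)
    peaks_dir: str | None = None
    fasta: str | None = None
    manifest: str | None = None
    out_dir: str = "results/pipeline"
    # simulation (used when peaks_dir is None)
    simulate: bool = True
    n_proteins: int = 30
    n_case: int = 20
    n_control: int = 15
    fraction_differential: float = 0.2
    noise_cv: float = 0.2
    detection_prob: float = 0.8
    # thresholds
    snr: float = 4.0
    ref_freq: float = 0.35
    n_standards: int = 22
    standard_min_freq: float = 0.8
    min_peptides: int = 2
    alpha: float = 0.05
    max_missed: int = 1
    # tolerance anchors ((mass Da, ppm), ...), ((time min, percent), ...)
    mass_anchors: tuple = ((800.0, 50.0), (15000.0, 75.0))
    time_anchors: tuple = ((19.0, 2.0), (50.0, 5.0))
    seed: int = 0

    def __post_init__(self) -> None:
        if self.snr <= 0 or not 0 < self.ref_freq <= 1 or self.min_peptides < 1:
            raise ValueError("threshold outside documented bounds")
        if not 0 < self.alpha < 1 or not 0 <= self.max_missed <= 3:
            raise ValueError("threshold outside documented bounds")

    def to_yaml(self, path: str | Path) -> None:
        d = dataclasses.asdict(self)
        d["mass_anchors"] = [list(a) for a in self.mass_anchors]
        d["time_anchors"] = [list(a) for a in self.time_anchors]
        Path(path).write_text(yaml.safe_dump(d, sort_keys=False))

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        d = yaml.safe_load(Path(path).read_text())
        for key in ("mass_anchors", "time_anchors"):
            if key in d:
                d[key] = tuple(tuple(a) for a in d[key])
        return cls(**d)

    def digest(self) -> str:
        """Stable hash of the configuration, for provenance logs."""
        d = dataclasses.asdict(self)
        return hashlib.sha256(
            json.dumps(d, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]
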