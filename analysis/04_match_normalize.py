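"""Cluster aligned features into consensus peptides and normalise intensities.

Greedy tolerance-based clustering across samples, removal of peptides seen
only once, data-driven selection of up to 22 internal standards (frequent,
disease-unassociated), and median-ratio scaling per sample. Writes the
normalised consensus x sample intensity matrix.
"""

from pathlib import Path

import pandas as pd

from vitreomics.calibration import normalize_intensities, select_internal_standards
from vitreomics.io import read_manifest
from vitreomics.matching import consensus_matrix, filter_singletons, match_features

IN = Path("results/analysis/aligned")
tables = {p.stem: pd.read_csv(p, sep="\t") for p in sorted(IN.glob("*.tsv"))}
labels = read_manifest("results/analysis/input/manifest.csv")

raw = match_features(tables)
consensuses = filter_singletons(raw)
matrix = consensus_matrix(consensuses, sorted(tables))
standards = select_internal_standards(matrix, labels, k=22)
matrix, scaler = normalize_intensities(matrix, standards, labels)
matrix.to_csv("results/analysis/consensus_matrix.csv")
pd.Series(scaler.factors, name="factor").rename_axis("sample_id").to_csv(
    "results/analysis/scaler.csv"
)

print(f"{len(raw)} clusters -> {len(consensuses)} consensus peptides after "
      f"singleton removal; {len(standards)} internal standards selected; "
      f"scale factors span [{min(scaler.factors.values()):.2f}, "
      f"{max(scaler.factors.values()):.2f}]")
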