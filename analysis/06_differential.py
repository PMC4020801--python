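"""Protein roll-up, differential testing and comparison against the truth.

Protein abundance is the mean of its detected peptide intensities; each
protein gets an F-test-gated t / Mann-Whitney p-value, a BH-adjusted p and
a case/control fold change. The report is then compared with the
generator's truth table.
"""

import pandas as pd

from vitreomics.annotation import Assignment, TheoreticalPeptide, enforce_min_peptides
from vitreomics.diffstats import protein_abundance_matrix, results_frame, summarize_results
from vitreomics.io import read_manifest

matrix = pd.read_csv("results/analysis/consensus_matrix.csv", index_col=0)
labels = read_manifest("results/analysis/input/manifest.csv")
adf = pd.read_csv("results/analysis/assignments.csv")
assignments = [
    Assignment(
        consensus_id=str(r.consensus_id),
        peptide=TheoreticalPeptide(sequence=r.sequence, protein=r.protein, missed_cleavages=0),
        mass_error_ppm=float(r.mass_error_ppm),
        charge_consistent=bool(r.charge_consistent),
    )
    for r in adf.itertuples(index=False)
]
kept = enforce_min_peptides(assignments, k=2)
table = protein_abundance_matrix(assignments, matrix, labels, proteins=kept)
report = results_frame(summarize_results(table, labels))
report.to_csv("results/analysis/report.csv", index=False)

truth = pd.read_csv("results/analysis/input/truth_proteins.csv")[["protein", "true_fold_change"]]
merged = report.merge(truth, on="protein")
sig = merged[merged["significant_adj"]]
diff = merged[merged["true_fold_change"] > 1]
found = diff[diff["significant_adj"]]
print(f"{len(report)} proteins tested; {len(sig)} significant after BH")
print(f"truth: {len(diff)} differential proteins, {len(found)} recovered "
      f"({len(sig) - len(found)} significant calls on null proteins)")
print("\ntop of the report (vs truth):")
print(
    merged.head(8)[
        ["protein", "fold_change", "raw_p", "adj_p", "test_used", "true_fold_change"]
    ].to_string(index=False)
)
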