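"""Assign consensus peptides to tryptic sequences of the protein database.

In-silico digest (trypsin, <= 1 missed cleavage, fixed carbamidomethyl-C,
variable Met oxidation / Pro hydroxylation) matched by monoisotopic mass
within the identity tolerance, with predicted CE charge breaking isobaric
ties. Writes the assignment table.
"""

import pandas as pd

from vitreomics.annotation import annotate_features, build_digest_database, enforce_min_peptides
from vitreomics.io import read_fasta
from vitreomics.matching import ConsensusPeptide

matrix = pd.read_csv("results/analysis/consensus_matrix.csv", index_col=0)
consensuses = [
    ConsensusPeptide(id=str(i), mass=row["mass"], time=row["time"])
    for i, row in matrix.iterrows()
]
db = build_digest_database(read_fasta("results/analysis/input/database.fasta"), max_missed=1)
assignments = annotate_features(consensuses, db)
pd.DataFrame(
    {
        "consensus_id": [a.consensus_id for a in assignments],
        "sequence": [a.peptide.sequence for a in assignments],
        "protein": [a.peptide.protein for a in assignments],
        "mass_error_ppm": [a.mass_error_ppm for a in assignments],
        "charge_consistent": [a.charge_consistent for a in assignments],
    }
).to_csv("results/analysis/assignments.csv", index=False)

kept = enforce_min_peptides(assignments, k=2)
print(f"digest database: {len(db)} theoretical peptide species; "
      f"{len(assignments)}/{len(consensuses)} consensus peptides annotated; "
      f"{len(kept)} proteins pass the minimum-two-peptides rule")
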