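"""Published reference values from the AMD vitreous case-control study.

These numbers come from the printed result tables of the clinical CE-MS
study of vitreous humor in age-related macular degeneration (73 AMD cases,
15 controls) whose analysis workflow this package implements. The raw
samples are not publicly available, so the printed per-protein statistics
serve two roles here: as inputs to worked examples (multiple-testing
arithmetic, fold-change arithmetic) and as realistic effect-size defaults
for the synthetic cohort generator.
"""

from __future__ import annotations

#: Number of identified proteins entering the differential analysis.
N_PROTEINS_TESTED = 97

#: Cohort group sizes (cases, controls) of the clinical study.
STUDY_GROUP_SIZES = (73, 15)

#: Unadjusted per-protein p-values of the differentially abundant proteins,
#: as printed (protein, raw p). Order follows the published table.
DIFFERENTIAL_RAW_P: list[tuple[str, float]] = [
    ("Ig kappa/lambda chain C region", 4.58e-06),
    ("Serum albumin", 3.27e-05),
    ("Ig gamma-1 chain C region", 6.54e-05),
    ("Antithrombin-III", 7.16e-05),
    ("Ig lambda-2 chain C regions", 1.30e-04),
    ("Serotransferrin", 3.99e-04),
    ("Afamin", 1.93e-03),
    ("Histidine-rich glycoprotein", 2.45e-03),
    ("Retinol-binding protein 3", 2.72e-03),
    ("Apolipoprotein A-I", 3.88e-03),
    ("Fibrinogen alpha chain", 3.94e-03),
    ("Ig alpha-1 chain C region", 2.32e-03),
    ("Alpha-2-HS-glycoprotein", 1.55e-02),
    ("Transthyretin", 1.61e-02),
    ("Prostaglandin-H2 D-isomerase", 2.33e-02),
    ("Haptoglobin", 3.34e-02),
    ("Glutathione peroxidase 3", 3.79e-02),
    ("Alpha-1-antitrypsin", 4.04e-02),
    ("Inter-alpha-trypsin inhibitor heavy chain H1", 4.82e-02),
]

#: Case/control fold changes of the same proteins, as printed. All are
#: upregulated in cases; the generator samples differential effect sizes
#: from this list.
DIFFERENTIAL_FOLD_CHANGES: list[float] = [
    6.56, 1.91, 3.14, 5.50, 4.55, 1.74, 3.28, 10.85, 2.78, 2.30,
    2.90, 35.34, 2.58, 1.74, 1.65, 2.92, 4.26, 1.73, 2.34,
]

#: Western-blot validation group means (protein -> (case mean, control mean),
#: chemiluminescence intensity units) used in the fold-change worked example.
WESTERN_BLOT_MEANS: dict[str, tuple[float, float]] = {
    "Alpha-1-Antitrypsin": (1618.6, 689.5),
    "Apolipoprotein A 1": (1925.3, 1463.2),
    "Retinol-binding protein 3": (471.9, 427.3),
    "Serotransferrin": (1224.1, 1059.6),
    "Transthyretin": (1169.8, 747.4),
}
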