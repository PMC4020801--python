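"""Physical constants and acquisition bounds used throughout the pipeline.

Masses are monoisotopic, in Daltons. The acquisition window and the
sequenced-peptide mass range mirror the CE-TOF setup the pipeline models:
ions recorded at m/z 350-3000, peptide neutral masses 804-3953 Da,
migration times spanning roughly 19-50 min.
"""

from __future__ import annotations

from pyteomics import mass as _pmass

#: Mass of a proton (charge carrier), Da.
PROTON_MASS = 1.00728

#: Average spacing between successive isotopologue peaks, Da (per unit charge).
ISOTOPE_SPACING = 1.00235

#: Monoisotopic mass of water (peptide-bond condensation), Da.
WATER_MASS = 18.01056

#: Fixed carbamidomethylation of cysteine, Da.
CARBAMIDOMETHYL_MASS = 57.02146

#: Oxidation of methionine / hydroxylation of proline, Da.
OXIDATION_MASS = 15.99491

#: The 20 standard residues with their monoisotopic residue masses.
RESIDUE_MASSES: dict[str, float] = {
    aa: _pmass.std_aa_mass[aa] for aa in "ACDEFGHIKLMNPQRSTVWY"
}

#: Acquisition m/z window (Thomson).
MZ_MIN = 350.0
MZ_MAX = 3000.0

#: Neutral-mass range of sequenced tryptic peptides, Da.
PEPTIDE_MASS_MIN = 804.0
PEPTIDE_MASS_MAX = 3953.0

#: CE migration-time window the tolerance model is anchored to, minutes.
CE_TIME_MIN = 19.0
CE_TIME_MAX = 50.0

#: Signal-to-noise ratio threshold: only peaks with SNR > 4 are used.
SNR_THRESHOLD = 4.0
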