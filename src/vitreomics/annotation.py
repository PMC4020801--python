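"""In-silico tryptic digestion and sequence assignment of consensus peptides.

The protein database is digested with trypsin rules (cleave C-terminal to
K/R unless followed by P), carbamidomethylation of Cys is applied as a fixed
modification, and oxidised Met / hydroxylated Pro are enumerated as variable
modifications (at most two variable sites per peptide). Consensus peptides
are assigned to theoretical peptides by monoisotopic mass within the
identity tolerance; ambiguous matches are resolved by the peptide's
predicted CE charge (at the acidic separation pH the charge is one proton
on the N-terminus plus one per basic side chain, K/R/H), then by mass error.

Proteins supported by fewer than two distinct assigned peptide sequences are
rejected.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from typing import Iterable, Mapping, Sequence

import numpy as np

from .constants import (
    CARBAMIDOMETHYL_MASS,
    OXIDATION_MASS,
    RESIDUE_MASSES,
    WATER_MASS,
)
from .matching import ConsensusPeptide, ToleranceModel, DEFAULT_TOLERANCES

__all__ = [
    "TheoreticalPeptide",
    "Assignment",
    "cleavage_fragments",
    "digest_protein",
    "peptide_mass",
    "predict_charge",
    "build_digest_database",
    "annotate_features",
    "enforce_min_peptides",
]


@dataclass(frozen=True)
class TheoreticalPeptide:
    """A tryptic peptide with its modifications and predicted CE charge."""

    sequence: str
    protein: str
    missed_cleavages: int
    n_oxidation: int = 0  # oxidised Met count
    n_hydroxyproline: int = 0  # hydroxylated Pro count
    monoisotopic_mass: float = 0.0
    predicted_charge: int = 1

    @property
    def modifications(self) -> set[str]:
        mods = set()
        if "C" in self.sequence:
            mods.add("carbamidomethyl-C")
        if self.n_oxidation:
            mods.add("oxidation-M")
        if self.n_hydroxyproline:
            mods.add("hydroxy-P")
        return mods

    @property
    def n_variable_mods(self) -> int:
        return self.n_oxidation + self.n_hydroxyproline


@dataclass(frozen=True)
class Assignment:
    """Link between a consensus peptide and one theoretical peptide."""

    consensus_id: str
    peptide: TheoreticalPeptide
    mass_error_ppm: float
    charge_consistent: bool


def _validate_sequence(sequence: str) -> None:
    for i, aa in enumerate(sequence):
        if aa not in RESIDUE_MASSES:
            raise ValueError(f"invalid residue {aa!r} at position {i} in sequence")


def cleavage_fragments(sequence: str) -> list[str]:
    """Fully cleaved tryptic fragments, in order along the protein.

    Cleaves C-terminal to K or R except when the next residue is P.
    Concatenating the fragments reconstructs the input exactly.
    """
    _validate_sequence(sequence)
    frags: list[str] = []
    start = 0
    for i, aa in enumerate(sequence):
        if aa in "KR" and (i + 1 == len(sequence) or sequence[i + 1] != "P"):
            frags.append(sequence[start : i + 1])
            start = i + 1
    if start < len(sequence):
        frags.append(sequence[start:])
    return frags


def peptide_mass(
    sequence: str, n_oxidation: int = 0, n_hydroxyproline: int = 0
) -> float:
    """Monoisotopic neutral mass in Da, with fixed and variable modifications.

    Every Cys carries the fixed carbamidomethyl group (+57.02146 Da);
    ``n_oxidation`` Met and ``n_hydroxyproline`` Pro each add +15.99491 Da.
    """
    _validate_sequence(sequence)
    m = WATER_MASS + sum(RESIDUE_MASSES[aa] for aa in sequence)
    m += CARBAMIDOMETHYL_MASS * sequence.count("C")
    m += OXIDATION_MASS * (n_oxidation + n_hydroxyproline)
    return m


def predict_charge(sequence: str) -> int:
    """Predicted CE charge: N-terminal proton plus one per K, R or H."""
    _validate_sequence(sequence)
    return 1 + sum(sequence.count(aa) for aa in "KRH")


def digest_protein(
    sequence: str,
    max_missed: int = 1,
    protein: str = "",
    max_variable_mods: int = 2,
) -> list[TheoreticalPeptide]:
    """Tryptic digest of one protein with bounded variable-mod enumeration.

    Emits every peptide with up to ``max_missed`` missed cleavage sites; for
    each, all combinations of oxidised-Met and hydroxylated-Pro counts with
    at most ``max_variable_mods`` modified sites in total.
    """
    if not 0 <= max_missed <= 3:
        raise ValueError(f"max_missed must be in [0, 3], got {max_missed}")
    frags = cleavage_fragments(sequence)
    peptides: list[TheoreticalPeptide] = []
    for i in range(len(frags)):
        for j in range(i, min(i + max_missed + 1, len(frags))):
            pep = "".join(frags[i : j + 1])
            n_m = pep.count("M")
            n_p = pep.count("P")
            for ox, hyp in itertools.product(range(n_m + 1), range(n_p + 1)):
                if ox + hyp > max_variable_mods:
                    continue
                peptides.append(
                    TheoreticalPeptide(
                        sequence=pep,
                        protein=protein,
                        missed_cleavages=j - i,
                        n_oxidation=ox,
                        n_hydroxyproline=hyp,
                        monoisotopic_mass=peptide_mass(pep, ox, hyp),
                        predicted_charge=predict_charge(pep),
                    )
                )
    return peptides


def build_digest_database(
    proteins: Mapping[str, str] | Iterable[tuple[str, str]],
    max_missed: int = 1,
    max_variable_mods: int = 2,
) -> list[TheoreticalPeptide]:
    """Digest a whole protein database (accession -> sequence)."""
    items = proteins.items() if isinstance(proteins, Mapping) else proteins
    db: list[TheoreticalPeptide] = []
    for accession, seq in items:
        db.extend(
            digest_protein(
                seq, max_missed=max_missed, protein=accession,
                max_variable_mods=max_variable_mods,
            )
        )
    return db


def annotate_features(
    consensuses: Sequence[ConsensusPeptide],
    digest_db: Sequence[TheoreticalPeptide],
    tolerances: ToleranceModel = DEFAULT_TOLERANCES,
) -> list[Assignment]:
    """Assign consensus peptides to theoretical peptides by mass and charge.

    Candidates are theoretical peptides whose mass lies within the identity
    tolerance of the consensus mass. If several remain, those whose predicted
    charge appears in the consensus's observed charge set are preferred; the
    final tie-break is smallest absolute mass error, then fewer variable
    modifications, then lexicographic sequence. Consensuses with no candidate
    are left unannotated (absent from the returned list).
    """
    if not digest_db:
        raise ValueError("digest database is empty")
    # sort theoretical peptides by mass once; deterministic tie order
    db = sorted(
        digest_db,
        key=lambda p: (p.monoisotopic_mass, p.sequence, p.n_variable_mods, p.protein),
    )
    db_masses = np.array([p.monoisotopic_mass for p in db])

    assignments: list[Assignment] = []
    for cp in consensuses:
        tol_da = tolerances.mass_tolerance_da(cp.mass)
        lo = int(np.searchsorted(db_masses, cp.mass - tol_da, side="left"))
        hi = int(np.searchsorted(db_masses, cp.mass + tol_da, side="right"))
        candidates = db[lo:hi]
        if not candidates:
            continue
        charge_consistent = True
        if len(candidates) > 1 and cp.charges:
            consistent = [p for p in candidates if p.predicted_charge in cp.charges]
            if consistent:
                candidates = consistent
            else:
                charge_consistent = False
        best = min(
            candidates,
            key=lambda p: (
                abs(p.monoisotopic_mass - cp.mass),
                p.n_variable_mods,
                p.sequence,
                p.protein,
                p.n_oxidation,
            ),
        )
        err_ppm = (cp.mass - best.monoisotopic_mass) / best.monoisotopic_mass * 1e6
        if cp.charges:
            charge_consistent = best.predicted_charge in cp.charges
        assignments.append(
            Assignment(
                consensus_id=cp.id,
                peptide=best,
                mass_error_ppm=err_ppm,
                charge_consistent=charge_consistent,
            )
        )
    return assignments


def enforce_min_peptides(
    assignments: Iterable[Assignment], k: int = 2
) -> dict[str, set[str]]:
    """Keep only proteins represented by at least ``k`` distinct peptides.

    Returns a mapping protein accession -> set of assigned peptide sequences.
    """
    if k < 1:
        raise ValueError(f"k must be >= 1, got {k}")
    by_protein: dict[str, set[str]] = {}
    for a in assignments:
        by_protein.setdefault(a.peptide.protein, set()).add(a.peptide.sequence)
    return {prot: seqs for prot, seqs in by_protein.items() if len(seqs) >= k}
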