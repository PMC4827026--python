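"""Monoisotopic peptide masses and accurate-mass PTM assignment.

Distinguishing lysine acetylation (+42.01057 Da) from trimethylation
(+42.04695 Da) needs accurate mass: the two differ by only 0.03638 Da on the
same peptide. ``monoisotopic_mh`` computes the singly protonated monoisotopic
mass (MH+) of a modified peptide; ``assign_modification`` picks the candidate
species closest to a measured m/z, provided the call is unambiguous at the
stated tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass, field

__all__ = [
    "RESIDUE_MASS",
    "MOD_DELTA",
    "PROTON",
    "WATER",
    "PeptideSpecies",
    "MassAssignment",
    "monoisotopic_mh",
    "assign_modification",
]

# IUPAC monoisotopic residue masses (Da, 6 decimals; 5-decimal tables can
# drop the last printed digit of a 7-residue MH+)
RESIDUE_MASS = {
    "G": 57.021464, "A": 71.037114, "S": 87.032028, "P": 97.052764,
    "V": 99.068414, "T": 101.047679, "C": 103.009185, "L": 113.084064,
    "I": 113.084064, "N": 114.042927, "D": 115.026943, "Q": 128.058578,
    "K": 128.094963, "E": 129.042593, "M": 131.040485, "H": 137.058912,
    "F": 147.068414, "R": 156.101111, "Y": 163.063329, "W": 186.079313,
}

MOD_DELTA = {
    "acetyl": 42.010565,
    "methyl": 14.015650,
    "dimethyl": 28.031300,
    "trimethyl": 42.046950,
}

PROTON = 1.007276  # Da
WATER = 18.010565  # Da


@dataclass(frozen=True)
class PeptideSpecies:
    """A peptide with site modifications and its theoretical masses.

    ``modifications`` is a list of (position, mod) with 1-based positions and
    mod one of acetyl/methyl/dimethyl/trimethyl.
    """

    sequence: str
    modifications: tuple[tuple[int, str], ...] = ()
    label: str = ""

    def __post_init__(self) -> None:
        object.__setattr__(self, "modifications", tuple(self.modifications))
        seen = set()
        for pos, mod in self.modifications:
            if not 1 <= pos <= len(self.sequence):
                raise ValueError(f"modification position {pos} outside sequence")
            if mod not in MOD_DELTA:
                raise ValueError(f"unknown modification {mod!r}")
            if pos in seen:
                raise ValueError(f"more than one modification at position {pos}")
            seen.add(pos)

    @property
    def neutral_mass(self) -> float:
        try:
            residues = sum(RESIDUE_MASS[aa] for aa in self.sequence)
        except KeyError as exc:
            raise ValueError(f"unknown residue {exc.args[0]!r}") from None
        mods = sum(MOD_DELTA[mod] for _, mod in self.modifications)
        return residues + WATER + mods

    @property
    def mh_plus(self) -> float:
        return round(self.neutral_mass + PROTON, 4)


def monoisotopic_mh(sequence: str, modifications=()) -> float:
    """MH+ = sum of residue masses + water + modification deltas + one proton,
    reported to 4 decimals."""
    return PeptideSpecies(sequence, tuple(modifications)).mh_plus


@dataclass
class MassAssignment:
    measured_mz: float
    tolerance: float
    status: str  # assigned | ambiguous | no_match
    best: PeptideSpecies | None = None
    delta: float | None = None  # measured - theoretical
    runner_up: PeptideSpecies | None = None


def assign_modification(measured_mz: float, candidates, tolerance: float,
                        margin: float = 0.005) -> MassAssignment:
    """Pick the candidate species nearest the measured mass, if unambiguous.

    The call is 'assigned' only when the best candidate lies within
    ``tolerance`` of the measurement and no other candidate could also
    explain it: a second candidate within tolerance, or within ``margin`` of
    the best candidate's error, makes the call 'ambiguous'. No candidate
    within tolerance gives 'no_match'.
    """
    candidates = list(candidates)
    if not candidates:
        raise ValueError("candidate list is empty")
    if tolerance <= 0:
        raise ValueError("tolerance must be positive")
    ranked = sorted(candidates, key=lambda c: abs(measured_mz - c.mh_plus))
    best = ranked[0]
    best_err = abs(measured_mz - best.mh_plus)
    if best_err > tolerance:
        return MassAssignment(measured_mz, tolerance, "no_match")
    if len(ranked) > 1:
        second = ranked[1]
        second_err = abs(measured_mz - second.mh_plus)
        if second_err <= tolerance or (second_err - best_err) < margin:
            return MassAssignment(measured_mz, tolerance, "ambiguous",
                                  best=best, delta=measured_mz - best.mh_plus,
                                  runner_up=second)
    return MassAssignment(measured_mz, tolerance, "assigned", best=best,
                          delta=measured_mz - best.mh_plus)
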