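"""Peptide mass computation and peak-identity consistency checks.

For singly charged linear-mode MALDI ions the observed m/z is, to within
the instrument's mass accuracy, the peptide's average mass (neutral) or
average mass + one proton ([M+H]+). These helpers compute average and
monoisotopic masses for unmodified peptides from the standard amino-acid
composition (via pyteomics) and test whether an observed peak m/z is
consistent with a candidate sequence under a relative tolerance.
"""

from __future__ import annotations

from dataclasses import dataclass

from pyteomics import mass as _pmass

VALID_RESIDUES = set("ACDEFGHIKLMNPQRSTVWY")

#: Average and monoisotopic mass of a proton-as-hydrogen addition for the
#: [M+H]+ ion (average uses the standard atomic weight of hydrogen).
PROTON_AVERAGE = 1.00794
PROTON_MONO = 1.007276


@dataclass(frozen=True)
class PeptideSequence:
    """A peptide over the 20 standard one-letter residue codes.

    Whitespace in the input is stripped (printed sequences are sometimes
    wrapped or spaced); lowercase is upcased. Anything else is rejected.
    """

    residues: str

    def __post_init__(self) -> None:
        cleaned = "".join(str(self.residues).split()).upper()
        if not cleaned:
            raise ValueError("empty peptide sequence")
        bad = set(cleaned) - VALID_RESIDUES
        if bad:
            raise ValueError(f"invalid residue code(s): {sorted(bad)}")
        object.__setattr__(self, "residues", cleaned)

    def __len__(self) -> int:
        return len(self.residues)

    def __str__(self) -> str:
        return self.residues


def _as_sequence(seq) -> PeptideSequence:
    return seq if isinstance(seq, PeptideSequence) else PeptideSequence(seq)


def average_mass(seq) -> float:
    """Average (isotope-abundance-weighted) mass of the neutral, unmodified
    peptide in Da: sum of average residue masses plus one water."""
    s = _as_sequence(seq)
    return float(_pmass.calculate_mass(sequence=s.residues, average=True))


def monoisotopic_mass(seq) -> float:
    """Monoisotopic mass of the neutral, unmodified peptide in Da."""
    s = _as_sequence(seq)
    return float(_pmass.calculate_mass(sequence=s.residues))


def match_peak(
    seq,
    observed_mz: float,
    mode: str = "neutral",
    tol_rel: float = 0.001,
) -> tuple[bool, float]:
    """Is an observed peak m/z consistent with a candidate peptide?

    ``mode`` is "neutral" (compare to the average mass) or "MH_plus"
    (average mass + one proton). Returns ``(match, ppm_error)`` where
    match means |observed - expected| / observed <= tol_rel and ppm_error
    is signed (observed - expected) / expected x 1e6.
    """
    if observed_mz <= 0:
        raise ValueError("observed_mz must be positive")
    if mode not in ("neutral", "MH_plus"):
        raise ValueError(f"unknown mode {mode!r}; expected 'neutral' or 'MH_plus'")
    expected = average_mass(seq)
    if mode == "MH_plus":
        expected += PROTON_AVERAGE
    ppm = (observed_mz - expected) / expected * 1e6
    return abs(observed_mz - expected) / observed_mz <= tol_rel, float(ppm)
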