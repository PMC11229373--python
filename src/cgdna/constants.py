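"""Physical constants and unit conventions.

Internal units throughout the package: length in Å, time in ps, energy in
kcal/mol, mass in Da (g/mol), temperature in K, charge in units of the
elementary charge e.  In this system one kcal/mol equals 418.4 Da·Å²/ps²,
so forces in kcal/mol/Å are converted to accelerations in Å/ps² by
multiplying with ``KCAL_TO_DA_A2_PS2 / mass``.
"""

from __future__ import annotations

#: Boltzmann constant, kcal/mol/K.
KB: float = 1.987204e-3

#: 1 kcal/mol expressed in Da·Å²/ps² (4184 J/mol → g·Å²/(ps²·mol)).
KCAL_TO_DA_A2_PS2: float = 418.4

#: Coulomb constant, kcal·Å/(mol·e²).
COULOMB_CONSTANT: float = 332.0637

#: Default nucleotide masses, Da (one bead per nucleotide).
DEFAULT_MASSES: dict[str, float] = {
    "A": 331.2,
    "C": 307.2,
    "G": 347.2,
    "T": 322.2,
}

#: Watson–Crick complement.
COMPLEMENT: dict[str, str] = {"A": "T", "T": "A", "G": "C", "C": "G"}

DNA_ALPHABET = frozenset("ACGT")


def reverse_complement(seq: str) -> str:
    """Reverse complement of a DNA string (uppercase ACGT)."""
    return "".join(COMPLEMENT[b] for b in reversed(seq))
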