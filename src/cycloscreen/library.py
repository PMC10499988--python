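"""Library architecture model for SXCX_nC macrocycle phage-display libraries.

The libraries display peptides of the form S-X-C-X…X-C (one variable residue
after the fixed N-terminal serine, then ``n`` variable residues bracketed by
two fixed cysteines).  The two cysteines are chemically cross-linked after
display, so the displayed genotype→phenotype contract is entirely determined
by the DNA insert between two constant priming regions.  This module owns
that contract: theoretical diversity, translation of the variable-region
insert, and classification of observed peptides against the designed
architectures.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping

import yaml
from Bio.Seq import Seq

__all__ = [
    "AMINO_ACIDS",
    "CODON_FOR_AA",
    "LibraryDesign",
    "PeptideRecord",
    "MalformedSequenceError",
    "UnsupportedArchitectureError",
    "theoretical_diversity",
    "translate_variable_region",
    "classify_architecture",
    "reverse_translate",
]

#: The 20 canonical amino acids (one-letter codes), alphabetical.
AMINO_ACIDS = "ACDEFGHIKLMNPQRSTVWY"

#: One trinucleotide per amino acid, emulating trinucleotide-codon synthesis.
#: Ser and Cys use the codons of the cloning template (TCT / TGT) so that
#: simulated inserts reproduce the published read structure.
CODON_FOR_AA: Mapping[str, str] = {
    "A": "GCT", "C": "TGT", "D": "GAT", "E": "GAA", "F": "TTT",
    "G": "GGT", "H": "CAT", "I": "ATT", "K": "AAA", "L": "CTG",
    "M": "ATG", "N": "AAT", "P": "CCG", "Q": "CAG", "R": "CGT",
    "S": "TCT", "T": "ACT", "V": "GTT", "W": "TGG", "Y": "TAT",
}

# Constant (priming) regions flanking the variable insert, from the cloning
# template; the fixed Ser/Cys codons belong to the insert, not these regions.
DEFAULT_CONSTANT_5P = "CCCGGGTACCTTTCTATTCTCACTCT"
DEFAULT_CONSTANT_3P = "GGTGGAGGTTCGGCCGGGCGCTTGATT"

_ARCHITECTURE_SIZES = (3, 4, 5)


class MalformedSequenceError(ValueError):
    """A DNA or peptide string violates the expected alphabet or frame."""


class UnsupportedArchitectureError(ValueError):
    """A cycle size outside the library design was requested."""


@dataclass(frozen=True)
class LibraryDesign:
    """Architecture of an SXCX_nC display library.

    Parameters
    ----------
    cycle_sizes
        The macrocycle ring sizes ``n`` present in the library; each yields
        the pattern ``S X C X*n C`` with ``n + 1`` variable positions.
    variable_alphabet
        Amino acids available at X positions (trinucleotide codon set);
        cysteine is excluded by default so the two fixed cysteines remain
        the unique cross-linking sites.
    """

    name: str = "SXCXnC"
    cycle_sizes: tuple[int, ...] = _ARCHITECTURE_SIZES
    variable_alphabet: str = "ADEFGHIKLMNPQRSTVWY"  # 19 aa, no Cys
    constant_5p: str = DEFAULT_CONSTANT_5P
    constant_3p: str = DEFAULT_CONSTANT_3P
    barcode_length: int = 8
    codon_policy: str = "trinucleotide"

    def __post_init__(self) -> None:
        for region, label in ((self.constant_5p, "constant_5p"),
                              (self.constant_3p, "constant_3p")):
            if not region or set(region) - set("ACGT"):
                raise MalformedSequenceError(
                    f"{label} must be a nonempty uppercase ACGT string")
        if not self.cycle_sizes:
            raise ValueError("cycle_sizes must be nonempty")
        if any(n < 1 for n in self.cycle_sizes):
            raise ValueError("cycle sizes must be positive")
        bad = set(self.variable_alphabet) - set(AMINO_ACIDS)
        if bad:
            raise MalformedSequenceError(f"non-canonical letters in alphabet: {bad}")

    def fixed_pattern(self, n: int) -> str:
        """Template string for cycle size ``n``, e.g. ``SXCXXXC`` for n=3."""
        if n not in self.cycle_sizes:
            raise UnsupportedArchitectureError(
                f"cycle size {n} not in design {sorted(self.cycle_sizes)}")
        return "SXC" + "X" * n + "C"

    def n_variable_positions(self, n: int) -> int:
        self.fixed_pattern(n)  # validates n
        return n + 1

    def peptide_length(self, n: int) -> int:
        return len(self.fixed_pattern(n))

    def insert_length(self, n: int) -> int:
        """Nucleotides of the variable-region insert (incl. fixed S/C codons)."""
        return 3 * self.peptide_length(n)

    @classmethod
    def from_dict(cls, data: Mapping) -> "LibraryDesign":
        kwargs = {}
        if "name" in data:
            kwargs["name"] = str(data["name"])
        if "cycle_sizes" in data:
            kwargs["cycle_sizes"] = tuple(int(n) for n in data["cycle_sizes"])
        if "alphabet" in data:
            kwargs["variable_alphabet"] = "".join(data["alphabet"])
        for key in ("constant_5p", "constant_3p", "barcode_length", "codon_policy"):
            if key in data:
                kwargs[key] = data[key]
        return cls(**kwargs)

    @classmethod
    def from_file(cls, path: str | Path) -> "LibraryDesign":
        """Load a design from a YAML (or JSON — a YAML subset) config file."""
        with open(path) as fh:
            data = yaml.safe_load(fh)
        return cls.from_dict(data)


@dataclass(frozen=True)
class PeptideRecord:
    """One displayed clone: DNA insert, translated peptide, architecture."""

    peptide: str
    dna: str
    architecture_class: str = "off_design"
    contains_stop: bool = False


def theoretical_diversity(design: LibraryDesign, n: int, alphabet_size: int) -> int:
    """Number of distinct peptides for cycle size ``n``.

    The library fixes S and the two C positions; diversity is
    ``alphabet_size ** (n + 1)`` over the variable positions.  The published
    count of 160,000 variants for the n=3 library corresponds to a 20-letter
    alphabet (20**4); with the cysteine-free 19-letter synthesis alphabet the
    count is 19**4 = 130,321 — both conventions are exposed via
    ``alphabet_size``.
    """
    if alphabet_size < 1:
        raise ValueError("alphabet_size must be >= 1")
    return alphabet_size ** design.n_variable_positions(n)


def translate_variable_region(dna: str) -> PeptideRecord:
    """Translate a variable-region insert with the standard genetic code.

    A stop codon truncates the peptide and sets ``contains_stop`` rather than
    raising, so the processing pipeline can discard such reads while keeping
    audit counts.
    """
    if set(dna) - set("ACGT"):
        raise MalformedSequenceError(f"non-ACGT character in insert: {dna!r}")
    if len(dna) % 3:
        raise MalformedSequenceError(f"insert length {len(dna)} not divisible by 3")
    aa = str(Seq(dna).translate())
    stop = aa.find("*")
    if stop >= 0:
        return PeptideRecord(peptide=aa[:stop], dna=dna, contains_stop=True)
    return PeptideRecord(peptide=aa, dna=dna,
                         architecture_class=classify_architecture(aa))


def classify_architecture(peptide: str,
                          design: LibraryDesign | None = None) -> str:
    """Classify a peptide as ``n3``/``n4``/``n5`` or ``off_design``.

    A peptide belongs to class ``n_k`` iff it has length k+4, starts with S,
    has C at positions 3 and k+4 (1-based, i.e. the last position) and
    carries no non-canonical letter.  Deletion products of the larger
    libraries fall into the smaller classes, which is why classification
    spans all sizes the design declares.
    """
    if not peptide:
        raise MalformedSequenceError("empty peptide")
    sizes = design.cycle_sizes if design is not None else _ARCHITECTURE_SIZES
    if set(peptide) - set(AMINO_ACIDS):
        return "off_design"
    for k in sorted(sizes):
        if (len(peptide) == k + 4
                and peptide[0] == "S"
                and peptide[2] == "C"
                and peptide[-1] == "C"):
            return f"n{k}"
    return "off_design"


def reverse_translate(peptide: str) -> str:
    """Encode a peptide with the simulation's trinucleotide codon set."""
    try:
        return "".join(CODON_FOR_AA[aa] for aa in peptide)
    except KeyError as exc:
        raise MalformedSequenceError(f"cannot encode residue {exc}") from exc


def enumerate_variable_peptides(design: LibraryDesign, n: int) -> Iterable[str]:
    """All in-design peptides for cycle size ``n`` (use only for tiny alphabets)."""
    import itertools

    pattern = design.fixed_pattern(n)
    slots = [i for i, c in enumerate(pattern) if c == "X"]
    for combo in itertools.product(design.variable_alphabet, repeat=len(slots)):
        seq = list(pattern)
        for pos, aa in zip(slots, combo):
            seq[pos] = aa
        yield "".join(seq)
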