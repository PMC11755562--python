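"""Residue constants, protein-chain representation, FASTA I/O and chain stitching.

Coordinates are 1-based inclusive on the translated chain, position 1 being
the initiator methionine (EcoRI numbering M1-K277 even though the initiator
is removed post-translationally). All higher-level modules share this
convention.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord
from Bio.SeqUtils.ProtParamData import DIWV as _BIOPYTHON_DIWV
from Bio.SeqUtils.ProtParamData import kd as _KYTE_DOOLITTLE

logger = logging.getLogger(__name__)

STANDARD_RESIDUES = frozenset("ACDEFGHIKLMNPQRSTVWY")


class FastaFormatError(ValueError):
    """Raised for empty files or records with non-standard residue letters."""


class StitchConflictError(ValueError):
    """Two overlapping peptides disagree at a position."""


class StitchGapError(ValueError):
    """The peptides (plus any prefix) do not cover a contiguous range."""


def _patched_diwv() -> dict:
    # The web descriptor tool the printed tables came from uses 24.68 for the
    # K->Q dipeptide where the commonly redistributed table has 24.64;
    # calibrated against the printed instability-index column.
    table = {a: dict(row) for a, row in _BIOPYTHON_DIWV.items()}
    table["K"]["Q"] = 24.68
    return table


@dataclass(frozen=True)
class ResidueConstants:
    """Per-residue constant tables used by the physicochemical descriptors.

    average_mass: Expasy average residue masses (Da); ``water_mass`` is added
        once per peptide for the free termini.
    hydropathy: Kyte-Doolittle scale.
    diwv: 20x20 dipeptide instability weights (Guruprasad DIWV, with the
        K->Q entry following the web tool).
    pKa model: Bjellqvist values as used by ProtParam -- side chains and
        termini in ``positive_pks``/``negative_pks``, plus the
        residue-dependent N-terminal pKas in ``nterm_pka``. The C-terminal
        pKa is fixed (the printed tables rule out C-terminal-residue
        dependence).
    aliphatic_coeffs: (a, b) = (2.9, 3.9) relative volumes of Val and Ile/Leu.
    aromatic_set: {F, H, W, Y}.
    hydrophilic_set: residues counted by the hydrophilic percentage.
    charge_increments: fractional per-residue charges at pH 7 for the
        table-calibrated net-charge model (His +0.09, Cys -0.05).
    """

    average_mass: dict = field(default_factory=lambda: {
        "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
        "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
        "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
        "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
        "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
    })
    water_mass: float = 18.0153
    hydropathy: dict = field(default_factory=lambda: dict(_KYTE_DOOLITTLE))
    diwv: dict = field(default_factory=_patched_diwv)
    positive_pks: dict = field(default_factory=lambda: {
        "Nterm": 7.5, "K": 10.0, "R": 12.0, "H": 5.98})
    negative_pks: dict = field(default_factory=lambda: {
        "Cterm": 3.55, "D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0})
    nterm_pka: dict = field(default_factory=lambda: {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36, "T": 6.82,
        "V": 7.44, "E": 7.7})
    aliphatic_coeffs: tuple = (2.9, 3.9)
    aromatic_set: frozenset = frozenset("FHWY")
    hydrophilic_set: frozenset = frozenset("DEKRNQS")
    charge_increments: dict = field(default_factory=lambda: {
        "K": 1.0, "R": 1.0, "D": -1.0, "E": -1.0, "H": 0.09, "C": -0.05})

    def __post_init__(self) -> None:
        for name in ("average_mass", "hydropathy", "diwv"):
            table = getattr(self, name)
            missing = STANDARD_RESIDUES - set(table)
            if missing:
                raise ValueError(f"{name} lacks residues {sorted(missing)}")


CONSTANTS = ResidueConstants()


def validate_sequence(sequence: str, *, name: str = "sequence") -> str:
    """Uppercase and validate a one-letter residue string."""
    seq = sequence.upper()
    if not seq:
        raise ValueError(f"{name}: empty sequence")
    for pos, letter in enumerate(seq, start=1):
        if letter not in STANDARD_RESIDUES:
            raise FastaFormatError(
                f"{name}: illegal residue {letter!r} at position {pos}")
    return seq


@dataclass(frozen=True)
class Interval:
    """1-based inclusive residue interval on a protein chain."""

    start: int
    end: int

    def __post_init__(self) -> None:
        if not 1 <= self.start <= self.end:
            raise ValueError(f"invalid interval {self.start}-{self.end}")

    def __len__(self) -> int:
        return self.end - self.start + 1

    def __str__(self) -> str:
        return f"{self.start}-{self.end}"


@dataclass(frozen=True)
class ProteinChain:
    """A named protein chain with 1-based numbering including the initiator."""

    name: str
    sequence: str

    def __post_init__(self) -> None:
        object.__setattr__(
            self, "sequence", validate_sequence(self.sequence, name=self.name))

    def __len__(self) -> int:
        return len(self.sequence)

    def subsequence(self, interval: Interval) -> str:
        if interval.end > len(self):
            raise ValueError(
                f"{interval} exceeds chain {self.name} length {len(self)}")
        return self.sequence[interval.start - 1:interval.end]

    def locate(self, sequence: str) -> Interval:
        """Interval of the unique occurrence of ``sequence`` in the chain."""
        first = self.sequence.find(sequence)
        if first < 0:
            raise ValueError(f"{sequence!r} not found in chain {self.name}")
        if self.sequence.find(sequence, first + 1) >= 0:
            raise ValueError(f"{sequence!r} occurs more than once in {self.name}")
        return Interval(first + 1, first + len(sequence))


def read_fasta(path: str | Path) -> list[ProteinChain]:
    """Read protein chains from a FASTA file (non-standard letters rejected)."""
    records = list(SeqIO.parse(str(path), "fasta"))
    if not records:
        raise FastaFormatError(f"{path}: no FASTA records found")
    return [ProteinChain(rec.id, str(rec.seq)) for rec in records]


def write_fasta(chains: Iterable[ProteinChain], path: str | Path) -> None:
    records = [SeqRecord(Seq(c.sequence), id=c.name, description="")
               for c in chains]
    SeqIO.write(records, str(path), "fasta")


def stitch_chain(
    peptides: Sequence[tuple[Interval, str]],
    known_prefix: str | None = None,
    name: str = "stitched",
) -> ProteinChain:
    """Reconstruct a chain from positioned, mutually overlapping peptides.

    Every peptide must read exactly as the chain substring at its interval;
    overlapping peptides must agree letter by letter. ``known_prefix``
    supplies residues from position 1 that no peptide covers (e.g. the
    initiator M of EcoRI, which the peptide set starts after). A peptide
    whose printed interval width disagrees with its sequence length keeps
    its start and extends to the sequence's true length, with a warning --
    the overlap-consistency check against its neighbours then proves or
    refutes the placement.
    """
    if not peptides:
        raise ValueError("no peptides to stitch")
    positions: dict[int, str] = {}
    if known_prefix:
        prefix = validate_sequence(known_prefix, name="known_prefix")
        positions.update(enumerate(prefix, start=1))
    # deterministic position-order placement makes the result permutation-invariant
    for interval, sequence in sorted(peptides, key=lambda p: (p[0].start, p[1])):
        seq = validate_sequence(sequence, name=f"peptide at {interval}")
        if len(interval) != len(seq):
            logger.warning(
                "interval %s is %d wide but sequence %r has length %d; "
                "keeping start %d and trusting the sequence",
                interval, len(interval), seq, len(seq), interval.start)
        for offset, letter in enumerate(seq):
            pos = interval.start + offset
            seen = positions.get(pos)
            if seen is None:
                positions[pos] = letter
            elif seen != letter:
                raise StitchConflictError(
                    f"position {pos}: {seen!r} vs {letter!r} "
                    f"(peptide at {interval})")
    first, last = min(positions), max(positions)
    missing = [p for p in range(first, last + 1) if p not in positions]
    if missing:
        raise StitchGapError(f"uncovered positions: {missing}")
    if first > 1:
        logger.warning(
            "stitched chain starts at position %d; supply known_prefix to "
            "anchor the numbering at position 1", first)
    return ProteinChain(
        name, "".join(positions[p] for p in range(first, last + 1)))
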