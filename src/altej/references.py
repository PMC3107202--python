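"""Cut-locus models and derivative-chromosome references.

A reciprocal translocation between two nuclease-cut loci produces two
derivative chromosomes.  For a nuclease leaving a 5' overhang, the overhang
is assumed to be filled in by polymerase before (or during) joining, so the
"perfect" junction — no sequence loss from either end — duplicates the
overhang bases on both derivatives.  The blunt, filled-in end is the
zero-deletion reference state for all downstream deletion measurements.

Coordinates are 0-based, half-open, on the top strand throughout.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

__all__ = [
    "ReferenceLocus",
    "DerivativeReference",
    "FastaError",
    "load_fasta",
    "fill_in_end",
    "build_derivative",
    "locus_from_config",
    "revcomp",
    "DNA_ALPHABET",
]

DNA_ALPHABET = frozenset("ACGTN")

_COMPLEMENT = str.maketrans("ACGTN", "TGCAN")


def revcomp(seq: str) -> str:
    """Reverse complement of an A/C/G/T/N string."""
    return seq.translate(_COMPLEMENT)[::-1]


class FastaError(ValueError):
    """Raised for malformed or empty FASTA input."""


def _check_alphabet(seq: str, context: str) -> None:
    bad = set(seq) - DNA_ALPHABET
    if bad:
        raise FastaError(
            f"{context}: disallowed character(s) {sorted(bad)!r}; "
            f"alphabet is A/C/G/T/N"
        )


@dataclass(frozen=True)
class ReferenceLocus:
    """One chromosome-side sequence with its nuclease nick positions.

    ``nick_top`` and ``nick_bottom`` are both top-strand coordinates:
    ``nick_top`` is where the top strand is nicked, ``nick_bottom`` the
    top-strand coordinate of the bottom-strand nick.  A 5' overhang of
    length ``nick_bottom - nick_top`` lies between them.

    ``variable_terminal_bases`` marks ends with variable cleavage: up to
    that many copies of the reference terminal base at the filled-in end
    may or may not be present in a junction and are not scored as
    insertions during annotation.
    """

    name: str
    sequence: str
    nick_top: int
    nick_bottom: int
    variable_terminal_bases: int = 0

    def __post_init__(self) -> None:
        object.__setattr__(self, "sequence", self.sequence.upper())
        _check_alphabet(self.sequence, f"locus {self.name!r}")
        if not self.sequence:
            raise ValueError(f"locus {self.name!r}: empty sequence")
        if not (0 <= self.nick_top <= self.nick_bottom <= len(self.sequence)):
            raise ValueError(
                f"locus {self.name!r}: require 0 <= nick_top <= nick_bottom "
                f"<= len(sequence), got nick_top={self.nick_top}, "
                f"nick_bottom={self.nick_bottom}, len={len(self.sequence)}"
            )
        if self.variable_terminal_bases < 0:
            raise ValueError("variable_terminal_bases must be >= 0")

    @property
    def overhang_len(self) -> int:
        return self.nick_bottom - self.nick_top

    @property
    def overhang_seq(self) -> str:
        return self.sequence[self.nick_top : self.nick_bottom]


def fill_in_end(locus: ReferenceLocus, side: str) -> str:
    """Sequence retained on one side of the cut after 5'-overhang fill-in.

    ``side="left"`` keeps the 5' fragment (everything up to the bottom-strand
    nick), ``side="right"`` the 3' fragment (everything from the top-strand
    nick).  For a non-blunt cut the two fragments jointly duplicate the
    overhang bases, reflecting polymerase fill-in of both 5' overhangs.
    """
    if side == "left":
        return locus.sequence[: locus.nick_bottom]
    if side == "right":
        return locus.sequence[locus.nick_top :]
    raise ValueError(f"side must be 'left' or 'right', got {side!r}")


@dataclass(frozen=True)
class DerivativeReference:
    """Expected perfect-join reference for one derivative chromosome.

    ``left`` contributes its 5' (filled-in) fragment, ``right`` its 3'
    fragment.  ``left_end`` / ``right_start`` are the blunt-end coordinates
    after fill-in (``left.nick_bottom`` / ``right.nick_top``), i.e. the
    zero-deletion state of each end.
    """

    name: str
    left: ReferenceLocus
    right: ReferenceLocus
    left_end: int = field(init=False)
    right_start: int = field(init=False)

    def __post_init__(self) -> None:
        object.__setattr__(self, "left_end", self.left.nick_bottom)
        object.__setattr__(self, "right_start", self.right.nick_top)

    @property
    def left_fragment(self) -> str:
        """Filled-in 5' fragment of the left locus (ends at ``left_end``)."""
        return self.left.sequence[: self.left_end]

    @property
    def right_fragment(self) -> str:
        """Filled-in 3' fragment of the right locus (starts at ``right_start``)."""
        return self.right.sequence[self.right_start :]

    @property
    def perfect_join(self) -> str:
        return self.left_fragment + self.right_fragment


def build_derivative(
    left: ReferenceLocus, right: ReferenceLocus, name: str = "der"
) -> DerivativeReference:
    """Construct the perfect-join derivative reference ``left + right``.

    The perfect join assumes fill-in of the 5' overhangs and no loss of
    sequence from either DNA end, so
    ``len(perfect_join) == left.nick_bottom + len(right.sequence) - right.nick_top``.
    """
    return DerivativeReference(name=name, left=left, right=right)


def load_fasta(path: str | Path) -> dict[str, str]:
    """Read a FASTA file into an ordered ``{id: uppercase sequence}`` mapping.

    Lowercase input is accepted and normalized.  Malformed input (text before
    the first header, duplicate ids, characters outside A/C/G/T/N, empty
    records) raises :class:`FastaError` naming the offending line where it
    can be located.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise FastaError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if not line.strip():
            continue
        if not line.startswith(">"):
            raise FastaError(
                f"{path}: line {lineno}: expected FASTA header '>' before "
                f"sequence data"
            )
        break

    records: dict[str, str] = {}
    with path.open() as handle:
        for rec in SeqIO.parse(handle, "fasta"):
            if not rec.id:
                raise FastaError(f"{path}: record with empty id")
            seq = str(rec.seq).upper()
            if not seq:
                raise FastaError(f"{path}: record {rec.id!r} has empty sequence")
            bad = set(seq) - DNA_ALPHABET
            if bad:
                lineno = _find_offending_line(text, bad)
                raise FastaError(
                    f"{path}: line {lineno}: record {rec.id!r} contains "
                    f"disallowed character(s) {sorted(bad)!r}"
                )
            if rec.id in records:
                raise FastaError(f"{path}: duplicate record id {rec.id!r}")
            records[rec.id] = seq
    if not records:
        raise FastaError(f"{path}: no FASTA records found")
    return records


def _find_offending_line(text: str, bad: set[str]) -> int:
    bad_upper = {b.upper() for b in bad} | {b.lower() for b in bad}
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.startswith(">"):
            continue
        if set(line) & bad_upper:
            return lineno
    return 0


def locus_from_config(config: dict, sequences: dict[str, str]) -> ReferenceLocus:
    """Build a :class:`ReferenceLocus` from a JSON config block.

    Expected keys: ``name``, ``fasta_id``, ``nick_top``, ``nick_bottom``,
    optional ``variable_terminal_bases``.  ``sequences`` is the mapping
    returned by :func:`load_fasta`.
    """
    fasta_id = config["fasta_id"]
    if fasta_id not in sequences:
        raise KeyError(f"fasta_id {fasta_id!r} not found in supplied sequences")
    return ReferenceLocus(
        name=config["name"],
        sequence=sequences[fasta_id],
        nick_top=int(config["nick_top"]),
        nick_bottom=int(config["nick_bottom"]),
        variable_terminal_bases=int(config.get("variable_terminal_bases", 0)),
    )


def loci_from_json(path: str | Path) -> dict[str, ReferenceLocus]:
    """Load a ``{"loci": [...]}`` JSON file, resolving FASTA paths within it."""
    path = Path(path)
    spec = json.loads(path.read_text())
    loci = {}
    for block in spec["loci"]:
        seqs = load_fasta(path.parent / block["fasta"])
        locus = locus_from_config(block, seqs)
        loci[locus.name] = locus
    return loci
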