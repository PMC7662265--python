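"""Peptide definitions with absolute residue numbering.

Every downstream table, profile and coordinate set in this package is keyed
by the *absolute* sequence number of each residue (the numbering of the
parent protein, e.g. 391-409 for the CB1 TMH7-H8 elbow peptide), never by a
0-based position.  Terminal modifications (N-acetyl, C-amide) are carried on
the peptide because they change both the mass and the ionizable-group
inventory.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

AMINO_ACIDS = set("ACDEFGHIKLMNPQRSTVWY")

N_TERM_MODS = ("free", "acetyl")
C_TERM_MODS = ("free", "amide")


class PeptideError(ValueError):
    """Invalid peptide definition or residue lookup."""


@dataclass(frozen=True)
class ResidueID:
    """One residue addressed by its absolute sequence number.

    ``bw_label`` optionally carries a Ballesteros-Weinstein style GPCR
    position tag (e.g. ``"7.47"``); it is user-supplied configuration.
    """

    number: int
    code: str
    bw_label: str | None = None

    def __str__(self) -> str:  # e.g. "D403"
        return f"{self.code}{self.number}"


@dataclass(frozen=True)
class Peptide:
    """A capped peptide with absolute residue numbering.

    ``start_number`` is the absolute number of the first residue, so residue
    ``i`` (0-based) carries number ``start_number + i``.
    """

    name: str
    sequence: str
    start_number: int
    n_term_mod: str = "free"
    c_term_mod: str = "free"
    bw_labels: Mapping[int, str] = field(default_factory=dict)

    def __post_init__(self) -> None:
        if not self.sequence:
            raise PeptideError("empty sequence")
        if len(self.sequence) < 2:
            raise PeptideError("peptide must have at least 2 residues")
        for i, aa in enumerate(self.sequence):
            if aa not in AMINO_ACIDS:
                raise PeptideError(
                    f"invalid amino-acid code {aa!r} at position {i + 1}"
                )
        if self.n_term_mod not in N_TERM_MODS:
            raise PeptideError(f"unknown n_term_mod {self.n_term_mod!r}")
        if self.c_term_mod not in C_TERM_MODS:
            raise PeptideError(f"unknown c_term_mod {self.c_term_mod!r}")
        for num in self.bw_labels:
            if num not in self.residue_numbers:
                raise PeptideError(
                    f"bw label mapped to residue {num}, outside "
                    f"{self.start_number}-{self.end_number}"
                )

    @property
    def end_number(self) -> int:
        return self.start_number + len(self.sequence) - 1

    @property
    def residue_numbers(self) -> range:
        return range(self.start_number, self.end_number + 1)

    def __len__(self) -> int:
        return len(self.sequence)

    def __contains__(self, number: int) -> bool:
        return number in self.residue_numbers

    def residue(self, number: int) -> ResidueID:
        """Look up a residue by absolute number."""
        if number not in self:
            raise PeptideError(
                f"residue {number} outside peptide range "
                f"{self.start_number}-{self.end_number}"
            )
        code = self.sequence[number - self.start_number]
        return ResidueID(number, code, self.bw_labels.get(number))

    def residues(self) -> list[ResidueID]:
        return [self.residue(n) for n in self.residue_numbers]


def parse_peptide(
    name: str,
    sequence: str,
    start_number: int,
    n_term_mod: str = "free",
    c_term_mod: str = "free",
) -> Peptide:
    """Construct a validated :class:`Peptide`.

    Raises :class:`PeptideError` naming the offending position for any
    non-canonical one-letter code.
    """
    return Peptide(name, sequence.upper(), int(start_number), n_term_mod, c_term_mod)


def attach_bw_labels(
    peptide: Peptide, mapping: Iterable[tuple[int, str]]
) -> Peptide:
    """Return a copy of ``peptide`` carrying Ballesteros-Weinstein labels.

    Unlabelled residues keep an empty label; a number outside the peptide's
    range raises :class:`PeptideError`.
    """
    labels = dict(peptide.bw_labels)
    for number, label in mapping:
        if number not in peptide:
            raise PeptideError(
                f"bw label mapped to residue {number}, outside "
                f"{peptide.start_number}-{peptide.end_number}"
            )
        labels[int(number)] = str(label)
    return replace(peptide, bw_labels=labels)


def to_dict(peptide: Peptide) -> dict:
    d = {
        "name": peptide.name,
        "sequence": peptide.sequence,
        "start_number": peptide.start_number,
        "n_term_mod": peptide.n_term_mod,
        "c_term_mod": peptide.c_term_mod,
    }
    if peptide.bw_labels:
        d["bw_labels"] = {str(k): v for k, v in peptide.bw_labels.items()}
    return d


def from_dict(d: Mapping) -> Peptide:
    pep = parse_peptide(
        d["name"],
        d["sequence"],
        d["start_number"],
        d.get("n_term_mod", "free"),
        d.get("c_term_mod", "free"),
    )
    bw = d.get("bw_labels") or {}
    return attach_bw_labels(pep, [(int(k), v) for k, v in bw.items()])


def write_peptide(peptide: Peptide, path: str | Path) -> None:
    """Serialize a peptide definition to a small JSON file."""
    Path(path).write_text(json.dumps(to_dict(peptide), indent=1) + "\n")


def read_peptide(path: str | Path) -> Peptide:
    """Read a peptide definition written by :func:`write_peptide`."""
    return from_dict(json.loads(Path(path).read_text()))
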