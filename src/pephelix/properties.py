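"""Design-stage physicochemical properties of capped peptides.

Masses are computed from element formulas: the sum of residue compositions
plus one water, plus an acetyl increment (C2H2O) for an acetylated N-terminus
and an OH→NH2 swap for an amidated C-terminus.  Average masses use the IUPAC
standard atomic weights, monoisotopic masses the principal-isotope masses.

Net charge follows the standard single-site Henderson-Hasselbalch sum over
the ionizable inventory (side chains plus any *free* termini — capped
termini contribute nothing), and the isoelectric point is the root of the
charge curve on (0, 14).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Mapping

from scipy.optimize import brentq

from .sequences import Peptide

# IUPAC standard atomic weights / principal-isotope (monoisotopic) masses
ATOMIC_WEIGHT = {"H": 1.008, "C": 12.011, "N": 14.007, "O": 15.999, "S": 32.06}
MONOISOTOPIC = {
    "H": 1.00782503,
    "C": 12.0,
    "N": 14.00307401,
    "O": 15.99491462,
    "S": 31.97207069,
}

# residue (= amino acid minus water) element compositions
RESIDUE_FORMULA = {
    "G": {"C": 2, "H": 3, "N": 1, "O": 1},
    "A": {"C": 3, "H": 5, "N": 1, "O": 1},
    "S": {"C": 3, "H": 5, "N": 1, "O": 2},
    "P": {"C": 5, "H": 7, "N": 1, "O": 1},
    "V": {"C": 5, "H": 9, "N": 1, "O": 1},
    "T": {"C": 4, "H": 7, "N": 1, "O": 2},
    "C": {"C": 3, "H": 5, "N": 1, "O": 1, "S": 1},
    "L": {"C": 6, "H": 11, "N": 1, "O": 1},
    "I": {"C": 6, "H": 11, "N": 1, "O": 1},
    "N": {"C": 4, "H": 6, "N": 2, "O": 2},
    "D": {"C": 4, "H": 5, "N": 1, "O": 3},
    "Q": {"C": 5, "H": 8, "N": 2, "O": 2},
    "K": {"C": 6, "H": 12, "N": 2, "O": 1},
    "E": {"C": 5, "H": 7, "N": 1, "O": 3},
    "M": {"C": 5, "H": 9, "N": 1, "O": 1, "S": 1},
    "H": {"C": 6, "H": 7, "N": 3, "O": 1},
    "F": {"C": 9, "H": 9, "N": 1, "O": 1},
    "R": {"C": 6, "H": 12, "N": 4, "O": 1},
    "Y": {"C": 9, "H": 9, "N": 1, "O": 2},
    "W": {"C": 11, "H": 10, "N": 2, "O": 1},
}

WATER = {"H": 2, "O": 1}
ACETYL = {"C": 2, "H": 2, "O": 1}  # H -> COCH3 on the alpha-amine
AMIDE = {"N": 1, "H": 1, "O": -1}  # OH -> NH2 on the alpha-carboxyl


class PropertyError(ValueError):
    pass


@dataclass(frozen=True)
class MassResult:
    average_da: float
    monoisotopic_da: float
    formula: Mapping[str, int]

    def __post_init__(self) -> None:
        if self.average_da <= 0 or self.monoisotopic_da <= 0:
            raise PropertyError("masses must be positive")


def _add(formula: dict[str, int], other: Mapping[str, int], sign: int = 1) -> None:
    for el, n in other.items():
        formula[el] = formula.get(el, 0) + sign * n


def peptide_formula(peptide: Peptide) -> dict[str, int]:
    """Element-count formula of the (possibly capped) peptide."""
    formula: dict[str, int] = {}
    for aa in peptide.sequence:
        _add(formula, RESIDUE_FORMULA[aa])
    _add(formula, WATER)
    if peptide.n_term_mod == "acetyl":
        _add(formula, ACETYL)
    if peptide.c_term_mod == "amide":
        _add(formula, AMIDE)
    return {el: n for el, n in formula.items() if n != 0}


def peptide_mass(peptide: Peptide) -> MassResult:
    """Average and monoisotopic mass of the capped peptide."""
    formula = peptide_formula(peptide)
    avg = sum(ATOMIC_WEIGHT[el] * n for el, n in formula.items())
    mono = sum(MONOISOTOPIC[el] * n for el, n in formula.items())
    return MassResult(average_da=avg, monoisotopic_da=mono, formula=formula)


# ---------------------------------------------------------------- titration

#: Lehninger-style pKa scale; "basic" groups are positive when protonated.
PKA_SCALES: dict[str, dict[str, tuple[float, str]]] = {
    "lehninger": {
        "n_term": (9.69, "basic"),
        "c_term": (2.34, "acidic"),
        "D": (3.65, "acidic"),
        "E": (4.25, "acidic"),
        "C": (8.18, "acidic"),
        "Y": (10.07, "acidic"),
        "H": (6.00, "basic"),
        "K": (10.53, "basic"),
        "R": (12.48, "basic"),
    },
    "emboss": {
        "n_term": (8.6, "basic"),
        "c_term": (3.6, "acidic"),
        "D": (3.9, "acidic"),
        "E": (4.1, "acidic"),
        "C": (8.5, "acidic"),
        "Y": (10.1, "acidic"),
        "H": (6.5, "basic"),
        "K": (10.8, "basic"),
        "R": (12.5, "basic"),
    },
}


@dataclass(frozen=True)
class TitrationModel:
    """Ionizable-group inventory of one peptide under a named pKa scale.

    ``groups`` is a list of (label, pKa, kind) with kind in {acidic, basic};
    capped termini are excluded from the inventory.
    """

    groups: tuple[tuple[str, float, str], ...]
    scale: str

    @classmethod
    def for_peptide(cls, peptide: Peptide, scale: str = "lehninger") -> "TitrationModel":
        try:
            pka = PKA_SCALES[scale]
        except KeyError:
            raise PropertyError(
                f"unknown pKa scale {scale!r}; available: {sorted(PKA_SCALES)}"
            ) from None
        groups: list[tuple[str, float, str]] = []
        if peptide.n_term_mod == "free":
            groups.append(("n_term", *pka["n_term"]))
        if peptide.c_term_mod == "free":
            groups.append(("c_term", *pka["c_term"]))
        for res in peptide.residues():
            if res.code in pka:
                groups.append((str(res), *pka[res.code]))
        return cls(tuple(groups), scale)


def net_charge(peptide: Peptide, pH: float, model: TitrationModel | None = None) -> float:
    """Fractional net charge (e) at the given pH.

    Each group contributes +1/(1+10^(pH−pKa)) if basic or −1/(1+10^(pKa−pH))
    if acidic; the result is non-increasing in pH.
    """
    if not 0.0 < pH < 14.0:
        raise PropertyError("pH must lie in (0, 14)")
    if model is None:
        model = TitrationModel.for_peptide(peptide)
    charge = 0.0
    for _, pka, kind in model.groups:
        if kind == "basic":
            charge += 1.0 / (1.0 + 10.0 ** (pH - pka))
        else:
            charge -= 1.0 / (1.0 + 10.0 ** (pka - pH))
    return charge


def isoelectric_point(
    peptide: Peptide, model: TitrationModel | None = None, tol: float = 1e-4
) -> float:
    """pH at which the net charge crosses zero.

    Undefined (raises) for peptides whose charge never changes sign on
    (0, 14), e.g. a capped peptide with only acidic or only basic groups.
    """
    if model is None:
        model = TitrationModel.for_peptide(peptide)
    kinds = {kind for _, _, kind in model.groups}
    lo, hi = 1e-3, 14.0 - 1e-3
    q_lo, q_hi = net_charge(peptide, lo, model), net_charge(peptide, hi, model)
    if kinds != {"acidic", "basic"} or q_lo <= 0.0 or q_hi >= 0.0:
        raise PropertyError(
            f"pI undefined for {peptide.name}: charge does not cross zero"
        )
    return float(
        brentq(lambda ph: net_charge(peptide, ph, model), lo, hi, xtol=tol)
    )
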