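"""Random-coil chemical-shift reference values.

Secondary shifts are deviations from the shift a residue type shows in a
disordered ("random coil") context, so every Δδ profile is defined relative
to a named reference set.  The default shipped here is the Wishart-style
¹H/¹³C random-coil table (25 °C, pH ~5, water) widely used for Hα/Cα
secondary-shift analysis of peptides.  Alternative sets can be registered
by name; the set identifier travels with every profile that used it.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping

NUCLEI = ("HA", "HN", "CA")

# aa -> (HA, CA, HN) ppm; Pro has no amide proton.
_WISHART_1995 = {
    "A": (4.32, 52.5, 8.24),
    "C": (4.55, 58.2, 8.32),
    "D": (4.64, 54.2, 8.34),
    "E": (4.35, 56.6, 8.42),
    "F": (4.62, 57.7, 8.30),
    "G": (3.96, 45.1, 8.33),
    "H": (4.73, 55.0, 8.42),
    "I": (4.17, 61.1, 8.00),
    "K": (4.32, 56.2, 8.29),
    "L": (4.34, 55.1, 8.16),
    "M": (4.48, 55.4, 8.28),
    "N": (4.74, 53.1, 8.40),
    "P": (4.42, 63.3, None),
    "Q": (4.34, 55.7, 8.32),
    "R": (4.34, 56.0, 8.23),
    "S": (4.47, 58.3, 8.31),
    "T": (4.35, 61.8, 8.15),
    "V": (4.12, 62.2, 8.03),
    "W": (4.66, 57.5, 8.25),
    "Y": (4.55, 57.9, 8.12),
}


class RandomCoilError(KeyError):
    pass


@dataclass(frozen=True)
class RandomCoilTable:
    """Per-residue-type random-coil shifts for HA/CA (and HN where defined)."""

    name: str
    values: Mapping[tuple[str, str], float]
    neighbor_corrections: Mapping[tuple[str, str], float] | None = field(default=None)

    def __post_init__(self) -> None:
        for aa in _WISHART_1995:
            for nuc in ("HA", "CA"):
                if (aa, nuc) not in self.values:
                    raise RandomCoilError(
                        f"reference set {self.name!r} incomplete: missing ({aa}, {nuc})"
                    )

    def shift(self, aa: str, nucleus: str) -> float:
        try:
            return self.values[(aa, nucleus)]
        except KeyError:
            raise RandomCoilError(
                f"no random-coil value for ({aa}, {nucleus}) in set {self.name!r}"
            ) from None

    def has(self, aa: str, nucleus: str) -> bool:
        return (aa, nucleus) in self.values


def wishart1995() -> RandomCoilTable:
    """The default Wishart-style random-coil reference set."""
    values: dict[tuple[str, str], float] = {}
    for aa, (ha, ca, hn) in _WISHART_1995.items():
        values[(aa, "HA")] = ha
        values[(aa, "CA")] = ca
        if hn is not None:
            values[(aa, "HN")] = hn
    return RandomCoilTable(name="wishart1995", values=values)


_REGISTRY = {"wishart1995": wishart1995}


def get_reference_set(name: str) -> RandomCoilTable:
    """Look up a registered random-coil reference set by name."""
    try:
        return _REGISTRY[name]()
    except KeyError:
        raise RandomCoilError(
            f"unknown random-coil set {name!r}; available: {sorted(_REGISTRY)}"
        ) from None
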