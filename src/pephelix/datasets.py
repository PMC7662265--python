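"""The two designed peptides and their published summary measurements.

This package was built around the CD/NMR characterization of two capped
model peptides of the putative CB1-receptor/β-arrestin1 interface:

* ``CB1_391_409`` — Ac-TVNPIIYALRSKDLRHAFR-NH2, the TMH7-H8 elbow of the
  CB1 cannabinoid receptor (absolute numbering 391-409);
* ``BARR1_63_76`` — Ac-YGREDLDVLGLTFR-NH2, the β-arrestin1 finger loop
  (absolute numbering 63-76);

each studied free in water, in 30% TFE and in 30 mM DPC micelles.  The
summary-level experimental measurements (mean-residue ellipticity at
222 nm; segment-averaged secondary shifts over the NMR-defined helical
spans) are inputs to the analysis drivers and to the reproduction script;
they are the numbers the estimators in this package are applied to.
"""

from __future__ import annotations

from dataclasses import dataclass

from .chemshift import HelixSegment
from .sequences import Peptide, parse_peptide

CB1_391_409: Peptide = parse_peptide(
    "CB1_391_409", "TVNPIIYALRSKDLRHAFR", 391, n_term_mod="acetyl", c_term_mod="amide"
)

BARR1_63_76: Peptide = parse_peptide(
    "BARR1_63_76", "YGREDLDVLGLTFR", 63, n_term_mod="acetyl", c_term_mod="amide"
)

#: mean-residue ellipticity at 222 nm, deg cm^2 dmol^-1, by (peptide, condition)
ELLIPTICITY_222 = {
    ("CB1_391_409", "H2O"): -2178.68,
    ("CB1_391_409", "TFE"): -7931.79,
    ("CB1_391_409", "DPC"): -9415.07,
    ("BARR1_63_76", "H2O"): -1750.71,
    ("BARR1_63_76", "TFE"): -10229.3,
    ("BARR1_63_76", "DPC"): -3626.36,
}

#: NMR-defined helical segments: TMH7 (P394-K402) and H8 (L404-F408) for the
#: CB1 elbow peptide; the finger-loop helix for β-arr1 (one residue longer
#: in DPC than in water/TFE).
CB1_TMH7 = HelixSegment(394, 402)
CB1_H8 = HelixSegment(404, 408)
BARR1_HELIX = HelixSegment(66, 74)
BARR1_HELIX_DPC = HelixSegment(65, 74)


@dataclass(frozen=True)
class SegmentAverages:
    """Measured segment-averaged secondary shifts for one table row."""

    peptide: str
    condition: str
    segment: HelixSegment
    avg_dha: float  # ppm
    avg_dca: float  # ppm
    temperature_C: float = 25.0


#: segment-averaged Δδ_Hα / Δδ_Cα (ppm) per peptide, condition and helix
SEGMENT_AVERAGES: tuple[SegmentAverages, ...] = (
    SegmentAverages("CB1_391_409", "H2O", CB1_TMH7, -0.09, 0.48, 5.0),
    SegmentAverages("CB1_391_409", "H2O", CB1_H8, -0.07, 0.33, 5.0),
    SegmentAverages("CB1_391_409", "TFE", CB1_TMH7, -0.24, 2.50),
    SegmentAverages("CB1_391_409", "TFE", CB1_H8, -0.14, 1.52),
    SegmentAverages("CB1_391_409", "DPC", CB1_TMH7, -0.25, 2.01),
    SegmentAverages("CB1_391_409", "DPC", CB1_H8, -0.23, 1.69),
    SegmentAverages("BARR1_63_76", "H2O", BARR1_HELIX, -0.06, 0.56, 5.0),
    SegmentAverages("BARR1_63_76", "TFE", BARR1_HELIX, -0.12, 1.79),
    SegmentAverages("BARR1_63_76", "DPC", BARR1_HELIX_DPC, -0.13, 1.22),
)

PEPTIDES = {p.name: p for p in (CB1_391_409, BARR1_63_76)}

#: inter-helix (TMH7/H8) elbow angles observed for the CB1 peptide, degrees
ELBOW_ANGLES = {"TFE": 94.0, "DPC": 75.0, "5XRA_crystal": 97.0}
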