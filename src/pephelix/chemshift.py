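"""Secondary-shift helicity analysis.

The conformational information in backbone chemical shifts enters through
the secondary shift Δδ(i) = δ_obs(i) − δ_RC(aa_i): in an alpha-helix Hα
moves upfield (negative Δδ_Hα) and Cα downfield (positive Δδ_Cα).  Under a
two-state helix-coil model the population of helix in a segment follows by
linear interpolation between the coil (Δδ = 0) and full-helix limiting
values,

    % helix = 100 * <Δδ> / Δδ_100%,

with Δδ_100%(Hα) = −0.39 ppm and Δδ_100%(Cα) = +3.1 ppm.  Helical segments
are read off the Δδ_Hα profile as runs of consecutive residues below the
random-coil band (|Δδ_Hα| ≤ 0.05 ppm); a single interior residue back inside
the band breaks a helix in two (a hinge residue).
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .cd import round_half_away
from .random_coil import RandomCoilTable
from .sequences import Peptide

#: Full-helix secondary-shift limits, ppm (two-state model calibration).
FULL_HELIX_LIMIT = {"HA": -0.39, "CA": 3.1}
#: Per-measurement experimental error, ppm, by nucleus type.
MEASUREMENT_ERROR = {"HA": 0.01, "HN": 0.01, "CA": 0.1}
#: Half-width of the random-coil band on Δδ_Hα, ppm.
RC_BAND_HA = 0.05

H_RANGE = (-2.0, 12.0)
C_RANGE = (10.0, 80.0)


class ShiftTableError(ValueError):
    pass


@dataclass(frozen=True)
class ShiftTable:
    """Per-residue, per-nucleus chemical shifts for one peptide/condition."""

    peptide: Peptide
    condition: str
    shifts: Mapping[tuple[int, str], float]
    temperature_C: float = 25.0
    pH: float = 5.5
    label: str = ""
    meta: dict = field(default_factory=dict)

    def __post_init__(self) -> None:
        for (num, nuc), ppm in self.shifts.items():
            if num not in self.peptide:
                raise ShiftTableError(
                    f"residue {num} not in peptide "
                    f"{self.peptide.name} ({self.peptide.start_number}-"
                    f"{self.peptide.end_number})"
                )
            if nuc not in MEASUREMENT_ERROR:
                raise ShiftTableError(f"unsupported nucleus {nuc!r}")
            if not math.isfinite(ppm):
                raise ShiftTableError(f"non-finite shift at ({num}, {nuc})")
            lo, hi = C_RANGE if nuc == "CA" else H_RANGE
            if not lo <= ppm <= hi:
                raise ShiftTableError(
                    f"shift {ppm} ppm at ({num}, {nuc}) outside [{lo}, {hi}]"
                )
            if nuc == "HN" and self.peptide.residue(num).code == "P":
                raise ShiftTableError(f"Pro {num} cannot carry an HN shift")

    @property
    def id(self) -> str:
        return self.label or f"{self.peptide.name}/{self.condition}"

    def get(self, number: int, nucleus: str) -> float | None:
        return self.shifts.get((number, nucleus))


@dataclass(frozen=True)
class DeltaProfile:
    """Per-residue secondary shifts Δδ for one nucleus.

    Residues without an observed shift are absent from ``values`` (never
    zero-filled).  ``source`` records the shift-table and reference-set
    identifiers the profile was computed from.
    """

    nucleus: str
    values: Mapping[int, float]
    source: str = ""

    def __getitem__(self, number: int) -> float:
        return self.values[number]

    def __contains__(self, number: int) -> bool:
        return number in self.values

    def residues(self) -> list[int]:
        return sorted(self.values)


@dataclass(frozen=True, order=True)
class HelixSegment:
    first: int
    last: int

    def __post_init__(self) -> None:
        if self.first >= self.last:
            raise ShiftTableError(
                f"segment first ({self.first}) must precede last ({self.last})"
            )

    def __str__(self) -> str:
        return f"{self.first}-{self.last}"

    def __contains__(self, number: int) -> bool:
        return self.first <= number <= self.last


@dataclass(frozen=True)
class PopulationEstimate:
    """A helix percentage with its propagated (or combined) error."""

    percent: float
    error_percent: float
    nucleus: str  # HA, CA or combined
    segment: HelixSegment | None = None
    in_range: bool = True

    def __post_init__(self) -> None:
        if self.error_percent < 0:
            raise ShiftTableError("error_percent must be >= 0")

    @property
    def percent_rounded(self) -> int:
        return round_half_away(self.percent)


# ---------------------------------------------------------------- I/O


def _validate_rows(
    peptide: Peptide, rows: list[tuple[int, str, str, float]], origin: str
) -> dict[tuple[int, str], float]:
    shifts: dict[tuple[int, str], float] = {}
    skipped = 0
    for num, code, nuc, ppm in rows:
        if nuc not in MEASUREMENT_ERROR:
            skipped += 1
            continue
        if num not in peptide:
            raise ShiftTableError(
                f"{origin}: residue {num} outside peptide "
                f"{peptide.name} ({peptide.start_number}-{peptide.end_number})"
            )
        expected = peptide.residue(num).code
        if code and code != expected:
            raise ShiftTableError(
                f"{origin}: residue {num} is {expected} in the peptide, "
                f"file says {code}"
            )
        if (num, nuc) in shifts:
            raise ShiftTableError(f"{origin}: duplicate entry for ({num}, {nuc})")
        shifts[(num, nuc)] = float(ppm)
    if skipped:
        import logging

        logging.getLogger(__name__).info(
            "%s: ignored %d entries with unsupported nuclei", origin, skipped
        )
    return shifts


_ONE_TO_THREE = {
    "A": "ALA", "C": "CYS", "D": "ASP", "E": "GLU", "F": "PHE",
    "G": "GLY", "H": "HIS", "I": "ILE", "K": "LYS", "L": "LEU",
    "M": "MET", "N": "ASN", "P": "PRO", "Q": "GLN", "R": "ARG",
    "S": "SER", "T": "THR", "V": "VAL", "W": "TRP", "Y": "TYR",
}
_THREE_TO_ONE = {v: k for k, v in _ONE_TO_THREE.items()}
# NMR-STAR uses atom id "H" for the backbone amide proton
_STAR_ATOM = {"HA": "HA", "HN": "H", "CA": "CA"}
_STAR_ATOM_INV = {v: k for k, v in _STAR_ATOM.items()}


def read_shift_table(
    path: str | Path,
    peptide: Peptide,
    condition: str = "",
    format: str = "csv",
    **kwargs,
) -> ShiftTable:
    """Read a shift table from delimited text or a minimal NMR-STAR loop.

    csv columns: residue_number, residue_code, nucleus, shift_ppm.
    NMR-STAR: the ``_Atom_chem_shift`` loop subset (Seq_ID, Comp_ID,
    Atom_ID, Val); sequence codes in the loop are absolute residue numbers.
    """
    path = Path(path)
    if format == "csv":
        df = pd.read_csv(path, comment="#")
        rows = [
            (int(r.residue_number), str(r.residue_code), str(r.nucleus), float(r.shift_ppm))
            for r in df.itertuples()
        ]
    elif format == "nmrstar":
        rows = _parse_star_shift_loop(path.read_text(), origin=str(path))
    else:
        raise ShiftTableError(f"unknown shift-table format {format!r}")
    shifts = _validate_rows(peptide, rows, origin=str(path))
    return ShiftTable(peptide, condition, shifts, **kwargs)


def write_shift_csv(table: ShiftTable, path: str | Path) -> None:
    recs = [
        {
            "residue_number": num,
            "residue_code": table.peptide.residue(num).code,
            "nucleus": nuc,
            "shift_ppm": round(ppm, 4),
        }
        for (num, nuc), ppm in sorted(table.shifts.items())
    ]
    pd.DataFrame(recs).to_csv(path, index=False)


def _parse_star_shift_loop(text: str, origin: str = "<star>"):
    """Parse the first ``_Atom_chem_shift`` loop of an NMR-STAR file.

    Deliberately minimal: handles only whitespace-delimited loops of the
    standard chemical-shift tags, which is all the deposited peptide shift
    lists use.
    """
    lines = [ln.strip() for ln in text.splitlines()]
    tags: list[str] = []
    rows: list[tuple[int, str, str, float]] = []
    in_loop = False
    reading_data = False
    for ln in lines:
        if not ln or ln.startswith("#"):
            continue
        if ln == "loop_":
            in_loop, reading_data, tags = True, False, []
            continue
        if in_loop and ln.startswith("_"):
            tags.append(ln.split(".")[-1] if "." in ln else ln.lstrip("_"))
            continue
        if in_loop and ln == "stop_":
            if any(t == "Val" for t in tags) and rows:
                return rows
            in_loop, reading_data = False, False
            continue
        if in_loop:
            reading_data = True
            if not {"Seq_ID", "Comp_ID", "Atom_ID", "Val"} <= set(tags):
                in_loop = False  # not a chemical-shift loop
                continue
            fields = ln.split()
            if len(fields) != len(tags):
                raise ShiftTableError(
                    f"{origin}: loop row has {len(fields)} fields, expected {len(tags)}"
                )
            rec = dict(zip(tags, fields))
            comp = rec["Comp_ID"].upper()
            code = _THREE_TO_ONE.get(comp, comp if len(comp) == 1 else "")
            atom = rec["Atom_ID"].upper()
            nuc = _STAR_ATOM_INV.get(atom, atom)
            rows.append((int(rec["Seq_ID"]), code, nuc, float(rec["Val"])))
    if not rows:
        raise ShiftTableError(f"{origin}: no _Atom_chem_shift loop found")
    return rows


def write_star_shift_loop(table: ShiftTable, path: str | Path) -> None:
    """Write the minimal ``_Atom_chem_shift`` loop for a shift table."""
    out = [
        f"data_{table.peptide.name}",
        "",
        "save_assigned_chemical_shifts",
        "   loop_",
        "      _Atom_chem_shift.Seq_ID",
        "      _Atom_chem_shift.Comp_ID",
        "      _Atom_chem_shift.Atom_ID",
        "      _Atom_chem_shift.Val",
        "",
    ]
    for (num, nuc), ppm in sorted(table.shifts.items()):
        code = _ONE_TO_THREE[table.peptide.residue(num).code]
        out.append(f"      {num} {code} {_STAR_ATOM[nuc]} {ppm:.4f}")
    out += ["   stop_", "save_", ""]
    Path(path).write_text("\n".join(out))


# ---------------------------------------------------------------- analysis


def secondary_shifts(
    table: ShiftTable,
    rc: RandomCoilTable,
    nucleus: str,
    use_neighbor_corrections: bool = False,
) -> DeltaProfile:
    """Δδ(i) = δ_obs(i) − δ_RC(aa_i) for HA or CA.

    Residues without an observed shift are absent from the result.  Neighbor
    (sequence-dependent) corrections are applied only when enabled and
    present in the reference set.
    """
    if nucleus not in ("HA", "CA"):
        raise ShiftTableError(
            f"Δδ profiles are defined for HA/CA only, not {nucleus!r}"
        )
    values: dict[int, float] = {}
    for num in table.peptide.residue_numbers:
        obs = table.get(num, nucleus)
        if obs is None:
            continue
        aa = table.peptide.residue(num).code
        ref = rc.shift(aa, nucleus)
        if use_neighbor_corrections and rc.neighbor_corrections:
            ref += rc.neighbor_corrections.get((aa, nucleus), 0.0)
        values[num] = obs - ref
    return DeltaProfile(nucleus=nucleus, values=values, source=f"{table.id}|{rc.name}")


def detect_helical_segments(
    profile: DeltaProfile,
    rc_band: float = RC_BAND_HA,
    min_length: int = 3,
) -> list[HelixSegment]:
    """Maximal runs of consecutive residues with Δδ_Hα below −rc_band.

    A single residue at or above −rc_band (or a gap in the profile)
    terminates a run, so a hinge residue splits one helix into two.  Runs
    shorter than ``min_length`` are discarded.
    """
    if profile.nucleus != "HA":
        raise ShiftTableError("segment detection operates on the Δδ_Hα profile")
    segments: list[HelixSegment] = []
    run: list[int] = []

    def close() -> None:
        if len(run) >= min_length:
            segments.append(HelixSegment(run[0], run[-1]))
        run.clear()

    for num in profile.residues():
        helical = profile[num] < -rc_band
        contiguous = bool(run) and num == run[-1] + 1
        if helical and (not run or contiguous):
            run.append(num)
        elif helical:
            close()
            run.append(num)
        else:
            close()
    close()
    return segments


def segment_average(profile: DeltaProfile, segment: HelixSegment) -> float:
    """Arithmetic mean of Δδ over profile residues inside the segment."""
    vals = [profile[n] for n in profile.residues() if n in segment]
    if not vals:
        raise ShiftTableError(f"no profile data inside segment {segment}")
    return sum(vals) / len(vals)


def helix_population(
    avg_delta: float, nucleus: str, segment: HelixSegment | None = None
) -> PopulationEstimate:
    """Two-state helix population from a segment-averaged secondary shift.

    percent = 100 * avg_delta / Δδ_100%(nucleus); the error is the
    measurement error propagated through the same linear map.  Out-of-range
    populations are flagged, not clamped.
    """
    if nucleus not in FULL_HELIX_LIMIT:
        raise ShiftTableError(f"no full-helix limit for nucleus {nucleus!r}")
    limit = FULL_HELIX_LIMIT[nucleus]
    if limit == 0:
        raise ShiftTableError("full-helix limit misconfigured to zero")
    percent = 100.0 * avg_delta / limit
    error = 100.0 * MEASUREMENT_ERROR[nucleus] / abs(limit)
    return PopulationEstimate(
        percent=percent,
        error_percent=error,
        nucleus=nucleus,
        segment=segment,
        in_range=0.0 <= percent <= 100.0,
    )


def combine_populations(
    p_ha: PopulationEstimate, p_ca: PopulationEstimate
) -> PopulationEstimate:
    """Average the Hα- and Cα-derived percentages for one segment.

    The combined value is the mean of the two integer-rounded percentages
    and the error their population standard deviation (half the absolute
    difference).
    """
    if p_ha.segment != p_ca.segment:
        raise ShiftTableError(
            f"cannot combine estimates for different segments "
            f"({p_ha.segment} vs {p_ca.segment})"
        )
    a, b = p_ha.percent_rounded, p_ca.percent_rounded
    return PopulationEstimate(
        percent=(a + b) / 2.0,
        error_percent=abs(a - b) / 2.0,
        nucleus="combined",
        segment=p_ha.segment,
        in_range=p_ha.in_range and p_ca.in_range,
    )
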