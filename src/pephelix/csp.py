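"""Chemical-shift-perturbation (CSP) interface mapping.

Comparing a peptide's shifts free in solution against the same peptide in a
mixture with its putative partner localizes the binding interface: residues
whose resonances move are in (or rearranged by) the contact.  Per-residue
changes of the three backbone reporters are combined into the weighted
perturbation

    Δδ_w = sqrt(Δδ_Hα² + Δδ_HN² + Δδ_Cα²/4),

the ¼ weight bringing the larger ¹³C dispersion onto the ¹H scale.  Residues
above a significance threshold become the "active residues" that seed
data-driven docking restraints.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd

from .chemshift import ShiftTable, ShiftTableError
from .sequences import Peptide, ResidueID

NUCLEI = ("HA", "HN", "CA")
#: weight applied to each squared nucleus difference inside Δδ_w
CSP_WEIGHTS = {"HA": 1.0, "HN": 1.0, "CA": 0.25}
#: default floor (fixed cutoff), ppm
DEFAULT_CUTOFF = 0.02


class CSPError(ValueError):
    pass


@dataclass(frozen=True)
class CSPProfile:
    """Per-residue weighted perturbations with per-nucleus components.

    ``components[i]`` maps nucleus -> Δδ (signed) or None where the nucleus
    was not present in both tables.  A residue with no shared nucleus at all
    is absent from the profile.
    """

    values: Mapping[int, float]
    components: Mapping[int, Mapping[str, float | None]]
    peptide: Peptide
    free_id: str = ""
    mixture_id: str = ""

    def __post_init__(self) -> None:
        for num, w in self.values.items():
            if w < 0:
                raise CSPError(f"negative Δδ_w at residue {num}")

    def residues(self) -> list[int]:
        return sorted(self.values)


@dataclass(frozen=True)
class ResidueSet:
    """Flagged interface residues plus the policy that selected them."""

    residues: tuple[ResidueID, ...]
    policy: str
    peptide_name: str = ""

    def __post_init__(self) -> None:
        nums = [r.number for r in self.residues]
        if len(nums) != len(set(nums)):
            raise CSPError("duplicate residues in set")

    def numbers(self) -> list[int]:
        return sorted(r.number for r in self.residues)


def weighted_csp(free: ShiftTable, mixture: ShiftTable) -> CSPProfile:
    """Δδ_w profile between the free-peptide and mixture shift tables.

    Only nuclei present in BOTH tables contribute; missing nuclei add zero
    to the sum and are recorded as absent in the components.  Residues with
    no shared nucleus are omitted (with a warning), never zero-filled.
    """
    if free.peptide.name != mixture.peptide.name or free.peptide.sequence != mixture.peptide.sequence:
        raise CSPError(
            f"cannot pair tables of different peptides "
            f"({free.peptide.name} vs {mixture.peptide.name})"
        )
    if free.condition != mixture.condition:
        raise CSPError(
            f"cannot pair tables of different conditions "
            f"({free.condition!r} vs {mixture.condition!r})"
        )
    values: dict[int, float] = {}
    components: dict[int, dict[str, float | None]] = {}
    omitted: list[int] = []
    for num in free.peptide.residue_numbers:
        comp: dict[str, float | None] = {}
        ssum = 0.0
        shared = 0
        for nuc in NUCLEI:
            a, b = free.get(num, nuc), mixture.get(num, nuc)
            if a is None or b is None:
                comp[nuc] = None
                continue
            d = b - a
            comp[nuc] = d
            ssum += CSP_WEIGHTS[nuc] * d * d
            shared += 1
        if shared == 0:
            if any(
                free.get(num, n) is not None or mixture.get(num, n) is not None
                for n in NUCLEI
            ):
                omitted.append(num)
            continue
        values[num] = math.sqrt(ssum)
        components[num] = comp
    if omitted:
        import logging

        logging.getLogger(__name__).warning(
            "residues %s omitted from Δδ_w: no nucleus present in both tables",
            omitted,
        )
    return CSPProfile(
        values=values,
        components=components,
        peptide=free.peptide,
        free_id=free.id,
        mixture_id=mixture.id,
    )


def flag_interacting_residues(
    profile: CSPProfile,
    policy: str = "mean_plus_sd",
    cutoff: float = DEFAULT_CUTOFF,
) -> ResidueSet:
    """Select residues with significant Δδ_w.

    mean_plus_sd : flag Δδ_w > max(mean + 1*SD of the profile, cutoff)
    fixed_cutoff : flag Δδ_w > cutoff
    """
    if not profile.values:
        raise CSPError("empty CSP profile")
    vals = [profile.values[n] for n in profile.residues()]
    if policy == "mean_plus_sd":
        mean = sum(vals) / len(vals)
        sd = math.sqrt(sum((v - mean) ** 2 for v in vals) / len(vals))
        threshold = max(mean + sd, cutoff)
        desc = f"mean_plus_sd(threshold={threshold:.4f} ppm, floor={cutoff} ppm)"
    elif policy == "fixed_cutoff":
        threshold = cutoff
        desc = f"fixed_cutoff({cutoff} ppm)"
    else:
        raise CSPError(f"unknown flagging policy {policy!r}")
    flagged = tuple(
        profile.peptide.residue(n)
        for n in profile.residues()
        if profile.values[n] > threshold
    )
    return ResidueSet(flagged, policy=desc, peptide_name=profile.peptide.name)


def write_csp_csv(profile: CSPProfile, path: str | Path) -> None:
    """Profile as csv: residue, ΔHA, ΔHN, ΔCA, Δδ_w (absent nuclei blank)."""
    recs = []
    for num in profile.residues():
        comp = profile.components[num]
        recs.append(
            {
                "residue_number": num,
                "residue_code": profile.peptide.residue(num).code,
                "delta_HA": comp["HA"],
                "delta_HN": comp["HN"],
                "delta_CA": comp["CA"],
                "delta_w": round(profile.values[num], 6),
            }
        )
    pd.DataFrame(recs).to_csv(path, index=False, float_format="%.6f")


def export_active_residues(rset: ResidueSet, path: str | Path) -> tuple[Path, Path]:
    """Write the active-residue list as twin text and JSON files.

    Both files are byte-stable across runs; an empty set writes headers
    only.  Returns the (text, json) paths.
    """
    path = Path(path)
    txt_path = path.with_suffix(".txt")
    json_path = path.with_suffix(".json")
    lines = [
        f"# active residues for {rset.peptide_name}",
        f"# policy: {rset.policy}",
        "residue_number\tresidue_code",
    ]
    for r in sorted(rset.residues, key=lambda r: r.number):
        lines.append(f"{r.number}\t{r.code}")
    txt_path.write_text("\n".join(lines) + "\n")
    payload = {
        "peptide": rset.peptide_name,
        "policy": rset.policy,
        "residues": [
            {"number": r.number, "code": r.code}
            for r in sorted(rset.residues, key=lambda r: r.number)
        ],
    }
    json_path.write_text(json.dumps(payload, indent=1, sort_keys=True) + "\n")
    return txt_path, json_path


def read_active_residues(json_path: str | Path) -> ResidueSet:
    """Inverse of :func:`export_active_residues` (reads the JSON twin)."""
    d = json.loads(Path(json_path).read_text())
    residues = tuple(ResidueID(r["number"], r["code"]) for r in d["residues"])
    return ResidueSet(residues, policy=d["policy"], peptide_name=d["peptide"])
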