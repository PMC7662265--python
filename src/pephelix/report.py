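"""Condition-comparison report.

Assembles, per peptide and solvent condition, the same summary a helicity
study tabulates: [θ]222 and the CD helix percentage, the detected helical
segments, the segment-averaged Δδ_Hα / Δδ_Cα with their population
estimates, the combined percentage ± SD, and (optionally) the CSP-flagged
interface residues.  Every numeric cell carries the identifiers of the
inputs it came from, and the calibration constants and policies in force
are echoed into the report header so a rerun is self-describing.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import pandas as pd
import yaml

from . import chemshift
from .cd import CDSampleInfo, helix_fraction_from_ellipticity, read_cd_csv, to_mean_residue_ellipticity
from .chemshift import (
    HelixSegment,
    combine_populations,
    detect_helical_segments,
    helix_population,
    read_shift_table,
    secondary_shifts,
    segment_average,
)
from .csp import flag_interacting_residues, weighted_csp
from .random_coil import get_reference_set
from .sequences import Peptide, from_dict


class PipelineError(RuntimeError):
    pass


@dataclass
class AnalysisReport:
    header: dict
    rows: list[dict] = field(default_factory=list)
    csp_summary: list[dict] = field(default_factory=list)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.rows)

    def to_text(self) -> str:
        lines = ["# helicity / interface report"]
        for k, v in sorted(self.header.items()):
            lines.append(f"# {k}: {v}")
        lines.append("")
        if self.rows:
            lines.append(self.to_frame().to_string(index=False))
        for entry in self.csp_summary:
            lines.append("")
            lines.append(
                f"CSP {entry['peptide']} ({entry['condition']}): "
                f"flagged {entry['residues'] or 'none'} [{entry['policy']}]"
            )
        return "\n".join(lines) + "\n"

    def write(self, out_dir: str | Path, fmt: str = "csv") -> list[Path]:
        out_dir = Path(out_dir)
        out_dir.mkdir(parents=True, exist_ok=True)
        written = [out_dir / "report.txt"]
        written[0].write_text(self.to_text())
        if fmt in ("csv", "text"):
            path = out_dir / "report.csv"
            self.to_frame().to_csv(path, index=False, float_format="%.4f")
            written.append(path)
        if fmt == "json":
            path = out_dir / "report.json"
            path.write_text(
                json.dumps(
                    {
                        "header": self.header,
                        "rows": self.rows,
                        "csp": self.csp_summary,
                    },
                    indent=1,
                    sort_keys=True,
                    default=str,
                )
                + "\n"
            )
            written.append(path)
        return written


def _load_peptides(config: dict) -> dict[str, Peptide]:
    peptides = {}
    for name, spec in (config.get("peptides") or {}).items():
        peptides[name] = from_dict({"name": name, **spec})
    if not peptides:
        raise PipelineError("config defines no peptides")
    return peptides


def _require_file(path_str: str, stage: str) -> Path:
    path = Path(path_str)
    if not path.exists():
        raise PipelineError(f"{stage}: input file not found: {path}")
    return path


def run_pipeline(
    config_path: str | Path,
    out_dir: str | Path | None = None,
    fmt: str = "csv",
    seed: int | None = None,
) -> AnalysisReport:
    """Run the full per-condition analysis described by a YAML config.

    The config names the peptides, the shift/CD input files per condition
    and the analysis options; the report (text + csv/json) is written under
    ``out_dir`` and also returned.  Any stage error raises
    :class:`PipelineError` naming the stage and file.
    """
    config_path = Path(config_path)
    if not config_path.exists():
        raise PipelineError(f"config file not found: {config_path}")
    config = yaml.safe_load(config_path.read_text()) or {}
    if seed is not None:
        config["seed"] = seed

    rc_set = config.get("rc_set", "wishart1995")
    rc = get_reference_set(rc_set)
    rc_band = float(config.get("rc_band", chemshift.RC_BAND_HA))
    min_len = int(config.get("min_segment_length", 3))
    csp_policy = config.get("csp_policy", "mean_plus_sd")
    csp_cutoff = float(config.get("csp_cutoff", 0.02))

    peptides = _load_peptides(config)
    header = {
        "rc_set": rc_set,
        "rc_band_ppm": rc_band,
        "min_segment_length": min_len,
        "full_helix_limit_HA_ppm": chemshift.FULL_HELIX_LIMIT["HA"],
        "full_helix_limit_CA_ppm": chemshift.FULL_HELIX_LIMIT["CA"],
        "csp_policy": csp_policy,
        "csp_cutoff_ppm": csp_cutoff,
        "seed": config.get("seed", 0),
    }
    report = AnalysisReport(header=header)

    for cond in config.get("conditions") or []:
        pep_name = cond["peptide"]
        if pep_name not in peptides:
            raise PipelineError(f"condition references unknown peptide {pep_name!r}")
        peptide = peptides[pep_name]
        cond_name = cond.get("name", "unnamed")
        row: dict = {"peptide": pep_name, "condition": cond_name}

        if "cd" in cond:
            cd_path = _require_file(cond["cd"], f"cd[{pep_name}/{cond_name}]")
            spec = read_cd_csv(cd_path)
            if spec.units == "millidegrees":
                info = cond.get("cd_sample")
                if info is None:
                    raise PipelineError(
                        f"cd[{pep_name}/{cond_name}]: raw mdeg data needs a cd_sample block"
                    )
                spec = to_mean_residue_ellipticity(
                    spec,
                    CDSampleInfo(
                        concentration_molar=float(info["concentration_molar"]),
                        path_length_cm=float(info["path_length_cm"]),
                        n_residues=int(info.get("n_residues", len(peptide))),
                    ),
                )
            theta222 = spec.value_at(222.0)
            frac = helix_fraction_from_ellipticity(theta222)
            row["theta222"] = round(theta222, 2)
            row["cd_percent"] = frac.percent_rounded
            row["cd_source"] = str(cd_path)

        if "shifts" in cond:
            sh_path = _require_file(cond["shifts"], f"shifts[{pep_name}/{cond_name}]")
            table = read_shift_table(
                sh_path, peptide, cond_name, format=cond.get("shifts_format", "csv")
            )
            prof_ha = secondary_shifts(table, rc, "HA")
            prof_ca = secondary_shifts(table, rc, "CA")
            segments = detect_helical_segments(prof_ha, rc_band=rc_band, min_length=min_len)
            row["segments"] = ";".join(str(s) for s in segments) or "none"
            seg_rows = []
            for seg in segments:
                avg_ha = segment_average(prof_ha, seg)
                avg_ca = segment_average(prof_ca, seg)
                p_ha = helix_population(avg_ha, "HA", seg)
                p_ca = helix_population(avg_ca, "CA", seg)
                p_comb = combine_populations(p_ha, p_ca)
                seg_rows.append(
                    {
                        **row,
                        "segment": str(seg),
                        "avg_dHA_ppm": round(avg_ha, 2),
                        "pct_from_HA": p_ha.percent_rounded,
                        "avg_dCA_ppm": round(avg_ca, 2),
                        "pct_from_CA": p_ca.percent_rounded,
                        "pct_combined": p_comb.percent,
                        "pct_combined_sd": p_comb.error_percent,
                        "shift_source": table.id,
                    }
                )
            if seg_rows:
                report.rows.extend(seg_rows)
            else:
                report.rows.append({**row, "segment": "none"})
        else:
            report.rows.append(row)

    for job in config.get("csp") or []:
        pep_name = job["peptide"]
        if pep_name not in peptides:
            raise PipelineError(f"csp job references unknown peptide {pep_name!r}")
        peptide = peptides[pep_name]
        cond_name = job.get("condition", "unnamed")
        fmt_in = job.get("format", "csv")
        free = read_shift_table(
            _require_file(job["free"], f"csp[{pep_name}/{cond_name}]"),
            peptide,
            cond_name,
            format=fmt_in,
        )
        mixture = read_shift_table(
            _require_file(job["mixture"], f"csp[{pep_name}/{cond_name}]"),
            peptide,
            cond_name,
            format=fmt_in,
            label=f"{pep_name}/{cond_name}/mixture",
        )
        profile = weighted_csp(free, mixture)
        flagged = flag_interacting_residues(profile, policy=csp_policy, cutoff=csp_cutoff)
        report.csp_summary.append(
            {
                "peptide": pep_name,
                "condition": cond_name,
                "residues": ",".join(str(r) for r in sorted(flagged.residues, key=lambda r: r.number)),
                "policy": flagged.policy,
            }
        )

    if out_dir is not None:
        report.write(out_dir, fmt=fmt)
    return report
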