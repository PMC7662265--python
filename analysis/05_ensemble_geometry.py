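"""Geometry of helix-hinge-helix ensembles at the observed elbow angles.

Builds 20-model synthetic ensembles of the CB1 elbow peptide with the
TMH7/H8 inter-helix angle prescribed at the values observed for the real
ensembles (94° in TFE, 75° in DPC) plus 0.2 Å coordinate jitter, writes
them as multi-model PDB, and measures angle statistics, pairwise backbone
RMSD and a Ramachandran summary.  Finding: the directed-axis angle
statistic recovers the construction angle within ~3° — the noise floor set
by fitting a 5-residue (H8) axis under 0.2 Å jitter — at both the obtuse
TFE-like and acute DPC-like elbow angles.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from pephelix import datasets as ds
from pephelix.geometry import (
    interhelix_angle,
    pairwise_rmsd_matrix,
    ramachandran_summary,
    write_model_ensemble,
)
from pephelix.synthetic import build_hinged_helix_ensemble

OUT = Path(__file__).resolve().parents[1] / "results"


def main(seed: int = 0) -> None:
    peptide = ds.CB1_391_409
    OUT.mkdir(exist_ok=True)
    rows = []
    for salt, (condition, angle) in enumerate(
        (("TFE", ds.ELBOW_ANGLES["TFE"]), ("DPC", ds.ELBOW_ANGLES["DPC"]))
    ):
        ens = build_hinged_helix_ensemble(
            peptide, ds.CB1_TMH7, ds.CB1_H8, angle,
            n_models=20, jitter=0.2, seed=seed + salt,
        )
        pdb_path = OUT / f"cb1_elbow_{condition.lower()}_synthetic.pdb"
        write_model_ensemble(ens, pdb_path)
        _, mean, sd = interhelix_angle(ens, ds.CB1_TMH7, ds.CB1_H8)
        rmsd = pairwise_rmsd_matrix(ens)
        rama = ramachandran_summary(ens)
        rows.append(
            {
                "condition": condition,
                "prescribed_angle_deg": angle,
                "recovered_mean_deg": round(mean, 2),
                "recovered_sd_deg": round(sd, 2),
                "mean_pairwise_rmsd_A": round(float(rmsd.to_numpy().sum() / (20 * 19)), 3),
                "rama_favored": round(rama["favored"], 3),
            }
        )
        print(
            f"{condition}: prescribed {angle:.0f} deg -> recovered "
            f"{mean:.2f} +- {sd:.2f} deg ({pdb_path.name})"
        )
    frame = pd.DataFrame(rows)
    frame.to_csv(OUT / "ensemble_geometry.csv", index=False)
    print(f"\nwrote {OUT / 'ensemble_geometry.csv'}")


if __name__ == "__main__":
    main()
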