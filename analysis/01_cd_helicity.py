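"""CD-based helicity of the free peptides.

Applies the 222 nm mean-residue-ellipticity estimator to the measured
[θ]222 of each peptide in water, 30% TFE and DPC micelles.  Finding: both
peptides are largely disordered in water (12-13% helix) and gain
substantial helicity in TFE and DPC (17-34%), the CB1 elbow peptide more so
in micelles and the finger-loop peptide more so in TFE.
"""

from pathlib import Path

import pandas as pd

from pephelix import datasets as ds
from pephelix.cd import helix_fraction_from_ellipticity

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for (peptide, condition), theta222 in ds.ELLIPTICITY_222.items():
        est = helix_fraction_from_ellipticity(theta222)
        rows.append(
            {
                "peptide": peptide,
                "condition": condition,
                "theta222_deg_cm2_dmol": theta222,
                "helix_percent": round(est.percent, 2),
                "helix_percent_rounded": est.percent_rounded,
            }
        )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "cd_helicity.csv", index=False)
    print(frame.to_string(index=False))
    print(f"\nwrote {OUT / 'cd_helicity.csv'}")


if __name__ == "__main__":
    main()
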