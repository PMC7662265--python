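"""Design-stage properties of the two capped peptides.

Computes the theoretical masses of the acetylated/amidated sequences, their
net charge at the mildly acidic pH of the measurements (5.5), and the
isoelectric point where defined.  Finding: the capped masses match the
synthesis QC values (2311.7 and 1694.9 Da); the elbow peptide is strongly
basic (+3 at pH 5.5, pI ~12) and the finger-loop peptide slightly acidic,
so both stay charged — hence soluble — far from their pI under the
measurement conditions.
"""

from pathlib import Path

import pandas as pd

from pephelix import datasets as ds
from pephelix.properties import PropertyError, isoelectric_point, net_charge, peptide_mass

OUT = Path(__file__).resolve().parents[1] / "results"


def main() -> None:
    rows = []
    for peptide in ds.PEPTIDES.values():
        mass = peptide_mass(peptide)
        try:
            pi = round(isoelectric_point(peptide), 2)
        except PropertyError:
            pi = None
        rows.append(
            {
                "peptide": peptide.name,
                "sequence": peptide.sequence,
                "caps": f"{peptide.n_term_mod}/{peptide.c_term_mod}",
                "average_mass_da": round(mass.average_da, 2),
                "monoisotopic_mass_da": round(mass.monoisotopic_da, 2),
                "net_charge_pH5.5": round(net_charge(peptide, 5.5), 2),
                "pI": pi,
            }
        )
    frame = pd.DataFrame(rows)
    OUT.mkdir(exist_ok=True)
    frame.to_csv(OUT / "peptide_design.csv", index=False)
    print(frame.to_string(index=False))
    print(f"\nwrote {OUT / 'peptide_design.csv'}")


if __name__ == "__main__":
    main()
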