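"""Crystal-structure comparators for the amorphous-state analyses.

The liquid/glass hydrogen-bond numbers only mean something next to the
crystal baselines.  This script computes them from whatever crystal
structures are available: always the synthetic toy crystal with a planted
3.00 Å N-H···O contact (a correctness check with known truth), and, when
the user has placed CIFs of the real polymorphs under
tests/data/external/ (CSD refcodes are printed), the published contact
geometries and densities.

Outputs: results/crystal_comparators.csv
"""

from pathlib import Path

import pandas as pd

from epsrkit.crystal_ref import crystal_contacts, crystal_density, parse_cif
from epsrkit.synthetic_data import make_toy_crystal

RESULTS = Path(__file__).resolve().parent.parent / "results"
RESULTS.mkdir(exist_ok=True)
EXTERNAL = Path(__file__).resolve().parent.parent / "tests" / "data" / "external"

# CIFs the user may supply (Cambridge Structural Database refcodes)
EXTERNAL_CIFS = {
    "BICCIZ07.cif": "nifedipine alpha polymorph",
    "BICCIZ03.cif": "nifedipine beta polymorph",
    "DONTIJ.cif": "felodipine form I",
    "DONTIJ01.cif": "felodipine form II",
}


def main():
    rows = []
    toy = make_toy_crystal(3.00)
    contacts = crystal_contacts(toy)
    rows.append({
        "structure": "synthetic toy crystal (planted 3.00 Å contact)",
        "shortest_NO_A": round(float(contacts.iloc[0].d_NO), 3),
        "NHO_angle_deg": round(float(contacts.iloc[0].angle_NHO), 1),
        "density_g_cm3": round(crystal_density(toy), 4),
    })
    for fname, desc in EXTERNAL_CIFS.items():
        path = EXTERNAL / fname
        if not path.exists():
            print(f"[skip] {desc}: supply {path} to include it")
            continue
        xs = parse_cif(path)
        contacts = crystal_contacts(xs, donor_n="N", acceptor="O")
        rows.append({
            "structure": f"{desc} ({fname})",
            "shortest_NO_A": round(float(contacts.iloc[0].d_NO), 3),
            "NHO_angle_deg": round(float(contacts.iloc[0].angle_NHO), 1),
            "density_g_cm3": round(crystal_density(xs), 4),
        })
    table = pd.DataFrame(rows)
    table.to_csv(RESULTS / "crystal_comparators.csv", index=False)
    print(table.to_string(index=False))


if __name__ == "__main__":
    main()
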