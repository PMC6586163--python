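#!/usr/bin/env python
"""Tabulate the PEG-8000 calibration used to impose osmotic stress.

Maps w/w mass fractions to water potential at 23 °C, including the three
stress solutions (17.5, 25.4, 31.6 % → −0.4, −0.8, −1.2 MPa nominal), and
the osmotic pressure of the 30 mM NaCl (60 mOsmol kg⁻¹) probe step.
Writes results/osmoticum_calibration.csv.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from rootprobe import ideal_osmolality, peg8000_water_potential, vant_hoff_osmotic_pressure

OUT = Path(__file__).resolve().parent.parent / "results"
OUT.mkdir(exist_ok=True)

rows = [
    {"mass_fraction": f, "water_potential_mpa": peg8000_water_potential(f, 23.0)}
    for f in np.round(np.arange(0.0, 0.41, 0.025), 3)
]
table = pd.DataFrame(rows)
table.to_csv(OUT / "osmoticum_calibration.csv", index=False)

print("PEG-8000 calibration at 23 °C (w/w fraction of total solution):")
for f in (0.175, 0.254, 0.316):
    psi = peg8000_water_potential(f, 23.0)
    print(f"  {f:5.1%}  ->  ψ = {psi:+.3f} MPa (nominal {round(psi, 1):+.1f})")

osmolality = ideal_osmolality(30.0, 2)
dpi = vant_hoff_osmotic_pressure(osmolality, 23.0)
print(f"30 mM NaCl -> {osmolality:.0f} mOsmol kg⁻¹ -> Δπ°s = {dpi:.3f} MPa at 23 °C")
print(f"wrote {OUT / 'osmoticum_calibration.csv'}")
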