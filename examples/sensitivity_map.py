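"""Fuse platform densities under the CV gates and build sensitivity layers.

Boat and aerial density surfaces for one species are fused cell by cell:
estimates with CV > 0.5 are excluded, the larger density wins if its
CV < 0.3, otherwise the lower-CV estimate is kept.  The fused density d
becomes score × ln(d + 1), summed across species into the final map; cells
where no species had usable data carry an exact 0 and a False data mask.
"""

import numpy as np
import pandas as pd

from seasens import sensmap, ssi
from seasens.dsm import DensitySurface


def surface(density, cv, species, platform):
    t = pd.DataFrame({"cell_id": np.arange(len(density)),
                      "density": density, "cv": cv,
                      "abundance": np.nan, "extrapolated": False})
    return DensitySurface(species=species, behaviour="combined",
                          season="winter", platform=platform, table=t)


# four cells showing each fusion rule in turn
boat = surface([2.0, 2.0, 2.0, 5.0], [0.20, 0.40, 0.60, 0.55],
               "Red-throated diver", "boat")
aerial = surface([3.0, 3.0, 3.0, 1.0], [0.25, 0.45, 0.70, 0.28],
                 "Red-throated diver", "aerial")
fused = sensmap.fuse_platforms(boat, aerial)
print("fused densities:", fused.table["density"].tolist())
print("  (max-density rule, lowest-CV rule, both excluded, sole survivor)")

sens = ssi.sensitivity_for(ssi.load_species_scores())
rtd = sens["Red-throated diver"]
layer = sensmap.risk_map({"Red-throated diver": fused},
                         {"Red-throated diver": rtd},
                         season="winter", risk_type="displacement")
print(f"\ndisplacement score {rtd.displacement_score} "
      f"({rtd.displacement_class})")
print("layer values:", [round(v, 2) for v in layer.table['value']])
print("data_ok mask:", layer.table["data_ok"].tolist())
print("  cell 3's 0.0 with data_ok=False marks unusable data, not absence")
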