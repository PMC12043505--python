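"""Regional culture-transition models under sigma and uniform boundaries.

Builds two synthetic regions whose Neolithic begins at 7900 and 7300 cal BP,
fits a two-phase (Mesolithic -> Neolithic) model per region under both
boundary treatments, and prints the estimated transition ages.
"""

import numpy as np
import pandas as pd

import phasecal as pc
from phasecal.pipeline import run_transition_model

curve = pc.simulate_calibration_curve((11000, 5000), wiggle_amplitude=15,
                                      wiggle_period=600, sigma=8, seed=3)
rng = np.random.default_rng(2)
rows = []
for region, neo_start in (("north", 7900.0), ("south", 7300.0)):
    for culture, (old, young) in (("mesolithic", (8600.0, neo_start)),
                                  ("neolithic", (neo_start, 6900.0))):
        for i in range(9):
            th = rng.uniform(young, old)
            mu, sc = curve(th)
            rows.append({"lab_code": f"{region}-{culture[:3]}-{i}",
                         "c14_age": float(rng.normal(mu, np.sqrt(1600 + sc**2))),
                         "c14_sigma": 40.0, "material": "terrestrial",
                         "region": region, "culture": culture})

report = run_transition_model(
    {"seed": 5, "boundary_type": "both",
     "mcmc": {"chains": 2, "iterations": 3000, "burn_in": 1200, "thin": 2}},
    curves={"terrestrial": curve}, dates=pd.DataFrame(rows))
cols = ["region", "boundary_type", "end_mesolithic_ka", "start_neolithic_ka"]
print(report["table"][cols].to_string(index=False))
print("\ntrue transitions: north 7.9 ka, south 7.3 ka.  Sigma boundaries let")
print("the phases overlap; uniform boundaries forbid it — reporting both")
print("brackets the plausible transition scenarios.")
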