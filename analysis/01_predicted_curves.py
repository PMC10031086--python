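"""Predicted CaM-MLCK titration curves for all models and CaM variants.

Evaluates the three mechanisms (random, partially ordered, fully ordered)
for wild-type CaM and the three EF-hand knockout variants at the
main-experiment concentrations, writes the curves to results/curves.csv
and prints the limiting fractions that drive model discrimination.
"""

from pathlib import Path

import numpy as np
import pandas as pd

from camnet.network import (
    Concentrations,
    MUTANTS,
    ModelVariant,
    ParameterSet,
    limit_binding,
    titration_curve,
)

OUT = Path(__file__).resolve().parents[1] / "results"
OUT.mkdir(exist_ok=True)

params = ParameterSet.reference()
conc = Concentrations(cam_tot=0.713, mlck_tot=0.0237)
grid = np.concatenate([[0.0], np.geomspace(0.005, 39.0, 80)])

frames = []
print("Limiting fractions of MLCK bound (zero-Ca -> high-Ca):")
for mutant, (n_fn, c_fn) in MUTANTS.items():
    for model_id in (1, 2, 3):
        variant = ModelVariant(model_id, n_fn, c_fn)
        curve = titration_curve(params, variant, conc.cam_tot, conc.mlck_tot, grid)
        frames.append(curve.to_frame(mutant_label=mutant))
        lo = limit_binding(params, variant, conc, "low")
        hi = limit_binding(params, variant, conc, "high")
        print(f"  Model {model_id} {mutant:>5}: {100 * lo:5.1f}% -> {100 * hi:5.1f}%")

pd.concat(frames, ignore_index=True).to_csv(OUT / "curves.csv", index=False)
print(f"\nOnly Model 1 predicts binding without Ca2+ (via the apo constant K9);")
print(f"only Model 3 predicts zero binding for the N-lobe knockout at high Ca2+.")
print(f"Wrote {OUT / 'curves.csv'}")
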