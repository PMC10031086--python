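"""Qualitative binding/no-binding prediction tables for model discrimination.

Each mechanism makes a binding (B) or no-binding (NB) prediction for every
(CaM variant, Ca2+ regime) condition.  NB entries are *structural zeros* —
the network truncation removes every MLCK-bound state, so the prediction
holds for any parameter values; B entries carry the quantitative predicted
fraction alongside.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import pandas as pd

from camnet.network import (
    Concentrations,
    MUTANTS,
    ModelVariant,
    ParameterSet,
    limit_binding,
)

__all__ = ["PredictionTable", "predict_table", "detection_call", "REGIMES"]

REGIMES = ("zero_ca", "high_ca")


@dataclass(frozen=True)
class PredictionTable:
    """B/NB calls plus predicted fractions, indexed by (mutant, regime).

    ``calls`` and ``fractions`` are DataFrames with a (mutant, regime)
    MultiIndex and one column per model.  An entry is NB iff its predicted
    fraction is a structural zero.
    """

    calls: pd.DataFrame
    fractions: pd.DataFrame

    def to_frame(self) -> pd.DataFrame:
        """Side-by-side export: call and fraction columns per model."""
        out = {}
        for col in self.calls.columns:
            out[f"{col}_call"] = self.calls[col]
            out[f"{col}_fraction"] = self.fractions[col]
        return pd.DataFrame(out, index=self.calls.index)


def predict_table(
    params: ParameterSet,
    models: Sequence[int] = (1, 2, 3),
    mutants: Sequence[str] = ("WT", "Nmut", "Cmut"),
    conc: Concentrations | None = None,
) -> PredictionTable:
    """Limit-binding predictions for every (model, mutant, regime).

    The B/NB call is made from network structure alone: NB when the
    mechanism plus lobe knockouts leave no MLCK-competent state in the
    regime's limiting Ca2+ occupancy (an exact zero), B otherwise.
    """
    if not models or not mutants:
        raise ValueError("models and mutants must be nonempty")
    unknown = [m for m in mutants if m not in MUTANTS]
    if unknown:
        raise ValueError(f"unknown mutants: {unknown}")
    if conc is None:
        conc = Concentrations(cam_tot=0.713, mlck_tot=0.0237)

    index = pd.MultiIndex.from_product(
        [list(mutants), list(REGIMES)], names=["mutant", "regime"]
    )
    calls = pd.DataFrame(index=index, columns=[f"model{m}" for m in models], dtype=object)
    fracs = pd.DataFrame(index=index, columns=calls.columns, dtype=float)
    for model_id in models:
        for mutant in mutants:
            n_fn, c_fn = MUTANTS[mutant]
            variant = ModelVariant(model_id, n_fn, c_fn)
            for regime in REGIMES:
                end = "low" if regime == "zero_ca" else "high"
                f = limit_binding(params, variant, conc, end)
                calls.loc[(mutant, regime), f"model{model_id}"] = (
                    "B" if f > 0.0 else "NB"
                )
                fracs.loc[(mutant, regime), f"model{model_id}"] = f
    return PredictionTable(calls=calls, fractions=fracs)


def detection_call(predicted_fraction: float, detection_limit: float = 0.09) -> str:
    """Would the assay see this predicted fraction?

    Returns "B" iff the fraction exceeds the measured assay sensitivity
    (default 9% of reporter bound).  This quantitative annotation never
    overrides a structural-zero NB — a structural zero is 0.0 and is NB
    under any limit.
    """
    if not 0.0 <= detection_limit <= 1.0:
        raise ValueError("detection_limit must be in [0, 1]")
    return "B" if predicted_fraction > detection_limit else "NB"
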