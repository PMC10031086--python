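"""Parameter-sensitivity analyses for the non-zero-binding predictions.

The qualitative no-binding predictions are structural and hold for any
parameter values; the non-zero predictions are quantitative, so their
robustness is probed by sweeping the apo association constant K9 and the
CaM amount (zero-Ca2+ prediction of Model 1), Monte-Carlo sampling of the
(K4, K6) pair for the Model 2 N-lobe-mutant prediction at 39 uM Ca2+, and
the assay-sensitivity margin calculation at two CaM:reporter ratios.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
import pandas as pd

from camnet.network import (
    Concentrations,
    ModelVariant,
    ParameterSet,
    effective_affinity,
    fraction_bound,
)

__all__ = ["MCResult", "k9_sweep", "monte_carlo_f2n", "f2n_grid_minimum", "ratio_margin"]


def k9_sweep(
    k9_values: Sequence[float],
    cam_values: Sequence[float],
    mlck_tot: float = 0.0237,
) -> pd.DataFrame:
    """Zero-Ca2+ Model 1 fraction bound over a (K9, CaM_tot) grid.

    The fraction increases monotonically with both K9 and the CaM:MLCK
    ratio, which motivates the high-CaM confirmation experiment.
    """
    k9 = np.asarray(k9_values, dtype=float)
    cam = np.asarray(cam_values, dtype=float)
    if np.any(k9 < 0) or np.any(cam < 0) or mlck_tot < 0:
        raise ValueError("all values must be >= 0")
    rows = [
        {
            "k9_per_uM": float(k),
            "cam_tot_uM": float(c),
            "mlck_tot_uM": float(mlck_tot),
            "fraction_bound": fraction_bound(float(k), float(c), mlck_tot),
        }
        for k in k9
        for c in cam
    ]
    return pd.DataFrame(rows)


@dataclass(frozen=True)
class MCResult:
    """Monte-Carlo distribution of a predicted binding fraction."""

    n_draws: int
    interval: tuple[float, float]
    law: str
    seed: int
    minimum: float
    quantiles: dict[float, float]
    histogram: pd.DataFrame  # bin_left, bin_right, count
    draws: pd.DataFrame | None = None  # k4, k6, fraction when retained


def monte_carlo_f2n(
    params: ParameterSet | None = None,
    n_draws: int = 200_000,
    interval: tuple[float, float] = (0.01, 100.0),
    law: str = "log-uniform",
    ca_free: float = 39.0,
    conc: Concentrations | None = None,
    seed: int = 0,
    keep_draws: bool = False,
    n_bins: int = 50,
) -> MCResult:
    """Distribution of the Model 2 N-mutant binding fraction at 39 uM Ca2+.

    K4 (C-lobe-loaded CaM - MLCK association) and K6 (C-lobe Ca2+
    association weight) are each drawn from interval multipliers
    (lo*v, hi*v) around their reference values v, by default log-uniformly
    (the interval spans four orders of magnitude around a scale
    parameter).  The fraction is evaluated at finite ca_free so K6
    participates; deterministic under a fixed seed.
    """
    if n_draws < 1:
        raise ValueError("n_draws must be >= 1")
    if law not in ("log-uniform", "uniform"):
        raise ValueError(f"unknown sampling law: {law!r}")
    params = params or ParameterSet.reference()
    conc = conc or Concentrations(cam_tot=0.713, mlck_tot=0.0237)
    lo, hi = interval
    rng = np.random.default_rng(seed)

    def draw(v: float) -> np.ndarray:
        if lo == hi:
            return np.full(n_draws, lo * v)
        if law == "log-uniform":
            return np.exp(rng.uniform(np.log(lo * v), np.log(hi * v), n_draws))
        return rng.uniform(lo * v, hi * v, n_draws)

    k4 = draw(params.k4)
    k6 = draw(params.k6)
    # Model 2, N-lobe knockout: admissible Ca states are apo (no MLCK) and
    # C-loaded (K4); K_eff = w K4 / (1 + w) with w = K6 * x^h.
    w = k6 * ca_free ** params.hill_exp
    k_eff = w * k4 / (1.0 + w)
    C, M = conc.cam_tot, conc.mlck_tot
    s = k_eff * (C + M)
    d = k_eff * (C - M)
    fractions = 2.0 * k_eff * C / (1.0 + s + np.sqrt(1.0 + 2.0 * s + d * d))

    qs = (0.001, 0.01, 0.05, 0.25, 0.5, 0.75, 0.95, 0.99)
    quantiles = {q: float(np.quantile(fractions, q)) for q in qs}
    counts, edges = np.histogram(fractions, bins=n_bins)
    hist = pd.DataFrame(
        {"bin_left": edges[:-1], "bin_right": edges[1:], "count": counts}
    )
    draws = (
        pd.DataFrame({"k4": k4, "k6": k6, "fraction": fractions})
        if keep_draws
        else None
    )
    return MCResult(
        n_draws=n_draws,
        interval=(float(lo), float(hi)),
        law=law,
        seed=seed,
        minimum=float(fractions.min()),
        quantiles=quantiles,
        histogram=hist,
        draws=draws,
    )


def f2n_grid_minimum(
    params: ParameterSet | None = None,
    interval: tuple[float, float] = (0.01, 100.0),
    n_grid: int = 100,
    ca_free: float = 39.0,
    conc: Concentrations | None = None,
) -> float:
    """Deterministic log-spaced grid-scan minimum of the same quantity.

    Serves as the independent oracle for the Monte-Carlo minimum.
    """
    params = params or ParameterSet.reference()
    conc = conc or Concentrations(cam_tot=0.713, mlck_tot=0.0237)
    lo, hi = interval
    k4 = np.geomspace(lo * params.k4, hi * params.k4, n_grid)
    k6 = np.geomspace(lo * params.k6, hi * params.k6, n_grid)
    best = 1.0
    for k6_val in k6:
        w = k6_val * ca_free ** params.hill_exp
        for k4_val in k4:
            k_eff = w * k4_val / (1.0 + w)
            best = min(best, fraction_bound(k_eff, conc.cam_tot, conc.mlck_tot))
    return best


def ratio_margin(
    params: ParameterSet | None = None,
    mlck_tot: float = 0.0229,
    cam_pair: tuple[float, float] = (0.01145, 0.01374),
    ca_free: float = 39.0,
) -> tuple[float, float, float]:
    """Predicted binding at two CaM amounts and their margin.

    Model 2 (wild type) fraction of reporter bound at each CaM amount and
    the difference in percentage points — the margin the assay must
    resolve in the sensitivity experiment (reporter in excess of CaM).
    """
    if mlck_tot <= 0 or cam_pair[0] <= 0 or cam_pair[1] <= 0:
        raise ValueError("concentrations must be > 0")
    params = params or ParameterSet.reference()
    variant = ModelVariant(2)
    k_eff = effective_affinity(params, variant, ca_free)
    f1 = fraction_bound(k_eff, cam_pair[0], mlck_tot)
    f2 = fraction_bound(k_eff, cam_pair[1], mlck_tot)
    return f1, f2, 100.0 * (f2 - f1)
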