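"""FRET-ratio statistics, on-bead quantification and model falsification.

Observed binding/no-binding calls follow a two-statistic rule: a condition
is called B only when a one-tailed Mann-Whitney U test on the endpoint
emission ratios versus reporter-only baseline *and* one on per-replicate
trapezoid areas under the binding curve are both significant at alpha.
For the zero-Ca2+ regime the endpoint is x = 0 and the area is restricted
to 0 <= x <= 0.038 uM; for the high-Ca2+ regime the endpoint is x = 39 uM
and the area spans the complete curve.
"""

from __future__ import annotations

import logging
import math
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import optimize, stats

from camnet.predictions import PredictionTable, REGIMES
from camnet.synthetic import PlateReaderDataset

__all__ = [
    "RatioSeries",
    "TestResult",
    "DoseResponseFit",
    "DiscriminationReport",
    "compute_ratios",
    "mann_whitney_one_tailed",
    "auc_trapezoid",
    "replicate_aucs",
    "onbead_percent_binding",
    "normalize_onbead",
    "fit_dose_response",
    "observed_calls",
    "classify_models",
    "ZERO_CA_AUC_RANGE",
]

logger = logging.getLogger(__name__)

#: Area range used for the zero-Ca2+ test (uM).
ZERO_CA_AUC_RANGE = (0.0, 0.038)

RatioSeries = pd.DataFrame  # condition, replicate, ca_free_uM, ratio


def compute_ratios(dataset: PlateReaderDataset | pd.DataFrame) -> pd.DataFrame:
    """Emission ratio em480/em535 per well, labels preserved.

    Records with a nonpositive intensity are rejected and logged.
    """
    records = dataset.records if isinstance(dataset, PlateReaderDataset) else dataset
    bad = (records["em480"] <= 0) | (records["em535"] <= 0)
    if bad.any():
        logger.warning("rejecting %d records with nonpositive intensity", bad.sum())
        records = records.loc[~bad]
    out = records[["condition", "replicate", "ca_free_uM"]].copy()
    out["ratio"] = records["em480"].to_numpy() / records["em535"].to_numpy()
    return out.reset_index(drop=True)


@dataclass(frozen=True)
class TestResult:
    """One-tailed Mann-Whitney U outcome."""

    statistic: float
    p_value: float
    n1: int
    n2: int
    direction: str
    method: str


def mann_whitney_one_tailed(
    sample: Sequence[float],
    baseline: Sequence[float],
    direction: str = "greater",
) -> TestResult:
    """One-tailed Mann-Whitney U test of sample versus baseline.

    Uses the exact null distribution when both groups have at most 20
    observations and the pooled data are tie-free; otherwise the normal
    approximation with continuity and tie correction.
    """
    x = np.asarray(sample, dtype=float)
    y = np.asarray(baseline, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both samples must be nonempty")
    if direction not in ("greater", "less"):
        raise ValueError("direction must be 'greater' or 'less'")
    pooled = np.concatenate([x, y])
    has_ties = np.unique(pooled).size < pooled.size
    method = "exact" if (x.size <= 20 and y.size <= 20 and not has_ties) else "asymptotic"
    res = stats.mannwhitneyu(x, y, alternative=direction, method=method)
    return TestResult(
        statistic=float(res.statistic),
        p_value=float(res.pvalue),
        n1=int(x.size),
        n2=int(y.size),
        direction=direction,
        method=method,
    )


def auc_trapezoid(
    x, y: Sequence[float] | None = None, ca_range: tuple[float, float] | None = None
) -> float:
    """Trapezoidal area under y(x) restricted to lo <= x <= hi.

    Accepts either explicit (x, y) arrays or a TitrationCurve.
    """
    if y is None:
        x, y = x.ca_grid, x.fraction_bound
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    order = np.argsort(xa, kind="stable")
    xa, ya = xa[order], ya[order]
    if ca_range is not None:
        lo, hi = ca_range
        if lo > xa[-1] or hi < xa[0]:
            raise ValueError("ca_range lies outside the data span")
        keep = (xa >= lo) & (xa <= hi)
        xa, ya = xa[keep], ya[keep]
    if xa.size < 2:
        raise ValueError("need at least 2 points inside the range")
    return float(np.trapezoid(ya, xa))


def replicate_aucs(
    ratios: pd.DataFrame, ca_range: tuple[float, float] | None = None
) -> pd.Series:
    """Per-replicate trapezoid AUC of the ratio-vs-Ca2+ curve."""
    return ratios.groupby("replicate").apply(
        lambda g: auc_trapezoid(g["ca_free_uM"], g["ratio"], ca_range),
        include_groups=False,
    )


def onbead_percent_binding(
    bound: float, unbound: float, background: float = 0.0
) -> float:
    """Percent CaM bound from background-corrected band intensities.

    % binding = bound / (bound + unbound) after background subtraction,
    clipped to [0, 100].  Returns NaN (flagged) when the corrected total
    signal is nonpositive.
    """
    if bound < 0 or unbound < 0 or background < 0:
        raise ValueError("intensities must be >= 0")
    b = bound - background
    u = unbound - background
    if b + u <= 0:
        logger.warning(
            "onbead_percent_binding undefined: corrected total <= 0 "
            "(bound=%s, unbound=%s, background=%s)", bound, unbound, background
        )
        return float("nan")
    return float(np.clip(100.0 * b / (b + u), 0.0, 100.0))


def normalize_onbead(percent_series: Mapping[float, float]) -> dict[float, float]:
    """Affine rescale so the x=0 entry maps to 0% and the x=39 entry to 100%."""
    if 0.0 not in percent_series or 39.0 not in percent_series:
        raise ValueError("series must contain x=0 and x=39 entries")
    lo = percent_series[0.0]
    hi = percent_series[39.0]
    if hi == lo:
        raise ValueError("degenerate series: value(39) == value(0)")
    return {x: 100.0 * (v - lo) / (hi - lo) for x, v in percent_series.items()}


@dataclass(frozen=True)
class DoseResponseFit:
    """Four-parameter logistic (Hill) dose-response fit on linear x."""

    bottom: float
    top: float
    ec50: float
    hill_slope: float
    residual_norm: float
    converged: bool
    message: str = ""


def _hill4(x, bottom, top, ec50, n):
    x = np.asarray(x, dtype=float)
    with np.errstate(divide="ignore", invalid="ignore"):
        xn = np.where(x > 0, x, 0.0) ** n
        return bottom + (top - bottom) * xn / (ec50 ** n + xn)


def fit_dose_response(x: Sequence[float], y: Sequence[float]) -> DoseResponseFit:
    """Least-squares 4PL fit r(x) = bottom + (top-bottom) x^n / (EC50^n + x^n).

    x = 0 is admissible (the term vanishes).  A flat series, or failure of
    the optimizer, is returned as a flagged (non-converged) fit with
    residual diagnostics rather than raised.
    """
    xa = np.asarray(x, dtype=float)
    ya = np.asarray(y, dtype=float)
    if np.unique(xa).size < 5:
        raise ValueError("need at least 5 distinct x values")
    span = ya.max() - ya.min()
    if span == 0 or span < 1e-12 * max(1.0, abs(ya.mean())):
        return DoseResponseFit(
            bottom=float(ya.mean()), top=float(ya.mean()), ec50=float("nan"),
            hill_slope=float("nan"), residual_norm=0.0, converged=False,
            message="flat series: EC50 unidentifiable",
        )
    pos = xa[xa > 0]
    p0 = [float(ya.min()), float(ya.max()), float(np.median(pos)), 1.0]
    try:
        popt, _ = optimize.curve_fit(
            _hill4, xa, ya, p0=p0,
            bounds=([-np.inf, -np.inf, 1e-12, 0.05], [np.inf, np.inf, np.inf, 20.0]),
            maxfev=20000,
        )
    except (RuntimeError, ValueError) as exc:
        resid = float(np.linalg.norm(ya - _hill4(xa, *p0)))
        return DoseResponseFit(
            bottom=p0[0], top=p0[1], ec50=p0[2], hill_slope=p0[3],
            residual_norm=resid, converged=False, message=str(exc),
        )
    resid = float(np.linalg.norm(ya - _hill4(xa, *popt)))
    return DoseResponseFit(
        bottom=float(popt[0]), top=float(popt[1]), ec50=float(popt[2]),
        hill_slope=float(popt[3]), residual_norm=resid, converged=True,
    )


def _endpoint_values(ratios: pd.DataFrame, x: float) -> np.ndarray:
    sel = ratios.loc[np.isclose(ratios["ca_free_uM"], x), "ratio"]
    return sel.to_numpy()


def observed_calls(
    sample_ratios: Mapping[str, pd.DataFrame],
    baseline_ratios: pd.DataFrame,
    alpha: float = 0.05,
    zero_range: tuple[float, float] = ZERO_CA_AUC_RANGE,
    high_endpoint: float = 39.0,
) -> pd.DataFrame:
    """Experimental B/NB calls per (mutant, regime) from ratio data.

    For each CaM condition and regime, B requires the one-tailed
    Mann-Whitney test versus baseline to be significant at ``alpha`` for
    *both* the endpoint ratios and the per-replicate AUCs.
    """
    rows = []
    base_zero_end = _endpoint_values(baseline_ratios, 0.0)
    base_high_end = _endpoint_values(baseline_ratios, high_endpoint)
    base_zero_auc = replicate_aucs(baseline_ratios, zero_range).to_numpy()
    base_full_auc = replicate_aucs(baseline_ratios, None).to_numpy()
    for mutant, ratios in sample_ratios.items():
        for regime in REGIMES:
            if regime == "zero_ca":
                end_vals = _endpoint_values(ratios, 0.0)
                auc_vals = replicate_aucs(ratios, zero_range).to_numpy()
                base_end, base_auc = base_zero_end, base_zero_auc
            else:
                end_vals = _endpoint_values(ratios, high_endpoint)
                auc_vals = replicate_aucs(ratios, None).to_numpy()
                base_end, base_auc = base_high_end, base_full_auc
            t_end = mann_whitney_one_tailed(end_vals, base_end, "greater")
            t_auc = mann_whitney_one_tailed(auc_vals, base_auc, "greater")
            call = "B" if (t_end.p_value < alpha and t_auc.p_value < alpha) else "NB"
            rows.append(
                {
                    "mutant": mutant,
                    "regime": regime,
                    "call": call,
                    "p_endpoint": t_end.p_value,
                    "p_auc": t_auc.p_value,
                }
            )
    return pd.DataFrame(rows).set_index(["mutant", "regime"])


@dataclass(frozen=True)
class DiscriminationReport:
    """Predicted-versus-observed comparison per model.

    ``comparison`` holds, per (mutant, regime) condition, each model's
    call, the observed call and a falsified flag.  Two falsification
    counts are reported per model:

    * ``n_falsified_rows`` — plain count of mismatching conditions
      (``n_falsified_rows + n_correct`` equals the number of conditions);
    * ``n_falsified`` — distinct falsified *predictions*, where
      conditions carrying an identical prediction (same regime, same call,
      same predicted fraction — e.g. the mutant-independent zero-Ca2+
      claim) count once.
    """

    comparison: pd.DataFrame
    n_falsified: dict[str, int]
    n_falsified_rows: dict[str, int]
    n_correct: dict[str, int]

    @property
    def unfalsified_models(self) -> list[str]:
        return [m for m, k in self.n_falsified_rows.items() if k == 0]

    def summary(self) -> str:
        lines = ["Model discrimination summary"]
        for model in self.n_falsified:
            lines.append(
                f"  {model}: {self.n_falsified[model]} falsified prediction(s) "
                f"({self.n_falsified_rows[model]} condition(s)), "
                f"{self.n_correct[model]} correct condition(s)"
            )
        sole = self.unfalsified_models
        if len(sole) == 1:
            lines.append(f"  unique unfalsified model: {sole[0]}")
        else:
            lines.append(f"  unfalsified models: {sole or 'none'}")
        return "\n".join(lines)


def classify_models(
    observed: pd.DataFrame | Mapping[tuple[str, str], str],
    table: PredictionTable,
) -> DiscriminationReport:
    """Compare observed B/NB calls against each model's prediction table.

    A prediction is falsified when the model says B where NB was observed
    or vice versa.  Both per-condition and distinct-prediction counts are
    reported (see :class:`DiscriminationReport`).
    """
    if isinstance(observed, pd.DataFrame):
        obs = observed["call"]
    else:
        obs = pd.Series(dict(observed))
        obs.index = pd.MultiIndex.from_tuples(obs.index, names=["mutant", "regime"])
    if set(obs.index) != set(table.calls.index):
        raise ValueError("observed and predicted (mutant, regime) index sets differ")
    obs = obs.reindex(table.calls.index)

    comp = table.calls.copy()
    comp["observed"] = obs
    n_falsified, n_rows, n_correct = {}, {}, {}
    for model in table.calls.columns:
        mismatch = comp[model] != comp["observed"]
        n_rows[model] = int(mismatch.sum())
        n_correct[model] = int((~mismatch).sum())
        # distinct falsified predictions: identical (regime, call, fraction)
        # rows are one claim (zero-Ca predictions are mutant-independent)
        seen = set()
        for (mutant, regime), bad in mismatch.items():
            if not bad:
                continue
            frac = table.fractions.loc[(mutant, regime), model]
            seen.add((regime, comp.loc[(mutant, regime), model], round(float(frac), 12)))
        n_falsified[model] = len(seen)
        comp[f"{model}_falsified"] = mismatch
    return DiscriminationReport(
        comparison=comp,
        n_falsified=n_falsified,
        n_falsified_rows=n_rows,
        n_correct=n_correct,
    )
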