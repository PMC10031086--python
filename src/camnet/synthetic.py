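"""Synthetic plate-reader FRET and on-bead densitometry datasets.

The FRET assay mixes a fixed amount of an EYFP-(MLCK CaM-binding
domain)-ECFP reporter with excess CaM across a 14-point free-Ca2+ ladder
(0-39 uM, set by EGTA-buffered calibration solutions) and reads emission
at 480 nm and 535 nm under 430 nm excitation; CaM binding disrupts energy
transfer, raising the Em480/Em535 ratio.  The generator draws per-channel
intensities whose ratio tracks an affine map of the true model-predicted
fraction bound, with multiplicative log-normal channel noise.  Ground
truth is retained for recovery tests.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from camnet.network import (
    Concentrations,
    ModelVariant,
    ParameterSet,
    titration_curve,
)

__all__ = [
    "TitrationLadder",
    "NoiseModel",
    "PlateReaderDataset",
    "OnBeadDataset",
    "default_ladder",
    "simulate_fret",
    "simulate_baseline",
    "simulate_onbead",
]

#: Free-Ca2+ ladder (uM).  The named experimental conditions are 0, 0.038,
#: 0.1, 0.35, 1.35, 3 and 39 uM; the remaining seven points follow the
#: calibration-kit series with approximately geometric spacing.
DEFAULT_LADDER: tuple[float, ...] = (
    0.0, 0.017, 0.038, 0.065, 0.1, 0.15, 0.225, 0.35, 0.6, 1.35, 3.0,
    8.0, 17.0, 39.0,
)

TitrationLadder = tuple  # ordered free-Ca2+ values, uM


def default_ladder() -> tuple[float, ...]:
    """The 14-point free-Ca2+ ladder from 0 to 39 uM."""
    return DEFAULT_LADDER


@dataclass(frozen=True)
class NoiseModel:
    """Per-channel multiplicative noise and reporter-only baselines.

    ``channel_cv`` is the coefficient of variation applied independently
    to each emission channel (log-normal, so intensities stay positive);
    ``baseline_480``/``baseline_535`` are the mean reporter-only well
    intensities in arbitrary units.
    """

    channel_cv: float = 0.02
    baseline_480: float = 500.0
    baseline_535: float = 1000.0

    def __post_init__(self) -> None:
        if self.channel_cv < 0:
            raise ValueError("channel_cv must be >= 0")
        if self.baseline_480 <= 0 or self.baseline_535 <= 0:
            raise ValueError("baseline intensities must be > 0")


@dataclass(frozen=True)
class PlateReaderDataset:
    """Per-well Em480/Em535 intensities with condition/replicate labels.

    ``records`` has columns condition, replicate, ca_free_uM, em480, em535.
    ``true_fractions`` maps each ladder point to the model-true fraction
    bound (ground truth for recovery tests); ``ratio_map`` is the
    (r0, delta_r) affine map used.
    """

    records: pd.DataFrame
    true_fractions: dict[float, float]
    ratio_map: tuple[float, float]
    condition: str
    variant: ModelVariant | None = None
    params: ParameterSet | None = None
    seed: int | None = None


@dataclass(frozen=True)
class OnBeadDataset:
    """Simulated bound/unbound band intensities per ladder point."""

    records: pd.DataFrame  # ca_free_uM, bound_intensity, unbound_intensity, background
    true_fractions: dict[float, float]
    seed: int | None = None


def _channel_noise(rng: np.random.Generator, cv: float, size: int) -> np.ndarray:
    if cv == 0.0:
        return np.ones(size)
    # log-normal multiplicative factor with unit mean and sd ~= cv
    sigma = np.sqrt(np.log1p(cv * cv))
    return rng.lognormal(mean=-0.5 * sigma * sigma, sigma=sigma, size=size)


def simulate_fret(
    params: ParameterSet,
    variant: ModelVariant,
    conc: Concentrations,
    ladder: Sequence[float] = DEFAULT_LADDER,
    n_replicates: int = 15,
    ratio_map: tuple[float, float] = (0.5, 0.5),
    noise: NoiseModel | None = None,
    seed: int = 0,
    condition: str = "sample",
) -> PlateReaderDataset:
    """Simulate a plate-reader FRET titration for one CaM variant.

    The true fraction bound F(x) comes from the equilibrium network; the
    expected emission ratio is r(x) = r0 + delta_r * F(x) (the assay's
    ratio need not map 1:1 onto fraction bound, so the affine map is
    explicit).  Channel intensities are drawn so the em480/em535 ratio has
    mean r(x) up to O(cv^2); the same seed reproduces the dataset exactly.
    """
    if n_replicates < 1:
        raise ValueError("n_replicates must be >= 1")
    noise = noise or NoiseModel()
    r0, delta_r = ratio_map
    curve = titration_curve(params, variant, conc.cam_tot, conc.mlck_tot, ladder)
    true_f = dict(zip(curve.ca_grid, curve.fraction_bound))
    rng = np.random.default_rng(seed)

    rows = []
    for x in curve.ca_grid:
        r = r0 + delta_r * true_f[x]
        em535 = noise.baseline_535 * _channel_noise(rng, noise.channel_cv, n_replicates)
        em480 = (
            r * noise.baseline_535
            * _channel_noise(rng, noise.channel_cv, n_replicates)
        )
        for rep in range(n_replicates):
            rows.append(
                {
                    "condition": condition,
                    "replicate": rep + 1,
                    "ca_free_uM": x,
                    "em480": em480[rep],
                    "em535": em535[rep],
                }
            )
    return PlateReaderDataset(
        records=pd.DataFrame(rows),
        true_fractions=true_f,
        ratio_map=ratio_map,
        condition=condition,
        variant=variant,
        params=params,
        seed=seed,
    )


def simulate_baseline(
    ladder: Sequence[float] = DEFAULT_LADDER,
    n_replicates: int = 13,
    ratio_map: tuple[float, float] = (0.5, 0.5),
    noise: NoiseModel | None = None,
    seed: int = 0,
) -> PlateReaderDataset:
    """Reporter-only wells: true fraction bound is zero at every ladder point."""
    noise = noise or NoiseModel()
    r0, delta_r = ratio_map
    rng = np.random.default_rng(seed)
    rows = []
    for x in ladder:
        em535 = noise.baseline_535 * _channel_noise(rng, noise.channel_cv, n_replicates)
        em480 = (
            r0 * noise.baseline_535
            * _channel_noise(rng, noise.channel_cv, n_replicates)
        )
        for rep in range(n_replicates):
            rows.append(
                {
                    "condition": "baseline",
                    "replicate": rep + 1,
                    "ca_free_uM": float(x),
                    "em480": em480[rep],
                    "em535": em535[rep],
                }
            )
    return PlateReaderDataset(
        records=pd.DataFrame(rows),
        true_fractions={float(x): 0.0 for x in ladder},
        ratio_map=ratio_map,
        condition="baseline",
        seed=seed,
    )


def simulate_onbead(
    true_fractions: Sequence[float],
    ladder: Sequence[float] = DEFAULT_LADDER,
    intensity_scale: float = 1000.0,
    background: float = 50.0,
    noise_cv: float = 0.0,
    seed: int = 0,
) -> OnBeadDataset:
    """Simulate on-bead pulldown band densitometry.

    The bound band carries intensity proportional to F, the unbound band
    to 1-F, each on top of a constant background; background-corrected
    bound/(bound+unbound) recovers F in expectation.
    """
    fr = np.asarray(true_fractions, dtype=float)
    lad = np.asarray(ladder, dtype=float)[: fr.size]
    if fr.size != lad.size:
        raise ValueError("true_fractions and ladder lengths differ")
    if np.any((fr < 0) | (fr > 1)):
        raise ValueError("fractions must be in [0, 1]")
    rng = np.random.default_rng(seed)
    bound = background + intensity_scale * fr * _channel_noise(rng, noise_cv, fr.size)
    unbound = background + intensity_scale * (1 - fr) * _channel_noise(
        rng, noise_cv, fr.size
    )
    records = pd.DataFrame(
        {
            "ca_free_uM": lad,
            "bound_intensity": bound,
            "unbound_intensity": unbound,
            "background": background,
        }
    )
    return OnBeadDataset(
        records=records,
        true_fractions=dict(zip(lad.tolist(), fr.tolist())),
        seed=seed,
    )
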