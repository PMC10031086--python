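"""Run configuration, CSV I/O and the end-to-end discrimination pipeline.

The run configuration is a YAML file with explicit units in key names
(``K9_per_uM``, ``cam_tot_uM`` ...).  Unknown keys are rejected so typos
cannot silently fall back to defaults.  All randomness flows from the
config seed; outputs carry a provenance header (config hash, seed,
package version).
"""

from __future__ import annotations

import hashlib
import io
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path
from typing import Mapping

import pandas as pd
import yaml

from camnet.discrimination import (
    DiscriminationReport,
    classify_models,
    compute_ratios,
    observed_calls,
)
from camnet.network import Concentrations, MUTANTS, ModelVariant, ParameterSet, titration_curve
from camnet.predictions import predict_table
from camnet.synthetic import (
    DEFAULT_LADDER,
    NoiseModel,
    PlateReaderDataset,
    simulate_baseline,
    simulate_fret,
)

__all__ = ["RunConfig", "read_plate_csv", "write_plate_csv", "run_pipeline"]

logger = logging.getLogger(__name__)

PLATE_COLUMNS = ["condition", "replicate", "ca_free_uM", "em480", "em535"]

#: Replicate counts of the main experiment per condition.
DEFAULT_REPLICATES = {"WT": 15, "Nmut": 16, "Cmut": 8, "quad": 3, "baseline": 13}


@dataclass
class RunConfig:
    """Validated run configuration for the discrimination pipeline."""

    K9_per_uM: float = 0.078
    K4_per_uM: float = 16.7
    K2_per_uM: float = 1000.0
    ca_assoc_N_per_uMh: float = 0.01
    ca_assoc_C_per_uMh: float = 0.25
    hill_exp: int = 2
    cam_tot_uM: float = 0.713
    mlck_tot_uM: float = 0.0237
    true_model: int = 2
    models: tuple[int, ...] = (1, 2, 3)
    # simulated conditions; classification runs on table_mutants only
    mutants: tuple[str, ...] = ("WT", "Nmut", "Cmut", "quad")
    table_mutants: tuple[str, ...] = ("WT", "Nmut", "Cmut")
    ladder_uM: tuple[float, ...] = DEFAULT_LADDER
    replicates: dict = field(default_factory=lambda: dict(DEFAULT_REPLICATES))
    channel_cv: float = 0.02
    ratio_r0: float = 0.5
    ratio_delta_r: float = 0.5
    alpha: float = 0.05
    seed: int = 0
    data_path: str | None = None
    out_dir: str | None = None

    def __post_init__(self) -> None:
        if self.true_model not in (1, 2, 3):
            raise ValueError("true_model must be 1, 2 or 3")
        unknown = [m for m in self.mutants if m not in MUTANTS]
        if unknown:
            raise ValueError(f"unknown mutants: {unknown}")
        extra = [m for m in self.table_mutants if m not in self.mutants]
        if extra:
            raise ValueError(f"table_mutants not among simulated mutants: {extra}")
        if not 0 < self.alpha < 1:
            raise ValueError("alpha must be in (0, 1)")
        if self.channel_cv < 0:
            raise ValueError("channel_cv must be >= 0")
        lad = list(self.ladder_uM)
        if sorted(lad) != lad or any(v < 0 for v in lad):
            raise ValueError("ladder_uM must be nonnegative and ascending")
        for key in ("K9_per_uM", "K4_per_uM", "K2_per_uM", "cam_tot_uM", "mlck_tot_uM"):
            if getattr(self, key) < 0:
                raise ValueError(f"{key} must be >= 0")

    @classmethod
    def from_yaml(cls, path: str | Path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        valid = set(cls.__dataclass_fields__)
        unknown = set(raw) - valid
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        for tup_key in ("models", "mutants", "table_mutants", "ladder_uM"):
            if tup_key in raw:
                raw[tup_key] = tuple(raw[tup_key])
        return cls(**raw)

    def to_yaml(self, path: str | Path) -> None:
        data = asdict(self)
        for tup_key in ("models", "mutants", "table_mutants", "ladder_uM"):
            data[tup_key] = list(data[tup_key])
        Path(path).write_text(yaml.safe_dump(data, sort_keys=False))

    def parameter_set(self) -> ParameterSet:
        return ParameterSet(
            ca_assoc_N=self.ca_assoc_N_per_uMh,
            ca_assoc_C=self.ca_assoc_C_per_uMh,
            hill_exp=self.hill_exp,
            mlck_assoc={
                (False, False): self.K9_per_uM,
                (False, True): self.K4_per_uM,
                (True, False): self.K4_per_uM,
                (True, True): self.K2_per_uM,
            },
        )

    def concentrations(self) -> Concentrations:
        return Concentrations(self.cam_tot_uM, self.mlck_tot_uM)

    def digest(self) -> str:
        payload = yaml.safe_dump(asdict(self), sort_keys=True, default_flow_style=True)
        return hashlib.sha256(payload.encode()).hexdigest()[:12]


def _provenance(config: RunConfig) -> str:
    from camnet import __version__

    return (
        f"# camnet v{__version__} config_hash={config.digest()} seed={config.seed}\n"
    )


def write_plate_csv(
    dataset: PlateReaderDataset, path: str | Path, config: RunConfig | None = None
) -> None:
    """Write per-well records as CSV, with a provenance comment header."""
    path = Path(path)
    with path.open("w") as fh:
        if config is not None:
            fh.write(_provenance(config))
        dataset.records.to_csv(fh, index=False)


def read_plate_csv(path: str | Path) -> PlateReaderDataset:
    """Read and validate a plate CSV; malformed rows are dropped and logged.

    The header must contain condition, replicate, ca_free_uM, em480,
    em535.  Rows with nonnumeric or missing numeric fields are reported
    with their line numbers.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise ValueError(f"{path}: empty file")
    df = pd.read_csv(io.StringIO(text), comment="#", dtype=str)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing columns {missing}")
    numeric = ["replicate", "ca_free_uM", "em480", "em535"]
    converted = df[numeric].apply(pd.to_numeric, errors="coerce")
    bad = converted.isna().any(axis=1) | df["condition"].isna()
    if bad.any():
        for idx in df.index[bad]:
            logger.warning("%s: rejecting malformed row at data line %d", path, idx + 2)
    out = df.loc[~bad, ["condition"]].copy()
    out[numeric] = converted.loc[~bad]
    out["replicate"] = out["replicate"].astype(int)
    records = out.reset_index(drop=True)
    true_f = {float(x): float("nan") for x in records["ca_free_uM"].unique()}
    return PlateReaderDataset(
        records=records,
        true_fractions=true_f,
        ratio_map=(float("nan"), float("nan")),
        condition="ingested",
    )


def _simulate_all(config: RunConfig) -> dict[str, PlateReaderDataset]:
    params = config.parameter_set()
    conc = config.concentrations()
    noise = NoiseModel(channel_cv=config.channel_cv)
    datasets: dict[str, PlateReaderDataset] = {}
    for i, mutant in enumerate(config.mutants):
        n_fn, c_fn = MUTANTS[mutant]
        variant = ModelVariant(config.true_model, n_fn, c_fn)
        datasets[mutant] = simulate_fret(
            params,
            variant,
            conc,
            ladder=config.ladder_uM,
            n_replicates=config.replicates.get(mutant, 15),
            ratio_map=(config.ratio_r0, config.ratio_delta_r),
            noise=noise,
            seed=config.seed * 1000 + i,
            condition=mutant,
        )
    datasets["baseline"] = simulate_baseline(
        ladder=config.ladder_uM,
        n_replicates=config.replicates.get("baseline", 13),
        ratio_map=(config.ratio_r0, config.ratio_delta_r),
        noise=noise,
        seed=config.seed * 1000 + 999,
    )
    return datasets


def run_pipeline(config: RunConfig) -> DiscriminationReport:
    """Simulate (or ingest) -> ratios -> rank tests -> model classification.

    Fully seed-deterministic.  When ``config.out_dir`` is set, the
    predicted curves, prediction table, observed calls, comparison table
    and a human-readable summary are written there with provenance
    headers.
    """
    params = config.parameter_set()
    conc = config.concentrations()

    if config.data_path is not None:
        ingested = read_plate_csv(config.data_path)
        datasets: dict[str, PlateReaderDataset] = {}
        for condition, group in ingested.records.groupby("condition"):
            datasets[condition] = PlateReaderDataset(
                records=group.reset_index(drop=True),
                true_fractions={},
                ratio_map=ingested.ratio_map,
                condition=str(condition),
            )
        if "baseline" not in datasets:
            raise ValueError("ingested data must include a 'baseline' condition")
    else:
        datasets = _simulate_all(config)

    baseline_ratios = compute_ratios(datasets.pop("baseline"))
    sample_ratios = {name: compute_ratios(ds) for name, ds in datasets.items()}
    calls = observed_calls(sample_ratios, baseline_ratios, alpha=config.alpha)
    table_mutants = [m for m in config.table_mutants if m in sample_ratios] or list(
        sample_ratios
    )
    table = predict_table(params, config.models, table_mutants, conc)
    report = classify_models(
        calls.loc[calls.index.get_level_values("mutant").isin(table_mutants)], table
    )

    if config.out_dir is not None:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        header = _provenance(config)
        curves = []
        for mutant in config.mutants:
            n_fn, c_fn = MUTANTS[mutant]
            for model_id in config.models:
                curve = titration_curve(
                    params,
                    ModelVariant(model_id, n_fn, c_fn),
                    conc.cam_tot,
                    conc.mlck_tot,
                    config.ladder_uM,
                )
                curves.append(curve.to_frame(mutant_label=mutant))
        for name, frame in (
            ("curves.csv", pd.concat(curves, ignore_index=True)),
            ("prediction_table.csv", table.to_frame().reset_index()),
            ("observed_calls.csv", calls.reset_index()),
            ("comparison.csv", report.comparison.reset_index()),
        ):
            with (out / name).open("w") as fh:
                fh.write(header)
                frame.to_csv(fh, index=False)
        (out / "summary.txt").write_text(header + report.summary() + "\n")
    return report
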