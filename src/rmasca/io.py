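"""File formats, pipeline configuration, and the end-to-end run.

Datasets are exchanged as plain CSV in two dialects: wide (one column per
panel variable) and long (``variable``/``value`` columns). The pipeline run
writes univariate screen results, RM-ASCA+ scores/loadings with bootstrap
envelopes, and a JSON manifest recording the configuration and library
versions, so a run is reproducible from its output directory alone.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .asca import RMASCA
from .bootstrap import bootstrap_cis
from .data import LongitudinalDataset, META_COLUMNS
from .design import GroupFactor, VISITS
from .lmm import run_univariate_screen
from .schema import VariableRegistry, build_lipoprotein_registry, build_metabolite_registry
from .simulate import SimulationConfig, simulate_cohort

__all__ = ["PipelineConfig", "read_long_csv", "run_pipeline", "registry_by_name"]

logger = logging.getLogger(__name__)

#: Synonyms accepted for visit labels in input files.
_VISIT_SYNONYMS = {
    "t1": "T1", "t2": "T2", "t3": "T3", "t4": "T4", "t5": "T5",
    "baseline": "T1", "pre-rt": "T1", "post-rt": "T2",
    "3m": "T3", "6m": "T4", "12m": "T5",
}


def registry_by_name(name: str) -> VariableRegistry:
    if name == "lipoprotein":
        return build_lipoprotein_registry()
    if name == "metabolite":
        return build_metabolite_registry()
    raise ValueError(f"unknown registry {name!r}; use 'lipoprotein' or 'metabolite'")


def read_long_csv(path: str | Path, registry: VariableRegistry) -> LongitudinalDataset:
    """Read a dataset CSV in either the wide or the long dialect.

    The dialect is detected from the header: a ``variable``/``value`` pair
    means long form. Visit labels are normalised to T1-T5; unknown variable
    columns are reported and ignored.
    """
    frame = pd.read_csv(path)
    missing_meta = [c for c in ("patient_id", "visit", "group") if c not in frame.columns]
    if missing_meta:
        raise ValueError(f"{path}: missing required columns {missing_meta}")
    if "survival" not in frame.columns:
        frame["survival"] = "survivor"
    frame["visit"] = [
        _VISIT_SYNONYMS.get(str(v).strip().lower(), str(v).strip()) for v in frame["visit"]
    ]
    bad = sorted(set(frame["visit"]) - set(VISITS))
    if bad:
        raise ValueError(f"{path}: unknown visit labels {bad}")
    if {"variable", "value"}.issubset(frame.columns):
        unknown = sorted(set(frame["variable"]) - set(registry.names))
        if unknown:
            logger.warning("%s: ignoring %d unknown variables (e.g. %s)", path, len(unknown), unknown[:3])
            frame = frame[~frame["variable"].isin(unknown)]
        dup = frame.duplicated(subset=["patient_id", "visit", "variable"])
        if dup.any():
            offenders = frame.loc[dup, ["patient_id", "visit"]].drop_duplicates().values.tolist()
            raise ValueError(f"{path}: duplicate (patient, visit) records: {offenders[:5]}")
        wide = frame.pivot(index=["patient_id", "visit", "group", "survival"],
                           columns="variable", values="value").reset_index()
        wide.columns.name = None
        frame = wide
    else:
        unknown = [c for c in frame.columns if c not in META_COLUMNS + registry.names]
        if unknown:
            logger.warning("%s: ignoring unknown columns %s", path, unknown[:5])
            frame = frame.drop(columns=unknown)
    return LongitudinalDataset(registry, frame)


@dataclass
class PipelineConfig:
    """Everything needed for one reproducible pipeline run."""

    registry: str = "lipoprotein"
    input_csv: str | None = None  # None -> simulate a cohort
    n_patients: int = 250
    factor_name: str = "group"
    factor_levels: tuple[str, ...] = ("Gr1", "Gr2", "Gr3", "Gr4", "Gr5")
    coding: str = "sum"
    reference_level: str | None = None
    combination: str = "time + group + time:group"
    univariate_family: str = "time"
    scale: bool = True
    n_components: int = 2
    n_boot: int = 1000
    seed: int = 0
    output_dir: str = "rmasca_out"

    def factor(self) -> GroupFactor:
        return GroupFactor(
            name=self.factor_name, levels=tuple(self.factor_levels),
            coding=self.coding, reference_level=self.reference_level,
        )

    @classmethod
    def from_yaml(cls, path: str | Path) -> "PipelineConfig":
        payload = yaml.safe_load(Path(path).read_text()) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(payload) - known
        if unknown:
            raise ValueError(f"{path}: unknown config keys {sorted(unknown)}")
        if "factor_levels" in payload:
            payload["factor_levels"] = tuple(payload["factor_levels"])
        return cls(**payload)

    def validate(self) -> None:
        registry_by_name(self.registry)
        self.factor()  # raises on bad coding/levels
        if self.n_boot < 2:
            raise ValueError("n_boot must be >= 2")
        if self.n_components < 1:
            raise ValueError("n_components must be >= 1")


def _float_fmt(x: float) -> str:
    return f"{x:.10g}"


def run_pipeline(config: PipelineConfig) -> dict[str, Path]:
    """Simulate-or-load, screen, decompose, bootstrap, and write outputs."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    registry = registry_by_name(config.registry)
    factor = config.factor()

    if config.input_csv is not None:
        logger.info("stage load: %s", config.input_csv)
        dataset = read_long_csv(config.input_csv, registry)
    else:
        logger.info("stage simulate: %d patients", config.n_patients)
        sim = SimulationConfig(
            registry=registry, n_patients=config.n_patients,
            group_names=tuple(config.factor_levels), seed=config.seed,
        )
        dataset = simulate_cohort(sim)
    paths: dict[str, Path] = {}
    paths["dataset"] = out / "dataset_wide.csv"
    dataset.write_csv(paths["dataset"], dialect="wide")

    logger.info("stage univariate: family %s", config.univariate_family)
    screen = run_univariate_screen(dataset, factor, family=config.univariate_family)
    paths["univariate"] = out / "univariate.tsv"
    screen.to_csv(paths["univariate"], sep="\t", index=False, float_format="%.10g")

    logger.info("stage rm-asca: %s", config.combination)
    results = RMASCA(
        dataset, factor, effects=config.combination,
        scale=config.scale, n_components=config.n_components,
    ).fit()

    logger.info("stage bootstrap: %d replicates", config.n_boot)
    envelope = bootstrap_cis(
        dataset, factor, combination=config.combination,
        n_boot=config.n_boot, seed=config.seed,
        scale=config.scale, n_components=config.n_components, point=results,
    )
    paths["scores"] = out / "scores.tsv"
    envelope.scores_frame().to_csv(paths["scores"], sep="\t", index=False, float_format="%.10g")
    paths["loadings"] = out / "loadings.tsv"
    envelope.loadings_frame().to_csv(paths["loadings"], sep="\t", index=False, float_format="%.10g")

    manifest = {
        "config": dataclasses.asdict(config),
        "rmasca_version": __version__,
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "n_patients": dataset.n_patients,
        "n_observations": dataset.n_observations,
        "explained_variance_ratio": [float(r) for r in results.explained_variance_ratio],
        "bootstrap_failures": envelope.n_failed,
    }
    paths["manifest"] = out / "manifest.json"
    paths["manifest"].write_text(json.dumps(manifest, indent=2))
    logger.info("pipeline complete: %s", out)
    return paths
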