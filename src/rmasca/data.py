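"""Long-format longitudinal dataset container.

A :class:`LongitudinalDataset` holds one row per (patient, visit) with the
patient's group and survival labels and a numeric vector over a registry's
variables. Internally the data live in a wide pandas DataFrame whose variable
columns follow registry order exactly.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd

from .design import VISITS
from .schema import VariableRegistry

__all__ = ["LongitudinalDataset", "META_COLUMNS"]

#: Metadata columns preceding the variable block in wide form.
META_COLUMNS = ["patient_id", "visit", "group", "survival"]


@dataclass
class LongitudinalDataset:
    """Observations over a variable registry.

    Invariants enforced at construction: at most one record per
    (patient, visit); group and survival labels constant within patient;
    every patient contributes at least one visit; visit labels canonical.
    """

    registry: VariableRegistry
    frame: pd.DataFrame

    def __post_init__(self) -> None:
        missing = [c for c in META_COLUMNS if c not in self.frame.columns]
        if missing:
            raise ValueError(f"dataset frame lacks columns {missing}")
        missing_vars = [n for n in self.registry.names if n not in self.frame.columns]
        if missing_vars:
            raise ValueError(
                f"dataset frame lacks {len(missing_vars)} registry variables "
                f"(first: {missing_vars[:3]})"
            )
        bad_visits = sorted(set(self.frame["visit"]) - set(VISITS))
        if bad_visits:
            raise ValueError(f"unknown visit labels: {bad_visits}")
        dup = self.frame.duplicated(subset=["patient_id", "visit"])
        if dup.any():
            offenders = self.frame.loc[dup, ["patient_id", "visit"]].values.tolist()
            raise ValueError(f"duplicate (patient, visit) records: {offenders[:5]}")
        for label in ("group", "survival"):
            nuniq = self.frame.groupby("patient_id", sort=False)[label].nunique()
            bad = nuniq[nuniq > 1]
            if len(bad):
                raise ValueError(
                    f"{label} label not constant within patient(s): {list(bad.index[:5])}"
                )
        # Canonical ordering and column layout.
        cols = META_COLUMNS + self.registry.names
        frame = self.frame[cols].copy()
        frame["visit"] = pd.Categorical(frame["visit"], categories=VISITS, ordered=True)
        frame = frame.sort_values(["patient_id", "visit"], kind="stable").reset_index(drop=True)
        frame["visit"] = frame["visit"].astype(str)
        object.__setattr__(self, "frame", frame)

    # -- accessors ---------------------------------------------------------

    @property
    def values(self) -> np.ndarray:
        """Observation matrix, rows aligned to ``frame``, columns to registry."""
        return self.frame[self.registry.names].to_numpy(dtype=float)

    @property
    def patients(self) -> list:
        return list(pd.unique(self.frame["patient_id"]))

    @property
    def n_patients(self) -> int:
        return self.frame["patient_id"].nunique()

    @property
    def n_observations(self) -> int:
        return len(self.frame)

    def visit_counts(self) -> pd.Series:
        return self.frame["visit"].value_counts().reindex(list(VISITS), fill_value=0)

    def patient_table(self) -> pd.DataFrame:
        """One row per patient with group and survival labels."""
        return (
            self.frame.groupby("patient_id", sort=False)[["group", "survival"]]
            .first()
            .reset_index()
        )

    def with_values(self, values: np.ndarray) -> "LongitudinalDataset":
        """Copy of the dataset with the variable block replaced."""
        frame = self.frame.copy()
        frame[self.registry.names] = np.asarray(values, dtype=float)
        return LongitudinalDataset(self.registry, frame)

    def subset_patients(self, patient_ids) -> "LongitudinalDataset":
        keep = self.frame["patient_id"].isin(set(patient_ids))
        return LongitudinalDataset(self.registry, self.frame[keep].copy())

    # -- serialisation -----------------------------------------------------

    def to_wide_frame(self) -> pd.DataFrame:
        return self.frame.copy()

    def to_long_frame(self) -> pd.DataFrame:
        return self.frame.melt(
            id_vars=META_COLUMNS, value_vars=self.registry.names,
            var_name="variable", value_name="value",
        )

    def write_csv(self, path: str | Path, dialect: str = "wide") -> None:
        if dialect == "wide":
            self.to_wide_frame().to_csv(path, index=False)
        elif dialect == "long":
            self.to_long_frame().to_csv(path, index=False)
        else:
            raise ValueError(f"unknown dialect {dialect!r}; use 'wide' or 'long'")
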