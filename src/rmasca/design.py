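"""Study design: visit labels, group factors, and fixed-effect design matrices.

The study has five visits (T1 = pre-radiotherapy baseline, T2 = end of
radiotherapy, T3/T4/T5 = 3, 6 and 12 months after). Time is always reference
coded to T1. The single grouping factor (treatment group, radiation extent,
or survival status) may be sum coded — to detect groups deviating from the
average trajectory — or reference coded against a stated reference level.
The fixed-effect design is intercept + time + group + time:group.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

__all__ = [
    "VISITS",
    "GroupFactor",
    "DesignMatrix",
    "encode_time",
    "encode_group",
    "build_design_matrix",
    "cell_grid",
]

#: Canonical visit labels, in temporal order; T1 is the reference level.
VISITS = ("T1", "T2", "T3", "T4", "T5")


def encode_time(visit: str) -> np.ndarray:
    """Reference-coded indicator vector for T2..T5; T1 maps to zeros."""
    if visit not in VISITS:
        raise ValueError(f"unknown visit label {visit!r}; expected one of {VISITS}")
    vec = np.zeros(len(VISITS) - 1)
    idx = VISITS.index(visit)
    if idx > 0:
        vec[idx - 1] = 1.0
    return vec


@dataclass(frozen=True)
class GroupFactor:
    """A categorical between-patient factor with its contrast coding.

    ``coding`` is ``"sum"`` (deviation from the grand mean; the last level is
    the dropped one and codes as -1 everywhere) or ``"reference"`` (indicator
    contrasts against ``reference_level``).
    """

    name: str
    levels: tuple[str, ...]
    coding: str = "sum"
    reference_level: str | None = None

    def __post_init__(self) -> None:
        if len(self.levels) < 2:
            raise ValueError("a group factor needs at least 2 levels")
        if len(set(self.levels)) != len(self.levels):
            raise ValueError("group levels must be unique")
        if self.coding not in ("sum", "reference"):
            raise ValueError(f"unknown coding {self.coding!r}")
        if self.coding == "reference":
            if self.reference_level is None:
                object.__setattr__(self, "reference_level", self.levels[0])
            if self.reference_level not in self.levels:
                raise ValueError(
                    f"reference level {self.reference_level!r} not among levels {self.levels}"
                )

    @property
    def n_levels(self) -> int:
        return len(self.levels)

    @property
    def coded_levels(self) -> tuple[str, ...]:
        """Levels that get their own design column (one is always dropped)."""
        if self.coding == "sum":
            return self.levels[:-1]
        return tuple(l for l in self.levels if l != self.reference_level)


def encode_group(level: str, factor: GroupFactor) -> np.ndarray:
    """Contrast vector (length levels-1) for one observation's group level."""
    if level not in factor.levels:
        raise ValueError(
            f"unknown level {level!r} for factor {factor.name!r}; levels are {factor.levels}"
        )
    coded = factor.coded_levels
    vec = np.zeros(len(coded))
    if factor.coding == "sum" and level == factor.levels[-1]:
        vec[:] = -1.0
    elif level in coded:
        vec[coded.index(level)] = 1.0
    return vec


@dataclass
class DesignMatrix:
    """Fixed-effect design with named column blocks.

    Blocks are ``intercept``, ``time``, ``group`` and ``time:group``; the
    interaction columns are elementwise products of the time and group
    columns. ``blocks`` maps a block name to integer column indices.
    """

    X: np.ndarray
    columns: list[str]
    blocks: dict[str, np.ndarray]
    factor: GroupFactor

    @property
    def n_columns(self) -> int:
        return self.X.shape[1]

    def block_columns(self, *names: str) -> np.ndarray:
        """Concatenated column indices of the named blocks, in design order."""
        idx = np.concatenate([self.blocks[n] for n in names])
        return np.sort(idx)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.X, columns=self.columns)


def _design_row(visit: str, level: str, factor: GroupFactor) -> np.ndarray:
    t = encode_time(visit)
    g = encode_group(level, factor)
    return np.concatenate([[1.0], t, g, np.outer(t, g).ravel()])


def _column_names(factor: GroupFactor) -> tuple[list[str], dict[str, np.ndarray]]:
    time_names = [f"time[{v}]" for v in VISITS[1:]]
    group_names = [f"{factor.name}[{l}]" for l in factor.coded_levels]
    inter_names = [f"time[{v}]:{factor.name}[{l}]" for v in VISITS[1:] for l in factor.coded_levels]
    names = ["Intercept"] + time_names + group_names + inter_names
    nt, ng = len(time_names), len(group_names)
    blocks = {
        "intercept": np.array([0]),
        "time": np.arange(1, 1 + nt),
        "group": np.arange(1 + nt, 1 + nt + ng),
        "time:group": np.arange(1 + nt + ng, 1 + nt + ng + nt * ng),
    }
    return names, blocks


def build_design_matrix(observations: pd.DataFrame, factor: GroupFactor) -> DesignMatrix:
    """Design matrix for long-format observations.

    ``observations`` needs columns ``patient_id``, ``visit`` and a column
    named after ``factor.name`` (or ``group``). The group label must be
    constant within each patient.
    """
    group_col = factor.name if factor.name in observations.columns else "group"
    if group_col not in observations.columns:
        raise ValueError(f"observations lack a {factor.name!r} or 'group' column")
    per_patient = observations.groupby("patient_id", sort=False)[group_col].nunique()
    bad = per_patient[per_patient > 1]
    if len(bad):
        raise ValueError(
            f"group label not constant within patient(s): {list(bad.index[:5])}"
        )
    names, blocks = _column_names(factor)
    rows = np.empty((len(observations), len(names)))
    # Vectorised assembly: encode the unique (visit, level) pairs once.
    pairs = list(zip(observations["visit"], observations[group_col]))
    unique_pairs = sorted(set(pairs))
    lookup = {p: _design_row(p[0], p[1], factor) for p in unique_pairs}
    for i, p in enumerate(pairs):
        rows[i] = lookup[p]
    return DesignMatrix(X=rows, columns=names, blocks=blocks, factor=factor)


def cell_grid(factor: GroupFactor) -> tuple[pd.DataFrame, np.ndarray]:
    """Full visit x group-level grid and its design rows.

    Returns the grid as a DataFrame with ``visit`` and ``level`` columns
    (visit-major order) and the matching design-row matrix. The full cross is
    always materialised, even for cells unobserved in a particular dataset,
    so score trajectories always span T1-T5 for every group.
    """
    records = [(v, l) for v in VISITS for l in factor.levels]
    grid = pd.DataFrame(records, columns=["visit", "level"])
    X = np.vstack([_design_row(v, l, factor) for v, l in records])
    return grid, X
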