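"""RM-ASCA+: effect-matrix decomposition of longitudinal panels with PCA.

The multivariate response is decomposed according to the per-variable
random-intercept LMM: the fitted fixed-effect linear predictor is split into
additive effect matrices (time, group, time:group) evaluated on the full
visit x group design-cell grid. Effect matrices can be analysed alone or
combined ('group + time:group' shows baseline differences plus their
development; 'time + group + time:group' shows every group's trajectory).
Each (combined) effect matrix is summarised by PCA: loadings over variables
and score trajectories over design cells.

For unbalanced data the PCA weights each design cell by its observation
count, which makes it equivalent to PCA of the per-observation effect
matrix. A deterministic sign convention (largest-magnitude loading entry
positive) fixes the PCA axes across runs and bootstrap replicates.

The public surface follows the Model/Results idiom: build an
:class:`RMASCA` model from a dataset, call :meth:`RMASCA.fit`, and work with
the returned :class:`RMASCAResults` (summary tables, bootstrap CIs, plots).
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .data import LongitudinalDataset
from .design import DesignMatrix, GroupFactor, build_design_matrix, cell_grid
from .lmm import LMMFit, RandomInterceptModel

__all__ = [
    "EFFECT_NAMES",
    "EffectMatrix",
    "ScoresLoadings",
    "RMASCA",
    "RMASCAResults",
    "center_and_scale",
    "construct_effect_matrix",
    "combine_effect_matrices",
    "pca_on_effect",
    "run_rm_asca",
    "parse_combination",
]

EFFECT_NAMES = ("time", "group", "time:group")


def parse_combination(combination: str) -> tuple[str, ...]:
    """Normalise a combination string like ``"group + time*group"``."""
    parts = [p.strip().replace("*", ":").replace("time:group", "time:group")
             for p in combination.split("+")]
    effects = []
    for p in parts:
        name = {"time": "time", "group": "group", "time:group": "time:group",
                "interaction": "time:group"}.get(p)
        if name is None:
            raise ValueError(f"unknown effect term {p!r} in combination {combination!r}")
        if name not in effects:
            effects.append(name)
    if not effects:
        raise ValueError("combination selects no effects")
    return tuple(effects)


def center_and_scale(
    values: np.ndarray, scale: bool = True, names: list[str] | None = None
) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Column-wise centering and (optionally) unit-variance scaling.

    Returns (transformed, means, scales); the transform inverts as
    ``values = transformed * scales + means``.
    """
    values = np.asarray(values, dtype=float)
    means = values.mean(axis=0)
    if scale:
        scales = values.std(axis=0, ddof=1)
        zero = np.flatnonzero(scales == 0)
        if zero.size:
            which = [names[i] for i in zero] if names else list(zero)
            raise ValueError(f"zero-variance variable(s), cannot scale: {which[:5]}")
    else:
        scales = np.ones(values.shape[1])
    return (values - means) / scales, means, scales


@dataclass
class EffectMatrix:
    """Fixed-effect contribution per design cell and variable.

    ``values`` has one row per (visit, level) cell of the full grid and one
    column per registry variable; ``weights`` carries each cell's observation
    count in the dataset the model was fitted to. Adding two effect matrices
    on the same grid sums their values and unions their effect names.
    """

    effects: tuple[str, ...]
    cells: pd.DataFrame
    values: np.ndarray
    variables: list[str]
    weights: np.ndarray

    def __add__(self, other: "EffectMatrix") -> "EffectMatrix":
        return combine_effect_matrices([self, other])

    def to_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        out[self.variables] = self.values
        return out


def construct_effect_matrix(
    fits: dict[str, LMMFit] | list[LMMFit],
    design: DesignMatrix,
    effects: tuple[str, ...] | str,
    variables: list[str],
    weights: np.ndarray | None = None,
) -> EffectMatrix:
    """Build the effect matrix for a subset of fixed effects.

    Each design cell's row is the selected design columns of that cell times
    the per-variable fixed-effect coefficients; the intercept is always
    excluded.
    """
    if isinstance(effects, str):
        effects = parse_combination(effects)
    unknown = set(effects) - set(EFFECT_NAMES)
    if unknown:
        raise ValueError(f"unknown effects {sorted(unknown)}")
    fit_map = fits if isinstance(fits, dict) else {f.variable: f for f in fits}
    missing = [v for v in variables if v not in fit_map]
    if missing:
        raise ValueError(f"missing LMM fits for variables: {missing[:5]}")
    grid, Xcell = cell_grid(design.factor)
    cols = design.block_columns(*effects)
    beta = np.column_stack([fit_map[v].beta for v in variables])  # p x K
    values = Xcell[:, cols] @ beta[cols, :]
    if weights is None:
        weights = np.ones(len(grid))
    return EffectMatrix(
        effects=tuple(effects), cells=grid, values=values,
        variables=list(variables), weights=np.asarray(weights, dtype=float),
    )


def combine_effect_matrices(matrices: list[EffectMatrix]) -> EffectMatrix:
    """Elementwise sum of effect matrices on an identical cell grid."""
    if not matrices:
        raise ValueError("no effect matrices to combine")
    first = matrices[0]
    effects: list[str] = []
    total = np.zeros_like(first.values)
    for m in matrices:
        if m.variables != first.variables or not m.cells.equals(first.cells):
            raise ValueError("effect matrices are on different grids or variable sets")
        total = total + m.values
        for e in m.effects:
            if e not in effects:
                effects.append(e)
    return EffectMatrix(
        effects=tuple(effects), cells=first.cells.copy(), values=total,
        variables=list(first.variables), weights=first.weights.copy(),
    )


@dataclass
class ScoresLoadings:
    """PCA summary of an effect matrix.

    Loadings rows are unit-norm right singular vectors (components x
    variables); scores are the effect-cell projections on them
    (cells x components); explained variance ratios refer to the
    occupancy-weighted effect matrix.
    """

    cells: pd.DataFrame
    scores: np.ndarray
    loadings: np.ndarray
    explained_variance_ratio: np.ndarray
    variables: list[str]

    @property
    def n_components(self) -> int:
        return self.loadings.shape[0]

    def scores_frame(self) -> pd.DataFrame:
        out = self.cells.copy()
        for j in range(self.n_components):
            out[f"PC{j + 1}"] = self.scores[:, j]
        return out

    def loadings_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"variable": self.variables})
        for j in range(self.n_components):
            out[f"PC{j + 1}"] = self.loadings[j]
        return out


def _apply_sign_convention(loadings: np.ndarray, scores: np.ndarray) -> None:
    """Make each component's largest-magnitude loading entry positive."""
    for j in range(loadings.shape[0]):
        i = int(np.argmax(np.abs(loadings[j])))
        if loadings[j, i] < 0:
            loadings[j] *= -1.0
            scores[:, j] *= -1.0


def pca_on_effect(effect: EffectMatrix, n_components: int = 2) -> ScoresLoadings:
    """PCA of an effect matrix via SVD of the occupancy-weighted cells.

    Rows are weighted by the square root of each cell's observation share so
    the decomposition equals PCA of the per-observation effect matrix. No
    additional centering is applied: effect matrices are contrasts already.
    """
    max_rank = min(effect.values.shape)
    if not 1 <= n_components <= max_rank:
        raise ValueError(
            f"n_components={n_components} outside [1, {max_rank}] for this effect matrix"
        )
    w = effect.weights / effect.weights.sum()
    weighted = np.sqrt(w)[:, None] * effect.values
    _, s, Vt = np.linalg.svd(weighted, full_matrices=False)
    total = float(np.sum(s**2))
    loadings = Vt[:n_components].copy()
    scores = effect.values @ loadings.T
    _apply_sign_convention(loadings, scores)
    evr = (s[:n_components] ** 2 / total) if total > 0 else np.zeros(n_components)
    return ScoresLoadings(
        cells=effect.cells.copy(), scores=scores, loadings=loadings,
        explained_variance_ratio=evr, variables=list(effect.variables),
    )


class RMASCA:
    """RM-ASCA+ model for a longitudinal dataset and one group factor.

    Parameters
    ----------
    dataset : LongitudinalDataset
        Observations over a variable registry.
    factor : GroupFactor
        The between-patient factor (treatment group, radiation extent,
        survival status) with its contrast coding.
    effects : str
        Effect combination to summarise, e.g. ``"time"``,
        ``"time + group + time:group"`` or ``"group + time:group"``.
    scale : bool
        Unit-variance scale each variable before fitting (default True;
        lipoprotein and metabolite units differ by orders of magnitude).
    n_components : int
        PCA components to retain (default 2).
    """

    def __init__(
        self,
        dataset: LongitudinalDataset,
        factor: GroupFactor,
        effects: str = "time + group + time:group",
        scale: bool = True,
        n_components: int = 2,
    ) -> None:
        self.dataset = dataset
        self.factor = factor
        self.effects = parse_combination(effects)
        self.scale = scale
        self.n_components = n_components

    @classmethod
    def from_dataframe(
        cls, frame: pd.DataFrame, registry, factor: GroupFactor, **kwargs
    ) -> "RMASCA":
        if "survival" not in frame.columns:
            frame = frame.assign(survival="survivor")
        return cls(LongitudinalDataset(registry, frame), factor, **kwargs)

    def fit(self) -> "RMASCAResults":
        ds = self.dataset
        names = ds.registry.names
        transformed, means, scales = center_and_scale(ds.values, scale=self.scale, names=names)
        design = build_design_matrix(ds.frame, self.factor)
        model = RandomInterceptModel(design.X, ds.frame["patient_id"], design.columns)
        fits = {
            name: model.fit(transformed[:, k], variable=name)
            for k, name in enumerate(names)
        }
        grid, _ = cell_grid(self.factor)
        # Cell occupancy in the observed data (full grid; empty cells weight 0
        # contribute nothing to the weighted PCA but keep their score row).
        counts = ds.frame.groupby(["visit", "group"]).size()
        weights = np.array(
            [counts.get((v, l), 0) for v, l in zip(grid["visit"], grid["level"])],
            dtype=float,
        )
        single = {
            e: construct_effect_matrix(fits, design, (e,), names, weights)
            for e in self.effects
        }
        combined = combine_effect_matrices([single[e] for e in self.effects])
        sl = pca_on_effect(combined, n_components=self.n_components)
        return RMASCAResults(
            model=self, fits=fits, design=design, effect_matrix=combined,
            single_effects=single, scores_loadings=sl,
            column_means=means, column_scales=scales,
        )


@dataclass
class RMASCAResults:
    """Fitted RM-ASCA+ decomposition.

    Carries the per-variable LMM fits, the (combined) effect matrix, and its
    PCA summary. ``bootstrap`` computes percentile confidence envelopes by
    patient-level resampling (see :mod:`rmasca.bootstrap`).
    """

    model: RMASCA
    fits: dict[str, LMMFit]
    design: DesignMatrix
    effect_matrix: EffectMatrix
    single_effects: dict[str, EffectMatrix]
    scores_loadings: ScoresLoadings
    column_means: np.ndarray
    column_scales: np.ndarray

    @property
    def scores(self) -> pd.DataFrame:
        return self.scores_loadings.scores_frame()

    @property
    def loadings(self) -> pd.DataFrame:
        return self.scores_loadings.loadings_frame()

    @property
    def explained_variance_ratio(self) -> np.ndarray:
        return self.scores_loadings.explained_variance_ratio

    def bootstrap(self, n_boot: int = 1000, seed: int = 0, stratify_by_group: bool = False):
        from .bootstrap import bootstrap_cis

        return bootstrap_cis(
            self.model.dataset, self.model.factor,
            combination=" + ".join(self.model.effects),
            n_boot=n_boot, seed=seed, stratify_by_group=stratify_by_group,
            scale=self.model.scale, n_components=self.model.n_components,
            point=self,
        )

    def plot_scores(self, envelope=None, ax=None):
        from .plotting import plot_scores

        return plot_scores(self, envelope=envelope, ax=ax)

    def plot_loadings(self, component: int = 1, envelope=None, ax=None):
        from .plotting import plot_loadings

        return plot_loadings(self, component=component, envelope=envelope, ax=ax)

    def summary(self) -> str:
        sl = self.scores_loadings
        lines = [
            "RM-ASCA+ decomposition",
            "=" * 54,
            f"Effects:        {' + '.join(self.effect_matrix.effects)}",
            f"Factor:         {self.model.factor.name} "
            f"({self.model.factor.coding}-coded, {self.model.factor.n_levels} levels)",
            f"Panel:          {self.model.dataset.registry.panel} "
            f"({len(self.model.dataset.registry)} variables)",
            f"Observations:   {self.model.dataset.n_observations} rows, "
            f"{self.model.dataset.n_patients} patients",
            "",
            "Explained variance ratio:",
        ]
        for j, r in enumerate(sl.explained_variance_ratio, start=1):
            lines.append(f"  PC{j}: {100 * r:6.2f}%")
        lines.append("")
        lines.append("Score trajectories (rows = visits, columns = groups), PC1:")
        s = sl.scores_frame().pivot(index="visit", columns="level", values="PC1")
        lines.append(s.round(3).to_string())
        return "\n".join(lines)


def run_rm_asca(
    dataset: LongitudinalDataset,
    factor: GroupFactor,
    combination: str = "time + group + time:group",
    scale: bool = True,
    n_components: int = 2,
) -> RMASCAResults:
    """One-call pipeline: scale, fit per-variable LMMs, decompose, PCA."""
    return RMASCA(
        dataset, factor, effects=combination, scale=scale, n_components=n_components
    ).fit()
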