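"""Nonparametric patient-level bootstrap for RM-ASCA+ scores and loadings.

Patients (clusters) are resampled with replacement until the original
patient count is reached; a drawn patient contributes all their visits.
The full pipeline — centering/scaling, per-variable LMM fits, effect-matrix
construction, PCA — is re-run on every replicate, replicate components are
sign-aligned to the point estimate, and 95% percentile envelopes are taken
elementwise at the 2.5th and 97.5th percentiles.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .asca import RMASCA, RMASCAResults, ScoresLoadings
from .data import LongitudinalDataset
from .design import GroupFactor

__all__ = [
    "BootstrapEnvelope",
    "resample_patients",
    "align_component_signs",
    "bootstrap_cis",
]

logger = logging.getLogger(__name__)


def resample_patients(
    dataset: LongitudinalDataset,
    seed: int | np.random.Generator = 0,
    stratify_by_group: bool = False,
) -> LongitudinalDataset:
    """Draw a bootstrap replicate of whole patients, with replacement.

    Duplicated patients receive fresh ids so the replicate remains a valid
    dataset with one record per (patient, visit). With
    ``stratify_by_group=True`` resampling is done within each group level,
    preserving group sizes.
    """
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    patients = dataset.patient_table()
    if len(patients) == 0:
        raise ValueError("cannot resample an empty dataset")
    if stratify_by_group:
        drawn_idx = []
        for _, idx in patients.groupby("group", sort=True).indices.items():
            drawn_idx.append(rng.choice(idx, size=len(idx), replace=True))
        drawn = np.concatenate(drawn_idx)
    else:
        drawn = rng.choice(len(patients), size=len(patients), replace=True)
    ids = patients["patient_id"].to_numpy()
    indices = dataset.frame.groupby("patient_id", sort=False).indices
    row_blocks = [indices[ids[i]] for i in drawn]
    row_idx = np.concatenate(row_blocks)
    frame = dataset.frame.iloc[row_idx].reset_index(drop=True)
    width = len(str(len(drawn)))
    frame["patient_id"] = np.repeat(
        [f"B{j + 1:0{width}d}" for j in range(len(drawn))],
        [len(b) for b in row_blocks],
    )
    return LongitudinalDataset(dataset.registry, frame)


def align_component_signs(
    reference_loadings: np.ndarray,
    loadings: np.ndarray,
    scores: np.ndarray | None = None,
) -> tuple[np.ndarray, np.ndarray | None]:
    """Flip replicate components whose loading opposes the reference.

    Each component is multiplied by the sign of its dot product with the
    matching reference component; scores flip consistently. A zero dot
    product leaves the sign at +1 (logged).
    """
    reference_loadings = np.asarray(reference_loadings, dtype=float)
    loadings = np.asarray(loadings, dtype=float).copy()
    if loadings.shape != reference_loadings.shape:
        raise ValueError("loadings shapes differ between replicate and reference")
    scores = None if scores is None else np.asarray(scores, dtype=float).copy()
    for j in range(loadings.shape[0]):
        d = float(reference_loadings[j] @ loadings[j])
        if d == 0.0:
            logger.warning("component %d orthogonal to reference; keeping sign +1", j + 1)
            continue
        if d < 0:
            loadings[j] *= -1.0
            if scores is not None:
                scores[:, j] *= -1.0
    return loadings, scores


@dataclass
class BootstrapEnvelope:
    """Percentile confidence envelopes around a fitted RM-ASCA+ summary."""

    point: ScoresLoadings
    scores_lower: np.ndarray
    scores_upper: np.ndarray
    loadings_lower: np.ndarray
    loadings_upper: np.ndarray
    n_boot: int
    n_failed: int
    seed: int

    def scores_frame(self) -> pd.DataFrame:
        out = self.point.cells.copy()
        for j in range(self.point.n_components):
            out[f"PC{j + 1}"] = self.point.scores[:, j]
            out[f"PC{j + 1}_lo"] = self.scores_lower[:, j]
            out[f"PC{j + 1}_hi"] = self.scores_upper[:, j]
        return out

    def loadings_frame(self) -> pd.DataFrame:
        out = pd.DataFrame({"variable": self.point.variables})
        for j in range(self.point.n_components):
            out[f"PC{j + 1}"] = self.point.loadings[j]
            out[f"PC{j + 1}_lo"] = self.loadings_lower[j]
            out[f"PC{j + 1}_hi"] = self.loadings_upper[j]
        return out


def bootstrap_cis(
    dataset: LongitudinalDataset,
    factor: GroupFactor,
    combination: str = "time + group + time:group",
    n_boot: int = 1000,
    seed: int = 0,
    stratify_by_group: bool = False,
    scale: bool = True,
    n_components: int = 2,
    point: RMASCAResults | None = None,
    max_failure_fraction: float = 0.10,
) -> BootstrapEnvelope:
    """95% percentile envelopes for scores and loadings.

    Replicates whose pipeline fails (e.g. a rank-deficient resample) are
    skipped and counted; the envelope is rejected if more than
    ``max_failure_fraction`` of replicates fail.
    """
    if n_boot < 2:
        raise ValueError("n_boot must be at least 2")
    if point is None:
        point = RMASCA(
            dataset, factor, effects=combination, scale=scale, n_components=n_components
        ).fit()
    ref = point.scores_loadings
    rng = np.random.default_rng(seed)
    boot_scores, boot_loadings = [], []
    n_failed = 0
    for _ in range(n_boot):
        replicate = resample_patients(dataset, rng, stratify_by_group=stratify_by_group)
        try:
            res = RMASCA(
                replicate, factor, effects=combination,
                scale=scale, n_components=n_components,
            ).fit()
        except Exception as exc:
            n_failed += 1
            logger.warning("bootstrap replicate failed: %s", exc)
            continue
        L, S = align_component_signs(
            ref.loadings, res.scores_loadings.loadings, res.scores_loadings.scores
        )
        boot_loadings.append(L)
        boot_scores.append(S)
    if n_failed > max_failure_fraction * n_boot:
        raise RuntimeError(
            f"{n_failed} of {n_boot} bootstrap replicates failed "
            f"(> {100 * max_failure_fraction:.0f}%)"
        )
    S = np.stack(boot_scores)
    L = np.stack(boot_loadings)
    s_lo, s_hi = np.percentile(S, [2.5, 97.5], axis=0)
    l_lo, l_hi = np.percentile(L, [2.5, 97.5], axis=0)
    return BootstrapEnvelope(
        point=ref, scores_lower=s_lo, scores_upper=s_hi,
        loadings_lower=l_lo, loadings_upper=l_hi,
        n_boot=n_boot, n_failed=n_failed, seed=seed if isinstance(seed, int) else -1,
    )
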