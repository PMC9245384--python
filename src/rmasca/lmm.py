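"""Random-intercept linear mixed models and the univariate screen.

The model per variable is y = X b + Z u + e with one random intercept per
patient, u_i ~ N(0, sigma_u^2) and e ~ N(0, sigma_e^2). Estimation is REML
via a one-dimensional profile over log(lambda), lambda = sigma_u^2 /
sigma_e^2: for a random-intercept model the marginal covariance is
V = sigma_e^2 (I + lambda J) blockwise per patient, so the GLS solve, the
determinants and the profiled residual sum of squares all reduce to
patient-level sums and the REML criterion is a smooth scalar function of
lambda. This makes a full panel of fits (and their bootstrap refits) cheap.

Wald tests against the baseline visit use the normal reference distribution;
with a few hundred independent patients the difference from a
degrees-of-freedom correction is negligible. Multiple testing is corrected
with Benjamini-Hochberg across variables within one coefficient family.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import linalg, stats
from scipy.optimize import minimize_scalar
from statsmodels.stats.multitest import multipletests

from .data import LongitudinalDataset
from .design import DesignMatrix, GroupFactor, build_design_matrix

__all__ = [
    "LMMFit",
    "ContrastResult",
    "RandomInterceptModel",
    "fit_random_intercept_lmm",
    "wald_contrast",
    "adjust_benjamini_hochberg",
    "run_univariate_screen",
]

logger = logging.getLogger(__name__)

_LOG_LAMBDA_BOUNDS = (-12.0, 12.0)


@dataclass
class LMMFit:
    """One variable's fitted random-intercept model."""

    variable: str
    beta: np.ndarray
    se: np.ndarray
    sigma_u: float
    sigma_e: float
    loglik: float
    n_obs: int
    n_patients: int
    converged: bool
    column_names: list[str]

    def coefficient(self, name: str) -> tuple[float, float]:
        if name not in self.column_names:
            raise KeyError(
                f"unknown coefficient {name!r}; available: {self.column_names}"
            )
        i = self.column_names.index(name)
        return float(self.beta[i]), float(self.se[i])


@dataclass
class ContrastResult:
    """Wald test of a single fixed-effect coefficient."""

    variable: str
    coefficient: str
    estimate: float
    se: float
    statistic: float
    p_value: float
    q_value: float | None = None


class RandomInterceptModel:
    """Profiled-REML machinery for one design shared across a panel.

    Precomputes the design cross-products and patient-level sums once, then
    fits any number of response vectors against them. This is the workhorse
    behind both the univariate screen and the RM-ASCA+ decomposition.
    """

    def __init__(self, X: np.ndarray, patient_ids, column_names=None) -> None:
        X = np.asarray(X, dtype=float)
        self.X = X
        self.n_obs, self.n_params = X.shape
        self.column_names = list(column_names) if column_names is not None else [
            f"x{j}" for j in range(self.n_params)
        ]
        uniq, self.codes = np.unique(np.asarray(patient_ids), return_inverse=True)
        self.n_groups = len(uniq)
        self.group_sizes = np.bincount(self.codes).astype(float)
        if self.n_groups < 2:
            raise ValueError("need at least 2 patients to fit a mixed model")
        rank = np.linalg.matrix_rank(X)
        if rank < self.n_params:
            # Name the dependent columns via pivoted QR for a useful error.
            _, _, piv = linalg.qr(X, mode="economic", pivoting=True)
            bad = [self.column_names[j] for j in piv[rank:]]
            raise ValueError(
                f"design is rank deficient on observed rows (rank {rank} of "
                f"{self.n_params}); dependent columns: {bad}"
            )
        self.XtX = X.T @ X
        # Per-patient column sums of X: (n_groups, p).
        self.Gx = np.zeros((self.n_groups, self.n_params))
        np.add.at(self.Gx, self.codes, X)

    # -- profiled REML criterion ------------------------------------------

    def _profile(self, lam: float, Xty: np.ndarray, gy: np.ndarray, yty: float):
        """GLS pieces at a given lambda. Returns (criterion, beta, A, q)."""
        w = lam / (1.0 + lam * self.group_sizes)
        A = self.XtX - self.Gx.T @ (w[:, None] * self.Gx)
        b = Xty - self.Gx.T @ (w * gy)
        c, low = linalg.cho_factor(A, check_finite=False)
        beta = linalg.cho_solve((c, low), b, check_finite=False)
        q = yty - np.dot(w * gy, gy) - float(beta @ b)
        q = max(q, 1e-300)
        logdet_A = 2.0 * np.sum(np.log(np.diag(c)))
        logdet_S = np.sum(np.log1p(lam * self.group_sizes))
        dof = self.n_obs - self.n_params
        crit = dof * np.log(q) + logdet_S + logdet_A
        return crit, beta, (c, low), q

    def fit(self, y: np.ndarray, variable: str = "y", tol: float = 1e-8) -> LMMFit:
        """REML fit of one response vector."""
        y = np.asarray(y, dtype=float)
        if y.shape != (self.n_obs,):
            raise ValueError("response length does not match design rows")
        Xty = self.X.T @ y
        gy = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        yty = float(y @ y)
        dof = self.n_obs - self.n_params

        def crit(loglam: float) -> float:
            return self._profile(np.exp(loglam), Xty, gy, yty)[0]

        res = minimize_scalar(
            crit, bounds=_LOG_LAMBDA_BOUNDS, method="bounded",
            options={"xatol": tol},
        )
        loglam = float(res.x)
        # A solution at the lower bound means sigma_u ~ 0; snap it to zero.
        at_lower = loglam <= _LOG_LAMBDA_BOUNDS[0] + 1e-4
        at_upper = loglam >= _LOG_LAMBDA_BOUNDS[1] - 1e-4
        lam = 0.0 if at_lower else np.exp(loglam)
        _, beta, chol, q = self._profile(lam, Xty, gy, yty)
        sigma_e2 = q / dof if dof > 0 else np.nan
        sigma_u2 = lam * sigma_e2
        Ainv = linalg.cho_solve(chol, np.eye(self.n_params), check_finite=False)
        se = np.sqrt(np.clip(sigma_e2 * np.diag(Ainv), 0.0, None))
        logdet_S = np.sum(np.log1p(lam * self.group_sizes))
        logdet_A = 2.0 * np.sum(np.log(np.diag(chol[0])))
        loglik = -0.5 * (
            dof * (np.log(2.0 * np.pi * sigma_e2) + 1.0) + logdet_S + logdet_A
        )
        return LMMFit(
            variable=variable,
            beta=beta,
            se=se,
            sigma_u=float(np.sqrt(sigma_u2)),
            sigma_e=float(np.sqrt(sigma_e2)),
            loglik=float(loglik),
            n_obs=self.n_obs,
            n_patients=self.n_groups,
            converged=bool(res.success) and not at_upper,
            column_names=self.column_names,
        )

    def fit_panel(self, Y: np.ndarray, variables: list[str], tol: float = 1e-8) -> list[LMMFit]:
        return [self.fit(Y[:, k], variables[k], tol=tol) for k in range(Y.shape[1])]

    def beta_at(self, lam: float, y: np.ndarray) -> np.ndarray:
        """GLS fixed effects at a fixed variance ratio lambda = su^2/se^2."""
        y = np.asarray(y, dtype=float)
        Xty = self.X.T @ y
        gy = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        return self._profile(lam, Xty, gy, float(y @ y))[1]

    def reml_criterion(self, lam: float, y: np.ndarray) -> float:
        """REML criterion (-2 log restricted likelihood up to a constant) at
        a fixed variance ratio; exposed for optimality diagnostics."""
        y = np.asarray(y, dtype=float)
        Xty = self.X.T @ y
        gy = np.bincount(self.codes, weights=y, minlength=self.n_groups)
        return self._profile(lam, Xty, gy, float(y @ y))[0]


def fit_random_intercept_lmm(
    y: np.ndarray,
    design: DesignMatrix | np.ndarray,
    patient_ids,
    variable: str = "y",
    column_names=None,
) -> LMMFit:
    """Fit one random-intercept LMM (functional entry point)."""
    if isinstance(design, DesignMatrix):
        X, names = design.X, design.columns
    else:
        X, names = np.asarray(design, dtype=float), column_names
    return RandomInterceptModel(X, patient_ids, names).fit(y, variable=variable)


def wald_contrast(fit: LMMFit, coefficient: str) -> ContrastResult:
    """Two-sided Wald z-test of one fixed-effect coefficient."""
    est, se = fit.coefficient(coefficient)
    if se > 0:
        z = est / se
        p = 2.0 * stats.norm.sf(abs(z))
    else:
        z = 0.0 if est == 0.0 else np.inf * np.sign(est)
        p = 1.0 if est == 0.0 else 0.0
    return ContrastResult(
        variable=fit.variable, coefficient=coefficient,
        estimate=est, se=se, statistic=float(z), p_value=float(p),
    )


def adjust_benjamini_hochberg(p_values) -> np.ndarray:
    """Benjamini-Hochberg step-up adjusted p-values (q-values)."""
    p = np.asarray(p_values, dtype=float)
    if p.ndim != 1:
        raise ValueError("p_values must be one-dimensional")
    if p.size == 0:
        return p.copy()
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def run_univariate_screen(
    dataset: LongitudinalDataset,
    factor: GroupFactor,
    family: str | list[str] = "time",
) -> pd.DataFrame:
    """Per-variable LMM fits with BH correction across variables.

    ``family`` selects the coefficient family: a block name (``"time"``,
    ``"group"``, ``"time:group"``) expands to every coefficient in that
    block, or pass explicit coefficient names. BH is applied across
    variables separately within each coefficient, matching a correction for
    the number of variables tested.

    Returns a DataFrame (variable, coefficient, estimate, se, statistic,
    p_value, q_value) sorted by q within coefficient.
    """
    design = build_design_matrix(dataset.frame, factor)
    if isinstance(family, str):
        names = [design.columns[i] for i in design.blocks[family]] if family in design.blocks else [family]
    else:
        names = list(family)
    for name in names:
        if name not in design.columns:
            raise ValueError(f"unknown coefficient {name!r}")
    model = RandomInterceptModel(design.X, dataset.frame["patient_id"], design.columns)
    rows = []
    Y = dataset.values
    for k, var in enumerate(dataset.registry.names):
        try:
            fit = model.fit(Y[:, k], variable=var)
        except Exception as exc:  # keep screening the remaining variables
            logger.warning("LMM fit failed for %s: %s", var, exc)
            continue
        for name in names:
            rows.append(wald_contrast(fit, name))
    out = pd.DataFrame([vars(r) for r in rows])
    if out.empty:
        raise RuntimeError("no variable could be fitted")
    out["q_value"] = np.nan
    for name in names:
        m = out["coefficient"] == name
        out.loc[m, "q_value"] = adjust_benjamini_hochberg(out.loc[m, "p_value"].to_numpy())
    return (
        out.sort_values(["coefficient", "q_value", "variable"], kind="stable")
        .reset_index(drop=True)
    )
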