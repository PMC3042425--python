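"""Nested logistic models for the incremental value of a new marker.

`NestedMarkerModel` holds one dataset (binary outcome y, established
marker X, candidate marker X*) and `fit()` estimates the two nested
logistic regressions

    restricted:  logit P(y=1) = b0 + b1 X
    expanded:    logit P(y=1) = b0 + b1 X + b2 X*

returning a results object with the coefficients, the three tests of
H0: b2 = 0 — likelihood ratio, Wald, and DeLong's paired comparison of
the AUCs of the two models' in-sample linear predictors — and a
`summary()` table.  The AUC comparison deliberately reuses the fitted
(in-sample) predictors with no cross-validation: that is the common
practice whose operating characteristics this package measures.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .logistic import (
    DegenerateDataError,
    fit_logistic,
    lrt_pvalue,
    wald_pvalue,
)
from .roc import AUCComparison, delong_paired_test
from .simulate import MarkerDataset

__all__ = ["NestedMarkerModel", "NestedMarkerResults", "linear_predictors"]


@dataclass(frozen=True)
class NestedMarkerResults:
    """Fitted nested logistic models and the three marker tests.

    Attributes
    ----------
    beta_restricted : ndarray (b0, b1)
    beta_expanded : ndarray (b0, b1, b2)
    loglik_restricted, loglik_expanded : float
        Maximised Bernoulli log-likelihoods; the expanded value can never
        fall below the restricted one beyond solver tolerance.
    z_restricted, z_expanded : ndarray, shape (n,)
        In-sample linear predictors from each model's own estimates.
    se_beta2 : float
        Model-based (observed-information) standard error of b2.
    lrt_stat : float
        G = 2 (l_expanded - l_restricted).
    p_lrt, p_wald : float
    auc_comparison : AUCComparison
        DeLong paired test of the two predictors' AUCs.
    converged : bool
    """

    beta_restricted: np.ndarray
    beta_expanded: np.ndarray
    loglik_restricted: float
    loglik_expanded: float
    z_restricted: np.ndarray
    z_expanded: np.ndarray
    se_beta2: float
    lrt_stat: float
    p_lrt: float
    p_wald: float
    auc_comparison: AUCComparison
    converged: bool
    n_obs: int

    @property
    def p_auc(self) -> float:
        return self.auc_comparison.p_value

    @property
    def wald_z(self) -> float:
        return float(self.beta_expanded[2] / self.se_beta2)

    def pvalues(self) -> dict[str, float]:
        """The three p-values for H0: the new marker adds nothing."""
        return {"lrt": self.p_lrt, "wald": self.p_wald, "auc": self.p_auc}

    def summary(self) -> str:
        a = self.auc_comparison
        b0r, b1r = self.beta_restricted
        b0e, b1e, b2e = self.beta_expanded
        lines = [
            "Nested logistic marker comparison",
            "=" * 58,
            f"n = {self.n_obs}    converged = {self.converged}",
            "",
            "Coefficients                b0        b1        b2",
            f"  restricted          {b0r:8.4f}  {b1r:8.4f}         -",
            f"  expanded            {b0e:8.4f}  {b1e:8.4f}  {b2e:8.4f}",
            f"  se(b2) = {self.se_beta2:.4f}",
            "",
            f"log-likelihood   restricted {self.loglik_restricted:.4f}   "
            f"expanded {self.loglik_expanded:.4f}",
            "",
            "Tests of H0: b2 = 0 (new marker adds no information)",
            f"  likelihood ratio   G = {self.lrt_stat:7.4f}   p = {self.p_lrt:.4f}",
            f"  Wald               z = {self.wald_z:7.4f}   p = {self.p_wald:.4f}",
            f"  DeLong paired AUC  z = {a.z_stat:7.4f}   p = {a.p_value:.4f}",
            "",
            f"AUC restricted = {a.auc_restricted:.4f}   "
            f"AUC expanded = {a.auc_expanded:.4f}",
            "=" * 58,
        ]
        return "\n".join(lines)


def linear_predictors(
    beta: np.ndarray, x: np.ndarray, x_star: np.ndarray | None = None
) -> np.ndarray:
    """Per-subject linear predictor b0 + b1 x (+ b2 x_star).

    A length-2 ``beta`` uses only x; a length-3 ``beta`` also needs
    ``x_star``.
    """
    beta = np.asarray(beta, dtype=float)
    x = np.asarray(x, dtype=float)
    z = beta[0] + beta[1] * x
    if len(beta) == 3:
        if x_star is None:
            raise ValueError("expanded coefficients need x_star")
        z = z + beta[2] * np.asarray(x_star, dtype=float)
    return z


class NestedMarkerModel:
    """Two nested logistic regressions for one (y, x, x_star) dataset."""

    def __init__(self, y, x, x_star):
        self.y = np.asarray(y)
        self.x = np.asarray(x, dtype=float)
        self.x_star = np.asarray(x_star, dtype=float)
        if not (len(self.y) == len(self.x) == len(self.x_star)):
            raise ValueError("y, x and x_star must have identical length")
        if not np.isin(self.y, (0, 1)).all():
            raise ValueError("y must be a 0/1 vector")
        if not (0 < self.y.sum() < len(self.y)):
            raise DegenerateDataError("both outcome classes must be present")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str = "y",
        marker: str = "x",
        new_marker: str = "x_star",
    ) -> "NestedMarkerModel":
        return cls(data[outcome], data[marker], data[new_marker])

    @classmethod
    def from_dataset(cls, dataset: MarkerDataset) -> "NestedMarkerModel":
        return cls(dataset.y, dataset.x, dataset.x_star)

    def fit(self) -> NestedMarkerResults:
        """ML fit of both models plus the three tests of b2 = 0."""
        n = len(self.y)
        ones = np.ones(n)
        X_r = np.column_stack([ones, self.x])
        X_e = np.column_stack([ones, self.x, self.x_star])

        fit_r = fit_logistic(X_r, self.y)
        fit_e = fit_logistic(X_e, self.y)
        converged = fit_r.converged and fit_e.converged

        z_r = linear_predictors(fit_r.params, self.x)
        z_e = linear_predictors(fit_e.params, self.x, self.x_star)

        if converged:
            se_beta2 = float(np.sqrt(fit_e.cov_params[2, 2]))
            p_lrt = lrt_pvalue(fit_r.loglik, fit_e.loglik)
            p_wald = wald_pvalue(fit_e.params[2], se_beta2)
            auc_cmp = delong_paired_test(z_r, z_e, self.y)
        else:
            se_beta2 = float("nan")
            p_lrt = p_wald = float("nan")
            auc_cmp = AUCComparison(
                auc_restricted=float("nan"),
                auc_expanded=float("nan"),
                var_diff=float("nan"),
                z_stat=float("nan"),
                p_value=float("nan"),
                degenerate=True,
            )

        return NestedMarkerResults(
            beta_restricted=fit_r.params,
            beta_expanded=fit_e.params,
            loglik_restricted=fit_r.loglik,
            loglik_expanded=fit_e.loglik,
            z_restricted=z_r,
            z_expanded=z_e,
            se_beta2=se_beta2,
            lrt_stat=2.0 * (fit_e.loglik - fit_r.loglik),
            p_lrt=p_lrt,
            p_wald=p_wald,
            auc_comparison=auc_cmp,
            converged=converged,
            n_obs=n,
        )
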