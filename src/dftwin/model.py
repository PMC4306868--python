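"""DeFries-Fulker model fitting with cluster-robust inference.

The estimator is ordinary least squares on the double-entered design,
with Huber-White sandwich standard errors clustered on twin pair:
double entry repeats every observation once as focal and once as co-twin,
so rows within a pair are not independent and naive OLS standard errors
would be deflated.

The sandwich covariance is

    (X'X)^-1 [ sum_g X_g' u_g u_g' X_g ] (X'X)^-1

over pair clusters g, scaled by the CR1 small-sample factor
``G/(G-1) * (N-1)/(N-k)`` (G clusters, N rows, k coefficients); test
statistics are referred to a t distribution with G-1 degrees of freedom.
CR0 (no correction) is available for comparison.

Under the mean-centered equation the coefficient on the co-twin score
estimates the shared-environmental variance share (c2) and the
coefficient on relatedness-by-co-twin-score estimates heritability (h2);
what remains, 1 - c2 - h2, is nonshared environment plus error.  The
estimates are plain regression coefficients and are reported
unconstrained — values outside [0, 1] signal misfit and produce a
warning, never truncation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .design import DFModelSpec, build_design, center_cotwin, double_enter

__all__ = [
    "DeFriesFulkerModel",
    "DFResults",
    "ols_fit",
    "cluster_robust_cov",
    "fit_df",
    "decompose_variance",
]


def ols_fit(X, y):
    """Least-squares fit returning ``(coefficients, residuals, r_squared)``.

    Solved by QR via :func:`numpy.linalg.lstsq`; residuals are orthogonal
    to the design columns and R^2 is computed against the intercept-only
    model.
    """
    Xa = np.asarray(X, dtype=float)
    ya = np.asarray(y, dtype=float)
    beta, _, rank, _ = np.linalg.lstsq(Xa, ya, rcond=None)
    if rank < Xa.shape[1]:
        from .design import RankDeficiencyError

        cols = list(X.columns) if hasattr(X, "columns") else list(range(Xa.shape[1]))
        raise RankDeficiencyError(cols)
    resid = ya - Xa @ beta
    sst = np.sum((ya - ya.mean()) ** 2)
    r2 = 1.0 - np.sum(resid**2) / sst if sst > 0 else 0.0
    return beta, resid, r2


def cluster_robust_cov(X, residuals, cluster_ids, correction: str = "cr1") -> np.ndarray:
    """Cluster-robust (Huber-White) covariance of OLS coefficients.

    Sums the score contributions within each cluster before forming the
    meat matrix, so arbitrary correlation within a cluster is allowed.
    ``correction="cr1"`` applies ``G/(G-1) * (N-1)/(N-k)``; ``"cr0"``
    applies none (with singleton clusters CR0 reduces to HC0).
    """
    if correction not in ("cr0", "cr1"):
        raise ValueError(f"unknown small-sample correction {correction!r}")
    Xa = np.asarray(X, dtype=float)
    u = np.asarray(residuals, dtype=float)
    n, k = Xa.shape
    codes, _ = pd.factorize(np.asarray(cluster_ids))
    G = codes.max() + 1
    if G < 2:
        raise ValueError("cluster-robust covariance requires at least two clusters")

    bread = np.linalg.inv(Xa.T @ Xa)
    scores = Xa * u[:, None]
    cluster_scores = np.zeros((G, k))
    np.add.at(cluster_scores, codes, scores)
    meat = cluster_scores.T @ cluster_scores
    cov = bread @ meat @ bread
    if correction == "cr1":
        cov = cov * (G / (G - 1)) * ((n - 1) / (n - k))
    return cov


def decompose_variance(params: Mapping[str, float], variant: str = "eq2") -> dict:
    """Variance shares implied by DF coefficients: c2, h2 and the residual.

    For the centered equations c2 is the coefficient on ``K2_centered``
    and h2 the coefficient on ``R_x_K2_centered``; for the classical
    equation h2 comes from ``R_x_K2`` instead.  ``residual = 1 - c2 - h2``
    is nonshared environment plus error, reported unconstrained; shares
    outside [0, 1] trigger a warning.
    """
    if variant == "eq1":
        c2 = params["K2"]
        h2 = params["R_x_K2"]
    else:
        c2 = params["K2_centered"]
        h2 = params["R_x_K2_centered"]
    residual = 1.0 - c2 - h2
    for label, value in (("c2", c2), ("h2", h2), ("residual", residual)):
        if not 0.0 <= value <= 1.0:
            warnings.warn(
                f"variance share {label}={value:.3f} outside [0, 1]; "
                "reported unconstrained (possible model misfit)",
                stacklevel=2,
            )
    return {"c2": float(c2), "h2": float(h2), "residual": float(residual)}


def _stars(p: float) -> str:
    return "**" if p <= 0.01 else "*" if p <= 0.05 else ""


@dataclass
class DFResults:
    """Fitted DeFries-Fulker model: estimates, clustered inference, shares.

    Attributes
    ----------
    params, bse, tvalues, pvalues : pandas.Series
        Coefficients, cluster-robust standard errors and two-tailed t
        tests on ``df_resid`` = (number of pairs - 1) degrees of freedom.
    cov_params : pandas.DataFrame
        Full sandwich covariance matrix.
    nobs, n_pairs : int
        Twins (rows) entering the model and pair clusters; nobs = 2 * n_pairs.
    rsquared : float
    variance_components : dict
        ``{"c2", "h2", "residual"}`` implied by the coefficients.
    """

    spec: DFModelSpec
    params: pd.Series
    bse: pd.Series
    tvalues: pd.Series
    pvalues: pd.Series
    cov_params: pd.DataFrame
    nobs: int
    n_pairs: int
    rsquared: float
    variance_components: dict
    resid: np.ndarray
    correction: str

    @property
    def df_resid(self) -> int:
        """Degrees of freedom for t reference: clusters minus one."""
        return self.n_pairs - 1

    def conf_int(self, alpha: float = 0.05) -> pd.DataFrame:
        """Two-sided (1-alpha) confidence intervals from the t reference."""
        q = stats.t.ppf(1 - alpha / 2, self.df_resid)
        return pd.DataFrame(
            {"lower": self.params - q * self.bse, "upper": self.params + q * self.bse}
        )

    def to_dict(self) -> dict:
        return {
            "variant": self.spec.variant,
            "envdif": list(self.spec.envdif),
            "params": self.params.to_dict(),
            "bse": self.bse.to_dict(),
            "tvalues": self.tvalues.to_dict(),
            "pvalues": self.pvalues.to_dict(),
            "n_twins": int(self.nobs),
            "n_pairs": int(self.n_pairs),
            "r_squared": float(self.rsquared),
            "variance_components": self.variance_components,
        }

    def summary(self, title: str | None = None) -> str:
        """Plain-text coefficient table with significance stars.

        Stars follow the two-tailed convention * p<=0.05, ** p<=0.01.
        """
        lines = []
        lines.append(title or f"DeFries-Fulker regression ({self.spec.variant})")
        lines.append("=" * 64)
        lines.append(f"{'term':<24}{'coef':>10}{'SE':>10}{'t':>8}{'p':>9}")
        lines.append("-" * 64)
        for name in self.params.index:
            p = self.pvalues[name]
            lines.append(
                f"{name:<24}{self.params[name]:>10.4f}{self.bse[name]:>10.4f}"
                f"{self.tvalues[name]:>8.2f}{p:>7.3f} {_stars(p):<2}"
            )
        lines.append("-" * 64)
        vc = self.variance_components
        lines.append(
            f"N = {self.nobs} twins ({self.n_pairs} pairs)   R^2 = {self.rsquared:.3f}"
        )
        lines.append(
            f"variance shares: c2 = {vc['c2']:.3f}  h2 = {vc['h2']:.3f}  "
            f"nonshared+error = {vc['residual']:.3f}"
        )
        lines.append(f"SEs: cluster-robust ({self.correction.upper()}), t on G-1 df")
        lines.append("* p<=0.05, ** p<=0.01 (two-tailed)")
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<DFResults {self.spec.variant} n_pairs={self.n_pairs} "
            f"c2={self.variance_components['c2']:.3f} "
            f"h2={self.variance_components['h2']:.3f}>"
        )


class DeFriesFulkerModel:
    """DeFries-Fulker kinship regression on a one-row-per-twin table.

    Parameters
    ----------
    data : pandas.DataFrame
        One row per twin with pair identifier, zygosity ("MZ"/"DZ"),
        outcome and any covariates used as difference scores.
    equation : {"eq2", "eq1", "eq3"}
        Model variant; "eq3" is implied when ``envdif`` is non-empty.
    envdif : sequence of str
        Covariates entered as within-pair difference scores.
    outcome, pair_id, zygosity : str
        Column names.

    Examples
    --------
    >>> res = DeFriesFulkerModel(df, envdif=["fast_food"]).fit()
    >>> print(res.summary())
    """

    def __init__(
        self,
        data: pd.DataFrame,
        equation: str | None = None,
        envdif: Sequence[str] = (),
        outcome: str = "outcome",
        pair_id: str = "pair_id",
        zygosity: str = "zygosity",
    ):
        envdif = tuple(envdif)
        if equation is None:
            equation = "eq3" if envdif else "eq2"
        self.spec = DFModelSpec(variant=equation, envdif=envdif)
        self.data = data
        self.outcome = outcome
        self.pair_id = pair_id
        self.zygosity = zygosity

        rows = double_enter(
            data,
            envdif=envdif,
            outcome=outcome,
            pair_id=pair_id,
            zygosity=zygosity,
        )
        if rows["R"].nunique() < 2:
            raise ValueError(
                "single-zygosity data: both MZ and DZ pairs are required to "
                "identify the shared-environment and heritability coefficients"
            )
        self.rows = center_cotwin(rows) if equation != "eq1" else rows
        self.exog, self.endog = build_design(self.rows, self.spec)

    def fit(self, cov: str = "cr1") -> DFResults:
        """Estimate by OLS with pair-clustered sandwich standard errors."""
        names = list(self.exog.columns)
        beta, resid, r2 = ols_fit(self.exog, self.endog)
        covm = cluster_robust_cov(self.exog, resid, self.rows["pair_id"], correction=cov)
        se = np.sqrt(np.diag(covm))
        n_pairs = self.rows["pair_id"].nunique()
        t = beta / se
        p = 2.0 * stats.t.sf(np.abs(t), n_pairs - 1)
        params = pd.Series(beta, index=names)
        return DFResults(
            spec=self.spec,
            params=params,
            bse=pd.Series(se, index=names),
            tvalues=pd.Series(t, index=names),
            pvalues=pd.Series(p, index=names),
            cov_params=pd.DataFrame(covm, index=names, columns=names),
            nobs=len(self.exog),
            n_pairs=int(n_pairs),
            rsquared=float(r2),
            variance_components=decompose_variance(params, self.spec.variant),
            resid=resid,
            correction=cov,
        )


def fit_df(
    data: pd.DataFrame,
    spec: DFModelSpec | None = None,
    cov: str = "cr1",
    **columns,
) -> DFResults:
    """Functional one-call interface: build the design and fit in one step."""
    spec = spec or DFModelSpec()
    model = DeFriesFulkerModel(
        data, equation=spec.variant, envdif=spec.envdif, **columns
    )
    return model.fit(cov=cov)
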