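"""Generalized estimating equations for clustered binary outcomes.

Marginal logistic regression for correlated 0/1 data, estimated with
GEE: binomial variance, logit link, an exchangeable (or independence)
working correlation, and the robust sandwich covariance.  This is the
population-averaged model used to analyse the crossover evaluation —
outcome regressed on treatment, period and sequence with responses
clustered within clinician — but the estimator is generic.

Estimation details
------------------
* Coefficients solve the estimating equations
  ``sum_i D_i' V_i^{-1} (y_i - mu_i) = 0`` by Fisher scoring, where
  ``D_i = A_i X_i``, ``V_i = A_i^{1/2} R(alpha) A_i^{1/2}`` and
  ``A_i = diag(mu_ij (1 - mu_ij))``.
* The exchangeable correlation ``alpha`` is the moment estimator of
  Liang & Zeger: the mean of within-cluster Pearson-residual
  cross-products with denominator ``sum_i n_i (n_i - 1) / 2 - p``.
  Dispersion is fixed at 1 (binomial).
* The robust covariance is the usual sandwich
  ``B^{-1} M B^{-1}`` with bread ``B = sum_i D_i' V_i^{-1} D_i`` and
  meat ``M = sum_i D_i' V_i^{-1} e_i e_i' V_i^{-1} D_i``; an optional
  Mancl–DeRouen small-sample correction inflates each cluster residual
  by ``(I - H_i)^{-1}``.
* Inference is Wald: z statistics against the standard normal, odds
  ratios ``exp(beta)`` with ``exp(beta +/- 1.96 se)`` 95% intervals.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "BinaryGEE",
    "GEEResults",
    "SeparationError",
    "analyze_crossover",
    "CrossoverAnalysis",
]

_BETA_DIVERGENCE_LIMIT = 15.0  # |logit| beyond this signals separation


class SeparationError(RuntimeError):
    """The logistic fit diverged (perfectly separated outcome)."""


def _expit(eta: np.ndarray) -> np.ndarray:
    return 0.5 * (1.0 + np.tanh(0.5 * eta))


class BinaryGEE:
    """Marginal logistic model for clustered binary data.

    Parameters
    ----------
    endog : array of 0/1 outcomes, length N.
    exog : (N, p) design matrix; supply your own intercept column.
    groups : length-N cluster labels.
    exog_names : optional column names for reporting.
    cov_struct : "exchangeable" or "independence" working correlation.
    max_iter, tol : Fisher-scoring controls; convergence is declared
        when the largest absolute coefficient update falls below tol.
    """

    def __init__(
        self,
        endog,
        exog,
        groups,
        exog_names: Optional[Sequence[str]] = None,
        cov_struct: str = "exchangeable",
        max_iter: int = 100,
        tol: float = 1e-8,
    ) -> None:
        self.endog = np.asarray(endog, dtype=float).ravel()
        self.exog = np.asarray(exog, dtype=float)
        if self.exog.ndim != 2 or self.exog.shape[0] != self.endog.shape[0]:
            raise ValueError("exog must be (N, p) aligned with endog")
        if not np.isin(self.endog, (0.0, 1.0)).all():
            raise ValueError("endog must be binary 0/1 with no missing values")
        if np.isnan(self.exog).any():
            raise ValueError("exog contains missing values")
        if cov_struct not in ("exchangeable", "independence"):
            raise ValueError("cov_struct must be 'exchangeable' or 'independence'")
        self.cov_struct = cov_struct
        self.max_iter = int(max_iter)
        self.tol = float(tol)
        self.exog_names = (
            list(exog_names)
            if exog_names is not None
            else [f"x{j}" for j in range(self.exog.shape[1])]
        )
        if len(self.exog_names) != self.exog.shape[1]:
            raise ValueError("exog_names length mismatch")
        # rank check: the estimating equations need a full-rank design
        if np.linalg.matrix_rank(self.exog) < self.exog.shape[1]:
            raise ValueError("design matrix is rank deficient")
        groups = np.asarray(groups)
        if groups.shape[0] != self.endog.shape[0]:
            raise ValueError("groups must align with endog")
        _, group_idx = np.unique(groups, return_inverse=True)
        order = np.argsort(group_idx, kind="stable")
        self._order = order
        self._y = self.endog[order]
        self._X = self.exog[order]
        gi = group_idx[order]
        # start index of each cluster in the sorted arrays
        self._starts = np.concatenate(([0], np.flatnonzero(np.diff(gi)) + 1, [len(gi)]))
        self.n_clusters = len(self._starts) - 1
        if self.n_clusters < 2:
            raise ValueError("GEE requires at least 2 clusters")

    @classmethod
    def from_dataframe(
        cls,
        data: pd.DataFrame,
        outcome: str,
        covariates: Sequence[str],
        cluster: str,
        add_intercept: bool = True,
        **kwargs,
    ) -> "BinaryGEE":
        """Build the model from a tidy table of numeric columns."""
        cols = [outcome, *covariates, cluster]
        missing = [c for c in cols if c not in data.columns]
        if missing:
            raise ValueError(f"data lacks column(s): {missing}")
        if data[[outcome, *covariates]].isna().any().any():
            raise ValueError("modelled columns contain missing values")
        X = data[list(covariates)].to_numpy(dtype=float)
        names = list(covariates)
        if add_intercept:
            X = np.column_stack([np.ones(len(data)), X])
            names = ["intercept", *names]
        return cls(
            endog=data[outcome].to_numpy(dtype=float),
            exog=X,
            groups=data[cluster].to_numpy(),
            exog_names=names,
            **kwargs,
        )

    # -- internals ---------------------------------------------------------

    def _clusters(self):
        for k in range(self.n_clusters):
            s, e = self._starts[k], self._starts[k + 1]
            yield self._y[s:e], self._X[s:e]

    def _alpha_moment(self, beta: np.ndarray) -> float:
        """Liang-Zeger moment estimator of the exchangeable correlation."""
        p = self._X.shape[1]
        cross = 0.0
        pairs = 0.0
        for y, X in self._clusters():
            mu = _expit(X @ beta)
            r = (y - mu) / np.sqrt(mu * (1.0 - mu))
            n = len(y)
            cross += 0.5 * (r.sum() ** 2 - (r**2).sum())
            pairs += 0.5 * n * (n - 1)
        if pairs == 0:
            return 0.0
        denom = pairs - p
        if denom <= 0:  # too few pairs for the df correction
            denom = pairs
        alpha = cross / denom
        # keep the working correlation positive definite
        max_n = int(np.max(np.diff(self._starts)))
        lo = -1.0 / (max_n - 1) + 1e-6 if max_n > 1 else 0.0
        return float(np.clip(alpha, lo, 1.0 - 1e-6))

    def _score_pieces(self, beta: np.ndarray, alpha: float):
        """Bread B, score U and per-cluster scores at (beta, alpha)."""
        p = self._X.shape[1]
        B = np.zeros((p, p))
        U = np.zeros(p)
        cluster_scores = []
        for y, X in self._clusters():
            mu = _expit(X @ beta)
            mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
            s = np.sqrt(mu * (1.0 - mu))
            Xs = X * s[:, None]          # A^{1/2} X  (= A^{-1/2} D)
            z = (y - mu) / s             # Pearson residual
            n = len(y)
            if alpha != 0.0 and n > 1:
                c = alpha / (1.0 + (n - 1) * alpha)
                scale = 1.0 / (1.0 - alpha)
                col = Xs.sum(axis=0)
                Bk = scale * (Xs.T @ Xs - c * np.outer(col, col))
                gk = scale * (Xs.T @ z - c * col * z.sum())
            else:
                Bk = Xs.T @ Xs
                gk = Xs.T @ z
            B += Bk
            U += gk
            cluster_scores.append(gk)
        return B, U, cluster_scores

    def fit(self, bias_corrected: bool = False) -> "GEEResults":
        """Estimate the model; returns a :class:`GEEResults`.

        ``bias_corrected=True`` applies the Mancl–DeRouen small-sample
        adjustment to the sandwich covariance (off by default).
        """
        p = self._X.shape[1]
        beta = np.zeros(p)
        alpha = 0.0
        converged = False
        iterations = 0
        for iterations in range(1, self.max_iter + 1):
            B, U, _ = self._score_pieces(beta, alpha)
            try:
                step = np.linalg.solve(B, U)
            except np.linalg.LinAlgError as exc:
                raise SeparationError(f"singular working information: {exc}") from exc
            beta = beta + step
            if np.max(np.abs(beta)) > _BETA_DIVERGENCE_LIMIT:
                worst = self.exog_names[int(np.argmax(np.abs(beta)))]
                raise SeparationError(
                    f"coefficient for {worst!r} diverged; the outcome appears "
                    "perfectly separated along this covariate"
                )
            if self.cov_struct == "exchangeable":
                alpha = self._alpha_moment(beta)
            if np.max(np.abs(step)) < self.tol:
                converged = True
                break
        if not converged:
            warnings.warn(
                f"GEE did not converge in {self.max_iter} iterations",
                RuntimeWarning,
                stacklevel=2,
            )
        B, _, cluster_scores = self._score_pieces(beta, alpha)
        bread = np.linalg.inv(B)
        if bias_corrected:
            cluster_scores = self._mancl_derouen_scores(beta, alpha, bread)
        meat = np.zeros((p, p))
        for gk in cluster_scores:
            meat += np.outer(gk, gk)
        robust_cov = bread @ meat @ bread
        robust_cov = 0.5 * (robust_cov + robust_cov.T)
        return GEEResults(
            model=self,
            params=pd.Series(beta, index=self.exog_names),
            alpha=float(alpha) if self.cov_struct == "exchangeable" else 0.0,
            cov_robust=pd.DataFrame(robust_cov, index=self.exog_names, columns=self.exog_names),
            cov_naive=pd.DataFrame(bread, index=self.exog_names, columns=self.exog_names),
            n_obs=len(self._y),
            n_clusters=self.n_clusters,
            converged=converged,
            iterations=iterations,
            bias_corrected=bias_corrected,
        )

    def _mancl_derouen_scores(self, beta, alpha, bread):
        """Cluster scores with (I - H_i)^{-1}-inflated residuals."""
        scores = []
        for y, X in self._clusters():
            mu = _expit(X @ beta)
            mu = np.clip(mu, 1e-10, 1.0 - 1e-10)
            s = np.sqrt(mu * (1.0 - mu))
            n = len(y)
            A = np.diag(mu * (1.0 - mu))
            if n > 1:
                R = np.full((n, n), alpha)
                np.fill_diagonal(R, 1.0)
            else:
                R = np.eye(n)
            Ahalf = np.diag(s)
            V = Ahalf @ R @ Ahalf
            Vinv = np.linalg.inv(V)
            D = A @ X
            H = D @ bread @ D.T @ Vinv
            e = np.linalg.solve(np.eye(n) - H, y - mu)
            scores.append(D.T @ Vinv @ e)
        return scores


@dataclass
class GEEResults:
    """Fitted GEE: coefficients, correlation, covariances, Wald inference."""

    model: BinaryGEE
    params: pd.Series
    alpha: float
    cov_robust: pd.DataFrame
    cov_naive: pd.DataFrame
    n_obs: int
    n_clusters: int
    converged: bool
    iterations: int
    bias_corrected: bool = False

    @property
    def bse(self) -> pd.Series:
        """Robust (sandwich) standard errors."""
        return pd.Series(np.sqrt(np.diag(self.cov_robust.to_numpy())), index=self.params.index)

    @property
    def naive_bse(self) -> pd.Series:
        return pd.Series(np.sqrt(np.diag(self.cov_naive.to_numpy())), index=self.params.index)

    def _loc(self, coefficient: str) -> int:
        if coefficient not in self.params.index:
            raise KeyError(f"no coefficient {coefficient!r} in fit")
        return int(self.params.index.get_loc(coefficient))

    def wald_test(self, coefficient: str) -> tuple[float, float]:
        """Robust Wald z statistic and two-sided normal p-value."""
        j = self._loc(coefficient)
        se = float(self.bse.iloc[j])
        if se == 0.0:
            raise ZeroDivisionError(f"robust SE for {coefficient!r} is zero")
        z = float(self.params.iloc[j]) / se
        p = 2.0 * stats.norm.sf(abs(z))
        return z, float(p)

    def odds_ratio(self, coefficient: str) -> tuple[float, float, float]:
        """Odds ratio with Wald 95% CI on the exponentiated scale."""
        j = self._loc(coefficient)
        b = float(self.params.iloc[j])
        se = float(self.bse.iloc[j])
        half = 1.959963984540054 * se
        return float(np.exp(b)), float(np.exp(b - half)), float(np.exp(b + half))

    def conf_int(self, level: float = 0.95) -> pd.DataFrame:
        zq = stats.norm.ppf(0.5 + level / 2.0)
        lo = self.params - zq * self.bse
        hi = self.params + zq * self.bse
        return pd.DataFrame({"lower": lo, "upper": hi})

    def to_dict(self) -> dict:
        return {
            "params": self.params.to_dict(),
            "robust_se": self.bse.to_dict(),
            "naive_se": self.naive_bse.to_dict(),
            "alpha": self.alpha,
            "n_obs": self.n_obs,
            "n_clusters": self.n_clusters,
            "converged": self.converged,
            "iterations": self.iterations,
            "bias_corrected": self.bias_corrected,
            "odds_ratios": {
                name: dict(zip(("or", "lower95", "upper95"), self.odds_ratio(name)))
                for name in self.params.index
            },
            "p_values": {name: self.wald_test(name)[1] for name in self.params.index},
        }

    def summary(self) -> str:
        corstr = self.model.cov_struct
        lines = [
            "Binary GEE (logit link, %s working correlation)" % corstr,
            f"clusters: {self.n_clusters}   observations: {self.n_obs}   "
            f"alpha: {self.alpha:.4f}   iterations: {self.iterations}   "
            f"converged: {self.converged}",
            "-" * 78,
            f"{'':<12}{'coef':>10}{'robust se':>12}{'z':>9}{'P>|z|':>9}"
            f"{'OR':>10}{'[0.025':>10}{'0.975]':>10}",
        ]
        for name in self.params.index:
            z, pval = self.wald_test(name)
            orr, lo, hi = self.odds_ratio(name)
            lines.append(
                f"{name:<12}{self.params[name]:>10.4f}{self.bse[name]:>12.4f}"
                f"{z:>9.3f}{_fmt_p(pval):>9}{orr:>10.3f}{lo:>10.3f}{hi:>10.3f}"
            )
        lines.append("-" * 78)
        return "\n".join(lines)


def _fmt_p(p: float) -> str:
    """Journal-style p formatting for text output only."""
    if p < 0.001:
        return "<.001"
    return f"{p:.3f}".lstrip("0") if p < 1 else "1.000"


_CODING = {
    "treatment": {"control": 0, "intervention": 1},
    "sequence": {"A": 0, "B": 1},
    "period": {1: 0, 2: 1},
}


@dataclass
class CrossoverAnalysis:
    """One outcome's report row: phase rates plus the adjusted GEE estimates."""

    outcome: str
    rates: pd.DataFrame
    fit: GEEResults

    def to_dict(self) -> dict:
        z, p = self.fit.wald_test("treatment")
        orr, lo, hi = self.fit.odds_ratio("treatment")
        return {
            "outcome": self.outcome,
            "intervention_rate": float(self.rates.loc["intervention", f"{self.outcome}_rate"])
            if f"{self.outcome}_rate" in self.rates.columns
            else None,
            "control_rate": float(self.rates.loc["control", f"{self.outcome}_rate"])
            if f"{self.outcome}_rate" in self.rates.columns
            else None,
            "aOR": orr,
            "ci95": [lo, hi],
            "p_value": p,
            "fit": self.fit.to_dict(),
        }

    def summary(self) -> str:
        z, p = self.fit.wald_test("treatment")
        orr, lo, hi = self.fit.odds_ratio("treatment")
        col = f"{self.outcome}_rate"
        head = (
            f"{'outcome':<10}{'intervention %':>15}{'control %':>11}"
            f"{'aOR (95% CI)':>22}{'P':>8}"
        )
        row = (
            f"{self.outcome:<10}"
            f"{self.rates.loc['intervention', col]:>15.1f}"
            f"{self.rates.loc['control', col]:>11.1f}"
            f"{orr:>10.2f} ({lo:.2f}-{hi:.2f}){'':<0}"
            f"{_fmt_p(p):>8}"
        )
        return "\n".join([head, row, "", self.fit.summary()])


def analyze_crossover(
    table: pd.DataFrame,
    outcome: str = "total",
    cov_struct: str = "exchangeable",
    bias_corrected: bool = False,
) -> CrossoverAnalysis:
    """Fit the crossover GEE for one outcome of the assembled table.

    ``table`` is the long-format analysis table (one row per participant
    x question) with labelled design columns; the model is
    outcome ~ treatment + period + sequence with responses clustered by
    participant, coded control/period1/sequenceA = 0.  Returns the raw
    phase rates together with the fitted model.
    """
    from .scoring import phase_rates  # local import to avoid cycle

    if outcome not in ("total", "ointment", "dressing"):
        raise ValueError("outcome must be one of: total, ointment, dressing")
    col = f"outcome_{outcome}"
    data = table.copy()
    for name, mapping in _CODING.items():
        coded = data[name].map(mapping)
        if coded.isna().any():
            raise ValueError(f"column {name!r} contains values outside {mapping}")
        data[name] = coded
    model = BinaryGEE.from_dataframe(
        data,
        outcome=col,
        covariates=["treatment", "period", "sequence"],
        cluster="participant_id",
        cov_struct=cov_struct,
    )
    fit = model.fit(bias_corrected=bias_corrected)
    rates = phase_rates(table).rename(
        columns={
            "total_rate": "total_rate",
            "ointment_rate": "ointment_rate",
            "dressing_rate": "dressing_rate",
        }
    )
    return CrossoverAnalysis(outcome=outcome, rates=rates, fit=fit)
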