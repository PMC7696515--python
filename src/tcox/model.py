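"""Weighted elastic-net Cox regression: model and results objects.

The model minimizes

    -l(beta)/n + F(beta),      F(beta) = lambda * [ alpha ||w o beta||_1
                                                    + (1 - alpha) ||w o beta||_2^2 ]

where l is the Cox partial log-likelihood, alpha in [0, 1] mixes lasso and
ridge, and w is a vector of per-gene penalty factors (all ones recovers the
plain elastic net). This "literal" parameterization keeps the factors inside
both norms, so the ridge term sees squared factors; a compatibility mode
(``penalty_mode='linear'``) instead applies the factors linearly to both
terms, F = lambda * sum_j w_j [alpha |beta_j| + (1-alpha) beta_j^2 / 2],
matching glmnet-style software.

The default solve route exploits an exact reduction of the literal problem:
substituting gamma_j = w_j beta_j and dividing column j of X by w_j yields a
standard unweighted elastic-net Cox problem in gamma, solved without any
internal re-standardization and back-transformed as beta_j = gamma_j / w_j.
A direct proximal-gradient solve on the original parameterization is kept
as an independent route (``solver='direct'``) and is the only route for the
linear compatibility mode or when some factor is 0 (unpenalized gene).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .data import SurvivalDataset
from .solver import (
    partial_log_likelihood,
    partial_loglik_and_gradient,
    prox_elastic_net_cox,
)
from .weights import PenaltyWeights

__all__ = ["WeightedCoxnet", "CoxnetResults", "select_lambda"]

_ALPHA_FLOOR = 1e-3  # path construction only; keeps lambda_max finite as alpha -> 0


class WeightedCoxnet:
    """Elastic-net Cox proportional-hazards model with per-gene penalty factors.

    Parameters
    ----------
    data
        Covariates with right-censored survival outcome.
    alpha
        Elastic-net mixing parameter in [0, 1]; 1 = lasso, 0 = ridge.
    penalty_factors
        Length-p positive factors w (None = all ones, the plain elastic net).
        May also be a :class:`~tcox.weights.PenaltyWeights`, in which case its
        factors and exclusion mask are used.
    excluded
        Boolean mask of genes forced out of the support (coefficient 0 at
        every lambda); used for zero-rewiring genes whose inverse-transform
        factor is infinite.
    penalty_mode
        'literal' (factors inside both norms) or 'linear' (glmnet-style).
    standardize
        Center and scale columns to unit variance before the weight
        rescaling; coefficients are reported on the original scale.
    ties
        'breslow' (default) or 'efron'.
    """

    def __init__(
        self,
        data: SurvivalDataset,
        alpha: float = 0.1,
        penalty_factors: np.ndarray | PenaltyWeights | None = None,
        excluded: np.ndarray | None = None,
        penalty_mode: str = "literal",
        standardize: bool = True,
        ties: str = "breslow",
    ) -> None:
        if not 0.0 <= alpha <= 1.0:
            raise ValueError(f"alpha must be in [0, 1], got {alpha}")
        if penalty_mode not in ("literal", "linear"):
            raise ValueError(f"unknown penalty_mode {penalty_mode!r}")
        if ties not in ("breslow", "efron"):
            raise ValueError(f"unknown tie method {ties!r}")
        self.data = data
        self.alpha = float(alpha)
        self.penalty_mode = penalty_mode
        self.standardize = standardize
        self.ties = ties
        p = data.n_genes
        if isinstance(penalty_factors, PenaltyWeights):
            if penalty_factors.gene_ids != data.gene_ids:
                raise ValueError("penalty-weight gene list does not match the dataset")
            excluded = penalty_factors.excluded if excluded is None else excluded
            penalty_factors = penalty_factors.factors
        self.excluded = (
            np.zeros(p, dtype=bool) if excluded is None else np.asarray(excluded, dtype=bool)
        )
        w = np.ones(p) if penalty_factors is None else np.asarray(penalty_factors, dtype=float)
        if w.shape != (p,):
            raise ValueError("penalty_factors must have one entry per gene")
        active = ~self.excluded
        if np.any(~np.isfinite(w[active])) or np.any(w[active] < 0):
            raise ValueError("non-excluded genes need finite, non-negative penalty factors")
        self.penalty_factors = w
        if data.n_events == 0:
            raise ValueError("no events in the data")
        # standardization statistics (population sd, as is conventional for
        # penalized paths); fitting happens on the standardized active columns
        Xa = data.X[:, active]
        self._active = active
        self._mean = Xa.mean(axis=0) if standardize else np.zeros(Xa.shape[1])
        sd = Xa.std(axis=0)
        if standardize and np.any(sd == 0):
            bad = [g for g, a in zip(data.gene_ids, active) if a][int(np.argmin(sd))]
            raise ValueError(f"zero-variance covariate cannot be standardized: {bad}")
        self._scale = sd if standardize else np.ones(Xa.shape[1])
        self._Xs = (Xa - self._mean) / self._scale
        self._w_active = w[active]

    @classmethod
    def from_dataframe(
        cls,
        df: pd.DataFrame,
        time_col: str = "time",
        status_col: str = "status",
        feature_cols: Sequence[str] | None = None,
        **kwargs,
    ) -> "WeightedCoxnet":
        """Build from a tidy frame with follow-up time, event status and covariates."""
        if feature_cols is None:
            feature_cols = [c for c in df.columns if c not in (time_col, status_col)]
        data = SurvivalDataset(
            df[list(feature_cols)].to_numpy(float),
            df[time_col].to_numpy(float),
            df[status_col].to_numpy(),
            list(feature_cols),
            [str(i) for i in df.index],
        )
        return cls(data, **kwargs)

    # ------------------------------------------------------------------ penalty
    def _sq_weights(self, lam: float) -> tuple[np.ndarray, np.ndarray]:
        """Per-coordinate soft-threshold weights s and quadratic weights q on the
        standardized active columns, for the configured penalty mode."""
        w = self._w_active
        if self.penalty_mode == "literal":
            return lam * self.alpha * w, lam * (1.0 - self.alpha) * w * w
        return lam * self.alpha * w, lam * (1.0 - self.alpha) * w / 2.0

    def lambda_max(self) -> float:
        """Smallest lambda at which the all-zero solution is optimal.

        From the KKT conditions at beta = 0: |grad_j(-l/n)| <= lambda*alpha*w_j
        for every active gene; alpha is floored for path construction so the
        ridge limit still yields a finite path start.
        """
        _, g = partial_loglik_and_gradient(
            np.zeros(self._Xs.shape[1]), self._Xs, self.data.time, self.data.status, self.ties
        )
        g = -g / self.data.n_samples
        a = max(self.alpha, _ALPHA_FLOOR)
        w = self._w_active
        with np.errstate(divide="ignore"):
            ratio = np.where(w > 0, np.abs(g) / (a * np.where(w > 0, w, 1.0)), np.inf)
        if np.any(w == 0):
            # unpenalized columns never vanish; lambda_max refers to penalized ones
            ratio = np.where(w > 0, ratio, 0.0)
        return float(np.max(ratio))

    def lambda_path(self, n_lambdas: int = 100, lambda_min_ratio: float | None = None) -> np.ndarray:
        """Log-spaced decreasing path from lambda_max down to a small fraction of it."""
        lmax = self.lambda_max()
        if lambda_min_ratio is None:
            lambda_min_ratio = 0.05 if self.data.n_samples < self.data.n_genes else 0.01
        return np.geomspace(lmax, lmax * lambda_min_ratio, n_lambdas)

    # -------------------------------------------------------------------- fit
    def _fit_at(self, lam: float, beta0: np.ndarray | None, solver: str, tol: float, max_iter: int) -> np.ndarray:
        """Solve at one lambda on the standardized active columns."""
        X, t, d = self._Xs, self.data.time, self.data.status
        s, q = self._sq_weights(lam)
        if solver == "reduction" and self.penalty_mode == "literal" and np.all(self._w_active > 0):
            Xr = X / self._w_active
            g0 = None if beta0 is None else beta0 * self._w_active
            gamma = prox_elastic_net_cox(
                Xr, t, d,
                s=np.full(X.shape[1], lam * self.alpha),
                q=np.full(X.shape[1], lam * (1.0 - self.alpha)),
                beta0=g0, tol=tol, max_iter=max_iter, ties=self.ties,
            )
            return gamma / self._w_active
        return prox_elastic_net_cox(
            X, t, d, s=s, q=q, beta0=beta0, tol=tol, max_iter=max_iter, ties=self.ties
        )

    def fit(
        self,
        lambdas: Sequence[float] | None = None,
        n_lambdas: int = 100,
        lambda_min_ratio: float | None = None,
        cv_folds: int | None = None,
        seed: int = 0,
        solver: str = "reduction",
        tol: float = 1e-7,
        max_iter: int = 100_000,
    ) -> "CoxnetResults":
        """Fit the coefficient path (decreasing lambda, warm starts).

        With ``cv_folds`` set, lambda is chosen by cross-validated partial-
        likelihood deviance and exposed as ``lambda_best`` on the results.
        """
        if solver not in ("reduction", "direct"):
            raise ValueError(f"unknown solver {solver!r}")
        if lambdas is None:
            lambdas = self.lambda_path(n_lambdas, lambda_min_ratio)
        lambdas = np.asarray(sorted(np.atleast_1d(lambdas), reverse=True), dtype=float)
        p_act = self._Xs.shape[1]
        betas_std = np.zeros((len(lambdas), p_act))
        beta0 = None
        for k, lam in enumerate(lambdas):
            beta0 = self._fit_at(float(lam), beta0, solver, tol, max_iter)
            betas_std[k] = beta0
        # back to original scale, excluded genes pinned at 0
        beta_full = np.zeros((len(lambdas), self.data.n_genes))
        beta_full[:, self._active] = betas_std / self._scale
        res = CoxnetResults(self, lambdas, beta_full, betas_std)
        if cv_folds is not None:
            lam_best, cv_dev = select_lambda(res, folds=cv_folds, seed=seed)
            res.lambda_best = lam_best
            res.cv_deviance = cv_dev
        return res


@dataclass
class CoxnetResults:
    """Fitted coefficient path plus lambda-selection diagnostics."""

    model: WeightedCoxnet
    lambdas: np.ndarray
    beta: np.ndarray  # n_lambda x p, original covariate scale
    _beta_std: np.ndarray = field(repr=False)
    lambda_best: float | None = None
    cv_deviance: np.ndarray | None = None

    @property
    def alpha(self) -> float:
        return self.model.alpha

    @property
    def penalty_factors(self) -> np.ndarray:
        return self.model.penalty_factors

    def _lambda_index(self, at_lambda: float | None) -> int:
        if at_lambda is None:
            if self.lambda_best is not None:
                at_lambda = self.lambda_best
            else:
                return len(self.lambdas) - 1
        idx = np.flatnonzero(np.isclose(self.lambdas, at_lambda, rtol=1e-10, atol=0.0))
        if len(idx) == 0:
            raise ValueError(f"lambda {at_lambda} is not on the fitted path")
        return int(idx[0])

    def coef(self, at_lambda: float | None = None) -> np.ndarray:
        """Coefficients (original scale) at one lambda; default = lambda_best
        when cross-validation ran, else the smallest lambda of the path."""
        return self.beta[self._lambda_index(at_lambda)]

    def support(self, at_lambda: float | None = None) -> np.ndarray:
        """Indices of genes with nonzero coefficient at the chosen lambda."""
        return np.flatnonzero(self.coef(at_lambda) != 0.0)

    def support_genes(self, at_lambda: float | None = None) -> list[str]:
        return [self.model.data.gene_ids[j] for j in self.support(at_lambda)]

    def predict_relative_risk(
        self, X: np.ndarray, at_lambda: float | None = None
    ) -> np.ndarray:
        """exp(x_i' beta): each sample's hazard relative to baseline (strictly > 0)."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2 or X.shape[1] != self.model.data.n_genes:
            raise ValueError("column count does not match the fitted gene set")
        return np.exp(X @ self.coef(at_lambda))

    def partial_log_likelihood(self, at_lambda: float | None = None) -> float:
        """Training-set Cox partial log-likelihood at the chosen lambda."""
        d = self.model.data
        return partial_log_likelihood(self.coef(at_lambda), d.X, d.time, d.status, self.model.ties)

    def coef_frame(self, at_lambda: float | None = None) -> pd.DataFrame:
        """Nonzero coefficients at the chosen lambda as a tidy frame."""
        b = self.coef(at_lambda)
        nz = np.flatnonzero(b != 0.0)
        return pd.DataFrame(
            {
                "gene_id": [self.model.data.gene_ids[j] for j in nz],
                "beta": b[nz],
                "penalty_factor": self.model.penalty_factors[nz],
                "hazard_ratio": np.exp(b[nz]),
            }
        )

    def summary(self, at_lambda: float | None = None) -> str:
        """Human-readable fit summary at the chosen lambda."""
        idx = self._lambda_index(at_lambda)
        lam = self.lambdas[idx]
        d = self.model.data
        nz = self.support(lam)
        ll = self.partial_log_likelihood(lam)
        ll0 = partial_log_likelihood(np.zeros(d.n_genes), d.X, d.time, d.status, self.model.ties)
        lines = [
            "Weighted elastic-net Cox regression",
            "=" * 58,
            f"n samples            {d.n_samples:>10d}",
            f"n events             {d.n_events:>10d}",
            f"n genes              {d.n_genes:>10d}  (excluded: {int(self.model.excluded.sum())})",
            f"alpha                {self.alpha:>10.4g}",
            f"penalty mode         {self.model.penalty_mode:>10s}",
            f"lambda               {lam:>10.4g}"
            + ("  (CV-selected)" if self.lambda_best is not None and np.isclose(lam, self.lambda_best) else ""),
            f"support size         {len(nz):>10d}",
            f"partial log-lik      {ll:>10.4f}  (null: {ll0:.4f})",
            "-" * 58,
        ]
        cf = self.coef_frame(lam).sort_values("beta", key=np.abs, ascending=False)
        if len(cf):
            lines.append(f"{'gene':<18s}{'beta':>12s}{'HR':>10s}{'factor':>10s}")
            for _, r in cf.iterrows():
                lines.append(
                    f"{r.gene_id:<18s}{r.beta:>12.5f}{r.hazard_ratio:>10.4f}{r.penalty_factor:>10.4g}"
                )
        else:
            lines.append("(empty support)")
        return "\n".join(lines)

    def to_frame(self) -> pd.DataFrame:
        """Full path as a long frame (lambda, gene_id, beta), nonzero entries only."""
        recs = []
        for lam, b in zip(self.lambdas, self.beta):
            for j in np.flatnonzero(b != 0.0):
                recs.append((lam, self.model.data.gene_ids[j], b[j]))
        return pd.DataFrame(recs, columns=["lambda", "gene_id", "beta"])


def _stratified_fold_labels(status: np.ndarray, folds: int, rng: np.random.Generator) -> np.ndarray:
    """Assign fold labels separately within censored and event strata."""
    labels = np.empty(len(status), dtype=int)
    for value in (0, 1):
        idx = np.flatnonzero(status == value)
        perm = rng.permutation(idx)
        labels[perm] = np.arange(len(perm)) % folds
    return labels


def select_lambda(
    results: CoxnetResults, folds: int = 5, seed: int = 0, max_retries: int = 5
) -> tuple[float, np.ndarray]:
    """Choose lambda by cross-validated partial-likelihood deviance.

    Uses the Verweij–van Houwelingen form: for each fold k the deviance
    contribution is -2 [ l_full(beta^(-k)) - l_train^(-k)(beta^(-k)) ],
    which stays well defined when a fold's own partial likelihood would be
    degenerate. Folds are stratified by event status; a fold layout leaving
    any training part without events is re-drawn a bounded number of times.
    """
    if folds < 2:
        raise ValueError("need at least 2 folds")
    model = results.model
    data = model.data
    for attempt in range(max_retries):
        rng = np.random.default_rng(np.random.SeedSequence([seed, attempt, 823]).generate_state(1)[0])
        labels = _stratified_fold_labels(data.status, folds, rng)
        if all(data.status[labels != k].sum() > 0 for k in range(folds)):
            break
    else:
        raise RuntimeError("could not build folds with events in every training part")
    dev = np.zeros(len(results.lambdas))
    for k in range(folds):
        train_idx = np.flatnonzero(labels != k)
        sub = data.subset(train_idx)
        sub_model = WeightedCoxnet(
            sub,
            alpha=model.alpha,
            penalty_factors=model.penalty_factors,
            excluded=model.excluded,
            penalty_mode=model.penalty_mode,
            standardize=model.standardize,
            ties=model.ties,
        )
        sub_res = sub_model.fit(lambdas=results.lambdas, solver="reduction"
                                if model.penalty_mode == "literal" and np.all(model.penalty_factors[~model.excluded] > 0)
                                else "direct")
        for i, b in enumerate(sub_res.beta):
            l_full = partial_log_likelihood(b, data.X, data.time, data.status, model.ties)
            l_train = partial_log_likelihood(b, sub.X, sub.time, sub.status, model.ties)
            dev[i] += -2.0 * (l_full - l_train)
    best = int(np.argmin(dev))
    return float(results.lambdas[best]), dev
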