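"""Correlation-dissimilarity penalty weights.

For a shared gene set measured in two conditions (tumor and normal), each
gene j has a correlation profile: its vector of correlations with the
remaining p-1 genes in that condition. The angle between the tumor and
normal profiles,

    d_j = arccos( <sigma_T(j), sigma_N(j)> / (||sigma_T(j)|| ||sigma_N(j)||) ),

measures how much gene j's co-expression pattern is rewired between the two
tissues: 0 for an identical pattern, pi for an opposite one. Dissimilarities
are max-normalized to w_j = d_j / max_k d_k in (0, 1] and then transformed
into per-gene penalty factors for the elastic-net Cox model; every inverting
transformation penalizes strongly-rewired genes less, so they are favoured
during feature selection. Genes with d_j = 0 (no rewiring at all) are
excluded from the model support outright.
"""

from __future__ import annotations

from dataclasses import dataclass
from pathlib import Path
from typing import Callable

import numpy as np
import pandas as pd
from scipy import stats

from .data import ExpressionMatrix

__all__ = [
    "CorrelationProfileSet",
    "PenaltyWeights",
    "TRANSFORMS",
    "correlation_matrix",
    "angular_dissimilarity",
    "normalize_weights",
    "transform_weights",
    "tcox_weights",
    "write_weights",
    "read_weights",
]

_SYMMETRY_TOL = 1e-12


@dataclass
class CorrelationProfileSet:
    """A p x p gene-gene correlation matrix for one condition.

    ``profile(j)`` is the length p-1 column of gene j's correlations with the
    remaining genes; the self-correlation (always 1 in both conditions) is
    excluded so that it cannot shrink every between-condition angle toward 0.
    """

    sigma: np.ndarray
    gene_ids: list[str]
    condition: str = ""

    def __post_init__(self) -> None:
        self.sigma = np.asarray(self.sigma, dtype=float)
        p = self.sigma.shape[0]
        if self.sigma.shape != (p, p):
            raise ValueError("correlation matrix must be square")
        if len(self.gene_ids) != p:
            raise ValueError("gene_ids length must match matrix size")
        if np.max(np.abs(self.sigma - self.sigma.T)) > _SYMMETRY_TOL:
            raise ValueError("correlation matrix is not symmetric")
        if not np.allclose(np.diag(self.sigma), 1.0, atol=_SYMMETRY_TOL):
            raise ValueError("correlation matrix diagonal must be 1")
        if np.min(self.sigma) < -1 - _SYMMETRY_TOL or np.max(self.sigma) > 1 + _SYMMETRY_TOL:
            raise ValueError("correlation entries must lie in [-1, 1]")
        np.fill_diagonal(self.sigma, 1.0)

    @property
    def n_genes(self) -> int:
        return self.sigma.shape[0]

    def profile(self, j: int) -> np.ndarray:
        """Gene j's correlations with the remaining genes (diagonal excluded)."""
        col = self.sigma[:, j]
        return np.delete(col, j)

    def profiles(self) -> np.ndarray:
        """All profiles as a (p-1) x p matrix, column j = profile(j)."""
        p = self.n_genes
        out = np.empty((p - 1, p))
        for j in range(p):
            out[:, j] = self.profile(j)
        return out


# transform name -> elementwise map of w in (0, 1] to a penalty factor
TRANSFORMS: dict[str, Callable[[np.ndarray], np.ndarray]] = {
    "one_minus": lambda w: 1.0 - w,
    "one_minus_cubed_arg": lambda w: 1.0 - w**3,
    "cubed_one_minus": lambda w: (1.0 - w) ** 3,
    "inverse": lambda w: 1.0 / w,
    "exp_neg_cubed": lambda w: np.exp(-(w**3)),
    "exp_cubed_one_minus": lambda w: np.exp((1.0 - w) ** 3),
}


@dataclass
class PenaltyWeights:
    """Per-gene penalty factors derived from tumor/normal correlation rewiring.

    ``d`` are the raw angles (radians, in [0, pi]); ``w`` the max-normalized
    weights; ``factors`` the transformed penalty factors actually passed to
    the solver; ``excluded`` flags zero-angle genes, which are kept out of the
    model support instead of receiving a finite factor.
    """

    gene_ids: list[str]
    d: np.ndarray
    w: np.ndarray
    factors: np.ndarray
    excluded: np.ndarray
    transform_kind: str = "inverse"

    def __post_init__(self) -> None:
        self.d = np.asarray(self.d, dtype=float)
        self.w = np.asarray(self.w, dtype=float)
        self.factors = np.asarray(self.factors, dtype=float)
        self.excluded = np.asarray(self.excluded, dtype=bool)
        active = ~self.excluded
        if active.any():
            f = self.factors[active]
            # factor 0 (an unpenalized gene, e.g. one_minus at w = 1) is legal;
            # negative or non-finite factors are not
            if not np.all(np.isfinite(f)) or np.any(f < 0):
                raise ValueError("non-excluded penalty factors must be finite and >= 0")

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "d_radians": self.d,
                "w": self.w,
                "factor": self.factors,
                "excluded": self.excluded,
            }
        )


def correlation_matrix(
    X: ExpressionMatrix, method: str = "pearson"
) -> CorrelationProfileSet:
    """Gene-gene correlation matrix of one condition's expression.

    Pearson by default (the angle computation operates on correlation vectors
    without rank assumptions); ``method='spearman'`` ranks first. Requires at
    least 3 samples and rejects zero-variance genes by name.
    """
    if X.n_samples < 3:
        raise ValueError(f"need at least 3 samples to estimate correlations, got {X.n_samples}")
    X.require_variable_genes()
    if method == "pearson":
        sigma = np.corrcoef(X.values, rowvar=False)
    elif method == "spearman":
        ranked = np.apply_along_axis(stats.rankdata, 0, X.values)
        sigma = np.corrcoef(ranked, rowvar=False)
    else:
        raise ValueError(f"unknown correlation method: {method!r}")
    sigma = np.clip((sigma + sigma.T) / 2.0, -1.0, 1.0)
    np.fill_diagonal(sigma, 1.0)
    return CorrelationProfileSet(sigma, list(X.gene_ids), X.condition)


def angular_dissimilarity(
    sigma_T: CorrelationProfileSet, sigma_N: CorrelationProfileSet
) -> np.ndarray:
    """Per-gene angle (radians) between tumor and normal correlation profiles.

    Evaluated in the numerically stable chord form
    d = 2 arcsin(||u/||u|| - v/||v||| / 2), algebraically identical to the
    arccos of the clipped cosine similarity but exact at the boundaries:
    identical profiles give exactly 0 (never NaN or a ~1e-8 rounding angle)
    and antipodal profiles exactly pi. Symmetric in the two conditions.
    """
    if sigma_T.gene_ids != sigma_N.gene_ids:
        raise ValueError("the two correlation sets must cover the same ordered gene list")
    pt = sigma_T.profiles()
    pn = sigma_N.profiles()
    norm_t = np.linalg.norm(pt, axis=0)
    norm_n = np.linalg.norm(pn, axis=0)
    for name, norms in (("tumor", norm_t), ("normal", norm_n)):
        if np.any(norms == 0.0):
            bad = [g for g, nz in zip(sigma_T.gene_ids, norms == 0.0) if nz]
            raise ValueError(f"zero-norm {name} correlation profile for gene(s): {', '.join(bad)}")
    chord = np.linalg.norm(pt / norm_t - pn / norm_n, axis=0)
    return 2.0 * np.arcsin(np.clip(chord / 2.0, 0.0, 1.0))


def normalize_weights(d: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Max-normalize angles to w = d / max(d); flag zero-angle genes as excluded.

    Zero-angle genes (identical profiles in both conditions) carry no
    rewiring signal and are discarded from the model support downstream.
    """
    d = np.asarray(d, dtype=float)
    dmax = d.max(initial=-np.inf)
    if not np.isfinite(dmax) or dmax <= 0.0:
        raise ValueError("all dissimilarities are zero: no rewiring signal to weight by")
    return d / dmax, d == 0.0


def transform_weights(
    w: np.ndarray, kind: str = "inverse", excluded: np.ndarray | None = None
) -> np.ndarray:
    """Map normalized weights to penalty factors.

    All inverting kinds assign smaller factors to larger w, so the most
    rewired genes are the least penalized. The default ``inverse`` (1/w) is
    the transformation that best separated high- and low-risk survival
    curves in the method's original evaluation. Under ``inverse``, w = 0 is
    only legal for genes already flagged excluded (their factor is returned
    as +inf and the solver keeps them out of the support).
    """
    w = np.asarray(w, dtype=float)
    if np.any(w < 0) or np.any(w > 1):
        raise ValueError("weights must lie in [0, 1]")
    if kind not in TRANSFORMS:
        raise ValueError(f"unknown transform kind {kind!r}; expected one of {sorted(TRANSFORMS)}")
    excluded = (
        np.zeros(w.shape, dtype=bool) if excluded is None else np.asarray(excluded, dtype=bool)
    )
    if kind == "inverse":
        if np.any((w == 0.0) & ~excluded):
            raise ValueError("w = 0 under the inverse transform requires the gene to be excluded")
        factors = np.full(w.shape, np.inf)
        nz = w > 0.0
        factors[nz] = 1.0 / w[nz]
        return factors
    return TRANSFORMS[kind](w)


def tcox_weights(
    tumor: ExpressionMatrix,
    normal: ExpressionMatrix,
    transform: str = "inverse",
    method: str = "pearson",
) -> PenaltyWeights:
    """Full weight pipeline: correlations per condition, angles, normalization, transform."""
    if tumor.gene_ids != normal.gene_ids:
        raise ValueError("tumor and normal matrices must share the same ordered gene list")
    sig_t = correlation_matrix(tumor, method=method)
    sig_n = correlation_matrix(normal, method=method)
    d = angular_dissimilarity(sig_t, sig_n)
    w, excluded = normalize_weights(d)
    factors = transform_weights(w, kind=transform, excluded=excluded)
    return PenaltyWeights(list(tumor.gene_ids), d, w, factors, excluded, transform)


def write_weights(weights: PenaltyWeights, path: str | Path, sep: str = "\t") -> None:
    weights.to_frame().to_csv(path, sep=sep, index=False)


def read_weights(path: str | Path, sep: str = "\t") -> PenaltyWeights:
    df = pd.read_csv(path, sep=sep, comment="#")
    return PenaltyWeights(
        df["gene_id"].astype(str).tolist(),
        df["d_radians"].to_numpy(float),
        df["w"].to_numpy(float),
        df["factor"].to_numpy(float),
        df["excluded"].to_numpy(bool),
    )
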