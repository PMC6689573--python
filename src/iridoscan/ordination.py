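"""Redundancy analysis (RDA), permutation tests and variance partitioning.

RDA is the constrained ordination at the heart of the dichromatism tests:
the multivariate colour-summary matrix Y is regressed on a constraint
design X (e.g. species identity), optionally after partialling out a
conditioning design Z (e.g. sex); the constrained axes are the principal
axes of the fitted values and the residual axes those of the residuals.
Significance is assessed with an ANOVA-like permutation pseudo-F test, and
explained variance is decomposed among predictor sets with
Ezekiel-adjusted R².

Everything here is implemented from first principles on top of numpy
linear algebra (QR/SVD); the module also exposes a small sklearn-style
estimator class :class:`RDA`.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd
from statsmodels.stats.multitest import multipletests

__all__ = [
    "standardize",
    "design_matrix",
    "rda",
    "permutation_test",
    "adjusted_r2",
    "variance_partition",
    "per_variable_anova",
    "RDA",
    "OrdinationResult",
    "VariancePartition",
]


# ---------------------------------------------------------------------------
# basic linear-algebra helpers

def _as_matrix(M) -> np.ndarray:
    A = np.asarray(M, dtype=float)
    if A.ndim == 1:
        A = A[:, None]
    if A.ndim != 2:
        raise ValueError("expected a 1-D or 2-D array")
    return A


def _center(M: np.ndarray) -> np.ndarray:
    return M - M.mean(axis=0)


def _orthonormal_basis(M: np.ndarray, *, require_full_rank: bool = False) -> np.ndarray:
    """Orthonormal basis of the column space of ``M`` (rank-revealing)."""
    if M.shape[1] == 0:
        return np.empty((M.shape[0], 0))
    q, r = np.linalg.qr(M)
    keep = np.abs(np.diag(r)) > 1e-10 * max(1.0, np.abs(np.diag(r)).max())
    if require_full_rank and not keep.all():
        raise ValueError("constraint design X is rank-deficient")
    return q[:, keep]


def _residualize(M: np.ndarray, basis: np.ndarray) -> np.ndarray:
    if basis.shape[1] == 0:
        return M
    return M - basis @ (basis.T @ M)


def standardize(table) -> np.ndarray:
    """Scale each column to zero mean, unit (sample) variance.

    Raises if a column is constant, naming it.
    """
    if isinstance(table, pd.DataFrame):
        names = list(table.columns)
        X = table.to_numpy(dtype=float)
    else:
        X = _as_matrix(table)
        names = [str(i) for i in range(X.shape[1])]
    if X.shape[0] < 2:
        raise ValueError("need at least 2 rows to standardize")
    if np.isnan(X).any():
        raise ValueError("missing values are not allowed")
    sd = X.std(axis=0, ddof=1)
    bad = np.where(sd == 0)[0]
    if bad.size:
        raise ValueError(f"constant column(s) cannot be standardized: {[names[i] for i in bad]}")
    Z = (X - X.mean(axis=0)) / sd
    if isinstance(table, pd.DataFrame):
        return pd.DataFrame(Z, columns=names, index=table.index)
    return Z


def design_matrix(sheet: pd.DataFrame, columns: Sequence[str]) -> np.ndarray:
    """Dummy-code categorical sample-sheet columns, dropping one level each."""
    missing = [c for c in columns if c not in sheet.columns]
    if missing:
        raise ValueError(f"sample sheet is missing columns: {missing}")
    dummies = pd.get_dummies(sheet[list(columns)].astype(str), drop_first=True)
    return dummies.to_numpy(dtype=float)


# ---------------------------------------------------------------------------
# results containers

@dataclass
class OrdinationResult:
    """Eigenstructure and test statistics of one (partial) RDA."""

    constrained_eigenvalues: np.ndarray
    residual_eigenvalues: np.ndarray
    prop_variance: np.ndarray  # constrained then residual axes; sums to 1
    site_scores: np.ndarray
    variable_scores: np.ndarray
    total_inertia: float
    pseudo_F: float
    p_value: float | None = None
    n_perm: int = 0
    adj_R2: float | None = None
    seed: int | None = None

    def axis_table(self) -> pd.DataFrame:
        k = len(self.constrained_eigenvalues)
        names = [f"RDA{i+1}" for i in range(k)] + [
            f"PC{i+1}" for i in range(len(self.residual_eigenvalues))
        ]
        eig = np.concatenate([self.constrained_eigenvalues, self.residual_eigenvalues])
        return pd.DataFrame({"axis": names, "eigenvalue": eig, "prop_variance": self.prop_variance})


@dataclass
class VariancePartition:
    """Adjusted-R² decomposition for two predictor sets."""

    adj_r2_x1: float
    adj_r2_x2: float
    adj_r2_both: float
    unique_x1: float = field(init=False)
    unique_x2: float = field(init=False)
    shared: float = field(init=False)
    residual: float = field(init=False)

    def __post_init__(self) -> None:
        self.unique_x1 = self.adj_r2_both - self.adj_r2_x2
        self.unique_x2 = self.adj_r2_both - self.adj_r2_x1
        self.shared = self.adj_r2_x1 + self.adj_r2_x2 - self.adj_r2_both
        self.residual = 1.0 - self.adj_r2_both


# ---------------------------------------------------------------------------
# core computations

def _prepare(Y, X, Z=None, *, require_full_rank: bool = True):
    """Center, condition and rank-check; returns pieces shared by all ops."""
    Y = _as_matrix(Y)
    X = _as_matrix(X)
    n = Y.shape[0]
    if X.shape[0] != n:
        raise ValueError("Y and X must have the same number of rows")
    Yc = _center(Y)
    Xc = _center(X)
    if Z is not None:
        Z = _as_matrix(Z)
        if Z.shape[0] != n:
            raise ValueError("Y and Z must have the same number of rows")
        Zb = _orthonormal_basis(_center(Z))
    else:
        Zb = np.empty((n, 0))
    p_z = Zb.shape[1]
    Yr = _residualize(Yc, Zb)
    Xr = _residualize(Xc, Zb)
    Qx = _orthonormal_basis(Xr, require_full_rank=require_full_rank)
    q = Qx.shape[1]
    if n <= q + p_z + 1:
        raise ValueError(f"too few rows (n={n}) for {q} constraint and {p_z} conditioning columns")
    return Yr, Qx, Zb, q, p_z, n


def _pseudo_f(ss_con: float, ss_res: float, q: int, n: int, p_z: int) -> float:
    return (ss_con / q) / (ss_res / (n - q - p_z - 1))


def rda(Y, X, Z=None) -> OrdinationResult:
    """Redundancy analysis of Y constrained by X, conditioned on Z.

    Y should already be column-standardized when variables are on different
    scales (see :func:`standardize`); it is centered here in any case.
    """
    Yr, Qx, Zb, q, p_z, n = _prepare(Y, X, Z)
    Yhat = Qx @ (Qx.T @ Yr)
    Yres = Yr - Yhat

    denom = n - 1
    total = float(np.sum(Yr**2)) / denom
    u, s, vt = np.linalg.svd(Yhat, full_matrices=False)
    k = min(q, Yr.shape[1])
    eig_c = (s[:k] ** 2) / denom
    ur, sr, vtr = np.linalg.svd(Yres, full_matrices=False)
    kr = int(np.sum(sr**2 / denom > 1e-12 * max(total, 1.0)))
    eig_r = (sr[:kr] ** 2) / denom

    ss_con = float(np.sum(Yhat**2))
    ss_res = float(np.sum(Yres**2))
    prop = np.concatenate([eig_c, eig_r]) / total if total > 0 else np.concatenate([eig_c, eig_r])

    return OrdinationResult(
        constrained_eigenvalues=eig_c,
        residual_eigenvalues=eig_r,
        prop_variance=prop,
        site_scores=u[:, :k] * s[:k],
        variable_scores=vt[:k].T,
        total_inertia=total,
        pseudo_F=_pseudo_f(ss_con, ss_res, q, n, p_z),
        adj_R2=adjusted_r2(Y, X) if Z is None else None,
    )


def permutation_test(
    Y, X, Z=None, n_perm: int = 9999, seed: int | None = None
) -> tuple[float, float]:
    """ANOVA-like permutation test for (partial) RDA.

    Under conditioning the reduced-model scheme is used: residuals of Y on
    Z are row-permuted and re-residualized before computing the permuted
    pseudo-F.  Returns ``(pseudo_F, p_value)`` with
    ``p = (1 + #{F* >= F}) / (1 + n_perm)``.
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    Yr, Qx, Zb, q, p_z, n = _prepare(Y, X, Z)
    ss_tot = float(np.sum(Yr**2))
    ss_con = float(np.sum((Qx.T @ Yr) ** 2))
    f_obs = _pseudo_f(ss_con, ss_tot - ss_con, q, n, p_z)

    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_perm):
        perm = rng.permutation(n)
        Yp = _residualize(Yr[perm], Zb)
        sst = float(np.sum(Yp**2))
        ssc = float(np.sum((Qx.T @ Yp) ** 2))
        f_p = _pseudo_f(ssc, sst - ssc, q, n, p_z)
        if f_p >= f_obs:
            count += 1
    p = (1 + count) / (1 + n_perm)
    return f_obs, p


def adjusted_r2(Y, X) -> float:
    """Ezekiel-adjusted R² of the multivariate regression of Y on X.

    Collinear columns are tolerated here (rank is used for the adjustment),
    since combined variance-partition designs may overlap.
    """
    Yr, Qx, _, q, _, n = _prepare(Y, X, None, require_full_rank=False)
    ss_tot = float(np.sum(Yr**2))
    if ss_tot == 0:
        return 0.0
    r2 = float(np.sum((Qx.T @ Yr) ** 2)) / ss_tot
    return 1.0 - (1.0 - r2) * (n - 1) / (n - q - 1)


def variance_partition(Y, X1, X2) -> VariancePartition:
    """Partition adjusted explained variance between predictor sets X1, X2."""
    X1 = _as_matrix(X1)
    X2 = _as_matrix(X2)
    both = np.hstack([X1, X2])
    return VariancePartition(
        adj_r2_x1=adjusted_r2(Y, X1),
        adj_r2_x2=adjusted_r2(Y, X2),
        adj_r2_both=adjusted_r2(Y, both),
    )


def per_variable_anova(
    Y, X, Z=None, n_perm: int = 9999, seed: int | None = None,
    columns: Sequence[str] | None = None,
) -> pd.DataFrame:
    """Permutation F-test per response column with Holm correction.

    Thin convenience wrapper applying the permutation engine to each column
    of Y separately and adjusting p-values across columns (Holm).
    """
    Ym = _as_matrix(Y)
    if columns is None:
        columns = (
            list(Y.columns) if isinstance(Y, pd.DataFrame)
            else [f"y{i}" for i in range(Ym.shape[1])]
        )
    rows = []
    rng = np.random.default_rng(seed)
    for j, name in enumerate(columns):
        f, p = permutation_test(
            Ym[:, j], X, Z, n_perm=n_perm, seed=int(rng.integers(2**31 - 1))
        )
        rows.append({"variable": name, "pseudo_F": f, "p_value": p})
    out = pd.DataFrame(rows)
    out["p_holm"] = multipletests(out["p_value"], method="holm")[1]
    return out


# ---------------------------------------------------------------------------
# sklearn-style estimator

class RDA:
    """Redundancy analysis as a sklearn-style estimator.

    Parameters
    ----------
    n_permutations:
        Permutations for the pseudo-F test (0 disables the test).
    random_state:
        Seed for the permutation stream; recorded on the result.

    After :meth:`fit`, results are exposed as trailing-underscore
    attributes (``constrained_eigenvalues_``, ``pseudo_F_``, ``p_value_``,
    ``site_scores_`` ...).
    """

    def __init__(self, n_permutations: int = 9999, random_state: int | None = None):
        self.n_permutations = n_permutations
        self.random_state = random_state

    # minimal get/set_params so the class composes with sklearn tooling
    def get_params(self, deep: bool = True) -> dict:
        return {"n_permutations": self.n_permutations, "random_state": self.random_state}

    def set_params(self, **params) -> "RDA":
        for k, v in params.items():
            if k not in self.get_params():
                raise ValueError(f"invalid parameter {k!r}")
            setattr(self, k, v)
        return self

    def fit(self, Y, X, Z=None) -> "RDA":
        res = rda(Y, X, Z)
        if self.n_permutations:
            f, p = permutation_test(
                Y, X, Z, n_perm=self.n_permutations, seed=self.random_state
            )
            res.pseudo_F, res.p_value, res.n_perm = f, p, self.n_permutations
            res.seed = self.random_state
        self.result_ = res
        self.constrained_eigenvalues_ = res.constrained_eigenvalues
        self.residual_eigenvalues_ = res.residual_eigenvalues
        self.prop_variance_ = res.prop_variance
        self.site_scores_ = res.site_scores
        self.variable_scores_ = res.variable_scores
        self.total_inertia_ = res.total_inertia
        self.pseudo_F_ = res.pseudo_F
        self.p_value_ = res.p_value
        self.adj_r2_ = res.adj_R2
        return self

    def transform(self, Y=None) -> np.ndarray:
        """Site scores on the constrained axes of the fitted ordination."""
        if not hasattr(self, "result_"):
            raise RuntimeError("RDA instance is not fitted")
        return self.site_scores_
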