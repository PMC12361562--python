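"""Gaussian graphical model core.

Maps between correlation, precision and partial-correlation representations,
the Gaussian ML discrepancy and fit indices, edge significance tests and
thresholding, and the two node-centrality primitives (expected influence and
predictability). Everything downstream — the measurement models, the pooled
meta-analytic network, the centrality bootstrap — is built on this module.

A network is parameterised by its partial-correlation matrix omega
(symmetric, zero diagonal): omega[i, j] is the correlation between items i
and j conditional on the remaining p-2 items. The implied correlation matrix
is recovered by inverting I - omega and standardising, so omega and R are in
one-to-one correspondence on the positive-definite cone.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.moment_helpers import cov2corr


# ---------------------------------------------------------------------------
# matrix maps

def pcor_from_corr(R: np.ndarray) -> np.ndarray:
    """Partial-correlation matrix of a positive-definite correlation matrix.

    With K = R^{-1}: omega[i, j] = -K[i, j] / sqrt(K[i, i] K[j, j]) off the
    diagonal and 0 on it.
    """
    R = np.asarray(R, dtype=float)
    _check_square_symmetric(R)
    cond = np.linalg.cond(R)
    if cond > 1e12:
        raise np.linalg.LinAlgError(
            f"correlation matrix is numerically singular (condition number {cond:.3g})"
        )
    K = np.linalg.inv(R)
    d = np.sqrt(np.diag(K))
    omega = -K / np.outer(d, d)
    np.fill_diagonal(omega, 0.0)
    return (omega + omega.T) / 2.0


def corr_from_pcor(omega: np.ndarray) -> np.ndarray:
    """Unique correlation matrix whose partial correlations equal ``omega``.

    Inverts I - omega and rescales to unit diagonal; requires I - omega to be
    positive definite. Exact inverse of :func:`pcor_from_corr` (round trip is
    accurate to ~1e-12).
    """
    omega = np.asarray(omega, dtype=float)
    _check_square_symmetric(omega)
    if np.any(np.abs(np.diag(omega)) > 1e-12):
        raise ValueError("partial-correlation matrix must have zero diagonal")
    A = np.eye(omega.shape[0]) - omega
    lam_min = np.linalg.eigvalsh(A)[0]
    if lam_min <= 0:
        raise np.linalg.LinAlgError(
            f"I - omega is not positive definite (min eigenvalue {lam_min:.3g})"
        )
    M = np.linalg.inv(A)
    R = cov2corr(M)
    return (R + R.T) / 2.0


def is_positive_definite(A: np.ndarray, tol: float = 0.0) -> bool:
    return bool(np.linalg.eigvalsh(np.asarray(A, dtype=float))[0] > tol)


def nearest_correlation(A: np.ndarray, eig_floor: float = 1e-6) -> np.ndarray:
    """Project a symmetric matrix to a positive-definite correlation matrix.

    Eigenvalues are clipped at ``eig_floor`` and the result is rescaled to
    unit diagonal. Idempotent on matrices that are already positive definite
    with unit diagonal.
    """
    A = np.asarray(A, dtype=float)
    A = (A + A.T) / 2.0
    lam, Q = np.linalg.eigh(A)
    if lam[0] > eig_floor and np.allclose(np.diag(A), 1.0, atol=1e-12):
        return A
    lam = np.clip(lam, eig_floor, None)
    B = (Q * lam) @ Q.T
    R = cov2corr(B)
    return (R + R.T) / 2.0


def _check_square_symmetric(A: np.ndarray) -> None:
    if A.ndim != 2 or A.shape[0] != A.shape[1]:
        raise ValueError(f"expected a square matrix, got shape {A.shape}")
    if not np.allclose(A, A.T, atol=1e-8):
        raise ValueError("matrix is not symmetric")


# ---------------------------------------------------------------------------
# edge inference

def edge_pvalues(omega: np.ndarray, N: int) -> np.ndarray:
    """Two-sided p-values for each partial correlation.

    Classical test for a partial correlation conditioning on k = p - 2
    remaining variables: t = w * sqrt((N - 2 - k) / (1 - w^2)) on N - 2 - k
    degrees of freedom.
    """
    omega = np.asarray(omega, dtype=float)
    p = omega.shape[0]
    k = p - 2
    df = N - 2 - k
    if df <= 0:
        raise ValueError(f"need N > {p}, got N={N}")
    w = np.clip(omega, -1.0, 1.0)
    at_unit = np.abs(w) >= 1.0 - 1e-15
    if np.any(at_unit & ~np.eye(p, dtype=bool)):
        warnings.warn("partial correlation at |1|; p-value set to 0", stacklevel=2)
    with np.errstate(divide="ignore"):
        t = w * np.sqrt(df / np.maximum(1.0 - w**2, 1e-300))
    pvals = 2.0 * stats.t.sf(np.abs(t), df)
    np.fill_diagonal(pvals, 1.0)
    return pvals


@dataclass
class GGMNetwork:
    """A partial-correlation network over an ordered node set.

    ``omega`` holds the (possibly thresholded) edge weights; when an edge is
    removed by thresholding the pre-threshold weights remain available in
    ``omega_full``.
    """

    nodes: tuple[str, ...]
    omega: np.ndarray
    se: np.ndarray | None = None
    pvals: np.ndarray | None = None
    retained: np.ndarray | None = None
    omega_full: np.ndarray | None = None

    def __post_init__(self) -> None:
        self.omega = np.asarray(self.omega, dtype=float)
        _check_square_symmetric(self.omega)
        if self.omega.shape[0] != len(self.nodes):
            raise ValueError("omega dimension does not match node count")
        if np.any(np.abs(np.diag(self.omega)) > 1e-10):
            raise ValueError("network matrix must be hollow (zero diagonal)")
        if np.any(np.abs(self.omega) >= 1.0):
            raise ValueError("edge weights must lie in (-1, 1)")
        if self.omega_full is None:
            self.omega_full = self.omega.copy()

    @property
    def p(self) -> int:
        return len(self.nodes)

    def implied_correlation(self) -> np.ndarray:
        return corr_from_pcor(self.omega)

    def n_edges(self) -> int:
        mask = self.retained if self.retained is not None else (self.omega != 0)
        return int(np.triu(mask, 1).sum())

    def to_edge_list(self) -> pd.DataFrame:
        """Edge-list DataFrame: node_i, node_j, weight, se, p, retained."""
        iu, ju = np.triu_indices(self.p, 1)
        df = pd.DataFrame(
            {
                "node_i": [self.nodes[i] for i in iu],
                "node_j": [self.nodes[j] for j in ju],
                "weight": self.omega_full[iu, ju],
                "se": self.se[iu, ju] if self.se is not None else np.nan,
                "p": self.pvals[iu, ju] if self.pvals is not None else np.nan,
                "retained": (
                    self.retained[iu, ju]
                    if self.retained is not None
                    else (self.omega[iu, ju] != 0)
                ).astype(int),
            }
        )
        return df

    def to_matrix_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.omega, index=self.nodes, columns=self.nodes)

    def to_graphml(self, path) -> None:
        """Write the retained network as GraphML (for external visualizers)."""
        import networkx as nx

        g = nx.Graph()
        g.add_nodes_from(self.nodes)
        for row in self.to_edge_list().itertuples():
            if row.retained:
                g.add_edge(row.node_i, row.node_j, weight=float(row.weight))
        nx.write_graphml(g, path)


def network_from_correlation(R: np.ndarray, nodes, N: int | None = None) -> GGMNetwork:
    """Saturated GGM of a correlation matrix, with p-values when N is given."""
    omega = pcor_from_corr(R)
    pvals = edge_pvalues(omega, N) if N is not None else None
    return GGMNetwork(nodes=tuple(nodes), omega=omega, pvals=pvals)


def threshold(network: GGMNetwork, alpha: float = 0.05) -> GGMNetwork:
    """Zero out edges with p >= alpha; no refit of the surviving edges."""
    if network.pvals is None:
        raise ValueError("network has no p-values; cannot threshold")
    retained = network.pvals < alpha
    np.fill_diagonal(retained, False)
    retained = retained & retained.T
    omega = np.where(retained, network.omega_full, 0.0)
    return replace(network, omega=omega, retained=retained, omega_full=network.omega_full)


# ---------------------------------------------------------------------------
# likelihood and fit indices

def gaussian_discrepancy(S: np.ndarray, Sigma: np.ndarray, N: int, p: int | None = None):
    """Gaussian ML discrepancy between sample and model covariance.

    Returns ``(F, loglik, chisq)`` where
    F = ln|Sigma| - ln|S| + tr(S Sigma^{-1}) - p, chisq = (N - 1) F, and
    loglik = -(N/2)(p ln 2pi + ln|Sigma| + tr(S Sigma^{-1})) (the standard
    Wishart-free convention; constants cancel in model comparisons).
    """
    S = np.asarray(S, dtype=float)
    Sigma = np.asarray(Sigma, dtype=float)
    if p is None:
        p = S.shape[0]
    sign_s, logdet_s = np.linalg.slogdet(S)
    sign_m, logdet_m = np.linalg.slogdet(Sigma)
    if sign_s <= 0 or sign_m <= 0:
        raise np.linalg.LinAlgError("S and Sigma must be positive definite")
    tr = float(np.trace(np.linalg.solve(Sigma, S)))
    F = logdet_m - logdet_s + tr - p
    loglik = -(N / 2.0) * (p * np.log(2.0 * np.pi) + logdet_m + tr)
    chisq = (N - 1.0) * F
    return float(F), float(loglik), float(chisq)


@dataclass
class FitIndices:
    """Chi-square based fit statistics for a fitted covariance-structure model."""

    chisq: float
    df: int
    chisq_baseline: float
    df_baseline: int
    N: int
    loglik: float
    n_params: int
    nfi: float = field(init=False)
    rfi: float = field(init=False)
    tli: float = field(init=False)
    cfi: float = field(init=False)
    rmsea: float = field(init=False)
    rmsea_low: float = field(init=False)
    rmsea_high: float = field(init=False)
    aic: float = field(init=False)
    bic: float = field(init=False)

    def __post_init__(self) -> None:
        c, df = self.chisq, self.df
        cb, dfb = self.chisq_baseline, self.df_baseline
        if dfb < df:
            raise ValueError("baseline df must be >= model df")
        self.nfi = (cb - c) / cb if cb > 0 else np.nan
        if df > 0 and dfb > 0:
            ratio_b = cb / dfb
            self.rfi = 1.0 - (c / df) / ratio_b
            self.tli = (ratio_b - c / df) / (ratio_b - 1.0)
        else:
            # saturated model: ratio-based indices are undefined
            self.rfi = np.nan
            self.tli = np.nan
        num = max(c - df, 0.0)
        den = max(cb - dfb, c - df, 0.0)
        self.cfi = 1.0 - num / den if den > 0 else 1.0
        if df > 0:
            self.rmsea = float(np.sqrt(max(c - df, 0.0) / (df * (self.N - 1))))
            self.rmsea_low, self.rmsea_high = _rmsea_ci(c, df, self.N)
        else:
            self.rmsea = 0.0
            self.rmsea_low = self.rmsea_high = 0.0
        self.aic = -2.0 * self.loglik + 2.0 * self.n_params
        self.bic = -2.0 * self.loglik + self.n_params * np.log(self.N)

    def to_series(self) -> pd.Series:
        return pd.Series(
            {
                "df": self.df,
                "chisq": self.chisq,
                "nfi": self.nfi,
                "tli": self.tli,
                "rfi": self.rfi,
                "cfi": self.cfi,
                "aic": self.aic,
                "bic": self.bic,
                "rmsea": self.rmsea,
                "rmsea_low": self.rmsea_low,
                "rmsea_high": self.rmsea_high,
            }
        )


def _rmsea_ci(chisq: float, df: int, N: int, level: float = 0.90) -> tuple[float, float]:
    """90% confidence interval for RMSEA via noncentral chi-square inversion."""
    from scipy.optimize import brentq

    hi_tail = (1.0 - level) / 2.0  # 0.05 each side

    def ncp_for(prob: float) -> float:
        # find ncp with P(X <= chisq | df, ncp) = prob
        f = lambda nc: stats.ncx2.cdf(chisq, df, nc) - prob
        upper = max(chisq * 2.0, df + 10.0)
        while f(upper) > 0:
            upper *= 2.0
            if upper > 1e9:
                break
        if f(1e-12) < 0:  # even ncp ~ 0 puts chisq below the prob quantile
            return 0.0
        return brentq(f, 1e-12, upper, xtol=1e-8)

    lam_low = ncp_for(1.0 - hi_tail)
    lam_high = ncp_for(hi_tail)
    low = np.sqrt(lam_low / (df * (N - 1)))
    high = np.sqrt(lam_high / (df * (N - 1)))
    return float(min(low, high)), float(max(low, high))


def fit_indices(
    chisq: float,
    df: int,
    chisq_baseline: float,
    df_baseline: int,
    N: int,
    loglik: float = np.nan,
    n_params: int = 0,
) -> FitIndices:
    """Assemble :class:`FitIndices` from chi-square statistics."""
    return FitIndices(
        chisq=chisq,
        df=df,
        chisq_baseline=chisq_baseline,
        df_baseline=df_baseline,
        N=N,
        loglik=loglik,
        n_params=n_params,
    )


# ---------------------------------------------------------------------------
# centrality primitives

def expected_influence(omega: np.ndarray) -> np.ndarray:
    """Signed sum of each node's edge weights (one-step expected influence)."""
    omega = np.asarray(omega, dtype=float)
    _check_square_symmetric(omega)
    return omega.sum(axis=1)


def predictability(R: np.ndarray) -> np.ndarray:
    """Per-node R^2: variance explained by all other nodes jointly.

    Equals 1 - 1/K[i, i] with K the inverse correlation matrix, which is the
    coefficient of determination of the regression of node i on the rest.
    """
    R = np.asarray(R, dtype=float)
    _check_square_symmetric(R)
    K = np.linalg.inv(R)
    return 1.0 - 1.0 / np.diag(K)
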