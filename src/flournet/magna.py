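"""Meta-analytic Gaussian network aggregation (MAGNA).

Pools per-country correlation matrices into one cross-country network under
a random-effects model: each country's vector of 66 sample correlations
y_c scatters around pooled fixed-effect correlations rho with covariance
V_c + T, where V_c is the analytic (Isserlis) sampling covariance of sample
correlations at the pooled estimate and T = diag(tau^2) holds per-edge
between-country variances. The pooled correlations are re-expressed as a
partial-correlation network with delta-method standard errors, confidence
intervals and significance thresholding.

Estimation is two-stage marginal maximum likelihood: for fixed tau the
fixed effects have a closed-form GLS solution, so the optimizer works on the
66 tau parameters only (box-constrained at zero, analytic profile gradient),
and the evaluation point of the sampling covariances is updated once at the
pooled solution. A heterogeneity pre-test compares saturated single-country
and pooled models by AIC/BIC.
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.linalg import cho_factor, cho_solve
from scipy.optimize import minimize
from scipy.stats import norm

from .correlate import CorrelationSet
from .ggm import (
    GGMNetwork,
    corr_from_pcor,
    gaussian_discrepancy,
    is_positive_definite,
    nearest_correlation,
    pcor_from_corr,
    threshold,
)
from .items import DEFAULT_SCHEMA


# ---------------------------------------------------------------------------
# half-vectorisation of the off-diagonal

def offdiag_pairs(p: int) -> tuple[np.ndarray, np.ndarray]:
    """Canonical edge order: lower-triangle column-major.

    Pairs (j, i) with j < i enumerated by column j then row i — identical to
    ``np.triu_indices(p, 1)`` read as (column, row). All length-p(p-1)/2
    vectors in this package use this order.
    """
    return np.triu_indices(p, 1)


def vech_offdiag(R: np.ndarray) -> np.ndarray:
    """Stack the off-diagonal of a symmetric matrix in canonical edge order."""
    R = np.asarray(R, dtype=float)
    iu, ju = offdiag_pairs(R.shape[0])
    return R[iu, ju].copy()


def unvech(y: np.ndarray, diag: float = 1.0) -> np.ndarray:
    """Inverse of :func:`vech_offdiag`; fills the diagonal with ``diag``."""
    y = np.asarray(y, dtype=float)
    m = len(y)
    p = int(round((1 + np.sqrt(1 + 8 * m)) / 2))
    if p * (p - 1) // 2 != m:
        raise ValueError(f"vector length {m} is not a triangular number")
    R = np.full((p, p), 0.0)
    iu, ju = offdiag_pairs(p)
    R[iu, ju] = y
    R = R + R.T
    np.fill_diagonal(R, diag)
    return R


def edge_labels(schema=DEFAULT_SCHEMA) -> list[str]:
    iu, ju = offdiag_pairs(schema.n_items)
    return [f"{schema.codes[i]}--{schema.codes[j]}" for i, j in zip(iu, ju)]


# ---------------------------------------------------------------------------
# sampling covariance of correlation coefficients

def corr_sampling_cov(R: np.ndarray, N: float) -> np.ndarray:
    """Asymptotic covariance of the sample correlations of N Gaussian rows.

    Pearson–Filon/Isserlis form evaluated at the population matrix R:

    N Cov(r_ij, r_kl) = 1/2 r_ij r_kl (r_ik^2 + r_il^2 + r_jk^2 + r_jl^2)
        + r_ik r_jl + r_il r_jk
        - r_ij (r_jk r_jl + r_ik r_il) - r_kl (r_ik r_jk + r_il r_jl)

    Returned symmetrized; positive semi-definite up to O(1/N) terms.
    """
    R = np.asarray(R, dtype=float)
    I, J = offdiag_pairs(R.shape[0])
    rij = R[I, J]
    # broadcast pair a over rows, pair b over columns
    r_ik = R[np.ix_(I, I)]
    r_il = R[np.ix_(I, J)]
    r_jk = R[np.ix_(J, I)]
    r_jl = R[np.ix_(J, J)]
    a = rij[:, None]
    b = rij[None, :]
    C = (
        0.5 * a * b * (r_ik**2 + r_il**2 + r_jk**2 + r_jl**2)
        + r_ik * r_jl
        + r_il * r_jk
        - a * (r_jk * r_jl + r_ik * r_il)
        - b * (r_ik * r_jk + r_il * r_jl)
    )
    C = (C + C.T) / (2.0 * N)
    return C


# ---------------------------------------------------------------------------
# heterogeneity pre-test

@dataclass
class HeterogeneityComparison:
    """AIC/BIC comparison of single-country vs pooled saturated models."""

    aic_single: float
    bic_single: float
    aic_pooled: float
    bic_pooled: float
    loglik_single: float
    loglik_pooled: float
    n_params_single: int
    n_params_pooled: int
    chisq_diff: float
    df_diff: int

    @property
    def preferred_aic(self) -> str:
        return "single" if self.aic_single < self.aic_pooled else "pooled"

    @property
    def preferred_bic(self) -> str:
        return "single" if self.bic_single < self.bic_pooled else "pooled"

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "loglik": [self.loglik_single, self.loglik_pooled],
                "n_params": [self.n_params_single, self.n_params_pooled],
                "aic": [self.aic_single, self.aic_pooled],
                "bic": [self.bic_single, self.bic_pooled],
            },
            index=["single_country", "pooled"],
        )


def fit_saturated_models(cset: CorrelationSet) -> HeterogeneityComparison:
    """Compare a per-country saturated model against a pooled saturated model.

    The single-country model gives every country its own correlation matrix
    (perfect fit, 66 correlation parameters per country); the pooled model
    constrains one common matrix across countries, whose ML solution is the
    N-weighted mean of the per-country matrices. Lower AIC/BIC for the
    single-country model indicates between-country heterogeneity beyond
    sampling variation.
    """
    C = cset.n_countries
    if C < 2:
        raise ValueError("heterogeneity comparison needs at least 2 countries")
    m = cset.schema.n_pairs
    N_tot = cset.total_n
    ll_single = sum(
        gaussian_discrepancy(S, S, n)[1] for S, n in zip(cset.R, cset.N)
    )
    R_pool = sum(n * S for S, n in zip(cset.R, cset.N)) / N_tot
    ll_pooled = sum(
        gaussian_discrepancy(S, R_pool, n)[1] for S, n in zip(cset.R, cset.N)
    )
    k_single, k_pooled = m * C, m
    logN = np.log(N_tot)
    return HeterogeneityComparison(
        aic_single=-2 * ll_single + 2 * k_single,
        bic_single=-2 * ll_single + k_single * logN,
        aic_pooled=-2 * ll_pooled + 2 * k_pooled,
        bic_pooled=-2 * ll_pooled + k_pooled * logN,
        loglik_single=ll_single,
        loglik_pooled=ll_pooled,
        n_params_single=k_single,
        n_params_pooled=k_pooled,
        chisq_diff=2.0 * (ll_single - ll_pooled),
        df_diff=m * (C - 1),
    )


# ---------------------------------------------------------------------------
# random-effects MAGNA

class MAGNA:
    """Random-effects meta-analytic Gaussian network aggregation model.

    Parameters
    ----------
    cset : CorrelationSet
        Per-country correlation matrices with post-deletion sample sizes.
    fisher_z : bool
        Estimate on the Fisher-z scale instead of the raw correlation scale
        (the default matches pooling of raw sample correlations).
    """

    def __init__(self, cset: CorrelationSet, fisher_z: bool = False):
        self.cset = cset
        self.fisher_z = fisher_z
        self.schema = cset.schema
        self.m = cset.schema.n_pairs
        self.y = np.array([vech_offdiag(R) for R in cset.R])  # C x m
        self.N = np.asarray(cset.N, dtype=float)

    # -- internals ---------------------------------------------------------

    def _transform(self, y):
        return np.arctanh(np.clip(y, -0.999999, 0.999999)) if self.fisher_z else y

    def _back(self, rho):
        return np.tanh(rho) if self.fisher_z else rho

    def _sampling_covs(self, R_eval: np.ndarray) -> list[np.ndarray]:
        V = corr_sampling_cov(R_eval, 1.0)
        if self.fisher_z:
            d = 1.0 / (1.0 - vech_offdiag(R_eval) ** 2)
            V = V * np.outer(d, d)
        # tiny ridge keeps near-singular V invertible for extreme matrices
        V = V + 1e-10 * np.eye(self.m)
        return [V / n for n in self.N]

    @staticmethod
    def _profile(tau, Vs, Y):
        """Profiled negative loglik over tau and its gradient.

        For fixed tau the GLS solution rho(tau) = (sum W_c)^-1 sum W_c y_c is
        the exact ML fixed effect, so by the envelope theorem the gradient of
        the profiled objective needs only the partial derivative in tau:
        d(-l)/d tau_k = tau_k * sum_c [ (W_c)_kk - ((W_c r_c)_k)^2 ].
        """
        m = Y.shape[1]
        T = np.diag(tau**2)
        Ws, logdets = [], 0.0
        A = np.zeros((m, m))
        b = np.zeros(m)
        for Vc, yc in zip(Vs, Y):
            cf = cho_factor(Vc + T, lower=True)
            logdets += 2.0 * np.log(np.diag(cf[0])).sum()
            Wc = cho_solve(cf, np.eye(m))
            Ws.append(Wc)
            A += Wc
            b += Wc @ yc
        rho = np.linalg.solve(A, b)
        nll = 0.5 * logdets
        grad = np.zeros(m)
        for Wc, yc in zip(Ws, Y):
            r = yc - rho
            Wr = Wc @ r
            nll += 0.5 * float(r @ Wr)
            grad += np.diag(Wc) - Wr**2
        return nll, tau * grad, rho, A

    def _start_tau(self, Vs, weights) -> np.ndarray:
        var_between = np.average(
            (self.y - np.average(self.y, axis=0, weights=weights)) ** 2,
            axis=0,
            weights=weights,
        )
        mean_sampling = np.mean([np.diag(V) for V in Vs], axis=0)
        return np.sqrt(np.clip(var_between - mean_sampling, 1e-6, None))

    # -- fitting -----------------------------------------------------------

    def fit(
        self,
        tau_fixed: np.ndarray | float | None = None,
        alpha: float = 0.05,
        n_outer: int = 2,
        tau_max: float = 0.8,
        gtol: float = 1e-8,
    ) -> "MAGNAResults":
        """Fit the random-effects model; returns :class:`MAGNAResults`.

        ``tau_fixed`` pins the random-effect SDs (e.g. 0 for a fixed-effect
        or single-country fit) instead of estimating them; estimating tau
        requires at least 3 countries.
        """
        C = self.y.shape[0]
        if tau_fixed is None and C < 3:
            raise ValueError("estimating tau requires >= 3 countries; pass tau_fixed")
        Y = self._transform(self.y)
        rho0 = np.average(Y, axis=0, weights=self.N)
        R_eval = nearest_correlation(unvech(self._back(rho0)))
        rho_hat, tau_hat, A = rho0, None, None
        converged = True
        message = ""
        for outer in range(n_outer):
            Vs = self._sampling_covs(R_eval)
            if tau_fixed is not None:
                tau_hat = np.broadcast_to(
                    np.asarray(tau_fixed, dtype=float), (self.m,)
                ).copy()
                nll, _, rho_hat, A = self._profile(tau_hat, Vs, Y)
            else:
                t_est = tau_hat if tau_hat is not None else self._start_tau(Vs, self.N)
                starts = [t_est, 0.5 * t_est, np.full(self.m, 0.1)]
                best = None
                for t0 in starts:
                    res = minimize(
                        lambda t: self._profile(t, Vs, Y)[:2],
                        np.clip(t0, 1e-4, tau_max),
                        jac=True,
                        method="L-BFGS-B",
                        bounds=[(0.0, tau_max)] * self.m,
                        options={"maxiter": 500, "gtol": gtol, "ftol": 1e-13},
                    )
                    if best is None or res.fun < best.fun:
                        best = res
                    if res.success or "ROUNDING" in str(res.message).upper():
                        break
                # accept a line-search stall if the projected gradient is tiny
                proj = best.jac.copy()
                proj[(best.x <= 1e-12) & (proj > 0)] = 0.0
                proj[(best.x >= tau_max - 1e-12) & (proj < 0)] = 0.0
                ok = (
                    best.success
                    or "ROUNDING" in str(best.message).upper()
                    or np.max(np.abs(proj)) < 1e-2 * (1.0 + abs(best.fun))
                )
                tau_hat = best.x
                nll, _, rho_hat, A = self._profile(tau_hat, Vs, Y)
                if not ok:
                    converged = False
                    message = str(best.message)
            R_new = unvech(self._back(rho_hat))
            if not is_positive_definite(R_new):
                warnings.warn("pooled correlation estimate projected to nearest PD", stacklevel=2)
                R_new = nearest_correlation(R_new)
            R_eval = R_new
        if not converged:
            raise RuntimeError(f"MAGNA optimizer failed to converge: {message}")
        vcov_rho_t = np.linalg.inv(A)  # on the working (possibly z) scale
        rho_raw = self._back(rho_hat)
        if self.fisher_z:
            d = 1.0 - rho_raw**2  # d tanh(z)/dz
            vcov_rho = vcov_rho_t * np.outer(d, d)
            tau_raw = tau_hat * d  # delta-method back-transform of SDs
        else:
            vcov_rho = vcov_rho_t
            tau_raw = tau_hat
        at_boundary = tau_fixed is None and bool(np.any(tau_hat <= 1e-4))
        return MAGNAResults(
            model=self,
            rho=rho_raw,
            tau=tau_raw,
            vcov_rho=vcov_rho,
            loglik=-nll,
            alpha=alpha,
            tau_estimated=tau_fixed is None,
            tau_at_boundary=at_boundary,
        )


class MAGNAResults:
    """Fitted MAGNA: pooled correlations, heterogeneity SDs, pooled network."""

    def __init__(self, model, rho, tau, vcov_rho, loglik, alpha, tau_estimated, tau_at_boundary):
        self.model = model
        self.schema = model.schema
        self.rho = rho
        self.tau = tau
        self.vcov_rho = vcov_rho
        self.loglik = loglik
        self.alpha = alpha
        self.tau_estimated = tau_estimated
        self.tau_at_boundary = tau_at_boundary
        if tau_at_boundary:
            warnings.warn("some tau estimates at the zero boundary", stacklevel=2)
        self.R_pooled = unvech(rho)
        if not is_positive_definite(self.R_pooled):
            self.R_pooled = nearest_correlation(self.R_pooled)
        omega = pcor_from_corr(self.R_pooled)
        self.omega_vec = vech_offdiag(omega)
        J = _pcor_jacobian(self.rho)
        self.vcov_omega = J @ self.vcov_rho @ J.T
        se_vec = np.sqrt(np.clip(np.diag(self.vcov_omega), 0.0, None))
        z = np.divide(self.omega_vec, se_vec, out=np.zeros_like(se_vec), where=se_vec > 0)
        p_vec = 2.0 * norm.sf(np.abs(z))
        self.se_vec = se_vec
        self.pvals_vec = p_vec
        self.ci_low = self.omega_vec - norm.ppf(0.975) * se_vec
        self.ci_high = self.omega_vec + norm.ppf(0.975) * se_vec
        net = GGMNetwork(
            nodes=self.schema.codes,
            omega=omega,
            se=unvech(se_vec, diag=0.0),
            pvals=unvech(p_vec, diag=1.0),
        )
        self.network_unthresholded = net
        self.network = threshold(net, alpha=alpha)

    @property
    def mean_tau(self) -> float:
        return float(self.tau.mean())

    @property
    def min_tau(self) -> float:
        return float(self.tau.min())

    @property
    def max_tau(self) -> float:
        return float(self.tau.max())

    def edge_table(self) -> pd.DataFrame:
        """Pooled edges with SEs, CIs, p-values, retention flag and tau."""
        retained = vech_offdiag(self.network.retained.astype(float)).astype(int)
        return pd.DataFrame(
            {
                "edge": edge_labels(self.schema),
                "weight": self.omega_vec,
                "se": self.se_vec,
                "ci_low": self.ci_low,
                "ci_high": self.ci_high,
                "p": self.pvals_vec,
                "retained": retained,
                "tau": self.tau,
            }
        )

    def random_effect_summary(self) -> pd.DataFrame:
        """Per-edge heterogeneity SDs sorted descending, with summary row."""
        df = pd.DataFrame({"edge": edge_labels(self.schema), "tau": self.tau})
        return df.sort_values("tau", ascending=False, kind="stable").reset_index(drop=True)

    def bootstrap_centrality_difference(self, B=100_000, seed=0, alpha=None, **kw):
        from .centrality import bootstrap_centrality_difference

        return bootstrap_centrality_difference(self, B=B, seed=seed, alpha=alpha, **kw)

    def centrality_table(self, label: str = "pooled"):
        from .centrality import centrality_table

        return centrality_table(self.network, label=label)

    def summary(self) -> str:
        n_sig = int((self.pvals_vec < self.alpha).sum())
        lines = [
            "Meta-analytic Gaussian network aggregation (random effects)",
            "=" * 60,
            f"countries: {self.model.cset.n_countries}   total N: {self.model.cset.total_n}",
            f"edges: {self.model.m}   significant at alpha={self.alpha:g}: {n_sig}",
            f"log-likelihood (marginal, working scale): {self.loglik:.2f}",
            (
                f"random-effect SD tau: mean {self.mean_tau:.3f} "
                f"(range {self.min_tau:.3f} to {self.max_tau:.3f})"
                if self.tau_estimated
                else f"tau fixed at mean {self.mean_tau:.3f}"
            ),
            "",
            "strongest pooled edges:",
        ]
        top = self.edge_table().reindex(
            self.edge_table()["weight"].abs().sort_values(ascending=False).index
        )
        for row in top.head(8).itertuples():
            lines.append(
                f"  {row.edge:>8s}  w={row.weight:+.3f}  se={row.se:.4f}  "
                f"95% CI [{row.ci_low:+.3f}, {row.ci_high:+.3f}]"
            )
        return "\n".join(lines)


def _pcor_jacobian(rho: np.ndarray, h: float = 1e-6) -> np.ndarray:
    """Numerical Jacobian of the correlation -> partial-correlation map."""
    m = len(rho)
    J = np.empty((m, m))
    for k in range(m):
        e = np.zeros(m)
        e[k] = h
        wp = vech_offdiag(pcor_from_corr(unvech(rho + e)))
        wm = vech_offdiag(pcor_from_corr(unvech(rho - e)))
        J[:, k] = (wp - wm) / (2.0 * h)
    return J
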