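"""Measurement-model comparison for the 12-item flourishing instrument.

Six competing structures for the item correlation matrix are fitted by
Gaussian maximum likelihood and compared on chi-square fit indices and
information criteria:

- ``cfa6``: first-order CFA, six correlated factors with two indicators each
- ``bifactor``: one orthogonal general factor plus six orthogonal specifics
- ``second_order_g``: a second-order g factor over the six first-order
  factors (first-order disturbances standardised)
- ``latent_network``: the CFA with the factor correlation matrix
  parameterised as a saturated latent partial-correlation network
  (likelihood-equivalent to ``cfa6`` by reparameterisation)
- ``residual_network``: one general factor plus a partial-correlation
  network over residuals, identified by stepwise pruning of
  non-significant residual edges
- ``ggm``: the saturated Gaussian graphical model over the 12 items

All models are identified by fixing latent variances to 1. Optimisation is
quasi-Newton (L-BFGS-B) with analytic gradients from five deterministic
start points; non-positive-definite implied matrices get a penalised
objective value rather than an exception.
"""
from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import minimize
from scipy.stats import chi2
from statsmodels.stats.moment_helpers import cov2corr

from .ggm import FitIndices, edge_pvalues, gaussian_discrepancy, pcor_from_corr
from .items import DEFAULT_SCHEMA, ItemSchema

MODEL_KINDS = ("cfa6", "bifactor", "second_order_g", "latent_network", "residual_network", "ggm")

MODEL_LABELS = {
    "cfa6": "First-order CFA model",
    "bifactor": "Bi-factor model",
    "second_order_g": "g-factor/second-order model",
    "latent_network": "Latent network model",
    "residual_network": "Residual network model",
    "ggm": "Network model",
}

_PENALTY = 1.0e6


def _loading_pattern(schema: ItemSchema) -> np.ndarray:
    """Item -> factor index, following the schema's domain order."""
    factor_of = np.empty(schema.n_items, dtype=int)
    for f, (_, pair) in enumerate(schema.domains.items()):
        for code in pair:
            factor_of[schema.index(code)] = f
    return factor_of


def _lambda_matrix(lam: np.ndarray, factor_of: np.ndarray, n_factors: int) -> np.ndarray:
    L = np.zeros((len(lam), n_factors))
    L[np.arange(len(lam)), factor_of] = lam
    return L


def _chol_ok(A: np.ndarray) -> bool:
    try:
        np.linalg.cholesky(A)
        return True
    except np.linalg.LinAlgError:
        return False


def _penalty(A: np.ndarray) -> tuple[float, np.ndarray]:
    lam_min = float(np.linalg.eigvalsh((A + A.T) / 2.0)[0])
    return _PENALTY * (1.0 + abs(lam_min)), np.zeros(0)


# ---------------------------------------------------------------------------
# model structures: Sigma(theta) and the gradient of F given G

@dataclass
class ModelStructure:
    """Implied-covariance structure of one measurement model.

    ``theta`` layouts (all factors scaled by fixing variances to 1):

    - cfa6:            [lam(12), phi_offdiag(15), theta_res(12)]
    - bifactor:        [lam_g(12), lam_s(12), theta_res(12)]
    - second_order_g:  [lam(12), gamma(6), theta_res(12)]
    - latent_network:  [lam(12), omega_lat(15), theta_res(12)]
    - residual_network:[lam(12), delta(12), omega_res(n_edges)]
    - ggm:             [omega(66), delta(12)]  (fitted in closed form)
    """

    kind: str
    schema: ItemSchema = DEFAULT_SCHEMA
    res_pattern: np.ndarray | None = None  # boolean edge mask for residual_network / pruned ggm
    factor_of: np.ndarray = field(init=False)
    p: int = field(init=False)

    def __post_init__(self) -> None:
        if self.kind not in MODEL_KINDS:
            raise ValueError(f"unknown model kind {self.kind!r}")
        self.factor_of = _loading_pattern(self.schema)
        self.p = self.schema.n_items

    # -- bookkeeping -------------------------------------------------------

    @property
    def _res_edges(self) -> tuple[np.ndarray, np.ndarray]:
        iu, ju = np.triu_indices(self.p, 1)
        if self.res_pattern is not None:
            keep = self.res_pattern[iu, ju]
            return iu[keep], ju[keep]
        return iu, ju

    @property
    def n_params(self) -> int:
        p = self.p
        return {
            "cfa6": 2 * p + 15,
            "bifactor": 3 * p,
            "second_order_g": 2 * p + 6,
            "latent_network": 2 * p + 15,
            "residual_network": 2 * p + len(self._res_edges[0]),
            "ggm": p + len(self._res_edges[0]),
        }[self.kind]

    @property
    def df(self) -> int:
        return self.p * (self.p + 1) // 2 - self.n_params

    def start(self, jitter: float = 0.0, rng: np.random.Generator | None = None) -> np.ndarray:
        p = self.p
        if self.kind == "cfa6":
            t = np.concatenate([np.full(p, 0.7), np.full(15, 0.3), np.full(p, 0.5)])
        elif self.kind == "bifactor":
            t = np.concatenate([np.full(p, 0.5), np.full(p, 0.5), np.full(p, 0.5)])
        elif self.kind == "second_order_g":
            t = np.concatenate([np.full(p, 0.7), np.full(6, 0.5), np.full(p, 0.5)])
        elif self.kind == "latent_network":
            t = np.concatenate([np.full(p, 0.7), np.full(15, 0.1), np.full(p, 0.5)])
        elif self.kind == "residual_network":
            ne = len(self._res_edges[0])
            t = np.concatenate([np.full(p, 0.5), np.full(p, 0.8), np.zeros(ne)])
        else:  # ggm
            ne = len(self._res_edges[0])
            t = np.concatenate([np.zeros(ne), np.ones(p)])
        if jitter > 0 and rng is not None:
            t = t + rng.uniform(-jitter, jitter, size=t.shape)
        return np.clip(t, [b[0] for b in self.bounds()], [b[1] for b in self.bounds()])

    def bounds(self) -> list[tuple[float, float]]:
        p = self.p
        lam_b = [(-1.5, 1.5)] * p
        cor_b = (-0.999, 0.999)
        var_b = (1e-6, 4.0)
        if self.kind == "cfa6":
            return lam_b + [cor_b] * 15 + [var_b] * p
        if self.kind == "bifactor":
            return lam_b * 2 + [var_b] * p
        if self.kind == "second_order_g":
            return lam_b + [cor_b] * 6 + [var_b] * p
        if self.kind == "latent_network":
            return lam_b + [cor_b] * 15 + [var_b] * p
        if self.kind == "residual_network":
            ne = len(self._res_edges[0])
            return lam_b + [(1e-3, 2.0)] * p + [cor_b] * ne
        ne = len(self._res_edges[0])
        return [cor_b] * ne + [(1e-3, 2.0)] * p

    # -- implied covariance ------------------------------------------------

    def sigma(self, theta: np.ndarray) -> np.ndarray:
        """Model-implied covariance matrix at ``theta``."""
        p = self.p
        fo = self.factor_of
        if self.kind == "cfa6":
            lam, phi_v, res = theta[:p], theta[p : p + 15], theta[p + 15 :]
            L = _lambda_matrix(lam, fo, 6)
            Phi = _sym_from_vec(phi_v, 6)
            return L @ Phi @ L.T + np.diag(res)
        if self.kind == "bifactor":
            lg, ls, res = theta[:p], theta[p : 2 * p], theta[2 * p :]
            Ls = _lambda_matrix(ls, fo, 6)
            return np.outer(lg, lg) + Ls @ Ls.T + np.diag(res)
        if self.kind == "second_order_g":
            lam, gam, res = theta[:p], theta[p : p + 6], theta[p + 6 :]
            L = _lambda_matrix(lam, fo, 6)
            Phi = np.outer(gam, gam)
            np.fill_diagonal(Phi, 1.0)
            return L @ Phi @ L.T + np.diag(res)
        if self.kind == "latent_network":
            lam, om_v, res = theta[:p], theta[p : p + 15], theta[p + 15 :]
            L = _lambda_matrix(lam, fo, 6)
            Om = _sym_from_vec(om_v, 6, diag=0.0)
            A = np.eye(6) - Om
            Minv = np.linalg.inv(A)
            Phi = cov2corr(Minv)
            return L @ Phi @ L.T + np.diag(res)
        if self.kind == "residual_network":
            lam, delta = theta[:p], theta[p : 2 * p]
            Om = self._res_omega(theta[2 * p :])
            Minv = np.linalg.inv(np.eye(p) - Om)
            D = np.diag(delta)
            return np.outer(lam, lam) + D @ Minv @ D
        # ggm
        ne = len(self._res_edges[0])
        Om = self._res_omega(theta[:ne])
        delta = theta[ne:]
        Minv = np.linalg.inv(np.eye(p) - Om)
        D = np.diag(delta)
        return D @ Minv @ D

    def _res_omega(self, vals: np.ndarray) -> np.ndarray:
        Om = np.zeros((self.p, self.p))
        iu, ju = self._res_edges
        Om[iu, ju] = vals
        return Om + Om.T

    def _intermediate_ok(self, theta: np.ndarray) -> bool:
        if self.kind == "latent_network":
            Om = _sym_from_vec(theta[self.p : self.p + 15], 6, diag=0.0)
            return _chol_ok(np.eye(6) - Om)
        if self.kind in ("residual_network", "ggm"):
            vals = theta[: -self.p] if self.kind == "ggm" else theta[2 * self.p :]
            Om = self._res_omega(vals)
            return _chol_ok(np.eye(self.p) - Om)
        return True

    # -- gradient of F = tr(G dSigma) --------------------------------------

    def grad_F(self, theta: np.ndarray, G: np.ndarray) -> np.ndarray:
        p = self.p
        fo = self.factor_of
        if self.kind == "cfa6":
            lam, phi_v = theta[:p], theta[p : p + 15]
            L = _lambda_matrix(lam, fo, 6)
            Phi = _sym_from_vec(phi_v, 6)
            GLP = G @ L @ Phi
            g_lam = 2.0 * GLP[np.arange(p), fo]
            M = L.T @ G @ L
            iu, ju = np.triu_indices(6, 1)
            g_phi = 2.0 * M[iu, ju]
            g_res = np.diag(G)
            return np.concatenate([g_lam, g_phi, g_res])
        if self.kind == "bifactor":
            lg, ls = theta[:p], theta[p : 2 * p]
            Ls = _lambda_matrix(ls, fo, 6)
            g_lg = 2.0 * (G @ lg)
            g_ls = 2.0 * (G @ Ls)[np.arange(p), fo]
            return np.concatenate([g_lg, g_ls, np.diag(G)])
        if self.kind == "second_order_g":
            lam, gam = theta[:p], theta[p : p + 6]
            L = _lambda_matrix(lam, fo, 6)
            Phi = np.outer(gam, gam)
            np.fill_diagonal(Phi, 1.0)
            GLP = G @ L @ Phi
            g_lam = 2.0 * GLP[np.arange(p), fo]
            M = L.T @ G @ L
            g_gam = 2.0 * (M @ gam) - 2.0 * gam * np.diag(M)
            return np.concatenate([g_lam, g_gam, np.diag(G)])
        if self.kind == "latent_network":
            lam, om_v = theta[:p], theta[p : p + 15]
            L = _lambda_matrix(lam, fo, 6)
            Om = _sym_from_vec(om_v, 6, diag=0.0)
            Minv = np.linalg.inv(np.eye(6) - Om)
            d = np.diag(Minv)
            Dm = np.diag(1.0 / np.sqrt(d))
            Phi = Dm @ Minv @ Dm
            GLP = G @ L @ Phi
            g_lam = 2.0 * GLP[np.arange(p), fo]
            M = L.T @ G @ L  # 6x6, symmetric
            iu, ju = np.triu_indices(6, 1)
            g_om = np.empty(15)
            for k, (f, g_) in enumerate(zip(iu, ju)):
                E = np.zeros((6, 6))
                E[f, g_] = E[g_, f] = 1.0
                dMinv = Minv @ E @ Minv
                ddiag = np.diag(dMinv)
                dDm = np.diag(-0.5 * d ** (-1.5) * ddiag)
                T1 = dDm @ Minv @ Dm
                dPhi = T1 + T1.T + Dm @ dMinv @ Dm
                g_om[k] = float(np.sum(M * dPhi))
            return np.concatenate([g_lam, g_om, np.diag(G)])
        if self.kind == "residual_network":
            lam, delta = theta[:p], theta[p : 2 * p]
            Om = self._res_omega(theta[2 * p :])
            Minv = np.linalg.inv(np.eye(p) - Om)
            D = np.diag(delta)
            g_lam = 2.0 * (G @ lam)
            GDM = G @ D @ Minv
            g_delta = 2.0 * np.diag(GDM)
            H = Minv @ D @ G @ D @ Minv
            iu, ju = self._res_edges
            g_om = 2.0 * H[iu, ju]
            return np.concatenate([g_lam, g_delta, g_om])
        # ggm
        ne = len(self._res_edges[0])
        Om = self._res_omega(theta[:ne])
        delta = theta[ne:]
        Minv = np.linalg.inv(np.eye(p) - Om)
        D = np.diag(delta)
        H = Minv @ D @ G @ D @ Minv
        iu, ju = self._res_edges
        g_om = 2.0 * H[iu, ju]
        g_delta = 2.0 * np.diag(G @ D @ Minv)
        return np.concatenate([g_om, g_delta])


def _sym_from_vec(v: np.ndarray, n: int, diag: float = 1.0) -> np.ndarray:
    A = np.zeros((n, n))
    iu, ju = np.triu_indices(n, 1)
    A[iu, ju] = v
    A = A + A.T
    np.fill_diagonal(A, diag)
    return A


def implied_sigma(kind: str, theta: np.ndarray, schema: ItemSchema = DEFAULT_SCHEMA,
                  res_pattern: np.ndarray | None = None) -> np.ndarray:
    """Model-implied covariance matrix for a parameter vector (see ModelStructure)."""
    return ModelStructure(kind, schema, res_pattern).sigma(np.asarray(theta, dtype=float))


# ---------------------------------------------------------------------------
# fitting

@dataclass
class ConvergenceReport:
    converged: bool
    grad_norm: float
    start_values: list[float]
    spread: float
    message: str = ""


class MeasurementModel:
    """One measurement model for a correlation matrix and sample size.

    statsmodels-style usage::

        res = MeasurementModel(R, N, kind="cfa6").fit()
        print(res.summary())
    """

    def __init__(
        self,
        R: np.ndarray,
        N: int,
        kind: str,
        schema: ItemSchema = DEFAULT_SCHEMA,
        prune_refit: bool = False,
        alpha_prune: float = 0.05,
    ):
        self.R = np.asarray(R, dtype=float)
        self.N = int(N)
        self.kind = kind
        self.schema = schema
        self.prune_refit = prune_refit
        self.alpha_prune = alpha_prune
        if self.R.shape != (schema.n_items,) * 2:
            raise ValueError(f"R must be {schema.n_items}x{schema.n_items}")
        if not _chol_ok(self.R):
            raise np.linalg.LinAlgError("input correlation matrix is not positive definite")

    @classmethod
    def from_dataframe(cls, R: pd.DataFrame, N: int, kind: str, **kw) -> "MeasurementModel":
        schema = kw.pop("schema", DEFAULT_SCHEMA)
        if list(R.columns) != list(schema.codes):
            raise ValueError("DataFrame columns must match the item schema order")
        return cls(R.to_numpy(dtype=float), N, kind, schema=schema, **kw)

    # -- objective ---------------------------------------------------------

    def _objective(self, struct: ModelStructure):
        S = self.R

        def fun(theta):
            if not struct._intermediate_ok(theta):
                val, _ = _penalty(np.eye(struct.p))
                return val, np.zeros_like(theta)
            Sigma = struct.sigma(theta)
            try:
                cF = np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                lam_min = float(np.linalg.eigvalsh(Sigma)[0])
                return _PENALTY * (1.0 + abs(lam_min)), np.zeros_like(theta)
            logdet = 2.0 * np.log(np.diag(cF)).sum()
            Sinv = np.linalg.inv(Sigma)
            F = logdet - self._logdet_S + float(np.sum(Sinv * S)) - struct.p
            G = Sinv @ (Sigma - S) @ Sinv
            return F, struct.grad_F(theta, G)

        sign, self._logdet_S = np.linalg.slogdet(S)
        return fun

    def _data_driven_start(self, struct: ModelStructure) -> np.ndarray | None:
        """Start values derived from the observed correlations.

        Loadings from within-domain pair correlations, factor correlations
        from rescaled cross-domain item correlations; puts every model kind
        in the basin of its ML solution even under heavy misspecification.
        """
        from .ggm import nearest_correlation

        R, p = self.R, struct.p
        fo = struct.factor_of
        pair_r = np.empty(6)
        for f in range(6):
            i, j = np.where(fo == f)[0]
            pair_r[f] = R[i, j]
        lam = np.sqrt(np.clip(pair_r, 0.09, 0.9))[fo]
        Phi = np.eye(6)
        for f in range(6):
            for g in range(f + 1, 6):
                cross = R[np.ix_(np.where(fo == f)[0], np.where(fo == g)[0])].mean()
                Phi[f, g] = Phi[g, f] = np.clip(
                    cross / (np.sqrt(np.clip(pair_r[f], 0.09, 0.9) * np.clip(pair_r[g], 0.09, 0.9))),
                    -0.9, 0.9,
                )
        Phi = nearest_correlation(Phi, eig_floor=1e-3)
        res = np.clip(1.0 - lam**2, 1e-3, None)
        iu6 = np.triu_indices(6, 1)
        if struct.kind == "cfa6":
            return np.concatenate([lam, Phi[iu6], res])
        if struct.kind == "latent_network":
            # start at the cfa6 solution re-expressed as a latent network; when
            # the cfa6 factor-correlation estimate is indefinite (inadmissible),
            # project it — the latent network is then a genuine restriction
            cfa = ModelStructure("cfa6", self.schema)
            try:
                th_cfa, _, _ = self._fit_structure(cfa, 1, 0)
                lam = th_cfa[: self.schema.n_items]
                res = th_cfa[self.schema.n_items + 15 :]
                Phi = _sym_from_vec(th_cfa[self.schema.n_items : self.schema.n_items + 15], 6)
            except RuntimeError:
                pass
            Phi = nearest_correlation(Phi, eig_floor=1e-3)
            om = pcor_from_corr(Phi)
            return np.concatenate([lam, np.clip(om[iu6], -0.99, 0.99), res])
        if struct.kind == "second_order_g":
            gam = np.sqrt(np.clip((Phi.sum(axis=1) - 1.0) / 5.0, 0.04, 0.9))
            return np.concatenate([lam, gam, res])
        if struct.kind == "bifactor":
            off = R.copy()
            np.fill_diagonal(off, np.nan)
            lg = np.sqrt(np.clip(np.nanmean(off, axis=1), 0.04, 0.9))
            ls = np.sqrt(np.clip(pair_r[fo] - lg**2, 0.01, 0.9))
            return np.concatenate([lg, ls, np.clip(1.0 - lg**2 - ls**2, 1e-3, None)])
        return None

    def _fit_structure(self, struct: ModelStructure, n_starts: int, seed: int):
        fun = self._objective(struct)
        rng = np.random.default_rng(seed)
        starts = []
        smart = self._data_driven_start(struct)
        if smart is not None:
            lo = np.array([b[0] for b in struct.bounds()])
            hi = np.array([b[1] for b in struct.bounds()])
            starts.append(np.clip(smart, lo, hi))
        sols = []
        for k in range(n_starts):
            if k < len(starts):
                t0 = starts[k]
            else:
                t0 = struct.start(jitter=0.0 if k == len(starts) else 0.2, rng=rng)
            res = minimize(
                fun,
                t0,
                jac=True,
                method="L-BFGS-B",
                bounds=struct.bounds(),
                options={"maxiter": 3000, "maxfun": 10000, "ftol": 1e-15, "gtol": 1e-10},
            )
            if res.fun < _PENALTY / 2:
                sols.append(res)
        if not sols:
            raise RuntimeError(
                f"{self.kind}: all {n_starts} optimisation starts failed (penalised region)"
            )
        best = min(sols, key=lambda r: r.fun)
        fvals = sorted(r.fun for r in sols)
        spread = float(fvals[-1] - fvals[0])
        # projected gradient: ignore components pushing into an active bound
        proj = best.jac.copy()
        for k, (lo, hi) in enumerate(struct.bounds()):
            if (best.x[k] - lo < 1e-8 and proj[k] > 0) or (hi - best.x[k] < 1e-8 and proj[k] < 0):
                proj[k] = 0.0
        gnorm = float(np.max(np.abs(proj)))
        report = ConvergenceReport(
            converged=(gnorm < 1e-4 and spread < 1e-4),
            grad_norm=gnorm,
            start_values=[float(v) for v in fvals],
            spread=spread,
            message=str(best.message),
        )
        return best.x, float(best.fun), report

    def _baseline(self) -> tuple[float, int]:
        F, _, chisq = gaussian_discrepancy(self.R, np.eye(self.schema.n_items), self.N)
        dfb = self.schema.n_pairs
        return chisq, dfb

    def fit(self, n_starts: int = 5, seed: int = 0) -> "MeasurementResults":
        p = self.schema.n_items
        if self.kind == "ggm" and not self.prune_refit:
            # saturated network: closed form, perfect fit
            struct = ModelStructure("ggm", self.schema)
            omega = pcor_from_corr(self.R)
            iu, ju = struct._res_edges
            Minv = np.linalg.inv(np.eye(p) - omega)
            delta = 1.0 / np.sqrt(np.diag(Minv))  # scales implied diag to 1
            theta = np.concatenate([omega[iu, ju], delta])
            F, chisq = 0.0, 0.0
            report = ConvergenceReport(True, 0.0, [0.0], 0.0, "closed form (saturated)")
        elif self.kind == "ggm" and self.prune_refit:
            struct, theta, F, report = self._fit_pruned_ggm(n_starts, seed)
            chisq = (self.N - 1) * F
        elif self.kind == "residual_network":
            struct, theta, F, report = self._fit_residual_network(n_starts, seed)
            chisq = (self.N - 1) * F
        else:
            struct = ModelStructure(self.kind, self.schema)
            theta, F, report = self._fit_structure(struct, n_starts, seed)
            chisq = (self.N - 1) * F
        Sigma = struct.sigma(theta)
        _, loglik, _ = gaussian_discrepancy(self.R, Sigma, self.N)
        chisq_b, df_b = self._baseline()
        fi = FitIndices(
            chisq=chisq,
            df=struct.df,
            chisq_baseline=chisq_b,
            df_baseline=df_b,
            N=self.N,
            loglik=loglik,
            n_params=struct.n_params,
        )
        return MeasurementResults(self, struct, theta, F, fi, report)

    # -- network models needing pruning ------------------------------------

    def _initial_residual_pattern(self) -> np.ndarray:
        """Residual-edge candidate pattern from a single-factor fit."""
        p = self.schema.n_items
        # quick single-factor fit: Sigma = lam lam' + diag
        lam0 = np.full(p, 0.6)

        def fun(lam):
            Sigma = np.outer(lam, lam) + np.diag(np.clip(1.0 - lam**2, 1e-3, None))
            try:
                np.linalg.cholesky(Sigma)
            except np.linalg.LinAlgError:
                return _PENALTY
            F, _, _ = gaussian_discrepancy(self.R, Sigma, self.N)
            return F

        res = minimize(fun, lam0, method="L-BFGS-B", bounds=[(-0.98, 0.98)] * p)
        lam = res.x
        resid = self.R - np.outer(lam, lam)
        resid_corr = cov2corr((resid + resid.T) / 2.0)
        from .ggm import nearest_correlation

        resid_corr = nearest_correlation(resid_corr)
        om = pcor_from_corr(resid_corr)
        pvals = edge_pvalues(om, self.N)
        pattern = pvals < self.alpha_prune
        np.fill_diagonal(pattern, False)
        return pattern & pattern.T

    def _enforce_identified(self, pattern: np.ndarray, extra_params: int) -> np.ndarray:
        """Drop weakest edges until df >= 1 (a saturated residual net is unidentified)."""
        p = self.schema.n_items
        max_edges = p * (p + 1) // 2 - extra_params - 1
        iu, ju = np.triu_indices(p, 1)
        n_edges = int(pattern[iu, ju].sum())
        if n_edges > max_edges:
            # drop the largest-p (least significant) surplus edges
            om0 = pcor_from_corr(self.R)
            order = np.argsort(-edge_pvalues(om0, self.N)[iu, ju])
            for k in order:
                if n_edges <= max_edges:
                    break
                if pattern[iu[k], ju[k]]:
                    pattern[iu[k], ju[k]] = pattern[ju[k], iu[k]] = False
                    n_edges -= 1
        return pattern

    def _fit_residual_network(self, n_starts: int, seed: int):
        pattern = self._initial_residual_pattern()
        pattern = self._enforce_identified(pattern, extra_params=2 * self.schema.n_items)
        prev = None
        theta = F = report = struct = None
        for _ in range(3):
            struct = ModelStructure("residual_network", self.schema, res_pattern=pattern)
            theta, F, report = self._fit_structure(struct, n_starts, seed)
            om_fit = struct._res_omega(theta[2 * self.schema.n_items :])
            pv = edge_pvalues(np.clip(om_fit, -0.999, 0.999), self.N)
            new_pattern = pattern & (pv < self.alpha_prune)
            if prev is not None and (new_pattern == pattern).all():
                break
            prev, pattern = pattern, new_pattern
            if not pattern.any():
                break
        return struct, theta, F, report

    def _fit_pruned_ggm(self, n_starts: int, seed: int):
        om0 = pcor_from_corr(self.R)
        pv = edge_pvalues(om0, self.N)
        pattern = pv < self.alpha_prune
        np.fill_diagonal(pattern, False)
        struct = ModelStructure("ggm", self.schema, res_pattern=pattern & pattern.T)
        theta, F, report = self._fit_structure(struct, n_starts, seed)
        return struct, theta, F, report


class MeasurementResults:
    """Fitted measurement model: parameters, fit indices, convergence report."""

    def __init__(self, model, struct, theta, F, fit_ind: FitIndices, report: ConvergenceReport):
        self.model = model
        self.struct = struct
        self.theta = theta
        self.discrepancy = F
        self.fit = fit_ind
        self.convergence = report

    @property
    def kind(self) -> str:
        return self.model.kind

    @property
    def converged(self) -> bool:
        return self.convergence.converged

    def implied_sigma(self) -> np.ndarray:
        return self.struct.sigma(self.theta)

    def params(self) -> dict[str, np.ndarray]:
        """Named parameter blocks of the fitted model."""
        p = self.model.schema.n_items
        t = self.theta
        if self.kind == "cfa6":
            return {"loadings": t[:p], "factor_corr": t[p : p + 15], "residuals": t[p + 15 :]}
        if self.kind == "bifactor":
            return {"general": t[:p], "specific": t[p : 2 * p], "residuals": t[2 * p :]}
        if self.kind == "second_order_g":
            return {"loadings": t[:p], "gamma": t[p : p + 6], "residuals": t[p + 6 :]}
        if self.kind == "latent_network":
            return {"loadings": t[:p], "latent_pcor": t[p : p + 15], "residuals": t[p + 15 :]}
        if self.kind == "residual_network":
            return {"loadings": t[:p], "delta": t[p : 2 * p], "residual_pcor": t[2 * p :]}
        ne = len(self.struct._res_edges[0])
        return {"pcor": t[:ne], "delta": t[ne:]}

    def summary(self) -> str:
        fi = self.fit
        lines = [
            f"Measurement model: {MODEL_LABELS[self.kind]}",
            "=" * 54,
            f"N = {fi.N}   params = {fi.n_params}   df = {fi.df}",
            f"chi2 = {fi.chisq:.2f}   RMSEA = {fi.rmsea:.4f} "
            f"[{fi.rmsea_low:.4f}, {fi.rmsea_high:.4f}]",
            f"CFI = {fi.cfi:.3f}   TLI = {fi.tli:.3f}   NFI = {fi.nfi:.3f}   RFI = {fi.rfi:.3f}",
            f"AIC = {fi.aic:.2f}   BIC = {fi.bic:.2f}",
            f"converged: {self.converged} (grad {self.convergence.grad_norm:.2e}, "
            f"start spread {self.convergence.spread:.2e})",
        ]
        return "\n".join(lines)


# ---------------------------------------------------------------------------
# comparison table

def compare_measurement_models(
    R: np.ndarray,
    N: int,
    kinds=MODEL_KINDS,
    schema: ItemSchema = DEFAULT_SCHEMA,
    n_starts: int = 5,
    seed: int = 0,
) -> "ModelComparison":
    """Fit all requested models on one (R, N) and tabulate, sorted by AIC.

    Chi-square differences are reported against the saturated network model
    (the most general structure considered).
    """
    results: dict[str, MeasurementResults] = {}
    for kind in kinds:
        results[kind] = MeasurementModel(R, N, kind, schema=schema).fit(
            n_starts=n_starts, seed=seed
        )
    ref = results.get("ggm")
    rows = []
    for kind, res in results.items():
        fi = res.fit
        row = fi.to_series()
        row["model"] = MODEL_LABELS[kind]
        row["kind"] = kind
        row["converged"] = res.converged
        if ref is not None:
            d_chi = fi.chisq - ref.fit.chisq
            d_df = fi.df - ref.fit.df
            row["chisq_diff_to_network"] = d_chi
            row["p_of_diff"] = float(chi2.sf(d_chi, d_df)) if d_df > 0 else (
                1.0 if abs(d_chi) < 1e-12 else np.nan
            )
        rows.append(row)
    table = pd.DataFrame(rows).set_index("kind").sort_values("aic")
    cols = ["model", "df", "chisq", "chisq_diff_to_network", "p_of_diff",
            "nfi", "tli", "rfi", "cfi", "aic", "bic", "rmsea", "rmsea_low",
            "rmsea_high", "converged"]
    table = table[[c for c in cols if c in table.columns]]
    return ModelComparison(table=table, results=results)


@dataclass
class ModelComparison:
    table: pd.DataFrame
    results: dict[str, MeasurementResults]

    def to_markdown(self) -> str:
        t = self.table.copy()
        for c in ("chisq", "chisq_diff_to_network", "aic", "bic"):
            if c in t:
                t[c] = t[c].map(lambda v: f"{v:,.2f}")
        for c in ("nfi", "tli", "rfi", "cfi", "rmsea"):
            if c in t:
                t[c] = t[c].map(lambda v: f"{v:.3f}" if np.isfinite(v) else "-")
        return t.to_markdown()

    def to_csv(self, path) -> None:
        self.table.to_csv(path)
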