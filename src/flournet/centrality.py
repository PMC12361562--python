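"""Centrality tables and parametric-bootstrap centrality-difference tests.

Expected influence (signed sum of a node's edge weights) and predictability
(variance of a node explained by all others) are tabulated for the pooled
network and for each single-country network. Stability of pooled centrality
orderings is assessed by drawing edge-weight vectors from the estimated
parameter covariance of the pooled fit, recomputing both indices per draw,
and converting sign proportions of pairwise differences into two-sided
p-values at a Bonferroni-corrected level (0.05 / 66 node pairs, rounded to
4 decimals = 0.0008 for 12 nodes).
"""
from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .correlate import CorrelationSet
from .ggm import (
    GGMNetwork,
    expected_influence,
    network_from_correlation,
    predictability,
    threshold,
)
from .items import DEFAULT_SCHEMA


def bonferroni_alpha(n_nodes: int, family_alpha: float = 0.05) -> float:
    """Family alpha divided by the node-pair count, rounded to 4 decimals."""
    n_pairs = n_nodes * (n_nodes - 1) // 2
    return round(family_alpha / n_pairs, 4)


def centrality_table(network: GGMNetwork, label: str = "pooled") -> pd.DataFrame:
    """Expected influence and predictability per node, with a mean row.

    Predictability is computed from the correlation matrix implied by the
    network's edge weights; an empty network implies independence (all zero).
    """
    ei = expected_influence(network.omega)
    r2 = predictability(network.implied_correlation())
    df = pd.DataFrame(
        {
            "item": list(network.nodes),
            "expected_influence": ei,
            "predictability": r2,
            "network": label,
        }
    )
    mean_row = pd.DataFrame(
        {
            "item": ["(mean)"],
            "expected_influence": [ei.mean()],
            "predictability": [r2.mean()],
            "network": [label],
        }
    )
    return pd.concat([df, mean_row], ignore_index=True)


def single_country_centralities(
    cset: CorrelationSet, alpha: float = 0.05
) -> dict[str, pd.DataFrame]:
    """Centrality table per country from thresholded saturated networks."""
    out = {}
    for country, R, n in zip(cset.countries, cset.R, cset.N):
        net = threshold(network_from_correlation(R, cset.schema.codes, N=n), alpha=alpha)
        out[country] = centrality_table(net, label=country)
    return out


@dataclass
class DifferenceTestResult:
    """Pairwise centrality-difference test from a parametric bootstrap."""

    index_name: str
    pvals: np.ndarray  # n_nodes x n_nodes symmetric, diag 1
    alpha_bonferroni: float
    B: int
    seed: int
    nodes: tuple[str, ...]

    @property
    def significant(self) -> np.ndarray:
        mask = self.pvals < self.alpha_bonferroni
        np.fill_diagonal(mask, False)
        return mask

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.pvals, index=self.nodes, columns=self.nodes)

    def plot(self, ax=None):
        """Significance-grid figure: dark cells mark significant differences."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots(figsize=(5, 5))
        ax.imshow(self.significant, cmap="Greys", vmin=0, vmax=1)
        ax.set_xticks(range(len(self.nodes)), self.nodes, rotation=90, fontsize=7)
        ax.set_yticks(range(len(self.nodes)), self.nodes, fontsize=7)
        ax.set_title(
            f"{self.index_name}: pairwise differences at alpha={self.alpha_bonferroni:g}",
            fontsize=9,
        )
        return ax


def _nearest_psd(C: np.ndarray) -> np.ndarray:
    lam, Q = np.linalg.eigh((C + C.T) / 2.0)
    if lam[0] >= 0:
        return (C + C.T) / 2.0
    warnings.warn("parameter covariance not PSD; clipped negative eigenvalues", stacklevel=3)
    lam = np.clip(lam, 0.0, None)
    return (Q * lam) @ Q.T


def bootstrap_centrality_difference(
    result,
    B: int = 1_000_000,
    seed: int = 0,
    alpha: float | None = None,
    use_thresholded: bool = False,
    chunk: int = 50_000,
) -> dict[str, DifferenceTestResult]:
    """Parametric bootstrap of pairwise centrality differences.

    Draws ``B`` edge-weight vectors from a multivariate normal centred at the
    pooled partial-correlation estimates with their delta-method covariance,
    computes expected influence and predictability per draw, and for each
    node pair reports p = 2 * min(P(diff < 0), P(diff > 0)), capped at 1.
    Zero proportions are floored at 2/B (the bootstrap resolution) rather
    than reported as exact zero.

    ``result`` is a fitted :class:`~flournet.magna.MAGNAResults`; by default
    the unthresholded pooled estimates are resampled.
    """
    if B < 1_000:
        raise ValueError("B must be at least 1,000")
    from .magna import offdiag_pairs  # local import to avoid cycle

    net = result.network if use_thresholded else result.network_unthresholded
    nodes = net.nodes
    p = len(nodes)
    if alpha is None:
        alpha = bonferroni_alpha(p)
    mu = (
        np.asarray(
            [net.omega[i, j] for i, j in zip(*offdiag_pairs(p))], dtype=float
        )
    )
    cov = _nearest_psd(result.vcov_omega)
    rng = np.random.default_rng(seed)
    L = np.linalg.cholesky(cov + 1e-14 * np.eye(len(mu)))
    iu, ju = offdiag_pairs(p)
    # incidence map: EI = row sums of the unvech'd draw
    A = np.zeros((p, len(mu)))
    for k, (i, j) in enumerate(zip(iu, ju)):
        A[i, k] = A[j, k] = 1.0

    counts = {
        "expected_influence": {"lt": np.zeros((p, p)), "gt": np.zeros((p, p))},
        "predictability": {"lt": np.zeros((p, p)), "gt": np.zeros((p, p))},
    }
    eye = np.eye(p)
    done = 0
    while done < B:
        nb = min(chunk, B - done)
        draws = mu + rng.standard_normal((nb, len(mu))) @ L.T
        ei = draws @ A.T  # nb x p
        # predictability: R2_i = 1 - 1/[(I - Omega)^-1]_ii per draw
        Om = np.zeros((nb, p, p))
        Om[:, iu, ju] = draws
        Om[:, ju, iu] = draws
        Minv = np.linalg.inv(eye[None, :, :] - Om)
        diagM = np.einsum("bii->bi", Minv)
        r2 = 1.0 - 1.0 / diagM
        for name, cent in (("expected_influence", ei), ("predictability", r2)):
            diff = cent[:, :, None] - cent[:, None, :]
            counts[name]["lt"] += (diff < 0).sum(axis=0)
            counts[name]["gt"] += (diff > 0).sum(axis=0)
        done += nb

    out = {}
    for name, c in counts.items():
        prop = np.minimum(c["lt"], c["gt"]) / B
        pv = np.minimum(2.0 * prop, 1.0)
        pv = np.maximum(pv, 2.0 / B)  # bootstrap resolution floor
        np.fill_diagonal(pv, 1.0)
        pv = (pv + pv.T) / 2.0
        out[name] = DifferenceTestResult(
            index_name=name,
            pvals=pv,
            alpha_bonferroni=alpha,
            B=B,
            seed=seed,
            nodes=nodes,
        )
    return out
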