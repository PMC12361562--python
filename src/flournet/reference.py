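"""Packaged reference tables from the 22-country flourishing network study.

These are the published summary quantities for the 12-item Secure Flourish
Measure pooled over 22 national samples (total N = 202,898): the
total-sample weighted correlation matrix, the pooled-network partial
correlations with their significance pattern, the pooled centrality table,
and the per-country sample sizes. They serve as fixture inputs (the raw
microdata are access-restricted) and as defaults for the synthetic
generator.
"""
from __future__ import annotations

from importlib import resources

import numpy as np
import pandas as pd

from .items import CODES

#: Total sample size across the 22 country samples.
TOTAL_N = 202_898


def _data_path(name: str):
    return resources.files("flournet.data").joinpath(name)


def total_sample_correlations() -> pd.DataFrame:
    """12x12 total-sample weighted item correlation matrix (unit diagonal)."""
    df = pd.read_csv(_data_path("total_sample_correlations.csv"), index_col=0)
    assert list(df.index) == list(CODES) and list(df.columns) == list(CODES)
    return df


def pooled_network_edges() -> pd.DataFrame:
    """Pooled-network partial correlations as an edge list.

    Columns: node_i, node_j, weight, significant (1 if the edge survived
    thresholding at alpha = 0.05 in the pooled fit).
    """
    return pd.read_csv(_data_path("pooled_network_edges.csv"))


def pooled_network_matrix() -> pd.DataFrame:
    """Pooled-network partial correlations as a symmetric hollow 12x12 matrix."""
    edges = pooled_network_edges()
    p = len(CODES)
    omega = np.zeros((p, p))
    idx = {c: k for k, c in enumerate(CODES)}
    for row in edges.itertuples():
        i, j = idx[row.node_i], idx[row.node_j]
        omega[i, j] = omega[j, i] = row.weight
    return pd.DataFrame(omega, index=CODES, columns=CODES)


def pooled_centrality() -> pd.DataFrame:
    """Published pooled-network centrality (expected influence, predictability)."""
    return pd.read_csv(_data_path("pooled_centrality.csv"))


def country_sample_sizes() -> pd.DataFrame:
    """Per-country respondent counts of the 22 national samples."""
    return pd.read_csv(_data_path("country_sample_sizes.csv"))
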