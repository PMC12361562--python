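"""Sample-weighted correlation matrices from raw per-country respondent tables.

Respondents with any missing item are removed (listwise deletion) before a
weighted Pearson correlation matrix is computed per country. The resulting
:class:`CorrelationSet` — matrices plus post-deletion sample sizes — is the
single input consumed by measurement-model comparison and the meta-analytic
network aggregation.
"""
from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from statsmodels.stats.moment_helpers import cov2corr

from .items import DEFAULT_SCHEMA, ItemSchema

#: Minimum complete cases for a country to enter model fitting.
MIN_COMPLETE_ROWS = 50


@dataclass
class CountrySample:
    """One country's raw data: an n x 12 response table and sample weights."""

    country_code: str
    responses: pd.DataFrame  # columns = item codes, NaN for missing
    weights: np.ndarray
    schema: ItemSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        self.weights = np.asarray(self.weights, dtype=float)
        if list(self.responses.columns) != list(self.schema.codes):
            raise ValueError(
                f"{self.country_code}: response columns must be the schema items "
                f"in order {self.schema.codes}"
            )
        if len(self.weights) != len(self.responses):
            raise ValueError(f"{self.country_code}: weights length != row count")
        if np.any(self.weights < 0) or not np.any(self.weights > 0):
            raise ValueError(f"{self.country_code}: weights must be nonnegative, not all zero")

    @property
    def n(self) -> int:
        return len(self.responses)


@dataclass
class CorrelationSet:
    """Aligned per-country weighted correlation matrices and sample sizes."""

    countries: list[str]
    R: list[np.ndarray]  # 12x12 each
    N: list[int]
    schema: ItemSchema = DEFAULT_SCHEMA

    def __post_init__(self) -> None:
        if not (len(self.countries) == len(self.R) == len(self.N)):
            raise ValueError("countries, R and N must be aligned")
        if len(set(self.countries)) != len(self.countries):
            raise ValueError("duplicate country codes")
        for c, R, n in zip(self.countries, self.R, self.N):
            if n <= 0:
                raise ValueError(f"{c}: nonpositive sample size")
            if R.shape != (self.schema.n_items,) * 2:
                raise ValueError(f"{c}: matrix has wrong shape {R.shape}")

    @property
    def n_countries(self) -> int:
        return len(self.countries)

    @property
    def total_n(self) -> int:
        return int(sum(self.N))

    def subset(self, countries) -> "CorrelationSet":
        keep = [self.countries.index(c) for c in countries]
        return CorrelationSet(
            countries=[self.countries[i] for i in keep],
            R=[self.R[i] for i in keep],
            N=[self.N[i] for i in keep],
            schema=self.schema,
        )


def listwise_complete(sample: CountrySample) -> tuple[CountrySample, int]:
    """Drop rows with any missing item; returns (complete sample, n dropped).

    Raises if fewer than ``MIN_COMPLETE_ROWS`` complete rows remain.
    """
    complete = sample.responses.notna().all(axis=1).to_numpy()
    dropped = int((~complete).sum())
    n_after = int(complete.sum())
    if n_after < MIN_COMPLETE_ROWS:
        raise ValueError(
            f"{sample.country_code}: only {n_after} complete rows after listwise "
            f"deletion (minimum {MIN_COMPLETE_ROWS})"
        )
    out = replace(
        sample,
        responses=sample.responses.loc[complete].reset_index(drop=True),
        weights=sample.weights[complete],
    )
    return out, dropped


def weighted_correlation_matrix(
    sample: CountrySample, kish_n: bool = False
) -> tuple[np.ndarray, float]:
    """Sample-weighted Pearson correlation matrix and effective N.

    Weights are normalised to mean 1 internally (the correlation is invariant
    to their scale). The effective N is the nominal complete-case count by
    default; with ``kish_n=True`` the Kish effective sample size
    (sum w)^2 / sum w^2 is returned instead.
    """
    X = sample.responses.to_numpy(dtype=float)
    if np.isnan(X).any():
        raise ValueError(
            f"{sample.country_code}: missing cells present; run listwise_complete first"
        )
    w = sample.weights / sample.weights.mean()
    sd = np.sqrt(np.cov(X.T, aweights=w, ddof=0).diagonal())
    zero_var = np.where(sd <= 0)[0]
    if zero_var.size:
        items = [sample.schema.codes[i] for i in zero_var]
        raise ValueError(f"{sample.country_code}: zero variance in item(s) {items}")
    R = cov2corr(np.cov(X.T, aweights=w, ddof=0))
    R = (R + R.T) / 2.0
    np.fill_diagonal(R, 1.0)
    if kish_n:
        n_eff = float(w.sum() ** 2 / (w**2).sum())
    else:
        n_eff = float(len(X))
    return R, n_eff


def build_correlation_set(
    samples, kish_n: bool = False, schema: ItemSchema = DEFAULT_SCHEMA
) -> tuple[CorrelationSet, pd.DataFrame]:
    """Listwise-delete and correlate every sample, preserving input order.

    Returns the :class:`CorrelationSet` and a per-country log DataFrame with
    the dropped-row counts.
    """
    samples = list(samples)
    if not samples:
        raise ValueError("need at least one sample")
    codes = [s.country_code for s in samples]
    if len(set(codes)) != len(codes):
        dupes = sorted({c for c in codes if codes.count(c) > 1})
        raise ValueError(f"duplicate country codes: {dupes}")
    countries, mats, ns, log_rows = [], [], [], []
    for s in samples:
        complete, dropped = listwise_complete(s)
        R, n_eff = weighted_correlation_matrix(complete, kish_n=kish_n)
        countries.append(s.country_code)
        mats.append(R)
        ns.append(int(round(n_eff)))
        log_rows.append(
            {"country": s.country_code, "n_raw": s.n, "dropped": dropped, "n": int(round(n_eff))}
        )
    cset = CorrelationSet(countries=countries, R=mats, N=ns, schema=schema)
    return cset, pd.DataFrame(log_rows)
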