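"""End-to-end pipeline: simulate/load -> correlate -> compare measurement
models -> heterogeneity test -> pooled MAGNA -> centrality -> bootstrap.

Every stage logs its inputs and outcomes; all randomness derives from the
single config seed, so reruns with the same config are byte-identical.
"""
from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .centrality import bonferroni_alpha, bootstrap_centrality_difference, centrality_table, single_country_centralities
from .correlate import CorrelationSet, CountrySample, build_correlation_set
from .ggm import is_positive_definite
from .items import DEFAULT_SCHEMA, ItemSchema
from .magna import MAGNA, fit_saturated_models
from .measurement import MODEL_KINDS, compare_measurement_models
from .simulate import DEFAULT_TAU, CountryConfig, generate_study

logger = logging.getLogger(__name__)


@dataclass
class PipelineConfig:
    """Configuration for :func:`run_pipeline` (YAML/JSON loadable)."""

    outdir: str = "flournet_output"
    seed: int = 0
    # input: exactly one of simulate / data_dir / correlations_dir
    simulate: dict | None = None  # keys: countries ([{code,n,...}] or null), tau, truth_source
    data_dir: str | None = None  # raw per-country CSVs
    correlations_dir: str | None = None  # precomputed matrices + manifest
    alpha_edge: float = 0.05
    alpha_bonferroni: float | None = None  # auto: 0.05 / node pairs, 4 decimals
    bootstrap_B: int = 1_000_000
    measurement_kinds: tuple = MODEL_KINDS
    # flags
    kish_n: bool = False
    fisher_z: bool = False
    prune_refit: bool = False
    discretize: bool = False

    def __post_init__(self) -> None:
        if not 0 < self.alpha_edge < 1:
            raise ValueError("alpha_edge must be in (0, 1)")
        if self.alpha_bonferroni is not None and not 0 < self.alpha_bonferroni < 1:
            raise ValueError("alpha_bonferroni must be in (0, 1)")
        if self.bootstrap_B < 1_000:
            raise ValueError("bootstrap_B must be >= 1,000")
        sources = [self.simulate is not None, self.data_dir is not None,
                   self.correlations_dir is not None]
        if sum(sources) == 0:
            self.simulate = {}
        elif sum(sources) > 1:
            raise ValueError("specify exactly one of simulate / data_dir / correlations_dir")

    @classmethod
    def from_file(cls, path) -> "PipelineConfig":
        text = Path(path).read_text()
        payload = yaml.safe_load(text)
        return cls(**payload)


# ---------------------------------------------------------------------------
# correlation-set persistence

def save_correlation_set(cset: CorrelationSet, outdir) -> None:
    """Write labeled 12x12 matrix CSVs plus a manifest of sample sizes."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    codes = list(cset.schema.codes)
    for country, R, n in zip(cset.countries, cset.R, cset.N):
        pd.DataFrame(R, index=codes, columns=codes).to_csv(
            outdir / f"{country}.csv", float_format="%.12g"
        )
    manifest = {"countries": list(cset.countries), "N": [int(n) for n in cset.N]}
    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1))


def load_correlation_set(path, schema: ItemSchema = DEFAULT_SCHEMA) -> CorrelationSet:
    """Read a correlation set written by :func:`save_correlation_set`.

    Round trip is lossless to ~1e-12. Raises when a manifest country is
    missing on disk or a matrix's labels disagree with the item schema.
    """
    path = Path(path)
    manifest = json.loads((path / "manifest.json").read_text())
    countries, mats = manifest["countries"], []
    for country in countries:
        f = path / f"{country}.csv"
        if not f.exists():
            raise FileNotFoundError(f"manifest lists {country!r} but {f} is missing")
        df = pd.read_csv(f, index_col=0)
        bad = [c for c in df.columns if c not in schema.codes] + [
            c for c in df.index if c not in schema.codes
        ]
        if list(df.columns) != list(schema.codes) or list(df.index) != list(schema.codes):
            raise ValueError(
                f"{country}: matrix labels do not match the item schema"
                + (f" (offending: {sorted(set(bad))})" if bad else " (wrong order)")
            )
        mats.append(df.to_numpy(dtype=float))
    return CorrelationSet(
        countries=countries, R=mats, N=[int(n) for n in manifest["N"]], schema=schema
    )


def _load_raw_samples(data_dir, schema: ItemSchema) -> list[CountrySample]:
    files = sorted(Path(data_dir).glob("*.csv"))
    files = [f for f in files if not f.name.endswith("_true_corr.csv")]
    samples = []
    for f in files:
        df = pd.read_csv(f)
        if "country" not in df.columns or "weight" not in df.columns:
            continue
        country = str(df["country"].iloc[0])
        resp = df[list(schema.codes)]
        samples.append(
            CountrySample(
                country_code=country,
                responses=resp,
                weights=df["weight"].to_numpy(dtype=float),
                schema=schema,
            )
        )
    if not samples:
        raise FileNotFoundError(f"no per-country CSVs found in {data_dir}")
    return samples


# ---------------------------------------------------------------------------
# the pipeline

def _round_floats(obj, nd: int = 10):
    if isinstance(obj, float):
        return round(obj, nd)
    if isinstance(obj, dict):
        return {k: _round_floats(v, nd) for k, v in obj.items()}
    if isinstance(obj, (list, tuple)):
        return [_round_floats(v, nd) for v in obj]
    return obj


def run_pipeline(config: PipelineConfig, schema: ItemSchema = DEFAULT_SCHEMA) -> dict:
    """Run every analysis stage; writes a result bundle and returns the summary.

    Outputs under ``config.outdir``: per-country correlation CSVs, the model
    comparison table, pooled edge list with CIs, random-effect summary,
    centrality tables, difference-test p-matrices, and ``summary.json``.
    """
    outdir = Path(config.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    summary: dict = {"seed": config.seed, "stages": []}

    def stage(name):
        logger.info("stage: %s", name)
        summary["stages"].append(name)

    # -- stage 1: data -----------------------------------------------------
    if config.correlations_dir is not None:
        stage("load_correlations")
        cset = load_correlation_set(config.correlations_dir, schema=schema)
        drop_log = None
    else:
        if config.simulate is not None:
            stage("simulate")
            sim = dict(config.simulate)
            countries = sim.pop("countries", None)
            configs = None
            if countries:
                configs = [CountryConfig(**c) for c in countries]
            study = generate_study(
                configs=configs,
                truth_source=sim.pop("truth_source", "reference"),
                tau=sim.pop("tau", DEFAULT_TAU),
                seed=sim.pop("seed", config.seed),
                schema=schema,
                discretize=config.discretize,
                **sim,
            )
            study.write(outdir / "data")
            samples = study.samples
            summary["truth"] = {
                "tau_mean": float(np.mean(study.truth.tau)),
                "n_countries": len(study.samples),
            }
        else:
            stage("load_raw")
            samples = _load_raw_samples(config.data_dir, schema)
        stage("correlate")
        cset, drop_log = build_correlation_set(samples, kish_n=config.kish_n, schema=schema)
        save_correlation_set(cset, outdir / "correlations")
        drop_log.to_csv(outdir / "deletion_log.csv", index=False)
        summary["deletion"] = drop_log.to_dict(orient="records")

    summary["countries"] = list(cset.countries)
    summary["N"] = [int(n) for n in cset.N]

    # total-sample matrix: N-weighted mean of the country matrices
    R_total = sum(n * R for R, n in zip(cset.R, cset.N)) / cset.total_n
    if not is_positive_definite(R_total):
        raise RuntimeError("stage measurement: total-sample matrix not positive definite")

    # -- stage 2: measurement-model comparison ------------------------------
    stage("measurement_comparison")
    comparison = compare_measurement_models(
        R_total, cset.total_n, kinds=config.measurement_kinds, schema=schema,
        seed=config.seed,
    )
    comparison.to_csv(outdir / "model_comparison.csv")
    summary["model_comparison"] = json.loads(
        comparison.table.drop(columns=["model"]).to_json(orient="index")
    )
    summary["best_model_by_aic"] = comparison.table.index[0]

    # -- stage 3: heterogeneity --------------------------------------------
    if cset.n_countries >= 2:
        stage("heterogeneity")
        het = fit_saturated_models(cset)
        het.to_frame().to_csv(outdir / "heterogeneity.csv")
        summary["heterogeneity"] = {
            "aic_single": het.aic_single, "bic_single": het.bic_single,
            "aic_pooled": het.aic_pooled, "bic_pooled": het.bic_pooled,
            "preferred_aic": het.preferred_aic, "preferred_bic": het.preferred_bic,
        }
    else:
        logger.info("heterogeneity stage skipped: single country")
        summary["heterogeneity"] = "skipped (single country)"

    # -- stage 4: pooled network (MAGNA) ------------------------------------
    stage("magna")
    model = MAGNA(cset, fisher_z=config.fisher_z)
    if cset.n_countries < 3:
        result = model.fit(tau_fixed=0.0, alpha=config.alpha_edge)
    else:
        result = model.fit(alpha=config.alpha_edge)
    edge_tab = result.edge_table()
    edge_tab.to_csv(outdir / "pooled_edges.csv", index=False)
    result.random_effect_summary().to_csv(outdir / "random_effects.csv", index=False)
    result.network.to_graphml(outdir / "pooled_network.graphml")
    summary["pooled_network"] = {
        "n_retained": int(edge_tab["retained"].sum()),
        "tau_mean": result.mean_tau,
        "tau_min": result.min_tau,
        "tau_max": result.max_tau,
        "edges": json.loads(edge_tab.set_index("edge").to_json(orient="index")),
    }

    # -- stage 5: centrality -------------------------------------------------
    stage("centrality")
    pooled_cent = centrality_table(result.network, label="pooled")
    pooled_cent.to_csv(outdir / "centrality_pooled.csv", index=False)
    country_cent = single_country_centralities(cset, alpha=config.alpha_edge)
    pd.concat(country_cent.values(), ignore_index=True).to_csv(
        outdir / "centrality_countries.csv", index=False
    )
    summary["centrality_pooled"] = json.loads(
        pooled_cent.set_index("item")[["expected_influence", "predictability"]]
        .to_json(orient="index")
    )

    # -- stage 6: bootstrap difference test ----------------------------------
    stage("bootstrap_difference")
    alpha_b = (
        config.alpha_bonferroni
        if config.alpha_bonferroni is not None
        else bonferroni_alpha(schema.n_items)
    )
    diff = bootstrap_centrality_difference(
        result, B=config.bootstrap_B, seed=config.seed, alpha=alpha_b
    )
    for name, res in diff.items():
        res.to_frame().to_csv(outdir / f"difference_{name}.csv")
    summary["difference_tests"] = {
        "alpha_bonferroni": alpha_b,
        "B": config.bootstrap_B,
        "n_significant": {
            name: int(res.significant.sum() // 2) for name, res in diff.items()
        },
    }

    payload = json.dumps(_round_floats(summary), indent=1, sort_keys=True)
    (outdir / "summary.json").write_text(payload)
    return summary
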