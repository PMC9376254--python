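"""End-to-end pipeline orchestration and the machine-readable run report.

A run goes: raw questionnaire CSVs (or a simulation preset, or an already
estimated weight matrix in network-only mode) -> screened score table ->
EBIC-GLASSO network -> centrality + bridge + predictability ->
case-dropping bootstrap stability -> artifacts (CSV/GraphML/JSON) and a
versioned JSON report. Every number in the report is recomputable from
the config and inputs; all randomness flows from the config seed.
"""

from __future__ import annotations

import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .bridge import bridge_expected_influence, identify_bridge_nodes
from .centrality import centrality_table
from .network import WeightedNetwork, estimate_network
from .predictability import node_predictability
from .scales import (DEFAULT_CERQ_KEY, DEFAULT_TAS_KEY, build_score_table,
                     keys_from_config)
from .stability import case_drop_bootstrap, cs_coefficient
from .datasets import COMMUNITIES, NODE_LABELS

logger = logging.getLogger(__name__)

REPORT_SCHEMA_VERSION = 1


@dataclass
class RunConfig:
    """Validated configuration of one pipeline run.

    Exactly one input mode applies: raw item CSVs (``iat_csv``/``tas_csv``/
    ``cerq_csv``), a pre-scored subscale CSV (``scores_csv``), a serialized
    weight matrix (``network_csv``, network-only mode), or a simulation
    preset (``simulate`` = ``study_cohort`` or ``reference_scores``).
    """

    iat_csv: str | None = None
    tas_csv: str | None = None
    cerq_csv: str | None = None
    scores_csv: str | None = None
    network_csv: str | None = None
    simulate: str | None = None
    sim_n: int = 560
    cutoff: int = 50
    method: str = "pearson"
    gamma: float = 0.5
    n_lambda: int = 100
    lambda_ratio: float = 0.01
    predictability_method: str = "ols"
    boot_reps: int = 1000
    boot_cor: float = 0.7
    boot_prob: float = 0.95
    seed: int = 0
    outdir: str | None = None
    keys: dict = field(default_factory=dict)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            cfg = yaml.safe_load(fh) or {}
        known = {f for f in cls.__dataclass_fields__}
        unknown = set(cfg) - known
        if unknown:
            raise ValueError(f"unknown config keys: {sorted(unknown)}")
        return cls(**cfg)

    def validate(self) -> None:
        modes = [m for m in (self.iat_csv, self.scores_csv,
                             self.network_csv, self.simulate)
                 if m is not None]
        if len(modes) != 1:
            raise ValueError("exactly one input mode must be set "
                             "(raw CSVs, scores_csv, network_csv, or "
                             "simulate)")
        if self.iat_csv is not None and (self.tas_csv is None
                                         or self.cerq_csv is None):
            raise ValueError("raw mode needs iat_csv, tas_csv and cerq_csv")
        for p in (self.iat_csv, self.tas_csv, self.cerq_csv,
                  self.scores_csv, self.network_csv):
            if p is not None and not Path(p).exists():
                raise FileNotFoundError(p)
        if self.simulate not in (None, "study_cohort", "reference_scores"):
            raise ValueError(f"unknown simulation preset: {self.simulate!r}")

    def digest(self) -> str:
        payload = json.dumps(
            {k: getattr(self, k) for k in self.__dataclass_fields__},
            sort_keys=True, default=str)
        return hashlib.sha256(payload.encode()).hexdigest()[:16]


@dataclass
class RunReport:
    """All computed outputs of a run plus provenance."""

    n_total: int | None
    n_screened: int | None
    network: WeightedNetwork
    centrality: pd.DataFrame
    bridge: pd.DataFrame
    bridge_nodes: dict[str, str]
    predictability: pd.DataFrame | None
    average_r2: float | None
    cs: dict[str, float] | None
    provenance: dict

    def to_dict(self) -> dict:
        def r6(x):
            return float(f"{float(x):.6g}")

        out = {
            "schema_version": REPORT_SCHEMA_VERSION,
            "n_total": self.n_total,
            "n_screened": self.n_screened,
            "network": {
                "labels": self.network.labels,
                "weights": [[r6(v) for v in row]
                            for row in self.network.weights],
                "meta": {k: (r6(v) if isinstance(v, float) else v)
                         for k, v in self.network.meta.items()},
            },
            "centrality": {
                col: {n: r6(v) for n, v in self.centrality[col].items()}
                for col in ("strength", "closeness", "betweenness")
            },
            "bridge": {
                col: {n: r6(v) for n, v in self.bridge[col].items()}
                for col in ("bei_signed", "bei_absolute")
            },
            "bridge_nodes": self.bridge_nodes,
            "predictability": (
                None if self.predictability is None else
                {n: r6(v) for n, v in self.predictability["r2"].items()}),
            "average_r2": None if self.average_r2 is None
            else r6(self.average_r2),
            "cs": None if self.cs is None
            else {k: r6(v) for k, v in self.cs.items()},
            "provenance": self.provenance,
        }
        return out

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_dict(), fh, indent=2)


def _stage(name: str):
    def wrap(fn):
        def inner(*args, **kwargs):
            t0 = time.perf_counter()
            try:
                result = fn(*args, **kwargs)
            except Exception as err:
                raise RuntimeError(f"stage {name!r} failed: {err}") from err
            logger.info("stage %-14s %.2fs", name, time.perf_counter() - t0)
            return result
        return inner
    return wrap


def _load_scores(config: RunConfig) -> tuple[pd.DataFrame, int | None]:
    """Score table (12 analysis columns) plus pre-screening cohort size."""
    if config.simulate == "study_cohort":
        from .synthetic import study_cohort

        cohort = study_cohort(seed=config.seed)
        tas_key, cerq_key = keys_from_config(config.keys)
        table = build_score_table(cohort.iat_items, cohort.tas_items,
                                  cohort.cerq_items, tas_key=tas_key,
                                  cerq_key=cerq_key, cutoff=config.cutoff)
        return table[list(NODE_LABELS)], len(cohort.iat_items)
    if config.simulate == "reference_scores":
        from .synthetic import sample_reference_scores

        return sample_reference_scores(config.sim_n, seed=config.seed), None
    if config.scores_csv is not None:
        df = pd.read_csv(config.scores_csv)
        if "participant_id" in df.columns:
            df = df.set_index("participant_id")
        n_total = len(df)
        if "iat_total" in df.columns:
            from .scales import screen_addiction

            df = df[screen_addiction(df["iat_total"], config.cutoff)]
            df = df.drop(columns="iat_total")
        missing = [c for c in NODE_LABELS if c not in df.columns]
        if missing:
            raise ValueError(f"scores file lacks columns: {missing}")
        return df[list(NODE_LABELS)], n_total
    tas_key, cerq_key = keys_from_config(config.keys)
    iat = pd.read_csv(config.iat_csv)
    tas = pd.read_csv(config.tas_csv)
    cerq = pd.read_csv(config.cerq_csv)
    table = build_score_table(iat, tas, cerq, tas_key=tas_key,
                              cerq_key=cerq_key, cutoff=config.cutoff)
    return table[list(NODE_LABELS)], len(iat)


def run_pipeline(config: RunConfig) -> RunReport:
    """Execute the configured analysis end to end.

    Deterministic given the config seed; writes artifacts to
    ``config.outdir`` when set. Stage failures propagate with the stage
    name attached.
    """
    config.validate()
    scores: pd.DataFrame | None = None
    n_total: int | None = None

    if config.network_csv is not None:
        net = _stage("ingest")(WeightedNetwork.from_weight_csv)(
            config.network_csv)
        n_screened = net.meta.get("n")
    else:
        scores, n_total = _stage("score")(_load_scores)(config)
        n_screened = len(scores)
        net = _stage("estimate")(estimate_network)(
            scores, gamma=config.gamma, method=config.method,
            n_lambda=config.n_lambda, ratio=config.lambda_ratio)

    cent = _stage("centrality")(centrality_table)(net)
    brid = _stage("bridge")(bridge_expected_influence)(net)
    bridge_nodes = identify_bridge_nodes(brid, mode="absolute")

    pred = avg_r2 = None
    cs = boot = None
    if scores is not None:
        pred = _stage("predictability")(node_predictability)(
            scores, method=config.predictability_method)
        avg_r2 = pred.attrs["average_r2"]
        if config.boot_reps > 0:
            boot = _stage("stability")(case_drop_bootstrap)(
                scores, n_replicates=config.boot_reps, seed=config.seed,
                estimator=lambda df: estimate_network(
                    df, gamma=config.gamma, method=config.method,
                    n_lambda=config.n_lambda, ratio=config.lambda_ratio))
            cs = cs_coefficient(boot, cor=config.boot_cor,
                                prob=config.boot_prob)

    report = RunReport(
        n_total=n_total, n_screened=n_screened, network=net,
        centrality=cent, bridge=brid, bridge_nodes=bridge_nodes,
        predictability=pred, average_r2=avg_r2, cs=cs,
        provenance={
            "package_version": __version__,
            "config_digest": config.digest(),
            "seed": config.seed,
            "mode": ("network_only" if config.network_csv else
                     config.simulate or "csv"),
        },
    )

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        net.to_weight_csv(outdir / "weights.csv")
        net.to_graphml(outdir / "network.graphml")
        net.to_json(outdir / "network.json")
        cent.to_csv(outdir / "centrality.csv")
        brid.to_csv(outdir / "bridge.csv")
        if pred is not None:
            pred.to_csv(outdir / "predictability.csv")
        if boot is not None:
            boot.to_csv(outdir / "stability.csv")
        if scores is not None:
            scores.to_csv(outdir / "scores.csv")
        report.to_json(outdir / "report.json")
    return report
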