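"""End-to-end orchestration: simulate → filter → networks → features →
reduction → ablation, with per-stage artifacts, seeds and a JSON manifest.

Each stage reads the artifacts of its prerequisites from the output
directory and writes its own, so stages can be rerun individually; a rerun
with the same config and seed is bit-identical for deterministic stages.
One global seed fans out to per-stage seeds by stable hashing of the stage
name, so stage-level reproducibility does not depend on execution order.

Era hygiene is structural: the multimorbidity network is built only from
records admitted in the MN era (the first span), while models, the
similarity index, per-disease LOS means and the LDA fit see only the
modeling era (the later span) — and within it, only training rows.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
import time
from dataclasses import dataclass, field
from datetime import date
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
import yaml

from . import features, modeling, network, records as rio, similarity, synthetic
from .eci import default_eci_mapping
from .records import ChronicDiseaseCatalog, InclusionConfig

logger = logging.getLogger("losnet")

STAGES = ["simulate", "filter", "build-mn", "build-psn", "featurize",
          "reduce", "train", "evaluate", "report"]


class ConfigError(ValueError):
    """The pipeline configuration is invalid."""


class StageDependencyError(RuntimeError):
    """A required upstream artifact is missing."""


def stage_seed(global_seed: int, stage: str) -> int:
    h = hashlib.sha256(f"{global_seed}:{stage}".encode()).hexdigest()
    return int(h, 16) % (2**31)


def _parse_date(v) -> date:
    return v if isinstance(v, date) else date.fromisoformat(str(v))


@dataclass
class PipelineConfig:
    seed: int = 0
    output_dir: Path = Path("losnet_out")
    records_path: Path | None = None       # external records; else simulate
    catalog_path: Path | None = None       # CSV with a `code` column
    simulate: dict = field(default_factory=lambda: {"preset": "small"})
    inclusion: dict = field(default_factory=dict)
    mn_era: tuple[date, date] = (date(2015, 1, 1), date(2017, 12, 31))
    modeling_era: tuple[date, date] = (date(2018, 1, 1), date(2019, 12, 31))
    mn: dict = field(default_factory=dict)        # min_pair_count, edge_rule,
                                                  # sigma_mode, weight_mode
    psn: dict = field(default_factory=dict)       # k, backend, exclude_same_patient
    features: dict = field(default_factory=dict)  # window_years
    lda: dict = field(default_factory=dict)       # components, candidates
    experiment: dict = field(default_factory=dict)

    def __post_init__(self):
        self.output_dir = Path(self.output_dir)
        self.mn_era = tuple(_parse_date(d) for d in self.mn_era)
        self.modeling_era = tuple(_parse_date(d) for d in self.modeling_era)
        problems = []
        if self.mn_era[0] > self.mn_era[1]:
            problems.append("mn_era start after end")
        if self.modeling_era[0] > self.modeling_era[1]:
            problems.append("modeling_era start after end")
        if not self.mn_era[1] < self.modeling_era[0]:
            problems.append("mn_era must strictly precede modeling_era")
        for key in ("records_path", "catalog_path"):
            p = getattr(self, key)
            if p is not None and not Path(p).exists():
                problems.append(f"{key} does not exist: {p}")
        if problems:
            raise ConfigError("; ".join(problems))

    @classmethod
    def from_yaml(cls, path) -> "PipelineConfig":
        with open(path) as fh:
            raw = yaml.safe_load(fh) or {}
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(raw) - known
        if unknown:
            raise ConfigError(f"unknown config fields: {sorted(unknown)}")
        return cls(**raw)


class Pipeline:
    def __init__(self, cfg: PipelineConfig):
        self.cfg = cfg
        self.out = cfg.output_dir
        self.out.mkdir(parents=True, exist_ok=True)
        self._manifest_path = self.out / "manifest.json"

    # -- manifest -----------------------------------------------------------

    def _manifest(self) -> dict:
        if self._manifest_path.exists():
            return json.loads(self._manifest_path.read_text())
        return {"stages": {}}

    def _log_stage(self, stage: str, counts: dict[str, Any],
                   outputs: list[str]) -> None:
        man = self._manifest()
        cfg_hash = hashlib.sha256(
            json.dumps(str(self.cfg), sort_keys=True).encode()
        ).hexdigest()[:12]
        man["stages"][stage] = {
            "seed": stage_seed(self.cfg.seed, stage),
            "config_hash": cfg_hash,
            "counts": counts,
            "outputs": outputs,
            "timestamp": time.strftime("%Y-%m-%dT%H:%M:%S"),
        }
        self._manifest_path.write_text(json.dumps(man, indent=1))
        logger.info("stage=%s counts=%s", stage, counts)

    def _require(self, stage: str, *paths: Path) -> None:
        for p in paths:
            if not p.exists():
                raise StageDependencyError(
                    f"stage {stage!r} needs missing artifact {p}; run the "
                    f"producing stage first"
                )

    # -- artifacts ----------------------------------------------------------

    @property
    def records_csv(self) -> Path:
        return (Path(self.cfg.records_path) if self.cfg.records_path
                else self.out / "records.csv")

    @property
    def catalog_csv(self) -> Path:
        return (Path(self.cfg.catalog_path) if self.cfg.catalog_path
                else self.out / "catalog.csv")

    def load_catalog(self) -> ChronicDiseaseCatalog:
        df = pd.read_csv(self.catalog_csv, dtype=str)
        return ChronicDiseaseCatalog.from_codes(df["code"], str(self.catalog_csv))

    # -- stages -------------------------------------------------------------

    def simulate(self) -> None:
        spec = dict(self.cfg.simulate)
        preset = spec.pop("preset", None)
        if preset:
            params = synthetic.FIXTURE_PRESETS[preset]
        else:
            if "planted_pairs" in spec:
                spec["planted_pairs"] = tuple(
                    synthetic.PlantedPair(*p) for p in spec["planted_pairs"]
                )
            spec.setdefault("seed", stage_seed(self.cfg.seed, "simulate"))
            params = synthetic.SyntheticParams(**spec)
        recs, truth = synthetic.generate_cohort(params)
        rio.write_records(recs, self.out / "records.csv")
        pd.DataFrame({"code": truth.codes}).to_csv(
            self.out / "catalog.csv", index=False)
        (self.out / "ground_truth.json").write_text(json.dumps({
            "codes": truth.codes,
            "prevalence": truth.prevalence.tolist(),
            "effect_days": truth.effect_days.tolist(),
            "planted_pairs": [
                dataclasses.asdict(p) for p in truth.planted_pairs
            ],
            "age_slope": truth.age_slope,
            "base_days": truth.base_days,
            "frailty": truth.frailty,
        }, indent=1))
        self._log_stage("simulate", {"records": len(recs)},
                        ["records.csv", "catalog.csv", "ground_truth.json"])

    def filter(self) -> None:
        self._require("filter", self.records_csv, self.catalog_csv)
        recs = rio.read_records(self.records_csv)
        catalog = self.load_catalog()
        inc = dict(self.cfg.inclusion)
        if "date_range" in inc and inc["date_range"] is not None:
            inc["date_range"] = tuple(_parse_date(d) for d in inc["date_range"])
        else:
            inc["date_range"] = (self.cfg.mn_era[0], self.cfg.modeling_era[1])
        kept, tally = rio.apply_inclusion_criteria(
            recs, catalog, InclusionConfig(**inc))
        rio.write_records(kept, self.out / "filtered.csv")
        self._log_stage("filter",
                        {"input": len(recs), "kept": len(kept), "tally": tally},
                        ["filtered.csv"])

    def _filtered(self) -> list:
        self._require("current", self.out / "filtered.csv")
        return rio.read_records(self.out / "filtered.csv")

    def _era_records(self, era) -> list:
        return [r for r in self._filtered()
                if era[0] <= r.admission_date <= era[1]]

    def build_mn(self) -> None:
        self._require("build-mn", self.out / "filtered.csv", self.catalog_csv)
        catalog = self.load_catalog()
        mn_recs = self._era_records(self.cfg.mn_era)
        M = network.build_patient_disease_matrix(mn_recs, catalog,
                                                 era=self.cfg.mn_era)
        opts = dict(self.cfg.mn)
        weight_mode = opts.pop("weight_mode", "rr")
        g = network.build_mn(M, **opts)
        evc = network.eigenvector_centrality(g, weight_mode=weight_mode)
        network.edge_table(g).to_csv(self.out / "mn_edges.csv", index=False)
        network.node_table(g, evc).to_csv(self.out / "mn_nodes.csv", index=False)
        import networkx as nx
        nx.write_graphml(g, self.out / "mn.graphml")
        self._log_stage("build-mn", {
            "mn_records": len(mn_recs), "patients": M.n_patients,
            "nodes": g.number_of_nodes(), "edges": g.number_of_edges(),
        }, ["mn_edges.csv", "mn_nodes.csv", "mn.graphml"])

    def _evc(self) -> dict[str, float]:
        self._require("current", self.out / "mn_nodes.csv")
        df = pd.read_csv(self.out / "mn_nodes.csv")
        return dict(zip(df["code"], df["evc"]))

    def _first_split(self, ids):
        base = int(self.cfg.experiment.get("base_seed",
                                           stage_seed(self.cfg.seed, "train")))
        return modeling.split_ids(ids, modeling.SplitSpec(seed=base))

    def build_psn(self) -> None:
        """Index the first split's training admissions; export the test
        rows' neighbor lists."""
        self._require("build-psn", self.out / "filtered.csv",
                      self.out / "mn_nodes.csv")
        catalog = self.load_catalog()
        recs = self._era_records(self.cfg.modeling_era)
        split = self._first_split([r.record_id for r in recs])
        train = [r for r in recs if r.record_id in set(split.train)]
        opts = dict(self.cfg.psn)
        k = opts.pop("k", 100)
        excl = opts.pop("exclude_same_patient", True)
        index = similarity.build_index(
            train, backend=opts.pop("backend", "exact"), catalog=catalog,
            seed=stage_seed(self.cfg.seed, "build-psn"), **opts)
        test = [r for r in recs if r.record_id in set(split.test)]
        lists = [similarity.query_neighbors(index, r, k=k,
                                            exclude_same_patient=excl)
                 for r in test]
        similarity.neighbor_table(lists).to_csv(
            self.out / "psn_neighbors.csv", index=False)
        self._log_stage("build-psn", {
            "train_indexed": len(train), "queries": len(test),
            "blocks": len(index.blocks),
        }, ["psn_neighbors.csv"])

    def _dataset(self) -> modeling.ModelingDataset:
        catalog = self.load_catalog()
        modeling_recs = self._era_records(self.cfg.modeling_era)
        psn = dict(self.cfg.psn)
        return modeling.ModelingDataset.build(
            modeling_recs, self._evc(), catalog, default_eci_mapping(),
            history_source=self._filtered(),
            window_years=self.cfg.features.get("window_years", 3),
            psn_k=psn.get("k", 100),
            psn_backend=psn.get("backend", "exact"),
            exclude_same_patient=psn.get("exclude_same_patient", True),
        )

    def featurize(self) -> None:
        self._require("featurize", self.out / "filtered.csv",
                      self.out / "mn_nodes.csv")
        ds = self._dataset()
        static = pd.concat([ds.baseline, ds.history, ds.evc_raw], axis=1)
        static["los"] = ds.labels()
        static.to_csv(self.out / "features_static.csv")
        schema = {c: "baseline" for c in ds.baseline.columns}
        schema.update({c: "history" for c in ds.history.columns})
        schema.update({c: "mn" for c in ds.evc_raw.columns})
        (self.out / "features_schema.json").write_text(
            json.dumps(schema, indent=1, sort_keys=True))
        self._log_stage("featurize", {
            "rows": len(static),
            "baseline_width": ds.baseline.shape[1],
            "history_width": ds.history.shape[1],
            "evc_width": ds.evc_raw.shape[1],
        }, ["features_static.csv", "features_schema.json"])

    def _plan(self) -> modeling.ExperimentPlan:
        exp = dict(self.cfg.experiment)
        lda_cfg = dict(self.cfg.lda)
        return modeling.ExperimentPlan(
            subsets=exp.get("subsets", modeling.DEFAULT_SUBSETS),
            model_grids=exp.get("models", modeling.DEFAULT_GRIDS),
            repeats=int(exp.get("repeats", 10)),
            base_seed=int(exp.get("base_seed",
                                  stage_seed(self.cfg.seed, "train"))),
            lda_components=lda_cfg.get("components", "select"),
            lda_candidates=tuple(lda_cfg.get("candidates", (8, 16, 32, 64))),
        )

    def reduce(self) -> None:
        """Fit the LDA projection on the first split and persist it."""
        self._require("reduce", self.out / "features_static.csv",
                      self.out / "features_schema.json")
        ds = self._dataset()
        plan = self._plan()
        split = self._first_split(ds.record_ids)
        y = ds.labels()
        X_tr = ds.evc_raw.loc[list(split.train)].to_numpy()
        y_tr = y.loc[list(split.train)].to_numpy()
        from .lda import fit_lda, select_components

        if plan.lda_components == "select":
            dim, scores = select_components(
                plan.lda_candidates, X_tr, y_tr,
                ds.evc_raw.loc[list(split.val)].to_numpy(),
                y.loc[list(split.val)].to_numpy())
        else:
            dim, scores = int(plan.lda_components), {}
        proj = fit_lda(X_tr, y_tr, dim)
        np.savetxt(self.out / "lda_projection.csv",
                   proj.estimator.scalings_[:, :dim], delimiter=",")
        (self.out / "lda_meta.json").write_text(json.dumps({
            "n_components": dim, "n_classes": proj.n_classes,
            "n_features": proj.n_features, "n_train_rows": proj.n_train_rows,
            "validation_mae": scores,
        }, indent=1))
        self._log_stage("reduce", {"n_components": dim,
                                   "n_classes": proj.n_classes},
                        ["lda_projection.csv", "lda_meta.json"])

    def train(self) -> None:
        self._require("train", self.out / "filtered.csv",
                      self.out / "mn_nodes.csv")
        ds = self._dataset()
        report = modeling.run_ablation(ds, self._plan())
        report.runs.to_csv(self.out / "ablation_runs.csv", index=False)
        self._log_stage("train", {
            "rows": len(ds.records),
            "cells": int(report.runs[["model", "subset"]]
                         .drop_duplicates().shape[0]),
        }, ["ablation_runs.csv"])
        self._report_cache = report

    def evaluate(self) -> None:
        self._require("evaluate", self.out / "ablation_runs.csv")
        report = getattr(self, "_report_cache", None)
        if report is None:
            runs = pd.read_csv(self.out / "ablation_runs.csv")
            report = modeling.EvalReport(runs, {})
        report.summary().to_csv(self.out / "report_summary.csv", index=False)
        if report.error_profile is not None:
            report.error_profile.to_csv(self.out / "error_profile.csv",
                                        index=False)
        for (model, subset), (sums, top) in report.importances.items():
            top.to_csv(self.out / f"importance_{model}_{subset}.csv",
                       index=False)
            pd.Series(sums).to_csv(
                self.out / f"importance_groups_{model}_{subset}.csv")
        self._log_stage("evaluate", {"cells": len(report.summary())},
                        ["report_summary.csv"])

    def report(self) -> dict:
        man = self._manifest()
        print(json.dumps(man, indent=1))
        return man

    def run(self, stage: str) -> None:
        if stage == "all":
            chain = STAGES if not self.cfg.records_path else STAGES[1:]
            for s in chain:
                self.run(s)
            return
        method = {
            "simulate": self.simulate, "filter": self.filter,
            "build-mn": self.build_mn, "build-psn": self.build_psn,
            "featurize": self.featurize, "reduce": self.reduce,
            "train": self.train, "evaluate": self.evaluate,
            "report": self.report,
        }.get(stage)
        if method is None:
            raise ConfigError(f"unknown stage {stage!r}; choose from "
                              f"{STAGES + ['all']}")
        t0 = time.time()
        method()
        logger.info("stage=%s elapsed=%.1fs", stage, time.time() - t0)
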