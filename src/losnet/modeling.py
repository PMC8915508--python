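"""Ablation harness: train/validation/test splitting, grid search, the
MAE/RMSE/R² metrics, feature-subset experiments with repeat statistics,
per-LOS error profiles and grouped feature importances.

Model internals are delegated to established regressors (gradient-boosted
trees, random forest, linear SVM, optional feed-forward net) behind a
uniform fit/predict/importances surface; everything upstream of them —
the networks, the features, the leakage discipline — is this package's
own machinery.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Callable, Mapping, Sequence

import numpy as np
import pandas as pd

from .eci import EciMapping
from .features import (
    FeatureTable, GROUPS, assemble, baseline_block, evc_block,
    evc_vocabulary, history_block, split_dependent_blocks,
)
from .lda import fit_lda, select_components
from .records import AdmissionRecord, ChronicDiseaseCatalog, age_group

# ---------------------------------------------------------------------------
# Splits

@dataclass(frozen=True)
class SplitSpec:
    """Random 80/20 train/test split, then 20% of train as validation."""

    seed: int = 0
    test_fraction: float = 0.2
    val_fraction: float = 0.2


@dataclass(frozen=True)
class Split:
    train: tuple[str, ...]
    val: tuple[str, ...]
    test: tuple[str, ...]

    def all_ids(self) -> tuple[str, ...]:
        return self.train + self.val + self.test


def split_ids(ids: Sequence[str], spec: SplitSpec) -> Split:
    """Deterministic disjoint cover of ``ids`` honoring the ratios."""
    if len(ids) < 10:
        raise ValueError("need at least 10 rows to split")
    rng = np.random.default_rng(spec.seed)
    perm = list(np.array(ids, dtype=object)[rng.permutation(len(ids))])
    n_test = round(spec.test_fraction * len(ids))
    test, rest = perm[:n_test], perm[n_test:]
    n_val = round(spec.val_fraction * len(rest))
    return Split(tuple(rest[n_val:]), tuple(rest[:n_val]), tuple(test))


# ---------------------------------------------------------------------------
# Metrics

def mae(y, y_hat) -> float:
    y, y_hat = _aligned(y, y_hat)
    return float(np.abs(y - y_hat).mean())


def rmse(y, y_hat) -> float:
    y, y_hat = _aligned(y, y_hat)
    return float(np.sqrt(((y - y_hat) ** 2).mean()))


def r2(y, y_hat) -> float:
    """1 − SSE/SST with SST around the mean of the *observed* values."""
    y, y_hat = _aligned(y, y_hat)
    sst = float(((y - y.mean()) ** 2).sum())
    if sst == 0.0:
        raise ZeroDivisionError("R² undefined: observed values are constant")
    return 1.0 - float(((y - y_hat) ** 2).sum()) / sst


def _aligned(y, y_hat) -> tuple[np.ndarray, np.ndarray]:
    y = np.asarray(y, dtype=float)
    y_hat = np.asarray(y_hat, dtype=float)
    if y.shape != y_hat.shape or y.size == 0:
        raise ValueError("y and ŷ must be non-empty and equal length")
    return y, y_hat


# ---------------------------------------------------------------------------
# Models

class UnsupportedModelError(TypeError):
    """The model does not expose per-feature importances."""


def make_model(name: str, params: Mapping | None = None, seed: int = 0):
    """Instantiate a registered regressor with the given hyperparameters."""
    params = dict(params or {})
    if name == "xgboost":
        from xgboost import XGBRegressor

        defaults = dict(n_estimators=150, max_depth=6, learning_rate=0.1,
                        tree_method="hist", n_jobs=1, verbosity=0)
        defaults.update(params)
        return XGBRegressor(random_state=seed, **defaults)
    if name == "gbdt":
        from sklearn.ensemble import GradientBoostingRegressor

        defaults = dict(n_estimators=100, max_depth=3)
        defaults.update(params)
        return GradientBoostingRegressor(random_state=seed, **defaults)
    if name == "rf":
        from sklearn.ensemble import RandomForestRegressor

        defaults = dict(n_estimators=100, n_jobs=1)
        defaults.update(params)
        return RandomForestRegressor(random_state=seed, **defaults)
    if name == "linear_svm":
        from sklearn.pipeline import make_pipeline
        from sklearn.preprocessing import StandardScaler
        from sklearn.svm import LinearSVR

        defaults = dict(C=1.0, max_iter=5000)
        defaults.update(params)
        return make_pipeline(StandardScaler(),
                             LinearSVR(random_state=seed, **defaults))
    if name == "dnn":
        # Optional feed-forward net; mirrors the stated training recipe
        # (ReLU, squared-error loss, Adam at 5e-4, weight decay 1e-5,
        # batch 4096, 200 epochs); hidden widths follow the same taper.
        from sklearn.neural_network import MLPRegressor

        defaults = dict(hidden_layer_sizes=(400, 200, 100, 50),
                        activation="relu", solver="adam",
                        learning_rate_init=5e-4, alpha=1e-5,
                        batch_size=4096, max_iter=200)
        defaults.update(params)
        return MLPRegressor(random_state=seed, **defaults)
    raise KeyError(f"unknown model {name!r}")


def feature_importances(model) -> np.ndarray:
    imp = getattr(model, "feature_importances_", None)
    if imp is None:
        raise UnsupportedModelError(
            f"{type(model).__name__} exposes no per-feature importances"
        )
    return np.asarray(imp, dtype=float)


def expand_grid(grid: Mapping[str, Sequence]) -> list[dict]:
    """All parameter combinations, in declared key/value order."""
    keys = list(grid)
    if not keys:
        return []
    return [
        dict(zip(keys, combo))
        for combo in itertools.product(*(grid[k] for k in keys))
    ]


def grid_search(
    model_name: str,
    grid: Mapping[str, Sequence],
    X_train, y_train, X_val, y_val,
    metric: Callable = mae,
    seed: int = 0,
) -> tuple[dict, float]:
    """Exhaustive search minimizing the validation metric.

    Ties keep the first parameter set in declared grid order.  A model-fit
    failure surfaces with the offending parameters attached.
    """
    combos = expand_grid(grid)
    if not combos:
        raise ValueError("empty parameter grid")
    best_params, best_score = None, np.inf
    for params in combos:
        model = make_model(model_name, params, seed=seed)
        try:
            model.fit(X_train, y_train)
        except Exception as exc:
            raise RuntimeError(f"{model_name} failed to fit with {params}") from exc
        score = metric(y_val, model.predict(X_val))
        if score < best_score:
            best_params, best_score = params, score
    return best_params, best_score


# ---------------------------------------------------------------------------
# Error profile and importances

def per_los_mae(
    y: Sequence[float],
    y_hat: Sequence[float],
    subgroups: Mapping[str, Sequence] | None = None,
) -> pd.DataFrame:
    """Per-integer-LOS n and MAE, overall and per subgroup level."""
    y = np.asarray(y, dtype=float)
    err = np.abs(y - np.asarray(y_hat, dtype=float))
    frames = [("all", np.array(["all"] * len(y), dtype=object))]
    for name, values in (subgroups or {}).items():
        frames.append((name, np.asarray(values, dtype=object)))
    rows = []
    for name, values in frames:
        for level in pd.unique(values):
            m = values == level
            for los_val in sorted(np.unique(y[m])):
                cell = m & (y == los_val)
                rows.append({
                    "subgroup": name, "level": level, "los": int(los_val),
                    "n": int(cell.sum()), "mae": float(err[cell].mean()),
                })
    return pd.DataFrame(rows, columns=["subgroup", "level", "los", "n", "mae"])


def grouped_importance(
    model,
    columns: Sequence[str],
    groups: Mapping[str, str],
    top_k: int = 10,
) -> tuple[dict[str, float], pd.DataFrame]:
    """Sum importances per feature group; rank top-k with min–max RI.

    RI rescales the top-k raw importances so the strongest feature scores 1
    and the weakest 0 (all 1 when they tie).
    """
    imp = feature_importances(model)
    if len(imp) != len(columns):
        raise ValueError("importance vector does not match the column list")
    sums = {g: 0.0 for g in GROUPS}
    for c, v in zip(columns, imp):
        sums[groups[c]] = sums.get(groups[c], 0.0) + float(v)
    order = np.argsort(-imp, kind="stable")[:top_k]
    top = imp[order]
    span = top.max() - top.min()
    ri = np.ones_like(top) if span == 0 else (top - top.min()) / span
    table = pd.DataFrame({
        "feature": [columns[i] for i in order],
        "group": [groups[columns[i]] for i in order],
        "importance": top,
        "ri": ri,
    })
    return sums, table


# ---------------------------------------------------------------------------
# The ablation experiment

DEFAULT_SUBSETS: dict[str, tuple[str, ...]] = {
    "baseline": ("baseline",),
    "baseline+history": ("baseline", "history"),
    "baseline+mn": ("baseline", "mn"),
    "baseline+psn": ("baseline", "psn"),
    "baseline+history+mn+psn": ("baseline", "history", "mn", "psn"),
}

DEFAULT_GRIDS: dict[str, dict] = {
    "xgboost": {"max_depth": [3, 6]},
}


@dataclass
class ExperimentPlan:
    subsets: Mapping[str, tuple[str, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SUBSETS))
    model_grids: Mapping[str, Mapping[str, Sequence]] = field(
        default_factory=lambda: dict(DEFAULT_GRIDS))
    repeats: int = 10
    base_seed: int = 0
    lda_components: int | str = "select"     # "select" or a fixed dimension
    lda_candidates: tuple[int, ...] = (8, 16, 32, 64)

    def __post_init__(self):
        if self.repeats < 1:
            raise ValueError("repeats must be ≥ 1")
        for name, groups in self.subsets.items():
            unknown = set(groups) - set(GROUPS)
            if unknown:
                raise ValueError(
                    f"subset {name!r} names unknown groups {sorted(unknown)}"
                )


@dataclass
class ModelingDataset:
    """Modeling-era admissions with their static feature blocks.

    Split-dependent blocks (disease risk, neighbor LOS, the LDA projection)
    are materialized per split so that no statistic ever sees a test row.
    """

    records: list[AdmissionRecord]
    evc: Mapping[str, float]
    catalog: ChronicDiseaseCatalog | None
    baseline: pd.DataFrame
    history: pd.DataFrame
    evc_raw: pd.DataFrame
    psn_k: int = 100
    psn_backend: str = "exact"
    exclude_same_patient: bool = True

    @classmethod
    def build(
        cls,
        records: Sequence[AdmissionRecord],
        evc: Mapping[str, float],
        catalog: ChronicDiseaseCatalog | None,
        eci_map: EciMapping,
        history_source: Sequence[AdmissionRecord] | None = None,
        window_years: int = 3,
        psn_k: int = 100,
        psn_backend: str = "exact",
        exclude_same_patient: bool = True,
    ) -> "ModelingDataset":
        records = list(records)
        vocab = evc_vocabulary(evc, records, catalog)
        return cls(
            records=records,
            evc=evc,
            catalog=catalog,
            baseline=baseline_block(records, eci_map),
            history=history_block(
                records, history_source if history_source is not None else records,
                window_years),
            evc_raw=evc_block(records, evc, vocab, catalog),
            psn_k=psn_k,
            psn_backend=psn_backend,
            exclude_same_patient=exclude_same_patient,
        )

    @property
    def record_ids(self) -> list[str]:
        return [r.record_id for r in self.records]

    def labels(self) -> pd.Series:
        return pd.Series([r.los for r in self.records],
                         index=self.record_ids, name="los")

    def feature_table(self, split: Split, plan: ExperimentPlan, seed: int = 0
                      ) -> FeatureTable:
        """Materialize all four group blocks for one split.

        Training rows alone supply the per-disease mean LOS, the similarity
        index and the LDA fit; validation and test rows are only projected
        and queried.
        """
        train_ids = set(split.train)
        dep = split_dependent_blocks(
            self.records, train_ids, self.evc, self.catalog,
            k=self.psn_k, backend=self.psn_backend,
            exclude_same_patient=self.exclude_same_patient, seed=seed,
        )
        y = self.labels()
        mn_parts = [dep.risk]
        if self.evc_raw.shape[1] > 0:
            X_tr = self.evc_raw.loc[list(split.train)].to_numpy()
            y_tr = y.loc[list(split.train)].to_numpy()
            if plan.lda_components == "select":
                dim, _ = select_components(
                    plan.lda_candidates, X_tr, y_tr,
                    self.evc_raw.loc[list(split.val)].to_numpy(),
                    y.loc[list(split.val)].to_numpy(),
                )
            else:
                dim = int(plan.lda_components)
            proj = fit_lda(X_tr, y_tr, dim)
            reduced = pd.DataFrame(
                proj.transform(self.evc_raw.to_numpy()),
                index=self.evc_raw.index,
                columns=[f"lda_{i + 1}" for i in range(dim)],
            )
            mn_parts.insert(0, reduced)
        mn = pd.concat(mn_parts, axis=1)
        return assemble(self.records, {
            "baseline": self.baseline,
            "history": self.history,
            "mn": mn,
            "psn": dep.psn,
        })


@dataclass
class EvalReport:
    """Ablation outcomes: per-cell repeat metrics plus analysis artifacts."""

    runs: pd.DataFrame                 # model, subset, repeat, mae, rmse, r2
    importances: dict[tuple[str, str], tuple[dict[str, float], pd.DataFrame]]
    error_profile: pd.DataFrame | None = None

    def summary(self) -> pd.DataFrame:
        """Mean ± sd of each metric over repeats, per (model, subset)."""
        g = self.runs.groupby(["model", "subset"])[["mae", "rmse", "r2"]]
        out = g.agg(["mean", "std"])
        out.columns = [f"{m}_{s}" for m, s in out.columns]
        return out.reset_index()

    def metric_values(self, model: str, subset: str, metric: str) -> np.ndarray:
        m = (self.runs["model"] == model) & (self.runs["subset"] == subset)
        return self.runs.loc[m].sort_values("repeat")[metric].to_numpy()


def run_ablation(dataset: ModelingDataset, plan: ExperimentPlan) -> EvalReport:
    """Run the feature-subset ablation.

    Per repeat r: reseed the split with base_seed + r, materialize the
    split's feature table, grid-search each model on train/validation per
    subset, refit on the training rows and score the held-out test rows.
    """
    rows = []
    importances: dict[tuple[str, str], tuple] = {}
    profile = None
    y_all = dataset.labels()

    for rep in range(plan.repeats):
        seed = plan.base_seed + rep
        split = split_ids(dataset.record_ids, SplitSpec(seed=seed))
        table = dataset.feature_table(split, plan, seed=seed)
        tr, va, te = list(split.train), list(split.val), list(split.test)
        y_tr, y_va, y_te = (y_all.loc[ix].to_numpy() for ix in (tr, va, te))

        for subset_name, groups in plan.subsets.items():
            X = table.subset(list(groups))
            X_tr, X_va, X_te = X.loc[tr], X.loc[va], X.loc[te]
            for model_name, grid in plan.model_grids.items():
                params, _ = grid_search(
                    model_name, grid, X_tr, y_tr, X_va, y_va, seed=seed
                )
                model = make_model(model_name, params, seed=seed)
                model.fit(X_tr, y_tr)
                pred = model.predict(X_te)
                rows.append({
                    "model": model_name, "subset": subset_name, "repeat": rep,
                    "mae": mae(y_te, pred), "rmse": rmse(y_te, pred),
                    "r2": r2(y_te, pred), "params": str(params),
                })
                if rep == plan.repeats - 1:
                    try:
                        importances[(model_name, subset_name)] = (
                            grouped_importance(model, list(X.columns),
                                               table.groups)
                        )
                    except UnsupportedModelError:
                        pass
                    if subset_name == max(plan.subsets, key=lambda s: len(plan.subsets[s])):
                        by_id = {r.record_id: r for r in dataset.records}
                        profile = per_los_mae(
                            y_te, pred,
                            subgroups={
                                "sex": [by_id[i].sex for i in te],
                                "age_group": [age_group(by_id[i].age) for i in te],
                            },
                        )
    return EvalReport(pd.DataFrame(rows), importances, profile)
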