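"""End-to-end modeling: splits, cross-validation, training and persistence.

The predictor is a pipeline over a labeled pair of sequence sets:

1. fit the position-specific trinucleotide propensity (PSTNPss) table on the
   *training* sequences only — it is the one trainable encoder;
2. encode all five feature blocks and fuse them;
3. train a gradient-boosted tree ensemble on the fused matrix, rank columns by
   mean |SHAP|, and keep the top K (default 64);
4. train the final classifier on the selected columns.

Cross-validation repeats steps 1-4 inside every fold so that neither the
propensity table nor the feature ranking can leak held-out information
(``selection_scope="global"`` deliberately relaxes this to mimic protocols
that select once on the full dataset).

Default hyperparameters for the booster: 200 trees, learning rate 0.01,
max depth 20, min child weight 10, gamma 0.5, binary-logistic objective,
seed 42; colsample_bylevel/reg_alpha/reg_lambda default to (0.8, 0.1, 1) with
an optional small internal grid over {0.5,0.8,1.0} x {0.1,1} x {0.1,1}.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from itertools import product
from pathlib import Path
from typing import Literal

import numpy as np
import pandas as pd
import xgboost as xgb
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .encoders import (
    DacConfig,
    HybridMatrix,
    MismatchConfig,
    PhysicochemicalTable,
    PstnpssModel,
    encode_all,
    fit_pstnpss,
)
from .evaluation import MetricsReport, confusion, metrics, roc_auc
from .feature_selection import SelectionResult, compute_shap_ranking, select_top_k
from .sequence_io import SequenceRecord, SequenceSet, validate_set


@dataclass(frozen=True)
class SplitConfig:
    """Per-class train/test split fractions (train gets ceil(fraction * n))."""

    train_fraction: float = 0.8
    stratified: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if not (0 < self.train_fraction < 1):
            raise ValueError("train_fraction must be in (0, 1)")


@dataclass(frozen=True)
class CvConfig:
    n_folds: int = 10
    stratified: bool = True
    seed: int = 42

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise ValueError("need at least 2 folds")


@dataclass(frozen=True)
class TrainConfig:
    """Booster hyperparameters; the three grid fields hold the candidate sets."""

    n_estimators: int = 200
    learning_rate: float = 0.01
    max_depth: int = 20
    min_child_weight: float = 10.0
    gamma: float = 0.5
    objective: str = "binary:logistic"
    colsample_bylevel: float = 0.8
    reg_alpha: float = 0.1
    reg_lambda: float = 1.0
    colsample_bylevel_grid: tuple[float, ...] = (0.5, 0.8, 1.0)
    reg_alpha_grid: tuple[float, ...] = (0.1, 1.0)
    reg_lambda_grid: tuple[float, ...] = (0.1, 1.0)
    grid_search: bool = False
    random_state: int = 42


@dataclass
class PipelineConfig:
    """Encoder and selection settings shared by CV and final training."""

    mismatch: MismatchConfig = field(default_factory=MismatchConfig)
    dac: DacConfig = field(default_factory=DacConfig)
    top_k: int = 64
    selection_scope: Literal["per_fold", "global"] = "per_fold"


@dataclass
class PipelineModel:
    """A fully fitted predictor: encoder state + selection + classifier."""

    pstnpss: PstnpssModel
    mismatch_cfg: MismatchConfig
    dac_cfg: DacConfig
    selection: SelectionResult
    column_labels: list[str]
    booster: xgb.Booster
    L: int
    metadata: dict = field(default_factory=dict)


def _subset(sset: SequenceSet, idx) -> SequenceSet:
    return SequenceSet(records=[sset.records[i] for i in idx])


def stratified_split(
    pos: SequenceSet, neg: SequenceSet, cfg: SplitConfig | None = None
) -> tuple[tuple[SequenceSet, SequenceSet], tuple[SequenceSet, SequenceSet]]:
    """Seeded per-class split; train size is ceil(train_fraction * n) per class
    (so 662 sequences at 0.8 give 530 train / 132 test, matching the benchmark
    protocol's 132+132 independent set)."""
    cfg = cfg or SplitConfig()
    rng = np.random.default_rng(cfg.seed)
    out = []
    for sset in (pos, neg):
        n = len(sset)
        n_train = math.ceil(cfg.train_fraction * n)
        if n_train == 0 or n_train == n:
            raise ValueError(f"class of size {n} too small to split at {cfg.train_fraction}")
        perm = rng.permutation(n)
        out.append((_subset(sset, perm[:n_train]), _subset(sset, perm[n_train:])))
    (train_pos, test_pos), (train_neg, test_neg) = out
    return (train_pos, train_neg), (test_pos, test_neg)


def make_xgb_classifier(cfg: TrainConfig | None = None, **overrides) -> xgb.XGBClassifier:
    cfg = cfg or TrainConfig()
    params = dict(
        n_estimators=cfg.n_estimators,
        learning_rate=cfg.learning_rate,
        max_depth=cfg.max_depth,
        min_child_weight=cfg.min_child_weight,
        gamma=cfg.gamma,
        objective=cfg.objective,
        colsample_bylevel=cfg.colsample_bylevel,
        reg_alpha=cfg.reg_alpha,
        reg_lambda=cfg.reg_lambda,
        random_state=cfg.random_state,
        n_jobs=1,
        tree_method="hist",
        base_score=0.5,
        eval_metric="logloss",
    )
    params.update(overrides)
    return xgb.XGBClassifier(**params)


def _fit_fold(
    train_pos: SequenceSet,
    train_neg: SequenceSet,
    train_cfg: TrainConfig,
    pipe_cfg: PipelineConfig,
    fixed: tuple[PstnpssModel, SelectionResult] | None = None,
):
    """Fit PSTNPss -> encode -> rank -> select -> final classifier on one
    training partition. ``fixed`` injects a pre-fitted propensity table and
    selection (global selection scope)."""
    if fixed is None:
        pstnp = fit_pstnpss(train_pos, train_neg)
    else:
        pstnp = fixed[0]
    X_pos = encode_all(train_pos, pstnp, pipe_cfg.mismatch, pipe_cfg.dac)
    X_neg = encode_all(train_neg, pstnp, pipe_cfg.mismatch, pipe_cfg.dac)
    X = HybridMatrix(
        matrix=np.vstack([X_pos.matrix, X_neg.matrix]),
        column_labels=X_pos.column_labels,
    )
    y = np.concatenate([np.ones(len(train_pos), int), np.zeros(len(train_neg), int)])
    if fixed is None:
        ranker = make_xgb_classifier(train_cfg)
        ranker.fit(X.matrix, y)
        ranking = compute_shap_ranking(ranker, X)
        k = min(pipe_cfg.top_k, X.n_features)
        X_sel, selection = select_top_k(X, ranking, k)
    else:
        selection = fixed[1]
        ranking = None
        X_sel = X.matrix[:, selection.selected_indices]
    clf = make_xgb_classifier(train_cfg)
    clf.fit(X_sel, y)
    return pstnp, selection, ranking, clf, X.column_labels


def _encode_selected(
    sset: SequenceSet, pstnp: PstnpssModel, selection: SelectionResult, pipe_cfg: PipelineConfig
) -> np.ndarray:
    X = encode_all(sset, pstnp, pipe_cfg.mismatch, pipe_cfg.dac)
    return X.matrix[:, selection.selected_indices]


def _evaluate_clf(clf, X_test: np.ndarray, y_test: np.ndarray) -> MetricsReport:
    prob = clf.predict_proba(X_test)[:, 1] if hasattr(clf, "predict_proba") else None
    score = prob if prob is not None else clf.decision_function(X_test)
    pred = (prob >= 0.5).astype(int) if prob is not None else (score > 0).astype(int)
    auc = roc_auc(y_test, score) if len(set(y_test)) == 2 else float("nan")
    return metrics(confusion(y_test, pred), auc=auc)


@dataclass
class CVReport:
    """Per-fold and averaged metrics for one cross-validated pipeline."""

    folds: list[MetricsReport]
    mean: MetricsReport

    def to_dataframe(self) -> pd.DataFrame:
        rows = [m.as_dict() for m in self.folds]
        df = pd.DataFrame(rows, index=[f"fold{i+1}" for i in range(len(rows))])
        df.loc["mean"] = self.mean.as_dict()
        return df


def _mean_report(folds: list[MetricsReport]) -> MetricsReport:
    arr = lambda f: float(np.mean([getattr(m, f) for m in folds]))  # noqa: E731
    return MetricsReport(
        accuracy=arr("accuracy"), sensitivity=arr("sensitivity"),
        precision=arr("precision"), specificity=arr("specificity"),
        f1=arr("f1"), mcc=arr("mcc"), auc=arr("auc"),
    )


def _stacked(pos: SequenceSet, neg: SequenceSet):
    records = list(pos.records) + list(neg.records)
    y = np.concatenate([np.ones(len(pos), int), np.zeros(len(neg), int)])
    return records, y


def run_cv(
    pos: SequenceSet,
    neg: SequenceSet,
    train_cfg: TrainConfig | None = None,
    cv_cfg: CvConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
) -> CVReport:
    """Stratified k-fold cross-validation of the whole pipeline.

    With the default ``selection_scope="per_fold"``, the PSTNPss table, the
    SHAP ranking and the top-K selection are all refit on each fold's training
    portion; the held-out fold is only ever transformed and scored.
    """
    train_cfg = train_cfg or TrainConfig()
    cv_cfg = cv_cfg or CvConfig()
    pipe_cfg = pipe_cfg or PipelineConfig()
    validate_set(pos), validate_set(neg)
    records, y = _stacked(pos, neg)

    fixed = None
    if pipe_cfg.selection_scope == "global":
        pstnp_g, selection_g, _, _, _ = _fit_fold(pos, neg, train_cfg, pipe_cfg)
        fixed = (pstnp_g, selection_g)

    skf = StratifiedKFold(n_splits=cv_cfg.n_folds, shuffle=True, random_state=cv_cfg.seed)
    folds: list[MetricsReport] = []
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        tr_pos = SequenceSet([records[i] for i in train_idx if y[i] == 1])
        tr_neg = SequenceSet([records[i] for i in train_idx if y[i] == 0])
        te = SequenceSet([records[i] for i in test_idx])
        y_te = y[test_idx]
        pstnp, selection, _, clf, _ = _fit_fold(tr_pos, tr_neg, train_cfg, pipe_cfg, fixed)
        X_te = _encode_selected(te, pstnp, selection, pipe_cfg)
        folds.append(_evaluate_clf(clf, X_te, y_te))
    return CVReport(folds=folds, mean=_mean_report(folds))


def _resolve_grid(
    X: np.ndarray, y: np.ndarray, train_cfg: TrainConfig
) -> TrainConfig:
    """Pick (colsample_bylevel, reg_alpha, reg_lambda) by internal 3-fold CV
    accuracy on the training partition; ties keep the first grid point."""
    best, best_acc = None, -1.0
    skf = StratifiedKFold(n_splits=3, shuffle=True, random_state=train_cfg.random_state)
    for cs, ra, rl in product(
        train_cfg.colsample_bylevel_grid, train_cfg.reg_alpha_grid, train_cfg.reg_lambda_grid
    ):
        accs = []
        for tr, te in skf.split(X, y):
            clf = make_xgb_classifier(
                train_cfg, colsample_bylevel=cs, reg_alpha=ra, reg_lambda=rl
            )
            clf.fit(X[tr], y[tr])
            accs.append(float(np.mean(clf.predict(X[te]) == y[te])))
        acc = float(np.mean(accs))
        if acc > best_acc:
            best, best_acc = (cs, ra, rl), acc
    from dataclasses import replace

    return replace(
        train_cfg, colsample_bylevel=best[0], reg_alpha=best[1], reg_lambda=best[2]
    )


def train_final(
    train_pos: SequenceSet,
    train_neg: SequenceSet,
    train_cfg: TrainConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
) -> PipelineModel:
    """Fit the complete pipeline on a training partition."""
    train_cfg = train_cfg or TrainConfig()
    pipe_cfg = pipe_cfg or PipelineConfig()
    if not len(train_pos) or not len(train_neg):
        raise ValueError("training data must contain both classes")
    validate_set(train_pos), validate_set(train_neg)
    if train_cfg.grid_search:
        pstnp0 = fit_pstnpss(train_pos, train_neg)
        Xp = encode_all(train_pos, pstnp0, pipe_cfg.mismatch, pipe_cfg.dac)
        Xn = encode_all(train_neg, pstnp0, pipe_cfg.mismatch, pipe_cfg.dac)
        X = np.vstack([Xp.matrix, Xn.matrix])
        y = np.concatenate([np.ones(len(train_pos), int), np.zeros(len(train_neg), int)])
        train_cfg = _resolve_grid(X, y, train_cfg)
    pstnp, selection, ranking, clf, labels = _fit_fold(
        train_pos, train_neg, train_cfg, pipe_cfg
    )
    try:
        from importlib.metadata import version

        pkg_version = version("hmckit")
    except Exception:
        pkg_version = "unknown"
    meta = {
        "seed": train_cfg.random_state,
        "hmckit_version": pkg_version,
        "xgboost_version": xgb.__version__,
        "train_config": asdict(train_cfg),
        "top_k": selection.k,
        "n_train_pos": len(train_pos),
        "n_train_neg": len(train_neg),
    }
    return PipelineModel(
        pstnpss=pstnp,
        mismatch_cfg=pipe_cfg.mismatch,
        dac_cfg=pipe_cfg.dac,
        selection=selection,
        column_labels=labels,
        booster=clf.get_booster(),
        L=train_pos.length,
        metadata=meta,
    )


def predict(model: PipelineModel, sset: SequenceSet) -> pd.DataFrame:
    """Per-record 5hmC probability and the 0.5-threshold label."""
    if not len(sset):
        return pd.DataFrame(columns=["id", "probability", "label"])
    validate_set(sset)
    if sset.length != model.L:
        raise ValueError(
            f"input length {sset.length} != model training length {model.L}"
        )
    pipe_cfg = PipelineConfig(mismatch=model.mismatch_cfg, dac=model.dac_cfg)
    X = _encode_selected(sset, model.pstnpss, model.selection, pipe_cfg)
    prob = model.booster.predict(xgb.DMatrix(X))
    return pd.DataFrame(
        {
            "id": sset.ids(),
            "probability": prob.astype(float),
            "label": (prob >= 0.5).astype(int),
        }
    )


# ---------------------------------------------------------------------------
# Baseline classifiers
# ---------------------------------------------------------------------------

def baseline_classifiers(seed: int = 42) -> dict[str, object]:
    """The comparison suite with its published settings."""
    return {
        "RF": RandomForestClassifier(
            n_estimators=200, criterion="entropy", max_depth=20,
            min_samples_split=9, min_samples_leaf=5, max_features="sqrt",
            bootstrap=True, random_state=seed, n_jobs=1,
        ),
        "SVM": SVC(kernel="rbf", C=15, gamma=0.001, random_state=seed),
        "KNN": KNeighborsClassifier(n_neighbors=11),
        "NB": GaussianNB(),
        "LR": LogisticRegression(max_iter=2000, random_state=seed),
    }


def run_baselines(
    pos: SequenceSet,
    neg: SequenceSet,
    train_cfg: TrainConfig | None = None,
    cv_cfg: CvConfig | None = None,
    pipe_cfg: PipelineConfig | None = None,
    feature_space: Literal["selected", "hybrid"] = "selected",
    include_xgb: bool = True,
) -> dict[str, CVReport]:
    """Cross-validate the baseline suite on identical folds and features.

    All classifiers see the same fold assignments and, under the default
    ``feature_space="selected"``, the same top-K columns chosen by the
    tree-ensemble SHAP ranking fitted on each fold's training portion.
    """
    train_cfg = train_cfg or TrainConfig()
    cv_cfg = cv_cfg or CvConfig()
    pipe_cfg = pipe_cfg or PipelineConfig()
    validate_set(pos), validate_set(neg)
    records, y = _stacked(pos, neg)
    skf = StratifiedKFold(n_splits=cv_cfg.n_folds, shuffle=True, random_state=cv_cfg.seed)
    names = (["XGBoost"] if include_xgb else []) + list(baseline_classifiers())
    per_clf: dict[str, list[MetricsReport]] = {n: [] for n in names}
    for train_idx, test_idx in skf.split(np.zeros(len(y)), y):
        tr_pos = SequenceSet([records[i] for i in train_idx if y[i] == 1])
        tr_neg = SequenceSet([records[i] for i in train_idx if y[i] == 0])
        te = SequenceSet([records[i] for i in test_idx])
        y_tr = np.concatenate([np.ones(len(tr_pos), int), np.zeros(len(tr_neg), int)])
        y_te = y[test_idx]
        pstnp = fit_pstnpss(tr_pos, tr_neg)
        Xp = encode_all(tr_pos, pstnp, pipe_cfg.mismatch, pipe_cfg.dac)
        Xn = encode_all(tr_neg, pstnp, pipe_cfg.mismatch, pipe_cfg.dac)
        X_tr = HybridMatrix(
            matrix=np.vstack([Xp.matrix, Xn.matrix]), column_labels=Xp.column_labels
        )
        X_te_full = encode_all(te, pstnp, pipe_cfg.mismatch, pipe_cfg.dac).matrix
        ranker = make_xgb_classifier(train_cfg)
        ranker.fit(X_tr.matrix, y_tr)
        if feature_space == "selected":
            ranking = compute_shap_ranking(ranker, X_tr)
            k = min(pipe_cfg.top_k, X_tr.n_features)
            Xtr_m, selection = select_top_k(X_tr, ranking, k)
            Xte_m = X_te_full[:, selection.selected_indices]
        else:
            Xtr_m, Xte_m = X_tr.matrix, X_te_full
        if include_xgb:
            clf = make_xgb_classifier(train_cfg)
            clf.fit(Xtr_m, y_tr)
            per_clf["XGBoost"].append(_evaluate_clf(clf, Xte_m, y_te))
        for name, clf in baseline_classifiers(train_cfg.random_state).items():
            clf.fit(Xtr_m, y_tr)
            per_clf[name].append(_evaluate_clf(clf, Xte_m, y_te))
    return {n: CVReport(folds=f, mean=_mean_report(f)) for n, f in per_clf.items()}


# ---------------------------------------------------------------------------
# Persistence (single JSON archive: booster JSON + encoder state + configs)
# ---------------------------------------------------------------------------

def save_pipeline(model: PipelineModel, path: str | Path) -> None:
    """Serialize the fitted pipeline to one JSON archive."""
    payload = {
        "format": "hmckit-pipeline",
        "format_version": 1,
        "L": model.L,
        "pstnpss_z": model.pstnpss.z.tolist(),
        "mismatch": {"k": model.mismatch_cfg.k, "m": model.mismatch_cfg.m,
                     "normalize": model.mismatch_cfg.normalize},
        "dac": {
            "lag_max": model.dac_cfg.lag_max,
            "indices": model.dac_cfg.table.indices,
            "values": model.dac_cfg.table.values.tolist(),
            "standardized": model.dac_cfg.table.standardized,
        },
        "selection": {
            "indices": model.selection.selected_indices.tolist(),
            "k": model.selection.k,
        },
        "column_labels": model.column_labels,
        "booster_json": model.booster.save_raw(raw_format="json").decode(),
        "metadata": model.metadata,
    }
    Path(path).write_text(json.dumps(payload))


def load_pipeline(path: str | Path) -> PipelineModel:
    """Load a pipeline archive written by :func:`save_pipeline`."""
    try:
        payload = json.loads(Path(path).read_text())
    except (OSError, json.JSONDecodeError) as exc:
        raise ValueError(f"cannot read pipeline archive {path}: {exc}") from exc
    if payload.get("format") != "hmckit-pipeline":
        raise ValueError(f"{path} is not a hmckit pipeline archive")
    booster = xgb.Booster()
    booster.load_model(bytearray(payload["booster_json"].encode()))
    table = PhysicochemicalTable(
        indices=payload["dac"]["indices"],
        values=np.array(payload["dac"]["values"]),
        standardized=payload["dac"]["standardized"],
    )
    return PipelineModel(
        pstnpss=PstnpssModel(z=np.array(payload["pstnpss_z"]), L=payload["L"]),
        mismatch_cfg=MismatchConfig(**payload["mismatch"]),
        dac_cfg=DacConfig(lag_max=payload["dac"]["lag_max"], table=table),
        selection=SelectionResult(
            selected_indices=np.array(payload["selection"]["indices"], dtype=int),
            k=payload["selection"]["k"],
        ),
        column_labels=payload["column_labels"],
        booster=booster,
        L=payload["L"],
        metadata=payload.get("metadata", {}),
    )
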