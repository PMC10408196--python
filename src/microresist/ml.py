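"""Baseline-microbiome response prediction.

Gradient-boosted decision trees classify responders vs non-responders
from baseline abundances.  Each training run removes near-zero-variance
features, z-scores with training-set statistics only, selects the top
``n_rfe_features`` by recursive feature elimination, tunes the boosting
hyper-parameters on a grid by cross-validated AUC (leave-one-out by
default, k-fold as the scalable fallback) and refits on the full training
split.  Robust performance is the mean +/- SD over repeated stratified
train/test splits, together with how often each feature is selected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from itertools import product

import numpy as np
import pandas as pd
from sklearn.ensemble import GradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import LeaveOneOut, StratifiedKFold, StratifiedShuffleSplit

POSITIVE_LABEL = "responder"

DEFAULT_GRID = {
    "max_depth": [1, 2, 3],            # interaction depth
    "n_estimators": [50, 100, 150],    # number of trees
    "learning_rate": [0.01, 0.1],      # shrinkage
    "min_samples_leaf": [5, 10],       # minimum node size
}

SMALL_GRID = {
    "max_depth": [1, 3],
    "n_estimators": [50, 100],
    "learning_rate": [0.1],
    "min_samples_leaf": [5],
}


@dataclass
class ModelConfig:
    feature_mode: str = "species"      # species | genus | taxonomic | hybrid
    n_rfe_features: int = 30
    n_repeats: int = 100
    train_fraction: float = 0.8
    grid: dict = field(default_factory=lambda: {k: list(v) for k, v in DEFAULT_GRID.items()})
    cv: object = "loo"                 # 'loo' or an integer fold count
    threshold: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0.0 < self.train_fraction < 1.0:
            raise ValueError("train_fraction must be in (0, 1)")
        if self.n_rfe_features < 1:
            raise ValueError("n_rfe_features must be >= 1")


@dataclass
class FittedModel:
    classifier: GradientBoostingClassifier
    features: list[str]                # selected feature ids, model order
    center: np.ndarray                 # training means of the selected features
    scale: np.ndarray                  # training SDs of the selected features
    params: dict
    classes: tuple[str, str] = ("non_responder", "responder")


@dataclass
class ModelReport:
    per_split: pd.DataFrame            # auc / sensitivity / specificity per split
    selection_frequency: pd.Series     # fraction of splits selecting each feature
    summary: pd.Series                 # mean/sd of the per-split metrics

    def __post_init__(self) -> None:
        bad = self.per_split["auc"].dropna()
        if ((bad < 0) | (bad > 1)).any():
            raise ValueError("AUC outside [0, 1]")


# ---------------------------------------------------------------------------
# preprocessing
# ---------------------------------------------------------------------------

def near_zero_variance(x: np.ndarray, freq_cut: float = 95.0 / 5.0,
                       unique_cut: float = 0.10) -> np.ndarray:
    """Mask of near-zero-variance columns (caret's convention).

    A column is near-zero-variance when the ratio of its most common to
    second most common value exceeds ``freq_cut`` AND the fraction of
    distinct values is below ``unique_cut``; constant columns always
    qualify.
    """
    n, _ = x.shape
    nzv = np.zeros(x.shape[1], dtype=bool)
    for j in range(x.shape[1]):
        vals, counts = np.unique(x[:, j], return_counts=True)
        if len(vals) == 1:
            nzv[j] = True
            continue
        counts = np.sort(counts)[::-1]
        freq_ratio = counts[0] / counts[1]
        unique_frac = len(vals) / n
        nzv[j] = freq_ratio > freq_cut and unique_frac < unique_cut
    return nzv


@dataclass
class Preprocessor:
    """NZV filter + z-scoring, fit on training data only (no leakage)."""

    feature_ids: list[str] = field(default_factory=list)
    center: np.ndarray = None
    scale: np.ndarray = None

    def fit(self, design: pd.DataFrame) -> "Preprocessor":
        x = design.to_numpy(dtype=float)
        keep = ~near_zero_variance(x)
        if not keep.any():
            raise ValueError("all features removed by the near-zero-variance filter")
        self.feature_ids = list(design.columns[keep])
        sub = x[:, keep]
        self.center = sub.mean(axis=0)
        sd = sub.std(axis=0, ddof=1)
        self.scale = np.where(sd > 0, sd, 1.0)
        return self

    def transform(self, design: pd.DataFrame) -> pd.DataFrame:
        sub = design.reindex(columns=self.feature_ids, fill_value=0.0)
        z = (sub.to_numpy(dtype=float) - self.center) / self.scale
        return pd.DataFrame(z, index=design.index, columns=self.feature_ids)

    def fit_transform(self, design: pd.DataFrame) -> pd.DataFrame:
        return self.fit(design).transform(design)


def preprocess(features: pd.DataFrame, labels: pd.Series) -> tuple[pd.DataFrame, pd.Series, Preprocessor]:
    """Design matrix (samples x features) for a binary response problem."""
    classes = set(labels)
    if not classes <= {"responder", "non_responder"}:
        raise ValueError(f"labels must be binary responder/non_responder, got {sorted(classes)}")
    if len(classes) < 2:
        raise ValueError("both classes must be present")
    prep = Preprocessor()
    design = prep.fit_transform(features.loc[labels.index])
    return design, labels, prep


# ---------------------------------------------------------------------------
# recursive feature elimination
# ---------------------------------------------------------------------------

def _base_learner(seed: int, **params) -> GradientBoostingClassifier:
    defaults = dict(max_depth=3, n_estimators=100, learning_rate=0.1,
                    min_samples_leaf=5, random_state=seed)
    defaults.update(params)
    return GradientBoostingClassifier(**defaults)


def rfe_select(design: pd.DataFrame, labels: pd.Series, n_features: int = 30,
               seed: int = 0) -> list[str]:
    """Top features by recursive importance-based elimination.

    Feature count is halved per round until at most 2 * n_features remain,
    then eliminated one at a time down to exactly n_features, refitting
    the base learner at every step.
    """
    if n_features > design.shape[1]:
        raise ValueError(f"n_features={n_features} exceeds {design.shape[1]} candidates")
    y = (labels == POSITIVE_LABEL).to_numpy(dtype=int)
    current = list(design.columns)
    # a light learner ranks importances; the tuned model is fit afterwards
    ranker = dict(n_estimators=50, max_depth=2)
    while len(current) > n_features:
        model = _base_learner(seed, **ranker).fit(design[current], y)
        importances = pd.Series(model.feature_importances_, index=current)
        if len(current) > 2 * n_features:
            target = max(len(current) // 2, 2 * n_features)
        else:
            target = len(current) - 1
        current = list(importances.sort_values(ascending=False).index[:target])
    return current


# ---------------------------------------------------------------------------
# tuning and fitting
# ---------------------------------------------------------------------------

def _cv_splitter(cv, y: np.ndarray, seed: int):
    if cv == "loo":
        return LeaveOneOut()
    k = min(int(cv), int(np.bincount(y).min()))
    return StratifiedKFold(n_splits=max(k, 2), shuffle=True, random_state=seed)

def _cv_auc(design: np.ndarray, y: np.ndarray, params: dict, cv, seed: int) -> float:
    """AUC over pooled out-of-fold probabilities (valid for LOO too)."""
    probs = np.empty(len(y))
    for train, test in _cv_splitter(cv, y, seed).split(design, y):
        model = _base_learner(seed, **params).fit(design[train], y[train])
        probs[test] = model.predict_proba(design[test])[:, 1]
    return roc_auc_score(y, probs)


def train_classifier(design: pd.DataFrame, labels: pd.Series,
                     config: ModelConfig) -> tuple[GradientBoostingClassifier, dict, float]:
    """Grid-tuned boosting fit; returns (fitted model, best params, CV AUC)."""
    y = (labels == POSITIVE_LABEL).to_numpy(dtype=int)
    if len(y) < 10:
        raise ValueError("need at least 10 samples to train")
    if len(np.unique(y)) < 2:
        raise ValueError("single-class training set")
    x = design.to_numpy(dtype=float)
    names = list(config.grid)
    combos = list(product(*(config.grid[n] for n in names)))
    best_params, best_auc = None, -np.inf
    for combo in combos:
        params = dict(zip(names, combo))
        auc = _cv_auc(x, y, params, config.cv, config.seed) if len(combos) > 1 else np.nan
        if len(combos) == 1 or auc > best_auc:
            best_params, best_auc = params, auc
    model = _base_learner(config.seed, **best_params).fit(x, y)
    return model, best_params, float(best_auc)


def _metrics(y_true: np.ndarray, probs: np.ndarray, threshold: float) -> dict:
    pred = (probs >= threshold).astype(int)
    pos, neg = y_true == 1, y_true == 0
    sens = float(pred[pos].mean()) if pos.any() else np.nan
    spec = float((1 - pred[neg]).mean()) if neg.any() else np.nan
    auc = roc_auc_score(y_true, probs) if len(np.unique(y_true)) == 2 else np.nan
    return {"auc": auc, "sensitivity": sens, "specificity": spec}


# ---------------------------------------------------------------------------
# repeated-split evaluation
# ---------------------------------------------------------------------------

def repeated_split_eval(features: pd.DataFrame, labels: pd.Series,
                        config: ModelConfig) -> ModelReport:
    """Stratified 80/20 splits repeated ``n_repeats`` times.

    Per split: NZV + scaling and RFE are fit inside the training portion
    only, the tuned model is evaluated on the held-out 20% (AUC,
    sensitivity and specificity at the probability threshold), and the
    selected features are tallied into selection frequencies.
    """
    labels = labels.loc[features.index]
    y_all = (labels == POSITIVE_LABEL).to_numpy(dtype=int)
    if np.bincount(y_all, minlength=2).min() < 5:
        raise ValueError("each class needs at least 5 samples for stratified splits")
    splitter = StratifiedShuffleSplit(n_splits=config.n_repeats,
                                      train_size=config.train_fraction,
                                      random_state=config.seed)
    counts = pd.Series(0.0, index=features.columns)
    rows = []
    rng = np.random.default_rng(config.seed)
    for split_no, (tr, te) in enumerate(splitter.split(features, y_all)):
        split_seed = int(rng.integers(2 ** 31))
        prep = Preprocessor()
        xtr = prep.fit_transform(features.iloc[tr])
        n_sel = min(config.n_rfe_features, xtr.shape[1])
        selected = rfe_select(xtr, labels.iloc[tr], n_features=n_sel, seed=split_seed)
        counts[selected] += 1
        cfg = ModelConfig(config.feature_mode, n_sel, 1, config.train_fraction,
                          config.grid, config.cv, config.threshold, split_seed)
        model, params, _ = train_classifier(xtr[selected], labels.iloc[tr], cfg)
        xte = prep.transform(features.iloc[te])[selected].to_numpy(dtype=float)
        probs = model.predict_proba(xte)[:, 1]
        rows.append({"split": split_no, **_metrics(y_all[te], probs, config.threshold)})
    per_split = pd.DataFrame(rows)
    summary = pd.Series({
        "auc_mean": per_split["auc"].mean(), "auc_sd": per_split["auc"].std(ddof=1),
        "sensitivity_mean": per_split["sensitivity"].mean(),
        "sensitivity_sd": per_split["sensitivity"].std(ddof=1),
        "specificity_mean": per_split["specificity"].mean(),
        "specificity_sd": per_split["specificity"].std(ddof=1),
    })
    return ModelReport(per_split, counts / config.n_repeats, summary)


def fit_final_model(features: pd.DataFrame, labels: pd.Series,
                    config: ModelConfig) -> FittedModel:
    """RFE + tuned fit on the entire data set (the deployable model)."""
    labels = labels.loc[features.index]
    prep = Preprocessor()
    design = prep.fit_transform(features)
    n_sel = min(config.n_rfe_features, design.shape[1])
    selected = rfe_select(design, labels, n_features=n_sel, seed=config.seed)
    model, params, _ = train_classifier(design[selected], labels, config)
    idx = [prep.feature_ids.index(f) for f in selected]
    return FittedModel(model, selected, prep.center[idx], prep.scale[idx], params)


def evaluate_external(model: FittedModel, external: pd.DataFrame,
                      external_labels: pd.Series, threshold: float = 0.5) -> dict:
    """Final-model metrics on an external cohort.

    External features are joined to the model's feature set by terminal
    clade name; features missing externally are imputed as 0 abundance
    before scaling.  A single-class external set yields NaN for the
    undefined rate with a warning.
    """
    def terminal(f: str) -> str:
        return f.rsplit("|", 1)[-1]

    ext_by_terminal = {}
    for col in external.columns:
        ext_by_terminal.setdefault(terminal(col), col)
    overlap = [f for f in model.features if terminal(f) in ext_by_terminal]
    if not overlap:
        raise ValueError("no overlapping features between model and external cohort")
    raw = np.zeros((len(external), len(model.features)))
    for j, f in enumerate(model.features):
        src = ext_by_terminal.get(terminal(f))
        if src is not None:
            raw[:, j] = external[src].to_numpy(dtype=float)
    z = (raw - model.center) / model.scale
    probs = model.classifier.predict_proba(z)[:, 1]
    y = (external_labels.loc[external.index] == POSITIVE_LABEL).to_numpy(dtype=int)
    if len(np.unique(y)) < 2:
        warnings.warn("single-class external set: AUC and one rate undefined")
    m = _metrics(y, probs, threshold)
    pred = (probs >= threshold).astype(int)
    confusion = pd.crosstab(pd.Series(y, name="true"), pd.Series(pred, name="pred"))
    m["confusion"] = confusion.reindex(index=[0, 1], columns=[0, 1], fill_value=0)
    m["n_overlapping_features"] = len(overlap)
    return m
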