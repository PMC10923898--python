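"""Dataset preparation, scaling, weighting, and the negative-subsample
gradient-boosted ensemble.

Ten gradient-boosted tree models are trained, each on the full positive
training set plus a freshly drawn negative subset of twice its size;
per-row weights are the inverse class frequencies over the three labels
(ID-PSP, noID-PSP, non-PSP).  The final score is the mean of the ten
member probabilities.  Missing feature values (NaN) are routed natively
by the tree learner, never imputed.

The tree backend is scikit-learn's HistGradientBoostingClassifier; the
hyperparameter surface keeps the familiar nine gradient-boosting names,
of which those without a direct equivalent in this backend (subsample,
colsample_bytree, gamma, reg_alpha) are accepted and ignored.
"""

from __future__ import annotations

import dataclasses
import json
import logging
from pathlib import Path
from typing import Dict, List, Optional, Sequence, Tuple

import joblib
import numpy as np
import pandas as pd
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score
from sklearn.model_selection import StratifiedKFold

from .features import feature_names

logger = logging.getLogger(__name__)

LABELS = ("ID-PSP", "noID-PSP", "non-PSP")
POSITIVE_LABELS = ("ID-PSP", "noID-PSP")
N_MEMBERS = 10
NEGATIVE_RATIO = 2  # negatives per positive in each training subset


@dataclasses.dataclass
class ScalerParams:
    """Per-feature (min, max) learned on training rows, NaN-ignoring."""

    mins: Dict[str, float]
    maxs: Dict[str, float]

    def __post_init__(self) -> None:
        for name in self.mins:
            if self.maxs[name] < self.mins[name]:
                raise ValueError(f"max < min for feature {name}")


def fit_scaler(train: pd.DataFrame) -> ScalerParams:
    if len(train) == 0:
        raise ValueError("cannot fit scaler on empty data")
    mins = train.min(axis=0, skipna=True)
    maxs = train.max(axis=0, skipna=True)
    return ScalerParams(mins=mins.to_dict(), maxs=maxs.to_dict())


def apply_scaler(params: ScalerParams, rows: pd.DataFrame) -> pd.DataFrame:
    """x' = (x − min) / (max − min); constant columns map to 0; NaN stays NaN.

    Values outside the training range are not clipped.
    """
    out = rows.copy()
    for name in rows.columns:
        lo, hi = params.mins[name], params.maxs[name]
        span = hi - lo
        if span == 0 or not np.isfinite(span):
            out[name] = np.where(rows[name].notna(), 0.0, np.nan)
        else:
            out[name] = (rows[name] - lo) / span
    return out


def class_weights(labels: Sequence[str]) -> np.ndarray:
    """Inverse-frequency weight per row: N_total / count(class of row)."""
    labels = list(labels)
    counts = pd.Series(labels).value_counts()
    for cls in set(labels):
        if counts.get(cls, 0) == 0:
            raise ValueError(f"empty class {cls}")
    total = len(labels)
    return np.array([total / counts[l] for l in labels], dtype=float)


def split_dataset(
    positives: pd.DataFrame,
    negatives: pd.DataFrame,
    seed: int = 42,
    reserved_ids: Sequence[str] = (),
) -> pd.DataFrame:
    """Assign train/test splits: each positive stratum (ID-PSP, noID-PSP)
    1:1, with reserved positives forced into training; negatives 1:1.

    Expects ``protein_id`` and ``label`` columns; returns the concatenated
    frame with a ``split`` column.  Deterministic under ``seed``.
    """
    rng = np.random.default_rng(seed)
    reserved = set(reserved_ids)
    frames: List[pd.DataFrame] = []
    for stratum in POSITIVE_LABELS:
        sub = positives[positives["label"] == stratum]
        if len(sub) == 0:
            continue
        if len(sub) < 2:
            raise ValueError(f"stratum {stratum} has fewer than 2 proteins")
        n_test = len(sub) // 2
        free = sub[~sub["protein_id"].isin(reserved)]
        if len(free) < n_test:
            raise ValueError(
                f"stratum {stratum}: too many reserved proteins to fill the test half"
            )
        test_ids = set(
            rng.choice(free["protein_id"].to_numpy(), size=n_test, replace=False)
        )
        sub = sub.copy()
        sub["split"] = np.where(sub["protein_id"].isin(test_ids), "test", "train")
        frames.append(sub)
    if len(negatives) < 2:
        raise ValueError("need at least 2 negatives")
    n_test = len(negatives) // 2
    test_ids = set(
        rng.choice(negatives["protein_id"].to_numpy(), size=n_test, replace=False)
    )
    neg = negatives.copy()
    neg["split"] = np.where(neg["protein_id"].isin(test_ids), "test", "train")
    frames.append(neg)
    out = pd.concat(frames, ignore_index=True)
    if out["protein_id"].duplicated().any():
        raise ValueError("duplicate protein ids across datasets")
    return out


def sample_negatives(
    negative_pool: Sequence[str],
    n_positives: int,
    round_index: int,
    seed: int = 42,
) -> List[str]:
    """Uniform draw of 2 × n_positives ids, deterministic per (seed, round)."""
    pool = list(negative_pool)
    size = NEGATIVE_RATIO * n_positives
    if len(pool) < size:
        raise ValueError(
            f"negative pool ({len(pool)}) smaller than required subset ({size})"
        )
    rng = np.random.default_rng([seed, round_index])
    return list(rng.choice(np.asarray(pool, dtype=object), size=size, replace=False))


@dataclasses.dataclass
class Hyperparameters:
    learning_rate: float = 0.1
    n_estimators: int = 200
    max_depth: int = 6
    min_child_weight: int = 5
    subsample: float = 1.0
    colsample_bytree: float = 1.0
    gamma: float = 0.0
    reg_lambda: float = 1.0
    reg_alpha: float = 0.0

    def to_sklearn(self) -> Dict[str, object]:
        ignored = {
            "subsample": self.subsample,
            "colsample_bytree": self.colsample_bytree,
            "gamma": self.gamma,
            "reg_alpha": self.reg_alpha,
        }
        defaults = Hyperparameters()
        for k, v in ignored.items():
            if v != getattr(defaults, k):
                logger.debug("hyperparameter %s=%s has no backend equivalent", k, v)
        return dict(
            learning_rate=self.learning_rate,
            max_iter=self.n_estimators,
            max_depth=self.max_depth,
            min_samples_leaf=max(1, int(round(self.min_child_weight))),
            l2_regularization=self.reg_lambda,
        )


#: Search space for hyperparameter tuning (conventional wide bounds).
SEARCH_SPACE = {
    "learning_rate": ("log", 0.01, 0.3),
    "n_estimators": ("int", 50, 400),
    "max_depth": ("int", 2, 10),
    "min_child_weight": ("int", 1, 10),
    "subsample": ("uniform", 0.5, 1.0),
    "colsample_bytree": ("uniform", 0.5, 1.0),
    "gamma": ("uniform", 0.0, 5.0),
    "reg_lambda": ("log", 1e-3, 10.0),
    "reg_alpha": ("log", 1e-3, 10.0),
}


def _sample_hp(rng: np.random.Generator) -> Hyperparameters:
    kwargs = {}
    for name, (kind, lo, hi) in SEARCH_SPACE.items():
        if kind == "log":
            kwargs[name] = float(np.exp(rng.uniform(np.log(lo), np.log(hi))))
        elif kind == "int":
            kwargs[name] = int(rng.integers(lo, hi + 1))
        else:
            kwargs[name] = float(rng.uniform(lo, hi))
    return Hyperparameters(**kwargs)


@dataclasses.dataclass
class EnsembleModel:
    members: List[HistGradientBoostingClassifier]
    scaler: ScalerParams
    hyperparameters: Hyperparameters
    schema: List[str]
    use_phos: bool
    seed: int

    def __post_init__(self) -> None:
        # production ensembles carry N_MEMBERS members; tuning folds may
        # train reduced ensembles for speed
        if not self.members:
            raise ValueError("ensemble needs at least one member")

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        for k, member in enumerate(self.members):
            joblib.dump(member, directory / f"member_{k}.joblib")
        meta = {
            "n_members": len(self.members),
            "schema": self.schema,
            "scaler": {"mins": self.scaler.mins, "maxs": self.scaler.maxs},
            "hyperparameters": dataclasses.asdict(self.hyperparameters),
            "use_phos": self.use_phos,
            "seed": self.seed,
        }
        (directory / "meta.json").write_text(json.dumps(meta, indent=2))

    @classmethod
    def load(cls, directory: str | Path) -> "EnsembleModel":
        directory = Path(directory)
        meta = json.loads((directory / "meta.json").read_text())
        members = [
            joblib.load(directory / f"member_{k}.joblib")
            for k in range(int(meta.get("n_members", N_MEMBERS)))
        ]
        return cls(
            members=members,
            scaler=ScalerParams(**meta["scaler"]),
            hyperparameters=Hyperparameters(**meta["hyperparameters"]),
            schema=list(meta["schema"]),
            use_phos=bool(meta["use_phos"]),
            seed=int(meta["seed"]),
        )


def _check_schema(df: pd.DataFrame, schema: Sequence[str]) -> pd.DataFrame:
    missing = [c for c in schema if c not in df.columns]
    extra = [
        c for c in df.columns
        if c not in schema and c not in ("protein_id", "label", "split")
    ]
    if missing or extra:
        raise ValueError(f"feature schema mismatch: missing={missing} extra={extra}")
    return df[list(schema)]


def train_ensemble(
    dataset: pd.DataFrame,
    hp: Optional[Hyperparameters] = None,
    seed: int = 42,
    use_phos: bool = False,
    n_members: int = N_MEMBERS,
) -> EnsembleModel:
    """Fit the negative-subsample ensemble on training rows.

    ``dataset`` carries ``protein_id``, ``label``, and the feature columns
    of :func:`phasesep.features.feature_names`.
    """
    hp = hp or Hyperparameters()
    schema = feature_names(use_phos=use_phos)
    X_all = _check_schema(dataset, schema)
    labels = dataset["label"]
    if not set(labels) <= set(LABELS):
        raise ValueError(f"unknown labels: {sorted(set(labels) - set(LABELS))}")
    pos_mask = labels.isin(POSITIVE_LABELS)
    if pos_mask.all() or not pos_mask.any():
        raise ValueError("training data must contain both positives and negatives")

    scaler = fit_scaler(X_all)
    X_scaled = apply_scaler(scaler, X_all)

    pos_idx = dataset.index[pos_mask]
    neg_idx = dataset.index[~pos_mask]
    members = []
    for round_index in range(n_members):
        subset = sample_negatives(list(neg_idx), len(pos_idx), round_index, seed)
        rows = list(pos_idx) + list(subset)
        y = pos_mask.loc[rows].to_numpy().astype(int)
        if len(set(y)) < 2:
            raise ValueError("degenerate single-class training subset")
        w = class_weights(labels.loc[rows])
        clf = HistGradientBoostingClassifier(random_state=seed, **hp.to_sklearn())
        clf.fit(X_scaled.loc[rows].to_numpy(), y, sample_weight=w)
        members.append(clf)
    return EnsembleModel(
        members=members,
        scaler=scaler,
        hyperparameters=hp,
        schema=schema,
        use_phos=use_phos,
        seed=seed,
    )


def predict(
    model: EnsembleModel, features: pd.DataFrame
) -> Tuple[np.ndarray, np.ndarray]:
    """(mean score, member std) per row; score is the mean of the ten
    member probabilities."""
    X = _check_schema(features, model.schema)
    X_scaled = apply_scaler(model.scaler, X).to_numpy()
    probs = np.stack([m.predict_proba(X_scaled)[:, 1] for m in model.members])
    return probs.mean(axis=0), probs.std(axis=0)


def tune_hyperparameters(
    dataset: pd.DataFrame,
    n_trials: int = 50,
    seed: int = 42,
    use_phos: bool = False,
    n_folds: int = 5,
    n_members: int = N_MEMBERS,
) -> Tuple[Hyperparameters, List[Tuple[Hyperparameters, float]]]:
    """Random search over the documented bounds, scored by stratified
    5-fold CV AUROC on ID-PSP vs non-PSP validation rows.

    Within each fold the positive training rows stay fixed and the usual
    ten negative subsets are drawn.  Returns the best configuration and
    the full trial history.
    """
    labels = dataset["label"].to_numpy()
    if "ID-PSP" not in labels:
        raise ValueError("tuning requires ID-PSP rows")
    rng = np.random.default_rng(seed)
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    folds = list(skf.split(np.zeros(len(dataset)), labels))

    history: List[Tuple[Hyperparameters, float]] = []
    best: Optional[Tuple[Hyperparameters, float]] = None
    for trial in range(n_trials):
        hp = _sample_hp(rng)
        fold_aucs = []
        for train_rows, val_rows in folds:
            train_df = dataset.iloc[train_rows]
            val_df = dataset.iloc[val_rows]
            if "ID-PSP" not in set(val_df["label"]):
                raise ValueError("a fold lacks ID-PSP validation rows")
            ens = train_ensemble(
                train_df, hp=hp, seed=seed, use_phos=use_phos, n_members=n_members
            )
            keep = val_df["label"].isin(["ID-PSP", "non-PSP"])
            scores, _ = predict(ens, val_df[keep])
            y = (val_df[keep]["label"] == "ID-PSP").to_numpy().astype(int)
            fold_aucs.append(roc_auc_score(y, scores))
        objective = float(np.mean(fold_aucs))
        history.append((hp, objective))
        if best is None or objective > best[1]:
            best = (hp, objective)
        logger.info("trial %d/%d: CV AUROC %.4f", trial + 1, n_trials, objective)
    assert best is not None
    return best[0], history
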