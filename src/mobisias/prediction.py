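"""Hierarchical daily SIAS prediction and its evaluation protocol.

The main method ("OM") trains one multilayer perceptron (2 hidden layers of
100 tanh units) on *daily* feature vectors, every day inheriting its
participant's SIAS total (regression) or high/low group (classification).
At prediction time each of a participant's days yields a candidate score;
candidates are aggregated with a 7% trimmed mean (regression) or a majority
vote with a seeded random tie-break (classification).  Two baselines share
the MLP architecture but differ in features: BM1 aggregates daily features
over the study period into one vector per participant; BM2 concatenates a
fixed number of daily vectors per participant and projects them onto
principal components fitted on the training participants only.

Evaluation follows leave-one-participant-out CV (all of a participant's
days held out together) or a balanced 10-fold CV whose validation folds
contain equal numbers of high and low participants.  Standardization, PCA
and model weights are always functions of the training fold only.
"""

from __future__ import annotations

from collections import Counter
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import trim_mean
from sklearn.compose import TransformedTargetRegressor
from sklearn.decomposition import PCA
from sklearn.metrics import f1_score
from sklearn.neural_network import MLPClassifier, MLPRegressor
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler

from .features import FEATURE_NAMES
from .io import SIAS_CUTOFF, classify_sias

__all__ = [
    "DailyModelConfig",
    "trimmed_mean",
    "majority_class",
    "bm1_features",
    "bm2_matrix",
    "SiasModel",
    "HierarchicalSiasModel",
    "SiasModelResults",
    "SiasEvalReport",
    "evaluate",
    "learning_curve",
]

_STAY_COLS = [c for c in FEATURE_NAMES if c.startswith("stay_frac_")]
_TRANS_COLS = [c for c in FEATURE_NAMES if c.startswith("trans_")]
_OCC_COLS = [c for c in FEATURE_NAMES if c.startswith("occ_")]


@dataclass(frozen=True)
class DailyModelConfig:
    """MLP architecture and training settings (architecture fixed by design)."""

    hidden_layers: tuple[int, int] = (100, 100)
    activation: str = "tanh"
    max_epochs: int = 500
    early_stopping: bool = True
    validation_fraction: float = 0.1
    patience: int = 12
    learning_rate_init: float = 1e-3
    alpha: float = 1e-4
    batch_size: int | str = "auto"
    trim_fraction: float = 0.07


def trimmed_mean(values, trim_fraction: float = 0.07) -> float:
    """Mean after dropping floor(trim_fraction * n) values from each tail."""
    values = np.asarray(values, dtype=float)
    if values.size == 0:
        raise ValueError("trimmed_mean of empty input")
    return float(trim_mean(values, trim_fraction))


def majority_class(values, seed: int | np.random.Generator = 0) -> str:
    """Modal class; exact ties are broken by a seeded uniform draw."""
    values = list(values)
    if not values:
        raise ValueError("majority_class of empty input")
    counts = Counter(values)
    best = max(counts.values())
    tied = sorted(c for c, n in counts.items() if n == best)
    if len(tied) == 1:
        return tied[0]
    rng = seed if isinstance(seed, np.random.Generator) else np.random.default_rng(seed)
    return tied[int(rng.integers(len(tied)))]


def _make_mlp(task: str, config: DailyModelConfig, seed: int):
    kwargs = dict(
        hidden_layer_sizes=config.hidden_layers,
        activation=config.activation,
        solver="adam",
        alpha=config.alpha,
        learning_rate_init=config.learning_rate_init,
        batch_size=config.batch_size,
        max_iter=config.max_epochs,
        early_stopping=config.early_stopping,
        validation_fraction=config.validation_fraction,
        n_iter_no_change=config.patience,
        random_state=int(seed) % (2**31),
    )
    if task == "regression":
        pipe = Pipeline([("scale", StandardScaler()), ("mlp", MLPRegressor(**kwargs))])
        # scale the target too: the raw 0-80 score is far from the net's
        # initial output range and stalls small-sample training
        return TransformedTargetRegressor(regressor=pipe, transformer=StandardScaler())
    return Pipeline([("scale", StandardScaler()), ("mlp", MLPClassifier(**kwargs))])


# ---------------------------------------------------------------------------
# baseline feature builders


_DAILY_STAY_COLS = [c for c in _STAY_COLS if c.endswith("_daily")]


def bm1_features(participant_days: pd.DataFrame, include_epochs: bool = True,
                 include_occupancy: bool = True) -> np.ndarray:
    """Study-period aggregate vector for one participant (baseline BM1).

    BM1 uses the same mobility features as the daily method but averaged
    over the whole study period: means of the daily staying-time fractions
    (all epochs), visit-occupancy bins, entropy and transition counts, plus
    weekday/weekend staying-time means.  The flags allow slimmer variants.
    Day-type means fall back to the all-day means when a participant has no
    day of that type.
    """
    if participant_days.empty:
        raise ValueError("participant has no observed days")
    stay_cols = _STAY_COLS if include_epochs else _DAILY_STAY_COLS
    overall = participant_days.mean()
    parts = [overall[stay_cols].to_numpy(), [overall["entropy"]],
             overall[_TRANS_COLS].to_numpy()]
    if include_occupancy:
        parts.append(overall[_OCC_COLS].to_numpy())
    for flag in (0.0, 1.0):
        sub = participant_days[participant_days["is_weekend"] == flag]
        src = sub.mean() if len(sub) else overall
        parts.append(src[stay_cols].to_numpy())
    return np.concatenate([np.atleast_1d(np.asarray(p, dtype=float)) for p in parts])


def _bm1_matrix(features: pd.DataFrame, pids: list[str]) -> np.ndarray:
    return np.vstack([bm1_features(features.loc[pid]) for pid in pids])


def bm2_matrix(
    features: pd.DataFrame,
    pids: list[str],
    n_days: int = 14,
) -> np.ndarray:
    """Concatenated per-day vectors, zero-padded/truncated to ``n_days``.

    A trailing observed-day-count column records how many real days each
    participant contributed.
    """
    cols = len(FEATURE_NAMES)
    out = np.zeros((len(pids), cols * n_days + 1))
    for i, pid in enumerate(pids):
        days = features.loc[pid].sort_index().to_numpy()[:n_days]
        out[i, : days.size] = days.ravel()
        out[i, -1] = days.shape[0]
    return out


def bm2_projection(train_matrix: np.ndarray, n_components: int) -> PCA:
    """Centered PCA fitted on training participants only."""
    if n_components >= min(train_matrix.shape):
        raise ValueError(
            f"n_components={n_components} must be < min(n_samples, n_features)"
            f"={min(train_matrix.shape)}"
        )
    return PCA(n_components=n_components, svd_solver="auto").fit(train_matrix)


# ---------------------------------------------------------------------------
# model / results


class SiasModel:
    """A SIAS predictor built from a cohort's daily feature table.

    Parameters
    ----------
    features : DataFrame indexed by (participant_id, date) with the daily
        feature columns.
    sias : mapping participant_id -> SIAS total (0-80).
    method : "om" (hierarchical daily method), "bm1", or "bm2".
    task : "regression" or "classification".
    """

    def __init__(
        self,
        features: pd.DataFrame,
        sias: dict[str, int],
        method: str = "om",
        task: str = "regression",
        config: DailyModelConfig | None = None,
        cutoff: int = SIAS_CUTOFF,
        bm2_days: int = 14,
        bm2_components: int = 200,
    ):
        if method not in ("om", "bm1", "bm2"):
            raise ValueError(f"unknown method {method!r}")
        if task not in ("regression", "classification"):
            raise ValueError(f"unknown task {task!r}")
        self.features = features
        self.sias = dict(sias)
        self.method = method
        self.task = task
        self.config = config or DailyModelConfig()
        self.cutoff = cutoff
        self.bm2_days = bm2_days
        self.bm2_components = bm2_components
        self.participants = sorted(features.index.get_level_values(0).unique())
        missing = [p for p in self.participants if p not in self.sias]
        if missing:
            raise ValueError(f"participants without SIAS score: {missing[:3]}")

    def _target(self, pid: str):
        if self.task == "regression":
            return float(self.sias[pid])
        return classify_sias(self.sias[pid], self.cutoff)

    def fit(self, seed: int = 0) -> "SiasModelResults":
        """Train the daily (OM) or participant-level (BM1/BM2) model."""
        pids = self.participants
        if self.method == "om":
            X = self.features.to_numpy()
            day_pids = self.features.index.get_level_values(0)
            y = np.array([self._target(p) for p in day_pids])
        elif self.method == "bm1":
            X = _bm1_matrix(self.features, pids)
            y = np.array([self._target(p) for p in pids])
        else:
            X = bm2_matrix(self.features, pids, self.bm2_days)
            y = np.array([self._target(p) for p in pids])
        if self.task == "classification":
            if len(set(y)) < 2:
                raise ValueError("classification training requires both SIAS groups")
            # balance the classes by oversampling the minority (the cohort
            # skews low-SIAS; unweighted training biases every day vote and
            # the majority aggregation amplifies that bias)
            rng = np.random.default_rng(seed)
            classes, counts = np.unique(y, return_counts=True)
            n_max = counts.max()
            idx = []
            for c, n_c in zip(classes, counts):
                rows = np.nonzero(y == c)[0]
                if n_c < n_max:
                    extra = rng.choice(rows, size=n_max - n_c, replace=True)
                    rows = np.concatenate([rows, extra])
                idx.append(rows)
            idx = np.concatenate(idx)
            X, y = X[idx], y[idx]
        pca = None
        if self.method == "bm2":
            ncomp = min(self.bm2_components, X.shape[0] - 1, X.shape[1] - 1)
            pca = bm2_projection(X, ncomp)
            X = pca.transform(X)
        pipe = _make_mlp(self.task, self.config, seed)
        pipe.fit(X, y)
        return SiasModelResults(model=self, pipeline=pipe, pca=pca,
                                train_participants=list(pids), seed=int(seed))


@dataclass
class SiasModelResults:
    """Fitted SIAS predictor: per-participant predictions and diagnostics."""

    model: SiasModel
    pipeline: Pipeline
    pca: PCA | None
    train_participants: list[str]
    seed: int

    def predict_candidates(self, participant_days: pd.DataFrame) -> np.ndarray:
        """Per-day candidate scores/classes for one participant (OM only)."""
        if self.model.method != "om":
            raise ValueError("daily candidates exist only for the hierarchical method")
        if participant_days.empty:
            raise ValueError("no observed days to predict from")
        out = self.pipeline.predict(participant_days.to_numpy())
        if self.model.task == "regression":
            out = np.clip(out, 0.0, 80.0)
        return out

    def predict(self, features: pd.DataFrame | None = None, seed: int | None = None) -> pd.Series:
        """Aggregated per-participant predictions.

        Regression: 7% trimmed mean of the day candidates, clipped to
        [0, 80].  Classification: majority class with seeded tie-break.
        BM1/BM2 predict directly from the participant-level vector.
        """
        feats = self.model.features if features is None else features
        pids = sorted(feats.index.get_level_values(0).unique())
        rng = np.random.default_rng(self.seed if seed is None else seed)
        m = self.model
        if m.method == "om":
            vals = {}
            for pid in pids:
                cand = self.predict_candidates(feats.loc[pid])
                if m.task == "regression":
                    v = float(np.clip(trimmed_mean(cand, m.config.trim_fraction), 0, 80))
                else:
                    v = majority_class(cand, rng)
                vals[pid] = v
            return pd.Series(vals, name="sias_pred")
        X = (
            _bm1_matrix(feats, pids)
            if m.method == "bm1"
            else bm2_matrix(feats, pids, m.bm2_days)
        )
        if self.pca is not None:
            X = self.pca.transform(X)
        pred = self.pipeline.predict(X)
        if m.task == "regression":
            pred = np.clip(pred, 0.0, 80.0)
        return pd.Series(pred, index=pids, name="sias_pred")

    def summary(self) -> str:
        m = self.model
        lines = [
            "SIAS prediction model",
            "=" * 40,
            f"method:        {m.method.upper()}",
            f"task:          {m.task}",
            f"architecture:  MLP {m.config.hidden_layers}, {m.config.activation}",
            f"participants:  {len(self.train_participants)}",
            f"training days: {len(m.features)}",
            f"seed:          {self.seed}",
        ]
        if self.pca is not None:
            lines.append(f"PCA components: {self.pca.n_components_}")
        return "\n".join(lines)


def HierarchicalSiasModel(features, sias, task="regression", **kw) -> SiasModel:
    """The hierarchical daily method (OM) as a model constructor."""
    return SiasModel(features, sias, method="om", task=task, **kw)


# ---------------------------------------------------------------------------
# evaluation protocol


@dataclass
class SiasEvalReport:
    """Cross-validated performance of one method on one task."""

    method: str
    task: str
    scheme: str
    fold_metrics: pd.DataFrame
    predictions: pd.Series
    folds: list[tuple[list[str], list[str]]]  # (train pids, test pids) per fold
    cutoff: int = SIAS_CUTOFF

    @property
    def rmse(self) -> float:
        return float(self.fold_metrics["rmse"].mean()) if "rmse" in self.fold_metrics else float("nan")

    @property
    def rmse_sd(self) -> float:
        return float(self.fold_metrics["rmse"].std(ddof=1)) if "rmse" in self.fold_metrics else float("nan")

    @property
    def accuracy(self) -> float:
        return float(self.fold_metrics["accuracy"].mean()) if "accuracy" in self.fold_metrics else float("nan")

    @property
    def accuracy_sd(self) -> float:
        return float(self.fold_metrics["accuracy"].std(ddof=1)) if "accuracy" in self.fold_metrics else float("nan")

    @property
    def f1(self) -> float:
        """Pooled F-1 over all held-out participants (high class positive)."""
        if self.task != "classification":
            return float("nan")
        truth, pred = self._pooled()
        return float(f1_score(truth, pred, pos_label="high"))

    def _pooled(self):
        truth = [self._truth[p] for p in self.predictions.index]
        return truth, list(self.predictions)

    def summary(self) -> str:
        lines = [
            f"SIAS {self.task} evaluation ({self.method.upper()}, {self.scheme})",
            "=" * 48,
            f"folds: {len(self.folds)}",
        ]
        if self.task == "regression":
            lines.append(f"RMSE: {self.rmse:.2f} (SD {self.rmse_sd:.2f})")
        else:
            lines.append(f"accuracy: {self.accuracy:.3f} (SD {self.accuracy_sd:.3f})")
            lines.append(f"F-1 (high): {self.f1:.3f}")
        return "\n".join(lines)


def _balanced_folds(pids, sias, cutoff, n_folds, rng):
    """Folds with equal numbers of high and low participants per test fold."""
    high = sorted(p for p in pids if sias[p] >= cutoff)
    low = sorted(p for p in pids if sias[p] < cutoff)
    rng.shuffle(high)
    rng.shuffle(low)
    k = min(len(high), len(low)) // n_folds
    if k == 0:
        raise ValueError(
            f"cannot build {n_folds} balanced folds from {len(high)} high / "
            f"{len(low)} low participants"
        )
    folds = []
    for i in range(n_folds):
        test = sorted(high[i * k : (i + 1) * k] + low[i * k : (i + 1) * k])
        train = sorted(set(pids) - set(test))
        folds.append((train, test))
    return folds


def evaluate(
    features: pd.DataFrame,
    sias: dict[str, int],
    method: str = "om",
    task: str = "regression",
    scheme: str = "fcv10",
    seed: int = 0,
    config: DailyModelConfig | None = None,
    cutoff: int = SIAS_CUTOFF,
    n_folds: int = 10,
    **model_kw,
) -> SiasEvalReport:
    """Cross-validated evaluation with participant-level held-out folds.

    ``scheme`` is ``"loocv"`` (leave one participant out, all their days
    together) or ``"fcv10"`` (balanced folds; exact 12 high + 12 low per
    fold when the cohort supports it, else the largest equal per-class
    count).  Metrics: fold-mean RMSE (regression) or accuracy (and pooled
    F-1, high class positive) for classification.
    """
    pids = sorted(features.index.get_level_values(0).unique())
    rng = np.random.default_rng(seed)
    if scheme == "loocv":
        folds = [(sorted(set(pids) - {p}), [p]) for p in pids]
    elif scheme == "fcv10":
        folds = _balanced_folds(list(pids), sias, cutoff, n_folds, rng)
    else:
        raise ValueError(f"unknown scheme {scheme!r}")

    rows = []
    preds: dict[str, float | str] = {}
    for train, test in folds:
        assert not set(train) & set(test), "participant leaked across the fold split"
        fold_seed = int(rng.integers(2**31))
        model = SiasModel(
            features.loc[train], sias, method=method, task=task,
            config=config, cutoff=cutoff, **model_kw,
        )
        res = model.fit(fold_seed)
        p = res.predict(features.loc[test], seed=fold_seed)
        row: dict[str, float] = {}
        if task == "regression":
            truth = np.array([sias[q] for q in p.index], dtype=float)
            row["rmse"] = float(np.sqrt(np.mean((p.to_numpy(dtype=float) - truth) ** 2)))
        else:
            truth = [classify_sias(sias[q], cutoff) for q in p.index]
            row["accuracy"] = float(np.mean([a == b for a, b in zip(p, truth)]))
        rows.append(row)
        preds.update(p.to_dict())

    report = SiasEvalReport(
        method=method,
        task=task,
        scheme=scheme,
        fold_metrics=pd.DataFrame(rows),
        predictions=pd.Series(preds).sort_index(),
        folds=folds,
        cutoff=cutoff,
    )
    report._truth = {
        p: (float(sias[p]) if task == "regression" else classify_sias(sias[p], cutoff))
        for p in report.predictions.index
    }
    return report


def learning_curve(
    features: pd.DataFrame,
    sias: dict[str, int],
    method: str = "om",
    day_counts=range(1, 15),
    seed: int = 0,
    scheme: str = "fcv10",
    config: DailyModelConfig | None = None,
    **kw,
) -> pd.Series:
    """Fold-mean regression RMSE using only each participant's first k days."""
    feats = features.sort_index()
    out = {}
    for k in day_counts:
        sub = feats.groupby(level="participant_id", group_keys=False).head(int(k))
        rep = evaluate(sub, sias, method=method, task="regression",
                       scheme=scheme, seed=seed, config=config, **kw)
        out[int(k)] = rep.rmse
    return pd.Series(out, name="rmse")
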